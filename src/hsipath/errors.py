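"""Exception hierarchy shared across the pipeline stages."""


class HsipathError(Exception):
    """Base class for all package errors."""


class FormatError(HsipathError):
    """Binary payload inconsistent with the declared shape/dtype."""


class HeaderError(HsipathError):
    """ENVI-style header missing or unparseable."""


class CalibrationError(HsipathError):
    """Degenerate input to flat-field or transmission standardization."""


class StageError(HsipathError):
    """Artifact fed to a stage it is not calibrated/prepared for."""


class ShapeError(HsipathError):
    """Layer arithmetic produced a non-positive feature-map extent."""


class DependencyError(HsipathError):
    """Pipeline stage missing an upstream artifact."""
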