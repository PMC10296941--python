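"""Flat-field calibration and transmission-spectrum standardization.

The scanner acquires one spatial column at a time, so uneven smear or
staining shows up as column-wise brightness structure.  Flat-fielding
divides every pixel of a scanning column, per band, by a trimmed mean of
that column (the largest and smallest values are excluded as outliers).
A second step removes global brightness differences between slides
(slice thickness, lamp intensity) by dividing every spectrum by the mean
spectrum of a background region without tissue, yielding a unitless
transmittance normalized so the background averages to one per band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datacube import DataCube
from .errors import CalibrationError, StageError

__all__ = [
    "CalibrationConfig",
    "flat_field",
    "transmission_standardize",
    "auto_background",
    "calibrate",
]

#: rows below which the default trim count of 150 is scaled down
_FULL_SCALE_ROWS = 601


@dataclass
class CalibrationConfig:
    """Knobs of the two calibration steps.

    trim_count
        Pixels excluded at each extreme of a column, per band, before
        averaging (default 150, the acquisition-scale value for
        1000-row columns).  For cubes with fewer than 601 rows the
        effective count scales down to ``(rows - 1) // 4`` so that toy
        cubes remain calibratable.
    epsilon_frac
        Division guard: column means below ``epsilon_frac * max(cube)``
        are floored to it.
    """

    trim_count: int = 150
    epsilon_frac: float = 1e-8

    def effective_trim(self, rows: int) -> int:
        trim = self.trim_count
        if rows < _FULL_SCALE_ROWS:
            trim = min(trim, (rows - 1) // 4)
        if 2 * trim >= rows:
            raise ValueError(
                f"trim_count {trim} leaves no pixels in a {rows}-row column"
            )
        return trim


def _trimmed_column_means(values: np.ndarray, trim: int) -> np.ndarray:
    """Per (band, column) mean after dropping `trim` extremes each end."""
    rows = values.shape[1]
    ordered = np.sort(values, axis=1)  # sorts each column within each band
    kept = ordered[:, trim : rows - trim, :]
    return kept.mean(axis=1)  # (bands, cols)


def flat_field(cube: DataCube, config: CalibrationConfig | None = None) -> DataCube:
    """Column-wise flat-field calibration (stage ``raw`` -> ``even``).

    For each (band, column) the column's values are sorted, the
    ``trim_count`` largest and smallest dropped, the remaining ``p``
    values averaged, and every pixel of the column divided by that
    average.
    """
    if config is None:
        config = CalibrationConfig()
    values = np.asarray(cube.values, dtype=np.float64)
    rows = values.shape[1]
    trim = config.effective_trim(rows)
    means = _trimmed_column_means(values, trim)

    dead = np.all(means == 0, axis=0)
    if dead.any():
        col = int(np.flatnonzero(dead)[0])
        raise CalibrationError(f"column {col} is all zero after trimming")

    floor = config.epsilon_frac * max(values.max(), 1.0)
    means = np.maximum(means, floor)
    out = values / means[:, None, :]
    return replace(cube, values=out, stage="even")


def transmission_standardize(
    cube: DataCube,
    background_mask: np.ndarray,
    epsilon: float = 1e-12,
) -> DataCube:
    """Divide every spectrum by the mean background spectrum SC.

    ``background_mask`` selects pixels without tissue or medium coating;
    SC is their per-band mean.  After standardization the background
    averages to exactly one in every band and the cube is scale
    invariant: multiplying the input by any positive constant leaves the
    output unchanged.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != cube.values.shape[1:]:
        raise ValueError("background mask extent does not match the cube")
    if not mask.any():
        raise ValueError("background mask selects no pixels")
    values = np.asarray(cube.values, dtype=np.float64)
    sc = values[:, mask].mean(axis=1)  # (bands,)
    weak = np.flatnonzero(sc <= epsilon)
    if weak.size:
        raise CalibrationError(
            f"background reference spectrum non-positive in band {int(weak[0])}"
        )
    out = values / sc[:, None, None]
    return replace(cube, values=out, stage="tran")


def auto_background(
    cube: DataCube,
    quantile: float = 0.95,
    cv_threshold: float = 0.05,
) -> np.ndarray:
    """Detect the bright, spectrally flat no-tissue region.

    Marks pixels whose band-mean intensity exceeds the ``quantile``-th
    quantile of the image and whose spectral coefficient of variation is
    below ``cv_threshold``.  Background on a transmitted-light slide is
    bright (nothing absorbs) and flat (no chromophore features).
    """
    if cube.stage not in ("even", "tran"):
        raise StageError("auto_background expects a flat-fielded cube")
    values = np.asarray(cube.values, dtype=np.float64)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.maximum(mean, 1e-30), np.inf)
    mask = (mean >= np.quantile(mean, quantile)) & (cv < cv_threshold)
    if not mask.any():
        raise CalibrationError(
            "no bright spectrally-flat region found; supply a background mask"
        )
    return mask


def calibrate(
    cube: DataCube,
    config: CalibrationConfig | None = None,
    background_mask: np.ndarray | None = None,
) -> DataCube:
    """Full calibration: flat-field then transmission standardization."""
    even = flat_field(cube, config)
    if background_mask is None:
        background_mask = auto_background(even)
    return transmission_standardize(even, background_mask)
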