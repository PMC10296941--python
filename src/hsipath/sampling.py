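"""Sample extraction: spectral windows, spatial patches, blanks, augmentation.

Two sample families feed the classifiers.  Spectral samples are small
``bands x 9 x 9`` windows centered on individually annotated cell pixels
(cancer / normal) and train the 3D spectral network.  Patch samples are
``250 x 250`` tiles of a slide image (the pseudo-color composite or the
full cube) and train the 2D image branch; a slide image tiles into a
non-overlapping row-major grid, and mostly-blank tiles are discarded.

Because microscopic tissue morphology is scale-bearing, augmentation is
restricted to rigid operations: the 8 dihedral variants (rotations and
flips) plus translation realized as jittered crop offsets at extraction
time.  No scaling operator exists in this API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datacube import DataCube, LabelMap, LABEL_CODES
from .errors import StageError

__all__ = [
    "SpectralSample",
    "PatchSample",
    "tile_patches",
    "blank_fraction",
    "extract_patch_dataset",
    "extract_spectral_samples",
    "dihedral_variants",
    "augment",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 9
DEFAULT_PATCH = 250
DEFAULT_BLANK_THRESHOLD = 0.92
DEFAULT_BLANK_FRACTION = 0.5
DEFAULT_PURITY = 0.8


@dataclass
class SpectralSample:
    """bands x w x w window centered on a labeled cell pixel."""

    window: np.ndarray
    label: str  # "cancer" | "normal"
    center: tuple[int, int]

    def __post_init__(self) -> None:
        if self.label not in ("cancer", "normal"):
            raise ValueError(f"label must be cancer/normal, got {self.label!r}")
        if self.window.shape[1] != self.window.shape[2]:
            raise ValueError("spectral window must be spatially square")


@dataclass
class PatchSample:
    """channels x s x s tile of a slide image."""

    pixels: np.ndarray
    label: str
    origin: tuple[int, int]
    source_id: str = ""
    jittered: bool = False

    @property
    def size(self) -> int:
        return self.pixels.shape[-1]


def tile_patches(shape_or_image, patch_size: int = DEFAULT_PATCH) -> list[tuple[int, int]]:
    """Origins of the non-overlapping patch grid, row-major from top-left.

    A 1000 x 1000 slide image with the default size yields 16 patches,
    numbered 1..16 row-major (patch ``i`` has origin ``origins[i-1]``).
    """
    if isinstance(shape_or_image, np.ndarray):
        h, w = shape_or_image.shape[-2:]
    else:
        h, w = shape_or_image
    if h < patch_size or w < patch_size:
        log.warning("image %dx%d smaller than patch size %d", h, w, patch_size)
        return []
    return [
        (r * patch_size, c * patch_size)
        for r in range(h // patch_size)
        for c in range(w // patch_size)
    ]


def blank_fraction(
    patch_values: np.ndarray,
    blank_threshold: float = DEFAULT_BLANK_THRESHOLD,
) -> float:
    """Fraction of patch pixels that look like empty glass.

    Operates on a ``(bands, h, w)`` transmittance patch; a pixel is blank
    when its band-mean transmittance exceeds ``blank_threshold`` (empty
    glass transmits ~1, absorbing tissue less).
    """
    mean = np.asarray(patch_values, dtype=np.float64).mean(axis=0)
    return float((mean > blank_threshold).mean())


def _patch_label(
    labels: np.ndarray,
    purity: float,
) -> str | None:
    """Majority class among labeled pixels, None if too mixed or unlabeled."""
    n_cancer = int((labels == LABEL_CODES["cancer"]).sum())
    n_normal = int((labels == LABEL_CODES["normal"]).sum())
    total = n_cancer + n_normal
    if total == 0:
        return None
    if n_cancer / total >= purity:
        return "cancer"
    if n_normal / total >= purity:
        return "normal"
    return None


def extract_patch_dataset(
    cube: DataCube,
    labels: LabelMap,
    patch_size: int = DEFAULT_PATCH,
    blank_threshold: float = DEFAULT_BLANK_THRESHOLD,
    max_blank_fraction: float = DEFAULT_BLANK_FRACTION,
    purity: float = DEFAULT_PURITY,
    image: np.ndarray | None = None,
) -> list[PatchSample]:
    """Tile a calibrated slide and keep pure, non-blank labeled patches.

    The whole area is traversed; tiles dominated by blank glass are
    removed, and tiles mixing cancer and normal annotation above the
    purity bound are excluded (and logged).  ``image`` optionally
    supplies the pixel payload (e.g. a 3-channel composite aligned to
    the cube); by default patches carry the cube's full bands.
    """
    if cube.stage != "tran":
        raise StageError("patch extraction expects a transmittance cube")
    if labels.labels.shape != cube.shape[1:]:
        raise ValueError("label map extent does not match the cube")
    payload = cube.values if image is None else np.asarray(image)
    if payload.shape[-2:] != cube.shape[1:]:
        raise ValueError("image extent does not match the cube")
    out: list[PatchSample] = []
    for r0, c0 in tile_patches(cube.shape[1:], patch_size):
        sl = (slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
        if blank_fraction(cube.values[(slice(None),) + sl], blank_threshold) > max_blank_fraction:
            continue
        label = _patch_label(labels.labels[sl], purity)
        if label is None:
            if (labels.labels[sl] > 0).any():
                log.info("patch at %s excluded: mixed annotation", (r0, c0))
            continue
        out.append(
            PatchSample(
                pixels=payload[(slice(None),) + sl].copy(),
                label=label,
                origin=(r0, c0),
                source_id=cube.acquisition_id,
            )
        )
    return out


def extract_spectral_samples(
    cube: DataCube,
    labels: LabelMap,
    window: int = DEFAULT_WINDOW,
    centers: list[tuple[int, int]] | None = None,
) -> list[SpectralSample]:
    """One window per labeled cancer/normal cell pixel.

    Centers closer than ``window // 2`` to a border are skipped rather
    than padded — padding would fabricate tissue.  ``centers`` restricts
    extraction to the given pixel list (still label- and border-checked).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if cube.stage != "tran":
        raise StageError("spectral samples expect a transmittance cube")
    half = window // 2
    _, rows, cols = cube.shape
    lab = labels.labels
    if centers is None:
        keep = (lab == LABEL_CODES["cancer"]) | (lab == LABEL_CODES["normal"])
        centers = [tuple(rc) for rc in np.argwhere(keep)]
    out: list[SpectralSample] = []
    for r, c in centers:
        if not (half <= r < rows - half and half <= c < cols - half):
            continue
        code = lab[r, c]
        if code == LABEL_CODES["cancer"]:
            label = "cancer"
        elif code == LABEL_CODES["normal"]:
            label = "normal"
        else:
            continue
        win = cube.values[:, r - half : r + half + 1, c - half : c + half + 1]
        out.append(SpectralSample(window=win.copy(), label=label, center=(int(r), int(c))))
    return out


def dihedral_variants(pixels: np.ndarray) -> list[np.ndarray]:
    """The 8 rigid variants of a square patch: 4 rotations x reflection."""
    if pixels.shape[-1] != pixels.shape[-2]:
        raise ValueError("dihedral variants require a square patch")
    out = []
    current = pixels
    for _ in range(4):
        out.append(current)
        out.append(current[..., ::-1])  # horizontal flip: (r, c) -> (r, W-1-c)
        current = np.rot90(current, axes=(-2, -1))
    return [np.ascontiguousarray(v) for v in out]


def augment(patch: PatchSample, ops: set[str] | None = None) -> list[PatchSample]:
    """Rigid augmentation of a patch; labels are preserved.

    ``ops`` may contain ``rotate90`` and ``flip``; with both, the full
    dihedral group of 8 variants is produced (the identity included).
    Translation jitter belongs at extraction time (crop offsets), not
    here, so it is deliberately absent from this operator.
    """
    if ops is None:
        ops = {"rotate90", "flip"}
    unknown = ops - {"rotate90", "flip"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    variants = dihedral_variants(patch.pixels)
    if "rotate90" not in ops:
        variants = variants[:2]  # identity + flip only
    if "flip" not in ops:
        variants = variants[::2]  # rotations only
    return [
        PatchSample(
            pixels=v,
            label=patch.label,
            origin=patch.origin,
            source_id=patch.source_id,
            jittered=patch.jittered,
        )
        for v in variants
    ]


def jittered_origin(
    origin: tuple[int, int],
    patch_size: int,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    jitter: int = 25,
) -> tuple[int, int]:
    """Translate a crop origin by up to ±jitter px, clipped to the image."""
    h, w = image_shape
    r = int(origin[0] + rng.integers(-jitter, jitter + 1))
    c = int(origin[1] + rng.integers(-jitter, jitter + 1))
    return (
        int(np.clip(r, 0, h - patch_size)),
        int(np.clip(c, 0, w - patch_size)),
    )
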