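"""Principal-component analysis of pixel spectra and pseudo-color synthesis.

Adjacent spectral bands are strongly correlated, so a handful of
principal components carries nearly all the variance of a calibrated
cube.  Score images of selected components are stretched and stacked as
RGB channels to form pseudo-color composites (e.g. "PCA134" = PC1, PC3,
PC4 as the three channels) that feed the 2D image-classification branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datacube import DataCube

__all__ = [
    "PCAModel",
    "CompositeSpec",
    "fit_pca",
    "transform",
    "explained_proportion",
    "pseudocolor",
    "composite_from_cube",
]


@dataclass
class PCAModel:
    """Covariance eigendecomposition of a set of spectra.

    components are stored row-wise, orthonormal, sorted by descending
    eigenvalue; each component's sign is fixed so its largest-magnitude
    loading is positive.  Covariance uses the n-1 denominator.
    """

    mean_spectrum: np.ndarray
    components: np.ndarray  # (n_components, bands)
    eigenvalues: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def n_bands(self) -> int:
        return self.components.shape[1]


@dataclass
class CompositeSpec:
    """Ordered triple of 1-based PC indices forming the RGB channels."""

    channel_pcs: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.channel_pcs = tuple(int(i) for i in self.channel_pcs)
        if len(self.channel_pcs) != 3 or min(self.channel_pcs) < 1:
            raise ValueError("channel_pcs must be three 1-based PC indices")

    @classmethod
    def from_code(cls, code: str | int) -> "CompositeSpec":
        """Parse a shorthand like ``134`` or ``"514"``."""
        digits = str(code)
        if len(digits) != 3 or not digits.isdigit():
            raise ValueError(f"composite code must be three digits, got {code!r}")
        return cls(tuple(int(d) for d in digits))


def fit_pca(pixels: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Eigendecompose the band-covariance of an ``(N, B)`` spectra matrix."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("pixels must be an (N, B) matrix")
    n, b = pixels.shape
    if n < 2:
        raise ValueError("need at least two spectra to estimate covariance")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("non-finite values in spectra")
    mean = pixels.mean(axis=0)
    centered = pixels - mean
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    comps = eigvecs[:, order].T  # row-wise components
    # deterministic sign: largest-|loading| entry positive
    for row in comps:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1
    if n_components is not None:
        comps = comps[:n_components]
        eigvals = eigvals[:n_components]
    return PCAModel(mean_spectrum=mean, components=comps, eigenvalues=eigvals)


def transform(cube: DataCube, model: PCAModel, k: int) -> np.ndarray:
    """Project a cube onto the first ``k`` components.

    Returns a ``(k, rows, cols)`` stack of score images; spatial layout
    is preserved.
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but model expects {model.n_bands}"
        )
    if not 1 <= k <= model.components.shape[0]:
        raise ValueError(f"k={k} outside fitted component count")
    _, rows, cols = cube.shape
    scores = (cube.spectra() - model.mean_spectrum) @ model.components[:k].T
    return scores.T.reshape(k, rows, cols)


def explained_proportion(model: PCAModel, m: int) -> float:
    """Cumulative variance proportion of the first ``m`` components."""
    if m < 0 or m > len(model.eigenvalues):
        raise ValueError(f"m={m} outside component count")
    if m == 0:
        return 0.0
    return float(model.proportions[:m].sum())


def _rescale_channel(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo <= np.finfo(np.float64).tiny:
        # constant score image carries no contrast; mid-gray, not a crash
        return np.full_like(img, 0.5, dtype=np.float64)
    return (img - lo) / (hi - lo)


def pseudocolor(scores: np.ndarray, spec: CompositeSpec) -> np.ndarray:
    """Assemble a 3-channel composite in [0, 1] from PC score images.

    Channel ``i`` is the min-max rescaled score image of
    ``spec.channel_pcs[i]``; the index order determines channel
    assignment, so PCA514 and PCA145 are different images.
    """
    scores = np.asarray(scores)
    if max(spec.channel_pcs) > scores.shape[0]:
        raise ValueError(
            f"composite requests PC{max(spec.channel_pcs)} but only "
            f"{scores.shape[0]} score images are available"
        )
    channels = [_rescale_channel(scores[pc - 1]) for pc in spec.channel_pcs]
    return np.stack(channels, axis=0)


def composite_from_cube(
    cube: DataCube,
    spec: CompositeSpec | str | int = "134",
    model: PCAModel | None = None,
) -> np.ndarray:
    """Fit (or reuse) a PCA on the cube's own pixels and build a composite."""
    if not isinstance(spec, CompositeSpec):
        spec = CompositeSpec.from_code(spec)
    k = max(spec.channel_pcs)
    if model is None:
        model = fit_pca(cube.spectra(), n_components=k)
    return pseudocolor(transform(cube, model, k), spec)
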