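"""Spectral-spatial joint diagnosis of a whole slide.

A calibrated slide image tiles into 16 patches; each gets a cancer
probability from the spectral-spatial (SS) patch model.  Confident
patches are gated out immediately (probability > 0.9 -> cancer,
< 0.1 -> normal).  For the undetermined band in between, the pipeline
removes non-target pixel populations (red blood cells, lymphocytes,
cytoplasm, interstitium) by unsupervised clustering plus spectral-angle
matching against reference spectra, classifies the surviving candidate
pixels with the spectral network, and fuses the per-pixel cancer
fraction with the patch probability into a joint probability.  The
final call uses a deliberately conservative threshold (default 0.3):
a patch with joint probability 0.377 is still reported cancerous,
trading specificity for the sensitivity clinicians require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .datacube import DataCube
from .errors import StageError
from .sampling import tile_patches

__all__ = [
    "JointConfig",
    "PatchDecision",
    "SlideReport",
    "sst_gate",
    "spectral_angle",
    "filter_non_target",
    "classify_pixels",
    "fuse",
    "decide_final",
    "render_overlay",
    "render_heatmap",
    "diagnose_slide",
    "diagnose_section",
    "CNNSpectralModel",
    "CompositeSSModel",
    "NearestReferenceModel",
]

OVERLAY_COLORS = {
    "normal": np.array([0.0, 0.8, 0.0]),  # green
    "cancer": np.array([0.0, 0.2, 1.0]),  # blue
    "suspected": np.array([1.0, 0.9, 0.0]),  # yellow
}


@dataclass
class JointConfig:
    """Thresholds and filter settings of the five-step procedure."""

    hi: float = 0.9
    lo: float = 0.1
    weights: tuple[float, float] = (0.5, 0.5)
    final_threshold: float = 0.3
    suspect_band: float = 0.15
    n_clusters: int = 6
    angle_threshold: float = 0.10
    window: int = 9
    patch_size: int = 250
    pixel_threshold: float = 0.5
    seed: int = 0


@dataclass
class PatchDecision:
    patch_no: int  # 1-based, row-major
    origin: tuple[int, int]
    sst_prob: float
    gate_status: str  # cancer | normal | undetermined
    spectral_fraction: float | None = None
    joint_prob: float = 0.0
    final_label: str = "normal"
    fallback: bool = False  # no candidate pixels survived filtering


@dataclass
class SlideReport:
    decisions: list[PatchDecision]
    prob_map: np.ndarray
    grid: tuple[int, int]
    summary: dict = field(default_factory=dict)


def sst_gate(sst_prob: float, hi: float = 0.9, lo: float = 0.1) -> str:
    """Trichotomy on the patch probability with strict comparisons.

    Probabilities in the closed band [lo, hi] are undetermined and go
    through the spectral stage.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if sst_prob > hi:
        return "cancer"
    if sst_prob < lo:
        return "normal"
    return "undetermined"


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in radians between two spectra; scale invariant."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def filter_non_target(
    patch_values: np.ndarray,
    references: dict[str, np.ndarray],
    n_clusters: int = 6,
    angle_threshold: float = 0.10,
    seed: int = 0,
) -> np.ndarray:
    """Remove pixel populations matching non-target reference spectra.

    Pixel spectra of the ``(bands, h, w)`` patch are clustered
    (seeded KMeans); any cluster whose centroid lies within
    ``angle_threshold`` radians of a reference (red blood cells,
    lymphocytes, cytoplasm, interstitium, ...) is removed.  The
    returned boolean raster marks the surviving candidate pixels; it
    may be empty, in which case the caller falls back to the patch
    probability alone.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if not references:
        raise ValueError("need at least one non-target reference spectrum")
    bands, h, w = patch_values.shape
    spectra = patch_values.reshape(bands, h * w).T
    n_clusters = min(n_clusters, len(np.unique(spectra, axis=0)))
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
    assignments = km.fit_predict(spectra)
    keep_cluster = np.ones(n_clusters, dtype=bool)
    for ci, centroid in enumerate(km.cluster_centers_):
        for ref in references.values():
            if spectral_angle(centroid, ref) <= angle_threshold:
                keep_cluster[ci] = False
                break
    return keep_cluster[assignments].reshape(h, w)


def classify_pixels(
    mask: np.ndarray,
    patch_values: np.ndarray,
    spectral_model,
    window: int = 9,
    pixel_threshold: float = 0.5,
    batch_size: int = 4096,
) -> tuple[np.ndarray, float | None]:
    """Per-pixel cancer probabilities for candidate pixels.

    Windows of ``window x window`` are cut around each candidate whose
    full window fits inside the patch (the same border rule as sample
    extraction) and scored by the spectral model.  Returns a float
    raster (NaN outside scored pixels) and the cancer fraction among
    scored candidates, or None when no candidate could be scored.
    """
    half = window // 2
    bands, h, w = patch_values.shape
    prob_map = np.full((h, w), np.nan)
    rows, cols = np.nonzero(mask)
    inside = (rows >= half) & (rows < h - half) & (cols >= half) & (cols < w - half)
    rows, cols = rows[inside], cols[inside]
    if rows.size == 0:
        return prob_map, None
    probs = np.empty(rows.size)
    for i in range(0, rows.size, batch_size):
        rs, cs = rows[i : i + batch_size], cols[i : i + batch_size]
        windows = np.stack(
            [
                patch_values[:, r - half : r + half + 1, c - half : c + half + 1]
                for r, c in zip(rs, cs)
            ]
        )
        probs[i : i + batch_size] = spectral_model.window_cancer_probs(windows)
    prob_map[rows, cols] = probs
    fraction = float((probs > pixel_threshold).mean())
    return prob_map, fraction


def fuse(
    sst_prob: float,
    spectral_fraction: float,
    weights: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Convex combination of patch probability and pixel cancer fraction."""
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return w1 * sst_prob + w2 * spectral_fraction


def decide_final(joint_prob: float, final_threshold: float = 0.3) -> str:
    """Cancer iff the joint probability reaches the threshold.

    The conservative default 0.3 keeps sensitivity high; pass 0.5 for
    the standard symmetric rule.
    """
    if not 0.0 < final_threshold < 1.0:
        raise ValueError("final_threshold must be in (0, 1)")
    return "cancer" if joint_prob >= final_threshold else "normal"


# ---------------------------------------------------------------------------
# model adapters


class CNNSpectralModel:
    """Wraps a trained 3D network as a per-window cancer scorer."""

    def __init__(self, network, batch_size: int = 512):
        self.network = network
        self.batch_size = batch_size

    def window_cancer_probs(self, windows: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(windows[:, None], dtype=np.float32)
        return self.network.predict_proba(x, batch_size=self.batch_size)[:, 1]


class NearestReferenceModel:
    """Spectral-angle nearest-reference scorer (oracle-quality baseline).

    Scores a window by the spectral angle of its center pixel to the
    cancer vs. normal reference spectra; the probability is a softmin
    over the two angles.
    """

    def __init__(self, cancer_ref: np.ndarray, normal_ref: np.ndarray, sharpness: float = 50.0):
        self.cancer_ref = np.asarray(cancer_ref, dtype=np.float64)
        self.normal_ref = np.asarray(normal_ref, dtype=np.float64)
        self.sharpness = sharpness

    def window_cancer_probs(self, windows: np.ndarray) -> np.ndarray:
        half_r = windows.shape[2] // 2
        half_c = windows.shape[3] // 2
        out = np.empty(len(windows))
        for i, win in enumerate(windows):
            center = win[:, half_r, half_c]
            a_c = spectral_angle(center, self.cancer_ref)
            a_n = spectral_angle(center, self.normal_ref)
            out[i] = 1.0 / (1.0 + np.exp(self.sharpness * (a_c - a_n)))
        return out

    def patch_cancer_prob(self, patch_values: np.ndarray) -> float:
        """Patch score = fraction of pixels nearer the cancer reference,
        restricted to pixels dark enough to be tissue."""
        bands, h, w = patch_values.shape
        spectra = patch_values.reshape(bands, h * w).T
        tissue = spectra.mean(axis=1) < 0.92
        if not tissue.any():
            return 0.0
        windows = spectra[tissue][:, :, None, None]
        return float((self.window_cancer_probs(windows) > 0.5).mean())


class CompositeSSModel:
    """Wraps a trained 2D network + a fitted PCA as a patch scorer."""

    def __init__(self, network, pca_model, composite_spec):
        from .pca import CompositeSpec

        self.network = network
        self.pca_model = pca_model
        self.spec = (
            composite_spec
            if isinstance(composite_spec, CompositeSpec)
            else CompositeSpec.from_code(composite_spec)
        )

    def patch_cancer_prob(self, patch_values: np.ndarray) -> float:
        from .datacube import DataCube
        from .pca import pseudocolor, transform

        cube = DataCube(
            patch_values,
            wavelengths=np.arange(patch_values.shape[0], dtype=float),
            stage="tran",
        )
        scores = transform(cube, self.pca_model, max(self.spec.channel_pcs))
        img = pseudocolor(scores, self.spec).astype(np.float32)
        return float(self.network.predict_proba(img[None])[0, 1])


# ---------------------------------------------------------------------------
# slide-level orchestration


def diagnose_slide(
    cube: DataCube,
    ss_model,
    spectral_model,
    references: dict[str, np.ndarray],
    config: JointConfig | None = None,
) -> SlideReport:
    """Run the five-step joint diagnosis on one calibrated cube."""
    if config is None:
        config = JointConfig()
    if cube.stage != "tran":
        raise StageError("joint diagnosis expects a transmittance-calibrated cube")
    _, h, w = cube.shape
    s = config.patch_size
    origins = tile_patches((h, w), s)
    prob_map = np.zeros((h, w))
    decisions: list[PatchDecision] = []
    for no, (r0, c0) in enumerate(origins, start=1):
        patch = cube.values[:, r0 : r0 + s, c0 : c0 + s]
        sst_prob = float(ss_model.patch_cancer_prob(patch))
        status = sst_gate(sst_prob, config.hi, config.lo)
        dec = PatchDecision(
            patch_no=no, origin=(r0, c0), sst_prob=sst_prob, gate_status=status,
        )
        region = prob_map[r0 : r0 + s, c0 : c0 + s]
        if status != "undetermined":
            dec.joint_prob = sst_prob
            dec.final_label = status
            region[:] = sst_prob
        else:
            mask = filter_non_target(
                patch, references, config.n_clusters,
                config.angle_threshold, seed=config.seed,
            )
            pixel_probs, fraction = classify_pixels(
                mask, patch, spectral_model, config.window, config.pixel_threshold,
            )
            if fraction is None:
                dec.fallback = True
                dec.joint_prob = sst_prob
            else:
                dec.spectral_fraction = fraction
                dec.joint_prob = fuse(sst_prob, fraction, config.weights)
            dec.final_label = decide_final(dec.joint_prob, config.final_threshold)
            region[:] = dec.joint_prob
            scored = ~np.isnan(pixel_probs) if fraction is not None else np.zeros_like(mask)
            region[scored] = pixel_probs[scored]
        decisions.append(dec)
    n_cancer = sum(d.final_label == "cancer" for d in decisions)
    report = SlideReport(
        decisions=decisions,
        prob_map=prob_map,
        grid=(h // s, w // s),
        summary={
            "n_patches": len(decisions),
            "cancer_patch_fraction": n_cancer / len(decisions) if decisions else 0.0,
            "max_joint_prob": max((d.joint_prob for d in decisions), default=0.0),
        },
    )
    return report


def diagnose_section(
    cubes: list[DataCube],
    ss_model,
    spectral_model,
    references: dict[str, np.ndarray],
    config: JointConfig | None = None,
) -> tuple[list[SlideReport], dict]:
    """Diagnose every cube of a section (typically 6-8 scans) and
    aggregate: fraction of cancerous patches and maximum joint
    probability across the section."""
    reports = [
        diagnose_slide(c, ss_model, spectral_model, references, config) for c in cubes
    ]
    all_dec = [d for r in reports for d in r.decisions]
    n_cancer = sum(d.final_label == "cancer" for d in all_dec)
    summary = {
        "n_cubes": len(cubes),
        "n_patches": len(all_dec),
        "cancer_patch_fraction": n_cancer / len(all_dec) if all_dec else 0.0,
        "max_joint_prob": max((d.joint_prob for d in all_dec), default=0.0),
    }
    return reports, summary


def render_overlay(
    report: SlideReport,
    background: np.ndarray,
    config: JointConfig | None = None,
    alpha: float = 0.45,
) -> np.ndarray:
    """Blend the decision grid over a pseudo-color background.

    Green marks normal patches, blue cancerous ones, and yellow the
    suspected patches whose joint probability falls within
    ``suspect_band`` of the final threshold.  Returns a (3, h, w) image
    in [0, 1].
    """
    if config is None:
        config = JointConfig()
    out = np.array(background, dtype=np.float64, copy=True)
    s = config.patch_size
    for dec in report.decisions:
        if abs(dec.joint_prob - config.final_threshold) <= config.suspect_band:
            color = OVERLAY_COLORS["suspected"]
        else:
            color = OVERLAY_COLORS[dec.final_label]
        r0, c0 = dec.origin
        region = out[:, r0 : r0 + s, c0 : c0 + s]
        region[:] = (1 - alpha) * region + alpha * color[:, None, None]
    return np.clip(out, 0.0, 1.0)


def render_heatmap(prob_map: np.ndarray) -> np.ndarray:
    """Continuous probability map: blue (normal) to red (cancerous)."""
    p = np.clip(np.nan_to_num(prob_map, nan=0.5), 0.0, 1.0)
    return np.stack([p, 0.15 * np.ones_like(p), 1.0 - p], axis=0)
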