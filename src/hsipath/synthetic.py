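"""Synthetic hyperspectral slide phantoms with ground truth.

Patient hyperspectral pathology data cannot be redistributed, so this
module generates phantoms that emulate every statistical feature the
pipeline relies on, under a transmitted-light (bright-field)
convention: empty glass transmits ~1 and absorbing tissue less.

* class-specific transmission spectra: a broad stain-like absorption
  band shared by all tissue plus narrow class fingerprint features
  (Beer-Lambert-style Gaussian dips), so cancer and normal cells are
  separable by spectrum alone;
* non-target pixel populations (red-blood-cell, lymphocyte, cytoplasm
  and interstitium analogues) with their own distinctive spectra, so
  spectral-angle filtering has real work to do;
* cell-like spatial texture: nuclei placed as disks in a stroma fill;
* column-wise illumination gain (what flat-fielding removes), a global
  intensity scale (what transmission standardization removes), a
  clear background region (the standardization reference) and
  additive Gaussian noise.

Two layouts: ``stripes`` assigns populations to full-width row bands,
making every column compositionally identical — on that layout the
column-wise calibration is exactly invertible at zero noise, which the
identifiability tests exploit.  ``quadrant`` places a cancerous
quadrant in otherwise-normal tissue for slide-diagnosis tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calibration import CalibrationConfig, flat_field, transmission_standardize
from .datacube import DataCube, LabelMap, LABEL_CODES, wavelength_axis
from .pca import CompositeSpec, fit_pca, pseudocolor, transform
from .sampling import extract_spectral_samples

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SampleSet",
    "make_class_spectrum",
    "generate_slide",
    "generate_datasets",
    "DEFAULT_CLASS_FEATURES",
]

#: Gaussian absorption features per population: (center nm, depth, width nm).
#: Every tissue population shares a broad stain band; target classes and
#: blood/immune populations add narrow fingerprint features.
DEFAULT_CLASS_FEATURES: dict[str, list[tuple[float, float, float]]] = {
    "normal": [(600.0, 0.45, 150.0), (530.0, 0.35, 22.0)],
    "cancer": [(600.0, 0.45, 150.0), (585.0, 0.45, 22.0), (760.0, 0.18, 35.0)],
    # hemoglobin analogue: Soret-like band near 420 nm plus the 545/577 doublet
    "red_cell": [(600.0, 0.45, 150.0), (420.0, 0.50, 15.0),
                 (545.0, 0.45, 14.0), (577.0, 0.40, 14.0)],
    "lymphocyte": [(600.0, 0.45, 150.0), (470.0, 0.40, 18.0)],
    "cytoplasm": [(660.0, 0.35, 110.0)],
    "interstitium": [(460.0, 0.40, 100.0)],
}

NON_TARGET_POPULATIONS = ("red_cell", "lymphocyte", "cytoplasm", "interstitium")

# population ids in the truth raster
POPULATION_IDS = {
    "background": 0,
    "normal": 1,
    "cancer": 2,
    "cytoplasm": 3,
    "interstitium": 4,
    "red_cell": 5,
    "lymphocyte": 6,
}


def make_class_spectrum(
    wavelengths: np.ndarray,
    features: list[tuple[float, float, float]],
) -> np.ndarray:
    """Transmission spectrum: baseline 1 minus Gaussian absorption dips.

    Each feature is (center nm, depth in (0,1), width nm).  The result
    is clipped into (0, 1]; with no features the spectrum is all ones.
    """
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    spectrum = np.ones_like(wavelengths)
    for center, depth, width in features:
        if not 0.0 < depth < 1.0:
            raise ValueError(f"feature depth must be in (0,1), got {depth}")
        if not wavelengths[0] <= center <= wavelengths[-1]:
            raise ValueError(
                f"feature center {center} nm outside axis "
                f"[{wavelengths[0]}, {wavelengths[-1]}] nm"
            )
        if width <= 0:
            raise ValueError("feature width must be positive")
        spectrum = spectrum - depth * np.exp(-((wavelengths - center) ** 2) / (2 * width**2))
    return np.clip(spectrum, 1e-3, 1.0)


@dataclass
class PhantomSpec:
    """Generation parameters; the defaults are the desk-scale study
    conditions (200 x 200 px, 50 bands).  ``paper_scale()`` returns the
    acquisition-scale variant (1000 x 1000, 200 bands)."""

    rows: int = 200
    cols: int = 200
    n_bands: int = 50
    lo_nm: float = 410.0
    hi_nm: float = 900.0
    class_features: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASS_FEATURES.items()}
    )
    layout: str = "quadrant"  # quadrant | stripes
    margin: int = 12  # background border, px
    stripe_height: int = 5
    nucleus_radius: int = 3
    nucleus_density: float = 0.012  # nuclei per tissue px^2
    sprinkle_density: float = 0.0008  # red cells / lymphocytes per px^2
    interstitium_fraction: float = 0.15
    noise_sd: float = 0.01
    column_gain_amplitude: float = 0.2
    global_scale: float = 1.3
    include_trim_margins: bool = False
    trim_margins: tuple[int, int] = (30, 26)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.layout not in ("quadrant", "stripes"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if 2 * self.margin >= min(self.rows, self.cols):
            raise ValueError("margins leave no tissue region")

    @classmethod
    def paper_scale(cls, **kw) -> "PhantomSpec":
        kw.setdefault("rows", 1000)
        kw.setdefault("cols", 1000)
        kw.setdefault("n_bands", 200)
        kw.setdefault("margin", 40)
        return cls(**kw)

    @property
    def wavelengths(self) -> np.ndarray:
        return wavelength_axis(self.n_bands, self.lo_nm, self.hi_nm)


@dataclass
class PhantomTruth:
    """Everything the generator knows about the emitted cube."""

    label_map: LabelMap
    population_map: np.ndarray
    class_spectra: dict[str, np.ndarray]
    cell_centers: list[tuple[int, int, str]]  # (row, col, label)
    column_gain: np.ndarray
    global_scale: float

    @property
    def background_mask(self) -> np.ndarray:
        return self.population_map == POPULATION_IDS["background"]

    def non_target_references(self) -> dict[str, np.ndarray]:
        return {k: self.class_spectra[k] for k in NON_TARGET_POPULATIONS}

    def patch_truth_labels(self, patch_size: int) -> list[str | None]:
        """Majority nucleus class per row-major tile (None if no nuclei)."""
        lab = self.label_map.labels
        out: list[str | None] = []
        for r in range(lab.shape[0] // patch_size):
            for c in range(lab.shape[1] // patch_size):
                tile = lab[
                    r * patch_size : (r + 1) * patch_size,
                    c * patch_size : (c + 1) * patch_size,
                ]
                n_cancer = int((tile == LABEL_CODES["cancer"]).sum())
                n_normal = int((tile == LABEL_CODES["normal"]).sum())
                if n_cancer + n_normal == 0:
                    out.append(None)
                else:
                    out.append("cancer" if n_cancer > n_normal else "normal")
        return out


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x**2 + y**2 <= radius**2


def _stamp(raster: np.ndarray, r: int, c: int, radius: int, value: int) -> None:
    disk = _disk(radius)
    r0, r1 = max(r - radius, 0), min(r + radius + 1, raster.shape[0])
    c0, c1 = max(c - radius, 0), min(c + radius + 1, raster.shape[1])
    d = disk[
        r0 - (r - radius) : disk.shape[0] - ((r + radius + 1) - r1),
        c0 - (c - radius) : disk.shape[1] - ((c + radius + 1) - c1),
    ]
    raster[r0:r1, c0:c1][d] = value


def _layout_stripes(spec: PhantomSpec) -> np.ndarray:
    pop = np.full((spec.rows, spec.cols), POPULATION_IDS["background"], dtype=np.int8)
    cycle = ["normal", "cytoplasm", "cancer", "interstitium", "red_cell", "lymphocyte"]
    row = spec.margin
    i = 0
    while row < spec.rows - spec.margin:
        name = cycle[i % len(cycle)]
        stop = min(row + spec.stripe_height, spec.rows - spec.margin)
        pop[row:stop, :] = POPULATION_IDS[name]
        row = stop
        i += 1
    return pop


def _layout_quadrant(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    pop = np.full((spec.rows, spec.cols), POPULATION_IDS["background"], dtype=np.int8)
    m = spec.margin
    tissue = np.zeros_like(pop, dtype=bool)
    tissue[m : spec.rows - m, m : spec.cols - m] = True
    pop[tissue] = POPULATION_IDS["cytoplasm"]

    # interstitium blobs in the stroma
    area = int(tissue.sum())
    n_blobs = max(1, int(spec.interstitium_fraction * area / 80))
    rows, cols = np.nonzero(tissue)
    for i in rng.choice(len(rows), size=n_blobs, replace=True):
        _stamp(pop, rows[i], cols[i], 5, POPULATION_IDS["interstitium"])
    pop[~tissue] = POPULATION_IDS["background"]

    # nuclei: cancer in the top-left quadrant of the slide, normal elsewhere
    n_nuclei = int(spec.nucleus_density * area)
    rr = rng.integers(m, spec.rows - m, size=n_nuclei)
    cc = rng.integers(m, spec.cols - m, size=n_nuclei)
    for r, c in zip(rr, cc):
        if r < spec.rows // 2 and c < spec.cols // 2:
            _stamp(pop, r, c, spec.nucleus_radius, POPULATION_IDS["cancer"])
        else:
            _stamp(pop, r, c, spec.nucleus_radius, POPULATION_IDS["normal"])

    # sprinkled blood / immune cells
    n_sprinkle = int(spec.sprinkle_density * area)
    rr = rng.integers(m, spec.rows - m, size=n_sprinkle)
    cc = rng.integers(m, spec.cols - m, size=n_sprinkle)
    kinds = rng.choice(
        [POPULATION_IDS["red_cell"], POPULATION_IDS["lymphocyte"]], size=n_sprinkle
    )
    for r, c, k in zip(rr, cc, kinds):
        _stamp(pop, r, c, 2, k)
    return pop


def _labels_from_populations(pop: np.ndarray) -> LabelMap:
    lab = np.full(pop.shape, LABEL_CODES["other"], dtype=np.int8)
    lab[pop == POPULATION_IDS["background"]] = LABEL_CODES["background"]
    lab[pop == POPULATION_IDS["normal"]] = LABEL_CODES["normal"]
    lab[pop == POPULATION_IDS["cancer"]] = LABEL_CODES["cancer"]
    return LabelMap(lab)


def generate_slide(spec: PhantomSpec) -> tuple[DataCube, PhantomTruth]:
    """Emit a raw (uncalibrated) phantom cube and its ground truth.

    Per-pixel spectrum = population transmittance x column gain x global
    scale + Gaussian noise.  Fixing the seed fixes every artifact
    bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths
    spectra = {"background": np.ones_like(wl)}
    for name, features in spec.class_features.items():
        spectra[name] = make_class_spectrum(wl, features)

    pop = (
        _layout_stripes(spec) if spec.layout == "stripes" else _layout_quadrant(spec, rng)
    )
    label_map = _labels_from_populations(pop)

    bank = np.stack([spectra[name] for name in POPULATION_IDS])  # (n_pops, bands)
    cube_vals = bank[pop].transpose(2, 0, 1)  # (bands, rows, cols)

    gain_noise = rng.uniform(-1.0, 1.0, size=spec.cols)
    smooth = gaussian_filter1d(gain_noise, sigma=8, mode="wrap")
    denom = np.abs(smooth).max() or 1.0
    gain = 1.0 + spec.column_gain_amplitude * smooth / denom
    values = cube_vals * gain[None, None, :] * spec.global_scale
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.maximum(values, 1e-6)

    if spec.include_trim_margins:
        lead, trail = spec.trim_margins
        step = wl[1] - wl[0]
        wl_full = np.concatenate(
            [wl[0] - step * np.arange(lead, 0, -1), wl, wl[-1] + step * np.arange(1, trail + 1)]
        )
        junk_lead = rng.uniform(0.0, 0.05, size=(lead,) + values.shape[1:])
        junk_trail = rng.uniform(0.0, 0.05, size=(trail,) + values.shape[1:])
        values = np.concatenate([junk_lead, values, junk_trail], axis=0)
        wl = wl_full

    centers = [
        (int(r), int(c), "cancer" if code == LABEL_CODES["cancer"] else "normal")
        for (r, c), code in np.ndenumerate(label_map.labels)
        if code in (LABEL_CODES["cancer"], LABEL_CODES["normal"])
    ]
    cube = DataCube(values, wl, stage="raw", acquisition_id=f"phantom-{spec.seed}")
    truth = PhantomTruth(
        label_map=label_map,
        population_map=pop,
        class_spectra=spectra,
        cell_centers=centers,
        column_gain=gain,
        global_scale=spec.global_scale,
    )
    return cube, truth


@dataclass
class SampleSet:
    """Train/test arrays plus a bookkeeping manifest."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    manifest: pd.DataFrame


def _stratified_split(
    labels: np.ndarray, split: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean train mask, per-class proportional."""
    train = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        train[idx[: int(round(split * len(idx)))]] = True
    return train


def calibrated_slide(spec: PhantomSpec) -> tuple[DataCube, PhantomTruth]:
    """Generate and calibrate a phantom with its own background truth."""
    raw, truth = generate_slide(spec)
    even = flat_field(raw, CalibrationConfig())
    tran = transmission_standardize(even, truth.background_mask)
    return tran, truth


def generate_datasets(
    spec: PhantomSpec,
    n_spectral: int = 2000,
    n_patches: int = 0,
    patch_size: int | None = None,
    split: float = 0.8,
    window: int = 9,
    composite: str = "134",
) -> dict:
    """Build spectral (and optionally composite-patch) sample sets.

    Spectral samples are ``bands x window x window`` cubes around
    labeled nucleus pixels, class-balanced up to availability.  Patch
    samples are PCA pseudo-color crops at jittered origins labeled by
    the majority nucleus class.  All randomness derives from
    ``spec.seed``; at zero noise a nearest-reference-spectrum oracle is
    exact on the spectral samples by construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    tran, truth = calibrated_slide(spec)

    centers = truth.cell_centers
    by_class: dict[str, list] = {"cancer": [], "normal": []}
    for r, c, lbl in centers:
        by_class[lbl].append((r, c))
    per_class = n_spectral // 2
    chosen: list[tuple[int, int]] = []
    for lbl, pts in by_class.items():
        if len(pts) < per_class:
            raise ValueError(
                f"phantom provides only {len(pts)} {lbl} cell pixels; "
                f"requested {per_class}"
            )
        idx = rng.choice(len(pts), size=per_class, replace=False)
        chosen.extend(pts[i] for i in idx)
    samples = extract_spectral_samples(tran, truth.label_map, window, centers=chosen)
    x = np.stack([s.window for s in samples]).astype(np.float32)
    y = np.array([1 if s.label == "cancer" else 0 for s in samples])
    train_mask = _stratified_split(y, split, rng)
    manifest = pd.DataFrame(
        {
            "sample_id": np.arange(len(samples)),
            "source": tran.acquisition_id,
            "row": [s.center[0] for s in samples],
            "col": [s.center[1] for s in samples],
            "label": [s.label for s in samples],
            "split": np.where(train_mask, "train", "test"),
        }
    )
    out = {
        "spectral": SampleSet(
            x[train_mask], y[train_mask], x[~train_mask], y[~train_mask], manifest
        ),
        "slide": (tran, truth),
    }

    if n_patches:
        ps = patch_size or spec.rows // 4
        model = fit_pca(tran.spectra(), n_components=5)
        scores = transform(tran, model, 5)
        comp = pseudocolor(scores, CompositeSpec.from_code(composite))
        lab = truth.label_map.labels
        xs, ys, origins = [], [], []
        attempts = 0
        while len(xs) < n_patches and attempts < 50 * n_patches:
            attempts += 1
            r0 = int(rng.integers(0, spec.rows - ps + 1))
            c0 = int(rng.integers(0, spec.cols - ps + 1))
            tile = lab[r0 : r0 + ps, c0 : c0 + ps]
            n_cancer = int((tile == LABEL_CODES["cancer"]).sum())
            n_normal = int((tile == LABEL_CODES["normal"]).sum())
            total = n_cancer + n_normal
            if total == 0 or max(n_cancer, n_normal) / total < 0.8:
                continue
            xs.append(comp[:, r0 : r0 + ps, c0 : c0 + ps].astype(np.float32))
            ys.append(1 if n_cancer > n_normal else 0)
            origins.append((r0, c0))
        xp = np.stack(xs)
        yp = np.array(ys)
        pmask = _stratified_split(yp, split, rng)
        pmanifest = pd.DataFrame(
            {
                "sample_id": np.arange(len(xs)),
                "source": tran.acquisition_id,
                "row": [o[0] for o in origins],
                "col": [o[1] for o in origins],
                "label": np.where(yp == 1, "cancer", "normal"),
                "split": np.where(pmask, "train", "test"),
            }
        )
        out["patches"] = SampleSet(xp[pmask], yp[pmask], xp[~pmask], yp[~pmask], pmanifest)
    return out
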