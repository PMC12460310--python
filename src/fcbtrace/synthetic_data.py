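"""Synthetic study data with the structure the analysis assumes.

The study design this package targets is five provenance classes of
Fritillariae Cirrhosae Bulbus (FCB) with 18 bulbs each:

====== ==========================================
code   provenance / agronomic practice
====== ==========================================
AH-AC  Anhong township, artificial cultivation
CZS-FC Chuanzhusi town, field collection (wild)
BM-TC  Bamei town, tissue-culture regeneration
SK-FC  Seka township, field collection (wild)
YM-AC  Yimu township, artificial cultivation
====== ==========================================

Three coupled data products are generated:

* **Reflectance spectra** (400–1000 nm, 300 channels): a smooth
  baseline minus class-specific Gaussian absorption bands centred at
  750, 800, 840 and 970 nm, plus i.i.d. sensor noise.  The
  tissue-culture class additionally shows depressed reflectance over
  460–750 nm (shorter growth period, fewer pigments/saponins).
* **Alkaloid panel** (peimisine, imperialine, peiminine, peimine in
  µg/g): per-class concentration ranges; peimine is only detectable in
  the tissue-culture class, and some sources report peiminine below
  the limit of detection (exact 0 with a below-LOD flag).
* **Element panel** (K, Na, Mn, Fe, Al, Cu, Mg, Zn in mg/kg):
  per-class ranges with the tissue-culture class accumulating the
  most of every element (nutrient-rich culture media).

Cross-panel element–alkaloid correlations are induced by a Gaussian
copula: each alkaloid owns a latent standard-normal factor, each
element loads on those factors with the requested signs, and both
panels map latent quantiles into their class ranges.  Class-mean
structure (e.g. the tissue-culture class being high in both elements
and peimine) contributes the same signs, mirroring the mechanism that
produces them in real bulbs.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import ConfusionMatrix
from .spectra_io import SpectraSet

__all__ = [
    "CLASS_CODES",
    "ALKALOIDS",
    "ELEMENTS",
    "GeneratorConfig",
    "PanelConfig",
    "AlkaloidPanel",
    "ElementPanel",
    "generate_spectra_set",
    "class_mean_spectra",
    "generate_panels",
    "fixture_confusion",
]

CLASS_CODES = ("AH-AC", "CZS-FC", "BM-TC", "SK-FC", "YM-AC")
ALKALOIDS = ("peimisine", "imperialine", "peiminine", "peimine")
ELEMENTS = ("K", "Na", "Mn", "Fe", "Al", "Cu", "Mg", "Zn")

#: index of the tissue-culture class (depressed 460–750 nm reflectance)
TISSUE_CULTURE_CLASS = CLASS_CODES.index("BM-TC")

# Per-class band-depth modulation pattern (unitless reflectance), scaled by
# effect_size and added to the shared base depths.  SK-FC and YM-AC are
# deliberately the closest pair: the two wild/cultivated neighbours from
# Ganzi prefecture that latent-variable baselines struggle to separate.
_BASE_DEPTHS = np.array([0.10, 0.08, 0.08, 0.12])
_CLASS_DELTAS = np.array(
    [
        [+1.0, -1.0, 0.0, +1.0],   # AH-AC
        [-1.0, +1.0, +1.0, 0.0],   # CZS-FC
        [0.0, 0.0, -1.0, -1.0],    # BM-TC
        [+1.0, 0.0, -1.0, +1.0],   # SK-FC
        [+1.0, -0.5, -1.0, +0.5],  # YM-AC
    ]
)
_DELTA_SCALE = 0.04


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic reflectance-spectra generator.

    ``band_depths`` (n_classes x n_bands, unitless reflectance) may be
    given explicitly; by default it is the shared base depth pattern
    plus ``effect_size``-scaled per-class offsets, so ``effect_size``
    is a single dial for between-class separability (0 = identical
    class means, 1 = comfortably separable).
    """

    n_classes: int = 5
    n_per_class: int = 18
    wavelength_start_nm: float = 400.0
    wavelength_end_nm: float = 1000.0
    n_channels: int = 300
    band_centers_nm: tuple = (750.0, 800.0, 840.0, 970.0)
    band_width_nm: float = 25.0
    band_depths: np.ndarray | None = None
    effect_size: float = 1.0
    visible_dip_offset: float = 0.06
    visible_dip_range_nm: tuple = (460.0, 750.0)
    dip_class: int = TISSUE_CULTURE_CLASS
    noise_sd: float = 0.01
    baseline_range: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not self.wavelength_end_nm > self.wavelength_start_nm:
            raise ValueError("wavelength grid must be increasing")
        centers = np.asarray(self.band_centers_nm, dtype=float)
        if np.any(centers < self.wavelength_start_nm) or np.any(centers > self.wavelength_end_nm):
            raise ValueError("band centers must lie within the wavelength range")
        if self.band_depths is None:
            if self.n_classes > _CLASS_DELTAS.shape[0] or centers.size != _BASE_DEPTHS.size:
                raise ValueError(
                    "default band_depths only cover 5 classes x 4 bands; "
                    "pass band_depths explicitly"
                )
            self.band_depths = (
                _BASE_DEPTHS[None, :]
                + self.effect_size * _DELTA_SCALE * _CLASS_DELTAS[: self.n_classes]
            )
        self.band_depths = np.asarray(self.band_depths, dtype=float)
        if self.band_depths.shape != (self.n_classes, centers.size):
            raise ValueError("band_depths must be n_classes x n_bands")
        if np.any(self.band_depths < 0):
            raise ValueError("band_depths must be non-negative")
        means = class_mean_spectra(self)
        if means.min() <= 0 or means.mean(axis=1).max() >= 1.5:
            raise ValueError("band depths produce class mean reflectance outside (0, 1.5)")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.wavelength_start_nm, self.wavelength_end_nm, self.n_channels)


def _baseline(w: np.ndarray) -> np.ndarray:
    # gentle upward slope typical of dried bulb reflectance
    return 0.55 + 0.10 * (w - w[0]) / (w[-1] - w[0])


def _dip_window(w: np.ndarray, lo: float, hi: float, edge_nm: float = 10.0) -> np.ndarray:
    # smooth-edged indicator of the visible-range dip
    return 1.0 / (1.0 + np.exp(-(w - lo) / edge_nm)) * 1.0 / (1.0 + np.exp((w - hi) / edge_nm))


def class_mean_spectra(config: GeneratorConfig) -> np.ndarray:
    """Noise-free class mean spectra (n_classes x n_channels), closed form."""
    w = config.wavelengths_nm
    centers = np.asarray(config.band_centers_nm, dtype=float)
    bands = np.exp(-0.5 * ((w[None, :] - centers[:, None]) / config.band_width_nm) ** 2)
    means = _baseline(w)[None, :] - config.band_depths @ bands
    if config.visible_dip_offset:
        lo, hi = config.visible_dip_range_nm
        means[config.dip_class] -= config.visible_dip_offset * _dip_window(w, lo, hi)
    return means


def generate_spectra_set(config: GeneratorConfig) -> SpectraSet:
    """Draw the labelled synthetic reflectance set.

    Each spectrum is its class mean plus a per-sample constant baseline
    shift (uniform over ±baseline_range/2, emulating illumination and
    surface-geometry variation) plus i.i.d. Gaussian channel noise.
    """
    rng = np.random.default_rng(config.seed)
    means = class_mean_spectra(config)
    n, p = config.n_per_class, config.n_channels
    codes = [
        CLASS_CODES[c] if config.n_classes <= len(CLASS_CODES) else f"C{c}"
        for c in range(config.n_classes)
    ]
    X = np.empty((config.n_classes * n, p))
    ids, labels = [], []
    for c in range(config.n_classes):
        shift = rng.uniform(-config.baseline_range / 2, config.baseline_range / 2, size=(n, 1))
        noise = rng.normal(0.0, config.noise_sd, size=(n, p)) if config.noise_sd else 0.0
        X[c * n : (c + 1) * n] = means[c][None, :] + shift + noise
        ids += [f"{codes[c]}-{i + 1:02d}" for i in range(n)]
        labels += [codes[c]] * n
    return SpectraSet(config.wavelengths_nm, X, ids, np.array(labels))


# ---------------------------------------------------------------------------
# Alkaloid / element panels

# Default per-class concentration ranges.  SK-FC alkaloids, BM-TC peimine,
# CZS-FC Al/Fe/Mn/Na and AH-AC K/Mg/Cu/Zn are measured ranges; the rest
# follow the qualitative source profile (tissue culture highest in elements
# and in most alkaloids except peimisine; wild Seka bulbs richest in
# peimisine/imperialine/peiminine).  (0, 0) encodes below-LOD.
_ALK_RANGES = {
    #            peimisine        imperialine      peiminine     peimine
    "AH-AC":  [(60.0, 100.0), (40.0, 90.0),   (0.0, 0.0),    (0.0, 0.0)],
    "CZS-FC": [(80.0, 130.0), (50.0, 110.0),  (0.5, 5.0),    (0.0, 0.0)],
    "BM-TC":  [(40.0, 80.0),  (60.0, 120.0),  (2.0, 10.0),   (64.13, 107.42)],
    "SK-FC":  [(120.69, 197.36), (64.71, 253.62), (1.53, 17.17), (0.0, 0.0)],
    "YM-AC":  [(55.0, 95.0),  (35.0, 85.0),   (0.0, 0.0),    (0.0, 0.0)],
}
_ELEM_RANGES = {
    #          K                    Na              Mn              Fe              Al              Cu            Mg                Zn
    "AH-AC":  [(7239.18, 13342.10), (8.0, 14.0),   (9.0, 12.0),   (45.0, 75.0),   (25.0, 38.0),  (2.35, 3.68), (518.71, 818.63), (12.86, 18.11)],
    "CZS-FC": [(5000.0, 8000.0),    (15.09, 21.63), (13.65, 16.06), (70.30, 115.85), (43.85, 52.94), (1.5, 2.5),  (380.0, 560.0),   (9.0, 13.0)],
    "BM-TC":  [(14000.0, 20000.0),  (25.0, 40.0),  (17.0, 24.0),  (120.0, 180.0), (55.0, 75.0),  (3.8, 5.5),   (850.0, 1200.0),  (19.0, 26.0)],
    "SK-FC":  [(4000.0, 6500.0),    (10.0, 16.0),  (8.0, 11.0),   (40.0, 65.0),   (22.0, 34.0),  (1.2, 2.2),   (300.0, 480.0),   (8.0, 12.0)],
    "YM-AC":  [(4500.0, 7000.0),    (11.0, 17.0),  (9.5, 12.5),   (50.0, 80.0),   (26.0, 40.0),  (1.6, 2.6),   (340.0, 520.0),   (9.5, 13.5)],
}

# Element x alkaloid correlation signs: every element correlates negatively
# with peimisine and imperialine and positively with peiminine and peimine.
_DEFAULT_SIGNS = pd.DataFrame(
    np.tile([-1, -1, +1, +1], (len(ELEMENTS), 1)),
    index=list(ELEMENTS),
    columns=list(ALKALOIDS),
)


def _ranges_frame(raw: dict, columns: tuple) -> pd.DataFrame:
    df = pd.DataFrame({cls: [tuple(map(float, r)) for r in rows] for cls, rows in raw.items()}).T
    df.columns = list(columns)
    return df


@dataclass
class PanelConfig:
    """Parameters of the coupled alkaloid/element panel generator.

    ``alkaloid_ranges`` / ``element_ranges`` are class x analyte tables
    of (low, high) concentration ranges (µg/g and mg/kg).  ``signs`` is
    the element x alkaloid correlation-sign matrix with entries in
    {-1, 0, +1}; ``strength`` in [0, 1) is the shared-latent-factor
    coupling (0 = independent panels).
    """

    alkaloid_ranges: pd.DataFrame = field(
        default_factory=lambda: _ranges_frame(_ALK_RANGES, ALKALOIDS)
    )
    element_ranges: pd.DataFrame = field(
        default_factory=lambda: _ranges_frame(_ELEM_RANGES, ELEMENTS)
    )
    signs: pd.DataFrame = field(default_factory=lambda: _DEFAULT_SIGNS.copy())
    strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for df in (self.alkaloid_ranges, self.element_ranges):
            for lo, hi in df.to_numpy().reshape(-1):
                if lo < 0 or hi < lo:
                    raise ValueError("concentration ranges must satisfy 0 <= low <= high")
        if not set(np.unique(self.signs.to_numpy())) <= {-1, 0, 1}:
            raise ValueError("sign matrix entries must be in {-1, 0, +1}")
        if list(self.signs.index) != list(self.element_ranges.columns) or list(
            self.signs.columns
        ) != list(self.alkaloid_ranges.columns):
            raise ValueError("sign matrix axes must match element/alkaloid names")
        if not 0 <= self.strength < 1:
            raise ValueError("strength must be in [0, 1)")
        # a nonzero sign against an analyte that is constant in every class
        # cannot be realised even in expectation
        for alk in self.signs.columns:
            rng_col = self.alkaloid_ranges[alk]
            degenerate = all(lo == hi for lo, hi in rng_col)
            if degenerate and self.signs[alk].to_numpy().any():
                raise ValueError(
                    f"infeasible sign matrix: {alk} has zero-width ranges in every "
                    "class but a nonzero requested correlation"
                )


@dataclass
class AlkaloidPanel:
    """Per-sample alkaloid concentrations (µg/g) with below-LOD flags."""

    values: pd.DataFrame
    below_lod: pd.DataFrame
    labels: np.ndarray


@dataclass
class ElementPanel:
    """Per-sample mineral element concentrations (mg/kg)."""

    values: pd.DataFrame
    below_lod: pd.DataFrame
    labels: np.ndarray


def _fill_panel(ranges: pd.DataFrame, labels, quantiles: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(labels)
    out = np.zeros((n, ranges.shape[1]))
    for i, cls in enumerate(labels):
        for j, analyte in enumerate(ranges.columns):
            lo, hi = ranges.loc[cls, analyte]
            out[i, j] = lo + (hi - lo) * quantiles[i, j]
    values = pd.DataFrame(out, columns=list(ranges.columns))
    below = values == 0.0
    return values, below


def _rank1_signs(M: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Decompose a {-1,0,+1} matrix as sign_e[i] * sign_a[j] on its support.

    Returns (sign_e, sign_a) with entries in {-1, 0, +1} (0 marks rows
    or columns with no nonzero requested sign), or None when the
    nonzero pattern is inconsistent with a single shared factor.
    """
    n_el, n_alk = M.shape
    se = np.zeros(n_el)
    sa = np.zeros(n_alk)
    for i0 in range(n_el):
        if se[i0] or not np.abs(M[i0]).any():
            continue
        se[i0] = 1.0
        queue = [("e", i0)]
        while queue:
            kind, idx = queue.pop()
            if kind == "e":
                for j in np.flatnonzero(M[idx]):
                    want = M[idx, j] * se[idx]
                    if sa[j] == 0:
                        sa[j] = want
                        queue.append(("a", j))
                    elif sa[j] != want:
                        return None
            else:
                for i in np.flatnonzero(M[:, idx]):
                    want = M[i, idx] * sa[idx]
                    if se[i] == 0:
                        se[i] = want
                        queue.append(("e", i))
                    elif se[i] != want:
                        return None
    return se, sa


def generate_panels(config: PanelConfig, n_per_class: int = 18) -> tuple[AlkaloidPanel, ElementPanel]:
    """Draw coupled alkaloid and element panels.

    Gaussian-copula construction.  When the requested sign matrix is
    consistent with a single shared factor (sign[i, j] =
    sign_e[i] * sign_a[j] on its support — true of the default), every
    correlated analyte loads on one latent z ~ N(0,1) with its sign:
    within-range quantile = Phi(sqrt(rho) * s * z + sqrt(1-rho) * eps).
    Otherwise each alkaloid owns its own factor and elements load on
    the sign-weighted mean of those factors.  Either way the sample
    correlation between element i and alkaloid j has the sign of
    ``signs[i, j]`` in expectation.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(config.seed)
    classes = list(config.alkaloid_ranges.index)
    labels = np.repeat(classes, n_per_class)
    n = len(labels)
    n_alk = len(config.signs.columns)
    n_el = len(config.signs.index)
    rho = config.strength

    M = config.signs.to_numpy(dtype=float)  # n_el x n_alk
    rank1 = _rank1_signs(M)
    if rank1 is not None:
        se, sa = rank1
        z = rng.standard_normal((n, 1))
        lat_a = sa[None, :] * z
        lat_e = se[None, :] * z
    else:
        z = rng.standard_normal((n, n_alk))  # one latent factor per alkaloid
        lat_a = z
        k = np.maximum(np.abs(M).sum(axis=1), 1.0)
        lat_e = (z @ M.T) / np.sqrt(k)[None, :]
    # noise scaled per analyte so every marginal quantile stays U(0, 1):
    # analytes with no requested sign carry a unit-variance pure-noise latent
    def _mix(lat, ncols):
        active = (np.abs(lat).sum(axis=0) > 0).astype(float)
        b = np.sqrt(1.0 - rho * active)
        return norm.cdf(np.sqrt(rho) * lat + b[None, :] * rng.standard_normal((n, ncols)))

    alk_q = _mix(lat_a, n_alk)
    el_q = _mix(lat_e, n_el)

    alk_vals, alk_lod = _fill_panel(config.alkaloid_ranges, labels, alk_q)
    el_vals, el_lod = _fill_panel(config.element_ranges, labels, el_q)
    if (alk_vals.to_numpy() < 0).any() or (el_vals.to_numpy() < 0).any():
        raise ValueError("negative concentration generated")  # unreachable by construction
    return AlkaloidPanel(alk_vals, alk_lod, labels), ElementPanel(el_vals, el_lod, labels)


def fixture_confusion() -> ConfusionMatrix:
    """External-validation confusion fixture: 15 bulbs, 3 per class.

    13 correct; one wild Chuanzhusi bulb predicted as the Yimu
    cultivated class and one tissue-culture bulb predicted as the
    Chuanzhusi class.
    """
    counts = np.diag([3, 3, 3, 3, 3]).astype(int)
    czs, bm, ym = (CLASS_CODES.index(c) for c in ("CZS-FC", "BM-TC", "YM-AC"))
    counts[czs, czs] -= 1
    counts[czs, ym] += 1
    counts[bm, bm] -= 1
    counts[bm, czs] += 1
    return ConfusionMatrix(counts, classes=list(CLASS_CODES))
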