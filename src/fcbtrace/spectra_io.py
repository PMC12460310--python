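"""Spectra containers, radiometric calibration and ROI extraction.

Hyperspectral workflows in this package operate on two levels:

* :class:`Cube` — a raw or calibrated hyperspectral image
  (rows x cols x channels) with an optional reference-panel mask and
  named sample ROI masks.
* :class:`SpectraSet` — the tabular object the downstream analysis
  actually consumes: one mean reflectance spectrum per sample on a
  shared, strictly increasing wavelength grid, plus class labels.

Raw sensor counts are converted to reflectance against a calibration
panel of known reflectance (20 % by default), optionally with a dark
frame:  R = (raw - dark) / (panel - dark) * panel_reflectance.

CSV is the canonical interchange format: a wide table whose first
column is ``wavelength_nm`` and whose remaining columns are one sample
each, with class labels in a separate two-column table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "Cube",
    "calibrate_reflectance",
    "roi_mean_spectrum",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_labels_csv",
    "write_labels_csv",
]


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with at least 2 entries")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return w


@dataclass(frozen=True)
class Spectrum:
    """A single sample's mean reflectance spectrum."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        w = _check_wavelengths(self.wavelengths_nm)
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != w.shape:
            raise ValueError(
                f"reflectance length {r.size} does not match wavelength grid length {w.size}"
            )
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "reflectance", r)


@dataclass
class SpectraSet:
    """n_samples x n_channels reflectance matrix with labels.

    ``reflectance[i]`` is sample ``sample_ids[i]``'s spectrum on the
    shared grid ``wavelengths_nm``; ``labels[i]`` is its class code
    (e.g. one of the five provenance codes AH-AC, CZS-FC, BM-TC,
    SK-FC, YM-AC).
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray  # (n_samples, n_channels)
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths_nm = _check_wavelengths(self.wavelengths_nm)
        X = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if X.shape[1] != self.wavelengths_nm.size:
            raise ValueError("reflectance column count does not match wavelength grid")
        if not np.all(np.isfinite(X)):
            raise ValueError("reflectance must be finite")
        self.reflectance = X
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(X.shape[0])]
        if len(self.sample_ids) != X.shape[0]:
            raise ValueError("sample_ids length does not match sample count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != X.shape[0]:
                raise ValueError("labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.reflectance[i], self.sample_ids[i])

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            self.wavelengths_nm,
            self.reflectance[idx],
            [self.sample_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.reflectance.mean(axis=0), "mean")

    def class_means(self) -> dict[str, np.ndarray]:
        if self.labels is None:
            raise ValueError("SpectraSet has no labels")
        return {
            str(c): self.reflectance[self.labels == c].mean(axis=0)
            for c in np.unique(self.labels)
        }


@dataclass
class Cube:
    """Hyperspectral image: rows x cols x channels raw intensity or reflectance."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    panel_mask: np.ndarray | None = None
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    calibrated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x channels")
        self.wavelengths_nm = _check_wavelengths(self.wavelengths_nm)
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError("cube channel count does not match wavelength grid")
        for name, mask in list(self.roi_masks.items()):
            self.roi_masks[name] = self._check_mask(mask, f"ROI mask {name!r}")
        if self.panel_mask is not None:
            self.panel_mask = self._check_mask(self.panel_mask, "panel mask")

    def _check_mask(self, mask: np.ndarray, what: str) -> np.ndarray:
        m = np.asarray(mask, dtype=bool)
        if m.shape != self.data.shape[:2]:
            raise ValueError(f"{what} shape {m.shape} does not match image {self.data.shape[:2]}")
        if not m.any():
            raise ValueError(f"{what} is empty")
        return m


def calibrate_reflectance(
    raw: Cube,
    panel_reflectance: float = 0.20,
    dark: np.ndarray | None = None,
) -> Cube:
    """Convert raw counts to reflectance against the reference panel.

    reflectance(pixel, ch) = (raw - dark) / (mean_panel - dark) * panel_reflectance

    where ``mean_panel`` is the per-channel mean of the panel-mask
    pixels.  ``dark`` is an optional per-channel dark-current frame
    (defaults to zero).  Re-calibrating an already calibrated cube is
    refused.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated; refusing to calibrate twice")
    if raw.panel_mask is None:
        raise ValueError("cube has no panel mask; cannot calibrate")
    if not 0 < panel_reflectance <= 1:
        raise ValueError("panel_reflectance must be in (0, 1]")
    if dark is None:
        dark = np.zeros(raw.wavelengths_nm.size)
    dark = np.asarray(dark, dtype=float)
    if dark.shape != raw.wavelengths_nm.shape:
        raise ValueError("dark frame must be a per-channel vector")
    panel = raw.data[raw.panel_mask].mean(axis=0) - dark
    bad = np.flatnonzero(panel <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive panel intensity at channel {bad[0]} "
            f"({raw.wavelengths_nm[bad[0]]:g} nm)"
        )
    refl = (raw.data - dark) / panel * panel_reflectance
    return Cube(
        refl,
        raw.wavelengths_nm,
        panel_mask=raw.panel_mask,
        roi_masks=dict(raw.roi_masks),
        calibrated=True,
        metadata={**raw.metadata, "panel_reflectance": panel_reflectance},
    )


def roi_mean_spectrum(cube: Cube, roi_mask: np.ndarray | str, sample_id: str = "") -> Spectrum:
    """Per-channel arithmetic mean reflectance over the masked pixels."""
    if isinstance(roi_mask, str):
        sample_id = sample_id or roi_mask
        try:
            roi_mask = cube.roi_masks[roi_mask]
        except KeyError:
            raise KeyError(f"cube has no ROI named {roi_mask!r}") from None
    mask = cube._check_mask(roi_mask, "ROI mask")
    return Spectrum(cube.wavelengths_nm, cube.data[mask].mean(axis=0), sample_id)


# ---------------------------------------------------------------------------
# CSV interchange


def write_spectra_csv(spectra: SpectraSet, path, labels_path=None) -> None:
    df = pd.DataFrame(
        spectra.reflectance.T, columns=spectra.sample_ids,
        index=pd.Index(spectra.wavelengths_nm, name="wavelength_nm"),
    )
    df.to_csv(path, float_format="%.12g")
    if labels_path is not None:
        if spectra.labels is None:
            raise ValueError("SpectraSet has no labels to write")
        write_labels_csv(spectra.sample_ids, spectra.labels, labels_path)


def write_labels_csv(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "class": list(labels)}).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "class"]:
        raise ValueError("labels CSV must have columns sample_id, class")
    return df


def read_spectra_csv(path, labels_path=None) -> SpectraSet:
    """Read a wide spectra CSV (first column wavelength_nm, one column per sample)."""
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("spectra CSV must have wavelength_nm as its first column")
    if df.isna().any().any():
        raise ValueError("spectra CSV has missing values (ragged rows?)")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(w) > 0):
        raise ValueError("non-monotone wavelength grid in spectra CSV")
    ids = [str(c) for c in df.columns[1:]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample ids in spectra CSV")
    X = df.iloc[:, 1:].to_numpy(dtype=float).T
    labels = None
    if labels_path is not None:
        ldf = read_labels_csv(labels_path)
        lut = dict(zip(ldf["sample_id"], ldf["class"]))
        missing = [s for s in ids if s not in lut]
        if missing:
            raise ValueError(f"labels CSV missing sample ids: {missing[:5]}")
        labels = np.array([lut[s] for s in ids])
    return SpectraSet(w, X, ids, labels)
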