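"""Generalized three-dimensional correlation spectroscopy (3DCOS).

Given m spectra measured under an external perturbation (here: the
sample identity across provenances), the dynamic spectrum at variable
v is the deviation from a reference, S(v) = {s(v, t1) ... s(v, tm)},
and the synchronous correlation intensity over a wavelength pair is

    phi(v1, v2) = 1/(m - 1) * S(v1)^T S(v2),

i.e. with set-mean centering the sample covariance of the spectra.
The synchronous map is symmetric and positive semi-definite and,
rendered as an image over the (v1, v2) plane, is the input to the
residual-CNN classifier.

Per-sample images use the rank-1 specialisation: a single sample's
deviation from the training-set mean spectrum gives
phi = outer(s~, s~).  The mean of those rank-1 maps times m/(m-1)
equals the full-set synchronous map, so per-sample images decompose
the set-level statistic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import Spectrum, SpectraSet

__all__ = [
    "SyncMap",
    "RenderSpec",
    "dynamic_spectra",
    "synchronous_map",
    "sample_sync_map",
    "render_map",
]


@dataclass
class SyncMap:
    """Square synchronous correlation matrix over wavelength pairs."""

    wavelengths_nm: np.ndarray
    phi: np.ndarray
    provenance: str = "full-set"  # or "per-sample"
    m_used: int = 0

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        n = self.wavelengths_nm.size
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square and match the wavelength grid")
        asym = np.abs(self.phi - self.phi.T).max() if n else 0.0
        if asym > 1e-9:
            raise ValueError(f"phi asymmetry {asym:g} exceeds 1e-9")


@dataclass
class RenderSpec:
    """How a synchronous map becomes an image.

    ``normalization='global'`` maps intensities through fixed
    (vmin, vmax) bounds shared across a whole image set (so the
    intensity scale stays class-informative); ``'per-image'`` rescales
    each map to its own range.  ``colormap=None`` yields a grayscale
    (H, W) float image in [0, 1]; otherwise a matplotlib colormap name
    produces (H, W, 3).  Elevation/azimuth describe the 3-D surface
    view and are metadata for surface exports.
    """

    width_px: int = 875
    height_px: int = 656
    colormap: str | None = "viridis"
    elevation_deg: float = 30.0
    azimuth_deg: float = -60.0
    normalization: str = "per-image"
    vmin: float | None = None
    vmax: float | None = None

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.normalization not in ("global", "per-image"):
            raise ValueError("normalization must be 'global' or 'per-image'")
        if self.normalization == "global" and (self.vmin is None or self.vmax is None):
            raise ValueError("global normalization requires vmin and vmax")


def _reference_vector(spectra: SpectraSet, reference) -> np.ndarray:
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean', a Spectrum, or an array")
        return spectra.reflectance.mean(axis=0)
    if isinstance(reference, Spectrum):
        if reference.wavelengths_nm.shape != spectra.wavelengths_nm.shape or not np.allclose(
            reference.wavelengths_nm, spectra.wavelengths_nm
        ):
            raise ValueError("reference spectrum is on a different wavelength grid")
        return reference.reflectance
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (spectra.n_channels,):
        raise ValueError("reference vector length does not match wavelength grid")
    return ref


def dynamic_spectra(spectra: SpectraSet, reference="mean") -> SpectraSet:
    """Deviation spectra s~(v, t) = s(v, t) - reference(v).

    With the default set-mean reference, every channel of the result
    sums to zero exactly (up to float round-off).
    """
    if spectra.n_samples < 1:
        raise ValueError("need at least one spectrum")
    ref = _reference_vector(spectra, reference)
    return SpectraSet(
        spectra.wavelengths_nm,
        spectra.reflectance - ref[None, :],
        list(spectra.sample_ids),
        spectra.labels,
    )


def synchronous_map(dynamic: SpectraSet) -> SyncMap:
    """Synchronous correlation intensity phi = S^T S / (m - 1).

    ``dynamic`` must hold m >= 2 dynamic (deviation) spectra; with
    set-mean centering the result equals the sample covariance matrix
    of the original spectra.
    """
    m = dynamic.n_samples
    if m < 2:
        raise ValueError(
            "synchronous map needs m >= 2 dynamic spectra (the 1/(m-1) factor is undefined)"
        )
    S = dynamic.reflectance
    phi = (S.T @ S) / (m - 1)
    phi = (phi + phi.T) / 2  # kill float round-off asymmetry
    return SyncMap(dynamic.wavelengths_nm, phi, provenance="full-set", m_used=m)


def sample_sync_map(spectrum: Spectrum, reference: Spectrum | np.ndarray) -> SyncMap:
    """Rank-1 per-sample map: phi = outer(s - ref, s - ref)."""
    if isinstance(reference, Spectrum):
        if not np.allclose(reference.wavelengths_nm, spectrum.wavelengths_nm):
            raise ValueError("reference spectrum is on a different wavelength grid")
        ref = reference.reflectance
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != spectrum.reflectance.shape:
            raise ValueError("reference vector length does not match wavelength grid")
    d = spectrum.reflectance - ref
    return SyncMap(spectrum.wavelengths_nm, np.outer(d, d), provenance="per-sample", m_used=1)


def render_map(sync: SyncMap, spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """Deterministic image array of the synchronous map.

    Intensities are clipped through the normalization bounds and the
    matrix is resampled to exactly (height_px, width_px) with bilinear
    interpolation.  Identical map + spec always yields identical
    bytes.
    """
    from skimage.transform import resize

    phi = sync.phi
    if not np.all(np.isfinite(phi)):
        raise ValueError("synchronous map contains NaN/Inf; cannot render")
    if spec.normalization == "global":
        vmin, vmax = spec.vmin, spec.vmax
    else:
        vmin, vmax = float(phi.min()), float(phi.max())
    span = vmax - vmin
    norm = np.clip((phi - vmin) / span, 0.0, 1.0) if span > 0 else np.zeros_like(phi)
    img = resize(
        norm, (spec.height_px, spec.width_px), order=1, mode="edge",
        anti_aliasing=norm.shape[0] > spec.height_px, preserve_range=True,
    )
    if spec.colormap is None:
        return img
    import matplotlib

    return np.asarray(matplotlib.colormaps[spec.colormap](img)[..., :3])
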