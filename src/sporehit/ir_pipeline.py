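"""IR microspectroscopy processing for spore populations.

The chain mirrors the standard biological-IR workflow: rubberband (convex
hull) baseline subtraction, 15-point Savitzky-Golay smoothing, vector
normalization to unit Euclidean norm over the full acquired range, and a
cut to the fingerprint region 1800-950 cm-1.  Chemistry is then summarized
by linear-baseline band integrals over four canonical bands

    proteins (amide I+II)  1735-1480 cm-1
    amide I                1700-1600 cm-1
    Ca2+-DPA               1480-1330 cm-1
    carbohydrates          1180-950 cm-1

whose ratios (Ca2+-DPA/proteins, carbohydrates/proteins) track core release
and envelope restructuring with dose, and by a mean-centered PCA across the
spectra population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .exceptions import (
    CoverageError,
    DegenerateRatioError,
    InsufficientDataError,
    InvalidInputError,
)
from .sers_analysis import Spectrum

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "PreprocessParams",
    "preprocess",
    "band_integral",
    "band_ratios",
    "PCAModel",
    "fit_pca",
    "confidence_ellipse",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_cm1: float
    hi_cm1: float

    def __post_init__(self) -> None:
        if self.lo_cm1 >= self.hi_cm1:
            raise InvalidInputError(f"band {self.name!r}: lo must be < hi")


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "protein": BandDefinition("protein", 1480.0, 1735.0),
    "amide_I": BandDefinition("amide_I", 1600.0, 1700.0),
    "dpa": BandDefinition("dpa", 1330.0, 1480.0),
    "carb": BandDefinition("carb", 950.0, 1180.0),
}


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing chain.

    ``baseline`` is "rubberband" (convex-hull lower envelope, the usual
    choice for biological IR), "polynomial" (least-squares detrend of the
    given degree) or "none".  ``normalize_before_cut`` keeps the published
    order (normalize over the whole acquired range, then cut); the
    alternative order is available because processing conventions vary.
    """

    baseline: str = "rubberband"
    polynomial_degree: int = 2
    sg_window: int = 15
    sg_order: int = 2
    normalize: bool = True
    cut_lo_cm1: float = 950.0
    cut_hi_cm1: float = 1800.0
    normalize_before_cut: bool = True


def _lower_hull_baseline(nu: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rubberband baseline: lower convex hull of (nu, y), interpolated.

    Monotone-chain construction; robust for collinear/degenerate spectra
    where a general hull code would reject the input.
    """
    hull: list[int] = []
    for i in range(len(nu)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (nu[i2] - nu[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (nu[i] - nu[i1])
            if cross <= 0:  # i2 lies on/above the chord i1->i: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(nu, nu[hull], y[hull])


def preprocess(spec: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Baseline-correct, smooth, vector-normalize and cut one spectrum.

    Order: baseline subtraction, Savitzky-Golay smoothing, division by the
    Euclidean norm over the full pre-cut range, restriction to the
    fingerprint cut.  With default params the output has unit norm over the
    full range *before* cutting.
    """
    nu, y = spec.wavenumbers, spec.intensities.astype(float)
    if nu[0] > params.cut_lo_cm1 or nu[-1] < params.cut_hi_cm1:
        raise CoverageError(
            f"grid [{nu[0]:.0f}, {nu[-1]:.0f}] does not cover the cut range "
            f"[{params.cut_lo_cm1:.0f}, {params.cut_hi_cm1:.0f}] cm-1"
        )
    if params.sg_window > len(nu):
        raise InvalidInputError("Savitzky-Golay window exceeds the spectrum length")

    if params.baseline == "rubberband":
        y = y - _lower_hull_baseline(nu, y)
    elif params.baseline == "polynomial":
        coeffs = np.polynomial.polynomial.polyfit(nu, y, params.polynomial_degree)
        y = y - np.polynomial.polynomial.polyval(nu, coeffs)
    elif params.baseline != "none":
        raise InvalidInputError(f"unknown baseline method {params.baseline!r}")

    if params.sg_window > 1:
        y = savgol_filter(y, params.sg_window, params.sg_order)

    def cut(nu_, y_):
        m = (nu_ >= params.cut_lo_cm1) & (nu_ <= params.cut_hi_cm1)
        return nu_[m], y_[m]

    if params.normalize and params.normalize_before_cut:
        norm = float(np.linalg.norm(y))
        if norm == 0:
            warnings.warn("zero spectrum: skipping vector normalization")
        else:
            y = y / norm
        nu, y = cut(nu, y)
    elif params.normalize:
        nu, y = cut(nu, y)
        norm = float(np.linalg.norm(y))
        if norm == 0:
            warnings.warn("zero spectrum: skipping vector normalization")
        else:
            y = y / norm
    else:
        nu, y = cut(nu, y)
    meta = dict(spec.meta)
    meta["preprocessed"] = True
    return Spectrum(nu, y, meta)


def band_integral(spec: Spectrum, band: BandDefinition) -> float:
    """Linear-baseline band area: trapezoid of (signal - chord) over the band.

    The chord joins the spectrum's values at the two band extremes (nearest
    grid points), so adding any affine function of wavenumber leaves the
    integral unchanged.  Negative areas are possible and meaningful for
    bands depleted below the chord.
    """
    nu, y = spec.wavenumbers, spec.intensities
    if band.lo_cm1 < nu[0] or band.hi_cm1 > nu[-1]:
        raise CoverageError(
            f"band {band.name!r} [{band.lo_cm1}, {band.hi_cm1}] outside grid "
            f"[{nu[0]}, {nu[-1]}]"
        )
    i_lo = int(np.argmin(np.abs(nu - band.lo_cm1)))
    i_hi = int(np.argmin(np.abs(nu - band.hi_cm1)))
    if i_hi <= i_lo + 1:
        raise CoverageError(f"band {band.name!r} spans fewer than 3 grid points")
    x = nu[i_lo : i_hi + 1]
    s = y[i_lo : i_hi + 1]
    chord = y[i_lo] + (y[i_hi] - y[i_lo]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(s - chord, x))


def band_ratios(
    spec: Spectrum, bands: dict[str, BandDefinition] = DEFAULT_BANDS
) -> dict[str, float]:
    """Named band areas and the two diagnostic ratios.

    Returns ``dpa_over_protein`` (Ca2+-DPA retained vs protein amide I+II)
    and ``carb_over_protein`` plus the raw ``dpa_area`` and ``amideI_area``.
    Scale-invariant under uniform intensity scaling.
    """
    areas = {name: band_integral(spec, b) for name, b in bands.items()}
    protein = areas["protein"]
    if protein == 0:
        raise DegenerateRatioError("protein band area is zero; ratios undefined")
    return {
        "dpa_over_protein": areas["dpa"] / protein,
        "carb_over_protein": areas["carb"] / protein,
        "dpa_area": areas["dpa"],
        "amideI_area": areas["amide_I"],
        "protein_area": protein,
        "carb_area": areas["carb"],
    }


@dataclass
class PCAModel:
    """Mean-centered PCA of a spectra population.

    ``loadings`` rows are orthonormal component vectors with a
    deterministic sign convention (largest-magnitude element positive);
    ``scores`` are the coordinates of each training spectrum.
    """

    wavenumbers: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    def transform(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        x = np.vstack([s.intensities for s in spectra])
        return (x - self.mean_spectrum) @ self.loadings.T


def fit_pca(specs: Sequence[Spectrum], n_components: int | None = None) -> PCAModel:
    """SVD-based PCA of preprocessed spectra sharing one grid."""
    if len(specs) < 3:
        raise InsufficientDataError("PCA needs >= 3 spectra")
    ref = specs[0].wavenumbers
    for s in specs[1:]:
        if not np.array_equal(s.wavenumbers, ref):
            raise InvalidInputError("all spectra must share a common grid")
    x = np.vstack([s.intensities for s in specs])
    n_components = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|.| element of each loading made positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAModel(
        wavenumbers=ref.copy(),
        mean_spectrum=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class ConfidenceEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_rad: float  # orientation of the major axis
    degenerate: bool


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Gaussian confidence ellipse for a 2-d score cloud.

    Semi-axes are sqrt(eigenvalue * chi2.ppf(level, df=2)) of the sample
    covariance; the ellipse is centered on the sample mean.  A rank-
    deficient covariance (collinear or identical points) is flagged
    ``degenerate`` rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise InvalidInputError("scores must be an (n, 2) array")
    if scores.shape[0] < 3:
        raise InsufficientDataError("confidence ellipse needs >= 3 points")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    q = chi2.ppf(level, df=2)
    semi = np.sqrt(evals * q)  # ascending
    major_vec = evecs[:, 1]
    angle = float(np.arctan2(major_vec[1], major_vec[0]))
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[1]), float(semi[0])),
        angle_rad=angle,
        degenerate=bool(evals[0] <= 1e-12 * max(evals[1], 1.0)),
    )
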