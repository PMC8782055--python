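"""Lorentzian decomposition of SERS spectra and the Ca2+-DPA/Phe ratio.

Surface-enhanced Raman spectra of spore suspensions are decomposed into a
sum of Lorentzian modes on a low-order polynomial baseline.  The statistic
of interest is the intensity ratio I_1025/I_1000 between the Ca2+-DPA mode
(~1024-1025 cm-1, dipicolinate chelate released from the spore core) and
the phenylalanine ring-breathing mode (~1000 cm-1, coat proteins), a proxy
for Ca2+-DPA leaked into the medium that cancels instrument- and
sample-scale artifacts.

Peaks are parameterized by height rather than area because the statistic is
an intensity (peak-height) ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .exceptions import FitFailureError, InvalidInputError, MissingModeError

__all__ = [
    "Spectrum",
    "LorentzianPeak",
    "lorentzian",
    "fit_lorentzians",
    "dpa_phe_ratio",
    "average_spectra",
    "DEFAULT_SERS_PEAKS",
]

#: Canonical spore SERS mode template: phenylalanine, Ca2+-DPA, lipid CH2.
DEFAULT_SERS_PEAKS = (1000.0, 1024.0, 1400.0)

#: Search windows for the ratio's two modes (± ~6 cm-1 ≈ 4 cm-1 resolution).
DPA_WINDOW = (1018.0, 1030.0)
PHE_WINDOW = (994.0, 1006.0)

MIN_POINTS = 16


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavenumber grid (cm-1).

    Descending-order input is silently reversed to the ascending canonical
    order; duplicated or NaN entries are rejected.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if nu.ndim != 1 or nu.shape != y.shape:
            raise InvalidInputError("wavenumbers and intensities must be equal-length 1-d")
        if len(nu) < MIN_POINTS:
            raise InvalidInputError(f"spectrum needs >= {MIN_POINTS} points, got {len(nu)}")
        if np.any(~np.isfinite(nu)) or np.any(~np.isfinite(y)):
            raise InvalidInputError("spectrum contains NaN/inf")
        d = np.diff(nu)
        if np.all(d < 0):  # descending file: canonicalize
            nu, y = nu[::-1], y[::-1]
            d = -d[::-1]
        if np.any(d <= 0):
            raise InvalidInputError("wavenumbers must be strictly monotonic")
        self.wavenumbers = nu
        self.intensities = y

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return Spectrum(self.wavenumbers[m], self.intensities[m], dict(self.meta))


@dataclass(frozen=True)
class LorentzianPeak:
    """One Lorentzian mode: center nu0, half-width at half-maximum, height."""

    center_cm1: float
    hwhm_cm1: float
    height: float

    def __post_init__(self) -> None:
        if self.hwhm_cm1 <= 0:
            raise InvalidInputError("hwhm_cm1 must be > 0")
        if self.height < 0:
            raise InvalidInputError("height must be >= 0")


def lorentzian(nu, peak: LorentzianPeak):
    """height * g^2 / ((nu - nu0)^2 + g^2); equals height at the center and
    height/2 at nu0 ± hwhm."""
    nu = np.asarray(nu, dtype=float)
    g2 = peak.hwhm_cm1**2
    out = peak.height * g2 / ((nu - peak.center_cm1) ** 2 + g2)
    return float(out) if out.ndim == 0 else out


@dataclass
class LorentzianFitReport:
    peaks: list[LorentzianPeak]
    baseline_coeffs: np.ndarray  # ascending powers of (nu - window center)
    residual_ss: float
    initial_residual_ss: float
    success: bool
    low_signal: bool
    nfev: int

    def model(self, nu) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        y = np.polynomial.polynomial.polyval(nu - self._x0, self.baseline_coeffs)
        for p in self.peaks:
            y = y + lorentzian(nu, p)
        return y

    _x0: float = 0.0


def fit_lorentzians(
    spec: Spectrum,
    initial: Sequence[LorentzianPeak],
    window: tuple[float, float] | None = None,
    baseline_degree: int = 1,
    center_tolerance_cm1: float = 10.0,
) -> LorentzianFitReport:
    """Least-squares decomposition: sum of Lorentzians + polynomial baseline.

    Centers are constrained within ``center_tolerance_cm1`` of their initial
    guesses (mode assignments must not wander onto neighbouring bands);
    heights are bounded below by zero.  Returns fitted peaks sorted by
    center plus residual diagnostics; ``low_signal`` flags fits whose
    largest height is indistinguishable from the residual noise floor.
    """
    if not initial:
        raise InvalidInputError("need at least one initial peak")
    centers = sorted(p.center_cm1 for p in initial)
    if any(b - a < 1e-6 for a, b in zip(centers, centers[1:])):
        raise InvalidInputError("initial peak centers must be distinct")

    if window is None:
        window = (float(spec.wavenumbers[0]), float(spec.wavenumbers[-1]))
    lo, hi = window
    if lo < spec.wavenumbers[0] - 1e-9 or hi > spec.wavenumbers[-1] + 1e-9:
        raise InvalidInputError("fit window must lie within the spectrum grid")
    sub = spec.crop(lo, hi) if (lo, hi) != (spec.wavenumbers[0], spec.wavenumbers[-1]) else spec
    if len(sub) < 3 * len(initial):
        raise InvalidInputError(
            f"window holds {len(sub)} points; need >= {3 * len(initial)} for "
            f"{len(initial)} peaks"
        )
    nu, y = sub.wavenumbers, sub.intensities
    x0 = 0.5 * (nu[0] + nu[-1])  # center the baseline polynomial for conditioning

    params = lmfit.Parameters()
    for i, p in enumerate(sorted(initial, key=lambda q: q.center_cm1)):
        params.add(
            f"c{i}",
            value=p.center_cm1,
            min=p.center_cm1 - center_tolerance_cm1,
            max=p.center_cm1 + center_tolerance_cm1,
        )
        params.add(f"g{i}", value=p.hwhm_cm1, min=0.1, max=(hi - lo))
        params.add(f"h{i}", value=max(p.height, 1e-12), min=0.0)
    scale = float(np.max(np.abs(y))) or 1.0
    for j in range(baseline_degree + 1):
        params.add(f"b{j}", value=0.0, min=-10 * scale, max=10 * scale)

    npeaks = len(initial)

    def model_of(pars) -> np.ndarray:
        v = pars.valuesdict()
        out = np.polynomial.polynomial.polyval(
            nu - x0, [v[f"b{j}"] for j in range(baseline_degree + 1)]
        )
        for i in range(npeaks):
            g2 = v[f"g{i}"] ** 2
            out = out + v[f"h{i}"] * g2 / ((nu - v[f"c{i}"]) ** 2 + g2)
        return out

    def residual(pars) -> np.ndarray:
        return model_of(pars) - y

    init_ss = float(np.sum(residual(params) ** 2))
    # Levenberg-Marquardt can stall short of the optimum on near-degenerate
    # baselines; restart from the solution until the residual stops moving.
    result = lmfit.minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    nfev = result.nfev
    for _ in range(3):
        prev_ss = float(np.sum(np.asarray(result.residual) ** 2))
        again = lmfit.minimize(
            residual, result.params, method="leastsq", xtol=1e-12, ftol=1e-12
        )
        nfev += again.nfev
        new_ss = float(np.sum(np.asarray(again.residual) ** 2))
        if new_ss <= prev_ss:
            result = again
        if new_ss >= prev_ss * (1 - 1e-9):
            break
    if not result.success:
        raise FitFailureError(
            "Lorentzian fit did not converge", diagnostics={"message": result.message}
        )
    v = result.params.valuesdict()
    peaks = sorted(
        (
            LorentzianPeak(v[f"c{i}"], v[f"g{i}"], max(v[f"h{i}"], 0.0))
            for i in range(npeaks)
        ),
        key=lambda p: p.center_cm1,
    )
    ss = float(np.sum(np.asarray(result.residual) ** 2))
    noise_rms = (ss / len(nu)) ** 0.5
    max_h = max(p.height for p in peaks)
    # a fitted height is "signal" only if it clears both the residual noise
    # floor and a relative floor against the data scale
    floor = max(5.0 * noise_rms, 1e-9 * scale, 1e-12)
    report = LorentzianFitReport(
        peaks=peaks,
        baseline_coeffs=np.array([v[f"b{j}"] for j in range(baseline_degree + 1)]),
        residual_ss=ss,
        initial_residual_ss=init_ss,
        success=True,
        low_signal=bool(max_h <= floor),
        nfev=int(nfev),
    )
    report._x0 = x0
    return report


def _find_peak(peaks: Sequence[LorentzianPeak], window: tuple[float, float]) -> LorentzianPeak:
    cands = [p for p in peaks if window[0] <= p.center_cm1 <= window[1]]
    if not cands:
        raise MissingModeError(
            f"no fitted mode with center in [{window[0]}, {window[1]}] cm-1"
        )
    return max(cands, key=lambda p: p.height)


def dpa_phe_ratio(peaks: Sequence[LorentzianPeak]) -> float:
    """I_1025/I_1000: Ca2+-DPA mode height over phenylalanine mode height.

    Requires one fitted center in [1018, 1030] cm-1 (Ca2+-DPA) and one in
    [994, 1006] cm-1 (Phe); invariant under uniform intensity scaling of
    the parent spectrum.
    """
    dpa = _find_peak(peaks, DPA_WINDOW)
    phe = _find_peak(peaks, PHE_WINDOW)
    if phe.height == 0:
        raise MissingModeError("phenylalanine mode has zero height")
    return dpa.height / phe.height


def average_spectra(specs: Sequence[Spectrum], resample: bool = False) -> Spectrum:
    """Pointwise mean of spectra measured at different positions.

    Grids must be identical unless ``resample`` is set, in which case each
    spectrum is linearly interpolated onto the first grid.
    """
    if not specs:
        raise InvalidInputError("cannot average an empty spectrum list")
    ref = specs[0]
    rows = []
    for s in specs:
        if np.array_equal(s.wavenumbers, ref.wavenumbers):
            rows.append(s.intensities)
        elif resample:
            rows.append(np.interp(ref.wavenumbers, s.wavenumbers, s.intensities))
        else:
            raise InvalidInputError(
                "spectra are on different grids; pass resample=True to interpolate"
            )
    return Spectrum(
        ref.wavenumbers.copy(),
        np.mean(rows, axis=0),
        {"n_averaged": len(specs)},
    )
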