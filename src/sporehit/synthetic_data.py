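"""Seeded generators emulating the study's measurements.

The raw measurements behind the pipeline (plated CFU counts, SERS and IR
spectra) are not publicly deposited, so every stage is exercised against
synthetic data carrying the same statistical structure the analysis
assumes:

* survival: plated counts Poisson-distributed around N0 * P0(Phi; lambda)
  at the facility dose ladder {0, 250, 500, 1000, 1500, 2000} Gy, initial
  titre 10^8 CFU/mL, triplicate platings;
* Ca2+-DPA release: the single-event curve b + A * P1(Phi) plus Gaussian
  measurement noise;
* SERS spectra: Lorentzian modes at the spore fingerprint positions
  (Phe 1000, Ca2+-DPA 1024, lipid CH2 1400 cm-1) on a smooth cubic
  background with additive Gaussian noise;
* IR spectra: Gaussian condensed-phase bands placed so that the
  linear-baseline band integrals over the protein / Ca2+-DPA / carbohydrate
  ranges hit prescribed target areas.

Each generator is bit-reproducible for a fixed seed and stores its full
ground truth in the output metadata so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .hit_model import DEFAULT_SEED, DoseResponseDataset, release_curve, survival_curve
from .ion_physics import IonBeam, normalized_sigma
from .sers_analysis import Spectrum

__all__ = [
    "SimulationDesign",
    "simulate_survival",
    "simulate_release_series",
    "synth_sers_spectrum",
    "synth_ir_spectrum",
    "IR_MODE_POSITIONS",
]

#: Facility dose ladder (Gy).
DEFAULT_DOSES = (0.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0)


@dataclass
class SimulationDesign:
    """Study design for dose-response simulation.

    Defaults reproduce the irradiation campaign's conditions: the Fe dose
    ladder up to 2000 Gy, 10^8 CFU/mL initial titre, triplicate platings.
    ``lambda_gy`` defaults to the fitted dose scale 258 Gy.
    """

    ion: str = "Fe"
    doses: tuple[float, ...] = DEFAULT_DOSES
    lambda_gy: float = 258.0
    n0_cfu: float = 1e8
    replicates: int = 3
    amplitude: float = 1.0
    baseline: float = 0.2
    noise_sd: float = 0.05
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise InvalidInputError("doses must be >= 0")
        if self.n0_cfu <= 0:
            raise InvalidInputError("n0_cfu must be > 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if self.lambda_gy <= 0:
            raise InvalidInputError("lambda_gy must be > 0")


def _phi(design: SimulationDesign, beam: IonBeam | None, reference: IonBeam | None):
    doses = np.asarray(design.doses, dtype=float)
    if beam is not None and reference is not None:
        return doses * normalized_sigma(beam, reference)
    return doses


def simulate_survival(
    design: SimulationDesign,
    beam: IonBeam | None = None,
    reference: IonBeam | None = None,
) -> DoseResponseDataset:
    """Poisson counting noise around the zero-event survival curve.

    For each dose and replicate draws N ~ Poisson(n0 * P0(Phi; lambda)),
    with Phi the reference-equivalent dose when beam/reference are given
    (raw doses otherwise), and returns counts plus N/N0 responses against
    the nominal titre.
    """
    rng = np.random.default_rng(design.seed)
    phi = _phi(design, beam, reference)
    doses, resp, counts = [], [], []
    for d, p in zip(design.doses, phi):
        mean = design.n0_cfu * survival_curve(p, design.lambda_gy)
        for _ in range(design.replicates):
            n = float(rng.poisson(mean))
            doses.append(d)
            counts.append((n, design.n0_cfu))
            resp.append(n / design.n0_cfu)
    return DoseResponseDataset(
        ion=design.ion,
        doses=np.array(doses),
        responses=np.array(resp),
        response_kind="survival",
        counts=counts,
        meta={"truth": {"lambda_gy": design.lambda_gy, "n0_cfu": design.n0_cfu},
              "seed": design.seed},
    )


def simulate_release_series(
    design: SimulationDesign,
    beam: IonBeam | None = None,
    reference: IonBeam | None = None,
) -> DoseResponseDataset:
    """Gaussian noise around the single-event release curve b + A*P1(Phi)."""
    rng = np.random.default_rng(design.seed)
    phi = _phi(design, beam, reference)
    doses, resp = [], []
    for d, p in zip(design.doses, phi):
        mean = release_curve(p, design.lambda_gy, design.amplitude, design.baseline)
        for _ in range(design.replicates):
            doses.append(d)
            resp.append(mean + rng.normal(0.0, design.noise_sd))
    return DoseResponseDataset(
        ion=design.ion,
        doses=np.array(doses),
        responses=np.array(resp),
        response_kind="release_ratio",
        meta={
            "truth": {
                "lambda_gy": design.lambda_gy,
                "amplitude": design.amplitude,
                "baseline": design.baseline,
                "noise_sd": design.noise_sd,
            },
            "seed": design.seed,
        },
    )


def synth_sers_spectrum(
    ratio: float,
    noise_sd: float = 0.005,
    seed: int = DEFAULT_SEED,
    background_scale: float = 0.3,
) -> Spectrum:
    """Spore-like SERS spectrum with a prescribed I_1025/I_1000 ratio.

    Lorentzian modes at 1000 cm-1 (Phe, height 1), 1024 cm-1 (Ca2+-DPA,
    height = ratio) and 1400 cm-1 (lipid CH2), a smooth cubic polynomial
    background of relative scale ``background_scale``, and additive
    Gaussian noise of standard deviation ``noise_sd`` (fractions of the Phe
    height), on an 870-1500 cm-1 grid at 2 cm-1 spacing.
    """
    if ratio < 0:
        raise InvalidInputError("ratio must be >= 0")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    nu = np.arange(870.0, 1500.0 + 1e-9, 2.0)
    peaks = [(1000.0, 6.0, 1.0), (1024.0, 6.0, ratio), (1400.0, 10.0, 0.6)]
    y = np.zeros_like(nu)
    for c, g, h in peaks:
        y += h * g**2 / ((nu - c) ** 2 + g**2)
    # smooth cubic background, centered for conditioning
    x = (nu - nu.mean()) / (nu[-1] - nu[0])
    bg_coeffs = background_scale * np.array([1.0, -0.4, 0.3, -0.2])
    y += np.polynomial.polynomial.polyval(x, bg_coeffs)
    y += rng.normal(0.0, noise_sd, size=nu.shape)
    return Spectrum(
        nu,
        y,
        meta={
            "truth": {
                "ratio": ratio,
                "peaks": peaks,
                "background_coeffs": bg_coeffs.tolist(),
                "noise_sd": noise_sd,
            },
            "seed": seed,
        },
    )


#: Gaussian mode positions (center, sigma) per IR band group.
IR_MODE_POSITIONS = {
    "protein": [(1654.0, 18.0), (1540.0, 16.0)],       # amide I, amide II
    "dpa": [(1445.0, 12.0), (1395.0, 12.0)],           # dipicolinate doublet
    "carb": [(1100.0, 12.0), (1070.0, 10.0), (1020.0, 10.0), (990.0, 9.0)],
}

_IR_BAND_LIMITS = {"protein": (1480.0, 1735.0), "dpa": (1330.0, 1480.0),
                   "carb": (950.0, 1180.0)}


def synth_ir_spectrum(
    band_targets: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
) -> Spectrum:
    """Spore-like IR spectrum whose band integrals hit prescribed areas.

    ``band_targets`` gives desired linear-baseline integrals (in intensity
    x cm-1) for the "protein", "dpa" and "carb" bands.  Each band group is a
    fixed composite of Gaussian modes at the canonical positions; the group
    amplitude is solved so the chord-subtracted trapezoidal integral over
    the band equals the target on the generation grid (900-1850 cm-1 at
    2 cm-1 — a margin beyond the 950-1800 fingerprint cut, as instruments
    acquire well past it, so smoothing edge effects stay outside the cut).
    An optional affine baseline and Gaussian noise are added on top; the
    chord construction makes the targets immune to the affine term.
    """
    for name in band_targets:
        if name not in IR_MODE_POSITIONS:
            raise InvalidInputError(f"unknown band {name!r}")
        if band_targets[name] < 0:
            raise InvalidInputError("band target areas must be >= 0")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    nu = np.arange(900.0, 1850.0 + 1e-9, 2.0)

    def chord_area(shape: np.ndarray, lo: float, hi: float) -> float:
        m = (nu >= lo) & (nu <= hi)
        x, seg = nu[m], shape[m]
        chord = seg[0] + (seg[-1] - seg[0]) * (x - x[0]) / (x[-1] - x[0])
        return float(np.trapezoid(seg - chord, x))

    names = list(band_targets)
    shapes = {}
    for name in names:
        shape = np.zeros_like(nu)
        for c, s in IR_MODE_POSITIONS[name]:
            shape += np.exp(-0.5 * ((nu - c) / s) ** 2)
        shapes[name] = shape
    # Gaussian tails leak across neighbouring bands (e.g. the 1445 cm-1
    # dipicolinate mode under the 1480 cm-1 protein-band anchor), so the
    # group amplitudes are solved jointly: A[i,j] = area contributed to
    # band i by unit-amplitude group j.
    a = np.array(
        [[chord_area(shapes[j], *_IR_BAND_LIMITS[i]) for j in names] for i in names]
    )
    t = np.array([band_targets[n] for n in names])
    amps = np.linalg.solve(a, t)
    amplitudes = {n: float(v) for n, v in zip(names, amps)}
    y = np.zeros_like(nu)
    for n in names:
        y += amplitudes[n] * shapes[n]
    y += baseline_offset + baseline_slope * (nu - nu[0])
    y += rng.normal(0.0, noise_sd, size=nu.shape)
    return Spectrum(
        nu,
        y,
        meta={
            "truth": {
                "band_targets": dict(band_targets),
                "amplitudes": amplitudes,
                "baseline_slope": baseline_slope,
                "baseline_offset": baseline_offset,
                "noise_sd": noise_sd,
            },
            "seed": seed,
        },
    )
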