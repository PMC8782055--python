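"""Erlang/Poisson target-hit dose-response model.

Target theory treats radiation damage as discrete "hit" events whose number
in a sensitive volume is Poisson distributed with mean Phi / lambda, where
Phi is the (Fe-equivalent) dose and lambda the mean dose per event.  The
probability of exactly k events,

    P_k(Phi) = (Phi/lambda)^k * exp(-Phi/lambda) / k!,

drives both observables of the study:

* spore survival is the zero-event probability, N/N0 = P_0(Phi) =
  exp(-Phi/lambda) — a pure exponential inactivation curve;
* Ca2+-DPA release (germination-like response) is activated by exactly one
  event, so the release statistic follows b + A * P_1(Phi), which rises to
  a unique maximum at Phi = lambda — the release threshold dose.

A single dose scale lambda (about 258 Gy on the Fe axis in the study this
model targets) then describes both the survival decay and the position of
the release maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    InvalidModelError,
    NonIdentifiableError,
)
from .ion_physics import IonBeam, normalized_sigma

__all__ = [
    "DoseResponseDataset",
    "HitModelFit",
    "erlang_hit_probability",
    "survival_curve",
    "release_curve",
    "fit_survival",
    "fit_release",
    "threshold_dose",
    "bootstrap_ci",
]

#: Default seed for stochastic routines (study publication date).
DEFAULT_SEED = 20220116


@dataclass
class DoseResponseDataset:
    """Measured responses of one ion series over a dose ladder.

    ``responses`` are either surviving fractions N/N0 (``response_kind =
    "survival"``) or a dimensionless release-ratio statistic
    (``response_kind = "release_ratio"``).  Optional plated counts
    ``counts`` hold (N, N0) pairs per row and enable the Poisson-likelihood
    survival fit.
    """

    ion: str
    doses: np.ndarray
    responses: np.ndarray
    response_kind: Literal["survival", "release_ratio"]
    counts: list[tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise InvalidInputError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise InvalidInputError("doses must be >= 0")
        if self.response_kind not in ("survival", "release_ratio"):
            raise InvalidInputError(
                f"unknown response_kind {self.response_kind!r}"
            )
        if self.response_kind == "survival" and np.any(self.responses < 0):
            raise InvalidInputError("survival fractions must be >= 0")
        if self.counts is not None:
            if len(self.counts) != len(self.doses):
                raise InvalidInputError("counts must align with doses")
            if any(n0 <= 0 for _, n0 in self.counts):
                raise InvalidInputError("N0 must be > 0 where counts present")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class HitModelFit:
    """Fitted Erlang hit-model parameters with uncertainties."""

    k: int
    lambda_gy: float
    amplitude: float = 1.0
    baseline: float = 0.0
    lambda_se: float = float("nan")
    covariance: np.ndarray | None = None
    residual_ss: float = float("nan")
    n_points: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        """JSON-serializable summary record."""
        rec = {
            "k": self.k,
            "lambda_gy": self.lambda_gy,
            "lambda_se": self.lambda_se,
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
        }
        rec.update({k: v for k, v in self.diagnostics.items() if np.isscalar(v)})
        return rec


def erlang_hit_probability(phi, k: int, lambda_gy: float):
    """Probability of exactly k hit events at equivalent dose ``phi``.

    Poisson pmf with mean phi/lambda: (phi/lambda)^k e^(-phi/lambda) / k!.
    Accepts scalar or array ``phi``.
    """
    if lambda_gy <= 0:
        raise InvalidInputError("lambda_gy must be > 0")
    if k < 0 or int(k) != k:
        raise InvalidInputError("k must be a non-negative integer")
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise InvalidInputError("phi must be >= 0")
    mu = phi / lambda_gy
    with np.errstate(divide="ignore"):
        # log-space evaluation stays finite for large k * log(mu)
        log_p = np.where(
            mu > 0,
            k * np.log(np.where(mu > 0, mu, 1.0)) - mu - math.lgamma(k + 1),
            0.0 if k == 0 else -np.inf,
        )
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


def survival_curve(phi, lambda_gy: float):
    """Predicted surviving fraction N/N0 = P_0(phi) = exp(-phi/lambda)."""
    return erlang_hit_probability(phi, 0, lambda_gy)


def release_curve(phi, lambda_gy: float, amplitude: float = 1.0, baseline: float = 0.0):
    """Predicted release ratio b + A * P_1(phi).

    Unimodal in phi with maximum b + A/e at phi = lambda.
    """
    if amplitude < 0:
        raise InvalidInputError("amplitude must be >= 0")
    return baseline + amplitude * erlang_hit_probability(phi, 1, lambda_gy)


def _equivalent_doses(
    doses: np.ndarray,
    equivalent: bool,
    beam: IonBeam | None,
    reference: IonBeam | None,
) -> np.ndarray:
    if not equivalent:
        return doses
    if beam is None or reference is None:
        raise InvalidInputError(
            "equivalent=True requires both beam and reference IonBeam objects"
        )
    return doses * normalized_sigma(beam, reference)


def fit_survival(
    data: DoseResponseDataset,
    equivalent: bool = False,
    beam: IonBeam | None = None,
    reference: IonBeam | None = None,
    method: Literal["loglinear", "poisson"] = "loglinear",
) -> HitModelFit:
    """Fit the k = 0 survival model N/N0 = exp(-Phi/lambda).

    Default is the closed-form no-intercept regression of ln(N/N0) on Phi
    (the zero-event model forces N/N0 = 1 at Phi = 0, so there is no free
    amplitude): lambda_hat = -1/slope with slope = sum(Phi*ln r)/sum(Phi^2).
    Survival values of exactly zero are excluded from the log fit (the log
    is undefined there); ``method="poisson"`` instead maximizes the Poisson
    likelihood of the raw plated counts and uses every row.

    With ``equivalent=True``, doses are first mapped to the reference-ion
    axis via the cross-section ratio, so lambda_hat is reported on the
    Fe-equivalent scale.
    """
    if data.response_kind != "survival":
        raise InvalidInputError("fit_survival needs response_kind='survival'")
    phi_all = _equivalent_doses(data.doses, equivalent, beam, reference)

    if method == "poisson":
        return _fit_survival_poisson(data, phi_all)

    mask = data.responses > 0
    phi = phi_all[mask]
    resp = data.responses[mask]
    if len(np.unique(phi)) < 2:
        raise InsufficientDataError(
            "need >= 2 distinct doses with positive survival responses"
        )
    y = np.log(resp)
    sxx = float(np.sum(phi**2))
    if sxx == 0:
        raise InsufficientDataError("all positive-response doses are zero")
    slope = float(np.sum(phi * y)) / sxx
    if slope >= 0:
        raise NonIdentifiableError(
            "survival does not decrease with dose; lambda is not identifiable"
        )
    lam = -1.0 / slope
    resid = y - slope * phi
    n = len(phi)
    dof = max(n - 1, 1)
    slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    lambda_se = slope_se / slope**2  # delta method on lambda = -1/slope
    n_excluded = int(np.sum(~mask))
    return HitModelFit(
        k=0,
        lambda_gy=lam,
        amplitude=1.0,
        baseline=0.0,
        lambda_se=lambda_se,
        covariance=np.array([[lambda_se**2]]),
        residual_ss=float(np.sum(resid**2)),
        n_points=n,
        diagnostics={"method": "loglinear", "n_zero_excluded": n_excluded},
    )


def _fit_survival_poisson(data: DoseResponseDataset, phi: np.ndarray) -> HitModelFit:
    """Poisson MLE for lambda from raw plated counts N ~ Poisson(N0 e^(-Phi/lambda)).

    Uses every row, including zero counts.  The score equation is solved in
    theta = 1/lambda by damped Newton iteration; the SE comes from the
    observed Fisher information.
    """
    if data.counts is None:
        raise InvalidInputError("method='poisson' requires counts (N, N0) per dose")
    n = np.array([c[0] for c in data.counts], dtype=float)
    n0 = np.array([c[1] for c in data.counts], dtype=float)
    if len(np.unique(phi)) < 2:
        raise InsufficientDataError("need >= 2 distinct doses")
    if np.all(n >= n0):
        raise NonIdentifiableError("no killing observed; lambda not identifiable")

    def negloglik(theta: float) -> float:
        mu = n0 * np.exp(-phi * theta)
        return float(np.sum(mu - n * np.log(mu)))

    # Newton on d/dtheta: sum((n - mu) * phi) = 0, mu = n0 exp(-phi theta)
    with np.errstate(divide="ignore"):
        start = [
            -np.sum(phi * np.log(np.maximum(n / n0, 1e-300))) / np.sum(phi**2)
        ]
    theta = max(start[0], 1e-12)
    for _ in range(200):
        mu = n0 * np.exp(-phi * theta)
        grad = float(np.sum((n - mu) * phi))  # d(negloglik)/dtheta
        hess = float(np.sum(mu * phi**2))  # d2(negloglik)/dtheta2 > 0
        if hess <= 0:
            break
        step = grad / hess
        new = theta - step
        while new <= 0 or negloglik(new) > negloglik(theta) + 1e-12:
            step /= 2
            new = theta - step
            if abs(step) < 1e-18:
                break
        if abs(new - theta) < 1e-14 * max(theta, 1.0):
            theta = new
            break
        theta = new
    lam = 1.0 / theta
    mu = n0 * np.exp(-phi * theta)
    info = float(np.sum(mu * phi**2))  # observed Fisher information in theta
    theta_se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    lambda_se = theta_se / theta**2
    return HitModelFit(
        k=0,
        lambda_gy=lam,
        lambda_se=lambda_se,
        covariance=np.array([[lambda_se**2]]),
        residual_ss=float(np.sum((n / n0 - np.exp(-phi * theta)) ** 2)),
        n_points=len(phi),
        diagnostics={"method": "poisson"},
    )


def fit_release(
    data: DoseResponseDataset,
    equivalent: bool = False,
    beam: IonBeam | None = None,
    reference: IonBeam | None = None,
    n_starts: int = 10,
) -> HitModelFit:
    """Fit the k = 1 release model b + A (Phi/lambda) exp(-Phi/lambda).

    Bounded nonlinear least squares with a deterministic multistart over
    ``n_starts`` log-spaced lambda values spanning [min positive dose / 4,
    max dose]; the unimodal curve has flat tails that trap single-start
    optimizers.  A lambda_hat pinned at the lower bound (data with no
    interior maximum) is flagged in ``diagnostics["lambda_at_bound"]``.
    """
    if data.response_kind != "release_ratio":
        raise InvalidInputError("fit_release needs response_kind='release_ratio'")
    phi = _equivalent_doses(data.doses, equivalent, beam, reference)
    resp = data.responses
    if len(np.unique(phi)) < 3:
        raise InsufficientDataError("need >= 3 distinct doses for the k=1 fit")

    pos = phi[phi > 0]
    lam_lo, lam_hi = float(pos.min()) / 4.0, float(phi.max())
    starts = np.geomspace(lam_lo, lam_hi, n_starts)
    span = float(resp.max() - resp.min())
    a0 = max(span * math.e, 1e-6)  # peak height above baseline is A/e
    b0 = max(float(resp.min()), 0.0)

    def resid(p: np.ndarray) -> np.ndarray:
        lam, a, b = p
        mu = phi / lam
        return b + a * mu * np.exp(-mu) - resp

    best = None
    for lam0 in starts:
        try:
            sol = least_squares(
                resid,
                x0=[lam0, a0, b0],
                bounds=([lam_lo, 0.0, 0.0], [4 * lam_hi, np.inf, np.inf]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy failures per start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError(
            "release-curve fit failed to converge from every start",
            diagnostics={"starts": list(starts)},
        )
    lam, a, b = best.x
    # Gaussian-approximation covariance from the Jacobian at the optimum
    jac = best.jac
    dof = max(len(phi) - 3, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        lambda_se = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        cov, lambda_se = None, float("nan")
    at_bound = bool(lam <= lam_lo * (1 + 1e-6))
    return HitModelFit(
        k=1,
        lambda_gy=float(lam),
        amplitude=float(a),
        baseline=float(b),
        lambda_se=lambda_se,
        covariance=cov,
        residual_ss=float(2 * best.cost),
        n_points=len(phi),
        diagnostics={"lambda_at_bound": at_bound, "n_starts": n_starts},
    )


def threshold_dose(fit: HitModelFit) -> float:
    """Release-threshold dose: the argmax of the k = 1 curve, which is lambda.

    d/dPhi [(Phi/lambda) e^(-Phi/lambda)] = 0 at Phi = lambda, so the dose
    at which single-event activation peaks equals the fitted dose scale.
    """
    if fit.k != 1:
        raise InvalidModelError("threshold dose is defined for the k=1 release fit")
    return fit.lambda_gy


def bootstrap_ci(
    data: DoseResponseDataset,
    fitter: Callable[[DoseResponseDataset], HitModelFit] = fit_survival,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
    level: float = 0.95,
) -> tuple[float, float]:
    """Case-resampling percentile bootstrap interval for lambda.

    Rows (dose, response[, counts]) are resampled with replacement; the
    supplied ``fitter`` is applied to each replicate and the percentile
    interval of the lambda_hat distribution returned.  Deterministic for a
    fixed seed.  Replicates on which the fitter raises (e.g. a resample
    drawing a single dose) are skipped.
    """
    if n_boot < 100:
        raise InvalidInputError("n_boot must be >= 100")
    if len(data) < 3:
        raise InsufficientDataError("bootstrap needs >= 3 data points")
    rng = np.random.default_rng(seed)
    n = len(data)
    lams = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = DoseResponseDataset(
            ion=data.ion,
            doses=data.doses[idx],
            responses=data.responses[idx],
            response_kind=data.response_kind,
            counts=[data.counts[i] for i in idx] if data.counts else None,
        )
        try:
            lams.append(fitter(boot).lambda_gy)
        except (InsufficientDataError, NonIdentifiableError, FitFailureError):
            continue
    if len(lams) < n_boot // 2:
        raise FitFailureError(
            "bootstrap failed on most replicates",
            diagnostics={"n_ok": len(lams), "n_boot": n_boot},
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(lams, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
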