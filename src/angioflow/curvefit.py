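"""Reference-curve models for time-density curves and their fitting.

Three parametric models reconstruct a noise-free, recirculation-free
reference curve from a sampled TDC:

* **Gamma variate** ``C(t) = Ka (t-AT)^alpha exp(-(t-AT)/beta)`` for
  ``t > AT`` (else 0) — the standard first-pass indicator-dilution shape:
  sharp wash-in, slow exponential wash-out. Its maximum sits at
  ``AT + alpha*beta`` and its area is ``Ka beta^(alpha+1) Gamma(alpha+1)``.
* **Lagged normal** — the convolution of a Gaussian ``N(mu, sigma^2)`` with
  a single exponential of rate ``lam`` (an exponentially modified Gaussian),
  modelling random dispersion plus compartmental mixing. Evaluated in the
  closed form ``(A/2) * K * [1 + erf(L)]`` with
  ``K = lam * exp(-lam t + lam mu + lam^2 sigma^2 / 2)`` and
  ``L = (t - mu - lam sigma^2) / sqrt(2 sigma^2)``; the implementation uses
  the numerically stable ``erfcx`` formulation of the same expression.
  Mean and variance are ``mu + 1/lam`` and ``sigma^2 + 1/lam^2``.
* **6th-degree polynomial** ``C(t) = sum_{i=1..7} a_i t^(i-1)`` by ordinary
  least squares over a fit window, clamped non-negative and zero outside
  the window for downstream use.

The nonlinear models are fitted by a coarse parameter grid followed by an
iterative fine refinement (pattern search) that minimizes the RMS residual;
the linear scale (``Ka`` or ``A``) is solved in closed form at every
candidate, which removes one grid dimension exactly.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import json
import math
import os
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import special

from .errors import FitError, NoBolusError
from .tdc import TimeDensityCurve

__all__ = [
    "FitModel",
    "GammaVariateParams",
    "LaggedNormalParams",
    "PolynomialParams",
    "FittedCurve",
    "evaluate",
    "fit",
    "fit_gamma_variate",
    "fit_lagged_normal",
    "fit_polynomial",
    "fit_to_json",
]


class FitModel(str, enum.Enum):
    GAMMA_VARIATE = "GAMMA_VARIATE"
    LAGGED_NORMAL = "LAGGED_NORMAL"
    POLYNOMIAL = "POLYNOMIAL"
    NONE = "NONE"


# ---------------------------------------------------------------------------
# Parameter containers and closed-form evaluation


@dataclasses.dataclass(frozen=True)
class GammaVariateParams:
    """Scale ``ka`` (intensity), appearance time ``at_s`` (s), shape
    ``alpha`` (dimensionless), decay scale ``beta_s`` (s)."""

    ka: float
    at_s: float
    alpha: float
    beta_s: float

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.alpha > 0 and self.beta_s > 0 and self.at_s >= 0):
            raise ValueError(f"invalid gamma-variate parameters: {self}")

    @property
    def peak_time_s(self) -> float:
        """Stationary point of the gamma variate: ``AT + alpha*beta``."""
        return self.at_s + self.alpha * self.beta_s

    @property
    def area(self) -> float:
        """Analytic area ``Ka beta^(alpha+1) Gamma(alpha+1)``."""
        return self.ka * self.beta_s ** (self.alpha + 1) * math.gamma(self.alpha + 1)


@dataclasses.dataclass(frozen=True)
class LaggedNormalParams:
    """Area ``area`` (intensity*s), Gaussian mean ``mu_s`` (s) and SD
    ``sigma_s`` (s), exponential rate ``lam_per_s`` (1/s)."""

    area: float
    mu_s: float
    sigma_s: float
    lam_per_s: float

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.sigma_s > 0 and self.lam_per_s > 0):
            raise ValueError(f"invalid lagged-normal parameters: {self}")

    @property
    def mean_s(self) -> float:
        return self.mu_s + 1.0 / self.lam_per_s

    @property
    def variance_s2(self) -> float:
        return self.sigma_s**2 + 1.0 / self.lam_per_s**2


@dataclasses.dataclass(frozen=True)
class PolynomialParams:
    """Ascending-power coefficients ``a1..a7`` and the fit window (s)."""

    coefficients: tuple
    fit_window: tuple

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) != 7:
            raise ValueError(f"exactly 7 coefficients required; got {len(coeffs)}")
        t0, t1 = self.fit_window
        if not t0 < t1:
            raise ValueError(f"fit window must satisfy t_start < t_end; got {self.fit_window}")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "fit_window", (float(t0), float(t1)))


def _gamma_variate_values(t: np.ndarray, p: GammaVariateParams) -> np.ndarray:
    x = np.asarray(t, dtype=np.float64) - p.at_s
    pos = x > 0
    out = np.zeros_like(x)
    # log-space evaluation avoids overflow of x**alpha at large alpha
    xp = x[pos]
    out[pos] = np.exp(np.log(p.ka) + p.alpha * np.log(xp) - xp / p.beta_s)
    return out


def _emg_unit(t, mu, sigma, lam) -> np.ndarray:
    """Unit-area lagged normal (EMG), numerically stable everywhere.

    ``(1/2) K [1 + erf(L)]`` is rewritten via ``erfcx`` for the body; deep in
    the exponential tail (L >> 0, where erfcx(-L) overflows) the asymptotic
    ``lam * exp(-lam (t - mu) + (lam sigma)^2 / 2)`` is exact to double
    precision because ``1 + erf(L)`` has saturated at 2.
    """
    z = (t - mu) / sigma
    ell = (t - mu - lam * sigma**2) / (math.sqrt(2.0) * sigma)
    with np.errstate(over="ignore", invalid="ignore"):
        body = 0.5 * lam * special.erfcx(-ell) * np.exp(-0.5 * z**2)
        tail = lam * np.exp(-lam * (t - mu) + 0.5 * (lam * sigma) ** 2)
    return np.where(ell > 20.0, tail, body)


def _lagged_normal_values(t: np.ndarray, p: LaggedNormalParams) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    # (A/2) K [1 + erf(L)] with K, L the closed-form EMG intermediates
    return p.area * _emg_unit(t, p.mu_s, p.sigma_s, p.lam_per_s)


def _polynomial_values(t: np.ndarray, p: PolynomialParams) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    t0, t1 = p.fit_window
    inside = (t >= t0) & (t <= t1)
    out = np.zeros_like(t)
    out[inside] = np.maximum(np.polynomial.polynomial.polyval(t[inside], p.coefficients), 0.0)
    return out


# ---------------------------------------------------------------------------
# Fitted curve container


@dataclasses.dataclass(frozen=True)
class FittedCurve:
    """A continuously evaluable reference curve tied to its source TDC.

    ``rmse`` is the root-mean-square residual between :meth:`evaluate` at the
    source sample times and the source values. ``model == NONE`` wraps the
    raw samples with piecewise-linear interpolation and ``rmse == 0``.
    """

    model: FitModel
    params: object | None
    rmse: float
    source: TimeDensityCurve

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        return evaluate(self, times)

    @property
    def delta_t_s(self) -> float:
        return self.source.delta_t_s


def evaluate(curve: FittedCurve, times: np.ndarray) -> np.ndarray:
    """Pointwise model value of a fitted curve at arbitrary times."""
    times = np.asarray(times, dtype=np.float64)
    if curve.model is FitModel.GAMMA_VARIATE:
        return _gamma_variate_values(times, curve.params)
    if curve.model is FitModel.LAGGED_NORMAL:
        return _lagged_normal_values(times, curve.params)
    if curve.model is FitModel.POLYNOMIAL:
        return _polynomial_values(times, curve.params)
    if curve.model is FitModel.NONE:
        return np.interp(times, curve.source.times_s, curve.source.values)
    raise ValueError(f"unknown model {curve.model!r}")


def _rms_residual(curve: FittedCurve) -> float:
    resid = curve.evaluate(curve.source.times_s) - curve.source.values
    return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# Coarse-to-fine RMSE minimization
#
# batch objective: thetas (k, d) -> (rmse (k,), amplitude (k,)) with the
# linear scale solved by non-negative closed-form least squares per row.


def _amplitude_and_rmse(y: np.ndarray, designs: np.ndarray):
    mm = np.einsum("kn,kn->k", designs, designs)
    my = designs @ y
    safe = mm > 0
    amp = np.where(safe, np.maximum(my, 0.0) / np.where(safe, mm, 1.0), 0.0)
    resid = y[None, :] - amp[:, None] * designs
    rmse = np.sqrt(np.mean(resid**2, axis=1))
    rmse[~np.isfinite(rmse)] = np.inf
    return rmse, amp


_REFINE_ROUNDS = 10
_STEP_SHRINK = 5.0
_MAX_MOVES_PER_ROUND = 300


def _pattern_refine(
    objective: Callable[[np.ndarray], tuple],
    theta0: np.ndarray,
    steps: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    tie_index: int,
    tol: float,
):
    """Iterative fine refinement around the incumbent.

    Each round explores the +-1 step neighborhood per parameter (all 3^d
    combinations), moving greedily until no move improves the RMSE by more
    than ``tol``; the step then shrinks by ``_STEP_SHRINK``. RMSE ties are
    broken toward the smaller value of ``theta[tie_index]`` for determinism.
    Monotone by construction: the incumbent is only ever replaced by a
    candidate with smaller RMSE.
    """
    d = theta0.size
    offsets = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=d)))
    theta = theta0.astype(np.float64).copy()
    rmse, amp = objective(theta[None, :])
    best_rmse, best_amp = float(rmse[0]), float(amp[0])
    step = steps.astype(np.float64).copy()

    for _ in range(_REFINE_ROUNDS):
        for _ in range(_MAX_MOVES_PER_ROUND):
            cand = np.clip(theta[None, :] + offsets * step[None, :], lower, upper)
            rmse, amp = objective(cand)
            order = np.lexsort((cand[:, tie_index], rmse))
            j = order[0]
            if rmse[j] < best_rmse - tol:
                theta, best_rmse, best_amp = cand[j].copy(), float(rmse[j]), float(amp[j])
            else:
                break
        step /= _STEP_SHRINK
    return theta, best_rmse, best_amp


def _prepare_bolus(tdc: TimeDensityCurve):
    t = tdc.times_s
    y = tdc.values
    peak = float(y.max())
    if not peak > 0:
        raise NoBolusError("curve has no positive peak; nothing to fit (no bolus)")
    i_peak = int(np.argmax(y))
    above = np.flatnonzero(y > 0.05 * peak)
    t_onset = float(t[above[0]])  # first sample exceeding 5% of peak
    return t, y, peak, float(t[i_peak]), t_onset


def fit_gamma_variate(tdc: TimeDensityCurve, refine: bool = True) -> FittedCurve:
    """Fit the gamma-variate model by coarse grid + fine RMSE refinement.

    The coarse grid spans shape ``alpha``, appearance time ``AT`` (from the
    curve start up to the 5%-of-peak onset) and decay ``beta`` anchored so
    the model peak ``AT + alpha*beta`` lands near the observed peak. ``Ka``
    is solved in closed form at every candidate. ``refine=False`` stops after
    the coarse grid (used to verify monotone descent).
    """
    t, y, peak, t_peak, t_onset = _prepare_bolus(tdc)
    dt = tdc.delta_t_s
    t0, t_last = float(t[0]), float(t[-1])

    def objective(thetas: np.ndarray):
        designs, log_ref = _gv_designs(t, thetas)
        rmse, amp = _amplitude_and_rmse(y, designs)
        # undo the per-row peak normalization so amp is the true Ka
        return rmse, amp * np.exp(-log_ref)

    alpha_grid = np.geomspace(0.6, 30.0, 7)
    at_hi = max(t0, t_onset - 0.25 * dt)
    at_grid = np.unique(np.linspace(t0, at_hi, 6))
    cands = []
    for alpha in alpha_grid:
        for at in at_grid:
            beta_anchor = max((t_peak - at) / alpha, dt / 4.0)
            for mult in (0.6, 1.0, 1.6):
                cands.append((alpha, beta_anchor * mult, at))
    cands = np.array(cands)
    rmse, _ = objective(cands)
    order = np.lexsort((cands[:, 2], rmse))
    theta = cands[order[0]]
    best_rmse = rmse[order[0]]
    if not np.isfinite(best_rmse):
        raise FitError("gamma-variate fit failed to bracket a finite-RMSE solution")

    if refine:
        steps = np.array(
            [
                max(0.5 * theta[0], 0.2),
                max(0.5 * theta[1], dt / 10.0),
                max(at_grid[1] - at_grid[0] if at_grid.size > 1 else dt, dt / 2.0),
            ]
        )
        lower = np.array([1e-2, 1e-4, t0])
        upper = np.array([150.0, 10.0 * (t_last - t0), t_last - dt])
        theta, best_rmse, _ = _pattern_refine(
            objective, theta, steps, lower, upper, tie_index=2, tol=1e-9 * max(1.0, peak)
        )

    _, amp = objective(theta[None, :])
    ka = float(amp[0])
    if not (np.isfinite(best_rmse) and ka > 0):
        raise FitError("gamma-variate fit failed to bracket a finite-RMSE solution")
    params = GammaVariateParams(ka=ka, at_s=max(float(theta[2]), 0.0), alpha=float(theta[0]), beta_s=float(theta[1]))
    curve = FittedCurve(FitModel.GAMMA_VARIATE, params, 0.0, tdc)
    return dataclasses.replace(curve, rmse=_rms_residual(curve))


def _gv_designs(t: np.ndarray, thetas: np.ndarray):
    """Peak-normalized gamma-variate design rows for a batch of
    (alpha, beta, AT) candidates; returns (designs, log normalization)."""
    alpha = thetas[:, 0][:, None]
    beta = thetas[:, 1][:, None]
    at = thetas[:, 2][:, None]
    x = t[None, :] - at
    pos = x > 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        logm = np.where(pos, alpha * np.log(np.where(pos, x, 1.0)) - x / beta, -np.inf)
        ref = np.max(logm, axis=1, keepdims=True)
        ref = np.where(np.isfinite(ref), ref, 0.0)
        return np.where(pos, np.exp(logm - ref), 0.0), ref[:, 0]


def fit_lagged_normal(tdc: TimeDensityCurve, refine: bool = True) -> FittedCurve:
    """Fit the lagged-normal (EMG) model over (mu, sigma, lam); area in
    closed form. Same coarse-to-fine strategy as the gamma variate."""
    t, y, peak, t_peak, t_onset = _prepare_bolus(tdc)
    dt = tdc.delta_t_s
    t0, t_last = float(t[0]), float(t[-1])
    width = max(t_peak - t_onset, 2.0 * dt)

    def objective(thetas: np.ndarray):
        mu = thetas[:, 0][:, None]
        sigma = thetas[:, 1][:, None]
        lam = thetas[:, 2][:, None]
        designs = _emg_unit(t[None, :], mu, sigma, lam)
        return _amplitude_and_rmse(y, designs)

    mu_grid = np.linspace(max(t0, t_onset - width), t_peak + 0.25 * width, 7)
    sigma_grid = np.geomspace(max(dt / 4.0, 0.05 * width), 1.5 * width, 5)
    lam_grid = np.geomspace(0.25 / width, 25.0 / width, 6)
    cands = np.array(list(itertools.product(mu_grid, sigma_grid, lam_grid)))
    rmse, _ = objective(cands)
    order = np.lexsort((cands[:, 0], rmse))
    theta = cands[order[0]]
    best_rmse = rmse[order[0]]
    if not np.isfinite(best_rmse):
        raise FitError("lagged-normal fit failed to bracket a finite-RMSE solution")

    if refine:
        steps = np.array(
            [
                max(mu_grid[1] - mu_grid[0], dt / 2.0),
                max(0.5 * theta[1], dt / 10.0),
                max(0.5 * theta[2], 0.01),
            ]
        )
        lower = np.array([t0 - (t_last - t0), 1e-4, 1e-3])
        upper = np.array([t_last, 5.0 * (t_last - t0), 1e4])
        theta, best_rmse, _ = _pattern_refine(
            objective, theta, steps, lower, upper, tie_index=0, tol=1e-9 * max(1.0, peak)
        )

    _, amp = objective(theta[None, :])
    area = float(amp[0])
    if not (np.isfinite(best_rmse) and area > 0):
        raise FitError("lagged-normal fit failed to bracket a finite-RMSE solution")
    params = LaggedNormalParams(
        area=area, mu_s=float(theta[0]), sigma_s=float(theta[1]), lam_per_s=float(theta[2])
    )
    curve = FittedCurve(FitModel.LAGGED_NORMAL, params, 0.0, tdc)
    return dataclasses.replace(curve, rmse=_rms_residual(curve))


def fit_polynomial(
    tdc: TimeDensityCurve, degree: int = 6, fit_window: tuple | None = None
) -> FittedCurve:
    """Ordinary least-squares polynomial fit (default degree 6) over the fit
    window (default: the full acquisition). Needs ``degree + 2`` samples."""
    t, y = tdc.times_s, tdc.values
    if fit_window is None:
        fit_window = (float(t[0]), float(t[-1]))
    t0, t1 = fit_window
    inside = (t >= t0) & (t <= t1)
    if int(inside.sum()) < degree + 2:
        raise ValueError(
            f"polynomial fit of degree {degree} needs at least {degree + 2} samples "
            f"in the window; got {int(inside.sum())}"
        )
    coeffs = np.polynomial.polynomial.polyfit(t[inside], y[inside], degree)
    coeffs = np.pad(coeffs, (0, 7 - coeffs.size)) if coeffs.size < 7 else coeffs[:7]
    if degree > 6:
        raise ValueError("degree above 6 is not supported")
    params = PolynomialParams(coefficients=tuple(coeffs), fit_window=(t0, t1))
    curve = FittedCurve(FitModel.POLYNOMIAL, params, 0.0, tdc)
    return dataclasses.replace(curve, rmse=_rms_residual(curve))


def fit(tdc: TimeDensityCurve, model: FitModel | str) -> FittedCurve:
    """Dispatch to the requested model; ``NONE`` wraps the raw samples with
    piecewise-linear interpolation and rmse 0."""
    model = FitModel(model)
    if model is FitModel.GAMMA_VARIATE:
        return fit_gamma_variate(tdc)
    if model is FitModel.LAGGED_NORMAL:
        return fit_lagged_normal(tdc)
    if model is FitModel.POLYNOMIAL:
        return fit_polynomial(tdc)
    if model is FitModel.NONE:
        return FittedCurve(FitModel.NONE, None, 0.0, tdc)
    raise ValueError(f"unknown model {model!r}")


def fit_to_json(curve: FittedCurve, path: str | os.PathLike | None = None) -> dict:
    """Serialize a fit result (model, params, rmse) as a JSON record."""
    record = {
        "model": curve.model.value,
        "rmse": curve.rmse,
        "params": dataclasses.asdict(curve.params) if curve.params is not None else None,
    }
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=2))
    return record
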