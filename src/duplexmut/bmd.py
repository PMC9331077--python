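"""Continuous-endpoint benchmark-dose (BMD) estimation with model averaging.

The dose-response is summarized per group (mean, SD, n).  Responses are
treated as lognormally distributed, the usual choice for strictly positive
endpoints such as mutation frequencies: each fitted function ``mu(d)``
describes the group median (geometric mean) response, and arithmetic
mean/SD summaries are first converted to log-scale moments.

Six increasing dose-response families are fitted by maximum likelihood
(equivalently, n-weighted least squares of log-medians once the shared
log-scale variance is profiled out):

==============  =========================================================
name            median function mu(d) = a * shape(d)
==============  =========================================================
exp3            a * exp(b * d^g)
exp5            a * (c - (c - 1) * exp(-b * d^g))
hill3           a * (1 + (c - 1) * d / (b + d))
hill5           a * (1 + (c - 1) * d^g / (b^g + d^g))
inv_exp         a * (1 + (c - 1) * exp(-b * d^(-g)))
log_normal      a * (1 + (c - 1) * Phi((ln d - b) / g))
==============  =========================================================

with a, b > 0, c > 1 and the power g constrained to [0.25, 4].  The
background scale ``a`` is profiled analytically, so every BMD depends only
on the shape parameters and is exactly invariant to rescaling the response.

The BMD at benchmark response ``bmr`` solves ``mu(d*) = (1 + bmr) * mu(0)``,
i.e. ``shape(d*) = 1 + bmr``; converged models are combined with equal
weights (arithmetic mean of the per-model BMDs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

MODEL_NAMES = ("exp3", "exp5", "hill3", "hill5", "inv_exp", "log_normal")

_POWER_BOUNDS = (0.25, 4.0)


@dataclass
class DoseResponseSummary:
    """Per-dose summary statistics of a positive continuous endpoint."""

    doses: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    response_label: str = "response"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        if not (len(self.doses) == len(self.means) == len(self.sds) == len(self.ns)):
            raise ValueError("summary arrays must have equal length")
        if len(np.unique(self.doses)) < 3 or 0.0 not in self.doses:
            raise ValueError("need >=3 distinct doses including 0")
        if (self.means <= 0).any():
            raise ValueError("lognormal-response fitting needs positive means")
        if (self.sds < 0).any() or (self.ns < 1).any():
            raise ValueError("SDs must be >=0 and ns >=1")

    def log_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Log-scale (mean, sd) per group from arithmetic mean/SD."""
        cv2 = (self.sds / self.means) ** 2
        sigma2 = np.log1p(cv2)
        m = np.log(self.means) - sigma2 / 2.0
        return m, np.sqrt(sigma2)


# ---- model shape functions -------------------------------------------------


def _shape(name: str, phi: np.ndarray, d: np.ndarray) -> np.ndarray:
    """shape(d) = mu(d)/a; phi holds the transformed shape parameters."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        if name == "exp3":
            b, g = np.exp(phi[0]), phi[1]
            return np.exp(b * d**g)
        if name == "exp5":
            b, cm1, g = np.exp(phi[0]), np.exp(phi[1]), phi[2]
            return 1.0 + cm1 * (1.0 - np.exp(-b * d**g))
        if name == "hill3":
            cm1, b = np.exp(phi[0]), np.exp(phi[1])
            return 1.0 + cm1 * d / (b + d)
        if name == "hill5":
            cm1, b, g = np.exp(phi[0]), np.exp(phi[1]), phi[2]
            dg = d**g
            return 1.0 + cm1 * dg / (b**g + dg)
        if name == "inv_exp":
            b, cm1, g = np.exp(phi[0]), np.exp(phi[1]), phi[2]
            out = np.ones_like(d)
            pos = d > 0
            out[pos] = 1.0 + cm1 * np.exp(-b * d[pos] ** (-g))
            return out
        if name == "log_normal":
            b, lg, cm1 = phi[0], phi[1], np.exp(phi[2])
            g = np.exp(lg)
            out = np.ones_like(d)
            pos = d > 0
            out[pos] = 1.0 + cm1 * norm.cdf((np.log(d[pos]) - b) / g)
            return out
    raise ValueError(f"unknown model {name!r}")


def _n_shape_params(name: str) -> int:
    return {"exp3": 2, "exp5": 3, "hill3": 2, "hill5": 3, "inv_exp": 3, "log_normal": 3}[name]


def _power_index(name: str) -> int | None:
    """Index of the power parameter g within phi (bounded), if any."""
    return {"exp3": 1, "exp5": 2, "hill3": None, "hill5": 2, "inv_exp": 2, "log_normal": None}[name]


def _decode_params(name: str, phi: np.ndarray) -> dict[str, float]:
    if name == "exp3":
        return {"b": float(np.exp(phi[0])), "g": float(phi[1])}
    if name == "exp5":
        return {"b": float(np.exp(phi[0])), "c": 1.0 + float(np.exp(phi[1])), "g": float(phi[2])}
    if name == "hill3":
        return {"c": 1.0 + float(np.exp(phi[0])), "b": float(np.exp(phi[1]))}
    if name == "hill5":
        return {"c": 1.0 + float(np.exp(phi[0])), "b": float(np.exp(phi[1])), "g": float(phi[2])}
    if name == "inv_exp":
        return {"b": float(np.exp(phi[0])), "c": 1.0 + float(np.exp(phi[1])), "g": float(phi[2])}
    if name == "log_normal":
        return {"b": float(phi[0]), "g": float(np.exp(phi[1])), "c": 1.0 + float(np.exp(phi[2]))}
    raise ValueError(name)


def _starts(name: str, summary: DoseResponseSummary) -> list[np.ndarray]:
    """Deterministic multi-start grid scaled to the data."""
    dmax = float(summary.doses.max())
    fold = float(summary.means.max() / summary.means[summary.doses == 0].mean())
    fold = max(fold, 1.05)
    log_cm1 = [np.log(fold - 1.0), np.log(2 * (fold - 1.0)), np.log(10 * (fold - 1.0))]
    log_b_half = [np.log(dmax * f) for f in (0.1, 0.3, 1.0, 3.0)]
    powers = [0.25, 0.5, 1.0, 2.0, 4.0]
    starts: list[np.ndarray] = []
    if name == "exp3":
        for g in powers:
            b = np.log(fold) / dmax**g
            for f in (0.5, 1.0, 2.0):
                starts.append(np.array([np.log(b * f), g]))
    elif name in ("exp5", "inv_exp"):
        for g in powers:
            for lc in log_cm1:
                # rate chosen so the curve is mid-rise around dmax/3
                for dh in (dmax / 10, dmax / 3, dmax):
                    b = np.log(2.0) / dh**g if name == "exp5" else np.log(2.0) * dh**g
                    starts.append(np.array([np.log(b), lc, g]))
    elif name == "hill3":
        for lc in log_cm1:
            for lb in log_b_half:
                starts.append(np.array([lc, lb]))
    elif name == "hill5":
        for g in powers:
            for lc in log_cm1:
                for lb in log_b_half:
                    starts.append(np.array([lc, lb, g]))
    elif name == "log_normal":
        for lg in (np.log(0.5), np.log(1.0), np.log(2.0)):
            for lc in log_cm1:
                for b in (np.log(dmax / 10), np.log(dmax / 3), np.log(dmax)):
                    starts.append(np.array([b, lg, lc]))
    return starts


@dataclass
class FittedModel:
    name: str
    params: dict[str, float]
    background: float  # fitted a (median response at dose 0)
    loglik: float
    converged: bool
    phi: np.ndarray = field(repr=False, default=None)

    def mu(self, d) -> np.ndarray:
        return self.background * _shape(self.name, self.phi, np.asarray(d, dtype=float))

    def shape(self, d) -> np.ndarray:
        return _shape(self.name, self.phi, np.asarray(d, dtype=float))


def fit_model(summary: DoseResponseSummary, model: str) -> FittedModel:
    """Fit one dose-response family by profiled lognormal maximum likelihood.

    Deterministic: a fixed data-scaled grid of starting values is polished
    with Nelder-Mead (power parameter bounded in [0.25, 4]); the best start
    wins.  For ``hill5`` the fitted ``hill3`` solution (g = 1) is added as a
    start, which guarantees the 5-parameter fit never has lower likelihood
    than the nested 3-parameter one.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; pick from {MODEL_NAMES}")
    m_log, s_log = summary.log_moments()
    n = summary.ns.astype(float)
    doses = summary.doses

    def objective(phi: np.ndarray) -> float:
        shape = _shape(model, phi, doses)
        if not np.all(np.isfinite(shape)) or np.any(shape <= 0):
            return 1e12
        log_shape = np.log(shape)
        log_a = np.sum(n * (m_log - log_shape)) / n.sum()
        return float(np.sum(n * (m_log - log_a - log_shape) ** 2))

    starts = _starts(model, summary)
    if model == "hill5":
        h3 = fit_model(summary, "hill3")
        if h3.converged:
            starts.append(np.array([np.log(h3.params["c"] - 1.0), np.log(h3.params["b"]), 1.0]))
    pidx = _power_index(model)
    bounds = None
    if pidx is not None:
        bounds = [(None, None)] * _n_shape_params(model)
        bounds[pidx] = _POWER_BOUNDS
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    phi = best.x
    sse = best.fun
    converged = bool(np.isfinite(sse) and sse < 1e11)
    shape = _shape(model, phi, doses)
    log_a = float(np.sum(n * (m_log - np.log(shape))) / n.sum())
    n_total = n.sum()
    ss_within = float(np.sum((n - 1) * s_log**2))
    sigma2_hat = (ss_within + sse) / n_total
    loglik = -0.5 * n_total * (np.log(2 * np.pi * sigma2_hat) + 1.0)
    return FittedModel(
        name=model,
        params=_decode_params(model, phi),
        background=float(np.exp(log_a)),
        loglik=float(loglik),
        converged=converged,
        phi=phi,
    )


def bmd_at_bmr(model, bmr: float, dose_max: float | None = None) -> float:
    """Dose at which the median response exceeds background by ``bmr``.

    ``model`` is a :class:`FittedModel` or any callable ``mu(d)``; the BMD
    solves ``mu(d*) = mu(0) * (1 + bmr)`` by bracketing + Brent bisection to
    1e-8 relative.  Raises if the response never reaches the target within
    10x the maximum observed dose.
    """
    if bmr < 0:
        raise ValueError("bmr must be nonnegative")
    if bmr == 0:
        return 0.0
    if isinstance(model, FittedModel):
        mu = model.mu
        if dose_max is None:
            raise ValueError("dose_max required")
    else:
        mu = model
        if dose_max is None:
            raise ValueError("dose_max required for a bare response function")
    hi = 10.0 * dose_max
    target = float(mu(0.0)) * (1.0 + bmr)

    def f(d: float) -> float:
        return float(mu(d)) - target

    if f(hi) < 0:
        raise ValueError("BMR not reached within 10x the maximum observed dose")
    lo = hi * 1e-12
    while f(lo) > 0 and lo > hi * 1e-300:
        lo /= 10.0
    return float(brentq(f, lo, hi, xtol=1e-300, rtol=1e-9))


@dataclass
class BmdResult:
    bmr: float
    per_model: list[dict]
    averaged_bmd: float

    def converged_bmds(self) -> dict[str, float]:
        return {
            e["name"]: e["bmd"]
            for e in self.per_model
            if e["converged"] and e["bmd"] is not None
        }


def model_average(
    summary: DoseResponseSummary,
    bmr: float = 0.5,
    models: tuple[str, ...] = MODEL_NAMES,
) -> BmdResult:
    """Fit the model suite and average the per-model BMDs with equal weights."""
    dmax = float(summary.doses.max())
    entries = []
    for name in models:
        fitted = fit_model(summary, name)
        bmd = None
        if fitted.converged:
            try:
                bmd = bmd_at_bmr(fitted, bmr, dose_max=dmax)
            except ValueError as exc:
                logger.warning("model %s: %s; excluded from the average", name, exc)
                fitted.converged = False
        entries.append(
            {
                "name": name,
                "params": fitted.params,
                "background": fitted.background,
                "loglik": fitted.loglik,
                "converged": fitted.converged,
                "bmd": bmd,
            }
        )
    bmds = [e["bmd"] for e in entries if e["converged"] and e["bmd"] is not None]
    if not bmds:
        raise ValueError("no model converged; cannot average")
    return BmdResult(bmr=bmr, per_model=entries, averaged_bmd=float(np.mean(bmds)))
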