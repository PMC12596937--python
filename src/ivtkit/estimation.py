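"""Calibration of capping parameters and D-optimal experiment design.

Maximum-likelihood estimation of the capping composites (lambda, theta) from
batch cap-fraction measurements under an independent-Gaussian error model
with per-measurement standard deviations, with the parameter covariance
taken from the inverse observed (Gauss-Newton) information.  Experiment
selection maximizes the determinant of the Fisher information matrix over
initial ATP/GTP/cap concentrations -- for a two-parameter model the optimal
two-point designs separate GTP levels, one high and one low, because theta
is only informed by curvature of the GTP saturation term.

The cap-fraction predictor used in both fitting and design defaults to the
instantaneous formula evaluated at the initial concentrations; a
batch-extent-integrated predictor is available via ``mode="batch"`` (the
drawdown of NTPs over a calibration batch shifts the cumulative cap
fraction upward; see ``capping.predictor_discrepancy``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .capping import (
    CappingParameters,
    batch_cap_fraction,
    instantaneous_cap_fraction,
)
from .errors import IdentifiabilityError, ValidationError

__all__ = [
    "CFMeasurement",
    "DesignCandidate",
    "cf_predict",
    "cf_gradient",
    "mle_fit",
    "fisher_information",
    "d_optimal_design",
]


@dataclass(frozen=True)
class CFMeasurement:
    """One calibration observation: initial concentrations in M, CF and sd."""

    atp: float
    gtp: float
    cap: float
    cf: float
    sd: float

    def __post_init__(self):
        if not 0.0 <= self.cf <= 1.0:
            raise ValidationError("CF must lie in [0, 1]")
        if self.sd <= 0:
            raise ValidationError("measurement sd must be positive")
        if min(self.atp, self.gtp, self.cap) < 0:
            raise ValidationError("concentrations must be nonnegative")


@dataclass(frozen=True)
class DesignCandidate:
    """Planned calibration experiments: one (ATP, GTP, cap) triplet each, M."""

    experiments: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if len(self.experiments) < 1:
            raise ValidationError("at least one experiment required")


def cf_predict(
    atp: float,
    gtp: float,
    cap: float,
    params: CappingParameters,
    *,
    mode: str = "instantaneous",
    n_A: int | None = None,
    n_G: int | None = None,
    conversion: float = 1.0,
) -> float:
    """Predicted cap fraction at one experimental condition."""
    if mode == "instantaneous":
        return instantaneous_cap_fraction(atp, gtp, cap, params)
    if mode == "batch":
        if n_A is None or n_G is None:
            raise ValidationError("batch mode requires sequence base counts")
        return batch_cap_fraction(
            atp, gtp, cap, params, n_A=n_A, n_G=n_G, conversion=conversion
        )
    raise ValidationError(f"unknown predictor mode {mode!r}")


def cf_gradient(
    atp: float, gtp: float, cap: float, params: CappingParameters
) -> np.ndarray:
    """Analytic gradient of the instantaneous CF w.r.t. (lambda, theta)."""
    lam, th = params.lam, params.theta
    q = lam * atp * gtp / (1.0 + gtp / th)
    denom = (cap + q) ** 2
    if denom == 0.0:
        return np.zeros(2)
    dcf_dq = -cap / denom
    dq_dlam = q / lam
    dq_dth = q * (gtp / th**2) / (1.0 + gtp / th)
    return np.array([dcf_dq * dq_dlam, dcf_dq * dq_dth])


def _predict_all(measurements, params, mode, predictor_kwargs):
    return np.array(
        [
            cf_predict(m.atp, m.gtp, m.cap, params, mode=mode, **predictor_kwargs)
            for m in measurements
        ]
    )


def mle_fit(
    measurements: list[CFMeasurement],
    initial: CappingParameters,
    *,
    mode: str = "instantaneous",
    min_information_rcond: float = 1e-10,
    **predictor_kwargs,
) -> CappingParameters:
    """Gaussian maximum-likelihood fit of (lambda, theta), in log space.

    Positivity is enforced by optimizing log parameters; the returned
    covariance is the inverse Gauss-Newton observed information in
    (lambda, theta) coordinates.  A numerically singular information matrix
    raises :class:`IdentifiabilityError` naming the flat direction.
    """
    if len(measurements) < 2:
        raise ValidationError("need at least two measurements for two parameters")
    if len({round(math.log10(max(m.gtp, 1e-30)), 3) for m in measurements}) < 2:
        raise IdentifiabilityError(
            "all measurements share one GTP level: theta is not identifiable",
            direction="theta",
        )
    sds = np.array([m.sd for m in measurements])
    cfs = np.array([m.cf for m in measurements])

    def nll(logp):
        p = CappingParameters(lam=math.exp(logp[0]), theta=math.exp(logp[1]))
        pred = _predict_all(measurements, p, mode, predictor_kwargs)
        return 0.5 * float(np.sum(((pred - cfs) / sds) ** 2))

    x0 = np.log([initial.lam, initial.theta])
    best = minimize(nll, x0, method="Nelder-Mead",
                    options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    polish = minimize(nll, best.x, method="BFGS",
                      options={"gtol": 1e-12, "maxiter": 500})
    x = polish.x if polish.fun <= best.fun else best.x
    if nll(x) > nll(x0) + 1e-12:
        x = x0  # never return a point worse than the starting guess
    fitted = CappingParameters(lam=math.exp(x[0]), theta=math.exp(x[1]))

    # observed information (Gauss-Newton), assembled in log-parameter space
    # so the conditioning check is scale-free, then mapped back to
    # (lambda, theta) coordinates for the reported covariance
    scale = np.array([fitted.lam, fitted.theta])
    info_log = np.zeros((2, 2))
    for m in measurements:
        if mode == "instantaneous":
            g = cf_gradient(m.atp, m.gtp, m.cap, fitted)
        else:
            g = _fd_gradient(m, fitted, mode, predictor_kwargs)
        g_log = g * scale
        info_log += np.outer(g_log, g_log) / m.sd**2
    w, v = np.linalg.eigh(info_log)
    if w[0] <= min_information_rcond * max(w[-1], 1.0):
        direction = "lambda" if abs(v[0, 0]) > abs(v[1, 0]) else "theta"
        raise IdentifiabilityError(
            f"likelihood is flat along the {direction} direction "
            f"(log-space information eigenvalues {w})",
            direction=direction,
        )
    cov_log = v @ np.diag(1.0 / w) @ v.T
    cov = np.diag(scale) @ cov_log @ np.diag(scale)
    return CappingParameters(lam=fitted.lam, theta=fitted.theta, covariance=cov)


def _fd_gradient(m, params, mode, predictor_kwargs, rel=1e-6):
    g = np.zeros(2)
    base = np.array([params.lam, params.theta])
    for i in range(2):
        h = rel * base[i]
        for sign, wgt in ((1, 1.0), (-1, -1.0)):
            p = base.copy()
            p[i] += sign * h
            g[i] += wgt * cf_predict(
                m.atp, m.gtp, m.cap,
                CappingParameters(lam=p[0], theta=p[1]),
                mode=mode, **predictor_kwargs,
            )
        g[i] /= 2 * h
    return g


def fisher_information(
    design: DesignCandidate,
    params: CappingParameters,
    sd: float | np.ndarray,
) -> np.ndarray:
    """Expected information of a design: sum of scaled gradient outer
    products of the predicted CF w.r.t. (lambda, theta)."""
    sds = np.broadcast_to(np.asarray(sd, dtype=float), (len(design.experiments),))
    if np.any(sds <= 0):
        raise ValidationError("sd must be positive")
    info = np.zeros((2, 2))
    for (atp, gtp, cap), s in zip(design.experiments, sds):
        g = cf_gradient(atp, gtp, cap, params)
        info += np.outer(g, g) / s**2
    return info


def d_optimal_design(
    n_experiments: int,
    bounds: dict,
    initial_params: CappingParameters,
    seed: int = 0,
    *,
    sd: float = 0.075,
    n_random: int = 2000,
    n_polish: int = 200,
) -> DesignCandidate:
    """Maximize det(FIM) over initial ATP/GTP/cap concentrations.

    ``bounds`` maps 'atp', 'gtp', 'cap' to (low, high) in M.  Seeded random
    search in log-concentration space followed by Nelder-Mead polish of the
    best candidate; deterministic given ``seed``.
    """
    if n_experiments < 2:
        raise ValidationError("need >= 2 experiments to identify two parameters")
    keys = ("atp", "gtp", "cap")
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])
    if np.any(hi <= lo) or np.any(lo <= 0):
        raise ValidationError("bounds must satisfy 0 < low < high")
    log_lo, log_hi = np.log(lo), np.log(hi)

    def det_of(flat: np.ndarray) -> float:
        exps = tuple(
            tuple(np.exp(flat[3 * i: 3 * i + 3])) for i in range(n_experiments)
        )
        return float(
            np.linalg.det(
                fisher_information(DesignCandidate(exps), initial_params, sd)
            )
        )

    rng = np.random.default_rng(seed)
    samples = rng.uniform(
        np.tile(log_lo, n_experiments),
        np.tile(log_hi, n_experiments),
        size=(n_random, 3 * n_experiments),
    )
    dets = np.array([det_of(s) for s in samples])
    best = samples[int(np.argmax(dets))]

    res = minimize(
        lambda x: -det_of(np.clip(x, np.tile(log_lo, n_experiments),
                                  np.tile(log_hi, n_experiments))),
        best,
        method="Nelder-Mead",
        options={"maxiter": n_polish * 3 * n_experiments, "xatol": 1e-10,
                 "fatol": 1e-18},
    )
    x = np.clip(res.x, np.tile(log_lo, n_experiments), np.tile(log_hi, n_experiments))
    if det_of(x) < dets.max():
        x = best
    return DesignCandidate(
        tuple(tuple(np.exp(x[3 * i: 3 * i + 3])) for i in range(n_experiments))
    )
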