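"""Co-transcriptional capping competition.

Transcripts of an A-then-G-initiating sequence acquire their first two
nucleotides either by one-step incorporation of an AG trinucleoside cap
analog (leaving a 5'-cap) or by two-step addition of ATP and GTP (leaving an
uncapped 5'-triphosphate).  A quasi-steady-state treatment of the initiation
complex collapses the elementary rate constants into two identifiable
composites, a competition coefficient ``lambda`` (M^-1) and a GTP half-effect
concentration ``theta`` (M), giving the instantaneous cap fraction

    CFi = [cap] / ([cap] + lambda [ATP][GTP] / (1 + [GTP]/theta)).

The denominator term (1 + [GTP]/theta) is dimensionless -- theta carries
concentration units -- so the competing flux lambda [ATP][GTP]/(1+[GTP]/theta)
has concentration units commensurate with [cap].  The elementary constants
k1, k2, k3, k4, k-1, k-2 of the two pathways are not individually
identifiable from cap-fraction data and are housed only through these
composites.

The cumulative cap fraction over a reactor trajectory integrates
d(capped)/dt = CFi * r against RNA production, consuming one cap analog per
capped transcript.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ValidationError

__all__ = [
    "CappingParameters",
    "CapState",
    "instantaneous_cap_fraction",
    "integrate_cap_fraction",
    "batch_cap_fraction",
    "invert_two_conditions",
    "prediction_interval",
    "predictor_discrepancy",
]


@dataclass(frozen=True)
class CappingParameters:
    """Identifiable capping composites with their joint uncertainty.

    lam    competition coefficient lambda, M^-1
    theta  GTP half-effect concentration, M
    covariance  2x2 covariance of (lam, theta); zero means point estimate
    """

    lam: float
    theta: float
    covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2))
    )

    def __post_init__(self):
        if self.lam <= 0 or self.theta <= 0:
            raise ValidationError("lambda and theta must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValidationError("covariance must be 2x2")
        if not np.allclose(cov, cov.T):
            raise ValidationError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12 * max(1.0, np.abs(cov).max())):
            raise ValidationError("covariance must be positive semidefinite")
        object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class CapState:
    """Cumulative capping bookkeeping at one instant."""

    capped: float       # M of capped RNA
    total: float        # M of total RNA
    cap_analog: float   # M of remaining cap analog

    @property
    def cap_fraction(self) -> float | None:
        """Cumulative CF; None when no RNA has been made."""
        if self.total <= 0:
            return None
        return self.capped / self.total


def instantaneous_cap_fraction(
    atp: float, gtp: float, cap: float, params: CappingParameters
) -> float:
    """CFi in [0, 1]; 0 when both pathways are closed (with a warning)."""
    if min(atp, gtp, cap) < 0:
        raise ValidationError("concentrations must be nonnegative")
    competing = params.lam * atp * gtp / (1.0 + gtp / params.theta)
    if cap == 0.0 and competing == 0.0:
        warnings.warn(
            "cap analog and ATP*GTP both zero: no initiation pathway open; "
            "CFi reported as 0",
            stacklevel=2,
        )
        return 0.0
    return cap / (cap + competing)


def integrate_cap_fraction(
    t: np.ndarray,
    atp: np.ndarray,
    gtp: np.ndarray,
    rate: np.ndarray,
    cap0: float,
    params: CappingParameters,
    *,
    substeps: int = 20,
) -> list[CapState]:
    """Integrate cumulative capping along a prescribed reactor trajectory.

    ``t`` must be nondecreasing and ``rate`` (RNA production, M/s)
    nonnegative; ATP/GTP are interpolated linearly between samples while the
    cap analog is evolved from ``cap0`` by d(cap)/dt = -CFi * r.  Each output
    sample aligns with the input grid.  If coarse stepping would drive the
    cap analog negative the step is refined; a genuinely exhausted cap pool
    pins CFi at 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("trajectory times must be nondecreasing")
    if np.any(np.asarray(rate) < 0):
        raise ValidationError("rates must be nonnegative")
    cap, capped, total = float(cap0), 0.0, 0.0
    out = [CapState(capped=0.0, total=0.0, cap_analog=cap)]
    for i in range(len(t) - 1):
        dt_full = t[i + 1] - t[i]
        n_sub = substeps
        for attempt in range(8):
            c_trial, cp_trial, tot_trial = cap, capped, total
            ok = True
            for s in range(n_sub):
                f0 = s / n_sub
                f1 = (s + 1) / n_sub
                h = dt_full / n_sub
                a_mid = atp[i] + (atp[i + 1] - atp[i]) * (f0 + f1) / 2
                g_mid = gtp[i] + (gtp[i + 1] - gtp[i]) * (f0 + f1) / 2
                r_mid = rate[i] + (rate[i + 1] - rate[i]) * (f0 + f1) / 2
                cfi = (
                    instantaneous_cap_fraction(a_mid, g_mid, max(c_trial, 0.0), params)
                    if c_trial > 0
                    else 0.0
                )
                dc = cfi * r_mid * h
                if dc > c_trial and c_trial > 0:
                    ok = False
                    break
                c_trial -= dc
                cp_trial += dc
                tot_trial += r_mid * h
            if ok:
                break
            n_sub *= 4
        else:
            raise ValidationError("cap analog driven negative despite refinement")
        cap, capped, total = max(c_trial, 0.0), cp_trial, tot_trial
        out.append(CapState(capped=capped, total=total, cap_analog=cap))
    return out


def batch_cap_fraction(
    atp0: float,
    gtp0: float,
    cap0: float,
    params: CappingParameters,
    *,
    n_A: int,
    n_G: int,
    conversion: float = 1.0,
) -> float:
    """Cumulative CF of a batch run, integrated in reaction extent.

    The cap fraction depends on the trajectory only through the extent of
    reaction xi (mol RNA per liter), not on the clock: ATP and GTP fall
    linearly in xi with slopes -n_A and -n_G while the cap analog obeys
    d(cap)/dxi = -CFi.  The batch is integrated to ``conversion`` times the
    extent at which the limiting base pool is exhausted.
    """
    if not 0 < conversion <= 1:
        raise ValidationError("conversion must be in (0, 1]")
    xi_f = conversion * min(atp0 / n_A, gtp0 / n_G)
    if xi_f <= 0:
        return instantaneous_cap_fraction(atp0, gtp0, cap0, params)

    def rhs(xi, y):
        atp = max(atp0 - n_A * xi, 0.0)
        gtp = max(gtp0 - n_G * xi, 0.0)
        cap = max(y[0], 0.0)
        cfi = instantaneous_cap_fraction(atp, gtp, cap, params) if cap > 0 else 0.0
        return [-cfi, cfi]

    sol = solve_ivp(
        rhs, (0.0, xi_f), [cap0, 0.0], method="LSODA", rtol=1e-9, atol=1e-15
    )
    if not sol.success:
        raise ValidationError(f"extent integration failed: {sol.message}")
    return float(sol.y[1, -1] / xi_f)


def invert_two_conditions(
    cond1: tuple[float, float, float, float],
    cond2: tuple[float, float, float, float],
    *,
    theta_bracket: tuple[float, float] = (1e-6, 1.0),
) -> tuple[float, float]:
    """Solve CFi(cond1) and CFi(cond2) for (lambda, theta).

    Each condition is (ATP, GTP, cap, CF) in M.  Given theta, lambda follows
    in closed form from one condition; the other becomes a scalar root
    problem in theta, solved by Brent bisection.  Used to reconstruct
    initial parameter estimates from a printed pair of predicted cap
    fractions.
    """

    def lam_from(cond, theta):
        atp, gtp, cap, cf = cond
        return cap * (1.0 / cf - 1.0) * (1.0 + gtp / theta) / (atp * gtp)

    def mismatch(theta):
        return lam_from(cond1, theta) - lam_from(cond2, theta)

    lo, hi = theta_bracket
    theta = brentq(mismatch, lo, hi, xtol=1e-15, rtol=8.9e-16)
    lam = lam_from(cond1, theta)
    if lam <= 0 or theta <= 0:
        raise ValidationError("inversion produced non-positive parameters")
    return lam, theta


def prediction_interval(
    params: CappingParameters,
    conditions: tuple[float, float, float],
    n_draws: int = 2000,
    seed: int = 0,
    *,
    predictor=None,
    level: float = 0.95,
) -> dict:
    """Central prediction interval of CF by Monte Carlo over the parameter
    covariance.

    ``predictor(atp, gtp, cap, params)`` defaults to the instantaneous
    formula; draws with non-positive parameters are rejected and counted.
    Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    atp, gtp, cap = conditions
    predictor = predictor or (
        lambda a, g, c, p: instantaneous_cap_fraction(a, g, c, p)
    )
    point = predictor(atp, gtp, cap, params)
    if not np.any(params.covariance):
        return {
            "point": point, "lower": point, "upper": point,
            "n_accepted": n_draws, "n_rejected": 0,
        }
    rng = np.random.default_rng(seed)
    mean = np.array([params.lam, params.theta])
    draws = rng.multivariate_normal(mean, params.covariance, size=n_draws,
                                    method="cholesky" if np.all(np.linalg.eigvalsh(params.covariance) > 0) else "svd")
    good = draws[(draws > 0).all(axis=1)]
    n_rej = n_draws - len(good)
    if len(good) == 0:
        raise ValidationError("all covariance draws violated positivity")
    cfs = np.array([
        predictor(atp, gtp, cap, CappingParameters(lam=l, theta=th))
        for l, th in good
    ])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(cfs, [alpha, 1.0 - alpha])
    return {
        "point": point, "lower": float(lo), "upper": float(hi),
        "n_accepted": int(len(good)), "n_rejected": int(n_rej),
    }


def predictor_discrepancy(
    atp0: float, gtp0: float, cap0: float, params: CappingParameters,
    *, n_A: int, n_G: int, conversion: float = 1.0,
) -> dict:
    """Instantaneous-at-t0 versus batch-integrated CF at one condition.

    Quantifies how much NTP drawdown over the batch shifts the cumulative
    cap fraction away from its initial instantaneous value.
    """
    inst = instantaneous_cap_fraction(atp0, gtp0, cap0, params)
    batch = batch_cap_fraction(
        atp0, gtp0, cap0, params, n_A=n_A, n_G=n_G, conversion=conversion
    )
    return {"instantaneous": inst, "batch": batch, "difference": batch - inst}
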