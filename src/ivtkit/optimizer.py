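"""Feed-policy optimization: NTP/pH setpoint tracking plus RNA yield.

The scalar objective is

    J(F) = nu_NTP * sum_{N in {A,U,C,G}} sum_{t in t_N} ([NTP]_{F,t} - [NTP]_sp)^2
         + nu_pH  * sum_{t in t_pH} (pH_{F,t} - pH_sp)^2
         - nu_RNA * [RNA]_{t_f},

minimized over a decision vector F encoding initial Mg, buffer and NTP
concentrations and per-event feed-stock volumes at fixed bolus times.  The
objective is nonsmooth at event times, so the search is derivative-free:
seeded uniform sampling within box bounds followed by Nelder-Mead polish of
the incumbent.  A failed simulation maps to a large finite penalty so the
search can continue, and an optional supersaturation cap sigma_max is
enforced the same way (candidates breaching it are never returned).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .capping import CappingParameters
from .errors import ValidationError
from .kinetics import CatalystState, KineticParameters, SequenceSpec
from .reactor import FeedEvent, FeedPolicy, SimulationResult, simulate
from .speciation import (
    NTP_BASES,
    EquilibriumConstantSet,
    SolutionComposition,
    titrate_to_ph,
)

__all__ = [
    "ObjectivePolicy",
    "PolicyTemplate",
    "DecisionVector",
    "ModelContext",
    "evaluate_objective",
    "optimize_policy",
    "low_ph_variant",
]


@dataclass(frozen=True)
class ObjectivePolicy:
    """Setpoints, evaluation grids and weights of the tracking objective."""

    ntp_setpoint: float = 2e-3          # M, per base
    ph_setpoint: float = 8.0
    t_ntp_eval: tuple[float, ...] = ()
    t_ph_eval: tuple[float, ...] = ()
    nu_ntp: float = 1e6                 # M^-2
    nu_ph: float = 1.0
    nu_rna: float = 1.5e6               # M^-1
    t_final: float = 9000.0
    sigma_max: float | None = None
    mg_bound_scale: float = 1.0
    low_ph: bool = False

    def __post_init__(self):
        if min(self.nu_ntp, self.nu_ph, self.nu_rna) < 0:
            raise ValidationError("objective weights must be nonnegative")
        for t in (*self.t_ntp_eval, *self.t_ph_eval):
            if not 0 <= t <= self.t_final:
                raise ValidationError("evaluation times must lie in [0, t_final]")

    @staticmethod
    def with_uniform_grids(
        t_final: float = 9000.0, interval: float = 300.0, **kwargs
    ) -> "ObjectivePolicy":
        grid = tuple(np.arange(interval, t_final + interval / 2, interval))
        return ObjectivePolicy(
            t_ntp_eval=grid, t_ph_eval=grid, t_final=t_final, **kwargs
        )


def low_ph_variant(obj: ObjectivePolicy, *, tail_fraction: float = 0.9,
                   end_ph: float = 7.3) -> ObjectivePolicy:
    """End-of-process pH targeting to suppress Mg3(PO4)2 supersaturation.

    Replaces whole-course pH tracking with a setpoint of ``end_ph`` evaluated
    only over the final (1 - tail_fraction) of the run, and slightly tightens
    the Mg feed bounds.  Idempotent.
    """
    if obj.low_ph:
        return obj
    tail = tuple(t for t in obj.t_ph_eval if t >= tail_fraction * obj.t_final)
    if not tail:
        tail = (obj.t_final,)
    return replace(
        obj,
        ph_setpoint=end_ph,
        t_ph_eval=tail,
        mg_bound_scale=0.85,
        low_ph=True,
    )


@dataclass(frozen=True)
class ModelContext:
    """Model pieces the objective needs to run a simulation."""

    kparams: KineticParameters
    constants: EquilibriumConstantSet
    seq: SequenceSpec
    cparams: CappingParameters | None = None
    report_interval: float = 120.0
    rtol: float = 1e-8


@dataclass(frozen=True)
class PolicyTemplate:
    """Scaffold mapping a numeric decision vector to a FeedPolicy.

    Decision layout (all O(1)-O(100) magnitudes for optimizer conditioning):
      x[0]  initial Mg, mM          x[1]  initial tris, mM
      x[2]  initial NTP per base, mM
      x[3 + 3k .. 5 + 3k]  feed volumes at event k, uL of
            (NTP stock, Mg stock, NaOH stock)

    The initial recipe carries Mg as the acetate salt and NTPs/cap as
    disodium salts and is titrated to ``initial_ph``.  The NTP stock feeds
    the four bases in proportion to the sequence base counts.
    """

    event_times: tuple[float, ...]
    catalysts: CatalystState
    initial_volume: float = 1e-3        # L
    t_final: float = 9000.0
    initial_ph: float = 7.9
    cap_mM: float = 0.0
    ntp_stock_total_mM: float = 200.0
    mg_stock_mM: float = 500.0
    naoh_stock_mM: float = 1000.0
    buffer_chloride_ratio: float = 0.0  # Cl per tris (1.0 = tris-HCl)
    stock_ph: float = 7.5               # NTP feed stocks are neutralized
    stock_neutralizer: str = "tris"     # "tris" (low-salt) or "naoh"
    seq: SequenceSpec | None = None
    constants: EquilibriumConstantSet | None = None

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def n_dims(self) -> int:
        return 3 + 3 * self.n_events

    def default_bounds(self, mg_scale: float = 1.0) -> list[tuple[float, float]]:
        b = [(2.0, 40.0), (5.0, 60.0), (1.0, 6.0)]
        for _ in range(self.n_events):
            b += [(0.0, 40.0), (0.0, 20.0 * mg_scale), (0.0, 40.0)]
        return b

    def _stocks(self):
        cs = self.constants or EquilibriumConstantSet.default()
        counts = self.seq.base_counts
        total = sum(counts.values())
        ntp_tot = self.ntp_stock_total_mM * 1e-3
        ntp_stock = SolutionComposition(
            total_NTP={b: ntp_tot * counts[b] / total for b in NTP_BASES},
            sodium=2.0 * ntp_tot,  # disodium salts
        )
        ntp_stock = neutralize_stock(
            ntp_stock, self.stock_ph, self.stock_neutralizer, cs
        )
        mg_stock = SolutionComposition(
            total_Mg=self.mg_stock_mM * 1e-3,
            total_acetate=2.0 * self.mg_stock_mM * 1e-3,
        )
        naoh_stock = SolutionComposition(
            strong_base_equivalents=self.naoh_stock_mM * 1e-3
        )
        return cs, ntp_stock, mg_stock, naoh_stock

    def build(self, x: np.ndarray, name: str = "") -> FeedPolicy:
        x = np.asarray(x, dtype=float)
        if len(x) != self.n_dims:
            raise ValidationError(
                f"decision vector has {len(x)} entries, expected {self.n_dims}"
            )
        mg0, tris0, ntp0 = x[0] * 1e-3, x[1] * 1e-3, x[2] * 1e-3
        cs, ntp_stock, mg_stock, naoh_stock = self._stocks()
        cap0 = self.cap_mM * 1e-3
        comp = SolutionComposition(
            total_Mg=mg0,
            total_NTP={b: ntp0 for b in NTP_BASES},
            total_cap_analog=cap0,
            total_tris=tris0,
            total_acetate=2.0 * mg0,
            sodium=2.0 * (4.0 * ntp0 + cap0),
            chloride=self.buffer_chloride_ratio * tris0,
        )
        comp = titrate_to_ph(comp, self.initial_ph, cs)
        events = []
        stocks = (ntp_stock, mg_stock, naoh_stock)
        labels = ("NTP", "Mg", "NaOH")
        for k, te in enumerate(self.event_times):
            for j, (stock, lab) in enumerate(zip(stocks, labels)):
                vol = x[3 + 3 * k + j] * 1e-6
                if vol > 0:
                    events.append(
                        FeedEvent(time=te, volume=vol, composition=stock, label=lab)
                    )
        merged = _merge_coincident(events)
        return FeedPolicy(
            initial_composition=comp,
            initial_volume=self.initial_volume,
            catalysts=self.catalysts,
            events=tuple(merged),
            t_final=self.t_final,
            name=name,
        )


def neutralize_stock(
    comp: SolutionComposition,
    target_ph: float,
    neutralizer: str,
    constants: EquilibriumConstantSet,
) -> SolutionComposition:
    """Bring a feed stock to its working pH.

    ``"naoh"`` adds strong base (the conventional, salt-heavy preparation);
    ``"tris"`` adds tris free base, whose partially protonated form carries a
    lower effective-salt weight -- the low-salt formulation choice.
    """
    from dataclasses import replace as _replace
    from scipy.optimize import brentq

    from .speciation import solve_speciation, titrate_to_ph

    if neutralizer == "naoh":
        return titrate_to_ph(comp, target_ph, constants)
    if neutralizer != "tris":
        raise ValidationError(f"unknown neutralizer {neutralizer!r}")

    def ph_with(tris_total: float) -> float:
        c = _replace(comp, total_tris=comp.total_tris + tris_total)
        return solve_speciation(c, constants).pH - target_ph

    if ph_with(0.0) >= 0:
        return comp
    hi = 2.0
    tris_needed = brentq(ph_with, 0.0, hi, xtol=1e-9)
    return _replace(comp, total_tris=comp.total_tris + tris_needed)


def _merge_coincident(events: list[FeedEvent]) -> list[FeedEvent]:
    """Combine same-time feeds into one bolus (amount-weighted mixing)."""
    from .reactor import composition_to_state, STATE_NAMES

    by_time: dict[float, list[FeedEvent]] = {}
    for ev in events:
        by_time.setdefault(ev.time, []).append(ev)
    out = []
    idx = {n: i for i, n in enumerate(STATE_NAMES)}
    for t in sorted(by_time):
        group = by_time[t]
        if len(group) == 1:
            out.append(group[0])
            continue
        vol = sum(e.volume for e in group)
        y = np.zeros(len(STATE_NAMES))
        for e in group:
            y += composition_to_state(e.composition, e.volume)
        c = y / vol
        comp = SolutionComposition(
            total_Mg=c[idx["Mg"]],
            total_NTP={b: c[idx[b]] for b in NTP_BASES},
            total_cap_analog=c[idx["cap"]],
            total_phosphate=c[idx["Pi"]],
            total_pyrophosphate=c[idx["PPi"]],
            total_tris=c[idx["tris"]],
            total_acetate=c[idx["Ac"]],
            sodium=c[idx["Na"]],
            chloride=c[idx["Cl"]],
            strong_base_equivalents=c[idx["SB"]],
        )
        out.append(
            FeedEvent(time=t, volume=vol, composition=comp,
                      label="+".join(e.label for e in group))
        )
    return out


@dataclass(frozen=True)
class DecisionVector:
    """A point in the box-bounded decision space of a template."""

    values: np.ndarray
    template: PolicyTemplate
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != self.template.n_dims:
            raise ValidationError("decision vector length mismatch")
        for xi, (lo, hi) in zip(v, self.bounds):
            if not lo - 1e-12 <= xi <= hi + 1e-12:
                raise ValidationError("decision vector violates box bounds")

    def decode(self, name: str = "") -> FeedPolicy:
        return self.template.build(self.values, name=name)


_FAILURE_PENALTY = 1e9


def evaluate_objective(
    F: DecisionVector,
    obj: ObjectivePolicy,
    ctx: ModelContext,
    *,
    return_result: bool = False,
):
    """Objective value of one candidate; large finite penalty on failure."""
    try:
        policy = F.decode()
        result = simulate(
            policy, ctx.kparams, ctx.cparams, ctx.constants, ctx.seq,
            report_interval=ctx.report_interval, rtol=ctx.rtol,
        )
    except Exception:
        return (_FAILURE_PENALTY, None) if return_result else _FAILURE_PENALTY
    value = objective_of_result(result, obj)
    return (value, result) if return_result else value


def objective_of_result(result: SimulationResult, obj: ObjectivePolicy) -> float:
    """Evaluate the tracking objective on an existing trajectory."""
    t = result.time
    j = 0.0
    if obj.t_ntp_eval and obj.nu_ntp > 0:
        for b in NTP_BASES:
            c = np.interp(obj.t_ntp_eval, t, result.conc(b))
            j += obj.nu_ntp * float(np.sum((c - obj.ntp_setpoint) ** 2))
    if obj.t_ph_eval and obj.nu_ph > 0:
        ph = np.interp(obj.t_ph_eval, t, result.pH)
        j += obj.nu_ph * float(np.sum((ph - obj.ph_setpoint) ** 2))
    j -= obj.nu_rna * float(result.rna_molar[-1])
    if obj.sigma_max is not None and float(np.max(result.sigma)) > obj.sigma_max:
        j += _FAILURE_PENALTY
    return j


def optimize_policy(
    obj: ObjectivePolicy,
    template: PolicyTemplate,
    ctx: ModelContext,
    seed: int,
    budget: int,
    *,
    bounds: list[tuple[float, float]] | None = None,
    x0: np.ndarray | None = None,
) -> tuple[DecisionVector, pd.DataFrame]:
    """Derivative-free search over the template's decision space.

    Spends about a third of the evaluation ``budget`` on seeded uniform
    sampling (always including ``x0`` when given) and the remainder on
    Nelder-Mead polish of the incumbent, with candidates clipped to the box.
    Returns the best decision vector and the full evaluation trace.
    Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValidationError("budget must be >= 1 evaluation")
    bounds = bounds or template.default_bounds(obj.mg_bound_scale)
    bounds = tuple(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)

    trace: list[dict] = []
    evals = 0

    def f(x):
        nonlocal evals
        x = np.clip(x, lo, hi)
        if evals >= budget:
            return math.inf
        evals += 1
        dv = DecisionVector(values=x, template=template, bounds=bounds)
        val = evaluate_objective(dv, obj, ctx)
        trace.append({"eval": evals, "objective": val, **{f"x{i}": xi for i, xi in enumerate(x)}})
        return val

    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
    n_random = max(0, min(budget - len(starts), max(1, budget // 3) - len(starts)))
    for _ in range(n_random):
        starts.append(rng.uniform(lo, hi))
    for x in starts:
        f(x)
    if not trace:
        raise ValidationError("budget exhausted before any evaluation")

    finite = [r for r in trace if r["objective"] < _FAILURE_PENALTY / 2]
    if not finite:
        raise ValidationError(
            "all candidates infeasible (simulation failures or sigma cap)"
        )

    if evals < budget:
        best_row = min(trace, key=lambda r: r["objective"])
        xb = np.array([best_row[f"x{i}"] for i in range(len(lo))])
        from scipy.optimize import minimize

        try:
            minimize(f, xb, method="Nelder-Mead",
                     options={"maxfev": budget - evals, "xatol": 1e-3,
                              "fatol": 1e-6})
        except Exception:
            pass

    ok = [r for r in trace if r["objective"] < _FAILURE_PENALTY / 2]
    best_row = min(ok, key=lambda r: r["objective"])
    xb = np.array([best_row[f"x{i}"] for i in range(len(lo))])
    best = DecisionVector(values=np.clip(xb, lo, hi), template=template, bounds=bounds)
    return best, pd.DataFrame(trace)
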