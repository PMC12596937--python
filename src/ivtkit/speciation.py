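"""Instantaneous ionic speciation of the IVT solution.

Given analytical (conserved) totals of every moiety in the reactor, solve the
coupled acid-base and Mg-binding equilibria for the free concentration of
every species, and report pH, the effective salt concentration (the
omega-weighted sum over ionic complexes that governs polymerase-promoter
detachment), and the thermodynamic supersaturation of magnesium phosphate,

    sigma = ln([Mg2+]^3 [PO4 3-]^2 / Ksp).

Formulation
-----------
Species are formed from free components {H, Mg, A, U, C, G, cap, Pi, PPi,
tris, Ac} by mass action, c_j = beta_j * prod_k x_k^(s_jk).  One mass-balance
equation is written per component with a positive total; the proton is
determined by electroneutrality (spectator ions Na+, Cl-, strong-base
equivalents, and RNA backbone phosphodiesters enter the charge balance but
are not equilibrated).  With this convention, totals are stated for the fully
deprotonated acid forms and counterions are supplied explicitly, so proton
release during transcription (NTP -> backbone + 2 phosphate) emerges from the
moiety transformation itself rather than from explicit acid bookkeeping.

Numerics: damped Newton iteration in log10-concentration space with the
analytic Jacobian, warm-startable; a nested 1-D solver (outer Brent root on
the charge balance in pH, inner Brent root on the Mg balance, ligand frees in
closed form) provides cold starts and a robust fallback.  Concentrations span
many orders of magnitude, which the log parameterization absorbs.

Activities are identified with concentrations (ideal solution).  A Davies-type
activity correction would slot into ``_compile`` as a per-species coefficient;
none is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import ConfigurationError, SpeciationError, ValidationError

__all__ = [
    "SolutionComposition",
    "SpeciesRecord",
    "EquilibriumConstantSet",
    "SpeciationResult",
    "solve_speciation",
    "effective_salt",
    "supersaturation",
    "titrate_to_ph",
    "NTP_BASES",
]

NTP_BASES = ("A", "U", "C", "G")

#: components that may appear in species stoichiometries
COMPONENTS = ("H", "Mg", "A", "U", "C", "G", "cap", "Pi", "PPi", "tris", "Ac")

_LN10 = math.log(10.0)
_TINY = 1e-300


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SolutionComposition:
    """Conserved analytical totals of the reactor solution, in mol/L.

    ``total_NTP`` maps base letters A/U/C/G to the total concentration of the
    corresponding nucleoside triphosphate moiety (free + protonated + Mg
    bound).  ``strong_base_equivalents`` counts inert +1 charge from e.g.
    NaOH feeds; ``rna_phosphodiester`` counts backbone phosphates of product
    RNA (inert -1 charge each).  Temperature is carried but constants are
    25 C values (no van 't Hoff correction).
    """

    total_Mg: float = 0.0
    total_NTP: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in NTP_BASES}
    )
    total_cap_analog: float = 0.0
    total_phosphate: float = 0.0
    total_pyrophosphate: float = 0.0
    total_tris: float = 0.0
    total_acetate: float = 0.0
    sodium: float = 0.0
    chloride: float = 0.0
    strong_base_equivalents: float = 0.0
    rna_phosphodiester: float = 0.0
    temperature: float = 298.15

    def __post_init__(self):
        ntp = {b: float(self.total_NTP.get(b, 0.0)) for b in NTP_BASES}
        unknown = set(self.total_NTP) - set(NTP_BASES)
        if unknown:
            raise ValidationError(f"unknown NTP bases: {sorted(unknown)}")
        object.__setattr__(self, "total_NTP", ntp)
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValidationError(f"negative total: {name} = {value}")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")

    def as_dict(self) -> dict[str, float]:
        d = {
            "total_Mg": self.total_Mg,
            "total_cap_analog": self.total_cap_analog,
            "total_phosphate": self.total_phosphate,
            "total_pyrophosphate": self.total_pyrophosphate,
            "total_tris": self.total_tris,
            "total_acetate": self.total_acetate,
            "sodium": self.sodium,
            "chloride": self.chloride,
            "strong_base_equivalents": self.strong_base_equivalents,
            "rna_phosphodiester": self.rna_phosphodiester,
        }
        for b in NTP_BASES:
            d[f"total_NTP_{b}"] = self.total_NTP[b]
        return d

    def component_totals(self) -> dict[str, float]:
        """Totals keyed by equilibrium component name (H excluded)."""
        t = {
            "Mg": self.total_Mg,
            "cap": self.total_cap_analog,
            "Pi": self.total_phosphate,
            "PPi": self.total_pyrophosphate,
            "tris": self.total_tris,
            "Ac": self.total_acetate,
        }
        for b in NTP_BASES:
            t[b] = self.total_NTP[b]
        return t

    @property
    def inert_charge(self) -> float:
        """Net charge of non-equilibrated (spectator) species, mol/L."""
        return (
            self.sodium
            + self.strong_base_equivalents
            - self.chloride
            - self.rna_phosphodiester
        )

    def inert_concentrations(self) -> dict[str, float]:
        return {
            "Na+": self.sodium,
            "Cl-": self.chloride,
            "strong_base+": self.strong_base_equivalents,
            "RNA_backbone-": self.rna_phosphodiester,
        }


@dataclass(frozen=True, eq=False)
class SpeciesRecord:
    name: str
    stoich: Mapping[str, float]
    log_beta: float
    charge: float
    omega: float = 0.0

    def __post_init__(self):
        unknown = set(self.stoich) - set(COMPONENTS)
        if unknown:
            raise ConfigurationError(
                f"species {self.name}: unknown components {sorted(unknown)}"
            )


@dataclass(frozen=True, eq=False)
class EquilibriumConstantSet:
    """Versioned set of formation constants, omega weights and Ksp."""

    species: tuple[SpeciesRecord, ...]
    inert_omega: Mapping[str, float]
    log_ksp_mg3po42: float
    version: str = "custom"

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "EquilibriumConstantSet":
        text = (
            resources.files("ivtkit.data")
            .joinpath("equilibrium_constants.yaml")
            .read_text()
        )
        return EquilibriumConstantSet.from_mapping(yaml.safe_load(text))

    @staticmethod
    def from_mapping(doc: Mapping) -> "EquilibriumConstantSet":
        species = tuple(
            SpeciesRecord(
                name=rec["name"],
                stoich=dict(rec["stoich"]),
                log_beta=float(rec["log_beta"]),
                charge=float(rec["charge"]),
                omega=float(rec.get("omega", 0.0)),
            )
            for rec in doc["species"]
        )
        inert = {
            rec["name"]: float(rec.get("omega", 0.0))
            for rec in doc.get("inert_species", [])
        }
        return EquilibriumConstantSet(
            species=species,
            inert_omega=inert,
            log_ksp_mg3po42=float(doc["log_ksp_mg3po42"]),
            version=str(doc.get("version", "custom")),
        )

    @property
    def ksp_mg3po42(self) -> float:
        return 10.0 ** self.log_ksp_mg3po42

    def omega_of(self, name: str) -> float:
        for rec in self.species:
            if rec.name == name:
                return rec.omega
        if name in self.inert_omega:
            return self.inert_omega[name]
        raise ConfigurationError(f"no omega entry for species {name!r}")

    def subset(self, names) -> "EquilibriumConstantSet":
        """Keep only the named non-reference species (free components are
        always kept); useful for closed-form comparison tests."""
        keep = set(names)
        kept = tuple(
            rec
            for rec in self.species
            if rec.name in keep or sum(abs(v) for v in rec.stoich.values()) <= 1
        )
        return replace(self, species=kept, version=self.version + "+subset")

    def with_log_beta(self, overrides: Mapping[str, float]) -> "EquilibriumConstantSet":
        species = tuple(
            replace(rec, log_beta=overrides.get(rec.name, rec.log_beta))
            for rec in self.species
        )
        return replace(self, species=species, version=self.version + "+override")

    def with_omega(self, overrides: Mapping[str, float]) -> "EquilibriumConstantSet":
        species = tuple(
            replace(rec, omega=overrides.get(rec.name, rec.omega))
            for rec in self.species
        )
        inert = {k: overrides.get(k, v) for k, v in self.inert_omega.items()}
        return replace(
            self, species=species, inert_omega=inert, version=self.version + "+override"
        )


@dataclass(frozen=True)
class SpeciationResult:
    """Free concentrations at one instant, with convergence diagnostics."""

    species: Mapping[str, float]          # every species incl. spectators, M
    free_components: Mapping[str, float]  # free component concentrations, M
    pH: float
    effective_salt: float                 # M
    supersaturation_sigma: float          # dimensionless; -inf if undersupplied
    mass_residual: float                  # max relative per-moiety residual
    charge_residual: float                # relative to total ionic charge
    iterations: int
    method: str
    composition: SolutionComposition

    @property
    def converged(self) -> bool:
        return self.mass_residual <= 1e-8 and self.charge_residual <= 1e-8


# ---------------------------------------------------------------------------
# compiled system


class _Compiled:
    """Arrays for one (constants, active component set) pair."""

    def __init__(self, constants: EquilibriumConstantSet, active: tuple[str, ...]):
        self.active = active  # 'H' first
        index = {c: i for i, c in enumerate(active)}
        records = [
            rec
            for rec in constants.species
            if all(c in index for c in rec.stoich)
        ]
        self.names = [rec.name for rec in records]
        n_sp, n_c = len(records), len(active)
        self.S = np.zeros((n_sp, n_c))
        for j, rec in enumerate(records):
            for c, v in rec.stoich.items():
                self.S[j, index[c]] = v
        self.log_beta = np.array([rec.log_beta for rec in records])
        self.z = np.array([rec.charge for rec in records])
        self.omega = np.array([rec.omega for rec in records])

    def concentrations(self, logx: np.ndarray) -> np.ndarray:
        return 10.0 ** np.clip(self.log_beta + self.S @ logx, -300, 300)


@lru_cache(maxsize=64)
def _compile(constants: EquilibriumConstantSet, active: tuple[str, ...]) -> _Compiled:
    return _Compiled(constants, active)


# ---------------------------------------------------------------------------
# solver


def _residuals(sys_: _Compiled, logx, totals, inert_charge):
    c = sys_.concentrations(logx)
    r = np.empty(len(sys_.active))
    # charge balance (row 0, H)
    q = float(sys_.z @ c) + inert_charge
    scale_q = float(np.abs(sys_.z) @ c) + abs(inert_charge) + _TINY
    r[0] = q / scale_q
    for k in range(1, len(sys_.active)):
        tk = totals[k]
        r[k] = (float(sys_.S[:, k] @ c) - tk) / max(tk, _TINY)
    return r, c, scale_q


def _newton(sys_, logx0, totals, inert_charge, tol=1e-12, max_iter=100):
    logx = logx0.copy()
    r, c, scale_q = _residuals(sys_, logx, totals, inert_charge)
    norm = float(np.max(np.abs(r)))
    it = 0
    while norm > tol and it < max_iter:
        n_c = len(sys_.active)
        J = np.empty((n_c, n_c))
        J[0, :] = _LN10 * (sys_.z * c) @ sys_.S / scale_q
        for k in range(1, n_c):
            J[k, :] = _LN10 * (sys_.S[:, k] * c) @ sys_.S / max(totals[k], _TINY)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return logx, norm, it, False
        mx = float(np.max(np.abs(step)))
        if mx > 2.0:
            step *= 2.0 / mx
        lam, ok = 1.0, False
        for _ in range(30):
            trial = logx + lam * step
            r2, c2, scale2 = _residuals(sys_, trial, totals, inert_charge)
            n2 = float(np.max(np.abs(r2)))
            if n2 < norm or n2 <= tol:
                logx, r, c, scale_q, norm, ok = trial, r2, c2, scale2, n2, True
                break
            lam *= 0.5
        it += 1
        if not ok:
            return logx, norm, it, norm <= tol
    return logx, norm, it, norm <= tol


def _nested(sys_, totals, inert_charge):
    """Outer Brent root in pH on charge balance; inner Mg balance root;
    ligand free concentrations in closed form.  Requires every non-H species
    to carry each non-H component with stoichiometry exactly one (true for
    the shipped species set)."""
    active = sys_.active
    iH = 0
    iMg = active.index("Mg") if "Mg" in active else None
    ligand_idx = [
        k for k in range(1, len(active)) if active[k] != "Mg"
    ]

    hS = sys_.S[:, iH]
    if np.any((sys_.S[:, 1:] != 0) & (sys_.S[:, 1:] != 1)):
        raise ConfigurationError(
            "nested fallback requires unit stoichiometry in non-proton components"
        )

    def frees(logH, logMg):
        logx = np.zeros(len(active))
        logx[iH] = logH
        if iMg is not None:
            logx[iMg] = logMg
        # ligand denominators: sum over species containing that ligand of
        # beta * H^h * Mg^m  (ligand itself excluded from the power product)
        for k in ligand_idx:
            mask = sys_.S[:, k] == 1
            expo = sys_.log_beta[mask] + hS[mask] * logH
            if iMg is not None:
                expo = expo + sys_.S[mask, iMg] * logMg
            denom = float(np.sum(10.0 ** np.clip(expo, -300, 300)))
            logx[k] = math.log10(max(totals[k], _TINY)) - math.log10(denom)
        return logx

    def mg_balance(logMg, logH):
        logx = frees(logH, logMg)
        c = sys_.concentrations(logx)
        return float(sys_.S[:, iMg] @ c) - totals[iMg]

    def solve_mg(logH):
        if iMg is None or totals[iMg] <= 0:
            return -300.0
        hi = math.log10(totals[iMg] + _TINY)
        lo = -30.0
        if mg_balance(hi, logH) < 0:  # free Mg ~ total (no binding partners)
            return hi
        return brentq(mg_balance, lo, hi, args=(logH,), xtol=1e-14, rtol=8.9e-16)

    def charge(pH):
        logH = -pH
        logMg = solve_mg(logH)
        logx = frees(logH, logMg)
        c = sys_.concentrations(logx)
        return float(sys_.z @ c) + inert_charge

    lo, hi = -2.0, 16.0
    qlo, qhi = charge(lo), charge(hi)
    if qlo < 0 or qhi > 0:
        raise SpeciationError(
            "charge balance has no root in pH [-2, 16]",
            residuals={"Q(-2)": qlo, "Q(16)": qhi},
        )
    pH = brentq(charge, lo, hi, xtol=1e-13, rtol=8.9e-16)
    logH = -pH
    return frees(logH, solve_mg(logH))


def solve_speciation(
    comp: SolutionComposition,
    constants: EquilibriumConstantSet | None = None,
    *,
    warm_start: Mapping[str, float] | None = None,
) -> SpeciationResult:
    """Solve instantaneous equilibria for ``comp``.

    ``warm_start`` maps component names to log10 free concentrations from a
    nearby solve (e.g. the previous ODE step); Newton iteration then usually
    converges in a few steps.  Without it, the robust nested 1-D solver runs
    first and a Newton polish tightens the residuals.
    """
    constants = constants or EquilibriumConstantSet.default()
    ctot = comp.component_totals()
    active = ("H",) + tuple(c for c in COMPONENTS[1:] if ctot[c] > 0)
    sys_ = _compile(constants, active)
    totals = np.array([0.0] + [ctot[c] for c in active[1:]])
    inert_charge = comp.inert_charge

    method, iterations = "newton", 0
    logx = None
    if warm_start is not None and all(c in warm_start for c in active):
        x0 = np.array([warm_start[c] for c in active])
        logx, norm, iterations, ok = _newton(sys_, x0, totals, inert_charge)
        if not ok:
            logx = None
    if logx is None:
        method = "nested+newton"
        logx = _nested(sys_, totals, inert_charge)
        logx, norm, it2, ok = _newton(sys_, logx, totals, inert_charge)
        iterations += it2

    r, c, _ = _residuals(sys_, logx, totals, inert_charge)
    mass_res = float(np.max(np.abs(r[1:]))) if len(r) > 1 else 0.0
    charge_res = float(abs(r[0]))
    if mass_res > 1e-8 or charge_res > 1e-8:
        raise SpeciationError(
            "speciation did not converge",
            residuals={"mass": mass_res, "charge": charge_res},
            composition=comp,
        )

    species = dict(zip(sys_.names, map(float, c)))
    species.update(comp.inert_concentrations())
    free = {a: float(10.0 ** logx[i]) for i, a in enumerate(sys_.active)}
    pH = -logx[0]

    result = SpeciationResult(
        species=species,
        free_components=free,
        pH=float(pH),
        effective_salt=float("nan"),
        supersaturation_sigma=float("nan"),
        mass_residual=mass_res,
        charge_residual=charge_res,
        iterations=iterations,
        method=method,
        composition=comp,
    )
    salt = effective_salt(result, constants)
    sigma = supersaturation(result, constants)
    object.__setattr__(result, "effective_salt", salt)
    object.__setattr__(result, "supersaturation_sigma", sigma)
    return result


# ---------------------------------------------------------------------------
# derived quantities


def effective_salt(
    result: SpeciationResult, constants: EquilibriumConstantSet | None = None
) -> float:
    """Effective salt concentration: sum_i omega_i [ion_i], in M."""
    constants = constants or EquilibriumConstantSet.default()
    total = 0.0
    for name, conc in result.species.items():
        total += constants.omega_of(name) * conc
    return total


def supersaturation(
    result: SpeciationResult, constants: EquilibriumConstantSet | None = None
) -> float:
    """Mg3(PO4)2 supersaturation sigma = ln([Mg2+]^3 [PO43-]^2 / Ksp).

    Returns ``-inf`` when either free ion is absent: the ionic activity
    product vanishes, so the solution is undersaturated with no finite
    driving force.
    """
    constants = constants or EquilibriumConstantSet.default()
    ksp = constants.ksp_mg3po42
    if ksp <= 0:
        raise ConfigurationError("Ksp must be positive")
    mg = result.species.get("Mg2+", 0.0)
    po4 = result.species.get("PO43-", 0.0)
    if mg <= 0 or po4 <= 0:
        return float("-inf")
    return 3.0 * math.log(mg) + 2.0 * math.log(po4) - math.log(ksp)


def titrate_to_ph(
    comp: SolutionComposition,
    target_ph: float,
    constants: EquilibriumConstantSet | None = None,
    *,
    max_equivalents: float = 1.0,
) -> SolutionComposition:
    """Return ``comp`` neutralized to ``target_ph`` with strong base or acid.

    Mirrors bench practice: a recipe of acid-form totals plus counterions is
    brought to its working pH with NaOH (added to
    ``strong_base_equivalents``) or HCl (added to ``chloride``).  The
    required equivalents are found by Brent root search on the speciated pH.
    """
    from dataclasses import replace as _replace

    constants = constants or EquilibriumConstantSet.default()

    def ph_with(delta: float) -> float:
        if delta >= 0:
            c = _replace(
                comp,
                strong_base_equivalents=comp.strong_base_equivalents + delta,
            )
        else:
            c = _replace(comp, chloride=comp.chloride - delta)
        return solve_speciation(c, constants).pH - target_ph

    if abs(ph_with(0.0)) < 1e-10:
        return comp
    delta = brentq(ph_with, -max_equivalents, max_equivalents, xtol=1e-12)
    if delta >= 0:
        return _replace(
            comp, strong_base_equivalents=comp.strong_base_equivalents + delta
        )
    return _replace(comp, chloride=comp.chloride - delta)
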