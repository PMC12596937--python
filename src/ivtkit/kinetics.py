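"""Transcription-rate law and reactor ODE right-hand side.

The instantaneous RNA production rate is a lumped elongation-limited
expression modulated by the solution state,

    r = k_cat * [DNA] * f_occ(salt) * Gamma_pH * prod_i S(MgNTP_i),

where ``f_occ`` is the equilibrium promoter occupancy under salt-dependent
detachment (k_off = k_off,1M * [salt]^n_salt, with [salt] the omega-weighted
effective salt concentration from speciation), ``Gamma_pH`` is the classical
diprotic enzyme pH response (1 + [H+]/Ka + Kb/[H+])^-1, and each ``S`` is a
Michaelis saturation term in the free Mg.NTP complex concentration of one of
the four bases.  High free Mg2+ therefore depresses the rate not through the
saturation terms (which stay full) but by inflating the effective salt and
hence promoter detachment.

Stoichiometry per RNA molecule of a sequence with base counts n_A..n_G:
each base pool is drawn down by its count, 2 orthophosphates per incorporated
NTP appear (pyrophosphate release with instantaneous pyrophosphatase
hydrolysis, so PPi never accumulates), and one backbone phosphodiester per
nucleotide joins the RNA polyanion.  The accompanying proton release -- and
hence the falling pH of a progressing reaction -- emerges from the
speciation charge balance applied to the transformed totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .speciation import (
    NTP_BASES,
    EquilibriumConstantSet,
    SolutionComposition,
    SpeciationResult,
    solve_speciation,
)

__all__ = [
    "SequenceSpec",
    "KineticParameters",
    "CatalystState",
    "k_off",
    "gamma_pH",
    "promoter_occupancy",
    "ntp_saturation",
    "transcription_rate",
    "RateBreakdown",
    "rate_with_breakdown",
    "ReactorContext",
    "ode_rhs",
    "STATE_NAMES",
]

#: mean residue masses of RNA nucleotide monophosphates in a chain, g/mol
RESIDUE_MASS = {"A": 329.206, "U": 306.166, "C": 305.181, "G": 345.205}
_WATER_MASS = 18.015


@dataclass(frozen=True)
class SequenceSpec:
    """Base composition of the transcribed construct.

    ``initiates_AG`` flags that transcription starts with A then G, the
    requirement for competition with an AG trinucleoside cap analog.
    """

    length: int
    n_A: int
    n_U: int
    n_C: int
    n_G: int
    initiates_AG: bool = True

    def __post_init__(self):
        counts = (self.n_A, self.n_U, self.n_C, self.n_G)
        if any(c < 0 for c in counts) or self.length < 0:
            raise ValidationError("base counts must be nonnegative")
        if sum(counts) != self.length:
            raise ValidationError(
                f"base counts sum to {sum(counts)}, expected length {self.length}"
            )

    @property
    def base_counts(self) -> dict[str, int]:
        return {"A": self.n_A, "U": self.n_U, "C": self.n_C, "G": self.n_G}

    @property
    def molar_mass(self) -> float:
        """g/mol, from per-residue masses plus terminal water."""
        return (
            sum(RESIDUE_MASS[b] * n for b, n in self.base_counts.items())
            + _WATER_MASS
        )

    @staticmethod
    def from_fasta(path) -> "SequenceSpec":
        seq = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(">") or not line.strip():
                    continue
                seq.append(line.strip().upper())
        s = "".join(seq).replace("T", "U")
        counts = {b: s.count(b) for b in NTP_BASES}
        if sum(counts.values()) != len(s):
            raise ValidationError("sequence contains non-AUCG(T) characters")
        return SequenceSpec(
            length=len(s),
            n_A=counts["A"],
            n_U=counts["U"],
            n_C=counts["C"],
            n_G=counts["G"],
            initiates_AG=s.startswith("AG"),
        )


@dataclass(frozen=True)
class KineticParameters:
    """Rate-law parameters.

    k_off_1M         promoter detachment scale at 1 M effective salt (s^-1)
    n_salt           salt-power-law exponent (dimensionless)
    k_on             polymerase-promoter association constant (M^-1 s^-1)
    k_cat            RNA molecules per occupied promoter per second (s^-1)
    K_M_mgntp        shared Michaelis constant in free Mg.NTP (M)
    K_a, K_b         acid/base limbs of the pH response (M)
    extra_proton_stoich  additional strong-acid equivalents released per NTP
                     incorporated, beyond what the moiety transformation
                     itself implies through the charge balance (default 0)
    """

    k_off_1M: float = 10.0 ** 2.93
    n_salt: float = 5.0
    k_on: float = 4.0e7
    k_cat: float = 0.25
    K_M_mgntp: float = 2.0e-4
    K_a: float = 1.0e-7
    K_b: float = 1.0e-9
    extra_proton_stoich: float = 0.0

    def __post_init__(self):
        for name in ("k_off_1M", "n_salt", "k_on", "k_cat", "K_M_mgntp", "K_a", "K_b"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class CatalystState:
    """DNA template and active polymerase concentrations (M)."""

    dna: float
    polymerase: float

    def __post_init__(self):
        if self.dna < 0 or self.polymerase < 0:
            raise ValidationError("catalyst concentrations must be nonnegative")


# ---------------------------------------------------------------------------
# rate-law factors


def k_off(effective_salt: float, params: KineticParameters) -> float:
    """Promoter detachment rate constant, k_off,1M * [salt]^n_salt.

    Zero salt gives zero detachment (irreversible-binding limit of the
    power law)."""
    if effective_salt < 0:
        raise ValidationError("effective salt must be nonnegative")
    if effective_salt == 0:
        return 0.0
    return params.k_off_1M * effective_salt ** params.n_salt


def gamma_pH(pH: float, params: KineticParameters) -> float:
    """Diprotic pH-response factor in (0, 1]; maximal at [H+]=sqrt(Ka*Kb)."""
    h = 10.0 ** (-pH)
    return 1.0 / (1.0 + h / params.K_a + params.K_b / h)


def promoter_occupancy(
    catalysts: CatalystState, k_off_value: float, params: KineticParameters
) -> float:
    """Equilibrium fraction of DNA promoters bound by polymerase.

    Exact two-species binding with depletion: the complex concentration is
    the smaller root of C^2 - (D+P+Kd) C + D P = 0.
    """
    d, p = catalysts.dna, catalysts.polymerase
    if d <= 0:
        return 1.0 if p > 0 and k_off_value == 0 else 0.0
    if p <= 0:
        return 0.0
    kd = k_off_value / params.k_on
    if kd == 0:
        return min(p, d) / d
    b = d + p + kd
    c = (b - math.sqrt(b * b - 4.0 * d * p)) / 2.0
    return min(c / d, 1.0)


def ntp_saturation(spec: SpeciationResult, params: KineticParameters) -> float:
    """Product of Michaelis terms in the free Mg.NTP complex of each base.

    A base whose total is zero has no Mg.NTP species in the speciation
    result and contributes a factor of zero (no transcription without all
    four monomers)."""
    sat = 1.0
    for b in NTP_BASES:
        mgntp = spec.species.get(f"Mg{b}TP2-", 0.0)
        sat *= mgntp / (params.K_M_mgntp + mgntp)
    return sat


@dataclass(frozen=True)
class RateBreakdown:
    """Multiplicative factors of the rate law at one instant."""

    rate: float          # M/s
    dna: float           # M
    occupancy: float
    gamma: float
    saturation: float
    k_off: float
    effective_salt: float
    pH: float


def rate_with_breakdown(
    spec: SpeciationResult,
    catalysts: CatalystState,
    params: KineticParameters,
) -> RateBreakdown:
    koff = k_off(spec.effective_salt, params)
    occ = promoter_occupancy(catalysts, koff, params)
    gam = gamma_pH(spec.pH, params)
    sat = ntp_saturation(spec, params)
    rate = params.k_cat * catalysts.dna * occ * gam * sat
    return RateBreakdown(
        rate=rate,
        dna=catalysts.dna,
        occupancy=occ,
        gamma=gam,
        saturation=sat,
        k_off=koff,
        effective_salt=spec.effective_salt,
        pH=spec.pH,
    )


def transcription_rate(
    spec: SpeciationResult,
    catalysts: CatalystState,
    params: KineticParameters,
    seq: SequenceSpec | None = None,
) -> float:
    """Instantaneous RNA production rate (M of full-length RNA per second)."""
    return rate_with_breakdown(spec, catalysts, params).rate


# ---------------------------------------------------------------------------
# reactor ODE right-hand side

#: state vector layout: amounts in mol except volume (L)
STATE_NAMES = (
    "Mg", "A", "U", "C", "G", "cap", "Pi", "PPi", "tris", "Ac",
    "Na", "Cl", "SB", "backbone", "RNA", "capped_RNA", "volume",
)
_IDX = {n: i for i, n in enumerate(STATE_NAMES)}


@dataclass
class ReactorContext:
    """Everything the RHS needs besides the state vector itself.

    Holds the catalyst *amounts* (mol) so that bolus dilution emerges from
    the growing volume, plus a warm-start cache for the speciation solver
    and an optional continuous feed (rate in L/s and the feed composition).
    """

    params: KineticParameters
    seq: SequenceSpec
    constants: EquilibriumConstantSet
    capping: "object | None" = None          # CappingParameters, optional
    dna_amount: float = 0.0                  # mol
    polymerase_amount: float = 0.0           # mol
    feed_rate: float = 0.0                   # L/s (continuous mode)
    feed_concentrations: np.ndarray | None = None  # per STATE_NAMES[:-1], M
    _warm: dict = field(default_factory=dict)

    def composition(self, y: np.ndarray) -> SolutionComposition:
        v = y[_IDX["volume"]]
        c = np.maximum(y[:-1], 0.0) / v
        return SolutionComposition(
            total_Mg=c[_IDX["Mg"]],
            total_NTP={b: c[_IDX[b]] for b in NTP_BASES},
            total_cap_analog=c[_IDX["cap"]],
            total_phosphate=c[_IDX["Pi"]],
            total_pyrophosphate=c[_IDX["PPi"]],
            total_tris=c[_IDX["tris"]],
            total_acetate=c[_IDX["Ac"]],
            sodium=c[_IDX["Na"]],
            chloride=c[_IDX["Cl"]],
            strong_base_equivalents=c[_IDX["SB"]],
            rna_phosphodiester=c[_IDX["backbone"]],
        )

    def speciate(self, y: np.ndarray) -> SpeciationResult:
        comp = self.composition(y)
        ws = self._warm.get("logx")
        try:
            res = solve_speciation(comp, self.constants, warm_start=ws)
        except Exception:
            res = solve_speciation(comp, self.constants)
        self._warm["logx"] = {
            k: math.log10(v) for k, v in res.free_components.items() if v > 0
        }
        return res

    def catalysts(self, y: np.ndarray) -> CatalystState:
        v = y[_IDX["volume"]]
        return CatalystState(dna=self.dna_amount / v, polymerase=self.polymerase_amount / v)


def ode_rhs(t: float, y: np.ndarray, ctx: ReactorContext) -> np.ndarray:
    """Time derivatives of the reactor state (amount basis).

    Transcription converts NTP amounts into RNA, backbone phosphodiesters
    and orthophosphate; the cap analog is consumed one-per-capped-RNA at the
    instantaneous cap fraction.  In continuous-feed mode, feed terms
    q * c_feed are added and dV/dt = q.
    """
    spec = ctx.speciate(y)
    bd = rate_with_breakdown(spec, ctx.catalysts(y), ctx.params)
    v = y[_IDX["volume"]]
    r_amt = bd.rate * v  # mol RNA / s
    seq = ctx.seq

    dy = np.zeros_like(y)
    for b in NTP_BASES:
        dy[_IDX[b]] = -seq.base_counts[b] * r_amt
    dy[_IDX["Pi"]] = 2.0 * seq.length * r_amt
    dy[_IDX["backbone"]] = seq.length * r_amt
    dy[_IDX["RNA"]] = r_amt
    dy[_IDX["SB"]] = -ctx.params.extra_proton_stoich * seq.length * r_amt

    if ctx.capping is not None and seq.initiates_AG:
        from .capping import instantaneous_cap_fraction

        comp = spec.composition
        cfi = instantaneous_cap_fraction(
            comp.total_NTP["A"], comp.total_NTP["G"], comp.total_cap_analog,
            ctx.capping,
        )
        dy[_IDX["cap"]] = -cfi * r_amt
        dy[_IDX["capped_RNA"]] = cfi * r_amt

    if ctx.feed_rate > 0 and ctx.feed_concentrations is not None:
        dy[:-1] += ctx.feed_rate * ctx.feed_concentrations
        dy[_IDX["volume"]] = ctx.feed_rate
    return dy
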