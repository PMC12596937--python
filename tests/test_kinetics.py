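"""Rate law: salt power law, pH response, occupancy, saturation, ODE."""

import math

import numpy as np
import pytest

from ivtkit.kinetics import (
    CatalystState,
    KineticParameters,
    SequenceSpec,
    gamma_pH,
    k_off,
    promoter_occupancy,
    rate_with_breakdown,
    transcription_rate,
)
from ivtkit.speciation import NTP_BASES, SolutionComposition, solve_speciation


@pytest.fixture(scope="module")
def params():
    return KineticParameters()


class TestKoff:
    def test_reference_at_one_molar(self, params):
        assert k_off(1.0, params) == pytest.approx(params.k_off_1M)

    def test_printed_detachment_scales(self):
        from ivtkit.scenarios import kinetic_defaults

        assert math.log10(kinetic_defaults(True).k_off_1M) == pytest.approx(3.93)
        assert math.log10(kinetic_defaults(False).k_off_1M) == pytest.approx(2.93)

    def test_power_law_halving(self, params):
        assert k_off(0.1, params) / k_off(0.05, params) == pytest.approx(
            2.0 ** params.n_salt
        )

    def test_zero_salt_means_no_detachment(self, params):
        assert k_off(0.0, params) == 0.0


class TestGammaPH:
    def test_wide_limits_give_unity(self):
        p = KineticParameters(K_a=1e6, K_b=1e-30)
        for ph in (3.0, 7.0, 11.0):
            assert gamma_pH(ph, p) == pytest.approx(1.0, abs=1e-6)

    def test_direct_evaluation(self):
        p = KineticParameters(K_a=1e-7, K_b=1e-9)
        assert gamma_pH(8.0, p) == pytest.approx(1.0 / 1.2, rel=1e-12)

    def test_maximum_at_geometric_mean(self, params):
        """dGamma/d[H+] = 0 at [H+] = sqrt(Ka Kb); check on a fine grid."""
        ph_star = -0.5 * math.log10(params.K_a * params.K_b)
        grid = np.linspace(2, 12, 2001)
        vals = [gamma_pH(p, params) for p in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(ph_star, abs=0.01)
        assert 0 < max(vals) <= 1.0


class TestOccupancy:
    def test_irreversible_binding_limit(self, params):
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        assert promoter_occupancy(cat, 0.0, params) == pytest.approx(1.0)

    def test_no_polymerase_no_occupancy(self, params):
        cat = CatalystState(dna=1e-8, polymerase=0.0)
        assert promoter_occupancy(cat, 1.0, params) == 0.0

    def test_langmuir_half_saturation(self, params):
        """When free polymerase equals K_d the isotherm gives exactly 1/2;
        use a trace DNA concentration so depletion is negligible."""
        koff = 0.5
        kd = koff / params.k_on
        cat = CatalystState(dna=1e-15, polymerase=kd)
        assert promoter_occupancy(cat, koff, params) == pytest.approx(0.5, rel=1e-6)

    def test_decreasing_in_koff(self, params):
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        occs = [promoter_occupancy(cat, k, params) for k in (0.01, 0.1, 1.0, 10.0)]
        assert all(b < a for a, b in zip(occs, occs[1:]))


def _speciate(comp, constants):
    return solve_speciation(comp, constants)


class TestTranscriptionRate:
    def base_comp(self, ntp=2e-3, mg=8e-3, **kw):
        defaults = dict(
            total_Mg=mg,
            total_NTP={b: ntp for b in NTP_BASES},
            total_tris=0.03,
            total_acetate=2 * mg,
            sodium=8 * ntp,
            strong_base_equivalents=5e-3,
        )
        defaults.update(kw)
        return SolutionComposition(**defaults)

    def test_missing_ntp_stops_transcription(self, constants, params):
        comp = SolutionComposition(
            total_Mg=8e-3,
            total_NTP={"A": 2e-3, "U": 2e-3, "C": 2e-3, "G": 0.0},
            total_tris=0.03, total_acetate=0.016, sodium=0.012,
        )
        spec = _speciate(comp, constants)
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        assert transcription_rate(spec, cat, params) == 0.0

    def test_linear_in_dna(self, constants, params):
        spec = _speciate(self.base_comp(), constants)
        r1 = transcription_rate(spec, CatalystState(1e-8, 1e-6), params)
        r2 = transcription_rate(spec, CatalystState(2e-8, 1e-6), params)
        # vast polymerase excess: occupancy unchanged, rate doubles
        assert r2 / r1 == pytest.approx(2.0, rel=1e-3)

    def test_excess_mg_depresses_rate(self, constants, params):
        """Beyond full Mg.NTP complexation, surplus free Mg2+ inflates the
        effective salt and promoter detachment, reducing the rate."""
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        r_bal = transcription_rate(
            _speciate(self.base_comp(mg=10e-3), constants), cat, params
        )
        r_high = transcription_rate(
            _speciate(self.base_comp(mg=40e-3), constants), cat, params
        )
        assert r_high < r_bal

    def test_rate_nonincreasing_in_effective_salt(self, constants, params):
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        rates = []
        for nacl in (0.0, 0.05, 0.1, 0.2):
            comp = self.base_comp(sodium=8 * 2e-3 + nacl, chloride=nacl)
            rates.append(
                transcription_rate(_speciate(comp, constants), cat, params)
            )
        assert all(b <= a for a, b in zip(rates, rates[1:]))

    def test_chloride_depresses_at_least_as_much_as_acetate(
        self, constants, params
    ):
        """Equimolar NaCl addition hits the rate at least as hard as sodium
        acetate, across 0-200 mM added salt."""
        cat = CatalystState(dna=1e-8, polymerase=1e-7)
        for x in (0.0, 0.05, 0.1, 0.15, 0.2):
            r_cl = transcription_rate(
                _speciate(
                    self.base_comp(sodium=8 * 2e-3 + x, chloride=x), constants
                ),
                cat, params,
            )
            r_ac = transcription_rate(
                _speciate(
                    self.base_comp(
                        sodium=8 * 2e-3 + x,
                        total_acetate=2 * 8e-3 + x,
                    ),
                    constants,
                ),
                cat, params,
            )
            assert r_cl <= r_ac + 1e-18


class TestSequenceSpec:
    def test_counts_must_sum_to_length(self):
        with pytest.raises(Exception):
            SequenceSpec(length=10, n_A=3, n_U=3, n_C=3, n_G=3)

    def test_fasta_roundtrip(self, tmp_path):
        fasta = tmp_path / "seq.fa"
        fasta.write_text(">construct\nAGGGCU\nUAAC\n")
        s = SequenceSpec.from_fasta(fasta)
        assert (s.length, s.n_A, s.n_U, s.n_C, s.n_G) == (10, 3, 2, 2, 3)
        assert s.initiates_AG

    def test_molar_mass_matches_printed_pair(self, seq):
        # 7 uM of the construct is 10 g/L at the printed precision
        assert 7e-6 * seq.molar_mass == pytest.approx(10.0, rel=2e-3)


class TestBatchStoichiometry:
    def test_batch_runs_to_limiting_ntp_exhaustion(self, sims, seq):
        """Integrated batch yield equals the stoichiometric bound
        min_i(NTP_i,0 / n_i) -- here set by GTP on a G-rich construct."""
        res = sims["batch_capping"]
        gtp0 = res.conc("G")[0]
        expected = gtp0 / seq.n_G
        assert res.rna_molar[-1] == pytest.approx(expected, rel=1e-3)

    def test_elemental_balances_close(self, sims):
        from ivtkit.reactor import phosphorus_total

        for name in ("batch_capping", "optimized_fedbatch_lowpH"):
            res = sims[name]
            p = phosphorus_total(res)
            fed = _cumulative_fed_phosphorus(res)
            drift = (p - p[0] - fed) / p[0]
            assert np.max(np.abs(drift)) < 1e-8

    def test_per_base_balance(self, sims, seq):
        """Each base pool + incorporated share of RNA is conserved up to
        amounts fed."""
        res = sims["optimized_fedbatch_lowpH"]
        for b, n_b in seq.base_counts.items():
            pool = res.amounts[b] + n_b * res.amounts["RNA"]
            fed = np.array(
                [
                    sum(
                        ev.composition.total_NTP[b] * ev.volume
                        for ev in res.policy.events
                        if ev.time < t or (ev.time == t and True)
                    )
                    for t in res.time
                ]
            )
            # at duplicated event times the pre-bolus sample must not count
            # the bolus; accept either bound at those instants
            drift = pool - pool[0] - fed
            tol = 1e-8 * pool[-1]
            ok = np.abs(drift) < tol
            dup = np.isin(res.time, [e.time for e in res.policy.events])
            assert np.all(ok | dup)


def _cumulative_fed_phosphorus(res):
    out = np.zeros_like(res.time)
    for ev in res.policy.events:
        p_fed = ev.volume * (
            3.0 * sum(ev.composition.total_NTP.values())
            + ev.composition.total_phosphate
            + 2.0 * ev.composition.total_pyrophosphate
            + 3.0 * ev.composition.total_cap_analog
            + ev.composition.rna_phosphodiester
        )
        # post-event samples: the second occurrence of the event time onward
        idx = np.searchsorted(res.time, ev.time, side="left") + 1
        out[idx:] += p_fed
    return out


def test_zero_rate_zeroes_all_derivatives(constants, seq):
    from ivtkit.kinetics import ReactorContext, ode_rhs
    from ivtkit.reactor import composition_to_state

    comp = SolutionComposition(
        total_Mg=8e-3, total_NTP={"A": 2e-3, "U": 2e-3, "C": 2e-3, "G": 0.0},
        total_tris=0.03, total_acetate=0.016, sodium=0.012,
    )
    ctx = ReactorContext(
        params=KineticParameters(), seq=seq, constants=constants,
        dna_amount=1e-11, polymerase_amount=1e-10,
    )
    y = composition_to_state(comp, 1e-3)
    assert np.allclose(ode_rhs(0.0, y, ctx), 0.0)
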