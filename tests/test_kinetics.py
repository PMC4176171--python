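"""Kinetic simulator: steady states, time-course oracle, perturbations."""

import numpy as np
import pytest

from rampkit.kinetics import (
    KineticsError,
    NoiseSpec,
    Perturbation,
    RateModel,
    SingularModelError,
    UnstableStepError,
    apply_perturbation,
    default_rate_model,
    random_models,
    scenario_battery,
    simulate_scenario_profile,
    steady_state,
    timecourse,
)
from rampkit.pathway import (
    Interval,
    PathwayGraph,
    Reaction,
    ReactionKind,
    Segment,
    SpeciesDef,
    replace_graph,
)
from rampkit.quantio import write_quant_table

from conftest import TOY_LENGTHS, paired_table


@pytest.fixture(scope="module")
def chain_model():
    """rho -> A -> B -> disposal, with closed-form steady state rho/k."""
    full = tuple(Interval(seg, 1, TOY_LENGTHS[seg]) for seg in Segment)
    species = {
        "A": SpeciesDef("A", full),
        "B": SpeciesDef("B", (Interval(Segment.S18, 1, TOY_LENGTHS[Segment.S18]),)),
    }
    reactions = [
        Reaction("txn", ReactionKind.TRANSCRIPTION, products=("A",)),
        Reaction("a2b", ReactionKind.EXONUCLEOLYTIC, "A", None, ("B",)),
        Reaction("bout", ReactionKind.TERMINAL, "B"),
    ]
    graph = PathwayGraph(dict(TOY_LENGTHS), {}, species, reactions)
    return RateModel(graph, 8.0, {"a2b": 2.0, "bout": 4.0})


class TestSteadyState:
    def test_two_step_chain_closed_form(self, chain_model):
        ss = steady_state(chain_model)
        assert ss.abundances["A"] == pytest.approx(4.0, rel=1e-12)
        assert ss.abundances["B"] == pytest.approx(2.0, rel=1e-12)

    def test_branch_ratio_equals_rate_ratio(self, graph):
        # symmetric consumption of 34S and 36S: [34S]/[36S] = k_2c/k_2b
        model = default_rate_model(graph, overrides={"A0@34S": 1.0, "2c@36S": 1.0})
        ss = steady_state(model)
        k2c = model.rate_constants["2c@PTP"]
        k2b = model.rate_constants["2b@PTP"]
        assert ss.abundances["34S"] / ss.abundances["36S"] == pytest.approx(k2c / k2b, rel=1e-12)

    def test_flux_conservation(self, model):
        ss = steady_state(model)
        rho = model.transcription_rate
        # one mature rRNA of each kind per transcript
        for mature in ("18S", "5.8S", "28S"):
            assert ss.sink_fluxes[mature] == pytest.approx(rho, rel=1e-10)
        lhs, rhs = ss.nucleotide_balance()
        assert rhs == pytest.approx(lhs, rel=1e-10)

    def test_singular_species_named(self, model):
        # strip the 19S disposal: inflow with zero outflow must be reported
        graph = model.graph
        reactions = [r for r in graph.reactions if r.id != "decay@19S"]
        rates = {k: v for k, v in model.rate_constants.items() if k != "decay@19S"}
        bad = RateModel(replace_graph(graph, reactions=reactions), model.transcription_rate, rates)
        with pytest.raises(SingularModelError, match="19S"):
            steady_state(bad)


class TestTimecourse:
    def test_matches_closed_form_chain(self, chain_model):
        t, traj, names = timecourse(chain_model, t_end=20 / 2.0)
        end = dict(zip(names, traj[-1]))
        assert end["A"] == pytest.approx(4.0, rel=1e-6)
        assert end["B"] == pytest.approx(2.0, rel=1e-6)
        # transient against the analytic solution [A](t) = 4(1 - e^{-2t})
        mid = len(t) // 2
        assert traj[mid, names.index("A")] == pytest.approx(
            4.0 * (1 - np.exp(-2.0 * t[mid])), rel=1e-5
        )

    def test_zero_time_is_empty(self, chain_model):
        t, traj, _ = timecourse(chain_model, t_end=0.0)
        assert np.all(traj == 0.0) and t[-1] == 0.0

    def test_homogeneity_in_transcription_rate(self, chain_model):
        doubled = RateModel(
            chain_model.graph, 2 * chain_model.transcription_rate, chain_model.rate_constants
        )
        _, traj1, _ = timecourse(chain_model, t_end=3.0)
        _, traj2, _ = timecourse(doubled, t_end=3.0)
        assert np.allclose(traj2, 2 * traj1, rtol=1e-12)

    def test_unstable_step_rejected_with_suggestion(self, chain_model):
        with pytest.raises(UnstableStepError, match="try dt"):
            timecourse(chain_model, t_end=1.0, dt=10.0)

    def test_oracle_equivalence_on_random_models(self):
        """Linear solve and explicit integration agree on random models."""
        for m in random_models(10, seed=11):
            ss = steady_state(m)
            k_min = min(
                sum(m.rate_constants[r.id] for r in m.graph.reactions_consuming(sp))
                for sp in ss.abundances
            )
            _, traj, names = timecourse(m, t_end=20.0 / k_min)
            end = dict(zip(names, traj[-1]))
            rel = max(
                abs(end[n] - ss.abundances[n]) / max(ss.abundances[n], 1e-300)
                for n in names
            )
            assert rel < 1e-6


class TestPerturbation:
    def test_scales_only_tagged_reactions(self, model):
        pert = apply_perturbation(model, Perturbation("t", {"2b": 0.5}))
        for rid, k in model.rate_constants.items():
            expected = k * 0.5 if rid in ("2b@PTP", "2b@20S") else k
            assert pert.rate_constants[rid] == expected

    def test_identity_factor(self, model):
        pert = apply_perturbation(model, Perturbation("t", {"2c": 1.0}))
        assert pert.rate_constants == model.rate_constants

    def test_composition_is_multiplicative(self, model):
        twice = apply_perturbation(
            apply_perturbation(model, Perturbation("a", {"2b": 0.5})),
            Perturbation("b", {"2b": 0.5}),
        )
        once = apply_perturbation(model, Perturbation("c", {"2b": 0.25}))
        assert twice.rate_constants == once.rate_constants

    def test_original_model_unmodified(self, model):
        before = dict(model.rate_constants)
        apply_perturbation(model, Perturbation("t", {"ITS2": 0.1}))
        assert model.rate_constants == before

    def test_unknown_tag_rejected(self, model):
        with pytest.raises(KineticsError, match="unknown factor tag"):
            apply_perturbation(model, Perturbation("t", {"nonsense": 0.5}))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(KineticsError):
            Perturbation("t", {"2b": 0.0})


class TestSynthesize:
    def test_noiseless_unit_factors_reproduce_abundances(self, model):
        table = paired_table(model)
        ss = steady_state(model)
        for sp in ("PTP", "34S", "36S", "12S"):
            blot = "B-ITS1-85" if sp in ("PTP", "34S", "36S") else "B-ITS2-100"
            assert table.lane_signal(blot, 1, sp) == ss.abundances[sp]

    def test_lane_factors_do_not_change_profiles(self, model, panel, graph):
        from rampkit.ramp import build_profile

        pert = Perturbation("t", {"late-18SE": 0.25})
        clean = paired_table(model, pert)
        noisy = paired_table(model, pert, NoiseSpec(lane_factor_sd=0.8, probe_factor_sd=0.8), seed=3)
        p_clean = build_profile(clean, "kd-E1", "ref-E1", panel, graph).values()
        p_noisy = build_profile(noisy, "kd-E1", "ref-E1", panel, graph).values()
        assert np.allclose(p_clean, p_noisy, atol=1e-12)

    def test_fixed_seed_is_byte_identical(self, tmp_path, model):
        pert = Perturbation("t", {"2b": 0.5})
        paths = []
        for i in (1, 2):
            table = paired_table(model, pert, NoiseSpec(sigma_log=0.2), seed=42)
            p = tmp_path / f"t{i}.csv"
            write_quant_table(table, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestScenarios:
    def test_battery_has_named_knockdown_scenarios(self):
        names = {s.name for s in scenario_battery()}
        assert {"rcl1_like", "fcf1_like", "utp23_like", "pes1_like", "nog1_like"} <= names
        assert len(names) >= 5

    def test_branch_law_under_2b_inhibition(self):
        """With 34S/36S consumption untouched, {2b: f} shifts 34S/36S by -log2 f."""
        prof = simulate_scenario_profile(Perturbation("t", {"2b": 0.5}))
        assert prof.value("34S/36S") == pytest.approx(1.0, abs=1e-9)
        prof = simulate_scenario_profile(Perturbation("t", {"2b": 0.1}))
        assert prof.value("34S/36S") == pytest.approx(-np.log2(0.1), abs=1e-9)

    @pytest.mark.parametrize("scenario", scenario_battery(), ids=lambda s: s.name)
    def test_noiseless_profiles_match_expected_signs(self, scenario):
        theta = np.log2(1.5)
        prof = simulate_scenario_profile(scenario.perturbation)
        for label, expected in scenario.expected_signs.items():
            v = prof.value(label)
            sign = 0 if abs(v) <= theta else (1 if v > 0 else -1)
            assert sign == expected, f"{label}: {v:+.3f} vs expected sign {expected}"

    def test_noisy_replicates_keep_strong_signs(self):
        theta = np.log2(1.5)
        noise = NoiseSpec(sigma_log=0.1, lane_factor_sd=0.3, probe_factor_sd=0.5)
        for sc in scenario_battery():
            clean = simulate_scenario_profile(sc.perturbation)
            noisy = simulate_scenario_profile(sc.perturbation, n_replicates=3, noise=noise, seed=9)
            for e, v_clean in zip(noisy.entries, clean.values()):
                if abs(v_clean) >= 2 * theta:
                    assert np.sign(e.value) == np.sign(v_clean), e.definition.label
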