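"""RAMP core: ratio classes, normalization, profiles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rampkit.kinetics import NoiseSpec, Perturbation
from rampkit.quantio import COLUMNS, QuantTable
from rampkit.ramp import (
    BelowDetectionError,
    ProvenanceError,
    RatioClass,
    RatioDefinition,
    RatioError,
    RatioPanel,
    aggregate_replicates,
    build_profile,
    compute_ratio,
    default_mouse_panel,
    normalized_log_ratio,
    read_profile_tsv,
    write_profile_tsv,
)

from conftest import paired_table


def _table(rows):
    return QuantTable(pd.DataFrame(rows, columns=list(COLUMNS)))


R_34_36 = RatioDefinition("34S", "36S", RatioClass.MUTUALLY_EXCLUSIVE)


class TestComputeRatio:
    rows = [
        ("B1", "p", "s", 1, "34S", 120.0, "E1", "reference"),
        ("B1", "p", "s", 1, "36S", 60.0, "E1", "reference"),
        ("B1", "p", "s", 1, "29S", 0.0, "E1", "reference"),
    ]

    def test_within_lane_ratio(self):
        assert compute_ratio(_table(self.rows), R_34_36, "B1", 1) == 2.0

    def test_cross_blot_is_provenance_error(self):
        with pytest.raises(ProvenanceError):
            compute_ratio(_table(self.rows), R_34_36, "B1", 1, denom_blot_id="B2")

    def test_cross_lane_is_provenance_error(self):
        with pytest.raises(ProvenanceError):
            compute_ratio(_table(self.rows), R_34_36, "B1", 1, denom_lane=2)

    def test_zero_denominator_below_detection(self):
        d = RatioDefinition("34S", "29S", RatioClass.SUBSTRATE_PRODUCT)
        with pytest.raises(BelowDetectionError) as exc:
            compute_ratio(_table(self.rows), d, "B1", 1)
        assert exc.value.species == "29S"


@pytest.mark.parametrize(
    "kd,ref,expected",
    [(2.0, 1.0, 1.0), (3.7, 3.7, 0.0), (0.25, 2.0, -3.0)],
)
def test_normalized_log_ratio(kd, ref, expected):
    assert normalized_log_ratio(kd, ref) == pytest.approx(expected)


def test_normalized_log_ratio_rejects_nonpositive():
    with pytest.raises(RatioError):
        normalized_log_ratio(0.0, 1.0)


class TestPanel:
    def test_default_panel_validates(self, graph, panel):
        panel.validate_against(graph)
        assert panel.labels[:2] == ("34S/PTP", "36S/PTP")
        assert "34S/36S" in panel.labels

    def test_mutually_exclusive_requires_disjoint_routes(self, graph):
        # 36S -> 32.5S -> 32S -> 12S is a real path, so this pair is not exclusive
        bad = RatioPanel((RatioDefinition("12S", "36S", RatioClass.MUTUALLY_EXCLUSIVE),))
        with pytest.raises(RatioError, match="one route"):
            bad.validate_against(graph)

    def test_tile_order_enforced(self):
        with pytest.raises(RatioError, match="tile"):
            RatioPanel(
                (
                    RatioDefinition("12S", "32S", RatioClass.SUBSTRATE_PRODUCT),
                    RatioDefinition("34S", "PTP", RatioClass.VS_PTP),
                )
            )


class TestBuildProfile:
    def test_identical_samples_give_zero_profile(self, model, panel, graph):
        table = paired_table(model)  # kd state == ref state
        prof = build_profile(table, "kd-E1", "ref-E1", panel, graph)
        assert np.allclose(prof.values(), 0.0)

    def test_simulated_2b_half_gives_plus_one_branch_shift(self, model, panel, graph):
        table = paired_table(model, Perturbation("t", {"2b": 0.5}))
        prof = build_profile(table, "kd-E1", "ref-E1", panel, graph)
        assert prof.value("34S/36S") == pytest.approx(1.0, abs=1e-9)

    def test_missing_species_flagged_not_zero(self, model, panel, graph):
        table = paired_table(model)
        f = table.frame
        table = QuantTable(f[~((f["species"] == "12S") & (f["lane"] == 2))])
        prof = build_profile(table, "kd-E1", "ref-E1", panel, graph)
        for label in ("12S/PTP", "12S/32S"):
            entry = prof.entry(label)
            assert entry.missing and entry.flags
        assert prof.value("34S/PTP") is not None

    def test_cross_experiment_pair_rejected(self, model, panel, graph):
        table = paired_table(model, replicates=2)
        with pytest.raises(RatioError, match="not a pair"):
            build_profile(table, "kd-E1", "ref-E2", panel, graph)


class TestAggregate:
    def _profile_with(self, panel, values):
        from rampkit.ramp import ProfileEntry, RAMPProfile

        entries = tuple(ProfileEntry(d, v) for d, v in zip(panel.definitions, values))
        return RAMPProfile(panel, entries)

    def test_equal_replicates(self, panel):
        p = self._profile_with(panel, [1.0] * len(panel))
        agg = aggregate_replicates([p, p, p])
        e = agg.entries[0]
        assert (e.value, e.sd, e.n) == (1.0, 0.0, 3)

    def test_sample_sd(self, panel):
        p1 = self._profile_with(panel, [0.0] * len(panel))
        p2 = self._profile_with(panel, [2.0] * len(panel))
        agg = aggregate_replicates([p1, p2])
        assert agg.entries[0].value == pytest.approx(1.0)
        assert agg.entries[0].sd == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_single_replicate_has_no_sd(self, panel):
        agg = aggregate_replicates([self._profile_with(panel, [0.7] * len(panel))])
        assert agg.entries[0].value == pytest.approx(0.7)
        assert agg.entries[0].sd is None and agg.entries[0].n == 1

    def test_panel_mismatch_rejected(self, panel):
        other = RatioPanel(panel.definitions[:-1])
        p1 = self._profile_with(panel, [0.0] * len(panel))
        p2 = self._profile_with(other, [0.0] * len(other))
        with pytest.raises(RatioError, match="mismatch"):
            aggregate_replicates([p1, p2])


_SCALING_CACHE = {}


def _scaling_fixture():
    if not _SCALING_CACHE:
        from rampkit.kinetics import default_rate_model
        from rampkit.pathway import build_default_mouse_pathway

        graph = build_default_mouse_pathway()
        model = default_rate_model(graph)
        panel = default_mouse_panel(graph)
        table = paired_table(model, Perturbation("t", {"SSU-A0": 0.25}), replicates=3)
        base = build_profile(table, "kd-E1", "ref-E1", panel, graph).values()
        _SCALING_CACHE.update(graph=graph, panel=panel, table=table, base=base)
    c = _SCALING_CACHE
    return c["graph"], c["panel"], c["table"], c["base"]


@given(lane=st.integers(1, 6), exponent=st.integers(-20, 20))
def test_lane_scaling_invariance_bit_identical(lane, exponent):
    """Per-lane loading factors cancel exactly.

    Power-of-two scalings keep float multiplication exact, so the profile
    must be *bit-identical*, not merely close.
    """
    graph, panel, table, base = _scaling_fixture()
    f = table.frame.copy()
    f.loc[f["lane"] == lane, "signal"] *= 2.0**exponent
    scaled = build_profile(QuantTable(f), "kd-E1", "ref-E1", panel, graph).values()
    assert np.array_equal(base, scaled)


@given(
    lane=st.integers(1, 6),
    scale=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False, exclude_min=True),
)
def test_lane_scaling_invariance_arbitrary_constant(lane, scale):
    """Arbitrary positive loadings cancel to floating-point rounding."""
    graph, panel, table, base = _scaling_fixture()
    f = table.frame.copy()
    f.loc[f["lane"] == lane, "signal"] *= scale
    scaled = build_profile(QuantTable(f), "kd-E1", "ref-E1", panel, graph).values()
    assert np.allclose(base, scaled, atol=1e-12, rtol=0)


def test_probe_efficiency_invariance(model, panel, graph):
    """Scaling a whole blot (probe efficiency) leaves the profile bit-identical."""
    table = paired_table(model, Perturbation("t", {"2c": 0.25}))
    base = build_profile(table, "kd-E1", "ref-E1", panel, graph).values()
    for blot, scale in [("B-ITS1-85", 16.0), ("B-ITS2-100", 2.0**-9)]:
        f = table.frame.copy()
        f.loc[f["blot_id"] == blot, "signal"] *= scale
        scaled = build_profile(QuantTable(f), "kd-E1", "ref-E1", panel, graph).values()
        assert np.array_equal(base, scaled)


def test_antisymmetry_swapping_kd_and_ref(model, panel, graph):
    table = paired_table(model, Perturbation("t", {"ITS2": 0.1}), NoiseSpec(sigma_log=0.2), seed=5)
    fwd = build_profile(table, "kd-E1", "ref-E1", panel, graph).values()
    rev = build_profile(table, "ref-E1", "kd-E1", panel, graph).values()
    assert np.allclose(fwd, -rev, atol=1e-12)


def test_profile_tsv_round_trip(tmp_path, model, panel, graph):
    table = paired_table(model, Perturbation("t", {"2b": 0.25}), replicates=2)
    profs = [build_profile(table, f"kd-E{i}", f"ref-E{i}", panel, graph) for i in (1, 2)]
    agg = aggregate_replicates(profs)
    p = tmp_path / "profile.tsv"
    write_profile_tsv(agg, p, header_comment="test")
    back = read_profile_tsv(p, graph)
    assert back.panel.labels == agg.panel.labels
    assert np.allclose(back.values(), agg.values(), equal_nan=True)
    assert [e.n for e in back.entries] == [e.n for e in agg.entries]
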