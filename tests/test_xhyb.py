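"""Cross-hybridizing probe calling: thresholds, evidence combination, homologs."""

import math

import numpy as np
import pytest

from stromacomp.simulate import SimulationParams, simulate_dual_rna_experiment
from stromacomp.xhyb import (
    AlignmentHit,
    HomologyMap,
    ProbeRecord,
    ThresholdModel,
    XhybCall,
    call_xhyb_expression,
    classify_homolog_target,
    combine_evidence,
    derive_background_cutoff,
    optimize_threshold,
    precision_recall_f,
)


def probe(pid, human, mouse, gene="G1"):
    return ProbeRecord(probe_id=pid, gene_id=gene,
                       intensity_human=human, intensity_mouse=mouse)


class TestBackgroundCutoff:
    def test_top18_percent_of_1_to_100(self):
        probes = [probe(f"p{i}", 5.0, float(i)) for i in range(1, 101)]
        expected = np.percentile(np.arange(1.0, 101.0), 82.0)
        assert derive_background_cutoff(probes, 18.0) == pytest.approx(expected)

    def test_x_100_gives_minimum(self):
        probes = [probe(f"p{i}", 5.0, float(i)) for i in range(1, 21)]
        assert derive_background_cutoff(probes, 100.0) == 1.0

    def test_constant_intensities(self):
        probes = [probe(f"p{i}", 5.0, 3.5) for i in range(12)]
        assert derive_background_cutoff(probes, 18.0) == 3.5

    @pytest.mark.parametrize("x", [0.0, -1.0, 101.0])
    def test_invalid_percentile_rejected(self, x):
        probes = [probe(f"p{i}", 5.0, float(i)) for i in range(12)]
        with pytest.raises(ValueError):
            derive_background_cutoff(probes, x)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            derive_background_cutoff([], 18.0)


class TestExpressionRule:
    MODEL = ThresholdModel(x=18.0, mouse_cutoff=6.0, human_margin=1.0)

    def test_below_cutoff_fails(self):
        [call] = call_xhyb_expression([probe("p1", 3.0, 5.9)], self.MODEL)
        assert not call.passes_expression_rule

    def test_margin_violated_fails(self):
        [call] = call_xhyb_expression([probe("p1", 7.0, 7.0)], self.MODEL)
        assert not call.passes_expression_rule

    def test_above_cutoff_with_margin_passes(self):
        [call] = call_xhyb_expression([probe("p1", 4.0, 7.0)], self.MODEL)
        assert call.passes_expression_rule
        assert call.background_percentile_used == 18.0

    def test_missing_channel_skipped(self):
        calls = call_xhyb_expression(
            [probe("p1", math.nan, 7.0), probe("p2", 4.0, 7.0)], self.MODEL
        )
        assert [c.probe_id for c in calls] == ["p2"]

    def test_zero_noise_simulation_perfect_recovery(self):
        params = SimulationParams(n_probes=1000, frac_xhyb=0.05, separation=2.0,
                                  noise_sd=0.0, seed=5)
        probes, truth = simulate_dual_rna_experiment(params)
        planted_x = 100.0 * sum(truth.values()) / len(probes)
        cutoff = derive_background_cutoff(probes, planted_x)
        model = ThresholdModel(x=planted_x, mouse_cutoff=cutoff, human_margin=2.0)
        calls = call_xhyb_expression(probes, model)
        predicted = {c.probe_id for c in calls if c.passes_expression_rule}
        assert predicted == {p for p, v in truth.items() if v}


def make_hit(pid, subject="M1", pident=95.0, length=55, bitscore=90.0):
    return AlignmentHit(probe_id=pid, subject_id=subject, percent_identity=pident,
                        alignment_length=length, evalue=1e-10, bitscore=bitscore)


class TestCombineEvidence:
    def expr_call(self, pid, passes):
        return XhybCall(probe_id=pid, is_xhyb=passes, has_alignment_support=False,
                        passes_expression_rule=passes)

    def test_intersection_requires_both(self):
        [call] = combine_evidence([self.expr_call("p1", True)], [], mode="intersection")
        assert not call.is_xhyb

    def test_union_accepts_either(self):
        [call] = combine_evidence([self.expr_call("p1", True)], [], mode="union")
        assert call.is_xhyb

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown evidence mode"):
            combine_evidence([], [], mode="both")

    def test_weak_hit_gives_no_support(self):
        [call] = combine_evidence(
            [self.expr_call("p1", True)], [make_hit("p1", pident=70.0, length=25)],
            mode="intersection",
        )
        assert not call.has_alignment_support and not call.is_xhyb

    @pytest.mark.parametrize("seed", range(3))
    def test_set_algebra_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        expr = [self.expr_call(f"p{i}", bool(rng.random() < 0.5)) for i in range(50)]
        hits = [make_hit(f"p{i}") for i in range(50) if rng.random() < 0.5]
        by_mode = {
            mode: {c.probe_id for c in combine_evidence(expr, hits, mode=mode) if c.is_xhyb}
            for mode in ("intersection", "union", "expression_only", "alignment_only")
        }
        assert by_mode["intersection"] == by_mode["expression_only"] & by_mode["alignment_only"]
        assert by_mode["union"] == by_mode["expression_only"] | by_mode["alignment_only"]
        assert by_mode["intersection"] <= by_mode["expression_only"] <= by_mode["union"]


class TestHomologTarget:
    HOMOLOGY = HomologyMap([("H1", "M1"), ("H2", "M2")])
    GENE_MAP = {"p1": "H1"}

    def xcall(self, pid="p1"):
        return XhybCall(probe_id=pid, is_xhyb=True, has_alignment_support=True,
                        passes_expression_rule=True)

    def test_best_hit_is_homolog(self):
        assert classify_homolog_target(
            self.xcall(), [make_hit("p1", "M1")], self.HOMOLOGY, self.GENE_MAP
        ) is True

    def test_best_hit_is_paralog(self):
        hits = [make_hit("p1", "M2", bitscore=99.0), make_hit("p1", "M1", bitscore=80.0)]
        assert classify_homolog_target(self.xcall(), hits, self.HOMOLOGY, self.GENE_MAP) is False

    def test_no_hits_is_unknown_not_false(self):
        assert classify_homolog_target(self.xcall(), [], self.HOMOLOGY, self.GENE_MAP) is None

    def test_missing_homolog_entry_is_unknown(self):
        assert classify_homolog_target(
            self.xcall(), [make_hit("p1", "M9")], self.HOMOLOGY, {"p1": "H9"}
        ) is None

    def test_bitscore_tie_favors_homolog(self):
        hits = [make_hit("p1", "M2", bitscore=90.0), make_hit("p1", "M1", bitscore=90.0)]
        assert classify_homolog_target(self.xcall(), hits, self.HOMOLOGY, self.GENE_MAP) is True

    def test_one_to_many_homology_rejected_with_default(self):
        hmap = HomologyMap([("H1", "M1"), ("H1", "M2")])
        assert len(hmap) == 1
        with pytest.raises(ValueError):
            HomologyMap([("H1", "M1"), ("H1", "M2")], on_conflict="error")


class TestOptimizeThreshold:
    def test_f_score_formula(self):
        assert precision_recall_f({"a"}, {"a"}) == (1.0, 1.0, 1.0)
        p, r, f = precision_recall_f({"a", "b", "c", "d", "e"},
                                     {"a", "b", "x", "y", "z", "w", "v", "u"})
        assert (p, r) == (0.4, 0.25)
        assert f == pytest.approx(2 * 0.4 * 0.25 / 0.65)
        assert f == pytest.approx(0.3077, abs=1e-4)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([probe("p1", 4.0, 7.0)], {"p1": True}, [], [1.0])

    def test_no_positive_labels_rejected(self):
        probes = [probe(f"p{i}", 4.0, 5.0) for i in range(12)]
        with pytest.raises(ValueError, match="positive truth labels"):
            optimize_threshold(probes, {p.probe_id: False for p in probes},
                               [10.0], [1.0])

    def test_argmax_near_planted_boundary(self):
        params = SimulationParams(n_probes=3000, frac_xhyb=0.10, separation=2.0,
                                  noise_sd=0.1, seed=21)
        probes, truth = simulate_dual_rna_experiment(params)
        planted_x = 100.0 * sum(truth.values()) / len(probes)
        x_grid = [2.0 * i for i in range(1, 11)]
        model, table = optimize_threshold(probes, truth, x_grid, [0.5, 1.0])
        step = x_grid[1] - x_grid[0]
        assert abs(model.x - planted_x) <= step
        assert table.f_score.max() >= 0.95

    def test_call_sets_nest_along_stricter_percentiles(self):
        params = SimulationParams(n_probes=2000, frac_xhyb=0.05, noise_sd=0.25, seed=3)
        probes, _ = simulate_dual_rna_experiment(params)
        previous = None
        for x in [20.0, 15.0, 10.0, 5.0, 2.0]:  # decreasing x = stricter cutoff
            cutoff = derive_background_cutoff(probes, x)
            calls = call_xhyb_expression(
                probes, ThresholdModel(x=x, mouse_cutoff=cutoff, human_margin=1.0)
            )
            current = {c.probe_id for c in calls if c.passes_expression_rule}
            if previous is not None:
                assert current <= previous
            previous = current
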