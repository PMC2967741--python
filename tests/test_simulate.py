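"""Synthetic-data generators: determinism, planted structure, model contracts."""

import numpy as np
import pandas as pd
import pytest

from stromacomp.go_dag import propagate_annotations
from stromacomp.simulate import (
    SimulationParams,
    log_fold_change,
    simulate_alignment_evidence,
    simulate_component_study,
    simulate_dual_rna_experiment,
    simulate_go_with_planted_enrichment,
    simulate_xenograft_de,
)
from stromacomp.xhyb import HitFilter, ThresholdModel, call_xhyb_expression, \
    derive_background_cutoff

SMALL = SimulationParams(n_probes=400, frac_xhyb=0.1, seed=42)


class TestDeterminism:
    def test_dual_rna_identical_under_fixed_seed(self):
        a, ta = simulate_dual_rna_experiment(SMALL)
        b, tb = simulate_dual_rna_experiment(SMALL)
        assert a == b and ta == tb

    def test_de_matrix_identical_under_fixed_seed(self):
        ma, _ = simulate_xenograft_de(SMALL)
        mb, _ = simulate_xenograft_de(SMALL)
        pd.testing.assert_frame_equal(ma, mb)

    def test_go_identical_under_fixed_seed(self):
        genes = {f"HG{i:05d}" for i in range(50)}
        stromal, cancer = set(list(genes)[:10]), set(list(genes)[10:20])
        d1, a1, p1 = simulate_go_with_planted_enrichment(SMALL, stromal, cancer, genes)
        d2, a2, p2 = simulate_go_with_planted_enrichment(SMALL, stromal, cancer, genes)
        assert set(d1.terms) == set(d2.terms)
        assert a1.direct == a2.direct
        assert p1 == p2

    def test_different_seeds_differ(self):
        other = SimulationParams(n_probes=400, frac_xhyb=0.1, seed=43)
        a, _ = simulate_dual_rna_experiment(SMALL)
        b, _ = simulate_dual_rna_experiment(other)
        assert a != b


class TestDualRna:
    def test_zero_noise_separation_is_clean(self):
        params = SimulationParams(n_probes=500, frac_xhyb=0.1, separation=2.0,
                                  noise_sd=0.0, seed=9)
        probes, truth = simulate_dual_rna_experiment(params)
        xhyb_mouse = [p.intensity_mouse for p in probes if truth[p.probe_id]]
        bg_mouse = [p.intensity_mouse for p in probes if not truth[p.probe_id]]
        assert min(xhyb_mouse) - max(bg_mouse) >= 0  # gap exists
        # Xhyb probes: mouse channel beats human channel by >= separation
        for p in probes:
            if truth[p.probe_id]:
                assert p.intensity_mouse - p.intensity_human >= params.separation - 1e-9

    def test_planted_fraction_approximately_respected(self):
        probes, truth = simulate_dual_rna_experiment(SMALL)
        frac = sum(truth.values()) / len(probes)
        assert frac == pytest.approx(SMALL.frac_xhyb, abs=0.05)

    def test_mixed_channel_dominated_by_stronger_source(self):
        params = SimulationParams(n_probes=200, frac_xhyb=0.1, noise_sd=0.0, seed=2)
        probes, _ = simulate_dual_rna_experiment(params)
        for p in probes:
            assert p.intensity_both >= max(p.intensity_human, p.intensity_mouse) - 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_probes=100, frac_xhyb=1.5)
        with pytest.raises(ValueError):
            SimulationParams(n_probes=100, noise_sd=-0.1)
        with pytest.raises(ValueError):
            SimulationParams(n_probes=100, n_samples_per_group=1)


class TestAlignmentEvidence:
    def test_every_xhyb_probe_gets_a_passing_hit(self):
        probes, truth = simulate_dual_rna_experiment(SMALL)
        hits, homology, homolog_truth = simulate_alignment_evidence(SMALL, probes, truth)
        hit_filter = HitFilter()
        supported = {h.probe_id for h in hits if hit_filter.passes(h)}
        xhyb = {p for p, v in truth.items() if v}
        assert xhyb <= supported
        # spurious hits on non-Xhyb probes fail the default filter
        assert supported == xhyb
        assert set(homolog_truth) == xhyb

    def test_homolog_fraction_matches_truth_labels(self):
        params = SimulationParams(n_probes=2000, frac_xhyb=0.2, seed=8)
        probes, truth = simulate_dual_rna_experiment(params)
        hits, homology, homolog_truth = simulate_alignment_evidence(params, probes, truth)
        frac = sum(homolog_truth.values()) / len(homolog_truth)
        assert frac == pytest.approx(params.homolog_frac, abs=0.07)
        # the truth labels agree with what the hits actually say
        from stromacomp.simulate import mouse_gene_of
        best_by_probe = {}
        for h in hits:
            cur = best_by_probe.get(h.probe_id)
            if cur is None or h.bitscore > cur.bitscore:
                best_by_probe[h.probe_id] = h
        gene = {p.probe_id: p.gene_id for p in probes}
        for pid, is_homolog in homolog_truth.items():
            assert (best_by_probe[pid].subject_id == mouse_gene_of(gene[pid])) == is_homolog


class TestXenograftDe:
    def test_zero_noise_logfc_recovers_planted_effect(self):
        params = SimulationParams(n_probes=300, frac_xhyb=0.2, noise_sd=0.0, seed=7)
        matrix, truth = simulate_xenograft_de(params)
        lfc = log_fold_change(matrix)
        for probe_id, effect in truth.planted_effect.items():
            assert lfc[probe_id] == pytest.approx(effect, abs=1e-9)

    def test_components_do_not_mix(self):
        params = SimulationParams(n_probes=600, frac_xhyb=0.2, noise_sd=0.0, seed=12)
        probes, xtruth = simulate_dual_rna_experiment(params)
        _, truth = simulate_xenograft_de(params, probes, xtruth)
        gene_is_xhyb = {p.gene_id: xtruth[p.probe_id] for p in probes}
        assert all(gene_is_xhyb[g] for g in truth.stromal_de_genes)
        assert not any(gene_is_xhyb[g] for g in truth.cancer_de_genes)

    def test_cancer_effect_on_xhyb_attenuated_by_leakage(self):
        params = SimulationParams(n_probes=600, frac_xhyb=0.3, noise_sd=0.0, seed=5,
                                  frac_de_stromal=0.0, frac_de_cancer=0.5,
                                  plant_cancer_on_xhyb=True, leakage=0.2)
        probes, xtruth = simulate_dual_rna_experiment(params)
        matrix, truth = simulate_xenograft_de(params, probes, xtruth)
        assert truth.cancer_effect_on_xhyb  # some planted and flagged
        lfc = log_fold_change(matrix)
        for pid, c_hs in truth.cancer_effect_on_xhyb.items():
            assert lfc[pid] == pytest.approx(params.leakage * c_hs, abs=1e-9)

    def test_noisy_logfc_error_small(self):
        params = SimulationParams(n_probes=500, frac_xhyb=0.2, noise_sd=0.3, seed=7,
                                  n_samples_per_group=5, frac_de_stromal=0.2)
        matrix, truth = simulate_xenograft_de(params)
        lfc = log_fold_change(matrix)
        planted = {p: e for p, e in truth.planted_effect.items() if e != 0.0}
        mae = np.mean([abs(lfc[p] - e) for p, e in planted.items()])
        assert mae < 0.2


class TestPlantedGo:
    def test_perfect_signal_makes_planted_terms_minimal_p(self):
        from stromacomp.enrichment import EnrichmentConfig, conditional_go_enrichment
        params = SimulationParams(n_probes=400, seed=3, annotation_prob=1.0,
                                  background_annotations_per_gene=1,
                                  n_planted_stromal=3, n_planted_cancer=0)
        genes = {f"HG{i:05d}" for i in range(200)}
        stromal = set(sorted(genes)[:30])
        dag, ann, planted = simulate_go_with_planted_enrichment(params, stromal, set(), genes)
        res = conditional_go_enrichment(
            EnrichmentConfig(foreground=stromal, universe=genes, conditional=False),
            dag, ann)
        by_p = sorted(res, key=lambda r: r.p_value)
        top = {r.term_id for r in by_p[:3]}
        assert top == planted["stromal"]

    def test_round_trip_through_module_invariants(self):
        study = simulate_component_study(SimulationParams(
            n_probes=300, frac_xhyb=0.3, seed=6, frac_de_stromal=0.3, frac_de_cancer=0.3))
        # annotations are propagated-consistent
        reprop = propagate_annotations(study.dag, study.annotations.direct)
        assert reprop.propagated == study.annotations.propagated
        # every planted term is a term of the DAG
        for terms in study.planted_terms.values():
            assert terms <= set(study.dag.terms)
        # truth labels cover every probe
        assert set(study.xhyb_truth) == {p.probe_id for p in study.probes}

    def test_caller_works_on_simulated_study(self):
        study = simulate_component_study(SimulationParams(
            n_probes=300, frac_xhyb=0.3, seed=6, frac_de_stromal=0.3, frac_de_cancer=0.3))
        x = 100.0 * study.params.frac_xhyb
        cutoff = derive_background_cutoff(study.probes, x)
        calls = call_xhyb_expression(
            study.probes, ThresholdModel(x=x, mouse_cutoff=cutoff, human_margin=1.0))
        predicted = {c.probe_id for c in calls if c.passes_expression_rule}
        truth = {p for p, v in study.xhyb_truth.items() if v}
        jaccard = len(predicted & truth) / len(predicted | truth)
        assert jaccard > 0.9
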