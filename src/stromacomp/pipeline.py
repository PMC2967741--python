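"""End-to-end analysis of a study: calling -> partition -> component enrichment.

Mirrors the two-part workflow: part A identifies Xhyb probes, splits the
deregulated gene list and runs the component enrichments; part B scores the
outcome against reference term sets (see :mod:`stromacomp.evaluation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import xhyb
from .enrichment import (
    ENRICHMENT_MODES,
    EnrichmentResult,
    run_component_enrichment,
    significant_terms,
)
from .partition import GenePartition, homolog_targeting_subset, partition_gene_list
from .simulate import ComponentStudy


@dataclass
class StudyAnalysis:
    """Bundle of everything part A produces for one study."""

    threshold: xhyb.ThresholdModel
    calls: list[xhyb.XhybCall]
    partition: GenePartition
    results: dict[str, list[EnrichmentResult]]
    significant: dict[str, set[str]] = field(default_factory=dict)

    @property
    def called_xhyb_probes(self) -> set[str]:
        return {c.probe_id for c in self.calls if c.is_xhyb}


def analyze_study(
    study: ComponentStudy,
    percentile: float | None = None,
    margin: float = 1.0,
    evidence_mode: str = "intersection",
    modes: tuple[str, ...] = ENRICHMENT_MODES,
    alpha: float = 0.01,
    p_cutoff: float = 0.01,
) -> StudyAnalysis:
    """Run calling, homolog classification, partition and enrichment a-d.

    ``percentile`` defaults to the study's planted Xhyb fraction (the operating
    point a threshold sweep would land on); pass an explicit value to emulate a
    mis-set cutoff.
    """
    if percentile is None:
        percentile = 100.0 * study.params.frac_xhyb
    cutoff = xhyb.derive_background_cutoff(study.probes, percentile)
    model = xhyb.ThresholdModel(x=percentile, mouse_cutoff=cutoff, human_margin=margin)
    calls = xhyb.call_xhyb_expression(study.probes, model)
    calls = xhyb.combine_evidence(calls, study.hits, mode=evidence_mode)
    probe_gene = study.probe_gene_map
    for call in calls:
        if call.is_xhyb:
            call.targets_homolog = xhyb.classify_homolog_target(
                call, study.hits, study.homology, probe_gene
            )

    part = partition_gene_list(study.de_truth.de_genes(), calls, probe_gene)
    xhyb_array_genes = {probe_gene[c.probe_id] for c in calls if c.is_xhyb}
    homolog_de = homolog_targeting_subset(part, calls, probe_gene)

    results: dict[str, list[EnrichmentResult]] = {}
    significant: dict[str, set[str]] = {}
    for mode in modes:
        results[mode] = run_component_enrichment(
            mode, part, study.array_genes, xhyb_array_genes, study.dag,
            study.annotations, homolog_xhyb_de_genes=homolog_de,
            alpha_conditional=alpha,
        )
        significant[mode] = significant_terms(results[mode], p_cutoff=p_cutoff)
    return StudyAnalysis(
        threshold=model, calls=calls, partition=part,
        results=results, significant=significant,
    )
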