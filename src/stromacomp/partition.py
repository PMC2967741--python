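"""Partition a deregulated gene list into stromal and cancer-cell candidates.

In a xenograft experiment run on a human array, deregulated genes whose probes
all cross-hybridize with mouse RNA carry a stromal (mouse) signal; genes with a
mixture of Xhyb and non-Xhyb probes are ambiguous; genes with no Xhyb probe
carry the cancer-cell (human) signal. The partition is computed at the gene
level from per-probe Xhyb calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .xhyb import XhybCall

logger = logging.getLogger(__name__)


@dataclass
class GenePartition:
    """Disjoint, exhaustive split of a deregulated gene list.

    ``xhyb_genes``: all of the gene's probes are Xhyb (stromal candidates).
    ``possible_xhyb_genes``: at least one but not all probes Xhyb (ambiguous).
    ``remaining_genes``: no Xhyb probe (cancer-cell candidates).
    ``unmapped_genes``: deregulated genes with no probe on the platform,
    reported separately rather than silently dropped.
    """

    xhyb_genes: set[str] = field(default_factory=set)
    possible_xhyb_genes: set[str] = field(default_factory=set)
    remaining_genes: set[str] = field(default_factory=set)
    unmapped_genes: set[str] = field(default_factory=set)
    per_gene_probe_detail: dict[str, tuple[int, int]] = field(default_factory=dict)

    def stromal_foreground(self, include_possible: bool = True) -> set[str]:
        """Genes carrying putative stromal signal (Xhyb-involved)."""
        if include_possible:
            return self.xhyb_genes | self.possible_xhyb_genes
        return set(self.xhyb_genes)

    def cancer_foreground(self, exclude_possible: bool = True) -> set[str]:
        """Genes carrying putative cancer-cell signal."""
        if exclude_possible:
            return set(self.remaining_genes)
        return self.remaining_genes | self.possible_xhyb_genes

    def validate(self) -> None:
        sets = [self.xhyb_genes, self.possible_xhyb_genes, self.remaining_genes]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise AssertionError("partition components are not disjoint")


def partition_gene_list(
    de_genes: Iterable[str],
    calls: Sequence[XhybCall],
    probe_gene_map: Mapping[str, str],
    strict_single_probe: bool = False,
) -> GenePartition:
    """Split deregulated genes by the Xhyb status of their probes.

    With ``strict_single_probe`` (literal reading of "only one cross-mouse
    hybridizing probe"), the stromal component admits only genes represented by
    exactly one probe, that probe being Xhyb. The default reading — every probe
    of the gene is Xhyb — coincides with it on single-probe genes, which
    dominate this platform.
    """
    gene_probes: dict[str, list[str]] = {}
    for probe_id, gene_id in probe_gene_map.items():
        gene_probes.setdefault(gene_id, []).append(probe_id)
    call_by_probe = {c.probe_id: c for c in calls}

    part = GenePartition()
    for gene in sorted(set(de_genes)):
        probes = gene_probes.get(gene, [])
        scored = [p for p in probes if p in call_by_probe]
        if not scored:
            part.unmapped_genes.add(gene)
            continue
        n_xhyb = sum(call_by_probe[p].is_xhyb for p in scored)
        part.per_gene_probe_detail[gene] = (len(scored), n_xhyb)
        if n_xhyb == 0:
            part.remaining_genes.add(gene)
        elif n_xhyb == len(scored):
            if strict_single_probe and len(scored) != 1:
                part.possible_xhyb_genes.add(gene)
            else:
                part.xhyb_genes.add(gene)
        else:
            part.possible_xhyb_genes.add(gene)
    if part.unmapped_genes:
        logger.warning(
            "partition_gene_list: %d deregulated genes had no scored probe on the platform",
            len(part.unmapped_genes),
        )
    part.validate()
    return part


def homolog_targeting_subset(
    partition: GenePartition, calls: Sequence[XhybCall], probe_gene_map: Mapping[str, str]
) -> set[str]:
    """Genes whose Xhyb probes cross-hybridize with their designed gene's homolog.

    The most stroma-specific foreground: a gene qualifies when every one of its
    Xhyb probes has ``targets_homolog`` resolved True. Probes with unknown
    homolog status exclude the gene (logged), keeping the subset conservative.
    """
    candidates = partition.stromal_foreground(include_possible=True)
    by_gene: dict[str, list[XhybCall]] = {}
    for call in calls:
        if not call.is_xhyb:
            continue
        gene = probe_gene_map.get(call.probe_id)
        if gene in candidates:
            by_gene.setdefault(gene, []).append(call)
    subset = set()
    n_unknown = 0
    for gene, gene_calls in by_gene.items():
        statuses = [c.targets_homolog for c in gene_calls]
        if any(s is None for s in statuses):
            n_unknown += 1
            continue
        if all(statuses):
            subset.add(gene)
    if n_unknown:
        logger.info(
            "homolog_targeting_subset: %d genes excluded for unresolved homolog status",
            n_unknown,
        )
    return subset
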