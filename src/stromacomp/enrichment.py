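"""Conditional (bottom-up) hypergeometric GO-BP enrichment with component backgrounds.

The test asks, for each GO biological-process term, whether the foreground gene
list contains more genes annotated to the term than expected under hypergeometric
sampling from the universe. Two features distinguish it from a plain term-by-term
test:

* **Conditioning.** Terms are visited bottom-up (children before parents). When a
  term is tested, genes already explained by a significant child — i.e. annotated
  (after propagation) to any direct child with p below ``alpha_conditional`` — are
  removed from the term's gene list, shrinking both its universe count K and its
  foreground count k while the margins n and N stay fixed. This stops a parent
  from appearing enriched merely because it inherits the genes of an enriched
  child, and makes small gene lists yield specific terms.

* **Component-matched backgrounds.** Four foreground/universe pairings target the
  two biological components of a xenograft:

  - mode a: all deregulated genes vs all array genes (conventional);
  - mode b: Xhyb deregulated genes vs all Xhyb array genes (stromal signal);
  - mode c: remaining deregulated genes vs non-Xhyb array genes (cancer signal);
  - mode d: homolog-targeting Xhyb deregulated genes vs all Xhyb array genes
    (most stroma-specific signal).

P-values are unadjusted upper-tail probabilities by default; Benjamini-Hochberg
adjustment is available for modern use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .go_dag import AnnotationSet, GoDag
from .partition import GenePartition

logger = logging.getLogger(__name__)

ENRICHMENT_MODES = ("a", "b", "c", "d")


class EmptyComponentError(ValueError):
    """Raised when the foreground implied by an enrichment mode is empty."""


@dataclass
class EnrichmentConfig:
    """Foreground/universe pair plus conditioning parameters for one run."""

    foreground: set[str]
    universe: set[str]
    mode: str | None = None
    alpha_conditional: float = 0.01
    conditional: bool = True

    def __post_init__(self):
        if not 0 < self.alpha_conditional < 1:
            raise ValueError(
                f"alpha_conditional must be in (0,1), got {self.alpha_conditional}"
            )
        if not self.foreground:
            raise EmptyComponentError("foreground gene set is empty")
        extra = self.foreground - self.universe
        if extra:
            raise ValueError(
                f"foreground must be a subset of the universe; "
                f"{len(extra)} genes outside (e.g. {sorted(extra)[:3]})"
            )


@dataclass
class EnrichmentResult:
    """Outcome of one term's conditional hypergeometric test.

    k/K are foreground/universe counts on the term after conditioning; n/N are
    the fixed foreground/universe sizes. ``conditioned_children`` lists the
    significant direct children whose genes were removed before testing.
    """

    term_id: str
    p_value: float
    k: int
    K: int
    n: int
    N: int
    conditioned_children: set[str] = field(default_factory=set)
    p_adjusted: float | None = None


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed via the log-gamma based survival function, stable for large
    counts. ``k=0`` gives exactly 1.
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible margins: K={K}, n={n}, N={N}")
    if k < 0 or k > K or k > n:
        raise ValueError(f"impossible table: k={k} with K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def conditional_go_enrichment(
    config: EnrichmentConfig, dag: GoDag, ann: AnnotationSet
) -> list[EnrichmentResult]:
    """Run the bottom-up conditional test over every testable term.

    Terms are visited children-before-parents in a deterministic order. For
    each term, the universe genes annotated to it (propagated) form its gene
    list; genes annotated to any direct child already significant at
    ``alpha_conditional`` are removed from that list (recomputing K and k)
    before the tail probability is evaluated. Foreground size n and universe
    size N never change. With ``conditional=False`` every term is tested on
    its full gene list.

    Foreground or universe genes without any annotation are dropped with a
    logged count before sizes are fixed.
    """
    annotated = ann.genes()
    universe = config.universe & annotated
    n_dropped = len(config.universe) - len(universe)
    if n_dropped:
        logger.info(
            "conditional_go_enrichment: dropped %d unannotated universe genes", n_dropped
        )
    foreground = config.foreground & universe
    if not foreground:
        raise EmptyComponentError("no annotated foreground genes remain")
    N = len(universe)
    n = len(foreground)

    term_genes: dict[str, set[str]] = {}
    for term in dag.terms:
        genes = ann.term_to_genes.get(term, set()) & universe
        if genes:
            term_genes[term] = genes

    results: list[EnrichmentResult] = []
    p_by_term: dict[str, float] = {}
    for term in dag.bottom_up_order():
        if term not in term_genes:
            continue
        genes = term_genes[term]
        conditioned: set[str] = set()
        if config.conditional:
            for child in sorted(dag.children(term)):
                if p_by_term.get(child, 1.0) < config.alpha_conditional:
                    conditioned.add(child)
            if conditioned:
                removed = set()
                for child in conditioned:
                    removed |= term_genes.get(child, set())
                genes = genes - removed
        K = len(genes)
        k = len(genes & foreground)
        p = hypergeom_upper_tail(k, K, n, N)
        p_by_term[term] = p
        results.append(
            EnrichmentResult(
                term_id=term,
                p_value=p,
                k=k,
                K=K,
                n=n,
                N=N,
                conditioned_children=conditioned,
            )
        )
    return results


def run_component_enrichment(
    mode: str,
    partition: GenePartition,
    array_genes: set[str],
    xhyb_array_genes: set[str],
    dag: GoDag,
    ann: AnnotationSet,
    homolog_xhyb_de_genes: set[str] | None = None,
    alpha_conditional: float = 0.01,
    conditional: bool = True,
) -> list[EnrichmentResult]:
    """Dispatch one of the four component enrichments (modes a-d).

    ``array_genes`` is the full platform gene set, ``xhyb_array_genes`` the
    platform genes with cross-hybridizing probes. Mode d additionally needs the
    homolog-targeting deregulated subset; its universe is all Xhyb array genes
    because homolog status is unknowable array-wide without per-probe evidence,
    making d an estimated statistic.
    """
    if mode not in ENRICHMENT_MODES:
        raise ValueError(f"unknown enrichment mode {mode!r}; choose from {ENRICHMENT_MODES}")
    de_genes = (
        partition.xhyb_genes | partition.possible_xhyb_genes | partition.remaining_genes
    )
    if mode == "a":
        foreground, universe = de_genes, array_genes
    elif mode == "b":
        foreground, universe = partition.stromal_foreground(), xhyb_array_genes
    elif mode == "c":
        foreground = partition.cancer_foreground()
        universe = array_genes - xhyb_array_genes
    else:
        if homolog_xhyb_de_genes is None:
            raise ValueError("mode d requires homolog_xhyb_de_genes")
        foreground, universe = set(homolog_xhyb_de_genes), xhyb_array_genes
    if not foreground:
        raise EmptyComponentError(f"enrichment mode {mode!r}: component foreground is empty")
    config = EnrichmentConfig(
        foreground=foreground & universe,
        universe=universe,
        mode=mode,
        alpha_conditional=alpha_conditional,
        conditional=conditional,
    )
    return conditional_go_enrichment(config, dag, ann)


def benjamini_hochberg(results: Sequence[EnrichmentResult]) -> None:
    """Attach BH-adjusted p-values in place (optional; the default workflow
    uses unadjusted p-values)."""
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        adj = min(prev, results[idx].p_value * m / rank)
        results[idx].p_adjusted = adj
        prev = adj


def significant_terms(
    results: Iterable[EnrichmentResult],
    p_cutoff: float = 0.01,
    use_adjusted: bool = False,
) -> set[str]:
    """Terms with (unadjusted, by default) p strictly below the cutoff.

    A cutoff of 1.0 selects every tested term (p <= 1 by definition), so a
    threshold sweep ending at 1.0 tops out at the full tested set.
    """
    out = set()
    for r in results:
        p = r.p_adjusted if use_adjusted else r.p_value
        if p is None:
            raise ValueError("adjusted p-values requested but not computed")
        if p < p_cutoff or p_cutoff >= 1.0:
            out.add(r.term_id)
    return out
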