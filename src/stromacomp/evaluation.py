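"""Score identified GO term sets against gold-standard stromal term lists.

Three complementary views: exact-identity overlap significance (one-sided
Fisher's exact test on the 2x2 term table), DAG-ancestry overlap (how many
identified terms fall at or strictly below a gold-standard term), and proxy
precision-recall curves across enrichment p-value cutoffs.

The overlap test needs a term universe — the set of terms that could have been
identified at all. It is a mandatory, logged parameter: published overlap
p-values are irrecoverable without knowing the universe behind them, so this
package always reports the universe size alongside the p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .enrichment import EnrichmentResult, hypergeom_upper_tail, significant_terms
from .go_dag import GoDag

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """A reference list of stromal (or cancer) GO-BP terms.

    Typically compiled from published enrichment tables of laser-capture
    microdissection studies; entirely user-replaceable. ``prognosis_stratum``
    optionally records which outcome stratum the list came from.
    """

    name: str
    terms: set[str]
    prognosis_stratum: str | None = None

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"gold standard {self.name!r} has no terms")

    def resolve(self, dag: GoDag) -> tuple[set[str], set[str]]:
        """Split terms into (resolvable in dag, unresolvable). Unresolvable
        terms are reported, never silently dropped."""
        resolvable = {t for t in self.terms if t in dag}
        missing = self.terms - resolvable
        if missing:
            logger.warning(
                "gold standard %s: %d terms not in working DAG: %s",
                self.name, len(missing), sorted(missing)[:5],
            )
        return resolvable, missing


@dataclass
class OverlapReport:
    """Outcome of one identified-vs-gold overlap test."""

    n_identified: int
    n_gold: int
    n_overlap: int
    universe_size: int
    fisher_p: float
    strict_descendant_count: int | None = None
    inclusive_descendant_count: int | None = None
    excluded_terms: set[str] = field(default_factory=set)

    def summary(self) -> str:
        lines = [
            f"identified terms : {self.n_identified}",
            f"gold terms       : {self.n_gold}",
            f"exact overlap    : {self.n_overlap}",
            f"term universe    : {self.universe_size}",
            f"Fisher p (1-sided): {self.fisher_p:.3g}",
        ]
        if self.inclusive_descendant_count is not None:
            lines.append(f"at/below gold    : {self.inclusive_descendant_count}")
        if self.strict_descendant_count is not None:
            lines.append(f"strictly below gold: {self.strict_descendant_count}")
        if self.excluded_terms:
            lines.append(f"excluded (outside universe): {len(self.excluded_terms)}")
        return "\n".join(lines)


def fisher_overlap_test(
    identified: set[str], gold: set[str], universe: set[str]
) -> OverlapReport:
    """One-sided Fisher's exact test for identified/gold term overlap.

    The 2x2 table classifies universe terms by membership in the gold list and
    in the identified list; the p-value is the enrichment-direction
    (upper-tail) probability of an overlap at least as large. Terms outside
    the universe are excluded with a warning and reported.
    """
    if not universe:
        raise ValueError("term universe is empty")
    excluded = (identified - universe) | (gold - universe)
    if excluded:
        logger.warning(
            "fisher_overlap_test: excluding %d terms outside the universe", len(excluded)
        )
    ident = identified & universe
    gld = gold & universe
    overlap = ident & gld
    # One-sided exact test on the 2x2 table == hypergeometric upper tail
    # (draw the identified terms from the universe, count gold members).
    p = hypergeom_upper_tail(len(overlap), len(gld), len(ident), len(universe))
    return OverlapReport(
        n_identified=len(ident),
        n_gold=len(gld),
        n_overlap=len(overlap),
        universe_size=len(universe),
        fisher_p=p,
        excluded_terms=excluded,
    )


def ancestry_overlap(
    identified: set[str], gold: set[str], dag: GoDag
) -> tuple[int, int]:
    """Count identified terms falling under gold-standard terms.

    Returns ``(inclusive, strict)``: inclusive counts terms that are gold
    members or have a gold ancestor; strict counts only terms strictly below a
    gold term (exact members excluded). Terms unresolvable in the DAG are
    excluded with a warning.
    """
    resolvable = {t for t in identified if t in dag}
    if len(resolvable) < len(identified):
        logger.warning(
            "ancestry_overlap: %d identified terms not in DAG, excluded",
            len(identified) - len(resolvable),
        )
    gold_in = {t for t in gold if t in dag}
    inclusive = sum(
        dag.is_descendant_of_any(t, gold_in, strict=False) for t in resolvable
    )
    strict = sum(dag.is_descendant_of_any(t, gold_in, strict=True) for t in resolvable)
    return inclusive, strict


def annotate_report_with_ancestry(
    report: OverlapReport, identified: set[str], gold: set[str], dag: GoDag
) -> OverlapReport:
    """Fill the ancestry-count columns of an overlap report (kept separate from
    exact-identity overlap, never silently substituted for it)."""
    inclusive, strict = ancestry_overlap(identified, gold, dag)
    report.inclusive_descendant_count = inclusive
    report.strict_descendant_count = strict
    return report


def precision_recall_by_threshold(
    results: Sequence[EnrichmentResult],
    gold: GoldStandard,
    thresholds: Sequence[float],
    dag: GoDag | None = None,
    ancestry_mode: bool = False,
) -> pd.DataFrame:
    """Proxy precision-recall curve across enrichment p-value cutoffs.

    At each cutoff, the identified set is the terms with p below it; proxy
    precision is overlap/|identified| (NaN when nothing is identified, never
    zero) and proxy recall is overlap/|gold|. With ``ancestry_mode`` the
    overlap counts identified terms at or below a gold term instead of exact
    membership (requires ``dag``).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0,1]")
    if ancestry_mode and dag is None:
        raise ValueError("ancestry_mode requires a DAG")
    rows = []
    for cutoff in thresholds:
        identified = significant_terms(results, p_cutoff=cutoff)
        if ancestry_mode:
            overlap = sum(
                dag.is_descendant_of_any(t, gold.terms, strict=False)
                for t in identified
                if t in dag
            )
        else:
            overlap = len(identified & gold.terms)
        precision = overlap / len(identified) if identified else math.nan
        recall = overlap / len(gold.terms)
        rows.append(
            {
                "p_cutoff": cutoff,
                "n_identified": len(identified),
                "n_overlap": overlap,
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)
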