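"""Cross-species hybridizing (Xhyb) probe calling.

Human-array probes that also bind mouse transcripts report mouse (stromal)
expression in a xenograft. Two evidence streams identify them:

* **biological** — a dual-RNA experiment in which array channels are exposed
  to pure mouse RNA, pure human RNA, or both. A probe is called by expression
  if its mouse-exposure intensity clears a background cutoff and exceeds its
  human-exposure intensity by a log-scale margin ("highly expressed when
  exposed to mouse RNA but lower when exposed to human RNA").
* **computational** — sequence alignment of the probe against mouse
  transcripts (BLAST-style tabular hits).

The background cutoff comes from the BGS2.x family: the top *x* percent of the
cross-species-exposure intensity distribution. The operating point (x, margin)
is chosen by F-score against truth labels, mirroring the published BGS2.18
operating point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_LENGTH_NT = 60  # 60-mer oligo platform

EVIDENCE_MODES = ("intersection", "union", "expression_only", "alignment_only")


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe with its dual-RNA experiment intensities (log2)."""

    probe_id: str
    gene_id: str
    intensity_human: float
    intensity_mouse: float
    intensity_both: float | None = None

    def has_both_channels(self) -> bool:
        return math.isfinite(self.intensity_human) and math.isfinite(self.intensity_mouse)


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular (outfmt-6 style) probe-vs-mouse-transcript alignment hit."""

    probe_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0,100], got {self.percent_identity}"
            )
        if self.alignment_length < 0 or self.alignment_length > PROBE_LENGTH_NT:
            raise ValueError(
                f"alignment_length must be in [0,{PROBE_LENGTH_NT}] nt, "
                f"got {self.alignment_length}"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be nonnegative, got {self.evalue}")


@dataclass(frozen=True)
class HitFilter:
    """Acceptance rule for alignment hits supporting cross-hybridization.

    Defaults (>=50 of 60 nt aligned, >=90% identity) are package defaults for a
    60-mer platform, not values taken from any published probe-level rule.
    """

    min_alignment_length: int = 50
    min_percent_identity: float = 90.0

    def passes(self, hit: AlignmentHit) -> bool:
        return (
            hit.alignment_length >= self.min_alignment_length
            and hit.percent_identity >= self.min_percent_identity
        )


@dataclass(frozen=True)
class ThresholdModel:
    """BGS2.x operating point: background percentile and human-exposure margin.

    ``x`` is the "top x percent" parameter; ``mouse_cutoff`` is the intensity
    at the (100-x)th percentile of the cross-species-exposure background
    distribution; ``human_margin`` is the required mouse-minus-human intensity
    difference in log2 units.
    """

    x: float
    mouse_cutoff: float
    human_margin: float = 1.0

    def __post_init__(self):
        if not 0 < self.x <= 100:
            raise ValueError(f"percentile x must be in (0,100], got {self.x}")
        if self.human_margin < 0:
            raise ValueError(f"human_margin must be >= 0, got {self.human_margin}")


@dataclass
class XhybCall:
    """Per-probe cross-hybridization classification."""

    probe_id: str
    is_xhyb: bool
    has_alignment_support: bool
    passes_expression_rule: bool
    targets_homolog: bool | None = None  # None = unknown; only meaningful when is_xhyb
    background_percentile_used: float | None = None


class HomologyMap:
    """Symmetric one-to-one human <-> mouse gene homology lookup.

    One-to-many pairs are rejected with a warning by default; pass
    ``on_conflict='error'`` to raise instead.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], on_conflict: str = "warn"):
        if on_conflict not in {"warn", "error"}:
            raise ValueError(f"on_conflict must be 'warn' or 'error', got {on_conflict!r}")
        self.human_to_mouse: dict[str, str] = {}
        self.mouse_to_human: dict[str, str] = {}
        n_rejected = 0
        for human, mouse in pairs:
            if (
                self.human_to_mouse.get(human, mouse) != mouse
                or self.mouse_to_human.get(mouse, human) != human
            ):
                if on_conflict == "error":
                    raise ValueError(f"one-to-many homology pair ({human!r}, {mouse!r})")
                n_rejected += 1
                continue
            self.human_to_mouse[human] = mouse
            self.mouse_to_human[mouse] = human
        if n_rejected:
            logger.warning("HomologyMap: rejected %d one-to-many pairs", n_rejected)

    def mouse_homolog(self, human_gene: str) -> str | None:
        return self.human_to_mouse.get(human_gene)

    def human_homolog(self, mouse_gene: str) -> str | None:
        return self.mouse_to_human.get(mouse_gene)

    def __len__(self) -> int:
        return len(self.human_to_mouse)


def derive_background_cutoff(probes: Sequence[ProbeRecord], x: float) -> float:
    """Intensity cutoff for the BGS2.x rule.

    Returns the (100-x)th percentile (linear interpolation) of the
    cross-species-exposure intensity distribution, i.e. the boundary of the top
    x percent. A probe must reach this intensity under cross-species exposure
    to be called Xhyb.
    """
    if not 0 < x <= 100:
        raise ValueError(f"percentile x must be in (0,100], got {x}")
    values = np.asarray(
        [p.intensity_mouse for p in probes if math.isfinite(p.intensity_mouse)],
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("no probes with finite cross-species-exposure intensity")
    if values.size < 10:
        logger.warning(
            "derive_background_cutoff: only %d finite intensities; "
            "percentile estimate will be coarse", values.size
        )
    return float(np.percentile(values, 100.0 - x))


def call_xhyb_expression(
    probes: Sequence[ProbeRecord], model: ThresholdModel
) -> list[XhybCall]:
    """Apply the dual-RNA expression rule to every probe.

    A probe passes when its mouse-exposure intensity reaches the background
    cutoff AND exceeds its human-exposure intensity by the margin. Probes with
    a missing channel are skipped with a logged count.
    """
    calls: list[XhybCall] = []
    n_skipped = 0
    for probe in probes:
        if not probe.has_both_channels():
            n_skipped += 1
            continue
        passes = (
            probe.intensity_mouse >= model.mouse_cutoff
            and probe.intensity_mouse - probe.intensity_human >= model.human_margin
        )
        calls.append(
            XhybCall(
                probe_id=probe.probe_id,
                is_xhyb=passes,
                has_alignment_support=False,
                passes_expression_rule=passes,
                background_percentile_used=model.x,
            )
        )
    if n_skipped:
        logger.warning("call_xhyb_expression: skipped %d probes with missing channels", n_skipped)
    return calls


def combine_evidence(
    expr_calls: Sequence[XhybCall],
    hits: Sequence[AlignmentHit],
    mode: str = "intersection",
    hit_filter: HitFilter | None = None,
) -> list[XhybCall]:
    """Combine expression and alignment evidence into final Xhyb calls.

    ``mode`` is one of intersection (default, both evidence streams required),
    union, expression_only, alignment_only.
    """
    if mode not in EVIDENCE_MODES:
        raise ValueError(f"unknown evidence mode {mode!r}; choose from {EVIDENCE_MODES}")
    hit_filter = hit_filter or HitFilter()
    supported = {h.probe_id for h in hits if hit_filter.passes(h)}
    combined = []
    for call in expr_calls:
        has_aln = call.probe_id in supported
        expr = call.passes_expression_rule
        if mode == "intersection":
            is_xhyb = expr and has_aln
        elif mode == "union":
            is_xhyb = expr or has_aln
        elif mode == "expression_only":
            is_xhyb = expr
        else:
            is_xhyb = has_aln
        combined.append(replace(call, is_xhyb=is_xhyb, has_alignment_support=has_aln))
    return combined


def best_hit(hits: Sequence[AlignmentHit], homolog: str | None = None) -> AlignmentHit | None:
    """Highest-bitscore hit; bitscore ties favor the homolog, then subject id."""
    if not hits:
        return None
    return max(
        hits,
        key=lambda h: (h.bitscore, h.subject_id == homolog, h.subject_id),
    )


def classify_homolog_target(
    call: XhybCall,
    hits: Sequence[AlignmentHit],
    homology: HomologyMap,
    probe_gene_map: Mapping[str, str],
) -> bool | None:
    """Whether an Xhyb probe's best mouse hit is the homolog of its designed gene.

    Returns ``None`` (unknown) when the probe has no hits or its designed gene
    has no homolog-map entry — distinct from ``False`` (best hit is a
    non-homolog mouse gene).
    """
    if not call.is_xhyb:
        raise ValueError(f"probe {call.probe_id!r}: homolog status only defined for Xhyb calls")
    human_gene = probe_gene_map.get(call.probe_id)
    if human_gene is None:
        return None
    expected = homology.mouse_homolog(human_gene)
    if expected is None:
        return None
    probe_hits = [h for h in hits if h.probe_id == call.probe_id]
    top = best_hit(probe_hits, homolog=expected)
    if top is None:
        return None
    return top.subject_id == expected


def precision_recall_f(
    predicted: set[str], truth: set[str]
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a predicted positive set against truth."""
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def optimize_threshold(
    probes: Sequence[ProbeRecord],
    truth_labels: Mapping[str, bool] | Callable[[str], bool],
    x_grid: Sequence[float],
    margin_grid: Sequence[float],
) -> tuple[ThresholdModel, pd.DataFrame]:
    """Grid-search the BGS2.x operating point by F-score.

    ``truth_labels`` maps probe id -> is-truly-cross-hybridizing; any
    probe->label function works, so alignment evidence, a theoretical
    prediction model, or simulation ground truth can all drive the sweep.
    Returns the argmax-F model (ties: smaller x, then smaller margin) plus the
    full precision/recall/F sweep table.
    """
    if not x_grid or not margin_grid:
        raise ValueError("x_grid and margin_grid must be nonempty")
    label = truth_labels if callable(truth_labels) else truth_labels.__getitem__
    labelled = [p for p in probes if _has_label(label, p.probe_id)]
    truth = {p.probe_id for p in labelled if label(p.probe_id)}
    if not truth:
        raise ValueError("no positive truth labels; cannot optimize threshold")

    rows = []
    best: tuple[float, float, float] | None = None  # (-F, x, margin) minimized
    best_model: ThresholdModel | None = None
    for x in x_grid:
        cutoff = derive_background_cutoff(probes, x)
        for margin in margin_grid:
            model = ThresholdModel(x=x, mouse_cutoff=cutoff, human_margin=margin)
            calls = call_xhyb_expression(labelled, model)
            predicted = {c.probe_id for c in calls if c.passes_expression_rule}
            precision, recall, f = precision_recall_f(predicted, truth)
            rows.append(
                {
                    "x": x,
                    "margin": margin,
                    "cutoff": cutoff,
                    "n_called": len(predicted),
                    "precision": precision,
                    "recall": recall,
                    "f_score": f,
                }
            )
            key = (-f, x, margin)
            if best is None or key < best:
                best = key
                best_model = model
    table = pd.DataFrame(rows)
    assert best_model is not None
    return best_model, table


def _has_label(label: Callable[[str], bool], probe_id: str) -> bool:
    try:
        label(probe_id)
    except KeyError:
        return False
    return True
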