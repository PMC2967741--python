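"""Readers and writers for every interchange format.

All tables are tab-delimited UTF-8 with ``#`` comment headers; gene and term
identifiers are opaque strings matched exactly. Formats: expression TSV,
12-column tabular alignment hits (outfmt-6 layout), gene lists (one id per
line), gene->GO annotation TSV, OBO 1.2, Xhyb call TSV, partition TSV,
enrichment result TSV, gold-standard term lists, DOT, and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentResult
from .go_dag import GoDag
from .partition import GenePartition
from .evaluation import GoldStandard
from .xhyb import AlignmentHit, HomologyMap, ProbeRecord, XhybCall

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table is missing required columns or violates the declared format."""


EXPRESSION_COLUMNS = ["probe_id", "gene_id", "intensity_human", "intensity_mouse"]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- expression tables -------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ProbeRecord]:
    """Read a dual-RNA expression table (log2 intensities).

    Rows with a missing intensity are kept but flagged by a NaN channel, so
    the caller can skip them with a logged count; malformed rows raise.
    """
    df = _read_tsv(path)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_both = "intensity_both" in df.columns
    records = []
    for row in df.itertuples(index=False):
        both = getattr(row, "intensity_both", None) if has_both else None
        if both is not None and isinstance(both, float) and math.isnan(both):
            both = None
        records.append(
            ProbeRecord(
                probe_id=str(row.probe_id),
                gene_id=str(row.gene_id),
                intensity_human=float(row.intensity_human),
                intensity_mouse=float(row.intensity_mouse),
                intensity_both=both,
            )
        )
    n_flagged = sum(1 for r in records if not r.has_both_channels())
    if n_flagged:
        logger.warning("%s: %d records with a missing channel (excluded from calling)",
                       path, n_flagged)
    return records


def write_expression_table(path: str | Path, probes: Sequence[ProbeRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# dual-RNA hybridization intensities, log2 scale\n")
        fh.write("probe_id\tgene_id\tintensity_human\tintensity_mouse\tintensity_both\n")
        for p in probes:
            both = "" if p.intensity_both is None else f"{p.intensity_both:.6g}"
            fh.write(
                f"{p.probe_id}\t{p.gene_id}\t{p.intensity_human:.6g}"
                f"\t{p.intensity_mouse:.6g}\t{both}\n"
            )


# -- alignment hits ----------------------------------------------------------

def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column outfmt-6-style tabular hits; empty file -> empty list."""
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise SchemaError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        probe_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    if not hits:
        logger.warning("%s: no alignment hits read", path)
    return hits


def write_alignment_hits(path: str | Path, hits: Sequence[AlignmentHit]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            qend = h.alignment_length
            fh.write(
                f"{h.probe_id}\t{h.subject_id}\t{h.percent_identity}\t{h.alignment_length}"
                f"\t0\t0\t1\t{qend}\t1\t{qend}\t{h.evalue}\t{h.bitscore}\n"
            )


# -- gene lists, homology, annotations ---------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; '#' lines are comments."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(path: str | Path, genes: Iterable[str], header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_homology_map(path: str | Path) -> HomologyMap:
    """Two-column TSV (human_gene, mouse_gene)."""
    df = _read_tsv(path, header=None, names=["human_gene", "mouse_gene"], dtype=str)
    return HomologyMap((r.human_gene, r.mouse_gene) for r in df.itertuples(index=False))


def write_homology_map(path: str | Path, homology: HomologyMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for human, mouse in sorted(homology.human_to_mouse.items()):
            fh.write(f"{human}\t{mouse}\n")


def read_annotations(
    path: str | Path, evidence_exclude: set[str] | None = None
) -> dict[str, set[str]]:
    """Tab-delimited (gene_id, term_id, evidence_code) -> direct annotation map.

    ``evidence_exclude`` optionally drops rows by evidence code (e.g. {'IEA'}).
    """
    df = _read_tsv(path, header=None, names=["gene_id", "term_id", "evidence_code"],
                   dtype=str)
    direct: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if evidence_exclude and row.evidence_code in evidence_exclude:
            continue
        direct.setdefault(row.gene_id, set()).add(row.term_id)
    return direct


def write_annotations(
    path: str | Path, direct: Mapping[str, set[str]], evidence_code: str = "IEA"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\t{evidence_code}\n")


# -- OBO ----------------------------------------------------------------------

def write_obo(path: str | Path, dag: GoDag) -> None:
    """Write a GoDag as a minimal OBO 1.2 file (round-trips through parse_obo)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for parent in sorted(term.parents):
                rel = term.parents[parent]
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {dag.terms[parent].name}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {dag.terms[parent].name}\n")


# -- calls, partition, results -----------------------------------------------

_BOOL = {"True": True, "False": False, "unknown": None}


def write_xhyb_calls(path: str | Path, calls: Sequence[XhybCall]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tis_xhyb\thas_alignment_support\tpasses_expression_rule"
                 "\ttargets_homolog\tbackground_percentile_used\n")
        for c in calls:
            th = "unknown" if c.targets_homolog is None else str(c.targets_homolog)
            x = "" if c.background_percentile_used is None else f"{c.background_percentile_used:g}"
            fh.write(f"{c.probe_id}\t{c.is_xhyb}\t{c.has_alignment_support}"
                     f"\t{c.passes_expression_rule}\t{th}\t{x}\n")


def read_xhyb_calls(path: str | Path) -> list[XhybCall]:
    df = _read_tsv(path, dtype=str)
    required = {"probe_id", "is_xhyb", "has_alignment_support", "passes_expression_rule"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        x = getattr(row, "background_percentile_used", None)
        calls.append(
            XhybCall(
                probe_id=row.probe_id,
                is_xhyb=_BOOL[row.is_xhyb],
                has_alignment_support=_BOOL[row.has_alignment_support],
                passes_expression_rule=_BOOL[row.passes_expression_rule],
                targets_homolog=_BOOL.get(getattr(row, "targets_homolog", "unknown")),
                background_percentile_used=None if x in (None, "") or pd.isna(x) else float(x),
            )
        )
    return calls


def read_xhyb_probe_list(path: str | Path) -> set[str]:
    """Published-style Xhyb probe list: one probe id per line."""
    return set(read_gene_list(path))


def write_partition(path: str | Path, partition: GenePartition) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcomponent\tn_xhyb_probes/n_probes\n")
        for component, genes in (
            ("xhyb", partition.xhyb_genes),
            ("possible_xhyb", partition.possible_xhyb_genes),
            ("remaining", partition.remaining_genes),
            ("unmapped", partition.unmapped_genes),
        ):
            for gene in sorted(genes):
                n, nx = partition.per_gene_probe_detail.get(gene, (0, 0))
                fh.write(f"{gene}\t{component}\t{nx}/{n}\n")


def read_partition(path: str | Path) -> GenePartition:
    df = _read_tsv(path, dtype=str)
    part = GenePartition()
    buckets = {
        "xhyb": part.xhyb_genes,
        "possible_xhyb": part.possible_xhyb_genes,
        "remaining": part.remaining_genes,
        "unmapped": part.unmapped_genes,
    }
    detail_col = "n_xhyb_probes/n_probes"
    for _, row in df.iterrows():
        buckets[row["component"]].add(row["gene_id"])
        nx, n = row[detail_col].split("/")
        if int(n):
            part.per_gene_probe_detail[row["gene_id"]] = (int(n), int(nx))
    return part


def write_enrichment_results(
    path: str | Path, results: Sequence[EnrichmentResult], dag: GoDag, mode: str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mode\tterm_id\tterm_name\tk\tK\tn\tN\tp_value\tconditioned_children\n")
        for r in sorted(results, key=lambda r: (r.p_value, r.term_id)):
            name = dag.terms[r.term_id].name if r.term_id in dag else ""
            kids = ",".join(sorted(r.conditioned_children))
            fh.write(f"{mode}\t{r.term_id}\t{name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                     f"\t{r.p_value:.6g}\t{kids}\n")


def read_enrichment_results(path: str | Path) -> list[EnrichmentResult]:
    df = _read_tsv(path, dtype=str)
    results = []
    for row in df.itertuples(index=False):
        kids = set() if pd.isna(row.conditioned_children) or not row.conditioned_children \
            else set(row.conditioned_children.split(","))
        results.append(
            EnrichmentResult(
                term_id=row.term_id,
                p_value=float(row.p_value),
                k=int(row.k), K=int(row.K), n=int(row.n), N=int(row.N),
                conditioned_children=kids,
            )
        )
    return results


def read_gold_standard(path: str | Path, name: str | None = None) -> GoldStandard:
    """One term id per line; the first comment line may name the source."""
    terms = set()
    header = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                if header is None:
                    header = line.lstrip("# ").strip()
                continue
            if line:
                terms.add(line)
    return GoldStandard(name=name or header or str(path), terms=terms)


def write_gold_standard(path: str | Path, gold: GoldStandard) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {gold.name}\n")
        for term in sorted(gold.terms):
            fh.write(f"{term}\n")


# -- manifest -----------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path: str | Path, seed: int, params: Mapping,
                   inputs: Sequence[str | Path] = (), outputs: Sequence[str | Path] = ()) -> None:
    """JSON run manifest: seed, parameters, and checksums of inputs/outputs."""
    import stromacomp

    manifest = {
        "stromacomp_version": stromacomp.__version__,
        "seed": seed,
        "params": dict(params),
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
        "output_checksums": {str(p): file_checksum(p) for p in outputs},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
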