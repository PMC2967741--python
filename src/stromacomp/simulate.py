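"""Synthetic xenograft microarray data with known ground truth.

Everything downstream of the wet lab is testable against these generators:

* a **dual-RNA hybridization experiment** — per-probe log2 intensities under
  pure-human, pure-mouse and mixed RNA exposure, with planted cross-hybridizing
  (Xhyb) probes sitting a fixed separation above the cross-species background;
* **alignment evidence** — tabular probe-vs-mouse-transcript hits, with a
  controlled fraction of Xhyb probes hitting the true homolog of their designed
  gene, plus weak spurious hits on non-Xhyb probes;
* a **two-phenotype xenograft expression matrix** following the additive
  log-scale model y = mu_i + c_ij + eps: the phenotype effect of an Xhyb probe
  acts through its mouse (stromal) component only, so its log-fold-change
  estimates the planted stromal effect, while non-Xhyb probes respond through
  the human (cancer) component. Residual binding of an Xhyb probe to its
  designed human target enters through an explicit leakage coefficient rather
  than being assumed away, so the cost of folding that term into the error is
  measurable;
* a **toy GO-BP DAG** with planted stromal/cancer leaf terms whose annotations
  concentrate on the corresponding planted DE genes.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .go_dag import AnnotationSet, GoDag, GoTerm, propagate_annotations
from .xhyb import AlignmentHit, HomologyMap, ProbeRecord

# Intensity geometry (log2 scale). Non-Xhyb probes' mouse-exposure signal is
# pure background on (BG_LO, BG_HI); planted Xhyb probes sit at least
# `separation` above BG_HI, so the planted boundary is the top-frac_xhyb
# percentile of the mouse-exposure distribution.
BG_LO, BG_HI = 3.0, 5.0
MU_HS_LO, MU_HS_HI = 7.0, 12.0
XHYB_SPREAD = 2.0  # width of the Xhyb mouse-intensity band above the separation


@dataclass
class SimulationParams:
    """All knobs of the synthetic xenograft study.

    Defaults are the package's standard study conditions: a 10k-probe array
    with 5% cross-hybridizing probes separated 2 log2 units from background
    under 0.25-sd channel noise; 5 + 5 samples per phenotype; 20% of each
    component's genes differentially expressed; a two-level toy ontology with
    eight planted terms per component annotated at probability 0.5 over two
    uniform background annotations per gene.
    """

    n_probes: int = 10_000
    frac_xhyb: float = 0.05
    separation: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0
    # probe -> gene structure
    frac_multiprobe: float = 0.1  # genes carrying two probes instead of one
    # alignment evidence
    homolog_frac: float = 13 / 17  # Xhyb probes whose best hit is the true homolog
    spurious_hit_prob: float = 0.05
    # xenograft differential expression
    n_samples_per_group: int = 5
    frac_de_stromal: float = 0.2
    frac_de_cancer: float = 0.2
    effect_lo: float = 1.0
    effect_hi: float = 2.0
    leakage: float = 0.2  # residual human-target signal on an Xhyb probe
    plant_cancer_on_xhyb: bool = False
    # toy ontology
    n_branches: int = 8
    leaves_per_branch: int = 5
    n_planted_stromal: int = 8
    n_planted_cancer: int = 8
    annotation_prob: float = 0.5
    background_annotations_per_gene: int = 2

    def __post_init__(self):
        for name in ("frac_xhyb", "frac_multiprobe", "homolog_frac",
                     "spurious_hit_prob", "frac_de_stromal", "frac_de_cancer",
                     "annotation_prob", "leakage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.separation <= 0:
            raise ValueError(f"separation must be > 0, got {self.separation}")
        if self.n_probes < 2:
            raise ValueError("need at least 2 probes")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per phenotype")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _probe_gene_structure(params: SimulationParams, rng: np.random.Generator):
    """Assign probes to genes: most genes carry one probe, a fraction two.

    Returns (probe_ids, gene_of_probe). Xhyb status is decided per gene so a
    gene's probes agree unless mixed status is planted downstream.
    """
    n = params.n_probes
    probe_ids = [f"P{i:06d}" for i in range(n)]
    genes: list[str] = []
    gi = 0
    i = 0
    while i < n:
        gene = f"HG{gi:05d}"
        if params.frac_multiprobe > 0 and rng.random() < params.frac_multiprobe and i + 1 < n:
            genes += [gene, gene]
            i += 2
        else:
            genes.append(gene)
            i += 1
        gi += 1
    return probe_ids, genes


def simulate_dual_rna_experiment(
    params: SimulationParams,
) -> tuple[list[ProbeRecord], dict[str, bool]]:
    """Generate the two-channel cross-species hybridization experiment.

    Non-Xhyb probes: the human channel reads the designed target (mu_i on
    MU_HS_LO..MU_HS_HI), the mouse channel pure cross-species background
    (BG_LO..BG_HI). Xhyb probes: the mouse channel reads the mouse homolog at
    least ``separation`` above BG_HI, while the human channel sits at least
    ``separation`` below the mouse channel ("highly expressed when exposed to
    mouse RNA but lower when exposed to human RNA"). Independent Gaussian
    noise (sd ``noise_sd``) is added per channel. The mixed channel combines
    both RNA pools on the linear scale.

    Returns the probe records and per-probe truth labels.
    """
    rng = params.rng(stream=1)
    probe_ids, genes = _probe_gene_structure(params, rng)
    n = params.n_probes
    gene_ids = sorted(set(genes))
    n_xhyb_genes = int(round(params.frac_xhyb * len(gene_ids)))
    xhyb_genes = set(rng.choice(gene_ids, size=n_xhyb_genes, replace=False))

    records: list[ProbeRecord] = []
    truth: dict[str, bool] = {}
    for pid, gene in zip(probe_ids, genes):
        is_x = gene in xhyb_genes
        eps = rng.normal(0.0, params.noise_sd, size=3) if params.noise_sd > 0 else np.zeros(3)
        if is_x:
            mouse_base = BG_HI + params.separation + rng.uniform(0.0, XHYB_SPREAD)
            human_base = mouse_base - params.separation - rng.uniform(0.0, 2.0)
            mouse_src, human_src = mouse_base, human_base
        else:
            human_base = rng.uniform(MU_HS_LO, MU_HS_HI)
            mouse_base = rng.uniform(BG_LO, BG_HI)
            mouse_src, human_src = mouse_base, human_base
        both = float(np.log2(2.0 ** human_src + 2.0 ** mouse_src))
        records.append(
            ProbeRecord(
                probe_id=pid,
                gene_id=gene,
                intensity_human=float(human_base + eps[0]),
                intensity_mouse=float(mouse_base + eps[1]),
                intensity_both=float(both + eps[2]),
            )
        )
        truth[pid] = bool(is_x)
    return records, truth


def mouse_gene_of(human_gene: str) -> str:
    return "MG" + human_gene[2:]


def simulate_alignment_evidence(
    params: SimulationParams,
    probes: Sequence[ProbeRecord],
    truth: dict[str, bool],
) -> tuple[list[AlignmentHit], HomologyMap, dict[str, bool]]:
    """Generate tabular alignment hits and the homology map.

    Every planted Xhyb probe receives one strong mouse hit — against the true
    homolog of its designed gene with probability ``homolog_frac``, otherwise
    against a random other mouse gene. Non-Xhyb probes occasionally receive a
    short, low-identity spurious hit that fails the default hit filter.
    Returns the hits, the human<->mouse homology map over all designed genes,
    and per-probe homolog-targeting truth (Xhyb probes only).
    """
    rng = params.rng(stream=2)
    gene_ids = sorted({p.gene_id for p in probes})
    homology = HomologyMap((g, mouse_gene_of(g)) for g in gene_ids)
    hits: list[AlignmentHit] = []
    homolog_truth: dict[str, bool] = {}
    for probe in probes:
        if truth[probe.probe_id]:
            to_homolog = bool(rng.random() < params.homolog_frac)
            homolog_truth[probe.probe_id] = to_homolog
            if to_homolog:
                subject = mouse_gene_of(probe.gene_id)
            else:
                other = probe.gene_id
                while other == probe.gene_id:
                    other = gene_ids[int(rng.integers(len(gene_ids)))]
                subject = mouse_gene_of(other)
            length = int(rng.integers(52, 61))
            pident = float(rng.uniform(92.0, 100.0))
            bitscore = round(1.8 * length * pident / 100.0, 1)
            hits.append(
                AlignmentHit(
                    probe_id=probe.probe_id,
                    subject_id=subject,
                    percent_identity=round(pident, 2),
                    alignment_length=length,
                    evalue=1e-20,
                    bitscore=bitscore,
                )
            )
        elif rng.random() < params.spurious_hit_prob:
            other = gene_ids[int(rng.integers(len(gene_ids)))]
            length = int(rng.integers(18, 40))
            pident = float(rng.uniform(70.0, 85.0))
            hits.append(
                AlignmentHit(
                    probe_id=probe.probe_id,
                    subject_id=mouse_gene_of(other),
                    percent_identity=round(pident, 2),
                    alignment_length=length,
                    evalue=0.5,
                    bitscore=round(1.2 * length * pident / 100.0, 1),
                )
            )
    return hits, homology, homolog_truth


@dataclass
class XenograftDeTruth:
    """Ground truth of the two-phenotype expression simulation."""

    stromal_de_genes: set[str]
    cancer_de_genes: set[str]
    planted_effect: dict[str, float]  # probe -> planted logFC (a minus b)
    cancer_effect_on_xhyb: dict[str, float] = field(default_factory=dict)

    def de_genes(self) -> set[str]:
        return self.stromal_de_genes | self.cancer_de_genes


def simulate_xenograft_de(
    params: SimulationParams,
    probes: Sequence[ProbeRecord] | None = None,
    truth: dict[str, bool] | None = None,
) -> tuple[pd.DataFrame, XenograftDeTruth]:
    """Two-phenotype xenograft expression under the additive log-scale model.

    Per sample j of phenotype a or b, probe i measures
    ``y_ij = mu_i + c_ij + eps`` where for an Xhyb probe mu and c belong to the
    mouse (stromal) component — plus ``leakage`` times the human-target term —
    and for a non-Xhyb probe they belong to the human (cancer) component. A
    fraction of each component's genes receives a planted phenotype effect
    (uniform magnitude on effect_lo..effect_hi, random sign, applied to
    phenotype a), so the probe's expected log-fold-change a-vs-b equals the
    planted effect. With ``plant_cancer_on_xhyb``, some Xhyb probes also carry
    a human-component effect, which reaches the signal only through the
    leakage term; those probes are flagged in the truth output.
    """
    if probes is None or truth is None:
        probes, truth = simulate_dual_rna_experiment(params)
    rng = params.rng(stream=3)
    ns = params.n_samples_per_group
    columns = [f"a{j + 1}" for j in range(ns)] + [f"b{j + 1}" for j in range(ns)]

    xhyb_genes = sorted({p.gene_id for p in probes if truth[p.probe_id]})
    nonx_genes = sorted({p.gene_id for p in probes if not truth[p.probe_id]})
    n_str = int(round(params.frac_de_stromal * len(xhyb_genes)))
    n_can = int(round(params.frac_de_cancer * len(nonx_genes)))
    stromal_de = set(rng.choice(xhyb_genes, size=n_str, replace=False)) if n_str else set()
    cancer_de = set(rng.choice(nonx_genes, size=n_can, replace=False)) if n_can else set()

    def draw_effect() -> float:
        mag = rng.uniform(params.effect_lo, params.effect_hi)
        return float(mag if rng.random() < 0.5 else -mag)

    gene_effect: dict[str, float] = {g: draw_effect() for g in sorted(stromal_de)}
    gene_effect.update({g: draw_effect() for g in sorted(cancer_de)})

    planted: dict[str, float] = {}
    cancer_on_xhyb: dict[str, float] = {}
    data = np.empty((len(probes), 2 * ns))
    for row, probe in enumerate(probes):
        is_x = truth[probe.probe_id]
        effect = gene_effect.get(probe.gene_id, 0.0)
        if is_x:
            mu = probe.intensity_mouse  # stromal baseline of the Xhyb probe
            mu_leak = params.leakage * rng.uniform(MU_HS_LO, MU_HS_HI)
            c_hs = 0.0
            if params.plant_cancer_on_xhyb and rng.random() < params.frac_de_cancer:
                c_hs = draw_effect()
                cancer_on_xhyb[probe.probe_id] = c_hs
            base = mu + mu_leak
            delta_a = effect + params.leakage * c_hs
        else:
            base = probe.intensity_human  # designed-target baseline
            delta_a = effect
        planted[probe.probe_id] = effect
        means = np.full(2 * ns, base)
        means[:ns] += delta_a
        noise = rng.normal(0.0, params.noise_sd, size=2 * ns) if params.noise_sd > 0 else 0.0
        data[row] = means + noise

    matrix = pd.DataFrame(data, index=[p.probe_id for p in probes], columns=columns)
    return matrix, XenograftDeTruth(
        stromal_de_genes=stromal_de,
        cancer_de_genes=cancer_de,
        planted_effect=planted,
        cancer_effect_on_xhyb=cancer_on_xhyb,
    )


def log_fold_change(matrix: pd.DataFrame) -> pd.Series:
    """Per-probe mean(a-samples) minus mean(b-samples)."""
    a_cols = [c for c in matrix.columns if c.startswith("a")]
    b_cols = [c for c in matrix.columns if c.startswith("b")]
    return matrix[a_cols].mean(axis=1) - matrix[b_cols].mean(axis=1)


# ---------------------------------------------------------------------------
# Toy ontology with planted enrichment
# ---------------------------------------------------------------------------

def _toy_dag(params: SimulationParams) -> GoDag:
    """Root -> branch -> leaf ontology with deterministic synthetic term ids."""
    terms = [GoTerm("GO:0900000", "synthetic biological process root",
                    "biological_process", {})]
    for b in range(params.n_branches):
        branch_id = f"GO:0901{b:02d}0"
        terms.append(
            GoTerm(branch_id, f"synthetic process family {b}",
                   "biological_process", {"GO:0900000": "is_a"})
        )
        for l in range(params.leaves_per_branch):
            terms.append(
                GoTerm(f"GO:0902{b:02d}{l}", f"synthetic process {b}.{l}",
                       "biological_process", {branch_id: "is_a"})
            )
    return GoDag(terms)


def simulate_go_with_planted_enrichment(
    params: SimulationParams,
    stromal_de_genes: set[str],
    cancer_de_genes: set[str],
    all_genes: set[str],
) -> tuple[GoDag, AnnotationSet, dict[str, set[str]]]:
    """Toy GO-BP DAG plus annotations with planted component enrichment.

    Every gene receives ``background_annotations_per_gene`` uniform leaf
    annotations. Each planted stromal leaf term additionally annotates each
    stromal DE gene with probability ``annotation_prob``; likewise planted
    cancer terms and cancer DE genes. Returns the DAG, the propagated
    annotation set, and the planted truth
    ``{"stromal": terms, "cancer": terms}``.
    """
    rng = params.rng(stream=4)
    dag = _toy_dag(params)
    leaves = sorted(dag.leaves())
    n_planted = params.n_planted_stromal + params.n_planted_cancer
    if n_planted > len(leaves):
        raise ValueError("more planted terms than leaves in the toy DAG")
    chosen = rng.choice(leaves, size=n_planted, replace=False)
    stromal_terms = set(chosen[: params.n_planted_stromal])
    cancer_terms = set(chosen[params.n_planted_stromal:])

    direct: dict[str, set[str]] = {g: set() for g in sorted(all_genes)}
    for gene in sorted(all_genes):
        picks = rng.choice(leaves, size=params.background_annotations_per_gene, replace=False)
        direct[gene].update(picks)
    for term in sorted(stromal_terms):
        for gene in sorted(stromal_de_genes):
            if rng.random() < params.annotation_prob:
                direct[gene].add(term)
    for term in sorted(cancer_terms):
        for gene in sorted(cancer_de_genes):
            if rng.random() < params.annotation_prob:
                direct[gene].add(term)

    ann = propagate_annotations(dag, direct)
    planted = {"stromal": stromal_terms, "cancer": cancer_terms}
    return dag, ann, planted


# ---------------------------------------------------------------------------
# Random DAGs/annotations for property tests
# ---------------------------------------------------------------------------

def random_dag(rng: np.random.Generator, n_terms: int = 30, max_parents: int = 2) -> GoDag:
    """Random rooted DAG: each non-root term picks 1..max_parents earlier terms."""
    terms = [GoTerm("T000", "root", "biological_process", {})]
    ids = ["T000"]
    for i in range(1, n_terms):
        tid = f"T{i:03d}"
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, len(ids))
        parents = rng.choice(ids, size=k, replace=False)
        terms.append(GoTerm(tid, f"term {i}", "biological_process",
                            {p: "is_a" for p in parents}))
        ids.append(tid)
    return GoDag(terms)


def random_annotations(
    rng: np.random.Generator, dag: GoDag, n_genes: int = 40, terms_per_gene: int = 2
) -> dict[str, set[str]]:
    """Uniform random direct annotations over a DAG's terms."""
    ids = sorted(dag.terms)
    return {
        f"g{i:03d}": set(rng.choice(ids, size=min(terms_per_gene, len(ids)), replace=False))
        for i in range(n_genes)
    }


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass
class ComponentStudy:
    """Everything one synthetic end-to-end run produces."""

    params: SimulationParams
    probes: list[ProbeRecord]
    xhyb_truth: dict[str, bool]
    hits: list[AlignmentHit]
    homology: HomologyMap
    homolog_truth: dict[str, bool]
    expression: pd.DataFrame
    de_truth: XenograftDeTruth
    dag: GoDag
    annotations: AnnotationSet
    planted_terms: dict[str, set[str]]

    @property
    def probe_gene_map(self) -> dict[str, str]:
        return {p.probe_id: p.gene_id for p in self.probes}

    @property
    def array_genes(self) -> set[str]:
        return {p.gene_id for p in self.probes}

    @property
    def true_xhyb_array_genes(self) -> set[str]:
        return {p.gene_id for p in self.probes if self.xhyb_truth[p.probe_id]}


def medium_signal_preset(seed: int = 11) -> SimulationParams:
    """Standard end-to-end study conditions: 2,000 probes, 30% Xhyb genes so
    both components have enough deregulated genes to drive enrichment."""
    return SimulationParams(
        n_probes=2_000,
        frac_xhyb=0.30,
        seed=seed,
        frac_de_stromal=0.3,
        frac_de_cancer=0.3,
    )


def simulate_component_study(params: SimulationParams) -> ComponentStudy:
    """Chain all generators into one coherent synthetic study."""
    probes, truth = simulate_dual_rna_experiment(params)
    hits, homology, homolog_truth = simulate_alignment_evidence(params, probes, truth)
    expression, de_truth = simulate_xenograft_de(params, probes, truth)
    all_genes = {p.gene_id for p in probes}
    dag, ann, planted = simulate_go_with_planted_enrichment(
        params, de_truth.stromal_de_genes, de_truth.cancer_de_genes, all_genes
    )
    return ComponentStudy(
        params=params,
        probes=probes,
        xhyb_truth=truth,
        hits=hits,
        homology=homology,
        homolog_truth=homolog_truth,
        expression=expression,
        de_truth=de_truth,
        dag=dag,
        annotations=ann,
        planted_terms=planted,
    )
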