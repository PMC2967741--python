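# Methods

## The measurement model

A human oligo array hybridized to xenograft RNA measures, for probe *i* in
sample *j* of clinical phenotype group *g*, a log2 intensity modeled
additively as

    y_ij = mu_i + c_ig + eps_ij

where `mu_i` is the probe's overall mean, `c_ig` the phenotype main effect
and `eps` stochastic error. For a probe reading its designed human target,
`mu` and `c` belong to the cancer-cell (human, Hs) component. For a
cross-hybridizing (Xhyb) probe the dominant signal is the homologous mouse
transcript, so `mu` and `c` belong to the stromal (mouse, Mm) component and
the residual human-target contribution `leakage * (mu_i^Hs + c_ig^Hs)` is
folded into the error term. Under this model the log-fold-change of an Xhyb
probe between two phenotypes estimates the *stromal* effect difference
`c_a^Mm - c_b^Mm`; for a non-Xhyb probe it estimates the cancer effect. Array
and array-interaction effects are omitted (single-batch design assumption).

The approximation of folding the human term into the error is not assumed
away in the simulator: the leakage coefficient (default 0.2) is explicit, so
one can plant a human-component effect on an Xhyb probe and measure that the
observed log-fold-change is attenuated to `leakage * effect` rather than
vanishing.

## Xhyb calling

Two evidence streams, combined per probe:

* **Expression rule.** From the dual-RNA experiment, a probe passes when
  `intensity_mouse >= cutoff(x)` and
  `intensity_mouse - intensity_human >= margin`. The cutoff is the
  (100−x)th percentile — linear interpolation, the numpy default; the
  convention only matters at ties — of the cross-species-exposure intensity
  distribution (the BGS2.x family, "top x percent"). The margin formalizes
  "lower when exposed to human RNA" as an additive log2 difference; no
  numeric rule is published, so the default of 1.0 log2 unit is a package
  choice, exposed as a parameter.
* **Alignment rule.** A probe has alignment support when at least one
  tabular hit passes the filter (defaults for a 60-mer platform: aligned
  length ≥ 50 nt, identity ≥ 90%; both configurable, stated as package
  defaults rather than a published acceptance rule).

The published method combines "a computational and a biological method"
without stating the set operation; the default here is **intersection**
(conservative: both streams required), with union and single-evidence modes
available. `optimize_threshold` grid-searches (x, margin) by F-score against
any probe→truth-label mapping — alignment evidence, simulation ground truth,
or an external theoretical prediction model can all drive it. Ties go to the
smaller x, then the smaller margin. Decreasing x tightens the cutoff, so call
sets are nested along the grid (asserted by tests).

An Xhyb probe *targets its homolog* when its best-bitscore mouse hit equals
the homology-map partner of its designed human gene; bitscore ties favor the
homolog, then the lexicographically larger subject id (deterministic). No
hits, or no homology entry, yields *unknown*, which is distinct from *false*.

## Partition and the four enrichment backgrounds

Deregulated genes split by the Xhyb status of their platform probes: all
probes Xhyb → `xhyb`; some → `possible_xhyb`; none → `remaining`; genes
without scored probes are reported as `unmapped`, never dropped. The phrase
"only one cross-mouse hybridizing probe" is read as "all of the gene's probes
are Xhyb" (the readings coincide on the single-probe genes that dominate this
platform); the literal single-probe reading is available via
`strict_single_probe`. Ambiguous (`possible_xhyb`) genes join the stromal
foreground for modes b/d but are excluded from the cancer foreground for
mode c by default; both directions are configurable.

The homolog-targeting subset (mode d's foreground) requires every Xhyb probe
of a gene to have homolog status resolved *true*; unknown status excludes the
gene. Mode d's universe is all Xhyb array genes, since homolog targeting is
unknowable array-wide without per-probe experimental evidence — d is an
estimated statistic by construction.

## The conditional hypergeometric test

For term t with K universe genes annotated (after upward propagation over
`is_a` and `part_of`; other relations ignored, configurable), foreground size
n, universe size N and k annotated foreground genes, the score is the
upper-tail probability P(X ≥ k), X ~ Hypergeom(N, K, n), computed via the
log-gamma-based survival function (exact to ~1e-15 against rational
enumeration on small tables; the test suite asserts 1e-12 over all tables
with N ≤ 30).

Conditioning visits terms children-before-parents, ordered by height (longest
path to a leaf) with lexicographic tie-break so runs are reproducible. When a
term is tested, the propagated gene sets of its *direct* children already
significant at `alpha_conditional` (default 0.01) are removed from its gene
list; K and k are recomputed, n and N stay fixed. Only direct children are
consulted because their own conditioning already absorbed deeper structure.
Removing genes from K and k (rather than shrinking n and N) keeps the test's
margins comparable across terms. `alpha_conditional` is constrained to (0, 1);
as it approaches 0 no child can be significant and conditional results equal
unconditional ones term-for-term (asserted on random draws at 1e-300).

P-values are reported unadjusted by default — the evaluation convention is an
unadjusted p < 1% cutoff — with optional Benjamini–Hochberg adjustment.
`significant_terms` uses strict `p < cutoff`, except that a cutoff of 1.0
selects every tested term so threshold sweeps top out at the tested set.
Terms with no annotated universe gene are skipped, not reported at p = 1.

## Evaluation against gold standards

Exact-identity overlap between an identified term set and a gold-standard
list is scored by the one-sided Fisher's exact test on the 2×2 table over a
**term universe** — here defaulting to all terms with at least one annotated
platform gene. The universe is a mandatory, logged parameter: an overlap
p-value is meaningless without it, and published overlap p-values cannot be
reproduced when the universe behind them is unstated. The test shares the
hypergeometric kernel above (asserted).

Ancestry overlap is reported separately, never silently substituted for exact
overlap: the *inclusive* count (term is a gold member or below one) serves
overlap-style statements, the *strict* count (below a gold term and not a
member) serves "child node" statements. Proxy precision–recall curves across
p cutoffs report precision as missing (NaN), not zero, when nothing is
identified.

Gold-standard term lists are plain one-term-per-line files supplied by the
user; the synthetic workflow writes its planted stromal/cancer term lists in
the same format and evaluates against them.

## The synthetic-data generator

What it emulates: the two-channel cross-species hybridization experiment
(non-Xhyb probes read background, 3–5 log2 units, in the mouse channel and
their designed target, 7–12, in the human channel; Xhyb probes read the mouse
transcript at least `separation` (default 2.0 log2 units) above background
and that much above their human channel; the mixed channel combines both
pools on the linear scale); BLAST-style hit tables in which 13/17 of Xhyb
probes hit their true homolog (the published homolog-targeting proportion
used as the default rate); the additive two-phenotype expression model above
with effects of magnitude 1–2 log2 units, random sign, on 20% of each
component's genes, 5+5 samples; and a 49-term, two-level toy GO DAG (root, 8
families, 5 leaves each) with 8 planted stromal and 8 planted cancer leaf
terms annotated on the corresponding planted DE genes at probability 0.5 over
2 uniform background annotations per gene. Noise terms are independent
Gaussians on the log2 scale (the model makes only standard stochastic
assumptions; the distribution is a package choice). All magnitudes are
order-of-magnitude choices for this platform class, fixed once and documented
here; none are fitted to data.

What it does **not** emulate — and hence what passing tests do not show about
real arrays: correlated probe effects and spatial artifacts, intensity-
dependent (heteroscedastic) noise, partial cross-hybridization with
intermediate affinities, many-to-many homology, the true GO DAG's depth and
annotation sparsity, and platform-scale probe counts. The end-to-end
separation result demonstrates correctness of the machinery under the stated
model, not field performance.

Standard problem sizes: 10,000 probes for caller calibration, 500 genes for
log-fold-change recovery, and a 2,000-probe / 30%-Xhyb "medium-signal" preset
for end-to-end runs — small enough for interactive use while leaving
component separation overdetermined.

## Degenerate inputs and error behavior

Empty foregrounds raise a component-empty error naming the mode; foreground
genes outside the universe are an error, unannotated genes are dropped with a
logged count; annotations to unknown terms drop-with-warning by default or
raise; one-to-many homology pairs are rejected with a warning; cycles in the
ontology are a structural error; malformed OBO lines and short hit-table rows
raise errors naming the line. Probes with a missing channel are excluded from
calling with a logged count. With zero noise the simulator is exact up to
floating-point addition (~1e-15), which is why "exact" recovery is asserted
at 1e-9 rather than equality.

## Known limitations

Only the biological-process namespace is analyzed. Gene identifiers are
opaque strings; mixed symbol/accession lists need a caller-supplied alias
table. The conditional test conditions on direct children only, so a gene
reachable through a significant *grand*child but annotated directly to the
parent is removed only if the intermediate child is itself significant.
Published platform-scale figures (thousands of Xhyb probes per array design)
depend on the original hybridization data and era-specific databases and are
out of scope; the package reproduces the methodology, not those counts.
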