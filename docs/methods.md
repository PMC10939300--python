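# Methods

This note documents the statistical procedures implemented in `eabench`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Differential expression

Microarray-style matrices are quantile normalized: every column receives
the per-rank mean of the column-sorted values, and ties within a column get
the mean of the reference values over their rank span. RNA-seq inputs are
accepted as log2 CPM and not re-normalized.

The per-gene statistic is an empirical-Bayes moderated two-sample t-test.
With gene-wise pooled variance s² on d = n₁+n₂−2 residual df, the
moderated variance is s̃² = (d₀·s₀² + d·s²)/(d₀ + d) and p-values come from
a t distribution on d₀ + d df. The prior (d₀, s₀²) is fitted by the
method of moments on log sample variances: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2)
determines d₀ through the inverse trigamma (Newton iteration), and s₀²
follows from the mean of e. When the observed spread does not exceed the
sampling spread, d₀ = ∞ (all genes share s₀², normal-tail p-values). A
constant prior is used for both platforms; no mean–variance trend is
fitted — a deliberate simplification that matters little for the balanced
3-vs-3 Gaussian designs the generator produces, but would understate
variance moderation for real RNA-seq counts.

DEG selection takes genes at BH-FDR q < 0.1; if fewer than 15 qualify it
retries at q < 0.2; below 15 the dataset fails QC (a typed signal, not an
exception). More than 500 qualifying genes are capped to the 500 smallest
p (ties: larger |t|, then gene-id). QC also requires at least three
samples per condition. Both thresholds, the floor and the cap are
arguments.

## Disease pathway network

Pairwise statistics. For pathways A, B on a functional network:
DL(A,B) is the number of edges with one endpoint in each set (an edge
inside A∩B counts once), SN(A,B) the number of outside genes adjacent to
both sets, IPC = DL + SN, and J(A,B) the Jaccard index of the gene sets.

Degree-aware null. The sampling universe (by default the collection's
genes; configurable) is sorted by network degree — genes absent from the
network have degree 0 — and cut into contiguous bins of 100 genes
(`bin_size`). A replacement for B substitutes each gene by a uniform draw
from its bin without duplicates; bins are widened to their neighbours only
when exhausted. Replacement sets may intersect A. The one-sided empirical
p-value over n = 1000 draws (default) is (r+1)/(n+1) with ties counted in
r, so p never reaches 0 and Fisher's method stays finite. Both directions
(resample B, resample A) are tested; the two p-values are combined as
X = −2(ln p₁ + ln p₂) against a χ²₄ upper tail. BH adjustment runs per
statistic family (connectivity; overlap) across all pairs; a joint family
is available via `joint_fdr=True`.

Because the connectivity and overlap tests use the same subsampling
scheme, both statistics are evaluated on the *same* null draws within a
direction; this halves runtime and leaves each test's marginal null
distribution unchanged. Per-pair, per-direction child seeds are derived
from the master seed and the lexicographically oriented pair ids, so
results do not depend on iteration order.

Assembly. Edges require q_conn < α and q_olap < α (α = 0.05). Accepted
edges are weighted by semantic similarity, and each designated target
keeps its k = 20 highest-weight neighbours (ties: smaller q_conn, then
pathway-id). Ranking by similarity rather than by significance was an open
choice; similarity is what the edge weight represents, so it governs the
pruning.

A note on the estimator's conservatism: with a discrete statistic
(integer link or overlap counts), the (r+1)/(n+1) estimator with ties
included is conservative — P(p < α) falls short of α by roughly half the
probability mass of the atom at the α-quantile. At desk scale (universes
of 1000–2000 genes) this deficit is visible: a perfectly calibrated
permutation method shows a pooled null rejection fraction of ~4% rather
than 5% at α = 0.05, more so for small DEG sets. This is a property of
empirical permutation p-values, not a miscalibration, and it vanishes as
counts grow.

## Semantic similarity (Wang method)

A term's S-value table assigns S = 1 to the term itself and, walking
toward the root, S(parent) = max over children of w·S(child) with
relation weights w(is_a) = 0.8 and w(part_of) = 0.6 (both configurable).
Term similarity is the shared S-mass over the total S-mass of the two
tables. Genes are compared by best-match averaging (BMA) over their
annotated terms, and gene sets by BMA over their annotated genes
(unannotated genes are skipped). Pathway-pair weights for the DPN use the
terms annotated to each pathway's genes, BMA-aggregated; an explicit
pathway→terms table can override this mapping, and a precomputed
pathway×pathway matrix can replace the provider entirely.

## Enrichment methods

* **Fisher**: one-sided hypergeometric tail on the DEG/pathway overlap.
* **EASE**: the same tail with the overlap reduced by one (floored at 0),
  always at least as conservative as Fisher.
* **crosstalk (hypergeometric)**: observed DL(DEGs, pathway) against a
  hypergeometric null on edge endpoints (population 2m, successes = total
  pathway degree, draws = total DEG degree). When the expectation exceeds
  the observation the depleted flag is set; depletion is not scored as
  enrichment — the reported significance is 1 − p.
* **crosstalk (binomial)**: the same statistic against Bin(D_degs,
  D_path/2m). This null assumes pathway edges are spread like the network
  average; community-like pathways violate that, which is exactly the bias
  the diagnostics quantify.
* **permutation reference**: DEG/pathway overlap against n uniform random
  DEG-label draws, empirical (r+1)/(n+1) p. Calibrated by construction;
  used as the yardstick in the null benchmarks.

The default test universe is the intersection of the dataset's genes with
the collection's universe ("dataset"); "collection" and "network" are
alternatives. Untested entries (QC failure, method error, missing
external result) always carry p = 1 and a false tested-flag. External
methods plug in as pathway×dataset p-value matrices.

## Benchmark

Positives for a dataset are its target pathway plus the target's DPN
neighbour list (≤ 21 pathways). TP/FN count positives with p < 0.05
(strict) on the real datasets. The negative benchmark rescores
gene-label-randomized copies of the datasets — labels drawn uniformly
without replacement from the genome pool, values and design untouched, so
DEG counts are preserved while DEG identities are random — 30 repeats per
dataset by default. TN/FP are counted on each null dataset restricted to
its source dataset's positive list, making the negative benchmark exactly
as large as the positive one per repeat (an alternative reading, rescaling
the full-panel FPR, sits behind `mode="rescale"`). Summaries: TPR, TNR,
G-mean = √(TPR·TNR), and the median tie-averaged relative rank
(rank−1)/N over all positives (the (rank−1)/(N−1) variant is an option).

Null diagnostics: per-pathway FPR (fraction of null tests with p < 0.05);
a skew profile classifying a method's null p-value distribution from the
mass in [0, 0.1] and [0.9, 1] (both > 0.15 → bimodal; one high →
right-/left-skewed; otherwise uniform — the band thresholds are
diagnostic conventions, not fitted quantities); and cross-dataset
consistency of significant pathway sets per disease group (median Jaccard
and Szymkiewicz–Simpson overlap coefficient; a pair with an empty
significant set scores 0 on both).

## Network-property diagnostics

Hubs are the ⌈0.2·n⌉ highest-degree nodes (ties at the boundary broken by
gene-id). Per pathway: size; connected components of the induced
subgraph; mean clustering coefficient of pathway members in the full
network; median and max member degree (absent genes count 0); intralink
fraction (internal edges over all edges incident to the pathway, internal
edges counted once in both numerator and denominator); link density
(internal edges over n(n−1)/2); hub fraction (pathway hubs over network
hubs) and hub density (pathway hubs over pathway size). Each property is
correlated with per-pathway FPR by tie-corrected Spearman rank
correlation; constant properties are reported as missing.

## Synthetic data

The generator emulates the study conditions end to end. Networks are
configuration-model draws on a heavy-tailed degree sequence (zipf exponent
2.5 rescaled to mean degree 10, 2000 genes by default); self-loops and
parallel edges from stub matching are discarded, so realized degrees sit
slightly below nominal. Pathway collections (20 pathways of 15–80 genes)
include planted related pairs: 50% of the smaller set's genes shared plus
150 extra cross-links wired between the exclusive parts. The cross-link
count is deliberately large relative to a pathway's own degree budget —
planted "related" pairs must be related strongly enough that the
degree-aware test has power, which is the point of planting ground truth;
weaker planting (e.g. a few dozen links on small pathways in a
heavy-tailed network) is statistically indistinguishable from background
for any number of null draws. An `intralink_boost` option densifies
pathways internally to create the community structure the bias
diagnostics look for.

Expression data are Gaussian on the log scale: 3 case and 3 control
samples, unit noise, a 2σ mean shift (random sign) on 80% of the target
pathway's genes and 1% of the background. This reproduces the *selection
regime* of real case/control datasets (DEG counts between the QC floor
and the cap) but none of their correlation structure, batch effects, or
count noise — so passing benchmarks here demonstrate the framework's
bookkeeping and calibration, not the field performance of any method.
Toy ontology DAGs are layered random graphs under a single root with
random is_a/part_of labels and 1–3 annotations for 90% of genes.

All generators are deterministic given the spec seed; per-dataset streams
are salted with a CRC of the dataset id so replicates decorrelate
reproducibly.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
desk scale: pairwise DPN statistics use 150–400 null draws (the default
1000 is for real analyses; the planted-pair recovery checks already pass
at 400), null batteries use 20–50 datasets × 20–100 pathways with 2000
permutations per test, and the EASE null battery uses the full 7248-gene
universe with 100 pathways × 1500 randomized datasets. These sizes were
chosen so each check completes in seconds to a few minutes while keeping
the Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The moderated-t prior is constant (no mean–variance trend); real
  RNA-seq data would benefit from the trend fit.
* Probe-to-gene mapping, batch-effect handling and dataset curation are
  out of scope; inputs are assumed pre-mapped and curated (QC exposes
  sample/DEG floors only).
* Empirical permutation p-values are conservative on discrete statistics
  (see above); at small universes the null rejection fraction of even a
  perfectly calibrated method sits visibly below the nominal level.
* The synthetic expression model is exchangeable Gaussian noise; methods
  whose strengths lie in exploiting gene–gene correlation or count
  overdispersion are not differentiated by it.
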