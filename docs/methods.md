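# Methods

This note documents the statistical procedures implemented in `coexpair`, the
generative model behind its synthetic cohorts, the numerical conventions that
make runs reproducible, and the known limits of what the test suite
demonstrates.

## Differential expression

**Abundance filter.** Only genes with mean FPKM strictly greater than 1
across *all* samples (tumor and normal pooled) enter the analysis. Low-FPKM
genes are quantified unreliably and would otherwise dominate the fold-change
tail through pseudocount artifacts. The boundary is strict: a gene at exactly
1.0 is removed.

**Test.** Each gene is tested on log2(FPKM + 1) with the two-factor blocked
ANOVA (condition + subject). With two conditions the condition F statistic is
exactly the squared paired-*t* statistic, so the implementation computes the
vectorized paired *t* over within-pair differences and converts through
F(1, n−1). Testing on the log scale matters: FPKM is approximately
log-normal, and an ANOVA on the raw scale would be badly heteroskedastic.
The +1 pseudocount keeps zeros finite at the cost of compressing signal in
genes below ~1 FPKM — which the abundance filter has already removed from the
tested set. An unpaired one-way ANOVA is available (`paired=False`) for
sensitivity analysis; it is never the default because the design is matched.

**Degenerate genes.** A gene whose within-pair differences have zero variance
(e.g. tumor equals normal everywhere) gets p = 1 with a logged flag rather
than an exception, so the pipeline is total over degenerate inputs. This is
deliberately conservative: such genes carry no usable evidence either way.

**Multiple testing.** Benjamini–Hochberg step-up,
q_(i) = min_{j ≥ i} (p_(j) · m / j) capped at 1, delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` and verified in
the tests against an independent implementation of the literal definition.

**Fold change and call.** Fold changes are reported on the linear FPKM scale
as (mean_T + ε)/(mean_N + ε) with ε = 10⁻³ — the scale on which results are
conventionally quoted — while significance comes from the log-scale test. A
per-pair geometric-mean variant is available (`method="per_pair_geometric"`);
ratio-of-means is the default because it is the natural descriptive ratio of
condition abundances. The call applies both criteria: up requires
fold > 2 (strict) and q ≤ 0.05 (inclusive); down the reciprocal. The up and
down sets are disjoint by construction, and swapping the condition labels
exactly swaps them.

## Structure exploration

HCA and PCA operate on per-gene standardized (z-scored) log2(FPKM + 1) over a
caller-chosen gene panel (typically the called DEGs). Standardization makes
both invariant to per-gene affine rescaling of the working-scale values.

**Linkage.** Euclidean distance with **Ward linkage** is the default; average
and complete linkage remain configurable. The k = 2 cut is fixed because it
is read as a tumor/normal dichotomy. Ward was chosen after observing that
average linkage occasionally spends the two-group cut isolating a single
extreme sample pair (a subject with unusually strong co-regulated program
activity) rather than splitting tumor from normal — a 156-vs-2 cut is a
correct average-linkage answer to the wrong question. Variance-minimizing
merges produce the balanced dichotomy the cut is defined to report.

**Labels and ties.** Cluster labels are deterministic given input order (the
first sample's cluster is labelled 1); a cluster's majority condition breaks
exact ties toward its first-encountered sample's condition. A cut that fails
to produce two non-empty clusters (all samples identical) is flagged
degenerate, and the discordance report returns empty lists rather than
fabricated discordance.

**Discordance report.** Every sample whose condition disagrees with its
cluster's majority is listed with a stage-class annotation; a discordant
normal is annotated with its *adjacent tumor's* stage class (its subject's
tumor row), since normal tissue has no stage of its own.

**PCA.** Genes are centered (scaling optional), components come from SVD, and
each component's sign is fixed by making its largest-magnitude loading
positive so scores are stable across runs and platforms. `group_dispersion`
reduces the heterogeneity comparison to a number: the mean Euclidean distance
of each condition's samples to their own centroid in score space.

## Enrichment

One-sided hypergeometric over-representation: for a query of n genes drawn
from a universe of N, a set with K members in the universe and k in the
query gets p = P[X ≥ k], X ~ Hypergeom(N, K, n), BH-corrected across all
tested sets, enriched iff q < 0.05 (strict). The universe is the
abundance-filtered gene list — the genes that were actually eligible to be
called — not the whole genome; using the genome as background would
manufacture enrichment from the abundance filter itself. Gene sets arrive as
flat GMT collections and are intersected with the universe before testing;
depletion is deliberately not tested. No ontology traversal or term-ancestry
propagation is performed.

## Co-expression network

Pearson correlation of log2(FPKM + 1) across the declared sample set — all
samples by default. Pooling tumor and normal is intentional: the strong
co/anti-correlations among DEGs are largely driven by the tumor–normal
contrast, which pooling preserves; tumors-only and normals-only modes exist
for sensitivity analysis. Constant genes are dropped with a logged list.

Edges connect pairs with |cc| strictly above the threshold (default 0.8) and
carry the signed correlation and a pos/neg class. Genes with no strong
partner are excluded from the node set. Hub genes are the top-k by degree per
direction with a documented tie-break (degree desc, |log2 FC| desc, gene id
asc). The hub neighborhood is the induced subgraph on hubs plus their direct
neighbors.

**Module correlation.** The paper-style module-level statement ("process A
correlates with process B at cc > 0.8") needs a module-level series; the
package uses the eigengene — the first principal component of the module's
standardized log2 values, sign-aligned with the module's mean profile — and
classifies each module pair positive/negative/none by eigengene correlation
against the same 0.8 threshold. The mean pairwise gene–gene correlation is
co-reported so the choice is auditable: eigengene correlations run higher
than mean pairwise correlations because the PC averages away gene-level
noise. Module definitions are an *input* (GMT or simulation truth), not an
inference; no WGCNA-style soft thresholding or topological overlap is
attempted.

## Synthetic cohort generator

The generator is the stand-in for a matched tumor/normal cohort whose real
data are not public. On the log2 scale, expression of gene g in sample s of
subject i is

    x_gs = b_g + u_gi + δ_g·[s is tumor] + λ·f_{m(g),s} + a_g·v_{h(g),i} + ε_gs

* **Baselines** b_g: a fraction `frac_low_abundance` (default 0.35) of genes
  is drawn from a low range (log2 FPKM in [−6, −1.5]) and stays below the
  FPKM 1 cutoff; the rest are uniform in [0, 8].
* **Subject effects** u_gi ~ N(0, subject_sd²), default SD 1.0, independent
  across genes, shared by the two samples of a pair — this is what makes the
  paired design real (within-pair correlation of gene-centered profiles
  exceeds between-pair correlation whenever subject_sd > 0).
* **Condition effects**: 10% of genes by default (always from the abundant
  stratum — an effect planted below the detection cutoff would be
  unrecoverable by design) receive log2 fold changes drawn log-uniformly from
  [2, 250], the observed span of strong deregulation in colorectal
  tumor/normal comparisons, half up and half down.
* **Modules**: per-sample latent factors f ~ N(0, R) with a signed
  inter-module correlation matrix R (default for five modules:
  0.1·I + 0.9·s·sᵀ with s = (+,+,−,−,−), i.e. two positively coupled
  "up-type" modules anti-correlated with three "down-type" modules). Members
  are abundant non-DE genes and load with λ = 0.9.
* **Hub programs**: subject-level factors v_hi (program activity varies
  between patients and is shared within a pair) with the hub gene loading at
  5.0 and each of its partners at 2.5. Subject-level (rather than per-sample)
  program activity keeps the paired test and the ratio-of-means fold estimate
  clean — the heavy log-normal weights cancel between the matched samples.
  Program genes are kept well expressed (baselines log2 in [8, 12]) so the +1
  pseudocount does not truncate the program signal, and carry strong fold
  changes (partners log-uniform in [4, 6], the hub itself in [32, 64], inside
  the observed deregulation envelope). These values were chosen from the
  population variance decomposition so that hub–partner correlations sit
  clearly above the 0.8 threshold, partner–partner correlations sit near it,
  and degree ties at program saturation resolve toward the hub through its
  larger fold change. One hub per direction is the default: the top-k-per-
  direction ranking is a per-direction resource, and two saturated
  same-direction programs would crowd it by construction.
* **Noise** ε ~ N(0, noise_sd²), default SD 0.5 in log2 units, with optional
  per-condition multipliers (used to emulate tumors being more or less
  heterogeneous than normals).
* **Metadata**: 79 pairs by default with a 2:1 high:low stage split (high
  stage = TNM 3–4) and a 17/36/26 well/moderate/poor grade mix.
  `tumor_like_normals` lists subjects whose *normal* sample additionally
  receives the condition effect — planting the histologically normal,
  molecularly tumor-like samples that discordance reports are meant to catch.

FPKM = 2^x. One global seed drives deterministic per-stage substreams
(`numpy.random.SeedSequence.spawn`), so identical configs give bit-identical
cohorts and partial re-runs are reproducible.

**What the generator does not emulate.** Count-level sampling noise,
library-size or GC artifacts, isoform structure, batch effects, and the
long-tailed empirical FPKM distribution of real tissue. Gene-level effects
are independent log-normals apart from the planted structure. Passing tests
therefore demonstrate that the *methods* behave correctly under a faithful
paired log-normal model with planted structure — not that any particular
biological conclusion from real data is reproduced.

## Numerical conventions

* Working scale everywhere: log2(FPKM + 1); linear fold changes with
  ε = 10⁻³.
* Boundary conventions mirror the quoted criteria literally: abundance
  strict (> 1), fold strict (> 2), DE FDR inclusive (≤ 0.05), network
  threshold strict (|cc| > 0.8), enrichment FDR strict (< 0.05).
* Volcano coordinates floor p = 0 at the smallest positive normal float
  before taking −log10.
* Correlation matrices are symmetrized, clipped to [−1, 1], unit diagonal.
* Pipeline outputs are written with fixed 6-significant/6-decimal float
  formatting and the manifest stores no timestamps or absolute paths, so a
  fixed seed yields byte-identical runs; the manifest records the config
  snapshot, input checksums, per-stage gene counts (the filtering funnel) and
  a SHA-256 per output file.
* Test problem sizes: the heavy properties run at the design point of 79
  pairs with 2,000–10,000 genes and 20–50 seeds — large enough for the
  Monte-Carlo statements being asserted while keeping a full suite run in
  well under a minute of compute per module.

## Known limitations

* "ANOVA" here is exactly the paired t-test; covariates beyond the subject
  blocking (age, location, batch) are out of scope.
* The network is a fixed-threshold relevance network: no partial
  correlations, no soft thresholding, no edge significance testing. Edge
  counts are strongly driven by the tumor–normal contrast when correlations
  are computed over pooled samples.
* Enrichment assumes exchangeable genes within the universe; correlated
  genes (e.g. co-regulated modules) inflate hypergeometric significance, as
  they do in all standard over-representation tools.
* The k = 2 cut forces a dichotomy; finer subgroup structure below the cut
  is reported only through the dendrogram export.
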