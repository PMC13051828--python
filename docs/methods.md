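# Methods

## The inference problem

A ceRNA ("sponge") network posits that an abundant driver lncRNA buffers a
pool of miRNAs, indirectly de-repressing the miRNAs' mRNA targets.  The
observable signature is a coupled response to driver perturbation: putative
targets fall when the driver is silenced and rise when it is activated,
and in patient cohorts they co-express positively with the driver.
`cernanet` operationalises this as a deterministic selection cascade over
measured inputs (DE tables, interaction databases, an expression matrix)
followed by statistical screens in cohorts and enrichment-based
cross-condition validation.  The package performs no DE estimation, read
alignment, or database retrieval: it consumes DE result tables
(gene, log2FC, p, FDR), interaction pair tables, expression matrices,
survival tables and GMT collections, all as plain TSV/GMT.

## Selection cascade

Candidate targets are genes present in both contrasts with
`kd_fdr < α ∧ kd_log2fc < 0 ∧ ovx_fdr < α ∧ ovx_log2fc > 0`, all strict,
with α = 0.05 by default.  Strictness follows the thresholds as printed
("FDR < 0.05", "log2 > 4", "at least 10 samples"); boundary rows are
excluded deterministically.  Genes measured in only one contrast are
dropped rather than imputed; fully disjoint gene namespaces raise, since
that almost always indicates an identifier-convention mismatch.  Gene ids
are treated as exact strings (Ensembl stable ids in the shipped fixtures,
miRBase mature names for miRNAs) after whitespace trimming.

The miRNA layer keeps miRNAs with ≥ 1 supported interaction to a candidate,
intersects them with the driver-binding list, and then applies the
expression filter: log2 intensity strictly greater than 4 in at least 10
samples of the profiling matrix.  miRNAs absent from the matrix fail the
filter with a logged warning (array platforms never cover the full miRNA
namespace).

The assembled network materialises one driver edge per retained miRNA in
addition to the miRNA–target edges.  Published renderings of such networks
often hide the driver hub for readability; edge counts are therefore
reported both split (`n_mt_edges`, `n_driver_edges`) and combined, so
either convention is reproducible.  At the published scale the bookkeeping
is 137 nodes = 1 driver + 96 miRNAs + 40 targets and 1152 edges = 1056
miRNA–target + 96 driver–miRNA; the 1056/96 split is this package's
interpretation (one driver edge per retained miRNA), recorded as a
configurable quantity in the synthetic preset.  Nodes left without any
miRNA–target edge cannot participate in sponging and are dropped (logged).
Pathway subnetwork extraction restricts targets to a gene set and keeps
miRNAs with ≥ 1 surviving edge; it is idempotent.

## Cohort statistics

All tests are two-sided; direction is recorded separately rather than
folded into one-sided p-values.

* **Spearman screen** — rho on midranks, p from the t-approximation
  `t = rho·sqrt((n−2)/(1−rho²))` on n−2 df (scipy), pairwise-complete
  observations, n ≥ 4 required, constant vectors raise.  rho = ±1 returns
  p at the numerical floor rather than 0.  A target is flagged
  `significant_positive` when rho > 0 and p < α; with two-sided p this
  gives an expected null false-positive rate of α/2, which the tests
  verify.  No multiplicity adjustment is applied to the 40-gene screens,
  matching how such target tables are conventionally reported; the
  threshold is a parameter.
* **Rank-sum / Kruskal–Wallis / Dunn** — Wilcoxon rank-sum via the normal
  approximation with midranks and tie-corrected variance and *no*
  continuity correction, so that for two groups the Kruskal–Wallis
  chi-square (1 df) equals the squared Wilcoxon z exactly (verified to
  1e-9).  Dunn's pairwise z uses the pooled-rank variance
  `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)` with optional
  Benjamini–Hochberg adjustment.
* **Survival screen** — patients are stratified at the median expression
  per gene with the tie rule `value ≤ median → low` (deterministic; the
  convention of common survival packages).  OS and PFS are compared by the
  standard two-group log-rank test (lifelines; hypergeometric variance
  summed over distinct event times).  Direction (`high_worse`) is read
  from the Kaplan–Meier survival estimates at end of follow-up.  Per-gene
  failures (constant expression, zero events) become missing rows with a
  note, not screen-level errors.  No Cox model is fitted; the screens are
  marginal by design.

## Enrichment

* **ORA** — one-sided hypergeometric tail `P(X ≥ overlap)` with population
  = background universe (the union of measured genes), successes = set ∩
  background, draws = query; BH-adjusted across sets.  EnrichR-style
  combined scores are deliberately not reproduced: downstream logic uses
  set membership, not score ranking.
* **GSEA** — the weighted Kolmogorov–Smirnov running sum: hits add
  `|score|^w` normalised by the in-set total, misses subtract
  `1/(N − N_hit)`; ES is the signed maximum deviation.  Weight defaults to
  1 (classic weighted statistic); weight 0 is retained because the
  unweighted statistic has a clean brute-force oracle, used by the tests.
  Since the running sum is piecewise linear between hits, its extremes are
  evaluated only at the 2·N_hit positions adjacent to hits (O(k) per
  permutation instead of O(N)); equality with the position-by-position
  oracle is asserted to 1e-12.  If the maximum positive and negative
  deviations tie exactly, the positive sign is reported.
  Ranking ties are broken lexicographically by gene id for
  reproducibility.
* **Nulls and normalisation** — pre-ranked mode draws `n_perm` random
  same-size gene sets (null draws are cached per set size); sample mode
  permutes group labels and recomputes the per-gene log2 fold change of
  group means, preserving inter-gene correlation, and requires ≥ 7
  samples per group.  NES divides ES by the mean |null ES| of matching
  sign; the nominal p is the +1-corrected same-sign tail (never exactly
  zero); FDR q follows the sign-split pooled-NES procedure.  Defaults
  follow the published analysis: set-size bounds 15–500 applied after
  intersecting with the ranked universe, 1000 permutations.
* **Validation matrix** — a cell passes iff |NES| ≥ 1.5 (inclusive) and
  FDR < 0.05 (exclusive), exactly as the criterion is printed.  Expected
  NES signs are supplied per condition (−1 for driver knock-down, +1 for
  overexpression or the high-driver quartile contrast); a row is
  sign-consistent when every passing cell matches.  The high/low-driver
  condition on cohort data is realised as extreme quartiles of driver
  expression (ties to the lower quartile), exposed as a parameter.

## Synthetic data generator

The generator's role is to make every downstream stage testable with known
truth, not to imitate platform noise.

* **DE tables** — disjoint gene blocks are planted per contrast: the
  candidate block (down-KD ∩ up-OVX), KD-only and OVX-only significant
  blocks, remainder null.  Planted FDRs are uniform on (0, α), null FDRs
  uniform on [α, 1], log2FC magnitudes |N(0,1)| + 0.25 with the planted
  sign; downstream logic reads only sign and threshold, so richer effect
  models would add nothing testable.
* **Interaction database** — the counted miRNA–target edge set is built on
  the (expressed miRNAs × candidates) grid: a covering assignment first
  (so every selected node has ≥ 1 edge), then uniformly drawn extra pairs
  up to the configured edge count; infeasible counts raise before any
  output.  The "expressed" subset is the lexicographically first
  `n_expressed` members of the intersection — a deterministic rule shared
  with the expression generator so the two agree without shared state.
  Decoy pairs to non-candidate genes are added for realism and never touch
  counted quantities.
* **miRNA expression** — passing miRNAs get ≥ 12 samples forced above the
  threshold; failing ones get at most 9, with all remaining values below
  4.  Group labels default to the 4 N + 113 MM + 30 PCL layout of the
  profiled cohort.
* **Cohorts** — the driver is a latent standard normal Z; each planted
  co-expressed gene is `ρ'·Z + sqrt(1−ρ'²)·ε` with `ρ' = 2·sin(π·ρ_S/6)`,
  the Gaussian-copula relation making the *population Spearman* correlation
  equal the configured value.  Survival times are exponential with the
  hazard multiplied by the configured hazard ratio once per planted
  prognostic gene the patient is above the median of; censoring is
  administrative at a horizon chosen to censor ~30% under the null
  (median OS 60 months, PFS 30 months).  Defaults (cohort_n = 753,
  rho = 0.4, HR = 2.5) mirror the cohort sizes and effect magnitudes of
  the study being emulated.
* **Enrichment inputs** — genes of designated sets get a mean shift in
  group B; the ranked list is the per-gene log2 fold change B vs A.

Every generator draws from `default_rng([seed, stream-id])` with a fixed
stream id per generator — pure functions of the config, no global state;
two identical calls produce byte-identical output files.

What the generator does **not** emulate: count noise and library-size
effects, probe-level artefacts, batch structure, correlated null genes,
informative censoring, and realistic miRNA–target degree distributions.
Passing tests therefore demonstrate the correctness of the selection
logic, the exactness of the planted recovery, and the calibration/power of
the statistical screens under clean sampling models — not robustness to
real-data artefacts.

## Numerical and design notes

* Planted-count recovery is exact for any seed; the acceptance script's
  reported values are computed by re-running the cascade on the written
  input files, and are seed-invariant by construction.
* Problem sizes used by the test-suite simulations: cohorts of 200–774
  patients for correlation calibration, 750 for survival power (matching
  the emulated cohort), 500-replicate nulls for rank-test calibration,
  GSEA nulls pooled over ≥ 500 (seed, set) pairs so KS sampling noise sits
  well below the 0.1 bound, and 100–1000 permutations per GSEA run.
* Deterministic ordering everywhere: candidate sets, node and edge lists,
  and GSEA set iteration are sorted lexicographically, so outputs are
  byte-reproducible across reruns.
* Degenerate inputs raise early with specific messages: infeasible planted
  configs, constant vectors in rank statistics, empty median-split strata,
  zero observed events, gene sets covering the whole ranked list.

## Known limitations

* The Spearman p-value uses the t-approximation throughout; it is accurate
  for the cohort sizes involved (n ≥ 20) but approximate below that.
* GSEA FDR q-values are the conventional pooled-permutation estimates and
  can be conservative for small collections.
* The survival screen is marginal per gene; correlated planted genes
  inherit each other's survival association by construction, as in real
  co-expressed gene sets — counts of "prognostic" genes in a synthetic run
  can therefore exceed the planted count.
* Identifier matching is exact-string; no alias or version mapping is
  attempted.
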