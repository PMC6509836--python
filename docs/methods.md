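# Methods

This note documents the models and procedures implemented in
`celltag-demux`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## Problem setting

Pooled samples are labeled before mixing by lentiviral transduction with
predefined 8-nt CellTag Index barcodes, expressed as polyadenylated
transcripts and captured alongside the transcriptome in droplet scRNA-seq.
Demultiplexing must decide, per cell, which single index dominates
(singlet), whether two or more indexes show significant signal (multiplet —
two cells in one droplet), or whether no index is convincingly present
(non-determined — typically insufficient viral dosage). Tag UMI counts are
small (medians in the single digits to tens), contaminated by ambient
molecules, and distorted by sequencing errors in the barcode itself, which
is why the pipeline has distinct extraction, error-collapse and
classification stages.

## Extraction and counting

Reads are scanned for `flank5 + [ACGT]{tag_length} + flank3` with exact
flank matching; the first left-to-right occurrence is used and reads whose
tag window contains `N` are discarded. The flanks are construct-specific
and required inputs — there is no default, because extracting with a wrong
motif silently yields an empty matrix. No reverse-complement search is
performed; orientation is the upstream caller's responsibility.

Counting deduplicates exact `(cell, umi, tag)` triples. UMI error
correction is deliberately omitted: per-tag counts are small, the
classifier depends on tag composition rather than absolute depth, and a ±1
UMI perturbation does not move the proportion scores appreciably. Error
tolerance belongs to the collapse stage, which acts on the variable region
where errors change barcode identity.

## Sphere-clustering collapse

Tag sequences are sorted by total count (descending, lexicographic
tie-break — deterministic and seed-free) and scanned once. A sequence
becomes a new centroid unless it lies within `max_dist` of an existing
centroid, in which case it is absorbed by the earliest-declared (most
abundant) such centroid. Only centroids absorb: there is no transitive
chaining through absorbed sequences, so centroids form a maximal
independent set at distance > `max_dist`. Matrix columns sharing a centroid
are summed, conserving per-cell totals exactly.

Distance is Levenshtein by default (via edlib's banded alignment), with
Hamming as a cheaper option for fixed-length tags. `max_dist` defaults to 1
for 8-nt tags: a length-scaled radius of 2 would risk merging distinct
predefined indexes that differ at only two positions, and several of the
standard index sequences are that close. Collapse operates on the pooled
tag set, matching the pipeline order (one matrix per lane, collapsed before
classification). No performance engineering beyond the O(n·k) greedy scan
is attempted; tag inventories at this stage are thousands, not millions.

## Dynamic binarization classifier

**Normalization.** `C_ij = ln(1 + s · x_ij / Σ_j x_ij)` over the selected
index tags, `s = 10` by default. Per-cell proportion scaling makes `C`
invariant to sequencing depth, and `s = 10` keeps values in a range where
kernel density estimation is well-behaved; the scale is configurable. Cells
with zero counts across the selected tags get all-zero rows and are flagged
non-determined up front.

**Density and sampling.** For each tag, a Gaussian KDE with Scott's
bandwidth `h = sd · n^(-1/5)` is fitted on the normalized column across all
cells, zeros included. Sampling draws a kernel center uniformly from the
data and adds `N(0, h²)` noise; negative draws are clamped to 0 since
normalized expression is non-negative. A zero-variance column degenerates
to a point mass (draws reproduce the single value; the survival function
becomes a step). Fitting on all cells rather than nonzero cells is a
deliberate choice: the zero/low mass is what separates background from
signal, and removing it would push moderate expression values into the
upper tail of a signal-only density, misclassifying true doublets as
non-determined.

**Proportions.** Per iteration, `n_samples = 1000` draws `S` are taken per
tag and `P_ij = |{s ∈ S : s ≥ C_ij}|/|S|`; the final matrix averages
`n_iter = 50` independent iterations. The sampled `P` converges to the
closed-form survival function of the clamped kernel mixture,
`P*_ij = mean_k Φ̄((C_ij − c_k)/h)` for `C_ij > 0` and 1 otherwise; the test
suite verifies entrywise agreement within ±0.02 at the default sampling
effort. `P` is monotonically non-increasing in `C` by construction.

**Classification.** With `m = min_j P_ij`: zero-flagged cells and cells
with `m ≥ nd_threshold` are non-determined; otherwise
`T = {j : P_ij − m ≤ δ}` yields a singlet (|T| = 1) or a multiplet
(|T| ≥ 2, including exact ties for the minimum — a tie is evidence for two
signals, not for either one alone). The baseline cutoff `δ = 0.238` is the
value learned in the original benchmarking of this procedure against
orthogonal species-alignment calls; re-learning it is out of scope and it
is exposed as a parameter. `nd_threshold` defaults to `1 − δ = 0.762`, a
symmetric reuse of the learned cutoff: a cell whose *best* tag still sits
in the weakest three quarters of the population has no convincing signal.

**Multiplet checkpoint.** The expected multiplet percentage follows the
droplet-loading calibration `0.0007589 · n + 0.0527214` (percent, `n` =
cells recovered). With `E = round(expected · n / 100)` and `M` called
multiplets, the checkpoint triggers when `M > 1.5·E`: multiplet calls are
ranked by the gap between their two smallest proportions (ascending, ties
by cell id — smallest gap = most multiplet-like), the first `1.5·E` are
retained, i.e. the `(1.5·E)/M` quantile of the ranking, and the rest are
reassigned to their minimum tag as singlets. The 1.5 factor makes the
retained fraction `≤ 1` exactly when the checkpoint triggers. `E` rounds to
the nearest integer; `E = 0` demotes every multiplet.

All stochastic stages consume a single seeded generator; identical seeds
give byte-identical outputs.

## Cluster-occupancy test

For one tag of interest, with `n` tagged and `s` untagged cells (after
removing excluded clusters), each of `n_draws` rounds samples `n` cells
without replacement from the pooled `n + s` and records per-cluster
occupancy counts. Tail p-values use +1 smoothing,
`p_enrich = (1 + #{draws ≥ observed})/(1 + n_draws)` and symmetrically for
depletion, so finite resampling never reports 0; both tails count equality,
hence `p_enrich + p_deplete ≥ 1`. Draw-versus-observed comparisons are on
integer counts, avoiding floating-point tie ambiguity. For a single
cluster, the draw distribution is exactly hypergeometric, which the test
suite uses as an enumeration oracle on small instances.

`n_draws` defaults to 10,000 — enough to resolve p ≈ 10⁻⁴; a warning is
emitted when `1/(1 + n_draws)` cannot resolve the requested alpha. Cluster
exclusion is a first-class parameter (e.g. removing a cluster composed of
the tagged population itself, which would dominate the null). One tag per
invocation; several tags iterate the test. No multiple-testing correction
is applied across clusters; callers comparing many clusters or tags should
apply their own.

## Synthetic data

The generator emulates the tag-count structure of a pooled indexing
experiment:

- **singlets** draw own-tag UMIs from a negative binomial (mean
  `mu_signal = 20`, size `dispersion = 2`) truncated to ≥ 1 — overdispersed
  counts are typical of lentiviral expression, and truncation encodes
  "transduced means at least one tag transcript";
- **ambient background**: every cell draws Poisson(`lambda_bg = 0.2`)
  counts per off-target tag;
- **doublets** (`doublet_rate = 0.05`) sum two independent singlet profiles
  with distinct tags; same-tag doublets are invisible to any tag-based
  caller and are not generated, so multiplet recall is measured on the
  detectable kind only;
- **untagged cells** (`untagged_rate = 0.10`) carry ambient counts only,
  modeling cells that escaped transduction (the ~90% transduction
  efficiency seen with GFP readout);
- the **read layer** wraps each UMI as `flank5 + tag + flank3` in random
  context, with per-base substitution errors (`error_rate = 0.01`) confined
  to the tag region so that read-level tests isolate collapse behavior from
  flank-matching losses. `reads_per_umi` defaults to 1: with several reads
  per UMI, error-discordant copies of the same molecule survive exact-triple
  deduplication as distinct raw tags and inflate counts after column
  merging; one read per UMI keeps the read layer a faithful round-trip of
  the count layer. The parameter is configurable and exercised at higher
  values in the dedup tests.

The default design is two samples of 5,000 cells each with the standard
index sequences TGCTATAT and GTTGGCTA. An optional cluster assignment
(`assign_clusters`) places cells into k clusters with per-label enrichment
weights, enabling power checks of the occupancy test.

**What the simulation does not capture.** Real data have variable ambient
load correlated with droplet content, cell-size and depth effects, PCR
chimeras, and index swapping between lanes — none are modeled. One
consequence matters for interpreting metrics: under per-cell proportion
normalization every *pure* singlet maps to the identical value
`ln(1 + s)`, so a tag's density has a point-like signal mode, and a true
singlet carrying a single ambient UMI of another tag can show a
proportion gap below δ and be called a multiplet. On the default design
this caps strict singlet accuracy near 0.94, while the assigned label still
contains the true tag for essentially all determined true singlets
(`singlet_tag_recovery ≈ 1.0`); both metrics are reported by `evaluate`.
Passing tests therefore demonstrate correctness of the procedure and its
convergence properties, not a performance guarantee on any particular real
dataset.

## Numerical and testing choices

- Ranking ties in tag selection: by number of cells detected, then total
  count, then lexicographic — fully deterministic.
- Cohen's kappa: scikit-learn's implementation behind `agreement_kappa`,
  wrapped to return 1.0 on complete agreement where the ratio is 0/0.
- Degenerate inputs: empty matrices round-trip I/O; empty tag sets refuse
  to classify; zero-total cells are flagged rather than dropped.
- Test problem sizes: the end-to-end recovery check runs the full default
  10,000-cell design through the read-level pipeline; the
  proportion-oracle check uses a 500-cell matrix; the permutation-test
  oracle enumerates every two-cluster instance with ≤ 12 cells at 50,000
  draws and compares against exact hypergeometric tails at the family
  level (nominal 3-SE exceedance rate, 5-SE hard cap), since a per-instance
  3-SE bound over thousands of independent Monte-Carlo comparisons is
  exceeded by chance with near certainty.
- Seeds are threaded through every stochastic call; no global RNG state is
  touched.

## Known limitations

- The `δ = 0.238` cutoff is taken as given from its original calibration
  against orthogonal species-mixing classification; no re-learning
  machinery is provided.
- Flank matching is exact; heavily degraded flanks lose reads at
  extraction rather than rescuing them.
- The collapse stage is correctness-oriented and quadratic in the number of
  distinct tags per scan; it is not meant for random-library lineage
  inventories of millions of barcodes.
- The occupancy test reports per-cluster p-values without cross-cluster
  correction, matching its intended use as a targeted follow-up test.
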