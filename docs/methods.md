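# Methods

This note documents the models, numerical choices and design decisions behind
`kinevo`, and what the synthetic-data generators do and do not emulate.

## Divergence scoring

**Model.** For a focal clade A (a kinase family or subfamily) and its nearest
sister clade B, each alignment column receives

S = RC − AC · p(AC)

* **RC** is the mean, over all unordered pairs of clade-A sequences, of the
  substitution-matrix similarity of their residues at the column, rescaled
  linearly so the matrix minimum maps to 0 and the maximum to 1. The default
  matrix is BLOSUM62 (range −4..11, so W–W rescales to exactly 1); the matrix
  and its normalisation are configurable. Pairs involving a gap contribute 0
  to the numerator while remaining in the denominator (a heavily gapped
  column is genuinely less conserved); columns with fewer than two residues
  are skipped and logged. RC ∈ [0, 1] by construction.
* **AC** is +1 if the predicted ancestral residues of clades A and B match,
  −1 otherwise. An ancestral gap is treated as a 21st symbol that never
  matches a residue.
* **p(AC)** weighs the call by the clade-B posterior: for a match, the
  posterior of the shared residue; for a mismatch, the summed posterior of
  everything except clade A's residue. S therefore lies in [−1, 2], with 2
  meaning "perfectly conserved in A, confidently different ancestors".

**Clade selection.** A unit's clade is found in two steps: take the MRCA of
all leaves carrying the label; if non-focal leaves make up ≥ 15% of that
clade, fall back to the largest fully pure subclade (ties broken in
preorder). This one rule covers both the polyphyletic case (the MRCA is
hopelessly impure, so the largest pure cluster is used) and the
tolerated-contamination case (< 15% spurious leaves are kept and reported as
purity). The sister is the other child of the clade's parent (largest other
child at a polytomy). A comparison is scored only when both clades hold ≥ 5
sequences and, above the bottom level, the sister's dominant parent label
matches the focal unit's (sister subfamilies must share a family, sister
families a group).

**Aggregation.** Scores are pooled per level; the switch threshold is the
95th percentile with linear interpolation between order statistics (the
ecosystem default, fixed so thresholds are reproducible), and a switch is a
score *strictly above* it. Comparisons sharing the same unordered pair of
ancestral nodes are collapsed before pooling so one duplication event is
never counted twice. "Frequently switching" domain positions are those whose
switch count strictly exceeds the 90th percentile of the per-position counts;
strict exceedance is chosen because the published per-level thresholds are
attained values. Category enrichment uses a one-sided Fisher exact test
(exact hypergeometric tail) on {frequent vs not} × {named category vs other}
and a one-tailed Mann-Whitney (normal approximation with tie correction)
comparing per-position counts of a chosen category against "other". Whether
to pool skipped columns into the percentile was an open choice; only emitted
scores are pooled.

## Ancestral reconstruction

The in-repo reconstructor is a single-rate marginal reconstruction:
Felsenstein pruning with per-node scaling for site likelihoods, and an
inside–outside sweep for marginal posteriors at every internal node (root
weighted by the model's equilibrium frequencies). Gaps are fully ambiguous
observations. The predicted residue is the posterior argmax with alphabetical
tie-breaking; ties are flagged in the table.

Models: Poisson (uniform) and LG (published exchangeabilities and
frequencies, embedded as constants). Transition matrices come from one
eigendecomposition of the symmetrised rate matrix per model; probabilities
below 1e−12 are clipped to zero and rows renormalised. Among-site rate
heterogeneity (gamma categories) is deliberately **not** implemented: the
divergence score consumes a posterior table, and production-grade
reconstructions with rate heterogeneity can be supplied as that table — the
TSV dialect is the contract, not the reconstructor. Consequently, numeric
agreement with external reconstruction tools is not asserted anywhere.

## Specificity models

PWMs are 20 × 14 matrices over flank positions −7..−1, +1..+7 of the 15-mer
window; the fixed S/T centre is excluded but its S:T ratio is retained.
Columns are (count + pseudocount) / (n_eff + 20·pseudocount) with terminal
padding excluded from counts (n_eff is per-column). The pseudocount default
is 0.5 per residue per column; threshold derivation and comparisons must use
one consistent setting. The minimum site count for a model defaults to 10.

The Frobenius distance ‖A − B‖F compares models; within- vs between-grouping
distances at each level keep the parent level fixed (families are compared
within a group, subfamilies within a family) and are contrasted with a
two-sided two-sample KS test.

The specificity-divergence threshold is derived from kinases with ≥ 50 sites:
per draw, two independent subsamples of 25 sites (each without replacement)
are turned into PWMs and their distance recorded; the threshold is the
maximum over all kinases and 100 draws. Whether the original protocol used
disjoint subsamples is unstated; independent draws are the more conservative
choice (they allow overlap, which shrinks same-kinase distances and the
threshold less). The operating value derived from literature-curated targets,
1.06, ships as a named constant; synthetic pipelines re-derive their own.

## Motif analysis

Backgrounds shuffle each site's 14 flank characters (padding included) with
the centre fixed, 10 shuffles per site, so foreground and background have
identical composition and background rows trace back to their source site.

Discovery is greedy motif-x-style extraction over single-residue constraints:
at each step the (position, residue) pair minimising the exact binomial upper
tail of its foreground count against the current background-subset frequency
is added, provided p < 1e−6 **and** the constrained foreground count stays
≥ 20. Requiring the occurrence floor at every step (as motif-x does)
guarantees emitted motifs meet the emission rule and makes the recursion
terminate. Ties break by smaller p, then smaller |position|, then alphabetical
residue. Emitted motifs' foreground matches — and their background shuffles —
are removed before the next round.

Enrichment of a motif is conditioned on its *most frequent superset motif*:
the single-constraint-removal variant with the most background matches (the
bare S/T centre for single-constraint motifs). The null probability is
background motif matches over background superset matches; the p-value is the
exact upper binomial tail over foreground superset matches. The published
description's worked example is two-constraint, leaving deeper motifs
ambiguous; single-constraint removal is the consistent generalisation.

Cross-species filtering first canonicalises motifs under the synonym classes
{R,K}, {D,E}, {L,I,V,M} and merges identical canonical forms (merging before
counting species was an open choice), then retains motifs present in ≥ 1/3 of
the species of some superphylum or in ≥ 2 excavate species, discarding motifs
exclusive to singleton superphyla (amoebozoa, heterokonts), motifs that are a
classical motif plus only S/T additions (likely phosphosite misassignment or
site clustering), and motifs that are the casein-kinase-2 motif S/T-D/E-x-D/E
plus only D/E additions. The classical-motif list is configurable. In motif
strings ("R-x-x-S/T-P") the first "S/T" token is the centre.

Coverage is the percentage of sites matching ≥ 1 eligible motif, where
single-constraint motifs are ineligible except the classical S/T-P and
R-x-x-S/T signatures, which suffice for targeting on their own.

## Trait dating

Presence/absence of a kinase unit evolves under the equal-rates two-state
Markov model, P(stay) = ½ + ½e^(−2qt). The single rate q is fitted by bounded
maximisation of the pruning likelihood over log q (search window 1e−8..1e3;
all-same-state data returns the floor with a boundary flag). Marginal
presence probabilities use a flat root prior (the convention of the standard
reconstruction function this emulates); polytomies are handled natively by
the pruning recursion. Origins are the deepest nodes with presence strictly
above 0.5 (threshold configurable; the source protocol states none) whose
parent is not above it; multiple candidates resolve to their MRCA with a
flag. Ages are read from a divergence-time table; the interval spans node age
to parent age, unbounded at the root.

## Comparative statistics

PICs follow Felsenstein's recursion with branch-length augmentation
b′ = b + b_l·b_r/(b_l + b_r); children are processed in sorted-name order so
contrast signs are deterministic, and polytomies are resolved by zero-length
bifurcations in the same deterministic order. Contrast regression is least
squares through the origin with n − 1 degrees of freedom (contrasts have mean
zero by construction). Blomberg's K uses the phylogenetically corrected mean
and the ratio of ordinary to GLS mean squared error against its
Brownian-motion expectation, with an add-one-corrected tip-shuffling
permutation p-value; the implementation was cross-checked against an
independent reference implementation during development. Pagel's λ scales
off-diagonal covariances, is profiled over the GLS mean and variance, and is
bounded above by the largest multiplier keeping the covariance matrix
positive definite (found by bisection); the test against λ = 0 is a 1-df
likelihood-ratio test. The quantity fed to PICs for motif-kinase coevolution
is log10 fold-enrichment (bounded and symmetric around zero) paired with
relative kinase frequency (unit kinases over total kinome size).

## Synthetic data: what it emulates, and what it does not

* **Family alignments** evolve by applying the model's transition matrix at a
  fixed expected substitution count per site per branch (branch-rate 0.05 by
  default — enough divergence to create fixed differences without saturating
  a 500-column alignment), with switches implanted by fixing a residue in a
  named clade. The returned ancestral table holds the *true* simulated
  residues with posterior 1 (optionally Dirichlet-noised around the truth to
  probe p(AC) weighting). No indels, no rate heterogeneity, no selection:
  the score test needs controlled divergence, not realism, so recovery
  results bound what the score can do when reconstruction is exact, not its
  robustness to alignment or reconstruction error.
* **Phosphoproteomes** are mixtures of motif-bearing and background 15-mers
  with stated weights over uniform background frequencies. Real
  phosphoproteomes have skewed composition, correlated positions and shared
  peptides between species; the mixture model isolates the enrichment
  machinery from those effects.
* **Binary and continuous traits** are exact simulations of the models the
  estimators assume (Mk, Brownian motion), so the recovery tests are
  well-specified calibrations, not robustness checks.
* All generators are pure functions of (spec, seed); random streams are keyed
  per branch by node name (and per call), so pruning a tree does not
  reshuffle draws elsewhere.

## Problem sizes

The test battery and the acceptance script use: 2 × 20-leaf two-clade trees
with 500 columns and 10 implanted switches for divergence recovery;
3,000-site phosphoproteomes at mixture weight 0.15 (50 seeds) and 2,000-site
pure-background proteomes (100 seeds) for discovery power and type-I
behaviour; a 15-species, 3-superphylum battery for the cross-species filter
and coverage; 200-leaf trees (50 seeds) for Mk rate recovery and 80-leaf
trees for origin recovery; 200-leaf trees (≥ 60 seeds) for PIC slope
recovery and 60-leaf trees for the K and λ calibrations. These sizes give
stable medians and rates while keeping a full run to a couple of minutes.

## Known limitations

* The reconstructor omits gamma rate heterogeneity (see above); supply
  external posteriors for analyses where that matters.
* RC's gap handling (gap pairs count as zero similarity) is one of several
  defensible conventions; it is configurable only via the scoring matrix, not
  the pair rule.
* The motif synonym classes are applied at the merge/filter stage, not during
  greedy discovery, mirroring the cited discovery tool's single-residue
  constraints.
* Blomberg's K is right-skewed around 1 under BM on small trees; medians need
  ~100 replicates to stabilise, which the calibration tests account for.
* `derive_threshold` is a maximum statistic: it grows slowly with the number
  of draws, so threshold comparisons must fix n_draws.
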