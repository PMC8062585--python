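# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `mlpd` package.

## Binding model and gating

A bead displaying an aptamer with dissociation constant K_D (nM), incubated
at target concentration [T] (nM), has equilibrium occupancy
Fr = [T]/([T]+K_D) ∈ [0,1). Bead fluorescence is modeled as
F = F_max · Fr · (1+ε) with ε ~ Normal(0, CV); F_max is normalized to 1, so
all intensities are fractions of F_max. The sorting gate is inclusive
(F ≥ F_max/3 is positive). Because Fr(K_D/2, K_D) = 1/3 exactly, a noiseless
sort at [T] isolates precisely the set {K_D ≤ 2[T]}; this identity anchors
the stringency ladder (concentrations decreasing fourfold, thresholds 2[T]
decreasing fourfold) and the interval rules used for approximate K_D
assignment (intensity ≤ F_max/5 ⇒ K_D > 4[T]; in (F_max/5, F_max/3] ⇒
2[T] < K_D < 4[T]; above ⇒ K_D < 2[T]).

The default fluorescence CV is 0.1. The noise model (multiplicative
Gaussian) is a package choice: it keeps the gate decision scale-free and
produces the realistic phenomenon that beads of a sequence near the gate
split between the positive and negative pools.

## Ground-truth affinity oracle

The simulator's fitness landscape is a rule set:
log K_D = log(baseline) − Σ_motifs occurrences·log(fold) + optional per-k-mer
weights + optional seeded lognormal noise. Defaults: baseline 10 µM, one
planted 7-nt core motif (TGGATAG) at a 100× fold bonus, no k-mer weights, no
noise. Occurrences are counted non-overlapping, so acquiring a second motif
copy compounds the bonus (1 nM) — this gives mutation walks something real to
discover beyond the training distribution. With noise disabled the landscape
is deterministic and the motif-ablation monotonicity (removing a motif
strictly raises K_D) holds exactly; with lognormal noise enabled the
per-sequence noise term can occasionally outweigh a motif bonus, which is why
noise is off by default.

The oracle is a deliberately simple stand-in for an unknown real landscape:
it has no epistasis, no secondary-structure effects, and a single discrete
affinity class per motif count. Tests passing on it demonstrate that the
pipeline recovers planted structure, not that it would perform equally on
real screens.

## Simulated screens

`simulate_experiment` sorts a library (default 2,500 random 40-mers, 10%
with one implanted motif copy, 10 beads per sequence) at each ladder
concentration. Round-1 positive pools are mixed at equal total bead mass
(1:1) and resampled multinomially to the original bead count to form the
round-2 input; round 1 uses all but the strongest stringency, round 2 all of
them. Each pool is sequenced as a multinomial draw with total reads set by
the expected bead coverage (default 100 reads per full bead-complement;
manifest metadata records per-pool coverage). Two ladders are built in: the
three-level training design (1024/256/64 nM → thresholds 2048/512/128 nM)
used to generate model training data, and the four-level validation design
(256/64/16/4 nM → 512/128/32/8 nM) used for walk evaluation.

## Labels

A sequence is positive at a stringency if its count in the positive pool
reaches 20% of the expected bead coverage AND its normalized pool fraction is
higher in the positive than in the negative pool. The negative criterion is
the exact mirror (the package's own construction — only the positive rule is
standard); everything else is ambiguous. When a stringency was screened in
several rounds, the latest round with a non-ambiguous call wins, so round-1
negative pools supply negatives for sequences that never reached round 2.

SuperBin collapses the per-stringency ternary labels into one level: with m
stringencies ordered weakest→strongest, level = 2·(consecutive clean passes
from the weakest) + 1 if the next stricter level is ambiguous (borderline),
giving 0..2m (seven levels for m = 3). Sequences positive at a stricter level
but negative at a weaker one (conflicts), or ambiguous everywhere, are
excluded. The interleaved pass/borderline semantics are this package's
reconstruction and are isolated in one function.

## Clustering

Sequencing error makes near-identical reads abundant, so train/test splits
must respect sequence neighborhoods. The reference algorithm is: connect all
pairs with Levenshtein distance ≤ 5 (inclusive), take connected components.
The scalable implementation generates candidate pairs from a 6-mer
inverted index filtered by cosine distance of k-mer count signatures, then
verifies candidates with banded edit-distance computation (edlib). The
cosine threshold default is 0.9: the q-gram bound says 5 scattered
substitutions in a 40-mer can leave as few as 35 − 6·5 = 5 shared 6-mers
(cosine similarity ≈ 0.14), so any much tighter threshold would break the
guarantee that candidates are a superset of all true edit-≤5 pairs; the test
suite checks that superset property against a brute-force oracle. For inputs
larger than `all_pairs_cap`, multi-read sequences (total count > 1) form the
all-pairs subset (padded with singletons up to the cap) and the remainder is
projected onto the nearest verified cluster — ties resolve by smaller edit
distance, then smaller cluster id. Cluster representatives are the
highest-count member (ties: lexicographically smallest). Folds are dealt
round-robin over shuffled clusters; no cluster ever spans folds.

## Models

Input encoding: 160 one-hot values (4 bases × 40 positions, order A,C,G,T)
concatenated with 340 overlapping k-mer counts (k = 1..4, lexicographic),
total 500. The network is an explicit-backprop numpy implementation: 0–3
valid 1-D convolutions over the one-hot block reshaped to 40×4 (the k-mer
block joins at the first dense layer), 0–4 dense hidden layers with ReLU and
optional dropout, and one of two heads. The fully connected head maps the
last hidden layer to all outputs; the latent-affinity head (Counts only —
it is meaningless for the scalar SuperBin target) funnels the hidden state
through one affinity scalar which is multiplied by a single trained
parameter per pool output.

Training is mini-batch squared-error regression. Presets (batch 64): Counts
— latent head, SGD momentum 0.903, lr 0.00138; Binned — fully connected,
momentum 0.737, lr 0.00388; SuperBin — fully connected, momentum 0.498,
lr 0.00203. An Adam alternative (lr 0.001) is selectable. All presets use one
64-unit hidden layer and 30 epochs; a seeded random-search utility is
provided for tuning. Two numerical choices matter:

* **Target standardization.** Each output column is standardized over its
  unmasked training entries and predictions are de-standardized. Without
  this the Counts targets (pool fractions ~10⁻⁴) leave gradients too small
  for the preset learning rate and the model collapses to a constant.
* **Masking and upsampling.** Ambiguous Binned entries are masked out of the
  loss rather than coded 0.5. Positive examples (Binned: any positive label;
  SuperBin: level ≥ 2; Counts: summed raw count ≥ four bead-complements of
  reads, a depth-scaled analogue of an absolute-count cutoff) are upsampled
  so every batch holds at least 10% positives.

Scoring: Counts reduces to the sum of the two highest-stringency round-2
positive-pool outputs; Binned uses a stringency-rank weighted sum of its
level outputs for walk ranking, but per-threshold (affinity-threshold AUC)
evaluation uses the model's own output for that level — the composite mixes
in the strongest level's output, whose training labels are the noisiest, and
is measurably less stable as a single-level ranking; SuperBin's score is its
scalar output. AUCs are rank-based with ties averaged (Mann–Whitney form).

## Walks and seed screening

A walk keeps a parent set (initially the seed). Per round it samples a fixed
number of mutants — parent chosen uniformly, substitution count uniform on
0..4 (the distribution is unspecified in the field description; uniform is
the simplest choice and is configurable), positions without replacement,
replacement base uniform over the three alternatives — scores them, records
the top 5, and promotes the top 200 to be the next parents (the selected 5
are inside the 200). Ties break score-descending then lexicographic. The
random-walk baseline is identical except selection is uniform, so the only
difference between arms is model guidance. Seed screening streams random
40-mers in constant memory and keeps the top fraction with the same
tie-break.

## Truncation and motif discovery

Core scans embed each subsequence (lengths 15/19/23/27/31/35/39 by default)
at every admissible start in each of the four homopolymer backgrounds —
exactly 4·(40−l+1) variants per core — and summarize the score distribution
by median and population variance. Ranking modes: max_median (default),
min_variance, and min_median (sanity picks expected to fail). Backgrounds
are pure homopolymers only; no shuffled backgrounds.

The motif finder is a Fisher-exact screen, a deliberate simplification of
EM/PWM motif discovery: per k-mer (k = 4..8), presence/absence Fisher test
(Bonferroni over 4^k) plus occurrence-frequency log-odds with pseudocount 1.
The consensus is the significant k-mer with the smallest raw p; exact ties —
which arise precisely when a motif and its substring cover the same positive
set — resolve to the longer k-mer (maximality), then higher log-odds.
Ranking admitted k-mers by Bonferroni-corrected p instead would
systematically prefer the shorter substring (the 4^k correction factor
dominates when both are perfectly discriminative) and report a truncated
consensus.

## K_D estimation

Full curves are fit by least squares (scipy `curve_fit`) to
F = F_max·[T]/([T]+K_D) with positivity bounds; at least three distinct
concentrations are required, and flat or all-zero curves raise a fit error
rather than returning silently. On noiseless synthetic curves over the
1–1024 nM twofold ladder the fit recovers the generating K_D to machine
precision; at 10% multiplicative noise the median relative error for a
ladder-bracketed K_D (8 nM) is ≈ 11% over 100 replicates. K_Ds near the top
of the concentration range are recovered less precisely because F_max is
poorly constrained there.

## Problem sizes

Desk-scale defaults keep every pipeline stage in seconds-to-minutes on one
CPU: libraries of 2,000–2,500 sequences, 100-read bead coverage, clustering
caps of 10⁵, walks of 200–1,000 mutants per round, and seed screens of
10⁴–10⁶ candidates (the 10⁶-candidate screen at fraction 5×10⁻⁶ is a scaled
instance of screening 10⁹ for the top 5,000). The acceptance script and test
suite use these sizes.

## Known limitations

* The oracle landscape is additive in motif count with no epistasis or
  structure; model AUCs near 1.0 on it say nothing quantitative about real
  screens, whose full-scale analogues require real NGS data from a wet-lab
  campaign.
* No sequencing-error model, no emulsion-PCR bias, no bead polyclonality,
  no primer-region indel handling beyond drop-and-tally.
* Secondary-structure effects are exposed only as an optional auxiliary
  regression hook (an external fold-energy provider for the Counts model,
  off by default); no folding is computed in-package.
* The latent-affinity head supports a single target protein; multi-target
  screens would need one latent scalar per target.
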