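# Methods

## Generative model

Reads mapped to a genome are reduced to (chromosome, 5′ coordinate,
strand); all internal coordinates are 0-based, converted from 1-based SAM
at the parse boundary and nowhere else. Reads are segmented into
independent regions at 5′-position gaps larger than 500 bp; regions with
fewer than 6 reads are discarded. Within a region, every base m is a
candidate binding event with weight π_m, and a read's likelihood under
event m is the read spatial distribution evaluated at the signed offset
(pos5 − b_m), mirrored for minus-strand reads. The model assumes reads are
conditionally independent given their events, that a single offset law
holds genome-wide per round, and that events occupy single bases.

A negative Dirichlet prior with exponent (−α_s + α_m) per component makes
the mixture sparse and sequence-aware. The M-step is the truncation
π_m ∝ max(0, N_m − α_s + α_m); components hitting zero are removed.
Read multiplicities at identical (pos5, strand) are collapsed into weights,
which leaves the EM unchanged but makes each iteration linear in distinct
positions.

### Sparse-prior strength and annealing

α_s defaults to √(region read count) and is ramped linearly from zero over
the first 10 iterations (the positional prior is scaled with the ramp so
α_m < α_s holds throughout). Starting the penalty at full strength kills
components before responsibilities have polarized and biases calls toward
single central components; the ramp lets the read data shape the
responsibilities first.

### Convergence and the objective trace

The penalized objective is
Σ_n w_n log Σ_m π_m p(r_n|m) + Σ_m (α_m − α_s) log π_m over the currently
active components, with reads of zero total likelihood excluded (their
weight is reported separately, and Σ_m N_m equals the live read weight
exactly). Iteration stops when the absolute change falls below 1e−5
(a relative criterion of similar magnitude stops too early and can leave
duplicate components one base apart at a single true event) or after 500
iterations.

The improper prior makes this objective discontinuous in the number of
components: as a dying component's π_m → 0, its penalty term
(α_m − α_s)·log π_m → +∞, so the objective is inflated immediately before
an elimination and necessarily drops when the term is removed. No
definition that sums over active components avoids this. The fitted state
therefore records, for every post-annealing iteration, whether a component
was eliminated; monotonicity of the objective is guaranteed — and asserted
in the tests — over iterations at which the active set is unchanged.

### Ties and degeneracies

With a double-exponential offset law, all bases between two read
concentrations can tie in single-placement likelihood; the positional
prior then decides the survivor (verified directly in the tests by moving
the α-boosted base). Exact residual ties are resolved by the EM dynamics
deterministically, since initialization is uniform and the arithmetic has
no randomness.

## Read spatial distribution

Support is the symmetric interval [−500, 500] bp; probabilities are
floored at 1e−9 over the support and normalized per strand; the minus
strand is the mirror image.

Defaults: the ChIP-seq initial distribution is a two-scale Laplace mixture
0.7·Lap(−37, 8) + 0.3·Lap(−37, 60) — a sharp summit over broad shoulders,
matching the shape of empirical 5′-end pileups at sequence-specific sites
(mode −37 bp upstream, tails to a few hundred bp). The sharp component is
what carries single-base positional information; a single broad Laplace
cannot separate homotypic events ~30 bp apart because their read
likelihoods overlap almost completely. The ChIP-exo preset is a tight
two-peak mixture (0.65·N(−10, 3²) + 0.35·N(+10, 3²)), with >99% of its
mass within ±50 bp.

Re-estimation histograms the signed offsets of all reads within 500 bp of
the 1000 strongest events (minus-strand mirrored), smooths with a Gaussian
kernel (bandwidth 5 bp by default; 1 bp when refining ChIP-exo shapes,
whose bimodality a 5 bp kernel would blur), floors and renormalizes. When
a primary motif is available, events are first snapped to the nearest
motif match within 50 bp: the motif center is the most accurate available
estimate of the interaction point. This matters for ChIP-exo adaptation —
under a mis-specified ChIP-seq initialization every exo site is split into
two events at ±(mode offset), and a distribution re-estimated from the
split events reproduces the split (a self-consistent translation
degeneracy); anchoring on the motif breaks it. The exo protocol is one
extra prediction round (`rounds=2`), after which the learned distribution
recovers the generating exo shape (total-variation distance reduced by
~70–90% in the tests).

## Significance testing

Only event read counts are tested. With a control: an upper-tail binomial
test with n = round(strength) + round(depth-scaled control count in a
201 bp window) and success probability 1/2; fold = strength/(scaled
control + 1). Without a control: an upper-tail Poisson test with a dynamic
rate, the maximum of the genome-wide, 5 kb and 10 kb local rates scaled to
the 201 bp window. Benjamini–Hochberg correction (via statsmodels) yields
q-values; the default reporting threshold is q ≤ 0.01.

## Motif discovery

Positive set: 61 bp windows centered on called events; negative set:
61 bp windows ±300 bp away, dropped when overlapping any positive window.
K-mers are counted once per sequence, reverse complements identified; a
k-mer is enriched at hypergeometric p < 0.001 and ≥ 3-fold.

Each enriched k-mer carries an expected event offset. The estimate anchors
on the modal rounded offset over the positive set and averages raw offsets
within 1 bp of it — a plain mean is dragged toward zero by off-site
occurrences in sequences whose central site lacks the k-mer — and the full
offset histogram is retained for the positional prior.

The most enriched k-mer seeds an equivalence class together with its
Hamming-distance-1 neighbors. Growth alternates: (a) admit pool k-mers
occurring at a consistent seed-frame offset in ≥ 1/3 of their occurrences
inside 2k+1 bp windows around class matches — with at least 3 consistent
occurrences, since one or two satisfy the fraction rule trivially and
admit misaligned members; (b) build a PWM from matched positive sequences,
each weighted by event strength times a logistic density ratio
w(d) = f(d)/f(0) (mean 0, variance 13, so scale s = √39/π ≈ 1.988) of the
distance between class match and event position, with 0.375 pseudocount
per cell, log-odds against a zero-order negative-set background; (c) trim
to the contiguous sub-PWM (width ≥ 5) whose 60%-of-max-score matching best
separates positives from negatives (ties: widest, then leftmost), and
re-admit k-mers around PWM matches. Iteration stops when the trimmed
hypergeometric p stops improving. Per sequence, one best match is used
(member priority by enrichment, then leftmost, plus strand first).

k runs over 5–13 and the k with the most significant trimmed primary PWM
wins. Secondary motifs: the seed is removed from the pool, PWM occurrences
are masked with N, and clustering repeats; if a secondary PWM beats the
primary, discovery restarts seeded from it (bounded at 3 restarts). A
class is accepted at trimmed p < 1e−6: the 1e−3 k-mer-level gate corrected
by ~10³ for the selection multiplicity of the seed (best of ~4^k/2
candidates over 9 values of k) and of trimming (~10² sub-ranges). With the
raw 1e−3 gate, ~30% of motif-free null datasets produce a spurious class;
at 1e−6 the null is clean while genuine primaries (p ≤ 3e−7 even with
fewer than 30 events) are retained.

## Positional prior

All member k-mers of the primary class (and their reverse complements) are
located in each region with an Aho–Corasick automaton (implemented in
`chipem._aho`; tests verify bit-identity against naive multi-pattern
scanning). Each occurrence votes at the bases its offset histogram points
to — for a forward occurrence at p, base p + δ with weight equal to the
number of positive-set sequences at offset δ; mirrored for reverse
occurrences — so C at a base counts the positive-set sequences whose
binding offsets match it. Votes from multiple k-mers are summed; votes
outside the region are clipped. α_m = μ·α_s·C_m/C_max with μ = 0.8 and
C_max global over all regions, so max α_m ≤ 0.8·α_s < α_s: the prior can
bias an event toward explanatory sequence but can never create one without
read support. μ = 0 reproduces the prior-free calls exactly.

## Spacing analysis

Each anchor (B) event is oriented by the strand of the nearest B-motif
match within 20 bp; unoriented anchors are kept in the + frame rather than
dropped. Partner (A) events within ±100 bp contribute one count at the
orientation-adjusted signed offset; flank counts are collected over
200 ≤ |offset| ≤ 400. The Poisson rate is the mean flank count per
position (floored at 1/402 when zero with nonzero window counts);
p-values are Bonferroni-corrected by 201 times the total number of
pairwise tests, with significance at 1e−8. Spatial resolution is the mean
absolute event-to-motif-middle offset after subtracting the mean offset,
over events within 100 bp of a match; `snap_to_motif` (inclusive 50 bp
radius, ties to the lower coordinate) serves as a comparison baseline.

## Synthetic data

The generator emulates: a zero-order background genome (A/C/G/T =
0.30/0.20/0.20/0.30), motif instances sampled per-base from a PWM (default
consensus weight 0.85) planted at event positions, per-event read counts
from a log-normal law (median 100 reads, log-sd 0.5), read 5′ offsets
drawn from the specified distribution with a fair strand coin, uniform
noise reads (default 30% of all reads) and a uniform control at matched
depth. Heterotypic pair simulations plant anchor events with their motif
on a random strand and the partner at an exact oriented offset, plus
independent background events for both factors. Everything is reproducible
bit-exactly from (parameters, seed), and outputs round-trip through the
package's own parsers.

The default planted motif is an odd-width 11-mer: an even-width motif has
no central base, which injects a half-base strand straddle into every
k-mer offset. The benchmark consensi (widths 9–12: TGGTGTTAA, CCTTACTATA,
GGGTTTGGCTC, CTTTGCGCCCAT) were chosen by seeded search to share no k-mer
(k ≥ 5) with themselves or their reverse complements, because internally
repetitive motifs make the "expected offset of a k-mer" inherently
multi-valued in any implementation.

The generator does not model PCR duplicates, mappability, chromatin
accessibility bias, fragment-length variation or indirect (tethered)
binding; passing tests therefore demonstrate correctness of the inference
under the stated generative assumptions, not robustness to those real-data
artifacts.

## Problem sizes and variability

The test suite and acceptance script run at desk scale: genomes of
0.15–2 Mb, 15–60 events per dataset, ~100 reads per event. The headline
checks use 100 seeded two-event simulations (deconvolution), 20 datasets
for the prior-improvement comparison, 100 motif-free and 200
independent-placement null runs, all with fixed seeds. On 5-dataset
batches at other seeds the per-dataset phase-5 ≤ phase-1 comparison
occasionally inverts by a few hundredths of a base pair — both errors sit
near 0.5–1.0 bp, so the paired difference is at the resolution floor —
while the aggregate improvement and the within-1-bp fraction (~85–90%)
are stable.

## Known limitations

- Candidate events at every base make the EM O(reads × region length) per
  iteration; mammalian-scale data needs the same streaming-per-chromosome
  discipline the desk-scale code uses, but has not been profiled here.
- The class-growth window (2k+1) cannot capture motif positions further
  than ~k/2 outside the seed for small k; trimming and the k-selection
  step compensate, but very wide dimeric motifs would be found as two
  classes.
- Orientation of spacing anchors falls back to the + frame when no motif
  match is within 20 bp, which dilutes (never inflates) a true oriented
  signal.
- The binomial/dynamic-Poisson significance parameterizations follow the
  established symmetric-count and local-rate conventions; other readings
  of those tests would shift absolute p-values but not the ranking.
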