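# Methods

## The model

`nichehybrid` asks, for one 16S OTU community at a time, whether its rare
members look like they were assembled by deterministic niche selection, by
stochastic (neutral) dynamics, or by a mixture of the two.

Each OTU is represented by one aligned sequence of length L, a point in an
L-dimensional sequence space. The distance between OTUs i and j is the
normalized Hamming distance

    H_ij = (1/L) * sum_a [1 - delta(S_a^i, S_a^j)],

the fraction of alignment columns at which the base labels differ. Gaps and
N are kept as distinct labels that match only themselves, so L never changes
from sequence to sequence. Distances are computed as exact integer mismatch
counts divided by L, so results cannot depend on vectorization or chunking.

OTUs are split at an abundance threshold k (default 5% relative abundance)
into **modal** (abundant) and **rare** OTUs. Every rare OTU is assigned to
its nearest modal OTU — a Voronoi partition of sequence space — and the
collection of minimal distances {E_k} is the diagnostic sample:

* **neutral** assembly scatters rare OTUs at random, so {E_k} forms a bell
  slightly below the neutral expectation E[H] = 3(L−M)/(4L), where M is the
  number of alignment columns conserved across the whole sample (fully
  random columns disagree with probability 3/4; conserved columns never
  disagree);
* **niche** assembly makes rare OTUs few-mutation satellites of modal OTUs,
  concentrating {E_k} near zero (the peak sits at the average niche size,
  not exactly at zero);
* a **hybrid** community produces both: a satellite peak near zero plus a
  second, non-zero peak at the neutral end-member.

M is computed over all sequences in the sample, modal and rare together,
because conservation is a property of the marker gene rather than of an
abundance class. Ties in the nearest-modal argmin are broken toward the
lexicographically smallest modal id; the E value is unaffected.

## Silverman's multimodality test

Whether {E_k} has one mode or more is decided by Silverman's bootstrap test
of the null "at most n modes" (n = 1 here). The statistic is the critical
bandwidth h_crit: the smallest Gaussian-kernel bandwidth at which the KDE of
the sample has at most n modes. Mode counting evaluates the KDE on a uniform
grid of 512 points spanning [min − 3h, max + 3h]; strict local maxima are
counted and a flat plateau counts once. h_crit is found by doubling/halving
from the rule-of-thumb bandwidth and bisection to relative tolerance 1e−3,
relying on the Gaussian kernel's property that the mode count is
non-increasing in bandwidth.

Significance comes from the variance-rescaled smoothed bootstrap: replicates

    y_i = xbar + (x_{J(i)} − xbar + h_crit * eps_i) / sqrt(1 + h_crit²/s²)

are drawn (J uniform indices, eps standard normal, s² the sample variance),
each replicate's modes are counted at h_crit, and

    p = (1 + #{replicates with > n modes}) / (n_boot + 1)

with n_boot = 999 by default. The add-one estimator bounds p below by
1/(n_boot+1). No Hall–York calibration is applied by default; the test is
left in its classical, conservative form (measured type-I error on Gaussian
samples is far below nominal — see the calibration suite). The bootstrap is
bit-reproducible for a fixed (sample, n_boot, seed), and the seed is
mandatory on the command line.

No boundary reflection is applied even though E ∈ [0, 1]; this matches
standard practice for the test, but mass piled against 0 (typical of niche
communities) is therefore smoothed slightly outside the support.

## Classification

The hybrid signature in this model is specifically a density peak at the
neutral end-member: a subpopulation of rare OTUs scattered near 3(L−M)/(4L)
on top of the satellite peak. Because normalized Hamming distances are
multiples of 1/L, a tight satellite cloud (niche radius of a few mutations)
is itself multimodal at the lattice scale — three atoms at {1,2,3}/L are
genuinely three modes, and Silverman's test correctly rejects unimodality on
such samples. That fine structure says nothing about neutral subpopulations,
so rejection alone is not taken as a hybrid call. The rule is:

* **HYBRID** — p < 0.05 *and* the kernel density plot (Silverman
  rule-of-thumb bandwidth, i.e. what a standard density plot shows) has a
  mode at or above c · 3(L−M)/(4L);
* **NICHE** — either a rejection whose density modes all sit below that cut,
  or no rejection with the primary mode below the cut;
* **NEUTRAL** — no rejection and the primary mode at or above the cut.

The factor c defaults to 0.5 and is exposed in the configuration; the
niche/neutral split of unimodal samples is this package's own convention
(observed cohorts contain essentially no pure-neutral samples, so the cut is
rarely load-bearing). The primary mode is the highest-density mode of the
KDE at h_crit.

Samples with fewer than `min_rare` (default 50) rare OTUs, a degenerate
modal/rare partition, or zero distance spread are flagged
`sufficient_data=False` and withheld rather than classified: with too few
rare OTUs the distance histogram is shapeless.

## Group comparison

Cohorts are compared by the fraction of samples called HYBRID. The 2×2
table (group × HYBRID/not-HYBRID, NEUTRAL counting as not-HYBRID) is tested
with the two-sided Fisher's exact test in the probability-mass convention:
the p-value sums hypergeometric point probabilities, margins fixed, of all
tables no more probable than the observed one (relative tie tolerance 1e−7).
The reported odds ratio is the sample odds ratio (a·d)/(b·c), infinite when
b·c = 0. Withheld samples are excluded and counted.

## The synthetic-community generator

`simulate_community` builds ground-truth communities for end-to-end
verification. Defaults describe a gut-like sample and are the conditions
used throughout the test suite: N = 600 OTUs, L = 400, M = 100 conserved
columns, 8 designated modal OTUs, niche radius r = 3, k = 5%.

* A single community template fixes M uniformly chosen conserved positions
  to shared random bases; the remaining L−M positions are free.
* Modal and neutral rare OTUs draw free positions i.i.d. uniform over the
  four bases. Niche rare OTUs copy a uniformly chosen modal OTU and apply
  u ~ Uniform{1..r} substitutions to a different base at distinct free
  positions, so their nearest-modal distance is exactly u/L ≤ r/L and
  strictly positive. A fraction alpha of the rare OTUs is niche-derived.
* All sequences are distinct; collisions are redrawn (cap 100 retries).
* Read counts use lognormal weights (sigma = 1): rare OTUs get small
  positive integers, modal OTUs get counts rescaled until every designated
  modal OTU sits strictly above k and every rare OTU strictly below it, and
  the partition at k is verified to recover the design exactly.

What the generator does **not** emulate: phylogenetic correlation among
neutral OTUs beyond the conserved columns, the 3%-identity spacing that OTU
picking imposes between real representatives (real satellite distances start
around 0.03 rather than 1/L), gaps/ambiguous bases, chimeras, and any
coupling between abundance and sequence position. Passing the recovery
suites therefore shows the statistical machinery behaves correctly on the
idealized regimes, not that real samples are this clean.

## Problem sizes and numerical choices

The verification suites use: 200 Gaussian datasets (n = 500, 199 bootstrap
replicates) for calibration, 100 two-component mixtures (separation 8 sd)
for power, 50 seeded communities per alpha ∈ {0, 0.5, 1} for recovery, and
199 bootstrap replicates in the recovery runs (p-resolution 1/200, ample for
a 0.05 threshold). Exhaustive Fisher validation covers every 2×2 table with
total ≤ 60, up to row/column/transpose symmetry. Degenerate inputs are
defined throughout: zero-spread samples have one mode by convention,
`critical_bandwidth` returns a vanishing bandwidth when the null is already
satisfied at arbitrarily small h, and all-identical abundance tables raise a
degenerate-partition error.

## Known limitations

* Silverman's test is conservative without calibration; small neutral
  admixtures (alpha near 0.1) will often escape detection.
* The niche/neutral cut c·3(L−M)/(4L) for unimodal samples is a convention;
  samples whose primary mode falls near the cut should be inspected.
* Heavily gapped alignments inflate distances because '-' is a mismatch to
  every base; the 3/4 limit assumes a 4-letter alphabet.
* The alpha estimate itself (niche fraction) is not inferred — only the
  presence or absence of a neutral subpopulation is tested.
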