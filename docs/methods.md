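# Methods

## Model and procedure

`trimerbias` classifies short DNA reads by the usage bias of 3-codon DNA
9-mers — nine consecutive nucleotides read as three in-frame codons encoding
an amino-acid trimer of the kind found in protein secondary structures.  The
reference table is a three-level hierarchy: characteristic trimer (each
residue mapped into one of 12 physicochemical classes; K,R positively
charged; D,E negatively charged; S,T and N,Q polar uncharged split by
volume; A,I,L,V and F,W,Y hydrophobic split by volume; C, G, H, M, P each a
class of their own; the stop signal its own class) → amino-acid trimer → the
set of synonymous 9-mers observed for it.  Only trimers free of stops are
valid reference entries; query-side translation may produce stop-containing
trimers, which can never match.

Per genus and per database type (CDS / non-CDS) the package estimates

* amino-acid trimer usage: the frequency of each trimer among the trimers
  of its characteristic trimer, and
* 3-codon usage: the frequency of each 9-mer among the stored synonymous
  9-mers of its trimer,

from 9-mer counts taken at stride 3 (consecutive codon windows overlapping
by two codons).  Coding training sequence is counted in its annotated frame
only; non-coding sequence in all six frames, since it has none.  Sequences
shorter than 9 nt or containing an ambiguity code are excluded.  The product
of the two usages is the trimer usage bias b_g(d), the quantity all scoring
rests on.

A query is scanned in six frames (three forward offsets, three on the
reverse complement), 9-nt windows at stride 3, windows with ambiguity codes
skipped; queries under 9 nt are rejected with a distinct status.  Within a
frame, genus g scores the mean of ln b_g(d) over the n fully matching
windows, and the per-frame scores are softmax-normalised over the genus
panel so they sum to 1 and are comparable across frames.  The call is the
argmax over (genus, frame, database type); the answer set holds every genus
of the winning frame and type whose normalised score lies strictly within
the cutoff (0.01, 0.05, 0.1, 0.15, 0.2 or 0.3; default 0.05) of the
maximum, ordered best-first.

### Rank-sum P-value score

Each matched 9-mer ranks the genus panel by bias, ascending, rank s = 54 for
the highest.  Under the null the winning genus's rank sum over n matches is
the sum of n fair s-sided dice.  The signed score is the exact probability
mass at the observed sum, multiplied by −1 when the sum falls below the
distribution's mode (the non-significant low side); reports use
log10(1/|score|).  The closed-form inclusion–exclusion PMF

    P(p,n,s) = s^−n · Σ_{k=0}^{⌊(p−n)/s⌋} (−1)^k C(n,k) C(p−sk−1, n−1)

is implemented exactly over rationals and serves as the small-n oracle;
production tables for n = 2…625 (624 tables) are built by iterated
convolution of the uniform PMF, which is exact to machine precision and
avoids the catastrophic cancellation of the alternating sum at large n.
Rank sums feeding these integer-support tables use ordinal ranks, ties
broken by manifest order (the earlier genus takes the higher rank); the
rank-probability method uses average ranks instead.

### Rank-probability method (taxon groups, coding queries only)

Mono-usage tables are estimated from coding training sequence: codon
frequency within each synonymous family and residue frequency within each
characteristic class.  Products of mono usages give expected trimer and
expected 3-codon usages; the standardized 3-codon usage is observed /
expected, the codon-context effect beyond single-codon bias.  Per reference
9-mer, the genus panel is ranked by bias and, separately, by standardized
usage; each ranking yields a tie-corrected Kruskal–Wallis H over the 13
taxon groups and centred group mean ranks, and genus g scores
H · (r̄_{G(g)} − (N+1)/2) / N, averaged over the two rankings (genera of a
group share the value; group scores weighted by size sum to zero).  A
query's per-group total is the sum over its matched 9-mers in the chosen
frame; the call is the argmax group.  The exact functional form combining H
and the group mean ranks is this package's concrete instantiation of a
rank-probability score; it is isolated in one function
(`scoring.build_rank_scores`) so alternatives can be swapped.

## Numerical choices

* **Smoothing.**  Every usage table is Laplace-smoothed (default
  pseudocount 1) over the reference support, so all biases are strictly
  positive and log scores are defined even for genera with no counts.
* **Standardized usage at low counts.**  The bulk per-genus estimator
  smooths the observed 3-codon usage toward the mono-usage expectation
  (renormalised over the stored family) rather than toward the uniform
  distribution.  Uniform smoothing makes the ratio uniform/expected explode
  for exactly the 9-mers a genus avoids, handing the top standardized-usage
  ranks to the least related genera; expectation-matched smoothing lets
  unobserved entries default to the neutral value 1 and converges to the
  plain observed/expected ratio as counts grow.  The one-entry function
  `standardized_3codon_usage` keeps the plain ratio definition.
* **Per-frame score.**  Mean log bias (a geometric mean) rather than the raw
  product, so frames with different match counts are comparable; the raw
  product of values < 1 would penalise frames with more matches.  The cutoff
  operates on the softmax-normalised scores, giving the printed thresholds a
  fixed scale.
* **Tie-breaks.**  Argmax ties resolve by manifest order, then CDS before
  non-CDS, then frame order (+1, +2, +3, −1, −2, −3).
* **Degenerate inputs.**  Queries < 9 nt → status `too_short`; queries with
  no full match in any frame → status `unclassifiable`; a Kruskal–Wallis
  statistic over fully tied ranks is defined as 0.
* **Mode of the rank-sum PMF.**  With even n·(s+1) the central pair is tied;
  the smaller sum is recorded as the mode, so the sign convention is
  deterministic.

## Synthetic data: what it emulates, and what it does not

The generator supplies the study conditions for all tests and benchmarks:

* **Reference fixture** — a seeded sample of stop-free amino-acid trimers
  with (by default all of) their synonymous 9-mers; consistent by
  construction.  Fixtures of 60–200 trimers stand in for the
  secondary-structure-derived reference (7674 trimers / 224,383 9-mers),
  which is not shipped.
* **Genus panel** — 54 genera in 13 taxon groups (45 bacterial-like genera
  across 10 groups, 9 fungal-like across 3), so the s = 54 P-value tables
  apply unchanged; smaller panels rescale s automatically.
* **Profiles** — per taxon group, a base codon preference per synonymous
  family (symmetric Dirichlet, concentration 0.1: strongly skewed, well
  separated) and a base trimer preference (concentration 0.3); each genus
  draws around its group base with total concentration mass 100, so genera
  within a group are similar but distinguishable.  Coding sequence chains
  reference trimers rendered through the genus codon preference; non-coding
  sequence is an order-0 nucleotide model per genus (Dirichlet(10) over
  ACGT — GC content roughly 35–65%), the minimal model creating the
  coding/non-coding contrast.
* **Fragments** — the sampling protocol cuts 150–300 bp at uniform random
  starts, default 100 per genus per database type, recording the true
  reading frame of coding fragments.

Real data differ in ways the generator does not emulate: codons are drawn
independently per residue, so there is no genuine codon-context effect (the
standardized-usage ranking carries no signal beyond sampling noise here,
while in real genomes it is informative); real non-coding sequence has
higher-order structure far beyond an order-0 model, which is why synthetic
non-CDS genus accuracy is near chance although coding/non-coding
discrimination stays above it; and there is no horizontal gene transfer,
nuclear heterogeneity or genus-specific GC skew in coding regions.  Passing
benchmarks therefore demonstrate that the implementation recovers planted
compositional signal — not field accuracy on real metagenomes.

## Problem sizes

Desk-scale runs keep the suite and the acceptance script fast: unit tests
use a 60-trimer reference and a 6-genus panel (15 training sequences of
~450 nt per genus and type, 8 fragments per genus and type); the acceptance
benchmark uses a 200-trimer reference, the full 54-genus panel, 18 training
sequences per genus and type, and 6 fragments per genus and type (648
reads), with the 4500-fragment sampling count computed at the full 100 per
bacterial genus.  The whole acceptance script completes in well under a
minute on one CPU.

## Known limitations

* The trimer-usage argmax over (genus, frame, database type) compares
  softmax-normalised scores across frames with different match counts;
  frames with very few matches occasionally produce sharper score vectors
  and steal the call from the true frame, bounding synthetic frame recovery
  around 60–65% (chance 17%).
* Non-CDS usage databases trained on order-0 synthetic sequence are close to
  their smoothed prior; synthetic non-CDS genus calls are near chance.
* The answer-set cutoff is applied within the winning frame and database
  type only, as specified; near-ties across frames are not merged.
* P-value tables assume the panel size used at fit time; mixing databases
  fitted over different panels is rejected.
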