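# Methods

This note documents the models, parameter choices and numerical decisions
behind `kinomescan`, and what the synthetic-data experiments do and do not
demonstrate.

## Profile-HMM identification

The scorer is a standard match/insert/delete profile HMM evaluated by
Viterbi in log-odds space (bits, relative to the model's background
distribution).  Alignment is fully local: a path may enter at any match
state with uniform probability 1/M and exit any match state at no cost;
residues outside the aligned region score zero (background odds).  This
local construction is what makes *model coverage* meaningful — a partial
domain aligns only the states it actually has, and
`coverage = (last − first + 1)/M` measures the matched fraction of the
model, counting deleted states inside the span but not insertions.

Decisions and defaults:

* **Bit-score threshold `tau = 10`** instead of an E-value cut-off.
  E-value calibration is a property of a specific scoring implementation
  and database size; the decisive filter in the workflow is coverage
  (≥ 50%, boundary inclusive), so identification thresholds on raw bits.
  10 bits means the hit is 2^10 times more likely under the model than
  under background — a conservative floor far below any true domain in the
  synthetic regime (true domains score 20–120 bits) and safely above
  random background (empirically < 10 bits in ≥ 95% of draws).
* **Multi-domain detection** by iterated best-hit-then-mask: report the
  best hit, mask its residues, repeat until the best remaining alignment
  falls below `tau`.  Scores are non-increasing across iterations by
  construction.
* **Ambiguous residues** (X, B, Z, ...) score log-odds 0 — neither
  evidence for nor against.
* The text format is a minimal HMMER3-style dialect; values are negative
  natural logs printed to 10 decimals so a write/read round trip preserves
  probabilities to 1e-9, and the background lives on the `COMPO` line.

The scorer is validated against exhaustive enumeration of all legal state
paths.  The enumeration is exact but exponential, so the exhaustive sweep
runs over all models with M ≤ 3 and all sequences of length ≤ 4 from a
three-letter sub-alphabet, plus randomized full-alphabet spot checks; the
property is alphabet-size-agnostic (per-residue scores enter additively),
so the sub-alphabet sweep exercises every path topology the full alphabet
would.

## Classification and tree concordance

Subfamily assignment is winner-takes-all over the subfamily HMM library
(best Viterbi bit score; `tau_classify = 10` bits below which a gene is
Unclassified; ties within `epsilon = 0.5` bits flagged ambiguous and broken
by score then lexicographic model id — determinism over elegance).

The phylogenetic cross-check builds a neighbour-joining tree from
p-distances over globally aligned kinase-domain sequences (BLOSUM62,
affine gaps open 10 / extend 1).  p-distance is the fraction of mismatched
non-gap columns; a Poisson-corrected variant (−ln(1−p)) is available.  NJ
follows Saitou–Nei exactly, joining the pair minimizing
`Q(i,j) = (n−2)d(i,j) − r_i − r_j` with ties broken on the
lexicographically smallest label pair; negative branch lengths are clamped
to zero and recorded.  On additive matrices the generating topology is
recovered exactly (validated up to n = 8 against enumerated true splits
and cross-checked against scikit-bio's implementation).

*Concordance* needs an explicit rule because "confirmed by tree
inspection" is not computable: a leaf is concordant when its nearest
labelled leaf by path length shares its HMM subfamily.  The rule is local
(robust to deep-branch arrangements) and strict enough that a single
mislabeled leaf in a tight cluster is caught.  Discordance is reported,
never used to override the HMM label.

## Ka/Ks (Nei–Gojobori 1986)

CDS pairs are aligned at the protein level (same aligner settings),
back-translated to codons, and gap columns dropped.  Site counting is the
classical per-position fraction of synonymous single-nucleotide changes;
mutations that would create a stop codon count as nonsynonymous, which
keeps the invariant S + N = 3 × aligned codons exact.  Multi-difference
codons average synonymous/nonsynonymous step counts over all orderings of
single-step paths, excluding orderings that pass through a stop codon and
falling back to all orderings when every path is blocked.  Proportions are
Jukes–Cantor corrected, `K = −¾ ln(1 − 4p/3)`; saturation (p ≥ 3/4) and
Ks = 0 denominators yield NaN rather than exceptions so genome-scale runs
never abort.  The per-codon counts match an independent recursive pathway
oracle on every pair of sense codons, and whole-pair estimates agree with
Biopython's NG86 implementation to 1e-9.

## Collinearity, WGD eras, tandem clusters

Anchors are gene pairs with global-alignment protein identity ≥ 40%
(inclusive), a dependency-free stand-in for a BLASTP screen.  Within each
chromosome pair, anchors are chained by dynamic programming into strictly
monotone chains (increasing on the first chromosome; increasing = plus or
decreasing = minus on the second) with successive rank differences ≤
`max_gap = 25`; chains are extracted greedily best-first (longest chain,
then lexicographically smallest), each anchor used at most once, and
chains shorter than `min_block = 5` are discarded.  The DP maximizes chain
*length* (unit anchor score) rather than an alignment-statistic-weighted
score — simpler, and exactly checkable against brute-force enumeration
(validated for all anchor sets ≤ 12).  `min_block` and `max_gap` mirror
the defaults of the standard collinearity scanner (MATCH_SIZE, MAX_GAPS).

Ks values of block anchor pairs are binned into duplication eras exactly
as the two printed closed intervals: [0.06, 0.39] → 13 Mya, [0.40, 0.80]
→ 59 Mya, everything else (including NaN) → other.  Values between the
intervals (e.g. 0.395) fall into "other"; no boundary smoothing is
applied because none is published.

Tandem clusters are same-chromosome, same-subfamily genes whose successive
rank differences are ≤ `max_intervening + 1` (default 5 intervening
genes), closed transitively; singletons are not clusters.  The exact
window of the original analysis is implicit in its tooling, so the window
is configurable and logged.  Unclassified genes are skipped (a cluster is
defined by a subfamily).

## Expression and networks

Relative expression is `log2(value / mean across tissues)` in tissue mode
and `log2(treatment / control)` in stress mode; the log2 convention is the
standard heat-map scale (a plain-ratio mode is available).  Replicate
columns sharing a tissue label are mean-collapsed first.  Subfamily
profiles **average the normalized intensities across measured members
first and then apply the relative transform** — the stated order of the
workflow, and measurably different from transform-then-average (asserted
on a fixture).  A subfamily is included only when at least one third of
its members are measured; the boundary is inclusive and evaluated in
integer arithmetic (3·measured ≥ total).  Intensities are floored at 1e-6
before logs; floored values are carried and flagged, not dropped.

Network edges require signed Pearson r ≥ 0.7 (positive co-expression; an
|r| mode exists behind a flag) and two-sided p < 0.01 from
`t = r√(n−2)/√(1−r²)`, with n the number of condition columns after
replicate collapse (14 tissue, 24 stress).  No multiple-testing
correction is applied, matching the published procedure.  Hubs are nodes
with degree ≥ 10 (tissue) or ≥ 15 (stress).  All orderings are canonical
so outputs are byte-reproducible.

## Synthetic data

The generators are pure functions of (config, seed).

* **HMM library** — a clan consensus of M = 40 positions with sharp match
  emissions (0.9 on the consensus residue); subfamily models redraw 25% of
  the *variable* positions while conserved motif blocks at the start,
  middle and end of the domain are shared by all subfamilies, mimicking
  the invariant kinase motifs (glycine loop, HRD, DFG).  Members of any
  subfamily therefore hit the clan model across the full domain span
  (high coverage) while scoring decisively best against their own model.
* **Genome** — three chromosomes: two carry 14 dispersed singletons each,
  cycling through seven subfamilies (cycle length 7 keeps dispersed
  same-subfamily genes outside the tandem window) plus one tandem array of
  three; the third carries the duplicated copies of two six-anchor
  collinear blocks, one plus and one minus orientation, with CDS pairs
  evolved to Ks targets 0.2 and 0.6 (the two WGD-era bins).  Planted
  extras: four multi-domain genes, four multi-isoform genes, ~12%
  intronless genes (the proportion such surveys report), three
  truncated-domain (atypical) genes and two non-kinase genes.  The
  generator *verifies* every planted gene against the clan model
  (resampling the rare degenerate draw, with margins clear of the
  pipeline's decision boundaries) so the truth record always describes
  what the emitted sequences really contain.  A layout checker rejects
  configurations whose dispersed/copy placement would create unplanted
  tandem runs.
* **Codon divergence** — substitutions are planted one per codon
  (synonymous or nonsynonymous single-nucleotide changes, never creating
  stops) with counts set to the NG86-expected differences implied by the
  Ks/Ka targets via the inverse Jukes–Cantor map.  This gives the
  estimator direct, oracle-free ground truth; mean recovery at 300 codons
  is within ±0.005 of targets 0.1/0.3/0.6.  Unreachable targets (no
  synonymous sites, or counts exceeding the one-change-per-codon budget)
  raise errors naming the bound.
* **Expression** — each subfamily receives a latent log2 profile over the
  design axis (14 tissues; 24 stress treatments plus 6 shared control
  columns); planted cliques share a scaled common factor giving target
  pairwise population correlation r (shared-factor construction, so only
  non-negative targets are representable); member genes add lognormal
  baselines and per-observation noise (sd 0.3 log2 units, amplitude 2.0 —
  strong but realistic array effect sizes).  Masking withholds a
  configurable set of genes; the default masks one subfamily (outside the
  planted cliques) below the one-third rule.

What passing recovery tests shows — and does not: the synthetic genome
has no sequencing noise, no annotation errors, no split/merged gene
models, no segmental inversions inside blocks and no probe-mapping
ambiguity.  Recovery therefore demonstrates the *correctness of the
algorithms against their own model assumptions*, not robustness to the
failure modes of real annotations.  Network recovery at n = 14 conditions
is inherently stochastic: a planted r = 0.9 edge fails the 0.7 cut-off in
roughly 2% of draws, and a flat latent-factor draw can attenuate a whole
clique, which is the sampling behaviour real compendium analyses face.

## Pipeline determinism and scale

Identical config + seed gives a byte-identical output tree: writes are
canonically ordered, floats formatted explicitly, the run log carries no
timestamps (stage timings go to the console only).  Percentages are
rounded half-up to two decimals and every reported percentage is
recomputable from its stored integer counts.  The default synthetic scale
(51 genes, 3 chromosomes, M = 40 models) runs the full pipeline in about
ten seconds on one CPU, which keeps the whole test suite and the
acceptance script comfortably interactive; all counts scale linearly
except all-vs-all anchor detection and the NJ distance matrix (quadratic
in typical genes).

## Known limitations

* The Viterbi scorer reports bit scores, not E-values; gene sets selected
  at a bit threshold are not directly comparable to E-value-selected sets.
* Only neighbour joining is implemented for the tree cross-check
  (no maximum likelihood, no bootstrap support).
* NG86 is the only Ka/Ks estimator (no maximum-likelihood codon models);
  it is the method the surveyed workflow used.
* Chaining maximizes anchor count, not an e-value-weighted score, and
  anchors come from global-identity screening rather than BLASTP.
* The expression model has no probe-level noise or cross-hybridization;
  normalization of raw arrays is out of scope (tables are ingested
  already normalized).
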