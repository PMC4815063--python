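# Methods

This note documents the models, estimators and design choices behind
`taumap`, the defaults that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Profile hidden Markov models

The model is the classic match/insert/delete profile over the 20-letter
amino-acid alphabet. Node *j* (0…L) groups the states M_j, I_j, D_j; node 0
is the emissionless begin state and node L+1 the end. Seven transition
probabilities leave each node (MM, MI, MD, IM, II, DM, DD); I↔D adjacencies
are not modelled, the standard profile restriction. During construction the
rare paths that would need them (an insert run flanking a delete) are
collapsed onto the match path — score-neutral, because insert emissions
equal the background.

**Construction.** Match columns are exactly those whose *raw* gap fraction
is strictly below `match_gap_threshold` (default 0.5; a tie becomes an
insert column). The raw fraction is used deliberately so that the
match/insert layout never depends on the weighting scheme. Emissions are
smoothed with a single background-proportional pseudocount,
`e_j(a) = (c_ja + α·bg(a)) / (N_j + α)` with α = 1 by default; transitions
use the same α split uniformly over each state's legal targets.
Dirichlet-mixture priors are out of scope: the single-parameter rule is
reproducible and analytically checkable. Sequence weighting is
position-based (each column splits weight 1 equally over the residue types
present; a sequence's weight is its normalized share sum), the usual
correction for taxon-biased ortholog sets. The background is uniform 1/20
by default (optionally empirical) and is recorded inside the model file.
An unknown residue `X` counts as non-gap and contributes uniform 1/20
fractional counts.

**Scoring.** All scores are log-odds in bits against an i.i.d. background
null. Two modes exist: *glocal* (whole sequence through the whole model)
and *local* (free entry into any match state with probability 1/L, free
exit from any match state; flanking residues unscored). Insert emissions
default to the background, so inserts cost only their transitions. The
production scorer is vectorised over model columns with a prefix-scan for
insert runs and within-row recurrence for deletes; a reference
implementation with explicit traceback provides state paths. Viterbi
tie-break: prefer M over D over I, then the lower state index. Forward uses
the same recurrences in log-sum-exp (base 2). Both scorers are verified
against brute-force path enumeration on small models in the test suite.

**Logos.** Column height is the relative entropy
`IC_j = Σ_a e_j(a) log2(e_j(a)/bg(a))` (bits); letter height is
`e_j(a)·IC_j`. The SVG renderer draws scaled glyph outlines with
matplotlib; the TSV table is the canonical output.

**Serialization.** A TSV profile format with `repr`-formatted floats gives
bit-exact round-trips. HMMER3 ASCII import is best-effort: match/insert
emissions and the seven node transitions are read (negative natural logs,
`*` = 0), and the file's COMPO average composition stands in for the
background; alignment-map and extension-statistic lines are ignored.

## Domain scanning and architectures

Each domain class (paralog × repeat, e.g. `MAPT_R2`) has its own profile.
Scanning one protein: per model, the best local hit is found, masked, and
the search repeated while hits clear the bit threshold (default 8 bits,
flag-exposed; bit scores replace database-dependent E-values). A candidate
must also align at least half of the model's match columns — without this
coverage rule, 4–8-residue chance matches occasionally clear 8 bits and
pollute architectures. Pooled candidates are accepted greedily by
descending score, discarding any candidate overlapping an accepted hit by
more than 10% of the shorter hit's length (MTBDs abut with short linkers,
so strict disjointness would split boundary jitter arbitrarily). Each
accepted hit is re-scored by every model on its window ±5 residues; the
argmax assigns the class (ties broken by model-name order), and the margin
to the runner-up is reported.

The KxGS core occupies repeat columns 15–18 with the variable position
('x', Cys in repeats 2–3, Ile/Val in 1 and 4) at column 16. Class models
built from classes carrying the position-12 deletion lose that column, so
core coordinates are translated through the build's match-column map
(`annotate_core_columns`). Architecture strings compact consecutive
same-class hits with run-length notation (`R2x4`) and list every class with
≥2 consecutive copies as an expansion.

## Specificity-determining positions

The statistic is plain residue/group mutual information per column,
estimated from counts over unambiguous residues (gaps and `X` excluded),
with pseudocount α = 0.5 added to every (observed residue, group) cell.
Published SDP tools differ in their internals and are not described to the
level of formulas; this module fixes one defensible statistic and
documents it. The null distribution permutes group labels across rows —
preserving every column's composition — with one shared permutation per
iteration so Z-scores are comparable between columns; 1000 iterations by
default, seed mandatory. `Z = (MI_obs − μ)/σ` (σ from the permutations,
ddof = 1); a degenerate null (σ < 1e-12, e.g. a constant column) gives
Z = 0. Ranks sort by descending Z with ties broken by column order.
Columns where any group has less than 50% residue coverage (flag-exposed)
are reported but excluded from selection — this is what removes the
systematic position-12 deletion column. Selection is `top_k` or a Z
threshold; each selected site gets per-group frequency stacks for
specificity logos.

## SubHMM segmentation and profile–profile matching

Columns with IC ≥ `ic_min` are marked; maximal marked runs separated by at
most `merge_gap` unmarked columns merge, runs shorter than `min_len` are
dropped, and survivors become standalone profiles labelled I, II, … left to
right (library defaults 1.0 bits / 6 / 3). The segmentation rule is this
module's own definition — the upstream splitting method it stands in for is
not specified anywhere reimplementable. Note that IC estimated from few
sequences is biased upward by roughly (19)/(2N·ln 2) bits; with the
pipeline's desk-scale alignments (~12–24 rows) that is ~0.6–1.2 bits, which
is why the pipeline preset raises `ic_min` to 2.5 while the library default
stays at 1.0.

A subHMM slice inherits its parent's internal transitions; begin mass
enters at the slice start and the final node's truncated delete path folds
into the end state. Matching against a target profile scores column pairs
by background-normalised co-emission,
`s(i,j) = log2(Σ_a e1_i(a)·e2_j(a)/bg(a)) − δ`, and takes the best
Smith–Waterman local alignment with affine column-gap penalties. The shift
δ = 1.0 bit keeps the expected score of unrelated column pairs negative —
without it, local alignment theory breaks down and chance coincidences of
conserved columns chain into large scores. Gap penalties default to
open 8.0 / extend 2.0 bits for the same reason. The match probability is
the logistic `1/(1+exp(−(score−s0)/τ))` with s0 = 10.0, τ = 1.5 — constants
calibrated once on simulated clade families (20 replicates: true motif
matches scored ≥ 30 bits, cross-clade noise ≤ 9 bits) and fixed in module
config; the presence threshold `p_min = 0.8` then corresponds to ~12 bits.

## Desk-scale phylogenetics

Distances use pairwise deletion — the repeat alignments carry a systematic
deletion column that complete deletion would discard — and the p, Poisson
(−ln(1−p)) or gamma (α((1−p)^{−1/α}−1), default α = 1.3) corrections.
`X` is treated as missing. NJ is the canonical Q-criterion agglomeration
with two determinism rules: ties in the Q minimum break by the
lexicographic pair of cluster keys (a cluster's key is its smallest leaf
label), and negative branch lengths clamp to zero with the deficit moved to
the sibling so path lengths are preserved. Midpoint rooting places the root
halfway along the longest leaf-to-leaf path (lexicographic tie-break) and
enforces equidistance of the two deepest leaves to numerical precision.
Bootstrap support resamples columns with replacement per replicate
(seeded); support is the percentage of replicate NJ trees containing each
bipartition of the point tree, which itself never depends on the seed.
NJ here is the desk-scale counterpart of large ML/Bayesian analyses, which
are explicitly delegated to external tools.

## The synthetic family generator

The generator emulates the family's documented evolutionary structure:

* two duplications preceding the species radiation
  (MAP4 → MAP2 at stem 0.15, MAP2 → MAPT at stem 0.10 substitutions/site),
  plus a shared pre-radiation stem of 0.05 per paralog so each paralog
  clade subtends a resolvable edge;
* four 33-column repeats per paralog built from a fixed MTBD-like consensus
  with the KxGS core at columns 15–18;
* five planted SDP columns (8, 10, 11, 16, 20 of the repeat frame) with
  per-repeat residue maps; column 16 carries the Ile/Val↔Cys core swap and
  the maps pair repeats 1+4 against 2+3, which is what makes the
  repeat-class consensus tree segregate 1+4 from 2+3;
* a deletion column (position 12) in repeats 1–3;
* a fast, low-conservation N-terminal projection region (90 columns, rate
  ×6 — the region is hypervariable in this family);
* an optional icefish-like tandem expansion: 4 copies of repeat 2 on one
  leaf lineage, each with Lys→Arg at column 15, adjacent to the core Cys,
  giving the 7-repeat architecture `R1-R2x4-R3-R4`.

Substitutions follow a 20-letter Jukes–Cantor-style uniform-replacement
process (P(change) = (19/20)(1−e^{−20b/19}) on a branch of length b), with
per-column rate multipliers imposing the conservation structure: planted
SDP columns ×0.05, KxGS core columns ×0.1, other repeat columns ×0.15
(strong purifying selection — MTBDs are highly conserved), N-terminus ×6.
Indels are N-terminal deletions only (rate 0.02·b per site); the repeats
evolve gap-free apart from the fixed deletion column. The default study
preset uses 12 species at root-to-tip depth 0.2 on a random ultrametric
tree; the architecture-recovery experiments use 34 species (102 proteins).

What the generator does **not** emulate — and hence what passing recovery
tests do and do not show: no rate matrix structure (WAG-like exchange
preferences), no among-site rate variation beyond the fixed multipliers,
no insertions, no alternative splicing, no alignment error (the true
alignment is known by construction), and class models are typically built
from the same simulated sequences they are then asked to classify.
Recovery rates on real, externally assembled ortholog sets will be lower;
the simulator establishes correctness of the machinery, not field
performance.

The spec of planted coordinates deserves one note: the family literature
numbers the core swap inconsistently (the motif is written KxGS at 15–18,
while the swap is sometimes quoted at positions 17–18 of the repeat). This
package fixes the convention K(15)-x(16)-G(17)-S(18) and uses it
consistently in the scanner, the generator and the documentation.

## Pipeline

One global seed derives per-stage seeds as
`SeedSequence((seed, stage_index)) mod 2^31`, so a stage re-run with its
derived seed reproduces the pipeline's output for that stage. Pre-flight
validation rejects unknown config keys and out-of-range values before any
stage executes; every run writes a resolved-config copy, a `run.log`, and a
markdown report whose numbers are read back from the stage TSVs rather than
recomputed. All outputs except the timestamped log are byte-identical on
re-run.

## Numerical conventions and degenerate inputs

Log base 2 everywhere ("bits"). Stochastic vectors validate to 1e-9.
Probability-zero transitions are −∞ in log space and excluded from
tracebacks. An all-gap column has gap fraction 1 and MI 0; a column
constant across all rows has MI 0 and Z 0. Distance corrections refuse
p = 1; distance computation refuses pairs with no comparable columns,
naming the pair. Midpoint rooting refuses all-zero branch lengths. The
profile round-trip uses `repr` floats (shortest exact decimal), so
serialization is bit-exact.

## Problem sizes used in the shipped experiments

The test suite and acceptance script use 12-species families (36 proteins,
147 repeat instances) for SDP and model-building experiments, 34 species
(102 proteins) for architecture recovery, 5 000 sampled sequences for
emission recovery, 50 additive matrices for NJ, 20 clade replicates for
subHMM presence, and 200 random instances for the path-enumeration oracle —
sizes at which each property is sharply testable on a single CPU.
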