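# Methods

`hadroclad` re-creates, as one tested pipeline, a classic species-level
cladistic workflow for hadrosauroid dinosaurs: maximum-parsimony analysis
of a discrete morphological character matrix, followed by a bespoke
probabilistic ancestral-area reconstruction for Hadrosaurinae over three
continental regions, and stratigraphic time calibration of the resulting
cladogram.

## Maximum parsimony

Characters are unordered, equally weighted multistate characters coded
`0`–`9`, with `?` (missing) and `-` (inapplicable) both treated as "any
state" during optimization — the standard treatment for unordered Fitch
optimization when no reductive coding scheme is declared. Polymorphic
cells contribute their observed state set.

**Scoring.** Tree length is computed by two-pass Fitch set-intersection
optimization, vectorized as bitmask operations across all characters.
Per-character bounds are:

- minimum steps `m_i`: the size of the smallest state set hitting every
  non-missing cell, minus one (for singleton-only columns this is the
  count of distinct observed states minus one);
- maximum steps `g_i`: the non-missing cell count minus the largest
  achievable modal-state count. With polymorphic cells the modal count
  lets each polymorphic cell side with the candidate modal state; this
  keeps `m_i <= s_i <= g_i` on every tree but is an upper bound on the
  true tree-wise maximum when polymorphism is present.

Ensemble indices follow CI = Σm_i / S and RI = (G − S)/(G − M). Reports
carry both the all-characters CI and the variant excluding
parsimony-uninformative characters (`m_i = g_i`), since both conventions
circulate in the literature; RI is identical under the two and is
undefined (reported as such) when G = M.

**Search.** Each replicate builds a random-addition Wagner tree (greedy
best insertion, random tie-breaking) and swaps it to a local optimum with
TBR by default (SPR and NNI selectable). Equal-length trees accumulate up
to the hold limit; a strictly better tree restarts the pool. The global
pool across replicates is unbounded and deduplicated. Trees are handled
rooted on the configured outgroup; since Fitch length is invariant to
rooting, this explores unrooted topologies through canonical
representatives. Before MPTs are counted, internal branches whose minimum
optimized length is zero (some most-parsimonious reconstruction assigns
them no change in any character) are collapsed; the rule is switchable
off because printed MPT counts depend on it. Zero-minimum branches and
unambiguous synapomorphies are identified exactly with a uniform-cost
inside/outside dynamic program per character and edge; a synapomorphy is
reported only when every most-parsimonious reconstruction changes state
on the branch and derives the same state (identical under accelerated and
delayed optimization).

**Supports.** Bootstrap proportions resample characters whole (missing
patterns preserved), run a reduced search per replicate, and count the
bipartitions of each replicate's MPT consensus. Bremer decay values are
computed exactly by exhaustive topology enumeration whenever the ingroup
is small enough (≤ 7 ingroup taxa); larger problems retain suboptimal
trees under an increasing margin until every consensus clade is
contradicted, reporting never-contradicted clades as lower bounds.

**Determinism.** Every stochastic stage derives an independent stream
from `(seed, stage, replicate)`: identical configurations give
bit-identical output, and raising a replicate count never reshuffles
earlier replicates.

**Desk scale.** The defaults mirror a traditional full-scale analysis
(1000 random-addition replicates, TBR, 100 trees held, seed 1). The test
suite runs reduced settings (2–10 replicates, hold 10–200), which the
oracle tests show recover complete MPT sets on problems up to 7 taxa.

## Ancestral-area probabilities

Areas are {Asia, NorthAmerica, SouthAmerica}. A species-level terminal is
certain of the region where its material was recovered. Moving rootward,
a node's vector is assembled from its two subclades by the pairwise
multiplication/addition rule with the subclades treated equally: every
ordered pair of child areas (a, b) contributes its probability product to
area a when a = b, and half to each of a and b otherwise. Without
constraints this is provably the arithmetic mean of the child vectors
(the averaging identity), which the property suite checks on random
trees.

The dispersal constraint removes product terms pairing Asia with South
America — the two regions share no direct Late Cretaceous land route, so
any such joint origin term would imply an unobserved intermediate. The
surviving mass is renormalized to a probability vector. Two genuinely
open readings are configurable:

- `constraint_scope`: the exclusion applies at every internal combination
  (default — dispersal impossibility is a property of every split) or
  only at the final (root) addition;
- `renormalize`: on (default — reported vectors are probabilities summing
  to 1) or off.

The worked tribe-level examples (Edmontosaurini 75% Asia / 25% North
America; Kritosaurini 75% North / 25% South America) contain no forbidden
mass, so they are identical under all four setting combinations — the
acceptance suite asserts this insensitivity explicitly. Arithmetic is
exact (`fractions.Fraction`) end to end; percentages are rendered to two
decimals only in reports.

**Polytomies.** A k-furcation is expanded into all (2k−3)!! rooted binary
resolution scenarios (subclades as atomic leaves); each scenario is
evaluated independently and the node's vector is their equal-weight mean.
Nested polytomies resolve independently — subclade vectors are computed
once and shared across scenarios. The default width limit is k = 8
(135135 scenarios); wider polytomies require manually specified
scenarios. A degenerate combination whose every term is forbidden (a
certain-Asia subclade sister to a certain-South-America subclade) raises
an error by default, or falls back to the unconstrained average when
configured.

On the full 21-taxon fixture with its basal trichotomy, the subfamily
root comes out ≈ 76% North America / 22% Asia / 2% South America — a
clear North American majority with an Asian minority. The exact published
point values for this node depend on supplementary arithmetic details and
figure-level topology choices that cannot be reconstructed from the text,
so the pipeline treats this node as a qualitative comparison rather than
an exact target (the tribe-level values above are exact).

## Time calibration

Splits are postulated to predate the oldest first appearance (FAD) among
the clade's members, so each internal node gets a minimum split-age bound
equal to the maximum FAD over descendant tips; nesting makes parent
bounds automatically dominate child bounds. Bounds are "no later than"
statements, never point estimates — no branch-duration model is invented.
Each bound is located in a geological stage from a boundary table shipped
as an editable TSV (GTS 2009 values by default, because time-scale
revisions recalibrate taxon ages); an age exactly on a boundary maps to
the older stage, so a bound at 83.5 Ma reads "end of Santonian". The
fixture's stage-level ranges put the first hadrosaurine split at or
before that boundary.

## Synthetic data

The generator targets the structural properties the pipeline consumes,
not any particular dataset:

- **Trees:** Yule (pure-birth) trees, ultrametric with exponential epoch
  waiting times, default 62 tips.
- **Characters:** unordered multistate (2–4 states per character),
  uniform root state, uniformly random different state on each change
  event. Morphological characters carry no molecular clock, so the
  default change model gives every branch the same change probability
  (`change_rate`, default 0.03 per branch — ≈ 3.7 expected changes per
  character on a 62-taxon tree, comparable to the homoplasy level of
  published hadrosauroid matrices); a clock-like per-branch-length model
  is selectable. Cells are masked to missing at a configurable fraction
  (default 0.30, typical of morphological matrices). 346 characters by
  default.
- **Tip areas:** a root-to-tip Markov walk on the area adjacency graph
  (Asia–NorthAmerica and NorthAmerica–SouthAmerica adjacent); forbidden
  pairs are never traversed in one step, which the audit test verifies
  over > 10⁴ branches.

The recovery experiment (8 taxa × 1000 characters, 100 seeds, per-branch
rate 0.08) recovers the generating topology (strict consensus RF = 0) in
every seed; recovery degrades monotonically as characters are removed.
Passing it shows the estimator is consistent on clock-free, conflict-free
data of this size — it does not certify performance on real matrices,
whose characters are correlated, unevenly sampled, and non-independent in
ways the generator does not emulate.

What the generator deliberately does not model: correlated characters,
ordered/additive characters, fossilization and sampling biases,
within-region structure (e.g. Laramidia vs Appalachia), or
branch-heterogeneous change rates.

## Numerical and design choices

- Exact rational arithmetic in biogeography; integer arithmetic in
  parsimony scoring; floats only at the reporting boundary.
- Newick/NEXUS parsing is delegated to dendropy; serialization is
  emitted directly. Character indices are 1-based in every user-facing
  report, matching published synapomorphy lists.
- Wagner-addition ties break by seeded RNG choice among equal-best
  insertions; swap neighbor order is deterministic.
- The fixture's stratigraphic ranges are stage-level synthetic
  reconstructions (marked as such in the filename); its tip areas follow
  the explicit region statements for each terminal, with the
  Kerberosaurus/Kundurosaurus pair merged into one Asian terminal.
- Known limitations: no implied/successive weighting, no ratchet or
  sectorial searches, no step matrices or ordered characters, no
  likelihood-based range evolution (DEC) or event-based area parsimony
  (DIVA); the full-scale published benchmark (62 × 346 matrix) requires
  the original supplementary matrix file and long searches, and is out of
  desk-scale test scope.
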