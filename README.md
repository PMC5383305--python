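# hadroclad

Maximum-parsimony phylogenetics and ancestral-area biogeography of
hadrosaurine dinosaurs.

Hadrosaurids — the "duck-billed" ornithopods of the Late Cretaceous —
are split into the flat-skulled/solid-crested Hadrosaurinae and the
hollow-crested Lambeosaurinae. Where Hadrosaurinae originated (Asia or
North America?) and how its tribes dispersed between continents are
long-standing questions that hinge on two computations: a cladistic
analysis of a large discrete morphological matrix, and a probabilistic
reconstruction of ancestral continental regions on the resulting
cladogram. `hadroclad` implements both as one reproducible pipeline, for
paleontologists and systematists who want these analyses scripted,
seeded, and testable rather than locked inside GUI workflows.

## What it computes

**Maximum parsimony** (a native TNT-style engine): Fitch two-pass scoring
of unordered multistate characters with missing/inapplicable/polymorphic
cells; random-addition Wagner trees + TBR/SPR/NNI branch swapping with a
hold limit; strict consensus; ensemble indices CI = Σmᵢ/S and
RI = (G−S)/(G−M); nonparametric bootstrap proportions; Bremer decay
values; unambiguous synapomorphy mapping (1-based character numbers).

**Ancestral areas** over {Asia, NorthAmerica, SouthAmerica}: tips are
certain of their region of occurrence; an ancestor's vector combines its
two subclades by the pairwise multiplication/addition rule

P̃(x) = Σ_{(a,b) allowed} P_L(a)·P_R(b)·w(x|a,b),  w = 1 if a=b=x, ½ if
exactly one of a,b is x,

which equals the arithmetic mean of the child vectors when nothing is
forbidden. Product terms pairing Asia with South America (no direct land
route) are excluded and the vector renormalized. Polytomies expand into
all (2k−3)!! binary resolution scenarios, averaged with equal weight.
Arithmetic is exact rational.

**Time calibration:** every split is bounded to be no later than the
oldest first appearance among its descendants, located on an editable
GTS 2009 stage table.

**Synthetic data:** Yule trees, Mk-style unordered characters with
missing data, dispersal-constrained tip-area walks, and the 21-taxon
hadrosaurine consensus fixture used by the worked examples.

## Worked example

Write the bundled hadrosaurine fixture and reconstruct ancestral areas
and split-age bounds for its strict-consensus topology:

```sh
hadroclad fixture --out fix
hadroclad areas fix/consensus.nwk fix/tip_areas.tsv --out areas.tsv
hadroclad chronogram fix/consensus.nwk fix/strat_ranges.tsv --out chron.tsv
```

`areas.tsv` (abridged; columns are percent probabilities):

```
clade                                   Asia_pct  NorthAmerica_pct  SouthAmerica_pct
<all 21 hadrosaurines>                  22.37     75.94             1.68
<Edmontosaurini: Kerberosaurus,...>     75.00     25.00             0.00
<Kritosaurini: Gryposaurus,...>         0.00      75.00             25.00
<E. regalis + E. annectens>             0.00      100.00            0.00
```

Reading: the subfamily as a whole most probably originated in North
America (~76%) with a real Asian alternative (~22%); Edmontosaurini —
*Kerberosaurus* + (*Shantungosaurus* + the two *Edmontosaurus* species) —
carries a 75% probability of an Asian origin, implying a dispersal into
North America along the *Edmontosaurus* stem; Kritosaurini splits 75/25
between North and South America. `chron.tsv` bounds the first
hadrosaurine split at 83.5 Ma, i.e. no later than the end of the
Santonian.

The same numbers come from the library directly:

```python
from hadroclad import ancestral_areas, fixture_hadrosaurinae
tree, areas, ranges = fixture_hadrosaurinae()
vectors = ancestral_areas(tree, areas)
print(vectors[tree.root])   # exact fractions, NorthAmerica majority
```

A full parsimony run on your own NEXUS matrix:

```sh
hadroclad search matrix.nex --outgroup Ouranosaurus_nigeriensis \
    --replicates 1000 --hold 100 --seed 1 --out mpts.nwk
hadroclad consensus mpts.nwk --out consensus.nwk
hadroclad support matrix.nex --outgroup Ouranosaurus_nigeriensis --out support.tsv
```

(Desk-scale runs use fewer replicates; results are bit-reproducible for
a fixed seed.) `hadroclad run matrix.nex areas.tsv ranges.tsv
--outgroup ... --out run/` chains all five stages and writes a manifest
with input checksums and the full configuration.

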