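# Methods

This note documents the models, parameters and design choices behind
`hbnet`, in the spirit of the methods documentation of established
scientific packages: what is computed, under which assumptions, and what the
shipped tests do and do not establish.

## Structure construction

PDB coordinate files carry no bond orders, so complexes are rebuilt from
coordinates. Standard amino acids use bundled templates (atom names, bonds,
one fixed Kekulé pattern per aromatic ring); atoms missing from the file are
added topologically without coordinates and are excluded from every geometric
computation thereafter. Everything else — ligands, waters-with-names, modified
residues whose atom names do not fit a template — goes through generic
perception:

* **Connectivity**: a bond exists when the interatomic distance is at most
  the covalent-radius sum × 1.15 (`covalent_tolerance`). Hydrogens, when
  present in the input, bond only to their nearest heavy atom; metals from a
  configurable element set never bond covalently and become single-atom rigid
  components.
* **Bond orders**: bonds shorter than 0.92 × radius sum are π candidates
  (0.82 for triple candidates between C/N). Connected candidate subgraphs of
  ≤ 16 bonds are solved exhaustively over order assignments; the score is
  lexicographic: (carbon π obligations violated, atoms with forced charge,
  total |forced charge|, length-weighted unmet short-bond demand). A carbon on
  any π-candidate bond must carry exactly one π bond (two when its bonds are
  nearly collinear) — this is what selects the Kekulé pattern in a 5-ring
  whose interior angles cannot distinguish sp² from sp³. Heteroatoms carry no
  obligation, because their lone pairs may conjugate instead of forming a π
  bond; the weighted-demand term then prefers the double bond on the
  proportionally shorter bond (e.g. C=O over C–N in an amide). Larger
  subgraphs fall back to a greedy shortest-bond-first matching. An unsolvable
  component is flagged `unperceived` and kept rigid.
* **Connection**: consecutive standard residues of a chain are joined by a
  peptide bond when the C–N distance is ≤ 1.8 Å; all other inter-component
  links (disulfides, covalent ligands) come from applying the distance
  criterion across component boundaries. CONECT records are merged in when
  present.

The cleanup filter chain applied before prediction mirrors standard practice
for curated complex sets and runs in fixed order: strip hydrogens; resolve
residue entries overlapping the reference ligand (≤ 1 Å atom distance) —
entries whose atoms all match a same-element ligand atom within 1 Å are
duplicates and are removed, entries with alternate locations keep their
best-fitting conformation (minimal mean matched-atom distance) and survive
only if their first altloc is overlap-free; keep the first alternate location
per atom; drop entries overlapping any preceding entry or internally
overlapping. Removing reference-ligand heavy atoms is a hard failure (CLI
exit code 2).

## Normalization and initial hydrogens

Default states follow a fixed physiological-pH convention rather than a
pK<sub>a</sub> computation: carboxylic, phosphoric and sulfonic acids
deprotonated; aliphatic amines, amidines and guanidines protonated; azole
rings neutral (histidine defaults to the Nε2-H tautomer); alcohols, thiols
and amides neutral. Chain termini are recognized structurally: the first
residue of a chain is a real N-terminus (ammonium), a residue with OXT a real
C-terminus (carboxylate); residues flanking an unformed peptide bond are
treated as incomplete parts of an amide bond and stay neutral — the break
nitrogen carries one amide-like hydrogen, the break carbonyl no hydroxyl.

Initial coordinates complete the ideal VSEPR polyhedron of the parent atom:
sp³ 109.47°, sp² 120° (in-plane), sp 180°, with X–H lengths C–H 1.09 Å,
N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å. Water is a special geometry class with
the experimental 104.5° H–O–H angle. Rotationally ambiguous sites (methyls,
ammonium, hydroxyls) start staggered/anti relative to the heaviest vicinal
substituent, chosen by atomic number with a coordinate-based tie-break so
that placement is invariant under atom relabeling. For parents with two or
three fixed heavy neighbours the new directions follow the exterior-bisector
completion: H–X–H angles are then exactly ideal, while H–X–heavy angles equal
the class angle only when the heavy frame itself is ideal (an aromatic CH on
a pentagon sits at 126°, not 120° — the geometry tests therefore assert
H–X–heavy angles only where a single neighbour fully determines them).

## Regions and modes

Variable Mode Regions partition each component disjointly:

* conjugated ring systems (fused rings of π-participating atoms) with at
  least one two-coordinate ring nitrogen, absorbing exocyclic keto/enol
  chalcogens — one region per system;
* acyclic carboxylates, guanidines/amidines, amines (terminal and
  secondary), hydroxyl/thiol rotors — one region each;
* each water; ASN/GLN amide groups (flip); HIS rings additionally flip.

Mode enumeration per kind: rotors take 12 torsions at 30° steps
(`rotor_steps`); waters get an interaction-directed orientation set (donate
toward each nearby partner with the second hydrogen sweeping six azimuths,
lone pairs toward each partner at three azimuths, plus the initial
orientation, deduplicated) rather than a fixed grid; cyclic secondary amines
get protonated (two H) plus two neutral placements; carboxylates get ionized
plus syn/anti neutral acids on either oxygen; ring systems enumerate all
hydrogen-count assignments over their variable positions, each validated by
a Kekulé search (every ring carbon exactly one π bond; an N–H may carry one
and is then a cation; a bare nitrogen must carry one unless ring anions are
enabled via `allow_ring_anions`). The net-charge window for ring systems is
−2…+2 by default, but anionic ring nitrogens are excluded by default:
azolate formation is rare at physiological pH and the reference mode census
for imidazole is two neutral tautomers plus the cation, which is exactly
what the enumeration yields. Per-region mode counts are capped
(`max_modes` = 64), keeping the best by stability.

Stability scores are integers from a plain-text fragment table
(`data/fragment_scores.txt`), summed over matched fragments with
whole-group-first, subgroups-as-fallback decomposition. Only the ordering
matters to the optimizer; the shipped values (e.g. neutral acid +4, neutral
amine +4, ring cation +2 per added proton, minor ring tautomer +1, enol +6)
mimic pK<sub>a</sub>-based preference. Ring-mode classes are derived from
canonical SMILES so that symmetry-equivalent tautomers provably receive
equal scores; exact SMILES entries in the table can override any class
default.

## Interaction model

Each mode is a set of interaction surfaces: one donor surface per polar
hydrogen (axis along X–H) and one acceptor surface per lone pair (carbonyl
oxygens two in-plane lobes at 120°, hydroxyl/ether/water oxygens tetrahedral
lobes, pyridine-type nitrogens one in-plane lobe, sp³ amines one apex lobe;
nitrogens whose lone pair is conjugated — amides, anilines, pyrrole-type —
accept nothing). Pair scores use piecewise-linear ramps that reach exactly
zero at their cutoffs:

| term | distance measure | ideal / cutoff (Å) | weight |
|---|---|---|---|
| hydrogen bond | H···acceptor | 1.9 / 2.6 | −1.0 × f(d)·g(α_D)·g(α_A) |
| metal coordination | metal···acceptor | 2.1 / 3.0 | −1.2 × f(d)·g(α_A) |
| donor–donor | H···H | 1.2 / 1.8 | +2.0 × f(d) |
| donor–metal | H···metal | 1.2 / 1.8 | +2.0 × f(d) |
| acceptor–acceptor | lone-pair probe tips (0.5 Å) | 1.2 / 1.8 | +2.0 × f(d) |

g(α) falls linearly from 1 at 0° to 0 at 70° of axis deviation from the
inter-anchor line. Two calibrations matter and were fixed from the geometry
of correct arrangements: the repulsion ramp ends at 1.8 Å because opposing
hydrogens in a *correct* hydrogen-bond chain (the donor's H and the accepting
water's own H) sit near 1.9 Å, while genuine clashes are ≤ 1.5 Å; and the
acceptor–acceptor probe length is 0.5 Å so that the term fires only when the
anchors themselves approach (≲ 2.8 Å) rather than whenever two lobes face
each other across a normal non-bonded separation. Stability enters the
objective at 0.1 per integer unit (`w_stability`): one ideal hydrogen bond
outweighs a one-unit preference penalty but not a four-unit one. Surface
pairs anchored on the same atom, on bonded atoms, or on atoms sharing a
neighbour never score.

## Optimization

Nodes are regions with per-mode base scores (stability + interactions with
the rigid environment, including template-added-atom exclusion); an edge
carries the matrix of pairwise mode scores and exists only when some mode
pair is nonzero within the 5 Å search radius (strictly larger than every
interaction cutoff, so no nonzero pair is missed). Dominated modes are
pruned with an earlier-index-dominator rule that provably preserves the
lexicographically smallest optimum. Each connected component is solved by
folding degree-≤2 nodes (path/cycle contraction by dynamic programming) and
solving the residual core exhaustively (caps: 12 nodes / 10⁶ combinations);
beyond the caps a deterministic beam search runs and the result is flagged
non-certified. Ties break to the lexicographically smallest mode-index
vector — mode 0 is the normalized default, so unforced regions keep their
default states. The lexicographic optimum is extracted by
restriction-and-recompute: the fold order is fixed by node index, so a
restricted run reproduces the optimal value bit-for-bit when the restricted
mode is optimal, making exact float comparison sound. The brute-force oracle
enumerates the full mode product vectorized; NumPy's first-minimum rule in C
order realizes the same tie-break, and the random-instance generator draws
all scores as dyadic rationals (k/16) so that sums are exact in double
precision under any association — "equal scores" between the two algorithms
is therefore well-defined.

Back-transfer replaces each region's hydrogens, charges and bond orders by
the selected mode (flip modes also exchange the heavy-atom coordinates);
hydrogens outside all regions are untouched. Re-scoring the applied
structure from scratch reproduces the optimizer's total within numerical
round-off (< 10⁻⁹ observed as exactly 0 on the shipped scenarios).

## Evaluation machinery

Hydrogen bonds: N/O donor–acceptor pairs with heavy-atom distance ≤ 3.5 Å
and D–H···A angle ≥ 150°. Undesirable contacts: donor–donor and donor–metal
proximities where exactly one counterpart belongs to the reference ligand
and the other to the ligand or active site (6.5 Å); four pure-distance
precision levels (H···H and H···metal ≤ 1.5/1.8/2.1/2.4 Å) and four combined
levels that additionally bound the heavy-atom distance and both D–H···D
angular deviations. The combined thresholds are a reconstruction — plausible
values labelled as such, monotone across levels by construction.
Acceptor–acceptor contacts are deliberately excluded from the audit (their
orientation cannot be judged without imposing a chemical model on the input)
although they participate in the optimization objective. State
classification compares unique canonical strings: equal → accordant;
different hydrogen count at equal net charge on the same skeleton → redox
(the severe class); different net charge → protonation state; otherwise
tautomer; the `_IE` suffix marks predictions whose complex shows level-2
contacts or fewer hydrogen bonds than the reference.

## Synthetic scenarios: what they show and what they do not

The fixture catalog generates every input programmatically with exact,
single-sourced geometry: a zigzag water wire (segments meeting at 108°,
because a collinear wire cannot accept and donate simultaneously), an
imidazole forced to switch tautomer between an amide donor and a
carboxylate, a serine hydroxyl choosing between two acceptors on its rotor
cone, piperidine/pyrrolidine amines resolving donor clashes by
deprotonation, a forced ASN flip, a histidine with the full tautomer × flip
product, a chain-break dipeptide, and a cleanup exercise with altlocs and
ligand duplicates. Ring geometry uses crystallographic bond lengths (the
perception thresholds genuinely discriminate); residue frames are idealized.

These scenarios exercise every code path under unambiguous geometry — they
demonstrate correctness of the machinery, not predictive accuracy on
experimental structures. Real crystal structures bring distorted geometry,
missing atoms, alternate conformations and chemistry outside the supported
inventory (ring-chain tautomerism, redox ambiguity, exotic valences), none
of which the synthetic catalog represents. The problem sizes used throughout
(single-residue proteins, ≤ 4 waters, networks of ≤ 8 regions in the oracle
suite) were chosen so the whole battery re-runs in seconds; the optimizer
itself is exact at any size where contraction plus the exhaustive core caps
apply.

## Known limitations

* Perception is a bounded search tuned to common chemistry; exotic ligands
  (extended cumulenes, unusual valence states) may perceive differently from
  the reference implementations it stands in for.
* No continuous refinement of hydrogen positions; donors point exactly along
  idealized directions.
* Redox forms are never enumerated — a saturation error in the input cannot
  be repaired, only detected by the classifier.
* The stability table is ordinal, not thermodynamic; absolute energies are
  meaningless and only comparisons within a region matter.
* Crystallographic water *addition* is out of scope; existing waters are
  reoriented only.
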