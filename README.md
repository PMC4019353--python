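# hbnet — hydrogen placement in protein–ligand complexes

Crystal structures in the PDB almost never resolve hydrogen atoms, yet every
downstream use of a protein–ligand complex — docking, scoring, pharmacophore
generation, interaction statistics — needs them. Placing hydrogens is not a
local problem: the orientation of a serine hydroxyl depends on its partners,
a histidine can carry its proton on either ring nitrogen, an aspartate can be
charged or neutral, a ligand may bind in any of several tautomers, and every
water molecule can turn freely. These choices are coupled through the
hydrogen-bond network.

`hbnet` treats the problem as discrete optimization. Each substructure with
interdependent hydrogen positions — a conjugated ring system, a carboxylate,
an amine, a rotatable hydroxyl, a water, a flip-ambiguous ASN/GLN/HIS side
chain — is a **Variable Mode Region (VMR)**, and each of its concrete
hydrogen/charge/bond-order states is a **mode** with an integer stability
score encoding tautomer and pK<sub>a</sub> preference. Modes interact through
geometric **interaction surfaces** (one per polar hydrogen and per lone
pair); a surface pair scores a hydrogen bond, a metal coordination, or a
repulsion (donor–donor, donor–metal, acceptor–acceptor). For a mode selection
*M* the network score is

```
totalScore(M) = Σ_m baseScore(m) + Σ_{m,n} [ interactions(m,n) + repulsions(m,n) ]
```

where `baseScore` combines the intrinsic stability of a mode with its
interactions against the rigid environment. The score-minimal selection is
found **exactly** on each connected component of the VMR graph by dynamic
programming (iterative contraction of degree-≤2 nodes plus exhaustive
solution of small residual cores), with ties broken toward the normalized
default states. The chosen modes are transferred back onto the structure and
written as PDB.

The package also ships the surrounding machinery: PDB reading with the
cleanup filter chain (hydrogen stripping, duplicate/overlap removal, first
alternate locations), residue templates and generic bond-order perception
from 3D coordinates, physiological-pH state normalization, VSEPR-ideal
initial placement, a contact audit at configurable precision levels, a
hydrogen-bond detector (heavy-atom distance ≤ 3.5 Å, D–H···A angle ≥ 150°),
and a tautomer/protonation/redox classifier against reference ligand states.

## Worked example

A bundled synthetic complex places a 4-methylimidazole ligand between a fixed
amide donor and a carboxylate: the default tautomer points its N–H straight
at the amide hydrogen, so the proton position decides between a severe clash
and two good hydrogen bonds.

```
$ hbnet fixtures --scenario imidazole_carboxylate --out complex.pdb
$ hbnet protonate --pdb complex.pdb --ligand IMZ:L:1 --out protonated.pdb --log run.log
wrote protonated.pdb (total score -1.0423)
$ cat run.log
regions: 2
network edges: 1
total score: -1.042309
certified optimal: True
modes: 1 0
$ hbnet audit --pdb protonated.pdb --ligand IMZ:L:1 --level 2
type	atom_a	atom_b	h_distance	heavy_distance	angles
type	donor	hydrogen	acceptor	distance	angle
hbond	IMZ:L:1:N3	IMZ:L:1:H3	FMT:C:1:O1	2.700	180.0
hbond	FMD:B:1:N	FMD:B:1:H1	IMZ:L:1:N1	2.900	179.9
```

`modes: 1 0` says the imidazole VMR switched from its default state (mode 0)
to the alternative tautomer (mode 1) — the proton moved from N1 to N3 — while
the carboxylate stayed ionized. The audit finds no undesirable contacts and
two ideal hydrogen bonds: the ligand now donates to the carboxylate and
accepts from the amide. Disabling tautomer/protonation analysis (`--no-tpa`,
the control arm) freezes the default tautomer and the audit instead reports a
donor–donor clash with an H···H distance of 0.88 Å and no hydrogen bond:

```
$ hbnet protonate --pdb complex.pdb --ligand IMZ:L:1 --out control.pdb --no-tpa
wrote control.pdb (total score 2.0000)
$ hbnet audit --pdb control.pdb --ligand IMZ:L:1 --level 2
type	atom_a	atom_b	h_distance	heavy_distance	angles
donor-donor	IMZ:L:1:N1	FMD:B:1:N	0.880	2.900	0.1,0.1
```

The same objects are available as a library:

```python
from hbnet import protonate, find_hbonds, make_fixture, FixtureSpec

text = make_fixture(FixtureSpec("water_bridge", {"n": 3}))
result = protonate(text)
print(result.total_score, len(find_hbonds(result.complex)))  # -3.8798 4
```

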