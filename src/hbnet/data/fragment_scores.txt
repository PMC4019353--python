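# Integer stability scores for structural fragments, relative to the
# normalized default state of each group (lower = preferred).  Values order
# the tautomeric/protonation preference the optimizer may override when the
# hydrogen-bond network gains enough; they mimic pKa-based ordering at
# physiological pH.  Lines: <pattern-key> <integer>.  Keys are either class
# keys (matched after whole-pattern decomposition) or exact canonical SMILES
# of a variable substructure.
carboxylate 0
carboxylic_acid 4
ammonium 0
amine_neutral 4
cyclic_ammonium 0
cyclic_amine_neutral 4
guanidinium 0
guanidine_neutral 4
amide 0
water 0
rotor 0
ring_default 0
ring_tautomer 1
ring_cation 2
ring_anion 6
enol 6
keto 0
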