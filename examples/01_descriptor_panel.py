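"""Compute the physicochemical descriptor panel for a few pesticides.

The two panel members the permeation classifier runs on are tPSA (polarity,
Å²) and WLogP (Wildman–Crippen lipophilicity); the rest characterise size,
flexibility and hydrogen bonding.
"""

from boiledegg import compute_descriptors

for name, smiles in [
    ("lindane", "ClC1C(Cl)C(Cl)C(Cl)C(Cl)C1Cl"),
    ("chlorpyrifos", "CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl"),
    ("paraquat", "C[n+]1ccc(-c2cc[n+](C)cc2)cc1"),
]:
    d = compute_descriptors(smiles)
    print(f"{name:14s} MW {d.mw:6.1f}  tPSA {d.tpsa:6.2f}  WLogP {d.wlogp:5.2f}  "
          f"HBA {d.n_hba}  HBD {d.n_hbd}  rotatable {d.n_rotatable}")

print("\nLindane's tPSA of 0 marks a fully non-polar organochlorine; "
      "chlorpyrifos' thiophosphoryl group pushes tPSA above 80 Å² "
      "when the extended S/P contributions are included.")
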