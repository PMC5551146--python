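"""Confront predicted intestinal absorption with measured human Fa values.

The bundled table carries 25 pesticides with a curated measured fraction
absorbed (point values or literature bounds). Both sides are dichotomised
at Fa >= 0.30 and the accuracy is the percentage of agreeing labels.
"""

from boiledegg import classify_table, confront, load_measured_fa, measured_from_frame

table, fa_frame = load_measured_fa()
preds = classify_table(table)
result = confront(measured_from_frame(fa_frame), preds)

print(f"accuracy: {result.accuracy:.0f}% ({result.n_concordant}/{result.n_total} concordant)")
print(f"discordant: {', '.join(result.discordant)}")
low = preds.loc[preds["gi_label"] == "low", "name"].tolist()
print(f"predicted GI-low: {', '.join(low)}")
print("\nTCDD is the lone miss: measured absorption is high (likely via dietary "
      "lipid micelles), but its non-polar, highly lipophilic position falls "
      "outside the intestinal ellipse.")
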