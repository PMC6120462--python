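"""Classify the bundled 14-enzyme reference panel (IRED-A .. IRED-N).

Each enzyme's partial active-site segments are read from the packaged
table; the proton-donor residue (187-equivalent) gives the D-type/Y-type
branch, and the 139/194 residue pair gives the predicted stereoselectivity.
One enzyme (IRED-G) is D-type yet carries the (S)-markers - the classifier
flags this donor/selectivity mismatch.
"""

from iredmine import classify_table1

calls, summary = classify_table1()
print(f"{'enzyme':8s} {'donor':7s} {'139':>3s} {'194':>3s} prediction")
for c in calls:
    print(f"{c.id:8s} {c.donor_type:7s} {c.evidence['res_139eq']:>3s} "
          f"{c.evidence['res_194eq']:>3s} {c.prediction}"
          + ("   <- donor/selectivity mismatch" if c.donor_selectivity_mismatch else ""))
print(f"\ndonor counts: {summary['donor_counts']}")
print(f"predictions:  {summary['prediction_counts']}")
print(f"indeterminate (match neither rule): {summary['indeterminate']}")
# S prediction = Pro139 + Phe194; R prediction = V/T/I at 139 + M/L at 194.
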