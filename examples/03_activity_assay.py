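"""Photometric activity arithmetic: specific activity, pH profile,
thermostability and enantiomeric excess.

Specific activity follows A = dOD / (epsilon * l * c_P) with the NADPH
extinction coefficient 2.216 L mmol^-1 cm^-1 at 370 nm; slopes are blank-
corrected against the enzyme-free control before the division.
"""

from iredmine import (
    ActivityResult,
    ProfilePoint,
    SlopeMeasurement,
    aggregate_replicates,
    conversion_and_ee,
    ph_optimum,
    specific_activity,
    thermal_retention,
)

# triplicate measurement at 0.5 mg/mL protein, blank-corrected
replicates = [
    SlopeMeasurement(delta_od=s, blank_delta_od=0.0479, protein_conc=0.5)
    for s in (0.4910, 0.4850, 0.4975)
]
res = aggregate_replicates(replicates)
print(f"specific activity: {res.activity:.3f} +/- {res.sd:.3f} U/mg "
      f"({res.activity_mU:.0f} mU/mg, n={res.n_replicates})")

# pH-activity profile: the optimum is the condition of maximal activity
profile = [
    ProfilePoint(ph, ActivityResult(activity=a, corrected_slope=0.0))
    for ph, a in [(5.0, 0.05), (6.0, 0.21), (7.0, 0.88), (7.5, 0.88), (8.0, 0.41)]
]
optima, normalised = ph_optimum(profile)
print(f"pH optimum: {sorted(optima)}  "
      f"(relative activity at pH 6.0: {normalised[6.0]:.0f} %)")

# thermostability: residual activity after 1 h pre-incubation, vs 30 degC
thermo = [
    ProfilePoint(t, ActivityResult(activity=a, corrected_slope=0.0))
    for t, a in [(30, 0.90), (37, 0.72), (42, 0.45), (50, 0.09)]
]
retention = thermal_retention(thermo, reference_temp=30)
print("thermal retention:", {t: round(r, 2) for t, r in sorted(retention.items())})

# chiral analysis: conversion and ee from chromatographic peak areas
conversion, ee = conversion_and_ee(product_major=995, product_minor=5, substrate=110)
print(f"conversion: {conversion:.1f} %, ee: {ee:.1f} %")
# conversion = product/(product+substrate); ee = (major-minor)/(major+minor).
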