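"""Detect sexually dimorphic transmitter gene expression.

Compares the two sexes' consensus calls over sex-shared neuron classes
and classifies each difference as on/off (expressed in one sex only),
scaling (expressed in both at annotated different intensity), or a
transmitter switch (repertoire gained and lost).
"""

from ntatlas import (
    assign_transmitters,
    default_kb,
    detect_dimorphisms,
    full_atlas_evidence,
    reconcile,
)

kb = default_kb()
calls = reconcile(full_atlas_evidence(kb), kb)
calls_h = [c for c in calls if c.sex == "hermaphrodite"]
calls_m = [c for c in calls if c.sex == "male"]
records = detect_dimorphisms(
    calls_h, calls_m,
    assign_transmitters(calls_h, kb), assign_transmitters(calls_m, kb), kb)

for kind in ("on_off", "scaling", "switch"):
    subset = sorted((r for r in records if r.type == kind),
                    key=lambda r: (r.cell, r.feature))
    print(f"\n{kind} ({len(subset)}):")
    for r in subset:
        extra = f", higher in {r.higher_sex}" if r.higher_sex != "n/a" else ""
        print(f"  {r.cell:<5} {r.feature}{extra}")

print("\nunc-47/VGAT is male-only in six sex-shared classes; AIM switches")
print("from glutamatergic to cholinergic in adult males; PVN scales eat-4")
print("up in males while ADF scales mod-5 up in hermaphrodites.")
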