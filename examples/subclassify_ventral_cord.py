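"""Partition the male ventral-cord CA/CP neurons into molecular sub-classes.

Neurons of one anatomical class can differ in their transmitter gene
profiles.  Partitioning the encoded per-neuron profiles by exact
identity recovers 4 CA and 5 CP sub-classes.
"""

from ntatlas import default_kb, fixture_fig10c, subclass_partition

kb = default_kb()
evidence = fixture_fig10c(kb)

for prefix in ("CA", "CP"):
    groups = subclass_partition(evidence, prefix, kb)
    print(f"{prefix}: {len(groups)} sub-classes")
    for profile, cells in groups:
        desc = ", ".join(f"{g}={lv[0].upper()}" for g, lv in profile)
        print(f"  {'/'.join(cells):<20} {desc}")

print("\nP = present, V = dim/variable; genes absent everywhere in a group")
print("are omitted.  The group count is the number of molecularly distinct")
print("sub-classes within each anatomical class.")
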