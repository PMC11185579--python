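"""Separate uptake-and-release neurons from clearance neurons.

A neuron that expresses an uptake transporter (mod-5/SERT for 5-HT,
snf-3/BGT1 for betaine) but lacks the vesicular monoamine transporter
cat-1/VMAT can only act as a sink; with cat-1 it can re-release what it
takes up.  This runs the classifier on the encoded uptake table.
"""

from ntatlas import assign_transmitters, default_kb, fixture_table1, reconcile

kb = default_kb()
assignments = assign_transmitters(reconcile(fixture_table1(kb), kb), kb)

print(f"{'neuron':>6}  {'transmitter':<8} {'uptake':<6} {'release':<7} verdict")
for a in sorted(assignments, key=lambda a: (a.transmitter, a.cell)):
    if not a.uptakes:
        continue
    verdict = "uptake + synaptic release" if a.vesicular_release else "clearance (sink)"
    print(f"{a.cell:>6}  {a.transmitter:<8} {str(a.uptakes):<6} "
          f"{str(a.vesicular_release):<7} {verdict}")

print("\nAIM and URX lack cat-1 and are 5-HT clearance neurons; RIH and")
print("PGA can re-use taken-up 5-HT for synaptic signaling.")
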