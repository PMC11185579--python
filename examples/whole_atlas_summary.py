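"""Whole-atlas proportions, orphan neurons and co-transmission.

Runs the pipeline over the bundled synthetic whole-atlas
reconstruction (both sexes) and prints system-level summaries: the
fraction of neurons using each transmitter system, the neurons with no
vesicular transporter at all (candidate neuropeptide-only neurons),
and the VGAT-without-GABA census.
"""

from ntatlas import (
    assign_transmitters,
    default_kb,
    find_orphans,
    full_atlas_evidence,
    reconcile,
    summarize_atlas,
)
from ntatlas.reconstruction import unc47_non_gaba_neurons

kb = default_kb()
evidence = full_atlas_evidence(kb)
calls = reconcile(evidence, kb)

for sex in ("hermaphrodite", "male"):
    sex_calls = [c for c in calls if c.sex == sex]
    assigns = assign_transmitters(sex_calls, kb)
    s = summarize_atlas(assigns, kb, sex, calls=sex_calls)
    print(f"\n{sex}: {s.total_neurons} neurons")
    for system, frac in s.fractions.items():
        print(f"  {system:<18} {s.counts[system]:>3} neurons ({frac:.1%})")
    print(f"  co-transmission histogram (released transmitters per cell): "
          f"{s.cotransmission_histogram}")

assigns_all = assign_transmitters(calls, kb)
print("\nOrphan (vesicular-transporter-negative) neuron classes:")
print("  sex-shared:", sorted(find_orphans(assigns_all, calls, kb, "hermaphrodite")))
print("  male-specific:", sorted(find_orphans(assigns_all, calls, kb, "male",
                                              male_specific_only=True)))

print("\nunc-47/VGAT-positive neurons without GABA evidence:")
print("  hermaphrodite:", unc47_non_gaba_neurons(evidence, kb, "hermaphrodite"),
      "of", kb.neuron_total("hermaphrodite"))
print("  male-specific:", unc47_non_gaba_neurons(evidence, kb, "male",
                                                 male_specific_only=True),
      "of", kb.male_specific_neuron_total())
print("\nThese neurons may use an unknown VGAT substrate; the orphans may be")
print("entirely neuropeptidergic.")
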