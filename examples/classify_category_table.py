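"""Classify the monoamine category table and print each neuron's label.

Runs the rule engine on the encoded category table (nine monoamine
pathway genes plus direct staining per neuron class) and prints the
derived category label for a selection of neurons.  Labels like
"tyramine (+ uptake) + betaine (uptake)" mean the neuron satisfies the
synthesis rule for tyramine, re-uptakes it (oct-1), and can release
betaine taken up via snf-3; a trailing "*" marks dim/variable support.
"""

from ntatlas import (
    assign_transmitters,
    categorize,
    default_kb,
    fixture_table2,
    reconcile,
)

kb = default_kb()
evidence = fixture_table2(kb)
calls = reconcile(evidence, kb)
assignments = assign_transmitters(calls, kb)

by_cell = {}
for a in assignments:
    by_cell.setdefault((a.cell, a.sex), []).append(a)

print(f"{len(evidence)} observations -> {len(calls)} consensus calls")
for cell, sex in [
    ("RIM", "hermaphrodite"), ("RIC", "hermaphrodite"), ("R8B", "male"),
    ("MI", "hermaphrodite"), ("CEM", "male"), ("AVL", "hermaphrodite"),
    ("R7A", "male"), ("URX", "hermaphrodite"),
]:
    label = categorize(by_cell.get((cell, sex), []), kb, cell=cell, sex=sex,
                       monoamine_only=True)
    print(f"{cell:>5} ({sex[0]}): {label.label}")

print("\nEach label is a pure function of the neuron's gene-level profile;")
print("dim/variable expression propagates into the trailing '*'.")
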