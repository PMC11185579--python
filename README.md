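# ntatlas

Rule-based neurotransmitter identity inference for the *C. elegans*
nervous system, in both sexes.

In *C. elegans*, neurotransmitter identity is not measured directly but
inferred from the combinatorial expression of **neurotransmitter
pathway genes**: biosynthetic enzymes, vesicular transporters, and
plasma-membrane uptake transporters.  Mapping those genes across all
302 hermaphrodite neurons and 93 male-specific neurons — with evidence
of uneven reliability (CRISPR knock-in reporter alleles, fosmid
reporters, promoter fusions, antibody/direct staining, and CeNGEN
scRNA threshold calls) — turns into a data-integration and rule-logic
problem.  `ntatlas` implements that problem end to end for anyone who
works with marker-gene evidence tables: it reconciles multimodal
observations into consensus calls, applies the field's assignment
rules, enumerates co-transmission, flags candidate novel transmitters,
and compares the sexes.

## The inference logic

Let `E(g)` denote consensus expression of gene `g` (robust or
dim/variable) in a neuron, and `stain(t)` a positive antibody/direct
stain for transmitter `t`.  The core rules are:

| transmitter | synthesis | release | uptake |
|---|---|---|---|
| Glu | `E(eat-4)` suffices | `eat-4`/VGLUT | — |
| ACh | implied by `E(unc-17)` (operon with *cha-1*) | `unc-17`/VAChT | — |
| GABA | `E(unc-25)`/GAD | `unc-47`/VGAT | `stain(GABA) ∧ ¬E(unc-25)` with a route (`snf-11` or recycling via `unc-47`) |
| 5-HT | `E(tph-1) ∧ E(bas-1)` | `cat-1`/VMAT | `E(mod-5)`/SERT |
| DA | `E(cat-2) ∧ E(bas-1)` | `cat-1` | — |
| tyramine | `E(tdc-1) ∧ ¬E(tbh-1)` | `cat-1` | `E(oct-1)` |
| octopamine | `E(tdc-1) ∧ E(tbh-1)` | `cat-1` | — |
| betaine | — (uptake-dominant) | `cat-1` | `E(snf-3)`/BGT1 |

Partial pathways flag candidate novel transmitters: `tph-1` without
`bas-1` → 5-HTP; `bas-1 ∧ tbh-1 ∧ ¬tdc-1` → PEOH?; `bas-1` with no
substrate-supplying enzyme → *bas-1*-dependent unknown monoamine;
`cat-1` or `tbh-1` alone → unknown monoamine; `unc-47` without any
GABA evidence → unknown VGAT substrate.  A positive stain with no
synthesis or uptake route is recorded as *unconventional acquisition*.
Neurons expressing none of the four vesicular transporters are
*orphans* — candidate neuropeptide-only neurons.

Consensus precedence is `reporter_allele > direct/antibody stain >
fosmid_reporter > promoter_transgene > scrna`; scRNA data alone can
establish expression only at 4/4 detection thresholds and never
against an explicit reporter-allele negative.

## Worked example

```python
from ntatlas import (default_kb, fixture_table2, reconcile,
                     assign_transmitters, categorize)

kb = default_kb()
calls = reconcile(fixture_table2(kb), kb)      # 1084 consensus calls
by_cell = {}
for a in assign_transmitters(calls, kb):
    by_cell.setdefault((a.cell, a.sex), []).append(a)

for cell, sex in [("RIM", "hermaphrodite"), ("R8B", "male"),
                  ("MI", "hermaphrodite"), ("AVL", "hermaphrodite")]:
    print(cell, categorize(by_cell[(cell, sex)], kb, monoamine_only=True).label)
```

prints

```
RIM tyramine (+ uptake) + betaine (uptake)
R8B octopamine
MI 5-HTP
AVL unknown monoamine?*
```

RIM synthesizes tyramine (*tdc-1*), re-uptakes it (*oct-1*), and can
release betaine taken up via *snf-3*; R8B makes octopamine but lacks
*cat-1* and so cannot release it vesicularly; MI produces only the
5-HT precursor; AVL carries *cat-1* with no known monoamine pathway —
a candidate carrier of an undiscovered amine (the `*` marks
dim/variable supporting expression).

The `examples/` directory holds one short script per capability
(category classification, uptake-vs-clearance, ventral-cord
sub-classification, whole-atlas summary, scRNA/reporter concordance,
sexual dimorphism, synthetic-atlas recovery).  A thin CLI mirrors the
library: `ntatlas classify|concordance|dimorphism|simulate|summarize`.

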