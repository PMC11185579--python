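# Methods

## Scope and model

`ntatlas` treats neurotransmitter identity as a deterministic function
of per-neuron gene-level expression calls.  The pipeline has four
stages: (1) a **knowledge base** fixes the gene/transmitter/cell
ontology; (2) **consensus** reduces multimodal observations to one
tri-level call per (gene, cell, sex); (3) the **rule engine** converts
each cell's call profile into per-transmitter mode flags (synthesis,
uptake, vesicular release, stain support, unconventional acquisition)
and a category label; (4) atlas-level queries aggregate flags into
proportions, orphan sets, co-transmission tallies and dimorphism
records.  Every stage is a pure function of its inputs; shuffling rows
never changes a result, and this is property-tested.

## Knowledge base

Sixteen loci are modeled: four vesicular transporters (*eat-4*,
*unc-17*, *unc-47*, *cat-1*), seven synthesis enzymes (*unc-25*,
*tph-1*, *bas-1*, *cat-2*, *tdc-1*, *tbh-1*, *hdl-1*), four uptake
transporters (*mod-5*, *snf-3*, *oct-1*, *snf-11*) and the sorting
co-factor *unc-46*.  The gene-role enum carries a fourth value,
`sorting_cofactor`, because *unc-46* is neither enzyme nor transporter;
it is recorded as evidence but never gates GABA assignment (its
expression is largely independent of *unc-47* outside classic
GABAergic neurons).  *cha-1*/ChAT is not modeled separately: ACh
synthesis is implied by *unc-17* (shared operon), with non-vesicular
ACh candidates such as AVJ expressible as evidence flags rather than
rules.  *snf-11* enters only as a prior-literature GABA-uptake
channel.

The biosynthesis steps (TPH-1: Trp→5-HTP; BAS-1: 5-HTP→5-HT and
L-Dopa→DA; CAT-2: Tyr→L-Dopa; TDC-1: Tyr→TA; TBH-1: TA→OA; UNC-25:
Glu→GABA) form a metabolite DAG, checked with networkx at load time.

The cell census ships in the KB YAML: 118 hermaphrodite neuron classes
(302 neurons, including the hermaphrodite-specific HSN and VC) and the
male-specific classes (93 neurons).  The male per-class counts are not
tabulated in any single primary table; the shipped census follows the
adult male wiring-diagram literature and is deliberately stored as
editable config (`census_source` documents this) so an alternative
census can be swapped in without code changes.  Ventral-cord and other
serially numbered classes carry explicit member names (VC1–VC6,
CA1–CA9, CP0–CP9, AS1–AS11, …) so evidence may be recorded at class or
single-neuron granularity; counting expands class-level calls by
member count and member-level calls by one.

Stage is fixed to young adult: larval-tagged rows (e.g. larval-only
*tph-1* in pharyngeal muscle) are stored but excluded from
classification.

## Consensus

Modality precedence: reporter allele > direct/antibody stain > fosmid
reporter > promoter transgene > scRNA.  Within a precedence tier the
strongest level wins.  scRNA-only support yields `present` only at 4/4
detection thresholds (3/4 is capped at `variable_dim`); an explicit
reporter-allele `absent` always wins, with the disagreement kept as a
conflict flag.  Missing (gene, cell) pairs are `absent` — a
closed-world assumption justified by the exhaustiveness of the encoded
tables for the sixteen loci; the atlas-level counting the package
reproduces requires it.  `variable_dim` counts as expressed everywhere
downstream but propagates into a `dim_variable` confidence flag and a
trailing `*` on labels; whether published totals counted dim cells is
not stated in the source, so the default counts them (the flag makes
the alternative a one-line filter).

## Rule engine

The rules are listed in the README.  Decisions the source left open or
stated inconsistently, and how they were fixed here:

* **GABA uptake** requires a positive anti-GABA stain without
  *unc-25*, plus a route: *snf-11* expression or recycling capability
  via *unc-47*.  Stained cells with neither (AVA, AVB) are flagged
  `unconventional_acquisition`, matching their published description.
* **bas-1-dependent unknown monoamine** fires when *bas-1* is
  expressed with no substrate-supplying enzyme (*tph-1*, *cat-2*) and
  without *tbh-1*; *tdc-1* co-expression does not veto it (the printed
  category table assigns the label to tyraminergic HOA and R8A).  When
  *tbh-1* is present the same evidence routes to PEOH? instead.
* **tbh-1-only unknown monoamine** fires for *tbh-1* without *tdc-1*
  and *bas-1* — and without *mod-5*: the printed table gives the label
  to CEM (no *mod-5*) but not to R9B (*mod-5*-positive), so 5-HT
  uptake is treated as accounting for the amine content.  The source
  prints no rationale; this is the package's reading.
* **unc-47 without GABA evidence** generates `unknown_VGAT_substrate`
  even at dim/variable levels, with the dim flag carried on the label
  (default "yes with dim flag" on the open question of whether low
  VGAT yields functional product).
* **Category grammar.**  Labels join canonical components with " + "
  in a fixed order and append `*` when any supporting gene is
  dim/variable.  The printed tables are typographically inconsistent
  ("and" vs "+", "(& uptake)" present or absent for the same flag
  pattern, stars attached to neuron names); a documented normalization
  (`normalize_printed_label`) maps printed labels into the canonical
  grammar — splitting on joiners, rewriting "5-HTP (synthesis)"→
  "5-HTP" and "5-HT (& uptake)"→"5-HT", reordering, and attaching the
  neuron-name star — and the reproduction test requires exact string
  equality after it.
* Glia and other non-neuronal cells run through the same rules but are
  labeled by KB kind and never enter neuron counts.

## Printed-table fixtures

Three printed artefacts ship as code-defined evidence: the monoamine
uptake table, the monoamine category table, and the male ventral-cord
CA/CP profiles.  Encoding rules: `+/−` and the dim-footnote both map
to `variable_dim`; ranges ("CP1–6", "VB1–11") expand per member;
"PVW (m)" is male-only.  Where the two printed tables disagree (NSM
and CEM *mod-5*; I5 *cat-1*), each fixture follows its own table.  The
uptake-table fixture carries one context row (RIM *tdc-1*) whose
synthesis context the printed tyramine section presupposes.  A
transcription template for extending fixtures is simply the documented
TSV schema (`gene, cell, sex, modality, level, scrna_threshold_pass,
stage, provenance[, intensity]`).

## Whole-atlas reconstruction

The complete supplementary expression tables are not redistributed.
`reconstruction.py` builds a *synthetic* whole-atlas table: every
per-class statement printed in the main text is encoded as-is, and
membership reported only in aggregate is filled with plausible classes
until the printed totals hold; the totals (orphans = AVH/BDU/PVM/PVQ/
PVW/RMG + SPD; 95/302 and 61/93 VGAT-without-GABA neurons; ~25% Glu,
>50% ACh, ~10% GABA, ~10% monoamine; eat-4 37-of-38 and unc-17
41/7/1-of-52 concordance buckets) are asserted at construction.
Results computed from it therefore validate the pipeline's
bookkeeping — member expansion, consensus, GABA subtraction, bucket
partitioning — against the printed aggregates; they do not
independently re-derive the biology from raw data, and tests on real
supplementary transcriptions would require the user to supply them in
the documented schema.

## Synthetic atlas generator

`simulate_atlas` emulates the documented phenomena of expression
surveys: per-modality detection dropout (`p_detect_present`,
`p_detect_dim`, defaults 0.9/0.05 — reporter alleles detect nearly
everything, dim-and-variable expression is common), optional false
positives (default 0), and scRNA stringency as a monotone step map
from a latent uniform strength to 0–4 thresholds passed (default cuts
0.05/0.20/0.45/0.80, i.e. a fifth of expressed genes reach 4/4).  Each
synthetic class draws its true profile as the minimal gene set of its
category's defining rule; the default composition mirrors whole-atlas
proportions (cholinergic majority, a quarter glutamatergic, ~10% GABA
and monoamine, a handful of orphans).  The generator does **not**
model per-animal replicates, image intensities, or correlated dropout
between modalities — so passing recovery tests show the logic is
sound under independent Bernoulli detection, not that real microscopy
noise is harmless.  Per draw, the generator records whether every
required gene was observed (`fully_observed`) and whether any spurious
row was emitted; with false positives off, classification is exact for
every fully observed class, and tests assert this draw-by-draw over
many seeds.  Determinism: one `numpy` generator seeded from the
config; identical seeds give identical tables.

## Dimorphism

Comparisons run over sex-shared classes only.  `on_off` needs absence
in one sex; `scaling` needs the optional ordinal intensity annotation
(low/medium/high) on both sides — image-based quantification is out of
scope, so without the annotation only on/off and switches are emitted;
`switch` needs a transmitter gained and another lost (AIM's Glu↔ACh).
Records are symmetric under sex swap except for `higher_sex`.  The
PQR fosmid-era report is not confirmed by the reporter allele and is
therefore absent from the reconstruction.

## Numerical and testing choices

Everything is exact integer/boolean logic except the generator; no
tolerances apply outside the stochastic tests.  The rule engine is
verified flag-for-flag against an independently coded brute-force
evaluator over all 3^10 profiles of the ten classification loci
(uptake loci and stains held at absent/unknown) plus 4000 seeded
random profiles over the full 14-gene × 3-stain grid.  The concordance
closed form (`E[agree_at_4] = n·P(pass=4)`) is checked at n=1000
classes against the 95% binomial interval.  Subset invariants
(release ⇒ transporter expressed; tyramine-synthesis excludes
octopamine) run over 1000 seeded noisy synthetic atlases.  Problem
sizes were chosen so the whole suite completes in seconds on one core
while still exercising every rule path exhaustively.

## Known limitations

* The consensus model is categorical; there is no probabilistic
  weighting of modalities or per-animal variability estimation.
* The whole-atlas reconstruction is a stand-in (see above); per-class
  entries outside the printed anchors are plausible fill, not data.
* AMsh glia GABA remains an open controversy in the source and is left
  unresolved here (no *unc-25* call for AMsh ships in the KB fixtures).
* The male census is literature-derived config, not a computed result.
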