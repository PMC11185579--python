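"""Independent brute-force evaluator of the transmitter assignment rules.

Deliberately written as a flat truth-table over expression booleans,
separate from the package's rule engine, so the two can be compared
flag-for-flag over exhaustive and random profile grids.
"""


def oracle_flags(levels, stains=None):
    """Set of (transmitter, synth, uptake, release, unconventional) tuples."""
    stains = stains or {}

    def e(gene):
        return levels.get(gene, "absent") in ("present", "variable_dim")

    def pos(target):
        return stains.get(target, "absent") in ("present", "variable_dim")

    eat4, unc17, unc25, unc47 = e("eat-4"), e("unc-17"), e("unc-25"), e("unc-47")
    cat1, tph, cat2, bas = e("cat-1"), e("tph-1"), e("cat-2"), e("bas-1")
    tdc, tbh = e("tdc-1"), e("tbh-1")
    mod5, snf3, oct1, snf11 = e("mod-5"), e("snf-3"), e("oct-1"), e("snf-11")

    out = set()
    if eat4:
        out.add(("Glu", True, False, True, False))
    if unc17:
        out.add(("ACh", True, False, True, False))

    if unc25 or pos("GABA"):
        uptake = pos("GABA") and not unc25 and (snf11 or unc47)
        unconventional = pos("GABA") and not unc25 and not uptake
        out.add(("GABA", unc25, uptake, unc47, unconventional))
    elif unc47:
        out.add(("unknown_VGAT_substrate", False, False, True, False))

    ht_synth = tph and bas
    if ht_synth or mod5 or pos("5-HT"):
        unconventional = pos("5-HT") and not ht_synth and not mod5
        out.add(("5-HT", ht_synth, mod5, cat1, unconventional))
    if tph and not bas:
        out.add(("5-HTP", True, False, False, False))

    da_synth = cat2 and bas
    if da_synth or pos("DA"):
        out.add(("DA", da_synth, False, cat1, pos("DA") and not da_synth))

    if (tdc and not tbh) or oct1:
        out.add(("TA", tdc and not tbh, oct1, cat1, False))
    if tdc and tbh:
        out.add(("OA", True, False, cat1, False))

    if snf3:
        out.add(("betaine", False, True, cat1, False))

    if bas and tbh and not tdc:
        out.add(("PEOH_candidate", True, False, cat1, False))
    if bas and not tph and not cat2 and not tbh:
        out.add(("bas1_unknown_MA", True, False, cat1, False))

    if cat1 and not (tph or cat2 or bas or tdc or tbh) and not (mod5 or snf3 or oct1):
        out.add(("unknown_MA", False, False, True, False))
    if tbh and not tdc and not bas and not mod5:
        out.add(("unknown_MA", False, False, cat1, False))
    return out
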