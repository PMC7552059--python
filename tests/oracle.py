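"""Independent brute-force oracle for formula enumeration.

Deliberately written as plain nested loops over the full element grid with a
closed-form hydrogen range per (C, N, O, S, P) — structurally unrelated to
the package's vectorized, mass-sorted database search.
"""

from vdomics.assignment import MONOISOTOPIC_MASS
from vdomics.datamodel import MolecularFormula

MC = MONOISOTOPIC_MASS["c"]
MH = MONOISOTOPIC_MASS["h"]
MN = MONOISOTOPIC_MASS["n"]
MO = MONOISOTOPIC_MASS["o"]
MS = MONOISOTOPIC_MASS["s"]
MP = MONOISOTOPIC_MASS["p"]


def brute_force_candidates(mass, rules):
    """Every rule-conformant formula within tolerance of a neutral mass."""
    half = mass * rules.tolerance_ppm * 1e-6
    lo, hi = mass - half, mass + half
    out = []
    for n in range(rules.n_max + 1):
        for s in range(rules.s_max + 1):
            for p in range(rules.p_max + 1):
                if n + s + p > rules.nsp_max:
                    continue
                base_nsp = n * MN + s * MS + p * MP
                if base_nsp > hi:
                    continue
                o_top = min(rules.o_max, int((hi - base_nsp - MC - MH) // MO))
                for o in range(rules.min_o_per_p * p, o_top + 1):
                    base_o = base_nsp + o * MO
                    for c in range(1, rules.c_max + 1):
                        base = base_o + c * MC
                        if base + MH > hi:
                            break
                        # integer h with total mass inside [lo, hi]
                        h_min = int(-(-(lo - base) // MH))  # ceil
                        h_max = int((hi - base) // MH)
                        for h in range(max(h_min, 1), h_max + 1):
                            if not (lo <= base + h * MH <= hi):
                                continue
                            if h > rules.h_max:
                                continue
                            if not (rules.hc_min * c <= h <= rules.hc_max * c):
                                continue
                            if o > rules.oc_max * c:
                                continue
                            dbe2 = 2 + 2 * c - h + n + p  # 2 * DBE
                            if dbe2 < 0 or dbe2 % 2:
                                continue
                            out.append(MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p))
    return set(out)
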