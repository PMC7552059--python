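"""CHNOSP molecular formula assignment for negative-mode FT-ICR-MS peaks.

Each detected m/z is treated as a singly deprotonated ion [M-H]-, converted
to a neutral monoisotopic mass, and matched against every chemically
plausible CHNOSP composition within a ppm tolerance. Plausibility rules
(element ranges, H/C and O/C bounds, integer non-negative double-bond
equivalents) follow standard marine-DOM assignment practice. When more than
one composition matches a peak, a fixed heteroatom-priority ladder removes
implausible heteroatom-rich candidates in order (NSP, N2S, N3S, N4S, N2P,
N3P, N4P, NS2, S2P); peaks that stay ambiguous after the full pass keep no
formula.

The candidate search enumerates the full element grid for a mass range once
(vectorized) into a sorted :class:`FormulaDatabase`; per-peak lookup is then
a binary search. An independent brute-force enumerator lives in the test
suite as the oracle for this search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .datamodel import MolecularFormula, Peak, Spectrum

logger = logging.getLogger("vdomics")

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "AssignmentRules",
    "FormulaDatabase",
    "Assignment",
    "monoisotopic_mass",
    "mz_to_neutral_mass",
    "neutral_mass_to_mz",
    "get_database",
    "enumerate_candidates",
    "resolve_double_assignments",
    "assign_spectrum",
    "HETEROATOM_PRIORITY",
]

#: Monoisotopic atomic masses in Da (carbon-12 scale).
MONOISOTOPIC_MASS = {
    "c": 12.0,
    "h": 1.007825032,
    "n": 14.003074005,
    "o": 15.994914620,
    "s": 31.972071174,
    "p": 30.973761998,
}

#: Proton mass in Da: neutral mass of an [M-H]- ion is m/z + this.
PROTON_MASS = 1.00727646688

#: Heteroatom-count patterns (n, s, p) deleted in order when a peak has
#: multiple candidate formulas.
HETEROATOM_PRIORITY = (
    (1, 1, 1),  # NSP
    (2, 1, 0),  # N2S
    (3, 1, 0),  # N3S
    (4, 1, 0),  # N4S
    (2, 0, 1),  # N2P
    (3, 0, 1),  # N3P
    (4, 0, 1),  # N4P
    (1, 2, 0),  # NS2
    (0, 2, 1),  # S2P
)


@dataclass(frozen=True)
class AssignmentRules:
    """Plausibility rules and tolerance for formula assignment.

    Element maxima mirror the heteroatom space the priority ladder spans
    (N up to 4, S up to 2, P up to 1); H/C, O/C and DBE bounds are the
    standard elemental-ratio filters for natural organic matter.
    """

    tolerance_ppm: float = 0.5
    c_max: int = 100
    h_max: int = 200
    n_max: int = 4
    o_max: int = 60
    s_max: int = 2
    p_max: int = 1
    nsp_max: int = 5  # combined heteroatom cap; the priority ladder spans up to N4S
    # P in negative-mode DOM spectra is detected as phosphate esters, so a
    # P-containing formula needs at least this many O per P
    min_o_per_p: int = 4
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2
    min_snr: float = 4.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        for name in ("c_max", "h_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_max", "o_max", "s_max", "p_max", "min_o_per_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    return sum(count * MONOISOTOPIC_MASS[el] for el, count in f.counts.items())


def mz_to_neutral_mass(mz: float) -> float:
    """Neutral mass of a singly deprotonated ion: M = m/z + proton mass."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz + PROTON_MASS


def neutral_mass_to_mz(mass: float) -> float:
    """Theoretical [M-H]- m/z of a neutral mass."""
    if mass <= PROTON_MASS:
        raise ValueError(f"neutral mass must exceed the proton mass, got {mass}")
    return mass - PROTON_MASS


class FormulaDatabase:
    """All rule-conformant CHNOSP formulas with neutral mass in a range, mass-sorted.

    Element counts are stored as parallel integer arrays, masses as a sorted
    float array, so a candidate query is one binary search.
    """

    def __init__(self, rules: AssignmentRules, mass_min: float, mass_max: float):
        self.rules = rules
        self.mass_min = mass_min
        self.mass_max = mass_max
        cols = _enumerate_grid(rules, mass_min, mass_max)
        order = np.argsort(cols["mass"], kind="stable")
        self.mass = cols["mass"][order]
        for el in ("c", "h", "n", "o", "s", "p"):
            setattr(self, el, cols[el][order])

    def __len__(self) -> int:
        return len(self.mass)

    def window(self, mass: float, tolerance_ppm: float) -> np.ndarray:
        """Indices of formulas within ``tolerance_ppm`` of a neutral mass."""
        half = mass * tolerance_ppm * 1e-6
        lo = np.searchsorted(self.mass, mass - half, side="left")
        hi = np.searchsorted(self.mass, mass + half, side="right")
        return np.arange(lo, hi)

    def formula(self, i: int) -> MolecularFormula:
        return MolecularFormula(
            c=int(self.c[i]), h=int(self.h[i]), n=int(self.n[i]),
            o=int(self.o[i]), s=int(self.s[i]), p=int(self.p[i]),
        )


def _enumerate_grid(rules: AssignmentRules, mass_min: float, mass_max: float) -> dict:
    """Vectorized exhaustive enumeration of the element grid for one mass range."""
    mh, mn, mo, ms, mp = (
        MONOISOTOPIC_MASS["h"], MONOISOTOPIC_MASS["n"], MONOISOTOPIC_MASS["o"],
        MONOISOTOPIC_MASS["s"], MONOISOTOPIC_MASS["p"],
    )
    out = {k: [] for k in ("c", "h", "n", "o", "s", "p", "mass")}
    c_hi = min(rules.c_max, int(mass_max // 12.0))
    for n in range(rules.n_max + 1):
        for s in range(rules.s_max + 1):
            for p in range(rules.p_max + 1):
                if n + s + p > rules.nsp_max:
                    continue
                hetero = n * mn + s * ms + p * mp
                if hetero + 12.0 + mh > mass_max:
                    continue
                for c in range(1, c_hi + 1):
                    base = hetero + 12.0 * c
                    if base + mh > mass_max:
                        break
                    # H bounds: >=1, parity fixed by integer DBE, DBE >= 0,
                    # and the H/C window.
                    h_lo = max(1, int(np.ceil(rules.hc_min * c)))
                    h_hi = min(rules.h_max, int(np.floor(rules.hc_max * c)),
                               2 * c + n + p + 2)  # DBE >= 0
                    if h_hi < h_lo:
                        continue
                    parity = (n + p) % 2  # h must equal n+p mod 2
                    h_start = h_lo + ((parity - h_lo) % 2)
                    h = np.arange(h_start, h_hi + 1, 2)
                    if h.size == 0:
                        continue
                    o_hi = min(rules.o_max, int(np.floor(rules.oc_max * c)),
                               int((mass_max - base - mh * h_lo) // mo))
                    o_lo = rules.min_o_per_p * p
                    if o_hi < o_lo:
                        continue
                    o = np.arange(o_lo, o_hi + 1)
                    hh, oo = np.meshgrid(h, o, indexing="ij")
                    mass = base + mh * hh + mo * oo
                    keep = (mass >= mass_min) & (mass <= mass_max)
                    if not keep.any():
                        continue
                    hh, oo, mass = hh[keep], oo[keep], mass[keep]
                    k = hh.size
                    out["c"].append(np.full(k, c, dtype=np.int32))
                    out["h"].append(hh.astype(np.int32))
                    out["n"].append(np.full(k, n, dtype=np.int32))
                    out["o"].append(oo.astype(np.int32))
                    out["s"].append(np.full(k, s, dtype=np.int32))
                    out["p"].append(np.full(k, p, dtype=np.int32))
                    out["mass"].append(mass)
    return {
        k: (np.concatenate(v) if v else np.empty(0, dtype=np.int32 if k != "mass" else float))
        for k, v in out.items()
    }


@lru_cache(maxsize=8)
def _cached_database(rules: AssignmentRules, mass_min: float, mass_max: float) -> FormulaDatabase:
    db = FormulaDatabase(rules, mass_min, mass_max)
    logger.info("formula database: %d formulas in [%.1f, %.1f] Da", len(db), mass_min, mass_max)
    return db


def get_database(
    rules: AssignmentRules, mass_min: float = 80.0, mass_max: float = 1000.0
) -> FormulaDatabase:
    """Cached exhaustive formula database covering [mass_min, mass_max] Da."""
    return _cached_database(rules, float(mass_min), float(mass_max))


def enumerate_candidates(
    mass: float, rules: AssignmentRules, db: FormulaDatabase | None = None
) -> list[tuple[MolecularFormula, float]]:
    """All rule-conformant formulas within tolerance of a neutral mass.

    Returns (formula, mass error in ppm) sorted by absolute error; an empty
    list is a valid result.
    """
    if db is None or not (db.mass_min <= mass <= db.mass_max):
        pad = mass * rules.tolerance_ppm * 1e-6 + 0.1
        db = get_database(rules, mass - pad, mass + pad)
    idx = db.window(mass, rules.tolerance_ppm)
    errors = (db.mass[idx] - mass) / mass * 1e6
    order = np.argsort(np.abs(errors), kind="stable")
    return [(db.formula(idx[j]), float(errors[j])) for j in order]


def resolve_double_assignments(
    candidates: list[tuple[MolecularFormula, float]]
) -> MolecularFormula | None:
    """Resolve a multi-candidate peak by the heteroatom-priority ladder.

    Candidates whose (N, S, P) counts equal each pattern are deleted in the
    ladder's printed order, stopping as soon as a single candidate survives.
    If more than one (or none) survives the full pass, the peak keeps no
    formula.
    """
    survivors = [f for f, _ in candidates]
    if len(survivors) <= 1:
        return survivors[0] if survivors else None
    for pattern in HETEROATOM_PRIORITY:
        survivors = [f for f in survivors if (f.n, f.s, f.p) != pattern]
        if len(survivors) == 1:
            return survivors[0]
        if not survivors:
            return None
    return None


@dataclass(frozen=True)
class Assignment:
    """Outcome of assigning one peak: formula (or None) and the reason."""

    peak: Peak
    formula: MolecularFormula | None
    error_ppm: float | None
    status: str  # assigned | no_candidate | ambiguous | sub_threshold


def assign_spectrum(
    spectrum: Spectrum,
    rules: AssignmentRules | None = None,
    db: FormulaDatabase | None = None,
) -> list[Assignment]:
    """Assign every peak of a spectrum.

    Peaks with S/N below ``rules.min_snr`` are flagged sub-threshold and get
    no formula; the rest pass through candidate enumeration and
    double-assignment resolution. The assignment rate is logged.
    """
    rules = rules or AssignmentRules()
    if len(spectrum) == 0:
        return []
    if db is None:
        masses = spectrum.mz + PROTON_MASS
        db = get_database(rules, max(80.0, masses.min() - 1.0), masses.max() + 1.0)
    results = []
    n_assigned = 0
    for peak in spectrum.peaks:
        if peak.snr < rules.min_snr:
            results.append(Assignment(peak, None, None, "sub_threshold"))
            continue
        mass = mz_to_neutral_mass(peak.mz)
        cands = enumerate_candidates(mass, rules, db=db)
        if not cands:
            results.append(Assignment(peak, None, None, "no_candidate"))
            continue
        formula = resolve_double_assignments(cands)
        if formula is None:
            results.append(Assignment(peak, None, None, "ambiguous"))
            continue
        err = next(e for f, e in cands if f == formula)
        results.append(Assignment(peak, formula, err, "assigned"))
        n_assigned += 1
    logger.info(
        "assign_spectrum %s: %d/%d peaks assigned", spectrum.sample_id, n_assigned, len(spectrum)
    )
    return results
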