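"""Molecular indices and compound classification for assigned formulas.

Double-bond equivalents (DBE) and the modified aromaticity index (AImod)
are computed from elemental composition:

    DBE   = 1 + (2C - H + N + P) / 2
    AImod = (1 + C - 0.5 O - S - 0.5 H) / (C - 0.5 O - N - S - P)

AImod is clamped to [0, 1] (0 when numerator or denominator is
non-positive). Formulas are classified into mutually exclusive compound
groups by a fixed precedence: saturated (DBE = 0), aromatic (AImod > 0.5),
highly unsaturated (AImod <= 0.5 and H/C < 1.5), potential protein
(H/C >= 1.5, DBE != 0, N > 0), unsaturated (H/C >= 1.5, DBE != 0).
The precedence makes the overlapping threshold definitions single-valued:
potential proteins are the N-containing subset of the unsaturated group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FormulaTable, MolecularFormula, parse_formula

__all__ = [
    "COMPOUND_CLASSES",
    "MolecularIndices",
    "dbe",
    "aimod",
    "classify",
    "compute_indices",
    "class_fractions",
    "vankrevelen_coords",
]

COMPOUND_CLASSES = (
    "saturated",
    "aromatic",
    "highly_unsaturated",
    "potential_protein",
    "unsaturated",
    "other",
)


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents: 1 + (2C - H + N + P)/2 (integer for valid formulas)."""
    return 1.0 + (2 * f.c - f.h + f.n + f.p) / 2.0


def aimod(f: MolecularFormula) -> float:
    """Modified aromaticity index, clamped to [0, 1]."""
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * f.h
    den = f.c - 0.5 * f.o - f.n - f.s - f.p
    if num <= 0 or den <= 0:
        return 0.0
    return min(num / den, 1.0)


@dataclass(frozen=True)
class MolecularIndices:
    dbe: float
    aimod: float
    hc: float
    oc: float
    label: str


def classify(f: MolecularFormula) -> str:
    """Assign exactly one compound-class label under the fixed precedence."""
    d = dbe(f)
    hc = f.h / f.c
    if d == 0:
        return "saturated"
    if aimod(f) > 0.5:
        return "aromatic"
    if hc < 1.5:  # AImod <= 0.5 here by precedence
        return "highly_unsaturated"
    if d != 0 and hc >= 1.5 and f.n > 0:
        return "potential_protein"
    if d != 0 and hc >= 1.5:
        return "unsaturated"
    return "other"


def compute_indices(f: MolecularFormula) -> MolecularIndices:
    return MolecularIndices(
        dbe=dbe(f), aimod=aimod(f), hc=f.h / f.c, oc=f.o / f.c, label=classify(f)
    )


def class_fractions(
    table: FormulaTable, weighting: str = "intensity"
) -> pd.DataFrame:
    """Per-sample compound-class fractions (rows sum to 1).

    ``weighting="intensity"`` shares out summed normalized intensity per
    class (requires a normalized table); ``"count"`` shares out the number
    of detected formulas.
    """
    if weighting not in ("intensity", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "intensity" and not table.normalized:
        raise ValueError("intensity-weighted class fractions require a normalized table")
    labels = np.array([classify(parse_formula(c)) for c in table.values.columns])
    values = table.values.to_numpy(dtype=float)
    if weighting == "count":
        values = (values > 0).astype(float)
    out = pd.DataFrame(
        0.0, index=table.values.index, columns=list(COMPOUND_CLASSES)
    )
    for cls in COMPOUND_CLASSES:
        mask = labels == cls
        if mask.any():
            out[cls] = values[:, mask].sum(axis=1)
    totals = out.sum(axis=1)
    if (totals == 0).any():
        bad = list(out.index[totals == 0])
        raise ValueError(f"samples with no detected formulas: {bad}")
    return out.div(totals, axis=0)


def vankrevelen_coords(
    table: FormulaTable,
    depth: str,
    arm: str,
    day: int,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Van Krevelen coordinates for one condition.

    Only formulas present (value > 0) in *all* non-excluded replicates of
    the condition are kept; intensity is the mean over those replicates.
    Columns: formula, oc, hc, n_flag, p_flag, cls, mean_rel_intensity.
    """
    samples = [s for s in table.samples_for(depth, arm, day) if not exclude or s not in exclude]
    if not samples:
        raise ValueError(f"no samples for condition ({depth}, {arm}, {day})")
    sub = table.values.loc[samples]
    present = (sub.to_numpy() > 0).all(axis=0)
    rows = []
    for col, keep in zip(sub.columns, present):
        if not keep:
            continue
        f = parse_formula(col)
        rows.append(
            {
                "formula": col,
                "oc": f.o / f.c,
                "hc": f.h / f.c,
                "n_flag": f.n > 0,
                "p_flag": f.p > 0,
                "cls": classify(f),
                "mean_rel_intensity": float(sub[col].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["formula", "oc", "hc", "n_flag", "p_flag", "cls",
                                       "mean_rel_intensity"])
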