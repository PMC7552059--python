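"""Differential detection and fate tracking of virus-derived DOM (vDOM).

vDOM is defined by set logic on per-condition presence sets: the molecular
formulas present (in all analytical replicates) in the treatment at the
induction time point that are present neither in the corresponding control
nor at day 0 in either arm. Persistence compares that set against the final
time point; heteroatom fractions summarize the share of vDOM formulas
containing N, S or P (overlapping categories, so they need not sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datamodel import FormulaTable, MolecularFormula, parse_formula

__all__ = [
    "PresenceSet",
    "VdomReport",
    "presence_set",
    "detect_vdom",
    "vdom_fate",
    "fraction_of_total",
]


@dataclass(frozen=True)
class PresenceSet:
    """Formulas present under one (depth, arm, day) condition."""

    depth: str
    arm: str
    day: int
    formulas: frozenset[MolecularFormula]

    def __len__(self) -> int:
        return len(self.formulas)


def presence_set(
    table: FormulaTable,
    depth: str,
    arm: str,
    day: int,
    rule: str = "all_replicates",
    exclude: set[str] | None = None,
) -> PresenceSet:
    """Presence set of a condition.

    ``rule="all_replicates"`` (default) requires detection (value > 0) in
    every non-excluded replicate; ``"any_replicate"`` requires detection in
    at least one.
    """
    if rule not in ("all_replicates", "any_replicate"):
        raise ValueError(f"unknown presence rule {rule!r}")
    samples = [s for s in table.samples_for(depth, arm, day) if not exclude or s not in exclude]
    if not samples:
        raise ValueError(f"condition ({depth}, {arm}, {day}) absent from table")
    detected = table.values.loc[samples].to_numpy() > 0
    keep = detected.all(axis=0) if rule == "all_replicates" else detected.any(axis=0)
    formulas = frozenset(
        parse_formula(col) for col, k in zip(table.values.columns, keep) if k
    )
    return PresenceSet(depth, arm, day, formulas)


def detect_vdom(
    treat_d6: PresenceSet,
    ctrl_d6: PresenceSet,
    treat_d0: PresenceSet,
    ctrl_d0: PresenceSet,
) -> frozenset[MolecularFormula]:
    """Formulas new in the treatment at induction: treat_d6 minus the union
    of the same-day control and both day-0 arms."""
    sets = (treat_d6, ctrl_d6, treat_d0, ctrl_d0)
    depths = {s.depth for s in sets}
    if len(depths) != 1:
        raise ValueError(f"presence sets from different depths: {sorted(depths)}")
    vdom = treat_d6.formulas - (ctrl_d6.formulas | treat_d0.formulas | ctrl_d0.formulas)
    assert vdom.isdisjoint(ctrl_d6.formulas)
    assert vdom.isdisjoint(treat_d0.formulas)
    assert vdom.isdisjoint(ctrl_d0.formulas)
    return frozenset(vdom)


@dataclass
class VdomReport:
    """Summary of the vDOM set, its persistence and heteroatom content."""

    vdom_set: frozenset[MolecularFormula]
    persistent_set: frozenset[MolecularFormula]
    n_vdom: int = field(init=False)
    removed_fraction: float | None = field(init=False)
    n_fraction: float | None = field(init=False)
    s_fraction: float | None = field(init=False)
    p_fraction: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not self.persistent_set <= self.vdom_set:
            raise ValueError("persistent set must be a subset of the vDOM set")
        self.n_vdom = len(self.vdom_set)
        if self.n_vdom == 0:
            self.removed_fraction = None
            self.n_fraction = self.s_fraction = self.p_fraction = None
            return
        self.removed_fraction = 1.0 - len(self.persistent_set) / self.n_vdom
        self.n_fraction = sum(f.n > 0 for f in self.vdom_set) / self.n_vdom
        self.s_fraction = sum(f.s > 0 for f in self.vdom_set) / self.n_vdom
        self.p_fraction = sum(f.p > 0 for f in self.vdom_set) / self.n_vdom


def vdom_fate(
    vdom: frozenset[MolecularFormula], treat_final: PresenceSet
) -> VdomReport:
    """Persistence report: which vDOM formulas survive to the final time point."""
    persistent = frozenset(vdom & treat_final.formulas)
    return VdomReport(vdom_set=frozenset(vdom), persistent_set=persistent)


def fraction_of_total(
    vdom: frozenset[MolecularFormula], treat_d6: PresenceSet
) -> float:
    """Share of the induction-day treatment formulas that are vDOM."""
    if len(treat_d6) == 0:
        raise ValueError("empty induction-day presence set")
    if not vdom <= treat_d6.formulas:
        raise ValueError("vDOM set must be a subset of the induction-day presence set")
    return len(vdom) / len(treat_d6)
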