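"""Domain types for dissolved organic matter (DOM) molecular analysis.

The unit of identity throughout the pipeline is the elemental composition
(a CHNOSP molecular formula) assigned to a singly deprotonated ion detected
by ultrahigh-resolution mass spectrometry. A :class:`Spectrum` is one
analytical measurement of one sample (or procedural blank); the pipeline's
central container is the :class:`FormulaTable`, a samples x formulas matrix
of (optionally normalized) signal intensities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MASS_WINDOW",
    "DESIGN_DAYS",
    "MolecularFormula",
    "Peak",
    "Spectrum",
    "SampleMeta",
    "FormulaTable",
    "parse_formula",
    "format_formula",
    "FormulaError",
]

#: Broadband acquisition mass window in Da; peaks outside are discarded at read time.
MASS_WINDOW = (92.1, 2000.0)

#: Designed sampling time points of the incubation experiment (days).
DESIGN_DAYS = (0, 6, 14, 55)

_ELEMENTS = ("c", "h", "n", "o", "s", "p")

# Hill order for CHNOSP: carbon, hydrogen, then remaining elements alphabetically.
_HILL_ORDER = (("C", "c"), ("H", "h"), ("N", "n"), ("O", "o"), ("P", "p"), ("S", "s"))

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically inadmissible formula strings."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Elemental composition over C, H, N, O, S, P.

    Equality and hashing are element-count equality; the canonical text form
    (:meth:`__str__`) is Hill order with zero counts and "1" subscripts omitted,
    so formula sets are string-stable.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in _ELEMENTS:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise FormulaError(f"element count {name}={v!r} must be a non-negative integer")
        if self.c < 1:
            raise FormulaError("formula must contain at least one carbon")
        if self.h < 1:
            raise FormulaError("formula must contain at least one hydrogen")

    def __str__(self) -> str:
        parts = []
        for symbol, attr in _HILL_ORDER:
            count = getattr(self, attr)
            if count == 0:
                continue
            parts.append(symbol if count == 1 else f"{symbol}{count}")
        return "".join(parts)

    @property
    def counts(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in _ELEMENTS}


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-order (or any-order) CHNOSP formula string.

    Raises :class:`FormulaError` naming the offending token for unknown
    elements, repeated elements, zero counts, or leftover characters.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r}: unexpected {text[pos:m.start()]!r}")
        if not m.group(0):
            continue
        symbol, digits = m.group(1), m.group(2)
        key = symbol.lower()
        if key not in _ELEMENTS:
            raise FormulaError(f"unknown element {symbol!r} in {text!r}")
        if key in counts:
            raise FormulaError(f"element {symbol!r} repeated in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {symbol!r} in {text!r}")
        counts[key] = count
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    try:
        return MolecularFormula(**{e: counts.get(e, 0) for e in _ELEMENTS})
    except FormulaError as exc:
        raise FormulaError(f"invalid formula {text!r}: {exc}") from exc


def format_formula(f: MolecularFormula) -> str:
    """Canonical Hill-order string for a formula (inverse of :func:`parse_formula`)."""
    return str(f)


@dataclass(frozen=True)
class Peak:
    """One detected mass: m/z in Da (singly charged assumed), intensity, S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mz) and self.mz > 0):
            raise ValueError(f"non-positive or non-finite m/z {self.mz!r}")
        if not (np.isfinite(self.intensity) and self.intensity > 0):
            raise ValueError(f"non-positive or non-finite intensity {self.intensity!r}")
        if not (np.isfinite(self.snr) and self.snr > 0):
            raise ValueError(f"non-positive or non-finite S/N {self.snr!r}")


@dataclass
class Spectrum:
    """One analytical measurement: peaks sorted ascending by m/z."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        mzs = np.array([p.mz for p in self.peaks])
        if len(mzs) > 1 and not np.all(np.diff(mzs) > 0):
            raise ValueError(f"spectrum {self.sample_id}: duplicate m/z values")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def snr(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks])


_DEPTHS = ("surface", "subsurface")
_ARMS = ("treatment", "control", "blank")


@dataclass(frozen=True)
class SampleMeta:
    """Experimental design coordinates of one spectrum.

    Blanks carry ``arm="blank"``; their day/depth fields are ignored.
    """

    sample_id: str
    depth_label: str
    arm: str
    day: int
    replicate: int

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"unknown arm {self.arm!r} (expected one of {_ARMS})")
        if self.arm != "blank":
            if self.depth_label not in _DEPTHS:
                raise ValueError(f"unknown depth {self.depth_label!r}")
            if self.replicate < 1:
                raise ValueError("replicate index must be >= 1")

    @property
    def is_blank(self) -> bool:
        return self.arm == "blank"

    @property
    def condition(self) -> tuple[str, str, int]:
        """(depth, arm, day) — one biological condition measured in replicates."""
        return (self.depth_label, self.arm, self.day)


def validate_sample_metas(metas: list[SampleMeta], allow_free_days: bool = False) -> None:
    """Enforce design uniqueness and the designed time points.

    (depth, arm, day, replicate) must be unique over non-blank samples;
    sample_ids unique overall; non-blank days restricted to the designed
    time points unless ``allow_free_days``.
    """
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    seen = set()
    for m in metas:
        if m.is_blank:
            continue
        key = (m.depth_label, m.arm, m.day, m.replicate)
        if key in seen:
            raise ValueError(f"duplicate design coordinates {key}")
        seen.add(key)
        if not allow_free_days and m.day not in DESIGN_DAYS:
            raise ValueError(
                f"sample {m.sample_id}: day {m.day} is not a designed time point {DESIGN_DAYS}"
            )


@dataclass
class FormulaTable:
    """Samples x formulas matrix of (relative) intensities; 0 = not detected.

    ``values`` is a pandas DataFrame indexed by sample_id with Hill formula
    strings as columns. When ``normalized`` is set, each row sums to 1 over
    detected entries.
    """

    values: pd.DataFrame
    metas: dict[str, SampleMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("formula table values must be finite and non-negative")
        if self.normalized and arr.size:
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized table rows must sum to 1")
        missing = set(self.values.index) - set(self.metas)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def formulas(self) -> list[MolecularFormula]:
        return [parse_formula(c) for c in self.values.columns]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def meta(self, sample_id: str) -> SampleMeta:
        return self.metas[sample_id]

    def samples_for(self, depth: str, arm: str, day: int) -> list[str]:
        """Sample ids of all replicates measured under one condition."""
        return [
            s
            for s in self.values.index
            if not self.metas[s].is_blank and self.metas[s].condition == (depth, arm, day)
        ]
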