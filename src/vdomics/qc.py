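"""Cross-spectrum peak alignment and dataset-level quality control.

The fixed filter order is: S/N threshold (applied during assignment) ->
alignment -> raised detection limit -> minimum occurrence -> blank removal
-> replicate outliers -> normalization. Each filter only ever shrinks the
feature set, is idempotent, and logs before/after counts.

Assigned peaks are aligned by their formula (the formula is the feature
key); unassigned peaks are clustered across spectra by single-linkage
within the ppm tolerance and keyed by their mean m/z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assignment import Assignment, AssignmentRules
from .datamodel import FormulaTable, SampleMeta
from .stats import bray_curtis

logger = logging.getLogger("vdomics")

__all__ = [
    "AlignedPeakMatrix",
    "align_peaks",
    "min_occurrence_filter",
    "raise_detection_limit",
    "blank_filter",
    "flag_replicate_outliers",
    "normalize",
    "run_qc",
]


@dataclass
class AlignedPeakMatrix:
    """Samples x aligned-features matrices of intensity and S/N (0 = not detected).

    Features carry a formula string when assigned, else a representative
    m/z key. Blank spectra are ordinary rows until :func:`blank_filter`
    drops them.
    """

    intensity: pd.DataFrame
    snr: pd.DataFrame
    metas: dict[str, SampleMeta]
    formula_features: list[str] = field(default_factory=list)
    #: per-spectrum minimum detected intensity, recorded at alignment time;
    #: this is the "detection limit" the +5% rule raises
    min_intensity: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.intensity.columns.equals(self.snr.columns) or not self.intensity.index.equals(
            self.snr.index
        ):
            raise ValueError("intensity and snr matrices must be aligned")

    @property
    def blank_samples(self) -> list[str]:
        return [s for s in self.intensity.index if self.metas[s].is_blank]

    @property
    def study_samples(self) -> list[str]:
        return [s for s in self.intensity.index if not self.metas[s].is_blank]

    def n_features(self) -> int:
        return self.intensity.shape[1]

    def _with_features(self, keep: pd.Index) -> "AlignedPeakMatrix":
        return replace(
            self,
            intensity=self.intensity[keep],
            snr=self.snr[keep],
            formula_features=[f for f in self.formula_features if f in set(keep)],
        )


def align_peaks(
    assignments: dict[str, list[Assignment]],
    metas: list[SampleMeta],
    tol_ppm: float = 0.5,
    min_snr: float = 4.0,
) -> AlignedPeakMatrix:
    """Align assigned and unassigned peaks across spectra.

    Sub-threshold peaks (S/N below ``min_snr``) never enter the matrix.
    If one spectrum contributes two peaks to a feature, the higher intensity
    wins (collision logged).
    """
    meta_map = {m.sample_id: m for m in metas}
    samples = [m.sample_id for m in metas]
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    formula_keys: set[str] = set()
    unassigned: list[tuple[float, str, float, float]] = []
    n_collisions = 0

    def put(sample: str, key: str, inten: float, snr: float) -> None:
        nonlocal n_collisions
        prev = cells.get((sample, key))
        if prev is not None:
            n_collisions += 1
            if prev[0] >= inten:
                return
        cells[(sample, key)] = (inten, snr)

    for sample_id, asgs in assignments.items():
        if sample_id not in meta_map:
            raise ValueError(f"assignments for unknown sample {sample_id!r}")
        for a in asgs:
            if a.status == "sub_threshold" or a.peak.snr < min_snr:
                continue
            if a.formula is not None:
                key = str(a.formula)
                formula_keys.add(key)
                put(sample_id, key, a.peak.intensity, a.peak.snr)
            else:
                unassigned.append((a.peak.mz, sample_id, a.peak.intensity, a.peak.snr))

    # single-linkage clustering of unassigned peaks: sort by m/z and split
    # where the gap between neighbours exceeds the tolerance
    unassigned.sort(key=lambda t: t[0])
    cluster: list[tuple[float, str, float, float]] = []

    def flush() -> None:
        if not cluster:
            return
        mzs = [t[0] for t in cluster]
        key = f"mz_{np.mean(mzs):.6f}"
        for _, sample, inten, snr in cluster:
            put(sample, key, inten, snr)
        cluster.clear()

    for item in unassigned:
        if cluster and (item[0] - cluster[-1][0]) > tol_ppm * 1e-6 * cluster[-1][0]:
            flush()
        cluster.append(item)
    flush()

    features = sorted({key for _, key in cells})
    inten = pd.DataFrame(0.0, index=samples, columns=features)
    snr = pd.DataFrame(0.0, index=samples, columns=features)
    for (sample, key), (iv, sv) in cells.items():
        inten.at[sample, key] = iv
        snr.at[sample, key] = sv
    if n_collisions:
        logger.info("align_peaks: %d within-spectrum collisions (kept higher intensity)",
                    n_collisions)
    logger.info("align_peaks: %d features across %d spectra", len(features), len(samples))
    min_intensity = inten.where(inten > 0).min(axis=1)
    return AlignedPeakMatrix(
        intensity=inten, snr=snr, metas=meta_map,
        formula_features=sorted(formula_keys),
        min_intensity=min_intensity,
    )


def min_occurrence_filter(m: AlignedPeakMatrix, k: int = 3) -> AlignedPeakMatrix:
    """Drop features detected in fewer than ``k`` non-blank spectra of the dataset."""
    counts = (m.intensity.loc[m.study_samples] > 0).sum(axis=0)
    keep = m.intensity.columns[counts >= k]
    logger.info("min_occurrence_filter(k=%d): %d -> %d features", k, m.n_features(), len(keep))
    return m._with_features(keep)


def raise_detection_limit(m: AlignedPeakMatrix, factor: float = 1.05) -> AlignedPeakMatrix:
    """Raise each spectrum's detection limit to factor x its minimum detected intensity.

    Entries below the raised limit are set to not-detected. With
    ``factor > 1`` the minimum-intensity peak of every spectrum is removed
    by construction; a spectrum whose intensities are all equal empties
    entirely (warned).
    """
    if factor < 1:
        raise ValueError("detection-limit factor must be >= 1")
    inten = m.intensity.copy()
    snr = m.snr.copy()
    floors = (
        m.min_intensity
        if m.min_intensity is not None
        else inten.where(inten > 0).min(axis=1)
    )
    for sample in inten.index:
        row = inten.loc[sample].to_numpy()
        detected = row > 0
        if not detected.any() or not np.isfinite(floors[sample]):
            continue
        limit = factor * floors[sample]
        kill = detected & (row < limit)
        if factor > 1 and kill.sum() == detected.sum():
            logger.warning("raise_detection_limit: spectrum %s emptied (all intensities equal)",
                           sample)
        row[kill] = 0.0
        inten.loc[sample] = row
        snr.loc[sample] = np.where(kill, 0.0, snr.loc[sample].to_numpy())
    out = replace(m, intensity=inten, snr=snr)
    # a feature that is nowhere detected any more is dropped
    keep = out.intensity.columns[(out.intensity > 0).any(axis=0)]
    return out._with_features(keep)


def blank_filter(
    m: AlignedPeakMatrix, ratio: float = 20.0, blank_majority: int = 7
) -> AlignedPeakMatrix:
    """Remove blank-derived features and drop blank rows.

    A feature is removed from the whole dataset if its maximum blank S/N
    exceeds ``ratio`` times its maximum sample S/N, or if it is detected in
    at least ``blank_majority`` blank spectra.
    """
    blanks = m.blank_samples
    if not blanks:
        logger.warning("blank_filter: no blank spectra present; no-op")
        return m
    samples = m.study_samples
    max_blank = m.snr.loc[blanks].max(axis=0)
    max_sample = m.snr.loc[samples].max(axis=0)
    n_blank_hits = (m.intensity.loc[blanks] > 0).sum(axis=0)
    contaminated = (max_blank > ratio * max_sample) | (n_blank_hits >= blank_majority)
    keep = m.intensity.columns[~contaminated]
    logger.info("blank_filter: removed %d contaminant features; dropping %d blanks",
                int(contaminated.sum()), len(blanks))
    out = m._with_features(keep)
    return replace(
        out,
        intensity=out.intensity.loc[samples],
        snr=out.snr.loc[samples],
        min_intensity=out.min_intensity.loc[samples] if out.min_intensity is not None else None,
    )


def flag_replicate_outliers(
    m: AlignedPeakMatrix,
    method: str = "manual",
    manual_ids: list[str] | None = None,
    threshold: float = 0.5,
) -> list[str]:
    """Identify replicate spectra to exclude downstream.

    ``method="manual"`` returns the configured list; ``method="distance"``
    flags a replicate whose Bray-Curtis dissimilarity to the mean relative
    intensity of its replicate group exceeds ``threshold``. Removing every
    replicate of a condition is an error.
    """
    if method == "manual":
        flagged = list(manual_ids or [])
        unknown = [s for s in flagged if s not in m.intensity.index]
        if unknown:
            raise ValueError(f"manual outlier ids not in matrix: {unknown}")
    elif method == "distance":
        flagged = []
        groups: dict[tuple, list[str]] = {}
        for s in m.study_samples:
            groups.setdefault(m.metas[s].condition, []).append(s)
        for cond, members in groups.items():
            if len(members) < 2:
                continue
            rel = m.intensity.loc[members]
            rel = rel.div(rel.sum(axis=1), axis=0)
            center = rel.mean(axis=0).to_numpy()
            for s in members:
                if bray_curtis(rel.loc[s].to_numpy(), center) > threshold:
                    flagged.append(s)
    else:
        raise ValueError(f"unknown outlier method {method!r}")
    by_cond: dict[tuple, list[str]] = {}
    for s in m.study_samples:
        by_cond.setdefault(m.metas[s].condition, []).append(s)
    for cond, members in by_cond.items():
        if members and all(s in flagged for s in members):
            raise ValueError(f"all replicates of condition {cond} flagged as outliers")
    if flagged:
        logger.info("flag_replicate_outliers: %d spectra flagged: %s", len(flagged), flagged)
    return flagged


def normalize(
    m: AlignedPeakMatrix,
    exclude: list[str] | None = None,
    total: str = "assigned",
) -> FormulaTable:
    """Normalize to relative intensities and keep assigned features only.

    Each assigned feature's intensity is divided by the spectrum's summed
    remaining intensity — over assigned features (default; rows then sum
    to 1) or over all remaining peaks (``total="all_peaks"``). Spectra
    emptied by QC raise an error naming the spectrum.
    """
    if total not in ("assigned", "all_peaks"):
        raise ValueError(f"unknown normalization total {total!r}")
    exclude = set(exclude or [])
    samples = [s for s in m.study_samples if s not in exclude]
    assigned = [f for f in m.formula_features if f in m.intensity.columns]
    sub = m.intensity.loc[samples, assigned]
    denom = (
        sub.sum(axis=1)
        if total == "assigned"
        else m.intensity.loc[samples].sum(axis=1)
    )
    empty = denom[denom == 0]
    if len(empty):
        raise ValueError(f"spectra with no remaining peaks after QC: {list(empty.index)}")
    values = sub.div(denom, axis=0)
    return FormulaTable(
        values=values,
        metas={s: m.metas[s] for s in samples},
        normalized=(total == "assigned"),
    )


def run_qc(
    assignments: dict[str, list[Assignment]],
    metas: list[SampleMeta],
    rules: AssignmentRules | None = None,
    min_occurrence: int = 3,
    detection_limit_factor: float = 1.05,
    blank_ratio: float = 20.0,
    blank_majority: int = 7,
    outlier_ids: list[str] | None = None,
    normalization_total: str = "assigned",
) -> FormulaTable:
    """Full quality-control pipeline in the fixed filter order."""
    rules = rules or AssignmentRules()
    m = align_peaks(assignments, metas, tol_ppm=rules.tolerance_ppm, min_snr=rules.min_snr)
    m = raise_detection_limit(m, factor=detection_limit_factor)
    m = min_occurrence_filter(m, k=min_occurrence)
    m = blank_filter(m, ratio=blank_ratio, blank_majority=blank_majority)
    flagged = flag_replicate_outliers(m, method="manual", manual_ids=outlier_ids or [])
    return normalize(m, exclude=flagged, total=normalization_total)
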