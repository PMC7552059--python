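"""Rarefaction-based diversity indices for OTU tables.

Each sample is repeatedly rarefied (subsampled without replacement) to a
common read depth; per rarefaction, richness (observed OTUs), Shannon
diversity H = -sum p ln p (natural log) and Pielou's evenness
J = H / ln(richness) are computed and summarized as mean +/- sd over the
bootstrap rarefactions. Also provides the low-abundance "Others" taxon
aggregation and the virus-to-cell ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityResult",
    "shannon",
    "pielou",
    "rarefy_bootstrap",
    "aggregate_others",
    "virus_to_cell_ratio",
]


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p over OTUs with count > 0 (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(counts: np.ndarray) -> float:
    """Pielou's evenness J = H / ln(richness); 0 by convention for one OTU."""
    counts = np.asarray(counts, dtype=float)
    richness = int((counts > 0).sum())
    if richness <= 1:
        return 0.0
    return shannon(counts) / np.log(richness)


@dataclass
class DiversityResult:
    """Per-sample mean +/- sd of richness, Shannon and Pielou over rarefactions."""

    summary: pd.DataFrame  # index sample, columns richness/shannon/pielou _mean/_sd
    depth: int
    n_boot: int
    skipped: list[str]


def _rarefy_one(rng: np.random.Generator, counts: np.ndarray, depth: int) -> np.ndarray:
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_bootstrap(
    otu: pd.DataFrame, depth: int = 11000, boots: int = 30, seed: int | None = None
) -> DiversityResult:
    """Bootstrap rarefaction diversity for an OTU count table (OTUs x samples).

    Samples with fewer total reads than ``depth`` are skipped with a warning
    entry in the result. A ``taxonomy`` column, if present, is ignored.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if boots < 1:
        raise ValueError("need at least one bootstrap")
    counts = otu.drop(columns="taxonomy", errors="ignore")
    rng = np.random.default_rng(seed)
    rows = {}
    skipped = []
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        if col.sum() < depth:
            skipped.append(sample)
            continue
        rich, h, j = [], [], []
        for _ in range(boots):
            sub = _rarefy_one(rng, col.astype(np.int64), depth)
            rich.append(int((sub > 0).sum()))
            h.append(shannon(sub))
            j.append(pielou(sub))
        rows[sample] = {
            "richness_mean": float(np.mean(rich)), "richness_sd": float(np.std(rich, ddof=1)) if boots > 1 else 0.0,
            "shannon_mean": float(np.mean(h)), "shannon_sd": float(np.std(h, ddof=1)) if boots > 1 else 0.0,
            "pielou_mean": float(np.mean(j)), "pielou_sd": float(np.std(j, ddof=1)) if boots > 1 else 0.0,
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return DiversityResult(summary=summary, depth=depth, n_boot=boots, skipped=skipped)


def aggregate_others(otu: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Aggregate taxa rare everywhere into "Others"; returns relative abundances.

    A taxon (taxonomy label) is merged into "Others" only if its relative
    abundance stays below ``threshold`` in every sample of the experiment.
    Output columns (samples) sum to 1.
    """
    if "taxonomy" not in otu.columns:
        raise ValueError("OTU table needs a 'taxonomy' column")
    counts = otu.drop(columns="taxonomy")
    by_taxon = counts.groupby(otu["taxonomy"]).sum()
    rel = by_taxon / by_taxon.sum(axis=0)
    rare = (rel < threshold).all(axis=1) & (threshold > 0)
    kept = rel.loc[~rare]
    if rare.any():
        others = rel.loc[rare].sum(axis=0).to_frame("Others").T
        kept = pd.concat([kept, others])
    return kept


def virus_to_cell_ratio(vlp: float, tcc: float) -> float:
    """Virus-like particles per microbial cell (both in counts mL^-1)."""
    if tcc <= 0:
        raise ValueError("total cell count must be positive")
    if vlp < 0:
        raise ValueError("VLP count must be non-negative")
    return vlp / tcc
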