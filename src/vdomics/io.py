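"""Delimited-text readers and writers.

All pipeline inputs are plain delimited text (tab default, comma via
``delimiter=","``): per-spectrum peak lists, the sample design table, the
samples x formulas intensity matrix, OTU count tables and environmental
parameter tables. Every filtering step performed here (the acquisition mass
window) is logged with before/after counts — the audit trail of the pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    MASS_WINDOW,
    FormulaTable,
    MolecularFormula,
    Peak,
    SampleMeta,
    Spectrum,
    format_formula,
    parse_formula,
    validate_sample_metas,
)

logger = logging.getLogger("vdomics")

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_sample_table",
    "write_sample_table",
    "read_formula_table",
    "write_formula_table",
    "read_otu_table",
    "write_otu_table",
    "read_env_table",
    "write_env_table",
    "load_config",
]


class ReadError(ValueError):
    """Malformed input file; the message carries the file and line number."""


def read_peaklist(
    path: str | Path,
    sample_id: str | None = None,
    delimiter: str = "\t",
    mass_window: tuple[float, float] = MASS_WINDOW,
) -> Spectrum:
    """Read one peak list (columns ``mz``, ``intensity``, ``snr``) into a Spectrum.

    Rows outside the acquisition mass window are dropped (count logged).
    Non-numeric cells and non-positive intensities raise :class:`ReadError`
    with the offending line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    required = {"mz", "intensity", "snr"}
    if not required.issubset(df.columns):
        raise ReadError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    peaks = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            mz = float(row.mz)
            intensity = float(row.intensity)
            snr = float(row.snr)
        except (TypeError, ValueError) as exc:
            raise ReadError(f"{path}:{i}: non-numeric cell ({exc})") from exc
        if not mass_window[0] <= mz <= mass_window[1]:
            n_dropped += 1
            continue
        try:
            peaks.append(Peak(mz=mz, intensity=intensity, snr=snr))
        except ValueError as exc:
            raise ReadError(f"{path}:{i}: {exc}") from exc
    if n_dropped:
        logger.info(
            "read_peaklist %s: dropped %d of %d peaks outside mass window %s",
            path.name, n_dropped, len(df), mass_window,
        )
    return Spectrum(sample_id=sample_id, peaks=peaks)


def write_peaklist(spectrum: Spectrum, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "mz": [f"{p.mz:.12g}" for p in spectrum.peaks],
            "intensity": [f"{p.intensity:.12g}" for p in spectrum.peaks],
            "snr": [f"{p.snr:.12g}" for p in spectrum.peaks],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_sample_table(
    path: str | Path, delimiter: str = "\t", allow_free_days: bool = False
) -> list[SampleMeta]:
    """Read the design table ``sample_id depth arm day replicate``.

    Enforces uniqueness of (depth, arm, day, replicate) and, unless
    ``allow_free_days``, the designed time points.
    """
    df = pd.read_csv(Path(path), sep=delimiter, dtype=str)
    required = {"sample_id", "depth", "arm", "day", "replicate"}
    if not required.issubset(df.columns):
        raise ReadError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    metas = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            metas.append(
                SampleMeta(
                    sample_id=str(row.sample_id),
                    depth_label=str(row.depth),
                    arm=str(row.arm),
                    day=int(row.day),
                    replicate=int(row.replicate),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ReadError(f"{path}:{i}: {exc}") from exc
    validate_sample_metas(metas, allow_free_days=allow_free_days)
    n_blanks = sum(m.is_blank for m in metas)
    logger.info("read_sample_table %s: %d samples (%d blanks)", path, len(metas), n_blanks)
    return metas


def write_sample_table(metas: list[SampleMeta], path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "depth": [m.depth_label for m in metas],
            "arm": [m.arm for m in metas],
            "day": [m.day for m in metas],
            "replicate": [m.replicate for m in metas],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def write_formula_table(table: FormulaTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write the samples x formulas matrix, formulas as Hill strings in rows.

    Values are printed at 12 significant digits so :func:`read_formula_table`
    inverts the write bit-exactly at that precision. The ``normalized`` flag
    is recorded in a leading comment line.
    """
    out = table.values.T.copy()
    out.index.name = "formula"
    with open(path, "w") as fh:
        fh.write(f"# normalized={table.normalized}\n")
        fh.write("# meta:" + delimiter)
        fh.write(
            delimiter.join(
                "{}|{}|{}|{}".format(
                    table.metas[s].depth_label,
                    table.metas[s].arm,
                    table.metas[s].day,
                    table.metas[s].replicate,
                )
                for s in out.columns
            )
            + "\n"
        )
        out.to_csv(fh, sep=delimiter, float_format="%.12g")


def read_formula_table(path: str | Path, delimiter: str = "\t") -> FormulaTable:
    normalized = False
    meta_line = None
    with open(path) as fh:
        header_comments = []
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("#"):
                header_comments.append(line)
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep=delimiter, index_col="formula")
    for line in header_comments:
        if "normalized=" in line:
            normalized = line.strip().endswith("True")
        elif line.startswith("# meta:"):
            meta_line = line[len("# meta:"):].strip().split(delimiter)
    values = df.T
    values.index.name = "sample_id"
    metas = {}
    if meta_line is not None:
        for sid, enc in zip(values.index, meta_line):
            depth, arm, day, rep = enc.split("|")
            metas[sid] = SampleMeta(sid, depth, arm, int(day), int(rep))
    else:  # bare matrix without design metadata
        metas = {sid: SampleMeta(sid, "surface", "treatment", 0, i + 1)
                 for i, sid in enumerate(values.index)}
    return FormulaTable(values=values.astype(float), metas=metas, normalized=normalized)


def read_otu_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """OTU count table: rows = OTUs, ``otu_id`` and ``taxonomy`` columns, then samples."""
    df = pd.read_csv(Path(path), sep=delimiter)
    if "otu_id" not in df.columns or "taxonomy" not in df.columns:
        raise ReadError(f"{path}: OTU table needs 'otu_id' and 'taxonomy' columns")
    df = df.set_index("otu_id")
    counts = df.drop(columns="taxonomy")
    if (counts.to_numpy() < 0).any() or not np.allclose(
        counts.to_numpy(), counts.to_numpy().astype(int)
    ):
        raise ReadError(f"{path}: OTU counts must be non-negative integers")
    df[counts.columns] = counts.astype(int)
    return df


def write_otu_table(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index_label="otu_id")


def read_env_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Environmental parameters: rows = samples (index ``sample_id``), numeric columns."""
    df = pd.read_csv(Path(path), sep=delimiter, index_col="sample_id")
    return df.astype(float)


def write_env_table(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index_label="sample_id", float_format="%.12g")


def write_assignments(assignments: dict, path: str | Path, delimiter: str = "\t") -> None:
    """Serialize per-spectrum assignments: sample_id mz intensity snr formula error_ppm status."""
    rows = []
    for sample_id, asgs in assignments.items():
        for a in asgs:
            rows.append(
                {
                    "sample_id": sample_id,
                    "mz": f"{a.peak.mz:.12g}",
                    "intensity": f"{a.peak.intensity:.12g}",
                    "snr": f"{a.peak.snr:.12g}",
                    "formula": "" if a.formula is None else str(a.formula),
                    "error_ppm": "" if a.error_ppm is None else f"{a.error_ppm:.6g}",
                    "status": a.status,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_assignments(path: str | Path, delimiter: str = "\t") -> dict:
    """Inverse of :func:`write_assignments`."""
    from .assignment import Assignment

    df = pd.read_csv(Path(path), sep=delimiter, dtype=str)
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        formula = parse_formula(row.formula) if isinstance(row.formula, str) and row.formula else None
        err = float(row.error_ppm) if isinstance(row.error_ppm, str) and row.error_ppm else None
        peak = Peak(mz=float(row.mz), intensity=float(row.intensity), snr=float(row.snr))
        out.setdefault(str(row.sample_id), []).append(
            Assignment(peak=peak, formula=formula, error_ppm=err, status=str(row.status))
        )
    return out


def load_config(path: str | Path | None) -> dict:
    """Load a YAML configuration file; every threshold in the pipeline is a key."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ReadError(f"{path}: config must be a mapping")
    return cfg


def formulas_to_strings(formulas) -> list[str]:
    return [format_formula(f) if isinstance(f, MolecularFormula) else str(f) for f in formulas]


def strings_to_formulas(strings) -> list[MolecularFormula]:
    return [parse_formula(s) for s in strings]
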