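"""Ground-truth simulator for the prophage-induction DOM experiment.

Generates everything the pipeline consumes, with a known answer key:

* a background CHNOSP formula library with realistic elemental-ratio and
  heteroatom composition, plus a disjoint set of "lysis-product" (vDOM)
  formulas enriched in N, S and P;
* replicate [M-H]- spectra for 2 depths x {treatment, control} x 4 days x
  3 analytical replicates plus procedural blanks, with ppm-scale mass
  jitter, intensity-dependent detection, low-S/N noise peaks and planted
  blank contaminants (one group triggering the 20x blank-S/N rule, one the
  7-of-10 blank-majority rule);
* a day-6 lysis pulse in the treatment of one depth whose formulas are
  attenuated at day 14 and partially removed by day 55;
* OTU count tables for a "bottle-effect bloom" versus a stabilized
  community scenario, and an environmental-parameter table.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import (
    AssignmentRules,
    FormulaDatabase,
    enumerate_candidates,
    get_database,
    neutral_mass_to_mz,
    resolve_double_assignments,
)
from .datamodel import MolecularFormula, Peak, SampleMeta, Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_formula_library",
    "simulate_experiment",
    "generate_otu_table",
    "generate_env_table",
    "ENV_PARAMETERS",
]

ENV_PARAMETERS = ("DOC", "DCAA", "DCCHO", "DFAA", "DFCHO", "TCC", "VLP")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated incubation experiment.

    Defaults mirror the real experiment's design: 1230 vDOM formulas with
    63/28/20% N/S/P content, 58% of them gone by day 55, triplicate
    measurements, 10 blanks, and mass jitter at the instrument's calibration
    error scale. The background library's heteroatom mixture (56% N, 10% S,
    1.5% P) matches the day-0 composition of the sediment porewater DOM.
    """

    seed: int
    n_library: int = 5000
    n_vdom: int = 1230
    vdom_heteroatom_targets: tuple[float, float, float] = (0.63, 0.28, 0.20)
    library_heteroatom_targets: tuple[float, float, float] = (0.56, 0.10, 0.015)
    vdom_removal_prob: float = 0.58
    vdom_day14_attenuation: float = 0.5
    vdom_day55_attenuation: float = 0.4
    mass_jitter_ppm_sd: float = 0.05
    n_noise_peaks: int = 200
    noise_snr_below_threshold_frac: float = 0.7
    n_blanks: int = 10
    replicates: int = 3
    days: tuple[int, ...] = (0, 6, 14, 55)
    depths: tuple[str, ...] = ("surface", "subsurface")
    lysis_depth: str = "subsurface"
    mass_range: tuple[float, float] = (150.0, 650.0)
    # realistic elemental-ratio band for sampled library formulas
    hc_band: tuple[float, float] = (0.7, 2.2)
    oc_band: tuple[float, float] = (0.2, 1.0)
    require_unique_assignment: bool = True
    # log10-intensity model
    intensity_log10_mean: float = 4.0
    intensity_log10_sd: float = 0.5
    library_min_log10: float = 2.5
    vdom_min_log10: float = 3.0
    sample_log10_sd: float = 0.15
    noise_floor: float = 50.0  # S/N = intensity / noise_floor
    # logistic detection-probability curve in log10 intensity
    detection_midpoint_log10: float = 2.0
    detection_scale_log10: float = 0.1
    # planted blank contaminants
    n_blank_shared: int = 5  # library formulas, huge S/N in few blanks (20x rule)
    n_blank_unique: int = 10  # unique formulas in most blanks (7-of-10 rule)
    blank_shared_snr: float = 1.0e6
    blank_shared_hits: int = 5
    blank_unique_hits: int = 8

    def __post_init__(self) -> None:
        for name in ("vdom_removal_prob", "noise_snr_below_threshold_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for t in (*self.vdom_heteroatom_targets, *self.library_heteroatom_targets):
            if not 0 <= t <= 1:
                raise ValueError(f"infeasible heteroatom target {t}")
        if self.replicates < 1 or self.n_blanks < 0:
            raise ValueError("replicates must be >= 1 and n_blanks >= 0")
        if self.lysis_depth not in self.depths:
            raise ValueError(f"lysis depth {self.lysis_depth!r} not among depths")

    def detection_prob(self, intensity: np.ndarray) -> np.ndarray:
        """Monotone map from intensity to detection probability (logistic in log10)."""
        x = (np.log10(np.maximum(intensity, 1e-12)) - self.detection_midpoint_log10)
        return 1.0 / (1.0 + np.exp(-x / self.detection_scale_log10))


@dataclass
class GroundTruth:
    """Answer key for a simulated experiment."""

    library: dict[MolecularFormula, float]  # baseline intensities
    vdom: dict[MolecularFormula, float]
    removed_set: frozenset[MolecularFormula]  # truly absent at the final day
    blank_shared: frozenset[MolecularFormula]  # subset of library
    blank_unique: dict[MolecularFormula, float]
    config: SimulationConfig
    rules: AssignmentRules = field(default_factory=AssignmentRules)

    @property
    def vdom_set(self) -> frozenset[MolecularFormula]:
        return frozenset(self.vdom)

    @property
    def blank_contaminants(self) -> frozenset[MolecularFormula]:
        return self.blank_shared | frozenset(self.blank_unique)

    def to_frame(self) -> pd.DataFrame:
        """Truth ledger as a table (formula, role, baseline intensity, removed flag)."""
        rows = []
        for f, b in sorted(self.library.items(), key=lambda kv: str(kv[0])):
            role = "blank_shared_contaminant" if f in self.blank_shared else "library"
            rows.append({"formula": str(f), "role": role, "baseline_intensity": b,
                         "removed_at_final_day": False})
        for f, b in sorted(self.vdom.items(), key=lambda kv: str(kv[0])):
            rows.append({"formula": str(f), "role": "vdom", "baseline_intensity": b,
                         "removed_at_final_day": f in self.removed_set})
        for f, b in sorted(self.blank_unique.items(), key=lambda kv: str(kv[0])):
            rows.append({"formula": str(f), "role": "blank_unique_contaminant",
                         "baseline_intensity": b, "removed_at_final_day": False})
        return pd.DataFrame(rows)


def _exact_count_flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean vector of length n with exactly round(fraction * n) True, shuffled."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _sample_formulas(
    rng: np.random.Generator,
    db: FormulaDatabase,
    rules: AssignmentRules,
    cfg: SimulationConfig,
    n: int,
    targets: tuple[float, float, float],
    taken: set[MolecularFormula],
) -> list[MolecularFormula]:
    """Sample n distinct formulas matching the heteroatom targets exactly.

    Heteroatom membership (contains N / S / P) is allocated by exact counts;
    compositions come uniformly from the realistic elemental-ratio band of
    the assignment grid, optionally restricted to formulas that the
    assignment rules resolve uniquely over the whole mass-jitter range
    (tolerance widened by six jitter standard deviations), so that sampled
    compounds are mass-resolved from interfering compositions in every
    simulated measurement.
    """
    hc = db.h / db.c
    oc = db.o / db.c
    band = (
        (hc >= cfg.hc_band[0]) & (hc <= cfg.hc_band[1])
        & (oc >= cfg.oc_band[0]) & (oc <= cfg.oc_band[1])
        & (db.mass >= cfg.mass_range[0]) & (db.mass <= cfg.mass_range[1])
    )
    has = {"n": db.n > 0, "s": db.s > 0, "p": db.p > 0}
    flag_n = _exact_count_flags(rng, n, targets[0])
    flag_s = _exact_count_flags(rng, n, targets[1])
    flag_p = _exact_count_flags(rng, n, targets[2])

    check_tol = rules.tolerance_ppm + 6.0 * cfg.mass_jitter_ppm_sd
    pools: dict[tuple[bool, bool, bool], np.ndarray] = {}
    out: list[MolecularFormula] = []
    for i in range(n):
        combo = (bool(flag_n[i]), bool(flag_s[i]), bool(flag_p[i]))
        if combo not in pools:
            mask = band.copy()
            for want, key in zip(combo, ("n", "s", "p")):
                mask &= has[key] if want else ~has[key]
            pools[combo] = np.flatnonzero(mask)
        pool = pools[combo]
        if pool.size == 0:
            raise ValueError(f"infeasible heteroatom combination {combo} for the current rules")
        for _ in range(10_000):
            j = int(rng.choice(pool))
            f = db.formula(j)
            if f in taken:
                continue
            if cfg.require_unique_assignment:
                idx = db.window(float(db.mass[j]), check_tol)
                cands = [(db.formula(int(i)), 0.0) for i in idx]
                if resolve_double_assignments(cands) != f:
                    continue
            taken.add(f)
            out.append(f)
            break
        else:
            raise ValueError("could not sample a fresh formula; pool exhausted")
    return out


def generate_formula_library(
    config: SimulationConfig, rules: AssignmentRules | None = None
) -> GroundTruth:
    """Build the ground-truth formula sets and baseline intensities."""
    rules = rules or AssignmentRules()
    rng = np.random.default_rng([config.seed, 1])
    pad = 1.0
    db = get_database(rules, config.mass_range[0] - pad, config.mass_range[1] + pad)

    taken: set[MolecularFormula] = set()
    library = _sample_formulas(
        rng, db, rules, config, config.n_library, config.library_heteroatom_targets, taken
    )
    vdom = _sample_formulas(
        rng, db, rules, config, config.n_vdom, config.vdom_heteroatom_targets, taken
    )
    blank_unique = _sample_formulas(
        rng, db, rules, config, config.n_blank_unique,
        config.library_heteroatom_targets, taken,
    )

    def baselines(formulas, min_log10):
        out = {}
        for f in formulas:
            x = rng.normal(config.intensity_log10_mean, config.intensity_log10_sd)
            while x < min_log10:
                x = rng.normal(config.intensity_log10_mean, config.intensity_log10_sd)
            out[f] = 10.0**x
        return out

    lib_base = baselines(library, config.library_min_log10)
    vdom_base = baselines(vdom, config.vdom_min_log10)
    unique_base = baselines(blank_unique, config.vdom_min_log10)

    n_removed = int(round(config.vdom_removal_prob * config.n_vdom))
    removed = frozenset(
        rng.choice(np.array(sorted(vdom, key=str), dtype=object), n_removed, replace=False)
    ) if config.n_vdom else frozenset()
    shared = frozenset(
        rng.choice(np.array(sorted(library, key=str), dtype=object),
                   min(config.n_blank_shared, len(library)), replace=False)
    ) if library else frozenset()

    return GroundTruth(
        library=lib_base, vdom=vdom_base, removed_set=removed,
        blank_shared=shared, blank_unique=unique_base,
        config=config, rules=rules,
    )


def _make_spectrum(
    rng: np.random.Generator,
    sample_id: str,
    formulas: list[tuple[MolecularFormula, float]],
    cfg: SimulationConfig,
    rules: AssignmentRules,
    fixed_snr: dict[MolecularFormula, float] | None = None,
) -> Spectrum:
    """One measured spectrum: detected true peaks plus noise peaks."""
    from .assignment import monoisotopic_mass

    mzs, intens, snrs = [], [], []
    for f, baseline in formulas:
        intensity = baseline * 10.0 ** rng.normal(0.0, cfg.sample_log10_sd)
        if rng.random() >= cfg.detection_prob(np.array(intensity)):
            continue
        mz = neutral_mass_to_mz(monoisotopic_mass(f))
        mz *= 1.0 + rng.normal(0.0, cfg.mass_jitter_ppm_sd) * 1e-6
        snr = (
            fixed_snr[f]
            if fixed_snr is not None and f in fixed_snr
            else intensity / cfg.noise_floor
        )
        mzs.append(mz)
        intens.append(intensity)
        snrs.append(snr)

    # spurious noise peaks at low S/N, a configurable fraction below threshold
    if cfg.n_noise_peaks:
        lo = max(92.1, cfg.mass_range[0] - 20.0)
        hi = cfg.mass_range[1] + 20.0
        noise_mz = rng.uniform(lo, hi, cfg.n_noise_peaks)
        # log10(S/N / threshold) ~ Normal(mu, 0.4) with P(below threshold) = frac
        from scipy.stats import norm

        mu = -0.4 * norm.ppf(cfg.noise_snr_below_threshold_frac)
        noise_snr = rules.min_snr * 10.0 ** rng.normal(mu, 0.4, cfg.n_noise_peaks)
        mzs.extend(noise_mz)
        intens.extend(noise_snr * cfg.noise_floor)
        snrs.extend(noise_snr)

    order = np.argsort(mzs)
    peaks: list[Peak] = []
    for i in order:
        if peaks and (mzs[i] - peaks[-1].mz) <= rules.tolerance_ppm * 1e-6 * peaks[-1].mz:
            # peaks closer than the alignment tolerance: keep the stronger one
            if intens[i] > peaks[-1].intensity:
                peaks[-1] = Peak(mz=float(mzs[i]), intensity=float(intens[i]),
                                 snr=float(snrs[i]))
            continue
        peaks.append(Peak(mz=float(mzs[i]), intensity=float(intens[i]), snr=float(snrs[i])))
    return Spectrum(sample_id=sample_id, peaks=peaks)


def simulate_experiment(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> tuple[list[Spectrum], list[SampleMeta]]:
    """Simulate all study and blank spectra of the incubation experiment.

    The lysis pulse (the vDOM set) enters the treatment arm of the
    configured depth at day 6, is attenuated at day 14, and loses its
    removed members at the final day; the other depth simulates the
    no-induction null.
    """
    cfg = config or truth.config
    rules = truth.rules
    rng = np.random.default_rng([cfg.seed, 2])
    lib_items = sorted(truth.library.items(), key=lambda kv: str(kv[0]))
    unique_items = sorted(truth.blank_unique.items(), key=lambda kv: str(kv[0]))
    vdom_items = sorted(truth.vdom.items(), key=lambda kv: str(kv[0]))
    final_day = max(cfg.days)

    spectra: list[Spectrum] = []
    metas: list[SampleMeta] = []
    for depth in cfg.depths:
        for arm in ("treatment", "control"):
            for day in cfg.days:
                for rep in range(1, cfg.replicates + 1):
                    sid = f"{depth}_{arm}_d{day:02d}_r{rep}"
                    formulas = list(lib_items) + list(unique_items)
                    if arm == "treatment" and depth == cfg.lysis_depth and day > 0:
                        if day == final_day:
                            factor = cfg.vdom_day55_attenuation
                            pulse = [
                                (f, b * factor)
                                for f, b in vdom_items
                                if f not in truth.removed_set
                            ]
                        else:
                            factor = cfg.vdom_day14_attenuation if day != cfg.days[1] else 1.0
                            pulse = [(f, b * factor) for f, b in vdom_items]
                        formulas += pulse
                    spectra.append(_make_spectrum(rng, sid, formulas, cfg, rules))
                    metas.append(SampleMeta(sid, depth, arm, day, rep))

    # blanks: unique contaminants in most blanks, library-shared contaminants
    # at extreme S/N in a few
    shared_sorted = sorted(truth.blank_shared, key=str)
    unique_sorted = [f for f, _ in unique_items]
    shared_hits = {
        f: set(rng.choice(cfg.n_blanks, min(cfg.blank_shared_hits, cfg.n_blanks),
                          replace=False))
        for f in shared_sorted
    }
    unique_hits = {
        f: set(rng.choice(cfg.n_blanks, min(cfg.blank_unique_hits, cfg.n_blanks),
                          replace=False))
        for f in unique_sorted
    }
    for b in range(cfg.n_blanks):
        sid = f"blank_{b + 1:02d}"
        formulas = []
        fixed = {}
        for f in shared_sorted:
            if b in shared_hits[f]:
                formulas.append((f, cfg.blank_shared_snr * cfg.noise_floor))
                fixed[f] = cfg.blank_shared_snr
        for f in unique_sorted:
            if b in unique_hits[f]:
                formulas.append((f, truth.blank_unique[f]))
        spectra.append(_make_spectrum(rng, sid, formulas, cfg, rules, fixed_snr=fixed))
        metas.append(SampleMeta(sid, "surface", "blank", 0, b + 1))
    return spectra, metas


def generate_otu_table(
    scenario: str,
    n_otus: int = 500,
    depth_reads: int = 30000,
    days: tuple[int, ...] = (0, 6, 14, 55),
    seed: int = 0,
    n_bloom_otus: int = 3,
) -> pd.DataFrame:
    """OTU count table for a bottle-effect bloom or a stabilized community.

    The bloom scenario shifts an increasing share of the read mass onto a
    few copiotroph OTUs over the incubation (evenness decreases); the
    stabilized scenario keeps the community composition constant so only
    multinomial sampling noise remains.
    """
    if scenario not in ("bloom", "stabilized"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    if depth_reads < 1:
        raise ValueError("read depth must be >= 1")
    rng = np.random.default_rng([seed, 3])
    base = rng.dirichlet(np.full(n_otus, 0.5))
    classes = (
        "Gammaproteobacteria", "Deltaproteobacteria", "Alphaproteobacteria",
        "Flavobacteriia", "Planctomycetacia", "Anaerolineae", "Clostridia",
        "Bacilli", "Phycisphaerae", "Dehalococcoidia", "Acidimicrobiia",
        "Nitrospira",
    )
    probs = np.array([0.16, 0.14, 0.1, 0.1, 0.08, 0.1, 0.06, 0.05, 0.05, 0.06,
                      0.05, 0.05])
    taxonomy = rng.choice(classes, n_otus, p=probs / probs.sum())
    bloom_idx = np.argsort(base)[-n_bloom_otus:]
    taxonomy[bloom_idx] = "Gammaproteobacteria"
    bloom_profile = np.zeros(n_otus)
    bloom_profile[bloom_idx] = 1.0 / n_bloom_otus

    weights = np.linspace(0.0, 0.85, len(days))
    data = {}
    for day, w in zip(days, weights):
        p = base if scenario == "stabilized" else (1 - w) * base + w * bloom_profile
        data[f"d{day:02d}"] = rng.multinomial(depth_reads, p)
    table = pd.DataFrame(data, index=[f"OTU_{i + 1:04d}" for i in range(n_otus)])
    table.insert(0, "taxonomy", taxonomy)
    table.index.name = "otu_id"
    return table


def generate_env_table(
    metas: list[SampleMeta],
    seed: int = 0,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Environmental parameters for every non-blank sample.

    Each parameter follows a linear trend in incubation day with arm- and
    depth-specific offsets plus multiplicative Gaussian noise; zero noise
    gives exactly linear trends. Units: organic carbon pools in umol L^-1,
    TCC/VLP in counts mL^-1.
    """
    rng = np.random.default_rng([seed, 4])
    # (intercept, slope per day, treatment offset, subsurface offset)
    params = {
        "DOC": (300.0, -1.5, 20.0, 50.0),
        "DCAA": (2.0, -0.02, 0.3, 0.5),
        "DCCHO": (4.0, -0.03, 0.2, 0.8),
        "DFAA": (0.5, -0.004, 0.05, 0.1),
        "DFCHO": (1.0, -0.008, 0.05, 0.2),
        "TCC": (1.5e9, -5.0e6, -1.0e8, -9.0e8),
        "VLP": (5.0e10, 1.0e8, 5.0e9, -2.5e10),
    }
    rows = {}
    for m in metas:
        if m.is_blank:
            continue
        vals = {}
        for name, (a, b, t_off, d_off) in params.items():
            v = a + b * m.day
            if m.arm == "treatment":
                v += t_off
            if m.depth_label == "subsurface":
                v += d_off
            if noise_sd:
                v *= 1.0 + rng.normal(0.0, noise_sd)
            vals[name] = max(v, 1e-9)
        rows[m.sample_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index").loc[:, list(ENV_PARAMETERS)]
    df.index.name = "sample_id"
    return df
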