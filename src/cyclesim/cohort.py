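"""Virtual-subject and per-cycle parameter sampling.

A cohort is a list of ``(SubjectProfile, [CycleParams])`` pairs.  Each
subject owns an independent random substream derived from
``(master_seed, subject_index)``, so a subject's parameters do not depend
on cohort size or ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    EUM,
    PCOS,
    PCOS_AMH_BOUNDS,
    PHENOTYPES,
    SimulationConfig,
)

_MAX_RETRIES = 1000


@dataclass
class SubjectProfile:
    """Trait-level description of one virtual individual.

    Eumenorrheic subjects carry the two-Gaussian estradiol / LH-surge /
    biphasic-FSH parameters; PCOS subjects carry flat (anovulatory) hormone
    levels instead.  Fields not applicable to the phenotype are ``None``.
    """

    subject_id: str
    phenotype: str
    age: float
    bmi: float
    amh_trait: float            # ng/mL, constant across days and cycles
    t_baseline: float           # ng/mL
    t_amplitude: float          # ng/mL
    t_phase: float              # radians
    # eumenorrheic-only
    e2_baseline: Optional[float] = None   # pg/mL
    e2_peak1: Optional[float] = None      # pre-ovulatory peak, pg/mL
    e2_peak2: Optional[float] = None      # luteal peak, pg/mL
    lh_baseline: Optional[float] = None   # mIU/mL
    lh_peak: Optional[float] = None       # mIU/mL
    fsh_baseline: Optional[float] = None  # mIU/mL
    gnrh_baseline: Optional[float] = None  # AU
    sigma1: Optional[float] = None        # d
    sigma2: Optional[float] = None        # d
    sigma_lh: Optional[float] = None      # d
    sigma_early: Optional[float] = None   # d
    sigma_periov: Optional[float] = None  # d
    sigma_gnrh: Optional[float] = None    # d
    alpha_early: Optional[float] = None   # mIU/mL
    alpha_periov: Optional[float] = None  # mIU/mL
    a_periov_gnrh: Optional[float] = None  # AU
    beta_e2: Optional[float] = None       # mIU/mL per pg/mL
    theta_e2: Optional[float] = None      # pg/mL
    t_early: Optional[float] = None       # d
    # PCOS-only flat levels
    e1_level: Optional[float] = None      # pg/mL
    e2_level: Optional[float] = None      # pg/mL
    lh_level: Optional[float] = None      # mIU/mL
    fsh_level: Optional[float] = None     # mIU/mL
    gnrh_level: Optional[float] = None    # AU
    # per-hormone observation-noise base SDs (hormone units)
    noise_base_sd: dict = field(default_factory=dict)


@dataclass
class CycleParams:
    """Timing parameters of one cycle (surge fields are None for PCOS)."""

    cycle_index: int                       # 1-based
    length: float                          # days
    lh_surge_day: Optional[float] = None   # cycle-time days
    delta: Optional[float] = None          # E2 peak -> LH surge lag, days
    mu1: Optional[float] = None            # pre-ovulatory E2 center, days
    delta_luteal: Optional[float] = None   # days
    mu2: Optional[float] = None            # luteal E2 center, days


def _check_phenotype(phenotype: str) -> None:
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")


def sample_cycle_length(phenotype: str, rng: np.random.Generator,
                        config: SimulationConfig | None = None) -> float:
    """Draw one cycle length (days) from the phenotype's truncated normal.

    Eumenorrheic: N(28, 2) truncated to [24, 35]; PCOS: N(35, 6) truncated
    to [28, 60].  Truncation is by rejection, so no mass piles at bounds.
    """
    _check_phenotype(phenotype)
    config = config or SimulationConfig()
    return config.dist(phenotype, "cycle_length").sample(rng)


def sample_subject(phenotype: str, subject_id: str, rng: np.random.Generator,
                   config: SimulationConfig | None = None) -> SubjectProfile:
    """Sample all trait-level parameters for one virtual subject.

    All draws are independent rejection-truncated draws from the configured
    distributions.  For PCOS the AMH trait is ``alpha + beta_bmi*(BMI-25)``,
    re-drawing ``alpha`` until the result lies in [4, 8] ng/mL.
    """
    _check_phenotype(phenotype)
    config = config or SimulationConfig()
    d = lambda name: config.dist(phenotype, name).sample(rng)  # noqa: E731

    age = d("age")
    bmi = d("bmi")
    common = dict(
        subject_id=subject_id,
        phenotype=phenotype,
        age=age,
        bmi=bmi,
        t_baseline=d("t_baseline"),
        t_amplitude=d("t_amplitude"),
        t_phase=d("t_phase"),
        noise_base_sd=dict(config.noise_sd),
    )

    if phenotype == EUM:
        gnrh0 = d("gnrh_baseline")
        return SubjectProfile(
            amh_trait=d("amh"),
            e2_baseline=d("e2_baseline"),
            e2_peak1=d("e2_peak1"),
            e2_peak2=d("e2_peak2"),
            lh_baseline=d("lh_baseline"),
            lh_peak=d("lh_peak"),
            fsh_baseline=d("fsh_baseline"),
            gnrh_baseline=gnrh0,
            sigma1=d("sigma1"),
            sigma2=d("sigma2"),
            sigma_lh=d("sigma_lh"),
            sigma_early=d("sigma_early"),
            sigma_periov=d("sigma_periov"),
            sigma_gnrh=d("sigma_gnrh"),
            alpha_early=d("alpha_early"),
            alpha_periov=d("alpha_periov"),
            a_periov_gnrh=config.dist(EUM, "gnrh_periov_frac").sample(rng) * gnrh0,
            beta_e2=d("beta_e2"),
            theta_e2=d("theta_e2"),
            t_early=d("t_early"),
            **common,
        )

    # PCOS: flat levels plus the BMI-adjusted AMH trait
    beta = d("amh_beta_bmi")
    lo, hi = PCOS_AMH_BOUNDS
    for _ in range(_MAX_RETRIES):
        amh = d("amh_alpha") + beta * (bmi - 25.0)
        if lo <= amh <= hi:
            break
    else:
        raise ValueError(
            "PCOS AMH trait rejection failed: alpha distribution incompatible "
            f"with bounds {PCOS_AMH_BOUNDS} at BMI {bmi:.1f}"
        )
    return SubjectProfile(
        amh_trait=amh,
        e1_level=d("e1_level"),
        e2_level=d("e2_level"),
        lh_level=d("lh_level"),
        fsh_level=d("fsh_level"),
        gnrh_level=d("gnrh_level"),
        **common,
    )


def sample_cycle_params(subject: SubjectProfile, cycle_index: int,
                        rng: np.random.Generator,
                        config: SimulationConfig | None = None) -> CycleParams:
    """Draw one cycle's length and (for eumenorrheic subjects) event timing.

    The LH surge is centered at mid-cycle (L/2) with small Gaussian jitter;
    the pre-ovulatory estradiol peak precedes it by the positive-feedback
    lag Delta ~ U[1.5, 2.0] d and the luteal peak follows the pre-ovulatory
    one by delta ~ U[5.5, 7.5] d.  Draws violating 1 < mu1 < mu2 < L are
    rejected and re-drawn (bounded retries).
    """
    config = config or SimulationConfig()
    length = sample_cycle_length(subject.phenotype, rng, config)
    if subject.phenotype == PCOS:
        return CycleParams(cycle_index=cycle_index, length=length)

    jitter_sd = config.dist(EUM, "surge_jitter_sd").sample(rng)
    for _ in range(_MAX_RETRIES):
        surge = length / 2.0 + rng.normal(0.0, jitter_sd)
        delta = config.dist(EUM, "delta").sample(rng)
        delta_luteal = config.dist(EUM, "delta_luteal").sample(rng)
        mu1 = surge - delta
        mu2 = mu1 + delta_luteal
        if 1.0 < mu1 < mu2 < length:
            return CycleParams(
                cycle_index=cycle_index,
                length=length,
                lh_surge_day=surge,
                delta=delta,
                mu1=mu1,
                delta_luteal=delta_luteal,
                mu2=mu2,
            )
    raise ValueError(
        f"could not place cycle events inside a cycle of length {length:.1f} d"
    )


def subject_seed_sequence(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Seed material for one subject, independent of cohort composition."""
    return np.random.SeedSequence([master_seed, subject_index])


def subject_rngs(master_seed: int, subject_index: int) -> tuple[np.random.Generator, np.random.Generator]:
    """(parameter stream, observation-noise stream) for one subject."""
    children = subject_seed_sequence(master_seed, subject_index).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def build_cohort(config: SimulationConfig) -> list[tuple[SubjectProfile, list[CycleParams]]]:
    """Sample the full cohort: eumenorrheic subjects first, then PCOS.

    Subject ids are ``S0001...``; each subject's draws come from its own
    substream keyed by (master_seed, subject_index), so results are
    reproducible subject-by-subject.
    """
    cohort: list[tuple[SubjectProfile, list[CycleParams]]] = []
    phenos = [EUM] * config.n_eumenorrheic + [PCOS] * config.n_pcos
    for idx, phenotype in enumerate(phenos):
        param_rng, _ = subject_rngs(config.master_seed, idx)
        subject = sample_subject(phenotype, f"S{idx + 1:04d}", param_rng, config)
        cycles = [
            sample_cycle_params(subject, c, param_rng, config)
            for c in range(1, config.cycles_per_subject + 1)
        ]
        cohort.append((subject, cycles))
    return cohort


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

_SUBJECT_EXPORT_RENAME = {
    "age": "age_years",
    "bmi": "BMI_kg_m2",
    "amh_trait": "AMH_ng_mL",
    "t_baseline": "T_baseline_ng_mL",
    "t_amplitude": "T_amplitude_ng_mL",
    "t_phase": "T_phase_rad",
    "e2_baseline": "E2_baseline_pg_mL",
    "e2_peak1": "E2_peak1_pg_mL",
    "e2_peak2": "E2_peak2_pg_mL",
    "lh_baseline": "LH_baseline_mIU_mL",
    "lh_peak": "LH_peak_mIU_mL",
    "fsh_baseline": "FSH_baseline_mIU_mL",
    "gnrh_baseline": "GnRH_baseline_AU",
    "e1_level": "E1_level_pg_mL",
    "e2_level": "E2_level_pg_mL",
    "lh_level": "LH_level_mIU_mL",
    "fsh_level": "FSH_level_mIU_mL",
    "gnrh_level": "GnRH_level_AU",
}


def subjects_table(cohort) -> pd.DataFrame:
    """One row per subject, unit-suffixed columns."""
    rows = []
    for subject, _ in cohort:
        row = {"subject_id": subject.subject_id, "phenotype": subject.phenotype}
        for attr, col in _SUBJECT_EXPORT_RENAME.items():
            row[col] = getattr(subject, attr)
        for extra in ("sigma1", "sigma2", "sigma_lh", "sigma_gnrh",
                      "alpha_early", "alpha_periov", "a_periov_gnrh"):
            row[f"{extra}"] = getattr(subject, extra)
        rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c not in ("subject_id", "phenotype")]
    # None (not-applicable phenotype fields) -> NaN, keeping float dtype
    df[value_cols] = df[value_cols].apply(pd.to_numeric)
    return df


def cycles_table(cohort) -> pd.DataFrame:
    """One row per (subject, cycle)."""
    rows = []
    for subject, cycles in cohort:
        for cyc in cycles:
            rows.append({
                "subject_id": subject.subject_id,
                "phenotype": subject.phenotype,
                "cycle_index": cyc.cycle_index,
                "cycle_length_days": cyc.length,
                "lh_surge_day": cyc.lh_surge_day if cyc.lh_surge_day is not None else math.nan,
                "mu1_days": cyc.mu1 if cyc.mu1 is not None else math.nan,
                "mu2_days": cyc.mu2 if cyc.mu2 is not None else math.nan,
            })
    return pd.DataFrame(rows)
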