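"""Observation pipeline: noise, truncation, phase labels, dataset IO.

Observations follow the truth-plus-noise contract
``Y(t) = Y_true(t) + eps(t)`` with zero-mean Gaussian noise.  Estradiol
and LH in ovulatory cycles use a time-dependent SD amplified near their
event centers (the pre-ovulatory E2 peak and the LH surge); all other
hormones use a constant subject-level SD.  Observations are clipped to
physiologic caps (observation-level clipping, unlike the rejection used
for parameter draws, so the record count and noise center are preserved).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CycleParams,
    SubjectProfile,
    build_cohort,
    cycles_table,
    subject_rngs,
    subjects_table,
)
from .config import EUM, NOISE_AMP_WIDTH_DAYS, PCOS, SimulationConfig
from .hormones import rescale_time, true_panel

logger = logging.getLogger(__name__)

HORMONE_COLUMNS = {
    "E2": "Estradiol_pg_mL",
    "E1": "Estrone_pg_mL",
    "FSH": "FSH_mIU_mL",
    "LH": "LH_mIU_mL",
    "AMH": "AMH_ng_mL",
    "T": "Testosterone_ng_mL",
    "GnRH": "GnRH_AU",
}

META_COLUMNS = [
    "subject_id", "phenotype", "cycle_index", "cycle_length_days",
    "day_index", "cycle_time_days", "phase", "lh_surge_flag",
]
DAILY_COLUMNS = META_COLUMNS + list(HORMONE_COLUMNS.values())

PHASE_FOLLICULAR = "follicular"
PHASE_PERIOV = "peri-ovulatory"
PHASE_LUTEAL = "luteal"
PHASE_ANOV = "anovulatory"

SURGE_LH_THRESHOLD = 30.0   # mIU/mL
SURGE_WINDOW_DAYS = 0.5     # flag window around the surge center
PERIOV_HALFWIDTH_DAYS = 1.0  # phase-label window around the surge center


@dataclass
class CohortDataset:
    """Long-format daily records plus sampling provenance."""

    data: pd.DataFrame                  # DailyRecord schema (DAILY_COLUMNS)
    subjects: pd.DataFrame              # one row per subject
    cycles: pd.DataFrame                # one row per (subject, cycle)
    config: SimulationConfig
    summary: dict = field(default_factory=dict)


def noise_sd(hormone: str, t, subject: SubjectProfile, cycle: CycleParams,
             config: SimulationConfig | None = None):
    """Observation-noise SD at cycle time(s) t, in the hormone's units.

    For eumenorrheic E2/LH: sigma(t) = sigma_base * sqrt(1 + kappa *
    exp(-(t - center)^2 / (2 * 1.2^2))) with center mu1 (E2) or the surge
    day (LH).  Everything else is the constant base SD.
    """
    config = config or SimulationConfig()
    base = subject.noise_base_sd.get(hormone, config.noise_sd.get(hormone, 0.0))
    t = np.asarray(t, dtype=float)
    if subject.phenotype == EUM and hormone in config.kappa:
        center = cycle.mu1 if hormone == "E2" else cycle.lh_surge_day
        kappa = config.kappa[hormone]
        amp = np.exp(-((t - center) ** 2) / (2.0 * NOISE_AMP_WIDTH_DAYS ** 2))
        return base * np.sqrt(1.0 + kappa * amp)
    return np.broadcast_to(np.float64(base), t.shape).copy() if t.shape else float(base)


def observe(value_true, sd, bounds, rng: np.random.Generator):
    """Add N(0, sd) noise and clip to the physiologic bounds [lo, hi]."""
    lo, hi = bounds
    if lo > hi:
        raise ValueError(f"invalid bounds: {lo} > {hi}")
    value_true = np.asarray(value_true, dtype=float)
    noisy = value_true + np.asarray(sd) * rng.standard_normal(value_true.shape)
    return np.clip(noisy, lo, hi)


def label_phase(t, cycle: CycleParams, phenotype: str = EUM):
    """Cycle-phase label(s) relative to the LH surge.

    Peri-ovulatory within +/-1 d of the surge center, follicular before,
    luteal after.  PCOS cycles are anovulatory throughout.
    """
    t = np.asarray(t, dtype=float)
    if phenotype == PCOS or cycle.lh_surge_day is None:
        out = np.full(t.shape, PHASE_ANOV, dtype=object)
        return out if t.shape else PHASE_ANOV
    rel = t - cycle.lh_surge_day
    out = np.where(np.abs(rel) <= PERIOV_HALFWIDTH_DAYS, PHASE_PERIOV,
                   np.where(rel < 0, PHASE_FOLLICULAR, PHASE_LUTEAL))
    return out if t.shape else str(out)


def surge_flag(lh_observed, t, cycle: CycleParams):
    """1 where observed LH >= 30 mIU/mL within +/-0.5 d of the surge."""
    t = np.asarray(t, dtype=float)
    if cycle.lh_surge_day is None:
        out = np.zeros(t.shape, dtype=int)
        return out if t.shape else 0
    hit = ((np.asarray(lh_observed) >= SURGE_LH_THRESHOLD)
           & (np.abs(t - cycle.lh_surge_day) <= SURGE_WINDOW_DAYS))
    out = hit.astype(int)
    return out if t.shape else int(out)


def simulate_cycle(subject: SubjectProfile, cycle: CycleParams,
                   rng: np.random.Generator,
                   config: SimulationConfig | None = None) -> pd.DataFrame:
    """One cycle of daily records: truth, noise, clip, labels.

    Returns exactly ``grid_points_per_cycle`` rows in day order.  Also
    annotates ``df.attrs['n_clipped']`` with the number of observations
    altered by the physiologic caps.
    """
    config = config or SimulationConfig()
    g = config.grid_points_per_cycle
    days = np.arange(1, g + 1)
    t = rescale_time(days, cycle.length, g)
    truth = true_panel(t, subject, cycle)

    row = {
        "subject_id": subject.subject_id,
        "phenotype": subject.phenotype,
        "cycle_index": cycle.cycle_index,
        "cycle_length_days": cycle.length,
        "day_index": days,
        "cycle_time_days": t,
    }
    n_clipped = 0
    obs = {}
    # fixed hormone order keeps the noise stream reproducible
    for hormone, col in HORMONE_COLUMNS.items():
        sd = noise_sd(hormone, t, subject, cycle, config)
        bounds = config.caps[hormone]
        raw = truth[hormone] + np.asarray(sd) * rng.standard_normal(t.shape)
        clipped = np.clip(raw, *bounds)
        n_clipped += int(np.count_nonzero(clipped != raw))
        obs[col] = clipped
    row["phase"] = label_phase(t, cycle, subject.phenotype)
    row["lh_surge_flag"] = surge_flag(obs["LH_mIU_mL"], t, cycle)
    row.update(obs)
    df = pd.DataFrame(row, columns=DAILY_COLUMNS)
    df.attrs["n_clipped"] = n_clipped
    return df


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Simulate the full cohort: sample parameters, then observe daily.

    Each subject's parameter and noise streams derive from
    (master_seed, subject_index), so the dataset is reproducible and a
    subject's records are invariant to cohort composition.
    """
    config = config or SimulationConfig()
    cohort = build_cohort(config)
    frames = []
    n_clipped = 0
    for idx, (subject, cycles) in enumerate(cohort):
        _, noise_rng = subject_rngs(config.master_seed, idx)
        for cyc in cycles:
            df = simulate_cycle(subject, cyc, noise_rng, config)
            n_clipped += df.attrs["n_clipped"]
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    n_obs = len(data) * len(HORMONE_COLUMNS)
    eum = data[data["phenotype"] == EUM]
    n_eum_cycles = config.n_eumenorrheic * config.cycles_per_subject
    surge_cycles = int(
        eum.groupby(["subject_id", "cycle_index"], sort=False)["lh_surge_flag"]
        .max().sum()
    ) if len(eum) else 0
    summary = {
        "n_subjects": config.n_subjects,
        "n_cycles": config.n_subjects * config.cycles_per_subject,
        "n_records": len(data),
        "clip_rate": n_clipped / n_obs if n_obs else 0.0,
        "surge_detection_rate": surge_cycles / n_eum_cycles if n_eum_cycles else float("nan"),
    }
    logger.info(
        "simulated %(n_subjects)d subjects, %(n_cycles)d cycles, "
        "%(n_records)d records; clip rate %(clip_rate).4f; "
        "surge detection %(surge_detection_rate).3f", summary,
    )
    return CohortDataset(
        data=data,
        subjects=subjects_table(cohort),
        cycles=cycles_table(cohort),
        config=config,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Dataset IO
# ---------------------------------------------------------------------------

DAILY_FILE = "daily_timeseries.csv"
SUBJECTS_FILE = "subjects.csv"
CYCLES_FILE = "cycles.csv"
MANIFEST_FILE = "run_manifest.json"

_FLOAT_FMT = "%.6g"  # round-trip precision stated for the CSV contract


class SchemaError(ValueError):
    """A required column is missing or misnamed in a dataset file."""


def write_dataset(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the daily table, parameter tables and run manifest as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "daily": out / DAILY_FILE,
        "subjects": out / SUBJECTS_FILE,
        "cycles": out / CYCLES_FILE,
        "manifest": out / MANIFEST_FILE,
    }
    dataset.data.to_csv(paths["daily"], index=False, float_format=_FLOAT_FMT)
    dataset.subjects.to_csv(paths["subjects"], index=False, float_format=_FLOAT_FMT)
    dataset.cycles.to_csv(paths["cycles"], index=False, float_format=_FLOAT_FMT)
    manifest = {
        "package": "cyclesim",
        "version": __version__,
        "config": dataset.config.to_dict(),
        "master_seed": dataset.config.master_seed,
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        "summary": dataset.summary,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def read_dataset(path: str | Path) -> CohortDataset:
    """Read a daily-timeseries CSV (or its directory) back into a dataset.

    Validates the DailyRecord column set and reloads the companion tables
    and manifest when present.
    """
    path = Path(path)
    if path.is_dir():
        daily_path = path / DAILY_FILE
    else:
        daily_path, path = path, path.parent
    data = pd.read_csv(daily_path)
    missing = [c for c in DAILY_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"daily table is missing required column(s): {missing}")
    data = data[DAILY_COLUMNS]

    subjects = cycles = pd.DataFrame()
    config = SimulationConfig()
    summary: dict = {}
    if (path / SUBJECTS_FILE).exists():
        subjects = pd.read_csv(path / SUBJECTS_FILE)
    if (path / CYCLES_FILE).exists():
        cycles = pd.read_csv(path / CYCLES_FILE)
    if (path / MANIFEST_FILE).exists():
        manifest = json.loads((path / MANIFEST_FILE).read_text())
        config = SimulationConfig.from_dict(manifest["config"])
        summary = manifest.get("summary", {})
    return CohortDataset(data=data, subjects=subjects, cycles=cycles,
                         config=config, summary=summary)
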