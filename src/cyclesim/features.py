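"""Subject-level feature extraction from daily records.

Each subject's daily observations (all cycles concatenated) are reduced
to per-hormone mean/SD/max, the LH/FSH and E1/E2 ratios (ratios of means,
which are stabler than means of daily ratios), cycle-phase day
proportions, and cycle-length statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import (
    CohortDataset,
    HORMONE_COLUMNS,
    PHASE_ANOV,
    PHASE_FOLLICULAR,
    PHASE_LUTEAL,
    PHASE_PERIOV,
    SchemaError,
)

logger = logging.getLogger(__name__)

_PHASES = [PHASE_FOLLICULAR, PHASE_PERIOV, PHASE_LUTEAL, PHASE_ANOV]
_PHASE_COLS = {p: f"frac_{p.replace('-', '_')}" for p in _PHASES}

#: the six standardized mean-level inputs to PCA / k-means / the classifier
PCA6_FEATURES = [
    "Estradiol_pg_mL_mean",
    "FSH_mIU_mL_mean",
    "LH_mIU_mL_mean",
    "AMH_ng_mL_mean",
    "Testosterone_ng_mL_mean",
    "GnRH_AU_mean",
]


def feature_columns(preset: str = "pca6") -> list[str]:
    """Feature-column names for a named preset ('pca6' or 'full')."""
    if preset == "pca6":
        return list(PCA6_FEATURES)
    if preset == "full":
        cols = []
        for col in HORMONE_COLUMNS.values():
            cols += [f"{col}_mean", f"{col}_sd", f"{col}_max"]
        cols += ["LH_FSH_ratio", "E1_E2_ratio"]
        cols += [_PHASE_COLS[p] for p in _PHASES]
        cols += ["cycle_length_mean_days", "cycle_length_sd_days"]
        return cols
    raise ValueError(f"unknown feature preset {preset!r}; use 'pca6' or 'full'")


def subject_features(records: pd.DataFrame) -> pd.Series:
    """Aggregate one subject's daily records into its feature vector.

    SDs are sample SDs (ddof=1); a subject with a single cycle gets
    cycle-length SD 0 by convention (logged as a warning).  Requires at
    least one record and a single subject id.
    """
    if len(records) == 0:
        raise ValueError("cannot compute features from an empty record set")
    ids = records["subject_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records must belong to one subject, got {list(ids)}")

    out: dict[str, object] = {
        "subject_id": ids[0],
        "phenotype": records["phenotype"].iloc[0],
    }
    for col in HORMONE_COLUMNS.values():
        vals = records[col].to_numpy(dtype=float)
        out[f"{col}_mean"] = vals.mean()
        # exact zero for constant columns (AMH): no float residue from the
        # mean subtraction
        out[f"{col}_sd"] = (vals.std(ddof=1)
                            if len(vals) > 1 and np.ptp(vals) > 0 else 0.0)
        out[f"{col}_max"] = vals.max()
    out["LH_FSH_ratio"] = out["LH_mIU_mL_mean"] / out["FSH_mIU_mL_mean"]
    out["E1_E2_ratio"] = out["Estrone_pg_mL_mean"] / out["Estradiol_pg_mL_mean"]

    phase_counts = records["phase"].value_counts()
    n = len(records)
    for p in _PHASES:
        out[_PHASE_COLS[p]] = phase_counts.get(p, 0) / n

    lengths = (records.drop_duplicates(["cycle_index"])
               ["cycle_length_days"].to_numpy(dtype=float))
    out["cycle_length_mean_days"] = lengths.mean()
    if len(lengths) > 1:
        out["cycle_length_sd_days"] = lengths.std(ddof=1)
    else:
        logger.warning("subject %s has a single cycle; cycle-length SD set to 0",
                       ids[0])
        out["cycle_length_sd_days"] = 0.0
    return pd.Series(out)


def feature_table(dataset: CohortDataset | pd.DataFrame) -> pd.DataFrame:
    """One feature row per subject, in subject-id order.

    The ``phenotype`` label column is carried alongside but is not part of
    any feature preset.
    """
    data = dataset.data if isinstance(dataset, CohortDataset) else dataset
    required = {"subject_id", "phenotype", "cycle_index", "cycle_length_days", "phase"}
    missing = required - set(data.columns)
    if missing:
        raise SchemaError(f"dataset is missing required column(s): {sorted(missing)}")
    sizes = data.groupby(["subject_id", "cycle_index"]).size()
    if sizes.groupby("subject_id").nunique().gt(1).any():
        raise SchemaError("subjects with differing grid sizes across cycles")

    rows = [subject_features(grp) for _, grp in data.groupby("subject_id", sort=True)]
    table = pd.DataFrame(rows).reset_index(drop=True)
    # deterministic column order: ids/label first, then the full preset
    return table[["subject_id", "phenotype"] + feature_columns("full")]


def split_features_labels(table: pd.DataFrame, preset: str = "pca6"):
    """(feature matrix DataFrame, phenotype label Series) for a preset."""
    return table[feature_columns(preset)], table["phenotype"]
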