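"""Run configuration: cohort sizes, seeds, and parameter distributions.

Every sampled quantity in the simulator is drawn from a named
:class:`Dist`.  The defaults below encode the study conditions — level
parameters as truncated normals calibrated to the published cohort
summaries, width/timing parameters as uniforms over their physiologic
ranges — and any of them can be overridden per run through
``SimulationConfig.overrides`` (or the equivalent YAML/JSON config file)
without touching code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

EUM = "EUM"
PCOS = "PCOS"
PHENOTYPES = (EUM, PCOS)


@dataclass(frozen=True)
class Dist:
    """A univariate sampling distribution with optional truncation bounds.

    ``kind`` is one of ``"normal"``, ``"uniform"`` or ``"constant"``.
    Normal draws outside ``(low, high)`` are rejected and redrawn, so the
    realized distribution is the truncated normal (no probability mass
    piles up at the bounds, which clipping would cause).
    """

    kind: str
    mean: float = 0.0
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf
    value: float = 0.0

    _MAX_REJECTIONS = 10_000

    def sample(self, rng) -> float:
        if self.kind == "constant":
            return self.value
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.kind == "normal":
            if self.sd == 0.0:
                return self.mean
            for _ in range(self._MAX_REJECTIONS):
                x = float(rng.normal(self.mean, self.sd))
                if self.low <= x <= self.high:
                    return x
            raise ValueError(
                f"rejection sampling failed: N({self.mean}, {self.sd}) is "
                f"incompatible with bounds [{self.low}, {self.high}]"
            )
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @classmethod
    def from_spec(cls, spec: Mapping[str, Any] | float) -> "Dist":
        """Build from a config-file entry (a mapping, or a bare number)."""
        if isinstance(spec, (int, float)):
            return constant(float(spec))
        kind = spec.get("dist", "normal")
        known = {"dist", "mean", "sd", "low", "high", "value"}
        extra = set(spec) - known
        if extra:
            raise ValueError(f"unknown distribution keys {sorted(extra)}")
        kwargs = {k: float(v) for k, v in spec.items() if k != "dist"}
        return cls(kind=kind, **kwargs)


def normal(mean: float, sd: float, low: float = -math.inf, high: float = math.inf) -> Dist:
    return Dist("normal", mean=mean, sd=sd, low=low, high=high)


def uniform(low: float, high: float) -> Dist:
    return Dist("uniform", low=low, high=high)


def constant(value: float) -> Dist:
    return Dist("constant", value=value)


# ---------------------------------------------------------------------------
# Default parameter distributions, keyed "<phenotype>.<parameter>".
#
# Levels (baselines, peaks, flat PCOS levels) are truncated normals whose
# centers/SDs reproduce the published cohort summary statistics; widths,
# lags and phases are uniform over their physiologic ranges.
# ---------------------------------------------------------------------------
DEFAULT_DISTS: dict[str, Dist] = {
    # --- eumenorrheic -----------------------------------------------------
    "EUM.cycle_length": normal(28.0, 2.0, 24.0, 35.0),
    "EUM.age": uniform(20.0, 45.0),
    "EUM.bmi": normal(24.0, 2.5),
    "EUM.e2_baseline": normal(20.0, 5.0, 10.0, 30.0),   # pg/mL
    "EUM.e2_peak1": normal(267.0, 28.0),                # pre-ovulatory peak
    "EUM.e2_peak2": normal(125.0, 12.0, 100.0, 150.0),  # luteal peak
    "EUM.lh_baseline": normal(7.0, 2.0, 2.0, 12.0),     # mIU/mL
    "EUM.lh_peak": normal(56.5, 6.4, 35.0, 80.0),
    "EUM.fsh_baseline": normal(7.8, 1.1, 5.0, 10.0),
    "EUM.amh": normal(2.9, 0.4, 1.0, 4.0),              # ng/mL, trait
    "EUM.t_baseline": normal(0.4, 0.04, 0.2, 0.6),      # ng/mL
    "EUM.gnrh_baseline": normal(1.0, 0.05, 0.5, 1.5),   # AU
    "EUM.sigma1": uniform(0.9, 1.3),        # pre-ovulatory E2 width, d
    "EUM.sigma2": uniform(1.5, 2.5),        # luteal E2 width, d
    "EUM.sigma_lh": uniform(0.6, 0.9),      # LH surge width, d
    "EUM.sigma_early": constant(1.5),       # early FSH bump width, d
    "EUM.sigma_periov": constant(0.8),      # peri-ovulatory FSH bump width, d
    "EUM.sigma_gnrh": uniform(0.8, 1.2),    # GnRH bump width, d
    "EUM.alpha_early": uniform(1.0, 2.0),   # early FSH bump, mIU/mL
    "EUM.alpha_periov": uniform(0.8, 1.6),  # peri-ovulatory FSH bump, mIU/mL
    "EUM.t_amplitude": uniform(0.02, 0.06),  # testosterone sinusoid, ng/mL
    "EUM.t_phase": uniform(0.0, 2.0 * math.pi),
    # per-cycle timing
    "EUM.surge_jitter_sd": constant(0.5),   # LH surge jitter around L/2, d
    "EUM.delta": uniform(1.5, 2.0),         # E2 peak -> LH surge lag, d
    "EUM.delta_luteal": uniform(5.5, 7.5),  # pre-ovulatory -> luteal lag, d
    # FSH/E2 feedback and GnRH bump scale
    "EUM.beta_e2": constant(0.01),          # mIU/mL per pg/mL above theta
    "EUM.theta_e2": constant(100.0),        # pg/mL suppression onset
    "EUM.t_early": constant(2.0),           # early FSH bump center, d
    "EUM.gnrh_periov_frac": constant(0.22),  # peri-ovulatory GnRH rise
    # --- PCOS-like --------------------------------------------------------
    "PCOS.cycle_length": normal(35.0, 6.0, 28.0, 60.0),
    "PCOS.age": uniform(20.0, 45.0),
    "PCOS.bmi": normal(28.0, 3.2),
    "PCOS.e1_level": normal(115.0, 12.0, 80.0, 150.0),  # pg/mL
    "PCOS.e2_level": normal(33.0, 9.0, 10.0, 60.0),
    "PCOS.lh_level": normal(18.0, 3.4, 12.0, 25.0),
    "PCOS.fsh_level": normal(5.2, 0.5, 4.0, 8.0),
    "PCOS.gnrh_level": normal(1.37, 0.06, 1.3, 1.6),
    "PCOS.amh_alpha": normal(5.7, 0.58),
    "PCOS.amh_beta_bmi": constant(-0.055),  # ng/mL per BMI unit
    "PCOS.t_baseline": normal(1.25, 0.12, 0.8, 2.0),
    "PCOS.t_amplitude": uniform(0.02, 0.06),
    "PCOS.t_phase": uniform(0.0, 2.0 * math.pi),
}

# AMH trait bounds applied after the BMI adjustment (PCOS only).
PCOS_AMH_BOUNDS = (4.0, 8.0)

# EUM estrone tracks estradiol at a fixed low ratio so the E1/E2 feature is
# defined for both phenotypes (extension beyond the flat PCOS E1 model).
EUM_E1_FACTOR = 0.7

# ---------------------------------------------------------------------------
# Observation noise and physiologic caps (observation-level clipping).
# ---------------------------------------------------------------------------
DEFAULT_NOISE_SD: dict[str, float] = {
    "E2": 10.0,   # pg/mL
    "E1": 10.0,   # pg/mL
    "LH": 1.5,    # mIU/mL
    "FSH": 0.6,   # mIU/mL
    "T": 0.03,    # ng/mL
    "GnRH": 0.04,  # AU
    "AMH": 0.0,   # trait-like: no daily noise
}
DEFAULT_KAPPA: dict[str, float] = {"E2": 1.5, "LH": 2.0}
NOISE_AMP_WIDTH_DAYS = 1.2

DEFAULT_CAPS: dict[str, tuple[float, float]] = {
    "E2": (0.0, 600.0),
    "E1": (0.0, 300.0),
    "LH": (0.0, 100.0),
    "FSH": (0.0, 30.0),
    "AMH": (0.0, 12.0),
    "T": (0.0, 3.0),
    "GnRH": (0.0, 3.0),
}


@dataclass
class SimulationConfig:
    """Cohort design and reproducibility settings for one simulated run."""

    n_eumenorrheic: int = 500
    n_pcos: int = 50
    cycles_per_subject: int = 3
    grid_points_per_cycle: int = 28
    master_seed: int = 12345
    overrides: dict[str, Dist] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    kappa: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    caps: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_CAPS))
    use_pulse_train: bool = False

    def __post_init__(self) -> None:
        for name in ("n_eumenorrheic", "n_pcos", "cycles_per_subject",
                     "grid_points_per_cycle"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_eumenorrheic + self.n_pcos == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.cycles_per_subject < 1:
            raise ValueError("cycles_per_subject must be >= 1")
        if self.grid_points_per_cycle < 2:
            raise ValueError("grid_points_per_cycle must be >= 2")
        for h, (lo, hi) in self.caps.items():
            if lo > hi:
                raise ValueError(f"caps for {h}: low {lo} > high {hi}")
        unknown = set(self.overrides) - set(DEFAULT_DISTS)
        if unknown:
            raise ValueError(f"unknown override parameters: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.n_eumenorrheic + self.n_pcos

    def dist(self, phenotype: str, name: str) -> Dist:
        """Resolve the distribution for ``<phenotype>.<name>``."""
        key = f"{phenotype}.{name}"
        if key in self.overrides:
            return self.overrides[key]
        try:
            return DEFAULT_DISTS[key]
        except KeyError:
            raise KeyError(f"no distribution defined for {key}") from None

    def with_overrides(self, **specs: Mapping[str, Any] | float | Dist) -> "SimulationConfig":
        """Return a copy with extra overrides, keys like ``'EUM.sigma1'``
        passed as ``EUM__sigma1=...`` keyword arguments."""
        new = dict(self.overrides)
        for key, spec in specs.items():
            key = key.replace("__", ".")
            new[key] = spec if isinstance(spec, Dist) else Dist.from_spec(spec)
        return replace(self, overrides=new)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "n_eumenorrheic": self.n_eumenorrheic,
            "n_pcos": self.n_pcos,
            "cycles_per_subject": self.cycles_per_subject,
            "grid_points_per_cycle": self.grid_points_per_cycle,
            "master_seed": self.master_seed,
            "use_pulse_train": self.use_pulse_train,
            "noise_sd": dict(self.noise_sd),
            "kappa": dict(self.kappa),
            "caps": {k: list(v) for k, v in self.caps.items()},
            "overrides": {},
        }
        for key, dist in self.overrides.items():
            if dist.kind == "constant":
                d["overrides"][key] = {"dist": "constant", "value": dist.value}
            elif dist.kind == "uniform":
                d["overrides"][key] = {"dist": "uniform", "low": dist.low, "high": dist.high}
            else:
                entry = {"dist": "normal", "mean": dist.mean, "sd": dist.sd}
                if math.isfinite(dist.low):
                    entry["low"] = dist.low
                if math.isfinite(dist.high):
                    entry["high"] = dist.high
                d["overrides"][key] = entry
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        overrides = {k: Dist.from_spec(v) for k, v in d.pop("overrides", {}).items()}
        caps = {k: tuple(v) for k, v in d.pop("caps", DEFAULT_CAPS).items()}
        return cls(overrides=overrides, caps=caps, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})
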