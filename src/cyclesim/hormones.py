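"""Noise-free hormone trajectory equations.

Eumenorrheic cycles use Gaussian-bump kinetics on a rescaled cycle-time
axis: a two-Gaussian biphasic estradiol curve, a brief LH surge that
follows the estradiol rise by the 36-48 h positive-feedback lag, a
biphasic FSH curve with estradiol-dependent suppression, a small
peri-ovulatory GnRH bump, and a low-amplitude testosterone sinusoid.
PCOS-like cycles are anovulatory: every hormone sits at a flat
subject-specific level except the testosterone sinusoid.

All functions accept scalar or ndarray ``t`` (cycle-time, days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EUM, EUM_E1_FACTOR, PCOS
from .cohort import CycleParams, SubjectProfile


def rescale_time(day_index, cycle_length: float, grid_points: int = 28):
    """Map a grid day index (1..grid_points) onto continuous cycle time.

    t = 1 + (d - 1)/(grid_points - 1) * (L - 1), so t(1) = 1 and
    t(grid_points) = L regardless of the subject's cycle length L.
    """
    d = np.asarray(day_index)
    if np.any(d < 1) or np.any(d > grid_points):
        raise ValueError(f"day_index must lie in [1, {grid_points}]")
    if cycle_length < 1:
        raise ValueError("cycle_length must be >= 1 day")
    t = 1.0 + (d - 1.0) / (grid_points - 1.0) * (cycle_length - 1.0)
    return float(t) if np.isscalar(day_index) else t


def _gauss(t, center, width):
    return np.exp(-((t - center) ** 2) / (2.0 * width ** 2))


def e2_eum(t, subject: SubjectProfile, cycle: CycleParams):
    """Biphasic estradiol (pg/mL): pre-ovulatory surge + luteal rise."""
    a1 = subject.e2_peak1 - subject.e2_baseline
    a2 = subject.e2_peak2 - subject.e2_baseline
    return (subject.e2_baseline
            + a1 * _gauss(t, cycle.mu1, subject.sigma1)
            + a2 * _gauss(t, cycle.mu2, subject.sigma2))


def lh_eum(t, subject: SubjectProfile, cycle: CycleParams):
    """LH (mIU/mL): baseline plus a brief Gaussian surge at the surge day."""
    return (subject.lh_baseline
            + (subject.lh_peak - subject.lh_baseline)
            * _gauss(t, cycle.lh_surge_day, subject.sigma_lh))


def fsh_eum(t, subject: SubjectProfile, cycle: CycleParams, e2_true_value):
    """Biphasic FSH (mIU/mL) with estradiol negative feedback.

    Early-follicular and peri-ovulatory bumps sit on the baseline; values
    of noise-free E2 above ``theta_e2`` (~100 pg/mL) subtract
    ``beta_e2`` mIU/mL per pg/mL of excess.  Floored at zero.
    """
    out = (subject.fsh_baseline
           + subject.alpha_early * _gauss(t, subject.t_early, subject.sigma_early)
           + subject.alpha_periov * _gauss(t, cycle.lh_surge_day - 1.0, subject.sigma_periov)
           - subject.beta_e2 * np.maximum(np.asarray(e2_true_value) - subject.theta_e2, 0.0))
    return np.maximum(out, 0.0)


def gnrh_eum(t, subject: SubjectProfile, cycle: CycleParams):
    """GnRH daily area (AU): ~1 AU with a peri-ovulatory bump."""
    return (subject.gnrh_baseline
            + subject.a_periov_gnrh * _gauss(t, cycle.lh_surge_day - 1.0, subject.sigma_gnrh))


def testosterone(t, subject: SubjectProfile, cycle: CycleParams):
    """Low-amplitude sinusoid around the phenotype's baseline (ng/mL)."""
    return (subject.t_baseline
            + subject.t_amplitude
            * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / cycle.length + subject.t_phase))


def amh(subject: SubjectProfile) -> float:
    """Trait-like AMH (ng/mL): constant for every day and cycle."""
    return subject.amh_trait


def pcos_levels(t, subject: SubjectProfile, cycle: CycleParams) -> dict:
    """Noise-free anovulatory panel: flat levels, no dependence on t.

    Returns arrays shaped like ``t`` for E1, E2, LH, FSH and GnRH.
    """
    if subject.phenotype != PCOS:
        raise ValueError("pcos_levels is defined only for PCOS subjects")
    shape = np.shape(np.asarray(t, dtype=float))
    flat = lambda v: np.full(shape, v) if shape else float(v)  # noqa: E731
    return {
        "E1": flat(subject.e1_level),
        "E2": flat(subject.e2_level),
        "LH": flat(subject.lh_level),
        "FSH": flat(subject.fsh_level),
        "GnRH": flat(subject.gnrh_level),
    }


def true_panel(t, subject: SubjectProfile, cycle: CycleParams) -> dict:
    """Noise-free values of all seven hormones at cycle time(s) ``t``.

    Eumenorrheic estrone is modelled as a fixed low fraction of estradiol
    so the E1/E2 ratio feature is defined for both phenotypes.
    """
    t = np.asarray(t, dtype=float)
    if subject.phenotype == EUM:
        e2 = e2_eum(t, subject, cycle)
        panel = {
            "E2": e2,
            "E1": EUM_E1_FACTOR * e2,
            "LH": lh_eum(t, subject, cycle),
            "FSH": fsh_eum(t, subject, cycle, e2),
            "GnRH": gnrh_eum(t, subject, cycle),
        }
    else:
        panel = pcos_levels(t, subject, cycle)
    panel["T"] = testosterone(t, subject, cycle)
    panel["AMH"] = np.full(t.shape, amh(subject))
    return panel


# ---------------------------------------------------------------------------
# Optional minute-resolution GnRH pulse train
# ---------------------------------------------------------------------------

MINUTES_PER_DAY = 1440.0


@dataclass
class PulseTrainParams:
    """A day of Gaussian GnRH pulses on a minute axis.

    Interpulse intervals are 60-90 min.  With the default amplitude and
    5-min pulse width the integrated daily area is ~1 AU, matching the
    daily-area bump model at baseline.
    """

    pulse_amplitudes: list = field(default_factory=list)  # AU
    pulse_times: list = field(default_factory=list)       # minutes in [0, 1440)
    pulse_width: float = 5.0                              # minutes
    daily_normalizer: float = MINUTES_PER_DAY


def sample_pulse_train(rng: np.random.Generator, amplitude_mean: float = 6.0,
                       amplitude_cv: float = 0.1, pulse_width: float = 5.0,
                       interpulse_low: float = 60.0,
                       interpulse_high: float = 90.0) -> PulseTrainParams:
    """Draw one day's pulse train with U[60, 90]-min interpulse intervals.

    The default amplitude is calibrated so that the expected daily area is
    ~1 AU: with a ~75-min mean interval there are ~19.2 pulses/day, each of
    area amplitude * width * sqrt(2*pi), divided by the 1440-min normalizer.
    """
    times, amps = [], []
    t = float(rng.uniform(0.0, interpulse_high))
    while t < MINUTES_PER_DAY:
        times.append(t)
        amps.append(float(amplitude_mean * (1.0 + amplitude_cv * rng.standard_normal())))
        t += float(rng.uniform(interpulse_low, interpulse_high))
    return PulseTrainParams(pulse_amplitudes=amps, pulse_times=times,
                            pulse_width=pulse_width)


def gnrh_pulse_train_daily_area(params: PulseTrainParams,
                                resolution_min: float = 0.5) -> float:
    """Numerically integrate the pulse train over one day; returns AU.

    The sum of Gaussian pulses is evaluated on a minute grid and
    trapezoid-integrated, then divided by the daily normalizer so a
    baseline train yields ~1 AU.  An empty pulse set gives 0.
    """
    if not params.pulse_times:
        return 0.0
    tau = np.arange(0.0, MINUTES_PER_DAY + resolution_min, resolution_min)
    train = np.zeros_like(tau)
    for a, tk in zip(params.pulse_amplitudes, params.pulse_times):
        train += a * _gauss(tau, tk, params.pulse_width)
    area = np.trapezoid(train, tau)
    return float(area / params.daily_normalizer)
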