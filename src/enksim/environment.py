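"""Target population of environments: schedules, sampling, weighting.

A TPE is a frequency vector over the 12 ordinal environment types (ETs).
Environmental change is modelled by moving the center of the ET frequency
distribution over breeding cycles, either *gradually* (a Gaussian-kernel
center sliding from ET1 to ET12) or *suddenly* (near-uniform weight over the
block ET1-6 for 20 cycles, then an abrupt shift to ET7-12). The realized ET
frequencies of a cycle are a single Dirichlet draw around those base weights,
mimicking random year-over-year variability; every ET always keeps a strictly
positive frequency.

Programs observe the TPE only through their multi-environment trials (MET):
per program and cycle, MET weights are drawn from a Dirichlet distribution
with concentration 500 times the true ET frequencies.

The concentration of a frequency vector is summarized by the inverse Simpson
index 1 / sum(b^2), the "effective number" of ETs. The default schedule
parameters are calibrated so that the cycle-averaged effective ET number is
about 5.9 (gradual) and 5.4 (sudden).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from enksim.exceptions import ConfigurationError, DegenerateDataError

N_ET_DEFAULT = 12
MET_CONCENTRATION = 500.0
#: Defaults calibrated against the target cycle-averaged effective ET numbers
#: (5.9 gradual / 5.4 sudden); see docs/methods.md.
GRADUAL_KERNEL_WIDTH = 2.0
GRADUAL_CONCENTRATION = 300.0
SUDDEN_FLOOR = 0.004
SUDDEN_CONCENTRATION = 29.0
_NORM_TOL = 1e-12
_FREQ_FLOOR = 1e-12


def ETFrequencyVector(freqs) -> np.ndarray:
    """Validate and return an ET frequency vector (strictly positive simplex)."""
    b = np.asarray(freqs, dtype=float)
    if b.ndim != 1:
        raise ConfigurationError("frequency vector must be one-dimensional")
    if (b <= 0).any():
        raise ConfigurationError("ET frequencies must be strictly positive")
    if abs(b.sum() - 1.0) > 1e-9:
        raise ConfigurationError("ET frequencies must sum to 1")
    return b / b.sum()


@dataclass(frozen=True)
class TPESchedule:
    """Parameters of a TPE change scenario over a fixed number of cycles.

    ``kernel_width`` is the Gaussian spread of the center weighting in ET
    units (gradual scenario); ``concentration`` is the total Dirichlet
    concentration of the per-cycle frequency draw. ``sudden_floor`` is the
    small base weight assigned to out-of-block ETs in the sudden scenario and
    ``shift_cycle`` the last cycle before the sudden shift.
    """

    scenario: str
    n_cycles: int = 30
    kernel_width: float = GRADUAL_KERNEL_WIDTH
    concentration: float | None = None
    n_et: int = N_ET_DEFAULT
    sudden_floor: float = SUDDEN_FLOOR
    shift_cycle: int = 20

    def __post_init__(self):
        if self.scenario not in ("gradual", "sudden"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.kernel_width <= 0:
            raise ConfigurationError("kernel_width must be > 0")
        if self.concentration is None:
            object.__setattr__(
                self,
                "concentration",
                GRADUAL_CONCENTRATION
                if self.scenario == "gradual"
                else SUDDEN_CONCENTRATION,
            )
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be > 0")


def base_weights(schedule: TPESchedule, cycle: int) -> np.ndarray:
    """Expected ET frequencies for one cycle (center of the Dirichlet draw)."""
    if not 1 <= cycle <= schedule.n_cycles:
        raise ConfigurationError(
            f"cycle {cycle} outside [1, {schedule.n_cycles}]"
        )
    E = schedule.n_et
    et = np.arange(1, E + 1, dtype=float)
    if schedule.scenario == "gradual":
        if schedule.n_cycles == 1:
            mu = (1.0 + E) / 2.0
        else:
            mu = 1.0 + (E - 1.0) * (cycle - 1) / (schedule.n_cycles - 1)
        w = np.exp(-0.5 * ((et - mu) / schedule.kernel_width) ** 2)
        return w / w.sum()
    # sudden: near-uniform over one half, small positive floor elsewhere
    half = E // 2
    block = et <= half if cycle <= schedule.shift_cycle else et > half
    w = np.full(E, schedule.sudden_floor)
    w[block] = (1.0 - (E - half) * schedule.sudden_floor) / half
    return w / w.sum()


def sample_tpe(
    schedule: TPESchedule, cycle: int, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet draw of the cycle's true ET frequencies."""
    alpha = schedule.concentration * base_weights(schedule, cycle)
    b = rng.dirichlet(alpha)
    b = np.maximum(b, _FREQ_FLOOR)  # guard exact zeros from underflow
    return b / b.sum()


def sample_met_weights(true_freqs, rng: np.random.Generator) -> np.ndarray:
    """Program-specific MET weights: Dirichlet around the true TPE, alpha0=500."""
    b = ETFrequencyVector(true_freqs)
    w = rng.dirichlet(MET_CONCENTRATION * b)
    w = np.maximum(w, _FREQ_FLOOR)
    return w / w.sum()


def effective_number(b) -> float:
    """Inverse Simpson index 1 / sum(b^2) of a nonnegative weight vector.

    Unnormalized inputs are normalized first; an all-zero vector is an error.
    The result lies in [1, len(b)].
    """
    w = np.asarray(b, dtype=float)
    if (w < 0).any():
        raise ConfigurationError("weights must be nonnegative")
    s = w.sum()
    if s <= 0:
        raise DegenerateDataError("all-zero weight vector")
    w = w / s
    return float(1.0 / np.dot(w, w))


def tpe_performance(model, genotype, b) -> float:
    """TPE-weighted performance: ET fitnesses averaged with frequencies ``b``."""
    return float(tpe_performance_batch(model, genotype, b)[0])


def tpe_performance_batch(model, dosages, b) -> np.ndarray:
    """Vectorized TPE-weighted performance for a batch of genotypes."""
    w = ETFrequencyVector(b)
    return model.tpe_weighted_performance(dosages, w)


def schedule_to_frame(
    schedule: TPESchedule, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample one full schedule realization as a tidy table.

    Columns: cycle, et_index, base_weight, sampled_freq.
    """
    rows = []
    for cycle in range(1, schedule.n_cycles + 1):
        w = base_weights(schedule, cycle)
        b = sample_tpe(schedule, cycle, rng)
        for e in range(schedule.n_et):
            rows.append((cycle, e + 1, w[e], b[e]))
    return pd.DataFrame(
        rows, columns=["cycle", "et_index", "base_weight", "sampled_freq"]
    )
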