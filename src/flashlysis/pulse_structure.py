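"""Temporal structure of pulsed irradiation.

A linac delivers dose in rectangular macro-pulses (here 1.8 us at up to
10 Gy per pulse, repeated at 100 Hz for multi-pulse trains).  Within a
pulse, primary electrons are emitted at random time points; several
electrons may share one emission time, forming *bunches* separated by a
time interval dt.  The chemistry engine consumes either the continuous
dose-rate profile of the train or, for instantaneous pulses (zero width),
discrete dose deposits at the pulse start times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseTrain",
    "BunchSchedule",
    "Scenario",
    "make_pulse_train",
    "sample_emission_times",
    "dose_rate_profile",
    "scenario_table",
]


@dataclass(frozen=True)
class PulseTrain:
    """A train of identical rectangular pulses.

    ``pulse_width == 0`` denotes instantaneous pulses (all electrons share
    one emission time); these are handled as discrete deposits by the
    integrator, not through the dose-rate profile.
    """

    dose_per_pulse: float  # Gy
    pulse_width: float  # s; 0 = instantaneous
    n_pulses: int = 1
    repetition_frequency: float | None = None  # Hz, required if n_pulses > 1
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.dose_per_pulse <= 0:
            raise ValueError("dose_per_pulse must be positive")
        if self.pulse_width < 0:
            raise ValueError("pulse_width must be >= 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.shape != "rectangular":
            raise ValueError(f"unsupported pulse shape {self.shape!r}")
        if self.n_pulses > 1:
            if not self.repetition_frequency or self.repetition_frequency <= 0:
                raise ValueError("multi-pulse train needs a repetition frequency")
            if 1.0 / self.repetition_frequency <= self.pulse_width:
                raise ValueError("pulses overlap: period <= pulse width")

    @property
    def instantaneous(self) -> bool:
        return self.pulse_width == 0.0

    @property
    def total_dose(self) -> float:
        return self.n_pulses * self.dose_per_pulse

    @property
    def pulse_starts(self) -> np.ndarray:
        if self.n_pulses == 1:
            return np.array([0.0])
        period = 1.0 / float(self.repetition_frequency)  # type: ignore[arg-type]
        return np.arange(self.n_pulses) * period

    @property
    def dose_rate(self) -> float:
        """In-pulse dose rate, Gy/s (undefined for instantaneous pulses)."""
        if self.instantaneous:
            raise ValueError("instantaneous pulse has no finite dose rate")
        return self.dose_per_pulse / self.pulse_width


@dataclass(frozen=True)
class BunchSchedule:
    """Emission times of electron bunches within one pulse."""

    emission_times: np.ndarray  # s, sorted
    bunch_sizes: np.ndarray  # electrons per bunch; last may carry a remainder
    electrons_per_bunch: int

    def __post_init__(self) -> None:
        if len(self.emission_times) != len(self.bunch_sizes):
            raise ValueError("one size per emission time required")

    @property
    def n_electrons(self) -> int:
        return int(self.bunch_sizes.sum())

    @property
    def n_bunches(self) -> int:
        return len(self.emission_times)

    @property
    def dt(self) -> np.ndarray:
        """Intervals between successive bunches."""
        return np.diff(self.emission_times)


def make_pulse_train(
    dose_per_pulse: float,
    width: float,
    n_pulses: int = 1,
    frequency: float | None = None,
) -> PulseTrain:
    """Construct a rectangular pulse train; see :class:`PulseTrain`."""
    return PulseTrain(dose_per_pulse, width, n_pulses, frequency)


def sample_emission_times(
    n_electrons: int,
    per_bunch: int,
    pulse: PulseTrain,
    rng: np.random.Generator,
    mode: str = "uniform",
    pulse_index: int = 0,
) -> BunchSchedule:
    """Assign bunch emission times within one pulse of the train.

    ``mode="uniform"`` draws bunch times uniformly over the pulse window
    (the rectangular temporal profile); ``mode="even"`` spaces them evenly
    for reproducibility studies.  A zero-width pulse puts every electron at
    the pulse start.  The last bunch carries the remainder when
    ``per_bunch`` does not divide ``n_electrons``.
    """
    if per_bunch < 1:
        raise ValueError("per_bunch must be >= 1")
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    start = float(pulse.pulse_starts[pulse_index])
    n_bunches = -(-n_electrons // per_bunch)  # ceil
    sizes = np.full(n_bunches, per_bunch, dtype=int)
    remainder = n_electrons - per_bunch * (n_bunches - 1)
    sizes[-1] = remainder
    if pulse.instantaneous:
        times = np.full(n_bunches, start)
    elif mode == "uniform":
        times = np.sort(rng.uniform(start, start + pulse.pulse_width, n_bunches))
    elif mode == "even":
        # bin midpoints, so a single bunch sits mid-pulse
        times = start + (np.arange(n_bunches) + 0.5) / n_bunches * pulse.pulse_width
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    return BunchSchedule(times, sizes, per_bunch)


def dose_rate_profile(train: PulseTrain, t: float | np.ndarray) -> float | np.ndarray:
    """Dose rate (Gy/s) of the rectangular train at time(s) ``t``.

    Inside any pulse window the rate is dose_per_pulse / width; outside it
    is zero.  Instantaneous pulses are Dirac deposits handled by the
    integrator's event path, so querying this profile for them is an error.
    """
    if train.instantaneous:
        raise ValueError(
            "instantaneous pulses have no dose-rate profile; "
            "use discrete deposits at pulse starts"
        )
    t = np.asarray(t, dtype=float)
    starts = train.pulse_starts
    # in-pulse iff t - nearest start below it is within the width
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    inside = (t >= starts[idx]) & (t <= starts[idx] + train.pulse_width)
    out = np.where(inside, train.dose_rate, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Scenario:
    """One study condition: a single pulse at a given dose-per-pulse."""

    name: str
    dose_per_pulse: float  # Gy
    pulse_width: float  # s (0 = instantaneous)
    electrons_per_bunch: int
    ssd_cm: float
    note: str = ""

    def pulse_train(self) -> PulseTrain:
        return PulseTrain(self.dose_per_pulse, self.pulse_width, 1, None)


_PULSE_WIDTH_S = 1.8e-6


def scenario_table() -> list[Scenario]:
    """The four single-pulse study scenarios (plus the instantaneous 5 Gy
    variant): dose-per-pulse 0.17/1/5/10 Gy, 1.8 us rectangular pulses,
    1/10/50/500 electrons per bunch, SSD annotations in cm."""
    return [
        Scenario("0.17Gy", 0.17, _PULSE_WIDTH_S, 1, 190.0,
                 "SSD reading ambiguous in source; likely 190 cm"),
        Scenario("1Gy", 1.0, _PULSE_WIDTH_S, 10, 95.0),
        Scenario("5Gy", 5.0, _PULSE_WIDTH_S, 50, 46.0),
        Scenario("5Gy-instant", 5.0, 0.0, 50, 46.0,
                 "instantaneous variant: all electrons share one emission time"),
        Scenario("10Gy", 10.0, _PULSE_WIDTH_S, 500, 34.0),
    ]


def get_scenario(name: str) -> Scenario:
    for sc in scenario_table():
        if sc.name == name:
            return sc
    raise KeyError(f"unknown scenario {name!r}")
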