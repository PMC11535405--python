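"""Homogeneous reaction-network kinetics over pulse trains.

Once the radiolytic species distribution can be treated as spatially
homogeneous, the chemistry reduces to a stiff ODE system

    dC/dt = S r(C) + inj(t)

with S the stoichiometry matrix, r the mass-action rate vector and inj(t)
the radiolytic source: primary yields (G values, entities per 100 eV)
converted to mol/L per gray and multiplied by the instantaneous dose rate.
Reservoir species (the solvent, optionally the acid/base pair or O2) are
held fixed.  Integration uses SciPy's ``solve_ivp`` with the LSODA method,
which switches automatically between stiff and non-stiff steppers, and is
restarted at every pulse boundary so the discontinuous source never crosses
a solver step.  Instantaneous (zero-width) pulses are applied as discrete
concentration increments at the pulse times.

G values reported during a pulse are normalized to the energy imparted by
the *entire* pulse train, not the dose delivered so far.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .constants import CONC_PER_G_PER_GY, O2_ONE_PERCENT_M, WATER_MOLARITY
from .pulse_structure import PulseTrain
from .reaction_network import ReactionNetwork

__all__ = [
    "ConcentrationState",
    "PrimaryYieldSet",
    "ConcentrationTimeSeries",
    "IntegratorConfig",
    "IntegrationError",
    "concentration_from_g",
    "g_from_concentration",
    "build_rhs",
    "integrate",
    "handoff_initialize",
    "background_water",
    "default_time_grid",
]


class IntegrationError(RuntimeError):
    """Solver failure, carrying the time reached and suspect species."""


@dataclass
class ConcentrationState:
    """Per-species concentrations (mol/L) at one time point."""

    concentrations: dict[str, float]
    time: float = 0.0

    def copy(self) -> "ConcentrationState":
        return ConcentrationState(dict(self.concentrations), self.time)


@dataclass(frozen=True)
class PrimaryYieldSet:
    """Primary (escape) yields per species, entities per 100 eV.

    These seed the homogeneous phase: either as the hand-off state after the
    track-structure phase, or as the injection rate during a pulse.
    """

    g_values: Mapping[str, float]
    mode: str = "handoff_5us"  # or "per_pulse_injection"

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.g_values.values()):
            raise ValueError("G values must be non-negative")

    def get(self, name: str) -> float:
        return float(self.g_values.get(name, 0.0))


def concentration_from_g(G: float, dose: float) -> float:
    """Convert a G value (per 100 eV) at a given dose (Gy) to mol/L in
    unit-density water: C = G * D / (100 e N_A) = 1.0364e-7 * G * D."""
    if G < 0 or dose < 0:
        raise ValueError("G and dose must be non-negative")
    return CONC_PER_G_PER_GY * G * dose

def g_from_concentration(C: float, total_dose: float) -> float:
    """Inverse conversion; ``total_dose`` is the full-pulse(-train) dose, so
    mid-pulse G values are normalized to the entire pulse energy."""
    if total_dose <= 0:
        raise ValueError("total_dose must be positive")
    return C / (CONC_PER_G_PER_GY * total_dose)


@dataclass
class IntegratorConfig:
    """Numerical knobs for the stiff integrator.

    The concentration span (1e-12 to 1e-3 M) demands a tight absolute
    tolerance; values in (-clip_floor, 0) at output are floored to zero,
    larger negative excursions abort.
    """

    rtol: float = 1e-8
    atol: float = 1e-14
    method: str = "LSODA"
    max_step: float = np.inf
    clip_floor: float = 1e-12
    #: dose (Gy) used to normalize G values when no train is supplied
    #: (hand-off mode); a supplied train uses its total dose.
    normalization_dose: float | None = None


@dataclass
class ConcentrationTimeSeries:
    """Concentrations and G values on a time grid.

    ``concentrations`` is (n_times, n_species); G values are derived from
    concentrations with the fixed conversion at ``normalization_dose``.
    """

    times: np.ndarray
    species: list[str]
    concentrations: np.ndarray
    normalization_dose: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def g_values(self) -> np.ndarray:
        return self.concentrations / (CONC_PER_G_PER_GY * self.normalization_dose)

    def concentration(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(name)]

    def g_value(self, name: str) -> np.ndarray:
        return self.g_values[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.times}
        for i, name in enumerate(self.species):
            data[f"{name}_M"] = self.concentrations[:, i]
        for i, name in enumerate(self.species):
            data[f"{name}_G_per_100eV"] = self.g_values[:, i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def _compile_rates(network: ReactionNetwork):
    """Precompute index arrays so the rate vector is a few numpy ops.

    Each reaction contributes rate = k_eff * y[iA] * y[iB], where constant
    reactants are folded into k_eff and absent slots read as 1.
    """
    n_rxn = len(network.reactions)
    k_eff = np.empty(n_rxn)
    iA = np.full(n_rxn, -1, dtype=int)
    iB = np.full(n_rxn, -1, dtype=int)
    for j, rxn in enumerate(network.reactions):
        k_eff[j] = rxn.k
        dyn = []
        for sp in rxn.kinetic_reactants():
            if sp.is_constant:
                k_eff[j] *= sp.constant_concentration
            else:
                dyn.append(network.species_index[sp.name])
        if len(dyn) > 0:
            iA[j] = dyn[0]
        if len(dyn) > 1:
            iB[j] = dyn[1]
    return k_eff, iA, iB


def build_rhs(
    network: ReactionNetwork,
    source: Callable[[float], np.ndarray] | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Assemble dC/dt = S r(C) + inj(t) for the dynamic species.

    ``source(t)`` returns a per-species injection vector in mol/L/s (full
    species order); rows of constant-concentration species are forced to
    zero so reservoirs are never integrated.
    """
    k_eff, iA, iB = _compile_rates(network)
    S = network.stoichiometry.copy()
    dynamic = np.array([not sp.is_constant for sp in network.species])
    S[~dynamic, :] = 0.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)  # guard small negative solver excursions
        fA = np.where(iA >= 0, yc[np.maximum(iA, 0)], 1.0)
        fB = np.where(iB >= 0, yc[np.maximum(iB, 0)], 1.0)
        rates = k_eff * fA * fB
        dy = S @ rates
        if source is not None:
            dy = dy + np.where(dynamic, source(t), 0.0)
        return dy

    return rhs


# ---------------------------------------------------------------------------
# Backgrounds, hand-off, time grids
# ---------------------------------------------------------------------------


def background_water(
    o2: float = O2_ONE_PERCENT_M, ph: float = 7.0
) -> dict[str, float]:
    """Unirradiated water composition: solvent, acid/base pair at the given
    pH (neutral: [H3O+] = [OH-] = 1e-7 M at 25 degC) and dissolved oxygen
    (default 1% of O2-saturated water)."""
    h = 10.0 ** (-ph)
    return {
        "H2O": WATER_MOLARITY,
        "H3O+": h,
        "OH-": 1e-14 / h,
        "O2": o2,
    }


def handoff_initialize(
    yields: PrimaryYieldSet,
    dose: float,
    background: Mapping[str, float] | None = None,
) -> ConcentrationState:
    """State at the hand-off time: background water plus the primary yields
    converted to concentrations at the delivered dose."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    conc = dict(background if background is not None else background_water())
    for name, g in yields.g_values.items():
        conc[name] = conc.get(name, 0.0) + concentration_from_g(g, dose)
    return ConcentrationState(conc, time=0.0)


def default_time_grid(
    t_start: float = 1e-9,
    t_end: float = 1e2,
    per_decade: int = 20,
    train: PulseTrain | None = None,
    n_in_pulse: int = 30,
) -> np.ndarray:
    """Logarithmic grid from t_start to t_end with linear refinement inside
    each pulse window of ``train``."""
    n = int(np.ceil(per_decade * np.log10(t_end / t_start))) + 1
    grid = np.geomspace(t_start, t_end, n)
    if train is not None and not train.instantaneous:
        for s in train.pulse_starts:
            lin = np.linspace(s, s + train.pulse_width, n_in_pulse)
            grid = np.concatenate([grid, lin[lin > 0]])
    grid = np.unique(grid)
    return grid[(grid >= min(t_start, grid[0])) & (grid <= t_end)]


# ---------------------------------------------------------------------------
# Integration over a pulse train
# ---------------------------------------------------------------------------


def _injection_vector(
    network: ReactionNetwork, yields: PrimaryYieldSet | None
) -> np.ndarray:
    """Per-species mol/L per Gy injected by the radiolytic source."""
    vec = np.zeros(len(network.species))
    if yields is None:
        return vec
    for name, g in yields.g_values.items():
        if name not in network.species_index:
            raise KeyError(f"yield for unknown species {name!r}")
        vec[network.species_index[name]] = CONC_PER_G_PER_GY * g
    return vec


def integrate(
    network: ReactionNetwork,
    initial: ConcentrationState,
    train: PulseTrain | None,
    yields: PrimaryYieldSet | None,
    t_grid: np.ndarray,
    config: IntegratorConfig | None = None,
) -> ConcentrationTimeSeries:
    """Integrate the network over ``t_grid``, injecting the pulse train.

    With ``train=None`` (or ``yields=None``) the system evolves freely from
    the initial state — the hand-off mode, where ``initial`` already
    contains the radiolytic species.  With a finite-width train, yields are
    injected continuously at the in-pulse dose rate; with an instantaneous
    train they are applied as concentration increments at the pulse starts.

    The output is sampled exactly on ``t_grid`` and G values are normalized
    to the train's total dose (or ``initial`` hand-off dose recorded by the
    caller via ``normalization_dose`` metadata).
    """
    config = config or IntegratorConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    t0 = initial.time
    if t_grid[0] < t0:
        raise ValueError("t_grid must start at or after the initial time")

    names = network.species_names()
    y0 = np.array([initial.concentrations.get(n, 0.0) for n in names])
    for sp in network.species:
        if sp.is_constant:
            y0[network.species_index[sp.name]] = sp.constant_concentration

    inj_per_gy = _injection_vector(network, yields)
    # breakpoints where the source term is discontinuous
    events: list[tuple[float, str]] = []
    if train is not None and yields is not None:
        for s in train.pulse_starts:
            if train.instantaneous:
                events.append((float(s), "kick"))
            else:
                events.append((float(s), "on"))
                events.append((float(s + train.pulse_width), "off"))
    events = sorted([e for e in events if e[0] >= t0], key=lambda e: e[0])

    t_end = float(t_grid[-1])
    breakpoints = sorted({t0, t_end, *[e[0] for e in events if e[0] <= t_end]})

    out = np.empty((len(t_grid), len(names)))
    filled = np.zeros(len(t_grid), dtype=bool)
    if t_grid[0] == t0:
        out[0] = y0
        filled[0] = True

    rate_on = train.dose_rate if (train is not None and not train.instantaneous) else 0.0

    y = y0.copy()
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        # apply instantaneous kicks scheduled at the segment start
        for et, kind in events:
            if et == a and kind == "kick":
                y = y + inj_per_gy * train.dose_per_pulse  # type: ignore[union-attr]
        # is the source on inside (a, b)?
        source_on = False
        if train is not None and not train.instantaneous:
            mid = 0.5 * (a + b)
            starts = train.pulse_starts
            source_on = bool(
                np.any((mid >= starts) & (mid <= starts + train.pulse_width))
            )
        inj = inj_per_gy * rate_on if source_on else None
        rhs = build_rhs(network, (lambda t, v=inj: v) if inj is not None else None)
        mask = (t_grid > a) & (t_grid <= b) & ~filled
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            max_step=config.max_step,
            t_eval=np.concatenate([t_eval, [b]]) if (len(t_eval) == 0 or t_eval[-1] < b) else t_eval,
            dense_output=False,
        )
        if not sol.success:
            worst = names[int(np.argmin(sol.y[:, -1]))] if sol.y.size else "?"
            raise IntegrationError(
                f"integrator failed at t={sol.t[-1] if sol.t.size else a:.3e} s "
                f"(segment [{a:.3e}, {b:.3e}]); suspect species: {worst}: {sol.message}"
            )
        if len(t_eval):
            out[mask] = sol.y[:, : len(t_eval)].T
            filled[mask] = True
        y = sol.y[:, -1]

    if not np.all(filled):
        # grid points at/below t0 other than the first are a caller error
        raise IntegrationError("internal: unfilled grid points")

    # instantaneous kicks land *at* pulse times: grid points equal to a kick
    # time report the post-kick (right-limit) state
    if train is not None and train.instantaneous and yields is not None:
        for s in train.pulse_starts:
            hit = (t_grid == s) & (t_grid >= t0)
            if np.any(hit):
                out[hit] += inj_per_gy * train.dose_per_pulse

    # floor tiny negative excursions; abort on large ones
    neg = out < 0
    if np.any(out < -config.clip_floor):
        i, j = np.unravel_index(np.argmin(out), out.shape)
        raise IntegrationError(
            f"negative concentration {out[i, j]:.3e} M for {names[j]} "
            f"at t={t_grid[i]:.3e} s"
        )
    out[neg] = 0.0

    # pin constant species in the output
    for sp in network.species:
        if sp.is_constant:
            out[:, network.species_index[sp.name]] = sp.constant_concentration

    if config.normalization_dose is not None:
        norm_dose = config.normalization_dose
    elif train is not None:
        norm_dose = train.total_dose
    else:
        norm_dose = 1.0
    meta = {
        "mode": (yields.mode if yields is not None else "free-evolution"),
        "rtol": config.rtol,
        "atol": config.atol,
        "method": config.method,
    }
    return ConcentrationTimeSeries(t_grid, names, out, float(norm_dose), meta)
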