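"""Synthetic stand-ins for the inputs normally scored by a macroscopic
beam-transport simulation.

Two fixtures make the pipeline self-contained:

* a joint (energy, cos(theta)) fluence distribution emulating the source
  scored in the irradiated sample — a forward-peaked high-energy component
  (electrons that kept most of the beam energy travel near the beam axis)
  on top of an isotropic low-energy component (slowed-down electrons lose
  directional memory), normalized to a configurable total fluence per gray
  (~32 um^-2 Gy^-1 for a minimum-ionizing electron beam);
* a primary-yield table (escape G values) seeding the homogeneous phase.

Both are labelled synthetic: they reproduce the *structure* of the real
inputs, not their scored values, so tests built on them probe pipeline
behaviour and trends rather than absolute levels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .kinetics_engine import PrimaryYieldSet
from .sphere_source import JointEnergyDirectionDistribution

__all__ = ["FixtureSpec", "synth_joint_distribution", "default_primary_yields"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic joint spectral-angular distribution.

    The high-energy component is Gaussian in energy (beam energy minus a
    few-MeV collisional loss) and exponentially concentrated toward
    cos(theta) = 1 with concentration ``angular_concentration``; a fraction
    ``isotropic_fraction`` of the fluence is carried by an isotropic
    exponential low-energy tail.
    """

    peak_energy_MeV: float = 3.0
    energy_spread_MeV: float = 0.5
    angular_concentration: float = 40.0
    isotropic_fraction: float = 0.3
    low_energy_scale_MeV: float = 0.5
    total_fluence_per_gy: float = 32.0  # um^-2 Gy^-1
    energy_max_MeV: float = 6.0
    n_energy_bins: int = 32
    n_cos_bins: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.isotropic_fraction <= 1.0):
            raise ValueError("isotropic_fraction must be in [0, 1]")
        if self.total_fluence_per_gy <= 0:
            raise ValueError("total fluence must be positive")


def synth_joint_distribution(spec: FixtureSpec) -> JointEnergyDirectionDistribution:
    """Build the binned joint distribution for a fixture spec.

    Weights are evaluated analytically on the bin grid (bin-center density
    times bin area) and renormalized to the spec total, so regeneration is
    deterministic and byte-identical for equal specs.
    """
    e_edges = np.linspace(0.0, spec.energy_max_MeV, spec.n_energy_bins + 1)
    c_edges = np.linspace(-1.0, 1.0, spec.n_cos_bins + 1)
    e_mid = 0.5 * (e_edges[:-1] + e_edges[1:])
    c_mid = 0.5 * (c_edges[:-1] + c_edges[1:])

    # forward-peaked high-energy component
    beam_e = np.exp(-0.5 * ((e_mid - spec.peak_energy_MeV) / spec.energy_spread_MeV) ** 2)
    kappa = spec.angular_concentration
    beam_c = np.exp(kappa * (c_mid - 1.0))
    beam = np.outer(beam_e / beam_e.sum(), beam_c / beam_c.sum())

    # isotropic low-energy component
    tail_e = np.exp(-e_mid / spec.low_energy_scale_MeV)
    tail = np.outer(tail_e / tail_e.sum(), np.full_like(c_mid, 1.0 / len(c_mid)))

    w = (1.0 - spec.isotropic_fraction) * beam + spec.isotropic_fraction * tail
    w *= spec.total_fluence_per_gy / w.sum()
    return JointEnergyDirectionDistribution(e_edges, c_edges, w)


def default_primary_yields(mode: str = "handoff_5us") -> PrimaryYieldSet:
    """Load the packaged synthetic primary-yield table.

    ``mode`` is either ``"handoff_5us"`` (yields define the state handed to
    the solver after the track-structure phase) or
    ``"per_pulse_injection"`` (yields define the in-pulse injection rate);
    both use the same stand-in escape-yield values, the mode is recorded so
    downstream output is labelled with how the yields were applied.
    """
    if mode not in ("handoff_5us", "per_pulse_injection"):
        raise ValueError(f"unknown yields mode {mode!r}")
    text = (
        importlib.resources.files("flashlysis.data")
        .joinpath("primary_yields_synthetic.tsv")
        .read_text()
    )
    g: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        g[fields[0]] = float(fields[1])
    return PrimaryYieldSet(g, mode=mode)
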