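"""Fluence/dose consistency bookkeeping.

For electron beams near the minimum-ionizing regime the mass stopping power
of water is ~2 MeV cm^2/g, so dividing the delivered dose by the stopping
power estimates the electron fluence: 10 Gy corresponds to about
312 um^-2 (i.e. ~31.2 um^-2 Gy^-1), a useful cross-check on any sampled
source distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GY_TO_MEV_PER_G

__all__ = ["StoppingPowerSpec", "fluence_from_dose", "electrons_through_sphere"]


@dataclass(frozen=True)
class StoppingPowerSpec:
    """A scalar mass stopping power with a validity annotation."""

    mass_stopping_power: float = 2.0  # MeV cm^2 / g
    note: str = "minimum-ionizing electrons (~MeV range) in water"

    def __post_init__(self) -> None:
        if self.mass_stopping_power <= 0:
            raise ValueError("mass stopping power must be positive")


def fluence_from_dose(dose: float, sp: StoppingPowerSpec) -> float:
    """Fluence (um^-2) implied by a dose (Gy) and mass stopping power:
    Phi = D * 6.242e9 (MeV/g/Gy) / (S/rho), converted from cm^-2."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    per_cm2 = dose * GY_TO_MEV_PER_G / sp.mass_stopping_power
    return per_cm2 * 1e-8  # cm^-2 -> um^-2


def electrons_through_sphere(fluence: float, R: float) -> float:
    """Expected electron count through a sphere of radius R (um) for a given
    fluence (um^-2): N = Phi * pi R^2 (cross-sectional disk area)."""
    if fluence < 0 or R < 0:
        raise ValueError("inputs must be >= 0")
    return fluence * np.pi * R * R
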