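"""Electron source on a micron-scale spherical water target.

The primary-electron source is characterized by a joint spectral-angular
distribution (energy x cos(theta), fluence density per bin in um^-2 Gy^-1)
scored in a macroscopic beam simulation, and by entry positions on the
sphere surface.  Positions follow the disk-chord construction: a point is
drawn uniformly on the disk of target radius perpendicular to the sampled
direction, and projected along that direction onto the upstream sphere
intersection, so the electron propagates toward the sphere interior.  For a
parallel beam this yields the classic chord-length density
p(l) = l / (2 R^2) on [0, 2R] with mean chord 4R/3.

Coordinates: beam along +z; theta is the polar angle from +z; cos(theta) is
stored rather than theta; the azimuth phi is isotropic by symmetry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ELEMENTARY_CHARGE_J

__all__ = [
    "JointEnergyDirectionDistribution",
    "SourcePoint",
    "sample_energy_direction",
    "chord_entry_point",
    "generate_source",
    "sphere_dose_to_energy",
    "n_electrons_for_dose",
]


@dataclass(frozen=True)
class JointEnergyDirectionDistribution:
    """Binned fluence density over (energy, cos(theta)).

    ``weights[i, j]`` is the fluence per unit dose (um^-2 Gy^-1) carried by
    electrons in energy bin i and direction bin j; the sum of all weights is
    the total fluence per gray.
    """

    energy_edges: np.ndarray  # MeV, strictly increasing, len nE+1
    cos_edges: np.ndarray  # in [-1, 1], strictly increasing, len nC+1
    weights: np.ndarray  # (nE, nC), >= 0

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_edges, dtype=float)
        c = np.asarray(self.cos_edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if c[0] < -1 - 1e-12 or c[-1] > 1 + 1e-12:
            raise ValueError("cos(theta) edges must lie in [-1, 1]")
        if w.shape != (len(e) - 1, len(c) - 1):
            raise ValueError("weights shape must be (n_energy_bins, n_cos_bins)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "energy_edges", e)
        object.__setattr__(self, "cos_edges", c)
        object.__setattr__(self, "weights", w)

    @property
    def total_fluence_per_gy(self) -> float:
        """Sum of all bin contents, um^-2 Gy^-1."""
        return float(self.weights.sum())

    def to_text(self) -> str:
        """Serialize as tabular text (energy-low/high, cos-low/high, weight)."""
        nE, nC = self.weights.shape
        ei, ci = np.meshgrid(np.arange(nE), np.arange(nC), indexing="ij")
        df = pd.DataFrame(
            {
                "energy_low_MeV": self.energy_edges[:-1][ei.ravel()],
                "energy_high_MeV": self.energy_edges[1:][ei.ravel()],
                "cos_low": self.cos_edges[:-1][ci.ravel()],
                "cos_high": self.cos_edges[1:][ci.ravel()],
                "weight_per_um2_per_Gy": self.weights.ravel(),
            }
        )
        return df.to_csv(sep="\t", index=False, float_format="%.9e")

    @classmethod
    def from_text(cls, text: str) -> "JointEnergyDirectionDistribution":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        e_edges = np.unique(
            np.concatenate([df["energy_low_MeV"], df["energy_high_MeV"]])
        )
        c_edges = np.unique(np.concatenate([df["cos_low"], df["cos_high"]]))
        weights = np.zeros((len(e_edges) - 1, len(c_edges) - 1))
        ei = np.searchsorted(e_edges, df["energy_low_MeV"])
        ci = np.searchsorted(c_edges, df["cos_low"])
        weights[ei, ci] = df["weight_per_um2_per_Gy"]
        return cls(e_edges, c_edges, weights)


@dataclass(frozen=True)
class SourcePoint:
    """One sampled primary electron at the sphere surface."""

    position: np.ndarray  # um, |position| = R
    direction: np.ndarray  # unit vector, points into the sphere
    energy: float  # MeV
    emission_time: float  # s


def sample_energy_direction(
    dist: JointEnergyDirectionDistribution,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw (energy MeV, cos(theta), phi) from the joint distribution.

    Bins are selected proportionally to their weights; values are uniform
    within a bin (the simplest faithful reading of a binned scoring);
    phi ~ Uniform[0, 2*pi).
    """
    total = dist.weights.sum()
    if total <= 0:
        raise ValueError("joint distribution has no positive weight")
    n = 1 if size is None else int(size)
    p = (dist.weights / total).ravel()
    flat = rng.choice(len(p), size=n, p=p)
    ei, ci = np.unravel_index(flat, dist.weights.shape)
    e_lo, e_hi = dist.energy_edges[ei], dist.energy_edges[ei + 1]
    c_lo, c_hi = dist.cos_edges[ci], dist.cos_edges[ci + 1]
    energy = rng.uniform(e_lo, e_hi)
    cos_theta = rng.uniform(c_lo, c_hi)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    if size is None:
        return float(energy[0]), float(cos_theta[0]), float(phi[0])
    return energy, cos_theta, phi


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``direction``."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def chord_entry_point(
    direction: np.ndarray,
    R: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Sample entry position(s) on the sphere for electrons travelling along
    ``direction``.

    A point is drawn uniformly on the disk of radius R perpendicular to the
    direction and projected upstream onto the sphere, so the returned
    position satisfies |position| = R and position . direction <= 0.  Rim
    points (zero chord) are a measure-zero event and are resampled.
    """
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if not np.isclose(norm, 1.0, rtol=1e-6):
        raise ValueError("direction must be a unit vector")
    d = d / norm
    n = 1 if size is None else int(size)
    u, v = _orthonormal_basis(d)
    # uniform on the disk: r = R*sqrt(U); resample exact rim hits
    usamp = rng.uniform(0.0, 1.0, n)
    while np.any(usamp == 1.0):  # pragma: no cover - measure-zero guard
        usamp[usamp == 1.0] = rng.uniform(0.0, 1.0, int(np.sum(usamp == 1.0)))
    r = R * np.sqrt(usamp)
    alpha = rng.uniform(0.0, 2.0 * np.pi, n)
    disk = r[:, None] * (np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * v)
    # upstream sphere intersection along d
    back = np.sqrt(R * R - r * r)
    pos = disk - back[:, None] * d
    return pos[0] if size is None else pos


def generate_source(
    dist: JointEnergyDirectionDistribution,
    schedule,
    R: float,
    rng: np.random.Generator,
) -> list[SourcePoint]:
    """Build the full per-electron source for one pulse.

    One :class:`SourcePoint` per electron; electrons within a bunch share
    the bunch emission time.  Deterministic under a fixed generator state.
    """
    if schedule.n_bunches == 0:
        return []
    n = schedule.n_electrons
    energy, cos_theta, phi = sample_energy_direction(dist, rng, size=n)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    directions = np.column_stack(
        (sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta)
    )
    times = np.repeat(schedule.emission_times, schedule.bunch_sizes)
    points = []
    for i in range(n):
        pos = chord_entry_point(directions[i], R, rng)
        points.append(SourcePoint(pos, directions[i], float(energy[i]), float(times[i])))
    return points


def sphere_dose_to_energy(dose: float, R: float) -> float:
    """Energy (eV) a given dose deposits in a unit-density water sphere of
    radius R (um): E = D * rho * (4/3) pi R^3.

    This is the dose-threshold bookkeeping that fixes how many electrons
    form a pulse.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    volume_m3 = (4.0 / 3.0) * np.pi * (R * 1e-6) ** 3
    mass_kg = 1000.0 * volume_m3  # rho = 1 g/cm^3
    return dose * mass_kg / ELEMENTARY_CHARGE_J


def n_electrons_for_dose(dose: float, R: float, mean_deposit_eV: float) -> int:
    """Electrons needed to reach a dose threshold in the sphere, given a
    caller-supplied mean energy deposit per electron (no track physics is
    modelled here)."""
    if mean_deposit_eV <= 0:
        raise ValueError("mean deposit per electron must be positive")
    return int(np.ceil(sphere_dose_to_energy(dose, R) / mean_deposit_eV))
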