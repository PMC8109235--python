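"""Closed-form auxiliary analyses.

Boltzmann inversion of number-density profiles into free-energy profiles,
conversion between a chain tilt angle and the second-order Legendre order
parameter, and the Sauerbrey relation between QCM-D frequency shifts and
areal mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GAS_CONSTANT",
    "DensityProfile",
    "FreeEnergyProfile",
    "QcmReading",
    "boltzmann_free_energy",
    "density_to_free_energy",
    "tilt_to_order_parameter",
    "order_parameter_to_tilt",
    "sauerbrey_mass",
]

GAS_CONSTANT = 8.314462  # J / (mol K)

#: Tilt angle (degrees) at which the order parameter crosses zero.
MAGIC_ANGLE = math.degrees(math.acos(1.0 / math.sqrt(3.0)))


@dataclass
class DensityProfile:
    """Number density n(z) against distance z from a reference surface.

    Densities beyond ``bulk_threshold`` (angstrom) define the bulk value
    N0 against which the free energy is measured.
    """

    z: np.ndarray
    n: np.ndarray
    bulk_threshold: float = 40.0

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.z.shape != self.n.shape:
            raise ValueError("z and n must have the same shape")
        if np.any(self.n < 0):
            raise ValueError("number densities must be non-negative")

    @classmethod
    def load(cls, path, bulk_threshold: float = 40.0) -> "DensityProfile":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], bulk_threshold)

    def bulk_density(self) -> float:
        mask = self.z > self.bulk_threshold
        if not np.any(mask):
            raise ConfigurationError(
                f"no profile points beyond the bulk threshold "
                f"({self.bulk_threshold} A); cannot define N0"
            )
        return float(self.n[mask].mean())


@dataclass
class FreeEnergyProfile:
    """Free energy dG(z) in kJ/mol relative to bulk (dG = 0 where n = N0)."""

    z: np.ndarray
    dG: np.ndarray
    temperature: float

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.z, self.dG]),
                   header="z [A]  dG [kJ/mol]")

    def minimum(self):
        """(z_min, dG_min): location and depth of the free-energy minimum."""
        i = int(np.nanargmin(self.dG))
        return float(self.z[i]), float(self.dG[i])


def boltzmann_free_energy(n_over_n0, temperature: float = 308.0):
    """dG = -R T ln(n/N0) in kJ/mol.

    Enrichment over bulk (n > N0) gives negative dG.  Zero densities map
    to +inf rather than raising, so profiles with excluded regions remain
    processable.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    ratio = np.asarray(n_over_n0, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("density ratio must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(ratio > 0,
                       -GAS_CONSTANT * temperature * np.log(np.maximum(ratio, 1e-300)) / 1e3,
                       np.inf)
    return out if np.ndim(n_over_n0) else float(out)


def density_to_free_energy(profile: DensityProfile,
                           temperature: float = 308.0) -> FreeEnergyProfile:
    """Boltzmann inversion of a density profile.

    N0 is the mean density beyond the profile's bulk threshold; the result
    is invariant to uniform rescaling of the densities.
    """
    n0 = profile.bulk_density()
    if n0 <= 0:
        raise ConfigurationError("bulk density is zero; cannot normalise")
    dg = boltzmann_free_energy(profile.n / n0, temperature)
    return FreeEnergyProfile(z=profile.z.copy(), dG=np.asarray(dg), temperature=temperature)


def tilt_to_order_parameter(theta: float) -> float:
    """Second-order Legendre order parameter S = (3 cos^2 theta - 1)/2.

    ``theta`` is the chain tilt from the surface normal in degrees; S = 1
    for a perfectly normal-aligned chain, 0 at the magic angle (54.74 deg).
    """
    if not 0.0 <= theta <= 90.0:
        raise ValueError(f"tilt angle must be in [0, 90] degrees, got {theta}")
    c = math.cos(math.radians(theta))
    return (3.0 * c * c - 1.0) / 2.0


def order_parameter_to_tilt(s: float) -> float:
    """Inverse of :func:`tilt_to_order_parameter` on the [0, 90] degree branch."""
    if not -0.5 <= s <= 1.0:
        raise ValueError(f"order parameter must be in [-0.5, 1], got {s}")
    return math.degrees(math.acos(math.sqrt((2.0 * s + 1.0) / 3.0)))


@dataclass
class QcmReading:
    """One QCM-D observation: frequency/dissipation change at an overtone.

    ``sensitivity_constant`` is the instrument mass sensitivity C in
    ng cm^-2 Hz^-1 (17.7 for a standard 5 MHz crystal); it must be
    configured, the analysis does not assume a crystal.
    """

    df: float
    overtone: int = 1
    dd: float = 0.0
    sensitivity_constant: float | None = None

    def __post_init__(self):
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ValueError(f"overtone must be an odd integer >= 1, got {self.overtone}")


def sauerbrey_mass(reading: QcmReading) -> float:
    """Areal mass change (ng/cm^2) from a rigid-film frequency shift.

    dm = -C df / n: a frequency decrease is a mass gain.
    """
    if reading.sensitivity_constant is None:
        raise ConfigurationError(
            "QcmReading.sensitivity_constant is not configured"
        )
    return -reading.sensitivity_constant * reading.df / reading.overtone


def read_qcm_trace(path):
    """Read a QCM-D trace from CSV: time, then df/dd pairs per overtone.

    The header row names the columns (e.g. ``time,df3,dd3,df5,dd5``);
    returns a dict mapping each column name to a numpy array.
    """
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise ConfigurationError(f"{path}: need a header row and data rows")
    names = [c.strip() for c in rows[0]]
    data = np.array([[float(v) for v in r] for r in rows[1:] if r])
    return {name: data[:, j] for j, name in enumerate(names)}
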