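"""Synthetic three-contrast reflectivity generation and ASCII dataset I/O.

The generator emulates the measurement design of the floating-bilayer
experiments: for every sample condition, reflectivity is produced in D2O,
H2O and gold-matched-water (AuMW, 75% D2O) contrasts on a log-spaced Q
grid (0.008-0.3 1/A, dQ/Q = 3.5% FWHM) with a constant incoherent
background and heteroscedastic counting noise.  Fixture scenarios carry
the resolved bilayer-to-SAM distances and conformal bilayer roughnesses
for each lipid composition across the CaCl2 -> EDTA -> NaCl -> CaCl2 salt
sequence, spanning distances of ~10-600 A and roughnesses of ~3-125 A so
that the micro-slicing regime (roughness comparable to the water-gap
thickness) is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParseError
from .fitting import ReflectivityDataset
from .model import (
    COMPOSITION_ALIASES,
    COMPOSITIONS,
    FFBStructure,
    IsotopicContrast,
    ffb_structure,
    model_reflectivity,
)
from .reflectivity import QGrid

__all__ = [
    "NoiseModel",
    "ScenarioFixture",
    "MEASURED_CELLS",
    "CONDITIONS",
    "default_qgrid",
    "simulate_dataset",
    "simulate_condition",
    "measured_fixture",
    "measured_scenario",
    "read_dataset",
    "write_dataset",
    "fixture_manifest",
]

CONDITIONS = ("CaCl2_initial", "EDTA", "NaCl", "CaCl2_final")

#: Resolved bilayer-to-SAM distance and conformal bilayer roughness (A) per
#: composition and salt condition, with 95% credible intervals, as obtained
#: from the co-refined measurements.  The plant-membrane EDTA cell could
#: not be determined experimentally and is absent.
MEASURED_CELLS = {
    ("POPC", "CaCl2_initial"): {"distance": (13, 11, 16), "roughness": (5, 4, 7)},
    ("POPC", "EDTA"): {"distance": (201, 195, 207), "roughness": (63, 60, 65)},
    ("POPC", "NaCl"): {"distance": (38, 36, 40), "roughness": (9, 7, 10)},
    ("POPC", "CaCl2_final"): {"distance": (13, 11, 15), "roughness": (3, 0, 5)},
    ("POPC:POPS 8:2", "CaCl2_initial"): {"distance": (12, 10, 13), "roughness": (8, 7, 9)},
    ("POPC:POPS 8:2", "EDTA"): {"distance": (594, 576, 611), "roughness": (125, 113, 138)},
    ("POPC:POPS 8:2", "NaCl"): {"distance": (100, 93, 107), "roughness": (55, 51, 59)},
    ("POPC:POPS 8:2", "CaCl2_final"): {"distance": (11, 9, 13), "roughness": (6, 4, 8)},
    ("POPC:POPS:DOPIP3 7:2:1", "CaCl2_initial"): {"distance": (11, 10, 13), "roughness": (6, 5, 7)},
    ("POPC:POPS:DOPIP3 7:2:1", "EDTA"): {"distance": (402, 392, 414), "roughness": (109, 102, 117)},
    ("POPC:POPS:DOPIP3 7:2:1", "NaCl"): {"distance": (97, 94, 100), "roughness": (35, 33, 37)},
    ("POPC:POPS:DOPIP3 7:2:1", "CaCl2_final"): {"distance": (10, 8, 11), "roughness": (6, 5, 7)},
    ("POPC:POPS:Chol:DGDG 5:2:2:1", "CaCl2_initial"): {"distance": (15, 13, 17), "roughness": (12, 11, 14)},
    ("POPC:POPS:Chol:DGDG 5:2:2:1", "NaCl"): {"distance": (121, 118, 125), "roughness": (31, 30, 34)},
    ("POPC:POPS:Chol:DGDG 5:2:2:1", "CaCl2_final"): {"distance": (14, 12, 16), "roughness": (10, 8, 11)},
}

DEFAULT_CONTRASTS = ("D2O", "H2O", "AuMW")


def default_qgrid(n: int = 120, qmin: float = 0.008, qmax: float = 0.3,
                  resolution: float = 0.035) -> QGrid:
    """Log-spaced Q grid typical of a time-of-flight reflectometer."""
    return QGrid(np.geomspace(qmin, qmax, n), resolution)


@dataclass
class NoiseModel:
    """Heteroscedastic counting-noise stand-in.

    The point uncertainty is ``dR = max(relative_floor * R, background_level)``:
    a fractional floor where the signal dominates and an absolute floor at
    the background level.  True instrument counting statistics are not
    emulated.
    """

    relative_floor: float = 0.02
    background_level: float = 5e-7

    def __post_init__(self):
        if self.relative_floor < 0 or self.background_level < 0:
            raise ConfigurationError("noise parameters must be non-negative")

    def dr(self, r: np.ndarray) -> np.ndarray:
        return np.maximum(self.relative_floor * np.abs(r), self.background_level)


@dataclass
class ScenarioFixture:
    """A measured-condition scenario: composition, salt condition, geometry."""

    composition: str
    condition: str
    distance: float
    roughness: float
    substrate: dict = field(default_factory=dict)
    area_per_molecule: float = 65.0
    coverage: float = 0.95
    sam_area_per_molecule: float = 22.0
    sam_coverage: float = 0.95

    def structure(self) -> FFBStructure:
        return ffb_structure(
            self.composition, self.condition, self.distance, self.roughness,
            area_per_molecule=self.area_per_molecule, coverage=self.coverage,
            sam_area_per_molecule=self.sam_area_per_molecule,
            sam_coverage=self.sam_coverage, substrate=self.substrate or None,
        )


def _canonical_composition(composition: str) -> str:
    comp = COMPOSITION_ALIASES.get(composition, composition)
    if comp not in COMPOSITIONS:
        raise ConfigurationError(f"unknown composition {composition!r}")
    return comp


def measured_scenario(composition: str, condition: str) -> ScenarioFixture:
    """Fixture scenario for one composition/condition cell."""
    comp = _canonical_composition(composition)
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    key = (comp, condition)
    if key not in MEASURED_CELLS:
        raise ConfigurationError(
            f"the {composition}/{condition} cell could not be determined "
            "experimentally; no fixture is available"
        )
    cell = MEASURED_CELLS[key]
    return ScenarioFixture(comp, condition, float(cell["distance"][0]),
                           float(cell["roughness"][0]))


def measured_fixture(composition: str, condition: str) -> FFBStructure:
    """Ground-truth structure at the resolved distance/roughness of a cell."""
    return measured_scenario(composition, condition).structure()


def fixture_manifest():
    """Every available (composition, condition) fixture cell."""
    return sorted(MEASURED_CELLS)


def simulate_dataset(structure: FFBStructure, contrast, grid: QGrid = None,
                     noise: NoiseModel = None, seed: int = 0, *,
                     scale: float = 1.0, n_quad: int = 17) -> ReflectivityDataset:
    """Simulate one reflectivity dataset: smeared model + background + noise.

    Reproducible for a given seed; with ``NoiseModel(0, 0)`` the simulated
    curve equals the deterministic forward model exactly.
    """
    if isinstance(contrast, str):
        contrast = IsotopicContrast.from_name(contrast)
    if grid is None:
        grid = default_qgrid()
    if noise is None:
        noise = NoiseModel()
    if grid.values[0] < 0.005 or grid.values[-1] > 0.4:
        import warnings
        warnings.warn("Q grid extends outside the validated 0.005-0.4 1/A range",
                      UserWarning, stacklevel=2)
    r_true = scale * model_reflectivity(structure, contrast, grid,
                                        slab_width=0.5, adaptive=False,
                                        n_quad=n_quad)
    r_true = r_true + noise.background_level
    dr = noise.dr(r_true)
    rng = np.random.default_rng(seed)
    r_sim = r_true + rng.normal(0.0, 1.0, r_true.size) * dr
    # strictly positive dR even for a zero-noise model, as fitting weights
    dr_out = np.maximum(dr, 1e-12)
    return ReflectivityDataset(
        grid=grid, r=r_sim, dr=dr_out, contrast=contrast,
        condition=structure.condition, scale=scale,
        background=noise.background_level,
        metadata={"seed": seed, "noise": noise, "truth": r_true},
    )


def simulate_condition(structure: FFBStructure, contrasts=DEFAULT_CONTRASTS,
                       grid: QGrid = None, noise: NoiseModel = None,
                       seed: int = 0, n_quad: int = 17):
    """Simulate the standard contrast series for one condition."""
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2 ** 31 - 1, size=len(contrasts))
    return [
        simulate_dataset(structure, c, grid, noise, int(s), n_quad=n_quad)
        for c, s in zip(contrasts, subseeds)
    ]


# ---------------------------------------------------------------------------
# ASCII dataset files: columns Q [1/A], R, dR, optional dQ (FWHM, 1/A);
# '#' comment lines; one file per contrast per condition.
# ---------------------------------------------------------------------------

def write_dataset(dataset: ReflectivityDataset, path) -> None:
    """Write a dataset as an ASCII column table (full float precision)."""
    res = dataset.grid.resolution_array
    cols = [dataset.grid.values, dataset.r, dataset.dr]
    header = [
        f"contrast: {dataset.contrast.name}",
        f"condition: {dataset.condition}",
        "columns: Q [1/A]  R  dR  dQ(FWHM) [1/A]",
    ]
    cols.append(res * dataset.grid.values)
    for line in dataset.metadata.get("header", []):
        header.append(line)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for row in zip(*cols):
            fh.write("  ".join(f"{v:.16e}" for v in row) + "\n")


def read_dataset(path, contrast=None, condition=None) -> ReflectivityDataset:
    """Read an ASCII reflectivity table.

    Three columns (Q, R, dR) use the file's or the default global dQ/Q;
    a fourth column gives per-point dQ (FWHM) which overrides it.  '#'
    lines are preserved as metadata; 'contrast:'/'condition:' headers set
    the labels unless overridden by the caller.
    """
    header, rows = [], []
    meta_contrast = meta_condition = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                header.append(text)
                low = text.lower()
                if low.startswith("contrast:"):
                    meta_contrast = text.split(":", 1)[1].strip()
                elif low.startswith("condition:"):
                    meta_condition = text.split(":", 1)[1].strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric value ({exc})") from None
            if len(vals) not in (3, 4):
                if len(vals) == 2:
                    raise ParseError(
                        f"{path}:{ln}: missing dR column; a point uncertainty "
                        "is required"
                    )
                raise ParseError(f"{path}:{ln}: expected 3 or 4 columns, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != ncol)
        raise ParseError(f"{path}: inconsistent column count at data row {bad + 1}")
    arr = np.array(rows, dtype=float)
    q = arr[:, 0]
    if ncol == 4:
        resolution = arr[:, 3] / q  # per-point dQ/Q from the dQ (FWHM) column
    else:
        resolution = 0.035
    grid = QGrid(q, resolution)
    contrast = contrast or meta_contrast or "D2O"
    if isinstance(contrast, str):
        contrast = IsotopicContrast.from_name(contrast)
    return ReflectivityDataset(
        grid=grid, r=arr[:, 1], dr=arr[:, 2], contrast=contrast,
        condition=condition or meta_condition or "custom",
        metadata={"header": header},
    )
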