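"""Molecular model of a gold/SAM/water-gap/floating-bilayer interface.

Layers are described at the molecule level — fragment volume, summed
coherent scattering length, area per molecule, coverage and bound water —
and rendered into slab stacks per isotopic contrast.  Two relations carry
the whole parametrisation:

* thickness = volume / (area per molecule)
* SLD = (sum of coherent scattering lengths) / volume

with any non-lipid / non-SAM fraction of a layer treated as
defect-associated solution, i.e. the layer SLD is the coverage-weighted
mean of the molecular SLD and the solvent SLD.  Head-group layers may
carry explicitly bound water, and solvent-exchangeable hydrogens take the
solvent's H/D labelling.

The full stack is ordered silicon / SiO2 / permalloy / gold / SAM / water
interlayer / inner head-groups / tails / outer head-groups / bulk solvent.
The water-interlayer thickness *is* the bilayer-to-SAM distance, the
headline observable of the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidModelError
from .reflectivity import (
    QGrid,
    Slab,
    SldProfile,
    adaptive_microslice,
    microslice,
    resolution_smeared_reflectivity,
    sld_profile,
)

__all__ = [
    "Parameter",
    "value_of",
    "IsotopicContrast",
    "MolecularLayer",
    "SubstrateLayer",
    "FFBStructure",
    "COMPOSITIONS",
    "component_table",
    "solvent_sld",
    "layer_thickness",
    "layer_sld",
    "molecular_layer",
    "sam_layer",
    "bilayer_leaflets",
    "ffb_structure",
    "build_stack",
    "bilayer_to_sam_distance",
    "structure_sld_profile",
    "model_reflectivity",
]

# fm -> 1e-6 A^-2 conversion for SLD = sumb / volume: 1 fm = 1e-5 A, and the
# result is reported in units of 1e-6 A^-2, so the net factor is 10.
_FM_PER_A3_TO_SLD = 10.0


def component_table() -> dict:
    """The editable reference table of fragment volumes and scattering lengths."""
    with resources.files("refloat.data").joinpath("lipid_components.json").open() as fh:
        return json.load(fh)


_TABLE = component_table()
_SOLVENT = _TABLE["solvent_sld"]
_WATER_VOLUME = _TABLE["water_volume"]
_B_EXCHANGE = _TABLE["b_exchange_per_h"]
SUBSTRATE_SLD = _TABLE["substrate_sld"]

#: Mole-fraction presets for the bilayer compositions studied.
COMPOSITIONS = {
    "POPC": {"POPC": 1.0},
    "POPC:POPS 8:2": {"POPC": 0.8, "POPS": 0.2},
    "POPC:POPS:DOPIP3 7:2:1": {"POPC": 0.7, "POPS": 0.2, "DOPIP3": 0.1},
    "POPC:POPS:Chol:DGDG 5:2:2:1": {
        "POPC": 0.5, "POPS": 0.2, "CHOL": 0.2, "DGDG": 0.1,
    },
}
#: Short aliases accepted wherever a composition label is expected.
COMPOSITION_ALIASES = {
    "mammalian": "POPC:POPS:DOPIP3 7:2:1",
    "plant": "POPC:POPS:Chol:DGDG 5:2:2:1",
}


class Parameter:
    """A named scalar that can be shared between structures and datasets.

    Sharing is by object identity: give two structures the *same*
    ``Parameter`` instance and a fit will refine one common value for both.
    """

    __slots__ = ("name", "value", "bounds", "vary")

    def __init__(self, value: float, name: str = "", bounds=None, vary: bool = False):
        self.value = float(value)
        self.name = name
        self.bounds = tuple(bounds) if bounds is not None else None
        self.vary = vary
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise ConfigurationError(f"bounds must satisfy lo < hi, got {bounds}")

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:
        tag = "vary" if self.vary else "fixed"
        return f"Parameter({self.name or '?'}={self.value:g}, {tag})"


def value_of(x) -> float:
    """Numeric value of a float or :class:`Parameter`."""
    return float(x)


@dataclass
class IsotopicContrast:
    """Solvent isotopic labelling state.

    ``d2o_fraction`` drives both the solvent SLD (linear mixing between the
    pure-H2O and pure-D2O values) and the labelling of solvent-exchangeable
    hydrogens in molecular fragments.  ``component_sumb`` may override the
    summed scattering length (fm) of a named layer under this labelling.
    """

    name: str
    d2o_fraction: float
    solvent_sld: float = None  # type: ignore[assignment]
    component_sumb: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ConfigurationError("d2o_fraction must lie in [0, 1]")
        if self.solvent_sld is None:
            self.solvent_sld = (
                self.d2o_fraction * _SOLVENT["D2O"]
                + (1.0 - self.d2o_fraction) * _SOLVENT["H2O"]
            )

    @classmethod
    def from_name(cls, name: str) -> "IsotopicContrast":
        key = name.upper().replace("₂", "2")
        if key == "D2O":
            return cls("D2O", 1.0)
        if key == "H2O":
            return cls("H2O", 0.0)
        if key == "AUMW":  # gold-matched water, 75:25 D2O:H2O by volume
            return cls("AuMW", 0.75)
        raise ConfigurationError(
            f"unknown contrast {name!r}; use D2O/H2O/AuMW or construct "
            "IsotopicContrast with an explicit d2o_fraction/solvent_sld"
        )

    @property
    def water_sumb(self) -> float:
        """Scattering length (fm) of one solvent molecule under this labelling."""
        return self.solvent_sld * _WATER_VOLUME / _FM_PER_A3_TO_SLD


def solvent_sld(contrast) -> float:
    """Solvent SLD (1e-6 A^-2) for a contrast name or IsotopicContrast."""
    if isinstance(contrast, str):
        contrast = IsotopicContrast.from_name(contrast)
    return contrast.solvent_sld


@dataclass
class MolecularLayer:
    """Molecule-level description of one layer.

    ``component_volume`` (A^3) and ``sumb_h`` (fm, fully protonated) refer
    to one molecule (or one mole-fraction-averaged pseudo-molecule for a
    mixture); ``labile_h`` counts solvent-exchangeable hydrogens.
    ``bound_waters`` adds explicitly associated water to head-group layers.
    """

    name: str
    component_volume: float
    sumb_h: float
    labile_h: float = 0.0
    area_per_molecule: Parameter | float = 60.0
    coverage: Parameter | float = 1.0
    bound_waters: Parameter | float = 0.0

    def sumb(self, contrast: IsotopicContrast) -> float:
        """Summed scattering length (fm) of the molecule under a labelling."""
        if self.name in contrast.component_sumb:
            return contrast.component_sumb[self.name]
        return self.sumb_h + self.labile_h * contrast.d2o_fraction * _B_EXCHANGE


def layer_thickness(layer: MolecularLayer) -> float:
    """thickness = volume / area-per-molecule, including bound water."""
    apm = value_of(layer.area_per_molecule)
    if apm <= 0:
        raise InvalidModelError(f"area per molecule must be positive, got {apm}")
    vol = layer.component_volume + value_of(layer.bound_waters) * _WATER_VOLUME
    return vol / apm


def layer_sld(layer: MolecularLayer, contrast: IsotopicContrast) -> float:
    """Coverage-mixed layer SLD (1e-6 A^-2) under a contrast.

    The molecular SLD is sumb/volume with bound water mixed in additively
    (both volume and scattering length); the remaining (1 - coverage)
    fraction of the layer is defect-associated solvent.
    """
    cov = value_of(layer.coverage)
    if not 0.0 <= cov <= 1.0:
        raise InvalidModelError(f"coverage must lie in [0, 1], got {cov}")
    if layer.component_volume <= 0:
        raise InvalidModelError("component volume must be positive")
    nw = value_of(layer.bound_waters)
    vol = layer.component_volume + nw * _WATER_VOLUME
    b = layer.sumb(contrast) + nw * contrast.water_sumb
    molecular = b / vol * _FM_PER_A3_TO_SLD
    return cov * molecular + (1.0 - cov) * contrast.solvent_sld


@dataclass
class SubstrateLayer:
    """One metallic/oxide under-layer (thickness, SLD, upper roughness)."""

    name: str
    thickness: Parameter | float
    sld: Parameter | float
    roughness: Parameter | float

    def slab(self) -> Slab:
        return Slab(value_of(self.thickness), value_of(self.sld),
                    value_of(self.roughness))


@dataclass
class FFBStructure:
    """Full interfacial structure for one sample condition.

    ``interlayer_thickness`` is the water-gap thickness between the SAM and
    the proximal bilayer head groups — the bilayer-to-SAM distance.  A
    SAM-only structure (no bilayer deposited) has ``inner_heads`` etc. set
    to ``None``.  ``bilayer_roughness`` is conformal: the same width is
    applied to every bilayer-adjacent interface.
    """

    condition: str
    sio2: SubstrateLayer
    permalloy: SubstrateLayer
    gold: SubstrateLayer
    sam: MolecularLayer
    sam_roughness: Parameter | float = 4.0        # gold/SAM interface
    sam_water_roughness: Parameter | float = 4.0  # SAM/water interface
    interlayer_thickness: Parameter | float = 0.0
    inner_heads: Optional[MolecularLayer] = None
    tails: Optional[MolecularLayer] = None
    outer_heads: Optional[MolecularLayer] = None
    bilayer_roughness: Parameter | float = 5.0
    composition: str = ""

    @property
    def has_bilayer(self) -> bool:
        return self.tails is not None

    def __post_init__(self):
        parts = (self.inner_heads, self.tails, self.outer_heads)
        if any(p is not None for p in parts) and any(p is None for p in parts):
            raise InvalidModelError(
                "inner_heads, tails and outer_heads must be given together"
            )
        if value_of(self.interlayer_thickness) < 0:
            raise InvalidModelError("interlayer thickness must be non-negative")

    def parameters(self):
        """Every :class:`Parameter` in the structure, deduplicated by identity."""
        seen, out = set(), []

        def visit(obj):
            if isinstance(obj, Parameter) and id(obj) not in seen:
                seen.add(id(obj))
                out.append(obj)

        for sub in (self.sio2, self.permalloy, self.gold):
            for f in (sub.thickness, sub.sld, sub.roughness):
                visit(f)
        layers = [self.sam, self.inner_heads, self.tails, self.outer_heads]
        for lay in layers:
            if lay is None:
                continue
            for f in (lay.area_per_molecule, lay.coverage, lay.bound_waters):
                visit(f)
        for f in (self.sam_roughness, self.sam_water_roughness,
                  self.interlayer_thickness, self.bilayer_roughness):
            visit(f)
        return out


def _fragments():
    return _TABLE["fragments"]


def molecular_layer(name, fragment_keys, fractions, **kw) -> MolecularLayer:
    """Mole-fraction-averaged pseudo-molecule layer from table fragments."""
    frags = _fragments()
    vol = sumb = labile = 0.0
    for key, x in zip(fragment_keys, fractions):
        if key is None:
            continue
        fr = frags[key]
        vol += x * fr["volume"]
        sumb += x * fr["sumb_h"]
        labile += x * fr["labile_h"]
    return MolecularLayer(name, vol, sumb, labile, **kw)


def sam_layer(area_per_molecule=22.0, coverage=1.0, bound_waters=0.0) -> MolecularLayer:
    """COOH-OEG alkanethiol monolayer as a single molecular slab."""
    fr = _fragments()["SAM"]
    return MolecularLayer("SAM", fr["volume"], fr["sumb_h"], fr["labile_h"],
                          area_per_molecule=area_per_molecule,
                          coverage=coverage, bound_waters=bound_waters)


def bilayer_leaflets(composition, *, area_per_molecule, coverage,
                     bound_waters=2.0, decouple_leaflets=False):
    """Build (inner_heads, tails, outer_heads) for a lipid composition.

    Head and tail layers of a leaflet share one area-per-molecule, which
    fixes the head:tail molar ratio at 1:1 (they are parts of the same
    molecule).  By default both leaflets share that area too; pass
    ``decouple_leaflets=True`` to give the outer leaflet its own copy.
    """
    if isinstance(composition, str):
        composition = COMPOSITIONS[COMPOSITION_ALIASES.get(composition, composition)]
    lipids = _TABLE["lipids"]
    names = list(composition)
    xs = np.array([composition[n] for n in names], dtype=float)
    xs = xs / xs.sum()
    head_keys = [lipids[n]["head"] for n in names]
    tail_keys = [lipids[n]["tail"] for n in names]

    inner = molecular_layer("inner_heads", head_keys, xs,
                            area_per_molecule=area_per_molecule,
                            coverage=coverage, bound_waters=bound_waters)
    tails = molecular_layer("tails", tail_keys, xs,
                            area_per_molecule=area_per_molecule,
                            coverage=coverage, bound_waters=0.0)
    outer_apm = area_per_molecule
    if decouple_leaflets and isinstance(area_per_molecule, Parameter):
        outer_apm = Parameter(area_per_molecule.value, "apm_outer",
                              area_per_molecule.bounds, area_per_molecule.vary)
    outer = replace(inner, name="outer_heads", area_per_molecule=outer_apm)
    return inner, tails, outer


#: Plausible substrate defaults (these metal thicknesses are configuration,
#: not literature values; edit per sample).
SUBSTRATE_DEFAULTS = {
    "sio2_thickness": 12.0, "permalloy_thickness": 150.0,
    "gold_thickness": 120.0,
    "sio2_roughness": 3.0, "permalloy_roughness": 5.0, "gold_roughness": 4.0,
}


def ffb_structure(composition, condition, distance, bilayer_roughness,
                  *, area_per_molecule=65.0, coverage=0.95, bound_waters=2.0,
                  sam_area_per_molecule=22.0, sam_coverage=0.95,
                  substrate=None, sam_only=False) -> FFBStructure:
    """Convenience factory for a complete floating-bilayer structure."""
    sub = dict(SUBSTRATE_DEFAULTS)
    if substrate:
        sub.update(substrate)
    sio2 = SubstrateLayer("SiO2", sub["sio2_thickness"], SUBSTRATE_SLD["SiO2"],
                          sub["sio2_roughness"])
    py = SubstrateLayer("permalloy", sub["permalloy_thickness"],
                        SUBSTRATE_SLD["permalloy"], sub["permalloy_roughness"])
    au = SubstrateLayer("gold", sub["gold_thickness"], SUBSTRATE_SLD["gold"],
                        sub["gold_roughness"])
    sam = sam_layer(sam_area_per_molecule, sam_coverage)
    if sam_only:
        inner = tails = outer = None
    else:
        inner, tails, outer = bilayer_leaflets(
            composition, area_per_molecule=area_per_molecule,
            coverage=coverage, bound_waters=bound_waters)
    label = composition if isinstance(composition, str) else ""
    return FFBStructure(
        condition=condition, sio2=sio2, permalloy=py, gold=au, sam=sam,
        interlayer_thickness=distance, inner_heads=inner, tails=tails,
        outer_heads=outer, bilayer_roughness=bilayer_roughness,
        composition=label,
    )


def build_stack(structure: FFBStructure, contrast) -> list:
    """Render a structure into the ordered slab stack for one contrast.

    Changing the contrast relabels SLDs only; geometry (thicknesses and
    roughnesses) is contrast-independent.
    """
    if isinstance(contrast, str):
        contrast = IsotopicContrast.from_name(contrast)
    rho_solv = contrast.solvent_sld
    stack = [
        Slab(0.0, SUBSTRATE_SLD["Si"]),
        structure.sio2.slab(),
        structure.permalloy.slab(),
        structure.gold.slab(),
        Slab(layer_thickness(structure.sam), layer_sld(structure.sam, contrast),
             value_of(structure.sam_roughness)),
    ]
    if structure.has_bilayer:
        br = value_of(structure.bilayer_roughness)
        stack += [
            Slab(value_of(structure.interlayer_thickness), rho_solv,
                 value_of(structure.sam_water_roughness)),
            Slab(layer_thickness(structure.inner_heads),
                 layer_sld(structure.inner_heads, contrast), br),
            Slab(layer_thickness(structure.tails),
                 layer_sld(structure.tails, contrast), br),
            Slab(layer_thickness(structure.outer_heads),
                 layer_sld(structure.outer_heads, contrast), br),
            Slab(0.0, rho_solv, br),
        ]
    else:
        stack.append(Slab(0.0, rho_solv, value_of(structure.sam_water_roughness)))
    return stack


def bilayer_to_sam_distance(structure: FFBStructure) -> float:
    """The bilayer-to-SAM distance: thickness of the water interlayer
    between the SAM/water interface and the proximal head-group layer."""
    return value_of(structure.interlayer_thickness)


def structure_sld_profile(structure: FFBStructure, contrast,
                          dz: float = 0.5) -> SldProfile:
    """Continuous SLD profile with z = 0 at the gold/SAM interface."""
    stack = build_stack(structure, contrast)
    prof = sld_profile(stack, dz=dz)
    z_gold_sam = (value_of(structure.sio2.thickness)
                  + value_of(structure.permalloy.thickness)
                  + value_of(structure.gold.thickness))
    return SldProfile(z=prof.z - z_gold_sam, rho=prof.rho)


def model_reflectivity(structure: FFBStructure, contrast, grid: QGrid,
                       *, slab_width: float = 0.5, adaptive: bool = True,
                       quality: float = 12.0, n_quad: int = 17) -> np.ndarray:
    """Resolution-smeared model reflectivity for one structure and contrast.

    The roughened profile is micro-sliced into sharp slabs before the
    matrix calculation.  With ``adaptive=True`` (default) slab widths
    scale with the local interface roughness (floor ``slab_width``), which
    keeps 100 A-scale conformal roughness affordable; ``adaptive=False``
    slices uniformly at ``slab_width``.
    """
    stack = build_stack(structure, contrast)
    if adaptive:
        sliced = adaptive_microslice(stack, quality=quality, floor=slab_width)
    else:
        sliced = microslice(stack, slab_width)
    return resolution_smeared_reflectivity(sliced, grid, n_quad=n_quad,
                                           staircase_compensation=True)
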