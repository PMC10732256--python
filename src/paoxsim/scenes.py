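"""Synthetic voxelized tissue scenes.

Builds the four study geometries — the layer-only skin model, the
varying-oxygenation vessel model, the realistic forearm model (artery +
vein) and the cylindrical phantom digital twin — plus randomized training
volumes for the learned spectral-decoloring regressor.

Conventions
-----------
The tissue surface is the z = 0 plane with z increasing into the tissue
(depth). The imaging plane is the x-z plane; embedded cylinders run along y,
perpendicular to the imaging plane. Vessel depth is measured from the
epidermis surface to the vessel *center*. Scenes are piecewise homogeneous:
a voxel label indexes into per-region optical-property tables, which keeps
multispectral volumes compact without loss (every region is a uniform
mixture).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    REGION_SCATTERING,
    ScatteringSpec,
    TissueComposition,
    WavelengthGrid,
    load_chromophore,
    tissue_optical_properties,
)

__all__ = [
    "LayerSpec",
    "CylinderInclusion",
    "SceneSpec",
    "VoxelScene",
    "melanosome_series",
    "build_layer_model",
    "build_vessel_model",
    "build_realistic_model",
    "build_phantom_twin",
    "voxelize",
    "sample_training_volume",
]

EPIDERMIS_THICKNESS_MM = 0.06
DERMIS_THICKNESS_MM = 1.0

DERMIS = TissueComposition(
    blood_frac=0.002, blood_so2=0.7, water_frac=0.65, lipid_frac=0.2,
    scattering=REGION_SCATTERING["dermis"],
)
BACKGROUND = TissueComposition(
    blood_frac=0.025, blood_so2=0.7, water_frac=0.65, lipid_frac=0.2,
    scattering=REGION_SCATTERING["background"],
)


def _epidermis(f_mel: float) -> TissueComposition:
    return TissueComposition(
        melanosome_frac=f_mel, scattering=REGION_SCATTERING["epidermis"]
    )


def _whole_blood(so2: float) -> TissueComposition:
    return TissueComposition(
        blood_frac=1.0, blood_so2=so2, scattering=REGION_SCATTERING["blood"]
    )


@dataclass(frozen=True)
class LayerSpec:
    """Horizontal slab; thickness_mm None marks the semi-infinite last layer."""

    name: str
    thickness_mm: float | None
    composition: TissueComposition

    def __post_init__(self):
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class CylinderInclusion:
    """Cylinder along y; depth is surface to cylinder center."""

    name: str
    radius_mm: float
    depth_mm: float
    composition: TissueComposition
    truth_so2: float | None = None
    center_x_mm: float = 0.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("cylinder radius must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Layered scene with optional cylindrical inclusions."""

    layers: tuple[LayerSpec, ...]
    inclusions: tuple[CylinderInclusion, ...] = ()
    extent_mm: tuple[float, float, float] = (13.2, 13.2, 8.04)
    kind: str = "layer"
    nested: bool = False    # concentric inclusions (phantom twin) skip overlap checks

    def __post_init__(self):
        if self.nested:
            return
        lz = self.extent_mm[2]
        for inc in self.inclusions:
            if inc.depth_mm - inc.radius_mm < 0 or inc.depth_mm + inc.radius_mm > lz:
                raise ValueError(f"inclusion {inc.name!r} not fully inside the volume")
        for a in self.inclusions:
            for b in self.inclusions:
                if a.name < b.name:
                    gap = np.hypot(a.center_x_mm - b.center_x_mm,
                                   a.depth_mm - b.depth_mm)
                    if gap < a.radius_mm + b.radius_mm:
                        raise ValueError(
                            f"inclusions {a.name!r} and {b.name!r} overlap"
                        )


def melanosome_series() -> np.ndarray:
    """Six log-spaced melanosome volume fractions from 2% to 40% v/v."""
    return 0.02 * (0.40 / 0.02) ** (np.arange(6) / 5.0)


def build_layer_model(f_mel: float,
                      extent_mm: tuple[float, float, float] = (13.2, 13.2, 8.04)
                      ) -> SceneSpec:
    """Three-layer skin: 60 um epidermis, 1 mm dermis, semi-infinite tissue."""
    if not 0.0 < f_mel <= 1.0:
        raise ValueError("melanosome fraction must lie in (0, 1]")
    return SceneSpec(
        layers=(
            LayerSpec("epidermis", EPIDERMIS_THICKNESS_MM, _epidermis(f_mel)),
            LayerSpec("dermis", DERMIS_THICKNESS_MM, DERMIS),
            LayerSpec("background", None, BACKGROUND),
        ),
        extent_mm=extent_mm,
        kind="layer",
    )


def build_vessel_model(f_mel: float, vessel_so2: float,
                       extent_mm: tuple[float, float, float] = (13.2, 13.2, 8.04)
                       ) -> SceneSpec:
    """Layer model plus a whole-blood cylinder (r = 1.25 mm, 2.5 mm deep)."""
    if not 0.0 <= vessel_so2 <= 1.0:
        raise ValueError("vessel_so2 must lie in [0, 1]")
    base = build_layer_model(f_mel, extent_mm)
    vessel = CylinderInclusion(
        "vessel", radius_mm=1.25, depth_mm=2.5,
        composition=_whole_blood(vessel_so2), truth_so2=vessel_so2,
    )
    return SceneSpec(layers=base.layers, inclusions=(vessel,),
                     extent_mm=extent_mm, kind="vessel")


def build_realistic_model(f_mel: float,
                          extent_mm: tuple[float, float, float] = (13.2, 13.2, 8.04)
                          ) -> SceneSpec:
    """Layer model with an artery (r=1.25, sO2=1.0) and a vein (r=0.625, 0.7)."""
    base = build_layer_model(f_mel, extent_mm)
    artery = CylinderInclusion(
        "artery", radius_mm=1.25, depth_mm=2.5,
        composition=_whole_blood(1.0), truth_so2=1.0, center_x_mm=-2.5,
    )
    vein = CylinderInclusion(
        "vein", radius_mm=0.625, depth_mm=2.5,
        composition=_whole_blood(0.7), truth_so2=0.7, center_x_mm=2.5,
    )
    return SceneSpec(layers=base.layers, inclusions=(artery, vein),
                     extent_mm=extent_mm, kind="realistic")


WATER_INTRALIPID = TissueComposition(
    water_frac=1.0, scattering=REGION_SCATTERING["intralipid"]
)


def build_phantom_twin(mu_a_melanin_700: float,
                       blood_so2: float = 1.0) -> SceneSpec:
    """Digital twin of the two-layer cylindrical phantom.

    Concentric cylinders along y inside a 22 mm cube: a central whole-blood
    tube (r = 0.75 mm), an inner water/intralipid body (23 mm diameter,
    truncated by the volume), and a 1 mm melanin-loaded outer shell whose
    melanosome fraction is chosen so mu_a(700 nm) matches the requested value.
    """
    if mu_a_melanin_700 < 0:
        raise ValueError("mu_a_melanin_700 must be non-negative")
    mel = load_chromophore("melanosome")([700.0])[0]
    f_mel = mu_a_melanin_700 / mel
    shell = TissueComposition(
        melanosome_frac=f_mel, water_frac=1.0 - f_mel,
        scattering=REGION_SCATTERING["intralipid"],
    )
    extent = (22.0, 22.0, 22.0)
    center = 11.0
    water_bath = TissueComposition(
        water_frac=1.0,
        scattering=ScatteringSpec(a500=0.25, f_rayleigh=0.0, b_mie=1.0, g=0.9),
    )
    layers = (LayerSpec("water_bath", None, water_bath),)
    tube = CylinderInclusion("blood_tube", radius_mm=0.75, depth_mm=center,
                             composition=_whole_blood(blood_so2),
                             truth_so2=blood_so2)
    inner = CylinderInclusion("phantom_body", radius_mm=11.5, depth_mm=center,
                              composition=WATER_INTRALIPID)
    outer = CylinderInclusion("melanin_shell", radius_mm=12.5, depth_mm=center,
                              composition=shell)
    # voxelization order: outer first so the nested regions overwrite it
    return SceneSpec(layers=layers, inclusions=(outer, inner, tube),
                     extent_mm=extent, kind="phantom", nested=True)


@dataclass
class VoxelScene:
    """Voxel label map plus per-region, per-wavelength optical properties.

    Scenes are piecewise homogeneous, so per-voxel properties are stored as
    a (region x wavelength) table indexed by `labels`; `mu_a_map` expands a
    single wavelength to a full volume when needed.
    """

    spacing_mm: float
    labels: np.ndarray                # (nx, ny, nz) uint8
    region_names: list[str]
    region_mu_a: np.ndarray           # (n_regions, n_wavelengths) cm^-1
    region_mu_s: np.ndarray           # (n_regions, n_wavelengths) cm^-1
    region_g: np.ndarray              # (n_regions,)
    region_so2: np.ndarray            # (n_regions,), nan where no blood
    region_blood_frac: np.ndarray     # (n_regions,)
    wavelengths: WavelengthGrid
    surface_at_z0: bool = True
    seed: int | None = None
    spec_json: str = ""

    @property
    def shape(self):
        return self.labels.shape

    def mu_a_map(self, wavelength_index: int) -> np.ndarray:
        return self.region_mu_a[:, wavelength_index][self.labels]

    def mu_s_map(self, wavelength_index: int) -> np.ndarray:
        return self.region_mu_s[:, wavelength_index][self.labels]

    @property
    def truth_so2_map(self) -> np.ndarray:
        return self.region_so2[self.labels]

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.region_names.index(name)

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("labels", data=self.labels, compression="gzip")
            fh["region_mu_a"] = self.region_mu_a
            fh["region_mu_s"] = self.region_mu_s
            fh["region_g"] = self.region_g
            fh["region_so2"] = self.region_so2
            fh["region_blood_frac"] = self.region_blood_frac
            fh["wavelengths"] = self.wavelengths.values
            fh.attrs["spacing_mm"] = self.spacing_mm
            fh.attrs["region_names"] = json.dumps(self.region_names)
            fh.attrs["surface_at_z0"] = self.surface_at_z0
            fh.attrs["seed"] = -1 if self.seed is None else self.seed
            fh.attrs["spec_json"] = self.spec_json

    @classmethod
    def from_hdf5(cls, path) -> "VoxelScene":
        import h5py

        with h5py.File(path, "r") as fh:
            seed = int(fh.attrs["seed"])
            return cls(
                spacing_mm=float(fh.attrs["spacing_mm"]),
                labels=fh["labels"][...],
                region_names=json.loads(fh.attrs["region_names"]),
                region_mu_a=fh["region_mu_a"][...],
                region_mu_s=fh["region_mu_s"][...],
                region_g=fh["region_g"][...],
                region_so2=fh["region_so2"][...],
                region_blood_frac=fh["region_blood_frac"][...],
                wavelengths=WavelengthGrid(fh["wavelengths"][...]),
                surface_at_z0=bool(fh.attrs["surface_at_z0"]),
                seed=None if seed < 0 else seed,
                spec_json=str(fh.attrs["spec_json"]),
            )


def _region_tables(compositions, grid):
    mu_a, mu_s, g, so2, blood = [], [], [], [], []
    for comp in compositions:
        props = tissue_optical_properties(comp, grid)
        mu_a.append(props.mu_a)
        mu_s.append(props.mu_s)
        g.append(props.g)
        so2.append(comp.blood_so2 if comp.blood_frac > 0 else np.nan)
        blood.append(comp.blood_frac)
    return (np.asarray(mu_a), np.asarray(mu_s), np.asarray(g),
            np.asarray(so2), np.asarray(blood))


def voxelize(spec: SceneSpec, spacing_mm: float, grid: WavelengthGrid) -> VoxelScene:
    """Rasterize a SceneSpec by voxel-center membership."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    shape = []
    for ext in spec.extent_mm:
        n = ext / spacing_mm
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"extent {ext} mm is not an integer number of {spacing_mm} mm voxels"
            )
        shape.append(int(round(n)))
    nx, ny, nz = shape

    # voxel-center coordinates; x and y centered on 0, z is depth from surface
    x = (np.arange(nx) + 0.5) * spacing_mm - spec.extent_mm[0] / 2.0
    z = (np.arange(nz) + 0.5) * spacing_mm

    names, comps = [], []
    labels_z = np.empty(nz, dtype=np.uint8)
    z0 = 0.0
    for layer in spec.layers:
        z1 = z0 + layer.thickness_mm if layer.thickness_mm is not None else spec.extent_mm[2]
        sel = (z >= z0) & (z < z1)
        labels_z[sel] = len(names)
        names.append(layer.name)
        comps.append(layer.composition)
        z0 = z1
    labels_z[z >= z0] = len(names) - 1     # semi-infinite tail

    labels = np.broadcast_to(labels_z[None, None, :], (nx, ny, nz)).copy()

    xx, zz = np.meshgrid(x, z, indexing="ij")
    for inc in spec.inclusions:
        inside = (xx - inc.center_x_mm) ** 2 + (zz - inc.depth_mm) ** 2 <= inc.radius_mm**2
        idx = len(names)
        names.append(inc.name)
        comps.append(inc.composition)
        labels[np.broadcast_to(inside[:, None, :], labels.shape)] = idx

    mu_a, mu_s, g, so2, blood = _region_tables(comps, grid)
    # truth sO2 of explicit inclusions may override the composition value
    for inc in spec.inclusions:
        if inc.truth_so2 is not None:
            so2[names.index(inc.name)] = inc.truth_so2

    return VoxelScene(
        spacing_mm=spacing_mm, labels=labels, region_names=names,
        region_mu_a=mu_a, region_mu_s=mu_s, region_g=g, region_so2=so2,
        region_blood_frac=blood, wavelengths=grid,
        surface_at_z0=(spec.kind != "phantom"),
        spec_json=json.dumps({"kind": spec.kind, "extent_mm": spec.extent_mm}),
    )


TRAINING_CUBE_MM = 19.2
TRAINING_SPACING_MM = 0.3


def sample_training_volume(seed: int, grid: WavelengthGrid | None = None) -> VoxelScene:
    """One randomized training volume for learned spectral decoloring.

    A 19.2 mm cube at 0.3 mm spacing (64^3): an epidermis surface layer with
    melanosome fraction ~ U[0.1%, 5%], a 1% v/v blood background at 70% sO2,
    and 0-9 whole-blood cylinders with radius ~ U[0.3, 3] mm (clipped to fit)
    and sO2 ~ U[0, 1]. All randomness derives from `seed`.
    """
    from .spectra import nir_grid

    if grid is None:
        grid = nir_grid()
    rng = np.random.default_rng(seed)
    f_mel = rng.uniform(0.001, 0.05)
    n_vessels = int(rng.integers(0, 10))

    n = int(round(TRAINING_CUBE_MM / TRAINING_SPACING_MM))
    labels = np.ones((n, n, n), dtype=np.uint8)
    labels[:, :, 0] = 0                       # epidermis surface voxel layer

    names = ["epidermis", "background"]
    comps = [
        _epidermis(f_mel),
        TissueComposition(blood_frac=0.01, blood_so2=0.7, water_frac=0.65,
                          lipid_frac=0.2,
                          scattering=REGION_SCATTERING["background"]),
    ]

    x = (np.arange(n) + 0.5) * TRAINING_SPACING_MM - TRAINING_CUBE_MM / 2.0
    z = (np.arange(n) + 0.5) * TRAINING_SPACING_MM
    xx, zz = np.meshgrid(x, z, indexing="ij")
    for k in range(n_vessels):
        radius = rng.uniform(0.3, 3.0)
        so2 = rng.uniform(0.0, 1.0)
        depth = rng.uniform(TRAINING_SPACING_MM + radius, TRAINING_CUBE_MM - radius)
        cx = rng.uniform(-TRAINING_CUBE_MM / 2 + radius, TRAINING_CUBE_MM / 2 - radius)
        inside = (xx - cx) ** 2 + (zz - depth) ** 2 <= radius**2
        labels[np.broadcast_to(inside[:, None, :], labels.shape)] = len(names)
        names.append(f"vessel_{k}")
        comps.append(_whole_blood(so2))

    mu_a, mu_s, g, so2_arr, blood = _region_tables(comps, grid)
    return VoxelScene(
        spacing_mm=TRAINING_SPACING_MM, labels=labels, region_names=names,
        region_mu_a=mu_a, region_mu_s=mu_s, region_g=g, region_so2=so2_arr,
        region_blood_frac=blood, wavelengths=grid, seed=seed,
        spec_json=json.dumps({"kind": "training", "f_mel": f_mel,
                              "n_vessels": n_vessels}),
    )
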