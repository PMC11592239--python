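"""Parametric synthetic vertebral specimens and voxel volumes.

Real donor scans for this analysis are not deposited, so the pipeline runs
on parametric stand-ins: each vertebral body is an elliptical cylinder
with a cosine waist (no posterior elements — the load path of the model
only involves the body), wrapped in a thin cortical shell and filled with
cancellous bone whose CT attenuation is drawn from a seeded Gaussian.

The reference specimen, :func:`default_donor_spine`, encodes the study
conditions of the analysed case: 22 vertebrae C3–L5 from an 83-year-old
donor (104.5 kg, 1.61 m, BMI 40.3) with osteoporosis and a DISH-type
endosclerosis of Th5–Th8.  Cortical shell thickness and cancellous HU are
set per spinal section to the measured medians (cervical/thoracic/lumbar
Cr.Th 156/188/149 µm; HU 222/117/47.8), with the DISH levels elevated
above the thoracic baseline.  Per-level geometric dimensions are generic
free parameters (the source case does not report them) chosen from adult
anthropometry and growing craniocaudally.

Voxel convention: 0-based voxel-centred indices; the world position of
voxel (i, j, k) is ``origin + index * spacing`` (mm).  Local vertebra
coordinates: x anterior (ventral), y left (mediolateral), z cranial, body
centre at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .meshing import structured_solid, surface_from_femesh, waist_scale

__all__ = [
    "LEVELS",
    "MICRO_CT_LEVELS",
    "SECTION_OF",
    "VertebraSpec",
    "SpineSpec",
    "ImageVolume",
    "default_donor_spine",
    "vertebra_surface",
    "rasterize",
    "mid_sagittal_volume",
    "spine_to_yaml",
    "spine_from_yaml",
]

LEVELS: tuple[str, ...] = (
    "C3", "C4", "C5", "C6", "C7",
    "Th1", "Th2", "Th3", "Th4", "Th5", "Th6", "Th7", "Th8", "Th9", "Th10", "Th11", "Th12",
    "L1", "L2", "L3", "L4", "L5",
)

#: levels imaged at 25 µm in the source protocol (15 of the 22 bodies)
MICRO_CT_LEVELS: tuple[str, ...] = (
    "C3", "C4", "C5", "C6", "C7",
    "Th8", "Th9", "Th10", "Th11", "Th12",
    "L1", "L2", "L3", "L4", "L5",
)

#: DISH-affected levels with endosclerotic HU elevation
DISH_LEVELS: tuple[str, ...] = ("Th5", "Th6", "Th7", "Th8")


def SECTION_OF(label: str) -> str:
    """Spinal section code of a level label: CS, TS or LS."""
    if label.startswith("C"):
        return "CS"
    if label.startswith("Th"):
        return "TS"
    if label.startswith("L"):
        return "LS"
    raise ValueError(f"unknown level label {label!r}")


# section-wise measurement medians used as generator defaults
SECTION_CORTICAL_THICKNESS_UM = {"CS": 156.0, "TS": 188.0, "LS": 149.0}
SECTION_CANCELLOUS_HU = {"CS": 222.0, "TS": 117.0, "LS": 47.8}
#: endosclerotic elevation of the DISH levels above the thoracic baseline, HU
DISH_HU_ELEVATION = 85.0

#: synthetic cortical / background attenuation (inside the stated micro-CT
#: contrast window); these drive masks only, never the material chain
CORTICAL_HU = 1500.0
BACKGROUND_HU = -800.0
DEFAULT_CANCELLOUS_SD = 25.0
DEFAULT_WAIST = 0.88

# craniocaudal geometric ramps (free parameters, mm): linear from C3 to L5
_AP_RANGE = (6.5, 10.5)   # anterior-posterior semi-axis
_ML_RANGE = (8.0, 15.0)   # mediolateral semi-axis
_HEIGHT_RANGE = (14.0, 27.0)


@dataclass
class VertebraSpec:
    """Ground-truth description of one vertebral body.

    Units: mm for geometry, µm for ``cortical_thickness`` (the shell
    thickness Cr.Th of the FE model), HU for attenuation.
    """

    label: str
    section: str
    body_height: float
    endplate_semi_axes: tuple[float, float]  # (anterior-posterior, mediolateral) mm
    waist_factor: float
    cortical_thickness: float  # µm
    cancellous_hu_mean: float
    cancellous_hu_sd: float
    dish_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in LEVELS:
            raise ValueError(f"unknown vertebral level {self.label!r}")
        if self.section != SECTION_OF(self.label):
            raise ValueError("section does not match label")
        if not (50.0 <= self.cortical_thickness <= 500.0):
            raise ValueError("cortical_thickness must lie in [50, 500] µm")
        if self.body_height <= 0:
            raise ValueError("body_height must be positive")
        if not (0 < self.waist_factor <= 1):
            raise ValueError("waist_factor must lie in (0, 1]")
        if self.cancellous_hu_sd < 0:
            raise ValueError("cancellous_hu_sd must be non-negative")
        if min(self.endplate_semi_axes) <= 0:
            raise ValueError("degenerate endplate semi-axes")

    # -- analytic geometry helpers -----------------------------------------

    def radial_scale(self, z: np.ndarray) -> np.ndarray:
        return waist_scale(np.asarray(z, dtype=float), self.body_height, self.waist_factor)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-test for world points (local coordinates, mm)."""
        p = np.atleast_2d(points)
        ap, ml = self.endplate_semi_axes
        h2 = self.body_height / 2.0
        s = self.radial_scale(p[:, 2])
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (p[:, 0] / (ap * s)) ** 2 + (p[:, 1] / (ml * s)) ** 2
        return (np.abs(p[:, 2]) <= h2) & (r2 <= 1.0)


@dataclass
class SpineSpec:
    """Ordered cranial-to-caudal collection of vertebral bodies plus the
    donor anthropometry driving the load model."""

    vertebrae: list[VertebraSpec]
    body_mass: float  # kg
    body_height_m: float  # m
    noise_seed: int = 0

    def __post_init__(self) -> None:
        labels = [v.label for v in self.vertebrae]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate vertebra labels")
        order = [LEVELS.index(l) for l in labels]
        if order != sorted(order):
            raise ValueError("vertebrae must be ordered cranial to caudal")
        if self.body_mass <= 0 or self.body_height_m <= 0:
            raise ValueError("body mass and height must be positive")

    def __getitem__(self, label: str) -> VertebraSpec:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    def index_of(self, label: str) -> int:
        return [v.label for v in self.vertebrae].index(label)

    def rng_for(self, label: str, stream: int = 0) -> np.random.Generator:
        """Independent noise substream for one vertebra.

        Streams are keyed by (spine seed, position in the list, stream)
        so a vertebra's voxel noise does not depend on how the list is
        sliced downstream, and different acquisitions (clinical CT,
        micro-CT) of the same body draw independent noise.
        """
        return np.random.default_rng(
            [int(self.noise_seed), self.index_of(label), int(stream)]
        )


@dataclass
class ImageVolume:
    """Axis-aligned voxel grid with HU values.

    ``labels`` (optional) classifies voxels: 0 exterior, 1 cancellous,
    2 cortical.  ``meta`` carries the vertebra label and any rasterizer
    warnings (e.g. a shell band thinner than a quarter voxel).
    """

    values: np.ndarray  # (nx, ny, nz) float32 HU
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, centre of voxel (0, 0, 0)
    modality_tag: str  # "CT" | "microCT"
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.values.size == 0:
            raise ValueError("empty voxel grid")

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
            for d in range(3)
        )

    def index_of_world(self, point) -> tuple[int, int, int]:
        idx = np.round((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(int(i) for i in idx)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


def _geometry_for_index(i: int, n: int = 22) -> tuple[float, float, float]:
    t = i / (n - 1)
    ap = _AP_RANGE[0] + t * (_AP_RANGE[1] - _AP_RANGE[0])
    ml = _ML_RANGE[0] + t * (_ML_RANGE[1] - _ML_RANGE[0])
    h = _HEIGHT_RANGE[0] + t * (_HEIGHT_RANGE[1] - _HEIGHT_RANGE[0])
    return ap, ml, h


def default_donor_spine(noise_seed: int = 0) -> SpineSpec:
    """The reference synthetic spine mirroring the analysed donor case.

    22 vertebrae C3–L5; section-median cortical thickness and cancellous
    HU; Th5–Th8 flagged as DISH with attenuation elevated above the
    thoracic baseline; donor mass 104.5 kg and height 1.61 m.
    """
    vertebrae = []
    for i, label in enumerate(LEVELS):
        section = SECTION_OF(label)
        ap, ml, h = _geometry_for_index(i)
        dish = label in DISH_LEVELS
        hu = SECTION_CANCELLOUS_HU[section] + (DISH_HU_ELEVATION if dish else 0.0)
        vertebrae.append(
            VertebraSpec(
                label=label,
                section=section,
                body_height=h,
                endplate_semi_axes=(ap, ml),
                waist_factor=DEFAULT_WAIST,
                cortical_thickness=SECTION_CORTICAL_THICKNESS_UM[section],
                cancellous_hu_mean=hu,
                cancellous_hu_sd=DEFAULT_CANCELLOUS_SD,
                dish_flag=dish,
            )
        )
    return SpineSpec(
        vertebrae=vertebrae, body_mass=104.5, body_height_m=1.61, noise_seed=noise_seed
    )


def vertebra_surface(spec: VertebraSpec, edge_target: float = 2.0):
    """Closed, watertight, outward-oriented triangulated surface of the
    parametric body (genus 0), carrying its structured solid in metadata."""
    ap, ml = spec.endplate_semi_axes
    solid = structured_solid(ap, ml, spec.body_height, spec.waist_factor, edge_target)
    return surface_from_femesh(
        solid,
        parametric=dict(
            semi_axis_ap=ap,
            semi_axis_ml=ml,
            height=spec.body_height,
            waist_factor=spec.waist_factor,
            edge_target=edge_target,
        ),
    )


# ---------------------------------------------------------------------------
# Rasterization


def _rasterize_vertebra(
    spec: VertebraSpec,
    spacing: np.ndarray,
    modality_tag: str,
    rng: np.random.Generator,
    bounds: np.ndarray | None,
    cortical_hu: float,
    background_hu: float,
) -> ImageVolume:
    ap, ml = spec.endplate_semi_axes
    h2 = spec.body_height / 2.0
    if bounds is None:
        margin = np.maximum(2.0 * spacing, 1.0)
        bounds = np.array(
            [
                [-ap - margin[0], ap + margin[0]],
                [-ml - margin[1], ml + margin[1]],
                [-h2 - margin[2], h2 + margin[2]],
            ]
        )
    else:
        bounds = np.asarray(bounds, dtype=float)
    shape = np.maximum(
        1, np.ceil((bounds[:, 1] - bounds[:, 0]) / spacing).astype(int)
    )
    origin = bounds[:, 0] + spacing / 2.0
    ax = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]
    s = spec.radial_scale(ax[2])[None, None, :]
    inside = (
        (np.abs(Z) <= h2)
        & ((X / (ap * s)) ** 2 + (Y / (ml * s)) ** 2 <= 1.0)
    )
    t_c_mm = spec.cortical_thickness / 1000.0
    meta: dict = {"vertebra": spec.label, "warnings": []}
    if t_c_mm < 0.25 * float(np.max(spacing)):
        meta["warnings"].append(
            f"shell band ({spec.cortical_thickness:.0f} µm) thinner than a "
            f"quarter voxel at {np.max(spacing):.3g} mm spacing"
        )
    # distance of each interior voxel centre to the nearest exterior voxel
    # centre; the half-voxel offset converts it to distance-to-surface
    dist = ndimage.distance_transform_edt(inside, sampling=spacing)
    band = inside & (dist <= t_c_mm + 0.5 * float(np.min(spacing)))
    labels = np.zeros(shape, dtype=np.uint8)
    labels[inside] = 1
    labels[band] = 2
    values = np.full(shape, background_hu, dtype=np.float32)
    cancellous = labels == 1
    n_canc = int(cancellous.sum())
    if spec.cancellous_hu_sd > 0:
        draws = rng.normal(spec.cancellous_hu_mean, spec.cancellous_hu_sd, size=n_canc)
    else:
        draws = np.full(n_canc, spec.cancellous_hu_mean)
    values[cancellous] = draws
    values[band] = cortical_hu
    return ImageVolume(
        values=values,
        spacing=spacing,
        origin=origin,
        modality_tag=modality_tag,
        labels=labels,
        meta=meta,
    )


def rasterize(
    spec: VertebraSpec | SpineSpec,
    spacing: float | tuple[float, float, float],
    modality_tag: str = "CT",
    seed: int = 0,
    rng: np.random.Generator | None = None,
    bounds=None,
    cortical_hu: float = CORTICAL_HU,
    background_hu: float = BACKGROUND_HU,
    disc_gap: float = 4.0,
) -> ImageVolume:
    """Voxelize a vertebra (or a whole spine stacked along z) into HU.

    Voxels whose centres fall in the cortical shell band get
    ``cortical_hu``; interior voxels get seeded Gaussian draws around the
    vertebra's cancellous mean; exterior voxels get ``background_hu``.
    Deterministic given the seed.  For a ``SpineSpec`` the per-vertebra
    noise substream is keyed by list position, and ``seed`` is ignored in
    favour of ``spec.noise_seed``.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if isinstance(spec, VertebraSpec):
        if rng is None:
            rng = np.random.default_rng([int(seed), 0])
        return _rasterize_vertebra(
            spec, spacing, modality_tag, rng, bounds, cortical_hu, background_hu
        )
    # whole spine: stack cranial (high z) to caudal (low z)
    total_h = sum(v.body_height for v in spec.vertebrae) + disc_gap * (
        len(spec.vertebrae) - 1
    )
    ztop = total_h / 2.0
    centres = []
    for v in spec.vertebrae:
        centres.append(ztop - v.body_height / 2.0)
        ztop -= v.body_height + disc_gap
    max_ap = max(v.endplate_semi_axes[0] for v in spec.vertebrae)
    max_ml = max(v.endplate_semi_axes[1] for v in spec.vertebrae)
    margin = np.maximum(2.0 * spacing, 1.0)
    if bounds is None:
        bounds = np.array(
            [
                [-max_ap - margin[0], max_ap + margin[0]],
                [-max_ml - margin[1], max_ml + margin[1]],
                [-total_h / 2.0 - margin[2], total_h / 2.0 + margin[2]],
            ]
        )
    bounds = np.asarray(bounds, dtype=float)
    shape = np.maximum(1, np.ceil((bounds[:, 1] - bounds[:, 0]) / spacing).astype(int))
    origin = bounds[:, 0] + spacing / 2.0
    values = np.full(shape, background_hu, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    meta: dict = {"vertebra": "spine", "warnings": [], "centres_z": dict()}
    for v, zc in zip(spec.vertebrae, centres):
        local_bounds = np.array(
            [
                bounds[0],
                bounds[1],
                [zc - v.body_height / 2.0 - spacing[2], zc + v.body_height / 2.0 + spacing[2]],
            ]
        )
        # snap the local slab onto the global grid
        k0 = int(np.floor((local_bounds[2, 0] - bounds[2, 0]) / spacing[2]))
        k0 = max(k0, 0)
        k1 = int(np.ceil((local_bounds[2, 1] - bounds[2, 0]) / spacing[2]))
        k1 = min(k1, shape[2])
        slab_bounds = np.array(
            [
                bounds[0],
                bounds[1],
                [bounds[2, 0] + k0 * spacing[2] - zc, bounds[2, 0] + k1 * spacing[2] - zc],
            ]
        )
        sub = _rasterize_vertebra(
            v, spacing, modality_tag, spec.rng_for(v.label), slab_bounds,
            cortical_hu, background_hu,
        )
        sel = sub.labels > 0
        values[:, :, k0:k1][sel] = sub.values[sel]
        labels[:, :, k0:k1][sel] = sub.labels[sel]
        meta["warnings"].extend(sub.meta["warnings"])
        meta["centres_z"][v.label] = zc
    return ImageVolume(
        values=values, spacing=spacing, origin=origin, modality_tag=modality_tag,
        labels=labels, meta=meta,
    )


def mid_sagittal_volume(
    spec: VertebraSpec,
    spacing: float = 0.025,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ImageVolume:
    """One-voxel-thick mid-sagittal micro-CT slab of a single vertebra.

    The cortical-thickness protocol only reads the mid-sagittal section;
    a full 25 µm volume of a vertebral body would be ~1e9 voxels, so the
    micro-CT modality is rasterized as a slab through y = 0.
    """
    ap, _ = spec.endplate_semi_axes
    h2 = spec.body_height / 2.0
    margin = max(2 * spacing, 0.5)
    bounds = np.array(
        [
            [-ap - margin, ap + margin],
            [-spacing / 2.0, spacing / 2.0],
            [-h2 - margin, h2 + margin],
        ]
    )
    if rng is None:
        rng = np.random.default_rng([int(seed), 0])
    return _rasterize_vertebra(
        spec,
        np.array([spacing] * 3),
        "microCT",
        rng,
        bounds,
        CORTICAL_HU,
        BACKGROUND_HU,
    )


# ---------------------------------------------------------------------------
# Serialization (YAML; units documented in the emitted header)

_YAML_HEADER = (
    "# spinefea spine specification\n"
    "# units: body_height/endplate_semi_axes mm, cortical_thickness µm,\n"
    "#        cancellous HU, body_mass kg, body_height_m m\n"
)


def spine_to_yaml(spine: SpineSpec, path=None) -> str:
    doc = {
        "body_mass": spine.body_mass,
        "body_height_m": spine.body_height_m,
        "noise_seed": spine.noise_seed,
        "vertebrae": [
            {**asdict(v), "endplate_semi_axes": list(v.endplate_semi_axes)}
            for v in spine.vertebrae
        ],
    }
    text = _YAML_HEADER + yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spine_from_yaml(source) -> SpineSpec:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    vertebrae = [
        VertebraSpec(**{**v, "endplate_semi_axes": tuple(v["endplate_semi_axes"])})
        for v in doc["vertebrae"]
    ]
    return SpineSpec(
        vertebrae=vertebrae,
        body_mass=doc["body_mass"],
        body_height_m=doc["body_height_m"],
        noise_seed=doc.get("noise_seed", 0),
    )
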