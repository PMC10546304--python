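"""Synthetic seven-modality pancreatic-cyst phantoms.

Each phantom is a seven-modality series sharing one lesion geometry (the
*content*) rendered with modality-specific intensities (the *appearance*):

* **SCN** (serous): a cluster of several small cysts with 1-voxel walls and a
  lobulated union contour; a central fibrous scar is present with probability
  ``scar_prob`` (default 0.30, the frequency reported for serous lesions).
  Scar tissue is dark on T2 and enhances mildly on delayed phases.
* **MCN** (mucinous): one dominant cyst with a thick uneven wall (2–4 voxels),
  1–3 mural nodules and 1–2 fibrous septations; wall, nodules and septations
  enhance strongly on the delayed contrast phases.

Cyst fluid is bright on T2 and dark on T1; wall-type tissue intensity ramps
monotonically over the six T1 contrast phases T1pre -> T1post, with a steeper
class-dependent slope for MCN. Geometry is built from ellipsoids, thin
shells, planar slabs and small spheres so every structure has analytically
checkable ground truth (exposed as ``PhantomTruth.region_map``).

Volumes are generated at anisotropic voxel spacing drawn from the acquisition
ranges of 1.5T/3T abdominal protocols (T1 in-plane 0.78–1.04 mm, axial
2.50–2.59 mm; T2 in-plane 0.625–0.88 mm, axial 4.80–8.40 mm), so isotropic
resampling downstream is genuinely exercised. An optional rigid per-modality
translation emulates imperfect inter-series alignment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .constants import CONTRAST_PHASES, LABELS, MODALITIES
from .errors import ConfigurationError, ValidationError
from .volume_io import ModalityVolume, PatientSeries

# Region codes in PhantomTruth.region_map.
BACKGROUND, FLUID, WALL, SEPTATION, NODULE, SCAR = 0, 1, 2, 3, 4, 5

#: Mean background (pancreatic tissue) level, arbitrary units.
TISSUE_LEVEL = 100.0

#: Fluid appearance: dark on all T1 phases, bright on T2.
FLUID_INTENSITY = {m: 40.0 for m in CONTRAST_PHASES} | {"T2": 250.0}

#: Scar appearance: mildly enhancing fibrous tissue, dark on T2.
SCAR_INTENSITY = {
    "T1pre": 105.0, "T1a1": 109.0, "T1a2": 113.0,
    "T1v1": 117.0, "T1v2": 121.0, "T1post": 125.0, "T2": 50.0,
}

#: Default wall/nodule/septation intensity ramp per class and modality
#: (order = MODALITIES). The six T1 phases ramp monotonically; the MCN ramp
#: is steeper on the delayed phases, reflecting strong delayed enhancement.
DEFAULT_ENHANCEMENT = {
    "SCN": (110.0, 118.0, 126.0, 134.0, 142.0, 150.0, 120.0),
    "MCN": (110.0, 135.0, 160.0, 185.0, 210.0, 235.0, 130.0),
}

_T1_INPLANE_RANGE = (0.78, 1.04)
_T1_AXIAL_RANGE = (2.50, 2.59)
_T2_INPLANE_RANGE = (0.625, 0.88)
_T2_AXIAL_RANGE = (4.80, 8.40)


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; the defaults are the study conditions.

    ``spacing_mm=None`` draws one spacing for the six T1 phases and one for T2
    from the protocol ranges above; an explicit triple applies to all seven.
    ``enhancement_slopes`` maps class label to the per-modality wall intensity
    ramp. With ``neutral_geometry`` both classes share one simple geometry
    (single cyst, 2-voxel wall, no scar/nodules/septations) so that any class
    signal comes from the intensity ramps alone — used for controlled
    planted-signal experiments.
    """

    grid_dims: tuple[int, int, int] = (128, 128, 36)
    spacing_mm: Optional[tuple[float, float, float]] = None
    scar_prob: float = 0.30
    n_cysts_scn: tuple[int, int] = (2, 5)
    cyst_radius_scn_mm: tuple[float, float] = (4.0, 8.0)
    mcn_radius_mm: tuple[float, float] = (10.0, 14.0)
    wall_thickness_mcn_vox: tuple[int, int] = (2, 4)
    nodule_count_mcn: tuple[int, int] = (1, 3)
    septation_count_mcn: tuple[int, int] = (1, 2)
    enhancement_slopes: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ENHANCEMENT.items()}
    )
    bias_amplitude: float = 10.0
    noise_sd: float = 4.0
    misalignment_sd_vox: float = 0.0
    neutral_geometry: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.scar_prob <= 1.0):
            raise ConfigurationError(f"scar_prob must be in [0,1], got {self.scar_prob}")
        if self.noise_sd < 0 or self.misalignment_sd_vox < 0:
            raise ConfigurationError("noise_sd and misalignment_sd_vox must be >= 0")
        if len(self.grid_dims) != 3 or any(int(d) <= 0 for d in self.grid_dims):
            raise ConfigurationError(f"grid_dims must be 3 positive ints, got {self.grid_dims}")
        for name in ("n_cysts_scn", "wall_thickness_mcn_vox", "nodule_count_mcn",
                     "septation_count_mcn"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < (1 if name == "n_cysts_scn" else 0):
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_cysts_scn[0] < 2 and not self.neutral_geometry:
            raise ConfigurationError("SCN phantoms are multicystic: n_cysts_scn min must be >= 2")
        for lab in LABELS:
            ramp = self.enhancement_slopes.get(lab)
            if ramp is None or len(ramp) != len(MODALITIES):
                raise ConfigurationError(
                    f"enhancement_slopes must give {len(MODALITIES)} values for {lab!r}"
                )
        if self.spacing_mm is not None:
            if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
                raise ConfigurationError(f"spacing must be positive, got {self.spacing_mm}")
        # The grid must cover an 80 mm cube after 1 mm resampling, under the
        # smallest spacing the configuration can draw.
        min_spacing = (
            self.spacing_mm
            if self.spacing_mm is not None
            else (_T2_INPLANE_RANGE[0], _T2_INPLANE_RANGE[0], _T1_AXIAL_RANGE[0])
        )
        extent = [d * s for d, s in zip(self.grid_dims, min_spacing)]
        if any(e < 80.0 for e in extent):
            raise ConfigurationError(
                f"grid physical extent {extent} mm cannot contain an 80-voxel crop "
                "after 1 mm resampling; enlarge grid_dims"
            )


def phantom_window_spec():
    """Fixed intensity window covering the phantom's rendered range.

    Phantom intensities live in roughly [0, 300] on every modality; a fixed
    window (like the fixed per-modality windows used on real scanner output)
    preserves absolute intensity differences between classes, which
    per-volume percentile windows would partially normalize away.
    """
    from .preprocess import WindowSpec

    return WindowSpec(windows={m: (0.0, 300.0) for m in MODALITIES})


def planted_t1post_config(**overrides) -> PhantomConfig:
    """A controlled configuration whose only class signal lives in T1post.

    Geometry is class-neutral and the wall ramps of the two classes coincide
    on every modality except the delayed phase T1post, where MCN walls
    enhance far more strongly. Used to test that the pipeline attributes
    discriminative power to the correct modality.
    """
    slopes = {
        "SCN": (110.0, 110.0, 110.0, 110.0, 110.0, 130.0, 120.0),
        "MCN": (110.0, 110.0, 110.0, 110.0, 110.0, 190.0, 120.0),
    }
    kwargs = dict(neutral_geometry=True, enhancement_slopes=slopes)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@dataclass
class PhantomTruth:
    """Ground truth for one phantom; ``region_map`` holds the region codes."""

    label: str
    scar_present: bool
    n_cysts: int
    n_nodules: int
    lesion_center_vox: tuple[int, int, int]
    per_modality_shift_vox: np.ndarray  # (7, 3) applied rigid shifts
    region_map: np.ndarray  # uint8 grid of region codes

    def __post_init__(self) -> None:
        if self.n_cysts < 1:
            raise ValidationError("n_cysts must be >= 1")
        if any(
            not (0 <= c < d) for c, d in zip(self.lesion_center_vox, self.region_map.shape)
        ):
            raise ValidationError("lesion center outside grid")

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "scar_present": bool(self.scar_present),
            "n_cysts": int(self.n_cysts),
            "n_nodules": int(self.n_nodules),
            "lesion_center_vox": [int(c) for c in self.lesion_center_vox],
            "per_modality_shift_vox": self.per_modality_shift_vox.tolist(),
        }


def _ellipsoid_mask(grid, center, radii_vox):
    """Boolean mask of an axis-aligned ellipsoid given in voxel units."""
    gx, gy, gz = grid
    u = (
        ((gx - center[0]) / radii_vox[0]) ** 2
        + ((gy - center[1]) / radii_vox[1]) ** 2
        + ((gz - center[2]) / radii_vox[2]) ** 2
    )
    return u < 1.0


def _mm_to_vox(r_mm: float, spacing) -> np.ndarray:
    return np.array([r_mm / s for s in spacing])


def _build_geometry(label, config, rng, spacing_ref):
    """Return (region_map, scar_present, n_cysts, n_nodules, center)."""
    dims = tuple(int(d) for d in config.grid_dims)
    region = np.zeros(dims, dtype=np.uint8)
    grid = np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]
    grid = [g.astype(np.float32) for g in grid]

    center = np.array(
        [
            dims[0] // 2 + rng.integers(-3, 4),
            dims[1] // 2 + rng.integers(-3, 4),
            dims[2] // 2 + rng.integers(-1, 2),
        ]
    )

    max_r_mm = max(config.cyst_radius_scn_mm[1] * 1.3 + 10.0, config.mcn_radius_mm[1] + 5.0)
    max_extent = _mm_to_vox(max_r_mm, spacing_ref) + 2
    if np.any(center - max_extent < 0) or np.any(center + max_extent >= np.array(dims)):
        raise ConfigurationError(
            f"grid {dims} too small to contain the lesion (needs +/-{max_extent} "
            f"voxels around {tuple(center)})"
        )

    scar_present = False
    n_nodules = 0

    if config.neutral_geometry:
        # Class-independent geometry: one spherical cyst, 2-voxel wall.
        r = _mm_to_vox(9.0, spacing_ref)
        fluid = _ellipsoid_mask(grid, center, r)
        outer = _ellipsoid_mask(grid, center, r + 2.0)
        region[fluid] = FLUID
        region[outer & ~fluid] = WALL
        n_cysts = 1
        return region, scar_present, n_cysts, n_nodules, center

    if label == "SCN":
        lo, hi = config.n_cysts_scn
        n_cysts = int(rng.integers(lo, hi + 1))
        fluid_total = np.zeros(dims, dtype=bool)
        outer_total = np.zeros(dims, dtype=bool)
        for i in range(n_cysts):
            r_mm = rng.uniform(*config.cyst_radius_scn_mm)
            radii = _mm_to_vox(r_mm, spacing_ref) * rng.uniform(0.85, 1.15, size=3)
            if i == 0:
                c = center.astype(float)
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                offset_mm = rng.uniform(0.6, 1.1) * r_mm
                c = center + direction * _mm_to_vox(offset_mm, spacing_ref)
            fluid_total |= _ellipsoid_mask(grid, c, radii)
            outer_total |= _ellipsoid_mask(grid, c, radii + 1.0)  # 1-voxel wall
        region[fluid_total] = FLUID
        region[outer_total & ~fluid_total] = WALL
        if rng.random() < config.scar_prob:
            scar_present = True
            scar = _ellipsoid_mask(grid, center, _mm_to_vox(2.5, spacing_ref))
            region[scar & fluid_total] = SCAR
        return region, scar_present, n_cysts, n_nodules, center

    if label == "MCN":
        n_cysts = 1
        r_mm = rng.uniform(*config.mcn_radius_mm)
        radii = _mm_to_vox(r_mm, spacing_ref) * rng.uniform(0.9, 1.1, size=3)
        # Uneven wall: independently drawn integer thickness per axis.
        t_lo, t_hi = config.wall_thickness_mcn_vox
        thickness = rng.integers(t_lo, t_hi + 1, size=3).astype(float)
        fluid = _ellipsoid_mask(grid, center, radii)
        outer = _ellipsoid_mask(grid, center, radii + thickness)
        region[fluid] = FLUID
        # Fibrous septations: thin planar slabs through the cyst interior.
        n_sept = int(rng.integers(config.septation_count_mcn[0], config.septation_count_mcn[1] + 1))
        for _ in range(n_sept):
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            offset = rng.uniform(-0.3, 0.3) * float(min(radii))
            dist = (
                (grid[0] - center[0]) * normal[0]
                + (grid[1] - center[1]) * normal[1]
                + (grid[2] - center[2]) * normal[2]
            )
            slab = np.abs(dist - offset) < 0.75
            region[slab & fluid] = SEPTATION
        # Mural nodules: small spheres protruding inward from the wall.
        n_nodules = int(rng.integers(config.nodule_count_mcn[0], config.nodule_count_mcn[1] + 1))
        for _ in range(n_nodules):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c = center + direction * radii * 0.92
            nodule = _ellipsoid_mask(grid, c, _mm_to_vox(rng.uniform(2.0, 3.0), spacing_ref))
            region[nodule & fluid] = NODULE
        region[outer & ~fluid] = WALL
        return region, scar_present, n_cysts, n_nodules, center

    raise ValidationError(f"unknown label {label!r}; expected one of {LABELS}")


def _draw_spacings(config: PhantomConfig, rng) -> dict[str, tuple[float, float, float]]:
    if config.spacing_mm is not None:
        return {m: tuple(config.spacing_mm) for m in MODALITIES}
    t1_ip = rng.uniform(*_T1_INPLANE_RANGE)
    t1_ax = rng.uniform(*_T1_AXIAL_RANGE)
    t2_ip = rng.uniform(*_T2_INPLANE_RANGE)
    t2_ax = rng.uniform(*_T2_AXIAL_RANGE)
    spacings = {m: (t1_ip, t1_ip, t1_ax) for m in CONTRAST_PHASES}
    spacings["T2"] = (t2_ip, t2_ip, t2_ax)
    return spacings


def generate_phantom(label: str, config: PhantomConfig) -> tuple[PatientSeries, PhantomTruth]:
    """Generate one seven-modality phantom, fully determined by ``config.seed``."""
    if label not in LABELS:
        raise ValidationError(f"unknown label {label!r}; expected one of {LABELS}")
    rng = np.random.default_rng(config.seed)

    spacings = _draw_spacings(config, rng)
    spacing_ref = spacings["T1post"]
    region, scar_present, n_cysts, n_nodules, center = _build_geometry(
        label, config, rng, spacing_ref
    )

    dims = region.shape
    # One smooth multiplicative-free bias field shared by all modalities.
    gx, gy, gz = np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]
    phase = rng.uniform(0, 2 * np.pi, size=3)
    bias = config.bias_amplitude * (
        np.sin(2 * np.pi * gx / dims[0] + phase[0])
        * np.sin(2 * np.pi * gy / dims[1] + phase[1])
        * np.sin(np.pi * gz / dims[2] + phase[2])
    ).astype(np.float32)

    shifts = np.zeros((len(MODALITIES), 3))
    if config.misalignment_sd_vox > 0:
        shifts = rng.normal(0.0, config.misalignment_sd_vox, size=(len(MODALITIES), 3))

    volumes: dict[str, ModalityVolume] = {}
    for mi, m in enumerate(MODALITIES):
        values = np.empty(6, dtype=np.float32)
        values[BACKGROUND] = TISSUE_LEVEL
        values[FLUID] = FLUID_INTENSITY[m]
        ramp = float(config.enhancement_slopes[label][mi])
        values[WALL] = ramp
        values[SEPTATION] = ramp
        values[NODULE] = ramp
        values[SCAR] = SCAR_INTENSITY[m]
        vol = values[region] + bias
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=dims).astype(np.float32)
        if config.misalignment_sd_vox > 0:
            vol = ndimage.shift(vol, shifts[mi], order=1, mode="nearest")
        volumes[m] = ModalityVolume(
            voxels=vol.astype(np.float32), spacing_mm=spacings[m], modality=m
        )

    series = PatientSeries(
        patient_id=f"phantom-{config.seed}",
        volumes=volumes,
        lesion_center_vox=tuple(int(c) for c in center),
        label=label,
    )
    truth = PhantomTruth(
        label=label,
        scar_present=scar_present,
        n_cysts=n_cysts,
        n_nodules=n_nodules,
        lesion_center_vox=tuple(int(c) for c in center),
        per_modality_shift_vox=shifts,
        region_map=region,
    )
    return series, truth


def generate_cohort(
    n_scn: int, n_mcn: int, config: PhantomConfig
) -> list[tuple[PatientSeries, PhantomTruth]]:
    """Generate ``n_scn + n_mcn`` phantoms with unique ids and derived seeds."""
    if n_scn < 0 or n_mcn < 0:
        raise ValidationError(f"counts must be >= 0, got ({n_scn}, {n_mcn})")
    n = n_scn + n_mcn
    if n == 0:
        return []
    # Independent per-patient streams, all reproducible from config.seed.
    seeds = np.random.SeedSequence(config.seed).generate_state(n, dtype=np.uint32) >> 1
    labels = ["SCN"] * n_scn + ["MCN"] * n_mcn
    cohort = []
    for i, (label, seed) in enumerate(zip(labels, seeds)):
        sub = dataclasses.replace(config, seed=int(seed))
        series, truth = generate_phantom(label, sub)
        series.patient_id = f"P{i:03d}"
        cohort.append((series, truth))
    return cohort
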