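"""Slice-level preprocessing.

Pipeline order: isotropic 1 mm resampling -> per-modality intensity window
normalization into [-1, 1] -> 80-voxel lesion-centred crop -> extraction of
paired axial slice packs -> (training only) paired augmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .constants import CROP_SIZE, MODALITIES, PAD_VALUE, REFERENCE_MODALITY
from .errors import ConfigurationError, ValidationError
from .volume_io import ModalityVolume, PatientSeries


@dataclass(frozen=True)
class WindowSpec:
    """Per-modality (lo, hi) intensity windows used for [-1, 1] normalization.

    The default window covers the full raw intensity range seen in abdominal
    MR exports (-1700 to 2048); in practice windows are usually derived per
    volume from robust percentiles via :meth:`from_volume`.
    """

    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {m: (-1700.0, 2048.0) for m in MODALITIES}
    )

    def __post_init__(self) -> None:
        for m, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ConfigurationError(f"window for {m!r} must have lo < hi, got ({lo}, {hi})")

    def bounds(self, modality: str) -> tuple[float, float]:
        if modality not in self.windows:
            raise ConfigurationError(f"no window defined for modality {modality!r}")
        return self.windows[modality]

    @staticmethod
    def from_volume(vol: ModalityVolume, percentiles=(0.5, 99.5)) -> tuple[float, float]:
        """Robust per-volume window from percentiles of the nonzero voxels."""
        v = vol.voxels[vol.voxels != 0]
        if v.size == 0:
            v = vol.voxels.ravel()
        lo, hi = np.percentile(v, percentiles)
        if not lo < hi:
            lo, hi = float(v.min()), float(v.min()) + 1.0
        return float(lo), float(hi)

    @classmethod
    def from_series(cls, series: PatientSeries, percentiles=(0.5, 99.5)) -> "WindowSpec":
        return cls(
            windows={
                m: cls.from_volume(series.volumes[m], percentiles) for m in MODALITIES
            }
        )


@dataclass
class SlicePack:
    """Seven aligned, normalized axial slices at one z position."""

    patient_id: str
    z_index: int
    slices: np.ndarray  # (7, CROP_SIZE, CROP_SIZE) in canonical modality order
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.shape != (len(MODALITIES), CROP_SIZE, CROP_SIZE):
            raise ValidationError(
                f"slices must have shape {(len(MODALITIES), CROP_SIZE, CROP_SIZE)}, "
                f"got {self.slices.shape}"
            )
        if self.slices.min() < -1.0 - 1e-6 or self.slices.max() > 1.0 + 1e-6:
            raise ValidationError("slice values must lie in [-1, 1]")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round positive values half away from zero (0.5 -> 1)."""
    return np.floor(np.asarray(x) + 0.5).astype(int)


def _lerp_axis(vox: np.ndarray, axis: int, out_len: int, spacing: float) -> np.ndarray:
    """Linear interpolation along one axis onto a 1 mm grid (edge clamped)."""
    n = vox.shape[axis]
    coords = np.arange(out_len, dtype=np.float64) / spacing
    coords = np.clip(coords, 0.0, n - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    frac = (coords - lo).astype(vox.dtype if vox.dtype.kind == "f" else np.float32)
    a = np.take(vox, lo, axis=axis)
    b = np.take(vox, hi, axis=axis)
    shape = [1] * vox.ndim
    shape[axis] = out_len
    frac = frac.reshape(shape)
    return a * (1.0 - frac) + b * frac


def resample_isotropic(vol: ModalityVolume) -> ModalityVolume:
    """Trilinearly resample a volume onto 1x1x1 mm spacing.

    Output dimension along each axis is round(dims * spacing), rounding half
    away from zero; output voxel j lies at physical position j mm, i.e. input
    coordinate j / spacing.
    """
    spacing = vol.spacing_mm
    out_dims = tuple(int(d) for d in _round_half_away(np.array(vol.dims) * np.array(spacing)))
    vox = np.asarray(vol.voxels, dtype=np.float32)
    if spacing == (1.0, 1.0, 1.0):
        return ModalityVolume(voxels=vox.copy(), spacing_mm=(1.0, 1.0, 1.0), modality=vol.modality)
    # Separable trilinear interpolation, one axis at a time.
    for axis in range(3):
        vox = _lerp_axis(vox, axis, out_dims[axis], spacing[axis])
    return ModalityVolume(voxels=vox, spacing_mm=(1.0, 1.0, 1.0), modality=vol.modality)


def window_normalize(vol: ModalityVolume, spec: WindowSpec) -> ModalityVolume:
    """Clip to the modality's window and map linearly onto [-1, 1]."""
    lo, hi = spec.bounds(vol.modality)
    v = np.clip(vol.voxels, lo, hi)
    # second clip guards against float32 roundoff at the window edges
    out = np.clip(2.0 * (v - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return ModalityVolume(
        voxels=out.astype(np.float32), spacing_mm=vol.spacing_mm, modality=vol.modality
    )


def _crop_centered(vox: np.ndarray, center: Sequence[int], size: int = CROP_SIZE) -> np.ndarray:
    """Crop ``[c - size/2, c + size/2)`` per axis, padding out-of-bounds with PAD_VALUE."""
    center = [int(c) for c in center]
    for ax in range(3):
        if not (0 <= center[ax] < vox.shape[ax]):
            raise ValidationError(
                f"lesion center {tuple(center)} outside volume of dims {vox.shape}"
            )
    half = size // 2
    out = np.full((size, size, size), PAD_VALUE, dtype=np.float32)
    src, dst = [], []
    for ax in range(3):
        start = center[ax] - half
        stop = center[ax] + half
        s0, s1 = max(start, 0), min(stop, vox.shape[ax])
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start, s1 - start))
    out[tuple(dst)] = vox[tuple(src)]
    return out


def crop_lesion(series: PatientSeries, centers: Optional[Mapping[str, Sequence[int]]] = None) -> PatientSeries:
    """Crop every modality to an 80-voxel cube around the lesion center.

    ``centers`` optionally gives a per-modality center (used by the pipeline
    when each modality was resampled from its own spacing); by default the
    shared ``series.lesion_center_vox`` is used for all modalities.
    """
    half = CROP_SIZE // 2
    volumes = {}
    for m in MODALITIES:
        c = centers[m] if centers is not None else series.lesion_center_vox
        cropped = _crop_centered(series.volumes[m].voxels, c)
        volumes[m] = ModalityVolume(voxels=cropped, spacing_mm=(1.0, 1.0, 1.0), modality=m)
    return PatientSeries(
        patient_id=series.patient_id,
        volumes=volumes,
        lesion_center_vox=(half, half, half),
        label=series.label,
    )


def extract_slice_packs(series_cropped: PatientSeries, k_slices: int) -> list[SlicePack]:
    """Extract ``k_slices`` consecutive axial packs centred at z = 40."""
    if k_slices % 2 == 0 or not (1 <= k_slices <= CROP_SIZE):
        raise ValidationError(f"k_slices must be odd and in [1, {CROP_SIZE}], got {k_slices}")
    ref_dims = series_cropped.reference.dims
    if ref_dims != (CROP_SIZE, CROP_SIZE, CROP_SIZE):
        raise ValidationError(f"series must be cropped to {CROP_SIZE}^3, got dims {ref_dims}")
    mid = CROP_SIZE // 2
    packs = []
    for z in range(mid - k_slices // 2, mid + k_slices // 2 + 1):
        slices = np.stack(
            [series_cropped.volumes[m].voxels[:, :, z] for m in MODALITIES], axis=0
        )
        packs.append(
            SlicePack(
                patient_id=series_cropped.patient_id,
                z_index=z,
                slices=slices,
                label=series_cropped.label,
            )
        )
    return packs


@dataclass(frozen=True)
class AugmentSpec:
    """Paired augmentation settings.

    The geometric part (flips, small rotation) is drawn once per pack and
    applied identically to all seven slices so inter-modality correspondence
    is preserved; the intensity jitter is drawn independently per modality.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rot_deg: float = 15.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    shift_range: tuple[float, float] = (-0.05, 0.05)

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls(p_hflip=0.0, p_vflip=0.0, rot_deg=0.0,
                   scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))


def augment(pack: SlicePack, seed: int, spec: AugmentSpec = AugmentSpec()) -> SlicePack:
    """Seeded paired augmentation of one slice pack."""
    rng = np.random.default_rng(seed)
    do_h = rng.random() < spec.p_hflip
    do_v = rng.random() < spec.p_vflip
    angle = rng.uniform(-spec.rot_deg, spec.rot_deg)
    slices = pack.slices
    if do_h:
        slices = slices[:, :, ::-1]
    if do_v:
        slices = slices[:, ::-1, :]
    if angle != 0.0:
        slices = ndimage.rotate(
            slices, angle, axes=(1, 2), reshape=False, order=1,
            mode="constant", cval=PAD_VALUE,
        )
    scale = rng.uniform(*spec.scale_range, size=len(MODALITIES))
    shift = rng.uniform(*spec.shift_range, size=len(MODALITIES))
    slices = slices * scale[:, None, None] + shift[:, None, None]
    slices = np.clip(slices, -1.0, 1.0)
    return SlicePack(
        patient_id=pack.patient_id, z_index=pack.z_index,
        slices=np.ascontiguousarray(slices, dtype=np.float32), label=pack.label,
    )


def expand_training_packs(
    packs: Sequence[SlicePack], n_aug: int, seed: int, spec: AugmentSpec = AugmentSpec()
) -> list[SlicePack]:
    """Return originals plus ``n_aug`` augmented copies of each pack."""
    if n_aug < 0:
        raise ValidationError(f"n_aug must be >= 0, got {n_aug}")
    out = list(packs)
    if n_aug == 0:
        return out
    seeds = np.random.SeedSequence(seed).generate_state(len(packs) * n_aug, dtype=np.uint32) >> 1
    k = 0
    for pack in packs:
        for _ in range(n_aug):
            out.append(augment(pack, int(seeds[k]), spec))
            k += 1
    return out


def preprocess_series(
    series: PatientSeries,
    window: Optional[WindowSpec] = None,
    k_slices: int = 27,
) -> list[SlicePack]:
    """Full per-patient chain: resample -> normalize -> crop -> slice packs.

    Each modality is resampled from its own native spacing, so the lesion
    center is rescaled per modality before cropping. When ``window`` is None
    a robust percentile window is derived per volume.
    """
    if window is None:
        window = WindowSpec.from_series(series)
    volumes, centers = {}, {}
    for m in MODALITIES:
        vol = series.volumes[m]
        centers[m] = _round_half_away(
            np.array(series.lesion_center_vox, dtype=float) * np.array(vol.spacing_mm)
        )
        rs = resample_isotropic(vol)
        volumes[m] = window_normalize(rs, window)
        centers[m] = np.minimum(centers[m], np.array(rs.dims) - 1)
    resampled = PatientSeries(
        patient_id=series.patient_id,
        volumes=volumes,
        lesion_center_vox=tuple(int(c) for c in centers[REFERENCE_MODALITY]),
        label=series.label,
    )
    cropped = crop_lesion(resampled, centers={m: centers[m] for m in MODALITIES})
    return extract_slice_packs(cropped, k_slices)
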