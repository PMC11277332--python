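"""Synthetic four-group CT phantom cohort.

Each patient is an ellipsoidal lesion VOI inside a small CT volume whose
in-mask texture heterogeneity is controlled per group.  The voxel model is

    volume = base_hu + smoothed white noise
             + extreme-intensity anchor voxels (all groups)
             + sparse high-contrast speckle (bone group only)

The white noise (sd = ``noise_sd`` HU) is Gaussian-smoothed in-plane with
width ``smooth_sigma`` voxels.  A handful of fixed-amplitude anchor voxels
(+/- ``anchor_hu``) inside the VOI emulate the extreme-intensity inclusions
(vessel contrast, calcification, cortical bone fragments) that dominate the
intensity range of real contrast-enhanced lesions; because feature
extraction quantizes over the in-mask min-max range, these anchors pin the
bin width, so the fraction of the gray-level axis occupied by the tissue
bulk - and with it the co-occurrence entropy - scales with the smoothed
noise amplitude.  Heterogeneity across groups is therefore driven by two
dials: the noise amplitude relative to the anchored range, and the
smoothing width (narrow = rough, white-noise-like texture; wide = smooth,
spatially correlated texture), plus a bone-specific speckle term mimicking
trabecular structure.  Group defaults are calibrated so that texture
heterogeneity decreases BM > SW > SM > SP (highest entropy and lowest
homogeneity/uniformity in BM), matching the qualitative group ordering the
analysis is meant to detect, while ages are drawn group-independently so
age shows no group effect.  The pure no-noise limit (``noise_sd = 0``)
yields an exactly constant VOI (anchors and speckle are skipped), which
downstream maps to entropy 0 and uniformity 1.

Everything is reproducible from (config, seed); per-patient streams are
derived from the cohort seed and the patient's index so cohorts are stable
under regeneration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import (
    CohortRecord,
    CTVolume,
    GROUP_DEFINITIONS,
    GROUP_ORDER,
    VOIMask,
    manifest_to_frame,
    write_nifti,
)

DEFAULT_GROUP_SIZES: dict[str, int] = {"BM": 5, "SW": 7, "SM": 30, "SP": 3}


@dataclass(frozen=True)
class GroupParams:
    """Per-group texture generator dials.

    base_hu: mean lesion intensity (HU); cosmetic under min-max quantization.
    noise_sd: white-noise amplitude before smoothing (HU).
    smooth_sigma: in-plane Gaussian smoothing width (voxels); the main
        heterogeneity dial (smaller = rougher texture).
    granularity: fraction of VOI voxels replaced by high-contrast speckle.
    speckle_hu: speckle amplitude (HU), added with random sign.
    """

    base_hu: float
    noise_sd: float
    smooth_sigma: float
    granularity: float = 0.0
    speckle_hu: float = 200.0


#: calibrated defaults: heterogeneity decreases BM > SW > SM > SP
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "BM": GroupParams(base_hu=300.0, noise_sd=110.0, smooth_sigma=0.4,
                      granularity=0.02, speckle_hu=300.0),
    "SW": GroupParams(base_hu=70.0, noise_sd=45.0, smooth_sigma=0.8),
    "SM": GroupParams(base_hu=60.0, noise_sd=38.0, smooth_sigma=1.0),
    "SP": GroupParams(base_hu=50.0, noise_sd=14.0, smooth_sigma=1.5),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    shape: tuple[int, int, int] = (64, 64, 8)
    voi_semiaxes: tuple[float, float, float] = (24.0, 24.0, 3.0)
    group_params: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    spacing: tuple[float, float, float] = (0.625, 0.625, 3.0)
    anchor_count: int = 12
    anchor_hu: float = 400.0
    age_range: tuple[int, int] = (33, 93)
    female_fraction: float = 0.87

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for g, p in self.group_params.items():
            if p.noise_sd < 0 or p.smooth_sigma < 0:
                raise ValueError(f"group {g}: noise_sd and smooth_sigma must be >= 0")
        if any(2 * a > s for a, s in zip(self.voi_semiaxes, self.shape)):
            raise ValueError(
                f"VOI semi-axes {self.voi_semiaxes} do not fit inside shape {self.shape}"
            )
        unknown = set(self.group_sizes) - set(GROUP_DEFINITIONS)
        if unknown:
            raise ValueError(f"unknown groups in config: {sorted(unknown)}")


@dataclass(frozen=True)
class PhantomSpec:
    patient_id: str
    group: str
    seed_offset: int
    params: GroupParams


def ellipsoid_mask(shape: tuple[int, int, int], semiaxes: tuple[float, float, float]) -> VOIMask:
    """Centered ellipsoidal VOI."""
    if any(2 * a > s for a, s in zip(semiaxes, shape)):
        raise ValueError(f"VOI semi-axes {semiaxes} do not fit inside volume shape {shape}")
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centers = [(s - 1) / 2.0 for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semiaxes))
    return VOIMask(voxels=r2 <= 1.0)


def generate_phantom(
    spec: PhantomSpec, cfg: SyntheticCohortConfig, seed: int
) -> tuple[CTVolume, VOIMask]:
    """Deterministic phantom volume + ellipsoid mask for one patient."""
    rng = np.random.default_rng([seed, spec.seed_offset])
    p = spec.params
    mask = ellipsoid_mask(cfg.shape, cfg.voi_semiaxes)
    vox = np.full(cfg.shape, p.base_hu, dtype=float)
    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=cfg.shape)
        if p.smooth_sigma > 0:
            # in-plane smoothing only: slices stay statistically independent
            noise = gaussian_filter(noise, sigma=(p.smooth_sigma, p.smooth_sigma, 0.0))
        vox += noise
        if p.granularity > 0:
            n = int(round(p.granularity * vox.size))
            idx = rng.choice(vox.size, size=n, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n)
            vox.ravel()[idx] += signs * p.speckle_hu
        if cfg.anchor_count > 0 and cfg.anchor_hu > 0:
            # extreme-intensity inclusions inside the VOI anchor the
            # quantization range identically across groups
            inside = np.flatnonzero(mask.voxels.ravel())
            n_anchor = min(cfg.anchor_count, inside.size)
            picks = rng.choice(inside, size=n_anchor, replace=False)
            anchor_signs = np.where(np.arange(n_anchor) % 2 == 0, 1.0, -1.0)
            vox.ravel()[picks] = p.base_hu + anchor_signs * cfg.anchor_hu
    vol = CTVolume(voxels=vox, spacing=cfg.spacing)
    return vol, mask


def cohort_specs(cfg: SyntheticCohortConfig) -> list[PhantomSpec]:
    specs = []
    offset = 0
    for g in GROUP_ORDER:
        size = cfg.group_sizes.get(g, 0)
        for i in range(size):
            specs.append(
                PhantomSpec(
                    patient_id=f"{g}{i + 1:02d}",
                    group=g,
                    seed_offset=offset,
                    params=cfg.group_params[g],
                )
            )
            offset += 1
    return specs


def iter_cohort(
    cfg: SyntheticCohortConfig, seed: int
) -> Iterator[tuple[CohortRecord, CTVolume, VOIMask]]:
    """Yield (record, volume, mask) per patient without touching disk.

    Ages are uniform over the configured range with no group effect, so any
    apparent age signal downstream is a false positive by construction.
    """
    demo_rng = np.random.default_rng([seed, 10_000_019])
    for spec in cohort_specs(cfg):
        tissue, grade = GROUP_DEFINITIONS[spec.group]
        age = int(demo_rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        sex = "F" if demo_rng.random() < cfg.female_fraction else "M"
        record = CohortRecord(
            patient_id=spec.patient_id, group=spec.group,
            age=age, sex=sex, tissue=tissue, grade=grade,
        )
        vol, mask = generate_phantom(spec, cfg, seed)
        yield record, vol, mask


def generate_cohort(
    cfg: SyntheticCohortConfig, out_dir: str | os.PathLike, seed: int
) -> Path:
    """Write the cohort to disk: NIfTI volumes/masks plus manifest.csv.

    Returns the manifest path; volume files are '<id>_ct.nii.gz' and masks
    '<id>_mask.nii.gz' in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for record, vol, mask in iter_cohort(cfg, seed):
        write_nifti(out_dir / f"{record.patient_id}_ct.nii.gz", vol.voxels, vol.spacing)
        write_nifti(
            out_dir / f"{record.patient_id}_mask.nii.gz",
            mask.voxels.astype(np.uint8),
            vol.spacing,
        )
        records.append(record)
    manifest = out_dir / "manifest.csv"
    manifest_to_frame(records).to_csv(manifest, index=False)
    return manifest


def null_config(cfg: SyntheticCohortConfig | None = None, group: str = "SM") -> SyntheticCohortConfig:
    """A copy of ``cfg`` where every group shares one set of generator params.

    Under this configuration the four groups are exchangeable, so any
    downstream per-variable rejection is a type-I error.
    """
    cfg = cfg or SyntheticCohortConfig()
    shared = cfg.group_params[group]
    return replace(cfg, group_params={g: shared for g in cfg.group_params})
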