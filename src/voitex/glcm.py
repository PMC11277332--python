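"""Mask-restricted GLCM construction and Haralick texture parameters.

Intensities inside the VOI are quantized to a fixed number of gray levels
(default 128) by equal-width binning over the in-mask min-max range, so the
features are invariant under positive affine transforms of the raw HU
values.  Co-occurrence is counted slice-wise in 2-D (the axial slices are
thick relative to the in-plane pixel size, so 3-D offsets would mix very
different physical step lengths): for each axial slice, ordered level pairs
are counted at the four in-plane directions (0, 45, 90, 135 degrees) at
offset magnitude d, in both directions, and pooled over all slices and
angles into a single symmetric matrix per distance before normalization.

Eleven parameters are computed from each normalized matrix p(i, j):
uniformity (energy), contrast, correlation, variance, homogeneity (inverse
difference moment), entropy, sum average, sum variance, sum entropy,
difference variance and difference entropy, with the 0*log(0)=0 convention
and the natural logarithm by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import CTVolume, VOIMask

logger = logging.getLogger(__name__)

#: canonical parameter order (matches the summary-table row order)
PARAMETERS: tuple[str, ...] = (
    "uniformity",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
)

DISTANCES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: in-plane (row, col) unit offsets per angle, scaled by the distance
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (1, 1),
    90: (1, 0),
    135: (1, -1),
}

ALL_ANGLES: tuple[int, ...] = (0, 45, 90, 135)

#: sentinel for out-of-mask voxels in a quantized grid
OUTSIDE = -1


@dataclass(frozen=True)
class QuantizedVOI:
    """Gray-level grid with values in {0..L-1} in-mask and -1 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    degenerate: bool = False  # constant in-mask intensity range

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("VOI has no voxels")
        if inside.min() < 0 or inside.max() > self.n_levels - 1:
            raise ValueError("quantized levels outside [0, L-1]")


@dataclass(frozen=True)
class GLCM:
    """Normalized symmetric co-occurrence matrix for one offset magnitude."""

    p: np.ndarray
    distance: int
    total_pairs: int

    def __post_init__(self) -> None:
        p = self.p
        if self.total_pairs <= 0:
            raise ValueError("GLCM built from zero pairs")
        if not np.allclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("GLCM probabilities do not sum to 1")
        if not np.array_equal(p, p.T):
            raise ValueError("GLCM is not symmetric")
        if (p < 0).any():
            raise ValueError("GLCM has negative entries")


@dataclass
class TextureVector:
    """The 11 parameters at each configured distance for one patient."""

    patient_id: str
    values: dict[tuple[str, int], float]
    degenerate_flags: dict[tuple[str, int], str] = field(default_factory=dict)

    def as_columns(self) -> dict[str, float]:
        """Flatten to '<parameter>_q<d>' keyed columns."""
        return {f"{p}_q{d}": v for (p, d), v in self.values.items()}


def quantize(vol: CTVolume, mask: VOIMask, n_levels: int = 128) -> QuantizedVOI:
    """Equal-width binning of in-mask intensities over their min-max range.

    level(v) = min(L-1, floor(L * (v - vmin) / (vmax - vmin))); a constant
    VOI maps everything to level 0 and raises the degenerate flag.
    """
    if n_levels < 2:
        raise ValueError(f"need at least 2 gray levels, got {n_levels}")
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    m = mask.voxels
    inside = vol.voxels[m]
    if not np.all(np.isfinite(inside)):
        raise ValueError("non-finite intensities inside the VOI")
    vmin = float(inside.min())
    vmax = float(inside.max())
    levels = np.full(vol.shape, OUTSIDE, dtype=np.int32)
    if vmax == vmin:
        levels[m] = 0
        return QuantizedVOI(levels=levels, n_levels=n_levels, mask=m, degenerate=True)
    binned = np.floor(n_levels * (inside - vmin) / (vmax - vmin)).astype(np.int32)
    np.minimum(binned, n_levels - 1, out=binned)
    levels[m] = binned
    return QuantizedVOI(levels=levels, n_levels=n_levels, mask=m, degenerate=False)


def _directed_counts(lv: np.ndarray, dr: int, dc: int, L: int) -> np.ndarray:
    """One-directional pair counts for a 2-D level grid with -1 sentinels."""
    rows, cols = lv.shape
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        return np.zeros(L * L, dtype=np.int64)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return np.zeros(L * L, dtype=np.int64)
    return np.bincount(a[valid].astype(np.int64) * L + b[valid], minlength=L * L)


def glcm_counts(q: QuantizedVOI, distance: int, angles: tuple[int, ...] = ALL_ANGLES) -> np.ndarray:
    """Raw symmetric pair counts pooled over slices and angles (unnormalized)."""
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    L = q.n_levels
    flat = np.zeros(L * L, dtype=np.int64)
    slice_has_mask = q.mask.any(axis=(0, 1))
    for z in np.nonzero(slice_has_mask)[0]:
        lv = q.levels[:, :, z]
        for ang in angles:
            ur, uc = ANGLE_OFFSETS[ang]
            flat += _directed_counts(lv, ur * distance, uc * distance, L)
    counts = flat.reshape(L, L)
    return counts + counts.T  # both directions: symmetric ordered-pair counts


def build_glcm(q: QuantizedVOI, distance: int, angles: tuple[int, ...] = ALL_ANGLES) -> GLCM:
    """Build the normalized VOI-level GLCM for one offset magnitude."""
    counts = glcm_counts(q, distance, angles)
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"VOI too small for distance {distance}: no valid voxel pair")
    return GLCM(p=counts / total, distance=distance, total_pairs=total)


def _entropy(p: np.ndarray, log_base: float | None) -> float:
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if log_base is not None:
        h /= math.log(log_base)
    return h


def haralick(glcm: GLCM, log_base: float | None = None) -> tuple[dict[str, float], dict[str, str]]:
    """Compute the 11 texture parameters from one normalized GLCM.

    Returns (values, degenerate_flags).  ``log_base=None`` means natural log.
    Correlation is defined as 0 (with a flag) when the marginal variance is
    zero, so downstream statistics never see non-finite values.
    """
    p = glcm.p
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    I = i[:, None]
    J = i[None, :]

    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    idx_sum = (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel()
    idx_diff = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel()
    p_sum = np.bincount(idx_sum, weights=p.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(idx_diff, weights=p.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    flags: dict[str, str] = {}
    values: dict[str, float] = {}

    values["uniformity"] = float((p ** 2).sum())
    values["contrast"] = float((((I - J) ** 2) * p).sum())
    if sigma2 > 0:
        values["correlation"] = float((((I - mu) * (J - mu)) * p).sum() / sigma2)
    else:
        values["correlation"] = 0.0
        flags["correlation"] = "zero marginal variance"
    values["variance"] = float((((I - mu) ** 2) * p).sum())
    values["homogeneity"] = float((p / (1.0 + (I - J) ** 2)).sum())
    values["entropy"] = _entropy(p, log_base)
    sa = float((k_sum * p_sum).sum())
    values["sum_average"] = sa
    values["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    values["sum_entropy"] = _entropy(p_sum, log_base)
    da = float((k_diff * p_diff).sum())
    values["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    values["difference_entropy"] = _entropy(p_diff, log_base)
    return values, flags


def extract_texture_vector(
    vol: CTVolume,
    mask: VOIMask,
    patient_id: str = "",
    distances: tuple[int, ...] = DISTANCES,
    n_levels: int = 128,
    angles: tuple[int, ...] = ALL_ANGLES,
    log_base: float | None = None,
    pooling: str = "pooled",
) -> TextureVector:
    """Quantize once and compute all parameters at every distance.

    ``pooling='pooled'`` (default) accumulates pair counts over all slices
    and angles into one VOI-level GLCM per distance; ``'per_slice_mean'``
    computes features per slice and averages them (slices without a valid
    pair at that distance are skipped).  A distance with no valid pair in
    pooled mode yields convention values of 0 with a degenerate flag so the
    vector always carries 11 x len(distances) entries.
    """
    q = quantize(vol, mask, n_levels)
    values: dict[tuple[str, int], float] = {}
    flags: dict[tuple[str, int], str] = {}
    if q.degenerate:
        for d in distances:
            flags[("quantization", d)] = "constant VOI intensity"

    n_ok = 0
    for d in distances:
        try:
            if pooling == "pooled":
                g = build_glcm(q, d, angles)
                vals, f = haralick(g, log_base)
            elif pooling == "per_slice_mean":
                vals, f = _per_slice_features(q, d, angles, log_base)
            else:
                raise ValueError(f"unknown pooling mode {pooling!r}")
        except ValueError as exc:
            if "too small" not in str(exc) and "no valid" not in str(exc):
                raise
            logger.warning("patient %s: %s; emitting convention zeros", patient_id, exc)
            for param in PARAMETERS:
                values[(param, d)] = 0.0
                flags[(param, d)] = "no valid pair at this distance"
            continue
        n_ok += 1
        for param in PARAMETERS:
            values[(param, d)] = vals[param]
        for param, reason in f.items():
            flags[(param, d)] = reason
    if n_ok == 0:
        raise ValueError(f"no distance in {distances} has a valid voxel pair in the VOI")
    return TextureVector(patient_id=patient_id, values=values, degenerate_flags=flags)


def _per_slice_features(
    q: QuantizedVOI, distance: int, angles: tuple[int, ...], log_base: float | None
) -> tuple[dict[str, float], dict[str, str]]:
    per_slice: list[dict[str, float]] = []
    flags: dict[str, str] = {}
    L = q.n_levels
    for z in np.nonzero(q.mask.any(axis=(0, 1)))[0]:
        sub = QuantizedVOI(
            levels=q.levels[:, :, z:z + 1],
            n_levels=L,
            mask=q.mask[:, :, z:z + 1],
            degenerate=q.degenerate,
        )
        try:
            g = build_glcm(sub, distance, angles)
        except ValueError:
            continue
        vals, f = haralick(g, log_base)
        per_slice.append(vals)
        flags.update(f)
    if not per_slice:
        raise ValueError(f"VOI too small for distance {distance}: no valid voxel pair")
    return {p: float(np.mean([s[p] for s in per_slice])) for p in PARAMETERS}, flags
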