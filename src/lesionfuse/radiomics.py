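"""Radiomics feature extraction over the lesion region of interest.

Implements, from their standard definitions, the six feature families
that matter downstream: first-order intensity statistics, 3-D shape
descriptors, and the four texture-matrix families GLCM (gray-level
co-occurrence), GLDM (gray-level dependence), GLSZM (gray-level
size-zone) and NGTDM (neighbouring gray tone difference).  Conventions,
fixed and documented here:

* equal-width discretization into ``n_levels`` bins over the ROI
  intensity range (levels 1..N_g; the top bin is right-closed);
* 26-connectivity and distance-1 neighbourhoods for every texture
  family; GLCM uses the 13 unique 3-D direction offsets, each counted
  symmetrically, and averages the per-direction normalized matrices;
* NGTDM coarseness returns 1e6 when its denominator vanishes
  (constant ROI), a common implementation convention;
* GLDM "dependence size" is the neighbour count plus one (the centre
  voxel), so emphasis features stay defined for isolated voxels;
* shape elongation and flatness are anisotropy ratios >= 1
  (sqrt(lambda_major / lambda_minor)); each voxel contributes its own
  cube inertia (spacing^2/12) so thin structures stay finite and a
  single voxel scores exactly 1;
* first-order entropy uses the same equal-width discretization; the
  kurtosis reported is the Fisher (excess) form.

The fixed feature order is ``FEATURE_NAMES``; every feature value is
finite on any non-empty ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

COARSENESS_CONSTANT = 1e6

# 13 unique direction offsets covering all 26 neighbours up to sign
GLCM_OFFSETS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

ALL_26_OFFSETS = [o for o in
                  ((dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1)) if o != (0, 0, 0)]

FEATURE_NAMES: tuple[str, ...] = (
    "firstorder_mean", "firstorder_range", "firstorder_energy",
    "firstorder_entropy", "firstorder_skewness", "firstorder_kurtosis",
    "firstorder_p10", "firstorder_p90",
    "shape_volume", "shape_surface_area", "shape_sphericity",
    "shape_elongation", "shape_flatness", "shape_max_diameter3d",
    "glcm_contrast", "glcm_correlation", "glcm_joint_entropy",
    "glcm_idm", "glcm_cluster_shade",
    "gldm_dependence_entropy", "gldm_small_dependence_emphasis",
    "gldm_large_dependence_emphasis", "gldm_gray_level_nonuniformity",
    "glszm_zone_entropy", "glszm_small_area_emphasis",
    "glszm_large_area_emphasis", "glszm_zone_size_nonuniformity",
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
)

FEATURE_FAMILIES: tuple[str, ...] = (
    "firstorder", "shape", "glcm", "gldm", "glszm", "ngtdm")


class FeatureUndefinedError(ValueError):
    """A texture family has no valid voxel pair/neighbourhood in the ROI."""


@dataclass(frozen=True)
class RadiomicsConfig:
    n_levels: int = 32
    gldm_alpha: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..n_levels) on ROI voxels; 0 elsewhere."""

    levels: np.ndarray  # int grid, full spatial shape
    mask: np.ndarray    # bool grid
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def roi_voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RadiomicsVector:
    values: dict[str, float] = field(default_factory=dict)

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=np.float64)

    @staticmethod
    def names() -> tuple[str, ...]:
        return FEATURE_NAMES


def discretize_roi(volume: np.ndarray, mask: np.ndarray, n_levels: int,
                   spacing=(1.0, 1.0, 1.0)) -> DiscretizedROI:
    """Equal-width binning of ROI intensities into ``n_levels`` levels."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 4:  # texture is computed on the first channel
        volume = volume[0]
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    vals = volume[mask]
    vmin, vmax = vals.min(), vals.max()
    levels = np.zeros(volume.shape, dtype=np.int64)
    if vmax == vmin:
        warnings.warn("constant ROI: all voxels assigned level 1",
                      RuntimeWarning, stacklevel=2)
        levels[mask] = 1
    else:
        width = (vmax - vmin) / n_levels
        lv = np.floor((vals - vmin) / width).astype(np.int64) + 1
        lv[lv > n_levels] = n_levels  # right-closed top bin
        levels[mask] = lv
    return DiscretizedROI(levels=levels, mask=mask, n_levels=n_levels,
                          spacing=tuple(spacing))


# -- first order --------------------------------------------------------

def firstorder_features(roi_intensities: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    x = np.asarray(roi_intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    if m2 > 0:
        skew = ((x - mean) ** 3).mean() / m2 ** 1.5
        kurt = ((x - mean) ** 4).mean() / m2 ** 2 - 3.0
    else:
        skew, kurt = 0.0, 0.0
    # entropy over the equal-width discretized histogram
    if x.max() > x.min():
        width = (x.max() - x.min()) / n_bins
        lv = np.minimum(np.floor((x - x.min()) / width).astype(int), n_bins - 1)
        p = np.bincount(lv, minlength=n_bins) / x.size
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    return {
        "mean": float(mean),
        "range": float(x.max() - x.min()),
        "energy": float((x ** 2).sum()),
        "entropy": entropy,
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


# -- shape --------------------------------------------------------------

def _surface_area_facecount(mask: np.ndarray, spacing) -> float:
    """Total area of voxel faces between ROI and background/border."""
    sz, sy, sx = spacing
    face_area = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    padded = np.pad(mask, 1).astype(np.int8)
    area = 0.0
    for axis in range(3):
        d = np.diff(padded, axis=axis)
        area += np.abs(d).sum() * face_area[axis]
    return float(area)


def _max_diameter(coords_mm: np.ndarray) -> float:
    n = coords_mm.shape[0]
    if n == 1:
        return 0.0
    best = 0.0
    chunk = 2048
    for i in range(0, n, chunk):
        d = coords_mm[i:i + chunk, None, :] - coords_mm[None, :, :]
        best = max(best, float(np.sqrt((d ** 2).sum(-1)).max()))
    return best


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxel_vol = float(np.prod(spacing))
    volume = n * voxel_vol
    area = _surface_area_facecount(mask, spacing)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    cov += np.diag(spacing ** 2) / 12.0  # each voxel as a uniform cube
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]  # lam1 >= lam2 >= lam3 > 0
    elongation = float(np.sqrt(lam[0] / lam[1]))
    flatness = float(np.sqrt(lam[0] / lam[2]))
    return {
        "volume": volume,
        "surface_area": area,
        "sphericity": sphericity,
        "elongation": elongation,
        "flatness": flatness,
        "max_diameter3d": _max_diameter(coords),
    }


# -- GLCM ---------------------------------------------------------------

def glcm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix."""
    lv, mask, ng = droi.levels, droi.mask, droi.n_levels
    mats = []
    for off in GLCM_OFFSETS:
        sl_a = tuple(slice(max(0, -o), lv.shape[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), lv.shape[i] + min(0, o)) for i, o in enumerate(off))
        a, b = lv[sl_a], lv[sl_b]
        valid = mask[sl_a] & mask[sl_b]
        if not valid.any():
            continue
        ai, bi = a[valid] - 1, b[valid] - 1
        m = np.zeros((ng, ng))
        np.add.at(m, (ai, bi), 1.0)
        np.add.at(m, (bi, ai), 1.0)  # symmetric
        mats.append(m / m.sum())
    if not mats:
        raise FeatureUndefinedError("no in-ROI voxel pair for any GLCM direction")
    return np.mean(mats, axis=0)


def glcm_features(droi: DiscretizedROI) -> dict[str, float]:
    if droi.roi_voxel_count < 2:
        raise FeatureUndefinedError("GLCM needs at least 2 ROI voxels")
    p = glcm_matrix(droi)
    ng = droi.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    if sig2 > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sig2)
    else:
        correlation = 1.0  # constant ROI convention
    pz = p[p > 0]
    return {
        "contrast": contrast,
        "correlation": correlation,
        "joint_entropy": float(-(pz * np.log2(pz)).sum()),
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "cluster_shade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
    }


# -- GLDM ---------------------------------------------------------------

def gldm_matrix(droi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """P[level-1, d]: ROI voxels of each level with d dependent neighbours
    (26-connectivity, |level difference| <= alpha)."""
    lv, mask, ng = droi.levels, droi.mask, droi.n_levels
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in ALL_26_OFFSETS:
        sl_a = tuple(slice(max(0, -o), lv.shape[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), lv.shape[i] + min(0, o)) for i, o in enumerate(off))
        ok = mask[sl_a] & mask[sl_b] & (np.abs(lv[sl_a] - lv[sl_b]) <= alpha)
        dep[sl_a] += ok
    m = np.zeros((ng, 27))
    np.add.at(m, (lv[mask] - 1, dep[mask]), 1.0)
    return m


def gldm_features(droi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    m = gldm_matrix(droi, alpha)
    nv = m.sum()
    s = np.arange(1, 28)  # dependence size = neighbour count + 1 (centre)
    row = m.sum(axis=1)
    p = m / nv
    pz = p[p > 0]
    return {
        "dependence_entropy": float(-(pz * np.log2(pz)).sum()),
        "small_dependence_emphasis": float((m / s[None, :] ** 2).sum() / nv),
        "large_dependence_emphasis": float((m * s[None, :] ** 2).sum() / nv),
        "gray_level_nonuniformity": float((row ** 2).sum() / nv),
    }


# -- GLSZM --------------------------------------------------------------

def glszm_zones(droi: DiscretizedROI) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone in the ROI."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for level in np.unique(droi.levels[droi.mask]):
        lab, nlab = ndimage.label(droi.levels == level, structure=structure)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(level), int(sz)) for sz in sizes)
    return zones


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    zones = glszm_zones(droi)
    nz = len(zones)
    sizes = np.array([z[1] for z in zones], dtype=np.float64)
    # zone-count matrix probabilities for entropy
    _, counts = np.unique(np.array(zones), axis=0, return_counts=True)
    p = counts / nz
    return {
        "zone_entropy": float(-(p * np.log2(p)).sum()),
        "small_area_emphasis": float((1.0 / sizes ** 2).sum() / nz),
        "large_area_emphasis": float((sizes ** 2).sum() / nz),
        "zone_size_nonuniformity": float(
            (np.bincount(sizes.astype(int)) ** 2).sum() / nz),
    }


# -- NGTDM --------------------------------------------------------------

def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) over ROI voxels with >= 1 in-ROI neighbour.

    s_i = sum over contributing voxels of |level - mean level of its
    in-ROI 26-neighbours|; n_i = number of contributing voxels of level
    i; returns (n, s, N_vc).
    """
    lv, mask, ng = droi.levels, droi.mask, droi.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate((lv * mask).astype(np.float64), kernel,
                                mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(mask.astype(np.float64), kernel,
                                mode="constant", cval=0.0)
    contrib = mask & (nbr_cnt > 0)
    if not contrib.any():
        raise FeatureUndefinedError("no ROI voxel has an in-ROI neighbour")
    diffs = np.abs(lv[contrib] - nbr_sum[contrib] / nbr_cnt[contrib])
    levels = lv[contrib]
    n = np.bincount(levels - 1, minlength=ng).astype(np.float64)
    s = np.bincount(levels - 1, weights=diffs, minlength=ng)
    return n, s, int(contrib.sum())


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    n, s, nvc = ngtdm_table(droi)
    p = n / nvc
    present = p > 0
    i = np.arange(1, droi.n_levels + 1, dtype=np.float64)
    ngp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CONSTANT

    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi_, pj_ = np.meshgrid(p[present], p[present], indexing="ij")
        si_, sj_ = np.meshgrid(s[present], s[present], indexing="ij")
        contrast = float((pi_ * pj_ * (ii - jj) ** 2).sum()
                         / (ngp * (ngp - 1)) * (s.sum() / nvc))
        busy_den = float(np.abs(ii * pi_ - jj * pj_).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_)
                            / (pi_ + pj_)).sum() / nvc)
        s_tot = float(s.sum())
        strength = (float(((pi_ + pj_) * (ii - jj) ** 2).sum()) / s_tot
                    if s_tot > 0 else 0.0)
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# -- full vector --------------------------------------------------------

def extract_feature_vector(study, config: RadiomicsConfig | None = None) -> RadiomicsVector:
    """All six families, fixed order, computed inside the lesion ROI."""
    config = config or RadiomicsConfig()
    volume = study.volume[0] if study.volume.ndim == 4 else study.volume
    mask = study.mask.astype(bool)
    droi = discretize_roi(volume, mask, config.n_levels, config.spacing)

    values: dict[str, float] = {}
    try:
        for k, v in firstorder_features(volume[mask], config.n_levels).items():
            values[f"firstorder_{k}"] = v
        for k, v in shape_features(mask, config.spacing).items():
            values[f"shape_{k}"] = v
        for k, v in glcm_features(droi).items():
            values[f"glcm_{k}"] = v
        for k, v in gldm_features(droi, config.gldm_alpha).items():
            values[f"gldm_{k}"] = v
        for k, v in glszm_features(droi).items():
            values[f"glszm_{k}"] = v
        for k, v in ngtdm_features(droi).items():
            values[f"ngtdm_{k}"] = v
    except FeatureUndefinedError as err:
        raise FeatureUndefinedError(
            f"study {getattr(study, 'study_id', '?')}: {err}") from err
    assert tuple(values) == FEATURE_NAMES
    return RadiomicsVector(values=values)


class FeatureStandardizer:
    """Per-feature z-standardization fitted on training folds only."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "FeatureStandardizer":
        matrix = np.asarray(matrix, dtype=np.float64)
        self.mean_ = matrix.mean(axis=0)
        sd = matrix.std(axis=0)
        sd[sd == 0] = 1.0  # constant features pass through centred
        self.sd_ = sd
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(matrix, dtype=np.float64) - self.mean_) / self.sd_


def feature_matrix(studies, config: RadiomicsConfig | None = None) -> np.ndarray:
    return np.stack([extract_feature_vector(s, config).to_array() for s in studies])
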