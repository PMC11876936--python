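"""Synthetic 3-D lesion phantoms with class-dependent texture and shape.

Each phantom emulates a brain-sized intensity volume containing one or
more blob lesions on a noise background, paired with a ground-truth
binary mask and a binary class label.  The two classes differ inside
the lesion only:

* class 1 ("AF-like"): high neighbourhood gray-tone contrast — a
  voxel-wise alternating high/low (checkerboard) texture at a
  controllable amplitude — and an elongated ellipsoidal shape;
* class 0 ("non-AF-like"): smooth low-pass-filtered noise texture and a
  near-spherical shape.

This makes the neighbouring gray tone difference (NGTDM) contrast of
the lesion region the designed discriminating statistic, together with
shape anisotropy, so the downstream radiomics, fusion-network and
feature-ranking machinery can be tested for recovery of a known signal.
All randomness flows through explicit seeds; cohort generation is a
pure function of (params, n, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


class PlacementError(ValueError):
    """A lesion of the drawn size cannot be placed inside the grid."""


@dataclass(frozen=True)
class ClassRecipe:
    """Texture and shape recipe for one class.

    base_intensity : mean lesion intensity above the zero background.
    texture_amplitude : peak amplitude of the within-lesion texture.
    elongation : ratio of the long ellipsoid semi-axis to the other two.
    smooth_sigma : Gaussian sigma of the low-pass texture (class 0 style);
        ignored when ``checkerboard`` is True.
    checkerboard : voxel-wise alternating texture (class 1 style).
    """

    base_intensity: float = 60.0
    texture_amplitude: float = 8.0
    elongation: float = 1.0
    smooth_sigma: float = 1.5
    checkerboard: bool = False


def default_class_effect() -> dict[int, ClassRecipe]:
    return {
        0: ClassRecipe(base_intensity=60.0, texture_amplitude=8.0,
                       elongation=1.0, smooth_sigma=1.5, checkerboard=False),
        1: ClassRecipe(base_intensity=60.0, texture_amplitude=40.0,
                       elongation=1.8, checkerboard=True),
    }


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for a phantom cohort."""

    grid_shape: tuple[int, int, int] = (32, 64, 64)
    n_lesions_range: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[float, float] = (3.0, 5.0)
    class_effect: dict[int, ClassRecipe] = field(default_factory=default_class_effect)
    noise_sd: float = 4.0
    intensity_scale_jitter: tuple[float, float] = (0.8, 1.2)
    n_channels: int = 1
    metadata_label_shift: float = 0.0  # 0 = metadata independent of label
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape dims must all be >= 8, got {self.grid_shape}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not {0, 1} <= set(self.class_effect):
            raise ValueError("class_effect must define recipes for classes 0 and 1")
        rmax = self.lesion_radius_range[1]
        emax = max(r.elongation for r in self.class_effect.values())
        if 2 * rmax * emax >= min(self.grid_shape[1:]):
            raise ValueError("largest lesion cannot fit inside the grid in-plane")


@dataclass
class Study:
    """One subject: intensity volume(s), lesion mask, label, metadata."""

    volume: np.ndarray  # (C, z, y, x) channel-first
    mask: np.ndarray    # (z, y, x) binary
    label: int
    study_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.ndim == 3:
            self.volume = self.volume[None]
        self.mask = np.asarray(self.mask).astype(bool)
        if self.volume.shape[1:] != self.mask.shape:
            raise ValueError("volume and mask spatial shapes differ")
        if self.mask.sum() < 1:
            raise ValueError("mask must contain at least one foreground voxel")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def _ellipsoid_mask(grid_shape, center, radius, elongation, long_axis):
    """Boolean ellipsoid: semi-axis radius*elongation along long_axis."""
    semi = np.full(3, float(radius))
    semi[long_axis] *= elongation
    zz, yy, xx = np.ogrid[:grid_shape[0], :grid_shape[1], :grid_shape[2]]
    d2 = (((zz - center[0]) / semi[0]) ** 2
          + ((yy - center[1]) / semi[1]) ** 2
          + ((xx - center[2]) / semi[2]) ** 2)
    return d2 <= 1.0


def generate_study(params: PhantomParams, label: int, rng) -> Study:
    """Generate one phantom Study; deterministic under a fixed rng state."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    recipe = params.class_effect[label]
    gs = params.grid_shape
    mask = np.zeros(gs, dtype=bool)
    texture = np.zeros(gs, dtype=np.float64)

    n_lesions = int(rng.integers(params.n_lesions_range[0],
                                 params.n_lesions_range[1] + 1))
    for _ in range(n_lesions):
        radius = float(rng.uniform(*params.lesion_radius_range))
        # long axis restricted to the (larger) in-plane axes
        long_axis = int(rng.integers(1, 3)) if recipe.elongation > 1.0 else 1
        semi = np.full(3, radius)
        semi[long_axis] *= recipe.elongation
        lo = np.ceil(semi).astype(int)
        hi = np.array(gs) - lo - 1
        if np.any(lo > hi):
            raise PlacementError(
                f"lesion semi-axes {semi} do not fit inside grid {gs}")
        center = np.array([rng.integers(lo[i], hi[i] + 1) for i in range(3)])
        lesion = _ellipsoid_mask(gs, center, radius, recipe.elongation, long_axis)
        mask |= lesion

        if recipe.checkerboard:
            zz, yy, xx = np.indices(gs)
            parity = (zz + yy + xx) % 2
            tex = recipe.texture_amplitude * (2.0 * parity - 1.0)
        else:
            tex = gaussian_filter(rng.standard_normal(gs), recipe.smooth_sigma)
            sd = tex.std()
            if sd > 0:
                tex *= recipe.texture_amplitude / (3.0 * sd)  # ~amplitude at 3 sigma
        texture[lesion] = recipe.base_intensity + tex[lesion]

    volume = np.zeros((params.n_channels,) + gs, dtype=np.float64)
    for c in range(params.n_channels):
        vol = texture.copy()
        if params.noise_sd > 0:
            vol += params.noise_sd * rng.standard_normal(gs)
        volume[c] = vol
    scale = float(rng.uniform(*params.intensity_scale_jitter))
    volume *= scale

    return Study(volume=volume, mask=mask, label=label, study_id="", metadata={})


def _sample_metadata(rng: np.random.Generator, label: int, shift: float) -> dict:
    """Metadata emulating a stroke cohort (age ~72 ± 12, NIHSS ~6.6 ± 6.9).

    By default independent of the label; ``shift`` > 0 moves the class-1
    distributions upward so label-correlated strata can be exercised.
    """
    age = rng.normal(71.6 + shift * label, 12.0)
    nihss = max(0, round(abs(rng.normal(6.6 + shift * label, 6.9))))
    chads = int(np.clip(rng.binomial(9, 0.4 + (0.02 * shift if label else 0.0)), 0, 9))
    return {
        "sex": "M" if rng.random() < 0.5 else "F",
        "age": round(float(np.clip(age, 18, 100)), 1),
        "nihss": int(nihss),
        "chads_vasc": chads,
    }


def generate_cohort(params: PhantomParams, n_per_class: int, seed: int) -> list[Study]:
    """Generate a balanced cohort of 2*n_per_class studies.

    Per-study generators are spawned from a master ``SeedSequence`` so
    the cohort is a pure function of (params, n_per_class, seed).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_class)
    studies: list[Study] = []
    idx = 0
    for label in (0, 1):
        for _ in range(n_per_class):
            child = children[idx]
            rng = np.random.default_rng(child)
            study = generate_study(params, label, rng)
            study.study_id = f"S{idx:04d}"
            study.metadata = _sample_metadata(rng, label, params.metadata_label_shift)
            studies.append(study)
            idx += 1
    return studies


# -- NIfTI / manifest round trip ---------------------------------------

def write_cohort(studies: list[Study], outdir: str | Path) -> Path:
    """Write volume+mask NIfTI pairs and a cohort manifest CSV."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in studies:
        vpath = outdir / f"{s.study_id}_vol.nii.gz"
        mpath = outdir / f"{s.study_id}_mask.nii.gz"
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(np.moveaxis(s.volume, 0, -1), affine), vpath)
        nib.save(nib.Nifti1Image(s.mask.astype(np.uint8), affine), mpath)
        rows.append({"study_id": s.study_id, "volume_path": str(vpath),
                     "mask_path": str(mpath), "label": s.label, **s.metadata})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def params_to_dict(params: PhantomParams) -> dict:
    d = dataclasses.asdict(params)
    d["class_effect"] = {k: dataclasses.asdict(v) for k, v in params.class_effect.items()}
    return d
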