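"""Manifests, run configuration, NIfTI round-tripping, checkpoints.

The cohort manifest is a plain CSV (study_id, volume_path, mask_path,
label, metadata columns).  The run configuration is one declarative
object whose content hash — SHA-256 over the sorted-key JSON — stamps
every checkpoint, so ensembling across mismatched configurations is
refused.  Volumes are NIfTI; affines are preserved untouched (no
reorientation is performed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetConfig
from .phantoms import Study
from .radiomics import RadiomicsConfig
from .training import TrainConfig, TrainState

METADATA_COLUMNS = ("sex", "age", "nihss", "chads_vasc")


class ManifestError(ValueError):
    pass


class DuplicateIdError(ManifestError):
    pass


class MissingFileError(ManifestError):
    pass


class LabelDomainError(ManifestError):
    pass


class EnsembleIntegrityError(RuntimeError):
    """The set of fold checkpoints is incomplete or inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Every knob of a run; hashable, validated, serializable."""

    # architecture
    in_channels: int = 1
    channels: tuple[int, int, int] = (16, 32, 64)
    semantic_dim: int = 64
    fusion_hidden: int = 64
    input_shape: tuple[int, int, int] = (32, 64, 64)
    # radiomics
    n_levels: int = 32
    gldm_alpha: int = 0
    # training protocol
    epochs: int = 50
    stage1_epochs: int = 25
    batch_size: int = 8
    lr0: float = 1e-4
    lr_decay: float = 0.98
    k_folds: int = 5
    augment: bool = True
    # evaluation
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self):
        checks = [
            (self.epochs >= 2, "epochs >= 2"),
            (0 < self.stage1_epochs < self.epochs, "0 < stage1_epochs < epochs"),
            (self.batch_size >= 1, "batch_size >= 1"),
            (self.lr0 > 0, "lr0 > 0"),
            (0 < self.lr_decay <= 1, "0 < lr_decay <= 1"),
            (self.k_folds >= 2, "k_folds >= 2"),
            (self.n_levels >= 2, "n_levels >= 2"),
            (self.n_boot >= 1, "n_boot >= 1"),
            (all(s >= 8 for s in self.input_shape), "input dims >= 8"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid RunConfig: requires {msg}")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "RunConfig":
        """Reduced profile for single-CPU runs: small grid and network,
        8 epochs (6 feature-extraction + 2 classification) at lr0 1e-2 to
        compensate for the ~100x fewer optimizer steps than the full
        50-epoch regime."""
        return cls(channels=(4, 8, 16), input_shape=(16, 32, 32),
                   epochs=8, stage1_epochs=6, lr0=1e-2, n_boot=500, seed=seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def net_config(self, n_features: int) -> NetConfig:
        return NetConfig(in_channels=self.in_channels, channels=self.channels,
                         n_features=n_features, semantic_dim=self.semantic_dim,
                         fusion_hidden=self.fusion_hidden,
                         input_shape=self.input_shape)

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, stage1_epochs=self.stage1_epochs,
                           batch_size=self.batch_size, lr0=self.lr0,
                           lr_decay=self.lr_decay, k_folds=self.k_folds,
                           augment=self.augment, n_levels=self.n_levels)

    def radiomics_config(self) -> RadiomicsConfig:
        return RadiomicsConfig(n_levels=self.n_levels, gldm_alpha=self.gldm_alpha)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("channels", "input_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class CohortManifest:
    frame: pd.DataFrame
    path: Path | None = None

    def __len__(self) -> int:
        return len(self.frame)


def load_manifest(path) -> CohortManifest:
    """Load and validate a cohort manifest CSV; row order preserved."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"manifest not found: {path}")
    frame = pd.read_csv(path)
    required = {"study_id", "volume_path", "mask_path", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    dupes = frame["study_id"][frame["study_id"].duplicated()].tolist()
    if dupes:
        raise DuplicateIdError(f"duplicate study ids: {sorted(set(dupes))}")
    bad = frame.loc[~frame["label"].isin([0, 1]), "label"].tolist()
    if bad:
        raise LabelDomainError(f"labels outside {{0,1}}: {bad}")
    for col in ("volume_path", "mask_path"):
        for p in frame[col]:
            if not Path(p).exists():
                raise MissingFileError(f"{col} not found: {p}")
    return CohortManifest(frame=frame, path=path)


def load_studies(manifest: CohortManifest) -> list[Study]:
    """Materialize every manifest row as a Study (volumes channel-first)."""
    import nibabel as nib

    studies = []
    for _, row in manifest.frame.iterrows():
        vimg = nib.load(row["volume_path"])
        vol = np.asarray(vimg.dataobj, dtype=np.float64)
        if vol.ndim == 4:  # stored (z, y, x, C)
            vol = np.moveaxis(vol, -1, 0)
        mask = np.asarray(nib.load(row["mask_path"]).dataobj) > 0.5
        meta = {k: row[k] for k in METADATA_COLUMNS if k in row.index}
        studies.append(Study(volume=vol, mask=mask, label=int(row["label"]),
                             study_id=str(row["study_id"]), metadata=meta))
    return studies


def save_saliency(grid: np.ndarray, path) -> None:
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), np.eye(4)), path)


# -- checkpoints --------------------------------------------------------

def save_checkpoint(state: TrainState, path) -> None:
    arrays = {f"param/{k}": v for k, v in state.best_checkpoint.items()}
    arrays["std_mean"] = state.standardizer_mean
    arrays["std_sd"] = state.standardizer_sd
    arrays["val_loss_trace"] = np.asarray(state.val_loss_trace)
    arrays["best_val_trace"] = np.asarray(state.best_val_trace)
    meta = np.array([state.fold, state.epoch], dtype=np.int64)
    arrays["meta"] = meta
    arrays["best_val_loss"] = np.asarray(state.best_val_loss)
    np.savez(path, config_hash=np.array(state.config_hash), **arrays)


def load_checkpoint(path) -> TrainState:
    path = Path(path)
    if not path.exists():
        raise EnsembleIntegrityError(f"checkpoint missing: {path}")
    with np.load(path, allow_pickle=False) as data:
        params = {k[len("param/"):]: data[k] for k in data.files
                  if k.startswith("param/")}
        return TrainState(
            fold=int(data["meta"][0]), epoch=int(data["meta"][1]),
            best_val_loss=float(data["best_val_loss"]),
            best_checkpoint=params,
            val_loss_trace=list(data["val_loss_trace"]),
            best_val_trace=list(data["best_val_trace"]),
            standardizer_mean=data["std_mean"], standardizer_sd=data["std_sd"],
            config_hash=str(data["config_hash"]),
        )


def load_fold_checkpoints(rundir, k: int) -> list[TrainState]:
    rundir = Path(rundir)
    states = [load_checkpoint(rundir / f"fold{f}.npz") for f in range(k)]
    hashes = {s.config_hash for s in states}
    if len(hashes) > 1:
        raise EnsembleIntegrityError(f"config hashes differ: {sorted(hashes)}")
    return states


def dump_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"), indent=1)
        fh.write("\n")
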