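"""Training protocol: augmentation, fivefold CV, two stages, ensembling.

Stage 1 trains the segmentation U-Net, the attention-modulated CNN
stack and the CNN head under DiceLoss + L_cnn.  Stage 2 freezes those
extractors (their semantic vectors are cached), and trains the
radiomics self-attention, the radiomics head and the fusion MLP under
L_rad + L_com.  Each stage keeps the parameter snapshot with the
minimum validation loss seen during that stage; the fold's final model
is the best stage-1 extractor state combined with the best stage-2
head state.  Radiomics standardization statistics are fitted on the
training split of each fold only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor
from .nn.autodiff import concat, log_softmax, relu, softmax
from .network import FusionModel, NetConfig, dice_loss, lr_schedule, nll_from_log_probs
from .preprocessing import ModelInput, prepare_study
from .radiomics import FeatureStandardizer, RadiomicsConfig, feature_matrix

HEADS = ("radiomics", "cnn", "combined")


@dataclass(frozen=True)
class TrainConfig:
    """Protocol knobs; defaults follow the published regime."""

    epochs: int = 50
    stage1_epochs: int = 25   # remaining epochs belong to stage 2
    batch_size: int = 8
    lr0: float = 1e-4
    lr_decay: float = 0.98
    k_folds: int = 5
    augment: bool = True
    n_levels: int = 32

    def __post_init__(self):
        if not 0 < self.stage1_epochs < self.epochs:
            raise ValueError("need 0 < stage1_epochs < epochs")


@dataclass(frozen=True)
class FoldPlan:
    assignment: dict[str, int]
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]


@dataclass
class TrainState:
    fold: int
    epoch: int
    best_val_loss: float
    best_checkpoint: dict[str, np.ndarray]
    val_loss_trace: list[float]
    best_val_trace: list[float]  # running min within each stage
    standardizer_mean: np.ndarray | None = None
    standardizer_sd: np.ndarray | None = None
    config_hash: str = ""
    seeds: dict = field(default_factory=dict)


def augment(model_input: ModelInput, rng: np.random.Generator) -> ModelInput:
    """Random axis flips and in-plane 90° rotations, volume and mask alike.

    Every transform is a voxel permutation; the identity (no flip, k=0)
    occurs with positive probability.
    """
    vol = model_input.data
    mask = model_input.mask_lowres
    for axis in (1, 2, 3):  # spatial axes of the channel-first volume
        if rng.random() < 0.5:
            vol = np.flip(vol, axis=axis)
            mask = np.flip(mask, axis=axis - 1)
    k = int(rng.integers(0, 4))
    if k:
        vol = np.rot90(vol, k=k, axes=(2, 3))
        mask = np.rot90(mask, k=k, axes=(1, 2))
    return ModelInput(data=np.ascontiguousarray(vol),
                      mask_lowres=np.ascontiguousarray(mask))


def assign_folds(study_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = list(study_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} studies, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[int(p)]: i % k for i, p in enumerate(perm)}
    return FoldPlan(assignment=assignment, k=k, seed=seed)


def _batch_tensors(inputs: list[ModelInput], feats: np.ndarray, idx) -> tuple:
    x = np.stack([inputs[i].data for i in idx]).astype(np.float64)
    m = np.stack([inputs[i].mask_lowres for i in idx]).astype(np.float64)
    return x, m[:, None], feats[list(idx)]


def _stage2_heads(model: FusionModel, h: Tensor, z: Tensor):
    w, zw = model.attention(z)
    logp_rad = log_softmax(model.head_rad(zw), axis=-1)
    fused = relu(model.fusion_in(concat([h, zw], axis=1)))
    logp_com = log_softmax(model.head_com(fused), axis=-1)
    return logp_rad, logp_com, w


def _semantic_cache(model: FusionModel, inputs, idx, chunk: int = 8) -> np.ndarray:
    out = []
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        x = Tensor(np.stack([inputs[i].data for i in sel]).astype(np.float64))
        seg, pools = model.seg_forward(x)
        from .network import prior_attention
        h, _ = model.cls_forward(x, [prior_attention(p) for p in pools])
        out.append(h.data.copy())
    return np.concatenate(out, axis=0)


def train_fold(studies, plan: FoldPlan, fold: int,
               net_config: NetConfig, train_config: TrainConfig,
               seed: int = 0, raw_features: np.ndarray | None = None,
               config_hash: str = "") -> TrainState:
    """Train one CV fold through both stages; fully seeded."""
    if not 0 <= fold < plan.k:
        raise ValueError(f"fold must be in 0..{plan.k - 1}")
    val_ids = set(plan.fold_ids(fold))
    train_idx = [i for i, s in enumerate(studies) if s.study_id not in val_ids]
    val_idx = [i for i, s in enumerate(studies) if s.study_id in val_ids]
    if not train_idx:
        raise ValueError("empty training split")

    inputs = [prepare_study(s.volume, s.mask, net_config.input_shape)
              for s in studies]
    if raw_features is None:
        raw_features = feature_matrix(
            studies, RadiomicsConfig(n_levels=train_config.n_levels))
    std = FeatureStandardizer().fit(raw_features[train_idx])
    feats = std.transform(raw_features)
    labels = np.array([s.label for s in studies], dtype=int)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold,))
    init_ss, order_ss, aug_ss = ss.spawn(3)
    model = FusionModel(net_config, seed=int(init_ss.generate_state(1)[0] % (2 ** 31)))
    order_rng = np.random.default_rng(order_ss)
    aug_rng = np.random.default_rng(aug_ss)

    val_trace: list[float] = []
    best_trace: list[float] = []

    def val_loss_stage1() -> float:
        x, m, z = _batch_tensors(inputs, feats, val_idx)
        out = model.forward_graph(Tensor(x), Tensor(z))
        l_seg = float(dice_loss(out["seg"], Tensor(m)).data)
        l_cnn = float(nll_from_log_probs(out["logp_cnn"], labels[val_idx]).data)
        return l_seg + l_cnn

    # ---- stage 1: extractors + CNN head --------------------------------
    opt1 = Adam(model.stage1_parameters(), lr=train_config.lr0)
    best1, best1_state = np.inf, None
    s1_epochs = train_config.stage1_epochs
    for epoch in range(s1_epochs):
        opt1.lr = lr_schedule(epoch, train_config.lr0, train_config.lr_decay)
        perm = order_rng.permutation(len(train_idx))
        for start in range(0, len(perm), train_config.batch_size):
            sel = [train_idx[int(p)] for p in perm[start:start + train_config.batch_size]]
            batch_inputs = [augment(inputs[i], aug_rng) if train_config.augment
                            else inputs[i] for i in sel]
            x = np.stack([bi.data for bi in batch_inputs]).astype(np.float64)
            m = np.stack([bi.mask_lowres for bi in batch_inputs]).astype(np.float64)[:, None]
            out = model.forward_graph(Tensor(x), Tensor(feats[sel]))
            loss = dice_loss(out["seg"], Tensor(m)) \
                + nll_from_log_probs(out["logp_cnn"], labels[sel])
            opt1.zero_grad()
            loss.backward()
            opt1.step()
        vl = val_loss_stage1() if val_idx else float(loss.data)
        val_trace.append(vl)
        if vl < best1:
            best1, best1_state = vl, model.state_dict()
        best_trace.append(best1)
    if best1_state is not None:
        model.load_state_dict(best1_state)

    # ---- stage 2: attention + radiomics head + fusion MLP ---------------
    h_all = _semantic_cache(model, inputs, list(range(len(studies))))
    opt2 = Adam(model.stage2_parameters(), lr=train_config.lr0)
    best2, best2_state = np.inf, None

    def stage2_loss(idx) -> Tensor:
        logp_rad, logp_com, _ = _stage2_heads(
            model, Tensor(h_all[list(idx)]), Tensor(feats[list(idx)]))
        return nll_from_log_probs(logp_rad, labels[list(idx)]) \
            + nll_from_log_probs(logp_com, labels[list(idx)])

    for epoch in range(s1_epochs, train_config.epochs):
        opt2.lr = lr_schedule(epoch, train_config.lr0, train_config.lr_decay)
        perm = order_rng.permutation(len(train_idx))
        for start in range(0, len(perm), train_config.batch_size):
            sel = [train_idx[int(p)] for p in perm[start:start + train_config.batch_size]]
            loss = stage2_loss(sel)
            opt2.zero_grad()
            loss.backward()
            opt2.step()
        vl = float(stage2_loss(val_idx).data) if val_idx else float(loss.data)
        val_trace.append(vl)
        if vl < best2:
            best2, best2_state = vl, model.state_dict()
        best_trace.append(best2)
    if best2_state is not None:
        model.load_state_dict(best2_state)

    return TrainState(
        fold=fold, epoch=train_config.epochs,
        best_val_loss=float(best2),
        best_checkpoint=model.state_dict(),
        val_loss_trace=val_trace, best_val_trace=best_trace,
        standardizer_mean=std.mean_.copy(), standardizer_sd=std.sd_.copy(),
        config_hash=config_hash,
        seeds={"master": seed, "fold": fold},
    )


def predict_scores(model: FusionModel, inputs, feats: np.ndarray,
                   chunk: int = 8) -> dict[str, np.ndarray]:
    """Class-1 probabilities per head for a list of model inputs."""
    n = len(inputs)
    scores = {h: np.empty(n) for h in HEADS}
    for start in range(0, n, chunk):
        idx = list(range(start, min(start + chunk, n)))
        x = np.stack([inputs[i].data for i in idx]).astype(np.float64)
        seg, p_rad, p_cnn, p_com = model.forward(x, feats[idx])
        scores["radiomics"][idx] = p_rad[:, 1]
        scores["cnn"][idx] = p_cnn[:, 1]
        scores["combined"][idx] = p_com[:, 1]
    return scores


def state_scores(state: TrainState, studies, net_config: NetConfig,
                 raw_features: np.ndarray,
                 inputs=None) -> dict[str, np.ndarray]:
    """Scores of one fold's best model with its own fold-fitted scaler."""
    model = FusionModel(net_config, seed=0)
    model.load_state_dict(state.best_checkpoint)
    if inputs is None:
        inputs = [prepare_study(s.volume, s.mask, net_config.input_shape)
                  for s in studies]
    feats = (raw_features - state.standardizer_mean) / state.standardizer_sd
    return predict_scores(model, inputs, feats)


def ensemble_predict(states: list[TrainState], studies, net_config: NetConfig,
                     raw_features: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Average the per-head class-1 probabilities of the fold models."""
    hashes = {s.config_hash for s in states}
    if len(hashes) > 1:
        raise ValueError(f"checkpoint config hashes differ: {sorted(hashes)}")
    if raw_features is None:
        raw_features = feature_matrix(studies)
    inputs = [prepare_study(s.volume, s.mask, net_config.input_shape)
              for s in studies]
    acc = {h: np.zeros(len(studies)) for h in HEADS}
    for st in states:
        sc = state_scores(st, studies, net_config, raw_features, inputs)
        for h in HEADS:
            acc[h] += sc[h]
    return {h: acc[h] / len(states) for h in HEADS}


def run_crossval(studies, net_config: NetConfig, train_config: TrainConfig,
                 seed: int = 0, config_hash: str = ""):
    """Fivefold CV: per-fold training plus pooled out-of-fold scores.

    Returns (plan, states, oof_scores, labels); every study is scored
    by the one model whose training never saw it.
    """
    plan = assign_folds([s.study_id for s in studies],
                        k=train_config.k_folds, seed=seed)
    raw_features = feature_matrix(
        studies, RadiomicsConfig(n_levels=train_config.n_levels))
    inputs = [prepare_study(s.volume, s.mask, net_config.input_shape)
              for s in studies]
    labels = np.array([s.label for s in studies], dtype=int)
    oof = {h: np.full(len(studies), np.nan) for h in HEADS}
    states = []
    for fold in range(train_config.k_folds):
        st = train_fold(studies, plan, fold, net_config, train_config,
                        seed=seed, raw_features=raw_features,
                        config_hash=config_hash)
        states.append(st)
        val_idx = [i for i, s in enumerate(studies)
                   if plan.assignment[s.study_id] == fold]
        sc = state_scores(st, studies, net_config, raw_features, inputs)
        for h in HEADS:
            oof[h][val_idx] = sc[h][val_idx]
    return plan, states, oof, labels
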