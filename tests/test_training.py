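"""Training protocol: augmentation, folds, two stages, ensembling."""

import numpy as np
import pytest

from lesionfuse.network import FusionModel, NetConfig
from lesionfuse.preprocessing import ModelInput, prepare_study
from lesionfuse.radiomics import RadiomicsConfig, feature_matrix
from lesionfuse import training as tr

SMALL_NET = NetConfig(channels=(2, 3, 4), n_features=32, semantic_dim=8,
                      fusion_hidden=8, input_shape=(16, 32, 32))
SMOKE_TRAIN = tr.TrainConfig(epochs=2, stage1_epochs=1, batch_size=4,
                             lr0=1e-3, k_folds=5)


def _model_input(rng):
    vol = rng.random((1, 8, 8, 8))
    mask = rng.random((8, 8, 8)) < 0.2
    return ModelInput(data=vol, mask_lowres=mask)


class TestAugment:
    def test_identity_has_positive_probability(self, rng):
        mi = _model_input(rng)
        seen_identity = False
        for seed in range(64):
            out = tr.augment(mi, np.random.default_rng(seed))
            if np.array_equal(out.data, mi.data) and \
                    np.array_equal(out.mask_lowres, mi.mask_lowres):
                seen_identity = True
                break
        assert seen_identity

    def test_voxel_multiset_preserved(self, rng):
        mi = _model_input(rng)
        out = tr.augment(mi, np.random.default_rng(3))
        np.testing.assert_array_equal(np.sort(out.data.ravel()),
                                      np.sort(mi.data.ravel()))
        assert out.mask_lowres.sum() == mi.mask_lowres.sum()

    def test_volume_and_mask_transformed_together(self, rng):
        vol = np.zeros((1, 8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        vol[0, 1, 2, 3] = 7.0
        mask[1, 2, 3] = True
        out = tr.augment(ModelInput(data=vol, mask_lowres=mask),
                         np.random.default_rng(11))
        hot = np.unravel_index(out.data[0].argmax(), (8, 8, 8))
        assert out.mask_lowres[hot]

    def test_double_flip_is_identity(self, rng):
        mi = _model_input(rng)
        flipped = ModelInput(data=np.flip(mi.data, axis=3).copy(),
                             mask_lowres=np.flip(mi.mask_lowres, axis=2).copy())
        again = ModelInput(data=np.flip(flipped.data, axis=3).copy(),
                           mask_lowres=np.flip(flipped.mask_lowres, axis=2).copy())
        np.testing.assert_array_equal(again.data, mi.data)


class TestAssignFolds:
    def test_balanced_partition_510(self):
        ids = [f"P{i}" for i in range(510)]
        plan = tr.assign_folds(ids, k=5, seed=0)
        sizes = [len(plan.fold_ids(f)) for f in range(5)]
        assert sizes == [102] * 5
        assert sorted(sum((plan.fold_ids(f) for f in range(5)), [])) == sorted(ids)

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = tr.assign_folds([f"s{i}" for i in range(7)], k=5, seed=1)
        sizes = sorted(len(plan.fold_ids(f)) for f in range(5))
        assert sizes == [1, 1, 1, 2, 2]

    def test_seed_reproducibility(self):
        ids = [f"s{i}" for i in range(23)]
        assert tr.assign_folds(ids, 5, 7).assignment == \
            tr.assign_folds(ids, 5, 7).assignment

    def test_too_few_studies(self):
        with pytest.raises(ValueError):
            tr.assign_folds(["a", "b"], k=5, seed=0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            tr.assign_folds(["a", "a", "b", "c", "d"], k=2, seed=0)


@pytest.fixture(scope="module")
def smoke_run(small_cohort):
    """One 2-epoch fold training shared across protocol tests."""
    studies = small_cohort[:16]
    plan = tr.assign_folds([s.study_id for s in studies], k=5, seed=0)
    raw = feature_matrix(studies, RadiomicsConfig())
    state = tr.train_fold(studies, plan, 0, SMALL_NET, SMOKE_TRAIN, seed=0,
                          raw_features=raw, config_hash="smoke")
    return studies, plan, raw, state


class TestTrainFold:
    def test_returns_checkpoint_and_monotone_best_trace(self, smoke_run):
        _, _, _, state = smoke_run
        assert state.best_checkpoint
        assert len(state.val_loss_trace) == SMOKE_TRAIN.epochs
        # running best within each stage is non-increasing
        s1 = state.best_val_trace[:SMOKE_TRAIN.stage1_epochs]
        s2 = state.best_val_trace[SMOKE_TRAIN.stage1_epochs:]
        assert all(b <= a for a, b in zip(s1, s1[1:]))
        assert all(b <= a for a, b in zip(s2, s2[1:]))

    def test_deterministic_rerun(self, smoke_run):
        studies, plan, raw, state = smoke_run
        again = tr.train_fold(studies, plan, 0, SMALL_NET, SMOKE_TRAIN, seed=0,
                              raw_features=raw, config_hash="smoke")
        assert again.best_val_loss == state.best_val_loss
        for k, v in state.best_checkpoint.items():
            np.testing.assert_array_equal(v, again.best_checkpoint[k])

    def test_standardizer_excludes_validation_fold(self, smoke_run):
        """No-leakage: fold statistics must equal a recomputation from the
        training split only."""
        studies, plan, raw, state = smoke_run
        val_ids = set(plan.fold_ids(0))
        train_rows = np.array([raw[i] for i, s in enumerate(studies)
                               if s.study_id not in val_ids])
        np.testing.assert_allclose(state.standardizer_mean,
                                   train_rows.mean(axis=0), atol=1e-12)

    def test_invalid_fold_index(self, smoke_run):
        studies, plan, raw, _ = smoke_run
        with pytest.raises(ValueError):
            tr.train_fold(studies, plan, 9, SMALL_NET, SMOKE_TRAIN, seed=0,
                          raw_features=raw)


class TestEnsemble:
    def test_identical_checkpoints_equal_single_model(self, smoke_run):
        studies, _, raw, state = smoke_run
        one = tr.state_scores(state, studies, SMALL_NET, raw)
        five = tr.ensemble_predict([state] * 5, studies, SMALL_NET, raw)
        for h in tr.HEADS:
            np.testing.assert_allclose(five[h], one[h], atol=1e-12)

    def test_mean_of_probabilities(self):
        vals = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        assert np.mean(vals) == pytest.approx(0.6)

    def test_order_invariance(self, smoke_run, small_cohort):
        studies, plan, raw, state = smoke_run
        other = tr.train_fold(studies, plan, 1, SMALL_NET, SMOKE_TRAIN, seed=0,
                              raw_features=raw, config_hash="smoke")
        a = tr.ensemble_predict([state, other], studies, SMALL_NET, raw)
        b = tr.ensemble_predict([other, state], studies, SMALL_NET, raw)
        for h in tr.HEADS:
            np.testing.assert_allclose(a[h], b[h], atol=1e-12)

    def test_config_hash_mismatch_rejected(self, smoke_run):
        studies, _, raw, state = smoke_run
        import dataclasses
        bad = dataclasses.replace(state, config_hash="other")
        with pytest.raises(ValueError):
            tr.ensemble_predict([state, bad], studies, SMALL_NET, raw)

    def test_inference_has_no_augmentation(self, smoke_run):
        studies, _, raw, state = smoke_run
        a = tr.state_scores(state, studies, SMALL_NET, raw)
        b = tr.state_scores(state, studies, SMALL_NET, raw)
        for h in tr.HEADS:
            np.testing.assert_array_equal(a[h], b[h])


def test_overfit_one_batch_sanity(small_cohort):
    """A small fused model driven 200 steps on one batch of 4 phantoms
    reaches near-zero combined stage losses — the architecture and the
    optimizer can fit the signal."""
    from lesionfuse.nn import Adam, Tensor
    from lesionfuse.network import dice_loss, nll_from_log_probs
    from lesionfuse.radiomics import FeatureStandardizer

    studies = [small_cohort[i] for i in (0, 1, 10, 11)]  # 2 per class
    inputs = [prepare_study(s.volume, s.mask, (16, 32, 32)) for s in studies]
    raw = feature_matrix(studies)
    feats = FeatureStandardizer().fit(raw).transform(raw)
    labels = np.array([s.label for s in studies])
    x = np.stack([i.data for i in inputs])
    m = np.stack([i.mask_lowres for i in inputs]).astype(float)[:, None]
    net = NetConfig(channels=(4, 8, 16), input_shape=(16, 32, 32))
    model = FusionModel(net, seed=0)
    opt = Adam(model.stage1_parameters() + model.stage2_parameters(), lr=1e-2)
    total = np.inf
    for _ in range(200):
        out = model.forward_graph(Tensor(x), Tensor(feats))
        l_seg = dice_loss(out["seg"], Tensor(m))
        l_cnn = nll_from_log_probs(out["logp_cnn"], labels)
        l_rad = nll_from_log_probs(out["logp_rad"], labels)
        l_com = nll_from_log_probs(out["logp_com"], labels)
        loss = l_seg + l_cnn + l_rad + l_com
        opt.zero_grad()
        loss.backward()
        opt.step()
        total = float(loss.data)
        if total < 0.05:
            break
    assert total < 0.05
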