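"""Model/Results facade over the fusion pipeline.

``LesionFusionModel`` is built from a cohort of studies plus a
``RunConfig``; ``fit()`` runs the fivefold two-stage protocol and
returns a ``LesionFusionResults`` carrying pooled out-of-fold scores,
per-fold and pooled metric reports, the feature-significance ranking,
and saliency accessors — in the spirit of a statsmodels model/results
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, interpretability, training
from .evaluation import CrossValSummary, MetricsReport
from .io import RunConfig
from .network import FusionModel
from .phantoms import PhantomParams, Study, generate_cohort
from .preprocessing import prepare_study
from .radiomics import FEATURE_NAMES, feature_matrix
from .training import HEADS, FoldPlan, TrainState


class LesionFusionModel:
    """Segmentation-guided lesion classifier over a labelled cohort."""

    def __init__(self, studies: list[Study], config: RunConfig | None = None):
        if len(studies) < 2:
            raise ValueError("need at least two studies")
        self.studies = list(studies)
        self.config = config or RunConfig()
        self._raw_features: np.ndarray | None = None

    @classmethod
    def from_manifest(cls, path, config: RunConfig | None = None) -> "LesionFusionModel":
        from .io import load_manifest, load_studies
        return cls(load_studies(load_manifest(path)), config)

    @classmethod
    def from_phantoms(cls, params: PhantomParams, n_per_class: int, seed: int,
                      config: RunConfig | None = None) -> "LesionFusionModel":
        return cls(generate_cohort(params, n_per_class, seed), config)

    @property
    def raw_features(self) -> np.ndarray:
        if self._raw_features is None:
            self._raw_features = feature_matrix(
                self.studies, self.config.radiomics_config())
        return self._raw_features

    def fit(self, seed: int | None = None) -> "LesionFusionResults":
        """Fivefold cross-validated two-stage training."""
        seed = self.config.seed if seed is None else seed
        net_cfg = self.config.net_config(n_features=len(FEATURE_NAMES))
        plan, states, oof, labels = training.run_crossval(
            self.studies, net_cfg, self.config.train_config(), seed=seed,
            config_hash=self.config.content_hash())
        return LesionFusionResults(model=self, plan=plan, states=states,
                                   oof_scores=oof, labels=labels, seed=seed)


@dataclass
class LesionFusionResults:
    """Fitted cross-validation ensemble and its evaluation surface."""

    model: LesionFusionModel
    plan: FoldPlan
    states: list[TrainState]
    oof_scores: dict[str, np.ndarray]
    labels: np.ndarray
    seed: int
    _report_cache: dict = field(default_factory=dict)

    # -- metrics ---------------------------------------------------------
    def report(self, head: str = "combined") -> MetricsReport:
        """Pooled out-of-fold metrics for one classifier head."""
        if head not in self._report_cache:
            self._report_cache[head] = evaluation.evaluate_head(
                self.oof_scores[head], self.labels, head=head,
                n_boot=self.model.config.n_boot, seed=self.seed)
        return self._report_cache[head]

    def fold_reports(self, head: str = "combined") -> list[MetricsReport]:
        """Per-fold validation metrics (per-fold optimal cutoffs)."""
        reports = []
        for fold in range(self.plan.k):
            idx = [i for i, s in enumerate(self.model.studies)
                   if self.plan.assignment[s.study_id] == fold]
            scores = self.oof_scores[head][idx]
            labels = self.labels[idx]
            if len(np.unique(labels)) < 2:
                continue
            auc = evaluation.roc_auc(scores, labels)
            cut = evaluation.optimal_cutoff(scores, labels)
            reports.append(evaluation.confusion_metrics(
                scores, labels, cut, head=head, auc_value=auc))
        return reports

    def crossval_summary(self, head: str = "combined") -> CrossValSummary:
        return evaluation.crossval_summary(self.fold_reports(head))

    def subgroup_report(self, head: str = "combined", strata_spec=None):
        return evaluation.subgroup_report(
            self.oof_scores[head], self.labels,
            [s.metadata for s in self.model.studies],
            strata_spec=strata_spec, head=head, seed=self.seed)

    # -- ensemble on new data -------------------------------------------
    def ensemble_predict(self, studies: list[Study]) -> dict[str, np.ndarray]:
        net_cfg = self.model.config.net_config(len(FEATURE_NAMES))
        feats = feature_matrix(studies, self.model.config.radiomics_config())
        return training.ensemble_predict(self.states, studies, net_cfg, feats)

    # -- interpretability ------------------------------------------------
    def _fold_model(self, fold: int) -> FusionModel:
        net_cfg = self.model.config.net_config(len(FEATURE_NAMES))
        m = FusionModel(net_cfg, seed=0)
        m.load_state_dict(self.states[fold].best_checkpoint)
        return m

    def _oof_standardized(self, idx: int) -> tuple[FusionModel, np.ndarray]:
        fold = self.plan.assignment[self.model.studies[idx].study_id]
        st = self.states[fold]
        z = (self.model.raw_features[idx] - st.standardizer_mean) / st.standardizer_sd
        return self._fold_model(fold), z

    def grad_cam(self, study_index: int, target_class: int | None = None,
                 target_head: str = "cnn") -> interpretability.SaliencyMap:
        """Saliency for one study from the fold model that held it out."""
        study = self.model.studies[study_index]
        fold_model, z = self._oof_standardized(study_index)
        mi = prepare_study(study.volume, study.mask,
                           self.model.config.input_shape)
        if target_class is None:
            target_class = int(self.oof_scores["cnn"][study_index] >= 0.5)
        return interpretability.grad_cam(fold_model, mi, z,
                                         target_class=target_class,
                                         target_head=target_head)

    def fsr(self, top_k: int = 8, use_true_labels: bool = False
            ) -> interpretability.FSRRanking:
        """Feature-significance ranking from held-out attention weights."""
        n = len(self.model.studies)
        rows = np.empty((n, len(FEATURE_NAMES)))
        for fold in range(self.plan.k):
            idx = [i for i, s in enumerate(self.model.studies)
                   if self.plan.assignment[s.study_id] == fold]
            st = self.states[fold]
            feats = (self.model.raw_features[idx] - st.standardizer_mean) \
                / st.standardizer_sd
            rows[idx] = interpretability.attention_weight_rows(
                self._fold_model(fold), feats)
        preds = (self.labels if use_true_labels
                 else (self.oof_scores["combined"] >= 0.5).astype(int))
        return interpretability.fsr_ranking(rows, preds, top_k=top_k)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Text table of pooled out-of-fold performance per head."""
        lines = [
            "Lesion fusion classifier — fivefold cross-validation".center(72),
            "=" * 72,
            f"studies: {len(self.model.studies)}   "
            f"pos: {int(self.labels.sum())}   neg: {int((1 - self.labels).sum())}   "
            f"folds: {self.plan.k}   seed: {self.seed}",
            f"config hash: {self.model.config.content_hash()}",
            "-" * 72,
            f"{'head':<10}{'AUC':>7}{'95% CI':>17}{'sens%':>8}{'spec%':>8}"
            f"{'acc%':>8}{'PPV%':>7}{'NPV%':>7}",
        ]
        for head in HEADS:
            r = self.report(head)
            fmt = lambda v: "  n/a" if v is None else f"{v:5.1f}"
            ci = f"[{r.auc_ci[0]:.2f}, {r.auc_ci[1]:.2f}]"
            lines.append(
                f"{head:<10}{r.auc:>7.3f}{ci:>17}{fmt(r.sensitivity):>8}"
                f"{fmt(r.specificity):>8}{fmt(r.accuracy):>8}"
                f"{fmt(r.ppv):>7}{fmt(r.npv):>7}")
        lines.append("-" * 72)
        lines.append("fold mean ± SD (per-fold cutoffs):")
        for head in HEADS:
            try:
                cs = self.crossval_summary(head)
            except ValueError:
                continue
            lines.append(
                f"{head:<10}AUC {cs.mean.get('auc', float('nan')):.3f} ± "
                f"{cs.sd.get('auc', float('nan')):.3f}   "
                f"acc {cs.mean.get('accuracy', float('nan')):5.1f} ± "
                f"{cs.sd.get('accuracy', float('nan')):4.1f}")
        lines.append("=" * 72)
        return "\n".join(lines)
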