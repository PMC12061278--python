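"""High-level modelling interface.

`BridgedSurvivalModel` holds an aligned cohort (patch bags, omics table,
clinical outcomes) plus a configuration; `fit()` runs seeded k-fold
cross-validation — leak-free per-fold standardization and time
discretization, network training, out-of-fold risk prediction — and
returns a `BridgedSurvivalResults` carrying per-fold concordance, the
aggregated estimate with its confidence interval, the trained fold
networks, and accessors for stratification, alignment and attribution
analyses. `summary()` prints the usual fitted-model table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .encoders import OmicsEmbedding, SlideEmbedding, minmax_normalize
from .io import (FoldSplit, PatchBag, SurvivalLabel, discretize_times,
                 filter_missing_features, make_folds, read_bags,
                 read_clinical, read_informative_masks, read_omics,
                 standardize_features)
from .model import BridgeNet, TrainedBridge, predict, train_model
from .survival_eval import (aggregate_cv, concordance_index, km_and_logrank,
                            median_stratify)

__all__ = ["BridgedSurvivalModel", "BridgedSurvivalResults"]


def _fold_seed(seed: int, fold_id: int, salt: int) -> int:
    return int((seed * 100003 + fold_id * 1009 + salt) % (2**31 - 1))


class BridgedSurvivalModel:
    """Multimodal discrete-time survival model over a paired cohort."""

    def __init__(self, bags: list[PatchBag], omics: pd.DataFrame,
                 clinical: pd.DataFrame, config: RunConfig | None = None,
                 modality: str = "multimodal",
                 informative_masks: dict[str, np.ndarray] | None = None):
        self.config = config or RunConfig()
        self.modality = modality
        self.bags = {b.patient_id: b for b in bags}
        clinical = clinical.copy()
        clinical["patient_id"] = clinical["patient_id"].astype(str)
        ids = sorted(self.bags)
        if sorted(clinical["patient_id"]) != ids:
            raise ValueError("clinical table and bags disagree on patients")
        if sorted(omics.index.astype(str)) != ids:
            raise ValueError("omics table and bags disagree on patients")
        self.patient_ids = ids
        self.omics = omics.loc[ids]
        self.clinical = clinical.set_index("patient_id").loc[ids].reset_index()
        self.informative_masks = informative_masks or {}
        # feature columns with any missing value are unusable for the model
        self.omics, self.dropped_features = filter_missing_features(self.omics)

    # ------------------------------------------------------- constructors
    @classmethod
    def from_directory(cls, path: str | Path,
                       config: RunConfig | None = None,
                       modality: str = "multimodal"
                       ) -> "BridgedSurvivalModel":
        path = Path(path)
        bags = read_bags(path / "bags.h5")
        omics = read_omics(path / "omics.tsv")
        clinical = read_clinical(path / "clinical.csv")
        masks = read_informative_masks(path / "bags.h5")
        return cls(bags, omics, clinical, config, modality, masks)

    @classmethod
    def from_synthetic(cls, cohort, config: RunConfig | None = None,
                       modality: str = "multimodal") -> "BridgedSurvivalModel":
        bags = [PatchBag(pid, f, c) for pid, f, c in
                zip(cohort.patient_ids, cohort.bag_features, cohort.bag_coords)]
        masks = dict(zip(cohort.patient_ids, cohort.informative_masks))
        return cls(bags, cohort.omics, cohort.clinical, config, modality,
                   masks)

    # --------------------------------------------------------------- fit
    def fit(self, seed: int = 0, n_folds: int | None = None,
            folds: list[FoldSplit] | None = None,
            progress: bool = False) -> "BridgedSurvivalResults":
        cfg = self.config
        n_folds = n_folds or cfg.n_folds
        if folds is None:
            folds = make_folds(self.patient_ids, n_folds, seed)
        labels = {row.patient_id: SurvivalLabel(row.patient_id,
                                                float(row.time),
                                                int(row.event))
                  for row in self.clinical.itertuples()}
        fold_models: list[TrainedBridge] = []
        rows = []
        for fold in folds:
            trained = self._fit_fold(fold, labels, seed)
            fold_models.append(trained)
            for pid in fold.test_ids:
                out = self._predict_patient(trained, pid)
                rows.append({"patient_id": pid, "fold": fold.fold_id,
                             "risk": out.risk,
                             "time": labels[pid].time,
                             "event": labels[pid].event})
            if progress:
                print(f"fold {fold.fold_id}: trained "
                      f"({len(fold.train_ids)} train / "
                      f"{len(fold.test_ids)} test)")
        preds = pd.DataFrame(rows)
        return BridgedSurvivalResults(self, folds, fold_models, preds, seed)

    def _fit_fold(self, fold: FoldSplit, labels: dict[str, SurvivalLabel],
                  seed: int) -> TrainedBridge:
        cfg = self.config
        train_labels = [labels[p] for p in fold.train_ids]
        edges = discretize_times(train_labels, cfg.train.n_bins)
        train_om = self.omics.loc[fold.train_ids]
        train_t, all_t, mean, sd, _ = standardize_features(
            train_om, self.omics)
        init_seed = _fold_seed(seed, fold.fold_id, 1)
        net = BridgeNet(cfg, self.omics.shape[1],
                      np.random.default_rng(init_seed), self.modality)
        bags = {p: self.bags[p].features for p in fold.train_ids}
        omics = {p: all_t.loc[p].to_numpy(dtype=float)
                 for p in fold.train_ids}
        bins = {p: labels[p].bin for p in fold.train_ids}
        events = {p: labels[p].event for p in fold.train_ids}
        log = train_model(net, bags, omics, bins, events, fold.train_ids,
                          cfg, _fold_seed(seed, fold.fold_id, 2))
        return TrainedBridge(net, cfg, fold.fold_id, log,
                           list(self.omics.columns), mean, sd, edges,
                           init_seed)

    # -------------------------------------------------------- prediction
    def standardized_omics(self, trained: TrainedBridge, pid: str) -> np.ndarray:
        raw = self.omics.loc[pid].to_numpy(dtype=float)
        return (raw - trained.feature_mean) / trained.feature_sd

    def _predict_patient(self, trained: TrainedBridge, pid: str,
                         missing_omics: bool = False):
        bag = self.bags[pid] if self.modality != "omics_only" else None
        om = None
        if self.modality != "wsi_only" and not missing_omics:
            om = self.standardized_omics(trained, pid)
        return predict(trained, bag, om, missing_omics=missing_omics)


@dataclass
class BridgedSurvivalResults:
    """Cross-validated fit: predictions, concordance, fold networks."""

    model: BridgedSurvivalModel
    folds: list[FoldSplit]
    fold_models: list[TrainedBridge]
    predictions: pd.DataFrame   # patient_id, fold, risk, time, event
    seed: int
    _fold_c: list | None = field(default=None, repr=False)

    # ------------------------------------------------------- concordance
    def fold_concordances(self) -> list[float]:
        if self._fold_c is None:
            cs = []
            for fold in self.folds:
                sub = self.predictions[self.predictions["fold"]
                                       == fold.fold_id]
                cs.append(concordance_index(sub["time"], sub["event"],
                                            sub["risk"]).c_index)
            self._fold_c = cs
        return self._fold_c

    def cindex_summary(self) -> dict:
        return aggregate_cv(self.fold_concordances())

    # ----------------------------------------------------- stratification
    def km_stratification(self):
        """Pooled out-of-fold risks, median split, KM + log-rank + HR."""
        groups = median_stratify(self.predictions["risk"].to_numpy())
        return km_and_logrank(self.predictions["time"].to_numpy(),
                              self.predictions["event"].to_numpy(), groups)

    # -------------------------------------------------------- embeddings
    def embeddings(self, fold_id: int = 0, which: str = "test"
                   ) -> tuple[list[SlideEmbedding], list[OmicsEmbedding]]:
        """Slide and omics embeddings from one fold's trained network."""
        trained = self.fold_models[fold_id]
        fold = self.folds[fold_id]
        pids = fold.test_ids if which == "test" else fold.train_ids
        model = self.model
        slides, omics = [], []
        net = trained.net
        net.eval()
        for pid in pids:
            if model.modality != "omics_only":
                emb, raw = net.embed_slide(model.bags[pid].features)
                slides.append(SlideEmbedding(pid, emb.data.copy(),
                                             minmax_normalize(raw)))
            if model.modality != "wsi_only":
                vec = net.embed_omics(
                    model.standardized_omics(trained, pid))
                omics.append(OmicsEmbedding(pid, vec.data.copy()))
        return slides, omics

    def predict_risks(self, missing_omics: bool = False) -> pd.DataFrame:
        """Out-of-fold risks, optionally through the pseudo-omics path."""
        rows = []
        for fold, trained in zip(self.folds, self.fold_models):
            for pid in fold.test_ids:
                out = self.model._predict_patient(trained, pid,
                                                  missing_omics)
                rows.append({"patient_id": pid, "fold": fold.fold_id,
                             "risk": out.risk,
                             "missing_omics": missing_omics})
        return pd.DataFrame(rows)

    # ------------------------------------------------------------ output
    def summary(self) -> str:
        agg = self.cindex_summary()
        strat = None
        try:
            strat = self.km_stratification()
        except ValueError:
            pass
        cfg = self.model.config
        lines = [
            "Bridged multimodal survival model — cross-validated fit",
            "=" * 56,
            f"modality:        {self.model.modality}",
            f"bridge mode:     {cfg.bridge.mode} (lambda={cfg.bridge.lam})",
            f"patients:        {len(self.model.patient_ids)}"
            f"   folds: {len(self.folds)}   seed: {self.seed}",
            f"omics features:  {self.model.omics.shape[1]}"
            f"   time bins: {cfg.train.n_bins}",
            f"config hash:     {config_hash(cfg)}",
            "-" * 56,
            "fold C-indices:  " + "  ".join(
                f"{c:.3f}" for c in self.fold_concordances()),
            f"mean C-index:    {agg['mean']:.3f}"
            + (f"   95% CI ({agg['ci_low']:.3f}, {agg['ci_high']:.3f})"
               if agg["ci_low"] is not None else ""),
        ]
        if strat is not None:
            hr = ("n/a" if strat.hazard_ratio is None else
                  f"{strat.hazard_ratio:.2f} "
                  f"({strat.hr_ci[0]:.2f}-{strat.hr_ci[1]:.2f})")
            lines += [
                f"log-rank chi2:   {strat.logrank_chi2:.2f}"
                f"   p = {strat.logrank_p:.2e}",
                f"hazard ratio:    {hr}  (high vs low, median split)",
            ]
        lines.append("=" * 56)
        return "\n".join(lines)
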