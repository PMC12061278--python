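"""Cohort input/output and leak-free preprocessing.

Readers for the three on-disk streams (HDF5 patch bags, TSV omics table,
CSV clinical table), the feature-filtering and standardization rules,
event-quantile discretization of survival times, and cross-validation fold
construction. All statistics used to transform test patients are computed
from training patients only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["PatchBag", "SurvivalLabel", "FoldSplit",
           "read_bags", "read_omics", "read_clinical",
           "filter_missing_features", "standardize_features",
           "discretize_times", "assign_bins", "make_folds"]


@dataclass
class PatchBag:
    """One slide's bag of patch feature vectors with grid coordinates."""
    patient_id: str
    features: np.ndarray   # (N, D) float
    coords: np.ndarray     # (N, 2) int, patch-grid units

    def validate(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(f"bag {self.patient_id}: empty or misshaped")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"bag {self.patient_id}: non-finite features")
        if len(self.coords) != len(self.features):
            raise ValueError(f"bag {self.patient_id}: coords length mismatch")
        uniq = {tuple(xy) for xy in self.coords.tolist()}
        if len(uniq) != len(self.coords):
            raise ValueError(f"bag {self.patient_id}: duplicate coordinates")


@dataclass
class SurvivalLabel:
    patient_id: str
    time: float
    event: int
    bin: int | None = None   # set by discretize_times / assign_bins

    def validate(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.patient_id}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]


# ---------------------------------------------------------------- readers

def read_bags(path: str | Path) -> list[PatchBag]:
    """Read all patch bags from an HDF5 container, sorted by patient id."""
    bags: list[PatchBag] = []
    with h5py.File(path, "r") as fh:
        for pid in sorted(fh.keys()):
            grp = fh[pid]
            bag = PatchBag(pid, np.asarray(grp["features"], dtype=np.float64),
                           np.asarray(grp["coords"], dtype=np.int64))
            bag.validate()
            bags.append(bag)
    if not bags:
        raise ValueError("no bags found")
    return bags


def read_informative_masks(path: str | Path) -> dict[str, np.ndarray]:
    """Optional ground-truth patch labels written by the synthetic generator."""
    masks: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for pid in sorted(fh.keys()):
            if "informative" in fh[pid]:
                masks[pid] = np.asarray(fh[pid]["informative"]).astype(bool)
    return masks


def read_omics(path: str | Path) -> pd.DataFrame:
    """Patients x features TSV; first column patient id, header = names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated patient ids in omics table: {dupes}")
    if df.columns.duplicated().any():
        raise ValueError("duplicated feature names in omics table")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicated patient ids in clinical table")
    for _, row in df.iterrows():
        SurvivalLabel(row["patient_id"], float(row["time"]),
                      int(row["event"])).validate()
    return df


# --------------------------------------------------------- transformations

def filter_missing_features(table: pd.DataFrame
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Drop every feature column containing at least one missing value."""
    missing = table.columns[table.isna().any(axis=0)]
    kept = table.drop(columns=missing)
    if kept.shape[1] == 0:
        raise ValueError("all features contain missing values")
    return kept, list(missing)


def standardize_features(train: pd.DataFrame,
                         apply_to: pd.DataFrame | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame | None,
                                    np.ndarray, np.ndarray, list[str]]:
    """Per-feature z-score with statistics from the training rows only.

    Population standard deviation (ddof=0). Zero-variance features keep
    sd=1 and are returned in the flagged list rather than producing NaN.
    """
    if len(train) < 2:
        raise ValueError("standardization needs >= 2 training rows")
    mean = train.to_numpy(dtype=float).mean(axis=0)
    sd = train.to_numpy(dtype=float).std(axis=0, ddof=0)
    flagged = [c for c, s in zip(train.columns, sd) if s == 0.0]
    sd = np.where(sd == 0.0, 1.0, sd)
    train_t = (train - mean) / sd
    apply_t = None if apply_to is None else (apply_to - mean) / sd
    return train_t, apply_t, mean, sd, flagged


def discretize_times(labels: list[SurvivalLabel], n_bins: int = 4
                     ) -> np.ndarray:
    """Bin edges at uncensored-event quantiles of the training labels.

    Edges are the {1/n_bins, ..., (n_bins-1)/n_bins} quantiles (linear
    interpolation, the type-7 rule) of event times; bins are right-closed
    and the last bin is open-ended. Labels are assigned in place.
    """
    event_times = np.array([l.time for l in labels if l.event == 1])
    if len(event_times) < n_bins:
        raise ValueError(
            f"only {len(event_times)} uncensored events; "
            f"use a smaller n_bins than {n_bins}")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(event_times, qs)  # default 'linear' = type 7
    assign_bins(labels, edges)
    return edges


def assign_bins(labels: list[SurvivalLabel], edges: np.ndarray) -> None:
    for l in labels:
        l.bin = int(np.searchsorted(edges, l.time, side="left"))


def make_folds(ids: list[str], n_folds: int = 5, seed: int = 0,
               stratify_events: dict[str, int] | None = None
               ) -> list[FoldSplit]:
    """Random near-equal test blocks from a seeded permutation.

    With `stratify_events` (patient id -> event indicator), the permutation
    is done within event strata so each fold sees a similar event rate;
    off by default.
    """
    ids = list(ids)
    if len(ids) < n_folds:
        raise ValueError("need at least n_folds patients")
    rng = np.random.default_rng(seed)
    if stratify_events is None:
        order = [ids[i] for i in rng.permutation(len(ids))]
    else:
        order = []
        for stratum in (1, 0):
            sub = [p for p in ids if stratify_events[p] == stratum]
            order.extend(sub[i] for i in rng.permutation(len(sub)))
        # interleave strata across folds
        order = [order[i::n_folds] for i in range(n_folds)]
        order = [p for block in order for p in block]
    blocks = np.array_split(np.array(order, dtype=object), n_folds)
    folds = []
    for k, block in enumerate(blocks):
        test = [str(p) for p in block]
        test_set = set(test)
        train = [p for p in ids if p not in test_set]
        folds.append(FoldSplit(k, train, test))
    return folds
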