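"""Synthetic paired cohort generator.

Emulates the data layout of a multimodal pathology-genomics survival study:
for each patient, a bag of patch feature vectors (as produced by a frozen
patch encoder on 256x256 whole-slide-image tiles), an omics profile with
expression / copy-number / mutation blocks, and right-censored survival.

A shared latent vector z_shared drives (a) the mean of a planted fraction
of "informative" patches, (b) part of the omics features, and (c) the
hazard through a linear predictor eta = beta . z_shared under a
proportional-hazards exponential event model. Private latents add
modality-specific structure with no effect on survival. This gives every
downstream stage a ground truth: true risk per patient, and per-patch
informativeness labels for attention checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["LatentSpec", "CohortSpec", "SyntheticCohort",
           "generate_cohort", "simulate_survival", "write_cohort"]


def _default_beta() -> np.ndarray:
    return np.full(8, 0.35)


@dataclass
class LatentSpec:
    """Shared/private latent structure and its effect on hazard.

    The hazard loads on all `d_shared` shared components, but each
    modality expresses only a leading (bags) or trailing (omics) fraction
    of them — `wsi_shared_frac` and `omics_shared_frac`. With the default
    0.75 the two modalities overlap on half the components and each holds
    a quarter privately, so neither alone can recover the full risk: the
    regime in which multimodal fusion has something to gain.
    `omics_noise_sd` defaults to `noise_sd`; set it to 0 (with
    d_omics_private=0 and omics_shared_frac=1) to make the omics signal a
    deterministic function of the slide latent.
    """
    d_shared: int = 8
    d_wsi_private: int = 4
    d_omics_private: int = 4
    beta: np.ndarray = field(default_factory=_default_beta)
    informative_fraction: float = 0.3
    noise_sd: float = 1.0
    wsi_shared_frac: float = 0.75
    omics_shared_frac: float = 0.75
    omics_noise_sd: float | None = None

    def validate(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.d_shared < 1:
            raise ValueError("d_shared must be >= 1")
        if len(self.beta) != self.d_shared:
            raise ValueError("beta length must equal d_shared")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("wsi_shared_frac", "omics_shared_frac"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def wsi_shared_idx(self) -> np.ndarray:
        n = max(1, int(round(self.wsi_shared_frac * self.d_shared)))
        return np.arange(0, n)

    @property
    def omics_shared_idx(self) -> np.ndarray:
        n = max(1, int(round(self.omics_shared_frac * self.d_shared)))
        return np.arange(self.d_shared - n, self.d_shared)


@dataclass
class CohortSpec:
    """Cohort size and observation layout."""
    n_patients: int = 600
    patch_dim: int = 1024
    n_omics_features: int = 300
    bag_size_range: tuple[int, int] = (16, 64)
    target_censoring_rate: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.patch_dim < 8:
            raise ValueError("patch_dim must be >= 8")
        if self.bag_size_range[0] < 4:
            raise ValueError("bag_size_range min must be >= 4")
        if self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("bag_size_range must be (min, max) with min <= max")
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if not (0.0 <= self.target_censoring_rate < 1.0):
            raise ValueError("target_censoring_rate must be in [0, 1)")
        if self.n_omics_features < 10:
            raise ValueError("n_omics_features must be >= 10")


@dataclass
class SyntheticCohort:
    patient_ids: list[str]
    bag_features: list[np.ndarray]      # each (N_i, patch_dim)
    bag_coords: list[np.ndarray]        # each (N_i, 2) int
    informative_masks: list[np.ndarray]  # each (N_i,) bool, planted signal
    omics: pd.DataFrame                 # patients x features
    omics_blocks: np.ndarray            # per-feature block label
    times: np.ndarray
    events: np.ndarray
    eta: np.ndarray                     # true linear predictor
    z_shared: np.ndarray                # (n, d_shared)
    spec: CohortSpec
    latent: LatentSpec

    @property
    def clinical(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_ids,
                             "time": self.times, "event": self.events})


BASELINE_HAZARD = 0.1


def _censoring_rate_for(c: float, rates: np.ndarray) -> float:
    # P(C < T) for independent exponentials with rates c and rates[i]
    return float(np.mean(c / (c + rates)))


def simulate_survival(eta: np.ndarray, target_censoring_rate: float,
                      seed: int, baseline_hazard: float = BASELINE_HAZARD
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times with calibrated
    independent exponential censoring.

    The censoring rate c solves mean_i[c / (c + h0 e^{eta_i})] = target,
    the exact marginal censoring probability of the exponential mixture,
    found by 1-d root bracketing (no rejection sampling).
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if target_censoring_rate >= 1.0 or target_censoring_rate < 0.0:
        raise ValueError("target_censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0 / rates)
    if target_censoring_rate == 0.0:
        return T, np.ones(len(T), dtype=int)
    lo, hi = 1e-12, 1e12
    c = brentq(lambda x: _censoring_rate_for(x, rates) - target_censoring_rate,
               lo, hi)
    C = rng.exponential(1.0 / c, size=len(T))
    times = np.minimum(T, C)
    events = (T <= C).astype(int)
    return times, events


def _unique_coords(rng: np.random.Generator, n: int) -> np.ndarray:
    """Distinct patch-grid coordinates on a square grid of ~2n cells."""
    side = int(np.ceil(np.sqrt(2 * n)))
    flat = rng.choice(side * side, size=n, replace=False)
    return np.column_stack([flat % side, flat // side]).astype(np.int64)


def generate_cohort(spec: CohortSpec | None = None,
                    latent: LatentSpec | None = None) -> SyntheticCohort:
    """Draw a full paired cohort. Same (spec, latent) => identical output."""
    spec = spec or CohortSpec()
    latent = latent or LatentSpec()
    spec.validate()
    latent.validate()

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ds, dwp, dop = latent.d_shared, latent.d_wsi_private, latent.d_omics_private

    z_shared = rng.standard_normal((n, ds))
    z_wsi = rng.standard_normal((n, dwp))
    z_om = rng.standard_normal((n, dop))

    wi = latent.wsi_shared_idx
    oi = latent.omics_shared_idx
    # mixing matrices scaled by 1/sqrt(d) so per-feature variance stays O(1)
    dA = len(wi) + dwp
    dB = len(oi) + dop
    A = rng.standard_normal((dA, spec.patch_dim)) / np.sqrt(dA)
    B = rng.standard_normal((dB, spec.n_omics_features)) / np.sqrt(dB)

    patch_mean = np.hstack([z_shared[:, wi], z_wsi]) @ A      # (n, patch_dim)
    omics_latent = np.hstack([z_shared[:, oi], z_om]) @ B      # (n, F)

    ids = [f"P{i:04d}" for i in range(n)]
    lo, hi = spec.bag_size_range
    bag_sizes = rng.integers(lo, hi + 1, size=n)

    bags, coords, masks = [], [], []
    for i in range(n):
        N = int(bag_sizes[i])
        n_info = max(1, int(round(latent.informative_fraction * N)))
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=n_info, replace=False)] = True
        feats = rng.normal(0.0, latent.noise_sd, size=(N, spec.patch_dim))
        feats[mask] += patch_mean[i]
        bags.append(feats)
        coords.append(_unique_coords(rng, N))
        masks.append(mask)

    # omics blocks: expression stays continuous, CNV is clip-rounded to
    # {-2..2}, mutation thresholds the latent at its 85th percentile
    F = spec.n_omics_features
    n_expr = int(round(0.65 * F))
    n_cnv = int(round(0.2 * F))
    n_mut = F - n_expr - n_cnv
    blocks = np.array(["expr"] * n_expr + ["cnv"] * n_cnv + ["mut"] * n_mut)
    om_sd = (latent.noise_sd if latent.omics_noise_sd is None
             else latent.omics_noise_sd)
    G = omics_latent + rng.normal(0.0, om_sd, size=(n, F))
    X = G.copy()
    cnv_sl = slice(n_expr, n_expr + n_cnv)
    mut_sl = slice(n_expr + n_cnv, F)
    X[:, cnv_sl] = np.clip(np.round(G[:, cnv_sl]), -2, 2)
    thresh = np.percentile(G[:, mut_sl], 85.0, axis=0)
    X[:, mut_sl] = (G[:, mut_sl] > thresh).astype(float)

    names = [f"{b}_{j:04d}" for j, b in enumerate(blocks)]
    omics = pd.DataFrame(X, index=ids, columns=names)
    omics.index.name = "patient_id"

    eta = z_shared @ latent.beta
    surv_seed = int(rng.integers(0, 2**31 - 1))
    times, events = simulate_survival(eta, spec.target_censoring_rate,
                                      surv_seed)

    return SyntheticCohort(ids, bags, coords, masks, omics, blocks,
                           times, events, eta, z_shared, spec, latent)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 include_truth: bool = True) -> Path:
    """Write the on-disk layout: bags.h5, omics.tsv, clinical.csv
    (+ truth.csv with the true linear predictor when requested)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "bags.h5", "w") as fh:
        for pid, feats, xy, mask in zip(cohort.patient_ids,
                                        cohort.bag_features,
                                        cohort.bag_coords,
                                        cohort.informative_masks):
            grp = fh.create_group(pid)
            # track_times off so identical cohorts are byte-identical files
            grp.create_dataset("features", data=feats, track_times=False)
            grp.create_dataset("coords", data=xy, track_times=False)
            if include_truth:
                grp.create_dataset("informative", data=mask.astype(np.int8),
                                   track_times=False)
    cohort.omics.to_csv(outdir / "omics.tsv", sep="\t")
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    if include_truth:
        pd.DataFrame({"patient_id": cohort.patient_ids, "eta": cohort.eta}
                     ).to_csv(outdir / "truth.csv", index=False)
    return outdir
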