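"""Bridged multimodal survival network: fusion, bridge, discrete-time head.

The network couples the two unimodal encoders through a bi-directional
bridge (an MLP from each embedding space into the other) and predicts a
discrete-time hazard from the concatenated embeddings. The bridge serves
two purposes: a training-time alignment loss that pulls the two embedding
spaces together, and an inference-time generator of pseudo-omics
embeddings when molecular data are missing.

Training minimizes

    L = L_surv + lambda * ( ||f_wo(h_w) - sg(h_o)||^2 / d_o
                          + ||f_ow(h_o) - sg(h_w)||^2 / d_w )

where L_surv is the censoring-aware discrete-time negative log-likelihood,
sg is stop-gradient (targets are detached so the survival task cannot
collapse both spaces onto a constant), and the residuals are normalized
per dimension so lambda is comparable when d_w != d_o. The
single-directional ablation keeps only the slide-to-omics term; the
non-bridge ablation sets lambda = 0 (plain late concatenation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .encoders import SNNEncoder, build_wsi_encoder
from .io import PatchBag
from .nn import Adam, Linear, Module, Tensor, concat

__all__ = ["SurvivalOutput", "BridgeNet", "TrainedBridge",
           "survival_nll", "bridge_loss", "total_loss", "train_model",
           "predict"]

MODALITY_CHOICES = ("multimodal", "wsi_only", "omics_only")
BRIDGE_MODES = ("bridge", "single_directional", "non_bridge")
_HCLIP = 1e-7


@dataclass
class SurvivalOutput:
    """Discrete-time survival prediction for one patient.

    hazards h_j = sigmoid(logit_j); survival S(j) = prod_{k<=j} (1 - h_k);
    risk = -sum_j S(j), so higher risk means shorter expected survival.
    """
    logits: np.ndarray
    hazards: np.ndarray
    survival: np.ndarray
    risk: float

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "SurvivalOutput":
        logits = np.asarray(logits, dtype=float)
        hazards = 1.0 / (1.0 + np.exp(-logits))
        survival = np.cumprod(1.0 - hazards)
        return cls(logits, hazards, survival, float(-survival.sum()))


class MLP2(Module):
    """Two-layer SELU MLP used for the bridge maps and the fusion head."""

    def __init__(self, d_in: int, hidden: int, d_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).selu())


class BridgeNet(Module):
    """Encoders + bridge + discrete-time survival head."""

    def __init__(self, cfg: RunConfig, n_omics_features: int,
                 rng: np.random.Generator, modality: str = "multimodal"):
        super().__init__()
        if modality not in MODALITY_CHOICES:
            raise ValueError(f"modality must be one of {MODALITY_CHOICES}")
        self.cfg = cfg
        self.modality = modality
        self.n_omics_features = n_omics_features
        enc = cfg.encoder
        if modality != "omics_only":
            self.wsi_encoder = build_wsi_encoder(enc, rng)
        if modality != "wsi_only":
            self.omics_encoder = SNNEncoder(n_omics_features, enc, rng)
        if modality == "multimodal":
            self.bridge_wo = MLP2(enc.d_wsi, cfg.bridge.hidden, enc.d_omics, rng)
            self.bridge_ow = MLP2(enc.d_omics, cfg.bridge.hidden, enc.d_wsi, rng)
            head_in = enc.d_wsi + enc.d_omics
        elif modality == "wsi_only":
            head_in = enc.d_wsi
        else:
            head_in = enc.d_omics
        self.head = MLP2(head_in, cfg.train.head_hidden, cfg.train.n_bins, rng)

    # ------------------------------------------------------------- forward
    def embed_slide(self, features: np.ndarray) -> tuple[Tensor, np.ndarray]:
        return self.wsi_encoder.forward(features)

    def embed_omics(self, values: np.ndarray) -> Tensor:
        return self.omics_encoder.forward(values.reshape(1, -1))[0, :]

    def bridge_forward(self, h_w: Tensor | None, h_o: Tensor | None
                       ) -> dict[str, Tensor]:
        """Pseudo-embeddings across the bridge; omits pseudo_slide when the
        omics embedding is absent (slide-only inference is supported,
        omics-only is not)."""
        if h_w is None and h_o is None:
            raise ValueError("at least the slide embedding must be present")
        if h_w is None:
            raise ValueError("bridge inference requires the slide embedding")
        out = {"pseudo_omics": self.bridge_wo(h_w.reshape(1, -1))[0, :]}
        if h_o is not None:
            out["pseudo_slide"] = self.bridge_ow(h_o.reshape(1, -1))[0, :]
        return out

    def fuse_logits(self, h_w: Tensor | None, h_o: Tensor | None) -> Tensor:
        if self.modality == "multimodal":
            if h_w is None or h_o is None:
                raise ValueError("fusion requires both embeddings "
                                 "(real or pseudo omics)")
            z = concat([h_w, h_o], axis=0)
        elif self.modality == "wsi_only":
            z = h_w
        else:
            z = h_o
        return self.head(z.reshape(1, -1))[0, :]


# ------------------------------------------------------------------ losses

def survival_nll(logits: Tensor, bins: np.ndarray, events: np.ndarray
                 ) -> Tensor:
    """Censoring-aware discrete-time negative log-likelihood.

    Event in bin j contributes -log h_j - sum_{k<j} log(1 - h_k);
    censoring in bin j contributes -sum_{k<=j} log(1 - h_k). Mean over the
    batch; hazards clamped to [1e-7, 1 - 1e-7].
    """
    bins = np.asarray(bins, dtype=int)
    events = np.asarray(events, dtype=int)
    n_bins = logits.shape[-1]
    if np.any(bins < 0) or np.any(bins >= n_bins):
        raise ValueError(f"bin index out of range [0, {n_bins})")
    h = logits.sigmoid() * (1.0 - 2.0 * _HCLIP) + _HCLIP
    log_h = h.log()
    log_1mh = (1.0 - h).log()
    B = logits.shape[0]
    k = np.arange(n_bins)[None, :]
    event_mask = np.zeros((B, n_bins))
    event_mask[np.arange(B), bins] = events
    # survive all bins before the event bin; censored patients also survive
    # their own bin
    surv_mask = (k < bins[:, None]).astype(float)
    surv_mask += (k == bins[:, None]) * (1 - events)[:, None]
    ll = (Tensor(event_mask) * log_h).sum() + (Tensor(surv_mask) * log_1mh).sum()
    return -ll * (1.0 / B)


def bridge_loss(net: BridgeNet, h_w: Tensor, h_o: Tensor, mode: str) -> Tensor:
    """Per-dimension mean squared bridge residuals with stop-grad targets."""
    if mode not in BRIDGE_MODES:
        raise ValueError(f"mode must be one of {BRIDGE_MODES}")
    if mode == "non_bridge":
        return Tensor(0.0)
    d_o = h_o.shape[-1]
    d_w = h_w.shape[-1]
    p_o = net.bridge_wo(h_w.reshape(1, -1))[0, :]
    res = p_o - h_o.detach()
    loss = (res * res).sum() * (1.0 / d_o)
    if mode == "bridge":
        p_w = net.bridge_ow(h_o.reshape(1, -1))[0, :]
        res_w = p_w - h_w.detach()
        loss = loss + (res_w * res_w).sum() * (1.0 / d_w)
    return loss


def total_loss(l_surv: Tensor, l_bridge: Tensor, lam: float) -> Tensor:
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0.0:
        return l_surv
    return l_surv + lam * l_bridge


# ---------------------------------------------------------------- training

@dataclass
class TrainedBridge:
    """A fitted network plus everything needed to reuse it leak-free."""
    net: BridgeNet
    config: RunConfig
    fold_id: int
    train_log: list[float]
    feature_names: list[str] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    seed: int = 0

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "modality": self.net.modality,
            "n_omics_features": self.net.n_omics_features,
            "fold_id": self.fold_id,
            "train_log": self.train_log,
            "feature_names": self.feature_names,
            "feature_mean": None if self.feature_mean is None
            else self.feature_mean.tolist(),
            "feature_sd": None if self.feature_sd is None
            else self.feature_sd.tolist(),
            "bin_edges": None if self.bin_edges is None
            else np.asarray(self.bin_edges).tolist(),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBridge":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = RunConfig.from_dict(sidecar["config"])
        rng = np.random.default_rng(sidecar["seed"])
        net = BridgeNet(cfg, sidecar["n_omics_features"], rng,
                      sidecar["modality"])
        with np.load(path.with_suffix(".npz")) as zf:
            arrays = [zf[f"p{i}"] for i in range(len(zf.files))]
        net.load_state_arrays(arrays)
        net.eval()
        return cls(net, cfg, sidecar["fold_id"], sidecar["train_log"],
                   sidecar["feature_names"],
                   None if sidecar["feature_mean"] is None
                   else np.array(sidecar["feature_mean"]),
                   None if sidecar["feature_sd"] is None
                   else np.array(sidecar["feature_sd"]),
                   None if sidecar["bin_edges"] is None
                   else np.array(sidecar["bin_edges"]),
                   sidecar["seed"])


def train_model(net: BridgeNet, bags: dict[str, np.ndarray],
                omics: dict[str, np.ndarray] | None,
                bins: dict[str, int], events: dict[str, int],
                train_ids: list[str], cfg: RunConfig, seed: int
                ) -> list[float]:
    """Mini-batch training, one slide (plus its omics) per step.

    Returns the per-epoch mean training loss. Raises on NaN loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=cfg.train.lr,
               weight_decay=cfg.train.weight_decay)
    mode = cfg.bridge.mode
    lam = 0.0 if mode == "non_bridge" else cfg.bridge.lam
    net.train()
    log: list[float] = []
    accum = max(1, cfg.train.accum_steps)
    for epoch in range(cfg.train.epochs):
        order = rng.permutation(len(train_ids))
        losses = []
        opt.zero_grad()
        for step, idx in enumerate(order):
            pid = train_ids[idx]
            h_w = h_o = None
            if net.modality != "omics_only":
                h_w, _ = net.embed_slide(bags[pid])
            if net.modality != "wsi_only":
                h_o = net.embed_omics(omics[pid])
            h_fuse = h_o
            if (net.modality == "multimodal" and mode != "non_bridge"
                    and cfg.train.modality_dropout > 0
                    and rng.random() < cfg.train.modality_dropout):
                # modality dropout: feed the bridge-generated pseudo-omics
                # embedding through the head instead of the real one
                h_fuse = net.bridge_forward(h_w, None)["pseudo_omics"]
            logits = net.fuse_logits(h_w, h_fuse).reshape(1, -1)
            l_surv = survival_nll(logits, np.array([bins[pid]]),
                                  np.array([events[pid]]))
            if net.modality == "multimodal" and lam > 0:
                loss = total_loss(l_surv, bridge_loss(net, h_w, h_o, mode),
                                  lam)
            else:
                loss = l_surv
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"patient {pid}")
            loss.backward(np.array(1.0 / accum))
            if (step + 1) % accum == 0 or step == len(order) - 1:
                opt.step()
                opt.zero_grad()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    net.eval()
    return log


def predict(trained: TrainedBridge, bag: PatchBag | None,
            omics_values: np.ndarray | None,
            missing_omics: bool = False) -> SurvivalOutput:
    """Risk prediction for one patient.

    With missing_omics=True the pseudo-omics embedding generated by the
    bridge from the slide embedding is routed through the same fusion
    head; omics inputs are never touched on that path.
    """
    net = trained.net
    net.eval()
    h_w = h_o = None
    if net.modality != "omics_only":
        if bag is None:
            raise ValueError("this model requires a patch bag")
        h_w, _ = net.embed_slide(bag.features)
    if net.modality == "multimodal" and missing_omics:
        h_o = net.bridge_forward(h_w, None)["pseudo_omics"]
    elif net.modality != "wsi_only":
        if omics_values is None:
            raise ValueError("omics values required unless missing_omics=True")
        h_o = net.embed_omics(omics_values)
    logits = net.fuse_logits(h_w, h_o)
    return SurvivalOutput.from_logits(logits.data)
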