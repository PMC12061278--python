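"""Self-attention primitives: exact softmax attention and a Nystrom
approximation for long patch sequences.

Both operate on token matrices with optional leading batch axes (used for
multi-head attention, where the head axis is the batch axis) and also return
the attention row of the first (class) token, which downstream
interpretability code maps back onto slide patches.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = ["exact_attention", "nystrom_attention", "segment_landmarks"]


def _check_finite(*tensors: Tensor) -> None:
    for t in tensors:
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite values in attention input")


def exact_attention(Q: Tensor, K: Tensor, V: Tensor) -> tuple[Tensor, Tensor]:
    """Full softmax attention. Returns (attended tokens, class-token row)."""
    _check_finite(Q, K, V)
    d = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
    attn = softmax(scores, axis=-1)
    out = attn @ V
    cls_row = attn[..., 0, :]
    return out, cls_row


def segment_landmarks(X: Tensor, m: int) -> Tensor:
    """Landmark tokens as means over m contiguous segments of the sequence."""
    n = X.shape[-2]
    if m > n:
        raise ValueError(f"n_landmarks={m} exceeds token count {n}")
    bounds = np.linspace(0, n, m + 1).astype(int)
    parts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        parts.append(X[..., lo:hi, :].mean(axis=-2, keepdims=True))
    return concat(parts, axis=-2)


def _iterative_pinv(A: Tensor, n_iter: int = 6) -> Tensor:
    """Moore-Penrose pseudoinverse by Newton-Schulz-type iteration.

    A is a (batched) square kernel of row-stochastic softmax values; the
    scaled initialization guarantees convergence of the cubic iteration.
    """
    m = A.shape[-1]
    eye = Tensor(np.broadcast_to(np.eye(m), A.shape).copy())
    a = A.data
    denom = (np.abs(a).sum(axis=-1).max(axis=-1, keepdims=True)
             * np.abs(a).sum(axis=-2).max(axis=-1, keepdims=True))
    scale = Tensor((1.0 / denom)[..., None])
    Z = A.swapaxes(-1, -2) * scale
    for _ in range(n_iter):
        AZ = A @ Z
        Z = 0.25 * (Z @ (13.0 * eye - AZ @ (15.0 * eye - AZ @ (7.0 * eye - AZ))))
    return Z


def nystrom_attention(Q: Tensor, K: Tensor, V: Tensor, n_landmarks: int,
                      pinv_iterations: int = 6) -> tuple[Tensor, Tensor]:
    """Nystrom-approximated softmax attention.

    Landmarks are segment means of Q and K; the attention matrix is
    approximated by the three-factor product
    softmax(Q K_l) · pinv(softmax(Q_l K_l)) · softmax(Q_l K),
    with the pseudoinverse computed by a fixed six-step iteration. The
    truncated iteration doubles as regularization: the landmark kernel is
    often near-singular and its fully converged pseudoinverse amplifies
    noise. Rows of the implied attention matrix are renormalized to sum
    to one, so attention over identical value rows reproduces that row
    exactly. The class token's approximate attention row is clipped at
    zero and renormalized likewise.
    """
    _check_finite(Q, K, V)
    if n_landmarks < 1:
        raise ValueError("n_landmarks must be >= 1")
    d = Q.shape[-1]
    s = 1.0 / np.sqrt(d)
    Ql = segment_landmarks(Q, n_landmarks)
    Kl = segment_landmarks(K, n_landmarks)
    F1 = softmax((Q @ Kl.swapaxes(-1, -2)) * s, axis=-1)      # n x m
    F2 = softmax((Ql @ Kl.swapaxes(-1, -2)) * s, axis=-1)     # m x m
    F3 = softmax((Ql @ K.swapaxes(-1, -2)) * s, axis=-1)      # m x n
    Z = _iterative_pinv(F2, pinv_iterations)
    # row sums of F1 Z F3 without materializing it; renormalizing keeps the
    # implied attention row-stochastic even when the landmark kernel is
    # ill-conditioned
    ones = Tensor(np.ones(F3.shape[:-2] + (F3.shape[-1], 1)))
    row_sums = F1 @ (Z @ (F3 @ ones))
    out = (F1 @ (Z @ (F3 @ V))) / row_sums
    # approximate class-token attention row over all tokens
    cls_row = (F1[..., 0:1, :] @ Z @ F3)[..., 0, :]
    cls_row = cls_row.clip_min(0.0)
    cls_row = cls_row / cls_row.sum(axis=-1, keepdims=True)
    return out, cls_row
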