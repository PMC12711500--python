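"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by explicit loops or closed form,
never by calling the code path it is meant to check.
"""

import numpy as np
from scipy.special import logsumexp


def patch_embed_loop(image: np.ndarray, weight: np.ndarray, bias: np.ndarray, patch: int) -> np.ndarray:
    """Slice every non-overlapping patch, flatten (C, p, p), project."""
    B, C, H, W = image.shape
    gh, gw = H // patch, W // patch
    out = np.zeros((B, gh * gw, weight.shape[0]), dtype=np.float64)
    for b in range(B):
        k = 0
        for i in range(gh):
            for j in range(gw):
                block = image[b, :, i * patch : (i + 1) * patch, j * patch : (j + 1) * patch]
                out[b, k] = weight.astype(np.float64) @ block.reshape(-1) + bias
                k += 1
    return out


def attention_loop(x: np.ndarray, wq, bq, wk, bk, wv, bv, wo, bo, num_heads: int) -> np.ndarray:
    """softmax(Q K^T / sqrt(d)) V with explicit per-head loops."""
    N, D = x.shape
    dh = D // num_heads
    q = x @ wq.T + bq
    k = x @ wk.T + bk
    v = x @ wv.T + bv
    out = np.zeros((N, D))
    for h in range(num_heads):
        sl = slice(h * dh, (h + 1) * dh)
        qs, ks, vs = q[:, sl], k[:, sl], v[:, sl]
        scores = qs @ ks.T / np.sqrt(dh)
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        out[:, sl] = w @ vs
    return out @ wo.T + bo


def sliding_window_max(x: np.ndarray, kernel: int) -> np.ndarray:
    """Stride-1, same-padded window maximum by explicit loops (B,C,H,W)."""
    B, C, H, W = x.shape
    pad = kernel // 2
    out = np.full_like(x, -np.inf)
    for b in range(B):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    i0, i1 = max(0, i - pad), min(H, i + pad + 1)
                    j0, j1 = max(0, j - pad), min(W, j + pad + 1)
                    out[b, c, i, j] = x[b, c, i0:i1, j0:j1].max()
    return out


def metrics_per_sample(y_true, y_pred, num_classes: int) -> dict:
    """Accuracy / per-class P, R, F1 counted sample by sample."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {"accuracy": float(np.mean(y_true == y_pred))}
    precision, recall, f1 = [], [], []
    for c in range(num_classes):
        tp = fp = fn = 0
        for t, p in zip(y_true, y_pred):
            if p == c and t == c:
                tp += 1
            elif p == c:
                fp += 1
            elif t == c:
                fn += 1
        P = tp / (tp + fp) if tp + fp else 0.0
        R = tp / (tp + fn) if tp + fn else 0.0
        precision.append(P)
        recall.append(R)
        f1.append(2 * P * R / (P + R) if P + R else 0.0)
    out["precision"] = np.array(precision)
    out["recall"] = np.array(recall)
    out["f1"] = np.array(f1)
    return out


def mann_whitney_auc(scores, positives) -> float:
    """AUC as the pairwise-comparison statistic over all (pos, neg) pairs."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def cross_entropy_ref(logits, labels) -> float:
    """Mean NLL in float64 via logsumexp (independent of the engine)."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    lse = logsumexp(logits, axis=1)
    return float(np.mean(lse - logits[np.arange(len(labels)), labels]))


def adamw_ref_trajectory(theta0, grads, lr, beta1, beta2, eps, wd, decay=True):
    """Hand-coded AdamW recurrences in float64; returns all iterates."""
    theta = np.asarray(theta0, dtype=np.float64).copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    out = []
    for t, g in enumerate(grads, start=1):
        g = np.asarray(g, dtype=np.float64)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        m_hat = m / (1 - beta1**t)
        v_hat = v / (1 - beta2**t)
        step = lr * m_hat / (np.sqrt(v_hat) + eps)
        if decay:
            step = step + lr * wd * theta  # decoupled term uses theta(t)
        theta = theta - step
        out.append(theta.copy())
    return out
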