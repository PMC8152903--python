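"""Batched linear soft-margin SVM and ECOC (one-vs-rest) prediction.

The decoding engine trains one small SVM per (time point, iteration, fold,
binary learner).  A full study involves millions of such problems, each with
only a handful of training rows (averaged scalp vectors), so the solver is
written to train an entire batch of time points -- and all one-vs-rest
learners -- simultaneously with vectorized numpy.

Solver: dual coordinate descent on the L1-loss (hinge) SVM dual,

    min_a  1/2 a^T Q a - e^T a   s.t.  0 <= a_i <= C,   Q_ij = y_i y_j x_i.x_j

with the intercept absorbed into an augmented constant feature (so the bias
is L2-regularized, as in liblinear's default formulation).  Points are
visited in a fixed order, which makes the result deterministic.  For the
tiny row counts used here (<= a few dozen) the iteration converges in a few
dozen sweeps.

ECOC prediction uses the one-vs-rest coding matrix M (M[c, l] = +1 when
l == c else -1) with hinge binary loss:

    loss(c) = sum_l max(0, 1 - M[c, l] * f_l(x))

and predicts the class minimizing the loss; ties break to the lowest class
code (argmin returns the first minimizer).
"""

from __future__ import annotations

import numpy as np

__all__ = ["train_ovr_batch", "ecoc_decision", "ecoc_predict_from_decision",
           "standardize_fold", "fit_predict_ecoc"]


def train_ovr_batch(X: np.ndarray, Y: np.ndarray, C: float = 1.0,
                    max_sweeps: int = 400, tol: float = 1e-4) -> np.ndarray:
    """Train L binary hinge-loss SVMs on each of B feature matrices.

    Parameters
    ----------
    X : (B, n, f) training rows per batch element (standardized, with the
        bias feature already appended).
    Y : (L, n) +/-1 labels per binary learner, shared across the batch.
    C : box constraint (regularization constant).
    tol : sweep terminates when no dual variable moved more than this.

    Returns
    -------
    W : (L, B, f) primal weight vectors (bias = last component).
    """
    X = np.asarray(X, dtype=np.float64)
    Yf = np.asarray(Y, dtype=np.float64)
    B, n, f = X.shape
    L = Yf.shape[0]
    # Q_ii, guarded: an all-zero row contributes nothing and keeps alpha=0.
    Qii = np.einsum("bnf,bnf->bn", X, X)
    Qii_safe = np.where(Qii > 0.0, Qii, 1.0)

    # Each batch element's coordinate-descent trajectory depends only on its
    # own data, so converged elements are frozen and removed from the working
    # set; the result is independent of how problems are batched together.
    alpha_full = np.zeros((L, B, n))
    idx = np.arange(B)
    Xa, Qa = X, Qii_safe
    Wa = np.zeros((L, B, f))
    aa = np.zeros((L, B, n))
    for _ in range(max_sweeps):
        dmax = np.zeros(idx.shape[0])
        for i in range(n):
            xi = Xa[:, i, :]                                   # (b, f)
            yi = Yf[:, i]                                      # (L,)
            grad = yi[:, None] * np.einsum("lbf,bf->lb", Wa, xi) - 1.0
            a_old = aa[:, :, i]
            a_new = np.clip(a_old - grad / Qa[None, :, i], 0.0, C)
            delta = a_new - a_old
            Wa += (delta * yi[:, None])[:, :, None] * xi[None, :, :]
            aa[:, :, i] = a_new
            np.maximum(dmax, np.abs(delta).max(axis=0), out=dmax)
        done = dmax < tol
        if done.any():
            alpha_full[:, idx[done], :] = aa[:, done, :]
            if done.all():
                idx = idx[:0]
                break
            keep = ~done
            idx, Xa, Qa = idx[keep], Xa[keep], Qa[keep]
            Wa, aa = Wa[:, keep], aa[:, keep]
    if idx.size:  # hit max_sweeps before full convergence
        alpha_full[:, idx, :] = aa
    # compute W from alpha directly (no accumulated update round-off)
    return np.einsum("lbn,bnf->lbf", alpha_full * Yf[:, None, :], X)


def standardize_fold(Xtr: np.ndarray, Xte: np.ndarray, ddof: int = 1):
    """Standardize features per batch element using training-row statistics,
    then append the bias feature (constant 1).

    Xtr : (B, n, f); Xte : (B, m, f).  Zero-variance features are left
    centered only (scale 1).
    """
    mu = Xtr.mean(axis=1, keepdims=True)
    sd = Xtr.std(axis=1, keepdims=True, ddof=ddof)
    sd = np.where(sd > 0.0, sd, 1.0)
    Ztr = (Xtr - mu) / sd
    Zte = (Xte - mu) / sd
    ones_tr = np.ones(Ztr.shape[:-1] + (1,))
    ones_te = np.ones(Zte.shape[:-1] + (1,))
    return np.concatenate([Ztr, ones_tr], axis=-1), np.concatenate([Zte, ones_te], axis=-1)


def ecoc_decision(W: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """Decision values f_l(x) for every learner / batch element / test row.

    W : (L, B, f); Xte : (B, m, f) -> (L, B, m).
    """
    return np.einsum("lbf,bmf->lbm", W, Xte)


def ecoc_predict_from_decision(D: np.ndarray) -> np.ndarray:
    """Hinge-loss ECOC decoding of one-vs-rest decision values.

    D : (C, B, m) -> predicted class codes 1..C, shape (B, m).

    loss(c) = relu(1 - d_c) + sum_{l != c} relu(1 + d_l); the sum is
    rearranged so no per-class loop is needed.  np.argmin takes the first
    (lowest-code) class on ties.
    """
    pos = np.maximum(0.0, 1.0 - D)
    neg = np.maximum(0.0, 1.0 + D)
    loss = pos - neg + neg.sum(axis=0, keepdims=True)
    return np.argmin(loss, axis=0).astype(np.int8) + 1


def fit_predict_ecoc(train_vectors, train_classes, test_vectors,
                     C: float = 1.0, standardize: bool = True,
                     n_classes: int | None = None) -> np.ndarray:
    """Train one-vs-rest linear SVMs and predict test rows' classes.

    The single-problem surface of the batched engine: ``train_vectors`` is
    (n, f) with 1-based ``train_classes``; returns predicted codes for each
    row of ``test_vectors``.  Deterministic; ties break to the lowest code.
    """
    Xtr = np.asarray(train_vectors, dtype=float)[None]          # (1, n, f)
    Xte = np.asarray(test_vectors, dtype=float)[None]           # (1, m, f)
    classes = np.asarray(train_classes)
    if n_classes is None:
        n_classes = int(classes.max())
    if np.unique(classes).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if standardize:
        Xtr, Xte = standardize_fold(Xtr, Xte)
    Y = np.where(classes[None, :] == np.arange(1, n_classes + 1)[:, None], 1.0, -1.0)
    W = train_ovr_batch(Xtr, Y, C=C)
    D = ecoc_decision(W, Xte)
    return ecoc_predict_from_decision(D)[0]
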