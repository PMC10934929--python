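"""Single-response partial least-squares regression (NIPALS PLS1).

The model regresses a numeric class coding (fertile = 1.0, non-fertile = 0.0)
on mean transmittance spectra.  X and y are mean-centered; no variance scaling
by default (an ``autoscale`` switch exists for sensitivity studies).  For a
single response, y-deflation is mathematically redundant, so only X is
deflated.

Component a (a = 1..A):

    w_a = X'y / ||X'y||          weight (unit norm)
    t_a = X w_a                  score
    p_a = X' t_a / (t_a' t_a)    x-loading
    q_a = y' t_a / (t_a' t_a)    y-loading
    X  <- X - t_a p_a'           deflation

Regression vector on the original (centered) variables:

    b = W (P' W)^{-1} q,    intercept = y_mean - x_mean . b

Components are nested: the first a columns of (W, P, q) are identical whether
A = a or A > a was requested, so ``PLSModel.coefficients(a)`` recovers every
smaller model from one fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .metrics import CLASS_CODING

#: early-stopping tolerance: stop when ||X'y|| falls below this fraction of
#: its value before the first deflation
EARLY_STOP_RTOL = 1e-12

FORMAT_VERSION = 1


class DegenerateResponseError(ValueError):
    """y is constant: there is no direction of covariance to extract."""


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model.

    Attributes
    ----------
    x_mean, y_mean : centering applied before extraction.
    W : (p, A) unit-norm weights.
    P : (p, A) x-loadings.
    q : (A,) y-loadings.
    T : (n, A) training scores, mutually orthogonal; kept for diagnostics.
    b, intercept : regression vector and offset on the raw variable scale.
    A : effective number of components (may be fewer than requested if the
        residual covariance underflowed).
    class_coding : label -> numeric value used when fitted as a classifier.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    intercept: float
    A: int
    x_scale: Optional[np.ndarray] = None
    class_coding: dict = field(default_factory=lambda: dict(CLASS_CODING))

    @property
    def n_features(self) -> int:
        return self.x_mean.shape[0]

    def coefficients(self, a: Optional[int] = None) -> tuple[np.ndarray, float]:
        """(b, intercept) of the nested sub-model with the first ``a`` components."""
        if a is None or a == self.A:
            return self.b, self.intercept
        if not 1 <= a <= self.A:
            raise ValueError(f"a={a} outside 1..{self.A}")
        b = _assemble_b(self.W[:, :a], self.P[:, :a], self.q[:a])
        if self.x_scale is not None:
            b = b / self.x_scale
        return b, self.y_mean - float(self.x_mean @ b)

    def to_json(self) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "T": self.T.tolist(),
            "b": self.b.tolist(),
            "intercept": self.intercept,
            "A": self.A,
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "class_coding": self.class_coding,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
        return cls(
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            W=np.asarray(doc["W"], dtype=float),
            P=np.asarray(doc["P"], dtype=float),
            q=np.asarray(doc["q"], dtype=float),
            T=np.asarray(doc["T"], dtype=float),
            b=np.asarray(doc["b"], dtype=float),
            intercept=float(doc["intercept"]),
            A=int(doc["A"]),
            x_scale=None if doc["x_scale"] is None else np.asarray(doc["x_scale"], dtype=float),
            class_coding=dict(doc["class_coding"]),
        )


def _assemble_b(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # b = W (P'W)^{-1} q; P'W is upper-triangular-ish but solve is safer
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(X: np.ndarray, y: np.ndarray, A: int, *,
             autoscale: bool = False) -> PLSModel:
    """Fit a PLS1 model with ``A`` latent components via NIPALS.

    Parameters
    ----------
    X : (n, p) predictor matrix (mean spectra, one row per egg).
    y : (n,) numeric response (class coding for classification use).
    A : requested number of components, 1 <= A <= min(n - 1, p).
    autoscale : additionally divide each column of X by its standard
        deviation (constant columns are left unscaled).

    Raises
    ------
    ValueError : A out of range or shape problems.
    DegenerateResponseError : constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    a_max = min(n - 1, p)
    if not 1 <= A <= a_max:
        raise ValueError(f"A={A} outside valid range 1..{a_max} for n={n}, p={p}")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("y is constant; no covariance direction exists")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if autoscale:
        sd = Xc.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
        Xc = Xc / x_scale
    yc = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))

    Xd = Xc.copy()
    s0 = float(np.linalg.norm(Xd.T @ yc))
    eff = 0
    for a in range(A):
        s = Xd.T @ yc
        ns = float(np.linalg.norm(s))
        if ns <= EARLY_STOP_RTOL * s0:
            break
        w = s / ns
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0.0:
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yc @ t) / tt
        Xd -= np.outer(t, P[:, a])
        eff = a + 1

    if eff == 0:
        raise DegenerateResponseError("X carries no covariance with y")
    W, P, q, T = W[:, :eff], P[:, :eff], q[:eff], T[:, :eff]

    b = _assemble_b(W, P, q)
    if x_scale is not None:
        b = b / x_scale
    intercept = y_mean - float(x_mean @ b)
    return PLSModel(x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, T=T,
                    b=b, intercept=intercept, A=eff, x_scale=x_scale)


def predict(model: PLSModel, X_new: np.ndarray, a: Optional[int] = None) -> np.ndarray:
    """Continuous predictions X_new . b + intercept (unclipped).

    ``a`` selects a nested sub-model with fewer components.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}")
    b, intercept = model.coefficients(a)
    return X_new @ b + intercept


def encode_labels(labels, coding: Optional[dict] = None) -> np.ndarray:
    """Map class labels to the numeric PLS response (fertile=1, non-fertile=0)."""
    coding = dict(CLASS_CODING) if coding is None else coding
    try:
        return np.array([coding[str(v)] for v in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in coding {coding}") from None
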