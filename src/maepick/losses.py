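"""Self-cross similarity loss with optional positive-unlabeled adjustment.

The few-shot objective compares pooled latent features of labeled
particle exemplars against features of randomly cropped (mostly
background) regions.  Writing ``S_cos`` for cosine similarity, with m
exemplar features E_i^l and n unlabeled features E_j^u:

* self-similarity   ``S_self  = (1/m^2)  sum_ij S_cos(E_i^l, E_j^l)``
* cross-similarity  ``S_cross = (1/(mn)) sum_ij S_cos(E_i^l, E_j^u)``

(both double sums include the i=j diagonal, exactly as defined).  The
self-cross similarity (SCS) loss is the floored hinge

    ``L_SCS = max(tau, 1 + alpha * S_cross - (1 - alpha) * S_self)``

which rewards tight exemplar clusters and exemplar/background
separation, with ``tau`` capping how far the separation is pushed.

Because a fraction ``pi_hat`` of the unlabeled crops actually contains
particles, the PU-adjusted variant recalibrates the similarities from
the raw pairwise sums S_ll, S_lu, S_uu:

    ``S^_self  = (S_ll + 2*pi S_lu + pi^2 S_uu) / (m+n)^2``
    ``S^_cross = ((1-pi) S_lu + pi(1-pi) S_uu) / ((m+n) n)``

These adjusted forms are implemented exactly as printed; note their
``pi_hat -> 0`` limits do not reduce to the unadjusted definitions (the
normalizations differ: 1/(m+n)^2 vs 1/m^2), so both variants are
selectable and the discrepancy is observable rather than hidden.

The total training objective is ``L_total = L_MSE + beta * L_SCS``.

All functions accept either plain NumPy arrays (returning floats) or
autodiff Tensors (returning Tensors, for training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor


@dataclass
class LossConfig:
    """Weights of the self-cross similarity objective.

    alpha in [0,1] balances the cross vs self term inside the hinge;
    tau is the hinge floor; beta >= 0 scales the SCS term in the total
    loss; pi_hat in [0,1] is the assumed fraction of unlabeled crops
    that contain a particle; ``adjusted`` selects the PU-adjusted
    similarities.  Defaults follow the sparse-particle prior: only a
    small fraction of random crops hits a particle.

    The default floor depends on the similarity variant, because tau
    must live on the scale of the similarities it floors.  The adjusted
    similarities carry a 1/(m+n)^2 normalization that compresses
    S^_self well below 1 (for m=15, n=32 its ceiling is ~0.2), so the
    hinge ranges over roughly [0.7, 1.1] and a floor of 0.05 can never
    engage — the loss would keep pushing until the feature space
    collapses onto two antipodal prototypes.  tau=0.8 halts that
    pressure once exemplars and background are well separated but
    before collapse; the unadjusted hinge spans [~0, 2] and keeps the
    conventional small floor 0.05.
    """

    alpha: float = 0.5
    tau: float | None = None  # resolved per variant, see above
    beta: float = 1.0
    pi_hat: float = 0.1
    adjusted: bool = True
    include_diagonal: bool = True  # the printed double sums include i=j

    def __post_init__(self):
        if self.tau is None:
            self.tau = 0.8 if self.adjusted else 0.05
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.pi_hat <= 1.0:
            raise ValueError(f"pi_hat must be in [0, 1], got {self.pi_hat}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class SimilaritySums:
    """Raw pairwise cosine sums S_ll, S_lu, S_uu and the set sizes."""

    s_ll: object  # float or Tensor
    s_lu: object
    s_uu: object
    m: int
    n: int


def _wrap(x):
    """Return (tensor, was_tensor)."""
    return (x, True) if isinstance(x, Tensor) else (as_tensor(np.asarray(x, np.float32)), False)


def _unwrap(t: Tensor, any_tensor: bool):
    return t if any_tensor else float(t.data)


def _normalize_rows(f: Tensor) -> Tensor:
    norms = (f * f).sum(axis=1, keepdims=True).sqrt()
    if np.any(norms.data <= 0) or not np.all(np.isfinite(norms.data)):
        raise ValueError("zero-norm or non-finite feature vector in cosine similarity")
    return f / norms


def cosine(a, b):
    """Cosine similarity a.b / (|a||b|); errors on zero-norm input."""
    ta, wa = _wrap(a)
    tb, wb = _wrap(b)
    na = (ta * ta).sum().sqrt()
    nb = (tb * tb).sum().sqrt()
    if na.data <= 0 or nb.data <= 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    out = (ta * tb).sum() / (na * nb)
    return _unwrap(out, wa or wb)


def similarity_sums(exemplar_features, unlabeled_features,
                    include_diagonal: bool = True) -> SimilaritySums:
    """Vectorized pairwise cosine sums between/within the two feature sets."""
    fl, wl = _wrap(exemplar_features)
    fu, wu = _wrap(unlabeled_features)
    if fl.ndim != 2 or fu.ndim != 2:
        raise ValueError("feature sets must be 2D (count x dim)")
    m, n = fl.shape[0], fu.shape[0]
    if m < 1 or n < 1:
        raise ValueError("similarity sums need at least one feature per set")
    gl = _normalize_rows(fl)
    gu = _normalize_rows(fu)
    s_ll = (gl @ gl.transpose(1, 0)).sum()
    s_lu = (gl @ gu.transpose(1, 0)).sum()
    s_uu = (gu @ gu.transpose(1, 0)).sum()
    if not include_diagonal:
        s_ll = s_ll - float(m)
        s_uu = s_uu - float(n)
    any_t = wl or wu
    return SimilaritySums(_unwrap(s_ll, any_t), _unwrap(s_lu, any_t),
                          _unwrap(s_uu, any_t), m, n)


def self_similarity(exemplar_features):
    """Mean pairwise cosine among exemplar features (diagonal included)."""
    fl, w = _wrap(exemplar_features)
    if fl.ndim != 2 or fl.shape[0] < 1:
        raise ValueError("self_similarity needs at least one feature vector")
    g = _normalize_rows(fl)
    m = fl.shape[0]
    out = (g @ g.transpose(1, 0)).sum() * (1.0 / m**2)
    return _unwrap(out, w)


def cross_similarity(exemplar_features, unlabeled_features):
    """Mean pairwise cosine between exemplar and unlabeled features."""
    fl, wl = _wrap(exemplar_features)
    fu, wu = _wrap(unlabeled_features)
    if fl.ndim != 2 or fu.ndim != 2 or fl.shape[0] < 1 or fu.shape[0] < 1:
        raise ValueError("cross_similarity needs nonempty 2D feature sets")
    gl, gu = _normalize_rows(fl), _normalize_rows(fu)
    m, n = fl.shape[0], fu.shape[0]
    out = (gl @ gu.transpose(1, 0)).sum() * (1.0 / (m * n))
    return _unwrap(out, wl or wu)


def adjusted_similarities(sums: SimilaritySums, pi_hat: float):
    """PU-adjusted (s_self_hat, s_cross_hat) from the raw pairwise sums."""
    m, n = sums.m, sums.n
    if m < 1 or n < 1:
        raise ValueError("adjusted similarities need m >= 1 and n >= 1")
    any_t = any(isinstance(s, Tensor) for s in (sums.s_ll, sums.s_lu, sums.s_uu))
    pi = float(pi_hat)
    if not any_t:  # float64 path for plain numeric input
        s_ll, s_lu, s_uu = (float(s) for s in (sums.s_ll, sums.s_lu, sums.s_uu))
    else:
        s_ll, s_lu, s_uu = (as_tensor(s) if not isinstance(s, Tensor) else s
                            for s in (sums.s_ll, sums.s_lu, sums.s_uu))
    s_self = (s_ll + (2.0 * pi) * s_lu + (pi * pi) * s_uu) * (1.0 / (m + n) ** 2)
    s_cross = ((1.0 - pi) * s_lu + (pi * (1.0 - pi)) * s_uu) * (1.0 / ((m + n) * n))
    if not any_t:
        return s_self, s_cross
    return _unwrap(s_self, any_t), _unwrap(s_cross, any_t)


def scs_loss(s_cross, s_self, cfg: LossConfig):
    """Floored hinge max(tau, 1 + alpha*S_cross - (1-alpha)*S_self)."""
    tc, wc = _wrap(s_cross)
    ts, ws = _wrap(s_self)
    raw = 1.0 + cfg.alpha * tc - (1.0 - cfg.alpha) * ts
    out = raw.maximum(cfg.tau)
    return _unwrap(out, wc or ws)


def total_loss(l_mse, l_scs, beta: float):
    """L_total = L_MSE + beta * L_SCS."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    tm, wm = _wrap(l_mse)
    ts, ws = _wrap(l_scs)
    return _unwrap(tm + beta * ts, wm or ws)


def scs_from_features(exemplar_features, unlabeled_features, cfg: LossConfig):
    """Compute the (possibly adjusted) SCS loss and its similarity terms.

    Returns ``(loss, s_self, s_cross)``; the similarity values are the
    ones actually used in the hinge (adjusted if ``cfg.adjusted``).
    """
    if cfg.adjusted:
        sums = similarity_sums(exemplar_features, unlabeled_features,
                               cfg.include_diagonal)
        s_self, s_cross = adjusted_similarities(sums, cfg.pi_hat)
    else:
        s_self = self_similarity(exemplar_features)
        s_cross = cross_similarity(exemplar_features, unlabeled_features)
    return scs_loss(s_cross, s_self, cfg), s_self, s_cross
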