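"""Ordered parenchymal-pattern dissimilarity (SILA) and affinity propagation.

Each subject's lung is summarised per region (left/right x upper/middle/
lower) as fractions of four *ordered* severity classes: Normal < Mild LAA <
Moderate LAA < Severe LAA.  SILA compares two subjects as an ordinal
earth-mover distance: per region the absolute differences of the cumulative
class distributions are summed over the three internal cut points, and the
regional distances are combined with volume weights.  With unit ground
distance between adjacent grades this is exactly the 1-Wasserstein distance
between the two ordered marginals, so SILA is a pseudometric (zero iff the
ordered marginals coincide in every region).

Subjects are grouped by affinity propagation on the negated dissimilarity
matrix: exemplar-based message passing (responsibilities/availabilities)
in which the number of clusters emerges from the self-similarity
"preference" rather than being fixed a priori.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, MalformedInputError

CLASS_NAMES = ("normal", "mild_laa", "moderate_laa", "severe_laa")
EXTRA_CLASS_NAMES = ("ground_glass", "reticular", "honeycombing")


@dataclass(frozen=True)
class PatternProfile:
    """Per-region fractions over the four ordered parenchymal classes."""

    regions: list
    fractions: np.ndarray  # (n_regions, 4), rows sum to 1
    volume_weights: np.ndarray  # (n_regions,), sums to 1

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        vw = np.asarray(self.volume_weights, dtype=float)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "volume_weights", vw)
        object.__setattr__(self, "regions", list(self.regions))
        if fr.ndim != 2 or fr.shape[0] != len(self.regions) or fr.shape[1] != len(CLASS_NAMES):
            raise MalformedInputError(
                f"fractions must be (n_regions, {len(CLASS_NAMES)})"
            )
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise DomainError("class fractions must lie in [0, 1]")
        if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-9):
            raise DomainError("class fractions must sum to 1 in every region")
        if vw.shape != (len(self.regions),) or np.any(vw < 0):
            raise MalformedInputError("one non-negative volume weight per region")
        if abs(vw.sum() - 1.0) > 1e-9:
            raise DomainError("volume weights must sum to 1")

    @classmethod
    def from_extended_fractions(cls, regions, fractions, volume_weights,
                                tol: float = 1e-9):
        """Build a profile from 7-class rows (ordered LAA + 3 texture classes).

        Only the four ordered classes enter SILA; nonzero ground-glass,
        reticular or honeycombing fractions are renormalised out with a
        warning.
        """
        fr = np.asarray(fractions, dtype=float)
        if fr.ndim != 2 or fr.shape[1] != 7:
            raise MalformedInputError("extended fractions must have 7 columns")
        extra = fr[:, 4:].sum()
        if extra > tol:
            warnings.warn(
                "nonzero ground-glass/reticular/honeycombing fractions "
                "renormalised out of the ordered-class profile",
                stacklevel=2,
            )
        core = fr[:, :4]
        core = core / core.sum(axis=1, keepdims=True)
        return cls(regions=regions, fractions=core, volume_weights=volume_weights)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    exemplars: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return int(self.exemplars.size)


def sila(p: PatternProfile, q: PatternProfile) -> float:
    """SILA dissimilarity between two ordered-pattern profiles.

    Per region, D_r = sum over the three internal grade cut points of
    |CDF_p(k) - CDF_q(k)|; the regional distances are combined with the
    pair's shared volume weights (the mean of the two subjects' weights).
    """
    if p.regions != q.regions:
        raise DomainError("profiles must share the same regions in the same order")
    cdf_p = np.cumsum(p.fractions, axis=1)[:, :-1]
    cdf_q = np.cumsum(q.fractions, axis=1)[:, :-1]
    d_r = np.abs(cdf_p - cdf_q).sum(axis=1)
    w = 0.5 * (p.volume_weights + q.volume_weights)
    return float(np.dot(w, d_r))


def sila_matrix(profiles: list) -> np.ndarray:
    """Pairwise SILA dissimilarity matrix (symmetric, zero diagonal)."""
    n = len(profiles)
    if n < 2:
        raise DomainError("need at least 2 profiles")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = sila(profiles[i], profiles[j])
    return out


def affinity_propagation(dissim: np.ndarray, preference: float | None = None,
                         damping: float = 0.7, max_iter: int = 500,
                         stable_iters: int = 50,
                         seed: int = 0) -> ClusterResult:
    """Cluster a dissimilarity matrix by affinity-propagation message passing.

    The similarity matrix is the negated dissimilarity with the diagonal set
    to ``preference`` (default: median off-diagonal similarity, which tends
    to yield a moderate number of clusters).  Responsibility/availability
    updates run with the given damping until the exemplar set is unchanged
    for ``stable_iters`` consecutive iterations or ``max_iter`` is reached;
    a result is returned either way, with ``converged`` flagging which.
    """
    dissim = np.asarray(dissim, dtype=float)
    if dissim.ndim != 2 or dissim.shape[0] != dissim.shape[1]:
        raise MalformedInputError("dissimilarity matrix must be square")
    if not np.allclose(dissim, dissim.T, atol=1e-8):
        raise MalformedInputError("dissimilarity matrix must be symmetric")
    if not 0.5 <= damping < 1.0:
        raise DomainError("damping must lie in [0.5, 1)")
    n = dissim.shape[0]
    if n == 1:
        return ClusterResult(labels=np.zeros(1, dtype=int),
                             exemplars=np.zeros(1, dtype=int),
                             n_iter=0, converged=True)
    S = -dissim.copy()
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    # tiny seeded jitter removes exact ties that would make messages oscillate
    rng = np.random.default_rng(seed)
    scale = max(np.ptp(S), 1.0)
    S = S + 1e-12 * scale * rng.standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    prev_exemplars: frozenset = frozenset()
    stable = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        max1_idx = np.argmax(AS, axis=1)
        max1 = AS[idx, max1_idx]
        AS[idx, max1_idx] = -np.inf
        max2 = AS.max(axis=1)
        Rnew = S - max1[:, None]
        Rnew[idx, max1_idx] = S[idx, max1_idx] - max2
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rpos = np.maximum(R, 0.0)
        np.fill_diagonal(Rpos, R.diagonal())
        col_sums = Rpos.sum(axis=0)
        Anew = np.minimum(0.0, col_sums[None, :] - Rpos)
        np.fill_diagonal(Anew, col_sums - Rpos.diagonal())
        A = damping * A + (1.0 - damping) * Anew

        exemplars = frozenset(np.flatnonzero((A + R).diagonal() > 0))
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= stable_iters:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    ex = np.flatnonzero((A + R).diagonal() > 0)
    if ex.size == 0:
        ex = np.array([int(np.argmax((A + R).diagonal()))])
    labels = ex[np.argmax(S[:, ex], axis=1)]
    labels[ex] = ex  # exemplars label themselves
    # relabel to consecutive cluster indices ordered by exemplar index
    lookup = {e: k for k, e in enumerate(ex)}
    labels = np.array([lookup[e] for e in labels], dtype=int)
    return ClusterResult(labels=labels, exemplars=ex.astype(int),
                         n_iter=n_iter, converged=converged)
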