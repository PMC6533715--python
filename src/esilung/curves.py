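"""Maximal expiratory flow-volume (MEFV) curves and descending-limb geometry.

A forced expiration traced as flow (L/s) against expired volume (L) rises
quickly to the peak expiratory flow (PEF) and then descends towards zero as
the lungs empty.  Everything downstream of this module works on the
*descending limb only*, rescaled to a unit square: ``u`` is the remaining
fraction of the descending-limb volume (1 at the PEF point, 0 at
end-expiration) and ``q`` is flow as a fraction of PEF.  The rescaling is
what makes the severity score independent of body size, effort magnitude
and percent-predicted reference equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import DegenerateCurveError, DomainError, MalformedInputError

#: flow at end-expiration must have decayed to this fraction of PEF
FLOW_TAIL_FRACTION = 0.05

MIN_SAMPLES = 30


@dataclass(frozen=True)
class MEFVCurve:
    """One forced expiration sampled as (expired volume, flow) pairs.

    Parameters
    ----------
    volume_l : ndarray
        Expired volume in litres, monotone non-decreasing.  Only volume
        *differences* matter to the severity score, so an offset origin
        (e.g. absolute thoracic volume) is accepted.
    flow_l_s : ndarray
        Expiratory flow in L/s, non-negative, same length.
    validate : bool
        Skip invariant checks when False (used for deliberately degenerate
        fixtures, e.g. constant-flow test curves).
    """

    volume_l: np.ndarray
    flow_l_s: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.volume_l, dtype=float)
        q = np.asarray(self.flow_l_s, dtype=float)
        object.__setattr__(self, "volume_l", v)
        object.__setattr__(self, "flow_l_s", q)
        if v.ndim != 1 or q.ndim != 1 or v.shape != q.shape:
            raise MalformedInputError("volume and flow must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(q))):
            raise MalformedInputError("volume and flow samples must be finite")
        if not self.validate:
            return
        if v.size < MIN_SAMPLES:
            raise MalformedInputError(f"need at least {MIN_SAMPLES} samples, got {v.size}")
        if np.any(np.diff(v) < 0):
            raise MalformedInputError("expired volume must be monotone non-decreasing")
        if np.any(q < 0):
            raise MalformedInputError("flow samples must be non-negative")
        if v[-1] - v[0] <= 0:
            raise DegenerateCurveError("volume span (FVC) must be positive")
        pef = q.max()
        if pef <= 0:
            raise DegenerateCurveError("peak expiratory flow must be positive")
        if q[-1] > FLOW_TAIL_FRACTION * pef + 1e-12:
            raise MalformedInputError(
                "final flow exceeds 5% of PEF: expiration not carried to completion"
            )
        peak_idx = np.flatnonzero(q == pef)
        if peak_idx[-1] - peak_idx[0] != peak_idx.size - 1:
            raise MalformedInputError("flow maximum must form a single contiguous region")

    @property
    def n_samples(self) -> int:
        return int(self.volume_l.size)

    @property
    def pef(self) -> float:
        """Peak expiratory flow (L/s)."""
        return float(self.flow_l_s.max())

    @property
    def pef_index(self) -> int:
        """Index of the PEF point: first sample attaining the global maximum."""
        return int(np.argmax(self.flow_l_s))

    @property
    def fvc(self) -> float:
        """Forced vital capacity (L): total expired-volume span."""
        return float(self.volume_l[-1] - self.volume_l[0])


@dataclass(frozen=True)
class NormalizedLimb:
    """Descending limb of an MEFV curve mapped onto the unit square.

    ``u`` runs from 1 (PEF point) down to 0 (end-expiration) in stored
    order; ``q`` is flow / PEF on the same grid.
    """

    u: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "q", q)
        if u.shape != q.shape or u.ndim != 1:
            raise MalformedInputError("u and q must be 1-D arrays of equal length")
        if np.any(np.diff(u) >= 0):
            raise MalformedInputError("u must be strictly decreasing (PEF -> end-expiration)")
        if abs(q[0] - 1.0) > 1e-9:
            raise MalformedInputError("q at u=1 must equal 1")
        if q[-1] > FLOW_TAIL_FRACTION + 1e-9:
            raise MalformedInputError("q at u=0 must not exceed 0.05")
        if np.any(q < -1e-12):
            raise MalformedInputError("q must be non-negative")

    @property
    def n_grid(self) -> int:
        return int(self.u.size)


def extract_descending_limb(curve: MEFVCurve, n_grid: int = 100) -> NormalizedLimb:
    """Normalize the descending limb of ``curve`` onto a uniform u-grid.

    The limb is built from the samples at/after the PEF point, with
    ``u = (FVC - V) / (FVC - V_PEF)`` and ``q = Q / PEF``, then resampled
    by linear interpolation onto ``n_grid`` uniformly spaced points
    including both u=1 and u=0.
    """
    if n_grid < 20:
        raise DomainError(f"n_grid must be >= 20, got {n_grid}")
    i0 = curve.pef_index
    if i0 == curve.n_samples - 1:
        raise DegenerateCurveError("flow maximum at the last sample: no descending limb")
    v = curve.volume_l[i0:]
    f = curve.flow_l_s[i0:]
    pef = curve.pef
    v_end = curve.volume_l[-1]
    span = v_end - v[0]
    if span <= 0:
        raise DegenerateCurveError("no volume expired past the PEF point")
    u = (v_end - v) / span  # 1 -> 0, non-increasing
    q = f / pef

    # ascending order for interpolation; drop duplicate u (volume plateaus)
    u_asc, first_idx = np.unique(u[::-1], return_index=True)
    q_asc = q[::-1][first_idx]
    grid = np.linspace(0.0, 1.0, n_grid)
    q_grid = np.interp(grid, u_asc, q_asc)
    q_grid = np.clip(q_grid, 0.0, None)
    q_grid[-1] = 1.0  # the PEF sample itself; exact by construction
    return NormalizedLimb(u=grid[::-1].copy(), q=q_grid[::-1].copy())


@dataclass(frozen=True)
class SpirometricIndices:
    """FEV1/FVC/PEF reconstructed from a sampled MEFV curve.

    ``fev1_capped`` flags curves whose reconstructed expiratory time never
    reaches 1 s, in which case FEV1 is reported as FVC.
    """

    fev1: float
    fvc: float
    pef: float
    fev1_fvc_ratio: float
    fev1_capped: bool = False


def spirometric_indices(curve: MEFVCurve) -> SpirometricIndices:
    """Reconstruct FEV1, FVC and PEF by time-integrating the flow trace.

    Time is recovered as t(V) = integral of dV'/Q(V') (trapezoid rule on
    the samples) and the clock is started at the back-extrapolated time
    zero — the standard spirometric convention in which the tangent at
    peak flow is extrapolated back to zero expired volume — so that the
    effort-dependent early rise does not leak into the timed volume.  FEV1
    is the volume expired at 1 s past that origin, by linear interpolation.
    Zero-flow endpoint samples borrow the reciprocal flow of their nearest
    positive-flow neighbour so the integral stays finite.
    """
    v = curve.volume_l
    f = curve.flow_l_s
    pos = f > 0
    if not np.any(pos):
        raise DegenerateCurveError("curve has no positive flow")
    recip = np.empty_like(f)
    recip[pos] = 1.0 / f[pos]
    if not np.all(pos):
        idx = np.flatnonzero(pos)
        # nearest positive neighbour for each zero-flow sample
        zero_idx = np.flatnonzero(~pos)
        nearest = idx[np.argmin(np.abs(zero_idx[:, None] - idx[None, :]), axis=1)]
        recip[zero_idx] = recip[nearest]
    t = cumulative_trapezoid(recip, v, initial=0.0)
    fvc = curve.fvc
    pef = curve.pef
    i0 = curve.pef_index
    t_zero = t[i0] - (v[i0] - v[0]) / pef  # back-extrapolated time zero
    t_one = max(t_zero, 0.0) + 1.0
    if t[-1] < t_one:
        fev1, capped = fvc, True
    else:
        fev1 = float(np.interp(t_one, t, v) - v[0])
        capped = False
    return SpirometricIndices(
        fev1=float(fev1),
        fvc=fvc,
        pef=pef,
        fev1_fvc_ratio=float(fev1 / fvc),
        fev1_capped=capped,
    )
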