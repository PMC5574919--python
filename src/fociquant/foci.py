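"""Foci segmentation by fuzzy c-means clustering of grayscale levels.

Each nucleus sub-image is clustered into ``c`` intensity classes (default
three) by fuzzy c-means (FCM) on the one-dimensional grayscale feature.
Pixels are hard-assigned to their maximum-membership cluster, and the
cluster with the highest centroid is taken as the foci class.  Because the
clustering is run per nucleus, the foci threshold adapts to each cell's own
background — the property that makes a single global threshold unnecessary.
The number of clusters is the only structural parameter.

FCM minimizes  J = Σ_k Σ_i u_ik^m d_ik²  subject to Σ_i u_ik = 1, with
d_ik = |x_k − v_i|, by alternating the membership update
u_ik = 1 / Σ_j (d_ik/d_jk)^(2/(m−1)) and the centroid update
v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m.  The implementation clusters the unique
intensity values weighted by their pixel counts, which is exactly
equivalent to clustering every pixel and much faster on integer images.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional

import numpy as np

from .exceptions import ClusterDegeneracyError

#: pixels with centroid distance below this (in [0,1]-normalized units) get
#: crisp membership, avoiding the 1/d singularity at d = 0
_SINGULARITY_EPS = 1e-12


@dataclass
class FCMResult:
    """Converged fuzzy c-means clustering of a 1-D intensity sample.

    ``centroids`` are in the original intensity units, sorted ascending,
    with membership columns permuted to match.  ``objective`` (and its
    per-iteration trace) is evaluated on intensities normalized to [0, 1].
    """

    centroids: np.ndarray
    memberships: np.ndarray  # (n_samples, c), rows sum to 1
    objective: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = dc_field(default_factory=lambda: np.empty(0))

    def hard_labels(self) -> np.ndarray:
        """Defuzzified labels: argmax membership, ties to the higher cluster."""
        c = self.memberships.shape[1]
        return c - 1 - np.argmax(self.memberships[:, ::-1], axis=1)


def _init_centroids(xs: np.ndarray, c: int, init: str, rng: np.random.Generator) -> np.ndarray:
    if init == "quantile":
        q = (2 * np.arange(c) + 1) / (2 * c)
        v = np.quantile(xs, q)
        if len(np.unique(v)) < c:  # heavily skewed data can collapse quantiles
            v = np.linspace(xs.min(), xs.max(), c)
    elif init == "random":
        v = rng.choice(np.unique(xs), size=c, replace=False)
    else:
        raise ValueError(f"unknown init {init!r}")
    return np.sort(v.astype(np.float64))


def fcm_cluster(
    intensities,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    init: str = "quantile",
    seed: Optional[int] = None,
) -> FCMResult:
    """Fuzzy c-means clustering of intensity values (1-D feature space).

    Parameters
    ----------
    intensities
        Flat sequence of pixel intensities.
    c
        Number of clusters (>= 2).
    m
        Fuzziness exponent (> 1); 2.0 is the conventional choice.
    tol
        Convergence tolerance on the maximum centroid shift, in intensity
        units normalized to [0, 1].
    init
        ``"quantile"`` (deterministic; centroids start at the
        (2i+1)/(2c) quantiles) or ``"random"`` (seeded draw of distinct
        observed values).

    Raises
    ------
    ClusterDegeneracyError
        If there are fewer than ``c`` distinct intensity values.

    Notes
    -----
    Non-convergence within ``max_iter`` is flagged on the result, not fatal.
    The objective is non-increasing across iterations by construction.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    uniq, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if uniq.size < c:
        raise ClusterDegeneracyError(
            f"{uniq.size} distinct intensity values < c = {c} clusters"
        )

    lo, hi = uniq[0], uniq[-1]
    scale = hi - lo
    us = (uniq - lo) / scale  # unique values, normalized to [0, 1]
    w = counts.astype(np.float64)

    rng = np.random.default_rng(seed)
    v = _init_centroids(us, c, init, rng)

    exponent = 2.0 / (m - 1.0)
    trace: List[float] = []
    converged = False
    n_iter = 0
    memberships_u = None
    for n_iter in range(1, max_iter + 1):
        d = np.abs(us[:, None] - v[None, :])  # (n_unique, c)
        zero = d < _SINGULARITY_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-exponent)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_with_zero = zero.any(axis=1)
        if rows_with_zero.any():
            u[rows_with_zero] = zero[rows_with_zero] / zero[rows_with_zero].sum(
                axis=1, keepdims=True
            )
        um = u ** m
        wm = w[:, None] * um
        v_new = (wm * us[:, None]).sum(axis=0) / wm.sum(axis=0)
        # objective with the just-updated memberships and new centroids
        d_new = np.abs(us[:, None] - v_new[None, :])
        trace.append(float((wm * d_new**2).sum()))
        shift = np.max(np.abs(v_new - v))
        v = v_new
        memberships_u = u
        if shift < tol:
            converged = True
            break

    order = np.argsort(v, kind="stable")
    v = v[order]
    memberships_u = memberships_u[:, order]
    centroids = v * scale + lo
    memberships = memberships_u[inverse]
    return FCMResult(
        centroids=centroids,
        memberships=memberships,
        objective=trace[-1],
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


@dataclass
class FociImage:
    """Extracted foci of one nucleus/channel: original intensities on the
    foci support, zero elsewhere.  ``support`` is the set S of foci pixels
    (S_G when the channel is the DSB marker)."""

    grid: np.ndarray
    support: np.ndarray  # bool, same shape
    flags: List[str] = dc_field(default_factory=list)
    fcm: Optional[FCMResult] = None

    @classmethod
    def empty(cls, shape, dtype=np.uint16, flags=None) -> "FociImage":
        return cls(
            grid=np.zeros(shape, dtype=dtype),
            support=np.zeros(shape, dtype=bool),
            flags=list(flags or []),
        )


def extract_foci(
    sub: np.ndarray,
    nucleus_mask: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    init: str = "quantile",
    seed: Optional[int] = None,
) -> FociImage:
    """Segment foci in a nucleus sub-image by intensity-level FCM.

    Only pixels inside ``nucleus_mask`` are clustered (the zero padding
    outside the mask would otherwise consume a cluster).  Each pixel goes to
    its maximum-membership cluster; the cluster with the highest centroid is
    the foci class.  A nucleus with fewer than ``c`` distinct intensities
    yields an empty, flagged FociImage rather than an error.
    """
    sub = np.asarray(sub)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if sub.shape != nucleus_mask.shape:
        raise ValueError("sub-image and mask shapes differ")
    values = sub[nucleus_mask]
    try:
        result = fcm_cluster(
            values, c=c, m=m, tol=tol, max_iter=max_iter, init=init, seed=seed
        )
    except ClusterDegeneracyError:
        return FociImage.empty(sub.shape, dtype=sub.dtype, flags=["degenerate_fcm"])

    labels = result.hard_labels()
    support = np.zeros(sub.shape, dtype=bool)
    support[nucleus_mask] = labels == (c - 1)
    support &= sub > 0  # zero-intensity pixels carry no foci signal
    grid = np.where(support, sub, 0).astype(sub.dtype, copy=False)
    flags = [] if result.converged else ["fcm_not_converged"]
    return FociImage(grid=grid, support=support, flags=flags, fcm=result)
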