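"""Step detection by singular-spectrum-transformation change-point scoring.

For every interior time point the SST compares the signal's behaviour in
a window just before the point with a window of the same length just
after it.  Each window is delay-embedded into a trajectory matrix whose
left singular vectors span the local signal subspace; the change-point
score is one minus the largest squared cosine between the leading future
singular vector and the span of the top past singular vectors.  The
score lives in [0, 1]: it is 0 when past and future dynamics share a
subspace and approaches 1 when the future direction is orthogonal to
everything seen before.

Detection then thresholds each acceleration axis at a fraction of that
axis's maximum score, takes a 2-of-3 majority vote across the axes, and
converts maximal runs of the vote into step intervals.

This subspace-angle score is one member of the SST family; note that it
is scale invariant (subspace angles ignore amplitude), so broadband
sensor noise must be removed by the low-pass stage first — on raw noisy
input the score saturates everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imu_io import ImuRecording, StepInterval
from .signal_prep import FilterSpec, low_pass

__all__ = [
    "SstConfig",
    "sst_score",
    "per_signal_mask",
    "majority_vote",
    "mask_to_intervals",
    "detect_cpd",
]

#: a trajectory matrix whose (column-centred) Frobenius norm falls below
#: this fraction of the series' standard deviation carries no dynamics
#: and scores 0 rather than a meaningless subspace angle.
_DEGENERATE_REL_TOL = 1e-7

CPD_CHANNELS = ("Acc_X", "Acc_Y", "Acc_Z")


@dataclass(frozen=True)
class SstConfig:
    """SST detector configuration.

    ``window`` (before/after window length, in samples) and the
    5 %-of-maximum threshold are fixed by the method; the embedding
    dimension and subspace rank are free parameters of the SST family,
    chosen small enough to be feasible inside a 10-sample window.
    """

    window: int = 10
    embed_dim: int = 5
    n_components: int = 2
    threshold_fraction: float = 0.05
    filter: FilterSpec = field(default_factory=FilterSpec)

    def __post_init__(self) -> None:
        if self.window < 1 or self.embed_dim < 1 or self.n_components < 1:
            raise ValueError("window, embed_dim, n_components must be >= 1")
        if self.embed_dim > self.window:
            raise ValueError("embed_dim must not exceed window")
        if self.n_components > self.embed_dim:
            raise ValueError("n_components must not exceed embed_dim")
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")


def sst_score(series, cfg: SstConfig = SstConfig()) -> np.ndarray:
    """Change-point score for one series; edges without full windows score 0.

    For time point ``t`` the past trajectory matrix embeds samples
    ``[t - window, t)`` and the future matrix samples ``[t, t + window)``
    (column-wise delay embedding of dimension ``embed_dim``).  Columns of
    each trajectory matrix are centred before the SVD so the score
    responds to dynamics, not to DC level: scores are invariant under
    affine maps ``a*x + b`` of the input.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    L, K, r = cfg.window, cfg.embed_dim, cfg.n_components
    if n < 2 * (L + K):
        raise ValueError(
            f"series of length {n} too short for SST with window {L} and "
            f"embedding dimension {K} (need >= {2 * (L + K)})"
        )
    scores = np.zeros(n)
    scale = float(np.std(x))
    if scale == 0.0:
        return scores

    # All trajectory matrices at once: traj[i] embeds samples [i, i+L).
    lagged = sliding_window_view(x, K)              # (n-K+1, K)
    traj = sliding_window_view(lagged, L - K + 1, axis=0)  # (n-L+1, K, L-K+1)
    traj = traj - traj.mean(axis=1, keepdims=True)  # centre each column
    fro = np.sqrt((traj ** 2).sum(axis=(1, 2)))
    tol = _DEGENERATE_REL_TOL * scale

    u, s, _ = np.linalg.svd(traj, full_matrices=False)

    # valid score positions: past matrix starts at t-L >= 0, future matrix
    # at t must fit, i.e. t <= n - L.
    ts = np.arange(L, n - L + 1)
    past, future = ts - L, ts
    defined = (fro[past] > tol) & (fro[future] > tol)

    # effective past rank: never project onto numerically-null directions
    s_past = s[past]
    rank = (s_past > s_past[:, :1] * 1e-10).sum(axis=1)
    r_eff = np.minimum(r, np.maximum(rank, 1))

    u_future = u[future, :, 0]                       # leading future vector
    proj = np.einsum("ik,ikj->ij", u_future, u[past])  # cosines, all comps
    comp_mask = np.arange(s.shape[1])[None, :] < r_eff[:, None]
    cos2 = ((proj ** 2) * comp_mask).sum(axis=1)
    vals = np.clip(1.0 - cos2, 0.0, 1.0)
    scores[ts] = np.where(defined, vals, 0.0)
    return scores


def per_signal_mask(scores, threshold_fraction: float) -> np.ndarray:
    """True where the score is strictly above ``fraction * max(score)``.

    An all-zero score series yields an all-false mask, and with fraction
    1.0 the strict inequality makes the mask false everywhere.
    """
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0):
        raise ValueError("scores must be non-negative")
    m = s.max(initial=0.0)
    if m <= 0:
        return np.zeros(len(s), dtype=bool)
    return s > threshold_fraction * m


def majority_vote(masks) -> np.ndarray:
    """True where at least two of the three per-axis masks are true."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) != 3:
        raise ValueError(f"expected exactly three masks, got {len(masks)}")
    if len({len(m) for m in masks}) != 1:
        raise ValueError("mask lengths differ")
    return np.sum(masks, axis=0) >= 2


def mask_to_intervals(mask) -> list[StepInterval]:
    """Maximal runs of True become half-open intervals, in order."""
    m = np.asarray(mask, dtype=bool)
    if len(m) == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [StepInterval(int(a), int(b)) for a, b in zip(starts, ends)]


def detect_cpd(rec: ImuRecording, cfg: SstConfig = SstConfig()) -> list[StepInterval]:
    """Run the full SST pipeline on the three acceleration axes."""
    rec.require_channels(CPD_CHANNELS)
    masks = []
    for name in CPD_CHANNELS:
        filtered = low_pass(rec.channel(name), cfg.filter, rec.sample_rate_hz)
        scores = sst_score(filtered, cfg)
        masks.append(per_signal_mask(scores, cfg.threshold_fraction))
    return mask_to_intervals(majority_vote(masks))
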