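"""Cluster-based permutation statistics for time-resolved group data.

One-sample (or paired-difference) t tests at each time point are
thresholded at a cluster-forming level; contiguous supra-threshold
clusters are scored by their mass (summed t) and compared with a null
distribution of maximum cluster masses obtained by flipping the sign
of whole subjects.  When the number of distinct sign patterns 2^S does
not exceed the requested permutation count the enumeration is
exhaustive (exact test); otherwise random sign flips are drawn from a
seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["Cluster", "ClusterTestResult", "cluster_permutation"]


@dataclass
class Cluster:
    start: int          # first time index
    stop: int           # last time index (inclusive)
    mass: float         # summed t values (signed)
    p: float            # corrected p value


@dataclass
class ClusterTestResult:
    tvals: np.ndarray
    threshold: float
    clusters: list
    n_perm: int
    exhaustive: bool

    @property
    def significant(self):
        return [c for c in self.clusters if c.p <= 0.05]


def _t_onesample(x: np.ndarray) -> np.ndarray:
    s = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = x.mean(axis=0) / (sd / np.sqrt(s))
    return np.where(sd > 0, t, 0.0)  # degenerate (constant) data carries no evidence


def _find_clusters(t: np.ndarray, thresh: float):
    out = []
    for sign in (1.0, -1.0):
        b = sign * t > thresh
        if not b.any():
            continue
        d = np.diff(np.r_[0, b.astype(int), 0])
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1) - 1
        for a, z in zip(starts, stops):
            out.append((a, z, float(t[a:z + 1].sum())))
    return sorted(out, key=lambda c: c[0])


def _max_cluster_mass(t_mat: np.ndarray, thresh: float) -> np.ndarray:
    """Max absolute cluster mass per row of a (perms x times) t matrix."""
    P, T = t_mat.shape
    out = np.zeros(P)
    pad = np.zeros((P, 1))
    for sign in (1.0, -1.0):
        b = sign * t_mat > thresh
        v = np.where(b, sign * t_mat, 0.0)
        bp = np.concatenate([b, pad.astype(bool)], axis=1).ravel()
        vp = np.concatenate([v, pad], axis=1).ravel()
        db = np.diff(np.r_[0, bp.astype(np.int8)])
        starts = np.flatnonzero(db == 1)
        if len(starts) == 0:
            continue
        stops = np.flatnonzero(np.diff(np.r_[bp.astype(np.int8), 0]) == -1)
        csum = np.r_[0.0, np.cumsum(vp)]
        masses = csum[stops + 1] - csum[starts]
        rows = starts // (T + 1)
        np.maximum.at(out, rows, masses)
    return out


def cluster_permutation(
    data: np.ndarray,
    data_b: np.ndarray | None = None,
    n_perm: int = 10_000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-corrected test of a subjects x times array against zero.

    Pass ``data_b`` for a paired-difference design (the test runs on
    ``data - data_b``).  The cluster-forming threshold is the two-sided
    t critical value at ``cluster_alpha``; cluster p values are the
    proportion of sign-flip permutations whose maximum cluster mass
    reaches the observed cluster's |mass|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(data, dtype=float)
    if data_b is not None:
        x = x - np.asarray(data_b, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be subjects x times with >= 2 subjects")
    S, T = x.shape
    thresh = stats.t.ppf(1.0 - cluster_alpha / 2.0, S - 1)
    t_obs = _t_onesample(x)
    found = _find_clusters(t_obs, thresh)

    exhaustive = 2 ** S <= n_perm
    if exhaustive:
        signs = np.array([[1 if (i >> j) & 1 else -1 for j in range(S)]
                          for i in range(2 ** S)], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    # sign flips leave per-subject second moments unchanged
    sumsq = (x ** 2).sum(axis=0)
    means = signs @ x / S
    var = (sumsq[None, :] - S * means ** 2) / (S - 1)
    var = np.maximum(var, 1e-300)
    t_perm = means / np.sqrt(var / S)
    null_max = _max_cluster_mass(t_perm, thresh)

    clusters = []
    for a, z, mass in found:
        hits = int(np.sum(null_max >= abs(mass)))
        if exhaustive:
            p = hits / len(signs)
        else:
            p = (1 + hits) / (len(signs) + 1)
        clusters.append(Cluster(start=int(a), stop=int(z), mass=mass, p=float(p)))
    return ClusterTestResult(tvals=t_obs, threshold=float(thresh), clusters=clusters,
                             n_perm=len(signs), exhaustive=exhaustive)
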