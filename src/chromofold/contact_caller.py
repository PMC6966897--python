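"""Calling specific pairwise Hi-C contacts against a random-polymer null.

Measured Hi-C counts are first quantile-normalized onto the contact-frequency
scale of the uniform random polymer ensemble.  A null distribution over
random contact frequencies is then built by a Bag of Little Bootstraps (BLB)
resampling procedure over the ensemble: each outer replicate draws a small
subset of conformations (size n^gamma) without replacement and resamples it
multinomially back to full ensemble size.  A contact (i, j) receives an
add-one p-value equal to the proportion of replicate frequencies at the same
genomic distance that reach its normalized frequency; Benjamini-Hochberg FDR
across all tested pairs yields the *specific* set (q < alpha).

The specific set is finally coarse-grained: pairs are clustered in (i, j)
index space (average-linkage hierarchical clustering, Chebyshev metric) and
one representative per cluster (the member with smallest p) is retained, with
a default retention of roughly 5% of the specific calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .model_io import HiCMatrix
from .polymer import Ensemble, contact_frequency

logger = logging.getLogger(__name__)

#: diagonals |i-j| <= MIN_DIAGONAL_EXCLUDED are never tested (contacts within
#: 10 kb at 5-kb bins are dominated by chain connectivity)
MIN_DIAGONAL_EXCLUDED = 2


@dataclass
class NullDistribution:
    """Per-genomic-distance collections of bootstrap replicate frequencies.

    ``strata[s]`` is the sorted pool of replicate contact frequencies for all
    bin pairs at genomic distance ``s`` (bins); pooling within a stratum is
    valid because the random-folding null is translation invariant at fixed
    distance.
    """

    strata: dict
    n_outer: int
    subset_exponent: float
    seed: int | None = None

    def p_value(self, distance: int, value: float) -> float:
        """Add-one p: proportion of null frequencies at `distance` >= value."""
        if distance not in self.strata:
            raise KeyError(f"no null stratum at genomic distance {distance}")
        pool = self.strata[distance]
        n_ge = len(pool) - np.searchsorted(pool, value, side="left")
        return (1.0 + n_ge) / (1.0 + len(pool))


@dataclass
class ContactCall:
    pair: tuple
    normalized_frequency: float
    p_value: float
    q_value: float = 1.0
    specific: bool = False


@dataclass
class CoarseGrainedContacts:
    retained: list
    clusters: dict
    retention_fraction: float


def quantile_normalize(hic: HiCMatrix, null_ensemble: Ensemble,
                       null_freq: np.ndarray | None = None) -> HiCMatrix:
    """Rank-map measured off-diagonal counts onto the null frequency scale.

    Ties in the measured matrix share the averaged target value; the mapping
    is monotone, so measured rank order is never inverted (distinct measured
    values may share a target where the null distribution itself has ties).
    The diagonal is set to 1 (the ensemble convention: a bin always contacts
    itself).
    """
    if null_freq is None:
        null_freq = contact_frequency(null_ensemble)
    n = hic.n_bins
    iu = np.triu_indices(n, k=1)
    measured = hic.values[iu]
    if np.ptp(measured) == 0:
        raise ValueError("constant measured matrix: ranks undefined")
    target = np.sort(null_freq[iu])
    ranks = rankdata(measured, method="average")  # 1..N, fractional for ties
    mapped = np.interp(ranks, np.arange(1, len(target) + 1), target)
    out = np.zeros((n, n))
    out[iu] = mapped
    out = out + out.T
    np.fill_diagonal(out, 1.0)
    return HiCMatrix(hic.locus, out, normalized=True)


def build_null(null_ensemble: Ensemble, n_outer: int = 1000,
               subset_exponent: float = 0.7, seed: int = 0) -> NullDistribution:
    """Bag of Little Bootstraps null over per-distance contact frequencies.

    Each outer replicate draws ceil(n^gamma) conformations without
    replacement and a multinomial resample (probabilities proportional to the
    importance weights of the subset) back to full ensemble size n; the
    resulting per-pair contact frequencies are pooled per genomic distance.
    """
    if n_outer < 100:
        warnings.warn("n_outer < 100: null distribution tails will be unstable")
    n_conf = len(null_ensemble)
    n_bins = null_ensemble.n_bins
    b = max(2, int(np.ceil(n_conf ** subset_exponent)))
    b = min(b, n_conf)
    rng = np.random.default_rng(seed)
    t = null_ensemble.params.contact_threshold
    iu = np.triu_indices(n_bins, k=1)
    # contact indicator per (pair, conformation)
    c = null_ensemble.coords
    ind = np.empty((len(iu[0]), n_conf), dtype=np.float32)
    chunk = max(1, int(2e7 // (n_bins ** 2)))
    for s in range(0, n_conf, chunk):
        blk = c[s:s + chunk]
        d2 = ((blk[:, :, None, :] - blk[:, None, :, :]) ** 2).sum(-1)
        ind[:, s:s + chunk] = (d2 <= t * t)[:, iu[0], iu[1]].T
    w_all = null_ensemble.weights
    dist = (iu[1] - iu[0]).astype(int)
    reps = np.empty((len(iu[0]), n_outer), dtype=np.float32)
    for r in range(n_outer):
        subset = rng.choice(n_conf, size=b, replace=False)
        p = w_all[subset]
        p = p / p.sum()
        m = rng.multinomial(n_conf, p).astype(np.float32)
        reps[:, r] = ind[:, subset] @ m / n_conf
    strata = {}
    for s in range(1, n_bins):
        pool = reps[dist == s].ravel()
        strata[s] = np.sort(pool)
    logger.info("BLB null: n_outer=%d subset=%d of %d seed=%s",
                n_outer, b, n_conf, seed)
    return NullDistribution(strata, n_outer, subset_exponent, seed=seed)


def call_specific(hic_norm: HiCMatrix, null: NullDistribution,
                  alpha: float = 0.05,
                  exclude_diagonals: int = MIN_DIAGONAL_EXCLUDED) -> list:
    """Per-pair add-one p-values against the distance-matched null, BH FDR.

    Pairs with |i-j| <= ``exclude_diagonals`` are not tested.
    """
    if not hic_norm.normalized:
        raise ValueError("call_specific expects a quantile-normalized matrix")
    n = hic_norm.n_bins
    calls = []
    for i in range(n):
        for j in range(i + 1 + exclude_diagonals, n):
            p = null.p_value(j - i, hic_norm.values[i, j])
            calls.append(ContactCall((i, j), float(hic_norm.values[i, j]), p))
    if not calls:
        return calls
    pvals = np.array([c.p_value for c in calls])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for c, q, rej in zip(calls, qvals, reject):
        c.q_value = float(q)
        c.specific = bool(rej)
    n_spec = sum(c.specific for c in calls)
    logger.info("call_specific: %d of %d pairs specific at FDR %g",
                n_spec, len(calls), alpha)
    return calls


def coarse_grain(specific_calls, retention_fraction: float = 0.05,
                 method: str = "average") -> CoarseGrainedContacts:
    """Cluster the specific pairs in (i, j) space and keep one per cluster.

    Hierarchical clustering (default average linkage, Chebyshev metric on bin
    indices) cut to ``round(retention_fraction * N)`` clusters, at least 1.
    The representative of a cluster is its member with the smallest p-value;
    ties broken by larger normalized frequency, then lexicographic pair
    order.
    """
    calls = [c for c in specific_calls if c.specific]
    if not calls:
        raise ValueError("no specific calls to coarse-grain")
    if not (0 < retention_fraction <= 1):
        raise ValueError("retention_fraction must be in (0, 1]")
    n = len(calls)
    n_keep = max(1, round(retention_fraction * n))
    if n_keep >= n:
        clusters = {c.pair: k for k, c in enumerate(calls)}
        return CoarseGrainedContacts([c.pair for c in calls], clusters,
                                     retention_fraction)
    pts = np.array([c.pair for c in calls], dtype=float)
    z = linkage(pts, method=method, metric="chebyshev")
    labels = fcluster(z, t=n_keep, criterion="maxclust")
    clusters = {c.pair: int(lab) for c, lab in zip(calls, labels)}
    retained = []
    for lab in sorted(set(labels)):
        members = [c for c, l in zip(calls, labels) if l == lab]
        best = min(members,
                   key=lambda c: (c.p_value, -c.normalized_frequency, c.pair))
        retained.append(best.pair)
    retained.sort()
    logger.info("coarse_grain: retained %d of %d specific calls (%.1f%%)",
                len(retained), n, 100.0 * len(retained) / n)
    return CoarseGrainedContacts(retained, clusters, retention_fraction)
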