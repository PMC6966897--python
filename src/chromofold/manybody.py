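"""Many-body (>=3) chromatin interaction calling and landscape summaries.

A many-body interaction is a set of k >= 3 bins whose pairwise Euclidean
distances are all within the contact threshold (80 nm) - a clique of the
contact graph.  Two flavours are analysed: exact 3-bodies (all triangles, not
required to be maximal) and maximal complexes (maximal cliques, k >= 3).
Each complex is characterised by its principal loop (the longest genomic span
between two members, whose endpoints are the anchors) and minor loop (the
shortest span).

Specific complexes are those whose frequency in the reconstructed single-cell
ensemble exceeds what bootstrap resampling of a uniform random ensemble
produces within the same stratum - (principal span, minor span) for 3-bodies,
(clique size class, principal span) for maximal complexes - with BH FDR
control at 0.05.

Concordance helpers score complexes against proximity-cluster data (sets of
co-captured bins): the coverage fraction of a complex is the proportion of
clusters containing all of its members (or both principal anchors), and a
label-permutation test compares specific vs non-specific per-span median
coverages.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from statsmodels.stats.multitest import multipletests

from .model_io import AnnotationTrack, ClusterData
from .polymer import Ensemble
from .ensemble_builder import ReconstructedEnsemble

logger = logging.getLogger(__name__)

#: pairs closer than this many bins are not clique edges (chain-connectivity
#: triangles between bonded neighbours are ubiquitous and uninformative)
DEFAULT_MIN_SEPARATION = 2

_SIZE_CLASSES = (3, 4, 5, 6)  # 6 == "6 or more"


@dataclass
class ManyBodyComplex:
    members: tuple          # sorted bin indices, k >= 3
    maximal: bool
    principal_span: int     # bp
    minor_span: int         # bp
    anchors: tuple          # bin pair realizing the principal span

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ManyBodyCall:
    signature: tuple
    frequency: float
    p_value: float
    q_value: float = 1.0
    specific: bool = False
    stratum: tuple = ()


@dataclass
class StratifiedNull:
    """Pooled bootstrap complex frequencies per stratum."""

    strata: dict            # stratum key -> sorted array of frequencies
    n_replicates: int
    mode: str               # "3body" | "maximal"
    seed: int | None = None


def _spans(members, bin_size):
    members = sorted(members)
    pairs = [(a, b) for ai, a in enumerate(members) for b in members[ai + 1:]]
    principal = max(pairs, key=lambda p: (p[1] - p[0], (p[0], p[1])))
    # deterministic tie-break: among pairs with maximal span the
    # lexicographically smallest pair wins
    best_span = principal[1] - principal[0]
    anchors = min(p for p in pairs if p[1] - p[0] == best_span)
    minor = min(b - a for a, b in pairs)
    return best_span * bin_size, minor * bin_size, anchors


def _contact_graph(coords: np.ndarray, threshold: float,
                   min_separation: int) -> ig.Graph:
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    adj = d2 <= threshold * threshold
    ii, jj = np.triu_indices(n, k=min_separation)
    edges = [(int(a), int(b)) for a, b in zip(ii, jj) if adj[a, b]]
    return ig.Graph(n=n, edges=edges)


def enumerate_3body(coords: np.ndarray, threshold: float = 80.0,
                    min_separation: int = DEFAULT_MIN_SEPARATION,
                    bin_size: int = 5000) -> list:
    """All bin triplets with the three pairwise distances within threshold."""
    if coords.shape[0] < 3:
        return []
    g = _contact_graph(coords, threshold, min_separation)
    out = []
    for tri in g.cliques(min=3, max=3):
        members = tuple(sorted(tri))
        pspan, mspan, anchors = _spans(members, bin_size)
        out.append(ManyBodyComplex(members, False, pspan, mspan, anchors))
    return out


def enumerate_maximal(coords: np.ndarray, threshold: float = 80.0,
                      min_separation: int = DEFAULT_MIN_SEPARATION,
                      bin_size: int = 5000) -> list:
    """Maximal cliques (size >= 3) of the contact graph."""
    if coords.shape[0] < 3:
        return []
    g = _contact_graph(coords, threshold, min_separation)
    out = []
    for cl in g.maximal_cliques(min=3):
        members = tuple(sorted(cl))
        pspan, mspan, anchors = _spans(members, bin_size)
        out.append(ManyBodyComplex(members, True, pspan, mspan, anchors))
    return out


def _signature(complex_: ManyBodyComplex, mode: str):
    """Tally key: exact members for 3-bodies; (size class, anchors) for
    maximal complexes (exact member multisets are too sparse to tally)."""
    if mode == "3body":
        return complex_.members
    k = min(complex_.size, _SIZE_CLASSES[-1])
    return (k, complex_.anchors)


def _stratum(complex_: ManyBodyComplex, mode: str, bin_size: int):
    if mode == "3body":
        return (complex_.principal_span // bin_size,
                complex_.minor_span // bin_size)
    k = min(complex_.size, _SIZE_CLASSES[-1])
    return (k, complex_.principal_span // bin_size)


def _enumerate(coords, mode, threshold, min_separation, bin_size):
    if mode == "3body":
        return enumerate_3body(coords, threshold, min_separation, bin_size)
    if mode == "maximal":
        return enumerate_maximal(coords, threshold, min_separation, bin_size)
    raise ValueError(f"unknown mode {mode!r}")


def _ensemble_signatures(ensemble, mode, min_separation, bin_size):
    """Per-signature conformation incidence over an ensemble.

    Returns (signatures, strata, incidence) where incidence[sig] is the list
    of conformation indices containing the signature.
    """
    if isinstance(ensemble, ReconstructedEnsemble):
        coords = ensemble.all_coords()
        weights = ensemble.cell_weights()
        threshold = ensemble.params.contact_threshold
    else:
        coords = ensemble.coords
        weights = ensemble.weights
        threshold = ensemble.params.contact_threshold
    incidence = defaultdict(list)
    strata = {}
    for n, conf in enumerate(coords):
        for cx in _enumerate(conf, mode, threshold, min_separation, bin_size):
            sig = _signature(cx, mode)
            lst = incidence[sig]
            if not lst or lst[-1] != n:  # one hit per conformation
                lst.append(n)
            strata.setdefault(sig, _stratum(cx, mode, bin_size))
    return incidence, strata, weights


def tally_frequencies(ensemble, mode: str = "3body",
                      min_separation: int = DEFAULT_MIN_SEPARATION,
                      bin_size: int = 5000) -> dict:
    """Weighted frequency of each complex signature over the ensemble.

    Returns ``(frequencies, strata)``: signature -> weighted frequency and
    signature -> stratum key.
    """
    incidence, strata, weights = _ensemble_signatures(
        ensemble, mode, min_separation, bin_size)
    return {sig: float(weights[idx].sum()) for sig, idx in incidence.items()}, strata


def build_stratified_null(null_ensemble: Ensemble, n_replicates: int = 1000,
                          mode: str = "3body", seed: int = 0,
                          min_separation: int = DEFAULT_MIN_SEPARATION,
                          bin_size: int = 5000) -> StratifiedNull:
    """Bootstrap the random ensemble to a per-stratum null over frequencies.

    Each replicate resamples conformations with replacement (probabilities
    proportional to importance weights) and re-tallies every observed
    signature; frequencies are pooled within their stratum.
    """
    incidence, strata, weights = _ensemble_signatures(
        null_ensemble, mode, min_separation, bin_size)
    n_conf = len(weights)
    sigs = sorted(incidence)
    rng = np.random.default_rng(seed)
    from scipy.sparse import csr_matrix
    rows, cols = [], []
    for r, sig in enumerate(sigs):
        for c in incidence[sig]:
            rows.append(r)
            cols.append(c)
    mat = csr_matrix((np.ones(len(rows), dtype=np.float32), (rows, cols)),
                     shape=(len(sigs), n_conf))
    p = weights / weights.sum()
    pools = defaultdict(list)
    for _ in range(n_replicates):
        m = rng.multinomial(n_conf, p).astype(np.float32)
        freqs = mat @ m / n_conf
        for sig, f in zip(sigs, freqs):
            pools[strata[sig]].append(f)
    pooled = {k: np.sort(np.asarray(v)) for k, v in pools.items()}
    logger.info("stratified null (%s): %d signatures, %d strata, %d replicates",
                mode, len(sigs), len(pooled), n_replicates)
    return StratifiedNull(pooled, n_replicates, mode, seed=seed)


def _neighbour_pool(null: StratifiedNull, stratum, radius: int = 2):
    """Pool nearest strata within +/- radius when a stratum is absent."""
    pools = []
    if null.mode == "3body":
        p0, m0 = stratum
        for key, vals in null.strata.items():
            if max(abs(key[0] - p0), abs(key[1] - m0)) <= radius:
                pools.append(vals)
    else:
        k0, p0 = stratum
        for key, vals in null.strata.items():
            if key[0] == k0 and abs(key[1] - p0) <= radius:
                pools.append(vals)
    if pools:
        return np.sort(np.concatenate(pools))
    return None


def call_specific_manybodies(ensemble, null: StratifiedNull,
                             mode: str | None = None, alpha: float = 0.05,
                             min_separation: int = DEFAULT_MIN_SEPARATION,
                             bin_size: int = 5000) -> list:
    """Add-one within-stratum p-values plus BH FDR over all tested complexes.

    Complexes falling in a stratum absent from the null are scored against
    the pooled neighbouring strata (within +/-2 span bins, logged); a
    complex with no usable null pool receives p = 1.
    """
    mode = mode or null.mode
    if mode != null.mode:
        raise ValueError("mode mismatch with null stratification")
    freqs, strata = tally_frequencies(ensemble, mode, min_separation, bin_size)
    calls = []
    n_pooled = 0
    for sig in sorted(freqs):
        f = freqs[sig]
        st = strata[sig]
        pool = null.strata.get(st)
        if pool is None or len(pool) == 0:
            pool = _neighbour_pool(null, st)
            n_pooled += 1
        if pool is None or len(pool) == 0:
            p = 1.0
        else:
            n_ge = len(pool) - np.searchsorted(pool, f, side="left")
            p = (1.0 + n_ge) / (1.0 + len(pool))
        calls.append(ManyBodyCall(sig, f, float(p), stratum=st))
    if n_pooled:
        logger.info("call_specific_manybodies: %d complexes used pooled "
                    "neighbouring strata", n_pooled)
    if calls:
        pvals = np.array([c.p_value for c in calls])
        reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for c, q, rej in zip(calls, qvals, reject):
            c.q_value = float(q)
            c.specific = bool(rej and c.frequency > 0)
    logger.info("call_specific_manybodies (%s): %d specific of %d",
                mode, sum(c.specific for c in calls), len(calls))
    return calls


# ---------------------------------------------------------------------------
# Landscape and concordance summaries
# ---------------------------------------------------------------------------


def _members_of(call: ManyBodyCall, mode: str):
    if mode == "3body":
        return call.signature
    return call.signature[1]  # anchors of the principal loop


def functional_landscape(calls, annotations: AnnotationTrack,
                         mode: str = "3body"):
    """Proportions of functional-label configurations, specific vs not.

    For each complex the member bins (3-body) or principal-loop anchors
    (maximal) are mapped to their annotation labels; reported per group:
    fraction with no functional association, fraction with >=2 SEs together
    with a promoter, fraction with >=3 SEs, and anchor label-pair fractions.
    """
    import pandas as pd

    labels = annotations.bin_labels()
    rows = {}
    for group, subset in (("specific", [c for c in calls if c.specific]),
                          ("non_specific", [c for c in calls if not c.specific])):
        n = len(subset)
        none_ct = ge2se_p = ge3se = 0
        pair_ct = defaultdict(int)
        for call in subset:
            members = _members_of(call, mode)
            labs = [labels[b] for b in members]
            flat = set().union(*labs) if labs else set()
            if not flat:
                none_ct += 1
            n_se = sum("SE" in l for l in labs)
            if n_se >= 2 and any("P" in l for l in labs):
                ge2se_p += 1
            if n_se >= 3:
                ge3se += 1
            if mode == "maximal" or len(members) >= 2:
                a, b = members[0], members[-1]
                la = sorted(labels[a]) or ["none"]
                lb = sorted(labels[b]) or ["none"]
                for x in la:
                    for y in lb:
                        pair_ct["-".join(sorted((x, y)))] += 1
        row = {"n": n,
               "no_functional": none_ct / n if n else np.nan,
               "ge2_SE_with_P": ge2se_p / n if n else np.nan,
               "ge3_SE": ge3se / n if n else np.nan}
        tot_pairs = sum(pair_ct.values())
        for key, ct in sorted(pair_ct.items()):
            row[f"anchors_{key}"] = ct / tot_pairs if tot_pairs else np.nan
        rows[group] = row
    return pd.DataFrame(rows).T


def coverage_fraction(members, clusters: ClusterData) -> float:
    """Proportion of clusters containing every given bin."""
    if not clusters.clusters:
        raise ValueError("no clusters provided")
    need = frozenset(members)
    hit = sum(1 for c in clusters.clusters if need <= c)
    return hit / len(clusters.clusters)


def coverage_by_span(calls, clusters: ClusterData, mode: str = "3body",
                     bin_size: int = 5000):
    """Per-span median coverage for specific and non-specific complexes.

    For maximal complexes only the two principal anchors are required to
    co-occur in a cluster; spans are in bins.
    """
    per_span = defaultdict(lambda: {"specific": [], "non_specific": []})
    for call in calls:
        members = _members_of(call, mode)
        span = (max(members) - min(members))
        cov = coverage_fraction(members, clusters)
        per_span[span]["specific" if call.specific else "non_specific"].append(cov)
    out = {}
    for span, d in per_span.items():
        out[span] = {k: (float(np.median(v)) if v else np.nan)
                     for k, v in d.items()}
    return out


def coverage_permutation_test(calls, clusters: ClusterData,
                              mode: str = "3body", n_permutations: int = 1000,
                              seed: int = 0, bin_size: int = 5000) -> dict:
    """Label-permutation test for elevated specific median coverage.

    Observed statistic: the proportion of spans (with both groups present)
    where the specific median coverage exceeds the non-specific one.  The
    specific/non-specific labels are permuted across complexes
    ``n_permutations`` times; p is the add-one fraction of permutations
    reaching the observed proportion.
    """
    rng = np.random.default_rng(seed)
    records = []
    for call in calls:
        members = _members_of(call, mode)
        span = max(members) - min(members)
        records.append((span, coverage_fraction(members, clusters),
                        call.specific))
    spans = np.array([r[0] for r in records])
    covs = np.array([r[1] for r in records])
    labels = np.array([r[2] for r in records], dtype=bool)

    def exceed_proportion(lab):
        num = den = 0
        for span in np.unique(spans):
            m = spans == span
            spec = covs[m & lab]
            nonspec = covs[m & ~lab]
            if len(spec) == 0 or len(nonspec) == 0:
                continue
            den += 1
            if np.median(spec) > np.median(nonspec):
                num += 1
        return num / den if den else np.nan, den

    observed, n_spans = exceed_proportion(labels)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        stat, _ = exceed_proportion(perm)
        if not np.isnan(stat) and stat >= observed:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return {"observed_proportion": observed, "n_spans": n_spans,
            "p_value": p, "n_permutations": n_permutations}


def principal_loop_heatmap(ensemble, k: int, n_bins: int | None = None,
                           min_separation: int = DEFAULT_MIN_SEPARATION,
                           bin_size: int = 5000) -> np.ndarray:
    """Frequency with which each pair anchors a maximal k-body principal loop.

    ``k`` in {3, 4, 5, 6} where 6 means "6 or more".
    """
    if k not in _SIZE_CLASSES:
        raise ValueError(f"k must be one of {_SIZE_CLASSES}")
    freqs, _ = tally_frequencies(ensemble, "maximal", min_separation, bin_size)
    if n_bins is None:
        n_bins = (ensemble.n_bins if not isinstance(ensemble, ReconstructedEnsemble)
                  else ensemble.n_bins)
    out = np.zeros((n_bins, n_bins))
    for (kk, (a, b)), f in freqs.items():
        if kk == k:
            out[a, b] += f
            out[b, a] += f
    return out
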