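"""In-silico knock-in perturbations and the contact-dependency DAG.

Knocking-in a contact means refolding the polymer ensemble with that single
pair constrained to be in contact; comparing per-pair contact frequencies
between the perturbed and baseline (null) ensembles reveals which other
contacts are cooperatively upregulated by loop closure.  Significantly
upregulated targets (one-sided p against the distance-matched bootstrap null,
BH FDR) become directed edges knock-in -> target.  Edges are oriented along a
frequency-ranked topological order (from the contact with larger normalized
Hi-C frequency to the smaller), which guarantees acyclicity.

Geometrically infeasible contact combinations - subsets of contacts that no
chain can satisfy jointly - are detected by a metric feasibility pre-check
plus persistent dead-ending of constrained growth, and recorded as forbidden
sets for the deconvolution prior.  Forbidden sets are closed under superset
by construction of the membership test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .contact_caller import NullDistribution
from .polymer import (InfeasibleState, PolymerParams,
                      contact_frequency, sample_constrained_ensemble)

logger = logging.getLogger(__name__)


@dataclass
class KnockInResult:
    knocked_in: tuple
    baseline_freq: np.ndarray
    perturbed_freq: np.ndarray
    p_values: dict  # target pair -> one-sided p vs distance-matched null

    @property
    def delta(self) -> np.ndarray:
        return self.perturbed_freq - self.baseline_freq


@dataclass
class DependencyDAG:
    """Directed dependencies among coarse-grained contacts plus forbidden sets."""

    nodes: list                      # list of contact pairs
    edges: list                      # (src_pair, dst_pair, delta, q_value)
    forbidden: list = field(default_factory=list)  # list of frozensets of pairs

    def __post_init__(self):
        self.nodes = [tuple(p) for p in self.nodes]
        self.forbidden = [frozenset(map(tuple, s)) for s in self.forbidden]
        for s in self.forbidden:
            if len(s) < 2:
                raise ValueError("forbidden sets must have size >= 2")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("dependency graph contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for src, dst, delta, q in self.edges:
            g.add_edge(tuple(src), tuple(dst), delta=delta, q=q)
        return g

    def parents(self, pair) -> list:
        pair = tuple(pair)
        return [tuple(src) for src, dst, *_ in self.edges if tuple(dst) == pair]

    def is_forbidden(self, active_pairs) -> bool:
        """True if any forbidden subset is fully active (superset-closed)."""
        active = set(map(tuple, active_pairs))
        return any(s <= active for s in self.forbidden)

    def to_dict(self) -> dict:
        return {
            "nodes": [list(p) for p in self.nodes],
            "edges": [[list(s), list(d), float(dl), float(q)]
                      for s, d, dl, q in self.edges],
            "forbidden": [sorted(map(list, s)) for s in self.forbidden],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DependencyDAG":
        return cls(
            nodes=[tuple(p) for p in d["nodes"]],
            edges=[(tuple(s), tuple(dst), dl, q) for s, dst, dl, q in d["edges"]],
            forbidden=[frozenset(map(tuple, s)) for s in d["forbidden"]],
        )


def knockin(params: PolymerParams, n_bins: int, contact, null: NullDistribution,
            baseline_freq: np.ndarray, n_chains: int, seed: int,
            **sampler_kwargs) -> KnockInResult:
    """Refold with one contact forced and score per-pair upregulation.

    One-sided p-values compare each perturbed pair frequency to the
    bootstrap null at the same genomic distance.  Propagates
    :class:`InfeasibleState` if the contact alone cannot be satisfied.
    """
    contact = (min(contact), max(contact))
    ens = sample_constrained_ensemble(params, n_bins, [contact], n_chains,
                                      seed, **sampler_kwargs)
    perturbed = contact_frequency(ens)
    pvals = {}
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            s = j - i
            if s in null.strata:
                pvals[(i, j)] = null.p_value(s, perturbed[i, j])
    return KnockInResult(contact, np.asarray(baseline_freq), perturbed, pvals)


def build_dag(knockin_results: dict, normalized_freq, alpha: float = 0.05,
              forbidden=()) -> DependencyDAG:
    """Assemble the dependency DAG from knock-in scans.

    ``knockin_results`` maps each coarse-grained contact to its
    :class:`KnockInResult`; ``normalized_freq`` maps contacts to their
    normalized Hi-C frequency (used for the acyclic ordering).  A candidate
    edge j -> k requires k's frequency under knock-in of j to be
    significantly above the null (BH q < alpha across all scans, one-sided)
    with a positive frequency change; only edges pointing down the
    frequency-ranked order are kept, so the result is acyclic by
    construction.
    """
    nodes = sorted(knockin_results)
    tested, pvals = [], []
    for j in nodes:
        res = knockin_results[j]
        for k in nodes:
            if k == j:
                continue
            if k in res.p_values:
                tested.append((j, k))
                pvals.append(res.p_values[k])
    edges = []
    if tested:
        reject, qvals, _, _ = multipletests(np.asarray(pvals), alpha=alpha,
                                            method="fdr_bh")
        rank = {p: (-normalized_freq[p], p) for p in nodes}
        for (j, k), q, rej in zip(tested, qvals, reject):
            if not rej:
                continue
            delta = float(knockin_results[j].delta[k[0], k[1]])
            if delta <= 0:
                continue
            if rank[j] < rank[k]:  # larger frequency first; ties lexicographic
                edges.append((j, k, delta, float(q)))
    dag = DependencyDAG(nodes, edges, list(forbidden))
    logger.info("build_dag: %d nodes, %d edges, %d forbidden sets",
                len(nodes), len(edges), len(dag.forbidden))
    return dag


def contour_feasibility_precheck(params: PolymerParams, n_bins: int,
                                 pairs) -> bool:
    """Fast metric check: False if the subset is provably unsatisfiable.

    Builds upper bounds on inter-bead distances from the chain contour
    (bond_length * |i-j|), the confinement diameter, and the required
    contacts (<= contact_threshold), closes them under shortest paths, and
    flags a contradiction when any closure falls below the hard lower bounds
    (fiber diameter for non-bonded beads, the exact bond length for bonded
    neighbours).
    """
    pairs = [(min(i, j), max(i, j)) for i, j in pairs]
    beads = sorted({b for p in pairs for b in p})
    # include bonded neighbours of constrained beads so bond-length lower
    # bounds participate in the closure
    nodes = sorted(set(beads) | {b + d for b in beads for d in (-1, 1)
                                 if 0 <= b + d < n_bins})
    idx = {b: k for k, b in enumerate(nodes)}
    m = len(nodes)
    big = 2.0 * params.confinement_radius
    u = np.empty((m, m))
    for a in range(m):
        for b in range(m):
            u[a, b] = min(big, params.bond_length * abs(nodes[a] - nodes[b]))
    for i, j in pairs:
        a, b = idx[i], idx[j]
        u[a, b] = u[b, a] = min(u[a, b], params.contact_threshold)
    for k in range(m):  # Floyd-Warshall closure
        u = np.minimum(u, u[:, k:k + 1] + u[k:k + 1, :])
    for a in range(m):
        for b in range(a + 1, m):
            gap = abs(nodes[a] - nodes[b])
            lower = params.bond_length if gap == 1 else params.fiber_diameter
            if u[a, b] < lower - 1e-9:
                return False
    return True


def detect_infeasible(params: PolymerParams, n_bins: int, contact_subsets,
                      n_chains: int = 20, seed: int = 0,
                      max_restarts: int = 20) -> list:
    """Mark contact subsets whose joint satisfaction persistently fails.

    A subset is forbidden when it fails the metric pre-check or when
    constrained growth dead-ends on every chain across all restarts.  Single
    satisfiable contacts are never forbidden (a forbidden set has size >= 2).
    """
    contact_subsets = list(contact_subsets)
    forbidden = []
    rng = np.random.default_rng(seed)
    for subset in contact_subsets:
        subset = tuple(sorted((min(i, j), max(i, j)) for i, j in subset))
        if len(subset) < 2:
            continue
        if not contour_feasibility_precheck(params, n_bins, subset):
            forbidden.append(frozenset(subset))
            continue
        try:
            sample_constrained_ensemble(params, n_bins, subset, n_chains,
                                        int(rng.integers(2 ** 31)),
                                        max_restarts=max_restarts)
        except InfeasibleState:
            forbidden.append(frozenset(subset))
    logger.info("detect_infeasible: %d of %d subsets forbidden",
                len(forbidden), len(contact_subsets))
    return forbidden
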