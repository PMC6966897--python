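"""Download-free synthetic test worlds with known ground truth.

A fixture plants M contacts on a toy locus together with a dependency
mechanism (a small DAG of conditional activation probabilities), samples
per-cell binary activation states from that mechanism, folds every cell with
the constrained chain-growth sampler, and aggregates the folds into a target
"measured" Hi-C matrix.  Functional annotations are placed over the planted
anchor bins, proximity clusters are sliced from the truth conformations
(including indirect co-capture, mimicking ligation-cluster data that cannot
distinguish direct from indirect cross-linking), and per-bin feature tracks
carry a planted signal on the anchor bins of the mechanism.

Everything the pipeline consumes can therefore be generated from a seed and
compared against exact ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_builder import ReconstructedEnsemble, simulated_hic
from .model_io import (AnnotationTrack, ClusterData, HiCMatrix, LocusSpec,
                       save_clusters, save_features, save_hic)
from .polymer import PolymerParams

logger = logging.getLogger(__name__)

#: default conditional activation probabilities of the planted mechanism;
#: strong, frequently co-active loops, as at the highly transcriptionally
#: active, super-enhancer-rich loci this kind of analysis targets
P_ROOT = 0.8     # contact with no mechanism parent
P_BASE = 0.35    # child contact, no parent active in the cell
P_BOOST = 0.95   # child contact, at least one parent active

#: parent -> child contact indices: two nested loop hierarchies (TAD-like
#: loops containing sub-loops) plus an independent pair and lone roots
DEFAULT_DAG_SPEC = ((0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (7, 8), (8, 9))

#: optional anchor fuzz: when a contact is active in a cell, each bin pair
#: within this Chebyshev radius of the nominal pair is co-constrained with
#: probability p_patch; the default fixture keeps anchors sharp (p_patch=0),
#: i.e. the truth lies exactly in the model class the pipeline fits
PATCH_RADIUS = 2
P_PATCH = 0.0


@dataclass
class FixtureTruth:
    locus: LocusSpec
    params: PolymerParams
    planted_contacts: list          # M bin pairs
    planted_dag: list               # (parent_idx, child_idx) contact indices
    activation: dict                # contact idx -> (p_inactive_parent, p_active)
    true_states: np.ndarray         # (n_cells, M)
    truth_ensemble: ReconstructedEnsemble
    target_hic: HiCMatrix
    annotations: AnnotationTrack
    clusters: ClusterData
    feature_tracks: pd.DataFrame
    planted_feature_names: list
    seed: int

    @property
    def true_marginals(self) -> np.ndarray:
        return self.true_states.mean(axis=0)

    @property
    def anchor_bins(self) -> list:
        return sorted({b for p in self.planted_contacts for b in p})


def _place_contacts(n_bins: int, m: int, rng, dag_spec=(), min_span: int = 8,
                    min_separation: int = 4) -> list:
    """Place M planted contacts, nesting mechanism children inside parents.

    A child contact of the dependency mechanism is placed genomically inside
    its parent's loop span, so that closing the parent loop geometrically
    promotes the child contact - the physical situation knock-in
    perturbations are designed to detect.  All pairs keep a Chebyshev
    separation in (i, j) space so they form distinct clusters.
    """
    parents = {c: p for p, c in dag_spec if p < m and c < m}
    has_child = {p for p, c in dag_spec}
    contacts: list = [None] * m
    lo_span = max(4, min_span // 2)
    for j in range(m):
        placed = False
        for attempt in range(20000):
            par = parents.get(j)
            nest = (attempt < 10000 and par is not None
                    and contacts[par] is not None
                    and contacts[par][1] - contacts[par][0] >= 2 * lo_span)
            if nest:
                # children are sub-loops of their parent: still long relative
                # to the parent span so every mechanism member is a strong,
                # callable loop
                a, b = contacts[par]
                span = max(lo_span, int((b - a) * (0.4 + 0.45 * rng.random())))
                i = int(rng.integers(a, b - span + 1))
                k = i + span
            else:
                # root loops span TAD-scale distances (the regime where
                # random-contact baselines are low and loops stand out)
                lo = max(min_span, n_bins // 4)
                hi = max(lo + 2, (4 * n_bins) // 5)
                i = int(rng.integers(1, n_bins - lo - 1))
                k = int(rng.integers(i + lo, min(n_bins - 1, i + hi)))
            ok = all(c is None or max(abs(i - c[0]), abs(k - c[1])) >= min_separation
                     for c in contacts)
            if ok:
                contacts[j] = (i, k)
                placed = True
                break
        if not placed:
            raise ValueError("could not place the requested planted contacts")
    return contacts


def _sample_states(m: int, n_cells: int, dag_spec, rng) -> tuple:
    parents = {j: [] for j in range(m)}
    for p, c in dag_spec:
        if not (0 <= p < m and 0 <= c < m) or p >= c:
            raise ValueError("dag_spec entries must satisfy 0 <= parent < child < M")
        parents[c].append(p)
    activation = {}
    states = np.zeros((n_cells, m), dtype=np.int8)
    for j in range(m):
        if parents[j]:
            activation[j] = (P_BASE, P_BOOST)
        else:
            activation[j] = (P_ROOT, P_ROOT)
    for c in range(n_cells):
        for j in range(m):  # ascending order respects parent < child
            p_off, p_on = activation[j]
            p = p_on if any(states[c, q] for q in parents[j]) else p_off
            states[c, j] = rng.random() < p
    return states, activation


def _slice_clusters(coords: np.ndarray, n_clusters: int, capture_radius: float,
                    keep_prob: float, rng) -> ClusterData:
    """Proximity clusters from conformations, with one indirect expansion hop
    and random member subsampling (clusters may contain members that are not
    pairwise proximal, as in ligation-cluster experiments)."""
    n_conf, n_bins, _ = coords.shape
    clusters = []
    while len(clusters) < n_clusters:
        conf = coords[rng.integers(n_conf)]
        seedbin = int(rng.integers(n_bins))
        d = np.linalg.norm(conf - conf[seedbin], axis=1)
        direct = np.flatnonzero(d <= capture_radius)
        indirect = set(direct.tolist())
        for b in direct:
            d2 = np.linalg.norm(conf - conf[b], axis=1)
            indirect.update(np.flatnonzero(d2 <= capture_radius).tolist())
        members = [b for b in sorted(indirect) if rng.random() < keep_prob]
        if len(members) >= 2:
            clusters.append(members)
    return ClusterData(clusters, n_bins=n_bins)


def _patch_constraints(contacts, state, n_bins, radius, p_patch, rng) -> list:
    """Per-cell constraint pairs: nominal active contacts plus their fuzzy
    anchor-patch neighbours (Chebyshev <= radius, probability p_patch)."""
    pairs = []
    for j in np.flatnonzero(state):
        i0, j0 = contacts[j]
        pairs.append((i0, j0))
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i0 + di, j0 + dj
                if 0 <= a < n_bins and 0 <= b < n_bins and b - a >= 3:
                    if rng.random() < p_patch:
                        pairs.append((a, b))
    return sorted(set(pairs))


def _fold_cells(cell_constraints, params, n_bins, folds_per_cell,
                rng) -> ReconstructedEnsemble:
    from .polymer import sample_constrained_ensemble

    cells = {}
    for c, pairs in enumerate(cell_constraints):
        cells[c] = sample_constrained_ensemble(
            params, n_bins, pairs, folds_per_cell, int(rng.integers(2 ** 31)))
    return ReconstructedEnsemble(cells, params)


def make_fixture(n_bins: int = 100, m: int = 12, n_cells: int = 200,
                 dag_spec=DEFAULT_DAG_SPEC, seed: int = 7, *,
                 folds_per_cell: int = 10, bin_size: int = 5000,
                 params: PolymerParams | None = None, n_clusters: int = 300,
                 capture_radius: float = 150.0, n_feature_tracks: int = 8,
                 n_planted_tracks: int = 3, planted_signal: float = 1.5,
                 patch_radius: int = PATCH_RADIUS,
                 p_patch: float = P_PATCH) -> FixtureTruth:
    """Generate a complete synthetic study with known ground truth."""
    rng = np.random.default_rng(seed)
    locus = LocusSpec("chrS", 0, n_bins * bin_size, bin_size)
    if params is None:
        params = PolymerParams(bead_bp=bin_size).with_radius_for(locus.length_bp)
    if m > 0:
        contacts = _place_contacts(n_bins, m, rng, dag_spec)
        states, activation = _sample_states(m, n_cells, dag_spec, rng)
    else:
        contacts, activation = [], {}
        states = np.zeros((n_cells, 0), dtype=np.int8)
        dag_spec = ()
    cell_constraints = [
        _patch_constraints(contacts, states[c], n_bins, patch_radius,
                           p_patch, rng)
        for c in range(n_cells)
    ]
    truth = _fold_cells(cell_constraints, params, n_bins, folds_per_cell, rng)
    target = simulated_hic(truth, locus)
    target = HiCMatrix(locus, target.values, normalized=False)

    anchors = sorted({b for p in contacts for b in p})
    labels = ["SE", "P", "E"]
    intervals = []
    for k, b in enumerate(anchors):
        s, e = locus.bin_span(b)
        intervals.append((s, e, labels[k % 3]))
    annotations = AnnotationTrack(intervals, locus)

    clusters = _slice_clusters(truth.all_coords(), n_clusters, capture_radius,
                               keep_prob=0.8, rng=rng)

    track_names = [f"track_{k}" for k in range(n_feature_tracks)]
    planted_tracks = track_names[:n_planted_tracks]
    signal = rng.normal(0.0, 1.0, size=(n_bins, n_feature_tracks))
    for t in range(n_planted_tracks):
        signal[anchors, t] += planted_signal
    features = pd.DataFrame(signal, columns=track_names)
    features = (features - features.mean()) / features.std(ddof=0)

    logger.info("fixture: n_bins=%d M=%d n_cells=%d folds=%d seed=%d",
                n_bins, m, n_cells, folds_per_cell, seed)
    return FixtureTruth(locus, params, contacts, list(dag_spec), activation,
                        states, truth, target, annotations, clusters,
                        features, planted_tracks, seed)


def write_fixture(truth: FixtureTruth, outdir) -> dict:
    """Write every fixture artifact in its standard on-disk format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hic": out / "target_hic.txt",
        "bed": out / "annotations.bed",
        "clusters": out / "clusters.txt",
        "features": out / "features.tsv",
        "states": out / "true_states.txt",
        "contacts": out / "planted_contacts.txt",
    }
    save_hic(truth.target_hic, paths["hic"])
    with open(paths["bed"], "w") as fh:
        for s, e, lab in truth.annotations.intervals:
            fh.write(f"{truth.locus.chrom}\t{s}\t{e}\t{lab}\n")
    save_clusters(truth.clusters, paths["clusters"])
    save_features(truth.feature_tracks, paths["features"])
    np.savetxt(paths["states"], truth.true_states, fmt="%d")
    np.savetxt(paths["contacts"], np.asarray(truth.planted_contacts), fmt="%d")
    return {k: str(v) for k, v in paths.items()}


def make_synthetic_calls(n_calls: int = 300, n_bins: int = 100,
                         seed: int = 0) -> list:
    """Synthetic specific contact-call records for coarse-graining studies.

    Draws ``n_calls`` distinct bin pairs (|i - j| >= 3) with random
    normalized frequencies and small p-values, all flagged specific.
    """
    from .contact_caller import ContactCall

    rng = np.random.default_rng(seed)
    pairs = set()
    while len(pairs) < n_calls:
        i = int(rng.integers(0, n_bins - 3))
        j = int(rng.integers(i + 3, n_bins))
        pairs.add((i, j))
    calls = []
    for i, j in sorted(pairs):
        calls.append(ContactCall((i, j),
                                 normalized_frequency=float(rng.random()),
                                 p_value=float(rng.random() * 1e-3),
                                 q_value=float(rng.random() * 0.05),
                                 specific=True))
    return calls


def _match(pair, targets, tol: int = 1):
    """Index of a target pair within Chebyshev tolerance, else None."""
    for k, (a, b) in enumerate(targets):
        if max(abs(pair[0] - a), abs(pair[1] - b)) <= tol:
            return k
    return None


def planted_triples(truth: FixtureTruth) -> list:
    """Bin triples implied by planted contacts sharing an anchor."""
    triples = set()
    for a, p in enumerate(truth.planted_contacts):
        for q in truth.planted_contacts[a + 1:]:
            shared = set(p) & set(q)
            if shared:
                triples.add(tuple(sorted(set(p) | set(q))))
    return sorted(t for t in triples if len(t) == 3)


def score_recovery(truth: FixtureTruth, outputs: dict, tol: int = 1) -> dict:
    """Score pipeline outputs against the fixture's ground truth.

    ``outputs`` may provide: ``specific_pairs`` (list of pairs),
    ``marginals`` + ``contacts`` (deconvolution), ``dag_edges`` (list of
    (src_pair, dst_pair)), ``manybody_calls`` (specific 3-body signatures),
    and ``sim_hic``.  Missing stages report None.
    """
    report = {"contact_recall": None, "contact_precision": None,
              "marginal_error": None, "dag_edge_recall": None,
              "manybody_recall": None, "hic_pearson": None}
    planted = truth.planted_contacts
    if "specific_pairs" in outputs:
        pairs = [tuple(p) for p in outputs["specific_pairs"]]
        hit = sum(1 for p in planted if _match(p, pairs, tol) is not None)
        report["contact_recall"] = hit / len(planted) if planted else 1.0
        good = sum(1 for p in pairs if _match(p, planted, tol) is not None)
        report["contact_precision"] = good / len(pairs) if pairs else np.nan
    if "marginals" in outputs and "contacts" in outputs:
        errs = []
        truth_marg = truth.true_marginals
        for pair, f in zip(outputs["contacts"], outputs["marginals"]):
            k = _match(tuple(pair), planted, tol)
            if k is not None:
                errs.append(abs(f - truth_marg[k]))
        report["marginal_error"] = float(np.mean(errs)) if errs else np.nan
    if "dag_edges" in outputs:
        true_edges = [(planted[p], planted[c]) for p, c in truth.planted_dag]
        hit = 0
        for src, dst in true_edges:
            for esrc, edst in outputs["dag_edges"]:
                if (_match(src, [tuple(esrc)], tol) is not None
                        and _match(dst, [tuple(edst)], tol) is not None):
                    hit += 1
                    break
        report["dag_edge_recall"] = hit / len(true_edges) if true_edges else 1.0
    if "manybody_calls" in outputs:
        triples = planted_triples(truth)
        found = [tuple(sorted(sig)) for sig in outputs["manybody_calls"]]
        hit = 0
        for t in triples:
            for f in found:
                if len(f) == 3 and all(abs(a - b) <= tol for a, b in zip(t, f)):
                    hit += 1
                    break
        report["manybody_recall"] = hit / len(triples) if triples else None
    if "sim_hic" in outputs:
        from .ensemble_builder import pearson
        report["hic_pearson"] = pearson(outputs["sim_hic"], truth.target_hic,
                                        exclude_diagonals=2)
    return report
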