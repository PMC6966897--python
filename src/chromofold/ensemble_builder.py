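"""Refolding deconvolved cell states and validating the reconstructed ensemble.

Each deconvolved cell state is folded into a small number of conformations
(default 50 at production scale) with the constrained chain-growth sampler;
aggregating all cells yields the reconstructed ensemble and its simulated
Hi-C.  Validation metrics: Pearson correlation with near-diagonal exclusion,
a distance-corrected correlation (stratum-weighted mean of per-genomic-
distance Pearson), mean/single-cell distance matrices, a ratio-based domain
boundary-strength profile, and the overlap coefficient against external
single-cell contact sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model_io import HiCMatrix, LocusSpec
from .polymer import (Ensemble, InfeasibleState, PolymerParams,
                      contact_frequency, sample_constrained_ensemble)

logger = logging.getLogger(__name__)


@dataclass
class ReconstructedEnsemble:
    """Per-cell folded ensembles sharing one parameter set."""

    cells: dict                   # cell_id -> Ensemble (kind="constrained")
    params: PolymerParams
    dropped_cells: list = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return sum(len(e) for e in self.cells.values())

    @property
    def n_bins(self) -> int:
        return next(iter(self.cells.values())).n_bins

    def all_coords(self) -> np.ndarray:
        return np.concatenate([e.coords for e in self.cells.values()])

    def cell_weights(self) -> np.ndarray:
        """Per-conformation weights: normalized within cell, cells equal."""
        parts = []
        n_cells = len(self.cells)
        for e in self.cells.values():
            parts.append(e.weights / n_cells)
        return np.concatenate(parts)

    def pooled(self) -> Ensemble:
        return Ensemble(self.all_coords(), np.log(self.cell_weights()),
                        self.params, kind="constrained")


def reconstruct(states, contacts, params: PolymerParams, n_bins: int,
                folds_per_cell: int = 50, seed: int = 0, retries: int = 3,
                **sampler_kwargs) -> ReconstructedEnsemble:
    """Fold every cell state into ``folds_per_cell`` conformations.

    ``states`` is an (n_cells, M) binary array over ``contacts``.  A cell
    whose state persistently dead-ends is re-folded with a fresh seed up to
    ``retries`` times and dropped (with a warning) if still infeasible.
    """
    states = np.asarray(states)
    contacts = [tuple(p) for p in contacts]
    rng = np.random.default_rng(seed)
    cells = {}
    dropped = []
    for c in range(states.shape[0]):
        active = [contacts[j] for j in np.flatnonzero(states[c])]
        ens = None
        for attempt in range(retries + 1):
            try:
                ens = sample_constrained_ensemble(
                    params, n_bins, active, folds_per_cell,
                    int(rng.integers(2 ** 31)), **sampler_kwargs)
                break
            except InfeasibleState:
                continue
        if ens is None:
            dropped.append(c)
            logger.warning("cell %d dropped: state infeasible after %d retries",
                           c, retries)
        else:
            cells[c] = ens
    if dropped:
        logger.info("reconstruct: dropped %d of %d cells", len(dropped),
                    states.shape[0])
    if not cells:
        raise InfeasibleState("every cell state was infeasible")
    return ReconstructedEnsemble(cells, params, dropped, seed=seed)


def simulated_hic(ensemble, locus: LocusSpec | None = None) -> np.ndarray | HiCMatrix:
    """Aggregate contact frequency over a reconstructed (or plain) ensemble."""
    if isinstance(ensemble, ReconstructedEnsemble):
        freq = contact_frequency(ensemble.pooled())
    else:
        freq = contact_frequency(ensemble)
    if locus is not None:
        return HiCMatrix(locus, freq, normalized=True)
    return freq


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, HiCMatrix) else np.asarray(m, dtype=float)


def pearson(sim, measured, exclude_diagonals: int = 2) -> float:
    """Pearson over upper-triangle entries with |i-j| > exclude_diagonals."""
    a = _as_values(sim)
    b = _as_values(measured)
    if a.shape != b.shape:
        raise ValueError("matrix shapes differ")
    iu = np.triu_indices(a.shape[0], k=exclude_diagonals + 1)
    x, y = a[iu], b[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def distance_corrected_pearson(sim, measured, exclude_diagonals: int = 2,
                               min_pairs: int = 3) -> float:
    """Stratum-weighted mean of per-genomic-distance Pearson correlations.

    Removes the shared distance-decay signal: each distance stratum
    contributes its own Pearson, weighted by its pair count; strata with
    fewer than ``min_pairs`` pairs or zero variance are skipped.
    """
    a = _as_values(sim)
    b = _as_values(measured)
    if a.shape != b.shape:
        raise ValueError("matrix shapes differ")
    n = a.shape[0]
    total_w = 0.0
    acc = 0.0
    for s in range(exclude_diagonals + 1, n):
        x = np.diagonal(a, s)
        y = np.diagonal(b, s)
        if len(x) < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        acc += len(x) * float(np.corrcoef(x, y)[0, 1])
        total_w += len(x)
    if total_w == 0:
        raise ValueError("all distance strata degenerate")
    return acc / total_w


def mean_distance_matrix(ensemble) -> np.ndarray:
    """Weighted mean pairwise Euclidean distance matrix (nm)."""
    if isinstance(ensemble, ReconstructedEnsemble):
        coords = ensemble.all_coords()
        w = ensemble.cell_weights()
    else:
        coords = ensemble.coords
        w = ensemble.weights
    if len(coords) == 0:
        raise ValueError("empty ensemble")
    out = np.zeros((coords.shape[1], coords.shape[1]))
    chunk = max(1, int(2e7 // (coords.shape[1] ** 2)))
    for s in range(0, len(coords), chunk):
        blk = coords[s:s + chunk]
        d = np.sqrt(((blk[:, :, None, :] - blk[:, None, :, :]) ** 2).sum(-1))
        out += np.einsum("n,nij->ij", w[s:s + chunk], d)
    return out


def cell_distance_matrix(ensemble: ReconstructedEnsemble, cell_id) -> np.ndarray:
    """Mean pairwise distance over one cell's folds (nm)."""
    if cell_id not in ensemble.cells:
        raise KeyError(f"unknown cell id {cell_id!r}")
    e = ensemble.cells[cell_id]
    w = e.weights
    d = np.sqrt(((e.coords[:, :, None, :] - e.coords[:, None, :, :]) ** 2).sum(-1))
    return np.einsum("n,nij->ij", w, d)


@dataclass
class BoundaryProfile:
    strength: np.ndarray  # NaN within `window` of the locus ends
    window: int


def boundary_strength(distance_matrix: np.ndarray, window: int = 10) -> BoundaryProfile:
    """Domain-boundary prominence from a pairwise distance matrix.

    Strength at bin i = mean cross-block distance between the flanking
    windows [i-w, i) and [i, i+w), divided by the mean within-block distance
    of those two windows.  Values near the locus ends (within one window)
    are undefined (NaN).  A uniform matrix scores 1 everywhere defined.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if window < 2:
        raise ValueError("window must be >= 2 bins")
    if 2 * window > n:
        raise ValueError("window exceeds half the locus length")
    strength = np.full(n, np.nan)
    iu = np.triu_indices(window, k=1)
    for i in range(window, n - window + 1):
        left = d[i - window:i, i - window:i]
        right = d[i:i + window, i:i + window]
        cross = d[i - window:i, i:i + window]
        within = 0.5 * (left[iu].mean() + right[iu].mean())
        if within == 0:
            continue
        strength[i] = cross.mean() / within
    return BoundaryProfile(strength, window)


def overlap_coefficient(state_contacts, external_contacts) -> float:
    """|A n B| / min(|A|, |B|) between two sets of bin pairs."""
    a = {(min(i, j), max(i, j)) for i, j in state_contacts}
    b = {(min(i, j), max(i, j)) for i, j in external_contacts}
    if min(len(a), len(b)) == 0:
        raise ValueError("overlap coefficient undefined for an empty set")
    return len(a & b) / min(len(a), len(b))


def best_overlap(external_contacts, cell_contact_sets: dict) -> tuple:
    """Match an external cell to the reconstructed cell of maximal overlap."""
    best_id, best = None, -1.0
    for cid, contacts in cell_contact_sets.items():
        if not contacts:
            continue
        o = overlap_coefficient(contacts, external_contacts)
        if o > best:
            best_id, best = cid, o
    return best_id, best
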