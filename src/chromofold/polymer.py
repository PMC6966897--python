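"""Self-avoiding chromatin chain model under spherical confinement.

A locus is modeled as a connected bead chain: each bead represents a fixed
amount of chromatin fiber (default 5 kb of 11-nm fiber), consecutive beads sit
at a fixed center-to-center bond length, no two beads may approach closer than
the fiber diameter, and the whole chain is confined to a sphere whose radius
preserves a constant base-pair density.  Two beads are "in contact" when their
Euclidean distance is at most ``contact_threshold`` (80 nm, a cross-linking
range).

Ensembles are generated by sequential Monte Carlo chain growth: at each step a
fixed number of candidate directions is drawn, candidates violating
self-avoidance, confinement, or active proximity constraints are discarded,
one survivor is chosen uniformly, and the chain accumulates a Rosenbluth-style
log-weight equal to the log of the candidate-survival fraction.  Weighted
averages over such chains target the uniform distribution over feasible
conformations.  Weight degeneracy is controlled by systematic resampling at
fixed growth checkpoints whenever the effective sample size drops below half
the population ("fractal"/enrichment-style deep sampling).

Constrained ensembles condition the same growth process on a set of required
bin-pair contacts, yielding near-uniform samples from the subset of chains
satisfying every required pair at ``contact_threshold``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

#: bp per nm^3, derived from a diploid genome (~6.2e9 bp) confined in a
#: nucleus of 7 um diameter; used only to convert locus length to a
#: confinement radius at constant base-pair density.
DEFAULT_GENOME_BP = 6.2e9
DEFAULT_NUCLEAR_DIAMETER_NM = 7000.0
DEFAULT_BP_DENSITY = DEFAULT_GENOME_BP / (
    4.0 / 3.0 * math.pi * (DEFAULT_NUCLEAR_DIAMETER_NM / 2.0) ** 3
)


class FoldingFailure(RuntimeError):
    """Chain growth dead-ended; carries the partial length reached."""

    def __init__(self, message: str, partial_length: int = 0):
        super().__init__(message)
        self.partial_length = partial_length


class InfeasibleState(RuntimeError):
    """A required contact state could not be satisfied by any sampled chain."""

    def __init__(self, message: str, pairs=()):
        super().__init__(message)
        self.pairs = tuple(pairs)


@dataclass(frozen=True)
class PolymerParams:
    """Geometric parameters of the bead-chain model (lengths in nm)."""

    bead_bp: int = 5000
    fiber_diameter: float = 11.0
    contact_threshold: float = 80.0
    bond_length: float = 30.0
    confinement_radius: float = 200.0
    bp_density: float = DEFAULT_BP_DENSITY

    def __post_init__(self):
        if not (self.bead_bp > 0 and self.fiber_diameter > 0 and self.bond_length > 0):
            raise ValueError("bead_bp, fiber_diameter, bond_length must be positive")
        if self.contact_threshold <= self.fiber_diameter:
            raise ValueError("contact_threshold must exceed fiber_diameter")
        if self.confinement_radius <= self.bond_length:
            raise ValueError("confinement_radius must exceed bond_length")
        if self.bp_density <= 0:
            raise ValueError("bp_density must be positive")

    def with_radius_for(self, locus_bp: int) -> "PolymerParams":
        return replace(self, confinement_radius=confinement_radius_for(locus_bp, self))


def confinement_radius_for(locus_bp, params: PolymerParams) -> float:
    """Confinement-sphere radius (nm) preserving constant base-pair density.

    radius = (3 L / (4 pi rho))^(1/3) for locus length L (bp) and density
    rho (bp / nm^3).
    """
    if hasattr(locus_bp, "length_bp"):  # LocusSpec-like
        locus_bp = locus_bp.length_bp
    if params.bp_density <= 0:
        raise ValueError("bp_density must be positive")
    return (3.0 * float(locus_bp) / (4.0 * math.pi * params.bp_density)) ** (1.0 / 3.0)


@dataclass
class Conformation:
    """One chromatin chain: ordered 3-D bead coordinates (nm) plus log-weight."""

    coords: np.ndarray
    log_weight: float = 0.0
    seed: int | None = None

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]

    def validate(self, params: PolymerParams, constraints=(), atol: float = 1e-6):
        """Assert bond lengths, self-avoidance, confinement, constraints."""
        c = self.coords
        bonds = np.linalg.norm(np.diff(c, axis=0), axis=1)
        if not np.allclose(bonds, params.bond_length, atol=atol):
            raise AssertionError("bond length violated")
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        n = len(c)
        off = ~np.eye(n, dtype=bool)
        if n > 1 and d[off].min() < params.fiber_diameter - atol:
            raise AssertionError("self-avoidance violated")
        if np.linalg.norm(c, axis=1).max() > params.confinement_radius + atol:
            raise AssertionError("confinement violated")
        for i, j in constraints:
            if d[i, j] > params.contact_threshold + atol:
                raise AssertionError(f"required contact ({i},{j}) not satisfied")


@dataclass
class Ensemble:
    """A weighted collection of conformations sharing one parameter set.

    Coordinates are stored stacked as ``(n_conformations, n_bins, 3)`` with
    per-conformation log-weights; ``kind`` is ``"null"`` for unconditioned
    ensembles and ``"constrained"`` when a contact state was enforced.
    """

    coords: np.ndarray
    log_weights: np.ndarray
    params: PolymerParams
    kind: str = "null"
    constraint_set: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.log_weights = np.asarray(self.log_weights, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_conformations, n_bins, 3)")
        if len(self.log_weights) != len(self.coords):
            raise ValueError("one log-weight per conformation required")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bins(self) -> int:
        return self.coords.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Normalized importance weights."""
        lw = self.log_weights - self.log_weights.max()
        w = np.exp(lw)
        return w / w.sum()

    def conformations(self):
        for k in range(len(self)):
            yield Conformation(self.coords[k], float(self.log_weights[k]))

    def validate(self):
        for conf in self.conformations():
            conf.validate(self.params, self.constraint_set)


# ---------------------------------------------------------------------------
# Growth kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _grow_segment(coords, alive, logw, died_at, start, stop, n_cand,
                  bond, fiber2, radius, thresh, con_i, con_j, seed):
    """Advance every live chain from bead `start` to `stop` (exclusive).

    Candidate filtering: confinement, active/look-ahead constraints, then
    self-avoidance.  Look-ahead: while growing bead b with a pending
    constraint (i, j), i < b < j, the tip must stay within
    thresh + (j - b) * bond of bead i, otherwise the constraint can no
    longer be closed.  Returns the number of chains that died.
    """
    np.random.seed(seed)
    n_chains = coords.shape[0]
    n_con = con_i.shape[0]
    cand = np.empty((n_cand, 3))
    ndied = 0
    r2 = radius * radius
    for c in range(n_chains):
        if not alive[c]:
            continue
        for b in range(start, stop):
            if b == 0:
                while True:
                    x = (np.random.random() * 2.0 - 1.0) * radius
                    y = (np.random.random() * 2.0 - 1.0) * radius
                    z = (np.random.random() * 2.0 - 1.0) * radius
                    if x * x + y * y + z * z <= r2:
                        break
                coords[c, 0, 0] = x
                coords[c, 0, 1] = y
                coords[c, 0, 2] = z
                continue
            n_valid = 0
            for k in range(n_cand):
                dx = np.random.normal()
                dy = np.random.normal()
                dz = np.random.normal()
                nrm = math.sqrt(dx * dx + dy * dy + dz * dz)
                if nrm == 0.0:
                    continue
                px = coords[c, b - 1, 0] + bond * dx / nrm
                py = coords[c, b - 1, 1] + bond * dy / nrm
                pz = coords[c, b - 1, 2] + bond * dz / nrm
                if px * px + py * py + pz * pz > r2:
                    continue
                ok = True
                for m in range(n_con):
                    ci = con_i[m]
                    cj = con_j[m]
                    if cj < b or ci >= b:
                        continue
                    # ci < b <= cj: bead ci already placed
                    ddx = px - coords[c, ci, 0]
                    ddy = py - coords[c, ci, 1]
                    ddz = pz - coords[c, ci, 2]
                    dd = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                    if cj == b:
                        if dd > thresh:
                            ok = False
                            break
                    else:
                        if dd > thresh + (cj - b) * bond:
                            ok = False
                            break
                if not ok:
                    continue
                for a in range(b - 1):
                    ddx = px - coords[c, a, 0]
                    ddy = py - coords[c, a, 1]
                    ddz = pz - coords[c, a, 2]
                    if ddx * ddx + ddy * ddy + ddz * ddz < fiber2:
                        ok = False
                        break
                if not ok:
                    continue
                cand[n_valid, 0] = px
                cand[n_valid, 1] = py
                cand[n_valid, 2] = pz
                n_valid += 1
            if n_valid == 0:
                alive[c] = False
                died_at[c] = b
                ndied += 1
                break
            pick = int(np.random.random() * n_valid)
            if pick == n_valid:
                pick = n_valid - 1
            coords[c, b, 0] = cand[pick, 0]
            coords[c, b, 1] = cand[pick, 1]
            coords[c, b, 2] = cand[pick, 2]
            logw[c] += math.log(n_valid) - math.log(n_cand)
    return ndied


def _systematic_resample(weights: np.ndarray, n: int, rng) -> np.ndarray:
    cum = np.cumsum(weights)
    cum /= cum[-1]
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(cum, positions)


def _normalize_constraints(required_contacts) -> np.ndarray:
    pairs = sorted({(min(i, j), max(i, j)) for i, j in required_contacts})
    for i, j in pairs:
        if i == j:
            raise ValueError("a contact must join two distinct bins")
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return arr


def _grow_population(params, n_bins, constraints, n_chains, rng, *,
                     checkpoint=10, n_cand=50, max_restarts=100):
    """SMC growth of `n_chains` chains; returns (coords, logw, stats)."""
    con = _normalize_constraints(constraints)
    if con.size and con.max() >= n_bins:
        raise ValueError("constraint bin index out of range")
    fiber2 = params.fiber_diameter ** 2
    out_coords, out_logw = [], []
    total_attempts = 0
    total_deadends = 0
    need = n_chains
    rounds = 0
    while need > 0 and rounds < max_restarts:
        coords = np.zeros((need, n_bins, 3))
        logw = np.zeros(need)
        alive = np.ones(need, dtype=np.bool_)
        died_at = np.full(need, -1, dtype=np.int64)
        total_attempts += need
        for start in range(0, n_bins, checkpoint):
            stop = min(start + checkpoint, n_bins)
            seg_seed = int(rng.integers(2 ** 31))
            total_deadends += _grow_segment(
                coords, alive, logw, died_at, start, stop, n_cand,
                params.bond_length, fiber2, params.confinement_radius,
                params.contact_threshold, con[:, 0].copy(), con[:, 1].copy(),
                seg_seed)
            if stop >= n_bins or not alive.any():
                break
            # enrichment/resampling checkpoint: replace low-weight and dead
            # chains when the effective sample size collapses
            w = np.where(alive, np.exp(logw - logw[alive].max()), 0.0)
            ess = w.sum() ** 2 / (w ** 2).sum()
            if ess < need / 2.0:
                idx = _systematic_resample(w, need, rng)
                coords = coords[idx].copy()
                logw = np.zeros(need)
                alive = np.ones(need, dtype=np.bool_)
                died_at = np.full(need, -1, dtype=np.int64)
        if alive.any():
            out_coords.append(coords[alive])
            # weights only comparable within a growth round: normalize here
            lw = logw[alive]
            w = np.exp(lw - lw.max())
            w = w / w.sum() * alive.sum()
            out_logw.append(np.log(w))
            need -= int(alive.sum())
        rounds += 1
    stats = {
        "attempts": total_attempts,
        "deadends": total_deadends,
        "rounds": rounds,
        "grown": n_chains - need,
        "last_partial": int(died_at.max()) if need > 0 else n_bins,
    }
    if need > 0:
        stats["short"] = need
    if out_coords:
        return np.concatenate(out_coords), np.concatenate(out_logw), stats
    return np.zeros((0, n_bins, 3)), np.zeros(0), stats


def grow_chain(params: PolymerParams, n_bins: int, required_contacts=(),
               rng=None, *, n_cand=50, max_restarts=100) -> Conformation:
    """Grow one self-avoiding confined chain (optionally constrained).

    Raises :class:`FoldingFailure` carrying the furthest bead reached if
    growth dead-ends ``max_restarts`` times.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    coords, logw, stats = _grow_population(
        params, n_bins, required_contacts, 1, rng,
        checkpoint=n_bins, n_cand=n_cand, max_restarts=max_restarts)
    if len(coords) == 0:
        raise FoldingFailure(
            f"chain growth dead-ended after {max_restarts} restarts",
            partial_length=stats["last_partial"])
    return Conformation(coords[0], float(logw[0]))


def sample_null_ensemble(params: PolymerParams, n_bins: int, n_chains: int,
                         seed: int, *, checkpoint=10, n_cand=50,
                         max_restarts=100) -> Ensemble:
    """Near-uniform ensemble of self-avoiding confined chains.

    SMC growth with systematic resampling at fixed checkpoints whenever the
    effective sample size drops below half the population.  Raises if more
    than half of all growth attempts dead-end (a sign the geometry is too
    tight for the sampler).
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    coords, logw, stats = _grow_population(
        params, n_bins, (), n_chains, rng,
        checkpoint=checkpoint, n_cand=n_cand, max_restarts=max_restarts)
    logger.info("null ensemble: seed=%s n_bins=%d grown=%d attempts=%d deadends=%d",
                seed, n_bins, stats["grown"], stats["attempts"], stats["deadends"])
    if stats["deadends"] > 0.5 * max(stats["attempts"], 1) and stats.get("short"):
        raise RuntimeError(
            "more than half of growth attempts dead-ended; review polymer "
            "parameters (confinement radius vs. bond length / fiber diameter)")
    return Ensemble(coords, logw, params, kind="null", seed=seed)


def sample_constrained_ensemble(params: PolymerParams, n_bins: int,
                                contact_state, n_chains: int, seed: int, *,
                                checkpoint=10, n_cand=50,
                                max_restarts=100) -> Ensemble:
    """Ensemble conditioned on a set of required bin-pair contacts.

    Every returned conformation satisfies every pair of ``contact_state`` at
    Euclidean distance <= ``contact_threshold``.  Raises
    :class:`InfeasibleState` if no chain could be grown at all.
    """
    pairs = tuple(sorted({(min(i, j), max(i, j)) for i, j in contact_state}))
    if not pairs:
        ens = sample_null_ensemble(params, n_bins, n_chains, seed,
                                   checkpoint=checkpoint, n_cand=n_cand,
                                   max_restarts=max_restarts)
        return replace_kind(ens, "constrained", ())
    rng = np.random.default_rng(seed)
    coords, logw, stats = _grow_population(
        params, n_bins, pairs, n_chains, rng,
        checkpoint=checkpoint, n_cand=n_cand, max_restarts=max_restarts)
    if len(coords) == 0:
        raise InfeasibleState(
            f"contact state {pairs} unsatisfiable after {max_restarts} "
            f"growth rounds (furthest bead {stats['last_partial']})",
            pairs=pairs)
    if stats.get("short"):
        logger.warning("constrained ensemble short: %d of %d chains grown",
                       stats["grown"], n_chains)
    logger.info("constrained ensemble: seed=%s pairs=%d grown=%d deadends=%d",
                seed, len(pairs), stats["grown"], stats["deadends"])
    return Ensemble(coords, logw, params, kind="constrained",
                    constraint_set=pairs, seed=seed)


def replace_kind(ens: Ensemble, kind: str, constraint_set) -> Ensemble:
    return Ensemble(ens.coords, ens.log_weights, ens.params, kind=kind,
                    constraint_set=tuple(constraint_set), seed=ens.seed)


def contact_frequency(ensemble: Ensemble, threshold: float | None = None) -> np.ndarray:
    """Weighted fraction of conformations with each bin pair in contact.

    Symmetric with unit diagonal (a bead is trivially in contact with
    itself).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    t = ensemble.params.contact_threshold if threshold is None else threshold
    w = ensemble.weights
    c = ensemble.coords
    freq = np.zeros((ensemble.n_bins, ensemble.n_bins))
    # chunk over conformations to bound the (n, nb, nb) temporary
    chunk = max(1, int(2e7 // (ensemble.n_bins ** 2)))
    for s in range(0, len(ensemble), chunk):
        blk = c[s:s + chunk]
        d2 = ((blk[:, :, None, :] - blk[:, None, :, :]) ** 2).sum(-1)
        freq += np.einsum("n,nij->ij", w[s:s + chunk], d2 <= t * t)
    return freq


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix for one conformation."""
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d ** 2).sum(-1))
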