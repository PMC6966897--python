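"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own samplers and enumerators: free
chain growth with rejection for uniform self-avoiding confined chains,
O(n^3)/exponential subset scans for cliques, and direct tallies for contact
frequencies.
"""

import itertools

import numpy as np


def rejection_sample_chains(params, n_bins, n_accept, rng, constraints=()):
    """Uniform chains by free growth + rejection (accept only feasible).

    Each step draws one uniform direction; the chain is accepted only if it
    is self-avoiding, confined, and satisfies every constraint.  Accepted
    chains are exact uniform draws over the feasible set.
    """
    out = []
    r2 = params.confinement_radius ** 2
    f2 = params.fiber_diameter ** 2
    t2 = params.contact_threshold ** 2
    while len(out) < n_accept:
        coords = np.empty((n_bins, 3))
        while True:
            p = rng.uniform(-params.confinement_radius,
                            params.confinement_radius, 3)
            if p @ p <= r2:
                break
        coords[0] = p
        ok = True
        for b in range(1, n_bins):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = coords[b - 1] + params.bond_length * d
            if pos @ pos > r2:
                ok = False
                break
            if b > 1:
                dd = ((coords[:b - 1] - pos) ** 2).sum(1)
                if dd.min() < f2:
                    ok = False
                    break
            coords[b] = pos
        if not ok:
            continue
        for i, j in constraints:
            if ((coords[i] - coords[j]) ** 2).sum() > t2:
                ok = False
                break
        if ok:
            out.append(coords)
    return np.asarray(out)


def contact_tally(coords, threshold):
    """Unweighted contact frequency by an explicit loop."""
    n_conf, n_bins, _ = coords.shape
    acc = np.zeros((n_bins, n_bins))
    for c in range(n_conf):
        for i in range(n_bins):
            for j in range(n_bins):
                d = np.linalg.norm(coords[c, i] - coords[c, j])
                if d <= threshold:
                    acc[i, j] += 1
    return acc / n_conf


def brute_force_3bodies(coords, threshold, min_separation):
    """All triplets with pairwise distances within threshold (triple loop)."""
    n = len(coords)
    out = []
    for i, j, k in itertools.combinations(range(n), 3):
        pairs = [(i, j), (i, k), (j, k)]
        if any(b - a < min_separation for a, b in pairs):
            continue
        if all(np.linalg.norm(coords[a] - coords[b]) <= threshold
               for a, b in pairs):
            out.append((i, j, k))
    return sorted(out)


def brute_force_maximal_cliques(coords, threshold, min_separation):
    """Maximal cliques (size >= 3) by exhaustive subset enumeration."""
    n = len(coords)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        if j - i >= min_separation and \
                np.linalg.norm(coords[i] - coords[j]) <= threshold:
            adj[i, j] = adj[j, i] = True
    cliques = []
    for size in range(3, n + 1):
        for sub in itertools.combinations(range(n), size):
            if all(adj[a, b] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = []
    for c in cliques:
        if not any(c < other for other in cliques):
            maximal.append(tuple(sorted(c)))
    return sorted(set(maximal))
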