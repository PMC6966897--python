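"""End-to-end orchestration: Hi-C in, reconstructed single-cell ensemble out.

Stages: sample the uniform-random null ensemble; quantile-normalize the
measured Hi-C onto its frequency scale; call specific pairwise contacts
against the Bag-of-Little-Bootstraps null; coarse-grain the specific set;
run knock-in perturbations to build the dependency DAG; Gibbs-deconvolve
single-cell contact states; refold every cell and aggregate the simulated
Hi-C.  All stage sizes are parameters: the production-scale settings
(hundreds of thousands of null chains, 10,000 bootstrap replicates, tens of
thousands of reconstructed folds) and the desk-scale defaults used
throughout the test suite differ only in these numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contact_caller import (build_null, call_specific, coarse_grain,
                             quantile_normalize)
from .deconvolution import DeconvolutionModel, gibbs_deconvolve
from .dependency import build_dag, knockin
from .ensemble_builder import (distance_corrected_pearson, pearson,
                               reconstruct, simulated_hic)
from .model_io import HiCMatrix
from .polymer import PolymerParams, contact_frequency, sample_null_ensemble

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_null_chains: int = 2000
    n_outer: int = 10000  # production bootstrap depth; the p-value floor
                          # 1/(1 + pool) must undercut the BH threshold
    subset_exponent: float = 0.7
    alpha: float = 0.05
    retention_fraction: float = 0.05
    n_knockin_chains: int = 2000
    n_cells: int = 200
    n_sweeps: int = 2000
    burn_in: int = 500
    folds_per_cell: int = 10
    prior_boost: float = np.e
    sparsity_weight: float = 0.1
    exclude_diagonals: int = 2
    background_correction: bool = True


@dataclass
class PipelineResult:
    null_ensemble: object
    null_freq: np.ndarray
    hic_norm: HiCMatrix
    calls: list
    coarse: object
    knockin_results: dict
    dag: object
    model: DeconvolutionModel
    gibbs: object
    reconstructed: object
    sim_hic: HiCMatrix
    pearson: float
    pearson_all: float
    distance_corrected: float


def target_frequencies(hic_norm: HiCMatrix, null_freq: np.ndarray, contacts,
                       background_correction: bool = True) -> np.ndarray:
    """Per-contact activation targets from the normalized Hi-C.

    With background correction the random-folding baseline is removed by
    inverting the mixture  observed = f + (1 - f) * baseline,  so that a
    cell fraction f with the contact pinned (frequency 1) plus the random
    baseline in the remaining cells reproduces the observed frequency.
    """
    out = []
    for i, j in contacts:
        obs = hic_norm.values[i, j]
        if background_correction:
            base = null_freq[i, j]
            f = (obs - base) / max(1.0 - base, 1e-9)
        else:
            f = obs
        out.append(np.clip(f, 0.0, 1.0))
    return np.asarray(out)


def run_pipeline(measured: HiCMatrix, params: PolymerParams, seed: int,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full deconvolution pipeline on one locus."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    n_bins = measured.n_bins

    null = sample_null_ensemble(params, n_bins, cfg.n_null_chains,
                                int(rng.integers(2 ** 31)))
    null_freq = contact_frequency(null)
    hic_norm = quantile_normalize(measured, null, null_freq)
    null_dist = build_null(null, cfg.n_outer, cfg.subset_exponent,
                           seed=int(rng.integers(2 ** 31)))
    calls = call_specific(hic_norm, null_dist, cfg.alpha,
                          cfg.exclude_diagonals)
    coarse = coarse_grain(calls, cfg.retention_fraction)

    kres = {}
    for pair in coarse.retained:
        kres[pair] = knockin(params, n_bins, pair, null_dist, null_freq,
                             cfg.n_knockin_chains, int(rng.integers(2 ** 31)))
    norm_freq = {p: hic_norm.values[p[0], p[1]] for p in coarse.retained}
    dag = build_dag(kres, norm_freq, cfg.alpha)

    f = target_frequencies(hic_norm, null_freq, coarse.retained,
                           cfg.background_correction)
    model = DeconvolutionModel(coarse.retained, f, dag,
                               prior_boost=cfg.prior_boost,
                               sparsity_weight=cfg.sparsity_weight,
                               n_cells=cfg.n_cells)
    gibbs = gibbs_deconvolve(model, cfg.n_sweeps, cfg.burn_in,
                             seed=int(rng.integers(2 ** 31)))
    recon = reconstruct(gibbs.states, coarse.retained, params, n_bins,
                        folds_per_cell=cfg.folds_per_cell,
                        seed=int(rng.integers(2 ** 31)))
    sim = simulated_hic(recon, measured.locus)
    r = pearson(sim, hic_norm, cfg.exclude_diagonals)
    r0 = pearson(sim, hic_norm, 0)
    dc = distance_corrected_pearson(sim, hic_norm, cfg.exclude_diagonals)
    logger.info("pipeline: %d specific, %d retained, %d DAG edges, "
                "Pearson=%.4f (excl. %d diagonals)",
                sum(c.specific for c in calls), len(coarse.retained),
                len(dag.edges), r, cfg.exclude_diagonals)
    return PipelineResult(null, null_freq, hic_norm, calls, coarse, kres, dag,
                          model, gibbs, recon, sim, r, r0, dc)
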