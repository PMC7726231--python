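"""Study-scale evaluation of the pipeline against planted ground truth.

These routines run the full chain — simulator, normalization, per-gene
tests, enrichment, correlation — at the emulated study conditions and score
the results against the generator's :class:`~degpath.synthetic.GroundTruth`
or against the published pathway tables. They are what the repository's
acceptance script and the heavier tests call; each returns a plain dict of
numbers so results can be serialized directly.

All randomness flows from one integer ``seed``; replicate ``i`` of a
multi-run evaluation uses ``seed + i``.
"""

from __future__ import annotations

import numpy as np

from . import published
from .diffexpr import run_differential
from .enrichment import (
    CalibrationFit,
    calibrate_background,
    enrich_collection,
    hypergeom_moment_table,
    zscore_counts,
)
from .preprocess import normalize
from .protein_corr import (
    correlate,
    fisher_z_interval,
    normalize_densitometry,
    pair_by_subject,
)
from .synthetic import (
    SimulationConfig,
    simulate_densitometry,
    simulate_expression,
    simulate_genesets,
    study_design,
)

__all__ = [
    "zscore_oracle_max_deviation",
    "published_calibration",
    "null_study",
    "planted_recovery",
    "correlation_recovery",
]


def zscore_oracle_max_deviation(max_N: int = 200) -> float:
    """Worst |z_closed_form - (r - mean)/sd| over every valid query with N <= max_N.

    The moments come from explicit hypergeometric summation
    (:func:`~degpath.enrichment.hypergeom_moment_table`); z is evaluated at
    both endpoints of the feasible support of r for every (N, R, n), which
    bounds the deviation over all r since both forms are linear in r.
    """
    worst = 0.0
    for N in range(2, max_N + 1):
        n = np.arange(1, N)
        for R in range(1, N):
            means, sds = hypergeom_moment_table(N, R, n_values=n)
            r_lo = np.maximum(0, n - (N - R))
            r_hi = np.minimum(n, R)
            for r in (r_lo, r_hi):
                z_closed = zscore_counts(r, n, R, N)
                z_oracle = (r - means) / sds
                worst = max(worst, float(np.abs(z_closed - z_oracle).max()))
    return worst


def published_calibration(direction: str,
                          search: tuple[int, int] | None = None,
                          ) -> CalibrationFit:
    """Grid-calibrate the background size N behind a published pathway table.

    ``direction`` selects the down table (R = 487) or the up table (R = 252).
    Default search ranges: [15,000, 30,000] for down, [15,000, 50,000] for up
    (the up table sits at a larger background and needs the wider grid).
    """
    R = published.N_DEG_DOWN if direction == "down" else published.N_DEG_UP
    if search is None:
        search = (15_000, 30_000) if direction == "down" else (15_000, 50_000)
    return calibrate_background(published.calibration_rows(direction), R=R,
                                search=search)


def _run_pipeline_once(cfg: SimulationConfig):
    raw, truth = simulate_expression(cfg)
    norm, _ = normalize(raw)
    results, partition = run_differential(norm, study_design(cfg))
    return norm, truth, results, partition


def null_study(seed: int, n_runs: int = 100, n_genes: int = 10_000,
               alpha: float = 0.05) -> dict:
    """No-effect simulations: per-gene type-I error and null-set flag rate.

    Every gene is null (no planted effect), so genes significant at alpha are
    false positives and any set flagged at |z| >= 2 is a false discovery.
    The type-I fraction is reported for the first (fixed-seed) run; the set
    flag rate pools all (set, direction) results across the ``n_runs`` runs.
    """
    type_i_first = None
    flagged = total = 0
    for i in range(n_runs):
        cfg = SimulationConfig(n_genes=n_genes, n_deg=0, effect_size_log2=0.0,
                               sets_spec=(), n_null_sets=10, seed=seed + i)
        norm, truth, results, partition = _run_pipeline_once(cfg)
        if type_i_first is None:
            type_i_first = partition.n_total / len(results)
        sets, _ = simulate_genesets(cfg, truth)
        enr = enrich_collection(partition, sets, norm.gene_ids)
        flagged += sum(e.significant for e in enr)
        total += len(enr)
    return {
        "type_i_error": float(type_i_first),
        "alpha": alpha,
        "n_genes": n_genes,
        "set_flag_rate": flagged / total if total else float("nan"),
        "n_set_results": total,
        "n_runs": n_runs,
    }


def planted_recovery(seed: int, n_runs: int = 100) -> dict:
    """Planted-effect simulations at the emulated study scale.

    Default conditions: 739 DEGs (66% down, |log2 FC| = 2, noise SD 0.5)
    among 20,000 genes, 4 vs 4 arrays, one planted set of 88 genes holding
    18 true down-DEGs. Reports, across runs: the direction split among the
    *recovered planted* DEGs (scored against ground truth), the raw
    partition split (which also contains the alpha-level false positives),
    per-direction recall, and how often the planted set is called
    significant in the down direction.
    """
    truth_down_fracs, raw_down_fracs, recalls_down, recalls_up = [], [], [], []
    planted_sig = 0
    for i in range(n_runs):
        cfg = SimulationConfig(seed=seed + i)
        norm, truth, _, partition = _run_pipeline_once(cfg)
        rec_down = set(partition.down) & set(truth.down_ids)
        rec_up = set(partition.up) & set(truth.up_ids)
        truth_down_fracs.append(len(rec_down) / (len(rec_down) + len(rec_up)))
        raw_down_fracs.append(partition.down_fraction)
        recalls_down.append(len(rec_down) / len(truth.down_ids))
        recalls_up.append(len(rec_up) / len(truth.up_ids))
        sets, truth = simulate_genesets(cfg, truth)
        enr = enrich_collection(partition, sets, norm.gene_ids)
        planted = truth.enriched_set_names[0]
        by_key = {(e.set_name, e.query.direction): e for e in enr}
        if by_key[(planted, "down")].significant:
            planted_sig += 1
    return {
        "recovered_down_fraction": float(truth_down_fracs[0]),
        "recovered_down_fraction_mean": float(np.mean(truth_down_fracs)),
        "partition_down_fraction": float(raw_down_fracs[0]),
        "recall_down": float(np.mean(recalls_down)),
        "recall_up": float(np.mean(recalls_up)),
        "planted_set_significant_runs": planted_sig,
        "n_runs": n_runs,
    }


def correlation_recovery(seed: int, n_runs: int = 100, rho: float = 0.6) -> dict:
    """Bivariate densitometry/transport simulations at the cohort size (19+25).

    Runs the full stage — loading-reference normalization, subject pairing,
    Pearson estimate — with no group shift, and counts how often the 95%
    Fisher-z interval covers the planted correlation.
    """
    covered = 0
    estimates = []
    n_subjects = None
    for i in range(n_runs):
        cfg = SimulationConfig(seed=seed + i, rho_densitometry=rho,
                               iugr_shift_log=0.0)
        dens, transport, _ = simulate_densitometry(cfg)
        rel = normalize_densitometry(dens, "AGA")
        paired = pair_by_subject(rel, transport, "relative_expression", "uptake")
        res = correlate(paired["relative_expression"], paired["uptake"])
        lo, hi = fisher_z_interval(res.r_pearson, res.n_subjects)
        covered += lo <= rho <= hi
        estimates.append(res.r_pearson)
        n_subjects = res.n_subjects
    return {
        "coverage_runs": covered,
        "n_runs": n_runs,
        "mean_r": float(np.mean(estimates)),
        "true_rho": rho,
        "n_subjects": n_subjects,
    }
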