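"""Planted-truth simulator for every input the pipeline consumes.

The generator emulates the study design the pipeline was built for: two
groups of 4 bead-array hybridizations (scramble siRNA vs raptor siRNA in
primary human trophoblast cells), ~20,000 measured genes with log-normal raw
intensities, 739 planted differentially expressed genes of which 66% are
down-regulated, gene sets of KEGG-like sizes with planted enrichment (the
default planted set — 88 genes containing 18 true down-DEGs — mirrors a
ribosome-pathway regime), and an AGA/IUGR densitometry cohort (19 + 25
subjects) whose protein and transport variables share a planted Pearson
correlation.

The generative model is additive on the log2 scale: per-gene baselines are
Normal(baseline_mean_log2, baseline_sd_log2); planted DEGs shift the
treatment group by ±effect_size_log2; i.i.d. Normal(0, noise_sd_log2)
measurement noise is added; values are exponentiated to the raw scale so the
pipeline's log2 transform recovers the construction. Effects multiplicative
on the raw scale are how array fold-changes behave.

Everything is driven by one integer seed; per-stage substreams are derived
by fixed offsets so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix_io import RAW, ExpressionMatrix, GeneSetCollection, StudyDesign

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "study_design",
    "simulate_expression",
    "simulate_genesets",
    "simulate_densitometry",
]

CONTROL_GROUP = "scramble"
TREATMENT_GROUP = "raptor_kd"

# fixed substream offsets (one global seed, independent per-stage streams)
_STREAM_EXPRESSION = 1
_STREAM_GENESETS = 2
_STREAM_DENSITOMETRY = 3
_STREAM_QUALITY = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator; defaults encode the emulated design."""

    n_genes: int = 20_000
    n_per_group: int = 4
    baseline_mean_log2: float = 8.0      # typical bead-array log2 intensity
    baseline_sd_log2: float = 1.5        # spread of expression levels across genes
    noise_sd_log2: float = 0.5           # replicate noise per value
    n_deg: int = 739
    frac_down: float = 0.66
    effect_size_log2: float = 2.0        # |log2 fold change| of planted DEGs
    # planted gene sets: (set size, planted down-DEG count)
    sets_spec: tuple[tuple[int, int], ...] = ((88, 18),)
    n_null_sets: int = 10
    null_set_sizes: tuple[int, ...] = (10, 20, 30, 50, 80, 120, 200, 300, 400, 500)
    disjoint_sets: bool = False
    quality_degrade_frac: float = 0.0    # fraction of genes given a failing score
    # densitometry cohort (AGA/IUGR)
    n_aga: int = 19
    n_iugr: int = 25
    rho_densitometry: float = 0.6
    iugr_shift_log: float = -0.4         # natural-log shift of IUGR means
    densitometry_sd_log: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_deg > self.n_genes:
            raise ValidationError("n_deg exceeds n_genes")
        if not (0.0 <= self.frac_down <= 1.0):
            raise ValidationError("frac_down outside [0, 1]")
        for sd in (self.baseline_sd_log2, self.noise_sd_log2, self.densitometry_sd_log):
            if sd <= 0:
                raise ValidationError("all standard deviations must be > 0")
        if self.n_per_group < 2:
            raise ValidationError("each group needs at least 2 samples")
        for size, planted in self.sets_spec:
            if planted > size:
                raise ValidationError(f"planted count {planted} exceeds set size {size}")
        if not (-1.0 < self.rho_densitometry < 1.0):
            raise ValidationError("|rho_densitometry| must be < 1")
        if not (0.0 <= self.quality_degrade_frac <= 1.0):
            raise ValidationError("quality_degrade_frac outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score the pipeline against the construction."""

    down_ids: tuple[str, ...]
    up_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    enriched_set_names: tuple[str, ...] = ()
    true_rho: float = float("nan")

    @property
    def deg_ids(self) -> tuple[str, ...]:
        return self.down_ids + self.up_ids

    def direction_of(self, gene_id: str) -> str:
        if gene_id in set(self.down_ids):
            return "down"
        if gene_id in set(self.up_ids):
            return "up"
        return "none"


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed), stream)))


def study_design(cfg: SimulationConfig) -> StudyDesign:
    """Two-group design matching the simulated sample names."""
    assignments = {f"SCR_{i + 1}": CONTROL_GROUP for i in range(cfg.n_per_group)}
    assignments.update(
        {f"RAP_{i + 1}": TREATMENT_GROUP for i in range(cfg.n_per_group)})
    return StudyDesign(assignments, CONTROL_GROUP, TREATMENT_GROUP)


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Raw two-group expression matrix with planted DEGs and full quality scores.

    Returns the matrix on the raw intensity scale (2**log2), quality all 1.0
    unless ``quality_degrade_frac`` > 0, and the planted ground truth.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_EXPRESSION)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    design = study_design(cfg)
    samples = design.control_samples + design.treatment_samples

    baseline = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, cfg.n_genes)
    deg_idx = rng.choice(cfg.n_genes, size=cfg.n_deg, replace=False)
    n_down = int(round(cfg.frac_down * cfg.n_deg))
    down_idx, up_idx = deg_idx[:n_down], deg_idx[n_down:]

    effect = np.zeros(cfg.n_genes)
    effect[down_idx] = -cfg.effect_size_log2
    effect[up_idx] = +cfg.effect_size_log2

    log2 = np.tile(baseline[:, None], (1, 2 * cfg.n_per_group))
    log2[:, cfg.n_per_group:] += effect[:, None]  # treatment columns
    log2 += rng.normal(0.0, cfg.noise_sd_log2, log2.shape)

    values = pd.DataFrame(np.exp2(log2), index=gene_ids, columns=samples)
    values.index.name = "gene_id"
    quality = pd.DataFrame(1.0, index=values.index, columns=values.columns)
    if cfg.quality_degrade_frac > 0:
        qrng = _rng(cfg, _STREAM_QUALITY)
        n_bad = int(round(cfg.quality_degrade_frac * cfg.n_genes))
        bad_genes = qrng.choice(cfg.n_genes, size=n_bad, replace=False)
        bad_samples = qrng.integers(0, len(samples), size=n_bad)
        q = quality.to_numpy()
        q[bad_genes, bad_samples] = qrng.uniform(0.0, 0.95, size=n_bad)
        quality = pd.DataFrame(q, index=values.index, columns=values.columns)

    truth = GroundTruth(
        down_ids=tuple(sorted(gene_ids[i] for i in down_idx)),
        up_ids=tuple(sorted(gene_ids[i] for i in up_idx)),
        gene_ids=tuple(gene_ids),
    )
    return ExpressionMatrix(values, quality, RAW), truth


def simulate_genesets(cfg: SimulationConfig, truth: GroundTruth) -> tuple[GeneSetCollection, GroundTruth]:
    """Gene sets with planted down-DEG overlap plus size-matched null sets.

    Planted set i receives its specified number of true down-DEGs plus random
    non-DEG fillers; null sets draw only non-DEG genes, so their enrichment
    z is centered at 0 by construction. With ``disjoint_sets`` every set is
    pairwise disjoint. Returns the collection and the truth updated with the
    planted set names.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_GENESETS)
    non_deg = [g for g in truth.gene_ids if g not in set(truth.deg_ids)]
    down_pool = list(truth.down_ids)
    used: set[str] = set()

    def draw(pool: list[str], k: int) -> list[str]:
        avail = [g for g in pool if g not in used] if cfg.disjoint_sets else pool
        if k > len(avail):
            raise ValidationError(
                f"not enough genes to draw {k} (only {len(avail)} available)")
        picked = list(rng.choice(avail, size=k, replace=False))
        used.update(picked)
        return picked

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    planted_names = []
    for i, (size, planted) in enumerate(cfg.sets_spec, start=1):
        name = f"PLANTED_{i:02d}"
        members = draw(down_pool, planted) + draw(non_deg, size - planted)
        sets[name] = (f"planted set: {planted} true down-DEGs of {size}",
                      tuple(sorted(members)))
        if planted > 0:
            planted_names.append(name)
    for i in range(cfg.n_null_sets):
        size = cfg.null_set_sizes[i % len(cfg.null_set_sizes)]
        name = f"NULL_{i + 1:02d}"
        sets[name] = ("null set: no planted members",
                      tuple(sorted(draw(non_deg, size))))
    collection = GeneSetCollection(sets)
    return collection, replace(truth, enriched_set_names=tuple(planted_names))


def simulate_densitometry(cfg: SimulationConfig,
                          target: str = "RPL26",
                          ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired densitometry and transport tables with planted correlation.

    Protein (band density over loading reference) and transport (System A
    uptake) values are generated from a bivariate normal on the natural-log
    scale with correlation ``rho_densitometry``, then exponentiated to keep
    densities positive; the IUGR group means are shifted down by
    ``iugr_shift_log`` to emulate reduced ribosomal-protein expression and
    transport. Returns (densitometry table, transport table, truth).
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_DENSITOMETRY)
    n = cfg.n_aga + cfg.n_iugr
    subjects = [f"AGA_{i + 1:02d}" for i in range(cfg.n_aga)] + \
               [f"IUGR_{i + 1:02d}" for i in range(cfg.n_iugr)]
    groups = ["AGA"] * cfg.n_aga + ["IUGR"] * cfg.n_iugr

    rho = cfg.rho_densitometry
    cov = cfg.densitometry_sd_log ** 2 * np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    shift = np.where(np.array(groups) == "IUGR", cfg.iugr_shift_log, 0.0)
    protein = np.exp(latent[:, 0] + shift)
    uptake = np.exp(latent[:, 1] + shift)

    loading = np.exp(rng.normal(0.0, 0.2, size=n))  # loading-reference variation
    scale = 1000.0  # arbitrary densitometry units
    dens = pd.DataFrame({
        "subject_id": subjects,
        "group": groups,
        "target": target,
        "raw_density": protein * loading * scale,
        "loading_reference": loading * scale,
    })
    transport = pd.DataFrame({
        "subject_id": subjects,
        "group": groups,
        "uptake": uptake,
    })
    truth = GroundTruth(down_ids=(), up_ids=(), gene_ids=(), true_rho=rho)
    return dens, transport, truth
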