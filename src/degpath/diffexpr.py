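"""Per-gene two-group t-tests and the up/down DEG partition.

Each gene is tested with a two-sided Student t-test (pooled variance by
default; Welch available) between the control and treatment groups on
log2-centered values, and called differentially expressed at raw p < alpha
(default 0.05, no multiple-testing correction — a Benjamini–Hochberg q-value
column is emitted for information only and never used for the call). The
direction of change is the sign of delta = mean(treatment) − mean(control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix_io import LOG2_CENTERED, ExpressionMatrix, StudyDesign

__all__ = ["GeneTestResult", "DegPartition", "gene_ttest", "run_differential"]

STUDENT = "student"
WELCH = "welch"


@dataclass(frozen=True)
class GeneTestResult:
    """t-test outcome for one gene (log2 units throughout)."""

    gene_id: str
    mean_control: float
    mean_treatment: float
    delta: float  # treatment - control
    t_stat: float
    df: float
    p_value: float
    direction: str  # "up" | "down" | "none"
    degenerate: bool = False  # both groups zero-variance with unequal means
    q_value: float | None = None  # BH-adjusted, informational only


@dataclass(frozen=True)
class DegPartition:
    """Up/down split of the significant genes at a given alpha."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    alpha: float

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("a gene cannot be both up- and down-regulated")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def down_fraction(self) -> float:
        return self.n_down / self.n_total if self.n_total else math.nan


def _t_arrays(x: np.ndarray, y: np.ndarray, variant: str):
    """Vectorized two-sided t-test on the last axis. Returns (t, df, p, degenerate)."""
    n1, n2 = x.shape[-1], y.shape[-1]
    m1, m2 = x.mean(axis=-1), y.mean(axis=-1)
    v1 = x.var(axis=-1, ddof=1)
    v2 = y.var(axis=-1, ddof=1)
    delta = m2 - m1
    if variant == STUDENT:
        df = np.full_like(delta, float(n1 + n2 - 2))
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == WELCH:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))
    else:
        raise ValidationError(f"unknown test variant {variant!r}")
    degenerate = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
        # both groups constant: equal means -> t=0, p=1; unequal -> +/-inf, p=0
        t = np.where(degenerate,
                     np.where(delta == 0.0, 0.0, np.sign(delta) * np.inf), t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where(degenerate & (t == 0.0), 1.0, p)
    degenerate = degenerate & (t != 0.0)
    return t, df, p, delta, m1, m2, degenerate


def gene_ttest(x, y, variant: str = STUDENT) -> GeneTestResult:
    """Two-sided t-test for one gene; ``x`` control, ``y`` treatment values.

    Pooled-variance Student test by default. Both-groups-constant input is
    handled explicitly rather than propagating NaN: equal means give
    (t=0, p=1); unequal means give a degenerate flag with a ±inf t sentinel
    and p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    t, df, p, delta, m1, m2, degen = _t_arrays(x[None, :], y[None, :], variant)
    return GeneTestResult(
        gene_id="", mean_control=float(m1[0]), mean_treatment=float(m2[0]),
        delta=float(delta[0]), t_stat=float(t[0]), df=float(df[0]),
        p_value=float(p[0]), direction="none", degenerate=bool(degen[0]),
    )


def run_differential(m: ExpressionMatrix, design: StudyDesign,
                     alpha: float = 0.05, variant: str = STUDENT,
                     ) -> tuple[list[GeneTestResult], DegPartition]:
    """Test every gene and partition the significant ones by direction.

    Results are sorted by ascending p-value with lexicographic gene-ID
    tie-break; the partition lists inherit that order. ``direction`` is
    ``up``/``down`` iff p < alpha and delta is positive/negative.
    """
    if m.scale != LOG2_CENTERED:
        raise ValidationError("run_differential expects a normalized (log2-centered) matrix")
    if not (0.0 <= alpha < 1.0):
        raise ValidationError(f"alpha {alpha} outside [0, 1)")
    missing = [s for s in design.assignments if s not in m.values.columns]
    if missing:
        raise ValidationError(f"design samples absent from matrix: {missing}")

    gene_ids = m.gene_ids
    x = m.values[design.control_samples].to_numpy()
    y = m.values[design.treatment_samples].to_numpy()
    t, df, p, delta, m1, m2, degen = _t_arrays(x, y, variant)
    q = multipletests(p, method="fdr_bh")[1]

    sig = p < alpha
    direction = np.where(sig & (delta > 0), "up",
                         np.where(sig & (delta < 0), "down", "none"))
    order = sorted(range(m.n_genes), key=lambda i: (p[i], gene_ids[i]))
    results = [
        GeneTestResult(
            gene_id=gene_ids[i], mean_control=float(m1[i]),
            mean_treatment=float(m2[i]), delta=float(delta[i]),
            t_stat=float(t[i]), df=float(df[i]), p_value=float(p[i]),
            direction=str(direction[i]), degenerate=bool(degen[i]),
            q_value=float(q[i]),
        )
        for i in order
    ]
    partition = DegPartition(
        up=tuple(r.gene_id for r in results if r.direction == "up"),
        down=tuple(r.gene_id for r in results if r.direction == "down"),
        alpha=alpha,
    )
    return results, partition
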