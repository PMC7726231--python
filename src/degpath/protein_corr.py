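"""Densitometry normalization and protein–phenotype correlation.

The clinical stage of the pipeline: Western-blot band densities for placental
targets (e.g. RPL26, RPS10, phospho-4E-BP1 Thr-37/46) are divided by a
loading reference (β-actin or a total-protein stain), scaled so the
control-group (AGA) mean equals exactly 1, compared between AGA and IUGR
groups by unpaired Student t-test, and correlated (Pearson) against
continuous readouts such as microvillous-membrane System A amino acid
uptake. Correlations are computed on the pooled AGA+IUGR subjects (both
groups share one axis on the published scatter plots); per-group values can
be obtained by subsetting before the call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import STUDENT, gene_ttest
from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "normalize_densitometry",
    "group_compare",
    "correlate",
    "pair_by_subject",
    "fisher_z_interval",
]

logger = logging.getLogger(__name__)

DENSITOMETRY_COLUMNS = ("subject_id", "group", "target", "raw_density",
                        "loading_reference")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two paired per-subject variables."""

    pair: tuple[str, str]
    r_pearson: float
    n_subjects: int
    p_value: float  # two-sided, from t = r sqrt((n-2)/(1-r^2)) on n-2 df


@dataclass(frozen=True)
class GroupComparison:
    """Means ± SEM per group plus the unpaired two-sided t-test."""

    means: dict
    sems: dict
    n: dict
    t_stat: float
    df: float
    p_value: float


def normalize_densitometry(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Express band densities relative to the control-group mean.

    Each row's ``raw_density`` is divided by its ``loading_reference``; the
    ratio is then divided, per target, by the mean ratio of the
    ``control_group`` subjects, so that the control mean of the returned
    ``relative_expression`` column is exactly 1.
    """
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"densitometry table lacks columns {missing}")
    if (table["loading_reference"] <= 0).any():
        bad = table.loc[table["loading_reference"] <= 0, "subject_id"].iloc[0]
        raise ValidationError(f"non-positive loading reference for subject {bad!r}")
    if (table["raw_density"] <= 0).any():
        bad = table.loc[table["raw_density"] <= 0, "subject_id"].iloc[0]
        raise ValidationError(f"non-positive raw density for subject {bad!r}")
    out = table.copy()
    ratio = out["raw_density"] / out["loading_reference"]
    rel = np.empty(len(out))
    for target, idx in out.groupby("target").groups.items():
        ctrl = idx[(out.loc[idx, "group"] == control_group).to_numpy()]
        if len(ctrl) == 0:
            raise ValidationError(
                f"control group {control_group!r} empty for target {target!r}"
            )
        rel[out.index.get_indexer(idx)] = ratio[idx] / ratio[ctrl].mean()
    out["relative_expression"] = rel
    return out


def group_compare(values, groups) -> GroupComparison:
    """Unpaired two-sided Student t-test between the two labels in ``groups``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValidationError(f"group_compare needs exactly two groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    res = gene_ttest(a, b, variant=STUDENT)
    return GroupComparison(
        means={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        sems={labels[0]: float(stats.sem(a)), labels[1]: float(stats.sem(b))},
        n={labels[0]: int(a.size), labels[1]: int(b.size)},
        t_stat=res.t_stat, df=res.df, p_value=res.p_value,
    )


def correlate(x, y, pair: tuple[str, str] = ("A", "B")) -> CorrelationResult:
    """Pearson correlation of two paired vectors with a two-sided t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(pair=pair, r_pearson=r, n_subjects=n, p_value=p)


def pair_by_subject(left: pd.DataFrame, right: pd.DataFrame,
                    left_value: str, right_value: str) -> pd.DataFrame:
    """Inner-join two per-subject tables on ``subject_id``.

    Subjects missing either measurement are dropped with a logged count —
    protein and transport panels rarely cover identical cohorts.
    """
    for df, col in ((left, left_value), (right, right_value)):
        if "subject_id" not in df.columns or col not in df.columns:
            raise ValidationError(f"table lacks 'subject_id' or {col!r}")
    merged = left[["subject_id", left_value]].merge(
        right[["subject_id", right_value]], on="subject_id", how="inner")
    dropped = (len(left) - len(merged)) + (len(right) - len(merged))
    if dropped:
        logger.info("pair_by_subject: dropped %d unmatched measurements", dropped)
    return merged


def fisher_z_interval(r: float, n: int, confidence: float = 0.95,
                      ) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation (n > 3)."""
    if n <= 3:
        raise ValidationError("Fisher-z interval needs n > 3")
    if abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))
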