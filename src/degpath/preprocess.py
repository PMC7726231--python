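"""All-median normalization and log2 transform.

Array intensities are multiplicative: a sample hybridized slightly hotter is
brighter across the board. The classical array-era fix is to log2-transform
and subtract each sample's median, after which every sample's median log2
value is exactly zero and between-sample comparisons are additive. Median
scaling in raw space followed by log2 is algebraically the same thing; this
module works on the log scale so that the QC criterion (post-normalization
medians equal 0) holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StateError, ValidationError
from .matrix_io import LOG2_CENTERED, RAW, ExpressionMatrix

__all__ = ["NormalizationReport", "normalize", "recenter", "qc_boxplot_stats"]


@dataclass(frozen=True)
class NormalizationReport:
    """Per-sample medians (log2 units) before/after centering and the offsets applied."""

    per_sample_median_before: pd.Series
    per_sample_median_after: pd.Series
    offset_applied: pd.Series


def normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationReport]:
    """log2-transform a raw matrix and subtract each sample's median log2 value.

    Raises
    ------
    StateError
        If the matrix is already normalized.
    ValidationError
        If any intensity is <= 0 (background-corrected arrays can go negative,
        but silently offsetting data would fabricate values; the caller must
        decide how to handle such probes).
    """
    if m.scale != RAW:
        raise StateError("matrix is already log2-centered; normalize expects raw input")
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        g, s = np.argwhere(vals <= 0)[0]
        raise ValidationError(
            f"non-positive intensity at gene {m.gene_ids[g]!r}, sample "
            f"{m.sample_ids[s]!r}: {vals[g, s]!r} (cannot take log2)"
        )
    log2 = pd.DataFrame(np.log2(vals), index=m.values.index, columns=m.values.columns)
    return _center(log2, m.quality)


def recenter(m: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Re-apply median centering to an already log2-centered matrix.

    Normalization is idempotent in effect: on properly centered input every
    offset is 0 and the values are returned unchanged.
    """
    if m.scale != LOG2_CENTERED:
        raise StateError("recenter expects a log2-centered matrix")
    return _center(m.values, m.quality)


def _center(log2: pd.DataFrame, quality) -> tuple[ExpressionMatrix, NormalizationReport]:
    before = log2.median(axis=0)
    centered = log2.sub(before, axis=1)
    after = centered.median(axis=0)
    report = NormalizationReport(
        per_sample_median_before=before.rename("median_before"),
        per_sample_median_after=after.rename("median_after"),
        offset_applied=before.rename("offset"),
    )
    return ExpressionMatrix(centered, quality, LOG2_CENTERED), report


def qc_boxplot_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per sample.

    Used to eyeball that medians sit at 0 and spreads are comparable across
    samples after normalization.
    """
    if m.scale != LOG2_CENTERED:
        raise StateError("qc_boxplot_stats expects a log2-centered matrix")
    q = np.percentile(m.values.to_numpy(), [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(
        q.T, index=m.sample_ids, columns=["min", "q1", "median", "q3", "max"]
    ).rename_axis("sample_id")
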