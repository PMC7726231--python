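"""Directional gene-set enrichment by the hypergeometric z-score.

For a gene set, let N be the number of genes measured (the background
universe), R the number of genes meeting the selection criterion (here, the
up- or down-regulated DEG list), n the number of measured genes annotated to
the set, and r the number of selected genes annotated to the set. The
enrichment statistic is

    z = (r - n R/N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

which is exactly (r - mu) / sigma of the hypergeometric(N, R, n) distribution
— the number of annotated genes expected in a random draw of R genes from the
universe. |z| >= 2 is the conventional significance call; positive z means
over-representation, negative z depletion.

Legacy array suites printed r, n and z per pathway but not N. Because z is a
smooth, monotone function of N at fixed (r, n, R), an integer grid search over
candidate backgrounds recovers the N a published table used
(:func:`calibrate_background`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .diffexpr import DegPartition
from .errors import ValidationError
from .matrix_io import GeneSetCollection

__all__ = [
    "EnrichmentQuery",
    "EnrichmentResult",
    "CalibrationFit",
    "zscore",
    "zscore_counts",
    "hypergeom_moments",
    "hypergeom_moment_table",
    "enrich_collection",
    "calibrate_background",
]

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class EnrichmentQuery:
    """The four counts of the z statistic for one set and one direction."""

    N: int  # genes measured (background universe)
    R: int  # genes meeting the selection criterion (DEG list for the direction)
    n: int  # measured genes annotated to the set
    r: int  # selected genes annotated to the set
    direction: str = DOWN

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValidationError(f"background N={self.N} must be >= 2")
        if not (0 <= self.R <= self.N):
            raise ValidationError(f"R={self.R} outside [0, N={self.N}]")
        if not (0 <= self.n <= self.N):
            raise ValidationError(f"n={self.n} outside [0, N={self.N}]")
        if not (0 <= self.r <= min(self.n, self.R)):
            raise ValidationError(f"r={self.r} outside [0, min(n={self.n}, R={self.R})]")
        if self.direction not in (UP, DOWN):
            raise ValidationError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """z statistic and significance call for one set in one direction."""

    set_name: str
    query: EnrichmentQuery
    z: float
    significant: bool
    n_diff: int  # r_up + r_down, mirroring a "diff regulated genes" column
    n_catalog: int  # full catalog set size, before intersecting with the universe


@dataclass(frozen=True)
class CalibrationFit:
    """Best-fitting integer background size against printed (r, n, z) rows."""

    N_hat: int
    residuals: tuple[float, ...]  # z(N_hat) - z_printed per row
    objective: float  # sum of squared residuals at N_hat
    search_range: tuple[int, int]

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals)

    @property
    def median_abs_residual(self) -> float:
        return float(np.median([abs(r) for r in self.residuals]))


def zscore_counts(r, n, R, N):
    """The z statistic from raw counts; broadcasts over numpy arrays.

    Undefined (division by zero variance) when R=0, R=N, n=0 or n=N.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any((R <= 0) | (R >= N) | (n <= 0) | (n >= N)):
        raise ValidationError(
            "z-score undefined: R and n must both lie strictly between 0 and N"
        )
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1.0) / (N - 1.0))
    out = (r - n * p) / np.sqrt(var)
    return out if out.ndim else float(out)


def zscore(q: EnrichmentQuery) -> float:
    """z statistic for a validated query (see module docstring for the formula)."""
    return float(zscore_counts(q.r, q.n, q.R, q.N))


def hypergeom_moments(N: int, R: int, n: int) -> tuple[float, float]:
    """Mean and SD of hypergeometric(N, R, n) by explicit summation of the pmf.

    Deliberately avoids the closed forms so it can serve as an independent
    cross-check of :func:`zscore`: the pmf is evaluated term by term over the
    feasible support of r and the first two central moments are accumulated.
    """
    if not (0 <= R <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, R={R}, n={n}")
    mean, sd_arr = hypergeom_moment_table(N, R, n_values=np.array([n]))
    return float(mean[0]), float(sd_arr[0])


_BINOM_CACHE: dict = {"n": -1, "table": None}


def _binom_table(N: int) -> np.ndarray:
    """Binomial coefficients C[a, b] for a, b <= N as float64.

    Computed exactly as integers and rounded once to float (relative error
    one ulp), so hypergeometric pmf terms carry no log/exp round-off.
    """
    if _BINOM_CACHE["n"] < N:
        t = np.zeros((N + 1, N + 1))
        for a in range(N + 1):
            t[a, :a + 1] = [float(math.comb(a, b)) for b in range(a + 1)]
        _BINOM_CACHE["n"] = N
        _BINOM_CACHE["table"] = t
    return _BINOM_CACHE["table"]


def hypergeom_moment_table(N: int, R: int, n_values=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized explicit-summation moments for many n at fixed (N, R).

    Returns (means, sds) aligned with ``n_values`` (default: all n in 0..N).
    For N up to 1000 the pmf is built from exact binomial coefficients,
    keeping the summed moments accurate to a few ulps even on two-point
    supports; beyond that (where C(N, n) overflows float64) a log-gamma
    formulation takes over.
    """
    if n_values is None:
        n_values = np.arange(N + 1)
    n_values = np.asarray(n_values, dtype=int)

    n = n_values[:, None]                  # (k, 1)
    r = np.arange(min(N, R) + 1)[None, :]  # (1, Rmax+1)
    valid = (r <= n) & (n - r <= N - R)
    rs = np.where(valid, r, 0)
    nr = np.where(valid, n - r, 0)
    if N <= 1000:
        t = _binom_table(N)
        pmf = np.where(valid, t[R, rs] * t[N - R, nr] / t[N, n], 0.0)
    else:
        lg = gammaln(np.arange(N + 1) + 1.0)  # lg[k] = log(k!)
        logpmf = (
            (lg[R] - lg[rs] - lg[R - rs])
            + (lg[N - R] - lg[nr] - lg[N - R - nr])
            - (lg[N] - lg[n] - lg[N - n])
        )
        pmf = np.where(valid, np.exp(logpmf), 0.0)
    pmf /= pmf.sum(axis=1, keepdims=True)
    means = (r * pmf).sum(axis=1)
    var = ((r - means[:, None]) ** 2 * pmf).sum(axis=1)
    return means, np.sqrt(np.maximum(var, 0.0))


def enrich_collection(partition: DegPartition, sets: GeneSetCollection,
                      universe, z_threshold: float = 2.0,
                      directions: tuple[str, ...] = (DOWN, UP),
                      ) -> list[EnrichmentResult]:
    """Score every set in every requested direction against the DEG partition.

    ``universe`` is the list of measured genes (the background); N is its
    size. For direction ``down``, R is the size of the down list and r the
    overlap of the set with it; analogously for ``up``. Sets with no measured
    members, and degenerate queries (R=0 or n=N) are skipped with a logged
    notice. Results are sorted by descending |z| with (set, direction)
    tie-break.
    """
    universe_set = {str(g).upper() for g in universe}
    N = len(universe_set)
    for name, lst in (("up", partition.up), ("down", partition.down)):
        stray = set(lst) - universe_set
        if stray:
            raise ValidationError(
                f"{name} DEG list contains genes outside the universe: {sorted(stray)[:5]}"
            )
    if N < partition.n_total:
        raise ValidationError("universe smaller than the DEG list")

    selected = {DOWN: set(partition.down), UP: set(partition.up)}
    results: list[EnrichmentResult] = []
    for set_name, (_, members) in sets:
        measured = universe_set.intersection(members)
        n = len(measured)
        if n == 0:
            logger.info("set %r skipped: no members in the measured universe", set_name)
            continue
        r_by_dir = {d: len(measured & selected[d]) for d in (DOWN, UP)}
        n_diff = r_by_dir[DOWN] + r_by_dir[UP]
        for direction in directions:
            R = partition.n_down if direction == DOWN else partition.n_up
            if R == 0 or R == N or n == N:
                logger.info("set %r (%s) skipped: degenerate query (R=%d, n=%d, N=%d)",
                            set_name, direction, R, n, N)
                continue
            query = EnrichmentQuery(N=N, R=R, n=n, r=r_by_dir[direction],
                                    direction=direction)
            z = zscore(query)
            results.append(EnrichmentResult(
                set_name=set_name, query=query, z=z,
                significant=abs(z) >= z_threshold, n_diff=n_diff,
                n_catalog=len(members),
            ))
    results.sort(key=lambda e: (-abs(e.z), e.set_name, e.query.direction))
    return results


def calibrate_background(rows, R: int, search: tuple[int, int]) -> CalibrationFit:
    """Recover the background size N behind a printed enrichment table.

    ``rows`` is a sequence of (r, n, z_printed) triples sharing one selection
    size R. An integer grid search over ``search = (lo, hi)`` minimizes the
    sum of squared differences between the recomputed and printed z values;
    ties break toward the smaller N for determinism. At least two rows are
    required — a single row is solved exactly by a one-parameter curve of N
    values and pins nothing down.
    """
    rows = [(int(r), int(n), float(z)) for r, n, z in rows]
    if len(rows) < 2:
        raise ValidationError("calibration needs at least 2 (r, n, z) rows")
    lo, hi = int(search[0]), int(search[1])
    feasible_lo = max(R, max(n for _, n, _ in rows)) + 1
    lo = max(lo, feasible_lo)
    if lo > hi:
        raise ValidationError(
            f"empty feasible search range: need N >= {feasible_lo}, got upper bound {hi}"
        )
    N_grid = np.arange(lo, hi + 1, dtype=float)
    objective = np.zeros_like(N_grid)
    for r, n, z_printed in rows:
        objective += (zscore_counts(r, n, R, N_grid) - z_printed) ** 2
    best = int(np.argmin(objective))  # argmin returns the first (smallest N) tie
    N_hat = int(N_grid[best])
    residuals = tuple(float(zscore_counts(r, n, R, N_hat) - z) for r, n, z in rows)
    return CalibrationFit(N_hat=N_hat, residuals=residuals,
                          objective=float(objective[best]), search_range=(lo, hi))
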