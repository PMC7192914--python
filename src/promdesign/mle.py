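"""Maximum-likelihood promoter activity estimation from binned sort counts.

Each sorted cell's log10 GFP:mCherry activity is modelled as Normal(mu_s,
sigma) around its sequence's mean, with a shared sigma, except that with
probability epsilon a cell is a contaminant landing in a uniformly random
bin.  The probability of observing a cell from sequence s in bin i with
edges (a_i, b_i) is

    P(i) = [F(b_i; mu, sigma) - F(a_i; mu, sigma)] * (1 - eps) + eps / N

with F the normal CDF.  Given per-bin cell counts r_i, the log-likelihood of
mu is  sum_i r_i * log P(i).  Over a grid of M candidate mu values and N
bins, W[i, j] = log P_{mu_j}(i); the matrix product A @ W scores all
sequences against all candidates at once, and the per-sequence argmax is the
estimate.  Summing the per-sequence maxima scores a (sigma, epsilon) pair
for the hyperparameter grid search.

By default the outermost bin edges are treated as -inf / +inf so that the
bin probabilities normalize (the sort gates cover the activity range
present); ``unbounded_tails=False`` restores finite outer edges for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_LOW_READS = "low_reads"
FLAG_EXTREME_BIN = "extreme_bin"
FLAG_REPLICATE_DISCORDANT = "replicate_discordant"
FLAG_NO_READS = "no_reads"


@dataclass(frozen=True)
class BinLayout:
    """Contiguous, increasing sort-bin edges in log10 activity units."""

    edges: np.ndarray  # length N + 1

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if not (np.diff(edges) > 0).all():
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def equal_width(cls, lo: float, hi: float, n_bins: int = 12) -> "BinLayout":
        return cls(np.linspace(lo, hi, n_bins + 1))

    def rescaled(self, slope: float, intercept: float) -> "BinLayout":
        return BinLayout(self.edges * slope + intercept)


@dataclass(frozen=True)
class MixtureParams:
    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass(frozen=True)
class LikelihoodGrid:
    mu_grid: np.ndarray  # (M,)
    W: np.ndarray  # (N, M) log bin-probabilities


def normalize_counts(
    raw_reads: np.ndarray, cells_sorted: np.ndarray, total_reads: np.ndarray
) -> np.ndarray:
    """Convert per-bin read counts to estimated cell counts.

    A[s, i] = r[s, i] * C_i / R_i where C_i is the number of cells sorted
    into bin i and R_i the total reads observed in bin i.  Bins with zero
    total reads contribute zero, with a logged warning.
    """
    r = np.atleast_2d(np.asarray(raw_reads, dtype=float))
    C = np.asarray(cells_sorted, dtype=float)
    R = np.asarray(total_reads, dtype=float)
    if (r < 0).any() or (C < 0).any() or (R < 0).any():
        raise ValueError("negative inputs")
    scale = np.zeros_like(R)
    ok = R > 0
    scale[ok] = C[ok] / R[ok]
    if (~ok).any():
        logger.warning("bins with zero reads contribute nothing: %s", np.nonzero(~ok)[0])
    return r * scale


def bin_prob(
    mu: float,
    params: MixtureParams,
    layout: BinLayout,
    unbounded_tails: bool = True,
) -> np.ndarray:
    """Probability of a cell with mean ``mu`` being observed in each bin."""
    return _bin_probs(np.asarray([mu], dtype=float), params, layout, unbounded_tails)[:, 0]


def _bin_probs(
    mu_grid: np.ndarray,
    params: MixtureParams,
    layout: BinLayout,
    unbounded_tails: bool = True,
) -> np.ndarray:
    """(N, M) matrix of bin probabilities for a grid of mu values."""
    edges = layout.edges.copy()
    if unbounded_tails:
        edges[0], edges[-1] = -np.inf, np.inf
    F = norm.cdf((edges[:, None] - mu_grid[None, :]) / params.sigma)
    core = np.diff(F, axis=0)
    return core * (1.0 - params.epsilon) + params.epsilon / layout.n_bins


def loglik_matrix(
    layout: BinLayout,
    mu_grid: np.ndarray,
    params: MixtureParams,
    unbounded_tails: bool = True,
) -> LikelihoodGrid:
    """W[i, j] = log P_{mu_j, sigma, eps}(i) over the candidate-mu grid."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.size == 0:
        raise ValueError("mu_grid must be nonempty")
    P = _bin_probs(mu_grid, params, layout, unbounded_tails)
    # clamp: P can underflow to 0 for mu far outside a bin when epsilon = 0;
    # a finite floor keeps 0-count bins from producing 0 * -inf = nan
    W = np.log(np.clip(P, 1e-300, None))
    return LikelihoodGrid(mu_grid, W)


def fit_means(A: np.ndarray, grid: LikelihoodGrid) -> pd.DataFrame:
    """Per-sequence ML activity via the A @ W product.

    Returns a frame with mu_hat, loglik and a flag; all-zero count rows are
    flagged (no estimate).  Argmax ties break to the smallest mu (the grid
    is ascending and the first maximum is taken).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != grid.W.shape[0]:
        raise ValueError("count columns must match bin count")
    L = A @ grid.W  # (S, M)
    j = L.argmax(axis=1)
    mu_hat = grid.mu_grid[j]
    loglik = L[np.arange(len(A)), j]
    empty = A.sum(axis=1) == 0
    out = pd.DataFrame(
        {
            "mu_hat": np.where(empty, np.nan, mu_hat),
            "loglik": np.where(empty, np.nan, loglik),
            "flag": np.where(empty, FLAG_NO_READS, FLAG_OK),
        }
    )
    return out


def default_mu_grid(layout: BinLayout, step: float = 0.005) -> np.ndarray:
    """Bin range extended by one bin width each side, at ``step`` spacing."""
    width = layout.edges[1] - layout.edges[0]
    lo, hi = layout.edges[0] - width, layout.edges[-1] + width
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def grid_search(
    A: np.ndarray,
    layout: BinLayout,
    sigma_grid: np.ndarray | None = None,
    epsilon_grid: np.ndarray | None = None,
    mu_grid: np.ndarray | None = None,
    unbounded_tails: bool = True,
) -> tuple[MixtureParams, pd.DataFrame]:
    """Hyperparameter grid search over (sigma, epsilon).

    The score of a pair is the sum over sequences of the maximized
    per-sequence log-likelihood.  Returns the argmax pair and the full score
    surface for sensitivity reporting.
    """
    if sigma_grid is None:
        sigma_grid = np.arange(0.05, 0.40 + 1e-9, 0.01)
    if epsilon_grid is None:
        epsilon_grid = np.arange(0.0, 0.20 + 1e-9, 0.01)
    if mu_grid is None:
        mu_grid = default_mu_grid(layout)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    epsilon_grid = np.asarray(epsilon_grid, dtype=float)
    if sigma_grid.size == 0 or epsilon_grid.size == 0:
        raise ValueError("grids must be nonempty")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    rows = []
    best = (-np.inf, None)
    for s in sigma_grid:
        for e in epsilon_grid:
            params = MixtureParams(float(s), float(e))
            grid = loglik_matrix(layout, mu_grid, params, unbounded_tails)
            score = float((A @ grid.W).max(axis=1).sum())
            rows.append({"sigma": float(s), "epsilon": float(e), "score": score})
            if score > best[0]:
                best = (score, params)
    surface = pd.DataFrame(rows)
    return best[1], surface


def combine_replicates(
    mu_rep1: np.ndarray, mu_rep2: np.ndarray, max_diff: float = 0.2
) -> pd.DataFrame:
    """Mean of replicate estimates; flags pairs differing by over
    ``max_diff`` as replicate-discordant and missing pairs as excluded."""
    a = np.asarray(mu_rep1, dtype=float)
    b = np.asarray(mu_rep2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate arrays must align")
    mean = (a + b) / 2.0
    delta = np.abs(a - b)
    missing = np.isnan(a) | np.isnan(b)
    flag = np.where(delta > max_diff, FLAG_REPLICATE_DISCORDANT, FLAG_OK)
    flag = np.where(missing, FLAG_NO_READS, flag)
    return pd.DataFrame({"mu": np.where(missing, np.nan, mean), "flag": flag})


def extreme_bin_filter(raw_reads_rows: np.ndarray) -> np.ndarray:
    """Flag sequences whose nonzero counts all fall in the lowest bin, or
    all in the highest bin.

    Accepts one condition's (S, N) counts, or a (S, N, k) stack of
    conditions / replicates, in which case a sequence is flagged if the rule
    holds in any condition (the inducible-library rule).
    """
    arr = np.asarray(raw_reads_rows)
    if arr.ndim == 1:
        arr = arr[None, :, None]
    elif arr.ndim == 2:
        arr = arr[:, :, None]
    flags = np.zeros(arr.shape[0], dtype=bool)
    for k in range(arr.shape[2]):
        a = arr[:, :, k]
        total = a.sum(axis=1)
        only_low = (a[:, 1:].sum(axis=1) == 0) & (total > 0)
        only_high = (a[:, :-1].sum(axis=1) == 0) & (total > 0)
        flags |= only_low | only_high
    return flags


def read_threshold_filter(raw_reads_rows: list[np.ndarray], min_reads: int) -> np.ndarray:
    """True where total reads reach ``min_reads`` in every supplied
    replicate / condition ("at least" semantics: boundary passes)."""
    if min_reads < 0:
        raise ValueError("min_reads must be nonnegative")
    keep = None
    for rows in raw_reads_rows:
        total = np.atleast_2d(np.asarray(rows)).sum(axis=1)
        ok = total >= min_reads
        keep = ok if keep is None else (keep & ok)
    return keep


def rescale_bin_edges(
    activities_condition_a: np.ndarray, activities_condition_b: np.ndarray
) -> tuple[float, float]:
    """Affine map relating per-cell activities measured under two instrument
    conditions.

    Both samples are sorted; the larger is interpolated onto the smaller's
    quantile grid to pair approximately corresponding cells; ordinary least
    squares on the matched pairs gives (slope, intercept) mapping condition
    A values onto condition B.  Apply to bin edges via
    ``BinLayout.rescaled``.
    """
    a = np.sort(np.asarray(activities_condition_a, dtype=float))
    b = np.sort(np.asarray(activities_condition_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance sample")

    def quantile_grid(n):
        return (np.arange(n) + 0.5) / n

    if len(a) <= len(b):
        x = a
        y = np.interp(quantile_grid(len(a)), quantile_grid(len(b)), b)
    else:
        y = b
        x = np.interp(quantile_grid(len(b)), quantile_grid(len(a)), a)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
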