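"""Pairwise-comparison psychophysics: choice probabilities, Thurstone Case V
scaling, and rank correlation of perception against model statistics.

Observers compare pairs of fishbone surfaces (nine rib intervals, 36
unordered pairs) and report which feels more indented.  Choice proportions
are converted to an interval scale with Thurstone's Case V model (equal,
independent normal discriminal dispersions), and perceived-indentation ranks
are correlated with simulated firing-rate and spike-entropy ranks using
Kendall's tau-b and Spearman's rho with exact permutation p-values at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, norm, rankdata, spearmanr

__all__ = [
    "PairwiseChoiceTable",
    "ScaleEstimate",
    "RankCorrelationResult",
    "choice_probability",
    "thurstone_scale",
    "rank_correlation",
    "correlate_model_perception",
]


@dataclass(frozen=True)
class PairwiseChoiceTable:
    """Counts of 2AFC outcomes over a set of stimuli.

    ``wins[i, j]`` is the number of trials on which stimulus ``i`` was judged
    more indented than ``j``; presentations of the pair are
    ``wins[i, j] + wins[j, i]``.  The diagonal is zero.
    """

    labels: tuple[float, ...]
    wins: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.wins.shape != (n, n):
            raise ValueError("wins must be square over the labels")
        if np.any(self.wins < 0) or np.any(np.diag(self.wins) != 0):
            raise ValueError("wins must be non-negative with a zero diagonal")

    @property
    def n_stimuli(self) -> int:
        return len(self.labels)

    @property
    def presentations(self) -> np.ndarray:
        return self.wins + self.wins.T

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PairwiseChoiceTable":
        """Build a pooled table from tidy trials with columns
        ``interval_a_mm``, ``interval_b_mm``, ``chosen_mm``."""
        labels = tuple(
            sorted(set(trials["interval_a_mm"]) | set(trials["interval_b_mm"]))
        )
        index = {lab: k for k, lab in enumerate(labels)}
        wins = np.zeros((len(labels), len(labels)), dtype=int)
        for a, b, c in zip(
            trials["interval_a_mm"], trials["interval_b_mm"], trials["chosen_mm"]
        ):
            i, j = index[a], index[b]
            if c == a:
                wins[i, j] += 1
            elif c == b:
                wins[j, i] += 1
            else:
                raise ValueError(f"chosen stimulus {c!r} not in pair ({a!r}, {b!r})")
        return cls(labels=labels, wins=wins)


@dataclass(frozen=True)
class ScaleEstimate:
    """Zero-mean latent scale values; only differences are meaningful."""

    labels: tuple[float, ...]
    values: np.ndarray
    method: str = "thurstone_case_v"

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name=self.method)


@dataclass(frozen=True)
class RankCorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str


def choice_probability(tables) -> pd.Series:
    """Per-stimulus probability of being judged more indented.

    ``p_i`` = (trials where ``i`` was chosen) / (trials where ``i`` was
    presented).  Accepts one pooled table or a list of per-participant
    tables (probabilities are then averaged over participants).
    """
    if isinstance(tables, PairwiseChoiceTable):
        tables = [tables]
    per_participant = []
    for table in tables:
        chosen = table.wins.sum(axis=1).astype(float)
        presented = table.presentations.sum(axis=1).astype(float)
        if np.any(presented == 0):
            missing = [table.labels[i] for i in np.nonzero(presented == 0)[0]]
            raise ValueError(f"stimuli never presented: {missing}")
        per_participant.append(
            pd.Series(chosen / presented, index=list(table.labels))
        )
    return pd.concat(per_participant, axis=1).mean(axis=1)


def thurstone_scale(table: PairwiseChoiceTable) -> ScaleEstimate:
    """Thurstone Case V scale values from a pooled choice table.

    ``scale_i`` is the column mean of the probit matrix
    ``z_ij = Phi^{-1}(P(i over j))`` (with ``z_ii = 0``), the classical
    least-squares Case V solution; for two stimuli the scale difference is
    exactly ``Phi^{-1}(P(A over B))``.  Proportions of unanimous pairs are
    clipped to ``[1/(2N), 1 - 1/(2N)]`` (``N`` presentations of that pair)
    so the probit stays finite.  The output is shifted to zero mean.
    """
    n = table.n_stimuli
    pres = table.presentations
    off = ~np.eye(n, dtype=bool)
    if np.any(pres[off] == 0):
        missing = [
            (table.labels[i], table.labels[j])
            for i, j in zip(*np.nonzero((pres == 0) & off))
            if i < j
        ]
        raise ValueError(f"pairs with zero presentations: {missing}")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(off, table.wins / np.where(pres == 0, 1, pres), 0.5)
        lo = 1.0 / (2.0 * np.where(pres == 0, 1, pres))
        prop = np.clip(prop, lo, 1.0 - lo)
    z = norm.ppf(prop)
    np.fill_diagonal(z, 0.0)
    values = z.sum(axis=1) / n
    values = values - values.mean()
    return ScaleEstimate(labels=table.labels, values=values)


def _kendall_tau_b(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force tie-corrected Kendall tau over all pairs (small n)."""
    n = a.size
    num = 0
    ties_a = ties_b = 0
    n0 = n * (n - 1) // 2
    for i, j in itertools.combinations(range(n), 2):
        sa = np.sign(a[i] - a[j])
        sb = np.sign(b[i] - b[j])
        num += sa * sb
        ties_a += sa == 0
        ties_b += sb == 0
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return float(num / denom) if denom > 0 else np.nan


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, method: str, observed: float) -> float:
    """Two-sided exact permutation p-value over all n! orderings of b."""
    n = a.size
    perms = _all_permutations(n)
    if method == "spearman":
        ra = rankdata(a)
        rb = rankdata(b)
        x = ra - ra.mean()
        mat = rb[perms] - rb.mean()
        denom = np.sqrt((x**2).sum() * (mat[0] ** 2).sum())
        stats = mat @ x / denom
    else:  # kendall tau-b
        pairs = np.array(list(itertools.combinations(range(n), 2)), dtype=np.intp)
        sa = np.sign(a[pairs[:, 0]] - a[pairs[:, 1]])
        bmat = b[perms]
        sb = np.sign(bmat[:, pairs[:, 0]] - bmat[:, pairs[:, 1]])
        n0 = n * (n - 1) // 2
        denom = np.sqrt((n0 - (sa == 0).sum()) * (n0 - (sb[0] == 0).sum()))
        stats = sb @ sa / denom
    return float(np.mean(np.abs(stats) >= np.abs(observed) - 1e-12))


def rank_correlation(a, b, method: str = "kendall") -> RankCorrelationResult:
    """Rank correlation between two sequences of condition-level values.

    ``method`` is ``"kendall"`` (tau-b, tie-corrected) or ``"spearman"``.
    For ``n <= 9`` the two-sided p-value is computed by exact enumeration of
    all permutations; larger inputs use the asymptotic p-value.  Constant
    input leaves the coefficient undefined (NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("inputs must be equal-length 1-d sequences of length >= 3")
    n = a.size
    if np.all(a == a[0]) or np.all(b == b[0]):
        return RankCorrelationResult(np.nan, np.nan, n, method)
    if method == "kendall":
        coef, p_asym = kendalltau(a, b)
    elif method == "spearman":
        coef, p_asym = spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    if n <= 9:
        p = _exact_permutation_p(a, b, method, coef)
    else:
        p = float(p_asym)
    return RankCorrelationResult(float(coef), p, n, method)


def correlate_model_perception(
    summary_agg: pd.DataFrame,
    perception,
) -> pd.DataFrame:
    """Correlate perceived-indentation values with simulation statistics.

    Parameters
    ----------
    summary_agg
        Per-condition aggregates (one row per matrix and rib interval) with
        columns ``matrix``, ``L2_mm``, ``mean_rate_per_ms``,
        ``entropy_nats`` (the output of :func:`fishbone.engine.aggregate`).
    perception
        Mapping from rib interval (mm) to a perceived-indentation value
        (choice probability, Thurstone scale value, or rank); either a
        single ``pandas.Series`` applied to every matrix or a dict
        ``{matrix: Series}``.

    Returns a tidy table with one row per (matrix, model metric, method):
    columns ``matrix``, ``metric``, ``method``, ``coefficient``,
    ``p_value``, ``n``.
    """
    rows = []
    for matrix, group in summary_agg.groupby("matrix"):
        perc = perception[matrix] if isinstance(perception, dict) else perception
        perc = pd.Series(perc)
        group = group.set_index("L2_mm")
        if set(group.index) != set(perc.index):
            raise ValueError(
                f"rib-interval mismatch for {matrix}: model {sorted(group.index)} "
                f"vs perception {sorted(perc.index)}"
            )
        perc = perc.loc[group.index]
        for metric, column in (
            ("n_spikes", "mean_rate_per_ms"),
            ("entropy", "entropy_nats"),
        ):
            for method in ("kendall", "spearman"):
                res = rank_correlation(perc.values, group[column].values, method)
                rows.append(
                    {
                        "matrix": matrix,
                        "metric": metric,
                        "method": method,
                        "coefficient": res.coefficient,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)
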