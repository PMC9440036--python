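"""Rank-based comparison statistics for repeated-run benchmarks.

Two tools standard in metaheuristic benchmarking: Friedman mean ranks across
algorithms (per run, the best-performing algorithm receives the *largest*
rank number, so "best ranked" means the largest mean rank) and the two-sided
Wilcoxon signed-rank test on paired per-run accuracies, read against a 0.05
significance level.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError, InputError

__all__ = ["friedman_mean_ranks", "wilcoxon_signed_rank", "WilcoxonResult"]


def friedman_mean_ranks(accuracy_table) -> np.ndarray:
    """Mean rank per algorithm from a runs-by-algorithms accuracy table.

    Within each run the algorithms are ranked by accuracy with the best
    getting rank ``k`` (ties receive average ranks); the result is the
    column mean over runs.
    """
    try:
        table = np.asarray(accuracy_table, dtype=float)
    except ValueError as exc:
        raise InputError(f"ragged or non-numeric accuracy table: {exc}") from exc
    if table.ndim != 2:
        raise InputError("accuracy table must be 2-D (runs x algorithms)")
    n_runs, n_algos = table.shape
    if n_algos < 2 or n_runs < 2:
        raise InputError("need at least 2 algorithms and 2 runs")
    ranks = np.apply_along_axis(sps.rankdata, 1, table)  # ascending: best = k
    return ranks.mean(axis=0)


class WilcoxonResult(NamedTuple):
    p_value: float
    n_used: int
    degenerate: bool  # all paired differences were zero

    @property
    def significant(self) -> bool:
        return not self.degenerate and self.p_value < 0.05


def wilcoxon_signed_rank(paired_a, paired_b, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank p-value on paired samples.

    Zero differences are dropped first; if everything cancels the test is
    undefined and reported as ``p = 1`` with the ``degenerate`` flag set.
    The exact null distribution is used up to ``exact_max_n`` effective
    pairs, the normal approximation with continuity correction above.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired samples must be 1-D and of equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return WilcoxonResult(p_value=1.0, n_used=0, degenerate=True)
    if nonzero.size < 5:
        raise ConfigError(
            f"need at least 5 nonzero paired differences, got {nonzero.size}"
        )
    method = "exact" if nonzero.size <= exact_max_n else "approx"
    res = sps.wilcoxon(
        nonzero,
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
    )
    return WilcoxonResult(
        p_value=float(res.pvalue), n_used=int(nonzero.size), degenerate=False
    )
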