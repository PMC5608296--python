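"""Exact rank testing, median-ratio RQ, cut-off calibration, gene selection.

With four samples per arm, asymptotic rank tests are meaningless; the
two-sided Mann-Whitney p-value is therefore computed exactly, as the tail
probability of the observed rank sum over all C(n1+n2, n1) equally likely
assignments of the pooled values to the two groups.  Ties are handled with
mid-ranks and the enumeration runs on the observed (tie-adjusted) rank
multiset, so tied data get their exact conditional null distribution.

The relative quantity (RQ) of a gene is the ratio of group median signals
(case / control) after two bookkeeping rules for background-subtracted
arbitrary-unit data: negative signals are set to 0 before taking medians,
and a control median of exactly 0 is replaced by 0.01 so the ratio stays
finite.

Because only a handful of discrete p-values are attainable at n = 4 vs 4,
the study's surrogate for multiple-testing control is an empirical
calibration: scan RQ cut-offs and find the smallest one above which the
fraction of significant genes exceeds the chance expectation alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, InputError, logger

#: largest combined sample size enumerated exactly; beyond this the
#: tie-corrected normal approximation is used.
MAX_EXACT_N = 30


class MwuResult(NamedTuple):
    u_stat: float
    p_two_sided: float
    degenerate: bool = False


@lru_cache(maxsize=4096)
def _rank_sum_null(doubled_ranks: tuple[int, ...], n1: int) -> np.ndarray:
    """Exact null distribution of the group-1 rank sum by counting.

    ``doubled_ranks`` is the pooled mid-rank multiset times two (mid-ranks
    are half-integers, so doubling makes them exact ints).  Entry ``s`` of
    the returned array counts the n1-subsets of the multiset with doubled
    rank sum ``s``; counts stay below 2**53 for the sizes enumerated here,
    so float64 arithmetic is exact.
    """
    total = sum(doubled_ranks)
    # counts[k, s] = number of k-subsets of the ranks seen so far with sum s
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        counts[1:, r:] += counts[:-1, :total + 1 - r]
    return counts[n1]


def exact_mwu(x: Sequence[float], y: Sequence[float]) -> MwuResult:
    """Exact two-sided Mann-Whitney U test for small groups.

    Returns the U statistic of ``x`` (from rank sums with mid-ranks) and
    the two-sided p-value, defined as twice the smaller one-sided tail of
    the exact permutation distribution of the rank sum, capped at 1.  For
    combined sizes above ``MAX_EXACT_N`` the tie-corrected normal
    approximation takes over.  Two groups of four with complete separation
    give p = 2/70, the smallest value attainable at that size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return MwuResult(u1, 1.0, degenerate=True)

    if n1 + n2 <= MAX_EXACT_N:
        doubled = np.rint(2.0 * ranks).astype(int)
        null = _rank_sum_null(tuple(sorted(doubled)), n1)
        n_total = null.sum()
        obs = int(round(2.0 * r1))
        p_ge = null[obs:].sum() / n_total
        p_le = null[:obs + 1].sum() / n_total
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        p = float(res.pvalue)
    return MwuResult(u1, p, degenerate=False)


def mwu_many(case: np.ndarray, ctrl: np.ndarray) -> pd.DataFrame:
    """Row-wise exact MWU over matched (genes x samples) arrays.

    The exact null distribution depends only on the tie pattern, which the
    per-pattern cache exploits: continuous data share a single pattern, so
    the enumeration is done once for thousands of genes.
    """
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    out = np.empty((case.shape[0], 2))
    for i in range(case.shape[0]):
        r = exact_mwu(case[i], ctrl[i])
        out[i] = (r.u_stat, r.p_two_sided)
    return pd.DataFrame(out, columns=["u", "p"])


def format_p(p: float, decimals: int = 3) -> str:
    """Truncate (not round) a p-value for display: 2/70 prints as 0.028."""
    scale = 10 ** decimals
    return f"{math.floor(p * scale) / scale:.{decimals}f}"


# ---------------------------------------------------------------------------
# median-ratio RQ table
# ---------------------------------------------------------------------------

def gene_rq_table(case: ExpressionMatrix, ctrl: ExpressionMatrix,
                  zero_substitute: float = 0.01,
                  add_fdr: bool = False) -> pd.DataFrame:
    """Per-gene medians, RQ and exact MWU p over a shared gene universe.

    Negative signals are set to 0 before medians; a control median of 0 is
    replaced by ``zero_substitute`` so RQ stays finite (a case median of
    18 AU over a zero control median yields RQ 1800).  Genes with RQ < 1
    are retained but flagged ``upregulated = False``; the analysis focuses
    on upregulation.  ``add_fdr=True`` appends a Benjamini-Hochberg
    ``p_bh`` column for reference; it never gates selection.
    """
    if not case.gene_ids.equals(ctrl.gene_ids):
        raise InputError("case and control matrices must share the same "
                         "gene universe in the same order")
    case_sig = case.signals.to_numpy().clip(min=0.0)
    ctrl_sig = ctrl.signals.to_numpy().clip(min=0.0)
    median_case = np.median(case_sig, axis=1)
    median_ctrl = np.median(ctrl_sig, axis=1)
    median_ctrl_sub = np.where(median_ctrl == 0.0, zero_substitute, median_ctrl)
    rq = median_case / median_ctrl_sub

    tests = mwu_many(case_sig, ctrl_sig)
    table = pd.DataFrame({
        "gene_id": case.gene_ids,
        "median_case": median_case,
        "median_ctrl": median_ctrl_sub,
        "rq": rq,
        "u": tests["u"].to_numpy(),
        "p": tests["p"].to_numpy(),
        "upregulated": rq >= 1.0,
    })
    if add_fdr:
        table["p_bh"] = scipy.stats.false_discovery_control(
            table["p"].to_numpy())
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# RQ cut-off calibration
# ---------------------------------------------------------------------------

DEFAULT_GRID = tuple(np.round(np.arange(1.0, 3.01, 0.1), 10))


@dataclass
class CalibrationCurve:
    """Fraction of significant genes above each RQ cut-off.

    ``curve`` has one row per grid cut-off with the gene count above it,
    the significant count, and their ratio (NaN where no gene lies above);
    ``chosen_cutoff`` is the smallest cut-off whose fraction exceeds alpha,
    or None if chance level is never exceeded.
    """

    curve: pd.DataFrame
    alpha: float
    chosen_cutoff: float | None
    mode: str = "cumulative"


def calibrate_rq_cutoff(results: pd.DataFrame, alpha: float = 0.05,
                        grid: Sequence[float] = DEFAULT_GRID,
                        mode: str = "cumulative") -> CalibrationCurve:
    """Find the RQ cut-off above which significance exceeds chance.

    For each cut-off c the cumulative mode (default) computes
    ``#{RQ > c and p <= alpha} / #{RQ > c}``; banded mode uses the genes
    between successive cut-offs instead.  Feed it the expressed,
    upregulated subset of :func:`gene_rq_table` output.
    """
    grid = [float(c) for c in grid]
    if not grid:
        raise InputError("calibration grid must be non-empty")
    if sorted(set(grid)) != grid:
        raise InputError("calibration grid must be strictly ascending")
    if not len(results):
        raise InputError("no gene results to calibrate on")
    if mode not in ("cumulative", "banded"):
        raise InputError(f"unknown calibration mode {mode!r}")

    rq = results["rq"].to_numpy()
    sig = results["p"].to_numpy() <= alpha
    rows = []
    edges = grid + [np.inf]
    for i, c in enumerate(grid):
        above = rq > c if mode == "cumulative" else (rq > c) & (rq <= edges[i + 1])
        n_above = int(above.sum())
        n_sig = int((above & sig).sum())
        frac = n_sig / n_above if n_above else np.nan
        rows.append({"cutoff": c, "n_above": n_above, "n_significant": n_sig,
                     "frac_significant": frac})
    curve = pd.DataFrame(rows)
    exceed = curve["frac_significant"] > alpha
    chosen = float(curve.loc[exceed, "cutoff"].iloc[0]) if exceed.any() else None
    return CalibrationCurve(curve, alpha, chosen, mode)


# ---------------------------------------------------------------------------
# final gene selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionCriteria:
    """The study's selection thresholds, applied literally."""

    expressed_min_signal: float = 15.0   # AU, case-median expressed filter
    min_signal_case: float = 60.0        # AU
    min_rq: float = 1.8
    alpha: float = 0.05
    direction_up_only: bool = True

    def __post_init__(self) -> None:
        if min(self.expressed_min_signal, self.min_signal_case,
               self.min_rq) < 0:
            raise InputError("thresholds must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")


@dataclass
class Selection:
    selected: list[str]
    audit: dict[str, int]
    table: pd.DataFrame


def select_genes(results: pd.DataFrame,
                 criteria: SelectionCriteria | None = None) -> Selection:
    """Apply the expressed / significant / RQ / signal filters in order.

    Selected genes satisfy case median >= ``min_signal_case``,
    RQ >= ``min_rq``, p <= ``alpha`` and (by default) RQ >= 1; the audit
    dict reports the count surviving each successive filter so threshold
    effects are traceable.  Raising any threshold can only shrink the
    selection.
    """
    crit = criteria or SelectionCriteria()
    expressed = results["median_case"] >= crit.expressed_min_signal
    if crit.direction_up_only:
        expressed &= results["rq"] >= 1.0
    significant = expressed & (results["p"] <= crit.alpha)
    rq_pass = significant & (results["rq"] >= crit.min_rq)
    signal_pass = rq_pass & (results["median_case"] >= crit.min_signal_case)

    table = results.copy()
    table["selected"] = signal_pass
    audit = {
        "input": int(len(results)),
        "expressed": int(expressed.sum()),
        "significant": int(significant.sum()),
        "rq": int(rq_pass.sum()),
        "signal": int(signal_pass.sum()),
    }
    selected = table.loc[signal_pass, "gene_id"].tolist()
    return Selection(selected, audit, table)
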