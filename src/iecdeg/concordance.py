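"""Cross-platform confirmation, diet-response classification, cell yield.

Array-selected genes are confirmed when an independent qPCR comparison of
active-disease versus control epithelial cells is both significant
(p <= alpha) and in the upward direction (case median RQ > 1); the summary
percentage is the confirmation rate over the genes actually tested.

Genes upregulated in active disease are classified by their behaviour
after a gluten-free diet: ``normalized`` when treated-vs-control shows no
significant difference, ``persistent_elevated`` when still significantly
above controls (the OAS2 / SLC2A10 pattern), ``decreased_below`` when
significantly under controls (the CX3CL1 / CXCL10 / ISG15 pattern).

Cell yield is estimated from total 18S rRNA via the empirical constant of
approximately 1 U of 18S per epithelial cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import InputError, logger

#: empirical 18S content of one epithelial cell, in units (U)
UNITS_18S_PER_CELL = 1.0


@dataclass
class ConfirmationReport:
    """Per-gene confirmation calls plus the summary rate."""

    per_gene: pd.DataFrame
    confirmed: int
    tested: int
    untested: list[str]
    percentage: int | None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confirmation_summary(selected_genes: Iterable[str],
                         qpcr_comparisons: pd.DataFrame,
                         alpha: float = 0.05) -> ConfirmationReport:
    """Summarise how many array-selected genes the qPCR data confirm.

    ``qpcr_comparisons`` needs one row per gene with columns ``gene_id``,
    ``p`` (active-vs-control two-sided p) and ``rq_median_case`` (median RQ
    of the active group).  A gene is confirmed iff p <= alpha and the
    median case RQ exceeds 1; selected genes without qPCR data are listed
    as untested, not failed.  25 confirmed of 33 tested reports 76%.
    """
    selected = list(dict.fromkeys(selected_genes))
    qp = qpcr_comparisons.set_index("gene_id")
    rows, untested = [], []
    for gene in selected:
        if gene not in qp.index:
            untested.append(gene)
            continue
        p = float(qp.loc[gene, "p"])
        rq = float(qp.loc[gene, "rq_median_case"])
        rows.append({"gene_id": gene, "p": p, "rq_median_case": rq,
                     "direction": "up" if rq > 1 else "down_or_flat",
                     "confirmed": p <= alpha and rq > 1.0})
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "p", "rq_median_case", "direction",
                       "confirmed"])
    tested = len(per_gene)
    confirmed = int(per_gene["confirmed"].sum()) if tested else 0
    percentage = (_round_half_up(100.0 * confirmed / tested)
                  if tested else None)
    return ConfirmationReport(per_gene, confirmed, tested, untested,
                              percentage)


@dataclass
class GfdResponseCall:
    """Gluten-free-diet response category for one gene."""

    gene_id: str
    category: str  # normalized | persistent_elevated | decreased_below
    p_treated_vs_ctrl: float
    rq_treated: float
    warning: str | None = None


def classify_gfd_response(gene_id: str, p_treated_vs_ctrl: float,
                          rq_treated: float,
                          alpha: float = 0.05) -> GfdResponseCall:
    """Classify one gene's expression after gluten-free diet.

    normalized if treated-vs-control p > alpha; persistent_elevated if
    significant with treated RQ > 1; decreased_below if significant with
    treated RQ < 1.  A significant result at RQ exactly 1 is degenerate
    and reported as normalized with a warning.
    """
    if p_treated_vs_ctrl > alpha:
        return GfdResponseCall(gene_id, "normalized", p_treated_vs_ctrl,
                               rq_treated)
    if rq_treated > 1.0:
        return GfdResponseCall(gene_id, "persistent_elevated",
                               p_treated_vs_ctrl, rq_treated)
    if rq_treated < 1.0:
        return GfdResponseCall(gene_id, "decreased_below",
                               p_treated_vs_ctrl, rq_treated)
    logger.warning("gene %s: significant at RQ exactly 1; calling normalized",
                   gene_id)
    return GfdResponseCall(gene_id, "normalized", p_treated_vs_ctrl,
                           rq_treated, warning="significant at RQ exactly 1")


def classify_gfd_table(treated_vs_ctrl: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Vector version: one GFD category per gene from a comparison table.

    ``treated_vs_ctrl`` has columns ``gene_id``, ``p`` and ``rq`` for the
    treated-versus-control comparison; every gene receives exactly one
    category.
    """
    calls = [classify_gfd_response(r.gene_id, float(r.p), float(r.rq), alpha)
             for r in treated_vs_ctrl.itertuples(index=False)]
    return pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls],
         "category": [c.category for c in calls],
         "p_treated_vs_ctrl": [c.p_treated_vs_ctrl for c in calls],
         "rq_treated": [c.rq_treated for c in calls],
         "warning": [c.warning for c in calls]})


@dataclass
class CellYieldEstimate:
    cells: float
    total_units: float
    approximate: bool = True  # the 1 U/cell constant is empirical


def cells_from_18s(total_units: float) -> CellYieldEstimate:
    """Estimate cell count from total 18S units (about 1 U per cell)."""
    if total_units < 0:
        raise InputError(f"18S amount must be non-negative, got {total_units}")
    return CellYieldEstimate(cells=total_units / UNITS_18S_PER_CELL,
                             total_units=float(total_units))
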