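"""18S standard-curve quantification, delta-delta-CT, QC, group comparisons.

Quantitative PCR abundance is read off a standard curve fitted to a serial
dilution of an RNA standard: least squares of mean CT on log10(amount),
with amplification efficiency ``10**(-1/slope)`` (a perfect doubling per
cycle gives slope -3.32 and efficiency 2).  One unit (U) of 18S rRNA is
defined as the amount contained in 10 pg of the standard; epithelial cells
carry approximately 1 U each, so total 18S units double as a cell-yield
estimate, and samples with <= 25 U per reaction are dropped as failed
preparations.

Target mRNAs are normalised within-sample to 18S by
``dCT = CT(gene) - CT(18S)`` and expressed relative to the control group as
``RQ = 2**(-ddCT)`` with ``ddCT = dCT - median dCT of the control samples``
(the conventional assumption of efficiency 2 in the exponent; the
curve-derived efficiency is reported but not applied).

Group differences are tested on dCT values with the study's three designs:
exact Mann-Whitney (two groups), the classical two-sample t test, or
one-way ANOVA with Dunnett-style many-to-one comparisons whose familywise
adjustment is computed by a seeded parametric Monte-Carlo max-|t| null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import exact_mwu
from .io import FitError, InputError, QpcrTable, StateError, logger
from .synth import PG_PER_UNIT


@dataclass
class StandardCurve:
    """Dilution-series fit: CT = intercept + slope * log10(amount in pg)."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int

    def ct_at(self, amount_pg: float) -> float:
        return self.intercept + self.slope * math.log10(amount_pg)


def fit_standard_curve(series: pd.DataFrame) -> StandardCurve:
    """Least-squares CT on log10(amount_pg), replicates averaged per point.

    Requires >= 3 distinct amounts; a non-negative slope (signal not
    decreasing with dilution) or efficiency outside (1, 2.2] fails the fit.
    A noiseless 2-fold series spaced 1 CT apart yields efficiency 2.0.
    """
    for col in ("amount_pg", "ct"):
        if col not in series.columns:
            raise InputError(f"standard series lacks column {col!r}")
    pts = series.groupby("amount_pg")["ct"].mean()
    if len(pts) < 3:
        raise InputError(f"need >= 3 distinct dilution points, got {len(pts)}")
    if (pts.index <= 0).any():
        raise InputError("standard amounts must be positive")
    fit = scipy.stats.linregress(np.log10(pts.index.to_numpy()),
                                 pts.to_numpy())
    if fit.slope >= 0:
        raise FitError(f"standard-curve slope must be negative, "
                       f"got {fit.slope:.3f} cycles/log10")
    efficiency = 10.0 ** (-1.0 / fit.slope)
    if not 1.0 < efficiency <= 2.2:
        raise FitError(f"implausible amplification efficiency {efficiency:.3f}")
    return StandardCurve(float(fit.slope), float(fit.intercept),
                         float(efficiency), float(fit.rvalue ** 2), len(pts))


def quantify_18s(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve: CT -> amount in U (10 pg standard = 1 U)."""
    if curve is None:
        raise StateError("standard curve not fitted")
    amount_pg = 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept)
                         / curve.slope)
    units = amount_pg / PG_PER_UNIT
    return float(units) if np.isscalar(ct) else units


# ---------------------------------------------------------------------------
# delta-delta-CT relative quantification
# ---------------------------------------------------------------------------

def relative_quantity(table: QpcrTable, housekeeping: str = "18S",
                      reference_group: str = "control") -> pd.DataFrame:
    """Per-(gene, sample) dCT, ddCT and RQ = 2**(-ddCT).

    Replicate CTs are averaged per (gene, sample); dCT subtracts the
    sample's housekeeping CT; ddCT subtracts, per gene, the median dCT of
    the reference-group samples, so the reference group's median RQ is 1
    by construction (exactly so for odd group sizes).
    """
    if table.samples is None:
        raise InputError("relative_quantity needs sample metadata (groups)")
    mean_ct = table.mean_ct()
    hk = (mean_ct[mean_ct["gene_id"] == housekeeping]
          .set_index("sample_id")["ct"])
    targets = mean_ct[mean_ct["gene_id"] != housekeeping].copy()
    missing = set(targets["sample_id"]) - set(hk.index)
    if missing:
        raise InputError(f"housekeeping {housekeeping!r} CT missing for "
                         f"sample(s) {sorted(missing)}")
    groups = table.samples["group"]
    ref_samples = groups.index[groups == reference_group]
    if len(ref_samples) == 0:
        raise InputError(f"reference group {reference_group!r} is empty")

    targets["delta_ct"] = (targets["ct"].to_numpy()
                           - hk.loc[targets["sample_id"]].to_numpy())
    ref_median = (targets[targets["sample_id"].isin(ref_samples)]
                  .groupby("gene_id")["delta_ct"].median())
    missing_ref = set(targets["gene_id"]) - set(ref_median.index)
    if missing_ref:
        raise InputError(f"no reference-group measurements for gene(s) "
                         f"{sorted(missing_ref)}")
    targets["delta_delta_ct"] = (targets["delta_ct"].to_numpy()
                                 - ref_median.loc[targets["gene_id"]].to_numpy())
    targets["rq"] = 2.0 ** (-targets["delta_delta_ct"])
    targets["group"] = groups.loc[targets["sample_id"]].to_numpy()
    targets["reference_group"] = reference_group
    return targets.drop(columns="ct").reset_index(drop=True)


def qc_filter(table: QpcrTable, curve: StandardCurve,
              min_18s_units: float = 25.0, housekeeping: str = "18S",
              ) -> tuple[QpcrTable, pd.DataFrame]:
    """Drop samples whose 18S content is at or below the unit threshold.

    Returns the filtered table plus an exclusion log with each sample's
    quantified 18S units; the threshold is strict (a 25 U sample at the
    default is excluded, 26 U is retained).
    """
    mean_ct = table.mean_ct()
    hk = (mean_ct[mean_ct["gene_id"] == housekeeping]
          .set_index("sample_id")["ct"])
    units = pd.Series(quantify_18s(hk.to_numpy(), curve), index=hk.index)
    log = pd.DataFrame({"sample_id": units.index, "units_18s": units.to_numpy()})
    log["excluded"] = log["units_18s"] <= min_18s_units
    keep = set(log.loc[~log["excluded"], "sample_id"])
    for sid in log.loc[log["excluded"], "sample_id"]:
        logger.info("qc_filter: sample %s excluded at %.1f U 18S",
                    sid, units[sid])
    filtered = QpcrTable(
        table.ct[table.ct["sample_id"].isin(keep)].reset_index(drop=True),
        None if table.samples is None
        else table.samples.loc[table.samples.index.isin(keep)])
    return filtered, log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One test of group differences on per-sample values.

    ``statistic``/``p_two_sided`` carry the headline test (U, t or the
    one-way F); in Dunnett mode ``comparisons`` holds one row per
    treatment-vs-reference contrast with its t, Monte-Carlo unadjusted p
    and familywise max-|t|-adjusted p (adjusted >= unadjusted always, as
    both come from the same resamples).
    """

    design: str
    groups: list[str]
    statistic: float
    p_two_sided: float
    comparisons: pd.DataFrame | None = None


def compare_groups(values: Mapping[str, Sequence[float]], design: str,
                   reference: str | None = None, n_resample: int = 100_000,
                   seed: int = 0) -> GroupComparison:
    """Compare per-sample dCT (or log2-RQ) values between groups.

    ``design`` is ``"mwu"`` (exact Mann-Whitney, two groups), ``"ttest"``
    (classical two-sided two-sample t, two groups), or ``"anova_dunnett"``
    (one-way F plus Dunnett-style many-to-one contrasts against
    ``reference``, adjusted by a seeded parametric Monte-Carlo max-|t|
    null at the observed group sizes).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise InputError("need at least two groups")
    names = list(groups)

    if design == "mwu":
        if len(groups) != 2:
            raise InputError("mwu design compares exactly two groups")
        res = exact_mwu(groups[names[0]], groups[names[1]])
        return GroupComparison("mwu", names, res.u_stat, res.p_two_sided)

    if any(len(v) < 2 for v in groups.values()):
        small = [g for g, v in groups.items() if len(v) < 2]
        raise InputError(f"t/ANOVA designs need >= 2 values per group, "
                         f"group(s) {small} too small")

    if design == "ttest":
        if len(groups) != 2:
            raise InputError("ttest design compares exactly two groups")
        t, p = scipy.stats.ttest_ind(groups[names[0]], groups[names[1]])
        return GroupComparison("ttest", names, float(t), float(p))

    if design != "anova_dunnett":
        raise InputError(f"unknown design {design!r}")
    if reference is None or reference not in groups:
        raise InputError("anova_dunnett needs a reference group name")

    f_stat, f_p = scipy.stats.f_oneway(*groups.values())
    comparisons = _dunnett_mc(groups, reference, n_resample, seed)
    return GroupComparison("anova_dunnett", names, float(f_stat), float(f_p),
                           comparisons)


def _dunnett_mc(groups: Mapping[str, np.ndarray], reference: str,
                n_resample: int, seed: int) -> pd.DataFrame:
    """Many-to-one t contrasts with a parametric Monte-Carlo max-|t| null.

    Each contrast uses the pooled within-group MSE (N - k df).  The null is
    simulated by drawing standard-normal groups at the observed sizes and
    recomputing every contrast with the resampled MSE; the statistic is
    pivotal, so for a single contrast the simulated null is exactly the
    Student t with N - k df and the adjusted p converges to the closed-form
    two-sample t p-value.  p estimates use the (1 + exceedances)/(B + 1)
    convention.
    """
    names = list(groups)
    sizes = np.array([len(groups[g]) for g in names])
    n_total, k = int(sizes.sum()), len(names)
    df = n_total - k
    if df < 1:
        raise InputError("no residual degrees of freedom for Dunnett")
    means = np.array([groups[g].mean() for g in names])
    ssw = sum(((groups[g] - groups[g].mean()) ** 2).sum() for g in names)
    mse = ssw / df
    ref_i = names.index(reference)
    treat_i = [i for i in range(k) if i != ref_i]
    se_scale = np.sqrt(1.0 / sizes[treat_i] + 1.0 / sizes[ref_i])
    t_obs = (means[treat_i] - means[ref_i]) / (np.sqrt(mse) * se_scale)

    rng = np.random.default_rng(seed)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    draws = rng.standard_normal((n_resample, n_total))
    g_means = np.stack([draws[:, bounds[i]:bounds[i + 1]].mean(axis=1)
                        for i in range(k)], axis=1)
    ssw_star = np.zeros(n_resample)
    for i in range(k):
        block = draws[:, bounds[i]:bounds[i + 1]]
        ssw_star += ((block - g_means[:, [i]]) ** 2).sum(axis=1)
    mse_star = ssw_star / df
    t_star = ((g_means[:, treat_i] - g_means[:, [ref_i]])
              / (np.sqrt(mse_star)[:, None] * se_scale[None, :]))
    abs_star = np.abs(t_star)
    max_star = abs_star.max(axis=1)

    rows = []
    for j, i in enumerate(treat_i):
        c = abs(t_obs[j])
        p_unadj = (1 + int((abs_star[:, j] >= c).sum())) / (n_resample + 1)
        p_adj = (1 + int((max_star >= c).sum())) / (n_resample + 1)
        rows.append({"group": names[i], "reference": reference,
                     "t": float(t_obs[j]),
                     "p_unadjusted": p_unadj, "p_adjusted": p_adj})
    return pd.DataFrame(rows)
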