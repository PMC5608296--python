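"""Seeded generators of array and qPCR datasets with planted truth.

The array generator emulates the data regime of a purified-cell bead-array
study of active celiac disease: log-normal signal in arbitrary units (AU)
spanning below 15 to above 10,000 AU, tiny groups (4-14 samples per arm), a
minority of genes planted with multiplicative upregulation in the disease
arm, a panel of T-cell marker genes expressed only in intraepithelial
lymphocytes (IELs), per-sample admixture of a few percent IEL signal into
the observed epithelial-cell (IEC) profiles, and additive background noise
that occasionally drives low signals negative.

Observed disease-arm profiles obey the two-population mixing model

    observed[g, j] = (1 - f_j) * pure_iec[g, j] + f_j * iel_profile[g] + eps

for the recorded per-sample admixture fraction ``f_j``, which is exactly the
model the contamination-correction stage inverts.

The qPCR generator produces triplicate CT values under the exponential
amplification model ``CT = ct_ref - log_E(amount)`` together with a 2-fold
18S rRNA dilution series anchored at the convention that 10 pg of the RNA
standard is 1 unit (U).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ConfigError, ExpressionMatrix, QpcrTable, logger,
                 write_matrix, write_qpcr_table, write_sample_sheet,
                 write_standard_series)

#: T-lymphocyte marker genes used to gauge IEL admixture in IEC preparations.
DEFAULT_MARKERS = ("CD3D", "CD3G", "CD2", "CD7", "CD8A", "CD247")

#: 1 unit (U) of 18S rRNA is the amount contained in 10 pg of the standard.
PG_PER_UNIT = 10.0


@dataclass
class ArraySimConfig:
    """Study-design parameters for the synthetic bead-array dataset.

    Defaults are the study conditions the pipeline is meant to exercise:
    4 vs 4 IEC samples, 5 IEL reference samples, ~5% of genes planted
    upregulated with effects spanning the selection threshold up to 10-fold,
    a log-normal AU baseline with ~55% of genes above the 15 AU expressed
    cut, and per-sample IEL admixture in the 5-10% range.
    """

    n_genes: int = 5000
    n_case: int = 4
    n_ctrl: int = 4
    n_iel: int = 5
    frac_de: float = 0.05
    effect_rq_range: tuple[float, float] = (1.8, 10.0)
    de_min_baseline: float | None = None  # plant only on baselines above this AU
    baseline_log_mean: float = 3.0   # natural-log AU; median ~20 AU
    baseline_log_sd: float = 1.6     # spans <1 to >10,000 AU
    cv_within: float = 0.25          # within-group coefficient of variation
    contamination_fractions: tuple[float, ...] | None = None  # default 5-10%
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS
    marker_iel_log_mean: float = 7.5  # IEL marker signal ~1800 AU
    marker_iel_log_sd: float = 0.4
    background_sd: float = 2.0       # additive AU noise; yields negatives
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or min(self.n_case, self.n_ctrl, self.n_iel) <= 0:
            raise ConfigError("counts must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigError(f"frac_de must be in [0, 1], got {self.frac_de}")
        lo, hi = self.effect_rq_range
        if lo < 1.0 or hi < lo:
            raise ConfigError("effect_rq_range lower bound must be >= 1")
        if self.cv_within < 0 or self.background_sd < 0:
            raise ConfigError("noise parameters must be non-negative")
        if self.contamination_fractions is None:
            # evenly spaced over the study's estimated 5-10% admixture range
            self.contamination_fractions = tuple(
                np.linspace(0.05, 0.10, self.n_case)
            )
        self.contamination_fractions = tuple(
            float(f) for f in self.contamination_fractions
        )
        if len(self.contamination_fractions) != self.n_case:
            raise ConfigError("need one contamination fraction per case sample")
        if any(not 0.0 <= f <= 0.2 for f in self.contamination_fractions):
            raise ConfigError("contamination fractions must be in [0, 0.2]")
        if len(set(self.marker_genes)) != len(self.marker_genes):
            raise ConfigError("marker gene identifiers must be unique")


@dataclass
class SyntheticTruth:
    """Planted ground truth: labels, effects, admixture fractions, seed."""

    de_genes: tuple[str, ...]
    true_rq: dict[str, float]
    contamination_fractions: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"de_genes": list(self.de_genes),
             "true_rq": self.true_rq,
             "contamination_fractions": self.contamination_fractions,
             "seed": self.seed}, indent=1))


@dataclass
class SyntheticDataset:
    """Matched pure, IEL and observed (admixed) matrices plus truth.

    ``iel_profile`` is the deterministic per-gene IEL expectation actually
    mixed into the observed case samples; the ``iel_matrix`` holds noisy
    IEL samples realized around that profile.
    """

    pure_iec_case: ExpressionMatrix
    pure_iec_ctrl: ExpressionMatrix
    iel_matrix: ExpressionMatrix
    observed_iec_case: ExpressionMatrix
    observed_iec_ctrl: ExpressionMatrix
    iel_profile: pd.Series
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        """Write all matrices, a combined sample sheet, and the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.observed_iec_case, outdir / "observed_iec_case.tsv")
        write_matrix(self.observed_iec_ctrl, outdir / "observed_iec_ctrl.tsv")
        write_matrix(self.pure_iec_case, outdir / "pure_iec_case.tsv")
        write_matrix(self.pure_iec_ctrl, outdir / "pure_iec_ctrl.tsv")
        write_matrix(self.iel_matrix, outdir / "iel.tsv")
        self.iel_profile.rename("signal").to_csv(
            outdir / "iel_profile.tsv", sep="\t", index_label="gene_id")
        sheet = pd.concat([m.samples for m in
                           (self.observed_iec_case, self.observed_iec_ctrl,
                            self.iel_matrix)])
        write_sample_sheet(sheet, outdir / "samples.tsv")
        self.truth.to_json(outdir / "truth.json")


def _lognormal_noise(rng: np.random.Generator, cv: float,
                     shape: tuple[int, ...]) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, shape)


def generate_array_dataset(config: ArraySimConfig) -> SyntheticDataset:
    """Generate a seeded bead-array dataset under the admixture model.

    Marker genes are appended after the ``n_genes`` ordinary genes; they
    have zero pure-IEC expectation and a high IEL expectation, and are never
    planted as differentially expressed (so the marker panel stays disjoint
    from the truth set by construction).  Identical seeds give bit-identical
    datasets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    gene_ids = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)]
                        + list(cfg.marker_genes), name="gene_id")
    n_marker = len(cfg.marker_genes)

    base_iec = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             cfg.n_genes)
    base_iel = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             cfg.n_genes)
    marker_iel = rng.lognormal(cfg.marker_iel_log_mean, cfg.marker_iel_log_sd,
                               n_marker)

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    eligible = (np.arange(cfg.n_genes) if cfg.de_min_baseline is None
                else np.flatnonzero(base_iec >= cfg.de_min_baseline))
    if len(eligible) < n_de:
        raise ConfigError(
            f"only {len(eligible)} genes exceed de_min_baseline="
            f"{cfg.de_min_baseline}, cannot plant {n_de}")
    de_idx = np.sort(rng.choice(eligible, size=n_de, replace=False))
    effects = rng.uniform(*cfg.effect_rq_range, size=n_de)

    iec_ctrl_expect = np.concatenate([base_iec, np.zeros(n_marker)])
    iec_case_expect = iec_ctrl_expect.copy()
    iec_case_expect[de_idx] *= effects
    iel_expect = np.concatenate([base_iel, marker_iel])

    case_ids = [f"IEC_CD_{j + 1}" for j in range(cfg.n_case)]
    ctrl_ids = [f"IEC_CTR_{j + 1}" for j in range(cfg.n_ctrl)]
    iel_ids = [f"IEL_CD_{j + 1}" for j in range(cfg.n_iel)]

    def _matrix(expect, ids, group, population):
        noise = _lognormal_noise(rng, cfg.cv_within, (len(expect), len(ids)))
        sig = pd.DataFrame(expect[:, None] * noise, index=gene_ids, columns=ids)
        sig.index.name = "gene_id"
        meta = pd.DataFrame({"group": group, "population": population},
                            index=pd.Index(ids, name="sample_id"))
        return ExpressionMatrix(sig, meta)

    pure_case = _matrix(iec_case_expect, case_ids, "active_cd", "IEC")
    pure_ctrl = _matrix(iec_ctrl_expect, ctrl_ids, "control", "IEC")
    iel_matrix = _matrix(iel_expect, iel_ids, "active_cd", "IEL")

    iel_profile = pd.Series(iel_expect, index=gene_ids, name="signal")
    fractions = np.asarray(cfg.contamination_fractions)

    obs_case_sig = ((1.0 - fractions)[None, :] * pure_case.signals.to_numpy()
                    + fractions[None, :] * iel_expect[:, None])
    obs_ctrl_sig = pure_ctrl.signals.to_numpy().copy()
    if cfg.background_sd > 0:
        obs_case_sig = obs_case_sig + rng.normal(
            0.0, cfg.background_sd, obs_case_sig.shape)
        obs_ctrl_sig = obs_ctrl_sig + rng.normal(
            0.0, cfg.background_sd, obs_ctrl_sig.shape)

    observed_case = ExpressionMatrix(
        pd.DataFrame(obs_case_sig, index=gene_ids, columns=case_ids),
        pure_case.samples.copy())
    observed_ctrl = ExpressionMatrix(
        pd.DataFrame(obs_ctrl_sig, index=gene_ids, columns=ctrl_ids),
        pure_ctrl.samples.copy())

    truth = SyntheticTruth(
        de_genes=tuple(gene_ids[i] for i in de_idx),
        true_rq={gene_ids[i]: float(e) for i, e in zip(de_idx, effects)},
        contamination_fractions={s: float(f)
                                 for s, f in zip(case_ids, fractions)},
        seed=cfg.seed,
    )
    return SyntheticDataset(pure_case, pure_ctrl, iel_matrix,
                            observed_case, observed_ctrl, iel_profile, truth)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass
class QpcrTruth:
    """True per-(gene, group) fold changes and per-sample 18S units."""

    fold_changes: dict[str, dict[str, float]]
    units_18s: dict[str, float]
    ct_ref: float
    efficiency: float
    seed: int


@dataclass
class SyntheticQpcrDataset:
    table: QpcrTable
    standard_series: pd.DataFrame
    truth: QpcrTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_qpcr_table(self.table, outdir / "qpcr_ct.tsv")
        write_standard_series(self.standard_series, outdir / "standard_18s.tsv")
        write_sample_sheet(self.table.samples, outdir / "qpcr_samples.tsv")
        Path(outdir / "qpcr_truth.json").write_text(json.dumps(
            {"fold_changes": self.truth.fold_changes,
             "units_18s": self.truth.units_18s,
             "ct_ref": self.truth.ct_ref,
             "efficiency": self.truth.efficiency,
             "seed": self.truth.seed}, indent=1))


def generate_qpcr_dataset(
    n_samples_per_group: Mapping[str, int],
    genes: Sequence[str],
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    *,
    fold_changes: Mapping[str, Mapping[str, float]] | None = None,
    reference_group: str = "control",
    n_replicates: int = 3,
    housekeeping: str = "18S",
    ct_ref: float = 25.0,
    mean_units_18s: float = 1000.0,
    base_delta_ct: float = 15.0,
    n_dilutions: int = 8,
) -> SyntheticQpcrDataset:
    """Generate replicate CT tables plus an 18S standard dilution series.

    Each sample carries a true 18S content (log-normal around
    ``mean_units_18s`` U per reaction) and each gene a true abundance
    relative to 18S (centred so that the reference-group delta-CT is about
    ``base_delta_ct`` cycles).  ``fold_changes[gene][group]`` multiplies the
    gene:18S ratio in that group (default 1 everywhere).  CT values follow
    ``CT = ct_ref - log_E(amount in U)`` with i.i.d. normal replicate noise
    of ``ct_noise_sd`` cycles; the standard series is ``n_dilutions``
    successive 2-fold dilutions anchored at the 10 pg = 1 U standard.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ConfigError(f"efficiency must be in (1, 2], got {efficiency}")
    if any(n < 1 for n in n_samples_per_group.values()):
        raise ConfigError("each group needs >= 1 sample")
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    log_e = math.log(efficiency)
    fold_changes = fold_changes or {}

    sample_ids, groups = [], []
    for group, n in n_samples_per_group.items():
        for j in range(n):
            sample_ids.append(f"{group}_{j + 1}")
            groups.append(group)
    samples = pd.DataFrame(
        {"group": groups, "population": "IEC"},
        index=pd.Index(sample_ids, name="sample_id"))

    units = rng.lognormal(math.log(mean_units_18s), 0.5, len(sample_ids))
    # gene:18S abundance ratio in the reference group, in efficiency-folds
    base_ratio = {g: efficiency ** (-base_delta_ct + rng.normal(0.0, 1.0))
                  for g in genes if g != housekeeping}

    rows = []
    rep_cols = [f"ct_rep{k + 1}" for k in range(n_replicates)]

    def _ct_rows(gene: str, amounts: np.ndarray) -> None:
        ct_true = ct_ref - np.log(amounts) / log_e
        noise = (rng.normal(0.0, ct_noise_sd, (len(amounts), n_replicates))
                 if ct_noise_sd > 0 else np.zeros((len(amounts), n_replicates)))
        for sid, ct, eps in zip(sample_ids, ct_true, noise):
            rows.append({"gene_id": gene, "sample_id": sid,
                         **{c: ct + e for c, e in zip(rep_cols, eps)}})

    _ct_rows(housekeeping, units)
    for gene, ratio in base_ratio.items():
        fold = np.array([fold_changes.get(gene, {}).get(g, 1.0)
                         for g in groups])
        _ct_rows(gene, units * ratio * fold)

    table = QpcrTable(pd.DataFrame(rows), samples)

    # 2-fold 18S dilution series anchored at 10 pg = 1 U
    amounts_pg = PG_PER_UNIT * 2.0 ** np.arange(n_dilutions - 1, -1, -1)
    std_rows = []
    for pg in amounts_pg:
        ct_true = ct_ref - math.log(pg / PG_PER_UNIT) / log_e
        for _ in range(n_replicates):
            eps = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            std_rows.append({"amount_pg": pg, "ct": ct_true + eps})
    standard = pd.DataFrame(std_rows)

    truth = QpcrTruth(
        fold_changes={g: dict(fold_changes.get(g, {})) for g in base_ratio},
        units_18s={s: float(u) for s, u in zip(sample_ids, units)},
        ct_ref=ct_ref, efficiency=efficiency, seed=seed)
    return SyntheticQpcrDataset(table, standard, truth)
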