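# iecdeg

Differential gene expression in **purified intestinal epithelial cells
(IECs)** in active celiac disease, for researchers analysing bead-array
signal matrices and qPCR CT tables from sorted-cell preparations with very
small groups (n = 4–14 per arm).

Purified IEC preparations are never perfectly pure: intraepithelial
lymphocytes (IELs) contribute a few percent of the measured signal. With
four samples per arm, asymptotic tests and ad-hoc fold-change thresholds
are both unreliable. This package implements the full analysis chain:

1. **Contamination correction.** The admixed fraction *f* is read off a
   T-cell marker panel (CD3D, CD3G, CD2, CD7, CD8A, CD247): for each marker
   the ratio of IEC signal to the IEL reference signal estimates *f*
   directly, since epithelial cells do not express these genes. The
   corrected signal is `observed − f · IEL_reference`, negatives clamped
   to 0, with fixed *f* = 0.10 as the default.
2. **Exact rank testing.** Per gene, the two-sided Mann–Whitney U test is
   computed exactly: the p-value is the tail probability of the observed
   rank sum over all C(n₁+n₂, n₁) group assignments, tie-aware via
   mid-ranks. For two groups of four, complete separation gives the
   smallest attainable p = 2/70 (printed 0.028).
3. **Median-ratio RQ and cut-off calibration.** The relative quantity
   RQ = median(case) / median(control) after two bookkeeping rules
   (negatives → 0 before medians; a control median of 0 → 0.01). An
   empirical calibration scans RQ cut-offs for the smallest one above which
   the fraction of significant genes exceeds the chance level α.
4. **Selection.** Genes of interest satisfy case median ≥ 60 AU,
   RQ ≥ 1.8, p ≤ 0.05 and RQ ≥ 1.
5. **qPCR confirmation.** 18S-normalised ΔCT, RQ = 2^(−ΔΔCT) against the
   control-group median ΔCT, an 18S standard curve (10 pg of standard
   = 1 U; efficiency = 10^(−1/slope)), a >25 U per-reaction QC gate, and
   group tests (exact Mann–Whitney, two-sample t, or one-way ANOVA with
   Monte-Carlo Dunnett many-to-one adjustment). Confirmation and
   gluten-free-diet response classification are summarised per gene.

A seeded synthetic-data generator (`iecdeg.synth`) reproduces the data
regime — log-normal AU signals, planted multiplicative upregulation, a
marker panel, per-sample admixture, background noise, triplicate CTs —
so every stage is testable without any external download.

## Worked example

```python
from iecdeg import (ArraySimConfig, generate_array_dataset,
                    run_array_analysis, exact_mwu, format_p)

cfg = ArraySimConfig(n_genes=5000, frac_de=0.05, effect_rq_range=(3.0, 10.0),
                     de_min_baseline=60.0,
                     contamination_fractions=(0.10,) * 4, seed=7)
ds = generate_array_dataset(cfg)
res = run_array_analysis(ds.observed_iec_case, ds.observed_iec_ctrl,
                         ds.iel_profile)
print(res.selection.audit)
r = exact_mwu([5, 6, 7, 8], [1, 2, 3, 4])
print("U =", r.u_stat, " p =", format_p(r.p_two_sided))
```

prints

```
{'input': 5006, 'expressed': 1038, 'significant': 260, 'rq': 251, 'signal': 250}
U = 16.0  p = 0.028
```

Of 5,006 genes (5,000 plus the 6 markers), 1,038 pass the 15 AU expressed
filter with RQ ≥ 1; 260 are significant at α = 0.05; 251 also have
RQ ≥ 1.8 and 250 clear the 60 AU signal criterion. Against the planted
truth (250 genes upregulated 3–10-fold) this selection has sensitivity
1.000 with 0 false discoveries. The `exact_mwu` line shows the floor of
the exact test at n = 4 vs 4: U = 16 (complete separation) and p = 2/70,
truncated to 0.028. The first selected genes look like:

```
gene_id  median_case  median_ctrl       rq    u        p
 G00007   869.730014   160.246778 5.427442 16.0 0.028571
 G00015   425.463063    60.434745 7.040041 16.0 0.028571
```

The same stages are available from the shell:

```bash
iecdeg simulate array --seed 7 --out sim/
iecdeg correct --matrix sim/observed_iec_case.tsv --iel sim/iel.tsv \
    --samples sim/samples.tsv --fraction 0.10 --out corrected.tsv
iecdeg de --case corrected.tsv --ctrl sim/observed_iec_ctrl.tsv --out results.tsv
iecdeg calibrate --results results.tsv --out calibration.tsv
iecdeg select --results results.tsv --out selected.tsv
```

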