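# petdna

Multisite PET shape/intensity quantification and its correlation with
circulating DNA, for whole-body diseases such as B-cell lymphomas.

Lymphomas are usually *multisite* tumours, which makes most single-lesion
radiomics (notably textural features) ill-suited; what does describe them
well is a small set of whole-disease "shape + intensity" parameters. In
parallel, liquid biopsy quantifies circulating tumour DNA (ctDNA) — the
tumour-derived fraction of plasma cell-free DNA (cfDNA) — whose level at
diagnosis reflects tumour burden. This package implements both sides and
the statistical machinery to relate them:

* **Twelve multisite PET parameters** from a 3D SUV volume + lesion mask:
  * burden: TMTV (cm³), TMTS (cm²), TLG = TMTV × SUVmean;
  * activity: SUVmax, SUVmean;
  * dispersion: TumBB (bounding-box volume, cm³), Dmax (largest
    inter-lesion distance, mm), nROI (lesion count);
  * massiveness/fragmentation: TVSR = TMTV/TMTS (mm), itErosion
    (mean iterative-erosion count), medPCD (median periphery–centroid
    distance, mm), medEdgeD (median opposite-edge distance, mm).
* **Circulating DNA quantification** in haploid genome equivalents:
  [cfDNA] = cfDNA(pg/mL)/3.3 and [ctDNA] = mean(VAF) × cfDNA(pg/mL)/3.3
  (one hGE weighs 3.3 pg); patients with no detected mutation carry a
  *null* (not zero) ctDNA and are excluded from ctDNA analyses only.
* **Scanner harmonization**: per-feature Wilcoxon–Mann–Whitney machine
  test with Benjamini–Hochberg control, then parametric empirical-Bayes
  ComBat on the flagged features only.
* **The statistical battery**: Spearman correlation tables with BH-adjusted
  p-values, high-correlation feature clusters, univariate OLS and
  bidirectional stepwise OLS (AIC) to determine [cfDNA]/[ctDNA] from the
  twelve parameters.
* **Synthetic phantom cohorts**: seeded 3D multisite SUV phantoms with a
  monotone TMTS→ctDNA link, VAF sampling consistent with the hGE formula,
  a detection false-negative process and per-machine batch shifts — so the
  whole pipeline is testable without any patient data.

## Worked example

```python
from petdna import CohortAnalysis, generate_cohort

cohort, mutations, truth = generate_cohort(n_patients=50, seed=1)
results = CohortAnalysis(cohort).fit()
print(results.summary())
```

prints (abridged):

```
[DLBCL] n = 50
  machine effect: 4 feature(s) flagged and harmonized: TumBB, Dmax, itErosion, medPCD
  ctdna_hge: 8 null row(s) excluded (no mutation found)
  cluster 1: TLG, TMTS, TMTV, TVSR, itErosion, medEdgeD, medPCD
  cluster 2: Dmax, TumBB
  top ctdna_hge correlates: TMTS (rho=0.66), TMTV (rho=0.64), TLG (rho=0.61)
  stepwise ctdna_hge: -3355.71 -6.34203*Dmax +203.528*nROI +1544.9*itErosion  [adj R2 = 0.50, p = 1.59e-06, n = 42]
```

Reading this: the gate found the four features the generator shifted
between machines and ComBat removed the shift; 8 of 50 patients had no
detectable mutation (the generator's 20 % false-negative rate) and were
excluded from ctDNA analyses; burden features form one high-correlation
cluster and dispersion features another; the generator links ctDNA to the
tumour surface TMTS, and the analysis recovers burden/surface features as
the top ctDNA correlates. The stepwise model explains half the ctDNA
variance (adjusted R² = 0.50 on the 42 non-null patients).

The same workflow is scriptable from a shell:

```bash
petdna simulate --n 50 --seed 1 --out cohort_dir/
petdna extract --suv suv.mha --mask mask.mha --out features.json
petdna harmonize --cohort cohort_dir/cohort.csv --out harmonized.csv --report h.json
petdna analyze --cohort cohort_dir/cohort.csv --out report_dir/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a seeded 50-patient synthetic cohort from scratch, runs the
full pipeline (extraction → gate/ComBat → correlations → regressions) and
writes the report bundle beside the JSON output.

See `docs/methods.md` for the precise feature definitions, the ComBat
model, the generator's stated parameters and known limitations.
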