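# famassoc

Marker-wise association under family structure: a tested pipeline for
comparing three strategies of coping with related individuals in
family-based association studies.

Association scans over families of siblings cannot treat individuals as
independent — shared polygenic background correlates their phenotypes and
inflates naive test statistics.  When the relationship structure is known,
the standard fix is a linear mixed model

    y = X beta + mu + eps,   mu ~ N(0, sigma2_mu K),   eps ~ N(0, sigma2_eps I),

with K the expected-relationship (kinship) matrix, so
Cov(y) = sigma2_mu K + sigma2_eps I.  When it is not known, two pragmatic
strategies compete: ignore relatedness entirely (**independence** option),
or keep one randomly drawn member per family and analyze the subsample as
independent (**representative** option).  `famassoc` implements all three —
the **kinship** option with from-scratch spectral REML variance components
and GLS Wald tests — plus a family-structured phenotype simulator with
known truth and a comparison harness that ranks markers, forms top-k sets,
computes 7-region Venn overlaps, truth recovery, false discovery rates and
the **hybrid** strategy (the intersection of the independence and
representative top-k sets).

Who it is for: statistical geneticists and biostatisticians who want a
transparent, fully seeded sandbox for studying how family structure
distorts marker rankings — and what each coping strategy costs.

## Worked example

```python
from famassoc import SimulationConfig, run_study

report = run_study(SimulationConfig(seed=20180917),
                   n_replicates=3, n_representative_draws=5, k=20)
print(report.summary_text())
```

prints (as run):

```
Comparison study: k=20, 3 replicates x 5 representative draws
Venn sets: A=representative, B=kinship, C=independence

Average region counts +/- SD:
    A:   8.53 +/- 1.68
    B:   0.93 +/- 0.80
    C:   1.00 +/- 0.85
   AB:   0.07 +/- 0.26
   AC:   0.00 +/- 0.00
   BC:   7.60 +/- 2.16
  ABC:  11.40 +/- 1.59

Truth recovery (mean true positives, mean FDR):
  representative: TP=9.73  FDR=0.513
         kinship: TP=10.00  FDR=0.500
    independence: TP=10.00  FDR=0.500
          hybrid: TP=9.73  FDR=0.134
```

Reading this: each simulated study has 1000 markers over 200 sibship
families (n = 1000), 10 of them true signals.  The kinship option recovers
all 10 true signals in its top 20 (TP = 10.00) — the best of the three —
and its top-20 set shares most of its members with the independence option
(regions BC + ABC ≈ 19) but much less with the representative option
(AB + ABC ≈ 11.5), whose 200-individual subsample makes its ranking
noisy (region A alone holds ≈ 8.5 markers nobody else picks).  The hybrid
intersection keeps nearly all true signals while discarding most false
ones: FDR 0.13 versus 0.50 for any single top-20 set — the case for
combining the two kinship-free strategies in practice.

The numbered drivers under `analysis/` run the same pipeline stepwise —
`01_simulate.py` (dataset), `02_fit_options.py` (per-option association
and Manhattan tables), `03_compare_options.py` (the study above),
`04_null_calibration.py` (type-I error: kinship ≈ 0.05 at nominal 0.05,
independence inflated ≈ 0.16) — writing their tables under `results/`.

A `famassoc` command-line interface wraps the same steps
(`famassoc simulate | assoc | compare`, see `--help`); every run writes a
manifest with config, seeds and version before any output.

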