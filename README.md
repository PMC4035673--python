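# dtabias

Tests for small study-effects (publication bias) in diagnostic test
accuracy (DTA) meta-analyses, built around per-study 2×2 contingency
tables (TP, FP, FN, TN):

* **Effect measures** — diagnostic odds ratio (DOR), lnDOR, Woolf
  variance, effective sample size ESS = 4·n₁·n₂/(n₁+n₂), and pooled
  lnDOR (fixed effect or DerSimonian–Laird).
* **Asymmetry tests** — Begg's rank correlation (standardized-deviate
  or naive variant; exact permutation p for k ≤ 8), Egger's weighted
  regression of lnDOR on its SE, and Deeks' regression of lnDOR on
  1/√ESS weighted by ESS.
* **Concordance** — pairwise agreement of significance calls across a
  corpus: Cohen's kappa with asymptotic or bootstrap 95% CI, raw
  concordance %, and p-value scatter plots with 0.05 gridlines.
* **Moderators** — univariable logistic regression of pairwise
  concordance on a high pooled DOR (≥ 38), the number of studies, and
  the number of patients.
* **Funnel plots** — a catalogue of axis conventions (lnDOR/DOR/
  sensitivity/specificity vs SE, 1/Var, 1/√ESS, sample size, binomial
  SE).
* **Simulator** — synthetic DTA corpora with tunable true lnDOR,
  between-study heterogeneity, threshold (positivity cut-off)
  variation and step selective-publication, plus Monte-Carlo
  rejection-rate (type-I error / power) estimation.

## Corpus format

Long-format delimited text (comma or tab), one row per primary study:

```
meta_id,study_id,tp,fp,fn,tn
m1,s1,45,6,5,44
```

or, with accuracy fractions that are reconstructed into counts
(round-half-to-even):

```
meta_id,study_id,n_diseased,n_nondiseased,sensitivity,specificity
m1,s1,100,50,0.9,0.8
```

## CLI

```sh
# simulate a 92-meta corpus with selective publication
dtabias simulate --n-metas 92 --ln-dor 1.2 --tau 0.5 --retain-prob 0.4 \
    --seed 7 --out corpus.csv

# full analysis: tests, concordance, moderators, tables, figures
dtabias report corpus.csv --outdir out/

# individual stages
dtabias effects corpus.csv --out effects.csv
dtabias test corpus.csv --out tests.csv
dtabias concordance corpus.csv --out concordance.json
dtabias moderators corpus.csv --out moderators.json

# Monte-Carlo operating characteristics (type-I error / power)
dtabias ocharacteristics --n-replicates 1000 --k 15 --seed 1 --out oc.json
```

`dtabias report` writes `report.json`, `table2.csv` (per-test
identified / not-identified counts), `concordance.csv`, `table3.csv`
(moderator odds-ratio grid), `exclusions.csv` and figures.  Reports
are byte-identical across reruns of the same inputs.

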