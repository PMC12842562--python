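# gdsirt

IRT-based abbreviation and psychometric audit of binary screening scales,
built around the 30-item Geriatric Depression Scale (GDS30).

## The problem

Short forms of screening questionnaires are usually derived with Classical
Test Theory (item–total correlations), which favours moderately endorsed,
non-specific items and can discard the most diagnostic ones.  `gdsirt`
implements the alternative: calibrate a two-parameter logistic (2PL) item
response model on yes/no items, rank items by discrimination, and shorten the
scale item by item until the reduced sum score is no longer statistically
equivalent (by AUC) to the full scale.  It is intended for psychometricians
and epidemiologists developing or auditing screening instruments.

## The model and procedure

Each item *j* follows the 2PL curve

P<sub>j</sub>(θ) = 1 / (1 + exp(−a<sub>j</sub>(θ − b<sub>j</sub>))),

where θ is the latent severity (standard normal in the calibration
population), *a<sub>j</sub>* the discrimination and *b<sub>j</sub>* the
severity at which the item is endorsed with probability ½.  The pipeline:

1. **Split** the cohort 1:1, stratified by diagnosis × recruitment source.
2. **Calibrate** the 2PL by marginal maximum likelihood (Bock–Aitkin EM,
   61-node quadrature) on the development half only; rank items by *â*.
3. **Reduce**: for each k (full pool down to 4), sum-score the top-k items
   and compare against the full scale with the paired DeLong test in both
   halves; across halves with the Hanley–McNeil independent-samples z.
   The selected k\* is the smallest k passing in both halves whose
   predecessor (k−1) fails; a test-information elbow diagnostic is reported
   alongside.
4. **Audit** the short form: Cronbach's α, Youden-index cutoff with
   sensitivity/specificity, predictive values under prevalence scenarios,
   the efficiency ratio (AUC / number of items) with percentile-bootstrap
   comparisons, and Mantel–Haenszel differential item functioning with ETS
   A/B/C classification plus subgroup-AUC differential test functioning.

The package ships a published 2PL calibration of the Korean GDS30
(`gdsirt.reference_bank()`) with the standard scale memberships (GDS15,
GDS4) and the 10-item IRT-optimised form (GDS10-IRT: items 1, 4, 6, 10, 11,
16, 17, 21, 22, 25), plus a synthetic cohort generator with the same
statistical structure as the calibration cohort (n = 6525, prevalence 3.8%,
community/clinic mix, diagnosis-linked latent trait, optional injected DIF).

## Worked example

```sh
$ gdsirt run --seed 5 --outdir out/
selected TOP17 with items [1, 3, 4, 6, 7, 9, 10, 11, 13, 16, 17, 18, 19, 21, 22, 24, 25]; cutoff >= 8, sens 83.9%, spec 73.8%
```

`out/` then contains the item-parameter table, the full reduction trace, the
screening-performance and efficiency tables, a DIF/DTF report, a cutoff
sweep, and a machine-readable `summary.json`.  For this seed the validation
half gives (from `screening_performance.tsv`):

| scale     | AUC (val) | efficiency | sens % | spec % |
|-----------|-----------|------------|--------|--------|
| GDS30     | 0.867     | 0.0289     | 80.5   | 76.8   |
| GDS15     | 0.859     | 0.0573     | 78.0   | 79.1   |
| GDS10-IRT | 0.868     | 0.0868     | 89.0   | 68.2   |
| TOP17 (k\*)| 0.866    | 0.0510     | 83.9   | 73.8   |

Read: all short forms keep an AUC statistically equivalent to the full
scale; the 10-item IRT form triples the per-item efficiency of the GDS30
(0.0868 vs 0.0289).  The selected k\* itself varies across synthetic seeds
(roughly 6–17): in a cohort generated *exactly* from the 2PL model, the
low-discrimination items carry almost no unique signal, so scales well below
10 items often remain equivalent to the full pool — see
`docs/methods.md` for what the generator does and does not emulate.

The same analysis is available as a library:

```python
from gdsirt import TwoPLModel, SequentialReduction, CohortConfig, generate_cohort, stratified_split

cohort = generate_cohort(CohortConfig(seed=5))
dev, val = stratified_split(cohort, 0.5, seed=6)
fit = TwoPLModel(dev.responses).fit()          # TwoPLResults
fit.attach_item_aucs(dev.diagnosis)
res = SequentialReduction(dev, val, fit.rank_items(), fit.item_bank).fit()
print(res.summary())                           # trace + selected scale
```

Other CLI subcommands: `simulate`, `fit`, `reduce`, `audit`, `report`
(see `gdsirt --help`).

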