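# pvkit

Signal detection, time-to-onset modelling, and risk-factor analysis for
FAERS-style spontaneous adverse-event reports — plus a ground-truth synthetic
data generator so the whole pipeline is testable offline.

## What it does

| Module | Purpose |
| --- | --- |
| `pvkit.synth_faers` | Generate `$`-delimited FAERS-dialect tables (DEMO/DRUG/REAC/THER/OUTC) with planted reporting-rate ratios, Weibull onset latencies, demographic risk effects, duplicate case versions, and configurable missingness. |
| `pvkit.faers_ingest` | Read the dialect, deduplicate to one report per case (latest receipt date, then highest version, then highest primary id), select primary-suspect reports, flag target-event cases via an SMQ-style PT list (narrow/broad scopes). |
| `pvkit.disprop` | 2x2 tables per drug–event pair (overall and stratified by sex / age cut / weight cut); ROR, PRR + chi-square, BCPNN E(IC)/IC025, EBGM/EBGM05; joint four-detector signal decision; BH/Bonferroni p-value adjustment. |
| `pvkit.tto_weibull` | Time-to-onset extraction (event date minus earliest PS therapy start), median/IQR summaries, Weibull MLE with Wald CIs, early/random/wear-out hazard classification. |
| `pvkit.risk_model` | Univariable and multivariable logistic regression, nomogram point scaling (largest contribution spans 100 points, probabilities reproduced exactly), rank-based ROC/AUC. |
| `pvkit.nettox_lite` | Gene-set intersection and degree-centrality hub ranking over a STRING-style TSV edge list (0–1000 score scale auto-detected). |
| `pvkit.pipeline` / `pvkit.cli` | End-to-end orchestration with a reproducibility manifest; byte-identical reruns for identical configs. |

## CLI

Every subcommand is available under a single `pvkit` entry point:

```bash
# generate a synthetic dataset from a JSON simulation config
pvkit simulate --config sim.json --out data/

# ingest + dedup counts
pvkit ingest --input data/

# disproportionality scan for one drug (overall + strata)
pvkit signal --input data/ --drug DRUG_001 --strata sex --strata age:65 \
             --strata weight:80 --out signals.csv

# time-to-onset and Weibull hazard classification
pvkit tto --input data/ --drug DRUG_001

# gene-set intersection + hub ranking
pvkit nettox --targets targets.txt --disease disease.txt --edges edges.tsv --top 3

# full pipeline from one config, then a human-readable report
pvkit run-all --config run.json --out run/
pvkit report --run-dir run/
```

A minimal `run.json`:

```json
{
  "simulate": {
    "n_cases": 50000, "n_drugs": 10, "n_events": 5,
    "background_rate": 0.01,
    "signal_matrix": {"DRUG_001|Pancreatitis acute": 10.0},
    "seed": 1
  },
  "drugs": ["DRUG_001"],
  "strata": {"sex": null, "age": 65, "weight": 80},
  "risk": {"covariates": ["age_le65", "weight_gt80", "female"]}
}
```

To analyze real quarterly extracts instead, replace `"simulate"` with
`"input_dir": "path/to/tables"` (files named `DEMO.txt`, `DRUG.txt`,
`REAC.txt`, `THER.txt`, `OUTC.txt`). The SMQ preferred-term list ships as an
editable text config (`src/pvkit/data/acute_pancreatitis_smq.txt`) and can be
overridden per run with `"smq_file"`.

## Conventions worth knowing

- Planted rate ratios and risk effects both act on the log-odds scale, so the
  population reporting odds ratio of a planted pair equals the configured
  ratio exactly.
- EBGM is the plain relative reporting ratio `a*N/((a+c)(a+b))` — no
  gamma-mixture shrinkage; IC025 is `E(IC) - 2*sd`, not a normal quantile.
- Zero cells trigger a Haldane–Anscombe +0.5 correction for ROR/PRR/EBGM
  (flagged `zero_corrected` in the output); the chi-square uses raw cells.
- Dates are parsed under a `strict_day` policy by default: partial FAERS
  dates (YYYYMM / YYYY) become missing so time-to-onset stays day-resolved.
- Raw p-values come from the chi-square statistic on 1 df; the default
  multiplicity adjustment is Benjamini–Hochberg (`bonferroni` available).
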