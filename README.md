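# pvsignals

Disproportionality signal detection for spontaneous adverse-event
reporting databases (FAERS-style quarterly ASCII extracts, generic CSV
exports, or synthetic databases with planted ground truth).

Spontaneous reporting systems are the backbone of post-marketing drug
safety: clinicians, pharmacists and consumers submit case reports naming
suspect drugs and adverse events coded as MedDRA Preferred Terms (PTs).
`pvsignals` implements the standard signal-detection workflow over such
data for a drug of interest — motivated by the safety profile of
dantrolene, the first-line treatment for malignant hyperthermia (MH), but
generic over drugs and databases: ingest and deduplicate case versions,
restrict to reports where the drug is the *primary suspect*, summarize
demographics (person-times counting), and score every drug-event pair
with four disproportionality indices on the 2x2 table
(a, b, c, d; N = a+b+c+d):

* **ROR** = ad/bc with 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`
* **PRR** = [a/(a+b)]/[c/(c+d)] with the uncorrected Pearson χ²
* **BCPNN** information component IC = log₂[aN/((a+b)(a+c))] with the
  closed-form Bayesian lower bound IC025 = E(IC) − 2√V(IC)
* **MGPS** empirical-Bayes geometric mean (simplified relative-reporting
  ratio with EB05 = exp(ln EBGM − 1.645·√(1/a+1/b+1/c+1/d)) by default;
  the full DuMouchel gamma-Poisson shrinker with a fitted
  mixture-of-gammas prior is configuration-selected)

A pair is a final signal only when **all four** indices are positive
(ROR lower bound > 1 with a ≥ 3; PRR ≥ 2 with χ² ≥ 4; IC025 > 0;
EB05 > 2).  Downstream of the combined rule: screening against an
Important-Medical-Event PT list, subgroup contrasts (age 18–44 vs ≥ 45,
treatment duration ≤ 180 vs > 180 days, indication such as MH vs non-MH)
with exact two-sided Fisher tests and between-group RORs, time-to-onset
binning, and case-by-case listings.  A synthetic-database generator with
planted drug-event relative risks makes every stage testable without
downloading any external database.  See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Score one table and a whole synthetic database:

```python
from pvsignals import (ContingencyTable, ror_score, prr_score, bcpnn_ic,
                       ebgm_simple, default_config, generate_reports,
                       deduplicate, score_all_pairs)

t = ContingencyTable(25, 75, 900, 9000)
print(ror_score(t))    # (3.3333, 2.1089, 5.2686)
print(prr_score(t))    # (2.75, 29.8495)
print(bcpnn_ic(t))     # (1.4344, 0.6894)
print(ebgm_simple(t))  # (2.7027, 1.8405)

cfg = default_config(n_reports=200_000, planted_rr=30.0, seed=1)
rs = deduplicate(generate_reports(cfg))
df = score_all_pairs(rs, drugs=["dantrolene"], events=["respiratory failure"])
print(df.round(2).to_string(index=False))
```

The planted pair (true relative risk 30, drug marginal 10⁻³, event
baseline 2·10⁻³) comes back as:

```
 a   b   c      d   ror  ror_lo  ror_hi   prr   chi2   ic  ic025  ebgm  eb05  positive_combined
15 175 442 199368 38.66   22.63   66.05 35.69 490.27 5.11   2.71 34.55 22.04               True
```

Fifteen of the 190 deduplicated reports with dantrolene as primary
suspect carry the planted PT, the ROR interval covers the true relative
risk, and all four indices clear their thresholds, so the combined rule
fires.

The same workflow runs from the command line over a configuration file
(JSON or YAML), either end-to-end or stage-wise:

```bash
pvsignals all --config run.yaml --out results/ --seed 1
pvsignals ingest --config run.yaml --out results/   # FAERS/CSV files
pvsignals score --config run.yaml --reports results/reports.csv
```

`pvsignals all` writes `demographics.csv`, `yearly.csv`, `signals.csv`,
`signals_ime.csv`, `subgroups.csv`, `tto.csv`, `cases.csv`, an
interchange `reports.csv` and a `manifest.json` with the configuration
hash and per-stage report counts; identical configuration and seed
reproduce the outputs byte for byte.

## Data expectations

FAERS-style input is the public "$"-delimited quarterly layout
(DEMO/DRUG/REAC, optionally OUTC/THER/INDI).  Generic CSV input is one
row per report-drug-event triple with a user-supplied column mapping.
The MedDRA IME term list is licensed and therefore **not bundled**: supply
your own copy as plain text, one PT per line.  No external database is
downloaded by this package.
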