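# pvsignal

Disproportionality signal detection for spontaneous adverse-event report
databases (FAERS-style), built around the two statistics most widely used
in pharmacovigilance: the **reporting odds ratio (ROR)** and the **BCPNN
information component (IC)**. The package was written for the
safety-surveillance use case of screening every adverse-event preferred
term (PT) co-reported with one target drug — the worked examples use
capmatinib, a MET inhibitor for *MET* exon-14-skipping NSCLC — but it is
drug-agnostic.

## The method

For one drug and one PT, each deduplicated report falls in exactly one
cell of the fourfold table

|                | target drug | other drugs |
|----------------|-------------|-------------|
| target PT      | a           | c           |
| other PTs      | b           | d           |

with N = a + b + c + d. The two statistics are

- **ROR** = (a·d)/(b·c), with the Wald 95% interval
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); a zero b, c or d cell gets
  the Haldane–Anscombe +0.5 correction, flagged in the result.
- **BCPNN IC** = log₂ of the observed-to-expected co-reporting
  probability, shrunk toward 0 under a conjugate Beta model
  (hyperparameters α₁ = β₁ = γ₁₁ = 1, α = β = 2, configurable). The
  closed forms for E(IC) and V(IC) give **IC025 = E(IC) − 2·√V(IC)**; a
  Monte-Carlo posterior quantile (`mc_ic_quantile`) is included as an
  independent check.

A drug–PT pair is a **signal** when both criteria hold simultaneously:
a ≥ 3 with ROR CI lower bound > 1, and IC025 > 0. Signals are then ranked
(by frequency or by ROR CI lower bound), aggregated by MedDRA system
organ class (SOC), optionally filtered of non-pharmacologic SOCs
(injuries, pregnancy, congenital, product issues), and annotated for
label expectedness against a product-label PT list.

A seeded synthetic-corpus generator produces FAERS-like extracts (case
versions, drug role codes, heavy demographic missingness) with *known
injected* disproportionality, so the whole pipeline can be validated for
recovery of ground truth.

## Worked example

```python
import pvsignal as pv

# a corpus with one injected signal: PT index 3 reported 25x its
# background rate on capmatinib reports
cfg = pv.SyntheticConfig(n_reports=4000, n_pts=40, n_socs=8,
                         injected_pairs=((3, 25.0),),
                         target_drug_prevalence=0.05, seed=0)
reports, truth = pv.generate_reports(cfg)

soc_map = pv.generate_pt_soc_map(cfg.n_pts, cfg.n_socs, cfg.seed)
model = pv.Disproportionality(reports, "capmatinib", pt_soc_map=soc_map)
res = model.fit()
print(res.summary())
```

prints

```
Disproportionality analysis (ROR + BCPNN)
=========================================================
target drug:        capmatinib
corpus reports:     4000
drug reports:       204
drug-PT pairs:      38
signals:            1  (a >= 3, ROR CI lower > 1, IC025 > 0)

top 1 signals by frequency:
PT                                    a      ROR   CI low   IC025
-----------------------------------------------------------------
pt0004                               47    34.14    21.27    2.66
```

The injected PT (index 3 → `pt0004`) is recovered: 47 of the 204
capmatinib reports carry it, its ROR is 34.1 with the 95% interval
bounded away from 1 (lower limit 21.3), and its IC025 of 2.66 is well
above 0, so both criteria flag it. `res.frame` holds the full per-PT
statistics table, `res.soc_summary()` the SOC aggregation, and
`res.annotate_label([...])` marks which signal PTs are already in the
product label.

The same run is available from the shell:

```sh
pvsignal simulate --n-reports 4000 --seed 0 --inject 3:25 --out corpus.tsv
pvsignal run --input corpus.tsv --drug capmatinib --out-dir out/
```

which writes `stats.tsv`, `signals.tsv`, `soc_summary.tsv`,
`demographics.tsv`, top-N rankings and their `.json` twins.

A worked capmatinib dataset is bundled (`pvsignal.datasets`): 79 signal
PTs over 18 SOCs with report counts, the 66-term product-label list
(13 signal PTs are not in the label), and the demographic composition
counts of the 2,201 signal-associated reports.

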