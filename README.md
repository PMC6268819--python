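# cypcons

Consensus classification of **potent vs weak CYP3A4 inhibitors**.

CYP3A4 is the most abundant hepatic and enteric cytochrome P450 isozyme; it
metabolizes roughly half of marketed drugs, so a chemical that potently
inhibits it can change the pharmacokinetics of co-administered drugs
(drug–drug/chemical interactions). `cypcons` implements, end to end, a
consensus pipeline for prioritizing such chemicals from clinical potency
categories, built for computational toxicologists and cheminformaticians:

* **IVIVE** (`cypcons.ivive`) — in vitro → in vivo extrapolation of HTS
  inhibition data. Under competitive inhibition the substrate AUC fold
  change is *R* = 1 + [I]/K<sub>i</sub>, and at low substrate concentration
  the Cheng–Prusoff relation K<sub>i</sub> = IC₅₀/(1 + [S]/K<sub>m</sub>)
  reduces to K<sub>i</sub> ≈ IC₅₀. Four variants estimate the inhibitor
  concentration [I] (MRDD × bioavailability / MW, predicted bioavailability,
  100% bioavailability, or C<sub>max</sub>); compounds are called potent
  (*R* > 2), weak (1.25 ≤ *R* ≤ 2) or not determined, with confidence
  intervals propagated by interval inversion of the IC₅₀ CI.
* **MW banding** (`cypcons.mwband`) — molecular-weight–band enrichment:
  normalized activity histograms, sigmoid/linear/Weibull curve fits whose
  intersection locates the ≈450 Da band threshold, Wilson score intervals,
  one-tailed pooled two-proportion z-tests with power, and expected-count
  intervals for auditing classifier output.
* **DLR** (`cypcons.dlr`) — logistic regression on standardized docking
  scores (4 programs × 7 binding sites = 28 columns), with forward/backward
  stepwise and "manual" Wald-test variable selection, ROC/cutoff analysis,
  the published seven-score model as a fixed-coefficient scorer, and a
  truncated (> 450 Da) applicability domain.
* **SDAR** (`cypcons.sdar`) — spectral data–activity relationship: predicted
  ¹³C/¹⁵N chemical shifts binned at 1/5 ppm, sparse bins dropped, and a
  forward-stepwise linear discriminant model (partial *F* > 4 to enter,
  equal class priors).
* **SAR forest** (`cypcons.sarforest`) — Shannon-entropy filtering of 777
  molecular descriptors down to 327, then a five-tree Gini decision forest
  whose trees use pairwise-disjoint descriptor sets.
* **Consensus** (`cypcons.consensus`) — majority-rules (or conjunction /
  disjunction) combination of the three Boolean votes with
  percent-agreement confidence tiers (*probable* = all three agree potent,
  *plausible* = >50% agreement, *uncertain* otherwise) and expectation-count
  audits.
* **Validation** (`cypcons.validation`) and **synthetic data**
  (`cypcons.synthdata`) — repeated 9:1 tenfold cross-validation, and
  generators that reproduce the statistical structure of the study inputs
  so the whole pipeline is testable without proprietary docking, NMR
  prediction, or descriptor software.

## Worked example

```python
>>> from cypcons import ivive, mwband
>>> rep = ivive.extrapolation_report()
>>> float(rep.loc["glibenclamide", "R3"]), rep.loc["glibenclamide", "C-3"]
(1.1, 'ND')
>>> mwband.wilson_interval(15, 82)
(0.1141102185364291, 0.2801218842914394)
>>> t = mwband.two_proportion_z_one_tailed(15, 82, 18, 39)
>>> round(t.z, 3), round(t.p_one_tailed, 6), round(t.power, 3)
(-3.216, 0.00065, 0.934)
>>> mwband.expected_count_interval(33, 121, 120)
(24, 43)
```

Reading: glibenclamide's AUC fold change at 100% bioavailability is 1.10
with a CI reaching past the potency threshold, hence "not determined"; only
18% (95% CI 11–28%) of low-MW training inhibitors are potent versus 46%
above 450 Da, a significant enrichment (p ≈ 6.5 × 10⁻⁴, power 93%); a
classifier applied to 120 similar compounds should call 24–43 of them
potent.

The same stages are exposed as a CLI:

```bash
cypcons simulate --preset training --seed 7 --out-dir sim/
cypcons dlr-train --scores sim/scores.csv --labels sim/truth.csv --model-out dlr.json
cypcons sdar-train --peaks sim/peaks.csv --labels sim/truth.csv --model-out sdar.json
cypcons sar-train --descriptors sim/descriptors.csv --labels sim/truth.csv --model-out sar.json
cypcons crossval --method sar --descriptors sim/descriptors.csv --labels sim/truth.csv --out cv.csv
```

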