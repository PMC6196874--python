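# pedometer-cea

Short-term and long-term cost-effectiveness analysis of pedometer-based
walking interventions in primary care, built around the PACE-UP trial
(ISRCTN98538934): a three-arm, household-randomised comparison of usual
care (control), a pedometer pack sent by post (postal), and the same pack
delivered through practice-nurse consultations (nurse).

The package is aimed at health economists and trial statisticians who want
a tested, reusable implementation of the two standard evaluation designs
this study combines:

* **Within-trial (1-year) evaluation.** QALYs as the trapezoidal area
  under the EQ-5D utility curve (measurements at 0, 3 and 12 months);
  per-participant costs (set-up, delivery, general health service use,
  participant-borne) under switchable perspectives; the trial's
  missing-data policy (arm-mean fill at ≤5% missingness, chained-equations
  multiple imputation above); covariate-adjusted arm means by *recycled
  predictions* from GLMs (Poisson/log for costs, logit-link binomial
  quasi-likelihood for QALY indices) with household-clustered uncertainty;
  and a 2000-replicate household cluster bootstrap feeding
  cost-effectiveness planes and acceptability curves (CEACs).
* **Lifetime Markov cohort model.** 100,000 people aged 59 followed in
  annual cycles to 88. After year 1 each person is active (≥150 weekly
  minutes of MVPA in ≥10-minute bouts) or inactive; activity lowers the
  age-specific risks of CHD, stroke and type 2 diabetes via relative risks
  that persist for 10 years (1 or 3 in sensitivity scenarios). Costs and
  QALYs are discounted at 3.5% a year; probabilistic sensitivity analysis
  samples beta/gamma/lognormal distributions around every parameter except
  baseline mortality.

Core statistics, in the field's notation: ICER = ΔC/ΔE with
cost-effectiveness-plane quadrant and dominance classification;
NMB(λ) = λ·ΔE − ΔC; CEAC(λ) = P(NMB(λ) > 0) over a willingness-to-pay
grid (default £0–£50,000 per QALY).

Participant-level trial records are not public, so a first-class
synthetic-data module generates trial tables with the published structure:
arm-level means/SDs for utilities, steps, MVPA-bout minutes and cost
components; household clustering (members share an arm); and configurable
MCAR/MAR missingness with a truth channel for imputation accuracy checks.
The lifetime model's epidemiology ships as a clearly labelled synthetic
placeholder parameter file (`src/pedometer_cea/data/synthetic_markov_params.yaml`)
chosen to reproduce the published qualitative pattern, not its magnitudes.

## Worked example

Re-deriving published table arithmetic from printed summary numbers:

```python
from pedometer_cea import IncrementalResult, icer_classify, net_monetary_benefit, qaly_auc

# nurse vs control at 3 months: +£135 for +61 weekly MVPA-bout minutes
icer_classify(IncrementalResult(135, 61, "mvpa_min")).value      # 2.2131... -> £2.21/min
# lifetime postal vs control: -£11m and +759 QALYs per 100,000 people
icer_classify(IncrementalResult(-11e6, 759, "qaly")).label       # 'dominant'
net_monetary_benefit(IncrementalResult(-11e6, 759, "qaly"), 20_000).nmb  # 26,180,000.0
# control-arm QALYs from mean EQ-5D at 0 / 3 / 12 months
qaly_auc([0, 0.25, 1.0], [0.837, 0.840, 0.833])                  # 0.837
```

Running the full pipeline from the shell:

```bash
pedometer-cea simulate --n-per-arm 320 --seed 1 --missing-rate 0.07 --out trial.csv
pedometer-cea within-trial --input trial.csv --b 2000 --seed 1 --outdir results/wt
pedometer-cea markov --scenario base --outdir results/mk
pedometer-cea psa --n 10000 --seed 1 --outdir results/psa
```

`markov` prints, under the shipped placeholder parameters:

```
                  row  cost_millions     qalys      icer nmb_millions
          arm:control          468.2 1291582.0
           arm:postal          451.0 1293070.0
            arm:nurse          473.7 1292884.0
cmp:postal_vs_control          -17.2    1488.0 dominates           47
 cmp:nurse_vs_control            5.5    1302.0 £4,241.60           21
  cmp:nurse_vs_postal           22.7    -186.0 dominated          -26
```

i.e. postal delivery saves money and gains QALYs against usual care
(dominant), nurse delivery gains QALYs at a positive ICER, and nurse is
dominated by postal — the published qualitative pattern; the magnitudes
reflect the placeholder epidemiology, not the original calibrated inputs.

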