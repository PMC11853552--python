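# booscore

A point-based risk score for **bladder outlet obstruction (BOO)** in men
with lower urinary tract symptoms (LUTS), implemented as a tested Python
pipeline: a synthetic patient-cohort generator, the published eight-variable
score card, the procedure that derives such a card from labelled data, and
the ROC/Youden evaluation that turns scores into subtype-wise diagnostic
performance tables.

## The problem

Videourodynamic studies (VUDS) are the reference standard for classifying
lower urinary tract dysfunction (LUTD) in men — distinguishing benign
prostatic obstruction (BPO) and bladder neck dysfunction (BND) from
functional disorders such as detrusor overactivity (DO), detrusor
underactivity (DU), dysfunctional voiding (DV), poor sphincter relaxation
(PRES) or a hypersensitive/normal bladder — but they are invasive and not
available in most clinics. The alternative is a composite score built from
**office-based** measurements: age, the IPSS voiding/storage ratio (V/S),
uroflowmetry (maximum flow rate Qmax, voided volume) and transrectal
ultrasound prostate parameters (total prostate volume TPV, transition-zone
index TZI, intravesical prostatic protrusion IPP, prostatic urethrovesical
angle PUV).

Each variable is categorised into 0–3 points at cutoffs chosen for their
specificity in predicting VUDS-confirmed BOO (the pooled BND + BPO group);
the composite risk score is the sum over the eight variables,

&nbsp;&nbsp;&nbsp;&nbsp;S = Σᵥ pointsᵥ(xᵥ) ∈ {0, …, 18}.

A high score flags prostatic obstruction (BPO: score ≥ threshold), while low
scores screen for the non-obstructive subtypes (score ≤ threshold). Operating
thresholds are chosen on a training split by maximising Youden's
J = sensitivity + specificity − 1, and discrimination is summarised by the
Mann–Whitney AUC with DeLong 95% confidence intervals.

Because the source cohort is not publicly deposited, the package ships a
first-class synthetic generator that emulates its printed statistical
structure: eight LUTD subtype prevalences, BOO/non-BOO group-conditional
means ± SDs for all eleven clinical variables, a Gaussian copula with a
documented correlation structure, physiological truncation bounds, and a
285/70 training/validation partition of 355 patients.

## Worked example

```python
import booscore as bs

config = bs.PipelineConfig(generator=bs.default_generator_config(n=355), seed=1)
result = bs.run_pipeline(config)
print(result.report.round(3))
```

Running `python examples/04_evaluate_subtypes.py` prints (abridged):

```
cohort n=355: training 285, validation 70

    target      split  threshold direction  sensitivity  specificity   auc  ci_low  ci_high
       BPO   training        8.0        ge        0.919        0.341 0.631   0.563    0.699
       BPO validation        8.0        ge        0.889        0.250 0.666   0.518    0.815
      PRES   training        5.0        le        0.444        0.906 0.741   0.623    0.858
        DU   training        9.0        le        0.706        0.522 0.638   0.521    0.755
...
```

Each row is a one-vs-rest evaluation of the composite score for one LUTD
subtype on one split: the integer threshold (chosen by Youden's index on the
training split only and frozen for validation), the flagging direction
(`ge`: high scores flag the target; `le`: low scores do), sensitivity and
specificity at that threshold, and the AUC with its DeLong 95% CI. For `le`
rows the AUC is computed on the negated score, so values above 0.5 mean the
low-score rule discriminates. The other examples show cohort simulation
(`01`), patient-level scoring with the per-variable point breakdown (`02`),
and derivation of a fresh card from labelled data (`03`).

The packaged default card is data, not code
(`src/booscore/data/default_card.json`); a seven-variable variant without
the age row ships alongside it (`bs.packaged_card("no_age")`).

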