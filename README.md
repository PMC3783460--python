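# leptindrive

Energy-balance modelling of food intake from long-term body-weight records:
estimate a subject's physiological parameters, reconstruct the latent
monthly *eating drive*, and quantify how much dieting and leptin pull that
drive down.

The package is aimed at biostatisticians and physiologists working with
multi-year weight histories (monthly weighings plus a record of dietary
periods), where calorie intake itself was never measured and must be
inferred.

## The model

Two state variables per subject: the calories *C* [cal] stored in adipose
tissue and the plasma leptin concentration *L* [ng ml⁻¹]. Intake is a
latent drive *D* [cal day⁻¹] damped by leptin; expenditure *Q* decays
slowly; dynamics are linear:

    dC/dt = (D − αL) − Q(t)
    dL/dt = βC − γL
    Q(t)  = Q₀ e^(−εt)         (piecewise in ε, with Q continuous)

Leptin clears with a half-life of 24.9 min (γ = 40.1 day⁻¹), orders of
magnitude faster than weight changes, so *L* sits on the quasi-steady
state L = βC/γ and the calorie balance reduces to

    dC/dt = D − ηC − Q(t),      η = αβ/γ,

with the explicit constant-drive solution C(t) = D/η − Q(t)/(η − ε)
(valid for η > ε). Weight follows as W = C/(ρδ), with ρ = 3500 cal per lb
of body fat and δ the body-fat fraction.

The workflow:

1. **fit** — estimate (D, Q₀, δ, η, ε) by bounded multi-start least squares
   on the weight record (only the triple A = D/(ηρδ), B = Q₀/((η−ε)ρδ), ε
   is identifiable; see `docs/methods.md`), then calibrate β from a
   reference plasma leptin level (20.3 ng ml⁻¹ at the record's mean weight)
   and α from η = αβ/γ. A piecewise variant handles a mid-record break in
   the expenditure trend with Q continuous at the break.
2. **reconstruct** — invert the discretized calorie balance month by month:
   D(τ) = ρδ·ΔW/Δt + αL(τ) + Q(τ), with L(τ) the quasi-steady-state level
   for the observed weight.
3. **diet-stats** — drive deficit E(τ) = D̄ − D(τ) relative to the mean
   drive outside dietary periods, per-period mean deficits with a one-sided
   one-sample t-test, dieting and leptin effects as percentages of D̄, and
   the cross-correlation X(s) of E with the dietary block indicator
   (normalized so X(0) = 1); a peak at negative lag s means the subject
   starts restraining intake *before* the formal dietary period.

A seeded synthetic-data generator produces weight records with the
structure the analysis assumes (slow expenditure-driven trend, noisy drive,
dietary reductions with anticipation/relapse leads), so the whole pipeline
is testable with known ground truth.

## Worked example

```sh
leptindrive synthesize --preset subject_A_like --seed 1 \
    --out-weights weights.csv --out-schedule schedule.csv \
    --out-truth truth.csv --out-params params.yaml
leptindrive run-all --weights weights.csv --schedule schedule.csv \
    --params params.yaml --outdir out
```

prints

```
Dieting and leptin effects on the eating drive
----------------------------------------------
mean drive outside dietary periods :   2618.9 cal/day (SD 155.6)
per-period mean deficits            : 97, 153, 140, 248, 118, 142, 153, 25
overall mean deficit (pop. SD)      :    134.5 (58.5) cal/day
one-sided t-test vs 0               : t = 6.085, p = 0.000
dieting effect                      : 5.1% of the mean drive (prints as 5%)
leptin effect (alpha*L_ref)         : 0.24% (prints as 0.2%)
cross-correlation X(0)              : 1.000000
smoothed X(s) peak at s             : -1 months
```

Reading this: the subject's reconstructed drive averages ≈ 2619 cal day⁻¹
outside dieting; in each of the eight dietary periods the drive drops by
25–248 cal day⁻¹ (mean 134.5), a highly significant reduction (p < 0.0005);
dieting suppresses about 5% of the habitual drive while the leptin feedback
term αL accounts for ≈ 0.2%; and the cross-correlation peak at s = −1
months shows the drive reduction beginning one month before the formal
dietary periods — exactly the anticipation lead this preset generates.
Omit `--params` to estimate the parameters from the weights instead of
using the generator's truth.

The same subcommands work on real data: a weight CSV
(`month,weight_lb`) and a schedule CSV (`start_month,end_month`, half-open
month intervals).

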