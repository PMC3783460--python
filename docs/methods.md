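# Methods

## Model and assumptions

The package models one subject's energy balance with two linear state
equations: stored adipose calories C [cal] change as intake minus
expenditure, dC/dt = (D − αL) − Q(t), and plasma leptin L [ng ml⁻¹]
relaxes as dL/dt = βC − γL. The drive D [cal day⁻¹] collects every
physiological and psychological incentive to eat that is not modelled
explicitly; leptin is the single explicit feedback (the hypothalamus reads
the fat store through circulating leptin, damping intake by αL).
Expenditure declines slowly, Q(t) = Q₀e^(−εt), encoding the assumption
that long-term weight gain reflects falling expenditure rather than rising
intake. Nonlinear effects (leptin resistance, ghrelin, explicit dieting
dynamics) are out of scope: the linear model is the most complex structure
that monthly weight data can constrain.

Time-scale separation is central. Leptin clears renally with a 24.9-minute
half-life, γ = ln 2/24.9 min = 40.1 day⁻¹, while the fat store drifts at
η = αβ/γ ≈ 10⁻⁵–10⁻⁴ day⁻¹. After minutes, L ≈ βC/γ (quasi-steady state)
and the system reduces to the scalar balance dC/dt = D − ηC − Q(t), whose
constant-drive solution is C(t) = D/η − Q(t)/(η − ε) once the initial
condition has been forgotten; the homogeneous term Ke^(−ηt) is always
dropped (valid for η ≫ ε; we enforce η > ε as a hard constraint and keep
K = 0 even where ηt is not large, as a deliberate fidelity choice).
Weight converts as W = C/(ρδ) with ρ = 3500 cal lb⁻¹ and δ the body-fat
fraction. With a multi-rate expenditure schedule only Q is made continuous
across a transition; W itself may kink (and, strictly, jump by the tiny
amount Q(t*)·(1/(η−ε₁) − 1/(η−ε₂))/(ρδ)) — continuity of W is not
imposed.

Units: dietary Calories ("cal" ≈ 2000/day scale), pounds, days internally;
month grids convert at 365.25/12 = 30.4375 days/month (configurable; the
astronomical mean is a convention, nothing in the data prefers another).

## Parameter derivations

γ comes from the half-life as above. β is calibrated so the quasi-steady
state reproduces a reference plasma level: β = γL_ref/(ρδW_ref) with
L_ref = 20.3 ng ml⁻¹ (mean for women) and W_ref the mean observed weight
of the fitted section — the section mean, not the whole-record mean, is
used because it is the natural anchor for a section-wise fit (for
two-section records the first section's mean is kept, since all parameters
except the later ε are estimated there). α then follows from η = αβ/γ
exactly, so the derived rates always satisfy the composite-rate identity
to machine precision.

## Estimation and identifiability

(D, Q₀, δ, η, ε) are estimated by minimizing the residual sum of squares
between observed weights and the explicit solution. On a single section
the model is W(t) = A − Be^(−εt) with A = D/(ηρδ) and B = Q₀/((η−ε)ρδ):
**only (A, B, ε) is identifiable**; the quintuple has an exact
two-dimensional ridge (any (D, Q₀, δ, η) with the same (A, B) fits
identically). We still optimize in the physiological quintuple because the
literature bounds — D, Q₀ ∈ [500, 6000] cal day⁻¹, δ ∈ [0.15, 0.5]
(human body fat is around 30%), η ∈ [10⁻⁶, 10⁻²] day⁻¹ (log-scaled
internally), ε parameterized as a fraction of η/10 so η > ε holds by
construction — confine the ridge to a plausible region. The optimizer is
bounded trust-region least squares restarted from 32 seeded
Latin-hypercube points (the ridge makes single starts stall); the best
local optimum is kept and, by construction, improves on every starting
point. Tests and reported diagnostics therefore assess the fitted curve
and the triple (A, B, ε), never the raw quintuple; `fix_delta` pins δ to a
literature value when a physiological parameterization is wanted.

Piecewise records (an abrupt change in the expenditure trend at a known
month) are fitted in two stages: everything on the pre-break section, then
only the second decay rate ε₂ on the later section with Q continuous at
the break. Because ε₂ is identifiable only *conditional* on η, recovery
experiments pin δ and narrow the η bounds to the generating value; an
unconditioned fit lands anywhere on the ridge and the conditional ε₂
absorbs the η error. Residuals are unweighted (no error model for the
scale readings is assumed), and the time origin is the first observation
of the fitted section. No standard errors are reported: on the ridge they
would be meaningless for the raw parameters.

## Drive reconstruction

Given parameters, the reduced balance is inverted month by month with a
forward difference: D(τ) = ρδ(W(τ+1) − W(τ))/Δt + αL(τ) + Q(τ·Δm), with
L(τ) = βρδW(τ)/γ evaluated at the left endpoint and Δm the month length
in days. The drive value is assigned to the left month — the convention
that matches the forward discretization. The reconstruction is raw (no
smoothing); its discretization error is O(η·ΔC_within-month), about
10⁻⁴ of the drive at monthly sampling, far below the monthly noise.
Summary statistics of the drive outside dietary periods use the
population (n-divisor) standard deviation, the convention that also
reproduces the worked-example tables' SD columns.

## Diet-effect statistics

The deficit E(τ) = D̄ − D(τ) is measured against the mean drive outside
all dietary periods, so it averages to zero outside by construction.
Per-period means are tested against zero with a one-sample, one-sided
t-test (sample variance): the one-sided alternative is the directional
hypothesis that dieting lowers the drive, and this combination reproduces
the reference worked example (two-sided would double the p-value).
Percentages: dieting = 100·Ē/D̄, leptin = 100·αL_ref/D̄; both are reported
unrounded plus in printed style (integer / one decimal).

The cross-correlation is X(s) = Σ E(τ)B(τ−s) / Σ E(τ)B(τ), with B the
dietary block indicator, s in months (negative = block shifted earlier),
sums over the drive record's month grid and the shifted block simply
truncated at the record boundaries (no wrap-around). Normalizing by the
s = 0 numerator makes X(0) = 1 exact. The peak location of a 3-month
moving-average smoothing of X(s) is the anticipation estimate: a peak at
s = −k indicates the deficit leads the formal periods by k months.

## Synthetic data

The generator emulates the study's data type: a monthly drive
D(τ) = baseline + N(0, σ_D) − depth·1[τ in lead-shifted periods], pushed
through the quasi-steady-state balance (piecewise-constant drive,
integration restarted at month boundaries) and sampled monthly with
N(0, σ_obs) observation noise. Anticipation and relapse are hard shifts of
the block edges (start moved earlier by the anticipation lead, end by the
relapse lead). All randomness flows from a single integer seed; the
observation-noise stream is split from the drive stream so disabling one
does not perturb the other, and identical seeds give bit-identical output.

Two presets mirror the reference subjects' printed anchors: Q₀ = 2571,
ε = 10⁻⁷, δ = 0.405, η = 2.78×10⁻⁵ with mean weight 157.0 lb (preset A);
Q₀ = 2100, ε = (2.06×10⁻⁶, 8.30×10⁻⁷) with a break at month 40, δ = 0.316,
η = 1.17×10⁻⁴, first-section mean 127.4 lb (preset B). Drive noise SDs
(131 / 183 cal day⁻¹) and diet depths (267 / 160 cal day⁻¹) are the
reference subjects' reconstructed fluctuation and mean-deficit scales;
leads default to one month each; observation noise is 1 lb. Because η is
tiny, relaxation is negligible over the record: diet deficits accumulate
as permanent weight losses, so the baseline drive is calibrated by an
exact affine solve (the ODE is linear in the drive; two deterministic runs
determine the coefficient) to put the *deterministic* record mean at the
target weight, and the starting weight is set explicitly (145 lb / 120 lb)
— the quasi-equilibrium starting formula amplifies baseline offsets by
1/η and is used only when no starting weight is given. The resulting
records are yoyo-like: a steady climb between diets, sharp diet losses,
drive-noise-driven weight wander of several pounds.

What the generator does **not** emulate: mean-reverting intake regulation
within months (real weight fluctuations are less persistent than the
integrated white drive noise used here), seasonal structure, measurement
gaps, and post-diet rebound overshoot. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to physiology outside the model.

## Numerical choices

Integration uses LSODA (stiff-capable; the full system mixes a ~36-minute
and a multi-year scale) at relative tolerance 10⁻⁸ for the full system and
10⁻¹⁰ for the scalar reduction, with output on the caller's grid;
integration restarts at declared drive discontinuities so step control
never straddles a jump. Least squares runs with trf at
xtol = ftol = gtol = 10⁻¹⁵ (the ridge needs tight termination for the
identifiable directions to converge fully). Expenditure schedules chain
section start values multiplicatively, making Q continuous to machine
precision by construction. Degenerate inputs fail loudly with typed
errors: non-monotone months, constant or < 6-point series for fitting,
overlapping schedules, η ≤ ε, empty out-of-diet month sets, zero
cross-correlation normalizers.

Test problem sizes are chosen to exercise the science at interactive
runtimes: 80-month records (the reference records' scale), 32 multi-start
fits for acceptance-grade recovery and 4–8 starts for unit-level checks,
100 random instances for the cross-correlation oracle, 10–20 seeds for
Monte-Carlo properties.

## Known limitations

- Raw (D, Q₀, δ, η) values from a fit are ridge coordinates, not
  physiological estimates; only bound-constrained and derived quantities
  (A, B, ε, β, α given the calibration) carry meaning.
- The ε = 10⁻⁷-scale decay of preset A is near the edge of numerical
  identifiability over 80 months (the curvature it induces is ~10⁻³ lb);
  recovery tests use better-conditioned generating values.
- The reconstruction inherits any parameter misspecification additively
  (through αL and Q), shifting the drive's level but barely its
  fluctuations; deficit statistics, which difference against D̄, are
  largely insensitive to such level shifts.
- The t-test treats per-period mean deficits as independent draws; with
  few periods and autocorrelated drive noise this is approximate.
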