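# Methods

## Model

A three-state progression model: disease-free (S0) → preclinical (Sp,
screen-detectable, entered at age T1) → clinical (Sc, symptomatic,
entered at age T2).  The *stable* variant makes every ingredient
age-independent:

| symbol | meaning | default | units |
|--------|---------|---------|-------|
| w      | yearly S0 → Sp transition rate | 0.004 | 1/yr |
| β      | per-exam sensitivity in Sp | trial-specific | — |
| λ      | mean sojourn time in Sp (exponential) | trial-specific | yr |
| t0     | age at first exam | 50 | yr |
| T      | program horizon | 80 | yr |
| Δ      | inter-exam interval | 0.5–2 | yr |

The default w spreads a lifetime onset risk bound of 0.20 over the 50
ages (30–80) at which onset is considered possible.  Exams sit at
t_i = t0 + iΔ, i = 0..K−1 with K = (T − t0)/Δ required integral.  A
woman already clinical before the next exam is diagnosed symptomatically
(an interval case); detection attempts at distinct exams are
independent.  An exam at age T itself would be irrelevant: every
quantity below conditions on clinical onset before T, and a detection at
T implies onset after T.  D = 1 denotes clinical onset inside (t0, T);
all lead-time summaries are over the D = 1 group, *zeros included* —
the mixture describes the whole diseased group, not just the
screen-detected.

For D = 1-conditional quantities the constant onset hazard is realized
as an onset-age density flat at w on (0, T).  Onsets after T cannot
produce D = 1, and the flat density integrates exactly to

    P(D=1) = w(T − t0) + wλ(e^{−T/λ} − e^{−t0/λ}).

## Closed forms

The interval-case probability I_{K,j} (clinical onset in
(t_{j−1}, t_j), all prior exams missed) decomposes on the onset age:

1. **onset before t0** — the woman is preclinical at all j exams
   preceding her clinical onset, contributing
   wλ(1−β)^j [e^{−(j−1)Δ/λ} − e^{−t_{j−1}/λ} − e^{−jΔ/λ} + e^{−t_j/λ}];
2. **onset in an earlier interval** (t_{i−1}, t_i), i < j — she misses
   the j−i exams t_i..t_{j−1}, contributing
   wλ Σ_{i=1}^{j−1} (1−β)^{j−i}[e^{−(j−i−1)Δ/λ} − 2e^{−(j−i)Δ/λ} + e^{−(j−i+1)Δ/λ}];
3. **onset inside the same interval** — no exam intervenes:
   wΔ − wλ(1 − e^{−Δ/λ}).

Each bracket is an exponential integral of the flat onset density
against the sojourn survival; the algebra is verified in the test suite
two independent ways (piecewise quadrature of the model definition, and
the Monte-Carlo simulator).  P = Σ_j I_{K,j} / P(D=1) is exactly
independent of w, since every term above is proportional to it.

**Moments.**  The *detection weight*
weight_i = P(first detection at exam t_i, still preclinical at t_i)
follows from the same decomposition with miss factors (1−β) per
intervening exam, survival e^{−(t_i − u)/λ} and a hit factor β.  By
memorylessness the residual T2 − t_i of a woman first detected at t_i is
again Exp(λ), truncated to (0, T − t_i) by the D = 1 conditioning — and
her lead time *is* that residual.  Mean and second moment of L over the
D = 1 group are therefore weighted sums of truncated-exponential partial
moments divided by P(D=1); the zero mass enters automatically because
interval cases contribute nothing to the sums but sit in the
denominator.  A conservation identity
(Σ_i weight_i(1 − e^{−(T−t_i)/λ}) + Σ_j I_{K,j} = P(D=1)) is asserted at
run time.

## Simulator

Rejection sampling realizes the D = 1 conditional law exactly, without
importance weights: draw onset ~ Uniform(0, T) (the flat-density
realization; only the shape matters once conditioned), sojourn ~ Exp(λ),
accept iff t0 < T2 < T.  Accepted women face Bernoulli(β) detection at
every exam with max(T1, t0) ≤ t_i < T2; the first success fixes the
detection age and L = T2 − t_i, otherwise L = 0.  The vectorized cohort
path draws the index of the first successful exam from a geometric(β)
variable, which is distributionally identical to the per-exam coin
flips; the scalar `simulate_case` performs the literal per-exam draws.
The acceptance record n_accepted/n_raw, rescaled by wT (flat proposal
density 1/T versus model density w), estimates P(D=1) and is counted up
to the raw draw that produced the last accepted case, keeping the ratio
unbiased.

Defaults: 10^6 accepted cases per cell (Monte-Carlo SE of the mean
≈ 0.002–0.004 yr, of P ≈ 0.0005) and a fixed documented seed; every
cell of a grid gets an independent child stream spawned from the one
seed, so single cells are reproducible in isolation.  Identical configs
give bit-identical cohorts.

What the generator emulates: the latent two-age history, imperfect
periodic detection, interval incidence, length-biased sampling of
screen-detected sojourns and right truncation at the horizon.  What it
deliberately does not: age-dependent sensitivity/sojourn/transition
rates, false positives, over-diagnosis, competing mortality, attendance
behaviour.  Tests passing on this generator therefore validate the
model's internal mathematics, not the fidelity of the stable model to
real screening cohorts.

## Numerical choices

- All exponentials take negative arguments; e^{−t_j/λ} with t_j ≈ 50–80
  and λ ≈ 2–4 underflows gracefully to zero in IEEE doubles, so no
  rescaling is needed.  `expm1` is used where 1 − e^{−x} loses digits.
- P is clamped into [0, 1] against 1-ulp overshoot at β = 0.
- Schedules reject non-integral K (tolerance 1e−9 relative) and T = t0;
  the conditional P(L=0 | D=1) raises an explicit error rather than
  returning NaN when P(D=1) = 0.
- Variances use the population convention (n denominator); SD standard
  errors use the fourth-central-moment delta method.

## Reference-value comparison

The shipped trial parameterizations reproduce published summary tables
for this screening design.  Those published per-cell estimates were
themselves obtained by Monte-Carlo simulation of unstated size: our
exact closed forms and our simulator agree with each other to within
2–3 SE at 10^6 cases on every cell, while several published cells sit
further away (up to ≈ 0.02 in P and ≈ 0.1 yr in the mean, with signs
correlated within trial blocks, the signature of moderate-size shared
random streams).  The strict table-reproduction tests in
`tests/test_acceptance.py` assert the printed precision regardless and
are expected to flag exactly those cells; the property-based and
dual-engine acceptance checks pass in full.

## Design choices

- **Zero inclusion** — mean and SD include the interval cases' zeros;
  the consistency check mean/Q ≤ λ (conditional mean of a truncated
  residual) holds on every grid tested.
- **K-interval convention** — "last exam at T" versus "last interval
  ends at T" are numerically identical here (see above); the package
  adopts the K-interval reading and documents the equivalence.
- **Engines kept symmetrical** — every table can be built analytically
  or by simulation through the same interface, so each is a regression
  oracle for the other.
- **No plotting** — the CLI writes tables and manifests only, keeping
  the runtime dependency surface to numpy/pandas/click/pyyaml.

## Limitations

Everything is age-independent by construction; parameter uncertainty in
(β, λ) is carried as metadata but not propagated into the tables; costs,
false positives and over-diagnosis are outside the model, so the
percent-benefit tables quantify only the early-detection side of any
screening-frequency trade-off.
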