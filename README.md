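# leadtime

Lead-time properties of periodic cancer screening programs under a
stable (age-independent) disease model: exact closed forms, a
Monte-Carlo natural-history simulator, and the resulting
screening-design tables for four historical breast-cancer trials.

## The problem

The *lead time* L is the time by which a screening exam advances a
cancer diagnosis.  A woman progresses through three states: disease-free
(S0), preclinical (Sp — asymptomatic but screen-detectable, entered at
age T1) and clinical (Sc, entered at age T2).  If an exam detects her at
age t in (T1, T2), her lead time is T2 − t; if she turns symptomatic
between exams (an *interval case*), screening bought her nothing and
L = 0.  The lead-time distribution over everyone who develops clinical
disease during the program is therefore a mixture: a point mass P at
zero plus a continuous positive part.

Under the stable model:

- onset of the preclinical state has constant yearly transition rate
  *w* (default 0.004 = a 0.20 lifetime risk spread over ages 30–80);
- the sojourn time T2 − T1 is exponential with mean λ years;
- each exam independently detects preclinical disease with sensitivity β;
- exams are offered every Δ years from age t0 = 50 up to the horizon
  T = 80, giving K = (T − t0)/Δ exams.

With D = 1 the event that clinical onset lands in (t0, T), the headline
quantity is

    P = P(L = 0 | D = 1) = Σ_{j=1}^{K} I_{K,j} / P(D = 1),

where I_{K,j} is the probability of becoming an interval case in the
j-th inter-exam interval, evaluated in closed form by decomposing on the
onset age (before the first exam; in an earlier interval; in the same
interval), and

    P(D = 1) = w(T − t0) + wλ(e^{−T/λ} − e^{−t0/λ}).

P depends only on (β, λ, Δ) — the transition rate cancels.  Q = 1 − P is
the proportion of clinical cases who potentially benefit.  Mean and SD
of L (zeros included) follow either from closed-form *detection weights*
plus the memoryless truncated-exponential residual law, or empirically
from the simulator; the package provides both engines and they agree to
Monte-Carlo error.

Parameter sets (β, λ) estimated from four screening trials ship with the
package: HIP (0.70, 2.50), Edinburgh (0.78, 4.30), CNBS1 (0.91, 1.90),
CNBS2 (0.82, 3.10).

## Worked example

```python
>>> import leadtime as lt
>>> params = lt.trial_params("HIP")          # beta=0.70, lam=2.50, w=0.004
>>> sched = lt.ScreeningSchedule(t0=50, T=80, delta=1.0)
>>> lt.prob_no_benefit(params, sched)
0.2838950394631732
>>> lt.analytic_mean_sd(params, sched)
LeadTimeSummary(P=0.2838950394631732, Q=0.7161049605368268,
                mean=1.6418026164791006, sd=2.182060693799249,
                ratio=0.6567210465916402, ...)
```

Under annual screening with the HIP parameters, 28.4% of women who
develop clinical cancer before 80 are interval cases (zero lead time);
the mean lead time over *all* clinical cases is 1.64 years, about 0.66
of the mean sojourn time.  The simulator reproduces this independently:

```python
>>> cohort = lt.simulate_cohort(lt.CohortConfig(params, sched, 1_000_000, seed=1))
>>> s = lt.empirical_summary(cohort)
>>> round(s.mean, 3), round(s.P, 4)
(1.644, 0.2837)
```

The same tables from the shell:

```sh
leadtime summary --trial HIP --delta 1            # P, Q, mean, SD, ratio
leadtime compare                                  # benefit of shorter intervals
leadtime simulate --trial HIP --n 100000 --out runs/hip  # case-level CSV
```

The numbered drivers under `analysis/` build the full result set into
`results/`: `01_closed_form_tables.py` (exact 16-cell summary grid),
`02_simulate_cohorts.py` (Monte-Carlo replication at 10^6 accepted cases
per cell, with exact-vs-simulated gaps in SE units) and
`03_interval_benefit.py` (percent gains per half-year interval cut — for
HIP parameters, moving from yearly to half-yearly exams raises Q by
16.8% and the mean lead time by 16.7%).

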