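# notchrdk

Tools for studying **motion transparency** — the percept of two superimposed
motions in the same region of the visual field — with criterion-free
psychophysics. The package synthesizes notched random-dot kinematograms
(RDKs), runs a simulated three-alternative odd-one-out task against model
observers, and fits the resulting performance curves.

## The method

Subjective "does this look transparent?" judgments are contaminated by each
observer's response criterion. The objective alternative implemented here is a
**3AFC oddity task**: two intervals contain the *standard* RDK, whose dot
speeds (or directions) are drawn per positional update from a uniform discrete
distribution; one interval, in a random position, contains the *comparison*,
whose dots come from two distributions separated by an empty interval — a
speed **notch** or a directional **gap** of width *W*. The observer reports
the odd interval; chance is 1/3. Because standard and comparison are matched
on their outer range [v_lo, v_hi], their span, and their global arithmetic
mean E[v], the only usable cue is the internal structure of the velocity
distribution — i.e. the notch assumed to drive transparency.

The constructions enforce the matching constraints exactly:

- speed-notch family: uniform standard on [0.4, 23.6] deg/s (E = 12 deg/s),
  comparisons with centered notches W ∈ {1, 4, 7, 10, 13, 16, 19} deg/s, all
  with E = 12 deg/s;
- mean-distance family: two 8.1 deg/s bands around a fixed 7 deg/s notch,
  per-band weights w_i ∝ exp(λ x_i) (maximum-entropy exponential tilting)
  steering the band means to E ∓ Δ/2 for Δ ∈ {13…17} deg/s;
- slow/fast families on [1.2, 8] and [17.2, 24] deg/s (E = 4.6 and
  20.6 deg/s) with varying notch but constant distance between band means;
- direction family: 58°-spanning uniform directions about 30°, gaps
  2°–50°, at fixed dot speeds 4, 13, 22 deg/s.

Dot speeds are resampled **per dot per update**, so tracking a single dot
reveals nothing about the extremes of the distribution. A single-interval
displacement-limit task (D_max) with everything moving left or right by the
same amount per update, and Weibull/logistic psychometric fitting with the
guess rate fixed by the task (γ = 1/3 or 1/2), complete the pipeline.

## Worked example

```python
import notchrdk as nr

std = nr.build_uniform(0.4, 23.6, 1.0)
cmp19 = nr.build_symmetric_notched(0.4, 23.6, 19.0, 1.0)
nr.moments(cmp19)
# DistributionStats(global_mean=12.0, span=23.2,
#                   band_means=(1.4, 22.6), mean_distance=21.2, notch_width=19.0)
nr.validate_matched(std, cmp19).passed   # True

log = nr.run_session(nr.make_conditions(1),
                     nr.SpeedGapObserver(noise_fraction=0.10),
                     n_trials_per_condition=400, seed=7)
nr.summarize(log)
#  condition_param  n_trials  proportion_correct    error
#              1.0       400              0.3475 0.023809
#              4.0       400              0.3200 0.023324
#              7.0       400              0.4175 0.024657
#             10.0       400              0.9500 0.010897
#             13.0       400              0.9925 0.004314
#             16.0       400              1.0000 0.000000
#             19.0       400              1.0000 0.000000
```

The noisy gap-statistic observer is near chance (0.33) for the narrowest
notches — a 1 deg/s notch removes no grid point from the 1 deg/s-sampled
standard, so the comparison is literally identical — and climbs to perfect
discrimination as the notch widens, the qualitative signature of
notch-driven transparency discrimination. `error` is the per-condition
binomial standard error.

Displacement-limit threshold recovery:

```python
dlog = nr.run_dmax_session(observer=nr.DmaxObserver(100.0),
                           n_trials_per_level=280, seed=7)
t = nr.summarize(dlog)
fit = nr.fit_psychometric(t.condition_param, t.n_trials, t.n_correct,
                          family="logistic", guess=0.5, criterion=0.75)
fit.threshold   # 95.1 arc min, within 5% of the simulated 100 arc min limit
```

A displacement of 100 arc min per update at 18.75 Hz corresponds to a dot
speed of 31.25 deg/s (`nr.speed_to_displacement(31.25, 18.75) * 60 == 100`);
all stimulus speeds stay below this limit.

The same pipeline is scriptable from a shell: `notchrdk build-dist`,
`gen-stimulus`, `simulate`, `analyze`, `fixtures` (see `notchrdk --help`);
every subcommand takes `--seed` and records it in a metadata sidecar.

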