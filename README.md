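# dynexpect

Trial-by-trial modelling of pain expectations for cued-pain experiments.

In probabilistic cueing paradigms, two visual cues predict low- or
high-intensity noxious stimulation (LP/HP) with 75% contingency, and
participants rate each stimulus on a 0–100 numerical rating scale (NRS).
Most analyses treat expectation as the static cue label.  `dynexpect`
instead models expectations as *dynamic* quantities that evolve with recent
experience, and provides the full analysis stack around that model: model
validation against alternative learning rules, Bayesian mixed-model
inference, mass-univariate electrode mapping, multilevel mediation, and EEG
feature extraction — all exercisable end-to-end on a synthetic paradigm
generator with planted ground-truth effects, so no recordings are needed to
test any stage.

## The model

For each cue, expectation **strength** at trial *t* is a recency-weighted
mean of past pain ratings after the same cue,

```
E_t = Σ_k w_k P_{t−k} / Σ_k w_k ,      w_k = exp(−k/ω),   k = 1 … t−1
```

with memory decay constant ω = 8 trials.  Expectation **precision** is the
inverse of the recency-weighted variance of past strength estimates
(`Var_t`, the weighted mean squared deviation around the weighted mean of
past `E` values); a fourth-root transform tames the skew of the raw
variance before inversion, and both quantities are min–max normalised to
[0, 1].  The first same-cue trial has no defined strength (and the second
no defined precision); those trials are excluded from inference.

Downstream, ratings and trial-wise neural features are analysed with
random-intercept linear mixed models,

```
outcome ~ Stimulus intensity + Strength × Precision + (1 | Participant)
```

summarised by the posterior mean (*Est*), 95% highest-posterior-density
interval and the posterior probability of the dominant sign (*Pp*); an
effect is called compelling when the HPD excludes 0 and *Pp* > 97.5%.
Competing accounts of expectation formation (Rescorla–Wagner delta rule,
scalar Kalman filter, static per-cue constants) are fitted per participant
by maximum likelihood and compared with random-effects Bayesian model
selection (Dirichlet variational update, exceedance probabilities).
Mediation of expectation effects through anticipatory oscillations is
estimated with participant-level path models and a participant bootstrap.

## Worked example

Run the full synthetic study (12 participants, 4 runs × 40 trials, planted
effect sizes) from Python:

```python
from dynexpect import pipeline
metrics = pipeline.run_study(pipeline.RunConfig(master_seed=5), "out")
```

or from the shell: `dynexpect run --seed 5 --out out`.  With master seed 5
this prints (abridged):

```
validation_r:              {'HE': 0.999, 'LE': 0.999}
log_bf_dynamic_vs_static:  570.8
exceedance:                {'leaky': 0.9996, 'rw': 0.0001, 'kalman': 0.0001, 'static': 0.0001}
effects:
  intensity                Est = 17.79, 95% HPD = [16.86, 18.79], Pp = 1.00
  E_strength               Est = 14.04, 95% HPD = [ 8.37, 20.31], Pp = 1.00
  E_precision              Est =  1.73, 95% HPD = [−8.95, 11.76], Pp = 0.62
mediation:
  strength  → alpha → LEP  indirect = +0.197, p = 0.104
  precision → alpha → LEP  indirect = −0.287, p = 0.018
```

Reading: the synthetic cohort's expectation reports are far better explained
by the dynamic strength estimate than by the static cue label (log evidence
ratio ≈ 571; exceedance probability ≈ 1 for the leaky integrator among four
learning rules); stimulus intensity and expectation strength both raise
pain ratings (the strength slope is on the min–max-normalised [0, 1] scale,
so it is not numerically equal to the latent generative slope); and the two
planted mediation paths come out with opposite signs, positive through the
strength mediator and negative through the precision mediator.  At this
smoke-test cohort size the precision fixed effect and the strength
mediation are underpowered — the test suite demonstrates their recovery at
the study's full scale (72 and 40 participants respectively).

## Command-line interface

`simulate`, `expect`, `fit-models`, `compare-models`, `fit-lmm`, `power`,
`mediate`, `features`, and `run` — each a thin wrapper over one library
function; see `dynexpect <cmd> --help`.

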