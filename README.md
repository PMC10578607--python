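# glyphcurate

Tools for asking whether *which exemplars you learn from* matters:
score category exemplars by how quickly people respond to them,
curate small "good" (fast, typical) and "bad" (slow, atypical)
training sets, train ensembles of a small convolutional classifier on
them, and quantify how well the networks' output-entropy confidence
accounts for per-exemplar reaction times and fitted drift rates.

The package is aimed at computational cognitive scientists studying
exemplar quality, dataset curation at very small sample sizes, and
the correspondence between network confidence and human response
dynamics.  Because behavioral datasets of this kind are rarely
deposited, the package ships a first-class synthetic-data module —
parametric glyph stimuli with graded typicality and diffusion-model
participants — so the entire chain is runnable and testable end to
end.

## The models in brief

**Stimuli.**  Binary glyphs from letter-like prototypes sharing a
stem (P/R/B/D style).  Each instance gets handwriting-like nuisance
jitter plus a deformation of `d` flipped pixels directed toward a
confusor class; typicality is `tau = exp(-d / sigma_tau)`.

**Participants.**  Two-boundary drift diffusion (start `z = a/2`,
noise `s = 0.1`, Euler step 1 ms): only the drift depends on the
stimulus, `v = beta * tau`, with boundary `a`, non-decision time
`Ter` and lapse rate per participant.  Accuracy follows the
closed form `P(correct) = 1 / (1 + exp(-a v / s^2))`.

**Exemplar scoring.**  Per participant, per-instance mean RTs are
midranked within class; each instance's ranks are compared with
pooled same-class ranks by a two-sided Welch t-test.  The good/bad
sets are the k most significantly fast/slow instances per class
(k = 5), with a never-answered-correctly exclusion on the good side.

**Networks.**  conv(6@5x5) - pool - conv(16@5x5) - pool - dense(128)
- dense(64) - softmax, 50% dropout on all but the output layer,
He/Glorot init, Adam (alpha 0.005), 64 epochs, batch 64 — implemented
in NumPy, bitwise reproducible under a seed.  Confidence of a
prediction is the entropy `H = -sum p_k ln p_k` of the softmax
output.

**Statistics.**  RTs and entropies are normalized per unit (each
participant's / network's values sum to 1 over the items), then
compared with Spearman's rho; sets of correlations are compared via
Fisher-z + Welch; per-exemplar drift rates come from the EZ-diffusion
closed form with a shared boundary and non-decision time.

## Worked example

```python
import numpy as np
import glyphcurate as gc

protos = gc.default_prototypes(4)                       # P/R/B/D-like glyphs
inst = gc.generate_instances(protos, 20, 11.0, seed=1,  # 80 stimuli
                             sigma_tau=7.5)
recs = gc.simulate_cohort(50, gc.CohortParams(), inst, repeats=2, seed=3)

kept = gc.filter_participants(recs, 0.75)
ranks = gc.rank_within_class(recs, kept)
print(f"retained {len(kept)}/50 participants")
res = gc.accuracy_rt_correlation(recs, ranks)
print(f"accuracy vs RT-rank: rho = {res.rho:.3f}, p = {res.p_value:.2e}")

scores = gc.score_instances(ranks, recs)
good = gc.curate_extreme(scores, 5, "good")
bad = gc.curate_extreme(scores, 5, "bad")
tau = {i.instance_id: i.typicality for i in inst}
print(f"mean typicality: good {np.mean([tau[i] for i in good.all_ids()]):.3f}, "
      f"bad {np.mean([tau[i] for i in bad.all_ids()]):.3f}")
```

Output:

```
retained 49/50 participants
accuracy vs RT-rank: rho = -0.867, p = 2.82e-25
mean typicality: good 0.612, bad 0.091
```

Participants respond faster to instances they classify correctly
(strongly negative rank correlation), and the reaction-time-curated
good set recovers genuinely typical exemplars (high `tau`) while the
bad set collects malformed ones — without the analysis ever seeing
the generator's ground truth.

The full replication — ensembles on good/bad/random/full augmented
sets, confidence–RT correlation reports, drift fits, and the
trained-cohort 2x2 grid — runs from one config:

```bash
glyphcurate all --seed 1 --out runs/demo        # library: gc.run_all(config)
```

Subcommands `simulate`, `analyze-rt`, `curate`, `augment`, `ddm`,
`exp1`, `exp3` expose the individual stages; see `docs/methods.md`
for the models, defaults and their rationale.

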