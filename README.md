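# mobisias

Passive GPS mobility phenotyping for social anxiety: a pipeline that turns
raw phone location traces into semantic mobility features and predicts
Social Interaction Anxiety Scale (SIAS) scores from them.

Social anxiety is usually assessed by self-report in a clinic. Continuously
and passively collected location data offer an ecologically valid
complement: where students spend time (home, leisure venues, supermarkets),
when they go there, how diverse their mobility is, and how they move
between place types all carry signal about social avoidance. `mobisias`
implements the full chain for a two-week campus study design:

1. **Stay-point clustering** — a streaming time-based algorithm groups GPS
   fixes into *significant places*: a cluster absorbs fixes within
   d = 60 m of its centroid, a pending-location rule discards lone
   outliers, and clusters spanning more than t = 600 s become stays.
2. **Semantic labeling** — stays map to a 10-class vocabulary (Home, Other
   houses, Education, Leisure, Food, Supermarket, Religious, Service, Out
   of town, Transition) via a pluggable place map; Home is the house where
   a participant spends the most time between 10 pm and 9 am. Sampling
   gaps are merged, labeled Transition, or removed by duration regime.
3. **Mobility features** — per day: staying-time fractions per class and
   epoch (8 am–4 pm, 4 pm–12 am, 12 am–8 am), visit-occupancy bins,
   Shannon location entropy H = −Σ pᵢ ln pᵢ over class time shares,
   unidirectional transition counts, and calendar flags (204 features).
4. **Association analysis** — Pearson correlations of features with SIAS,
   Welch t-tests for high (SIAS ≥ 34) vs low groups, and filtered
   transition-correlation tables.
5. **Hierarchical prediction** — an MLP (2×100 tanh units) predicts a
   candidate SIAS score for every day; a 7% trimmed mean (regression) or
   majority vote (classification) aggregates candidates per participant.
   Aggregated baselines BM1 (study-period feature means) and BM2
   (concatenated days + PCA) share the architecture. Evaluation uses
   leave-one-participant-out or balanced 10-fold cross-validation.

Because no real cohort is distributed, the package includes a first-class
**synthetic cohort generator**: a campus place map, SIAS-conditioned weekly
routine templates whose expected dwell times shift with the latent score
(more evening home time, less evening/weekend leisure, more supermarket
time, narrower mobility repertoires, rigid routines at high SIAS), GPS
jitter, and realistic sampling gaps — with full ground truth for testing
every stage. See `docs/methods.md` for the model details.

## Worked example

```python
from mobisias.synth import CohortConfig, generate_cohort
from mobisias.pipeline import process_bundle
from mobisias import association, prediction

bundle = generate_cohort(CohortConfig(n_participants=60, n_days=14), seed=1)
proc = process_bundle(bundle)          # cluster -> label -> features

rec = association.entropy_correlation(proc.table, proc.sias, "weekday")
print(f"entropy vs SIAS (weekdays): r={rec['r']:.2f}, p={rec['p']:.3g}")

rep = prediction.evaluate(proc.table.features, proc.sias,
                          method="om", task="regression",
                          scheme="fcv10", seed=1)
print(rep.summary())
```

Output from this exact snippet:

```
entropy vs SIAS (weekdays): r=-0.28, p=0.0295
SIAS regression evaluation (OM, fcv10)
================================================
folds: 10
RMSE: 5.46 (SD 1.80)
```

The negative entropy correlation says higher-anxiety participants visit a
narrower range of place types on weekdays; the cross-validated RMSE of
about 5.5 points on the 0–80 SIAS scale is the error of the per-day
neural-network predictor after aggregating each held-out participant's
daily candidate scores.

The same stages are scriptable from the shell:

```bash
mobisias run --n 20 --days 7 --seed 0 --out artifacts/
mobisias predict --n 60 --days 7 --seed 0 --method om --task classification
```

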