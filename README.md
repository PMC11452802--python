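# ticscreen

Video-based screening for Gilles de la Tourette syndrome (GTS), from
per-second tic probabilities onward. An upstream video detector (out of
scope here) emits one tic probability per 1-second interval of a ~150-second
standardized video. `ticscreen` implements everything downstream of that
signal, for researchers evaluating automated tic diagnostics:

1. **Tic summary scores** — each video's probability trace is binarized at
   0.5 ("tic interval" iff p ≥ 0.5) and summarized into five scores:
   proportion of tic intervals (%), mean tic probability, maximal tic
   segment (s), maximal tic-free segment (s), and tic clusters per minute
   (a cluster is a maximal run of ≥ 3 consecutive tic intervals).
2. **Matched-pair classification** — logistic regression of group (GTS vs
   matched healthy control, HC) on the scores, evaluated by leave-pair-out
   cross-validation: a video's prediction comes from a model trained with
   all videos of that participant *and* their individually matched partner
   held out. Performance: balanced accuracy ½(sensitivity + specificity)
   and AUROC (Mann–Whitney P(score_GTS > score_HC), ties ½).
3. **Hybrid human/machine decisions** — predictions with confidence
   max(p, 1−p) > 0.9 are accepted automatically; the rest are routed to an
   expert reviewer (simulated, 95% accurate by default). Reported: subgroup
   accuracies, review burden, and the combined accuracy
   (n_high·acc_high + n_low·acc_expert)/(n_high + n_low).
4. **Synthetic cohorts** — real tic videos cannot be shared, so a generator
   produces matched GTS/HC cohorts of per-second probability traces: a
   hidden two-state Markov chain (quiescent/tic) per second with
   Beta-distributed emissions and per-participant rate jitter, reproducing
   the temporal clustering of tics and "few tics / many tics" heterogeneity.

## Worked example

```python
import ticscreen as ts

cohort = ts.generate_cohort(ts.SimulationConfig(seed=1))   # 42 matched pairs
tab = ts.scores_table(cohort.videos)
preds = ts.leave_pair_out_cv(cohort.manifest(), tab, ["clusters_per_minute"])
print(f"AUROC {ts.roc_auroc(preds).auroc:.3f}")
print(f"balanced accuracy {ts.balanced_accuracy(preds):.1f}%")
report = ts.run_hybrid(preds, confidence_threshold=0.9, expert_accuracy=95.0, seed=1)
print(f"review fraction {report.review_fraction:.1f}%")
print(f"combined accuracy {report.combined_accuracy:.2f}%")
```

prints

```
AUROC 0.945
balanced accuracy 93.8%
review fraction 7.7%
combined accuracy 97.04%
```

i.e. on this 194-video synthetic cohort the tic-clusters-per-minute score
separates the groups almost perfectly (AUROC 0.945), and accepting
high-confidence automated calls while referring the 7.7% low-confidence
videos to a 95%-accurate expert yields a 97% overall accuracy.

The same pipeline runs from a shell:

```sh
ticscreen run-all --seed 1 --out-dir run/
ticscreen simulate --seed 1 --out-dir cohort/        # or stage by stage
ticscreen score --probabilities cohort/probabilities.csv \
    --manifest cohort/manifest.csv --out scores.csv
ticscreen classify --scores scores.csv --manifest cohort/manifest.csv \
    --predictors clusters_per_minute --out preds.csv
ticscreen hybrid --predictions preds.csv --out report.json
```

Exchange formats are plain CSV (a long table `video_id, second_index,
probability[, hidden_state]` plus a cohort manifest), so any upstream
detector can feed the pipeline.

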