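"""Diagnostic evaluation: metrics with Wilson intervals, ROC/AUC, size
stratification, and reconstruction of a confusion matrix from printed
percentages.
"""
import numpy as np

from euslite import evaluate as ev

# metrics from a confusion matrix (GIST = positive class)
c = ev.ConfusionSummary(tp=62, fp=2, tn=41, fn=4)
m = ev.metrics_from_confusion(c)
print("confusion (tp, fp, tn, fn):", (c.tp, c.fp, c.tn, c.fn))
for name, val in m.as_percent_dict().items():
    if val is None:
        print(f"  {name:12s} undefined")
    elif m.ci and name in m.ci:
        lo, hi = m.ci[name]
        print(f"  {name:12s} {val:6.1f}%   Wilson 95% CI [{100*lo:.1f}, {100*hi:.1f}]")
    else:
        print(f"  {name:12s} {val:6.1f}%")

# invert printed percentages back to integer counts: with 66 GIST and 43
# leiomyoma test images, four metrics pin down a unique (tp, tn)
printed = {"sensitivity": 93.9, "accuracy": 94.5, "ppv": 96.9, "npv": 91.1}
cands, report = ev.reconstruct_confusion(printed, n_pos=66, n_neg=43)
print("\nreconstruction from printed percentages:",
      [(x.tp, x.tn) for x in cands])
print("adding specificity 95.4 ->",
      ev.reconstruct_confusion({**printed, "specificity": 95.4}, 66, 43)[1])
# 41/43 = 95.35% rounds to 95.3, so a printed 95.4 is reported as a
# near-miss rather than silently accepted.

# ROC/AUC equals the rank statistic
rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 200)
scores = np.clip(labels * 0.5 + rng.normal(0.3, 0.25, 200), 0, 1)
roc = ev.roc_auc(scores, labels)
print(f"\nROC on 200 noisy scores: AUC {roc.auc:.3f}")

# 20-mm size stratification, model vs a synthetic always-positive reader
sizes = rng.uniform(4, 35, 200)
strat = ev.stratified_compare(labels, sizes, model_predictions=(scores > 0.5),
                              reader_predictions=np.ones(200, int))
for stratum, readers in strat.strata.items():
    msens = readers["model"].sensitivity
    rspec = readers["endoscopist"].specificity
    print(f"  {stratum} (n={strat.counts[stratum]}): model sensitivity "
          f"{msens:.2f}, always-positive reader specificity {rspec:.2f}")
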