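"""Simulate a multi-omics case/control cohort with planted biomarkers.

Draws 300 samples (2:1 cases:controls) across five assay types, plants 10
shared (disease-level) and 3-per-symptom specific biomarkers, and prints what
was planted where.  The GroundTruth ledger is the oracle used by every
recovery experiment.
"""

import symptomap as sm

cfg = sm.SimConfig(n_samples=300, effect_size=2.0, noise_sd=0.5, seed=1)
omics, scores, labels, truth = sm.simulate_cohort(cfg)

print(f"cohort: {cfg.n_samples} samples, {int(labels.sum())} cases / "
      f"{int((1 - labels).sum())} controls")
for kind, X in omics.items():
    print(f"  {kind:<11} {X.n_features:>4} features "
          f"(row sums to 1: {kind == 'species'})")
print(f"scores: {scores.data.shape[1]} outputs "
      f"({[s.dtype for s in scores.schema.outputs].count('continuous')} continuous, "
      f"1 categorical, 1 binary)")
print(f"planted biomarkers: {len(truth.shared_features)} shared across all symptoms, "
      f"{sum(1 for p in truth.planted if not p.shared)} symptom-specific")
print("first three planted effects:")
for p in truth.planted[:3]:
    targets = "ALL outputs" if p.shared else p.targets[0]
    print(f"  {p.feature} ({p.kind}) -> {targets}: {p.shape}, "
          f"sign {p.sign:+d}, strength x{p.multiplier}")
# Each planted feature is the hub of its own co-abundance module; the module
# assignment is what the eigengene-network example consumes.
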