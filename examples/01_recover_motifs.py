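"""Recover planted response motifs from a synthetic stimulation session.

Generates the three-motif study conditions (24 stimulation-pair subgroups,
10-12 trials each, three shared response motifs plus six pure-noise
subgroups), runs the full pipeline, and compares the recovered basis
profile curves with the planted ground truth.
"""

import numpy as np

from bpcurve import PipelineConfig, generate, run_pipeline, scenario

trials, events, truth = generate(scenario("three_motifs", seed=7))
print(f"{trials.n_trials} trials, {trials.subgroups.size} subgroups, "
      f"{trials.n_samples} samples per trial at {trials.fs:.0f} Hz")

result = run_pipeline(trials, PipelineConfig(seed=7))

print(f"\nrecovered {result.bpcs.n_curves} basis profile curves "
      f"(final inner dimension Q={result.factorization.q}, "
      f"zeta={result.factorization.zeta:.3f})")
print(f"excluded subgroups: {[str(s) for s in result.assignment.excluded]}")

for q in range(result.bpcs.n_curves):
    corrs = [abs(np.corrcoef(result.bpcs.curves[:, q], truth.motifs[:, j])[0, 1])
             for j in range(truth.motifs.shape[1])]
    j = int(np.argmax(corrs))
    members = result.bpcs.cluster_members[q]
    print(f"curve B{q + 1}: |corr| with true motif {j} = {corrs[j]:.4f}, "
          f"{len(members)} subgroups, {result.bpcs.trial_counts[q]} trials")

inc = result.params.included
print(f"\nmean trial explained variance (included trials): "
      f"{result.params.explained_variance[inc].mean():.3f}")
print("-> each curve is the canonical temporal shape its cluster's trials "
      "share; |corr| near 1 means the planted motif was recovered, and the "
      "pure-noise subgroups land in the excluded list.")
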