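"""Explained variance as a function of the forced inner dimension Q.

With three planted motifs, the pooled explained variance of the fitted
curves rises until Q reaches the true number of motifs and then plateaus —
independent confirmation of the dimension the degeneracy pruning selects on
its own.  Two normalizations are reported: by the energy of all trials
(ev_total) and by the energy of the trials actually included in the
clustering (ev_included); the latter is immune to dilution by stimulation
sites that evoke nothing.
"""

from bpcurve import GeneratorConfig, explained_variance_vs_Q, generate

cfg = GeneratorConfig(
    n_subgroups=9,
    motif_assignment=[0, 0, 0, 1, 1, 1, 2, 2, 2],
    n_motifs=3,
    trials_per_subgroup=(10, 12),
    fs=512.0,  # shorter trials keep this demo quick; structure is unchanged
    seed=6,
)
trials, _, _ = generate(cfg)
df = explained_variance_vs_Q(trials, [1, 2, 3, 4, 5], restarts=10, seed=1)
print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("-> ev_total rises until Q = 3 (the true motif count) and then "
      "plateaus: below Q = 3 whole motif families are left out of the "
      "clustering. ev_included can stay high at small Q when the included "
      "clusters are pure, but drops whenever a cluster mixes motifs.")
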