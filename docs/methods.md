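# Methods

This note documents the model, the numerical choices, and what the
synthetic study conditions do and do not establish.

## Model and assumptions

The framework treats the voltage response at one measurement electrode as a
library of a few canonical temporal motifs. Trials are grouped a priori by
stimulation pair (subgroup `n`), and the method assumes:

- responses within a subgroup are repetitions of one motif with varying
  scalar amplitude plus zero-mean noise (`E(ε) = 0`, comparable noise
  energy across trials);
- a motif contributes with one sign only — a sign-flipped shape reflects
  different laminar physiology and must form its own cluster, which is why
  the factorization is non-negative and why projections, not correlations,
  drive the similarity measure;
- each subgroup expresses at most one motif (winner-take-all assignment;
  superposition of motifs within a trial is out of scope);
- trials within a subgroup are approximately independent (adaptation to
  repeated stimulation violates this mildly; the significance matrix
  tolerates and even reveals it — see below).

No temporal shape (N1/N2 or otherwise), latency, or smoothness is assumed.

## Stages and tunable parameters

**Epoching.** Window `[t1, t2] = [0.050, 2.000]` s relative to each pulse:
starting after stimulation artifact and volume-conducted transients,
ending when responses have returned to baseline. Event times are snapped
to the nearest sample; the window covers samples `ceil(t1·fs)` through
`floor(t2·fs)` inclusive (T = 3994 at 2048 Hz), identical by count for all
trials, no interpolation or filtering. Trials whose window leaves the
recording are dropped with a warning.

**Significance matrix.** Per-set t-value = mean / (sd/√count) with the
sample standard deviation (count − 1). The dispersion convention is not
forced by the math; the conventional sample-sd reading is used, and the
choice only rescales cells slightly at the set sizes involved (~100
elements). Zero-variance sets get a finite sentinel t (1e6·sign(mean)) to
keep the pipeline total on degenerate synthetic input; sets with fewer
than two elements (single-trial subgroups) score 0 with a warning. If
every cell clips to zero, the method reports "no reliable structure"
rather than factorizing an all-zero matrix.

**Factorization.** Multiplicative updates in the order: H-update,
H-row-normalization (scale moved into W's columns; product unchanged),
W-update. Denominators carry an epsilon floor of 1e−12 against 0/0.
Convergence when Δη/η < 1e−5 (`tol`), cap 10 000 iterations, 20 restarts
from uniform [0, 1) initial factors, best (lowest-η) restart kept. All
restarts draw from independent streams spawned from one user seed, so runs
are bit-reproducible. Defaults `q_start = min(N, 10)` (the number of
distinct laminar input motifs at one site is plausibly small, and starting
near it is cheaper than starting at N), `ζ` threshold 0.5. An alternative
global-overlap degeneracy (sum rather than max of upper-off-diagonal
`HH⊤`) is available via `degeneracy_metric="sum"`.

**Clustering.** Winner-take-all ties break to the lowest row index
(deterministic output). Surviving weight must exceed `1/(2N)`: half of the
weight each subgroup would carry if all contributed equally. Empty
clusters are dropped and the rest renumbered by descending total assigned
weight — the ordering is otherwise arbitrary, and descending weight is
stable and interpretable.

**Curve extraction.** The Gram matrix is symmetrized before
eigendecomposition and eigenvalues clipped at zero (numerical hygiene).
Trials are *not* mean-centered: centering would break the identity
`α_k = Σ_t B_q(t)V_k(t)`. Eigenvector sign is fixed so the mean projection
of member trials onto the curve is positive, matching the non-negative
contribution semantics; a tie (exactly zero mean projection) keeps the
positive orientation. The mapping from Gram eigenvectors back to curve
space is `X = V_(q)F` with the leading column normalized — dimensional
analysis admits no transpose on `F`.

**Back-projection.** Signal-to-noise `α/ε⊤ε` is capped at ±1e12 (with a
flag) when the residual energy is zero to machine precision, keeping
tabular output finite. α is reported as-is, including negative values for
individual trials; significance of a subgroup's αs against zero is
reported with both one- and two-sided p-values. Residual structure is
reported both raw (`⟨ε_k⊤ε_l⟩`, the canonical form) and as a normalized
correlation, since the raw inner product scales with noise energy.

## The synthetic study conditions

The generator emulates the convergent-session structure: N subgroups of
10–12 trials, 2048 Hz, 0.050–2.000 s windows, a small library of smooth
unit-norm motifs (damped oscillations and biexponential deflections,
cosine-tapered to zero at the window edges, pairwise |corr| < 0.5) shared
across blocks of adjacent stimulation pairs, pure-noise subgroups, white
Gaussian noise (default σ = 5 µV per sample) plus a 1/f-shaded component
(default 0.5·σ), and optional per-repeat amplitude drift.

**Amplitude scale.** Subgroup amplitudes are set through a *trial-level*
signal-to-noise ratio: amplitude = SNR · σ_eff · √T, i.e. the ratio of the
trial's signal norm to the expected noise norm. This is the natural SNR
for functional data — it is what determines whether the signal eigenvalue
of a trial block stands above the Marchenko–Pastur noise floor, and at the
default SNR = 5 it corresponds to a clearly expressed evoked potential
(per-trial explained variance ≈ 0.96). A per-sample amplitude/σ reading of
the same number would bury the signal eigenvalue far below the noise floor
at T ≈ 4000 and describes no usable CCEP.

**Adaptation scenario.** Two equal-size (11-trial) subgroups share one
motif with drift 0.06/repeat (the 11th response is 40% of the first), at
trial SNR 8. The off-diagonal-exceeds-diagonal signature then follows
deterministically, for two reasons: the cross sets have |n||m| = 121
elements versus |n|(|n|−1) = 110 for the self sets (smaller standard
error at essentially equal mean and spread), and the omitted `k = l` pairs
are exactly those in which the normalized trial's cosine and the raw
trial's amplitude are maximally positively correlated, so their removal
lowers the self-set mean. Both effects push the same way, and the
amplitude pattern is deterministic, so the signature is stable across
seeds.

**What passing does and does not show.** The generator's trials are exact
scalar multiples of a fixed motif plus stationary noise. Real CCEPs add
latency jitter, shape variability within subgroup, stimulation-artifact
residue, line noise, non-stationary background, and overlapping motifs;
none of these are modeled (artifact simulation inside the analysis window
is explicitly out of scope). Recovery at SNR 5 therefore demonstrates the
correctness of the algebra and the clustering logic under the model's own
assumptions — not robustness to every pathology of clinical recordings.
Conversely the null (all-noise) conditions show the honest failure mode:
the pipeline still fits *something* (the 1/f component is itself smooth,
so a fitted curve explains ~8% of pure-noise energy, not ~1/T), and
meaninglessness shows up as near-zero significance cells, instability
under data splitting, and low explained variance — not as an automatic
refusal to produce output.

## Problem sizes used in the checks

The per-stage tests run on small matrices (tens of timepoints, ≤ 12
trials) against brute-force oracles. End-to-end recovery runs the full
2048 Hz, 24-subgroup conditions over 10 seeds; the split-half and
adaptation checks run their scenarios at full scale; structural tests that
only exercise plumbing use a reduced 256–512 Hz variant of the same
family, chosen so the whole suite stays comfortably interactive.

## Known limitations

- Winner-take-all cannot represent superimposed motifs; data generated by
  genuine superposition will be forced into single-motif clusters.
- The NNMF restart strategy finds a reliable minimum in practice but
  carries no global-optimality guarantee; pathological Ξ matrices may need
  more restarts.
- Subgroups with a single trial cannot enter the significance matrix
  (no dispersion estimate) and are effectively excluded upstream.
- The number of discovered curves depends on the ζ threshold; 0.5 is the
  default operating point, and lowering it splits clusters sharing limited
  transient structure.
- Epoching assumes a clean, uniformly sampled, preprocessed trace;
  artifact rejection, re-referencing and filtering are the caller's
  responsibility.
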