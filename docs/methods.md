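# Methods

`tdprisk` implements an in-silico proarrhythmia (torsade-de-pointes, TdP)
risk pipeline: channel-block pharmacology is propagated through a paced
human ventricular myocyte model into action-potential (AP) shapes, and a
small 1D convolutional network classifies those shapes into three TdP-risk
classes (high / intermediate / low). This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Dose-response model and uncertainty

Each drug-channel pair is summarized by the Hill equation for the blocked
fraction of current at free drug concentration D (µM):

    block(D) = 1 / (1 + (IC50 / D)^h)

with IC50 the half-blocking concentration and h the Hill coefficient,
fit by least squares over (log10 IC50, h), h constrained to (0, 10],
from replicate patch-clamp block fractions at several concentrations.
Fitting in log10 IC50 makes the optimization scale-invariant; three
starting points (below, inside, above the measured concentration range)
guard against local minima, with ties broken by residual then by smaller h.
A pair whose block is zero at every concentration is encoded with the
sentinel IC50 = +∞ ("no block"), which downstream code maps to a neutral
conductance scale.

Experimental uncertainty is quantified by a nonparametric bootstrap:
replicates are resampled with replacement within each concentration and
refit until B fits (default B = 2000 per drug-channel pair) are accepted;
fits whose log10 IC50 lies outside the central 95% interval of the accepted
set are replaced by redraws from the retained fits, so exactly B samples
remain and all lie inside the central envelope. When every concentration
has a single replicate, a residual bootstrap (resampling fit residuals) is
used instead and a warning is logged. A Markov-chain Monte Carlo posterior
sampler over the same likelihood is a natural extension point; the
bootstrap was chosen because it is assumption-light and reproduces the
intended outcome — a seeded set of B plausible (IC50, h) pairs trimmed to
a 95% envelope. Resampling identical replicates cannot change the fit, so
noise-free inputs short-circuit to B copies of the point fit.

The conductance multiplier applied to the cell model is the *unblocked*
fraction, s(D) = 1 − block(D) = 1 / (1 + (D/IC50)^h). Writing the scaled
current as s·G_ion·m_ion(V − E_ion) guarantees the drug-free limit
(D → 0 ⇒ s → 1) reduces to the unmodified model; both conventions agree at
D = IC50 (s = 0.5).

## Cell model and pacing protocol

The myocyte is the O'Hara-Rudy dynamic human ventricular model (41 state
variables: membrane potential, Hodgkin-Huxley and Markov-style gates,
eight ionic concentrations, CaMK signalling) with the CiPA conductance
re-optimization multiplying five repolarization-critical currents
(IKr ×1.013, IKs ×1.870, IK1 ×1.698, ICaL ×1.007, INaL ×2.661). Those
multipliers and the baseline conductances live in a versioned YAML file
(`tdprisk/data/ord_conductances.yaml`), not in code. Static drug block
scales the seven assayed currents (INa, INaL, ICaL, IKr, IKs, IK1, Ito);
drug concentrations are taken at 1-4× the peak serum concentration Cmax.

Protocol defaults (all configurable on `CellModelConfig`):

| parameter | default | meaning |
|---|---|---|
| cell type | endo | endocardial variant (epi and M supported) |
| cycle length | 2000 ms | bradycardia pacing (30 bpm), the TdP-prone regime |
| stimulus | −80 µA/µF for 0.5 ms | applied at each cycle start |
| dt | 0.1 ms | base integration step |
| recording dt | 2 ms | 1000 samples per beat |
| beats per run | 1000 | full protocol; reduced runs continue from steady state |

The stimulus amplitude/duration and the endocardial cell type are this
package's defaults where the protocol is otherwise silent; they are the
conventional choices for this model family.

**Integration.** Fixed-step forward Euler for membrane potential,
concentrations and the CaMK trap, with the Rush-Larsen exponential update
for all gating variables (unconditionally stable for the stiff gates).
The sodium upstroke (~1 ms) is the one phase faster than the 0.1 ms base
step, so the first 10 ms of every cycle are integrated with 10 substeps
per base step (effective 0.01 ms). With this refinement, halving dt from
0.1 to 0.05 ms moves drug-free APD90 by ≈0.25 ms (< 1 ms), and the peak
overshoot is converged; without it the peak alone differs by several mV.
Singular exchanger/pump voltage factors at V → 0 use a series guard.

**Initialization.** All drug runs start from the drug-free steady state
reached after 10,000 paced beats from the published initial conditions.
That state ships as a JSON fixture (41 named floats plus a model-version
tag) and can be regenerated with `tdprisk steady-state`; the final
per-beat state-change norm of the shipped fixture is ~2×10⁻⁴. Starting
drug runs from this state means drug effects on AP shape stabilize within
a few beats, which is what makes reduced-beat test runs (20 beats instead
of 1000) representative of the full protocol.

## AP biomarkers and beat selection

Within one recorded beat: resting potential is the first sample
(pre-stimulus at this cycle length), the activation time is the sample of
maximum dV/dt before the peak, and APD at level x is the time from
activation to the first crossing of V_thr = peak − x·(peak − rest) after
the peak, linearly interpolated between the 2 ms samples (the grid is
coarse relative to the repolarization slope). A beat that never crosses
the threshold returns the trace duration with a did-not-repolarize flag —
expected for extreme IKr block.

The repolarization window for slope and EAD metrics starts 50 ms after
the peak — the phase-1 notch of this model can produce a brief positive
dV/dt that is not an early afterdepolarization — and ends at the APD90
crossing (or trace end). An EAD is flagged when dV/dt exceeds +0.01 mV/ms
for at least two consecutive samples in the window; both constants are
module-level and configurable. Under selective IKr scaling the model
reproduces the expected phenomenology: APD90 grows monotonically as the
scale drops (≈306 ms drug-free → ≈424 ms at scale 0.5) and EADs appear
near-complete block (scale ≤ 0.04).

The machine-learning input beat is chosen from the last 250 beats of the
1000-beat run (window 751-1000; reduced runs scale the window) as the beat
with the **most positive** repolarization-phase slope, ties to the latest
beat. "Maximal repolarization slope" could also be read as steepest
descent; the most-positive reading is adopted because its purpose is to
capture the beat exhibiting an EAD when one occurs, and a clean monotone
repolarization has only negative slopes. The reading is configurable
through `max_repol_slope` if a different selection rule is wanted.

## Datasets

A dataset row is one raw 1000-point AP shape — deliberately **not**
normalized; the network's single batch-normalization layer is the only
standardization. Full-scale counts: 2000 Hill samples × 4 Cmax multiples
= 8000 shapes per drug; 12 training drugs → 24,000 rows; 16 test drugs →
32,000 rows; a 500-per-drug subsample of the training drugs gives 6,000
rows (both training-set sizes appear in the protocol's description; the
2000-per-drug set is the default and `subsample_per_drug=500` reproduces
the other). Folds for cross-validation are stratified by risk class (not
by drug) at sample level; because shapes from one drug are correlated,
sample-level folds measure optimization behaviour rather than drug-level
generalization — the held-out-drug split is the honest generalization
test, which is why train and test drug lists are disjoint at full scale.

## Network

1D CNN, three convolutions of two filters each (kernels 32/16/8), ReLU
activations, softmax over three classes:

    1000 → conv(k32,s2) → 485 → BN → ReLU → maxpool(4,s1) → 482
         → conv(k16,s2) → 234 → ReLU → dropout(0.2) → maxpool(8,s2) → 114
         → conv(k8,s1)  → 107   ×2 filters → flatten = 214
         → dense(5, ReLU) → dense(3, softmax)

Two published sizes anchor this chain — conv1 output length 485 and
flattened feature count 214 — and the pooling strides are the unique
assignment consistent with the stated kernel/pool sizes and both anchors
(found by exhaustive search over stride assignments); `ArchitectureSpec`
asserts both anchors at construction and fails loudly, printing the
chain, for any non-conforming variant. Dropout sits between conv2 and
pool2, and the single batch-normalization layer sits after conv1; batch
statistics are used in training and exponential moving averages at
inference, so prediction is deterministic.

Training: categorical cross-entropy, Adam at learning rate 0.01, batch
size 32 (the batch size is this package's choice), 100 epochs with
10-fold cross-validation at full scale; the final model retrains on all
training data; because a ~1.3k-parameter ReLU net occasionally collapses
from an unlucky initialization, the final fit runs three seeded restarts
and keeps the one with the best training accuracy (deterministic given
the seed). The network and backpropagation are
implemented directly on NumPy arrays — at this size a deep-learning
framework buys nothing — and analytic gradients are verified against
central finite differences in the test suite. Weight init is seeded
He-normal; training is deterministic given the seed.

## Evaluation

`repeated_test` draws `per_drug` shapes per test drug without replacement
(default 100 — the protocol does not state the per-repeat draw size; this
is the harness's main free parameter), classifies them, and reduces each
class one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
LR+ = sens/max(1−spec, ε), LR− = (1−sens)/max(spec, ε) with ε = 10⁻⁴
(LRs are always computed from unrounded values — at specificity ≈ 0.999
rounding before the ratio distorts LR+ by orders of magnitude), and AUC
as the Mann-Whitney pair statistic with ties counted 0.5 (equal to the
trapezoidal ROC area; asserted against an independent implementation to
1e-12). Over n_repeats repeats (10,000 at full scale) the report gives
per-metric means with central 95% percentile intervals and a
row-normalized mean confusion matrix. Note these intervals describe the
spread of the repeat distribution; growing n_repeats stabilizes them but
does not shrink them toward zero. A per-drug aggregation (mean class
probability per drug) is provided as a secondary view since shapes within
a drug are correlated.

## Synthetic fixtures: what they show

`synth_fixtures` provides two generators, both pure functions of
(spec, seed):

* **Synthetic dose-response panels** with designed mechanisms — high risk:
  selective IKr block with IC50 well below Cmax; intermediate: IKr IC50
  near 2× Cmax; low: no block in the therapeutic range or offsetting
  ICaL/Na block. The default panel has 9 drugs (3 per class), 4
  concentrations log-spaced around Cmax (¼×-16×), 6 replicates with block
  noise σ = 0.02 — noise comparable to a clean patch-clamp assay.
* **Surrogate AP shapes** from a parametric template (rest −85 mV, fast
  upstroke with decaying overshoot, plateau, sigmoidal repolarization with
  class-shifted APD90, optional Gaussian EAD bump, smoothed additive noise)
  so classifier and evaluation tests never pay the ODE cost.

These fixtures make every stage executable and falsifiable offline, but
they are *constructed to be separable*: high/low AUC ≥ 0.8 on the reduced
end-to-end run demonstrates that the plumbing — bootstrap → conductance
scaling → paced simulation → beat selection → training → repeated testing
— is wired correctly and that the network can learn AP-shape differences
of the magnitude the mechanisms produce. It does **not** demonstrate
classification skill on real drugs, where channel profiles are messier,
risk labels disputed, and intermediate-risk overlaps both neighbours.
Reproducing published performance on the real 28-drug panel requires the
external experimental dataset and a full-scale campaign, and is out of
scope here.

Reduced problem sizes used by the tests and the acceptance script:
bootstrap B = 50, 8 Hill samples per drug simulated (split 4 train / 4
test), 20 beats per run with selection over the last 5, 15 training
epochs with 3 folds, 100 evaluation repeats with 8 shapes per drug. These
are the package's desk-scale defaults in `PipelineConfig`; every knob
scales up to the full protocol.

## Known limitations

* Static (conductance-scaling) block only; state-dependent hERG binding
  kinetics are out of scope, although they are known to sharpen high-risk
  discrimination.
* Endocardial single cell only — no transmural tissue, pseudo-ECG, or
  beta-adrenergic modulation.
* The bootstrap quantifies replicate scatter but, unlike a full posterior
  sampler, not concentration-range inadequacy; drugs assayed over too
  narrow a range will look more certain than they are.
* The 2 ms recording grid undersamples the upstroke; biomarkers mitigate
  this with interpolation, but the network sees the coarse grid.
* Fold assignment at sample level (default) overstates generalization
  when train and test share drugs; use disjoint drug splits for honest
  claims.
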