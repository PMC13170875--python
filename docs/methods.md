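# Methods

This note documents what `crisisdetect` computes, the assumptions behind
its synthetic data, and the numerical and design choices that were
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The prediction problem

Each hotline call carries four binary labels: depressed mood, suicidal
ideation, suicide plan, and high-risk status. The labels are strongly
dependent: plans imply ideation, and high risk is a deterministic triage
rule — ideation with a specific plan, or ideation without a plan plus a
risk-factor score ≥ 5, where the score aggregates questionnaire items and
mood contributes 1 point (moderate) or 2 points (severe depression); mild
depression counts toward the binary mood label but adds no points. The
model consumes fixed-length text embeddings of the call transcript and
variable-length sequences of audio segment embeddings.

## Synthetic cohort generator

Real calls are private, so cohorts are simulated. A latent severity scalar
s (two-component normal mixture: case-like and control-like candidates)
drives every label:

- ordinal mood level via noisy thresholds on s (logistic noise, sd 0.6);
- ideation ~ Bernoulli(σ(2.0·(s − 0.3)));
- plan, only when ideation is present, ~ Bernoulli(σ(1.6·(s − 1.3)));
- non-mood risk-score points ~ Binomial(8, σ(0.9·(s − 0.6))), abstracting
  the questionnaire's other items (their individual wording is not
  reproduced here — only the ≥ 5 threshold and the mood points matter to
  the rule);
- high risk from the triage rule, exactly, when `rule_strict` is on.

Candidates are routed to the high-risk or control quota by the rule
outcome, so a requested case/control split (default 526/531, the published
cohort size) is met exactly while label correlations arise mechanistically.
Defaults were calibrated once so the group-conditional margins resemble the
published cohort (near-universal ideation and ~3/4 plans among high-risk
calls; rare plans among controls). Under the strict rule P(ideation | high
risk) is 1 by construction; the published table reports 26/526 high-risk
calls without recorded ideation, an inconsistency with the stated rule that
the generator reproduces only via the optional `label_noise_rate` (random
independent label flips, which require `rule_strict=False`).

Embeddings are class-conditional Gaussians: the modality mean is a fixed
random linear map (unit-norm signal directions) of the four labels plus
tanh-squashed severity, scaled by the modality SNR, plus unit isotropic
noise. Audio calls receive a Poisson number (mean 12, min 2) of 10-second
segment vectors sharing the call-level mean with independent noise. Text
defaults to 3072 dimensions (the dimension of the large text-embedding
model used on real transcripts) and audio to 1024 (a typical large
speech-encoder hidden size — never printed in the original work).
`snr = 0` yields a pure-noise, uninformative modality.

What the generator does **not** emulate: raw audio or text content,
transcription/ASR noise, demographic structure and case–control matching,
temporal drift between cohort years (the prospective split is random,
stratified by risk status), or any dependence of embedding noise across
calls. Tests passing on these cohorts show that the pipeline recovers
planted structure correctly under its own assumptions; they are not
evidence about real hotline data.

## Joint autoencoder–classifier

Encoder: input → 256 → latent 64 (ReLU; widths configurable — the original
architecture diagram is not public, so these are this package's defaults
chosen as the smallest shape exercising every loss term). Decoder mirrors
the encoder; classifier is one shared trunk (latent → 64, ReLU) with a
4-unit sigmoid output, one unit per label. Losses:

- reconstruction: batch mean of the per-sample **summed** squared error
  (not per-dimension mean), so the magnitude scales with embedding
  dimension;
- per-label binary cross-entropy with probabilities clipped at 1e-7 for
  stability;
- total: λ₁·L_rec + λ₂·Σ γⱼ·L_bce(j), defaults λ₁=1, λ₂=0.8, γ=(1,1,1,1).

Optimization: Adam (lr 1e-4, batch 32), at most 150 epochs, early stopping
when validation loss fails to improve for 40 consecutive epochs; the
best-validation weights are restored. Training is a pure function of
(data, config, seed). Decision threshold 0.5, ties mapped to positive;
ROC support covers other operating points. The autodiff engine is float64
numpy with a tape; gradients are verified against central finite
differences in the test suite.

### Gated fusion

In fused mode each modality has its own encoder/decoder; a gate (latents
concatenated → 32 ReLU → 1 sigmoid) emits a per-call α and the classifier
consumes α·z_text + (1−α)·z_audio. Two choices here were forced by
identifiability, not taste:

1. **Latent RMS normalization before fusion.** Without it the network can
   silence a modality by shrinking that encoder's output scale, leaving α
   meaningless; each latent is scaled to unit root-mean-square per sample
   before gating, so α is the only mechanism for suppressing a modality.
   Reconstruction still consumes the unnormalized latents.
2. **Pool size vs capacity in the dominance study.** With small training
   pools the network can memorize fixed per-call audio noise as random
   features, and the loss stops pressing α upward even though a
   forced-α probe shows the loss surface favors α ≈ 1. The reference
   dominance study therefore uses a 1800-call pool with latent size 8,
   a regime where that escape is closed and the gate converges toward the
   informative modality across seeds.

Fusion training is end-to-end (gate and both encoders jointly); in fused
mode the reconstruction term is the average of the two modality losses.

### Segment aggregation

`mean` is the default order-invariant pooling. `birnn` is a fixed, seeded
bidirectional Elman-tanh pass whose final forward/backward hidden states
are concatenated — an untrained random-feature summary that preserves
order sensitivity; it stands in for a trained BiLSTM pooling layer, which
is out of scope.

## Evaluation protocol

The earlier-period pool is re-partitioned 9:1 into train/validation
(100 iterations in the full protocol; reference studies use 10), the model
is retrained from scratch each iteration, and metrics are computed on the
fixed later-period prospective set. Per-label precision, recall, F1 and
accuracy are reported per label (binary, not micro/macro pooled);
zero-denominator ratios are reported as 0 with an `undefined` flag rather
than NaN. Aggregates carry percentile-bootstrap CIs (1000 resamples,
bootstrapping across iterations, since the published CIs accompany
iteration-aggregated means; the original bootstrap unit and resample count
are unstated). ROC curves and AUC use the standard threshold sweep with
the pairwise-probability tie convention (scikit-learn under the hood; the
test suite checks it against a brute-force pairwise oracle).

The prevalence simulation draws 4 positives and 270 negatives without
replacement per draw (500 draws by default; the original draw count is
unstated) from fixed prospective predictions and recomputes metrics per
draw. Sensitivity and specificity are prevalence-invariant, so mean recall
matches the full-set recall while precision falls to the closed-form
PPV = se·p / (se·p + (1−sp)(1−p)) at p = 4/274.

## Statistical comparison

Pairs of metric distributions are routed by sample size: both ≥ 30 →
Welch's t (Welch–Satterthwaite df); both < 30 → Wilcoxon rank-sum, exact
by enumeration of the rank-sum null (midranks for ties, two-sided p =
2·min(lower, upper tail) capped at 1) for per-group n ≤ 10, normal
approximation with tie correction beyond; otherwise a permutation test on
the absolute mean difference — exhaustive when C(n, n_a) ≤ 20,000, else
Monte-Carlo with add-one smoothing. The 30-threshold generalizes the
protocol's literal 100-vs-100 / 100-vs-5 / 5-vs-5 cases, all of which
route as printed. Holm–Bonferroni is applied within each metric family
across all model pairs (the original correction family is not defined more
precisely than "all p-values"). The exact rank-sum test is conservative at
5-vs-5 because of the discreteness of its null.

## LLM harness

Prompts are deterministic concatenations of task instructions, the 7-level
risk hierarchy (chain-of-thought scaffold), optional few-shot examples,
the transcript, and a JSON output directive naming the four boolean
fields. The shipped hierarchy wording is this package's own placeholder
text spanning "no distress" to "ideation with a specific plan" — the
original clinical ladder is not reproduced. Parsing scans the reply for
JSON object literals, takes the last one containing all four fields, and
accepts common affirmative/negative variants; a parse failure triggers one
retry, after which the call is excluded and logged. Each of the 5
repetitions is evaluated independently (no majority vote). The mock
backend answers with ground-truth labels flipped independently per label
at a configurable rate, deterministic per (seed, call, repetition) via a
CRC-keyed RNG. Explanations are requested through the same backend
contract; rubric scoring uses five 1–5 Likert dimensions with two raters,
a dimension counting as consistent when scores differ by ≤ 1.

## Reference study sizes

The reference studies (test suite and `scripts/acceptance.py`) use
1000–2000-call cohorts with 128–256-dimensional text embeddings rather
than the 3072-dim generator default: the embedding mechanism and model are
dimension-agnostic, and these sizes keep single-CPU runs in minutes. The
"high-SNR" recovery cohort uses text SNR 10 (class-conditional means ~10
noise SDs apart along their signal directions), a regime chosen to be
cleanly Bayes-separable so that near-perfect recovery is an implementation
check, not a statistical accident.

## Known limitations

- The synthetic generator's conditional independencies (labels independent
  given severity; embedding noise isotropic and independent across calls)
  are stronger than anything plausible for real calls.
- The joint model is CPU-sized; no GPU path, no pretrained-model
  inference, no tokenization.
- `birnn` aggregation is an untrained random-feature pass, not a learned
  temporal model.
- Published headline metrics from the private hotline corpus are not
  reproducible here by design; the package validates mechanism, not those
  numbers.
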