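# Methods

This note documents the models implemented in `fedmdl`, the parameter
choices that matter, what the synthetic benchmarks do and do not show,
and the numerical conventions used throughout.

## Problem setting

N clients each hold images X_i with binary labels Y_i. The data of a
single client is a mixture of K latent *domains* (distinct
distributions), and K and the per-sample domain memberships are unknown.
The pipeline learns F = {f(w), g(θ; φ), h(ω)}: a federated clustering
module f that assigns each sample a domain label d ∈ {1..K}; a
multi-domain classifier g with shared frozen parameters θ and per-domain
final-layer parameters φ_d; and a graph network h that fine-tunes φ.

## Federated ClusterGAN

The clustering module is a ClusterGAN: generator G (latent → image),
discriminator D (image → realness), encoder E (image → latent
estimate), trained on the adversarial objective plus two latent
inversion regularizers (coefficients β_n, β_c). The latent prior mixes a
continuous part z_n ~ N(0, σ²I) and an exact one-hot z_c uniform over K
categories; it is the one-hot block that makes the encoder's latent
space cluster. Training is federated: every round each client runs local
alternating D / (G,E) steps and the server averages all three parameter
sets (FedAvg, sample-count weights).

Defaults: σ = 0.1, dim(z_n) = 30, β_n = β_c = 10 (the usual ClusterGAN
convention — the setting is not prescribed by the problem), q = log with
a sigmoid-squashed discriminator; a Wasserstein mode (q = identity, no
gradient penalty) is provided but flagged experimental. Local steps use
batch size 32 and learning rate 5·10⁻⁴ for a few epochs.

G, D and E are size-parameterized MLPs (one tanh hidden layer of width
64) over flattened images. A convolutional stack would be the natural
choice at 128×128; at the 16×16 desk scale the MLPs train in seconds on
one CPU and the encoder geometry — which is all the clustering uses — is
equally well behaved, so the MLP is the default architecture here.

Domain assignment pools the encoded codes (ẑ_n concatenated with
softmax(ẑ_c)) of *all* clients and runs K-Means (k-means++, 10 restarts,
fixed seed) server-side; pooling is what makes the domain space shared
across clients. Cluster labels are canonicalized by descending cluster
size so assignments are reproducible. Unseen samples (test clients) are
assigned to the nearest centroid in Euclidean distance.

## Estimating the number of domains

K is chosen by an incremental search: for NumDomain = 2, 3, … a
federated ClusterGAN with a NumDomain-way one-hot prior is trained at
reduced epochs (the prior dimension depends on K, so the model must be
retrained per candidate), samples are clustered, and the clustering is
scored by the average Silhouette: each client's Silhouette is computed
on its own codes with its sample labels, and client scores are averaged
*unweighted*. The best score seen so far is tracked; the search stops
after `patience` consecutive candidates without improvement or at
`max_domains`. Conventions: samples in singleton clusters score 0, and a
client whose samples all share one label contributes 0. Defaults:
min 2, max 10 (max 6 in the desk benchmark), patience 2, one search
epoch per candidate. After the search, the ClusterGAN is retrained at
K = BestNum at full epochs for the final assignment. The scorer is
injectable, so the search logic is tested exactly against a few-line
reference trace, independent of GAN stochasticity.

## Federated multi-domain learning

The classifier g keeps a single backbone θ, frozen after initialization,
and K independent heads φ_d — the last fully connected layer, weights
plus bias, (feature_dim + 1) × n_classes parameters each. A sample with
domain d is routed through head φ_d. Local training minimizes the
routed cross-entropy with SGD (momentum 0.9, weight decay 10⁻⁴); only
heads update, and heads of domains absent from a client are untouched.
Aggregation is per head: φ_d is averaged over clients weighted by each
client's domain-d sample count, so clients without domain d contribute
nothing to it. Early stopping monitors pooled validation accuracy on a
held-out 10% split of the training clients (patience 5 rounds, max 50;
the best-metric model is kept).

The desk backbone is a frozen random *linear* convolutional projection:
two 3×3 convolution banks with 2×2 average pooling and a final linear
map to 32 features. Linearity is deliberate: the frozen features are
then a linear function of the pixels, so the single-head (FedAvg)
baseline is exactly a linear classifier and the conflicting-label
pathology built by the generator (see below) is provably outside its
hypothesis class, while per-domain heads — linear *given the domain* —
fit it easily. Method comparisons therefore measure the value of domain
routing, not incidental backbone capacity. A pretrained deep backbone
(the natural case-study choice) would require a pretrained-CNN
dependency this build does not ship; requesting it raises a clear error.

Desk-scale optimization: head learning rate 0.03 (the 32-dimensional
features have scale ≈ 0.2, far from a deep backbone's feature scale, so
the case-study rate of 10⁻³ would be needlessly slow), 20 local epochs,
batch 32.

## Graph-attention fine-tuning

Each head is flattened (weights raveled, then bias) into a vertex v_d ∈
R^M of a complete graph without self-loops: the neighborhood of d is
every other vertex. Per layer and attention head, coefficients are

    e_dj = softmax over j ∈ N_d of LeakyReLU(score(W v_d, W v_j))

with two score functions: the literal concat-linear form
a·[W v_d ⊕ W v_j], and the default scaled cosine
cos(a ⊙ W v_d, W v_j)/τ with τ = 0.5 — cosine keeps scores bounded so
gradients do not vanish with vertex scale; the learnable vector a
re-weights the query's coordinates before the cosine. The layer output
averages the L attention heads and applies ELU:

    v̂_d = ELU( (1/L) Σ_l Σ_{j∈N_d} e^l_dj W^l v_j )

stacked 5 layers deep with hidden width M and L = 5 heads per layer,
dropout 0.2 on inputs and coefficients during training, Xavier
initialization. Head-averaging is used at every layer (the classic GAT
concatenates at hidden layers; the averaged form is used consistently
here). A small-K caveat: with one or two neighbors, a zero-norm
transformed vertex can occur (e.g., when dropout removes the only
incoming edge of the previous layer); the cosine then raises unless the
ε-norm guard (`cosine_eps > 0`) is enabled, as it is in the experiment
defaults.

Fine-tuning is residual by default: the fine-tuned head is
φ′_d = φ_d + v̂_d, with v̂ the GAT output. A pure replacement φ′_d = v̂_d
(available via `residual=False`) forces the network to reconstruct every
head from its *neighbors* from scratch, which at desk scale reliably
degrades a well-trained model before the few fine-tuning epochs can
recover it; the residual form makes an untrained GAT a near-no-op and
lets training learn a cross-domain correction, which is what
"fine-tuning" should mean. Training is client-local — with the graph
built from the global heads, each client trains its own GAT parameters
ω to minimize the routed cross-entropy of the corrected heads on its
data (φ and θ fixed; gradients flow through the GAT only; learning rate
5·10⁻³ at desk scale, 5 epochs, batch 32) — and the per-client φ′ are
then averaged per head with domain sample-count weights. The GCN
ablation fixes every edge weight at 1/|N_d| and removes the attention
parameters; everything else is identical.

## Synthetic federation generator

Domains are Walsh-type stripe templates: products of dyadic row/column
parities at intensity `contrast`, so any two distinct templates disagree
on exactly half the pixels and the pairwise mean absolute difference is
contrast/2 by construction (the candidate list is filtered against that
bound; exceeding the constructible set raises). A sample is its domain's
template plus i.i.d. Gaussian pixel noise, clipped to [0,1]; clipping is
preferred to rescaling so templates remain comparable across noise
levels. Class labels come from a reserved central patch written at
0.5 ± 0.25: bright patch means class 1, and with `conflicting_labels`
the rule is inverted on even-numbered domains. The conflict is the
pathology under study: the XOR of domain identity and patch brightness
is not linearly separable, so a single linear classifier is capped near
0.75 on an even domain mix while per-domain rules are near-perfect.

The desk benchmark: 8 training + 4 test clients, 150 samples each,
16×16 images, 3 true domains, noise 0.05, conflicting labels on, and
per-client mixtures 0.7/0.15/0.15 with the dominant domain cycling
across clients. The dominant-but-mixed composition reflects the
motivating setting (a subject has one prevailing regime plus substantial
excursions) and keeps both heterogeneity axes active: dominant domains
differ across clients (inter-client) and every client still holds all
domains (intra-client). At much higher dominance the minority regimes
carry so little mass that per-client Silhouette scores start favoring
merged clusterings; 0.7 is comfortably inside the regime where the
true K is recovered.

The ECG generator emulates a chest-worn single-lead recording: a
quasi-periodic train of Gaussian P/QRS/T bumps at a given heart rate and
sampling rate (700 Hz default), with a regime schedule that switches
beat morphology (T amplitude, R width, P amplitude) and the condition
tag (baseline/stress) over time, and exact R-peak ground truth. It is
explicitly not a physiological simulation — no RR variability model, no
artifacts, no multi-channel signals — and supports testing of peak
detection, segmentation and rasterization, not claims about real ECG.

## ECG preprocessing conventions

R peaks: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
derivative, squaring, 150 ms moving-window integration, threshold at
25% of the 98th percentile of the integrated signal, 0.2 s refractory
period, and refinement of each candidate to the raw-signal maximum
within ±100 ms. Cycles span midpoint-to-midpoint between adjacent peaks
(first/last peaks dropped). Each cycle is resampled to the image width,
min–max normalized (constant cycles map to a centered line), and drawn
as a connected polyline, foreground 1 on background 0 — a rendering
that is resolution-exact and invariant to positive affine amplitude
changes. Beat labels are the majority condition tag over the beat span,
kept only if the majority is a retained tag (baseline = 0, stress = 1)
and holds ≥ 80% of the span; transition-straddling and excluded-tag
beats are dropped.

## What the benchmarks show — and what they cannot

Passing the desk benchmarks demonstrates that the machinery is correct
and that the method ordering (per-domain heads > client clustering >
one global model) emerges whenever intra-client heterogeneity takes the
conflicting-rule form the generator constructs. It does not demonstrate
performance on real wearable data: the synthetic domains are far more
separable than physiological regimes, the class signal is noiseless by
construction, and the frozen linear backbone sidesteps representation
learning entirely. Results on real ECG would additionally depend on
peak-detection robustness and on how well a ClusterGAN separates true
physiological regimes — neither is exercised beyond the synthetic
stand-ins.

## Numerical and reproducibility notes

- All randomness flows from integer seeds through
  `numpy.random.Generator`; per-client, per-round streams are derived
  with `SeedSequence([seed, round, client])`. Every stage is
  bit-reproducible under a fixed seed.
- All trainable components run on the package's own reverse-mode
  autodiff over float64 NumPy arrays (`fedmdl.nn`), with gradients
  verified against finite differences in the test suite.
- Aggregation requires identical parameter names/shapes and rejects
  non-finite values; weights are normalized to sum to 1.
- K-Means and Silhouette computations use scikit-learn; F1 is the
  binary F1 of the positive (stress) class, pooled over all test
  samples for the overall score, and overall accuracy is sample-weighted
  pooled accuracy.
- Divergence (NaN loss) aborts training with a diagnostic rather than
  propagating.
- Problem sizes in tests and in `scripts/acceptance.py` (4–12 clients,
  60–150 samples per client, 16×16 images, 10 seeds) are the package's
  desk-scale defaults, chosen so the complete pipeline runs end-to-end
  in minutes on one CPU core.

## Known limitations

- The Wasserstein mode lacks a gradient penalty and is not recommended
  beyond experimentation.
- Full client participation is assumed every round; there is no client
  sampling, dropout handling, secure aggregation or differential
  privacy.
- Test-time domain routing uses nearest latent centroids; if the
  encoder drifts from the clustering geometry, routed accuracy degrades
  (an oracle-label mode exists for diagnosis).
- `max_domains` above the smallest client size is rejected; clients
  smaller than a batch still train (one short batch per epoch).
- The GAT consumes raw flattened heads; for very large heads (deep
  backbone, M in the thousands) the M×M layer weights would be the
  dominant cost and a compressed vertex representation would be needed.
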