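# fedmdl — federated clustered multi-domain learning

Federated learning trains a shared model across data-holding clients
without moving their raw data. In health monitoring each client is one
person wearing a sensor, and the textbook i.i.d. assumption fails twice:
clients differ from each other (*inter-client* heterogeneity), and a
single client's data spans several latent distributions over time
(*intra-client* heterogeneity — e.g., distinct physiological regimes in
an ECG stream). A one-size-fits-all federated model, and even
client-clustering methods, cannot resolve structure *inside* a client.

`fedmdl` implements a federated clustered multi-domain learning pipeline
that discovers the latent domains and learns per-domain classifiers:

1. **Federated ClusterGAN.** A generator G, discriminator D and encoder
   E are trained federatedly with the mixed latent prior
   z = (z_n, z_c), z_n ~ N(0, σ²I), z_c uniform one-hot over K, and
   objective

       min_{G,E} max_D  E_x q(D(x)) + E_z q(1 − D(G(z)))
                  + β_n E‖z_n − E_n(G(z))‖² + β_c E CE(z_c, E_c(G(z)))

   with q = log (vanilla) or q = identity (Wasserstein mode). K-Means on
   the pooled encoder codes assigns every sample a domain label d ∈
   {1..K} in a domain space shared by all clients.
2. **Domain-number estimation.** K is not assumed known: candidate
   values are scanned incrementally, each scored by the average
   Silhouette of its clustering across clients, with patience-based
   early stopping (`estimate_domain_number`).
3. **Federated multi-domain learning.** One CNN backbone θ (frozen,
   domain-agnostic) plus a domain-specific final layer φ_d per domain;
   sample (x, d) is scored by head φ_d. Heads are trained federatedly
   with per-head sample-count-weighted averaging.
4. **Graph-attention fine-tuning.** The flattened heads become the K
   vertices of a complete graph and a GAT with scaled-cosine attention
   (multi-head averaged, e_dj normalized over the neighbors of d)
   fine-tunes them against the classification loss, letting related
   domains share statistical strength. A GCN variant (uniform edge
   weights) and a no-graph ablation are included.

The package also ships the two data front-ends needed to exercise all of
this without any external download: a synthetic federation generator
with known ground-truth domains and an optional conflicting-label rule
(so one global head provably cannot fit a client), and an ECG
preprocessing chain (Pan–Tompkins-style R-peak detection, cycle
segmentation, 128×128 beat-image rasterization) mirroring a wearable
stress-detection setting at 700 Hz.

## Worked example

```python
from fedmdl import ExperimentConfig, run_all_methods

config = ExperimentConfig()          # the desk-scale conflicting-label benchmark
results, state = run_all_methods(config, seed=42)

print(f"estimated number of domains K = {state.search_result.best_num}")
print(f"domain-assignment purity       = {state.purity:.3f}")
for method, m in results.items():
    print(f"{method:16s} accuracy={m.overall_accuracy:.3f}  F1={m.overall_f1:.3f}")
```

Output:

```
estimated number of domains K = 3
domain-assignment purity       = 1.000
fedavg           accuracy=0.725  F1=0.709
cluster_fl       accuracy=0.852  F1=0.835
proposed_no_gnn  accuracy=1.000  F1=1.000
proposed_gcn     accuracy=1.000  F1=1.000
proposed         accuracy=1.000  F1=1.000
```

The benchmark federation has 8 training and 4 held-out test clients,
each a 0.7/0.15/0.15 mixture of three latent domains of 16×16 images,
with the class rule inverted on one domain. The search recovers K = 3
and assigns domains perfectly. FedAvg's single head cannot represent the
inverted rule (72.5%); clustering whole clients helps with inter-client
but not intra-client structure (85.2%); per-domain heads with
domain-routed inference solve the task, and graph fine-tuning preserves
that (100%).

The same stages are available from the shell:

```sh
fedmdl generate   --seed 3 --out-dir runs/demo
fedmdl estimate-k --seed 3 --out-dir runs/demo
fedmdl compare    --seed 42 --repeats 10 --out-dir runs/comparison
```

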