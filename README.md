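# spatialfuse

Spatial-domain detection for **spatial multi-omics** data. Given two
spot-by-feature count matrices measured on the same tissue section (RNA plus
chromatin accessibility or surface proteins), the spot coordinates, and
optionally a precomputed per-spot embedding from a single-cell language model
(e.g. scGPT), `spatialfuse` learns one fused latent representation per spot
and clusters it into spatially coherent tissue domains.

It is aimed at analysts of sequencing-based spatial multi-omics platforms
(MISAR-seq, 10x Visium CytAssist RNA+protein, SPOTS, Spatial-CITE-seq style
data) who want annotated-region-quality domain calls from sparse multimodal
spot data.

## Method

For a section with $N$ spots, inputs are $X_1 \in \mathbb{R}^{N\times D_1}$,
$X_2 \in \mathbb{R}^{N\times D_2}$, coordinates $P \in \mathbb{R}^{N\times 2}$,
and optionally a language-model embedding $Emb_f \in \mathbb{R}^{N\times D_f}$.

1. **Preprocessing.** Spots are inner-joined across inputs; RNA/ATAC counts
   are library-size normalized and log1p-transformed, ADT counts are CLR
   normalized; each modality is reduced by PCA to $Emb_1, Emb_2 \in
   \mathbb{R}^{N\times 50}$.
2. **Graphs.** A spatial kNN graph $G_s$ connects each spot to its $k_1 = 3$
   nearest neighbors in Euclidean space. For each embedding ($Emb_f$,
   $Emb_1$, $Emb_2$) a correlation graph connects each spot to the $k_2 = 20$
   spots with the highest Pearson correlation $r(E_i, E_j)$. Graphs are
   symmetrized and normalized as $\hat A = D^{-1/2}(A+I)D^{-1/2}$.
3. **Encoders.** Three 3-layer graph-convolutional encoders
   ($Z^{(l+1)} = \sigma(\hat A Z^{(l)} W^{(l)})$, final layer linear) produce
   six latents of width 64: the language-model embedding through $G_s$ and
   through its own correlation graph ($R_{f_s}, R_{f_e}$, shared weights),
   and each omics embedding through $G_s$ and its correlation graph
   ($R_{os_1}, R_{oe_1}, R_{os_2}, R_{oe_2}$).
4. **Attention fusion.** At each of five fusion sites, per-spot scores
   $v = \tanh(R W_\omega)\,\mu_\omega$ are softmaxed over the inputs and the
   fused latent is the weighted sum: $(R_{f_s}, R_{os_1}) \to EA_s$,
   $(R_{f_e}, R_{oe_1}) \to EA_e$, $(EA_s, EA_e) \to EA_1$,
   $(R_{os_2}, R_{oe_2}) \to EA_2$, and $(EA_1, EA_2) \to Emb$, the final
   embedding. The retained weights say which modality drove each spot.
5. **Loss.** Mirrored graph-convolutional decoders give four MSE
   reconstruction terms ($Emb_f$ from $R_{f_s}$ and from $R_{f_e}$; $Emb_1$
   and $Emb_2$ from $Emb$) and two cross-modality correspondence terms
   ($EA_1$ decoded by the *other* modality's decoder, re-encoded, compared
   to itself; likewise $EA_2$):
   $L = \alpha_1 L_{rec_1} + \alpha_2 L_{rec_2} + \alpha_3 L_{rec_{fs}} +
   \alpha_4 L_{rec_{fe}} + \beta_1 L_{cor_1} + \beta_2 L_{cor_2}$.
   Training is full-graph Adam (lr $10^{-3}$, 200 epochs), on a small
   reverse-mode autodiff engine included in the package.
6. **Clustering.** $Emb$ is partitioned by a Gaussian mixture with one shared
   full covariance (the mclust *EEE* model), seeded multi-restart EM, best
   restart by likelihood.

Setting the language-model embedding to all zeros gives the **zero-embedding
ablation**, which isolates the embedding's contribution; the same pipeline
runs unchanged. Agreement with ground truth is scored by homogeneity,
v-measure, AMI, NMI, and ARI.

## Worked example

```python
import spatialfuse as sf

# synthetic section: 20x20 spots, 4 block domains, RNA + ADT, effect size 2.0
spec = sf.SyntheticSpec()
rna, adt, coords, truth = sf.generate(spec)

# informative stand-in for a language-model embedding
emb = sf.make_informative_embedding(truth, dim=64, noise_sd=0.1, seed=0)

pipe = sf.SpatialDomainPipeline(n_domains=4, random_state=0)
pipe.fit(rna, adt, coords, emb)

print(sf.compute_metrics(pipe.labels_, truth).as_dict())
hist = pipe.model_.loss_history_
print(round(hist[0].total, 3), "->", round(hist[-1].total, 3))
```

prints

```
{'homogeneity': 1.0, 'v_measure': 1.0, 'ami': 1.0, 'nmi': 1.0, 'ari': 1.0}
338.622 -> 104.577
```

i.e. the training loss falls from 338.6 to 104.6 over 200 epochs and the
recovered domains agree perfectly with the planted ones (all five supervised
scores = 1). `pipe.attention_summary()` returns the per-spot attention
weights in long format for violin plots, plus per-cluster means.

The same run is available from the shell:

```sh
spatialfuse simulate --out fixture/
spatialfuse run fixture/config.yaml --out results/   # config lists the file paths
spatialfuse evaluate results/labels.csv fixture/truth_labels.csv
```

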