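# caedec

Deep embedded clustering of survey microdata with a convolutional
autoencoder, plus the downstream statistics used to turn the clusters
into an epidemiological story: contingency profiling and areal spatial
analysis.

## The problem

Population surveys of psychoactive-substance (PAS) use record tens of
thousands of households across dozens of mixed-type variables (region,
gender, housing type, socioeconomic stratum, age, household finances,
consumption indicators). Classical clustering degrades on such data:
irrelevant and redundant columns dominate the distance structure. The
approach implemented here learns a low-dimensional latent feature space
and the cluster structure *jointly*, then carries the discovered
consumption patterns into geography: which areas concentrate use, and
which contiguous regions share a profile.

## The model

**Convolutional autoencoder (CAE).** Each record, encoded to a
`[0, 1]`-scaled feature vector of length *d* (one-hot nominals,
rank-scaled ordinals, min-max numerics), is presented as a 1-channel
sequence. The encoder applies two strided convolutions
`z = W·x_window + b` with ReLU activations and a fully connected map
onto an *L*-dimensional latent space; the decoder mirrors it and ends in
a sigmoid. Pretraining minimizes the reconstruction loss
`L_r = mean_k ||x_k − x̃_k||²`.

**Clustering layer (DEC).** Similarity between an embedded point `z_k`
and a centroid `c_m` uses a Student-t kernel,

    q_km ∝ (1 + ||z_k − c_m||² / α)^(−(α+1)/2),   α = 1 by default,

normalized so each row of `Q` is a distribution. A sharpened,
frequency-normalized target

    p_km = (q_km² / f_m) / Σ_i (q_ki² / f_i),   f_m = Σ_k q_km

defines the clustering loss `L_c = KL(P ‖ Q)`. Joint training minimizes
`L_t = L_r + C·L_c`, updating weights, biases and centroids by gradient
descent; `P` is refreshed every few epochs and training stops when the
hard labelling stabilizes. Centroids are initialized by spectral
clustering of the pretrained latent space (cluster means as centroid
estimators); final labels are `argmax_m q_km`.

**Profiling.** Cluster × covariate contingency tables, Pearson χ² tests,
Haberman adjusted standardized residuals
`(O − E) / sqrt(E (1 − row/n)(1 − col/n))`, per-cluster outcome
prevalence, and silhouette / Calinski–Harabasz / Davies–Bouldin indices.

**Spatial stage.** Queen/rook contiguity weights from polygons; global
Moran's I, Geary's C and Getis–Ord G with permutation inference; local
Moran (LISA) with HH/LH/LL/HL quadrants under conditional permutation;
eight choropleth classifiers (equal intervals, quantiles, maximum
breaks, box plot, head–tail, Jenks–Caspall, exact Fisher–Jenks, a max-p
heuristic) compared by the ADCM criterion; and spatially constrained
Ward regionalization whose regions are always contiguous.

A synthetic-data module generates mixed-type surveys with known latent
clusters and areal lattices with controllable spatial structure, so the
whole pipeline is testable without any external download.

## Worked example

```bash
python examples/01_cluster_synthetic_survey.py
```

```
survey: 1500 records, 16 encoded features (columns: ['region', 'gender', 'housing', 'ses', 'age_band', 'contributes'])
pretraining reconstruction loss: 3.4924 -> 0.1743
joint phase: 5 epochs, cluster sizes [730, 437, 333]
adjusted Rand index vs generator truth: 0.961
```

The pretrained autoencoder reduces the reconstruction loss twenty-fold;
the joint phase converges in a handful of epochs on well-separated data
and the recovered labels agree with the generator's latent mixture
almost perfectly (ARI 0.96; 1.0 would be identical partitions).

The other examples profile clusters against covariates
(`02_profile_clusters.py` — prints χ² statistics such as
`gender chi2 = 386.72, df = 2, p < .0001` and the residual matrix),
run the spatial statistics on a hot-spot lattice
(`03_spatial_autocorrelation.py` — `Moran's I: 0.7230 (pseudo p =
0.0010)` with 11 HH and 10 LL units), and rank choropleth classifiers by
ADCM before regionalizing a two-block lattice exactly
(`04_choropleth_and_regions.py`).

A thin CLI wraps the same pipeline: `caedec simulate | fit | profile |
spatial | regionalize` (see `caedec --help`).

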