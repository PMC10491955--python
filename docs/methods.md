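# Methods

## Model

Let R be the n × m drug × side-effect matrix with entries in {0, 1, …, 5},
where classes 1–5 encode observed frequency (very rare … very frequent) and
0 marks an unobserved pair. I_Ω and I° are the indicator masks of known and
unknown cells (I_Ω + I° = E, the all-ones matrix). The model factorizes
R ≈ UV with U ∈ ℝ^{n×k}_{≥0}, V ∈ ℝ^{k×m}_{≥0} and minimizes

J(U, V, w, h) = ½‖I_Ω ⊙ (R − UV)‖²_F
              + (α/2)‖I° ⊙ (UV − μE)‖²_F
              + (β/2) tr(Uᵀ Σ_p w_p^δ L_dp U)
              + (γ/2) tr(V Σ_q h_q^δ L_eq Vᵀ),

subject to U, V ≥ 0, Σ_p w_p = 1, w_p ≥ 0, Σ_q h_q = 1, h_q ≥ 0.

The second term is the negative log-likelihood of a Gaussian N(μ, σ²) on
the predicted scores of unknown cells, with precision α = 1/σ². It encodes
the epidemiological prior that an unreported pair, if it occurs at all, is
most likely in the lowest class (μ = 1 by default), and it prevents the
factorization from inflating scores in the vast unobserved region.

### Similarity views and Laplacians

Drug views: (1) cosine similarity of side-effect frequency profiles (rows
of R), (2) Tanimoto similarity of topological fingerprints, (3) Jaccard
similarity of multi-hot GO molecular-function annotations of the drug's
targets. Effect views: (1) cosine similarity of frequency profiles
(columns of R), (2) Jaccard similarity of multi-hot MedDRA terms (SOC,
HLGT, HLT, PT levels). All views are symmetric with entries in [0, 1];
all-zero profiles get similarity 0 to everything rather than NaN.

Each view A is sparsified to a k₁-nearest-neighbor graph: row i keeps only
the k₁ largest similarities to other nodes (ties broken by the smaller
column index, so graphs are deterministic), zeros elsewhere; Ã is
generally asymmetric. Its Laplacian is L = (D + D̃) − (Ã + Ãᵀ) with D, D̃
the diagonal row-sum and column-sum matrices, and satisfies
tr(Uᵀ L U) = Σ_{i,μ} Ã(i,μ)‖u_i − u_μ‖², penalizing embedding differences
along graph edges. L is symmetric, has zero row sums and is positive
semidefinite.

### Optimization

U and V are initialized from seeded uniform(0, 1) draws, each divided by
its own Frobenius norm (multiplicative updates absorb the overall scale
within a few sweeps); w and h start uniform. One sweep applies, in order,

1. U ← U₀ ⊙ [(R + αμI°)V₀ᵀ + β(Σ_p w_p^δ(Ã_dp + Ã_dpᵀ))U₀]
        ⊘ [(I_Ω ⊙ U₀V₀ + αI° ⊙ U₀V₀)V₀ᵀ + β(Σ_p w_p^δ(D_dp + D̃_dp))U₀ + ε]
2. the analogous V update, using the already-updated U with the pre-sweep V₀
3. w_p ← t_p^{−1/(δ−1)} / Σ_{p'} t_{p'}^{−1/(δ−1)} with t_p = tr(Uᵀ L_dp U),
   using the post-sweep factors
4. the analogous h update with t_q = tr(V L_eq Vᵀ).

Steps 1–2 are multiplicative, so non-negativity is preserved exactly and
zero entries stay zero; steps 3–4 are the exact minimizers of the weight
subproblem over the simplex (δ > 1 is required; δ = 2 by default so that
every view keeps a nonzero weight). The objective is recorded after every
sweep and is non-increasing (verified to 1e-9 in tests). A guard ε = 1e-12
is added to every denominator and to the traces before exponentiation; it
prevents 0/0 at locked zeros without measurably moving fixed points. The
iteration count is fixed (max_iter = 500 by default) to keep traces
comparable across runs; an optional relative-change early stop (`tol`)
exists but is off by default.

### Cold start

After the sweeps, every all-zero row i of R (a drug with no known
frequency item) has its signature replaced by
u_i ← Σ_{j∈N(d_i)} s_ij u_j / Σ_{j∈N(d_i)} s_ij, where
s_ij = Σ_{p≥2} w_p^δ Ã_dp(i, j) combines the non-frequency views only — a
new entity's frequency profile is identically zero, so view 1 carries no
signal for it — and N(d_i) holds the k₂ known drugs with the largest s_ij
(k₂ = 10). All-zero columns of R are treated symmetrically through the
columns of the effect graphs. If every s_ij is zero the unweighted mean
signature of all known entities is used: the least-informative consistent
choice. The replacement is a convex combination, so each refined
coordinate lies within the neighbors' envelope.

## Hyperparameters

| name | meaning | warm default | cold default |
| --- | --- | --- | --- |
| α | precision of the unknown-cell prior (1/σ²) | 0.05 | 0.05 |
| μ | prior mean score of unknown cells | 1 | 1 |
| β, γ | drug / effect Laplacian strength | 2 | 4 |
| k (`n_components`) | latent dimension | 200 | 200 |
| k₁ (`n_neighbors`) | kNN graph size | 20 | 10 |
| k₂ (`n_cold_neighbors`) | cold-start neighbor count | 10 | 10 |
| δ | view-weight exponent | 2 | 2 |
| max_iter | full sweeps | 500 | 500 |

The warm set is used for fitting and CV1; CV2 (whole drugs held out)
switches to the cold set. Small studies in the tests and the acceptance
script use k = 5–10 and 60–200 sweeps, matched to their synthetic matrix
sizes (k must be generous relative to the true rank, not to 200, and the
objective plateaus well before 200 sweeps at these sizes).

## Evaluation protocol

CV1 randomly partitions the known cells into 10 folds; CV2 partitions the
drugs. Each fold's test entries (cells, or every known cell of the test
drugs) are set to 0 in the training matrix, and the frequency-profile
views are recomputed from that training matrix so held-out information
never enters the similarity graphs. Per drug with ≥ 1 test cell, AUC and
AUPR treat that drug's test cells as positives and all of its
never-observed cells as negatives; drugs with no positives or no negatives
are skipped and counted. Fold AUC/AUPR is the mean over eligible drugs;
AUPR uses step-wise precision–recall summation without interpolation (the
conservative choice for sparse positives). RMSE, MAE and PCC are computed
over the fold's test cells; a zero-variance side yields PCC = 0 with a
warning instead of NaN. Scores are always the raw continuous UV values.

## Synthetic data

The generator draws U* (n × r) and V* (r × m) from Gamma(2, 1), forms
U*V*, adds Gaussian noise (noise_sd, default 0.1), rescales scores
affinely to [1, 5] anchored on the 1st/99th percentiles (the gamma-product
distribution is right-skewed; percentile anchoring keeps mass in every
equal-width class bin) and rounds to classes. Cells are observed with
probability proportional to class^mask_bias, normalized to the target
density (default 0.3); mask_bias = 1 emulates the reporting bias that
makes frequent effects far more likely to be recorded than very rare ones
and is what gives the known/unknown distinction — and hence the ranking
metrics — signal. Non-frequency similarity views are Gaussian kernels of
the true latent distances (bandwidth = median squared distance), mixed
with an independent symmetric uniform similarity by weight view_noise
(default 0.2); frequency-profile views are computed from the generated
matrix exactly as for real data. Options zero whole rows/columns to create
cold-start entities while retaining their ground truth.

What the generator does not emulate: the real benchmark's exact class
proportions, MedDRA's hierarchical structure (views are exchangeable
kernels, not ontology-derived), correlations between views beyond their
common latent origin, and the scale of the real matrix (664 × 994 at ~5%
density). Passing tests therefore demonstrate correctness of the
machinery and sane statistical behaviour under the assumed generative
model, not benchmark-level performance numbers.

## Numerical and design choices

* kNN ties are broken by ascending node index → identical graphs across
  platforms and seeds.
* View lists are ordered with the frequency-profile view first; cold-start
  weighting excludes views tagged `frequency_profile` (falling back to
  "all but the first" for untagged inputs).
* Whether the weight updates should use pre- or post-sweep factors is a
  free choice; the post-sweep factors are used, which makes the recorded
  objective value consistent with the state at the end of the sweep.
* Multiplicative updates lock zeros: an entry that reaches exact 0 stays
  0. With uniform initialization no entry starts at 0, so this only
  matters for deliberately zeroed inputs.
* The fingerprint helper accepts either a precomputed binary table or a
  SMILES table (RDKit path-based fingerprints, default 2048 bits, recorded
  in the run log); without RDKit the SMILES path raises a clear error
  directing to precomputation.
* Per-fold metrics are invariant to test-cell ordering; CV folds come from
  a seeded permutation, so a run is bitwise reproducible from its seed.

## Limitations

* The objective is non-convex; different seeds reach different local
  minima (the descent guarantee is per-run). Traces and factors are only
  comparable at a fixed seed.
* The Gaussian prior on unknown cells is a modelling convenience; at large
  α it dominates and flattens unknown-cell scores toward μ, which destroys
  ranking resolution — α and μ should be tuned jointly (see the
  sensitivity sweep).
* Per-drug AUPR with very few positives is high-variance; fold means
  stabilize it but single-drug values should not be over-interpreted.
* Cold-start refinement depends entirely on the quality of the
  non-frequency views; with uninformative views it degrades to the mean
  embedding, which predicts the population average for the new entity.
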