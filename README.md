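# bandnet

Voxelwise multi-frequency-band brain functional networks from
resting-state fMRI: decompose each voxel's BOLD time series into low
(0.01–0.06 Hz), intermediate (0.06–0.15 Hz) and high (0.15–0.2 Hz)
components, build one thresholded similarity network per band, compare
the band networks with complex-network statistics, and classify
subjects by fusing per-band graph kernels.

## Why frequency bands?

In a voxelwise functional network each voxel is a vertex and two voxels
are connected when their BOLD signals are similar.  Conventionally the
similarity is computed on the full filtered signal — but the low-frequency
component carries most of the raw power and masks what the intermediate
and high bands are doing.  Two voxels can disagree in every band yet
look similar in the full signal, or agree in every band and look
dissimilar overall.  Splitting the signal first exposes band-specific
connectivity that a single full-band network cannot represent.

The model: each voxel signal is Fourier-transformed, the spectrum is
masked to a band, and the band signal is restored by the inverse
transform at the original length.  Vertices *x*, *y* are connected in a
band when the Euclidean distance

d(x, y) = √Σₙ(xₙ − yₙ)² < λ

falls below a threshold λ (given absolutely, or chosen to hit a target
edge density).  The per-band graphs H_L, H_I, H_H share one vertex set
and form a multi-graph G with E(G) = E_L ∪ E_I ∪ E_H; "collaboration"
patterns (edge present in every chosen band — intersection) and the
"interleaved" pattern (edge present in any band — union) are derived by
edge-set algebra.  Band networks are profiled by:

- **small-worldness** — clustering C and characteristic path length L
  against degree-preserving rewired references: γ = C/Cᴿ, λ = L/Lᴿ,
  σ = γ/λ (σ > 1 ⇒ small-world);
- **scale-free statistics** — discrete maximum-likelihood power-law fit
  of the degree distribution with KS-selected x_min;
- **hub coverage** — top-degree vertices matched to atlas region centers
  within a radius δ, coverage A = M/R;
- **region connectivity matrices** and permutation difference tests.

For classification, each subject's band graph enters a Weisfeiler–Lehman
subtree kernel (Kernelᵢᵐ = (f(χᵢᵐ, χ₁ᵐ), …, f(χᵢᵐ, χₙᵐ))); band kernels
are fused convexly, Kernel = Σₘ μₘ Kernelᵐ with μₘ ≥ 0, Σμₘ = 1, and a
kernel extreme learning machine ((I/C + K)β = y) or kernel SVM scores
subjects under stratified cross-validation.

A synthetic-data module generates voxel signals with known band-specific
community structure (random-phase multi-sine carriers on frequency bins
strictly inside each band, plus Gaussian noise) and labelled cohorts in
which the two groups differ only in one band's within-community
coupling — so every stage of the pipeline is testable with ground truth.

## Worked example

```python
import networkx as nx
import bandnet as bn

# one synthetic subject: 60 voxels, 128 volumes at TR 2 s
bold, truth = bn.generate_bold(bn.SyntheticSpec(seed=1))
mg = bn.build_multigraph(bold, density=0.15)   # H_L, H_I, H_H, H_Full
print({k: len(v) for k, v in mg.edge_sets.items()})
# {'low': 266, 'intermediate': 266, 'high': 266, 'full': 266}
print(bn.edge_algebra_count(mg, "L ∩ I"))      # 43
print(bn.edge_algebra_count(mg, "L ∪ I ∪ H"))  # 678

# small-worldness of a modular small-world graph
g = bn.VoxelGraph.from_networkx(nx.connected_watts_strogatz_graph(200, 10, 0.1, seed=42))
gm = bn.small_world_indices(g, n_random=20, seed=1)
print(f"gamma={gm.gamma:.3f} lambda={gm.lambda_ratio:.3f} sigma={gm.sigma:.3f}")
# gamma=12.263 lambda=1.295 sigma=9.467
```

At density 0.15 each band network gets the same number of edges, yet
only 43 of the 266 low-band edges coincide with intermediate-band edges
— the bands connect different voxel pairs.  σ = 9.5 ≫ 1 says the
modular test graph keeps lattice-like clustering (γ = 12.3) at nearly
random path lengths (λ = 1.3).

Classifying a synthetic cohort (20 + 20 subjects, groups differing only
in intermediate-band coupling, effect size 0.8):

```python
cs = bn.SyntheticCohortSpec(base=bn.SyntheticSpec(seed=0), n_per_group=20,
                            affected_band="intermediate", effect_size=0.8, seed=1)
subjects = bn.generate_cohort(cs)
mgs = bn.build_cohort_multigraphs([b for _, b, _ in subjects], density=0.15)
cohort = [bn.SubjectMultiGraph(sid, m, lab) for (sid, _, lab), m in zip(subjects, mgs)]
fused = bn.cross_validate(cohort, bn.PipelineConfig(weights_mode="select"), n_folds=10, seed=1)
full = bn.cross_validate(cohort, bn.PipelineConfig(bands=("full",), weights_mode="uniform"),
                         n_folds=10, seed=1)
print(fused.accuracy, full.accuracy)   # 0.975 0.925
```

The fused multi-band kernel (0.975 accuracy, AUC 1.00) beats the
full-band single kernel (0.925, AUC 0.98): the band split preserves
group information that low-frequency dominance hides in the full
signal.

A `bandnet` console command exposes the same stages
(`simulate | decompose | build | algebra | metrics | classify`); run
`bandnet --help`.

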