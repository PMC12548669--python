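# mbnet — stable metabolic brain networks via multiple sampling

Metabolic brain networks (MBNs) are built from PET SUVR tables by
correlating every pair of brain regions (volumes of interest, VOIs) *across
subjects* of a diagnostic group: with `X ∈ ℝ^{N×d}` the group's SUVR matrix,
the network is the Pearson adjacency `M = (r_pq)` over columns of `X`,
thresholded for multiple comparisons.  Because a single spurious subject
enters every edge estimate at once, these networks are notoriously unstable
— outliers, small cohorts and group-size imbalance all reshape them.

`mbnet` implements a multiple-sampling (MS) construction that addresses
this, aimed at researchers analysing FDG-PET (or other radiotracer) group
data:

1. **Ensemble** — draw `n` bootstrap samples `Y¹..Yⁿ` of `X` (or subsamples
   without replacement), and build one Benjamini–Hochberg-FDR-corrected
   Pearson network `Mᵏ` per draw.
2. **Representative** — return the *member* closest (Frobenius norm) to the
   elementwise mean matrix `M = argmin_k ‖Mᵏ − M̄‖_F` (median and
   maximum-density "mode" criteria are also available and empirically
   interchangeable).
3. **Pmap threshold** — record for every edge the fraction of ensemble
   networks in which it survived FDR (the probability map `Ṗ`), and keep
   only edges with `Ṗ_pq > θ`, `θ = 1 − α` (a Hadamard mask on `M`).  This
   occurrence-based second threshold is deliberately more conservative than
   FDR alone.

Stability is quantified by an **outlier attack** protocol: rows sampled
half/half from the other two diagnostic groups are appended to the table
that produced the network (cross-group metabolic patterns differ only
subtly, so such rows evade outlier screening), the network is recomputed,
and the change is measured four ways — Frobenius (`dF`) and Hausdorff
(`dH`) distances between the adjacency matrices, and Euclidean (`dE`) and
Canberra (`dC`) distances between the graph-feature vectors
`f = [ge, ac, ad, as, d, acc]` (global efficiency, assortativity, average
degree, average strength, density, average clustering).  The package also
provides random undersampling and ADASYN oversampling for imbalanced
cohorts, and an ensemble-size (`n`) selection rule based on the
Bhattacharyya distance between degree distributions at `n = k` and
`n = k + 100`.

A synthetic cohort generator (multivariate normal with block-structured
correlation and graded group-level hypometabolia) stands in for clinical
data throughout the test suite.

## Worked example

```python
from mbnet import (AttackConfig, example_cohort_spec, generate_cohort,
                   ms_network, run_attack_experiment)

spec = example_cohort_spec({"CU": 150, "MCI": 150, "AD": 150}, d=30, seed=11)
cohort = generate_cohort(spec)

res = ms_network(cohort["CU"], n=500, alpha=0.01, criterion="mean", seed=42)
print(f"representative member: {res.representative_index} of {len(res.ensemble)}")
print(f"density after FDR:        {res.ensemble.networks[res.representative_index].density():.3f}")
print(f"density after FDR + Pmap: {res.network.density():.3f}")

for method in ("ms_bootstrap", "conventional"):
    cfg = AttackConfig(p_o=2.0, q_attacks=64, method=method, seed=7)
    report = run_attack_experiment(cohort, "CU", ["MCI", "AD"], cfg,
                                   alpha=0.01, n_samples=500)
    m = report.records[["dF", "dH", "dE", "dC"]].mean()
    print(f"{method:13s} mean dF={m.dF:.3f} dH={m.dH:.3f} dE={m.dE:.3f} dC={m.dC:.3f}")
```

prints

```
representative member: 472 of 500
density after FDR:        0.752
density after FDR + Pmap: 0.159
ms_bootstrap  mean dF=0.083 dH=0.035 dE=0.009 dC=0.003
conventional  mean dF=1.712 dH=0.572 dE=1.132 dC=0.422
```

Reading: the Pmap mask prunes the FDR network from 75% to 16% edge density,
keeping only edges present in effectively every bootstrap replicate — and
under 2%-outlier attacks the resulting MS network moves roughly 20× less
than the conventional single-pass network on every distance measure.

The same stages are scriptable from the shell (`mbn generate`, `mbn build`,
`mbn attack`, `mbn balance`, `mbn tune`) or as a YAML-configured pipeline
with a checksummed reproducibility manifest (`mbn run config.yaml`); see
`mbn --help`.

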