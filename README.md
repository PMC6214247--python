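# painmark

Topological markers of pain in time-varying functional connectomes.

`painmark` is a Python toolkit for asking whether the *topology* of a
functional brain network tracks a behavioural signal over time. It was built
around a chronic-neuropathic-pain study design: after a nerve injury, local
field potentials are recorded at a handful of time points (hours to weeks)
from two brain regions — primary somatosensory cortex (S1) and the ventral
posterolateral thalamus (VPL) — through 31 probes. Each recording window
yields an *ensemble* of symmetric weighted adjacency matrices (short-time
functional connectomes), and a Von Frey test gives one behavioural pain
threshold (grams) per time point. The question the toolkit answers: which
topological network measures co-vary with the behavioural pain trajectory,
and is that covariation statistically defensible given how sparse the time
sampling is?

## What it computes

**14 topological measures** per binarized connectome — nine deterministic:

- average node degree `AND = Σᵢ dᵢ / n`
- characteristic path length `CPL = Σ_{i<j} sp_ij / (n(n−1)/2)`
- average efficiency `AE = Σ_{i<j} 2 / (n(n−1)·sp_ij)`
- average clustering coefficient `ACC = (1/n) Σᵢ tᵢ / (kᵢ(kᵢ−1)/2)`
- average closeness centrality `ACCE = (1/n) Σᵢ (n−1)/Σ_j sp_ij`
- average node betweenness `ANBC`, average edge betweenness `AEBC`
- average radiality `AR = (1/n) Σᵢ Σ_{j≠i} (D+1−sp_ij)/(D−1)`
- local-community-paradigm correlation
  `LCP-corr = Pearson(CN, LCL)` over links with more than one common
  neighbour, where `CN` counts the common neighbours of a link's endpoints
  and `LCL` the links among them (the local community)

and five stochastic: small-worldness `σ = (C/C_rand)/(L/L_rand)` and
`ω = L_rand/L − C/C_latt` against degree-preserving random and lattice
nulls, the Clauset-style bootstrap goodness-of-fit p-value for a discrete
power-law degree distribution (accepted when p ≥ 0.1), modularity
`Q = Σ_u [e_uu − (Σ_v e_uv)²]` of the best partition, and structural
consistency (link predictability from first-order eigen-perturbation).

**Correlation analysis.** Per measure, the per-step ensemble means are
interpolated onto an hourly grid with monotone shape-preserving cubic
Hermite interpolation (PCHIP; 382 points for the default 3 h → day 16
schedule) and correlated (Pearson and Spearman) with the equally
interpolated behavioural curve. A dedicated permutation test guards against
interpolation artefacts: M random behavioural 8-tuples are drawn from a
Gaussian (G) or distribution-preserving permutation (DP) null, interpolated
identically, and the two-tailed p-value is
`p = 2·min(#[C_rand ≤ c]/M, #[C_rand ≥ c]/M)`.

**Unsupervised comparison.** The 15 interpolated signals (14 topological +
behavioural) are embedded by PCA (z-scored, sign-aligned) and by Minimum
Curvilinear Embedding — pairwise distances over the Euclidean minimum
spanning tree, factorized by SVD without centering — after quantile
normalization.

**Engram analysis.** Per step the representative connectome (LCP-corr
closest to the step mean) is split into intra-S1 / intra-VPL / inter-region
links, and edge-set intersections between consecutive representatives count
the links retained over time — persistent connectivity read as a memory
trace.

**Synthetic studies.** A generator produces study-shaped data with planted
ground truth: a latent pain trajectory (acute dip at day 4, chronic plateau
from day 11) drives both the behavioural signal and a degree-preserving
rewiring of a community-rich 31-node template, so LCP-corr is a planted
positive marker and average degree a planted negative control.

## Worked example

```python
from painmark import (SyntheticConfig, StudyConfig, generate_study,
                      summary_table, engram_timecourse)

series, truth = generate_study(
    SyntheticConfig(n_matrices_per_step=100, keep_middle=40, seed=1))
table = summary_table(
    series, StudyConfig(measures=("LCPcorr", "CPL", "AND"), M=1000, seed=1))
print(table[["measure", "pearson", "spearman", "max_correlation",
             "max_p", "significant"]].round(3).to_string(index=False))
```

prints

```
measure  pearson  spearman  max_correlation  max_p  significant
LCPcorr    0.933     0.872            0.933  0.000         True
    CPL    0.384     0.161            0.384  0.292        False
    AND   -0.607    -0.588           -0.607  0.144        False
```

The planted marker (LCP-corr) correlates 0.93 with the behavioural curve
and survives both null models (`max_p` is the conservative maximum over G
and DP); path length and the degree control show only chance-level
correlations with non-significant p-values. Adding

```python
counts, retained = engram_timecourse(series)
print([(r.interval, r.count_full) for r in retained])
```

prints

```
[('3 h/4d', 83), ('4d/6d', 96), ('6d/9d', 108), ('9d/11d', 102),
 ('11d/12d', 101), ('12d/15d', 105), ('15d/16d', 105)]
```

— fewer links retained across the acute transition (3 h/4d) than across the
stable chronic plateau, the signature of engram consolidation.

A command-line interface mirrors the library
(`painmark simulate / measure / analyze / embed / engram / report`).

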