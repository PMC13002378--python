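# meanet

Paired-condition analysis of multielectrode-array (MEA) spike recordings,
built for the kind of experiment in which the same hippocampal slice is
recorded under a baseline and a treated condition (for example acute
amyloid-β exposure) and the question is how unit activity and the functional
network it forms reorganize between the two.

Given sorted spike timestamps per unit (single-unit and multi-unit activity),
the library computes, per slice and condition:

- **Unit activity** — firing rates, direction of rate change per unit, and a
  population-burst statistic: the summed raster in 500-ms bins, with events
  defined as local maxima ≥ 5 SD (RMS) above the mean.
- **Cell typing** — K-means clustering of single units in
  (trough-to-peak width, log₁₀ firing rate) space into putative pyramidal
  neurons (broad waveform, lower rate) and putative interneurons (narrow
  waveform, higher rate), with Mann–Whitney comparisons, Cohen's *d*, and a
  chi-square association between cell type and change direction.
- **Functional connectivity** — pairwise spike-time cross-correlograms at
  1 ms over ±50 ms, normalized by √(NᵢNⱼ); a pair is linked when its peak
  (or trough) within the ±5 ms tight-synchrony window exceeds the flank
  (10–50 ms) noise mean by 5 flank-SDs. Signed binary and weighted link
  matrices, and Δ-correlation statistics between conditions.
- **Graph topology** — degree *kᵢ*, average degree *K*, density *ρ*,
  connected components, characteristic path length *l(G)*, clustering *CCᵢ*
  and *C̄C*, betweenness *C_B*, closeness *C_C*, eigenvector centrality *xᵢ*,
  eccentricity, and the degree distribution with its 1–6 / ≥7 bands.
- **Small-world indices** — σ = (C/C_rand)/(L/L_rand) and
  ω = L_rand/L − C/C_latt against ensembles of degree-preserving random
  (double-edge-swap) and lattice (ring-band) null networks.
- **Spectral topology classes** — the Estrada index EE = Σᵢ e^{λᵢ},
  odd-subgraph centrality SC_odd(i) = Σⱼ φⱼ(i)² sinh λⱼ, and spectral
  scaling: each node's vertical log₁₀ distance from the ideal line
  log₁₀ xᵢ = ½ log₁₀[SC_odd(i)/sinh λ_max] classifies it as class I
  (homogeneous, within ±τ), II (structural holes, below) or III (central
  cores, above); networks with both class II and III nodes are class IV.
  The classification runs on the positive weighted correlation matrix with
  τ estimated from the data (RMS distance from the line).

A synthetic-data generator produces paired-condition recordings with known
ground truth — two cell classes, planted community and hub coupling via
jittered common-parent coincidences, a majority-decrease/minority-increase
condition effect, and injected synchrony epochs — so the entire pipeline is
testable end to end without access to any recordings. An LFP synthesizer and
Hann-periodogram band powers (delta/theta/beta/gamma) round out the
activity module.

## Worked example

```python
from meanet import simulate_slice, unit_rates
from meanet.connectivity import connectivity_from_spikes
from meanet.graph_metrics import Graph, network_metrics
from meanet.smallworld import small_world_indices

base, treated, gt_base, gt_treated = simulate_slice(seed=7)
print(unit_rates(base).mean(), unit_rates(treated).mean())

conn = connectivity_from_spikes(base)
G = Graph.from_connectivity(conn, sign="pos")
print(network_metrics(G))
print(small_world_indices(G, n_nulls=100, seed=1))
```

With seed 7 this prints a mean rate of 5.61 Hz baseline against 5.10 Hz
treated (the planted effect: ~60% of units thinned to half rate, ~40%
boosted), and for a seed-3 baseline slice a functional graph with n=64,
m=205, average degree 6.41, density 0.102, path length 3.31 and clustering
0.41 — whose σ = 2.59 and ω = −0.001 mark it as a small-world network
(σ > 1, ω within ±0.3). The `examples/` directory walks through each
capability the same way, one short script per stage:

```bash
python examples/01_simulate_recording.py
python examples/05_estrada_classes.py   # spectral classes I-IV
python examples/06_full_pipeline.py     # the whole study, summarized
```

A thin CLI wraps the same calls (`meanet simulate`, `meanet analyze`,
`meanet connectivity`, `meanet graph`, `meanet smallworld`,
`meanet estrada`), writing CSV matrices, GEXF graphs and JSON reports.

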