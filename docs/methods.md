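# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the pipeline applies them.

## Synthetic recordings

The generator's purpose is to produce paired-condition spike data with the
statistical structure the analysis assumes, with every planted feature
recoverable, so that each downstream stage can be validated quantitatively.

**Baseline trains.** Each unit is a renewal process with dead time: an
inter-spike interval is the refractory period (default 2 ms) plus an
exponential draw whose mean is chosen so the stationary rate equals the
target exactly. This keeps two properties simultaneously that a thinned
Poisson process would trade off: every ISI respects the refractory period,
and the empirical rate is unbiased (a thinned 10-Hz Poisson train loses
~2% of its spikes to refractory deletion).

**Populations.** A slice holds `n_sua` single units (default 60, within the
32–88 per-slice range of the emulated recordings) and `n_mua` multi-unit
channels (default 4). Single units are drawn from two classes: broad-waveform
putative pyramidal cells (78.9% of SUA; trough-to-peak 0.76 ± 0.12 ms, rate
lognormal around 3.2 Hz) and narrow-waveform putative interneurons
(0.22 ± 0.05 ms, around 6.9 Hz); log₁₀-rate SD is 0.25 in both classes. The
class means are the feature centroids the typing stage is expected to
recover; the spreads are set so the waveform axis separates the classes with
a Cohen's *d* near 4 (as observed in CA1 data) while the rate axis overlaps
substantially. MUA channels are superpositions of 2–4 hidden broad-waveform
trains, carry no waveform feature, and are excluded from typing but included
in connectivity.

**Coupling.** Pairwise coupling strength c ∈ [0,1] plants common-parent
coincidences: parent events arrive at c × 1 Hz and each of the two children
receives the parent time plus independent uniform ±0.5 ms jitter, giving a
correlogram peak ~1 ms wide centered at lag 0 — tight, monosynaptic-like
synchrony well inside the ±5 ms analysis window. At this injection rate a
600-s recording detects c = 0.1 pairs with sensitivity ≥ 0.9 at the 5-SD
rule. The baseline study scenario uses a block (community) coupling matrix:
6 communities, within-community pair probability 0.55, between 0.008,
strengths U(0.1, 0.3). These values were fixed once so that a default slice
lands near the emulated baseline network profile (average degree ≈ 6,
density ≈ 0.10, clustering ≈ 0.45–0.49, σ ≈ 3, ω near 0, a class-IV
spectral mix).

**Condition effect.** Directions are assigned per unit (62% decrease, 37%
increase, 1% unchanged). Decreases thin spikes with keep probability 0.5;
increases superpose an independent train at 0.3× the unit's baseline rate;
unchanged units keep their timestamps verbatim. The two scales are free
parameters chosen so the mixture reproduces the observed mean-rate ratio
(0.62·0.5 + 0.37·1.3 + 0.01 ≈ 0.80). Synchrony epochs — `burst_rate_per_min`
(default 1) non-overlapping windows of 100–500 ms in which half the units
fire 25 Hz of extra spikes — are rate elevations, not pasted identical
spikes, so the refractory invariant survives. The epoch count is
deterministic (rate × minutes, randomly placed) so burst-count recovery can
be asserted within ±2.

**Treated coupling.** The treated condition adds hubs: 3 units each coupled
at strength 0.25 to 20 partners recruited from their own baseline coupling
neighborhood (breadth-first tiers), plus re-injection of 15% of the baseline
coupling. Locality matters: hubs recruiting across the whole network bridge
the communities and wash out their spectral signature, whereas local
recruitment matches the emulated phenomenon — strongly local increases in
correlation strength with emergent 20–30-degree nodes — and leaves the
positive-correlation sums statistically flat between conditions (the
re-injection offsets the coincidences lost to thinning).

**What the generator does not emulate.** No biophysics, no electrode
geometry, no waveform synthesis, no oscillatory spike timing, no
common-population (brain-state) rate fluctuations, and negative functional
links arise only from chance troughs (none are planted). Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it models — rates, coincidence coupling, community/hub topology — not that
it would be robust to every artifact of real recordings.

**LFP.** Traces are synthesized directly in the frequency domain: constant
amplitude per requested band scaled so each band's power share equals its
weight, uniform random phases. Band powers of such a trace match the
requested weights essentially exactly, which makes the band-power contract
(10%) easy to audit.

## Activity statistics

Time is milliseconds end to end; raster bins are half-open [t, t+Δ), so a
spike on a bin edge belongs to the later bin and occupied-bin counts never
exceed spike counts. Bursts: the 1-ms raster is re-aggregated to 500-ms bins
by summing occupied fine bins over units; the noise level is the RMS of the
mean-subtracted signal over the whole record (a deterministic reading of
"noise RMS"); events are local maxima — plateaus credited to their first
bin — whose height above the mean reaches 5×RMS. Both burst statistics
(count per minute and mean peak height) are reported, since either reading
of "bursting activity" may be wanted.

Rate-change classification calls a unit unchanged when |Δrate|/baseline
< `rel_tol` (default 0.01; the tolerance is logged in every report — with
near-exact repetition of unchanged units the choice is not critical, and
the emulated data imply near-exact equality for the unchanged group).

Cell typing z-scores (trough-to-peak, log₁₀ rate) and runs K-means (k = 2,
k-means++ seeding, 50 restarts, fixed seed). Cluster labels are anchored to
the feature, not the cluster index: the cluster with the larger mean
trough-to-peak is the pyramidal one. Chi-square association is Pearson
without continuity correction (a Yates-corrected and a Fisher-exact variant
are flags); an expected cell below 1 triggers a warning recommending the
exact test.

Band powers come from a Hann-tapered periodogram of the final 60 s.
Band intervals are half-open [lo, hi) except the topmost band, closed at
50 Hz; broadband spans 0–50 Hz inclusive and equals the four bands plus the
0–0.5 Hz remainder.

Paired comparisons are normality-gated: Shapiro–Wilk on the paired
differences chooses a paired t-test (not rejected at 0.05) or the Wilcoxon
matched-pairs signed-rank test; all-zero differences return the no-change
convention (statistic 0, p = 1), and a constant nonzero shift returns the
degenerate-t convention (p = 0). Kolmogorov–Smirnov is provided separately
for cumulative-distribution comparisons (degree distributions).

## Connectivity

Correlograms are raw coincidence counts of (tⱼ − tᵢ) in 1-ms bins centered
on integer lags over ±50 ms, normalized by √(NᵢNⱼ). This normalization
bounds weights by 1 and makes a self-comparison's lag-0 value exactly 1;
its expected flank level scales with √(rᵢrⱼ), which is why significance is
judged against the flank's own statistics rather than an absolute level.
Flank noise is measured deterministically from lags 10 < |lag| ≤ 50 ms
(mean and SD with ddof = 1). The peak and trough are the extrema within
±5 ms. A positive link requires peak − flank_mean > k·flank_SD (k = 5
default); a negative link is the mirror condition on the trough; if both
cross, the larger absolute excess wins. The stored weight is the normalized
excess over the flank mean (the raw peak height is a flag), clipped into
[0, 1]. Pairs with fewer than 10 spikes on either side are skipped with a
warning — their normalization is unstable. A zero-lag exclusion flag exists
for same-electrode pairs (sorting artifacts); the synthetic data carries no
electrode assignment, so it defaults off.

Δ-correlation uses the signed weighted matrix: per-pair Δ = W_treated −
W_base, pairs split by sign, and the |Δ| distributions of increases versus
decreases compared with Mann–Whitney U (the two groups differ in size, so a
paired test does not apply) plus pooled-SD Cohen's d.

## Graph metrics

Metrics run on the binary positive-link adjacency. Conventions for
disconnected graphs (the realistic case): the characteristic path length
averages hop distances over connected ordered pairs only, with the excluded
fraction reported; closeness is the unnormalized reciprocal of the total
distance to the other nodes of the same component (0 for isolated nodes);
eccentricity is per component; eigenvector centrality is the leading
(Perron) eigenvector of the full adjacency, max-normalized, which
concentrates on the dominant component — flagged in the docs rather than
silently averaged. Betweenness is unnormalized, endpoints excluded, each
unordered pair counted once. Degree-band summaries report the mean number
of nodes per degree value within 1–6 and within ≥7 (up to the maximum
degree present).

## Small-world nulls

Both null models preserve n, m and the degree sequence. Random nulls: 10·m
accepted double-edge swaps. Lattice nulls: a ring-band construction — nodes
keep ring positions, edges are placed at circular distance 1, 2, …
while both endpoints have remaining degree (random visiting order per
null), leftover stubs repaired by degree-preserving rewiring. A swap-based
latticization (greedy or annealed) was tried first and rejected: on
Watts–Strogatz graphs it stalls in local optima with C_latt below the
source clustering, which inverts ω; the band-fill construction reproduces a
ring lattice exactly and reaches near-optimal banding for arbitrary degree
sequences in milliseconds. σ = (C/C_rand)/(L/L_rand) and ω = L_rand/L −
C/C_latt, with C_rand, L_rand, C_latt ensemble means; ω is clipped into
[−1, 1] with a warning. The production default is 1,000 nulls; tests and
the acceptance script use 100, where doubling the ensemble changes σ by
well under 2% on a Watts–Strogatz benchmark.

## Spectral classification

Estrada index and centralities come from a full symmetric
eigendecomposition (`numpy.linalg.eigh`); the spectral identity
Σᵢ SC(i) = EE holds to 1e-9 relative precision. The scaling classification
runs on the positive weighted matrix: x is the Perron eigenvector
(unit norm — the norm under which the ideal relation
xᵢ ≈ √(SC_odd(i)/sinh λ_max) holds), residuals are vertical log₁₀
distances from the slope-½ ideal line, and the class-I band is centered on
the line with half-width τ equal to the root-mean-square residual
("sd" mode; the "variance" mode squares it, with the caveat that squared
log-units make the band dimensionally inconsistent — it is kept as a flag
because the emulated analysis printed "variance"). Measuring τ about the
line rather than about the residual mean is deliberate: it preserves the
class semantics (a network whose nodes all sit below the line is
structural-hole dominated, class II, not "on average fine"), and it makes
regular connected non-bipartite graphs exactly 100% class I (all residuals
equal ⇒ |r| = τ, a boundary case padded by 1e-9). Nodes with SC_odd or
eigenvector weight ≤ 1e-12 are unclassified and reported; a fully
unclassifiable matrix (bipartite: sinh terms cancel) raises an explicit
error. Network classes: IV when both class-II and class-III shares reach
5%, II or III when only one does, I otherwise; the CII/CIII ratio is absent
when no class-III node exists. One known consequence of the
band-about-the-line choice: dense Erdős–Rényi graphs classify roughly
two-thirds class I rather than the ~70%+ a mean-centered band would give —
the archetype semantics were judged more important than the homogeneous-case
percentage.

## Pipeline

Per slice and condition the stages run in order (activity → connectivity →
graph → small-world → spectral classes); slices are the statistical unit
for network endpoints, compared with the normality-gated paired test;
class-IV network counts get Fisher's exact test; pooled degree
distributions a KS test. No multiple-testing correction is applied by
default (a Benjamini–Hochberg flag exists and is off, matching the emulated
reporting convention); every reported p carries the test that produced it.
Reports are nested dicts serialized deterministically; the provenance block
records the seed, a config hash and the parameters. Problem sizes in the
test suite and acceptance script — 5 slices of ~64 units × 600 s, 100-null
ensembles, 50-graph oracle batteries — were chosen as the smallest sizes at
which every recovery contract (sensitivity, false-positive rate, fraction
tolerances) is comfortably measurable.

## Known limitations

- The generator's coincidence model produces positive coupling only;
  negative-link handling is exercised mainly by construction-level tests.
- Eigenvector centrality of a graph with near-degenerate leading
  eigenvalues (two equal disconnected components) is not unique; the
  implementation returns eigh's leading vector and flags the convention.
- The spectral classification of very sparse weighted matrices leaves
  isolated or near-isolated nodes unclassified; their share is logged.
- Burst detection merges synchrony epochs that straddle one 500-ms bin
  boundary into a single local maximum, so recovered counts can undershoot
  the planted count by 1–2 at the default rate.
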