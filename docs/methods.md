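# Methods

## Drug-likeness screen

QED is computed from the eight-descriptor vector through the published
asymmetric double-sigmoid desirability functions, shipped as versioned
constants in `netpharm.admet.ADS_PARAMS`; nothing is fitted at runtime.
Each desirability d(x) = (a + b·s₁(x)·(1−s₂(x)))/d_max is max-normalised so
the modal value scores 1, and descriptors combine as
exp(Σ wᵢ ln dᵢ / Σ wᵢ). The default is the unweighted geometric mean
(wᵢ = 1); the published mean-optimal weight set is selectable with
`weights="mean"`. Both variants are in the literature and the screen's
source tables do not say which was used, so the simpler one is the default
and the test suite cross-checks both against an independent implementation
(RDKit's QED module) to 1e-9 relative.

Veber's rule is applied with all three boundaries inclusive
(ROTB ≤ 10, HBA+HBD ≤ 12, PSA ≤ 140 Å²), exactly as printed in the source
screening protocol. A compound is an EAC iff QED ≥ `qed_min` (default 0.3)
and Veber passes.

## Target mapping

Gene symbols are normalised by uppercase+trim with first-seen-wins
deduplication (deterministic output; collisions logged). The published
protocol removes "false-positive targets" without defining them; since
target predictors emit a probability per prediction, this is implemented as
a `min_probability` filter with default 0 — i.e. keep everything predicted
with positive probability. The relevance cutoff `"mean"` is the arithmetic
mean of the *intersected* gene scores (the protocol does not say whether
the mean was taken before or after intersection; after-intersection is the
default because the printed cutoff is described alongside the intersected
list, and an explicit numeric cutoff is accepted for either reading).

## PPI topology

Edges at combined score ≥ 0.7 (high confidence) form an undirected simple
graph; duplicate orientations collapse keeping the maximum score.
Centrality conventions follow Cytoscape's network analyzer, which produced
the values this procedure is calibrated against: betweenness is shortest-path
betweenness normalised by 2/((n−1)(n−2)) with endpoints excluded; closeness
is 1 / mean distance to *reachable* nodes (component-restricted), 0 for
isolated nodes. The Wasserman–Faust global form is available via
`closeness="wf"`. Key-target thresholds (degree ≥ 10, betweenness ≥ 0.001,
closeness ≥ 0.430, all inclusive) are applied to the potential-target
network; centralities are then recomputed on the induced key-target
subnetwork, which is exposed as a separate step because published per-node
tables of this kind report post-subnetwork values (their degree sums obey
the handshake lemma for the subnetwork edge count).

## Pathway enrichment

Plain one-sided hypergeometric tail P[X ≥ k] (Fisher over-representation);
the DAVID-style EASE variant (tail at k−1) is available by flag but is not
the default, being non-standard outside that tool. Background N defaults to
20,000 protein-coding genes and is configurable; an explicit background
gene list restricts query and pathways before testing. BH-FDR is the
standard step-up (statsmodels-backed). Ranking is ascending p, ties broken
by descending overlap then pathway id, and "top 20 by p-value" is the
default report. Note that re-applying the BH adjustment to an
already-adjusted vector is *not* a no-op (each pass multiplies non-maximal
entries by a further m/rank factor); only dominance over raw p, the cap at
1 and order preservation are invariants of the adjustment.

## Integrated H-C-T-P network

Herb–compound, compound–target and target–pathway edges assemble into a
multipartite graph; within-layer or layer-skipping edges are structural
errors. Compound degree counts edges from both neighbouring layers (one
herb link plus the key-target links — consistent with published key-component
degrees), configurable to targets-only by ranking on a compound–target-only
subgraph. EAC with zero key-target links are dropped before ranking, which
is why the network can contain slightly fewer compound nodes than the EAC
list. Key components are the max-degree tie class by default (`top="max-tie"`),
or a fixed top-k.

## Mass identification

Calculated [M-H]⁻ m/z = Σ count × monoisotopic element mass − 1.0078250319.
The neutral-hydrogen convention (no electron-mass term) is the default
because it reproduces instrument-software "calculated m/z" columns to four
decimals; `electron_correction=True` adds +0.00054858 Da for the strict
ion-mass convention. ppm error is signed: (obs − calc)/calc × 10⁶. Peak
matching is exhaustive within a symmetric ppm tolerance; unmatched peaks
are reported with null candidate fields rather than dropped.

## Dose-response

The inhibition model is the four-parameter logistic
y = bottom + (top−bottom)/(1+(c/IC50)^slope), fitted by bounded
least squares on log₁₀ concentration (bottom ≥ 0, top ≤ 110 %,
slope ∈ [0.1, 10], log-IC50 within ±2 decades of the tested range).
Initialisation is data-driven — bottom/top from the per-concentration mean
extrema, IC50 from the first concentration whose mean crosses the
half-range, slope 1 — so fits are deterministic and IC50 is equivariant
under rescaling of the concentration axis. Series with fewer than 4
distinct concentrations or a flat response raise a fit error instead of
returning a spurious IC50, and a fit whose IC50 lands at the search
boundary is flagged unconverged.

Percent inhibition is (agonist − treated)/(agonist − baseline) × 100,
defined only when the agonist response exceeds baseline; negative values
clip to 0 with a warning. Significance against the vehicle control uses
Welch's unequal-variance t-test (two-sided) by default — robust to the
small-n unequal-variance setting of 4-replicate aggregometry — with a
Mann–Whitney option; stars are assigned at p < 0.05 (*) and p < 0.001 (**).
Two identical constant samples return p = 1 by convention.

## Synthetic data generator

The generator emulates a study of the motivating design: 9 herbs,
119 compounds, a 400-gene universe, 300 disease genes, 110 pathways
(sizes 10–40), 4 planted key compounds, 5 planted hub targets, and
dose-response at 6 log-spaced concentrations (1–100 µM) with 4 replicates
and 2% Gaussian noise truncated to [0, 100] — replicate count and noise
scale chosen to match mean ± SD error bars typical of washed-platelet
aggregometry. Design choices:

* **Descriptors** are drawn uniformly inside drug-like ranges; designated
  disjoint fractions (`frac_fail_qed`, `frac_fail_veber`, default 0.1 each)
  are forced out of range (huge MW/ALOGP/ALERT for QED failures; one Veber
  violation for Veber failures) so both screen branches are exercised and
  the EAC count is exactly predictable.
* **Relevance scores** are lognormal(0, 1), so the mean cutoff retains a
  minority of genes, matching the right-skew of real disease-relevance
  exports. Planted signal genes get scores inflated above the 90th
  percentile so they always survive the cutoff.
* **PPI** is a Barabási–Albert preferential-attachment graph (m = 3) over
  the disease genes; each planted hub is additionally wired to 30% of all
  nodes, guaranteeing the hubs top the degree distribution while the
  heavy-tailed background makes the degree threshold meaningful.
* **Planted compounds** target all signal genes (hubs + the highest-degree
  attachment nodes) with probabilities ≥ 0.7; background compounds get 2–6
  random targets. The planted pathway contains every signal gene plus
  random padding; other pathways are random draws.
* **Randomness** flows from one root seed through named substreams (one per
  table, fixed indices), so bundles are byte-identical under a fixed seed
  and changing one table's logic leaves the rest untouched.

What the generator does *not* emulate: real chemistry (SMILES are blank in
synthetic mode), real gene nomenclature, correlated descriptors,
assortative or modular PPI structure, overlapping pathway hierarchies, or
heteroscedastic assay noise. Passing the planted-recovery tests therefore
shows the pipeline's selection logic is correct and well-calibrated on
heavy-tailed networks with clean planted signal — not that the thresholds
are optimal for any particular real dataset.

## Problem sizes in the test suite

Property tests use the default generator configuration over 100 seeds
(planted-pathway ranking), 20 seeds (end-to-end key-compound recovery),
50 seeds (noisy IC50 recovery), 10,000 simulations (Welch type-I
calibration), 200 random ≤8-node graphs (centrality oracle) and the full
parameter lattice N ≤ 25 (hypergeometric oracle); the complete suite runs
in well under a minute on one CPU.

## Known limitations

* QED descriptor computation from SMILES is out of scope; descriptors come
  from the input table (SwissADME-style export).
* Only the [M-H]⁻ adduct is registered; the registry is extensible.
* The 4PL fitter assumes a monotone inhibition curve; biphasic responses
  are not modelled.
* Enrichment treats pathways as flat gene sets (no topology, no GO).
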