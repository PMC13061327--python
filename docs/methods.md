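# Methods

## Model overview

The package simulates a growing 3D population of cells, each carrying a
stochastic three-gene regulatory network, inside a cubic domain of edge
80 spatial units (1 unit = 6.4 µm). The model couples three scales:

1. **Molecular.** Per gene *i* ∈ {CD133, SYP, CyclinE}, mRNA and protein
   *amounts* (M_i, P_i) follow a bursty piecewise-deterministic Markov
   process: between bursts M_i′ = −d₀M_i and P_i′ = s₁M_i − d₁P_i, solved
   in closed form (never by Euler stepping); bursts add an
   Exponential(mean 50) jump to M_i and arrive at rate
   k_on = k₀ + (k₁−k₀)·(1+e^{−σ})⁻¹ with
   σ_i = β_i + Σ_j θ(j→i)·P_j, plus the signaling term for CD133 only.
   State is stored as amounts rather than concentrations so that halving at
   division is exact and conservative.
2. **Cellular.** Cells are visco-elastic spheres with a rigid core
   (core/shell radius ratio 0.5). Volume grows linearly and is capped at
   2.2; a cell divides when volume ≥ 2 *and* P_CyclinE ≥ 0.01. Daughters
   take half the volume and half of each molecular amount, are placed
   symmetrically at ± half a daughter radius along a uniform random
   direction, and each daughter's fate is set by P_CD133 ≥ Th (stem) at
   division only; type never changes between divisions. There is no cell
   death.
3. **Population.** Each tick of dt = 0.1 h: contact detection → signaling
   terms (from start-of-step state) → per-cell PDMP advance → growth →
   divisions with event logging → movement, overlap relaxation and
   reflexive boundary handling. Runs start from 15 stem founders packed at
   the domain center (P_CD133 = 2·Th, M_CD133 ~ Exp(50), everything else 0)
   and stop when the population exceeds the configured count.

## Signaling

*Contact*: a stem cell with at least one stem contact neighbor receives
S = 1 and the term γ·S enters σ_CD133. Emission and perception are both
stem-only.

*Diffusive*: stem cells emit Gaussian plumes; the perceived signal is the
Gauss transform S_diff = Σ_j q·e^{−‖l−h_j‖²/δ} over stem sources, including
the autocrine self-term (configurable). δ, the "reachable area", is the
squared length scale: δ = 2 units² corresponds to e⁻¹ attenuation at
≈ 9 µm, i.e. roughly first-neighbor range. Perception is restricted to stem
cells by default (a flag allows all-cell perception for sensitivity
analysis). The fast evaluation truncates the kernel at a cutoff radius and
*certifies* the result: the neglected tail is bounded by
(excluded strength)·e^{−r_c²/δ}, and the cutoff is enlarged per target until
that bound is below ε times the retained sum (ε = 0.01 by default), falling
back to the exact direct sum in the worst case. The signal is recomputed
every tick from current positions and types (quasi-static kernel, no PDE
relaxation lag).

## Mechanics

Forces, stiffnesses and damping are modeling choices here (the behavior,
not a specific force law, is the constraint): overlapping pairs receive
symmetric central displacements from a linear spring on the external-radius
overlap plus a 10× stiffer spring on rigid-core overlap, applied in
overdamped sweeps (≤ 20 per tick) until the worst core overlap is below
10⁻³ units. In the default "mobile" mode this relaxation is the only source
of motion — cells move because growth and division push them. In "motile"
mode cells additionally self-propel at 0.3 units/h along a persistent
heading, re-drawn on contact events and reflections, with contact-class
speeds (S-S / S-D / D-D) acting as a differential-adhesion surrogate; the
S-D speed applies symmetrically to both partners of a mixed contact.

Pair search uses a cell-list grid (near-linear cost) with a 0.2-unit skin
so one pair list serves contact detection, signaling and relaxation within
a tick; at divisions the list is extended incrementally (a newborn second
daughter inherits its mother's neighborhood plus the sibling pair), which
is valid because daughters are born inside the mother sphere, within the
skin margin.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| d₀ | 1 (all genes) | h⁻¹ | mRNA turnover fast relative to protein |
| d₁ | 0.001 (CD133), 0.01 (SYP, CycE) | h⁻¹ | CD133 protein long-lived |
| s₁ | 0.01·d₁ | h⁻¹ | fixes the protein amount scale |
| β | −3 (CD133), −5 (SYP, CycE) | – | basal activity |
| θ | toggle: ±15/−40; SYP→CycE 250; CD133→CycE −2 | – | interaction matrix |
| burst mean | 50 | molecules | exponential burst size |
| k₀, k₁ | 0, 1 (all genes) | h⁻¹ | see below |
| growth rate g | 0.05 | volume/h | ≈ 20 h volume doubling; see below |
| Th | 0.003–0.004 | protein amount | differentiation threshold (scanned) |
| proliferation threshold | 0.01 | protein amount | Cyclin E gate |
| γ | 0.3 | – | contact-signal strength |
| q, δ, ε | 0.3, 2, 0.01 | –, units², – | diffusive signal |
| dt | 0.1 | h | tick length |
| domain L | 80 | units | 512 µm cube |

**Burst-frequency bounds k₀/k₁.** The minimum and maximum burst frequencies
are not published; we fix k₀ = 0 and k₁ = 1 h⁻¹ for every gene as
documented defaults. This choice is order-of-magnitude consistent with the
protein thresholds: at full activation a gene delivers
k₁·T·s₁·(burst mean)/d₀ ≈ 0.01 protein units over a 20 h cell cycle,
matching the 0.003–0.01 threshold scale. All quantitative outputs that
involve absolute rates (notably the de-differentiation percentages and the
degree of stem clustering) are sensitive to this choice; the package's
results should be read with that caveat.

**Growth rate.** Never stated; 0.05 volume/h gives a ≈ 20 h growth phase.
The effective cycle time is longer because Cyclin E gating dominates:
differentiated cells (high SYP → high Cyclin E burst rate) cycle in a few
tens of hours while stem cells divide several-fold more slowly, which is
the intended phenotype of the θ matrix.

## Spatial statistics

Sections are planes z = z_fraction·L; a cell belongs to a section when its
sphere intersects the plane, and coordinates are exported in µm. The four
indices and their conventions:

* **Percentage**: 100·N_S/N_t.
* **Moran's I**: binary stem labels, neighbors at ≤ 15 µm, w_ii = 0, rows
  normalized to sum 1; isolated cells keep zero rows (they stay in N and in
  the variance but drop from the numerator, and the weight total counts
  only live rows). Under random permutation of labels its mean is
  −1/(N−1), which the tests verify.
* **Entropy**: Shannon entropy (natural log) of the stem–stem pairwise
  distance histogram with 64 equal-width bins over [0, D], D the diameter
  of the full point pattern (chosen over the bounding-box diagonal so the
  index is invariant under rigid motions). The experimental band for this
  index depends on an unknown binning convention, so entropy-based
  classification is calibration-sensitive and is exercised only through
  property tests.
* **Centrality**: mean stem-to-center distance over mean
  differentiated-to-center distance, with the center defaulting to the
  centroid of all cells (robust to image framing; a bounding-box option
  exists).
* **aSS intra-coefficient**: focal-cell-excluded neighborhood counts,
  boundary-inclusive (≤ r) like the Moran neighbors; the 0/0 ratio of an
  isolated focal cell counts as 1. The normalization identity — mean aSS
  over random labelings equals 1 — is exact only when no neighborhood is
  empty; isolated cells bias the permutation mean upward through the 0/0
  convention (a property test documents the direction). Tissue sections
  are confluent, so the identity's precondition holds in the intended
  regime. The null variance of aSS is estimated by uniform label
  permutations with fixed stem count (default 1,000) rather than by an
  analytic formula, and the band is the Chebyshev-style
  [1−q, 1+q] with q = √(σ²/α), guaranteeing ≥ 1−α coverage (hence
  conservative: the observed null rejection rate is well below α).

## Synthetic patterns

The generator emulates the tabular shape of QuPath cell-detection exports:
~2,500 cells on a ~450 µm field (the observed mean section holds
2,548 ± 336 cells of radius ≈ 4.5 µm), stem fractions of a few percent, and
three label structures — random (i.i.d. labels; the null model), clustered
(a fixed stem count assigned preferentially near Gaussian cluster centers)
and dispersed (stem–stem separation enforced greedily). Labels are assigned
on a *fixed* uniform point set so the generators manipulate only label
autocorrelation, not point density — exactly the quantity the indices
measure. What the generators do **not** emulate: staining artifacts,
segmentation errors, anisotropic cell shapes, density gradients across a
section, and edge effects of real tumoroids; tests passing on these
patterns validate the statistics and their null behavior, not the
biological realism of any particular section.

## Problem sizes and numerical choices

Simulations in the test suite and the acceptance script run to a
10,000-cell stopping population (the full-scale stopping rule of 50,000
cells is exercised once, as a long-running integration check of the
cross-section cell count); replicate counts are 3 (tests) or 5 (acceptance
script). With the default kinetics a 10,000-cell run covers ≈ 1,200–1,500
simulated hours. Scaled-down runs carry a caveat: the 15 stem founders sit
at the domain center, and their legacy cluster is proportionally larger in
a 10,000-cell tumoroid than in a 50,000-cell one, which inflates
central-section Moran's I in scenarios without spatial rules and adds
seed-to-seed variance everywhere.

Other numerics: burst clocks are exponential at rates held constant between
events and recomputed after every burst and at tick boundaries; per-cell
clock draws happen in fixed gene order for reproducibility. The relaxation
flow uses the analytic d₀ = d₁ limit where needed. Coincident cell centers
break ties along a fixed axis in the overlap relaxation. Reflection at the
domain boundary folds positions back inside (repeatedly, to handle large
excursions) and re-randomizes motile headings. One seeded generator drives
initialization and division placement; a separately seeded stream (derived
from the same run seed) drives the compiled PDMP kernel; identical
seed + config reproduces runs bit-for-bit.

## Known limitations

* k₀/k₁ are assumed, not measured; absolute rates inherit that uncertainty
  (see above).
* No cell death, no cell-cycle structure beyond the Cyclin E gate, no
  extracellular matrix, no mechanical feedback on fate.
* The entropy index's experimental band cannot be matched without the
  original binning convention; classification on that index is a
  convention, not a measurement.
* The mechanics constants (spring stiffnesses, sweep limits) are behavioral
  choices; packing fractions, and therefore section cell counts at a given
  population size, depend on them.
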