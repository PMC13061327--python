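# tumoroid

A multiscale agent-based model of cancer stem-cell patterning in
neuroblastoma patient-derived tumoroids, together with the spatial
statistics needed to compare simulated cross-sections with
immunohistochemistry-derived cell tables.

## The scientific problem

Neuroblastoma tumoroids contain a small CD133⁺ stem-cell subpopulation
embedded in a majority of SYP⁺ (synaptophysin) differentiated cells, and in
histological sections those stem cells are spatially *clustered*, not
randomly scattered. This package asks: which cell-level rules are
sufficient to produce that spatial structure? It implements

* **a per-cell stochastic gene network** — a bursty piecewise-deterministic
  Markov process over three genes (CD133, SYP, Cyclin E). mRNA *Mᵢ* and
  protein *Pᵢ* relax deterministically (*Mᵢ′ = −d₀Mᵢ*, *Pᵢ′ = s₁Mᵢ − d₁Pᵢ*)
  between transcriptional bursts of exponential size (mean 50 molecules)
  that arrive at rate *k_on = k₀ + (k₁−k₀)/(1+e^{−σ})*, where
  *σᵢ = βᵢ + Σⱼ θⱼᵢ Pⱼ (+ signal)*. CD133 and SYP form a toggle switch
  (mutual repression −40, self-activation 15); SYP strongly activates
  Cyclin E (+250), which gates division — so differentiated cells cycle
  faster than stem cells.
* **cell agents in 3D** — soft spheres with a rigid core in an 80-unit cube
  (1 unit = 6.4 µm). Cells grow linearly, divide once volume ≥ 2 and
  Cyclin E protein ≥ 0.01, split volume and molecular content exactly in
  half, and each daughter is assigned stem/differentiated fate by comparing
  its CD133 protein with a threshold *Th*. A differentiated mother whose two
  daughters are both stem is a *de-differentiation* event.
* **stem-cell signaling** — either a binary stem–stem contact signal of
  strength γ, or a nonlocal diffusive signal: every stem cell emits a
  Gaussian plume and perceives the Gauss transform
  *S_diff = Σⱼ qⱼ e^{−‖l−hⱼ‖²/δ}* over stem sources (δ is the "reachable
  area"; evaluated with a certified fast cutoff scheme, relative error
  ≤ 0.01). Both signals act only on the CD133 burst rate.
* **spatial statistics on 2D sections** — stem percentage, Moran's *I*
  (binary labels, row-normalized weights, 15 µm neighbor radius), Shannon
  entropy of the stem–stem distance histogram, the stem/differentiated
  centrality ratio, and the aSS intra-coefficient
  *aSS = (N_t−1)/(N_S(N_S−1)) Σᵢ N_S(Cᵢ,r)/N_t(Cᵢ,r)* with a permutation
  confidence band — classified against the experimentally observed ranges.
* **synthetic section generators** — random / clustered / dispersed labeled
  point patterns in the geometry of the histology sections, so every
  statistic is testable without any image data.

## Worked example

```python
from tumoroid import SimulationConfig, run
from tumoroid.cell_agents import FateConfig
from tumoroid.simulator import dedifferentiation_fraction
from tumoroid.spatial_stats import cross_section, stem_percentage, morans_I

cfg = SimulationConfig(
    scenario="diffusive",          # short-range Gaussian stem signal
    stop_count=10_000,             # desk-scale stopping rule
    seed=2,
    fate=FateConfig(differentiation_threshold=0.004),
)
res = run(cfg)
table = cross_section(res.population, 0.5)   # central z-section, µm units
print(f"{len(res.population)} cells after {res.final_time:.0f} simulated hours")
print(f"de-differentiation: {dedifferentiation_fraction(res):.2f}% of divisions")
print(f"section: {len(table)} cells, {stem_percentage(table):.1f}% stem, "
      f"Moran's I = {morans_I(table):.3f}")
```

Output from this exact configuration:

```
10003 cells after 1183 simulated hours
de-differentiation: 3.18% of divisions
section: 631 cells, 6.5% stem, Moran's I = 0.091
```

The de-differentiation rate sits in the experimentally plausible few-percent
range and roughly doubles relative to contact-only signaling; the section's
stem percentage falls inside the observed histology band (2.8–11.2%).

The numbered scripts under `analysis/` reproduce the full study at desk
scale: `01_simulate_scenarios.py` runs the three signaling scenarios and
saves cross-sections and division logs under `results/`;
`02_spatial_indices.py` and `03_dedifferentiation.py` tabulate the four
indices and the de-differentiation rates; `04_ass_scan.py` computes aSS
curves with confidence bands; `05_reachable_area_scan.py` sweeps the
diffusive length scale δ.

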