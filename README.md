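# ribodrop

Simulation and analysis of fluorescence-activated droplet sorting (FADS)
screens for **cell-free riboswitches**.

Riboswitches — ligand-responsive RNA elements in a transcript's 5′ UTR —
can be engineered directly in cell-free protein synthesis (CFPS) systems
by expressing a degenerate library in water-in-oil droplets (one DNA-coated
magnetic bead per droplet, Poisson-loaded) and sorting droplets on two
fluorescence channels: a ROX molecular beacon that marks transcriptionally
active droplets, and a split-GFP reporter that reads out the riboswitch
output. Alternating ON-sorting (ligand present, keep the brightest GFP)
and OFF-sorting (no ligand, keep the dimmest) enriches true switches from
libraries of >5000 variants. Each cycle's pool is barcoded and sequenced,
and variants are ranked by their **enrichment trend**.

`ribodrop` is for computational scientists who want to simulate such
screens (to choose loading rates, gate sizes, round counts, sequencing
depth) and to analyze their sequencing output.

## The model and the statistic

- **Encapsulation.** Beads per droplet `K ~ Poisson(λ)`; occupancy
  `P(K≥1) = 1 − e^{−λ}`, monoclonality `P(K=1 | K≥1) = λe^{−λ}/(1−e^{−λ})`.
  Working at ≤30% occupancy keeps ≥70% of droplets empty. Optional bead
  aggregation is modeled as geometric clumps that preserve the mean λ.
- **Dose response.** Each variant's expression follows a Hill curve
  `y(c) = y_off + (y_on − y_off)·c^h/(EC50^h + c^h)`; the split-GFP
  detector saturates summed droplet expression at a ceiling, which
  compresses (never inflates) measured ON/OFF ratios.
- **Gating.** The ROX floor is set from the empty-droplet cluster; the GFP
  threshold is the quantile of the ROX-positive population such that the
  gate holds at most a cap (≤10%, typically ~3%) of *all* droplets.
- **Enrichment trend.** With per-cycle percentage abundances
  `y_0, …, y_C` (cycle 0 = unsorted library), each variant's score is the
  ordinary least-squares slope of `y` against the cycle index; variants
  are ranked by descending slope.
- **Post-screen arithmetic.** Expression is normalized as
  `(GFP/ROX)_sample / (GFP/ROX)_control`; dose responses are corrected for
  nonspecific ligand effects as a ratio of ratios
  `(v_c/v_0)/(ctrl_c/ctrl_0)` at each concentration before Hill fitting;
  mock sorts report efficiency, purity, and droplet- vs template-level
  fold enrichment.

## Worked example

Simulate a 4-round alternating screen of the 5376-variant histamine ON
library with 1% planted switches, then rank variants by enrichment trend:

```python
import ribodrop as rd
from ribodrop.droplet_sim import (EffectParams, alternating_schedule,
                                  assign_phenotypes, simulate_screen)
from ribodrop.enrichment import rank_variants

design = rd.HISTAMINE_ON_DESIGN
print("variants:", rd.design_space_size(design))          # variants: 5376

phenotypes = assign_phenotypes(design, planted_fraction=0.01,
                               effect_params=EffectParams(ratio_range=(8, 20)),
                               seed=11)
pool = {v: 1.0 for v in phenotypes}
history = simulate_screen(pool, alternating_schedule(4, on_conc=5.0),
                          phenotypes, seed=1)
ranked = rank_variants(history.abundance_frame())
print(ranked.head(5).to_string(index=False))
```

```
variant_id    slope  cycles_detected  final_abundance  rank
    CGGCTA 1.513981                5         5.171834     1
     CTCCA 1.408156                5         5.615711     2
    CGCGGG 1.181326                5         3.423230     3
    GTCTGT 1.053908                5         2.374067     4
    CCCGAT 0.646546                5         1.714977     5
```

The slope is in percentage points of read abundance per sorting cycle;
`CGGCTA` rose from 0.019% (1/5376 of the input library) to 5.2% of reads
by cycle 4. In this run all 20 top-ranked variants are planted switches.

The two-template mock experiment (5:95 strong/weak-RBS mixture, clumped
bead loading) reproduces the gap between droplet-level and template-level
enrichment caused by multi-bead droplets:

```python
from ribodrop.droplet_sim import simulate_mock
r = simulate_mock(minor_fraction=0.05, sort_for="ON", seed=0)
print(f"purity {r.purity:.1f}%  droplet {r.droplet_enrichment_fold:.0f}x  "
      f"template {r.template_enrichment_fold:.0f}x")
# purity 82.2%  droplet 49x  template 9x
```

A thin CLI mirrors the common analyses: `ribodrop rank`, `ribodrop
dose-fit`, `ribodrop mock-metrics` (see `--help`).

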