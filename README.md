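# adipotrace

Quantification toolkit for Cre/lox lineage-tracing experiments that ask
whether the proliferative cells appearing in "dedifferentiated adipocyte"
(DFAT) cultures actually come from adipocytes.  In *Adipoq:Cre* reporter
mice, adipocytes and their descendants irreversibly switch from tdTomato to
GFP; imaging a culture then splits every cell into an adipocyte-derived
(GFP⁺) and a non-adipocyte (GFP⁻) lineage, and an S-phase/mitosis marker
(EdU or phospho-histone H3) tells which lineage is proliferating.

The package provides:

* `adipotrace.simulate` — a synthetic microscopy generator (four channels:
  nuclear stain, GFP, RFP/tdTomato, proliferation marker) with exact
  per-cell ground truth, emulating both nuclear (nT/nG) and membrane (mT/mG)
  reporter geometries;
* `adipotrace.segmentation` — nuclear segmentation from the DNA counterstain
  (Otsu threshold, distance-transform watershed) and per-nucleus
  measurement: mean GFP/RFP, integrated marker, nGFP/nTomato ratio;
* `adipotrace.quantify` — fixed-cutoff gating (one gate per experiment),
  per-well counts and percentages, mean ± SEM and Student t tests across
  replicate wells, timecourse tables;
* `adipotrace.popmodel` — the two-compartment composition model

      adipocyte_{n+1} = adipocyte_n · s
      other_{n+1}     = other_n · s · (1 + 24/T_d)

  (equal daily survival *s*, doubling time *T_d* in hours), its closed-form
  fraction f_n = f₀gⁿ/(f₀gⁿ + 1 − f₀), the exact inversion for the minimal
  initial proliferative fraction, and doubling-time sweeps;
* a CLI (`adipotrace simulate|segment|gate|summarize|stats|model|run`) tying
  the stages into reproducible, manifest-logged runs.

## Worked example

```python
from adipotrace.popmodel import (
    PopulationModelParams, simulate_composition, minimal_initial_fraction,
)

params = PopulationModelParams(
    survival=0.99, division_time=24.0, adipocyte_0=99.0, other_0=1.0, n_days=26,
)
traj = simulate_composition(params)
print(f"day-26 proliferative fraction: {traj.final_fraction_pct:.4f}%")
print(f"minimal initial fraction for 95%: "
      f"{100 * minimal_initial_fraction(0.95, 24.0, 26):.2e}%")
```

prints

```
day-26 proliferative fraction: 99.9999%
minimal initial fraction for 95%: 2.83e-05%
```

i.e. a 1 % proliferative contaminant overgrows a post-mitotic culture almost
completely within 26 days, and the contamination needed to reach 95 % is
orders of magnitude below 1 % — culture overgrowth is no evidence of
adipocyte cell-cycle re-entry.

The imaging side, end-to-end on synthetic data:

```python
from adipotrace.simulate import SimulationConfig, simulate_field
from adipotrace.segmentation import segment_nuclei, measure_nuclei
from adipotrace.quantify import GateConfig, gate_cells, summarize_wells

field, truth = simulate_field(SimulationConfig(seed=7))   # 60 cells, ~6% GFP+
labels = segment_nuclei(field.channel("nuclear"))
records = gate_cells(measure_nuclei(labels, field), GateConfig())
(summary,) = summarize_wells(records)
print(summary.n_total, summary.n_gfp_pos, summary.n_marker_pos_in_gfp_pos)
```

prints `60 3 0`: all 60 nuclei recovered, a small GFP⁺ minority, and no
marker-positive cell in the adipocyte-derived lineage (the generator's
default confines proliferation to GFP⁻ cells).

Command-line equivalent of the model:

```bash
adipotrace model --f0 0.01 --n-days 26 \
    --division-time 24 --division-time 48 --division-time 72 \
    --outdir out/ --plot out/sweep.png
```

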