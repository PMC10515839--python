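# wormcircuit

Analysis toolkit for studying how "undead" neurons — cells that escape
programmed cell death (PCD) in *C. elegans* cell-death mutants such as
*ced-3* — integrate into circuits and alter behavior.  It bundles the four
computational pieces such a study needs, each exercised against synthetic
data with known ground truth:

1. **Calcium-trace extraction and correction** from two-channel volumetric
   movies.  Each voxel trace is modeled as three multiplying terms plus
   additive noise, `S_c(t) = F_c(t)·B_c(t)·A(t) + N_c`: fluorophore signal,
   double-exponential photobleaching `B_c(t) = a1·e^(−λ1 t) + a2·e^(−λ2 t)`,
   and a multiplicative artifact `A(t)` shared between the calcium-sensitive
   green channel and the calcium-insensitive red channel.  The red channel's
   constant `F` lets a double-exponential fit isolate `A(t)`, which is then
   divided out of the green channel before its own bleach correction and
   normalization.
2. **Reversal-triggered analysis**: event-triggered averages of the change
   ratio `(F − F0)/F0` with F0 from a [−3 s, 0] baseline, per-event
   ("spaghetti") normalization, and pairwise Pearson correlations between
   neuron pairs (left–right vs normal–undead), compared with Welch's t test.
3. **Behavior metrics** from centroid tracks: reversal counts and durations
   in a 2-minute assay window, and dorsal–ventral turning angles measured
   between movement steps of five undulation waves (180° straight,
   < 180° dorsal, > 180° ventral).
4. **The lineage mosaic model**: an extrachromosomal array retained through
   D divisions by a fraction f of animals implies a per-division
   transmission probability `p = f^(1/D)`, and retention through k further
   divisions occurs with probability `p^k`.  The package ships a reduced
   lineage fixture, closed-form retention predictions conditioned either on
   the divergence node or on the zygote P0, a Monte Carlo validator, and
   the PCD census arithmetic.

A synthetic-data module generates all inputs — movies, event trains, worm
tracks, mosaic populations — with the exact statistical structure the
analyses assume, plus ground-truth records for parameter-recovery tests.

## Worked example: the mosaic transmission model

Out of 181 array-carrying animals, 39 retained the array through all 18
divisions into both RIM sister cells (2 shared divisions to the divergence
node, then 8 per side):

```sh
$ wormcircuit mosaic estimate --retained 39 --assayed 181 --divisions 18
{"f": 0.2154696132596685, "D": 18, "p": 0.9182604738205498, "p_reported": 0.9182}
```

Given that probability, the fraction of 2-RIM animals also retaining the
array in each other lineage that expresses the rescue construct:

```sh
$ wormcircuit mosaic predict --conditioning divergence
cell_type  k  shared_divisions conditioning  predicted_fraction  predicted_fraction_2dp
      ASI 16                 0   divergence            0.255537                    0.26
      ADL 18                 0   divergence            0.215470                    0.22
      ASK 20                 0   divergence            0.181684                    0.18
      ADA 16                 0   divergence            0.255537                    0.26
      PHB 16                 0   divergence            0.255537                    0.26
      PVQ 14                 0   divergence            0.303126                    0.30
      RIC  8                 0   divergence            0.505540                    0.51
```

`k` is the number of divisions in the minimal subtree from the divergence
node to the two cells of the pair; conditioning on P0 instead adds the two
shared divisions (`p^(k+2)`), e.g. RIC drops from 0.51 to 0.43.  The census
arithmetic — where PCD falls in the hermaphrodite lineage — prints as
percentages:

```sh
$ wormcircuit mosaic census
{"neural_proximate_pct": 80, "neuronal_lineage_pct": 72, "neuron_pct": 31, "undead_increase_pct": 31}
```

80% of the 131 programmed deaths are neural-proximate, 72% fall in
exclusively neuronal branches, neurons are 31% of somatic cells, and if
every neuronal-lineage death instead produced a neuron the neuron count
would grow by 31%.

## Worked example: trace correction on synthetic ground truth

```python
import numpy as np, pandas as pd
import wormcircuit as wc
from wormcircuit.synthetic import SimulationConfig

cfg = SimulationConfig(random_seed=1)          # 240 s, 4 Hz, two neurons
events = wc.simulate_event_train(cfg)
movie, truth = wc.simulate_calcium_movie(cfg, events)
ann = pd.DataFrame([{"t_index": t, "neuron_id": f"neuron{i}",
                     "x_vox": p[0], "y_vox": p[1], "z_vox": p[2]}
                    for t in range(cfg.n_volumes)
                    for i, p in enumerate(cfg.neuron_positions)])
result = wc.extract_corrected_traces(movie, ann, events)
fit = result["neurons"]["neuron0"]["red_fit"]
corr = result["neurons"]["neuron0"]["corrected"].values
r = np.corrcoef(corr, 1 + truth.true_calcium["neuron0"])[0, 1]
print(f"events: {len(events)}")
print(f"red bleach rates: {fit.lam1:.4f}, {fit.lam2:.5f} /s (true 0.0300, 0.00400)")
print(f"corrected-trace correlation with truth: r = {r:.3f}")
```

prints

```
events: 8
red bleach rates: 0.0289, 0.00409 /s (true 0.0300, 0.00400)
corrected-trace correlation with truth: r = 0.999
```

i.e. the photobleaching rates fitted from the calcium-insensitive channel
land within a few percent of the generating values, and the corrected
green trace tracks the true calcium signal almost perfectly.

The full pipeline (simulate → extract → event analysis → behavior →
mosaic, with a reproducibility manifest) runs as

```sh
wormcircuit run --seed 5 --out results/
```

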