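# dalan

Patient-level deep Cox survival modelling for **bags of lesion ROI images**.

When a patient contributes several region-of-interest (ROI) images — e.g.
multiple curated lesion tiles from brain-tumour histopathology slides — an
ROI-wise hazard model produces several conflicting predictions per patient.
`dalan` implements a *learned* aggregation network that embeds every ROI
with a weight-shared CNN, passes the embedding sequence through two
Attention-LSTM blocks (multi-head self-attention, then co-attention whose
query is the raw embedding sequence, each followed by a two-stacked LSTM),
and maps a summary of the final hidden sequence through an MLP to a single
patient-level log-hazard. It is trained end-to-end on the Cox negative
partial log-likelihood

```
L(θ) = − Σ_{i∈U} [ ĥ_θ(x_i) − log Σ_{j∈R_i} exp(ĥ_θ(x_j)) ],
```

where `U` is the set of event (uncensored) patients and `R_i = {j : Y_j ≥
Y_i}` the risk set at patient *i*'s observed time. Performance is measured
by Harrell-style concordance over admissible pairs,

```
c-index = Σ_{i∈U} Σ_{T_j>T_i} 1[f_j > f_i]  /  Σ_{i∈U} Σ_{T_j>T_i} 1,
```

with predicted survival `f = −risk` (a strict-inequality reading is the
default; a 0.5-per-tie variant is available for comparability with
standard packages).

The package also provides:

* **Naive aggregation baselines** — one CNN Cox model trained at ROI level,
  with patient risk formed by the average / min / max / median of the
  per-ROI hazards.
* **An image-conditioned survival simulator** — each ROI gets a time
  `T = exp(mean(I ⊙ M) + 0.001·ε)`, `ε ~ Lognormal(0,1)`, with one random
  Uniform(0,1) pixel-weight mask `M` per cohort; patient time is the mean
  over that patient's ROI times, 50% of the cohort is randomly censored and
  an 80/20 patient-level split is drawn. Two designs are built in: two-ROI
  bags of 28×28 digit-like strokes and multi-ROI bags of 3-channel
  textures. No external image data is needed.
* **Survival analysis utilities** — Cox loss, concordance, Kaplan–Meier,
  log-rank, risk z-scoring and tertile (low/mid/high) stratification with
  Wilcoxon/Kruskal–Wallis covariate reports.
* **A NumPy neural-network engine** (`dalan.nn`) — a compact reverse-mode
  autodiff with conv / LSTM / multi-head-attention layers and AdamW, fully
  deterministic on CPU under fixed seeds.

## Worked example

```python
from dalan.simulator import SimulationConfig, build_simulation
from dalan.experiments import run_comparison

res, summary = run_comparison(
    SimulationConfig(n_patients=500),          # two-ROI digit design
    ["dalan", "average", "min", "max"],
    n_repeats=5, master_seed=0, profile="desk")
print(summary.round(3))
```

which prints the held-out patient-level c-index per method (mean ± SD over
the five simulated cohorts):

```
          mean     sd  n
method
average  0.918  0.009  5
dalan    0.932  0.010  5
max      0.795  0.027  5
min      0.824  0.018  5
```

Higher is better; 0.5 is chance. The learned aggregator ranks patients
best, plain averaging of ROI-wise hazards is a strong baseline, and the
min/max order statistics lag behind — the expected pattern when the
patient's true time is the *average* of its ROI-level times.

The same study is available from the shell:

```bash
dalan simulate --n-patients 500 --seed 0 --out scratch/sim
dalan compare --methods dalan,average,min,max --n-repeats 5 --seed 0 \
      --out scratch/results.csv
dalan report --predictions preds.csv --manifest scratch/sim/manifest.csv \
      --plot scratch/km.svg
```

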