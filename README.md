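# erenorm

Tools for selecting and validating **expressed repetitive elements (EREs)**
as reference targets for RT-qPCR normalization.

Normalizing a gene of interest's expression requires reference targets whose
expression is stable across the samples being compared — and popular
reference genes (*Actb*, *Gapdh*, ...) often are not. Because copies of a
repeat family sit inside many different transcripts, a repeat-family assay
measures an aggregate that tracks the total mRNA fraction and is robust to
differential expression of any individual host gene. `erenorm` implements
the complete computational workflow for establishing such ERE reference
targets, for any species with a repeat catalogue:

1. **Assay screening** (`erenorm.screen`) — conservation of repeat copies
   against the family consensus (mean identity ≥ 97% by default) and
   mismatch-tolerant in-silico PCR over a transcript set (Hamming matching,
   exact 3′-terminal base, both strands) to count expressed targets per
   mismatch cap (≥ 30 hits considered adequate; more is better).
2. **Efficiency QC** (`erenorm.efficiency`) — standard-curve fits from
   dilution series; assays retained when efficiency
   `E = (10^(−1/slope) − 1)·100` lies in [90, 110]% and r² > 0.98.
3. **geNorm stability analysis** (`erenorm.genorm`) — per-target stability
   `M_j = mean_{k≠j} SD_i[log2(Q_ij/Q_ik)]`, stepwise-exclusion ranking,
   normalization factors (geometric means), the pairwise-variation series
   `V_{n/n+1}`, and the optimal reference-target count (smallest *n* with
   `V < 0.15`). `M < 0.5` / `M < 0.2` mark high / very high stability.
4. **Genomic-DNA QC** (`erenorm.gdna`) — ERE assays inevitably co-amplify
   genomic DNA, so paired +RT/−RT reactions quantify the residual signal:
   per-sample ΔCq, t-based 95% CI, and residual fraction `2^(−ΔCq)`
   (ΔCq = 11.64 cycles ⇒ 0.031%).
5. **Cross-experiment rank aggregation** (`erenorm.rankagg`) — consensus
   ordering minimizing the (weighted) Spearman footrule distance to the
   per-experiment rankings, exactly for ≤ 9 targets and by a cross-entropy
   Monte Carlo search for more.
6. **Synthetic data** (`erenorm.simulate`) — seeded generators for every
   input the pipeline reads, built on the shared-shift Cq model
   `Cq_ij = baseline_j − s_i − δ − η_ij − ε_ij`, so the whole workflow is
   testable end to end without any external download.

## Worked example

Simulate a 12-sample experiment with three stable ERE assays and two
unstable classic reference genes, then run the stability analysis:

```python
from erenorm.simulate import ExperimentDesign, TargetSpec, generate_cq
from erenorm.data_model import to_relative_quantities
from erenorm.genorm import analyze_stability

design = ExperimentDesign(
    n_samples=12,
    targets=(
        TargetSpec("Orr1a0", 22.0),
        TargetSpec("Rltr2aiap", 24.0),
        TargetSpec("Rltr13a3", 21.0),
        TargetSpec("Actb", 20.0, instability_sd=0.6),
        TargetSpec("Gapdh", 19.5, instability_sd=0.4),
    ),
    global_shift_sd=1.0,   # shared per-sample mRNA-abundance shift (cycles)
    noise_sd=0.1,          # technical Cq noise (cycles)
    seed=42,
)
matrix, truth = generate_cq(design)
result = analyze_stability(to_relative_quantities(matrix))
for rank, t in enumerate(result.ranked_targets, 1):
    print(f"{rank}  {t:<10} M={result.m_values[t]:.3f}  {result.classes[t]}")
print("V series:", {n: round(v, 3) for n, v in result.v_series.items()})
print("optimal number of reference targets:", result.optimal_n)
```

```
1  Orr1a0     M=0.259  high
2  Rltr2aiap  M=0.272  high
3  Rltr13a3   M=0.266  high
4  Gapdh      M=0.462  high
5  Actb       M=0.567  unstable
V series: {2: 0.029, 3: 0.093, 4: 0.11}
optimal number of reference targets: 2
```

The three τ = 0 targets occupy ranks 1–3 with the lowest M-values; the
ranking is the stepwise-exclusion order (which is why rank 2/3 can differ
from sorting the first-pass M-values). `V_2/3 = 0.029 < 0.15`, so two
reference targets suffice for this experiment.

The same stages are available from the shell:

```sh
erenorm simulate design.yaml --seed 1 --out exp1.csv
erenorm stability exp1.csv --out-prefix out/exp1
erenorm curve-qc dilutions.tsv --out verdicts.tsv
erenorm gdna-qc plus.csv minus.csv --out-prefix out/gdna
erenorm aggregate rankings.tsv --out consensus.json
erenorm run-all pipeline.yaml
```

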