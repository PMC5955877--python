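# Methods

## The normalization model

RT-qPCR normalization assumes each sample *i* carries a multiplicative
abundance factor common to all stably expressed targets. On the Cq (log2)
scale this is additive, which motivates both the stability statistic and the
synthetic-data generator used throughout:

    Cq_ij = baseline_j − s_i − δ_{g(i),j} − η_ij − ε_ij

* `s_i ~ N(0, σ_s²)` — the shared per-sample mRNA-fraction shift. It cancels
  from every pairwise log-ratio, which is exactly why geNorm statistics are
  invariant to it (property-tested).
* `δ` — a fixed condition effect (e.g. genotype), zero for a valid
  reference target.
* `η_ij ~ N(0, τ_j²)` — target-specific biological instability. A *stable*
  target is defined as τ = 0 and δ ≡ 0.
* `ε_ij ~ N(0, σ_ε²)` — technical noise.

Relative quantities are `Q_ij = a_j^(minCq_j − Cq_ij)` with amplification
factor `a_j = 1 + E_j/100` (2 when no standard curve is supplied, the geNorm
convention); the per-target maximum is exactly 1 by construction, and this
is enforced as a container invariant.

## geNorm statistics

* Pairwise variation `V_jk = SD_i[log2(Q_ij/Q_ik)]`, **sample** standard
  deviation (n−1), matching the original geNorm implementation.
* `M_j = mean_{k≠j} V_jk`; stepwise ranking removes the highest-M target and
  recomputes on the reduced set until two remain. A pairwise measure cannot
  separate the final two; they share the last M and are reported tied,
  ordered lexicographically. Ties on M during elimination are broken by
  removing the lexicographically later id — an arbitrary but deterministic
  rule.
* Normalization factor `NF_n,i` = geometric mean of the n most stable
  targets' Q; `V_{n/n+1} = SD_i[log2(NF_n,i/NF_{n+1,i})]`; the recommended
  target count is the smallest n with `V < 0.15`, falling back to all
  targets (flagged) when no V crosses the cutoff.
* Stability classes use strict inequalities: `M < 0.2` very high,
  `M < 0.5` high, else unstable.
* Analysis requires a complete matrix. Non-detects are never imputed; the
  caller drops samples or targets explicitly (`CqMatrix.drop`). Replicates
  are averaged on the Cq scale, and a replicate range above 0.5 cycles
  (configurable) is flagged but still averaged.

Both the first-pass M (computed on the full target set) and the M at
elimination are reported, since either may be the quantity a reader wants to
compare across experiments.

## Efficiency QC

OLS of Cq on log10 input; `E = (10^(−1/slope) − 1)·100`; r² is the squared
Pearson correlation of the fitted points. The retention gate reads its
thresholds literally: efficiency bounds inclusive (90 ≤ E ≤ 110), the r²
bound exclusive (r² > 0.98). A useful closed form for interpreting test
design: with per-point Cq noise σ on a 6-point ¼-dilution grid,
`SD(slope) = σ/√Sxx` with `Sxx = log10(4)²·17.5 ≈ 6.34`, and
`dE/dslope = 100·a·ln10/slope²` ≈ 41.7 %/unit at E = 100, so σ = 0.1 cycles
propagates to an efficiency-estimate sd of ≈ 1.66 percentage points. The
estimate is unbiased but lands within ±3 points of truth only ~93% of the
time under those conditions — a limit set by the design itself, not by the
fitting code, and verified against this closed form in the test suite.

## Genomic-DNA QC

Per sample, ΔCq = mean(−RT Cq) − mean(+RT Cq) over the chosen targets
(average-then-subtract, per the standard presentation of such controls; a
per-target-difference-then-average switch exists and coincides whenever both
conditions detect the same targets). Residual gDNA signal = `100·2^(−ΔCq)`
percent, reported at full precision and rounded to two significant figures.
The 95% CI uses the t-distribution with n−1 df — chosen because these
control panels are small — and the choice is recorded in the report
metadata. A −RT non-detect is censored at the instrument ceiling (default
40 cycles): the substituted ΔCq is a lower bound on the truth, the sample is
flagged and excluded from the CI but retained in the min/max range. A +RT
non-detect invalidates the comparison and is an error.

## In-silico PCR

A predicted amplicon requires the forward primer and the reverse-complement
of the reverse primer on the same template strand, each within the mismatch
cap (Hamming distance; indels are out of scope), each with an exactly
matching 3′-terminal base (a 3′ mismatch blocks extension), non-overlapping
primer footprints, and a product length inside a window (default 50–1000 nt
— the tool this emulates does not publish its window, so it is
configurable). Both strands are searched; coordinates are 0-based half-open
on the input transcript with orientation reported. The cap applies
**per primer** by default; "≤ k mismatches per primer pair" is ambiguous in
common usage, so a `pair_total=True` switch implements the summed
interpretation. Counting is transcript-level: a transcript counts once
however many amplicons it yields, which makes counts non-decreasing in the
cap (property-tested).

## Rank aggregation

The consensus ordering minimizes `Σ_L Σ_t w_L(t)·|pos_c(t) − pos_L(t)|`
(1-based positions). Weighted mode (default) min-max-normalizes each list's
M-values to [0,1] as weights, mirroring the weighted mode of the standard
rank-aggregation tooling; the unweighted footrule is retained as the
brute-force-verifiable fallback. Universes of ≤ 9 targets are enumerated
exactly, with objective ties broken by mean rank then lexicographically.
Larger universes use a cross-entropy Monte Carlo search: a k×k
position-probability matrix (initialized uniform) is sampled
position-by-position without replacement, the elite fraction (0.1) of
`10k²` sampled permutations updates the matrix with learning rate 0.25, and
the search stops after 15 iterations without improvement (or 100 total).
These magnitudes are conventional for cross-entropy permutation search, are
echoed in the output metadata, and identical seeds give identical results.

The aggregation inputs are per-experiment rankings by **first-pass M**
(ascending, ties lexicographic). The stepwise-exclusion order is reported
per experiment, but its M-at-elimination values are not guaranteed monotone
along the ranking, which would break the ranked-list contract (ordering
consistent with non-decreasing scores); sorting on first-pass M is the
self-consistent choice and corresponds to overlaying per-target stability
measurements on the aggregation.

## Synthetic-data generators and what passing tests show

All generators are pure functions of (design, seed). Defaults encode the
study conditions exercised by the test suite and acceptance script:

* Stability recovery: 20 samples, three stable targets (τ = 0) and three
  unstable ones (τ = 0.5 cycles), σ_s = 1 cycle, σ_ε = 0.1 cycles;
  baselines 21–25 Cq (mid-range for moderately expressed targets).
* gDNA: fractions around `2^−11.64 ≈ 3.1·10⁻⁴` and 10⁻³, −RT noise sd 0.3
  cycles, 12-sample panels, 3 ERE targets.
* Dilution series: 6 points, factor ¼, maximum input 10 µg, intercept 20 Cq.
* Transcriptomes: 500–2000 nt uniform-random backbones; cassette = forward
  site + 80 nt spacer + reverse-complemented reverse site; per-base cassette
  mutation rates 0–0.03; antisense insertions with the stated probability.
  Ground truth records every insertion's realized per-primer mismatch counts
  and whether both 3′ termini survived mutation.

The generators emulate the *statistical structure* the analysis assumes —
shared log-scale shifts, independent Gaussian instability, Hamming-mutated
primer sites. They do not model RNA degradation, amplification inhibitors,
inter-plate effects, repeat-copy phylogeny (mutations are independent per
site), or non-uniform transcript composition. Passing recovery tests
therefore demonstrate that the algorithms identify the structure they are
designed for, not that any particular biological sample behaves this way.

Problem sizes in the suite (100 oracle matrices of 4–8 targets × 5–20
samples, 50 recovery seeds, 25 six-experiment consensus runs, 200 dilution
series, 100 gDNA panels, 50 transcriptomes of 40 sequences) keep a full run
in the tens of seconds while leaving Monte Carlo rates with comfortable
margins.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviations everywhere in geNorm statistics.
* Quantity-matrix maxima validated to 1 within 1e-9; oracle-equivalence
  tests compare at 1e-12.
* Zero variance in dilution inputs, single-target M, sub-2-sample matrices,
  empty replicate tables, non-permutation candidates and degenerate CE
  configurations are rejected with specific errors rather than propagating
  NaNs.
* A non-negative standard-curve slope yields an efficiency-undefined curve
  (gate fails with a reason) instead of an exception, so screening tables
  can include broken assays.
* File round-trips write floats with Python `repr`, so decimal Cq values
  with ≤ 6 fractional digits survive write→read bit-identically
  (property-tested).

## Known limitations

* geNorm requires complete matrices; there is no missing-data model.
* The in-silico matcher is a dense scanner suited to transcript sets, not a
  genome-scale indexed search.
* The aggregation consensus on real multi-experiment data depends on
  distance and weighting choices the upstream literature rarely states;
  both modes are exposed and recorded in output metadata.
* Inter-plate calibration, RDML/vendor exports, and thermodynamic primer
  checks are out of scope.
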