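# Methods

This note records the statistical models, conventions and design
choices behind `refstab`, in the order the pipeline runs them.

## Input model and the quantity transform

The pipeline's currency is a genes × samples Ct matrix with per-sample
metadata (colony, body part, sampling day). Present Ct values must lie
in (0, 45]: the assay programs 40 cycles, and the band leaves headroom
for instruments that extrapolate slightly past the last cycle. Missing
wells are explicit NaN and are never imputed; each algorithm declares
its own policy (pairwise-complete for geNorm/ΔCt, complete samples for
NormFinder, per-gene complete for BestKeeper).

Relative quantities are `q_ij = E_i^(minCt_i − Ct_ij)` with the
amplification factor `E_i = 1 + E%_i/100` from the standard curve, so
each gene's most abundant sample has q = 1 and every extra cycle
divides q by E. Whether published stability analyses used per-assay
efficiencies or assumed perfect doubling is generally unknowable from
reported values alone, so both are supported: an efficiency table when
given (`--efficiency table`, the default) or E = 2 for every gene
(`--efficiency 2.0`). The ΔCt method and BestKeeper operate on raw Ct
by their own convention and are unaffected by the flag; the exact
ΔCt ≡ geNorm-M identity therefore holds only when geNorm also runs at
E = 2.

The stem-loop primer check verifies that a primer's 3′-terminal hexamer
is the DNA reverse complement of the miRNA's 3′ hexamer, allowing a
one-base offset (some designs skip the terminal base); it is an input
QC, not part of the statistics.

## Prescreen

Per gene, a two-way fixed-effects ANOVA with body part and sampling day
as factors, interaction included (the 2 × 5 × 4 design supports it; the
screening decision uses only the day main effect either way). Balanced
designs use the classical closed-form decomposition, which is exact and
fast enough for large null ensembles; unbalanced inputs fall back to
type-II sums of squares via statsmodels, which coincides with the
classical decomposition when the design is balanced. A gene is excluded
iff its day p-value is below alpha (default 0.05), per gene with no
multiplicity correction — the rule is a per-assay safety check, not a
family-wise inference. Colonies are treated as replicates, not modelled
as random effects; that matches how such designs are analysed in
practice and keeps the screening a plain F test (which is exact under
the Gaussian null — the 10,000-replicate calibration in the acceptance
suite confirms a type-I rate within [0.04, 0.06]).

## The four stability algorithms

**geNorm.** `V_jk = SD(log2 q_j/q_k)` over pairwise-complete samples,
`M_j = mean_{k≠j} V_jk`. Sample SDs use the n−1 denominator throughout.
The ranking removes the largest-M gene repeatedly; the removed gene's M
at removal is its stability value. The final two genes are
algorithmically indistinguishable: both carry the final-pair M and share
rank 1, and the next gene takes rank 3 (competition ranking). Ties in M
during exclusion are broken by removing the later gene in input order.
`NF_n` is the geometric mean of the top-n genes' quantities;
`V_{n/n+1} = SD(log2 NF_n/NF_{n+1})`, and the recommended number of
references is the smallest n with V < 0.15. When no entry passes, the
recommendation is explicitly "none" rather than a default. Because
using many references is impractical at the bench, the pipeline also
reports `capped_n = min(recommended_n, max_refs)` with `max_refs = 2`
by default.

**NormFinder.** On log2 quantities, each sample is centered across
genes to remove the sample-specific common amount; per gene i and group
g (groups are sampling days within one body-part stratum — five groups
of four in the study design; colony is not a group), the residual
variance `s²_ig` is unmixed into the gene-specific intragroup variance
by `σ̂²_ig = max{0, (k/(k−2))·[s²_ig − Σ_{i′} s²_{i′g}/(k(k−1))]}` —
the k/(k−2) factor undoes the variance absorbed by centering, making
the estimator unbiased for exchangeable noise (clamping at 0 is logged
in the diagnostics as a zero). Intergroup deviations
`z_ig = d̄_ig − mean_g d̄_ig` are shrunk by the empirical-Bayes factor
`τ̂²/(τ̂² + σ̂²_ig/n_g)` with
`τ̂² = max{0, Σ z²/((G−1)k) − mean(σ̂²/n_g)}`, and
`ρ_ig = |γ̂_ig| + sqrt(σ̂²_ig/n_g)` averages over groups into the
stability value. With one group the value reduces to `sqrt(σ̂²_i)`.
Under an exchangeable iid null the stability value converges to
`σ/sqrt(n_g)` (the unbiasing makes `E[σ̂²] = σ²` exactly); the test
suite checks that convergence by simulation. The "best pair of genes"
output of some NormFinder implementations is deliberately not
reproduced — pair choice is the consensus module's correlation rule.

**BestKeeper.** Raw-Ct descriptive statistics per gene. The default
dispersion (`sd_mode="mad"`) is the mean absolute deviation from the
arithmetic mean, which is what the original spreadsheet tool labels
"SD (± CP)"; the conventional sample SD is available side by side
because published tables rarely say which was used. CV = 100·SD/mean.
The index is the per-sample geometric mean over **all** candidates (no
SD > 1 pre-filter; the SD > 1 "inconsistent" heuristic is reported as a
flag only), and each gene's Pearson r with the index is tested two-sided
via the t transform with n−2 df. A zero-variance gene has no defined r
and is reported missing with a warning, never coerced to 0. SD ranking
and |r| ranking genuinely disagree on real data; both are emitted, and
the consensus consumes the SD ranking (see below).

**Comparative ΔCt.** `stability_i = mean_{i′≠i} SD(Ct_i − Ct_i′)` on
raw Ct. Algebraically identical to geNorm M at E = 2, which the test
suite asserts to machine precision on random matrices — the two modules
act as mutual oracles.

## Consensus and pair selection

Each method contributes competition ranks ("1, 2, 2, 4": ties share the
lowest rank); the comprehensive value is the geometric mean of the four
ranks (ΔCt, NormFinder, geNorm, BestKeeper-SD), displayed to 2 decimals
but ordered unrounded, GM ties broken by the ΔCt rank. Two conventions
were fixed by back-solving the complete published GM columns for both
strata (16 values, all reproduced exactly by the test suite): the geNorm
final pair shares rank 1, and BestKeeper contributes its SD ordering
(not |r|) — a config option can switch the latter. Ties that exist only
in printed (rounded) values are resolved by published row order; genuine
value ties get competition ranks.

The normalization plan takes the GM-top gene as primary reference and
scans the remaining genes in ascending GM order for a partner whose
raw-Ct Pearson r with the primary is **strictly** below 0.9 on the
unrounded value (0.899 passes; 0.90 does not): two highly correlated
references duplicate information and cannot reduce technical variation.
If every candidate fails the gate the plan is a single reference.

## Target validation

The target's quantity over the references' NF (geometric mean of
quantities — for two references this is exactly geNorm's NF₂; averaging
Ct instead would coincide only for equal efficiencies), log2
transformed, calibrated so the day-0 group has geometric mean 1 (a
display convention; the ANOVA is invariant to it), then a classical
one-way ANOVA across days. Five days × four colonies give df = (4, 15).
A degenerate all-equal input reports F = 0, p = 1.

## Synthetic data

`Ct = baseline_i + bodypart_offset_i·[thorax] + colony_c + day_effects_i[d] + ε`,
with one `Normal(0, colony_sd²)` effect per colony shared across genes,
days and body parts, and iid `Normal(0, noise_sd_i²)` well noise,
inflated ×1.3 in the thorax + abdomen stratum (qPCR replicate noise is
well described as Gaussian on the cycle scale; the shared colony effect
reproduces both colony-level response variability and the positive
between-gene Ct correlation that the pair-selection gate probes). The
generator does **not** emulate amplification-curve artefacts, pipetting
outliers, inhibitors, or missingness — passing tests demonstrate
correct recovery of the generative structure, not robustness to such
real-data pathologies.

The frozen default scenario (`study_like_config`, seed 20230609) has
nine genes in the 2 × 4 × 5 design (360 cells): seven stable candidates
with baselines 22–28 Ct and body-part offsets of ±0.2–0.8 Ct, one
drifting U6-like candidate (day effects 0 → −2.0 Ct, noise 0.6), and a
rising let-7-like target (day effects 0 → −2.8 Ct, noise 0.4). Two
choices deserve explanation:

- **A designed winner.** The scenario needs one clearly best gene for
  recovery tests, so the designated winner has noise 0.1 Ct versus 0.4
  for the other six (both realistic replicate SDs). The gap was sized
  once, by a calibration ensemble, so that the winner tops the consensus
  in ≈99/100 seeds, then frozen.
- **Drift direction.** The drifting candidate's expression rises
  *alongside* the target's. Normalizing a rising target to a rising
  reference flattens the apparent trend — the classic failure mode an
  unstable reference causes, and the one the validation stage must
  reproduce (a reference drifting opposite to the target would instead
  exaggerate the trend and make the unstable reference look *more*
  powerful).

Ensemble pass thresholds used in tests (winner top in ≥ 95/100 seeds,
drifting gene excluded by prescreen in ≥ 90/100, power under the stable
reference strictly above power under the drifting one over 200 seeds)
were fixed at design time alongside that calibration and are not
adjusted per run.

## Numerical conventions and edge cases

- Sample SDs: n−1 denominator everywhere.
- Competition ranking for all methods; documented tie-breaks (input
  order in geNorm exclusion, ΔCt rank for GM ties, row order for
  printed-value ties).
- Negative variance estimates in NormFinder clamp to 0; `τ̂² = 0`
  disables shrinkage entirely (γ̂ = 0).
- Degenerate ANOVA inputs (zero residual variance) report F = 0 rather
  than NaN, with p = 1.
- All simulation entry points take explicit seeds
  (`numpy.random.default_rng`); outputs are byte-identical across
  reruns.

## Problem sizes in tests

The test-suite ensembles use the study-scale design (9 × 40) with 100
seeds for recovery and 200 for the power contrast, 10,000 reduced-size
(2 × 5 × 2) replicates for the ANOVA null calibration, and 100 random
8 × 40 matrices for the ΔCt/geNorm identity; these sizes give stable
Monte-Carlo estimates (binomial SE ≈ 0.002 at the calibration size)
while keeping the default run to about a minute.

## Known limitations

- NormFinder estimator details vary between published implementations;
  third-decimal differences from other tools are expected.
- The consensus reproduces geometric-mean-of-ranks aggregation only, not
  every behaviour of web-based comprehensive ranking services.
- The prescreen treats colony as replication; strong colony random
  effects inflate residual variance but do not bias the day F test.
- BestKeeper's two criteria (SD, r) can disagree; the package reports
  both and leaves the choice of which feeds the consensus to
  configuration.
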