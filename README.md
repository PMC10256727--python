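# refstab

Reference-gene stability screening for miRNA RT-qPCR.

Relative quantification by RT-qPCR stands or falls with the reference
gene: the target's quantity is divided by the reference's, so a
reference that itself responds to the treatment skews or erases the
biology. `refstab` implements the complete screening workflow used to
choose reference miRNAs for stem-loop RT-qPCR in studies of termite
soldier caste differentiation (methoprene bioassay, 2 body parts × 4
colonies × 5 sampling days), and works for any Ct dataset with that
kind of factorial design:

- **Prescreen** — per-gene two-way ANOVA (body part × sampling day); a
  candidate whose Ct depends on the sampling day is excluded.
- **geNorm** — stability value `M_j = mean_k SD(log2 q_j/q_k)`, stepwise
  exclusion ranking, normalization factors `NF_n` (geometric mean of
  quantities), and the pairwise variation `V_{n/n+1} = SD(log2 NF_n/NF_{n+1})`
  with the 0.15 rule for the number of reference genes.
- **NormFinder** — model-based stability combining intragroup variance
  and shrunk intergroup bias: `rho_ig = |gamma_ig| + sqrt(sigma²_ig/n_g)`.
- **BestKeeper** — per-gene dispersion (mean absolute deviation or SD)
  of raw Ct, the per-sample geometric-mean index, and each gene's
  Pearson correlation with it.
- **Comparative ΔCt** — mean SD of pairwise Ct differences (identical to
  geNorm M when every assay doubles perfectly).
- **Consensus** — geometric mean of the four method ranks (GM), plus a
  correlation-gated two-reference rule: a partner for the top gene is
  accepted only if their raw-Ct Pearson r is strictly below 0.9.
- **Validation** — relative quantification of a target miRNA under
  competing references, log2 transform, one-way ANOVA across days.
- **Synthetic data** — a generator reproducing the full study design
  with planted stable/drifting genes, so every stage can be tested
  against known ground truth.

Quantities use the efficiency transform `q = E^(minCt − Ct)` with
per-assay amplification factors `E = 1 + E%/100` (or `E = 2` when no
efficiency table is given).

## Worked example

Simulate the default scenario (9 genes — seven stable candidates, one
drifting U6-like candidate, one rising let-7-like target — in the
2 × 4 × 5 design) and run the full pipeline:

```
$ refstab simulate --out sim.tsv --truth-out truth.json
wrote 9 genes x 40 samples to sim.tsv

$ refstab screen sim.tsv
kept: novel-m0649-3p, miR-193-3p, miR-971-5p, miR-3049-5p, miR-216-5p, miR-7-3p, miR-2788-3p
excluded: U6, let-7-3p

$ refstab report sim.tsv --target let-7-3p --outdir report
[head] consensus top: novel-m0649-3p; plan: {'primary_ref': 'novel-m0649-3p',
  'partner_ref': 'miR-193-3p', 'partner_r': 0.636..., 'rejected': [],
  'recommended_n': 2, 'capped_n': 2}
```

The prescreen removed the two planted drifting genes (U6-like candidate
and the target itself). The head-stratum consensus table
(`report/consensus_head.tsv`):

```
                rank_delta_ct  rank_normfinder  rank_genorm  rank_bestkeeper  gm_exact    gm
novel-m0649-3p              1                1            1                1  1.000000  1.00
miR-193-3p                  2                3            1                7  2.545730  2.55
miR-7-3p                    5                2            4                2  2.990698  2.99
...
```

GM = 1.00 means unanimously best under all four algorithms — the
simulated gene planted as most stable. The pair plan accepts
miR-193-3p as partner (r = 0.64 < 0.9), and the geNorm V-series
recommends 2 reference genes.

Validation shows why the screening matters. Normalizing the target to
the stable winner recovers its planted rising time-course; normalizing
to the drifting candidate destroys it:

```
$ refstab quantify sim.tsv --target let-7-3p --refs novel-m0649-3p --body-part head
F = 26.16, df = (4, 15), p = 1.3e-06      # clear day effect

$ refstab quantify sim.tsv --target let-7-3p --refs U6 --body-part head
F = 0.71, df = (4, 15), p = 0.60          # trend erased
```

The same operations are available as library functions
(`refstab.genorm_rank`, `refstab.normfinder_stability`,
`refstab.reffinder_gm`, `refstab.run_pipeline`, ...).

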