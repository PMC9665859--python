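# mppqtl

IBD-based mixed-model QTL mapping for multi-parent populations (MPPs):
nested association mapping (NAM) panels, diallels and other collections of
biparental families (DH, F2, RILn) that share a common set of founder
parents.

MPP designs combine wide founder diversity with controlled population
structure, but mapping QTL in them requires tracking *which founder* each
offspring allele descends from. `mppqtl` implements the two-step workflow
used for this class of designs:

1. **IBD calculation.** For every offspring, a hidden Markov model over
   parental-origin states (per family, per chromosome, Haldane
   transitions, per-allele genotyping-error emissions) yields the
   posterior probability of each founder origin at every point of a
   regular cM evaluation grid. These posteriors become the expected
   founder allele counts `M_q` — the locus design matrix.

2. **QTL mapping.** Each grid position is tested with the single-locus
   variance-component model

   ```
   Y = X β + M_q a_q + g + ε
   a_q ~ N(0, I_P σ_q²),   g ~ N(0, K σ_g²),   ε ~ N(0, ⊕_k I_{n_k} σ_εk²)
   ```

   where `Y` are phenotypes, `X`/`β` fixed family intercepts, `a_q` the
   random per-parent allelic effects of the tested locus (P founders),
   `g` an optional polygenic term with kinship `K` (off by default,
   leave-one-chromosome-out when on), and each of the F families has its
   own residual variance. Variance components are estimated by REML;
   `σ_q² = 0` is tested with a likelihood-ratio statistic referred to the
   boundary mixture `0.5 χ²₀ + 0.5 χ²₁`, reported as −log10(p). Multiple
   scan rounds add selected QTLs as random cofactors (composite-interval
   convention: a cofactor within the exclusion window of the tested
   position is dropped for that test) until no new peak clears the
   threshold or a QTL cap is reached. The final joint model reports
   per-parent BLUP effects with prediction-error SEs.

For complex pedigrees (e.g. MAGIC) whose ancestry must be reconstructed
by dedicated external software, precomputed IBD probabilities can be
imported from a simple long-format CSV instead.

A simulator generates full MPP datasets (founders, meiosis under the
Haldane model, DH/F2/RILn crossing schemes, genotyping error,
phenotypes from the generative model above) with exact ground truth, and
backs the validation suite end to end.

## Worked example

Simulate a 3-family DH NAM (150 lines/family, founders P1–P4 with P1
common; markers every 2 cM on two 80 cM chromosomes) with one QTL at
35 cM on chromosome 1 explaining 50% of the within-family variance
(true allelic effects P1: 0, P2: +1, P3: −1, P4: +1), then map it:

```bash
mppqtl simulate --out demo/sim --seed 11 --families 3 --n-per-family 150 \
    --qtl 1:35 --qtl-share 0.5
mppqtl run --map demo/sim/map.csv --genotypes demo/sim/genotypes.csv \
    --cross demo/sim/cross.csv --phenotypes demo/sim/phenotypes.csv \
    --out demo/out
```

which prints

```
found 1 QTL in 2 round(s); outputs in demo/out
```

`demo/out/qtl.csv` — the QTL is located exactly at the simulated
position, far above the default −log10(p) threshold of 3:

```
qtl_id,chromosome,position,round,peak_minus_log10_p
qtl1,1,35,1,68.7661322
```

`demo/out/effects.csv` — per-parent BLUP allelic effects ± SE from the
final joint fit. BLUPs are shrunken and centred relative to the true
effects (0, +1, −1, +1), but their ordering and contrasts recover the
simulated pattern: P3 carries the low allele, P2/P4 the high ones:

```
qtl_id,parent,effect,se
qtl1,P1,-0.2484415215,0.4882372269
qtl1,P2,0.6572973513,0.4922107187
qtl1,P3,-1.2659424,0.4910358978
qtl1,P4,0.8570865701,0.4914452136
```

`demo/out/profile.csv` holds the final-round scan profile
(chromosome, position, LRT, p, −log10 p per 5 cM grid position), ready
for plotting.

The same analysis is available as library calls
(`calc_ibd_mpp` → `multi_round_scan`), and `mppqtl calc-ibd` /
`mppqtl scan` expose the two pipeline stages separately — `scan` accepts
the long-format IBD CSV, whether written by `calc-ibd` or converted from
an external ancestry-reconstruction tool.

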