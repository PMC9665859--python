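# Methods

This note documents the models implemented in `mppqtl`, the defaults and
the numerical choices, and what the simulator-based validation does and
does not establish.

## Coordinate system and evaluation grid

All positions are genetic (cM). Distances map to recombination fractions
through the Haldane function `r(d) = ½(1 − e^(−2d/100))` — no crossover
interference — which makes recombination a Markov process along the
chromosome and keeps the HMM and the simulator mutually consistent. No
other map function is offered.

The evaluation grid is anchored at the first marker of each chromosome
and advances in steps of `step_cM` (default 5 cM), with the last marker
appended when the progression does not land on it. The grid deliberately
does not extend beyond the mapped span: outside it there is no marker
information and posteriors would merely decay toward the prior.
Positions are compared with an absolute tolerance of 1e-9 cM so that
values surviving a CSV round trip still match.

## Parental-origin HMM

Within a biparental family, the hidden state at a locus is the (ordered)
pair of founder origins of the offspring's two haplotypes. Supported
schemes:

| type   | states | prior | transition kernel |
|--------|--------|-------|-------------------|
| DH     | 2 homozygous | ½, ½ | two-state chain, switch prob `r` |
| F2     | 4 ordered pairs | ¼ each | Kronecker product of two two-state chains (independent gametes) |
| RILn, n = 2..8 | 4 ordered pairs | heterozygosity `h = 0.5^(n−1)` split over the two heterozygous states | prior-preserving jump kernel, see below |
| RILinf | 2 homozygous | ½, ½ | two-state chain with the inbred-line fraction `R = 2r/(1+2r)` |

**Finite-RIL approximation.** The exact two-point ancestry process of a
RIL produced by selfing is not Markov on the four origin-pair states.
We collapse it to a Markov kernel chosen to satisfy two constraints that
matter for inference: (i) the marginal (prior) distribution, with
residual heterozygosity `0.5^(n−1)`, is exactly stationary under the
kernel, and (ii) the per-haplotype switch rate over an interval equals
the classic Haldane–Waddington inbred-line recombination fraction
`R = 2r/(1+2r)`. The kernel is the "jump" form
`T = (1−λ) I + λ 1 πᵀ` with `λ = 2R`: with probability λ the origin pair
is redrawn from the prior π, otherwise it is retained (λ ≤ 1 for all
r ≤ ½). This ignores the finite-generation map-expansion transient and
state-dependent switch correlations; for n ≥ 6, where residual
heterozygosity is below 2%, the behaviour is essentially that of the
exact RILinf chain. Lines whose ancestry needs an exact treatment (or
any non-biparental scheme) should come in through the long-format IBD
import instead.

**Emissions.** Founders are assumed homozygous. At a marker where the
two parents carry distinct alleles, each observed allele independently
matches the allele implied by the state's origin with probability
`1 − ε_g` and mismatches with `ε_g` (default 0.01 — strictly positive so
that no data path has zero likelihood, small enough not to blur tight
linkage); unordered genotype calls are scored as the average over the
two pairings. Markers that are missing, monomorphic between the parents,
or missing in a parent are uninformative (equal emission across states)
and are retained rather than dropped, preserving column alignment. An
observed allele carried by no founder raises an input error.

**Posteriors.** Grid positions are spliced into the marker chain as
pseudo-observations with uniform emissions; a scaled (per-step
normalised) forward–backward pass over the augmented chain then gives
exact posteriors at every grid point in one sweep — no underflow on
chromosome-length chains and no log-space overhead. If the forward pass
loses all mass (impossible data at `ε_g = 0`), a degeneracy error advises
a positive error rate. State posteriors convert to expected founder
allele counts (entries in [0, 2] summing to the ploidy 2), assembled per
family into the global genotype × position × founder array with
structural zeros for non-parental founders — families are independent
HMMs; NAM/diallel structure enters only through the shared founder axis.

## Variance-component model and REML

The single-locus model tested at each grid position is

    Y = Xβ + M_q a_q + g + ε,
    a_q ~ N(0, I_P σ_q²), g ~ N(0, K σ_g²), ε ~ N(0, ⊕_k I_{n_k} σ_εk²).

Fixed effects are family intercepts only. Each random term contributes
`σ² Z Zᵀ` to the phenotypic covariance `V`; the polygenic term passes
`Z = K^{1/2}` from an eigendecomposition. Residual variances are
family-specific. The same residual structure is used in the null and the
full model; only the tested `σ_q²` differs (the conservative choice).
Genotypes with missing phenotypes are dropped row-wise from `Y`, `X` and
every `Z`.

The restricted log-likelihood

    ℓ_R = −½ [ log|V| + log|XᵀV⁻¹X| + (Y−Xβ̂)ᵀV⁻¹(Y−Xβ̂) + (n−p) log 2π ]

is evaluated through the Woodbury identity: with diagonal residual `R`
and stacked low-rank `U = [Z₁ … Z_T]`, one evaluation costs O(n·c²) for
c total random columns (c = P per locus term), which keeps scans with
several cofactors fast at n in the thousands; a dense direct evaluation
of the same criterion is retained (`restricted_loglik`) and
cross-checked in the tests. Optimisation is bounded L-BFGS-B on
log-variances (numerical gradients, ftol 1e-12, ≤ 200 iterations) from
two starts — an equal split of the OLS residual variance across
components, and a residual-heavy start (90/10) — taking the better
optimum. Variances are floored at `1e-10 · var(Y)` for Cholesky
stability and reported as exactly 0 when they finish at the floor;
at such boundaries the constrained optimum is still exact (e.g. the
one-way layout collapses to the iid n−1 variance estimate).
Non-convergence is flagged on the fit object, not raised. BLUPs are
`â = σ̂² Zᵀ V̂⁻¹(Y − Xβ̂)` with prediction-error variance
`σ̂² − σ̂⁴ · diag(Zᵀ P Z)`; their square roots are the reported effect
SEs.

**Test.** `LRT = max(0, 2(ℓ_full − ℓ_null))` is referred to the boundary
mixture `0.5 χ²₀ + 0.5 χ²₁` (p = 0.5 at LRT = 0), the standard
approximation for a single variance component on its boundary. The
weights are fixed at (½, ½); with P correlated BLUP contrasts behind the
single variance this is an approximation, and the null simulations in
the validation suite show it runs slightly conservative (empirical
rejection at nominal 0.05 around 0.01–0.05) — acceptable for a genome
scan threshold, not exact.

## Scan and QTL selection

Defaults: threshold −log10(p) = 3, exclusion window 10 cM, at most 10
QTLs — common linkage-mapping practice, all overridable. Each round
scans every grid position with previously selected QTLs as random
cofactors, each with its own variance. A cofactor within the window of
the tested position is removed from both the null and full model for
that test, so a true signal is never absorbed by its own cofactor; null
fits are cached per active-cofactor set. Selection takes the highest
eligible peak (ties: chromosome order, then lowest cM) at least one
window away from every existing QTL on the same chromosome; rounds stop
when no eligible peak reaches the threshold or the cap is hit. The final
model refits all selected loci jointly for the reported effects.

Kinship, when enabled, is `K = (1/2L) Σ_l M_l M_lᵀ` over grid positions,
rescaled to unit mean diagonal, and is rebuilt per chromosome
leave-one-chromosome-out so the tested locus does not compete with
itself inside `K`. It is off by default.

## Simulator

The simulator draws crossovers per marker interval as independent
Bernoulli events with the Haldane probability of the interval — exactly
the HMM's transition marginals. Founders carry allele = founder index at
polymorphic markers (a monomorphic fraction is configurable); DH = one
meiosis then doubling, F2 = two meioses from the F1, RILn = n−1
selfing generations of paired meioses (RILinf: 25 generations).
Genotyping error flips an allele to the other parent's allele;
missingness blanks whole calls. Phenotypes use the *true* origin counts
(QTL positions snap to the nearest marker), family intercepts, fixed or
N(0, σ_q²)-drawn per-parent effects, and family-specific Gaussian
residuals. One RNG stream drives everything, so fixtures are
bit-reproducible from a single seed.

Because the simulator and the HMM share the recombination model, the
validation suite demonstrates *internal* correctness — exact posteriors,
ploidy conservation, REML agreement with closed forms, calibration,
position recovery at realistic sample sizes — not robustness to features
real data have and the generator does not: crossover interference,
segregation distortion, heterozygous or mis-genotyped founders,
pedigree errors, non-Gaussian residuals, selection during line
development. Epistasis and QTL-by-environment structure are likewise
out of scope of both the simulator and the scan model.

## Validation problem sizes

The replicated scenarios use 3 DH families × 150 lines on two 80 cM
chromosomes with 2 cM markers and a 5 cM grid (20 replicates), 500
phenotype replicates at n = 200 for null calibration, and 50 random
balanced layouts for the REML oracle — sizes chosen so the whole
battery, including the file-based determinism checks, completes in a few
minutes on a single CPU while keeping Monte Carlo error well inside the
asserted bounds.
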