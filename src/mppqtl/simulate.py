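"""Synthetic multi-parent populations with known ground truth.

Generates founders, offspring genomes by simulated meiosis under the
Haldane model (per-interval independent crossovers, no interference),
marker genotypes with optional genotyping error and missingness, and
phenotypes drawn from the variance-component QTL model

    Y_i = beta_family(i) + sum_q sum_p count_{i,q,p} * a_{q,p} + eps_i

using the *true* parental-origin counts, so every downstream module can
be validated against exact truth.

The crossover process is deliberately identical to the HMM transition
model (exact Haldane marginals between adjacent markers), which makes the
simulator a generative counterpart of the IBD machinery rather than an
independent biological model; see docs/methods.md for what this does and
does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    Family,
    GeneticMap,
    InputError,
    MarkerData,
    MppDesign,
    PopType,
    haldane_cm_to_r,
)

#: Selfing generations used to emulate a fully inbred (RILinf) line.
_RILINF_GENERATIONS = 25


def simulate_meiosis(
    haplotypes: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a parent's two haplotypes over one chromosome.

    ``haplotypes`` is (2, M) (any dtype: allele codes or origin labels);
    ``positions`` the sorted marker positions in cM.  The starting
    haplotype is chosen uniformly; between adjacent markers the gamete
    switches haplotype independently with the Haldane recombination
    fraction of the interval.
    """
    M = haplotypes.shape[1]
    choose = np.empty(M, dtype=np.int64)
    choose[0] = rng.integers(2)
    if M > 1:
        rs = np.array([haldane_cm_to_r(d) for d in np.diff(positions)])
        switches = rng.random(M - 1) < rs
        choose[1:] = (choose[0] + np.cumsum(switches)) % 2
    return haplotypes[choose, np.arange(M)]


@dataclass(frozen=True)
class QtlSpec:
    """A simulated QTL: a map position with per-founder allelic effects.

    ``effects`` maps founder id -> additive effect per inherited allele;
    founders absent from the mapping contribute 0.  If ``effects`` is
    None, effects are drawn once per simulation from N(0, sigma_q^2).
    """

    chromosome: str
    position_cM: float
    effects: dict[str, float] | None = None
    sigma_q: float | None = None


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    ``origins`` is (n_offspring, n_markers, 2): the founder index (into
    ``founders``) of each haplotype at each marker.  Parental-origin
    segments per chromosome can be derived from the per-marker labels.
    """

    founders: tuple[str, ...]
    offspring_ids: tuple[str, ...]
    gmap: GeneticMap
    origins: np.ndarray
    seed: int | None = None
    qtls: list[QtlSpec] = field(default_factory=list)
    qtl_effects: list[dict[str, float]] = field(default_factory=list)
    beta: dict[str, float] = field(default_factory=dict)
    sigma_eps: dict[str, float] = field(default_factory=dict)

    def true_counts_at_marker(self, marker_index: int) -> np.ndarray:
        """(n_offspring, n_founders) true founder allele counts."""
        G = self.origins.shape[0]
        P = len(self.founders)
        counts = np.zeros((G, P))
        for h in range(2):
            np.add.at(counts, (np.arange(G), self.origins[:, marker_index, h]), 1.0)
        return counts

    def nearest_marker(self, chromosome: str, position_cM: float) -> int:
        idx = self.gmap.chromosome_indices(chromosome)
        if idx.size == 0:
            raise InputError(f"no markers on chromosome {chromosome!r}")
        pos = np.asarray(self.gmap.positions)[idx]
        return int(idx[np.argmin(np.abs(pos - position_cM))])

    def true_counts_at(self, chromosome: str, position_cM: float) -> np.ndarray:
        """Counts at the marker nearest to an arbitrary cM position."""
        return self.true_counts_at_marker(self.nearest_marker(chromosome, position_cM))

    def segments(self, offspring_index: int, chromosome: str) -> list[tuple[float, float, tuple[int, int]]]:
        """(start_cM, end_cM, (origin_hap1, origin_hap2)) tiles of one
        chromosome, derived from the per-marker origin labels."""
        idx = self.gmap.chromosome_indices(chromosome)
        pos = np.asarray(self.gmap.positions)[idx]
        orig = self.origins[offspring_index, idx, :]
        segs = []
        start = pos[0]
        cur = tuple(orig[0])
        for m in range(1, len(idx)):
            lab = tuple(orig[m])
            if lab != cur:
                mid = 0.5 * (pos[m - 1] + pos[m])
                segs.append((float(start), float(mid), cur))
                start, cur = mid, lab
        segs.append((float(start), float(pos[-1]), cur))
        return segs


def make_grid_map(
    chrom_lengths_cM: dict[str, float], marker_step_cM: float = 1.0
) -> GeneticMap:
    """Regular map: markers every *marker_step_cM* along each chromosome."""
    markers, chroms, poss = [], [], []
    for chrom, length in chrom_lengths_cM.items():
        n = int(np.floor(length / marker_step_cM)) + 1
        for k in range(n):
            markers.append(f"{chrom}_m{k}")
            chroms.append(chrom)
            poss.append(k * marker_step_cM)
    return GeneticMap(tuple(markers), tuple(chroms), tuple(poss))


def make_design(
    founders: list[str],
    crosses: list[tuple[str, str, str, str]],
    n_per_family: int,
) -> MppDesign:
    """Design from (family_id, parent1, parent2, pop_type) crosses with
    ``n_per_family`` offspring each, named ``<family>_<i>``."""
    fams = tuple(
        Family(
            fid, p1, p2, PopType.parse(pt),
            tuple(f"{fid}_{i}" for i in range(n_per_family)),
        )
        for fid, p1, p2, pt in crosses
    )
    return MppDesign(tuple(founders), fams)


def _founder_alleles(
    n_founders: int, n_markers: int, monomorphic_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder f carries allele code f at polymorphic markers, 0 at
    monomorphic ones."""
    alleles = np.tile(np.arange(n_founders)[:, None], (1, n_markers))
    if monomorphic_fraction > 0:
        mono = rng.random(n_markers) < monomorphic_fraction
        alleles[:, mono] = 0
    return alleles.astype(np.int64)


def simulate_population(
    design: MppDesign,
    gmap: GeneticMap,
    rng: np.random.Generator,
    monomorphic_fraction: float = 0.0,
    genotype_error: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[MarkerData, SimTruth]:
    """Simulate founder and offspring genotypes for a whole design.

    DH offspring: one meiosis from the F1 then genome doubling.  F2: two
    independent meioses from the F1.  RILn: n - 1 generations of selfing
    with fresh meioses each generation (RILinf uses a long selfing
    series).  True parental origins are recorded per marker before
    genotyping error (allele flipped to the other parent's allele with
    probability *genotype_error*) and missingness are applied.
    """
    if min(design.family_sizes, default=1) < 1:
        raise InputError("each family needs at least one offspring")
    n_markers = gmap.n_markers
    founder_alleles = _founder_alleles(
        design.n_founders, n_markers, monomorphic_fraction, rng
    )
    offspring_ids = design.genotype_ids
    G = len(offspring_ids)
    origins = np.zeros((G, n_markers, 2), dtype=np.int64)
    obs = np.zeros((G, n_markers, 2), dtype=np.int64)

    chrom_idx = {c: gmap.chromosome_indices(c) for c in gmap.chromosome_names}
    row = 0
    for fam in design.families:
        p1 = design.founder_index(fam.parent1)
        p2 = design.founder_index(fam.parent2)
        n_self = 0
        if fam.pop_type.kind == "RIL":
            n_self = (
                _RILINF_GENERATIONS
                if fam.pop_type.selfing_n is None
                else fam.pop_type.selfing_n - 1
            )
        for _ in fam.genotypes:
            for chrom, midx in chrom_idx.items():
                pos = np.asarray(gmap.positions)[midx]
                f1 = np.array(
                    [np.full(midx.size, p1), np.full(midx.size, p2)], dtype=np.int64
                )
                if fam.pop_type.kind == "DH":
                    gam = simulate_meiosis(f1, pos, rng)
                    pair = np.stack([gam, gam])
                elif fam.pop_type.kind == "F2":
                    pair = np.stack(
                        [simulate_meiosis(f1, pos, rng), simulate_meiosis(f1, pos, rng)]
                    )
                else:  # RIL by selfing
                    ind = f1
                    for _g in range(n_self):
                        ind = np.stack(
                            [simulate_meiosis(ind, pos, rng),
                             simulate_meiosis(ind, pos, rng)]
                        )
                    pair = ind
                origins[row, midx, 0] = pair[0]
                origins[row, midx, 1] = pair[1]
            row += 1
    # observed genotypes from origins
    for h in range(2):
        obs[:, :, h] = founder_alleles[
            origins[:, :, h], np.tile(np.arange(n_markers), (G, 1))
        ]
    if genotype_error > 0:
        # flip to the other parental allele where parents differ
        fam_parents = np.zeros((G, 2), dtype=np.int64)
        r0 = 0
        for fam in design.families:
            fam_parents[r0: r0 + len(fam.genotypes)] = (
                design.founder_index(fam.parent1), design.founder_index(fam.parent2),
            )
            r0 += len(fam.genotypes)
        a1 = founder_alleles[fam_parents[:, 0]][:, :, None]  # (G, M, 1)
        a2 = founder_alleles[fam_parents[:, 1]][:, :, None]
        other = np.where(obs == a1, a2, a1)
        flip = (rng.random(obs.shape) < genotype_error) & (a1 != a2)
        obs = np.where(flip, other, obs)
    if missing_rate > 0:
        # drop whole calls (both alleles) with the given probability
        miss = rng.random(obs.shape[:2]) < missing_rate
        obs[miss] = MISSING

    markers = MarkerData(
        founder_ids=design.founders,
        founder_alleles=founder_alleles,
        offspring_ids=offspring_ids,
        offspring_alleles=obs,
    )
    truth = SimTruth(
        founders=design.founders,
        offspring_ids=offspring_ids,
        gmap=gmap,
        origins=origins,
        seed=seed,
    )
    return markers, truth


def simulate_phenotype(
    truth: SimTruth,
    design: MppDesign,
    qtls: list[QtlSpec],
    beta: dict[str, float],
    sigma_eps: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes from the generative QTL model using true origin counts.

    ``beta`` maps family id -> intercept; ``sigma_eps`` maps family id ->
    residual *variance* sigma_eps_k^2.  QTL effects are taken from each
    :class:`QtlSpec` (fixed ``effects``) or drawn once from
    N(0, sigma_q^2); the drawn or fixed effects are recorded on
    ``truth.qtl_effects``.
    """
    fam_of = design.family_of()
    G = len(truth.offspring_ids)
    y = np.zeros(G)
    fam_ids = np.array([fam_of[g] for g in truth.offspring_ids], dtype=object)
    for fid, b in beta.items():
        y[fam_ids == fid] += b

    truth.qtls = list(qtls)
    truth.qtl_effects = []
    truth.beta = dict(beta)
    truth.sigma_eps = dict(sigma_eps)
    for q in qtls:
        pos_span = truth.gmap.chromosome_positions(q.chromosome)
        if not (pos_span[0] - 1e-9 <= q.position_cM <= pos_span[-1] + 1e-9):
            raise InputError(
                f"QTL at {q.chromosome}:{q.position_cM} outside the mapped span"
            )
        if q.effects is not None:
            eff = dict(q.effects)
        else:
            sd = float(q.sigma_q if q.sigma_q is not None else 1.0)
            eff = {f: float(rng.normal(0.0, sd)) for f in truth.founders}
        truth.qtl_effects.append(eff)
        a = np.array([eff.get(f, 0.0) for f in truth.founders])
        counts = truth.true_counts_at(q.chromosome, q.position_cM)
        y += counts @ a
    for fid, s2 in sigma_eps.items():
        mask = fam_ids == fid
        y[mask] += rng.normal(0.0, np.sqrt(s2), size=int(mask.sum()))
    return y


# ---------------------------------------------------------------------------
# Canned scenarios used by the validation suite and examples
# ---------------------------------------------------------------------------

def nam_dh_scenario(
    rng: np.random.Generator,
    n_families: int = 3,
    n_per_family: int = 150,
    chrom_lengths: dict[str, float] | None = None,
    marker_step: float = 2.0,
    qtl_positions: list[tuple[str, float]] | None = None,
    qtl_variance_share: float = 0.6,
    sigma_eps: float = 1.0,
    genotype_error: float = 0.0,
    seed: int | None = None,
):
    """NAM of DH families sharing founder P1, with QTLs of a chosen
    within-family variance share.

    In a DH family the tested-parent allele count is 0 or 2 with equal
    probability, so a QTL with effect difference d between the family's
    parents contributes genetic variance d^2 within the family.  Effects
    are chosen as P1 -> 0 and alternating +/- delta for the other
    founders, with delta set so each QTL explains ``qtl_variance_share``
    of the within-family variance in every family (share s of total:
    d^2 = s / (1 - s_total) * sigma_eps^2 per QTL, with equal shares).

    Returns (design, gmap, markers, truth, y).
    """
    if chrom_lengths is None:
        chrom_lengths = {"1": 80.0, "2": 80.0}
    if qtl_positions is None:
        qtl_positions = [("1", 35.0)]
    gmap = make_grid_map(chrom_lengths, marker_step)
    founders = ["P1"] + [f"P{k + 2}" for k in range(n_families)]
    crosses = [
        (f"F{k + 1}", "P1", founders[k + 1], "DH") for k in range(n_families)
    ]
    design = make_design(founders, crosses, n_per_family)
    markers, truth = simulate_population(
        design, gmap, rng, genotype_error=genotype_error, seed=seed
    )
    n_q = len(qtl_positions)
    total_share = qtl_variance_share * n_q
    if not total_share < 1.0:
        raise InputError("total QTL variance share must be < 1")
    # per-allele effect difference |a_P1 - a_Pk| = delta gives within-family
    # genetic variance delta^2 in a DH family
    delta = np.sqrt(qtl_variance_share / (1.0 - total_share) * sigma_eps)
    qtls = []
    for chrom, pos in qtl_positions:
        effects = {"P1": 0.0}
        for j, f in enumerate(founders[1:]):
            effects[f] = delta * (1.0 if j % 2 == 0 else -1.0)
        qtls.append(QtlSpec(chrom, pos, effects=effects))
    beta = {f"F{k + 1}": 10.0 * (k + 1) for k in range(n_families)}
    eps = {f"F{k + 1}": sigma_eps for k in range(n_families)}
    y = simulate_phenotype(truth, design, qtls, beta, eps, rng)
    return design, gmap, markers, truth, y
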