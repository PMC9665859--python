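"""Parental-origin (IBD) probabilities via a forward-backward HMM.

Each offspring of a biparental family carries, at every genome position, a
pair of haplotypes whose ancestry traces to one of the family's two founder
parents.  The hidden state is the (ordered) pair of parental origins; the
observations are the offspring's marker genotypes compared against the
founder alleles.  Recombination makes origin a Markov chain along the
chromosome with transition probabilities driven by the Haldane map
function; a small genotyping error rate makes emissions robust to
miscalls.  Running the forward-backward algorithm on the chain of markers,
augmented with pseudo-observations at the requested evaluation grid,
yields exact posterior origin probabilities at every grid point.  These
posteriors are converted to the expected number of alleles inherited from
each founder (entries of the locus design matrix M_q used downstream by
the mixed model).

State spaces
------------
DH
    One meiosis then genome doubling: a single haplotype duplicated.  Two
    states (origin parent 1 / parent 2), prior 1/2 each, two-state Markov
    chain with switch probability r.
F2
    Two independent gametes from the F1: four ordered origin pairs, prior
    1/4 each, transition matrix the Kronecker product of two two-state
    chains.
RILn (n = 2..8)
    n - 1 generations of selfing after the F1.  Four ordered origin pairs
    with residual heterozygosity 0.5^(n-1) split over the two heterozygous
    states.  Transitions use the selfing-series chain collapsed to the
    observed line: the per-interval switch intensity matches the classic
    2r/(1+2r) inbred-line recombination fraction, applied as a
    prior-preserving jump kernel so the stationary law equals the RILn
    prior (see docs/methods.md for the derivation and the approximation
    involved).
RILinf
    Fully inbred line: two homozygous states, switch probability
    2r/(1+2r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ConfigError,
    EvalGrid,
    GeneticMap,
    InputError,
    MarkerData,
    MppDesign,
    NumericalDegeneracyError,
    PopType,
    build_grid,
    haldane_cm_to_r,
)

PLOIDY = 2

DEFAULT_ERROR_RATE = 0.01


def _ril_r(r: float) -> float:
    """Haldane-Waddington recombination fraction for an inbred line."""
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class OriginStateSpace:
    """Hidden-state space of parental origins for one population type.

    ``origin_pairs[s]`` gives, for state ``s``, the local parent index
    (0 = parent1, 1 = parent2) of each of the two haplotypes; for the
    collapsed two-state spaces (DH, RILinf) both haplotypes share one
    origin.  ``prior`` is the stationary distribution over states.
    """

    pop_type: PopType
    origin_pairs: tuple[tuple[int, int], ...]
    prior: np.ndarray

    @classmethod
    def for_pop_type(cls, pop_type: PopType) -> "OriginStateSpace":
        if pop_type.kind == "DH" or (pop_type.kind == "RIL" and pop_type.selfing_n is None):
            return cls(pop_type, ((0, 0), (1, 1)), np.array([0.5, 0.5]))
        if pop_type.kind == "F2":
            pairs = ((0, 0), (0, 1), (1, 0), (1, 1))
            return cls(pop_type, pairs, np.full(4, 0.25))
        if pop_type.kind == "RIL":
            h = pop_type.residual_heterozygosity
            pairs = ((0, 0), (0, 1), (1, 0), (1, 1))
            prior = np.array([(1 - h) / 2, h / 2, h / 2, (1 - h) / 2])
            return cls(pop_type, pairs, prior)
        raise ConfigError(f"unsupported population type {pop_type}")

    @property
    def n_states(self) -> int:
        return len(self.origin_pairs)

    @property
    def allele_counts(self) -> np.ndarray:
        """(n_states, 2) matrix: haplotypes contributed by each local parent."""
        counts = np.zeros((self.n_states, 2))
        for s, pair in enumerate(self.origin_pairs):
            # collapsed two-state spaces represent a doubled/inbred genome
            for origin in pair:
                counts[s, origin] += 1.0
        return counts


def transition_matrix(space: OriginStateSpace, r: float) -> np.ndarray:
    """Origin-state transition matrix across an interval with recombination
    fraction *r*.

    Rows sum to 1 and the state-space prior is stationary under the
    returned matrix.
    """
    if not (0.0 <= r <= 0.5):
        raise InputError(f"recombination fraction must be in [0, 0.5], got {r}")
    pt = space.pop_type
    if pt.kind == "DH":
        return np.array([[1 - r, r], [r, 1 - r]])
    if pt.kind == "RIL" and pt.selfing_n is None:
        R = _ril_r(r)
        return np.array([[1 - R, R], [R, 1 - R]])
    if pt.kind == "F2":
        d = np.array([[1 - r, r], [r, 1 - r]])
        return np.kron(d, d)
    # finite RILn: prior-preserving jump kernel with inbred-line switch rate
    R = _ril_r(r)
    lam = 2.0 * R  # per-haplotype switch prob R = lam * pi(other origin) = lam/2
    prior = space.prior
    return (1.0 - lam) * np.eye(space.n_states) + lam * np.tile(prior, (space.n_states, 1))


def emission_prob(
    space: OriginStateSpace,
    observed: tuple[int, int],
    parent_alleles: tuple[int, int],
    error_rate: float = DEFAULT_ERROR_RATE,
) -> np.ndarray:
    """Per-state emission probabilities for one observed genotype call.

    ``observed`` is the (unordered) pair of observed allele codes, with
    :data:`MISSING` entries allowed; ``parent_alleles`` are the homozygous
    allele codes of the family's two parents at this marker.  Each
    observed allele matches the allele implied by the state's origin with
    probability ``1 - error_rate`` and mismatches with ``error_rate``.  A
    fully missing call, or a marker where either parent allele is missing
    or both parents carry the same allele, is uninformative: emission 1
    for every state.
    """
    if not (0.0 <= error_rate < 0.5):
        raise InputError(f"error_rate must be in [0, 0.5), got {error_rate}")
    obs = np.array(
        [[observed[0], observed[1]]], dtype=np.int64
    )
    out = _emissions_at_marker(
        space, obs, int(parent_alleles[0]), int(parent_alleles[1]), error_rate,
        allele_universe=None,
    )
    return out[0]


def _emissions_at_marker(
    space: OriginStateSpace,
    observed: np.ndarray,
    allele_p1: int,
    allele_p2: int,
    error_rate: float,
    allele_universe: set[int] | None,
) -> np.ndarray:
    """Vectorised emissions: observed (n_geno, 2) -> (n_geno, n_states)."""
    n = observed.shape[0]
    S = space.n_states
    out = np.ones((n, S))
    if allele_p1 == MISSING or allele_p2 == MISSING or allele_p1 == allele_p2:
        return out  # uninformative marker
    parent_allele = np.array([allele_p1, allele_p2])

    o1, o2 = observed[:, 0], observed[:, 1]
    both_missing = (o1 == MISSING) & (o2 == MISSING)
    if allele_universe is not None:
        seen = np.unique(observed[observed != MISSING])
        bad = [int(a) for a in seen if int(a) not in allele_universe]
        if bad:
            raise InputError(
                f"observed allele(s) {bad} not present in any founder at this marker"
            )

    eps, match = error_rate, 1.0 - error_rate

    def allele_lik(obs_col: np.ndarray, implied: int) -> np.ndarray:
        # missing single allele contributes factor 1
        lik = np.where(obs_col == implied, match, eps)
        return np.where(obs_col == MISSING, 1.0, lik)

    for s, pair in enumerate(space.origin_pairs):
        a1 = int(parent_allele[pair[0]])
        a2 = int(parent_allele[pair[1]])
        # unordered observation: average over the two pairings
        p = 0.5 * (
            allele_lik(o1, a1) * allele_lik(o2, a2)
            + allele_lik(o2, a1) * allele_lik(o1, a2)
        )
        out[:, s] = p
    out[both_missing] = 1.0
    return out


def _forward_backward(
    emissions: list[np.ndarray],
    transitions: list[np.ndarray],
    prior: np.ndarray,
) -> np.ndarray:
    """Scaled forward-backward over a chain of nodes.

    ``emissions[t]`` has shape (n_geno, S); ``transitions[t]`` is the S x S
    matrix from node t to node t+1.  Returns posteriors with shape
    (n_geno, n_nodes, S), each row summing to 1.
    """
    T = len(emissions)
    n, S = emissions[0].shape
    alpha = np.empty((n, T, S))
    scale = np.empty((n, T))

    a = prior[None, :] * emissions[0]
    c = a.sum(axis=1)
    if np.any(c <= 0):
        raise NumericalDegeneracyError(
            "forward pass lost all probability mass (impossible data); "
            "use a genotyping error rate > 0"
        )
    a = a / c[:, None]
    alpha[:, 0], scale[:, 0] = a, c
    for t in range(1, T):
        a = (a @ transitions[t - 1]) * emissions[t]
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise NumericalDegeneracyError(
                "forward pass lost all probability mass (impossible data); "
                "use a genotyping error rate > 0"
            )
        a = a / c[:, None]
        alpha[:, t], scale[:, t] = a, c

    post = np.empty((n, T, S))
    b = np.ones((n, S))
    post[:, T - 1] = alpha[:, T - 1] * b
    for t in range(T - 2, -1, -1):
        b = (emissions[t + 1] * b / scale[:, t + 1][:, None]) @ transitions[t].T
        post[:, t] = alpha[:, t] * b
    post /= post.sum(axis=2, keepdims=True)
    return post


def posterior_origin_probs(
    marker_positions: np.ndarray,
    observations: np.ndarray,
    parent_alleles: np.ndarray,
    space: OriginStateSpace,
    grid_positions: np.ndarray,
    error_rate: float = DEFAULT_ERROR_RATE,
    allele_universe_per_marker: list[set[int]] | None = None,
) -> np.ndarray:
    """Posterior origin-state probabilities at grid positions on one
    chromosome.

    Parameters
    ----------
    marker_positions : (M,) sorted marker positions in cM.
    observations : (n_geno, M, 2) observed allele-code pairs.
    parent_alleles : (2, M) homozygous allele codes of the two parents.
    space : state space for the family's population type.
    grid_positions : (L,) sorted evaluation positions in cM.
    error_rate : per-allele genotyping error probability.

    Returns
    -------
    (n_geno, L, n_states) posteriors; each (genotype, position) row sums
    to 1.

    Grid positions are inserted into the marker chain as pseudo-markers
    with uniform emissions; the forward-backward pass over the augmented
    chain gives exact posteriors at every grid point.
    """
    marker_positions = np.asarray(marker_positions, dtype=float)
    grid_positions = np.asarray(grid_positions, dtype=float)
    if np.any(np.diff(marker_positions) < 0):
        raise InputError("marker positions must be sorted")
    if np.any(np.diff(grid_positions) < 0):
        raise InputError("grid positions must be sorted")
    observations = np.asarray(observations, dtype=np.int64)
    n_geno = observations.shape[0]
    M, L = len(marker_positions), len(grid_positions)

    # merged chain: markers and grid pseudo-markers, stable on ties
    nodes = [(p, "m", i) for i, p in enumerate(marker_positions)]
    nodes += [(p, "g", i) for i, p in enumerate(grid_positions)]
    nodes.sort(key=lambda t: (t[0], 0 if t[1] == "m" else 1))

    emissions: list[np.ndarray] = []
    for pos, kind, idx in nodes:
        if kind == "g":
            emissions.append(np.ones((n_geno, space.n_states)))
        else:
            universe = (
                allele_universe_per_marker[idx]
                if allele_universe_per_marker is not None
                else None
            )
            emissions.append(
                _emissions_at_marker(
                    space,
                    observations[:, idx, :],
                    int(parent_alleles[0, idx]),
                    int(parent_alleles[1, idx]),
                    error_rate,
                    universe,
                )
            )
    transitions = [
        transition_matrix(space, haldane_cm_to_r(nodes[t + 1][0] - nodes[t][0]))
        for t in range(len(nodes) - 1)
    ]
    post = _forward_backward(emissions, transitions, space.prior)
    grid_node_index = [t for t, nd in enumerate(nodes) if nd[1] == "g"]
    return post[:, grid_node_index, :]


@dataclass
class IbdResult:
    """Expected founder allele counts per genotype and grid position.

    ``counts`` has shape (n_genotypes, n_positions, n_founders) with
    entries in [0, 2]; per (genotype, position) the founder counts sum to
    the ploidy (2).  Founders not parental to a genotype's family have
    exact zeros.  ``counts[:, l, :]`` is the locus design matrix M_q for
    grid position ``l``.
    """

    genotypes: tuple[str, ...]
    grid: EvalGrid
    founders: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (len(self.genotypes), self.grid.n_positions, len(self.founders))
        if self.counts.shape != expected:
            raise InputError(
                f"counts shape {self.counts.shape} != {expected}"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def design_matrix(self, position_index: int) -> np.ndarray:
        """M_q at one grid position: (n_genotypes, n_founders)."""
        return self.counts[:, position_index, :]

    def subset(self, genotype_ids: list[str]) -> "IbdResult":
        lookup = {g: i for i, g in enumerate(self.genotypes)}
        try:
            idx = [lookup[g] for g in genotype_ids]
        except KeyError as e:
            raise InputError(f"genotype {e.args[0]!r} absent from IBD result") from e
        return IbdResult(
            tuple(genotype_ids), self.grid, self.founders, self.counts[idx]
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: genotype, chromosome, position, parent, prob.

        ``prob`` is the expected count divided by the ploidy, i.e. the
        probability that a random allele of the genotype descends from
        the parent.
        """
        g_idx, l_idx, p_idx = np.meshgrid(
            np.arange(self.n_genotypes),
            np.arange(self.grid.n_positions),
            np.arange(len(self.founders)),
            indexing="ij",
        )
        chroms = np.asarray(self.grid.chromosomes, dtype=object)
        poss = np.asarray(self.grid.positions, dtype=float)
        return pd.DataFrame(
            {
                "genotype": np.asarray(self.genotypes, dtype=object)[g_idx.ravel()],
                "chromosome": chroms[l_idx.ravel()],
                "position": poss[l_idx.ravel()],
                "parent": np.asarray(self.founders, dtype=object)[p_idx.ravel()],
                "prob": self.counts.ravel() / PLOIDY,
            }
        )


def calc_ibd_mpp(
    gmap: GeneticMap,
    markers: MarkerData,
    design: MppDesign,
    step_cM: float = 5.0,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> IbdResult:
    """Compute IBD expected founder allele counts for a whole MPP design.

    Runs the per-family, per-chromosome forward-backward HMM and converts
    origin-state posteriors to expected parental allele counts, assembled
    into a global (genotype, grid position, founder) array with zeros in
    the columns of non-parental founders.
    """
    for f in design.founders:
        if f not in markers.founder_ids:
            raise InputError(f"founder {f!r} missing from marker data")
    grid = build_grid(gmap, step_cM)
    genotypes = design.genotype_ids
    counts = np.zeros((len(genotypes), grid.n_positions, design.n_founders))
    row_of = {g: i for i, g in enumerate(genotypes)}

    # allele universe per marker: all alleles seen in any founder
    universes: list[set[int]] = [
        {int(a) for a in markers.founder_alleles[:, m] if a != MISSING}
        for m in range(markers.n_markers)
    ]

    for fam in design.families:
        try:
            space = OriginStateSpace.for_pop_type(fam.pop_type)
        except ConfigError as e:
            raise ConfigError(
                f"family {fam.family_id}: {e}"
            ) from e
        obs_all = markers.offspring_rows(fam.genotypes)
        p1_row = markers.founder_row(fam.parent1)
        p2_row = markers.founder_row(fam.parent2)
        acounts = space.allele_counts  # (S, 2)
        fam_rows = [row_of[g] for g in fam.genotypes]
        p_cols = [design.founder_index(fam.parent1), design.founder_index(fam.parent2)]
        for chrom in gmap.chromosome_names:
            midx = gmap.chromosome_indices(chrom)
            gidx = grid.chromosome_slice(chrom)
            post = posterior_origin_probs(
                np.asarray(gmap.positions)[midx],
                obs_all[:, midx, :],
                np.vstack([p1_row[midx], p2_row[midx]]),
                space,
                np.asarray(grid.positions)[gidx],
                error_rate,
                allele_universe_per_marker=[universes[m] for m in midx],
            )
            expected = post @ acounts  # (n_geno, L_chrom, 2)
            counts[np.ix_(fam_rows, gidx, p_cols)] = expected
    return IbdResult(genotypes, grid, design.founders, counts)
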