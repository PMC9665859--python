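"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mppqtl as m


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def enumerate_chain_posteriors(emissions, transitions, prior):
    """Exhaustive hidden-path posterior for one genotype on a short chain.

    ``emissions`` is a (T, S) array, ``transitions`` a list of T-1 SxS
    matrices.  Sums the joint probability over every one of S**T hidden
    paths — independent of the forward-backward recursion it checks.
    """
    emissions = np.asarray(emissions, dtype=float)
    T, S = emissions.shape
    post = np.zeros((T, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=T):
        p = prior[path[0]] * emissions[0, path[0]]
        for t in range(1, T):
            p *= transitions[t - 1][path[t - 1], path[t]] * emissions[t, path[t]]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def per_allele_emission(obs, parent_alleles, origin_pairs, eps):
    """Test-side emission model, written independently of the package.

    ``obs`` is an unordered pair of allele codes (-1 missing);
    ``parent_alleles`` the two parents' homozygous codes at the marker.
    """
    S = len(origin_pairs)
    if parent_alleles[0] == parent_alleles[1] or -1 in parent_alleles:
        return np.ones(S)
    if obs[0] == -1 and obs[1] == -1:
        return np.ones(S)

    def lik(o, a):
        if o == -1:
            return 1.0
        return 1.0 - eps if o == a else eps

    out = np.empty(S)
    for s, (h1, h2) in enumerate(origin_pairs):
        a1, a2 = parent_alleles[h1], parent_alleles[h2]
        out[s] = 0.5 * (lik(obs[0], a1) * lik(obs[1], a2)
                        + lik(obs[1], a1) * lik(obs[0], a2))
    return out


def oracle_grid_posteriors(space, marker_pos, grid_pos, observations,
                           parent_alleles, eps):
    """Grid posteriors by exhaustive enumeration on the augmented chain.

    Grid positions must not coincide with marker positions (keeps the
    merged node order unambiguous).  ``observations``: (n_geno, M, 2).
    """
    nodes = sorted(
        [(p, "m", i) for i, p in enumerate(marker_pos)]
        + [(p, "g", i) for i, p in enumerate(grid_pos)]
    )
    transitions = [
        m.ibd.transition_matrix(space, m.haldane_cm_to_r(nodes[t + 1][0] - nodes[t][0]))
        for t in range(len(nodes) - 1)
    ]
    out = np.empty((observations.shape[0], len(grid_pos), space.n_states))
    for g in range(observations.shape[0]):
        emissions = []
        for pos, kind, idx in nodes:
            if kind == "g":
                emissions.append(np.ones(space.n_states))
            else:
                emissions.append(
                    per_allele_emission(
                        tuple(observations[g, idx]),
                        (int(parent_alleles[0, idx]), int(parent_alleles[1, idx])),
                        space.origin_pairs, eps,
                    )
                )
        post = enumerate_chain_posteriors(emissions, transitions, space.prior)
        gi = [t for t, nd in enumerate(nodes) if nd[1] == "g"]
        out[g] = post[gi]
    return out


def anova_reml_oneway(y, groups, n_per_group):
    """Closed-form REML for the balanced one-way random-effects layout:
    sigma_between = max(0, (MSB - MSW) / m), sigma_within = MSW."""
    y = np.asarray(y, dtype=float)
    g = len(np.unique(groups))
    means = np.array([y[groups == k].mean() for k in range(g)])
    grand = y.mean()
    msb = n_per_group * np.sum((means - grand) ** 2) / (g - 1)
    msw = sum(np.sum((y[groups == k] - means[k]) ** 2) for k in range(g)) / (
        g * (n_per_group - 1)
    )
    return max(0.0, (msb - msw) / n_per_group), msw


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_map():
    """Two chromosomes, markers every 5 cM over 0-20 cM."""
    return m.make_grid_map({"1": 20.0, "2": 20.0}, 5.0)


@pytest.fixture
def dh_nam(rng):
    """Seeded 2-family DH NAM with one QTL on chromosome 1 at 10 cM."""
    design, gmap, markers, truth, y = m.nam_dh_scenario(
        rng, n_families=2, n_per_family=60,
        chrom_lengths={"1": 40.0, "2": 40.0}, marker_step=5.0,
        qtl_positions=[("1", 10.0)], qtl_variance_share=0.5,
    )
    pheno = pd.Series(y, index=pd.Index(design.genotype_ids), name="trait")
    return design, gmap, markers, truth, pheno
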