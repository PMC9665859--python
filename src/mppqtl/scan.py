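"""Genome scan and multi-round QTL selection.

Every evaluation-grid position is tested with the single-locus random-QTL
mixed model: the locus design matrix M_q (expected founder allele counts
from the IBD step) enters as a random term with variance sigma_q^2, and
the test compares the REML fits with and without that term using the
boundary-mixture chi-square LRT.  Already-selected QTLs act as random
cofactors (each with its own variance), following the composite-interval
mapping convention: when the tested position falls within the exclusion
window of a cofactor, that cofactor is dropped from both the null and the
full model for that position's test.  Rounds continue until no new
position exceeds the -log10(p) threshold outside the window around
existing QTLs, or a maximum QTL count is reached; the final model refits
all selected QTLs jointly and reports per-parent BLUP effects with
prediction-error SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InputError, MppDesign
from .ibd import IbdResult
from .mixed_model import (
    ModelSpec,
    RandomTerm,
    VarCompFit,
    kinship_term,
    lrt_mixture_pvalue,
    reml_fit,
)

DEFAULT_THRESHOLD = 3.0
DEFAULT_WINDOW_CM = 10.0
DEFAULT_MAX_QTL = 10


def kinship_from_ibd(ibd: IbdResult, exclude_chromosome: str | None = None) -> np.ndarray:
    """Kinship matrix from genome-wide IBD design matrices.

    K = (1 / (2 L)) * sum_l M_l M_l', over the L grid positions (optionally
    excluding one chromosome for leave-one-chromosome-out), rescaled so
    mean(diag(K)) = 1.  Symmetric PSD by construction.
    """
    if ibd.grid.n_positions == 0:
        raise InputError("empty IBD result")
    if exclude_chromosome is None:
        use = np.arange(ibd.grid.n_positions)
    else:
        chroms = np.asarray(ibd.grid.chromosomes, dtype=object)
        use = np.flatnonzero(chroms != exclude_chromosome)
        if use.size == 0:
            raise InputError("no grid positions left after chromosome exclusion")
    M = ibd.counts[:, use, :]
    L = use.size
    K = np.einsum("glp,hlp->gh", M, M) / (2.0 * L)
    K = 0.5 * (K + K.T)
    d = float(np.mean(np.diag(K)))
    if d > 0:
        K = K / d
    return K


@dataclass
class ScanProfile:
    """Per-position test results: one row per grid position."""

    frame: pd.DataFrame  # chromosome, position, lrt, p, minus_log10_p

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "lrt", "p", "minus_log10_p"}
        if not required.issubset(self.frame.columns):
            raise InputError(f"profile frame needs columns {sorted(required)}")

    @property
    def minus_log10_p(self) -> np.ndarray:
        return self.frame["minus_log10_p"].to_numpy()

    def peak(self) -> pd.Series:
        return self.frame.loc[self.frame["minus_log10_p"].idxmax()]


@dataclass
class Qtl:
    chromosome: str
    position_cM: float
    grid_index: int
    round_found: int
    peak_minus_log10_p: float


@dataclass
class QtlModel:
    """Selected QTLs, their per-parent effects, and the final joint fit."""

    qtls: list[Qtl]
    effects: pd.DataFrame  # qtl_id, parent, effect, se
    final_fit: VarCompFit | None
    final_profile: ScanProfile
    n_rounds: int

    def qtl_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qtl_id": [f"qtl{i + 1}" for i in range(len(self.qtls))],
                "chromosome": [q.chromosome for q in self.qtls],
                "position": [q.position_cM for q in self.qtls],
                "round": [q.round_found for q in self.qtls],
                "peak_minus_log10_p": [q.peak_minus_log10_p for q in self.qtls],
            }
        )


def _align(ibd: IbdResult, phenotypes: pd.Series, design: MppDesign):
    """Intersect IBD genotypes with non-missing phenotypes, keeping IBD
    order; build fixed design and residual grouping."""
    pheno = phenotypes.dropna()
    ids = [g for g in ibd.genotypes if g in pheno.index]
    if not ids:
        raise InputError("no overlap between phenotype ids and IBD genotype ids")
    sub = ibd.subset(ids)
    y = pheno.loc[ids].to_numpy(dtype=float)
    fam_of = design.family_of()
    fam_ids = [fam_of[g] for g in ids]
    present = [f.family_id for f in design.families if f.family_id in set(fam_ids)]
    code = {f: i for i, f in enumerate(present)}
    groups = np.array([code[f] for f in fam_ids], dtype=int)
    X = np.zeros((len(ids), len(present)))
    X[np.arange(len(ids)), groups] = 1.0
    return sub, y, X, groups, tuple(present)


class _ScanEngine:
    """Shared state for one round of genome scanning."""

    def __init__(
        self,
        ibd: IbdResult,
        phenotypes: pd.Series,
        design: MppDesign,
        cofactor_indices: list[int],
        use_kinship: bool,
        window_cM: float,
    ):
        self.ibd, self.y, self.X, self.groups, self.labels = _align(
            ibd, phenotypes, design
        )
        self.cof_idx = list(cofactor_indices)
        self.window = window_cM
        self.use_kinship = use_kinship
        self.grid = self.ibd.grid
        self.chroms = np.asarray(self.grid.chromosomes, dtype=object)
        self.positions = np.asarray(self.grid.positions, dtype=float)
        self._kin_terms: dict[str, RandomTerm] = {}
        self._null_cache: dict[tuple, float] = {}

    def _kin_term(self, chrom: str) -> RandomTerm:
        if chrom not in self._kin_terms:
            K = kinship_from_ibd(
                self.ibd,
                exclude_chromosome=chrom if len(set(self.chroms)) > 1 else None,
            )
            self._kin_terms[chrom] = kinship_term(K)
        return self._kin_terms[chrom]

    def _cof_term(self, idx: int) -> RandomTerm:
        return RandomTerm(f"cof@{idx}", self.ibd.design_matrix(idx))

    def active_cofactors(self, l: int) -> list[int]:
        """Cofactors kept for testing position l: those farther than the
        window (or on another chromosome)."""
        out = []
        for c in self.cof_idx:
            same = self.chroms[c] == self.chroms[l]
            if not same or abs(self.positions[c] - self.positions[l]) >= self.window:
                out.append(c)
        return out

    def null_loglik(self, active: list[int], chrom: str) -> float:
        key = (tuple(active), chrom if self.use_kinship else "")
        if key not in self._null_cache:
            terms = [self._cof_term(c) for c in active]
            if self.use_kinship:
                terms.append(self._kin_term(chrom))
            fit = reml_fit(
                ModelSpec(self.y, self.X, terms, self.groups, self.labels)
            )
            self._null_cache[key] = fit.loglik
        return self._null_cache[key]

    def test_position(self, l: int) -> tuple[float, float, float]:
        chrom = str(self.chroms[l])
        active = self.active_cofactors(l)
        ll_null = self.null_loglik(active, chrom)
        terms = [RandomTerm("qtl", self.ibd.design_matrix(l))]
        terms += [self._cof_term(c) for c in active]
        if self.use_kinship:
            terms.append(self._kin_term(chrom))
        fit = reml_fit(ModelSpec(self.y, self.X, terms, self.groups, self.labels))
        return lrt_mixture_pvalue(fit.loglik, ll_null)


def scan_genome(
    ibd: IbdResult,
    phenotypes: pd.Series,
    design: MppDesign,
    cofactor_indices: list[int] | None = None,
    use_kinship: bool = False,
    window_cM: float = DEFAULT_WINDOW_CM,
) -> ScanProfile:
    """Single-round genome scan: mixture-chi2 p-value per grid position.

    ``cofactor_indices`` are grid indices of already-selected QTLs,
    included as random cofactor terms except within *window_cM* of the
    tested position (dropped-and-refit treatment).
    """
    eng = _ScanEngine(
        ibd, phenotypes, design, cofactor_indices or [], use_kinship, window_cM
    )
    rows = []
    for l in range(eng.grid.n_positions):
        lrt, p, mlp = eng.test_position(l)
        rows.append((str(eng.chroms[l]), float(eng.positions[l]), lrt, p, mlp))
    return ScanProfile(
        pd.DataFrame(rows, columns=["chromosome", "position", "lrt", "p", "minus_log10_p"])
    )


def select_qtl(
    profile: ScanProfile,
    existing: list[tuple[str, float]],
    threshold: float = DEFAULT_THRESHOLD,
    window_cM: float = DEFAULT_WINDOW_CM,
) -> tuple[str, float, int, float] | None:
    """Best new QTL candidate, or None.

    Returns (chromosome, position, row_index, minus_log10_p) for the
    position with maximal -log10(p) among positions at least *window_cM*
    from every existing QTL on the same chromosome, if that maximum
    reaches the threshold.  Ties break by chromosome order then lowest cM.
    """
    if not threshold > 0 or not window_cM > 0:
        raise InputError("threshold and window_cM must be > 0")
    df = profile.frame
    eligible = np.ones(len(df), dtype=bool)
    for chrom, pos in existing:
        same = (df["chromosome"] == chrom).to_numpy()
        near = np.abs(df["position"].to_numpy() - pos) < window_cM
        eligible &= ~(same & near)
    if not eligible.any():
        return None
    sub = df[eligible]
    best_val = sub["minus_log10_p"].max()
    if best_val < threshold:
        return None
    ties = sub[sub["minus_log10_p"] == best_val]
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(df["chromosome"]))}
    order = sorted(
        ties.index,
        key=lambda i: (chrom_rank[ties.loc[i, "chromosome"]], ties.loc[i, "position"]),
    )
    row = ties.loc[order[0]]
    return str(row["chromosome"]), float(row["position"]), int(order[0]), float(best_val)


def multi_round_scan(
    ibd: IbdResult,
    phenotypes: pd.Series,
    design: MppDesign,
    threshold: float = DEFAULT_THRESHOLD,
    window_cM: float = DEFAULT_WINDOW_CM,
    max_qtl: int = DEFAULT_MAX_QTL,
    use_kinship: bool = False,
) -> QtlModel:
    """Multi-round genome scan with random cofactors.

    Round r scans with the r - 1 previously selected QTLs as cofactors
    and appends the best eligible candidate; stops when no candidate
    reaches the threshold or *max_qtl* is reached.  The final model
    refits all selected QTLs jointly to report per-parent BLUP effects
    with prediction-error SEs.
    """
    if max_qtl < 1:
        raise InputError("max_qtl must be >= 1")
    qtls: list[Qtl] = []
    profile = scan_genome(ibd, phenotypes, design, [], use_kinship, window_cM)
    n_rounds = 1
    while True:
        cand = select_qtl(
            profile, [(q.chromosome, q.position_cM) for q in qtls], threshold, window_cM
        )
        if cand is None:
            break
        chrom, pos, idx, mlp = cand
        qtls.append(Qtl(chrom, pos, idx, n_rounds, mlp))
        if len(qtls) >= max_qtl:
            break
        n_rounds += 1
        profile = scan_genome(
            ibd, phenotypes, design, [q.grid_index for q in qtls], use_kinship, window_cM
        )

    # final joint refit for effects
    final_fit = None
    eff_rows = []
    if qtls:
        sub, y, X, groups, labels = _align(ibd, phenotypes, design)
        terms = [
            RandomTerm(f"qtl{i + 1}", sub.design_matrix(q.grid_index))
            for i, q in enumerate(qtls)
        ]
        if use_kinship:
            terms.append(kinship_term(kinship_from_ibd(sub)))
        final_fit = reml_fit(ModelSpec(y, X, terms, groups, labels))
        for i, q in enumerate(qtls):
            label = f"qtl{i + 1}"
            for j, parent in enumerate(sub.founders):
                eff_rows.append(
                    (
                        label,
                        parent,
                        float(final_fit.blups[label][j]),
                        float(final_fit.blup_se[label][j]),
                    )
                )
    effects = pd.DataFrame(eff_rows, columns=["qtl_id", "parent", "effect", "se"])
    return QtlModel(qtls, effects, final_fit, profile, n_rounds)
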