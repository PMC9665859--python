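"""Variance-component mixed model: REML fitting and the boundary-mixture LRT.

The single-locus QTL model is

    Y = X beta + M_q a_q + g + eps,
    a_q ~ N(0, I_P sigma_q^2),  g ~ N(0, K sigma_g^2),
    eps ~ N(0, blockdiag_k I_{n_k} sigma_eps_k^2),

with Y the phenotypes, X the fixed family-intercept design, M_q the
expected founder allele counts at the tested locus, a_q the random
parental QTL effects, g an optional polygenic term with kinship K, and a
family-specific residual variance for each of the F families.  All
variance components are estimated by restricted maximum likelihood
(REML); the presence of a QTL is tested by a likelihood-ratio statistic
whose null distribution on the variance boundary is the 0.5 chi2_0 +
0.5 chi2_1 mixture.

Implementation notes
--------------------
Every random term is carried as a design matrix Z_t scaled so that its
covariance contribution is ``sigma_t^2 Z_t Z_t'`` (a term with a
non-identity covariance such as K passes Z = K^{1/2}).  The covariance

    V = sum_t sigma_t^2 Z_t Z_t' + R,   R diagonal per-family

is inverted via the Woodbury identity, so one likelihood evaluation costs
O(n c^2) for c total random columns — small for locus terms (one column
per founder).  Optimisation is bounded quasi-Newton (L-BFGS-B) on
log-variances with two starting points (equal split and residual-heavy);
components may converge to the boundary, where they are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .core import InputError

#: Variance floor during optimisation, as a fraction of var(Y).
VARIANCE_FLOOR_FRACTION = 1e-10

MAX_ITER = 200


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: covariance contribution ``sigma^2 * Z @ Z.T``."""

    label: str
    Z: np.ndarray


@dataclass
class ModelSpec:
    """A fully specified variance-component model.

    Parameters
    ----------
    y : (n,) phenotype vector.
    X : (n, p) fixed-effect design (family intercepts); full column rank.
    terms : random terms, each with its own variance component.
    residual_groups : (n,) integer family index per observation; each
        group gets its own residual variance.
    group_labels : optional family labels, index-aligned with the group
        codes.
    """

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm] = field(default_factory=list)
    residual_groups: np.ndarray | None = None
    group_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.shape[0]
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise InputError("X must be (n, p) with n matching y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise InputError("fixed-effect design X is rank deficient")
        if n < self.X.shape[1] + 1:
            raise InputError("need n >= number of fixed effects + 1")
        if self.residual_groups is None:
            self.residual_groups = np.zeros(n, dtype=int)
        self.residual_groups = np.asarray(self.residual_groups, dtype=int)
        if self.residual_groups.shape != (n,):
            raise InputError("residual_groups must be length n")
        codes = np.unique(self.residual_groups)
        if not np.array_equal(codes, np.arange(codes.size)):
            raise InputError("residual_groups must be coded 0..G-1 with no gaps")
        for t in self.terms:
            Z = np.asarray(t.Z, dtype=float)
            if Z.ndim != 2 or Z.shape[0] != n:
                raise InputError(f"random term {t.label!r}: Z must be (n, c)")
        if self.group_labels is None:
            self.group_labels = tuple(str(g) for g in range(codes.size))

    @property
    def n_groups(self) -> int:
        return int(self.residual_groups.max()) + 1


def kinship_term(K: np.ndarray, label: str = "polygenic") -> RandomTerm:
    """Random term for a polygenic effect with covariance ``K sigma_g^2``.

    K must be symmetric positive semidefinite; it is factored as
    ``Z Z.T`` through an eigendecomposition (eigenvalues below -1e-8
    raise, tiny negatives are clipped).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise InputError("K must be symmetric")
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise InputError(f"K is not positive semidefinite (min eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    keep = w > 1e-12 * max(1.0, w.max())
    return RandomTerm(label, U[:, keep] * np.sqrt(w[keep]))


@dataclass
class VarCompFit:
    """REML estimates for one :class:`ModelSpec`.

    ``variances`` maps term label -> sigma_t^2 and ``residual_variances``
    maps family label -> sigma_eps_k^2 (boundary estimates reported as
    0.0).  ``blups`` / ``blup_se`` hold the predicted random effects and
    their prediction-error SDs per term.
    """

    variances: dict[str, float]
    residual_variances: dict[str, float]
    loglik: float
    beta: np.ndarray
    blups: dict[str, np.ndarray]
    blup_se: dict[str, np.ndarray]
    converged: bool
    n_iter: int


class _RemlWorkspace:
    """Precomputed pieces shared by all likelihood evaluations."""

    def __init__(self, spec: ModelSpec):
        self.y = spec.y
        self.X = spec.X
        self.n, self.p = spec.X.shape
        self.groups = spec.residual_groups
        self.n_groups = spec.n_groups
        self.terms = spec.terms
        if self.terms:
            self.U = np.hstack([np.asarray(t.Z, dtype=float) for t in self.terms])
            self.term_cols = []
            start = 0
            for t in self.terms:
                c = t.Z.shape[1]
                self.term_cols.append(slice(start, start + c))
                start += c
        else:
            self.U = np.zeros((self.n, 0))
            self.term_cols = []
        self.c = self.U.shape[1]
        vy = float(np.var(self.y))
        self.var_y = vy if vy > 0 else 1.0
        self.floor = VARIANCE_FLOOR_FRACTION * self.var_y

    def _vinv_apply(self, sig_terms: np.ndarray, sig_res: np.ndarray):
        """Return (solve, logdetV) for the current variances.

        ``solve(B)`` computes V^{-1} B via the Woodbury identity.
        """
        rinv = 1.0 / sig_res[self.groups]  # (n,)
        logdet_R = float(np.sum(np.log(sig_res[self.groups])))
        if self.c == 0:
            def solve(B: np.ndarray) -> np.ndarray:
                return B * rinv[:, None] if B.ndim == 2 else B * rinv
            return solve, logdet_R
        d = np.concatenate(
            [np.full(sl.stop - sl.start, s) for sl, s in zip(self.term_cols, sig_terms)]
        )
        sqrt_d = np.sqrt(d)
        Us = self.U * sqrt_d[None, :]  # U D^{1/2}
        RiUs = Us * rinv[:, None]
        A = np.eye(self.c) + Us.T @ RiUs
        cho = linalg.cho_factor(A, lower=True)
        logdetV = logdet_R + 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

        def solve(B: np.ndarray) -> np.ndarray:
            one_d = B.ndim == 1
            Bm = B[:, None] if one_d else B
            RiB = Bm * rinv[:, None]
            out = RiB - RiUs @ linalg.cho_solve(cho, Us.T @ RiB)
            return out[:, 0] if one_d else out

        return solve, logdetV

    def neg_restricted_ll(self, theta: np.ndarray) -> float:
        try:
            return -self.restricted_ll(np.exp(theta))[0]
        except linalg.LinAlgError:
            return 1e30

    def restricted_ll(self, variances: np.ndarray):
        """Restricted log-likelihood and GLS pieces at given variances.

        ``variances`` concatenates term variances then group residual
        variances.  Returns (ll, beta, solve).
        """
        sig_terms = variances[: len(self.terms)]
        sig_res = variances[len(self.terms):]
        solve, logdetV = self._vinv_apply(sig_terms, sig_res)
        ViX = solve(self.X)
        XtViX = self.X.T @ ViX
        cho_x = linalg.cho_factor(XtViX, lower=True)
        logdet_X = 2.0 * float(np.sum(np.log(np.diag(cho_x[0]))))
        beta = linalg.cho_solve(cho_x, ViX.T @ self.y)
        e = self.y - self.X @ beta
        Vie = solve(e)
        quad = float(e @ Vie)
        ll = -0.5 * (
            logdetV + logdet_X + quad + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return ll, beta, solve


def _starts(ws: _RemlWorkspace) -> list[np.ndarray]:
    """Two heuristic starting points on the variance scale."""
    beta_ols, *_ = np.linalg.lstsq(ws.X, ws.y, rcond=None)
    resid_var = float(np.var(ws.y - ws.X @ beta_ols))
    resid_var = max(resid_var, 10 * ws.floor)
    T = len(ws.terms)
    starts = []
    # equal split across all components
    eq = resid_var / (T + 1)
    starts.append(np.concatenate([np.full(T, eq), np.full(ws.n_groups, eq)]))
    # residual-heavy
    starts.append(
        np.concatenate(
            [np.full(T, 0.1 * resid_var / max(T, 1)), np.full(ws.n_groups, 0.9 * resid_var)]
        )
    )
    return starts


def reml_fit(spec: ModelSpec) -> VarCompFit:
    """Fit a variance-component model by restricted maximum likelihood.

    Maximises the restricted log-likelihood over log-parametrised
    variances (bounded quasi-Newton, two starts).  Components at the
    variance floor are reported as exactly 0.  Non-convergence is flagged
    on the returned fit, not raised.
    """
    ws = _RemlWorkspace(spec)
    n_par = len(ws.terms) + ws.n_groups
    lo = np.log(ws.floor)
    hi = np.log(1e4 * ws.var_y)
    best = None
    total_iter = 0
    converged = False
    for x0 in _starts(ws):
        res = optimize.minimize(
            ws.neg_restricted_ll,
            np.log(np.clip(x0, ws.floor, None)),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * n_par,
            options={"maxiter": MAX_ITER, "ftol": 1e-14, "gtol": 1e-10},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    variances = np.exp(best.x)
    ll, beta, solve = ws.restricted_ll(variances)

    # BLUPs: a_hat = sigma_t^2 Z_t' V^{-1} (y - X beta); PEV via P
    e = spec.y - spec.X @ beta
    Vie = solve(e)
    blups: dict[str, np.ndarray] = {}
    blup_se: dict[str, np.ndarray] = {}
    if ws.terms:
        ViX = solve(spec.X)
        XtViX_inv = np.linalg.inv(spec.X.T @ ViX)
        for t_i, term in enumerate(ws.terms):
            s2 = variances[t_i]
            Z = np.asarray(term.Z, dtype=float)
            blups[term.label] = s2 * (Z.T @ Vie)
            ViZ = solve(Z)
            # P Z = V^{-1}Z - V^{-1}X (X'V^{-1}X)^{-1} X'V^{-1}Z
            PZ = ViZ - ViX @ (XtViX_inv @ (ViX.T @ Z))
            pev = s2 - s2**2 * np.einsum("ij,ij->j", Z, PZ)
            blup_se[term.label] = np.sqrt(np.clip(pev, 0.0, None))

    at_floor = variances <= ws.floor * (1.0 + 1e-6)
    reported = np.where(at_floor, 0.0, variances)
    term_vars = {
        t.label: float(reported[i]) for i, t in enumerate(ws.terms)
    }
    res_vars = {
        spec.group_labels[g]: float(reported[len(ws.terms) + g])
        for g in range(ws.n_groups)
    }
    return VarCompFit(
        variances=term_vars,
        residual_variances=res_vars,
        loglik=float(ll),
        beta=beta,
        blups=blups,
        blup_se=blup_se,
        converged=converged,
        n_iter=total_iter,
    )


def restricted_loglik(spec: ModelSpec, variances: np.ndarray) -> float:
    """Direct evaluation of the REML criterion at given variances
    (term variances first, then per-family residual variances)."""
    ws = _RemlWorkspace(spec)
    return ws.restricted_ll(np.asarray(variances, dtype=float))[0]


def lrt_mixture_pvalue(ll_full: float, ll_null: float) -> tuple[float, float, float]:
    """Boundary-mixture likelihood-ratio test for a single variance
    component.

    Returns ``(lrt, p, -log10 p)`` where ``lrt = max(0, 2 (ll_full -
    ll_null))`` and the null distribution is the 0.5 chi2_0 + 0.5 chi2_1
    mixture appropriate for testing sigma^2 = 0 on the parameter
    boundary: ``p = 0.5 * P(chi2_1 > lrt)`` for lrt > 0 and p = 0.5 at
    lrt = 0.
    """
    if not (np.isfinite(ll_full) and np.isfinite(ll_null)):
        raise InputError("log-likelihoods must be finite")
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = 0.5 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return lrt, p, float(-np.log10(p))
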