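"""Single-marker linear mixed models and nested likelihood-ratio tests.

The observation model is

    y = 1*mu + X b + I_a b1 + I_d b2 + I_i b3 + Z u + Q c + e

with fixed covariates ``b`` (e.g. sex, cage density), optional marker
regressions on the additive / dominance / imprinting codes, a polygenic
random effect ``u ~ N(0, A sigma2_u)`` with ``A`` the pedigree relationship
matrix, an i.i.d. cage effect ``c ~ N(0, I sigma2_c)`` and residual ``e``.
Variance components are estimated by REML, profiled over the variance
ratios ``gamma = sigma2 / sigma2_e``; a single random structure is handled
through one eigendecomposition (reused across the thousands of per-marker
fits of a genome scan), the two-structure case through dense Cholesky
factorizations inside a Nelder-Mead search.

Likelihood-ratio tests between models differing in *fixed* marker terms
use maximum-likelihood log-likelihoods by default, because REML criteria
are not comparable across fixed-effect structures; ``paper_mode=True``
differences the REML criteria instead, mimicking common REML-package
practice.  Both log-likelihoods are therefore carried on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2

from .data import Dataset
from .kinship import build_A

__all__ = [
    "ADDITIVE",
    "DOMINANCE",
    "IMPRINTING",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "fit",
    "lrt",
]

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
DOMINANCE = "dominance"
IMPRINTING = "imprinting"
_TERM_ORDER = (ADDITIVE, DOMINANCE, IMPRINTING)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which marker terms, covariates and random structures a model has."""

    marker_terms: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    include_polygenic: bool = False
    include_cage: bool = False

    def __post_init__(self) -> None:
        bad = set(self.marker_terms) - set(_TERM_ORDER)
        if bad:
            raise ValueError(f"unknown marker terms {sorted(bad)}")

    @classmethod
    def for_data(cls, data: Dataset, marker_terms=()) -> "ModelSpec":
        """Spec using the dataset's covariates and available random terms."""
        return cls(
            marker_terms=tuple(t for t in _TERM_ORDER if t in marker_terms),
            covariates=tuple(data.covariates),
            include_polygenic=data.pedigree is not None,
            include_cage=data.has_cage,
        )

    def with_terms(self, *terms: str) -> "ModelSpec":
        return ModelSpec(
            marker_terms=tuple(t for t in _TERM_ORDER if t in terms),
            covariates=self.covariates,
            include_polygenic=self.include_polygenic,
            include_cage=self.include_cage,
        )


@dataclass
class FitResult:
    spec: ModelSpec
    marker: object
    beta: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    varcomps: dict = field(default_factory=dict)
    varcomp_sd: dict = field(default_factory=dict)
    loglik_ml: float = np.nan
    loglik_reml: float = np.nan
    n: int = 0
    p: int = 0
    n_dropped: int = 0
    converged: bool = False
    n_iter: int = 0
    inestimable: tuple[str, ...] = ()
    message: str = ""

    def to_record(self) -> dict:
        """Flat JSON-serialisable diagnostic record for one fit."""
        return {
            "marker": None if self.marker is None else str(self.marker),
            "terms": list(self.spec.marker_terms),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "varcomps": {k: float(v) for k, v in self.varcomps.items()},
            "loglik_ml": float(self.loglik_ml),
            "loglik_reml": float(self.loglik_reml),
            "n": self.n,
            "iterations": self.n_iter,
            "converged": bool(self.converged),
            "inestimable": list(self.inestimable),
        }


class LRTResult(NamedTuple):
    statistic: float
    pvalue: float
    df: int


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

def _design(data: Dataset, marker, spec: ModelSpec):
    phen = data.phenotypes
    y = phen["trait"].to_numpy(dtype=float)
    cols = [np.ones(len(y))]
    names = ["mu"]
    for cov in spec.covariates:
        if cov not in phen.columns:
            raise KeyError(f"covariate {cov!r} not in phenotype table")
        cols.append(phen[cov].to_numpy(dtype=float))
        names.append(cov)
    base = np.column_stack(cols)

    mask = np.isfinite(y) & np.isfinite(base).all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d individuals with missing phenotype/covariates",
                    n_dropped)
    y = y[mask]
    W = base[mask]

    inestimable: list[str] = []
    if spec.marker_terms:
        if marker is None:
            raise ValueError("model spec requests marker terms but no marker given")
        j = _marker_index(data, marker)
        ia, idom, iimp = data.design_codes(j)
        term_cols = {ADDITIVE: ia, DOMINANCE: idom, IMPRINTING: iimp}
        for term in _TERM_ORDER:
            if term not in spec.marker_terms:
                continue
            col = term_cols[term][mask]
            # estimability: must add a direction not spanned by current W
            resid = col - W @ np.linalg.lstsq(W, col, rcond=None)[0]
            if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(col), 1.0):
                inestimable.append(term)
                continue
            W = np.column_stack([W, col])
            names.append(term)
    return y, W, names, tuple(inestimable), n_dropped, mask


def _marker_index(data: Dataset, marker) -> int:
    if isinstance(marker, (int, np.integer)):
        return int(marker)
    hits = np.flatnonzero(data.markers["marker"].to_numpy() == str(marker))
    if hits.size != 1:
        raise KeyError(f"marker {marker!r} not found (or duplicated)")
    return int(hits[0])


def _random_structures(data: Dataset, spec: ModelSpec, mask: np.ndarray):
    """Covariance kernels (and cached eigendecompositions) for the
    requested random terms, restricted to the unmasked individuals.

    Kernels and their eigendecompositions are cached on the dataset keyed
    by the missingness mask, so a genome scan pays for ``build_A`` and
    ``eigh`` once and reuses them across all per-marker fits.
    """
    mkey = mask.tobytes()
    kernels, eigh_fns, names = [], [], []

    def cached_eigh(cache_key, K):
        def get():
            hit = data._cache.get(cache_key)
            if hit is None:
                vals, U = np.linalg.eigh(K)
                hit = (np.clip(vals, 0.0, None), U)
                data._cache[cache_key] = hit
            return hit

        return get

    if spec.include_polygenic:
        if data.pedigree is None:
            raise ValueError("include_polygenic requires a pedigree")
        K = data._cache.get("K")
        if K is None:
            A, ids = build_A(data.pedigree[["id", "sire", "dam"]])
            pos = {v: k for k, v in enumerate(ids)}
            rows = np.array([pos[i] for i in data.ids])
            K = A[np.ix_(rows, rows)]
            data._cache["K"] = K
        key = ("K", mkey)
        Km = data._cache.get(key)
        if Km is None:
            idx = mask.nonzero()[0]
            Km = K[np.ix_(idx, idx)]
            data._cache[key] = Km
        kernels.append(Km)
        eigh_fns.append(cached_eigh(("eigh_K", mkey), Km))
        names.append("sigma2_u")
    Q = None
    if spec.include_cage:
        if not data.has_cage:
            raise ValueError("include_cage requires a 'cage' phenotype column")
        key = ("C", mkey)
        hit = data._cache.get(key)
        if hit is None:
            labels = data.phenotypes["cage"].to_numpy()[mask]
            _, codes = np.unique(labels, return_inverse=True)
            Q = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)
            hit = (Q @ Q.T, Q)
            data._cache[key] = hit
        Cm, Q = hit
        kernels.append(Cm)
        eigh_fns.append(cached_eigh(("eigh_C", mkey), Cm))
        names.append("sigma2_c")
    return kernels, eigh_fns, names, Q


# ----------------------------------------------------------------------
# likelihood machinery
# ----------------------------------------------------------------------

def _gls_pieces(y, W, solve):
    """Return (beta, quad, logdet_WtViW, WtViW_inv) for V-solves ``solve``."""
    Viy = solve(y)
    ViW = solve(W)
    WtViW = W.T @ ViW
    WtViy = W.T @ Viy
    cf = linalg.cho_factor(WtViW)
    beta = linalg.cho_solve(cf, WtViy)
    quad = float(y @ Viy - beta @ WtViy)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, quad, logdet, WtViW


def _profiled_ll(quad, logdet_V, logdet_WtViW, n, p, criterion):
    """Profile log-likelihood with sigma2_e concentrated out of H-scale
    solves (V = sigma2_e H; ``quad`` and the log-dets are on the H scale)."""
    if criterion == "ml":
        s2 = quad / n
        return -0.5 * (n * (_LOG2PI + np.log(s2) + 1.0) + logdet_V), s2
    s2 = quad / (n - p)
    return (
        -0.5 * ((n - p) * (_LOG2PI + np.log(s2) + 1.0) + logdet_V + logdet_WtViW),
        s2,
    )


def _fit_no_random(y, W):
    n, p = W.shape
    beta, rss, rank, _ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ beta
    quad = float(resid @ resid)
    _, logdet_WtW = np.linalg.slogdet(W.T @ W)
    ll_ml, _ = _profiled_ll(quad, 0.0, logdet_WtW, n, p, "ml")
    ll_reml, s2r = _profiled_ll(quad, 0.0, logdet_WtW, n, p, "reml")
    cov = s2r * np.linalg.inv(W.T @ W)
    se = np.sqrt(np.diag(cov))
    sd_e = s2r * np.sqrt(2.0 / (n - p))
    return beta, se, {"sigma2_e": s2r}, {"sigma2_e": sd_e}, ll_ml, ll_reml, 0


def _eigen_profile(y, W, vals, criterion):
    """1D profile over the variance ratio for one eigendecomposed kernel.

    ``y`` and ``W`` must already be rotated into the kernel eigenbasis.
    Returns (gamma_hat, loglik, n_iter).
    """
    n, p = W.shape

    def negll(t):
        g = np.exp(t)
        h = 1.0 + g * vals
        sw = 1.0 / np.sqrt(h)
        Ws = W * sw[:, None]
        ys = y * sw
        beta, _, _, _ = np.linalg.lstsq(Ws, ys, rcond=None)
        r = ys - Ws @ beta
        quad = float(r @ r)
        _, logdet_WtViW = np.linalg.slogdet(Ws.T @ Ws)
        ll, _ = _profiled_ll(quad, float(np.log(h).sum()), logdet_WtViW,
                             n, p, criterion)
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(-15.0, 15.0), method="bounded",
        options={"xatol": 1e-9},
    )
    # boundary gamma = 0 (component absent) is always a candidate
    beta0, _, _, _ = np.linalg.lstsq(W, y, rcond=None)
    r0 = y - W @ beta0
    _, ld0 = np.linalg.slogdet(W.T @ W)
    llb, _ = _profiled_ll(float(r0 @ r0), 0.0, ld0, n, p, criterion)
    ll_opt = -res.fun
    if llb >= ll_opt:
        return 0.0, llb, int(res.nfev)
    return float(np.exp(res.x)), ll_opt, int(res.nfev)


def _dense_solve_factory(H):
    cf = linalg.cho_factor(H, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

    def solve(b):
        return linalg.cho_solve(cf, b)

    return solve, logdet


def _dense_ll(gammas, y, W, kernels, criterion):
    n, p = W.shape
    H = np.eye(n)
    for g, K in zip(gammas, kernels):
        if g > 0:
            H += g * K
    solve, logdet_V = _dense_solve_factory(H)
    beta, quad, logdet_WtViW, WtViW = _gls_pieces(y, W, solve)
    ll, s2 = _profiled_ll(quad, logdet_V, logdet_WtViW, n, p, criterion)
    return ll, beta, s2, WtViW


def _woodbury_ll(gu, gc, yt, Wt, vals, Qt, criterion):
    """Profiled log-likelihood for H = I + gu*K + gc*QQ' evaluated in the
    eigenbasis of K via the Woodbury identity; the grouping factor Q is
    low-rank so each evaluation costs O(n q) instead of a dense Cholesky.
    """
    n, p = Wt.shape
    q = Qt.shape[1]
    dinv = 1.0 / (1.0 + gu * vals)
    QD = Qt * dinv[:, None]
    F = np.eye(q) + gc * (Qt.T @ QD)
    cfF = linalg.cho_factor(F, lower=True)
    logdet_H = float(-np.log(dinv).sum() + 2.0 * np.sum(np.log(np.diag(cfF[0]))))

    def solve(x):
        dx = dinv[:, None] * x if x.ndim == 2 else dinv * x
        return dx - gc * (QD @ linalg.cho_solve(cfF, Qt.T @ dx))

    beta, quad, logdet_WtViW, WtViW = _gls_pieces(yt, Wt, solve)
    ll, s2 = _profiled_ll(quad, logdet_H, logdet_WtViW, n, p, criterion)
    return ll, beta, s2, WtViW


def _optimize_gammas(y, W, kernels, eigh_fns, criterion, Q=None, start=None):
    """Maximize the profiled likelihood over variance ratios >= 0.

    One kernel: bounded scalar search over the log-ratio after rotating
    into the kernel eigenbasis.  Two kernels: Nelder-Mead in log-ratio
    space (Woodbury fast objective when the second kernel has a grouping
    factor ``Q``), warm-startable, always compared against the boundary
    solutions where one or both components vanish.
    """
    k = len(kernels)
    if k == 1:
        vals, U = eigh_fns[0]()
        g, ll, it = _eigen_profile(U.T @ y, U.T @ W, vals, criterion)
        return np.array([g]), ll, it, True

    best = (None, -np.inf)
    n_iter = 0
    converged = True
    # boundary: each single-kernel profile (the other ratio pinned at 0);
    # the gamma = 0 / OLS corner is checked inside _eigen_profile itself
    for keep in range(k):
        vals, U = eigh_fns[keep]()
        g, ll, it = _eigen_profile(U.T @ y, U.T @ W, vals, criterion)
        n_iter += it
        gam = np.zeros(k)
        gam[keep] = g
        if ll > best[1]:
            best = (gam, ll)

    if Q is not None:
        vals, U = eigh_fns[0]()
        yt, Wt, Qt = U.T @ y, U.T @ W, U.T @ Q

        def negll(t):
            return -_woodbury_ll(np.exp(t[0]), np.exp(t[1]), yt, Wt, vals, Qt,
                                 criterion)[0]
    else:
        def negll(t):
            return -_dense_ll(np.exp(t), y, W, kernels, criterion)[0]

    if start is not None:
        starts = (np.log(np.clip(start, 1e-4, None)),)
    else:
        starts = (np.log([0.5] * k), np.log([0.1] * k))
    for s0 in starts:
        res = optimize.minimize(
            negll, s0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        n_iter += int(res.nfev)
        if -res.fun > best[1]:
            best = (np.exp(res.x), -res.fun)
            converged = bool(res.success)
    return best[0], best[1], n_iter, converged


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

def fit(data: Dataset, marker=None, spec: ModelSpec | None = None,
        start_gammas=None, compute_varcomp_sd: bool = True) -> FitResult:
    """Fit one (mixed) model by REML; carry the ML log-likelihood too.

    Marker design columns that are constant or collinear with the columns
    already in the model (e.g. no heterozygotes makes the dominance code
    constant; a single heterozygote class makes the imprinting code
    collinear with it) are flagged in ``FitResult.inestimable`` and the
    remaining terms are still fitted.

    ``start_gammas`` warm-starts the variance-ratio search (a genome scan
    passes the null model's ratios); ``compute_varcomp_sd=False`` skips the
    finite-difference information matrix for the component SDs, which a
    scan only needs on the null fit.
    """
    if spec is None:
        spec = ModelSpec.for_data(data)
    y, W, names, inestimable, n_dropped, mask = _design(data, marker, spec)
    n, p = W.shape
    if n <= p:
        raise ValueError(f"only {n} observations for {p} fixed effects")
    kernels, eigh_fns, vc_names, Q = _random_structures(data, spec, mask)

    result = FitResult(spec=spec, marker=marker, n=n, p=p,
                       n_dropped=n_dropped, inestimable=inestimable)

    if not kernels:
        beta, se, vc, vc_sd, ll_ml, ll_reml, it = _fit_no_random(y, W)
        result.beta = dict(zip(names, beta))
        result.se = dict(zip(names, se))
        result.varcomps = vc
        result.varcomp_sd = vc_sd
        result.loglik_ml = ll_ml
        result.loglik_reml = ll_reml
        result.converged = True
        result.n_iter = it
        return result

    gam_reml, ll_reml, it_r, conv_r = _optimize_gammas(
        y, W, kernels, eigh_fns, "reml", Q=Q, start=start_gammas)
    # warm-start the ML search from the REML optimum
    ml_start = np.clip(gam_reml, 1e-4, None) if len(kernels) > 1 else None
    _, ll_ml, it_m, conv_m = _optimize_gammas(
        y, W, kernels, eigh_fns, "ml", Q=Q, start=ml_start)

    _, beta, s2e, WtViW = _dense_ll(gam_reml, y, W, kernels, "reml")
    cov = s2e * np.linalg.inv(WtViW)
    result.beta = dict(zip(names, beta))
    result.se = dict(zip(names, np.sqrt(np.diag(cov))))
    result.varcomps = {"sigma2_e": s2e}
    for name, g in zip(vc_names, gam_reml):
        result.varcomps[name] = float(g * s2e)
    result.loglik_ml = ll_ml
    result.loglik_reml = ll_reml
    result.converged = conv_r and conv_m
    result.n_iter = it_r + it_m
    if compute_varcomp_sd:
        result.varcomp_sd = _varcomp_sds(y, W, kernels, vc_names, result.varcomps)
    return result


def _varcomp_sds(y, W, kernels, vc_names, varcomps) -> dict:
    """Asymptotic SDs from the observed information of the REML
    log-likelihood in variance-component coordinates (finite differences);
    components at the zero boundary get NaN."""
    order = list(vc_names) + ["sigma2_e"]
    v0 = np.array([varcomps[k] for k in order])
    n, p = W.shape

    def reml_ll(v):
        if np.any(v[-1:] <= 0):
            return -np.inf
        V = v[-1] * np.eye(n)
        for vk, K in zip(v[:-1], kernels):
            V += vk * K
        try:
            solve, logdet_V = _dense_solve_factory(V)
        except np.linalg.LinAlgError:
            return -np.inf
        _, quad, logdet_WtViW, _ = _gls_pieces(y, W, solve)
        return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_WtViW + quad)

    free = [k for k, v in enumerate(v0) if v > 1e-10]
    sds = {name: np.nan for name in order}
    if not free:
        return sds
    steps = np.array([1e-3 * max(v0[k], 1e-4) for k in free])
    m = len(free)
    Hess = np.zeros((m, m))
    f0 = reml_ll(v0)
    for a in range(m):
        for b in range(a, m):
            va, vb = free[a], free[b]
            ha, hb = steps[a], steps[b]
            if a == b:
                vp, vm = v0.copy(), v0.copy()
                vp[va] += ha
                vm[va] = max(vm[va] - ha, 1e-12)
                Hess[a, a] = (reml_ll(vp) - 2 * f0 + reml_ll(vm)) / (ha * ha)
            else:
                vals = []
                for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    v = v0.copy()
                    v[va] = max(v[va] + sa * ha, 1e-12)
                    v[vb] = max(v[vb] + sb * hb, 1e-12)
                    vals.append(reml_ll(v))
                Hess[a, b] = Hess[b, a] = (
                    (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * ha * hb)
                )
    try:
        cov = np.linalg.inv(-Hess)
        diag = np.diag(cov)
        for k, name_idx in enumerate(free):
            if diag[k] > 0:
                sds[order[name_idx]] = float(np.sqrt(diag[k]))
    except np.linalg.LinAlgError:
        pass
    return sds


def lrt(full: FitResult, reduced: FitResult, paper_mode: bool = False) -> LRTResult:
    """Likelihood-ratio test of the marker terms added by the full model.

    The statistic is ``2 * (ll_full - ll_reduced)`` clipped at zero and
    referred to a chi-square with df equal to the difference in the number
    of estimable marker terms.  ML log-likelihoods are used unless
    ``paper_mode`` asks for REML differencing.
    """
    f, r = full.spec, reduced.spec
    if (f.covariates != r.covariates
            or f.include_polygenic != r.include_polygenic
            or f.include_cage != r.include_cage):
        raise ValueError("models differ in covariates or random structure; not nested")
    full_terms = set(f.marker_terms) - set(full.inestimable)
    red_terms = set(r.marker_terms) - set(reduced.inestimable)
    if not red_terms <= full_terms:
        raise ValueError(
            f"reduced model terms {sorted(red_terms)} not nested in "
            f"{sorted(full_terms)}"
        )
    df = len(full_terms) - len(red_terms)
    ll_f = full.loglik_reml if paper_mode else full.loglik_ml
    ll_r = reduced.loglik_reml if paper_mode else reduced.loglik_ml
    stat = max(0.0, 2.0 * (ll_f - ll_r))
    if df == 0:
        return LRTResult(stat, 1.0, 0)
    return LRTResult(stat, float(chi2.sf(stat, df)), df)
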