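"""Poisson GLMM with crossed random effects by Laplace approximation.

The abundance model for count N_it at site i in year t (region j) is

    log E[N_it] = alpha + sum_c (b1_c x_ci + b2_c x_ci^2) + year_t
                  + [log P_iv]  (detectability offset, birds)
                  + Observation_it + Site_i + Region_j,

with independent normal random effects Observation_it ~ N(0, s2_obs)
(an observation-level random effect absorbing extra-Poisson dispersion),
Site_i ~ N(0, s2_site) and Region_j ~ N(0, s2_region) for 50-km grid
blocks.  Environmental covariates enter as second-order raw polynomials
on their [0, 1] scale.

Estimation maximises the Laplace-approximated marginal likelihood

    l(beta, theta) = l_Pois(eta_hat) - u_hat' D^-1 u_hat / 2
                     - log|D|/2 - log|Z' W Z + D^-1|/2

over fixed effects and log standard deviations jointly, with the
conditional modes u_hat from Newton iterations on the penalised Poisson
log-likelihood and analytic outer gradients that include the determinant
term's dependence on the modes.  Starting values are fixed, so fits are
deterministic.  The observation-level term's diagonal Hessian block, and
the nesting of sites within regions, reduce every solve and
log-determinant to closed forms of size (number of sites + regions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import gammaln

from .synthdata import AGRICULTURE_CLASSES, LAND_COVER_CLASSES

__all__ = [
    "ModelSpec",
    "DesignData",
    "GLMMFit",
    "build_design",
    "aggregate_bird_surveys",
    "fit_poisson_glmm",
    "fit_model",
    "predict_eta",
]

_COVARIATE_SETS = {
    "full": LAND_COVER_CLASSES + ["altitude"],
    "agriculture": AGRICULTURE_CLASSES + ["altitude"],
    "linear_only": [],
    "year_only": [],
}

#: Bounds on log sigma for each variance component.  The lower bound is
#: numerically indistinguishable from a zero variance component (it
#: perturbs fixed effects by far less than their reporting precision).
_LOG_SIGMA_BOUNDS = (-9.0, 3.0)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which covariates, how linear features enter.

    covariate_set: 'full' (all land-cover classes + altitude),
    'agriculture' (arable, improved and rough grassland + altitude),
    'linear_only' (linear features + year only) or 'year_only'.
    lf_term: 'none', 'additive' (length + length^2) or 'interaction'
    (additive plus length x arable and length x improved grassland).
    lf_variable: 'total' or 'woody' linear-feature length.
    """

    covariate_set: str
    lf_term: str = "none"
    lf_variable: str = "total"
    include_offset: bool = False

    def __post_init__(self) -> None:
        if self.covariate_set not in _COVARIATE_SETS:
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        if self.lf_term not in ("none", "additive", "interaction"):
            raise ValueError(f"unknown lf_term {self.lf_term!r}")
        if self.lf_variable not in ("total", "woody"):
            raise ValueError(f"unknown lf_variable {self.lf_variable!r}")
        if self.lf_term == "interaction" and self.covariate_set not in ("full", "agriculture"):
            raise ValueError("interaction terms require the full or agriculture set")
        if self.covariate_set == "linear_only" and self.lf_term != "additive":
            raise ValueError("linear_only requires lf_term='additive'")
        if self.covariate_set == "year_only" and self.lf_term != "none":
            raise ValueError("year_only admits no linear-features term")

    @property
    def label(self) -> str:
        parts = [self.covariate_set]
        if self.lf_term != "none":
            parts.append(f"lf_{self.lf_term}")
        if self.lf_variable != "total":
            parts.append(self.lf_variable)
        return "+".join(parts)

    def with_lf_variable(self, lf_variable: str) -> "ModelSpec":
        return ModelSpec(self.covariate_set, self.lf_term, lf_variable, self.include_offset)


@dataclass
class DesignData:
    """Model matrices and grouping structure for one candidate model."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    offset: np.ndarray
    groups: dict[str, np.ndarray]          # term -> integer codes per row
    group_levels: dict[str, np.ndarray]    # term -> level labels
    frame: pd.DataFrame                    # row metadata (site_id, year, ...)
    spec: ModelSpec | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "DesignData":
        """Row subset with group codes recomputed over retained levels."""
        groups, levels = {}, {}
        for term, codes in self.groups.items():
            labels = self.group_levels[term][codes[mask]]
            new_levels, new_codes = np.unique(labels, return_inverse=True)
            groups[term] = new_codes
            levels[term] = new_levels
        return DesignData(
            y=self.y[mask],
            X=self.X[mask],
            columns=self.columns,
            offset=self.offset[mask],
            groups=groups,
            group_levels=levels,
            frame=self.frame.loc[mask].reset_index(drop=True),
            spec=self.spec,
        )


def aggregate_bird_surveys(surveys: pd.DataFrame, detection_model=None) -> pd.DataFrame:
    """Collapse per-visit band counts to one response per site x year.

    The response is the maximum 0-100 m count over the two visits; the
    detection probability attached to a site-year is that of the visit
    supplying the maximum (the earlier visit on ties).  Without a
    detection model P is set to 1 (no offset).
    """
    from .detection import detection_probability

    df = surveys.copy()
    df["count"] = df["count_band1"] + df["count_band2"]
    df = df.sort_values(["species_id", "site_id", "year", "visit"], kind="mergesort")
    # idxmax on a mergesort-stable frame takes the earlier visit on ties
    idx = df.groupby(["species_id", "site_id", "year"], sort=False)["count"].idxmax()
    agg = df.loc[idx].reset_index(drop=True)
    if detection_model is not None:
        agg["p_detect"] = detection_probability(
            detection_model, agg["visit"].to_numpy(), agg["habitat"].to_numpy()
        )
    else:
        agg["p_detect"] = 1.0
    return agg[["species_id", "site_id", "year", "visit", "habitat", "count", "p_detect"]]


def build_design(sites: pd.DataFrame, surveys: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Assemble response, fixed-effect matrix and grouping indices.

    ``surveys`` must carry one row per site x year with a ``count``
    column (use :func:`aggregate_bird_surveys` for raw bird visits) and,
    when ``spec.include_offset``, a ``p_detect`` column.
    """
    if "count" not in surveys:
        raise ValueError("surveys must have a 'count' column (aggregate bird visits first)")
    counts = surveys["count"].to_numpy()
    if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
        raise ValueError("counts must be non-negative integers")

    df = surveys.merge(sites, on="site_id", how="left", validate="many_to_one")
    if df["region_id"].isna().any():
        missing = surveys.loc[df["region_id"].isna(), "site_id"].unique()
        raise ValueError(f"sites missing covariates: {list(missing)[:5]}")

    env = list(_COVARIATE_SETS[spec.covariate_set])
    lf_col = "lf_total" if spec.lf_variable == "total" else "lf_woody"

    cols: list[str] = ["intercept"]
    mats: list[np.ndarray] = [np.ones(len(df))]

    def add(name: str, values: np.ndarray) -> None:
        cols.append(name)
        mats.append(values)

    for c in env:
        if c not in df:
            raise ValueError(f"missing covariate column {c!r}")
        x = df[c].to_numpy(dtype=float)
        add(c, x)
        add(f"{c}^2", x * x)
    if spec.lf_term in ("additive", "interaction") or spec.covariate_set == "linear_only":
        if lf_col not in df:
            raise ValueError(f"missing covariate column {lf_col!r}")
        lf = df[lf_col].to_numpy(dtype=float)
        add(lf_col, lf)
        add(f"{lf_col}^2", lf * lf)
        if spec.lf_term == "interaction":
            add(f"{lf_col}:arable", lf * df["arable"].to_numpy(dtype=float))
            add(
                f"{lf_col}:improved_grassland",
                lf * df["improved_grassland"].to_numpy(dtype=float),
            )

    years = np.sort(df["year"].unique())
    for yr in years[1:]:
        add(f"year_{yr}", (df["year"] == yr).to_numpy(dtype=float))

    X = np.column_stack(mats)

    if spec.include_offset:
        if "p_detect" not in df:
            raise ValueError("include_offset requires a 'p_detect' column")
        offset = np.log(df["p_detect"].to_numpy(dtype=float))
    else:
        offset = np.zeros(len(df))

    obs_labels = (df["site_id"].astype(str) + ":" + df["year"].astype(str)).to_numpy()
    groups, levels = {}, {}
    for term, labels in (
        ("obs", obs_labels),
        ("site", df["site_id"].to_numpy()),
        ("region", df["region_id"].to_numpy()),
    ):
        lv, codes = np.unique(labels, return_inverse=True)
        groups[term] = codes
        levels[term] = lv

    frame_cols = ["species_id", "site_id", "year"] if "species_id" in df else ["site_id", "year"]
    return DesignData(
        y=counts.astype(float),
        X=X,
        columns=cols,
        offset=offset,
        groups=groups,
        group_levels=levels,
        frame=df[frame_cols].copy(),
        spec=spec,
    )


@dataclass
class GLMMFit:
    """Result of a Laplace-approximated Poisson GLMM fit."""

    fixed: pd.Series
    fixed_se: pd.Series
    varcomp: dict[str, float]              # term -> variance (sigma^2)
    loglik: float
    aic: float
    eta_fixed: np.ndarray                  # X beta + offset, training rows
    re_modes: dict[str, pd.Series]         # term -> modes indexed by level
    offset: np.ndarray
    converged: bool
    boundary: bool
    n_obs: int
    spec: ModelSpec | None = None
    n_iter: int = 0
    log_sigma_se: dict[str, float] = field(default_factory=dict)

    @property
    def k_parameters(self) -> int:
        return len(self.fixed) + len(self.varcomp)

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed.to_dict(),
            "fixed_se": self.fixed_se.to_dict(),
            "varcomp": self.varcomp,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "spec": None if self.spec is None else self.spec.label,
        }


def _build_Z(groups: Mapping[str, np.ndarray], group_levels: Mapping[str, np.ndarray], n: int):
    """Sparse random-effect design and per-term column slices."""
    blocks = []
    slices: dict[str, slice] = {}
    start = 0
    for term, codes in groups.items():
        q = len(group_levels[term])
        blocks.append(
            sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
        )
        slices[term] = slice(start, start + q)
        start += q
    Z = sparse.hstack(blocks, format="csr") if blocks else sparse.csr_matrix((n, 0))
    return Z, slices, start


def _logdet_sparse_spd(M: sparse.spmatrix) -> float:
    lu = splu(M.tocsc())
    d = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(d))))


def fit_poisson_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: Mapping[str, np.ndarray],
    offset: np.ndarray | None = None,
    *,
    group_levels: Mapping[str, np.ndarray] | None = None,
    columns: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
    max_inner: int = 80,
    max_outer: int = 300,
    compute_varcomp_se: bool = False,
    ftol: float = 1e-10,
    gtol: float = 1e-6,
    dense_limit: int = 1200,
) -> GLMMFit:
    """Maximise the Laplace marginal likelihood of the Poisson GLMM.

    ``groups`` maps each random-effect term to integer codes per row
    (e.g. ``obs`` = row identity, ``site``, ``region``).  The marginal
    likelihood is the Laplace approximation

        l(beta, theta) = l_Pois(eta_hat) - u_hat' D^-1 u_hat / 2
                         - log|D| / 2 - log|Z'WZ + D^-1| / 2,

    with conditional modes u_hat from Newton iterations on the penalised
    Poisson log-likelihood.  Fixed effects (internally orthonormalised,
    the raw polynomial columns being strongly collinear) and log standard
    deviations are optimised jointly by L-BFGS-B with analytic gradients
    that include the determinant term's dependence on the modes, from
    fixed starting values (Poisson-GLM coefficients, variances at 0.1) —
    fits are deterministic.  When an observation-level term is present
    its diagonal Hessian block is eliminated by a Schur complement over
    the remaining group levels, so cost scales with the number of sites
    and regions rather than observations; models without one use dense
    linear algebra up to ``dense_limit`` coefficients-plus-levels and
    sparse factorisations with finite-difference outer gradients beyond.
    A variance component on the lower bound is reported as a boundary
    fit, numerically a zero variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + len(groups):
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")
    if y.sum() == 0:
        raise ValueError("all counts are zero; abundance model is degenerate")
    if offset is None:
        offset = np.zeros(n)
    if group_levels is None:
        group_levels = {t: np.arange(int(c.max()) + 1) for t, c in groups.items()}
    if columns is None:
        columns = [f"x{j}" for j in range(p)]

    Z, slices, q = _build_Z(groups, group_levels, n)
    Zt = Z.T.tocsr()
    terms = list(groups)
    q_sizes = np.array([len(group_levels[t]) for t in terms], dtype=float)
    const = float(np.sum(gammaln(y + 1)))

    # orthonormalise the fixed-effect basis; map coefficients back on exit
    X_orig = X
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise ValueError("fixed-effect design matrix is rank deficient")
    scale = math.sqrt(n)
    X = Q * scale
    R_scaled = R / scale  # beta_orig = R_scaled^-1 beta_work

    import statsmodels.api as sm

    glm_beta = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit().params

    def dinv_vec(log_sigma: np.ndarray) -> np.ndarray:
        out = np.empty(q)
        for k, t in enumerate(terms):
            out[slices[t]] = math.exp(-2.0 * log_sigma[k])
        return out

    olre_term = None
    for t in terms:
        if len(group_levels[t]) == n:
            olre_term = t
            break

    x0 = np.concatenate([glm_beta, np.full(len(terms), 0.5 * math.log(0.1))])
    bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS] * len(terms)
    opts = {"ftol": ftol, "gtol": gtol, "maxiter": max_outer}

    if olre_term is not None:
        kernel = _OlreKernel(y, X, offset, terms, groups, group_levels, olre_term, max_inner)
        res = optimize.minimize(
            kernel.neg_full_with_grad, x0, jac=True, method="L-BFGS-B",
            bounds=bounds, options=opts,
        )
        beta_w, log_sigma = res.x[:p], res.x[p:]
        loglik = -float(kernel.neg_full_value(res.x))
        u = kernel.u_global(slices, q)
        cov_work = kernel.wald_cov()
        neg_value = kernel.neg_full_value
    else:
        use_dense = (p + q) <= dense_limit
        kernel = _GenericKernel(
            y, X, offset, Z, Zt, terms, slices, q_sizes, dinv_vec, const,
            glm_beta, use_dense, max_inner, max_outer, p, q, n,
        )
        if use_dense:
            res = optimize.minimize(
                kernel.neg_full_with_grad, x0, jac=True, method="L-BFGS-B",
                bounds=bounds, options=opts,
            )
        else:
            res = kernel.two_stage(x0, bounds, opts)
        beta_w, log_sigma = res.x[:p], res.x[p:]
        loglik = -float(kernel.neg_full_value(res.x))
        u = kernel.state_u["u"].copy()
        cov_work = kernel.wald_cov(beta_w, dinv_vec(log_sigma))
        neg_value = kernel.neg_full_value

    jac = getattr(res, "jac", None)
    converged = bool(res.success) or (
        jac is not None and not callable(jac) and float(np.max(np.abs(jac))) < 1e-3
    )

    Rinv = np.linalg.inv(R_scaled)
    beta = Rinv @ beta_w
    cov = Rinv @ cov_work @ Rinv.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    varcomp = {t: float(math.exp(2.0 * log_sigma[k])) for k, t in enumerate(terms)}
    boundary = bool(np.any(log_sigma <= _LOG_SIGMA_BOUNDS[0] + 1e-6))

    log_sigma_se: dict[str, float] = {}
    if compute_varcomp_se and not boundary:
        # Wald SEs for log sigma from the full observed information over
        # (beta, log sigma) jointly — conditioning on beta would ignore
        # the beta/theta correlation and understate the uncertainty.
        m = len(terms)
        dim = p + m
        hstep = 1e-4
        grad_fn = getattr(kernel, "neg_full_with_grad", None)
        try:
            if grad_fn is not None and (olre_term is not None or getattr(kernel, "use_dense", False)):
                Hobs = np.empty((dim, dim))
                for a in range(dim):
                    ea = np.zeros(dim); ea[a] = hstep
                    _, gp = grad_fn(res.x + ea)
                    _, gm = grad_fn(res.x - ea)
                    Hobs[:, a] = (gp - gm) / (2 * hstep)
                Hobs = 0.5 * (Hobs + Hobs.T)
                cov_all = np.linalg.inv(Hobs)
                d = np.diag(cov_all)[p:]
            else:
                # value-only fallback: information in log sigma at fixed beta
                hstep = 1e-3
                f0 = -loglik

                def f_ls(ls: np.ndarray) -> float:
                    return neg_value(np.concatenate([beta_w, ls]))

                Hobs = np.empty((m, m))
                for a in range(m):
                    for b in range(a, m):
                        ea = np.zeros(m); ea[a] = hstep
                        eb = np.zeros(m); eb[b] = hstep
                        if a == b:
                            val = (f_ls(log_sigma + ea) - 2 * f0 + f_ls(log_sigma - ea)) / hstep**2
                        else:
                            val = (
                                f_ls(log_sigma + ea + eb)
                                - f_ls(log_sigma + ea - eb)
                                - f_ls(log_sigma - ea + eb)
                                + f_ls(log_sigma - ea - eb)
                            ) / (4 * hstep**2)
                        Hobs[a, b] = Hobs[b, a] = val
                d = np.diag(np.linalg.inv(Hobs))
            if (np.asarray(d) > 0).all():
                log_sigma_se = {t: float(math.sqrt(d[k])) for k, t in enumerate(terms)}
        except np.linalg.LinAlgError:
            pass

    eta_fixed = X_orig @ beta + offset
    re_modes = {t: pd.Series(u[slices[t]], index=group_levels[t]) for t in terms}
    aic = -2.0 * loglik + 2.0 * (p + len(terms))
    return GLMMFit(
        fixed=pd.Series(beta, index=list(columns)),
        fixed_se=pd.Series(se, index=list(columns)),
        varcomp=varcomp,
        loglik=loglik,
        aic=aic,
        eta_fixed=eta_fixed,
        re_modes=re_modes,
        offset=offset,
        converged=converged,
        boundary=boundary,
        n_obs=n,
        spec=spec,
        n_iter=int(res.nit),
        log_sigma_se=log_sigma_se,
    )


class _DenseC:
    """Dense Cholesky operations on the Schur complement C."""

    def __init__(self, C, cols2):
        self.chol = linalg.cho_factor(C, lower=True)
        self.m = C.shape[0]
        self.cols2 = cols2
        self._Cinv = None

    def logdet(self):
        return 2.0 * float(np.sum(np.log(np.diag(self.chol[0]))))

    def solve(self, r2):
        return linalg.cho_solve(self.chol, r2)

    @property
    def Cinv(self):
        if self._Cinv is None:
            self._Cinv = linalg.cho_solve(self.chol, np.eye(self.m))
        return self._Cinv

    def tau_rows(self, n):
        tau = np.zeros(n)
        for ci in self.cols2:
            for cj in self.cols2:
                tau += self.Cinv[ci, cj]
        return tau

    def diag_sum(self, seg):
        return float(np.sum(np.diag(self.Cinv)[seg]))


class _NestedC:
    """Closed-form operations on C when one grouping nests in the other.

    With sites nested in regions (each site belonging to one region) the
    Schur complement over (site, region) levels is an arrow matrix
    [[diag(Ds), B], [B', diag(Dr)]] whose own Schur complement is again
    diagonal, so solves, log-determinant, traces and the per-row
    quadratic forms tau_i all cost O(S + R).  The single-grouping case
    (C diagonal) is the degenerate version with no outer term.
    """

    def __init__(self, w, dinv2, codes_a, size_a, off_a, codes_b, size_b, off_b, nest_map):
        # a = inner term (e.g. site), b = outer term (e.g. region)
        self.size_a, self.size_b = size_a, size_b
        self.off_a, self.off_b = off_a, off_b
        self.nest_map = nest_map                     # level of a -> level of b
        Bs = np.bincount(codes_a, weights=w, minlength=size_a)
        self.Ds = Bs + dinv2[off_a:off_a + size_a]
        self.Bs = Bs
        if size_b:
            Dr = np.bincount(codes_b, weights=w, minlength=size_b) \
                + dinv2[off_b:off_b + size_b]
            self.Sr = Dr - np.bincount(nest_map, weights=Bs * Bs / self.Ds, minlength=size_b)
        else:
            self.Sr = np.zeros(0)

    def logdet(self):
        out = float(np.sum(np.log(self.Ds)))
        if self.size_b:
            out += float(np.sum(np.log(self.Sr)))
        return out

    def _split(self, r2):
        ra = r2[self.off_a:self.off_a + self.size_a]
        rb = r2[self.off_b:self.off_b + self.size_b] if self.size_b else np.zeros(0)
        return ra, rb

    def solve(self, r2):
        ra, rb = self._split(r2)
        out = np.empty_like(r2)
        if self.size_b:
            xb = (rb - np.bincount(self.nest_map, weights=self.Bs * ra / self.Ds,
                                   minlength=self.size_b)) / self.Sr
            xa = (ra - self.Bs * xb[self.nest_map]) / self.Ds
            out[self.off_b:self.off_b + self.size_b] = xb
        else:
            xa = ra / self.Ds
        out[self.off_a:self.off_a + self.size_a] = xa
        return out

    # selected entries of C^-1
    def diag_a(self):
        d = 1.0 / self.Ds
        if self.size_b:
            d = d + (self.Bs / self.Ds) ** 2 / self.Sr[self.nest_map]
        return d

    def cross_a(self):
        if not self.size_b:
            return np.zeros(self.size_a)
        return -self.Bs / (self.Ds * self.Sr[self.nest_map])

    def tau_rows_from_codes(self, codes_a, codes_b):
        tau = self.diag_a()[codes_a]
        if self.size_b:
            tau = tau + 2.0 * self.cross_a()[codes_a] + (1.0 / self.Sr)[codes_b]
        return tau

    def diag_sum_for(self, which):
        if which == "a":
            return float(np.sum(self.diag_a()))
        return float(np.sum(1.0 / self.Sr))


class _OlreKernel:
    """Laplace objective/gradient exploiting a diagonal observation block.

    With an observation-level random effect, the u-Hessian is
    [[diag(a), B], [B', E]] with a_i = mu_i + 1/s2_obs; eliminating the
    diagonal block leaves an m x m Schur complement C over the site and
    region levels.  When the site grouping nests in the region grouping
    (the usual design) C is an arrow matrix handled in closed form, so
    the whole evaluation is O(n + S + R); otherwise C is factorised
    densely, O(n m + m^3) — still far below O((n + m)^3).
    """

    def __init__(self, y, X, offset, terms, groups, group_levels, olre_term, max_inner):
        self.y, self.X, self.offset = y, X, offset
        self.n, self.p = X.shape
        self.terms = terms
        self.olre = olre_term
        self.olre_codes = groups[olre_term]
        self.others = [t for t in terms if t != olre_term]
        self.max_inner = max_inner
        self.sizes = {t: len(group_levels[t]) for t in terms}
        self.m = sum(self.sizes[t] for t in self.others)
        self.off2 = {}
        start = 0
        for t in self.others:
            self.off2[t] = start
            start += self.sizes[t]
        # per-row index into the stacked other-level vector
        self.cols2 = [groups[t] + self.off2[t] for t in self.others]
        self.qs = np.array([self.sizes[t] for t in terms], dtype=float)
        self.const = float(np.sum(gammaln(y + 1)))
        self.u1 = np.zeros(self.n)          # per-row obs effects
        self.u2 = np.zeros(self.m)
        self._cache = None

        # nesting structure among the non-observation groupings
        self.nest = None
        if len(self.others) == 1:
            t = self.others[0]
            self.nest = (t, None, None)
        elif len(self.others) == 2:
            for ta, tb in ((self.others[0], self.others[1]),
                           (self.others[1], self.others[0])):
                ca, cb = groups[ta], groups[tb]
                mapping = np.zeros(self.sizes[ta], dtype=int)
                mapping[ca] = cb
                if np.array_equal(mapping[ca], cb):
                    self.nest = (ta, tb, mapping)
                    break
        if self.nest is not None:
            ta = self.nest[0]
            self.codes_a = groups[ta]
            self.codes_b = groups[self.nest[1]] if self.nest[1] else None

    # -- linear algebra helpers -------------------------------------------

    def _z2_dot(self, v2):
        """Z2 @ v2 in row space."""
        out = np.zeros(self.n)
        for c in self.cols2:
            out += v2[c]
        return out

    def _z2t_dot(self, r):
        """Z2' @ r for a per-row vector r."""
        out = np.empty(self.m)
        for t, c in zip(self.others, self.cols2):
            seg = np.bincount(c - self.off2[t], weights=r, minlength=self.sizes[t])
            out[self.off2[t]:self.off2[t] + self.sizes[t]] = seg
        return out

    def _assemble(self, mu, d_obs, dinv2):
        a = mu + d_obs
        if not self.m:
            return a, None
        w = mu - mu * mu / a
        if self.nest is not None:
            ta, tb, mapping = self.nest
            cop = _NestedC(
                w, dinv2,
                self.codes_a, self.sizes[ta], self.off2[ta],
                self.codes_b if tb else np.zeros(0, dtype=int),
                self.sizes[tb] if tb else 0,
                self.off2[tb] if tb else 0,
                mapping if tb else None,
            )
        else:
            C = np.zeros((self.m, self.m))
            for ci in self.cols2:
                for cj in self.cols2:
                    np.add.at(C, (ci, cj), w)
            C[np.diag_indices_from(C)] += dinv2
            cop = _DenseC(C, self.cols2)
        return a, cop

    def _solve(self, a, cop, mu, r1, r2):
        """Solve the joint u-Hessian system for (r1, r2)."""
        if self.m:
            rhs2 = r2 - self._z2t_dot(mu * r1 / a)
            x2 = cop.solve(rhs2)
            x1 = (r1 - mu * self._z2_dot(x2)) / a
        else:
            x2 = np.zeros(0)
            x1 = r1 / a
        return x1, x2

    def _tau(self, cop):
        if not self.m:
            return np.zeros(self.n)
        if self.nest is not None:
            return cop.tau_rows_from_codes(
                self.codes_a, self.codes_b if self.nest[1] else None
            )
        return cop.tau_rows(self.n)

    def _diag_sum(self, cop, t):
        if self.nest is not None:
            return cop.diag_sum_for("a" if t == self.nest[0] else "b")
        return cop.diag_sum(slice(self.off2[t], self.off2[t] + self.sizes[t]))

    # -- mode finding ------------------------------------------------------

    def _inner(self, beta, d_obs, dinv2):
        u1, u2 = self.u1.copy(), self.u2.copy()
        eta_x = self.X @ beta + self.offset
        y = self.y

        def h_of(u1_, u2_):
            eta = eta_x + u1_ + self._z2_dot(u2_)
            if np.max(eta) > 40.0:
                return -np.inf, eta
            pen = 0.5 * (d_obs * float(u1_ @ u1_) + float(dinv2 * u2_ @ u2_ if self.m else 0.0))
            return float(y @ eta - np.exp(eta).sum()) - pen, eta

        h, eta = h_of(u1, u2)
        if not np.isfinite(h):
            u1, u2 = np.zeros(self.n), np.zeros(self.m)
            h, eta = h_of(u1, u2)
        mu = np.exp(np.clip(eta, -40, 40))
        for _ in range(self.max_inner):
            resid = y - mu
            g1 = resid - d_obs * u1
            g2 = self._z2t_dot(resid) - (dinv2 * u2 if self.m else np.zeros(0))
            a, cop = self._assemble(mu, d_obs, dinv2)
            s1, s2 = self._solve(a, cop, mu, g1, g2)
            t_step = 1.0
            for _ in range(30):
                u1n, u2n = u1 + t_step * s1, u2 + t_step * s2
                hn, etan = h_of(u1n, u2n)
                if hn >= h - 1e-12:
                    break
                t_step *= 0.5
            else:
                break
            dh = hn - h
            u1, u2, h, eta = u1n, u2n, hn, etan
            mu = np.exp(np.clip(eta, -40, 40))
            resid = y - mu
            g1 = resid - d_obs * u1
            g2 = self._z2t_dot(resid) - (dinv2 * u2 if self.m else np.zeros(0))
            gnorm = max(
                float(np.max(np.abs(g1))),
                float(np.max(np.abs(g2))) if self.m else 0.0,
            )
            if gnorm < 1e-11 and dh < 1e-12 * (abs(h) + 1.0):
                break
        self.u1, self.u2 = u1.copy(), u2.copy()
        a, cop = self._assemble(mu, d_obs, dinv2)
        return u1, u2, h, mu, a, cop

    def _split_params(self, x):
        beta, ls = x[:self.p], x[self.p:]
        k_obs = self.terms.index(self.olre)
        d_obs = math.exp(-2.0 * ls[k_obs])
        dinv2 = np.empty(self.m)
        for k, t in enumerate(self.terms):
            if t != self.olre:
                dinv2[self.off2[t]:self.off2[t] + self.sizes[t]] = math.exp(-2.0 * ls[k])
        return beta, ls, k_obs, d_obs, dinv2

    def _value_parts(self, x):
        beta, ls, k_obs, d_obs, dinv2 = self._split_params(x)
        u1, u2, h, mu, a, cop = self._inner(beta, d_obs, dinv2)
        logdet = float(np.sum(np.log(a)))
        if self.m:
            logdet += cop.logdet()
        ll = h - self.const - float(np.sum(self.qs * ls)) - 0.5 * logdet
        return ll, (beta, ls, k_obs, d_obs, dinv2, u1, u2, mu, a, cop)

    def neg_full_value(self, x):
        ll, parts = self._value_parts(x)
        self._cache = (x.copy(), parts)
        return -ll

    def neg_full_with_grad(self, x):
        ll, parts = self._value_parts(x)
        self._cache = (x.copy(), parts)
        beta, ls, k_obs, d_obs, dinv2, u1, u2, mu, a, cop = parts
        n, p, m = self.n, self.p, self.m
        y, X = self.y, self.X

        tau = self._tau(cop)
        r = mu / a
        s = 1.0 / a + (1.0 - r) ** 2 * tau      # z_i' Hinv z_i
        ms = mu * s
        resid = y - mu

        # beta gradient: envelope term minus half the det-term derivative
        g_beta = X.T @ resid
        zdu = np.empty((n, p))
        for j in range(p):
            r1 = mu * X[:, j]
            r2 = self._z2t_dot(r1)
            x1, x2 = self._solve(a, cop, mu, r1, r2)
            zdu[:, j] = x1 + (self._z2_dot(x2) if m else 0.0)
        C_mat = X - zdu                          # c_j = x_j + Z du_j, du = -solve
        g_beta -= 0.5 * ms @ C_mat

        g_theta = np.empty(len(self.terms))
        tr11 = float(np.sum(1.0 / a + r * r * tau))
        for k, t in enumerate(self.terms):
            if t == self.olre:
                dk = d_obs
                g = dk * float(u1 @ u1) - self.qs[k] + dk * tr11
                x1, x2 = self._solve(a, cop, mu, 2.0 * dk * u1, np.zeros(m))
            else:
                dk = math.exp(-2.0 * ls[k])
                seg = slice(self.off2[t], self.off2[t] + self.sizes[t])
                uk = u2[seg]
                tr_k = self._diag_sum(cop, t)
                g = dk * float(uk @ uk) - self.qs[k] + dk * tr_k
                rhs2 = np.zeros(m)
                rhs2[seg] = 2.0 * dk * uk
                x1, x2 = self._solve(a, cop, mu, np.zeros(n), rhs2)
            zdu_k = x1 + (self._z2_dot(x2) if m else 0.0)
            g -= 0.5 * float(ms @ zdu_k)
            g_theta[k] = g
        return -ll, -np.concatenate([g_beta, g_theta])

    def u_global(self, slices, q):
        """Modes in the global (term-sliced, level-ordered) layout."""
        u = np.zeros(q)
        tmp = np.zeros(self.n)
        tmp[self.olre_codes] = self.u1
        u[slices[self.olre]] = tmp
        for t in self.others:
            seg = slice(self.off2[t], self.off2[t] + self.sizes[t])
            u[slices[t]] = self.u2[seg]
        return u

    def wald_cov(self):
        """beta-block of the inverse joint Hessian at the cached optimum."""
        _, parts = self._cache
        beta, ls, k_obs, d_obs, dinv2, u1, u2, mu, a, cop = parts
        X = self.X
        R1 = mu[:, None] * X                              # n x p
        Hbb = X.T @ R1
        S = Hbb.copy()
        for j in range(self.p):
            r1 = R1[:, j]
            r2 = self._z2t_dot(r1) if self.m else np.zeros(0)
            x1, x2 = self._solve(a, cop, mu, r1, r2)
            col = R1.T @ x1
            if self.m:
                col = col + np.column_stack(
                    [self._z2t_dot(R1[:, l]) for l in range(self.p)]
                ).T @ x2
            S[:, j] -= col
        return np.linalg.inv(S)


class _GenericKernel:
    """Laplace objective for models without an observation-level term.

    Dense linear algebra with analytic gradients up to a size limit;
    beyond it, a sparse two-stage scheme (profiled fixed effects, then a
    finite-difference polish of the full objective).
    """

    def __init__(self, y, X, offset, Z, Zt, terms, slices, q_sizes, dinv_vec,
                 const, glm_beta, use_dense, max_inner, max_outer, p, q, n):
        self.y, self.X, self.offset = y, X, offset
        self.Z, self.Zt = Z, Zt
        self.terms, self.slices = terms, slices
        self.q_sizes, self.dinv_vec, self.const = q_sizes, dinv_vec, const
        self.glm_beta = glm_beta
        self.use_dense = use_dense
        self.max_inner, self.max_outer = max_inner, max_outer
        self.p, self.q, self.n = p, q, n
        self.Zd = Z.toarray() if use_dense else None
        self.state_u = {"u": np.zeros(q)}

    def inner_u(self, beta, dinv):
        u = self.state_u["u"].copy()
        eta_x = self.X @ beta + self.offset
        y, Z, Zt, q = self.y, self.Z, self.Zt, self.q

        def h_of(uu):
            eta = eta_x + Z @ uu
            if np.max(eta) > 40.0:
                return -np.inf, eta
            return float(y @ eta - np.exp(eta).sum() - 0.5 * (dinv * uu * uu).sum()), eta

        h, eta = h_of(u)
        if not np.isfinite(h):
            u = np.zeros(q)
            h, eta = h_of(u)
        mu = np.exp(np.clip(eta, -40, 40))

        def build(mu_):
            if self.use_dense:
                M = (self.Zd * mu_[:, None]).T @ self.Zd
                M[np.diag_indices_from(M)] += dinv
                return M
            return (Zt @ sparse.diags(mu_) @ Z + sparse.diags(dinv)).tocsc()

        Huu = build(mu)
        for _ in range(self.max_inner):
            grad = Zt @ (y - mu) - dinv * u
            try:
                if self.use_dense:
                    step = linalg.cho_solve(linalg.cho_factor(Huu, lower=True), grad)
                else:
                    step = splu(Huu).solve(grad)
            except (RuntimeError, np.linalg.LinAlgError, linalg.LinAlgError) as e:
                raise ConvergenceError(f"inner Newton failed: {e}") from e
            t_step = 1.0
            for _ in range(30):
                u_new = u + t_step * step
                h_new, eta_new = h_of(u_new)
                if h_new >= h - 1e-12:
                    break
                t_step *= 0.5
            else:
                break
            dh = h_new - h
            u, h, eta = u_new, h_new, eta_new
            mu = np.exp(np.clip(eta, -40, 40))
            Huu = build(mu)
            if (
                float(np.max(np.abs(Zt @ (y - mu) - dinv * u))) < 1e-11
                and dh < 1e-12 * (abs(h) + 1.0)
            ):
                break
        self.state_u["u"] = u.copy()
        return u, h, mu, Huu

    def neg_full_value(self, x):
        beta, log_sigma = x[:self.p], x[self.p:]
        dinv = self.dinv_vec(log_sigma)
        _, h, mu, Huu = self.inner_u(beta, dinv)
        if self.use_dense:
            chol = linalg.cho_factor(Huu, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        else:
            logdet = _logdet_sparse_spd(Huu)
        return -(h - self.const - float(np.sum(self.q_sizes * log_sigma)) - 0.5 * logdet)

    def neg_full_with_grad(self, x):
        beta, log_sigma = x[:self.p], x[self.p:]
        dinv = self.dinv_vec(log_sigma)
        u, h, mu, Huu = self.inner_u(beta, dinv)
        chol = linalg.cho_factor(Huu, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        ll = h - self.const - float(np.sum(self.q_sizes * log_sigma)) - 0.5 * logdet

        X, Zd, q = self.X, self.Zd, self.q
        Hinv = linalg.cho_solve(chol, np.eye(q))
        ZH = Zd @ Hinv
        s = np.einsum("ij,ij->i", ZH, Zd)
        resid = self.y - mu

        B = Zd.T @ (mu[:, None] * X)
        dU = -Hinv @ B
        C = X + Zd @ dU
        g_beta = X.T @ resid - 0.5 * (mu * s) @ C

        g_theta = np.empty(len(self.terms))
        for k, t in enumerate(self.terms):
            idx = self.slices[t]
            dk = math.exp(-2.0 * log_sigma[k])
            uk = u[idx]
            g = float(uk @ uk) * dk - self.q_sizes[k]
            g += dk * float(np.trace(Hinv[idx, idx]))
            rhs = np.zeros(q)
            rhs[idx] = 2.0 * dk * uk
            du_k = Hinv @ rhs
            g -= 0.5 * float((mu * s) @ (Zd @ du_k))
            g_theta[k] = g
        return -ll, -np.concatenate([g_beta, g_theta])

    def two_stage(self, x0, bounds, opts):
        p, q = self.p, self.q
        A = sparse.hstack([sparse.csr_matrix(self.X), self.Z], format="csr")
        AT = A.T.tocsr()
        y, offset = self.y, self.offset
        state = {"beta": self.glm_beta.copy()}

        def neg_profiled(log_sigma):
            dinv = self.dinv_vec(log_sigma)
            pen = np.concatenate([np.zeros(p), dinv])
            v = np.concatenate([state["beta"], self.state_u["u"]])

            def h_of(vv):
                eta = A @ vv + offset
                if np.max(eta) > 40.0:
                    return -np.inf, eta
                return float(y @ eta - np.exp(eta).sum() - 0.5 * (pen * vv * vv).sum()), eta

            h, eta = h_of(v)
            if not np.isfinite(h):
                v = np.concatenate([self.glm_beta, np.zeros(q)])
                h, eta = h_of(v)
            mu = np.exp(np.clip(eta, -40, 40))
            H = None
            for _ in range(self.max_inner):
                grad = AT @ (y - mu) - pen * v
                H = (AT @ sparse.diags(mu) @ A + sparse.diags(pen)).tocsc()
                try:
                    step = splu(H).solve(grad)
                except RuntimeError as e:
                    raise ConvergenceError(f"inner Newton failed: {e}") from e
                t_step = 1.0
                for _ in range(30):
                    v_new = v + t_step * step
                    h_new, eta_new = h_of(v_new)
                    if h_new >= h - 1e-12:
                        break
                    t_step *= 0.5
                else:
                    break
                dh = h_new - h
                v, h, eta = v_new, h_new, eta_new
                mu = np.exp(np.clip(eta, -40, 40))
                if (
                    float(np.max(np.abs(AT @ (y - mu) - pen * v))) < 1e-11
                    and dh < 1e-12 * (abs(h) + 1.0)
                ):
                    break
            state["beta"], self.state_u["u"] = v[:p].copy(), v[p:].copy()
            logdet = _logdet_sparse_spd(H[p:, p:].tocsc())
            return -(h - self.const - float(np.sum(self.q_sizes * log_sigma)) - 0.5 * logdet)

        res1 = optimize.minimize(
            neg_profiled, x0[p:], method="L-BFGS-B",
            bounds=bounds[p:],
            options={"ftol": 1e-9, "gtol": 1e-4, "maxiter": self.max_outer, "eps": 1e-6},
        )
        x1 = np.concatenate([state["beta"], res1.x])
        res = optimize.minimize(
            self.neg_full_value, x1, method="L-BFGS-B", bounds=bounds,
            options={**opts, "gtol": max(opts.get("gtol", 1e-5), 1e-5), "eps": 1e-6},
        )
        res.nit += res1.nit
        return res

    def wald_cov(self, beta, dinv):
        u, h, mu, Huu = self.inner_u(beta, dinv)
        WX = mu[:, None] * self.X
        Hbb = self.X.T @ WX
        Hub = self.Zt @ WX
        if self.use_dense:
            sol = linalg.cho_solve(linalg.cho_factor(Huu, lower=True), Hub)
        else:
            sol = splu(Huu).solve(Hub)
        return np.linalg.inv(Hbb - Hub.T @ sol)


def fit_model(design: DesignData, **kwargs) -> GLMMFit:
    """Fit the Poisson GLMM described by a :class:`DesignData`."""
    return fit_poisson_glmm(
        design.y,
        design.X,
        design.groups,
        design.offset,
        group_levels=design.group_levels,
        columns=design.columns,
        spec=design.spec,
        **kwargs,
    )


def predict_eta(
    fit: GLMMFit,
    design: DesignData,
    include_random: bool = False,
) -> np.ndarray:
    """Linear predictors for the rows of ``design`` under a fitted model.

    eta_hat = X beta_hat + offset, plus conditional random-effect modes
    for group levels seen in training when ``include_random``; levels
    unseen in training contribute 0 (their conditional mean).
    """
    if design.columns != list(fit.fixed.index):
        raise ValueError("design columns do not match the fitted model")
    eta = design.X @ fit.fixed.to_numpy() + design.offset
    if include_random:
        for term, modes in fit.re_modes.items():
            if term not in design.groups:
                continue
            labels = design.group_levels[term][design.groups[term]]
            eta = eta + modes.reindex(labels).fillna(0.0).to_numpy()
    return eta
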