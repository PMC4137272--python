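"""Penalized regression splines: 1-D P-splines, thin-plate regression splines,
GCV smoothing-parameter selection with an over-fit-guard multiplier, effective
degrees of freedom, Bayesian posterior covariance, and Wald tests on smooth terms.

The additive fits used throughout the package are penalized least-squares
problems

    min_beta ||W^{1/2}(y - X beta)||^2 + sum_j lambda_j beta' S_j beta

where each smooth term contributes a design block and a symmetric PSD penalty
S_j.  Smoothing parameters are chosen to minimise the GCV criterion

    GCV(lambda) = n * RSS / (n - gamma * edf)^2

with ``gamma >= 1`` inflating the effective degrees of freedom to deter
over-fitting.  ``edf`` is the trace of the influence matrix
X (X'WX + sum lambda_j S_j)^{-1} X'W.

Two basis families are provided:

* :class:`Basis1D` -- cubic B-splines with knots at quantiles of the distinct
  covariate values and a second-order difference penalty (null space:
  constant + linear), i.e. P-splines.
* :class:`BasisTPRS` -- eigen-truncated thin-plate regression splines in two
  dimensions (radial kernel r^2 log r), with a 3-dimensional polynomial null
  space (constant + two linear coordinates).

Everything in this module is deterministic: no random numbers are drawn.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.spatial.distance import cdist
from scipy.stats import chi2

logger = logging.getLogger(__name__)

LAMBDA_GRID = np.logspace(-6.0, 6.0, 41)


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

class InvalidArgument(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class Basis1D:
    """Cubic B-spline basis with a second-order difference penalty.

    ``k`` counts basis functions; the penalty null space (constant + linear
    in the coefficient index) has dimension 2.
    """

    name: str
    k: int
    knots: np.ndarray           # full knot vector, boundary knots repeated
    degree: int
    penalty: np.ndarray         # k x k, symmetric PSD
    null_dim: int = 2

    @classmethod
    def from_data(cls, x, k: int = 10, name: str = "x") -> "Basis1D":
        x = np.asarray(x, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise InvalidArgument(f"non-finite values in covariate {name!r}")
        if k < 3:
            raise InvalidArgument("basis dimension k must be >= 3")
        ux = np.unique(x)
        if ux.size < 2:
            raise InvalidArgument(f"covariate {name!r} is constant")
        if ux.size < k:
            logger.warning(
                "covariate %r has %d distinct values < k=%d; reducing k",
                name, ux.size, k,
            )
            k = ux.size
        degree = 3 if k >= 4 else k - 1
        # knots at quantiles of the distinct values, extended beyond the data
        # range so that index-linear coefficients map to x-linear fits when the
        # quantile knots are themselves equally spaced
        n_tau = k - degree + 1
        tau = np.quantile(ux, np.linspace(0.0, 1.0, n_tau))
        h_lo = tau[1] - tau[0] if n_tau > 1 else 1.0
        h_hi = tau[-1] - tau[-2] if n_tau > 1 else 1.0
        h_lo = h_lo if h_lo > 0 else 1.0
        h_hi = h_hi if h_hi > 0 else 1.0
        t = np.concatenate([
            tau[0] - h_lo * np.arange(degree, 0, -1),
            tau,
            tau[-1] + h_hi * np.arange(1, degree + 1),
        ])
        D = np.diff(np.eye(k), n=2, axis=0)
        S = D.T @ D
        return cls(name=name, k=k, knots=t, degree=degree, penalty=S)

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        lo = self.knots[self.degree]
        hi = self.knots[-(self.degree + 1)]
        xc = np.clip(x, lo, hi)
        M = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        return M


@dataclass(frozen=True)
class BasisTPRS:
    """Eigen-truncated bivariate thin-plate regression spline basis.

    The spline is f(s) = sum_i delta_i eta(|s - s_i|) + a0 + a1 x + a2 y with
    eta(r) = r^2 log r and the side condition T' delta = 0.  The delta vector
    is restricted to the span of the leading k eigenvectors of the kernel
    matrix, the side condition absorbs 3 of those directions, and the
    polynomial null space contributes the final 3 columns, for a total basis
    dimension of k.  Column layout: k-3 penalized columns, then [1, x, y].
    """

    k: int
    points: np.ndarray          # m x 2 construction points (normalised units)
    delta_map: np.ndarray       # m x (k-3): delta = delta_map @ z
    penalty: np.ndarray         # k x k; zero rows/cols for the null space
    center: np.ndarray = None   # coordinate normalisation: (s - center)/scale
    scale: float = 1.0
    null_dim: int = 3

    MAX_CONSTRUCTION = 600

    @staticmethod
    def _eta(r: np.ndarray) -> np.ndarray:
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out

    @classmethod
    def from_data(cls, coords, k: int = 30) -> "BasisTPRS":
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        pts = np.unique(coords, axis=0)
        if pts.shape[0] < 2:
            raise InvalidArgument("need at least 2 distinct coordinate pairs")
        if k < 4:
            raise InvalidArgument("TPRS basis dimension k must be >= 4")
        # normalise coordinates so design columns are O(1) regardless of the
        # projection units; essential for well-conditioned normal equations
        center = pts.mean(axis=0)
        scale = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
        scale = scale if scale > 0 else 1.0
        pts = (pts - center) / scale
        if pts.shape[0] > cls.MAX_CONSTRUCTION:
            logger.warning(
                "TPRS construction on %d points capped at %d space-filling knots",
                pts.shape[0], cls.MAX_CONSTRUCTION,
            )
            pts = _space_filling_subset(pts, cls.MAX_CONSTRUCTION)
        m = pts.shape[0]
        if k > m:
            logger.warning("TPRS k=%d exceeds %d distinct points; reducing", k, m)
            k = m
        if k < 4:
            raise InvalidArgument("fewer than 4 distinct coordinate pairs")
        E = cls._eta(cdist(pts, pts))
        T = np.column_stack([np.ones(m), pts[:, 0], pts[:, 1]])
        w, U = linalg.eigh(E)
        order = np.argsort(np.abs(w))[::-1][:k]
        w_k, U_k = w[order], U[:, order]
        # absorb the side condition T' U_k z = 0 (3 constraints)
        C = T.T @ U_k                        # 3 x k
        _, sv, Vt = linalg.svd(C)
        Z = Vt[3:].T                         # k x (k-3)
        delta_map = U_k @ Z
        P = Z.T @ (w_k[:, None] * Z)         # Z' diag(w) Z
        P = 0.5 * (P + P.T)
        # the bending energy is PSD under the side condition; clip round-off
        pw, pv = linalg.eigh(P)
        P = (pv * np.clip(pw, 0.0, None)) @ pv.T
        S = np.zeros((k, k))
        S[: k - 3, : k - 3] = P
        return cls(k=k, points=pts, delta_map=delta_map, penalty=S,
                   center=center, scale=scale)

    def design(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        u = (coords - self.center) / self.scale
        K = self._eta(cdist(u, self.points))
        pen = K @ self.delta_map
        return np.column_stack([pen, np.ones(len(u)), u[:, 0], u[:, 1]])


def _space_filling_subset(pts: np.ndarray, m: int) -> np.ndarray:
    """Greedy farthest-point subset; deterministic (starts nearest centroid)."""
    n = pts.shape[0]
    start = int(np.argmin(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1)))
    chosen = [start]
    d = np.sum((pts - pts[start]) ** 2, axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.sum((pts - pts[nxt]) ** 2, axis=1))
    return pts[np.sort(chosen)]


def build_basis_1d(x, k: int = 10, name: str = "x") -> Basis1D:
    """Quantile-knot cubic P-spline basis for a single covariate."""
    return Basis1D.from_data(x, k=k, name=name)


def build_basis_tprs(coords, k: int = 30) -> BasisTPRS:
    """Eigen-truncated thin-plate spline basis for planar coordinates."""
    return BasisTPRS.from_data(coords, k=k)


# ---------------------------------------------------------------------------
# penalized fitting
# ---------------------------------------------------------------------------

@dataclass
class TermSpec:
    """One additive-model term: a design block and (optionally) a penalty.

    ``penalty=None`` marks a parametric (unpenalized) block.  ``lam`` fixes the
    smoothing parameter; ``lam=None`` requests GCV selection.
    """

    name: str
    design: np.ndarray
    penalty: np.ndarray | None = None
    null_dim: int = 0
    lam: float | None = None


@dataclass
class TermFit:
    name: str
    sl: slice
    lam: float | None
    edf: float
    null_dim: int
    k: int


@dataclass
class PenalizedFit:
    """A fitted penalized least-squares model.

    ``cov`` is the Bayesian posterior covariance sigma^2 (X'WX + sum l S)^-1;
    ``scale`` is sigma^2 = RSS / (n - edf); ``edf`` the trace of the influence
    matrix.
    """

    beta: np.ndarray
    cov: np.ndarray
    scale: float
    edf: float
    gcv: float
    gamma: float
    terms: list[TermFit]
    fitted: np.ndarray
    residuals: np.ndarray
    n_obs: int
    rank_deficient: bool = False
    # fitting context retained so edf caps / refits are possible
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)
    _penalties: dict = field(repr=False, default_factory=dict)

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def coef_block(self, name: str) -> np.ndarray:
        return self.beta[self.term(name).sl]

    def cov_block(self, name: str) -> np.ndarray:
        sl = self.term(name).sl
        return self.cov[sl, sl]

    def summary(self) -> str:
        """Structured text report: term, k, lambda, edf, Wald p."""
        lines = [f"PenalizedFit: n={self.n_obs} edf={self.edf:.2f} "
                 f"scale={self.scale:.4g} gamma={self.gamma}"]
        for t in self.terms:
            if t.lam is None:
                lines.append(f"  {t.name}: k={t.k} parametric "
                             f"edf={t.edf:.2f}")
            else:
                p = wald_smooth_test(self, t.name)
                lines.append(f"  {t.name}: k={t.k} lam={t.lam:.3g} "
                             f"edf={t.edf:.2f} wald_p={p:.3g}")
        return "\n".join(lines)


class _PLSWork:
    """Cached cross-products for repeated solves along a lambda path."""

    def __init__(self, terms: list[TermSpec], y, weights=None):
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise InvalidArgument("non-finite response values")
        n = y.size
        for t in terms:
            if t.design.shape[0] != n:
                raise InvalidArgument(f"term {t.name!r} design has wrong length")
        X = np.hstack([t.design for t in terms])
        if X.shape[1] > n:
            logger.warning(
                "design has %d columns for %d observations; penalized fit "
                "proceeds but the unpenalized limit is not identifiable",
                X.shape[1], n,
            )
        w = np.ones(n) if weights is None else np.asarray(weights, float).ravel()
        if np.any(w < 0):
            raise InvalidArgument("negative weights")
        slices, off = [], 0
        for t in terms:
            p = t.design.shape[1]
            slices.append(slice(off, off + p))
            off += p
        self.terms, self.X, self.y, self.w = terms, X, y, w
        self.slices = slices
        self.n, self.p = n, off
        self.Xw = X * w[:, None]
        self.XtWX = X.T @ self.Xw
        self.XtWy = self.Xw.T @ y
        self.yWy = float(y @ (w * y))
        self.rank_deficient = False

    def with_response(self, y) -> "_PLSWork":
        """Cheap clone for a new response on the same design (X'WX reused)."""
        import copy
        new = copy.copy(self)
        y = np.asarray(y, dtype=float).ravel()
        new.y = y
        new.XtWy = self.Xw.T @ y
        new.yWy = float(y @ (self.w * y))
        new.rank_deficient = False
        return new

    def penalty_total(self, lams: dict[int, float]) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for j, t in enumerate(self.terms):
            if t.penalty is not None:
                sl = self.slices[j]
                S[sl, sl] += lams[j] * t.penalty
        return S

    def solve(self, lams: dict[int, float]):
        A = self.XtWX + self.penalty_total(lams)
        try:
            cf = linalg.cho_factor(A, check_finite=False)
            beta = linalg.cho_solve(cf, self.XtWy, check_finite=False)
            B = linalg.cho_solve(cf, self.XtWX, check_finite=False)
            Ainv = linalg.cho_solve(cf, np.eye(self.p), check_finite=False)
        except linalg.LinAlgError:
            self.rank_deficient = True
            Ainv = np.linalg.pinv(A, hermitian=True)
            beta = Ainv @ self.XtWy
            B = Ainv @ self.XtWX
        edf_terms = np.array([np.trace(B[sl, sl]) for sl in self.slices])
        edf = float(np.trace(B))
        r = self.y - self.X @ beta
        rss = float(r @ (self.w * r))
        return beta, Ainv, edf, edf_terms, rss

    def gcv(self, lams: dict[int, float], gamma: float) -> float:
        _, _, edf, _, rss = self.solve(lams)
        denom = self.n - gamma * edf
        if denom <= 0:
            return np.inf
        return self.n * rss / denom ** 2


def _golden_refine(fun, grid_lams, best_idx, iters=12):
    """Golden-section search on log-lambda between the grid neighbours."""
    lo = grid_lams[max(best_idx - 1, 0)]
    hi = grid_lams[min(best_idx + 1, len(grid_lams) - 1)]
    a, b = math.log(lo), math.log(hi)
    if b - a < 1e-12:
        return grid_lams[best_idx]
    invphi = (math.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fun(math.exp(c)), fun(math.exp(d))
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(math.exp(d))
    return math.exp((a + b) / 2)


def _single_term_gcv_lambda(work: "_PLSWork", gamma: float) -> float | None:
    """Fast GCV minimisation for a model with exactly one penalized term.

    Simultaneous diagonalisation of (X'WX, S) makes each lambda evaluation
    O(p).  Returns the selected lambda, or None if the decomposition fails
    (caller falls back to the generic grid search).
    """
    t = work.terms[0]
    B, S = work.XtWX, t.penalty
    try:
        mu, V = linalg.eigh(S, B)
    except linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(mu)):
        return None
    mu = np.clip(mu, 0.0, None)
    c = V.T @ work.XtWy
    c2 = c ** 2
    n, yWy = work.n, work.yWy

    def gcv(lam):
        shrink = 1.0 / (1.0 + lam * mu)
        rss = yWy - 2.0 * np.sum(c2 * shrink) + np.sum(c2 * shrink ** 2)
        edf = np.sum(shrink)
        denom = n - gamma * edf
        return n * max(rss, 0.0) / denom ** 2 if denom > 0 else np.inf

    scores = [gcv(lam) for lam in LAMBDA_GRID]
    best = _argmin_prefer_smooth(scores)
    return _golden_refine(gcv, LAMBDA_GRID, best)


def _argmin_prefer_smooth(scores) -> int:
    """Index of the minimum score; ties resolve to the largest lambda."""
    s = np.asarray(scores, dtype=float)
    m = np.nanmin(s)
    tied = np.where(s <= m + 1e-9 * max(abs(m), 1e-300))[0]
    return int(tied[-1])


def fit_penalized(
    terms: list[TermSpec],
    y,
    gamma: float = 1.0,
    weights=None,
    n_sweeps: int = 2,
    _work: "_PLSWork | None" = None,
) -> PenalizedFit:
    """Fit an additive penalized least-squares model.

    Smoothing parameters for terms with ``lam=None`` minimise the
    gamma-inflated GCV score over a 41-point log-spaced grid per term
    (coordinate-wise cycling over terms for ``n_sweeps`` sweeps) followed by a
    golden-section refinement.  Terms with ``lam`` set are held fixed.
    """
    if gamma < 1.0:
        raise InvalidArgument("gamma must be >= 1")
    work = _work if _work is not None else _PLSWork(terms, y, weights)
    lams: dict[int, float] = {}
    free: list[int] = []
    for j, t in enumerate(terms):
        if t.penalty is None:
            continue
        if t.lam is not None:
            lams[j] = float(t.lam)
        else:
            lams[j] = 1.0
            free.append(j)

    if free:
        fast = None
        if len(terms) == 1 and free == [0]:
            fast = _single_term_gcv_lambda(work, gamma)
        if fast is not None:
            lams[0] = fast
        else:
            for _ in range(n_sweeps):
                for j in free:
                    scores = []
                    for lam in LAMBDA_GRID:
                        lams[j] = lam
                        scores.append(work.gcv(lams, gamma))
                    best = int(np.argmin(scores))
                    lams[j] = LAMBDA_GRID[best]

                    def fj(lam, j=j):
                        lams[j] = lam
                        return work.gcv(lams, gamma)

                    lams[j] = _golden_refine(fj, LAMBDA_GRID, best)

    beta, Ainv, edf, edf_terms, rss = work.solve(lams)
    scale = rss / max(work.n - edf, 1e-8)
    denom = work.n - gamma * edf
    gcv = work.n * rss / denom ** 2 if denom > 0 else np.inf
    fits = [
        TermFit(
            name=t.name,
            sl=work.slices[j],
            lam=lams.get(j) if t.penalty is not None else None,
            edf=float(edf_terms[j]),
            null_dim=t.null_dim,
            k=t.design.shape[1],
        )
        for j, t in enumerate(terms)
    ]
    fitted = work.X @ beta
    return PenalizedFit(
        beta=beta, cov=scale * Ainv, scale=scale, edf=edf, gcv=gcv,
        gamma=gamma, terms=fits, fitted=fitted, residuals=work.y - fitted,
        n_obs=work.n, rank_deficient=work.rank_deficient,
        _X=work.X, _y=work.y, _w=work.w,
        _penalties={j: t.penalty for j, t in enumerate(terms)
                    if t.penalty is not None},
    )


def _refit_with_lams(fit: PenalizedFit, lams: dict[int, float]) -> PenalizedFit:
    terms = [
        TermSpec(
            name=t.name,
            design=fit._X[:, t.sl],
            penalty=fit._penalties.get(j),
            null_dim=t.null_dim,
            lam=lams.get(j, t.lam),
        )
        for j, t in enumerate(fit.terms)
    ]
    return fit_penalized(terms, fit._y, gamma=fit.gamma, weights=fit._w)


def cap_edf(fit: PenalizedFit, term_name: str, max_df: float,
            tol: float = 0.05) -> PenalizedFit:
    """Increase a term's smoothing parameter until its edf <= ``max_df``.

    Mirrors constraining a smooth to a maximum degrees of freedom via its
    smoothing parameter.  Monotone bisection on log-lambda; the cap must not
    fall below the term's penalty null-space dimension (the infinite-lambda
    limit).
    """
    j = [i for i, t in enumerate(fit.terms) if t.name == term_name]
    if not j:
        raise KeyError(term_name)
    j = j[0]
    t = fit.terms[j]
    if t.lam is None:
        raise InvalidArgument(f"term {term_name!r} is parametric")
    if max_df < t.null_dim:
        raise InvalidArgument(
            f"cap {max_df} below null-space dimension {t.null_dim}")
    if t.edf <= max_df + tol:
        return fit

    work = _PLSWork(
        [TermSpec(tt.name, fit._X[:, tt.sl], fit._penalties.get(i),
                  tt.null_dim, tt.lam) for i, tt in enumerate(fit.terms)],
        fit._y, fit._w,
    )
    lams = {i: tt.lam for i, tt in enumerate(fit.terms) if tt.lam is not None}

    def edf_at(lam):
        lams[j] = lam
        return work.solve(lams)[3][j]

    lo = math.log(t.lam)
    hi = lo
    for _ in range(60):
        hi += 1.5
        if edf_at(math.exp(hi)) <= max_df:
            break
    else:
        raise InvalidArgument("edf cap unattainable")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        e = edf_at(math.exp(mid))
        if e > max_df:
            lo = mid
        else:
            hi = mid
        if max_df - e <= tol and e <= max_df:
            break
    lams[j] = math.exp(hi)
    return _refit_with_lams(fit, lams)


@dataclass
class CenteredSmooth1D:
    """A fitted, sum-to-zero-centred 1-D smooth: evaluable at new covariate
    values.  ``col_means`` are the training design column means subtracted for
    identifiability against the model intercept."""

    basis: Basis1D
    col_means: np.ndarray
    beta: np.ndarray
    lam: float
    edf: float

    def __call__(self, x) -> np.ndarray:
        return (self.basis.design(x) - self.col_means) @ self.beta

    def design_row(self, x) -> np.ndarray:
        return self.basis.design(x) - self.col_means


@dataclass
class CenteredSurface:
    """A fitted, mean-centred thin-plate surface evaluable anywhere.

    ``col_means`` is the average design row over the observations the surface
    was centred on, so prediction variance propagates through the centring.
    """

    basis: BasisTPRS
    col_means: np.ndarray
    beta: np.ndarray
    lam: float
    edf: float
    cov: np.ndarray | None = None     # posterior covariance of beta

    def __call__(self, coords) -> np.ndarray:
        return (self.basis.design(coords) - self.col_means) @ self.beta

    def design_row(self, coords) -> np.ndarray:
        return self.basis.design(coords) - self.col_means

    def predict_var(self, coords) -> np.ndarray:
        if self.cov is None:
            return np.zeros(np.asarray(coords).reshape(-1, 2).shape[0])
        D = self.design_row(coords)
        return np.einsum("ij,jk,ik->i", D, self.cov, D)


def wald_smooth_test(fit: PenalizedFit, term_name: str) -> float:
    """Wald test that a smooth term's coefficient block is zero.

    Uses the pseudo-inverse of the block's posterior covariance and a
    chi-squared reference with df equal to the rounded per-term edf.
    Returns p in [0, 1]; a zero-edf (fully shrunk) term returns p = 1.
    """
    t = fit.term(term_name)
    beta = fit.beta[t.sl]
    if np.allclose(beta, 0.0):
        return 1.0
    df = int(round(t.edf))
    if df < 1:
        logger.warning("term %r has ~zero edf; Wald p set to 1", term_name)
        return 1.0
    V = fit.cov[t.sl, t.sl]
    Vinv = rank_truncated_inverse(V, df)
    stat = float(beta @ Vinv @ beta)
    return float(chi2.sf(stat, df))


def rank_truncated_inverse(V: np.ndarray, rank: int) -> np.ndarray:
    """Pseudo-inverse of a covariance block truncated to its leading
    ``rank`` eigen-directions.

    Matching the inverse's rank to the reference chi-squared df keeps Wald
    statistics on penalized coefficient blocks approximately calibrated:
    heavily shrunk directions contribute neither to the statistic nor to the
    degrees of freedom.
    """
    V = 0.5 * (V + V.T)
    w, U = linalg.eigh(V)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = min(max(rank, 1), np.sum(w > 1e-12 * max(w[0], 1e-300)))
    Uk = U[:, :keep]
    return Uk @ np.diag(1.0 / w[:keep]) @ Uk.T
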