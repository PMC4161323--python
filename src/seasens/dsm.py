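"""Density surface modelling.

Detection-corrected segment abundances are fitted against space and habitat
covariates with a penalized GAM:

    E[n̂_i] = exp( β₀ + s(x_i, y_i) + s(cdist_i) + log(covered_area_i) )

with a negative-binomial (default) or Tweedie response.  Smooths are
penalized regression splines: a tensor-product P-spline for the 2-D spatial
term and a 1-D P-spline for distance-to-coast, each with second-order
difference penalties.  Smoothing parameters are chosen by REML via the
generalized Fellner–Schall update inside a penalized IRLS loop; the NB size
parameter θ is profiled by an outer bounded (Brent) search on the Laplace
REML score.  An optional null-space ("double") penalty per term allows
automatic term selection by shrinking a whole smooth out of the model.

Prediction on the 3 km grid uses cell area as the offset, so predictions are
densities in birds/km²; cell CVs come from the Bayesian view of the GAM
(posterior draws of the coefficients) combined with the detection-function CV
by the delta method.  Smoothing is over unconstrained planar space; land is
handled by restricting prediction to the sea mask and carrying cdist as a
covariate, with cells outside the effort's convex hull flagged extrapolated.

The per-cell CVs ignore residual spatial autocorrelation and so should be
read as lower bounds on the true uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, spatial
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

__all__ = [
    "SmoothSpec",
    "DensityModel",
    "DensitySurface",
    "compute_vif",
    "choose_covariates",
    "fit_dsm",
    "predict_grid",
    "cell_cv",
    "relative_density_fallback",
    "assign_cells",
    "write_surface_csv",
]


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def compute_vif(cov: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per covariate: 1 / (1 − R²_j)."""
    if cov.shape[1] < 2:
        raise ValueError("need at least two covariates")
    if cov.shape[0] <= cov.shape[1]:
        raise ValueError("need more rows than covariates")
    out: dict[str, float] = {}
    X = cov.to_numpy(dtype=float)
    for j, name in enumerate(cov.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(yj)),
                                  np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 > 1 - 1e-10 else 1.0 / (1.0 - r2)
    return out


def choose_covariates(cov: pd.DataFrame, explanatory_power: dict[str, float],
                      threshold: float = 5.0) -> list[str]:
    """Greedy collinearity pruning.

    While any VIF exceeds ``threshold``, drop the offending covariate with the
    lowest single-term explanatory power (e.g. deviance explained) and
    recompute.  Mirrors preferring cdist over depth when the two are
    confounded but cdist explains more.
    """
    keep = list(cov.columns)
    while len(keep) >= 2:
        vifs = compute_vif(cov[keep])
        offenders = [c for c in keep if vifs[c] > threshold]
        if not offenders:
            break
        worst = min(offenders, key=lambda c: explanatory_power.get(c, 0.0))
        keep.remove(worst)
    return keep


# ---------------------------------------------------------------------------
# Spline machinery
# ---------------------------------------------------------------------------

_DEGREE = 3


def _pspline_knots(lo: float, hi: float, k: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0
    nseg = k - _DEGREE
    step = (hi - lo) / nseg
    return lo + step * np.arange(-_DEGREE, k + 1)


def _bspline_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[_DEGREE], knots[-_DEGREE - 1]
    xc = np.clip(x, lo, hi - 1e-9 * max(1.0, abs(hi)))
    return BSpline.design_matrix(xc, knots, _DEGREE).toarray()


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


@dataclass
class SmoothSpec:
    """Recipe for one smooth term (before fitting)."""
    covariates: tuple[str, ...]          # ("x", "y") or ("cdist_km",)
    k: int                                # total basis dimension target


@dataclass
class _FittedTerm:
    covariates: tuple[str, ...]
    knots: list[np.ndarray]               # per marginal covariate
    Z: np.ndarray                         # constraint transform (p, p-1)
    penalties: list[np.ndarray]           # in constrained space
    ncoef: int

    def design(self, data: pd.DataFrame, shifts: dict[str, float]) -> np.ndarray:
        mats = [
            _bspline_matrix(
                data[c].to_numpy(dtype=float) - shifts.get(c, 0.0), kn)
            for c, kn in zip(self.covariates, self.knots)]
        if len(mats) == 1:
            B = mats[0]
        else:  # row-wise tensor product
            B = (mats[0][:, :, None] * mats[1][:, None, :]).reshape(
                len(data), -1)
        return B @ self.Z


def _build_term(spec: SmoothSpec, data: pd.DataFrame,
                shifts: dict[str, float],
                domain: dict[str, tuple[float, float]] | None,
                select: bool) -> _FittedTerm:
    knots = []
    for c in spec.covariates:
        v = data[c].to_numpy(dtype=float) - shifts.get(c, 0.0)
        if domain and c in domain:
            lo, hi = domain[c]
            lo, hi = lo - shifts.get(c, 0.0), hi - shifts.get(c, 0.0)
        else:
            span = np.ptp(v) or 1.0
            lo, hi = v.min() - 0.05 * span, v.max() + 0.05 * span
        k_marg = (spec.k if len(spec.covariates) == 1
                  else max(int(np.ceil(np.sqrt(spec.k))), 4))
        n_unique = len(np.unique(np.round(v, 6)))
        if n_unique < k_marg:
            warnings.warn(
                f"smooth over {spec.covariates}: basis shrunk from {k_marg} "
                f"to {max(n_unique, 4)} (few unique locations)", stacklevel=2)
            k_marg = max(n_unique, 4)
        knots.append(_pspline_knots(lo, hi, k_marg))

    sizes = [kn.size - _DEGREE - 1 for kn in knots]
    if len(sizes) == 1:
        raw_pens = [_diff_penalty(sizes[0])]
        p = sizes[0]
    else:
        kx, ky = sizes
        raw_pens = [np.kron(_diff_penalty(kx), np.eye(ky)),
                    np.kron(np.eye(kx), _diff_penalty(ky))]
        p = kx * ky
    # sum-to-zero constraint over the observed data
    mats = [_bspline_matrix(data[c].to_numpy(dtype=float) - shifts.get(c, 0.0), kn)
            for c, kn in zip(spec.covariates, knots)]
    B = (mats[0] if len(mats) == 1
         else (mats[0][:, :, None] * mats[1][:, None, :]).reshape(len(data), -1))
    cvec = B.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(cvec.T, mode="complete")
    Z = q[:, 1:]
    pens = [Z.T @ S @ Z for S in raw_pens]
    if select:
        # null-space penalty: shrink the component no difference penalty reaches
        Stot = sum(pens)
        evals, evecs = np.linalg.eigh(Stot)
        tol = max(evals.max(), 1.0) * 1e-8
        null = evecs[:, evals < tol]
        if null.shape[1]:
            pens.append(null @ null.T)
    return _FittedTerm(covariates=spec.covariates, knots=knots, Z=Z,
                       penalties=pens, ncoef=p - 1)


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

class _Family:
    name = "base"
    scale_known = True

    def variance(self, mu): ...
    def loglik(self, y, mu): ...
    def deviance(self, y, mu): ...


class NegativeBinomial(_Family):
    """NB2: Var = μ + μ²/θ.  θ is profiled during fitting."""
    name = "negative-binomial"

    def __init__(self, theta: float = 1.0):
        if theta <= 0:
            raise ValueError("theta must be > 0")
        self.theta = theta

    def variance(self, mu):
        return mu + mu ** 2 / self.theta

    def loglik(self, y, mu):
        th = self.theta
        mu = np.clip(mu, 1e-12, None)
        return float(np.sum(
            gammaln(y + th) - gammaln(th) - gammaln(y + 1)
            + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu))))

    def deviance(self, y, mu):
        th = self.theta
        mu = np.clip(mu, 1e-12, None)
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1) / mu), 0.0)
        return float(2 * np.sum(
            ylogy - (y + th) * np.log((y + th) / (mu + th))))


class Tweedie(_Family):
    """Compound-Poisson Tweedie, 1 < p < 2: Var = φ μ^p; zero-inflated continuous."""
    name = "tweedie"
    scale_known = False

    def __init__(self, p: float = 1.5):
        if not 1 < p < 2:
            raise ValueError("Tweedie power must satisfy 1 < p < 2")
        self.p = p

    def variance(self, mu):
        return mu ** self.p

    def deviance(self, y, mu):
        p = self.p
        mu = np.clip(mu, 1e-12, None)
        t1 = np.where(y > 0,
                      np.power(np.where(y > 0, y, 1), 2 - p) / ((1 - p) * (2 - p)),
                      0.0)
        return float(2 * np.sum(
            t1 - y * mu ** (1 - p) / (1 - p) + mu ** (2 - p) / (2 - p)))

    def loglik(self, y, mu):  # saddlepoint approximation (used for scoring only)
        dev = self.deviance(y, mu)
        return -0.5 * dev


def _family(family: str | _Family, theta: float | None = None,
            tweedie_p: float = 1.5) -> _Family:
    if isinstance(family, _Family):
        return family
    if family in ("nb", "negative-binomial"):
        return NegativeBinomial(theta or 1.0)
    if family == "tweedie":
        return Tweedie(tweedie_p)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class DensityModel:
    terms: list[_FittedTerm]
    beta: np.ndarray
    Vb: np.ndarray                      # Bayesian posterior covariance of β
    lambdas: np.ndarray
    family: _Family
    scale: float                        # φ (1 for NB)
    shifts: dict[str, float]
    region: str
    deviance: float
    null_deviance: float
    edf: float
    reml: float
    effort_xy: np.ndarray | None = None     # segment midpoints, for hull test
    cdist_range: tuple[float, float] | None = None

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    def design(self, data: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(data), 1))]
        blocks += [t.design(data, self.shifts) for t in self.terms]
        return np.hstack(blocks)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return self.design(data) @ self.beta


@dataclass
class DensitySurface:
    """Per-cell density (birds/km²) and CV for one species slice."""
    species: str
    behaviour: str
    season: str
    platform: str
    table: pd.DataFrame = field(repr=False)
    # table columns: cell_id, density, cv, abundance, extrapolated

    def aligned(self, column: str) -> pd.Series:
        return self.table.set_index("cell_id")[column]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _assemble_penalties(terms: list[_FittedTerm]) -> tuple[list[np.ndarray], int]:
    """Embed per-term penalties into full-coefficient space (after intercept)."""
    p_tot = 1 + sum(t.ncoef for t in terms)
    mats = []
    offset = 1
    for t in terms:
        for S in t.penalties:
            M = np.zeros((p_tot, p_tot))
            M[offset:offset + t.ncoef, offset:offset + t.ncoef] = S
            mats.append(M)
        offset += t.ncoef
    return mats, p_tot


def _pirls(X, y, off, fam: _Family, S_list, lam, beta0=None,
           max_iter=100, tol=1e-8):
    n, p = X.shape
    Slam = sum(l * S for l, S in zip(lam, S_list)) if S_list else np.zeros((p, p))
    if beta0 is None:
        mu = np.clip(y, 0.1, None) + np.mean(y) * 0.1 + 0.1
        eta = np.log(mu) - off
    else:
        eta = X @ beta0
        mu = np.exp(np.clip(eta + off, -30, 30))
    beta = beta0
    dev = np.inf
    for _ in range(max_iter):
        V = np.clip(fam.variance(mu), 1e-12, None)
        wts = mu ** 2 / V
        z = eta + (y - mu) / np.clip(mu, 1e-12, None)
        WX = X * wts[:, None]
        A = X.T @ WX + Slam
        b = WX.T @ z
        try:
            c, low = cho_factor(A + 1e-10 * np.eye(p))
            beta_new = cho_solve((c, low), b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + 1e-6 * np.eye(p), b)
        eta = X @ beta_new
        mu = np.exp(np.clip(eta + off, -30, 30))
        dev_new = fam.deviance(y, mu)
        if beta is not None and abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            beta = beta_new
            dev = dev_new
            break
        beta, dev = beta_new, dev_new
    V = np.clip(fam.variance(mu), 1e-12, None)
    wts = mu ** 2 / V
    H = X.T @ (X * wts[:, None])
    return beta, mu, H, Slam, dev


def _logdet_pinv(S: np.ndarray, rank_tol: float = 1e-8):
    evals, evecs = np.linalg.eigh(S)
    thresh = max(evals.max(), 1e-300) * rank_tol
    pos = evals > thresh
    pinv = (evecs[:, pos] / evals[pos]) @ evecs[:, pos].T
    logdet = float(np.sum(np.log(evals[pos])))
    return pinv, logdet, int(np.sum(~pos))


def _laml(fam, y, mu, beta, Slam, H, scale):
    """Negative Laplace-approximate REML score (smaller is better)."""
    pen = float(beta @ Slam @ beta)
    ll = fam.loglik(y, mu) / scale
    _, logdet_S, nullity = _logdet_pinv(Slam)
    sign, logdet_A = np.linalg.slogdet(H / scale + Slam / scale
                                       + 1e-10 * np.eye(len(beta)))
    return -(ll - 0.5 * pen / scale - 0.5 * logdet_A
             + 0.5 * (logdet_S - Slam.shape[0] * 0)  # generalized det
             - 0.5 * nullity * np.log(2 * np.pi))


def _fit_at(X, y, off, fam, S_list, max_fs_iter=40):
    """Inner loop: Fellner–Schall REML optimisation of the λ vector."""
    p = X.shape[1]
    lam = np.full(len(S_list), 1.0)
    beta = None
    for _ in range(max_fs_iter):
        beta, mu, H, Slam, dev = _pirls(X, y, off, fam, S_list, lam, beta0=beta)
        if fam.scale_known:
            scale = 1.0
        else:
            V = np.clip(fam.variance(mu), 1e-12, None)
            edf_quick = p  # conservative before edf known
            scale = max(float(np.sum((y - mu) ** 2 / V))
                        / max(len(y) - edf_quick, 1), 1e-8)
        Spinv, _, _ = _logdet_pinv(Slam + 1e-12 * np.eye(p))
        Ainv = np.linalg.inv(H + Slam + 1e-10 * np.eye(p))
        new_lam = lam.copy()
        for j, Sj in enumerate(S_list):
            num = np.trace(Spinv @ Sj) - np.trace(Ainv @ Sj)
            den = float(beta @ Sj @ beta)
            if den < 1e-12 or num <= 0:
                new_lam[j] = min(lam[j] * 10.0, 1e7)
            else:
                new_lam[j] = np.clip(scale * num / den, 1e-7, 1e7)
        step = np.abs(np.log(new_lam) - np.log(lam))
        # damp large moves for stability
        ratio = np.exp(np.clip(np.log(new_lam / lam), -3, 3))
        lam = lam * ratio
        if step.max() < 0.02:
            break
    beta, mu, H, Slam, dev = _pirls(X, y, off, fam, S_list, lam, beta0=beta)
    if fam.scale_known:
        scale = 1.0
    else:
        Ainv = np.linalg.inv(H + Slam + 1e-10 * np.eye(p))
        edf = float(np.trace(Ainv @ H))
        V = np.clip(fam.variance(mu), 1e-12, None)
        scale = max(float(np.sum((y - mu) ** 2 / V))
                    / max(len(y) - edf, 1), 1e-8)
    return beta, mu, H, Slam, dev, lam, scale


def fit_dsm(segments: pd.DataFrame, response: str = "n_hat",
            family: str | _Family = "negative-binomial",
            smooths: list[SmoothSpec] | None = None,
            offset: str = "covered_area_km2",
            region: str = "main",
            domain: dict[str, tuple[float, float]] | None = None,
            select: bool = True,
            profile_theta: bool = True,
            theta: float | None = None,
            tweedie_p: float = 1.5) -> DensityModel:
    """Fit the density GAM to detection-corrected segment abundances.

    ``segments`` must contain the response, the offset area (km²) and every
    smooth covariate.  ``domain`` optionally widens the spline support (e.g.
    to the prediction grid's extent) so grid cells are interpolated rather
    than clamped.
    """
    if smooths is None:
        smooths = [SmoothSpec(("x", "y"), k=30), SmoothSpec(("cdist_km",), k=10)]
    seg = segments.reset_index(drop=True)
    y = seg[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    off = np.log(seg[offset].to_numpy(dtype=float))

    shifts = {}
    for c in {c for s in smooths for c in s.covariates}:
        shifts[c] = float(seg[c].mean())

    fam = _family(family, theta=theta, tweedie_p=tweedie_p)
    terms = [_build_term(s, seg, shifts, domain, select) for s in smooths]
    S_list, p_tot = _assemble_penalties(terms)
    blocks = [np.ones((len(seg), 1))] + [t.design(seg, shifts) for t in terms]
    X = np.hstack(blocks)

    if isinstance(fam, NegativeBinomial) and profile_theta and theta is None:
        # moment start from a roughly-fitted mean, then Brent on the REML score
        fam.theta = 1.0
        beta, mu, H, Slam, dev, lam, scale = _fit_at(X, y, off, fam, S_list)
        resid_var = max(np.mean((y - mu) ** 2 - mu), 1e-6)
        th0 = np.clip(np.mean(mu ** 2) / resid_var, 0.05, 100.0)

        def neg_reml(log_th):
            f = NegativeBinomial(float(np.exp(log_th)))
            b, m, h, sl, d = _pirls(X, y, off, f, S_list, lam, beta0=beta)
            return _laml(f, y, m, b, sl, h, 1.0)

        res = optimize.minimize_scalar(
            neg_reml, bounds=(np.log(max(th0 / 30, 0.02)), np.log(th0 * 30 + 1)),
            method="bounded", options={"maxiter": 12, "xatol": 0.05})
        fam.theta = float(np.exp(res.x))

    beta, mu, H, Slam, dev, lam, scale = _fit_at(X, y, off, fam, S_list)
    if not np.all(np.isfinite(beta)):
        raise RuntimeError("DSM did not converge: non-finite coefficients")

    A = H + Slam + 1e-10 * np.eye(p_tot)
    Ainv = np.linalg.inv(A)
    Vb = scale * Ainv
    edf = float(np.trace(Ainv @ H))
    null_mu = np.full_like(y, max(y.mean(), 1e-12))
    reml = _laml(fam, y, mu, beta, Slam, H, scale)

    cr = None
    if "cdist_km" in seg.columns:
        cr = (float(seg["cdist_km"].min()), float(seg["cdist_km"].max()))
    return DensityModel(
        terms=terms, beta=beta, Vb=Vb, lambdas=lam, family=fam, scale=scale,
        shifts=shifts, region=region, deviance=dev,
        null_deviance=fam.deviance(y, null_mu), edf=edf, reml=reml,
        effort_xy=seg[["x", "y"]].to_numpy(dtype=float)
        if {"x", "y"} <= set(seg.columns) else None,
        cdist_range=cr)


# ---------------------------------------------------------------------------
# Prediction and uncertainty
# ---------------------------------------------------------------------------

def _extrapolation_flags(model: DensityModel, grid: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(grid), dtype=bool)
    if model.effort_xy is not None and len(model.effort_xy) >= 4:
        try:
            tri = spatial.Delaunay(model.effort_xy)
            inside = tri.find_simplex(
                grid[["x", "y"]].to_numpy(dtype=float)) >= 0
            flags |= ~inside
        except Exception:  # degenerate effort geometry (collinear transects)
            pass
    if model.cdist_range is not None and "cdist_km" in grid.columns:
        cd = grid["cdist_km"].to_numpy(dtype=float)
        lo, hi = model.cdist_range
        flags |= (cd < lo) | (cd > hi)
    return flags


def predict_grid(model: DensityModel, grid: pd.DataFrame,
                 species: str = "", behaviour: str = "", season: str = "",
                 platform: str = "", cv: np.ndarray | None = None,
                 region: str | None = None) -> DensitySurface:
    """Predict density (birds/km²) on the grid's sea cells.

    Cells outside the model's region, on land, or with zero sea area are
    returned as missing (NaN), not zero.
    """
    g = grid.reset_index(drop=True)
    usable = (g["is_sea"].to_numpy(dtype=bool)
              & (g["area_km2"].to_numpy(dtype=float) > 0))
    if region is not None and "region" in g.columns:
        usable &= (g["region"] == region).to_numpy()
    dens = np.full(len(g), np.nan)
    if usable.any():
        eta = model.linear_predictor(g.loc[usable])
        dens[usable] = np.exp(np.clip(eta, -30, 30))
    flags = _extrapolation_flags(model, g)
    table = pd.DataFrame({
        "cell_id": g["cell_id"], "density": dens,
        "cv": cv if cv is not None else np.full(len(g), np.nan),
        "abundance": dens * g["area_km2"].to_numpy(dtype=float),
        "extrapolated": flags,
    })
    return DensitySurface(species=species, behaviour=behaviour, season=season,
                          platform=platform, table=table)


def cell_cv(model: DensityModel, grid: pd.DataFrame,
            detection_cv: float = 0.0, n_draws: int = 500,
            seed: int = 0) -> np.ndarray:
    """Per-cell CV of predicted density.

    Coefficients are drawn from the Gaussian posterior N(β̂, V_β); the GAM CV
    is sd/mean of the per-draw densities, combined with the detection CV as
    sqrt(CV_gam² + cv_p²).
    """
    g = grid.reset_index(drop=True)
    usable = (g["is_sea"].to_numpy(dtype=bool)
              & (g["area_km2"].to_numpy(dtype=float) > 0))
    out = np.full(len(g), np.nan)
    if not usable.any():
        return out
    X = model.design(g.loc[usable])
    Vb = model.Vb
    if np.allclose(Vb, 0):
        cv_gam = np.zeros(X.shape[0])
    else:
        rng = np.random.default_rng(seed)
        try:
            L = np.linalg.cholesky(Vb)
        except np.linalg.LinAlgError:
            warnings.warn("posterior covariance singular; ridge-stabilized",
                          stacklevel=2)
            L = np.linalg.cholesky(Vb + 1e-8 * np.eye(len(Vb))
                                   * max(np.trace(Vb), 1.0))
        draws = model.beta[None, :] + rng.standard_normal(
            (n_draws, len(model.beta))) @ L.T
        eta = X @ draws.T                      # (cells, draws)
        d = np.exp(np.clip(eta, -30, 30))
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        cv_gam = np.where(mean > 0, sd / mean, np.nan)
    out[usable] = np.sqrt(cv_gam ** 2 + detection_cv ** 2)
    return out


# ---------------------------------------------------------------------------
# Coverage-normalised fallback for sparse species
# ---------------------------------------------------------------------------

def assign_cells(segments: pd.DataFrame, grid: pd.DataFrame) -> np.ndarray:
    """Nearest-centroid cell_id for each segment midpoint."""
    gx = grid["x"].to_numpy(dtype=float)
    gy = grid["y"].to_numpy(dtype=float)
    ids = grid["cell_id"].to_numpy()
    tree = spatial.cKDTree(np.column_stack([gx, gy]))
    _, idx = tree.query(segments[["x", "y"]].to_numpy(dtype=float))
    return ids[idx]


def relative_density_fallback(segments: pd.DataFrame, grid: pd.DataFrame,
                              response: str = "n_hat",
                              species: str = "", behaviour: str = "",
                              season: str = "", platform: str = "",
                              cv: np.ndarray | None = None) -> DensitySurface:
    """Relative density with no spatial modelling.

    Per cell: Σ detection-corrected counts of the segments whose midpoints
    fall in the cell, divided by Σ covered area there.  Cells with zero
    effort are missing, not zero.
    """
    seg = segments.copy()
    seg["_cell"] = assign_cells(seg, grid)
    agg = seg.groupby("_cell").agg(
        nhat=(response, "sum"), area=("covered_area_km2", "sum"))
    g = grid.reset_index(drop=True)
    dens = np.full(len(g), np.nan)
    pos = g["cell_id"].map(agg["nhat"] / agg["area"])
    dens = pos.to_numpy(dtype=float)
    dens = np.where(g["is_sea"].to_numpy(dtype=bool), dens, np.nan)
    table = pd.DataFrame({
        "cell_id": g["cell_id"], "density": dens,
        "cv": cv if cv is not None else np.full(len(g), np.nan),
        "abundance": dens * g["area_km2"].to_numpy(dtype=float),
        "extrapolated": ~np.isfinite(dens),
    })
    return DensitySurface(species=species, behaviour=behaviour, season=season,
                          platform=platform, table=table)


def write_surface_csv(surface: DensitySurface, path) -> None:
    surface.table.to_csv(path, index=False)
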