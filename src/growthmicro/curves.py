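"""Smooth growth curves from sparse visits: pooled FPCA, splines, registration.

Individual growth-index curves are reconstructed from sparse longitudinal
visits by pooling information across children: the mean function and the
covariance surface are estimated by local-linear kernel smoothing of the
pooled observations (and pooled off-diagonal raw covariance products), the
eigenfunctions/eigenvalues come from the discretized covariance operator,
and per-child scores are best linear unbiased predictors (conditional
expectations given that child's own sparse observations).  Reconstructed
curves are expressed in a rich cubic B-spline basis (102 functions with
evenly spaced knots by default) and can be temporally aligned by monotone
time warping toward the cross-sectional mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import BSpline, CubicSpline
from scipy.optimize import minimize

from .anthro import AnthroRecord, growth_index
from .errors import InvalidArgumentError
from .fosr import trapezoid_weights

DOMAIN = (0.0, 730.0)
DEFAULT_N_BASIS = 102


# --------------------------------------------------------------------------
# local-linear smoothing helpers (Gaussian kernel, data pre-binned)
# --------------------------------------------------------------------------

def _loclin_1d(xb, yb, nb, xout, bw):
    """Weighted local-linear fit of binned data; returns estimates at xout.

    Uses the centred form (local slope around the weighted mean abscissa) so
    evaluation points far from the data stay numerically stable.
    """
    dx = xout[:, None] - xb[None, :]
    k = np.exp(-0.5 * (dx / bw) ** 2) * nb[None, :]
    s0 = np.maximum(k.sum(axis=1), 1e-300)
    mx = (k * dx).sum(axis=1) / s0
    ybar = (k * yb[None, :]).sum(axis=1) / s0
    dxc = dx - mx[:, None]
    varx = (k * dxc ** 2).sum(axis=1)
    cov = (k * dxc * (yb[None, :] - ybar[:, None])).sum(axis=1)
    slope = cov / np.maximum(varx, 1e-10 * bw ** 2 * s0 + 1e-300)
    return ybar - slope * mx


def _loclin_1d_gcv(xb, yb, nb, candidates):
    best_bw, best_gcv = candidates[0], np.inf
    B = xb.size
    for bw in candidates:
        yhat = _loclin_1d(xb, yb, nb, xb, bw)
        # equivalent-kernel self-weight at each bin (local-constant bound)
        k0 = nb / np.maximum(
            (np.exp(-0.5 * ((xb[:, None] - xb[None, :]) / bw) ** 2)
             * nb[None, :]).sum(axis=1), 1e-300)
        trace = float(k0.sum())
        denom = 1.0 - trace / B
        if denom <= 0.05:
            continue
        gcv = float((nb * (yb - yhat) ** 2).sum() / nb.sum()) / denom ** 2
        if gcv < best_gcv:
            best_gcv, best_bw = gcv, bw
    return best_bw


def _loclin_2d(pts, vals, nb, out_pts, bw):
    """Local plane fit of binned surface data at out_pts (centred form)."""
    dx = out_pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = out_pts[:, 1][:, None] - pts[:, 1][None, :]
    k = np.exp(-0.5 * ((dx / bw) ** 2 + (dy / bw) ** 2)) * nb[None, :]
    s0 = np.maximum(k.sum(axis=1), 1e-300)
    mx = (k * dx).sum(axis=1) / s0
    my = (k * dy).sum(axis=1) / s0
    vbar = (k * vals).sum(axis=1) / s0
    dxc = dx - mx[:, None]
    dyc = dy - my[:, None]
    vc = vals[None, :] - vbar[:, None]
    sxx = (k * dxc ** 2).sum(axis=1)
    syy = (k * dyc ** 2).sum(axis=1)
    sxy = (k * dxc * dyc).sum(axis=1)
    svx = (k * dxc * vc).sum(axis=1)
    svy = (k * dyc * vc).sum(axis=1)
    ridge = 1e-10 * bw ** 2 * s0 + 1e-300
    det = np.maximum((sxx + ridge) * (syy + ridge) - sxy ** 2, ridge ** 2)
    bx = ((syy + ridge) * svx - sxy * svy) / det
    by = ((sxx + ridge) * svy - sxy * svx) / det
    return vbar - bx * mx - by * my


def _loclin_2d_gcv(pts, vals, nb, candidates):
    best_bw, best_gcv = candidates[0], np.inf
    B = pts.shape[0]
    for bw in candidates:
        fitted = _loclin_2d(pts, vals, nb, pts, bw)
        # approximate trace via equivalent-kernel self-weights
        dx = pts[:, 0][:, None] - pts[:, 0][None, :]
        dy = pts[:, 1][:, None] - pts[:, 1][None, :]
        k = np.exp(-0.5 * ((dx / bw) ** 2 + (dy / bw) ** 2)) * nb[None, :]
        trace = float((nb / np.maximum(k.sum(axis=1), 1e-300)).sum())
        denom = 1.0 - trace / B
        if denom <= 0.05:
            continue
        gcv = float((nb * (vals - fitted) ** 2).sum() / nb.sum()) / denom ** 2
        if gcv < best_gcv:
            best_gcv, best_bw = gcv, bw
    return best_bw


# --------------------------------------------------------------------------
# FPCA
# --------------------------------------------------------------------------

@dataclass
class FPCAModel:
    """Mean, eigenstructure and per-child scores of the growth-index process."""

    grid: np.ndarray           # dense age grid
    mu: np.ndarray             # mean function on grid
    phi: np.ndarray            # (K, T) orthonormal eigenfunctions
    lam: np.ndarray            # (K,) eigenvalues, nonincreasing
    sigma2: float              # measurement-noise variance
    scores: np.ndarray         # (n, K) conditional-expectation scores
    child_ids: list[str]
    fve: float
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return int(self.lam.size)

    def curves(self) -> np.ndarray:
        """Reconstructed curves mu + sum_k xi_ik phi_k, (n, T)."""
        if self.n_components == 0:
            return np.tile(self.mu, (len(self.child_ids), 1))
        return self.mu[None, :] + self.scores @ self.phi


def index_observations(records: list[AnthroRecord]):
    """(ages, growth-index values, child_id) triples from anthropometry records."""
    out = []
    for rec in records:
        gi = growth_index(rec)
        out.append((gi["age_days"].to_numpy(dtype=float),
                    gi["index"].to_numpy(dtype=float), rec.child_id))
    return out


def _as_observations(data):
    obs = []
    for item in data:
        if isinstance(item, AnthroRecord):
            gi = growth_index(item)
            obs.append((gi["age_days"].to_numpy(dtype=float),
                        gi["index"].to_numpy(dtype=float), item.child_id))
        elif len(item) == 3:
            t, y, cid = item
            obs.append((np.asarray(t, dtype=float), np.asarray(y, dtype=float), str(cid)))
        else:
            t, y = item
            obs.append((np.asarray(t, dtype=float), np.asarray(y, dtype=float),
                        f"c{len(obs):04d}"))
    return obs


def fit_fpca(records, fve_threshold: float = 0.99, grid: np.ndarray | None = None,
             n_workgrid: int = 51, bandwidth_mean: float | None = None,
             bandwidth_cov: float | None = None,
             bandwidth_floor: float | None = None) -> FPCAModel:
    """Pooled sparse FPCA of growth-index observations.

    ``records`` is a list of AnthroRecords or of ``(ages, values[, id])``
    tuples.  Smoothing bandwidths default to generalized cross-validation
    over a geometric candidate grid with a floor keyed to the largest design
    gap (so the smoother can bridge sparse visit schedules).
    """
    obs = _as_observations(records)
    if len(obs) < 20:
        raise InvalidArgumentError(f"need at least 20 children, got {len(obs)}")
    if not any(t.size >= 2 for t, _, _ in obs):
        raise InvalidArgumentError(
            "cannot form a covariance: no child has two or more observations"
        )
    t_all = np.concatenate([t for t, _, _ in obs])
    y_all = np.concatenate([y for _, y, _ in obs])
    lo, hi = float(t_all.min()), float(t_all.max())
    if grid is None:
        grid = np.linspace(DOMAIN[0], DOMAIN[1], 731)
        lo, hi = DOMAIN
    grid = np.asarray(grid, dtype=float)
    span = hi - lo

    work = np.linspace(lo, hi, n_workgrid)

    # ---- mean function ---------------------------------------------------
    # bin positions use the within-bin mean age (not the bin centre) so the
    # binned smoother stays exact for linear trends
    bins = np.clip(np.rint((t_all - lo) / span * (n_workgrid - 1)).astype(int),
                   0, n_workgrid - 1)
    nb = np.bincount(bins, minlength=n_workgrid).astype(float)
    ysum = np.bincount(bins, weights=y_all, minlength=n_workgrid)
    tsum = np.bincount(bins, weights=t_all, minlength=n_workgrid)
    occ = nb > 0
    xb, yb, wb = tsum[occ] / nb[occ], ysum[occ] / nb[occ], nb[occ]
    floor = bandwidth_floor if bandwidth_floor is not None else span / 30.0
    candidates = np.geomspace(floor, span / 3.0, 6)
    bw_mu = bandwidth_mean if bandwidth_mean is not None else _loclin_1d_gcv(
        xb, yb, wb, candidates)
    mu_grid = _loclin_1d(xb, yb, wb, grid, bw_mu)
    mu_work = _loclin_1d(xb, yb, wb, work, bw_mu)

    # ---- raw covariance products, binned --------------------------------
    cov_sum = np.zeros((n_workgrid, n_workgrid))
    cov_cnt = np.zeros((n_workgrid, n_workgrid))
    cov_s = np.zeros((n_workgrid, n_workgrid))
    cov_t = np.zeros((n_workgrid, n_workgrid))
    diag_sum = np.zeros(n_workgrid)
    diag_cnt = np.zeros(n_workgrid)
    for t, y, _ in obs:
        b = np.clip(np.rint((t - lo) / span * (n_workgrid - 1)).astype(int),
                    0, n_workgrid - 1)
        r = y - np.interp(t, grid, mu_grid)
        np.add.at(diag_sum, b, r * r)
        np.add.at(diag_cnt, b, 1.0)
        if t.size < 2:
            continue
        prod = np.outer(r, r)
        mask = ~np.eye(t.size, dtype=bool).ravel()
        bi = np.repeat(b, t.size)[mask]
        bj = np.tile(b, t.size)[mask]
        np.add.at(cov_sum, (bi, bj), prod.ravel()[mask])
        np.add.at(cov_cnt, (bi, bj), 1.0)
        np.add.at(cov_s, (bi, bj), np.repeat(t, t.size)[mask])
        np.add.at(cov_t, (bi, bj), np.tile(t, t.size)[mask])

    occ2 = cov_cnt > 0
    pts = np.column_stack([cov_s[occ2] / cov_cnt[occ2],
                           cov_t[occ2] / cov_cnt[occ2]])
    vals = cov_sum[occ2] / cov_cnt[occ2]
    wts = cov_cnt[occ2]
    # the surface smoother must bridge the largest gap in the visit design
    # (sparse schedules leave long unobserved stretches), so its bandwidth
    # floor is keyed to that gap
    gap = float(np.diff(np.sort(np.unique(xb))).max(initial=span / n_workgrid))
    cov_candidates = np.geomspace(max(0.5 * gap, floor), span / 3.0, 6)
    bw_cov = bandwidth_cov if bandwidth_cov is not None else _loclin_2d_gcv(
        pts, vals, wts, cov_candidates)
    mesh = np.column_stack([np.repeat(work, n_workgrid), np.tile(work, n_workgrid)])
    G = _loclin_2d(pts, vals, wts, mesh, bw_cov).reshape(n_workgrid, n_workgrid)
    G = (G + G.T) / 2.0

    # ---- noise variance: smoothed diagonal minus surface diagonal --------
    occd = diag_cnt > 0
    vdiag = _loclin_1d(work[occd], diag_sum[occd] / diag_cnt[occd],
                       diag_cnt[occd], work, bw_mu)
    central = slice(n_workgrid // 4, 3 * n_workgrid // 4 + 1)
    sigma2 = float(max(0.0, np.mean(vdiag[central] - np.diag(G)[central])))

    # ---- eigendecomposition on the working grid --------------------------
    w_work = trapezoid_weights(work)
    sw = np.sqrt(w_work)
    lam_all, vec_all = np.linalg.eigh(sw[:, None] * G * sw[None, :])
    order = np.argsort(lam_all)[::-1]
    lam_all, vec_all = lam_all[order], vec_all[:, order]
    total = float(np.clip(lam_all, 0.0, None).sum())
    keep = lam_all > max(1e-12, 1e-10 * total)
    lam_pos = lam_all[keep]
    if lam_pos.size == 0 or total <= 0.0:
        K = 0
    else:
        frac = np.cumsum(lam_pos) / lam_pos.sum()
        K = int(np.searchsorted(frac, fve_threshold) + 1)
    lam = lam_pos[:K]
    fve = float(lam.sum() / lam_pos.sum()) if K > 0 else 1.0

    child_ids = [cid for _, _, cid in obs]
    n = len(obs)
    if K == 0:
        phi_dense = np.zeros((0, grid.size))
        scores = np.zeros((n, 0))
    else:
        phi_work = (vec_all[:, keep][:, :K] / sw[:, None]).T  # (K, n_workgrid)
        phi_dense = np.vstack([CubicSpline(work, phi_work[k])(grid)
                               for k in range(K)])
        # re-orthonormalize on the dense grid quadrature
        u = (grid - grid[0]) / (grid[-1] - grid[0]) if grid.size > 1 else grid
        w_dense = trapezoid_weights(grid)
        gram = phi_dense @ (w_dense[:, None] * phi_dense.T)
        L = np.linalg.cholesky(gram)
        phi_dense = np.linalg.solve(L, phi_dense)
        # sign convention: positive integral (or positive max) per component
        for k in range(K):
            if phi_dense[k] @ w_dense < 0:
                phi_dense[k] = -phi_dense[k]
        scores = np.zeros((n, K))
        Lam = np.diag(lam)
        for i, (t, y, _) in enumerate(obs):
            Phi_i = np.vstack([np.interp(t, grid, phi_dense[k]) for k in range(K)]).T
            r = y - np.interp(t, grid, mu_grid)
            prior = Phi_i @ Lam @ Phi_i.T
            # ridge keeps the solve well-conditioned when sigma2 ~ 0 and the
            # prior covariance at the child's ages is rank deficient
            jitter = max(sigma2, 1e-4 * max(np.mean(np.diag(prior)), 0.0),
                         1e-14)
            Ci = prior + jitter * np.eye(t.size)
            scores[i] = Lam @ Phi_i.T @ np.linalg.solve(Ci, r)

    return FPCAModel(
        grid=grid, mu=mu_grid, phi=phi_dense, lam=lam, sigma2=sigma2,
        scores=scores, child_ids=child_ids, fve=fve,
        meta={"bandwidth_mean": float(bw_mu), "bandwidth_cov": float(bw_cov),
              "n_workgrid": n_workgrid, "fve_threshold": fve_threshold,
              "mu_work_range": [float(mu_work.min()), float(mu_work.max())]},
    )


# --------------------------------------------------------------------------
# B-spline curve sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BSplineBasis:
    """Cubic B-spline basis with evenly spaced knots on a fixed domain."""

    domain: tuple[float, float] = DOMAIN
    degree: int = 3
    n_basis: int = DEFAULT_N_BASIS

    @property
    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        inner = np.linspace(lo, hi, self.n_basis - self.degree + 1)
        return np.concatenate([[lo] * self.degree, inner, [hi] * self.degree])

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.domain[0], self.domain[1])
        # nudge the right endpoint inside the half-open support
        hi = self.domain[1]
        x = np.where(x >= hi, hi - 1e-9 * (hi - self.domain[0]), x)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def to_dict(self) -> dict:
        return {"domain": list(self.domain), "degree": self.degree,
                "n_basis": self.n_basis, "knots": self.knots.tolist()}


@dataclass
class CurveSet:
    """Children x basis coefficient matrix plus optional warping functions."""

    child_ids: list[str]
    basis: BSplineBasis
    coef: np.ndarray                      # (n, n_basis)
    warps: np.ndarray | None = None       # (n, G) warp values h_i on warp_grid
    warp_grid: np.ndarray | None = None
    default_grid_size: int = 731

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return self.coef @ self.basis.design(np.asarray(grid, dtype=float)).T

    def default_grid(self) -> np.ndarray:
        return np.linspace(self.basis.domain[0], self.basis.domain[1],
                           self.default_grid_size)

    def write(self, csv_path, json_path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.coef, index=pd.Index(self.child_ids, name="child_id"),
                             columns=[f"b{j:03d}" for j in range(self.coef.shape[1])])
        frame.to_csv(csv_path)
        with open(json_path, "w") as fh:
            json.dump(self.basis.to_dict(), fh, indent=1)

    @classmethod
    def read(cls, csv_path, json_path) -> "CurveSet":
        import pandas as pd

        frame = pd.read_csv(csv_path, index_col=0)
        with open(json_path) as fh:
            spec = json.load(fh)
        basis = BSplineBasis(domain=tuple(spec["domain"]), degree=spec["degree"],
                             n_basis=spec["n_basis"])
        return cls(child_ids=[str(i) for i in frame.index], basis=basis,
                   coef=frame.to_numpy(dtype=float))


def predict_curves(model: FPCAModel, n_basis: int = DEFAULT_N_BASIS) -> CurveSet:
    """Project reconstructed curves onto the rich cubic B-spline basis."""
    basis = BSplineBasis(domain=(float(model.grid[0]), float(model.grid[-1])),
                         n_basis=n_basis)
    design = basis.design(model.grid)
    curves = model.curves()
    coef, *_ = np.linalg.lstsq(design, curves.T, rcond=None)
    return CurveSet(child_ids=list(model.child_ids), basis=basis, coef=coef.T,
                    default_grid_size=model.grid.size)


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def _warp_basis(u: np.ndarray, n_interior: int = 5, degree: int = 3) -> np.ndarray:
    inner = np.linspace(0.0, 1.0, n_interior + 2)
    knots = np.concatenate([[0.0] * degree, inner, [1.0] * degree])
    uu = np.where(u >= 1.0, 1.0 - 1e-9, u)
    return BSpline.design_matrix(uu, knots, degree).toarray()


def register_curves(curves: CurveSet, max_iter: int = 3, grid_size: int = 201,
                    penalty: float = 1e-3) -> CurveSet:
    """Continuous registration to the cross-sectional mean.

    Each warp ``h_i`` is strictly increasing and endpoint-fixed, built as the
    normalized integral of the exponential of a spline, and fitted by
    minimizing the squared distance between ``curve_i o h_i`` and the current
    mean (plus a small ridge on the warp coefficients that makes the identity
    warp the exact optimum for already-aligned curves).  The mean and the
    warps are alternately updated at most ``max_iter`` times.
    """
    lo, hi = curves.basis.domain
    grid = np.linspace(lo, hi, grid_size)
    u = (grid - lo) / (hi - lo)
    Y = curves.evaluate(grid)
    if not np.all(np.isfinite(Y)):
        raise InvalidArgumentError("curves contain non-finite values")
    n = Y.shape[0]
    Bw = _warp_basis(u)
    npar = Bw.shape[1]
    scale = float(np.var(Y)) + 1e-12

    def warp_from(a):
        s = np.clip(Bw @ a, -20.0, 20.0)
        e = np.exp(s)
        H = cumulative_trapezoid(e, u, initial=0.0)
        return lo + (hi - lo) * H / H[-1]

    params = np.zeros((n, npar))
    template = Y.mean(axis=0)
    aligned = Y.copy()
    for _ in range(max_iter):
        for i in range(n):
            fi = CubicSpline(grid, Y[i])

            def loss(a, fi=fi):
                h = warp_from(a)
                return (float(np.mean((fi(h) - template) ** 2)) / scale
                        + penalty * float(np.mean(a ** 2)))

            res = minimize(loss, params[i], method="L-BFGS-B",
                           options={"maxiter": 60})
            params[i] = res.x
            aligned[i] = CubicSpline(grid, Y[i])(warp_from(params[i]))
        new_template = aligned.mean(axis=0)
        if np.max(np.abs(new_template - template)) < 1e-10:
            break
        template = new_template

    warps = np.vstack([warp_from(params[i]) for i in range(n)])
    design = curves.basis.design(grid)
    coef, *_ = np.linalg.lstsq(design, aligned.T, rcond=None)
    return CurveSet(child_ids=list(curves.child_ids), basis=curves.basis,
                    coef=coef.T, warps=warps, warp_grid=grid,
                    default_grid_size=curves.default_grid_size)
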