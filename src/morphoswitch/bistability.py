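"""Equilibria, saddle-node continuation and hysteresis protocols.

Locates fixed points of the circuit ODEs by damped-Newton refinement from
log-spaced multi-starts, follows equilibrium branches with pseudo-arclength
continuation to find fold (saddle-node) points, maps the bistable region in
(C6, C12) space, and reproduces the conditioning/exposure hysteresis
protocol in silico.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .circuit_model import (
    ParamSet,
    SignalEnvironment,
    integrate_many,
    rates_vec,
    single_pathway_steady_state,
)

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "BistabilityMap",
    "HysteresisGrid",
    "GridSpec",
    "find_equilibria",
    "continue_branch",
    "map_bistable_region",
    "hysteresis_protocol",
]


@dataclass
class Equilibrium:
    state: np.ndarray               # shape (6,)
    stability: str                  # {"stable", "saddle", "unstable"}
    env: SignalEnvironment
    eigenvalues: np.ndarray | None = None

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class EquilibriumBranch:
    param_name: str
    param_values: np.ndarray
    equilibria: list[Equilibrium]
    fold_points: list[float]
    fold_states: list[np.ndarray] = field(default_factory=list)
    terminated: str = "range"       # "range" | "step_collapse" | "max_steps"


@dataclass
class GridSpec:
    """Log-spaced grid over (C6, C12) concentrations."""

    c6_min: float = 1.0
    c6_max: float = 1000.0
    n_c6: int = 12
    c12_min: float = 1.0
    c12_max: float = 10000.0
    n_c12: int = 12

    def __post_init__(self) -> None:
        if min(self.c6_min, self.c12_min) <= 0:
            raise ValueError("log-spaced grids need positive minima")
        if self.c6_max <= self.c6_min or self.c12_max <= self.c12_min:
            raise ValueError("grid maxima must exceed minima")
        if min(self.n_c6, self.n_c12) < 8:
            raise ValueError("need >= 8 points per axis")

    @property
    def c6_values(self) -> np.ndarray:
        return np.geomspace(self.c6_min, self.c6_max, self.n_c6)

    @property
    def c12_values(self) -> np.ndarray:
        return np.geomspace(self.c12_min, self.c12_max, self.n_c12)


@dataclass
class BistabilityMap:
    grid: GridSpec
    counts: np.ndarray              # shape (n_c6, n_c12), stable-equilibrium counts
    boundary: list[np.ndarray] = field(default_factory=list)  # polylines in log10 nM
    iptg: float = 0.0
    atc: float = 0.0

    def is_bistable(self, c6: float, c12: float) -> bool:
        """Count >= 2 in the grid cell nearest to (c6, c12)."""
        i = int(np.argmin(np.abs(np.log10(self.grid.c6_values) - np.log10(c6))))
        j = int(np.argmin(np.abs(np.log10(self.grid.c12_values) - np.log10(c12))))
        return bool(self.counts[i, j] >= 2)

    def to_dataframe(self):
        import pandas as pd

        c6g, c12g = np.meshgrid(self.grid.c6_values, self.grid.c12_values, indexing="ij")
        return pd.DataFrame(
            {"c6": c6g.ravel(), "c12": c12g.ravel(), "n_stable": self.counts.ravel()}
        )


@dataclass
class HysteresisGrid:
    grid: GridSpec
    conditioning: str               # "C6" | "C12"
    readout: np.ndarray             # (cfp - yfp)/(cfp + yfp + eps), shape (n_c6, n_c12)
    iptg: float = 0.0
    atc: float = 0.0

    def to_dataframe(self):
        import pandas as pd

        c6g, c12g = np.meshgrid(self.grid.c6_values, self.grid.c12_values, indexing="ij")
        return pd.DataFrame(
            {"c6": c6g.ravel(), "c12": c12g.ravel(), "readout": self.readout.ravel()}
        )


# ---------------------------------------------------------------------------
# equilibrium finding
# ---------------------------------------------------------------------------


def _jacobian(y: np.ndarray, env: SignalEnvironment, params: ParamSet,
              rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the rate function.

    All 2n perturbed evaluations are batched through one vectorised call.
    """
    n = y.size
    h = rel_step * np.maximum(np.abs(y), 1.0)
    Y = np.repeat(y[:, None], 2 * n, axis=1)
    for k in range(n):
        Y[k, k] = y[k] + h[k]
        Y[k, n + k] = max(y[k] - h[k], 0.0)
    F = rates_vec(Y, env.c6, env.c12, env.iptg, env.atc, params)
    denom = Y[np.arange(n), np.arange(n)] - Y[np.arange(n), n + np.arange(n)]
    return (F[:, :n] - F[:, n:]) / denom[None, :]


def _newton(y0: np.ndarray, env: SignalEnvironment, params: ParamSet,
            tol: float, max_iter: int = 80) -> np.ndarray | None:
    """Damped Newton iteration on the rate function; None if not converged."""
    out = _newton_batch(np.asarray(y0, float)[:, None], env, params, tol, max_iter)
    return out[0] if out else None


def _newton_batch(Y0: np.ndarray, env: SignalEnvironment, params: ParamSet,
                  tol: float, max_iter: int = 60) -> list[np.ndarray]:
    """Damped Newton from many starts at once; returns the converged roots.

    ``Y0`` has shape (6, m).  Residuals, finite-difference Jacobians and the
    linear solves are batched across all active starts per iteration.
    """
    def f_of(Y):
        return rates_vec(Y, env.c6, env.c12, env.iptg, env.atc, params)

    Y = np.maximum(np.asarray(Y0, float), 0.0)
    m = Y.shape[1]
    active = np.ones(m, dtype=bool)
    F = f_of(Y)
    roots: list[np.ndarray] = []
    eye = np.arange(6)
    for _ in range(max_iter):
        nf = np.linalg.norm(F, axis=0)
        newly = active & (nf < tol)
        for j in np.flatnonzero(newly):
            roots.append(Y[:, j].copy())
        active &= ~newly
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ya = Y[:, idx]
        # batched central-difference Jacobians: (6, m_a * 12) in one call
        h = 1e-6 * np.maximum(np.abs(Ya), 1.0)
        P = np.repeat(Ya[:, :, None], 12, axis=2)
        for k in range(6):
            P[k, :, k] = Ya[k] + h[k]
            P[k, :, 6 + k] = np.maximum(Ya[k] - h[k], 0.0)
        Fp = f_of(P.reshape(6, -1)).reshape(6, idx.size, 12)
        denom = P[eye, :, eye] - P[eye, :, 6 + eye]      # (6, m_a): per-species step
        J = (Fp[:, :, :6] - Fp[:, :, 6:]) / denom.T[None, :, :]
        J = np.transpose(J, (1, 0, 2))                   # (m_a, 6, 6)
        try:
            steps = np.linalg.solve(J, -F[:, idx].T[..., None])[..., 0]  # (m_a, 6)
        except np.linalg.LinAlgError:
            steps = np.full((idx.size, 6), np.nan)
            for j in range(idx.size):
                try:
                    steps[j] = np.linalg.solve(J[j], -F[:, idx[j]])
                except np.linalg.LinAlgError:
                    pass
        bad = ~np.all(np.isfinite(steps), axis=1)
        # vectorised backtracking: halve the step until the residual shrinks
        lam = np.ones(idx.size)
        nfa = nf[idx]
        done = np.zeros(idx.size, dtype=bool)
        Ynew, Fnew = Ya.copy(), F[:, idx].copy()
        for _ls in range(12):
            trial = np.maximum(Ya + (lam * steps.T), 0.0)
            Ftr = f_of(trial)
            ok = (np.linalg.norm(Ftr, axis=0) < nfa * (1 - 1e-4 * lam)) | \
                 (np.linalg.norm(Ftr, axis=0) < tol)
            take = ok & ~done & ~bad
            Ynew[:, take] = trial[:, take]
            Fnew[:, take] = Ftr[:, take]
            done |= ok
            if np.all(done | bad):
                break
            lam = np.where(done, lam, lam * 0.5)
        # starts whose line search failed are abandoned
        fail = idx[bad | ~done]
        active[fail] = False
        keep = idx[~(bad | ~done)]
        sel = ~(bad | ~done)
        Y[:, keep] = Ynew[:, sel]
        F[:, keep] = Fnew[:, sel]
    return roots


def _classify(y: np.ndarray, env: SignalEnvironment, params: ParamSet,
              eig_tol: float = 1e-7) -> tuple[str, np.ndarray]:
    eig = np.linalg.eigvals(_jacobian(y, env, params))
    re = eig.real
    if np.max(re) < eig_tol:
        return "stable", eig
    if np.min(re) < -eig_tol:
        return "saddle", eig
    return "unstable", eig


def _slaved_state(laci: float, tetr: float, env: SignalEnvironment, params: ParamSet) -> np.ndarray:
    """Full state with receptors and fluorophores at quasi-steady values."""
    p = params
    from .circuit_model import effective_repressor, hill_act, hill_rep

    if p.circuit_variant == "receiver":
        luxr = lasr = (p.b_r + p.a_r) / p.g_r
    else:
        laci_eff = effective_repressor(laci, env.iptg, p.K_iptg, p.n_iptg)
        tetr_eff = effective_repressor(tetr, env.atc, p.K_atc, p.n_atc)
        luxr = (p.b_r + p.a_r * hill_rep(tetr_eff, p.K_tet, p.n_tet)) / p.g_r
        lasr = (p.b_r + p.a_r * hill_rep(laci_eff, p.K_lac, p.n_lac)) / p.g_r
    h6 = hill_act(env.c6, p.K6, p.n6) + p.cross_lux_c12 * hill_act(env.c12, p.K12, p.n12)
    h12 = hill_act(env.c12, p.K12, p.n12) + p.cross_las_c6 * hill_act(env.c6, p.K6, p.n6)
    cfp = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_cfp
    yfp = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_yfp
    return np.array([luxr, lasr, laci, tetr, cfp, yfp])


def find_equilibria(
    env: SignalEnvironment,
    params: ParamSet,
    n_starts: int = 12,
    tol: float = 1e-9,
    seed: int = 0,
) -> list[Equilibrium]:
    """All fixed points at the given environment, classified by stability.

    Newton refinement from log-spaced (LacI, TetR) starts (other species at
    quasi-steady values) plus the two single-pathway analytic candidate
    states.  Deduplicated at relative state distance 1e-4.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be >= 8")
    p = params
    s_max = (p.b_f + p.a_f) / min(p.g_laci, p.g_tetr)
    rng = np.random.default_rng(seed)
    side = max(3, int(np.ceil(np.sqrt(n_starts))))
    vals = np.geomspace(1e-3 * s_max, 1.5 * s_max, side)
    starts = [
        _slaved_state(u, v, env, params) for u in vals for v in vals
    ]
    # tiny seeded jitter keeps degenerate grids from all collapsing identically
    starts = [s * (1 + 1e-9 * rng.standard_normal(6)) for s in starts]
    starts.append(single_pathway_steady_state(env, params, "c6"))
    starts.append(single_pathway_steady_state(env, params, "c12"))

    roots = _newton_batch(np.stack(starts, axis=1), env, params, tol * max(1.0, p.a_f))
    found: list[np.ndarray] = []
    for y in roots:
        if any(np.linalg.norm(y - f) < 1e-4 * (1 + np.linalg.norm(f)) for f in found):
            continue
        found.append(y)
    if not found:
        warnings.warn("no equilibrium search converged; returning empty list")
        return []
    found.sort(key=lambda y: y[2] - y[3])  # LacI-low (YFP) first, stable order
    out = []
    for y in found:
        stab, eig = _classify(y, env, params)
        out.append(Equilibrium(state=y, stability=stab, env=env, eigenvalues=eig))
    return out


def count_stable(env: SignalEnvironment, params: ParamSet, **kw) -> int:
    return sum(e.is_stable for e in find_equilibria(env, params, **kw))


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------


def _env_with(env: SignalEnvironment, free: str, value: float) -> SignalEnvironment:
    return env.replace(**{free: float(value)})


class _AugmentedSystem:
    """Equilibrium system augmented with log10 of one signal as an unknown.

    Works in scaled coordinates w = (y / s_scale, log10 p) so that arclength
    steps weight state and parameter comparably.
    """

    def __init__(self, env0: SignalEnvironment, free: str, params: ParamSet):
        self.env0 = env0
        self.free = free
        self.p = params
        self.s_scale = max((params.b_f + params.a_f)
                           / min(params.g_laci, params.g_tetr), 1.0)

    def env_at(self, lp: float) -> SignalEnvironment:
        return _env_with(self.env0, self.free, 10.0 ** lp)

    def residual(self, w: np.ndarray) -> np.ndarray:
        y = np.maximum(w[:6] * self.s_scale, 0.0)
        e = self.env_at(w[6])
        return rates_vec(y, e.c6, e.c12, e.iptg, e.atc, self.p)

    def jac(self, w: np.ndarray) -> np.ndarray:
        """d residual / d w, shape (6, 7)."""
        y = np.maximum(w[:6] * self.s_scale, 0.0)
        e = self.env_at(w[6])
        J = np.empty((6, 7))
        J[:, :6] = _jacobian(y, e, self.p) * self.s_scale
        h = 1e-6
        ep, em = self.env_at(w[6] + h), self.env_at(w[6] - h)
        fp = rates_vec(y, ep.c6, ep.c12, ep.iptg, ep.atc, self.p)
        fm = rates_vec(y, em.c6, em.c12, em.iptg, em.atc, self.p)
        J[:, 6] = (fp - fm) / (2 * h)
        return J

    def correct(self, w_pred: np.ndarray, tangent: np.ndarray,
                tol: float = 1e-10, max_iter: int = 25) -> np.ndarray | None:
        """Newton on (residual, tangent . (w - w_pred)) = 0."""
        w = w_pred.copy()
        for _ in range(max_iter):
            f = self.residual(w)
            g = float(tangent @ (w - w_pred))
            if np.linalg.norm(f) < tol * max(1.0, self.p.a_f) * self.s_scale and abs(g) < 1e-10:
                return w
            A = np.vstack([self.jac(w), tangent])
            try:
                dw = np.linalg.solve(A, -np.concatenate([f, [g]]))
            except np.linalg.LinAlgError:
                return None
            w = w + dw
            w[:6] = np.maximum(w[:6], 0.0)
            if not np.all(np.isfinite(w)):
                return None
        return None


def continue_branch(
    env0: SignalEnvironment,
    free: str,
    prange: tuple[float, float],
    params: ParamSet,
    ds0: float = 0.05,
    ds_min: float = 1e-7,
    ds_max: float = 0.2,
    max_steps: int = 3000,
    start_state: np.ndarray | None = None,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch in one signal.

    ``free`` is ``"c6"`` or ``"c12"``.  The branch starts from an equilibrium
    at ``prange[0]`` (a stable one unless ``start_state`` is given) and is
    followed with a secant predictor / Newton corrector until it exits the
    range, the step collapses, or ``max_steps`` is reached.  Fold points are
    detected by a sign change of the tangent's parameter component and
    refined by arclength bisection to 1e-4 relative tolerance in the
    parameter.
    """
    if free not in ("c6", "c12"):
        raise ValueError("free parameter must be 'c6' or 'c12'")
    p_lo, p_hi = prange
    if not (0 < p_lo < p_hi):
        raise ValueError("range must be positive and increasing")
    sys = _AugmentedSystem(env0, free, params)

    env_start = sys.env_at(np.log10(p_lo))
    if start_state is None:
        eqs = find_equilibria(env_start, params)
        if not eqs:
            raise ValueError("no equilibrium found at the start of the range")
        stable = [e for e in eqs if e.is_stable]
        y = (stable[0] if stable else eqs[0]).state.copy()
    else:
        y = np.asarray(start_state, float).copy()

    lp_lo, lp_hi = np.log10(p_lo), np.log10(p_hi)
    w = np.concatenate([y / sys.s_scale, [lp_lo]])

    eqs_list: list[Equilibrium] = []
    branch_p: list[float] = []

    def record(w_):
        e = sys.env_at(w_[6])
        y_ = np.maximum(w_[:6] * sys.s_scale, 0.0)
        stab, eig = _classify(y_, e, params)
        eqs_list.append(Equilibrium(y_, stab, e, eig))
        branch_p.append(float(10.0 ** w_[6]))

    record(w)
    tangent = np.zeros(7)
    tangent[6] = 1.0  # initial direction: increasing parameter
    ds = ds0
    folds: list[float] = []
    terminated = "max_steps"

    for _ in range(max_steps):
        w_new = sys.correct(w + ds * tangent, tangent)
        if w_new is None or np.linalg.norm(w_new - w) > 10 * ds + 1e-9:
            ds *= 0.5
            if ds < ds_min:
                terminated = "step_collapse"
                warnings.warn(
                    f"continuation step collapsed at {free}={10.0 ** w[6]:.4g}; "
                    "returning partial branch"
                )
                break
            continue
        dw = w_new - w
        nrm = np.linalg.norm(dw)
        if nrm == 0:
            ds = min(2 * ds, ds_max)
            continue
        new_tangent = dw / nrm
        if new_tangent[6] * tangent[6] < 0:
            refined = _refine_fold(sys, w, tangent, ds)
            if refined is not None:
                fold_p, w_fold = refined
                polished = _polish_fold(sys, fold_p, w_fold, params)
                if polished is not None:
                    fold_p, fold_state = polished
                else:
                    fold_state = np.maximum(w_fold[:6] * sys.s_scale, 0.0)
                folds.append((fold_p, fold_state))
        w, tangent = w_new, new_tangent
        record(w)
        ds = min(ds * 1.4, ds_max)
        if w[6] > lp_hi + 1e-12 or w[6] < lp_lo - 1e-12:
            terminated = "range"
            break

    folds.sort(key=lambda fp: fp[0])
    return EquilibriumBranch(
        param_name=free,
        param_values=np.asarray(branch_p),
        equilibria=eqs_list,
        fold_points=[fp for fp, _ in folds],
        fold_states=[st for _, st in folds],
        terminated=terminated,
    )


def _polish_fold(sys: _AugmentedSystem, p_guess: float, w_near: np.ndarray,
                 params: ParamSet) -> tuple[float, np.ndarray] | None:
    """Newton polish of a fold on the extended saddle-node system.

    Unknowns (y, log10 p, v): rates = 0, J v = 0, c . v = 1 with c the
    initial null-vector estimate.  Leaves |det J| at solver precision.
    """
    from scipy.optimize import root as _scipy_root

    y0 = np.maximum(w_near[:6] * sys.s_scale, 0.0)
    lp0 = np.log10(p_guess)
    env0 = sys.env_at(lp0)
    J0 = _jacobian(y0, env0, params)
    eigvals, eigvecs = np.linalg.eig(J0)
    k = int(np.argmin(np.abs(eigvals.real)))
    v0 = np.real(eigvecs[:, k])
    n0 = np.linalg.norm(v0)
    if n0 == 0:
        return None
    v0 = v0 / n0
    c = v0.copy()

    def G(z):
        y, lp, v = z[:6], z[6], z[7:]
        env = sys.env_at(lp)
        f = rates_vec(np.maximum(y, 0.0), env.c6, env.c12, env.iptg, env.atc, params)
        J = _jacobian(np.maximum(y, 0.0), env, params)
        return np.concatenate([f, J @ v, [c @ v - 1.0]])

    z0 = np.concatenate([y0, [lp0], v0])
    sol = _scipy_root(G, z0, method="hybr", tol=1e-13)
    if not sol.success:
        return None
    y, lp = np.maximum(sol.x[:6], 0.0), sol.x[6]
    p = float(10.0 ** lp)
    # accept only if the polish stayed near the bisection bracket
    if not np.isfinite(p) or abs(np.log10(p / p_guess)) > 0.3:
        return None
    return p, y


def _refine_fold(sys: _AugmentedSystem, w0: np.ndarray, tangent: np.ndarray,
                 ds: float, rel_tol: float = 1e-4) -> tuple[float, np.ndarray] | None:
    """Arclength bisection for the step interval containing the fold.

    On entry the tangent's parameter component flips sign somewhere in
    (0, ds] ahead of ``w0``.  Halve the step until the bracketing parameter
    interval is below ``rel_tol`` relative; returns the fold parameter and
    the nearby on-branch point.
    """
    lo, hi = 0.0, ds
    w_lo = w0
    t_lo = tangent
    best = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mid == lo:
            break
        w_mid = sys.correct(w_lo + (mid - lo) * t_lo, t_lo)
        if w_mid is None:
            return best
        d = w_mid - w_lo
        n = np.linalg.norm(d)
        if n == 0:
            break
        t_mid = d / n
        best = (float(10.0 ** w_mid[6]), w_mid)
        p_lo_v, p_hi_v = 10.0 ** w_lo[6], best[0]
        if abs(p_hi_v - p_lo_v) <= rel_tol * max(p_hi_v, p_lo_v):
            break
        if t_mid[6] * t_lo[6] > 0:
            # still heading the same way in parameter: fold is beyond mid
            lo, w_lo, t_lo = mid, w_mid, t_mid
        else:
            hi = mid
    return best


# ---------------------------------------------------------------------------
# bistable region mapping
# ---------------------------------------------------------------------------


def map_bistable_region(
    grid_spec: GridSpec,
    params: ParamSet,
    iptg: float = 0.0,
    atc: float = 0.0,
    seed: int = 0,
    n_starts: int = 12,
) -> BistabilityMap:
    """Stable-equilibrium counts on a log grid plus the count>=2 boundary."""
    c6s, c12s = grid_spec.c6_values, grid_spec.c12_values
    counts = np.zeros((c6s.size, c12s.size), dtype=int)
    for i, c6 in enumerate(c6s):
        for j, c12 in enumerate(c12s):
            env = SignalEnvironment(c6=c6, c12=c12, iptg=iptg, atc=atc)
            counts[i, j] = sum(
                e.is_stable for e in find_equilibria(env, params, n_starts=n_starts, seed=seed)
            )
    boundary = _contour_boundary(counts, np.log10(c6s), np.log10(c12s))
    return BistabilityMap(grid=grid_spec, counts=counts, boundary=boundary,
                          iptg=iptg, atc=atc)


def _contour_boundary(counts: np.ndarray, lx: np.ndarray, ly: np.ndarray) -> list[np.ndarray]:
    """Polylines around the count >= 2 region, in (log10 c6, log10 c12)."""
    from skimage import measure

    mask = (counts >= 2).astype(float)
    if mask.max() == 0:
        return []
    polys = []
    for contour in measure.find_contours(mask, 0.5):
        pts = np.empty_like(contour)
        pts[:, 0] = np.interp(contour[:, 0], np.arange(lx.size), lx)
        pts[:, 1] = np.interp(contour[:, 1], np.arange(ly.size), ly)
        polys.append(pts)
    return polys


# ---------------------------------------------------------------------------
# hysteresis protocol
# ---------------------------------------------------------------------------


def hysteresis_protocol(
    conditioning: str,
    grid_spec: GridSpec,
    params: ParamSet,
    conditioning_conc: float = 500.0,
    t_condition: float = 2.0,
    t_exposure: float = 5.0,
    iptg: float = 0.0,
    atc: float = 0.0,
    eps: float = 1e-9,
    dt: float = 0.02,
) -> HysteresisGrid:
    """Condition at 500 nM of one signal, wash, expose to the grid, read out.

    Readout per grid point is (cfp - yfp)/(cfp + yfp + eps) at protocol end.
    """
    if conditioning not in ("C6", "C12"):
        raise ValueError("conditioning must be 'C6' or 'C12'")
    cond_env = {"C6": (conditioning_conc, 0.0), "C12": (0.0, conditioning_conc)}[conditioning]
    y0 = np.zeros((6, 1))
    y_cond = integrate_many(
        y0, cond_env[0], cond_env[1], iptg, atc, params, t_condition, dt=dt
    )
    c6g, c12g = np.meshgrid(grid_spec.c6_values, grid_spec.c12_values, indexing="ij")
    n = c6g.size
    y = np.repeat(y_cond, n, axis=1)
    y_end = integrate_many(
        y, c6g.ravel(), c12g.ravel(), iptg, atc, params, t_exposure, dt=dt
    )
    cfp, yfp = y_end[4], y_end[5]
    readout = ((cfp - yfp) / (cfp + yfp + eps)).reshape(c6g.shape)
    return HysteresisGrid(grid=grid_spec, conditioning=conditioning,
                          readout=readout, iptg=iptg, atc=atc)
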