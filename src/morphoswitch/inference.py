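"""Ratiometric promoter-activity extraction and staged parameter inference.

Bulk fluorescence from a plate fluorometer is read out as F/RFP against a
constitutive RFP reference, restricted to the exponential-phase OD window,
so growth and common-mode instrument gain cancel.  Parameters are inferred
in stages on circuits of increasing complexity: sensing/synthesis
parameters on the no-repression receiver first, repression parameters on
the mutual-inhibition circuit afterwards with the shared subset frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .circuit_model import ParamSet, SignalEnvironment, integrate_many

__all__ = [
    "PlateTimecourse",
    "FitResult",
    "DataError",
    "promoter_activity",
    "simulate_ratio_curves",
    "fit_stage",
    "staged_inference",
    "DEFAULT_BOUNDS",
    "STAGE1_FREE",
    "STAGE2_FREE",
]


class DataError(ValueError):
    """Raised when a timecourse cannot supply the requested estimate."""


@dataclass
class PlateTimecourse:
    """One well: times (h), OD and bulk RFP/CFP/YFP fluorescence (a.u.)."""

    well: str
    env: SignalEnvironment
    times: np.ndarray
    od: np.ndarray
    rfp: np.ndarray
    cfp: np.ndarray
    yfp: np.ndarray
    variant: str = "exclusive_receiver"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("od", "rfp", "cfp", "yfp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must align with times in well {self.well}")
            if name != "od" and np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0 in well {self.well}")
            setattr(self, name, arr)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be increasing in well {self.well}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "well": self.well, "t": self.times, "od": self.od,
            "rfp": self.rfp, "cfp": self.cfp, "yfp": self.yfp,
            "c6": self.env.c6, "c12": self.env.c12,
            "iptg": self.env.iptg, "atc": self.env.atc,
            "variant": self.variant,
        })


@dataclass
class FitResult:
    params: ParamSet
    free: list[str]
    fixed: list[str]
    loss: float
    restart_losses: list[float]
    uncertainty: dict[str, float]
    seed: int
    success: bool
    message: str = ""


def promoter_activity(tc: PlateTimecourse, od_window=(0.05, 0.3)) -> dict:
    """Ratiometric per-channel activity estimates in the exponential window.

    Returns, for each of CFP and YFP, the window mean of F/RFP and (as a
    secondary estimate) the least-squares slope of F/RFP against time.
    """
    lo, hi = od_window
    mask = (tc.od >= lo) & (tc.od <= hi)
    if not np.any(mask):
        raise DataError(
            f"well {tc.well}: OD never enters the window [{lo}, {hi}]"
        )
    if np.any(tc.rfp[mask] <= 0):
        raise DataError(f"well {tc.well}: non-positive RFP inside the OD window")
    t = tc.times[mask]
    out = {"window": (lo, hi), "n_points": int(mask.sum())}
    for name in ("cfp", "yfp"):
        ratio = getattr(tc, name)[mask] / tc.rfp[mask]
        slope = float(np.polyfit(t, ratio, 1)[0]) if t.size > 1 else 0.0
        out[name] = {"mean_ratio": float(ratio.mean()), "slope": slope}
    return out


def simulate_ratio_curves(
    params: ParamSet,
    envs: list[SignalEnvironment],
    times: np.ndarray,
    dt: float = 0.1,
) -> np.ndarray:
    """Model-predicted per-cell (CFP/RFP, YFP/RFP) curves, shape (n_env, n_t, 2).

    Cells start from the zero state (fresh 1:1000 dilution); the constitutive
    RFP reference is the calibration constant ``params.rfp0``.
    """
    times = np.asarray(times, dtype=float)
    n_env = len(envs)
    c6 = np.array([e.c6 for e in envs])
    c12 = np.array([e.c12 for e in envs])
    iptg = np.array([e.iptg for e in envs])
    atc = np.array([e.atc for e in envs])
    y = np.zeros((6, n_env))
    out = np.empty((n_env, times.size, 2))
    t_prev = 0.0
    for k, t in enumerate(times):
        if t > t_prev:
            y = integrate_many(y, c6, c12, iptg, atc, params, t - t_prev, dt=dt)
            t_prev = t
        out[:, k, 0] = y[4] / params.rfp0
        out[:, k, 1] = y[5] / params.rfp0
    return out


# factor bounds around the default calibration, in natural units
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a_r": (1.0, 1e3), "b_r": (1e-3, 10.0), "g_r": (0.05, 10.0),
    "a_f": (1.0, 1e4), "b_f": (1e-3, 10.0),
    "g_laci": (0.05, 10.0), "g_tetr": (0.05, 10.0),
    "g_cfp": (0.005, 2.0), "g_yfp": (0.005, 2.0),
    "K6": (0.5, 2e3), "n6": (1.0, 4.0),
    "K12": (1.0, 2e4), "n12": (1.0, 4.0),
    "K_lac": (0.1, 200.0), "n_lac": (1.0, 4.0),
    "K_tet": (0.1, 200.0), "n_tet": (1.0, 4.0),
    "K_iptg": (0.5, 1e3), "n_iptg": (1.0, 4.0),
    "K_atc": (0.5, 1e3), "n_atc": (1.0, 4.0),
    "rfp0": (1.0, 1e4),
}

STAGE1_FREE = ["K6", "n6", "K12", "n12", "a_f"]
STAGE2_FREE = ["K_lac", "n_lac", "K_tet", "n_tet"]

_ACTIVATION_PARAMS = {"K6": "c6", "n6": "c6", "K12": "c12", "n12": "c12"}


def _observed_ratios(tc: PlateTimecourse, od_window) -> tuple[np.ndarray, np.ndarray]:
    """(mask, (n_t_window, 2)) observed F/RFP inside the OD window."""
    lo, hi = od_window
    mask = (tc.od >= lo) & (tc.od <= hi) & (tc.rfp > 0)
    obs = np.stack([tc.cfp[mask] / tc.rfp[mask], tc.yfp[mask] / tc.rfp[mask]], axis=-1)
    return mask, obs


def fit_stage(
    variant: str,
    datasets: list[PlateTimecourse],
    free: list[str],
    fixed: ParamSet,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    od_window=(0.05, 0.3),
    max_nfev: int | None = None,
    dt: float = 0.1,
) -> FitResult:
    """Multi-start bounded least squares on F/RFP trajectories.

    Free parameters are optimised in log space within ``bounds``; everything
    else is pinned at its value in ``fixed``.  Deterministic given ``seed``;
    the best restart wins and all restart losses are reported.
    """
    if not datasets:
        raise ValueError("datasets must be non-empty")
    bad = [tc.well for tc in datasets if tc.variant != variant]
    if bad:
        raise ValueError(
            f"variant mismatch: wells {bad} are not {variant!r} data"
        )
    free = list(free)
    if len(set(free)) != len(free):
        raise ValueError("duplicate names in free")
    unknown = [f for f in free if f not in DEFAULT_BOUNDS]
    if unknown:
        raise ValueError(f"no bounds known for parameters {unknown}")
    fixed = fixed.replace(circuit_variant=variant)

    # identifiability: each free activation parameter needs >= 2 distinct
    # signal conditions that exercise it
    for name, signal in _ACTIVATION_PARAMS.items():
        if name in free:
            n_distinct = len({getattr(tc.env, signal) for tc in datasets})
            if n_distinct < 2:
                warnings.warn(
                    f"parameter {name} is weakly identified: only {n_distinct} "
                    f"distinct {signal} conditions (flat-loss risk)"
                )

    envs = [tc.env for tc in datasets]
    masks_obs = [_observed_ratios(tc, od_window) for tc in datasets]
    times = datasets[0].times
    for tc in datasets:
        if tc.times.shape != times.shape or not np.allclose(tc.times, times):
            raise ValueError("all wells must share a common time grid")
    # only simulate at times any well actually uses
    union = np.zeros(times.size, dtype=bool)
    for mask, _ in masks_obs:
        union |= mask
    t_fit = times[union]
    sub_masks = [mask[union] for mask, _ in masks_obs]

    b = dict(DEFAULT_BOUNDS, **(bounds or {}))
    lb = np.log([b[f][0] for f in free]) if free else np.empty(0)
    ub = np.log([b[f][1] for f in free]) if free else np.empty(0)

    def residuals(x_log: np.ndarray) -> np.ndarray:
        p = fixed.replace(**{f: float(np.exp(v)) for f, v in zip(free, x_log)})
        curves = simulate_ratio_curves(p, envs, t_fit, dt=dt)
        res = []
        for i, (_, obs) in enumerate(masks_obs):
            res.append((curves[i][sub_masks[i]] - obs).ravel())
        return np.concatenate(res)

    if not free:
        r = residuals(np.empty(0))
        loss = float(r @ r)
        return FitResult(params=fixed, free=[], fixed=sorted(fixed.to_dict()),
                         loss=loss, restart_losses=[loss], uncertainty={},
                         seed=seed, success=True, message="no free parameters")

    rng = np.random.default_rng(seed)
    x_default = np.clip(
        np.log([getattr(fixed, f) for f in free]), lb + 1e-9, ub - 1e-9
    )
    starts = [x_default]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(lb, ub))

    best, losses = None, []
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub),
                                max_nfev=max_nfev, xtol=1e-10, ftol=1e-10)
        except Exception as exc:  # pragma: no cover - solver edge cases
            losses.append(float("inf"))
            continue
        loss = float(2 * sol.cost)
        losses.append(loss)
        if best is None or loss < best[0]:
            best = (loss, sol)
    if best is None:
        raise RuntimeError("all restarts failed")
    loss, sol = best
    fitted = fixed.replace(**{f: float(np.exp(v)) for f, v in zip(free, sol.x)})

    # crude per-parameter uncertainty from the Gauss-Newton curvature
    unc = {}
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(JTJ) * max(loss, 1e-300) / max(sol.fun.size - len(free), 1)
        sd_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        unc = {f: float(s) for f, s in zip(free, sd_log)}  # sd of log-param
    except Exception:  # pragma: no cover
        pass

    return FitResult(
        params=fitted, free=free,
        fixed=[f for f in fitted.to_dict() if f not in free],
        loss=loss, restart_losses=losses, uncertainty=unc, seed=seed,
        success=bool(sol.success), message=str(sol.message),
    )


def staged_inference(
    receiver_data: list[PlateTimecourse],
    exclusive_data: list[PlateTimecourse],
    base: ParamSet | None = None,
    free_stage1: list[str] | None = None,
    free_stage2: list[str] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kw,
) -> tuple[ParamSet, dict]:
    """Two-stage inference reusing receiver parameters in the toggle model.

    Stage 1 fits shared sensing/synthesis parameters on receiver data;
    stage 2 freezes them and fits the repression parameters on
    mutual-inhibition data.  Returns the final parameter set and a
    provenance record mapping each parameter to the stage that set it.
    """
    base = base or ParamSet()
    free1 = list(free_stage1 if free_stage1 is not None else STAGE1_FREE)
    free2 = list(free_stage2 if free_stage2 is not None else STAGE2_FREE)
    overlap = set(free1) & set(free2)
    if overlap:
        raise ValueError(f"parameters {sorted(overlap)} requested in both stages")

    stage1 = fit_stage("receiver", receiver_data, free1, base,
                       n_restarts=n_restarts, seed=seed, **fit_kw)
    stage2 = fit_stage("exclusive_receiver", exclusive_data, free2,
                       stage1.params, n_restarts=n_restarts, seed=seed + 1,
                       **fit_kw)
    # fixing contract: stage 2 must not have altered stage-1 parameters
    for f in free1:
        assert getattr(stage2.params, f) == getattr(stage1.params, f)

    final = stage2.params.replace(circuit_variant="exclusive_receiver")
    provenance = {
        name: ("stage1" if name in free1 else "stage2" if name in free2 else "fixed")
        for name in final.to_dict()
    }
    return final, {
        "provenance": provenance,
        "stage1": stage1,
        "stage2": stage2,
    }
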