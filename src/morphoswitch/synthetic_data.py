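"""Synthetic data generators with known ground truth.

Emulates the three measurement modalities consumed downstream: bulk
plate-fluorometer timecourses over signal grids, conditioning/exposure
flow-like per-cell samples with cell-to-cell variability, and space-time
kymograph tables with a prescribed boundary trajectory.  Every generator is
a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_model import ParamSet, SignalEnvironment, integrate_many
from .inference import PlateTimecourse

__all__ = [
    "GrowthModel",
    "NoiseModel",
    "generate_plate",
    "generate_flow",
    "generate_kymograph_fixture",
]


@dataclass(frozen=True)
class GrowthModel:
    """Logistic OD curve: od0 -> carrying capacity at the given rate (1/h)."""

    od0: float = 0.005
    rate: float = 0.8
    carrying: float = 0.6

    def __post_init__(self) -> None:
        if min(self.od0, self.rate, self.carrying) <= 0:
            raise ValueError("growth parameters must be > 0")
        if self.od0 > self.carrying:
            raise ValueError("od0 must not exceed the carrying capacity")

    def od(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        K, r, o0 = self.carrying, self.rate, self.od0
        return K / (1.0 + (K / o0 - 1.0) * np.exp(-r * t))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and population noise levels.

    ``mult_sd``: lognormal sd per fluorescence read; ``background``: additive
    offset (a.u.); ``flow_cv``: cell-to-cell CV on synthesis rates in flow
    mode.
    """

    mult_sd: float = 0.05
    background: float = 50.0
    flow_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.mult_sd < 0 or self.background < 0 or self.flow_cv < 0:
            raise ValueError("noise levels must be >= 0")


def _read_noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    # lognormal with unit median
    return rng.lognormal(mean=0.0, sigma=sd, size=shape)


def generate_plate(
    params: ParamSet,
    env_grid: list[SignalEnvironment],
    growth: GrowthModel | None = None,
    noise: NoiseModel | None = None,
    n_reps: int = 1,
    seed: int = 0,
    t_end: float = 16.67,
    cadence: float = 1.0 / 6.0,
    dt: float = 0.05,
) -> list[PlateTimecourse]:
    """Bulk fluorometer wells over an environment grid.

    Bulk fluorescence is OD(t) times the per-cell protein level from the
    circuit model (constitutive ``rfp0`` for RFP), with multiplicative read
    noise and an additive background.  Reads every 10 min for ~1000 min by
    default, matching the assay cadence.
    """
    if not env_grid:
        raise ValueError("env_grid must be non-empty")
    growth = growth or GrowthModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + 1e-9, cadence)
    od = growth.od(times)

    n_env = len(env_grid)
    c6 = np.array([e.c6 for e in env_grid])
    c12 = np.array([e.c12 for e in env_grid])
    iptg = np.array([e.iptg for e in env_grid])
    atc = np.array([e.atc for e in env_grid])

    # one clean integration; replicates differ only in measurement noise
    y = np.zeros((6, n_env))
    cfp_cell = np.zeros((n_env, times.size))
    yfp_cell = np.zeros((n_env, times.size))
    t_prev = 0.0
    for k, t in enumerate(times):
        if t > t_prev:
            y = integrate_many(y, c6, c12, iptg, atc, params, t - t_prev, dt=dt)
            t_prev = t
        cfp_cell[:, k] = y[4]
        yfp_cell[:, k] = y[5]

    wells = []
    for rep in range(n_reps):
        for i, env in enumerate(env_grid):
            bg = noise.background
            sd = noise.mult_sd
            wells.append(PlateTimecourse(
                well=f"r{rep}_e{i}",
                env=env,
                times=times.copy(),
                od=od.copy(),
                rfp=od * params.rfp0 * _read_noise(rng, times.size, sd) + bg,
                cfp=od * cfp_cell[i] * _read_noise(rng, times.size, sd) + bg,
                yfp=od * yfp_cell[i] * _read_noise(rng, times.size, sd) + bg,
                variant=params.circuit_variant,
            ))
    return wells


def generate_flow(
    params: ParamSet,
    conditioning: str,
    exposure_env: SignalEnvironment,
    n_cells: int = 1000,
    noise: NoiseModel | None = None,
    seed: int = 0,
    conditioning_conc: float = 500.0,
    t_condition: float = 2.0,
    t_exposure: float = 5.0,
    rfp_gate_floor_frac: float = 0.2,
    dt: float = 0.02,
) -> pd.DataFrame:
    """Per-cell conditioning/exposure sample with cell-to-cell variability.

    Each cell draws lognormal scalings of its synthesis rates (CV from the
    noise model), runs 2 h conditioning at 500 nM of one signal, is washed
    into the exposure environment for 5 h, and is read with multiplicative
    noise.  Cells below the RFP gate floor are discarded, emulating the
    RFP-positive gate.
    """
    if conditioning not in ("C6", "C12"):
        raise ValueError("conditioning must be 'C6' or 'C12'")
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    cv = noise.flow_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        scale_f = rng.lognormal(-0.5 * sigma ** 2, sigma, n_cells)
        scale_r = rng.lognormal(-0.5 * sigma ** 2, sigma, n_cells)
        rfp_scale = rng.lognormal(-0.5 * sigma ** 2, sigma, n_cells)
    else:
        scale_f = scale_r = rfp_scale = np.ones(n_cells)

    cond_c6 = conditioning_conc if conditioning == "C6" else 0.0
    cond_c12 = conditioning_conc if conditioning == "C12" else 0.0
    y = np.zeros((6, n_cells))
    y = integrate_many(y, cond_c6, cond_c12, exposure_env.iptg, exposure_env.atc,
                       params, t_condition, dt=dt, scale_f=scale_f, scale_r=scale_r)
    y = integrate_many(y, exposure_env.c6, exposure_env.c12, exposure_env.iptg,
                       exposure_env.atc, params, t_exposure, dt=dt,
                       scale_f=scale_f, scale_r=scale_r)

    sd = noise.mult_sd
    cfp = y[4] * _read_noise(rng, n_cells, sd)
    yfp = y[5] * _read_noise(rng, n_cells, sd)
    rfp = params.rfp0 * rfp_scale * _read_noise(rng, n_cells, sd)
    df = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "cfp": cfp, "yfp": yfp, "rfp": rfp,
        "conditioning": conditioning,
        "c6": exposure_env.c6, "c12": exposure_env.c12,
    })
    gate = df["rfp"] >= rfp_gate_floor_frac * params.rfp0
    return df[gate].reset_index(drop=True)


def generate_kymograph_fixture(
    shape: str,
    grid: tuple[int, int] = (49, 101),
    seed: int = 0,
    L: float = 8.0,
    t_end: float = 24.0,
    noise_sd: float = 0.02,
    front_width: float = 0.03,
    ramp_tau: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Analytic kymograph table with a known boundary trajectory.

    ``shape`` selects the boundary class: "static" (fixed crossing),
    "moving" (linear drift covering 30% of the domain) or "absent" (single
    channel only).  Returns a long-format (t, x, cfp, yfp) table and the
    ground truth {beta(t), label, delta_beta}.
    """
    if shape not in ("static", "moving", "absent"):
        raise ValueError("shape must be 'static', 'moving' or 'absent'")
    n_t, n_x = grid
    if n_t < 2 or n_x < 8:
        raise ValueError("grid too small")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_t)
    x = (np.arange(n_x) + 0.5) * (L / n_x)
    amp = 1.0 - np.exp(-times / ramp_tau)          # detectability ramp
    w = front_width * L

    if shape == "static":
        beta = np.full(n_t, 0.45 * L)
        label = "S"
    elif shape == "moving":
        beta = 0.3 * L + 0.3 * L * times / t_end
        label = "M"
    else:
        beta = np.full(n_t, np.nan)
        label = "N"

    if shape == "absent":
        cfp = np.zeros((n_t, n_x))
        yfp = amp[:, None] * np.ones((n_t, n_x))
    else:
        z = (x[None, :] - beta[:, None]) / w
        cfp = amp[:, None] / (1.0 + np.exp(z))
        yfp = amp[:, None] / (1.0 + np.exp(-z))
    if noise_sd > 0:
        cfp = cfp * rng.lognormal(0.0, noise_sd, cfp.shape)
        yfp = yfp * rng.lognormal(0.0, noise_sd, yfp.shape)

    df = pd.DataFrame({
        "t": np.repeat(times, n_x),
        "x": np.tile(x, n_t),
        "cfp": cfp.ravel(),
        "yfp": yfp.ravel(),
    })
    truth = {
        "label": label,
        "beta": beta,
        "times": times,
        "delta_beta": 0.0 if shape != "moving" else float(abs(beta[-1] - beta[0])),
        "L": L,
    }
    return df, truth
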