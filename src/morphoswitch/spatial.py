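"""1D reaction-diffusion simulation of signal gradients over a cell lawn.

Signals diffuse through the substrate (Crank-Nicolson, no-flux boundaries)
while immobile cells at every grid point run the intracellular circuit ODEs
with the local signal concentrations as their environment.  Relay variants
add a production term to the secondary signal's PDE proportional to the
synthase co-expressed with one pathway.

Geometry is Cartesian with cell-centred grid points, so no-flux diffusion
conserves each signal's discrete mass exactly (to linear-solver roundoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .circuit_model import ParamSet, _rates_terms, _signal_terms

__all__ = [
    "SpatialConfig",
    "SpatialFields",
    "make_antiparallel_ic",
    "make_central_source_ic",
    "simulate_rd",
    "simulate_relay",
    "phase_trajectories",
]


@dataclass
class SpatialConfig:
    """Domain, transport and solver settings for the 1D simulation.

    Defaults reflect the solid-culture assay: a short strip of lawn,
    small-molecule diffusivity in agar, 10 uM IPTG in the substrate and no
    signal degradation.  C12 diffuses slower than C6 by default (bulkier
    acyl chain, partitioning into the gel).
    """

    L: float = 8.0               # domain length, mm
    n_x: int = 101
    D_c6: float = 1.8            # mm^2/h
    D_c12: float = 0.72          # C12 is larger and partitions into agar
    iptg: float = 10.0           # uM, substrate context
    atc: float = 0.0
    hsl_decay: float = 0.0       # 1/h first-order loss of both signals
    t_end: float = 24.0          # h
    dt_split: float = 0.02       # operator-splitting interval, h
    reaction_substeps: int = 2   # RK4 substeps per splitting interval
    output_every: float = 0.25   # h between recorded frames

    def __post_init__(self) -> None:
        if self.L <= 0 or self.n_x < 3:
            raise ValueError("need L > 0 and n_x >= 3")
        if self.D_c6 <= 0 or self.D_c12 <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.hsl_decay < 0 or self.iptg < 0 or self.atc < 0:
            raise ValueError("iptg, atc and hsl_decay must be >= 0")
        if self.t_end <= 0 or self.dt_split <= 0 or self.output_every <= 0:
            raise ValueError("t_end, dt_split and output_every must be > 0")

    @property
    def dx(self) -> float:
        return self.L / self.n_x

    @property
    def x(self) -> np.ndarray:
        """Cell-centred grid coordinates."""
        return (np.arange(self.n_x) + 0.5) * self.dx


@dataclass
class SpatialFields:
    """Space-time output of the reaction-diffusion simulator."""

    x: np.ndarray                # (n_x,) mm
    times: np.ndarray            # (n_t,) h
    c6: np.ndarray               # (n_t, n_x) nM
    c12: np.ndarray              # (n_t, n_x) nM
    states: np.ndarray           # (n_t, 6, n_x) intracellular levels
    config: SpatialConfig
    params: ParamSet | None = None

    @property
    def cfp(self) -> np.ndarray:
        return self.states[:, 4, :]

    @property
    def yfp(self) -> np.ndarray:
        return self.states[:, 5, :]

    def mass(self, signal: str) -> np.ndarray:
        """Total amount of a signal (nM * mm) at each recorded time."""
        f = {"c6": self.c6, "c12": self.c12}[signal]
        return f.sum(axis=1) * self.config.dx

    def to_dataframe(self):
        import pandas as pd

        n_t, n_x = self.c6.shape
        return pd.DataFrame({
            "t": np.repeat(self.times, n_x),
            "x": np.tile(self.x, n_t),
            "c6": self.c6.ravel(),
            "c12": self.c12.ravel(),
            "cfp": self.cfp.ravel(),
            "yfp": self.yfp.ravel(),
            "luxR": self.states[:, 0, :].ravel(),
            "lasR": self.states[:, 1, :].ravel(),
            "lacI": self.states[:, 2, :].ravel(),
            "tetR": self.states[:, 3, :].ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


def _band_field(total_mass_cells: float, lo: float, hi: float, config: SpatialConfig) -> np.ndarray:
    """Uniform concentration on [lo, hi) with partial boundary-cell weighting.

    ``total_mass_cells`` is the target field sum (mean * n_x); the overlap of
    each grid cell with the band sets its share, so the domain mean is exact
    regardless of grid alignment.
    """
    dx = config.dx
    edges_lo = np.arange(config.n_x) * dx
    edges_hi = edges_lo + dx
    overlap = np.clip(np.minimum(edges_hi, hi) - np.maximum(edges_lo, lo), 0.0, dx)
    width = hi - lo
    if width <= 0:
        return np.zeros(config.n_x)
    conc = total_mass_cells / (width / dx)     # concentration inside the band
    return conc * overlap / dx


def make_antiparallel_ic(
    avg_c6: float,
    avg_c12: float,
    source_fraction: float = 0.25,
    config: SpatialConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Antiparallel source bands: C12 on the left, C6 on the right.

    Each source occupies ``source_fraction`` of the domain at amplitude
    ``avg / source_fraction`` so the domain mean equals the requested
    average exactly.
    """
    if config is None:
        config = SpatialConfig()
    if not 0 < source_fraction <= 0.5:
        raise ValueError("source_fraction must lie in (0, 0.5]")
    if avg_c6 < 0 or avg_c12 < 0:
        raise ValueError("averages must be >= 0")
    L = config.L
    c12 = _band_field(avg_c12 * config.n_x, 0.0, source_fraction * L, config)
    c6 = _band_field(avg_c6 * config.n_x, (1 - source_fraction) * L, L, config)
    return c6, c12


def make_central_source_ic(
    conc: float,
    source_fraction: float = 0.1,
    config: SpatialConfig | None = None,
) -> np.ndarray:
    """Central window at ``conc``, zero elsewhere; domain mean = conc * fraction."""
    if config is None:
        config = SpatialConfig()
    if not 0 < source_fraction <= 0.5:
        raise ValueError("source_fraction must lie in (0, 0.5]")
    if conc < 0:
        raise ValueError("conc must be >= 0")
    L = config.L
    lo = 0.5 * L * (1 - source_fraction)
    hi = 0.5 * L * (1 + source_fraction)
    return _band_field(conc * source_fraction * config.n_x, lo, hi, config)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _cn_operator(n_x: int, alpha: float):
    """Banded LHS matrix and RHS stencil for Crank-Nicolson with no-flux BCs.

    Uses the reflective (mirror ghost cell) Laplacian whose rows sum to zero,
    so the discrete mass sum(u) is conserved exactly.
    """
    lap_diag = np.full(n_x, -2.0)
    lap_diag[0] = lap_diag[-1] = -1.0
    # LHS = I - (alpha/2) Lap  in banded form (upper, main, lower)
    ab = np.zeros((3, n_x))
    ab[0, 1:] = -0.5 * alpha            # superdiagonal
    ab[1, :] = 1.0 - 0.5 * alpha * lap_diag
    ab[2, :-1] = -0.5 * alpha           # subdiagonal
    return ab, lap_diag


def _cn_step(u: np.ndarray, ab: np.ndarray, lap_diag: np.ndarray, alpha: float) -> np.ndarray:
    rhs = u + 0.5 * alpha * (lap_diag * u)
    rhs[:-1] += 0.5 * alpha * u[1:]
    rhs[1:] += 0.5 * alpha * u[:-1]
    return solve_banded((1, 1), ab, rhs)


def simulate_rd(
    config: SpatialConfig,
    params: ParamSet,
    ic: tuple[np.ndarray, np.ndarray],
    relay: str | None = None,
) -> SpatialFields:
    """Operator-split reaction-diffusion run.

    ``ic`` is the pair of initial (c6, c12) fields.  Per splitting interval:
    one Crank-Nicolson diffusion step for each signal, then the intracellular
    ODEs advanced with local signals frozen (RK4 substeps).  With ``relay``
    set ("c6_to_c12" or "c12_to_c6") the secondary signal gains a production
    term k_relay * synthase, where the synthase tracks the reporter of the
    co-expressed pathway.
    """
    c6 = np.asarray(ic[0], dtype=float).copy()
    c12 = np.asarray(ic[1], dtype=float).copy()
    if c6.shape != (config.n_x,) or c12.shape != (config.n_x,):
        raise ValueError("initial fields must match the grid")
    if np.any(c6 < 0) or np.any(c12 < 0):
        raise ValueError("initial fields must be >= 0")
    if relay not in (None, "c6_to_c12", "c12_to_c6"):
        raise ValueError("relay must be None, 'c6_to_c12' or 'c12_to_c6'")

    dt = config.dt_split
    n_steps = max(1, int(round(config.t_end / dt)))
    dt = config.t_end / n_steps
    alpha6 = config.D_c6 * dt / config.dx ** 2
    alpha12 = config.D_c12 * dt / config.dx ** 2
    ab6, lap = _cn_operator(config.n_x, alpha6)
    ab12, _ = _cn_operator(config.n_x, alpha12)

    y = np.zeros((6, config.n_x))
    record_stride = max(1, int(round(config.output_every / dt)))
    times = [0.0]
    c6_out, c12_out, y_out = [c6.copy()], [c12.copy()], [y.copy()]

    decay = math.exp(-config.hsl_decay * dt) if config.hsl_decay > 0 else 1.0
    sub_dt = dt / config.reaction_substeps

    for step in range(1, n_steps + 1):
        c6 = _cn_step(c6, ab6, lap, alpha6)
        c12 = _cn_step(c12, ab12, lap, alpha12)
        np.maximum(c6, 0.0, out=c6)
        np.maximum(c12, 0.0, out=c12)
        if config.hsl_decay > 0:
            c6 *= decay
            c12 *= decay
        # reaction: cells respond to the local, frozen signal levels
        terms = _signal_terms(c6, c12, config.iptg, config.atc, params)
        for _ in range(config.reaction_substeps):
            k1 = _rates_terms(y, terms, params)
            k2 = _rates_terms(y + 0.5 * sub_dt * k1, terms, params)
            k3 = _rates_terms(y + 0.5 * sub_dt * k2, terms, params)
            k4 = _rates_terms(y + sub_dt * k3, terms, params)
            y += (sub_dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.maximum(y, 0.0, out=y)
        if relay == "c6_to_c12":
            c12 += dt * params.k_relay * y[2]   # LasI tracks the CFP/LacI operon
        elif relay == "c12_to_c6":
            c6 += dt * params.k_relay * y[3]    # LuxI tracks the YFP/TetR operon
        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            c6_out.append(c6.copy())
            c12_out.append(c12.copy())
            y_out.append(y.copy())

    return SpatialFields(
        x=config.x,
        times=np.asarray(times),
        c6=np.asarray(c6_out),
        c12=np.asarray(c12_out),
        states=np.asarray(y_out),
        config=config,
        params=params,
    )


def simulate_relay(
    config: SpatialConfig,
    params: ParamSet,
    primary: str,
    source_conc: float = 40000.0,
    source_fraction: float = 0.1,
) -> SpatialFields:
    """Central-source relay run: the primary signal diffuses from the centre
    and cells produce the secondary signal through the co-expressed synthase.
    """
    if primary not in ("C6", "C12"):
        raise ValueError("primary must be 'C6' or 'C12'")
    central = make_central_source_ic(source_conc, source_fraction, config)
    zero = np.zeros(config.n_x)
    if primary == "C6":
        ic = (central, zero)
        relay = "c6_to_c12"
        want = "relay_c6_to_c12"
    else:
        ic = (zero, central)
        relay = "c12_to_c6"
        want = "relay_c12_to_c6"
    if params.circuit_variant not in (want, "exclusive_receiver"):
        raise ValueError(
            f"params variant {params.circuit_variant!r} inconsistent with primary {primary}"
        )
    return simulate_rd(config, params, ic, relay=relay)


def phase_trajectories(
    fields: SpatialFields,
    positions: np.ndarray | None = None,
) -> dict:
    """Per-position (c6, c12) paths plus the spatial-average path.

    ``positions`` are x coordinates (mm); default is 9 evenly spaced points.
    Returns {"positions", "paths" (n_pos, n_t, 2), "mean_path" (n_t, 2),
    "times"}.
    """
    if positions is None:
        positions = np.linspace(fields.x[0], fields.x[-1], 9)
    positions = np.asarray(positions, dtype=float)
    idx = np.searchsorted(fields.x, positions)
    idx = np.clip(idx, 0, fields.x.size - 1)
    paths = np.stack([fields.c6[:, idx].T, fields.c12[:, idx].T], axis=-1)
    mean_path = np.stack([fields.c6.mean(axis=1), fields.c12.mean(axis=1)], axis=-1)
    return {
        "positions": fields.x[idx],
        "paths": paths,
        "mean_path": mean_path,
        "times": fields.times,
    }
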