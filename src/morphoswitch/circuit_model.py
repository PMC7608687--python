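"""ODE model of the two-signal mutual-inhibition (toggle) receiver circuit.

Species (fixed order): LuxR, LasR, LacI, TetR, CFP, YFP.

Two signalling pathways mutually repress each other: the C6 signal (binding
LuxR) drives CFP and LacI, which represses LasR expression; the C12 signal
(binding LasR) drives YFP and TetR, which represses LuxR expression.
Receptor-signal binding is absorbed into a Hill activation scaled by the
receptor level relative to its unrepressed steady state.  Chemical inducers
(IPTG, aTc) reduce the effective concentration of LacI and TetR respectively.

Circuit variants:

``receiver``
    no mutual inhibition -- LuxR and LasR are produced constitutively.
``exclusive_receiver``
    full mutual-inhibition topology.
``relay_c6_to_c12`` / ``relay_c12_to_c6``
    exclusive receiver co-transformed with a synthase relay; intracellular
    dynamics are identical to the exclusive receiver, signal production is
    handled by the spatial simulator through ``k_relay``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "SignalEnvironment",
    "CircuitState",
    "ParamSet",
    "Trajectory",
    "hill_act",
    "hill_rep",
    "effective_repressor",
    "derivatives",
    "rates_vec",
    "integrate",
    "integrate_many",
    "single_pathway_steady_state",
    "default_params",
]

SPECIES = ("luxR", "lasR", "lacI", "tetR", "cfp", "yfp")

VARIANTS = ("receiver", "exclusive_receiver", "relay_c6_to_c12", "relay_c12_to_c6")


class ConfigurationError(ValueError):
    """Raised when a parameter set and a requested operation are inconsistent."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries solver diagnostics."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalEnvironment:
    """Extracellular inputs seen by one cell or one grid point.

    c6, c12 in nM; iptg in uM; atc in ng/mL.  All non-negative and finite.
    """

    c6: float = 0.0
    c12: float = 0.0
    iptg: float = 0.0
    atc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c6", "c12", "iptg", "atc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def replace(self, **kw) -> "SignalEnvironment":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class CircuitState:
    """Intracellular protein levels (a.u.), one value per species."""

    luxR: float = 0.0
    lasR: float = 0.0
    lacI: float = 0.0
    tetR: float = 0.0
    cfp: float = 0.0
    yfp: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.luxR, self.lasR, self.lacI, self.tetR, self.cfp, self.yfp])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CircuitState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"state vector must have length 6, got shape {y.shape}")
        return cls(*[float(v) for v in y])


@dataclass
class ParamSet:
    """All kinetic, regulatory, transport and calibration parameters.

    Units: synthesis rates a.u./h, removal rates 1/h, activation constants
    nM, repression constants a.u., K_iptg uM, K_atc ng/mL, k_relay
    nM/(a.u. h), time h.
    """

    # receptor (LuxR/LasR) expression
    a_r: float = 50.0       # maximal synthesis rate
    b_r: float = 0.5        # basal synthesis rate
    g_r: float = 1.0        # removal (degradation + dilution)
    # regulated reporter/repressor operons (shared production terms)
    a_f: float = 100.0
    b_f: float = 0.5
    g_laci: float = 1.0
    g_tetr: float = 1.0
    g_cfp: float = 0.05     # stable fluorescent proteins: slow dilution only
    g_yfp: float = 0.05
    # signal activation
    K6: float = 20.0
    n6: float = 2.0
    K12: float = 400.0
    n12: float = 1.5
    # mutual repression
    K_lac: float = 4.0
    n_lac: float = 2.5
    K_tet: float = 2.0
    n_tet: float = 3.0
    # inducer binding (derepression)
    K_iptg: float = 20.0
    n_iptg: float = 2.0
    K_atc: float = 20.0
    n_atc: float = 2.0
    # receptor reference levels for activity scaling
    luxR_ref: float = 50.5
    lasR_ref: float = 50.5
    # crosstalk gains (off-target receptor/signal activation), in [0, 1]
    cross_lux_c12: float = 0.0
    cross_las_c6: float = 0.0
    # relay synthase rate (used by the spatial simulator)
    k_relay: float = 2.0
    # constitutive per-cell RFP reference (calibration constant)
    rfp0: float = 100.0
    circuit_variant: str = "exclusive_receiver"

    _POSITIVE = (
        "a_r", "g_r", "a_f", "g_laci", "g_tetr", "g_cfp", "g_yfp",
        "K6", "K12", "K_lac", "K_tet", "K_iptg", "K_atc",
        "luxR_ref", "lasR_ref", "rfp0",
    )
    _HILL = ("n6", "n12", "n_lac", "n_tet", "n_iptg", "n_atc")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {v!r}")
        for name in ("b_r", "b_f", "k_relay"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v!r}")
        for name in self._HILL:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1, got {v!r}")
        for name in ("cross_lux_c12", "cross_las_c6"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"crosstalk gain {name} must lie in [0, 1], got {v!r}")
        if self.circuit_variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown circuit_variant {self.circuit_variant!r}; "
                f"expected one of {VARIANTS}"
            )

    def replace(self, **kw) -> "ParamSet":
        return dataclasses.replace(self, **kw)

    def gammas(self) -> np.ndarray:
        """Removal rates in species order."""
        return np.array(
            [self.g_r, self.g_r, self.g_laci, self.g_tetr, self.g_cfp, self.g_yfp]
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ParamSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """Integrated time course: times (h, strictly increasing) and aligned states."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 6)
    env: SignalEnvironment | Sequence | Callable

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 6):
            raise ValueError("states must have shape (n_times, 6)")

    @property
    def terminal(self) -> CircuitState:
        return CircuitState.from_array(self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{s: self.states[:, i] for i, s in enumerate(SPECIES)}}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regulatory functions
# ---------------------------------------------------------------------------


def _check_conc(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError(f"{name} must be finite and >= 0")
    return x


def hill_act(s, K: float, n: float):
    """Activating Hill function ``s^n / (K^n + s^n)``, in [0, 1]."""
    s = _check_conc(s, "s")
    if K <= 0:
        raise ValueError("K must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    with np.errstate(over="ignore"):
        r = (s / K) ** n
        out = np.where(np.isfinite(r), r / (1.0 + r), 1.0)
    return out if out.ndim else float(out)


def hill_rep(r, K: float, n: float):
    """Repressing Hill function ``K^n / (K^n + r^n)``, in [0, 1]."""
    r = _check_conc(r, "r")
    if K <= 0:
        raise ValueError("K must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    with np.errstate(over="ignore"):
        q = (r / K) ** n
        out = np.where(np.isfinite(q), 1.0 / (1.0 + q), 0.0)
    return out if out.ndim else float(out)


def effective_repressor(total, inducer, K_ind: float, n_ind: float):
    """Repressor concentration remaining active at the given inducer level.

    Equals ``total`` with no inducer and tends to 0 at saturating inducer.
    """
    total = _check_conc(total, "total")
    inducer = np.asarray(inducer, dtype=float)
    if np.any(inducer < 0) or np.any(np.isnan(inducer)):
        raise ValueError("inducer must be >= 0")
    out = total * hill_rep(np.where(np.isfinite(inducer), inducer, 0.0), K_ind, n_ind)
    out = np.where(np.isfinite(inducer), out, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# rate equations
# ---------------------------------------------------------------------------


def pathway_activities(y: np.ndarray, c6, c12, p: ParamSet):
    """Receptor-scaled promoter activities (A6, A12) of the two pathways.

    ``y`` has shape (6, ...); c6/c12 broadcast against the trailing axes.
    """
    h6 = hill_act(c6, p.K6, p.n6)
    h12 = hill_act(c12, p.K12, p.n12)
    a6 = (y[0] / p.luxR_ref) * (h6 + p.cross_lux_c12 * h12)
    a12 = (y[1] / p.lasR_ref) * (h12 + p.cross_las_c6 * h6)
    return a6, a12


def _signal_terms(c6, c12, iptg, atc, p: ParamSet):
    """Precomputed environment-dependent factors (constant while integrating).

    Returns (h6x, h12x, f_iptg, f_atc): crosstalk-combined activation levels
    and the inducer attenuation factors for LacI and TetR.
    """
    h6 = hill_act(c6, p.K6, p.n6)
    h12 = hill_act(c12, p.K12, p.n12)
    h6x = h6 + p.cross_lux_c12 * h12
    h12x = h12 + p.cross_las_c6 * h6
    f_iptg = hill_rep(iptg, p.K_iptg, p.n_iptg)
    f_atc = hill_rep(atc, p.K_atc, p.n_atc)
    return h6x, h12x, f_iptg, f_atc


def _rates_terms(y: np.ndarray, terms, p: ParamSet, scale_f=1.0, scale_r=1.0) -> np.ndarray:
    """RHS given precomputed signal terms; the hot path for all integrators."""
    h6x, h12x, f_iptg, f_atc = terms
    out = np.empty_like(y)
    if p.circuit_variant == "receiver":
        prod_luxr = p.b_r + scale_r * p.a_r + 0.0 * y[0]
        prod_lasr = prod_luxr
    else:
        q_lac = (np.maximum(y[2], 0.0) * (f_iptg / p.K_lac)) ** p.n_lac
        q_tet = (np.maximum(y[3], 0.0) * (f_atc / p.K_tet)) ** p.n_tet
        prod_luxr = p.b_r + scale_r * p.a_r / (1.0 + q_tet)
        prod_lasr = p.b_r + scale_r * p.a_r / (1.0 + q_lac)
    prod6 = p.b_f + scale_f * p.a_f * (y[0] / p.luxR_ref) * h6x
    prod12 = p.b_f + scale_f * p.a_f * (y[1] / p.lasR_ref) * h12x
    out[0] = prod_luxr - p.g_r * y[0]
    out[1] = prod_lasr - p.g_r * y[1]
    out[2] = prod6 - p.g_laci * y[2]
    out[3] = prod12 - p.g_tetr * y[3]
    out[4] = prod6 - p.g_cfp * y[4]
    out[5] = prod12 - p.g_yfp * y[5]
    return out


def rates_vec(y: np.ndarray, c6, c12, iptg, atc, p: ParamSet,
              scale_f=1.0, scale_r=1.0) -> np.ndarray:
    """Vectorised right-hand side.  ``y`` has shape (6,) or (6, N).

    ``scale_f`` / ``scale_r`` multiply the regulated and receptor maximal
    synthesis rates; arrays broadcast against N model cell-to-cell
    variability in expression strength.
    """
    y = np.asarray(y, dtype=float)
    return _rates_terms(y, _signal_terms(c6, c12, iptg, atc, p), p, scale_f, scale_r)


def derivatives(state: CircuitState, env: SignalEnvironment, params: ParamSet) -> CircuitState:
    """Time derivatives (a.u./h) of every species at the given state."""
    y = state.as_array()
    if np.any(y < 0):
        raise ValueError("state concentrations must be >= 0")
    dy = rates_vec(y, env.c6, env.c12, env.iptg, env.atc, params)
    return CircuitState.from_array(dy)


def single_pathway_steady_state(env: SignalEnvironment, params: ParamSet, pathway: str) -> np.ndarray:
    """Steady state assuming only one pathway is expressed.

    The opposing pathway's repressor is pinned at its own-pathway-on value,
    giving the analytic CFP-only / YFP-only candidate states used to seed
    equilibrium searches.
    """
    p = params
    h6 = hill_act(env.c6, p.K6, p.n6) + p.cross_lux_c12 * hill_act(env.c12, p.K12, p.n12)
    h12 = hill_act(env.c12, p.K12, p.n12) + p.cross_las_c6 * hill_act(env.c6, p.K6, p.n6)
    if pathway not in ("c6", "c12"):
        raise ValueError("pathway must be 'c6' or 'c12'")
    # iterate the scalar chain: own repressor high -> other receptor low
    if pathway == "c6":
        laci = (p.b_f + p.a_f * h6) / p.g_laci  # first guess: full expression
        for _ in range(200):
            laci_eff = effective_repressor(laci, env.iptg, p.K_iptg, p.n_iptg)
            lasr = (p.b_r + p.a_r * hill_rep(laci_eff, p.K_lac, p.n_lac)) / p.g_r
            tetr = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_tetr
            tetr_eff = effective_repressor(tetr, env.atc, p.K_atc, p.n_atc)
            luxr = (p.b_r + p.a_r * hill_rep(tetr_eff, p.K_tet, p.n_tet)) / p.g_r
            new = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci
            if abs(new - laci) < 1e-12 * (1 + abs(laci)):
                laci = new
                break
            laci = new
        laci_eff = effective_repressor(laci, env.iptg, p.K_iptg, p.n_iptg)
        lasr = (p.b_r + p.a_r * hill_rep(laci_eff, p.K_lac, p.n_lac)) / p.g_r
        tetr = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_tetr
        tetr_eff = effective_repressor(tetr, env.atc, p.K_atc, p.n_atc)
        luxr = (p.b_r + p.a_r * hill_rep(tetr_eff, p.K_tet, p.n_tet)) / p.g_r
    else:
        tetr = (p.b_f + p.a_f * h12) / p.g_tetr
        for _ in range(200):
            tetr_eff = effective_repressor(tetr, env.atc, p.K_atc, p.n_atc)
            luxr = (p.b_r + p.a_r * hill_rep(tetr_eff, p.K_tet, p.n_tet)) / p.g_r
            laci = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci
            laci_eff = effective_repressor(laci, env.iptg, p.K_iptg, p.n_iptg)
            lasr = (p.b_r + p.a_r * hill_rep(laci_eff, p.K_lac, p.n_lac)) / p.g_r
            new = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_tetr
            if abs(new - tetr) < 1e-12 * (1 + abs(tetr)):
                tetr = new
                break
            tetr = new
        tetr_eff = effective_repressor(tetr, env.atc, p.K_atc, p.n_atc)
        luxr = (p.b_r + p.a_r * hill_rep(tetr_eff, p.K_tet, p.n_tet)) / p.g_r
        laci = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci
        laci_eff = effective_repressor(laci, env.iptg, p.K_iptg, p.n_iptg)
        lasr = (p.b_r + p.a_r * hill_rep(laci_eff, p.K_lac, p.n_lac)) / p.g_r
    if params.circuit_variant == "receiver":
        luxr = lasr = (p.b_r + p.a_r) / p.g_r
        laci = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci
        tetr = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_tetr
    cfp = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_cfp
    yfp = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_yfp
    return np.array([luxr, lasr, laci, tetr, cfp, yfp])


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _normalise_schedule(env, t_end: float):
    """Return a list of (t0, t1, SignalEnvironment) segments covering [0, t_end]."""
    if isinstance(env, SignalEnvironment):
        return [(0.0, t_end, env)]
    segments = []
    env = list(env)
    for i, (t0, e) in enumerate(env):
        t1 = env[i + 1][0] if i + 1 < len(env) else t_end
        if t1 > t0 and t0 < t_end:
            segments.append((t0, min(t1, t_end), e))
    if not segments or segments[0][0] > 0:
        raise ValueError("environment schedule must start at t = 0")
    return segments


def integrate(
    state0: CircuitState | np.ndarray,
    env,
    params: ParamSet,
    t_end: float,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the circuit ODEs to ``t_end`` hours.

    ``env`` is a constant :class:`SignalEnvironment` or a piecewise schedule
    given as a sequence of ``(t_start, SignalEnvironment)`` pairs.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = state0.as_array() if isinstance(state0, CircuitState) else np.asarray(state0, float)
    segments = _normalise_schedule(env, t_end)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = y0.copy()
    for (t0, t1, e) in segments:
        def rhs(t, yy, e=e):
            return rates_vec(np.maximum(yy, 0.0), e.c6, e.c12, e.iptg, e.atc, params)

        wanted = t_eval[(t_eval >= t0) & (t_eval < t1)]
        # always solve through t1 so the next segment starts from its end state
        pts = np.unique(np.concatenate([wanted, [t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol, t_eval=pts,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        keep = np.isin(sol.t, wanted) if t1 < t_end else np.isin(sol.t, pts)
        times_out.append(sol.t[keep])
        states_out.append(sol.y.T[keep])
        y = np.maximum(sol.y[:, -1], 0.0)

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    states = np.maximum(states, 0.0)
    # deduplicate identical segment-boundary times
    uniq = np.concatenate([[True], np.diff(times) > 0])
    return Trajectory(times[uniq], states[uniq], env)


def integrate_many(
    y0: np.ndarray,
    c6,
    c12,
    iptg,
    atc,
    params: ParamSet,
    t_end: float,
    dt: float = 0.02,
    scale_f=1.0,
    scale_r=1.0,
) -> np.ndarray:
    """Fixed-step RK4 for many independent cells at once.

    ``y0`` has shape (6, N); signal arguments and synthesis-rate scalings
    broadcast against N.  Returns the terminal states, shape (6, N).  Used
    where thousands of cells or grid points share a clock (hysteresis
    grids, flow samples, RD reaction substeps); the dynamics are non-stiff
    at the default rates.
    """
    y = np.array(y0, dtype=float)
    n_steps = max(1, int(math.ceil(t_end / dt)))
    h = t_end / n_steps
    terms = _signal_terms(c6, c12, iptg, atc, params)
    for _ in range(n_steps):
        k1 = _rates_terms(y, terms, params, scale_f, scale_r)
        k2 = _rates_terms(y + 0.5 * h * k1, terms, params, scale_f, scale_r)
        k3 = _rates_terms(y + 0.5 * h * k2, terms, params, scale_f, scale_r)
        k4 = _rates_terms(y + h * k3, terms, params, scale_f, scale_r)
        y += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.maximum(y, 0.0, out=y)
    return y


def default_params(variant: str = "exclusive_receiver") -> ParamSet:
    """The default calibrated parameter set (see scripts/calibrate.py)."""
    return ParamSet(circuit_variant=variant)
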