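"""Shared fixtures and the independent scalar-chain equilibrium oracle."""

from __future__ import annotations

import numpy as np
import pytest

from morphoswitch.circuit_model import ParamSet, SignalEnvironment, default_params


@pytest.fixture(scope="session")
def params() -> ParamSet:
    return default_params()


@pytest.fixture(scope="session")
def receiver_params() -> ParamSet:
    return default_params("receiver")


def chain_stable_count(c6: float, c12: float, iptg: float, p: ParamSet,
                       n_grid: int = 4000) -> int:
    """Stable-equilibrium count by brute-force scalar root scanning.

    Independent oracle: at steady state all species are slaved to LacI, so
    fixed points are sign changes of a scalar map on a dense log grid --
    no Newton iteration, no Jacobian, no continuation involved.
    """
    a6 = float(c6 ** p.n6 / (p.K6 ** p.n6 + c6 ** p.n6)) if c6 > 0 else 0.0
    a12 = float(c12 ** p.n12 / (p.K12 ** p.n12 + c12 ** p.n12)) if c12 > 0 else 0.0
    h6 = a6 + p.cross_lux_c12 * a12
    h12 = a12 + p.cross_las_c6 * a6
    fi = 1.0 / (1.0 + (iptg / p.K_iptg) ** p.n_iptg)
    umax = (p.b_f + p.a_f) / p.g_laci
    us = np.concatenate([[0.0], np.geomspace(1e-7 * umax, 1.5 * umax, n_grid)])
    if p.circuit_variant == "receiver":
        luxr = np.full_like(us, (p.b_r + p.a_r) / p.g_r)
        G = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci - us
    else:
        lasr = (p.b_r + p.a_r / (1 + (us * fi / p.K_lac) ** p.n_lac)) / p.g_r
        v = (p.b_f + p.a_f * (lasr / p.lasR_ref) * h12) / p.g_tetr
        luxr = (p.b_r + p.a_r / (1 + (v / p.K_tet) ** p.n_tet)) / p.g_r
        G = (p.b_f + p.a_f * (luxr / p.luxR_ref) * h6) / p.g_laci - us
    sgn = np.sign(G)
    n_roots = int(np.sum(sgn[:-1] * sgn[1:] < 0))
    return {1: 1, 3: 2, 5: 3}.get(n_roots, max(1, (n_roots + 1) // 2))


@pytest.fixture(scope="session")
def chain_oracle():
    return chain_stable_count
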