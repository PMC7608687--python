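"""Kymograph normalization, boundary location and S/M/N classification.

The boundary is the locus of equal normalized CFP and YFP intensity.  A run
is classified static (S) if the boundary's displacement between first
detectability and the end of the observation is under a fixed fraction of
the domain (default 10%), moving (M) otherwise, and not-present (N) when no
valid boundary exists at the final time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Kymograph",
    "BoundaryTrace",
    "normalize_channels",
    "locate_boundary",
    "classify_boundary",
]


@dataclass
class Kymograph:
    """Normalized CFP/YFP intensities on a (time, space) grid; values in [0, 1]."""

    x: np.ndarray        # (n_x,) mm
    times: np.ndarray    # (n_t,) h
    cfp: np.ndarray      # (n_t, n_x)
    yfp: np.ndarray      # (n_t, n_x)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        shape = (self.times.size, self.x.size)
        if self.cfp.shape != shape or self.yfp.shape != shape:
            raise ValueError("channel arrays must have shape (n_times, n_x)")

    @property
    def L(self) -> float:
        """Domain size spanned by the grid."""
        if self.x.size < 2:
            return 0.0
        dx = self.x[1] - self.x[0]
        return float(self.x[-1] - self.x[0] + dx)


@dataclass
class BoundaryTrace:
    """Equal-fluorescence boundary position over time.

    ``beta`` is NaN where no valid crossing exists.  ``delta_beta`` is the
    distance between the boundary at the last valid time and at first
    detectability.
    """

    times: np.ndarray
    beta: np.ndarray
    t_det: float | None
    delta_beta: float
    label: str | None = None          # set by classify_boundary
    dominant: str | None = None
    # terminal snapshot used for dominance calls
    final_cfp_mean: float = 0.0
    final_yfp_mean: float = 0.0
    final_cfp_domain_frac: float = 0.0

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.beta)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "beta": self.beta})


def normalize_channels(source) -> Kymograph:
    """Normalize each channel by its own global (space x time) maximum.

    ``source`` is a :class:`~morphoswitch.spatial.SpatialFields`, an existing
    :class:`Kymograph`, or a tuple ``(x, times, cfp, yfp)`` of raw arrays.
    An identically-zero channel stays zero; the operation is idempotent.
    """
    if hasattr(source, "cfp") and hasattr(source, "x") and hasattr(source, "times"):
        x, times = source.x, source.times
        cfp = np.asarray(source.cfp, dtype=float)
        yfp = np.asarray(source.yfp, dtype=float)
    else:
        x, times, cfp, yfp = source
        cfp = np.asarray(cfp, dtype=float)
        yfp = np.asarray(yfp, dtype=float)
    if np.any(cfp < 0) or np.any(yfp < 0):
        raise ValueError("intensities must be >= 0")
    cmax, ymax = cfp.max(initial=0.0), yfp.max(initial=0.0)
    return Kymograph(
        x=np.asarray(x, dtype=float),
        times=np.asarray(times, dtype=float),
        cfp=cfp / cmax if cmax > 0 else cfp.copy(),
        yfp=yfp / ymax if ymax > 0 else yfp.copy(),
    )


def _crossings_at(x, d, cfp, yfp, threshold):
    """Valid equal-intensity crossings at one time point.

    A crossing between grid cells i, i+1 needs a sign change of d = cfp - yfp
    and both channels detectable (>= threshold) within one cell of it.
    """
    out = []
    sign = np.sign(d)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        win = slice(max(i - 1, 0), min(i + 3, x.size))
        if cfp[win].max() < threshold or yfp[win].max() < threshold:
            continue
        frac = d[i] / (d[i] - d[i + 1])
        out.append(x[i] + frac * (x[i + 1] - x[i]))
    # exact zeros spanning a plateau: treat the midpoint of each zero run
    zero_runs = np.flatnonzero((sign == 0))
    if zero_runs.size and not out:
        i = zero_runs[zero_runs.size // 2]
        win = slice(max(i - 1, 0), min(i + 2, x.size))
        if cfp[win].max() >= threshold and yfp[win].max() >= threshold:
            out.append(float(x[i]))
    return out


def locate_boundary(kymo: Kymograph, detection_threshold: float = 0.1) -> BoundaryTrace:
    """Track the equal-normalized-fluorescence position over time.

    Among multiple crossings the one nearest the previous boundary wins
    (nearest the domain centre at the first valid time).  Absence of a valid
    crossing is encoded as NaN, never an error.
    """
    if not 0 < detection_threshold < 1:
        raise ValueError("detection_threshold must lie in (0, 1)")
    n_t = kymo.times.size
    beta = np.full(n_t, np.nan)
    centre = 0.5 * (kymo.x[0] + kymo.x[-1])
    prev = None
    for k in range(n_t):
        cands = _crossings_at(
            kymo.x, kymo.cfp[k] - kymo.yfp[k], kymo.cfp[k], kymo.yfp[k],
            detection_threshold,
        )
        if not cands:
            continue
        ref = centre if prev is None else prev
        beta[k] = min(cands, key=lambda c: abs(c - ref))
        prev = beta[k]

    valid = np.flatnonzero(~np.isnan(beta))
    if valid.size:
        t_det = float(kymo.times[valid[0]])
        delta = float(abs(beta[valid[-1]] - beta[valid[0]]))
    else:
        t_det, delta = None, 0.0

    cfp_end, yfp_end = kymo.cfp[-1], kymo.yfp[-1]
    return BoundaryTrace(
        times=kymo.times.copy(),
        beta=beta,
        t_det=t_det,
        delta_beta=delta,
        final_cfp_mean=float(cfp_end.mean()),
        final_yfp_mean=float(yfp_end.mean()),
        final_cfp_domain_frac=float(np.mean(cfp_end > yfp_end)),
    )


def classify_boundary(trace: BoundaryTrace, L: float, stable_fraction: float = 0.10) -> BoundaryTrace:
    """Assign the S/M/N label and dominant channel to a boundary trace.

    N: no valid boundary at the final time (dominant from terminal channel
    means, "neither" when they differ by < 0.05).  S: displacement below
    ``stable_fraction * L``.  M: otherwise.  For S/M the dominant channel is
    the one occupying the larger terminal domain.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    trace = BoundaryTrace(**{k: getattr(trace, k) for k in trace.__dataclass_fields__})
    if np.isnan(trace.beta[-1]):
        trace.label = "N"
        diff = trace.final_cfp_mean - trace.final_yfp_mean
        if abs(diff) < 0.05:
            trace.dominant = "neither"
        else:
            trace.dominant = "CFP" if diff > 0 else "YFP"
        return trace
    trace.label = "S" if trace.delta_beta < stable_fraction * L else "M"
    trace.dominant = "CFP" if trace.final_cfp_domain_frac > 0.5 else "YFP"
    return trace
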