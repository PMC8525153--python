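"""Logicle (biexponential) scale and automatic parameter estimation.

The logicle scale maps raw cytometry counts onto display decades: linear
around zero (width ``W`` decades) and logarithmic at high signal, over ``M``
total decades with top-of-scale ``T`` and ``A`` extra negative decades.  The
forward map here is the analytic *biexponential* ``B(y)`` (decades -> raw);
``logicle`` is its numerical inverse.  All downstream positivity calls
(threshold >= 1) are made on this transformed scale.

Automatic estimation ("autoLgcl") sets, per channel, ``T`` to the channel
maximum, ``M = 4.5``, ``A = 0`` and derives ``W`` from a low quantile of the
channel's negative values, falling back to ``W = 0.25`` when the channel has
none (the usual case for mass cytometry, whose dual counts are non-negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .panel_io import Cohort

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class LogicleParams:
    """Logicle parameter quadruple (T, M, W, A).

    T > 0 raw top of scale; M > 0 total decades; 0 <= W <= M/2 linearization
    width; A >= 0 additional negative decades.
    """

    T: float
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > 0 and np.isfinite(self.T)):
            raise ValueError(f"T must be positive, got {self.T}")
        if not (self.M > 0):
            raise ValueError(f"M must be positive, got {self.M}")
        if not (0.0 <= self.W <= self.M / 2):
            raise ValueError(f"W={self.W} outside [0, M/2]")
        if not (self.A >= 0):
            raise ValueError(f"A must be >= 0, got {self.A}")

    @property
    def p0(self) -> float:
        """Solution of W = 2 p0 log10(p0) / (p0 + 1); p0 = 1 when W = 0."""
        if self.W < 1e-9:  # g(p0) ~ (p0-1)/ln10 near 1; avoid a void bracket
            return 1.0
        w = self.W

        def g(p: float) -> float:
            return 2.0 * p * np.log10(p) / (p + 1.0) - w

        return brentq(g, 1.0 + 1e-12, 1e9, xtol=1e-12, rtol=1e-14)


def biexponential(y: float | np.ndarray, p: LogicleParams) -> np.ndarray:
    """Raw value B(y) at transformed position ``y`` decades.

    For y >= W + A:
        B(y) = T * 10^{-(M-W)} * (10^z - p0^2 * 10^{-z/p0} + p0^2 - 1),
    with z = y - W - A; for y below the symmetry centre W + A the curve is
    continued by odd symmetry, so B(W + A) = 0 and B is strictly increasing.
    """
    y = np.asarray(y, dtype=float)
    p0 = p.p0
    centre = p.W + p.A
    z = np.abs(y - centre)
    scale = p.T * 10.0 ** (-(p.M - p.W))
    core = scale * (10.0 ** z - p0 * p0 * 10.0 ** (-z / p0) + p0 * p0 - 1.0)
    out = np.sign(y - centre) * core
    return out if out.ndim else float(out)


def logicle(x: float | np.ndarray, p: LogicleParams,
            tol: float = 1e-8) -> np.ndarray:
    """Transformed position (decades) of raw value ``x``: inverse of B.

    Bracketed bisection on [-A - 1, M + A + 3] to ``tol`` decades; vectorized.
    Values above the bracket's image (raw > ~1000 T) are a hard error.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo = np.full(x.shape, -p.A - 1.0)
    hi = np.full(x.shape, p.M + p.A + 3.0)
    if np.any(x > biexponential(hi[0], p)) or np.any(x < biexponential(lo[0], p)):
        bad = x[(x > biexponential(hi[0], p)) | (x < biexponential(lo[0], p))]
        raise ValueError(
            f"logicle inversion out of bracket for values like {bad[:3]}"
        )
    n_iter = int(np.ceil(np.log2((hi[0] - lo[0]) / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_low = biexponential(mid, p) < x
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    y = 0.5 * (lo + hi)
    return float(y[0]) if scalar else y


def estimate_autolgcl(channel_values: np.ndarray, m: float = 4.5,
                      quantile_q: float = 0.05,
                      w_fallback: float = 0.25) -> LogicleParams:
    """Automatic logicle parameters for one channel.

    T = channel maximum, M = ``m``, A = 0; W derived from the ``quantile_q``
    quantile ``r`` of the channel's strictly negative values as
    ``W = (M - log10(T / |r|)) / 2`` (clamped to [0, M/2]), or ``w_fallback``
    when no negatives exist.
    """
    v = np.asarray(channel_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0 or v.max() <= v.min():
        raise ValueError("degenerate channel: all values equal")
    T = float(v.max())
    if T <= 0:
        raise ValueError("channel has no positive values")
    neg = v[v < 0]
    if neg.size:
        r = float(np.quantile(neg, quantile_q))
        W = (m - np.log10(T / abs(r))) / 2.0
    else:
        W = w_fallback
    W = float(np.clip(W, 0.0, m / 2.0))
    return LogicleParams(T=T, M=m, W=W, A=0.0)


def transform_cohort(c: Cohort, m: float = 4.5, quantile_q: float = 0.05,
                     w_fallback: float = 0.25,
                     return_params: bool = False):
    """Merge-then-transform: per-channel autoLgcl on the pooled events.

    Parameters are estimated once per channel on the events of *all* samples
    pooled together, then applied to every sample, so a given raw intensity
    maps to the same decade everywhere in the cohort.
    """
    for s in c.samples:
        if s.scale_state != "raw":
            raise ValueError(f"sample {s.sample_id} is not raw-scale")
    markers = c.panel.marker_names
    pooled = np.vstack([s.data.to_numpy(dtype=float) for s in c.samples])
    params = {mk: estimate_autolgcl(pooled[:, j], m=m, quantile_q=quantile_q,
                                    w_fallback=w_fallback)
              for j, mk in enumerate(markers)}
    for mk, pr in params.items():
        logger.info("autoLgcl %-10s T=%.1f M=%.2f W=%.4f A=%.1f",
                    mk, pr.T, pr.M, pr.W, pr.A)
    new_samples = []
    for s in c.samples:
        vals = s.data.to_numpy(dtype=float)
        out = np.empty_like(vals)
        for j, mk in enumerate(markers):
            out[:, j] = logicle(vals[:, j], params[mk])
        new_samples.append(s.with_values(out, "transformed"))
    cohort = Cohort(samples=new_samples, panel=c.panel)
    if return_params:
        table = pd.DataFrame(
            [(mk, pr.T, pr.M, pr.W, pr.A) for mk, pr in params.items()],
            columns=["channel", "T", "M", "W", "A"],
        )
        return cohort, table
    return cohort
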