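"""Energetic cost model linking the maximum growth rate r to carrying capacity K.

A growing population pays two kinds of energetic cost: a maintenance cost
``a`` per cell per hour, which accrues over the generation time T = ln2/r,
and a fixed cost ``b`` to build each new cell.  Faster ATP production is
less efficient, which is captured by a decreasing efficiency function
f(r) on [0, r_max].  The resource consumed per cell per generation when the
population is far below carrying capacity is then

    C(r) = (a ln2 / r + b) / f(r)

With a fixed total amount of resource, a larger C means fewer generations of
growth and hence a smaller K, so the sign of dC/dr determines whether a
mutation that raises r also raises K (trade-up, dC/dr < 0) or lowers it
(tradeoff, dC/dr > 0).  For any a > 0 and decreasing f, C falls at very low
r (maintenance dominates) and rises near r_max (efficiency collapses), so an
interior cost minimum r_star separates the trade-up and tradeoff regimes.

The default efficiency family is f(r) = 1 - (r/r_max)^w with w > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .exceptions import ConfigurationError, MultimodalCostError, NoInteriorMinimumError

LN2 = float(np.log(2.0))

__all__ = [
    "CostParams",
    "efficiency",
    "cost",
    "cost_derivative",
    "find_cost_minimum",
    "predict_K_proxy",
    "simulate_resource_depletion",
    "cost_curve",
]


@dataclass(frozen=True)
class CostParams:
    """Parameters of the per-generation resource cost model.

    a      -- maintenance energy per cell per hour (>= 0)
    b      -- energy to produce one new cell (> 0)
    r_max  -- maximum possible per-capita growth rate, per hour (> 0)
    w      -- exponent of the power-law efficiency family (> 0)
    f      -- optional user-supplied efficiency function on [0, r_max];
              must be decreasing with f(0) <= 1 and f >= 0.  When given, it
              replaces the power-law family and derivatives are taken
              numerically.
    """

    a: float = 0.01
    b: float = 1.0
    r_max: float = 0.5
    w: float = 3.0
    f: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ConfigurationError(f"maintenance cost a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise ConfigurationError(f"division cost b must be > 0, got {self.b}")
        if self.r_max <= 0:
            raise ConfigurationError(f"r_max must be > 0, got {self.r_max}")
        if self.w <= 0:
            raise ConfigurationError(f"exponent w must be > 0, got {self.w}")


def _check_domain(r, params: CostParams, open_interval: bool) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if open_interval:
        bad = (r <= 0) | (r >= params.r_max)
    else:
        bad = (r < 0) | (r > params.r_max)
    if np.any(bad):
        kind = "(0, r_max)" if open_interval else "[0, r_max]"
        raise ConfigurationError(f"r must lie in {kind} with r_max={params.r_max}")
    return r


def efficiency(r, params: CostParams = CostParams()):
    """Resource-use efficiency f(r) in [0, 1] for r in [0, r_max]."""
    r = _check_domain(r, params, open_interval=False)
    if params.f is not None:
        out = np.asarray(params.f(r), dtype=float)
    else:
        out = 1.0 - (r / params.r_max) ** params.w
    return out if out.ndim else float(out)


def cost(r, params: CostParams = CostParams()):
    """Per-cell per-generation resource cost C(r) = (a ln2/r + b)/f(r)."""
    r = _check_domain(r, params, open_interval=True)
    c = (params.a * LN2 / r + params.b) / efficiency(r, params)
    return c if np.ndim(c) else float(c)


def _f_prime(r, params: CostParams):
    if params.f is None:
        return -params.w * r ** (params.w - 1.0) / params.r_max ** params.w
    # central difference for user-supplied f
    h = 1e-7 * params.r_max
    lo = np.maximum(np.asarray(r) - h, 0.0)
    hi = np.minimum(np.asarray(r) + h, params.r_max)
    return (np.asarray(params.f(hi)) - np.asarray(params.f(lo))) / (hi - lo)


def cost_derivative(r, params: CostParams = CostParams()):
    """Analytic dC/dr on (0, r_max).

    dC/dr = [-a ln2 f(r)/r^2 - f'(r)(a ln2/r + b)] / f(r)^2
    """
    r = _check_domain(r, params, open_interval=True)
    fr = efficiency(r, params)
    fp = _f_prime(r, params)
    num = -params.a * LN2 * fr / r**2 - fp * (params.a * LN2 / r + params.b)
    out = num / fr**2
    return out if np.ndim(out) else float(out)


def find_cost_minimum(
    params: CostParams = CostParams(),
    tol: float = 1e-6,
    n_scan: int = 1000,
) -> float:
    """Locate the interior minimum r_star of C(r) on (0, r_max).

    A coarse scan of the derivative brackets every sign change; a single
    -to+ crossing is refined by root finding (Brent) to ``tol``.  No
    crossing means C is monotone on the interval and the minimum sits on
    the boundary, which is signalled with :class:`NoInteriorMinimumError`;
    more than one crossing is signalled with :class:`MultimodalCostError`
    rather than silently returning one of them.
    """
    eps = 1e-4 * params.r_max
    grid = np.linspace(eps, params.r_max - eps, n_scan)
    d = np.asarray(cost_derivative(grid, params))
    sign = np.sign(d)
    crossings = np.nonzero((sign[:-1] < 0) & (sign[1:] > 0))[0]
    if len(crossings) == 0:
        raise NoInteriorMinimumError(
            "dC/dr has no - to + sign change on (0, r_max); boundary minimum"
        )
    if len(crossings) > 1:
        raise MultimodalCostError(
            f"{len(crossings)} interior minima detected on (0, r_max)"
        )
    i = crossings[0]
    if params.f is None:
        r_star = float(brentq(lambda x: cost_derivative(x, params), grid[i], grid[i + 1], xtol=tol))
    else:
        res = minimize_scalar(
            lambda x: cost(x, params), bounds=(grid[max(i - 1, 0)], grid[min(i + 2, n_scan - 1)]),
            method="bounded", options={"xatol": tol},
        )
        r_star = float(res.x)
    return r_star


def predict_K_proxy(r, params: CostParams = CostParams(), R_total: float = 1.0):
    """Carrying-capacity proxy K = R_total / C(r) for a fixed resource pool.

    Monotone decreasing in C, so it peaks at r_star: raising r below r_star
    raises the proxy (trade-up) and lowering it above r_star lowers it
    (tradeoff).
    """
    if R_total <= 0:
        raise ConfigurationError(f"R_total must be > 0, got {R_total}")
    out = R_total / np.asarray(cost(r, params))
    return out if np.ndim(out) else float(out)


def simulate_resource_depletion(
    r: float,
    params: CostParams = CostParams(),
    R_total: float = 1.0,
    N0: float = 1.0,
) -> float:
    """Emergent carrying capacity from discrete-generation resource depletion.

    Operates in the N << K regime where every cell pays C = C(r) per
    generation and the population doubles while the resource lasts; the last
    partial generation is pro-rated (each unit of remaining resource buys
    1/C new cells).  Returns the final population size.
    """
    if N0 < 1:
        raise ConfigurationError(f"N0 must be >= 1, got {N0}")
    if R_total < 0:
        raise ConfigurationError(f"R_total must be >= 0, got {R_total}")
    c = cost(r, params)
    # invariant of the underlying balance: C * f(r) == a ln2 / r + b
    assert abs(c * efficiency(r, params) - (params.a * LN2 / r + params.b)) <= 1e-9 * c
    N = float(N0)
    resource = float(R_total)
    while resource >= N * c:
        resource -= N * c
        N *= 2.0
    N += resource / c
    return N


def cost_curve(params: CostParams = CostParams(), n_grid: int = 1000):
    """Evaluate (r, f, C, dC/dr) on an interior grid; used by the CLI."""
    eps = 1e-4 * params.r_max
    r = np.linspace(eps, params.r_max - eps, n_grid)
    return r, np.asarray(efficiency(r, params)), np.asarray(cost(r, params)), np.asarray(
        cost_derivative(r, params)
    )
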