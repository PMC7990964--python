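"""Sensory encoding of the electroshock and low-pass trace dynamics.

The shock voltage ``S`` maps to an internal representation ``s`` via the
Weber-Fechner law ``s = alpha * log(S / S0)`` (or, alternatively, Stevens'
power law ``s = (S / S0)**alpha``), with ``s = 0`` below the minimal
detectable strength ``S0``.  The behavioral performance index of a pure
shock test is parametrized as

    PI(S) = (1 - (S0/S)**alpha) / (1 + (S0/S)**alpha),   S >= S0,

which under the Weber-Fechner law equals ``2*p_us(s) - 1`` with the logistic
avoidance probability ``p_us(s) = 1/(1+exp(-s))``.

Eligibility traces (the low-pass-filtered odor and shock signals feeding the
plasticity rules) follow ``tau * dx/dt = -x + input`` and are discretized
with the exact exponential update, so the filter output is dt-robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "EncodingParams",
    "shock_to_internal",
    "performance_index_of_strength",
    "low_pass",
]


@dataclass
class EncodingParams:
    """Parameters of the shock-to-internal mapping and the eligibility traces.

    Attributes
    ----------
    S0 : float
        Minimal detectable shock strength (V), > 0.
    alpha : float
        Sensitivity scaling of the internal representation, > 0.
    tau_o : float
        Odor eligibility-trace time constant (s), > 0.
    tau_s : float or None
        Shock-trace time constant (s); used by the STDP and covariance rules.
    law : {'weber_fechner', 'stevens'}
    """

    S0: float
    alpha: float
    tau_o: float
    tau_s: float | None = None
    law: str = "weber_fechner"

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau_o <= 0:
            raise ValueError("tau_o must be positive")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.law not in ("weber_fechner", "stevens"):
            raise ValueError(f"unknown law {self.law!r}")


def shock_to_internal(S, params: EncodingParams):
    """Internal shock representation ``s(S)`` (dimensionless, >= 0).

    Below the detection threshold ``S0`` the representation is 0 for both
    laws (for the Stevens variant the limit from the definition would be 1;
    returning 0 keeps the sub-threshold behavior consistent).
    """
    S = np.asarray(S, dtype=float)
    above = S >= params.S0
    ratio = np.where(above, S / params.S0, 1.0)
    if params.law == "weber_fechner":
        s = params.alpha * np.log(ratio)
    else:
        s = np.where(above, ratio ** params.alpha, 0.0)
    out = np.where(above, s, 0.0)
    return float(out) if out.ndim == 0 else out


def performance_index_of_strength(S, params: EncodingParams):
    """Parametrized performance index PI(S) of the pure-shock avoidance test.

    PI(S0) = 0 and PI grows monotonically towards 1 for large S; below
    threshold the index is 0.
    """
    S = np.asarray(S, dtype=float)
    above = S >= params.S0
    r = np.where(above, params.S0 / np.where(S > 0, S, 1.0), 1.0) ** params.alpha
    out = np.where(above, (1.0 - r) / (1.0 + r), 0.0)
    return float(out) if out.ndim == 0 else out


def low_pass(trace, tau: float, dt: float, initial: float = 0.0) -> np.ndarray:
    """Exponentially filter a uniformly sampled signal.

    Solves ``tau * dx/dt = -x + u`` exactly under the convention that the
    input sample ``u[i]`` is held constant over ``[t_i, t_i + dt)``: the
    returned array satisfies ``x[0] == initial`` and

        x[i+1] = x[i] * exp(-dt/tau) + u[i] * (1 - exp(-dt/tau)).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(trace, dtype=float)
    a = np.exp(-dt / tau)
    out = np.empty_like(u)
    out[0] = initial
    if len(u) > 1:
        filtered, _ = lfilter([1.0 - a], [1.0, -a], u[:-1], zi=np.array([a * initial]))
        out[1:] = filtered
    return out
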