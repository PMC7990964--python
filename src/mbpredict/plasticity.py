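"""The five synaptic plasticity rules and their integration over protocols.

The single learned quantity is the KC-to-MBON synaptic weight ``w`` driving
the odor value ``v = w * o``.  Weight dynamics, per rule (all quantities are
behavioral-timescale analog traces; ``~x`` denotes the low-pass filter of x):

=================  ====================================================
predictive         dw/dt = eta * (s - v) * ~o          (error correcting)
hebbian            dw/dt = eta * s * ~o                (pure association)
stdp_linear        dw/dt = eta1 * s * ~o - eta2 * ~s * o
stdp_nonlinear     dw/dt = eta1*tanh(alpha1*~o*s) - eta2*tanh(alpha2*o*~s)
covariance         dw/dt = eta * (s - ~s) * (o - ~o)
=================  ====================================================

The learning rate may adapt: a step increase of the shock representation
``s`` bumps ``eta`` by ``delta_eta * max(ds, 0)`` and ``eta`` otherwise
decays with time constant ``tau_eta``; the two STDP branches carry one rate
process each.  Integration is explicit Euler for ``w`` with exact
exponential updates for the filters and the rate decay (dt = 0.01 s default,
convergent under dt halving).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .encoding import EncodingParams, shock_to_internal
from .protocols import StimulusProtocol

__all__ = [
    "RULES",
    "PlasticityParams",
    "SimulationTrace",
    "dw_predictive",
    "dw_hebbian",
    "dw_stdp_linear",
    "dw_stdp_nonlinear",
    "dw_covariance",
    "step_learning_rate",
    "integrate",
    "BatteryArrays",
    "pack_battery",
    "battery_weights",
    "paper_fit",
]

RULES = ("predictive", "hebbian", "stdp_linear", "stdp_nonlinear", "covariance")
_RULE_ID = {name: i for i, name in enumerate(RULES)}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class PlasticityParams:
    """Parameter set of one plasticity rule.

    Only the fields relevant for the selected ``rule`` are used.  With
    ``adaptive_rate`` the learning rate(s) start at ``eta_init`` (0 for a
    naive fly: all drive comes from shock onsets) and follow the jump/decay
    dynamics; otherwise ``eta`` (and ``eta2`` for the STDP branches) are
    constants.
    """

    rule: str
    encoding: EncodingParams
    adaptive_rate: bool = True
    # fixed-rate parameters
    eta: float = 0.0
    eta2: float = 0.0
    # adaptive-rate parameters (branch 1 doubles as the single rate process)
    delta_eta: float = 0.0
    tau_eta: float = 1.0
    delta_eta2: float = 0.0
    tau_eta2: float = 1.0
    # nonlinear-STDP gains
    alpha1: float = 1.0
    alpha2: float = 1.0
    eta_init: float = 0.0
    clip_weight: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if self.adaptive_rate and (self.tau_eta <= 0 or self.tau_eta2 <= 0):
            raise ValueError("tau_eta must be positive for adaptive rates")
        if self.rule in ("stdp_linear", "stdp_nonlinear", "covariance") \
                and self.encoding.tau_s is None:
            raise ValueError(f"{self.rule} requires encoding.tau_s")

    @property
    def rule_id(self) -> int:
        return _RULE_ID[self.rule]

    def replace(self, **kw) -> "PlasticityParams":
        return replace(self, **kw)


#: free-parameter counts entering the AIC comparison, per rule
FREE_PARAMETER_COUNTS = {
    "predictive": 5,       # S0, alpha, tau_o, delta_eta, tau_eta
    "hebbian": 5,          # S0, alpha, tau_o, delta_eta, tau_eta
    "stdp_linear": 8,      # + tau_s and a second rate process
    "stdp_nonlinear": 10,  # + alpha1, alpha2
    "covariance": 6,       # S0, alpha, tau_o, tau_s, delta_eta, tau_eta
}


def paper_fit(rule: str, adaptive: bool = True) -> PlasticityParams:
    """The published best-fit parameter set for ``rule``.

    ``adaptive=True`` returns the adaptive-learning-rate variant (the one
    entering the AIC comparison); ``adaptive=False`` the fixed-rate fit
    where one was reported.
    """
    if rule == "predictive":
        return PlasticityParams(
            "predictive", EncodingParams(S0=6.90, alpha=0.79, tau_o=14.25),
            adaptive_rate=True, delta_eta=0.057, tau_eta=133.48)
    if rule == "hebbian":
        if adaptive:
            return PlasticityParams(
                "hebbian", EncodingParams(S0=5.08, alpha=0.05, tau_o=1.50),
                adaptive_rate=True, delta_eta=5.46, tau_eta=49.81)
        # fixed-rate fit reports the product alpha*eta = 0.0723 with
        # S0 = 7 V and tau_o = 15 s; we adopt the alpha = 1 convention.
        return PlasticityParams(
            "hebbian", EncodingParams(S0=7.0, alpha=1.0, tau_o=15.0),
            adaptive_rate=False, eta=0.0723)
    if rule == "stdp_linear":
        if adaptive:
            return PlasticityParams(
                "stdp_linear",
                EncodingParams(S0=3.20, alpha=0.31, tau_o=8.29, tau_s=171.05),
                adaptive_rate=True, delta_eta=0.39, tau_eta=16.01,
                delta_eta2=5.71, tau_eta2=5.78)
        return PlasticityParams(
            "stdp_linear",
            EncodingParams(S0=9.31, alpha=0.23, tau_o=7.47, tau_s=17.87),
            adaptive_rate=False, eta=-0.47, eta2=-0.47)
    if rule == "stdp_nonlinear":
        if adaptive:
            return PlasticityParams(
                "stdp_nonlinear",
                EncodingParams(S0=3.21, alpha=0.13, tau_o=8.30, tau_s=171.10),
                adaptive_rate=True, delta_eta=8.96, tau_eta=16.02,
                delta_eta2=5.14, tau_eta2=5.82, alpha1=0.24, alpha2=6.05)
        return PlasticityParams(
            "stdp_nonlinear",
            EncodingParams(S0=11.91, alpha=9.93, tau_o=51.20, tau_s=124.12),
            adaptive_rate=False, eta=0.01, eta2=0.19, alpha1=9.93, alpha2=0.44)
    if rule == "covariance":
        if adaptive:
            return PlasticityParams(
                "covariance",
                EncodingParams(S0=3.68, alpha=0.12, tau_o=37.70, tau_s=1498.38),
                adaptive_rate=True, delta_eta=1.00, tau_eta=60.54)
        return PlasticityParams(
            "covariance",
            EncodingParams(S0=9.13, alpha=0.53, tau_o=300.00, tau_s=19.18),
            adaptive_rate=False, eta=0.12)
    raise ValueError(f"unknown rule {rule!r}")


#: circuit-level simulations use a faster learning-rate process
FIG6B_RATE = {"delta_eta": 0.74, "tau_eta": 26.7}


# ---------------------------------------------------------------------------
# instantaneous rule right-hand sides (reference forms, used in tests/docs)
# ---------------------------------------------------------------------------


def dw_predictive(s, v, o_tilde, eta):
    """Error-correcting update ``eta * (s - v) * ~o``."""
    return eta * (s - v) * o_tilde


def dw_hebbian(s, o_tilde, eta):
    """Pure associative update ``eta * s * ~o`` (never negative for s,~o,eta >= 0)."""
    return eta * s * o_tilde


def dw_stdp_linear(s, s_tilde, o, o_tilde, eta1, eta2):
    """Linear stimulus-timing-dependent update ``eta1*s*~o - eta2*~s*o``."""
    return eta1 * s * o_tilde - eta2 * s_tilde * o


def dw_stdp_nonlinear(s, s_tilde, o, o_tilde, eta1, eta2, alpha1, alpha2):
    """Saturating STDP update, bounded by |eta1| + |eta2|."""
    return eta1 * np.tanh(alpha1 * o_tilde * s) - eta2 * np.tanh(alpha2 * o * s_tilde)


def dw_covariance(s, s_tilde, o, o_tilde, eta):
    """Covariance update ``eta * (s - ~s) * (o - ~o)``."""
    return eta * (s - s_tilde) * (o - o_tilde)


def step_learning_rate(eta: float, ds: float, dt: float,
                       delta_eta: float, tau_eta: float) -> float:
    """One discrete step of the adaptive learning rate.

    The rate decays by ``exp(-dt/tau_eta)`` and jumps by ``delta_eta * ds``
    on a positive step increase ``ds`` of the shock representation; negative
    increments are ignored.
    """
    if tau_eta <= 0:
        raise ValueError("tau_eta must be positive")
    return eta * np.exp(-dt / tau_eta) + delta_eta * max(ds, 0.0)


# ---------------------------------------------------------------------------
# numba cores
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate_core(o, s, dt, rule_id, adaptive, tau_o, tau_s,
                    de1, te1, de2, te2, a1, a2, e1c, e2c, eta_init, w0, clip):
    n = len(o)
    w_rec = np.empty(n)
    ot_rec = np.empty(n)
    st_rec = np.empty(n)
    e1_rec = np.empty(n)
    e2_rec = np.empty(n)
    a_o = np.exp(-dt / tau_o)
    a_s = np.exp(-dt / tau_s)
    d1 = np.exp(-dt / te1)
    d2 = np.exp(-dt / te2)
    w = w0
    ot = 0.0
    st = 0.0
    e1 = eta_init if adaptive else e1c
    e2 = eta_init if adaptive else e2c
    s_prev = 0.0
    ok = True
    for i in range(n):
        si = s[i]
        oi = o[i]
        if adaptive:
            ds = si - s_prev
            if ds < 0.0:
                ds = 0.0
            e1 = e1 * d1 + de1 * ds
            e2 = e2 * d2 + de2 * ds
        w_rec[i] = w
        ot_rec[i] = ot
        st_rec[i] = st
        e1_rec[i] = e1
        e2_rec[i] = e2
        if rule_id == 0:
            dw = e1 * (si - w * oi) * ot
        elif rule_id == 1:
            dw = e1 * si * ot
        elif rule_id == 2:
            dw = e1 * si * ot - e2 * st * oi
        elif rule_id == 3:
            dw = e1 * np.tanh(a1 * ot * si) - e2 * np.tanh(a2 * oi * st)
        else:
            dw = e1 * (si - st) * (oi - ot)
        w = w + dt * dw
        if clip and w < 0.0:
            w = 0.0
        if not np.isfinite(w) or abs(w) > 1e6:
            ok = False
            break
        ot = ot * a_o + (1.0 - a_o) * oi
        st = st * a_s + (1.0 - a_s) * si
        s_prev = si
    return w_rec, ot_rec, st_rec, e1_rec, e2_rec, ok


@njit(cache=True)
def _battery_core(odor, volt, logv, offsets, iend, dt, law_id, S0, alpha,
                  rule_id, adaptive, tau_o, tau_s, de1, te1, de2, te2,
                  a1, a2, e1c, e2c, eta_init):
    ncond = len(offsets) - 1
    out = np.empty(ncond)
    logS0 = np.log(S0)
    a_o = np.exp(-dt / tau_o)
    a_s = np.exp(-dt / tau_s)
    d1 = np.exp(-dt / te1)
    d2 = np.exp(-dt / te2)
    for c in range(ncond):
        lo = offsets[c]
        hi = offsets[c + 1]
        target = lo + iend[c]
        w = 0.0
        ot = 0.0
        st = 0.0
        e1 = eta_init if adaptive else e1c
        e2 = eta_init if adaptive else e2c
        s_prev = 0.0
        w_end = np.nan
        ok = True
        for i in range(lo, hi):
            if volt[i] >= S0:
                if law_id == 0:
                    si = alpha * (logv[i] - logS0)
                else:
                    si = np.exp(alpha * (logv[i] - logS0))
            else:
                si = 0.0
            oi = odor[i]
            if adaptive:
                ds = si - s_prev
                if ds < 0.0:
                    ds = 0.0
                e1 = e1 * d1 + de1 * ds
                e2 = e2 * d2 + de2 * ds
            if i == target:
                w_end = w
            if rule_id == 0:
                dw = e1 * (si - w * oi) * ot
            elif rule_id == 1:
                dw = e1 * si * ot
            elif rule_id == 2:
                dw = e1 * si * ot - e2 * st * oi
            elif rule_id == 3:
                dw = e1 * np.tanh(a1 * ot * si) - e2 * np.tanh(a2 * oi * st)
            else:
                dw = e1 * (si - st) * (oi - ot)
            w = w + dt * dw
            if not np.isfinite(w) or abs(w) > 1e6:
                ok = False
                break
            ot = ot * a_o + (1.0 - a_o) * oi
            st = st * a_s + (1.0 - a_s) * si
            s_prev = si
        out[c] = w_end if ok else np.nan
    return out


def _core_scalars(params: PlasticityParams) -> tuple:
    enc = params.encoding
    tau_s = enc.tau_s if enc.tau_s is not None else 1.0
    return (params.rule_id, params.adaptive_rate, enc.tau_o, tau_s,
            params.delta_eta, params.tau_eta, params.delta_eta2,
            params.tau_eta2, params.alpha1, params.alpha2,
            params.eta, params.eta2, params.eta_init)


# ---------------------------------------------------------------------------
# single-protocol integration
# ---------------------------------------------------------------------------


@dataclass
class SimulationTrace:
    """Full time series of one rule integrated over one protocol."""

    protocol: StimulusProtocol
    params: PlasticityParams
    t: np.ndarray
    w: np.ndarray
    s: np.ndarray
    o_tilde: np.ndarray
    s_tilde: np.ndarray
    eta_t: np.ndarray
    eta2_t: np.ndarray
    v: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v = self.w * self.protocol.odor

    @property
    def learned_weight(self) -> float:
        """Synaptic weight at ``train_end`` (the quantity read out at test)."""
        return float(self.w[self.protocol.train_end_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "w": self.w, "v": self.v, "s": self.s,
            "o_tilde": self.o_tilde, "s_tilde": self.s_tilde, "eta": self.eta_t,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        """Reproducibility record: rule, parameters and protocol identity."""
        enc = self.params.encoding
        return {
            "protocol": self.protocol.name,
            "dt": self.protocol.dt,
            "rule": self.params.rule,
            "encoding": {"S0": enc.S0, "alpha": enc.alpha, "tau_o": enc.tau_o,
                         "tau_s": enc.tau_s, "law": enc.law},
            "adaptive_rate": self.params.adaptive_rate,
            "eta": self.params.eta, "eta2": self.params.eta2,
            "delta_eta": self.params.delta_eta, "tau_eta": self.params.tau_eta,
            "delta_eta2": self.params.delta_eta2,
            "tau_eta2": self.params.tau_eta2,
            "alpha1": self.params.alpha1, "alpha2": self.params.alpha2,
        }


def integrate(protocol: StimulusProtocol, params: PlasticityParams,
              w0: float = 0.0) -> SimulationTrace:
    """Integrate a plasticity rule over a protocol and record all series.

    Per grid step: the shock voltage maps to the internal representation,
    the adaptive learning rate decays and jumps on positive increments of
    ``s``, the recorded state is the value at ``t_i``, the weight advances
    by explicit Euler, and the eligibility traces advance by the exact
    exponential update.  Raises ``FloatingPointError`` on divergence.
    """
    s = np.asarray(shock_to_internal(protocol.voltage, params.encoding))
    (rule_id, adaptive, tau_o, tau_s, de1, te1, de2, te2,
     a1, a2, e1c, e2c, eta_init) = _core_scalars(params)
    w, ot, st, e1, e2, ok = _integrate_core(
        protocol.odor, s, protocol.dt, rule_id, adaptive, tau_o, tau_s,
        de1, te1, de2, te2, a1, a2, e1c, e2c, eta_init, w0,
        params.clip_weight)
    if not ok:
        raise FloatingPointError(
            f"integration diverged: rule={params.rule} protocol={protocol.name}")
    return SimulationTrace(protocol, params, protocol.t, w, s, ot, st, e1, e2)


# ---------------------------------------------------------------------------
# fast battery path (used by fitting and the synthetic-data generator)
# ---------------------------------------------------------------------------


@dataclass
class BatteryArrays:
    """Concatenated stimulus arrays of a protocol battery for the fast core."""

    odor: np.ndarray
    voltage: np.ndarray
    log_voltage: np.ndarray
    offsets: np.ndarray
    train_end_idx: np.ndarray
    dt: float
    names: list[str]


def pack_battery(battery: list[StimulusProtocol]) -> BatteryArrays:
    """Concatenate a battery's grids into flat arrays for the numba core."""
    dt = battery[0].dt
    for p in battery:
        if abs(p.dt - dt) > 1e-12:
            raise ValueError("all battery protocols must share one dt")
    odor = np.concatenate([p.odor for p in battery])
    volt = np.concatenate([p.voltage for p in battery])
    logv = np.log(np.where(volt > 0, volt, 1.0))
    offsets = np.zeros(len(battery) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(p.t) for p in battery])
    iend = np.array([p.train_end_index for p in battery], dtype=np.int64)
    return BatteryArrays(odor, volt, logv, offsets, iend, dt,
                         [p.name for p in battery])


def battery_weights(params: PlasticityParams, batt: BatteryArrays) -> np.ndarray:
    """Learned weight ``w(train_end)`` for every condition of a packed battery.

    Diverged conditions come back as NaN.
    """
    (rule_id, adaptive, tau_o, tau_s, de1, te1, de2, te2,
     a1, a2, e1c, e2c, eta_init) = _core_scalars(params)
    law_id = 0 if params.encoding.law == "weber_fechner" else 1
    return _battery_core(
        batt.odor, batt.voltage, batt.log_voltage, batt.offsets,
        batt.train_end_idx, batt.dt, law_id, params.encoding.S0,
        params.encoding.alpha, rule_id, adaptive, tau_o, tau_s,
        de1, te1, de2, te2, a1, a2, e1c, e2c, eta_init)
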