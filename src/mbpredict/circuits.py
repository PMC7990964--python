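"""Neuronal-timescale mushroom-body circuit implementations.

Two circuit realizations of predictive plasticity are simulated with leaky
rate neurons (integration time constant ``tau`` ~ 10 ms):

* **error-driven** — the DANs represent the prediction error ``e = s - v``:

      tau dv/dt = -v + w*o,    tau de/dt = -e + s - v,    dw/dt = eta*e*~o

* **target-driven** — the DANs carry the learning target ``d``, nudged by
  the shock with strength ``lambda``; both synapse classes learn to predict
  their target:

      tau dv/dt = -v + (1-lam)*w_MK*o + lam*d
      tau dd/dt = -d + (1-lam)*w_DM*v + lam*s
      dw_MK/dt  = eta*(d - w_MK*o)*~o,   dw_DM/dt = eta*(s - w_DM*v)*v

After odor-alone presentation with fully learned weights the target-driven
MBON sustains ``v = (1-lam)/(1-lam*(1-lam)) * s0`` of the conditioned shock
representation (~0.99 at lam = 0.1).

The valence extension computes paired DAN activities through a saturating
transfer function, and the novelty-familiarity rule redistributes weight
across the ``n_K`` KC synapses with a mean-shifted presynaptic factor,
reproducing repetition suppression, passive and active recovery, and
DAN-alone potentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .encoding import shock_to_internal
from .plasticity import PlasticityParams, _core_scalars
from .protocols import StimulusProtocol

__all__ = [
    "CircuitParams",
    "CircuitTrace",
    "simulate_error_driven",
    "simulate_target_driven",
    "target_driven_test_gain",
    "dan_valence_activity",
    "valence_targets",
    "mbon_activity",
    "update_novelty_rule",
]


@dataclass
class CircuitParams:
    """Circuit-level constants.

    ``o_spont``/``d_spont`` are spontaneous KC/DAN activity levels and
    ``n_K`` the number of KC synapses for the novelty model; none of these
    are experimentally pinned down, so they are plain configurable defaults.
    """

    tau: float = 0.01            # neuronal integration time constant (s)
    lambda_nudge: float = 0.1    # teaching-signal mixing strength
    w_MK: float = 0.0            # initial KC->MBON weight
    w_DM: float = 0.0            # initial MBON->DAN weight
    w_DK: float = 0.0            # KC->DAN weight (valence model)
    eta0: float = 1.0            # base learning rate of the novelty rule
    o_spont: float = 0.05
    d_spont: float = 0.05
    n_K: int = 100
    phi: str = "clip"            # saturating DAN transfer: 'clip' or 'logistic'

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.lambda_nudge <= 1.0:
            raise ValueError("lambda_nudge must lie in [0, 1]")
        if self.n_K < 1:
            raise ValueError("n_K must be at least 1")
        if self.o_spont < 0 or self.d_spont < 0:
            raise ValueError("spontaneous rates must be non-negative")


@dataclass
class CircuitTrace:
    """Time series of one circuit simulation."""

    kind: str                    # 'error_driven' or 'target_driven'
    t: np.ndarray
    v: np.ndarray                # MBON rate
    dan: np.ndarray              # DAN rate: prediction error e or target d
    w_MK: np.ndarray
    w_DM: np.ndarray | None = None
    s: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "v": self.v, "dan": self.dan, "w_MK": self.w_MK}
        if self.w_DM is not None:
            data["w_DM"] = self.w_DM
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_stability(dt: float, tau: float) -> None:
    if dt > tau / 2:
        raise ValueError(f"unstable integration: dt={dt} > tau/2={tau / 2}; "
                         "build the protocol on a finer grid")


@njit(cache=True)
def _error_core(o, s, dt, tau, tau_o, adaptive, de1, te1, e1c, eta_init,
                w0, freeze):
    n = len(o)
    v_rec = np.empty(n)
    e_rec = np.empty(n)
    w_rec = np.empty(n)
    a_o = np.exp(-dt / tau_o)
    d1 = np.exp(-dt / te1)
    v = 0.0
    e = 0.0
    w = w0
    ot = 0.0
    eta = eta_init if adaptive else e1c
    s_prev = 0.0
    for i in range(n):
        si = s[i]
        oi = o[i]
        if adaptive:
            ds = si - s_prev
            if ds < 0.0:
                ds = 0.0
            eta = eta * d1 + de1 * ds
        v_rec[i] = v
        e_rec[i] = e
        w_rec[i] = w
        dv = (-v + w * oi) / tau
        de = (-e + si - v) / tau
        dw = 0.0 if freeze else eta * e * ot
        v += dt * dv
        e += dt * de
        w += dt * dw
        ot = ot * a_o + (1.0 - a_o) * oi
        s_prev = si
    return v_rec, e_rec, w_rec


@njit(cache=True)
def _target_core(o, s, dt, tau, tau_o, lam, adaptive, de1, te1, e1c, eta_init,
                 w_mk0, w_dm0, freeze):
    n = len(o)
    v_rec = np.empty(n)
    d_rec = np.empty(n)
    wmk_rec = np.empty(n)
    wdm_rec = np.empty(n)
    a_o = np.exp(-dt / tau_o)
    d1 = np.exp(-dt / te1)
    v = 0.0
    d = 0.0
    w_mk = w_mk0
    w_dm = w_dm0
    ot = 0.0
    eta = eta_init if adaptive else e1c
    s_prev = 0.0
    for i in range(n):
        si = s[i]
        oi = o[i]
        if adaptive:
            ds = si - s_prev
            if ds < 0.0:
                ds = 0.0
            eta = eta * d1 + de1 * ds
        v_rec[i] = v
        d_rec[i] = d
        wmk_rec[i] = w_mk
        wdm_rec[i] = w_dm
        dv = (-v + (1.0 - lam) * w_mk * oi + lam * d) / tau
        dd = (-d + (1.0 - lam) * w_dm * v + lam * si) / tau
        if freeze:
            dwmk = 0.0
            dwdm = 0.0
        else:
            dwmk = eta * (d - w_mk * oi) * ot
            dwdm = eta * (si - w_dm * v) * v
        v += dt * dv
        d += dt * dd
        w_mk += dt * dwmk
        w_dm += dt * dwdm
        ot = ot * a_o + (1.0 - a_o) * oi
        s_prev = si
    return v_rec, d_rec, wmk_rec, wdm_rec


def simulate_error_driven(protocol: StimulusProtocol, cparams: CircuitParams,
                          pparams: PlasticityParams,
                          freeze_weights: bool = False) -> CircuitTrace:
    """Integrate the error-driven MBON/DAN circuit over a protocol.

    The protocol grid is also the circuit integration grid, so build the
    protocol with ``dt <= tau/2`` (1 ms for the default 10 ms ``tau``).
    """
    _check_stability(protocol.dt, cparams.tau)
    s = np.asarray(shock_to_internal(protocol.voltage, pparams.encoding))
    (_, adaptive, tau_o, _, de1, te1, *_rest) = _core_scalars(pparams)
    v, e, w = _error_core(protocol.odor, s, protocol.dt, cparams.tau, tau_o,
                          adaptive, de1, te1, pparams.eta, pparams.eta_init,
                          cparams.w_MK, freeze_weights)
    return CircuitTrace("error_driven", protocol.t, v, e, w, s=s)


def simulate_target_driven(protocol: StimulusProtocol, cparams: CircuitParams,
                           pparams: PlasticityParams,
                           freeze_weights: bool = False) -> CircuitTrace:
    """Integrate the target-driven MBON/DAN circuit over a protocol."""
    _check_stability(protocol.dt, cparams.tau)
    s = np.asarray(shock_to_internal(protocol.voltage, pparams.encoding))
    (_, adaptive, tau_o, _, de1, te1, *_rest) = _core_scalars(pparams)
    v, d, w_mk, w_dm = _target_core(
        protocol.odor, s, protocol.dt, cparams.tau, tau_o, cparams.lambda_nudge,
        adaptive, de1, te1, pparams.eta, pparams.eta_init,
        cparams.w_MK, cparams.w_DM, freeze_weights)
    return CircuitTrace("target_driven", protocol.t, v, d, w_mk, w_DM=w_dm, s=s)


def target_driven_test_gain(lam: float) -> float:
    """Closed-form odor-alone MBON gain ``(1-lam)/(1-lam*(1-lam))``.

    After conditioning to shock representation ``s0`` with fully learned
    feedback (``w_MK*o = s0``, ``w_DM = 1``), presenting the odor alone
    sustains ``v = gain * s0`` through the MBON-DAN loop (~0.99 at lam=0.1).
    """
    return (1.0 - lam) / (1.0 - lam * (1.0 - lam))


# ---------------------------------------------------------------------------
# valence DAN pair and novelty-familiarity weight redistribution
# ---------------------------------------------------------------------------


def _phi(x, kind: str):
    if kind == "clip":
        return np.clip(x, 0.0, 1.0)
    if kind == "logistic":
        return expit(x)
    raise ValueError(f"unknown transfer function {kind!r}")


def dan_valence_activity(v_plus: float, v_minus: float, s_plus: float,
                         s_minus: float, o: float,
                         params: CircuitParams) -> tuple[float, float]:
    """Appetitive/aversive DAN pair rates through the saturating transfer.

    ``d_pm = phi((1-lam)*w_DM*v_pm + lam*(s_pm + w_DK*o))`` with outputs in
    [0, 1] for the default clipping transfer.
    """
    lam = params.lambda_nudge
    d_plus = _phi((1 - lam) * params.w_DM * v_plus + lam * (s_plus + params.w_DK * o),
                  params.phi)
    d_minus = _phi((1 - lam) * params.w_DM * v_minus + lam * (s_minus + params.w_DK * o),
                   params.phi)
    return float(d_plus), float(d_minus)


def valence_targets(d_plus: float, d_minus: float) -> tuple[float, float]:
    """Sign-flipping learning targets ``d+*(1-d-)`` and ``d-*(1-d+)``.

    A co-active opposite-valence DAN silences the target, so a previously
    learned synapse of the mismatched valence sees a negative error and
    depresses.
    """
    return d_plus * (1.0 - d_minus), d_minus * (1.0 - d_plus)


def mbon_activity(weights: np.ndarray, o: np.ndarray) -> float:
    """Population MBON drive: the mean of the per-synapse products ``w_i*o_i``."""
    weights = np.asarray(weights, dtype=float)
    o = np.asarray(o, dtype=float)
    return float(np.mean(weights * o))


def update_novelty_rule(weights: np.ndarray, o_tilde: np.ndarray, d: float,
                        params: CircuitParams, dt: float,
                        o: np.ndarray | None = None) -> np.ndarray:
    """One Euler step of the novelty-familiarity redistribution rule.

    Per synapse ``i``:

        dw_i/dt = eta * (d - v) * (~o_i - obar),
        obar = mean_j(~o_j) - o_spont,      eta = d * eta0,

    where ``v = mbon_activity(w, o)`` is the KC-driven MBON rate.  The
    mean-shifted presynaptic factor makes depression of activated synapses
    (when ``d < v``) come with potentiation of the non-activated ones, and
    spontaneous activity alone (``~o_i = o_spont`` everywhere, so obar = 0)
    drives the weights until ``v`` at spontaneous drive matches ``d``.

    ``o`` defaults to the eligibility trace when the instantaneous KC
    activity is not tracked separately.
    """
    weights = np.asarray(weights, dtype=float)
    o_tilde = np.asarray(o_tilde, dtype=float)
    if len(weights) != len(o_tilde):
        raise ValueError("weights and o_tilde must have one entry per KC synapse")
    o_now = o_tilde if o is None else np.asarray(o, dtype=float)
    v = mbon_activity(weights, o_now)
    obar = float(np.mean(o_tilde)) - params.o_spont
    eta = d * params.eta0
    return weights + dt * eta * (d - v) * (o_tilde - obar)
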