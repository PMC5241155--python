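"""Two-compartment model of label propagation along the crypt-villus axis.

After a pulse of a thymine analog (BrdU/IdU), labeled cells in the crypt
proliferate at specific rate ``delta`` (h^-1).  Once the labeled crypt
population reaches a threshold ``L_C*``, labeled cells are transferred to
the villus at the same specific rate (crypt size is constant under
homeostasis, so proliferation is exactly balanced by transfer).  Once the
labeled villus population reaches a second threshold ``L_V*``, labeled
cells are additionally shed from the villus tip at specific rate ``gamma``.

The gated system

    dL_C/dt = delta * L_C * (1 - H(L_C - L_C*))
    dL_V/dt = delta * L_C * H(L_C - L_C*) - gamma * L_V * H(L_V - L_V*)

(H the Heaviside step, with H(0) = 1 so a process is active exactly at
threshold) admits a piecewise closed-form solution with phase boundaries
``t1`` (transfer onset, L_C reaches L_C*) and ``t2`` (shedding onset, L_V
reaches L_V*):

    t0 <= t < t1 :  L_C = L_C0 * exp(delta*(t - t0)),        L_V = L_V0
    t1 <= t < t2 :  L_C = L_C*,   L_V = L_V0 + delta*L_C* * (t - t1)
    t  >= t2     :  L_C = L_C*,   L_V = b + (L_V* - b) * exp(-gamma*(t - t2))

with balance level b = delta*L_C*/gamma, and thresholds tied to the phase
times by  L_C* = L_C0*exp(delta*(t1 - t0))  and
L_V* = L_V0 + delta*L_C**(t2 - t1).

Counts are real-valued: they are sums of labeled-cell proportions averaged
over >= 30 crypt-villus units, not integer cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "LabelState",
    "LabelTrajectory",
    "ode_rhs",
    "pre_shedding_solution",
    "explicit_solution",
    "thresholds_from_times",
    "heaviside",
]

#: Relative tolerance for the threshold/phase-time consistency invariant.
_CONSISTENCY_RTOL = 1e-9


def heaviside(u: float) -> float:
    """Heaviside step with H(0) = 1: a gated process is active at threshold."""
    return 1.0 if u >= 0.0 else 0.0


def thresholds_from_times(
    delta: float,
    l_c0: float,
    l_v0: float,
    t0: float,
    t1: float,
    t2: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Compute the transfer and shedding thresholds implied by the phase times.

    ``L_C* = L_C0 * exp(delta*(t1 - t0))`` and, when ``t2`` is given,
    ``L_V* = L_V0 + delta * L_C* * (t2 - t1)`` (the value of L_V at shedding
    onset under the pre-shedding solution).

    Returns ``(l_c_star, l_v_star)``; ``l_v_star`` is None when ``t2`` is None.
    """
    if min(delta, l_c0, l_v0, t0, t1) < 0 or (t2 is not None and t2 < 0):
        raise ValueError("all inputs must be non-negative")
    if t1 < t0:
        raise ValueError(f"t1={t1} must be >= t0={t0}")
    if t2 is not None and t2 < t1:
        raise ValueError(f"t2={t2} must be >= t1={t1}")
    l_c_star = l_c0 * np.exp(delta * (t1 - t0))
    l_v_star = None if t2 is None else l_v0 + delta * l_c_star * (t2 - t1)
    return float(l_c_star), (None if l_v_star is None else float(l_v_star))


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the two-compartment label-propagation model.

    Parameters
    ----------
    delta : float
        Specific cell proliferation rate in the crypt, equal to the specific
        crypt-to-villus transfer rate (h^-1).
    n_crypt : float
        Crypt compartment size in cells; also the crypt-villus boundary
        position of the 1-D crypt-villus unit.
    l_c0, l_v0 : float
        Labeled cells in crypt / on villus at ``t0``.
    t0 : float
        Initial time (h); the analysis clock starts 2 h after the label pulse.
    t1 : float
        Time at which crypt-to-villus transfer of labeled cells begins (h).
    t2 : float, optional
        Time at which shedding of labeled cells begins; None means "beyond
        the observation window" (all data pre-shedding).
    gamma : float, optional
        Specific shedding rate from the villus tip (h^-1); only needed when
        the shedding phase is modeled.
    l_c_star, l_v_star : float, optional
        Thresholds triggering transfer / shedding.  Derived from the phase
        times when omitted; when supplied they must be consistent with them.
    """

    delta: float
    n_crypt: float
    l_c0: float
    l_v0: float
    t0: float = 0.0
    t1: float = 0.0
    t2: Optional[float] = None
    gamma: Optional[float] = None
    l_c_star: Optional[float] = field(default=None)
    l_v_star: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.delta < 0:
            # Negative delta is tolerated only for the degenerate t1 == t0
            # scheme used in proliferation-arrest fits, where L_C is constant
            # and L_V is linear (slope may be estimated slightly negative).
            if self.t1 != self.t0:
                raise ValueError("delta < 0 requires t1 == t0")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_crypt < 1:
            raise ValueError("n_crypt must be >= 1")
        if self.t0 < 0 or self.t1 < self.t0:
            raise ValueError("phase times must satisfy t1 >= t0 >= 0")
        if self.t2 is not None and self.t2 < self.t1:
            raise ValueError("phase times must satisfy t2 >= t1")
        if self.l_c0 < 0 or self.l_v0 < 0:
            raise ValueError("initial labeled counts must be >= 0")
        if self.delta >= 0:
            lc_star, lv_star = thresholds_from_times(
                self.delta, self.l_c0, self.l_v0, self.t0, self.t1, self.t2
            )
        else:  # t1 == t0: transfer active throughout, plateau at L_C0
            lc_star, lv_star = self.l_c0, None
        if self.l_c_star is None:
            object.__setattr__(self, "l_c_star", lc_star)
        elif not np.isclose(self.l_c_star, lc_star, rtol=_CONSISTENCY_RTOL, atol=0):
            raise ValueError(
                f"l_c_star={self.l_c_star} inconsistent with "
                f"l_c0*exp(delta*(t1-t0))={lc_star}"
            )
        if self.t2 is not None:
            if self.l_v_star is None:
                object.__setattr__(self, "l_v_star", lv_star)
            elif lv_star is not None and not np.isclose(
                self.l_v_star, lv_star, rtol=_CONSISTENCY_RTOL, atol=0
            ):
                raise ValueError(
                    f"l_v_star={self.l_v_star} inconsistent with "
                    f"pre-shedding L_V(t2)={lv_star}"
                )
        if self.l_c0 > self.l_c_star * (1 + 1e-12):
            raise ValueError("requires l_c0 <= l_c_star")
        if self.l_c_star > self.n_crypt * (1 + 1e-9):
            raise ValueError("l_c_star cannot exceed the crypt size n_crypt")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        """Flat key-value form (keys: delta, gamma, n_crypt, l_c0, l_v0, t0, t1, t2)."""
        return {
            "delta": self.delta,
            "gamma": self.gamma,
            "n_crypt": self.n_crypt,
            "l_c0": self.l_c0,
            "l_v0": self.l_v0,
            "t0": self.t0,
            "t1": self.t1,
            "t2": self.t2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        keys = ("delta", "gamma", "n_crypt", "l_c0", "l_v0", "t0", "t1", "t2")
        return cls(**{k: d.get(k) for k in keys if d.get(k) is not None or k in ("gamma", "t2")})

    def with_(self, **kw) -> "ModelParams":
        """Copy with fields replaced (thresholds re-derived)."""
        base = {**self.to_dict(), **kw}
        return ModelParams.from_dict(base)


@dataclass(frozen=True)
class LabelState:
    """Labeled-cell counts (real-valued) in the two compartments at time t."""

    t: float
    l_crypt: float
    l_villus: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t) and np.isfinite(self.l_crypt) and np.isfinite(self.l_villus)):
            raise ValueError("state must be finite")
        if self.l_crypt < 0 or self.l_villus < 0:
            raise ValueError("labeled counts must be >= 0")


@dataclass(frozen=True)
class LabelTrajectory:
    """Solution of the model evaluated on a time grid."""

    t: np.ndarray
    l_crypt: np.ndarray
    l_villus: np.ndarray

    def __iter__(self):
        for ti, lc, lv in zip(self.t, self.l_crypt, self.l_villus):
            yield LabelState(float(ti), float(lc), float(lv))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.t, "l_crypt": self.l_crypt, "l_villus": self.l_villus}
        )


def ode_rhs(
    state: LabelState,
    params: ModelParams,
    gates: Optional[tuple[bool, bool]] = None,
) -> tuple[float, float]:
    """Instantaneous rates (dL_C/dt, dL_V/dt) of the gated two-compartment system.

    Transfer switches on when L_C reaches the crypt threshold; shedding when
    L_V reaches the villus threshold.  Both gates use H(0) = 1.

    ``gates`` optionally fixes the (transfer, shedding) gate states instead
    of evaluating the Heavisides from the current state.  This matters for
    the shedding gate: once attained, the model keeps shedding active even
    though L_V then falls back below L_V* (the threshold marks the time the
    labeled front reaches the villus tip, after which shed cells stay
    labeled).  A literal state-dependent Heaviside would instead produce a
    sliding mode pinned at L_V* whenever delta*L_C* < gamma*L_V*; the
    piecewise solutions encode the latched-gate reading.
    """
    lc, lv = state.l_crypt, state.l_villus
    if not (np.isfinite(lc) and np.isfinite(lv)):
        raise ValueError("non-finite state")
    if gates is None:
        gate_c = heaviside(lc - params.l_c_star)
        gate_v = 0.0
        if params.l_v_star is not None:
            gate_v = heaviside(lv - params.l_v_star)
    else:
        gate_c, gate_v = float(gates[0]), float(gates[1])
    gamma = params.gamma or 0.0
    d_lc = params.delta * lc * (1.0 - gate_c)
    d_lv = params.delta * lc * gate_c - gamma * lv * gate_v
    return d_lc, d_lv


def _check_times(params: ModelParams, times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D vector")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    if t[0] < params.t0:
        raise ValueError(f"times before t0={params.t0} are outside the model domain")
    return t


def pre_shedding_solution(params: ModelParams, times: Sequence[float]) -> LabelTrajectory:
    """Closed-form solution for the pre-shedding phases (t < t2).

    Exponential crypt growth until ``t1``, then a crypt plateau at ``L_C*``
    with linear villus accumulation at rate ``delta * L_C*``.  Continuous at
    ``t1``.  Raises if any requested time reaches the shedding phase; use
    :func:`explicit_solution` for the full three-phase trajectory.
    """
    t = _check_times(params, times)
    if params.t2 is not None and np.any(t >= params.t2):
        raise ValueError(
            f"times >= t2={params.t2} are in the shedding phase; use explicit_solution"
        )
    lc = np.where(
        t < params.t1,
        params.l_c0 * np.exp(params.delta * (t - params.t0)),
        params.l_c_star,
    )
    lv = np.where(
        t < params.t1,
        params.l_v0,
        params.l_v0 + params.delta * params.l_c_star * (t - params.t1),
    )
    return LabelTrajectory(t, lc, lv)


def explicit_solution(params: ModelParams, times: Sequence[float]) -> LabelTrajectory:
    """Full piecewise solution, including the shedding phase t >= t2.

    For ``t >= t2`` the villus count relaxes exponentially at rate ``gamma``
    from ``L_V*`` toward the balance level ``delta*L_C*/gamma`` where transfer
    in equals shedding out.  Continuous at ``t2``.
    """
    t = _check_times(params, times)
    if params.t2 is None or np.all(t < params.t2):
        return pre_shedding_solution(params, t)
    if params.gamma is None or params.gamma <= 0:
        raise ValueError("shedding phase requires gamma > 0")
    pre = t < params.t2
    lc = np.full_like(t, params.l_c_star)
    lv = np.empty_like(t)
    if np.any(pre):
        sol = pre_shedding_solution(params, t[pre])
        lc[pre] = sol.l_crypt
        lv[pre] = sol.l_villus
    balance = params.delta * params.l_c_star / params.gamma
    post = ~pre
    lv[post] = balance + (params.l_v_star - balance) * np.exp(
        -params.gamma * (t[post] - params.t2)
    )
    return LabelTrajectory(t, lc, lv)
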