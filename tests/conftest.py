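"""Shared fixtures and the independent ODE-integration oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cveukit import ModelParams
from cveukit.model import LabelState, ode_rhs


def integrate_gated_ode(p: ModelParams, ts: np.ndarray, rtol: float = 1e-9,
                        atol: float = 1e-11) -> np.ndarray:
    """Numerically integrate the gated two-compartment ODE system.

    Independent oracle for the closed-form solutions: adaptive integration
    of ``ode_rhs`` phase by phase, with a terminal event at each threshold
    crossing and the corresponding gate latched on after its event (the
    solution concept the piecewise model defines; a literal state-dependent
    gate would produce a sliding mode at the shedding threshold).
    Returns an array of shape (2, len(ts)).
    """
    ts = np.asarray(ts, dtype=float)

    def make_rhs(gates):
        def rhs(t, y):
            return ode_rhs(LabelState(t, max(y[0], 0.0), max(y[1], 0.0)), p, gates=gates)
        return rhs

    def ev_c(t, y):
        return y[0] - p.l_c_star

    def ev_v(t, y):
        return y[1] - (p.l_v_star if p.l_v_star is not None else 1e12)

    ev_c.terminal = ev_v.terminal = True
    out = np.full((2, len(ts)), np.nan)
    t_cur = p.t0
    y = np.array([p.l_c0, p.l_v0], dtype=float)
    transfer_on = y[0] >= p.l_c_star
    shed_on = p.l_v_star is not None and y[1] >= p.l_v_star
    for _ in range(4):
        events = [e for e, on in ((ev_c, transfer_on), (ev_v, shed_on)) if not on]
        mask = (ts >= t_cur - 1e-12) & ~np.isfinite(out[0])
        sol = solve_ivp(
            make_rhs((transfer_on, shed_on)), (t_cur, ts[-1] + 1e-9), y,
            t_eval=ts[mask], events=events or None, rtol=rtol, atol=atol,
        )
        ysol = np.asarray(sol.y)
        if ysol.size:
            out[:, np.flatnonzero(mask)[: ysol.shape[1]]] = ysol
        if sol.status != 1:
            break
        k = [i for i, te in enumerate(sol.t_events) if len(te)][-1]
        t_cur = sol.t_events[k][-1]
        y = np.array(sol.y_events[k][-1], dtype=float)
        if events[k] is ev_c:
            transfer_on = True
            y[0] = p.l_c_star
        else:
            shed_on = True
            y[1] = p.l_v_star
    return out


def random_params(rng: np.random.Generator, with_shedding: bool = True) -> ModelParams:
    """A random valid parameter set spanning realistic kinetic ranges."""
    delta = rng.uniform(0.01, 0.2)
    t1 = rng.uniform(1, 20)
    t2 = t1 + rng.uniform(1, 30) if with_shedding else None
    return ModelParams(
        delta=delta,
        n_crypt=1000,  # large so the crypt capacity never binds
        l_c0=rng.uniform(0.5, 5),
        l_v0=rng.uniform(0, 3),
        t0=0.0,
        t1=t1,
        t2=t2,
        gamma=rng.uniform(0.01, 0.3) if with_shedding else None,
    )


@pytest.fixture(scope="session")
def control_duod_params() -> ModelParams:
    """Pre-shedding parameters at the control-duodenum point estimates."""
    return ModelParams(delta=0.0760, n_crypt=20, l_c0=2.0, l_v0=0.0, t0=0.0, t1=20.0)


@pytest.fixture(scope="session")
def control_duod_sim():
    """One seeded control-duodenum simulated experiment (30 CVEUs x 8 times)."""
    from cveukit import scenario_presets, simulate_cveu

    return simulate_cveu(scenario_presets("control_duodenum"), seed=1)
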