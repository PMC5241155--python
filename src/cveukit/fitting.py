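"""Nonlinear least-squares fitting of the pre-shedding label model.

The labeled-cell counts in the crypt and villus compartments are fitted
jointly with the pre-shedding closed-form solution, on the
variance-homogenizing scale log(L + 1), by nonlinear least squares.
Which parameters are fixed and which are free depends on the experimental
regime (:class:`FitScheme`):

* control / omomyc:  t0 = 0 and L_V0 = 0 fixed; delta, t1, L_C0 free.
* arac_early:  t0 = t1 = 15 h fixed (label front already on the villus at
  the first sampling after label activation); delta, L_C0, L_V0 free.
* arac_late:   t0 = t1 = 25 h fixed (10 extra hours of arrested
  proliferation); delta, L_C0, L_V0 free.

Late data points affected by label dilution (crypt counts declining) or by
shedding (villus counts plateauing) violate the model assumptions and are
excluded before fitting (:func:`exclude_diluted_points`).

The fitted rate feeds the kinematic quantities: under mitotic pressure in a
1-D column the velocity at crypt position x is V_x = delta*x, the velocity
at the crypt-villus boundary (= crypt cell production rate) is
V_CV = delta*N_C, and transit times follow by integrating 1/V_x across the
crypt and dividing the villus length by V_CV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelParams, pre_shedding_solution

__all__ = [
    "FitScheme",
    "ExclusionPolicy",
    "ExclusionReport",
    "exclude_diluted_points",
    "CompartmentLabelModel",
    "CompartmentLabelResults",
    "FrontVelocityFit",
    "fit_front_velocity",
    "Kinematics",
    "derive_kinematics",
    "front_recovery_time",
    "boundary_sensitivity",
]

_PARAM_NAMES = ("delta", "t1", "l_c0", "l_v0", "t0")


@dataclass(frozen=True)
class FitScheme:
    """Fixed/free parameter scheme for one experimental regime."""

    name: str
    fixed: Mapping[str, float]
    free: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", dict(self.fixed))
        object.__setattr__(self, "free", tuple(self.free))
        overlap = set(self.fixed) & set(self.free)
        if overlap:
            raise ValueError(f"parameters both fixed and free: {sorted(overlap)}")
        covered = set(self.fixed) | set(self.free)
        missing = set(_PARAM_NAMES) - covered
        if missing:
            raise ValueError(f"scheme leaves parameters unspecified: {sorted(missing)}")

    @classmethod
    def for_regime(cls, name: str) -> "FitScheme":
        """Named schemes: control, omomyc, arac_early, arac_late."""
        if name in ("control", "omomyc"):
            return cls(name, fixed={"t0": 0.0, "l_v0": 0.0}, free=("delta", "t1", "l_c0"))
        if name == "arac_early":
            return cls(name, fixed={"t0": 15.0, "t1": 15.0}, free=("delta", "l_c0", "l_v0"))
        if name == "arac_late":
            return cls(name, fixed={"t0": 25.0, "t1": 25.0}, free=("delta", "l_c0", "l_v0"))
        raise ValueError(
            f"unknown scheme {name!r}; expected control, omomyc, arac_early, arac_late"
        )

    @property
    def t1_free(self) -> bool:
        return "t1" in self.free


# ---------------------------------------------------------------------------
# dilution / shedding exclusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionPolicy:
    """Rule flagging data points affected by label dilution or shedding.

    crypt decline: exclude crypt counts from the first time at which the
    count stays below ``runmax_factor`` x its running maximum for all later
    observed times (label dilution below detection).

    villus plateau: exclude villus counts from the first split point at
    which the OLS slope of the trailing segment drops below
    ``plateau_slope_factor`` x the leading-segment slope (shedding onset).

    ``couple_dilution`` (default True): dilution is a property of the
    sampling time, not of one compartment — labels reaching the villus late
    have divided just as often — so villus points from the crypt-decline
    onset onward are excluded as well.

    ``manual_crypt`` / ``manual_villus``: explicit lists of times to exclude
    instead of the automatic rules.
    """

    runmax_factor: float = 0.9
    plateau_slope_factor: float = 0.1
    couple_dilution: bool = True
    manual_crypt: Optional[tuple[float, ...]] = None
    manual_villus: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class ExclusionReport:
    keep_crypt: np.ndarray
    keep_villus: np.ndarray
    excluded_crypt_times: tuple[float, ...]
    excluded_villus_times: tuple[float, ...]

    @property
    def n_excluded(self) -> int:
        return int((~self.keep_crypt).sum() + (~self.keep_villus).sum())


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average (ends use available neighbors)."""
    if len(y) < 3:
        return y.astype(float)
    out = np.empty(len(y))
    out[0] = y[:2].mean()
    out[-1] = y[-2:].mean()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def _decline_onset(y: np.ndarray, factor: float) -> int:
    """First index from which y stays below factor*running-max; len(y) if none.

    Applied to a 3-point moving average so a single noisy high-water mark
    does not flag an entire flat plateau as declining.
    """
    ys = _smooth3(np.asarray(y, dtype=float))
    runmax = np.maximum.accumulate(ys)
    below = ys < factor * runmax
    for i in range(len(ys)):
        if below[i:].all() and below[i]:
            return i
    return len(ys)


def _plateau_onset(t: np.ndarray, y: np.ndarray, slope_factor: float) -> int:
    """First split where the trailing OLS slope < slope_factor x leading slope."""
    n = len(y)
    for i in range(2, n - 1):
        lead = np.polyfit(t[: i + 1], y[: i + 1], 1)[0]
        trail = np.polyfit(t[i:], y[i:], 1)[0]
        if lead > 0 and trail < slope_factor * lead:
            return i + 1  # keep the split point itself (last rising point)
    return n


def exclude_diluted_points(
    counts: pd.DataFrame, policy: ExclusionPolicy = ExclusionPolicy()
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Flag count records that violate the pre-shedding, pre-dilution model.

    Returns the counts frame augmented with boolean ``keep_crypt`` /
    ``keep_villus`` columns, plus a report.  Exclusion is per compartment:
    a late crypt point may be dropped while the villus point at the same
    time is kept.
    """
    df = counts.sort_values("time_h", ignore_index=True).copy()
    t = df["time_h"].to_numpy(dtype=float)
    lc = df["l_crypt_obs"].to_numpy(dtype=float)
    lv = df["l_villus_obs"].to_numpy(dtype=float)
    n = len(df)

    decline_at = _decline_onset(lc, policy.runmax_factor)
    if policy.manual_crypt is not None:
        keep_c = ~np.isin(t, np.asarray(policy.manual_crypt, dtype=float))
    else:
        keep_c = np.ones(n, dtype=bool)
        keep_c[decline_at:] = False

    if policy.manual_villus is not None:
        keep_v = ~np.isin(t, np.asarray(policy.manual_villus, dtype=float))
    else:
        keep_v = np.ones(n, dtype=bool)
        onset = _plateau_onset(t, lv, policy.plateau_slope_factor)
        if policy.couple_dilution:
            onset = min(onset, decline_at)
        keep_v[onset:] = False

    df["keep_crypt"] = keep_c
    df["keep_villus"] = keep_v
    report = ExclusionReport(
        keep_crypt=keep_c,
        keep_villus=keep_v,
        excluded_crypt_times=tuple(t[~keep_c]),
        excluded_villus_times=tuple(t[~keep_v]),
    )
    return df, report


# ---------------------------------------------------------------------------
# the Model / Results pair
# ---------------------------------------------------------------------------

class CompartmentLabelModel:
    """Pre-shedding two-compartment label model, ready to fit to count data.

    Parameters
    ----------
    counts : DataFrame
        Columns ``time_h``, ``l_crypt_obs``, ``l_villus_obs`` (one row per
        sampling time).  Counts are sums of labeled proportions.
    boundary : int
        Crypt-villus boundary / crypt size N_C used to form the counts.
    scheme : FitScheme or str
        Fixed/free parameter scheme (a regime name is accepted).
    exclusion : ExclusionPolicy, optional
        Dilution/shedding exclusion rule applied before fitting.  Pass
        ``None`` to fit all points.

    Examples
    --------
    >>> model = CompartmentLabelModel(counts, boundary=20, scheme="control")
    >>> res = model.fit()
    >>> res.params.delta  # doctest: +SKIP
    """

    #: deterministic multi-start grid over (delta, t1)
    _N_STARTS = 5

    def __init__(
        self,
        counts: pd.DataFrame,
        boundary: int,
        scheme: Union[FitScheme, str] = "control",
        exclusion: Optional[ExclusionPolicy] = ExclusionPolicy(),
    ) -> None:
        required = {"time_h", "l_crypt_obs", "l_villus_obs"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts missing columns {sorted(missing)}")
        if isinstance(scheme, str):
            scheme = FitScheme.for_regime(scheme)
        self.scheme = scheme
        self.boundary = int(boundary)
        self.exclusion = exclusion

        df = counts.sort_values("time_h", ignore_index=True)
        if exclusion is not None:
            df, self.exclusion_report = exclude_diluted_points(df, exclusion)
        else:
            n = len(df)
            df = df.copy()
            df["keep_crypt"] = np.ones(n, dtype=bool)
            df["keep_villus"] = np.ones(n, dtype=bool)
            self.exclusion_report = ExclusionReport(
                df["keep_crypt"].to_numpy(), df["keep_villus"].to_numpy(), (), ()
            )
        self.data = df
        self._t = df["time_h"].to_numpy(dtype=float)
        self._lc = df["l_crypt_obs"].to_numpy(dtype=float)
        self._lv = df["l_villus_obs"].to_numpy(dtype=float)
        self._kc = df["keep_crypt"].to_numpy(dtype=bool)
        self._kv = df["keep_villus"].to_numpy(dtype=bool)

        n_resid = int(self._kc.sum() + self._kv.sum())
        n_free = len(scheme.free)
        n_times = len(np.unique(self._t[self._kc | self._kv]))
        if n_times < 3:
            raise ValueError(
                f"need >= 3 time points after exclusions, got {n_times}"
            )
        if n_resid <= n_free:
            raise ValueError(
                f"under-determined fit: {n_free} free parameters, "
                f"{n_resid} informative points"
            )

    @classmethod
    def from_profiles(
        cls,
        profiles: Iterable,
        boundary: int,
        scheme: Union[FitScheme, str] = "control",
        **kw,
    ) -> "CompartmentLabelModel":
        """Build directly from PositionProfiles (sums proportions per side)."""
        from .profiles import compartment_series

        return cls(compartment_series(profiles, boundary), boundary, scheme, **kw)

    # -- parameter plumbing ------------------------------------------------
    def _values(self, theta: np.ndarray) -> dict:
        vals = dict(self.scheme.fixed)
        vals.update(zip(self.scheme.free, np.asarray(theta, dtype=float)))
        if not self.scheme.t1_free:
            vals.setdefault("t1", vals["t0"])
        return vals

    def _assemble(self, theta: np.ndarray) -> ModelParams:
        vals = self._values(theta)
        return ModelParams(
            delta=float(vals["delta"]),
            n_crypt=float(self.boundary),
            l_c0=float(vals["l_c0"]),
            l_v0=float(vals["l_v0"]),
            t0=float(vals["t0"]),
            t1=float(vals["t1"]),
        )

    def predict(self, params: ModelParams, times: Optional[Sequence[float]] = None):
        """Model counts (l_crypt, l_villus) at the given times."""
        t = self._t if times is None else np.asarray(times, dtype=float)
        sol = pre_shedding_solution(params, t)
        return sol.l_crypt, sol.l_villus

    def _raw_predict(self, theta: np.ndarray, t: np.ndarray):
        """Closed-form counts without invariant validation (optimizer path)."""
        v = self._values(theta)
        delta, t0, t1, lc0, lv0 = v["delta"], v["t0"], v["t1"], v["l_c0"], v["l_v0"]
        lc_star = lc0 * np.exp(delta * (t1 - t0))
        lc = np.where(t < t1, lc0 * np.exp(delta * (t - t0)), lc_star)
        lv = np.where(t < t1, lv0, lv0 + delta * lc_star * (t - t1))
        return lc, lv, lc_star

    #: weight of the smooth penalty keeping the fitted plateau within N_C
    _CAP_PENALTY = 10.0

    def _residuals(self, theta: np.ndarray, with_penalty: bool = True) -> np.ndarray:
        lc, lv, lc_star = self._raw_predict(theta, self._t)
        # negative predicted counts can occur transiently for delta < 0
        # (arrest schemes); floor at zero so the log stays defined
        lc, lv = np.maximum(lc, 0.0), np.maximum(lv, 0.0)
        rc = np.log(lc[self._kc] + 1.0) - np.log(self._lc[self._kc] + 1.0)
        rv = np.log(lv[self._kv] + 1.0) - np.log(self._lv[self._kv] + 1.0)
        out = np.concatenate([rc, rv])
        if with_penalty:
            # soft capacity constraint: labeled crypt plateau cannot exceed
            # the crypt size; active only when the optimizer wanders outside
            excess = max(0.0, float(lc_star) - self.boundary)
            out = np.append(out, self._CAP_PENALTY * excess)
        out[~np.isfinite(out)] = 1e6
        return out

    def _starts(self) -> list[np.ndarray]:
        deltas = np.linspace(0.01, 0.2, self._N_STARTS)
        t1s = np.linspace(2.0, 30.0, self._N_STARTS)
        lc0_guess = max(self._lc[self._kc].min() if self._kc.any() else 1.0, 0.5)
        lv0_guess = max(self._lv[self._kv].min() if self._kv.any() else 0.0, 0.1)
        starts = []
        for i in range(self._N_STARTS):
            vals = {"delta": deltas[i], "t1": t1s[i], "l_c0": lc0_guess, "l_v0": lv0_guess}
            starts.append(np.array([vals[name] for name in self.scheme.free]))
        return starts

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        t0 = float(self.scheme.fixed.get("t0", 0.0))
        tmax = float(self._t.max())
        lo, hi = [], []
        for name in self.scheme.free:
            if name == "delta":
                # with t1 fixed to t0 (arrest regimes) the villus slope may be
                # estimated negative; with free t1 the exponential phase
                # requires delta > 0
                lo.append(-1.0 if not self.scheme.t1_free else 1e-8)
                hi.append(1.0)
            elif name == "t1":
                lo.append(t0)
                hi.append(max(tmax, t0 + 1e-6))
            elif name in ("l_c0", "l_v0"):
                lo.append(0.0)
                hi.append(np.inf)
            else:
                lo.append(-np.inf)
                hi.append(np.inf)
        return np.asarray(lo), np.asarray(hi)

    def fit(self) -> "CompartmentLabelResults":
        """Nonlinear least squares on the log(L+1) scale, multi-start.

        Both compartments enter one residual vector with equal weight.
        Standard errors come from the Gauss-Newton covariance
        ``s^2 (J'J)^-1`` at the optimum.
        """
        lo, hi = self._bounds()
        best = None
        for x0 in self._starts():
            x0c = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0 + 1e9))
            try:
                sol = optimize.least_squares(
                    self._residuals, x0c, bounds=(lo, hi), method="trf", x_scale="jac"
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "optimizer failed to converge from every starting point "
                f"(scheme={self.scheme.name}, n={len(self._t)})"
            )
        theta = best.x.copy()
        # project a residual capacity violation (penalty keeps it tiny) back
        # onto the feasible set by shrinking l_c0
        _, _, lc_star = self._raw_predict(theta, self._t)
        if lc_star > self.boundary and "l_c0" in self.scheme.free:
            i = self.scheme.free.index("l_c0")
            theta[i] *= self.boundary / lc_star * (1.0 - 1e-12)

        resid = self._residuals(theta, with_penalty=False)
        n_resid = resid.size
        n_free = len(self.scheme.free)
        ssr = float(resid @ resid)
        dof = max(n_resid - n_free, 1)
        s2 = ssr / dof
        J = best.jac[:-1, :]  # drop the penalty row
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((n_free, n_free), np.nan)
            se = np.full(n_free, np.nan)
        return CompartmentLabelResults(
            model=self,
            params=self._assemble(theta),
            theta=pd.Series(theta, index=list(self.scheme.free)),
            bse=pd.Series(se, index=list(self.scheme.free)),
            cov=cov,
            rmse=float(np.sqrt(ssr / n_resid)),
            n_used=n_resid,
            n_excluded=self.exclusion_report.n_excluded,
        )


@dataclass
class CompartmentLabelResults:
    """Fit results: point estimates, standard errors and diagnostics."""

    model: CompartmentLabelModel
    params: ModelParams
    theta: pd.Series
    bse: pd.Series
    cov: np.ndarray
    rmse: float
    n_used: int
    n_excluded: int

    @property
    def scheme(self) -> FitScheme:
        return self.model.scheme

    @property
    def production_rate(self) -> float:
        """Crypt cell production rate / boundary velocity V_CV = delta*N_C (cells/h)."""
        return self.params.delta * self.params.n_crypt

    def predict(self, times: Sequence[float]):
        return self.model.predict(self.params, times)

    def kinematics(
        self,
        cveu_length_cells: float,
        density_cells_per_10um: Optional[float] = None,
        front_fit: Optional["FrontVelocityFit"] = None,
    ) -> "Kinematics":
        return derive_kinematics(
            self, cveu_length_cells, density_cells_per_10um, front_fit
        )

    def summary(self) -> str:
        lines = [
            "Two-compartment label model (pre-shedding), NLS on log(L+1)",
            "=" * 62,
            f"scheme: {self.scheme.name:<12s}  boundary N_C: {self.params.n_crypt:g} cells",
            f"n residuals used: {self.n_used}   excluded: {self.n_excluded}   "
            f"RMSE (log scale): {self.rmse:.4f}",
            "-" * 62,
            f"{'parameter':<10s}{'estimate':>12s}{'std err':>12s}",
        ]
        for name in self.theta.index:
            lines.append(
                f"{name:<10s}{self.theta[name]:>12.4g}{self.bse[name]:>12.3g}"
            )
        for name, val in self.scheme.fixed.items():
            lines.append(f"{name:<10s}{val:>12.4g}{'(fixed)':>12s}")
        lines.append("-" * 62)
        lines.append(
            f"V_CV = delta*N_C = {self.production_rate:.3g} cells/h "
            f"(crypt cell production rate)"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# labeled-front velocity (villus migration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrontVelocityFit:
    """OLS fit of front position (um) on time (h): X_LF(t) = V_LF*t + K."""

    v_lf: float
    intercept_k: float
    se_slope: float
    se_intercept: float
    n: int

    def predict(self, t):
        return self.v_lf * np.asarray(t, dtype=float) + self.intercept_k


def fit_front_velocity(track: pd.DataFrame) -> FrontVelocityFit:
    """Estimate the labeled-front velocity along the villus by linear regression.

    ``track`` needs columns ``time_h`` and ``front_position_um``; rows with
    missing positions are dropped.
    """
    df = track.dropna(subset=["time_h", "front_position_um"])
    t = df["time_h"].to_numpy(dtype=float)
    y = df["front_position_um"].to_numpy(dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("front-velocity fit needs >= 2 distinct times")
    res = stats.linregress(t, y)
    return FrontVelocityFit(
        v_lf=float(res.slope),
        intercept_k=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n=len(t),
    )


# ---------------------------------------------------------------------------
# kinematics: velocities and transit times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kinematics:
    """Velocities and transit times implied by the fitted model.

    ``v_cv = delta*N_C`` is both the crypt cell production rate and the cell
    migration velocity at the crypt-villus boundary (cells/h).  Crypt transit
    is the travel time from position 1 to N_C under V_x = delta*x, i.e.
    ln(N_C)/delta; villus transit is the remaining cells divided by v_cv.
    """

    delta: float
    n_crypt: float
    cveu_length_cells: float
    v_cv: float
    crypt_transit_h: float
    villus_transit_h: float
    total_transit_h: float
    v_lf: Optional[float] = None
    intercept_k: Optional[float] = None
    density_cells_per_10um: Optional[float] = None

    def velocity_at(self, x) -> np.ndarray:
        """Mitotic-pressure velocity V_x = delta*x at crypt positions 1 <= x <= N_C."""
        x = np.asarray(x, dtype=float)
        if np.any((x < 1) | (x > self.n_crypt)):
            raise ValueError("positions must lie within the crypt, 1..N_C")
        return self.delta * x


def derive_kinematics(
    fit: Union[CompartmentLabelResults, ModelParams],
    cveu_length_cells: float,
    density_cells_per_10um: Optional[float] = None,
    front_fit: Optional[FrontVelocityFit] = None,
) -> Kinematics:
    """Velocities and crypt/villus/total transit times from a fitted model.

    ``cveu_length_cells`` is the full crypt-base-to-villus-tip length in
    cells.  Requires delta > 0 (transit times are undefined otherwise).
    """
    params = fit.params if isinstance(fit, CompartmentLabelResults) else fit
    delta, n_c = params.delta, params.n_crypt
    if delta <= 0:
        raise ValueError("transit times undefined for delta <= 0")
    if cveu_length_cells < n_c:
        raise ValueError("CVEU length must be >= the crypt size")
    v_cv = delta * n_c
    crypt_transit = float(np.log(n_c) / delta)  # integral of dx/(delta*x), x: 1..N_C
    villus_transit = float((cveu_length_cells - n_c) / v_cv)
    return Kinematics(
        delta=delta,
        n_crypt=n_c,
        cveu_length_cells=float(cveu_length_cells),
        v_cv=float(v_cv),
        crypt_transit_h=crypt_transit,
        villus_transit_h=villus_transit,
        total_transit_h=crypt_transit + villus_transit,
        v_lf=None if front_fit is None else front_fit.v_lf,
        intercept_k=None if front_fit is None else front_fit.intercept_k,
        density_cells_per_10um=density_cells_per_10um,
    )


def front_recovery_time(
    held_position_um: float, resumed_position_um: float, v_lf_um_per_h: float
) -> float:
    """Hours for the labeled front to travel from a held to a resumed position.

    Used to back-calculate when proliferation restarted after a transient
    arrest, assuming migration resumed at the homeostatic front velocity.
    """
    if v_lf_um_per_h <= 0:
        raise ValueError("front velocity must be > 0")
    if resumed_position_um < held_position_um:
        raise ValueError("resumed position must be >= held position")
    return (resumed_position_um - held_position_um) / v_lf_um_per_h


# ---------------------------------------------------------------------------
# crypt-villus boundary sensitivity sweep
# ---------------------------------------------------------------------------

def boundary_sensitivity(
    counts_by_boundary: Mapping[int, pd.DataFrame],
    scheme: Union[FitScheme, str] = "control",
    exclusion: Optional[ExclusionPolicy] = ExclusionPolicy(),
    cv_cutoff: float = 0.10,
) -> pd.DataFrame:
    """Refit the model across candidate crypt-villus boundaries.

    For each candidate boundary (with compartment counts recomputed at that
    boundary) the model is refitted; the returned table reports delta, its
    standard error and the production rate delta*N_C per boundary, and flags
    the stable plateau: the widest suffix of ascending boundaries whose
    production-rate coefficient of variation is below ``cv_cutoff``.

    If the chosen criterion boundary sits above all proliferative cells,
    production is stable for boundaries at or above it, with compensatory
    reductions in delta as the boundary grows; instability below indicates
    proliferative cells spilling into the villus side.

    Fit failures for individual boundaries are recorded (NaN row) without
    aborting the sweep.
    """
    rows = []
    for b in sorted(counts_by_boundary):
        try:
            res = CompartmentLabelModel(
                counts_by_boundary[b], boundary=b, scheme=scheme, exclusion=exclusion
            ).fit()
            rows.append(
                {
                    "boundary": b,
                    "delta": res.params.delta,
                    "se_delta": float(res.bse.get("delta", np.nan)),
                    "production": res.production_rate,
                    "rmse": res.rmse,
                    "converged": True,
                    "error": "",
                }
            )
        except Exception as exc:  # keep sweeping
            rows.append(
                {
                    "boundary": b,
                    "delta": np.nan,
                    "se_delta": np.nan,
                    "production": np.nan,
                    "rmse": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    # widest suffix with CV(production) below cutoff
    stable = np.zeros(len(table), dtype=bool)
    prod = table["production"].to_numpy()
    for start in range(len(table)):
        tail = prod[start:]
        if len(tail) >= 2 and np.all(np.isfinite(tail)):
            cv = float(np.std(tail, ddof=1) / np.mean(tail))
            if cv < cv_cutoff:
                stable[start:] = True
                break
    table["stable"] = stable
    return table
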