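"""End-to-end analysis pipeline and file-format plumbing.

Ties the stages together in the order the analysis requires:
score matrices -> position profiles -> crypt-villus boundary -> compartment
counts -> dilution/shedding exclusion -> model fit -> kinematics (+ front
velocity when a front track is available).

All artifacts are plain delimited text; a run writes every intermediate
table plus a manifest of output files with content hashes, so reruns with
the same inputs and seed are byte-identical.

File conventions (one directory per (group, tissue, analog) dataset):

* ``scores_t<time>h.csv``  — one score matrix per sample time
* ``front_track.csv``      — columns time_h, front_position_um
* ``config.txt``           — flat ``key = value`` metadata (density, scheme...)
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import profiles as prof
from .fitting import (
    CompartmentLabelModel,
    CompartmentLabelResults,
    ExclusionPolicy,
    FrontVelocityFit,
    Kinematics,
    fit_front_velocity,
)
from .simulate import SimulationResult

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "write_simulation",
    "read_flat_config",
    "write_flat_config",
    "write_fit_result",
    "read_fit_spec",
]

log = logging.getLogger("cveukit")

_SCORE_RE = re.compile(r"scores_t(?P<time>[0-9.]+)h\.(csv|tsv)$")


# ---------------------------------------------------------------------------
# flat key = value config files
# ---------------------------------------------------------------------------

def read_flat_config(path: Union[str, Path]) -> dict:
    """Parse a flat ``key = value`` file; numbers become floats."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val
    return out


def write_flat_config(d: dict, path: Union[str, Path]) -> None:
    lines = [f"{k} = {v}" for k, v in d.items() if v is not None]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fit_result(
    res: CompartmentLabelResults,
    path: Union[str, Path],
    kin: Optional[Kinematics] = None,
    front: Optional[FrontVelocityFit] = None,
    label: str = "",
) -> None:
    """Persist a fit (and optional kinematics) as a flat config block."""
    d = {
        "label": label,
        "scheme": res.scheme.name,
        "n_crypt": res.params.n_crypt,
        "delta": res.params.delta,
        "se_delta": float(res.bse.get("delta", np.nan)),
        "t1": res.params.t1,
        "l_c0": res.params.l_c0,
        "l_v0": res.params.l_v0,
        "t0": res.params.t0,
        "rmse": res.rmse,
        "n_used": res.n_used,
        "n_excluded": res.n_excluded,
        "production": res.production_rate,
    }
    for name in res.theta.index:
        d[f"se_{name}"] = float(res.bse[name])
    if kin is not None:
        d.update(
            cveu_length_cells=kin.cveu_length_cells,
            v_cv=kin.v_cv,
            crypt_transit_h=kin.crypt_transit_h,
            villus_transit_h=kin.villus_transit_h,
            total_transit_h=kin.total_transit_h,
        )
    if front is not None:
        d.update(v_lf=front.v_lf, se_v_lf=front.se_slope, intercept_k=front.intercept_k)
    write_flat_config(d, path)


def read_fit_spec(path: Union[str, Path]) -> dict:
    """Read a fit-result file back as a dict (for the compare stage)."""
    return read_flat_config(path)


# ---------------------------------------------------------------------------
# simulation output
# ---------------------------------------------------------------------------

def write_simulation(sim: SimulationResult, out_dir: Union[str, Path]) -> list[Path]:
    """Write a simulated dataset in the pipeline's input layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for t, m in sorted(sim.matrices.items()):
        p = out / f"scores_t{t:g}h.csv"
        prof.write_score_matrix(m, p)
        written.append(p)
    p = out / "front_track.csv"
    prof.write_front_track(sim.front_track, p)
    written.append(p)
    p = out / "truth.csv"
    sim.truth.to_csv(p, index=False)
    written.append(p)
    cfg = {
        "preset": sim.config.name,
        "delta_true": sim.config.delta,
        "n_crypt_true": sim.config.n_crypt,
        "cveu_length_cells": sim.config.cveu_length_mean,
        "density_cells_per_10um": sim.config.density_cells_per_10um,
        "detection_limit_generations": sim.config.detection_limit_generations,
    }
    p = out / "config.txt"
    write_flat_config(cfg, p)
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    input_dir: Union[str, Path]
    output_dir: Optional[Union[str, Path]] = None
    scheme: str = "control"
    boundary: Optional[int] = None  # override; estimated from time-0 profile if None
    threshold: float = 0.01
    density_cells_per_10um: Optional[float] = None
    cveu_length_cells: Optional[float] = None
    runmax_factor: float = 0.9
    plateau_slope_factor: float = 0.1
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


@dataclass
class PipelineResult:
    """Everything one run produced, stage by stage."""

    profiles: list
    boundary: int
    counts: pd.DataFrame
    fit: CompartmentLabelResults
    kinematics: Optional[Kinematics]
    front_fit: Optional[FrontVelocityFit]
    outputs: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_score_matrices(input_dir: Union[str, Path], **meta) -> list[prof.CVEUScoreMatrix]:
    """Load every ``scores_t<time>h.csv`` matrix from a dataset directory."""
    input_dir = Path(input_dir)
    found = []
    for p in sorted(input_dir.iterdir()):
        m = _SCORE_RE.match(p.name)
        if m:
            found.append((float(m.group("time")), p))
    if not found:
        raise FileNotFoundError(
            f"schema error: no 'scores_t<time>h.csv' files in {input_dir}"
        )
    return [
        prof.read_score_matrix(p, time_h=t, **meta) for t, p in sorted(found)
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run profile -> boundary -> counts -> exclusion -> fit -> kinematics.

    Deterministic given the inputs and config.  When ``output_dir`` is set,
    every intermediate table is written along with ``manifest.txt`` listing
    each output with its sha256 content hash.
    """
    in_dir = Path(config.input_dir)
    sidecar = {}
    if (in_dir / "config.txt").exists():
        sidecar = read_flat_config(in_dir / "config.txt")

    log.info("stage profile: reading score matrices from %s", in_dir)
    matrices = load_score_matrices(in_dir)
    profile_list = [prof.profile_from_scores(m) for m in matrices]

    if config.boundary is not None:
        boundary = int(config.boundary)
        log.info("stage boundary: override N_C = %d", boundary)
    else:
        t0_profile = min(profile_list, key=lambda p: p.time_h)
        boundary = prof.estimate_boundary(t0_profile, threshold=config.threshold)
        log.info(
            "stage boundary: estimated N_C = %d (threshold %g at t = %g h)",
            boundary, config.threshold, t0_profile.time_h,
        )

    counts = prof.compartment_series(profile_list, boundary)
    policy = ExclusionPolicy(
        runmax_factor=config.runmax_factor,
        plateau_slope_factor=config.plateau_slope_factor,
    )
    log.info("stage fit: scheme %s, %d time points", config.scheme, len(counts))
    model = CompartmentLabelModel(counts, boundary, config.scheme, exclusion=policy)
    fit = model.fit()
    log.info(
        "stage fit: delta = %.4g +- %.2g, rmse = %.3g, excluded %d",
        fit.params.delta, fit.bse.get("delta", np.nan), fit.rmse, fit.n_excluded,
    )

    front_fit = None
    if (in_dir / "front_track.csv").exists():
        track = prof.read_front_track(in_dir / "front_track.csv")
        try:
            front_fit = fit_front_velocity(track)
            log.info("stage velocity: V_LF = %.3g um/h", front_fit.v_lf)
        except ValueError as exc:
            log.warning("stage velocity skipped: %s", exc)

    length = config.cveu_length_cells or sidecar.get("cveu_length_cells")
    if length is None:
        length = max(p.length for p in profile_list)
        log.info("stage kinematics: CVEU length from data = %g cells", length)
    density = config.density_cells_per_10um or sidecar.get("density_cells_per_10um")
    kinematics = None
    if fit.params.delta > 0:
        kinematics = fit.kinematics(length, density, front_fit)
        log.info(
            "stage kinematics: V_CV = %.3g cells/h, total transit = %.3g h",
            kinematics.v_cv, kinematics.total_transit_h,
        )
    else:
        log.warning("stage kinematics skipped: fitted delta <= 0")

    outputs: dict = {}
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in profile_list:
            f = out / f"profile_t{p.time_h:g}h.csv"
            prof.write_profile(p, f)
            outputs[f.name] = f
        f = out / "counts.csv"
        data = model.data.copy()
        prof.write_counts(data, f)
        outputs[f.name] = f
        f = out / "fit.txt"
        write_fit_result(fit, f, kin=kinematics, front=front_fit)
        outputs[f.name] = f
        f = out / "boundary.txt"
        write_flat_config({"boundary": boundary, "threshold": config.threshold}, f)
        outputs[f.name] = f
        manifest = out / "manifest.txt"
        manifest.write_text(
            "".join(f"{name}\t{_sha256(path)}\n" for name, path in sorted(outputs.items()))
        )
        outputs["manifest.txt"] = manifest

    return PipelineResult(
        profiles=profile_list,
        boundary=boundary,
        counts=counts,
        fit=fit,
        kinematics=kinematics,
        front_fit=front_fit,
        outputs=outputs,
    )
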