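"""From raw per-CVEU binary label scores to compartment counts and fronts.

A CVEU (crypt-villus epithelial unit) is scored as a 1-D column of cells:
position 1 at the crypt base, increasing toward the villus tip, each
position 1 if the cell there is labeled, 0 if not.  At least ~30 CVEUs are
scored per sample; ragged lengths are padded with NaN and excluded
per-position from averaging.

This module derives, from such matrices:

* the per-position labeled proportion (``profile_from_scores``),
* the crypt-villus boundary / crypt size N_C, estimated as the first
  position above the profile peak at which the 2-h labeled proportion
  drops below a small threshold (default 0.01),
* compartment counts: sums of labeled proportions below/above the boundary,
* the labeled-front position (highest labeled cell, in micrometers),
* cell density of labeled strips (cells per 10 um).

All tables are plain delimited text with header rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CVEUScoreMatrix",
    "PositionProfile",
    "CompartmentRecord",
    "profile_from_scores",
    "estimate_boundary",
    "compartment_counts",
    "compartment_series",
    "front_position",
    "cell_density",
    "read_score_matrix",
    "write_score_matrix",
    "write_profile",
    "write_counts",
    "read_front_track",
    "write_front_track",
]


@dataclass(frozen=True)
class CVEUScoreMatrix:
    """Binary label scores: rows = individual CVEUs, columns = positions 1..L.

    Entries are 0/1 (float), NaN marking positions beyond a shorter CVEU.
    """

    scores: np.ndarray
    time_h: float
    tissue: str = ""
    group: str = ""
    analog: str = "BrdU"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1 or s.shape[1] < 1:
            raise ValueError("scores must be a non-empty 2-D matrix")
        vals = s[~np.isnan(s)]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("scores must contain only 0, 1 or NaN")
        object.__setattr__(self, "scores", s)

    @property
    def n_cveu(self) -> int:
        return self.scores.shape[0]

    @property
    def length(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class PositionProfile:
    """Per-position labeled proportion along the CVEU, with sample sizes."""

    proportion: np.ndarray
    n_obs: np.ndarray
    time_h: float
    tissue: str = ""
    group: str = ""
    analog: str = "BrdU"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportion, dtype=float)
        n = np.asarray(self.n_obs, dtype=int)
        if p.shape != n.shape or p.ndim != 1:
            raise ValueError("proportion and n_obs must be 1-D and equal length")
        ok = ~np.isnan(p)
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "proportion", p)
        object.__setattr__(self, "n_obs", n)

    @property
    def length(self) -> int:
        return self.proportion.size

    @property
    def positions(self) -> np.ndarray:
        """1-based cell positions from the crypt base."""
        return np.arange(1, self.length + 1)


@dataclass(frozen=True)
class CompartmentRecord:
    """Labeled-cell counts in crypt and villus at one sampling time."""

    time_h: float
    l_crypt_obs: float
    l_villus_obs: float
    boundary_used: int

    def __post_init__(self) -> None:
        if self.l_crypt_obs < 0 or self.l_villus_obs < 0:
            raise ValueError("counts must be >= 0")
        if self.l_crypt_obs > self.boundary_used * (1 + 1e-9):
            raise ValueError("crypt count cannot exceed the boundary position")


def profile_from_scores(m: CVEUScoreMatrix) -> PositionProfile:
    """Column-wise mean of scores, ignoring NaN padding.

    Positions observed in no CVEU get proportion NaN and n_obs 0.
    """
    with np.errstate(invalid="ignore"):
        prop = np.nanmean(m.scores, axis=0)
    n_obs = np.sum(~np.isnan(m.scores), axis=0)
    prop = np.where(n_obs == 0, np.nan, prop)
    return PositionProfile(
        prop, n_obs, time_h=m.time_h, tissue=m.tissue, group=m.group, analog=m.analog
    )


def estimate_boundary(profile_2h: PositionProfile, threshold: float = 0.01) -> int:
    """Crypt-villus boundary N_C from the time-0 (2 h post-injection) profile.

    The boundary is the lowest position in the upper part of the crypt at
    which the labeled proportion falls below ``threshold`` — operationally,
    the first position strictly above the profile's peak whose proportion is
    below threshold.  (The profile is also low at the crypt base, so a global
    scan would return a base position; scanning above the peak avoids that.)

    Returns the 1-based boundary position, which equals the crypt size N_C.
    """
    if not 0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    p = np.nan_to_num(profile_2h.proportion, nan=0.0)
    if np.all(p == 0):
        raise ValueError("profile has no labeled region")
    peak = int(np.argmax(p))  # 0-based index of the maximum proportion
    below = np.flatnonzero(p[peak + 1 :] < threshold)
    if below.size == 0:
        raise ValueError(
            f"no position above the peak falls below threshold {threshold}"
        )
    return peak + 1 + int(below[0]) + 1  # back to 1-based positions


def compartment_counts(profile: PositionProfile, boundary: int) -> CompartmentRecord:
    """Sum labeled proportions into crypt (1..N_C) and villus (N_C+1..L).

    Unobserved positions (NaN) contribute 0 to either sum.
    """
    if not 1 <= boundary <= profile.length:
        raise ValueError(
            f"boundary {boundary} outside profile length {profile.length}"
        )
    p = np.nan_to_num(profile.proportion, nan=0.0)
    return CompartmentRecord(
        time_h=profile.time_h,
        l_crypt_obs=float(p[:boundary].sum()),
        l_villus_obs=float(p[boundary:].sum()),
        boundary_used=int(boundary),
    )


def compartment_series(
    profiles: Iterable[PositionProfile], boundary: int
) -> pd.DataFrame:
    """Compartment counts over time as a tidy frame (the fitting target).

    Columns: time_h, l_crypt_obs, l_villus_obs, boundary_used; sorted by time.
    """
    recs = [compartment_counts(p, boundary) for p in profiles]
    df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
    return df.sort_values("time_h", ignore_index=True)


def front_position(
    m: CVEUScoreMatrix, cell_length_um: float
) -> float:
    """Mean labeled-front position in micrometers.

    Per CVEU, the front is the highest labeled position (distance from the
    crypt base); it is converted to micrometers with ``cell_length_um`` and
    averaged over the CVEUs that contain at least one labeled cell.
    """
    if cell_length_um <= 0:
        raise ValueError("cell_length_um must be > 0")
    s = np.nan_to_num(m.scores, nan=0.0)
    labeled_rows = s.sum(axis=1) > 0
    if not labeled_rows.any():
        raise ValueError("no labeled cell in the score matrix")
    # highest labeled 1-based index per CVEU
    idx = s.shape[1] - np.argmax(s[labeled_rows, ::-1], axis=1)
    return float(np.mean(idx) * cell_length_um)


def cell_density(strip_cell_count: float, strip_length_um: float) -> float:
    """Cell density of a labeled strip in cells per 10 micrometers."""
    if strip_length_um <= 0:
        raise ValueError("strip length must be > 0")
    return 10.0 * strip_cell_count / strip_length_um


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------

def read_score_matrix(
    path: Union[str, Path],
    time_h: Optional[float] = None,
    tissue: str = "",
    group: str = "",
    analog: str = "BrdU",
    sep: Optional[str] = None,
) -> CVEUScoreMatrix:
    """Read one score matrix from delimited text.

    Layout: header row of 1-based positions, one row per CVEU; empty fields
    or "NA" mark positions beyond a shorter CVEU.  Metadata not stored in the
    file is supplied by the caller (or by a sidecar config upstream).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty score matrix")
    if time_h is None:
        raise ValueError("time_h must be provided for a score matrix")
    return CVEUScoreMatrix(
        df.to_numpy(dtype=float), time_h=time_h, tissue=tissue, group=group, analog=analog
    )


def write_score_matrix(m: CVEUScoreMatrix, path: Union[str, Path], sep: str = ",") -> None:
    df = pd.DataFrame(m.scores, columns=[str(i) for i in range(1, m.length + 1)])
    # keep 0/1 readable; NaN becomes NA
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%g")


def write_profile(p: PositionProfile, path: Union[str, Path], sep: str = ",") -> None:
    """Tidy per-position table: group, tissue, analog, time_h, position, value, n_obs."""
    df = pd.DataFrame(
        {
            "group": p.group,
            "tissue": p.tissue,
            "analog": p.analog,
            "time_h": p.time_h,
            "position": p.positions,
            "value": p.proportion,
            "n_obs": p.n_obs,
        }
    )
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def write_counts(
    counts: pd.DataFrame, path: Union[str, Path], sep: str = ",", **meta: str
) -> None:
    """Write a compartment-count series, with optional constant metadata columns."""
    df = counts.copy()
    for k, v in meta.items():
        df[k] = v
    df.to_csv(path, sep=sep, index=False)


def write_front_track(track: pd.DataFrame, path: Union[str, Path], sep: str = ",") -> None:
    track.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_front_track(path: Union[str, Path], sep: Optional[str] = None) -> pd.DataFrame:
    """Front-track table with columns time_h, front_position_um."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    missing = {"time_h", "front_position_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
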