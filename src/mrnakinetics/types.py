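"""Core domain types for the translation-kinetics models.

The reaction network has two species, mRNA (``x1``) and GFP (``x2``),
and three first-order reactions: mRNA degradation (rate ``theta1``),
translation (``theta2``) and GFP degradation (``theta3``).  All mRNA is
released at once at time ``t0`` (``m0`` copies); the fluorescence signal
is ``scale * x2 + offset`` corrupted by multiplicative lognormal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd


class InvalidParameterError(ValueError):
    """A model or experiment parameter violates its constraints."""


class DataFormatError(ValueError):
    """An on-disk trajectory/observation file violates the expected format."""


class InsufficientDataError(ValueError):
    """An operation received fewer data points than it requires."""


class DegenerateSignalError(ValueError):
    """The noise model is undefined (zero signal with positive noise scale)."""


@dataclass(frozen=True)
class KineticParams:
    """Mass-action rate constants, all in 1/h.

    theta1: mRNA degradation, theta2: translation, theta3: GFP degradation.
    """

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)

    def swapped(self) -> "KineticParams":
        """Exchange the two degradation rates (theta1 <-> theta3)."""
        return KineticParams(self.theta3, self.theta2, self.theta1)


@dataclass(frozen=True)
class ExperimentParams:
    """Release size/time, signal calibration and noise level.

    m0: initial mRNA copy number released at t0 (m0 = 0 is the degenerate
    empty system); t0: release time in hours; scale: fluorescence per GFP
    molecule (a.u.); offset: background fluorescence (a.u.); sigma: scale of
    the multiplicative lognormal measurement error.
    """

    m0: float
    t0: float
    scale: float
    offset: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.m0) or self.m0 < 0:
            raise InvalidParameterError(f"m0 must be >= 0, got {self.m0!r}")
        if not np.isfinite(self.t0) or self.t0 < 0:
            raise InvalidParameterError(f"t0 must be >= 0, got {self.t0!r}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale!r}")
        if not np.isfinite(self.offset) or self.offset < 0:
            raise InvalidParameterError(f"offset must be >= 0, got {self.offset!r}")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma!r}")


@dataclass
class StatePath:
    """A time-indexed (x1, x2) trajectory.

    ``kind`` is one of ``jump`` (integer-valued Markov jump process sample,
    piecewise constant, right-continuous), ``diffusion`` (Euler-Maruyama
    path, linearly interpolated) or ``deterministic`` (ODE solution).
    The path starts at the release time; the state is (0, 0) before it.
    """

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.kind not in ("jump", "diffusion", "deterministic"):
            raise ValueError(f"unknown path kind {self.kind!r}")
        if not (len(self.times) == len(self.x1) == len(self.x2)):
            raise ValueError("times, x1, x2 must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def states_at(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sample the path on ``grid``.

        Jump paths use right-continuous step interpolation (the state after
        the last event at or before t); diffusion/deterministic paths are
        interpolated linearly.  Times before the path start map to (0, 0).
        """
        grid = np.asarray(grid, dtype=float)
        if self.kind == "jump":
            idx = np.searchsorted(self.times, grid, side="right") - 1
            pre = idx < 0
            idx = np.clip(idx, 0, len(self.times) - 1)
            x1 = self.x1[idx]
            x2 = self.x2[idx]
            x1[pre] = 0.0
            x2[pre] = 0.0
            return x1, x2
        x1 = np.interp(grid, self.times, self.x1, left=0.0)
        x2 = np.interp(grid, self.times, self.x2, left=0.0)
        return x1, x2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "x1": self.x1, "x2": self.x2})

    def to_csv(self, path: str | Path, write_meta: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if write_meta and self.meta:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            sidecar.write_text(json.dumps({"kind": self.kind, **self.meta}, indent=1))


@dataclass
class ObservationSeries:
    """Fluorescence intensities y_k > 0 on an (equidistant) time grid t_k."""

    times: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    #: relative tolerance on grid-spacing constancy
    GRID_RTOL = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) != len(self.y):
            raise DataFormatError("times and y must have equal length")
        if len(self.times) < 2:
            raise InsufficientDataError("an observation series needs K >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise DataFormatError("observation times must be strictly increasing")
        if np.any(self.y <= 0):
            raise DataFormatError("all intensities must be strictly positive")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def is_equidistant(self) -> bool:
        d = np.diff(self.times)
        return bool(np.allclose(d, d[0], rtol=self.GRID_RTOL, atol=0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "intensity": self.y})

    def to_csv(self, path: str | Path, write_meta: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if write_meta and self.meta:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            sidecar.write_text(json.dumps(self.meta, indent=1))


def first_index_at_or_after(times: np.ndarray, t0: float) -> int:
    """0-based index k* of the first observation time >= t0."""
    times = np.asarray(times, dtype=float)
    k = int(np.searchsorted(times, t0, side="left"))
    if k >= len(times):
        raise InvalidParameterError(f"t0={t0} lies beyond the last observation time")
    return k


def params_to_dict(kp: KineticParams, ep: ExperimentParams) -> dict:
    return {**asdict(kp), **asdict(ep)}
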