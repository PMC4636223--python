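"""Pulling-trace parsing, rupture detection and rupture-dataset assembly.

A force-probe pulling run yields channels sampled on a common time axis:
spring separation, transducer force, and optionally the buried interface
area and the end-to-end distance of the pulled groups.  The rupture force
is the highest peak of the (smoothed) force trace; when an interface-area
channel is present the peak is cross-checked against the first area drop,
which the pulling experiments show to coincide with the force maximum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .dfs_models import PullingProtocol, ValidationError

__all__ = [
    "ForceTrace",
    "RuptureEvent",
    "AreaSteps",
    "TraceFormatError",
    "read_force_trace",
    "detect_rupture",
    "loading_rate",
    "cumulative_event_curve",
    "detect_area_steps",
]

CSV_COLUMNS = ("time_ns", "spring_sep_nm", "force_pN", "area_nm2", "ee_nm")


class TraceFormatError(ValueError):
    """Malformed trace file (ragged columns, bad time axis, ...)."""


@dataclass
class ForceTrace:
    """Force-probe pulling time series.

    All channels share the strictly increasing ``time`` axis (ns).  Optional
    channels are None when absent.  ``metadata`` carries protocol context
    (velocity nm/ns, stiffness pN/nm, run id) when known.
    """

    time: np.ndarray
    spring_separation: np.ndarray
    force: np.ndarray
    interface_area: Optional[np.ndarray] = None
    end_to_end: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.spring_separation = np.asarray(self.spring_separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if n < 10:
            raise ValidationError(f"trace needs >= 10 samples, got {n}")
        for name in ("spring_separation", "force", "interface_area", "end_to_end"):
            ch = getattr(self, name)
            if ch is None:
                continue
            ch = np.asarray(ch, dtype=float)
            setattr(self, name, ch)
            if ch.size != n:
                raise ValidationError(
                    f"channel {name} has {ch.size} samples, time axis has {n}"
                )
        bad = np.nonzero(np.diff(self.time) <= 0)[0]
        if bad.size:
            raise TraceFormatError(
                f"time axis not strictly increasing at sample {bad[0] + 1}"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_ns": self.time,
            "spring_sep_nm": self.spring_separation,
            "force_pN": self.force,
        }
        if self.interface_area is not None:
            cols["area_nm2"] = self.interface_area
        if self.end_to_end is not None:
            cols["ee_nm"] = self.end_to_end
        return pd.DataFrame(cols)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RuptureEvent:
    """A detected rupture: peak force and where/when it happened.

    ``event_type`` distinguishes dissociation of the F2-lobe from the kinase
    C-lobe ("F2-C") from the later release of the Tyr576/577 activation loop
    ("F-YY").  ``area_consistency`` is "consistent" when the force peak falls
    within one smoothing window of the first interface-area drop,
    "inconsistent" when it does not, and "no-area" when the trace carries no
    area channel.
    """

    rupture_force: float
    time: float
    d_spring: float
    d_ee: Optional[float] = None
    event_type: str = "F2-C"
    area_consistency: str = "no-area"

    def __post_init__(self) -> None:
        if self.rupture_force <= 0:
            raise ValidationError("rupture force must be positive")
        if self.event_type not in ("F2-C", "F-YY"):
            raise ValidationError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class AreaSteps:
    """Piecewise-constant segmentation of an interface-area channel."""

    step_times: tuple
    plateau_levels: tuple
    intermediate_present: bool

    @property
    def intermediate_level(self) -> Optional[float]:
        return self.plateau_levels[1] if self.intermediate_present else None


# ---------------------------------------------------------------------------
# I/O


def read_force_trace(
    path: Union[str, Path], format: Optional[str] = None, metadata: Optional[dict] = None
) -> ForceTrace:
    """Read a pulling trace from CSV (named columns) or GROMACS XVG.

    CSV requires the header ``time_ns,spring_sep_nm,force_pN[,area_nm2,ee_nm]``.
    XVG comment/legend lines (# and @) are skipped and columns are taken
    positionally in the same order.
    """
    path = Path(path)
    if format is None:
        format = "xvg" if path.suffix.lower() == ".xvg" else "csv"
    if format not in ("csv", "xvg"):
        raise ValidationError(f"unknown trace format {format!r}")
    text = path.read_text()
    if not text.strip():
        raise TraceFormatError(f"{path}: empty file")
    if format == "csv":
        df = pd.read_csv(io.StringIO(text))
        missing = [c for c in CSV_COLUMNS[:3] if c not in df.columns]
        if missing:
            raise TraceFormatError(f"{path}: missing required columns {missing}")
        if df.isna().any().any():
            line = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
            raise TraceFormatError(f"{path}: ragged/missing values near line {line}")
        cols = [df[c].to_numpy() for c in CSV_COLUMNS if c in df.columns]
        names = [c for c in CSV_COLUMNS if c in df.columns]
    else:
        rows, names = [], []
        width = None
        for ln, raw in enumerate(text.splitlines(), start=1):
            s = raw.strip()
            if not s or s.startswith(("#", "@")):
                continue
            vals = s.split()
            if width is None:
                width = len(vals)
                if width < 3:
                    raise TraceFormatError(f"{path}: line {ln}: expected >= 3 columns")
            elif len(vals) != width:
                raise TraceFormatError(
                    f"{path}: line {ln}: ragged row ({len(vals)} columns, expected {width})"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise TraceFormatError(f"{path}: line {ln}: {exc}") from None
        if not rows:
            raise TraceFormatError(f"{path}: no data rows")
        arr = np.asarray(rows)
        cols = [arr[:, i] for i in range(min(arr.shape[1], 5))]
        names = list(CSV_COLUMNS[: len(cols)])
    kw = dict(zip(names, cols))
    try:
        return ForceTrace(
            time=kw["time_ns"],
            spring_separation=kw["spring_sep_nm"],
            force=kw["force_pN"],
            interface_area=kw.get("area_nm2"),
            end_to_end=kw.get("ee_nm"),
            metadata=dict(metadata or {}),
        )
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Detection


def _smooth(y: np.ndarray, n_window: int) -> np.ndarray:
    """Centered moving average; edges use the available (shorter) window."""
    if n_window <= 1:
        return y.astype(float)
    kernel = np.ones(n_window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def _window_samples(time: np.ndarray, window_ns: float) -> int:
    dt = np.median(np.diff(time))
    return max(1, int(round(window_ns / dt)))


def detect_rupture(
    trace: ForceTrace,
    smoothing_window: Optional[float] = None,
    event_type: str = "F2-C",
) -> Optional[RuptureEvent]:
    """Find the rupture event of a pulling trace.

    The force channel is smoothed with a centered moving average (default
    window: 1% of the trace duration) and the rupture force is its global
    maximum.  If the maximum sits at the trailing edge the force is still
    rising -- no rupture occurred -- and None is returned (data, not an
    exception: a minority of pulling runs end in conformational damage
    instead of dissociation).

    When an interface-area channel is present, the event is validated to lie
    within one smoothing window of the first area drop.
    """
    if smoothing_window is None:
        smoothing_window = 0.01 * trace.duration
    nw = _window_samples(trace.time, smoothing_window)
    f = _smooth(trace.force, nw)
    i_peak = int(np.argmax(f))
    if i_peak >= trace.time.size - max(nw, 2):
        return None  # still rising at the end: no event
    t_peak = float(trace.time[i_peak])

    consistency = "no-area"
    if trace.interface_area is not None:
        steps = detect_area_steps(trace.interface_area, trace.time)
        if steps.step_times:
            t_drop = steps.step_times[0]
            tol = max(smoothing_window, trace.time[1] - trace.time[0])
            consistency = "consistent" if abs(t_peak - t_drop) <= tol else "inconsistent"
        else:
            consistency = "inconsistent"

    dee = None
    if trace.end_to_end is not None:
        dee = float(np.interp(t_peak, trace.time, trace.end_to_end))
    return RuptureEvent(
        rupture_force=float(f[i_peak]),
        time=t_peak,
        d_spring=float(np.interp(t_peak, trace.time, trace.spring_separation)),
        d_ee=dee,
        event_type=event_type,
        area_consistency=consistency,
    )


def loading_rate(source: Union[PullingProtocol, ForceTrace]) -> float:
    """Loading rate in pN/s.

    From a protocol: exactly ``stiffness_factor * kappa_s * v``.  From a
    trace: the Theil-Sen slope of the pre-rupture force ramp (10-90% of the
    time up to the force peak), robust to the thermal force noise.
    """
    if isinstance(source, PullingProtocol):
        if source.velocity == 0:
            raise ValidationError("zero velocity: loading rate undefined")
        return source.loading_rate
    trace = source
    event = detect_rupture(trace)
    t_end = event.time if event is not None else trace.time[-1]
    t0, t1 = trace.time[0], t_end
    lo, hi = t0 + 0.1 * (t1 - t0), t0 + 0.9 * (t1 - t0)
    sel = (trace.time >= lo) & (trace.time <= hi)
    if sel.sum() < 3:
        raise ValidationError("too few pre-rupture samples to fit a ramp")
    slope = stats.theilslopes(trace.force[sel], trace.time[sel]).slope
    return float(slope * 1e9)  # pN/ns -> pN/s


def cumulative_event_curve(
    events: Sequence[RuptureEvent], event_type: Optional[str] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative number of dissociation events vs end-to-end distance.

    Returns ``(d_ee, count)`` where ``count[i]`` is the number of events of
    the requested type with D_e-e <= d_ee[i]; invariant under input order.
    """
    dee = sorted(
        e.d_ee
        for e in events
        if (event_type is None or e.event_type == event_type) and e.d_ee is not None
    )
    return np.asarray(dee, dtype=float), np.arange(1, len(dee) + 1, dtype=int)


# ---------------------------------------------------------------------------
# Interface-area step segmentation


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Index minimizing the two-segment SSE of y, plus the SSE reduction."""
    n = y.size
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    i = np.arange(1, n)  # split before index i
    sse_l = c2[i - 1] - c1[i - 1] ** 2 / i
    tot1, tot2 = c1[-1], c2[-1]
    sse_r = (tot2 - c2[i - 1]) - (tot1 - c1[i - 1]) ** 2 / (n - i)
    sse0 = tot2 - tot1**2 / n
    j = int(np.argmin(sse_l + sse_r))
    return int(i[j]), float(sse0 - (sse_l[j] + sse_r[j]))


def detect_area_steps(
    area: np.ndarray,
    time: np.ndarray,
    min_drop: float = 1.0,
    min_segment: int = 5,
) -> AreaSteps:
    """Segment an interface-area channel into plateaus by change-point splits.

    Recursive binary splitting on within-segment variance; a split is kept
    while the level change across it is at least ``min_drop`` (nm^2).  The
    pulling data show a two-step collapse: initial contact area, a short
    intermediate plateau, then zero.
    """
    area = np.asarray(area, dtype=float)
    time = np.asarray(time, dtype=float)
    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_segment:
            return
        split, _gain = _best_split(area[lo:hi])
        split += lo
        if split - lo < min_segment or hi - split < min_segment:
            return
        left = float(np.mean(area[lo:split]))
        right = float(np.mean(area[split:hi]))
        if abs(left - right) < min_drop:
            return
        recurse(lo, split)
        boundaries.append(split)
        recurse(split, hi)

    recurse(0, area.size)
    boundaries.sort()
    edges = [0, *boundaries, area.size]
    levels = tuple(float(np.mean(area[a:b])) for a, b in zip(edges[:-1], edges[1:]))
    times = tuple(float(time[b]) for b in boundaries)
    return AreaSteps(
        step_times=times,
        plateau_levels=levels,
        intermediate_present=len(levels) >= 3,
    )
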