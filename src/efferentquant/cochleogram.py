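"""Cochlear geometry: spiral-bundle traces, the place-frequency map, and
placement of per-frequency analysis frames.

The organ of Corti is reconstructed en face from dissected surface
preparations and a polyline traced along the spiral bundle measures the
cochlear length.  A Greenwood-form map

    F(x) = A * (10**(a*x) - k)        x = fractional arc position

assigns a characteristic frequency to each fractional position ``x`` in
[0, 1] along the trace, measured from the apex (low frequencies) toward the
base.  Default constants are Greenwood's published fit for the rat
(A = 0.398 kHz, a = 2.2, k = 0.631), which spans roughly 0.15-63 kHz and
therefore covers the six standard analysis frequencies 2.8, 8, 11.3, 16, 32
and 45.2 kHz.  Constants are configuration, not truth: traces from other
species or other map fits drop in unchanged.

Frequency assignment depends only on the *fractional* arc position, so a
uniformly rescaled trace maps every frequency to the same relative place;
absolute arc positions scale with the measured trace length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpiralTrace",
    "PlaceFrequencyMap",
    "FrequencyFrame",
    "trace_length",
    "place_to_frequency",
    "frequency_to_place",
    "locate_frequency_frames",
    "read_trace_csv",
    "RAT_MAP",
]


@dataclass(frozen=True)
class SpiralTrace:
    """Ordered polyline along the spiral bundle, apex first, in micrometres."""

    points: np.ndarray  # (n, 2) float array, µm, image convention (y down)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("trace needs at least two (x, y) points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace coordinates must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive trace points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())

    def point_at_arc(self, s: float) -> np.ndarray:
        """Linearly interpolated (x, y) at arc position ``s`` µm from the start."""
        if not 0 <= s <= self.length:
            raise ValueError(f"arc position {s} outside [0, {self.length}]")
        arcs = self.arc_lengths
        x = np.interp(s, arcs, self.points[:, 0])
        y = np.interp(s, arcs, self.points[:, 1])
        return np.array([x, y])


@dataclass(frozen=True)
class PlaceFrequencyMap:
    """Greenwood-form place-frequency map F(x) = A*(10**(a*x) - k).

    ``x`` is the fraction of cochlear length measured from the apex.
    ``reference_length_um`` is a normalisation reference only (the adult
    Wistar basilar membrane is about 9,400 µm); arc positions are always
    computed on the measured trace length.
    """

    A: float = 0.398  # kHz
    a: float = 2.2
    k: float = 0.631
    reference_length_um: float = 9400.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a <= 0:
            raise ValueError("map constants A and a must be positive")
        if not 0 <= self.k < 1:
            raise ValueError("k must lie in [0, 1) for an invertible apex-to-base map")

    @property
    def f_min(self) -> float:
        return self.A * (1.0 - self.k)

    @property
    def f_max(self) -> float:
        return self.A * (10.0 ** self.a - self.k)


#: Greenwood's published rat constants, the package default.
RAT_MAP = PlaceFrequencyMap()


@dataclass(frozen=True)
class FrequencyFrame:
    """An analysis frame centered on the trace at one target frequency."""

    frequency_khz: float
    arc_position_um: float
    center: tuple[float, float]
    bounds: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax) µm
    clipped: bool = False


def trace_length(trace: SpiralTrace) -> float:
    """Total polyline length in µm (sum of Euclidean segment lengths)."""
    return trace.length


def place_to_frequency(x, m: PlaceFrequencyMap = RAT_MAP):
    """Characteristic frequency (kHz) at fractional position ``x`` from the apex."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise ValueError("fractional position must lie in [0, 1]")
    f = m.A * (10.0 ** (m.a * xa) - m.k)
    return float(f) if np.isscalar(x) or xa.ndim == 0 else f


def frequency_to_place(f, m: PlaceFrequencyMap = RAT_MAP):
    """Inverse map: fractional position from the apex of frequency ``f`` kHz."""
    fa = np.asarray(f, dtype=float)
    if np.any(fa < m.f_min) or np.any(fa > m.f_max):
        raise ValueError(
            f"frequency outside map range [{m.f_min:.4g}, {m.f_max:.4g}] kHz"
        )
    x = np.log10(fa / m.A + m.k) / m.a
    # guard the endpoints against round-off leaking outside [0, 1]
    x = np.clip(x, 0.0, 1.0)
    return float(x) if np.isscalar(f) or fa.ndim == 0 else x


def locate_frequency_frames(
    trace: SpiralTrace,
    frequencies_khz,
    m: PlaceFrequencyMap = RAT_MAP,
    frame_size_um: float = 80.0,
    image_bounds: tuple[float, float, float, float] | None = None,
    trace_starts_at: str = "apex",
) -> list[FrequencyFrame]:
    """Place one axis-aligned square analysis frame per requested frequency.

    Arc positions are fractions of the *measured* trace length.  If
    ``image_bounds`` is given and a frame extends beyond it, the frame is
    clipped with a warning (flagged on the result).
    """
    if trace_starts_at not in ("apex", "base"):
        raise ValueError("trace_starts_at must be 'apex' or 'base'")
    L = trace.length
    half = frame_size_um / 2.0
    frames = []
    for f in frequencies_khz:
        x = frequency_to_place(f, m)
        if trace_starts_at == "base":
            x = 1.0 - x
        s = x * L
        cx, cy = trace.point_at_arc(s)
        bounds = (cx - half, cy - half, cx + half, cy + half)
        clipped = False
        if image_bounds is not None:
            bx0, by0, bx1, by1 = image_bounds
            cb = (
                max(bounds[0], bx0),
                max(bounds[1], by0),
                min(bounds[2], bx1),
                min(bounds[3], by1),
            )
            if cb != bounds:
                warnings.warn(
                    f"frame at {f} kHz extends beyond the image and was clipped",
                    stacklevel=2,
                )
                bounds, clipped = cb, True
        frames.append(
            FrequencyFrame(
                frequency_khz=float(f),
                arc_position_um=float(s),
                center=(float(cx), float(cy)),
                bounds=bounds,
                clipped=clipped,
            )
        )
    return frames


def read_trace_csv(path) -> SpiralTrace:
    """Read an ordered x,y (µm) polyline from a headered CSV file."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError("trace CSV needs 'x' and 'y' columns (µm)")
    return SpiralTrace(df[[cols["x"], cols["y"]]].to_numpy(dtype=float))
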