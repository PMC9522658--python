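"""Line-scan preprocessing: from raw per-profile intensities to the binned,
normalized space x time waveform matrix consumed by the decomposition.

The pipeline mirrors the standard kymograph workflow: ~50 line-scan profiles
are drawn across each tubule cell per time point, their position axes are
rescaled onto [0, 1] (0 = apical, 1 = basolateral), all samples of a tubule
and time point are pooled and mean-binned onto a uniform grid, and the binned
vectors are assembled into a position x time matrix.  A QC pass flags time
points whose spatial profile decorrelates from the record or whose total
intensity jumps, as happens with focus drift or collapsing tubules; flagged
points are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Orientation = Literal["apical_first", "basal_first"]


@dataclass
class LineScanProfile:
    """One line scan across a cell at one time point."""

    tubule_id: str
    time: float
    positions: np.ndarray
    intensities: np.ndarray
    profile_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size < 2:
            raise ValueError("a line-scan profile needs at least 2 samples")
        if self.positions.size != self.intensities.size:
            raise ValueError("positions and intensities must have equal length")
        d = np.diff(self.positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("positions must be strictly monotone")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class WaveformMatrix:
    """Space x time intensity matrix for one tubule.

    ``values[i, j]`` is the mean intensity in position bin ``i`` at time
    ``times[j]``; ``position_bins`` are the bin centers, uniform on [0, 1]
    with 0 = apical.
    """

    tubule_id: str
    position_bins: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.position_bins = np.asarray(self.position_bins, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        b, t = self.values.shape
        if self.position_bins.size != b or self.times.size != t:
            raise ValueError("values shape must be (n_bins, n_times)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("waveform intensities must be >= 0")
        widths = np.diff(self.position_bins)
        if b > 1 and not np.allclose(widths, widths[0]):
            raise ValueError("position bins must be uniform")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def bin_centers(n_bins: int) -> np.ndarray:
    """Centers of ``n_bins`` uniform bins on [0, 1]."""
    return (np.arange(n_bins) + 0.5) / n_bins


def rescale_positions(profile: LineScanProfile,
                      orientation: Orientation = "apical_first") -> LineScanProfile:
    """Affinely map a profile's position axis onto [0, 1], apical-first.

    ``basal_first`` profiles (drawn basal -> apical) are flipped so that 0 is
    always the apical side.  Endpoints map exactly to 0 and 1; intensities are
    unchanged.  Idempotent for already-normalized apical-first profiles.
    """
    pos = profile.positions
    lo, hi = pos[0], pos[-1]
    if hi == lo:
        raise ValueError("degenerate profile: zero position extent")
    x = (pos - lo) / (hi - lo)
    inten = profile.intensities
    if x[0] > x[-1]:  # descending coordinates: re-sort ascending
        x, inten = x[::-1], inten[::-1]
    if orientation == "basal_first":
        x, inten = (1.0 - x)[::-1], inten[::-1]
    elif orientation != "apical_first":
        raise ValueError(f"unknown orientation {orientation!r}")
    return LineScanProfile(profile.tubule_id, profile.time, x, inten,
                           profile.profile_id)


def bin_profiles(profiles: Sequence[LineScanProfile], n_bins: int = 100
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-bin the pooled samples of all profiles of one tubule/time point.

    Bins are half-open ``[i/B, (i+1)/B)`` with the last bin closed.  Bins that
    receive no sample are filled by linear interpolation from their neighbors
    and reported in the returned boolean mask.

    Returns ``(binned_vector, empty_bin_mask)``.
    """
    if not profiles:
        raise ValueError("no profiles to bin")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t0, tub = profiles[0].time, profiles[0].tubule_id
    for p in profiles:
        if p.time != t0 or p.tubule_id != tub:
            raise ValueError("all profiles must share tubule_id and time")
    pos = np.concatenate([p.positions for p in profiles])
    inten = np.concatenate([p.intensities for p in profiles])
    idx = np.minimum((pos * n_bins).astype(int), n_bins - 1)  # closes last bin
    sums = np.bincount(idx, weights=inten, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    empty = counts == 0
    vec = np.zeros(n_bins)
    vec[~empty] = sums[~empty] / counts[~empty]
    if empty.any():
        if empty.all():
            raise ValueError("all bins empty")
        centers = bin_centers(n_bins)
        vec[empty] = np.interp(centers[empty], centers[~empty], vec[~empty])
    return vec, empty


def assemble_waveform(binned: dict[float, np.ndarray], tubule_id: str = "tubule",
                      n_bins: int | None = None) -> WaveformMatrix:
    """Stack per-time binned vectors into a waveform matrix, columns sorted by time."""
    if not binned:
        raise ValueError("no binned vectors")
    times = sorted(binned)
    if len(times) != len(set(times)):
        raise ValueError("duplicate times")
    lengths = {len(binned[t]) for t in times}
    if len(lengths) != 1:
        raise ValueError(f"ragged binned vectors: lengths {sorted(lengths)}")
    (b,) = lengths
    if n_bins is not None and b != n_bins:
        raise ValueError(f"expected {n_bins} bins, got {b}")
    values = np.column_stack([np.asarray(binned[t], dtype=float) for t in times])
    return WaveformMatrix(tubule_id, bin_centers(b), np.asarray(times), values)


@dataclass
class QCFlag:
    time_index: int
    time: float
    reason: str
    value: float


def qc_flags(waveform: WaveformMatrix, corr_min: float = 0.5,
             intensity_band: tuple[float, float] = (0.2, 5.0),
             window: int = 11) -> list[QCFlag]:
    """Flag time points with unstable imaging or tissue changes.

    A column is flagged when (a) its Pearson correlation with the median-over-
    time spatial vector falls below ``corr_min``, or (b) its total intensity
    leaves ``intensity_band`` times the running median (centered window) of
    column totals.  Flags are reported; nothing is dropped.
    """
    vals = waveform.values
    if vals.shape[1] < 2:
        raise ValueError("QC needs at least 2 time points")
    flags: list[QCFlag] = []
    median_vec = np.median(vals, axis=1)
    mv = median_vec - median_vec.mean()
    mv_norm = np.sqrt((mv ** 2).sum())
    for j in range(vals.shape[1]):
        col = vals[:, j] - vals[:, j].mean()
        cn = np.sqrt((col ** 2).sum())
        if cn == 0 or mv_norm == 0:
            r = 0.0
        else:
            r = float(np.dot(col, mv) / (cn * mv_norm))
        if r < corr_min:
            flags.append(QCFlag(j, float(waveform.times[j]),
                                "low_spatial_correlation", r))
    totals = vals.sum(axis=0)
    half = window // 2
    for j in range(len(totals)):
        lo, hi = max(0, j - half), min(len(totals), j + half + 1)
        run_med = float(np.median(totals[lo:hi]))
        if run_med > 0 and not (intensity_band[0] * run_med <= totals[j]
                                <= intensity_band[1] * run_med):
            flags.append(QCFlag(j, float(waveform.times[j]),
                                "total_intensity_outlier", float(totals[j])))
    return flags


def cumulative_normalize(intensities: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative intensity vector to unit total (sums to 1)."""
    x = np.asarray(intensities, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be >= 0")
    s = x.sum()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero intensity vector")
    return x / s


def waveform_from_profiles(profiles: Iterable[LineScanProfile], n_bins: int = 100,
                           orientation: Orientation = "apical_first"
                           ) -> tuple[WaveformMatrix, dict]:
    """Full preprocessing chain: rescale -> group by time -> bin -> assemble.

    Returns the waveform and a report dict (empty-bin fractions per time).
    """
    by_time: dict[float, list[LineScanProfile]] = {}
    tubule_id = None
    for p in profiles:
        q = rescale_positions(p, orientation)
        by_time.setdefault(q.time, []).append(q)
        tubule_id = q.tubule_id
    if not by_time:
        raise ValueError("no profiles")
    binned, empty_frac = {}, {}
    for t, group in by_time.items():
        vec, empty = bin_profiles(group, n_bins)
        binned[t] = vec
        empty_frac[t] = float(empty.mean())
    wf = assemble_waveform(binned, tubule_id or "tubule", n_bins)
    return wf, {"empty_bin_fraction": empty_frac}
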