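"""Slow-oscillation analysis: global Up-state detection, per-cell Up/Down
intervals, onset/offset latencies, participation, propagation speed,
regularity, and the intact score.

Conventions
-----------
Global Up states are local maxima of a layer LFP (mean layer-2 voltage x 20)
with a minimum separation of 500 ms and a minimum prominence of half the
signal range; the amplitude of an event is the peak minus the lowest point
before the next peak, and the oscillation frequency is the mean of the
inverse inter-peak intervals.

Per-cell states use a double threshold (Up above -65 mV, Down below -68 mV);
runs of the same state closer than 100 ms are merged first, and any state
shorter than 100 ms is then removed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit
from scipy.signal import find_peaks

from .connectome import CORTICAL_EXC_CLASSES, Connectome
from .mesh import HemisphereMesh, geodesic_distances

V_UP = -65.0    # mV, Up-state threshold
V_DOWN = -68.0  # mV, Down-state threshold
MIN_STATE_MS = 100.0
MIN_PEAK_SEPARATION_MS = 500.0


# ---------------------------------------------------------------------------
# global Up states
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class UpStateEvent:
    peak_time_s: float
    peak_index: int
    amplitude: float            # LFP units (scaled mV)
    window: tuple[int, int]     # sample window between surrounding minima
    onsets_ms: np.ndarray | None = None      # per-column onset latency, NaN = absent
    offsets_ms: np.ndarray | None = None
    participation: float | None = None       # percent
    speed_mm_s: float | None = None
    origin_column: int | None = None


@dataclasses.dataclass
class UpStateCatalog:
    events: list
    dt_s: float
    frequency_hz: float          # mean of inverse inter-peak intervals
    mean_amplitude: float
    onset_std_ms: float | None = None
    offset_std_ms: float | None = None
    mean_participation: float | None = None
    mean_speed_mm_s: float | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


def detect_global_up_states(lfp: np.ndarray, dt_s: float = 5e-4) -> UpStateCatalog:
    """Detect global Up-state peaks on an LFP trace.

    A constant trace yields zero events.  Frequency is defined only when at
    least two peaks exist.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    if len(lfp) * dt_s <= 1.0:
        raise ValueError("trace must be longer than 1 s")
    rng_ = lfp.max() - lfp.min()
    if rng_ == 0:
        return UpStateCatalog(events=[], dt_s=dt_s, frequency_hz=0.0, mean_amplitude=0.0)
    min_sep = int(round(MIN_PEAK_SEPARATION_MS / 1000.0 / dt_s))
    peaks, _ = find_peaks(lfp, distance=min_sep, prominence=0.5 * rng_)
    events = []
    for i, p in enumerate(peaks):
        nxt = peaks[i + 1] if i + 1 < len(peaks) else len(lfp)
        amplitude = float(lfp[p] - lfp[p:nxt].min())
        events.append(UpStateEvent(peak_time_s=p * dt_s, peak_index=int(p),
                                   amplitude=amplitude, window=(0, 0)))
    if len(peaks) >= 2:
        freq = float(np.mean(1.0 / (np.diff(peaks) * dt_s)))
    else:
        freq = 0.0
    mean_amp = float(np.mean([e.amplitude for e in events])) if events else 0.0
    return UpStateCatalog(events=events, dt_s=dt_s, frequency_hz=freq, mean_amplitude=mean_amp)


# ---------------------------------------------------------------------------
# per-cell Up/Down intervals
# ---------------------------------------------------------------------------

def detect_cell_states(
    voltage: np.ndarray, dt_s: float, v_up: float = V_UP, v_down: float = V_DOWN
) -> list[tuple[str, int, int]]:
    """Threshold a single-cell voltage trace into Up/Down intervals.

    Returns a list of ``(state, start, end)`` with half-open sample indices.
    Intervals of the same kind separated by less than 100 ms are merged
    first; intervals shorter than 100 ms are then removed.
    """
    v = np.asarray(voltage, dtype=np.float64)
    lab = np.zeros(len(v), dtype=np.int8)  # +1 Up, -1 Down, 0 neither
    lab[v > v_up] = 1
    lab[v < v_down] = -1
    runs = _runs(lab)
    min_len = int(round(MIN_STATE_MS / 1000.0 / dt_s))
    runs = _merge_gaps(runs, min_len)
    runs = [(s, a, b) for (s, a, b) in runs if s == 0 or (b - a) >= min_len]
    return [("up" if s == 1 else "down", a, b) for (s, a, b) in runs if s != 0]


def _runs(lab: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            out.append((int(lab[start]), start, i))
            start = i
    return out


def _merge_gaps(runs, min_len):
    """Merge same-kind states separated by a gap (of anything else) under
    the minimum length."""
    runs = list(runs)
    i = 0
    while i < len(runs):
        s, a, b = runs[i]
        if s != 0:
            j = i + 1
            gap = 0
            while j < len(runs) and runs[j][0] != s:
                gap += runs[j][2] - runs[j][1]
                j += 1
            if j < len(runs) and gap < min_len and runs[j][0] == s:
                runs[i:j + 1] = [(s, a, runs[j][2])]
                continue  # re-examine the merged run for further merges
        i += 1
    return runs


@njit(cache=True)
def _refine_labels(lab: np.ndarray, min_len: int) -> None:
    """In-place merge-then-remove refinement of a +1/0/-1 label trace."""
    n = len(lab)
    # merge same-kind runs separated by < min_len of anything else
    i = 0
    while i < n:
        s = lab[i]
        j = i
        while j < n and lab[j] == s:
            j += 1
        if s != 0:
            k = j
            gap = 0
            while k < n and lab[k] != s:
                gap += 1
                k += 1
            if k < n and gap < min_len:
                for t in range(j, k):
                    lab[t] = s
                continue  # re-examine the extended run
        i = j
    # remove residual runs shorter than min_len
    i = 0
    while i < n:
        s = lab[i]
        j = i
        while j < n and lab[j] == s:
            j += 1
        if s != 0 and (j - i) < min_len:
            for t in range(i, j):
                lab[t] = 0
        i = j


@njit(cache=True)
def _label_matrix(v: np.ndarray, v_up: float, v_down: float, min_len: int) -> np.ndarray:
    n, m = v.shape
    out = np.zeros((n, m), dtype=np.int8)
    col = np.zeros(n, dtype=np.int8)
    for c in range(m):
        for t in range(n):
            x = v[t, c]
            col[t] = 1 if x > v_up else (-1 if x < v_down else 0)
        _refine_labels(col, min_len)
        for t in range(n):
            out[t, c] = col[t]
    return out


def cell_states_matrix(
    v: np.ndarray, dt_s: float, v_up: float = V_UP, v_down: float = V_DOWN
) -> np.ndarray:
    """Per-column state labels (+1 Up / -1 Down / 0) with the merge-then-
    remove refinement, for a (samples, columns) voltage matrix."""
    min_len = int(round(MIN_STATE_MS / 1000.0 / dt_s))
    return _label_matrix(np.ascontiguousarray(v, dtype=np.float64), v_up, v_down, min_len)


# ---------------------------------------------------------------------------
# onsets, offsets, participation, speed
# ---------------------------------------------------------------------------

def event_windows(
    mean_trace: np.ndarray, peaks: list[int], smooth_steps: int = 40
) -> list[tuple[int, int]]:
    """Analysis window for each event: the span between the Down-state
    troughs of the mean-voltage trace immediately flanking its peak.

    The trace is smoothed (20 ms running mean at the 0.5 ms step) and the
    nearest local minima below the event's mid-level are taken on each side;
    if none exists the deepest point towards the neighboring peak is used.
    """
    x = np.asarray(mean_trace, dtype=np.float64)
    n = len(x)
    if smooth_steps > 1:
        kernel = np.ones(smooth_steps) / smooth_steps
        xs = np.convolve(x, kernel, mode="same")
    else:
        xs = x
    glob_min = xs.min()
    minima, _ = find_peaks(-xs)
    windows = []
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else 0
        hi = peaks[i + 1] if i + 1 < len(peaks) else n
        mid = 0.5 * (xs[p] + glob_min)
        left = minima[(minima >= lo) & (minima < p) & (xs[minima] < mid)]
        right = minima[(minima > p) & (minima < hi) & (xs[minima] < mid)]
        a = int(left[-1]) if left.size else (lo + int(np.argmin(xs[lo:p])) if p > lo else lo)
        b = int(right[0]) if right.size else (p + int(np.argmin(xs[p:hi])) if hi > p else p)
        windows.append((int(a), int(max(b, a + 1))))
    return windows


def onsets_offsets(
    catalog: UpStateCatalog,
    v_columns: np.ndarray,
    mean_trace: np.ndarray,
    record_stride: int = 1,
    v_up: float = V_UP,
    v_down: float = V_DOWN,
) -> UpStateCatalog:
    """Per-column onset/offset latencies for each global Up state.

    ``v_columns`` is the (samples, columns) voltage matrix sampled every
    ``record_stride`` engine steps; ``mean_trace`` is at full resolution.
    Latencies are relative to the earliest onset (offset) in the window;
    columns that never reach an Up state in the window get NaN.
    """
    dt_rec = catalog.dt_s * record_stride
    states = cell_states_matrix(v_columns, dt_rec, v_up, v_down)
    peaks = [e.peak_index for e in catalog.events]
    windows = event_windows(mean_trace, peaks)
    all_on, all_off = [], []
    for ev, (a, b) in zip(catalog.events, windows):
        ev.window = (a, b)
        ar, br = a // record_stride, max(b // record_stride, a // record_stride + 1)
        sub = states[ar:br]
        n_cols = sub.shape[1]
        onset = np.full(n_cols, np.nan)
        offset = np.full(n_cols, np.nan)
        for c in range(n_cols):
            up_idx = np.flatnonzero(sub[:, c] == 1)
            if up_idx.size == 0:
                continue
            onset[c] = up_idx[0]
            down_after = np.flatnonzero((sub[:, c] == -1) & (np.arange(sub.shape[0]) > up_idx[0]))
            if down_after.size:
                offset[c] = down_after[0]
        if np.all(np.isnan(onset)):
            ev.onsets_ms = onset
            ev.offsets_ms = offset
            continue
        t0 = np.nanmin(onset)
        ev.onsets_ms = (onset - t0) * dt_rec * 1000.0
        if not np.all(np.isnan(offset)):
            o0 = np.nanmin(offset)
            ev.offsets_ms = (offset - o0) * dt_rec * 1000.0
        else:
            ev.offsets_ms = offset
        all_on.append(ev.onsets_ms[~np.isnan(ev.onsets_ms)])
        all_off.append(ev.offsets_ms[~np.isnan(ev.offsets_ms)])
    catalog.onset_std_ms = float(np.std(np.concatenate(all_on))) if all_on else None
    catalog.offset_std_ms = float(np.std(np.concatenate(all_off))) if all_off else None
    return catalog


def participation(event: UpStateEvent, mesh: HemisphereMesh, active_columns: np.ndarray) -> float:
    """Percent of non-medial-wall columns with a detected onset in the event."""
    if event.onsets_ms is None:
        raise ValueError("run onsets_offsets first")
    total = int(mesh.active.sum())
    detected = int(np.sum(~np.isnan(event.onsets_ms)))
    pct = 100.0 * detected / total
    event.participation = pct
    return pct


def propagation_speed(
    event: UpStateEvent,
    mesh: HemisphereMesh,
    active_columns: np.ndarray,
    origin_ms: float = 10.0,
    area_mm: float = 150.0,
    r2_min: float = 0.25,
) -> float | None:
    """Propagation speed of one Up state.

    The origin is the column with the minimal summed geodesic distance to all
    columns with onset delay under ``origin_ms``; onset delay is regressed on
    geodesic distance within ``area_mm`` of the origin, and when the fit has
    R^2 above ``r2_min`` the speed is reported in mm/s as the inverse of the
    ms/mm slope.
    """
    on = event.onsets_ms
    if on is None:
        raise ValueError("run onsets_offsets first")
    ok = ~np.isnan(on)
    early = ok & (on <= origin_ms)
    if early.sum() < 3:
        return None
    cand = active_columns[early]
    d_early = geodesic_distances(mesh, cand)[:, cand]
    origin = cand[int(np.argmin(d_early.sum(axis=1)))]
    event.origin_column = int(origin)
    d_all = geodesic_distances(mesh, np.array([origin]))[0][active_columns]
    area = ok & (d_all <= area_mm)
    if area.sum() < 3:
        return None
    x, y = d_all[area], on[area]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 <= r2_min or slope <= 0:
        return None
    speed = 1000.0 / slope  # (ms/mm)^-1 -> mm/s
    event.speed_mm_s = float(speed)
    return float(speed)


def summarize(catalog: UpStateCatalog, mesh: HemisphereMesh, active_columns: np.ndarray) -> UpStateCatalog:
    parts, speeds = [], []
    for ev in catalog.events:
        if ev.onsets_ms is None:
            continue
        parts.append(participation(ev, mesh, active_columns))
        s = propagation_speed(ev, mesh, active_columns)
        if s is not None:
            speeds.append(s)
    catalog.mean_participation = float(np.mean(parts)) if parts else None
    catalog.mean_speed_mm_s = float(np.mean(speeds)) if speeds else None
    return catalog


# ---------------------------------------------------------------------------
# regularity and intact score
# ---------------------------------------------------------------------------

@njit(cache=True)
def _apen(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    if n <= m + 1:
        return 0.0

    def phi(mm):
        count = np.zeros(n - mm + 1)
        for i in range(n - mm + 1):
            for j in range(n - mm + 1):
                d = 0.0
                for k in range(mm):
                    dd = abs(x[i + k] - x[j + k])
                    if dd > d:
                        d = dd
                if d <= r:
                    count[i] += 1.0
        s = 0.0
        for i in range(n - mm + 1):
            s += np.log(count[i] / (n - mm + 1))
        return s / (n - mm + 1)

    return phi(m) - phi(m + 1)


def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """ApEn(m, r) with tolerance ``r = r_factor * std`` (Chebyshev metric)."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        return 0.0
    return float(_apen(x, m, r_factor * sd))


@dataclasses.dataclass
class RegularityReport:
    per_parcel: np.ndarray        # regularity = 1 / max(ApEn, eps)
    mean: float
    variance: float
    intact_score: float | None = None
    regime: str | None = None


def regularity(
    parcel_lfps: np.ndarray,
    fs_hz: float,
    resample_hz: float = 100.0,
    m: int = 2,
    r_factor: float = 0.2,
    eps: float = 1e-3,
    mixed_band: tuple[float, float] = (4.0, 12.0),
) -> RegularityReport:
    """Per-parcel regularity (inverse approximate entropy) of parcel LFPs.

    Signals are resampled to 100 Hz before computing ApEn(m=2, 0.2 sd).
    Mean regularity above the mixed band is classified 'global', below it
    'local', inside it 'mixed'.
    """
    x = np.asarray(parcel_lfps, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected (parcels, samples)")
    step = max(1, int(round(fs_hz / resample_hz)))
    x = x[:, ::step]
    if x.shape[1] * step / fs_hz < 30.0:
        raise ValueError("need at least 30 s of signal per parcel")
    vals = np.array([1.0 / max(approximate_entropy(row, m, r_factor), eps) for row in x])
    mean = float(vals.mean())
    if mean > mixed_band[1]:
        regime = "global"
    elif mean < mixed_band[0]:
        regime = "local"
    else:
        regime = "mixed"
    return RegularityReport(per_parcel=vals, mean=mean, variance=float(vals.var()), regime=regime)


def intact_score(conn: Connectome, base: Connectome) -> float:
    """Percent of remaining cortical excitatory synaptic strength vs the base
    model (effective per-synapse weights, compensation included)."""
    def total(c: Connectome) -> float:
        w = c.normalized_weights()
        m = np.isin(c.cls, CORTICAL_EXC_CLASSES) & (c.receptor != 2)
        return float(w[m].sum())

    t_base = total(base)
    if t_base == 0:
        raise ValueError("base connectome has zero excitatory weight")
    return 100.0 * total(conn) / t_base
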