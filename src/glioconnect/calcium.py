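"""Functional coactivity from calcium fluorescence traces.

Pipeline: Gaussian smoothing (sigma 10 s) and prominence-based peak
detection; cells with fewer than four peaks are inactive and excluded.  For
each remaining pair closer than 100 um, the traces are shifted against one
another over the admissible lags implied by a propagation speed between 4 and
25 um/s (|tau| in [d/25, d/4] s) and the best Pearson correlation over any
10-minute segment is taken as the pair's coactivity.  A linear-shift null —
the same computation with the partner segment displaced by more than 5
minutes, preserving each trace's autocorrelation — calibrates the coactivity
threshold at its 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .synthetic import CalciumRecording


@dataclass
class CoactivityParams:
    sigma_smooth_s: float = 10.0
    min_peaks: int = 4
    prominence_frac: float = 0.25      # prominence floor as fraction of smoothed range
    max_dist_um: float = 100.0
    speed_min: float = 4.0             # um/s
    speed_max: float = 25.0
    segment_s: float = 600.0
    segment_stride_s: float = 30.0
    null_min_shift_s: float = 300.0
    threshold_percentile: float = 95.0
    n_null_draws: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_min >= self.speed_max:
            raise ValueError("speed_min must be below speed_max")


@dataclass
class PairCorrelation:
    cell_a: int
    cell_b: int
    distance_um: float
    rho_max: float
    tau_star_s: float
    segment_start_s: float
    defined: bool = True
    coactive: bool = False


@dataclass
class CoactivityResult:
    pairs: list[PairCorrelation]
    threshold: float
    null_sample: np.ndarray
    active: np.ndarray                  # bool per cell
    peak_counts: np.ndarray
    params: CoactivityParams

    def edges(self) -> list[tuple[int, int]]:
        return [(p.cell_a, p.cell_b) for p in self.pairs if p.coactive]

    def functional_degree(self) -> np.ndarray:
        deg = np.zeros(self.active.size, dtype=int)
        for a, b in self.edges():
            deg[a] += 1
            deg[b] += 1
        return deg


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def smooth_trace(trace: np.ndarray, sigma_s: float, frame_interval_s: float) -> np.ndarray:
    return scipy.ndimage.gaussian_filter1d(trace, sigma_s / frame_interval_s)


def smooth_and_detect_peaks(
    rec: CalciumRecording, params: CoactivityParams | None = None
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-cell peak frame indices on the smoothed traces, plus the active mask.

    A peak is a local maximum with prominence at least ``prominence_frac`` of
    the smoothed trace's range; a cell is active iff it has at least
    ``min_peaks`` peaks.
    """
    params = params or CoactivityParams()
    peaks_per_cell: list[np.ndarray] = []
    for c in range(rec.n_cells):
        trace = rec.traces[c]
        if np.any(~np.isfinite(trace)):
            raise ValueError(f"trace of cell {rec.cell_ids[c]!r} contains NaN/inf")
        sm = smooth_trace(trace, params.sigma_smooth_s, rec.frame_interval_s)
        rng_ = sm.max() - sm.min()
        if rng_ == 0:
            peaks_per_cell.append(np.array([], dtype=int))
            continue
        peaks, _ = scipy.signal.find_peaks(sm, prominence=params.prominence_frac * rng_)
        peaks_per_cell.append(peaks)
    counts = np.array([p.size for p in peaks_per_cell])
    return peaks_per_cell, counts >= params.min_peaks


# ---------------------------------------------------------------------------
# lags and correlation
# ---------------------------------------------------------------------------


def admissible_lags(
    distance_um: float, params: CoactivityParams, frame_interval_s: float
) -> np.ndarray:
    """Admissible lags in whole frames (both signs) for a pair at the given
    distance: |tau| in [d / speed_max, d / speed_min] seconds, bounds rounded
    inward to frames, tau = 0 excluded (it would imply infinite speed).
    Distances beyond the cutoff yield an empty set (the pair is excluded)."""
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    if distance_um > params.max_dist_um:
        return np.array([], dtype=int)
    lo = int(np.ceil(distance_um / params.speed_max / frame_interval_s))
    hi = int(np.floor(distance_um / params.speed_min / frame_interval_s))
    lo = max(lo, 1)
    if hi < lo:
        return np.array([], dtype=int)
    mags = np.arange(lo, hi + 1)
    return np.concatenate([-mags[::-1], mags])


def _segment_starts(n_frames: int, seg_len: int, stride: int) -> np.ndarray:
    last = n_frames - seg_len
    if last < 0:
        raise ValueError("recording shorter than one segment")
    return np.arange(0, last + 1, max(stride, 1))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _windowed_pearson(u: np.ndarray, v: np.ndarray, starts: np.ndarray,
                      seg_len: int) -> np.ndarray:
    """Pearson correlation of u[s:s+L] vs v[s:s+L] for each start s,
    computed with cumulative sums (zero-variance windows give NaN)."""
    cu = np.concatenate([[0.0], np.cumsum(u)])
    cv = np.concatenate([[0.0], np.cumsum(v)])
    cuu = np.concatenate([[0.0], np.cumsum(u * u)])
    cvv = np.concatenate([[0.0], np.cumsum(v * v)])
    cuv = np.concatenate([[0.0], np.cumsum(u * v)])
    e = starts + seg_len
    su = cu[e] - cu[starts]
    sv = cv[e] - cv[starts]
    suu = cuu[e] - cuu[starts]
    svv = cvv[e] - cvv[starts]
    suv = cuv[e] - cuv[starts]
    n = float(seg_len)
    cov = suv - su * sv / n
    var_u = suu - su**2 / n
    var_v = svv - sv**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = cov / np.sqrt(var_u * var_v)
    rho[(var_u <= 0) | (var_v <= 0)] = np.nan
    return rho


def best_lagged_correlation(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    lags: np.ndarray,
    params: CoactivityParams,
    frame_interval_s: float,
    b_starts: np.ndarray | None = None,
) -> tuple[float, float, float, bool]:
    """Maximum Pearson correlation of the tau-shifted a segment against the b
    segment over all admissible lags and 10-min segment positions.

    ``b_starts`` optionally supplies the partner-segment start (in frames)
    for each a-segment position — identical starts for the empirical
    computation (the default), randomly displaced starts for the linear-shift
    null, so both maximise over the same number of segment pairs.
    Returns (rho_max, tau_star_s, segment_start_s, defined).
    """
    if lags.size == 0:
        raise ValueError("empty lag set")
    n = trace_a.size
    seg_len = int(round(params.segment_s / frame_interval_s))
    stride = int(round(params.segment_stride_s / frame_interval_s))
    starts = _segment_starts(n, seg_len, stride)
    if b_starts is None:
        b_starts = starts
    best = (-np.inf, 0.0, 0.0)
    defined = False
    aligned = np.array_equal(b_starts, starts)
    for tau in lags:
        if aligned:
            # windows a[s+tau : s+tau+L] vs b[s : s+L]: slice to a common grid
            lo = max(-tau, 0)
            hi = n - seg_len - max(tau, 0)
            valid = (starts >= lo) & (starts <= hi)
            if not valid.any():
                continue
            s_val = starts[valid]
            rhos = _windowed_pearson(trace_a[tau + s_val[0]: tau + s_val[-1] + seg_len],
                                     trace_b[s_val[0]: s_val[-1] + seg_len],
                                     s_val - s_val[0], seg_len)
            s_report = s_val
        else:
            rhos, s_report = [], []
            for s, sb in zip(starts, b_starts):
                sa = s + tau
                if sa < 0 or sa + seg_len > n or sb < 0 or sb + seg_len > n:
                    continue
                rhos.append(_pearson(trace_a[sa:sa + seg_len],
                                     trace_b[sb:sb + seg_len]))
                s_report.append(s)
            rhos = np.asarray(rhos)
            s_report = np.asarray(s_report)
            if rhos.size == 0:
                continue
        ok = ~np.isnan(rhos)
        if not ok.any():
            continue
        defined = True
        i = np.nanargmax(rhos)
        if rhos[i] > best[0]:
            best = (float(rhos[i]), tau * frame_interval_s,
                    float(s_report[i]) * frame_interval_s)
    if not defined:
        return np.nan, np.nan, np.nan, False
    return best[0], best[1], best[2], True


def _eligible_pairs(
    rec: CalciumRecording, active: np.ndarray, params: CoactivityParams
) -> list[tuple[int, int, float, np.ndarray]]:
    out = []
    for a in range(rec.n_cells):
        if not active[a]:
            continue
        for b in range(a + 1, rec.n_cells):
            if not active[b]:
                continue
            d = rec.distance(a, b)
            if d == 0 or d > params.max_dist_um:
                continue
            lags = admissible_lags(d, params, rec.frame_interval_s)
            if lags.size:
                out.append((a, b, d, lags))
    return out


def null_correlations(
    rec: CalciumRecording, active: np.ndarray, params: CoactivityParams
) -> np.ndarray:
    """Linear-shift null: the whole partner trace is shifted circularly by a
    random offset of more than ``null_min_shift_s`` before the identical
    maximisation.  Each a-segment is thereby paired with a b segment
    displaced by the shift — the same traces and the same number of segment
    pairs are correlated, each trace's autocorrelation is preserved, and only
    the cross-trace alignment is destroyed.  Pools ``n_null_draws`` values
    per eligible pair."""
    rng = np.random.default_rng(params.seed)
    dt = rec.frame_interval_s
    min_shift = int(np.ceil(params.null_min_shift_s / dt)) + 1
    max_shift = rec.n_frames - min_shift
    if max_shift < min_shift:
        raise ValueError("recording too short for the linear-shift null")
    rhos = []
    for a, b, _d, lags in _eligible_pairs(rec, active, params):
        for _ in range(params.n_null_draws):
            shift = int(rng.integers(min_shift, max_shift + 1))
            b_shifted = np.roll(rec.traces[b], shift)
            rho, _t, _s, ok = best_lagged_correlation(
                rec.traces[a], b_shifted, lags, params, dt,
            )
            if ok:
                rhos.append(rho)
    return np.asarray(rhos)


def coactivity_threshold(null_sample: np.ndarray, percentile: float = 95.0) -> float:
    """Stated percentile of the null correlation sample (linear interpolation)."""
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    return float(np.percentile(null_sample, percentile))


def build_coactivity_graph(
    rec: CalciumRecording, params: CoactivityParams | None = None
) -> CoactivityResult:
    """Full coactivity pipeline: exclusions, pair correlations, null
    calibration, thresholding.  Edges are pairs with rho_max above the
    95th-percentile null threshold."""
    params = params or CoactivityParams()
    peaks, active = smooth_and_detect_peaks(rec, params)
    counts = np.array([p.size for p in peaks])
    null = null_correlations(rec, active, params)
    thr = coactivity_threshold(null, params.threshold_percentile) if null.size else np.inf
    pairs = []
    for a, b, d, lags in _eligible_pairs(rec, active, params):
        rho, tau, seg, ok = best_lagged_correlation(
            rec.traces[a], rec.traces[b], lags, params, rec.frame_interval_s
        )
        pairs.append(PairCorrelation(a, b, d, rho, tau, seg, ok,
                                     coactive=bool(ok and rho > thr)))
    return CoactivityResult(pairs, thr, null, active, counts, params)


def pairs_table(result: CoactivityResult, cell_ids: list[str]) -> pd.DataFrame:
    rows = [
        (cell_ids[p.cell_a], cell_ids[p.cell_b], p.distance_um, p.rho_max,
         p.tau_star_s, p.coactive)
        for p in result.pairs
    ]
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "distance_um",
                                       "rho_max", "tau_star_s", "coactive"])


# ---------------------------------------------------------------------------
# activity stratification
# ---------------------------------------------------------------------------


def activity_percentile_groups(peak_counts: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Label cells by activity: the lowest ceil(frac*n) are "bottom", the
    highest ceil(frac*n) are "top", cells between the (50 - frac/2)th and
    (50 + frac/2)th percentiles are "middle", everything else "none".
    Count ties at a group boundary expand the group."""
    counts = np.asarray(peak_counts)
    n = counts.size
    k = int(np.ceil(frac * n))
    order = np.argsort(counts, kind="stable")
    labels = np.array(["none"] * n, dtype=object)

    bottom_cut = counts[order[k - 1]]
    labels[counts <= bottom_cut] = "bottom"
    top_cut = counts[order[n - k]]
    labels[counts >= top_cut] = "top"

    lo, hi = np.percentile(counts, [50 - 100 * frac / 2, 50 + 100 * frac / 2])
    mid = (counts >= lo) & (counts <= hi) & (labels == "none")
    labels[mid] = "middle"
    return labels
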