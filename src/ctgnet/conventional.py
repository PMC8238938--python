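"""Conventional CTG pipeline: despiking, smoothing, Hilbert-envelope episode
detection, two-feature extraction, and the SVM / k-means baselines.

Classical CTG classifiers cannot digest a raw 1800-sample trace; the chain
here reduces each record to two human-interpretable features — the number of
accelerations and the total deceleration area (bpm·s) — which feed a
radial-basis SVM and a 2-cluster k-means baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .signal_core import FHR_MAX_BPM, FHR_MIN_BPM

__all__ = [
    "Episode",
    "FeatureVector",
    "remove_spikes",
    "smooth",
    "detect_episodes",
    "extract_features",
    "fit_svm",
    "predict_svm",
    "fit_kmeans",
    "predict_kmeans",
]

#: Episode gates: standard clinical criteria (15 bpm excursion, 15 s duration).
EPISODE_MIN_DEPTH_BPM = 15.0
EPISODE_MIN_DURATION_S = 15.0
#: Despiking: max plausible FHR change per sample step.
MAX_SLOPE_BPM_PER_STEP = 25.0
#: Baseline: centered running-median window.
BASELINE_WINDOW_S = 600.0
SMOOTH_WINDOW = 15
#: Deviations below this magnitude count as baseline when refining boundaries.
ZERO_CROSS_EPS_BPM = 0.5


@dataclass(frozen=True)
class Episode:
    """A detected acceleration or deceleration relative to the FHR baseline."""

    kind: str  # "acceleration" | "deceleration"
    onset_s: float
    offset_s: float
    extremum_bpm: float  # signed peak deviation from baseline
    area_bpm_s: float  # unsigned area between signal and baseline

    def __post_init__(self) -> None:
        if self.kind not in ("acceleration", "deceleration"):
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError("episode offset must exceed onset")
        if self.kind == "acceleration" and self.extremum_bpm <= 0:
            raise ValueError("acceleration extremum must be positive")
        if self.kind == "deceleration" and self.extremum_bpm >= 0:
            raise ValueError("deceleration extremum must be negative")
        if self.area_bpm_s < 0:
            raise ValueError("episode area must be non-negative")


@dataclass(frozen=True)
class FeatureVector:
    n_accelerations: int
    total_decel_area: float  # bpm·s

    def as_array(self) -> np.ndarray:
        return np.array([self.n_accelerations, self.total_decel_area], dtype=float)


def remove_spikes(series: np.ndarray, fs: float = 1.0) -> np.ndarray:
    """Replace physiologically implausible samples by neighbor averages.

    A sample is flagged if it lies outside [50, 210] bpm or departs from the
    last unflagged sample by more than 25 bpm per elapsed sample step. Flagged
    runs are replaced by the mean of the nearest unflagged samples on either
    side; runs touching an edge take the single nearest unflagged value.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot despike an empty series")
    flagged = ~np.isfinite(x) | (x < FHR_MIN_BPM) | (x > FHR_MAX_BPM)
    last_ok = None  # index of last unflagged sample
    for i in range(len(x)):
        if flagged[i]:
            continue
        if last_ok is not None:
            steps = i - last_ok
            if abs(x[i] - x[last_ok]) > MAX_SLOPE_BPM_PER_STEP * steps:
                flagged[i] = True
                continue
        last_ok = i
    if flagged.all():
        raise ValueError("every sample is flagged as implausible")
    idx = np.arange(len(x))
    ok = idx[~flagged]
    out = x.copy()
    for i in idx[flagged]:
        left = ok[ok < i]
        right = ok[ok > i]
        if len(left) and len(right):
            out[i] = 0.5 * (x[left[-1]] + x[right[0]])
        elif len(left):
            out[i] = x[left[-1]]
        else:
            out[i] = x[right[0]]
    return out


def smooth(series: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered bilateral moving average of ``window`` points (default 15).

    Edges use the truncated-window mean, so a constant series is preserved
    everywhere.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < window:
        raise ValueError(f"series of length {len(x)} shorter than window {window}")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window >= len(x):
        return np.full_like(x, np.median(x))
    if window % 2 == 0:
        window += 1
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def _estimate_baseline(x: np.ndarray, window: int) -> np.ndarray:
    """Episode-robust running baseline.

    A plain running median is dragged down when decelerations occupy more
    than half the window (common in severely abnormal traces), so the
    estimate is refined by excluding samples deviating more than 15 bpm from
    the current baseline and re-taking the running median of the rest.
    """
    baseline = _running_median(x, window)
    for _ in range(2):
        keep = np.abs(x - baseline) <= EPISODE_MIN_DEPTH_BPM
        if keep.all():
            break
        masked = np.where(keep, x, np.nan)
        refined = (
            pd.Series(masked)
            .rolling(window if window % 2 else window + 1, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        gaps = ~np.isfinite(refined)
        if gaps.all():
            break
        if gaps.any():
            idx = np.arange(len(x))
            refined[gaps] = np.interp(idx[gaps], idx[~gaps], refined[~gaps])
        baseline = refined
    return baseline


def detect_episodes(
    fhr_smoothed: np.ndarray,
    fs: float = 1.0,
    min_depth_bpm: float = EPISODE_MIN_DEPTH_BPM,
    min_duration_s: float = EPISODE_MIN_DURATION_S,
    smooth_window: int = SMOOTH_WINDOW,
) -> list[Episode]:
    """Detect accelerations/decelerations via the analytic-signal envelope.

    Pipeline: (1) baseline = 10-min centered running median (global median if
    the trace is shorter); (2) deviation d = FHR − baseline; (3) envelope =
    |analytic signal of d|; (4) candidate episodes are maximal runs where the
    envelope exceeds 0.6 × ``min_depth_bpm``; (5) kind from the sign of d at
    the run extremum; (6) the pulse support is traced outward from the
    extremum to the bracketing zero-crossings of d and onset/offset are
    estimated from the deviation-weighted second moment, deconvolving the
    known variance the ``smooth_window``-point moving average adds; (7) area
    by trapezoidal integration of |d| over the support; (8) an episode is
    kept if it lasts >= ``min_duration_s`` and its depth estimate reaches
    ``min_depth_bpm``.

    Because the upstream moving average attenuates the peak of short episodes
    but preserves their area, the depth estimate is the larger of the
    observed extremum and the area-equivalent peak ``2·area/duration`` (a
    raised-cosine pulse of peak A has mean depth A/2).
    """
    x = np.asarray(fhr_smoothed, dtype=float)
    if x.size == 0:
        return []
    window = int(round(BASELINE_WINDOW_S * fs))
    baseline = _estimate_baseline(x, window)
    d = x - baseline
    envelope = np.abs(hilbert(d))
    above = envelope >= 0.6 * min_depth_bpm
    if not above.any():
        return []
    # maximal runs of `above`
    run_bounds = []
    i = 0
    while i < len(x):
        if above[i]:
            j = i
            while j + 1 < len(x) and above[j + 1]:
                j += 1
            run_bounds.append((i, j))
            i = j + 1
        else:
            i += 1

    cand_thresh = 0.6 * min_depth_bpm
    raw: list[Episode] = []
    # a run may host several episodes (e.g. a deceleration directly followed
    # by an acceleration): carve out the extremum's episode, then recurse on
    # the remainder of the run on both sides
    stack = list(run_bounds)
    while stack:
        i0, j0 = stack.pop()
        if j0 - i0 + 1 < 2:
            continue
        seg = d[i0 : j0 + 1]
        if envelope[i0 : j0 + 1].max() < cand_thresh:
            continue
        ext_rel = int(np.argmax(np.abs(seg)))
        ext = seg[ext_rel]
        sign = 1.0 if ext > 0 else -1.0
        # support of the pulse: walk outward from the extremum until the
        # deviation falls to (near) zero
        support_eps = max(ZERO_CROSS_EPS_BPM, 0.02 * abs(ext))
        a = b = i0 + ext_rel
        while a > 0 and d[a - 1] * sign > support_eps:
            a -= 1
        while b + 1 < len(x) and d[b + 1] * sign > support_eps:
            b += 1
        stack.append((i0, a - 1))
        stack.append((b + 1, j0))

        # moment-based boundary estimate: the moving average spreads a pulse
        # but adds a known variance (W²−1)/12, which is subtracted out; a
        # raised-cosine pulse of duration D has deviation-weighted variance
        # D²·(1/12 − 1/(2π²)), giving a smoothing-unbiased duration
        w = np.abs(d[a : b + 1])
        tt = np.arange(a, b + 1, dtype=float)
        mass = w.sum()
        if mass <= 0:
            continue
        center = float((tt * w).sum() / mass)
        var = float(((tt - center) ** 2 * w).sum() / mass)
        var -= (smooth_window**2 - 1) / 12.0
        _RC_STD_FRAC = np.sqrt(1.0 / 12.0 - 1.0 / (2.0 * np.pi**2))
        duration = np.sqrt(max(var, 1.0)) / _RC_STD_FRAC / fs
        onset = max(center - duration * fs / 2.0, 0.0) / fs
        offset = min(center + duration * fs / 2.0, len(x) - 1.0) / fs
        if offset - onset < min_duration_s:
            continue
        # the moving average preserves the pulse area, so integrating the
        # smoothed deviation over the full support is unbiased
        area = float(np.trapezoid(w, dx=1.0 / fs))
        depth_est = max(abs(ext), 2.0 * area / duration)
        if depth_est < min_depth_bpm:
            continue
        raw.append(
            Episode(
                kind="acceleration" if sign > 0 else "deceleration",
                onset_s=onset / fs,
                offset_s=offset / fs,
                extremum_bpm=float(ext),
                area_bpm_s=area,
            )
        )
    # overlap suppression, deepest episode first: carving a pulse out of a
    # run can leave flank fragments that re-detect as shallow duplicates
    raw.sort(key=lambda e: -abs(e.extremum_bpm))
    episodes: list[Episode] = []
    for ep in raw:
        if any(ep.onset_s < kept.offset_s and ep.offset_s > kept.onset_s for kept in episodes):
            continue
        episodes.append(ep)
    episodes.sort(key=lambda e: e.onset_s)
    return episodes


def extract_features(episodes: list[Episode]) -> FeatureVector:
    """Reduce an episode list to (acceleration count, total deceleration area)."""
    n_acc = sum(1 for e in episodes if e.kind == "acceleration")
    area = sum(e.area_bpm_s for e in episodes if e.kind == "deceleration")
    return FeatureVector(n_accelerations=n_acc, total_decel_area=float(area))


def trace_features(trace, fs: float | None = None) -> FeatureVector:
    """Full conventional chain on a trace: despike, smooth, detect, extract."""
    from .signal_core import interpolate_invalid

    fs = fs or trace.fs
    filled = interpolate_invalid(trace)
    clean = remove_spikes(filled.fhr, fs)
    sm = smooth(clean)
    return extract_features(detect_episodes(sm, fs))


# ---------------------------------------------------------------------------
# Baseline classifiers (scikit-learn behind the module surface)
# ---------------------------------------------------------------------------


@dataclass
class SVMModel:
    scaler: StandardScaler
    svc: SVC


def fit_svm(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> SVMModel:
    """Radial-basis SVM on z-scored features (C = 1, gamma = 'scale')."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training requires at least two classes")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    svc.fit(scaler.transform(X), y)
    return SVMModel(scaler=scaler, svc=svc)


def predict_svm(model: SVMModel, features: np.ndarray) -> np.ndarray:
    return model.svc.predict(model.scaler.transform(np.asarray(features, dtype=float)))


def svm_decision_scores(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Signed distance to the margin, oriented so larger = more abnormal."""
    scores = model.svc.decision_function(model.scaler.transform(np.asarray(features, float)))
    classes = list(model.svc.classes_)
    return scores if classes[-1] == 1 or classes[-1] == "abnormal" else -scores


@dataclass
class KMeansModel:
    scaler: StandardScaler
    km: KMeans
    label_map: dict[int, int]


def fit_kmeans(features: np.ndarray, labels: np.ndarray, k: int = 2, seed: int = 0) -> KMeansModel:
    """Seeded k-means (10 restarts) with majority-vote cluster-to-label map.

    Ties map the cluster to the abnormal label (1).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"k-means needs at least {k} distinct feature rows")
    scaler = StandardScaler().fit(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(scaler.transform(X))
    label_map = {}
    for c in range(k):
        members = y[assign == c]
        if len(members) == 0:
            label_map[c] = 1
            continue
        n_ab = int((members == 1).sum())
        label_map[c] = 1 if n_ab * 2 >= len(members) else 0
    return KMeansModel(scaler=scaler, km=km, label_map=label_map)


def predict_kmeans(model: KMeansModel, features: np.ndarray) -> np.ndarray:
    assign = model.km.predict(model.scaler.transform(np.asarray(features, dtype=float)))
    return np.array([model.label_map[int(c)] for c in assign])
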