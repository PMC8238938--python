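"""Synthetic cardiotocograms and clinical registries with ground truth.

The simulator targets the statistical and event structure a CTG classifier
sees, not cardiovascular physiology: a fetal-heart-rate baseline with
band-limited variability, raised-cosine accelerations and decelerations
time-locked to a Gaussian-bump uterine-contraction train, contiguous signal
dropout, and a delivery registry whose stage sizes and group-conditional
outcome distributions (umbilical-artery pH, 1-minute Apgar) match the cohort
pipeline's assumptions. Every planted event is returned as an annotation so
detection and classification stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .cohort import ABNORMAL, NORMAL, ClinicalRecord, label_outcome
from .signal_core import CTGTrace

__all__ = [
    "EpisodeSpec",
    "TraceGenParams",
    "CohortGenParams",
    "generate_trace",
    "generate_cohort",
    "sample_outcomes",
    "TraceStore",
]

DECEL_KINDS = ("early_decel", "late_decel", "variable_decel", "prolonged_decel")
EPISODE_KINDS = ("acceleration",) + DECEL_KINDS

#: Planted events per 30 minutes (Poisson means), by class.
DEFAULT_EVENT_RATES = {
    NORMAL: {
        "acceleration": 5.0,
        "early_decel": 1.0,
        "variable_decel": 0.5,
        "late_decel": 0.0,
        "prolonged_decel": 0.0,
    },
    ABNORMAL: {
        "acceleration": 0.5,
        "early_decel": 0.5,
        "variable_decel": 1.0,
        "late_decel": 3.0,
        "prolonged_decel": 0.7,
    },
}

#: FHR variability amplitude (bpm) by class; reduced variability marks hypoxia.
DEFAULT_VARIABILITY = {NORMAL: 10.0, ABNORMAL: 3.0}


@dataclass(frozen=True)
class EpisodeSpec:
    """One planted acceleration or deceleration.

    ``depth_bpm`` is the signed peak deviation from baseline (accelerations
    positive, decelerations negative). ``lag_s`` is the nadir offset relative
    to the associated contraction peak, for deceleration kinds only.
    """

    kind: str
    onset_s: float
    offset_s: float
    depth_bpm: float
    lag_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_KINDS:
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError("episode offset must exceed onset")
        dur = self.offset_s - self.onset_s
        if self.kind == "acceleration":
            if self.depth_bpm < 15.0 or dur < 15.0:
                raise ValueError("acceleration requires depth >= +15 bpm and duration >= 15 s")
        else:
            if self.depth_bpm >= 0:
                raise ValueError("deceleration depth must be negative")
        if self.kind == "prolonged_decel" and dur < 120.0:
            raise ValueError("prolonged deceleration requires duration >= 120 s")
        if self.kind == "late_decel" and (self.lag_s is None or self.lag_s < 30.0):
            raise ValueError("late deceleration requires lag >= 30 s after the contraction peak")
        if self.kind == "early_decel" and (self.lag_s is None or abs(self.lag_s) > 5.0):
            raise ValueError("early deceleration requires |lag| <= 5 s")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def area_bpm_s(self) -> float:
        """Analytic unsigned area of the raised-cosine pulse: |depth|·duration/2."""
        return abs(self.depth_bpm) * self.duration_s / 2.0


@dataclass(frozen=True)
class TraceGenParams:
    """Trace-generator settings; ``None`` fields fall back to class defaults."""

    duration_s: float = 1800.0
    fs: float = 4.0
    baseline_bpm: float | None = None  # None -> U(110, 160)
    variability_amp_bpm: float | None = None  # None -> 10 normal / 3 abnormal
    contraction_period_s: float = 180.0
    contraction_width_s: float = 70.0
    contraction_amp: float = 50.0
    uc_tone: float = 10.0
    event_rates: Mapping[str, Mapping[str, float]] | None = None
    dropout_fraction: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must lie in [0, 1)")
        for name in ("contraction_period_s", "contraction_width_s", "contraction_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _raised_cosine(t: np.ndarray, onset: float, offset: float, depth: float) -> np.ndarray:
    """Smooth compact pulse: 0 at edges, ``depth`` at the midpoint."""
    dur = offset - onset
    out = np.zeros_like(t)
    inside = (t >= onset) & (t <= offset)
    out[inside] = depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - onset) / dur))
    return out


def _contraction_peaks(params: TraceGenParams, rng: np.random.Generator) -> np.ndarray:
    period = params.contraction_period_s
    if period <= 0:
        return np.array([])
    first = rng.uniform(0.3, 1.0) * period
    peaks = []
    t = first
    while t < params.duration_s:
        peaks.append(t)
        t += period + rng.normal(0.0, period * 0.05)
    return np.asarray(peaks)


def _draw_episodes(
    params: TraceGenParams, label: str, peaks: np.ndarray, rng: np.random.Generator
) -> list[EpisodeSpec]:
    rates = dict((params.event_rates or DEFAULT_EVENT_RATES)[label])
    scale = params.duration_s / 1800.0
    counts = {k: int(rng.poisson(rates.get(k, 0.0) * scale)) for k in EPISODE_KINDS}
    if label == ABNORMAL and counts["late_decel"] + counts["prolonged_decel"] == 0:
        counts["late_decel"] = 1  # abnormal traces always carry a non-reassuring decel

    episodes: list[EpisodeSpec] = []
    free_peaks = list(rng.permutation(len(peaks))) if len(peaks) else []

    def _peak() -> float | None:
        return float(peaks[free_peaks.pop()]) if free_peaks else None

    for _ in range(counts["acceleration"]):
        dur = rng.uniform(15.0, 40.0)
        onset = rng.uniform(0.0, max(params.duration_s - dur, 1.0))
        episodes.append(
            EpisodeSpec("acceleration", onset, onset + dur, depth_bpm=rng.uniform(15.0, 30.0))
        )
    decel_draws = {
        "early_decel": (lambda: rng.uniform(-5.0, 5.0), (40.0, 90.0), (15.0, 35.0)),
        "late_decel": (lambda: rng.uniform(30.0, 60.0), (40.0, 90.0), (20.0, 45.0)),
        "variable_decel": (lambda: rng.uniform(-20.0, 20.0), (20.0, 60.0), (20.0, 50.0)),
        "prolonged_decel": (lambda: rng.uniform(0.0, 60.0), (120.0, 240.0), (25.0, 50.0)),
    }
    for kind in DECEL_KINDS:
        for _ in range(counts[kind]):
            peak_t = _peak()
            if peak_t is None:
                continue
            lag_fn, dur_rng, depth_rng = decel_draws[kind]
            lag = lag_fn()
            dur = rng.uniform(*dur_rng)
            nadir = peak_t + lag
            onset = nadir - dur / 2.0
            offset = nadir + dur / 2.0
            if onset < 0.0 or offset > params.duration_s:
                continue
            episodes.append(
                EpisodeSpec(kind, onset, offset, depth_bpm=-rng.uniform(*depth_rng), lag_s=lag)
            )
    # drop overlaps, keeping earlier-onset episodes
    episodes.sort(key=lambda e: e.onset_s)
    kept: list[EpisodeSpec] = []
    for ep in episodes:
        if kept and ep.onset_s < kept[-1].offset_s:
            continue
        kept.append(ep)
    return kept


def _plant_dropout(
    n: int, fraction: float, fs: float, rng: np.random.Generator, mean_run_s: float = 30.0
) -> np.ndarray:
    """Boolean dropout mask with contiguous geometric runs, exact total count."""
    target = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    lost = 0
    attempts = 0
    while lost < target and attempts < 10_000:
        attempts += 1
        run = min(1 + rng.geometric(1.0 / (mean_run_s * fs)), target - lost)
        start = int(rng.integers(0, max(n - run, 1)))
        seg = mask[start : start + run]
        add = int(np.count_nonzero(~seg))
        if add == 0:
            continue
        if lost + add > target:
            continue
        seg[:] = True
        lost += add
    if lost < target:  # fill deterministically from the front
        free = np.nonzero(~mask)[0]
        mask[free[: target - lost]] = True
    return mask


def generate_trace(
    params: TraceGenParams,
    label: str = NORMAL,
    rng: np.random.Generator | None = None,
) -> tuple[CTGTrace, list[EpisodeSpec]]:
    """Generate one labeled CTG trace plus its exact planted annotations.

    UC is a resting tone plus a Gaussian-bump contraction train; FHR is
    baseline + band-limited variability + raised-cosine episode deflections,
    with decelerations time-locked to contraction peaks at their lag. Dropout
    replaces the requested fraction of FHR samples with NaN in contiguous
    runs. If the summed deflections push FHR below 50 bpm the episode draw is
    retried a bounded number of times.
    """
    if label not in (NORMAL, ABNORMAL):
        raise ValueError(f"label must be {NORMAL!r} or {ABNORMAL!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    baseline = params.baseline_bpm
    if baseline is None:
        baseline = rng.uniform(110.0, 160.0)
    var_amp = params.variability_amp_bpm
    if var_amp is None:
        var_amp = DEFAULT_VARIABILITY[label]

    peaks = _contraction_peaks(params, rng)
    uc = np.full(n, params.uc_tone)
    sigma_s = params.contraction_width_s / 4.0
    for pk in peaks:
        amp = params.contraction_amp * rng.uniform(0.8, 1.2)
        uc += amp * np.exp(-0.5 * ((t - pk) / sigma_s) ** 2)
    uc += gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=2.0 * params.fs)
    uc = np.clip(uc, 0.0, None)

    variability = np.zeros(n)
    if var_amp > 0:
        raw = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=2.0 * params.fs)
        sd = raw.std()
        if sd > 0:
            variability = raw / sd * (var_amp / 2.0)

    episodes: list[EpisodeSpec] = []
    deflect = np.zeros(n)
    for attempt in range(20):
        episodes = _draw_episodes(params, label, peaks, rng)
        deflect = np.zeros(n)
        for ep in episodes:
            deflect += _raised_cosine(t, ep.onset_s, ep.offset_s, ep.depth_bpm)
        if (baseline + deflect + variability).min() >= 50.0:
            break
    else:
        raise RuntimeError("could not place episodes without dropping FHR below 50 bpm")

    fhr = baseline + deflect + variability
    valid_fhr = np.ones(n, dtype=bool)
    if params.dropout_fraction > 0:
        drop = _plant_dropout(n, params.dropout_fraction, params.fs, rng)
        fhr = np.where(drop, np.nan, fhr)
        valid_fhr = ~drop
        uc_drop = _plant_dropout(n, params.dropout_fraction, params.fs, rng)
        uc = np.where(uc_drop, np.nan, uc)

    trace = CTGTrace(
        fhr=fhr,
        uc=uc,
        fs=params.fs,
        valid_fhr=valid_fhr,
        meta={"label": label, "baseline_bpm": float(baseline)},
    )
    return trace, episodes


# ---------------------------------------------------------------------------
# Registry / cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortGenParams:
    """Registry stage sizes and group-conditional outcome distributions.

    Stage sizes default to the sorting flowchart the pipeline reproduces:
    5406 deliveries; 15 stillbirths, 316 twins, 775 preterm and 619
    insufficient-data exclusions leave 3681; 298 label abnormal, of which 136
    fail CTG quality leaving 162; the normal branch loses 617 emergency
    cesareans and 812 quality failures leaving 1954 eligible.
    """

    n_initial: int = 5406
    n_stillbirth: int = 15
    n_twins: int = 316
    n_preterm: int = 775
    n_insufficient: int = 619
    n_abnormal: int = 298
    n_abnormal_quality_fail: int = 136
    n_emergency_cs: int = 617
    n_normal_quality_fail: int = 812
    ph_normal: tuple[float, float] = (7.31, 0.05)
    ph_abnormal: tuple[float, float] = (7.25, 0.11)
    apgar_normal: tuple[float, float] = (8.31, 0.65)
    apgar_abnormal: tuple[float, float] = (4.30, 1.81)
    trace_params: TraceGenParams = field(default_factory=TraceGenParams)
    seed: int = 0

    def validate(self) -> None:
        excluded = self.n_stillbirth + self.n_twins + self.n_preterm + self.n_insufficient
        remaining = self.n_initial - excluded
        if remaining < 0:
            raise ValueError("exclusion stages remove more records than exist")
        if self.n_abnormal > remaining:
            raise ValueError("abnormal group larger than the post-exclusion cohort")
        n_normal = remaining - self.n_abnormal
        if self.n_abnormal_quality_fail > self.n_abnormal:
            raise ValueError("abnormal quality failures exceed the abnormal group")
        if self.n_emergency_cs + self.n_normal_quality_fail > n_normal:
            raise ValueError("normal-branch removals exceed the normal group")


def sample_outcomes(
    label: str, n: int, rng: np.random.Generator, params: CohortGenParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ua_pH, apgar1) pairs whose labels agree with ``label``.

    Pairs are drawn from the group-conditional Gaussians and rejection-sampled
    until the pH/Apgar rule reproduces the intended label; necessary because
    the abnormal-group mean pH (7.25) sits above the 7.20 threshold, so many
    abnormal deliveries qualify through the Apgar criterion alone.
    """
    params = params or CohortGenParams()
    ph_mu, ph_sd = params.ph_normal if label == NORMAL else params.ph_abnormal
    ap_mu, ap_sd = params.apgar_normal if label == NORMAL else params.apgar_abnormal
    ph_out = np.empty(n)
    ap_out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        ph = rng.normal(ph_mu, ph_sd, m)
        ap = np.clip(np.round(rng.normal(ap_mu, ap_sd, m)), 0, 10).astype(int)
        is_abn = (ph < 7.20) | (ap < 7)
        ok = is_abn if label == ABNORMAL else ~is_abn
        take = min(int(ok.sum()), n - filled)
        ph_out[filled : filled + take] = ph[ok][:take]
        ap_out[filled : filled + take] = ap[ok][:take]
        filled += take
    return ph_out, ap_out


class TraceStore(Mapping):
    """Lazy id -> CTGTrace mapping backed by per-record deterministic seeds.

    The cohort's master seed is split into per-record substreams, so any
    subset of traces regenerates identically regardless of access order.
    """

    def __init__(self, plans: dict[str, dict], master_seed: int):
        self._plans = plans
        self._seed = master_seed
        self._cache: dict[str, tuple[CTGTrace, list[EpisodeSpec]]] = {}

    def _generate(self, record_id: str) -> tuple[CTGTrace, list[EpisodeSpec]]:
        if record_id in self._cache:
            return self._cache[record_id]
        plan = self._plans[record_id]
        rng = np.random.default_rng([self._seed, plan["index"]])
        trace, episodes = generate_trace(plan["params"], plan["label"], rng)
        trace.meta["record_id"] = record_id
        self._cache[record_id] = (trace, episodes)
        return self._cache[record_id]

    def __getitem__(self, record_id: str) -> CTGTrace:
        return self._generate(record_id)[0]

    def episodes(self, record_id: str) -> list[EpisodeSpec]:
        return self._generate(record_id)[1]

    def __iter__(self) -> Iterator[str]:
        return iter(self._plans)

    def __len__(self) -> int:
        return len(self._plans)


def _trace_plan(
    base: TraceGenParams, fate: str, label: str, rng: np.random.Generator
) -> TraceGenParams:
    if fate == "short":
        return replace(base, duration_s=float(rng.uniform(600.0, 1500.0)))
    if fate == "loss":
        return replace(
            base,
            duration_s=float(rng.uniform(1800.0, 2700.0)),
            dropout_fraction=float(rng.uniform(0.20, 0.40)),
        )
    return replace(
        base,
        duration_s=float(rng.uniform(1800.0, 2700.0)),
        dropout_fraction=float(rng.uniform(0.02, 0.12)),
    )


def generate_cohort(params: CohortGenParams) -> tuple[list[ClinicalRecord], TraceStore]:
    """Generate a delivery registry plus a lazy store of matching CTG traces.

    Exclusion flags are disjoint and their counts equal the configured stage
    sizes exactly. Outcome values are rejection-sampled so every record's
    drawn (pH, Apgar) pair reproduces its intended label. CTG quality failures
    (short record or excessive dropout) are planted in the exact configured
    numbers per branch.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_initial
    ids = [f"d{i:05d}" for i in range(n)]
    order = rng.permutation(n)

    roles = np.full(n, "clean", dtype=object)
    pos = 0
    for role, count in (
        ("stillbirth", params.n_stillbirth),
        ("twin", params.n_twins),
        ("preterm", params.n_preterm),
        ("insufficient", params.n_insufficient),
    ):
        roles[order[pos : pos + count]] = role
        pos += count
    clean_idx = order[pos:]

    n_clean = len(clean_idx)
    labels = np.full(n_clean, NORMAL, dtype=object)
    labels[: params.n_abnormal] = ABNORMAL
    labels = labels[rng.permutation(n_clean)]

    # branch fates: abnormal -> quality pass/fail; normal -> CS / quality fail / eligible
    ab_pos = np.nonzero(labels == ABNORMAL)[0]
    no_pos = np.nonzero(labels == NORMAL)[0]
    fates = np.full(n_clean, "pass", dtype=object)
    ab_fail = rng.choice(ab_pos, params.n_abnormal_quality_fail, replace=False)
    half = params.n_abnormal_quality_fail // 2
    fates[ab_fail[:half]] = "short"
    fates[ab_fail[half:]] = "loss"
    no_removed = rng.choice(
        no_pos, params.n_emergency_cs + params.n_normal_quality_fail, replace=False
    )
    cs_idx = set(no_removed[: params.n_emergency_cs].tolist())
    q_fail = no_removed[params.n_emergency_cs :]
    halfn = len(q_fail) // 2
    fates[q_fail[:halfn]] = "short"
    fates[q_fail[halfn:]] = "loss"

    ph_n, ap_n = sample_outcomes(NORMAL, int((labels == NORMAL).sum()), rng, params)
    ph_a, ap_a = sample_outcomes(ABNORMAL, int((labels == ABNORMAL).sum()), rng, params)
    # outcomes for excluded-but-delivered records: normal-group draws
    n_excl_outcomes = params.n_stillbirth + params.n_twins + params.n_preterm
    ph_x, ap_x = sample_outcomes(NORMAL, n_excl_outcomes, rng, params)

    records: list[ClinicalRecord] = []
    plans: dict[str, dict] = {}
    i_n = i_a = i_x = 0
    clean_rank = {int(idx): k for k, idx in enumerate(clean_idx)}
    for i in range(n):
        role = roles[i]
        rec = ClinicalRecord(id=ids[i])
        if role == "stillbirth":
            rec.stillbirth = True
        elif role == "twin":
            rec.plurality = 2
        elif role == "preterm":
            rec.gestational_age_weeks = float(rng.uniform(24.0, 36.9))
        elif role == "insufficient":
            rec.has_sufficient_data = False
            records.append(rec)
            continue
        if role in ("stillbirth", "twin", "preterm"):
            rec.ua_pH = float(ph_x[i_x])
            rec.apgar1 = int(ap_x[i_x])
            i_x += 1
            records.append(rec)
            continue

        k = clean_rank[i]
        label = labels[k]
        fate = fates[k]
        if label == ABNORMAL:
            rec.ua_pH, rec.apgar1 = float(ph_a[i_a]), int(ap_a[i_a])
            i_a += 1
        else:
            rec.ua_pH, rec.apgar1 = float(ph_n[i_n]), int(ap_n[i_n])
            i_n += 1
            rec.emergency_cs = k in cs_idx
        rec.meta = {"sim_label": label, "sim_quality": fate}
        sub_rng = np.random.default_rng([params.seed, 7, k])
        plans[rec.id] = {
            "index": k,
            "label": label,
            "params": _trace_plan(params.trace_params, fate, label, sub_rng),
        }
        records.append(rec)

    return records, TraceStore(plans, params.seed)
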