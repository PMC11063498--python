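"""Seeded generator of synthetic labor cohorts, trace rendering, and a
round-trip deceleration detector.

The generator emulates the statistical structure the acidemia analysis
assumes, quantifying the clinical narrative that repeated decelerations
first produce hypoxemia with respiratory acidosis (CO2 accumulation) and,
as they keep recurring, a gradually deepening metabolic acidosis (base
deficit):

1. each case draws a latent severity class (low / mid / high);
2. a time-inhomogeneous deceleration stream is emitted whose per-event
   five-tier levels follow the class-conditional level mix (event axes are
   drawn from the default rule table's preimage of the target level, so
   table lookup reproduces the drawn level);
3. recent deceleration burden (the score of the final monitored 30 minutes
   before transducer removal) drives PCO2 through ``respiratory_gain``;
   cumulative burden over the whole recording drives base excess through
   ``metabolic_gain``;
4. pH is the joint solution of the Henderson-Hasselbalch relation
   ``pH = 6.1 + log10(HCO3 / (0.03 PCO2))`` and the Van Slyke-type base
   excess relation ``BE = HCO3 - 24.4 + 14.83 (pH - 7.4)``; HCO3 is then
   back-computed from pH so every panel satisfies Henderson-Hasselbalch
   exactly;
5. Apgar scores and the NICU-for-asphyxia flag are noisy functions of pH;
   timelines are drawn from distributions centred on the published medians
   (decision-to-delivery 69 min, removal-to-delivery 45 min).

Reproducibility: a single integer seed; each case uses an independent
substream spawned from it, so case ``i`` is identical regardless of
``n_cases``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, signal as sp_signal

from .events import (
    BloodGasPanel,
    DecelerationEvent,
    FiveTierRuleTable,
    LaborCase,
    PROLONGED_MAX_S,
    PROLONGED_MIN_S,
    classify_level,
)
from .exceptions import GenerationError, SignalError
from .scoring import ScoreWindow, score_window

SeverityClass = str  # "low" | "mid" | "high"


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic labor-cohort generator.

    Defaults are calibrated so a generated cohort resembles the anchors of a
    term eCD-for-NRFS population: acidemia (pH < 7.2) prevalence near 0.10,
    mean pH near 7.29, mean PCO2 near 49 mm Hg, mean BE near -3 mEq/L, and a
    30-minute pre-removal score with median near 22 and range reaching ~90.
    """

    model_config = ConfigDict(frozen=True)

    n_cases: int = Field(default=113, gt=0)
    seed: int = 0
    target_prevalence: float = Field(default=0.10, gt=0.0, lt=1.0)

    # latent severity classes and their deceleration streams
    class_probs: tuple[float, float, float] = (0.38, 0.52, 0.10)  # low/mid/high
    events_per_30min: tuple[float, float, float] = (3.0, 6.5, 9.5)
    level_mix: dict[str, dict[int, float]] = Field(default={
        "low": {2: 0.55, 3: 0.40, 4: 0.05},
        "mid": {2: 0.20, 3: 0.50, 4: 0.30},
        "high": {3: 0.25, 4: 0.55, 5: 0.20},
    })
    ramp: tuple[float, float] = (0.6, 1.4)  # event-rate multiplier, start -> end
    prolonged_prob: tuple[float, float, float] = (0.01, 0.04, 0.12)
    prolonged_median_min: float = 3.0  # minutes
    decel_duration_median_s: float = 60.0

    # acid-base coupling
    pco2_base: float = 42.0  # mm Hg at zero recent burden
    respiratory_gain: float = 0.30  # mm Hg PCO2 per unit recent burden
    be_base: float = -1.0  # mEq/L at zero cumulative burden
    metabolic_gain: float = 0.022  # mEq/L BE drop per unit cumulative burden
    pco2_sd: float = 5.0
    be_sd: float = 1.4

    # timelines (minutes); lognormal draws centred on published medians
    recording_median_min: float = 150.0
    recording_sigma: float = 0.35
    decision_to_removal_median_min: float = 24.0
    decision_to_removal_sigma: float = 0.45
    removal_to_delivery_median_min: float = 45.0
    removal_to_delivery_sigma: float = 0.45
    removal_to_delivery_range_min: tuple[float, float] = (15.0, 99.0)

    # covariates / outcome coupling
    maternal_age_mean: float = 34.4
    maternal_age_sd: float = 5.4
    induction_prob: float = 0.67
    vacuum_prob: float = 0.08
    apgar_ph_slope: float = 12.0  # Apgar-5 points per pH unit below 7.3
    nicu_ph_center: float = 7.05
    nicu_ph_scale: float = 0.04

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for mix in self.level_mix.values():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("each level mix must sum to 1")
            if any(not 1 <= lvl <= 5 for lvl in mix):
                raise ValueError("level mix keys must be levels 1..5")
        for name in ("respiratory_gain", "metabolic_gain", "pco2_sd", "be_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


# ---------------------------------------------------------------------------
# acid-base solver
# ---------------------------------------------------------------------------

#: buffer slope of the simplified Van Slyke relation, mmol/L per pH unit
_BUFFER_SLOPE = 14.83
_HCO3_REF = 24.4


def solve_blood_gas(pco2: float, be: float) -> tuple[float, float]:
    """Solve jointly for (pH, HCO3) given PCO2 and base excess.

    Uses Henderson-Hasselbalch ``pH = 6.1 + log10(HCO3/(0.03 PCO2))`` and the
    Van Slyke-type relation ``BE = HCO3 - 24.4 + 14.83 (pH - 7.4)``.  The
    returned HCO3 is back-computed from the solved pH so the
    Henderson-Hasselbalch identity holds exactly.
    """
    def hco3_of(ph: float) -> float:
        return _HCO3_REF + be - _BUFFER_SLOPE * (ph - 7.4)

    def gap(ph: float) -> float:
        h = hco3_of(ph)
        if h <= 0.1:
            return -10.0  # force bracket away from non-physical HCO3
        return 6.1 + math.log10(h / (0.03 * pco2)) - ph

    lo, hi = 6.51, 7.59
    ph = optimize.brentq(gap, lo, hi) if gap(lo) > 0 > gap(hi) else (
        lo if gap(lo) <= 0 else hi)
    ph = min(max(ph, 6.52), 7.58)
    hco3 = 0.03 * pco2 * 10.0 ** (ph - 6.1)
    return ph, hco3


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _level_preimages(table: FiveTierRuleTable) -> tuple[dict[int, list], dict[int, list]]:
    """Axis combinations of the rule table grouped by level, split into
    non-prolonged and prolonged deceleration types."""
    regular: dict[int, list] = {}
    prolonged: dict[int, list] = {}
    for (b, v, d, s), lvl in sorted(table.entries.items()):
        if d == "none":
            continue
        target = prolonged if d == "prolonged" else regular
        target.setdefault(lvl, []).append((b, v, d, s))
    return regular, prolonged


def _nearest_key(d: dict[int, list], level: int) -> int:
    return min(d.keys(), key=lambda k: (abs(k - level), k))


def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))))


def _burden(events: Sequence[DecelerationEvent], window: ScoreWindow) -> int:
    return score_window(events, window, strict_coverage=False).total


def _feasibility_check(config: SyntheticConfig) -> None:
    """Deterministic calibration check: the highest severity class at 1.5x
    its expected burden must be able to cross the acidemia threshold."""
    rec_min = config.recording_median_min
    n_windows = rec_min / 30.0
    b_total = 1.5 * config.events_per_30min[2] * n_windows * 4.0  # level ~4
    b_recent = 1.5 * config.events_per_30min[2] * 4.0
    pco2 = config.pco2_base + config.respiratory_gain * b_recent + 2 * config.pco2_sd
    be = config.be_base - config.metabolic_gain * b_total - 2 * config.be_sd
    ph, _ = solve_blood_gas(pco2, max(be, -28.0))
    if ph >= 7.2 and config.target_prevalence >= 0.02:
        raise GenerationError(
            f"infeasible config: even the extreme severity tail reaches only "
            f"pH {ph:.3f} >= 7.2, so target_prevalence="
            f"{config.target_prevalence:g} is unreachable; increase the "
            f"acid-base gains or event rates"
        )


def generate_case(config: SyntheticConfig, index: int,
                  table: Optional[FiveTierRuleTable] = None) -> LaborCase:
    """Generate one labor case from the seeded substream for ``index``."""
    rng = _case_rng(config.seed, index)
    table = table or FiveTierRuleTable.default()
    regular_pre, prolonged_pre = _level_preimages(table)

    cls = int(rng.choice(3, p=np.asarray(config.class_probs)))
    cls_name = ("low", "mid", "high")[cls]
    mix = config.level_mix[cls_name]
    mix_levels = np.array(sorted(mix))
    mix_probs = np.array([mix[l] for l in mix_levels], dtype=float)

    # timeline (seconds)
    d2r = 60.0 * config.decision_to_removal_median_min * math.exp(
        config.decision_to_removal_sigma * rng.standard_normal())
    r2d = 60.0 * config.removal_to_delivery_median_min * math.exp(
        config.removal_to_delivery_sigma * rng.standard_normal())
    lo, hi = config.removal_to_delivery_range_min
    r2d = float(np.clip(r2d, 60.0 * lo, 60.0 * hi))
    rec_len = 60.0 * config.recording_median_min * math.exp(
        config.recording_sigma * rng.standard_normal())
    rec_len = max(rec_len, d2r + 2100.0)  # keep 30 min of CTG before the decision
    removal = rec_len
    decision = removal - d2r
    delivery = removal + r2d

    # time-inhomogeneous deceleration stream (30-min blocks, linear ramp)
    rate30 = config.events_per_30min[cls]
    ramp0, ramp1 = config.ramp
    events: list[DecelerationEvent] = []
    n_blocks = int(math.ceil(rec_len / 1800.0))
    for blk in range(n_blocks):
        t0 = 1800.0 * blk
        t1 = min(rec_len, t0 + 1800.0)
        frac_mid = ((t0 + t1) / 2.0) / rec_len
        mult = ramp0 + (ramp1 - ramp0) * frac_mid
        lam = rate30 * mult * (t1 - t0) / 1800.0
        for _ in range(rng.poisson(lam)):
            onset = float(rng.uniform(t0, t1))
            level = int(rng.choice(mix_levels, p=mix_probs))
            if rng.random() < config.prolonged_prob[cls]:
                pool = prolonged_pre[_nearest_key(prolonged_pre, level)]
                dur = 60.0 * config.prolonged_median_min * math.exp(
                    0.35 * rng.standard_normal())
                dur = float(np.clip(dur, PROLONGED_MIN_S, PROLONGED_MAX_S - 10.0))
            else:
                pool = regular_pre[_nearest_key(regular_pre, level)]
                dur = config.decel_duration_median_s * math.exp(
                    0.30 * rng.standard_normal())
                dur = float(np.clip(dur, 20.0, PROLONGED_MIN_S - 5.0))
            b, v, d, s = pool[int(rng.integers(len(pool)))]
            onset = min(onset, rec_len)
            ev = DecelerationEvent(onset=onset, duration=dur, decel_type=d,
                                   severity=s, baseline_rate=b, variability=v)
            events.append(classify_level(ev, table))
    events.sort(key=lambda e: e.onset)

    # burdens -> acid-base
    b_total = _burden(events, ScoreWindow(end_time=rec_len, length=max(rec_len, 1.0)))
    b_recent = _burden(events, ScoreWindow(end_time=removal, length=1800.0, variant="RCT"))
    pco2 = config.pco2_base + config.respiratory_gain * b_recent \
        + config.pco2_sd * rng.standard_normal()
    pco2 = float(np.clip(pco2, 18.0, 130.0))
    be = config.be_base - config.metabolic_gain * b_total \
        + config.be_sd * rng.standard_normal()
    be = float(np.clip(be, -28.0, 5.0))
    ph, hco3 = solve_blood_gas(pco2, be)
    be_consistent = hco3 - _HCO3_REF + _BUFFER_SLOPE * (ph - 7.4)
    po2 = float(np.clip(16.5 - 0.01 * b_total + 5.0 * rng.standard_normal(), 2.0, 40.0))
    lactate = float(np.clip(2.0 + 0.55 * max(0.0, -be_consistent)
                            + 0.8 * rng.standard_normal(), 0.3, 25.0))
    panel = BloodGasPanel(ph=ph, pco2=pco2, po2=po2, hco3=hco3,
                          be=be_consistent, lactate=lactate)

    apgar5 = int(np.clip(round(9.0 + config.apgar_ph_slope * (ph - 7.3)
                               + 0.6 * rng.standard_normal()), 0, 10))
    apgar1 = int(np.clip(apgar5 - 1 + round(0.7 * rng.standard_normal()), 0, apgar5))
    nicu = bool(rng.random() < 1.0 / (1.0 + math.exp(
        -(config.nicu_ph_center - ph) / config.nicu_ph_scale)))

    return LaborCase(
        case_id=f"S{index:04d}",
        events=tuple(events),
        recording_start=0.0,
        recording_end=rec_len,
        decision_time=decision,
        removal_time=removal,
        delivery_time=delivery,
        maternal_age=float(np.clip(config.maternal_age_mean
                                   + config.maternal_age_sd * rng.standard_normal(),
                                   16.0, 52.0)),
        parity=int(rng.choice([0, 1, 2, 3], p=[0.62, 0.25, 0.10, 0.03])),
        gestational_week=float(np.clip(40.0 + 1.2 * rng.standard_normal(), 37.0, 41.9)),
        induction=bool(rng.random() < config.induction_prob),
        vacuum=bool(rng.random() < config.vacuum_prob),
        blood_gas=panel,
        apgar1=apgar1,
        apgar5=apgar5,
        nicu_asphyxia=nicu,
    )


def generate_cohort(config: SyntheticConfig,
                    table: Optional[FiveTierRuleTable] = None) -> list[LaborCase]:
    """Generate a full cohort; same config (incl. seed) -> identical cohort."""
    _feasibility_check(config)
    table = table or FiveTierRuleTable.default()
    return [generate_case(config, i, table) for i in range(config.n_cases)]


# ---------------------------------------------------------------------------
# trace rendering and deceleration detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorParams:
    """Thresholds of the deceleration detector (standard conventions:
    drop >= 15 bpm sustained >= 15 s; prolonged when >= 2 min)."""

    sampling_rate: float = 4.0
    drop_bpm: float = 15.0
    min_duration_s: float = 15.0
    prolonged_min_s: float = PROLONGED_MIN_S
    severe_depth_bpm: float = 35.0
    late_lag_s: float = 15.0
    merge_gap_s: float = 5.0


def render_trace(case: LaborCase, sampling_rate: float = 4.0,
                 baseline_bpm: float = 140.0, variability_bpm: float = 6.0,
                 noise_bpm: float = 1.5, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render FHR and uterine-activity signals for a case's event stream.

    The FHR is a constant baseline with sinusoidal short-term variability
    plus noise; each annotated deceleration is a half-cosine dip (depth 25
    bpm mild / 45 bpm severe).  The uterine channel is a train of Gaussian
    contraction bumps every ~3 minutes.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = int(math.ceil((case.recording_end - case.recording_start) * sampling_rate)) + 1
    t = case.recording_start + np.arange(n) / sampling_rate
    fhr = (baseline_bpm
           + (variability_bpm / 2.0) * np.sin(2 * np.pi * t / 4.0)
           + noise_bpm * rng.standard_normal(n))
    for ev in case.events:
        depth = 45.0 if ev.severity == "severe" else 25.0
        mask = (t >= ev.onset) & (t <= ev.end)
        phase = (t[mask] - ev.onset) / ev.duration
        fhr[mask] -= depth * np.sin(np.pi * phase)
    uc = np.zeros(n)
    peak = case.recording_start + 60.0 + rng.uniform(0, 30)
    while peak < case.recording_end:
        uc += 60.0 * np.exp(-0.5 * ((t - peak) / 25.0) ** 2)
        peak += 180.0 + rng.uniform(-20, 20)
    uc += 5.0 + 1.0 * rng.standard_normal(n)
    return fhr, uc


def detect_decelerations(fhr: np.ndarray, uc: np.ndarray,
                         params: DetectorParams = DetectorParams()) -> list[DecelerationEvent]:
    """Detect decelerations in an FHR trace and classify type and severity.

    A deceleration is a sustained drop >= ``drop_bpm`` below the estimated
    baseline lasting >= ``min_duration_s``; >= 2 min makes it prolonged,
    otherwise the lag of its nadir behind the nearest preceding contraction
    peak separates late (lag > ``late_lag_s``) from variable.  Severity is by
    depth.  Deterministic.
    """
    fhr = np.asarray(fhr, dtype=float)
    uc = np.asarray(uc, dtype=float)
    if fhr.shape != uc.shape:
        raise SignalError(f"FHR and UC lengths differ: {fhr.shape} vs {uc.shape}")
    fs = params.sampling_rate
    baseline = float(np.median(fhr))

    below = fhr < baseline - params.drop_bpm
    # run-length encode the below-baseline mask
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(below)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [len(idx) - 1]])
        runs = [(int(idx[a]), int(idx[b])) for a, b in zip(seg_starts, seg_ends)]
    # merge runs separated by < merge_gap_s
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) / fs < params.merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    uc_peaks, _ = sp_signal.find_peaks(uc, height=uc.mean() + uc.std(),
                                       distance=int(60 * fs))
    peak_times = uc_peaks / fs

    # variability category from the non-decelerating residual
    keep = np.ones(len(fhr), dtype=bool)
    for a, b in merged:
        keep[a:b + 1] = False
    resid_sd = float(np.std(fhr[keep] - baseline)) if keep.any() else 0.0
    variability = ("absent" if resid_sd < 1.0 else "minimal" if resid_sd < 3.0
                   else "moderate" if resid_sd < 8.0 else "marked")
    baseline_cat = ("bradycardia" if baseline < 110 else
                    "tachycardia" if baseline > 160 else "normal")

    out: list[DecelerationEvent] = []
    for a, b in merged:
        duration = (b - a + 1) / fs
        if duration < params.min_duration_s:
            continue
        onset = a / fs
        seg = fhr[a:b + 1]
        depth = baseline - float(seg.min())
        nadir = (a + int(np.argmin(seg))) / fs
        if duration >= params.prolonged_min_s:
            dtype = "prolonged"
            duration = min(duration, PROLONGED_MAX_S - 1.0)
        else:
            prior = peak_times[peak_times <= nadir]
            lag = nadir - prior[-1] if len(prior) else float("inf")
            dtype = "late" if params.late_lag_s < lag <= 60.0 else "variable"
        out.append(DecelerationEvent(
            onset=onset, duration=duration, decel_type=dtype,
            severity="severe" if depth >= params.severe_depth_bpm else "mild",
            baseline_rate=baseline_cat, variability=variability,
        ))
    out.sort(key=lambda e: e.onset)
    return out
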