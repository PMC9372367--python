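"""Coupled maternal-fetal beat-train simulator with cohort metadata.

The generator plants exact m:n phase locking: maternal RR intervals are
drawn from a truncated normal (typical maternal ~80 bpm), maternal beats
are grouped into consecutive m-beat cycles, and each cycle emits n fetal
beats at fixed fractions of the cycle span plus per-beat Gaussian phase
jitter.  Uncoupled controls draw fetal RR independently (typical fetal
~140 bpm).  A cohort generator adds per-subject gestational age, maternal
age and BMI, and can plant a jitter-vs-gestational-age slope so that
coupling strength trends with gestation, mimicking cohort-level analyses.

The model is a phase-locking point process, not a biophysical conduction
model: it realizes exactly the m:n structure that phase-occurrence counting
and the phase coherence index measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fetalcoupling.beat_series import (
    REFRACTORY_S,
    BeatSeries,
    SegmentPair,
    SubjectMeta,
    segment_minutes,
)
from fetalcoupling.coupling_label import SUPPORTED_RATIOS, CouplingRatio

__all__ = [
    "UNCOUPLED",
    "GeneratorConfig",
    "CohortConfig",
    "generate_pair",
    "generate_cohort",
    "write_truth_csv",
]

#: Sentinel ratio value for uncoupled control records.
UNCOUPLED = "uncoupled"


class GenerationError(RuntimeError):
    """Generator could not satisfy the physiological invariants."""


def _default_offsets(n: int) -> np.ndarray:
    """n equally spaced cycle fractions, first at 0.2/n.

    Spacing 1/n keeps the fetal rhythm even; the 0.2/n lead-in keeps every
    offset clear of the maternal-beat window boundaries so that small phase
    jitter does not flip beats between adjacent counting windows.
    """
    return (0.2 + np.arange(n)) / n


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic maternal-fetal record.

    Defaults emulate the study conditions: 1-min-and-longer records,
    maternal ~80 bpm (mean RR 0.75 s) slower than fetal ~140 bpm
    (mean RR 0.42 s), small phase jitter.
    """

    ratio: CouplingRatio | str = SUPPORTED_RATIOS[0]
    maternal_mean_rr: float = 0.75  # s
    maternal_sd_rr: float = 0.02  # s
    fetal_phase_offsets: tuple | None = None  # fractions of the m-beat cycle
    phase_jitter_sd: float = 0.01  # cycle fraction
    fetal_mean_rr: float = 0.42  # s, uncoupled mode
    fetal_sd_rr: float = 0.03  # s, uncoupled mode
    duration: float = 60.0  # s
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.maternal_mean_rr - 4 * self.maternal_sd_rr <= REFRACTORY_S:
            raise ValueError("maternal RR distribution violates the refractory floor")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fetal_phase_offsets is not None:
            off = np.asarray(self.fetal_phase_offsets, dtype=float)
            if np.any(np.diff(off) <= 0) or off[0] < 0 or off[-1] >= 1:
                raise ValueError("fetal_phase_offsets must be strictly increasing in [0, 1)")

    def offsets(self) -> np.ndarray:
        if self.ratio == UNCOUPLED:
            raise ValueError("offsets undefined for uncoupled mode")
        if self.fetal_phase_offsets is not None:
            return np.asarray(self.fetal_phase_offsets, dtype=float)
        return _default_offsets(self.ratio.n)


def _truncnorm_rr(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated-normal RR intervals by resampling out-of-range draws."""
    rr = rng.normal(mean, sd, size)
    bad = (rr < lo) | (rr > hi)
    for _ in range(100):
        if not bad.any():
            break
        rr[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (rr < lo) | (rr > hi)
    np.clip(rr, lo, hi, out=rr)
    return rr


def _beat_train(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, duration: float) -> np.ndarray:
    n_max = int(duration / max(lo, mean - 4 * sd)) + 2
    rr = _truncnorm_rr(rng, mean, sd, lo, hi, n_max)
    t = np.cumsum(rr) - rr[0]  # first beat at 0
    return t[t < duration]


def generate_pair(config: GeneratorConfig) -> tuple[BeatSeries, BeatSeries, dict]:
    """Generate one maternal-fetal beat-train pair plus its truth record.

    Coupled mode: maternal beats grouped into m-beat cycles; each cycle
    emits n fetal beats at ``(offset_i + jitter) * span`` past the cycle
    start, jitter drawn per beat from N(0, phase_jitter_sd).  Beats that
    violate monotonicity or the refractory floor are resampled up to 10
    times, then dropped (count recorded).  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    # generate past the requested duration so the locked pattern covers the
    # trailing counting windows, then truncate both trains at `duration`
    m_groups = 1 if config.ratio == UNCOUPLED else config.ratio.m
    pad = 2.0 * m_groups * 1.5
    mat_ext = _beat_train(
        rng, config.maternal_mean_rr, config.maternal_sd_rr, 0.4, 1.5, config.duration + pad
    )
    mat_t = mat_ext[mat_ext < config.duration]
    truth = {
        "subject_id": config.subject_id,
        "planted_ratio": str(config.ratio) if config.ratio != UNCOUPLED else UNCOUPLED,
        "phase_jitter_sd": config.phase_jitter_sd,
        "n_dropped": 0,
    }
    if config.ratio == UNCOUPLED:
        fet_t = _beat_train(rng, config.fetal_mean_rr, config.fetal_sd_rr, 0.25, 0.8, config.duration)
    else:
        m = config.ratio.m
        offsets = config.offsets()
        n_cycles = (len(mat_ext) - 1) // m
        fet: list[float] = []
        n_dropped = 0
        for j in range(n_cycles):
            start, end = mat_ext[j * m], mat_ext[(j + 1) * m]
            span = end - start
            for off in offsets:
                ok = False
                for _ in range(10):
                    t = start + (off + rng.normal(0.0, config.phase_jitter_sd)) * span
                    if not fet or t - fet[-1] >= REFRACTORY_S:
                        fet.append(float(t))
                        ok = True
                        break
                if not ok:
                    n_dropped += 1
        n_total = n_cycles * len(offsets)
        if n_total and n_dropped > 0.05 * n_total:
            raise GenerationError(
                f"dropped {n_dropped}/{n_total} fetal beats after resampling; "
                f"offsets/jitter are unsatisfiable under the refractory floor"
            )
        truth["n_dropped"] = n_dropped
        fet_t = np.asarray(fet)
        fet_t = fet_t[(fet_t >= 0) & (fet_t < config.duration)]
    maternal = BeatSeries(config.subject_id, "maternal", mat_t, record_duration=config.duration)
    fetal = BeatSeries(config.subject_id, "fetal", fet_t, record_duration=config.duration)
    return maternal, fetal, truth


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort of subjects.

    ``ratio_mix`` gives the proportions of ([1:2], [2:3], [3:5], uncoupled)
    subjects; the default is skewed toward [1:2], the dominant scenario in
    real cohorts.  ``jitter_vs_ga_slope`` plants a coupling-strength trend:
    each subject's phase jitter is ``base + slope * (ga - 30)`` clipped at 0.
    """

    n_subjects: int = 30
    ratio_mix: tuple = (0.5, 0.2, 0.2, 0.1)
    gestational_age_range: tuple = (20.0, 40.0)
    base_jitter_sd: float = 0.01
    jitter_vs_ga_slope: float = 0.0  # cycle fraction per week
    record_duration_range: tuple = (120.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.ratio_mix) != 4 or abs(sum(self.ratio_mix) - 1.0) > 1e-9:
            raise ValueError("ratio_mix must be 4 proportions summing to 1")
        lo, hi = self.record_duration_range
        if not (0 < lo <= hi):
            raise ValueError("record_duration_range must be a positive, ordered interval")


def generate_cohort(
    config: CohortConfig, return_records: bool = False
) -> tuple[list[SegmentPair], pd.DataFrame] | tuple[list[SegmentPair], pd.DataFrame, dict]:
    """Generate a cohort of segmented records plus the truth table.

    Returns the pooled usable :class:`SegmentPair` list and a DataFrame
    with columns ``subject_id, segment_index, planted_ratio,
    phase_jitter_sd, gestational_age``.  With ``return_records`` the full
    (unsegmented) beat trains are returned as a third element, a dict
    ``subject_id -> (maternal, fetal)``.  Drawn record durations are
    floored to whole minutes plus a 2-s margin so every window is fully
    covered by beats.
    """
    rng = np.random.default_rng(config.seed)
    choices = list(SUPPORTED_RATIOS) + [UNCOUPLED]
    assignments = rng.choice(4, size=config.n_subjects, p=np.asarray(config.ratio_mix))
    segments: list[SegmentPair] = []
    rows: list[dict] = []
    records: dict[str, tuple[BeatSeries, BeatSeries]] = {}
    for i in range(config.n_subjects):
        sid = f"synth{i:03d}"
        ga = float(rng.uniform(*config.gestational_age_range))
        jitter = max(0.0, config.base_jitter_sd + config.jitter_vs_ga_slope * (ga - 30.0))
        drawn = float(rng.uniform(*config.record_duration_range))
        duration = max(60.0, 60.0 * np.floor(drawn / 60.0)) + 2.0
        meta = SubjectMeta(
            gestational_age=ga,
            maternal_age=float(rng.uniform(20.0, 45.0)),
            bmi=float(rng.uniform(19.0, 30.0)),
        )
        gcfg = GeneratorConfig(
            ratio=choices[assignments[i]],
            phase_jitter_sd=jitter,
            duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=sid,
        )
        maternal, fetal, truth = generate_pair(gcfg)
        records[sid] = (maternal, fetal)
        for seg in segment_minutes(maternal, fetal, meta):
            segments.append(seg)
            rows.append(
                {
                    "subject_id": sid,
                    "segment_index": seg.segment_index,
                    "planted_ratio": truth["planted_ratio"],
                    "phase_jitter_sd": jitter,
                    "gestational_age": ga,
                }
            )
    truth_table = pd.DataFrame(
        rows,
        columns=["subject_id", "segment_index", "planted_ratio", "phase_jitter_sd", "gestational_age"],
    )
    if return_records:
        return segments, truth_table, records
    return segments, truth_table


def write_truth_csv(truth_table: pd.DataFrame, path) -> None:
    truth_table.to_csv(path, index=False)
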