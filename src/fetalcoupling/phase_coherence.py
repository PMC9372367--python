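"""Instantaneous phase, synchrogram and the windowed phase coherence index.

For a candidate m:n coupling, maternal beats are grouped into consecutive
non-overlapping m-beat cycles ``[t_{jm}, t_{(j+1)m})``.  Each fetal beat at
time t inside cycle k has an (unbounded) instantaneous phase

    phi = 2*pi*(t - t_k) / (t_{k+m} - t_k) + 2*pi*k

and a relative phase of occurrence ``psi = (phi mod 2*pi) / (2*pi)`` in
[0, 1).  Plotting psi against time gives the synchrogram: n parallel
horizontal bands under m:n locking, a uniform scatter when uncoupled.

The phase coherence index of a window of relative phases is the squared
modulus of their mean unit vector,

    lambda_p = | (1/N_eff) sum_j exp(i * 2*pi * n * psi_j) |^2,

computed over a symmetric window of up to N (default 15, odd) consecutive
fetal-beat records and lying in [0, 1]: 1 under perfect locking, about 1/N
for independent phases.  Two reconstruction choices are deliberate and
documented: the full-circle angular factor 2*pi (psi itself spans only one
radian) and the harmonic factor n, without which the n equally spaced bands
of a perfectly locked m:n segment would cancel to lambda ~ 0.  The
literally printed formula (``exp(i*psi)``, fixed 1/N) remains available via
``mode="printed"``.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fetalcoupling.beat_series import SegmentPair
from fetalcoupling.coupling_label import CouplingRatio

__all__ = [
    "PhaseParams",
    "PhaseRecord",
    "CoherenceSeries",
    "instantaneous_phase",
    "relative_phase",
    "phase_series",
    "lambda_p",
    "synchrogram_points",
    "write_coherence_csv",
    "write_synchrogram_csv",
]


@dataclass(frozen=True)
class PhaseParams:
    """Parameters of the phase/coherence computation for one m:n ratio.

    Parameters
    ----------
    m : int
        Maternal beats per cycle.
    n : int
        Fetal beats per cycle group (harmonic order of the coherence
        average).
    N : int
        Expected number of records per coherence window; odd, default 15
        (suited to 1-min segments).
    """

    m: int
    n: int
    N: int = 15

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError(f"m and n must be >= 1, got {self.m}, {self.n}")
        if self.N < 3 or self.N % 2 == 0:
            raise ValueError(f"N must be odd and >= 3, got {self.N}")

    @classmethod
    def from_ratio(cls, ratio: CouplingRatio, N: int = 15) -> "PhaseParams":
        return cls(m=ratio.m, n=ratio.n, N=N)


@dataclass(frozen=True)
class PhaseRecord:
    """Phase of one fetal beat within its enclosing maternal cycle."""

    t: float  # fetal beat time, seconds
    k: int  # maternal cycle index
    cycle_start: float
    cycle_end: float
    phi: float  # unbounded instantaneous phase, radians
    psi: float  # relative phase of occurrence, in [0, 1)


@dataclass(frozen=True)
class CoherenceSeries:
    """Windowed phase coherence values anchored at fetal-beat times."""

    times: np.ndarray
    values: np.ndarray  # lambda in [0, 1]
    params: PhaseParams
    per_minute: float = field(default=math.nan)  # mean lambda over the segment


def instantaneous_phase(t: float, t_k: float, t_k_plus_m: float, k: int) -> float:
    """Unbounded instantaneous phase of a fetal beat in maternal cycle k."""
    if t_k_plus_m <= t_k:
        raise ValueError(f"degenerate maternal cycle [{t_k}, {t_k_plus_m}]")
    if not (t_k <= t < t_k_plus_m):
        raise ValueError(f"fetal beat {t} outside cycle [{t_k}, {t_k_plus_m})")
    return 2.0 * math.pi * (t - t_k) / (t_k_plus_m - t_k) + 2.0 * math.pi * k


def relative_phase(phi: float) -> float:
    """Relative phase of occurrence: ``(phi mod 2*pi) / (2*pi)`` in [0, 1)."""
    psi = (phi % (2.0 * math.pi)) / (2.0 * math.pi)
    return psi if psi < 1.0 else 0.0  # guard against float round-up


def phase_series(seg: SegmentPair, params: PhaseParams) -> list[PhaseRecord]:
    """Phase records of all fetal beats inside complete maternal m-cycles.

    Maternal cycles tile the segment non-overlapping (stride m, cycle index
    k = j for ``[t_{jm}, t_{(j+1)m})``).  Fetal beats before the first or
    after the last complete cycle are skipped (warned with a count).
    """
    mat = seg.maternal.times
    m = params.m
    n_cycles = (len(mat) - 1) // m
    if n_cycles < 1:
        warnings.warn(
            f"{seg.subject_id} segment {seg.segment_index}: no complete m={m} cycle",
            stacklevel=2,
        )
        return []
    bounds = mat[: n_cycles * m + 1 : m]  # cycle edges t_0, t_m, t_2m, ...
    fet = seg.fetal.times
    records: list[PhaseRecord] = []
    n_skipped = 0
    for t in fet:
        k = int(np.searchsorted(bounds, t, side="right")) - 1
        if k < 0 or k >= n_cycles:
            n_skipped += 1
            continue
        phi = instantaneous_phase(float(t), float(bounds[k]), float(bounds[k + 1]), k)
        records.append(
            PhaseRecord(
                t=float(t),
                k=k,
                cycle_start=float(bounds[k]),
                cycle_end=float(bounds[k + 1]),
                phi=phi,
                psi=relative_phase(phi),
            )
        )
    if n_skipped:
        warnings.warn(
            f"{seg.subject_id} segment {seg.segment_index}: skipped {n_skipped} fetal "
            f"beat(s) outside complete cycles",
            stacklevel=2,
        )
    return records


def _windowed_lambda(psi: np.ndarray, n: int, N: int, mode: str) -> np.ndarray:
    """lambda value at every record index (symmetric window of up to N)."""
    if mode == "corrected":
        z = np.exp(1j * 2.0 * np.pi * n * psi)
    elif mode == "printed":
        z = np.exp(1j * psi)
    else:
        raise ValueError(f"mode must be 'corrected' or 'printed', got {mode!r}")
    half = N // 2
    csum = np.concatenate(([0.0 + 0.0j], np.cumsum(z)))
    j = np.arange(psi.size)
    lo = np.maximum(j - half, 0)
    hi = np.minimum(j + half, psi.size - 1) + 1
    sums = csum[hi] - csum[lo]
    denom = (hi - lo) if mode == "corrected" else N
    return np.abs(sums / denom) ** 2


def lambda_p(
    records: list[PhaseRecord], params: PhaseParams, mode: str = "corrected"
) -> CoherenceSeries:
    """Windowed phase coherence index over a segment's phase records.

    Records are ordered by time; at each record a symmetric window of up to
    N records (truncated at the edges, renormalized by the actual member
    count) yields ``lambda = |mean exp(i*2*pi*n*psi)|^2``.  ``per_minute``
    is the arithmetic mean of lambda over the segment.  ``mode="printed"``
    switches to the bare formula ``|1/N sum exp(i*psi)|^2`` without angular
    rescaling, harmonic correction or edge renormalization.
    """
    if len(records) < 3:
        raise ValueError(f"coherence undefined: need >= 3 phase records, have {len(records)}")
    order = np.argsort([r.t for r in records], kind="stable")
    times = np.asarray([records[i].t for i in order])
    psi = np.asarray([records[i].psi for i in order])
    lam = _windowed_lambda(psi, params.n, params.N, mode)
    return CoherenceSeries(times=times, values=lam, params=params, per_minute=float(lam.mean()))


def segment_lambda(seg: SegmentPair, params: PhaseParams, mode: str = "corrected") -> CoherenceSeries:
    """Convenience: phase records + windowed coherence for one segment."""
    return lambda_p(phase_series(seg, params), params, mode=mode)


def synchrogram_points(records: list[PhaseRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(time, psi) pairs for synchrogram plotting (inputs not mutated)."""
    if not records:
        raise ValueError("synchrogram needs at least one phase record")
    order = np.argsort([r.t for r in records], kind="stable")
    t = np.asarray([records[i].t for i in order])
    psi = np.asarray([records[i].psi for i in order])
    return t, psi


def band_spread(psi: np.ndarray, n_bands: int) -> float:
    """Largest within-band spread after partitioning psi into n circular bands.

    The circle is cut at the ``n_bands`` largest gaps of the sorted psi
    values; returns the maximum within-cluster circular range.  Near 0 for
    an m:n-locked synchrogram with n bands; large for uncoupled scatter.
    """
    psi = np.sort(np.asarray(psi, dtype=float) % 1.0)
    if psi.size <= n_bands:
        return 0.0
    gaps = np.diff(np.concatenate([psi, [psi[0] + 1.0]]))
    cut = np.sort(np.argsort(gaps)[-n_bands:])
    spreads = []
    starts = np.concatenate([[(cut[-1] + 1) % psi.size], cut[:-1] + 1])
    for s, e in zip(starts, cut):
        if s <= e:
            members = psi[s : e + 1]
        else:  # wraps around the cut point
            members = np.concatenate([psi[s:], psi[: e + 1] + 1.0])
        spreads.append(float(members.max() - members.min()) if members.size else 0.0)
    return max(spreads)


def write_coherence_csv(rows: list[dict], path: str | os.PathLike) -> pd.DataFrame:
    """Write per-segment coherence summaries.

    Each row: subject_id, segment_index, ratio_m, ratio_n,
    lambda_per_minute, n_records.
    """
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "segment_index", "ratio_m", "ratio_n", "lambda_per_minute", "n_records"],
    )
    df.to_csv(path, index=False)
    return df


def write_synchrogram_csv(records: list[PhaseRecord], path: str | os.PathLike) -> pd.DataFrame:
    t, psi = synchrogram_points(records)
    df = pd.DataFrame({"time_s": t, "psi": psi})
    df.to_csv(path, index=False)
    return df
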