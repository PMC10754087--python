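"""Single-molecule burst identification and per-burst FRET observables.

Bursts are maximal runs of photons whose inter-photon gaps never exceed
a threshold Delta-T; retained bursts must contain between N_min and
N_max photons.  Per burst the corrected transfer efficiency E,
stoichiometry S and anisotropy r are computed from the channel counts
with crosstalk (alpha), direct-excitation (delta), detection/quantum
yield (gamma), excitation (beta) and polarization (G, l1, l2)
corrections.  Degenerate denominators yield NaN sentinels rather than
exceptions so stream-scale processing is uninterrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photons import PhotonStream, SRC_GREEN, SRC_RED

__all__ = [
    "BurstSearchParams",
    "CorrectionFactors",
    "Burst",
    "delta_t_burst_search",
    "apply_rcm",
    "fret_efficiency",
    "stoichiometry",
    "burst_anisotropy",
    "burst_features",
    "select_substate",
    "bursts_to_frame",
]

log = logging.getLogger(__name__)


@dataclass
class BurstSearchParams:
    """Delta-T burst search parameters (defaults follow common practice:
    100 us gap threshold, 35 to 10 000 photons)."""

    delta_t: float = 100e-6
    n_min: int = 35
    n_max: int = 10_000
    dual_channel: bool = False

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if not 0 < self.n_min <= self.n_max:
            raise ValueError("need 0 < n_min <= n_max")


@dataclass
class CorrectionFactors:
    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0
    g_factor: float = 1.0
    l1: float = 0.0308
    l2: float = 0.0368
    rcm: np.ndarray | None = None     # 4x4 route correction matrix

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be >= 0")
        if min(self.gamma, self.beta, self.g_factor) <= 0:
            raise ValueError("gamma, beta and G must be > 0")
        if self.rcm is not None:
            self.rcm = np.asarray(self.rcm, dtype=float)
            if self.rcm.shape != (4, 4) or np.any(self.rcm < 0):
                raise ValueError("RCM must be 4x4 with nonnegative entries")


@dataclass
class Burst:
    start_index: int
    stop_index: int                   # inclusive
    start_time: float                 # s
    stop_time: float                  # s
    f_dd: float                       # donor emission after green excitation
    f_da: float                       # acceptor emission after green excitation
    f_aa: float                       # acceptor emission after red excitation
    f_par: float
    f_perp: float
    n_photons: int
    indices: np.ndarray = field(repr=False, default=None)
    e: float = np.nan
    s: float = np.nan
    r: float = np.nan

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time


def _segments(times: np.ndarray, delta_t: float):
    """Maximal runs with all inter-photon gaps <= delta_t (brute-force-
    equivalent segmentation in O(N))."""
    if times.size == 0:
        return []
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps > delta_t)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [times.size - 1]])
    return list(zip(starts, stops))


def delta_t_burst_search(stream: PhotonStream, params: BurstSearchParams,
                         cf: CorrectionFactors | None = None) -> list[Burst]:
    """Identify single-molecule bursts with the Delta-T algorithm.

    In dual-channel mode the gap criterion must hold independently in the
    donor-excited and acceptor-excited photon subsets; a burst is kept
    where such segments overlap (intersection rule) and the size bounds
    apply to the combined photon count.
    """
    t = stream.times_s
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("stream must be time-sorted")

    if not params.dual_channel:
        segs = [(a, b) for a, b in _segments(t, params.delta_t)]
        candidates = [(np.arange(a, b + 1), t[a], t[b]) for a, b in segs]
    else:
        green = np.flatnonzero(stream.source == SRC_GREEN)
        red = np.flatnonzero(stream.source == SRC_RED)
        segs_g = [(t[green[a]], t[green[b]]) for a, b in _segments(t[green], params.delta_t)]
        segs_r = [(t[red[a]], t[red[b]]) for a, b in _segments(t[red], params.delta_t)]
        candidates = []
        j = 0
        for g0, g1 in segs_g:
            while j < len(segs_r) and segs_r[j][1] < g0:
                j += 1
            k = j
            while k < len(segs_r) and segs_r[k][0] <= g1:
                lo, hi = max(g0, segs_r[k][0]), min(g1, segs_r[k][1])
                idx = np.flatnonzero((t >= lo) & (t <= hi))
                if idx.size:
                    candidates.append((idx, lo, hi))
                k += 1

    bursts: list[Burst] = []
    for idx, t0, t1 in candidates:
        n = idx.size
        if not params.n_min <= n <= params.n_max:
            continue
        ch = stream.channel[idx]
        src = stream.source[idx]
        counts = np.array([np.sum((ch == c) & (src == SRC_GREEN)) for c in range(4)], dtype=float)
        if cf is not None and cf.rcm is not None:
            counts = apply_rcm(counts, cf.rcm)
        f_dd = counts[0] + counts[1]
        f_da = counts[2] + counts[3]
        f_aa = float(np.sum((ch >= 2) & (src == SRC_RED)))
        f_par = float(counts[0] + counts[2])
        f_perp = float(counts[1] + counts[3])
        bursts.append(Burst(int(idx[0]), int(idx[-1]), float(t0), float(t1),
                            f_dd, f_da, f_aa, f_par, f_perp, int(n), indices=idx))
    return bursts


def apply_rcm(raw_counts: np.ndarray, rcm: np.ndarray) -> np.ndarray:
    """Route-correct 4-channel counts by the route correction matrix.

    Negative results are clamped to zero with a warning.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.shape != (4,):
        raise ValueError("expected 4 channel counts")
    out = np.asarray(rcm, dtype=float) @ raw
    if np.any(out < 0):
        log.warning("RCM produced negative counts; clamping to zero")
        out = np.clip(out, 0.0, None)
    return out


def fret_efficiency(f_dd: float, f_da: float, f_aa: float, cf: CorrectionFactors) -> float:
    """Corrected transfer efficiency E = F_c / (gamma F_DD + F_c) with
    F_c = G F_DA - alpha F_DD - delta F_AA.  Returns NaN when the
    denominator is <= 0 and 0 when F_c <= 0 with a positive denominator."""
    f_c = cf.g_factor * f_da - cf.alpha * f_dd - cf.delta * f_aa
    denom = cf.gamma * f_dd + f_c
    if denom <= 0:
        log.debug("degenerate FRET denominator (F_DD=%s F_DA=%s F_AA=%s)", f_dd, f_da, f_aa)
        return np.nan
    return f_c / denom


def stoichiometry(f_dd: float, f_da: float, f_aa: float, cf: CorrectionFactors) -> float:
    """Corrected stoichiometry; beta balances donor vs acceptor excitation."""
    green = cf.gamma * f_dd + f_da - cf.alpha * f_dd - cf.delta * f_aa
    denom = green + cf.beta * f_aa
    if denom <= 0:
        return np.nan
    return green / denom


def burst_anisotropy(f_par: float, f_perp: float, cf: CorrectionFactors) -> float:
    """Steady-state burst anisotropy with G balance and objective
    depolarization factors l1, l2."""
    denom = (1.0 - 3.0 * cf.l2) * cf.g_factor * f_par + (2.0 - 3.0 * cf.l1) * f_perp
    if denom == 0:
        return np.nan
    return (cf.g_factor * f_par - f_perp) / denom


def burst_features(bursts: list[Burst], cf: CorrectionFactors) -> list[Burst]:
    """Attach E, S, r to each burst in place (and return the list)."""
    for b in bursts:
        b.e = fret_efficiency(b.f_dd, b.f_da, b.f_aa, cf)
        b.s = stoichiometry(b.f_dd, b.f_da, b.f_aa, cf)
        b.r = burst_anisotropy(b.f_par, b.f_perp, cf)
    return bursts


def select_substate(bursts: list[Burst], e_range: tuple[float, float],
                    s_range: tuple[float, float] | None = None) -> list[Burst]:
    """Bursts whose E (and optionally S) lie inside closed intervals.

    Order-preserving; NaN features never match.
    """
    e_lo, e_hi = e_range
    if e_lo > e_hi:
        raise ValueError("inverted E range")
    if s_range is not None and s_range[0] > s_range[1]:
        raise ValueError("inverted S range")
    out = []
    for b in bursts:
        if not (np.isfinite(b.e) and e_lo <= b.e <= e_hi):
            continue
        if s_range is not None and not (np.isfinite(b.s) and s_range[0] <= b.s <= s_range[1]):
            continue
        out.append(b)
    return out


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    """Burst table (one row per burst) for TSV export."""
    return pd.DataFrame({
        "start_time_s": [b.start_time for b in bursts],
        "stop_time_s": [b.stop_time for b in bursts],
        "n_photons": [b.n_photons for b in bursts],
        "F_DD": [b.f_dd for b in bursts],
        "F_DA": [b.f_da for b in bursts],
        "F_AA": [b.f_aa for b in bursts],
        "F_par": [b.f_par for b in bursts],
        "F_perp": [b.f_perp for b in bursts],
        "E": [b.e for b in bursts],
        "S": [b.s for b in bursts],
        "r": [b.r for b in bursts],
    })
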