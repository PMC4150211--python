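"""Sliding-window binomial read-depth CNV calling.

For each 100-kb window (tiled at 10-kb steps) the normal sample defines the
per-window read-mapping probability p_w = n_w / N, absorbing mapability and
other window-specific effects. The tumor count t_w is then tested against
Binomial(T, p_w): upper tail P[X >= t_w] when the adjusted ratio

    r_w = (t_w / T) / (n_w / N)

exceeds 1 (candidate gain), lower tail P[X <= t_w] otherwise (candidate
loss). A window is called significant when its one-sided tail probability
falls below a fixed stringent threshold (default 1e-8, no multiple-testing
correction) AND the ratio clears the corresponding gate (>= 1.5 for gains,
<= 0.5 for losses). Overlapping/book-ended significant windows of one
direction merge into segments; the integer dosage estimate is
round(2 * segment ratio), with dosage-2 results suppressed as inconsistent
with a copy-number call.

Windows with n_w = 0 have undefined p_w; they are masked as untestable
(mapability artifact), never reported as losses.
"""

from __future__ import annotations

import warnings as _warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import CnvConfig
from .intervals import GenomeIntervals
from .records import CnvSegment, WindowTrack


def tile_windows(chrom_lengths: Mapping[str, int], config: CnvConfig) -> pd.DataFrame:
    """Tile each chromosome with fixed-size windows at a fixed step.

    Windows are 0-based half-open, start at 0, step, 2*step, ... and must lie
    fully inside the chromosome; a chromosome shorter than one window yields
    no windows (with a warning). For length L, window W and step s the count
    is floor((L - W) / s) + 1.
    """
    rows = []
    W, s = config.window_size, config.step
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < W:
            _warnings.warn(f"{chrom} (length {length}) shorter than one window; skipped")
            continue
        n = (length - W) // s + 1
        starts = np.arange(n, dtype=np.int64) * s
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + W}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def window_binomial_test(t_w, n_w, T: int, N: int,
                         two_sided: bool = False) -> pd.DataFrame:
    """Per-window binomial tail test; vectorized over window count arrays.

    Returns a DataFrame with columns p_value, ratio, direction, testable.
    Tail evaluation uses scipy's regularized incomplete-beta implementation,
    numerically stable at read totals of order 1e7.
    """
    t = np.asarray(t_w, dtype=np.int64)
    n = np.asarray(n_w, dtype=np.int64)
    if T <= 0 or N <= 0:
        raise ValueError("read totals must be positive")
    if (t < 0).any() or (n < 0).any():
        raise ValueError("negative window counts")

    testable = n > 0
    p_w = np.where(testable, n, 1) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (t / T) / p_w
    ratio = np.where(testable, ratio, np.nan)

    gain = ratio > 1.0
    upper = stats.binom.sf(t - 1, T, p_w)   # P[X >= t]
    lower = stats.binom.cdf(t, T, p_w)      # P[X <= t]
    p_value = np.where(gain, upper, lower)
    if two_sided:
        p_value = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    p_value = np.where(testable, p_value, np.nan)

    direction = np.where(gain, "gain", "loss")
    out = pd.DataFrame({
        "p_value": p_value,
        "ratio": ratio,
        "direction": direction,
        "testable": testable,
    })
    out.loc[~testable, "direction"] = "untestable"
    return out


def evaluate_track(track: WindowTrack, config: CnvConfig) -> pd.DataFrame:
    """Windows of a track with test results appended (diagnostics table)."""
    res = window_binomial_test(track.windows["tumor_count"].to_numpy(),
                               track.windows["normal_count"].to_numpy(),
                               track.tumor_total, track.normal_total,
                               two_sided=config.two_sided)
    return pd.concat([track.windows.reset_index(drop=True), res], axis=1)


def call_significant_windows(track: WindowTrack, config: CnvConfig) -> pd.DataFrame:
    """Windows passing both the P-value threshold and the ratio gate."""
    diag = evaluate_track(track, config)
    sig_p = diag["p_value"] < config.p_threshold
    gate = np.where(diag["direction"] == "gain",
                    diag["ratio"] >= config.gain_ratio_min,
                    diag["ratio"] <= config.loss_ratio_max)
    flagged = diag[diag["testable"] & sig_p & gate].copy()
    return flagged.reset_index(drop=True)


def merge_segments(flagged: pd.DataFrame, track: WindowTrack,
                   config: CnvConfig) -> list[CnvSegment]:
    """Merge overlapping/book-ended flagged windows of one direction.

    Segment coordinates are the union span of constituent windows. The
    segment ratio is recomputed from counts summed over those windows
    (overlap double-counting cancels between numerator and denominator) and
    the dosage estimate is round-half-up(2 * ratio); dosage-2 segments are
    suppressed. min_p is the smallest constituent window P-value — the
    constituent tests overlap and are correlated, so no combined statistic
    is reported.
    """
    segments: list[CnvSegment] = []
    if flagged.empty:
        return segments
    T, N = track.tumor_total, track.normal_total
    for (chrom, direction), grp in flagged.groupby(["chrom", "direction"], sort=False):
        grp = grp.sort_values("start")
        runs: list[list[int]] = []
        cur: list[int] = []
        cur_end = None
        for idx, row in grp.iterrows():
            if cur and row["start"] > cur_end:
                runs.append(cur)
                cur = []
            cur.append(idx)
            cur_end = row["end"] if cur_end is None or len(cur) == 1 else max(cur_end, row["end"])
        if cur:
            runs.append(cur)
        for run in runs:
            sub = grp.loc[run]
            t_sum = int(sub["tumor_count"].sum())
            n_sum = int(sub["normal_count"].sum())
            ratio = (t_sum / T) / (n_sum / N) if n_sum > 0 else float("nan")
            dosage = int(np.floor(2.0 * ratio + 0.5)) if np.isfinite(ratio) else 0
            seg = CnvSegment(
                chrom=chrom,
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                direction=direction,
                ratio=float(ratio),
                dosage=dosage,
                min_p=float(sub["p_value"].min()),
                n_windows=len(sub),
            )
            if seg.dosage == 2:
                continue  # inconsistent with a confident copy-number change
            segments.append(seg)
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def call_cnv_segments(track: WindowTrack, config: CnvConfig) -> list[CnvSegment]:
    """Full caller: significant windows -> merged, dosage-annotated segments."""
    return merge_segments(call_significant_windows(track, config), track, config)


def annotate_segments(segments: Iterable[CnvSegment],
                      gene_intervals: GenomeIntervals) -> list[CnvSegment]:
    """Attach gene symbols overlapping each segment by >= 1 bp, in position order."""
    annotated = []
    for seg in segments:
        hits = gene_intervals.overlapping(seg.chrom, seg.start, seg.end)
        seg.genes = [str(d) for (_s, _e, d) in hits if d is not None]
        annotated.append(seg)
    return annotated
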