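"""X-QTL genome scan: allele-frequency skew from pooled probe intensities.

A selected pool (extreme phenotypic tail) and the whole unselected
population are each hybridized to an allele-specific array. For every SNP
the log10 intensity difference Delta = log10(I_BY) - log10(I_RM) is formed
per pool; subtracting the whole-population Delta removes allele-frequency
bias introduced during pool construction. The corrected skew is smoothed
with a centered physical-distance sliding window (40 kb by default) and
peaks are called against an empirical null band: positive peaks mark
BY-allele enrichment in the selected pool, negative peaks RM enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("chrom", "pos", "delta", "corrected")


class FrameMismatchError(ValueError):
    """Selected and whole-population tables must share one marker frame."""


@dataclass(frozen=True)
class QtlPeak:
    """A called QTL: local extremum of |smoothed skew| above the null band.

    ``sign`` is +1 for BY-allele enrichment (skew > 0), -1 for RM.
    (start, end) is the flanking interval (bp, inclusive) where the
    smoothed skew magnitude stays above half the peak value.
    """

    chrom: int
    pos: int
    value: float
    sign: int
    start: int
    end: int
    threshold: float
    significant: bool = True

    def __post_init__(self) -> None:
        if not self.start <= self.pos <= self.end:
            raise ValueError("peak interval must contain the peak")


def _check_frames(selected: pd.DataFrame, whole: pd.DataFrame) -> None:
    for col in ("chrom", "pos"):
        if col not in selected.columns or col not in whole.columns:
            raise FrameMismatchError(f"missing required column {col!r}")
    if len(selected) != len(whole):
        raise FrameMismatchError(
            f"marker frames differ in length: {len(selected)} vs {len(whole)}")
    same = (selected["chrom"].to_numpy() == whole["chrom"].to_numpy()) & \
           (selected["pos"].to_numpy() == whole["pos"].to_numpy())
    if not same.all():
        i = int(np.flatnonzero(~same)[0])
        raise FrameMismatchError(
            f"marker frames disagree first at row {i}: "
            f"{selected['chrom'].iat[i]}:{selected['pos'].iat[i]} vs "
            f"{whole['chrom'].iat[i]}:{whole['pos'].iat[i]}")


def compute_skew(selected: pd.DataFrame, whole: pd.DataFrame) -> pd.DataFrame:
    """Background-corrected log10 BY/RM intensity skew per SNP.

    Both inputs need columns (chrom, pos, intensity_BY, intensity_RM) on an
    identical, position-sorted marker frame. Returns a track with columns
    (chrom, pos, delta, corrected) where delta is the selected pool's log10
    intensity difference and corrected = delta_selected - delta_whole.
    """
    _check_frames(selected, whole)
    for df, label in ((selected, "selected"), (whole, "whole")):
        for col in ("intensity_BY", "intensity_RM"):
            vals = df[col].to_numpy(dtype=float)
            if (vals <= 0).any() or not np.isfinite(vals).all():
                raise ValueError(f"{label} pool: {col} must be finite and > 0")
    delta_sel = (np.log10(selected["intensity_BY"].to_numpy(dtype=float))
                 - np.log10(selected["intensity_RM"].to_numpy(dtype=float)))
    delta_whole = (np.log10(whole["intensity_BY"].to_numpy(dtype=float))
                   - np.log10(whole["intensity_RM"].to_numpy(dtype=float)))
    return pd.DataFrame({
        "chrom": selected["chrom"].to_numpy(),
        "pos": selected["pos"].to_numpy(),
        "delta": delta_sel,
        "corrected": delta_sel - delta_whole,
    })


def smooth(track: pd.DataFrame, window_bp: int = 40_000,
           value_col: str = "corrected") -> pd.DataFrame:
    """Centered sliding-window mean over markers within +/- window/2 bp.

    Windows never span a chromosome boundary and shrink at chromosome ends
    so that every SNP emits a value. Returns the track with a ``smoothed``
    column added.
    """
    if window_bp <= 0:
        raise ValueError("window must be > 0")
    chrom = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy(dtype=np.int64)
    vals = track[value_col].to_numpy(dtype=float)
    out = np.empty_like(vals)
    half = window_bp / 2.0
    for c in np.unique(chrom):
        m = chrom == c
        p, v = pos[m], vals[m]
        if not (np.diff(p) >= 0).all():
            raise ValueError(f"track not position-sorted on chromosome {c}")
        left = np.searchsorted(p, p - half, side="left")
        right = np.searchsorted(p, p + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(v)])
        out[m] = (csum[right] - csum[left]) / (right - left)
    res = track.copy()
    res["smoothed"] = out
    return res


def sign_permutation_null(track: pd.DataFrame, window_bp: int = 40_000,
                          n_perm: int = 10, seed: int = 0,
                          block_bp: int | None = None) -> list[np.ndarray]:
    """Smoothed null tracks from random sign flips of the corrected skew.

    Per-marker flips (default) give a null for exchangeable, independent
    marker noise; ``block_bp`` flips contiguous physical blocks as units,
    preserving short-range autocorrelation. Returns one smoothed array per
    permutation.
    """
    rng = np.random.default_rng(seed)
    pos = track["pos"].to_numpy(dtype=np.int64)
    chrom = track["chrom"].to_numpy()
    corrected = track["corrected"].to_numpy(dtype=float)
    if block_bp is None:
        block_ids = np.arange(len(pos))
    else:
        # block index combines chromosome and physical bin so blocks never
        # span a chromosome boundary
        bins = pos // block_bp
        _, block_ids = np.unique(np.stack([chrom, bins]), axis=1, return_inverse=True)
    n_blocks = int(block_ids.max()) + 1
    nulls = []
    base = track[["chrom", "pos"]].copy()
    for _ in range(n_perm):
        flips = rng.choice((-1.0, 1.0), size=n_blocks)
        base["corrected"] = corrected * flips[block_ids]
        nulls.append(smooth(base, window_bp=window_bp)["smoothed"].to_numpy())
    return nulls


def null_band(null_tracks, quantile: float = 0.999,
              family: str = "pointwise") -> float:
    """Symmetric significance threshold from smoothed null tracks.

    ``family='pointwise'``: the given quantile of |smoothed null skew| over
    all markers of all null tracks. ``family='max'``: the quantile of each
    null track's genome-wide maximum |smoothed skew| — a familywise band
    appropriate when the null tracks carry the same along-genome
    autocorrelation as the observed scan.
    """
    tracks = [np.abs(np.asarray(t, dtype=float)) for t in null_tracks]
    if len(tracks) == 0:
        raise ValueError("at least one null track is required")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    if family == "pointwise":
        return float(np.quantile(np.concatenate(tracks), quantile))
    if family == "max":
        return float(np.quantile([t.max() for t in tracks], quantile))
    raise ValueError("family must be 'pointwise' or 'max'")


def _segments(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True as (start, end) inclusive index pairs."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_peaks(smoothed: pd.DataFrame, threshold: float,
               window_bp: int = 40_000) -> list[QtlPeak]:
    """Call QTL peaks: extrema of |smoothed skew| above the null band.

    Super-threshold segments separated by less than one window are merged;
    adjacent candidate peaks are further merged when the track between them
    never drops below half the lower peak magnitude (the decay flank of a
    strong QTL flutters around any pointwise threshold and must not
    shatter into several calls). Each peak reports the signed extremum and
    the half-height flanking interval.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    chrom = smoothed["chrom"].to_numpy()
    pos = smoothed["pos"].to_numpy(dtype=np.int64)
    vals = smoothed["smoothed"].to_numpy(dtype=float)
    peaks: list[QtlPeak] = []
    for c in np.unique(chrom):
        m = chrom == c
        p, v = pos[m], vals[m]
        a = np.abs(v)
        segs = _segments(a > threshold)
        if not segs:
            continue
        # merge segments separated by less than one window
        merged = [segs[0]]
        for s, e in segs[1:]:
            if p[s] - p[merged[-1][1]] < window_bp:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        # one candidate peak per merged segment
        cand = []
        for s, e in merged:
            j = s + int(np.argmax(a[s:e + 1]))
            cand.append(j)
        # topographic merge: drop the lower of two adjacent peaks when the
        # valley between them stays above half the lower peak
        changed = True
        while changed and len(cand) > 1:
            changed = False
            for i in range(len(cand) - 1):
                j1, j2 = cand[i], cand[i + 1]
                valley = a[j1:j2 + 1].min()
                lower = min(a[j1], a[j2])
                if valley > 0.5 * lower:
                    cand.pop(i if a[j1] < a[j2] else i + 1)
                    changed = True
                    break
        for j in cand:
            half = 0.5 * a[j]
            lo = j
            while lo > 0 and a[lo - 1] > half:
                lo -= 1
            hi = j
            while hi < len(a) - 1 and a[hi + 1] > half:
                hi += 1
            peaks.append(QtlPeak(
                chrom=int(c), pos=int(p[j]), value=float(v[j]),
                sign=1 if v[j] > 0 else -1,
                start=int(p[lo]), end=int(p[hi]),
                threshold=float(threshold),
            ))
    return peaks


def peaks_to_frame(peaks: list[QtlPeak]) -> pd.DataFrame:
    cols = ["chrom", "pos", "value", "sign", "start", "end", "threshold", "significant"]
    return pd.DataFrame([{k: getattr(pk, k) for k in cols} for pk in peaks],
                        columns=cols)
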