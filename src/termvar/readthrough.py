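"""Percent stop-codon readthrough from dual-luciferase (and GFP) reporters.

The dual-luciferase reporter places Renilla and firefly luciferase in
tandem, separated by a single test codon. With a stop codon in between,
firefly activity is produced only when the ribosome reads through the stop;
the firefly/Renilla ratio normalizes for expression. Percent readthrough is
the stop-codon ratio expressed relative to the matched sense-codon ratio:

    readthrough% = 100 * (F/R | stop) / (F/R | sense)

Background luminescence (no-lysate controls) is subtracted from each
channel before ratios are formed. Replicate assays are summarized as mean
+/- sample SD, with QC warnings when fewer than eight assays or four
biological replicates are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STOP = "stop"
SENSE = "sense"


class AssayError(ValueError):
    """Raised for unusable assay records (e.g. zero Renilla signal)."""


@dataclass(frozen=True)
class LuminescenceRecord:
    """One reporter assay: raw RLUs plus matched no-lysate background RLUs."""

    strain: str
    construct: str            # "stop" or "sense"
    firefly_rlu: float
    renilla_rlu: float
    firefly_bg: float
    renilla_bg: float
    assay_id: str = "a1"
    bio_rep: str = "b1"

    def __post_init__(self) -> None:
        if self.construct not in (STOP, SENSE):
            raise AssayError(f"construct must be 'stop' or 'sense', got {self.construct!r}")
        for name in ("firefly_rlu", "renilla_rlu", "firefly_bg", "renilla_bg"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise AssayError(f"record {self.strain}/{self.assay_id}: missing {name}")
            if v < 0:
                raise AssayError(f"record {self.strain}/{self.assay_id}: negative {name}")


@dataclass(frozen=True)
class RatioEstimate:
    """Mean firefly/Renilla ratio with sample SD over n replicate assays."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ReadthroughEstimate:
    """Mean +/- SD percent readthrough over n assays for one strain."""

    strain: str
    mean_pct: float
    sd_pct: float
    n: int


def background_subtract(record: LuminescenceRecord) -> tuple[float, float]:
    """Subtract the matched no-lysate background from each channel.

    Negative corrected signals are floored at 0 with a warning —
    luminescence cannot be negative, so a sub-background reading is noise.
    """
    fire = record.firefly_rlu - record.firefly_bg
    reni = record.renilla_rlu - record.renilla_bg
    if fire < 0:
        warnings.warn(
            f"firefly signal below background for {record.strain}/{record.assay_id}; floored at 0",
            stacklevel=2)
        fire = 0.0
    if reni < 0:
        warnings.warn(
            f"Renilla signal below background for {record.strain}/{record.assay_id}; floored at 0",
            stacklevel=2)
        reni = 0.0
    return float(fire), float(reni)


def luciferase_ratio(firefly: float, renilla: float) -> float:
    """Firefly/Renilla activity ratio; zero Renilla marks a failed assay."""
    if renilla <= 0:
        raise AssayError("Renilla signal is zero (assay failure); ratio undefined")
    return firefly / renilla


def readthrough_percent(stop_ratio: float, sense_ratio: float) -> float:
    """Percent readthrough: stop-codon ratio normalized by the sense ratio."""
    if sense_ratio <= 0:
        raise AssayError("sense-construct ratio must be > 0")
    return 100.0 * stop_ratio / sense_ratio


def gfp_readthrough(signal_with_stop: float, signal_without_stop: float) -> float:
    """GFP-reporter readthrough: stop-containing over intact-reporter signal."""
    if signal_without_stop <= 0:
        raise AssayError("intact-reporter GFP signal must be > 0")
    return 100.0 * signal_with_stop / signal_without_stop


def summarize_replicates(values, strain: str = "",
                         n_bio_reps: int | None = None) -> ReadthroughEstimate:
    """Mean and sample SD (n-1 denominator) of per-assay readthrough values.

    Warns if fewer than 8 assays or fewer than 4 biological replicates are
    provided (the assay's QC recommendation). With a single value the
    sample SD is undefined and reported as 0.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise AssayError("no readthrough values to summarize")
    if vals.size < 8:
        warnings.warn(f"only {vals.size} assays for {strain or 'strain'} (recommend >= 8)",
                      stacklevel=2)
    if n_bio_reps is not None and n_bio_reps < 4:
        warnings.warn(f"only {n_bio_reps} biological replicates (recommend >= 4)",
                      stacklevel=2)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ReadthroughEstimate(strain=strain, mean_pct=float(vals.mean()),
                               sd_pct=sd, n=int(vals.size))


def ratio_sd_propagation(stop: RatioEstimate, sense: RatioEstimate) -> float:
    """Delta-method SD of percent readthrough from the two ratio summaries.

    Secondary report for comparison with per-assay summarization:
    sd(100*s/n) ~ (100*s/n) * sqrt((sd_s/s)^2 + (sd_n/n)^2).
    """
    if stop.mean <= 0 or sense.mean <= 0:
        raise AssayError("delta-method propagation needs positive mean ratios")
    rt = 100.0 * stop.mean / sense.mean
    return rt * math.sqrt((stop.sd / stop.mean) ** 2 + (sense.sd / sense.mean) ** 2)


def _assay_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Background-correct and form per-assay ratios from a plate table."""
    rows = []
    for rec in df.itertuples(index=False):
        record = LuminescenceRecord(
            strain=str(rec.strain), construct=str(rec.construct),
            firefly_rlu=float(rec.firefly_rlu), renilla_rlu=float(rec.renilla_rlu),
            firefly_bg=float(rec.firefly_bg), renilla_bg=float(rec.renilla_bg),
            assay_id=str(rec.assay_id), bio_rep=str(rec.bio_rep),
        )
        fire, reni = background_subtract(record)
        rows.append({
            "strain": record.strain, "construct": record.construct,
            "assay_id": record.assay_id, "bio_rep": record.bio_rep,
            "ratio": luciferase_ratio(fire, reni),
        })
    return pd.DataFrame(rows)


def estimate_readthrough(plate: pd.DataFrame,
                         pairing: str = "batch_mean") -> pd.DataFrame:
    """Per-strain readthrough estimates from a plate-reading table.

    ``pairing`` controls how stop assays find their sense denominator:

    * ``"batch_mean"`` (default): each stop-construct assay is normalized by
      the mean sense-construct ratio of the same strain (stop and sense
      reporters live in separate transformants, so there is no natural
      per-assay pairing).
    * ``"per_assay"``: stop and sense assays sharing an ``assay_id`` are
      paired directly.

    Returns one row per strain: mean_pct, sd_pct, n_assays, n_bio_reps,
    plus the two ratio summaries and a delta-method SD for comparison.
    """
    if pairing not in ("batch_mean", "per_assay"):
        raise ValueError("pairing must be 'batch_mean' or 'per_assay'")
    ratios = _assay_ratios(plate)
    out = []
    for strain, grp in ratios.groupby("strain", sort=True):
        stop = grp[grp["construct"] == STOP]
        sense = grp[grp["construct"] == SENSE]
        if stop.empty or sense.empty:
            raise AssayError(f"strain {strain}: need both stop and sense assays")
        sense_summary = RatioEstimate(
            mean=float(sense["ratio"].mean()),
            sd=float(sense["ratio"].std(ddof=1)) if len(sense) > 1 else 0.0,
            n=len(sense))
        stop_summary = RatioEstimate(
            mean=float(stop["ratio"].mean()),
            sd=float(stop["ratio"].std(ddof=1)) if len(stop) > 1 else 0.0,
            n=len(stop))
        if pairing == "batch_mean":
            per_assay = [readthrough_percent(r, sense_summary.mean)
                         for r in stop["ratio"]]
        else:
            sense_by_assay = sense.set_index("assay_id")["ratio"]
            per_assay = []
            for rec in stop.itertuples(index=False):
                if rec.assay_id not in sense_by_assay.index:
                    raise AssayError(
                        f"strain {strain}: no sense assay paired with {rec.assay_id}")
                per_assay.append(readthrough_percent(rec.ratio,
                                                     float(sense_by_assay[rec.assay_id])))
        n_bio = stop["bio_rep"].nunique()
        est = summarize_replicates(per_assay, strain=strain, n_bio_reps=n_bio)
        out.append({
            "strain": strain,
            "mean_pct": est.mean_pct, "sd_pct": est.sd_pct, "n_assays": est.n,
            "n_bio_reps": n_bio,
            "sense_ratio_mean": sense_summary.mean, "sense_ratio_sd": sense_summary.sd,
            "stop_ratio_mean": stop_summary.mean, "stop_ratio_sd": stop_summary.sd,
            "sd_pct_delta_method": ratio_sd_propagation(stop_summary, sense_summary),
        })
    return pd.DataFrame(out)
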