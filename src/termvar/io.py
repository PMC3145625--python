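"""Readers and writers for every format the pipeline touches.

Coordinate conventions: TSV files use 1-based inclusive positions (the
array-probe convention); BED output is 0-based half-open. Genotype panels
travel either as a strain x locus TSV matrix (cells BY/RM/NA) plus a locus
metadata TSV, or as a haploid VCF (GT 0 = BY, 1 = RM, . = missing; written
and read with pysam). Every writer's output round-trips through its
reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .ld import GenotypePanel
from .simulate import MarkerMap, PoolProfile

logger = logging.getLogger("termvar")

INTENSITY_COLUMNS = ("chrom", "pos", "intensity_BY", "intensity_RM")
LUMINESCENCE_COLUMNS = ("strain", "construct", "firefly_rlu", "renilla_rlu",
                        "firefly_bg", "renilla_bg", "assay_id", "bio_rep")


class FormatError(ValueError):
    """Raised for malformed input files; messages carry 1-based line numbers."""


# ---------------------------------------------------------------------------
# marker maps
# ---------------------------------------------------------------------------

def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    """TSV with columns (chrom, pos, id); positions 1-based inclusive."""
    mmap.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path, map_rate_cm_per_kb: float = 0.35,
                    chrom_lengths: np.ndarray | None = None) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    chrom = df["chrom"].to_numpy(dtype=np.int64)
    pos = df["pos"].to_numpy(dtype=np.int64)
    if chrom_lengths is None:
        lengths = np.zeros(chrom.max(), dtype=np.int64)
        for c in range(1, chrom.max() + 1):
            sel = pos[chrom == c]
            lengths[c - 1] = sel.max() if sel.size else 1
    else:
        lengths = np.asarray(chrom_lengths, dtype=np.int64)
    return MarkerMap(chrom=chrom, pos=pos,
                     ids=df["id"].to_numpy(dtype=object),
                     chrom_lengths=lengths,
                     map_rate_cm_per_kb=map_rate_cm_per_kb)


def marker_map_to_bed(mmap: MarkerMap, path: str | Path) -> None:
    """BED3+1: 0-based half-open single-base intervals (start = pos - 1)."""
    bed = pd.DataFrame({
        "chrom": mmap.chrom,
        "start": mmap.pos - 1,
        "end": mmap.pos,
        "name": mmap.ids,
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------

def write_intensity_table(profile: PoolProfile | pd.DataFrame,
                          path: str | Path) -> None:
    df = profile.to_frame() if isinstance(profile, PoolProfile) else profile
    df.to_csv(path, sep="\t", index=False,
              columns=list(INTENSITY_COLUMNS))


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Validated, (chrom, pos)-sorted intensity table.

    Rejects malformed or non-numeric rows (reporting the 1-based file line
    number), non-positive intensities, and duplicated (chrom, pos) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = {}
    for col, kind in (("chrom", np.int64), ("pos", np.int64),
                      ("intensity_BY", float), ("intensity_RM", float)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}:{line}: malformed value in column {col!r}")
        out[col] = vals.to_numpy(dtype=kind)
    for col in ("intensity_BY", "intensity_RM"):
        nonpos = out[col] <= 0
        if nonpos.any():
            line = int(np.flatnonzero(nonpos)[0]) + 2
            raise FormatError(f"{path}:{line}: non-positive {col}")
    dup = pd.DataFrame({"chrom": out["chrom"], "pos": out["pos"]}).duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise FormatError(f"{path}:{line}: duplicated (chrom, pos)")
    res = pd.DataFrame(out)
    return res.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    """Skew track TSV: (chrom, pos, delta, corrected[, smoothed])."""
    track.to_csv(path, sep="\t", index=False)


def peaks_to_bed(peaks_frame: pd.DataFrame, path: str | Path) -> None:
    """Peak intervals as BED (0-based half-open); score = smoothed skew."""
    if len(peaks_frame) == 0:
        Path(path).write_text("")
        return
    bed = pd.DataFrame({
        "chrom": peaks_frame["chrom"],
        "start": peaks_frame["start"] - 1,
        "end": peaks_frame["end"],
        "name": [f"peak{i}" for i in range(len(peaks_frame))],
        "score": peaks_frame["value"],
        "strand": np.where(peaks_frame["sign"] > 0, "+", "-"),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# luminescence plates
# ---------------------------------------------------------------------------

def read_luminescence_csv(path: str | Path) -> pd.DataFrame:
    """Plate-reading CSV with the canonical header; returns a typed frame."""
    df = pd.read_csv(path)
    missing = [c for c in LUMINESCENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("firefly_rlu", "renilla_rlu", "firefly_bg", "renilla_bg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise FormatError(f"{path}:{line}: malformed value in column {col!r}")
        df[col] = vals
    return df


# ---------------------------------------------------------------------------
# genotype panels: TSV matrix and haploid VCF
# ---------------------------------------------------------------------------

_ALLELE_TO_STR = {0: "BY", 1: "RM", -1: "NA"}
_STR_TO_ALLELE = {"BY": 0, "RM": 1, "NA": -1}


def write_panel_tsv(panel: GenotypePanel, matrix_path: str | Path,
                    loci_path: str | Path) -> None:
    """Strain x locus matrix (cells BY/RM/NA) plus locus metadata TSV."""
    cells = np.vectorize(_ALLELE_TO_STR.get)(panel.genotypes)
    mat = pd.DataFrame(cells, index=panel.strain_ids,
                       columns=panel.loci["id"].tolist())
    mat.index.name = "strain"
    mat.to_csv(matrix_path, sep="\t")
    panel.loci.to_csv(loci_path, sep="\t", index=False)


def read_panel_tsv(matrix_path: str | Path,
                   loci_path: str | Path) -> GenotypePanel:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    loci = pd.read_csv(loci_path, sep="\t")
    if list(mat.columns) != loci["id"].tolist():
        raise FormatError(f"{matrix_path}: locus columns disagree with {loci_path}")
    geno = np.empty(mat.shape, dtype=np.int8)
    raw = mat.to_numpy()
    for sym, code in _STR_TO_ALLELE.items():
        geno[raw == sym] = code
    unknown = ~np.isin(raw, list(_STR_TO_ALLELE))
    if unknown.any():
        i, j = map(int, np.argwhere(unknown)[0])
        raise FormatError(
            f"{matrix_path}: unknown allele symbol {raw[i, j]!r} "
            f"(strain {mat.index[i]}, locus {mat.columns[j]})")
    return GenotypePanel(genotypes=geno, strain_ids=list(mat.index), loci=loci)


def write_panel_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Haploid VCF: REF/ALT are placeholder bases, GT 0 = BY, 1 = RM."""
    header = pysam.VariantHeader()
    chrom_max = panel.loci.groupby("chrom")["pos"].max()
    for c, length in chrom_max.items():
        header.contigs.add(str(c), length=int(length) + 1)
    header.formats.add("GT", 1, "String", "Genotype (haploid; 0=BY allele, 1=RM allele)")
    for s in panel.strain_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, row in enumerate(panel.loci.itertuples(index=False)):
            rec = vf.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                                stop=int(row.pos), alleles=("A", "T"),
                                id=str(row.id))
            for i, s in enumerate(panel.strain_ids):
                g = int(panel.genotypes[i, j])
                rec.samples[s]["GT"] = (None,) if g == -1 else (g,)
            vf.write(rec)


def read_panel_vcf(path: str | Path) -> GenotypePanel:
    """Read a haploid biallelic VCF; diploid or multiallelic records error."""
    with pysam.VariantFile(str(path)) as vf:
        strain_ids = list(vf.header.samples)
        geno_cols, loci_rows = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic")
            col = np.empty(len(strain_ids), dtype=np.int8)
            for i, s in enumerate(strain_ids):
                gt = rec.samples[s]["GT"]
                if gt is None or len(gt) == 0 or (len(gt) == 1 and gt[0] is None):
                    col[i] = -1
                    continue
                if len(gt) != 1:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {s}: "
                        f"ploidy {len(gt)} != 1")
                col[i] = gt[0]
            geno_cols.append(col)
            loci_rows.append({"chrom": int(rec.chrom), "pos": int(rec.pos),
                              "id": rec.id or f"{rec.chrom}:{rec.pos}"})
    return GenotypePanel(genotypes=np.stack(geno_cols, axis=1),
                         strain_ids=strain_ids,
                         loci=pd.DataFrame(loci_rows))


# ---------------------------------------------------------------------------
# run configuration, seeds and manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative run parameters; defaults match the study design."""

    seed: int = 0
    window_bp: int = 40_000
    tail_fraction: float = 0.01
    cells_per_tail: int = 20_000
    n_pairs: int = 1000
    tolerance: float = 0.05
    noise_cv: float = 0.2
    measurement_noise_sd: float = 0.05
    trait_noise_sd: float = 0.05
    n_markers: int = 18_000
    n_segregants: int = 10_000
    n_strains: int = 63
    out_prefix: str = "termvar"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from (seed, stage)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: identical manifests imply bit-identical outputs."""

    package_version: str
    config_digest: str
    input_checksums: dict
    stage_seeds: dict
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def build_manifest(config: RunConfig, inputs: dict[str, str | Path],
                   stages: list[str]) -> RunManifest:
    from . import __version__
    return RunManifest(
        package_version=__version__,
        config_digest=config.digest(),
        input_checksums={k: file_sha256(v) for k, v in inputs.items()},
        stage_seeds={s: stage_seed(config.seed, s) for s in stages},
    )
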