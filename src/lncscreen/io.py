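"""Readers and writers for the tabular and interval formats the pipeline touches.

All genomic coordinates are 0-based half-open internally (BED convention).
GTF input (1-based inclusive) is converted at the boundary and nowhere else.
Tables are tab-separated with a header row; missing values are written "NA".
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

VALID_STATUS = ("normal", "bph", "primary", "metastasis")
VALID_BIOTYPES = ("lncRNA", "protein_coding", "pseudogene")

GENE_MODEL_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand", "biotype", "tss", "transcript_length",
]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A single gene: interval, strand, biotype, TSS and transcript length."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    transcript_length: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"end <= start for {self.gene_id}: [{self.start}, {self.end})")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return (self.transcript_length if self.transcript_length is not None
                else self.end - self.start)


@dataclasses.dataclass
class PeakSet:
    """ChIP-seq peaks for one TF; intervals sorted per chromosome, half-open."""

    tf_name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        df = self.intervals
        if list(df.columns[:3]) != ["chrom", "start", "end"]:
            df = df.iloc[:, :3].set_axis(["chrom", "start", "end"], axis=1)
        df = df.astype({"start": np.int64, "end": np.int64})
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(
                f"peak with end <= start for {self.tf_name}: "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}")
        if (df["start"] < 0).any():
            raise ValueError(f"negative peak coordinate for {self.tf_name}")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


def models_to_frame(models: list[GeneModel]) -> pd.DataFrame:
    """Tabulate gene models; the frame is the in-memory currency downstream."""
    rows = [
        (m.gene_id, m.chrom, m.start, m.end, m.strand, m.biotype, m.tss, m.length)
        for m in models
    ]
    df = pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in gene models: {dup!r}")
    return df


# ---------------------------------------------------------------------------
# count matrix


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    if np.isnan(arr.astype(float)).any():
        i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
        raise ValueError(f"missing count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}")
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}")
    return counts.astype(np.int64)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene IDs, header sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return validate_count_matrix(df)


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample table


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "patient_id", "cancer_status", "tissue_site"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    bad = set(samples["cancer_status"]) - set(VALID_STATUS)
    if bad:
        raise ValueError(f"unknown cancer_status values: {sorted(bad)}")
    prostate_only = samples["cancer_status"].isin(["bph", "primary"])
    if (samples.loc[prostate_only, "tissue_site"] != "prostate").any():
        raise ValueError("BPH and primary samples must have tissue_site == 'prostate'")
    return samples.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Read gene models from BED-like TSV (0-based half-open) or gene-level GTF.

    The BED variant is headerless with columns
    chrom, start, end, gene_id, score, strand, biotype[, transcript_length].
    GTF coordinates (1-based inclusive) are converted to half-open.
    """
    models: list[GeneModel] = []
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 7:
            raise ValueError("BED gene-model file needs >= 7 columns (incl. biotype)")
        for _, row in df.iterrows():
            length = int(row[7]) if df.shape[1] > 7 else None
            models.append(GeneModel(
                gene_id=str(row[3]), chrom=str(row[0]), start=int(row[1]), end=int(row[2]),
                strand=str(row[5]), biotype=str(row[6]), transcript_length=length))
    elif format == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValueError(f"malformed GTF line {lineno}")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attrs(fields[8])
                gene_id = attrs.get("gene_id")
                biotype = attrs.get("gene_biotype", attrs.get("gene_type"))
                if gene_id is None or biotype is None:
                    raise ValueError(f"GTF line {lineno}: missing gene_id/gene_biotype")
                length = attrs.get("transcript_length")
                models.append(GeneModel(
                    gene_id=gene_id, chrom=fields[0],
                    start=int(fields[3]) - 1, end=int(fields[4]),
                    strand=fields[6], biotype=biotype,
                    transcript_length=int(length) if length else None))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return models_to_frame(models)


def write_gene_models_bed(models: pd.DataFrame, path: str | Path) -> None:
    out = models[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out = pd.concat([out, models[["strand", "biotype", "transcript_length"]]], axis=1)
    out.to_csv(path, sep="\t", index=False, header=False)


def write_gene_models_gtf(models: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, m in models.iterrows():
            attrs = (f'gene_id "{m.gene_id}"; gene_biotype "{m.biotype}"; '
                     f'transcript_length "{int(m.transcript_length)}";')
            fh.write("\t".join([
                m.chrom, "lncscreen", "gene", str(int(m.start) + 1), str(int(m.end)),
                ".", m.strand, ".", attrs]) + "\n")


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, tf_name: str) -> PeakSet:
    """Read a >=3-column BED of peaks for one TF."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno} (need >= 3 columns)")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(tf_name=tf_name, intervals=df)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    peaks.intervals.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# survival / clinical table


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns or "event" not in df.columns:
        raise ValueError("clinical table needs 'time' and 'event' columns")
    if (df["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (progression)")
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
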