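"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate conventions: everything is 0-based half-open internally. BED
is already 0-based half-open and passes through unchanged; SEG-like
tables are 1-based inclusive on disk and converted on read/write.
Malformed lines are reported with their line number.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .cna import CNACall, Segment
from .intervals import Interval

SEG_COLUMNS = ["sample", "chrom", "start", "end", "mean_log2", "n_markers"]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> dict[str, list[Interval]]:
    """Read a BED file into {chrom: [(start, end), ...]} (0-based half-open)."""
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}:{i}: non-integer coordinates") from e
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{i}: invalid interval [{start}, {end})")
            out.setdefault(parts[0], []).append((start, end))
    return out


def write_bed(path, intervals: Mapping[str, Iterable[tuple]], scores: bool = False) -> None:
    """Write {chrom: intervals} as BED; each interval may carry extra
    columns (name, score) after (start, end)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for iv in sorted(intervals[chrom]):
                fh.write("\t".join([chrom] + [str(x) for x in iv]) + "\n")


# ---------------------------------------------------------------------------
# SEG-like TSV

def write_seg(path, calls_per_sample: Mapping[str, Iterable[CNACall]]) -> None:
    """Write CNA calls as a SEG-like TSV (1-based inclusive on disk)."""
    rows = []
    for sample, calls in calls_per_sample.items():
        for c in calls:
            s = c.segment
            rows.append(
                {
                    "sample": sample,
                    "chrom": s.chrom,
                    "start": s.start + 1,   # to 1-based inclusive
                    "end": s.end,
                    "mean_log2": s.mean_log2,
                    "n_markers": s.n_markers,
                }
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> dict[str, list[Segment]]:
    """Read a SEG-like TSV back into per-sample Segment lists (0-based
    half-open internally)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[Segment]] = {}
    for i, row in df.iterrows():
        start = int(row["start"]) - 1
        end = int(row["end"])
        if start < 0 or start >= end:
            raise FormatError(f"{path}: line {i + 2}: invalid segment coordinates")
        out.setdefault(str(row["sample"]), []).append(
            Segment(
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                mean_log2=float(row["mean_log2"]),
                n_markers=int(row["n_markers"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# matrices and annotation

def write_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate row ids, e.g. {dupes}")
    return df


def read_probe_matrix(path) -> pd.DataFrame:
    """Probe table with chrom/pos columns followed by per-sample values."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: negative probe positions")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene, chrom, strand, tss, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "strand", "tss", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: gene start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, patient_id, timepoint, batch."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id", "timepoint", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if not df["timepoint"].isin(["diagnosis", "relapse"]).all():
        raise FormatError(f"{path}: timepoint must be diagnosis/relapse")
    if df.duplicated(subset=["patient_id", "timepoint"]).any():
        raise FormatError(f"{path}: duplicate (patient_id, timepoint)")
    return df


def pairing_from_sheet(sheet: pd.DataFrame) -> dict[str, str]:
    """diagnosis sample id -> relapse sample id, for complete pairs only."""
    wide = sheet.pivot(index="patient_id", columns="timepoint", values="sample_id")
    wide = wide.dropna(subset=["diagnosis", "relapse"])
    return dict(zip(wide["diagnosis"], wide["relapse"]))
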