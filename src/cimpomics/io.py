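"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED/narrowPeak/BEDPE are 0-based, half-open on disk and in memory. FASTA goes
through Biopython; JASPAR position-frequency matrices through Bio.motifs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import GenomicInterval

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


# -- BED ---------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


# -- narrowPeak --------------------------------------------------------------

def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    """``peaks`` needs columns chrom/start/end/name/qValue (others optional)."""
    df = peaks.copy()
    for col, default in [
        ("score", 0), ("strand", "."), ("signalValue", 0.0),
        ("pValue", -1.0), ("peak", -1),
    ]:
        if col not in df:
            df[col] = default
    df[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS)
    return df


# -- BEDPE -------------------------------------------------------------------

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]


def write_bedpe(loops: pd.DataFrame, path: str | Path) -> None:
    df = loops.copy()
    if "score" not in df:
        df["score"] = 0.0
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS)


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- JASPAR PFMs -------------------------------------------------------------

def write_jaspar_pfms(pfms: Sequence[motifs.Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(motifs.write(pfms, "jaspar"))


def read_jaspar_pfms(path: str | Path) -> list[motifs.Motif]:
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


# -- matrices & manifest -----------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="feature")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(entries: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"files": entries}, fh, indent=2, sort_keys=True)
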