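"""Readers and writers for the standard text formats the pipeline speaks.

Formats: FASTA (genome), GFF3 1-based inclusive (annotation), cytosine-report
TSV (per-cytosine counts, the dialect defined below), read-calls TSV
(simulator dialect), BED 0-based half-open and bedGraph.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pyfaidx

from .annotation import GeneAnnotation
from .calling import CytosineTable, ReadSet
from .contexts import CONTEXTS

_REPORT_COLS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


# -- FASTA ------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# -- GFF3 ---------------------------------------------------------------------

_GFF_TYPES = {"gene": "gene", "TE": "transposable_element"}
_GFF_KINDS = {v: k for k, v in _GFF_TYPES.items()}


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> Path:
    """GFF3 with 1-based inclusive coordinates, exons carrying Parent tags."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, f in annotation.features.iterrows():
            fh.write(
                "\t".join(
                    [
                        f["chrom"],
                        "hcgkit",
                        _GFF_TYPES[f["kind"]],
                        str(int(f["start"]) + 1),
                        str(int(f["end"])),
                        ".",
                        f["strand"],
                        ".",
                        f"ID={f['id']}",
                    ]
                )
                + "\n"
            )
            if f["kind"] != "gene":
                continue
            exons = annotation.exons_of(f["id"]).sort_values("start")
            for j, (_, ex) in enumerate(exons.iterrows()):
                fh.write(
                    "\t".join(
                        [
                            f["chrom"],
                            "hcgkit",
                            "exon",
                            str(int(ex["start"]) + 1),
                            str(int(ex["end"])),
                            ".",
                            f["strand"],
                            ".",
                            f"ID={f['id']}.exon{j + 1};Parent={f['id']}",
                        ]
                    )
                    + "\n"
                )
    return path


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        k, _, v = part.partition("=")
        if k == key:
            return v
    return None


def read_gff3(path: str | Path) -> GeneAnnotation:
    feats, exons = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            start0, end0 = int(start) - 1, int(end)
            if ftype == "exon":
                exons.append(
                    dict(parent=_gff_attr(attrs, "Parent"), chrom=chrom, start=start0, end=end0)
                )
            elif ftype in _GFF_KINDS:
                feats.append(
                    dict(
                        id=_gff_attr(attrs, "ID"),
                        chrom=chrom,
                        strand=strand,
                        start=start0,
                        end=end0,
                        kind=_GFF_KINDS[ftype],
                    )
                )
    return GeneAnnotation(
        pd.DataFrame(feats, columns=["id", "chrom", "strand", "start", "end", "kind"]),
        pd.DataFrame(exons, columns=["parent", "chrom", "start", "end"]),
    )


# -- cytosine report ----------------------------------------------------------


def write_cytosine_report(
    table: CytosineTable, path: str | Path, trinucleotides: pd.Series | None = None
) -> Path:
    """Tab-separated per-cytosine report with a header line.

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context, trinucleotide ('.' when unknown).
    """
    path = Path(path)
    df = table.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "count_methylated": df["meth"],
            "count_unmethylated": df["total"] - df["meth"],
            "context": df["context"],
            "trinucleotide": trinucleotides if trinucleotides is not None else ".",
        }
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def read_cytosine_report(path: str | Path) -> CytosineTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "count_methylated": np.int64,
            "count_unmethylated": np.int64,
            "context": str,
        },
    )
    missing = [c for c in _REPORT_COLS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"cytosine report missing columns {missing}")
    return CytosineTable(
        pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"],
                "strand": df["strand"],
                "context": df["context"],
                "meth": df["count_methylated"],
                "total": df["count_methylated"] + df["count_unmethylated"],
            }
        )
    )


# -- read calls ---------------------------------------------------------------


def write_read_calls(reads: ReadSet, path: str | Path) -> Path:
    """Simulator read-calls dialect: one read per row, calls packed as
    comma-separated ``pos:context:M|U`` triples."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tstrand\tcalls\n")
        for i in range(len(reads)):
            lo, hi = reads.indptr[i], reads.indptr[i + 1]
            calls = ",".join(
                f"{reads.pos[j]}:{CONTEXTS[reads.context[j]]}:{'M' if reads.meth[j] else 'U'}"
                for j in range(lo, hi)
            )
            start = int(reads.pos[lo]) if hi > lo else 0
            fh.write(
                f"{reads.read_id(i)}\t{reads.chroms[reads.read_chrom[i]]}\t{start}\t{reads.read_strand[i]}\t{calls}\n"
            )
    return path


def read_read_calls(path: str | Path) -> ReadSet:
    from .calling import ReadMethCalls

    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "chrom", "start", "strand"]:
            raise ValueError("not a read-calls TSV")
        for line in fh:
            rid, chrom, start, strand, calls = line.rstrip("\n").split("\t")
            parsed = []
            if calls:
                for item in calls.split(","):
                    pos, ctx, m = item.split(":")
                    parsed.append((int(pos), ctx, m == "M"))
            reads.append(ReadMethCalls(rid, chrom, int(start), strand, parsed))
    return ReadSet.from_reads(reads)


# -- BED / bedGraph -----------------------------------------------------------


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    """BED (0-based half-open): requires chrom/start/end, keeps extra columns."""
    path = Path(path)
    cols = ["chrom", "start", "end"] + [
        c for c in df.columns if c not in ("chrom", "start", "end")
    ]
    df[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        comment="#",
    )
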