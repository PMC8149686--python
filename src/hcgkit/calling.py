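"""Read-level methylation calls to filtered per-cytosine/-region levels.

The whole-genome bisulfite workflow represented here starts from per-read
methylation calls (one aligned read = an ordered list of cytosine calls),
removes reads that look like bisulfite-conversion failures (a run of more
than three consecutive methylated CHH calls), and accumulates the surviving
calls into a per-cytosine table where the methylation level of a site is
#C / (#C + #T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .contexts import CONTEXTS

_CTX_CODE = {c: i for i, c in enumerate(CONTEXTS)}


@dataclass
class ReadMethCalls:
    """One read's ordered per-cytosine methylation calls.

    ``calls`` is a list of (position 1-based, context, methylated) with
    strictly increasing positions.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    calls: list[tuple[int, str, bool]]

    def __post_init__(self) -> None:
        pos = [p for p, _, _ in self.calls]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"read {self.read_id}: call positions not strictly increasing")
        for _, ctx, _ in self.calls:
            if ctx not in _CTX_CODE:
                raise ValueError(f"read {self.read_id}: unknown context {ctx!r}")


class ReadSet:
    """Column-oriented collection of reads (flat call arrays + offsets).

    Equivalent to a list of :class:`ReadMethCalls` but holds the calls of all
    reads in flat numpy arrays so that whole-collection operations (the
    conversion filter, per-cytosine aggregation) are vectorised.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        read_chrom: np.ndarray,
        read_strand: np.ndarray,
        indptr: np.ndarray,
        pos: np.ndarray,
        context: np.ndarray,
        meth: np.ndarray,
        read_ids: Sequence[str] | None = None,
    ) -> None:
        self.chroms = list(chroms)
        self.read_chrom = np.asarray(read_chrom, dtype=np.int32)
        self.read_strand = np.asarray(read_strand)  # '+'/'-' per read
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.context = np.asarray(context, dtype=np.uint8)
        self.meth = np.asarray(meth, dtype=bool)
        self.read_ids = list(read_ids) if read_ids is not None else None
        if self.indptr[0] != 0 or self.indptr[-1] != self.pos.size:
            raise ValueError("inconsistent call offsets")
        widths = np.diff(self.indptr)
        if (widths < 0).any():
            raise ValueError("negative read width")
        # positions strictly increasing within each read
        if self.pos.size > 1:
            inc = np.diff(self.pos) > 0
            starts = self.indptr[1:-1]
            starts = starts[(starts > 0) & (starts < self.pos.size)]
            inc[starts - 1] = True  # read boundaries exempt
            if not inc.all():
                raise ValueError("call positions not strictly increasing within a read")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_reads(cls, reads: Iterable[ReadMethCalls]) -> "ReadSet":
        reads = list(reads)
        chroms: list[str] = []
        cmap: dict[str, int] = {}
        read_chrom = np.empty(len(reads), np.int32)
        read_strand = np.empty(len(reads), dtype="U1")
        indptr = np.zeros(len(reads) + 1, np.int64)
        pos_parts, ctx_parts, m_parts, ids = [], [], [], []
        for i, r in enumerate(reads):
            if r.chrom not in cmap:
                cmap[r.chrom] = len(chroms)
                chroms.append(r.chrom)
            read_chrom[i] = cmap[r.chrom]
            read_strand[i] = r.strand
            indptr[i + 1] = indptr[i] + len(r.calls)
            pos_parts.extend(p for p, _, _ in r.calls)
            ctx_parts.extend(_CTX_CODE[c] for _, c, _ in r.calls)
            m_parts.extend(m for _, _, m in r.calls)
            ids.append(r.read_id)
        return cls(
            chroms,
            read_chrom,
            read_strand,
            indptr,
            np.asarray(pos_parts, np.int64),
            np.asarray(ctx_parts, np.uint8),
            np.asarray(m_parts, bool),
            read_ids=ids,
        )

    def __len__(self) -> int:
        return self.indptr.size - 1

    @property
    def n_calls(self) -> int:
        return self.pos.size

    def read_id(self, i: int) -> str:
        return self.read_ids[i] if self.read_ids is not None else f"r{i}"

    def __iter__(self) -> Iterator[ReadMethCalls]:
        for i in range(len(self)):
            lo, hi = self.indptr[i], self.indptr[i + 1]
            yield ReadMethCalls(
                self.read_id(i),
                self.chroms[self.read_chrom[i]],
                int(self.pos[lo]) if hi > lo else 0,
                str(self.read_strand[i]),
                [
                    (int(self.pos[j]), CONTEXTS[self.context[j]], bool(self.meth[j]))
                    for j in range(lo, hi)
                ],
            )

    def subset(self, keep: np.ndarray) -> "ReadSet":
        """New ReadSet with the reads where ``keep`` is True."""
        keep = np.asarray(keep, bool)
        widths = np.diff(self.indptr)
        call_keep = np.repeat(keep, widths)
        new_indptr = np.concatenate([[0], np.cumsum(widths[keep])])
        ids = (
            [rid for rid, k in zip(self.read_ids, keep) if k]
            if self.read_ids is not None
            else None
        )
        return ReadSet(
            self.chroms,
            self.read_chrom[keep],
            self.read_strand[keep],
            new_indptr,
            self.pos[call_keep],
            self.context[call_keep],
            self.meth[call_keep],
            read_ids=ids,
        )

    def call_read_index(self) -> np.ndarray:
        """Read index of every flat call."""
        return np.repeat(np.arange(len(self)), np.diff(self.indptr))


def _as_readset(reads: "ReadSet | Iterable[ReadMethCalls]") -> ReadSet:
    return reads if isinstance(reads, ReadSet) else ReadSet.from_reads(reads)


def max_mchh_run(reads: "ReadSet | Iterable[ReadMethCalls]", span_other_contexts: bool = True) -> np.ndarray:
    """Longest run of consecutive methylated CHH calls per read.

    With ``span_other_contexts`` (default) the run is counted along the
    read's subsequence of CHH calls, so intervening CG/CHG calls do not break
    it — conversion failure affects the whole read, and this is the signature
    the filter targets.  With ``span_other_contexts=False`` any intervening
    non-CHH call resets the run.
    """
    rs = _as_readset(reads)
    n = len(rs)
    if rs.n_calls == 0:
        return np.zeros(n, np.int64)
    ridx = rs.call_read_index()
    chh = rs.context == _CTX_CODE["CHH"]
    rows = np.flatnonzero(chh)
    if rows.size == 0:
        return np.zeros(n, np.int64)
    m = rs.meth[rows]
    rr = ridx[rows]
    idx = np.arange(rows.size)
    new_read = np.empty(rows.size, bool)
    new_read[0] = True
    new_read[1:] = rr[1:] != rr[:-1]
    broken = new_read.copy()
    if not span_other_contexts:
        gap = np.empty(rows.size, bool)
        gap[0] = True
        gap[1:] = np.diff(rows) != 1
        broken |= gap
    # anchor[i] = last index before the run containing i (idx where m==0, or
    # idx-1 where a new segment starts); run length = idx - max anchor so far
    anchor = np.where(~m, idx, np.where(broken, idx - 1, -1))
    run = idx - np.maximum.accumulate(anchor)
    run[~m] = 0
    out = np.zeros(n, np.int64)
    np.maximum.at(out, rr, run)
    return out


def filter_nonconverted_reads(
    reads: "ReadSet | Iterable[ReadMethCalls]",
    max_run: int = 3,
    span_other_contexts: bool = True,
):
    """Drop reads with a run of more than ``max_run`` consecutive methylated
    CHH calls (the canonical signature of bisulfite-conversion failure).

    Returns ``(surviving ReadSet, number removed)``.  A read with a run of
    exactly ``max_run`` survives: the threshold is strictly "more than".
    """
    rs = _as_readset(reads)
    runs = max_mchh_run(rs, span_other_contexts=span_other_contexts)
    keep = runs <= max_run
    return rs.subset(keep), int((~keep).sum())


# ---------------------------------------------------------------------------
# per-cytosine table
# ---------------------------------------------------------------------------

_TABLE_COLS = ["chrom", "pos", "strand", "context", "meth", "total"]


class CytosineTable:
    """Per-cytosine methylated/total read counts; the atom of all levels.

    ``df`` columns: chrom, pos (1-based), strand, context, meth (#C),
    total (#C + #T).  ``level`` is derived as meth/total and is undefined
    (absent row) for uncovered sites.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in _TABLE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"cytosine table missing columns {missing}")
        df = df[_TABLE_COLS].copy()
        if (df["meth"] > df["total"]).any() or (df["meth"] < 0).any():
            raise ValueError("methylated count outside [0, total]")
        df = df.sort_values(["chrom", "pos", "strand"], ignore_index=True, kind="stable")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def levels(self) -> pd.Series:
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.df["meth"] / self.df["total"]
        return lv.where(self.df["total"] > 0)

    def by_context(self, context: str) -> pd.DataFrame:
        return self.df[self.df["context"] == context]

    def covered(self, min_coverage: int) -> "CytosineTable":
        return CytosineTable(self.df[self.df["total"] >= min_coverage])


def aggregate_cytosines(
    reads: "ReadSet | Iterable[ReadMethCalls]", context_map: pd.DataFrame
) -> CytosineTable:
    """Accumulate filtered read calls into per-(chrom, pos, strand) counts.

    ``context_map`` is a genome-derived table with chrom/pos/strand/context
    (see :func:`hcgkit.contexts.cytosine_contexts`); a call at a position with
    no cytosine in the map is an error, named by position.
    """
    rs = _as_readset(reads)
    ridx = rs.call_read_index()
    calls = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(
                rs.read_chrom[ridx], categories=rs.chroms
            ),
            "pos": rs.pos,
            "strand": np.asarray(rs.read_strand)[ridx],
            "meth": rs.meth.astype(np.int64),
        }
    )
    agg = (
        calls.groupby(["chrom", "pos", "strand"], observed=True, sort=False)
        .agg(meth=("meth", "sum"), total=("meth", "size"))
        .reset_index()
    )
    agg["chrom"] = agg["chrom"].astype(str)
    cmap = context_map[["chrom", "pos", "strand", "context"]]
    merged = agg.merge(cmap, on=["chrom", "pos", "strand"], how="left")
    orphan = merged["context"].isna()
    if orphan.any():
        row = merged[orphan].iloc[0]
        raise KeyError(
            f"no cytosine in context map at {row['chrom']}:{row['pos']}({row['strand']})"
        )
    return CytosineTable(merged)


@dataclass
class RegionMethylation:
    """Per-cytosine levels plus the count-pooled level over one region."""

    per_cytosine: pd.DataFrame  # chrom,pos,strand,context,meth,total,level
    pooled: float | None  # None when no cytosine survives the coverage rule
    pooled_unweighted: float | None = None
    n_cytosines: int = 0


def region_methylation(
    table: CytosineTable,
    chrom: str,
    start: int,
    end: int,
    context: str,
    min_coverage: int = 4,
) -> RegionMethylation:
    """Methylation of one half-open region in one context.

    With ``min_coverage=20`` this reproduces the targeted-amplicon rule that
    cytosines under 20 reads are excluded.  The pooled level is count-weighted
    (sum #C / sum total); the unweighted mean of per-cytosine levels is also
    reported.  A region with no surviving cytosine is a defined "no data"
    result, not an exception.
    """
    df = table.df
    sel = (
        (df["chrom"] == chrom)
        & (df["pos"] >= start + 1)
        & (df["pos"] <= end)
        & (df["context"] == context)
        & (df["total"] >= min_coverage)
    )
    sub = df[sel].copy()
    if sub.empty:
        return RegionMethylation(sub.assign(level=np.nan), None, None, 0)
    sub["level"] = sub["meth"] / sub["total"]
    pooled = float(sub["meth"].sum() / sub["total"].sum())
    return RegionMethylation(sub, pooled, float(sub["level"].mean()), len(sub))


@dataclass
class GenomeDifference:
    """Mean per-cytosine level difference (A − B) over shared covered sites."""

    context: str
    mean: float
    per_chromosome: pd.Series
    n_sites: int


def genome_wide_difference(
    table_a: CytosineTable,
    table_b: CytosineTable,
    context: str,
    min_coverage: int = 4,
) -> GenomeDifference:
    """Genome-wide mean methylation difference in one context.

    Computed over cytosines of the given context covered at
    ``min_coverage`` or more in both samples; errors when no site is shared.
    """
    a = table_a.by_context(context)
    b = table_b.by_context(context)
    a = a[a["total"] >= min_coverage]
    b = b[b["total"] >= min_coverage]
    merged = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise ValueError(f"no shared covered {context} cytosines between samples")
    diff = merged["meth_a"] / merged["total_a"] - merged["meth_b"] / merged["total_b"]
    per_chrom = diff.groupby(merged["chrom"]).mean()
    return GenomeDifference(context, float(diff.mean()), per_chrom, len(merged))
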