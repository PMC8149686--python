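"""200-bp bin methylome, rank percentiles and the four-cluster assignment.

The genome is tiled with fixed-width bins from position 0.  Per bin and
context the table pools methylated/total read counts over cytosines covered
at the per-cytosine minimum (default 4 reads) and tallies how many cytosines
contributed.  Bins are ranked by the reference sample's CG level in
DESCENDING order — percentile 1 holds the most-methylated (heterochromatic)
bins — and split into four clusters at configurable percentile boundaries
(defaults 13/25/43, i.e. clusters 1–13, 14–25, 26–43 and 44–100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CytosineTable
from .contexts import CONTEXTS, chromosome_cytosines

BinId = tuple[str, int]

_BIN_COLS = ["chrom", "start", "context", "meth", "total", "n_cyt"]


@dataclass
class BinMethylome:
    """Per-bin pooled counts for one sample on a fixed grid.

    ``df`` columns: chrom, start (0-based, half-open, width ``bin_size``),
    context, meth, total, n_cyt.  Every grid bin is present (possibly with
    zero counts), so grids are directly comparable across samples.
    """

    sample_id: str
    bin_size: int
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df[_BIN_COLS].sort_values(
            ["chrom", "start", "context"], ignore_index=True, kind="stable"
        )

    def context_df(self, context: str, indexed: bool = True) -> pd.DataFrame:
        sub = self.df[self.df["context"] == context].copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            sub["level"] = (sub["meth"] / sub["total"]).where(sub["total"] > 0)
        if indexed:
            sub = sub.set_index(["chrom", "start"])
        return sub

    def grid(self) -> pd.MultiIndex:
        cg = self.df[self.df["context"] == "CG"]
        return pd.MultiIndex.from_frame(cg[["chrom", "start"]])


def bin_methylome(
    table: CytosineTable,
    chrom_lengths: Mapping[str, int],
    sample_id: str = "sample",
    bin_size: int = 200,
    min_coverage: int = 4,
) -> BinMethylome:
    """Pool per-cytosine counts into fixed grid bins.

    Only cytosines covered at least ``min_coverage`` times contribute, in
    line with the per-cytosine coverage rule of the differential test.  A
    cytosine beyond the stated chromosome end is an error.
    """
    df = table.df
    unknown = set(df["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"chromosome(s) {sorted(unknown)} not in chrom_lengths")
    lengths = df["chrom"].map(chrom_lengths)
    over = df["pos"] > lengths
    if over.any():
        row = df[over].iloc[0]
        raise ValueError(
            f"cytosine {row['chrom']}:{row['pos']} beyond chromosome end"
        )

    used = df[df["total"] >= min_coverage]
    binned = pd.DataFrame(
        {
            "chrom": used["chrom"].to_numpy(),
            "start": ((used["pos"].to_numpy() - 1) // bin_size) * bin_size,
            "context": used["context"].to_numpy(),
            "meth": used["meth"].to_numpy(),
            "total": used["total"].to_numpy(),
        }
    )
    agg = (
        binned.groupby(["chrom", "start", "context"], sort=False)
        .agg(meth=("meth", "sum"), total=("total", "sum"), n_cyt=("total", "size"))
        .reset_index()
    )

    # full grid, empty bins kept with zero counts
    grids = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, bin_size)
        grids.append(
            pd.DataFrame(
                {
                    "chrom": np.repeat(chrom, starts.size * len(CONTEXTS)),
                    "start": np.repeat(starts, len(CONTEXTS)),
                    "context": np.tile(np.array(CONTEXTS), starts.size),
                }
            )
        )
    grid = pd.concat(grids, ignore_index=True)
    full = grid.merge(agg, on=["chrom", "start", "context"], how="left").fillna(0)
    for col in ("meth", "total", "n_cyt"):
        full[col] = full[col].astype(np.int64)
    return BinMethylome(sample_id, bin_size, full)


def _check_shared_grid(bin_methylomes: Sequence[BinMethylome]) -> pd.MultiIndex:
    grids = [bm.grid() for bm in bin_methylomes]
    first = grids[0]
    for g in grids[1:]:
        if not first.equals(g):
            raise ValueError("bin methylomes are not on the same grid")
    return first


def filter_unmethylated_bins(bin_methylomes: Sequence[BinMethylome]) -> pd.MultiIndex:
    """Bins with CG methylation in at least one genotype.

    A bin is retained iff any sample shows a CG level above zero; the
    returned (chrom, start) index is the universe used for ranking.
    """
    if not bin_methylomes:
        raise ValueError("need at least one bin methylome")
    grid = _check_shared_grid(bin_methylomes)
    any_meth = np.zeros(len(grid), bool)
    for bm in bin_methylomes:
        cg = bm.context_df("CG")
        any_meth |= ((cg["meth"] > 0) & (cg["total"] > 0)).to_numpy()
    return grid[any_meth]


def rank_percentiles(
    reference: BinMethylome,
    retained: pd.MultiIndex,
    n_percentiles: int = 100,
) -> pd.Series:
    """Percentile (1..n) of every retained bin by reference CG level.

    Bins are sorted in DESCENDING level order (percentile 1 = most
    methylated) and split into ``n_percentiles`` contiguous groups whose
    sizes differ by at most one bin; ties and uncovered reference bins
    (treated as level 0) break deterministically by (chrom, start).
    """
    if len(retained) < n_percentiles:
        raise ValueError(
            f"only {len(retained)} retained bins; use a smaller percentile count "
            f"(n_percentiles <= {len(retained)})"
        )
    cg = reference.context_df("CG")
    levels = cg["level"].reindex(retained).fillna(0.0)
    order = (
        pd.DataFrame({"level": levels})
        .reset_index()
        .sort_values(["level", "chrom", "start"], ascending=[False, True, True], kind="stable")
    )
    n = len(order)
    base, rem = divmod(n, n_percentiles)
    sizes = np.full(n_percentiles, base)
    sizes[:rem] += 1
    pct = np.repeat(np.arange(1, n_percentiles + 1), sizes)
    out = pd.Series(
        pct, index=pd.MultiIndex.from_frame(order[["chrom", "start"]]), name="percentile"
    )
    return out.sort_index()


@dataclass
class ClusterAssignment:
    """Percentile and cluster label per retained bin.

    Clusters partition the retained bins: with boundaries (b1, b2, b3) the
    labels are 1 for percentiles 1..b1, 2 for b1+1..b2, 3 for b2+1..b3 and
    4 for the rest.
    """

    df: pd.DataFrame  # index (chrom, start); columns percentile, cluster
    boundaries: tuple[int, int, int]

    def cluster_of(self, bin_id: BinId) -> int:
        return int(self.df.loc[bin_id, "cluster"])

    def bins_in_cluster(self, cluster: int) -> pd.MultiIndex:
        return self.df.index[self.df["cluster"] == cluster]

    def sizes(self) -> pd.Series:
        return self.df["cluster"].value_counts().sort_index()


def assign_clusters(
    percentiles: pd.Series, boundaries: tuple[int, int, int] = (13, 25, 43)
) -> ClusterAssignment:
    """Map percentiles to the four clusters at the given boundaries."""
    b1, b2, b3 = boundaries
    if not 0 < b1 < b2 < b3:
        raise ValueError(f"cluster boundaries must increase: {boundaries}")
    p = percentiles.to_numpy()
    cluster = np.select([p <= b1, p <= b2, p <= b3], [1, 2, 3], default=4)
    df = pd.DataFrame(
        {"percentile": p, "cluster": cluster}, index=percentiles.index
    )
    return ClusterAssignment(df, boundaries)


def sequence_composition(
    regions: pd.DataFrame, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Per-region (C+G) fraction and CG/CHG/CHH cytosine densities.

    Densities count context cytosines on both strands inside the region,
    per bp of region length (contexts may extend into flanking sequence).
    Empty regions are an error.
    """
    if ((regions["end"] - regions["start"]) <= 0).any():
        raise ValueError("empty region in sequence_composition")
    ctx_cache: dict[str, pd.DataFrame] = {}
    rows = []
    for _, r in regions.iterrows():
        chrom, start, end = r["chrom"], int(r["start"]), int(r["end"])
        seq = genome[chrom][start:end]
        gc = (seq.count("C") + seq.count("G")) / len(seq)
        if chrom not in ctx_cache:
            ctx_cache[chrom] = chromosome_cytosines(chrom, genome[chrom])
        ctab = ctx_cache[chrom]
        sub = ctab[(ctab["pos"] >= start + 1) & (ctab["pos"] <= end)]
        counts = sub["context"].value_counts()
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "gc_fraction": gc,
                "cg_density": counts.get("CG", 0) / len(seq),
                "chg_density": counts.get("CHG", 0) / len(seq),
                "chh_density": counts.get("CHH", 0) / len(seq),
            }
        )
    return pd.DataFrame(rows)
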