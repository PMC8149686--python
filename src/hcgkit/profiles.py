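"""Scaled metaplots over regions and between-genotype signal comparisons.

A metaplot averages a per-base signal over a set of stranded regions after
rescaling each region body to a fixed number of relative-coordinate bins,
with absolute-bp flanks on either side; minus-strand regions are reversed so
the profile always reads 5'→3'.  The group comparison computes a per-region
mean over the full region or its 3' half and applies an unpaired Welch
two-sample t-test between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CytosineTable


class SignalTrack:
    """Dense per-base signal on each chromosome; NaN marks "no data"."""

    def __init__(self, values: Mapping[str, np.ndarray]):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for chrom, v in self.values.items():
            if not np.isfinite(v[~np.isnan(v)]).all():
                raise ValueError(f"non-finite signal values on {chrom}")

    @classmethod
    def constant(cls, chrom_lengths: Mapping[str, int], value: float) -> "SignalTrack":
        return cls({c: np.full(L, value) for c, L in chrom_lengths.items()})

    @classmethod
    def from_bedgraph(
        cls, df: pd.DataFrame, chrom_lengths: Mapping[str, int]
    ) -> "SignalTrack":
        vals = {c: np.full(L, np.nan) for c, L in chrom_lengths.items()}
        for _, r in df.iterrows():
            vals[r["chrom"]][int(r["start"]) : int(r["end"])] = r["value"]
        return cls(vals)

    @classmethod
    def from_cytosine_table(
        cls,
        table: CytosineTable,
        context: str,
        chrom_lengths: Mapping[str, int],
        min_coverage: int = 4,
    ) -> "SignalTrack":
        """Per-cytosine methylation levels as a sparse-in-NaN dense track."""
        vals = {c: np.full(L, np.nan) for c, L in chrom_lengths.items()}
        sub = table.by_context(context)
        sub = sub[sub["total"] >= min_coverage]
        for chrom, grp in sub.groupby("chrom", sort=False, observed=True):
            if chrom not in vals:
                raise KeyError(f"chromosome {chrom!r} not in chrom_lengths")
            vals[str(chrom)][grp["pos"].to_numpy() - 1] = (
                grp["meth"].to_numpy() / grp["total"].to_numpy()
            )
        return cls(vals)

    def segment(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end), NaN-padded beyond chromosome bounds."""
        v = self.values[chrom]
        out = np.full(end - start, np.nan)
        lo, hi = max(start, 0), min(end, v.size)
        if hi > lo:
            out[lo - start : hi - start] = v[lo:hi]
        return out


@dataclass
class MetaProfile:
    """Mean ± SE of a signal over regions, on flank/body/flank bins."""

    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray  # regions contributing per bin
    n_flank_bins: int
    n_body_bins: int
    n_regions: int

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def to_frame(self) -> pd.DataFrame:
        labels = (
            [f"up{i + 1}" for i in range(self.n_flank_bins)]
            + [f"body{i + 1}" for i in range(self.n_body_bins)]
            + [f"down{i + 1}" for i in range(self.n_flank_bins)]
        )
        return pd.DataFrame(
            {"bin": labels, "mean": self.mean, "se": self.se, "n": self.n}
        )


def _nan_slice_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` split into ``n_bins`` near-equal contiguous slices."""
    edges = np.linspace(0, values.size, n_bins + 1).round().astype(int)
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        seg = values[edges[i] : edges[i + 1]]
        if seg.size and not np.isnan(seg).all():
            out[i] = np.nanmean(seg)
    return out


def region_profile(
    track: SignalTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    n_body_bins: int,
    flank_bp: int,
    n_flank_bins: int,
) -> np.ndarray | None:
    """One region's profile row (upstream flank, scaled body, downstream).

    Returns None when the region is shorter than the number of body bins
    (no meaningful rescaling exists).
    """
    if end - start < n_body_bins:
        return None
    body = _nan_slice_means(track.segment(chrom, start, end), n_body_bins)
    if flank_bp > 0 and n_flank_bins > 0:
        left = _nan_slice_means(track.segment(chrom, start - flank_bp, start), n_flank_bins)
        right = _nan_slice_means(track.segment(chrom, end, end + flank_bp), n_flank_bins)
    else:
        left = right = np.empty(0)
    row = np.concatenate([left, body, right])
    if strand == "-":
        row = row[::-1]
    return row


def metaplot(
    track: SignalTrack,
    regions: pd.DataFrame,
    n_body_bins: int = 20,
    flank_bp: int = 2000,
    n_flank_bins: int = 10,
) -> MetaProfile:
    """Average a signal over stranded regions (columns chrom/start/end/strand).

    Region bodies are rescaled to ``n_body_bins`` relative slices, flanks
    binned in absolute bp; regions with no data in a bin are skipped for that
    bin; regions shorter than the body bin count are skipped entirely.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    rows = []
    for _, r in regions.iterrows():
        row = region_profile(
            track,
            r["chrom"],
            int(r["start"]),
            int(r["end"]),
            str(r.get("strand", "+")),
            n_body_bins,
            flank_bp,
            n_flank_bins,
        )
        if row is not None:
            rows.append(row)
    if not rows:
        raise ValueError("no usable region for metaplot")
    mat = np.vstack(rows)
    n = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    se[n == 0] = np.nan
    return MetaProfile(mean, se, n, n_flank_bins if flank_bp > 0 else 0, n_body_bins, mat.shape[0])


def plot_metaprofile(profiles: Mapping[str, MetaProfile], path: str) -> None:
    """Write a simple mean ± SE curve plot for one or more profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, prof in profiles.items():
        x = np.arange(prof.n_bins)
        ax.plot(x, prof.mean, label=name)
        ax.fill_between(x, prof.mean - prof.se, prof.mean + prof.se, alpha=0.3)
    ax.axvline(prof.n_flank_bins - 0.5, color="grey", lw=0.5)
    ax.axvline(prof.n_flank_bins + prof.n_body_bins - 0.5, color="grey", lw=0.5)
    ax.legend()
    ax.set_xlabel("bin (5'→3')")
    ax.set_ylabel("signal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# group comparison (Welch)
# ---------------------------------------------------------------------------


@dataclass
class SignalComparison:
    per_region_a: pd.Series
    per_region_b: pd.Series
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    fraction: str
    warning: str | None = None


def _region_fraction_interval(
    start: int, end: int, strand: str, fraction: str
) -> tuple[int, int]:
    if fraction == "full":
        return start, end
    if fraction != "last_half":
        raise ValueError(f"unknown fraction {fraction!r}")
    mid = (start + end) // 2
    # the 3' half: downstream half in transcription orientation
    return (start, mid) if strand == "-" else (mid, end)


def compare_signal(
    group_a: Sequence[SignalTrack],
    group_b: Sequence[SignalTrack],
    regions: pd.DataFrame,
    fraction: str = "full",
) -> SignalComparison:
    """Welch two-sample t-test between genotypes over per-region means.

    Each region's value is the signal mean over the chosen fraction of the
    region ("full" or the strand-aware "last_half" = 3' half); replicate
    tracks within a group are averaged per region first, and the test is
    unpaired across the two groups' per-region values.  Degenerate
    zero-variance input yields statistic 0 / p 1 with a warning rather than
    an error.
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one track")

    def _values(tracks: Sequence[SignalTrack]) -> pd.Series:
        vals = {}
        for idx, r in regions.iterrows():
            lo, hi = _region_fraction_interval(
                int(r["start"]), int(r["end"]), str(r.get("strand", "+")), fraction
            )
            per_track = [np.nanmean(t.segment(r["chrom"], lo, hi)) for t in tracks]
            vals[idx] = float(np.nanmean(per_track))
        return pd.Series(vals)

    with np.errstate(invalid="ignore"):
        a = _values(group_a).dropna()
        b = _values(group_b).dropna()
    if a.empty or b.empty:
        raise ValueError("no region with data in one of the groups")
    if np.allclose(a.var(ddof=1) if len(a) > 1 else 0.0, 0.0) and np.allclose(
        b.var(ddof=1) if len(b) > 1 else 0.0, 0.0
    ):
        equal = np.isclose(a.mean(), b.mean())
        return SignalComparison(
            a, b, 0.0 if equal else np.inf, 1.0 if equal else 0.0,
            float(a.mean()), float(b.mean()), fraction,
            warning="zero variance in both groups",
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return SignalComparison(
        a, b, float(t), float(p), float(a.mean()), float(b.mean()), fraction
    )


def windowed_genome_difference(
    table_a: CytosineTable,
    table_b: CytosineTable,
    context: str,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 100_000,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Fixed-window mean level difference (A − B) along each chromosome.

    Windows tile every chromosome from 0 (the final window may be short);
    windows with no shared covered cytosine get NaN.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    a = table_a.by_context(context)
    b = table_b.by_context(context)
    a = a[a["total"] >= min_coverage]
    b = b[b["total"] >= min_coverage]
    merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    merged["diff"] = (
        merged["meth_a"] / merged["total_a"] - merged["meth_b"] / merged["total_b"]
    )
    merged["window"] = ((merged["pos"] - 1) // window_bp) * window_bp
    means = merged.groupby(["chrom", "window"])["diff"].mean()

    rows = []
    for chrom, L in chrom_lengths.items():
        for w in range(0, L, window_bp):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w,
                    "end": min(w + window_bp, L),
                    "diff": means.get((chrom, w), np.nan),
                }
            )
    return pd.DataFrame(rows)
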