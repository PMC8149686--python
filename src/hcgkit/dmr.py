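"""Bin-level differential-methylation calling and heritability tracking.

A 200-bp bin is a hyper DMR when, in the chosen context, (i) at least four
cytosines are covered (each at ≥4 reads — enforced upstream when the bin
methylome is built) in BOTH samples, (ii) the test sample's pooled level
exceeds the reference by more than 0.10, and (iii) a two-sided Fisher's exact
test on the pooled 2×2 count table is significant at 0.05.  No
multiple-testing correction is applied by default: the rule is an uncorrected
per-bin significance level (an FDR option exists).  Hypo DMRs mirror the rule
with the difference sign flipped.

DMR sets support the bin-identity set algebra used to intersect lines within
a generation, union generations, and chain intersections across generations
to quantify how much of the gained methylation is inherited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bins import BinId, BinMethylome, ClusterAssignment

_DMR_COLS = [
    "chrom",
    "start",
    "direction",
    "pvalue",
    "diff",
    "meth_test",
    "total_test",
    "meth_ref",
    "total_ref",
]


# ---------------------------------------------------------------------------
# exact two-sided Fisher test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _hypergeom_numerators(n1: int, n2: int, k: int) -> tuple[int, tuple[int, ...]]:
    """Integer numerators C(n1, x)·C(n2, k−x) over the support of x.

    The hypergeometric probability of x successes in the first row given the
    margins is numerator(x) / C(n1+n2, k); working with the integer
    numerators keeps tie comparisons exact.
    """
    lo = max(0, k - n2)
    hi = min(k, n1)
    return lo, tuple(comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1))


def fisher_exact_bin(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-sided Fisher's exact p for the 2×2 table [[m1, u1], [m2, u2]].

    Computed by exact integer hypergeometric enumeration (the
    point-probability method: sum every table, under the fixed margins, whose
    probability does not exceed the observed one), so it agrees with brute
    force enumeration to machine precision.
    """
    for v in (m1, u1, m2, u2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n1, n2 = m1 + u1, m2 + u2
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be positive")
    k = m1 + m2
    lo, nums = _hypergeom_numerators(n1, n2, k)
    obs = nums[m1 - lo]
    selected = sum(v for v in nums if v <= obs)
    return selected / sum(nums)


def score_test_bin(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-proportion score (z) test p-value; a sensitivity-analysis variant."""
    from scipy.stats import norm

    n1, n2 = m1 + u1, m2 + u2
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be positive")
    p_pool = (m1 + m2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (m1 / n1 - m2 / n2) / se
    return float(2 * norm.sf(abs(z)))


_TESTS = {"fisher": fisher_exact_bin, "score": score_test_bin}


# ---------------------------------------------------------------------------
# DMR sets
# ---------------------------------------------------------------------------


@dataclass
class DMRSet:
    """Differentially methylated bins for one comparison.

    ``records`` columns: chrom, start, direction (hyper|hypo), pvalue, diff
    (test − reference), and the pooled counts used.  ``label`` carries
    provenance (e.g. "T2plus_line1").
    """

    context: str
    test_id: str
    ref_id: str
    records: pd.DataFrame
    label: str = ""
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.records.empty:
            self.records = pd.DataFrame(columns=_DMR_COLS)
        self.records = self.records[_DMR_COLS].sort_values(
            ["chrom", "start"], ignore_index=True, kind="stable"
        )
        hyper = self.records["direction"] == "hyper"
        if not (
            (self.records.loc[hyper, "diff"] > 0).all()
            and (self.records.loc[~hyper, "diff"] < 0).all()
        ):
            raise ValueError("direction inconsistent with sign of difference")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> frozenset[BinId]:
        return frozenset(
            zip(self.records["chrom"], self.records["start"].astype(int))
        )

    @property
    def directions(self) -> set[str]:
        return set(self.records["direction"].unique())

    def select(self, direction: str) -> "DMRSet":
        return replace(
            self,
            records=self.records[self.records["direction"] == direction],
            label=f"{self.label}:{direction}" if self.label else direction,
        )

    def restrict(self, ids: "frozenset[BinId] | set[BinId]", label: str = "") -> "DMRSet":
        keys = list(zip(self.records["chrom"], self.records["start"].astype(int)))
        mask = np.array([k in ids for k in keys], dtype=bool) if keys else np.array([], bool)
        return replace(self, records=self.records[mask], label=label or self.label)

    def intersect(self, other: "DMRSet", label: str = "") -> "DMRSet":
        _check_compatible(self, other)
        return self.restrict(self.ids & other.ids, label=label)

    def union(self, other: "DMRSet", label: str = "") -> "DMRSet":
        _check_compatible(self, other)
        extra = other.restrict(other.ids - self.ids)
        rec = pd.concat([self.records, extra.records], ignore_index=True)
        return replace(self, records=rec, label=label or self.label)


def _check_compatible(a: DMRSet, b: DMRSet) -> None:
    if a.context != b.context:
        raise ValueError(f"context mismatch: {a.context} vs {b.context}")
    if a.directions and b.directions and a.directions != b.directions:
        raise ValueError(
            f"direction mismatch between sets: {a.directions} vs {b.directions}"
        )


def call_dmrs(
    test: BinMethylome,
    reference: BinMethylome,
    context: str = "CG",
    min_cytosines: int = 4,
    min_diff: float = 0.10,
    alpha: float = 0.05,
    method: str = "fisher",
    fdr: bool = False,
    label: str = "",
) -> DMRSet:
    """Call hyper and hypo DMR bins between two samples in one context.

    All three filters are conjunctive: coverage (≥ ``min_cytosines`` covered
    cytosines per bin in both samples), effect size (|pooled level
    difference| > ``min_diff``) and significance (p < ``alpha``, raw by
    default; ``fdr=True`` applies Benjamini–Hochberg across the bins that
    reach the test).
    """
    t = test.context_df(context)
    r = reference.context_df(context)
    if t.empty or r.empty:
        raise ValueError(f"context {context!r} absent from bin methylomes")
    if not t.index.equals(r.index):
        raise ValueError("bin methylomes are not on the same grid")

    covered = (
        (t["n_cyt"] >= min_cytosines)
        & (r["n_cyt"] >= min_cytosines)
        & (t["total"] > 0)
        & (r["total"] > 0)
    ).to_numpy()
    diff = (t["level"] - r["level"]).to_numpy()
    candidate = covered & (np.abs(diff) > min_diff)

    idx = np.flatnonzero(candidate)
    test_fn = _TESTS[method]
    mt = t["meth"].to_numpy()
    tt = t["total"].to_numpy()
    mr = r["meth"].to_numpy()
    tr = r["total"].to_numpy()
    pvals = np.array(
        [
            test_fn(int(mt[i]), int(tt[i] - mt[i]), int(mr[i]), int(tr[i] - mr[i]))
            for i in idx
        ]
    )
    if fdr and pvals.size:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    keep = pvals < alpha
    idx = idx[keep]
    pvals = pvals[keep]

    rows = t.index[idx]
    records = pd.DataFrame(
        {
            "chrom": rows.get_level_values(0),
            "start": rows.get_level_values(1),
            "direction": np.where(diff[idx] > 0, "hyper", "hypo"),
            "pvalue": pvals,
            "diff": diff[idx],
            "meth_test": mt[idx],
            "total_test": tt[idx],
            "meth_ref": mr[idx],
            "total_ref": tr[idx],
        }
    )
    return DMRSet(
        context,
        test.sample_id,
        reference.sample_id,
        records,
        label=label or f"{test.sample_id}_vs_{reference.sample_id}",
        bin_size=test.bin_size,
    )


def combine_line_generation(
    sets_by_generation: Mapping[str, Sequence[DMRSet]], label: str = ""
) -> DMRSet:
    """Intersect lines within each generation, then union the generations.

    The per-generation intersection keeps only bins differential in every
    transgenic line of that generation; the cross-generation union collects
    all potential sites for a genotype.  A single line passes through
    unchanged.
    """
    gen_sets: list[DMRSet] = []
    for gen, line_sets in sets_by_generation.items():
        if not line_sets:
            raise ValueError(f"generation {gen!r} supplied no DMR sets")
        acc = line_sets[0]
        for other in line_sets[1:]:
            acc = acc.intersect(other)
        gen_sets.append(replace(acc, label=str(gen)))
    out = gen_sets[0]
    for other in gen_sets[1:]:
        out = out.union(other)
    gens = "+".join(str(g) for g in sets_by_generation)
    return replace(out, label=label or f"union({gens})")


def partition_by_cluster(
    dmrs: DMRSet, clusters: ClusterAssignment
) -> dict[int | str, DMRSet]:
    """Assign each DMR bin to its cluster; bins outside the retained set go
    to the ``"unassigned"`` entry.  Counts are conserved:
    sum(per cluster) + unassigned = total."""
    out: dict[int | str, DMRSet] = {}
    assigned_ids: set[BinId] = set()
    for c in range(1, len(clusters.boundaries) + 2):
        ids = frozenset(clusters.bins_in_cluster(int(c)))
        sub = dmrs.restrict(ids, label=f"{dmrs.label}|cluster{c}")
        out[int(c)] = sub
        assigned_ids |= set(sub.ids)
    out["unassigned"] = dmrs.restrict(
        dmrs.ids - assigned_ids, label=f"{dmrs.label}|unassigned"
    )
    return out


# ---------------------------------------------------------------------------
# heritability chains
# ---------------------------------------------------------------------------


@dataclass
class HeritabilityStep:
    """One chain step: the heritable set of ``target`` is target ∩ (∩ references).

    ``references`` may name input DMR sets or earlier steps (whose heritable
    sets are then used), which is how chains like
    heritable(T5−) = T5− ∩ heritable(T4−) are expressed.
    """

    name: str
    target: str
    references: list[str] = field(default_factory=list)


@dataclass
class HeritabilityReport:
    table: pd.DataFrame
    heritable_ids: dict[str, frozenset[BinId]]


def heritability_chain(
    dmr_sets: Mapping[str, "DMRSet | frozenset[BinId] | set[BinId]"],
    plan: Sequence[HeritabilityStep | tuple],
) -> HeritabilityReport:
    """Track how much of a DMR set persists along a generation chain.

    For each step the heritable set is the target intersected with the
    chained intersection of its references.  Two percentages are reported:
    ``pct_of_reference`` = |heritable| / |∩ references| (the primary,
    "fraction of the earlier DMRs still present" reading) and
    ``pct_of_target`` = |heritable| / |target|.
    """

    def _ids(name: str, computed: dict[str, frozenset]) -> frozenset[BinId]:
        if name in computed:
            return computed[name]
        if name not in dmr_sets:
            raise KeyError(f"heritability plan references unknown set {name!r}")
        obj = dmr_sets[name]
        return obj.ids if isinstance(obj, DMRSet) else frozenset(obj)

    computed: dict[str, frozenset[BinId]] = {}
    rows = []
    for step in plan:
        if not isinstance(step, HeritabilityStep):
            step = HeritabilityStep(*step)
        target = _ids(step.target, computed)
        if not step.references:
            raise ValueError(f"step {step.name!r} lists no references")
        ref = _ids(step.references[0], computed)
        for more in step.references[1:]:
            ref = ref & _ids(more, computed)
        heritable = target & ref
        computed[step.name] = heritable
        rows.append(
            {
                "name": step.name,
                "target": step.target,
                "references": "&".join(step.references),
                "n_target": len(target),
                "n_reference": len(ref),
                "n_heritable": len(heritable),
                "pct_of_reference": 100.0 * len(heritable) / len(ref) if ref else np.nan,
                "pct_of_target": 100.0 * len(heritable) / len(target) if target else np.nan,
            }
        )
    return HeritabilityReport(pd.DataFrame(rows), computed)
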