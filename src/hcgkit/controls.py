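"""Percentile-matched ("mCG-equivalent") control regions.

For enrichment analyses each hyper-DMR bin needs a background bin with
comparable pre-existing CG methylation in the reference sample.  Controls are
drawn per rank percentile: for every percentile holding k DMR bins, k bins
are sampled uniformly without replacement from the retained non-differential
bins of that same percentile, so the control set reproduces the DMR set's
percentile histogram exactly while staying disjoint from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .bins import BinId
from .dmr import DMRSet


class ShortfallError(RuntimeError):
    """A percentile has fewer eligible bins than controls needed."""


@dataclass
class ControlSet:
    ids: frozenset[BinId]
    matched_label: str
    seed: int
    per_percentile: pd.Series  # controls drawn per percentile
    shortfall: pd.Series | None = None  # deficits, only in shortfall mode

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.ids), columns=["chrom", "start"])
        return df


def _as_ids(obj: "DMRSet | Iterable[BinId]") -> frozenset[BinId]:
    return obj.ids if isinstance(obj, DMRSet) else frozenset(obj)


def sample_mcg_equivalent(
    dmrs: "DMRSet | Iterable[BinId]",
    percentiles: pd.Series,
    retained: pd.MultiIndex,
    seed: int,
    exclude: "DMRSet | Iterable[BinId] | None" = None,
    allow_shortfall: bool = False,
) -> ControlSet:
    """Draw percentile-matched control bins for a DMR set.

    ``percentiles`` maps every retained bin to its rank percentile;
    ``exclude`` removes further bins from the eligible pool (typically the
    opposite-direction DMRs of the same comparison, since a control must be
    non-differential).  Deterministic given ``seed``.  A percentile with too
    few eligible bins raises :class:`ShortfallError` unless
    ``allow_shortfall``, in which case all available bins are taken and the
    deficit recorded.
    """
    dmr_ids = _as_ids(dmrs)
    excluded = dmr_ids | (_as_ids(exclude) if exclude is not None else frozenset())
    missing = dmr_ids - set(percentiles.index)
    if missing:
        raise KeyError(f"DMR bin {sorted(missing)[0]} has no percentile assignment")

    rng = np.random.default_rng(seed)
    retained_set = set(retained)
    demand = (
        pd.Series(
            [percentiles.loc[b] for b in sorted(dmr_ids)], dtype=int
        ).value_counts().sort_index()
    )

    chosen: list[BinId] = []
    deficits = {}
    pct_groups = percentiles.groupby(percentiles).groups  # percentile -> index
    for pct, k in demand.items():
        pool = [
            b
            for b in pct_groups.get(pct, [])
            if b in retained_set and b not in excluded
        ]
        pool.sort()
        if len(pool) < k:
            if not allow_shortfall:
                raise ShortfallError(
                    f"percentile {pct}: need {k} control bins, only {len(pool)} eligible"
                )
            deficits[pct] = k - len(pool)
            chosen.extend(pool)
            continue
        take = rng.choice(len(pool), size=int(k), replace=False)
        chosen.extend(pool[i] for i in take)

    got = pd.Series([percentiles.loc[b] for b in chosen], dtype=int)
    per_pct = got.value_counts().sort_index() if len(got) else pd.Series(dtype=int)
    label = dmrs.label if isinstance(dmrs, DMRSet) else ""
    return ControlSet(
        frozenset(chosen),
        label,
        seed,
        per_pct,
        pd.Series(deficits, dtype=int) if deficits else None,
    )
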