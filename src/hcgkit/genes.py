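"""Gene-body methylation, gbM-change classes, matched control genes, and
region-to-feature annotation with observed/expected enrichment.

Gene-body methylation (gbM) is the count-pooled CG level over a gene's full
annotated span.  Genes are classified by gbM change between a reference and a
test methylome with strict-inequality thresholds: "de novo" gbM requires a
reference level below 3% plus a gain above 10 percentage points; "enhanced"
gbM the same gain on top of a reference level above 3%.  A separate labelling
compares a wild-type methylome with a hypomethylated epimutant: genes with
gbM above 40% in the wild type but below 1% in the mutant have "lost" gbM,
above 40% in both "maintained" it, below 1% in both never had it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneAnnotation, introns_of, promoter_window, tts_window
from .bins import BinId
from .calling import CytosineTable, region_methylation
from .dmr import DMRSet

FEATURE_CATEGORIES = ("promoter", "TTS", "exon", "intron", "TE", "intergenic")


# ---------------------------------------------------------------------------
# gene-body methylation and classification
# ---------------------------------------------------------------------------


def gene_body_methylation(
    table: CytosineTable,
    annotation: GeneAnnotation,
    gene_id: str,
    min_coverage: int = 4,
    exons_only: bool = False,
) -> float | None:
    """Pooled CG level over a gene body; None when no cytosine survives.

    The body is the full annotated span by default (``exons_only`` restricts
    to exonic cytosines).
    """
    gene = annotation.feature(gene_id)
    if exons_only:
        exons = annotation.exons_of(gene_id)
        spans = list(zip(exons["start"], exons["end"])) or [
            (int(gene["start"]), int(gene["end"]))
        ]
    else:
        spans = [(int(gene["start"]), int(gene["end"]))]
    meth = total = 0
    for s, e in spans:
        r = region_methylation(table, gene["chrom"], s, e, "CG", min_coverage)
        if r.pooled is not None:
            meth += int(r.per_cytosine["meth"].sum())
            total += int(r.per_cytosine["total"].sum())
    return meth / total if total else None


def gene_body_methylation_all(
    table: CytosineTable,
    annotation: GeneAnnotation,
    min_coverage: int = 4,
    exons_only: bool = False,
) -> pd.Series:
    """gbM level for every gene (NaN where no data)."""
    out = {}
    for gid in annotation.genes()["id"]:
        v = gene_body_methylation(table, annotation, gid, min_coverage, exons_only)
        out[gid] = np.nan if v is None else v
    return pd.Series(out, name="gbm")


def classify_gbm_change(
    ref_level: float,
    test_level: float,
    low_threshold: float = 0.03,
    gain_threshold: float = 0.10,
) -> str:
    """Label a gene's gbM change: de_novo / enhanced / unchanged.

    Strict inequalities throughout; a gene whose reference level equals the
    low threshold exactly falls in neither gbM-change class.
    """
    gain = test_level - ref_level
    if gain > gain_threshold:
        if ref_level < low_threshold:
            return "de_novo"
        if ref_level > low_threshold:
            return "enhanced"
    return "unchanged"


def classify_fwa_gbm(
    col0_level: float,
    fwa_level: float,
    absent_threshold: float = 0.01,
    present_threshold: float = 0.40,
) -> str:
    """Label gbM status between wild type and a hypomethylated epimutant."""
    if col0_level < absent_threshold and fwa_level < absent_threshold:
        return "no_gbm"
    if col0_level > present_threshold and fwa_level < absent_threshold:
        return "lost"
    if col0_level > present_threshold and fwa_level > present_threshold:
        return "maintained"
    return "other"


def classify_genes(
    ref_gbm: pd.Series, test_gbm: pd.Series, **thresholds
) -> pd.DataFrame:
    """Vector version of :func:`classify_gbm_change` over shared genes with data."""
    shared = ref_gbm.dropna().index.intersection(test_gbm.dropna().index)
    rows = [
        {
            "gene": g,
            "ref_level": float(ref_gbm[g]),
            "test_level": float(test_gbm[g]),
            "change": classify_gbm_change(float(ref_gbm[g]), float(test_gbm[g]), **thresholds),
        }
        for g in shared
    ]
    return pd.DataFrame(rows, columns=["gene", "ref_level", "test_level", "change"])


# ---------------------------------------------------------------------------
# matched control genes
# ---------------------------------------------------------------------------


def select_control_genes(
    gbm: pd.Series,
    targets: Sequence[str],
    seed: int,
    percentile_tolerance: int = 5,
    hyper_dmrs: "DMRSet | Iterable[BinId] | None" = None,
    annotation: GeneAnnotation | None = None,
    bin_size: int = 200,
    allow_shortfall: bool = False,
) -> dict[str, str]:
    """Match each target gene with an unused control gene of similar gbM.

    Controls come from the same reference-gbM percentile band (± tolerance
    percentiles) and, when a hyper-DMR set and annotation are given, must not
    overlap any hyper-DMR bin — a control must be non-differential.
    Sampling is seeded and without replacement.
    """
    rng = np.random.default_rng(seed)
    levels = gbm.dropna()
    pct = levels.rank(method="first", pct=True).mul(100).apply(np.ceil).astype(int)

    blocked: set[str] = set(targets)
    if hyper_dmrs is not None and annotation is not None:
        dmr_ids = hyper_dmrs.ids if isinstance(hyper_dmrs, DMRSet) else frozenset(hyper_dmrs)
        genes = annotation.genes().set_index("id")
        for gid in levels.index:
            if gid not in genes.index:
                continue
            g = genes.loc[gid]
            b0 = (int(g["start"]) // bin_size) * bin_size
            b1 = ((int(g["end"]) - 1) // bin_size) * bin_size
            if any((g["chrom"], b) in dmr_ids for b in range(b0, b1 + 1, bin_size)):
                blocked.add(gid)

    out: dict[str, str] = {}
    used: set[str] = set()
    for target in targets:
        if target not in pct.index:
            raise KeyError(f"target gene {target!r} has no gbM value")
        band = pct.index[
            (pct - pct[target]).abs() <= percentile_tolerance
        ]
        pool = sorted(set(band) - blocked - used)
        if not pool:
            if allow_shortfall:
                continue
            raise RuntimeError(
                f"gbM percentile band of {target!r} exhausted; no eligible control gene"
            )
        out[target] = pool[int(rng.integers(0, len(pool)))]
        used.add(out[target])
    return out


# ---------------------------------------------------------------------------
# feature annotation and enrichment
# ---------------------------------------------------------------------------


class FeatureAnnotator:
    """Midpoint-based region annotator with fixed category precedence.

    Categories: promoter > TTS > exon > intron > TE > intergenic.  The
    promoter is the strand-aware window from 1 kb upstream to 100 bp
    downstream of the TSS; the TTS window mirrors it around the
    transcription termination site.
    """

    def __init__(self, annotation: GeneAnnotation, chrom_lengths: Mapping[str, int] | None = None):
        self.annotation = annotation
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self._trees: dict[str, dict[str, IntervalTree]] = {
            cat: {} for cat in ("promoter", "TTS", "exon", "intron", "TE")
        }

        def _add(cat: str, chrom: str, start: int, end: int) -> None:
            if end <= start:
                return
            self._trees[cat].setdefault(chrom, IntervalTree()).addi(start, end)

        for _, g in annotation.genes().iterrows():
            chrom = g["chrom"]
            _add("promoter", chrom, *promoter_window(g))
            _add("TTS", chrom, *tts_window(g))
            exons = annotation.exons_of(g["id"])
            if exons.empty:
                _add("exon", chrom, int(g["start"]), int(g["end"]))
            else:
                for _, ex in exons.iterrows():
                    _add("exon", chrom, int(ex["start"]), int(ex["end"]))
                for s, e in introns_of(annotation, g["id"]):
                    _add("intron", chrom, s, e)
        for _, te in annotation.tes().iterrows():
            _add("TE", te["chrom"], int(te["start"]), int(te["end"]))

    def category_of(self, chrom: str, start: int, end: int) -> str:
        if end <= start:
            raise ValueError("empty region")
        if self.chrom_lengths is not None:
            L = self.chrom_lengths.get(chrom)
            if L is None or start < 0 or end > L:
                raise ValueError(f"region {chrom}:{start}-{end} off chromosome")
        mid = (start + end) // 2
        for cat in ("promoter", "TTS", "exon", "intron", "TE"):
            tree = self._trees[cat].get(chrom)
            if tree is not None and tree.overlaps_point(mid):
                return cat
        return "intergenic"


def annotate_features(
    regions: pd.DataFrame,
    annotation: GeneAnnotation,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.Series:
    """Category per region (columns chrom/start/end), by region midpoint."""
    ann = FeatureAnnotator(annotation, chrom_lengths)
    cats = [
        ann.category_of(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in regions.iterrows()
    ]
    return pd.Series(pd.Categorical(cats, categories=FEATURE_CATEGORIES), index=regions.index, name="category")


def observed_expected_enrichment(
    region_categories: pd.Series, background_categories: pd.Series
) -> pd.DataFrame:
    """Per-category observed/expected frequency ratio.

    Expected frequencies come from the background set (typically the
    percentile-matched controls).  A category absent from the background has
    an undefined ratio (NaN) rather than infinity.
    """
    if len(background_categories) == 0:
        raise ValueError("background set is empty")
    obs = region_categories.value_counts(normalize=True).reindex(
        FEATURE_CATEGORIES, fill_value=0.0
    )
    exp = background_categories.value_counts(normalize=True).reindex(
        FEATURE_CATEGORIES, fill_value=0.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = obs / exp
    ratio[exp == 0] = np.nan
    return pd.DataFrame(
        {"observed_freq": obs, "expected_freq": exp, "oe_ratio": ratio}
    )
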