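"""Gene/TE annotation container.

Coordinates are 0-based half-open internally; GFF3 emission converts to the
1-based inclusive convention of that format.  Feature kinds are restricted to
protein-coding genes and transposable elements (TEs), the two classes the
downstream analyses distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("gene", "TE")

_FEATURE_COLS = ["id", "chrom", "strand", "start", "end", "kind"]
_EXON_COLS = ["parent", "chrom", "start", "end"]


@dataclass
class GeneAnnotation:
    """Genes and TEs with per-gene exon intervals.

    ``features`` columns: id, chrom, strand, start, end, kind (gene|TE).
    ``exons`` columns: parent, chrom, start, end.  Exons lie within their
    parent gene's span; intervals are half-open and non-negative length.
    """

    features: pd.DataFrame
    exons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EXON_COLS)
    )

    def __post_init__(self) -> None:
        self.features = self.features[_FEATURE_COLS].reset_index(drop=True)
        self.exons = self.exons[_EXON_COLS].reset_index(drop=True)
        f = self.features
        if (f["end"] < f["start"]).any():
            raise ValueError("annotation contains negative-length features")
        bad = ~f["kind"].isin(FEATURE_KINDS)
        if bad.any():
            raise ValueError(f"unknown feature kind: {f.loc[bad, 'kind'].iloc[0]!r}")
        if not self.exons.empty:
            spans = f.set_index("id")
            par = self.exons["parent"]
            inside = (
                self.exons["start"].to_numpy()
                >= spans.loc[par, "start"].to_numpy()
            ) & (self.exons["end"].to_numpy() <= spans.loc[par, "end"].to_numpy())
            if not inside.all():
                raise ValueError("exon outside parent gene bounds")
        self.features = f.sort_values(
            ["chrom", "start", "end"], ignore_index=True, kind="stable"
        )

    # -- convenience views -------------------------------------------------
    def genes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "gene"]

    def tes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "TE"]

    def exons_of(self, gene_id: str) -> pd.DataFrame:
        return self.exons[self.exons["parent"] == gene_id]

    def __len__(self) -> int:
        return len(self.features)

    def feature(self, feature_id: str) -> pd.Series:
        hit = self.features[self.features["id"] == feature_id]
        if hit.empty:
            raise KeyError(f"unknown feature id {feature_id!r}")
        return hit.iloc[0]


def tss_tts(feature: pd.Series) -> tuple[int, int]:
    """Transcription start/termination coordinates of a stranded feature.

    For a plus-strand feature spanning [start, end) the TSS is ``start`` and
    the TTS is ``end``; minus-strand features are mirrored.
    """
    if feature["strand"] == "-":
        return int(feature["end"]), int(feature["start"])
    return int(feature["start"]), int(feature["end"])


def promoter_window(feature: pd.Series, upstream: int = 1000, downstream: int = 100) -> tuple[int, int]:
    """Strand-aware promoter interval: upstream 1 kb and downstream 100 bp of the TSS."""
    tss, _ = tss_tts(feature)
    if feature["strand"] == "-":
        return tss - downstream, tss + upstream
    return tss - upstream, tss + downstream


def tts_window(feature: pd.Series, upstream: int = 100, downstream: int = 1000) -> tuple[int, int]:
    """Strand-aware TTS interval mirroring the promoter convention."""
    _, tts = tss_tts(feature)
    if feature["strand"] == "-":
        return tts - downstream, tts + upstream
    return tts - upstream, tts + downstream


def introns_of(annotation: GeneAnnotation, gene_id: str) -> list[tuple[int, int]]:
    """Intron intervals = gene span minus exons (empty for single-exon genes)."""
    gene = annotation.feature(gene_id)
    exons = annotation.exons_of(gene_id).sort_values("start")
    if exons.empty:
        return []
    out = []
    prev_end = int(gene["start"])
    for _, ex in exons.iterrows():
        if ex["start"] > prev_end:
            out.append((prev_end, int(ex["start"])))
        prev_end = int(ex["end"])
    if prev_end < int(gene["end"]):
        out.append((prev_end, int(gene["end"])))
    # leading/trailing gaps only occur if exons do not reach the gene bounds
    return out
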