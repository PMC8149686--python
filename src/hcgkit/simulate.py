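"""Synthetic multi-generation bisulfite methylome generator.

Emulates the statistical structure the downstream analyses assume: a small
genome with gene-dense chromosome arms and a TE-dense pericentromere; gene
body methylation (gbM) genes carrying CG-only methylation with a mid-body
dome; TEs methylated in all three contexts; a methyltransferase-driven wave
of ectopic CG-only gains biased toward gene bodies and less accessible
chromatin; region-level transgenerational retention with probability ``r``;
and binomial read sampling at configurable coverage, including a configurable
fraction of unconverted (fully methylated) reads that the conversion filter
downstream must catch.

Every operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .annotation import GeneAnnotation, promoter_window
from .calling import CytosineTable, ReadSet
from .contexts import cytosine_contexts


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Simulation parameters (defaults are the package's study conditions).

    Probabilities are in [0, 1]; lengths in bp.  ``chrom_length_bp`` should be
    divisible by ``bin_size`` so ground truth maps 1:1 onto analysis bins.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 400_000
    pericentromere_fraction: float = 0.2
    n_genes: int = 240
    n_tes: int = 100
    gene_length_range: tuple[int, int] = (800, 3000)
    te_length_range: tuple[int, int] = (300, 1200)
    fraction_gbm_genes: float = 0.3
    gbm_body_cg_level: float = 0.6
    te_levels: tuple[float, float, float] = (0.9, 0.7, 0.1)  # CG, CHG, CHH
    chh_background: float = 0.0
    ectopic_gain_rate: float = 0.06
    ectopic_gain_level: float = 0.7
    accessibility_bias: float = 2.0
    gene_body_bias: float = 4.0
    retention_rate_r: float = 0.8
    coverage_mean: float = 8.0
    read_length_cytosines: int = 10
    nonconversion_read_fraction: float = 0.005
    bin_size: int = 200

    def validate(self) -> None:
        def _prob(name: str) -> None:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

        for name in (
            "fraction_gbm_genes",
            "gbm_body_cg_level",
            "chh_background",
            "ectopic_gain_rate",
            "ectopic_gain_level",
            "retention_rate_r",
            "nonconversion_read_fraction",
        ):
            _prob(name)
        for i, v in enumerate(self.te_levels):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"te_levels[{i}] must be in [0, 1], got {v}")
        if not 0.0 < self.pericentromere_fraction < 1.0:
            raise ConfigError(
                f"pericentromere_fraction must be in (0, 1), got {self.pericentromere_fraction}"
            )
        for name in ("n_chromosomes", "chrom_length_bp", "bin_size", "read_length_cytosines"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_tes < 0:
            raise ConfigError("n_genes/n_tes must be non-negative")
        if self.coverage_mean <= 0:
            raise ConfigError(f"coverage_mean must be positive, got {self.coverage_mean}")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigError(f"gene_length_range invalid: {self.gene_length_range}")
        lo, hi = self.te_length_range
        if not 0 < lo <= hi:
            raise ConfigError(f"te_length_range invalid: {self.te_length_range}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config field(s): {sorted(bad)}")
        d = dict(d)
        for key in ("gene_length_range", "te_length_range", "te_levels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def pericentromere(self, chrom_length: int | None = None) -> tuple[int, int]:
        """Central [start, end) window holding the TE-dense compartment."""
        L = chrom_length or self.chrom_length_bp
        half = int(round(L * self.pericentromere_fraction / 2))
        mid = L // 2
        return mid - half, mid + half


@dataclass
class AccessibilityTrack:
    """Per-bin chromatin-accessibility covariate in [0, 1].

    A simulator-only stand-in for an accessibility assay: high over promoters
    and TE-free arms, low over the pericentromere and a random subset of gene
    bodies.  It exists so that "gains prefer less open chromatin" is a
    testable property of the gain sampler.
    """

    bin_size: int
    values: dict[str, np.ndarray]

    def at_bins(self, chrom: str, starts: np.ndarray) -> np.ndarray:
        return self.values[chrom][np.asarray(starts) // self.bin_size]

    def genome_mean(self) -> float:
        return float(np.mean(np.concatenate(list(self.values.values()))))


@dataclass
class GainRegion:
    """One ectopic-gain region (grid-aligned) and its inheritance state."""

    chrom: str
    start: int
    end: int
    established: int  # generation index at establishment
    retained: bool = True
    lost_at: int | None = None

    @property
    def bin_id(self) -> tuple[str, int]:
        return (self.chrom, self.start)


@dataclass
class TrueMethylome:
    """Ground-truth per-cytosine methylation probabilities.

    ``sites`` columns: chrom, pos (1-based), strand, context, trinucleotide,
    p_base (pre-gain probability), p (current probability).  The
    ``gain_registry`` records every ectopic-gain region and whether it is
    still retained; a region lost at generation g stays lost afterwards.
    """

    sites: pd.DataFrame
    gain_registry: list[GainRegion] = field(default_factory=list)
    generation: int = 0
    label: str = "baseline"

    def copy(self, label: str | None = None) -> "TrueMethylome":
        return TrueMethylome(
            self.sites.copy(),
            [dataclasses.replace(g) for g in self.gain_registry],
            self.generation,
            label if label is not None else self.label,
        )

    def retained_regions(self) -> list[GainRegion]:
        return [g for g in self.gain_registry if g.retained]


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _place_intervals(
    rng: np.random.Generator,
    arm: tuple[int, int],
    lengths: np.ndarray,
) -> np.ndarray:
    """Place non-overlapping intervals of the given lengths inside one arm.

    Uses stick-breaking on the leftover space so placement always succeeds
    when the features fit, with random gaps between neighbours.
    """
    lo, hi = arm
    slack = (hi - lo) - int(lengths.sum())
    if slack < 0:
        raise ConfigError(
            "features do not fit: total feature length exceeds available arm space"
        )
    gaps = rng.dirichlet(np.ones(lengths.size + 1)) * slack
    cumgap = np.floor(np.cumsum(gaps[:-1])).astype(int)
    starts = lo + cumgap + np.concatenate([[0], np.cumsum(lengths[:-1])]).astype(int)
    return starts


def _split_exons(
    rng: np.random.Generator, start: int, end: int, min_seg: int = 50
) -> list[tuple[int, int]]:
    length = end - start
    max_exons = max(1, min(4, (length // (2 * min_seg) + 1) // 2 + 1))
    n_ex = int(rng.integers(1, max_exons + 1))
    n_seg = 2 * n_ex - 1
    if n_ex == 1 or length < n_seg * min_seg:
        return [(start, end)]
    extra = rng.dirichlet(np.ones(n_seg)) * (length - n_seg * min_seg)
    widths = np.floor(extra).astype(int) + min_seg
    widths[-1] += length - widths.sum()
    bounds = start + np.concatenate([[0], np.cumsum(widths)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], GeneAnnotation, AccessibilityTrack]:
    """Generate genome sequence, gene/TE annotation and accessibility track.

    Chromosomes are uniform-random sequence of the configured length; genes
    sit on the arms, TEs inside the central pericentromeric window.  The
    whole layout is deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    feats: list[dict] = []
    exon_rows: list[dict] = []

    peri = config.pericentromere()
    n_chrom = config.n_chromosomes
    genes_per = np.full(n_chrom, config.n_genes // n_chrom)
    genes_per[: config.n_genes % n_chrom] += 1
    tes_per = np.full(n_chrom, config.n_tes // n_chrom)
    tes_per[: config.n_tes % n_chrom] += 1

    gid = tid = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=config.chrom_length_bp)
        genome[chrom] = seq.tobytes().decode("ascii")

        # genes on the two arms, proportional to arm length
        arms = [(0, peri[0]), (peri[1], config.chrom_length_bp)]
        arm_len = np.array([a[1] - a[0] for a in arms], float)
        n_left = int(round(genes_per[ci] * arm_len[0] / arm_len.sum()))
        for arm, n_arm in zip(arms, (n_left, genes_per[ci] - n_left)):
            if n_arm == 0:
                continue
            lengths = rng.integers(
                config.gene_length_range[0], config.gene_length_range[1] + 1, n_arm
            )
            starts = _place_intervals(rng, arm, lengths)
            strands = rng.choice(np.array(["+", "-"]), size=n_arm)
            for s, L, st in zip(starts, lengths, strands):
                gene_id = f"gene{gid:05d}"
                gid += 1
                feats.append(
                    dict(id=gene_id, chrom=chrom, strand=st, start=int(s), end=int(s + L), kind="gene")
                )
                for es, ee in _split_exons(rng, int(s), int(s + L)):
                    exon_rows.append(dict(parent=gene_id, chrom=chrom, start=es, end=ee))

        # TEs inside the pericentromere
        if tes_per[ci]:
            lengths = rng.integers(
                config.te_length_range[0], config.te_length_range[1] + 1, tes_per[ci]
            )
            starts = _place_intervals(rng, peri, lengths)
            strands = rng.choice(np.array(["+", "-"]), size=tes_per[ci])
            for s, L, st in zip(starts, lengths, strands):
                feats.append(
                    dict(id=f"te{tid:05d}", chrom=chrom, strand=st, start=int(s), end=int(s + L), kind="TE")
                )
                tid += 1

    annotation = GeneAnnotation(
        pd.DataFrame(feats), pd.DataFrame(exon_rows) if exon_rows else pd.DataFrame(columns=["parent", "chrom", "start", "end"])
    )

    accessibility = _accessibility_track(rng, config, annotation)
    return genome, annotation, accessibility


def _accessibility_track(
    rng: np.random.Generator, config: SimConfig, annotation: GeneAnnotation
) -> AccessibilityTrack:
    nb = config.chrom_length_bp // config.bin_size
    peri = config.pericentromere()
    values: dict[str, np.ndarray] = {}
    genes = annotation.genes()
    closed_genes = set(
        genes["id"].iloc[
            rng.choice(len(genes), size=max(1, int(0.3 * len(genes))), replace=False)
        ]
    ) if len(genes) else set()
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        acc = np.full(nb, 0.75)
        bs, be = peri[0] // config.bin_size, peri[1] // config.bin_size
        acc[bs:be] = 0.15
        sub = genes[genes["chrom"] == chrom]
        for _, g in sub.iterrows():
            p0, p1 = promoter_window(g)
            acc[max(0, p0 // config.bin_size): max(0, p1 // config.bin_size) + 1] = 0.9
            if g["id"] in closed_genes:
                acc[g["start"] // config.bin_size: (g["end"] - 1) // config.bin_size + 1] = 0.3
        acc = np.clip(acc + rng.uniform(-0.05, 0.05, nb), 0.0, 1.0)
        values[chrom] = acc
    return AccessibilityTrack(config.bin_size, values)


# ---------------------------------------------------------------------------
# ground-truth methylomes
# ---------------------------------------------------------------------------


def _dome(x: np.ndarray) -> np.ndarray:
    """Smooth mid-gene-body weight, peaking at 60% of gene length."""
    w = x**3 * (1 - x) ** 2
    return w / (0.6**3 * 0.4**2)


def gbm_gene_ids(annotation: GeneAnnotation, config: SimConfig, seed: int) -> list[str]:
    """Seeded choice of which genes carry gene-body methylation."""
    genes = annotation.genes()
    n = int(round(config.fraction_gbm_genes * len(genes)))
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    pick = rng.choice(len(genes), size=n, replace=False)
    return sorted(genes["id"].iloc[pick])


def simulate_baseline_methylome(
    genome: Mapping[str, str],
    annotation: GeneAnnotation,
    config: SimConfig,
    seed: int | None = None,
) -> TrueMethylome:
    """Ground-truth wild-type methylome.

    gbM genes carry CG-only body methylation around ``gbm_body_cg_level``
    with a mid-body dome; TEs carry CG/CHG/CHH at ``te_levels``; everything
    else sits at ~0 (CHH at the configured background).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    sites = cytosine_contexts(genome)
    sites["p_base"] = 0.0
    is_chh = (sites["context"] == "CHH").to_numpy()
    if config.chh_background > 0:
        sites.loc[is_chh, "p_base"] = config.chh_background

    pos0 = sites["pos"].to_numpy() - 1  # 0-based
    chrom_arr = sites["chrom"].to_numpy()
    ctx = sites["context"].to_numpy()
    p = sites["p_base"].to_numpy().copy()

    # per-chromosome position index for fast span slicing
    order_ok = sites.groupby("chrom", sort=False)["pos"].is_monotonic_increasing
    assert order_ok.all()
    chrom_slices: dict[str, tuple[int, int]] = {}
    start_idx = 0
    for chrom, group in sites.groupby("chrom", sort=False):
        chrom_slices[str(chrom)] = (start_idx, start_idx + len(group))
        start_idx += len(group)

    def span_indices(chrom: str, start: int, end: int) -> np.ndarray:
        lo, hi = chrom_slices[chrom]
        sub = pos0[lo:hi]
        a = np.searchsorted(sub, start, side="left")
        b = np.searchsorted(sub, end, side="left")
        return np.arange(lo + a, lo + b)

    # TEs: all three contexts
    te_cg, te_chg, te_chh = config.te_levels
    for _, te in annotation.tes().iterrows():
        idx = span_indices(te["chrom"], te["start"], te["end"])
        c = ctx[idx]
        p[idx[c == "CG"]] = te_cg
        p[idx[c == "CHG"]] = te_chg
        p[idx[c == "CHH"]] = te_chh

    # gbM genes: CG only, dome-shaped along the transcription direction
    for gene_id in gbm_gene_ids(annotation, config, seed):
        g = annotation.feature(gene_id)
        idx = span_indices(g["chrom"], g["start"], g["end"])
        idx = idx[ctx[idx] == "CG"]
        if idx.size == 0:
            continue
        rel = (pos0[idx] - g["start"]) / max(1, g["end"] - g["start"])
        if g["strand"] == "-":
            rel = 1.0 - rel
        p[idx] = np.maximum(p[idx], config.gbm_body_cg_level * _dome(rel))

    sites["p_base"] = p
    sites["p"] = p.copy()
    assert ((sites["p"] >= 0) & (sites["p"] <= 1)).all()
    return TrueMethylome(sites, [], generation=0, label="baseline")


# ---------------------------------------------------------------------------
# ectopic gain and transgenerational propagation
# ---------------------------------------------------------------------------

SATURATION_LEVEL = 0.9  # sites at or above this true level never gain


def _bin_cg_stats(methylome: TrueMethylome, bin_size: int) -> pd.DataFrame:
    """Per-bin count of gain-eligible CG sites and their mean true level."""
    s = methylome.sites
    cg = s[s["context"] == "CG"]
    binned = pd.DataFrame(
        {
            "chrom": cg["chrom"].to_numpy(),
            "start": ((cg["pos"].to_numpy() - 1) // bin_size) * bin_size,
            "p": cg["p"].to_numpy(),
            "eligible_site": (cg["p"].to_numpy() < SATURATION_LEVEL).astype(int),
        }
    )
    out = (
        binned.groupby(["chrom", "start"], sort=True)
        .agg(n_cg=("p", "size"), mean_p=("p", "mean"), n_eligible=("eligible_site", "sum"))
        .reset_index()
    )
    return out


def eligible_gain_bins(
    methylome: TrueMethylome, config: SimConfig
) -> pd.DataFrame:
    """Grid bins eligible for ectopic gain: ≥1 non-saturated CG site."""
    stats = _bin_cg_stats(methylome, config.bin_size)
    return stats[stats["n_eligible"] > 0].reset_index(drop=True)


def _gain_weights(
    bins: pd.DataFrame,
    annotation: GeneAnnotation,
    accessibility: AccessibilityTrack,
    config: SimConfig,
) -> np.ndarray:
    """Sampling weight per eligible bin.

    Weight decreases with accessibility (strength ``accessibility_bias``) and
    is multiplied by ``gene_body_bias`` when the bin midpoint lies in a gene
    body, making the gains prefer less open chromatin and gene bodies.
    """
    acc = np.concatenate(
        [
            accessibility.at_bins(chrom, grp["start"].to_numpy())
            for chrom, grp in bins.groupby("chrom", sort=False)
        ]
    )
    w = np.exp(-config.accessibility_bias * acc)
    mid = bins["start"].to_numpy() + config.bin_size // 2
    in_gene = np.zeros(len(bins), bool)
    genes = annotation.genes()
    for chrom, grp in bins.groupby("chrom", sort=False):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        starts = np.sort(sub["start"].to_numpy())
        # genes never overlap by construction, so interval membership can use
        # the matched sorted ends
        ends = sub.sort_values("start")["end"].to_numpy()
        j = np.searchsorted(starts, mid[grp.index], side="right") - 1
        ok = j >= 0
        hit = np.zeros(len(grp), bool)
        hit[ok] = mid[grp.index][ok] < ends[j[ok]]
        in_gene[grp.index] = hit
    w = w * np.where(in_gene, config.gene_body_bias, 1.0)
    return w


def _systematic_pps(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Fixed-size weighted sample without replacement (systematic PPS).

    Inclusion probability of unit i is exactly ``n * w_i / sum(w)`` (units
    whose probability would exceed 1 are included with certainty and the
    remainder re-sampled), so expectations calibrated from the weights hold
    exactly while the sample size is deterministic.
    """
    m = weights.size
    if n > m:
        raise ValueError(f"cannot sample {n} of {m} bins")
    chosen = np.zeros(m, bool)
    idx = np.arange(m)
    w = weights.astype(float).copy()
    while n > 0:
        pi = n * w / w.sum()
        certain = pi >= 1.0
        if certain.any():
            chosen[idx[certain]] = True
            n -= int(certain.sum())
            idx, w = idx[~certain], w[~certain]
            continue
        order = rng.permutation(w.size)
        cw = np.cumsum(w[order])
        stride = cw[-1] / n
        points = (rng.uniform(0, 1) + np.arange(n)) * stride
        take = np.searchsorted(cw, points, side="right")
        chosen[idx[order[take]]] = True
        n = 0
    return np.flatnonzero(chosen)


def simulate_ectopic_gain(
    methylome: TrueMethylome,
    annotation: GeneAnnotation,
    accessibility: AccessibilityTrack,
    config: SimConfig,
    seed: int,
    label: str | None = None,
) -> TrueMethylome:
    """Add CG-only ectopic gains to grid-aligned regions.

    Regions are 200-bp analysis bins sampled preferentially at low
    accessibility and inside gene bodies; ``ectopic_gain_rate`` is the
    expected fraction of eligible bins that gain.  Within a gained bin every
    non-saturated CG site has ``ectopic_gain_level`` added to its true
    probability (clipped at 1); CHG/CHH are untouched.
    """
    config.validate()
    out = methylome.copy(label=label or f"gen{methylome.generation + 1}")
    out.generation = methylome.generation + 1
    bins = eligible_gain_bins(methylome, config)
    n_gain = int(round(config.ectopic_gain_rate * len(bins)))
    if n_gain == 0:
        return out
    rng = np.random.default_rng(seed)
    w = _gain_weights(bins, annotation, accessibility, config)
    take = _systematic_pps(rng, w, n_gain)
    chosen = bins.iloc[take]

    s = out.sites
    pos0 = s["pos"].to_numpy() - 1
    bin_of_site = (pos0 // config.bin_size) * config.bin_size
    key = pd.MultiIndex.from_arrays([s["chrom"].to_numpy(), bin_of_site])
    chosen_key = pd.MultiIndex.from_frame(chosen[["chrom", "start"]])
    in_gain = key.isin(chosen_key)
    target = in_gain & (s["context"] == "CG").to_numpy() & (s["p"].to_numpy() < SATURATION_LEVEL)
    p = s["p"].to_numpy().copy()
    p[target] = np.clip(p[target] + config.ectopic_gain_level, 0.0, 1.0)
    out.sites["p"] = p

    for _, b in chosen.sort_values(["chrom", "start"]).iterrows():
        out.gain_registry.append(
            GainRegion(
                chrom=str(b["chrom"]),
                start=int(b["start"]),
                end=int(b["start"]) + config.bin_size,
                established=out.generation,
            )
        )
    return out


def calibrated_gain_rate(
    methylome: TrueMethylome,
    annotation: GeneAnnotation,
    accessibility: AccessibilityTrack,
    config: SimConfig,
    target_mean_cg_gain: float,
) -> float:
    """Gain rate giving a chosen expected genome-wide mean CG gain.

    The genome-wide CG difference induced by gains is the total added
    probability mass over all CG sites divided by the number of CG sites.
    Because the gain sampler's inclusion probabilities are exactly
    proportional to the bin weights, the expected added mass is
    ``n_gain * sum(w_i * m_i) / sum(w)`` with ``m_i`` the mass bin i would
    add if gained; solving for ``n_gain`` yields the rate.
    """
    s = methylome.sites
    cg = s[s["context"] == "CG"]
    n_cg_total = len(cg)
    bins = eligible_gain_bins(methylome, config)
    w = _gain_weights(bins, annotation, accessibility, config)
    # per-bin addable mass
    p = cg["p"].to_numpy()
    b = pd.DataFrame(
        {
            "chrom": cg["chrom"].to_numpy(),
            "start": ((cg["pos"].to_numpy() - 1) // config.bin_size) * config.bin_size,
            "mass": np.where(
                p < SATURATION_LEVEL,
                np.minimum(config.ectopic_gain_level, 1.0 - p),
                0.0,
            ),
        }
    )
    mass = (
        b.groupby(["chrom", "start"], sort=True)["mass"].sum().reset_index()
    )
    merged = bins.merge(mass, on=["chrom", "start"], how="left").fillna({"mass": 0.0})
    mean_mass = float((w * merged["mass"].to_numpy()).sum() / w.sum())
    if mean_mass <= 0:
        raise ConfigError("no addable CG mass; cannot calibrate gain rate")
    n_gain = target_mean_cg_gain * n_cg_total / mean_mass
    rate = n_gain / len(bins)
    if rate > 1.0:
        raise ConfigError(
            f"target mean CG gain {target_mean_cg_gain} not reachable: needs rate {rate:.3f} > 1"
        )
    return rate


def propagate_generation(
    methylome: TrueMethylome, r: float, seed: int, label: str | None = None
) -> TrueMethylome:
    """One generation of region-level retention.

    Each still-retained gained region is independently kept with probability
    ``r``; a lost region reverts its CG sites to the baseline probability.
    Baseline (pre-existing) methylation always persists, and no new gain
    region is ever created here.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"retention probability must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    out = methylome.copy(label=label or f"gen{methylome.generation + 1}")
    out.generation = methylome.generation + 1

    s = out.sites
    pos0 = s["pos"].to_numpy() - 1
    chrom_arr = s["chrom"].to_numpy()
    is_cg = (s["context"] == "CG").to_numpy()
    p = s["p"].to_numpy().copy()
    p_base = s["p_base"].to_numpy()

    still = [g for g in out.gain_registry if g.retained]
    keep = rng.random(len(still)) < r
    for g, k in zip(still, keep):
        if k:
            continue
        g.retained = False
        g.lost_at = out.generation
        revert = (
            (chrom_arr == g.chrom)
            & (pos0 >= g.start)
            & (pos0 < g.end)
            & is_cg
        )
        p[revert] = p_base[revert]
    out.sites["p"] = p
    return out


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


def sample_reads(methylome: TrueMethylome, config: SimConfig, seed: int) -> ReadSet:
    """Simulate bisulfite read calls from ground truth.

    Reads cover ``read_length_cytosines`` consecutive cytosines of one strand
    with uniform-random starts, giving per-cytosine depth ~
    Poisson(``coverage_mean``); each covered cytosine's call is
    Bernoulli(true probability).  A ``nonconversion_read_fraction`` of reads
    is emitted fully methylated regardless of truth — the conversion-failure
    signature the downstream filter must catch.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    s = methylome.sites
    L = config.read_length_cytosines

    chrom_codes_parts, strand_parts, ptr_widths = [], [], []
    pos_parts, ctx_parts, meth_parts = [], [], []
    chroms = list(dict.fromkeys(s["chrom"]))
    ctx_code = pd.Categorical(s["context"], categories=["CG", "CHG", "CHH"]).codes

    for (chrom, strand), grp_idx in s.groupby(["chrom", "strand"], sort=True, observed=True).indices.items():
        grp_idx = np.sort(grp_idx)
        n_cyt = grp_idx.size
        if n_cyt == 0:
            continue
        eff_len = min(L, n_cyt)
        n_reads = int(round(n_cyt * config.coverage_mean / eff_len))
        if n_reads == 0:
            continue
        starts = rng.integers(0, n_cyt - eff_len + 1, n_reads)
        starts.sort()
        idx = starts[:, None] + np.arange(eff_len)[None, :]
        flat = grp_idx[idx.ravel()]
        p = s["p"].to_numpy()[flat]
        calls = rng.random(flat.size) < p
        noncv = rng.random(n_reads) < config.nonconversion_read_fraction
        if noncv.any():
            calls = calls.reshape(n_reads, eff_len)
            calls[noncv] = True
            calls = calls.ravel()
        chrom_codes_parts.append(np.full(n_reads, chroms.index(chrom), np.int32))
        strand_parts.append(np.full(n_reads, strand, dtype="U1"))
        ptr_widths.append(np.full(n_reads, eff_len, np.int64))
        pos_parts.append(s["pos"].to_numpy()[flat])
        ctx_parts.append(ctx_code[flat].astype(np.uint8))
        meth_parts.append(calls)

    if not pos_parts:
        return ReadSet([], np.empty(0, np.int32), np.empty(0, "U1"), np.zeros(1, np.int64),
                       np.empty(0, np.int64), np.empty(0, np.uint8), np.empty(0, bool))
    widths = np.concatenate(ptr_widths)
    return ReadSet(
        chroms,
        np.concatenate(chrom_codes_parts),
        np.concatenate(strand_parts),
        np.concatenate([[0], np.cumsum(widths)]),
        np.concatenate(pos_parts),
        np.concatenate(ctx_parts),
        np.concatenate(meth_parts),
    )


def expected_counts_table(methylome: TrueMethylome, depth: int = 20) -> CytosineTable:
    """Noise-free cytosine table: every site covered ``depth`` times with
    ``round(p * depth)`` methylated reads.

    Useful for deterministic pipeline runs where read-sampling noise is not
    under study (e.g. isolating retention randomness).
    """
    s = methylome.sites
    return CytosineTable(
        pd.DataFrame(
            {
                "chrom": s["chrom"].to_numpy(),
                "pos": s["pos"].to_numpy(),
                "strand": s["strand"].to_numpy(),
                "context": s["context"].to_numpy(),
                "meth": np.rint(s["p"].to_numpy() * depth).astype(np.int64),
                "total": depth,
            }
        )
    )


def true_cytosine_table(methylome: TrueMethylome) -> pd.DataFrame:
    """Context map view (chrom/pos/strand/context) for aggregation."""
    return methylome.sites[["chrom", "pos", "strand", "context"]]


# ---------------------------------------------------------------------------
# output plumbing
# ---------------------------------------------------------------------------


def write_outputs(
    outdir: str | Path,
    genome: Mapping[str, str] | None = None,
    annotation: GeneAnnotation | None = None,
    reads: ReadSet | None = None,
    tables: Mapping[str, CytosineTable] | None = None,
    accessibility: AccessibilityTrack | None = None,
) -> dict[str, Path]:
    """Write simulated artefacts to standard text formats.

    FASTA for the genome, GFF3 (1-based inclusive) for the annotation, the
    cytosine-report TSV per sample, a read-calls TSV and a bedGraph of the
    accessibility covariate.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if genome is not None:
        written["genome"] = hio.write_fasta(genome, outdir / "genome.fa")
    if annotation is not None:
        written["annotation"] = hio.write_gff3(annotation, outdir / "annotation.gff3")
    if reads is not None:
        written["reads"] = hio.write_read_calls(reads, outdir / "read_calls.tsv")
    for name, table in (tables or {}).items():
        written[f"table:{name}"] = hio.write_cytosine_report(
            table, outdir / f"{name}.cytosine_report.tsv"
        )
    if accessibility is not None:
        rows = []
        for chrom, vals in accessibility.values.items():
            starts = np.arange(vals.size) * accessibility.bin_size
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + accessibility.bin_size, "value": vals}
                )
            )
        written["accessibility"] = hio.write_bedgraph(
            pd.concat(rows, ignore_index=True), outdir / "accessibility.bedgraph"
        )
    return written
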