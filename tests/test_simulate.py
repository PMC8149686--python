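"""Generator behaviour: determinism, layout, ground-truth levels, gains,
retention, and read sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from hcgkit import io as hio
from hcgkit.simulate import (
    ConfigError,
    SimConfig,
    eligible_gain_bins,
    propagate_generation,
    sample_reads,
    simulate_baseline_methylome,
    simulate_ectopic_gain,
    simulate_genome,
    write_outputs,
)


class TestGenomeLayout:
    def test_deterministic_outputs_byte_identical(self, small_config, tmp_path):
        for d in ("a", "b"):
            genome, ann, _ = simulate_genome(small_config)
            write_outputs(tmp_path / d, genome=genome, annotation=ann)
        assert (tmp_path / "a/genome.fa").read_bytes() == (tmp_path / "b/genome.fa").read_bytes()
        assert (tmp_path / "a/annotation.gff3").read_bytes() == (tmp_path / "b/annotation.gff3").read_bytes()

    def test_te_confinement_and_gene_count(self):
        cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length_bp=500_000,
                        pericentromere_fraction=0.2, n_genes=100, n_tes=40)
        genome, ann, _ = simulate_genome(cfg)
        lo, hi = cfg.pericentromere()
        assert (hi - lo) == 100_000
        tes = ann.tes()
        assert (tes["start"] >= lo).all() and (tes["end"] <= hi).all()
        assert len(ann.genes()) == 100
        assert len(genome["chr1"]) == 500_000

    def test_genes_do_not_overlap(self, small_world):
        for chrom, grp in small_world["annotation"].genes().groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="pericentromere_fraction"):
            SimConfig(pericentromere_fraction=1.5).validate()
        with pytest.raises(ConfigError, match="coverage_mean"):
            SimConfig(coverage_mean=0).validate()

    def test_accessibility_low_in_pericentromere(self, small_world):
        acc = small_world["accessibility"]
        cfg = small_world["config"]
        lo, hi = cfg.pericentromere()
        v = acc.values["chr1"]
        peri = v[lo // cfg.bin_size: hi // cfg.bin_size]
        arms = np.concatenate([v[: lo // cfg.bin_size], v[hi // cfg.bin_size:]])
        assert peri.mean() < arms.mean() - 0.3


class TestBaselineMethylome:
    def test_no_gbm_limit(self, small_config):
        cfg = dataclasses.replace(small_config, fraction_gbm_genes=0.0)
        genome, ann, _ = simulate_genome(cfg)
        m = simulate_baseline_methylome(genome, ann, cfg)
        s = m.sites
        genes = ann.genes()
        for _, g in genes.iterrows():
            body = s[(s["chrom"] == g["chrom"]) & (s["pos"] - 1 >= g["start"])
                     & (s["pos"] - 1 < g["end"]) & (s["context"] == "CG")]
            assert (body["p"] < 0.01).all()

    def test_chh_background_outside_tes(self, small_world):
        s = small_world["baseline"].sites
        ann = small_world["annotation"]
        chh = s[s["context"] == "CHH"].copy()
        in_te = np.zeros(len(chh), bool)
        for _, te in ann.tes().iterrows():
            in_te |= ((chh["chrom"] == te["chrom"]) & (chh["pos"] - 1 >= te["start"])
                      & (chh["pos"] - 1 < te["end"])).to_numpy()
        assert (chh.loc[~in_te, "p"] == 0.0).all()

    def test_te_cg_level_matches_config(self):
        cfg = SimConfig(seed=21, n_chromosomes=1, chrom_length_bp=400_000,
                        pericentromere_fraction=0.5, n_genes=60, n_tes=120,
                        te_length_range=(800, 2000))
        genome, ann, _ = simulate_genome(cfg)
        s = simulate_baseline_methylome(genome, ann, cfg).sites
        in_te = np.zeros(len(s), bool)
        for _, te in ann.tes().iterrows():
            in_te |= ((s["chrom"] == te["chrom"]) & (s["pos"] - 1 >= te["start"])
                      & (s["pos"] - 1 < te["end"])).to_numpy()
        cg = s[in_te & (s["context"] == "CG").to_numpy()]
        assert len(cg) >= 10_000
        assert abs(cg["p"].mean() - cfg.te_levels[0]) <= 0.02

    def test_gbm_dome_peaks_mid_body(self, small_world):
        """The gbM weight must peak between 40% and 80% of gene length."""
        from hcgkit.simulate import _dome

        x = np.linspace(0, 1, 1001)
        peak = x[np.argmax(_dome(x))]
        assert 0.4 <= peak <= 0.8
        assert _dome(np.array([peak])).max() <= 1.0 + 1e-9


class TestEctopicGain:
    def test_zero_rate_is_identity(self, small_world):
        cfg = dataclasses.replace(small_world["config"], ectopic_gain_rate=0.0)
        out = simulate_ectopic_gain(
            small_world["baseline"], small_world["annotation"],
            small_world["accessibility"], cfg, seed=1,
        )
        assert out.gain_registry == []
        assert (out.sites["p"] == small_world["baseline"].sites["p"]).all()

    def test_non_cg_untouched(self, small_world):
        base, gained = small_world["baseline"], small_world["gained"]
        non_cg = base.sites["context"] != "CG"
        assert (gained.sites.loc[non_cg, "p"].to_numpy()
                == base.sites.loc[non_cg, "p"].to_numpy()).all()

    def test_gains_prefer_low_accessibility(self):
        cfg = SimConfig(seed=5, n_chromosomes=2, chrom_length_bp=200_000,
                        n_genes=120, n_tes=50, ectopic_gain_rate=0.15,
                        accessibility_bias=2.0)
        genome, ann, acc = simulate_genome(cfg)
        base = simulate_baseline_methylome(genome, ann, cfg)
        gained = simulate_ectopic_gain(base, ann, acc, cfg, seed=2)
        assert len(gained.gain_registry) >= 200
        gained_acc = np.array(
            [acc.at_bins(g.chrom, np.array([g.start]))[0] for g in gained.gain_registry]
        )
        assert gained_acc.mean() < acc.genome_mean()

    def test_saturated_bins_never_gain(self, small_world):
        base, gained = small_world["baseline"], small_world["gained"]
        cfg = small_world["config"]
        s = base.sites
        cg = s[s["context"] == "CG"]
        for g in gained.gain_registry:
            sel = (cg["chrom"] == g.chrom) & (cg["pos"] - 1 >= g.start) & (cg["pos"] - 1 < g.end)
            assert (cg.loc[sel, "p"] < 0.9).any()  # at least one eligible site

    def test_registry_matches_elevated_sites(self, small_world):
        base, gained = small_world["baseline"], small_world["gained"]
        cfg = small_world["config"]
        raised = gained.sites["p"] > base.sites["p"]
        bins = set(
            zip(
                base.sites.loc[raised, "chrom"],
                ((base.sites.loc[raised, "pos"] - 1) // cfg.bin_size) * cfg.bin_size,
            )
        )
        assert bins == {g.bin_id for g in gained.gain_registry}


class TestPropagation:
    def test_r_one_keeps_everything(self, small_world):
        out = propagate_generation(small_world["gained"], 1.0, seed=4)
        assert all(g.retained for g in out.gain_registry)
        assert (out.sites["p"] == small_world["gained"].sites["p"]).all()

    def test_r_zero_reverts_to_baseline(self, small_world):
        out = propagate_generation(small_world["gained"], 0.0, seed=4)
        assert not any(g.retained for g in out.gain_registry)
        assert (out.sites["p"] == small_world["baseline"].sites["p"]).all()

    def test_lost_stays_lost_and_no_new_regions(self, small_world):
        g1 = propagate_generation(small_world["gained"], 0.5, seed=4)
        g2 = propagate_generation(g1, 0.5, seed=5)
        lost1 = {g.bin_id for g in g1.gain_registry if not g.retained}
        lost2 = {g.bin_id for g in g2.gain_registry if not g.retained}
        assert lost1 <= lost2
        assert len(g2.gain_registry) == len(small_world["gained"].gain_registry)

    def test_retention_count_in_binomial_band(self):
        """1000 regions at r=0.8: retained count inside the exact 99% band."""
        cfg = SimConfig(seed=9, n_chromosomes=2, chrom_length_bp=400_000,
                        n_genes=240, n_tes=100)
        genome, ann, acc = simulate_genome(cfg)
        base = simulate_baseline_methylome(genome, ann, cfg)
        n_eligible = len(eligible_gain_bins(base, cfg))
        cfg2 = dataclasses.replace(cfg, ectopic_gain_rate=1000 / n_eligible)
        est = simulate_ectopic_gain(base, ann, acc, cfg2, seed=10)
        assert len(est.gain_registry) == 1000
        nxt = propagate_generation(est, 0.8, seed=11)
        kept = len(nxt.retained_regions())
        lo = stats.binom.ppf(0.005, 1000, 0.8)
        hi = stats.binom.ppf(0.995, 1000, 0.8)
        assert lo <= kept <= hi

    def test_invalid_r(self, small_world):
        with pytest.raises(ValueError):
            propagate_generation(small_world["gained"], 1.5, seed=0)


class TestReadSampling:
    def test_all_unmethylated_limit(self, small_world):
        base = small_world["baseline"].copy()
        base.sites["p"] = 0.0
        cfg = dataclasses.replace(small_world["config"], nonconversion_read_fraction=0.0,
                                  coverage_mean=2.0)
        reads = sample_reads(base, cfg, seed=1)
        assert reads.meth.sum() == 0

    def test_bernoulli_law_at_high_depth(self):
        """Observed level at a p=0.5 site converges at 10^4 depth."""
        import pandas as pd

        from hcgkit.calling import aggregate_cytosines
        from hcgkit.simulate import TrueMethylome, true_cytosine_table

        sites = pd.DataFrame(
            {
                "chrom": "chr1", "pos": np.arange(1, 22), "strand": "+",
                "context": "CG", "trinucleotide": "CGA",
                "p_base": 0.5, "p": 0.5,
            }
        )
        m = TrueMethylome(sites)
        cfg = SimConfig(coverage_mean=10_000.0, read_length_cytosines=21,
                        nonconversion_read_fraction=0.0)
        reads = sample_reads(m, cfg, seed=2)
        table = aggregate_cytosines(reads, true_cytosine_table(m))
        site = table.df[table.df["pos"] == 11].iloc[0]
        assert site["total"] >= 10_000
        assert abs(site["meth"] / site["total"] - 0.5) <= 0.02

    def test_seed_determinism(self, small_world):
        cfg = small_world["config"]
        a = sample_reads(small_world["gained"], cfg, seed=42)
        b = sample_reads(small_world["gained"], cfg, seed=42)
        assert (a.pos == b.pos).all() and (a.meth == b.meth).all()
        assert (a.indptr == b.indptr).all()

    def test_depth_approximately_poisson(self, small_world):
        cfg = dataclasses.replace(small_world["config"], coverage_mean=6.0)
        reads = sample_reads(small_world["baseline"], cfg, seed=3)
        from hcgkit.calling import aggregate_cytosines
        from hcgkit.simulate import true_cytosine_table

        table = aggregate_cytosines(reads, true_cytosine_table(small_world["baseline"]))
        mean_depth = table.df["total"].mean()
        assert abs(mean_depth - 6.0) < 0.5
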