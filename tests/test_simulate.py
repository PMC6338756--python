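"""Simulator contracts: determinism, SNV statistics, truth structure,
read geometry and conversion chemistry."""

import numpy as np
import pytest

from hybridmeth import SimConfig, generate_genomes, simulate_reads, simulate_study
from hybridmeth.config import PlantedDMR, SampleSpec, default_samples
from hybridmeth.genome import C, G, T, cpg_positions
from hybridmeth.reads import OT
from hybridmeth.simulate import assign_methylation

TINY_SAMPLES = (
    SampleSpec("p1a", "P1", "M", "sire"),
    SampleSpec("p1b", "P1", "F", "dam"),
    SampleSpec("p2a", "P2", "M", "sire"),
    SampleSpec("p2b", "P2", "F", "dam"),
    SampleSpec("f1a", "F1_P1xP2", "F", "virgin"),
    SampleSpec("f1b", "F1_P2xP1", "M", "virgin"),
)


def tiny_config(**kw):
    base = dict(
        seed=5,
        n_chroms=1,
        chrom_length=50_000,
        cpg_island_count=3,
        depth=8,
        samples=TINY_SAMPLES,
        dmr_specs=(),
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_rejects_invalid_rates_and_ids(self):
        with pytest.raises(ValueError):
            SimConfig(conversion_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(bio_sd=-0.1)
        with pytest.raises(ValueError):
            SimConfig(depth=0)
        dup = (TINY_SAMPLES[0], TINY_SAMPLES[0])
        with pytest.raises(ValueError):
            SimConfig(samples=dup)

    def test_default_design_is_the_24_animal_cross(self):
        samples = default_samples()
        assert len(samples) == 24
        assert sum(s.genotype == "P1" for s in samples) == 6
        assert sum(s.is_f1 for s in samples) == 12
        assert sum(s.parity == "dam" for s in samples) == 6


class TestGenomes:
    def test_same_seed_identical_assemblies(self):
        cfg = tiny_config()
        g1 = generate_genomes(cfg)
        g2 = generate_genomes(cfg)
        for chrom in cfg.chrom_names:
            assert np.array_equal(g1.p1[chrom], g2.p1[chrom])
            assert np.array_equal(g1.p2[chrom], g2.p2[chrom])
        assert g1.snvs.equals(g2.snvs)

    def test_zero_snv_rate_identical_strains(self):
        g = generate_genomes(tiny_config(snv_rate=0.0))
        assert len(g.snvs) == 0
        assert np.array_equal(g.p1["chr1"], g.p2["chr1"])

    def test_snv_count_poisson(self):
        cfg = tiny_config(chrom_length=1_000_000, snv_rate=1 / 1000)
        g = generate_genomes(cfg)
        lam = 1000.0
        assert abs(len(g.snvs) - lam) < 4 * np.sqrt(lam)

    def test_assemblies_differ_only_at_snvs(self):
        g = generate_genomes(tiny_config())
        diff = np.flatnonzero(g.p1["chr1"] != g.p2["chr1"])
        assert np.array_equal(np.sort(diff), np.sort(g.snvs["pos"].to_numpy()))

    def test_some_snvs_disrupt_cpgs(self):
        g = generate_genomes(tiny_config())
        p1_cpg = set(cpg_positions(g.p1["chr1"]).tolist())
        p2_cpg = set(cpg_positions(g.p2["chr1"]).tolist())
        assert p1_cpg - p2_cpg, "no CpGs destroyed in P2"
        assert p2_cpg - p1_cpg, "no CpGs created in P2"


class TestTruth:
    def test_zero_bio_sd_replicates_identical(self):
        cfg = tiny_config(bio_sd=0.0)
        truth = assign_methylation(cfg, generate_genomes(cfg))
        a = truth.truth_for("p1a", "P1", "chr1")
        b = truth.truth_for("p1b", "P1", "chr1")
        assert np.array_equal(a, b)

    def test_cis_genotype_dmr_exact_delta_in_f1(self):
        cfg = tiny_config(bio_sd=0.0)
        genomes = generate_genomes(cfg)
        dmr = PlantedDMR("chr1", 10_000, 11_000, "genotype", "P1", 0.5)
        truth = assign_methylation(cfg, genomes, planted_dmrs=[dmr])
        pos = truth.sites["chr1"]
        inside = (pos >= 10_000) & (pos < 11_000)
        h1 = truth.truth_for("f1a", "P1", "chr1")
        h2 = truth.truth_for("f1a", "P2", "chr1")
        assert np.allclose((h1 - h2)[inside], 0.5)
        assert np.allclose((h1 - h2)[~inside], 0.0)

    def test_sex_dmr_affects_all_females_equally(self):
        cfg = tiny_config(bio_sd=0.0)
        genomes = generate_genomes(cfg)
        dmr = PlantedDMR("chr1", 20_000, 21_000, "sex", "F", 0.4)
        truth = assign_methylation(cfg, genomes, planted_dmrs=[dmr])
        pos = truth.sites["chr1"]
        inside = (pos >= 20_000) & (pos < 21_000)
        dam = truth.truth_for("p1b", "P1", "chr1")[inside]
        virgin_f = truth.truth_for("f1a", "P1", "chr1")[inside]
        male = truth.truth_for("p1a", "P1", "chr1")[inside]
        assert np.allclose(dam, virgin_f)
        assert np.allclose(dam - male, 0.4)

    def test_rejects_overlapping_or_out_of_bounds_dmrs(self):
        cfg = tiny_config()
        genomes = generate_genomes(cfg)
        overlapping = [
            PlantedDMR("chr1", 1000, 2000, "genotype", "P1", 0.5),
            PlantedDMR("chr1", 1500, 2500, "genotype", "P2", 0.5),
        ]
        with pytest.raises(ValueError):
            assign_methylation(cfg, genomes, planted_dmrs=overlapping)
        with pytest.raises(ValueError):
            assign_methylation(
                cfg,
                genomes,
                planted_dmrs=[PlantedDMR("chr1", 49_500, 50_600, "sex", "M", 0.5)],
            )

    def test_islands_hypomethylated_background_high(self):
        cfg = tiny_config(bio_sd=0.0)
        genomes = generate_genomes(cfg)
        truth = assign_methylation(cfg, genomes)
        pos = truth.sites["chr1"]
        vals = truth.truth_for("p1a", "P1", "chr1")
        isl = genomes.islands
        in_island = np.zeros(pos.size, dtype=bool)
        for s, e in zip(isl["start"], isl["end"]):
            in_island |= (pos >= s) & (pos < e)
        assert np.allclose(vals[in_island], cfg.island_meth)
        assert np.allclose(vals[~in_island], cfg.background_meth)


class TestReads:
    def test_determinism_and_fragment_conservation(self):
        cfg = tiny_config()
        study = simulate_study(cfg)
        s = cfg.samples[0]
        b1 = study.batches[s.sample_id]
        b2 = simulate_reads(study.truth, s, cfg)
        assert np.array_equal(b1.r1_seq, b2.r1_seq)
        assert np.array_equal(b1.frag_start, b2.frag_start)
        n_auto = int(
            (b1.chrom_idx < cfg.n_chroms).sum()
        )
        expected = round(cfg.depth * cfg.genome_length / cfg.fragment_length_mean)
        assert n_auto == expected

    def test_full_conversion_reads_all_c_as_t_on_ot(self):
        cfg = tiny_config(
            conversion_rate=1.0,
            error_rate=0.0,
            island_meth=0.0,
            background_meth=0.0,
            bio_sd=0.0,
        )
        study = simulate_study(cfg)
        b = study.batches["p1a"]
        sel = (b.strand == OT) & (b.chrom_idx == 0)
        g = study.genomes.p1["chr1"]
        sub = b.subset(sel)
        pos = sub.r1_pos[:, None] + np.arange(cfg.read_length)
        genomic_c = g[pos] == C
        assert (sub.r1_seq[genomic_c] == T).all()

    def test_error_free_xm_marks_every_haplotype_cpg(self):
        cfg = tiny_config(error_rate=0.0)
        study = simulate_study(cfg)
        b = study.batches["p1a"].subset(
            (study.batches["p1a"].strand == OT) & (study.batches["p1a"].chrom_idx == 0)
        )
        g = study.genomes.p1["chr1"]
        pos = b.r1_pos[:, None] + np.arange(cfg.read_length)
        is_cpg_c = (g[pos] == C) & (g[np.minimum(pos + 1, g.size - 1)] == G) & (
            pos + 1 < g.size
        )
        xm = b.r1_xm
        assert np.isin(xm[is_cpg_c], [ord("z"), ord("Z")]).all()

    def test_f1_haplotypes_bernoulli_half(self):
        cfg = tiny_config(depth=20)
        study = simulate_study(cfg)
        b = study.batches["f1a"]
        n = b.n_fragments
        frac = b.hap.mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_fragment_coverage_matches_depth(self, study_small):
        cfg = study_small.config
        b = study_small.batches[cfg.samples[0].sample_id]
        sites = study_small.truth.sites["chr1"]
        sites = sites[(sites > 1000) & (sites < cfg.chrom_length - 1000)]
        assert sites.size >= 10_000
        auto = b.subset(b.chrom_idx == 0)
        events = np.zeros(cfg.chrom_length + 1, dtype=np.int64)
        np.add.at(events, auto.frag_start, 1)
        np.add.at(events, auto.frag_start + auto.frag_len, -1)
        cov = np.cumsum(events)[:-1]
        mean_cov = cov[sites].mean()
        assert abs(mean_cov - cfg.depth) / cfg.depth < 0.05

    def test_deep_sequencing_recovers_truth(self):
        cfg = tiny_config(
            chrom_length=30_000, depth=300, error_rate=0.0, samples=TINY_SAMPLES[:1]
        )
        study = simulate_study(cfg)
        s = cfg.samples[0]
        b = study.batches[s.sample_id]
        sites = study.truth.sites["chr1"]
        app = study.truth.apparent_truth(s, "chr1")
        # empirical fraction from raw CpG calls (no validation needed here)
        meth = np.zeros(sites.size)
        depth = np.zeros(sites.size)
        for read, xmat in ((1, b.r1_xm), (2, b.r2_xm)):
            rows, cols, pos = b.read_cells(read)
            keep = b.chrom_idx[rows] == 0
            rows, cols, pos = rows[keep], cols[keep], pos[keep]
            xm = xmat[rows, cols]
            z = (xm == ord("z")) | (xm == ord("Z"))
            site = pos[z] - (b.strand[rows[z]] == 1)
            idx = np.searchsorted(sites, site)
            ok = (idx < sites.size) & (sites[np.minimum(idx, sites.size - 1)] == site)
            np.add.at(depth, idx[ok], 1)
            np.add.at(meth, idx[ok], (xm[z][ok] == ord("Z")).astype(float))
        covered = depth >= 150
        emp = meth[covered] / depth[covered]
        frac_close = np.mean(np.abs(emp - app[covered]) < 0.1)
        assert frac_close >= 0.99
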