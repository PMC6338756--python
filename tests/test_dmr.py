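"""DMC/DMR calling: exact-test oracles, segmentation recovery,
the filter suite, and summary statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hybridmeth.config import SampleSpec
from hybridmeth.dmr import (
    DMRegion,
    GroupComparison,
    call_dmcs,
    export_dmrs,
    filter_dmrs,
    import_dmrs,
    quartile_groups,
    reported,
    score_matrix,
    segment_dmrs,
    summarize,
)
from hybridmeth.pipeline import comparisons, dmr_recovery
from hybridmeth.quantify import MethylationCounts
from hybridmeth.stats import fisher_exact_2x2, rank_sum_test


def make_counts(meth, depth, spacing=50, sample_prefixes=("a", "b")):
    meth = np.asarray(meth)
    depth = np.asarray(depth)
    n_sites, n_samples = meth.shape
    half = n_samples // 2
    samples = [
        SampleSpec(f"{sample_prefixes[0]}{i}", "P1", "M", "sire") for i in range(half)
    ] + [
        SampleSpec(f"{sample_prefixes[1]}{i}", "P2", "M", "sire")
        for i in range(n_samples - half)
    ]
    comp = GroupComparison(
        "test",
        tuple(s.sample_id for s in samples[:half]),
        tuple(s.sample_id for s in samples[half:]),
    )
    counts = MethylationCounts(
        samples=samples,
        chroms=["c"],
        positions={"c": np.arange(n_sites) * spacing},
        meth={"c": meth.astype(np.int32)},
        depth={"c": depth.astype(np.int32)},
    )
    return counts, comp


# ----------------------------------------------------------------------
# statistical oracles
# ----------------------------------------------------------------------
def fisher_oracle(a, b, c, d):
    """Brute-force hypergeometric two-sided p: sum of all table
    probabilities not exceeding the observed one."""
    n1, n2, k = a + b, c + d, a + c
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = sps.hypergeom.pmf(support, n1 + n2, n1, k)
    p_obs = sps.hypergeom.pmf(a, n1 + n2, n1, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestExactTestOracles:
    def test_fisher_matches_enumeration_exhaustive_small(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b == 0 or c + d == 0:
                            continue
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-12
                        )

    def test_fisher_matches_enumeration_margins_to_50(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 26, size=4)
            if a + b == 0 or c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
            )

    def test_rank_sum_matches_924_split_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            data = rng.normal(size=12)
            x, y = data[:6], data[6:]
            p = rank_sum_test(x, y)
            ranks = sps.rankdata(data)
            u_obs = ranks[:6].sum() - 21
            us = np.array(
                [
                    ranks[list(comb)].sum() - 21
                    for comb in itertools.combinations(range(12), 6)
                ]
            )
            assert us.size == 924
            p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
            assert p == pytest.approx(p_enum, abs=1e-12)


# ----------------------------------------------------------------------
# DMC calling
# ----------------------------------------------------------------------
class TestDMC:
    def test_total_separation_is_dmc(self):
        meth = np.array([[10, 10, 10, 0, 0, 0]])
        depth = np.full((1, 6), 10)
        counts, comp = make_counts(meth, depth)
        dmcs = call_dmcs(counts, comp)
        assert len(dmcs) == 1
        assert dmcs["diff"].iloc[0] == pytest.approx(1.0)
        assert dmcs["p_value"].iloc[0] < 1e-6

    def test_identical_groups_not_dmc(self):
        meth = np.full((5, 6), 5)
        depth = np.full((5, 6), 10)
        counts, comp = make_counts(meth, depth)
        assert len(call_dmcs(counts, comp)) == 0

    def test_small_difference_rejected_despite_significance(self):
        # diff 0.15 with overwhelming counts -> still not a DMC
        meth = np.array([[650, 650, 650, 500, 500, 500]])
        depth = np.full((1, 6), 1000)
        counts, comp = make_counts(meth, depth)
        assert len(call_dmcs(counts, comp)) == 0
        pooled_p = fisher_exact_2x2(1950, 1050, 1500, 1500)
        assert pooled_p < 1e-6  # significance alone would have passed

    def test_sites_uncovered_in_one_group_skipped(self):
        meth = np.array([[10, 10, 10, 0, 0, 0]])
        depth = np.array([[10, 10, 10, 0, 0, 0]])
        counts, comp = make_counts(meth, depth)
        assert len(call_dmcs(counts, comp)) == 0


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------
def _simulated_block_counts(seed, n_sites=400, dmr_blocks=(), depth=20,
                            p_bg=0.8, n_per_group=6, bio_sd=0.05):
    """Binomial counts with rectangular planted differences."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    p = np.full((n_sites, n), p_bg)
    for lo, hi, pa, pb in dmr_blocks:
        p[lo:hi, :n_per_group] = pa
        p[lo:hi, n_per_group:] = pb
    p = np.clip(p + rng.normal(0, bio_sd, size=(1, n)), 0.01, 0.99)
    d = rng.poisson(depth, size=(n_sites, n)).clip(min=1)
    m = rng.binomial(d, p)
    return make_counts(m, d)


class TestSegmentation:
    def test_recovers_planted_block(self):
        counts, comp = _simulated_block_counts(
            1, dmr_blocks=[(100, 110, 0.75, 0.25)]
        )
        out = reported(segment_dmrs(counts, comp))
        assert len(out) == 1
        r = out[0]
        assert r.polarity == "a>b"
        # boundaries within 2 sites (site spacing 50)
        assert abs(r.start - 100 * 50) <= 100
        assert abs(r.end - (110 * 50 + 2)) <= 100

    def test_flat_signal_yields_no_candidates(self):
        for seed in range(5):
            counts, comp = _simulated_block_counts(100 + seed, n_sites=2000)
            assert segment_dmrs(counts, comp) == []

    def test_adjacent_opposite_polarity_blocks_both_found(self):
        counts, comp = _simulated_block_counts(
            2,
            dmr_blocks=[(100, 110, 0.8, 0.3), (130, 140, 0.3, 0.8)],
        )
        out = reported(segment_dmrs(counts, comp))
        assert sorted(r.polarity for r in out) == ["a>b", "b>a"]

    def test_candidates_do_not_overlap(self):
        counts, comp = _simulated_block_counts(
            3, dmr_blocks=[(50, 60, 0.8, 0.3), (80, 95, 0.2, 0.7), (200, 215, 0.9, 0.4)]
        )
        out = sorted(reported(segment_dmrs(counts, comp)), key=lambda r: r.start)
        for r1, r2 in zip(out, out[1:]):
            assert r1.end <= r2.start

    def test_max_gap_splits_runs(self):
        # same signal, but a 400 bp gap inside the planted block splits it
        counts, comp = _simulated_block_counts(4, dmr_blocks=[(100, 120, 0.8, 0.2)])
        pos = counts.positions["c"].copy()
        pos[110:] += 400
        counts.positions["c"] = pos
        out = reported(segment_dmrs(counts, comp))
        assert len(out) == 2

    def test_recovery_on_full_simulation(self, counts_small, study_small):
        _, counts = counts_small
        comp = comparisons(study_small.config)["genotype"]
        called = filter_dmrs(segment_dmrs(counts, comp), counts, comp)
        rec = dmr_recovery(called, study_small.truth.planted_dmrs, counts, "genotype")
        assert rec.sensitivity >= 0.9
        assert rec.false_discovery_proportion <= 0.1
        assert np.median(rec.boundary_offsets_cpg) <= 2

    def test_polarity_balance_under_symmetric_planting(self, counts_small, study_small):
        _, counts = counts_small
        comp = comparisons(study_small.config)["genotype"]
        called = reported(filter_dmrs(segment_dmrs(counts, comp), counts, comp))
        planted = [d for d in study_small.truth.planted_dmrs if d.axis == "genotype"]
        rec = {"P1": 0, "P2": 0}
        tot = {"P1": 0, "P2": 0}
        for t in planted:
            tot[t.polarity] += 1
            if any(r.overlaps(t.chrom, t.start, t.end) for r in called):
                rec[t.polarity] += 1
        p = fisher_exact_2x2(rec["P1"], tot["P1"] - rec["P1"], rec["P2"], tot["P2"] - rec["P2"])
        assert p > 0.01


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------
def _filter_fixture():
    """Ten candidates over a designed count matrix, one violating each
    filter; returns (counts, comp, candidates, expected_flags)."""
    rng = np.random.default_rng(9)
    n_sites = 200
    depth = np.full((n_sites, 6), 30)
    p = np.full((n_sites, 6), 0.5)
    # candidate regions are 10 sites each, spaced apart (spacing 50 bp)
    region = lambda k: (k * 20, k * 20 + 10)
    # region 0: clean pass (diff 0.5)
    p[0:10, :3], p[0:10, 3:] = 0.8, 0.3
    # region 1: only 4 CpGs worth of signal -> trimmed candidate (min_cpgs)
    # we'll instead shrink the candidate interval below
    p[20:30, :3], p[20:30, 3:] = 0.8, 0.3
    # region 2: weak diff 0.1 -> min_diff flag
    p[40:50, :3], p[40:50, 3:] = 0.55, 0.45
    # region 3: huge depth in both groups (imbalance < 5x) -> depth_cap flag
    p[60:70, :3], p[60:70, 3:] = 0.8, 0.3
    depth[60:70, :3] = 600
    depth[60:70, 3:] = 400
    # region 4: depth ratio 6 -> depth_ratio flag
    p[80:90, :3], p[80:90, 3:] = 0.8, 0.3
    depth[80:90, :3] = 120
    depth[80:90, 3:] = 20
    # region 5: no coverage in group b -> low_coverage flag
    p[100:110, :3], p[100:110, 3:] = 0.8, 0.3
    depth[100:110, 3:] = 0
    # regions 6..9: clean passes
    for k in (6, 7, 8, 9):
        lo, hi = region(k)
        p[lo:hi, :3], p[lo:hi, 3:] = 0.9, 0.2
    meth = rng.binomial(depth, p)
    counts, comp = make_counts(meth, depth, spacing=50)

    def cand(k, n_cpg=10):
        lo, hi = region(k)
        return DMRegion(chrom="c", start=lo * 50, end=(lo + n_cpg - 1) * 50 + 2,
                        polarity="a>b")

    candidates = [
        cand(0),
        cand(1, n_cpg=4),
        cand(2),
        cand(3),
        cand(4),
        cand(5),
        cand(6),
        cand(7),
        cand(8),
        cand(9),
    ]
    expected_flags = {
        0: set(),
        1: {"min_cpgs"},
        2: {"min_diff"},
        3: {"depth_cap"},
        4: {"depth_ratio"},
        5: {"low_coverage", "min_diff"},
        6: set(),
        7: set(),
        8: set(),
        9: set(),
    }
    return counts, comp, candidates, expected_flags


class TestFilters:
    def test_each_filter_flags_its_violator(self):
        counts, comp, candidates, expected = _filter_fixture()
        out = filter_dmrs(candidates, counts, comp)
        for i, r in enumerate(out):
            assert r.filter_flags == expected[i], f"candidate {i}: {r.filter_flags}"
        survivors = [i for i, r in enumerate(out) if r.passed]
        assert survivors == [0, 6, 7, 8, 9]

    def test_filtering_is_idempotent(self):
        counts, comp, candidates, _ = _filter_fixture()
        once = filter_dmrs(candidates, counts, comp)
        twice = filter_dmrs(once, counts, comp)
        key = lambda r: (r.start, r.end, sorted(r.filter_flags), repr(round(r.diff, 12)))
        assert [key(r) for r in once] == [key(r) for r in twice]

    def test_import_export_round_trip(self, tmp_path):
        counts, comp, candidates, _ = _filter_fixture()
        out = filter_dmrs(candidates, counts, comp)
        path = tmp_path / "dmrs.bed"
        export_dmrs(reported(out), str(path))
        back = import_dmrs(str(path))
        assert [(r.chrom, r.start, r.end) for r in back] == [
            (r.chrom, r.start, r.end) for r in reported(out)
        ]
        assert all(r.source == "imported" for r in back)
        refiltered = filter_dmrs(back, counts, comp)
        assert all(r.passed for r in refiltered)
        assert all(r.n_cpgs >= 5 for r in refiltered)

    def test_import_malformed_lines_reported(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("c\t10\t100\nc\tnope\t200\nc\t50\t40\n")
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            import_dmrs(str(path))

    def test_import_zero_cpg_interval_flagged(self, tmp_path):
        counts, comp, _, _ = _filter_fixture()
        path = tmp_path / "z.bed"
        path.write_text("c\t9950\t9980\n")  # beyond the last site
        out = filter_dmrs(import_dmrs(str(path)), counts, comp)
        assert not out[0].passed and "min_cpgs" in out[0].filter_flags


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------
class TestSummaries:
    def _toy(self):
        dmcs = pd.DataFrame(
            {
                "chrom": ["c"] * 10,
                "pos": [5, 15, 25, 35, 45, 55, 500, 600, 700, 800],
            }
        )
        dmrs = [
            DMRegion("c", 0, 60, "a>b", n_cpgs=6),
        ]
        return dmcs, dmrs

    def test_pct_dmcs_in_dmrs(self):
        dmcs, dmrs = self._toy()
        s = summarize(dmcs, dmrs, genome_size=1_000_000)
        assert s["dmcs_in_dmrs"] == 6
        assert s["pct_dmcs_in_dmrs"] == pytest.approx(60.0)
        assert s["pct_dmr_cpgs_dmc"] == pytest.approx(100.0)

    def test_genome_fraction(self):
        dmcs, _ = self._toy()
        dmrs = [DMRegion("c", 0, 1000, "a>b", n_cpgs=10)]
        s = summarize(dmcs, dmrs, genome_size=1_000_000)
        assert s["dmr_pct_genome"] == pytest.approx(0.1)

    def test_no_dmrs_degenerate(self):
        dmcs, _ = self._toy()
        s = summarize(dmcs, [], genome_size=1_000_000)
        assert s["n_dmrs"] == 0
        assert s["pct_dmcs_in_dmrs"] == 0.0
        assert s["dmr_pct_genome"] == 0.0

    def test_score_matrix_shape_and_quartiles(self):
        counts, comp, candidates, _ = _filter_fixture()
        out = reported(filter_dmrs(candidates, counts, comp))
        mat = score_matrix(out, counts)
        assert mat.shape == (len(out), len(counts.samples))
        q = quartile_groups(out, mat, comp)
        sizes = q.groupby(["polarity", "quartile"]).size()
        for pol in q["polarity"].unique():
            s = sizes[pol]
            assert s.max() - s.min() <= 1

    def test_zero_depth_cell_is_nan(self):
        counts, comp, candidates, _ = _filter_fixture()
        counts.depth["c"][0:10, 0] = 0
        mat = score_matrix([candidates[0]], counts)
        assert np.isnan(mat.iloc[0, 0])
        assert np.isfinite(mat.iloc[0, 1])
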