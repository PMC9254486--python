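import subprocess

import numpy as np
import pytest
from scipy import stats

import rloopscape as rl
from rloopscape.enrichment import UnplaceablePeakError

from conftest import iv


def perbase_overlap(a, b):
    """Independent per-bp set oracle for the overlap statistic."""
    cov_a = {(p.chrom, x) for p in a for x in range(p.start, p.end)}
    cov_b = {(p.chrom, x) for p in b for x in range(p.start, p.end)}
    return len(cov_a & cov_b)


class TestOverlapStatistic:
    def test_disjoint_and_identical(self):
        a = [iv("c", 0, 100), iv("c", 500, 600)]
        assert rl.overlap_statistic(a, [iv("c", 200, 300)]) == 0
        assert rl.overlap_statistic(a, a) == 200

    def test_nested_toy_against_perbase_oracle(self):
        a = [iv("c", 0, 100), iv("c", 50, 150), iv("c", 140, 200)]
        b = [iv("c", 80, 160)]
        # merged a covers [0,200); intersection with [80,160) is 80 bp
        assert rl.overlap_statistic(a, b) == perbase_overlap(a, b) == 80

    def test_random_sets_match_perbase_oracle(self):
        rng = np.random.default_rng(0)
        layout = rl.GenomeLayout({"c": 3000, "d": 1000})
        for _ in range(40):
            def draw(n):
                out = []
                for _ in range(n):
                    chrom = "c" if rng.random() < 0.7 else "d"
                    s = int(rng.integers(0, layout[chrom] - 200))
                    out.append(iv(chrom, s, s + int(rng.integers(1, 200))))
                return out

            a, b = draw(int(rng.integers(1, 10))), draw(int(rng.integers(1, 10)))
            assert rl.overlap_statistic(a, b, layout) == perbase_overlap(a, b)

    def test_matches_bedtools_on_fixture(self, tmp_path):
        rng = np.random.default_rng(1)
        a = [iv("c", int(s), int(s + l)) for s, l in
             zip(rng.integers(0, 5000, 12), rng.integers(10, 400, 12))]
        b = [iv("c", int(s), int(s + l)) for s, l in
             zip(rng.integers(0, 5000, 9), rng.integers(10, 400, 9))]
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        rl.write_bed(sorted(a, key=lambda x: x.start), fa)
        rl.write_bed(sorted(b, key=lambda x: x.start), fb)
        try:
            merged_a = subprocess.run(
                ["bedtools", "merge", "-i", str(fa)], capture_output=True, text=True, check=True
            ).stdout
            (tmp_path / "am.bed").write_text(merged_a)
            merged_b = subprocess.run(
                ["bedtools", "merge", "-i", str(fb)], capture_output=True, text=True, check=True
            ).stdout
            (tmp_path / "bm.bed").write_text(merged_b)
            out = subprocess.run(
                ["bedtools", "intersect", "-a", str(tmp_path / "am.bed"),
                 "-b", str(tmp_path / "bm.bed")],
                capture_output=True, text=True, check=True,
            ).stdout
        except FileNotFoundError:
            pytest.skip("bedtools not on PATH")
        expected = sum(
            int(l.split("\t")[2]) - int(l.split("\t")[1])
            for l in out.strip().splitlines()
            if l
        )
        assert rl.overlap_statistic(a, b) == expected


class TestShuffle:
    def test_forced_placement_single_slot(self):
        layout = rl.GenomeLayout({"c": 1000})
        mask = rl.RegionMask([iv("c", 0, 400), iv("c", 500, 1000)])
        shuffled, _ = rl.shuffle_once([iv("c", 0, 100, "+", "pk")], mask, layout, rng=0)
        assert (shuffled[0].start, shuffled[0].end) == (400, 500)

    def test_unplaceable_peak_named(self):
        layout = rl.GenomeLayout({"c": 1000})
        mask = rl.RegionMask([iv("c", 400, 600)])
        with pytest.raises(UnplaceablePeakError, match="big_peak"):
            rl.shuffle_once([iv("c", 0, 500, "+", "big_peak")], mask, layout, rng=0)

    def test_lengths_preserved_and_mask_avoided(self, dataset):
        peaks = dataset.tracks.rloops["S2"][:100]
        shuffled, frac = rl.shuffle_once(peaks, dataset.mask, dataset.layout, rng=3)
        assert frac == 1.0
        assert sorted(len(p) for p in shuffled) == sorted(len(p) for p in peaks)
        for p in shuffled:
            assert not dataset.mask.overlaps(p.chrom, p.start, p.end)
            dataset.layout.validate(p)

    def test_placement_uniform_over_valid_starts(self):
        # small genome, exhaustive enumeration of valid starts, chi-square
        layout = rl.GenomeLayout({"c": 120, "d": 60})
        mask = rl.RegionMask([iv("c", 40, 50)])
        L = 10
        valid = []
        for chrom, s, e in mask.free_gaps(layout):
            valid += [(chrom, p) for p in range(s, e - L + 1)]
        free = rl.FreeSpace(layout, mask)
        rng = np.random.default_rng(11)
        draws = free.sample_starts(L, 10_000, rng)
        observed = {}
        for g in draws:
            observed[free.to_local(int(g))] = observed.get(free.to_local(int(g)), 0) + 1
        assert set(observed) <= set(valid)
        counts = np.array([observed.get(v, 0) for v in valid])
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=len(valid) - 1)
        assert p > 0.001

    def test_per_chromosome_placement(self):
        layout = rl.GenomeLayout({"c": 10_000, "d": 10_000})
        peaks = [iv("c", 0, 100, "+", f"p{i}") for i in range(30)]
        cfg = rl.ShuffleConfig(per_chromosome=True)
        shuffled, _ = rl.shuffle_once(peaks, None, layout, cfg=cfg, rng=5)
        assert all(p.chrom == "c" for p in shuffled)

    def test_probe_density_matching_two_regimes(self, dataset):
        pm = rl.ProbeMap(dataset.tracks.probes)
        peaks = dataset.tracks.chipchip_peaks
        shuffled, frac = rl.shuffle_once(
            peaks, dataset.mask, dataset.layout, probe_map=pm,
            cfg=rl.ShuffleConfig(), rng=13,
        )
        assert frac >= 0.99
        # matched peaks carry dense-regime-like density
        dense = [pm.density(p) for p in peaks]
        got = [pm.density(p) for p in shuffled]
        tol = 2 * np.std(dense)
        within = np.mean([abs(g - d) <= tol for g, d in zip(got, dense)])
        assert within >= 0.99


class TestEnrichmentTest:
    def test_marker_copy_of_rloops_maximal(self):
        layout = rl.GenomeLayout({"c": 100_000})
        rloops = [iv("c", s, s + 500, "+") for s in range(5_000, 50_000, 10_000)]
        n = 200
        res = rl.enrichment_test(
            rloops, list(rloops), None, layout,
            cfg=rl.ShuffleConfig(n_permutations=n), rng=1,
        )
        assert res.p_enrich == pytest.approx(1 / (n + 1))
        assert res.log2_fold > 0
        assert res.direction == "enriched"

    def test_two_tail_accounting_identity(self, dataset):
        res = rl.enrichment_test(
            dataset.tracks.rloops["S2"],
            dataset.tracks.markers["independent_factor"],
            dataset.mask,
            dataset.layout,
            cfg=rl.ShuffleConfig(n_permutations=99),
            rng=2,
        )
        n = 99
        ties = int((res.null_bp == res.observed_bp).sum())
        assert res.p_enrich + res.p_deplete == pytest.approx(1 + (1 + ties) / (n + 1))

    def test_seeded_reproducibility(self, dataset):
        kwargs = dict(
            mask=dataset.mask,
            layout=dataset.layout,
            cfg=rl.ShuffleConfig(n_permutations=50),
        )
        r1 = rl.enrichment_test(
            dataset.tracks.rloops["S2"], dataset.tracks.markers["bound_factor"],
            rng=42, **kwargs,
        )
        r2 = rl.enrichment_test(
            dataset.tracks.rloops["S2"], dataset.tracks.markers["bound_factor"],
            rng=42, **kwargs,
        )
        assert np.array_equal(r1.null_bp, r2.null_bp)
        assert r1.p_enrich == r2.p_enrich

    def test_infinite_fold_flagged(self):
        layout = rl.GenomeLayout({"c": 1_000})
        mask = rl.RegionMask([iv("c", 0, 400), iv("c", 500, 1000)])
        # R-loop sits inside masked territory: the observed marker overlaps
        # it but every shuffle is forced into the single mask-free slot
        res = rl.enrichment_test(
            [iv("c", 600, 700, "+")],
            [iv("c", 600, 700, ".")],
            mask,
            layout,
            cfg=rl.ShuffleConfig(n_permutations=10),
            rng=3,
        )
        assert res.observed_bp == 100 and res.null_mean_bp == 0
        assert res.log2_fold == np.inf and res.infinite_fold


class TestPanel:
    def test_single_marker_bonferroni_identity(self, dataset):
        results, table = rl.enrichment_panel(
            {"S2": dataset.tracks.rloops["S2"]},
            {"bound_factor": dataset.tracks.markers["bound_factor"]},
            dataset.mask,
            dataset.layout,
            cfg=rl.ShuffleConfig(n_permutations=99),
            seed=4,
        )
        (r,) = results
        assert r.p_adjusted == r.p_value
        assert len(table) == 1

    def test_restriction_subsets_rloops(self, dataset):
        regions = [iv("chr2L", 0, 300_000)]
        kept = rl.restrict_peaks(dataset.tracks.rloops["S2"], regions)
        assert kept
        assert all(p.chrom == "chr2L" and p.start < 300_000 for p in kept)

    def test_panel_reproducible_given_seed(self, dataset):
        args = (
            {"S2": dataset.tracks.rloops["S2"][:50]},
            {"independent_factor": dataset.tracks.markers["independent_factor"][:50]},
            dataset.mask,
            dataset.layout,
        )
        _, t1 = rl.enrichment_panel(
            *args, cfg=rl.ShuffleConfig(n_permutations=50), seed=9
        )
        _, t2 = rl.enrichment_panel(
            *args, cfg=rl.ShuffleConfig(n_permutations=50), seed=9
        )
        assert t1.equals(t2)
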