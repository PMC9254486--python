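import numpy as np
import pytest

import rloopscape as rl
from conftest import iv

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


class TestSkewTrack:
    def test_all_g_window_is_maximal(self):
        (w,) = rl.compute_skew_track({"c": "G" * 50})
        assert w.gc_skew == 1.0 and w.at_skew is None

    def test_balanced_window_is_zero(self):
        (w,) = rl.compute_skew_track({"c": "GC" * 25})
        assert w.gc_skew == 0.0

    def test_literal_count_oracle(self):
        seq = "G" * 30 + "C" * 10 + "A" * 6 + "T" * 4
        (w,) = rl.compute_skew_track({"c": seq})
        assert (w.g, w.c, w.a, w.t) == (30, 10, 6, 4)
        assert w.gc_skew == pytest.approx(0.5)
        assert w.at_skew == pytest.approx(0.2)

    def test_case_insensitive_and_n_uncounted(self):
        (w,) = rl.compute_skew_track({"c": "gGnNcC" + "N" * 44})
        assert (w.g, w.c) == (2, 2) and w.gc_skew == 0.0

    def test_partial_tail_rule(self):
        # tail of 24 < window/2 dropped; tail of 25 kept
        assert len(rl.compute_skew_track({"c": "A" * 74})) == 1
        wins = rl.compute_skew_track({"c": "A" * 75})
        assert len(wins) == 2 and (wins[1].start, wins[1].end) == (50, 75)

    def test_missing_chromosome_error(self):
        with pytest.raises(ValueError, match="absent"):
            rl.compute_skew_track({"c": "ACGT"}, layout=rl.GenomeLayout({"other": 10}))

    def test_reverse_complement_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            (fw,) = rl.compute_skew_track({"c": seq})
            (rv,) = rl.compute_skew_track({"c": revcomp(seq)})
            assert rv.gc_skew == pytest.approx(-fw.gc_skew)
            assert rv.at_skew == pytest.approx(-fw.at_skew)

    def test_bounds_on_synthetic_genome(self, dataset):
        wins = rl.compute_skew_track(dataset.genome.seqs, 50, dataset.layout)
        gc = [w.gc_skew for w in wins if w.gc_skew is not None]
        at = [w.at_skew for w in wins if w.at_skew is not None]
        assert max(gc) <= 1 and min(gc) >= -1
        assert max(at) <= 1 and min(at) >= -1
        # N-gap windows are missing, never zero-filled
        masked = [
            w
            for w in wins
            if dataset.mask.coverage(w.chrom, w.start, w.end) == w.end - w.start
        ]
        assert masked and all(w.gc_skew is None and w.at_skew is None for w in masked)

    def test_bedgraph_omits_undefined(self):
        wins = rl.compute_skew_track({"c": "G" * 50 + "N" * 50})
        entries = rl.skew_bedgraph_entries(wins, "GC")
        assert entries == [("c", 0, 50, 1.0)]


def naive_profile(values, regions, mode, bin_size, flank, body, anchor="center"):
    """Brute-force per-region resampling oracle (independent loops)."""
    rows = []
    for r in regions:
        vals = values[r.chrom]

        def at(p):
            return vals[p] if 0 <= p < len(vals) else np.nan

        if mode == "scale_regions":
            if r.end - r.start < bin_size:
                continue
            vec = []
            for j in range(flank // bin_size):
                block = [at(r.start - flank + j * bin_size + k) for k in range(bin_size)]
                vec.append(np.nanmean(block) if not all(np.isnan(block)) else np.nan)
            L = r.end - r.start
            nb = body // bin_size
            for j in range(nb):
                lo = (j * L) // nb
                hi = max(lo + 1, ((j + 1) * L) // nb)
                block = [at(r.start + p) for p in range(lo, hi)]
                vec.append(np.nanmean(block) if not all(np.isnan(block)) else np.nan)
            for j in range(flank // bin_size):
                block = [at(r.end + j * bin_size + k) for k in range(bin_size)]
                vec.append(np.nanmean(block) if not all(np.isnan(block)) else np.nan)
        else:
            a = anchor
            if r.strand == "-" and a in ("start", "end"):
                a = {"start": "end", "end": "start"}[a]
            p0 = {"start": r.start, "end": r.end, "center": (r.start + r.end) // 2}[a]
            vec = []
            for j in range(2 * flank // bin_size):
                block = [at(p0 - flank + j * bin_size + k) for k in range(bin_size)]
                vec.append(np.nanmean(block) if not all(np.isnan(block)) else np.nan)
        vec = np.array(vec)
        if r.strand == "-":
            vec = vec[::-1]
        rows.append(vec)
    return np.nanmean(np.vstack(rows), axis=0)


class TestMetaProfile:
    def test_constant_track(self):
        layout = rl.GenomeLayout({"c": 10_000})
        values = {"c": np.full(10_000, 3.25)}
        prof = rl.metaprofile(
            values, [iv("c", 2000, 4000, "+"), iv("c", 5000, 8000, "+")]
        )
        assert np.allclose(prof.means, 3.25)
        assert np.allclose(prof.sems, 0.0)
        assert prof.n_bins == 10 + 20 + 10

    def test_reference_point_identity_single_plus_region(self):
        rng = np.random.default_rng(1)
        values = {"c": rng.normal(size=4000)}
        region = iv("c", 1000, 3000, "+")
        prof = rl.metaprofile(
            values, [region], mode="reference_point", anchor="center", flank=500
        )
        center = 2000
        expected = values["c"][center - 500 : center + 500].reshape(20, 50).mean(axis=1)
        assert np.allclose(prof.means, expected)

    def test_orientation_symmetrizes_opposite_strands(self):
        # asymmetric ramp: oriented profiles from +/- regions coincide,
        # unoriented ones do not
        values = {"c": np.concatenate([np.zeros(2000), np.ones(2000)])}
        regions = [iv("c", 1800, 2200, "+"), iv("c", 1800, 2200, "-")]
        oriented = rl.metaprofile(
            values, regions, mode="reference_point", anchor="center",
            flank=200, bin_size=100, orient_by_strand=True,
        )
        plus_only = rl.metaprofile(
            values, regions[:1], mode="reference_point", anchor="center",
            flank=200, bin_size=100,
        )
        minus_oriented = rl.metaprofile(
            values, regions[1:], mode="reference_point", anchor="center",
            flank=200, bin_size=100, orient_by_strand=True,
        )
        assert np.allclose(plus_only.means, minus_oriented.means[::-1])
        assert np.allclose(oriented.means, 0.5)  # ramp symmetrized
        unoriented = rl.metaprofile(
            values, regions, mode="reference_point", anchor="center",
            flank=200, bin_size=100, orient_by_strand=False,
        )
        assert np.allclose(unoriented.means, plus_only.means)

    def test_sign_flip_on_minus(self):
        values = {"c": np.full(1000, 0.4)}
        prof = rl.metaprofile(
            values,
            [iv("c", 200, 800, "-")],
            mode="reference_point",
            anchor="center",
            flank=100,
            bin_size=50,
            flip_sign_on_minus=True,
        )
        assert np.allclose(prof.means, -0.4)

    def test_short_region_skipped_with_count(self):
        values = {"c": np.zeros(10_000)}
        prof = rl.metaprofile(
            values, [iv("c", 100, 120, "+"), iv("c", 2000, 4000, "+")]
        )
        assert prof.n_skipped == 1 and prof.n_regions == 1

    @pytest.mark.parametrize("mode", ["scale_regions", "reference_point"])
    def test_matches_bruteforce_oracle(self, mode):
        rng = np.random.default_rng(7)
        layout = rl.GenomeLayout({"c": 20_000, "d": 8_000})
        values = {c: rng.normal(size=layout[c]) for c in layout}
        for c in values:  # sprinkle missing data
            values[c][rng.integers(0, layout[c], 500)] = np.nan
        regions = []
        for _ in range(10):
            chrom = "c" if rng.random() < 0.7 else "d"
            start = int(rng.integers(600, layout[chrom] - 3000))
            length = int(rng.integers(80, 2500))
            strand = "+" if rng.random() < 0.5 else "-"
            regions.append(iv(chrom, start, start + length, strand))
        prof = rl.metaprofile(values, regions, mode=mode, anchor="center")
        oracle = naive_profile(values, regions, mode, 50, 500, 1000)
        assert np.allclose(prof.means, oracle, equal_nan=True, atol=1e-9)


class TestSkewAtFeatures:
    def test_planted_transition_crosses_zero_at_center(self):
        cfg = rl.SimulationConfig(
            seed=5,
            chrom_sizes={"chr2L": 400_000, "chr3R": 200_000, "chrM": 5_000},
            gap_regions=[],
            n_skew_sites=12,
            n_transcripts=30,
            n_background_peaks=10,
            marker_programs=[],
            n_chipchip_peaks=10,
            probe_dense_region=("chr2L", 0, 100_000),
        )
        ds = rl.generate_dataset(cfg)
        prof = rl.skew_at_features(
            ds.genome.seqs,
            ds.tracks.site_peaks,
            ds.layout,
            which="AT",
            mode="reference_point",
        )
        half = prof.n_bins // 2
        # positive AT skew 5' of the center, negative 3' of it
        assert prof.means[half - 3 : half].mean() > 0.1
        assert prof.means[half : half + 3].mean() < -0.1
        signs = np.sign(prof.means)
        crossings = np.flatnonzero(np.diff(signs[signs != 0]))
        assert any(abs(c - (half - 1)) <= 1 for c in crossings)

    def test_uniform_genome_profile_flat(self, dataset):
        peaks = dataset.tracks.rloops["S2"][:150]
        prof = rl.skew_at_features(
            dataset.genome.seqs, peaks, dataset.layout, which="GC"
        )
        ok = ~np.isnan(prof.means)
        assert np.all(np.abs(prof.means[ok]) <= 3 * prof.sems[ok] + 0.05)

    def test_all_g_genome(self):
        layout = rl.GenomeLayout({"c": 2_000})
        prof = rl.skew_at_features(
            {"c": "G" * 2000},
            [iv("c", 500, 1500, "+")],
            layout,
            which="GC",
            mode="scale_regions",
            flank=100,
            bin_size=50,
        )
        assert np.allclose(prof.means, 1.0)
        at = rl.skew_at_features(
            {"c": "G" * 2000},
            [iv("c", 500, 1500, "+")],
            layout,
            which="AT",
            mode="scale_regions",
            flank=100,
            bin_size=50,
        )
        assert np.all(np.isnan(at.means))
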