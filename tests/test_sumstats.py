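"""Summary-statistics, annotation and LD file handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transgwas import simulate
from transgwas.sumstats import (
    AnnotationTrack,
    LDMatrix,
    SumStatsFormatError,
    annotate_variants,
    harmonise_studies,
    merge_intervals,
    read_annotations,
    read_ld,
    read_sumstats,
    write_ld,
    write_sumstats,
)


def _write_tsv(path, rows, header="CHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tN\tINFO"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


WELL_FORMED = [
    "1\t100\tA\tG\t0.3\t0.1\t0.05\t1000\t0.95",
    "2\t200\tC\tT\t0.5\t-0.2\t0.04\t1000\t0.99",
    "22\t300\tG\tA\t0.8\t0.05\t0.06\t900\t1.0",
]


class TestReadSumstats:
    def test_well_formed_file_roundtrips(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_tsv(f, WELL_FORMED)
        ss, qc = read_sumstats(f, "s1", "EUR")
        assert ss.n_variants == 3
        assert qc.n_dropped == 0
        assert ss.table["pos"].tolist() == [100, 200, 300]

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("1\t100\tA\tG\t1.0\t0.1\t0.05\t1000\t0.95", "eaf_out_of_range"),
            ("1\t100\tA\tG\t0.0\t0.1\t0.05\t1000\t0.95", "eaf_out_of_range"),
            ("1\t100\tA\tG\t0.3\t0.1\t0.0\t1000\t0.95", "nonpositive_se"),
            ("1\t100\tA\tA\t0.3\t0.1\t0.05\t1000\t0.95", "identical_alleles"),
            ("X\t100\tA\tG\t0.3\t0.1\t0.05\t1000\t0.95", "non_autosomal"),
            ("1\t100\tA\tG\t0.3\t0.1\t0.05\t1000\t0.2", "low_imputation_quality"),
            ("1\t100\tA\tG\t0.3\t0.1\t0.05\t-5\t0.95", "nonpositive_n"),
        ],
    )
    def test_invalid_record_dropped_and_counted(self, tmp_path, row, reason):
        f = tmp_path / "s.tsv"
        _write_tsv(f, [WELL_FORMED[1], row])
        ss, qc = read_sumstats(f, "s1", "EUR")
        assert ss.n_variants == 1
        assert qc.dropped == {reason: 1}

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("CHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\n1\t1\tA\tG\t0.5\t0.1\t0.05\n")
        with pytest.raises(SumStatsFormatError, match="N"):
            read_sumstats(f, "s1", "EUR")

    def test_empty_file_is_error(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("CHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tN\tINFO\n")
        with pytest.raises(ValueError, match="no records"):
            read_sumstats(f, "s1", "EUR")

    def test_write_then_read_identical(self, tmp_path, rng):
        cfg = simulate.SimConfig(seed=3, n_loci=1, n_null_variants=50)
        panel = simulate.simulate_panel(cfg)
        original = panel.studies[0]
        f = tmp_path / "out.tsv"
        write_sumstats(original, f)
        back, qc = read_sumstats(f, original.study_id, original.ancestry_group)
        assert qc.n_dropped == 0
        a, b = original.table, back.table
        for col in ["chrom", "pos", "effect_allele", "other_allele"]:
            assert (a[col].to_numpy() == b[col].to_numpy()).all()
        for col in ["eaf", "beta", "se", "n", "info"]:
            np.testing.assert_allclose(a[col], b[col], rtol=1e-5)


class TestHarmonisation:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        t1 = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "effect_allele": ["A"], "other_allele": ["G"],
             "rsid": ["rs1"], "eaf": [0.3], "beta": [0.1], "se": [0.05], "n": [1000], "info": [1.0]}
        )
        t2 = t1.copy()
        t2[["effect_allele", "other_allele"]] = [["G", "A"]]
        t2["eaf"], t2["beta"] = 0.7, -0.1
        from transgwas.sumstats import StudySumStats

        out, counts = harmonise_studies(
            [StudySumStats("a", "EUR", t1), StudySumStats("b", "EAS", t2)]
        )
        assert counts["flipped"] == 1
        assert out[1].table["beta"].iloc[0] == pytest.approx(0.1)
        assert out[1].table["eaf"].iloc[0] == pytest.approx(0.3)
        assert out[1].table["effect_allele"].iloc[0] == "A"

    def test_unresolvable_mismatch_dropped(self):
        from transgwas.sumstats import StudySumStats

        t1 = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "effect_allele": ["A"], "other_allele": ["G"],
             "rsid": [""], "eaf": [0.3], "beta": [0.1], "se": [0.05], "n": [1000], "info": [1.0]}
        )
        t2 = t1.copy()
        t2[["effect_allele", "other_allele"]] = [["C", "T"]]
        out, counts = harmonise_studies(
            [StudySumStats("a", "EUR", t1), StudySumStats("b", "EAS", t2)]
        )
        assert counts["dropped_mismatch"] == 1
        assert out[1].n_variants == 0


class TestAnnotations:
    def test_overlapping_intervals_merge(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("1\t10\t20\n1\t15\t30\n")
        (track,) = read_annotations([f], ["a"], ["genic"])
        assert track.intervals[["start", "end"]].to_numpy().tolist() == [[10, 30]]

    def test_empty_bed_gives_empty_track(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("")
        (track,) = read_annotations([f], ["a"], ["genic"])
        assert len(track.intervals) == 0 and track.total_length == 0

    def test_bad_interval_reports_line_number(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("1\t10\t20\n1\t30\t30\n")
        with pytest.raises(SumStatsFormatError, match=":2:"):
            read_annotations([f], ["a"], ["genic"])

    def test_merged_length_matches_per_base_union(self, rng):
        starts = rng.integers(0, 1000, size=100)
        lengths = rng.integers(1, 50, size=100)
        iv = pd.DataFrame({"chrom": "1", "start": starts, "end": starts + lengths})
        merged = merge_intervals(iv)
        covered = set()
        for s, e in zip(starts, starts + lengths):
            covered.update(range(s, e))
        track_len = int((merged["end"] - merged["start"]).sum())
        assert track_len == len(covered)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=40
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_merge_is_idempotent(self, ivs):
        iv = pd.DataFrame(
            {"chrom": "1", "start": [s for s, _ in ivs], "end": [s + l for s, l in ivs]}
        )
        once = merge_intervals(iv)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAnnotateVariants:
    def _variants(self, positions, chrom="1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_one_based_position_boundary_convention(self):
        track = AnnotationTrack(
            "a", "genic", pd.DataFrame({"chrom": ["1"], "start": [10], "end": [11]})
        )
        z = annotate_variants(self._variants([11]), [track])
        assert z[0, 0] == 1  # 1-based 11 -> 0-based 10, inside [10, 11)
        track2 = AnnotationTrack(
            "a", "genic", pd.DataFrame({"chrom": ["1"], "start": [11], "end": [20]})
        )
        z2 = annotate_variants(self._variants([11]), [track2])
        assert z2[0, 0] == 0

    def test_matches_bruteforce_scan(self, rng):
        variants = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], size=1000),
                "pos": rng.integers(1, 5000, size=1000),
            }
        )
        tracks = []
        for k in range(10):
            starts = np.sort(rng.integers(0, 5000, size=20))
            iv = pd.DataFrame(
                {"chrom": rng.choice(["1", "2"], size=20), "start": starts,
                 "end": starts + rng.integers(1, 200, size=20)}
            )
            tracks.append(AnnotationTrack(f"t{k}", "genic", merge_intervals(iv)))
        z = annotate_variants(variants, tracks)
        for k, tr in enumerate(tracks):
            for v in range(len(variants)):
                hit = any(
                    row.chrom == variants["chrom"].iloc[v]
                    and row.start <= variants["pos"].iloc[v] - 1 < row.end
                    for row in tr.intervals.itertuples()
                )
                assert z[v, k] == int(hit)


class TestLDMatrix:
    def _index(self, tmp_path, m):
        f = tmp_path / "idx.txt"
        f.write_text("".join(f"1\t{100 + i}\tA\tG\n" for i in range(m)))
        return f

    def test_identity_is_valid(self, tmp_path):
        mat = tmp_path / "ld.txt"
        np.savetxt(mat, np.eye(2))
        ld = read_ld(mat, self._index(tmp_path, 2))
        assert ld.n_variants == 2
        np.testing.assert_allclose(ld.r, np.eye(2))

    def test_out_of_range_entry_rejected(self, tmp_path):
        mat = tmp_path / "ld.txt"
        np.savetxt(mat, np.array([[1.0, 1.2], [1.2, 1.0]]))
        with pytest.raises(SumStatsFormatError, match="exceed"):
            read_ld(mat, self._index(tmp_path, 2))

    def test_non_square_rejected(self, tmp_path):
        mat = tmp_path / "ld.txt"
        np.savetxt(mat, np.ones((2, 3)))
        with pytest.raises(SumStatsFormatError, match="square"):
            read_ld(mat, self._index(tmp_path, 2))

    def test_matches_sample_correlation_of_genotypes(self, tmp_path, rng):
        freqs = rng.uniform(0.2, 0.8, 8)
        g, _, _ = simulate.simulate_genotype_locus(rng, 4000, freqs, 0.6, np.zeros(8))
        r = np.corrcoef(g.T)
        mat = tmp_path / "ld.txt"
        np.savetxt(mat, r, fmt="%.10g")
        ld = read_ld(mat, self._index(tmp_path, 8))
        np.testing.assert_allclose(ld.r, r, atol=1e-6)

    def test_write_read_roundtrip(self, tmp_path, rng):
        r = simulate.ar1_ld(5, 0.7)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(5) + 1, "effect_allele": "A", "other_allele": "G"}
        )
        ld = LDMatrix(variants, r, "EUR")
        write_ld(ld, tmp_path / "m.txt", tmp_path / "i.txt")
        back = read_ld(tmp_path / "m.txt", tmp_path / "i.txt", "EUR")
        np.testing.assert_allclose(back.r, r, atol=1e-5)
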