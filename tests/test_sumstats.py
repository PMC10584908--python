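import gzip

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gwasaudit as ga
from gwasaudit.sumstats import P_FLOOR, SumStatsError

from conftest import small_table


def write_generic(path, df, columns=None):
    out = df.copy()
    mapping = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
               "beta": "BETA", "se": "SE", "z": "Z", "p": "P", "n": "N"}
    out.columns = [mapping.get(c, c) for c in out.columns]
    if columns:
        out = out[columns]
    out.to_csv(path, sep="\t", index=False)
    return path


class TestRead:
    def test_well_formed_file_loads_identically(self, tmp_path):
        df = small_table(3)
        ss = ga.read_sumstats(write_generic(tmp_path / "a.tsv", df))
        assert len(ss) == 3
        assert ss.report.n_dropped == 0
        np.testing.assert_allclose(ss.table["beta"], df["beta"], rtol=1e-9)

    def test_z_computed_from_beta_se(self, tmp_path):
        df = small_table(4).drop(columns=["z"])
        ss = ga.read_sumstats(write_generic(tmp_path / "a.tsv", df))
        np.testing.assert_allclose(ss.table["z"], df["beta"] / df["se"], rtol=1e-9)

    def test_unparseable_row_dropped_and_logged(self, tmp_path):
        df = small_table(3).astype({"p": object})
        df.loc[1, "p"] = "NA"
        ss = ga.read_sumstats(write_generic(tmp_path / "a.tsv", df))
        assert len(ss) == 2
        assert ss.report.n_dropped == 1
        assert any("P" in r for r in ss.report.drop_reasons)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = write_generic(tmp_path / "a.tsv", small_table(3),
                             columns=["SNP", "A1", "A2", "Z", "P"])
        with pytest.raises(SumStatsError, match="N"):
            ga.read_sumstats(path)

    def test_ldsc_dialect_derives_p_from_z(self, tmp_path):
        df = small_table(3)[["snp_id", "a1", "a2", "z", "n"]]
        path = write_generic(tmp_path / "a.sumstats", df)
        ss = ga.read_sumstats(path, dialect="ldsc")
        np.testing.assert_allclose(ss.table["p"], 2 * stats.norm.sf(np.abs(df["z"])), rtol=1e-9)

    def test_zero_p_floored(self, tmp_path):
        df = small_table(3)
        df.loc[0, "p"] = 0.0
        ss = ga.read_sumstats(write_generic(tmp_path / "a.tsv", df))
        assert ss.table.loc[0, "p"] == P_FLOOR

    def test_inconsistent_z_recomputed(self, tmp_path):
        df = small_table(3)
        df.loc[0, "z"] = df.loc[0, "z"] + 5.0
        ss = ga.read_sumstats(write_generic(tmp_path / "a.tsv", df))
        np.testing.assert_allclose(ss.table["z"], df["beta"] / df["se"], rtol=1e-6)
        assert any("recomputed" in note for note in ss.report.notes)

    def test_gzip_transparent(self, tmp_path):
        df = small_table(3)
        text = df.rename(columns=str.upper).rename(
            columns={"SNP_ID": "SNP", "POS": "BP"}).to_csv(sep="\t", index=False)
        path = tmp_path / "a.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(text)
        assert len(ga.read_sumstats(path)) == 3


class TestWrite:
    def test_round_trip(self, tmp_path):
        ss = ga.SumStats(small_table(5))
        ga.write_sumstats(ss, tmp_path / "out.tsv")
        back = ga.read_sumstats(tmp_path / "out.tsv")
        for col in ("beta", "se", "z", "p", "n"):
            np.testing.assert_allclose(back.table[col], ss.table[col], rtol=1e-8)
        assert list(back.table["snp_id"]) == list(ss.table["snp_id"])

    def test_outlier_column_sums_to_flag_count(self, tmp_path):
        t = small_table(5)
        t["outlier"] = [0, 1, 0, 1, 0]
        ga.write_sumstats(ga.SumStats(t), tmp_path / "out.tsv", include_flags=True)
        written = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert written["OUTLIER"].sum() == 2

    def test_flags_absent_when_disabled(self, tmp_path):
        ga.write_sumstats(ga.SumStats(small_table(3)), tmp_path / "out.tsv", include_flags=False)
        assert "OUTLIER" not in pd.read_csv(tmp_path / "out.tsv", sep="\t").columns

    def test_random_tables_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        for i in range(5):
            n = int(rng.integers(3, 40))
            df = small_table(5, seed=i)
            df = pd.concat([df.assign(snp_id=[f"c{j}_{s}" for s in df.snp_id])
                            for j in range(max(1, n // 5))], ignore_index=True)
            ss = ga.SumStats(df)
            ga.write_sumstats(ss, tmp_path / "r.tsv")
            back = ga.read_sumstats(tmp_path / "r.tsv")
            np.testing.assert_allclose(back.table["z"], ss.table["z"], rtol=1e-8)


class TestEffectiveSampleSize:
    @pytest.mark.parametrize("cohorts,expected", [
        ([("a", 0.5, 1000)], 1000.0),
        ([("a", 0.25, 1000)], 750.0),
        ([("a", 0.5, 1000), ("b", 0.1, 5000)], 2800.0),
    ])
    def test_binary_formula(self, cohorts, expected):
        specs = [ga.CohortSpec(l, v, n) for l, v, n in cohorts]
        assert ga.effective_sample_size(specs) == pytest.approx(expected)

    def test_continuous_traits_sum_n(self):
        specs = [ga.CohortSpec("a", None, 1200), ga.CohortSpec("b", None, 800)]
        assert ga.effective_sample_size(specs) == 2000

    def test_out_of_range_case_proportion_rejected(self):
        with pytest.raises(SumStatsError):
            ga.CohortSpec("a", 1.2, 100)

    def test_maximized_at_balanced_design(self):
        vals = [ga.effective_sample_size([ga.CohortSpec("a", v, 1000)])
                for v in np.linspace(0.05, 0.95, 19)]
        assert np.argmax(vals) == 9  # v = 0.5
        assert max(vals) == pytest.approx(1000.0)


class TestHarmonize:
    def test_identical_tables_unchanged(self):
        ss = ga.SumStats(small_table(5))
        f, d, log = ga.harmonize_pair(ss, ss)
        assert log.n_swapped == 0 and log.n_strand_flipped == 0
        pd.testing.assert_frame_equal(f.table, d.table)

    def test_swapped_alleles_restore_beta(self):
        t = small_table(4)
        ss_full = ga.SumStats(t)
        swapped = t.copy()
        swapped[["a1", "a2"]] = swapped[["a2", "a1"]].to_numpy()
        swapped[["beta", "z"]] = -swapped[["beta", "z"]]
        f, d, log = ga.harmonize_pair(ss_full, ga.SumStats(swapped))
        assert log.n_swapped == len(f)
        np.testing.assert_allclose(d.table["beta"], f.table["beta"], rtol=1e-12)
        assert list(d.table["a1"]) == list(f.table["a1"])

    def test_strand_flip_resolved(self):
        t = small_table(4)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        flipped = t.copy()
        flipped["a1"] = flipped["a1"].map(comp)
        flipped["a2"] = flipped["a2"].map(comp)
        f, d, log = ga.harmonize_pair(ga.SumStats(t), ga.SumStats(flipped))
        assert log.n_strand_flipped == len(f)
        np.testing.assert_allclose(d.table["beta"], f.table["beta"])

    def test_ambiguous_snp_dropped_and_counted(self):
        t = small_table(4)
        t.loc[0, ["a1", "a2"]] = ["A", "T"]
        ss = ga.SumStats(t)
        f, d, log = ga.harmonize_pair(ss, ss, ambiguous_policy="drop")
        assert log.n_ambiguous == 1
        assert "rs1" not in set(f.table["snp_id"])
        f2, _, log2 = ga.harmonize_pair(ss, ss, ambiguous_policy="keep")
        assert "rs1" in set(f2.table["snp_id"])

    def test_irreconcilable_pair_dropped_not_kept(self):
        t = small_table(4)
        other = t.copy()
        other.loc[0, ["a1", "a2"]] = ["A", "C"]  # full row 0 is A/G
        f, d, log = ga.harmonize_pair(ga.SumStats(t), ga.SumStats(other))
        assert log.n_irreconcilable == 1
        assert "rs1" not in set(f.table["snp_id"])

    def test_swap_transform_is_involutive(self):
        t = small_table(4)
        swap = t.copy()
        swap[["a1", "a2"]] = swap[["a2", "a1"]].to_numpy()
        swap[["beta", "z"]] = -swap[["beta", "z"]]
        twice = swap.copy()
        twice[["a1", "a2"]] = twice[["a2", "a1"]].to_numpy()
        twice[["beta", "z"]] = -twice[["beta", "z"]]
        pd.testing.assert_frame_equal(twice, t)
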