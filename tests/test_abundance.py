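import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from trypcat.abundance import (
    AbundanceTable,
    DifferentialResult,
    differential_genera,
    pathway_links,
    read_abundance_table,
    read_sankey,
    relative_abundance,
    wilcoxon_rank_sum,
    write_sankey,
)
from trypcat.errors import FormatError, ManifestError, NormalizationError
from trypcat.simulate import StudyDesign, make_abundance_study, simulate_abundance

from _oracles import ranksum_exact_bruteforce


def make_table(counts, groups, normalized=False):
    return AbundanceTable(pd.DataFrame(counts), pd.Series(groups),
                          normalized=normalized)


class TestReadAbundance:
    def write_study(self, tmp_path, rows, groups):
        apath = tmp_path / "abundance.tsv"
        apath.write_text("sample_id\tgenus\tcount\n"
                         + "".join(f"{s}\t{g}\t{c}\n" for s, g, c in rows))
        gpath = tmp_path / "groups.tsv"
        gpath.write_text("sample_id\tgroup\n"
                         + "".join(f"{s}\t{g}\n" for s, g in groups))
        return apath, gpath

    def test_long_format_pivots_dense(self, tmp_path):
        apath, gpath = self.write_study(
            tmp_path,
            [("s1", "A", 3), ("s1", "B", 5), ("s1", "C", 2),
             ("s2", "A", 1), ("s2", "B", 0), ("s2", "C", 9)],
            [("s1", "case"), ("s2", "control")])
        table = read_abundance_table(apath, gpath)
        assert table.counts.shape == (2, 3)
        assert table.counts.loc["s2", "C"] == 9

    def test_missing_pair_becomes_zero(self, tmp_path):
        apath, gpath = self.write_study(
            tmp_path, [("s1", "A", 3), ("s2", "B", 4)],
            [("s1", "case"), ("s2", "control")])
        table = read_abundance_table(apath, gpath)
        assert table.counts.loc["s1", "B"] == 0
        assert table.counts.loc["s2", "A"] == 0

    def test_sample_without_group_rejected(self, tmp_path):
        apath, gpath = self.write_study(
            tmp_path, [("s1", "A", 3), ("s2", "A", 4)], [("s1", "case")])
        with pytest.raises(ManifestError, match="s2"):
            read_abundance_table(apath, gpath)

    def test_negative_count_rejected(self, tmp_path):
        apath, gpath = self.write_study(
            tmp_path, [("s1", "A", -3)], [("s1", "case")])
        with pytest.raises(FormatError, match="negative"):
            read_abundance_table(apath, gpath)

    def test_generator_round_trip(self, tmp_path):
        design = StudyDesign(n_case=4, n_control=4, seed=5)
        apath, gpath, _ = make_abundance_study(design, tmp_path)
        counts, groups, _ = simulate_abundance(design)
        table = read_abundance_table(apath, gpath)
        assert table.counts.equals(
            counts.sort_index().sort_index(axis=1))
        assert (table.groups.sort_index() == groups.sort_index()).all()


class TestRelativeAbundance:
    def test_row_arithmetic(self):
        table = make_table({"A": [2.0], "B": [3.0], "C": [5.0]},
                           {0: "case"})
        out = relative_abundance(table)
        assert list(out.counts.iloc[0]) == [0.2, 0.3, 0.5]
        assert out.normalized

    def test_single_genus_all_ones(self):
        table = make_table({"A": [7.0, 11.0]}, {0: "case", 1: "control"})
        out = relative_abundance(table)
        assert (out.counts["A"] == 1.0).all()

    def test_rows_sum_to_one_on_random_tables(self, rng):
        counts = pd.DataFrame(rng.uniform(0.1, 50, (12, 7)))
        table = AbundanceTable(counts, pd.Series(["case"] * 6 + ["control"] * 6))
        out = relative_abundance(table)
        assert np.allclose(out.counts.sum(axis=1), 1.0)

    def test_all_zero_sample_rejected(self):
        table = make_table({"A": [0.0, 1.0], "B": [0.0, 2.0]},
                           {0: "case", 1: "control"})
        with pytest.raises(NormalizationError, match="0"):
            relative_abundance(table)


class TestWilcoxonRankSum:
    def test_textbook_exact_example(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])[1] == 1.0
        assert wilcoxon_rank_sum([5.0] * 4, [5.0] * 4)[1] == 1.0

    def test_symmetry_and_rank_sum_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 9)))
            y = rng.normal(size=int(rng.integers(2, 9)))
            wx, px = wilcoxon_rank_sum(x, y)
            wy, py = wilcoxon_rank_sum(y, x)
            n = len(x) + len(y)
            assert wx + wy == pytest.approx(n * (n + 1) / 2)
            assert px == pytest.approx(py)

    def test_exact_branch_equals_full_enumeration(self, rng):
        for _ in range(15):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            w, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(
                ranksum_exact_bruteforce(8, 16, w), abs=1e-12)

    def test_exact_branch_agrees_with_scipy(self, rng):
        for _ in range(15):
            x = rng.normal(size=int(rng.integers(3, 10)))
            y = rng.normal(size=int(rng.integers(3, 10)))
            _, p = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, method="exact").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_asymptotic_branch_agrees_with_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=25)
            y = np.round(rng.normal(size=25), 1)  # induce occasional ties
            _, p = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, method="asymptotic",
                               use_continuity=True).pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestDifferentialGenera:
    def normalized_study(self, case, control):
        genera = list(case)
        rows, groups = {}, {}
        n_case = len(next(iter(case.values())))
        n_control = len(next(iter(control.values())))
        for i in range(n_case):
            sid = f"c{i}"
            rows[sid] = {g: case[g][i] for g in genera}
            groups[sid] = "case"
        for i in range(n_control):
            sid = f"h{i}"
            rows[sid] = {g: control[g][i] for g in genera}
            groups[sid] = "control"
        counts = pd.DataFrame.from_dict(rows, orient="index")
        counts = counts.div(counts.sum(axis=1), axis=0)
        return AbundanceTable(counts, pd.Series(groups), normalized=True)

    def test_requires_normalized_table(self):
        table = make_table({"A": [1.0, 2.0]}, {0: "case", 1: "control"})
        with pytest.raises(ValueError, match="relative"):
            differential_genera(table)

    def test_complete_separation_retained_case_enriched(self):
        # closure: as A rises in cases, B's relative abundance must fall,
        # so the mirrored genus comes out control-enriched
        table = self.normalized_study(
            {"A": list(range(20, 30)), "B": [1] * 10},
            {"A": list(range(1, 11)), "B": [1] * 10})
        results = differential_genera(table, p_max=0.01)
        assert {(r.genus, r.direction) for r in results} == {
            ("A", "case_enriched"), ("B", "control_enriched")}

    def test_p_max_one_keeps_all_and_zero_none(self):
        table = self.normalized_study({"A": [1, 2, 3], "B": [2, 2, 2]},
                                      {"A": [2, 3, 4], "B": [2, 2, 2]})
        assert len(differential_genera(table, p_max=1.0)) == 2
        assert differential_genera(table, p_max=1e-12) == []

    def test_null_study_rarely_passes(self):
        # identical sampling in both groups: expect ~0.2 passes over 20 genera
        total = 0
        for seed in range(10):
            design = StudyDesign(n_case=10, n_control=10, seed=seed,
                                 effect_genera={})
            counts, groups, _ = simulate_abundance(design)
            table = relative_abundance(AbundanceTable(counts, groups))
            total += len(differential_genera(table, p_max=0.01))
        assert total <= 6  # 200 null tests at the 1% level

    def test_planted_shift_recovered(self):
        recovered = 0
        for seed in range(30):
            design = StudyDesign(seed=seed)  # 4-fold shift in 2 of 20 genera
            counts, groups, truth = simulate_abundance(design)
            table = relative_abundance(AbundanceTable(counts, groups))
            hits = {r.genus for r in differential_genera(table, p_max=0.01)}
            recovered += set(truth.effect_genera) <= hits
        assert recovered >= 29


class TestLinksAndSankey:
    def scores_frame(self):
        return pd.DataFrame(
            {"kynurenine": [8.61, 0.0], "indole": [0.0, 1.5]},
            index=["Burkholderia", "Alistipes"])

    def diff(self, genus, direction="case_enriched", p=0.004):
        return DifferentialResult(genus, 100.0, p, direction, 0.2, 0.1)

    def test_single_positive_cell_single_edge(self):
        links = pathway_links([self.diff("Burkholderia")], self.scores_frame())
        assert len(links) == 1
        assert links[0].metabolite == "kynurenine"
        assert links[0].scorbpeo_weight == pytest.approx(8.61)

    def test_unknown_genus_emits_nothing(self, caplog):
        with caplog.at_level("INFO", logger="trypcat.abundance"):
            links = pathway_links([self.diff("Mystery")], self.scores_frame())
        assert links == []
        assert any("Mystery" in rec.message for rec in caplog.records)

    def test_edge_set_is_cross_product_of_positives(self):
        diffs = [self.diff("Burkholderia"),
                 self.diff("Alistipes", "control_enriched")]
        links = pathway_links(diffs, self.scores_frame())
        assert {(l.genus, l.metabolite, l.group) for l in links} == {
            ("Burkholderia", "kynurenine", "case"),
            ("Alistipes", "indole", "control")}

    def test_sankey_round_trip(self, tmp_path):
        diffs = [self.diff("Burkholderia"),
                 self.diff("Alistipes", "control_enriched")]
        links = pathway_links(diffs, self.scores_frame())
        path = tmp_path / "sankey.json"
        write_sankey(links, path)
        assert read_sankey(path) == links

    def test_empty_links_valid_document(self, tmp_path):
        path = tmp_path / "sankey.json"
        write_sankey([], path)
        assert read_sankey(path) == []
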