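"""Drug/gene/process matrix construction, virtual drug, and distances."""

import numpy as np
import pandas as pd
import pytest

from procpharm import (
    DrugRecord,
    MatrixBuildError,
    NoSharedProcessError,
    ORAConfig,
    build_drug_gene,
    build_gene_process,
    build_virtual_drug,
    distances_to_virtual,
    drug_process_product,
    read_drug_targets,
    restrict_shared,
)
from procpharm.drug_matrix import VIRTUAL_DRUG_LABEL


def drug(did, *targets):
    return DrugRecord(did, f"name-{did}", frozenset(targets))


class TestReadDrugTargets:
    def test_dedup_and_comments(self, tmp_path):
        p = tmp_path / "drugs.tsv"
        p.write_text(
            "# header comment\ndrug_id\tdrug_name\tgene_id\n"
            "D1\taspirin\tG1\nD1\taspirin\tG1\nD1\taspirin\tG2\nD2\tibuprofen\tG1\n"
        )
        records = read_drug_targets(p)
        assert [(r.drug_id, sorted(r.targets)) for r in records] == [
            ("D1", ["G1", "G2"]),
            ("D2", ["G1"]),
        ]

    def test_empty_errors(self, tmp_path):
        p = tmp_path / "drugs.tsv"
        p.write_text("# nothing\n")
        with pytest.raises(MatrixBuildError):
            read_drug_targets(p)


class TestBuildDrugGene:
    def test_single_drug(self):
        m = build_drug_gene([drug("D1", "G1", "G2")], {"G1", "G2"})
        assert m.shape == (1, 2) and (m.to_numpy() == 1).all()

    def test_shared_target_column_sum(self):
        m = build_drug_gene([drug(f"D{i}", "G1") for i in range(3)], {"G1"})
        assert m["G1"].sum() == 3

    def test_out_of_universe_drug_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            m = build_drug_gene([drug("D1", "G1"), drug("D2", "GX")], {"G1"})
        assert list(m.index) == ["D1"]
        assert "dropped 1 drug" in caplog.text

    def test_all_outside_universe(self):
        with pytest.raises(MatrixBuildError):
            build_drug_gene([drug("D1", "GX")], {"G1"})


class TestBuildGeneProcess:
    def test_filter_disabled_keeps_all_annotated_terms(self, small_annotated):
        onto, table = small_annotated
        m = build_gene_process(
            ["g000", "g001"], table, onto, ORAConfig(1.0, "bonferroni")
        )
        assert set(m.columns) == {t for t, K in table.term_counts().items() if K >= 1}
        # all-zero rows are retained (row conservation)
        assert list(m.index) == ["g000", "g001"]

    def test_too_strict_threshold_errors(self, small_annotated):
        onto, table = small_annotated
        with pytest.raises(MatrixBuildError, match="relaxing"):
            build_gene_process(
                ["g000", "g001"], table, onto, ORAConfig(1e-30, "bonferroni")
            )

    def test_planted_term_survives_filter(self, small_annotated):
        onto, table = small_annotated
        m = build_gene_process(
            [f"g{i:03d}" for i in range(10)], table, onto, ORAConfig(0.05, "bonferroni")
        )
        assert "t_planted" in m.columns
        assert m["t_planted"].sum() == 10


class TestDrugProcessProduct:
    def test_two_targets_same_process(self):
        dg = pd.DataFrame([[1, 1]], index=["D1"], columns=["G1", "G2"])
        gp = pd.DataFrame([[1], [1]], index=["G1", "G2"], columns=["P1"])
        assert drug_process_product(dg, gp).loc["D1", "P1"] == 2

    def test_identity_returns_gene_process(self):
        gp = pd.DataFrame(
            [[1, 0], [0, 1], [1, 1]], index=list("abc"), columns=["P1", "P2"]
        )
        dg = pd.DataFrame(np.eye(3, dtype=int), index=list("xyz"), columns=list("abc"))
        out = drug_process_product(dg, gp)
        assert (out.to_numpy() == gp.to_numpy()).all()

    def test_label_alignment_not_positional(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(6)]
        dg = pd.DataFrame(rng.integers(0, 2, (4, 6)), index=list("wxyz"), columns=genes)
        gp = pd.DataFrame(
            rng.integers(0, 2, (6, 3)), index=genes, columns=["P1", "P2", "P3"]
        )
        shuffled = gp.sample(frac=1.0, random_state=1)  # permute gene rows
        assert drug_process_product(dg, shuffled).equals(drug_process_product(dg, gp))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_d, n_g, n_p = rng.integers(2, 10, size=3)
        dg = pd.DataFrame(
            rng.integers(0, 2, (n_d, n_g)),
            index=[f"D{i}" for i in range(n_d)],
            columns=[f"G{i}" for i in range(n_g)],
        )
        gp = pd.DataFrame(
            rng.integers(0, 2, (n_g, n_p)),
            index=list(dg.columns),
            columns=[f"P{i}" for i in range(n_p)],
        )
        out = drug_process_product(dg, gp)
        for d in dg.index:
            for p in gp.columns:
                want = sum(int(dg.loc[d, g]) * int(gp.loc[g, p]) for g in dg.columns)
                assert out.loc[d, p] == want

    def test_gene_mismatch_errors(self):
        dg = pd.DataFrame([[1]], index=["D1"], columns=["G1"])
        gp = pd.DataFrame([[1]], index=["G2"], columns=["P1"])
        with pytest.raises(MatrixBuildError):
            drug_process_product(dg, gp)


class TestVirtualDrug:
    def test_counts_and_saturation(self, small_annotated):
        onto, table = small_annotated
        vd = build_virtual_drug(["g000"], table, ["t_planted", "t0"])
        assert vd["t_planted"] == 1
        vd_all = build_virtual_drug(
            [f"g{i:03d}" for i in range(10)], table, ["t_planted"]
        )
        assert vd_all["t_planted"] == 10  # saturated at the query size

    def test_counts_equal_column_sums(self, small_annotated):
        onto, table = small_annotated
        trait = [f"g{i:03d}" for i in range(7)]
        terms = sorted({t for g in trait for t in table.terms_of(g)})
        vd = build_virtual_drug(trait, table, terms)
        for t in terms:
            assert vd[t] == sum(1 for g in trait if t in table.terms_of(g))

    def test_all_zero_errors(self, small_annotated):
        onto, table = small_annotated
        with pytest.raises(NoSharedProcessError):
            build_virtual_drug(["g050"], table, ["t_planted"])


class TestRestrictShared:
    def test_nothing_dropped_when_fully_shared(self):
        dp = pd.DataFrame([[1, 2], [3, 1]], index=["D1", "D2"], columns=["P1", "P2"])
        vd = pd.Series([2, 1], index=["P1", "P2"], name=VIRTUAL_DRUG_LABEL)
        out, kept = restrict_shared(dp, vd)
        assert kept == ["P1", "P2"]
        assert list(out.index) == ["D1", "D2", VIRTUAL_DRUG_LABEL]

    def test_virtual_zero_column_dropped(self):
        dp = pd.DataFrame([[5, 1]], index=["D1"], columns=["P1", "P2"])
        vd = pd.Series([0, 1], index=["P1", "P2"], name=VIRTUAL_DRUG_LABEL)
        out, kept = restrict_shared(dp, vd)
        assert kept == ["P2"]

    def test_unsupported_drugs_dropped(self):
        dp = pd.DataFrame(
            [[1, 0], [0, 2], [0, 3]],
            index=["D1", "D2", "D3"],
            columns=["P1", "P2"],
        )
        vd = pd.Series([1, 0], index=["P1", "P2"], name=VIRTUAL_DRUG_LABEL)
        out, kept = restrict_shared(dp, vd)
        assert kept == ["P1"]
        assert list(out.index) == ["D1", VIRTUAL_DRUG_LABEL]

    def test_no_overlap_errors(self):
        dp = pd.DataFrame([[1]], index=["D1"], columns=["P1"])
        vd = pd.Series([0], index=["P1"], name=VIRTUAL_DRUG_LABEL)
        with pytest.raises(NoSharedProcessError):
            restrict_shared(dp, vd)


class TestDistances:
    def _matrix(self, rows, labels):
        m = pd.DataFrame(rows, index=labels, columns=[f"P{i}" for i in range(len(rows[0]))])
        return m

    def test_identical_vector_zero(self):
        m = self._matrix([[3, 0], [3, 0]], ["D1", VIRTUAL_DRUG_LABEL])
        assert distances_to_virtual(m)["D1"] == 0.0

    def test_three_four_five(self):
        m = self._matrix([[0, 4], [3, 0]], ["D1", VIRTUAL_DRUG_LABEL])
        assert distances_to_virtual(m)["D1"] == pytest.approx(5.0)

    def test_matches_bruteforce_and_column_permutation(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 5, (11, 6))
        labels = [f"D{i}" for i in range(10)] + [VIRTUAL_DRUG_LABEL]
        m = self._matrix(rows.tolist(), labels)
        d = distances_to_virtual(m)
        for i in range(10):
            want = np.sqrt(((rows[i] - rows[-1]) ** 2).sum())
            assert d[f"D{i}"] == pytest.approx(want)
        shuffled = m[rng.permutation(m.columns)]
        assert distances_to_virtual(shuffled).equals(d)

    def test_standardize_switch(self):
        m = self._matrix([[0, 4], [3, 0]], ["D1", VIRTUAL_DRUG_LABEL])
        d = distances_to_virtual(m, standardize=True)
        # each column has sd 1.5 and 2 -> scaled diffs are both 2
        assert d["D1"] == pytest.approx(np.sqrt(8.0))

    def test_missing_virtual_row(self):
        m = self._matrix([[1, 2]], ["D1"])
        with pytest.raises(MatrixBuildError):
            distances_to_virtual(m)
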