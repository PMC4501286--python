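"""Matrix and scale predictors: scanning, scoring, parameter I/O, registry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epitopescan as es
from epitopescan.binding_predictors import MHC2_METHOD, _as_matrix_map
from epitopescan.sequence_io import FormatError

from conftest import motif_matrices, random_matrix, random_peptide

AA = es.AA_ALPHABET


class TestScanPeptides:
    @pytest.mark.parametrize(
        "sequence,n,expected_starts",
        [
            ("ACDEFGHIK", 9, [1]),
            ("ACDEFGHIKLM", 9, [1, 2, 3]),
            ("ACDEFGHI", 9, []),
        ],
    )
    def test_window_counts(self, sequence, n, expected_starts):
        peptides = es.scan_peptides(sequence, n)
        assert [s for s, _ in peptides] == expected_starts
        assert all(p == sequence[s - 1 : s - 1 + n] for s, p in peptides)


class TestScorePeptide:
    def test_zero_matrix(self):
        m = es.ScoringMatrix("z", np.zeros((9, 20)))
        assert es.score_peptide(m, "ACDEFGHIK") == 0.0

    def test_additive_ones(self):
        m = es.ScoringMatrix("ones", np.ones((9, 20)))
        assert es.score_peptide(m, "WYWYWYWYW") == pytest.approx(9.0)

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            m = random_matrix("t", seed=trial)
            pep = random_peptide(rng)
            expected = 0.0
            for p, aa in enumerate(pep):
                expected += m.values[p, AA.index(aa)]
            assert es.score_peptide(m, pep) == pytest.approx(expected, rel=1e-12)

    def test_x_contributes_zero(self, toy_matrix):
        with_x = "ACDEXGHIK"
        expected = sum(
            toy_matrix.values[p, AA.index(aa)] for p, aa in enumerate(with_x) if aa != "X"
        )
        assert es.score_peptide(toy_matrix, with_x) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch(self, toy_matrix):
        with pytest.raises(ValueError, match="length"):
            es.score_peptide(toy_matrix, "ACDEF")

    def test_unknown_residue(self, toy_matrix):
        with pytest.raises(ValueError, match="B"):
            es.score_peptide(toy_matrix, "ACDEFGHIB")

    @given(st.integers(0, 2**31 - 1))
    def test_additivity_of_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m1 = es.ScoringMatrix("a", rng.normal(size=(9, 20)))
        m2 = es.ScoringMatrix("b", rng.normal(size=(9, 20)))
        msum = es.ScoringMatrix("s", m1.values + m2.values)
        pep = random_peptide(rng)
        assert es.score_peptide(msum, pep) == pytest.approx(
            es.score_peptide(m1, pep) + es.score_peptide(m2, pep), rel=1e-12, abs=1e-12
        )

    def test_translation_invariance(self, toy_matrix):
        # the score depends only on the peptide string, not its source context
        pep = "MKLVINACD"
        p = es.Proteome(
            "g",
            [
                es.ProteinRecord("a", "g", "WWW" + pep + "YYY"),
                es.ProteinRecord("b", "g", pep),
            ],
        )
        res = es.predict_mhc2(p, [toy_matrix])
        score_in_context = res[(res.protein_id == "a") & (res.start == 4)].score.iloc[0]
        score_alone = res[res.protein_id == "b"].score.iloc[0]
        assert score_in_context == pytest.approx(score_alone, rel=1e-12)


class TestPredictMhc2:
    def proteome(self, lengths):
        recs = [
            es.ProteinRecord(f"p{i}", "g", random_peptide(np.random.default_rng(i), n=L))
            for i, L in enumerate(lengths)
        ]
        return es.Proteome("g", recs)

    def test_row_count_single_protein_two_alleles(self):
        p = self.proteome([9])
        mats = {"A1": random_matrix("A1", 1), "A2": random_matrix("A2", 2)}
        assert len(es.predict_mhc2(p, mats)) == 2

    def test_row_count_law(self):
        p = self.proteome([9, 10, 20])
        res = es.predict_mhc2(p, [random_matrix("A1", 1)])
        assert len(res) == 1 + 2 + 12

    def test_unknown_allele_lists_available(self):
        p = self.proteome([9])
        with pytest.raises(ValueError, match="A1"):
            es.predict_mhc2(p, {"A1": random_matrix("A1", 1)}, alleles=["nope"])

    def test_method_and_peptide_columns(self):
        p = self.proteome([12])
        res = es.predict_mhc2(p, [random_matrix("A1", 1)])
        assert (res["method"] == MHC2_METHOD).all()
        seq = p.records[0].sequence
        for row in res.itertuples():
            assert row.peptide == seq[row.start - 1 : row.start + 8]

    def test_planted_motif_scores_maximally(self):
        motif = "ACDEFGHIK"
        mats = motif_matrices(motif, n_alleles=2, seed=3)
        p = es.generate_random_proteome(4, (80, 120), seed=5)
        planted, placements = es.plant_epitopes(p, motif, ["SYN0002", "SYN0003"], 2, seed=6)
        res = es.predict_mhc2(planted, mats)
        matrix = mats["DRB1_0001"]
        motif_score = es.score_peptide(matrix, motif)
        assert motif_score == pytest.approx(matrix.values.max(axis=1).sum())
        for carrier, starts in placements.items():
            sub = res[(res.protein_id == carrier) & (res.allele == "DRB1_0001")]
            top = sub.loc[sub.score.idxmax()]
            assert int(top.start) in starts
            assert top.score == pytest.approx(motif_score)


class TestPredictBcell:
    def test_constant_scale(self):
        scale = es.PropensityScale("const", {aa: 2.5 for aa in AA}, window=7)
        p = es.generate_random_proteome(2, (30, 30), seed=1)
        res = es.predict_bcell(p, scale)
        assert np.allclose(res["score"], 2.5)
        assert len(res) == 2 * (30 - 7 + 1)

    def test_window_equals_length_gives_whole_sequence_mean(self):
        rng = np.random.default_rng(2)
        vals = {aa: float(rng.normal()) for aa in AA}
        seq = random_peptide(rng, n=9)
        scale = es.PropensityScale("s", vals, window=9)
        p = es.Proteome("g", [es.ProteinRecord("p1", "g", seq)])
        res = es.predict_bcell(p, scale)
        assert len(res) == 1
        assert res.score.iloc[0] == pytest.approx(np.mean([vals[aa] for aa in seq]), rel=1e-12)

    def test_window_one_reproduces_scale(self):
        rng = np.random.default_rng(3)
        vals = {aa: float(rng.normal()) for aa in AA}
        scale = es.PropensityScale("s", vals, window=1)
        seq = random_peptide(rng, n=25)
        p = es.Proteome("g", [es.ProteinRecord("p1", "g", seq)])
        res = es.predict_bcell(p, scale)
        assert list(res.score) == pytest.approx([vals[aa] for aa in seq], rel=1e-12)

    def test_matches_sliding_sum_oracle(self):
        rng = np.random.default_rng(4)
        vals = {aa: float(rng.normal()) for aa in AA}
        scale = es.PropensityScale("s", vals, window=7)
        p = es.generate_random_proteome(3, (40, 80), seed=5)
        res = es.predict_bcell(p, scale)
        for row in res.itertuples():
            expected = sum(vals[aa] for aa in row.peptide) / 7
            assert row.score == pytest.approx(expected, rel=1e-12)

    def test_x_contributes_zero_with_full_divisor(self):
        vals = {aa: 1.0 for aa in AA}
        scale = es.PropensityScale("s", vals, window=5)
        p = es.Proteome("g", [es.ProteinRecord("p1", "g", "AAXAA")])
        res = es.predict_bcell(p, scale)
        assert res.score.iloc[0] == pytest.approx(4.0 / 5.0)

    def test_short_protein_skipped_with_warning(self, caplog):
        scale = es.PropensityScale("s", {aa: 1.0 for aa in AA}, window=7)
        p = es.Proteome(
            "g",
            [es.ProteinRecord("tiny", "g", "ACDEF"), es.ProteinRecord("ok", "g", "ACDEFGHIK")],
        )
        with caplog.at_level("WARNING"):
            res = es.predict_bcell(p, scale)
        assert set(res.protein_id) == {"ok"}
        assert any("tiny" in m for m in caplog.messages)


class TestParameterFiles:
    def test_matrix_roundtrip(self, tmp_path):
        mats = [random_matrix("DRB1_0101", 1), random_matrix("DRB1_0401", 2)]
        path = tmp_path / "m.txt"
        es.write_matrix_file(mats, path)
        back = es.load_matrix_file(path)
        assert [m.allele for m in back] == ["DRB1_0101", "DRB1_0401"]
        for orig, new in zip(mats, back):
            assert np.allclose(orig.values, new.values, rtol=1e-12)

    def test_fixture_file_dimensions(self, tmp_path):
        path = tmp_path / "m.txt"
        es.write_matrix_file([random_matrix("A1", 3)], path)
        (m,) = es.load_matrix_file(path)
        assert m.n == 9 and m.values.shape == (9, 20)

    def test_missing_residue_column_named(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "#allele A1 n 1\n#residues ACDEFGHIKLMNPQRSTVW\n" + "\t".join(["1"] * 20) + "\n"
        )
        with pytest.raises(FormatError, match="Y"):
            es.load_matrix_file(path)

    def test_wrong_cell_count_reports_line(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("#allele A1 n 1\n" + "\t".join(["1"] * 19) + "\n")
        with pytest.raises(FormatError, match=":2"):
            es.load_matrix_file(path)

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "m.txt"
        cells = ["1"] * 20
        cells[5] = "oops"
        path.write_text("#allele A1 n 1\n" + "\t".join(cells) + "\n")
        with pytest.raises(FormatError, match="non-numeric"):
            es.load_matrix_file(path)

    def test_wrong_row_count(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("#allele A1 n 9\n" + "\t".join(["1"] * 20) + "\n")
        with pytest.raises(FormatError, match="rows"):
            es.load_matrix_file(path)

    def test_scale_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        scale = es.PropensityScale("parker", {aa: float(rng.normal()) for aa in AA}, window=5)
        path = tmp_path / "s.txt"
        es.write_scale_file(scale, path)
        back = es.load_scale_file(path)
        assert back.name == "parker" and back.window == 5
        for aa in AA:
            assert back.values[aa] == pytest.approx(scale.values[aa], rel=1e-12)

    def test_scale_missing_residue(self):
        with pytest.raises(ValueError, match="W"):
            es.PropensityScale("bad", {aa: 1.0 for aa in AA if aa != "W"})


class TestRegistry:
    def test_register_and_lookup(self, toy_matrix):
        reg = es.PredictorRegistry()
        spec = es.make_mhc2_spec([toy_matrix])
        reg.register(spec)
        assert reg.get("tepitope") is spec

    def test_duplicate_name_rejected(self, toy_matrix):
        reg = es.PredictorRegistry()
        reg.register(es.make_mhc2_spec([toy_matrix]))
        with pytest.raises(ValueError, match="already registered"):
            reg.register(es.make_mhc2_spec([toy_matrix]))

    def test_mock_adapter_flows_through_analysis(self, toy_matrix):
        """A registered external-adapter spec that emits fixed rows produces the
        same thresholding/promiscuity results as the built-in predictor whose
        table it mirrors: downstream analysis is predictor-agnostic."""
        p = es.generate_random_proteome(3, (30, 60), seed=12)
        mats = {"A1": random_matrix("A1", 1), "A2": random_matrix("A2", 2)}
        builtin = es.predict_mhc2(p, mats)

        mocked = builtin.copy()
        mocked["method"] = "mockext"
        spec = es.PredictorSpec(
            name="mockext",
            peptide_length=9,
            alleles=("A1", "A2"),
            predict=lambda proteome, alleles=None: mocked,
        )
        reg = es.PredictorRegistry()
        reg.register(spec)
        emitted = reg.get("mockext").run(p)

        prom_pairs = []
        for table in (builtin, emitted):
            thresholds = es.compute_global_thresholds(table, levels=[10.0], seed=0)
            binders = es.select_binders(table, thresholds, 10.0)
            prom_pairs.append(es.find_promiscuous(binders, k=2))
        pd.testing.assert_frame_equal(prom_pairs[0], prom_pairs[1])

    def test_foreign_method_label_rejected(self, toy_matrix):
        bad = es.PredictorSpec(
            name="mock",
            peptide_length=9,
            alleles=("A1",),
            predict=lambda proteome, alleles=None: es.predict_mhc2(
                proteome, {"A1": toy_matrix}
            ),
        )
        p = es.generate_random_proteome(1, (20, 20), seed=1)
        with pytest.raises(ValueError, match="foreign method"):
            bad.run(p)


def test_matrix_map_duplicate_allele():
    with pytest.raises(ValueError, match="duplicate"):
        _as_matrix_map([random_matrix("A1", 1), random_matrix("A1", 2)])
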