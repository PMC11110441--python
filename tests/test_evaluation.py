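"""Sampling caps, fingerprints, similarity, potency tests and SA scores."""

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from biochemlm.evaluation import (FP_BITS, CandidateSet, compare_potency_distributions,
                                  count_reproduced, evaluate, fingerprint,
                                  nn_similarity, sa_scores, sample_candidates,
                                  significance_stars, tanimoto)


class TestTanimoto:
    def test_identical_fingerprints(self):
        fp = fingerprint("CCO")
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_nonzero(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(a, b) == 0.0

    def test_four_bit_toy_case(self):
        # brute force over bits: |1100 & 1010| / |1100 | 1010| = 1/3
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([1, 0, 1, 0], dtype=np.uint8)
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_both_zero_defined_as_one(self):
        z = np.zeros(8, dtype=np.uint8)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4, dtype=np.uint8), np.zeros(8, dtype=np.uint8))

    def test_agrees_with_rdkit_bulk_tanimoto(self, fixture_molecules):
        """Cross-check the bit-vector arithmetic against the RDKit metric."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        mols = fixture_molecules[:10]
        bvs = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in mols]
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                ref = DataStructs.TanimotoSimilarity(bvs[i], bvs[j])
                mine = tanimoto(fingerprint(mols[i]), fingerprint(mols[j]))
                assert mine == pytest.approx(ref, abs=1e-12)


class TestFingerprint:
    def test_contract(self):
        fp = fingerprint("c1ccccc1O")
        assert fp.shape == (FP_BITS,) == (2048,)
        assert set(np.unique(fp)) <= {0, 1}
        np.testing.assert_array_equal(fp, fingerprint("c1ccccc1O"))

    def test_invalid_molecule_rejected(self):
        with pytest.raises(ValueError):
            fingerprint("notasmiles((")


class TestNNSimilarity:
    def test_query_in_reference_hits_one(self):
        sims = nn_similarity(["CCO"], ["CCN", "CCO", "CCC"])
        assert sims[0] == 1.0

    def test_single_reference_equals_pairwise(self, fixture_molecules):
        q = fixture_molecules[:5]
        ref = [fixture_molecules[10]]
        sims = nn_similarity(q, ref)
        for s, smi in zip(sims, q):
            assert s == pytest.approx(tanimoto(fingerprint(smi), fingerprint(ref[0])))

    def test_matches_bruteforce_pairwise_oracle(self, fixture_molecules):
        queries = fixture_molecules[:20]
        refs = fixture_molecules[20:40]
        sims = nn_similarity(queries, refs)
        for i, q in enumerate(queries):
            brute = max(tanimoto(fingerprint(q), fingerprint(r)) for r in refs)
            assert sims[i] == pytest.approx(brute, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            nn_similarity(["CCO"], [])


class TestCountReproduced:
    def test_full_overlap(self):
        s = {"CCO", "CCN"}
        assert count_reproduced(s, s) == 2

    def test_disjoint(self):
        assert count_reproduced({"CCO"}, {"CCN"}) == 0

    def test_bounded_by_both_sides(self):
        cands = {"CCO", "CCN", "CCC"}
        tests = {"CCO", "CCS"}
        n = count_reproduced(cands, tests)
        assert n <= min(len(cands), len(tests))


class TestPotencyComparison:
    def test_identical_nondegenerate_groups_not_significant(self):
        g = [5.0, 5.5, 6.0, 6.5, 7.0]
        out = compare_potency_distributions({"a": g, "b": list(g)})
        assert out[("a", "b")]["p"] == pytest.approx(1.0)
        assert out[("a", "b")]["stars"] == "ns"

    def test_strongly_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5.0, 0.1, 30)
        b = rng.normal(9.0, 0.1, 30)
        out = compare_potency_distributions({"a": a, "b": b})
        assert out[("a", "b")]["stars"] == "****"

    @pytest.mark.parametrize("p,stars", [
        (0.03, "*"), (0.005, "**"), (5e-4, "***"), (5e-5, "****"),
        (0.2, "ns"), (0.05, "*"), (1e-4, "****"),
    ])
    def test_star_scheme(self, p, stars):
        assert significance_stars(p) == stars

    def test_small_group_annotated_na(self):
        out = compare_potency_distributions({"a": [5.0], "b": [5.0, 6.0, 7.0]})
        assert out[("a", "b")]["stars"] == "NA"


class TestSAScores:
    def test_ethanol_is_trivially_accessible(self):
        assert sa_scores(["CCO"])[0] < 3.0

    def test_deterministic(self):
        a = sa_scores(["CCc1ccc2ccccc2c1"])
        b = sa_scores(["CCc1ccc2ccccc2c1"])
        assert a[0] == b[0]

    def test_scores_on_canonical_scale(self, fixture_molecules):
        scores = sa_scores(fixture_molecules[:30])
        assert len(scores) == 30
        assert np.all((scores >= 1.0) & (scores <= 10.0))

    def test_invalid_molecule_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            scores = sa_scores(["CCO", "notasmiles(("])
        assert len(scores) == 1
        assert "skipping" in caplog.text


class TestSampleCandidates:
    def test_per_instance_cap_and_determinism(self, trained_model, protein_vec):
        instances = {"CCc1ccc2ccccc2c1": 5.0, "Cc1cc2ccccc2o1": 5.5}
        a = sample_candidates(trained_model, protein_vec, instances,
                              per_instance=20, attempt_cap=60, seed=4)
        b = sample_candidates(trained_model, protein_vec, instances,
                              per_instance=20, attempt_cap=60, seed=4)
        for smi in instances:
            assert len(a.per_instance[smi]) <= 20
        assert a.per_instance == b.per_instance

    def test_pooled_candidates_unique(self, trained_model, protein_vec):
        instances = {"CCc1ccc2ccccc2c1": 5.0}
        cands = sample_candidates(trained_model, protein_vec, instances,
                                  per_instance=30, attempt_cap=90, seed=1)
        pooled = cands.pooled
        assert len(pooled) == len(set(pooled))
        for smi in pooled:
            assert Chem.MolFromSmiles(smi) is not None

    def test_attempt_cap_limits_draws(self, tiny_config, tiny_vocab, protein_vec):
        from biochemlm.model import BiochemLM

        hopeless = BiochemLM(tiny_config, tiny_vocab, seed=5)  # untrained
        cands = sample_candidates(hopeless, protein_vec, {"CCO": 5.0},
                                  per_instance=10, attempt_cap=15, seed=0)
        assert cands.raw_draws <= 15


class TestEvaluate:
    def test_report_fields_consistent(self, trained_model, protein_vec):
        ft = {"CCc1ccc2ccccc2c1": 5.0, "Cc1cc2ccccc2o1": 5.5}
        test = {"FCc1ccc(-c2ccccc2)cc1": 6.0, "CCCc1cc2ccccc2[nH]1": 6.5}
        cands = sample_candidates(trained_model, protein_vec, test,
                                  per_instance=20, attempt_cap=60, seed=2)
        report = evaluate("T0", "conditional", cands, ft, test)
        assert report.n_reproduced <= report.n_candidates_unique
        assert np.all((report.nn_candidates_vs_test >= 0)
                      & (report.nn_candidates_vs_test <= 1))
        d = report.to_dict()
        assert d["variant"] == "conditional"
        assert set(d["potency_tests"]) == {"finetune|test", "finetune|reproduced",
                                           "test|reproduced"}

    def test_rerunning_on_same_candidates_is_identical(self):
        cands = CandidateSet(per_instance={"x": ["CCO", "CCN"]}, raw_draws=5)
        ft = {"CCO": 5.0, "CCC": 6.0}
        test = {"CCN": 5.5, "CCS": 6.5}
        r1 = evaluate("T", "conditional", cands, ft, test)
        r2 = evaluate("T", "conditional", cands, ft, test)
        assert r1.to_dict() == r2.to_dict()
        assert r1.n_reproduced == 1
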