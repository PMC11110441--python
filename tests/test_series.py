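"""Fragmentation, analogue-series grouping and the disjoint split."""

from itertools import combinations

import numpy as np
import pytest
from rdkit import Chem

from biochemlm.series import (DEFAULT_RULES, AnalogueSeries, FragmentationError,
                              core_size_filter, eligible_bonds, fragment,
                              group_series, heavy_atoms, reassemble,
                              split_series, write_split)


class TestFragment:
    def test_benzene_has_no_cuttable_bonds(self):
        assert fragment("c1ccccc1") == []

    def test_toluene_like_single_cut(self):
        """Exhaustive single-bond enumeration on ethyl-naphthalene: exactly one
        eligible bond (aromatic C - sp3 C), two orientations."""
        results = fragment("CCc1ccc2ccccc2c1")
        cores = {r.core for r in results}
        assert cores == {"CC[*:1]", "c1ccc2cc([*:1])ccc2c1"}
        for r in results:
            assert reassemble(r.core, r.substituents) == r.parent

    def test_amide_rule_cut(self):
        results = fragment("CC(=O)Nc1ccccc1")
        assert any(set(r.substituents) == {"CC(=O)[*:1]"} for r in results)

    def test_multiple_cut_sites_label_consistency(self):
        # two methyls on naphthalene: the 2-cut fragmentation has a 2-site core
        results = fragment("Cc1ccc2cc(C)ccc2c1")
        two_site = [r for r in results if r.n_sites == 2]
        assert two_site
        for r in two_site:
            assert reassemble(r.core, r.substituents) == r.parent

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(FragmentationError):
            fragment("notasmiles((")

    def test_reassembly_invariant_on_fixture_corpus(self, fixture_molecules):
        for smi in fixture_molecules[:60]:
            for res in fragment(smi, max_cuts=3):
                assert reassemble(res.core, res.substituents) == res.parent

    @staticmethod
    def _capped(smiles: str) -> str:
        """Canonical SMILES with attachment points replaced by hydrogens."""
        mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomicNum(1)
                atom.SetAtomMapNum(0)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(Chem.RemoveHs(mol))

    def test_matches_bruteforce_bond_enumeration(self, fixture_molecules):
        """Independent oracle: delete every combination of <= 3 eligible bonds
        from an RWMol, keep combinations where one piece touches every cut and
        the rest touch exactly one, and compare the fragment identities."""
        small = [s for s in fixture_molecules
                 if Chem.MolFromSmiles(s).GetNumHeavyAtoms() <= 15][:25]
        assert len(small) >= 10
        for smi in small:
            mol = Chem.MolFromSmiles(smi)
            bonds = eligible_bonds(mol)
            expected = set()
            for k in range(1, min(3, len(bonds)) + 1):
                for combo in combinations(bonds, k):
                    em = Chem.RWMol(mol)
                    pairs = [(mol.GetBondWithIdx(b).GetBeginAtomIdx(),
                              mol.GetBondWithIdx(b).GetEndAtomIdx()) for b in combo]
                    for i, j in pairs:
                        em.RemoveBond(i, j)
                    Chem.SanitizeMol(em)
                    frags = Chem.GetMolFrags(em)
                    if len(frags) != k + 1:
                        continue

                    def frag_of(atom):
                        return next(fi for fi, f in enumerate(frags) if atom in f)

                    touch: dict[int, set] = {}
                    for i, j in pairs:
                        for a in (i, j):
                            touch.setdefault(frag_of(a), set()).add((i, j))
                    cores = [fi for fi, cuts in touch.items() if len(cuts) == k]
                    if len(cores) != 1 and k > 1:
                        continue
                    if k > 1 and any(len(c) != 1 for fi, c in touch.items()
                                     if fi != cores[0]):
                        continue
                    pieces = Chem.GetMolFrags(em, asMols=True)
                    expected.add(tuple(sorted(Chem.MolToSmiles(p) for p in pieces)))
            got = {
                tuple(sorted([self._capped(res.core)]
                             + [self._capped(s) for s in res.substituents]))
                for res in fragment(smi, max_cuts=3)
            }
            assert got == expected


class TestCoreSizeFilter:
    def test_boundary(self):
        core12 = "c1ccc2cc(-c3ccccc3)cc([*:1])c2c1"  # not exact atoms; use counts
        assert core_size_filter("c1ccc2cc([*:1])ccc2c1", ["CC[*:1]"])  # 10 vs 2

    def test_exact_two_to_one_accepted(self):
        # core 10 heavy atoms vs substituents totalling 5 -> 10 >= 2*5
        assert core_size_filter("c1ccc2cc([*:1])ccc2c1", ["CCCCC[*:1]"])

    def test_oversized_substituents_rejected(self):
        assert not core_size_filter("c1ccc2cc([*:1])ccc2c1", ["CCCCCC[*:1]"])

    def test_attachment_points_excluded_from_counts(self):
        # atom-enumeration oracle: wildcards do not count as heavy atoms
        assert heavy_atoms("CC[*:1]") == 2
        assert heavy_atoms("[*:1]c1ccc([*:2])cc1") == 6


class TestGroupSeries:
    def test_planted_series_recovered(self, toy_world):
        focal = toy_world.triples[0].target_id
        pki = toy_world.pki_lookup(focal)
        series = group_series(list(pki), pki=pki)
        truth = {frozenset(m) for m in toy_world.series_truth[focal].values()}
        got = {frozenset(s.members) for s in series}
        assert got == truth

    def test_six_analogues_one_core(self):
        scaffold = "c1ccc2cc([*:1])ccc2c1"
        members = [reassemble(scaffold, [s]) for s in
                   ("C[*:1]", "CC[*:1]", "CCC[*:1]", "FC[*:1]", "ClC[*:1]",
                    "OCC[*:1]")]
        series = group_series(members)
        assert len(series) == 1 and len(series[0]) == 6
        assert Chem.MolFromSmiles(series[0].core) is not None

    def test_singletons_dropped(self):
        series = group_series(["CCc1ccc2ccccc2c1", "CCc1cc2ccccc2o1"])
        assert series == []

    def test_compound_in_at_most_one_series(self):
        scaffold_a = "c1ccc2cc([*:1])ccc2c1"
        scaffold_b = "c1ccc2oc([*:1])cc2c1"
        compounds = [reassemble(scaffold_a, [s])
                     for s in ("C[*:1]", "CC[*:1]", "CCC[*:1]")]
        compounds += [reassemble(scaffold_b, [s]) for s in ("C[*:1]", "CC[*:1]")]
        series = group_series(compounds)
        seen = [m for s in series for m in s.members]
        assert len(seen) == len(set(seen))


class TestSplitSeries:
    @staticmethod
    def _synthetic_series(n, rng):
        out = []
        for i in range(n):
            size = int(rng.integers(2, 9))
            out.append(AnalogueSeries(core=f"core{i:03d}[*:1]",
                                      members=[f"M{i}_{j}" for j in range(size)],
                                      pki={f"M{i}_{j}": 6.0 for j in range(size)}))
        return out

    def test_even_split_and_labeling(self):
        rng = np.random.default_rng(0)
        series = self._synthetic_series(100, rng)
        split = split_series(series, seed=17)
        assert len(split.finetune_series) == 50
        assert len(split.test_series) == 50
        assert not (split.finetune_cores & split.test_cores)
        assert len(split.finetune_compounds) <= len(split.test_compounds)

    def test_union_preserves_all_compounds(self):
        series = self._synthetic_series(11, np.random.default_rng(1))
        split = split_series(series, seed=3)
        everything = {m for s in series for m in s.members}
        assert set(split.finetune_compounds) | set(split.test_compounds) == everything
        assert not (set(split.finetune_compounds) & set(split.test_compounds))

    def test_odd_count_extra_series_not_lost(self):
        series = self._synthetic_series(7, np.random.default_rng(2))
        split = split_series(series, seed=1)
        assert len(split.finetune_series) + len(split.test_series) == 7

    def test_same_seed_same_split(self):
        series = self._synthetic_series(20, np.random.default_rng(3))
        a = split_series(series, seed=9)
        b = split_series(series, seed=9)
        assert a.finetune_cores == b.finetune_cores

    def test_too_few_series_rejected(self):
        series = self._synthetic_series(1, np.random.default_rng(4))
        with pytest.raises(ValueError):
            split_series(series, seed=0)

    def test_manifest_written(self, tmp_path):
        series = self._synthetic_series(4, np.random.default_rng(5))
        split = split_series(series, seed=2)
        manifest = write_split(split, tmp_path, rules=DEFAULT_RULES)
        assert manifest.exists()
        assert (tmp_path / "finetune.tsv").exists()
        assert (tmp_path / "test.tsv").exists()
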