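"""Analogue-series identification and structurally disjoint data splitting.

Compounds are fragmented by cutting 1-5 acyclic single bonds drawn from a
configurable retrosynthetic rule set (matched-molecular-pair style).  Each
fragmentation yields one connected core carrying numbered attachment points
and up to five single-attachment substituents; the core must contain at
least twice as many non-hydrogen atoms as all substituents combined.
Compounds sharing an identical canonical core form an analogue series
(singletons are disregarded).  Series are randomly halved into fine-tuning
and test partitions with disjoint core structures; the side with the
smaller total number of compounds is used for fine-tuning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

MAX_CUTS = 5

#: Default retrosynthetic bond set: exocyclic acyclic single bonds at
#: RECAP-style environments.  Each entry is (name, SMARTS, (i, j)) where i, j
#: index the matched atoms whose bond is cut.  The list is a documented,
#: swappable simplification of full retrosynthetic rule collections.
DEFAULT_RULES: tuple[tuple[str, str, tuple[int, int]], ...] = (
    ("amide C-N", "[CX3](=O)-[NX3]", (0, 2)),
    ("ester C-O", "[CX3](=O)-[OX2][#6]", (0, 2)),
    ("amine N-C", "[NX3;!$(N~[C,S]=[O,S,N])]-[CX4]", (0, 1)),
    ("ether O-C", "[OX2;!$(O[C,S]=O)]-[CX4]", (0, 1)),
    ("aromatic C - sp3 C", "[c]-[CX4]", (0, 1)),
    ("sulfonamide S-N", "[SX4](=O)(=O)-[NX3]", (0, 3)),
)


class FragmentationError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentationResult:
    """One way of cutting a molecule into a core plus substituents.

    The core carries numbered wildcard attachment points ``[*:1]``-``[*:5]``;
    each substituent carries the matching label.  Reassembling core and
    substituents reproduces the parent molecule.
    """

    parent: str
    core: str
    substituents: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.substituents)


@dataclass
class AnalogueSeries:
    """Compounds sharing one canonical core, differing only in substituents."""

    core: str
    members: list[str]
    substituents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pki: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SplitResult:
    finetune_series: list[AnalogueSeries]
    test_series: list[AnalogueSeries]
    seed: int

    @property
    def finetune_cores(self) -> set[str]:
        return {s.core for s in self.finetune_series}

    @property
    def test_cores(self) -> set[str]:
        return {s.core for s in self.test_series}

    @property
    def finetune_compounds(self) -> list[str]:
        return [m for s in self.finetune_series for m in s.members]

    @property
    def test_compounds(self) -> list[str]:
        return [m for s in self.test_series for m in s.members]

    def pki_of(self, smiles: str) -> float:
        for s in self.finetune_series + self.test_series:
            if smiles in s.pki:
                return s.pki[smiles]
        raise KeyError(smiles)


# -- fragmentation ------------------------------------------------------------

def heavy_atoms(smiles: str) -> int:
    """Non-hydrogen, non-attachment-point atom count of a fragment SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"unparseable fragment {smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def eligible_bonds(mol: Chem.Mol,
                   rules: Sequence[tuple] = DEFAULT_RULES) -> list[int]:
    """Indices of acyclic single bonds matched by the retrosynthetic rules."""
    bonds: set[int] = set()
    for _, smarts, (i, j) in rules:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[i], match[j])
            if bond is None or bond.IsInRing():
                continue
            if bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            bonds.add(bond.GetIdx())
    return sorted(bonds)


def _relabel_dummies_to_maps(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)


def _canonical_core(core: Chem.Mol, subs: list[Chem.Mol]) -> tuple[str, tuple[str, ...]]:
    """Renumber attachment points canonically so identical cores compare equal.

    Attachment maps are assigned 1..k following the canonical atom ranking of
    the map-stripped core; substituent labels are remapped to match.
    """
    work = Chem.Mol(core)
    for a in work.GetAtoms():
        a.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(work, breakTies=True))
    dummies = [a.GetIdx() for a in core.GetAtoms() if a.GetAtomicNum() == 0]
    order = sorted(dummies, key=lambda i: ranks[i])
    remap = {core.GetAtomWithIdx(i).GetAtomMapNum(): new + 1
             for new, i in enumerate(order)}
    out = Chem.Mol(core)
    for a in out.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(remap[a.GetAtomMapNum()])
    new_subs = []
    for s in subs:
        sm = Chem.Mol(s)
        for a in sm.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(remap[a.GetAtomMapNum()])
        new_subs.append(Chem.MolToSmiles(sm))
    # sort substituents by their attachment label for a stable tuple
    def label(smi: str) -> int:
        m = Chem.MolFromSmiles(smi)
        return next(a.GetAtomMapNum() for a in m.GetAtoms() if a.GetAtomicNum() == 0)

    return Chem.MolToSmiles(out), tuple(sorted(new_subs, key=label))


def fragment(smiles: str, max_cuts: int = MAX_CUTS,
             rules: Sequence[tuple] = DEFAULT_RULES) -> list[FragmentationResult]:
    """All core/substituent fragmentations from cutting 1..max_cuts rule bonds.

    A bond combination is valid when exactly one fragment (the core) touches
    every cut and each remaining fragment touches exactly one.  For single
    cuts both orientations are returned; downstream filtering decides which
    side may serve as a core.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"unparseable SMILES {smiles!r}")
    parent = Chem.MolToSmiles(mol)
    bonds = eligible_bonds(mol, rules)
    results: list[FragmentationResult] = []
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for k in range(1, min(max_cuts, len(bonds)) + 1):
        for combo in combinations(bonds, k):
            frag = Chem.FragmentOnBonds(
                mol, list(combo), addDummies=True,
                dummyLabels=[(i + 1, i + 1) for i in range(k)],
            )
            _relabel_dummies_to_maps(frag)
            try:
                pieces = list(Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True))
            except Chem.rdchem.AtomValenceException:  # pragma: no cover
                continue
            if len(pieces) != k + 1:
                continue  # a cut inside a ring path did not split the molecule
            counts = [sum(1 for a in p.GetAtoms() if a.GetAtomicNum() == 0)
                      for p in pieces]
            core_candidates = [i for i, c in enumerate(counts) if c == k]
            if k == 1:
                orientations = [(0, [1]), (1, [0])]
            else:
                if len(core_candidates) != 1:
                    continue
                ci = core_candidates[0]
                if any(c != 1 for i, c in enumerate(counts) if i != ci):
                    continue
                orientations = [(ci, [i for i in range(len(pieces)) if i != ci])]
            for ci, sub_idx in orientations:
                core_smi, sub_smis = _canonical_core(pieces[ci],
                                                     [pieces[i] for i in sub_idx])
                key = (core_smi, tuple(sorted(sub_smis)))
                if key not in seen:
                    seen.add(key)
                    results.append(FragmentationResult(parent, core_smi, sub_smis))
    return results


def reassemble(core: str, substituents: Iterable[str]) -> str:
    """Rejoin a core and its labeled substituents into the parent molecule."""
    mol = Chem.MolFromSmiles(core)
    for smi in substituents:
        mol = Chem.CombineMols(mol, Chem.MolFromSmiles(smi))
    zipped = Chem.molzip(mol)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def core_size_filter(core: str, substituents: Iterable[str]) -> bool:
    """Core must carry at least twice the heavy atoms of all substituents."""
    return heavy_atoms(core) >= 2 * sum(heavy_atoms(s) for s in substituents)


# -- series grouping and splitting --------------------------------------------

def group_series(compounds: Sequence[str],
                 pki: dict[str, float] | None = None,
                 max_cuts: int = MAX_CUTS,
                 rules: Sequence[tuple] = DEFAULT_RULES,
                 ) -> list[AnalogueSeries]:
    """Group compounds into analogue series by shared canonical core.

    Every compound joins at most one series; candidate cores are consumed
    largest-first (ties broken by lexicographically smallest core string)
    and series of size one are dropped.
    """
    pki = pki or {}
    core_members: dict[str, dict[str, tuple[str, ...]]] = {}
    for smi in compounds:
        for res in fragment(smi, max_cuts=max_cuts, rules=rules):
            if not core_size_filter(res.core, res.substituents):
                continue
            core_members.setdefault(res.core, {})[smi] = res.substituents
    assigned: set[str] = set()
    series: list[AnalogueSeries] = []
    while True:
        best_core, best_free = None, None
        for core, members in core_members.items():
            free = [m for m in members if m not in assigned]
            if len(free) < 2:
                continue
            if (best_free is None or len(free) > len(best_free)
                    or (len(free) == len(best_free) and core < best_core)):
                best_core, best_free = core, free
        if best_core is None:
            break
        assigned.update(best_free)
        members = sorted(best_free)
        series.append(AnalogueSeries(
            core=best_core,
            members=members,
            substituents={m: core_members[best_core][m] for m in members},
            pki={m: pki[m] for m in members if m in pki},
        ))
    return series


def split_series(series: Sequence[AnalogueSeries], seed: int) -> SplitResult:
    """Randomly halve the series into core-disjoint fine-tuning/test sides.

    With an odd series count the extra series goes to the test side; the
    side with the smaller total compound count is labeled fine-tuning.
    """
    if len(series) < 2:
        raise ValueError("need at least two analogue series to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(series))
    half = len(series) // 2
    side_a = [series[i] for i in order[:half]]
    side_b = [series[i] for i in order[half:]]  # gets the extra series if odd
    n_a = sum(len(s) for s in side_a)
    n_b = sum(len(s) for s in side_b)
    if n_a <= n_b:
        finetune, test = side_a, side_b
    else:
        finetune, test = side_b, side_a
    return SplitResult(finetune_series=finetune, test_series=test, seed=seed)


# -- I/O ----------------------------------------------------------------------

def write_split(split: SplitResult, out_dir: str | Path,
                rules: Sequence[tuple] = DEFAULT_RULES) -> Path:
    """Series TSVs plus a JSON manifest recording seed, rules and counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, side in (("finetune", split.finetune_series), ("test", split.test_series)):
        lines = ["core\tcanonical_smiles\tpki"]
        for s in side:
            for m in s.members:
                lines.append(f"{s.core}\t{m}\t{s.pki.get(m, float('nan'))}")
        (out_dir / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "seed": split.seed,
        "rules": [r[0] for r in rules],
        "n_finetune_series": len(split.finetune_series),
        "n_test_series": len(split.test_series),
        "n_finetune_compounds": len(split.finetune_compounds),
        "n_test_compounds": len(split.test_compounds),
    }
    path = out_dir / "split.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
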