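"""Self-contained synthetic chemistry world for desk-scale testing.

The generator assembles compounds as scaffold + substituent(s) from small
curated pools, so analogue-series structure is planted by construction and
recoverable by the fragmentation machinery.  Potency follows a known
additive rule, pKi = base(target) + sum(contribution(substituent)) + noise,
which makes the potency value statistically informative about the compound
— the signal that potency conditioning is supposed to exploit.  Scaffolds
are shared across targets while each target draws its substituents from a
disjoint subset of the pool, so compound sets never overlap between
activity classes (as in the real corpus) and a model that has never seen a
class's substituent chemistry cannot trivially emit its compounds.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .curation import canonical_smiles
from .embeddings import BuiltinKmerEmbedder, EmbeddingCache
from .evaluation import CandidateSet, EvaluationReport, evaluate, sample_candidates
from .model import ModelConfig
from .series import group_series, heavy_atoms, reassemble, split_series
from .tokenization import PotencyBinner
from .training import Checkpoint, TrainingPlan, Triple, finetune, pretrain

logger = logging.getLogger(__name__)

#: Two-attachment-point aromatic cores, each >= 12 heavy atoms so the
#: core-size filter accepts every substituent pair (<= 3 heavy atoms each).
#: Two sites make the compound space combinatorial: exact reproduction of a
#: held-out compound requires composing the right scaffold with the right
#: substituent pair, which chance sampling essentially never does.
SCAFFOLD_POOL: tuple[str, ...] = (
    "c1ccc(-c2ccc([*:1])c([*:2])c2)cc1",        # biphenyl
    "[*:1]c1ccc2c(c1)oc1cc([*:2])ccc12",        # dibenzofuran
    "[*:1]c1ccc2c(c1)[nH]c1cc([*:2])ccc12",     # carbazole
    "[*:1]c1ccc2c(c1)Cc1cc([*:2])ccc1-2",       # fluorene
    "[*:1]c1ccc2cc3cc([*:2])ccc3cc2c1",         # anthracene
    "[*:2]c1ccc(-c2ccc3ncc([*:1])cc3c2)cc1",    # phenylisoquinoline
    "[*:1]c1ccc(-c2ccc3[nH]c([*:2])cc3c2)cc1",  # phenylindole
    "[*:1]c1ccc(-c2ccc3sc([*:2])cc3c2)cc1",     # phenylbenzothiophene
    "[*:1]c1ccc(-c2ccc3oc([*:2])cc3c2)cc1",     # phenylbenzofuran
    "[*:1]c1ccc(-c2ccc([*:2])cn2)cc1",          # phenylpyridine
)

#: Substituents attached through an sp3 carbon (cut by the aromatic C - sp3 C
#: rule), 1-4 heavy atoms each.  Pairs are drawn with a combined size cap so
#: the core-size filter accepts every assembled compound.
SUBSTITUENT_POOL: tuple[str, ...] = (
    "C[*:1]",
    "CC[*:1]", "FC[*:1]", "ClC[*:1]", "OC[*:1]", "NC[*:1]",
    "CCC[*:1]", "CC([*:1])C", "FCC[*:1]", "ClCC[*:1]", "OCC[*:1]", "NCC[*:1]",
    "C=CC[*:1]", "COC[*:1]", "CNC[*:1]", "CC([*:1])F", "CC([*:1])O",
    "CC([*:1])N", "C#CC[*:1]",
    "CCCC[*:1]", "CC(C)C[*:1]", "CC([*:1])(C)C", "FCCC[*:1]", "ClCCC[*:1]",
    "OCCC[*:1]", "NCCC[*:1]", "CCOC[*:1]", "CCNC[*:1]", "CC=CC[*:1]",
    "CC(C)([*:1])O", "CC(C)([*:1])N", "FC(F)(F)[*:1]", "OCC([*:1])C",
    "NCC([*:1])C", "C#CCC[*:1]", "ClCC([*:1])C",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ToyWorldConfig:
    """Study conditions for the synthetic world."""

    n_targets: int = 3
    series_per_target: int = 6
    members_per_series: int = 10
    scaffold_pool: tuple[str, ...] = SCAFFOLD_POOL
    substituent_pool: tuple[str, ...] = SUBSTITUENT_POOL
    base_pki_range: tuple[float, float] = (4.8, 6.8)
    #: substituent potency contribution = slope * heavy_atoms + jitter: bulk
    #: drives potency, a global structure-activity rule every class shares,
    #: so conditioning semantics are learnable during pre-training and only
    #: the class-specific details must come from fine-tuning
    contribution_slope: float = 0.35
    contribution_jitter: float = 0.15
    noise_sd: float = 0.1
    #: substituents per target (disjoint across targets)
    substituents_per_target: int = 12
    #: size of the class-level substituent-set pool: each series draws its
    #: members from these shared combinations, so the same substituent pair
    #: recurs on several scaffolds — as substituents recur across real
    #: analogue series — giving scaffold-invariant potency evidence
    pairs_per_target: int = 12
    #: combined heavy-atom cap for a substituent set on one scaffold, keeping
    #: every fragmentation inside the core-size filter
    max_combined_sub_atoms: int = 6
    #: potency values land on this reporting grid (pKi units); coarser than
    #: the 0.01 tokenization bins, so bins recur across compounds the way a
    #: densely annotated corpus covers them
    pki_grid: float = 0.1
    seq_length_range: tuple[int, int] = (50, 300)
    seed: int = 0


@dataclass(frozen=True)
class ToyTriple:
    target_id: str
    sequence: str
    smiles: str  # canonical
    pki: float


@dataclass
class ToyWorld:
    config: ToyWorldConfig
    triples: list[ToyTriple]
    sequences: dict[str, str]
    #: ground truth: target -> scaffold -> member canonical SMILES
    series_truth: dict[str, dict[str, list[str]]]
    #: potency rule actually used: bases per target, contribution per substituent
    bases: dict[str, float]
    contributions: dict[str, float]

    def class_triples(self, target_id: str) -> list[ToyTriple]:
        return [t for t in self.triples if t.target_id == target_id]

    def pki_lookup(self, target_id: str) -> dict[str, float]:
        return {t.smiles: t.pki for t in self.class_triples(target_id)}


def generate_world(config: ToyWorldConfig) -> ToyWorld:
    """Assemble the toy world deterministically from the config seed."""
    if not config.scaffold_pool or not config.substituent_pool:
        raise ValueError("scaffold and substituent pools must be non-empty")
    if config.series_per_target > len(config.scaffold_pool):
        raise ValueError("not enough scaffolds in the pool")
    per_target = config.substituents_per_target
    need = config.n_targets * per_target
    if need > len(config.substituent_pool):
        raise ValueError(
            f"substituent pool too small: need {need} for disjoint per-target sets"
        )
    rng = np.random.default_rng(config.seed)
    binner = PotencyBinner()

    contributions = {
        sub: float(config.contribution_slope * heavy_atoms(sub)
                   + rng.uniform(-config.contribution_jitter,
                                 config.contribution_jitter))
        for sub in config.substituent_pool
    }
    sub_order = list(rng.permutation(len(config.substituent_pool)))

    sequences: dict[str, str] = {}
    bases: dict[str, float] = {}
    triples: list[ToyTriple] = []
    truth: dict[str, dict[str, list[str]]] = {}
    scaffolds = list(config.scaffold_pool[: config.series_per_target])

    for t in range(config.n_targets):
        tid = f"T{t:03d}"
        length = int(rng.integers(*config.seq_length_range, endpoint=True))
        sequences[tid] = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        bases[tid] = float(rng.uniform(*config.base_pki_range))
        lo = t * per_target
        subs = [config.substituent_pool[i] for i in sub_order[lo:lo + per_target]]
        truth[tid] = {}
        sub_atoms = {s: heavy_atoms(s) for s in subs}
        k_sites = {scaffold: scaffold.count("[*:") for scaffold in scaffolds}
        # class-level pool of substituent sets shared across the scaffolds
        pair_pool: dict[int, list[tuple[int, ...]]] = {}
        for k in set(k_sites.values()):
            combos = [c for c in combinations(range(len(subs)), k)
                      if sum(sub_atoms[subs[i]] for i in c)
                      <= config.max_combined_sub_atoms]
            n_pool = min(max(config.pairs_per_target, config.members_per_series),
                         len(combos))
            if n_pool < config.members_per_series:
                raise ValueError(
                    f"cannot draw {config.members_per_series} distinct "
                    f"substituent {k}-sets from {len(subs)} substituents"
                )
            pool_idx = rng.choice(len(combos), size=n_pool, replace=False)
            pair_pool[k] = [combos[i] for i in pool_idx]
        for scaffold in scaffolds:
            combos = pair_pool[k_sites[scaffold]]
            picks = rng.choice(len(combos), size=config.members_per_series,
                               replace=False)
            members = []
            for pick in picks:
                chosen = [subs[i] for i in combos[pick]]
                placed = [s.replace("[*:1]", f"[*:{j + 1}]")
                          for j, s in enumerate(chosen)]
                smi = canonical_smiles(reassemble(scaffold, placed))
                if smi is None:  # pragma: no cover - pools are pre-validated
                    logger.warning("invalid assembly %s + %s; skipped",
                                   scaffold, chosen)
                    continue
                pki = (bases[tid] + sum(contributions[s] for s in chosen)
                       + rng.normal(0.0, config.noise_sd))
                pki = round(pki / config.pki_grid) * config.pki_grid
                pki = float(np.clip(pki, binner.lo, binner.hi))
                members.append(smi)
                triples.append(ToyTriple(tid, sequences[tid], smi, round(pki, 4)))
            truth[tid][scaffold] = members
    return ToyWorld(config=config, triples=triples, sequences=sequences,
                    series_truth=truth, bases=bases, contributions=contributions)


def write_world(world: ToyWorld, out_dir: str | Path) -> None:
    """Write the TSV/FASTA files the real pipeline reads, plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["smiles\ttarget_id\trelationship\tconfidence\tki_nM"]
    for t in world.triples:
        ki_nM = 10 ** (9 - t.pki)
        rows.append(f"{t.smiles}\t{t.target_id}\tD\t9\t{ki_nM:.6g}")
    (out / "activities.tsv").write_text("\n".join(rows) + "\n")
    fasta = "".join(f">{tid}\n{seq}\n" for tid, seq in world.sequences.items())
    (out / "targets.fasta").write_text(fasta)
    (out / "truth.json").write_text(json.dumps({
        "series": world.series_truth,
        "bases": world.bases,
        "contributions": world.contributions,
        "config": {k: v for k, v in world.config.__dict__.items()
                   if not isinstance(v, tuple) or k.endswith("_range")},
    }, indent=2))


# -- random molecule generator for property tests ------------------------------

_DECORATION_SCAFFOLDS = (
    "c1ccccc1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccncc1",
    "c1ccc2ncccc2c1", "c1ccc2occc2c1", "c1ccsc1", "c1ccc(-c2ccccc2)cc1",
    "c1cncnc1",
)

_DECORATIONS = (
    "C[*:1]", "CC[*:1]", "CC([*:1])C", "OC[*:1]", "O[*:1]", "N[*:1]",
    "CN([*:1])C", "F[*:1]", "Cl[*:1]", "Br[*:1]", "N#C[*:1]",
    "O=[N+]([O-])[*:1]", "NS(=O)(=O)[*:1]", "FC(F)(F)[*:1]", "C(=O)(N)[*:1]",
)


def random_molecules(n: int, seed: int = 0, max_sites: int = 3) -> list[str]:
    """`n` distinct valid canonical SMILES assembled from small pools.

    Aromatic scaffolds are decorated at 1-3 random CH positions with random
    substituents (including bracketed-token chemistry such as nitro groups),
    giving a diverse corpus for round-trip and fragmentation tests.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        scaffold = _DECORATION_SCAFFOLDS[rng.integers(len(_DECORATION_SCAFFOLDS))]
        mol = Chem.RWMol(Chem.MolFromSmiles(scaffold))
        k = int(rng.integers(1, max_sites + 1))
        subs = []
        ok = True
        for j in range(k):
            sites = [a.GetIdx() for a in mol.GetAtoms()
                     if a.GetIsAromatic() and a.GetTotalNumHs() > 0
                     and a.GetAtomicNum() == 6]
            if not sites:
                ok = False
                break
            site = int(sites[rng.integers(len(sites))])
            dummy = mol.AddAtom(Chem.Atom(0))
            mol.GetAtomWithIdx(dummy).SetAtomMapNum(j + 1)
            mol.AddBond(site, dummy, Chem.BondType.SINGLE)
            mol.GetAtomWithIdx(site).SetNumExplicitHs(0)
            sub = _DECORATIONS[rng.integers(len(_DECORATIONS))]
            subs.append(sub.replace("[*:1]", f"[*:{j + 1}]"))
        if not ok:
            continue
        try:
            Chem.SanitizeMol(mol)
            smi = reassemble(Chem.MolToSmiles(mol), subs)
        except Exception:
            continue
        if smi and smi not in seen:
            seen.add(smi)
            out.append(smi)
    if len(out) < n:
        raise RuntimeError(f"could only generate {len(out)} distinct molecules")
    return out


# -- learnability probe ---------------------------------------------------------

@dataclass(frozen=True)
class DeskProfile:
    """CPU-sized model and schedule for the probe (not the full-scale profile)."""

    d_model: int = 128
    n_heads: int = 2
    d_feedforward: int = 256
    dropout: float = 0.0
    pretrain_epochs: int = 140
    finetune_epochs: int = 30
    learning_rate: float = 7e-4
    finetune_learning_rate: float = 2e-4
    grad_accumulation: int = 8
    per_instance: int = 40
    attempt_cap: int = 160
    max_len: int = 60


@dataclass
class ProbeClassResult:
    variant: str
    n_candidates_unique: int
    n_candidates_raw: int
    n_reproduced: int
    report: EvaluationReport


@dataclass
class ProbeReport:
    seed: int
    focal_target: str
    n_finetune: int
    n_test: int
    conditional: ProbeClassResult
    unconditional: ProbeClassResult
    control: ProbeClassResult  # pre-trained conditional model, no fine-tuning

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "focal_target": self.focal_target,
            "n_finetune": self.n_finetune,
            "n_test": self.n_test,
            "reproduced": {
                "conditional": self.conditional.n_reproduced,
                "unconditional": self.unconditional.n_reproduced,
                "no_finetune_control": self.control.n_reproduced,
            },
            "candidates_unique": {
                "conditional": self.conditional.n_candidates_unique,
                "unconditional": self.unconditional.n_candidates_unique,
                "no_finetune_control": self.control.n_candidates_unique,
            },
        }


def _to_triples(pairs: dict[str, float], target_id: str, vec: np.ndarray,
                binner: PotencyBinner) -> list[Triple]:
    return [Triple(target_id, vec, binner.bin(p), s) for s, p in sorted(pairs.items())]


def learnability_probe(config: ToyWorldConfig | None = None, seed: int = 0,
                       profile: DeskProfile = DeskProfile()) -> ProbeReport:
    """End-to-end desk-scale check that potency conditioning has signal.

    Generates a seeded world, holds out the first target as the focal
    activity class, splits it into core-disjoint fine-tuning/test sides,
    pre-trains conditional and unconditional models on the remaining
    classes, fine-tunes each on the focal fine-tuning side, samples
    candidates for every test instance, and reports exact-reproduction
    counts — including the no-fine-tuning control, which samples from the
    pre-trained conditional model directly.
    """
    config = replace(config or ToyWorldConfig(), seed=seed)
    world = generate_world(config)
    binner = PotencyBinner()
    embedder = BuiltinKmerEmbedder(dim=profile.d_model, seed=7)
    cache = EmbeddingCache(embedder)

    focal = world.triples[0].target_id
    focal_pki = world.pki_lookup(focal)
    series = group_series(list(focal_pki), pki=focal_pki)
    split = split_series(series, seed=seed)
    ft_pairs = {s: split.pki_of(s) for s in split.finetune_compounds}
    test_pairs = {s: split.pki_of(s) for s in split.test_compounds}
    focal_vec = cache.get(world.sequences[focal])

    pretrain_triples = [
        Triple(t.target_id, cache.get(t.sequence), binner.bin(t.pki), t.smiles)
        for t in world.triples if t.target_id != focal
    ]
    ft_triples = _to_triples(ft_pairs, focal, focal_vec, binner)

    pre_plan = TrainingPlan.desk(
        epochs=profile.pretrain_epochs, learning_rate=profile.learning_rate,
        grad_accumulation=profile.grad_accumulation, seed=seed,
        dropout_enabled=profile.dropout > 0,
    )
    ft_plan = replace(pre_plan, epochs=profile.finetune_epochs,
                      learning_rate=profile.finetune_learning_rate, seed=seed + 1)

    def evaluate_ckpt(ckpt: Checkpoint, variant: str, sample_seed: int) -> ProbeClassResult:
        model = ckpt.build()
        cands = sample_candidates(
            model, focal_vec, test_pairs, per_instance=profile.per_instance,
            attempt_cap=profile.attempt_cap, seed=sample_seed, binner=binner,
        )
        report = evaluate(focal, variant, cands, ft_pairs, test_pairs)
        return ProbeClassResult(variant, cands.n_unique, cands.raw_draws,
                                report.n_reproduced, report)

    def config_for(conditional: bool) -> ModelConfig:
        return ModelConfig.desk(n_heads=profile.n_heads, d_model=profile.d_model,
                                d_feedforward=profile.d_feedforward,
                                dropout=profile.dropout,
                                conditional=conditional, max_len=profile.max_len)

    from .tokenization import SmilesVocabulary
    vocab = SmilesVocabulary.from_corpus(
        [t.smiles for t in pretrain_triples] + [t.smiles for t in ft_triples]
    )

    # desk-scale training runs in float32 for speed; gradients at this
    # precision are ample for the probe (the library default stays float64)
    from .autodiff import get_default_dtype, set_default_dtype

    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32)
    try:
        cond_pre = pretrain(pretrain_triples, pre_plan, config_for(True), vocab=vocab)
        cond_ft = finetune(cond_pre, ft_triples, ft_plan)
        uncond_pre = pretrain(pretrain_triples, pre_plan, config_for(False), vocab=vocab)
        uncond_ft = finetune(uncond_pre, ft_triples, ft_plan)
    finally:
        set_default_dtype(prev_dtype)
    control = evaluate_ckpt(cond_pre, "no-finetune", sample_seed=seed + 13)
    conditional = evaluate_ckpt(cond_ft, "conditional", sample_seed=seed + 11)
    unconditional = evaluate_ckpt(uncond_ft, "unconditional", sample_seed=seed + 12)
    return ProbeReport(
        seed=seed, focal_target=focal,
        n_finetune=len(ft_pairs), n_test=len(test_pairs),
        conditional=conditional, unconditional=unconditional, control=control,
    )


def probe_suite(seeds: Sequence[int], config: ToyWorldConfig | None = None,
                profile: DeskProfile = DeskProfile()) -> list[ProbeReport]:
    """The probe repeated over seeds (conditioning should win in most)."""
    return [learnability_probe(config, seed=s, profile=profile) for s in seeds]
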