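"""Candidate sampling and the evaluation statistics.

For each test compound a (protein embedding, potency embedding) input is
built from its experimental potency, and up to 100 valid SMILES are drawn
by multinomial sampling (a per-instance attempt cap keeps degenerate models
from looping forever).  Candidates are canonicalized and pooled per class
as unique strings.  Evaluation covers exact reproduction counts, 1-nearest-
neighbor Tanimoto similarity on 2048-bit Morgan fingerprints (radius 3),
potency-distribution comparisons with Welch t-tests, and synthetic-
accessibility score distributions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .curation import canonical_smiles
from .model import BiochemLM
from .tokenization import PotencyBinner

logger = logging.getLogger(__name__)

FP_BITS = 2048
FP_RADIUS = 3
PER_INSTANCE = 100
ATTEMPT_CAP = 1000

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


@dataclass
class CandidateSet:
    """Sampled candidates: per test instance and pooled unique per class."""

    per_instance: dict[str, list[str]]
    raw_draws: int = 0

    @property
    def pooled(self) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        for smis in self.per_instance.values():
            for s in smis:
                if s not in seen:
                    seen.add(s)
                    out.append(s)
        return out

    @property
    def n_unique(self) -> int:
        return len(self.pooled)


def sample_candidates(model: BiochemLM, protein_vec: np.ndarray,
                      test_instances: Mapping[str, float],
                      per_instance: int = PER_INSTANCE,
                      attempt_cap: int = ATTEMPT_CAP,
                      seed: int = 0,
                      binner: PotencyBinner | None = None) -> CandidateSet:
    """Sample up to `per_instance` valid compounds for every test instance.

    `test_instances` maps a test compound's canonical SMILES to its
    experimental pKi, which conditions the draw (ignored by unconditional
    models).  Draws continue until `per_instance` valid SMILES are collected
    or `attempt_cap` attempts are spent; an instance yielding nothing is
    flagged with a warning rather than treated as fatal.
    """
    binner = binner or PotencyBinner()
    rng = np.random.default_rng(seed)
    conditional = model.config.conditional
    items = list(test_instances.items())
    remaining = {smi: per_instance for smi, _ in items}
    attempts = {smi: 0 for smi, _ in items}
    collected: dict[str, list[str]] = {smi: [] for smi, _ in items}
    raw = 0
    while True:
        batch_keys: list[str] = []
        batch_bins: list[int] = []
        for smi, pki in items:
            need = remaining[smi]
            budget = attempt_cap - attempts[smi]
            n = min(need, budget)
            batch_keys.extend([smi] * n)
            batch_bins.extend([binner.bin(pki)] * n)
        if not batch_keys:
            break
        vecs = np.repeat(protein_vec[None, :], len(batch_keys), axis=0)
        bins = np.asarray(batch_bins) if conditional else None
        seqs, _ = model.sample_batch(vecs, bins, rng)
        raw += len(seqs)
        for key, ids in zip(batch_keys, seqs):
            attempts[key] += 1
            if remaining[key] == 0:
                continue
            smi_out = canonical_smiles(model.vocab.decode(ids)) if ids else None
            # valid means the canonical form itself re-parses (rare RDKit
            # edge cases can emit canonical strings that do not)
            if smi_out and Chem.MolFromSmiles(smi_out) is not None:
                collected[key].append(smi_out)
                remaining[key] -= 1
    for smi, _ in items:
        if not collected[smi]:
            logger.warning("no valid samples for test instance %s within cap", smi)
    return CandidateSet(per_instance=collected, raw_draws=raw)


def count_reproduced(candidates: Iterable[str], test_set: Iterable[str]) -> int:
    """Exactly reproduced test compounds, by canonical-string equality."""
    return len(set(candidates) & set(test_set))


# -- fingerprints and similarity ----------------------------------------------

def fingerprint(smiles: str) -> np.ndarray:
    """2048-bit Morgan fingerprint (radius 3) as a uint8 0/1 array."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    bv = _fpgen.GetFingerprint(mol)
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over equal-length binary fingerprints.

    Defined as 1.0 when both fingerprints are all-zero.
    """
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def nn_similarity(query_set: Sequence[str], reference_set: Sequence[str]) -> np.ndarray:
    """Per-query maximum Tanimoto coefficient against the reference set."""
    if not len(query_set):
        return np.zeros(0)
    if not len(reference_set):
        raise ValueError("empty reference set")
    q = np.stack([fingerprint(s) for s in query_set]).astype(np.int64)
    r = np.stack([fingerprint(s) for s in reference_set]).astype(np.int64)
    inter = q @ r.T
    union = q.sum(1)[:, None] + r.sum(1)[None, :] - inter
    sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return sim.max(axis=1)


# -- potency statistics --------------------------------------------------------

def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_potency_distributions(groups: Mapping[str, Sequence[float]]
                                  ) -> dict[tuple[str, str], dict]:
    """Pairwise Welch t-tests between labeled pKi distributions.

    Returns p-values with the star annotation scheme used in the figures;
    pairs involving a group of fewer than two values are annotated "NA".
    """
    labels = list(groups)
    out: dict[tuple[str, str], dict] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ga, gb = np.asarray(groups[a], float), np.asarray(groups[b], float)
            if len(ga) < 2 or len(gb) < 2:
                out[(a, b)] = {"p": None, "stars": "NA"}
                continue
            if (np.array_equal(np.sort(ga), np.sort(gb))
                    and np.ptp(ga) == 0 and np.ptp(gb) == 0):
                out[(a, b)] = {"p": 1.0, "stars": "ns"}
                continue
            res = stats.ttest_ind(ga, gb, equal_var=False)
            p = float(res.pvalue)
            if np.isnan(p):
                p = 1.0
            out[(a, b)] = {"p": p, "stars": significance_stars(p)}
    return out


# -- synthetic accessibility ---------------------------------------------------

_sascorer = None


def _get_sascorer():
    """RDKit's shipped fragment-contribution synthetic-accessibility scorer."""
    global _sascorer
    if _sascorer is None:
        import sys
        from rdkit.Chem import RDConfig
        sys.path.append(str(Path(RDConfig.RDContribDir) / "SA_Score"))
        import sascorer  # type: ignore
        _sascorer = sascorer
    return _sascorer


def sa_scores(smiles: Iterable[str]) -> np.ndarray:
    """Per-molecule synthetic-accessibility scores on the 1-10 scale.

    Low scores mean easy to synthesize; invalid molecules are skipped with
    a warning.
    """
    scorer = _get_sascorer()
    out = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.warning("sa_scores: skipping invalid SMILES %r", s)
            continue
        out.append(scorer.calculateScore(mol))
    return np.asarray(out)


# -- report --------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class evaluation of one model variant against a split."""

    target_id: str
    variant: str  # "conditional" | "unconditional" | "no-finetune"
    n_candidates_unique: int
    n_candidates_raw: int
    n_reproduced: int
    nn_candidates_vs_test: np.ndarray
    nn_reproduced_vs_finetune: np.ndarray
    potency_tests: dict = field(default_factory=dict)
    potency_groups: dict[str, list[float]] = field(default_factory=dict)
    sa_finetune: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sa_candidates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_dict(self) -> dict:
        def summarize(x: np.ndarray) -> dict:
            if len(x) == 0:
                return {"n": 0}
            return {"n": int(len(x)), "median": float(np.median(x)),
                    "mean": float(np.mean(x)), "min": float(np.min(x)),
                    "max": float(np.max(x))}

        return {
            "target_id": self.target_id,
            "variant": self.variant,
            "n_candidates_unique": self.n_candidates_unique,
            "n_candidates_raw": self.n_candidates_raw,
            "n_reproduced": self.n_reproduced,
            "nn_candidates_vs_test": summarize(self.nn_candidates_vs_test),
            "nn_reproduced_vs_finetune": summarize(self.nn_reproduced_vs_finetune),
            "potency_tests": {f"{a}|{b}": v for (a, b), v in self.potency_tests.items()},
            "sa_finetune": summarize(self.sa_finetune),
            "sa_candidates": summarize(self.sa_candidates),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(target_id: str, variant: str, candidates: CandidateSet,
             finetune: Mapping[str, float], test: Mapping[str, float]) -> EvaluationReport:
    """Compute the full per-class report for one sampled candidate set.

    `finetune` and `test` map canonical SMILES to experimental pKi.
    """
    pooled = candidates.pooled
    reproduced = sorted(set(pooled) & set(test))
    nn_cand = nn_similarity(pooled, list(test)) if pooled else np.zeros(0)
    nn_rep = (nn_similarity(reproduced, list(finetune))
              if reproduced and finetune else np.zeros(0))
    groups = {
        "finetune": list(finetune.values()),
        "test": list(test.values()),
        "reproduced": [test[s] for s in reproduced],
    }
    report = EvaluationReport(
        target_id=target_id,
        variant=variant,
        n_candidates_unique=candidates.n_unique,
        n_candidates_raw=candidates.raw_draws,
        n_reproduced=len(reproduced),
        nn_candidates_vs_test=nn_cand,
        nn_reproduced_vs_finetune=nn_rep,
        potency_tests=compare_potency_distributions(groups),
        potency_groups={k: list(v) for k, v in groups.items()},
        sa_finetune=sa_scores(finetune) if finetune else np.zeros(0),
        sa_candidates=sa_scores(pooled) if pooled else np.zeros(0),
    )
    return report


def plot_report(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Optional boxplot/histogram figures mirroring the evaluation report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = {k: v for k, v in report.potency_groups.items() if len(v)}
    if groups:
        ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
        ax.set_ylabel("pKi")
        ax.set_title(f"{report.target_id} ({report.variant})")
        p = out_dir / f"{report.target_id}_{report.variant}_potency.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    if len(report.nn_candidates_vs_test):
        ax.hist(report.nn_candidates_vs_test, bins=20, alpha=0.6,
                label="candidates vs test")
    if len(report.nn_reproduced_vs_finetune):
        ax.hist(report.nn_reproduced_vs_finetune, bins=20, alpha=0.6,
                label="reproduced vs fine-tuning")
    ax.set_xlabel("1-NN Tanimoto similarity")
    ax.legend()
    p = out_dir / f"{report.target_id}_{report.variant}_nn.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    paths.append(p)
    plt.close(fig)
    return paths
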