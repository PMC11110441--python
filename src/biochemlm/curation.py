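"""Activity-data curation: from raw assay tables to target-based activity classes.

Selection rules: direct binding interactions only (assay relationship type
``"D"``), highest assay confidence (score 9), numerically specified Ki
values, and targets with a monomer sequence of at most 4000 residues.
Ki values (nM) are converted to pKi = -log10(Ki in M).  When a compound has
several measurements against the same target, the geometric mean of Ki is
used as the final potency annotation provided all values fall within the
same order of magnitude (max/min <= 10); otherwise the compound is excluded
from the class.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

MAX_SEQUENCE_LENGTH = 4000
#: largest tolerated Ki spread among replicate measurements ("same order of magnitude")
MAX_KI_RATIO = 10.0

ACTIVITY_COLUMNS = ("smiles", "target_id", "relationship", "confidence", "ki_nM")


class REJECT:
    """Sentinel: compound excluded because replicate Ki values disagree."""


def canonical_smiles(smiles: str) -> str | None:
    """The single deterministic canonicalizer used everywhere in the package.

    Compound identity throughout the pipeline is equality of these strings.
    Returns None for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def pki_from_ki_nM(ki_nM: float) -> float:
    """pKi = -log10(Ki in molar units) for a Ki given in nM."""
    if not ki_nM > 0:
        raise ValueError(f"Ki must be positive, got {ki_nM}")
    return -math.log10(ki_nM * 1e-9)


@dataclass(frozen=True)
class ActivityRecord:
    """One curated compound-target potency annotation."""

    compound_smiles: str  # canonical
    target_id: str
    pki: float


@dataclass
class ActivityClass:
    """All curated records for one target."""

    target_id: str
    target_sequence: str
    records: list[ActivityRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def filter_rows(rows: pd.DataFrame, sequences: Mapping[str, str]) -> pd.DataFrame:
    """Apply the selection rules to a raw activity table.

    `rows` needs columns smiles, target_id, relationship, confidence, ki_nM.
    Malformed rows (missing Ki, unknown target sequence, non-positive Ki,
    bad confidence) are dropped with a logged warning, not an error.
    """
    missing = [c for c in ACTIVITY_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"activity table lacks columns: {missing}")
    df = rows.copy()
    n0 = len(df)

    ki = pd.to_numeric(df["ki_nM"], errors="coerce")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    has_seq = df["target_id"].map(lambda t: t in sequences)
    seq_ok = df["target_id"].map(
        lambda t: t in sequences and 1 <= len(sequences[t]) <= MAX_SEQUENCE_LENGTH
    )

    keep = (
        (df["relationship"].astype(str) == "D")
        & (conf == 9)
        & ki.notna()
        & (ki > 0)
        & seq_ok
    )
    dropped_no_seq = int((~has_seq).sum())
    if dropped_no_seq:
        logger.warning("%d rows dropped: target sequence unavailable", dropped_no_seq)
    dropped = n0 - int(keep.sum())
    if dropped:
        logger.warning("filter_rows: %d of %d rows removed", dropped, n0)
    out = df.loc[keep].copy()
    out["ki_nM"] = ki.loc[keep]
    return out


def aggregate_potency(ki_values_nM: Iterable[float]) -> float | type[REJECT]:
    """Final potency for replicate Ki measurements of one compound.

    Geometric mean of Ki converted to pKi — equivalently the arithmetic
    mean of per-measurement pKi — provided all values fall within the same
    order of magnitude (max/min <= 10); otherwise :class:`REJECT`.
    """
    values = [float(v) for v in ki_values_nM]
    if not values:
        raise ValueError("no Ki values to aggregate")
    if any(not v > 0 for v in values):
        raise ValueError("Ki values must be positive")
    if max(values) / min(values) > MAX_KI_RATIO * (1 + 1e-12):
        return REJECT
    return float(np.mean([pki_from_ki_nM(v) for v in values]))


def build_classes(rows: pd.DataFrame, sequences: Mapping[str, str]) -> dict[str, ActivityClass]:
    """Group filtered rows into target-based activity classes.

    SMILES are canonicalized once at ingestion; replicate measurements are
    aggregated per (target, canonical compound); compounds whose replicates
    disagree by more than an order of magnitude are excluded.  Classes left
    with zero compounds are omitted.
    """
    df = rows.copy()
    df["canonical"] = df["smiles"].map(canonical_smiles)
    bad = df["canonical"].isna()
    if bad.any():
        logger.warning("%d rows dropped: unparseable SMILES", int(bad.sum()))
        df = df.loc[~bad]

    classes: dict[str, ActivityClass] = {}
    for target_id, group in df.groupby("target_id", sort=True):
        records = []
        for smi, meas in group.groupby("canonical", sort=True):
            pki = aggregate_potency(meas["ki_nM"].tolist())
            if pki is REJECT:
                logger.info("compound %s excluded from %s: inconsistent Ki", smi, target_id)
                continue
            records.append(ActivityRecord(smi, str(target_id), round(pki, 4)))
        if records:
            classes[str(target_id)] = ActivityClass(
                target_id=str(target_id),
                target_sequence=sequences[target_id],
                records=records,
            )
    return classes


# -- I/O ----------------------------------------------------------------------

def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV activity table with the named columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Target sequences keyed by FASTA record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_classes(classes: Mapping[str, ActivityClass], out_dir: str | Path) -> Path:
    """One TSV per class (canonical_smiles, pki) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for target_id, cls in sorted(classes.items()):
        fn = out_dir / f"{target_id}.tsv"
        pd.DataFrame(
            {"canonical_smiles": [r.compound_smiles for r in cls.records],
             "pki": [r.pki for r in cls.records]}
        ).to_csv(fn, sep="\t", index=False)
        manifest[target_id] = {
            "file": fn.name,
            "n_compounds": len(cls),
            "sequence_length": len(cls.target_sequence),
        }
    manifest_path = out_dir / "classes.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_class(path: str | Path, target_id: str | None = None,
               sequence: str = "") -> ActivityClass:
    """Load an activity-class TSV written by :func:`write_classes`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    tid = target_id or path.stem
    records = [ActivityRecord(s, tid, float(p))
               for s, p in zip(df["canonical_smiles"], df["pki"])]
    return ActivityClass(target_id=tid, target_sequence=sequence, records=records)
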