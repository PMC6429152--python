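"""Sequence records, interaction-pair tables, negative sampling and CV folds.

An :class:`RPIDataset` bundles RNA and protein :class:`SequenceRecord` objects
with labeled :class:`InteractionPair` rows.  Benchmarks of this kind usually
ship only the observed (positive) pairs, so balanced training sets are built
by :func:`generate_negatives`: RNAs and proteins occurring in positive pairs
are re-paired at random, and a candidate pair is discarded when it resembles
a known interaction — i.e. some positive pair exists whose RNA shares >= 80%
identity with the candidate RNA *and* whose protein shares >= 40% identity
with the candidate protein.

Sequence identity follows the clustering convention of counting aligned
matches relative to the shorter sequence: the global alignment maximizes the
number of matches (match +1, mismatch 0, gaps free), and identity is
matches / min(len(a), len(b)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import PROTEIN, RNA

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Malformed dataset input."""


class InsufficientCandidatesError(RuntimeError):
    """Negative-pair sampling could not reach the requested count."""

    def __init__(self, requested: int, found: int):
        self.requested, self.found = requested, found
        super().__init__(
            f"only {found} admissible negative pairs found, {requested} requested "
            f"(shortfall {requested - found})"
        )


@dataclass
class SequenceRecord:
    """One RNA or protein sequence, optionally with an aligned structure string."""

    id: str
    molecule: str  # "rna" | "protein"
    sequence: str
    structure: str | None = None

    def __post_init__(self):
        if not self.id:
            raise DatasetError("record id must be nonempty")
        if self.molecule not in (RNA, PROTEIN):
            raise DatasetError(f"unknown molecule {self.molecule!r}")
        if not self.sequence:
            raise DatasetError(f"record {self.id!r}: empty sequence")
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise DatasetError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class InteractionPair:
    rna_id: str
    protein_id: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise DatasetError(f"label must be 0/1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.rna_id, self.protein_id)


@dataclass
class RPIDataset:
    """Sequence records plus labeled interaction pairs.

    ``rnas`` and ``proteins`` are id-keyed dicts; every pair's ids must
    resolve and (rna_id, protein_id) keys must be unique.
    """

    rnas: dict[str, SequenceRecord] = field(default_factory=dict)
    proteins: dict[str, SequenceRecord] = field(default_factory=dict)
    pairs: list[InteractionPair] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for p in self.pairs:
            if p.key in seen:
                raise DatasetError(f"duplicate pair {p.key}")
            seen.add(p.key)
            if p.rna_id not in self.rnas:
                raise DatasetError(f"pair references unknown RNA {p.rna_id!r}")
            if p.protein_id not in self.proteins:
                raise DatasetError(f"pair references unknown protein {p.protein_id!r}")

    @property
    def positives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def negatives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 0]

    def with_pairs(self, pairs: Sequence[InteractionPair]) -> "RPIDataset":
        return RPIDataset(self.rnas, self.proteins, list(pairs))

    def has_structures(self) -> bool:
        recs = list(self.rnas.values()) + list(self.proteins.values())
        return all(r.structure is not None for r in recs)


@dataclass(frozen=True)
class IdentityThresholds:
    """Similarity-discard thresholds for negative-pair generation."""

    rna_identity: float = 0.80
    protein_identity: float = 0.40

    def __post_init__(self):
        for v in (self.rna_identity, self.protein_identity):
            if not 0.0 <= v <= 1.0:
                raise DatasetError(f"identity threshold {v} outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_fasta(path, molecule: str) -> list[SequenceRecord]:
    """Read FASTA into records; IDs are the first header token, bodies uppercased."""
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DatasetError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, molecule, str(entry.seq).upper()))
    if not records:
        raise DatasetError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[SequenceRecord]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path), "fasta",
    )


def read_structures(path) -> dict[str, str]:
    """Read a FASTA-like structure file: the 'sequence' line is the structure."""
    structs = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in structs:
            raise DatasetError(f"duplicate structure id {entry.id!r} in {path}")
        structs[entry.id] = str(entry.seq)
    if not structs:
        raise DatasetError(f"no structure records in {path}")
    return structs


def write_structures(path, records: Iterable[SequenceRecord]) -> None:
    recs = [r for r in records if r.structure is not None]
    SeqIO.write(
        (SeqRecord(Seq(r.structure), id=r.id, description="") for r in recs),
        str(path), "fasta",
    )


def attach_structures(records: Sequence[SequenceRecord],
                      structures: dict[str, str]) -> list[SequenceRecord]:
    """Return copies of ``records`` with structure strings attached by id."""
    out = []
    for r in records:
        if r.id not in structures:
            raise DatasetError(f"no structure for record {r.id!r}")
        out.append(replace(r, structure=structures[r.id]))
    return out


def read_pairs(path) -> list[InteractionPair]:
    """Read a pair table: TSV with columns rna_id, protein_id[, label].

    A header row is optional and detected by the third column not parsing as
    an integer.  A missing label column defaults to 1 (observed interaction).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] not in (2, 3):
        raise DatasetError(f"pair table {path} must have 2 or 3 columns")
    first = df.iloc[0]
    try:
        if df.shape[1] == 3:
            int(first.iloc[2])
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise DatasetError(f"empty pair table {path}")
    labels = df.iloc[:, 2].astype(int) if df.shape[1] == 3 else pd.Series(1, index=df.index)
    return [
        InteractionPair(str(r), str(p), int(l))
        for r, p, l in zip(df.iloc[:, 0], df.iloc[:, 1], labels)
    ]


def write_pairs(path, pairs: Iterable[InteractionPair]) -> None:
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\n")
        for p in pairs:
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{p.label}\n")


# ---------------------------------------------------------------------------
# Sequence identity and negative-pair generation
# ---------------------------------------------------------------------------

_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = 0
_ALIGNER.open_gap_score = 0
_ALIGNER.extend_gap_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: max #matches / length of the shorter sequence.

    Match scores +1 and mismatches/gaps score 0, so the optimal score is the
    longest common subsequence; the shorter-sequence denominator follows the
    CD-HIT convention.  Symmetric, in [0, 1].
    """
    if not a or not b:
        raise DatasetError("pairwise_identity requires nonempty sequences")
    matches = _ALIGNER.score(a, b)
    return float(matches) / min(len(a), len(b))


class _IdentityCache:
    """Memoized pairwise identity over a fixed record dict."""

    def __init__(self, records: dict[str, SequenceRecord]):
        self.records = records
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        key = (id_a, id_b) if id_a < id_b else (id_b, id_a)
        if key not in self._cache:
            self._cache[key] = pairwise_identity(
                self.records[id_a].sequence, self.records[id_b].sequence
            )
        return self._cache[key]


def similar_to_positive(rna_id: str, protein_id: str,
                        positives: Sequence[InteractionPair],
                        rna_ident, prot_ident,
                        thresholds: IdentityThresholds) -> bool:
    """True if some positive (R2, P2) has rna identity >= t_rna AND protein >= t_prot."""
    for pos in positives:
        if (rna_ident(rna_id, pos.rna_id) >= thresholds.rna_identity
                and prot_ident(protein_id, pos.protein_id) >= thresholds.protein_identity):
            return True
    return False


def generate_negatives(dataset: RPIDataset,
                       thresholds: IdentityThresholds = IdentityThresholds(),
                       seed: int = 0,
                       attempt_factor: int = 1000) -> list[InteractionPair]:
    """Sample non-interaction pairs by random re-pairing with a similarity discard.

    Draws (rna, protein) uniformly with replacement from the entities of the
    positive pairs until as many admissible negatives as positives are found.
    A candidate is discarded when it duplicates a positive pair or an accepted
    negative, or when it is similar to a known interaction per
    :func:`similar_to_positive`.  Reproducible under ``seed``; gives up after
    ``attempt_factor * n_positives`` draws.
    """
    positives = dataset.positives
    if not positives:
        raise DatasetError("dataset has no positive pairs")
    n_needed = len(positives)
    rng = np.random.default_rng(seed)
    rna_ids = sorted({p.rna_id for p in positives})
    prot_ids = sorted({p.protein_id for p in positives})
    rna_ident = _IdentityCache(dataset.rnas)
    prot_ident = _IdentityCache(dataset.proteins)
    taken = {p.key for p in positives}
    out: list[InteractionPair] = []
    for _ in range(attempt_factor * n_needed):
        if len(out) == n_needed:
            break
        r = rna_ids[rng.integers(len(rna_ids))]
        p = prot_ids[rng.integers(len(prot_ids))]
        if (r, p) in taken:
            continue
        if similar_to_positive(r, p, positives, rna_ident, prot_ident, thresholds):
            continue
        out.append(InteractionPair(r, p, 0))
        taken.add((r, p))
    if len(out) < n_needed:
        raise InsufficientCandidatesError(n_needed, len(out))
    logger.info("generated %d negative pairs (seed=%d)", len(out), seed)
    return out


def deduplicate_positives(dataset: RPIDataset,
                          thresholds: IdentityThresholds = IdentityThresholds()) -> RPIDataset:
    """Optionally drop positive pairs whose RNA *and* protein are near-duplicates
    of an earlier kept positive (same conjunction as the negative discard rule)."""
    rna_ident = _IdentityCache(dataset.rnas)
    prot_ident = _IdentityCache(dataset.proteins)
    kept: list[InteractionPair] = []
    for p in dataset.positives:
        if not similar_to_positive(p.rna_id, p.protein_id, kept, rna_ident,
                                   prot_ident, thresholds):
            kept.append(p)
    return dataset.with_pairs(kept + dataset.negatives)


# ---------------------------------------------------------------------------
# Stratified cross-validation folds
# ---------------------------------------------------------------------------

def stratified_kfold(pairs: Sequence[InteractionPair], k: int = 5,
                     seed: int = 0) -> list[list[InteractionPair]]:
    """Partition pairs into k folds with per-class counts proportional within 1."""
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise DatasetError(f"k must be >= 2, got {k}")
    labels = np.array([p.label for p in pairs])
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if 0 < n_cls < k:
            raise DatasetError(f"class {cls} has {n_cls} pairs, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [[pairs[i] for i in test_idx]
            for _, test_idx in skf.split(np.zeros(len(pairs)), labels)]
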