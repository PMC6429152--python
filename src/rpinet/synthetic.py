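"""Seeded synthetic RNA-protein interaction data with a planted, learnable rule.

The generator emulates the shape of curated RPI benchmarks — variable-length
sequences, balanced positive/negative pair tables, per-sequence secondary
structure strings — without any biophysics.  Interaction is decided by a
motif conjunction: a pair is positive iff the RNA contains ``rna_motif`` and
the protein contains ``protein_motif`` (optionally flipped with probability
``label_noise``).  Motifs are planted into a configurable fraction of the
entities so both classes are well populated; because the rule is a function
of k-mer content, the planted signal is representable by the conjoint-triad
family encoders.

Structure strings carry no interaction signal: protein structures are
three-state (H/E/C) strings with geometrically distributed run lengths, and
RNA structures are random balanced dot-bracket strings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import (DatasetError, InteractionPair, RPIDataset, SequenceRecord,
                      write_fasta, write_pairs, write_structures)
from .encoding import PROTEIN, RNA

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGU"


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults give a mid-sized benchmark-shaped problem: a few hundred
    entities with lengths 50-250 (real collections span roughly 0-4000, but
    most chains sit in the low hundreds), 1000 positive and 1000 negative
    pairs, a 4-nt RNA motif and a 3-aa protein motif (within the encoders'
    k ranges), and noise-free labels.
    """

    n_rna: int = 150
    n_protein: int = 150
    rna_length_range: tuple[int, int] = (50, 250)
    protein_length_range: tuple[int, int] = (50, 250)
    n_positive: int = 1000
    rna_motif: str = "AUCG"
    protein_motif: str = "CWK"
    plant_fraction: float = 0.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.rna_length_range, self.protein_length_range):
            if not (0 < lo <= hi):
                raise SyntheticConfigError(f"bad length range ({lo}, {hi})")
        if len(self.rna_motif) > self.rna_length_range[0]:
            raise SyntheticConfigError("rna_motif longer than minimum RNA length")
        if len(self.protein_motif) > self.protein_length_range[0]:
            raise SyntheticConfigError("protein_motif longer than minimum protein length")
        if set(self.rna_motif) - set(NUCLEOTIDES):
            raise SyntheticConfigError("rna_motif must be over ACGU")
        if set(self.protein_motif) - set(AMINO_ACIDS):
            raise SyntheticConfigError("protein_motif must be over the 20 amino acids")
        if not 0.0 <= self.label_noise < 1.0:
            raise SyntheticConfigError("label_noise must be in [0, 1)")
        if not 0.0 < self.plant_fraction <= 1.0:
            raise SyntheticConfigError("plant_fraction must be in (0, 1]")
        if min(self.n_rna, self.n_protein, self.n_positive) < 1:
            raise SyntheticConfigError("counts must be positive")


def _simulate_entities(rng: np.random.Generator, prefix: str, molecule: str,
                       n: int, length_range: tuple[int, int], alphabet: str,
                       motif: str, plant_fraction: float) -> list[SequenceRecord]:
    width = len(str(n))
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = rng.choice(list(alphabet), size=length)
        if rng.random() < plant_fraction:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos:pos + len(motif)] = list(motif)
        records.append(SequenceRecord(f"{prefix}{i + 1:0{width}d}", molecule,
                                      "".join(seq)))
    return records


def simulate_dataset(config: SyntheticConfig = SyntheticConfig()) -> RPIDataset:
    """Generate a balanced dataset labeled by the planted motif conjunction.

    Emits exactly ``n_positive`` positive and ``n_positive`` negative pairs,
    sampled without replacement from the n_rna x n_protein grid; raises when
    the grid cannot supply enough pairs of either class.  Byte-identical
    output under the same config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    rnas = _simulate_entities(rng, "R", RNA, config.n_rna, config.rna_length_range,
                              NUCLEOTIDES, config.rna_motif, config.plant_fraction)
    prots = _simulate_entities(rng, "P", PROTEIN, config.n_protein,
                               config.protein_length_range, AMINO_ACIDS,
                               config.protein_motif, config.plant_fraction)
    rna_has = {r.id: config.rna_motif in r.sequence for r in rnas}
    prot_has = {p.id: config.protein_motif in p.sequence for p in prots}

    grid = [(r.id, p.id) for r in rnas for p in prots]
    rng.shuffle(grid)
    pos, neg = [], []
    for rid, pid in grid:
        label = int(rna_has[rid] and prot_has[pid])
        if label and len(pos) < config.n_positive:
            pos.append((rid, pid, label))
        elif not label and len(neg) < config.n_positive:
            neg.append((rid, pid, label))
        if len(pos) == config.n_positive and len(neg) == config.n_positive:
            break
    else:
        raise SyntheticConfigError(
            f"grid of {len(grid)} pairs yielded only {len(pos)} positives / "
            f"{len(neg)} negatives of {config.n_positive} requested; "
            "increase n_rna/n_protein or plant_fraction"
        )
    pairs = []
    for rid, pid, label in pos + neg:
        if config.label_noise and rng.random() < config.label_noise:
            label = 1 - label
        pairs.append(InteractionPair(rid, pid, label))
    return RPIDataset({r.id: r for r in rnas}, {p.id: p for p in prots}, pairs)


# ---------------------------------------------------------------------------
# Synthetic secondary structure
# ---------------------------------------------------------------------------

#: success probability of the geometric run-length law for protein structure
PROTEIN_RUN_P = 0.2


def _protein_structure(rng: np.random.Generator, length: int) -> str:
    """H/E/C string as i.i.d. states with geometric(PROTEIN_RUN_P) run lengths."""
    out = []
    states = "HEC"
    prev = None
    while len(out) < length:
        choices = [s for s in states if s != prev]
        state = choices[rng.integers(len(choices))]
        run = int(rng.geometric(PROTEIN_RUN_P))
        out.extend(state * run)
        prev = state
    return "".join(out[:length])


def _rna_structure(rng: np.random.Generator, length: int) -> str:
    """Balanced dot-bracket string: every '(' is closed by a later ')'."""
    out = []
    depth = 0
    for i in range(length):
        remaining = length - i
        if depth == remaining:  # must close everything
            out.append(")")
            depth -= 1
            continue
        r = rng.random()
        if depth > 0 and r < 0.3:
            out.append(")")
            depth -= 1
        elif r < 0.6 and depth + 1 < remaining:
            out.append("(")
            depth += 1
        else:
            out.append(".")
    return "".join(out)


def simulate_structures(records: Sequence[SequenceRecord],
                        seed: int = 0) -> list[SequenceRecord]:
    """Attach synthetic structure strings matching each record's length."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        if rec.molecule == PROTEIN:
            struct = _protein_structure(rng, len(rec.sequence))
        else:
            struct = _rna_structure(rng, len(rec.sequence))
        out.append(replace(rec, structure=struct))
    return out


def simulate_dataset_with_structures(config: SyntheticConfig = SyntheticConfig()) -> RPIDataset:
    """Convenience wrapper: planted-rule dataset plus synthetic structures."""
    ds = simulate_dataset(config)
    rnas = simulate_structures(list(ds.rnas.values()), seed=config.seed + 1)
    prots = simulate_structures(list(ds.proteins.values()), seed=config.seed + 2)
    return RPIDataset({r.id: r for r in rnas}, {p.id: p for p in prots}, ds.pairs)


def write_dataset(dataset: RPIDataset, outdir) -> None:
    """Write FASTA x2, structure files x2 (when present) and the pair TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "rna.fasta", dataset.rnas.values())
    write_fasta(outdir / "protein.fasta", dataset.proteins.values())
    if any(r.structure for r in dataset.rnas.values()):
        write_structures(outdir / "rna_struct.fasta", dataset.rnas.values())
    if any(p.structure for p in dataset.proteins.values()):
        write_structures(outdir / "protein_struct.fasta", dataset.proteins.values())
    write_pairs(outdir / "pairs.tsv", dataset.pairs)
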