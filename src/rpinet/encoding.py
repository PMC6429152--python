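"""Conjoint-triad-family k-mer frequency encoders for RNA and protein sequences.

A variable-length RNA or protein sequence (optionally paired with a
secondary-structure string) is turned into a fixed-length vector of k-mer
relative frequencies.  Proteins are first rewritten in a reduced seven-letter
alphabet that groups the 20 standard amino acids by dipole moment and
side-chain volume; RNA uses the four ribonucleotides; structure strings use a
three-state (helix/sheet/coil) or two-state (paired/unpaired) alphabet.

Three schemes are supported, per molecule:

========  =======================  ===========================  =========
scheme    RNA blocks               protein blocks               dims
========  =======================  ===========================  =========
ctf       4-mers                   3-mers                       256 / 343
ictf      1..4-mers                1..3-mers                    340 / 399
isctf     ictf + structure 1..4    ictf + structure 1..3        370 / 438
========  =======================  ===========================  =========

Within each k-block the entries are counts of that k-mer divided by the total
number of valid k-mers of that length, so every block sums to one (or is
identically zero when the sequence is shorter than k or every window touches
an ambiguous residue).  Blocks are concatenated in ascending k, sequence
blocks first, structure blocks after.  Entry order inside a block is the
lexicographic order of k-mers under the declared alphabet order
(A,C,G,U for RNA; group 1..7 for protein; H,E,C and unpaired,paired for
structure alphabets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RNA = "rna"
PROTEIN = "protein"

#: marker for residues that cannot be mapped; k-mers covering it are skipped
UNKNOWN = "?"

#: the seven amino-acid groups, in order; group i is written as digit i+1
PROTEIN_GROUPS = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

PROTEIN_GROUP_ALPHABET = "1234567"
RNA_ALPHABET = "ACGU"
#: two-state RNA structure alphabet: U(npaired) before P(aired)
RNA_STRUCT_ALPHABET = "UP"
#: three-state protein secondary structure: helix, sheet, coil
PROTEIN_STRUCT_ALPHABET = "HEC"

_AA_TO_GROUP = {aa: str(i + 1) for i, grp in enumerate(PROTEIN_GROUPS) for aa in grp}
_RNA_MAP = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U"}


class EncodingError(ValueError):
    """Invalid sequence, structure or scheme input."""


@dataclass(frozen=True)
class EncodingScheme:
    """One (molecule, scheme) encoder configuration.

    ``k_seq`` / ``k_struct`` are inclusive ``(lo, hi)`` k ranges over the
    sequence and structure alphabets; ``k_struct`` is ``None`` for the
    sequence-only schemes.
    """

    name: str
    molecule: str
    seq_alphabet: str
    k_seq: tuple[int, int]
    struct_alphabet: str | None = None
    k_struct: tuple[int, int] | None = None

    @property
    def uses_structure(self) -> bool:
        return self.k_struct is not None

    @property
    def dimension(self) -> int:
        dim = sum(
            len(self.seq_alphabet) ** k
            for k in range(self.k_seq[0], self.k_seq[1] + 1)
        )
        if self.uses_structure:
            assert self.struct_alphabet is not None
            dim += sum(
                len(self.struct_alphabet) ** k
                for k in range(self.k_struct[0], self.k_struct[1] + 1)
            )
        return dim


CTF = "ctf"
IMPROVED_CTF = "ictf"
IMPROVED_STRUCT_CTF = "isctf"

SCHEME_NAMES = (CTF, IMPROVED_CTF, IMPROVED_STRUCT_CTF)

_SCHEMES: dict[tuple[str, str], EncodingScheme] = {}
for _mol, _alpha, _kmax, _salpha in (
    (RNA, RNA_ALPHABET, 4, RNA_STRUCT_ALPHABET),
    (PROTEIN, PROTEIN_GROUP_ALPHABET, 3, PROTEIN_STRUCT_ALPHABET),
):
    _SCHEMES[(CTF, _mol)] = EncodingScheme(CTF, _mol, _alpha, (_kmax, _kmax))
    _SCHEMES[(IMPROVED_CTF, _mol)] = EncodingScheme(IMPROVED_CTF, _mol, _alpha, (1, _kmax))
    _SCHEMES[(IMPROVED_STRUCT_CTF, _mol)] = EncodingScheme(
        IMPROVED_STRUCT_CTF, _mol, _alpha, (1, _kmax), _salpha, (1, _kmax)
    )


def get_scheme(name: str, molecule: str) -> EncodingScheme:
    """Look up the encoder for ``name`` in {ctf, ictf, isctf} and molecule."""
    try:
        return _SCHEMES[(name.lower(), molecule.lower())]
    except KeyError:
        raise EncodingError(f"unknown scheme/molecule: {name!r}/{molecule!r}") from None


def reduce_protein(sequence: str) -> str:
    """Rewrite an amino-acid sequence in the reduced seven-group alphabet.

    Non-standard residues (B, J, O, U, X, Z, ``*`` ...) become the unknown
    marker, which k-mer counting skips.  Case-insensitive.
    """
    if not sequence:
        raise EncodingError("empty protein sequence")
    return "".join(_AA_TO_GROUP.get(c, UNKNOWN) for c in sequence.upper())


def normalize_rna(sequence: str) -> str:
    """Canonicalize an RNA sequence to {A,C,G,U}; T becomes U, others unknown."""
    if not sequence:
        raise EncodingError("empty RNA sequence")
    return "".join(_RNA_MAP.get(c, UNKNOWN) for c in sequence.upper())


def rna_structure_two_state(dot_bracket: str) -> str:
    """Collapse a dot-bracket string to the two-state paired/unpaired alphabet.

    ``.`` maps to U (unpaired); ``(`` and ``)`` both map to P (paired).
    Pseudoknot or other characters are rejected.
    """
    if not dot_bracket:
        raise EncodingError("empty structure string")
    bad = set(dot_bracket) - set(".()")
    if bad:
        raise EncodingError(f"invalid dot-bracket characters: {sorted(bad)}")
    return dot_bracket.replace(".", "U").replace("(", "P").replace(")", "P")


def protein_structure_three_state(structure: str) -> str:
    """Validate/uppercase a three-state (H/E/C) protein structure string."""
    if not structure:
        raise EncodingError("empty structure string")
    out = structure.upper()
    bad = set(out) - set(PROTEIN_STRUCT_ALPHABET)
    if bad:
        raise EncodingError(f"invalid protein structure characters: {sorted(bad)}")
    return out


def kmer_frequency_block(symbols: str, k: int, alphabet: str) -> np.ndarray:
    """Relative k-mer frequencies of ``symbols`` over ``alphabet``.

    Returns a ``len(alphabet)**k`` vector in lexicographic k-mer order under
    the alphabet's declared symbol order.  Windows covering the unknown
    marker are skipped; each entry is count / (number of valid windows).
    All-zero when no valid window exists.
    """
    if k < 1:
        raise EncodingError(f"k must be >= 1, got {k}")
    n_sym = len(alphabet)
    lut = {c: i for i, c in enumerate(alphabet)}
    codes = np.fromiter((lut.get(c, -1) for c in symbols), dtype=np.int64,
                        count=len(symbols))
    out = np.zeros(n_sym ** k)
    if len(codes) < k:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return out
    powers = n_sym ** np.arange(k - 1, -1, -1)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=n_sym ** k)
    return counts / counts.sum()


def _prepare(record, scheme: EncodingScheme) -> tuple[str, str | None]:
    """Map a record's sequence/structure to the scheme's alphabets."""
    if record.molecule != scheme.molecule:
        raise EncodingError(
            f"record {record.id!r} is {record.molecule}, scheme expects {scheme.molecule}"
        )
    if scheme.molecule == PROTEIN:
        seq = reduce_protein(record.sequence)
    else:
        seq = normalize_rna(record.sequence)
    struct = None
    if scheme.uses_structure:
        if record.structure is None:
            raise EncodingError(f"record {record.id!r} lacks the structure string "
                                f"required by scheme {scheme.name!r}")
        if len(record.structure) != len(record.sequence):
            raise EncodingError(
                f"record {record.id!r}: structure length {len(record.structure)} "
                f"!= sequence length {len(record.sequence)}"
            )
        if scheme.molecule == RNA:
            struct = rna_structure_two_state(record.structure)
        else:
            struct = protein_structure_three_state(record.structure)
    return seq, struct


def encode(record, scheme: EncodingScheme) -> np.ndarray:
    """Encode one sequence record into the scheme's fixed-length vector.

    Blocks are concatenated in ascending k, sequence alphabet first, then
    (for the structure-augmented scheme) structure alphabet.
    """
    seq, struct = _prepare(record, scheme)
    blocks = [
        kmer_frequency_block(seq, k, scheme.seq_alphabet)
        for k in range(scheme.k_seq[0], scheme.k_seq[1] + 1)
    ]
    if scheme.uses_structure:
        assert struct is not None and scheme.struct_alphabet is not None
        blocks += [
            kmer_frequency_block(struct, k, scheme.struct_alphabet)
            for k in range(scheme.k_struct[0], scheme.k_struct[1] + 1)
        ]
    vec = np.concatenate(blocks)
    assert vec.shape == (scheme.dimension,)
    return vec


def encode_records(records: Iterable, scheme: EncodingScheme) -> tuple[list[str], np.ndarray]:
    """Encode many records; returns (ids, matrix of shape (n, dimension))."""
    ids, rows = [], []
    for rec in records:
        ids.append(rec.id)
        rows.append(encode(rec, scheme))
    if not ids:
        raise EncodingError("no records to encode")
    return ids, np.vstack(rows)


def write_feature_tsv(path, ids: Sequence[str], matrix: np.ndarray,
                      scheme: EncodingScheme) -> None:
    """Write a feature matrix as TSV, one row per ID.

    The header names columns f0..f{d-1}; the index column is named
    ``<scheme>:<molecule>:<dimension>`` so the file is self-describing.
    """
    df = pd.DataFrame(matrix, index=pd.Index(ids, name=f"{scheme.name}:{scheme.molecule}:{scheme.dimension}"),
                      columns=[f"f{i}" for i in range(matrix.shape[1])])
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
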