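"""Alphabets, one-hot sequence encoding, FASTA/label I/O and the
position-to-unit-circle mapping shared by the kernel modules.

Positions are 1-based everywhere in the public API; conversion to 0-based
array indices happens only at the point of array access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO


class SequenceError(ValueError):
    """Raised for malformed sequence input (unknown residue, bad FASTA...)."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with ambiguity-code support.

    Parameters
    ----------
    symbols:
        Ordered tuple of unambiguous residue characters (upper case).
    kind:
        ``"dna"`` or ``"protein"``.
    ambiguity_map:
        Maps ambiguity codes to the non-empty subset of ``symbols`` they
        stand for.  Codes are resolved case-insensitively.
    """

    symbols: tuple[str, ...]
    kind: str
    ambiguity_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        expected = {"dna": 4, "protein": 20}
        if self.kind not in expected:
            raise ValueError(f"kind must be 'dna' or 'protein', got {self.kind!r}")
        if len(self.symbols) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} alphabet needs {expected[self.kind]} symbols, got {len(self.symbols)}"
            )
        for code, subset in self.ambiguity_map.items():
            if not subset:
                raise ValueError(f"ambiguity code {code!r} maps to an empty subset")
            unknown = set(subset) - set(self.symbols)
            if unknown:
                raise ValueError(f"ambiguity code {code!r} maps to unknown symbols {unknown}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def column(self, residue: str) -> np.ndarray:
        """Unit-l2-norm encoding column for a single residue.

        Unambiguous residues give one-hot columns; ambiguity codes give a
        uniform distribution over their subset rescaled to unit l2 norm.
        """
        r = residue.upper()
        if self.kind == "dna" and r == "U":
            r = "T"
        col = np.zeros(self.size)
        if r in self.symbols:
            col[self.index(r)] = 1.0
            return col
        subset = self.ambiguity_map.get(r)
        if subset is None:
            raise SequenceError(f"unknown residue {residue!r} for {self.kind} alphabet")
        for s in subset:
            col[self.index(s)] = 1.0
        return col / np.linalg.norm(col)


DNA = Alphabet(
    symbols=("A", "C", "G", "T"),
    kind="dna",
    ambiguity_map={
        "R": ("A", "G"),
        "Y": ("C", "T"),
        "S": ("C", "G"),
        "W": ("A", "T"),
        "K": ("G", "T"),
        "M": ("A", "C"),
        "B": ("C", "G", "T"),
        "D": ("A", "G", "T"),
        "H": ("A", "C", "T"),
        "V": ("A", "C", "G"),
        "N": ("A", "C", "G", "T"),
    },
)

_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
PROTEIN = Alphabet(
    symbols=_AA,
    kind="protein",
    ambiguity_map={
        "B": ("D", "N"),
        "Z": ("E", "Q"),
        "J": ("I", "L"),
        "X": _AA,
    },
)


def get_alphabet(name: str) -> Alphabet:
    try:
        return {"dna": DNA, "protein": PROTEIN}[name.lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}; use 'dna' or 'protein'") from None


@dataclass
class EncodedSequence:
    """A sequence as a ``|A| x L`` matrix of unit-l2-norm columns."""

    id: str
    matrix: np.ndarray
    alphabet: Alphabet
    label: int | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.length

    def validate(self) -> None:
        if self.matrix.shape[0] != self.alphabet.size:
            raise SequenceError("matrix row count does not match alphabet size")
        norms = np.linalg.norm(self.matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise SequenceError("encoded columns must have unit l2 norm")


@dataclass(frozen=True)
class CirclePosition:
    """A sequence position mapped onto the upper half of the unit circle."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if v.shape != (2,):
            raise ValueError("circle position must be a 2-vector")
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError("circle position must have unit l2 norm")
        if v[1] < -1e-12:
            raise ValueError("circle position must lie on the upper half circle")

    def dot(self, other: "CirclePosition") -> float:
        return float(self.vector @ other.vector)


def map_position(p: int, length: int) -> CirclePosition:
    """Map 1-based position ``p`` of a length-``length`` sequence onto the
    upper half of the unit circle: ``(cos(p*pi/L), sin(p*pi/L))``.
    """
    if length < 1:
        raise ValueError(f"sequence length must be >= 1, got {length}")
    if not 1 <= p <= length:
        raise ValueError(f"position {p} out of range 1..{length}")
    angle = p * np.pi / length
    return CirclePosition(np.array([np.cos(angle), np.sin(angle)]))


def circle_positions(length: int, count: int | None = None) -> np.ndarray:
    """Vectorized ``map_position`` for positions ``1..count`` (default: all
    of ``1..length``); returns a ``count x 2`` array."""
    if count is None:
        count = length
    angles = np.arange(1, count + 1) * np.pi / length
    return np.column_stack([np.cos(angles), np.sin(angles)])


def encode_sequence(seq: str, alphabet: Alphabet, id: str = "", label: int | None = None) -> EncodedSequence:
    """One-hot encode a residue string (ambiguity codes become uniform
    unit-l2-norm columns over their subset)."""
    cols = np.empty((alphabet.size, len(seq)))
    for i, ch in enumerate(seq):
        try:
            cols[:, i] = alphabet.column(ch)
        except SequenceError:
            raise SequenceError(
                f"unknown character {ch!r} at position {i + 1}"
                + (f" in sequence {id!r}" if id else "")
            ) from None
    return EncodedSequence(id=id, matrix=cols, alphabet=alphabet, label=label)


def decode_sequence(enc: EncodedSequence) -> str:
    """Inverse of :func:`encode_sequence` for unambiguous sequences."""
    out = []
    for j in range(enc.length):
        col = enc.matrix[:, j]
        idx = int(np.argmax(col))
        if not np.isclose(col[idx], 1.0, atol=1e-9):
            raise SequenceError(f"column {j + 1} is not one-hot; cannot decode unambiguously")
        out.append(enc.alphabet.symbols[idx])
    return "".join(out)


def _parse_label(token: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise SequenceError(f"label {token!r} is not an integer") from None


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table (no header)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SequenceError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sid, token = parts[0].strip(), parts[1].strip()
        if sid in labels:
            raise SequenceError(f"{path}:{lineno}: duplicate id {sid!r}")
        labels[sid] = _parse_label(token)
    return labels


def read_fasta(
    path: str | Path,
    alphabet: Alphabet,
    label_source: str | Path | None = None,
) -> list[EncodedSequence]:
    """Read a multi-record FASTA into encoded sequences with labels.

    ``label_source`` may be a sidecar TSV path (``id<TAB>label``).  When it
    is ``None``, a ``|label`` suffix on the record id is accepted as a
    fallback; records without either resolve to ``label=None``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: empty FASTA input")
    sidecar = read_labels_tsv(label_source) if label_source is not None else None

    out: list[EncodedSequence] = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id
        label: int | None = None
        if sidecar is None and "|" in rid:
            rid, _, token = rid.rpartition("|")
            label = _parse_label(token)
        if rid in seen:
            raise SequenceError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        if sidecar is not None:
            if rid not in sidecar:
                raise SequenceError(f"{path}: no label for sequence id {rid!r} in {label_source}")
            label = sidecar[rid]
        out.append(encode_sequence(str(rec.seq), alphabet, id=rid, label=label))
    return out


def write_fasta(
    path: str | Path,
    sequences: Sequence[str],
    ids: Sequence[str],
    labels_path: str | Path | None = None,
    labels: Sequence[int] | None = None,
) -> None:
    """Write plain sequences as unwrapped FASTA, optionally with a label TSV."""
    with open(path, "w") as fh:
        for sid, seq in zip(ids, sequences):
            fh.write(f">{sid}\n{seq}\n")
    if labels_path is not None:
        if labels is None:
            raise ValueError("labels required when labels_path is given")
        with open(labels_path, "w") as fh:
            for sid, lab in zip(ids, labels):
                fh.write(f"{sid}\t{lab}\n")
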