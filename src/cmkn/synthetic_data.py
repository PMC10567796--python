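"""Synthetic two-class DNA benchmark: uniform random background sequences
with class-specific degenerate motifs planted at class-specific positions
under bounded positional jitter.

The shipped default emulates the published setup: 1000 length-100
sequences, equally split; a 5-mer planted at position 20 +/- 5 in the
negative class and at position 80 +/- 5 in the positive class.  One motif
column is degenerate ({G: 2/3, T: 1/3} at motif position 2 of the
negative motif; the positive motif carries an analogous degenerate
column); the remaining columns are deterministic stand-ins, since the
full published motif matrices are not recoverable from text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cmkn.pam_kernel import NPFM
from cmkn.seq_io import DNA, Alphabet


@dataclass(frozen=True)
class PlantSpec:
    """A class-specific motif to plant.

    consensus_columns: per motif position, a residue -> probability map.
    center: 1-based planting position (window start) in the sequence.
    jitter: maximum absolute positional offset (discrete uniform over
        ``center - jitter .. center + jitter``).
    """

    consensus_columns: tuple[dict[str, float], ...]
    center: int
    jitter: int
    class_index: int
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if not self.consensus_columns:
            raise ValueError("motif must have at least one column")
        for i, col in enumerate(self.consensus_columns):
            if not col:
                raise ValueError(f"column {i + 1} is empty")
            if abs(sum(col.values()) - 1.0) > 1e-9:
                raise ValueError(f"column {i + 1} probabilities must sum to 1")
            if any(p < 0 for p in col.values()):
                raise ValueError(f"column {i + 1} has negative probabilities")
            unknown = set(col) - set(self.alphabet.symbols)
            if unknown:
                raise ValueError(f"column {i + 1} uses unknown residues {unknown}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.center - self.jitter < 1:
            raise ValueError("planting window extends past the sequence start")

    @property
    def length(self) -> int:
        return len(self.consensus_columns)

    @property
    def consensus(self) -> str:
        """Per-column most probable residue (ties: alphabet order)."""
        out = []
        for col in self.consensus_columns:
            best = max(self.alphabet.symbols, key=lambda s: col.get(s, 0.0))
            out.append(best)
        return "".join(out)

    def non_degenerate_columns(self) -> list[int]:
        """0-based indices of columns with a single probability-1 residue."""
        return [
            i
            for i, col in enumerate(self.consensus_columns)
            if any(abs(p - 1.0) < 1e-12 for p in col.values())
        ]

    def check_fits(self, length: int) -> None:
        if self.center + self.jitter + self.length - 1 > length:
            raise ValueError(
                f"planting window (center {self.center}, jitter {self.jitter}, "
                f"motif length {self.length}) overflows sequence length {length}"
            )


def default_plant_specs() -> list[PlantSpec]:
    """The shipped two-class default (see module docstring)."""
    negative = PlantSpec(
        consensus_columns=(
            {"G": 1.0},
            {"G": 2 / 3, "T": 1 / 3},
            {"G": 1.0},
            {"A": 1.0},
            {"T": 1.0},
        ),
        center=20,
        jitter=5,
        class_index=0,
    )
    positive = PlantSpec(
        consensus_columns=(
            {"T": 1.0},
            {"T": 1.0},
            {"C": 2 / 3, "A": 1 / 3},
            {"G": 1.0},
            {"G": 1.0},
        ),
        center=80,
        jitter=5,
        class_index=1,
    )
    return [negative, positive]


def spec_to_npfm(spec: PlantSpec) -> NPFM:
    """Ground-truth motif of a spec as an nPFM (probability columns
    rescaled to unit l2 norm)."""
    a = spec.alphabet.size
    mat = np.zeros((a, spec.length))
    for j, col in enumerate(spec.consensus_columns):
        for residue, p in col.items():
            mat[spec.alphabet.index(residue), j] = p
    mat /= np.linalg.norm(mat, axis=0, keepdims=True)
    return NPFM(mat)


def generate_dataset(
    n_seqs: int = 1000,
    length: int = 100,
    specs: list[PlantSpec] | None = None,
    seed: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Generate the synthetic dataset.

    Background residues are i.i.d. uniform over the DNA alphabet; every
    sequence carries exactly one motif instance sampled columnwise from
    its class spec and planted at ``center + U{-jitter..jitter}``,
    overwriting the background.  Classes are exactly balanced; sequences
    are emitted class-by-class in class-index order.

    Returns (sequences as strings, integer label array).
    """
    specs = default_plant_specs() if specs is None else specs
    classes = sorted({s.class_index for s in specs})
    if [s.class_index for s in sorted(specs, key=lambda s: s.class_index)] != classes:
        raise ValueError("exactly one PlantSpec per class is required")
    if classes != list(range(len(classes))):
        raise ValueError("class indices must be 0..n_classes-1")
    n_classes = len(classes)
    if n_seqs % n_classes != 0:
        raise ValueError(f"n_seqs={n_seqs} must be divisible by the class count {n_classes}")
    for s in specs:
        s.check_fits(length)

    rng = np.random.default_rng(seed)
    symbols = np.array(list(specs[0].alphabet.symbols))
    seqs: list[str] = []
    labels: list[int] = []
    per_class = n_seqs // n_classes
    for spec in sorted(specs, key=lambda s: s.class_index):
        probs = [
            np.array([col.get(s, 0.0) for s in symbols]) for col in spec.consensus_columns
        ]
        for _ in range(per_class):
            chars = rng.choice(symbols, size=length)
            start = spec.center + int(rng.integers(-spec.jitter, spec.jitter + 1))
            for j, p in enumerate(probs):
                chars[start - 1 + j] = rng.choice(symbols, p=p)
            seqs.append("".join(chars))
            labels.append(spec.class_index)
    return seqs, np.array(labels, dtype=int)
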