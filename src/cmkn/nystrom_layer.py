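"""Nystrom projection layer: anchor management and the finite-dimensional
subspace projection that forms the network's first layer.

Anchors are motif-position pairs.  The implicit RKHS images of the anchors
are never materialized; the projection of a window ``w`` is
``psi(w) = K_ZZ^{-1/2} (K0(z_1, w), ..., K0(z_n, w))^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from cmkn.pam_kernel import NPFM, PAMParams, sequence_windows
from cmkn.seq_io import Alphabet, CirclePosition, EncodedSequence, circle_positions, get_alphabet


class StaleStateError(RuntimeError):
    """Anchors changed after the Nystrom state was computed."""


@dataclass
class AnchorSet:
    """``n`` motif-position anchor pairs spanning the kernel subspace.

    motifs: ``n x |A| x k`` array; each slice is a valid nPFM after every
        constraint projection.
    positions: ``n x 2`` array of unit vectors on the upper half circle.
    """

    motifs: np.ndarray
    positions: np.ndarray
    trainable: bool = True

    def __post_init__(self) -> None:
        self.motifs = np.asarray(self.motifs, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.motifs.ndim != 3:
            raise ValueError("motifs must be an n x |A| x k array")
        if self.positions.shape != (self.motifs.shape[0], 2):
            raise ValueError("positions must be an n x 2 array")

    @property
    def n(self) -> int:
        return self.motifs.shape[0]

    @property
    def alphabet_size(self) -> int:
        return self.motifs.shape[1]

    @property
    def k(self) -> int:
        return self.motifs.shape[2]

    @property
    def motifs_flat(self) -> np.ndarray:
        """``n x (|A| k)`` column-concatenated motif matrix."""
        n, a, k = self.motifs.shape
        return self.motifs.transpose(0, 2, 1).reshape(n, a * k)

    def motif(self, i: int) -> NPFM:
        return NPFM(self.motifs[i])

    def position(self, i: int) -> CirclePosition:
        return CirclePosition(self.positions[i])

    def validate(self) -> None:
        for i in range(self.n):
            self.motif(i)
            self.position(i)

    def copy(self) -> "AnchorSet":
        return AnchorSet(self.motifs.copy(), self.positions.copy(), self.trainable)


@dataclass
class NystromState:
    """Gram matrix of the anchors under ``K0`` and its (pseudo-)inverse
    square root, with the anchor snapshot used to detect staleness."""

    K_ZZ: np.ndarray
    K_ZZ_inv_sqrt: np.ndarray
    epsilon: float
    _motifs: np.ndarray = field(repr=False, default=None)
    _positions: np.ndarray = field(repr=False, default=None)

    def check_fresh(self, anchors: AnchorSet) -> None:
        if self._motifs is None:
            return
        if not (
            np.array_equal(self._motifs, anchors.motifs)
            and np.array_equal(self._positions, anchors.positions)
        ):
            raise StaleStateError("anchors changed since the Nystrom state was computed")


def sample_pairs(
    data: list[EncodedSequence],
    m: int,
    k: int,
    seed: int | None = None,
) -> list[tuple[NPFM, CirclePosition]]:
    """Sample ``m`` motif-position pairs uniformly over all (sequence,
    valid window start) combinations of the training data."""
    if not data:
        raise ValueError("cannot sample pairs from an empty dataset")
    if m < 1:
        raise ValueError("m must be >= 1")
    counts = np.array([x.length - k + 1 for x in data])
    if np.any(counts < 1):
        raise ValueError(f"every sequence must have length >= k={k}")
    rng = np.random.default_rng(seed)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    flat = rng.integers(0, offsets[-1], size=m)
    pairs: list[tuple[NPFM, CirclePosition]] = []
    for f in flat:
        si = int(np.searchsorted(offsets, f, side="right") - 1)
        p = int(f - offsets[si]) + 1  # 1-based window start
        x = data[si]
        window = x.matrix[:, p - 1 : p - 1 + k]
        pairs.append((NPFM(window), CirclePosition(_circle_vec(p, x.length))))
    return pairs


def _circle_vec(p: int, length: int) -> np.ndarray:
    angle = p * np.pi / length
    return np.array([np.cos(angle), np.sin(angle)])


def project_motif_array(motifs: np.ndarray) -> np.ndarray:
    """Clamp motif entries to >= 0 columnwise, rescale every column to unit
    l2 norm; all-zero columns fall back to the uniform unit-norm column."""
    m = np.clip(motifs, 0.0, None)
    norms = np.linalg.norm(m, axis=-2, keepdims=True)
    zero = norms[..., 0, :] < 1e-300
    a = m.shape[-2]
    out = np.divide(m, norms, out=np.zeros_like(m), where=norms > 0)
    out[..., :, :] = np.where(zero[..., None, :], 1.0 / np.sqrt(a), out)
    return out


def project_position_array(positions: np.ndarray) -> np.ndarray:
    """Clamp the second coordinate to >= 0, then rescale rows to unit norm;
    degenerate zero rows fall back to the top of the circle (0, 1)."""
    p = positions.copy()
    p[..., 1] = np.clip(p[..., 1], 0.0, None)
    norms = np.linalg.norm(p, axis=-1, keepdims=True)
    zero = norms[..., 0] < 1e-300
    out = np.divide(p, norms, out=np.zeros_like(p), where=norms > 0)
    out[zero] = np.array([0.0, 1.0])
    return out


def constraint_project(anchors: AnchorSet) -> AnchorSet:
    """Enforce the nPFM and circle constraints on every anchor (total,
    idempotent function; returns a new AnchorSet)."""
    return AnchorSet(
        motifs=project_motif_array(anchors.motifs),
        positions=project_position_array(anchors.positions),
        trainable=anchors.trainable,
    )


def init_anchors(
    pairs: list[tuple[NPFM, CirclePosition]],
    n: int,
    seed: int | None = None,
) -> AnchorSet:
    """k-means++ clustering of the concatenated (flat motif, position)
    vectors; cluster centers are projected back to valid anchors."""
    if n > len(pairs):
        raise ValueError(f"need at least n={n} pairs, got {len(pairs)}")
    a, k = pairs[0][0].alphabet_size, pairs[0][0].k
    X = np.array([np.concatenate([w.flat, p.vector]) for w, p in pairs])
    km = KMeans(
        n_clusters=n,
        init="k-means++",
        n_init=1,
        max_iter=100,
        tol=1e-4,
        random_state=seed,
    ).fit(X)
    centers = km.cluster_centers_
    motifs = centers[:, : a * k].reshape(n, k, a).transpose(0, 2, 1)
    positions = centers[:, a * k :]
    return constraint_project(AnchorSet(motifs=motifs, positions=positions))


def anchor_gram(anchors: AnchorSet, params: PAMParams) -> np.ndarray:
    """``n x n`` Gram matrix of K0 over the anchors (unit diagonal)."""
    m = anchors.motifs_flat
    dots = m @ m.T
    cosines = anchors.positions @ anchors.positions.T
    return np.exp(params.alpha * (dots - params.k) + params.position_scale * (cosines - 1.0))


def gram_inverse_sqrt(
    anchors: AnchorSet,
    params: PAMParams,
    epsilon: float = 1e-6,
) -> NystromState:
    """Symmetric eigendecomposition of K_ZZ with eigenvalues floored at
    ``epsilon``; assembles the (pseudo-)inverse square root."""
    kzz = anchor_gram(anchors, params)
    if not np.all(np.isfinite(kzz)):
        raise FloatingPointError("non-finite entries in the anchor Gram matrix")
    eigval, eigvec = np.linalg.eigh(kzz)
    inv_sqrt = (eigvec * (1.0 / np.sqrt(np.maximum(eigval, epsilon)))) @ eigvec.T
    return NystromState(
        K_ZZ=kzz,
        K_ZZ_inv_sqrt=inv_sqrt,
        epsilon=epsilon,
        _motifs=anchors.motifs.copy(),
        _positions=anchors.positions.copy(),
    )


def kernel_responses(
    windows_flat: np.ndarray,
    window_positions: np.ndarray,
    anchors: AnchorSet,
    params: PAMParams,
) -> np.ndarray:
    """K0 between every (window, anchor) pair.

    windows_flat: ``... x (|A| k)`` flattened one-hot windows.
    window_positions: ``... x 2`` circle positions of the window starts
    (leading shape must match windows_flat).
    Returns ``... x n``.
    """
    dots = windows_flat @ anchors.motifs_flat.T
    cosines = window_positions @ anchors.positions.T
    return np.exp(params.alpha * (dots - params.k) + params.position_scale * (cosines - 1.0))


def project_window(
    w: tuple[NPFM, CirclePosition],
    state: NystromState,
    anchors: AnchorSet,
    params: PAMParams,
) -> np.ndarray:
    """Project one motif-position pair onto the anchor subspace."""
    state.check_fresh(anchors)
    motif, pos = w
    kz = kernel_responses(motif.flat[None, :], pos.vector[None, :], anchors, params)[0]
    return state.K_ZZ_inv_sqrt @ kz


def forward_sequence(
    x: EncodedSequence,
    state: NystromState,
    anchors: AnchorSet,
    params: PAMParams,
) -> np.ndarray:
    """Kernel-layer feature map of a sequence: ``(L - k + 1) x n``; row p
    is the projection of the window starting at 1-based position p."""
    state.check_fresh(anchors)
    win = sequence_windows(x, params.k)
    pos = circle_positions(x.length, count=win.shape[0])
    k0 = kernel_responses(win, pos, anchors, params)
    return k0 @ state.K_ZZ_inv_sqrt


# -- anchor archive (tab-separated text) ------------------------------------

def save_anchors_tsv(path: str | Path, anchors: AnchorSet, params: PAMParams, alphabet: Alphabet) -> None:
    """Write anchors as a TSV archive: metadata header then one block per
    anchor (|A| x k matrix rows followed by the position angle)."""
    with open(path, "w") as fh:
        fh.write(
            f"#alphabet={alphabet.kind}\t k={params.k}\talpha={params.alpha!r}"
            f"\tbeta={params.beta!r}\tsigma={params.sigma!r}\tn={anchors.n}\n"
        )
        for i in range(anchors.n):
            fh.write(f">anchor{i}\n")
            for row in anchors.motifs[i]:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
            angle = float(np.arctan2(anchors.positions[i, 1], anchors.positions[i, 0]))
            fh.write(f"angle\t{angle!r}\n")


def load_anchors_tsv(path: str | Path) -> tuple[AnchorSet, PAMParams, Alphabet]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing anchor archive metadata header")
    meta = dict(tok.strip().split("=", 1) for tok in lines[0][1:].split("\t"))
    alphabet = get_alphabet(meta["alphabet"])
    params = PAMParams(
        alpha=float(meta["alpha"]),
        beta=float(meta["beta"]),
        sigma=float(meta["sigma"]),
        k=int(meta["k"]),
    )
    motifs, positions = [], []
    i = 1
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected anchor block at line {i + 1}")
        block = [
            [float(v) for v in lines[i + 1 + r].split("\t")] for r in range(alphabet.size)
        ]
        tag, angle = lines[i + 1 + alphabet.size].split("\t")
        if tag != "angle":
            raise ValueError(f"{path}: malformed anchor block near line {i + 1}")
        motifs.append(block)
        a = float(angle)
        positions.append([np.cos(a), np.sin(a)])
        i += 2 + alphabet.size
    anchors = AnchorSet(motifs=np.array(motifs), positions=np.array(positions))
    return anchors, params, alphabet
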