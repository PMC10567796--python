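"""The position-aware motif kernel.

Three ingredients:

* a position comparison kernel ``exp(beta/(2 sigma^2) (p~.q~ - 1))`` on
  positions mapped to the upper unit half-circle,
* a motif comparison kernel ``exp(alpha (w.w' - k))`` on flattened
  normalized position frequency matrices (nPFMs),
* their product ``K0``, summed over all window pairs of two sequences and
  scaled by the constant ``C = sqrt(pi^2 sigma^2 / (2 alpha beta))`` to
  give the sequence-level kernel.

Windows run over left-aligned starts ``p = 1 .. L - k + 1``; the window's
circle position is that of its start.  All reference-path computation is
done in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cmkn.seq_io import CirclePosition, EncodedSequence, circle_positions


@dataclass(frozen=True)
class PAMParams:
    """Hyperparameters of the position-aware motif kernel.

    alpha: motif sharpness (> 0).
    beta: position scaling (> 0); compensates the shrunk distances of the
        circle mapping.
    sigma: positional uncertainty bandwidth (> 0).
    k: motif length (integer >= 1).
    """

    alpha: float
    beta: float
    sigma: float
    k: int

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.sigma > 0):
            raise ValueError("alpha, beta and sigma must be strictly positive")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError(f"k must be an integer >= 1, got {self.k!r}")

    @property
    def position_scale(self) -> float:
        """The exponent scale beta / (2 sigma^2)."""
        return self.beta / (2.0 * self.sigma**2)

    @property
    def C(self) -> float:
        """Normalization constant sqrt(pi^2 sigma^2 / (2 alpha beta))."""
        return float(np.sqrt(np.pi**2 * self.sigma**2 / (2.0 * self.alpha * self.beta)))


@dataclass
class NPFM:
    """A normalized position frequency matrix: non-negative ``|A| x k``
    with unit-l2-norm columns.  One-hot sequence windows are (trivially
    valid) nPFMs, so input windows and learned anchors share this type.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("nPFM must be a 2-D matrix")
        self.validate()

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def alphabet_size(self) -> int:
        return self.matrix.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Column-concatenated (Fortran-order) vector; squared norm = k."""
        return self.matrix.flatten(order="F")

    def validate(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("nPFM entries must be non-negative")
        norms = np.linalg.norm(self.matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every nPFM column must have unit l2 norm")


def k_position(p: CirclePosition, q: CirclePosition, params: PAMParams) -> float:
    """Position comparison kernel ``exp(beta/(2 sigma^2) (p~.q~ - 1))``."""
    return float(np.exp(params.position_scale * (p.dot(q) - 1.0)))


def k_npfm(w1: NPFM, w2: NPFM, params: PAMParams) -> float:
    """Motif comparison kernel ``exp(alpha (w.w' - k))`` on flattened nPFMs."""
    if w1.matrix.shape != w2.matrix.shape:
        raise ValueError(
            f"nPFM shape mismatch: {w1.matrix.shape} vs {w2.matrix.shape}"
        )
    return float(np.exp(params.alpha * (w1.flat @ w2.flat - w1.k)))


def k0(
    z1: tuple[NPFM, CirclePosition],
    z2: tuple[NPFM, CirclePosition],
    params: PAMParams,
) -> float:
    """Product kernel over motif-position pairs; ``k0(z, z) = 1``."""
    return k_npfm(z1[0], z2[0], params) * k_position(z1[1], z2[1], params)


def sequence_windows(x: EncodedSequence, k: int) -> np.ndarray:
    """All length-``k`` windows of ``x`` as flattened rows.

    Returns a ``(L - k + 1) x (|A| k)`` array; row ``p-1`` is the flattened
    (column-concatenated) one-hot window starting at 1-based position ``p``.
    """
    if x.length < k:
        raise ValueError(f"sequence length {x.length} < motif length {k}")
    a = x.matrix  # |A| x L
    n_win = x.length - k + 1
    # sliding view over the position axis -> (n_win, |A|, k), then F-flatten
    win = np.lib.stride_tricks.sliding_window_view(a, k, axis=1)  # |A| x n_win x k
    win = np.moveaxis(win, 1, 0)  # n_win x |A| x k
    return win.reshape(n_win, -1, order="F").copy()


def _k0_matrix(
    wx: np.ndarray,
    wy: np.ndarray,
    px: np.ndarray,
    py: np.ndarray,
    params: PAMParams,
) -> np.ndarray:
    """K0 over all window pairs: rows index x-windows, columns y-windows."""
    dots = wx @ wy.T
    cosines = px @ py.T
    return np.exp(params.alpha * (dots - params.k) + params.position_scale * (cosines - 1.0))


def k_pam(x: EncodedSequence, y: EncodedSequence, params: PAMParams) -> float:
    """Sequence-level position-aware motif kernel ``C * sum_pq K0``."""
    if x.alphabet.symbols != y.alphabet.symbols:
        raise ValueError("sequences must share the same alphabet")
    k = params.k
    wx, wy = sequence_windows(x, k), sequence_windows(y, k)
    px = circle_positions(x.length, count=wx.shape[0])
    py = circle_positions(y.length, count=wy.shape[0])
    return params.C * float(_k0_matrix(wx, wy, px, py, params).sum())


def gram_matrix(sequences: list[EncodedSequence], params: PAMParams) -> np.ndarray:
    """Dense symmetric Gram matrix of ``k_pam`` (testing aid for small n)."""
    n = len(sequences)
    g = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            g[i, j] = g[j, i] = k_pam(sequences[i], sequences[j], params)
    return g
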