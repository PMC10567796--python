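"""Global and local interpretation of a trained model.

Global: per-position, per-class importances obtained by a backward
recursion over positive-weight edges from the output node of the class of
interest, sliding-window peak detection on the importance profile, and
class-associated weighted mean motifs at any window position.

Local: per-input explanations that rank the class mean motifs at selected
positions by the l2-norm of their motif functions evaluated on the input.

The motif-function expression used here is a reconstruction (the product
of the motif match score with the positional smoothing kernel, evaluated
on the integer position grid); it reduces to the classical oligo function
for one-hot motifs and exact matches.  See README for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cmkn.cmkn_model import TrainedModel
from cmkn.pam_kernel import NPFM, PAMParams, sequence_windows
from cmkn.seq_io import EncodedSequence, circle_positions


@dataclass
class ImportanceProfile:
    """Window-position by class importance matrix with detected peaks."""

    iota: np.ndarray  # (n_windows, n_classes), non-negative
    peaks: list[list[tuple[int, float]]]  # per class: (1-based position, height)
    window: int = 11


@dataclass
class ClassMotif:
    """Weighted mean motif associated with a class at one window position."""

    position: int  # 1-based window start
    class_index: int
    npfm: NPFM
    contributing_weights: np.ndarray  # per contributing anchor, sums to 1
    anchor_indices: np.ndarray

    def top_residues(self, column: int, alphabet_symbols: tuple[str, ...], count: int = 2) -> list[str]:
        """Residues of one motif column ranked by descending contribution."""
        order = np.argsort(-self.npfm.matrix[:, column], kind="stable")
        return [alphabet_symbols[i] for i in order[:count]]


@dataclass
class PositionExplanation:
    position: int
    residue: str
    assigned_class: int
    tie: bool
    norms: np.ndarray  # per class, scaled to [0, 1] by the per-position max


@dataclass
class LocalExplanation:
    sequence_id: str
    entries: list[PositionExplanation] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "positions": [
                {
                    "position": e.position,
                    "residue": e.residue,
                    "assigned_class": e.assigned_class,
                    "tie": e.tie,
                    "norms": e.norms.tolist(),
                }
                for e in self.entries
            ],
        }


def importance_from_stack(stack: list[np.ndarray], class_index: int) -> np.ndarray:
    """Backward positive-path importance recursion over a stack of FC
    weight matrices (each ``next_layer x layer``, input side first).

    A pre-output neuron scores 1 if its positive-weight successors in the
    output layer are exactly the class node, 0 otherwise; an interior
    neuron scores the positive-weight weighted sum of its successors'
    scores.  Only strictly positive weights define edges; biases carry no
    importance.  Returns the scores of the first (input-side) layer.
    """
    n_out = stack[-1].shape[0]
    if not 0 <= class_index < n_out:
        raise IndexError(f"class_index {class_index} out of range 0..{n_out - 1}")
    pos = stack[-1] > 0
    # exactly one positive output edge, and it is the class node
    scores = ((pos.sum(axis=0) == 1) & pos[class_index]).astype(float)
    for w in reversed(stack[:-1]):
        scores = np.where(w > 0, w, 0.0).T @ scores
    return scores


def neuron_importance(model: TrainedModel, class_index: int) -> np.ndarray:
    """Importance of every kernel-layer output neuron for one class."""
    return importance_from_stack(model.weight_stack, class_index)


def position_importance(model: TrainedModel, class_index: int) -> np.ndarray:
    """Mean kernel-neuron importance at each window position (length
    ``L - k + 1``, non-negative)."""
    scores = neuron_importance(model, class_index)
    return scores.reshape(model.n_windows, model.anchors.n).mean(axis=1)


def detect_peaks(
    iota_column: np.ndarray,
    window: int = 11,
    top: int = 10,
) -> list[tuple[int, float]]:
    """Peak heights by sliding-window mean subtraction.

    ``height(p) = iota(p) - mean(iota over the length-``window`` interval
    centered at p, truncated at the boundaries)``.  Returns the ``top``
    largest heights as (1-based position, height), ties broken by the
    lower position index.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    iota = np.asarray(iota_column, dtype=float)
    half = window // 2
    n = iota.size
    heights = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        heights[i] = iota[i] - iota[lo:hi].mean()
    order = np.lexsort((np.arange(n), -heights))
    return [(int(i) + 1, float(heights[i])) for i in order[: min(top, n)]]


def importance_profile(
    model: TrainedModel,
    window: int = 11,
    top: int = 10,
) -> ImportanceProfile:
    """Full per-position per-class importance matrix with peaks."""
    n_classes = model.W2.shape[0]
    iota = np.column_stack([position_importance(model, c) for c in range(n_classes)])
    peaks = [detect_peaks(iota[:, c], window=window, top=top) for c in range(n_classes)]
    return ImportanceProfile(iota=iota, peaks=peaks, window=window)


def class_mean_motif(
    model: TrainedModel,
    position: int,
    class_index: int,
) -> ClassMotif | None:
    """Weighted mean of the anchor motifs at one window position, weighted
    by the anchors' positive-path importances for the class.

    Returns ``None`` when no anchor at the position carries positive
    importance (no class-associated motif).
    """
    if not 1 <= position <= model.n_windows:
        raise ValueError(f"window position {position} out of range 1..{model.n_windows}")
    scores = neuron_importance(model, class_index).reshape(model.n_windows, model.anchors.n)
    weights = scores[position - 1]
    mask = weights > 0
    if not np.any(mask):
        return None
    w = weights[mask] / weights[mask].sum()
    mean = np.einsum("i,iak->ak", w, model.anchors.motifs[mask])
    norms = np.linalg.norm(mean, axis=0, keepdims=True)
    a = mean.shape[0]
    mean = np.where(norms > 1e-300, mean / np.maximum(norms, 1e-300), 1.0 / np.sqrt(a))
    return ClassMotif(
        position=position,
        class_index=class_index,
        npfm=NPFM(mean),
        contributing_weights=w,
        anchor_indices=np.nonzero(mask)[0],
    )


def motif_function_norm(
    motif: ClassMotif | NPFM,
    x: EncodedSequence,
    params: PAMParams,
) -> float:
    """l2-norm over the integer position grid of the motif function

    ``f(t) = sum_p K_nPFM(motif, window_p(x)) * K_position(t, p)``,

    the position-smoothed profile of how well the motif matches the
    sequence at each window start.
    """
    npfm = motif.npfm if isinstance(motif, ClassMotif) else motif
    if npfm.alphabet_size != x.alphabet.size:
        raise ValueError("motif and sequence must share the same alphabet")
    k = npfm.k
    win = sequence_windows(x, k)  # (P, |A|k)
    match = np.exp(params.alpha * (win @ npfm.flat - k))  # (P,)
    pos_all = circle_positions(x.length)  # t = 1..L
    pos_win = pos_all[: win.shape[0]]  # p = 1..L-k+1
    smooth = np.exp(params.position_scale * (pos_all @ pos_win.T - 1.0))  # (L, P)
    f = smooth @ match
    return float(np.linalg.norm(f))


def explain_input(
    model: TrainedModel,
    x: EncodedSequence,
    positions: list[int],
    params: PAMParams | None = None,
) -> LocalExplanation:
    """Local explanation: for each selected window position, rank the
    per-class mean motifs by their motif-function norms on the input.

    Norms are scaled to [0, 1] per position by dividing by their maximum;
    the class with the largest norm is assigned (ties go to the lower
    class index and are flagged).
    """
    params = params or model.pam
    n_classes = model.W2.shape[0]
    entries = []
    for pos in positions:
        if not 1 <= pos <= model.n_windows:
            raise ValueError(f"window position {pos} out of range 1..{model.n_windows}")
        norms = np.zeros(n_classes)
        for c in range(n_classes):
            motif = class_mean_motif(model, pos, c)
            if motif is not None:
                norms[c] = motif_function_norm(motif, x, params)
        top = norms.max()
        scaled = norms / top if top > 0 else norms
        assigned = int(np.argmax(scaled))
        tie = bool(np.sum(np.isclose(scaled, scaled[assigned], rtol=0, atol=1e-12)) > 1)
        col = x.matrix[:, pos - 1]
        residue = x.alphabet.symbols[int(np.argmax(col))]
        entries.append(
            PositionExplanation(
                position=pos, residue=residue, assigned_class=assigned, tie=tie, norms=scaled
            )
        )
    return LocalExplanation(sequence_id=x.id, entries=entries)
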