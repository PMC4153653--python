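"""Discriminant-weight interpretation of a trained classifier.

The sample coefficients a_i obtained from kernel-based training (the
label-signed dual weights, zero off the support) combine with the
training feature matrix M into a per-feature discriminant weight vector

    W_j = sum_i a_i * M[i, j]

For the RBF kernel this is the standard interpretive linear
approximation of feature importance, not an exact primal weight; report
output is labelled accordingly. Summing the positive weights of the
pair features (a, b) over all distances gives an n_c x n_c pair score
matrix whose large cells name the residue pairs that drive the
DNA-binding call (empirically arginine/lysine pairs such as R-R). The
remaining operations localize occurrences of a chosen pair on a
sequence and count how many fall inside annotated regions such as
helix-turn-helix DNA-binding domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabets import ReducedAlphabet, cp20, map_residue, translate_sequence
from .exceptions import EncodingError
from .features import EncodingConfig
from .io_fasta import ProteinRecord
from .model import TrainedModel

#: Region-membership rules for a pair spanning residues p .. p+d.
SPAN_RULES = ("intersect", "strict")


def discriminant_weights(model: TrainedModel, training_features: np.ndarray) -> np.ndarray:
    """Per-feature discriminant weights W from the fitted model.

    ``training_features`` must be the exact matrix the model was fitted
    on (checked by row count). W_j = sum_i a_i M[i, j] with a_i the
    label-signed dual coefficients, zero for non-support rows.
    """
    M = np.asarray(training_features, dtype=float)
    if M.ndim != 2 or M.shape[0] != model.n_train:
        raise ValueError(
            f"training matrix has {M.shape[0]} rows but the model was "
            f"fitted on {model.n_train}"
        )
    if M.shape[1] != model.n_features:
        raise ValueError(
            f"training matrix has {M.shape[1]} columns but the model has "
            f"{model.n_features} features"
        )
    coef = np.zeros(model.n_train, dtype=float)
    coef[model.svc.support_] = model.svc.dual_coef_[0]
    return coef @ M


@dataclass
class DiscriminantMap:
    """Weights W plus the derived pair-score matrix."""

    W: np.ndarray
    pair_scores: np.ndarray  # n_c x n_c, summed positive pair weights
    config: EncodingConfig

    def per_distance(self, pair: tuple[str, str]) -> pd.Series:
        """Weight of one residue/cluster pair at each distance 1..d_max."""
        a, b = pair
        return pd.Series(
            pair_feature_weights(self.W, self.config, a, b),
            index=range(1, self.config.d_max + 1),
            name=f"{a}-{b}",
        )


def _pair_offsets(config: EncodingConfig, a_idx: int, b_idx: int) -> np.ndarray:
    n_c = config.alphabet.n_c
    base = n_c + np.arange(config.d_max) * n_c * n_c
    return base + a_idx * n_c + b_idx


def pair_feature_weights(
    W: np.ndarray, config: EncodingConfig, a: str, b: str
) -> np.ndarray:
    """Raw (signed) weights of pair (a, b) at distances 1..d_max."""
    a_idx = map_residue(config.alphabet, a)
    b_idx = map_residue(config.alphabet, b)
    return np.asarray(W, dtype=float)[_pair_offsets(config, a_idx, b_idx)]


def pair_score_matrix(W: np.ndarray, config: EncodingConfig) -> np.ndarray:
    """Sum of positive pair-feature weights per ordered cluster pair.

    Entry (a, b) sums max(W_j, 0) over the d_max features for the pair,
    excluding the composition block; all entries are >= 0.
    """
    W = np.asarray(W, dtype=float)
    if W.shape != (config.dimension,):
        raise ValueError(
            f"W has shape {W.shape}, expected ({config.dimension},)"
        )
    n_c = config.alphabet.n_c
    pair_block = W[n_c:].reshape(config.d_max, n_c, n_c)
    return np.clip(pair_block, 0.0, None).sum(axis=0)


def discriminant_map(
    model: TrainedModel, training_features: np.ndarray, config: EncodingConfig
) -> DiscriminantMap:
    """Convenience bundle: weights plus pair-score matrix."""
    W = discriminant_weights(model, training_features)
    return DiscriminantMap(W=W, pair_scores=pair_score_matrix(W, config),
                           config=config)


def pair_scores_frame(scores: np.ndarray, alphabet: ReducedAlphabet) -> pd.DataFrame:
    """Pair-score matrix as a labelled DataFrame.

    Rows are the first residue of the pair and columns the second,
    ordered by the standard one-letter alphabet (cluster order).
    """
    labels = alphabet.cluster_labels
    return pd.DataFrame(scores, index=labels, columns=labels)


def plot_pair_scores(scores: np.ndarray, alphabet: ReducedAlphabet, path) -> None:
    """Optional heatmap export; the first residue is on the horizontal
    axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = alphabet.cluster_labels
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(scores.T, origin="upper", cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel("first residue of pair")
    ax.set_ylabel("second residue of pair")
    fig.colorbar(im, ax=ax, label="sum of positive discriminant weights")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class OccurrenceHit:
    """One occurrence of a residue/cluster pair on a sequence.

    ``position`` is the 1-based index of the first residue; the pair
    spans positions ``position .. position + distance``.
    """

    pair: tuple[str, str]
    distance: int
    position: int

    @property
    def end(self) -> int:
        return self.position + self.distance


def locate_pair_occurrences(
    record: ProteinRecord,
    pair: tuple[str, str],
    distances: Sequence[int],
    alphabet: ReducedAlphabet | None = None,
) -> list[OccurrenceHit]:
    """All occurrences of pair (a, b) at the requested distances.

    A hit at distance d' and 1-based position p means residue p is in
    cluster a and residue p + d' in cluster b. Hits are returned sorted
    by distance then position.
    """
    alphabet = alphabet if alphabet is not None else cp20()
    if any(d < 1 for d in distances):
        raise ValueError(f"pair distances must be >= 1, got {list(distances)}")
    a_idx = map_residue(alphabet, pair[0])
    b_idx = map_residue(alphabet, pair[1])
    t = np.asarray(translate_sequence(alphabet, record), dtype=np.intp)
    hits = []
    for d in distances:
        if t.size <= d:
            continue
        pos = np.nonzero((t[:-d] == a_idx) & (t[d:] == b_idx))[0]
        hits.extend(
            OccurrenceHit(pair=tuple(pair), distance=int(d), position=int(p) + 1)
            for p in pos
        )
    return sorted(hits, key=lambda h: (h.distance, h.position))


def region_overlap(
    hits: Sequence[OccurrenceHit],
    regions: Sequence[tuple[int, int]],
    pair_span_rule: str = "intersect",
) -> tuple[int, int]:
    """Count hits inside vs outside annotated sequence regions.

    Regions are 1-based inclusive intervals, non-overlapping and
    sorted. Under the default ``intersect`` rule a hit is inside when
    its residue span [position, position + distance] intersects any
    region; under ``strict`` both endpoints must lie in one region.
    Returns ``(inside, outside)``, a partition of the hits.
    """
    if pair_span_rule not in SPAN_RULES:
        raise ValueError(f"unknown pair_span_rule {pair_span_rule!r}")
    prev_end = 0
    for start, end in regions:
        if start < 1 or end < start:
            raise ValueError(f"malformed region ({start}, {end})")
        if start <= prev_end:
            raise ValueError("regions must be sorted and non-overlapping")
        prev_end = end
    inside = 0
    for hit in hits:
        s, e = hit.position, hit.end
        if pair_span_rule == "intersect":
            is_in = any(s <= rend and e >= rstart for rstart, rend in regions)
        else:
            is_in = any(s >= rstart and e <= rend for rstart, rend in regions)
        inside += is_in
    return inside, len(hits) - inside


def hits_to_frame(hits: Sequence[OccurrenceHit], record_id: str) -> pd.DataFrame:
    """Hits as a BED-like table with 1-based inclusive coordinates."""
    return pd.DataFrame(
        [
            {
                "id": record_id,
                "start": h.position,
                "end": h.end,
                "pair": f"{h.pair[0]}-{h.pair[1]}",
                "distance": h.distance,
            }
            for h in hits
        ],
        columns=["id", "start", "end", "pair", "distance"],
    )
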