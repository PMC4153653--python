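"""Distance-pair pseudo amino acid composition (PseAAC) encoding.

A protein of length ``L`` is represented by a fixed-length vector built
from cluster composition plus ordered distance-pair frequencies under a
reduced alphabet with ``n_c`` clusters:

* the first ``n_c`` entries are the cluster occurrence frequencies
  (the amino acid composition when the alphabet is the full cp(20));
* for each distance ``d' = 1..d_max`` there is an ``n_c x n_c`` block
  whose entry ``(a, b)`` is the frequency of ordered pairs with cluster
  ``a`` at position ``p`` and cluster ``b`` at position ``p + d'``.

The distance convention is the index offset: ``d' = 3`` means the two
residues are separated by two others along the chain. Total dimension is
``Lambda = n_c + n_c**2 * d_max``.

Feature layout (frozen; the discriminant module depends on it):
index ``0..n_c-1`` is the composition block in cluster order; the block
for distance ``d'`` starts at offset ``n_c + (d'-1) * n_c**2`` and is
row-major, pair ``(a, b)`` at offset ``a * n_c + b`` within the block.

Normalization ``per_stratum`` divides the composition block by ``L`` and
each distance block by its pair count ``L - d'``, so every defined block
is a probability distribution; ``raw_counts`` keeps integer counts. A
sequence shorter than ``d' + 1`` has no pairs at that distance: the
block is all zeros (with a logged warning), not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .alphabets import ReducedAlphabet, translate_sequence
from .exceptions import EncodingError
from .io_fasta import ProteinRecord

logger = logging.getLogger(__name__)

Normalization = Literal["per_stratum", "raw_counts"]


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the distance-pair PseAAC encoding."""

    alphabet: ReducedAlphabet
    d_max: int = 3
    normalization: Normalization = "per_stratum"

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError(f"d_max must be >= 0, got {self.d_max}")
        if self.normalization not in ("per_stratum", "raw_counts"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def dimension(self) -> int:
        return feature_dimension(self.alphabet.n_c, self.d_max)


@dataclass(frozen=True)
class FeatureVector:
    """The Lambda-dimensional encoding of one protein."""

    values: np.ndarray
    config: EncodingConfig

    def __post_init__(self) -> None:
        if self.values.shape != (self.config.dimension,):
            raise EncodingError(
                f"feature vector has shape {self.values.shape}, expected "
                f"({self.config.dimension},)"
            )


def feature_dimension(n_c: int, d_max: int) -> int:
    """Dimension of the encoding: ``n_c + n_c**2 * d_max``.

    E.g. the full 20-letter alphabet at d_max=3 gives 1220 features; a
    13-cluster profile gives 520; a 14-cluster profile 14+14*14*3 = 602.
    """
    if not 1 <= n_c <= 20:
        raise ValueError(f"n_c must be in [1, 20], got {n_c}")
    if d_max < 0:
        raise ValueError(f"d_max must be >= 0, got {d_max}")
    return n_c + n_c * n_c * d_max


def count_distance_pairs(
    translated: Sequence[int], d: int, n_c: int
) -> np.ndarray:
    """Ordered-pair counts at index offset ``d``.

    Entry ``(a, b)`` counts positions ``p`` (0-based) with
    ``translated[p] == a`` and ``translated[p + d] == b``. The matrix
    total is ``max(L - d, 0)``.
    """
    if d < 1:
        raise ValueError(f"pair distance must be >= 1, got {d}")
    t = np.asarray(translated, dtype=np.intp)
    counts = np.zeros((n_c, n_c), dtype=np.int64)
    if t.size > d:
        np.add.at(counts, (t[:-d], t[d:]), 1)
    return counts


def encode(record: ProteinRecord, config: EncodingConfig) -> FeatureVector:
    """Encode one protein as a distance-pair PseAAC vector."""
    translated = np.asarray(
        translate_sequence(config.alphabet, record), dtype=np.intp
    )
    L = translated.size
    n_c = config.alphabet.n_c
    per_stratum = config.normalization == "per_stratum"

    comp = np.bincount(translated, minlength=n_c).astype(float)
    blocks = [comp / L if per_stratum else comp]
    for d in range(1, config.d_max + 1):
        counts = count_distance_pairs(translated, d, n_c).astype(float)
        if L <= d:
            logger.warning(
                "record %r: length %d <= distance %d; stratum left all-zero",
                record.id, L, d,
            )
        elif per_stratum:
            counts /= L - d
        blocks.append(counts.ravel())
    return FeatureVector(values=np.concatenate(blocks), config=config)


def feature_names(config: EncodingConfig) -> list[str]:
    """Column names matching the frozen layout.

    Composition features are ``comp:<cluster>`` and pair features
    ``pair:<c1>><c2>:d<k>``, with clusters labelled by their member
    letters (e.g. ``pair:ILV>FWY:d2`` for multi-residue clusters).
    """
    labels = config.alphabet.cluster_labels
    names = [f"comp:{lab}" for lab in labels]
    for d in range(1, config.d_max + 1):
        for a in labels:
            for b in labels:
                names.append(f"pair:{a}>{b}:d{d}")
    return names


def encode_batch(
    records: Sequence[ProteinRecord], config: EncodingConfig
) -> tuple[np.ndarray, list[str]]:
    """Encode many records into one matrix.

    Returns ``(matrix, ids)`` with row ``i`` equal to
    ``encode(records[i], config).values``; an empty record list yields a
    ``(0, Lambda)`` matrix. Per-record failures are aggregated into one
    error listing the offending ids.
    """
    dim = config.dimension
    rows = np.empty((len(records), dim), dtype=float)
    ids = []
    failures = []
    for i, rec in enumerate(records):
        try:
            rows[i] = encode(rec, config).values
        except EncodingError as e:
            failures.append(f"{rec.id}: {e}")
            continue
        ids.append(rec.id)
    if failures:
        raise EncodingError(
            "failed to encode %d record(s):\n  " % len(failures)
            + "\n  ".join(failures)
        )
    return rows, ids


def features_to_frame(
    matrix: np.ndarray, ids: Sequence[str], config: EncodingConfig
) -> pd.DataFrame:
    """Feature matrix as a DataFrame (rows = sequence ids)."""
    return pd.DataFrame(matrix, index=list(ids), columns=feature_names(config))


def write_features_tsv(
    matrix: np.ndarray, ids: Sequence[str], config: EncodingConfig, path
) -> None:
    """Export the feature matrix as TSV with named columns."""
    features_to_frame(matrix, ids, config).to_csv(
        path, sep="\t", index_label="id"
    )
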