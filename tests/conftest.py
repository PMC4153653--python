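"""Shared fixtures and the brute-force encoding oracle.

The oracle re-derives distance-pair counts by enumerating every
(p, p + d) index pair in pure Python, independently of the vectorised
encoder it checks against.
"""

from __future__ import annotations

import numpy as np
import pytest

from dpseaac import ProteinRecord, ReducedAlphabet, cp20
from dpseaac.io_fasta import STANDARD_AA


def oracle_vector(
    seq: str, alphabet: ReducedAlphabet, d_max: int, normalization: str
) -> np.ndarray:
    """Reference distance-pair PseAAC vector by direct enumeration."""
    idx = {aa: i for i, cl in enumerate(alphabet.clusters) for aa in cl}
    t = [idx[c] for c in seq]
    n, L = alphabet.n_c, len(t)
    comp = [0.0] * n
    for c in t:
        comp[c] += 1
    if normalization == "per_stratum":
        comp = [x / L for x in comp]
    out = list(comp)
    for d in range(1, d_max + 1):
        mat = [[0.0] * n for _ in range(n)]
        for p in range(L - d):
            mat[t[p]][t[p + d]] += 1
        if normalization == "per_stratum" and L > d:
            mat = [[x / (L - d) for x in row] for row in mat]
        out.extend(x for row in mat for x in row)
    return np.array(out)


def random_partition(n_c: int, seed: int) -> ReducedAlphabet:
    """A deterministic arbitrary partition of the 20 residues into n_c
    clusters (memberships are irrelevant to the properties under test)."""
    rng = np.random.default_rng(seed)
    letters = list(STANDARD_AA)
    rng.shuffle(letters)
    # n_c - 1 cut points give n_c non-empty ordered chunks
    cuts = sorted(rng.choice(np.arange(1, 20), size=n_c - 1, replace=False))
    bounds = [0, *cuts, 20]
    clusters = tuple(
        frozenset(letters[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return ReducedAlphabet(name=f"random-cp{n_c}-s{seed}", clusters=clusters)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture(scope="session")
def alphabet20() -> ReducedAlphabet:
    return cp20()


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord(id="p1", seq="MKRRAKDEW"),
        ProteinRecord(id="p2", seq="ACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord(id="p3", seq="GGGGSSSSGGGG"),
    ]
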