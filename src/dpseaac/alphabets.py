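"""Reduced amino acid alphabets (cluster profiles).

A reduced alphabet is an ordered partition of the 20 standard amino
acids into ``n_c`` clusters; treating each cluster as one letter shrinks
the ordered-pair feature space from ``400 * d`` to ``n_c**2 * d``. The
full 20-letter alphabet (every residue its own cluster, here called
``cp(20)``) is built in. Other profiles — e.g. the 3/13/14/15-cluster
schemes from published reduced-alphabet collections — are loaded from
profile files: one line, clusters separated by ``;``, residues within a
cluster concatenated, e.g. ``ILV;FWY;...``. We do not hard-code any
published multi-cluster memberships; supply them as profile files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import EncodingError, ProfileError
from .io_fasta import STANDARD_AA, ProteinRecord


@dataclass(frozen=True)
class ReducedAlphabet:
    """An ordered partition of the 20 amino acids into clusters.

    ``clusters[i]`` is the set of one-letter codes mapping to cluster
    index ``i`` (0-based). User-facing reports should label clusters by
    :attr:`cluster_labels`, never by bare indices.
    """

    name: str
    clusters: tuple[frozenset[str], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, cluster in enumerate(self.clusters):
            if not cluster:
                raise ProfileError(f"{self.name}: cluster {i} is empty")
            for aa in cluster:
                if aa not in STANDARD_AA:
                    raise ProfileError(
                        f"{self.name}: unknown amino acid letter {aa!r}"
                    )
                if aa in seen:
                    raise ProfileError(
                        f"{self.name}: residue {aa!r} appears in more than "
                        "one cluster"
                    )
                seen[aa] = i
        missing = sorted(set(STANDARD_AA) - set(seen))
        if missing:
            raise ProfileError(
                f"{self.name}: profile does not cover residue(s) "
                f"{', '.join(missing)}"
            )
        object.__setattr__(self, "_index", seen)

    @property
    def n_c(self) -> int:
        """Number of clusters."""
        return len(self.clusters)

    @property
    def cluster_labels(self) -> tuple[str, ...]:
        """Member letters of each cluster, sorted, as display labels."""
        return tuple("".join(sorted(c)) for c in self.clusters)

    def to_profile_string(self) -> str:
        """Serialize back to the ``;``-separated profile dialect."""
        return ";".join("".join(sorted(c)) for c in self.clusters)


def cp20() -> ReducedAlphabet:
    """The identity partition: every amino acid its own cluster,
    alphabetical order."""
    return ReducedAlphabet(
        name="cp(20)", clusters=tuple(frozenset(aa) for aa in STANDARD_AA)
    )


def parse_profile(text: str, name: str) -> ReducedAlphabet:
    """Parse a ``;``-separated cluster profile string."""
    parts = [p.strip().upper() for p in text.strip().split(";")]
    parts = [p for p in parts if p]
    if not parts:
        raise ProfileError(f"{name}: no clusters found")
    return ReducedAlphabet(name=name, clusters=tuple(frozenset(p) for p in parts))


def load_alphabet(path) -> ReducedAlphabet:
    """Load one profile file; profile name = file stem.

    The file holds a single profile on one line (blank lines and
    ``#`` comments are ignored).
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ProfileError(f"{path}: no profile line found")
    if len(lines) > 1:
        raise ProfileError(f"{path}: expected one profile line, found {len(lines)}")
    return parse_profile(lines[0], name=path.stem)


def load_profile_dir(path) -> dict[str, ReducedAlphabet]:
    """Load every profile file in a directory, keyed by file stem."""
    path = Path(path)
    profiles = {}
    for f in sorted(path.iterdir()):
        if f.is_file() and not f.name.startswith("."):
            alpha = load_alphabet(f)
            profiles[alpha.name] = alpha
    if not profiles:
        raise ProfileError(f"{path}: no profile files found")
    return profiles


def map_residue(alphabet: ReducedAlphabet, residue: str) -> int:
    """0-based cluster index of a one-letter residue code."""
    try:
        return alphabet._index[residue]
    except KeyError:
        raise EncodingError(
            f"residue {residue!r} is not one of the 20 standard amino acids"
        ) from None


def translate_sequence(
    alphabet: ReducedAlphabet, record: ProteinRecord
) -> list[int]:
    """Map every residue of a record to its cluster index.

    Raises :class:`EncodingError` carrying the 1-based position of the
    first non-standard residue.
    """
    out = []
    idx = alphabet._index
    for pos, aa in enumerate(record.seq, start=1):
        try:
            out.append(idx[aa])
        except KeyError:
            raise EncodingError(
                f"record {record.id!r}: residue {aa!r} at position {pos} "
                "is not a standard amino acid",
                position=pos,
            ) from None
    return out
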