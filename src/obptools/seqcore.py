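"""Protein sequence handling, cysteine-pairing classification, pairwise
identity, Kimura-corrected protein distances, and neighbor-joining trees.

Chelicerata odorant-binding proteins carry six conserved cysteines whose
pairing pattern (C1-C6, C2-C3, C4-C5 — "adjacent") differs from the
interlocked insect pattern (C1-C3, C2-C5, C4-C6).  This module classifies
observed bridge sets against those two motifs and provides the
distance-based phylogenetic machinery used to place such sequences in trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masscalc import RESIDUE_MASS

__all__ = [
    "ProteinRecord",
    "Bridge",
    "TopologyCall",
    "DistanceMatrix",
    "ADJACENT_LABEL",
    "INTERLOCKED_LABEL",
    "read_fasta",
    "classify_pairing",
    "pairwise_identity",
    "kimura_distance",
    "KIMURA_P_MAX",
    "distance_matrix_from_alignment",
    "nj_tree",
]

ADJACENT_LABEL = "C1-C6,C2-C3,C4-C5"
INTERLOCKED_LABEL = "C1-C3,C2-C5,C4-C6"

_VALID_RESIDUES = frozenset(RESIDUE_MASS)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its ordered 1-based cysteine positions."""

    id: str
    sequence: str
    cys_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not self.sequence.isupper():
            raise ValueError(f"sequence for {self.id!r} must be uppercase")
        if not self.cys_positions:
            object.__setattr__(
                self,
                "cys_positions",
                tuple(i + 1 for i, r in enumerate(self.sequence) if r == "C"),
            )
        if list(self.cys_positions) != sorted(set(self.cys_positions)):
            raise ValueError("cys_positions must be strictly increasing")
        for pos in self.cys_positions:
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "C":
                raise ValueError(f"position {pos} of {self.id!r} is not a cysteine")


@dataclass(frozen=True, order=True)
class Bridge:
    """A disulfide bridge between two 1-based residue positions."""

    pos_a: int
    pos_b: int

    def __post_init__(self) -> None:
        if self.pos_a >= self.pos_b:
            raise ValueError(f"bridge positions must satisfy pos_a < pos_b, got "
                             f"({self.pos_a}, {self.pos_b})")


@dataclass(frozen=True)
class TopologyCall:
    """A set of bridges plus its canonical cysteine-ordinal label."""

    bridges: frozenset[Bridge]
    ordinal_label: str
    pattern: str  # "adjacent (Chelicerata)" | "interlocked (insect)" | "other"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (sequences uppercased).

    Raises ``ValueError`` naming the offending line on malformed input or
    non-amino-acid characters.
    """
    from Bio import SeqIO

    records: list[ProteinRecord] = []
    path = Path(path)
    # pre-scan for a header before any sequence, with line numbers for errors
    with open(path) as fh:
        lineno_of_first = None
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if lineno_of_first is None:
                lineno_of_first = lineno
                if not stripped.startswith(">"):
                    raise ValueError(
                        f"{path}:{lineno}: FASTA must start with a '>' header"
                    )
    if lineno_of_first is None:
        raise ValueError(f"{path}: empty FASTA file")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def classify_pairing(
    bridges: Iterable[Bridge | tuple[int, int]],
    cys_positions: Sequence[int],
) -> TopologyCall:
    """Map bridge residue positions to cysteine ordinals and name the motif.

    C1 is the smallest cysteine position; the label lists bridges sorted by
    their first ordinal (e.g. ``"C1-C6,C2-C3,C4-C5"``).  The two named motifs
    are reported as ``"adjacent (Chelicerata)"`` and ``"interlocked (insect)"``;
    anything else, including an empty bridge set, is ``"other"``.
    """
    cys = sorted(cys_positions)
    ordinal = {pos: i + 1 for i, pos in enumerate(cys)}
    norm: set[Bridge] = set()
    for b in bridges:
        if not isinstance(b, Bridge):
            b = Bridge(min(b), max(b))
        for pos in (b.pos_a, b.pos_b):
            if pos not in ordinal:
                raise ValueError(f"bridge endpoint {pos} is not a cysteine position")
        norm.add(b)
    used: set[int] = set()
    for b in norm:
        for pos in (b.pos_a, b.pos_b):
            if pos in used:
                raise ValueError(
                    f"cysteine {pos} is shared by more than one bridge"
                )
            used.add(pos)
    pairs = sorted((ordinal[b.pos_a], ordinal[b.pos_b]) for b in norm)
    label = ",".join(f"C{i}-C{j}" for i, j in pairs)
    if label == ADJACENT_LABEL:
        pattern = "adjacent (Chelicerata)"
    elif label == INTERLOCKED_LABEL:
        pattern = "interlocked (insect)"
    else:
        pattern = "other"
    return TopologyCall(frozenset(norm), label, pattern)


def pairwise_identity(
    seq_a: str, seq_b: str, mode: str = "ungapped"
) -> tuple[float, int]:
    """Fraction of identical residues and the overlap length.

    ``mode="ungapped"`` anchors both sequences at the C-terminus and compares
    the overlapping stretch without gaps (suited to homolog pairs differing
    only by an N-terminal extension).  ``mode="aligned"`` treats the inputs as
    two rows of an alignment (``-`` for gaps) and counts identities over the
    columns where neither row is gapped.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if mode == "ungapped":
        n = min(len(seq_a), len(seq_b))
        ta, tb = seq_a[-n:], seq_b[-n:]
        if n == 0:
            raise ValueError("zero overlap between sequences")
        matches = sum(x == y for x, y in zip(ta, tb))
        return matches / n, n
    if mode == "aligned":
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned mode requires equal-length rows")
        cols = [(x, y) for x, y in zip(seq_a, seq_b) if x != "-" and y != "-"]
        if not cols:
            raise ValueError("zero overlap: no ungapped columns")
        matches = sum(x == y for x, y in cols)
        return matches / len(cols), len(cols)
    raise ValueError(f"unknown mode {mode!r}")


#: largest observed-difference proportion with a finite Kimura distance
KIMURA_P_MAX = (-1 + math.sqrt(1.8)) / 0.4


def kimura_distance(p: float) -> float:
    """Kimura-corrected protein distance −ln(1 − p − p²/5).

    ``p`` is the observed proportion of differing sites.  The correction
    saturates at p ≈ 0.8541; larger values raise ``ValueError`` instead of
    returning infinity.
    """
    if p < 0:
        raise ValueError(f"proportion of differing sites must be >= 0, got {p}")
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0:
        raise ValueError(
            f"saturated distance: p={p} >= {KIMURA_P_MAX:.4f} has no finite "
            "Kimura correction"
        )
    return -math.log(arg)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        """Read a TSV with a header row of labels and a leading label column."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def distance_matrix_from_alignment(
    records: Sequence[ProteinRecord] | Sequence[tuple[str, str]],
    correction: str = "kimura",
) -> DistanceMatrix:
    """Pairwise p-distances (optionally Kimura-corrected) from aligned rows."""
    items = [
        (r.id, r.sequence) if isinstance(r, ProteinRecord) else (r[0], r[1])
        for r in records
    ]
    labels = tuple(name for name, _ in items)
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(items[i][1], items[j][1], mode="aligned")
            p = 1.0 - ident
            d[i, j] = d[j, i] = kimura_distance(p) if correction == "kimura" else p
    return DistanceMatrix(labels, d)


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children=None):
        self.label = label
        # children: list of (child _Node, branch length)
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{c.newick()}:{bl:.6f}" for c, bl in self.children
        )
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbor-joining; returns an unrooted tree in Newick.

    Deterministic: joins are selected by smallest Q, ties broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by the smallest leaf name it contains).  Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.  On an
    additive matrix the tree reproduces all pairwise path lengths exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor-joining needs at least 3 taxa, got {n}")

    nodes: dict[str, _Node] = {lab: _Node(lab) for lab in dm.labels}
    # sort key per cluster: smallest contained leaf label
    key: dict[str, str] = {lab: lab for lab in dm.labels}
    dist: dict[frozenset[str], float] = {}
    active = list(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.d[i, j])

    def d(x: str, y: str) -> float:
        return dist[frozenset((x, y))]

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {x: sum(d(x, y) for y in active if y != x) for x in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                x, y = active[ii], active[jj]
                q = (m - 2) * d(x, y) - r[x] - r[y]
                tie = tuple(sorted((key[x], key[y])))
                cand = (q, tie, x, y)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, x, y = best
        dxy = d(x, y)
        lx = dxy / 2 + (r[x] - r[y]) / (2 * (m - 2))
        ly = dxy - lx
        if lx < 0:
            ly, lx = ly + lx, 0.0
        if ly < 0:
            lx, ly = lx + ly, 0.0
        new = f"__nj{counter}"
        counter += 1
        nodes[new] = _Node(None, [(nodes[x], lx), (nodes[y], ly)])
        key[new] = min(key[x], key[y])
        for z in active:
            if z in (x, y):
                continue
            dist[frozenset((new, z))] = (d(x, z) + d(y, z) - dxy) / 2
        active = [z for z in active if z not in (x, y)] + [new]

    a, b, c = sorted(active, key=lambda z: key[z])
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    lengths = {a: la, b: lb, c: lc}
    # clamp any negative terminal branch, moving the deficit to the others
    for z in (a, b, c):
        if lengths[z] < 0:
            deficit = lengths[z]
            lengths[z] = 0.0
            others = [w for w in (a, b, c) if w != z]
            for w in others:
                lengths[w] += deficit / 2
    root = _Node(
        None, [(nodes[z], lengths[z]) for z in (a, b, c)]
    )
    return root.newick() + ";"
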