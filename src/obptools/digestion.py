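"""In-silico proteolysis: trypsin, chymotrypsin, sequential double digestion,
missed cleavages, and semi-specific (one aspecific terminus) expansion.

Cleavage follows the classical rules: an enzyme cuts C-terminally to its
target residues unless the next residue is proline (the proline block can be
disabled per rule).  Protein termini always count as enzymatically specific.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .masscalc import Peptide

__all__ = [
    "EnzymeRule",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "NULL_ENZYME",
    "DigestParams",
    "digest",
    "sequential_digest",
    "semi_specific_expansion",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Cleave after any residue in ``cleave_after`` unless the following
    residue is in ``blocked_by_next``."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset("P")

    def cut_sites(self, seq: str) -> list[int]:
        """0-based indices i such that the enzyme cuts between i and i+1."""
        return [
            i
            for i in range(len(seq) - 1)
            if seq[i] in self.cleave_after and seq[i + 1] not in self.blocked_by_next
        ]


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"))
# F/W/Y/L specificity: high-specificity chymotrypsin set, extended with Leu
CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("FWYL"))
#: cuts nowhere; useful as the identity second stage
NULL_ENZYME = EnzymeRule("null", frozenset())


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 5
    min_length: int = 2
    max_length: int = 30
    semi_specific: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 9:
            raise ValueError("max_missed_cleavages must be in 0..9")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


def digest(
    seq: str,
    enzyme: EnzymeRule,
    params: DigestParams = DigestParams(),
    offset: int = 1,
    termini_specific: tuple[bool, bool] = (True, True),
) -> list[Peptide]:
    """Fully-specific peptides with up to ``max_missed_cleavages`` internal
    uncleaved sites, ordered by span.

    ``offset`` is the 1-based protein position of ``seq[0]``, so peptide spans
    land in host-protein coordinates when a fragment of a protein is digested.
    ``termini_specific`` states whether the ends of ``seq`` itself are
    enzymatically specific (protein termini are).
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    cuts = enzyme.cut_sites(seq)
    bounds = [0] + [i + 1 for i in cuts] + [len(seq)]
    out: list[Peptide] = []
    for bi in range(len(bounds) - 1):
        for bj in range(bi + 1, min(bi + 2 + params.max_missed_cleavages,
                                    len(bounds))):
            start, end = bounds[bi], bounds[bj]
            length = end - start
            if not params.min_length <= length <= params.max_length:
                continue
            n_spec = termini_specific[0] if bi == 0 else True
            c_spec = termini_specific[1] if bj == len(bounds) - 1 else True
            out.append(
                Peptide(
                    seq[start:end],
                    span=(offset + start, offset + end - 1),
                    termini_specific=(n_spec, c_spec),
                )
            )
    return sorted(out, key=lambda p: p.span)


def sequential_digest(
    seq: str,
    first: EnzymeRule,
    second: EnzymeRule,
    params: DigestParams = DigestParams(),
) -> list[Peptide]:
    """Digest with ``first``, then apply ``second`` to every product.

    The union of all second-stage products is returned, de-duplicated by
    span; the missed-cleavage budget applies per enzyme, so a first-stage
    peptide with uncut second-enzyme sites within budget survives intact.
    """
    stage1 = digest(seq, first, params)
    seen: dict[tuple[int, int], Peptide] = {}
    for pep in stage1:
        for sub in digest(
            pep.sequence,
            second,
            params,
            offset=pep.span[0],
            termini_specific=pep.termini_specific,
        ):
            seen.setdefault(sub.span, sub)
    return sorted(seen.values(), key=lambda p: p.span)


def semi_specific_expansion(p: Peptide, min_length: int = 2) -> list[Peptide]:
    """All truncations of ``p`` that keep at least one specific terminus.

    Every prefix (specific N-terminus, aspecific C-terminus) and suffix
    (aspecific N-terminus, specific C-terminus) of length >= ``min_length``
    is generated; the fully-specific parent itself is included.
    """
    n = len(p.sequence)
    start = p.span[0] if p.span else 1
    out: list[Peptide] = [p] if n >= min_length else []
    for k in range(min_length, n):
        out.append(
            replace(
                p,
                sequence=p.sequence[:k],
                span=(start, start + k - 1),
                termini_specific=(p.termini_specific[0], False),
            )
        )
        out.append(
            replace(
                p,
                sequence=p.sequence[n - k:],
                span=(start + n - k, start + n - 1),
                termini_specific=(False, p.termini_specific[1]),
            )
        )
    return sorted(out, key=lambda q: q.span)
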