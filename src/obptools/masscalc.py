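"""Monoisotopic mass calculus for peptides and disulfide-crosslinked species.

All masses are monoisotopic and expressed in daltons.  A disulfide bond
between two peptides removes two hydrogen atoms (2 x 1.0078250 Da); the
charge carrier for every charge state is a proton (1.0072765 Da).

The module covers four needs of disulfide mapping from mass-spectrometric
evidence:

* neutral peptide masses with post-translational modifications
  (carbamidomethyl, Met oxidation, Asn/Gln deamidation, N-terminal
  pyroglutamate),
* neutral and per-charge m/z values of two peptides joined by one S-S bond,
* b/y fragment ions of each constituent peptide, where a fragment retaining
  the bridged cysteine carries the full partner peptide (minus 2 H),
* validation that modifications respect their site rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "WATER",
    "PROTON",
    "HYDROGEN",
    "DISULFIDE_DELTA",
    "RESIDUE_MASS",
    "Modification",
    "CARBAMIDOMETHYL",
    "OXIDATION_M",
    "DEAMIDATION",
    "PYROGLUTAMATE",
    "BUILTIN_MODS",
    "Peptide",
    "CrosslinkedSpecies",
    "peptide_mass",
    "crosslink_mass",
    "mz",
    "apply_modification",
    "fragment_ions",
]

WATER = 18.010565
PROTON = 1.0072765
HYDROGEN = 1.0078250
#: mass removed when one disulfide bond forms (loss of two H atoms)
DISULFIDE_DELTA = 2 * HYDROGEN

#: monoisotopic residue masses for the 20 standard amino acids
RESIDUE_MASS: Mapping[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


@dataclass(frozen=True)
class Modification:
    """A fixed-delta covalent modification with a residue/terminus site rule.

    ``residues`` is the set of one-letter codes the modification may sit on;
    ``terminus`` restricts it to the peptide N- or C-terminal residue
    (``"N"``/``"C"``) or leaves it positionally free (``None``).
    """

    name: str
    delta_mass: float
    residues: frozenset[str]
    terminus: str | None = None

    def allowed_at(self, sequence: str, position: int) -> bool:
        """True if this modification may sit at 1-based ``position``."""
        if not 1 <= position <= len(sequence):
            return False
        if sequence[position - 1] not in self.residues:
            return False
        if self.terminus == "N" and position != 1:
            return False
        if self.terminus == "C" and position != len(sequence):
            return False
        return True


CARBAMIDOMETHYL = Modification("carbamidomethyl", 57.021464, frozenset("C"))
OXIDATION_M = Modification("oxidation", 15.994915, frozenset("M"))
DEAMIDATION = Modification("deamidation", 0.984016, frozenset("NQ"))
PYROGLUTAMATE = Modification("pyroglutamate", -17.026549, frozenset("Q"), terminus="N")

BUILTIN_MODS: Mapping[str, Modification] = {
    m.name: m for m in (CARBAMIDOMETHYL, OXIDATION_M, DEAMIDATION, PYROGLUTAMATE)
}
# short aliases used in evidence tables
BUILTIN_MODS = {
    **BUILTIN_MODS,
    "cam": CARBAMIDOMETHYL,
    "ox": OXIDATION_M,
    "deam": DEAMIDATION,
    "pglu": PYROGLUTAMATE,
}


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide, optionally located in a host protein.

    ``span`` is the 1-based inclusive (start, end) of the peptide in its host
    protein, or ``None`` when the host is unknown.  ``mods`` holds
    (1-based position within the peptide, Modification) pairs.
    ``termini_specific`` flags whether the N- and C-terminus were produced by
    the declared enzyme specificity (protein termini count as specific).
    """

    sequence: str
    span: tuple[int, int] | None = None
    mods: tuple[tuple[int, Modification], ...] = ()
    termini_specific: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        if self.span is not None:
            start, end = self.span
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"span {self.span} length does not match sequence "
                    f"{self.sequence!r}"
                )
        for pos, mod in self.mods:
            if not mod.allowed_at(self.sequence, pos):
                raise ValueError(
                    f"modification {mod.name} not allowed at position {pos} "
                    f"of {self.sequence!r}"
                )

    @property
    def cys_positions(self) -> tuple[int, ...]:
        """1-based positions of cysteines within the peptide."""
        return tuple(i + 1 for i, r in enumerate(self.sequence) if r == "C")

    def cys_protein_positions(self) -> tuple[int, ...]:
        """Cysteine positions in host-protein coordinates (requires span)."""
        if self.span is None:
            raise ValueError("peptide has no host span")
        return tuple(self.span[0] + p - 1 for p in self.cys_positions)

    def free_cys_positions(self) -> tuple[int, ...]:
        """Cysteines not blocked by carbamidomethylation (peptide coords)."""
        cam = {p for p, m in self.mods if m.name == CARBAMIDOMETHYL.name}
        return tuple(p for p in self.cys_positions if p not in cam)

    @property
    def mass(self) -> float:
        return peptide_mass(self)

    def annotated(self) -> str:
        """Sequence with inline mod annotations, e.g. ``Q(pglu)CK``."""
        short = {"carbamidomethyl": "cam", "oxidation": "ox",
                 "deamidation": "deam", "pyroglutamate": "pglu"}
        by_pos = {p: short.get(m.name, m.name) for p, m in self.mods}
        return "".join(
            r + (f"({by_pos[i]})" if i in by_pos else "")
            for i, r in enumerate(self.sequence, start=1)
        )


def peptide_mass(p: Peptide | str) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    if isinstance(p, str):
        p = Peptide(p)
    total = WATER + sum(RESIDUE_MASS[r] for r in p.sequence)
    total += sum(m.delta_mass for _, m in p.mods)
    return total


def mz(neutral_mass: float, z: int) -> float:
    """m/z of a species carrying ``z`` protons."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (neutral_mass + z * PROTON) / z


def apply_modification(p: Peptide, m: Modification, position: int) -> Peptide:
    """Return a copy of ``p`` with ``m`` attached at 1-based ``position``.

    The site rule is enforced (e.g. pyroglutamate only at an N-terminal Gln);
    violations raise ``ValueError``.
    """
    if not m.allowed_at(p.sequence, position):
        raise ValueError(
            f"modification {m.name} not allowed at position {position} of "
            f"{p.sequence!r}"
        )
    if any(pos == position for pos, _ in p.mods):
        raise ValueError(f"position {position} already modified")
    return replace(p, mods=tuple(sorted(p.mods + ((position, m),))))


@dataclass(frozen=True)
class CrosslinkedSpecies:
    """Two peptides joined by a single S-S bond (loss of two hydrogens).

    ``bridged_cys`` holds the bridged cysteine positions, in host-protein
    coordinates when both peptides carry spans, otherwise in peptide-local
    coordinates.
    """

    peptide_a: Peptide
    peptide_b: Peptide
    bridged_cys: tuple[int, int]
    neutral_mass: float = field(init=False)

    def __post_init__(self) -> None:
        for pep, cys in zip((self.peptide_a, self.peptide_b), self.bridged_cys):
            local = cys
            if pep.span is not None:
                local = cys - pep.span[0] + 1
            if local not in pep.free_cys_positions():
                raise ValueError(
                    f"{pep.sequence!r} has no free (non-carbamidomethylated) "
                    f"cysteine at position {cys}"
                )
        object.__setattr__(
            self,
            "neutral_mass",
            peptide_mass(self.peptide_a) + peptide_mass(self.peptide_b)
            - DISULFIDE_DELTA,
        )

    @property
    def mz_by_charge(self) -> dict[int, float]:
        """m/z at charge states 1-4 (the range reported for such species)."""
        return {z: mz(self.neutral_mass, z) for z in range(1, 5)}

    @property
    def species_id(self) -> str:
        a, b = self.peptide_a, self.peptide_b
        sa = f"{a.annotated()}@{a.span[0]}-{a.span[1]}" if a.span else a.annotated()
        sb = f"{b.annotated()}@{b.span[0]}-{b.span[1]}" if b.span else b.annotated()
        return f"[{sa}]-[{sb}]|{self.bridged_cys[0]}-{self.bridged_cys[1]}"


def crosslink_mass(
    a: Peptide | str,
    b: Peptide | str,
    bridged_cys: tuple[int, int] | None = None,
) -> CrosslinkedSpecies:
    """Join two cysteine-containing peptides by one disulfide bond.

    When ``bridged_cys`` is omitted, the first free cysteine of each peptide
    is used (in host coordinates when spans are known).
    """
    if isinstance(a, str):
        a = Peptide(a)
    if isinstance(b, str):
        b = Peptide(b)
    if bridged_cys is None:
        pair = []
        for pep in (a, b):
            free = pep.free_cys_positions()
            if not free:
                raise ValueError(
                    f"peptide {pep.sequence!r} has no free cysteine"
                )
            pos = free[0]
            if pep.span is not None:
                pos = pep.span[0] + pos - 1
            pair.append(pos)
        bridged_cys = (pair[0], pair[1])
    return CrosslinkedSpecies(a, b, bridged_cys)


def _prefix_masses(p: Peptide) -> list[float]:
    """Cumulative residue+mod masses of prefixes, index i = first i residues."""
    by_pos: dict[int, float] = {}
    for pos, m in p.mods:
        by_pos[pos] = by_pos.get(pos, 0.0) + m.delta_mass
    acc, out = 0.0, [0.0]
    for i, r in enumerate(p.sequence, start=1):
        acc += RESIDUE_MASS[r] + by_pos.get(i, 0.0)
        out.append(acc)
    return out


def fragment_ions(
    s: CrosslinkedSpecies,
    series: Iterable[str] = ("b", "y"),
    z_max: int = 2,
) -> list[tuple[str, float]]:
    """Predicted b/y fragment ions of both constituent peptides.

    Fragments that retain the bridged cysteine carry the entire partner
    peptide minus two hydrogens (the S-S bond stays intact); the others are
    ordinary linear b/y ions.  Labels read like ``A.b3^2+`` where ``A``/``B``
    names the peptide.
    """
    series = set(series)
    unknown = series - {"b", "y"}
    if unknown:
        raise ValueError(f"unknown ion series: {sorted(unknown)}")
    out: list[tuple[str, float]] = []
    peptides = (("A", s.peptide_a, s.peptide_b), ("B", s.peptide_b, s.peptide_a))
    for tag, pep, partner in peptides:
        n = len(pep.sequence)
        pref = _prefix_masses(pep)
        total = pref[n]
        bridged_local = s.bridged_cys[0] if tag == "A" else s.bridged_cys[1]
        if pep.span is not None:
            bridged_local = bridged_local - pep.span[0] + 1
        partner_payload = peptide_mass(partner) - DISULFIDE_DELTA
        for i in range(1, n):
            # neutral fragment masses; b = prefix, y = suffix + water
            if "b" in series:
                m_b = pref[i]
                if bridged_local <= i:
                    m_b += partner_payload
                for z in range(1, z_max + 1):
                    out.append((f"{tag}.b{i}^{z}+", mz(m_b, z)))
            if "y" in series:
                m_y = total - pref[n - i] + WATER
                if bridged_local > n - i:
                    m_y += partner_payload
                for z in range(1, z_max + 1):
                    out.append((f"{tag}.y{i}^{z}+", mz(m_y, z)))
    return out


def expand_mod_variants(
    p: Peptide,
    mods: Sequence[Modification],
    max_mods: int = 2,
) -> list[Peptide]:
    """All variants of ``p`` carrying 0..max_mods of the given modifications.

    Each applicable (site, modification) combination is applied at most once
    per site; the unmodified peptide is always first.
    """
    sites: list[tuple[int, Modification]] = []
    for m in mods:
        for pos in range(1, len(p.sequence) + 1):
            if m.allowed_at(p.sequence, pos):
                sites.append((pos, m))
    variants = [p]
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(sites, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            q = p
            try:
                for pos, m in combo:
                    q = apply_modification(q, m, pos)
            except ValueError:
                continue
            variants.append(q)
    return variants
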