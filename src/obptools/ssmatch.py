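"""Candidate enumeration, precursor matching, MS2 annotation, and disulfide
topology inference.

The search strategy mirrors a disulfide-mapping experiment: enumerate every
unordered pair of cysteine-containing peptides (one S-S bond per species,
overlapping spans excluded), match observed precursors to candidate neutral
masses within a ppm tolerance, optionally count matching b/y fragments in
MS2 spectra, and assemble the per-cysteine-pair evidence into a bridge graph
from which a maximum-weight matching yields the topology call.

Scoring is a deliberately transparent heuristic
(``n_fragments_matched − 10 × mean |Da error|``); identifications rest on
mass agreement and topology recovery, not on a calibrated statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masscalc import (
    DISULFIDE_DELTA,
    PROTON,
    CrosslinkedSpecies,
    Modification,
    Peptide,
    expand_mod_variants,
    fragment_ions,
    mz,
)
from .seqcore import Bridge, ProteinRecord, TopologyCall, classify_pairing

__all__ = [
    "Precursor",
    "PeakList",
    "MatchResult",
    "BridgeGraph",
    "read_peaklist",
    "enumerate_candidates",
    "match_precursors",
    "annotate_ms2",
    "infer_topology",
]


@dataclass(frozen=True)
class Precursor:
    mz: float
    charge: int
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if not 1 <= self.charge <= 6:
            raise ValueError(f"charge must be in 1..6, got {self.charge}")

    @property
    def neutral_mass(self) -> float:
        return self.charge * self.mz - self.charge * PROTON


@dataclass(frozen=True)
class PeakList:
    """Precursor peaks with optional per-precursor MS2 fragment lists."""

    precursors: tuple[Precursor, ...]
    ms2: dict[int, tuple[tuple[float, float], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx in self.ms2:
            if not 0 <= idx < len(self.precursors):
                raise ValueError(f"MS2 index {idx} out of range")


def read_peaklist(path: str | Path) -> PeakList:
    """Read precursors from an MGF file or a TSV (columns mz, z, intensity)."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        from pyteomics import mgf

        precursors: list[Precursor] = []
        ms2: dict[int, tuple[tuple[float, float], ...]] = {}
        with mgf.read(str(path), use_index=False) as reader:
            for spec in reader:
                params = spec["params"]
                pep_mz = float(params["pepmass"][0])
                charge = int(params["charge"][0])
                intensity = float(params.get("pepintensity", 0.0) or 0.0)
                idx = len(precursors)
                precursors.append(Precursor(pep_mz, charge, intensity))
                frags = tuple(
                    zip(spec["m/z array"].tolist(), spec["intensity array"].tolist())
                )
                if frags:
                    ms2[idx] = frags
        return PeakList(tuple(precursors), ms2)
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    precursors = tuple(
        Precursor(float(r["mz"]), int(r["z"]), float(r.get("intensity", 0.0)))
        for _, r in df.iterrows()
    )
    return PeakList(precursors)


@dataclass(frozen=True)
class MatchResult:
    species: CrosslinkedSpecies
    observed_mz: float
    charge: int
    ppm_error: float
    precursor_index: int = -1
    n_fragments_matched: int | None = None
    score: float = 0.0


@dataclass(frozen=True)
class BridgeGraph:
    """Cysteine positions with per-pair evidence weights (distinct species)."""

    nodes: tuple[int, ...]
    edges: dict[tuple[int, int], int]


def _spans_overlap(a: Peptide, b: Peptide) -> bool:
    if a.span is None or b.span is None:
        # without host coordinates only self-pairing can be ruled out
        return a.sequence == b.sequence and a.mods == b.mods
    return not (a.span[1] < b.span[0] or b.span[1] < a.span[0])


def enumerate_candidates(
    peptides: Sequence[Peptide],
    mods: Sequence[Modification] = (),
    max_per_peptide_mods: int = 2,
) -> list[CrosslinkedSpecies]:
    """All disulfide-crosslinked species over a peptide list.

    Every unordered pair of cysteine-containing peptides (including their
    modified variants) is joined by one S-S bond, once per combination of
    free cysteines; pairs whose spans overlap in the host protein — in
    particular a peptide with itself — are excluded.
    """
    # canonical orientation: the peptide nearer the protein N-terminus first
    cys_peps = sorted(
        (p for p in peptides if p.cys_positions),
        key=lambda p: (p.span if p.span else (0, 0), p.sequence),
    )
    variants: list[list[Peptide]] = [
        expand_mod_variants(p, mods, max_per_peptide_mods) if mods else [p]
        for p in cys_peps
    ]
    out: list[CrosslinkedSpecies] = []
    seen: set[str] = set()
    for i, j in itertools.combinations_with_replacement(range(len(cys_peps)), 2):
        if _spans_overlap(cys_peps[i], cys_peps[j]):
            continue
        for pa, pb in itertools.product(variants[i], variants[j]):
            for ca, cb in itertools.product(
                pa.free_cys_positions(), pb.free_cys_positions()
            ):
                if pa.span is not None:
                    ca_host = pa.span[0] + ca - 1
                else:
                    ca_host = ca
                if pb.span is not None:
                    cb_host = pb.span[0] + cb - 1
                else:
                    cb_host = cb
                sp = CrosslinkedSpecies(pa, pb, (ca_host, cb_host))
                if sp.species_id not in seen:
                    seen.add(sp.species_id)
                    out.append(sp)
    return sorted(out, key=lambda s: s.species_id)


def match_precursors(
    candidates: Sequence[CrosslinkedSpecies],
    peaks: PeakList,
    tol_ppm: float = 10.0,
) -> list[MatchResult]:
    """Match each precursor to the candidate with the smallest |ppm error|.

    The observed neutral mass is ``z·(m/z) − z·proton``; only candidates
    within ``tol_ppm`` qualify and ties are broken by species id.  Precursors
    without a qualifying candidate are omitted.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not candidates or not peaks.precursors:
        return []
    order = np.argsort([c.neutral_mass for c in candidates])
    cand = [candidates[k] for k in order]
    masses = np.array([c.neutral_mass for c in cand])
    results: list[MatchResult] = []
    for idx, prec in enumerate(peaks.precursors):
        obs = prec.neutral_mass
        half = obs * tol_ppm * 1e-6
        lo = np.searchsorted(masses, obs - half, side="left")
        hi = np.searchsorted(masses, obs + half, side="right")
        best: tuple[float, str, CrosslinkedSpecies] | None = None
        for k in range(lo, hi):
            ppm = (obs - masses[k]) / masses[k] * 1e6
            if abs(ppm) > tol_ppm:
                continue
            entry = (abs(ppm), cand[k].species_id, cand[k])
            if best is None or entry[:2] < best[:2]:
                best = entry
        if best is not None:
            _, _, sp = best
            results.append(
                MatchResult(
                    species=sp,
                    observed_mz=prec.mz,
                    charge=prec.charge,
                    ppm_error=(obs - sp.neutral_mass) / sp.neutral_mass * 1e6,
                    precursor_index=idx,
                )
            )
    return results


def annotate_ms2(
    match: MatchResult,
    peaks: PeakList,
    fragment_tol_da: float = 0.05,
) -> MatchResult:
    """Count MS2 peaks within ``fragment_tol_da`` of predicted b/y ions.

    Each predicted ion is matched to its nearest fragment peak; the score is
    ``n_matched − 10 × mean |Da error|`` over the matched ions.  A match
    whose precursor has no MS2 spectrum is returned unchanged.
    """
    frags = peaks.ms2.get(match.precursor_index)
    if not frags:
        return match
    frag_mz = np.sort(np.array([f[0] for f in frags]))
    n_matched = 0
    abs_errors: list[float] = []
    for _, pred in fragment_ions(match.species):
        k = np.searchsorted(frag_mz, pred)
        best = np.inf
        for kk in (k - 1, k):
            if 0 <= kk < len(frag_mz):
                best = min(best, abs(frag_mz[kk] - pred))
        if best <= fragment_tol_da:
            n_matched += 1
            abs_errors.append(best)
    score = float(n_matched - 10.0 * np.mean(abs_errors)) if n_matched else 0.0
    return replace(match, n_fragments_matched=n_matched, score=max(score, 0.0))


@dataclass(frozen=True)
class _MinimalSpecies:
    """Species stub (id + bridged cysteines) for evidence-table workflows."""

    species_id: str
    bridged_cys: tuple[int, int]


def minimal_species(species_id: str, cys_a: int, cys_b: int) -> _MinimalSpecies:
    """A species carrying only what topology inference needs."""
    return _MinimalSpecies(species_id, (cys_a, cys_b))


def _species_bridge(sp: CrosslinkedSpecies) -> tuple[int, int]:
    a, b = sp.bridged_cys
    return (a, b) if a <= b else (b, a)


def infer_topology(
    matches: Iterable[MatchResult | CrosslinkedSpecies],
    protein: ProteinRecord | Sequence[int],
) -> tuple[TopologyCall, BridgeGraph, dict]:
    """Assemble matched species into a cysteine bridge graph and call the
    pairing topology.

    Edge weights count distinct supporting species (sequence + mods), not
    spectra.  A maximum-weight matching is selected greedily by descending
    weight with ties broken by position pair; the call is flagged
    ``ambiguous`` when a skipped edge of equal weight conflicts with a chosen
    one.  Returns (TopologyCall, BridgeGraph, report) where the report lists
    unpaired cysteines and the ambiguity flag.
    """
    cys = tuple(
        protein.cys_positions if isinstance(protein, ProteinRecord) else protein
    )
    cys_set = set(cys)
    support: dict[tuple[int, int], set[str]] = {}
    for m in matches:
        sp = m.species if isinstance(m, MatchResult) else m
        edge = _species_bridge(sp)
        if edge[0] not in cys_set or edge[1] not in cys_set:
            raise ValueError(
                f"bridged positions {edge} are not cysteines of the protein"
            )
        support.setdefault(edge, set()).add(sp.species_id)
    edges = {e: len(ids) for e, ids in support.items()}
    graph = BridgeGraph(cys, edges)

    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    ambiguous = False
    ranked = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))
    for (a, b), w in ranked:
        if a in used or b in used:
            # conflicting edge; ambiguous if it ties a chosen edge's weight
            for (ca, cb) in chosen:
                if {a, b} & {ca, cb} and edges[(ca, cb)] == w:
                    ambiguous = True
            continue
        chosen.append((a, b))
        used.update((a, b))
    call = classify_pairing([Bridge(a, b) for a, b in chosen], cys)
    unpaired = tuple(sorted(cys_set - used))
    report = {"unpaired_cysteines": unpaired, "ambiguous": ambiguous}
    return call, graph, report
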