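"""Seeded generators for every input the pipeline consumes.

Three generators emulate the study's data-producing steps:

* :func:`gen_protein` — a random protein with a planted six-cysteine
  disulfide topology (adjacent, interlocked, or a random matching);
* :func:`gen_peaklist` — an in-silico tryptic/chymotryptic digest of such a
  protein, with every planted crosslinked species emitted as precursor peaks
  at charges 1-4 under multiplicative ppm-scale Gaussian mass error, buried
  in uniformly distributed decoy peaks; a ground-truth ledger records every
  peak;
* :func:`gen_titration` — saturation or competition fluorescence titrations
  from the one-site binding model (ligand range 2-16 μM) with proportional
  Gaussian noise.

A single integer seed governs all randomness; identical configurations
reproduce identical outputs.  Writers for FASTA, MGF, TSV and CSV round-trip
through the package's readers without loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import TitrationCurve
from .digestion import CHYMOTRYPSIN, TRYPSIN, DigestParams, sequential_digest
from .masscalc import CrosslinkedSpecies, mz
from .seqcore import Bridge, ProteinRecord, TopologyCall, classify_pairing
from .ssmatch import PeakList, Precursor

__all__ = [
    "GENERATOR_VERSION",
    "SimConfig",
    "GenerationError",
    "gen_protein",
    "gen_peaklist",
    "gen_titration",
    "simulate_experiment",
    "write_fasta",
    "write_peaklist_tsv",
    "write_peaklist_mgf",
    "write_titration_csv",
    "read_titration_csv",
]

GENERATOR_VERSION = "1"

_NON_CYS_RESIDUES = np.array(list("GASPVTLINDQKEMHFRYW"))


class GenerationError(RuntimeError):
    """A planted structure could not be realised (e.g. cysteines too close)."""


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_cys: int = 6
    protein_length: int = 180
    topology_pattern: str = "adjacent"  # adjacent | interlocked | random
    ppm_sigma: float = 2.0
    decoy_ratio: float = 5.0
    species_per_bridge: int = 2
    titration_noise: float = 0.01
    max_missed_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.n_cys <= 0 or self.n_cys % 2:
            raise ValueError("n_cys must be a positive even integer")
        if min(self.protein_length, self.species_per_bridge) <= 0:
            raise ValueError("protein_length and species_per_bridge must be "
                             "positive")
        if self.ppm_sigma < 0 or self.decoy_ratio < 0 or self.titration_noise < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.topology_pattern not in ("adjacent", "interlocked", "random"):
            raise ValueError(f"unknown topology pattern "
                             f"{self.topology_pattern!r}")


def _planted_matching(n: int, pattern: str, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pairing of cysteine ordinals (1-based) per topology pattern."""
    if pattern == "adjacent":
        # C1-Cn, then successive adjacent pairs: C2-C3, C4-C5, ...
        return [(1, n)] + [(i, i + 1) for i in range(2, n, 2)]
    if pattern == "interlocked":
        if n != 6:
            raise ValueError("the interlocked motif is defined for 6 cysteines")
        return [(1, 3), (2, 5), (4, 6)]
    ordinals = rng.permutation(n) + 1
    return [tuple(sorted((int(ordinals[2 * k]), int(ordinals[2 * k + 1]))))
            for k in range(n // 2)]


def gen_protein(cfg: SimConfig) -> tuple[ProteinRecord, TopologyCall]:
    """A random protein with exactly ``n_cys`` cysteines and a planted
    disulfide matching.

    Cysteines are placed at well-separated positions so proteolysis can
    isolate them in distinct peptides; the rest of the sequence is uniform
    over the other 19 residues.
    """
    if cfg.protein_length <= 3 * cfg.n_cys:
        raise GenerationError(
            f"protein_length {cfg.protein_length} too short for "
            f"{cfg.n_cys} well-separated cysteines"
        )
    rng = np.random.default_rng(cfg.seed)
    L, n = cfg.protein_length, cfg.n_cys
    gap = min(8, (L - n) // n)
    # sample strictly increasing positions with a minimum inter-cysteine gap
    slack = L - n - (n - 1) * gap
    offsets = np.sort(rng.choice(slack + 1, size=n, replace=True))
    positions = [int(offsets[i] + i * (gap + 1) + 1) for i in range(n)]
    seq = rng.choice(_NON_CYS_RESIDUES, size=L)
    for pos in positions:
        seq[pos - 1] = "C"
    record = ProteinRecord(
        id=f"synthetic_{cfg.topology_pattern}_{cfg.seed}",
        sequence="".join(seq),
    )
    ordinal_pairs = _planted_matching(n, cfg.topology_pattern, rng)
    bridges = [
        Bridge(positions[i - 1], positions[j - 1]) for i, j in ordinal_pairs
    ]
    return record, classify_pairing(bridges, positions)


def gen_peaklist(
    protein: ProteinRecord,
    topology: TopologyCall,
    cfg: SimConfig,
) -> tuple[PeakList, pd.DataFrame]:
    """Precursor peaks for the planted crosslinked species plus decoys.

    The protein is digested in silico (trypsin then chymotrypsin);
    ``species_per_bridge`` peptide pairs are drawn per planted bridge and
    emitted at charges 1-4 with multiplicative mass error
    ``~N(0, ppm_sigma·1e-6)``; ``decoy_ratio`` times as many uniform decoy
    peaks are added.  The ledger DataFrame records every peak (planted and
    decoy) with its generating species and theoretical m/z.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    params = DigestParams(
        max_missed_cleavages=cfg.max_missed_cleavages, min_length=2,
        max_length=30,
    )
    peptides = sequential_digest(protein.sequence, TRYPSIN, CHYMOTRYPSIN, params)
    # plant species whose peptides carry exactly one cysteine each, the form
    # observed disulfide-bridged species take; multi-cysteine peptides stay
    # in the search space as candidates but are not planted
    by_cys: dict[int, list] = {}
    for pep in peptides:
        host_cys = pep.cys_protein_positions()
        if len(host_cys) == 1:
            by_cys.setdefault(host_cys[0], []).append(pep)

    species: list[CrosslinkedSpecies] = []
    for bridge in sorted(topology.bridges):
        pa_list = by_cys.get(bridge.pos_a, [])
        pb_list = by_cys.get(bridge.pos_b, [])
        pairs = [
            (pa, pb)
            for pa in pa_list
            for pb in pb_list
            if pa.span[1] < pb.span[0] or pb.span[1] < pa.span[0]
        ]
        if len(pairs) < cfg.species_per_bridge:
            raise GenerationError(
                f"bridge {bridge.pos_a}-{bridge.pos_b}: only {len(pairs)} "
                f"generatable species (cysteines too close to a terminus or "
                f"to each other); regenerate the protein"
            )
        take = rng.choice(len(pairs), size=cfg.species_per_bridge, replace=False)
        for k in sorted(take):
            pa, pb = pairs[k]
            species.append(
                CrosslinkedSpecies(pa, pb, (bridge.pos_a, bridge.pos_b))
            )

    rows = []
    for sp in species:
        for z in range(1, 5):
            theor = mz(sp.neutral_mass, z)
            obs = theor * (1.0 + rng.normal(0.0, cfg.ppm_sigma * 1e-6))
            rows.append(
                {
                    "species_id": sp.species_id,
                    "cys_a": sp.bridged_cys[0],
                    "cys_b": sp.bridged_cys[1],
                    "z": z,
                    "mz_theor": theor,
                    "mz_obs": obs,
                    "intensity": float(rng.lognormal(10.0, 1.0)),
                    "decoy": False,
                }
            )
    n_decoys = int(round(cfg.decoy_ratio * len(rows)))
    if rows:
        lo = min(r["mz_obs"] for r in rows) * 0.9
        hi = max(r["mz_obs"] for r in rows) * 1.1
    else:  # degenerate config with no planted species
        lo, hi = 350.0, 1350.0
    for _ in range(n_decoys):
        rows.append(
            {
                "species_id": "",
                "cys_a": -1,
                "cys_b": -1,
                "z": int(rng.integers(1, 5)),
                "mz_theor": np.nan,
                "mz_obs": float(rng.uniform(lo, hi)),
                "intensity": float(rng.lognormal(9.0, 1.0)),
                "decoy": True,
            }
        )
    order = rng.permutation(len(rows))
    ledger = pd.DataFrame([rows[k] for k in order])
    ledger.insert(0, "generator_version", GENERATOR_VERSION)
    precursors = tuple(
        Precursor(r["mz_obs"], int(r["z"]), r["intensity"])
        for r in ledger.to_dict("records")
    )
    return PeakList(precursors), ledger


def gen_titration(
    kind: str,
    truth: dict,
    cfg: SimConfig,
    concentrations: Sequence[float] = (2, 4, 6, 8, 10, 12, 14, 16),
) -> tuple[TitrationCurve, dict]:
    """A noisy titration curve from the one-site binding model.

    ``kind="saturation"`` needs ``truth`` keys ``kd`` (μM) and optionally
    ``f_max``; ``kind="competition"`` needs ``kd``, ``probe_conc``,
    ``k_probe`` and optionally ``f0`` (the planted IC50 is derived as
    ``kd · (1 + probe_conc/k_probe)``).  Signals carry proportional Gaussian
    noise of fraction ``cfg.titration_noise``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    L = np.asarray(concentrations, dtype=float)
    if kind == "saturation":
        kd = float(truth["kd"])
        f_max = float(truth.get("f_max", 100.0))
        if kd <= 0 or f_max <= 0:
            raise ValueError("truth parameters must be positive")
        clean = f_max * L / (kd + L)
        record = {"kind": kind, "kd": kd, "f_max": f_max}
    elif kind == "competition":
        kd = float(truth["kd"])
        probe = float(truth.get("probe_conc", 2.0))
        k_probe = float(truth["k_probe"])
        f0 = float(truth.get("f0", 100.0))
        if min(kd, probe, k_probe, f0) <= 0:
            raise ValueError("truth parameters must be positive")
        ic50 = kd * (1.0 + probe / k_probe)
        clean = f0 / (1.0 + L / ic50)
        record = {
            "kind": kind, "kd": kd, "probe_conc": probe,
            "k_probe": k_probe, "f0": f0, "ic50": ic50,
        }
    else:
        raise ValueError(f"unknown titration kind {kind!r}")
    noisy = clean * (1.0 + cfg.titration_noise * rng.standard_normal(L.size))
    curve = TitrationCurve(tuple(L.tolist()), tuple(noisy.tolist()))
    return curve, record


def simulate_experiment(
    cfg: SimConfig, max_attempts: int = 20
) -> tuple[ProteinRecord, TopologyCall, PeakList, pd.DataFrame]:
    """gen_protein + gen_peaklist with regeneration on infeasible proteins.

    When a planted bridge admits fewer than ``species_per_bridge`` species,
    a warning is issued and the protein is regenerated from a derived seed.
    """
    last: GenerationError | None = None
    for attempt in range(max_attempts):
        sub = replace(cfg, seed=(cfg.seed + 99991 * attempt) % (2**31 - 1))
        protein, topology = gen_protein(sub)
        try:
            peaks, ledger = gen_peaklist(protein, topology, sub)
        except GenerationError as exc:
            warnings.warn(str(exc), stacklevel=2)
            last = exc
            continue
        return protein, topology, peaks, ledger
    raise GenerationError(
        f"no feasible protein after {max_attempts} attempts: {last}"
    )


# ---------------------------------------------------------------------------
# plain-text writers (full float precision, so reads reproduce writes exactly)


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_peaklist_tsv(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# obptools synthetic peak list v{GENERATOR_VERSION}\n")
        fh.write("mz\tz\tintensity\n")
        for p in peaks.precursors:
            fh.write(f"{p.mz!r}\t{p.charge}\t{p.intensity!r}\n")


def write_peaklist_mgf(peaks: PeakList, path: str | Path) -> None:
    """Write precursors (and any MS2 fragments) as a standard MGF file."""
    with open(path, "w") as fh:
        for idx, p in enumerate(peaks.precursors):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=precursor_{idx}\n")
            fh.write(f"PEPMASS={p.mz!r}\n")
            fh.write(f"CHARGE={p.charge}+\n")
            for fmz, fint in peaks.ms2.get(idx, ()):
                fh.write(f"{fmz!r} {fint!r}\n")
            fh.write("END IONS\n")


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("conc_uM,signal\n")
        for c, s in zip(curve.ligand_conc, curve.signal):
            fh.write(f"{c!r},{s!r}\n")


def read_titration_csv(path: str | Path, protein_conc: float = 2.0) -> TitrationCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return TitrationCurve(
        tuple(float(x) for x in df["conc_uM"]),
        tuple(float(x) for x in df["signal"]),
        protein_conc=protein_conc,
    )
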