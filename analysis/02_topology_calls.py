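"""Infer the disulfide topology of each of the four proteins from the
bundled bridged-species evidence.

Writes results/topology_calls.tsv with the ordinal pairing label, motif
name, per-bridge evidence weights, and unpaired cysteines per protein.
"""

from pathlib import Path

import pandas as pd

from obptools import datasets
from obptools.ssmatch import infer_topology

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for protein, sub in datasets.load_bridged_species().groupby("protein"):
        species = [datasets.species_from_row(r) for _, r in sub.iterrows()]
        call, graph, report = infer_topology(
            species, datasets.CYS_POSITIONS[protein]
        )
        weights = ";".join(f"{a}-{b}:{w}" for (a, b), w in
                           sorted(graph.edges.items()))
        rows.append({
            "protein": protein,
            "n_species": len(species),
            "ordinal_label": call.ordinal_label,
            "pattern": call.pattern,
            "bridges": ";".join(f"{b.pos_a}-{b.pos_b}"
                                for b in sorted(call.bridges)),
            "edge_weights": weights,
            "unpaired": len(report["unpaired_cysteines"]),
            "ambiguous": report["ambiguous"],
        })
        print(f"{protein}: {call.ordinal_label} [{call.pattern}], "
              f"{len(species)} species, "
              f"{len(report['unpaired_cysteines'])} unpaired")
    pd.DataFrame(rows).to_csv(OUT / "topology_calls.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
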