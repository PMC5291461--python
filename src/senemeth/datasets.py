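"""A curated example miRNA-target network from replicative senescence.

Seven miRNAs whose expression falls during replicative senescence of human
diploid fibroblasts alongside promoter hypermethylation, and the 27
up-regulated genes each targeted by at least two of them (with the genes'
linear expression fold changes, senescent versus proliferating).  The network
is small enough to serve both as a worked example and as a regression fixture
for the triad filter.
"""

from __future__ import annotations

import pandas as pd

#: Mature names of the seven promoter-hypermethylated, down-regulated miRNAs.
SENESCENCE_MIRNAS = (
    "hsa-miR-7-5p",
    "hsa-miR-17-5p",
    "hsa-miR-25-3p",
    "hsa-miR-130b-3p",
    "hsa-miR-193a-5p",
    "hsa-miR-335-5p",
    "hsa-miR-505-3p",
)

#: gene symbol -> (fold change, supporting miRNAs)
SENESCENCE_TRIAD_GENES: dict[str, tuple[float, tuple[str, ...]]] = {
    "EIF4EBP2": (3.0, ("hsa-miR-7-5p", "hsa-miR-193a-5p", "hsa-miR-335-5p")),
    "HECW2": (4.2, ("hsa-miR-7-5p", "hsa-miR-25-3p", "hsa-miR-505-3p")),
    "CADM1": (8.2, ("hsa-miR-7-5p", "hsa-miR-505-3p")),
    "CNNM2": (2.9, ("hsa-miR-335-5p", "hsa-miR-505-3p")),
    "CPEB2": (2.6, ("hsa-miR-7-5p", "hsa-miR-505-3p")),
    "CRY2": (2.2, ("hsa-miR-7-5p", "hsa-miR-17-5p")),
    "DAAM1": (2.5, ("hsa-miR-130b-3p", "hsa-miR-335-5p")),
    "DGKH": (2.5, ("hsa-miR-130b-3p", "hsa-miR-505-3p")),
    "DOK6": (2.2, ("hsa-miR-17-5p", "hsa-miR-335-5p")),
    "EGR2": (2.8, ("hsa-miR-17-5p", "hsa-miR-25-3p")),
    "FAM134C": (2.2, ("hsa-miR-17-5p", "hsa-miR-335-5p")),
    "GRIN2A": (2.0, ("hsa-miR-7-5p", "hsa-miR-130b-3p")),
    "HPCAL4": (7.6, ("hsa-miR-7-5p", "hsa-miR-335-5p")),
    "IL6ST": (2.2, ("hsa-miR-130b-3p", "hsa-miR-505-3p")),
    "KLHL28": (2.4, ("hsa-miR-7-5p", "hsa-miR-335-5p")),
    "MEF2D": (2.7, ("hsa-miR-335-5p", "hsa-miR-505-3p")),
    "MYO1D": (5.9, ("hsa-miR-193a-5p", "hsa-miR-335-5p")),
    "NR4A3": (2.1, ("hsa-miR-7-5p", "hsa-miR-335-5p")),
    "OXR1": (2.9, ("hsa-miR-7-5p", "hsa-miR-17-5p")),
    "PGM2L1": (4.8, ("hsa-miR-17-5p", "hsa-miR-130b-3p")),
    "PIP4K2C": (2.1, ("hsa-miR-25-3p", "hsa-miR-505-3p")),
    "PPARGC1B": (2.6, ("hsa-miR-7-5p", "hsa-miR-505-3p")),
    "RAB11FIP5": (2.8, ("hsa-miR-7-5p", "hsa-miR-17-5p")),
    "RNF141": (2.4, ("hsa-miR-7-5p", "hsa-miR-335-5p")),
    "SEMA6D": (5.9, ("hsa-miR-7-5p", "hsa-miR-193a-5p")),
    "ZDHHC8": (5.2, ("hsa-miR-17-5p", "hsa-miR-335-5p")),
    "ZMAT3": (3.4, ("hsa-miR-7-5p", "hsa-miR-130b-3p")),
}


def senescence_triad_example() -> dict[str, pd.DataFrame]:
    """The example network as the three tables the triad filter consumes.

    Returns ``{"concordance", "targets", "gene_fc"}``: a concordance table
    marking all seven miRNAs hyper_down, the (mirna_id, gene_id) target pairs,
    and the gene fold-change table.
    """
    concordance = pd.DataFrame({
        "mirna_symbol": list(SENESCENCE_MIRNAS),
        "concordance": "hyper_down",
    }, index=pd.Index(SENESCENCE_MIRNAS, name="mirna_id"))
    target_rows = [(m, g) for g, (_, mirnas) in SENESCENCE_TRIAD_GENES.items()
                   for m in mirnas]
    targets = pd.DataFrame(target_rows, columns=["mirna_id", "gene_id"])
    gene_fc = pd.DataFrame(
        {"fc": [fc for fc, _ in SENESCENCE_TRIAD_GENES.values()]},
        index=pd.Index(SENESCENCE_TRIAD_GENES.keys(), name="gene_id"))
    return {"concordance": concordance, "targets": targets, "gene_fc": gene_fc}
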