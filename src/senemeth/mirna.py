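"""miRNA promoter-methylation / expression concordance and the triad filter.

The axis has three steps:

1. **select_mirna_probes** — methylation-array probes annotated to a miRNA
   host entry (gene symbols matching the MIR naming pattern: "MIR" followed by
   a digit or "LET", so MIR7-1 and MIRLET7A1 match but MIRROR1 does not),
   optionally restricted to promoter features (TSS1500/TSS200 by default).
2. **call_concordance** — a miRNA is ``hyper_down`` when at least one of its
   promoter probes is hypermethylated (Δβ ≥ 0.2) and its expression falls
   ≥ 1.5-fold; ``hypo_up`` is the mirror; both directions are evaluated.
   Manifest symbols (MIR7-1) are harmonized to mature miRNA array names
   (hsa-miR-7-5p) through a user-supplied alias table.
3. **triad_filter** — a target gene passes when it is hit by at least
   ``min_mirnas`` concordant miRNAs of one direction and its own expression
   change is opposite in direction past the gene fold-change cutoff (a gene
   repressed by hypermethylation-silenced miRNAs should be de-repressed, i.e.
   up-regulated).  Target predictions are an input table, never computed here.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .array_io import ProbeAnnotation
from .errors import ValidationError

logger = logging.getLogger(__name__)

CONC_HYPER_DOWN = "hyper_down"
CONC_HYPO_UP = "hypo_up"
CONC_NONE = "none"
CONC_UNEVALUABLE = "unevaluable"

#: Symbols counting as miRNA entries: MIR then a digit, or the let-7 family.
MIR_PATTERN = re.compile(r"^MIR(?:\d|LET)")

PROMOTER_FEATURES = ("TSS1500", "TSS200")


def select_mirna_probes(annotation: ProbeAnnotation,
                        features: tuple[str, ...] | None = PROMOTER_FEATURES
                        ) -> pd.DataFrame:
    """Probe -> miRNA symbol map from MIR-matching gene annotations.

    When *features* is given, only probes whose MIR annotation carries one of
    those gene features (promoter probes) are returned.  One row per
    (probe_id, mirna_symbol) pair.
    """
    gf = annotation.gene_features
    is_mir = gf["gene"].map(lambda g: bool(MIR_PATTERN.match(g)))
    sel = gf[is_mir]
    if features is not None:
        sel = sel[sel["feature"].isin(features)]
    out = sel[["probe_id", "gene"]].drop_duplicates().rename(
        columns={"gene": "mirna_symbol"})
    logger.info("selected %d miRNA promoter probe annotations (%d miRNAs)",
                len(out), out["mirna_symbol"].nunique())
    return out.reset_index(drop=True)


def normalize_mirna(raw: pd.DataFrame, percentile: float = 90.0) -> pd.DataFrame:
    """log2 then per-sample percentile shift (default: 90-percentile shift).

    After normalization the *percentile*-th percentile of every sample is 0;
    the transform is invariant to per-sample rescaling of raw intensities.
    """
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ValidationError("empty miRNA expression table")
    if (raw.to_numpy(dtype=float) <= 0).any():
        raise ValidationError("miRNA intensities must be positive")
    from .expression import percentile_shift
    return percentile_shift(np.log2(raw), percentile)


def mirna_fold_changes(normalized: pd.DataFrame, test_samples: list[str],
                       control_samples: list[str]) -> pd.Series:
    """Linear-scale fold change per miRNA: 2^(mean log2 test − mean log2 control)."""
    if not test_samples or not control_samples:
        raise ValidationError("need at least one test and one control sample")
    log2fc = normalized[list(test_samples)].mean(axis=1) \
        - normalized[list(control_samples)].mean(axis=1)
    return np.exp2(log2fc).rename("fc")


def call_concordance(mirna_probes: pd.DataFrame, meth_calls: pd.DataFrame,
                     mirna_fc: pd.Series, alias: pd.Series | None = None,
                     dbeta: float = 0.2, fc_cut: float = 1.5) -> pd.DataFrame:
    """Concordance call per miRNA from promoter methylation and expression.

    *mirna_probes* is the (probe_id, mirna_symbol) map; *meth_calls* the
    differential-methylation table (indexed by probe_id, column delta_beta);
    *mirna_fc* linear fold changes indexed by mature miRNA name; *alias* maps
    manifest symbol -> mature name (identity when omitted).  miRNAs whose
    mature name is absent from *mirna_fc* are reported ``unevaluable``.
    """
    merged = mirna_probes.merge(meth_calls, left_on="probe_id",
                                right_index=True, how="inner")
    rows = []
    for symbol, grp in merged.groupby("mirna_symbol"):
        mature = alias.get(symbol, symbol) if alias is not None else symbol
        tol = 1e-12  # inclusive cutoffs despite float subtraction error
        has_hyper = bool((grp["delta_beta"] >= dbeta - tol).any())
        has_hypo = bool((grp["delta_beta"] <= -dbeta + tol).any())
        max_db = float(grp["delta_beta"].max())
        min_db = float(grp["delta_beta"].min())
        if mature not in mirna_fc.index:
            rows.append((symbol, mature, len(grp), max_db, min_db, np.nan,
                         CONC_UNEVALUABLE))
            continue
        fc = float(mirna_fc.loc[mature])
        if has_hyper and fc <= 1.0 / fc_cut:
            conc = CONC_HYPER_DOWN
        elif has_hypo and fc >= fc_cut:
            conc = CONC_HYPO_UP
        else:
            conc = CONC_NONE
        rows.append((symbol, mature, len(grp), max_db, min_db, fc, conc))
    return pd.DataFrame(rows, columns=[
        "mirna_symbol", "mirna_id", "n_promoter_probes", "max_delta_beta",
        "min_delta_beta", "fc", "concordance"]).set_index("mirna_id")


def triad_filter(concordance: pd.DataFrame, targets: pd.DataFrame,
                 gene_fold_changes: pd.DataFrame, min_mirnas: int = 2,
                 gene_fc: float = 2.0) -> pd.DataFrame:
    """Genes targeted by >= *min_mirnas* concordant miRNAs with opposite regulation.

    *targets* lists (mirna_id, gene_id) predicted-target pairs;
    *gene_fold_changes* is indexed by gene_id with a linear ``fc`` column.  A
    gene supported by hyper_down miRNAs must itself be up-regulated
    (fc ≥ *gene_fc*); a gene supported by hypo_up miRNAs down-regulated
    (fc ≤ 1/*gene_fc*).  Returns one row per passing gene with its fold change,
    direction and sorted supporting miRNAs.
    """
    rows = []
    for direction, wanted_up in ((CONC_HYPER_DOWN, True), (CONC_HYPO_UP, False)):
        conc_ids = set(concordance.index[concordance["concordance"] == direction])
        if not conc_ids:
            continue
        hits = targets[targets["mirna_id"].isin(conc_ids)]
        for gene, grp in hits.groupby("gene_id"):
            support = sorted(grp["mirna_id"].unique())
            if len(support) < min_mirnas:
                continue
            if gene not in gene_fold_changes.index:
                continue
            fc = float(gene_fold_changes.loc[gene, "fc"])
            if wanted_up and fc < gene_fc:
                continue
            if not wanted_up and fc > 1.0 / gene_fc:
                continue
            rows.append((gene, fc, direction, len(support), ";".join(support)))
    out = pd.DataFrame(rows, columns=[
        "gene_id", "fc", "mirna_direction", "n_mirnas", "supporting_mirnas"])
    return out.sort_values("gene_id").set_index("gene_id")
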