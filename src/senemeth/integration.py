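"""Methylation-expression integration via nearest-TSS pairing.

Each CpG probe is paired with the single nearest gene TSS on its chromosome,
provided the unsigned distance |cpg_pos − tss| does not exceed a window
(default 8 kb); more distant probes stay unmapped.  Equidistant TSS candidates
are broken deterministically towards the lexicographically smallest gene_id,
so the mapping is invariant to gene-table row order.  Isoform transcripts
compete independently; the winning accession is reported.

A mapped pair gets a joint call from its methylation and expression changes:
``hyper_down`` (Δβ ≥ 0.2 and fc ≤ 0.5) or ``hypo_up`` (Δβ ≤ −0.2 and fc ≥ 2)
flag CpG sites whose methylation change is concordant with repression /
activation of the nearest gene; everything else is ``none``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

JOINT_HYPER_DOWN = "hyper_down"
JOINT_HYPO_UP = "hypo_up"
JOINT_NONE = "none"


def map_probes_to_nearest_tss(probes: pd.DataFrame, genes: pd.DataFrame,
                              window: int = 8000) -> pd.DataFrame:
    """Map each probe to its nearest TSS within *window* bp.

    *probes* is indexed by probe_id with columns chrom and pos; *genes* needs
    gene_id, chrom and tss.  Returns a table indexed by probe_id with columns
    gene_id, tss, distance (unsigned) and signed_distance (cpg_pos − tss);
    unmapped probes are absent from it.  Ties on distance go to the smallest
    gene_id.
    """
    results = []
    gene_groups = {c: g for c, g in genes.groupby("chrom")}
    for chrom, psub in probes.groupby("chrom"):
        gsub = gene_groups.get(chrom)
        if gsub is None:
            continue
        # sort by (tss, gene_id) so equal-position ties resolve to min gene_id
        gsub = gsub.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        gids = gsub["gene_id"].to_numpy()
        pos = psub["pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(tss, pos)
        for pid, p, i in zip(psub.index, pos, idx):
            # candidate TSSs flank the insertion point; scan outwards over ties
            best_d, best_gene, best_tss = None, None, None
            for j in (i - 1, i):
                if 0 <= j < len(tss):
                    d = abs(int(p) - int(tss[j]))
                    if best_d is None or d < best_d:
                        best_d, best_gene, best_tss = d, gids[j], int(tss[j])
            if best_d is None or best_d > window:
                continue
            # resolve ties at exactly best_d among all TSS at distance best_d
            for j in range(i - 1, -1, -1):
                if abs(int(p) - int(tss[j])) != best_d:
                    break
                if gids[j] < best_gene:
                    best_gene, best_tss = gids[j], int(tss[j])
            for j in range(i, len(tss)):
                if abs(int(p) - int(tss[j])) != best_d:
                    break
                if gids[j] < best_gene:
                    best_gene, best_tss = gids[j], int(tss[j])
            results.append((pid, best_gene, best_tss, best_d, int(p) - best_tss))
    out = pd.DataFrame(results, columns=[
        "probe_id", "gene_id", "tss", "distance", "signed_distance"])
    logger.info("nearest-TSS mapping: %d/%d probes within %d bp",
                len(out), len(probes), window)
    return out.set_index("probe_id")


def joint_call(mapped: pd.DataFrame, meth_calls: pd.DataFrame,
               fold_changes: pd.DataFrame, dbeta: float = 0.2,
               fc: float = 2.0) -> pd.DataFrame:
    """Join methylation calls with the nearest gene's expression fold change.

    Returns one row per mapped probe that has a methylation call, with columns
    gene_id, distance, delta_beta, fc and joint_call.  Pairs whose gene lacks
    an expression value keep joint_call = "none" (fc is NaN, logged).
    """
    pairs = mapped.join(meth_calls, how="inner")
    pairs = pairs.merge(fold_changes[["fc"]], left_on="gene_id",
                        right_index=True, how="left")
    missing = pairs["fc"].isna()
    if missing.any():
        logger.info("%d pair(s) lack expression data; joint_call=none",
                    int(missing.sum()))
    jc = np.full(len(pairs), JOINT_NONE, dtype=object)
    tol = 1e-12  # inclusive thresholds despite float subtraction error
    with np.errstate(invalid="ignore"):
        hyper_down = (pairs["delta_beta"] >= dbeta - tol) & \
            (pairs["fc"] <= 1.0 / fc + tol)
        hypo_up = (pairs["delta_beta"] <= -dbeta + tol) & \
            (pairs["fc"] >= fc - tol)
    jc[hyper_down.fillna(False).to_numpy()] = JOINT_HYPER_DOWN
    jc[hypo_up.fillna(False).to_numpy()] = JOINT_HYPO_UP
    pairs["joint_call"] = jc
    return pairs[["gene_id", "distance", "signed_distance", "delta_beta",
                  "fc", "joint_call"]]


def deduplicated_gene_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Gene-level view of concordant pairs: one row per gene with its best probe.

    The per-CpG joint-call counts deliberately count sites, not genes; this
    companion summary lists each gene once with the number of supporting CpG
    sites and the largest-|Δβ| probe.
    """
    conc = pairs[pairs["joint_call"] != JOINT_NONE].copy()
    if conc.empty:
        return pd.DataFrame(columns=["joint_call", "n_sites", "max_abs_delta_beta", "fc"])
    conc["abs_db"] = conc["delta_beta"].abs()
    grouped = conc.groupby(["gene_id", "joint_call"])
    out = grouped.agg(n_sites=("abs_db", "size"),
                      max_abs_delta_beta=("abs_db", "max"),
                      fc=("fc", "first")).reset_index().set_index("gene_id")
    return out


def distance_distribution(pairs: pd.DataFrame, promoter_classes: pd.DataFrame,
                          bin_width: int = 250, window: int = 8000
                          ) -> dict[str, pd.DataFrame | pd.Series]:
    """Histogram of probe-to-TSS distances per promoter class.

    *pairs* needs columns gene_id and distance; *promoter_classes* is indexed
    by gene_id with a promoter_class column.  Returns ``{"histogram": table
    (bins x classes), "within_1kb": per-class counts of pairs at distance
    ≤ 1000 bp}``.
    """
    joined = pairs.merge(promoter_classes[["promoter_class"]],
                         left_on="gene_id", right_index=True, how="inner")
    edges = np.arange(0, window + bin_width, bin_width)
    classes = ["CGI", "nonCGI"]
    hist = {}
    for cls in classes:
        d = joined.loc[joined["promoter_class"] == cls, "distance"].to_numpy()
        counts, _ = np.histogram(d, bins=edges)
        hist[cls] = counts
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    histogram = pd.DataFrame(hist, index=pd.Index(labels, name="distance_bin"))
    within_1kb = joined[joined["distance"] <= 1000].groupby("promoter_class") \
        .size().reindex(classes).fillna(0).astype(int)
    return {"histogram": histogram, "within_1kb": within_1kb}


def functional_group_ratios(gene_to_group: pd.Series,
                            gene_sets: dict[tuple[str, str], set]) -> pd.DataFrame:
    """Cross-tabulate gene sets against functional groups.

    *gene_to_group* maps gene -> functional group label (a user-supplied map,
    e.g. digested GO-term clustering output); genes absent from it count as
    "others".  *gene_sets* is keyed by (subcategory, direction) with sets of
    gene ids.  Returns a long table with count and fraction per
    (subcategory, direction, group); empty sets yield no rows.
    """
    rows = []
    for (subcat, direction), genes in sorted(gene_sets.items()):
        if not genes:
            continue
        groups = pd.Series(sorted(genes)).map(gene_to_group).fillna("others")
        counts = groups.value_counts()
        for group, n in counts.items():
            rows.append((subcat, direction, group, int(n), n / len(genes)))
    return pd.DataFrame(rows, columns=[
        "subcategory", "direction", "group", "count", "fraction"])


def conservation_check(pairs: pd.DataFrame, mapped: pd.DataFrame,
                       n_input_probes: int) -> dict[str, int]:
    """Bookkeeping counts used by the reporting layer and the test suite."""
    joint_counts = pairs["joint_call"].value_counts()
    return {
        "input_probes": int(n_input_probes),
        "mapped": int(len(mapped)),
        "unmapped": int(n_input_probes - len(mapped)),
        "hyper_down": int(joint_counts.get(JOINT_HYPER_DOWN, 0)),
        "hypo_up": int(joint_counts.get(JOINT_HYPO_UP, 0)),
        "joint_none": int(joint_counts.get(JOINT_NONE, 0)),
    }
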