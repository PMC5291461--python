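"""Expression-array normalization, fold-change calling and sample clustering.

The processing chain mirrors a standard one-colour microarray workflow:

1. low-signal cutoff — raw intensities below a floor (default 1.0) are
   replaced by the floor;
2. log2 transformation;
3. global percentile-shift normalization — each sample's 75th percentile
   (linear interpolation between order statistics) is subtracted, so the 75th
   percentile of every normalized sample is exactly 0;
4. probe → gene aggregation by the mean of log2 values over probes sharing a
   RefSeq ID;
5. fold-change calling per senescence contrast: fc = 2^(mean log2 test − mean
   log2 control); fc ≥ 2 is "up", fc ≤ 0.5 is "down" (inclusive bounds).

Because fold change is computed in log2 space, it equals a ratio of geometric
means and is invariant to any common per-sample rescaling of raw intensities
(absorbed by the percentile shift).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NONE = "none"


def normalize_expression(raw: pd.DataFrame, low_cutoff: float = 1.0,
                         percentile: float = 75.0) -> pd.DataFrame:
    """Low-signal replacement, log2, then per-sample percentile shift.

    Parameters
    ----------
    raw : DataFrame
        Probes x samples intensities (must be positive after replacement).
    low_cutoff : float
        Intensities below this value are replaced by it before the log.
    percentile : float
        The per-sample percentile subtracted after log2 (default 75).

    Returns a probes x samples table of normalized log2 intensities whose
    per-sample *percentile*-th percentile is 0.
    """
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ValidationError("empty expression table")
    clipped = raw.clip(lower=low_cutoff)
    return percentile_shift(np.log2(clipped), percentile)


def percentile_shift(logged: pd.DataFrame, percentile: float) -> pd.DataFrame:
    """Subtract each sample's percentile (linear interpolation); idempotent."""
    shift = logged.apply(lambda col: np.percentile(col.dropna(), percentile))
    return logged.sub(shift, axis=1)


def aggregate_probes_to_genes(normalized: pd.DataFrame,
                              probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe rows to one row per gene by the mean of log2 values.

    *probe_to_gene* maps probe id -> RefSeq gene id.  Probes absent from the
    map are dropped (logged); single-probe genes pass through unchanged.
    """
    genes = probe_to_gene.reindex(normalized.index)
    unmapped = genes.isna()
    if unmapped.any():
        logger.info("dropping %d probe(s) with no gene mapping", int(unmapped.sum()))
    kept = normalized.loc[~unmapped]
    return kept.groupby(genes.loc[~unmapped]).mean().rename_axis("gene_id")


def call_fold_changes(gene_table: pd.DataFrame, test_samples: list[str],
                      control_samples: list[str], up_fc: float = 2.0,
                      go_fc: float = 3.0, contrast: str = "contrast") -> pd.DataFrame:
    """Fold change and up/down call for one senescence-versus-control contrast.

    fc = 2^(mean log2 over test − mean log2 over control).  A gene is called
    "up" when fc ≥ *up_fc* and "down" when fc ≤ 1/*up_fc* (both inclusive).
    ``go_set`` additionally marks the genes past the stricter *go_fc* cutoff
    used for functional-category summaries.  Genes with all-missing values in
    either group are omitted (logged).
    """
    if not test_samples or not control_samples:
        raise ValidationError("need at least one test and one control sample")
    test_mean = gene_table[list(test_samples)].mean(axis=1)
    ctrl_mean = gene_table[list(control_samples)].mean(axis=1)
    ok = test_mean.notna() & ctrl_mean.notna()
    if (~ok).any():
        logger.info("omitting %d gene(s) missing in a group for %s",
                    int((~ok).sum()), contrast)
    log2fc = (test_mean - ctrl_mean)[ok]
    fc = np.exp2(log2fc)
    call = pd.Series(CALL_NONE, index=fc.index)
    call[fc >= up_fc] = CALL_UP
    call[fc <= 1.0 / up_fc] = CALL_DOWN
    return pd.DataFrame({
        "contrast": contrast,
        "fc": fc,
        "call": call,
        "go_set": (fc >= go_fc) | (fc <= 1.0 / go_fc),
    }).rename_axis("gene_id")


def count_shared_calls(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Venn region counts for three (or more) labelled ID sets.

    Returns a dict keyed by the sorted tuple of set labels an ID belongs to,
    covering every non-empty membership pattern; region counts sum to the size
    of the union.
    """
    labels = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            counts[combo] = len(inside - outside)
    return counts


def uncentered_correlation_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise uncentered-correlation distance between samples (columns).

    r_u(x, y) = Σ xᵢyᵢ / sqrt(Σ xᵢ² · Σ yᵢ²); distance = 1 − r_u.  Unlike
    Pearson's r the means are not subtracted, so the distance is sensitive to
    overall signal level as well as shape.  Symmetric with a zero diagonal.
    """
    if table.shape[1] < 2:
        raise ValidationError("need at least two samples")
    x = table.to_numpy(dtype=float)
    norms = np.sqrt((x ** 2).sum(axis=0))
    if np.any(norms == 0):
        bad = table.columns[norms == 0].tolist()
        raise ValidationError(f"zero-norm sample(s): {bad}")
    r = (x.T @ x) / np.outer(norms, norms)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(dist, index=table.columns, columns=table.columns)


def average_linkage(dist: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram (scipy linkage matrix) from a distance matrix."""
    condensed = squareform(dist.to_numpy(), checks=False)
    return linkage(condensed, method="average")
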