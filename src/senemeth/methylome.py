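"""β-value computation, QC filtering, differential and sequential methylation.

A BeadChip probe's methylation level is summarised as

    β = M / (U + M + 100)

with M and U the methylated- and unmethylated-allele intensities; the +100
offset regularises low-intensity probes, so β ∈ [0, 1).  Differential
methylation between two samples is called from Δβ = β_test − β_control with
inclusive thresholds: Δβ ≥ 0.2 is hypermethylated, Δβ ≤ −0.2 hypomethylated.
No variance model is fitted — the arrays carry one sample per condition.

Across an ordered passage series (e.g. PDL 36 → 49 → 69 → 85) a called probe
shows *sequential* (stepwise) change when its β values are monotone in the
called direction across every consecutive passage pair, within a tolerance ε
(default 0, i.e. non-strict monotonicity).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import INTERGENIC, BetaMatrix, CPG_CONTEXTS, GENE_FEATURES, ProbeAnnotation
from .errors import ValidationError

logger = logging.getLogger(__name__)

CALL_HYPER = "hyper"
CALL_HYPO = "hypo"
CALL_NONE = "none"


def beta_from_intensities(methylated, unmethylated, offset: float = 100.0):
    """β = M / (U + M + offset); accepts scalars or arrays, returns same shape."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError("intensities must be non-negative")
    beta = m / (u + m + offset)
    return float(beta) if beta.ndim == 0 else beta


def filter_probes(bm: BetaMatrix, p_max: float = 0.05,
                  samples: list[str] | None = None) -> BetaMatrix:
    """Remove probes failing QC in *any* sample of the analysis set.

    A probe is eliminated when, in any of *samples* (default: all), its
    detection p-value exceeds *p_max* (strictly) or its β value is missing.
    Filtering is analysis-set-wide: a probe failing in one used sample is
    dropped from all.
    """
    cols = list(samples) if samples is not None else bm.sample_labels
    beta = bm.beta[cols]
    detp = bm.detection_p[cols]
    bad = beta.isna().any(axis=1) | (detp > p_max).any(axis=1) | detp.isna().any(axis=1)
    kept = bm.probe_ids[~bad.to_numpy()]
    logger.info("probe filter: %d/%d probes pass (p_max=%g)",
                len(kept), len(bm.probe_ids), p_max)
    return bm.subset(kept)


def call_differential(bm: BetaMatrix, test_sample: str, control_sample: str,
                      dbeta: float = 0.2) -> pd.DataFrame:
    """Per-probe Δβ and hyper/hypo/none call for one contrast.

    Δβ = β(test) − β(control); thresholds are inclusive (Δβ ≥ dbeta → hyper,
    Δβ ≤ −dbeta → hypo).  Probes with a missing β in either sample are
    excluded from the output.
    """
    delta = bm.beta[test_sample] - bm.beta[control_sample]
    delta = delta.dropna()
    call = pd.Series(CALL_NONE, index=delta.index)
    # inclusive thresholds with a guard against float subtraction error
    tol = 1e-12
    call[delta >= dbeta - tol] = CALL_HYPER
    call[delta <= -dbeta + tol] = CALL_HYPO
    return pd.DataFrame({"delta_beta": delta, "call": call}).rename_axis("probe_id")


def classify_sequential(bm: BetaMatrix, calls: pd.DataFrame,
                        passages: list[str], epsilon: float = 0.0) -> pd.Series:
    """Flag called probes whose β drifts monotonically across the passage series.

    *passages* must be ≥ 3 sample labels in biological order; *calls* are the
    final-versus-first differential calls.  A hyper-called probe is sequential
    iff β_{i+1} ≥ β_i − ε for every consecutive pair; mirrored for hypo.
    Returns a nullable boolean Series (pd.NA for uncalled probes).
    """
    if len(passages) < 3:
        raise ValidationError("sequential classification needs >= 3 ordered passages")
    if len(set(passages)) != len(passages):
        raise ValidationError("passage labels must be distinct")
    beta = bm.beta[list(passages)].loc[calls.index]
    diffs = beta.to_numpy(dtype=float)
    steps = np.diff(diffs, axis=1)
    nondecreasing = (steps >= -epsilon).all(axis=1)
    nonincreasing = (steps <= epsilon).all(axis=1)
    flags = pd.Series(pd.NA, index=calls.index, dtype="boolean")
    hyper = calls["call"] == CALL_HYPER
    hypo = calls["call"] == CALL_HYPO
    flags[hyper] = pd.array(nondecreasing[hyper.to_numpy()], dtype="boolean")
    flags[hypo] = pd.array(nonincreasing[hypo.to_numpy()], dtype="boolean")
    return flags.rename("sequential")


def summarize_subcategories(calls: pd.DataFrame, annotation: ProbeAnnotation
                            ) -> dict[str, pd.DataFrame]:
    """Hyper/hypo counts, rates and rate ratios per annotation subcategory.

    Returns ``{"cpg_context": ..., "gene_feature": ...}``.  Each table has one
    row per subcategory with columns total, hyper, hypo, hyper_rate, hypo_rate
    and ratio (hyper_rate / hypo_rate; NaN where undefined).  On the CpG-context
    axis every probe counts exactly once; on the gene-feature axis a probe
    annotated to several genes/features counts once per annotation, and probes
    with no gene annotation form the "Intergenic" bucket.
    """
    calls = calls.copy()

    def _tally(groups: pd.DataFrame, order: tuple[str, ...]) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(order, name="subcategory"))
        grouped = groups.groupby("subcategory")["call"]
        out["total"] = grouped.size().reindex(order).fillna(0).astype(int)
        out["hyper"] = grouped.apply(lambda s: int((s == CALL_HYPER).sum())) \
            .reindex(order).fillna(0).astype(int)
        out["hypo"] = grouped.apply(lambda s: int((s == CALL_HYPO).sum())) \
            .reindex(order).fillna(0).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["hyper_rate"] = np.where(out["total"] > 0,
                                         out["hyper"] / out["total"], np.nan)
            out["hypo_rate"] = np.where(out["total"] > 0,
                                        out["hypo"] / out["total"], np.nan)
            out["ratio"] = np.where(out["hypo_rate"] > 0,
                                    out["hyper_rate"] / out["hypo_rate"], np.nan)
        return out

    ctx = calls.join(annotation.probes["cpg_context"]).rename(
        columns={"cpg_context": "subcategory"})
    context_summary = _tally(ctx[["subcategory", "call"]], CPG_CONTEXTS)

    gf = annotation.gene_features.merge(
        calls.reset_index(), on="probe_id", how="inner")
    gf = gf.rename(columns={"feature": "subcategory"})[["subcategory", "call"]]
    inter = calls.loc[calls.index.isin(annotation.intergenic_probes)].copy()
    inter["subcategory"] = INTERGENIC
    gf = pd.concat([gf, inter[["subcategory", "call"]]], ignore_index=True)
    feature_summary = _tally(gf, GENE_FEATURES + (INTERGENIC,))

    return {"cpg_context": context_summary, "gene_feature": feature_summary}


def beta_scatter_stats(a: pd.Series, b: pd.Series) -> float:
    """Squared Pearson correlation (r²) between two paired β vectors.

    Pairs with a missing value on either side are dropped first; a constant
    vector (zero variance) is an error.
    """
    paired = pd.concat([a, b], axis=1, join="inner").dropna()
    x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
    if len(x) < 2:
        raise ValidationError("need at least two paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
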