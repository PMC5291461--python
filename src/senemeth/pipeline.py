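"""End-to-end analysis of a (synthetic or real) study bundle.

`analyze` runs the full chain — probe QC filtering, differential and
sequential methylation calling, subcategory summaries, expression
normalization / aggregation / fold-change calling, promoter classification,
nearest-TSS integration and the miRNA triad filter — and returns the
intermediate tables plus a flat dict of headline numbers.  When the study is
synthetic, `score_against_truth` adds planted-signal recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import expression as expr_mod
from . import integration
from . import methylome
from . import mirna as mirna_mod
from . import promoters
from .config import DEFAULTS, Thresholds
from .synthetic_data import CONTRASTS, MIRNA_SAMPLES, SyntheticStudy


@dataclass
class AnalysisResult:
    """All intermediate tables of one pipeline run plus headline metrics."""

    filtered_beta: object
    meth_calls: pd.DataFrame
    sequential: pd.Series
    subcategories: dict
    normalized_expression: pd.DataFrame
    gene_expression: pd.DataFrame
    fold_changes: dict[str, pd.DataFrame]
    venn_up: dict
    venn_down: dict
    promoter_classes: pd.DataFrame
    mapped: pd.DataFrame
    pairs: pd.DataFrame
    gene_level_pairs: pd.DataFrame
    distance_dist: dict
    mirna_concordance: pd.DataFrame
    triads: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def analyze(study: SyntheticStudy, thr: Thresholds = DEFAULTS) -> AnalysisResult:
    passages = list(study.config.passage_labels)
    first, last = passages[0], passages[-1]

    # methylome
    filtered = methylome.filter_probes(study.beta, p_max=thr.detection_p_max,
                                       samples=passages)
    calls = methylome.call_differential(filtered, last, first, dbeta=thr.delta_beta)
    sequential = methylome.classify_sequential(filtered, calls, passages,
                                               epsilon=thr.epsilon)
    subcats = methylome.summarize_subcategories(calls, study.annotation)
    r2 = methylome.beta_scatter_stats(filtered.beta[last], filtered.beta[first])

    # expression
    normalized = expr_mod.normalize_expression(study.expression,
                                               low_cutoff=thr.low_cutoff,
                                               percentile=thr.expr_percentile)
    gene_table = expr_mod.aggregate_probes_to_genes(normalized, study.probe_to_gene)
    fold_changes = {
        label: expr_mod.call_fold_changes(gene_table, [test], [control],
                                          up_fc=thr.fc, go_fc=thr.fc_go,
                                          contrast=label)
        for label, (test, control) in CONTRASTS.items()
    }
    up_sets = {c: set(fc.index[fc["call"] == expr_mod.CALL_UP])
               for c, fc in fold_changes.items()}
    down_sets = {c: set(fc.index[fc["call"] == expr_mod.CALL_DOWN])
                 for c, fc in fold_changes.items()}
    venn_up = expr_mod.count_shared_calls(up_sets)
    venn_down = expr_mod.count_shared_calls(down_sets)

    # promoter classification (protein-coding and miRNA host loci alike)
    promoter_classes = promoters.classify_promoters(
        study.genes, study.genome, upstream=thr.promoter_upstream,
        downstream=thr.promoter_downstream, gc_min=thr.gc_min, oe_min=thr.oe_min)

    # integration around the replicative contrast
    rep_fc = fold_changes["replicative"]
    mapped = integration.map_probes_to_nearest_tss(
        study.annotation.probes, study.genes, window=thr.tss_window)
    pairs = integration.joint_call(mapped, calls, rep_fc, dbeta=thr.delta_beta,
                                   fc=thr.fc)
    gene_level = integration.deduplicated_gene_summary(pairs)
    distance_dist = integration.distance_distribution(
        pairs.reset_index(), promoter_classes, bin_width=thr.bin_width,
        window=thr.tss_window)

    # miRNA axis (final miRNA passage versus the first)
    mirna_norm = mirna_mod.normalize_mirna(study.mirna_expression,
                                           percentile=thr.mirna_percentile)
    mirna_fc = mirna_mod.mirna_fold_changes(mirna_norm, [MIRNA_SAMPLES[-1]],
                                            [MIRNA_SAMPLES[0]])
    mirna_probes = mirna_mod.select_mirna_probes(study.annotation)
    concordance = mirna_mod.call_concordance(mirna_probes, calls, mirna_fc,
                                             alias=study.alias,
                                             dbeta=thr.delta_beta,
                                             fc_cut=thr.mirna_fc)
    triads = mirna_mod.triad_filter(concordance, study.targets, rep_fc,
                                    min_mirnas=thr.min_mirnas, gene_fc=thr.fc)

    call_counts = calls["call"].value_counts()
    seq_hyper = sequential[calls["call"] == methylome.CALL_HYPER]
    seq_hypo = sequential[calls["call"] == methylome.CALL_HYPO]
    metrics = {
        "probes_total": int(len(study.beta.probe_ids)),
        "probes_pass_filter": int(len(filtered.probe_ids)),
        "n_hyper": int(call_counts.get(methylome.CALL_HYPER, 0)),
        "n_hypo": int(call_counts.get(methylome.CALL_HYPO, 0)),
        "n_none": int(call_counts.get(methylome.CALL_NONE, 0)),
        "frac_hyper_sequential": float(seq_hyper.mean()) if len(seq_hyper) else float("nan"),
        "frac_hypo_sequential": float(seq_hypo.mean()) if len(seq_hypo) else float("nan"),
        "beta_r2_final_vs_first": float(r2),
        "n_up_replicative": len(up_sets["replicative"]),
        "n_down_replicative": len(down_sets["replicative"]),
        "venn_up_all_three": int(venn_up.get(tuple(sorted(CONTRASTS)), 0)),
        "venn_down_all_three": int(venn_down.get(tuple(sorted(CONTRASTS)), 0)),
        "n_mapped_probes": int(len(mapped)),
        "n_unmapped_probes": int(len(study.annotation.probes) - len(mapped)),
        "n_hyper_down_pairs": int((pairs["joint_call"] == integration.JOINT_HYPER_DOWN).sum()),
        "n_hypo_up_pairs": int((pairs["joint_call"] == integration.JOINT_HYPO_UP).sum()),
        "n_genes_with_concordant_pair": int(gene_level.index.nunique()),
        "n_concordant_mirnas": int((concordance["concordance"] != "none").sum()
                                   - (concordance["concordance"] == "unevaluable").sum()),
        "n_triad_genes": int(len(triads)),
    }
    return AnalysisResult(
        filtered_beta=filtered, meth_calls=calls, sequential=sequential,
        subcategories=subcats, normalized_expression=normalized,
        gene_expression=gene_table, fold_changes=fold_changes, venn_up=venn_up,
        venn_down=venn_down, promoter_classes=promoter_classes, mapped=mapped,
        pairs=pairs, gene_level_pairs=gene_level, distance_dist=distance_dist,
        mirna_concordance=concordance, triads=triads, metrics=metrics)


def score_against_truth(result: AnalysisResult, study: SyntheticStudy) -> dict:
    """Planted-signal recovery metrics for a synthetic study.

    Recovery is evaluated over probes that pass QC filtering (filtering is
    part of the pipeline under test, and a probe removed for a planted
    detection failure carries no β evidence either way).
    """
    truth = study.truth
    calls = result.meth_calls
    probe_truth = truth.probe_class.reindex(calls.index)

    hyper_truth = probe_truth == "hyper_drift"
    hypo_truth = probe_truth == "hypo_drift"
    stable_truth = probe_truth == "stable"
    hyper_called = calls["call"] == methylome.CALL_HYPER
    hypo_called = calls["call"] == methylome.CALL_HYPO

    def _recall(truth_mask, called_mask):
        n = int(truth_mask.sum())
        return float((truth_mask & called_mask).sum() / n) if n else float("nan")

    false_calls = int((stable_truth & (hyper_called | hypo_called)).sum())
    n_stable = int(stable_truth.sum())

    # expression recovery (replicative contrast)
    rep = result.fold_changes["replicative"]
    expr_truth = truth.gene_expr_class.reindex(rep.index)
    up_t, down_t = expr_truth == "up", expr_truth == "down"
    up_c, down_c = rep["call"] == "up", rep["call"] == "down"

    # promoter classification accuracy over all loci with truth
    prom_truth = truth.gene_promoter_class
    prom_pred = result.promoter_classes["promoter_class"].reindex(prom_truth.index)
    prom_acc = float((prom_pred == prom_truth).mean())

    conc = result.mirna_concordance
    conc_pred = set(conc.index[conc["concordance"] == "hyper_down"])
    conc_truth = set(truth.mirna_concordant.index[truth.mirna_concordant])

    return {
        "hyper_recall": _recall(hyper_truth, hyper_called),
        "hypo_recall": _recall(hypo_truth, hypo_called),
        "stable_false_call_rate": float(false_calls / n_stable) if n_stable else float("nan"),
        "expr_up_recall": _recall(up_t, up_c),
        "expr_down_recall": _recall(down_t, down_c),
        "promoter_accuracy": prom_acc,
        "mirna_concordance_exact": float(conc_pred == conc_truth),
        "n_triad_recovered": int(len(set(result.triads.index) & truth.triad_genes)),
        "n_triad_planted": int(len(truth.triad_genes)),
        "triad_exact": float(set(result.triads.index) == truth.triad_genes),
    }
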