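"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the design of a replicative-senescence array study: a
methylation passage series (four population-doubling levels) in which a
fraction of CpG probes drift monotonically up or down in β by a fixed step per
passage, expression tables with planted fold changes for three
senescence-versus-control contrasts, a toy genome whose gene promoters are
built compositionally as CGI or non-CGI windows, and a miRNA layer with
planted promoter-hypermethylated / down-regulated miRNAs, target links and
triad genes.  Every planted assignment is recorded in a :class:`TruthTable`,
so downstream calls can be scored for exact recovery.

Layout conventions (deterministic functions of the configuration):

* one synthetic chromosome ``chrS``; gene loci every 20 kb, TSS of locus *i*
  at 10000 + 20000·i, strands alternating, protein-coding genes first and
  miRNA host loci after them;
* promoter windows are [TSS − 1000, TSS + 500) (mirrored on −), tiled from a
  10-mer motif: ``ACGTGCTAGC`` for CGI windows (GC = 0.6, one CpG per 10 bp,
  O/E ≈ 1.1) and ``AGTCATGACT`` for non-CGI windows (GC = 0.4, no CpG,
  O/E = 0), guaranteeing the planted class by construction;
* drifting probes start at a β where the full drift fits inside [0, 1], so
  with zero noise the planted change is recovered exactly;
* detection p-values are Uniform(0, 0.04) for good entries and
  Uniform(0.06, 1) for planted failures — no mass on the 0.05 boundary.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .array_io import (BetaMatrix, CPG_CONTEXTS, GENE_FEATURES, ProbeAnnotation,
                       write_beta_matrix, write_matrix, write_probe_annotation,
                       write_refgene)
from .errors import ConfigError

CGI_MOTIF = "ACGTGCTAGC"     # GC 0.6, one CpG / 10 bp
NONCGI_MOTIF = "AGTCATGACT"  # GC 0.4, zero CpG

_LOCUS_SPACING = 20_000
_FIRST_TSS = 10_000

CLASS_HYPER_DRIFT = "hyper_drift"
CLASS_HYPO_DRIFT = "hypo_drift"
CLASS_STABLE = "stable"

#: contrast label -> (test sample, control sample) in the expression table
CONTRASTS = {
    "replicative": ("RS", "PRO"),
    "ris": ("RIS", "VEC"),
    "svts8": ("SVSEN", "SVPRO"),
}

MIRNA_SAMPLES = ("PDL44", "PDL60", "PDL78", "PDL80")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic data generator."""

    n_probes: int = 1000
    n_genes: int = 100
    n_mirnas: int = 100
    passage_labels: tuple[str, ...] = ("PDL36", "PDL49", "PDL69", "PDL85")
    frac_hyper_drift: float = 0.1
    frac_hypo_drift: float = 0.1
    drift_step: float = 0.1       # Δβ per passage step
    beta_noise_sd: float = 0.01   # truncated-Gaussian noise on β
    n_planted_cgi: int | None = None  # default: half the genes
    genome_length: int | None = None   # derived from the locus layout if None
    expr_effect_log2: float = 2.0      # planted log2 fold change (4-fold)
    frac_up: float = 0.1
    frac_down: float = 0.1
    expr_noise_sd: float = 0.1         # log2-scale expression noise
    frac_detection_fail: float = 0.005  # per-entry detection-p failures
    n_triad: int = 5
    n_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_cgi is None:
            object.__setattr__(self, "n_planted_cgi", max(1, self.n_genes // 2))
        for name in ("n_probes", "n_genes", "n_mirnas", "n_planted_cgi"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.drift_step <= 0:
            raise ConfigError("drift_step must be > 0")
        if self.frac_hyper_drift < 0 or self.frac_hypo_drift < 0 or \
           self.frac_hyper_drift + self.frac_hypo_drift > 1:
            raise ConfigError("drift fractions must be >= 0 and sum to <= 1")
        if len(self.passage_labels) < 2:
            raise ConfigError("need at least two passage labels")
        nums = []
        for lab in self.passage_labels:
            m = re.search(r"(\d+)$", lab)
            if m is None:
                raise ConfigError(f"passage label {lab!r} carries no PDL number")
            nums.append(int(m.group(1)))
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ConfigError("passage labels must be strictly increasing in PDL")
        total_drift = self.drift_step * (len(self.passage_labels) - 1)
        if total_drift >= 0.9:
            raise ConfigError("total drift must leave room inside [0, 1]")
        if self.n_planted_cgi > self.n_genes:
            raise ConfigError("n_planted_cgi cannot exceed n_genes")
        if self.genome_length is not None:
            if self.genome_length < 1000 * self.n_planted_cgi:
                raise ConfigError("genome_length must be >= 1000 * n_planted_cgi")
            if self.genome_length < self.required_genome_length:
                raise ConfigError(
                    f"genome_length must be >= {self.required_genome_length} "
                    "to fit the locus layout")

    @property
    def n_loci(self) -> int:
        return self.n_genes + self.n_mirnas

    @property
    def required_genome_length(self) -> int:
        return _FIRST_TSS + self.n_loci * _LOCUS_SPACING

    @property
    def effective_genome_length(self) -> int:
        return self.genome_length or self.required_genome_length

    @property
    def total_drift(self) -> float:
        return self.drift_step * (len(self.passage_labels) - 1)


@dataclass
class TruthTable:
    """Planted ground truth for every generated probe, gene and miRNA."""

    probe_class: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    gene_expr_class: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    gene_promoter_class: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    mirna_concordant: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    triad_genes: set = field(default_factory=set)

    def write(self, path: str | Path) -> None:
        rows = [("probe", pid, cls) for pid, cls in self.probe_class.items()]
        rows += [("gene_expr", g, c) for g, c in self.gene_expr_class.items()]
        rows += [("gene_promoter", g, c) for g, c in self.gene_promoter_class.items()]
        rows += [("mirna_concordant", m, str(bool(v)))
                 for m, v in self.mirna_concordant.items()]
        rows += [("triad_gene", g, "True") for g in sorted(self.triad_genes)]
        pd.DataFrame(rows, columns=["entity", "id", "value"]) \
            .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# deterministic layout helpers
# ---------------------------------------------------------------------------

def gene_layout(cfg: SimConfig) -> pd.DataFrame:
    """Locus table for all protein-coding genes and miRNA host loci."""
    rows = []
    for i in range(cfg.n_loci):
        tss = _FIRST_TSS + i * _LOCUS_SPACING
        strand = "+" if i % 2 == 0 else "-"
        if i < cfg.n_genes:
            gene_id, symbol = f"NM_{i:06d}", f"GENE{i:04d}"
            promoter = "CGI" if i < cfg.n_planted_cgi else "nonCGI"
        else:
            j = i - cfg.n_genes
            gene_id, symbol = f"NR_{j:06d}", f"MIR{900 + j}"
            promoter = "nonCGI"
        tx_start = tss if strand == "+" else tss + 1 - 2000
        tx_end = tss + 2000 if strand == "+" else tss + 1
        rows.append((gene_id, symbol, "chrS", strand, tx_start, tx_end, tss,
                     promoter, i >= cfg.n_genes))
    return pd.DataFrame(rows, columns=[
        "gene_id", "symbol", "chrom", "strand", "txStart", "txEnd", "tss",
        "promoter_class", "is_mirna"])


def mirna_names(cfg: SimConfig) -> tuple[list[str], list[str], pd.Series]:
    """(host symbols, mature names, symbol -> mature alias table)."""
    symbols = [f"MIR{900 + j}" for j in range(cfg.n_mirnas)]
    mature = [f"hsa-miR-{900 + j}-5p" for j in range(cfg.n_mirnas)]
    alias = pd.Series(mature, index=symbols, name="mirna_id")
    return symbols, mature, alias


def mirna_roles(cfg: SimConfig) -> pd.Series:
    """Planted role per miRNA host symbol.

    ``concordant`` miRNAs get a hypermethylating promoter probe and falling
    expression; ``hyper_flat`` a hypermethylating probe with flat expression;
    ``down_only`` falling expression over a stable promoter; ``quiet`` neither.
    The last two are decoy roles that must not be called concordant.
    """
    symbols, _, _ = mirna_names(cfg)
    # a small changed fraction keeps the percentile-shift normalization stable,
    # as on a real array where most miRNAs do not move
    n_conc = min(max(2, round(cfg.n_mirnas * 0.07)), cfg.n_mirnas)
    roles = []
    for j in range(cfg.n_mirnas):
        if j < n_conc:
            roles.append("concordant")
        elif j < n_conc + 2:
            roles.append("hyper_flat")
        elif j < n_conc + 4:
            roles.append("down_only")
        else:
            roles.append("quiet")
    return pd.Series(roles, index=symbols, name="role")


def _gene_classes(cfg: SimConfig) -> pd.Series:
    """Planted replicative-contrast expression class per protein-coding gene."""
    layout = gene_layout(cfg)
    genes = layout.loc[~layout["is_mirna"], "gene_id"]
    n_down = round(cfg.frac_down * cfg.n_genes)
    n_up = round(cfg.frac_up * cfg.n_genes)
    classes = (["down"] * n_down + ["up"] * n_up
               + ["null"] * (cfg.n_genes - n_down - n_up))
    return pd.Series(classes, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_methylation_series(cfg: SimConfig
                                ) -> tuple[BetaMatrix, ProbeAnnotation, TruthTable]:
    """β matrix over the passage series, probe annotation and planted truth.

    Regular probes are laid out around protein-coding gene TSSs, cycling
    through the six CpG contexts and the seven gene-feature subcategories
    (intergenic probes sit > 8 kb from every TSS).  One extra promoter probe
    per miRNA host locus is appended; probes of ``concordant`` and
    ``hyper_flat`` miRNAs are planted hyper-drifting.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_probes
    layout = gene_layout(cfg)
    pgenes = layout[~layout["is_mirna"]].reset_index(drop=True)

    # planted classes, randomly placed over the regular probes
    n_hyper = round(cfg.frac_hyper_drift * n)
    n_hypo = round(cfg.frac_hypo_drift * n)
    classes = np.array([CLASS_HYPER_DRIFT] * n_hyper + [CLASS_HYPO_DRIFT] * n_hypo
                       + [CLASS_STABLE] * (n - n_hyper - n_hypo), dtype=object)
    rng.shuffle(classes)

    probe_ids = [f"cg{i:08d}" for i in range(n)]
    feature_cycle = list(GENE_FEATURES) + [None]  # None -> intergenic
    offset_ranges = {  # bp from TSS, in gene orientation
        "TSS1500": (-1500, -200), "TSS200": (-200, 0), "5UTR": (0, 300),
        "1stExon": (300, 600), "Body": (600, 5000), "3UTR": (5000, 7800),
        None: (9000, 10500),
    }
    probe_rows, gf_rows = [], []
    for i, pid in enumerate(probe_ids):
        g = pgenes.iloc[i % len(pgenes)]
        feature = feature_cycle[i % len(feature_cycle)]
        lo, hi = offset_ranges[feature]
        offset = int(rng.integers(lo, hi))
        pos = g["tss"] + offset if g["strand"] == "+" else g["tss"] - offset
        pos = int(np.clip(pos, 0, cfg.effective_genome_length - 1))
        context = CPG_CONTEXTS[i % len(CPG_CONTEXTS)]
        probe_rows.append((pid, "chrS", pos, "+", context))
        if feature is not None:
            gf_rows.append((pid, g["symbol"], feature))

    # one TSS200 promoter probe per miRNA host locus
    mir_loci = layout[layout["is_mirna"]].reset_index(drop=True)
    roles = mirna_roles(cfg)
    mir_probe_ids, mir_classes = [], []
    for j, g in mir_loci.iterrows():
        pid = f"cgM{j:07d}"
        offset = -100
        pos = g["tss"] + offset if g["strand"] == "+" else g["tss"] - offset
        probe_rows.append((pid, "chrS", int(pos), "+",
                           CPG_CONTEXTS[j % len(CPG_CONTEXTS)]))
        gf_rows.append((pid, g["symbol"], "TSS200"))
        mir_probe_ids.append(pid)
        mir_classes.append(CLASS_HYPER_DRIFT
                           if roles[g["symbol"]] in ("concordant", "hyper_flat")
                           else CLASS_STABLE)

    all_ids = probe_ids + mir_probe_ids
    all_classes = np.concatenate([classes, np.array(mir_classes, dtype=object)])

    # β series: drifting probes start where the full drift fits inside [0, 1]
    n_all = len(all_ids)
    n_pass = len(cfg.passage_labels)
    margin = 0.05
    start = rng.uniform(0.02, 0.98, size=n_all)
    hyper = all_classes == CLASS_HYPER_DRIFT
    hypo = all_classes == CLASS_HYPO_DRIFT
    start[hyper] = rng.uniform(margin, 1 - cfg.total_drift - margin, size=hyper.sum())
    start[hypo] = rng.uniform(cfg.total_drift + margin, 1 - margin, size=hypo.sum())
    steps = np.zeros(n_all)
    steps[hyper] = cfg.drift_step
    steps[hypo] = -cfg.drift_step
    expected = start[:, None] + steps[:, None] * np.arange(n_pass)[None, :]
    noise = rng.normal(0.0, cfg.beta_noise_sd, size=expected.shape) \
        if cfg.beta_noise_sd > 0 else 0.0
    beta = np.clip(expected + noise, 0.0, 1.0)

    # planted detection failures exercise QC filtering on the regular probes;
    # miRNA promoter probes are exempt so each miRNA's single evidence probe
    # survives and the planted concordance truth stays evaluable
    fail = rng.random(size=beta.shape) < cfg.frac_detection_fail
    fail[n:, :] = False
    detp = rng.uniform(0.0, 0.04, size=beta.shape)
    detp[fail] = rng.uniform(0.06, 1.0, size=int(fail.sum()))

    cols = list(cfg.passage_labels)
    bm = BetaMatrix(
        beta=pd.DataFrame(beta, index=pd.Index(all_ids, name="probe_id"), columns=cols),
        detection_p=pd.DataFrame(detp, index=pd.Index(all_ids, name="probe_id"),
                                 columns=cols))
    ann = ProbeAnnotation(
        probes=pd.DataFrame(probe_rows, columns=[
            "probe_id", "chrom", "pos", "strand", "cpg_context"]).set_index("probe_id"),
        gene_features=pd.DataFrame(gf_rows, columns=["probe_id", "gene", "feature"]))
    truth = TruthTable(
        probe_class=pd.Series(all_classes, index=pd.Index(all_ids, name="probe_id")))
    return bm, ann, truth


def generate_genome_with_cgis(cfg: SimConfig
                              ) -> tuple[dict[str, str], pd.DataFrame, TruthTable]:
    """Toy genome with compositional CGI / non-CGI promoter windows.

    Returns (genome, gene models, truth).  Each locus's promoter window is
    overwritten with the tiled class motif; the TSS lies inside its window and
    windows never overlap (raised as an error otherwise).
    """
    from .promoters import promoter_window  # local import avoids a cycle

    rng = np.random.default_rng([cfg.seed, 2])
    length = cfg.effective_genome_length
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])

    layout = gene_layout(cfg)
    windows = []
    for rec in layout.itertuples(index=False):
        win = promoter_window(rec.chrom, int(rec.tss), rec.strand,
                              upstream=1000, downstream=500, contig_length=length)
        windows.append((win.start, win.end, rec.promoter_class))
    windows_sorted = sorted(windows)
    for (s1, e1, _), (s2, e2, _) in zip(windows_sorted, windows_sorted[1:]):
        if s2 < e1:
            raise ConfigError("planted promoter windows overlap")
    for start, end, cls in windows:
        motif = CGI_MOTIF if cls == "CGI" else NONCGI_MOTIF
        tile = (motif * (((end - start) // len(motif)) + 1))[: end - start]
        genome[start:end] = np.frombuffer(tile.encode(), dtype="S1")

    seq = genome.tobytes().decode()
    genes = layout[["gene_id", "symbol", "chrom", "strand", "txStart",
                    "txEnd", "tss"]].copy()
    truth = TruthTable(gene_promoter_class=pd.Series(
        layout["promoter_class"].to_numpy(),
        index=pd.Index(layout["gene_id"], name="gene_id")))
    return {"chrS": seq}, genes, truth


def generate_expression_tables(cfg: SimConfig) -> tuple[
        pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame, pd.Series, TruthTable]:
    """Raw expression, probe map, miRNA expression, targets, alias and truth.

    Returns ``(expr, probe_to_gene, mirna_expr, targets, alias, truth)``:

    * ``expr`` — raw intensity table (expression probes x the six samples of
      the three contrasts); every fifth gene carries two probes to exercise
      mean aggregation;
    * ``probe_to_gene`` — expression probe -> RefSeq accession;
    * ``mirna_expr`` — raw miRNA intensities over a four-passage series;
    * ``targets`` — (mirna_id, gene_id) predicted-target pairs containing the
      planted triad genes (>= 2 concordant miRNAs each), decoys supported by
      exactly one concordant miRNA, and fold-change decoys with flat
      expression;
    * ``alias`` — miRNA host symbol -> mature name.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    gene_classes = _gene_classes(cfg)
    genes = list(gene_classes.index)

    # expression probes: every 5th gene gets two probes
    probe_rows = []
    for i, g in enumerate(genes):
        n_probes = 2 if i % 5 == 0 else 1
        for k in range(n_probes):
            probe_rows.append((f"A_{i:06d}_{k}", g))
    probe_to_gene = pd.Series({p: g for p, g in probe_rows}, name="gene_id")

    samples = [s for pair in CONTRASTS.values() for s in pair]
    baseline = rng.normal(6.0, 1.5, size=len(genes))
    base_by_gene = dict(zip(genes, baseline))

    # which contrasts each planted gene is altered in: some shared by all
    # three senescence models, some specific to one.  The first
    # n_triad + n_decoys planted up genes are always altered in the
    # replicative contrast so the miRNA layer has its triad/decoy genes.
    patterns = [("replicative", "ris", "svts8"), ("replicative",),
                ("ris",), ("svts8",)]
    rep_patterns = patterns[:2]
    n_reserved = cfg.n_triad + cfg.n_decoys
    effect = {}
    gene_pattern: dict[str, tuple[str, ...]] = {}
    up_seen = 0
    for idx, (g, cls) in enumerate(gene_classes.items()):
        if cls == "null":
            continue
        if cls == "up":
            if up_seen < n_reserved:
                pat = rep_patterns[up_seen % len(rep_patterns)]
            else:
                pat = patterns[idx % len(patterns)]
            up_seen += 1
        else:
            pat = patterns[idx % len(patterns)]
        gene_pattern[g] = pat
        sign = 1.0 if cls == "up" else -1.0
        for contrast in pat:
            effect[(g, CONTRASTS[contrast][0])] = sign * cfg.expr_effect_log2

    log2 = np.empty((len(probe_rows), len(samples)))
    for r, (pid, g) in enumerate(probe_rows):
        for c, s in enumerate(samples):
            log2[r, c] = base_by_gene[g] + effect.get((g, s), 0.0)
    if cfg.expr_noise_sd > 0:
        log2 = log2 + rng.normal(0.0, cfg.expr_noise_sd, size=log2.shape)
    expr = pd.DataFrame(np.exp2(log2),
                        index=pd.Index([p for p, _ in probe_rows], name="probe_id"),
                        columns=samples)

    # replicative-contrast truth includes only genes altered in that contrast
    expr_truth = gene_classes.copy()
    for g, cls in gene_classes.items():
        if cls != "null" and "replicative" not in gene_pattern[g]:
            expr_truth[g] = "null"

    # miRNA expression: concordant and down_only roles fall ~2-fold by the end
    symbols, mature, alias = mirna_names(cfg)
    roles = mirna_roles(cfg)
    mir_base = rng.normal(5.0, 1.0, size=cfg.n_mirnas)
    mlog2 = np.tile(mir_base[:, None], (1, len(MIRNA_SAMPLES)))
    down = roles.isin(["concordant", "down_only"]).to_numpy()
    ramp = np.linspace(0.0, 1.0, len(MIRNA_SAMPLES))
    mlog2[down] = mlog2[down] - ramp[None, :]  # final fold change 0.5
    mlog2 = mlog2 + rng.normal(0.0, 0.05, size=mlog2.shape)
    mirna_expr = pd.DataFrame(np.exp2(mlog2),
                              index=pd.Index(mature, name="mirna_id"),
                              columns=list(MIRNA_SAMPLES))

    concordant_sym = [s for s in symbols if roles[s] == "concordant"]
    concordant = [alias[s] for s in concordant_sym]
    other = [alias[s] for s in symbols if roles[s] != "concordant"]

    # target links: planted triads among up genes, then decoys
    up_genes = [g for g, c in expr_truth.items() if c == "up"]
    null_genes = [g for g, c in expr_truth.items() if c == "null"]
    n_triad = min(cfg.n_triad, max(0, len(up_genes) - cfg.n_decoys))
    triad = up_genes[:n_triad]
    support_decoys = up_genes[n_triad:n_triad + cfg.n_decoys]
    fc_decoys = null_genes[:cfg.n_decoys]
    links: list[tuple[str, str]] = []
    for i, g in enumerate(triad):
        k = 2 + (i % 2)  # two or three supporting miRNAs
        for off in range(k):
            links.append((concordant[(i + off) % len(concordant)], g))
    for i, g in enumerate(support_decoys):
        links.append((concordant[i % len(concordant)], g))
        if other:
            links.append((other[i % len(other)], g))
    for i, g in enumerate(fc_decoys):
        links.append((concordant[i % len(concordant)], g))
        links.append((concordant[(i + 1) % len(concordant)], g))
    for i, g in enumerate(null_genes[cfg.n_decoys:cfg.n_decoys + 10]):
        if other:
            links.append((other[i % len(other)], g))
    targets = pd.DataFrame(sorted(set(links)), columns=["mirna_id", "gene_id"])

    truth = TruthTable(
        gene_expr_class=expr_truth,
        mirna_concordant=pd.Series(
            [roles[s] == "concordant" for s in symbols],
            index=pd.Index([alias[s] for s in symbols], name="mirna_id")),
        triad_genes=set(triad))
    return expr, probe_to_gene, mirna_expr, targets, alias, truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimConfig
    beta: BetaMatrix
    annotation: ProbeAnnotation
    genome: dict[str, str]
    genes: pd.DataFrame
    expression: pd.DataFrame
    probe_to_gene: pd.Series
    mirna_expression: pd.DataFrame
    targets: pd.DataFrame
    alias: pd.Series
    truth: TruthTable


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate every pipeline input as one internally consistent study."""
    bm, ann, meth_truth = generate_methylation_series(cfg)
    genome, genes, genome_truth = generate_genome_with_cgis(cfg)
    expr, p2g, mirna_expr, targets, alias, expr_truth = generate_expression_tables(cfg)
    truth = TruthTable(
        probe_class=meth_truth.probe_class,
        gene_expr_class=expr_truth.gene_expr_class,
        gene_promoter_class=genome_truth.gene_promoter_class,
        mirna_concordant=expr_truth.mirna_concordant,
        triad_genes=expr_truth.triad_genes)
    return SyntheticStudy(config=cfg, beta=bm, annotation=ann, genome=genome,
                          genes=genes, expression=expr, probe_to_gene=p2g,
                          mirna_expression=mirna_expr, targets=targets,
                          alias=alias, truth=truth)


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in its standard on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "annotation": outdir / "probe_annotation.tsv",
        "refgene": outdir / "refGene.txt",
        "genome": outdir / "genome.fa",
        "expression": outdir / "expression.tsv",
        "probe_to_gene": outdir / "expression_probe_to_gene.tsv",
        "mirna_expression": outdir / "mirna_expression.tsv",
        "targets": outdir / "mirna_targets.tsv",
        "alias": outdir / "mirna_alias.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_beta_matrix(study.beta, paths["beta"], paths["detection_p"])
    write_probe_annotation(study.annotation, paths["annotation"])
    write_refgene(study.genes, paths["refgene"])
    write_fasta(study.genome, paths["genome"])
    write_matrix(study.expression, paths["expression"])
    study.probe_to_gene.rename_axis("probe_id").to_csv(paths["probe_to_gene"], sep="\t")
    write_matrix(study.mirna_expression, paths["mirna_expression"])
    study.targets.to_csv(paths["targets"], sep="\t", index=False)
    study.alias.rename_axis("symbol").to_csv(paths["alias"], sep="\t")
    study.truth.write(paths["truth"])
    cfg_dict = dataclasses.asdict(study.config)
    cfg_dict["passage_labels"] = list(cfg_dict["passage_labels"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    return paths


def load_study(indir: str | Path) -> SyntheticStudy:
    """Read a study bundle written by :func:`write_study` back from disk."""
    from .array_io import read_beta_matrix, read_matrix, read_probe_annotation
    import pyfaidx

    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        cfg_dict = yaml.safe_load(fh)
    cfg_dict["passage_labels"] = tuple(cfg_dict["passage_labels"])
    cfg = SimConfig(**cfg_dict)

    bm = read_beta_matrix(indir / "beta.tsv", indir / "detection_p.tsv")
    ann = read_probe_annotation(indir / "probe_annotation.tsv", dialect="simple")
    from .array_io import read_refgene
    genes = read_refgene(indir / "refGene.txt")
    fasta = pyfaidx.Fasta(str(indir / "genome.fa"))
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    expr = read_matrix(indir / "expression.tsv")
    p2g = pd.read_csv(indir / "expression_probe_to_gene.tsv", sep="\t",
                      index_col=0)["gene_id"]
    mirna_expr = read_matrix(indir / "mirna_expression.tsv")
    targets = pd.read_csv(indir / "mirna_targets.tsv", sep="\t")
    alias = pd.read_csv(indir / "mirna_alias.tsv", sep="\t", index_col=0)["mirna_id"]

    truth_df = pd.read_csv(indir / "truth.tsv", sep="\t")
    def _series(entity: str) -> pd.Series:
        sub = truth_df[truth_df["entity"] == entity]
        return pd.Series(sub["value"].to_numpy(), index=sub["id"].to_numpy())
    truth = TruthTable(
        probe_class=_series("probe"),
        gene_expr_class=_series("gene_expr"),
        gene_promoter_class=_series("gene_promoter"),
        mirna_concordant=_series("mirna_concordant") == "True",
        triad_genes=set(truth_df.loc[truth_df["entity"] == "triad_gene", "id"]))
    return SyntheticStudy(config=cfg, beta=bm, annotation=ann, genome=genome,
                          genes=genes, expression=expr, probe_to_gene=p2g,
                          mirna_expression=mirna_expr, targets=targets,
                          alias=alias, truth=truth)
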