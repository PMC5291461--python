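"""Readers and writers for the on-disk formats the pipeline consumes.

Formats supported:

* methylation-array probe annotation, either the Illumina 450K-manifest CSV
  dialect (``IlmnID``, ``CHR``, ``MAPINFO``, ``RELATION_TO_UCSC_CPG_ISLAND``,
  ``UCSC_REFGENE_NAME``, ``UCSC_REFGENE_GROUP``) or a tidy tab-separated
  "simple" dialect written by this package;
* UCSC ``refGene.txt`` gene models (16 tab-separated columns, no header);
* probes x samples matrices (β values, detection p-values, expression
  intensities) as tab-separated text with a header row of sample labels.

All coordinates are 0-based half-open internally; the manifest's 1-based
``MAPINFO`` is converted on read.  Readers are strict: malformed rows raise
:class:`~senemeth.errors.FormatError` naming the offending line, out-of-range
β values raise :class:`~senemeth.errors.ValidationError`, and blank cells are
parsed as missing — never as zero.  Gzip-compressed input is handled
transparently for every text format.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The six CpG-context subcategories (location relative to a CpG island).
CPG_CONTEXTS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: The six gene-feature subcategories carried by probe annotation; probes with
#: no gene annotation form the seventh, "Intergenic".
GENE_FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
INTERGENIC = "Intergenic"

# manifest spellings -> canonical context / feature names
_CONTEXT_ALIASES = {
    "Island": "Island", "N_Shore": "N_Shore", "S_Shore": "S_Shore",
    "N_Shelf": "N_Shelf", "S_Shelf": "S_Shelf", "OpenSea": "OpenSea",
    "": "OpenSea",  # the manifest leaves the relation blank for open sea
}
_FEATURE_ALIASES = {
    "TSS1500": "TSS1500", "TSS200": "TSS200",
    "5'UTR": "5UTR", "5UTR": "5UTR",
    "1stExon": "1stExon", "1st Exon": "1stExon",
    "Body": "Body", "3'UTR": "3UTR", "3UTR": "3UTR",
}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Probe-level annotation split into per-probe and per-(probe, gene) tables.

    ``probes`` is indexed by probe_id with columns ``chrom``, ``pos`` (0-based),
    ``strand`` and ``cpg_context``.  ``gene_features`` is a long table with one
    row per (probe_id, gene, feature) triple; probes absent from it are
    intergenic.
    """

    probes: pd.DataFrame
    gene_features: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "gene", "feature"]))

    def __post_init__(self) -> None:
        if self.probes.index.has_duplicates:
            dupes = self.probes.index[self.probes.index.duplicated()].unique()
            raise FormatError(f"duplicate probe_id(s): {list(dupes[:5])}")
        bad = set(self.probes["cpg_context"]) - set(CPG_CONTEXTS)
        if bad:
            raise FormatError(f"unknown CpG context value(s): {sorted(bad)}")
        if (self.probes["pos"] < 0).any():
            raise ValidationError("probe positions must be >= 0")
        bad_feat = set(self.gene_features["feature"]) - set(GENE_FEATURES)
        if bad_feat:
            raise FormatError(f"unknown gene feature value(s): {sorted(bad_feat)}")

    def refgene_names(self, probe_id: str) -> list[str]:
        """All gene symbols annotated to *probe_id* (may include MIR* symbols)."""
        sub = self.gene_features[self.gene_features["probe_id"] == probe_id]
        return sorted(sub["gene"].unique())

    @property
    def intergenic_probes(self) -> pd.Index:
        """Probes with no gene annotation — the seventh feature subcategory."""
        annotated = set(self.gene_features["probe_id"])
        return self.probes.index[~self.probes.index.isin(annotated)]

    def __len__(self) -> int:
        return len(self.probes)


def _explode_semicolon(cell: str) -> list[str]:
    if cell is None or cell == "" or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return str(cell).split(";")


def read_probe_annotation(path: str | Path, dialect: str = "simple") -> ProbeAnnotation:
    """Read a probe annotation table in the given *dialect*.

    ``illumina450k`` expects a comma-separated manifest with 1-based MAPINFO and
    semicolon-packed gene/feature columns (exploded to per-gene rows here);
    ``simple`` expects the tidy tab-separated layout written by
    :func:`write_probe_annotation` with 0-based positions.
    """
    if dialect not in ("illumina450k", "simple"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "illumina450k" else "\t"
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        ncol = len(header)
        col = {name: i for i, name in enumerate(header)}
        if dialect == "illumina450k":
            required = ["IlmnID", "CHR", "MAPINFO"]
        else:
            required = ["probe_id", "chrom", "pos", "strand", "cpg_context",
                        "genes", "features"]
        missing = [c for c in required if c not in col]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")

        probe_rows: list[tuple] = []
        gf_rows: list[tuple] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}")
            try:
                if dialect == "illumina450k":
                    pid = fields[col["IlmnID"]]
                    chrom = fields[col["CHR"]]
                    pos = int(fields[col["MAPINFO"]]) - 1  # 1-based -> 0-based
                    strand = fields[col["STRAND"]] if "STRAND" in col else "+"
                    raw_ctx = (fields[col["RELATION_TO_UCSC_CPG_ISLAND"]]
                               if "RELATION_TO_UCSC_CPG_ISLAND" in col else "")
                    genes = _explode_semicolon(
                        fields[col["UCSC_REFGENE_NAME"]] if "UCSC_REFGENE_NAME" in col else "")
                    feats = _explode_semicolon(
                        fields[col["UCSC_REFGENE_GROUP"]] if "UCSC_REFGENE_GROUP" in col else "")
                else:
                    pid = fields[col["probe_id"]]
                    chrom = fields[col["chrom"]]
                    pos = int(fields[col["pos"]])
                    strand = fields[col["strand"]]
                    raw_ctx = fields[col["cpg_context"]]
                    genes = _explode_semicolon(fields[col["genes"]])
                    feats = _explode_semicolon(fields[col["features"]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if raw_ctx not in _CONTEXT_ALIASES:
                raise FormatError(f"{path}:{lineno}: unknown CpG context {raw_ctx!r}")
            if len(genes) != len(feats):
                raise FormatError(
                    f"{path}:{lineno}: gene list and feature list lengths differ")
            probe_rows.append((pid, chrom, pos, strand, _CONTEXT_ALIASES[raw_ctx]))
            for g, f in zip(genes, feats):
                if f not in _FEATURE_ALIASES:
                    raise FormatError(f"{path}:{lineno}: unknown gene feature {f!r}")
                gf_rows.append((pid, g, _FEATURE_ALIASES[f]))

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "strand", "cpg_context"]
    ).set_index("probe_id")
    gene_features = pd.DataFrame(gf_rows, columns=["probe_id", "gene", "feature"])
    return ProbeAnnotation(probes=probes, gene_features=gene_features)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    """Write annotation in the tidy "simple" dialect (0-based positions)."""
    gf = ann.gene_features.groupby("probe_id").agg({
        "gene": lambda s: ";".join(s), "feature": lambda s: ";".join(s)})
    out = ann.probes.copy()
    out["genes"] = gf["gene"].reindex(out.index).fillna("")
    out["features"] = gf["feature"].reindex(out.index).fillna("")
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# beta matrices and generic matrices
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples β values in [0, 1] with per-entry detection p-values.

    Missing entries are NaN in both tables.  ``beta`` and ``detection_p`` share
    index (probe ids) and columns (sample labels).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index) or \
           not self.beta.columns.equals(self.detection_p.columns):
            raise ValidationError("beta and detection_p must share index and columns")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValidationError("beta values must lie in [0, 1]")
        pvals = self.detection_p.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(pvals, initial=0.0) < 0 or np.nanmax(pvals, initial=0.0) > 1:
                raise ValidationError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.beta.columns)

    def subset(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[probe_ids], self.detection_p.loc[probe_ids])


def read_matrix(path: str | Path, value_range: tuple[float, float] | None = None
                ) -> pd.DataFrame:
    """Read a tab-separated probes x samples matrix.

    The first row holds sample labels, the first column row identifiers.  Blank
    cells become NaN (missing).  Ragged rows raise :class:`FormatError`; values
    outside *value_range* (when given) raise :class:`ValidationError`.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.rstrip("\n") and len(line.rstrip("\n").split("\t")) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: ragged row (expected {ncol} fields)")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="raise")
    if value_range is not None:
        lo, hi = value_range
        vals = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=lo) < lo or np.nanmax(vals, initial=hi) > hi:
                raise ValidationError(
                    f"{path}: values outside [{lo}, {hi}]")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id", na_rep="")


def read_beta_matrix(beta_path: str | Path, detection_p_path: str | Path) -> BetaMatrix:
    """Read the β-value and detection-p matrices that together form a BetaMatrix."""
    beta = read_matrix(beta_path, value_range=(0.0, 1.0))
    detp = read_matrix(detection_p_path, value_range=(0.0, 1.0))
    return BetaMatrix(beta=beta, detection_p=detp)


def write_beta_matrix(bm: BetaMatrix, beta_path: str | Path,
                      detection_p_path: str | Path) -> None:
    write_matrix(bm.beta, beta_path)
    write_matrix(bm.detection_p, detection_p_path)


# ---------------------------------------------------------------------------
# refGene gene models
# ---------------------------------------------------------------------------

_REFGENE_COLUMNS = [
    "bin", "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
    "exonCount", "exonStarts", "exonEnds", "score", "name2", "cdsStartStat",
    "cdsEndStat", "exonFrames",
]


def read_refgene(path: str | Path) -> pd.DataFrame:
    """Read gene models in UCSC refGene.txt layout (16 columns, no header).

    Returns one row per transcript with columns ``gene_id`` (RefSeq accession),
    ``symbol``, ``chrom``, ``strand``, ``txStart``, ``txEnd``, ``tss`` and
    ``placed``.  The TSS is txStart on the + strand and txEnd − 1 on the −
    strand (0-based).  Duplicate accessions (isoforms) are retained as distinct
    TSS candidates.  Records on unplaced contigs (chromosome names containing
    "_") are kept but flagged ``placed = False``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_REFGENE_COLUMNS,
                     dtype={"chrom": str, "strand": str})
    if (df["txStart"] >= df["txEnd"]).any():
        bad = df.loc[df["txStart"] >= df["txEnd"], "name"].tolist()
        raise FormatError(f"{path}: txStart >= txEnd for {bad[:5]}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    out = pd.DataFrame({
        "gene_id": df["name"],
        "symbol": df["name2"],
        "chrom": df["chrom"],
        "strand": df["strand"],
        "txStart": df["txStart"],
        "txEnd": df["txEnd"],
    })
    out["tss"] = np.where(out["strand"] == "+", out["txStart"], out["txEnd"] - 1)
    out["placed"] = ~out["chrom"].str.contains("_")
    return out


def write_refgene(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models back out in the 16-column refGene.txt layout."""
    n = len(genes)
    df = pd.DataFrame({
        "bin": np.zeros(n, dtype=int),
        "name": genes["gene_id"].to_numpy(),
        "chrom": genes["chrom"].to_numpy(),
        "strand": genes["strand"].to_numpy(),
        "txStart": genes["txStart"].to_numpy(),
        "txEnd": genes["txEnd"].to_numpy(),
        "cdsStart": genes["txStart"].to_numpy(),
        "cdsEnd": genes["txEnd"].to_numpy(),
        "exonCount": np.ones(n, dtype=int),
        "exonStarts": [f"{s}," for s in genes["txStart"]],
        "exonEnds": [f"{e}," for e in genes["txEnd"]],
        "score": np.zeros(n, dtype=int),
        "name2": genes["symbol"].to_numpy(),
        "cdsStartStat": ["cmpl"] * n,
        "cdsEndStat": ["cmpl"] * n,
        "exonFrames": ["0,"] * n,
    })
    df.to_csv(path, sep="\t", header=False, index=False)
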