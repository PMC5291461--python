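"""Sequence-based CGI / non-CGI promoter classification.

A promoter window around each TSS is scored by base composition:

* GC fraction   gc = (#C + #G) / L
* CpG observed/expected ratio (Gardiner-Garden convention)
  oe = (#CpG dinucleotides × L) / (#C × #G)

with L the effective window length (N bases excluded).  A promoter is a CGI
promoter iff gc ≥ 0.5 AND oe ≥ 0.6 (inclusive); otherwise non-CGI.  Both
statistics are strand-symmetric — CpG is its own reverse complement — so a
window and its reverse complement always classify identically.

The promoter extent defaults to [TSS − 1000, TSS + 500) on the + strand,
mirrored on the − strand, clipped at contig bounds; the extent is a free
parameter of the analysis and is configurable and reported in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

CLASS_CGI = "CGI"
CLASS_NONCGI = "nonCGI"


@dataclass(frozen=True)
class PromoterWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(f"invalid window [{self.start}, {self.end})")


def promoter_window(chrom: str, tss: int, strand: str, upstream: int = 1000,
                    downstream: int = 500, contig_length: int | None = None
                    ) -> PromoterWindow:
    """Promoter window around a TSS, mirrored by strand and clipped to the contig.

    On the + strand the window is [tss − upstream, tss + downstream); on the −
    strand the mirror [tss − downstream, tss + upstream + 1), so upstream still
    means 5' of the gene.  Windows falling entirely outside the contig raise.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream + 1
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    start = max(start, 0)
    if contig_length is not None:
        end = min(end, contig_length)
    if end <= start:
        raise ValidationError(
            f"promoter window for tss {tss} ({strand}) lies outside the contig")
    return PromoterWindow(chrom=chrom, start=start, end=end)


def gc_oe(sequence: str) -> tuple[float, float]:
    """GC fraction and CpG observed/expected ratio of a sequence.

    Case-insensitive; soft-masked (lowercase) bases count.  N bases are
    excluded from the effective length and break CpG dinucleotides.  When
    #C = 0 or #G = 0 the O/E ratio is defined as 0.
    """
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    eff_len = len(seq) - seq.count("N")
    if eff_len == 0:
        raise ValidationError("all-N (or empty) window: composition undefined")
    gc = (n_c + n_g) / eff_len
    oe = (n_cg * eff_len) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def classify_promoter(sequence: str, gc_min: float = 0.5, oe_min: float = 0.6,
                      max_n_frac: float = 0.5) -> tuple[float, float, str]:
    """(gc, oe, class) for one promoter sequence; thresholds are inclusive."""
    if len(sequence) == 0:
        raise ValidationError("empty promoter sequence")
    if sequence.upper().count("N") / len(sequence) > max_n_frac:
        raise ValidationError("promoter window exceeds the allowed N fraction")
    gc, oe = gc_oe(sequence)
    cls = CLASS_CGI if (gc >= gc_min and oe >= oe_min) else CLASS_NONCGI
    return gc, oe, cls


def classify_promoters(genes: pd.DataFrame, fasta, upstream: int = 1000,
                       downstream: int = 500, gc_min: float = 0.5,
                       oe_min: float = 0.6) -> pd.DataFrame:
    """Classify every gene's promoter from a genome FASTA.

    *genes* needs columns gene_id, chrom, strand and tss; *fasta* is a
    ``pyfaidx.Fasta`` (or any mapping of contig name to sliceable sequence with
    ``len``).  Returns a table indexed by gene_id with the window coordinates,
    gc_fraction, oe_ratio and promoter_class.
    """
    rows = []
    for rec in genes.itertuples(index=False):
        contig = fasta[rec.chrom]
        win = promoter_window(rec.chrom, int(rec.tss), rec.strand,
                              upstream=upstream, downstream=downstream,
                              contig_length=len(contig))
        seq = str(contig[win.start:win.end])
        gc, oe, cls = classify_promoter(seq, gc_min=gc_min, oe_min=oe_min)
        rows.append((rec.gene_id, rec.chrom, win.start, win.end, gc, oe, cls))
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "gc_fraction", "oe_ratio",
        "promoter_class"]).set_index("gene_id")
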