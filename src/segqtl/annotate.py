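"""Gene-level annotation of QTL intervals from a GFF3 annotation."""

from __future__ import annotations

import gffutils
import pandas as pd

from .intervals import QTLInterval, central_subinterval


def read_gff(path: str) -> pd.DataFrame:
    """Load gene records from GFF3 into a frame.

    Columns: name (systematic), standard_name (gene symbol if annotated),
    chrom, start, end (1-based inclusive), strand.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("ID", [gene.id])[0]
        std = gene.attributes.get("gene", gene.attributes.get("Name", [name]))[0]
        rows.append((name, std, gene.seqid, gene.start, gene.end, gene.strand))
    df = pd.DataFrame(
        rows, columns=["name", "standard_name", "chrom", "start", "end", "strand"]
    )
    if df["name"].duplicated().any():
        raise ValueError("duplicate gene names in annotation")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_qtls(
    intervals: list[QTLInterval],
    genes: pd.DataFrame,
    central_fraction: float | None = None,
) -> list[tuple[QTLInterval, pd.DataFrame]]:
    """Genes overlapping each interval (any shared base, 1-based inclusive).

    With ``central_fraction`` set, genes are listed for the central
    sub-interval only — the conventional "center of the locus" report.
    Chromosome names of the intervals must all exist in the annotation.
    """
    known = set(genes["chrom"])
    missing = sorted({iv.chrom for iv in intervals} - known)
    if missing:
        raise ValueError(f"chromosomes absent from annotation: {', '.join(missing)}")
    out = []
    for iv in intervals:
        region = central_subinterval(iv, central_fraction) if central_fraction else iv
        hits = genes[
            (genes["chrom"] == region.chrom)
            & (genes["start"] <= region.end)
            & (genes["end"] >= region.start)
        ].sort_values("start")
        out.append((iv, hits.reset_index(drop=True)))
    return out
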