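"""Readers and writers for the pipeline's on-disk formats.

Text formats only: TSV for counts/frequencies/phenotypes/intervals, VCF
(via pysam) for the parental marker table and per-sample allele depths, BED
(0-based half-open) and bedGraph-style tracks for genome intervals, GFF3
(via gffutils, read-only) for gene annotation.  Interval TSVs keep 1-based
inclusive coordinates; BED exports convert.  Every writer accepts a
``meta`` mapping emitted as ``# key=value`` header lines so outputs carry
their config hash and seed.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .counts import AlleleCountMatrix
from .genome import GenomeLayout, HaplotypeMosaic, label_name
from .individual import AveragedLinkageTrack, ParentOfOriginTrack
from .intervals import QTLInterval


def _write_header(fh, meta: Mapping[str, object] | None) -> None:
    for key, value in (meta or {}).items():
        fh.write(f"# {key}={value}\n")


def _write_tsv(df: pd.DataFrame, path: str, meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, meta)
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# allele counts


def write_counts_tsv(
    counts: AlleleCountMatrix, path: str, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(counts.to_frame(), path, meta)


def read_counts_tsv(path: str) -> AlleleCountMatrix:
    long = _read_tsv(path)
    samples = list(dict.fromkeys(long["sample"]))  # preserve order
    markers = (
        long[long["sample"] == samples[0]][["chrom", "pos"]].reset_index(drop=True)
    )
    n = len(markers)
    sup = np.empty((n, len(samples)), dtype=np.int64)
    inf = np.empty_like(sup)
    qual = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        grp = long[long["sample"] == s]
        sup[:, j] = grp["superior_count"].to_numpy()
        inf[:, j] = grp["inferior_count"].to_numpy()
        qual[:, j] = grp["mean_phred"].to_numpy()
    return AlleleCountMatrix(
        markers=markers,
        samples=samples,
        sup=sup,
        inf=inf,
        qual=qual,
        mask=np.zeros((n, len(samples)), dtype=bool),
    )


# ---------------------------------------------------------------------------
# marker tables (TSV and minimal VCF)


def write_markers_tsv(
    markers: pd.DataFrame, path: str, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(markers, path, meta)


def read_markers_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path)


def write_markers_vcf(markers: pd.DataFrame, layout: GenomeLayout, path: str) -> None:
    """Minimal VCFv4.2: two haploid samples; REF = inferior allele, ALT =
    superior allele, superior parent GT=1, inferior GT=0."""
    header = pysam.VariantHeader()
    for chrom, length in zip(layout.names, layout.lengths):
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("superior")
    header.add_sample("inferior")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for row in markers.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.inferior_allele, row.superior_allele),
            )
            rec.samples["superior"]["GT"] = (1,)
            rec.samples["inferior"]["GT"] = (0,)
            vcf.write(rec)


def read_markers_vcf(path: str) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            gt_sup = rec.samples["superior"]["GT"][0]
            alleles = rec.alleles
            rows.append(
                (
                    rec.contig,
                    rec.pos,
                    alleles[gt_sup],
                    alleles[1 - gt_sup],
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "superior_allele", "inferior_allele"])


def read_counts_vcf(path: str, roles: Mapping[str, str]) -> AlleleCountMatrix:
    """Allele-depth VCF -> count matrix, using a sample-role manifest.

    ``roles`` maps roles to sample names and must name the ``superior`` and
    ``inferior`` parents; the parents' GT fields orient which allele's
    depth is the superior count at each site.  All samples in the file
    become columns.
    """
    for need in ("superior", "inferior"):
        if need not in roles:
            raise ValueError(f"sample-role manifest lacks the {need!r} parent")
    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        sup_cols, inf_cols, qual_cols = [], [], []
        for rec in vcf:
            gt_sup = rec.samples[roles["superior"]]["GT"][0]
            ad = {s: rec.samples[s].get("AD") for s in samples}
            rows.append((rec.contig, rec.pos))
            sup_cols.append([a[gt_sup] if a is not None else 0 for a in ad.values()])
            inf_cols.append([a[1 - gt_sup] if a is not None else 0 for a in ad.values()])
            qual_cols.append([rec.qual if rec.qual is not None else 0.0] * len(samples))
    markers = pd.DataFrame(rows, columns=["chrom", "pos"])
    return AlleleCountMatrix(
        markers=markers,
        samples=samples,
        sup=np.array(sup_cols, dtype=np.int64),
        inf=np.array(inf_cols, dtype=np.int64),
        qual=np.array(qual_cols, dtype=float),
        mask=np.zeros((len(markers), len(samples)), dtype=bool),
    )


def write_counts_vcf(
    counts: AlleleCountMatrix, markers: pd.DataFrame, layout: GenomeLayout, path: str
) -> None:
    """Per-sample allele depths as a minimal VCF (haploid GT + AD)."""
    header = pysam.VariantHeader()
    for chrom, length in zip(layout.names, layout.lengths):
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in counts.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, row in enumerate(markers.itertuples(index=False)):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.inferior_allele, row.superior_allele),
            )
            for j, s in enumerate(counts.samples):
                sup, inf = int(counts.sup[i, j]), int(counts.inf[i, j])
                rec.samples[s]["AD"] = (inf, sup)
                rec.samples[s]["GT"] = (1,) if sup >= inf else (0,)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# intervals


def write_intervals_tsv(
    intervals: Iterable[QTLInterval], path: str, meta: Mapping[str, object] | None = None
) -> None:
    df = pd.DataFrame(
        [
            (iv.chrom, iv.start, iv.end, iv.peak, iv.direction, iv.tier, iv.peak_value)
            for iv in intervals
        ],
        columns=["chrom", "start", "end", "peak", "direction", "tier", "peak_value"],
    )
    _write_tsv(df, path, meta)


def read_intervals_tsv(path: str) -> list[QTLInterval]:
    df = _read_tsv(path)
    return [
        QTLInterval(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            peak=int(row.peak),
            direction=row.direction,
            tier=row.tier,
            peak_value=float(row.peak_value),
        )
        for row in df.itertuples(index=False)
    ]


def write_intervals_bed(
    intervals: Iterable[QTLInterval], path: str, meta: Mapping[str, object] | None = None
) -> None:
    """0-based half-open BED describing the same base sets as the TSV."""
    with open(path, "w") as fh:
        _write_header(fh, meta)
        for iv in intervals:
            name = f"{iv.tier}:{iv.direction}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def read_intervals_bed(path: str) -> list[QTLInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            tier, direction = name.split(":")
            s, e = int(start) + 1, int(end)
            out.append(
                QTLInterval(
                    chrom=chrom, start=s, end=e, peak=(s + e) // 2,
                    direction=direction, tier=tier,
                )
            )
    return out


# ---------------------------------------------------------------------------
# tracks, phenotypes, truth


def write_track_bedgraph(
    track: "ParentOfOriginTrack | AveragedLinkageTrack",
    path: str,
    meta: Mapping[str, object] | None = None,
) -> None:
    values = track.calls if isinstance(track, ParentOfOriginTrack) else track.values
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("chrom\tstart\tend\tvalue\n")
        for chrom in track.layout.names:
            starts = track.window_starts(chrom)
            length = track.layout.length_of(chrom)
            for s, v in zip(starts, values[chrom]):
                e = min(s + track.window - 1, length)
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{v:g}\n")


def read_track_bedgraph(path: str) -> pd.DataFrame:
    return _read_tsv(path)


def write_phenotypes_tsv(
    ids: Iterable[str],
    scores: Iterable[float],
    path: str,
    meta: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame({"segregant": list(ids), "score": list(scores)})
    _write_tsv(df, path, meta)


def read_phenotypes_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path)


def write_truth_bed(
    mosaic: HaplotypeMosaic, path: str, meta: Mapping[str, object] | None = None
) -> None:
    """True parental blocks of one segregant as BED (0-based half-open)."""
    with open(path, "w") as fh:
        _write_header(fh, meta)
        for chrom in mosaic.layout.names:
            start = 0
            for e, l in zip(mosaic.ends[chrom], mosaic.labels[chrom]):
                fh.write(f"{chrom}\t{start}\t{int(e)}\t{label_name(int(l))}\n")
                start = int(e)


def write_frequency_tsv(
    freq: pd.DataFrame, path: str, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(freq, path, meta)


def write_curve_tsv(curve, path: str, meta: Mapping[str, object] | None = None) -> None:
    header = dict(meta or {})
    header["bandwidth"] = curve.bandwidth
    header["alpha"] = curve.alpha
    _write_tsv(curve.data, path, header)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
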