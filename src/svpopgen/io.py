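"""Readers and writers for the SV-VCF dialect, BED-like tables, and metadata.

The VCF dialect is the merged multi-sample convention produced by multi-caller
SV pipelines: one biallelic record per locus with ``SVTYPE`` and ``END`` (or
``SVLEN`` for insertions) in INFO and diploid ``GT`` fields.  VCF coordinates
(1-based inclusive) are preserved on :class:`~svpopgen.types.SvRecord`;
interval arithmetic converts at the boundary.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
from cyvcf2 import VCF

from .types import (
    MISSING,
    SV_TYPES,
    GeneModel,
    Genome,
    GenomicInterval,
    IntervalSet,
    Metadata,
    QtlRecord,
    SampleMeta,
    SvRecord,
    SvSet,
)


class SvVcfError(ValueError):
    """Record-level VCF parsing failure; carries the offending record ids."""

    def __init__(self, message: str, record_ids: list[str] | None = None) -> None:
        super().__init__(message)
        self.record_ids = record_ids or []


def read_sv_vcf(path: Union[str, os.PathLike]) -> SvSet:
    """Parse an SV VCF into an :class:`SvSet`.

    Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Records lacking SVTYPE, or lacking both END and SVLEN, or with an unknown
    SV type, a non-biallelic ALT, or non-diploid GT are rejected with an
    error listing the offending ids.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[SvRecord] = []
    columns: list[np.ndarray] = []
    errors: list[str] = []
    for i, v in enumerate(vcf):
        rid = v.ID or f"record_{i + 1}"
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            errors.append(f"{rid}: missing SVTYPE")
            continue
        if svtype not in SV_TYPES:
            errors.append(f"{rid}: unknown svtype {svtype!r}")
            continue
        start = v.POS
        info_end = v.INFO.get("END")
        svlen = v.INFO.get("SVLEN")
        if svtype == "INS":
            if svlen is None:
                errors.append(f"{rid}: INS without SVLEN")
                continue
            end = start
            length = abs(int(svlen))
        else:
            if info_end is None:
                errors.append(f"{rid}: missing END")
                continue
            end = int(info_end)
            # SVLEN, when present, is authoritative (a TRA breakend pair has a
            # 1-bp span but carries the event length); else the span length
            length = abs(int(svlen)) if svlen is not None else end - start + 1
        if v.ALT and len(v.ALT) > 1:
            errors.append(f"{rid}: multiallelic record (split upstream)")
            continue
        chrom2 = v.INFO.get("CHR2")
        pos2 = v.INFO.get("POS2")
        col = np.empty(len(samples), dtype=np.int8)
        gt_err = False
        for s, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if len(alleles) != 2:
                errors.append(f"{rid}: non-diploid GT for sample {samples[s]}")
                gt_err = True
                break
            if alleles[0] < 0 or alleles[1] < 0:
                col[s] = MISSING
            else:
                col[s] = alleles[0] + alleles[1]
        if gt_err:
            continue
        records.append(
            SvRecord(
                id=rid,
                chrom=v.CHROM,
                start=start,
                end=end,
                svtype=svtype,
                length=length,
                chrom2=chrom2,
                pos2=int(pos2) if pos2 is not None else None,
            )
        )
        columns.append(col)
    vcf.close()
    if errors:
        raise SvVcfError(
            f"{len(errors)} malformed SV record(s): " + "; ".join(errors[:10]),
            record_ids=[e.split(":")[0] for e in errors],
        )
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return SvSet(records, geno, samples)


def write_sv_vcf(svset: SvSet, path: Union[str, os.PathLike], genome: Genome | None = None) -> None:
    """Write an :class:`SvSet` as a VCF 4.2 text file.

    Contig headers come from ``genome`` when given, else from the loci
    themselves (length = max end seen, padded).
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    if genome is not None:
        contigs = dict(genome.chroms)
    else:
        contigs = {}
        for r in svset.records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1)
            if r.chrom2 is not None:
                contigs[r.chrom2] = max(contigs.get(r.chrom2, 0), (r.pos2 or 0) + 1)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svpopgen",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome of a translocation">',
        '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position of a translocation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted(contigs):
        lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(svset.samples)
    )
    for j, r in enumerate(svset.records):
        info = [f"SVTYPE={r.svtype}", f"END={r.end}", f"SVLEN={r.length}"]
        if r.chrom2 is not None and r.pos2 is not None:
            info += [f"CHR2={r.chrom2}", f"POS2={r.pos2}"]
        gts = "\t".join(gt_str[int(g)] for g in svset.genotypes[:, j])
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.id}\tN\t<{r.svtype}>\t.\tPASS\t"
            + ";".join(info)
            + f"\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


MAX_QTL_SPAN = 5_000_000  # QTL intervals larger than 5 Mb are excluded


def read_interval_table(path: Union[str, os.PathLike], dialect: str):
    """Read a BED-like table.

    Dialects:

    ``bed`` / ``peak``
        BED3+ -> :class:`IntervalSet` (column 4, when present, is the name).
    ``gene``
        BED12 -> list of :class:`GeneModel`; exon blocks from
        blockSizes/blockStarts, CDS bounds from thickStart/thickEnd.
    ``qtl``
        TSV ``chrom  start  end  trait`` -> ``(list[QtlRecord], n_removed)``
        after dropping intervals longer than 5 Mb.
    """
    if dialect not in ("bed", "peak", "gene", "qtl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append([str(lineno)] + line.split("\t"))

    def _coords(row: list[str]) -> tuple[int, str, int, int]:
        lineno = int(row[0])
        chrom, start, end = row[1], int(row[2]), int(row[3])
        if end <= start:
            raise ValueError(f"line {lineno}: end {end} <= start {start}")
        return lineno, chrom, start, end

    if dialect in ("bed", "peak"):
        out = []
        for row in rows:
            _, chrom, start, end = _coords(row)
            name = row[4] if len(row) > 4 else None
            out.append(GenomicInterval(chrom, start, end, name=name))
        return IntervalSet(out)

    if dialect == "qtl":
        kept, removed = [], 0
        for row in rows:
            lineno, chrom, start, end = _coords(row)
            if len(row) < 5:
                raise ValueError(f"line {lineno}: qtl dialect requires a trait column")
            if end - start > MAX_QTL_SPAN:
                removed += 1
                continue
            kept.append(QtlRecord(GenomicInterval(chrom, start, end), trait=row[4]))
        return kept, removed

    genes = []
    for row in rows:
        lineno, chrom, start, end = _coords(row)
        if len(row) < 13:
            raise ValueError(
                f"line {lineno}: gene dialect requires 12 BED columns (exon blocks)"
            )
        name, strand = row[4], row[6]
        thick_s, thick_e = int(row[7]), int(row[8])
        n_blocks = int(row[10])
        sizes = [int(x) for x in row[11].rstrip(",").split(",")]
        starts = [int(x) for x in row[12].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"line {lineno}: blockCount does not match block lists")
        exons = tuple(
            sorted((start + off, start + off + size) for off, size in zip(starts, sizes))
        )
        cds_s, cds_e = (thick_s, thick_e) if thick_e > thick_s else (None, None)
        genes.append(
            GeneModel(
                gene_id=name,
                chrom=chrom,
                tx_start=start,
                tx_end=end,
                strand=strand,
                exons=exons,
                cds_start=cds_s,
                cds_end=cds_e,
            )
        )
    return genes


def write_bed(intervals: IntervalSet, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for g in intervals:
            name = g.name if g.name is not None else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{name}\n")


def read_sample_metadata(path: Union[str, os.PathLike]) -> Metadata:
    """Read a TSV with columns sample_id, population, group, species."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        required = ("sample_id", "population", "group", "species")
        missing = [c for c in required if c not in idx]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                SampleMeta(
                    sample_id=f[idx["sample_id"]],
                    population=f[idx["population"]],
                    group=f[idx["group"]],
                    species=f[idx["species"]],
                )
            )
    return Metadata(rows)


def write_sample_metadata(meta: Metadata, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\tgroup\tspecies\n")
        for r in meta:
            fh.write(f"{r.sample_id}\t{r.population}\t{r.group}\t{r.species}\n")


def read_genome(path: Union[str, os.PathLike]) -> Genome:
    """Read a two-column chrom/length TSV (faidx-style first two columns)."""
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            chroms[f[0]] = int(f[1])
    return Genome(chroms)


def write_genome(genome: Genome, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chroms.items():
            fh.write(f"{chrom}\t{length}\n")


def read_ortholog_map(path: Union[str, os.PathLike]) -> list[tuple[str, str]]:
    """Read a two-column gene-symbol ortholog table, one pair per line."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                raise ValueError(f"ortholog map line lacks two columns: {line!r}")
            pairs.append((f[0], f[1]))
    return pairs
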