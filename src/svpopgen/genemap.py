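"""SV-to-gene annotation into seven genic categories and gene-set summaries.

Categories: intergenic, intronic, exonic, upstream (2 kb 5' of the gene,
strand-aware), downstream (2 kb 3'), 3' UTR and 5' UTR.  Assignment is by
positional overlap (>= 1 bp) with each feature span; an SV spanning several
features of one or more genes carries every matching category simultaneously.
An SV is intergenic only if it touches no gene feature and no 2-kb flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .types import GeneModel, SvSet

CATEGORIES = ("intergenic", "intronic", "exonic", "upstream", "downstream", "utr3", "utr5")

FLANK = 2_000  # bp, the upstream/downstream window


@dataclass
class GenicAnnotation:
    """Per-SV category sets and per-category gene hits."""

    sv_categories: dict[str, set[str]] = field(default_factory=dict)
    genes_by_category: dict[str, set[str]] = field(default_factory=dict)
    sv_genes: dict[str, set[str]] = field(default_factory=dict)  # sv_id -> gene ids

    def category_incidence(self) -> dict[str, int]:
        """Number of SVs carrying each category (an SV may count in several)."""
        out = {c: 0 for c in CATEGORIES}
        for cats in self.sv_categories.values():
            for c in cats:
                out[c] += 1
        return out


def _gene_features(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Category -> half-open spans for one gene (strand-aware flanks)."""
    utr5, utr3 = gene.utr_spans()
    if gene.strand == "+":
        up = (max(0, gene.tx_start - FLANK), gene.tx_start)
        down = (gene.tx_end, gene.tx_end + FLANK)
    else:
        up = (gene.tx_end, gene.tx_end + FLANK)
        down = (max(0, gene.tx_start - FLANK), gene.tx_start)
    feats = {
        "exonic": list(gene.exons),
        "intronic": gene.introns(),
        "upstream": [up] if up[1] > up[0] else [],
        "downstream": [down] if down[1] > down[0] else [],
        "utr5": utr5,
        "utr3": utr3,
    }
    return feats


def classify_genic_regions(svset: SvSet, genes: list[GeneModel]) -> GenicAnnotation:
    """Assign the seven genic categories to every SV.

    Genes without exons are treated as a single exon covering the span (with a
    notice).  Per-gene hit lists are accumulated per category.
    """
    fixed_genes = []
    for g in genes:
        if not g.exons:
            warnings.warn(
                f"gene {g.gene_id} has no exons; using its span as one exon",
                stacklevel=2,
            )
            g = GeneModel(
                g.gene_id, g.chrom, g.tx_start, g.tx_end, g.strand,
                exons=((g.tx_start, g.tx_end),),
                cds_start=g.cds_start, cds_end=g.cds_end,
            )
        fixed_genes.append(g)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in fixed_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.tx_start)

    ann = GenicAnnotation(
        genes_by_category={c: set() for c in CATEGORIES},
    )
    for r in svset.records:
        iv = r.interval
        cats: set[str] = set()
        hit_genes: set[str] = set()
        for g in by_chrom.get(iv.chrom, []):
            if g.tx_start - FLANK >= iv.end:
                break
            if g.tx_end + FLANK <= iv.start:
                continue
            for cat, spans in _gene_features(g).items():
                for s, e in spans:
                    if min(e, iv.end) > max(s, iv.start):
                        cats.add(cat)
                        hit_genes.add(g.gene_id)
                        ann.genes_by_category[cat].add(g.gene_id)
                        break
        if not cats:
            cats = {"intergenic"}
        ann.sv_categories[r.id] = cats
        ann.sv_genes[r.id] = hit_genes
    return ann


@dataclass
class SvGeneSummary:
    """Gene-level summary of an annotation."""

    n_genes: int
    n_sv_genes: int
    n_nonsv_genes: int
    n_exonic_genes: int
    n_intronic_genes: int
    pct_exonic: float
    pct_intronic: float
    intron_exon_ratio: float


def intron_exon_gene_ratio(n_intronic_genes: int, n_exonic_genes: int) -> float:
    """Ratio of genes with intronic SVs to genes with exonic SVs."""
    if n_exonic_genes == 0:
        return float("nan")
    return n_intronic_genes / n_exonic_genes


def sv_gene_summary(ann: GenicAnnotation, all_genes: list[str]) -> SvGeneSummary:
    """Counts of SV-genes, exon/intron-hit genes, and the intron/exon ratio.

    Percentages are over the SV-gene total; the ratio is undefined (NaN and
    flagged by a warning) when no gene has exonic SVs.
    """
    sv_genes = set().union(*ann.sv_genes.values()) if ann.sv_genes else set()
    n_sv = len(sv_genes)
    n_ex = len(ann.genes_by_category["exonic"])
    n_in = len(ann.genes_by_category["intronic"])
    if n_sv == 0:
        warnings.warn("no SV-genes: summary ratios undefined", stacklevel=2)
    return SvGeneSummary(
        n_genes=len(all_genes),
        n_sv_genes=n_sv,
        n_nonsv_genes=len(set(all_genes) - sv_genes),
        n_exonic_genes=n_ex,
        n_intronic_genes=n_in,
        pct_exonic=100.0 * n_ex / n_sv if n_sv else float("nan"),
        pct_intronic=100.0 * n_in / n_sv if n_sv else float("nan"),
        intron_exon_ratio=intron_exon_gene_ratio(n_in, n_ex),
    )


def annotation_table(ann: GenicAnnotation) -> pd.DataFrame:
    """Tidy per-SV table: one row per SV with semicolon-joined categories."""
    rows = [
        {
            "sv_id": sv,
            "categories": ";".join(sorted(cats)),
            "genes": ";".join(sorted(ann.sv_genes.get(sv, ()))),
        }
        for sv, cats in sorted(ann.sv_categories.items())
    ]
    return pd.DataFrame(rows)
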