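"""Core domain types for structural-variant (SV) population genomics.

Coordinate conventions
----------------------
``SvRecord`` carries VCF-style 1-based inclusive ``start``/``end`` exactly as
parsed; every interval operation goes through :attr:`SvRecord.interval`, which
converts to the internal BED-style 0-based half-open convention
``[start - 1, end)``.  Insertions are points: ``end == start`` and the
half-open span has length 1 (the insertion site base).

Genotypes are diploid alternate-allele dosages ``{0, 1, 2}`` with the
dedicated sentinel :data:`MISSING` (never 0) for uncalled genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

#: Genotype sentinel for a missing (uncalled) diploid genotype.
MISSING: int = -1

#: Closed vocabulary of SV types.
SV_TYPES = ("DEL", "DUP", "INV", "INS", "TRA")

#: Closed vocabulary of domestication groups.
GROUPS = ("wild", "native", "improved")


@dataclass(frozen=True)
class SvRecord:
    """One SV locus.

    ``start``/``end`` are 1-based inclusive (VCF convention).  ``length`` is
    the inserted length for INS and ``end - start + 1`` otherwise.  TRA loci
    are single records with one genotype column; the partner breakend, when
    known, lives in ``chrom2``/``pos2``.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    chrom2: Optional[str] = None
    pos2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"SV {self.id}: unknown svtype {self.svtype!r}")
        if self.start < 1:
            raise ValueError(f"SV {self.id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"SV {self.id}: end {self.end} < start {self.start}")
        if self.length < 1:
            raise ValueError(f"SV {self.id}: length must be >= 1, got {self.length}")

    @property
    def interval(self) -> "GenomicInterval":
        """0-based half-open span; INS collapses to the 1-bp insertion site."""
        if self.svtype == "INS":
            return GenomicInterval(self.chrom, self.start - 1, self.start, name=self.id)
        return GenomicInterval(self.chrom, self.start - 1, self.end, name=self.id)

    def breakpoints(self) -> list[tuple[str, int]]:
        """Breakpoint positions (0-based) used for density counting.

        DEL/DUP/INV contribute both ends, INS one, TRA one per involved
        chromosome.
        """
        if self.svtype == "INS":
            return [(self.chrom, self.start - 1)]
        if self.svtype == "TRA":
            pts = [(self.chrom, self.start - 1)]
            if self.chrom2 is not None and self.pos2 is not None:
                pts.append((self.chrom2, self.pos2 - 1))
            return pts
        return [(self.chrom, self.start - 1), (self.chrom, self.end - 1)]


def _record_sort_key(rec: SvRecord) -> tuple:
    return (rec.chrom, rec.start, rec.end, rec.id)


class SvSet:
    """An ordered set of SV loci with a diploid genotype matrix.

    Parameters
    ----------
    records
        SV loci; stored sorted by ``(chrom, start, end, id)``.
    genotypes
        ``(n_samples, n_loci)`` integer matrix of alt dosages with
        :data:`MISSING` for uncalled genotypes; columns follow record order.
    samples
        Sample identifiers, one per matrix row.
    """

    def __init__(
        self,
        records: Sequence[SvRecord],
        genotypes: np.ndarray,
        samples: Sequence[str],
    ) -> None:
        records = list(records)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D [samples x loci]")
        if genotypes.shape != (len(samples), len(records)):
            raise ValueError(
                f"genotype matrix {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(records)} loci"
            )
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"genotypes contain values outside {{0,1,2,{MISSING}}}")
        order = sorted(range(len(records)), key=lambda i: _record_sort_key(records[i]))
        self.records: list[SvRecord] = [records[i] for i in order]
        self.genotypes: np.ndarray = genotypes[:, order]
        self.samples: list[str] = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=np.int64)

    def subset_loci(self, mask_or_index) -> "SvSet":
        idx = np.arange(self.n_loci)[mask_or_index]
        return SvSet(
            [self.records[i] for i in idx], self.genotypes[:, idx], self.samples
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "SvSet":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in SvSet: {missing}")
        rows = [pos[s] for s in wanted]
        return SvSet(self.records, self.genotypes[rows, :], wanted)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SvSet):
            return NotImplemented
        return (
            self.records == other.records
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Sample -> population -> group -> species mapping row."""

    sample_id: str
    population: str
    group: str
    species: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )


class Metadata:
    """Indexed collection of :class:`SampleMeta` rows."""

    def __init__(self, rows: Sequence[SampleMeta]) -> None:
        self.rows = list(rows)
        self._by_id = {r.sample_id: r for r in self.rows}
        if len(self._by_id) != len(self.rows):
            raise ValueError("duplicate sample ids in metadata")

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def strata(self, grouping: str) -> dict[str, list[str]]:
        """Sample ids keyed by stratum label for a grouping.

        ``grouping`` is one of ``population``, ``group``, ``species``.
        """
        if grouping not in ("population", "group", "species"):
            raise ValueError(f"unknown grouping {grouping!r}")
        out: dict[str, list[str]] = {}
        for r in self.rows:
            out.setdefault(getattr(r, grouping), []).append(r.sample_id)
        return out

    def samples_of(self, grouping: str, label: str) -> list[str]:
        return self.strata(grouping).get(label, [])

    def check_covers(self, svset: SvSet) -> None:
        missing = [s for s in svset.samples if s not in self._by_id]
        if missing:
            raise KeyError(f"samples without metadata: {missing}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    payload: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: end must be > start"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """Sorted collection of :class:`GenomicInterval`."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self.intervals = sorted(intervals, key=lambda g: (g.chrom, g.start, g.end))

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for g in self.intervals:
            out.setdefault(g.chrom, []).append(g)
        return out

    def merge(self) -> "IntervalSet":
        """Union of the intervals: overlapping/bookended runs are merged."""
        merged: list[GenomicInterval] = []
        for chrom, ivs in self.by_chrom().items():
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for g in ivs[1:]:
                if g.start <= cur_e:
                    cur_e = max(cur_e, g.end)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = g.start, g.end
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(merged)

    def total_span(self) -> int:
        return sum(len(g) for g in self.merge())

    def is_merged(self) -> bool:
        for ivs in self.by_chrom().values():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    return False
        return True


@dataclass(frozen=True)
class GeneModel:
    """Gene span with exon structure (0-based half-open), strand-aware.

    ``cds_start``/``cds_end`` delimit the coding region when known; UTR spans
    are derived from them.  When absent, UTR categories are unassignable for
    the gene (no inference).
    """

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"gene {self.gene_id}: empty span")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site position (0-based)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def utr_spans(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5' UTR, 3' UTR) exonic spans derived from the CDS bounds."""
        if self.cds_start is None or self.cds_end is None or self.cds_start >= self.cds_end:
            return [], []
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        if self.strand == "+":
            return left, right
        return right, left


@dataclass(frozen=True)
class QtlRecord:
    """A QTL interval with its trait label."""

    interval: GenomicInterval
    trait: str


@dataclass
class Genome:
    """Chromosome names and lengths (bp)."""

    chroms: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def total_length(self) -> int:
        return sum(self.chroms.values())
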