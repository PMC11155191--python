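"""Interval genomics: breakpoint densities, hotspots, telomere enrichment,
reciprocal-overlap matching, QTL fold enrichment, and open-chromatin (peak)
classification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import Genome, GenomicInterval, IntervalSet, GeneModel, Metadata, QtlRecord, SvSet


# ---------------------------------------------------------------------------
# breakpoint density and hotspots


def sliding_windows(genome: Genome, window: int, step: int) -> pd.DataFrame:
    """Window tiling per chromosome: starts at 0, advance by ``step`` while the
    start lies inside the chromosome; window end is clipped to the chromosome."""
    rows = []
    for chrom, length in genome.chroms.items():
        start = 0
        while start < length:
            rows.append(
                {"chrom": chrom, "start": start, "end": min(start + window, length)}
            )
            start += step
    return pd.DataFrame(rows)


def breakpoint_positions(svset: SvSet) -> list[tuple[str, int]]:
    """All breakpoint positions (0-based): two per span SV, one per INS, one
    per chromosome involved in a TRA."""
    pts = []
    for r in svset.records:
        pts.extend(r.breakpoints())
    return pts


def breakpoint_density(
    svset: SvSet, genome: Genome, window: int = 1_000_000, step: int = 500_000
) -> pd.DataFrame:
    """SV-breakpoint count per sliding window (1 Mb / 500 kb by default).

    A breakpoint falling where two windows overlap counts in both.
    """
    wins = sliding_windows(genome, window, step)
    counts = np.zeros(len(wins), dtype=np.int64)
    # group windows per chromosome; with step < window a position x lies in the
    # windows whose start is in (x - window, x]
    win_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in wins.groupby("chrom"):
        win_by_chrom[chrom] = (grp["start"].to_numpy(), grp.index.to_numpy())
    for chrom, pos in breakpoint_positions(svset):
        if chrom not in genome:
            raise ValueError(f"SV breakpoint on unknown chromosome {chrom!r}")
        starts, idx = win_by_chrom[chrom]
        hit = (starts <= pos) & (pos < starts + window)
        counts[idx[hit]] += 1
    wins = wins.copy()
    wins["count"] = counts
    return wins


@dataclass
class HotspotSet:
    """Hotspot windows (top decile by breakpoint count) and merged regions."""

    windows: pd.DataFrame
    regions: IntervalSet
    threshold: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_span(self) -> int:
        return sum(len(g) for g in self.regions)


def hotspot_detect(
    density: pd.DataFrame, top_fraction: float = 0.10, per_chromosome: bool = False
) -> HotspotSet:
    """Call hotspot windows at the top ``top_fraction`` of breakpoint counts
    (rank cutoff ceil(f*W), threshold ties included) and merge
    adjacent/overlapping hotspot windows into regions.

    The decile is genome-wide by default; ``per_chromosome`` ranks within each
    chromosome instead.
    """
    if len(density) < 10:
        raise ValueError("need at least 10 windows for a decile rule")
    if (density["count"] == 0).all():
        raise ValueError("all-zero breakpoint density: no meaningful decile")

    def _flag(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        k = max(1, int(np.ceil(top_fraction * len(df))))
        thr = int(np.sort(df["count"].to_numpy())[::-1][k - 1])
        out = df[df["count"] >= thr]
        return out, thr

    if per_chromosome:
        parts, thr = [], 0
        for _, grp in density.groupby("chrom"):
            sel, t = _flag(grp)
            parts.append(sel)
            thr = max(thr, t)
        hot = pd.concat(parts)
    else:
        hot, thr = _flag(density)
    regions = IntervalSet(
        [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in hot.itertuples()]
    ).merge()
    return HotspotSet(windows=hot.reset_index(drop=True), regions=regions, threshold=thr)


# ---------------------------------------------------------------------------
# telomere enrichment


def telomere_enrichment(
    svset: SvSet,
    genome: Genome,
    telomere_len: int = 5_000_000,
    bin_size: int = 1_000_000,
    exclude_chroms: tuple[str, ...] = (),
    both_ends: bool = True,
) -> dict:
    """Wilcoxon rank-sum comparison of per-1-Mb-bin breakpoint counts,
    telomeric (first and last 5 Mb of each chromosome) versus the rest.

    Assemblies here do not encode centromeres, so "chromosome arm ends" are
    taken as both chromosome ends (``both_ends=False`` uses only the distal
    end, for acrocentric single-arm conventions).  Chromosomes can be
    excluded (the published analysis dropped the incomplete goat X).
    """
    pts = breakpoint_positions(svset)
    telo_counts, non_counts = [], []
    n_telo_bp = 0
    for chrom, length in genome.chroms.items():
        if chrom in exclude_chroms:
            continue
        if length <= 2 * telomere_len:
            raise ValueError(f"chromosome {chrom} too short for telomere bins")
        n_bins = int(np.ceil(length / bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        for c, pos in pts:
            if c == chrom:
                counts[min(pos // bin_size, n_bins - 1)] += 1
        lo = telomere_len // bin_size
        hi_start = (length - telomere_len) // bin_size
        telo_bins = set(range(hi_start, n_bins))  # distal arm end
        if both_ends:
            telo_bins |= set(range(0, lo))
        for b in range(n_bins):
            (telo_counts if b in telo_bins else non_counts).append(counts[b])
        n_telo_bp += sum(1 for c, pos in pts if c == chrom and (min(pos // bin_size, n_bins - 1) in telo_bins))
    if not non_counts:
        raise ValueError("no non-telomeric bins")
    res = stats.ranksums(telo_counts, non_counts)
    # rank-sum statistic W of the telomeric sample, as rank-sum tools report it
    ranks = stats.rankdata(np.concatenate([telo_counts, non_counts]))
    w = float(ranks[: len(telo_counts)].sum())
    return {
        "n_telomeric_bins": len(telo_counts),
        "n_other_bins": len(non_counts),
        "telomeric_breakpoints": int(n_telo_bp),
        "total_breakpoints": len(pts),
        "rank_sum": w,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# reciprocal-overlap matching


@dataclass(frozen=True)
class OverlapRule:
    """Fractional overlap rule mirroring BEDtools ``-f/-F`` with ``-e``
    ("either") or both-sides semantics, and ``-v`` (invert)."""

    fraction_a: float = 0.5
    fraction_b: float = 0.5
    mode: str = "either"
    invert: bool = False

    def __post_init__(self) -> None:
        for f in (self.fraction_a, self.fraction_b):
            if not (0 < f <= 1):
                raise ValueError("overlap fractions must be in (0, 1]")
        if self.mode not in ("either", "both"):
            raise ValueError("mode must be 'either' or 'both'")

    def matches(self, a: GenomicInterval, b: GenomicInterval) -> bool:
        ov = a.overlap_len(b)
        if ov <= 0:
            return False
        ok_a = ov >= self.fraction_a * len(a)
        ok_b = ov >= self.fraction_b * len(b)
        return (ok_a or ok_b) if self.mode == "either" else (ok_a and ok_b)


def overlap_match(
    set_a: IntervalSet, set_b: IntervalSet, rule: OverlapRule
) -> tuple[list[tuple[GenomicInterval, GenomicInterval]], list[GenomicInterval]]:
    """Match intervals of A against B under the rule (sorted sweep).

    Returns ``(matched pairs, unmatched A records)``; with ``rule.invert`` the
    caller typically consumes the unmatched list (BEDtools ``-v``).  Output
    order follows the sorted order of A.
    """
    for s in (set_a, set_b):
        for g in s:
            if len(g) <= 0:
                raise ValueError(f"zero-length interval {g}")
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    unmatched: list[GenomicInterval] = []
    b_by_chrom = set_b.by_chrom()
    for chrom, a_list in set_a.by_chrom().items():
        b_list = b_by_chrom.get(chrom, [])
        b_starts = np.array([g.start for g in b_list])
        b_max_len = max((len(g) for g in b_list), default=0)
        for a in a_list:
            hit = False
            if len(b_list):
                lo = int(np.searchsorted(b_starts, a.start - b_max_len))
                for k in range(lo, len(b_list)):
                    if b_starts[k] >= a.end:
                        break
                    if rule.matches(a, b_list[k]):
                        pairs.append((a, b_list[k]))
                        hit = True
            if not hit:
                unmatched.append(a)
    return pairs, unmatched


def novel_svs(
    svset: SvSet, catalog: IntervalSet, fraction: float = 0.3
) -> tuple[list[str], pd.DataFrame]:
    """SVs with no catalog match under the reciprocal-overlap rule
    (``-f 0.3 -F 0.3 -e -v`` semantics).

    Returns the novel SV ids and a per-type count/percentage table.
    """
    if len(catalog) == 0:
        warnings.warn("empty catalog: all SVs reported novel", stacklevel=2)
    rule = OverlapRule(fraction, fraction, mode="either", invert=True)
    ivs = IntervalSet([r.interval for r in svset.records])
    _, unmatched = overlap_match(ivs, catalog, rule)
    novel_ids = sorted(g.name for g in unmatched)
    novel_set = set(novel_ids)
    rows = []
    for svtype in sorted({r.svtype for r in svset.records}):
        total = sum(1 for r in svset.records if r.svtype == svtype)
        novel = sum(
            1 for r in svset.records if r.svtype == svtype and r.id in novel_set
        )
        rows.append(
            {
                "svtype": svtype,
                "n_total": total,
                "n_novel": novel,
                "pct_novel": 100.0 * novel / total if total else float("nan"),
            }
        )
    return novel_ids, pd.DataFrame(rows)


def novel_del_dup_total(per_type: pd.DataFrame) -> tuple[int, float]:
    """Combined DEL+DUP novel count and percentage from a per-type table."""
    sel = per_type[per_type["svtype"].isin(["DEL", "DUP"])]
    n_novel = int(sel["n_novel"].sum())
    n_total = int(sel["n_total"].sum())
    return n_novel, 100.0 * n_novel / n_total if n_total else float("nan")


# ---------------------------------------------------------------------------
# QTL fold enrichment

LOG2_PSEUDOCOUNT = 0.5


def qtl_enrichment(
    svset: SvSet,
    meta: Metadata,
    qtls: list[QtlRecord],
    genome: Genome,
    rule: OverlapRule | None = None,
) -> pd.DataFrame:
    """log2 fold enrichment of each individual's carried SVs in each QTL trait.

    Observed = carried SVs matching the trait's QTL intervals under the
    0.5/0.5 "either" rule; expected = carried SVs x (merged QTL span /
    genome span) under uniform placement.  When observed is 0 the
    pseudocount 0.5 replaces it for the log2 (flagged in ``zero_observed``).
    """
    if genome.total_length() <= 0:
        raise ValueError("zero genome span")
    rule = rule or OverlapRule(0.5, 0.5, mode="either")
    by_trait: dict[str, list[GenomicInterval]] = {}
    for q in qtls:
        by_trait.setdefault(q.trait, []).append(q.interval)
    trait_sets = {t: IntervalSet(v) for t, v in by_trait.items()}
    trait_span = {t: s.total_span() for t, s in trait_sets.items()}
    rows = []
    meta.check_covers(svset)
    for si, sample in enumerate(svset.samples):
        carried = [
            svset.records[j]
            for j in range(svset.n_loci)
            if svset.genotypes[si, j] > 0
        ]
        n_carried = len(carried)
        if n_carried == 0:
            continue
        ivs = IntervalSet([r.interval for r in carried])
        for trait, tset in trait_sets.items():
            pairs, _ = overlap_match(ivs, tset, rule)
            observed = len({a.name for a, _b in pairs})
            expected = n_carried * trait_span[trait] / genome.total_length()
            obs_for_log = observed if observed > 0 else LOG2_PSEUDOCOUNT
            fold = obs_for_log / expected if expected > 0 else float("nan")
            rows.append(
                {
                    "sample_id": sample,
                    "trait": trait,
                    "n_carried": n_carried,
                    "observed": observed,
                    "expected": expected,
                    "fold": observed / expected if expected > 0 else float("nan"),
                    "log2_fold": float(np.log2(fold)) if expected > 0 else float("nan"),
                    "zero_observed": observed == 0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak (open chromatin) classification


def _overlap_sum(iv: GenomicInterval, merged: list[GenomicInterval]) -> int:
    """Total overlap of ``iv`` with a sorted merged interval list."""
    if not merged:
        return 0
    starts = np.array([g.start for g in merged])
    total = 0
    lo = int(np.searchsorted(starts, iv.start)) - 1
    for k in range(max(lo, 0), len(merged)):
        g = merged[k]
        if g.start >= iv.end:
            break
        total += iv.overlap_len(g)
    return total


def peak_sv_classify(svset: SvSet, peaks: IntervalSet) -> pd.DataFrame:
    """Partition SVs into Peak-SVs and nonPeak-SVs.

    Peak-SV: total overlap with the merged peak set covers at least 50% of
    the SV length (overlap may accumulate across peaks).  Unmerged peaks are
    merged internally.
    """
    if not peaks.is_merged():
        warnings.warn("peaks were not merged; merging internally", stacklevel=2)
        peaks = peaks.merge()
    by_chrom = peaks.by_chrom()
    rows = []
    for r in svset.records:
        iv = r.interval
        ov = _overlap_sum(iv, by_chrom.get(iv.chrom, []))
        rows.append(
            {
                "sv_id": r.id,
                "svtype": r.svtype,
                "overlap_bp": ov,
                "sv_len": len(iv),
                "peak_sv": ov >= 0.5 * len(iv),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enhancer candidates


def enhancer_candidates(
    peaks: IntervalSet,
    genes: list[GeneModel],
    promoter_window: int = 2_000,
) -> tuple[IntervalSet, IntervalSet]:
    """Split peaks into promoter peaks and candidate enhancers.

    A promoter peak intersects some gene's TSS +/- ``promoter_window``; the
    remaining peaks are enhancer candidates.
    """
    promoters = []
    for g in genes:
        tss = g.tss
        promoters.append(
            GenomicInterval(g.chrom, max(0, tss - promoter_window), tss + promoter_window + 1)
        )
    prom_set = IntervalSet(promoters).merge()
    by_chrom = prom_set.by_chrom()
    cand, prom = [], []
    for p in peaks:
        if _overlap_sum(p, by_chrom.get(p.chrom, [])) > 0:
            prom.append(p)
        else:
            cand.append(p)
    return IntervalSet(cand), IntervalSet(prom)


def sv_supported_enhancers(candidates: IntervalSet, svset: SvSet) -> IntervalSet:
    """Candidate enhancer peaks overlapped by an SV at >= 50% of the SV length."""
    sv_ivs = IntervalSet([r.interval for r in svset.records])
    supported: set[tuple[str, int, int]] = set()
    by_chrom = candidates.by_chrom()
    for iv in sv_ivs:
        cand_list = by_chrom.get(iv.chrom, [])
        if not cand_list:
            continue
        starts = np.array([g.start for g in cand_list])
        max_len = max(len(g) for g in cand_list)
        lo = int(np.searchsorted(starts, iv.start - max_len))
        for k in range(lo, len(cand_list)):
            g = cand_list[k]
            if g.start >= iv.end:
                break
            if iv.overlap_len(g) >= 0.5 * len(iv):
                supported.add((g.chrom, g.start, g.end))
    return IntervalSet(
        [g for g in candidates if (g.chrom, g.start, g.end) in supported]
    )


def candidate_enhancer_count(n_peaks: int, n_promoter_peaks: int) -> int:
    """Candidate enhancers left after excluding promoter-annotated peaks."""
    if n_promoter_peaks > n_peaks:
        raise ValueError("promoter peaks exceed total peaks")
    return n_peaks - n_promoter_peaks
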