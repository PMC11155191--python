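"""Cohort-level filtering, allele frequencies, and sharing summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, Metadata, SvSet


def dosage_stats(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt frequency, called diploid count) over non-missing calls.

    Loci with no calls get frequency NaN.
    """
    called = genotypes != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    return p, n_called


@dataclass
class FilterReport:
    """Per-rule removal tally from :func:`filter_svs`."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)


def filter_svs(
    svset: SvSet,
    min_len: int = 50,
    max_len: int = 1_000_000,
    max_missing: float = 0.25,
    min_maf: float = 0.01,
) -> tuple[SvSet, FilterReport]:
    """Retain loci with min_len <= length <= max_len (inclusive bounds),
    missing rate <= max_missing, and MAF >= min_maf.

    A locus failing several rules is tallied once per rule it fails.
    """
    if min_len <= 0 or max_len <= 0 or min_len > max_len:
        raise ValueError("invalid length thresholds")
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    lengths = svset.lengths()
    p, n_called = dosage_stats(svset.genotypes)
    missing_rate = 1.0 - n_called / svset.n_samples
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    too_short = lengths < min_len
    too_long = lengths > max_len
    too_missing = missing_rate > max_missing
    low_maf = ~(maf >= min_maf)  # NaN MAF (no calls) also fails
    keep = ~(too_short | too_long | too_missing | low_maf)
    report = FilterReport(
        n_input=svset.n_loci,
        n_retained=int(keep.sum()),
        removed={
            "min_len": int(too_short.sum()),
            "max_len": int(too_long.sum()),
            "max_missing": int(too_missing.sum()),
            "min_maf": int(low_maf.sum()),
        },
    )
    if report.n_retained == 0:
        warnings.warn("all loci removed by filters", stacklevel=2)
    return svset.subset_loci(keep), report


def allele_frequencies(
    svset: SvSet, meta: Metadata, grouping: str = "population"
) -> pd.DataFrame:
    """Per-(locus, stratum) allele-frequency table.

    Columns: ``sv_id, stratum, p, n_called, maf, missing_rate``.  ``p`` is the
    alt dosage sum over twice the called diploid count; strata with no calls
    at a locus get ``p = NaN`` (flagged undefined, never silently 0).
    """
    meta.check_covers(svset)
    strata = meta.strata(grouping)
    ids = svset.ids
    frames = []
    row_of = {s: i for i, s in enumerate(svset.samples)}
    for label, samples in sorted(strata.items()):
        rows = [row_of[s] for s in samples if s in row_of]
        if not rows:
            continue
        sub = svset.genotypes[rows, :]
        p, n_called = dosage_stats(sub)
        with np.errstate(invalid="ignore"):
            maf = np.minimum(p, 1.0 - p)
        frames.append(
            pd.DataFrame(
                {
                    "sv_id": ids,
                    "stratum": label,
                    "p": p,
                    "n_called": n_called,
                    "maf": maf,
                    "missing_rate": 1.0 - n_called / len(rows),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frequency_matrix(
    svset: SvSet, meta: Metadata, grouping: str = "population"
) -> pd.DataFrame:
    """Loci x strata matrix of alt-allele frequencies (NaN where no calls)."""
    table = allele_frequencies(svset, meta, grouping)
    return table.pivot(index="sv_id", columns="stratum", values="p").loc[svset.ids]


def presence_by_group(svset: SvSet, meta: Metadata, grouping: str = "group") -> pd.DataFrame:
    """Loci x strata boolean table: carrier (dosage > 0) present in stratum."""
    meta.check_covers(svset)
    strata = meta.strata(grouping)
    row_of = {s: i for i, s in enumerate(svset.samples)}
    out = {}
    for label, samples in sorted(strata.items()):
        rows = [row_of[s] for s in samples if s in row_of]
        if rows:
            out[label] = (svset.genotypes[rows, :] > 0).any(axis=0)
        else:
            out[label] = np.zeros(svset.n_loci, dtype=bool)
    return pd.DataFrame(out, index=svset.ids)


def sharing_summary(svset: SvSet, meta: Metadata) -> dict[str, int]:
    """Venn-cell SV counts among the wild/native/improved groups.

    An SV is present in a group iff at least one of the group's samples
    carries it (non-missing dosage > 0).  Keys: per-group totals
    (``wild`` ...), exclusive cells (``wild_only``, ``wild_native`` ...),
    and ``all_three`` / ``union``.  Cells satisfy inclusion-exclusion by
    construction; :func:`audit_sharing` re-checks it.
    """
    pres = presence_by_group(svset, meta, "group")
    for g in ("wild", "native", "improved"):
        if g not in pres.columns:
            pres[g] = False
    w, n, i = (pres[g].to_numpy() for g in ("wild", "native", "improved"))
    cells = {
        "wild": int(w.sum()),
        "native": int(n.sum()),
        "improved": int(i.sum()),
        "wild_only": int((w & ~n & ~i).sum()),
        "native_only": int((~w & n & ~i).sum()),
        "improved_only": int((~w & ~n & i).sum()),
        "wild_native": int((w & n & ~i).sum()),
        "wild_improved": int((w & ~n & i).sum()),
        "native_improved": int((~w & n & i).sum()),
        "all_three": int((w & n & i).sum()),
        "union": int((w | n | i).sum()),
    }
    audit_sharing(cells)
    return cells


def audit_sharing(cells: dict[str, int]) -> None:
    """Inclusion-exclusion audit of a sharing summary; raises on violation."""
    union_ie = (
        cells["wild_only"]
        + cells["native_only"]
        + cells["improved_only"]
        + cells["wild_native"]
        + cells["wild_improved"]
        + cells["native_improved"]
        + cells["all_three"]
    )
    if union_ie != cells["union"]:
        raise AssertionError("sharing summary violates inclusion-exclusion")


def sv_accumulation_curve(
    svset: SvSet,
    n_points: int = 10,
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean distinct segregating-SV count versus subsample size.

    Random subsets of individuals are drawn without replacement; an SV counts
    as discovered if any sampled individual carries it.  Returns a tidy frame
    with one row per (size, replicate) plus the per-size mean; per replicate
    the counts come from nested subsets so each curve is monotone.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = svset.n_samples
    if n_points < 1 or n_points > n:
        raise ValueError("n_points must be in [1, n_samples]")
    sizes = np.unique(np.linspace(1, n, n_points).round().astype(int))
    carriers = svset.genotypes > 0
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        order = rng.permutation(n)
        cum = np.cumsum(carriers[order, :], axis=0) > 0
        for size in sizes:
            rows.append(
                {"size": int(size), "rep": rep, "n_svs": int(cum[size - 1].sum())}
            )
    df = pd.DataFrame(rows)
    mean = df.groupby("size", as_index=False)["n_svs"].mean().rename(columns={"n_svs": "mean_n_svs"})
    return df.merge(mean, on="size")


def rare_maf_percentage(n_rare: int, n_total: int) -> float:
    """Percentage of SVs below a MAF cutoff, from spectrum counts."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_rare / n_total
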