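"""Diversity and differentiation statistics for SV genotype matrices.

Implements per-site nucleotide diversity with the small-sample correction
``pi = n/(n-1) * 2 p (1-p)`` (``n`` = number of sequences = twice the called
diploids), heterozygosity rates, the Weir & Cockerham (1984) two-level
variance-component F_ST estimator computed from genotype counts, breed-vs-rest
"global" F_ST, and genotype-dosage linkage disequilibrium r^2 with distance
profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import dosage_stats
from .types import MISSING, Metadata, SvSet


# ---------------------------------------------------------------------------
# nucleotide diversity


def site_pi(p: np.ndarray | float, n_called: np.ndarray | int) -> np.ndarray | float:
    """Per-site pi; undefined (NaN) where fewer than 2 called diploids.

    With ``n = 2 * n_called`` sequences and alt frequency ``p``, the mean
    number of pairwise allele differences per locus is
    ``n/(n-1) * 2 p (1-p)``.
    """
    p = np.asarray(p, dtype=float)
    n_seq = 2.0 * np.asarray(n_called, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = n_seq / (n_seq - 1.0) * 2.0 * p * (1.0 - p)
    return np.where(n_seq >= 4, pi, np.nan) if pi.ndim else (
        float(pi) if n_seq >= 4 else float("nan")
    )


def windowed_pi(
    svset: SvSet,
    meta: Metadata,
    stratum: str | None = None,
    grouping: str = "population",
    window: int = 10_000_000,
) -> pd.DataFrame:
    """Mean pi in non-overlapping windows, reported two ways.

    ``pi_bp`` divides the window's summed per-site pi by the window length
    (per-bp convention of sliding-window tools); ``pi_site`` averages over the
    SV sites in the window.  Both are emitted because the field's convention
    is ambiguous for SV loci.
    """
    if stratum is not None:
        samples = meta.samples_of(grouping, stratum)
        if not samples:
            raise ValueError(f"no samples in {grouping}={stratum!r}")
        sub = svset.subset_samples([s for s in samples if s in svset.samples])
    else:
        sub = svset
    p, n_called = dosage_stats(sub.genotypes)
    pi = site_pi(p, n_called)
    rows = []
    pos = np.array([r.interval.start for r in sub.records])
    chroms = np.array([r.chrom for r in sub.records])
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        w_idx = pos[sel] // window
        for w in np.unique(w_idx):
            vals = pi[sel][w_idx == w]
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(w * window),
                    "end": int((w + 1) * window),
                    "n_sites": int(vals.size),
                    "pi_bp": float(vals.sum() / window),
                    "pi_site": float(vals.mean()) if vals.size else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def heterozygosity_rate(
    svset: SvSet, meta: Metadata, stratum: str, grouping: str = "population"
) -> tuple[float, int, int]:
    """Proportion of heterozygous calls among non-missing calls at
    segregating sites within a stratum.

    Returns ``(rate, n_het, n_called)``; rate is NaN when nothing is called.
    """
    samples = [
        s for s in meta.samples_of(grouping, stratum) if s in svset.samples
    ]
    if not samples:
        raise ValueError(f"stratum {stratum!r} has no samples in the SvSet")
    sub = svset.subset_samples(samples)
    p, _ = dosage_stats(sub.genotypes)
    seg = (p > 0) & (p < 1)
    g = sub.genotypes[:, seg]
    n_called = int((g != MISSING).sum())
    n_het = int((g == 1).sum())
    rate = n_het / n_called if n_called else float("nan")
    return rate, n_het, n_called


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST


def _wc_components(
    counts: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) and a defined-mask.

    ``counts`` holds one (3, n_loci) genotype-count array per population
    (rows: dosage 0, 1, 2 counts over called diploids).  Implements the
    two-level diploid estimator with observed heterozygosity entering the
    within-individual component c.
    """
    r = len(counts)
    n_i = np.stack([c.sum(axis=0) for c in counts]).astype(float)  # pops x loci
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([(c[1] + 2 * c[2]) for c in counts]) / (2 * n_i)
        h_i = np.stack([c[1] for c in counts]) / n_i
    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    # defined: every population has >= 2 called diploids and the locus is
    # polymorphic across the pooled sample (monomorphic -> 0/0)
    enough = (n_i >= 2).all(axis=0)
    poly = (p_bar > 0) & (p_bar < 1)
    defined = enough & poly & (n_bar > 1)
    return a, b, c, defined


def genotype_counts(svset: SvSet, sample_ids: list[str]) -> np.ndarray:
    """(3, n_loci) dosage-count array for a set of samples."""
    sub = svset.subset_samples([s for s in sample_ids if s in svset.samples])
    g = sub.genotypes
    return np.stack([(g == d).sum(axis=0) for d in (0, 1, 2)])


def wc_fst(
    svset: SvSet,
    meta: Metadata,
    pops: list[str],
    grouping: str = "population",
) -> pd.DataFrame:
    """Per-locus Weir–Cockerham theta-hat among two or more populations.

    Returns a frame with columns ``sv_id, a, b, c, theta, defined``; per-site
    theta may be negative (kept unclamped).  Use :func:`genomewide_fst` for
    the weighted ratio-of-sums summary.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    counts = [genotype_counts(svset, meta.samples_of(grouping, p)) for p in pops]
    a, b, c, defined = _wc_components(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    theta = np.where(defined, theta, np.nan)
    return pd.DataFrame(
        {
            "sv_id": svset.ids,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "defined": defined,
        }
    )


def genomewide_fst(fst_table: pd.DataFrame) -> dict[str, float]:
    """Genome-wide summaries of a :func:`wc_fst` table.

    ``weighted`` is the ratio of sums ``sum(a) / sum(a+b+c)`` over defined
    loci (the "weighted" convention); ``mean_of_ratios`` averages per-site
    theta.  The number of undefined loci excluded is reported.
    """
    d = fst_table[fst_table["defined"]]
    denom = (d["a"] + d["b"] + d["c"]).sum()
    return {
        "weighted": float(d["a"].sum() / denom) if denom != 0 else float("nan"),
        "mean_of_ratios": float(d["theta"].mean()) if len(d) else float("nan"),
        "n_defined": int(len(d)),
        "n_undefined": int((~fst_table["defined"]).sum()),
    }


def global_fst(svset: SvSet, meta: Metadata, grouping: str = "population") -> pd.DataFrame:
    """Per-SV mean over breeds of the breed-vs-all-other-breeds theta-hat.

    Populations whose one-vs-rest theta is undefined at a locus are omitted
    from that locus's mean; loci with < 2 defined contrasts are undefined.
    """
    strata = meta.strata(grouping)
    names = sorted(strata)
    if len(names) < 2:
        raise ValueError("global F_ST needs at least two populations")
    thetas = []
    for name in names:
        rest = [s for other in names if other != name for s in strata[other]]
        counts = [
            genotype_counts(svset, strata[name]),
            genotype_counts(svset, rest),
        ]
        a, b, c, defined = _wc_components(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = a / (a + b + c)
        thetas.append(np.where(defined, t, np.nan))
    mat = np.stack(thetas)  # pops x loci
    n_def = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=0)
    mean = np.where(n_def >= 2, mean, np.nan)
    return pd.DataFrame(
        {"sv_id": svset.ids, "global_fst": mean, "n_contrasts": n_def}
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(svset: SvSet, locus_a: str, locus_b: str) -> float:
    """Squared Pearson correlation of dosages over samples called at both loci."""
    idx = {sid: j for j, sid in enumerate(svset.ids)}
    ga = svset.genotypes[:, idx[locus_a]].astype(float)
    gb = svset.genotypes[:, idx[locus_b]].astype(float)
    rec_a, rec_b = svset.records[idx[locus_a]], svset.records[idx[locus_b]]
    if rec_a.chrom != rec_b.chrom:
        raise ValueError("r^2 is defined within a chromosome only")
    called = (ga != MISSING) & (gb != MISSING)
    if called.sum() < 2:
        return float("nan")
    ga, gb = ga[called], gb[called]
    if ga.var() == 0 or gb.var() == 0:
        return float("nan")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def ld_decay_profile(
    svset: SvSet,
    max_dist: int = 300_000,
    n_bins: int = 30,
    max_pairs_per_chrom: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean r^2 per distance bin for same-chromosome pairs within max_dist.

    Distances are between SV start positions.  ``max_pairs_per_chrom``
    subsamples pairs for large sets.
    """
    g = svset.genotypes.astype(float)
    g[g == MISSING] = np.nan
    pos = np.array([r.interval.start for r in svset.records])
    chroms = np.array([r.chrom for r in svset.records])
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        order = idx[np.argsort(pos[idx])]
        pairs = []
        for ai in range(len(order)):
            for bi in range(ai + 1, len(order)):
                d = pos[order[bi]] - pos[order[ai]]
                if d > max_dist:
                    break
                pairs.append((order[ai], order[bi], d))
        if max_pairs_per_chrom is not None and len(pairs) > max_pairs_per_chrom:
            keep = rng.choice(len(pairs), size=max_pairs_per_chrom, replace=False)
            pairs = [pairs[k] for k in keep]
        for ia, ib, d in pairs:
            ga, gb = g[:, ia], g[:, ib]
            ok = ~(np.isnan(ga) | np.isnan(gb))
            if ok.sum() < 2:
                continue
            va, vb = ga[ok], gb[ok]
            if va.std() == 0 or vb.std() == 0:
                continue
            r = np.corrcoef(va, vb)[0, 1]
            b = min(int(np.searchsorted(edges, d, side="right") - 1), n_bins - 1)
            sums[b] += r * r
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1].astype(int),
            "bin_hi": edges[1:].astype(int),
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
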