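"""Selection statistics: ancestral polarization, DI_SV, permutation F_ST
P-values, the population branch statistic, top-quantile candidate calling,
and grouped allele-frequency Wilcoxon tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import dosage_stats
from .popstats import _wc_components, genotype_counts
from .types import Metadata, SvSet


# ---------------------------------------------------------------------------
# polarization and DI_SV


def polarize_ancestral(
    svset: SvSet, meta: Metadata, wild_population: str, grouping: str = "population"
) -> pd.DataFrame:
    """Ancestral allele per locus from the majority allele of the wild
    ancestral-proxy population.

    Returns columns ``sv_id, ancestral`` (``ref``/``alt``/``ambiguous``/
    ``unpolarizable``).  Ties between ref and alt copies are ambiguous;
    loci with no wild calls are unpolarizable; both are excluded from DI_SV.
    """
    samples = [
        s for s in meta.samples_of(grouping, wild_population) if s in svset.samples
    ]
    if not samples:
        raise ValueError(f"wild population {wild_population!r} has no samples")
    sub = svset.subset_samples(samples)
    p, n_called = dosage_stats(sub.genotypes)
    label = np.where(p < 0.5, "ref", np.where(p > 0.5, "alt", "ambiguous"))
    label = np.where(n_called == 0, "unpolarizable", label)
    return pd.DataFrame({"sv_id": svset.ids, "ancestral": label})


def derived_frequencies(
    svset: SvSet,
    meta: Metadata,
    polarization: pd.DataFrame,
    populations: list[str],
    grouping: str = "population",
) -> pd.DataFrame:
    """Derived-allele frequency per (locus, population).

    Derived frequency is the alt frequency where the ancestral allele is ref
    and ``1 - p_alt`` where it is alt; NaN where unpolarizable/ambiguous or
    uncalled.
    """
    anc = polarization.set_index("sv_id").loc[svset.ids, "ancestral"].to_numpy()
    out = {"sv_id": svset.ids}
    for pop in populations:
        samples = [s for s in meta.samples_of(grouping, pop) if s in svset.samples]
        if not samples:
            raise ValueError(f"population {pop!r} has no samples")
        p, n_called = dosage_stats(svset.subset_samples(samples).genotypes)
        derived = np.where(anc == "ref", p, np.where(anc == "alt", 1.0 - p, np.nan))
        derived = np.where(n_called > 0, derived, np.nan)
        out[pop] = derived
    return pd.DataFrame(out)


def di_sv(derived: pd.DataFrame, domestic_pop: str, wild_pop: str) -> pd.DataFrame:
    """Differentiation index: derived-allele frequency difference
    ``f_derived(domestic) - f_derived(wild)`` per locus (signed)."""
    return pd.DataFrame(
        {
            "sv_id": derived["sv_id"],
            "di_sv": derived[domestic_pop] - derived[wild_pop],
        }
    )


# ---------------------------------------------------------------------------
# permutation P-values for F_ST


def fst_permutation_pvalue(
    svset: SvSet,
    meta: Metadata,
    pop_a: str,
    pop_b: str,
    n_perm: int = 200,
    seed: int | None = None,
    per_locus: bool = False,
    grouping: str = "population",
    smoothing: bool = False,
) -> pd.DataFrame:
    """Permutation P-value per locus for pairwise theta-hat.

    ``P = #{permuted theta > observed theta} / B`` (strict "higher than"
    rule; ``P = 0`` is reportable).  By default one sample-label permutation
    per replicate is shared across all loci, which preserves inter-locus
    correlation; ``per_locus=True`` shuffles independently per locus.
    ``smoothing`` applies the (k+1)/(B+1) correction.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    samples_a = [s for s in meta.samples_of(grouping, pop_a) if s in svset.samples]
    samples_b = [s for s in meta.samples_of(grouping, pop_b) if s in svset.samples]
    n_a = len(samples_a)
    pooled = svset.subset_samples(samples_a + samples_b)
    g = pooled.genotypes

    def theta_of(rows_a: np.ndarray) -> np.ndarray:
        mask = np.zeros(g.shape[0], dtype=bool)
        mask[rows_a] = True
        counts = [
            np.stack([(g[mask] == d).sum(axis=0) for d in (0, 1, 2)]),
            np.stack([(g[~mask] == d).sum(axis=0) for d in (0, 1, 2)]),
        ]
        a, b, c, defined = _wc_components(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = a / (a + b + c)
        return np.where(defined, t, np.nan)

    observed = theta_of(np.arange(n_a))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(svset.n_loci, dtype=np.int64)
    n_total = g.shape[0]
    if per_locus:
        for _ in range(n_perm):
            perm_t = np.empty(svset.n_loci)
            for j in range(svset.n_loci):
                rows = rng.permutation(n_total)[:n_a]
                mask = np.zeros(n_total, dtype=bool)
                mask[rows] = True
                col = g[:, j : j + 1]
                counts = [
                    np.stack([(col[mask] == d).sum(axis=0) for d in (0, 1, 2)]),
                    np.stack([(col[~mask] == d).sum(axis=0) for d in (0, 1, 2)]),
                ]
                a, b, c, defined = _wc_components(counts)
                with np.errstate(invalid="ignore", divide="ignore"):
                    t = a / (a + b + c)
                perm_t[j] = t[0] if defined[0] else np.nan
            with np.errstate(invalid="ignore"):
                exceed += (perm_t > observed).astype(np.int64)
    else:
        for _ in range(n_perm):
            rows = rng.permutation(n_total)[:n_a]
            perm_t = theta_of(rows)
            with np.errstate(invalid="ignore"):
                exceed += (perm_t > observed).astype(np.int64)
    if smoothing:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    p = np.where(np.isnan(observed), np.nan, p)
    return pd.DataFrame(
        {"sv_id": svset.ids, "theta": observed, "p_perm": p, "n_perm": n_perm}
    )


# ---------------------------------------------------------------------------
# population branch statistic

_THETA_CAP = 1.0 - 1e-9


def pbs(theta_12, theta_13, theta_23):
    """Population branch statistic for focal population 1.

    ``T_ij = -log(1 - theta_ij)`` (theta clamped below 1 to avoid log(0);
    negative theta passes through), ``PBS = (T12 + T13 - T23) / 2``.
    """
    t12, t13, t23 = (
        -np.log1p(-np.minimum(np.asarray(t, dtype=float), _THETA_CAP))
        for t in (theta_12, theta_13, theta_23)
    )
    out = (t12 + t13 - t23) / 2.0
    return float(out) if np.ndim(out) == 0 else out


def pbs_scan(
    svset: SvSet,
    meta: Metadata,
    focal: list[str],
    contrast: list[str],
    outgroup: list[str],
    grouping: str = "population",
) -> pd.DataFrame:
    """Per-locus PBS for a focal sample group against a contrast group and an
    outgroup (each given as a list of populations pooled together)."""

    def theta(pops_x: list[str], pops_y: list[str]) -> np.ndarray:
        sx = [s for p in pops_x for s in meta.samples_of(grouping, p)]
        sy = [s for p in pops_y for s in meta.samples_of(grouping, p)]
        counts = [genotype_counts(svset, sx), genotype_counts(svset, sy)]
        a, b, c, defined = _wc_components(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = a / (a + b + c)
        return np.where(defined, t, np.nan)

    t12 = theta(focal, contrast)
    t13 = theta(focal, outgroup)
    t23 = theta(contrast, outgroup)
    return pd.DataFrame({"sv_id": svset.ids, "pbs": pbs(t12, t13, t23)})


# ---------------------------------------------------------------------------
# candidate calling


@dataclass(frozen=True)
class ThresholdRecord:
    statistic: str
    quantile: float
    threshold: float
    n_defined: int
    n_flagged: int


def top_quantile_flags(
    values: pd.Series | np.ndarray, q: float = 0.05, min_defined: int = 20
) -> tuple[np.ndarray, ThresholdRecord]:
    """Upper-tail flags: threshold at descending rank ceil(q*m), ties included."""
    v = np.asarray(values, dtype=float)
    defined = ~np.isnan(v)
    m = int(defined.sum())
    if m == 0:
        raise ValueError("statistic undefined at every locus")
    if m < min_defined:
        warnings.warn(
            f"top-quantile rule degenerate: only {m} defined loci", stacklevel=2
        )
    k = max(1, int(np.ceil(q * m)))
    thr = float(np.sort(v[defined])[::-1][k - 1])
    flags = defined & (v >= thr)
    rec = ThresholdRecord(
        statistic="value", quantile=q, threshold=thr, n_defined=m,
        n_flagged=int(flags.sum()),
    )
    return flags, rec


def candidate_selection(
    stat_table: pd.DataFrame,
    p_col: str | None = "p_perm",
    stat_col: str | None = "di_sv",
    alpha: float = 0.05,
    q: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Candidate selected SVs by the intersection rule.

    Default mirrors the domestication rule: permutation P of F_ST below
    ``alpha`` AND the statistic in its upper ``q`` tail.  Either component may
    be disabled by passing None.  Returns the table with flag columns and a
    threshold record (stored so the call is reproducible).
    """
    table = stat_table.copy()
    flags = np.ones(len(table), dtype=bool)
    record: dict = {"alpha": alpha, "q": q}
    if p_col is not None:
        pv = table[p_col].to_numpy(dtype=float)
        p_flag = ~np.isnan(pv) & (pv < alpha)
        table["flag_p"] = p_flag
        flags &= p_flag
        record["p_col"] = p_col
    if stat_col is not None:
        s_flags, rec = top_quantile_flags(table[stat_col], q=q)
        table["flag_stat"] = s_flags
        flags &= s_flags
        record["stat_col"] = stat_col
        record["stat_threshold"] = rec.threshold
        record["n_defined"] = rec.n_defined
    table["candidate"] = flags
    record["n_candidates"] = int(flags.sum())
    if record["n_candidates"] == 0:
        warnings.warn("intersection rule produced an empty candidate set", stacklevel=2)
    return table, record


# ---------------------------------------------------------------------------
# grouped allele-frequency tests


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum P by enumerating all group-1 assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mu)
    count = total = 0
    for comb in combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum P.

    Exact enumeration (tie-safe) when ``min(n1, n2) <= exact_max``; otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) <= exact_max:
        return float(_exact_ranksum_p(x, y))
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def group_freq_wilcoxon(
    freq_matrix: pd.DataFrame,
    group1_pops: list[str],
    group2_pops: list[str],
) -> pd.DataFrame:
    """Per-SV Wilcoxon rank-sum on population-level allele frequencies
    between two groups of populations, with BH adjustment across the SV set.

    ``freq_matrix`` is loci x populations (e.g. from
    :func:`svpopgen.cohort.frequency_matrix`).
    """
    if len(group1_pops) < 2 or len(group2_pops) < 2:
        raise ValueError("each group needs at least two populations")
    missing = [
        p for p in group1_pops + group2_pops if p not in freq_matrix.columns
    ]
    if missing:
        raise KeyError(f"populations absent from frequency matrix: {missing}")
    pvals = []
    for _, row in freq_matrix.iterrows():
        x = row[group1_pops].to_numpy(dtype=float)
        y = row[group2_pops].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            pvals.append(np.nan)
            continue
        pvals.append(wilcoxon_rank_sum(x, y))
    pvals = np.asarray(pvals, dtype=float)
    adj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"sv_id": freq_matrix.index, "p_raw": pvals, "p_adj": adj}
    ).reset_index(drop=True)
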