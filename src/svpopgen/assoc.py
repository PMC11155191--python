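"""Association post-processing: per-SV scores, the variance-explained
formula, top-quantile significance calling, and qPCR-derived helpers.

The per-locus score is an ordinary least-squares regression of phenotype on
genotype dosage — a deliberately simple stand-in whose role is to produce
``(beta, se, MAF, N)`` tuples end-to-end; the variance-explained formula also
accepts externally fitted mixed-model summary statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import dosage_stats
from .selection import ThresholdRecord
from .types import MISSING, SvSet


def per_sv_association(svset: SvSet, phenotype: np.ndarray) -> pd.DataFrame:
    """Per-locus OLS of phenotype on dosage.

    Columns: ``sv_id, beta, se, p, maf, n``.  Loci with fewer than 3 jointly
    observed samples or zero dosage variance are skipped (NaN, flagged in
    ``skipped``).
    """
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != svset.n_samples:
        raise ValueError("phenotype length does not match sample count")
    p_freq, _ = dosage_stats(svset.genotypes)
    rows = []
    for j, sv_id in enumerate(svset.ids):
        g = svset.genotypes[:, j].astype(float)
        ok = (g != MISSING) & ~np.isnan(y_all)
        n = int(ok.sum())
        maf = float(min(p_freq[j], 1 - p_freq[j])) if not np.isnan(p_freq[j]) else np.nan
        if n < 3 or g[ok].var() == 0:
            rows.append(
                {"sv_id": sv_id, "beta": np.nan, "se": np.nan, "p": np.nan,
                 "maf": maf, "n": n, "skipped": True}
            )
            continue
        res = stats.linregress(g[ok], y_all[ok])
        rows.append(
            {"sv_id": sv_id, "beta": float(res.slope), "se": float(res.stderr),
             "p": float(res.pvalue), "maf": maf, "n": n, "skipped": False}
        )
    return pd.DataFrame(rows)


def variance_explained(beta, se, maf, n):
    """Phenotypic variance explained by a variant from GWAS summary stats:

        v = 2 b^2 m (1-m) / (2 b^2 m (1-m) + 2 N se^2 m (1-m))

    with b the effect estimate, se its standard error, m the minor allele
    frequency and N the sample size.  The MAF factor cancels algebraically
    (v = b^2 / (b^2 + N se^2)) but the expression is evaluated as stated;
    m = 0 yields NaN (0/0, flagged undefined).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    if np.any(se <= 0):
        raise ValueError("standard error must be positive")
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("MAF must be in [0, 0.5]")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    den = num + 2.0 * n * se**2 * maf * (1.0 - maf)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = num / den
    v = np.where(maf == 0, np.nan, v)
    return float(v) if v.ndim == 0 else v


def significant_svs(
    assoc: pd.DataFrame, q: float = 0.05, min_defined: int = 20
) -> tuple[pd.DataFrame, ThresholdRecord]:
    """Flag the SVs in the top ``q`` of smallest P values (ties included).

    Deterministic given the P vector: the threshold is the value at ascending
    rank ceil(q*m); re-running on the flagged subset returns the subset.
    """
    pv = assoc["p"].to_numpy(dtype=float)
    defined = ~np.isnan(pv)
    m = int(defined.sum())
    if m == 0:
        raise ValueError("all P values undefined")
    if m < min_defined:
        import warnings

        warnings.warn(f"top-quantile rule degenerate: {m} defined P values", stacklevel=2)
    k = max(1, int(np.ceil(q * m)))
    thr = float(np.sort(pv[defined])[k - 1])
    out = assoc.copy()
    out["significant"] = defined & (pv <= thr)
    rec = ThresholdRecord(
        statistic="p", quantile=q, threshold=thr, n_defined=m,
        n_flagged=int(out["significant"].sum()),
    )
    return out, rec


DDCT_LO = 1.414  # sqrt(2)
DDCT_HI = 2.449  # sqrt(6)


def ddct_copy_number(value: float) -> str:
    """qPCR copy-number rule: ddCT in [1.414, 2.449] (inclusive) means a
    normal copy number of two; anything else does not."""
    if not np.isfinite(value):
        raise ValueError("ddCT value must be finite")
    return "two" if DDCT_LO <= value <= DDCT_HI else "not_two"


def pooled_validation_rate(assays: list[tuple[int, int]]) -> float:
    """Pooled concordance percentage over validation assays.

    Each assay contributes ``(concordant, tested)`` genotype counts; the rate
    is 100 * sum(concordant) / sum(tested).
    """
    conc = sum(c for c, _t in assays)
    tested = sum(t for _c, t in assays)
    if tested <= 0:
        raise ValueError("no tested genotypes")
    if conc > tested:
        raise ValueError("concordant count exceeds tested count")
    return 100.0 * conc / tested
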