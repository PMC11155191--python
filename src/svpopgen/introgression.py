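"""Allele-frequency scan for candidate wild-to-domestic introgressed SVs.

A domestic population's SV is called introgressed when

(i)   it is carried in that population (frequency > 0), absent (frequency
      exactly 0) from every other domestic population, and fixed (frequency
      exactly 1) in at least one wild species;
(ii)  its frequency is exactly 0 in the designated outgroup species, to
      exclude shared ancestral alleles; and
(iii) population-level guards hold: every population consulted has at least
      ``min_samples`` genotyped samples overall, and only recipient
      populations with more than ``min_svs`` candidate SVs are reported
      (guarding against drift).

"Fixed" and "absent" are evaluated over non-missing calls; a population with
no genotyped sample at a locus cannot certify absence or fixation, so the
locus fails there (conservative).  A frequency tolerance (default 0) exists
because exactness is fragile under missingness at small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import dosage_stats
from .types import Metadata, SvSet


@dataclass(frozen=True)
class IntrogressionCall:
    sv_id: str
    recipient_pop: str
    donor_species: str
    recipient_freq: float
    donor_freq: float
    outgroup_freq: float
    max_other_domestic_freq: float


def _pop_freqs(svset: SvSet, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    sub = svset.subset_samples([s for s in samples if s in svset.samples])
    return dosage_stats(sub.genotypes)


def introgression_scan(
    svset: SvSet,
    meta: Metadata,
    domestic_pops: list[str],
    wild_species: list[str],
    outgroup_species: str,
    min_samples: int = 2,
    min_svs: int = 2,
    require_recipient_fixed: bool = False,
    tol: float = 0.0,
) -> tuple[list[IntrogressionCall], pd.DataFrame]:
    """Scan every domestic population for introgressed SVs per criteria i–iii.

    Returns the calls (only for populations clearing the ``> min_svs`` rule —
    strict inequality) and a per-population summary including populations that
    were excluded up front for having fewer than ``min_samples`` samples.
    ``require_recipient_fixed`` demands frequency 1 in the recipient instead
    of mere presence.
    """
    strata_pop = meta.strata("population")
    strata_sp = meta.strata("species")
    if outgroup_species not in strata_sp:
        raise ValueError(f"outgroup species {outgroup_species!r} absent from metadata")

    excluded = [
        p for p in domestic_pops if len(strata_pop.get(p, [])) < min_samples
    ]
    scanned = [p for p in domestic_pops if p not in excluded]

    dom_freq = {}
    dom_called = {}
    for p in scanned:
        f, n = _pop_freqs(svset, strata_pop[p])
        dom_freq[p], dom_called[p] = f, n
    wild_freq = {}
    wild_called = {}
    for w in wild_species:
        if w not in strata_sp:
            raise ValueError(f"wild species {w!r} absent from metadata")
        f, n = _pop_freqs(svset, strata_sp[w])
        wild_freq[w], wild_called[w] = f, n
    out_freq, out_called = _pop_freqs(svset, strata_sp[outgroup_species])

    ids = svset.ids
    calls_by_pop: dict[str, list[IntrogressionCall]] = {p: [] for p in scanned}
    for j in range(svset.n_loci):
        # criterion ii: certified absent in outgroup
        if out_called[j] == 0 or not (out_freq[j] <= tol):
            continue
        # fixed wild donors
        donors = [
            w
            for w in wild_species
            if wild_called[w][j] > 0 and wild_freq[w][j] >= 1.0 - tol
        ]
        if not donors:
            continue
        for p in scanned:
            if dom_called[p][j] == 0 or not (dom_freq[p][j] > tol):
                continue
            others_ok = True
            for q in scanned:
                if q == p:
                    continue
                if dom_called[q][j] == 0 or not (dom_freq[q][j] <= tol):
                    others_ok = False
                    break
            if not others_ok:
                continue
            if require_recipient_fixed and dom_freq[p][j] < 1.0 - tol:
                continue
            other_max = max(
                (dom_freq[q][j] for q in scanned if q != p and dom_called[q][j] > 0),
                default=0.0,
            )
            calls_by_pop[p].append(
                IntrogressionCall(
                    sv_id=ids[j],
                    recipient_pop=p,
                    donor_species=donors[0],
                    recipient_freq=float(dom_freq[p][j]),
                    donor_freq=float(wild_freq[donors[0]][j]),
                    outgroup_freq=float(out_freq[j]),
                    max_other_domestic_freq=float(other_max),
                )
            )

    calls: list[IntrogressionCall] = []
    rows = []
    for p in domestic_pops:
        if p in excluded:
            rows.append(
                {"population": p, "n_samples": len(strata_pop.get(p, [])),
                 "n_candidates": 0, "reported": False, "excluded_small": True}
            )
            continue
        n_cand = len(calls_by_pop[p])
        reported = n_cand > min_svs
        if reported:
            calls.extend(calls_by_pop[p])
        rows.append(
            {"population": p, "n_samples": len(strata_pop[p]),
             "n_candidates": n_cand, "reported": reported, "excluded_small": False}
        )
    return calls, pd.DataFrame(rows)
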