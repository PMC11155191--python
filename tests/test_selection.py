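from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from svpopgen.cohort import frequency_matrix
from svpopgen.selection import (
    candidate_selection,
    derived_frequencies,
    di_sv,
    fst_permutation_pvalue,
    group_freq_wilcoxon,
    pbs,
    polarize_ancestral,
    top_quantile_flags,
    wilcoxon_rank_sum,
)
from svpopgen.simulate import PopulationSpec, Scenario, SelectedLocus, simulate_cohort
from svpopgen.types import MISSING

from conftest import make_meta, make_svset, wc_theta_oracle


def _meta_ab(n_a, n_b, pop_a="dom", pop_b="wld", group_b="wild"):
    assign = {}
    for i in range(n_a + n_b):
        if i < n_a:
            assign[f"s{i+1}"] = (pop_a, "native", "sheep")
        else:
            assign[f"s{i+1}"] = (pop_b, group_b, "mouflon")
    return make_meta(assign)


# ---------------------------------------------------------------------------
# polarization / DI_SV


def test_majority_allele_polarization_counts():
    svset = make_svset([[0, 0, 1]])  # 5 ref, 1 alt copies in the wild pop
    meta = make_meta({s: ("wld", "wild", "mouflon") for s in svset.samples})
    pol = polarize_ancestral(svset, meta, "wld")
    assert pol["ancestral"].iloc[0] == "ref"
    der = derived_frequencies(svset, meta, pol, ["wld"])
    assert der["wld"].iloc[0] == pytest.approx(1 / 6)


def test_polarization_tie_is_ambiguous_and_excluded():
    svset = make_svset([[1, 1]])
    meta = make_meta({s: ("wld", "wild", "mouflon") for s in svset.samples})
    pol = polarize_ancestral(svset, meta, "wld")
    assert pol["ancestral"].iloc[0] == "ambiguous"
    der = derived_frequencies(svset, meta, pol, ["wld"])
    assert np.isnan(der["wld"].iloc[0])


def test_no_wild_calls_is_unpolarizable():
    svset = make_svset([[MISSING, MISSING, 1]])
    meta = make_meta(
        {"s1": ("wld", "wild", "mouflon"), "s2": ("wld", "wild", "mouflon"),
         "s3": ("dom", "native", "sheep")}
    )
    pol = polarize_ancestral(svset, meta, "wld")
    assert pol["ancestral"].iloc[0] == "unpolarizable"


def test_polarization_recovers_simulated_ancestral_state():
    # alt is ancestral where p0 > 0.5: polarization should label those 'alt'
    sc = Scenario(
        genome=[("chr1", 50_000_000)],
        n_loci=2000,
        populations=[
            PopulationSpec("dom", "native", "sheep", 30, 0.1),
            PopulationSpec("wld", "wild", "mouflon", 30, 0.05),
        ],
        seed=21,
    )
    svset, meta, truth = simulate_cohort(sc)
    pol = polarize_ancestral(svset, meta, "wld").set_index("sv_id")
    p0 = pd.Series(truth.p0)
    clear = p0[(p0 < 0.35) | (p0 > 0.65)].index  # away from the tie region
    labels = pol.loc[clear, "ancestral"]
    ok = labels.isin(["ref", "alt"])
    expected = np.where(p0[clear] > 0.5, "alt", "ref")
    agree = (labels[ok] == expected[ok]).mean()
    assert agree > 0.95


def test_di_sv_signed_difference_and_swap_flip():
    svset = make_svset([[2, 2, 2, 2, 2, 0, 0, 0, 0, 1]])
    meta = _meta_ab(5, 5)
    pol = polarize_ancestral(svset, meta, "wld")  # wild: 9 ref,1 alt -> ref anc
    der = derived_frequencies(svset, meta, pol, ["dom", "wld"])
    d1 = di_sv(der, "dom", "wld")["di_sv"].iloc[0]
    d2 = di_sv(der, "wld", "dom")["di_sv"].iloc[0]
    assert d1 == pytest.approx(1.0 - 0.1)
    assert d2 == pytest.approx(-d1)


# ---------------------------------------------------------------------------
# permutation P


def test_fixed_difference_has_permutation_p_zero():
    svset = make_svset([[2, 2, 2, 2, 0, 0, 0, 0]])
    meta = _meta_ab(4, 4)
    res = fst_permutation_pvalue(svset, meta, "dom", "wld", n_perm=50, seed=0)
    assert res["theta"].iloc[0] == pytest.approx(1.0)
    assert res["p_perm"].iloc[0] == 0.0


def test_permutation_p_matches_exhaustive_enumeration():
    col = [0, 1, 2, 2, 0, 0, 1, 0]
    svset = make_svset([col])
    meta = _meta_ab(4, 4)
    # exhaustive oracle over all C(8,4) = 70 label splits, strict ">" rule
    obs = wc_theta_oracle([col[:4], col[4:]])
    count = total = 0
    for comb in combinations(range(8), 4):
        ga = [col[i] for i in comb]
        gb = [col[i] for i in range(8) if i not in comb]
        th = wc_theta_oracle([ga, gb])
        total += 1
        if not np.isnan(th) and th > obs:
            count += 1
    exact_p = count / total
    res = fst_permutation_pvalue(svset, meta, "dom", "wld", n_perm=10_000, seed=2)
    assert res["p_perm"].iloc[0] == pytest.approx(exact_p, abs=0.02)


def test_permutation_p_uniform_under_null():
    # true null: one population split into two arbitrary labels, so the two
    # "populations" share the same empirical distribution
    from svpopgen.cohort import dosage_stats
    from svpopgen.types import Metadata, SampleMeta

    sc = Scenario(
        genome=[("chr1", 50_000_000)],
        n_loci=400,
        populations=[PopulationSpec("P", "native", "sheep", 120, 0.08)],
        seed=13,
    )
    svset, _meta, _ = simulate_cohort(sc)
    meta = Metadata(
        [
            SampleMeta(s, "A" if i < 60 else "B", "native", "sheep")
            for i, s in enumerate(svset.samples)
        ]
    )
    res = fst_permutation_pvalue(
        svset, meta, "A", "B", n_perm=200, seed=3, per_locus=True
    )
    p_f, _ = dosage_stats(svset.genotypes)
    maf = np.minimum(p_f, 1 - p_f)
    p = res["p_perm"].to_numpy()[maf >= 0.1]
    p = p[~np.isnan(p)]
    assert len(p) > 100
    # discrete uniform on {0, 1/B, ...}: half-step continuity shift for KS
    ks = sps.kstest(p + 0.5 / 200, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# PBS


def test_pbs_closed_forms():
    assert pbs(0.0, 0.0, 0.0) == pytest.approx(0.0)
    assert pbs(0.5, 0.5, 0.0) == pytest.approx(-np.log(0.5))
    assert np.isfinite(pbs(1.0, 0.5, 0.5))  # clamped, no log(0)


@settings(deadline=None, max_examples=100)
@given(
    st.floats(-0.2, 0.95), st.floats(-0.2, 0.95), st.floats(-0.2, 0.95)
)
def test_pbs_symmetry_and_monotonicity(t12, t13, t23):
    # symmetric under exchanging populations 2 and 3
    assert pbs(t12, t13, t23) == pytest.approx(pbs(t13, t12, t23))
    # strictly increasing in theta_12
    if t12 < 0.9:
        assert pbs(t12 + 0.05, t13, t23) > pbs(t12, t13, t23)


def test_pbs_equidistant_outgroup_reduces_to_half_t12():
    t12 = 0.3
    for t in (0.1, 0.4):
        expected = -np.log1p(-t12) / 2
        assert pbs(t12, t, t) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# candidate calling


def test_top_quantile_rank_arithmetic():
    vals = np.arange(100, dtype=float)
    flags, rec = top_quantile_flags(vals, q=0.05)
    assert flags.sum() == 5
    assert rec.threshold == 95.0


def test_top_quantile_includes_threshold_ties():
    vals = np.array([1.0] * 95 + [5.0] * 5 + [5.0] * 3)  # ties beyond rank 5
    flags, _ = top_quantile_flags(vals, q=0.05)
    assert flags.sum() == 8


def test_intersection_rule_disjoint_sets_warns_empty():
    table = pd.DataFrame(
        {
            "p_perm": [0.01] * 10 + [0.5] * 30,
            "di_sv": [0.0] * 10 + [0.9] * 2 + [0.1] * 28,
        }
    )
    with pytest.warns(UserWarning, match="empty candidate"):
        out, rec = candidate_selection(table, alpha=0.05, q=0.05)
    assert rec["n_candidates"] == 0


def test_candidate_selection_idempotent_from_stored_threshold():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({"p_perm": rng.uniform(size=200), "di_sv": rng.normal(size=200)})
    out, rec = candidate_selection(table)
    re_flag = (out["p_perm"] < rec["alpha"]) & (out["di_sv"] >= rec["stat_threshold"])
    assert (re_flag == out["candidate"]).all()


def test_planted_selection_recovered_by_intersection_rule():
    """Power check: delta = 0.6 planted loci pass P < 0.05 AND top-5% DI_SV
    with precision and recall >= 0.5 at 30+30 samples."""
    sc = Scenario(
        genome=[("chr1", 60_000_000)],
        n_loci=2000,
        populations=[
            PopulationSpec("dom", "native", "sheep", 30, 0.1),
            PopulationSpec("wld", "wild", "mouflon", 30, 0.05),
        ],
        selected_loci=[SelectedLocus(("dom",), delta=0.6, p0=0.15) for _ in range(100)],
        seed=29,
    )
    svset, meta, truth = simulate_cohort(sc)
    perm = fst_permutation_pvalue(svset, meta, "dom", "wld", n_perm=200, seed=1)
    pol = polarize_ancestral(svset, meta, "wld")
    der = derived_frequencies(svset, meta, pol, ["dom", "wld"])
    table = perm.merge(di_sv(der, "dom", "wld"), on="sv_id")
    out, _rec = candidate_selection(table, alpha=0.05, q=0.05)
    called = set(out.loc[out["candidate"], "sv_id"])
    planted = set(truth.selected_ids)
    precision = len(called & planted) / len(called)
    recall = len(called & planted) / len(planted)
    assert precision >= 0.5
    assert recall >= 0.5


def test_sparsely_planted_loci_rank_in_di_sv_upper_tail():
    """With planted loci well below the top-5% capacity, nearly all of them
    rank in the DI_SV upper tail (delta = 0.6, 30+30 samples, 2000 loci)."""
    sc = Scenario(
        genome=[("chr1", 60_000_000)],
        n_loci=2000,
        populations=[
            PopulationSpec("dom", "native", "sheep", 30, 0.1),
            PopulationSpec("wld", "wild", "mouflon", 30, 0.05),
        ],
        selected_loci=[SelectedLocus(("dom",), delta=0.6, p0=0.15) for _ in range(10)],
        seed=33,
    )
    svset, meta, truth = simulate_cohort(sc)
    pol = polarize_ancestral(svset, meta, "wld")
    der = derived_frequencies(svset, meta, pol, ["dom", "wld"])
    table = di_sv(der, "dom", "wld")
    di_flags, _ = top_quantile_flags(table["di_sv"], q=0.05)
    top_di = set(table.loc[di_flags, "sv_id"])
    planted = set(truth.selected_ids)
    assert len(planted & top_di) / len(planted) >= 0.9


# ---------------------------------------------------------------------------
# Wilcoxon


def test_wilcoxon_identical_groups_maximal_p():
    assert wilcoxon_rank_sum([0.5, 0.5, 0.5], [0.5, 0.5]) == pytest.approx(1.0)


def test_wilcoxon_matches_exhaustive_rank_permutation_oracle():
    x, y = [0.9, 0.8, 0.85], [0.1, 0.2]
    pooled = x + y
    ranks = sps.rankdata(pooled)
    mu = 3 * 6 / 2.0
    obs = abs(ranks[:3].sum() - mu)
    hits = sum(
        1
        for comb in combinations(range(5), 3)
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-12
    )
    assert wilcoxon_rank_sum(x, y) == pytest.approx(hits / 10)


def test_group_wilcoxon_bh_adjustment_monotone():
    rng = np.random.default_rng(4)
    sc = Scenario(
        genome=[("chr1", 20_000_000)],
        n_loci=60,
        populations=[
            PopulationSpec(f"p{i}", "native", "sheep", 8, 0.1) for i in range(6)
        ],
        seed=2,
    )
    svset, meta, _ = simulate_cohort(sc)
    fm = frequency_matrix(svset, meta)
    res = group_freq_wilcoxon(fm, ["p0", "p1", "p2"], ["p3", "p4", "p5"])
    ok = res.dropna()
    assert (ok["p_adj"] >= ok["p_raw"] - 1e-12).all()
    # BH preserves the P-value ordering
    srt = ok.sort_values("p_raw")
    assert (np.diff(srt["p_adj"].to_numpy()) >= -1e-12).all()
    with pytest.raises(ValueError):
        group_freq_wilcoxon(fm, ["p0"], ["p1", "p2"])
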