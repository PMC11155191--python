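import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from svpopgen.simulate import (
    PopulationSpec,
    Scenario,
    simulate_cohort,
)
from svpopgen.types import Metadata, SampleMeta, SvRecord, SvSet


@pytest.fixture(scope="session")
def default_cohort():
    """Study-like default scenario at a small locus count."""
    scenario = Scenario.default(seed=3, n_loci=600)
    svset, meta, truth = simulate_cohort(scenario)
    return scenario, svset, meta, truth


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two equally drifted populations, no planted loci."""
    scenario = Scenario(
        genome=[("chr1", 50_000_000)],
        n_loci=2000,
        populations=[
            PopulationSpec("dom", "native", "sheep", 30, 0.15),
            PopulationSpec("wild", "wild", "mouflon", 30, 0.15),
        ],
        seed=11,
    )
    svset, meta, truth = simulate_cohort(scenario)
    return svset, meta, truth


def make_svset(columns, svtype="DEL", chrom="chr1", spacing=10_000, length=500):
    """Toy SvSet from genotype columns: list of per-locus sample-dosage lists."""
    columns = np.asarray(columns, dtype=np.int8)
    n_loci, n_samples = columns.shape
    records = []
    for j in range(n_loci):
        start = 1_000 + j * spacing
        records.append(
            SvRecord(
                id=f"sv{j + 1}",
                chrom=chrom,
                start=start,
                end=start + length - 1,
                svtype=svtype,
                length=length,
            )
        )
    return SvSet(records, columns.T, [f"s{i + 1}" for i in range(n_samples)])


def make_meta(assignments):
    """Metadata from {sample_id: (population, group, species)}."""
    return Metadata(
        [SampleMeta(s, p, g, sp) for s, (p, g, sp) in assignments.items()]
    )


# ---------------------------------------------------------------------------
# independent Weir & Cockerham (1984) oracle, scalar, written from the
# published variance-component formulas before the vectorized implementation


def wc_theta_oracle(genotype_lists):
    """theta-hat for one locus from per-population diploid genotype lists."""
    r = len(genotype_lists)
    n = [len(g) for g in genotype_lists]
    p = [sum(g) / (2 * ni) for g, ni in zip(genotype_lists, n)]
    h = [sum(1 for x in g if x == 1) / ni for g, ni in zip(genotype_lists, n)]
    n_bar = sum(n) / r
    n_total = sum(n)
    n_c = (n_total - sum(ni**2 for ni in n) / n_total) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_total
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_total
    a = (n_bar / n_c) * (
        s2
        - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")
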