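"""Synthetic multi-population diploid SV cohorts with ground truth.

The generator emulates the statistical structure of a merged multi-sample SV
call set from wild and domestic small-ruminant populations:

* a DEL-dominant SV type mix with log-uniform lengths (most < 1 kb);
* a rare-skewed ancestral allele-frequency spectrum (Beta law);
* population divergence under the Balding–Nichols drift model, where each
  population's frequency is ``Beta(p0(1-F)/F, (1-p0)(1-F)/F)`` around the
  ancestral ``p0`` so that the expected Weir–Cockerham F_ST equals ``F``;
* breakpoints drawn from a mixture of a uniform background and Gaussian
  hotspot clusters;
* planted selected loci (a frequency shift ``delta`` in target populations),
  planted introgressed loci constructed to satisfy the allele-frequency
  introgression criteria exactly, and SV-linked phenotypes.

Everything is deterministic given the scenario seed, and a
:class:`TruthRecord` carries the ground truth for recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import io as svio
from .types import (
    MISSING,
    Genome,
    GenomicInterval,
    IntervalSet,
    GeneModel,
    Metadata,
    QtlRecord,
    SampleMeta,
    SvRecord,
    SvSet,
)

DEFAULT_TYPE_MIX = {"DEL": 0.77, "DUP": 0.05, "INV": 0.02, "INS": 0.10, "TRA": 0.06}

DEFAULT_LENGTH_LAW = {
    "DEL": (50, 10_000),
    "DUP": (100, 100_000),
    "INV": (100, 100_000),
    "INS": (50, 5_000),
    "TRA": (50, 10_000),
}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    group: str
    species: str
    n_samples: int
    drift_f: float

    def __post_init__(self) -> None:
        if not (0 < self.drift_f < 1):
            raise ValueError(f"population {self.name}: drift F must be in (0,1)")
        if self.n_samples < 1:
            raise ValueError(f"population {self.name}: n_samples must be >= 1")


@dataclass(frozen=True)
class HotspotCluster:
    chrom: str
    center: int
    sd: int
    weight: float


@dataclass(frozen=True)
class SelectedLocus:
    """A locus whose frequency is shifted by ``delta`` in ``target_pops``.

    ``p0`` optionally pins the ancestral frequency; ``index`` optionally pins
    the locus (final sorted order), else one is assigned.
    """

    target_pops: tuple[str, ...]
    delta: float
    p0: Optional[float] = None
    index: Optional[int] = None


@dataclass(frozen=True)
class IntrogressedLocus:
    """A locus planted to satisfy the introgression criteria.

    Fixed (frequency 1) in all populations of ``donor_species``, carried at
    ``recipient_freq`` in ``recipient_pop``, absent from every other domestic
    population and from the outgroup.
    """

    recipient_pop: str
    donor_species: str
    recipient_freq: float = 0.4
    index: Optional[int] = None


@dataclass(frozen=True)
class PhenoSpec:
    n_causal: int
    beta: float
    noise_sd: float
    causal_indices: Optional[tuple[int, ...]] = None


@dataclass
class Scenario:
    """Full specification of a synthetic SV cohort."""

    genome: list[tuple[str, int]]
    n_loci: int
    populations: list[PopulationSpec]
    type_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    length_law: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_LAW)
    )
    maf_law: tuple[float, float] = (0.3, 2.0)
    hotspot_clusters: list[HotspotCluster] = field(default_factory=list)
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    introgressed_loci: list[IntrogressedLocus] = field(default_factory=list)
    pheno: Optional[PhenoSpec] = None
    outgroup_population: Optional[str] = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mix probabilities sum to {total}, expected 1")
        for t, (lo, hi) in self.length_law.items():
            if lo < 50 or hi > 1_000_000 or lo > hi:
                raise ValueError(f"length law for {t} outside [50 bp, 1 Mb]")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for sel in self.selected_loci:
            if sel.p0 is not None and not (0.0 <= sel.p0 + sel.delta <= 1.0):
                raise ValueError(
                    f"infeasible selected locus: p0={sel.p0} with delta={sel.delta} "
                    "leaves [0,1]"
                )
            unknown = set(sel.target_pops) - set(names)
            if unknown:
                raise ValueError(f"selected locus targets unknown populations {unknown}")
        species = {p.species for p in self.populations}
        for intro in self.introgressed_loci:
            if intro.recipient_pop not in names:
                raise ValueError(f"unknown recipient population {intro.recipient_pop}")
            if intro.donor_species not in species:
                raise ValueError(f"unknown donor species {intro.donor_species}")
            if not (0 < intro.recipient_freq <= 1):
                raise ValueError("recipient_freq must be in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    @classmethod
    def default(cls, seed: int = 0, n_loci: int = 3000) -> "Scenario":
        """The reference study-like scenario used throughout the test suite.

        A wild ancestral-proxy population, a distant wild outgroup, two native
        and one improved domestic population; two breakpoint hotspot clusters;
        30 domestication-selected loci (delta = 0.6), 5 introgressed loci into
        one native population, and two causal loci for a quantitative trait.
        """
        genome = [("chr1", 60_000_000), ("chr2", 50_000_000), ("chr3", 40_000_000)]
        pops = [
            PopulationSpec("mouflon", "wild", "asiatic_mouflon", 15, 0.05),
            PopulationSpec("bighorn", "wild", "bighorn", 6, 0.30),
            PopulationSpec("native_A", "native", "sheep", 20, 0.12),
            PopulationSpec("native_B", "native", "sheep", 20, 0.12),
            PopulationSpec("improved_A", "improved", "sheep", 15, 0.20),
        ]
        clusters = [
            HotspotCluster("chr1", 45_000_000, 250_000, 8.0),
            HotspotCluster("chr2", 10_000_000, 250_000, 8.0),
        ]
        selected = [
            SelectedLocus(("native_A", "native_B", "improved_A"), delta=0.6, p0=0.15)
            for _ in range(30)
        ]
        introgressed = [
            IntrogressedLocus("native_A", "asiatic_mouflon") for _ in range(5)
        ]
        return cls(
            genome=genome,
            n_loci=n_loci,
            populations=pops,
            hotspot_clusters=clusters,
            selected_loci=selected,
            introgressed_loci=introgressed,
            pheno=PhenoSpec(n_causal=2, beta=1.0, noise_sd=2.0),
            outgroup_population="bighorn",
            missing_rate=0.02,
            seed=seed,
        )


@dataclass
class TruthRecord:
    """Ground truth for every simulated locus, keyed by SV id."""

    p0: dict[str, float]
    pop_freq: dict[str, dict[str, float]]  # sv_id -> population -> true frequency
    cluster_of: dict[str, int]  # -1 = uniform background
    selected_ids: list[str]
    introgressed: list[dict]  # {sv_id, recipient_pop, donor_species}
    causal: list[dict]  # {sv_id, beta}
    noise_sd: Optional[float]
    seed: int

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _draw_positions(scenario: Scenario, svtypes: list[str], lengths: np.ndarray, rng):
    """Chromosome and 0-based start per locus from the hotspot mixture."""
    chrom_names = [c for c, _ in scenario.genome]
    chrom_len = {c: l for c, l in scenario.genome}
    lens = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    clusters = scenario.hotspot_clusters
    weights = np.array([1.0] + [c.weight for c in clusters])
    weights = weights / weights.sum()
    n = len(svtypes)
    source = rng.choice(len(weights), size=n, p=weights) - 1  # -1 = background
    chroms, starts = [], np.empty(n, dtype=np.int64)
    bg_chrom_idx = rng.choice(len(chrom_names), size=n, p=lens / lens.sum())
    for i in range(n):
        span = int(lengths[i]) if svtypes[i] not in ("INS", "TRA") else 1
        if source[i] < 0:
            chrom = chrom_names[bg_chrom_idx[i]]
            hi = max(1, chrom_len[chrom] - span)
            pos = int(rng.integers(0, hi))
        else:
            cl = clusters[source[i]]
            chrom = cl.chrom
            hi = max(1, chrom_len[chrom] - span)
            pos = int(np.clip(round(rng.normal(cl.center, cl.sd)), 0, hi - 1))
        chroms.append(chrom)
        starts[i] = pos
    return chroms, starts, source


def simulate_cohort(scenario: Scenario) -> tuple[SvSet, Metadata, TruthRecord]:
    """Draw a cohort under the scenario; deterministic given ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_loci
    types = list(scenario.type_mix)
    probs = np.array([scenario.type_mix[t] for t in types])
    svtypes = [types[i] for i in rng.choice(len(types), size=n, p=probs)]
    lengths = np.empty(n, dtype=np.int64)
    for i, t in enumerate(svtypes):
        lo, hi = scenario.length_law[t]
        lengths[i] = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    chroms, starts, source = _draw_positions(scenario, svtypes, lengths, rng)

    chrom_names = [c for c, _ in scenario.genome]
    chrom_len = {c: l for c, l in scenario.genome}
    # build records in final sorted order (ids assigned along the SvSet sort
    # key so locus order and id order coincide), then assign ids
    ends = np.empty(n, dtype=np.int64)
    for i in range(n):
        start1 = int(starts[i]) + 1
        ends[i] = start1 if svtypes[i] in ("INS", "TRA") else start1 + int(lengths[i]) - 1
    order = sorted(
        range(n), key=lambda i: (chroms[i], int(starts[i]) + 1, int(ends[i]))
    )
    records: list[SvRecord] = []
    cluster_of: dict[str, int] = {}
    for rank, i in enumerate(order):
        sid = f"SV{rank + 1:06d}"
        start1 = int(starts[i]) + 1  # to 1-based
        chrom2 = pos2 = None
        if svtypes[i] == "TRA":
            others = [c for c in chrom_names if c != chroms[i]] or [chroms[i]]
            chrom2 = others[int(rng.integers(0, len(others)))]
            pos2 = int(rng.integers(1, chrom_len[chrom2]))
        records.append(
            SvRecord(
                id=sid,
                chrom=chroms[i],
                start=start1,
                end=int(ends[i]),
                svtype=svtypes[i],
                length=int(lengths[i]),
                chrom2=chrom2,
                pos2=pos2,
            )
        )
        cluster_of[sid] = int(source[i])

    # ancestral frequencies
    a, b = scenario.maf_law
    p0 = np.clip(rng.beta(a, b, size=n), 1e-4, 1 - 1e-4)

    # assign special loci to distinct indices (sorted-order indices)
    taken: set[int] = set()

    def _claim(idx: Optional[int]) -> int:
        if idx is not None:
            if idx in taken:
                raise ValueError(f"locus index {idx} claimed twice")
            taken.add(idx)
            return idx
        while True:
            cand = int(rng.integers(0, n))
            if cand not in taken:
                taken.add(cand)
                return cand

    sel_idx = [
        ( _claim(s.index), s) for s in scenario.selected_loci
    ]
    intro_idx = [(_claim(s.index), s) for s in scenario.introgressed_loci]
    causal_idx: list[int] = []
    if scenario.pheno is not None:
        if scenario.pheno.causal_indices is not None:
            causal_idx = [_claim(i) for i in scenario.pheno.causal_indices]
        else:
            causal_idx = [_claim(None) for _ in range(scenario.pheno.n_causal)]
        # causal loci get mid-range ancestral frequency so they segregate
        for i in causal_idx:
            p0[i] = rng.uniform(0.3, 0.7)
    for i, s in sel_idx:
        if s.p0 is not None:
            p0[i] = s.p0

    # Balding–Nichols population frequencies
    pops = scenario.populations
    freq = np.empty((len(pops), n))
    for k, pop in enumerate(pops):
        F = pop.drift_f
        alpha = p0 * (1 - F) / F
        beta = (1 - p0) * (1 - F) / F
        freq[k] = rng.beta(alpha, beta)

    pop_index = {p.name: k for k, p in enumerate(pops)}
    for i, s in sel_idx:
        for name in s.target_pops:
            freq[pop_index[name], i] = np.clip(freq[pop_index[name], i] + s.delta, 0, 1)

    domestic = [p.name for p in pops if p.group in ("native", "improved")]
    for i, s in intro_idx:
        for k, pop in enumerate(pops):
            if pop.species == s.donor_species:
                freq[k, i] = 1.0
            elif pop.name == s.recipient_pop:
                freq[k, i] = s.recipient_freq
            elif pop.name in domestic or pop.name == scenario.outgroup_population:
                freq[k, i] = 0.0

    # genotypes
    geno_blocks = []
    samples: list[str] = []
    meta_rows: list[SampleMeta] = []
    intro_cols = {i for i, _ in intro_idx}
    protected = intro_cols | set(causal_idx)
    for k, pop in enumerate(pops):
        block = rng.binomial(2, freq[k][None, :], size=(pop.n_samples, n)).astype(np.int8)
        if pop.species in {s.donor_species for _, s in intro_idx} or pop.name in domestic:
            # re-impose exact fixation/absence on introgression-constrained loci
            for i, s in intro_idx:
                if pop.species == s.donor_species:
                    block[:, i] = 2
                elif pop.name in domestic and pop.name != s.recipient_pop:
                    block[:, i] = 0
                elif pop.name == scenario.outgroup_population:
                    block[:, i] = 0
        if scenario.outgroup_population == pop.name:
            for i, _s in intro_idx:
                block[:, i] = 0
        for i, s in intro_idx:
            if pop.name == s.recipient_pop:
                tries = 0
                while not (block[:, i] > 0).any():
                    block[:, i] = rng.binomial(2, s.recipient_freq, size=pop.n_samples)
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError("could not plant introgressed carrier")
        if scenario.missing_rate > 0:
            mask = rng.random(block.shape) < scenario.missing_rate
            mask[:, list(protected)] = False
            block[mask] = MISSING
        geno_blocks.append(block)
        for s_i in range(pop.n_samples):
            sid = f"{pop.name}_{s_i + 1:03d}"
            samples.append(sid)
            meta_rows.append(SampleMeta(sid, pop.name, pop.group, pop.species))
    genotypes = np.vstack(geno_blocks)

    ids = [r.id for r in records]
    truth = TruthRecord(
        p0={ids[i]: float(p0[i]) for i in range(n)},
        pop_freq={
            ids[i]: {pops[k].name: float(freq[k, i]) for k in range(len(pops))}
            for i in range(n)
        },
        cluster_of=cluster_of,
        selected_ids=sorted(ids[i] for i, _ in sel_idx),
        introgressed=[
            {"sv_id": ids[i], "recipient_pop": s.recipient_pop, "donor_species": s.donor_species}
            for i, s in intro_idx
        ],
        causal=[
            {"sv_id": ids[i], "beta": scenario.pheno.beta} for i in causal_idx
        ]
        if scenario.pheno is not None
        else [],
        noise_sd=scenario.pheno.noise_sd if scenario.pheno is not None else None,
        seed=scenario.seed,
    )
    svset = SvSet(records, genotypes, samples)
    assert svset.ids == ids, "simulator locus order drifted from sorted order"
    return svset, Metadata(meta_rows), truth


def simulate_phenotypes(
    svset: SvSet,
    causal: Sequence[tuple[str, float]],
    noise_sd: float,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Additive phenotypes ``y_i = sum_k beta_k g_ik + eps_i``.

    Missing dosages at causal loci contribute 0 (carriers only).  Returns the
    phenotype vector (sample order of ``svset``) and the realized per-locus
    variance share ``Var(beta_k g_k) / Var(y)``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    idx = {sid: j for j, sid in enumerate(svset.ids)}
    y = rng.normal(0.0, noise_sd, size=svset.n_samples)
    shares = {}
    contribs = {}
    for sv_id, beta in causal:
        if sv_id not in idx:
            raise KeyError(f"causal locus {sv_id} not in SvSet")
        g = svset.genotypes[:, idx[sv_id]].astype(float)
        g[g == MISSING] = 0.0
        contribs[sv_id] = beta * g
        y = y + beta * g
    var_y = float(np.var(y))
    for sv_id, c in contribs.items():
        shares[sv_id] = float(np.var(c) / var_y) if var_y > 0 else float("nan")
    return y, shares


def default_annotation_fixtures(
    genome: Genome, seed: int = 0, gene_spacing: int = 400_000
) -> tuple[list[GeneModel], list[QtlRecord], IntervalSet]:
    """Deterministic gene/QTL/peak fixtures tiling a genome.

    Genes are 20-kb three-exon models every ``gene_spacing`` bp with
    alternating strand and a CDS leaving one UTR exon at each end; QTLs are
    2-Mb intervals every 10 Mb with cycling trait labels; peaks are 500-bp
    intervals, one per 100 kb with a jitter drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    qtls: list[QtlRecord] = []
    peaks: list[GenomicInterval] = []
    traits = ("litter_size", "muscle_depth", "wool_fineness", "milk_yield")
    g_i = 0
    for chrom, length in genome.chroms.items():
        for start in range(200_000, length - 20_000, gene_spacing):
            strand = "+" if g_i % 2 == 0 else "-"
            exons = (
                (start, start + 2_000),
                (start + 8_000, start + 10_000),
                (start + 18_000, start + 20_000),
            )
            genes.append(
                GeneModel(
                    gene_id=f"GENE{g_i + 1:05d}",
                    chrom=chrom,
                    tx_start=start,
                    tx_end=start + 20_000,
                    strand=strand,
                    exons=exons,
                    cds_start=start + 1_000,
                    cds_end=start + 19_000,
                )
            )
            g_i += 1
        for q_start in range(2_000_000, length - 2_000_000, 10_000_000):
            qtls.append(
                QtlRecord(
                    GenomicInterval(chrom, q_start, q_start + 2_000_000),
                    trait=traits[len(qtls) % len(traits)],
                )
            )
        for p_start in range(0, length - 500, 100_000):
            jitter = int(rng.integers(0, 50_000))
            s = min(p_start + jitter, length - 501)
            peaks.append(GenomicInterval(chrom, s, s + 500, name=f"peak_{len(peaks) + 1}"))
    return genes, qtls, IntervalSet(peaks)


def write_fixture_set(
    svset: SvSet,
    meta: Metadata,
    truth: TruthRecord,
    outdir: str | os.PathLike,
    genome: Genome | None = None,
) -> dict[str, str]:
    """Write the cohort plus annotation fixtures; returns the path map."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    if genome is None:
        contigs: dict[str, int] = {}
        for r in svset.records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1_000_000)
        genome = Genome(contigs)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "meta": os.path.join(outdir, "samples.tsv"),
        "genome": os.path.join(outdir, "genome.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "genes": os.path.join(outdir, "genes.bed"),
        "qtls": os.path.join(outdir, "qtls.tsv"),
        "peaks": os.path.join(outdir, "peaks.bed"),
    }
    svio.write_sv_vcf(svset, paths["vcf"], genome=genome)
    svio.write_sample_metadata(meta, paths["meta"])
    svio.write_genome(genome, paths["genome"])
    truth.to_json(paths["truth"])
    genes, qtls, peaks = default_annotation_fixtures(genome, seed=truth.seed)
    with open(paths["genes"], "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )
    with open(paths["qtls"], "w") as fh:
        for q in qtls:
            fh.write(
                f"{q.interval.chrom}\t{q.interval.start}\t{q.interval.end}\t{q.trait}\n"
            )
    svio.write_bed(peaks, paths["peaks"])
    return paths
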