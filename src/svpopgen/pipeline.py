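"""End-to-end pipeline: filter -> diversity -> selection scans -> regions ->
annotation -> convergence -> introgression -> association, with a
machine-readable run manifest.

The pipeline consumes a fixture directory in the layout written by
:func:`svpopgen.simulate.write_fixture_set` (SV-VCF, sample metadata TSV,
genome TSV, gene/QTL/peak tables, optional truth JSON) or simulates a cohort
in place when ``simulate=True``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import assoc as assoc_mod
from . import cohort as cohort_mod
from . import convergence as conv_mod
from . import genemap
from . import introgression as intro_mod
from . import io as svio
from . import popstats
from . import regions as regions_mod
from . import selection
from . import simulate as sim_mod

ALL_STAGES = (
    "filter",
    "diversity",
    "scan",
    "regions",
    "annotate",
    "converge",
    "introgress",
    "assoc",
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for :func:`run_pipeline`."""

    input_dir: str | None = None
    out_dir: str = "svpopgen_out"
    simulate: bool = False
    n_loci: int = 2000
    stages: tuple[str, ...] = ALL_STAGES
    # filter thresholds
    min_len: int = 50
    max_len: int = 1_000_000
    max_missing: float = 0.25
    min_maf: float = 0.01
    # analysis parameters
    window_pi: int = 10_000_000
    density_window: int = 1_000_000
    density_step: int = 500_000
    hotspot_fraction: float = 0.10
    telomere_len: int = 5_000_000
    n_perm_fst: int = 200
    n_perm_convergence: int = 1000
    top_q: float = 0.05
    wild_population: str | None = None  # ancestral proxy for polarization
    outgroup_species: str | None = None  # for the introgression scan
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("min_len", "max_len", "window_pi", "density_window",
                     "density_step", "telomere_len", "n_perm_fst"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load a config from a YAML (or JSON, a YAML subset) mapping whose
        keys are the dataclass field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, outdir: str, name: str, manifest: dict) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"].append(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary.

    Two runs with identical config (including seed) produce byte-identical
    tables.  A stage failure aborts with the stage name and cause; outputs
    written before the failure are listed in the manifest as partial.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "outputs": [],
        "stages_run": [],
        "partial": False,
    }

    truth = None
    if config.simulate:
        scenario = sim_mod.Scenario.default(seed=config.seed, n_loci=config.n_loci)
        svset, meta, truth = sim_mod.simulate_cohort(scenario)
        genome = svio.Genome({c: l for c, l in scenario.genome})
        fixture_dir = os.path.join(config.out_dir, "fixture")
        sim_mod.write_fixture_set(svset, meta, truth, fixture_dir, genome=genome)
        input_dir = fixture_dir
    else:
        if config.input_dir is None:
            raise ValueError("input_dir is required unless simulate=True")
        input_dir = config.input_dir
        svset = svio.read_sv_vcf(os.path.join(input_dir, "cohort.vcf"))
        meta = svio.read_sample_metadata(os.path.join(input_dir, "samples.tsv"))
        genome = svio.read_genome(os.path.join(input_dir, "genome.tsv"))
        truth_path = os.path.join(input_dir, "truth.json")
        if os.path.exists(truth_path):
            truth = sim_mod.TruthRecord.from_json(truth_path)
    genes = svio.read_interval_table(os.path.join(input_dir, "genes.bed"), "gene")
    qtls, n_qtl_removed = svio.read_interval_table(
        os.path.join(input_dir, "qtls.tsv"), "qtl"
    )
    peaks = svio.read_interval_table(os.path.join(input_dir, "peaks.bed"), "peak")
    manifest["inputs"] = {"input_dir": input_dir, "n_qtl_removed": n_qtl_removed}

    pops = meta.strata("population")
    wild_pops = sorted(
        (p for p, s in pops.items() if all(meta[x].group == "wild" for x in s)),
        key=lambda p: -len(pops[p]),
    )
    domestic_pops = sorted(p for p in pops if p not in wild_pops)
    wild_pop = config.wild_population or (wild_pops[0] if wild_pops else None)

    filtered = svset
    annotation = None
    stage = "start"
    try:
        if "filter" in config.stages:
            stage = "filter"
            filtered, report = cohort_mod.filter_svs(
                svset, config.min_len, config.max_len, config.max_missing, config.min_maf
            )
            _write(
                pd.DataFrame(
                    [{"rule": k, "n_removed": v} for k, v in report.removed.items()]
                    + [{"rule": "retained", "n_removed": report.n_retained}]
                ),
                config.out_dir, "filter_report.tsv", manifest,
            )
            sharing = cohort_mod.sharing_summary(filtered, meta)
            _write(
                pd.DataFrame([{"cell": k, "n": v} for k, v in sharing.items()]),
                config.out_dir, "sharing_summary.tsv", manifest,
            )
            manifest["stages_run"].append(stage)

        if "diversity" in config.stages:
            stage = "diversity"
            tables = []
            for pop in sorted(pops):
                rate, n_het, n_called = popstats.heterozygosity_rate(
                    filtered, meta, pop
                )
                tables.append(
                    {"population": pop, "heterozygosity": rate,
                     "n_het": n_het, "n_called": n_called}
                )
            _write(pd.DataFrame(tables), config.out_dir, "heterozygosity.tsv", manifest)
            _write(
                popstats.windowed_pi(filtered, meta, window=config.window_pi),
                config.out_dir, "windowed_pi.tsv", manifest,
            )
            _write(
                popstats.ld_decay_profile(
                    filtered, max_pairs_per_chrom=20000, seed=config.seed
                ),
                config.out_dir, "ld_decay.tsv", manifest,
            )
            manifest["stages_run"].append(stage)

        if "scan" in config.stages:
            stage = "scan"
            if wild_pop is None or not domestic_pops:
                raise ValueError("scan stage needs a wild and a domestic population")
            native = [p for p in domestic_pops if meta[pops[p][0]].group == "native"]
            focal_dom = native[0] if native else domestic_pops[0]
            perm = selection.fst_permutation_pvalue(
                filtered, meta, focal_dom, wild_pop,
                n_perm=config.n_perm_fst, seed=config.seed,
            )
            pol = selection.polarize_ancestral(filtered, meta, wild_pop)
            derived = selection.derived_frequencies(
                filtered, meta, pol, [focal_dom, wild_pop]
            )
            di = selection.di_sv(derived, focal_dom, wild_pop)
            stat = perm.merge(di, on="sv_id")
            stat, record = selection.candidate_selection(
                stat, p_col="p_perm", stat_col="di_sv",
                alpha=0.05, q=config.top_q,
            )
            _write(stat, config.out_dir, "domestication_scan.tsv", manifest)
            with open(os.path.join(config.out_dir, "scan_thresholds.json"), "w") as fh:
                json.dump(record, fh, indent=1, sort_keys=True)
            manifest["outputs"].append("scan_thresholds.json")
            gl = popstats.global_fst(filtered, meta)
            flags, _rec = selection.top_quantile_flags(
                gl["global_fst"], q=config.top_q
            )
            gl["candidate"] = flags
            _write(gl, config.out_dir, "global_fst.tsv", manifest)
            if len(domestic_pops) >= 2 and wild_pop is not None:
                pbs_table = selection.pbs_scan(
                    filtered, meta,
                    focal=[domestic_pops[0]], contrast=[domestic_pops[1]],
                    outgroup=[wild_pop],
                )
                pbs_flags, _ = selection.top_quantile_flags(
                    pbs_table["pbs"], q=config.top_q
                )
                pbs_table["candidate"] = pbs_flags
                _write(pbs_table, config.out_dir, "pbs_scan.tsv", manifest)
            manifest["stages_run"].append(stage)

        if "regions" in config.stages:
            stage = "regions"
            density = regions_mod.breakpoint_density(
                filtered, genome, config.density_window, config.density_step
            )
            _write(density, config.out_dir, "breakpoint_density.tsv", manifest)
            hs = regions_mod.hotspot_detect(density, config.hotspot_fraction)
            _write(
                pd.DataFrame(
                    [{"chrom": g.chrom, "start": g.start, "end": g.end}
                     for g in hs.regions]
                ),
                config.out_dir, "hotspot_regions.tsv", manifest,
            )
            telo = regions_mod.telomere_enrichment(
                filtered, genome, telomere_len=config.telomere_len
            )
            with open(os.path.join(config.out_dir, "telomere_test.json"), "w") as fh:
                json.dump(telo, fh, indent=1, sort_keys=True)
            manifest["outputs"].append("telomere_test.json")
            _write(
                regions_mod.qtl_enrichment(filtered, meta, qtls, genome),
                config.out_dir, "qtl_enrichment.tsv", manifest,
            )
            peak_cls = regions_mod.peak_sv_classify(filtered, peaks.merge())
            _write(peak_cls, config.out_dir, "peak_sv.tsv", manifest)
            cands, proms = regions_mod.enhancer_candidates(peaks, genes)
            supported = regions_mod.sv_supported_enhancers(cands, filtered)
            _write(
                pd.DataFrame(
                    {
                        "n_peaks": [len(peaks)],
                        "n_promoter_peaks": [len(proms)],
                        "n_candidate_enhancers": [len(cands)],
                        "n_sv_supported": [len(supported)],
                    }
                ),
                config.out_dir, "enhancer_summary.tsv", manifest,
            )
            manifest["stages_run"].append(stage)

        if "annotate" in config.stages:
            stage = "annotate"
            annotation = genemap.classify_genic_regions(filtered, genes)
            _write(
                genemap.annotation_table(annotation),
                config.out_dir, "sv_annotation.tsv", manifest,
            )
            summary = genemap.sv_gene_summary(annotation, [g.gene_id for g in genes])
            _write(
                pd.DataFrame([asdict(summary)]),
                config.out_dir, "sv_gene_summary.tsv", manifest,
            )
            manifest["stages_run"].append(stage)

        if "converge" in config.stages:
            stage = "converge"
            if annotation is None:
                annotation = genemap.classify_genic_regions(filtered, genes)
            # demonstration on one cohort: genes hit by domestication-candidate
            # SVs vs genes hit by improvement-candidate SVs, identity orthologs
            scan_path = os.path.join(config.out_dir, "domestication_scan.tsv")
            gl_path = os.path.join(config.out_dir, "global_fst.tsv")
            if os.path.exists(scan_path) and os.path.exists(gl_path):
                dom = pd.read_csv(scan_path, sep="\t")
                imp = pd.read_csv(gl_path, sep="\t")
                genes_a = set().union(
                    *(annotation.sv_genes.get(s, set())
                      for s in dom.loc[dom["candidate"], "sv_id"])
                ) if dom["candidate"].any() else set()
                genes_b = set().union(
                    *(annotation.sv_genes.get(s, set())
                      for s in imp.loc[imp["candidate"], "sv_id"])
                ) if imp["candidate"].any() else set()
                universe = [g.gene_id for g in genes]
                omap = conv_mod.OrthologMap.from_pairs([(g, g) for g in universe])
                shared, _unmapped = conv_mod.shared_orthologs(genes_a, genes_b, omap)
                if genes_a and genes_b and shared:
                    res = conv_mod.convergence_permutation_test(
                        len(genes_a), len(genes_b), len(universe), len(shared),
                        n_perm=config.n_perm_convergence, seed=config.seed,
                    )
                    with open(
                        os.path.join(config.out_dir, "convergence.json"), "w"
                    ) as fh:
                        json.dump(res.summary(), fh, indent=1, sort_keys=True)
                    manifest["outputs"].append("convergence.json")
                else:
                    warnings.warn("convergence stage: empty gene sets; skipped test")
            manifest["stages_run"].append(stage)

        if "introgress" in config.stages:
            stage = "introgress"
            wild_species = sorted(
                {meta[s].species for s in svset.samples if meta[s].group == "wild"}
            )
            outgroup = config.outgroup_species
            if outgroup is None and len(wild_species) > 1:
                outgroup = wild_species[-1]
            if outgroup is None:
                raise ValueError("introgress stage needs an outgroup species")
            donors = [w for w in wild_species if w != outgroup]
            calls, summary = intro_mod.introgression_scan(
                filtered, meta, domestic_pops, donors, outgroup
            )
            _write(
                pd.DataFrame([asdict(c) for c in calls])
                if calls
                else pd.DataFrame(
                    columns=["sv_id", "recipient_pop", "donor_species",
                             "recipient_freq", "donor_freq", "outgroup_freq",
                             "max_other_domestic_freq"]
                ),
                config.out_dir, "introgression_calls.tsv", manifest,
            )
            _write(summary, config.out_dir, "introgression_summary.tsv", manifest)
            manifest["stages_run"].append(stage)

        if "assoc" in config.stages:
            stage = "assoc"
            if truth is not None and truth.causal:
                causal = [(c["sv_id"], c["beta"]) for c in truth.causal]
                y, _shares = sim_mod.simulate_phenotypes(
                    svset, causal, truth.noise_sd, seed=config.seed
                )
                # align phenotype to the filtered set's samples (same cohort)
                table = assoc_mod.per_sv_association(filtered, y)
                table["variance_explained"] = assoc_mod.variance_explained(
                    table["beta"].to_numpy(), table["se"].to_numpy(),
                    np.clip(table["maf"].to_numpy(), 1e-9, 0.5),
                    table["n"].to_numpy(),
                )
                table, _rec = assoc_mod.significant_svs(table, q=config.top_q)
                _write(table, config.out_dir, "association.tsv", manifest)
            else:
                warnings.warn("assoc stage: no phenotype model available; skipped")
            manifest["stages_run"].append(stage)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["partial"] = True
        _dump_manifest(manifest, config.out_dir)
        raise StageError(stage, exc) from exc

    _dump_manifest(manifest, config.out_dir)
    return manifest


def _dump_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
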