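"""End-to-end orchestration: simulate/load -> preprocess -> pca -> svm ->
network -> de -> integrate, with per-stage derived seeds, stage outputs on
disk, and a checksummed JSON manifest so identical configs reproduce
identical runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import integrate as integrate_mod
from . import network as network_mod
from . import pca as pca_mod
from . import preprocess as pre
from . import simulate as sim
from . import svm as svm_mod

logger = logging.getLogger("socortex")

STAGES = ("simulate", "preprocess", "pca", "svm", "network", "de", "integrate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing, so adding a stage never shifts
    another stage's random stream. Always below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``counts_paths``/``metadata_path``/``orthogroups_path`` point at
    real inputs, or ``simulate=True`` generates a synthetic dataset with
    ``sim_config`` (planting known structure for recovery scoring).
    """

    outdir: str = "socortex_run"
    seed: int = 0
    simulate: bool = True
    sim_config: sim.SimulationConfig | None = None
    counts_paths: dict[str, str] = field(default_factory=dict)
    metadata_path: str | None = None
    orthogroups_path: str | None = None
    terms_path: str | None = None
    stages: tuple[str, ...] = STAGES
    svm_config: svm_mod.SvmConfig = field(default_factory=svm_mod.SvmConfig)
    network_config: network_mod.NetworkConfig = field(
        default_factory=network_mod.NetworkConfig)
    pca_n_top: int = 10
    pca_alpha: float = 0.05
    de_alpha: float = 0.05
    de_min_species: int = 2
    de_balance_permutations: int = 50
    run_resampling: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        ordered = [s for s in STAGES if s in self.stages]
        if list(self.stages) != ordered:
            raise ValueError("stages must respect pipeline order")
        if not self.simulate:
            if "simulate" in self.stages:
                raise ValueError("simulate stage requested without simulate=True")
            for p in [self.metadata_path, *self.counts_paths.values()]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, klass in (("sim_config", sim.SimulationConfig),
                           ("svm_config", svm_mod.SvmConfig),
                           ("network_config", network_mod.NetworkConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)


def study_conditions(
    seed: int,
    toolkit_lfc: float = 1.5,
    clade_lfc: float = 1.0,
    rfe_floor: int = 20,
) -> tuple[sim.SimulationConfig, svm_mod.SvmConfig, network_mod.NetworkConfig]:
    """Desk-scale study conditions for end-to-end toolkit recovery.

    Six species in two clades, 300 genes of which 40 form the planted toolkit
    (log2 fold change ``toolkit_lfc`` in every species), 15 clade-restricted
    genes per clade, four phenotype-neutral co-expression modules, 8 samples
    per phenotype per species; SVM elimination to a 20-gene floor and the
    30/20/10 module-size relaxation sweep.
    """
    sim_cfg = sim.SimulationConfig(
        n_genes=300, n_toolkit_genes=40, toolkit_lfc=toolkit_lfc,
        n_clade_specific_genes=15, clade_lfc=clade_lfc,
        n_modules=4, module_size_range=(20, 35),
        n_trait_modules=0,
        n_samples_per_phenotype={sp: (8, 8) for sp in sim.DEFAULT_SPECIES},
        seed=seed)
    svm_cfg = svm_mod.SvmConfig(rfe_floor=rfe_floor, seed=seed)
    net_cfg = network_mod.NetworkConfig(
        min_module_sizes=(30, 20, 10), seed=seed)
    return sim_cfg, svm_cfg, net_cfg


def run_toolkit_study(
    seed: int, toolkit_lfc: float = 1.5, clade_lfc: float | None = None
) -> dict:
    """One end-to-end run under :func:`study_conditions`.

    ``clade_lfc`` defaults to 1.0 under signal and to 0 when ``toolkit_lfc``
    is 0 (a no-signal run means no phenotype-linked genes at all, including
    clade-restricted ones). Returns the planted truth, the three method gene
    sets, the toolkit report, recovery scores, and the per-focal-species SVM
    randomization p-values.
    """
    if clade_lfc is None:
        clade_lfc = 0.0 if toolkit_lfc == 0 else 1.0
    sim_cfg, svm_cfg, net_cfg = study_conditions(
        seed, toolkit_lfc=toolkit_lfc, clade_lfc=clade_lfc)
    dataset, truth = sim.simulate_dataset(sim_cfg)
    vst = pre.variance_stabilize(dataset, species_aware=True)
    scaled = pre.center_scale(vst, scope="per_species", metadata=dataset.samples)
    svm_out = svm_mod.run_svm_analysis(scaled, dataset.samples, svm_cfg)
    svm_set = svm_out["intersection"]["common_all"]
    net = network_mod.run_consensus_network(
        vst, dataset.samples, net_cfg, compute_preservation=False)
    de_res = de_mod.run_de(dataset, balance=False, seed=seed)
    de_set = de_mod.overlap_de(de_res.significant_sets(), min_species=2)["shared"]
    report = integrate_mod.build_toolkit(svm_set, net.trait_genes, de_set)
    recovery = report.recovery(truth)
    return {
        "truth": truth,
        "svm_set": svm_set,
        "wgcna_set": net.trait_genes,
        "de_set": de_set,
        "report": report,
        "recovery": recovery,
        "randomization_p": {
            sp: r.randomization_p for sp, r in svm_out["results"].items()},
        "n_genes": sim_cfg.n_genes,
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    manifest: dict = {"seed": config.seed, "stages": {}, "status": "running"}
    state: dict = {}

    def record(stage: str, outputs: dict[str, Path], extras: dict | None = None):
        manifest["stages"][stage] = {
            "status": "completed",
            "seed": stage_seed(config.seed, stage),
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": {k: _checksum(p) for k, p in outputs.items()},
            **(extras or {}),
        }

    try:
        for stage in config.stages:
            t0 = time.time()
            _run_stage(stage, config, state, outdir, record)
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)
        manifest["status"] = "completed"
    except Exception as exc:
        failed = next((s for s in config.stages
                       if s not in manifest["stages"]), "?")
        manifest["status"] = "failed"
        manifest["failed_stage"] = failed
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.removeHandler(handler)
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.removeHandler(handler)
    return manifest


def _run_stage(stage, config: RunConfig, state: dict, outdir: Path, record):
    if stage == "simulate":
        sc = config.sim_config or sim.SimulationConfig()
        sc = dataclasses.replace(sc, seed=stage_seed(config.seed, "simulate"))
        dataset, truth = sim.simulate_dataset(sc)
        paths = sim.write_dataset(dataset, truth, outdir / "synthetic")
        state["dataset"], state["truth"] = dataset, truth
        record(stage, paths, {"n_genes": dataset.counts.shape[0],
                              "n_samples": dataset.counts.shape[1]})
        return

    if stage == "preprocess":
        if "dataset" not in state:
            per_species = {
                sp: pre.read_counts(p) for sp, p in config.counts_paths.items()}
            metadata = pre.read_metadata(config.metadata_path)
            ortho_map, dropped = pre.read_orthogroups(
                config.orthogroups_path, species=list(per_species))
            state["dataset"] = pre.assemble_ortho_matrix(
                per_species, ortho_map, metadata)
            state["drop_log"] = dropped
        dataset = state["dataset"]
        vst = pre.variance_stabilize(dataset, species_aware=True)
        scaled = pre.center_scale(vst, scope="per_species",
                                  metadata=dataset.samples)
        state["vst"], state["scaled"] = vst, scaled
        p1 = _write_tsv(vst.values, outdir / "vst.tsv")
        p2 = _write_tsv(scaled.values, outdir / "vst_scaled.tsv")
        record(stage, {"vst": p1, "vst_scaled": p2},
               {"transform": vst.transform,
                "dispersion_trend": list(vst.dispersion_trend or [])})
        return

    if stage == "pca":
        dataset = state["dataset"]
        res = pca_mod.run_pca(state["vst"])
        traits = dataset.samples[["clade", "species", "phenotype"]]
        screen = pca_mod.trait_correlation_screen(
            res, traits, n_top=config.pca_n_top, alpha=config.pca_alpha)
        control = pca_mod.randomized_phenotype_control(
            state["vst"], dataset.samples, n_shuffles=100,
            seed=stage_seed(config.seed, "pca"))
        state["pca"] = res
        p1 = _write_tsv(res.scores, outdir / "pca_scores.tsv")
        p2 = _write_tsv(screen, outdir / "pca_trait_correlations.tsv")
        p3 = outdir / "pca_summary.json"
        p3.write_text(json.dumps({
            "explained_variance_fraction":
                res.explained_variance_fraction.round(6).to_dict(),
            "randomized_control": {
                "observed": control["observed"],
                "p_exceedance": control["p_exceedance"]},
        }, indent=1))
        record(stage, {"scores": p1, "trait_correlations": p2, "summary": p3})
        return

    if stage == "svm":
        dataset = state["dataset"]
        cfg = dataclasses.replace(
            config.svm_config, seed=stage_seed(config.seed, "svm"))
        out = svm_mod.run_svm_analysis(state["scaled"], dataset.samples, cfg)
        state["svm"] = out
        paths = {}
        for sp, r in out["results"].items():
            paths[f"trace_{sp}"] = _write_tsv(r.trace, outdir / f"svm_trace_{sp}.tsv")
            paths[f"predictors_{sp}"] = _write_tsv(
                r.predictor_genes, outdir / f"svm_predictors_{sp}.tsv")
        paths["rank_matrix"] = _write_tsv(
            out["rank_matrix"], outdir / "svm_rank_matrix.tsv")
        extras = {"randomization_p": {
            sp: r.randomization_p for sp, r in out["results"].items()}}
        if out["intersection"] is not None:
            paths["intersection"] = _write_tsv(
                out["intersection"]["membership"].astype(int),
                outdir / "svm_intersection.tsv")
            extras["n_common_all"] = len(out["intersection"]["common_all"])
        record(stage, paths, extras)
        return

    if stage == "network":
        dataset = state["dataset"]
        cfg = dataclasses.replace(
            config.network_config, seed=stage_seed(config.seed, "network"))
        res = network_mod.run_consensus_network(state["vst"], dataset.samples, cfg)
        state["network"] = res
        paths = {}
        assign = pd.DataFrame({f"min_size_{ms}": mod
                               for ms, mod in res.modules_by_size.items()})
        paths["modules"] = _write_tsv(assign, outdir / "network_modules.tsv")
        paths["gene_trait"] = _write_tsv(
            res.gene_trait, outdir / "network_gene_trait.tsv")
        for ms, mt in res.module_trait.items():
            paths[f"module_trait_{ms}"] = _write_tsv(
                mt, outdir / f"network_module_trait_min{ms}.tsv")
        extras = {"soft_power": res.soft_power,
                  "n_trait_genes": len(res.trait_genes)}
        if config.run_resampling and res.trait_genes:
            null = network_mod.resampling_null(
                state["vst"], dataset.samples, cfg,
                point_estimate=res.trait_genes)
            pr = outdir / "network_resampling.json"
            pr.write_text(json.dumps({
                "p_literal_two_tailed": null["p_literal_two_tailed"],
                "p_exceedance": null["p_exceedance"],
                "proportions": null["proportions"].tolist()}, indent=1))
            paths["resampling"] = pr
        record(stage, paths, extras)
        return

    if stage == "de":
        dataset = state["dataset"]
        res = de_mod.run_de(dataset, alpha=config.de_alpha, balance=True,
                            n_permutations=config.de_balance_permutations,
                            seed=stage_seed(config.seed, "de"))
        overlap = de_mod.overlap_de(res.significant_sets(),
                                    min_species=config.de_min_species)
        state["de"], state["de_overlap"] = res, overlap
        paths = {}
        for sp, tab in res.tables.items():
            paths[f"de_{sp}"] = _write_tsv(tab, outdir / f"de_{sp}.tsv")
        paths["overlap"] = _write_tsv(
            overlap["membership"].astype(int), outdir / "de_overlap.tsv")
        record(stage, paths, {
            "counts_by_cardinality": overlap["counts_by_cardinality"]})
        return

    if stage == "integrate":
        svm_out = state.get("svm")
        net = state.get("network")
        overlap = state.get("de_overlap")
        svm_set = (svm_out["intersection"]["common_all"]
                   if svm_out and svm_out["intersection"] else set())
        wgcna_set = net.trait_genes if net else set()
        de_set = overlap["shared"] if overlap else set()
        report = integrate_mod.build_toolkit(svm_set, wgcna_set, de_set)
        state["toolkit"] = report
        summary = report.summary()
        if state.get("truth") is not None and report.toolkit | svm_set | wgcna_set:
            rec = report.recovery(state["truth"])
            summary["recovery"] = {"precision": rec.precision,
                                   "recall": rec.recall, "f1": rec.f1}
        p1 = outdir / "toolkit_genes.tsv"
        pd.Series(sorted(report.toolkit), name="gene").to_csv(
            p1, sep="\t", index=False)
        p2 = outdir / "toolkit_summary.json"
        p2.write_text(json.dumps(summary, indent=1))
        paths = {"toolkit": p1, "summary": p2}
        if config.terms_path:
            terms = pd.read_csv(config.terms_path, sep="\t")
            background = set(state["dataset"].orthogroup_ids)
            if report.toolkit:
                enr = integrate_mod.fisher_enrichment(
                    report.toolkit, background, terms)
                paths["enrichment"] = _write_tsv(enr, outdir / "enrichment.tsv")
        record(stage, paths, {k: v for k, v in summary.items()
                              if isinstance(v, (int, float))})
        return

    raise ValueError(f"unknown stage {stage!r}")
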