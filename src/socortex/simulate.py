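"""Synthetic multi-species orthogroup count data with planted ground truth.

The generator emulates the structure of a cross-species brain RNA-seq
meta-analysis of reproductive vs non-reproductive phenotypes: six species in
two clades, 3-12 samples per phenotype per species, unequal library sizes,
negative-binomial counts dominated by species/clade expression signal, a small
"toolkit" of genes with sign-consistent phenotype effects in every species,
clade-restricted effect genes, and latent-factor co-expression modules some of
which track phenotype.

Counts for gene g in sample j are drawn as

    NB(mean = lib_j * exp(base_g + clade_gc + species_gs
                          + loading_g * factor_{m(g),j} + effect_gj),
       Var = mu + alpha_g * mu^2)

with the phenotype effect ``effect_gj = sign_g * lfc * ln2 * state_j`` applied
to toolkit genes in all species, to clade-specific genes only within their
clade, and to trait modules via a state-shifted factor mean. ``state_j`` is
the 0/1 phenotype plus Gaussian noise — castes in rudimentary societies are
plastic, so individuals scatter around their nominal phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .preprocess import OrthoExpressionDataset, write_counts, write_metadata, write_orthogroups

LN2 = float(np.log(2.0))

DEFAULT_SPECIES = ("bee1", "bee2", "bee3", "wasp1", "wasp2", "wasp3")
DEFAULT_CLADES = {
    "bee1": "bees", "bee2": "bees", "bee3": "bees",
    "wasp1": "wasps", "wasp2": "wasps", "wasp3": "wasps",
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-species count generator.

    Effect sizes with ``lfc`` in the name are in log2 units; the ``*_sd``
    parameters are natural-log standard deviations of per-gene random shifts.
    ``dispersion_shape`` is (mean, sd) of log(alpha) for the log-normal
    gene-wise NB dispersion.
    """

    species: tuple[str, ...] = DEFAULT_SPECIES
    clade_of_species: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLADES))
    n_samples_per_phenotype: Mapping[str, tuple[int, int]] | None = None
    n_genes: int = 1500
    n_toolkit_genes: int = 40
    toolkit_lfc: float = 1.0
    n_clade_specific_genes: int = 20
    clade_lfc: float = 1.0
    n_modules: int = 8
    module_size_range: tuple[int, int] = (20, 40)
    n_trait_modules: int = 2
    trait_factor_shift: float = 1.5
    phenotype_state_sd: float = 0.35
    species_effect_sd: float = 1.0
    clade_effect_sd: float = 0.5
    base_mean: float = 100.0
    base_mean_log_sd: float = 1.0
    dispersion_shape: tuple[float, float] = (float(np.log(0.2)), 0.5)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    allow_role_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_phenotype is None:
            self.n_samples_per_phenotype = {sp: (8, 8) for sp in self.species}
        for sp, (nr, nn) in self.n_samples_per_phenotype.items():
            if not (3 <= nr <= 12 and 3 <= nn <= 12):
                raise ValueError(
                    f"{sp}: samples per phenotype must lie in [3, 12], got {(nr, nn)}")
        for name in ("species_effect_sd", "clade_effect_sd", "base_mean_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        if self.module_size_range[0] < 2:
            raise ValueError("modules need at least 2 genes")
        if self.n_trait_modules > self.n_modules:
            raise ValueError("n_trait_modules cannot exceed n_modules")
        missing = set(self.species) - set(self.clade_of_species)
        if missing:
            raise ValueError(f"species without clade: {sorted(missing)}")

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.clade_of_species[sp] for sp in self.species))


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated dataset, for recovery scoring."""

    toolkit_gene_ids: set[str]
    clade_specific_gene_ids: dict[str, set[str]]
    module_membership: dict[str, int]  # gene -> module id (1-based)
    trait_modules: set[int]
    realized_lfc: dict[tuple[str, str], float]  # (gene, species) -> log2 effect
    seed: int

    def module_gene_ids(self, module: int) -> set[str]:
        return {g for g, m in self.module_membership.items() if m == module}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "toolkit_gene_ids": sorted(self.toolkit_gene_ids),
            "clade_specific_gene_ids": {
                c: sorted(v) for c, v in self.clade_specific_gene_ids.items()},
            "module_membership": self.module_membership,
            "trait_modules": sorted(self.trait_modules),
            "realized_lfc": {f"{g}\t{s}": v for (g, s), v in self.realized_lfc.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            toolkit_gene_ids=set(d["toolkit_gene_ids"]),
            clade_specific_gene_ids={
                c: set(v) for c, v in d["clade_specific_gene_ids"].items()},
            module_membership={g: int(m) for g, m in d["module_membership"].items()},
            trait_modules=set(d["trait_modules"]),
            realized_lfc={
                tuple(k.split("\t")): v for k, v in d["realized_lfc"].items()},
            seed=int(d["seed"]),
        )


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    ari: float | None = None


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[OrthoExpressionDataset, SyntheticTruth]:
    """Draw one synthetic dataset; identical configs and seeds are reproducible."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = [f"OG{i:05d}" for i in range(n_genes)]

    # --- gene role assignment (disjoint unless allow_role_overlap) ---------
    clades = config.clades
    module_sizes = rng.integers(
        config.module_size_range[0], config.module_size_range[1] + 1,
        size=config.n_modules)
    n_needed = (config.n_toolkit_genes
                + config.n_clade_specific_genes * len(clades)
                + int(module_sizes.sum()))
    if not config.allow_role_overlap and n_needed > n_genes:
        raise ValueError(
            f"gene roles need {n_needed} genes but n_genes={n_genes}; "
            "increase n_genes or set allow_role_overlap=True")

    pool = list(rng.permutation(n_genes))

    def take(n: int) -> list[int]:
        if config.allow_role_overlap:
            return list(rng.choice(n_genes, size=n, replace=False))
        out, rest = pool[:n], pool[n:]
        pool[:] = rest
        return out

    toolkit_idx = take(config.n_toolkit_genes)
    clade_idx = {c: take(config.n_clade_specific_genes) for c in clades}
    module_idx = {m + 1: take(int(sz)) for m, sz in enumerate(module_sizes)}
    trait_modules = set(range(1, config.n_trait_modules + 1))

    # --- per-gene baseline, shifts, dispersions ----------------------------
    base = np.log(config.base_mean) + rng.normal(0, config.base_mean_log_sd, n_genes)
    species_shift = {
        sp: rng.normal(0, config.species_effect_sd, n_genes) for sp in config.species}
    clade_shift = {c: rng.normal(0, config.clade_effect_sd, n_genes) for c in clades}
    log_alpha_mu, log_alpha_sd = config.dispersion_shape
    alpha = np.exp(rng.normal(log_alpha_mu, log_alpha_sd, n_genes))

    toolkit_sign = rng.choice([-1.0, 1.0], size=config.n_toolkit_genes)
    clade_sign = {c: rng.choice([-1.0, 1.0], size=config.n_clade_specific_genes)
                  for c in clades}
    # module loadings: magnitude in [0.5, 1], random sign, fixed across species
    loadings = np.zeros(n_genes)
    for m, idx in module_idx.items():
        mag = rng.uniform(0.5, 1.0, len(idx))
        sgn = rng.choice([-1.0, 1.0], size=len(idx))
        loadings[idx] = mag * sgn

    # --- samples -----------------------------------------------------------
    sample_rows = []
    for sp in config.species:
        nr, nn = config.n_samples_per_phenotype[sp]
        for i in range(nr):
            sample_rows.append((f"{sp}_R{i + 1}", sp,
                                config.clade_of_species[sp], "reproductive"))
        for i in range(nn):
            sample_rows.append((f"{sp}_N{i + 1}", sp,
                                config.clade_of_species[sp], "non_reproductive"))
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "species", "clade", "phenotype"]
    ).set_index("sample_id", drop=False)
    n_samples = len(meta)
    x = (meta["phenotype"] == "reproductive").to_numpy(dtype=float)
    # continuous reproductive state: castes in rudimentary societies are
    # plastic, so individuals scatter around their nominal phenotype and
    # effect genes respond to the state, not the label
    state = x + rng.normal(0.0, config.phenotype_state_sd, n_samples)
    lo, hi = config.library_size_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))

    # --- log-mean assembly -------------------------------------------------
    log_mu = np.tile(base[:, None], (1, n_samples))
    for j, (sid, sp, cl, ph) in enumerate(meta.itertuples(index=False)):
        log_mu[:, j] += species_shift[sp] + clade_shift[cl]
    # latent module factors, per sample, phenotype-shifted for trait modules
    for m, idx in module_idx.items():
        shift = config.trait_factor_shift if m in trait_modules else 0.0
        factor = rng.normal(shift * (state - 0.5), 1.0)
        log_mu[idx, :] += np.outer(loadings[idx], factor)
    # sign-consistent toolkit effect in every species, driven by the state
    effect = np.zeros((n_genes, n_samples))
    effect[toolkit_idx, :] = np.outer(
        toolkit_sign * config.toolkit_lfc * LN2, state)
    # clade-restricted effects
    for c in clades:
        in_clade = (meta["clade"] == c).to_numpy(dtype=float)
        effect[clade_idx[c], :] = np.outer(
            clade_sign[c] * config.clade_lfc * LN2, state * in_clade)
    log_mu += effect

    mu = libsize[None, :] * np.exp(log_mu)
    if (mu <= 0).any():
        raise ValueError("non-positive expected counts")

    # --- NB sampling (Poisson limit for tiny dispersion) -------------------
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        counts[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        a = alpha[~tiny][:, None]
        counts[~tiny] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mu[~tiny]))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta.index)
    dataset = OrthoExpressionDataset(
        counts=counts_df, samples=meta,
        provenance={"source": "simulate_dataset", "seed": config.seed})

    # --- truth -------------------------------------------------------------
    realized: dict[tuple[str, str], float] = {}
    for k, gi in enumerate(toolkit_idx):
        for sp in config.species:
            realized[(gene_ids[gi], sp)] = float(toolkit_sign[k] * config.toolkit_lfc)
    for c in clades:
        for k, gi in enumerate(clade_idx[c]):
            for sp in config.species:
                if config.clade_of_species[sp] == c:
                    realized[(gene_ids[gi], sp)] = float(
                        clade_sign[c][k] * config.clade_lfc)
    for m in trait_modules:
        for gi in module_idx[m]:
            for sp in config.species:
                realized[(gene_ids[gi], sp)] = float(
                    loadings[gi] * config.trait_factor_shift / LN2)

    truth = SyntheticTruth(
        toolkit_gene_ids={gene_ids[i] for i in toolkit_idx},
        clade_specific_gene_ids={
            c: {gene_ids[i] for i in clade_idx[c]} for c in clades},
        module_membership={
            gene_ids[i]: m for m, idx in module_idx.items() for i in idx},
        trait_modules=trait_modules,
        realized_lfc=realized,
        seed=config.seed,
    )
    return dataset, truth


def score_recovery(
    predicted,
    truth: SyntheticTruth,
    role: str = "toolkit",
    clade: str | None = None,
) -> RecoveryScore:
    """Precision/recall/F1 of a predicted gene set against the planted truth.

    ``role`` selects the reference set: ``toolkit``, ``clade`` (with the clade
    named), or ``module``. For ``module``, ``predicted`` may be a mapping
    gene -> module label, in which case the adjusted Rand index is computed
    over genes assigned in truth.
    """
    ari = None
    if role == "toolkit":
        ref = set(truth.toolkit_gene_ids)
    elif role == "clade":
        if clade is None:
            raise ValueError("role='clade' requires a clade name")
        ref = set(truth.clade_specific_gene_ids[clade])
    elif role == "module":
        ref = set(truth.module_membership)
        if isinstance(predicted, Mapping):
            genes = sorted(ref)
            true_labels = [truth.module_membership[g] for g in genes]
            pred_labels = [predicted.get(g, 0) for g in genes]
            ari = float(adjusted_rand_score(true_labels, pred_labels))
            predicted = {g for g, m in predicted.items() if m != 0}
    else:
        raise ValueError(f"unknown role {role!r}")
    pred = set(predicted)
    tp = len(pred & ref)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(ref) if ref else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return RecoveryScore(precision=precision, recall=recall, f1=f1, ari=ari)


def write_dataset(
    dataset: OrthoExpressionDataset,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the on-disk formats the pipeline consumes.

    One counts TSV per species (with species-local gene ids), a metadata TSV,
    an Orthogroups.tsv mapping orthogroups to those gene ids, and a truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    species = dataset.species
    ortho_map = {
        og: {sp: [f"{sp}|{og}"] for sp in species} for og in dataset.orthogroup_ids}
    for sp in species:
        sub = dataset.species_counts(sp).copy()
        sub.index = [f"{sp}|{og}" for og in sub.index]
        p = outdir / f"counts_{sp}.tsv"
        write_counts(sub.astype(int), p)
        paths[f"counts_{sp}"] = p
    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(dataset.samples, paths["metadata"])
    paths["orthogroups"] = outdir / "Orthogroups.tsv"
    write_orthogroups(ortho_map, species, paths["orthogroups"])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
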