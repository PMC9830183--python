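"""Consensus weighted gene co-expression networks across species.

Per-species signed/unsigned adjacencies are raised to a soft-thresholding
power, converted to topological overlap matrices (TOM), quantile-calibrated,
and combined into a consensus TOM (component-wise quantile; the default
quantile 0 is the minimum, keeping only co-expression shared by every
species). Modules come from average-linkage hierarchical clustering of the
consensus dissimilarity with a static cut and a minimum-size filter applied at
a decreasing sweep of sizes (relaxation). Module eigengenes, kME, and
gene/module trait associations are combined across species with a
sample-size-weighted Stouffer meta-analysis, validated by a permutation
preservation Z and a label-shuffle resampling null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import bh_adjust
from .preprocess import NormalizedMatrix

logger = logging.getLogger("socortex")


@dataclass
class NetworkConfig:
    """Consensus network construction settings.

    ``soft_power=None`` picks the smallest beta in 1..20 whose scale-free
    topology fit reaches R^2 >= 0.8 (median across species), else 6.
    ``consensus_quantile=0`` takes the component-wise minimum across species.
    ``min_module_sizes`` is the relaxation sweep, largest first.
    """

    soft_power: int | None = None
    network_sign: str = "unsigned"
    consensus_quantile: float = 0.0
    calibrate: bool = True
    calibration_quantile: float = 0.95
    min_module_sizes: tuple[int, ...] = (30, 20, 10)
    cut_height_fraction: float = 0.995
    resampling_k: int = 100
    n_preservation_permutations: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soft_power is not None and self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError(f"unknown network sign {self.network_sign!r}")
        if not 0.0 <= self.consensus_quantile <= 1.0:
            raise ValueError("consensus_quantile must be in [0, 1]")
        if list(self.min_module_sizes) != sorted(
                self.min_module_sizes, reverse=True):
            raise ValueError("min_module_sizes must be strictly decreasing")


@dataclass
class ConsensusNetworkResult:
    """Everything the consensus pipeline computes, on a shared gene order."""

    genes: list[str]
    per_species_tom: dict[str, np.ndarray]
    consensus_tom: np.ndarray
    linkage: np.ndarray
    modules_by_size: dict[int, pd.Series]  # min_size -> gene -> label (0 = unassigned)
    eigengenes: dict[int, dict[str, pd.DataFrame]]  # size -> species -> samples x modules
    kme: dict[int, dict[str, pd.DataFrame]]  # size -> species -> genes x modules
    consensus_kme: dict[int, pd.DataFrame]  # size -> genes x modules (mean of species)
    module_trait: dict[int, pd.DataFrame]  # size -> per-module meta stats
    gene_trait: pd.DataFrame  # per-gene meta stats
    trait_genes_by_size: dict[int, set[str]]
    trait_genes: set[str]  # union over the size sweep
    soft_power: int
    preservation_z: dict[int, pd.Series] = field(default_factory=dict)
    resampling: dict | None = None


# ---------------------------------------------------------------------------
# Adjacency / TOM primitives
# ---------------------------------------------------------------------------

def filter_variable_genes(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with zero expression or no variance across samples."""
    vals = expr.to_numpy(dtype=float)
    bad = (np.nanstd(vals, axis=1) == 0) | np.isnan(vals).any(axis=1)
    removed = expr.index[bad].tolist()
    if removed:
        logger.info("network: removed %d zero-variance/missing genes", len(removed))
    return expr.loc[~bad], removed


def adjacency(
    expr: pd.DataFrame | np.ndarray,
    beta: int = 6,
    sign: str = "unsigned",
) -> np.ndarray:
    """Co-expression adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta.

    ``expr`` is genes x samples; requires >= 4 samples and variable rows
    (use :func:`filter_variable_genes` first).
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 4:
        raise ValueError("adjacency requires >= 4 samples")
    if (np.std(X, axis=1) == 0).any():
        raise ValueError("zero-variance rows must be removed before adjacency")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    if sign == "unsigned":
        a = np.abs(r) ** beta
    elif sign == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown sign {sign!r}")
    np.fill_diagonal(a, 1.0)
    return a


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; diagonal 1.
    """
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    shared = a @ a - 2.0 * a  # removes u=i and u=j terms (diag = 1)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return t


def pick_soft_power(
    exprs: Mapping[str, pd.DataFrame],
    sign: str = "unsigned",
    r2_target: float = 0.8,
    powers: Sequence[int] = tuple(range(1, 21)),
) -> int:
    """Smallest beta whose median scale-free fit R^2 reaches the target, else 6.

    The scale-free fit regresses log10 frequency of binned connectivity on
    log10 mean connectivity per bin (10 bins), per species.
    """
    def fit_r2(k: np.ndarray) -> float:
        k = k[k > 0]
        if k.size < 10:
            return 0.0
        bins = np.quantile(k, np.linspace(0, 1, 11))
        bins = np.unique(bins)
        if len(bins) < 4:
            return 0.0
        which = np.clip(np.digitize(k, bins[1:-1]), 0, len(bins) - 2)
        xs, ys = [], []
        for b in range(len(bins) - 1):
            sel = which == b
            if sel.sum() == 0:
                continue
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
        if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            return 0.0
        r, _ = stats.pearsonr(xs, ys)
        return float(r**2) if r < 0 else 0.0

    for beta in powers:
        r2s = []
        for expr in exprs.values():
            a = adjacency(expr, beta=beta, sign=sign)
            k = a.sum(axis=0) - 1.0
            r2s.append(fit_r2(k))
        if np.median(r2s) >= r2_target:
            logger.info("soft power beta=%d (median R^2=%.2f)", beta,
                        float(np.median(r2s)))
            return int(beta)
    logger.info("no beta reached scale-free R^2 %.2f; default 6", r2_target)
    return 6


def consensus_tom(
    toms: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    quantile: float = 0.0,
    calibrate: bool = True,
    calibration_quantile: float = 0.95,
) -> np.ndarray:
    """Component-wise quantile of (optionally calibrated) per-species TOMs.

    Calibration rescales every TOM so its off-diagonal ``calibration_quantile``
    matches the first species', preventing one dataset's scale dominating the
    minimum. quantile 0 is the component-wise minimum.
    """
    mats = list(toms.values()) if isinstance(toms, Mapping) else list(toms)
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("TOMs must share the gene set and order")
    mats = [m.copy() for m in mats]
    if calibrate and len(mats) > 1:
        off = ~np.eye(shape[0], dtype=bool)
        ref = np.quantile(mats[0][off], calibration_quantile)
        for m in mats[1:]:
            q = np.quantile(m[off], calibration_quantile)
            if q > 0:
                m[off] = np.clip(m[off] * (ref / q), 0.0, 1.0)
    cons = np.quantile(np.stack(mats), quantile, axis=0)
    cons = np.clip((cons + cons.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return cons


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def tom_linkage(consensus: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering of the 1 - TOM dissimilarity."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    return hierarchy.average(squareform(d, checks=False))


def detect_modules(
    consensus: np.ndarray,
    genes: Sequence[str],
    min_size: int,
    cut_height_fraction: float = 0.995,
    linkage: np.ndarray | None = None,
) -> pd.Series:
    """Static-cut module assignment; clusters below min_size become label 0.

    The tree is cut at ``cut_height_fraction`` x the maximum merge height;
    surviving clusters are renamed 1..K by decreasing size (ties broken by the
    smallest member gene id) so labels are deterministic.
    """
    if linkage is None:
        linkage = tom_linkage(consensus)
    cut = cut_height_fraction * linkage[:, 2].max()
    raw = hierarchy.fcluster(linkage, t=cut, criterion="distance")
    labels = pd.Series(raw, index=list(genes))
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size]
    if keep.empty:
        logger.warning("no module reached min_size=%d; all genes unassigned",
                       min_size)
        return pd.Series(0, index=list(genes))
    ordered = sorted(
        keep.index,
        key=lambda lab: (-keep[lab], min(labels.index[labels == lab])))
    rename = {lab: i + 1 for i, lab in enumerate(ordered)}
    return labels.map(lambda lab: rename.get(lab, 0))


# ---------------------------------------------------------------------------
# Eigengenes / kME
# ---------------------------------------------------------------------------

def eigengene(expr: pd.DataFrame, module_genes: Sequence[str]) -> pd.Series:
    """First principal component of a module's standardized expression.

    Unit variance across samples; sign oriented so the mean gene-eigengene
    correlation is non-negative.
    """
    sub = expr.loc[list(module_genes)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("eigengene requires a module of >= 2 genes")
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("module contains constant genes")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    corrs = z @ e
    if corrs.mean() < 0:
        e = -e
    e = e / e.std(ddof=1)
    e = e - e.mean()
    return pd.Series(e, index=expr.columns)


def kme(expr: pd.DataFrame, eg: pd.Series) -> pd.Series:
    """Correlation of each gene's expression with a module eigengene."""
    X = expr.to_numpy(dtype=float)
    e = eg.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    den = np.sqrt((Xc**2).sum(axis=1) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, Xc @ ec / den, np.nan)
    return pd.Series(np.clip(r, -1.0, 1.0), index=expr.index)


# ---------------------------------------------------------------------------
# Meta-analysis of trait association
# ---------------------------------------------------------------------------

def stouffer_meta(
    r_by_species: pd.DataFrame, n_by_species: Mapping[str, int]
) -> pd.DataFrame:
    """Sample-size-weighted Stouffer combination of per-species correlations.

    z_s = atanh(r_s) sqrt(n_s - 3); Z = sum(w_s z_s) / sqrt(sum w_s^2) with
    w_s = sqrt(n_s); two-sided normal p. Species with missing r are dropped
    entity-wise.
    """
    zs = {}
    ws = {}
    for sp in r_by_species.columns:
        n = n_by_species[sp]
        if n < 4:
            logger.warning("meta-analysis: species %s has n=%d < 4; excluded",
                           sp, n)
            continue
        r = np.clip(r_by_species[sp].to_numpy(dtype=float), -0.999999, 0.999999)
        zs[sp] = np.arctanh(r) * np.sqrt(n - 3)
        ws[sp] = np.sqrt(n)
    zmat = pd.DataFrame(zs, index=r_by_species.index)
    wvec = pd.Series(ws)
    valid = zmat.notna()
    num = (zmat * wvec).where(valid).sum(axis=1)
    den = np.sqrt(((wvec**2) * valid).sum(axis=1))
    Z = num / den.replace(0, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(Z))
    out = pd.DataFrame({"meta_z": Z, "p": p}, index=r_by_species.index)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out


def trait_association(
    values_by_species: Mapping[str, pd.DataFrame],
    phenotype_by_species: Mapping[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-entity per-species Pearson r plus Stouffer meta statistics.

    ``values_by_species[sp]`` is entities x samples; the phenotype vector is
    0/1 per sample. Species with a constant phenotype are excluded with a
    warning. Returns (per-species r table, meta table with Z/p/p_adjusted).
    """
    rs = {}
    ns = {}
    for sp, vals in values_by_species.items():
        x = np.asarray(phenotype_by_species[sp], dtype=float)
        if np.std(x) == 0:
            logger.warning("species %s has constant phenotype; excluded", sp)
            continue
        X = vals.to_numpy(dtype=float)
        Xc = X - X.mean(axis=1, keepdims=True)
        xc = x - x.mean()
        den = np.sqrt((Xc**2).sum(axis=1) * (xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, Xc @ xc / den, np.nan)
        rs[sp] = pd.Series(r, index=vals.index)
        ns[sp] = len(x)
    r_table = pd.DataFrame(rs)
    meta = stouffer_meta(r_table, ns)
    return r_table, meta


# ---------------------------------------------------------------------------
# Preservation Z and resampling null
# ---------------------------------------------------------------------------

def preservation_z(
    consensus_kme_assigned: pd.Series,
    all_consensus_kme: pd.DataFrame,
    modules: pd.Series,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Permutation Z for mean intramodular consensus kME per module.

    For each module the observed statistic is the mean consensus kME of its
    members in their own module column; the null redraws same-size gene sets
    at random and evaluates their mean kME in that column.
    """
    rng = np.random.default_rng(seed)
    out = {}
    gene_index = list(all_consensus_kme.index)
    for m in sorted(set(modules) - {0}):
        members = modules.index[modules == m]
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        col = all_consensus_kme[m]
        obs = float(col.loc[members].mean())
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            pick = rng.choice(len(gene_index), size=len(members), replace=False)
            null[i] = float(col.iloc[pick].mean())
        sd = null.std(ddof=1)
        out[m] = (obs - null.mean()) / sd if sd > 0 else np.nan
    return pd.Series(out, name="preservation_z")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _split_by_species(
    matrix: NormalizedMatrix, metadata: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], dict[str, np.ndarray]]:
    meta = metadata.loc[matrix.values.columns]
    exprs, phenos = {}, {}
    for sp in dict.fromkeys(meta["species"]):
        cols = meta.index[meta["species"] == sp]
        exprs[sp] = matrix.values[cols]
        phenos[sp] = (meta.loc[cols, "phenotype"] == "reproductive"
                      ).to_numpy(dtype=float)
    return exprs, phenos


def run_consensus_network(
    matrix: NormalizedMatrix,
    metadata: pd.DataFrame,
    config: NetworkConfig | None = None,
    compute_preservation: bool = True,
) -> ConsensusNetworkResult:
    """Build the consensus network and all trait statistics.

    A gene is called trait-associated when (i) its own phenotype meta-p passes
    BH at alpha, (ii) it belongs to a module whose eigengene meta-p passes BH
    at alpha at some minimum size in the sweep, and (iii) its kME meta-p for
    that module passes BH at alpha. The reported set is the union over the
    size-relaxation sweep.
    """
    config = config or NetworkConfig()
    exprs, phenos = _split_by_species(matrix, metadata)
    # complete-case, variable genes in every species
    common = None
    for sp, expr in exprs.items():
        kept, _ = filter_variable_genes(expr)
        common = set(kept.index) if common is None else common & set(kept.index)
    genes = [g for g in matrix.values.index if g in common]
    exprs = {sp: expr.loc[genes] for sp, expr in exprs.items()}

    beta = config.soft_power or pick_soft_power(exprs, sign=config.network_sign)
    toms = {sp: tom(adjacency(expr, beta=beta, sign=config.network_sign))
            for sp, expr in exprs.items()}
    cons = consensus_tom(
        toms, quantile=config.consensus_quantile, calibrate=config.calibrate,
        calibration_quantile=config.calibration_quantile)
    link = tom_linkage(cons)

    gene_r, gene_meta = trait_association(exprs, phenos)
    gene_trait = gene_r.add_prefix("r_").join(gene_meta)

    modules_by_size: dict[int, pd.Series] = {}
    eigengenes: dict[int, dict[str, pd.DataFrame]] = {}
    kmes: dict[int, dict[str, pd.DataFrame]] = {}
    consensus_kmes: dict[int, pd.DataFrame] = {}
    module_trait: dict[int, pd.DataFrame] = {}
    preservation: dict[int, pd.Series] = {}
    trait_by_size: dict[int, set[str]] = {}

    for min_size in config.min_module_sizes:
        modules = detect_modules(cons, genes, min_size,
                                 config.cut_height_fraction, linkage=link)
        modules_by_size[min_size] = modules
        labels = sorted(set(modules) - {0})
        eigengenes[min_size] = {}
        kmes[min_size] = {}
        per_sp_kme: dict[str, pd.DataFrame] = {}
        eg_by_sp: dict[str, pd.DataFrame] = {}
        for sp, expr in exprs.items():
            egs = {}
            kms = {}
            for m in labels:
                members = modules.index[modules == m]
                eg = eigengene(expr, members)
                egs[m] = eg
                kms[m] = kme(expr, eg)
            eg_by_sp[sp] = pd.DataFrame(egs, index=expr.columns)
            per_sp_kme[sp] = pd.DataFrame(kms, index=expr.index)
        eigengenes[min_size] = eg_by_sp
        kmes[min_size] = per_sp_kme
        cons_kme = (sum(per_sp_kme.values()) / len(per_sp_kme)
                    if labels else pd.DataFrame(index=pd.Index(genes)))
        consensus_kmes[min_size] = cons_kme

        if labels:
            eg_t = {sp: eg_by_sp[sp].T for sp in exprs}
            me_r, me_meta = trait_association(eg_t, phenos)
            module_trait[min_size] = me_r.add_prefix("r_").join(me_meta)
        else:
            module_trait[min_size] = pd.DataFrame(
                columns=["meta_z", "p", "p_adjusted"])

        sig_modules = set(
            module_trait[min_size].index[
                (module_trait[min_size]["p_adjusted"] < config.alpha).fillna(False)])
        # kME meta significance per gene in its own module
        trait_genes: set[str] = set()
        if sig_modules:
            kme_r = {sp: per_sp_kme[sp] for sp in exprs}
            ns = {sp: exprs[sp].shape[1] for sp in exprs}
            for m in sig_modules:
                members = modules.index[modules == m]
                r_tab = pd.DataFrame(
                    {sp: kme_r[sp].loc[members, m] for sp in exprs})
                kme_meta = stouffer_meta(r_tab, ns)
                kme_ok = set(kme_meta.index[
                    (kme_meta["p_adjusted"] < config.alpha).fillna(False)])
                gene_ok = set(gene_meta.index[
                    (gene_meta["p_adjusted"] < config.alpha).fillna(False)])
                trait_genes |= set(members) & kme_ok & gene_ok
        trait_by_size[min_size] = trait_genes

        if compute_preservation and labels:
            preservation[min_size] = preservation_z(
                cons_kme, cons_kme, modules,
                n_permutations=config.n_preservation_permutations,
                seed=config.seed + min_size)

    return ConsensusNetworkResult(
        genes=genes,
        per_species_tom=toms,
        consensus_tom=cons,
        linkage=link,
        modules_by_size=modules_by_size,
        eigengenes=eigengenes,
        kme=kmes,
        consensus_kme=consensus_kmes,
        module_trait=module_trait,
        gene_trait=gene_trait,
        trait_genes_by_size=trait_by_size,
        trait_genes=set().union(*trait_by_size.values()) if trait_by_size else set(),
        soft_power=beta,
        preservation_z=preservation,
    )


def single_species_network(
    expr: pd.DataFrame,
    phenotype: np.ndarray,
    config: NetworkConfig | None = None,
) -> dict:
    """Orthology-independent network for one species (no consensus step)."""
    config = config or NetworkConfig()
    kept, removed = filter_variable_genes(expr)
    beta = config.soft_power or pick_soft_power({"self": kept},
                                                sign=config.network_sign)
    t = tom(adjacency(kept, beta=beta, sign=config.network_sign))
    link = tom_linkage(t)
    genes = list(kept.index)
    modules_by_size = {
        ms: detect_modules(t, genes, ms, config.cut_height_fraction, linkage=link)
        for ms in config.min_module_sizes}
    x = np.asarray(phenotype, dtype=float)
    gene_r, gene_meta = trait_association({"self": kept}, {"self": x})
    return {
        "tom": t,
        "linkage": link,
        "genes": genes,
        "removed": removed,
        "modules_by_size": modules_by_size,
        "gene_trait": gene_r.add_prefix("r_").join(gene_meta),
        "soft_power": beta,
    }


def resampling_null(
    matrix: NormalizedMatrix,
    metadata: pd.DataFrame,
    config: NetworkConfig,
    point_estimate: set[str] | None = None,
) -> dict:
    """Label-shuffle resampling null for the trait-associated gene set.

    Phenotype labels are shuffled within species, the whole network and trait
    screen rebuilt, and the proportion of the point-estimate set recovered
    recorded, k times. Two p-values are reported: the literal two-tailed rule
    (share of resamples whose proportion deviates from the 50% null
    expectation), which degenerates when all null proportions sit on one side,
    and the conventional one-tailed exceedance p = (1 + #{null >= observed}) /
    (k + 1) with the observed full recovery proportion of 1.
    """
    if point_estimate is None:
        point = run_consensus_network(
            matrix, metadata, config, compute_preservation=False).trait_genes
    else:
        point = set(point_estimate)
    if not point:
        raise ValueError("empty point-estimate trait gene set")
    rng = np.random.default_rng(config.seed)
    meta = metadata.loc[matrix.values.columns]
    species = meta["species"].to_numpy()
    props = np.empty(config.resampling_k)
    for i in range(config.resampling_k):
        shuffled = meta.copy()
        pheno = shuffled["phenotype"].to_numpy().copy()
        for sp in np.unique(species):
            idx = np.nonzero(species == sp)[0]
            pheno[idx] = pheno[rng.permutation(idx)]
        shuffled["phenotype"] = pheno
        cfg = NetworkConfig(**{**config.__dict__, "seed": config.seed + i + 1})
        null_set = run_consensus_network(
            matrix, shuffled, cfg, compute_preservation=False).trait_genes
        props[i] = len(null_set & point) / len(point)
    p_literal = float(np.mean(np.abs(props - 0.5) > 0))
    p_exceedance = float((1 + np.sum(props >= 1.0)) / (config.resampling_k + 1))
    return {
        "point_estimate": point,
        "proportions": props,
        "p_literal_two_tailed": p_literal,
        "p_exceedance": p_exceedance,
    }
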