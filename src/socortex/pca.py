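"""PCA trait screening: does expression cluster by phylogeny or by phenotype?

Runs a sample-space PCA of the normalized expression matrix, screens the top
components for Pearson correlation with clade, species, and reproductive
phenotype (BH-corrected jointly), and provides a randomized-phenotype control
in which phenotype labels are shuffled within species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .de import bh_adjust
from .preprocess import NormalizedMatrix

logger = logging.getLogger("socortex")


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x PCs
    loadings: pd.DataFrame      # genes x PCs
    explained_variance_fraction: pd.Series
    trait_correlations: pd.DataFrame | None = None
    n_top_pcs: int = 0
    dropped_rows: list[str] = field(default_factory=list)


def run_pca(matrix: NormalizedMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples in gene space; deterministic up to a fixed sign convention.

    Rows (genes) containing missing values are dropped and logged. The sign of
    each component is fixed so the gene with the largest |loading| is positive.
    """
    values = matrix.values
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    na_rows = values.index[values.isna().any(axis=1)].tolist()
    if na_rows:
        logger.info("PCA: dropping %d rows with missing values", len(na_rows))
        values = values.dropna()
    X = values.to_numpy(dtype=float).T  # samples x genes
    k = min(n_samples - 1, values.shape[0])
    if n_components is not None:
        k = min(k, n_components)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x PCs
    # sign convention: largest-|loading| gene positive
    for j in range(k):
        g = np.argmax(np.abs(loadings[:, j]))
        if loadings[g, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=values.index, columns=pcs),
        explained_variance_fraction=pd.Series(
            pca.explained_variance_ratio_, index=pcs),
        dropped_rows=na_rows,
    )


def _trait_codings(traits: pd.DataFrame, coding: str = "one_vs_rest") -> pd.DataFrame:
    """Expand trait columns into numeric 0/1 codings.

    Binary columns keep one coding; multi-level columns are expanded
    one-vs-rest (default) or coerced to alphabetical integer codes
    (``coding='integer'``, order-dependent and therefore not the default).
    """
    out = {}
    for col in traits.columns:
        vals = traits[col]
        if pd.api.types.is_numeric_dtype(vals):
            out[col] = vals.astype(float)
            continue
        levels = sorted(vals.unique())
        if len(levels) < 2:
            out[col] = pd.Series(np.nan, index=traits.index)
        elif len(levels) == 2:
            out[col] = (vals == levels[1]).astype(float)
        elif coding == "integer":
            out[col] = vals.map({lv: i for i, lv in enumerate(levels)}).astype(float)
        else:
            for lv in levels:
                out[f"{col}={lv}"] = (vals == lv).astype(float)
    return pd.DataFrame(out, index=traits.index)


def trait_correlation_screen(
    pca: PcaResult,
    traits: pd.DataFrame,
    n_top: int = 10,
    alpha: float = 0.05,
    coding: str = "one_vs_rest",
) -> pd.DataFrame:
    """Pearson r and BH-adjusted p per (PC, trait coding) over the top PCs.

    BH adjustment is applied jointly across all tested (PC, coding) pairs.
    Constant codings yield missing r/p. For multi-level traits the per-(PC,
    trait) summary ``max_abs_r`` reports the largest |r| over its codings.
    """
    n_top = min(n_top, pca.scores.shape[1])
    codings = _trait_codings(traits.loc[pca.scores.index], coding=coding)
    rows = []
    for pc in pca.scores.columns[:n_top]:
        sc = pca.scores[pc].to_numpy()
        for name in codings.columns:
            tv = codings[name].to_numpy()
            trait = name.split("=")[0]
            if np.nanstd(tv) == 0 or np.isnan(tv).any():
                rows.append((pc, trait, name, np.nan, np.nan))
                continue
            if np.std(sc) == 0:
                rows.append((pc, trait, name, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(sc, tv)
            rows.append((pc, trait, name, r, p))
    table = pd.DataFrame(rows, columns=["pc", "trait", "coding", "r", "p"])
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = (table["p_adjusted"] < alpha).fillna(False)
    pca.trait_correlations = table
    pca.n_top_pcs = n_top
    return table


def trait_variance_fraction(pca: PcaResult, trait: str) -> float:
    """Share of total variance on PCs significantly correlated with a trait.

    Defined as sum over significant (PC, coding) pairs of
    explained_variance_fraction * r^2, using each PC once with its best
    coding.
    """
    if pca.trait_correlations is None:
        raise ValueError("run trait_correlation_screen first")
    t = pca.trait_correlations
    t = t[(t["trait"] == trait) & t["significant"]]
    if t.empty:
        return 0.0
    # one contribution per PC: its best (largest |r|) significant coding
    best = t.assign(abs_r=t["r"].abs()).sort_values("abs_r").groupby("pc").tail(1)
    total = 0.0
    for _, row in best.iterrows():
        total += float(pca.explained_variance_fraction[row["pc"]] * row["r"] ** 2)
    return total


def randomized_phenotype_control(
    matrix: NormalizedMatrix,
    metadata: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
    n_top: int = 10,
) -> dict:
    """Null distribution of max |r(PC, phenotype)| under within-species shuffles.

    The PCA itself does not depend on the labels, so components are computed
    once; phenotype labels are then shuffled within species and the top-PC
    correlation screen repeated. Returns the observed statistic, the null
    distribution, and the empirical exceedance quantile.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    rng = np.random.default_rng(seed)
    pca = run_pca(matrix)
    n_top = min(n_top, pca.scores.shape[1])
    scores = pca.scores.iloc[:, :n_top].to_numpy()
    meta = metadata.loc[pca.scores.index]
    x = (meta["phenotype"] == "reproductive").to_numpy(dtype=float)
    species = meta["species"].to_numpy()

    def max_abs_r(labels: np.ndarray) -> float:
        xc = labels - labels.mean()
        if np.all(xc == 0):
            return 0.0
        sc = scores - scores.mean(axis=0)
        num = sc.T @ xc
        den = np.sqrt((sc**2).sum(axis=0) * (xc**2).sum())
        with np.errstate(invalid="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        return float(np.max(np.abs(r)))

    observed = max_abs_r(x)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = x.copy()
        for sp in np.unique(species):
            idx = np.nonzero(species == sp)[0]
            shuffled[idx] = shuffled[rng.permutation(idx)]
        null[i] = max_abs_r(shuffled)
    quantile = float(np.mean(null < observed))
    return {
        "observed": observed,
        "null": null,
        "quantile": quantile,
        "p_exceedance": float((1 + np.sum(null >= observed)) / (n_shuffles + 1)),
    }
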