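"""Negative-binomial differential expression between phenotypes.

Per-gene NB log-link regression of counts on phenotype with a log size-factor
offset, gene-wise dispersion by Cox-Reid-adjusted profile maximum likelihood
(method-of-moments fallback), and a Wald test on the phenotype coefficient.
Also provides Benjamini-Hochberg adjustment, a permutation-balancing wrapper
for unequal group sizes, a clade-adjusted joint model, and cross-species
overlap counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger("socortex")

LN2 = float(np.log(2.0))
_ALPHA_GRID = np.exp(np.linspace(np.log(1e-8), np.log(50.0), 60))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# Vectorized two-group NB fit
# ---------------------------------------------------------------------------

def _fit_group_theta(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of theta in mean = s_j * exp(theta) for NB(alpha), per gene.

    Returns (theta, expected information). Genes are rows of ``y``; ``alpha``
    is per-gene. Scalar Newton-Raphson, vectorized across genes.
    """
    with np.errstate(divide="ignore"):
        theta = np.log(np.maximum(np.mean(y / s, axis=1), 1e-8))
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = s * np.exp(theta)[:, None]
        score = np.sum((y - mu) / (1.0 + a * mu), axis=1)
        info = np.sum(mu / (1.0 + a * mu), axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s * np.exp(theta)[:, None]
    info = np.sum(mu / (1.0 + a * mu), axis=1)
    return theta, info


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log likelihood (alpha broadcast per gene)."""
    a = alpha[:, None]
    inv = 1.0 / a
    return np.sum(
        special.gammaln(y + inv) - special.gammaln(inv)
        + y * np.log(a * mu / (1.0 + a * mu))
        - inv * np.log1p(a * mu),
        axis=1,
    )


def _moment_alpha(y: np.ndarray, s: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion on normalized counts, pooled within groups."""
    q = y / s
    mu = np.mean(q, axis=1)
    ss = np.zeros(y.shape[0])
    dof = 0
    for g in np.unique(groups):
        sub = q[:, groups == g]
        if sub.shape[1] < 2:
            continue
        ss += np.var(sub, axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    var = ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (var - mu) / mu**2
    return np.clip(np.where(np.isfinite(a), a, 0.0), 1e-8, 50.0)


def _profile_alpha(
    y: np.ndarray, s: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Cox-Reid-adjusted profile-ML dispersion for the two-group model.

    For each alpha on a log grid, group means are refit and the CR-adjusted
    profile likelihood evaluated; the per-gene argmax is refined by a
    parabolic step in log alpha. Falls back to the moment estimate where the
    profile is degenerate (flat or boundary).
    """
    n_genes = y.shape[0]
    i0, i1 = x == 0, x == 1
    ll = np.full((len(_ALPHA_GRID), n_genes), -np.inf)
    for k, a in enumerate(_ALPHA_GRID):
        av = np.full(n_genes, a)
        th0, inf0 = _fit_group_theta(y[:, i0], s[i0], av, n_iter=12)
        th1, inf1 = _fit_group_theta(y[:, i1], s[i1], av, n_iter=12)
        mu = np.empty_like(y, dtype=float)
        mu[:, i0] = s[i0] * np.exp(th0)[:, None]
        mu[:, i1] = s[i1] * np.exp(th1)[:, None]
        cr = 0.5 * (np.log(np.maximum(inf0, 1e-12))
                    + np.log(np.maximum(inf1, 1e-12)))
        ll[k] = _nb_loglik(y, mu, av) - cr
    best = np.argmax(ll, axis=0)
    log_a = np.log(_ALPHA_GRID)
    alpha = np.exp(log_a[best])
    # parabolic refinement on interior maxima
    interior = (best > 0) & (best < len(_ALPHA_GRID) - 1)
    if interior.any():
        b = best[interior]
        cols = np.nonzero(interior)[0]
        l0, l1, l2 = ll[b - 1, cols], ll[b, cols], ll[b + 1, cols]
        h = log_a[1] - log_a[0]
        denom = l0 - 2 * l1 + l2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * h * (l0 - l2) / denom, 0.0)
        shift = np.clip(shift, -h, h)
        alpha[interior] = np.exp(log_a[b] + shift)
    mom = _moment_alpha(y, s, x)
    bad = ~np.isfinite(alpha) | (best == len(_ALPHA_GRID) - 1)
    alpha[bad] = mom[bad]
    return np.clip(alpha, 1e-8, 50.0)


def nb_wald_test(
    counts: pd.DataFrame,
    phenotype: np.ndarray | Sequence[int],
    factors: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of phenotype (reproductive=1 vs 0).

    Returns a DataFrame indexed by gene with columns ``lfc`` (log2 fold
    change, group 1 over group 0), ``stat``, ``p``. All-zero genes get NaN.
    """
    x = np.asarray(phenotype, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("phenotype must be coded 0/1")
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if n0 < 3 or n1 < 3:
        raise ValueError("each phenotype needs >= 3 samples")
    from .preprocess import size_factors as _sf
    if factors is None:
        factors = _sf(counts)
    s = np.asarray(factors, dtype=float)
    y = counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0

    lfc = np.full(y.shape[0], np.nan)
    stat = np.full(y.shape[0], np.nan)
    p = np.full(y.shape[0], np.nan)
    if nonzero.any():
        ysub = y[nonzero]
        alpha = _profile_alpha(ysub, s, x)
        th0, inf0 = _fit_group_theta(ysub[:, x == 0], s[x == 0], alpha)
        th1, inf1 = _fit_group_theta(ysub[:, x == 1], s[x == 1], alpha)
        se = np.sqrt(1.0 / np.maximum(inf0, 1e-12)
                     + 1.0 / np.maximum(inf1, 1e-12))
        z = (th1 - th0) / se
        lfc[nonzero] = (th1 - th0) / LN2
        stat[nonzero] = z
        p[nonzero] = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"lfc": lfc, "stat": stat, "p": p}, index=counts.index)


# ---------------------------------------------------------------------------
# Joint clade-adjusted model
# ---------------------------------------------------------------------------

def nb_wald_test_joint(
    counts: pd.DataFrame,
    phenotype: np.ndarray | Sequence[int],
    clade: Sequence[str],
    factors: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """NB Wald test of phenotype with an additive clade term.

    Design: intercept + clade indicators + phenotype; the Wald test is on the
    phenotype coefficient. Dispersion is estimated by moments pooled within
    clade x phenotype cells.
    """
    x = np.asarray(phenotype, dtype=float)
    clade = np.asarray(clade)
    from .preprocess import size_factors as _sf
    if factors is None:
        factors = _sf(counts)
    s = np.asarray(factors, dtype=float)
    y = counts.to_numpy(dtype=float)

    levels = sorted(set(clade))
    X = np.column_stack(
        [np.ones_like(x)]
        + [(clade == c).astype(float) for c in levels[1:]]
        + [x])
    cells = np.array([f"{c}|{int(v)}" for c, v in zip(clade, x)])
    alpha = _moment_alpha(y, s, cells)

    n_genes, n_par = y.shape[0], X.shape[1]
    beta = np.zeros((n_genes, n_par))
    with np.errstate(divide="ignore"):
        beta[:, 0] = np.log(np.maximum(np.mean(y / s, axis=1), 1e-8))
    a = alpha[:, None]
    for _ in range(40):
        mu = s * np.exp(beta @ X.T)
        w = mu / (1.0 + a * mu)
        score = ((y - mu) / (1.0 + a * mu)) @ X
        XtWX = np.einsum("gj,jk,jl->gkl", w, X, X)
        XtWX += 1e-10 * np.eye(n_par)
        step = np.linalg.solve(XtWX, score[:, :, None])[:, :, 0]
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s * np.exp(beta @ X.T)
    w = mu / (1.0 + a * mu)
    XtWX = np.einsum("gj,jk,jl->gkl", w, X, X) + 1e-10 * np.eye(n_par)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(cov[:, -1, -1])
    z = beta[:, -1] / se
    nonzero = y.sum(axis=1) > 0
    p = np.where(nonzero, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    lfc = np.where(nonzero, beta[:, -1] / LN2, np.nan)
    z = np.where(nonzero, z, np.nan)
    return pd.DataFrame({"lfc": lfc, "stat": z, "p": p}, index=counts.index)


# ---------------------------------------------------------------------------
# Per-species run, permutation balancing, overlap
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    """Per-species differential expression tables and significance sets."""

    tables: dict[str, pd.DataFrame]  # species -> gene table with padj
    alpha: float = 0.05
    mode: str = "orthology_dependent"
    support: dict[str, pd.Series] = field(default_factory=dict)

    def significant(self, species: str) -> set[str]:
        t = self.tables[species]
        return set(t.index[(t["padj"] < self.alpha).fillna(False)])

    def significant_sets(self) -> dict[str, set[str]]:
        return {sp: self.significant(sp) for sp in self.tables}


def run_de(
    dataset,
    alpha: float = 0.05,
    balance: bool = False,
    n_permutations: int = 50,
    support_threshold: float = 0.5,
    seed: int = 0,
    mode: str = "orthology_dependent",
) -> DeResult:
    """Per-species phenotype DE over an :class:`OrthoExpressionDataset`."""
    tables: dict[str, pd.DataFrame] = {}
    support: dict[str, pd.Series] = {}
    for k, sp in enumerate(dataset.species):
        cols = dataset.per_species_view[sp]
        counts = dataset.counts[cols].dropna()
        x = dataset.phenotype_vector(cols)
        tab = nb_wald_test(counts, x)
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
        if balance and int(x.sum()) != int((1 - x).sum()):
            robust, frac = permutation_balance(
                counts, x, n_permutations=n_permutations,
                support_threshold=support_threshold,
                alpha=alpha, seed=seed + 7919 * k)
            support[sp] = frac
            keep = tab.index.isin(robust)
            tab.loc[~keep, "padj"] = np.maximum(
                tab.loc[~keep, "padj"], np.nextafter(alpha, 1))
        tables[sp] = tab
    return DeResult(tables=tables, alpha=alpha, mode=mode, support=support)


def permutation_balance(
    counts: pd.DataFrame,
    phenotype: np.ndarray,
    n_permutations: int = 50,
    support_threshold: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[set[str], pd.Series]:
    """Balance unequal group sizes by repeated subsampling of the larger group.

    A gene is retained when it is BH-significant in at least
    ``support_threshold`` of the balanced subsamples. With already equal
    groups this is an identity passthrough of the single-run significant set.
    """
    x = np.asarray(phenotype, dtype=float)
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if n0 == n1:
        logger.info("groups already balanced; passthrough")
        tab = nb_wald_test(counts, x)
        padj = bh_adjust(tab["p"].to_numpy())
        sig = set(counts.index[(padj < alpha) & np.isfinite(padj)])
        frac = pd.Series(
            np.isin(counts.index, list(sig)).astype(float), index=counts.index)
        return sig, frac
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    rng = np.random.default_rng(seed)
    big, small = (1, 0) if n1 > n0 else (0, 1)
    big_idx = np.nonzero(x == big)[0]
    small_idx = np.nonzero(x == small)[0]
    hits = np.zeros(counts.shape[0])
    for _ in range(n_permutations):
        sub = rng.choice(big_idx, size=len(small_idx), replace=False)
        sel = np.sort(np.concatenate([small_idx, sub]))
        tab = nb_wald_test(counts.iloc[:, sel], x[sel])
        padj = bh_adjust(tab["p"].to_numpy())
        hits += ((padj < alpha) & np.isfinite(padj)).astype(float)
    frac = pd.Series(hits / n_permutations, index=counts.index)
    robust = set(counts.index[frac >= support_threshold])
    return robust, frac


def overlap_de(
    sets: Mapping[str, set[str]], min_species: int = 2
) -> dict:
    """Exact set algebra over per-species significant sets.

    Returns per-gene species counts, counts per overlap cardinality, and the
    genes shared by at least ``min_species`` species.
    """
    all_genes = sorted(set().union(*sets.values())) if sets else []
    member = pd.DataFrame(
        {sp: [g in s for g in all_genes] for sp, s in sets.items()},
        index=all_genes, dtype=bool)
    card = member.sum(axis=1)
    counts_by_card = card.value_counts().sort_index().to_dict()
    shared = set(card.index[card >= min_species])
    return {
        "membership": member,
        "counts_by_cardinality": {int(k): int(v) for k, v in counts_by_card.items()},
        "shared": shared,
        "min_species": min_species,
    }
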