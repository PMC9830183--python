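"""Input parsing, orthogroup assembly, and expression normalization.

This module turns per-species raw count tables plus an orthology map into a
single orthogroup x sample count matrix (:class:`OrthoExpressionDataset`) and
applies the three transformations the downstream analyses expect:

1. median-of-ratios size factors,
2. a closed-form negative-binomial variance-stabilizing transform (VST) with
   an optionally species-aware dispersion trend,
3. per-gene center-scaling, globally or within species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("socortex")

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "clade", "phenotype")
PHENOTYPES = ("reproductive", "non_reproductive")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class OrthologyFilterPolicy:
    """Relaxed near-single-copy orthogroup filter.

    An orthogroup is kept when every species has at most
    ``max_copies_per_species`` gene copies and the orthogroup is absent from at
    most ``max_absent_species`` species.
    """

    max_copies_per_species: int = 3
    max_absent_species: int = 1
    multi_copy_reduction: str = "sum"

    def __post_init__(self) -> None:
        if self.max_copies_per_species < 1:
            raise ValueError("max_copies_per_species must be >= 1")
        if self.max_absent_species < 0:
            raise ValueError("max_absent_species must be >= 0")
        if self.multi_copy_reduction not in ("sum", "max", "mean"):
            raise ValueError(f"unknown reduction {self.multi_copy_reduction!r}")


@dataclass
class OrthoExpressionDataset:
    """Orthogroup x sample count matrix with sample annotations.

    ``counts`` rows are orthogroup ids, columns sample ids; ``samples`` is a
    DataFrame indexed by sample_id with species/clade/phenotype columns.
    Missing values (orthogroup absent in a species) are NaN.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        if self.counts.isna().all(axis=1).any():
            raise ValueError("all-missing orthogroup rows are not allowed")
        for col in ("species", "clade", "phenotype"):
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation missing column {col!r}")

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.samples["species"]))

    @property
    def per_species_view(self) -> dict[str, list[str]]:
        return {
            sp: list(self.samples.index[self.samples["species"] == sp])
            for sp in self.species
        }

    def species_counts(self, species: str) -> pd.DataFrame:
        return self.counts[self.per_species_view[species]]

    def phenotype_vector(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Phenotype coded reproductive=1, non_reproductive=0."""
        ann = self.samples if samples is None else self.samples.loc[list(samples)]
        return (ann["phenotype"] == "reproductive").to_numpy(dtype=float)


@dataclass
class NormalizedMatrix:
    """Transformed expression values plus the record of how they were made."""

    values: pd.DataFrame
    transform: str  # "vst" or "log_size_factor"
    species_aware: bool
    centered: bool = False
    scaled: bool = False
    size_factors: pd.Series | None = None
    dispersion_trend: tuple[float, float] | None = None
    zero_variance_rows: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV of raw counts (first column = gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene ids {dupes[:5]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: malformed row for gene {bad!r} (missing cells)")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, species, clade, phenotype)."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    bad_pheno = set(meta["phenotype"]) - set(PHENOTYPES)
    if bad_pheno:
        raise ValueError(f"{path}: unknown phenotype labels {sorted(bad_pheno)}")
    return meta.set_index("sample_id", drop=False)


def read_orthogroups(
    path: str | Path,
    policy: OrthologyFilterPolicy | None = None,
    species: Sequence[str] | None = None,
) -> tuple[dict[str, dict[str, list[str]]], list[tuple[str, str]]]:
    """Read an OrthoFinder-style Orthogroups.tsv and apply the copy/absence policy.

    Returns ``(orthogroup -> species -> gene list, drop_log)`` where drop_log
    holds ``(orthogroup_id, reason)`` pairs with reason ``copy_number`` or
    ``absence``. Input order is preserved.
    """
    policy = policy or OrthologyFilterPolicy()
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = table.columns[0]
    sp_cols = [c for c in table.columns[1:] if species is None or c in species]
    if species is not None:
        unknown = set(species) - set(table.columns[1:])
        if unknown:
            raise ValueError(f"{path}: species {sorted(unknown)} not in header")
    kept: dict[str, dict[str, list[str]]] = {}
    drop_log: list[tuple[str, str]] = []
    for i, row in enumerate(table.itertuples(index=False)):
        og = getattr(row, og_col) if hasattr(row, og_col) else row[0]
        og = row[0]
        genes = {
            sp: [g for g in str(row[table.columns.get_loc(sp)]).split(", ") if g]
            for sp in sp_cols
        }
        n_absent = sum(1 for sp in sp_cols if not genes[sp])
        max_copies = max((len(v) for v in genes.values()), default=0)
        if max_copies > policy.max_copies_per_species:
            drop_log.append((og, "copy_number"))
            continue
        if n_absent > policy.max_absent_species:
            drop_log.append((og, "absence"))
            continue
        if og in kept:
            raise ValueError(f"{path}, line {i + 2}: duplicated orthogroup id {og!r}")
        kept[og] = {sp: gs for sp, gs in genes.items() if gs}
    logger.info(
        "orthogroups: kept %d, dropped %d of %d", len(kept), len(drop_log), len(table)
    )
    return kept, drop_log


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_REDUCERS = {"sum": np.sum, "max": np.max, "mean": np.mean}


def assemble_ortho_matrix(
    per_species_counts: Mapping[str, pd.DataFrame],
    ortho_map: Mapping[str, Mapping[str, Sequence[str]]],
    metadata: pd.DataFrame,
    reduction: str = "sum",
    policy: OrthologyFilterPolicy | None = None,
) -> OrthoExpressionDataset:
    """Collapse per-species gene counts into one orthogroup x sample matrix.

    Multi-copy genes within a species are collapsed with ``reduction``
    (sum/max/mean). A species where none of the mapped genes is present in its
    count table gets NaN for that orthogroup; rows whose missingness violates
    the policy are dropped and logged.
    """
    if reduction not in _REDUCERS:
        raise ValueError(f"unknown reduction {reduction!r}")
    policy = policy or OrthologyFilterPolicy()
    reduce = _REDUCERS[reduction]
    species = list(per_species_counts)
    sample_order = [
        s for s in metadata.index if metadata.loc[s, "species"] in species
    ]
    for sp, cnt in per_species_counts.items():
        extra = set(cnt.columns) - set(metadata.index)
        if extra:
            raise ValueError(f"samples {sorted(extra)} of {sp} absent from metadata")
    rows = {}
    dropped: list[tuple[str, str]] = []
    for og, sp_genes in ortho_map.items():
        vals = np.full(len(sample_order), np.nan)
        n_absent = 0
        for sp in species:
            cols = [
                i for i, s in enumerate(sample_order)
                if metadata.loc[s, "species"] == sp
            ]
            genes = [g for g in sp_genes.get(sp, ()) if g in per_species_counts[sp].index]
            missing = [g for g in sp_genes.get(sp, ()) if g not in per_species_counts[sp].index]
            if missing:
                logger.warning("%s: genes %s missing from %s counts", og, missing, sp)
            if not genes:
                n_absent += 1
                continue
            sub = per_species_counts[sp].loc[genes, [sample_order[i] for i in cols]]
            vals[cols] = reduce(sub.to_numpy(), axis=0)
        if n_absent > policy.max_absent_species:
            dropped.append((og, "absence_after_mapping"))
            continue
        rows[og] = vals
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=sample_order)
    ds = OrthoExpressionDataset(
        counts=counts,
        samples=metadata.loc[sample_order],
        provenance={"reduction": reduction, "dropped": dropped},
    )
    return ds


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes expressed in every sample of
    count_gj / geometric_mean_g. Falls back to ratio-of-totals (normalized to
    geometric mean 1) when no gene is expressed in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    complete = ~np.isnan(mat).any(axis=1)
    positive = complete & (mat > 0).all(axis=1, where=~np.isnan(mat))
    mat_pos = mat[positive]
    if mat_pos.shape[0] == 0:
        logger.warning("no gene expressed in all samples; size factors from totals")
        totals = np.nansum(mat, axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    log_geo = np.mean(np.log(mat_pos), axis=1, keepdims=True)
    ratios = np.log(mat_pos) - log_geo
    f = np.exp(np.median(ratios, axis=0))
    return pd.Series(f, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Variance-stabilizing transform
# ---------------------------------------------------------------------------

def _moment_dispersions(
    q: np.ndarray, groups: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion and mean of normalized counts.

    With ``groups`` given (species-aware mode), dispersion is the
    sample-size-weighted average of per-group moment estimates, so
    between-species mean shifts do not inflate the dispersion. Negative
    estimates (sampling noise under weak overdispersion) are floored at a
    tiny positive value before trend fitting.
    """
    mu = np.nanmean(q, axis=1)
    if groups is None:
        var = np.nanvar(q, axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mu) / mu**2
    else:
        num = np.zeros(q.shape[0])
        den = 0.0
        for g in np.unique(groups):
            sub = q[:, groups == g]
            n = sub.shape[1]
            if n < 2:
                continue
            mu_g = np.nanmean(sub, axis=1)
            var_g = np.nanvar(sub, axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a_g = (var_g - mu_g) / mu_g**2
            a_g = np.where(np.isfinite(a_g), a_g, 0.0)
            num += a_g * (n - 1)
            den += n - 1
        alpha = num / max(den, 1.0)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.clip(alpha, 1e-6, None), mu


def _fit_dispersion_trend(alpha: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Robust fit of the parametric dispersion trend alpha(mu) = a0 + a1/mu.

    a0 is the asymptotic (large-mean) dispersion and a1 the extra-Poisson
    term — the parametrization the closed-form stabilizer expects. Ordinary
    least squares of alpha on 1/mu, iterated with trimming of the largest
    absolute residuals (robustness against DE / outlier genes).
    """
    keep = (mu > 0) & np.isfinite(alpha)
    x, y = 1.0 / mu[keep], alpha[keep]
    if x.size < 3:
        return (-1.0, 0.0)
    for _ in range(3):
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = np.abs(y - X @ coef)
        if x.size <= 10:
            break
        cutoff = np.quantile(resid, 0.9)
        sel = resid <= cutoff
        x, y = x[sel], y[sel]
    a0, a1 = float(coef[0]), float(coef[1])
    return a0, max(a1, 0.0)


def vst_closed_form(q: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form NB variance stabilizer for the trend alpha(mu)=a0+a1/mu.

    Antiderivative of 1/sqrt(q (1 + a1 + a0 q)) up to scale, i.e. the exact
    stabilizer for Var(q) = (1 + a1) q + a0 q^2; sqrt-like at small a0*q and
    log2-like at large q (slope 1 against log2 q).
    """
    q = np.asarray(q, dtype=float)
    inner = (1.0 + a1 + 2.0 * a0 * q
             + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q)))
    return np.log2(inner / (4.0 * a0))


def variance_stabilize(
    dataset: OrthoExpressionDataset,
    species_aware: bool = True,
    factors: pd.Series | None = None,
) -> NormalizedMatrix:
    """Variance-stabilize normalized counts via the closed-form NB transform.

    When ``species_aware`` the dispersion trend is fitted on within-species
    residual dispersions (species-mean model), so cross-species expression
    shifts do not masquerade as biological dispersion. If the fitted trend is
    degenerate (a0 <= 0) the transform falls back to log2(q + 1).
    """
    if factors is None:
        factors = size_factors(dataset.counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    q = dataset.counts.to_numpy(dtype=float) / factors.to_numpy()
    groups = dataset.samples["species"].to_numpy() if species_aware else None
    alpha, mu = _moment_dispersions(q, groups)
    a0, a1 = _fit_dispersion_trend(alpha, mu)
    if a0 <= 0:
        logger.warning("dispersion trend fit degenerate (a0=%.3g); using log2(q+1)", a0)
        values = np.log2(q + 1.0)
        return NormalizedMatrix(
            values=pd.DataFrame(values, index=dataset.counts.index,
                                columns=dataset.counts.columns),
            transform="log_size_factor",
            species_aware=species_aware,
            size_factors=factors,
            dispersion_trend=None,
        )
    values = vst_closed_form(q, a0, a1)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=dataset.counts.index,
                            columns=dataset.counts.columns),
        transform="vst",
        species_aware=species_aware,
        size_factors=factors,
        dispersion_trend=(a0, a1),
    )


def center_scale(
    matrix: NormalizedMatrix,
    scope: str = "per_species",
    metadata: pd.DataFrame | None = None,
    scale: bool = True,
) -> NormalizedMatrix:
    """Center (and scale to unit sd) each gene, globally or within species.

    Zero-variance rows (within a scope block) are set to 0 and flagged in
    ``zero_variance_rows``.
    """
    if scope not in ("global", "per_species"):
        raise ValueError(f"unknown scope {scope!r}")
    vals = matrix.values.to_numpy(dtype=float).copy()
    flagged: set[str] = set()

    def _block(sub: np.ndarray) -> np.ndarray:
        m = np.nanmean(sub, axis=1, keepdims=True)
        out = sub - m
        if scale:
            sd = np.nanstd(out, axis=1, ddof=1, keepdims=True)
            zero = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
            sd[zero, 0] = 1.0
            out = out / sd
            out[zero] = 0.0
            flagged.update(np.asarray(matrix.values.index)[zero])
        return out

    if scope == "global":
        vals = _block(vals)
    else:
        if metadata is None:
            raise ValueError("per_species scope requires metadata")
        sp = metadata.loc[matrix.values.columns, "species"].to_numpy()
        for s in np.unique(sp):
            idx = sp == s
            vals[:, idx] = _block(vals[:, idx])
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=matrix.values.index,
                            columns=matrix.values.columns),
        transform=matrix.transform,
        species_aware=matrix.species_aware,
        centered=True,
        scaled=scale,
        size_factors=matrix.size_factors,
        dispersion_trend=matrix.dispersion_trend,
        zero_variance_rows=sorted(flagged),
    )


# ---------------------------------------------------------------------------
# Writers (round-trip format support)
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def write_orthogroups(
    ortho_map: Mapping[str, Mapping[str, Sequence[str]]],
    species: Sequence[str],
    path: str | Path,
) -> None:
    rows = []
    for og, sp_genes in ortho_map.items():
        rows.append([og] + [", ".join(sp_genes.get(sp, ())) for sp in species])
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        path, sep="\t", index=False
    )
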