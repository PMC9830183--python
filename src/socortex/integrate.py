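"""Multi-method integration: the putative toolkit set and term enrichment.

The toolkit is the intersection of the cross-species SVM predictor set with
the trait-associated consensus-network gene set; differential expression
overlaps are reported alongside. Enrichment is plain per-term one-sided
Fisher testing over a user-supplied gene -> term map, restricted to terms
with a minimum number of annotated genes in the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .de import bh_adjust
from .simulate import SyntheticTruth, score_recovery

logger = logging.getLogger("socortex")


@dataclass
class ToolkitReport:
    """Sets from the three methods and their exact intersections.

    Percentages are always recomputed from the stored sets with an explicit
    denominator, never stored independently.
    """

    svm_predictors: set[str]
    wgcna_trait_genes: set[str]
    de_genes: set[str]
    toolkit: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.toolkit = self.svm_predictors & self.wgcna_trait_genes
        if not self.svm_predictors or not self.wgcna_trait_genes:
            logger.warning("empty SVM or WGCNA set; toolkit is empty")

    @property
    def three_way(self) -> set[str]:
        return self.toolkit & self.de_genes

    def pairwise(self) -> dict[str, set[str]]:
        return {
            "svm&wgcna": self.svm_predictors & self.wgcna_trait_genes,
            "svm&de": self.svm_predictors & self.de_genes,
            "wgcna&de": self.wgcna_trait_genes & self.de_genes,
        }

    def percentage(self, subset: set[str], reference: str) -> dict:
        """|subset ∩ reference| as a percentage of the named reference set."""
        refs = {
            "svm": self.svm_predictors,
            "wgcna": self.wgcna_trait_genes,
            "de": self.de_genes,
            "toolkit": self.toolkit,
        }
        ref = refs[reference]
        pct = 100.0 * len(subset & ref) / len(ref) if ref else float("nan")
        return {"count": len(subset & ref), "denominator": reference,
                "denominator_size": len(ref), "percent": pct}

    def summary(self) -> dict:
        pw = self.pairwise()
        return {
            "n_svm": len(self.svm_predictors),
            "n_wgcna": len(self.wgcna_trait_genes),
            "n_de": len(self.de_genes),
            "n_toolkit": len(self.toolkit),
            "n_three_way": len(self.three_way),
            "pairwise": {k: len(v) for k, v in pw.items()},
            "de_in_toolkit": self.percentage(self.de_genes, "toolkit"),
            "de_in_svm": self.percentage(self.de_genes, "svm"),
        }

    def recovery(self, truth: SyntheticTruth):
        return score_recovery(self.toolkit, truth, role="toolkit")


def build_toolkit(
    svm_set: set[str], wgcna_set: set[str], de_set: set[str]
) -> ToolkitReport:
    """Exact set intersections of the three method outputs."""
    return ToolkitReport(
        svm_predictors=set(svm_set),
        wgcna_trait_genes=set(wgcna_set),
        de_genes=set(de_set),
    )


def fisher_enrichment(
    foreground: set[str],
    background: set[str],
    term_map: pd.DataFrame,
    min_annotated: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment per term.

    ``term_map`` has columns gene_id, term_id, and optionally term_name; genes
    outside the background are ignored, background genes without annotation
    count as unannotated. Terms with fewer than ``min_annotated`` annotated
    background genes are excluded. BH adjustment across the tested terms.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("empty foreground set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    required = {"gene_id", "term_id"}
    if not required <= set(term_map.columns):
        raise ValueError(f"term map needs columns {sorted(required)}")
    tm = term_map[term_map["gene_id"].isin(background)].drop_duplicates(
        subset=["gene_id", "term_id"])
    names = {}
    if "term_name" in tm.columns:
        names = tm.drop_duplicates("term_id").set_index("term_id")[
            "term_name"].to_dict()
    N = len(background)
    n_fg = len(foreground)
    rows = []
    for term, grp in tm.groupby("term_id"):
        annotated = set(grp["gene_id"])
        K = len(annotated)
        if K < min_annotated:
            continue
        k = len(annotated & foreground)
        # one-sided hypergeometric upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_fg))
        rows.append((term, names.get(term, ""), K, k, n_fg * K / N, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "annotated", "significant",
                       "expected", "p"]).set_index("term_id")
    out = out.sort_values("p")
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
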