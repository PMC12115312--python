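"""Homoeolog expression bias (HEB) and expression-atlas summaries.

In an allotetraploid, each 1:1 homoeolog pair contributes relative
expression (p_a, p_b) = (FPKM_a, FPKM_b) / (FPKM_a + FPKM_b) per tissue.
The pair's bias category is the Euclidean-nearest of three ideal patterns —
dominance of subgenome A (1, 0), dominance of subgenome B (0, 1), or
balanced expression (0.5, 0.5) — after an FPKM > 0.5 expression filter;
pairs with neither homoeolog expressed are NOT_EXPRESSED.  Distance ties
are resolved to BALANCED, so the dominance boundary sits exactly at
p > 0.75.  Replicates are averaged (arithmetic mean FPKM) before all rules.

Atlas summaries report per-tissue mean FPKM, the dominant tissue and its
predominance ratio; duplicate-pair reports compare per-tissue log2 ratios
(pseudocount +1) and Pearson concordance to call pairs redundant, diverged,
or one-silent (a pseudogenization signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ConfigError, ExpressionMatrix, ValidationError

__all__ = [
    "HEB_CATEGORIES",
    "DEFAULT_IDEALS",
    "EXPRESSION_THRESHOLD",
    "HEBCall",
    "AtlasSummary",
    "PairExpressionReport",
    "filter_expressed",
    "normalize_pair",
    "classify_heb",
    "classify_heb_table",
    "summarize_atlas",
    "compare_pair_expression",
    "heb_heatmap",
]

HEB_CATEGORIES = ("BALANCED", "DOM_A", "DOM_B", "NOT_EXPRESSED")

#: Ideal normalized (p_a, p_b) patterns for the three expressed categories.
DEFAULT_IDEALS = {
    "DOM_A": (1.0, 0.0),
    "DOM_B": (0.0, 1.0),
    "BALANCED": (0.5, 0.5),
}

#: Strict FPKM threshold above which a homoeolog counts as expressed.
EXPRESSION_THRESHOLD = 0.5


@dataclass
class HEBCall:
    pair_id: str
    tissue: str
    p: tuple[float, float] | None          # None for NOT_EXPRESSED
    distances: dict[str, float] = field(default_factory=dict)
    category: str = "NOT_EXPRESSED"

    def __post_init__(self) -> None:
        if self.category not in HEB_CATEGORIES:
            raise ValidationError(f"unknown HEB category {self.category!r}")
        if self.category != "NOT_EXPRESSED":
            if self.p is None or not math.isclose(sum(self.p), 1.0, abs_tol=1e-9):
                raise ValidationError("p must sum to 1 for expressed pairs")


@dataclass
class AtlasSummary:
    gene_id: str
    tissue_means: dict[str, float]
    dominant_tissue: str
    predominance_ratio: float
    predominant: bool
    expressed_anywhere: bool


@dataclass
class PairExpressionReport:
    gene_a: str
    gene_b: str
    log2_ratio: dict[str, float]            # per tissue, log2((a+1)/(b+1))
    concordance: float | None               # Pearson r, None if undefined
    call: str                               # 'redundant'|'diverged'|'one_silent'


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float = EXPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Boolean gene x tissue mask: expressed iff mean FPKM over the tissue's
    replicates is strictly above ``threshold``."""
    if threshold < 0:
        raise ConfigError("expression threshold must be >= 0")
    return matrix.tissue_means() > threshold


def normalize_pair(fpkm_a: float, fpkm_b: float) -> tuple[float, float]:
    """Relative subgenome contributions (p_a, p_b); requires a + b > 0."""
    total = fpkm_a + fpkm_b
    if total <= 0:
        raise ValidationError(
            "cannot normalize a pair with zero total expression; "
            "route to NOT_EXPRESSED instead"
        )
    pa = fpkm_a / total
    return pa, 1.0 - pa


def classify_heb(
    pair_id: str,
    tissue: str,
    fpkm_a: float,
    fpkm_b: float,
    threshold: float = EXPRESSION_THRESHOLD,
    ideals: dict[str, tuple[float, float]] | None = None,
    require_both: bool = False,
) -> HEBCall:
    """Classify one homoeolog pair in one tissue.

    ``fpkm_a``/``fpkm_b`` are replicate-mean FPKMs.  With ``require_both``
    the pair must have both homoeologs above threshold to be classified
    (otherwise at least one suffices; a sub-threshold member keeps its
    measured value in the normalization).  Exact distance ties go to
    BALANCED.
    """
    ideals = DEFAULT_IDEALS if ideals is None else ideals
    expressed_a = fpkm_a > threshold
    expressed_b = fpkm_b > threshold
    ok = (expressed_a and expressed_b) if require_both else (expressed_a or expressed_b)
    if not ok:
        return HEBCall(pair_id=pair_id, tissue=tissue, p=None,
                       category="NOT_EXPRESSED")
    p = normalize_pair(fpkm_a, fpkm_b)
    distances = {
        cat: math.hypot(p[0] - v[0], p[1] - v[1]) for cat, v in ideals.items()
    }
    dmin = min(distances.values())
    # Resolve exact ties conservatively in favour of BALANCED.
    if "BALANCED" in distances and math.isclose(
        distances["BALANCED"], dmin, rel_tol=0, abs_tol=1e-12
    ):
        category = "BALANCED"
    else:
        category = min(distances, key=lambda c: (distances[c], c))
    return HEBCall(pair_id=pair_id, tissue=tissue, p=p, distances=distances,
                   category=category)


def classify_heb_table(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    threshold: float = EXPRESSION_THRESHOLD,
    ideals: dict[str, tuple[float, float]] | None = None,
    require_both: bool = False,
) -> pd.DataFrame:
    """HEB calls for every homoeolog pair x tissue.

    ``pairs`` needs columns pair_id, gene_a, gene_b (gene_a from subgenome A).
    Returns one row per pair x tissue with the normalized contributions,
    distances, and category.
    """
    means = matrix.tissue_means()
    rows = []
    for _, pr in pairs.iterrows():
        for tissue in matrix.tissues:
            for g in (pr["gene_a"], pr["gene_b"]):
                if g not in means.index:
                    raise ValidationError(f"gene {g} missing from matrix")
            call = classify_heb(
                str(pr["pair_id"]), tissue,
                float(means.at[pr["gene_a"], tissue]),
                float(means.at[pr["gene_b"], tissue]),
                threshold=threshold, ideals=ideals, require_both=require_both,
            )
            rows.append(
                {
                    "pair_id": call.pair_id,
                    "tissue": call.tissue,
                    "gene_a": pr["gene_a"],
                    "gene_b": pr["gene_b"],
                    "p_a": call.p[0] if call.p else float("nan"),
                    "p_b": call.p[1] if call.p else float("nan"),
                    "category": call.category,
                }
            )
    return pd.DataFrame(rows)


def summarize_atlas(
    matrix: ExpressionMatrix,
    predominance_factor: float = 2.0,
    threshold: float = EXPRESSION_THRESHOLD,
) -> list[AtlasSummary]:
    """Per-gene tissue summary: dominant tissue and predominance flag.

    A gene is 'predominant' in its top tissue when the ratio of the top to
    the second-highest tissue mean is at least ``predominance_factor`` and
    the gene is expressed there.  Display transforms (log10(FPKM + 0.01)
    for atlas heatmaps, log2(FPKM + 1) for HEB heatmaps) are provided by
    :func:`display_log10` / :func:`display_log2`.
    """
    means = matrix.tissue_means()
    out = []
    for gene, row in means.iterrows():
        vals = row.sort_values(ascending=False)
        top_tissue, top = vals.index[0], float(vals.iloc[0])
        second = float(vals.iloc[1]) if len(vals) > 1 else 0.0
        if len(vals) > 1:
            ratio = top / second if second > 0 else float("inf")
            ratio = max(ratio, 1.0)
        else:
            ratio = 1.0
        out.append(
            AtlasSummary(
                gene_id=str(gene),
                tissue_means={t: float(v) for t, v in row.items()},
                dominant_tissue=top_tissue,
                predominance_ratio=ratio,
                predominant=ratio >= predominance_factor and top > threshold,
                expressed_anywhere=bool((row > threshold).any()),
            )
        )
    return out


def display_log10(fpkm: float | np.ndarray) -> float | np.ndarray:
    """Atlas heatmap transform, log10(FPKM + 0.01); zero maps to -2."""
    return np.log10(np.asarray(fpkm) + 0.01)


def display_log2(fpkm: float | np.ndarray) -> float | np.ndarray:
    """HEB heatmap transform, log2(FPKM + 1)."""
    return np.log2(np.asarray(fpkm) + 1.0)


def compare_pair_expression(
    gene_a: str,
    gene_b: str,
    matrix: ExpressionMatrix,
    silent_threshold: float = EXPRESSION_THRESHOLD,
    r_floor: float = 0.8,
) -> PairExpressionReport:
    """Compare a duplicate (or homoeolog) pair's expression profiles.

    one_silent: exactly one member expressed in no tissue (a
    pseudogenization signal).  Otherwise redundant when the tissue profiles
    agree (Pearson r >= ``r_floor`` and mean |log2 ratio| <= 1), else
    diverged.  With fewer than 3 tissues (or a constant profile) the
    concordance is undefined and the call rests on the ratios alone.
    """
    means = matrix.tissue_means()
    for g in (gene_a, gene_b):
        if g not in means.index:
            raise ValidationError(f"gene {g} missing from matrix")
    a = means.loc[gene_a]
    b = means.loc[gene_b]
    log2_ratio = {
        t: float(np.log2((a[t] + 1.0) / (b[t] + 1.0))) for t in means.columns
    }
    silent_a = bool((a <= silent_threshold).all())
    silent_b = bool((b <= silent_threshold).all())
    if silent_a != silent_b:
        return PairExpressionReport(gene_a, gene_b, log2_ratio, None, "one_silent")

    r: float | None = None
    if len(means.columns) >= 3 and a.std() > 0 and b.std() > 0:
        from scipy.stats import pearsonr

        r = float(pearsonr(a.to_numpy(), b.to_numpy())[0])
    mean_abs_ratio = float(np.mean(np.abs(list(log2_ratio.values()))))
    if (r is None or r >= r_floor) and mean_abs_ratio <= 1.0:
        call = "redundant"
    else:
        call = "diverged"
    return PairExpressionReport(gene_a, gene_b, log2_ratio, r, call)


def heb_heatmap(calls: pd.DataFrame, path: str) -> None:
    """Optional category heatmap (pairs x tissues) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cat_codes = {c: i for i, c in enumerate(HEB_CATEGORIES)}
    grid = (
        calls.assign(code=calls["category"].map(cat_codes))
        .pivot_table(index="pair_id", columns="tissue", values="code",
                     aggfunc="first")
    )
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * grid.shape[1], 1 + 0.25 * grid.shape[0])
    )
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=len(HEB_CATEGORIES) - 1)
    ax.set_xticks(range(grid.shape[1]), grid.columns)
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=6)
    cbar = fig.colorbar(im, ticks=list(cat_codes.values()))
    cbar.ax.set_yticklabels(list(cat_codes.keys()))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
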