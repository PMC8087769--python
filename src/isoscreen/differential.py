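"""Differential dependency between isogenic genotypes.

Knockout-genotype gene scores are regressed on wild-type scores (ordinary
least squares with intercept, one point per gene); standardized residuals
give each gene a Z score, and genes with Z strictly above the threshold
(default 3.5) are called selective dependencies.  Term enrichment among the
called genes uses the one-sided hypergeometric upper tail, reported
unadjusted (Benjamini-Hochberg offered as an extra column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "fit_bf_linear_model",
    "residual_z_scores",
    "select_dependencies",
    "enrichment_test",
    "differential_table",
]

Z_THRESHOLD_DEFAULT = 3.5


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of knockout scores on wild-type scores."""

    slope: float
    intercept: float
    n: int
    rss: float
    residuals: pd.Series
    excluded: tuple[str, ...]  # genes missing a genotype

    def predict(self, bf_wt: pd.Series) -> pd.Series:
        return self.intercept + self.slope * bf_wt


def fit_bf_linear_model(bf_wt: pd.Series, bf_ko: pd.Series) -> ModelFit:
    """OLS with intercept; wild-type is the predictor, knockout the response.

    Genes lacking a finite value in either genotype are excluded and listed.
    """
    common = bf_wt.index.intersection(bf_ko.index)
    x = bf_wt.loc[common].astype(float)
    y = bf_ko.loc[common].astype(float)
    keep = x.notna() & y.notna()
    excluded = tuple(
        sorted(set(bf_wt.index.symmetric_difference(bf_ko.index)) | set(common[~keep]))
    )
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 genes with both genotypes, got {len(x)}")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("zero variance in wild-type predictor")
    design = np.column_stack([np.ones(len(x)), x.to_numpy()])
    coef, _, _, _ = np.linalg.lstsq(design, y.to_numpy(), rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    residuals = y - (intercept + slope * x)
    return ModelFit(
        slope=slope,
        intercept=intercept,
        n=len(x),
        rss=float((residuals**2).sum()),
        residuals=residuals,
        excluded=excluded,
    )


def residual_z_scores(residuals: pd.Series, ddof: int = 0) -> pd.Series:
    """Z = (residual - mean(residuals)) / stddev(residuals).

    Population standard deviation (``ddof=0``) by default; pass ``ddof=1``
    for the sample convention.
    """
    r = residuals.astype(float)
    if len(r) < 2:
        raise ValueError("need >= 2 residuals")
    sd = float(r.std(ddof=ddof))
    if sd == 0:
        raise ValueError("zero standard deviation: all residuals equal")
    return (r - float(r.mean())) / sd


def select_dependencies(
    z: pd.Series,
    threshold: float = Z_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Call dependencies at ``z > threshold`` (strict) and rank by
    descending z, ties broken lexicographically by gene symbol."""
    df = pd.DataFrame({"z": z.astype(float)})
    df.index.name = "gene"
    df = (
        df.reset_index()
        .sort_values(["z", "gene"], ascending=[False, True], kind="stable")
        .set_index("gene")
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_dependency"] = df["z"] > threshold
    return df


def differential_table(
    bf_wt: pd.Series,
    bf_ko: pd.Series,
    threshold: float = Z_THRESHOLD_DEFAULT,
    ddof: int = 0,
) -> tuple[pd.DataFrame, ModelFit]:
    """Full per-gene table: scores, fit, residual, z, rank, call."""
    fit = fit_bf_linear_model(bf_wt, bf_ko)
    z = residual_z_scores(fit.residuals, ddof=ddof)
    calls = select_dependencies(z, threshold=threshold)
    genes = calls.index
    out = pd.DataFrame(
        {
            "bf_ko": bf_ko.loc[genes].astype(float),
            "bf_wt": bf_wt.loc[genes].astype(float),
            "fitted": fit.predict(bf_wt.loc[genes].astype(float)),
            "residual": fit.residuals.loc[genes],
            "z": calls["z"],
            "rank": calls["rank"],
            "is_dependency": calls["is_dependency"],
        }
    )
    out.index.name = "gene"
    return out, fit


def enrichment_test(
    selected: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of the selected genes.

    For a term with K universe genes, n selected genes of which k carry the
    term in a universe of N: p = upper-tail P(X >= k) for
    X ~ Hypergeom(N, K, n); fold = (k/n) / (K/N).  P values are unadjusted;
    ``adjust=True`` adds a Benjamini-Hochberg column alongside.
    Terms with K = 0 after restriction to the universe are skipped.
    """
    universe_set = set(universe)
    selected_set = set(selected)
    stray = selected_set - universe_set
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe_set), len(selected_set)
    rows = []
    for term, genes in annotation.items():
        members = set(genes) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        fold = (k / n) / (K / N) if n else float("nan")
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "fold": fold, "p": p})
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "fold", "p"])
    if adjust and len(df):
        df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adj[order[i]] = running
    return adj
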