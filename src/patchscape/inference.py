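"""Statistical layer: screening, group tests, PCA, GLMs and the three-block
adjusted variance partitioning.

The inferential chain mirrors a standard community-assembly analysis: each
predictor block (abiotic, present-day, historical landscape configuration)
is screened for collinearity, reduced to its first two principal-component
axes, and related to a diversity response through a GLM (Poisson log link
for richness counts, Gaussian identity for bounded dissimilarity indices).
Explained variation is the deviance-based D² with an Ezekiel-style
small-sample adjustment (reducing to adjusted R² in the Gaussian case), and
the unique/shared contributions of the three blocks are obtained by
inclusion–exclusion over the seven nested model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError, VarianceDecomposition

__all__ = [
    "BlockSpec",
    "PcaAxes",
    "GlmFit",
    "collinearity_screen",
    "welch_t_test",
    "fdr_adjust",
    "pearson",
    "block_pca",
    "fit_glm",
    "explained_variation",
    "variance_partition",
    "per_variable_glms",
    "significance_stars",
]

FAMILIES = {
    "poisson": sm.families.Poisson(),
    "gaussian": sm.families.Gaussian(),
}


@dataclass
class BlockSpec:
    """One predictor block: its variables and per-variable transforms."""

    name: str
    variables: Sequence[str]
    transforms: Mapping[str, str] = field(default_factory=dict)  # var -> none|log|log10
    standardize: bool = True

    def apply_transforms(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data[list(self.variables)].copy()
        for var, tf in self.transforms.items():
            if var not in out.columns or tf in (None, "none", ""):
                continue
            if tf == "log":
                out[var] = np.log(out[var])
            elif tf == "log10":
                out[var] = np.log10(out[var])
            else:
                raise ValidationError(f"unknown transform '{tf}' for '{var}'")
        return out


@dataclass
class PcaAxes:
    """First two PCA axes of one block: loadings, variance proportions (%)
    and per-patch scores."""

    block: str
    loadings: pd.DataFrame  # variables × ("PC1", "PC2")
    proportion: np.ndarray  # per-axis % of total variance
    cumulative: np.ndarray
    scores: pd.DataFrame  # patches × ("PC1", "PC2")
    dropped_rows: list = field(default_factory=list)


@dataclass
class GlmFit:
    """A fitted GLM with the quantities the pipeline reports."""

    response: str
    family: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    null_deviance: float
    deviance: float
    aic: float
    n: int
    n_predictors: int

    def __post_init__(self):
        if self.deviance > self.null_deviance + 1e-9:
            raise ValidationError("residual deviance exceeds null deviance")
        if not np.isfinite(self.aic):
            raise ValidationError("non-finite AIC")


def collinearity_screen(
    data: pd.DataFrame,
    threshold: float = 0.5,
    priority: Optional[Sequence[str]] = None,
    min_keep: int = 0,
) -> tuple:
    """Greedy collinearity screen: walk variables in priority order, keep a
    variable only if its |Pearson r| with every already-kept variable is at
    or below the threshold.

    Constant variables (undefined correlation) are excluded with a warning.
    ``min_keep`` stops dropping once that many variables survive (a block
    that must feed a two-axis PCA keeps at least two).  Returns the kept
    list and a report of (dropped, kept-partner, r) tuples.
    """
    order = list(priority) if priority is not None else list(data.columns)
    if set(order) != set(data.columns):
        raise ValidationError("priority list must name exactly the data columns")
    kept: list = []
    dropped: list = []
    for var in order:
        col = data[var]
        if col.std(ddof=0) == 0 or col.isna().all():
            warnings.warn(f"constant variable '{var}' excluded from screen",
                          stacklevel=2)
            dropped.append((var, None, np.nan))
            continue
        clash = None
        for kv in kept:
            r = data[var].corr(data[kv])
            if abs(r) > threshold:
                clash = (var, kv, float(r))
                break
        if clash is None:
            kept.append(var)
        else:
            dropped.append(clash)
    # restore dropped variables (in priority order) if below the floor
    while len(kept) < min_keep and dropped:
        var = dropped.pop(0)[0]
        if data[var].std(ddof=0) > 0:
            kept.append(var)
    return kept, dropped


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("zero variance in both samples")
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pearson(x: Sequence[float], y: Sequence[float]) -> dict:
    """Sample Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("Pearson test needs n >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValidationError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def block_pca(data: pd.DataFrame, spec: Optional[BlockSpec] = None) -> PcaAxes:
    """First two axes of a correlation-matrix PCA of one predictor block.

    Variables are transformed per the spec and standardised to unit
    variance; rows with missing values are dropped (and reported).  Each
    axis is oriented so its largest-|loading| variable loads positively.
    """
    name = spec.name if spec is not None else "block"
    if spec is not None:
        data = spec.apply_transforms(data)
    if data.shape[1] < 2:
        raise ValidationError(
            f"block '{name}' must contain >= 2 variables for a two-axis PCA"
        )
    complete = data.dropna()
    dropped = sorted(set(data.index) - set(complete.index))
    if len(complete) < 3:
        raise ValidationError(f"block '{name}' has fewer than 3 complete rows")
    z = (complete - complete.mean()) / complete.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    loadings = eigvec[:, :2].copy()
    for ax in range(2):
        top = np.argmax(np.abs(loadings[:, ax]))
        if loadings[top, ax] < 0:
            loadings[:, ax] *= -1
    proportion = 100.0 * eigval[:2] / eigval.sum()
    scores = z.to_numpy() @ loadings
    return PcaAxes(
        block=name,
        loadings=pd.DataFrame(loadings, index=data.columns, columns=["PC1", "PC2"]),
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        scores=pd.DataFrame(scores, index=complete.index, columns=["PC1", "PC2"]),
        dropped_rows=dropped,
    )


def fit_glm(
    y: pd.Series,
    X: Optional[pd.DataFrame],
    family: str,
    response: str = "y",
) -> GlmFit:
    """Maximum-likelihood GLM fit (IRLS) with Wald z statistics and AIC.

    ``X`` may be None/empty for the intercept-only (null) model.  Families:
    ``poisson`` (log link, integer non-negative response) or ``gaussian``
    (identity link).
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family '{family}'")
    y = pd.Series(y).astype(float)
    if family == "poisson" and ((y < 0).any() or not np.allclose(y, np.round(y))):
        raise ValidationError("Poisson response must be non-negative integers")
    if y.isna().any():
        raise ValidationError("response contains missing values")
    if X is None or X.shape[1] == 0:
        design = pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
        k = 0
    else:
        X = X.loc[y.index]
        if X.isna().any().any():
            raise ValidationError(
                "predictors contain missing values; drop incomplete rows first"
            )
        design = sm.add_constant(X.astype(float), has_constant="add")
        k = X.shape[1]
    if len(y) <= k + 1:
        raise ValidationError("need n > p + 1 observations")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError("singular design matrix")
    model = sm.GLM(y, design, family=FAMILIES[family])
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:
        raise ValidationError(f"GLM failed to converge: {exc}") from exc
    return GlmFit(
        response=response,
        family=family,
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=pd.Series(
            2 * sps.norm.sf(np.abs(res.tvalues)), index=res.params.index
        ),
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        aic=float(res.aic),
        n=int(res.nobs),
        n_predictors=k,
    )


def explained_variation(fit: GlmFit, adjust: bool = True) -> float:
    """Deviance-based explained variation D² of a fitted GLM.

    D² = (null deviance − residual deviance) / null deviance, identical to
    R² for the Gaussian family.  With ``adjust``, the Ezekiel correction
    1 − [(n−1)/(n−p−1)](1−D²) is applied (0 predictors adjust to D² itself).
    """
    if fit.n <= fit.n_predictors + 1:
        raise ValidationError("need n > p + 1 for explained variation")
    if fit.null_deviance == 0:
        return 0.0
    d2 = (fit.null_deviance - fit.deviance) / fit.null_deviance
    if not adjust or fit.n_predictors == 0:
        return float(d2)
    return float(1 - (fit.n - 1) / (fit.n - fit.n_predictors - 1) * (1 - d2))


def _drop_dependent_columns(X: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Remove columns linearly dependent (incl. the intercept) on earlier
    ones, so overlapping blocks can be combined in one model fit."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    keep = [0]
    for j in range(1, arr.shape[1]):
        trial = arr[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * np.linalg.norm(trial)) > len(keep):
            keep.append(j)
    return X.iloc[:, [j - 1 for j in keep[1:]]]


def variance_partition(
    y: pd.Series,
    blocks: Mapping[str, pd.DataFrame],
    family: str,
    response: str = "y",
) -> VarianceDecomposition:
    """Adjusted variance partitioning of one response over three blocks.

    Fits the seven GLMs on all non-empty block combinations, converts each
    to adjusted explained variation, and solves the three-set inclusion–
    exclusion system for the 3 unique, 3 pairwise-shared and 1 triple-shared
    fractions.  Fractions are reported in % and sum exactly to the TVE
    (the adjusted explained variation of the full model); adjusted fractions
    can be negative and are not truncated.
    """
    names = list(blocks)
    if len(names) != 3:
        raise ValidationError("variance partitioning requires exactly 3 blocks")
    common = y.index
    for b in blocks.values():
        common = common.intersection(b.index)
    y = y.loc[common]

    def adj(subset):
        X = pd.concat(
            [blocks[nm].loc[common].add_prefix(f"{nm}_") for nm in subset], axis=1
        )
        X = _drop_dependent_columns(X)
        fit = fit_glm(y, X, family, response)
        return explained_variation(fit, adjust=True)

    s = {nm: adj([nm]) for nm in names}
    pair = {frozenset(c): adj(list(c)) for c in combinations(names, 2)}
    total = adj(names)

    n1, n2, n3 = names
    g = sum(s.values()) - sum(pair.values()) + total
    uniq = {
        n1: total - pair[frozenset((n2, n3))],
        n2: total - pair[frozenset((n1, n3))],
        n3: total - pair[frozenset((n1, n2))],
    }
    shared2 = {
        frozenset((a, b)): s[a] + s[b] - pair[frozenset((a, b))] - g
        for a, b in combinations(names, 2)
    }
    # map generic names to the canonical abi/pre/his keys by position
    key = dict(zip(names, ("abi", "pre", "his")))
    fractions = {f"unique_{key[nm]}": 100 * uniq[nm] for nm in names}
    for a, b in combinations(names, 2):
        fractions[f"shared_{key[a]}_{key[b]}"] = 100 * shared2[frozenset((a, b))]
    fractions["shared_all"] = 100 * g
    tve = sum(fractions.values())  # equals 100*total up to float rounding
    return VarianceDecomposition(
        response=response,
        family=family,
        fractions=fractions,
        tve=tve,
        n=len(y),
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def per_variable_glms(
    y: pd.Series,
    blocks: Mapping[str, pd.DataFrame],
    family: str,
    response: str = "y",
) -> tuple:
    """One multi-variable GLM per predictor block on its raw variables.

    Returns ``(table, fits)``: a long-format table with per-variable
    coefficient, z, p and significance stars plus each block's AIC, and the
    dict of fits ranked by AIC (lower is better).
    """
    rows = []
    fits = {}
    for name, X in blocks.items():
        X = X.dropna()
        common = y.index.intersection(X.index)
        fit = fit_glm(y.loc[common], X.loc[common], family, response)
        fits[name] = fit
        for var in X.columns:
            rows.append(
                {
                    "block": name,
                    "variable": var,
                    "coef": fit.params[var],
                    "z": fit.zvalues[var],
                    "p": fit.pvalues[var],
                    "stars": significance_stars(fit.pvalues[var]),
                    "AIC": fit.aic,
                }
            )
    table = pd.DataFrame(rows)
    ranking = sorted(fits, key=lambda nm: fits[nm].aic)
    table["aic_rank"] = table["block"].map(
        {nm: i + 1 for i, nm in enumerate(ranking)}
    )
    return table, fits
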