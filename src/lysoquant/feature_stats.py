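"""Two-round PCA variable selection over per-cell imaging features, plus a
group-comparison wrapper on component scores.

The intended workflow: a first PCA over the full per-cell feature table
(colocalization indices, overlaps, object counts/volumes — incommensurate
scales, hence standardization by default), selection of the variables that
dominate the leading components, a second PCA on the reduced set, and a
two-factor analysis of variance on first-component scores with step-down
(Holm-Sidak) multiplicity-adjusted pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAResult",
    "pca_round",
    "n_informative_components",
    "select_variables",
    "component_score_test",
]


@dataclass
class PCAResult:
    """Loadings (variables x components), scores (cells x components),
    explained-variance fractions and eigenvalues, components ordered by
    decreasing explained variance."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: np.ndarray
    eigenvalues: np.ndarray


def pca_round(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """One PCA round over the numeric columns of a per-cell feature table.

    With ``standardize`` (default), each variable is scaled to unit variance;
    a constant column is then an error naming the column.  Loadings are
    orthonormal; each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 2 or num.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 numeric columns")
    X = num.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if standardize:
        const = [c for c, s in zip(num.columns, sd) if s == 0]
        if const:
            raise ValueError(
                f"constant column(s) cannot be standardized: {const}"
            )
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=num.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        explained=pca.explained_variance_ratio_,
        eigenvalues=pca.explained_variance_,
    )


def n_informative_components(
    eigenvalues: np.ndarray, rule: str = "kaiser"
) -> int:
    """Number of informative components; the Kaiser rule (eigenvalue > 1 on
    standardized data) is the default."""
    if rule != "kaiser":
        raise ValueError(f"unknown rule {rule!r}")
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def select_variables(
    loadings: pd.DataFrame,
    explained: np.ndarray,
    n_keep: int,
    cum_threshold: float = 0.55,
) -> pd.DataFrame:
    """Rank variables by their maximum absolute loading across the leading
    components whose cumulative explained variance reaches ``cum_threshold``.

    Returns the top ``n_keep`` variables with the component each one loads
    most heavily on.  Invariant to sign flips of the loadings.
    """
    if n_keep > loadings.shape[0]:
        raise ValueError("n_keep exceeds the number of variables")
    m = int(np.searchsorted(np.cumsum(explained), cum_threshold) + 1)
    m = min(max(m, 1), loadings.shape[1])
    top = loadings.iloc[:, :m].abs()
    weight = top.max(axis=1)
    component = top.idxmax(axis=1)
    out = pd.DataFrame(
        {"variable": loadings.index, "component": component, "weight": weight}
    ).sort_values(["weight", "variable"], ascending=[False, True], kind="mergesort")
    return out.head(n_keep).reset_index(drop=True)


def component_score_test(
    scores,
    group_labels: pd.DataFrame | dict,
    design: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Two-factor ANOVA on first-component scores with Holm-Sidak pairwise
    comparisons.

    ``group_labels`` supplies one or two factor columns (e.g. condition and
    organelle marker); ``design`` overrides the model formula.  Returns a
    dict with the ANOVA table and a pairwise-comparison table per factor
    (difference of means, adjusted p-value, significance at ``alpha``).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = pd.DataFrame(group_labels)
    if len(labels) != scores.size:
        raise ValueError("scores and group labels differ in length")
    factors = list(labels.columns)
    for f in factors:
        levels = labels[f].unique()
        if len(levels) < 2 and len(factors) == 1:
            raise ValueError(f"factor {f!r} needs >= 2 groups")
        counts = labels.groupby(f, observed=True).size()
        if (counts < 3).any():
            raise ValueError(f"every level of {f!r} needs >= 3 samples")
    if sum(labels[f].nunique() > 1 for f in factors) == 0:
        raise ValueError("need >= 2 groups overall")

    df = labels.copy()
    df["score"] = scores
    if design is None:
        terms = " * ".join(f"C({f})" for f in factors)
        design = f"score ~ {terms}"
    model = smf.ols(design, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    pairwise_tables = {}
    for f in factors:
        levels = sorted(df[f].unique())
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = df.loc[df[f] == levels[i], "score"]
                b = df.loc[df[f] == levels[j], "score"]
                t, p = sps.ttest_ind(a, b)
                rows.append(
                    {
                        "factor": f,
                        "level_a": levels[i],
                        "level_b": levels[j],
                        "diff": float(a.mean() - b.mean()),
                        "p_raw": float(p),
                    }
                )
        tab = pd.DataFrame(rows)
        if len(tab):
            rej, padj, _, _ = multipletests(
                tab["p_raw"], alpha=alpha, method="holm-sidak"
            )
            tab["p_adj"] = padj
            tab["significant"] = rej
        pairwise_tables[f] = tab
    return {"anova": anova, "pairwise": pairwise_tables, "alpha": alpha}
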