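"""Classification and statistics for the six-feature liver tables.

The six measurements per subject-timepoint (shear wave speed and
attenuation, B-scan and H-scan image intensities, IVC-normalized peak
enhancement and wash-in rate) live on very different scales, so all analyses
start from Z-scored features.  Included here:

* ``zscore`` - per-feature standardization (sample SD, n-1), returning the
  parameters so held-out rows can be transformed without leakage;
* ``pca_contributions`` - PCA with a per-feature contribution percentage:
  contribution_j = 100 * sum_{k<=K} lambda_k w_jk^2 / sum_{k<=K} lambda_k,
  the eigenvalue-weighted squared loadings over the K retained components
  (with all six components retained this degenerates to a uniform 100/6 per
  feature on standardized data, so rankings are read from K=3);
* ``svm_train_eval`` - RBF-kernel SVM with a stratified 80/20 split and
  grid-searched hyperparameters, in two-category (normal vs high-fat) or
  three-category mode, reporting train, held-out test, and whole-table
  accuracies;
* ``mann_whitney_u`` - the rank-sum test with an exact (enumerative) null
  for small, tie-free samples and a tie- and continuity-corrected normal
  approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURE_COLUMNS = ["sws", "swa", "bscan", "hscan", "pe_nlp", "wir_nlp"]

__all__ = [
    "FEATURE_COLUMNS",
    "Standardizer",
    "PCAResult",
    "ClassificationReport",
    "MannWhitneyResult",
    "zscore",
    "pca_contributions",
    "svm_train_eval",
    "mann_whitney_u",
]

SVM_C_GRID = tuple(10.0**e for e in range(-1, 4))
SVM_GAMMA_GRID = tuple(10.0**e for e in range(-3, 2))


@dataclass
class Standardizer:
    """Per-feature mean/SD used for Z-scoring (sample SD, ddof=1)."""

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[FEATURE_COLUMNS] = (table[FEATURE_COLUMNS] - self.means) / self.sds
        return out


@dataclass
class PCAResult:
    scores: np.ndarray                 # rows x retained components
    loadings: np.ndarray               # features x retained components
    explained_variance_pct: np.ndarray
    contributions: pd.Series           # percent per feature, sums to 100
    eigenvalues: np.ndarray


@dataclass
class ClassificationReport:
    mode: str
    input_space: str
    train_accuracy: float              # percent
    test_accuracy: float               # percent
    overall_accuracy: float            # percent, all rows through the fitted model
    seed: int
    best_params: dict = field(default_factory=dict)
    classes: tuple[str, ...] = ()


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    significant: bool                  # p < 0.05
    method: str = "exact"


def _feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table[FEATURE_COLUMNS]


def zscore(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize each feature column to mean 0, sample SD 1."""
    feats = _feature_matrix(table)
    sds = feats.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature column(s): {list(zero.index)}")
    std = Standardizer(means=feats.mean(), sds=sds)
    return std.apply(table), std


def pca_contributions(table: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of a standardized table with per-feature contribution percentages.

    The input must already be Z-scored.  Component signs follow the
    convention that each component's largest-magnitude loading is positive.
    """
    X = _feature_matrix(table).to_numpy()
    if not (
        np.allclose(X.mean(axis=0), 0.0, atol=1e-8)
        and np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-6)
    ):
        raise ValueError("table must be Z-scored before PCA (see zscore)")
    n_feat = X.shape[1]
    if not 1 <= n_components <= n_feat:
        raise ValueError(f"n_components must be in 1..{n_feat}")
    rank = np.linalg.matrix_rank(np.cov(X, rowvar=False))
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds data rank {rank}")

    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()        # features x components
    eigenvalues = pca.explained_variance_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    weighted = eigenvalues[None, :] * loadings**2
    contributions = 100.0 * weighted.sum(axis=1) / eigenvalues.sum()
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
        contributions=pd.Series(contributions, index=FEATURE_COLUMNS),
        eigenvalues=eigenvalues,
    )


def _select_mode(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "two_category":
        sub = table[table["cohort"].isin(["normal", "high_fat"])]
    elif mode == "three_category":
        sub = table
    else:
        raise ValueError("mode must be 'two_category' or 'three_category'")
    counts = sub["cohort"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(f"each cohort needs >= 2 rows; got {counts.to_dict()}")
    return sub


def svm_train_eval(
    table: pd.DataFrame,
    mode: str = "two_category",
    input_space: str = "raw_features",
    split: float = 0.8,
    seed: int = 0,
) -> ClassificationReport:
    """Train and evaluate the Gaussian-kernel SVM on a feature table.

    A stratified, seeded 80/20 (by default) split is drawn; Z-scoring and
    any PCA are fitted on the training split only.  Hyperparameters
    (C in 10^-1..10^3, gamma in 10^-3..10^1) are grid-searched with 5-fold
    cross-validation on the training split; the multiclass scheme is
    one-vs-one.  ``input_space``: 'raw_features', 'all_pcs' or 'first_3_pcs'.
    The overall accuracy runs every row (train and test) through the fitted
    model and is reported separately from the held-out test accuracy.
    """
    if not 0.5 <= split < 1.0:
        raise ValueError("split must be in [0.5, 1)")
    sub = _select_mode(table, mode)
    X = _feature_matrix(sub).to_numpy()
    y = sub["cohort"].to_numpy()
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=split, stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    if len(set(y_te)) < len(set(y)):
        raise ValueError("split left an empty test class; adjust split fraction")

    steps = [("scale", StandardScaler())]
    if input_space == "first_3_pcs":
        steps.append(("pca", PCA(n_components=3)))
    elif input_space == "all_pcs":
        steps.append(("pca", PCA()))
    elif input_space != "raw_features":
        raise ValueError(
            "input_space must be 'raw_features', 'all_pcs' or 'first_3_pcs'"
        )
    steps.append(("svm", SVC(kernel="rbf", decision_function_shape="ovo")))
    n_folds = min(5, int(np.min(np.unique(y_tr, return_counts=True)[1])))
    search = GridSearchCV(
        Pipeline(steps),
        param_grid={
            "svm__C": list(SVM_C_GRID),
            "svm__gamma": list(SVM_GAMMA_GRID),
        },
        cv=n_folds,
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    model = search.best_estimator_
    return ClassificationReport(
        mode=mode,
        input_space=input_space,
        train_accuracy=100.0 * float(model.score(X_tr, y_tr)),
        test_accuracy=100.0 * float(model.score(X_te, y_te)),
        overall_accuracy=100.0 * float(model.score(X, y)),
        seed=seed,
        best_params=dict(search.best_params_),
        classes=tuple(sorted(set(y))),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_counts(n_x: int, n_y: int) -> np.ndarray:
    """Number of rank arrangements per U value (Gaussian-binomial recurrence).

    counts[u] over u = 0..n_x*n_y; total sums to C(n_x+n_y, n_x).
    """
    max_u = n_x * n_y
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # multiply the generating polynomial by (1 - q^(n_y + i)) / (1 - q^i)
    for i in range(1, n_x + 1):
        # divide by (1 - q^i): prefix recurrence
        for u in range(i, max_u + 1):
            counts[u] += counts[u - i]
        # multiply by (1 - q^(n_y + i))
        for u in range(max_u, n_y + i - 1, -1):
            counts[u] -= counts[u - (n_y + i)]
    return counts


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, U = min(U_x, U_y), midrank ties.

    The p-value is exact (full enumeration of the null U distribution) when
    n_x * n_y <= 400 and there are no ties; otherwise a normal approximation
    with tie and continuity corrections is used.  Significance is flagged at
    p < 0.05.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    u_y = n_x * n_y - u_x
    u = min(u_x, u_y)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n_x * n_y <= 400:
        counts = _exact_u_counts(n_x, n_y)
        total = counts.sum()
        p = min(1.0, 2.0 * counts[: int(round(u)) + 1].sum() / total)
        method = "exact"
    else:
        n = n_x + n_y
        mean_u = n_x * n_y / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
        var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (u - mean_u + 0.5) / np.sqrt(var_u)  # continuity correction
            p = min(1.0, 2.0 * norm.cdf(z))
        method = "asymptotic"
    return MannWhitneyResult(u=float(u), p=float(p), significant=p < 0.05, method=method)
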