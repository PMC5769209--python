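"""Feature-table analysis: SVM classification and PCA/t-SNE phenotype scoring.

The supervised route fits a support vector machine on a labelled feature
table (optionally standardized, cross-validated) and reports held-out
per-class true-positive rates.  The unsupervised route reduces the feature
space with PCA — the first principal component serves as a continuous
phenotype score (e.g. a masculinization scale placing intersex worms
between the male and hermaphrodite poles) — optionally followed by t-SNE
for low-dimensional visualisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

_KERNEL_MAP = {"linear": "linear", "rbf": "rbf", "polynomial": "poly"}


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM training options exposed to the user."""

    kernel: str = "linear"
    standardize: bool = True
    cv_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_MAP:
            raise ValueError(f"kernel must be one of {sorted(_KERNEL_MAP)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class SvmResult:
    """Fitted SVM plus its evaluation on the held-out split."""

    model: SVC
    scaler: StandardScaler | None
    features: list[str]
    classes: list
    cv_accuracy: float
    test_accuracy: float
    true_positive_rates: dict
    n_train: int
    n_test: int


@dataclass
class EmbeddingScore:
    """Low-dimensional coordinates of each worm plus method metadata."""

    coordinates: np.ndarray
    method: str
    features: list[str]
    explained_variance: np.ndarray | None = None
    loadings: np.ndarray | None = None
    scaled: bool = True

    @property
    def score(self) -> np.ndarray:
        """First embedding coordinate — the continuous phenotype score."""
        return self.coordinates[:, 0]


def _select_features(
    table: pd.DataFrame, features: list[str], label: str | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    missing_cols = [f for f in features if f not in table.columns]
    if missing_cols:
        raise KeyError(f"feature columns absent from table: {missing_cols}")
    x = table[features].apply(pd.to_numeric, errors="coerce")
    keep = x.notna().all(axis=1)
    if label is not None:
        keep &= table[label].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d rows with missing selected features", dropped)
    y = table.loc[keep, label].to_numpy() if label is not None else None
    return x[keep].to_numpy(dtype=float), y, keep.to_numpy()


def train_svm(
    table: pd.DataFrame,
    label: str,
    features: list[str],
    config: ClassifierConfig | None = None,
) -> SvmResult:
    """Fit a binary SVM on the selected features with CV and a held-out test.

    Rows with any missing selected feature are dropped (logged).  The
    standardizer is fitted on training rows only; test rows never touch the
    scaler or the fit.
    """
    config = config or ClassifierConfig()
    x, y, _ = _select_features(table, features, label)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes.tolist()}")

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=config.test_fraction, random_state=config.seed, stratify=y
    )
    scaler = None
    if config.standardize:
        scaler = StandardScaler().fit(x_tr)
        x_tr = scaler.transform(x_tr)
        x_te = scaler.transform(x_te)

    min_class = int(np.bincount(pd.factorize(y_tr)[0]).min())
    folds = min(config.cv_folds, min_class)
    svm = SVC(kernel=_KERNEL_MAP[config.kernel], random_state=config.seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    cv_acc = float(cross_val_score(svm, x_tr, y_tr, cv=cv).mean())

    svm.fit(x_tr, y_tr)
    pred = svm.predict(x_te)
    tpr = {
        cls: float((pred[y_te == cls] == cls).mean()) if (y_te == cls).any() else math.nan
        for cls in classes
    }
    return SvmResult(
        model=svm,
        scaler=scaler,
        features=list(features),
        classes=classes.tolist(),
        cv_accuracy=cv_acc,
        test_accuracy=float((pred == y_te).mean()),
        true_positive_rates=tpr,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def classify(result: SvmResult, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted SVM to new worms; appends prediction and decision score."""
    out = table.copy()
    if len(table) == 0:
        out["prediction"] = pd.Series(dtype=object)
        out["decision_score"] = pd.Series(dtype=float)
        return out
    x, _, keep = _select_features(table, result.features)
    if result.scaler is not None:
        x = result.scaler.transform(x)
    out["prediction"] = pd.NA
    out["decision_score"] = np.nan
    out.loc[keep, "prediction"] = result.model.predict(x)
    out.loc[keep, "decision_score"] = result.model.decision_function(x)
    return out


def pca_score(
    table: pd.DataFrame,
    features: list[str],
    *,
    scale: bool = True,
    n_components: int | None = None,
) -> EmbeddingScore:
    """Principal-component phenotype scoring of the feature table.

    Optionally unit-variance scales each feature (constant features are
    dropped with a warning); the sign of each component is fixed so its
    first-feature loading is non-negative, making the score direction
    reproducible across runs.
    """
    x, _, _ = _select_features(table, features)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 features")
    kept = list(features)
    if scale:
        stds = x.std(axis=0, ddof=1)
        constant = stds < 1e-12
        if constant.any():
            dropped = [f for f, c in zip(kept, constant) if c]
            logger.warning("dropping constant features under scaling: %s", dropped)
            kept = [f for f, c in zip(kept, constant) if not c]
            x = x[:, ~constant]
        x = StandardScaler().fit_transform(x)
    else:
        x = x - x.mean(axis=0)

    n_components = n_components or min(x.shape)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    loadings = pca.components_
    # Deterministic sign: first-feature loading of each component >= 0.
    signs = np.where(loadings[:, 0] < 0, -1.0, 1.0)
    loadings = loadings * signs[:, None]
    coords = coords * signs[None, :]
    return EmbeddingScore(
        coordinates=coords,
        method="pca",
        features=kept,
        explained_variance=pca.explained_variance_ratio_,
        loadings=loadings,
        scaled=scale,
    )


def tsne_score(
    table: pd.DataFrame,
    features: list[str],
    *,
    perplexity: float = 30.0,
    dims: int = 2,
    seed: int = 0,
    scale: bool = True,
    variance_target: float = 0.95,
    max_pca_components: int = 10,
) -> EmbeddingScore:
    """t-SNE embedding of the feature table with PCA pre-reduction.

    PCA first retains the leading components covering ``variance_target``
    of the variance (at most ``max_pca_components``); t-SNE then embeds to
    ``dims`` in {1, 2, 3} with a fixed seed.  Labels play no role in the
    embedding; they are only for colouring plots afterwards.
    """
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    x, _, _ = _select_features(table, features)
    n = x.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for {n} rows (need > 3x)")
    pre = pca_score(table, features, scale=scale)
    cum = np.cumsum(pre.explained_variance)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, max_pca_components, pre.coordinates.shape[1])
    reduced = pre.coordinates[:, :k]
    tsne = TSNE(
        n_components=dims,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if dims <= reduced.shape[1] else "random",
        method="exact" if dims == 1 or n < 50 else "barnes_hut",
    )
    coords = tsne.fit_transform(reduced)
    return EmbeddingScore(coordinates=coords, method="tsne", features=pre.features, scaled=scale)


def svm_learning_curve(
    table: pd.DataFrame,
    label: str,
    features: list[str],
    *,
    sizes: tuple[int, ...] = (30, 90, 270, 810, 2000),
    n_test_per_class: int = 100,
    n_seeds: int = 10,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> dict[int, float]:
    """Held-out accuracy as a function of training-set size.

    A fixed test set of ``n_test_per_class`` rows per class is drawn first
    and excluded from all training; for each size, ``n_seeds`` random
    training subsets are fitted and evaluated against that same test set.
    Returns the median accuracy per size.
    """
    base = config or ClassifierConfig(cv_folds=2)
    rng = np.random.default_rng(seed)
    classes = table[label].unique()
    test_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero((table[label] == cls).to_numpy())
        test_idx.extend(rng.choice(idx, size=n_test_per_class, replace=False))
    is_test = np.zeros(len(table), dtype=bool)
    is_test[test_idx] = True
    test = table.iloc[is_test.nonzero()[0]]
    pool = table.iloc[(~is_test).nonzero()[0]]

    medians: dict[int, float] = {}
    for size in sizes:
        accs = []
        for k in range(n_seeds):
            sub_rng = np.random.default_rng(rng.integers(2**31))
            sub = pool.iloc[sub_rng.choice(len(pool), size=min(size, len(pool)), replace=False)]
            if sub[label].nunique() < 2:
                continue
            fit = train_svm(
                sub, label, features,
                ClassifierConfig(kernel=base.kernel, standardize=base.standardize,
                                 cv_folds=base.cv_folds, test_fraction=base.test_fraction,
                                 seed=k),
            )
            pred = classify(fit, test)
            accs.append(float((pred["prediction"] == test[label]).mean()))
        medians[size] = float(np.median(accs))
    return medians


def plot_embedding(score: EmbeddingScore, labels=None, path=None):  # pragma: no cover
    """Scatter the first two embedding coordinates, coloured by labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = score.coordinates
    y = coords[:, 1] if coords.shape[1] > 1 else np.zeros(len(coords))
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is not None:
        for lab in pd.unique(np.asarray(labels)):
            sel = np.asarray(labels) == lab
            ax.scatter(coords[sel, 0], y[sel], s=12, label=str(lab), alpha=0.7)
        ax.legend()
    else:
        ax.scatter(coords[:, 0], y, s=12, alpha=0.7)
    ax.set_xlabel(f"{score.method.upper()} 1")
    ax.set_ylabel(f"{score.method.upper()} 2" if coords.shape[1] > 1 else "")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
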