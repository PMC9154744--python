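"""Random-forest classification of real vs control pause loci.

A forest (2500 trees, 20 features per split — mirroring the original
analysis; the legacy ``ncat = 4`` setting is interpreted as the largest
category cardinality kept categorical, which after one-hot encoding of
the four-letter sequence columns is a no-op) is trained on 75% of loci
and evaluated by AUC on the held-out 25%.  The split is stratified by
gene as well as by label: all loci of a gene land on the same side, so
gene-level signal cannot leak between train and test.  Feature
importance is the mean decrease in accuracy over out-of-bag
predictions when a feature column is permuted after training but
before prediction, averaged over trees.  The transfer-of-learning
matrix trains on 100% of one strain's loci and tests on another
strain's loci; diagonal cells report the strain's own 75/25 AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

META_COLUMNS = ("chrom", "position", "strand", "gene_id", "label",
                "edge_flag")


@dataclass
class ClassifierConfig:
    n_trees: int = 2500
    mtry: int = 20
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class EvaluationResult:
    auc: float
    roc: pd.DataFrame  # columns fpr, tpr
    importance: pd.Series | None
    model: RandomForestClassifier
    feature_names: list[str]
    n_train: int
    n_test: int


def encode_features(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """One-hot encode categorical columns; return (X, y) with y = 1 for
    real loci.  Rows with missing values are median/mode imputed."""
    if set(table["label"].unique()) != {"real", "control"}:
        raise ValueError("table must contain both real and control loci")
    y = (table["label"] == "real").to_numpy(dtype=int)
    X = table.drop(columns=[c for c in META_COLUMNS if c in table.columns])
    cat = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    X = pd.get_dummies(X, columns=cat, dtype=float)
    X = X.fillna(X.median(numeric_only=True))
    return X, y


def _gene_stratified_split(genes: pd.Series, train_fraction: float,
                           rng: np.random.Generator,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole genes to train/test, targeting train_fraction rows."""
    counts = genes.value_counts()
    order = rng.permutation(counts.index.to_numpy())
    target = train_fraction * len(genes)
    train_genes, total = set(), 0
    for gid in order:
        if total < target:
            train_genes.add(gid)
            total += counts[gid]
    in_train = genes.isin(train_genes).to_numpy()
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


def train_and_evaluate(table: pd.DataFrame, config: ClassifierConfig,
                       compute_importance: bool = False,
                       ) -> EvaluationResult:
    """75/25 gene-stratified split, forest fit, held-out AUC."""
    X, y = encode_features(table)
    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = _gene_stratified_split(
        table["gene_id"], config.train_fraction, rng)
    if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
        raise ValueError("train/test split lost a class")
    model = _fit_forest(X.iloc[train_idx], y[train_idx], config)
    prob = model.predict_proba(X.iloc[test_idx].to_numpy())[:, 1]
    auc = float(roc_auc_score(y[test_idx], prob))
    fpr, tpr, _ = roc_curve(y[test_idx], prob)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    importance = permutation_importance(model, X.iloc[train_idx],
                                        y[train_idx]) \
        if compute_importance else None
    return EvaluationResult(auc=auc, roc=roc, importance=importance,
                            model=model, feature_names=list(X.columns),
                            n_train=len(train_idx), n_test=len(test_idx))


def _fit_forest(X: pd.DataFrame, y: np.ndarray,
                config: ClassifierConfig) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.mtry, X.shape[1]),
        random_state=int(config.seed) % (2 ** 31),
        oob_score=False, n_jobs=1)
    model.fit(X.to_numpy(), y)
    return model


def permutation_importance(model: RandomForestClassifier, X: pd.DataFrame,
                           y: np.ndarray, seed: int = 0) -> pd.Series:
    """Mean decrease in accuracy on out-of-bag samples when one feature
    is permuted, averaged over trees."""
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)

    rng = np.random.default_rng(seed)
    Xv = X.to_numpy()
    n = Xv.shape[0]
    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    drops = np.zeros((len(model.estimators_), Xv.shape[1]))
    for t, tree in enumerate(model.estimators_):
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot,
                                          None)
        if oob.size == 0:
            continue
        X_oob = Xv[oob]
        y_oob = y[oob]
        base = (tree.predict(X_oob) == y_oob).mean()
        for j in range(Xv.shape[1]):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            drops[t, j] = base - (tree.predict(Xp) == y_oob).mean()
    return pd.Series(drops.mean(axis=0), index=X.columns,
                     name="mean_decrease_accuracy")


def transfer_matrix(tables: dict[str, pd.DataFrame],
                    config: ClassifierConfig) -> pd.DataFrame:
    """Strain x strain AUC matrix: off-diagonal cells train on 100% of
    the row strain and test on the column strain; diagonal cells are
    the row strain's own 75/25 evaluation."""
    strains = sorted(tables)
    encoded = {s: encode_features(tables[s]) for s in strains}
    cols0 = list(encoded[strains[0]][0].columns)
    for s in strains[1:]:
        cols = list(encoded[s][0].columns)
        if cols != cols0:
            bad = set(cols) ^ set(cols0)
            raise ValueError(f"feature columns differ across strains: "
                             f"{sorted(bad)}")
    mat = pd.DataFrame(np.nan, index=strains, columns=strains)
    for a in strains:
        Xa, ya = encoded[a]
        full = _fit_forest(Xa, ya, config)
        for b in strains:
            if a == b:
                mat.loc[a, b] = train_and_evaluate(tables[a], config).auc
            else:
                Xb, yb = encoded[b]
                prob = full.predict_proba(Xb.to_numpy())[:, 1]
                mat.loc[a, b] = float(roc_auc_score(yb, prob))
    return mat
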