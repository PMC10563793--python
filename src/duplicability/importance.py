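"""Age-controlled duplicate-type classifier protocol.

The protocol repeatedly (default 100 iterations) splits the gene set 80/20,
fits a balanced-class-weight random forest on the training split, records
held-out accuracy, and measures permutation importance on the held-out
split (the drop in accuracy on randomly permuting one feature at a time
relative to the unpermuted baseline).  Importances, ranks and accuracies
are aggregated across iterations; the age-controlled variant runs the same
protocol on residuals of each feature regressed on duplicate age.

Also provided: randomized hyperparameter search (10-fold CV maximising F1),
a feature-dependence matrix (each feature predicted from the others), and
the correlated-feature isolation analysis in which each member of a
correlated group is re-run with the other members dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, make_scorer
from sklearn.model_selection import KFold, RandomizedSearchCV, train_test_split


def _held_out_permutation_importance(
    forest,
    X_te: pd.DataFrame,
    y_te: np.ndarray,
    base_accuracy: float,
    rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accuracy drop per feature on permuting it in the held-out split.

    All feature x round permutations are stacked into a single prediction
    call, which is substantially faster than one model call per permutation
    while computing the identical quantity.
    """
    X_arr = X_te.to_numpy()
    n, p = X_arr.shape
    blocks = []
    for j in range(p):
        for _ in range(rounds):
            Xp = X_arr.copy()
            Xp[:, j] = X_arr[rng.permutation(n), j]
            blocks.append(Xp)
    stacked = pd.DataFrame(np.vstack(blocks), columns=X_te.columns)
    preds = forest.predict(stacked).reshape(p, rounds, n)
    acc = (preds == np.asarray(y_te)).mean(axis=2)  # (p, rounds)
    return base_accuracy - acc.mean(axis=1)

from .stats import residualize_features

_SEED_MAX = 2**31 - 1

#: Search space for the randomized hyperparameter search; the searched
#: names follow the usual forest grid.
DEFAULT_PARAM_DISTRIBUTIONS: dict[str, list] = {
    "n_estimators": [25, 39, 50, 100, 200],
    "max_features": ["sqrt", "log2", None],
    "max_depth": [None, 5, 10, 20],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "bootstrap": [True, False],
}


@dataclass
class ClassifierProtocolConfig:
    """Protocol settings for the repeated train/test importance estimation."""

    n_iterations: int = 100
    test_fraction: float = 0.2
    n_trees: int = 39
    max_features: str | int | None = "sqrt"
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    bootstrap: bool = True
    class_weight: str = "balanced"
    cv_folds: int = 10
    n_search_iter: int = 20
    n_permutation_rounds: int = 1
    scale: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")

    def forest_params(self) -> dict:
        return dict(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
        )


@dataclass
class ImportanceReport:
    """Aggregated output of the repeated-fit importance protocol."""

    importances: pd.DataFrame  # feature, mean_importance, sd_importance, mean_rank
    accuracies: np.ndarray
    accuracy_mean: float
    accuracy_ci: tuple[float, float]
    confusion_counts: pd.DataFrame
    confusion_precision: pd.DataFrame
    confusion_recall: pd.DataFrame
    feature_names: list[str]
    age_controlled: bool
    config: ClassifierProtocolConfig = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            ("Age-controlled " if self.age_controlled else "")
            + f"duplicate-type classifier protocol ({len(self.accuracies)} iterations)",
            f"  mean accuracy: {self.accuracy_mean:.4f} "
            f"(95% CI: {self.accuracy_ci[0]:.4f}-{self.accuracy_ci[1]:.4f})",
            "  feature importances (mean permutation importance, held-out):",
        ]
        for _, row in self.importances.iterrows():
            lines.append(
                f"    {row['feature']:28s} {row['mean_importance']:+.4f} "
                f"(sd {row['sd_importance']:.4f}, mean rank {row['mean_rank']:.1f})"
            )
        return "\n".join(lines)

    def plot_importances(self, ax=None):
        """Horizontal bar chart of mean importances with 1-sd error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(self.importances) + 1))
        imp = self.importances.iloc[::-1]
        ax.barh(imp["feature"], imp["mean_importance"], xerr=imp["sd_importance"])
        ax.set_xlabel("mean permutation importance")
        return ax


def _prepare(X: pd.DataFrame, y: pd.Series, on_missing: str = "error"):
    y = y.reindex(X.index)
    incomplete = X.index[X.isna().any(axis=1) | y.isna()]
    if len(incomplete):
        if on_missing == "drop":
            X = X.drop(index=incomplete)
            y = y.drop(index=incomplete)
        else:
            raise ValueError(
                f"{len(incomplete)} genes have missing feature/label values "
                f"(e.g. {list(incomplete[:5])}); pass on_missing='drop' to exclude them"
            )
    if y.nunique() < 2:
        raise ValueError("need at least two classes")
    return X, y


def _maybe_scale(X: pd.DataFrame, config: ClassifierProtocolConfig) -> pd.DataFrame:
    if not config.scale:
        return X
    return (X - X.mean()) / X.std(ddof=0)


def run_protocol(
    X: pd.DataFrame,
    y: pd.Series,
    config: ClassifierProtocolConfig | None = None,
    on_missing: str = "error",
    age_controlled: bool = False,
) -> ImportanceReport:
    """Repeated 80/20 random-forest fits with held-out permutation importance.

    Splits are simple random (not stratified); class imbalance is handled by
    balanced class weights.  Deterministic for a fixed ``config.seed``.
    """
    config = config or ClassifierProtocolConfig()
    X, y = _prepare(X, y, on_missing)
    X = _maybe_scale(X, config)
    feature_names = list(X.columns)
    classes = sorted(y.unique())
    rng = np.random.default_rng(config.seed)

    imps = np.empty((config.n_iterations, len(feature_names)))
    ranks = np.empty_like(imps)
    accs = np.empty(config.n_iterations)
    conf = np.zeros((len(classes), len(classes)), dtype=float)

    for it in range(config.n_iterations):
        it_seed = int(rng.integers(_SEED_MAX))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=config.test_fraction, random_state=it_seed
        )
        forest = RandomForestClassifier(
            class_weight=config.class_weight,
            random_state=it_seed,
            **config.forest_params(),
        ).fit(X_tr, y_tr)
        y_hat = forest.predict(X_te)
        accs[it] = accuracy_score(y_te, y_hat)
        conf += confusion_matrix(y_te, y_hat, labels=classes)
        imps[it] = _held_out_permutation_importance(
            forest,
            X_te,
            y_te.to_numpy(),
            accs[it],
            config.n_permutation_rounds,
            np.random.default_rng(it_seed),
        )
        ranks[it] = sps.rankdata(-imps[it])

    mean_imp = imps.mean(axis=0)
    importances = (
        pd.DataFrame(
            {
                "feature": feature_names,
                "mean_importance": mean_imp,
                "sd_importance": imps.std(axis=0, ddof=1) if config.n_iterations > 1 else 0.0,
                "mean_rank": ranks.mean(axis=0),
            }
        )
        .sort_values("mean_importance", ascending=False)
        .reset_index(drop=True)
    )
    acc_mean = float(accs.mean())
    if config.n_iterations > 1:
        half = 1.96 * accs.std(ddof=1) / np.sqrt(config.n_iterations)
    else:
        half = float("nan")
    conf_df = pd.DataFrame(conf, index=classes, columns=classes)
    with np.errstate(invalid="ignore"):
        precision = conf_df / conf_df.sum(axis=0)
        recall = conf_df.div(conf_df.sum(axis=1), axis=0)
    return ImportanceReport(
        importances=importances,
        accuracies=accs,
        accuracy_mean=acc_mean,
        accuracy_ci=(acc_mean - half, acc_mean + half),
        confusion_counts=conf_df,
        confusion_precision=precision,
        confusion_recall=recall,
        feature_names=feature_names,
        age_controlled=age_controlled,
        config=config,
    )


def run_age_controlled_protocol(
    X: pd.DataFrame,
    ages: pd.Series,
    y: pd.Series,
    config: ClassifierProtocolConfig | None = None,
    on_missing: str = "error",
) -> ImportanceReport:
    """The same protocol on residuals of each feature regressed on age."""
    X, y = _prepare(X, y, on_missing)
    ages = pd.Series(ages).reindex(X.index)
    if ages.isna().any():
        missing = sorted(X.index[ages.isna()])
        raise ValueError(f"ages missing for genes: {missing[:10]}")
    X_resid = residualize_features(X, ages)
    return run_protocol(X_resid, y, config=config, age_controlled=True)


class DuplicateTypeClassifier:
    """Model object wrapping the repeated-fit importance protocol.

    Built from a complete-case feature table and duplicate-type labels;
    ``fit`` runs the protocol (age-controlled when ``ages`` were supplied
    and ``age_control`` is left on) and returns an :class:`ImportanceReport`.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        ages: pd.Series | None = None,
        config: ClassifierProtocolConfig | None = None,
        on_missing: str = "error",
    ):
        self.X = X
        self.y = y
        self.ages = ages
        self.config = config or ClassifierProtocolConfig()
        self.on_missing = on_missing

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: list[str],
        label_col: str = "label",
        age_col: str | None = None,
        **kwargs,
    ) -> "DuplicateTypeClassifier":
        ages = df[age_col] if age_col else None
        return cls(df[feature_cols], df[label_col], ages=ages, **kwargs)

    def tune(self, param_distributions: dict | None = None) -> ClassifierProtocolConfig:
        self.config = tune_hyperparameters(
            self.X, self.y, self.config, param_distributions=param_distributions
        )
        return self.config

    def fit(self, age_control: bool | None = None) -> ImportanceReport:
        if age_control is None:
            age_control = self.ages is not None
        if age_control:
            if self.ages is None:
                raise ValueError("age control requested but no ages supplied")
            return run_age_controlled_protocol(
                self.X, self.ages, self.y, config=self.config, on_missing=self.on_missing
            )
        return run_protocol(self.X, self.y, config=self.config, on_missing=self.on_missing)


def tune_hyperparameters(
    X: pd.DataFrame,
    y: pd.Series,
    config: ClassifierProtocolConfig | None = None,
    param_distributions: dict | None = None,
    pos_label: str | None = None,
) -> ClassifierProtocolConfig:
    """Randomized hyperparameter search, 10-fold CV, maximising F1.

    The positive label for F1 defaults to the minority class.  Returns a new
    config carrying the best forest hyperparameters; deterministic given
    ``config.seed``.
    """
    config = config or ClassifierProtocolConfig()
    X, y = _prepare(X, y)
    if param_distributions is None:
        param_distributions = DEFAULT_PARAM_DISTRIBUTIONS
    if pos_label is None:
        pos_label = y.value_counts().idxmin()
    scorer = make_scorer(f1_score, pos_label=pos_label)
    n_candidates = int(np.prod([len(v) for v in param_distributions.values()]))
    search = RandomizedSearchCV(
        RandomForestClassifier(class_weight=config.class_weight, random_state=config.seed),
        param_distributions,
        n_iter=min(config.n_search_iter, n_candidates),
        cv=KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed),
        scoring=scorer,
        random_state=config.seed,
    ).fit(X, y)
    best = search.best_params_
    return replace(
        config,
        n_trees=best.get("n_estimators", config.n_trees),
        max_features=best.get("max_features", config.max_features),
        max_depth=best.get("max_depth", config.max_depth),
        min_samples_split=best.get("min_samples_split", config.min_samples_split),
        min_samples_leaf=best.get("min_samples_leaf", config.min_samples_leaf),
        bootstrap=best.get("bootstrap", config.bootstrap),
    )


def dependence_matrix(
    X: pd.DataFrame,
    config: ClassifierProtocolConfig | None = None,
) -> pd.DataFrame:
    """How well each feature is predicted by all the others.

    For each feature a random-forest regressor is fitted with that feature
    as target and the rest as predictors on an 80/20 split; the
    ``dependence`` column holds the held-out R^2 and the remaining columns
    the per-predictor permutation importances, all clipped to [0, 1].  The
    diagonal is undefined (NaN).
    """
    config = config or ClassifierProtocolConfig()
    if X.shape[1] < 3:
        raise ValueError("dependence matrix requires at least 3 features")
    rng = np.random.default_rng(config.seed)
    feature_names = list(X.columns)
    out = pd.DataFrame(np.nan, index=feature_names, columns=["dependence"] + feature_names)
    for feat in feature_names:
        seed = int(rng.integers(_SEED_MAX))
        others = [f for f in feature_names if f != feat]
        X_tr, X_te, y_tr, y_te = train_test_split(
            X[others], X[feat], test_size=config.test_fraction, random_state=seed
        )
        forest = RandomForestRegressor(random_state=seed, **config.forest_params()).fit(
            X_tr, y_tr
        )
        out.loc[feat, "dependence"] = np.clip(forest.score(X_te, y_te), 0.0, 1.0)
        perm = permutation_importance(
            forest,
            X_te,
            y_te,
            scoring="r2",
            n_repeats=config.n_permutation_rounds,
            random_state=seed,
        )
        out.loc[feat, others] = np.clip(perm.importances_mean, 0.0, 1.0)
    return out


def isolation_analysis(
    X: pd.DataFrame,
    y: pd.Series,
    config: ClassifierProtocolConfig | None = None,
    groups: dict[str, list[str]] | None = None,
    baseline: ImportanceReport | None = None,
) -> pd.DataFrame:
    """Re-rank each correlated feature with its group-mates dropped.

    For every feature in every (disjoint) group, the full protocol is rerun
    with the *other* group members removed so the feature's importance is no
    longer diluted by correlated companions.  The previous rank comes from
    the all-feature protocol's ranked mean importances; the new rank is the
    insertion position of the isolated mean importance into that ranked
    list.  Mean accuracies with and without the group-mates are reported.
    """
    config = config or ClassifierProtocolConfig()
    if groups is None:
        raise ValueError("isolation_analysis requires feature groups")
    flat = [f for members in groups.values() for f in members]
    if len(flat) != len(set(flat)):
        raise ValueError("isolation groups must be disjoint")
    missing = sorted(set(flat) - set(X.columns))
    if missing:
        raise ValueError(f"group features absent from feature table: {missing}")

    if baseline is None:
        baseline = run_protocol(X, y, config=config)
    prev_imp = baseline.importances.set_index("feature")["mean_importance"]
    prev_rank = {f: i + 1 for i, f in enumerate(baseline.importances["feature"])}

    rows = []
    for group_name, members in groups.items():
        for feat in members:
            dropped = [m for m in members if m != feat]
            reduced = X.drop(columns=dropped)
            report = run_protocol(reduced, y, config=config)
            new_imp = float(
                report.importances.set_index("feature").loc[feat, "mean_importance"]
            )
            others = prev_imp.drop(index=feat)
            new_rank = int((others > new_imp).sum()) + 1
            rows.append(
                {
                    "group": group_name,
                    "feature": feat,
                    "previous_rank": prev_rank[feat],
                    "new_rank": new_rank,
                    "previous_importance": float(prev_imp[feat]),
                    "isolated_importance": new_imp,
                    "previous_accuracy": baseline.accuracy_mean,
                    "new_accuracy": report.accuracy_mean,
                }
            )
    return pd.DataFrame(rows)
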