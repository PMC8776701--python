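"""Radiation-pneumonitis prediction protocol and nonparametric statistics.

The model-development protocol: repeated stratified 70/30 train/test
splits; per-split Z-scoring fit on the training partition only; an
RBF-kernel support vector machine whose hyperparameters (C, gamma) are
chosen by Bayesian optimization of the mean stratified 5-fold inner-CV
AUC; rank-based AUC evaluation of the decision-function scores on both
partitions.  Four nested candidate feature sets are compared pairwise with
the paired Wilcoxon signed-rank test, individual features are screened
with the Mann-Whitney U test, and feature redundancy is summarized with
Spearman correlation matrices.

Within one repeat every feature set sees the identical train/test
partition (paired design), so set comparisons are paired by repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import bayesopt
from .dosimetry import CLINICAL_FEATURES, DFH_FEATURES, DVH_FEATURES

LABEL_COLUMN = "rp"

#: The four nested candidate feature sets.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "clinical": CLINICAL_FEATURES,
    "clinical+dvh": CLINICAL_FEATURES + DVH_FEATURES,
    "clinical+dfh": CLINICAL_FEATURES + DFH_FEATURES,
    "clinical+dvh+dfh": CLINICAL_FEATURES + DVH_FEATURES + DFH_FEATURES,
}


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified split protocol and hyperparameter search settings."""

    train_fraction: float = 0.7
    n_repeats: int = 50
    inner_folds: int = 5
    seed: int = 0
    bo_calls: int = 30
    bo_initial: int = 10
    log10_c_bounds: tuple[float, float] = (-3.0, 3.0)
    log10_gamma_bounds: tuple[float, float] = (-4.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.n_repeats < 1 or self.inner_folds < 2 or self.bo_calls < 1:
            raise ValueError("invalid split scheme sizes")


@dataclass
class ModelRun:
    repeat: int
    feature_set: str
    C: float
    gamma: float
    train_auc: float
    test_auc: float
    inner_cv_auc: float


@dataclass
class ExperimentResult:
    runs: dict[str, list[ModelRun]] = dataclass_field(default_factory=dict)

    def test_aucs(self, feature_set: str) -> np.ndarray:
        return np.array([r.test_auc for r in self.runs[feature_set]])

    def train_aucs(self, feature_set: str) -> np.ndarray:
        return np.array([r.train_auc for r in self.runs[feature_set]])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": r.repeat, "feature_set": r.feature_set, "C": r.C,
             "gamma": r.gamma, "train_auc": r.train_auc, "test_auc": r.test_auc,
             "inner_cv_auc": r.inner_cv_auc}
            for runs in self.runs.values() for r in runs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Median, IQR, mean, and two 95% CI constructions per feature set.

        The percentile CI is the empirical 2.5-97.5% range of the repeat
        AUCs; the normal-theory CI is mean +- 1.96 SE.  Both are reported
        because AUC dispersion across repeated splits has no canonical
        interval.
        """
        rows = []
        for name, runs in self.runs.items():
            for part, aucs in (("train", self.train_aucs(name)), ("test", self.test_aucs(name))):
                q1, q3 = np.percentile(aucs, [25, 75])
                lo_p, hi_p = np.percentile(aucs, [2.5, 97.5])
                se = aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0
                rows.append({
                    "feature_set": name, "partition": part, "n_models": len(aucs),
                    "median_auc": float(np.median(aucs)), "iqr": float(q3 - q1),
                    "mean_auc": float(aucs.mean()),
                    "ci95_percentile_lo": float(lo_p), "ci95_percentile_hi": float(hi_p),
                    "ci95_normal_lo": float(aucs.mean() - 1.96 * se),
                    "ci95_normal_hi": float(aucs.mean() + 1.96 * se),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardization and splits


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame, columns: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Z-score features using training-partition statistics only.

    Per-feature mean and population SD (denominator N) are estimated on the
    training partition and applied to both.  Features constant on the
    training partition are dropped from both with a warning.
    """
    if columns is None:
        columns = [c for c in train.columns if c not in ("patient_id", LABEL_COLUMN)]
    kept, dropped = [], []
    for c in columns:
        if train[c].to_numpy(dtype=float).std() > 0:
            kept.append(c)
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropping constant training features: {dropped}", stacklevel=2)
    if not kept:
        raise ValueError("all features are constant on the training partition")
    mu = train[kept].to_numpy(dtype=float).mean(axis=0)
    sd = train[kept].to_numpy(dtype=float).std(axis=0)  # population SD
    params = {"columns": kept, "mean": mu, "sd": sd, "dropped": dropped}
    xtr = (train[kept].to_numpy(dtype=float) - mu) / sd
    xte = (test[kept].to_numpy(dtype=float) - mu) / sd
    return xtr, xte, params


def stratified_split(
    table: pd.DataFrame, scheme: SplitScheme, repeat: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified train/test split, deterministic in (scheme.seed, repeat).

    Sampling is per class without replacement; the per-class training count
    is round(train_fraction * class size).  Both partitions must retain
    both classes.
    """
    labels = table[LABEL_COLUMN].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, repeat]))
    train_idx, test_idx = [], []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = int(round(scheme.train_fraction * len(members)))
        if n_train < 1 or n_train >= len(members):
            raise ValueError(
                f"train fraction {scheme.train_fraction} leaves class {cls} empty "
                "in one partition"
            )
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return table.iloc[sorted(train_idx)], table.iloc[sorted(test_idx)]


# ---------------------------------------------------------------------------
# AUC and SVM tuning


def auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays of k stratified folds; every fold keeps both classes."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        members = rng.permutation(np.flatnonzero(labels == cls))
        if len(members) < k:
            raise ValueError(f"class {cls} has fewer members ({len(members)}) than folds ({k})")
        for i, idx in enumerate(members):
            folds[i % k].append(int(idx))
    return [np.sort(np.array(f)) for f in folds]


def tune_svm(
    X: np.ndarray, y: np.ndarray, scheme: SplitScheme,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, bayesopt.BayesOptResult]:
    """Choose (C, gamma) maximizing mean stratified inner-CV AUC.

    The search is Bayesian optimization over the log-uniform box
    C in 10^[log10_c_bounds], gamma in 10^[log10_gamma_bounds] with a fixed
    evaluation budget.  Returns the optimum and the full optimization trace.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y)
    folds = _stratified_folds(y, scheme.inner_folds, rng)

    def objective(params: np.ndarray) -> float:
        C, gamma = 10.0 ** params[0], 10.0 ** params[1]
        scores = []
        for i, test_f in enumerate(folds):
            train_f = np.concatenate([f for j, f in enumerate(folds) if j != i])
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(X[train_f], y[train_f])
            s = clf.decision_function(X[test_f])
            scores.append(auc(s, y[test_f]))
        return float(np.mean(scores))

    bounds = np.array([scheme.log10_c_bounds, scheme.log10_gamma_bounds])
    result = bayesopt.maximize(
        objective, bounds, n_calls=scheme.bo_calls, n_initial=scheme.bo_initial, rng=rng
    )
    C, gamma = 10.0 ** result.best_x[0], 10.0 ** result.best_x[1]
    return float(C), float(gamma), result


# ---------------------------------------------------------------------------
# The experiment


def _check_nested(feature_sets: dict[str, tuple[str, ...]]) -> None:
    names = list(FEATURE_SETS)
    if set(feature_sets) == set(names):
        base = set(feature_sets[names[0]])
        full = set(feature_sets[names[3]])
        for mid in names[1:3]:
            s = set(feature_sets[mid])
            if not (base <= s <= full):
                warnings.warn(f"feature set {mid!r} is not nested between "
                              f"{names[0]!r} and {names[3]!r}", stacklevel=3)


def run_experiment(
    table: pd.DataFrame,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    scheme: SplitScheme | None = None,
) -> ExperimentResult:
    """Run the full repeated-split protocol over the candidate feature sets.

    Per repeat: one stratified split shared by all feature sets; per set:
    Z-score on the training partition, Bayesian-optimize (C, gamma) by
    inner CV, refit on the whole training partition, record train and test
    AUC of the decision-function scores.
    """
    feature_sets = dict(FEATURE_SETS) if feature_sets is None else dict(feature_sets)
    scheme = SplitScheme() if scheme is None else scheme
    _check_nested(feature_sets)
    missing = {c for cols in feature_sets.values() for c in cols} - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    result = ExperimentResult(runs={name: [] for name in feature_sets})
    for repeat in range(scheme.n_repeats):
        train, test = stratified_split(table, scheme, repeat)
        y_train = train[LABEL_COLUMN].to_numpy()
        y_test = test[LABEL_COLUMN].to_numpy()
        for k, (name, cols) in enumerate(feature_sets.items()):
            rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, repeat, 1, k]))
            xtr, xte, _ = zscore_fit_apply(train, test, list(cols))
            try:
                C, gamma, trace = tune_svm(xtr, y_train, scheme, rng)
            except ValueError as err:
                raise RuntimeError(f"repeat {repeat}, set {name!r}: {err}") from err
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(xtr, y_train)
            result.runs[name].append(ModelRun(
                repeat=repeat, feature_set=name, C=C, gamma=gamma,
                train_auc=auc(clf.decision_function(xtr), y_train),
                test_auc=auc(clf.decision_function(xte), y_test),
                inner_cv_auc=trace.best_value,
            ))
    return result


# ---------------------------------------------------------------------------
# Nonparametric statistics


def compare_feature_sets(a: list[ModelRun] | np.ndarray, b: list[ModelRun] | np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on test AUCs.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero pairs, the tie-corrected normal approximation beyond.
    """
    def _aucs(x):
        if len(x) and isinstance(x[0], ModelRun):
            return np.asarray([r.test_auc for r in x], dtype=float)
        return np.asarray(x, dtype=float)

    xa, xb = _aucs(a), _aucs(b)
    if xa.shape != xb.shape:
        raise ValueError("paired comparison requires equal-length run lists")
    d = xa - xb
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    return float(stats.wilcoxon(d, alternative="two-sided", method=method).pvalue)


def univariate_screen(table: pd.DataFrame, columns: list[str] | None = None) -> pd.Series:
    """Per-feature two-sided Mann-Whitney U p-values, positive vs negative class.

    Exact null for combined n <= 20, tie-corrected normal approximation
    otherwise.
    """
    labels = table[LABEL_COLUMN].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if columns is None:
        columns = [c for c in table.columns if c not in ("patient_id", LABEL_COLUMN)]
    out = {}
    for c in columns:
        x = table.loc[labels == 1, c].to_numpy(dtype=float)
        y = table.loc[labels == 0, c].to_numpy(dtype=float)
        n = len(x) + len(y)
        method = "exact" if n <= 20 else "asymptotic"
        out[c] = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return pd.Series(out, name="p_value")


def correlation_matrix(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Tie-corrected Spearman rank correlation matrix of the named columns."""
    if len(table) < 3:
        raise ValueError("Spearman correlation needs at least 3 patients")
    data = table[list(columns)].to_numpy(dtype=float)
    constant = [c for c, col in zip(columns, data.T) if np.unique(col).size == 1]
    if constant:
        warnings.warn(f"constant columns give undefined correlations: {constant}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=list(columns), columns=list(columns))
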