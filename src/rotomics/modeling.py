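"""Train-on-original / test-on-rotated repeated cross-validation.

Three-phase pipeline per feature partition (wavelet-only ``WD`` vs everything
else ``nWD``): (i) preliminary filtering on all samples (zero-variance and
near-duplicate removal), (ii) per-fold fine selection (train-only:
standardize, Kruskal-Wallis ranking, L1-multinomial shrinkage), (iii) five
classifiers fit on R0 training folds and evaluated on R0..R80 test-fold
features.  Default protocol: 50 repeats x 5 stratified folds = 250 train-test
cycles per classifier x partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stability import effect_stratum

__all__ = [
    "PipelineConfig",
    "CLASSIFIER_NAMES",
    "wide_tables",
    "partition_columns",
    "prelim_filter",
    "fine_select",
    "train_classifiers",
    "evaluate_rotated",
    "run_repeated_cv",
    "performance_trend",
    "macro_metrics",
]

CLASSIFIER_NAMES = ("KNN", "logistic", "random_forest", "svm_linear", "svm_rbf")


@dataclass
class PipelineConfig:
    n_repeats: int = 50
    n_folds: int = 5
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    partitions: tuple[str, ...] = ("WD", "nWD")
    max_features: int = 30
    kw_top_k: int = 60
    corr_threshold: float = 0.95
    include_shape: bool = True  # shape features ride in the nWD partition
    seed: int = 0


def _make_classifier(name: str, seed: int):
    # fixed, documented hyperparameters
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "svm_linear":
        return SVC(kernel="linear", random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", gamma="scale", random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def wide_tables(df: pd.DataFrame) -> tuple[dict[int, pd.DataFrame], pd.Series]:
    """Long feature table -> {rotation_label: patients x features} + labels.

    Feature columns are ``channel|category|feature`` strings, identically
    ordered in every table.
    """
    df = df.copy()
    df["key"] = df["channel"] + "|" + df["category"] + "|" + df["feature"]
    tables = {}
    for label, sub in df.groupby("rotation_label"):
        tables[int(label)] = sub.pivot(index="patient_id", columns="key",
                                       values="value").sort_index()
    cols = tables[min(tables)].columns
    tables = {k: t[cols] for k, t in tables.items()}
    labels = (df.drop_duplicates("patient_id").set_index("patient_id")["class_label"]
              .sort_index().astype(int))
    return tables, labels


def partition_columns(columns, partition: str, include_shape: bool = True) -> list[str]:
    """WD = wavelet channels; nWD = all other channels (+ shape if enabled)."""
    out = []
    for col in columns:
        channel = col.split("|", 1)[0]
        is_wd = channel.startswith("wavelet-")
        is_shape = channel == "shape"
        if partition == "WD" and is_wd:
            out.append(col)
        elif partition == "nWD" and not is_wd and (include_shape or not is_shape):
            out.append(col)
    if not out:
        raise ValueError(f"partition {partition!r} selected no features")
    return out


def prelim_filter(r0: pd.DataFrame, partition: str,
                  corr_threshold: float = 0.95,
                  include_shape: bool = True) -> list[str]:
    """All-samples preliminary filter: restrict to the partition, drop
    zero-variance columns, then one of each |Spearman rho| > threshold pair
    (keep-first in stable column order)."""
    cols = partition_columns(r0.columns, partition, include_shape)
    x = r0[cols].to_numpy()
    keep_var = x.std(axis=0) > 0
    cols = [c for c, k in zip(cols, keep_var) if k]
    if not cols:
        raise ValueError("no features survive the variance filter")
    ranks = stats.rankdata(r0[cols].to_numpy(), axis=0)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    keep: list[int] = []
    for j in range(len(cols)):
        if all(abs(rho[j, k]) <= corr_threshold for k in keep):
            keep.append(j)
    return [cols[j] for j in keep]


def _kruskal_pvals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    pvals = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        groups = [x[y == c, j] for c in classes]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = stats.kruskal(*groups)
            pvals[j] = p if np.isfinite(p) else 1.0
        except ValueError:  # all values identical
            pvals[j] = 1.0
    return pvals


def fine_select(train_x: pd.DataFrame, train_y: np.ndarray,
                max_features: int = 30, kw_top_k: int = 60,
                seed: int = 0) -> list[str]:
    """Train-fold-only fine selection.

    Standardize on the training fold, rank features by Kruskal-Wallis p-value
    across the classes, keep the top ``kw_top_k``, then shrink with an
    L1-penalized one-vs-rest logistic model and keep at most ``max_features``
    columns by coefficient magnitude.  Deterministic given the seed.
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("fine selection needs >= 2 classes in the training fold")
    scaler = StandardScaler().fit(train_x)
    xs = scaler.transform(train_x)
    pvals = _kruskal_pvals(xs, np.asarray(train_y))
    order = np.argsort(pvals, kind="stable")[:kw_top_k]
    cand = [train_x.columns[j] for j in order]
    xs_cand = xs[:, order]
    lasso = LogisticRegression(penalty="elasticnet", l1_ratio=1.0, solver="saga",
                               C=1.0, random_state=seed, max_iter=2000, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        lasso.fit(xs_cand, train_y)
    weight = np.abs(lasso.coef_).max(axis=0)
    nz = np.flatnonzero(weight > 0)
    if nz.size == 0:  # degenerate fit: fall back to the best KW features
        nz = np.arange(min(max_features, len(cand)))
    ranked = nz[np.argsort(weight[nz], kind="stable")[::-1]][:max_features]
    return [cand[j] for j in sorted(ranked)]


def train_classifiers(train_x: pd.DataFrame, train_y: np.ndarray,
                      classifiers=CLASSIFIER_NAMES, seed: int = 0):
    """Fit the classifier bundle on standardized selected features.

    Returns (scaler, {name: fitted model}); the scaler must be reused on all
    test data.
    """
    scaler = StandardScaler().fit(train_x)
    xs = scaler.transform(train_x)
    bundle = {}
    for name in classifiers:
        model = _make_classifier(name, seed)
        model.fit(xs, train_y)
        bundle[name] = model
    return scaler, bundle


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  classes: np.ndarray) -> dict[str, float]:
    """Accuracy + one-vs-rest macro F1 / sensitivity / specificity."""
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "macro_f1": float(f1_score(y_true, y_pred, labels=classes,
                                   average="macro", zero_division=0)),
        "macro_sensitivity": float(sens.mean()),
        "macro_specificity": float(spec.mean()),
    }


def evaluate_rotated(bundle, scaler, selected: list[str],
                     tables: dict[int, pd.DataFrame], labels: pd.Series,
                     test_ids, classes: np.ndarray,
                     base: dict | None = None) -> list[dict]:
    """One cycle's records: every classifier x every rotation label."""
    base = base or {}
    records = []
    for rot_label, table in sorted(tables.items()):
        avail = [pid for pid in test_ids if pid in table.index]
        if len(avail) < len(test_ids):
            warnings.warn(f"R{rot_label}: {len(test_ids) - len(avail)} test patients "
                          "missing, dropped from this label", stacklevel=2)
        xt = scaler.transform(table.loc[avail, selected])
        yt = labels.loc[avail].to_numpy()
        for name, model in bundle.items():
            pred = model.predict(xt)
            rec = dict(base)
            rec.update({"classifier": name, "rotation_label": rot_label,
                        "n_selected_features": len(selected)})
            rec.update(macro_metrics(yt, pred, classes))
            records.append(rec)
    return records


def run_repeated_cv(df: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full protocol over both partitions; returns the CVRunRecord table.

    One record per (partition x repeat x fold x classifier x rotation label);
    feature selection and scaling are refit inside every training fold (no
    test leakage), and folds are stratified by class.
    """
    config = config or PipelineConfig()
    tables, labels = wide_tables(df)
    if 0 not in tables:
        raise ValueError("rotation label 0 (training features) missing")
    classes = np.unique(labels.to_numpy())
    records: list[dict] = []
    for partition in config.partitions:
        candidates = prelim_filter(tables[0], partition, config.corr_threshold,
                                   config.include_shape)
        part_tables = {k: t[candidates] for k, t in tables.items()}
        r0 = part_tables[0]
        for repeat in range(config.n_repeats):
            skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                                  random_state=config.seed + repeat)
            ids = r0.index.to_numpy()
            y = labels.loc[ids].to_numpy()
            for fold, (tr, te) in enumerate(skf.split(ids, y)):
                train_ids, test_ids = ids[tr], ids[te]
                cycle_seed = (config.seed * 1_000_003 + repeat * 101 + fold) & 0x7FFFFFFF
                selected = fine_select(r0.loc[train_ids], labels.loc[train_ids].to_numpy(),
                                       config.max_features, config.kw_top_k, cycle_seed)
                scaler, bundle = train_classifiers(
                    r0.loc[train_ids, selected], labels.loc[train_ids].to_numpy(),
                    config.classifiers, cycle_seed)
                records.extend(evaluate_rotated(
                    bundle, scaler, selected, part_tables, labels, test_ids, classes,
                    base={"partition": partition, "repeat_idx": repeat, "fold_idx": fold},
                ))
    return pd.DataFrame(records)


METRICS = ("accuracy", "macro_f1", "macro_sensitivity", "macro_specificity")


def performance_trend(records: pd.DataFrame,
                      metrics: tuple[str, ...] = METRICS) -> pd.DataFrame:
    """Spearman trend of each metric vs rotation label.

    Rows: per (partition, classifier) plus a pooled "All" row per partition.
    Points are per-(cycle, label) records (so each classifier contributes
    n_repeats*n_folds*n_labels points); CI by the Fisher z transform.
    """
    rows = []
    for partition, part in records.groupby("partition"):
        groups = [("All", part)] + [(c, g) for c, g in part.groupby("classifier")]
        for clf, g in groups:
            for metric in metrics:
                y = g[metric].to_numpy()
                x = g["rotation_label"].to_numpy(dtype=float)
                n = len(y)
                if np.allclose(y, y[0]):
                    warnings.warn(f"{partition}/{clf}/{metric}: constant metric",
                                  stacklevel=2)
                    cc, p = 0.0, 1.0
                else:
                    cc, p = stats.spearmanr(x, y)
                if n > 3 and abs(cc) < 1:
                    z = np.arctanh(cc)
                    hw = 1.959963984540054 / np.sqrt(n - 3)
                    ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
                else:
                    ci = (float(cc), float(cc))
                rows.append({
                    "partition": partition, "classifier": clf, "metric": metric,
                    "n": n, "spearman_cc": float(cc), "ci_lo": ci[0], "ci_hi": ci[1],
                    "spearman_p": float(p), "stratum": effect_stratum(cc),
                })
    return pd.DataFrame(rows)
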