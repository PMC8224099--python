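"""Feature ranking and subject-wise SVM evaluation.

The modelling surface follows the statsmodels idiom: build a
:class:`SubjectwiseSVM` from a feature table, call :meth:`~SubjectwiseSVM.fit`
to run the subject-wise k-fold protocol, and read the per-fold and averaged
accuracy / sensitivity / specificity off the returned
:class:`SubjectwiseSVMResults` (or print ``summary()``).

Protocol details that matter:

* folds partition *subjects*, never segments, stratified by label -- no
  individual contributes segments to both training and test sets;
* feature ranking (information gain or SVM-RFE) is recomputed inside each
  training fold by default, so feature selection never sees test subjects
  (``global_ranking=True`` reproduces the optimistic variant);
* features are standardized with training-fold statistics only;
* the RBF-kernel SVM's C and gamma are chosen on an inner subject-wise
  5-fold accuracy grid over powers of two from 2**-5 to 2**5, with
  class-balanced weighting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features.pipeline import META_COLUMNS, FeatureSetSpec, build_feature_set

POWER_GRID = tuple(2.0 ** k for k in range(-5, 6))
POSITIVE_LABEL = "CAD"


# ---------------------------------------------------------------------------
# feature ranking

@dataclass
class Ranking:
    """Feature names ordered most to least important."""

    features: list
    method: str
    scores: dict | None = None

    def top(self, n: int) -> list:
        return self.features[:min(n, len(self.features))]


def information_gain(feature_values, labels, n_bins: int = 10) -> float:
    """Reduction in label entropy (bits) from an equal-frequency
    discretization of one feature.

    ``H(label) - H(label | bin)`` with base-2 logs; bounded by the label
    entropy.  Duplicate quantile edges (heavily tied features) merge bins.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels are constant")
    if min(np.bincount(y_idx)) < 2:
        raise ValueError("need at least 2 samples per class")

    def entropy(counts):
        p = counts[counts > 0] / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h_y = entropy(np.bincount(y_idx))
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(x, edges)
    h_cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_cond += mask.mean() * entropy(np.bincount(y_idx[mask],
                                                    minlength=len(classes)))
    return h_y - h_cond


def rank_information_gain(x: pd.DataFrame, y, n_bins: int = 10) -> Ranking:
    """Rank every column of a feature table by information gain."""
    scores = {c: information_gain(x[c].to_numpy(), y, n_bins)
              for c in x.columns}
    ordered = sorted(x.columns, key=lambda c: (-scores[c], c))
    return Ranking(features=list(ordered), method="infogain", scores=scores)


def svm_rfe(x, y, elimination_step: int = 1, C: float = 1.0,
            feature_names=None) -> Ranking:
    """Recursive feature elimination driven by linear-SVM weight magnitudes.

    Repeatedly fits a linear-kernel SVM on standardized features, scores
    each remaining feature by its squared weight, and removes the
    ``elimination_step`` lowest; the reversed removal order is the ranking.
    When fewer than ``elimination_step`` features remain, the final batch
    removes them all (lowest weight first).
    """
    if isinstance(x, pd.DataFrame):
        feature_names = list(x.columns)
        x = x.to_numpy(dtype=np.float64)
    else:
        x = np.asarray(x, dtype=np.float64)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(x.shape[1])]
    if elimination_step < 1:
        raise ValueError("elimination_step must be >= 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes")
    remaining = list(range(x.shape[1]))
    removed = []
    while remaining:
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[:, remaining], y)
        w2 = np.ravel(clf.coef_) ** 2
        order = np.argsort(w2, kind="stable")  # ascending: weakest first
        n_drop = min(elimination_step, len(remaining))
        drop_local = order[:n_drop]
        for loc in sorted(drop_local, key=lambda i: w2[i]):
            removed.append(remaining[loc])
        remaining = [f for i, f in enumerate(remaining) if i not in set(drop_local)]
    ranked = [feature_names[i] for i in reversed(removed)]
    return Ranking(features=ranked, method="svmrfe")


# ---------------------------------------------------------------------------
# subject-wise folds

def subject_kfold(subjects, labels, k: int = 5, seed: int = 0) -> list:
    """Partition subjects (not segments) into k label-stratified folds.

    ``subjects`` and ``labels`` are per-segment arrays; returns a list of
    ``(train_subject_ids, test_subject_ids)`` tuples (sets of subject IDs).
    """
    if k < 2:
        raise ValueError("k must be >= 2 (a held-out set is required)")
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    subj_ids, first_idx = np.unique(subjects, return_index=True)
    subj_labels = labels[first_idx]
    counts = pd.Series(subj_labels).value_counts()
    if counts.min() < k:
        raise ValueError(f"need at least k={k} subjects per class, "
                         f"got {counts.to_dict()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(subj_ids, subj_labels):
        folds.append((set(subj_ids[train_idx]), set(subj_ids[test_idx])))
    return folds


# ---------------------------------------------------------------------------
# metrics

def confusion_metrics(y_true, y_pred) -> dict:
    """Acc/Se/Sp in percent from binary arrays (1 = CAD positive)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "acc": acc, "se": se, "sp": sp}


# ---------------------------------------------------------------------------
# the model object

class _AllColumnsSpec:
    """Feature-set stand-in: every non-metadata column of the table."""

    id = "all"
    channel = None

class SubjectwiseSVM:
    """Subject-wise cross-validated RBF-SVM over one feature set.

    Parameters
    ----------
    table : DataFrame with ``subject_id``, ``label``, ``segment_index`` and
        feature columns (one row per 10-s segment).
    feature_set : FeatureSetSpec or set id string ("Mul3", ...); single-
        channel sets need ``channel=``.
    selector : "infogain" or "svmrfe".
    rfe_step : elimination step size of SVM-RFE.
    global_ranking : rank once on the full table instead of per training
        fold (optimistic; off by default).
    """

    def __init__(self, table: pd.DataFrame, feature_set="Mul3",
                 channel: int | None = None, selector: str = "infogain",
                 rfe_step: int = 10, n_bins: int = 10,
                 global_ranking: bool = False,
                 c_grid=POWER_GRID, gamma_grid=POWER_GRID,
                 inner_k: int = 5):
        if isinstance(feature_set, str):
            feature_set = FeatureSetSpec(feature_set, channel)
        if selector not in ("infogain", "svmrfe"):
            raise ValueError("selector must be 'infogain' or 'svmrfe'")
        if feature_set is None:
            feature_set = _AllColumnsSpec()
            sub = table.reset_index(drop=True)
        else:
            sub = build_feature_set(table, feature_set).reset_index(drop=True)
        feat_cols = [c for c in sub.columns if c not in META_COLUMNS]
        if sub[feat_cols].isna().any().any():
            raise ValueError("feature table contains missing values; "
                             "drop incomplete rows first")
        self.spec = feature_set
        self.selector = selector
        self.rfe_step = rfe_step
        self.n_bins = n_bins
        self.global_ranking = global_ranking
        self.c_grid = tuple(c_grid)
        self.gamma_grid = tuple(gamma_grid)
        self.inner_k = inner_k
        self.feature_names = feat_cols
        self.x = sub[feat_cols]
        self.y = (sub["label"].to_numpy() == POSITIVE_LABEL).astype(int)
        self.subjects = sub["subject_id"].to_numpy()

    @classmethod
    def from_dataframe(cls, table, **kwargs) -> "SubjectwiseSVM":
        return cls(table, **kwargs)

    # -- internals --------------------------------------------------------

    def _rank(self, x_std: pd.DataFrame, y) -> Ranking:
        if self.selector == "infogain":
            return rank_information_gain(x_std, y, self.n_bins)
        return svm_rfe(x_std, y, elimination_step=self.rfe_step)

    def _grid_search(self, x, y, subjects, seed: int):
        """Inner subject-wise CV accuracy over the (C, gamma) grid.

        The inner fold count shrinks to the number of training subjects in
        the rarer class when that is below ``inner_k`` (tiny cohorts).
        """
        subj_labels = pd.Series(y).groupby(pd.Series(subjects)).first()
        k = int(min(self.inner_k, subj_labels.value_counts().min()))
        if k < 2:
            return 1.0, 1.0  # too few subjects to tune: mid-grid defaults
        inner = subject_kfold(subjects, y, k=k, seed=seed)
        splits = [(np.isin(subjects, list(tr)), np.isin(subjects, list(te)))
                  for tr, te in inner]
        best = (-np.inf, None)
        for c, g in itertools.product(self.c_grid, self.gamma_grid):
            accs = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=c, gamma=g, class_weight="balanced")
                clf.fit(x[tr], y[tr])
                accs.append(np.mean(clf.predict(x[te]) == y[te]))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, (c, g))
        return best[1]

    @staticmethod
    def _standardize(train, test=None):
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        if test is None:
            return (train - mu) / sd
        return (train - mu) / sd, (test - mu) / sd

    # -- fitting ----------------------------------------------------------

    def fit(self, n_features: int | None = None, k: int = 5,
            seed: int = 0, folds=None) -> "SubjectwiseSVMResults":
        """Run the outer subject-wise k-fold protocol with top-n features.

        ``folds`` overrides the stratified subject partition with an
        explicit list of ``(train_subject_ids, test_subject_ids)`` pairs.
        """
        total = len(self.feature_names)
        n_features = total if n_features is None else min(n_features, total)
        x_all = self.x.to_numpy(dtype=np.float64)
        if folds is None:
            folds = subject_kfold(self.subjects, self.y, k=k, seed=seed)

        global_ranking = None
        if self.global_ranking:
            x_std = pd.DataFrame(self._standardize(x_all),
                                 columns=self.feature_names)
            global_ranking = self._rank(x_std, self.y)

        fold_rows = []
        fold_details = []
        for fold_id, (train_subj, test_subj) in enumerate(folds):
            tr = np.isin(self.subjects, list(train_subj))
            te = np.isin(self.subjects, list(test_subj))
            x_tr, x_te = self._standardize(x_all[tr], x_all[te])
            if global_ranking is not None:
                ranking = global_ranking
            else:
                ranking = self._rank(
                    pd.DataFrame(x_tr, columns=self.feature_names), self.y[tr])
            selected = ranking.top(n_features)
            idx = [self.feature_names.index(f) for f in selected]
            c, g = self._grid_search(x_tr[:, idx], self.y[tr],
                                     self.subjects[tr], seed=seed + fold_id)
            clf = SVC(kernel="rbf", C=c, gamma=g, class_weight="balanced")
            clf.fit(x_tr[:, idx], self.y[tr])
            y_pred = clf.predict(x_te[:, idx])
            metrics = confusion_metrics(self.y[te], y_pred)
            fold_rows.append({"fold": fold_id, "C": c, "gamma": g, **metrics})
            fold_details.append({"ranking": ranking, "selected": selected})
        return SubjectwiseSVMResults(
            model=self, n_features=n_features, k=k, seed=seed,
            per_fold=pd.DataFrame(fold_rows), fold_details=fold_details)

    def sweep(self, step: int, k: int = 5, seed: int = 0,
              max_features: int | None = None) -> pd.DataFrame:
        """Feature-count sweep: evaluate at n = step, 2*step, ...

        The last point is truncated to the full set size.  Returns one row
        per n with mean and SD of Acc/Se/Sp (percent) across folds.
        """
        total = len(self.feature_names)
        if max_features is not None:
            total = min(total, max_features)
        ns = list(range(step, total + 1, step))
        if not ns or ns[-1] != total:
            ns.append(total)
        rows = []
        for n in ns:
            res = self.fit(n_features=n, k=k, seed=seed)
            rows.append({"feature_set": self.spec.id, "selector": self.selector,
                         "n_features": n, **res.mean_metrics()})
        return pd.DataFrame(rows)


@dataclass
class SubjectwiseSVMResults:
    """Per-fold and averaged classification results of one evaluation."""

    model: SubjectwiseSVM
    n_features: int
    k: int
    seed: int
    per_fold: pd.DataFrame
    fold_details: list = field(default_factory=list, repr=False)

    def mean_metrics(self) -> dict:
        out = {}
        for name in ("acc", "se", "sp"):
            out[f"{name}_mean"] = float(self.per_fold[name].mean())
            out[f"{name}_sd"] = float(self.per_fold[name].std(ddof=0))
        return out

    @property
    def accuracy(self) -> float:
        return self.mean_metrics()["acc_mean"]

    @property
    def sensitivity(self) -> float:
        return self.mean_metrics()["se_mean"]

    @property
    def specificity(self) -> float:
        return self.mean_metrics()["sp_mean"]

    def summary(self) -> str:
        m = self.mean_metrics()
        lines = [
            "Subject-wise SVM evaluation",
            "===========================",
            f"feature set : {self.model.spec.id}"
            + (f" (channel {self.model.spec.channel})"
               if self.model.spec.channel else ""),
            f"selector    : {self.model.selector}"
            + (" [global ranking]" if self.model.global_ranking else ""),
            f"n features  : {self.n_features}",
            f"folds       : {self.k} (subject-wise, seed {self.seed})",
            "",
            self.per_fold[["fold", "C", "gamma", "tp", "tn", "fp", "fn",
                           "acc", "se", "sp"]].to_string(index=False),
            "",
            f"Acc = {m['acc_mean']:.2f} +/- {m['acc_sd']:.2f} %   "
            f"Se = {m['se_mean']:.2f} +/- {m['se_sd']:.2f} %   "
            f"Sp = {m['sp_mean']:.2f} +/- {m['sp_sd']:.2f} %",
        ]
        return "\n".join(lines)
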