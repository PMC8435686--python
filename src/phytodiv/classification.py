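"""Organ classification and Boruta shadow-feature selection.

A bagged ensemble-tree classifier (random forest, delegated to
scikit-learn behind a narrow fit / OOB-predict / importance interface)
assigns samples to organ classes from the binary feature table.  This
module owns the out-of-bag (OOB) accounting — confusion matrix and error
rates from OOB predictions only — the OOB permutation importance, and the
Boruta all-relevant feature-selection loop:

each iteration appends one "shadow" copy per undecided real feature (an
independent row-permutation of its column), fits the classifier, and
scores a *hit* for every real feature whose importance exceeds the maximum
shadow importance; a two-sided binomial test on accumulated hit counts
confirms (more hits than chance) or rejects (fewer) features, shrinking
the undecided set until all are decided or the iteration cap is reached.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from phytodiv.occurrence import FeatureTable

__all__ = ["ClassifierResult", "BorutaResult", "default_mtry",
           "fit_organ_classifier", "boruta", "boruta_xy",
           "oob_permutation_importance"]


def default_mtry(n_features: int) -> int:
    """Default number of variables tried at each split: floor(sqrt(p))."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return int(np.floor(np.sqrt(n_features)))


@dataclass
class ClassifierResult:
    """OOB performance of the organ classifier."""

    oob_error_overall: float
    oob_error_per_class: dict[str, float]
    confusion: pd.DataFrame  # rows: true organ; columns: OOB-predicted organ
    n_trees: int
    m_try: int

    def to_dict(self) -> dict:
        return {
            "oob_error_overall": self.oob_error_overall,
            "oob_error_per_class": self.oob_error_per_class,
            "confusion": self.confusion.to_dict(),
            "n_trees": self.n_trees,
            "m_try": self.m_try,
        }


def _oob_masks(forest: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    """Per-tree OOB sample indices, reconstructed from tree random states."""
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    return [_generate_unsampled_indices(est.random_state, n_samples, n_boot, None)
            for est in forest.estimators_]


def fit_organ_classifier(
    table: FeatureTable,
    n_trees: int = 2000,
    m_try: int | None = None,
    seed: int = 0,
) -> ClassifierResult:
    """Train the organ classifier and report OOB error and confusion.

    ``m_try`` defaults to floor(sqrt(p)) variables per split.  All error
    rates come from out-of-bag predictions: each sample is predicted only
    by trees that did not train on it.
    """
    y = table.metadata["organ"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 organ classes")
    if counts.min() < 2:
        raise ValueError(f"organ class {classes[counts.argmin()]!r} has < 2 samples")
    x = table.presence.to_numpy(dtype=np.float32)
    if m_try is None:
        m_try = default_mtry(x.shape[1])
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=m_try, oob_score=True,
        bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(x, y)
    votes = forest.oob_decision_function_
    if np.isnan(votes).any() or (votes.sum(axis=1) == 0).any():
        raise ValueError("some samples received no OOB votes; increase n_trees")
    pred = forest.classes_[votes.argmax(axis=1)]

    organ_levels = sorted(classes)
    confusion = pd.DataFrame(0, index=organ_levels, columns=organ_levels, dtype=int)
    for t, q in zip(y, pred):
        confusion.loc[t, q] += 1
    per_class = {
        o: float(1.0 - confusion.loc[o, o] / confusion.loc[o].sum())
        for o in organ_levels
    }
    overall = float((pred != y).mean())
    return ClassifierResult(
        oob_error_overall=overall, oob_error_per_class=per_class,
        confusion=confusion, n_trees=n_trees, m_try=m_try)


def _feature_seed(base_seed: int, iteration: int, name: str) -> int:
    """Stable per-feature stream: depends on the feature name, not its
    column position, so decisions survive column reordering."""
    return zlib.crc32(f"{base_seed}:{iteration}:{name}".encode()) % (2 ** 31)


def oob_permutation_importance(
    forest: RandomForestClassifier,
    x: np.ndarray,
    y_codes: np.ndarray,
    feature_names: list[str],
    base_seed: int = 0,
    iteration: int = 0,
    max_block_cells: int = 20_000_000,
) -> np.ndarray:
    """OOB permutation importance (mean decrease in OOB accuracy).

    For each tree and feature, the feature's column is permuted within the
    tree's OOB samples and the drop in that tree's OOB accuracy recorded;
    importances are the per-tree drops averaged over trees (unscaled).
    """
    n, p = x.shape
    rngs = [np.random.default_rng(_feature_seed(base_seed, iteration, f))
            for f in feature_names]
    importance = np.zeros(p)
    masks = _oob_masks(forest, n)
    for est, oob in zip(forest.estimators_, masks):
        if len(oob) == 0:
            continue
        x_oob = x[oob]
        y_oob = y_codes[oob]
        # trees inside a forest are fitted on encoded labels 0..k-1, in
        # the order of forest.classes_ (sorted), matching y_codes
        base_pred = est.predict(x_oob).astype(np.intp)
        acc_base = float((base_pred == y_oob).mean())
        n_oob = len(oob)
        block = max(1, max_block_cells // (n_oob * p))
        for start in range(0, p, block):
            feats = range(start, min(start + block, p))
            stacked = np.repeat(x_oob[None, :, :], len(feats), axis=0)
            for b, f in enumerate(feats):
                perm = rngs[f].permutation(n_oob)
                stacked[b, :, f] = x_oob[perm, f]
            pred = est.predict(stacked.reshape(-1, p)).astype(np.intp)
            acc_perm = (pred.reshape(len(feats), n_oob) == y_oob[None, :]).mean(axis=1)
            importance[start:start + len(feats)] += acc_base - acc_perm
    return importance / len(forest.estimators_)


@dataclass
class BorutaResult:
    """Outcome of the Boruta loop."""

    decisions: dict[str, str]  # feature -> confirmed | rejected | tentative
    importance_history: pd.DataFrame  # iterations x features (NaN once decided)
    shadow_max_history: list[float]
    n_iterations: int
    seed: int
    hit_counts: dict[str, int] = field(default_factory=dict)

    @property
    def confirmed(self) -> set[str]:
        return {f for f, d in self.decisions.items() if d == "confirmed"}

    @property
    def rejected(self) -> set[str]:
        return {f for f, d in self.decisions.items() if d == "rejected"}

    @property
    def tentative(self) -> set[str]:
        return {f for f, d in self.decisions.items() if d == "tentative"}

    def to_frame(self) -> pd.DataFrame:
        """Decision table: feature id, decision, median importance score."""
        med = self.importance_history.median(axis=0, skipna=True)
        return pd.DataFrame({
            "feature": list(self.decisions),
            "decision": [self.decisions[f] for f in self.decisions],
            "median_importance": [float(med.get(f, np.nan)) for f in self.decisions],
        })

    def to_dict(self) -> dict:
        return {
            "decisions": self.decisions,
            "shadow_max_history": [float(v) for v in self.shadow_max_history],
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "hit_counts": self.hit_counts,
        }


def boruta_xy(
    x: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    max_iterations: int = 100,
    alpha: float = 0.01,
    n_trees: int = 500,
    m_try: int | None = None,
    importance: str = "permutation",
    multiple_testing: bool = True,
    seed: int = 0,
) -> BorutaResult:
    """Boruta shadow-feature selection around the ensemble classifier.

    ``importance``: "permutation" (OOB-based mean decrease in accuracy,
    default) or "gini" (impurity-based, faster).  Shadows are rebuilt each
    iteration from the undecided features only.  With ``multiple_testing``
    (default, as in the reference algorithm) the per-feature binomial
    p-value is Bonferroni-adjusted across the features still in play,
    guarding against chance-correlated noise features.
    """
    if max_iterations < 5:
        raise ValueError("max_iterations must be >= 5 (the binomial hit test "
                         "is underpowered below that)")
    if importance not in ("permutation", "gini"):
        raise ValueError("importance must be 'permutation' or 'gini'")
    x = np.asarray(x, dtype=np.float32)
    n, p = x.shape
    if len(feature_names) != p or len(set(feature_names)) != p:
        raise ValueError("feature_names must be unique and match x columns")
    classes = np.unique(y)
    y_codes = np.searchsorted(classes, y)

    undecided = list(feature_names)
    decisions = {f: "tentative" for f in feature_names}
    hits = {f: 0 for f in feature_names}
    history_rows: list[dict[str, float]] = []
    shadow_max_history: list[float] = []
    rng = np.random.default_rng(seed)
    name_to_col = {f: j for j, f in enumerate(feature_names)}

    it = 0
    while undecided and it < max_iterations:
        it += 1
        cols = [name_to_col[f] for f in undecided]
        x_real = x[:, cols]
        # one shadow per undecided feature: independent row permutation,
        # drawn from a stream keyed to the feature name
        shadows = np.empty_like(x_real)
        for j, f in enumerate(undecided):
            srng = np.random.default_rng(_feature_seed(seed, it, "shadow:" + f))
            shadows[:, j] = x_real[srng.permutation(n), j]
        x_it = np.hstack([x_real, shadows])
        names_it = undecided + ["__shadow__" + f for f in undecided]
        mt = m_try if m_try is not None else default_mtry(x_it.shape[1])
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features=mt, oob_score=False,
            bootstrap=True, random_state=seed + it, n_jobs=1)
        forest.fit(x_it, y)
        if importance == "permutation":
            imp = oob_permutation_importance(
                forest, x_it, y_codes, names_it, base_seed=seed, iteration=it)
        else:
            imp = forest.feature_importances_
        k = len(undecided)
        imp_real, imp_shadow = imp[:k], imp[k:]
        shadow_max = float(imp_shadow.max())
        shadow_max_history.append(shadow_max)
        history_rows.append(dict(zip(undecided, imp_real.astype(float))))

        for f, v in zip(undecided, imp_real):
            if v > shadow_max:
                hits[f] += 1
        still = []
        adj = len(undecided) if multiple_testing else 1
        for f in undecided:
            pval = min(1.0, binomtest(hits[f], it, 0.5).pvalue * adj)
            if pval < alpha:
                decisions[f] = "confirmed" if hits[f] > it / 2 else "rejected"
            else:
                still.append(f)
        undecided = still

    history = pd.DataFrame(history_rows, columns=feature_names)
    return BorutaResult(
        decisions=decisions, importance_history=history,
        shadow_max_history=shadow_max_history, n_iterations=it, seed=seed,
        hit_counts=dict(hits))


def boruta(
    table: FeatureTable,
    max_iterations: int = 100,
    alpha: float = 0.01,
    n_trees: int = 500,
    m_try: int | None = None,
    importance: str = "permutation",
    seed: int = 0,
) -> BorutaResult:
    """Boruta selection of organ-informative compounds from a table."""
    return boruta_xy(
        table.presence.to_numpy(dtype=np.float32),
        table.metadata["organ"].to_numpy(),
        table.compound_ids,
        max_iterations=max_iterations, alpha=alpha, n_trees=n_trees,
        m_try=m_try, importance=importance, seed=seed)
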