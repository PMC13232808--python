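"""Six-member ensemble habitat models with repeated-split evaluation.

The member set mirrors the classic ensemble-SDM algorithm families — gradient
boosting (GBM), random forest (RF), feed-forward neural network (ANN),
piecewise-linear adaptive splines (MARS), smooth additive model (GAM) and a
single classification tree (CTA).  Each member is evaluated by repeated random
70/30 calibration/evaluation splits (Cohen's Kappa, the True Skill Statistic and
AUC); members whose mean AUC clears a gate (default 0.7) are combined into
AUC-weighted-mean (EMwmean), coefficient-of-variation (EMcv) and
confidence-interval (EMci) ensembles.  Variable importance is permutation based:
one minus the correlation between EMwmean predictions before and after shuffling
a predictor column.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import (DegenerateLabelsError, NoEnsembleError, SchemaError,
                     UndefinedMetricError)
from .occurrences import ModelingTable

logger = logging.getLogger(__name__)

MEMBER_TAGS = ("GBM", "RF", "ANN", "MARS", "GAM", "CTA")
DEFAULT_AUC_GATE = 0.7
DEFAULT_CALIB_FRAC = 0.7
DEFAULT_REPS = 3
DEFAULT_CI_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("both classes must be present")


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    """2x2 counts with presence predicted where score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size < 2:
        raise ValueError("scores and labels must have equal length >= 2")
    _check_two_classes(labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(tp=int(np.sum(pred & pos)), fn=int(np.sum(~pred & pos)),
                           tn=int(np.sum(~pred & ~pos)), fp=int(np.sum(pred & ~pos)))


def tss(c: ConfusionCounts) -> float:
    """True Skill Statistic: sensitivity + specificity − 1, in [−1, 1]."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("TSS undefined with an empty class")
    return c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp) - 1.0


def kappa(c: ConfusionCounts) -> float:
    """Cohen's Kappa: (p_o − p_e) / (1 − p_e) with p_e from the marginals."""
    n = c.tp + c.fn + c.tn + c.fp
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("Kappa undefined with an empty class")
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / n**2
    if p_e >= 1.0:
        raise UndefinedMetricError("Kappa undefined when expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann–Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n1 = int(np.sum(labels == 1))
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss_max_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest cutoff maximizing TSS over candidates = unique scores ∪ {0, 1}."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    # sens/spec at every candidate via broadcasting (n_cand x n)
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    tss_vals = tp / n1 + (n0 - fp) / n0 - 1.0
    best = tss_vals.max()
    return float(candidates[np.flatnonzero(tss_vals >= best - 1e-12)[0]])


# ---------------------------------------------------------------------------
# Learner backings
# ---------------------------------------------------------------------------

class _SkModel:
    """Probabilistic scikit-learn classifier wrapper (predicts P(presence))."""

    def __init__(self, est, weight_by_replication: bool = False):
        self.est = est
        self.weight_by_replication = weight_by_replication

    def fit(self, X, y, w):
        if self.weight_by_replication:
            # learner has no sample_weight support: replicate rows ~ weight
            reps = np.maximum(1, np.rint(w / w.min())).astype(int)
            reps = np.minimum(reps, 50)
            idx = np.repeat(np.arange(len(y)), reps)
            self.est.fit(X[idx], y[idx])
        else:
            self.est.fit(X, y, sample_weight=w)
        return self

    def predict(self, X) -> np.ndarray:
        p = self.est.predict_proba(X)[:, list(self.est.classes_).index(1)]
        return np.clip(p, 0.0, 1.0)


class _HingeSplineLogit:
    """Adaptive piecewise-linear (hinge) spline logistic model.

    For every predictor, hinge pairs max(x−k, 0) / max(k−x, 0) are formed at
    training-quantile knots and the expansion is fitted with an L2-penalized
    logistic regression — the MARS family of reflected-pair basis functions.
    """

    def __init__(self, quantiles=(0.25, 0.5, 0.75), C: float = 1.0, seed: int = 0):
        self.quantiles = quantiles
        self.C = C
        self.seed = seed

    def _expand(self, X: np.ndarray) -> np.ndarray:
        feats = [X]
        for j in range(X.shape[1]):
            for k in self.knots_[j]:
                feats.append(np.maximum(X[:, j : j + 1] - k, 0.0))
                feats.append(np.maximum(k - X[:, j : j + 1], 0.0))
        return np.hstack(feats)

    def fit(self, X, y, w):
        X = np.asarray(X, dtype=float)
        self.knots_ = [np.unique(np.quantile(X[:, j], self.quantiles)) for j in range(X.shape[1])]
        self.scaler_ = StandardScaler().fit(self._expand(X))
        self.clf_ = LogisticRegression(C=self.C, max_iter=500, random_state=self.seed)
        self.clf_.fit(self.scaler_.transform(self._expand(X)), y, sample_weight=w)
        return self

    def predict(self, X) -> np.ndarray:
        Z = self.scaler_.transform(self._expand(np.asarray(X, dtype=float)))
        p = self.clf_.predict_proba(Z)[:, list(self.clf_.classes_).index(1)]
        return np.clip(p, 0.0, 1.0)


class _AdditiveSplineLogit:
    """Smooth additive model: cubic B-spline basis per predictor + logistic link."""

    def __init__(self, n_knots: int = 5, C: float = 1.0, seed: int = 0):
        self.n_knots = n_knots
        self.C = C
        self.seed = seed

    def fit(self, X, y, w):
        X = np.asarray(X, dtype=float)
        self.spline_ = SplineTransformer(n_knots=self.n_knots, degree=3,
                                         include_bias=False).fit(X)
        self.clf_ = LogisticRegression(C=self.C, max_iter=500, random_state=self.seed)
        self.clf_.fit(self.spline_.transform(X), y, sample_weight=w)
        return self

    def predict(self, X) -> np.ndarray:
        p = self.clf_.predict_proba(self.spline_.transform(np.asarray(X, dtype=float)))
        return np.clip(p[:, list(self.clf_.classes_).index(1)], 0.0, 1.0)


def _make_learner(tag: str, seed: int):
    if tag == "GBM":
        return _SkModel(GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed))
    if tag == "RF":
        return _SkModel(RandomForestClassifier(
            n_estimators=200, min_samples_leaf=5, random_state=seed, n_jobs=1))
    if tag == "ANN":
        return _SkModel(MLPClassifier(
            hidden_layer_sizes=(8,), max_iter=600, random_state=seed),
            weight_by_replication=True)
    if tag == "MARS":
        return _HingeSplineLogit(seed=seed)
    if tag == "GAM":
        return _AdditiveSplineLogit(seed=seed)
    if tag == "CTA":
        return _SkModel(DecisionTreeClassifier(
            max_depth=8, min_samples_leaf=10, random_state=seed))
    raise ValueError(f"unknown member tag '{tag}'")


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed from a master seed and string/int tags (< 2^31)."""
    import hashlib

    h = hashlib.blake2b(("/".join(str(t) for t in (master, *tags))).encode(),
                        digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Members, evaluation, ensemble
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    replicate: int
    tss: float
    kappa: float
    auc: float


@dataclass
class FittedMember:
    learner_tag: str
    fitted_state: object
    metrics: list[EvalMetrics] = field(default_factory=list)
    failed: bool = False
    failure: str = ""

    @property
    def mean_auc(self) -> float:
        if not self.metrics:
            return float("nan")
        return float(np.mean([m.auc for m in self.metrics]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fitted_state.predict(X)


def fit_member(tag: str, table: ModelingTable, seed: int = 0) -> FittedMember:
    """Fit one member on the full table; failures yield a flagged record, not a crash."""
    _check_two_classes(table.y)
    try:
        state = _make_learner(tag, seed).fit(table.X, table.y, table.weights)
        return FittedMember(tag, state)
    except Exception as exc:  # member failure must not kill the pipeline
        logger.warning("member %s failed to fit: %s", tag, exc)
        return FittedMember(tag, None, failed=True, failure=str(exc))


def _split_once(table: ModelingTable, calib_frac: float, seed: int,
                max_retries: int = 5):
    y = table.y
    for attempt in range(max_retries):
        idx_cal, idx_eval = train_test_split(
            np.arange(len(y)), train_size=calib_frac, random_state=seed + attempt,
            stratify=y)
        if len(np.unique(y[idx_cal])) == 2 and len(np.unique(y[idx_eval])) == 2:
            return idx_cal, idx_eval
    raise DegenerateLabelsError("could not produce a two-class split")


def cross_validate(tag: str, table: ModelingTable,
                   calib_frac: float = DEFAULT_CALIB_FRAC,
                   reps: int = DEFAULT_REPS, seed: int = 0,
                   return_scores: bool = False):
    """Repeated random split evaluation of one member.

    Each replicate fits on a stratified ``calib_frac`` share and scores the rest;
    TSS and Kappa are evaluated at the TSS-maximizing threshold of the held-out
    scores, AUC is threshold-free.  Returns the metric list, or
    ``(metrics, [(scores, labels, idx_eval), ...])`` with ``return_scores``.
    """
    metrics, held_out = [], []
    for rep in range(reps):
        rep_seed = derive_seed(seed, "split", rep)
        idx_cal, idx_eval = _split_once(table, calib_frac, rep_seed)
        learner = _make_learner(tag, derive_seed(seed, tag, rep))
        learner.fit(table.X[idx_cal], table.y[idx_cal], table.weights[idx_cal])
        scores = learner.predict(table.X[idx_eval])
        labels = table.y[idx_eval]
        thr = tss_max_threshold(scores, labels)
        c = confusion_at(scores, labels, thr)
        metrics.append(EvalMetrics(rep, tss(c), kappa(c), auc(scores, labels)))
        held_out.append((scores, labels, idx_eval))
    return (metrics, held_out) if return_scores else metrics


def select_members(members: Sequence[FittedMember],
                   auc_min: float = DEFAULT_AUC_GATE) -> list[FittedMember]:
    """Keep members whose mean held-out AUC >= the gate (inclusive), in order."""
    if not members:
        raise ValueError("no members to select from")
    ok = [m for m in members if not m.failed and m.mean_auc >= auc_min]
    if not ok:
        raise NoEnsembleError(f"no member reached AUC >= {auc_min}")
    return ok


@dataclass
class EnsembleModel:
    """AUC-gated member committee with skill-proportional weights."""

    members: list[FittedMember]
    weights: np.ndarray
    variables: list[str]
    auc_gate: float = DEFAULT_AUC_GATE
    ci_alpha: float = DEFAULT_CI_ALPHA
    threshold: float | None = None  # TSS-max binarization cutoff (pooled held-out)
    seed: int = 0
    species: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        self.weights = self.weights / total

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(X) for m in self.members])

    def predict(self, X: np.ndarray, kind: str = "EMwmean") -> np.ndarray:
        return ensemble_predict(self, X, kind)


def ensemble_predict(ens: EnsembleModel, X: np.ndarray,
                     kind: str = "EMwmean") -> np.ndarray:
    """Ensemble summary of the member predictions on predictor rows.

    * ``EMwmean`` — Σ wᵢ pᵢ, weights ∝ member mean AUC;
    * ``EMcv`` — sd(p)/mean(p), 0 where the mean is 0;
    * ``EMci_lower`` / ``EMci_upper`` — mean ∓ z₁₋α/₂·sd, clipped to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ens.variables):
        raise SchemaError(
            f"expected {len(ens.variables)} predictor columns ({ens.variables})")
    P = ens.member_predictions(X)
    if kind == "EMwmean":
        return np.clip(np.tensordot(ens.weights, P, axes=1), 0.0, 1.0)
    mean = P.mean(axis=0)
    sd = P.std(axis=0, ddof=1) if len(ens.members) > 1 else np.zeros_like(mean)
    if kind == "EMcv":
        return np.where(mean > 0, np.divide(sd, mean, out=np.zeros_like(mean),
                                            where=mean > 0), 0.0)
    z = norm.ppf(1.0 - ens.ci_alpha / 2.0)
    if kind == "EMci_lower":
        return np.clip(mean - z * sd, 0.0, 1.0)
    if kind == "EMci_upper":
        return np.clip(mean + z * sd, 0.0, 1.0)
    raise ValueError(f"unknown ensemble kind '{kind}'")


def build_ensemble(table: ModelingTable, tags: Sequence[str] = MEMBER_TAGS,
                   calib_frac: float = DEFAULT_CALIB_FRAC, reps: int = DEFAULT_REPS,
                   auc_gate: float = DEFAULT_AUC_GATE,
                   ci_alpha: float = DEFAULT_CI_ALPHA, seed: int = 0,
                   species: str = "") -> EnsembleModel:
    """Evaluate, gate and combine members; set the TSS-max binarization threshold.

    All members share the same per-replicate splits (they are derived from the
    seed alone), so a weighted mean of member held-out scores is well defined;
    the binarization threshold is the TSS-max cutoff of those pooled ensemble
    scores across replicates.
    """
    members: list[FittedMember] = []
    held_out: dict[str, list] = {}
    for tag in tags:
        try:
            metrics, ho = cross_validate(tag, table, calib_frac, reps,
                                         seed=seed, return_scores=True)
        except Exception as exc:
            logger.warning("member %s failed evaluation: %s", tag, exc)
            members.append(FittedMember(tag, None, failed=True, failure=str(exc)))
            continue
        member = fit_member(tag, table, seed=derive_seed(seed, tag, "full"))
        member.metrics = metrics
        members.append(member)
        held_out[tag] = ho
    retained = select_members(members, auc_gate)
    dropped = [m.learner_tag for m in members if m not in retained]
    if dropped:
        logger.info("AUC gate %.2f removed members: %s", auc_gate, dropped)
    weights = np.array([m.mean_auc for m in retained])
    ens = EnsembleModel(retained, weights, [], auc_gate=auc_gate,
                        ci_alpha=ci_alpha, seed=seed, species=species)
    ens.variables = list(table.variables)

    # pooled held-out EMwmean scores -> binarization threshold
    pooled_scores, pooled_labels = [], []
    for rep in range(reps):
        rep_scores = np.stack([held_out[m.learner_tag][rep][0] for m in retained])
        pooled_scores.append(ens.weights @ rep_scores)
        pooled_labels.append(held_out[retained[0].learner_tag][rep][1])
    ens.threshold = tss_max_threshold(np.concatenate(pooled_scores),
                                      np.concatenate(pooled_labels))
    return ens


def metrics_frame(members: Sequence[FittedMember]) -> pd.DataFrame:
    rows = [{"member": m.learner_tag, "replicate": em.replicate, "tss": em.tss,
             "kappa": em.kappa, "auc": em.auc}
            for m in members if not m.failed for em in m.metrics]
    return pd.DataFrame(rows, columns=["member", "replicate", "tss", "kappa", "auc"])


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(ens: EnsembleModel, table: ModelingTable, variable: str,
                           n_perm: int = 3, seed: int = 0) -> float:
    """Permutation importance of one predictor for the EMwmean ensemble.

    Mean over permutations of 1 − Pearson r between EMwmean predictions on the
    original table and on the table with that column shuffled; clipped to [0, 1].
    """
    if variable not in table.variables:
        raise SchemaError(f"variable '{variable}' not in the modelling table")
    X = table.X
    base = ensemble_predict(ens, X)
    if np.std(base) == 0:
        logger.info("importance of %s: zero-variance predictions -> 0", variable)
        return 0.0
    j = table.variables.index(variable)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        perm = ensemble_predict(ens, Xp)
        if np.std(perm) == 0:
            vals.append(1.0)
            continue
        vals.append(1.0 - float(np.corrcoef(base, perm)[0, 1]))
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def importance_table(ens: EnsembleModel, table: ModelingTable,
                     n_perm: int = 3, seed: int = 0) -> pd.DataFrame:
    rows = [{"variable": v,
             "importance": permutation_importance(ens, table, v, n_perm,
                                                  derive_seed(seed, "imp", v))}
            for v in table.variables]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_ensemble(ens: EnsembleModel, path: str | Path) -> dict:
    """Pickle the ensemble; returns the JSON-ready manifest describing it."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(ens, fh)
    return {
        "species": ens.species,
        "members": [m.learner_tag for m in ens.members],
        "weights": [float(w) for w in ens.weights],
        "member_mean_auc": {m.learner_tag: float(m.mean_auc) for m in ens.members},
        "auc_gate": ens.auc_gate,
        "ci_alpha": ens.ci_alpha,
        "threshold": None if ens.threshold is None else float(ens.threshold),
        "seed": ens.seed,
        "variables": ens.variables,
        "file": path.name,
    }


def load_ensemble(path: str | Path) -> EnsembleModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
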