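"""Bootstrapped three-learner consensus ranking of filtered SNPs.

The cohort is repeatedly (default 100 times) re-split into stratified
training (80%) and validation (20%) sets.  On each training set three
learners — a random forest, a linear-kernel SVM, and a cross-validated
LASSO — rank the SNPs by importance, and each learner's top-k set is
recorded.  A SNP's consensus count is the number of (iteration, learner)
pairs whose top-k set contains it; the final ranking sorts by count
descending with ties broken by ascending SNP id.

This is a stability-selection style aggregation: a SNP that matters only
under one resampling or one learner accumulates few counts.

Interpretation note: the repeated random 80/20 re-split (sampling without
replacement within each label stratum) is the default resampling scheme; a
classical with-replacement bootstrap of the training set is available via
``RankingConfig.with_replacement``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LassoCV
from sklearn.svm import SVC

from .io import MISSING, GenotypeMatrix

METHODS = ("forest", "svm", "lasso")


@dataclass(frozen=True)
class RankingConfig:
    """Configuration of the bootstrapped consensus ranking.

    ``top_k`` is the per-iteration, per-learner top-set size whose members
    earn one count each.  Learner hyperparameters are fixed and documented
    here rather than tuned: forest with ``forest_trees`` trees on raw
    additive codes; linear-kernel SVM with unit cost on standardized codes;
    LASSO with an internally cross-validated penalty on standardized codes.
    """

    n_iterations: int = 100
    train_fraction: float = 0.8
    top_k: int = 20
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    with_replacement: bool = False
    forest_trees: int = 100
    svm_cost: float = 1.0
    lasso_alphas: int = 20
    lasso_cv: int = 3

    def validate(self, n_snps: int | None = None) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if n_snps is not None and self.top_k > n_snps:
            raise ValueError(f"top_k ({self.top_k}) exceeds SNP count ({n_snps})")


@dataclass
class ConsensusRanking:
    """Aggregated consensus counts and the per-iteration selection log."""

    counts: pd.Series  # snp_id -> count, sorted desc, ties by ascending id
    n_iterations: int
    methods: tuple[str, ...]
    top_k: int
    log: list[dict] = field(default_factory=list, repr=False)

    @property
    def order(self) -> list[str]:
        return list(self.counts.index)

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.rename("count").to_frame()
        out["rank"] = np.arange(1, len(out) + 1)
        out.index.name = "snp_id"
        out.to_csv(path, sep="\t")

    def log_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.log, indent=1) + "\n")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def bootstrap_splits(
    labels: np.ndarray, config: RankingConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/validation index splits, reproducible from the seed.

    Each iteration assigns ``train_fraction`` of every label stratum
    (rounded to nearest, at least 1 per stratum on each side) to training
    and the rest to validation; train and validation are disjoint.  In
    with-replacement mode the training indices are then resampled with
    replacement within strata; validation remains the untouched remainder.
    """
    labels = np.asarray(labels)
    config.validate()
    if len(labels) < 10:
        raise ValueError("need at least 10 labeled subjects")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain two classes")
    if counts.min() < 2:
        raise ValueError("each label class needs at least 2 subjects")
    rng = np.random.default_rng(config.seed)
    splits = []
    for _ in range(config.n_iterations):
        train_parts, val_parts = [], []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            n_train = int(round(config.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_cls = idx[:n_train]
            if config.with_replacement:
                train_cls = rng.choice(train_cls, size=len(train_cls), replace=True)
            train_parts.append(train_cls)
            val_parts.append(idx[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts)))
        )
    return splits


# ---------------------------------------------------------------------------
# single-learner importance ranking
# ---------------------------------------------------------------------------

def impute_mode(calls: np.ndarray) -> np.ndarray:
    """Replace missing calls by the per-SNP modal genotype (float output).

    The mode is computed over non-missing training calls; an all-missing
    column imputes to 0.  Ties favor the smaller genotype code.
    """
    X = calls.astype(np.float64)
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            mode = 0.0
        else:
            vals, cnts = np.unique(obs, return_counts=True)
            mode = vals[np.argmax(cnts)]
        col[miss] = mode
    return X


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features map to all-zero columns
    return (X - mu) / sd


def rank_one(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    config: RankingConfig = RankingConfig(),
    random_state: int = 0,
) -> np.ndarray:
    """Importance order (best first) of the columns of ``X`` for one learner.

    ``X`` must be complete (impute first); ``y`` binary.  Scores are sorted
    descending with ties broken by ascending column index, so constant or
    zero-coefficient features always sink to the end in a stable order.
    """
    y = np.asarray(y).astype(int)
    if method == "forest":
        model = RandomForestClassifier(
            n_estimators=config.forest_trees, random_state=random_state, n_jobs=1
        ).fit(X, y)
        scores = model.feature_importances_
    elif method == "svm":
        model = SVC(kernel="linear", C=config.svm_cost).fit(_standardize(X), y)
        scores = np.abs(np.asarray(model.coef_).ravel())
    elif method == "lasso":
        model = LassoCV(
            alphas=config.lasso_alphas,
            cv=config.lasso_cv,
            random_state=random_state,
            max_iter=2000,
        ).fit(_standardize(X), y.astype(float))
        scores = np.abs(model.coef_)
    else:
        raise ValueError(f"unknown method {method!r}")
    # stable: descending score, ascending index on ties
    return np.lexsort((np.arange(len(scores)), -scores))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_counts(
    top_sets: Sequence[dict[str, Sequence[str]]],
    snp_ids: Sequence[str],
    methods: Sequence[str],
    top_k: int,
) -> ConsensusRanking:
    """Count top-set memberships over (iteration, learner) pairs and sort.

    ``top_sets`` holds, per iteration, a mapping method -> top-k SNP ids.
    """
    counts = {s: 0 for s in snp_ids}
    for it in top_sets:
        for method in methods:
            for s in it[method]:
                counts[s] += 1
    ser = pd.Series(counts)
    ser = ser.iloc[np.lexsort((ser.index.to_numpy(), -ser.to_numpy()))]
    return ConsensusRanking(
        counts=ser.astype(int),
        n_iterations=len(top_sets),
        methods=tuple(methods),
        top_k=top_k,
    )


def consensus_rank(
    matrix: GenotypeMatrix,
    labels: np.ndarray,
    config: RankingConfig = RankingConfig(),
) -> ConsensusRanking:
    """Full stage-2 ranking: resample, fit the learners, aggregate counts.

    ``labels`` is a boolean/binary vector aligned with the matrix rows.
    Deterministic for a fixed (matrix, labels, config).
    """
    config.validate(n_snps=matrix.n_snps)
    labels = np.asarray(labels).astype(int)
    splits = bootstrap_splits(labels, config)
    snp_ids = np.asarray(matrix.snp_ids, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    top_sets: list[dict[str, list[str]]] = []
    log: list[dict] = []
    for it, (train, val) in enumerate(splits):
        X = impute_mode(matrix.calls[train])
        y = labels[train]
        fit_seed = int(rng.integers(0, 2**31 - 1))
        entry: dict[str, list[str]] = {}
        for method in config.methods:
            order = rank_one(X, y, method, config=config, random_state=fit_seed)
            entry[method] = [str(s) for s in snp_ids[order[: config.top_k]]]
        top_sets.append(entry)
        log.append(
            {
                "iteration": it,
                "train": [int(i) for i in train],
                "validation": [int(i) for i in val],
                "top_sets": entry,
            }
        )
    ranking = aggregate_counts(top_sets, snp_ids, config.methods, config.top_k)
    ranking.log = log
    return ranking
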