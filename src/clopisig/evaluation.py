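"""Feature-number sweep, signature selection, and genotype-frequency tests.

Given a consensus ranking, classifiers are fitted on the top-k SNPs for
k = 1..K and scored on held-out validation folds (AUC and accuracy at a 0.5
probability threshold, averaged over folds).  The signature is the smallest
k whose best-model AUC comes within a tolerance of the global maximum —
a formalization of "minimum needed feature number".

Evaluation model set defaults to random forest, linear SVM, decision tree
and gradient-boosted trees (XGBoost); a LASSO-regression classifier is also
available so either four-model variant can be swept.

The genotype-frequency comparison contrasts the 0/1/2 genotype distribution
of a SNP between resistant and non-resistant subjects with a Pearson
chi-square on the group x genotype table (empty genotype columns dropped,
degrees of freedom reduced accordingly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import MISSING, GenotypeMatrix
from .ranking import ConsensusRanking, impute_mode

EVAL_MODELS = ("forest", "svm", "tree", "xgboost")
ALT_EVAL_MODELS = ("forest", "svm", "lasso", "tree")


@dataclass
class EvalCurve:
    """AUC/accuracy per (model, feature count) plus the selected signature."""

    table: pd.DataFrame  # columns: model, k, auc, accuracy
    selected_model: str | None = None
    selected_feature_count: int | None = None
    selected_snps: list[str] = field(default_factory=list)

    def auc(self, model: str, k: int) -> float:
        row = self.table[(self.table["model"] == model) & (self.table["k"] == k)]
        return float(row["auc"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_model": self.selected_model,
            "selected_feature_count": self.selected_feature_count,
            "selected_snps": self.selected_snps,
            "curve": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _make_model(name: str, seed: int):
    if name == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "lasso":
        return Lasso(alpha=0.01, max_iter=5000)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            n_jobs=1,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown evaluation model {name!r}")


def _scores(model, name: str, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(continuous score for AUC, hard 0/1 prediction at the 0.5 threshold)."""
    if name == "lasso":
        score = model.predict(X)
        return score, (score > 0.5).astype(int)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X)[:, 1]
        return score, (score > 0.5).astype(int)
    score = model.decision_function(X)
    return score, (score > 0).astype(int)


def evaluate_curve(
    matrix: GenotypeMatrix,
    labels: np.ndarray,
    ranking: ConsensusRanking | Sequence[str],
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    models: Sequence[str] = EVAL_MODELS,
    max_features: int = 10,
    seed: int = 0,
    annotation: pd.DataFrame | None = None,
    tolerance: float = 0.005,
) -> EvalCurve:
    """Sweep k = 1..max_features over the ranked SNPs for each model.

    For every validation fold in ``splits`` each model is fitted on the
    training subjects restricted to the top-k SNPs and scored on the
    held-out subjects; AUC and accuracy are averaged over folds.  When an
    ``annotation`` table is given, SNPs without a gene symbol are dropped
    from the ranking before the sweep (the annotated-signature variant).
    """
    order = list(ranking.order) if isinstance(ranking, ConsensusRanking) else list(ranking)
    if annotation is not None:
        genes = annotation["gene"] if "gene" in annotation.columns else annotation.iloc[:, -1]
        annotated = {s for s, g in genes.items() if isinstance(g, str) and g != ""}
        order = [s for s in order if s in annotated]
    if max_features > len(order):
        raise ValueError(
            f"max_features ({max_features}) exceeds ranked SNP count ({len(order)})"
        )
    labels = np.asarray(labels).astype(int)
    sub = matrix.subset_snps(order[:max_features])
    X_all = impute_mode(sub.calls)

    rows = []
    for name in models:
        for k in range(1, max_features + 1):
            aucs, accs = [], []
            for train, val in splits:
                Xtr, Xval = X_all[train][:, :k], X_all[val][:, :k]
                ytr, yval = labels[train], labels[val]
                model = _make_model(name, seed)
                model.fit(Xtr, ytr.astype(float) if name == "lasso" else ytr)
                score, pred = _scores(model, name, Xval)
                if len(np.unique(yval)) < 2:
                    continue  # fold with one class carries no AUC information
                aucs.append(roc_auc_score(yval, score))
                accs.append(float(np.mean(pred == yval)))
            rows.append((name, k, float(np.mean(aucs)), float(np.mean(accs))))
    curve = EvalCurve(table=pd.DataFrame(rows, columns=["model", "k", "auc", "accuracy"]))
    select_signature(curve, snp_order=order, tolerance=tolerance)
    return curve


def select_signature(
    curve: EvalCurve,
    snp_order: Sequence[str] | None = None,
    tolerance: float = 0.005,
) -> tuple[str, int, list[str]]:
    """Pick the smallest k whose best-model AUC is within ``tolerance`` of
    the global maximum; the model is the AUC argmax at that k.

    Ties break toward fewer features, then alphabetical model name.  The
    result is stored on the curve and returned.
    """
    tab = curve.table
    best_by_k = tab.groupby("k")["auc"].max()
    global_max = float(best_by_k.max())
    eligible = best_by_k[best_by_k >= global_max - tolerance]
    k_sel = int(eligible.index.min())
    at_k = tab[tab["k"] == k_sel].sort_values(["auc", "model"], ascending=[False, True])
    model_sel = str(at_k["model"].iloc[0])
    curve.selected_model = model_sel
    curve.selected_feature_count = k_sel
    curve.selected_snps = list(snp_order[:k_sel]) if snp_order is not None else []
    return model_sel, k_sel, curve.selected_snps


def genotype_frequency_test(
    calls: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Pearson chi-square on the group x genotype (0/1/2) table for one SNP.

    ``labels`` boolean (True = resistant).  Missing calls are dropped.
    Genotype columns absent from both groups are removed and the degrees of
    freedom reduced accordingly; with fewer than two non-empty columns the
    SNP is untestable and (table, nan, nan) is returned.
    """
    calls = np.asarray(calls)
    labels = np.asarray(labels, dtype=bool)
    ok = calls != MISSING
    if not (labels & ok).any() or not (~labels & ok).any():
        raise ValueError("both groups must be non-empty")
    table = np.empty((2, 3), dtype=np.int64)
    for i, grp in enumerate((labels, ~labels)):
        sel = ok & grp
        table[i] = [(calls[sel] == g).sum() for g in (0, 1, 2)]
    nonempty = table.sum(axis=0) > 0
    reduced = table[:, nonempty]
    if reduced.shape[1] < 2:
        return table, float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(reduced, correction=False)
    return table, float(chi2), float(p)


def genotype_frequency_table(
    matrix: GenotypeMatrix, labels: np.ndarray, snps: Sequence[str]
) -> pd.DataFrame:
    """Per-SNP genotype-frequency comparison for a list of signature SNPs."""
    rows = []
    pos = {s: i for i, s in enumerate(matrix.snp_ids)}
    for s in snps:
        tab, chi2, p = genotype_frequency_test(matrix.calls[:, pos[s]], labels)
        rows.append((s, *tab.ravel(), chi2, p))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "res_0", "res_1", "res_2", "non_0", "non_1", "non_2",
                 "chi2", "p"],
    ).set_index("snp_id")


def plot_curve(curve: EvalCurve, path: str | Path) -> None:
    """Accuracy and AUC versus feature count, one panel per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for metric, ax in zip(("auc", "accuracy"), axes):
        for model, grp in curve.table.groupby("model"):
            ax.plot(grp["k"], grp[metric], marker="o", ms=3, label=model)
        ax.set_xlabel("number of top-ranked SNPs")
        ax.set_ylabel(metric.upper() if metric == "auc" else "accuracy")
    if curve.selected_feature_count is not None:
        for ax in axes:
            ax.axvline(curve.selected_feature_count, ls="--", c="grey", lw=0.8)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
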