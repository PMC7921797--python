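"""Nested threefold cross-validation with an SVM judge.

The cohort (default 9 HFE + 9 LFE animals) is stratified into three
folds of 3 + 3. Each fold serves once as the held-out test set. The
remaining twelve animals are used differently by the two families of
selectors:

* DE selectors (t-test, NB exact): both remaining folds are the
  training set.
* ML selectors (RF, XGBoost, RX): one remaining fold trains the
  learner, the other is the validation set for hyperparameter tuning
  and early stopping.

Whatever the selector, an RBF-kernel SVM is then trained on the twelve
non-test animals restricted to the selected genes (features z-scored
with training statistics only) and judged on the test fold. Reported
metrics are overall accuracy, precision, recall and F1, with HFE the
positive class; fold means and standard deviations are aggregated per
tissue and across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import de as de_mod
from . import select as select_mod
from .preprocess import CountMatrix, normalize
from .select import HyperparameterGrid

METHODS = ("ttest", "nb_exact", "rf", "xgb", "rx")
METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass
class FoldPlan:
    """Assignment of animals to the three CV folds.

    ``roles(rotation, scheme)`` yields the train/validation/test split
    for rotation 0-2: the test fold is fold ``rotation``; the DE scheme
    merges the other two folds into training, the ML scheme keeps them
    separate as train and validation.
    """

    assignments: pd.Series  # animal id -> fold index in {0, 1, 2}
    seed: int

    def fold_members(self, fold: int) -> list[str]:
        return self.assignments.index[self.assignments == fold].tolist()

    def roles(self, rotation: int, scheme: str) -> dict[str, list[str]]:
        if rotation not in (0, 1, 2):
            raise ValueError("rotation must be 0, 1 or 2")
        test = self.fold_members(rotation)
        a = self.fold_members((rotation + 1) % 3)
        b = self.fold_members((rotation + 2) % 3)
        if scheme == "de":
            return {"train": a + b, "valid": [], "test": test}
        if scheme == "ml":
            return {"train": a, "valid": b, "test": test}
        raise ValueError(f"unknown scheme {scheme!r}")

    def check_partition(self) -> None:
        """Structural leakage guard: folds partition the cohort."""
        tests = [set(self.fold_members(r)) for r in range(3)]
        all_animals = set(self.assignments.index)
        if set().union(*tests) != all_animals:
            raise AssertionError("test folds do not cover all animals")
        for i in range(3):
            for j in range(i + 1, 3):
                if tests[i] & tests[j]:
                    raise AssertionError("test folds overlap")
        for r in range(3):
            for scheme in ("de", "ml"):
                roles = self.roles(r, scheme)
                fit_set = set(roles["train"]) | set(roles["valid"])
                if fit_set & set(roles["test"]):
                    raise AssertionError("selection reads test animals")


def make_folds(labels: pd.Series, seed: int = 0) -> FoldPlan:
    """Stratified random partition of animals into three folds.

    With 9 animals per class each fold gets exactly 3 + 3. Class sizes
    not divisible by three are dealt round-robin (nearest-balanced)
    with a warning.
    """
    classes = labels.unique()
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 animals")
        if (labels == c).sum() % 3 != 0:
            warnings.warn(
                f"class {c!r} size not divisible by 3; folds will be "
                "nearest-balanced"
            )
    rng = np.random.default_rng(seed)
    assign: dict[str, int] = {}
    for c in classes:
        members = labels.index[labels == c].to_numpy()
        members = members[rng.permutation(len(members))]
        for i, animal in enumerate(members):
            assign[animal] = i % 3
    plan = FoldPlan(
        assignments=pd.Series(assign, name="fold").reindex(labels.index),
        seed=seed,
    )
    plan.check_partition()
    return plan


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    true_labels: pd.Series, predicted: pd.Series, positive_class: str = "HFE"
) -> ConfusionCounts:
    t = true_labels == positive_class
    p = predicted.reindex(true_labels.index) == positive_class
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )


def compute_metrics(conf: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from a confusion table.

    accuracy = (tp + tn) / n, precision = tp / (tp + fp),
    recall = tp / (tp + fn), f1 = 2 P R / (P + R). Ratios with a zero
    denominator are reported as 0 and flagged (``undefined`` lists the
    affected metrics).
    """
    if conf.total == 0:
        raise ValueError("empty confusion table")
    undefined = []
    accuracy = (conf.tp + conf.tn) / conf.total
    if conf.tp + conf.fp == 0:
        precision, flag = 0.0, True
        undefined.append("precision")
    else:
        precision = conf.tp / (conf.tp + conf.fp)
    if conf.tp + conf.fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = conf.tp / (conf.tp + conf.fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": undefined,
    }


@dataclass(frozen=True)
class SVMParams:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "auto"  # 'auto' = 1 / n_features


def svm_judge(
    train_expr: pd.DataFrame,
    train_labels: pd.Series,
    test_expr: pd.DataFrame,
    params: SVMParams = SVMParams(),
    positive_class: str = "HFE",
) -> pd.Series:
    """Train an SVM on the selected genes and predict the test animals.

    Expression frames are genes x samples, already restricted to the
    selected panel; features are z-scored with training-fold mean and
    SD (constant genes get unit SD). Deterministic given its inputs.
    """
    if train_expr.shape[0] == 0:
        raise ValueError(
            "empty gene set: record a failed fold instead of judging it"
        )
    if not train_expr.index.equals(test_expr.index):
        raise ValueError("train and test matrices must share the gene panel")
    mu = train_expr.mean(axis=1)
    sd = train_expr.std(axis=1, ddof=1).replace(0.0, 1.0).fillna(1.0)
    Xt = ((train_expr.sub(mu, axis=0)).div(sd, axis=0)).to_numpy().T
    Xs = ((test_expr.sub(mu, axis=0)).div(sd, axis=0)).to_numpy().T
    y = (train_labels.reindex(train_expr.columns) == positive_class).to_numpy(int)
    clf = SVC(kernel=params.kernel, C=params.C, gamma=params.gamma)
    clf.fit(Xt, y)
    pred = clf.predict(Xs)
    neg = [c for c in train_labels.unique() if c != positive_class][0]
    return pd.Series(
        np.where(pred == 1, positive_class, neg), index=test_expr.columns
    )


@dataclass
class BenchmarkConfig:
    methods: tuple[str, ...] = METHODS
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    alpha: float = 0.05
    svm: SVMParams = field(default_factory=SVMParams)
    seed: int = 0
    positive_class: str = "HFE"

    def validate(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class BenchmarkReport:
    """Collected outputs of one benchmark run.

    ``per_fold`` has one row per (tissue, method, fold) with confusion
    counts, metrics and the number of genes selected; ``summary``
    aggregates metric means and SDs per (tissue, method) plus the
    per-tissue best method and the across-tissue overall average;
    ``gene_counts`` mirrors the per-fold panel sizes with their union
    ("total") per tissue and method. ``rx_gain`` holds fold-averaged
    RX Gain scores per tissue for the network stage, ``selections``
    the per-fold gene lists.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    gene_counts: pd.DataFrame
    selections: dict = field(default_factory=dict)
    rx_gain: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_fold.to_csv(outdir / "metrics_per_fold.csv", index=False)
        self.summary.to_csv(outdir / "metrics_summary.csv", index=False)
        self.gene_counts.to_csv(outdir / "gene_counts.csv", index=False)


def _select_genes(
    method: str,
    norm,
    counts: CountMatrix,
    labels: pd.Series,
    roles: dict,
    cfg: BenchmarkConfig,
    fold_seed: int,
    rf_cache: dict,
):
    """Run one selector on one rotation; returns (genes, gain_or_None)."""
    expr = norm.filtered_log_expr
    if method == "ttest":
        res = de_mod.ttest_de(
            expr[roles["train"]], labels[roles["train"]], cfg.alpha,
            cfg.positive_class,
        )
        return res.loc[res["is_deg"], "gene_id"].tolist(), None
    if method == "nb_exact":
        sub = CountMatrix(
            counts.values.loc[norm.retained_genes, roles["train"]],
            tissue=counts.tissue,
        )
        res = de_mod.nb_exact_de(
            sub,
            norm.tmm_factors[roles["train"]],
            labels[roles["train"]],
            cfg.alpha,
            cfg.positive_class,
        )
        return res.loc[res["is_deg"], "gene_id"].tolist(), None
    tr, va = roles["train"], roles["valid"]
    both = tr + va
    if method == "rf":
        params = rf_cache.setdefault(
            "rf_params",
            select_mod.tune_rf(
                expr[tr], labels[tr], expr[va], labels[va], cfg.grid, fold_seed
            ),
        )
        imp = select_mod.rf_importance(
            expr[both], labels[both], params["ntree"], params["mtry"], fold_seed
        )
        return select_mod.select_rf(imp), None
    if method == "xgb":
        params = select_mod.tune_xgb(
            expr[tr], labels[tr], expr[va], labels[va], cfg.grid, seed=fold_seed
        )
        imp = select_mod.xgb_importance(
            expr[both], labels[both], params["eta"], params["colsample"],
            seed=fold_seed, valid_expr=expr[va], valid_labels=labels[va],
        )
        return select_mod.select_xgb(imp), None
    if method == "rx":
        rx = select_mod.rx_select(
            expr[tr], labels[tr], expr[va], labels[va], cfg.grid, fold_seed,
            rf_params=rf_cache.get("rf_params"),
        )
        rf_cache.setdefault("rf_params", rx.rf_params)
        return rx.genes, rx.gain_table
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    counts_by_tissue: dict[str, CountMatrix],
    labels: pd.Series,
    config: BenchmarkConfig | None = None,
) -> BenchmarkReport:
    """Full nested-CV benchmark over tissues and selection methods."""
    cfg = config or BenchmarkConfig()
    cfg.validate()
    plan = make_folds(labels, cfg.seed)
    rows, count_rows, selections, rx_gain_acc, failures = [], [], {}, {}, []

    for t_i, (tissue, counts) in enumerate(counts_by_tissue.items()):
        norm = normalize(counts)
        expr = norm.filtered_log_expr
        for method in cfg.methods:
            scheme = "de" if method in ("ttest", "nb_exact") else "ml"
            fold_sets = []
            for rotation in range(3):
                roles = plan.roles(rotation, scheme)
                fold_seed = cfg.seed + 1000 * t_i + 10 * rotation
                rf_cache = selections.setdefault(
                    (tissue, rotation, "_cache"), {}
                )
                try:
                    genes, gain = _select_genes(
                        method, norm, counts, labels, roles, cfg,
                        fold_seed, rf_cache,
                    )
                except Exception as exc:  # selector hard failure
                    failures.append((tissue, method, rotation, repr(exc)))
                    continue
                selections[(tissue, method, rotation)] = genes
                fold_sets.append(set(genes))
                if gain is not None and len(gain.scores):
                    rx_gain_acc.setdefault(tissue, []).append(gain.scores)
                row = {
                    "tissue": tissue,
                    "method": method,
                    "fold": rotation + 1,
                    "n_genes": len(genes),
                }
                if not genes:
                    failures.append((tissue, method, rotation, "empty panel"))
                    row.update({m: np.nan for m in METRICS})
                    rows.append(row)
                    continue
                judge_train = roles["train"] + roles["valid"]
                pred = svm_judge(
                    expr.loc[genes, judge_train],
                    labels[judge_train],
                    expr.loc[genes, roles["test"]],
                    cfg.svm,
                    cfg.positive_class,
                )
                conf = confusion_counts(
                    labels[roles["test"]], pred, cfg.positive_class
                )
                m = compute_metrics(conf)
                row.update(
                    tp=conf.tp, fp=conf.fp, fn=conf.fn, tn=conf.tn,
                    **{k: m[k] for k in METRICS},
                )
                rows.append(row)
            union = set().union(*fold_sets) if fold_sets else set()
            count_rows.append(
                {
                    "tissue": tissue,
                    "method": method,
                    **{
                        f"fold{r + 1}": len(s) if r < len(fold_sets) else np.nan
                        for r, s in enumerate(fold_sets)
                    },
                    "total": len(union),
                }
            )
            selections[(tissue, method, "total")] = sorted(union)

    per_fold = pd.DataFrame(rows)
    summary = _summarize(per_fold, cfg)
    rx_gain = {
        tissue: pd.concat(series_list, axis=1).fillna(0.0).mean(axis=1)
        for tissue, series_list in rx_gain_acc.items()
    }
    selections = {k: v for k, v in selections.items() if k[-1] != "_cache"}
    return BenchmarkReport(
        per_fold=per_fold,
        summary=summary,
        gene_counts=pd.DataFrame(count_rows),
        selections=selections,
        rx_gain=rx_gain,
        failures=failures,
    )


def _summarize(per_fold: pd.DataFrame, cfg: BenchmarkConfig) -> pd.DataFrame:
    if per_fold.empty:
        return pd.DataFrame()
    rows = []
    for (tissue, method), grp in per_fold.groupby(["tissue", "method"], sort=False):
        row = {"tissue": tissue, "method": method}
        for m in METRICS:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_sd"] = grp[m].std(ddof=1)
        rows.append(row)
    out = pd.DataFrame(rows)
    # per-tissue best method by mean accuracy
    best = (
        out.loc[out.groupby("tissue")["accuracy_mean"].idxmax()]
        .set_index("tissue")["method"]
    )
    out["best_in_tissue"] = [
        best[t] == m for t, m in zip(out["tissue"], out["method"])
    ]
    overall = []
    for method, grp in out.groupby("method", sort=False):
        row = {"tissue": "OVERALL", "method": method, "best_in_tissue": False}
        for m in METRICS:
            row[f"{m}_mean"] = grp[f"{m}_mean"].mean()
            row[f"{m}_sd"] = np.nan
        overall.append(row)
    return pd.concat([out, pd.DataFrame(overall)], ignore_index=True)
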