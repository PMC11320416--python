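"""Cross-validated evaluation harness and ablation driver.

Runs the full pipeline — class-blind segmentation training, mask-gated
feature extraction per variant and modality, per-fold PCA + classifier
fitting — under stratified 5-fold cross-validation, reporting AUC/F1/ACC as
fold-wise mean +- std.  The reducer and classifier are always fitted inside
the training fold; by default the segmentation network is retrained per fold
as well (a ``shared_segnet`` mode trains it once on all cases, which is
faster but lets segmentation — though never class labels — see held-out
images).

A master seed fans out to every stochastic component (phantom cohort, fold
shuffling, weight init, training order, permutation tests) through a CRC32
tag scheme, so a report is bit-reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classify, features, phantom, segnet, volume_io


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed from a master seed and a tag path (< 2**31)."""
    h = zlib.crc32(repr((int(master),) + tuple(tags)).encode())
    return int(h % 2**31)


# -- folds and metrics ---------------------------------------------------------


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1 per case) preserving class proportions."""
    y = np.asarray(y, int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} cases, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class Metrics:
    auc: float | None
    f1: float
    acc: float


def compute_metrics(scores, hard_labels, y, allow_degenerate: bool = False) -> Metrics:
    """AUC (tie-aware rank statistic), F1 for class 1, and accuracy."""
    scores = np.asarray(scores, float)
    hard = np.asarray(hard_labels, int)
    y = np.asarray(y, int)
    if not (len(scores) == len(hard) == len(y)):
        raise ValueError("scores, hard labels and y must have equal length")
    f1 = float(f1_score(y, hard, zero_division=0))
    acc = float(accuracy_score(y, hard))
    if len(np.unique(y)) < 2:
        if allow_degenerate:
            return Metrics(auc=None, f1=f1, acc=acc)
        raise ValueError("AUC undefined: only one class present in y")
    return Metrics(auc=float(roc_auc_score(y, scores)), f1=f1, acc=acc)


# -- experiment configuration --------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything `run_experiment` needs besides the data source and seed."""

    preset: str | None = "tumor3"
    manifest: str | None = None
    variants: tuple[str, ...] = ("plain", "m3")
    modalities: tuple[str, ...] | None = None  # None = all in the data
    backend: str = "svm"
    folds: int = 5
    fuse: str | None = "feature_concat"  # feature_concat | score_average | None
    pca_variance: float | int = 0.95
    width_scale: float = 1 / 32
    epochs: int = 50
    loss: str = "ce_plus_dice"
    learning_rate: float = 1e-3
    batch_size: int = 8
    shared_segnet: bool = False

    def encoder_config(self) -> segnet.EncoderConfig:
        return segnet.EncoderConfig(width_scale=self.width_scale)

    def train_config(self, seed: int) -> segnet.TrainConfig:
        return segnet.TrainConfig(
            epochs=self.epochs,
            loss=self.loss,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=seed,
        )


@dataclass
class MetricReport:
    """Fold-wise metrics plus held-out case scores per (variant, target)."""

    config: dict
    seed: int
    n_folds: int
    fold_assignment: list[int]
    y: list[int]
    # entries[(variant, target)] = {"auc": [...], "f1": [...], "acc": [...]}
    entries: dict[tuple[str, str], dict[str, list[float]]] = field(default_factory=dict)
    # case-level held-out scores aligned with `y`
    scores: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def mean_std(self, variant: str, target: str, metric: str) -> tuple[float, float]:
        vals = np.asarray(self.entries[(variant, target)][metric], float)
        return float(vals.mean()), float(vals.std())

    def to_dict(self) -> dict:
        rows = {}
        for (variant, target), metrics in self.entries.items():
            row = {}
            for metric, vals in metrics.items():
                mean, std = self.mean_std(variant, target, metric)
                row[metric] = {"folds": vals, "mean": mean, "std": std}
            rows[f"{variant}/{target}"] = row
        return {
            "config": self.config,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "results": rows,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# -- experiment driver ---------------------------------------------------------


def _load_cases(cfg: ExperimentConfig, seed: int):
    if cfg.manifest is not None:
        return volume_io.read_manifest(cfg.manifest)
    pcfg = phantom.get_preset(cfg.preset, seed=derive_seed(seed, "phantom"))
    return phantom.generate_cohort(pcfg)


def _hard_labels(scores: np.ndarray, backend: str) -> np.ndarray:
    threshold = 0.0 if backend == "svm" else 0.5
    return (np.asarray(scores) > threshold).astype(int)


def run_experiment(config: ExperimentConfig, seed: int = 0, cases=None) -> MetricReport:
    """Full cross-validated ablation experiment; see module docstring.

    ``cases`` may be supplied directly (e.g. an already-generated cohort);
    otherwise they come from ``config.manifest`` or ``config.preset``.
    """
    if cases is None:
        cases = _load_cases(config, seed)
    cases = list(cases)
    y = np.asarray([c.class_label for c in cases], int)
    modalities = (
        list(config.modalities)
        if config.modalities
        else list(cases[0].volumes.keys())
    )
    folds = stratified_folds(y, config.folds, derive_seed(seed, "folds"))
    enc_cfg = config.encoder_config()

    ext_cfgs = {v: features.ExtractionConfig(variant=v) for v in config.variants}
    targets = list(modalities) + (["fused"] if config.fuse and len(modalities) > 1 else [])
    report = MetricReport(
        config={**asdict(config), "modalities": modalities},
        seed=seed,
        n_folds=config.folds,
        fold_assignment=folds.tolist(),
        y=y.tolist(),
        entries={(v, t): {"auc": [], "f1": [], "acc": []} for v in config.variants for t in targets},
        scores={(v, t): [np.nan] * len(cases) for v in config.variants for t in targets},
    )

    # with a shared (all-case, class-blind) segmentation net, features do not
    # depend on the fold split and are extracted once
    shared_vecs: dict[str, dict[str, list]] = {}
    if config.shared_segnet:
        blind = [c.without_class_label() for c in cases]
        for m in modalities:
            model = segnet.build_model(enc_cfg, seed=derive_seed(seed, "init", m))
            segnet.train_segmentation(
                model, blind, m, config.train_config(derive_seed(seed, "train", m))
            )
            per_case = [
                features.extract_variants(c, model, m, ext_cfgs) for c in cases
            ]
            shared_vecs[m] = {v: [pc[v] for pc in per_case] for v in config.variants}

    for fold in range(config.folds):
        train_idx = np.flatnonzero(folds != fold)
        test_idx = np.flatnonzero(folds == fold)
        # variant -> modality -> (train table, test table)
        tables: dict[str, dict[str, tuple]] = {v: {} for v in config.variants}
        for m in modalities:
            if config.shared_segnet:
                vecs = shared_vecs[m]
            else:
                model = segnet.build_model(enc_cfg, seed=derive_seed(seed, "init", m, fold))
                blind = [cases[i].without_class_label() for i in train_idx]
                segnet.train_segmentation(
                    model, blind, m, config.train_config(derive_seed(seed, "train", m, fold))
                )
                per_case = [
                    features.extract_variants(c, model, m, ext_cfgs) for c in cases
                ]
                vecs = {v: [pc[v] for pc in per_case] for v in config.variants}
            for v in config.variants:
                train_tab = classify.table_from_vectors(
                    [vecs[v][i] for i in train_idx], y[train_idx], modality=m
                )
                test_tab = classify.table_from_vectors(
                    [vecs[v][i] for i in test_idx], y[test_idx], modality=m
                )
                tables[v][m] = (train_tab, test_tab)

        for v in config.variants:
            per_modality_scores = {}
            for m in modalities:
                train_tab, test_tab = tables[v][m]
                scores = _fit_score(
                    train_tab, test_tab, config, derive_seed(seed, "clf", v, m, fold)
                )
                per_modality_scores[m] = scores
                _record(report, v, m, scores, y, test_idx, config.backend)
            if "fused" in targets:
                if config.fuse == "feature_concat":
                    train_tab = classify.fuse_modalities([tables[v][m][0] for m in modalities])
                    test_tab = classify.fuse_modalities([tables[v][m][1] for m in modalities])
                    scores = _fit_score(
                        train_tab, test_tab, config, derive_seed(seed, "clf", v, "fused", fold)
                    )
                else:  # score_average
                    scores = classify.average_scores(
                        [per_modality_scores[m] for m in modalities]
                    )
                _record(report, v, "fused", scores, y, test_idx, config.backend)
    return report


def _fit_score(train_tab, test_tab, config: ExperimentConfig, seed: int) -> np.ndarray:
    reducer = classify.fit_reducer(train_tab, config.pca_variance)
    Z_train = classify.transform(reducer, train_tab)
    clf = classify.fit_classifier(Z_train, train_tab.y, config.backend, seed)
    scores, _ = classify.predict_scores(clf, classify.transform(reducer, test_tab))
    return scores


def _record(report: MetricReport, variant: str, target: str, scores, y, test_idx, backend: str):
    hard = _hard_labels(scores, backend)
    metrics = compute_metrics(scores, hard, y[test_idx])
    entry = report.entries[(variant, target)]
    entry["auc"].append(metrics.auc)
    entry["f1"].append(metrics.f1)
    entry["acc"].append(metrics.acc)
    for j, i in enumerate(test_idx):
        report.scores[(variant, target)][i] = float(scores[j])


# -- variant comparison --------------------------------------------------------


def compare_variants(
    report: MetricReport,
    variant_a: str,
    variant_b: str,
    metric: str = "auc",
    target: str | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired fold-wise difference of a metric and a permutation p-value.

    The null distribution is built by randomly swapping, per case, which
    variant each held-out score is attributed to, then recomputing the
    fold-wise mean difference; the p-value is two-sided.
    """
    if target is None:
        target = report.config["modalities"][0]
    key_a, key_b = (variant_a, target), (variant_b, target)
    if key_a not in report.scores or key_b not in report.scores:
        raise KeyError("variant/target not present in report")
    sa = np.asarray(report.scores[key_a], float)
    sb = np.asarray(report.scores[key_b], float)
    y = np.asarray(report.y, int)
    folds = np.asarray(report.fold_assignment, int)
    if sa.shape != sb.shape:
        raise ValueError("mismatched fold structures between variants")

    def fold_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
        diffs = []
        for f in np.unique(folds):
            idx = folds == f
            ma = compute_metrics(a[idx], _hard_labels(a[idx], report.config["backend"]), y[idx])
            mb = compute_metrics(b[idx], _hard_labels(b[idx], report.config["backend"]), y[idx])
            diffs.append(getattr(ma, metric) - getattr(mb, metric))
        return float(np.mean(diffs))

    observed = fold_mean_diff(sa, sb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        swap = rng.random(len(y)) < 0.5
        pa = np.where(swap, sb, sa)
        pb = np.where(swap, sa, sb)
        if abs(fold_mean_diff(pa, pb)) >= abs(observed) - 1e-12:
            count += 1
    pvalue = (count + 1) / (n_permutations + 1)
    return observed, pvalue
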