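"""Subject-level splitting, classification metrics, and the end-to-end
pipeline.

Partitioning is done at the subject level: all of a participant's
recordings travel into the same partition, stratified by group, with
largest-remainder rounding of the 6:2:2 subject counts (ties go to the
later partition, protecting the test-set size).  T2DM is the positive
class throughout, so recall is sensitivity to disease.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .exceptions import ConfigError, PipelineError, VDT2Error
from .features import FEATURE_NAMES, GROUP_T2DM

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "subject_split",
    "confusion_metrics",
    "roc_auc",
    "run_pipeline",
]


@dataclass
class SplitSpec:
    """Train/validation/test split specification (subject-level)."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify_by: str = "group"
    seed: int = 42
    min_subjects_per_class: int = 5

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError("ratios must be three fractions summing to 1")
        if any(r < 0 for r in self.ratios):
            raise ConfigError("ratios must be non-negative")


def _largest_remainder(n: int, ratios) -> list[int]:
    """Apportion n seats by largest remainder; ties favour later partitions."""
    quotas = np.asarray(ratios, dtype=float) * n
    base = np.floor(quotas).astype(int)
    leftover = n - base.sum()
    # sort by (remainder desc, partition index desc)
    order = sorted(range(len(ratios)), key=lambda i: (quotas[i] - base[i], i), reverse=True)
    for i in order[:leftover]:
        base[i] += 1
    return base.tolist()


def subject_split(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into train/val/test by subject, stratified by class.

    Within each class, subjects are shuffled (seeded) and assigned by
    largest-remainder counts; every subject's rows land in exactly one
    partition.  Errors if a class has too few subjects or a partition ends
    up empty.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    parts: list[list[str]] = [[], [], []]
    for _, block in cohort.groupby(spec.stratify_by):
        subjects = np.array(sorted(block["subject"].unique()))
        if len(subjects) < spec.min_subjects_per_class:
            raise VDT2Error(
                f"need >= {spec.min_subjects_per_class} subjects per class, "
                f"got {len(subjects)}"
            )
        rng.shuffle(subjects)
        counts = _largest_remainder(len(subjects), spec.ratios)
        idx = 0
        for p, c in enumerate(counts):
            parts[p].extend(subjects[idx : idx + c])
            idx += c
    if any(len(p) == 0 for p in parts):
        raise VDT2Error("too few subjects to fill every partition")
    out = tuple(
        cohort[cohort["subject"].isin(p)].reset_index(drop=True) for p in parts
    )
    return out  # type: ignore[return-value]


@dataclass
class MetricsReport:
    """Confusion counts and the four headline screening metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float | None
    specificity: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def confusion_metrics(y_true, y_pred) -> MetricsReport:
    """Accuracy, recall (sensitivity to T2DM) and specificity from 0/1
    labels.  Recall/specificity are ``None`` (not 0) when undefined."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) == 0:
        raise VDT2Error("empty input")
    if len(y_true) != len(y_pred):
        raise VDT2Error("length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise VDT2Error("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(y_true),
        recall=tp / n_pos if n_pos else None,
        specificity=tn / n_neg if n_neg else None,
    )


def roc_auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise VDT2Error("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, ensure_ascii=False)


def run_pipeline(config, outdir, log=print) -> dict:
    """Chain simulate/load -> validity stats -> split -> normalize ->
    select -> train -> evaluate, writing one artifact per stage.

    ``config`` is a dict or YAML path with keys ``input`` (one of
    ``simulate`` (cohort-generator settings), ``features`` (CSV path) or
    ``wav_dir``), ``split``, ``select``, ``model`` and ``eval``.  A global
    ``seed`` seeds every stage that does not override it.  Artifacts are
    stamped with the config hash and seed; reruns with the same config are
    byte-identical.
    """
    from . import acoustic, selection, synth, tree, validity

    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 42))
    stamp = {"config_hash": _config_hash(cfg), "seed": seed}
    artifacts: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            try:
                log(f"[vdt2] stage: {name}")
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    inp = cfg.get("input") or {}
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)

        def _simulate():
            cohort = synth.sample_cohort(synth.CohortConfig(**sim))
            cohort.to_csv(outdir / "features.csv", index=False)
            return cohort

        cohort = stage("simulate")(_simulate)
    elif "features" in inp:
        cohort = stage("load-features")(lambda: pd.read_csv(inp["features"]))
        cohort.to_csv(outdir / "features.csv", index=False)
    elif "wav_dir" in inp:

        def _extract():
            table = acoustic.extract_directory(inp["wav_dir"])
            table.to_csv(outdir / "features.csv", index=False)
            return table

        cohort = stage("extract")(_extract)
    else:
        raise ConfigError(
            "config needs an input source: a 'simulate' block, "
            "input.features or input.wav_dir"
        )
    artifacts["features"] = str(outdir / "features.csv")

    val_cfg = cfg.get("stats", {})

    def _stats():
        report = validity.validity_report(
            cohort,
            variant=val_cfg.get("variant", "welch"),
            n_bins=int(val_cfg.get("bins", 20)),
            group_size=val_cfg.get("group_size"),
        )
        report.to_csv(outdir / "validity.csv", index=False)
        return report

    stage("stats")(_stats)
    artifacts["validity"] = str(outdir / "validity.csv")

    split_cfg = cfg.get("split", {})
    spec = SplitSpec(
        ratios=tuple(split_cfg.get("ratios", (0.6, 0.2, 0.2))),
        seed=int(split_cfg.get("seed", seed)),
    )
    train, val, test = stage("split")(lambda: subject_split(cohort, spec))

    def _normalize():
        norm = selection.fit_normalizer(train)
        return norm, norm.transform(train), norm.transform(val), norm.transform(test)

    norm, train_n, val_n, test_n = stage("normalize")(_normalize)

    sel_cfg = cfg.get("select", {})

    def _select():
        y_train = (train_n["group"] == GROUP_T2DM).astype(int).to_numpy()
        res = selection.select_features(
            train_n[list(FEATURE_NAMES)],
            y_train,
            k=sel_cfg.get("k", 6),
            seed=int(sel_cfg.get("seed", seed)),
        )
        res.to_json(outdir / "selection.json")
        return res

    sel = stage("select")(_select)
    artifacts["selection"] = str(outdir / "selection.json")

    model_cfg = cfg.get("model", {})

    def _train():
        model = tree.VowelDiabetesTree.from_dataframe(
            train_n,
            features=sel.union_set,
            depth=int(model_cfg.get("depth", 4)),
            attention=model_cfg.get("attention", "softmax"),
            l2_penalty=float(model_cfg.get("l2_penalty", 0.0)),
            seed=int(model_cfg.get("seed", seed)),
        )
        res = model.fit(
            max_iter=int(model_cfg.get("max_iter", 200)),
            grad_tol=float(model_cfg.get("grad_tol", 1e-5)),
        )
        res.save(outdir / "model.json")
        return res

    results = stage("train")(_train)
    artifacts["model"] = str(outdir / "model.json")

    eval_cfg = cfg.get("eval", {})
    threshold = float(eval_cfg.get("threshold", 0.5))

    def _evaluate():
        out = dict(stamp)
        for name, part in (("validation", val_n), ("test", test_n)):
            y = (part["group"] == GROUP_T2DM).astype(int).to_numpy()
            scores = results.predict_proba(part)
            preds = (scores >= threshold).astype(int)
            rep = confusion_metrics(y, preds)
            rep.auc = roc_auc(y, scores) if 0 < y.sum() < len(y) else None
            out[name] = rep.to_dict()
        _dump_json(out, outdir / "metrics.json")
        return out

    metrics = stage("evaluate")(_evaluate)
    artifacts["metrics"] = str(outdir / "metrics.json")

    return {"artifacts": artifacts, "metrics": metrics, **stamp}
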