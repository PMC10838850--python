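"""Multiple Instance Ensembling (MIE) prediction and evaluation reports.

The MIE rule averages the softmax probability vectors of the classifier over
the N instance volumes sampled from one sinus:

    y_hat = (1/N) * sum_i softmax(f(x_i))

The single-instance baseline scores a sinus by its first sampled instance
only.  Metrics are AUPRC (step-wise average precision) and F1 with the
anomalous class positive, reported per cross-validation fold and aggregated
as mean +/- sample (n-1) standard deviation.  Percentage-increase reports
across architecture families use the population (n) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score

from .classifier import (ClassifierConfig, TrainedClassifier,
                         predict_proba_batch, train_classifier)
from .dataset import (FoldSplit, LabeledSinus, build_labeled_instances,
                      make_folds)
from .sampling import (CentroidModel, SamplingScheme, Side, SinusInstance,
                       extract_cohort)

#: Decision threshold on p_anomalous; exact ties classify positive.
DECISION_THRESHOLD = 0.5


@dataclass
class EnsemblePrediction:
    """Per-sinus averaged class-probability vector."""

    patient_id: str
    side: Side
    y_hat: np.ndarray              # (p_normal, p_anomalous), sums to 1
    n_instances: int
    instance_probas: np.ndarray    # (N, 2), retained for inspection

    def __post_init__(self) -> None:
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y_hat.shape != (2,) or np.any(self.y_hat < 0) \
                or abs(self.y_hat.sum() - 1.0) > 1e-6:
            raise ValueError("y_hat must be a probability pair")

    @property
    def p_anomalous(self) -> float:
        return float(self.y_hat[1])


def ensemble_predict(model: TrainedClassifier,
                     instances: Sequence[SinusInstance]) -> EnsemblePrediction:
    """MIE prediction for one sinus: the arithmetic mean of the per-instance
    softmax probabilities."""
    if not instances:
        raise ValueError("need at least one instance")
    keys = {(i.patient_id, i.side) for i in instances}
    if len(keys) != 1:
        raise ValueError(f"instances from multiple sinuses: {sorted(keys)}")
    probas = predict_proba_batch(model, instances)
    return EnsemblePrediction(patient_id=instances[0].patient_id,
                              side=instances[0].side,
                              y_hat=probas.mean(axis=0),
                              n_instances=len(instances),
                              instance_probas=probas)


def ensemble_mean(instance_probas: Sequence[Sequence[float]]) -> np.ndarray:
    """The MIE average applied to explicit probability pairs."""
    p = np.asarray(instance_probas, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("expected an (N, 2) array of probability pairs")
    return p.mean(axis=0)


def auprc(labels: Sequence[int], positive_scores: Sequence[float]) -> float:
    """Area under the precision-recall curve via step-wise average precision
    (sum over thresholds of (R_k - R_{k-1}) * P_k, no interpolation)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(positive_scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC undefined: only one class present")
    return float(average_precision_score(y, s))


def f1(labels: Sequence[int], predicted_labels: Sequence[int]) -> float:
    """F1 = 2TP / (2TP + FP + FN) with the anomalous class positive;
    0 when the denominator is 0."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if len(y) == 0:
        raise ValueError("need at least one prediction")
    return float(f1_score(y, p, pos_label=1, zero_division=0))


@dataclass
class MetricsReport:
    """Per-fold AUPRC/F1 with mean +/- sample sd aggregation."""

    per_fold: list[dict]           # each: {'fold', 'auprc', 'f1'}
    evaluation_unit: str           # 'per_sinus_MIE' or 'per_instance'

    def summary(self) -> dict:
        out = {"evaluation_unit": self.evaluation_unit}
        for metric in ("auprc", "f1"):
            vals = [f[metric] for f in self.per_fold]
            m, s = cross_fold_summary(vals) if len(vals) > 1 else (vals[0], 0.0)
            out[f"{metric}_mean"] = m
            out[f"{metric}_sd"] = s
        return out


def evaluate_fold(model: TrainedClassifier,
                  sinus_instances: Mapping[tuple[str, Side], Sequence[SinusInstance]],
                  labels: Mapping[tuple[str, Side], int] | Sequence[LabeledSinus],
                  use_mie: bool = True) -> dict:
    """AUPRC/F1 on one test fold.

    With MIE the evaluation unit is the sinus, scored by the ensemble
    average (Eq. above); without MIE each sinus is scored by its first
    sampled instance only.  Hard labels use threshold 0.5 on p_anomalous
    with ties classified positive.
    """
    if not isinstance(labels, Mapping):
        labels = {(l.patient_id, l.side): l.label for l in labels}
    y_true, scores = [], []
    for key in sorted(sinus_instances):
        insts = sorted(sinus_instances[key], key=lambda i: i.instance_index)
        if key not in labels:
            raise ValueError(f"no label for sinus {key}")
        if use_mie:
            score = ensemble_predict(model, list(insts)).p_anomalous
        else:
            score = float(predict_proba_batch(model, [insts[0]])[0, 1])
        y_true.append(labels[key])
        scores.append(score)
    y_pred = [int(s >= DECISION_THRESHOLD) for s in scores]
    return {"auprc": auprc(y_true, scores), "f1": f1(y_true, y_pred),
            "n_sinuses": len(y_true),
            "evaluation_unit": "per_sinus_MIE" if use_mie else "per_instance"}


def cross_fold_summary(per_fold_metrics: Sequence[float]
                       ) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation across folds."""
    vals = np.asarray(per_fold_metrics, dtype=float)
    if vals.size == 0:
        raise ValueError("no fold metrics given")
    if vals.size < 2:
        raise ValueError("need at least two folds for a sample sd")
    return float(vals.mean()), float(vals.std(ddof=1))


def percentage_increase(baseline: float, variant: float) -> float:
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (variant - baseline) / baseline


def percentage_increase_report(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- population sd of AUPRC percent increases per family.

    ``table`` has one row per architecture with columns ``family``,
    ``baseline`` (single-sample AUPRC), ``sampled`` (N>1 sampling) and
    ``sampled_mie`` (sampling + MIE).  For each family and each variant the
    report gives the mean and population (n) standard deviation of
    100*(variant - baseline)/baseline across the family's rows.
    """
    required = {"family", "baseline", "sampled", "sampled_mie"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["baseline"] <= 0).any():
        raise ValueError("all baselines must be > 0")
    rows = []
    for family, grp in table.groupby("family", sort=False):
        for variant in ("sampled", "sampled_mie"):
            inc = 100.0 * (grp[variant] - grp["baseline"]) / grp["baseline"]
            rows.append({"family": family, "variant": variant,
                         "mean_increase_pct": float(inc.mean()),
                         "sd_increase_pct": float(inc.std(ddof=0)),
                         "n_architectures": len(grp)})
    return pd.DataFrame(rows)


def relative_decrease(reference_auprc: float, variant_auprc: float) -> float:
    """Percent AUPRC decrease of a variant relative to a reference."""
    if reference_auprc <= 0:
        raise ValueError("reference AUPRC must be > 0")
    return 100.0 * (reference_auprc - variant_auprc) / reference_auprc


# -- experiment orchestration -------------------------------------------------

def run_cv_experiment(volumes, labels: Sequence[LabeledSinus],
                      folds: Sequence[FoldSplit], model: CentroidModel,
                      scheme: SamplingScheme, patch_size: int,
                      config: ClassifierConfig,
                      use_mie: bool = True,
                      also_single_instance: bool = False):
    """Extract -> train -> evaluate over cross-validation folds.

    ``volumes`` is a sequence (or other iterable) of VolumeImage.  Returns a
    MetricsReport, or a pair (mie_report, single_instance_report) when
    ``also_single_instance`` is set (both evaluated with the same trained
    model per fold).
    """
    cohort = extract_cohort(volumes, model, scheme, patch_size)
    label_list = list(labels)
    label_map = {(l.patient_id, l.side): l.label for l in label_list}
    per_fold_mie, per_fold_single = [], []
    for fold in folds:
        part_of = fold.assignment
        def subset(partition):
            keys = [k for k in cohort if part_of.get(k[0]) == partition]
            insts = [i for k in keys for i in cohort[k]]
            return build_labeled_instances(insts, label_list)
        trained = train_classifier(subset("train"), subset("val"),
                                   ClassifierConfig(**{
                                       **config.__dict__,
                                       "seed": config.seed + fold.fold_index}))
        test_map = {k: v for k, v in cohort.items()
                    if part_of.get(k[0]) == "test"}
        res = evaluate_fold(trained, test_map, label_map, use_mie=use_mie)
        res["fold"] = fold.fold_index
        per_fold_mie.append(res)
        if also_single_instance:
            res1 = evaluate_fold(trained, test_map, label_map, use_mie=False)
            res1["fold"] = fold.fold_index
            per_fold_single.append(res1)
    mie_report = MetricsReport(per_fold=per_fold_mie,
                               evaluation_unit="per_sinus_MIE" if use_mie
                               else "per_instance")
    if also_single_instance:
        return mie_report, MetricsReport(per_fold=per_fold_single,
                                         evaluation_unit="per_instance")
    return mie_report


def sampling_strategy_comparison(volumes, labels: Sequence[LabeledSinus],
                                 strategies: Sequence[SamplingScheme],
                                 model: CentroidModel, patch_size: int,
                                 config: ClassifierConfig,
                                 folds: Sequence[FoldSplit] | None = None,
                                 k: int = 3, seed: int = 0) -> pd.DataFrame:
    """Rerun extract->train->evaluate per sampling strategy with shared
    folds and seeds; one row of mean +/- sd AUPRC/F1 per strategy."""
    volumes = list(volumes)
    if folds is None:
        folds = make_folds(labels, k=k, seed=seed)
    rows = []
    for scheme in strategies:
        report = run_cv_experiment(volumes, labels, folds, model,
                                   scheme, patch_size, config, use_mie=True)
        s = report.summary()
        rows.append({"strategy": scheme.label(), "mode": scheme.mode,
                     "vary_x": scheme.vary[0], "vary_y": scheme.vary[1],
                     "vary_z": scheme.vary[2], "n": scheme.n,
                     "auprc_mean": s["auprc_mean"], "auprc_sd": s["auprc_sd"],
                     "f1_mean": s["f1_mean"], "f1_sd": s["f1_sd"]})
    return pd.DataFrame(rows)
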