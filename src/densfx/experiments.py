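"""End-to-end orchestration: cohort splitting, the two pipelines, the
DSC-stability grid and a split-isolation (leakage) audit.

Test-set isolation is enforced by construction: classifier fitting and any
standardization statistics only ever see training-split rows; the validation
split is reserved for neural checkpoint selection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import ClassifierSpec, EvalResult, evaluate, fit_classifier
from .errors import ParameterError, SplitError, ValidationError
from .io import Mask, Volume, resample_isotropic, zscore_normalize
from .mask_analysis import PerturbationPlan, perturb_to_dsc
from .nn import (
    M1Config,
    TrainingConfig,
    UNetConfig,
    predict_m1,
    predict_mask,
    train_m1,
    train_segmenter,
)
from .radiomics import FEATURE_SCHEMA, DiscretizationSpec, extract_all
from .windowing import WindowSpec, apply_windowing

__all__ = [
    "SplitPlan",
    "split_dataset",
    "run_m2_pipeline",
    "run_m1_pipeline",
    "stability_analysis",
    "leakage_audit",
    "StabilityGrid",
    "PipelineResult",
    "DEFAULT_DSC_LEVELS",
]

#: DSC levels exercised by the stability analysis (0.82 ... 0.94, step 0.02)
DEFAULT_DSC_LEVELS = tuple(round(0.82 + 0.02 * i, 2) for i in range(7))


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test fractions with the floor / half-up-round /
    remainder size rule; assignment is a seeded permutation, optionally
    stratified by label."""

    fractions: tuple = (0.70, 0.10, 0.20)
    stratified: bool = False
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9 or len(self.fractions) != 3:
            raise ParameterError(f"fractions must be 3 values summing to 1, got {self.fractions}")


def _split_sizes(n: int, fractions) -> tuple:
    n_train = int(math.floor(n * fractions[0]))
    n_val = int(math.floor(n * fractions[1] + 0.5))
    n_test = n - n_train - n_val
    return n_train, n_val, n_test


def split_dataset(case_ids, plan: SplitPlan, labels=None) -> tuple:
    """Partition ids into disjoint, exhaustive (train, val, test) lists.

    Stratified mode applies the same size rule within each class and
    concatenates, guaranteeing both classes in every split when each class
    is large enough.
    """
    ids = list(case_ids)
    n = len(ids)
    if n < 3:
        raise SplitError(f"need at least 3 cases to split, got {n}")
    rng = np.random.default_rng(plan.seed)
    if plan.stratified:
        if labels is None:
            raise ParameterError("stratified splitting requires labels")
        labels = np.asarray(labels)
        train, val, test = [], [], []
        for cls in np.unique(labels):
            sub = [ids[i] for i in np.flatnonzero(labels == cls)]
            nt, nv, _ = _split_sizes(len(sub), plan.fractions)
            perm = rng.permutation(len(sub))
            train += [sub[i] for i in perm[:nt]]
            val += [sub[i] for i in perm[nt : nt + nv]]
            test += [sub[i] for i in perm[nt + nv :]]
    else:
        nt, nv, _ = _split_sizes(n, plan.fractions)
        perm = rng.permutation(n)
        train = [ids[i] for i in perm[:nt]]
        val = [ids[i] for i in perm[nt : nt + nv]]
        test = [ids[i] for i in perm[nt + nv :]]
    if not train or not val or not test:
        raise SplitError(
            f"split of {n} cases with fractions {plan.fractions} leaves an empty partition"
        )
    return train, val, test


@dataclass
class PipelineResult:
    """Evaluation on the held-out test split plus run metadata."""

    eval: EvalResult
    excluded: int
    meta: dict = field(default_factory=dict)


def _prepare_cohort(cohort, resample_mm: float):
    """Resample every case to isotropic resolution once; returns
    (volume, dens_mask, label) triples on the working grid."""
    prepared = []
    for case in cohort:
        vol = resample_isotropic(case.volume, resample_mm)
        mask = resample_isotropic(case.dens_mask, resample_mm)
        prepared.append((vol, mask, bool(case.label)))
    return prepared


def _case_mask(mask: Mask, seg_source, seed: int, idx: int) -> Mask:
    if seg_source == "oracle":
        return mask
    if isinstance(seg_source, tuple) and seg_source[0] == "perturbed":
        target = float(seg_source[1])
        pseed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % 2**31)
        return perturb_to_dsc(mask, PerturbationPlan(target_dsc=target, seed=pseed))
    raise ParameterError(f"unknown seg_source {seg_source!r}")


def _feature_table(prepared, masks, window_spec, disc, feature_intensity):
    rows, labels, excluded = [], [], 0
    keep_idx = []
    for i, ((vol, _, lab), mask) in enumerate(zip(prepared, masks)):
        if mask.is_empty():
            excluded += 1
            continue
        if window_spec.method == "roi":
            windowed = apply_windowing(vol, window_spec, mask=mask)
        else:
            windowed = apply_windowing(vol, window_spec)
        if feature_intensity == "windowed":
            # x1000 rescale keeps bin widths meaningful across methods
            ivol = windowed.with_data(windowed.data * 1000.0)
        elif feature_intensity == "raw":
            ivol = vol
        else:
            raise ParameterError(f"feature_intensity must be 'windowed' or 'raw'")
        fv = extract_all(ivol, mask, disc)
        rows.append(fv.values)
        labels.append(int(lab))
        keep_idx.append(i)
    table = pd.DataFrame(np.array(rows), columns=list(FEATURE_SCHEMA))
    return table, np.array(labels), keep_idx, excluded


def run_m2_pipeline(
    cohort,
    window_spec: WindowSpec,
    classifier_spec: ClassifierSpec,
    split_plan: SplitPlan,
    seg_source="oracle",
    disc: DiscretizationSpec | None = None,
    feature_intensity: str = "windowed",
    resample_mm: float = 1.0,
    seg_train_cfg: TrainingConfig | None = None,
    seg_net_cfg: UNetConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Two-stage pipeline: (segment | oracle | perturbed mask) -> windowing
    -> radiomics -> classifier fitted on the training split, evaluated on
    the test split.

    ``seg_source``: ``"oracle"`` (ground-truth masks), ``("perturbed", dsc)``
    (oracle masks degraded to a DSC target), or ``"trained"`` (fit the
    segmentation network on the training split and use its predictions).
    """
    disc = disc or DiscretizationSpec()
    labels_all = [bool(c.label) for c in cohort]
    idx = list(range(len(cohort)))
    tr, va, te = split_dataset(idx, split_plan, labels=labels_all)
    prepared = _prepare_cohort(cohort, resample_mm)

    if seg_source == "trained":
        cfg = seg_train_cfg or TrainingConfig(input_shape=(16, 16, 16), max_epochs=5)
        pre = []
        for vol, mask, lab in prepared:
            w = apply_windowing(vol, window_spec, mask=mask if window_spec.method == "roi" else None)
            pre.append((zscore_normalize(w).data, mask.data, lab))
        model = train_segmenter([pre[i] for i in tr], [pre[i] for i in va], cfg, seg_net_cfg)
        masks = []
        for i, (vol, mask, lab) in enumerate(prepared):
            if i in set(te):
                w = apply_windowing(vol, window_spec, mask=mask if window_spec.method == "roi" else None)
                masks.append(predict_mask(model, zscore_normalize(w)))
            else:
                masks.append(mask)  # oracle masks guide training-split features
    else:
        masks = [_case_mask(prepared[i][1], seg_source, seed, i) for i in idx]

    table, labels, keep, excluded = _feature_table(prepared, masks, window_spec, disc, feature_intensity)
    pos = {orig: row for row, orig in enumerate(keep)}
    tr_rows = [pos[i] for i in tr if i in pos]
    te_rows = [pos[i] for i in te if i in pos]
    if np.unique(labels[tr_rows]).size < 2 or np.unique(labels[te_rows]).size < 2:
        raise ValidationError("both classes must be present in the train and test splits")
    model = fit_classifier(table.iloc[tr_rows], labels[tr_rows], classifier_spec)
    result = evaluate(model, table.iloc[te_rows], labels[te_rows])
    meta = {
        "window": window_spec.method,
        "classifier": classifier_spec.algorithm,
        "seg_source": str(seg_source),
        "split_seed": split_plan.seed,
        "seed": seed,
        "n_train": len(tr_rows),
        "n_test": len(te_rows),
    }
    return PipelineResult(eval=result, excluded=excluded, meta=meta)


def run_m1_pipeline(
    cohort,
    window_spec: WindowSpec,
    m1_cfg: M1Config | None = None,
    train_cfg: TrainingConfig | None = None,
    split_plan: SplitPlan | None = None,
    resample_mm: float = 1.0,
) -> PipelineResult:
    """Single-stage pipeline: windowing -> z-score -> CNN+FNN classifier.

    Ground-truth masks are used only for the dens-retaining crop constraint
    during training-set augmentation and the centered evaluation crop,
    mirroring the training-time use of annotations in a single-stage setup.
    """
    split_plan = split_plan or SplitPlan()
    train_cfg = train_cfg or TrainingConfig(learning_rate=0.001, input_shape=(16, 16, 16), max_epochs=8)
    labels_all = [bool(c.label) for c in cohort]
    idx = list(range(len(cohort)))
    tr, va, te = split_dataset(idx, split_plan, labels=labels_all)
    prepared = _prepare_cohort(cohort, resample_mm)
    pre = []
    for vol, mask, lab in prepared:
        w = apply_windowing(vol, window_spec, mask=mask if window_spec.method == "roi" else None)
        pre.append((zscore_normalize(w).data, mask.data, lab))

    model = train_m1([pre[i] for i in tr], [pre[i] for i in va], train_cfg, m1_cfg)
    probs = predict_m1(model, [pre[i] for i in te])
    preds = (probs[:, 1] >= 0.5).astype(int)
    y = np.array([int(labels_all[i]) for i in te])
    from .classification import balanced_accuracy, confusion_counts

    cc = confusion_counts(y, preds)
    result = EvalResult(
        **cc,
        accuracy=float((cc["tp"] + cc["tn"]) / y.size),
        balanced_accuracy=float(balanced_accuracy(**cc)),
        predictions=tuple(int(v) for v in preds),
    )
    meta = {
        "window": window_spec.method,
        "model": "m1",
        "split_seed": split_plan.seed,
        "best_val_metric": model.best_val_metric,
        "probabilities": probs.tolist(),
        "n_test": len(te),
    }
    return PipelineResult(eval=result, excluded=0, meta=meta)


@dataclass
class StabilityGrid:
    """Accuracy and balanced accuracy indexed by DSC level, windowing
    method and classifier (long format; one row per seed)."""

    frame: pd.DataFrame
    complete: bool
    meta: dict = field(default_factory=dict)

    def table(self, metric: str = "accuracy") -> pd.DataFrame:
        """(window, classifier) x DSC pivot of seed-averaged values."""
        return self.frame.pivot_table(
            index=["window", "classifier"], columns="dsc", values=metric, aggfunc="mean"
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def heatmap(self, path) -> None:
        """Two-panel heatmap (accuracy left, balanced accuracy right),
        darker shades meaning higher values."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(12, 4 + 0.3 * len(self.table())))
        for ax, metric in zip(axes, ("accuracy", "balanced_accuracy")):
            piv = self.table(metric)
            im = ax.imshow(piv.to_numpy(), cmap="Greys", vmin=0.0, vmax=1.0, aspect="auto")
            ax.set_xticks(range(piv.shape[1]), [f"{c:.2f}" for c in piv.columns])
            ax.set_yticks(range(piv.shape[0]), [f"{w}/{c}" for w, c in piv.index])
            ax.set_xlabel("DSC level")
            ax.set_title(metric.replace("_", " "))
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def stability_analysis(
    cohort,
    dsc_levels=DEFAULT_DSC_LEVELS,
    window_specs: dict | None = None,
    classifier_specs: dict | None = None,
    split_plan: SplitPlan | None = None,
    seeds=(0,),
    **pipeline_kwargs,
) -> StabilityGrid:
    """One perturbed-mask M2 run per (DSC level, windowing, classifier,
    seed) cell; failures leave the grid marked incomplete with partial
    results preserved."""
    if not dsc_levels or not all(0.0 < d <= 1.0 for d in dsc_levels):
        raise ParameterError("dsc_levels must be non-empty and within (0, 1]")
    window_specs = window_specs or {"roi": WindowSpec(method="roi")}
    classifier_specs = classifier_specs or {"knn": ClassifierSpec(algorithm="knn")}
    split_plan = split_plan or SplitPlan(stratified=True)
    rows, complete = [], True
    for wname, wspec in window_specs.items():
        for cname, cspec in classifier_specs.items():
            for level in dsc_levels:
                for seed in seeds:
                    src = "oracle" if level == 1.0 else ("perturbed", level)
                    try:
                        res = run_m2_pipeline(
                            cohort, wspec, cspec, split_plan,
                            seg_source=src, seed=seed, **pipeline_kwargs,
                        )
                    except Exception:
                        complete = False
                        continue
                    rows.append(
                        {
                            "dsc": level,
                            "window": wname,
                            "classifier": cname,
                            "seed": seed,
                            "accuracy": res.eval.accuracy,
                            "balanced_accuracy": res.eval.balanced_accuracy,
                        }
                    )
    frame = pd.DataFrame(rows)
    meta = {"seeds": tuple(seeds), "n_cases": len(cohort), "levels": tuple(dsc_levels)}
    return StabilityGrid(frame=frame, complete=complete, meta=meta)


def leakage_audit(
    cohort,
    window_spec: WindowSpec | None = None,
    split_plan: SplitPlan | None = None,
    resample_mm: float = 1.0,
    seed: int = 0,
) -> dict:
    """Split-isolation audit: a marker column carrying the true label is
    planted in test rows only, and the pipeline is re-run with a
    decision-tree classifier (which can only use splits learned from
    training rows, where the marker is constant zero). Any accuracy change
    would prove that test information reached the fitting stage."""
    window_spec = window_spec or WindowSpec(method="bone")
    split_plan = split_plan or SplitPlan(stratified=True)
    spec = ClassifierSpec(algorithm="decision_tree", seed=seed)
    disc = DiscretizationSpec()
    labels_all = [bool(c.label) for c in cohort]
    idx = list(range(len(cohort)))
    tr, va, te = split_dataset(idx, split_plan, labels=labels_all)
    prepared = _prepare_cohort(cohort, resample_mm)
    masks = [m for _, m, _ in prepared]
    table, labels, keep, _ = _feature_table(prepared, masks, window_spec, disc, "windowed")
    pos = {orig: row for row, orig in enumerate(keep)}
    tr_rows = [pos[i] for i in tr]
    te_rows = [pos[i] for i in te]

    model = fit_classifier(table.iloc[tr_rows], labels[tr_rows], spec)
    base = evaluate(model, table.iloc[te_rows], labels[te_rows])

    marked = table.copy()
    marked["audit_marker"] = 0.0
    marked.loc[marked.index[te_rows], "audit_marker"] = labels[te_rows] * 1e3
    model_m = fit_classifier(marked.iloc[tr_rows], labels[tr_rows], spec)
    with_marker = evaluate(model_m, marked.iloc[te_rows], labels[te_rows])
    return {
        "accuracy_clean": base.accuracy,
        "accuracy_marked": with_marker.accuracy,
        "delta": abs(base.accuracy - with_marker.accuracy),
        "predictions_identical": base.predictions == with_marker.predictions,
    }
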