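"""Protocol orchestration: random splits, multi-run evaluation, kernel and
ratio comparisons, model selection and overlap analysis.

One *run* is an independent random split of the modelling set into
training and test subsets, followed by the full pipeline fitted without
ever touching the test or external rows: scaling on training rows,
F-score ranking, correlation pruning, greedy forward selection against a
training-internal cross-validated accuracy, an exponential (C, γ) grid
search, and a final fit on the whole training set. The external set enters
exactly once per run, for evaluation. Averaging the per-category metrics
over many runs (100 by convention) gives the protocol's headline numbers.

The best single model is the run with the smallest |training − test|
accuracy gap, then the fewest selected descriptors — a deliberately
anti-overfitting rule; external performance never participates in the
ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .chem_io import (
    NON_SUBSTRATE,
    SUBSTRATE,
    Molecule,
    molecule_from_smiles,
    read_sdf,
)
from .descriptors import (
    NATIVE_DESCRIPTORS,
    DescriptorMatrix,
)
from .evaluation import PerformanceReport, classification_overlap, evaluate
from .feature_selection import (
    SelectionTrace,
    greedy_forward_selection,
    prune_correlated,
    rank_features,
)
from .preprocess import ScalingParams, apply_scaling, filter_descriptors, fit_scaling
from .svm_engine import (
    C_GRID,
    GAMMA_GRID,
    GridSearchResult,
    KernelSpec,
    SVMConfig,
    TrainedModel,
    _fit_svc,
    grid_search,
    load_model,
    train,
)


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    fraction: float = 0.75
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ExperimentError("train fraction must be in (0, 1)")


def random_split(
    ids: Sequence[str],
    spec: SplitSpec,
    labels: pd.Series | Mapping[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive (train, test) partition; |train| = floor(f·n).

    Stratified mode preserves the class ratio to within one compound per
    class and requires ``labels``.
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 2:
        raise ExperimentError("need at least 2 ids to split")
    n_train = int(math.floor(spec.fraction * n))
    if n_train == 0 or n_train == n:
        raise ExperimentError("fraction leaves an empty train or test side")
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        train_ids = [ids[i] for i in sorted(perm[:n_train])]
        test_ids = [ids[i] for i in sorted(perm[n_train:])]
        return train_ids, test_ids
    if labels is None:
        raise ExperimentError("stratified split requires labels")
    labels = pd.Series(labels)
    classes: dict[str, list[str]] = {}
    for i in ids:
        classes.setdefault(str(labels[i]), []).append(i)
    # largest-remainder allocation of n_train across classes
    quotas = {c: spec.fraction * len(members) for c, members in classes.items()}
    base = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n_train - sum(base.values())
    for c in sorted(classes, key=lambda c: -(quotas[c] - base[c]))[:short]:
        base[c] += 1
    train_ids: list[str] = []
    for c, members in classes.items():
        perm = rng.permutation(len(members))
        train_ids += [members[i] for i in perm[: base[c]]]
    train_set = set(train_ids)
    return [i for i in ids if i in train_set], [i for i in ids if i not in train_set]


@dataclass
class RunRecord:
    """One random-split experiment: seed, selection trace, per-set reports."""

    index: int
    seed: int
    split: SplitSpec
    train_ids: list[str]
    test_ids: list[str]
    selected_features: list[str]
    grid: GridSearchResult
    model: TrainedModel
    reports: dict[str, PerformanceReport]  # training / test / external
    trace: SelectionTrace

    @property
    def accuracy_gap(self) -> float:
        return abs(self.reports["training"].acc - self.reports["test"].acc)


@dataclass
class ProtocolResult:
    records: list[RunRecord]
    failures: list[tuple[int, str]]
    kernel: str
    fraction: float
    base_seed: int

    def mean_reports(self) -> dict[str, dict[str, float]]:
        """Per-category means of ACC/SE/SP/MCC over successful runs.

        Undefined (None) entries are excluded from their metric's mean.
        """
        out: dict[str, dict[str, float]] = {}
        for cat in ("training", "test", "external"):
            metrics: dict[str, float] = {}
            for key in ("acc", "se", "sp", "mcc"):
                vals = [
                    getattr(r.reports[cat], key)
                    for r in self.records
                    if getattr(r.reports[cat], key) is not None
                ]
                metrics[key] = float(np.mean(vals)) if vals else float("nan")
            out[cat] = metrics
        return out

    def report_text(self) -> str:
        lines = [
            f"kernel: {self.kernel}",
            f"fraction: {self.fraction!r}",
            f"base_seed: {self.base_seed}",
            f"n_runs: {len(self.records)}",
            f"n_failures: {len(self.failures)}",
            "run\tseed\tn_features\tC\tgamma\tacc_train\tacc_test\tacc_external",
        ]
        for r in self.records:
            lines.append(
                f"{r.index}\t{r.seed}\t{len(r.selected_features)}\t"
                f"{r.grid.best_C!r}\t{r.grid.best_gamma!r}\t"
                f"{r.reports['training'].acc:.6f}\t{r.reports['test'].acc:.6f}\t"
                f"{r.reports['external'].acc:.6f}"
            )
        means = self.mean_reports()
        for cat in ("training", "test", "external"):
            m = means[cat]
            lines.append(
                f"mean_{cat}\tACC={m['acc']:.6f}\tSE={m['se']:.6f}\t"
                f"SP={m['sp']:.6f}\tMCC={m['mcc']:.6f}"
            )
        return "\n".join(lines) + "\n"


def _cv_accuracy(
    X: np.ndarray, y01: np.ndarray, cfg: SVMConfig, folds: int, seed: int
) -> float:
    minority = min(int(y01.sum()), int((1 - y01).sum()))
    folds = max(2, min(folds, minority))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    yy = np.where(y01 == 1, 1, -1)
    correct = 0
    for tr, te in skf.split(X, yy):
        svc = _fit_svc(X[tr], yy[tr], cfg)
        correct += int((svc.predict(X[te]) == yy[te]).sum())
    return correct / len(yy)


def _run_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_protocol(
    dm: DescriptorMatrix,
    labels: pd.Series | Mapping[str, str],
    external_dm: DescriptorMatrix,
    external_labels: pd.Series | Mapping[str, str],
    *,
    fraction: float = 0.75,
    kernel: str = "rbf",
    n_runs: int = 100,
    base_seed: int = 0,
    stratified: bool = False,
    filter_per_split: bool = False,
    r_threshold: float = 0.9,
    max_candidates: int = 30,
    C_grid: Sequence[float] = C_GRID,
    gamma_grid: Sequence[float] = GAMMA_GRID,
    grid_folds: int = 5,
    selection_folds: int = 3,
    degree: int = 3,
    coef0: float = 0.0,
    max_failure_fraction: float = 0.1,
) -> ProtocolResult:
    """Run ``n_runs`` independent random-split experiments and average them.

    The modelling set and the external set must be disjoint; the external
    rows are used only for the once-per-run external evaluation. Descriptor
    elimination is applied once to the modelling matrix before splitting
    (the conventional reading of the method order); ``filter_per_split``
    refits the filters on each training split instead.
    """
    labels = pd.Series(labels)
    external_labels = pd.Series(external_labels)
    if set(dm.ids) & set(external_dm.ids):
        raise ExperimentError("modelling and external sets overlap")

    if not filter_per_split:
        dm, _ = filter_descriptors(dm)
        external_dm = external_dm.select_columns(dm.descriptor_names)

    seeds = _run_seeds(base_seed, n_runs)
    records: list[RunRecord] = []
    failures: list[tuple[int, str]] = []
    for run_idx, seed in enumerate(seeds):
        try:
            records.append(
                _single_run(
                    run_idx, seed, dm, labels, external_dm, external_labels,
                    fraction=fraction, kernel=kernel, stratified=stratified,
                    filter_per_split=filter_per_split, r_threshold=r_threshold,
                    max_candidates=max_candidates, C_grid=C_grid,
                    gamma_grid=gamma_grid, grid_folds=grid_folds,
                    selection_folds=selection_folds, degree=degree, coef0=coef0,
                )
            )
        except Exception as exc:  # run-level failure policy
            failures.append((run_idx, f"{type(exc).__name__}: {exc}"))
            if len(failures) > max_failure_fraction * n_runs:
                raise ExperimentError(
                    f"more than {max_failure_fraction:.0%} of runs failed; "
                    f"last error: {failures[-1][1]}"
                ) from exc
    return ProtocolResult(
        records=records, failures=failures, kernel=kernel,
        fraction=fraction, base_seed=base_seed,
    )


def _single_run(
    run_idx, seed, dm, labels, external_dm, external_labels, *, fraction,
    kernel, stratified, filter_per_split, r_threshold, max_candidates,
    C_grid, gamma_grid, grid_folds, selection_folds, degree, coef0,
) -> RunRecord:
    split = SplitSpec(fraction=fraction, seed=seed, stratified=stratified)
    train_ids, test_ids = random_split(dm.ids, split, labels)

    work_dm, work_ext = dm, external_dm
    if filter_per_split:
        filtered, _ = filter_descriptors(dm.select_rows(train_ids))
        cols = filtered.descriptor_names
        work_dm = dm.select_columns(cols)
        work_ext = external_dm.select_columns(cols)

    scaling = fit_scaling(work_dm, train_ids, fitted_on=f"run{run_idx}")
    scaled = apply_scaling(work_dm, scaling)
    scaled_ext = apply_scaling(work_ext, scaling)

    train_dm = scaled.select_rows(train_ids)
    y_train = labels.loc[train_ids]
    scores = rank_features(train_dm, y_train)
    survivors, prune_trace = prune_correlated(train_dm, scores, r_threshold)
    ranked = [s.name for s in scores if s.name in set(survivors)]

    y01 = (y_train == SUBSTRATE).to_numpy().astype(int)
    frame = train_dm.frame
    majority = max(y01.mean(), 1 - y01.mean())

    def evaluate_subset(features: list[str]) -> float:
        X = frame[features].to_numpy()
        gamma = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
        cfg = SVMConfig(C=1.0, kernel=KernelSpec(kernel, gamma=gamma, degree=degree, coef0=coef0))
        return _cv_accuracy(X, y01, cfg, selection_folds, seed)

    trace = greedy_forward_selection(
        train_dm, y_train, ranked, evaluate_subset,
        baseline=majority, max_features=max_candidates,
    )
    trace.pruned_pairs = prune_trace.pruned_pairs
    selected = trace.selected

    grid = grid_search(
        frame[selected], list(y_train), C_grid=C_grid, gamma_grid=gamma_grid,
        folds=grid_folds, seed=seed, kernel_kind=kernel, degree=degree, coef0=coef0,
    )
    cfg = grid.best_config(kernel, degree=degree, coef0=coef0)
    model_scaling = ScalingParams(
        columns=selected,
        mins=np.array([scaling.mins[scaling.columns.index(c)] for c in selected]),
        maxs=np.array([scaling.maxs[scaling.columns.index(c)] for c in selected]),
        fitted_on=scaling.fitted_on,
    )
    model = train(frame, list(y_train), cfg, feature_names=selected, scaling=model_scaling)

    reports = {}
    for cat, part, truth in (
        ("training", scaled.select_rows(train_ids), labels.loc[train_ids]),
        ("test", scaled.select_rows(test_ids), labels.loc[test_ids]),
        ("external", scaled_ext, external_labels.loc[scaled_ext.ids]),
    ):
        pred, _ = model.predict(part.select_columns(selected))
        reports[cat] = evaluate(list(truth), pred)

    return RunRecord(
        index=run_idx, seed=seed, split=split,
        train_ids=train_ids, test_ids=test_ids,
        selected_features=selected, grid=grid, model=model,
        reports=reports, trace=trace,
    )


# ---------------------------------------------------------------------------
# protocol variants


def compare_kernels(
    dm, labels, external_dm, external_labels, *,
    kernels: Sequence[str] = ("linear", "polynomial", "rbf"),
    fraction: float = 0.75, n_runs: int = 100, base_seed: int = 0, **kwargs,
) -> dict[str, ProtocolResult]:
    """One full protocol per kernel, same base seed (so splits coincide)."""
    return {
        k: run_protocol(
            dm, labels, external_dm, external_labels,
            fraction=fraction, kernel=k, n_runs=n_runs, base_seed=base_seed, **kwargs,
        )
        for k in kernels
    }


def sweep_ratios(
    dm, labels, external_dm, external_labels, *,
    fractions: Sequence[float] = (0.5, 0.6, 0.7, 0.75, 0.8, 0.85),
    kernel: str = "rbf", n_runs: int = 100, base_seed: int = 0, **kwargs,
) -> dict[float, ProtocolResult]:
    """One full protocol per training fraction."""
    return {
        f: run_protocol(
            dm, labels, external_dm, external_labels,
            fraction=f, kernel=kernel, n_runs=n_runs, base_seed=base_seed, **kwargs,
        )
        for f in fractions
    }


def protocol_table_text(results: Mapping[str | float, ProtocolResult]) -> str:
    """Mean-performance table, one row per (setting, category)."""
    lines = ["setting\tcategory\tACC\tSE\tSP\tMCC"]
    for key, res in results.items():
        means = res.mean_reports()
        for cat in ("training", "test", "external"):
            m = means[cat]
            lines.append(
                f"{key}\t{cat}\t{m['acc']:.1f}\t{m['se']:.1f}\t{m['sp']:.1f}\t{m['mcc']:.3f}"
            )
    return "\n".join(lines) + "\n"


def select_best_model(runs: Sequence[RunRecord]) -> list[RunRecord]:
    """Rank runs by (|ACC_train − ACC_test|, feature count, run index).

    External performance is deliberately excluded from the ranking; the
    winner is the head of the returned list.
    """
    if not runs:
        raise ExperimentError("no successful runs to select from")
    return sorted(runs, key=lambda r: (r.accuracy_gap, len(r.selected_features), r.index))


@dataclass
class OverlapMatrix:
    model_ids: list[str]
    matrix: np.ndarray  # symmetric percentages, diagonal 100

    def summary(self) -> dict[str, float]:
        iu = np.triu_indices(len(self.model_ids), k=1)
        off = self.matrix[iu]
        return {
            "min": float(off.min()),
            "max": float(off.max()),
            "mean": float(off.mean()),
        }

    def to_text(self) -> str:
        lines = ["model\t" + "\t".join(self.model_ids)]
        for mid, row in zip(self.model_ids, self.matrix):
            lines.append(mid + "\t" + "\t".join(f"{v:.2f}" for v in row))
        return "\n".join(lines) + "\n"


def overlap_matrix(
    models: Sequence[TrainedModel],
    dm: DescriptorMatrix,
    model_ids: Sequence[str] | None = None,
    already_scaled: bool = False,
) -> OverlapMatrix:
    """Pairwise classification overlap of several models on one compound set.

    ``dm`` holds raw descriptor values by default; each model applies its
    own stored scaling before predicting.
    """
    if len(models) < 2:
        raise ExperimentError("need at least 2 models for overlap analysis")
    if model_ids is None:
        model_ids = [f"m{k + 1}" for k in range(len(models))]
    preds = []
    for model in models:
        sub = dm.select_columns(model.feature_names)
        if model.scaling is not None and not already_scaled:
            sub = apply_scaling(sub, model.scaling)
        labels, _ = model.predict(sub)
        preds.append(labels)
    k = len(models)
    mat = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = classification_overlap(preds[i], preds[j])
    return OverlapMatrix(model_ids=list(model_ids), matrix=mat)


def predict_compound(
    model: TrainedModel | str | Path,
    structure: str | Path | Molecule | Sequence[Molecule],
) -> list[dict]:
    """End-to-end prediction for query structures against a saved model.

    ``structure`` may be a SMILES string, an SDF path, a Molecule, or a
    list of Molecules. Every model feature must be a natively computable
    descriptor; models built on ingested descriptor tables cannot predict
    from raw structures. 2D-only inputs are refused when the model uses 3D
    descriptors (supply an SDF with coordinates instead).
    """
    if not isinstance(model, TrainedModel):
        model = load_model(model)
    non_native = [f for f in model.feature_names if f not in NATIVE_DESCRIPTORS]
    if non_native:
        raise ExperimentError(
            f"model uses descriptors that cannot be computed from structure: {non_native}"
        )
    if isinstance(structure, Molecule):
        mols = [structure]
    elif isinstance(structure, (list, tuple)):
        mols = list(structure)
    else:
        text = str(structure)
        if text.lower().endswith(".sdf") or Path(text).exists():
            mols = read_sdf(text)
        else:
            mols = [molecule_from_smiles(text)]
    needs_3d = any(f != "AAC" for f in model.feature_names)
    out = []
    for k, mol in enumerate(mols):
        if needs_3d and not mol.has_3d:
            raise ExperimentError(
                f"molecule {mol.name or k} is 2D-only but the model uses 3D "
                "descriptors; provide an SDF with 3D coordinates"
            )
        values = {f: NATIVE_DESCRIPTORS[f](mol) for f in model.feature_names}
        frame = pd.DataFrame([values], index=[mol.name or f"query{k + 1}"])
        sub = DescriptorMatrix(frame)
        if model.scaling is not None:
            sub = apply_scaling(sub, model.scaling)
        labels, decisions = model.predict(sub)
        out.append(
            {
                "id": mol.name or f"query{k + 1}",
                "label": labels[0],
                "decision_value": float(decisions[0]),
                "descriptors": values,
            }
        )
    return out
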