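"""F-score ranking and the two-step wrapper feature-selection schedule.

The discriminative power of feature ``i`` between two classes is scored
with the F-score

    F(i) = [ (x+_i - x_i)^2 + (x-_i - x_i)^2 ]
           / [ 1/(n+ - 1) * sum_k (x+_{k,i} - x+_i)^2
             + 1/(n- - 1) * sum_k (x-_{k,i} - x-_i)^2 ]

where x_i, x+_i and x-_i are the overall, positive-class and
negative-class means and n+, n- the class sizes.  A larger F-score means
a larger between-class separation relative to the within-class scatter.

Selection is wrapper-based, driven by jackknife accuracy of the
downstream SVM:

1. *coarse threshold scan* over the BPB features — keep features with
   F-score >= w for a grid of thresholds (default step 0.001);
2. *fine dimension scan* — vary the number d of top-ranked features
   around the coarse optimum (default step 2);
3. *greedy add* of top-ranked NC features, each kept only if it strictly
   improves the accuracy;
4. the same coarse (default step 0.01) + fine (step 2) scan pair for the
   PseNC features, evaluated as additions to the set selected so far.

Accuracy alone drives every decision; Sn/Sp/MCC are logged in the scan
trajectory but never choose a feature set.  Ties resolve toward fewer
features (larger threshold, smaller dimension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .classifier import LAYER1_SVM, SvmConfig
from .encoders import FeatureMatrix, encode_dataset, fit_bpb
from .evaluation import (
    EvalMetrics,
    FeatureSpec,
    MatrixEvaluator,
    make_matrix_evaluator,
)
from .sequence_io import LayeredDataset


@dataclass
class FScoreRanking:
    """Per-feature F-scores with a deterministic descending order.

    ``order`` ranks features by descending score; equal scores (including
    the +inf sentinel for perfectly class-constant separating features)
    fall back to ascending original index.
    """

    scores: np.ndarray
    order: np.ndarray
    feature_names: list[str]
    overall_means: np.ndarray
    pos_means: np.ndarray
    neg_means: np.ndarray
    n_pos: int
    n_neg: int

    def top(self, d: int) -> list[str]:
        return [self.feature_names[i] for i in self.order[:d]]

    def names_at_threshold(self, w: float) -> list[str]:
        """Features with F-score >= w, in rank order."""
        return [
            self.feature_names[i] for i in self.order if self.scores[i] >= w
        ]

    @property
    def max_finite_score(self) -> float:
        finite = self.scores[np.isfinite(self.scores)]
        return float(finite.max()) if finite.size else 0.0


def fscore(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    feature_names: Sequence[str] | None = None,
) -> FScoreRanking:
    """Rank features by their between/within-class F-score.

    Degenerate features: zero within-class scatter scores +inf when the
    class means differ (a perfectly separating constant-in-class feature,
    ranked first) and 0 when they do not (an uninformative constant).
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        names = list(matrix.feature_names)
    else:
        X = np.asarray(matrix, dtype=float)
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
    y = np.asarray(labels)
    pos = X[y > 0]
    neg = X[y < 0]
    n_pos, n_neg = pos.shape[0], neg.shape[0]
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            "F-score needs at least 2 samples per class "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    overall = X.mean(axis=0)
    pos_mean = pos.mean(axis=0)
    neg_mean = neg.mean(axis=0)
    numer = (pos_mean - overall) ** 2 + (neg_mean - overall) ** 2
    denom = ((pos - pos_mean) ** 2).sum(axis=0) / (n_pos - 1) + (
        (neg - neg_mean) ** 2
    ).sum(axis=0) / (n_neg - 1)
    tol = 1e-300
    scores = np.zeros(X.shape[1])
    regular = denom > tol
    scores[regular] = numer[regular] / denom[regular]
    scores[~regular & (numer > tol)] = np.inf
    # descending score; ties broken by ascending original index
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return FScoreRanking(
        scores=scores,
        order=order,
        feature_names=names,
        overall_means=overall,
        pos_means=pos_mean,
        neg_means=neg_mean,
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass(frozen=True)
class ScanPoint:
    """One evaluated grid point of a wrapper scan."""

    param: float | int | str
    metrics: EvalMetrics | None  # None: grid point invalid (no features)
    n_features: int


@dataclass
class SelectionResult:
    """An ordered selected feature set plus the scan log that produced it."""

    selected: list[str]
    trajectory: list[ScanPoint]
    best_acc: float
    stage: str = ""
    stages: dict[str, "SelectionResult"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "selected": list(self.selected),
            "best_acc": self.best_acc,
            "trajectory": [
                {
                    "param": p.param,
                    "n_features": p.n_features,
                    **(p.metrics.to_dict() if p.metrics else {"invalid": True}),
                }
                for p in self.trajectory
            ],
        }

    def trajectory_tsv(self) -> str:
        """Scan log as TSV (param, n_features, Sn, Sp, Acc, MCC)."""
        lines = ["param\tn_features\tSn\tSp\tAcc\tMCC"]
        for p in self.trajectory:
            if p.metrics is None:
                lines.append(f"{p.param}\t{p.n_features}\tNA\tNA\tNA\tNA")
            else:
                m = p.metrics
                lines.append(
                    f"{p.param}\t{p.n_features}\t{m.sn:.4f}\t{m.sp:.4f}"
                    f"\t{m.acc:.4f}\t{m.mcc:.4f}"
                )
        return "\n".join(lines) + "\n"


class _EvalCache:
    """Memoise evaluator calls on identical column subsets.

    Adjacent thresholds of a coarse scan usually retain the same feature
    set; caching makes the published fine step sizes affordable.
    """

    def __init__(self, matrix: FeatureMatrix, labels, evaluator: MatrixEvaluator):
        self.matrix = matrix
        self.y = np.asarray(labels)
        self.evaluator = evaluator
        self._cache: dict[tuple[str, ...], EvalMetrics] = {}

    def __call__(self, names: Sequence[str]) -> EvalMetrics:
        key = tuple(names)
        if key not in self._cache:
            idx = self.matrix.column_index(names)
            self._cache[key] = self.evaluator(self.matrix.values[:, idx], self.y)
        return self._cache[key]


def coarse_threshold_scan(
    ranking: FScoreRanking,
    matrix: FeatureMatrix,
    labels: Sequence[int],
    evaluator: MatrixEvaluator,
    *,
    w_start: float = 0.0,
    w_end: float | None = None,
    step: float = 0.001,
    base: Sequence[str] = (),
    stage: str = "coarse",
) -> SelectionResult:
    """Scan F-score thresholds; keep features scoring >= the threshold.

    At each grid threshold the retained candidate features (appended to
    the fixed ``base`` set, if any) are evaluated by jackknife accuracy.
    The best threshold wins; ties go to the larger threshold, i.e. the
    smaller feature set.  Thresholds retaining zero candidates are logged
    as invalid and skipped.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if w_end is None:
        w_end = ranking.max_finite_score
    cache = _EvalCache(matrix, labels, evaluator)
    grid = np.arange(w_start, w_end + step / 2, step)
    trajectory: list[ScanPoint] = []
    best: tuple[float, float, list[str]] | None = None  # (acc, w, names)
    base = list(base)
    for w in grid:
        cand = ranking.names_at_threshold(float(w))
        if not cand:
            trajectory.append(ScanPoint(float(w), None, 0))
            continue
        metrics = cache(base + cand)
        trajectory.append(ScanPoint(float(w), metrics, len(base) + len(cand)))
        # ties resolve to the larger threshold (fewer features)
        if best is None or metrics.acc >= best[0] - 1e-12:
            if best is None or metrics.acc > best[0] + 1e-12 or w > best[1]:
                best = (metrics.acc, float(w), cand)
    if best is None:
        raise ValueError("no threshold on the grid retained any feature")
    return SelectionResult(
        selected=base + best[2],
        trajectory=trajectory,
        best_acc=best[0],
        stage=stage,
    )


def fine_dimension_scan(
    ranking: FScoreRanking,
    matrix: FeatureMatrix,
    labels: Sequence[int],
    evaluator: MatrixEvaluator,
    *,
    d_min: int,
    d_max: int,
    step: int = 2,
    base: Sequence[str] = (),
    stage: str = "fine",
) -> SelectionResult:
    """Scan the number d of top-ranked features; best accuracy wins.

    Ties resolve to the smaller d.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if not (1 <= d_min <= d_max):
        raise ValueError("need 1 <= d_min <= d_max")
    if d_max > len(ranking.feature_names):
        raise ValueError(
            f"d_max={d_max} exceeds available features ({len(ranking.feature_names)})"
        )
    cache = _EvalCache(matrix, labels, evaluator)
    base = list(base)
    trajectory: list[ScanPoint] = []
    best: tuple[float, int, list[str]] | None = None
    for d in range(d_min, d_max + 1, step):
        cand = ranking.top(d)
        metrics = cache(base + cand)
        trajectory.append(ScanPoint(d, metrics, len(base) + d))
        if best is None or metrics.acc > best[0] + 1e-12:
            best = (metrics.acc, d, cand)
    assert best is not None
    return SelectionResult(
        selected=base + best[2],
        trajectory=trajectory,
        best_acc=best[0],
        stage=stage,
    )


def greedy_add(
    base: SelectionResult,
    candidate_ranking: FScoreRanking,
    matrix: FeatureMatrix,
    labels: Sequence[int],
    evaluator: MatrixEvaluator,
    *,
    k_max: int = 4,
    strict: bool = True,
    stage: str = "greedy",
) -> SelectionResult:
    """Try candidates in descending F-score order, keeping improvers.

    A candidate is retained only if the jackknife accuracy of
    (current set + candidate) improves on the current best — strictly by
    default, reading the accept rule literally; ``strict=False`` also
    keeps accuracy-neutral additions.
    """
    cache = _EvalCache(matrix, labels, evaluator)
    selected = list(base.selected)
    best_acc = base.best_acc
    trajectory: list[ScanPoint] = []
    tried = 0
    for i in candidate_ranking.order:
        name = candidate_ranking.feature_names[i]
        if name in selected:
            continue
        if tried >= k_max:
            break
        tried += 1
        metrics = cache(selected + [name])
        trajectory.append(ScanPoint(name, metrics, len(selected) + 1))
        accepted = (
            metrics.acc > best_acc + 1e-12
            if strict
            else metrics.acc >= best_acc - 1e-12
        )
        if accepted:
            selected.append(name)
            best_acc = metrics.acc
    return SelectionResult(
        selected=selected, trajectory=trajectory, best_acc=best_acc, stage=stage
    )


@dataclass(frozen=True)
class SelectionConfig:
    """Schedule parameters for the full two-step selection pipeline.

    The default step sizes are the published operating points (coarse
    BPB step 0.001, fine dimension step 2, coarse PseNC step 0.01, fine
    PseNC step 2).  Scan bounds default to the data-driven range
    [0, max finite F-score]; the fine scans default to a window of
    ``fine_window`` dimensions around the coarse optimum.
    """

    svm: SvmConfig = LAYER1_SVM
    families: tuple[str, ...] = ("BPB", "NC", "PseNC")
    alpha: float = 0.0
    run_bpb_scan: bool = True
    run_nc_greedy: bool = True
    run_psenc_scan: bool = True
    bpb_coarse_start: float = 0.0
    bpb_coarse_end: float | None = None
    bpb_coarse_step: float = 0.001
    bpb_fine_step: int = 2
    fine_window: int = 10
    nc_k_max: int = 4
    psenc_coarse_start: float = 0.0
    psenc_coarse_end: float | None = None
    psenc_coarse_step: float = 0.01
    psenc_fine_step: int = 2
    strict_accept: bool = True
    evaluator: MatrixEvaluator | None = None


def _accept_stage(
    current: SelectionResult, stage: SelectionResult
) -> SelectionResult:
    """Keep a stage's outcome only if it does not lose accuracy."""
    if stage.best_acc >= current.best_acc - 1e-12:
        return stage
    return replace_selection(current, stage_name=stage.stage + "_rejected")


def replace_selection(res: SelectionResult, stage_name: str) -> SelectionResult:
    return SelectionResult(
        selected=list(res.selected),
        trajectory=[],
        best_acc=res.best_acc,
        stage=stage_name,
    )


def run_full_selection(
    dataset: LayeredDataset,
    layer: str,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Execute the full selection schedule for one cascade layer.

    BPB coarse threshold scan, BPB fine dimension scan, NC greedy add,
    PseNC coarse threshold scan, PseNC fine dimension scan — each later
    stage evaluated on top of the set selected so far and accepted only
    if it does not lose jackknife accuracy, so the final accuracy never
    falls below the first stage's.

    The BPB model is fitted once on the full layer (the wrapper evaluates
    candidate sets by jackknife over that fixed matrix, reproducing the
    published protocol; see the evaluation module's mode discussion).
    """
    from .evaluation import _layer_view

    records, y = _layer_view(dataset, layer)
    y = np.asarray(y)
    pos = [r for r, yy in zip(records, y) if yy > 0]
    neg = [r for r, yy in zip(records, y) if yy < 0]
    families = tuple(config.families)
    bpb = (
        fit_bpb(pos, neg, dataset.n, alpha=config.alpha)
        if "BPB" in families
        else None
    )
    matrix = encode_dataset(records, bpb=bpb, families=families)
    evaluator = config.evaluator or make_matrix_evaluator(config.svm)
    stages: dict[str, SelectionResult] = {}

    def family_ranking(family: str) -> FScoreRanking:
        names = matrix.family_columns(family)
        sub = matrix.subset(names)
        return fscore(sub, y)

    # --- stage 0: no selection at all ---------------------------------
    if not (config.run_bpb_scan or config.run_nc_greedy or config.run_psenc_scan):
        metrics = evaluator(matrix.values, y)
        return SelectionResult(
            selected=list(matrix.feature_names),
            trajectory=[ScanPoint("all", metrics, matrix.n_features)],
            best_acc=metrics.acc,
            stage="no_selection",
        )

    current: SelectionResult | None = None

    if config.run_bpb_scan and "BPB" in families:
        ranking = family_ranking("BPB")
        coarse = coarse_threshold_scan(
            ranking,
            matrix,
            y,
            evaluator,
            w_start=config.bpb_coarse_start,
            w_end=config.bpb_coarse_end,
            step=config.bpb_coarse_step,
            stage="bpb_coarse",
        )
        stages["bpb_coarse"] = coarse
        d_star = len(coarse.selected)
        d_min = max(1, d_star - config.fine_window)
        d_max = min(len(ranking.feature_names), d_star + config.fine_window)
        fine = fine_dimension_scan(
            ranking,
            matrix,
            y,
            evaluator,
            d_min=d_min,
            d_max=d_max,
            step=config.bpb_fine_step,
            stage="bpb_fine",
        )
        stages["bpb_fine"] = fine
        current = _accept_stage(coarse, fine)
    elif "BPB" in families:
        names = matrix.family_columns("BPB")
        metrics = evaluator(matrix.subset(names).values, y)
        current = SelectionResult(names, [], metrics.acc, stage="bpb_all")
        stages["bpb_all"] = current
    else:
        current = SelectionResult([], [], 0.0, stage="empty")

    if config.run_nc_greedy and "NC" in families:
        nc_rank = family_ranking("NC")
        greedy = greedy_add(
            current,
            nc_rank,
            matrix,
            y,
            evaluator,
            k_max=config.nc_k_max,
            strict=config.strict_accept,
            stage="nc_greedy",
        )
        stages["nc_greedy"] = greedy
        current = greedy  # greedy never loses accuracy by construction

    if config.run_psenc_scan and "PseNC" in families:
        ps_rank = family_ranking("PseNC")
        ps_coarse = coarse_threshold_scan(
            ps_rank,
            matrix,
            y,
            evaluator,
            w_start=config.psenc_coarse_start,
            w_end=config.psenc_coarse_end,
            step=config.psenc_coarse_step,
            base=current.selected,
            stage="psenc_coarse",
        )
        stages["psenc_coarse"] = ps_coarse
        after_coarse = _accept_stage(current, ps_coarse)
        k_star = len(after_coarse.selected) - len(current.selected)
        if k_star > 0:
            d_min = max(1, k_star - config.fine_window)
            d_max = min(len(ps_rank.feature_names), k_star + config.fine_window)
            ps_fine = fine_dimension_scan(
                ps_rank,
                matrix,
                y,
                evaluator,
                d_min=d_min,
                d_max=d_max,
                step=config.psenc_fine_step,
                base=current.selected,
                stage="psenc_fine",
            )
            stages["psenc_fine"] = ps_fine
            current = _accept_stage(after_coarse, ps_fine)
            if current.stage.endswith("_rejected"):
                current = after_coarse

    final = SelectionResult(
        selected=list(current.selected),
        trajectory=list(current.trajectory),
        best_acc=current.best_acc,
        stage="final",
        stages=stages,
    )
    return final
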