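"""Forward stepwise source selection, k-fold CV, and the inference pipeline.

The unit of observation is the clonal family: folds and the train/test
split are partitions of CFs (stratified by donor when donor labels are
available), never of individual sequences.  Candidate external sources are
screened greedily — at each step the previously chosen sources are kept and
each remaining candidate is scored by k-fold cross-validated *unpenalized*
performance — and the surviving groupings are then tuned over the
(lambda1, lambda2, d) penalty grid before a final penalized fit on all
training CFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .external import InputTensor
from .model import (
    FitOptions,
    JaccardConfig,
    PenaltyConfig,
    WeightMatrix,
    fit,
    jaccard_exact,
    l2_error,
    predict,
)
from .profiles import ProfileTensor

Objective = Literal["l2", "jaccard_smooth"]

#: Penalty values cross-validated over by default.
DEFAULT_LAMBDAS = (1e-7, 5.05e-6, 1e-5)
DEFAULT_DS = (1, 2, 3)


@dataclass
class TuningGrid:
    lambdas1: tuple[float, ...] = DEFAULT_LAMBDAS
    lambdas2: tuple[float, ...] = DEFAULT_LAMBDAS
    ds: tuple[int, ...] = DEFAULT_DS
    groupings: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not (self.lambdas1 and self.lambdas2 and self.ds):
            raise ValueError("grid axes must be non-empty")

    def cells(self):
        for l1 in self.lambdas1:
            for l2 in self.lambdas2:
                for d in self.ds:
                    yield PenaltyConfig(l1, l2, d)


@dataclass
class ModelData:
    """Aligned query profiles, targets, and all candidate source slabs."""

    x: ProfileTensor
    y: ProfileTensor
    xstar: InputTensor
    donors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) != self.xstar.values.shape[0]:
            raise ValueError("x, y, xstar must cover the same CFs")
        if self.donors and len(self.donors) != len(self.x):
            raise ValueError("donors must be parallel to CFs")

    @property
    def n_cf(self) -> int:
        return len(self.x)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.xstar.sources)

    def subset_cfs(self, idx: Sequence[int]) -> "ModelData":
        idx = list(idx)
        donors = tuple(self.donors[i] for i in idx) if self.donors else ()
        return ModelData(self.x.subset(idx), self.y.subset(idx),
                         self.xstar.subset_cfs(idx), donors)

    def subset_sources(self, names: Sequence[str]) -> "ModelData":
        lookup = {n: i for i, n in enumerate(self.source_names)}
        idx = [lookup[n] for n in names]
        return ModelData(self.x, self.y, self.xstar.subset_sources(idx),
                         self.donors)


def score(data: ModelData, w: WeightMatrix, objective: Objective,
          jcfg: JaccardConfig | None = None) -> float:
    """Unpenalized performance of fixed weights on a dataset (L2 error for
    the L2 objective, exact Jaccard similarity for the Jaccard objective)."""
    yhat = predict(data.x, data.xstar, w)
    if objective == "l2":
        return l2_error(data.y, yhat)
    jcfg = jcfg or JaccardConfig()
    return jaccard_exact(data.y, yhat, jcfg.t)


def is_better(a: float, b: float, objective: Objective) -> bool:
    """True when score ``a`` beats ``b`` (lower L2; higher Jaccard)."""
    return a < b if objective == "l2" else a > b


def make_folds(n: int, k: int, seed: int,
               donors: Sequence[str] | None = None) -> list[np.ndarray]:
    """Partition CF indices 0..n-1 into k folds by seeded shuffle.

    When donor labels are given, each donor's CFs are dealt round-robin
    across folds (after a seeded shuffle) so no fold is dominated by one
    donor.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer CFs than folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if donors:
        by_donor: dict[str, list[int]] = {}
        for i, d in enumerate(donors):
            by_donor.setdefault(d, []).append(i)
        start = 0
        for d in sorted(by_donor):
            idx = np.array(by_donor[d])
            rng.shuffle(idx)
            for off, i in enumerate(idx):
                folds[(start + off) % k].append(int(i))
            start += len(idx)
    else:
        perm = rng.permutation(n)
        for f, part in enumerate(np.array_split(perm, k)):
            folds[f].extend(int(i) for i in part)
    return [np.array(sorted(f), dtype=int) for f in folds]


def kfold_cv(data: ModelData, objective: Objective = "l2",
             pcfg: PenaltyConfig | None = None,
             jcfg: JaccardConfig | None = None,
             k: int = 5, seed: int = 0,
             fit_opts: FitOptions | None = None) -> float:
    """Mean held-out unpenalized score over k seeded folds.

    Each fold's model is fitted (with the requested penalties, if any) on
    the remaining folds and scored without penalties on the held-out CFs.
    """
    folds = make_folds(data.n_cf, k, seed, data.donors or None)
    scores = []
    for fold in folds:
        held = set(int(i) for i in fold)
        train_idx = [i for i in range(data.n_cf) if i not in held]
        train = data.subset_cfs(train_idx)
        test = data.subset_cfs(sorted(held))
        if data.xstar.p == 0:
            w = WeightMatrix.zeros(0)
        else:
            w = fit(objective, train.x, train.xstar, train.y, pcfg, jcfg,
                    opts=fit_opts).weights
        scores.append(score(test, w, objective, jcfg))
    return float(np.mean(scores))


@dataclass
class SelectionStep:
    source: str
    cv_score: float
    candidate_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectionPath:
    """Greedy forward-selection path, including the source-free baseline."""

    baseline_score: float
    steps: list[SelectionStep]
    objective: Objective

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(s.source for s in self.steps)

    @property
    def best_step(self) -> int:
        """1-based index of the best-scoring step (0 means the baseline)."""
        scores = [self.baseline_score] + [s.cv_score for s in self.steps]
        best = 0
        for i, sc in enumerate(scores):
            if is_better(sc, scores[best], self.objective):
                best = i
        return best

    def grouping(self, length: int) -> tuple[str, ...]:
        return tuple(s.source for s in self.steps[:length])


def forward_select(data: ModelData,
                   candidates: Sequence[str] | None = None,
                   objective: Objective = "l2",
                   max_profiles: int = 5, k: int = 5, seed: int = 0,
                   jcfg: JaccardConfig | None = None,
                   fit_opts: FitOptions | None = None) -> SelectionPath:
    """Greedy forward selection of external sources by unpenalized CV.

    At each step every remaining candidate is tried alongside the already
    chosen sources; the best CV score wins, ties broken by candidate order.
    The path always grows to ``min(max_profiles, n_candidates)`` entries so
    the full trade-off curve is reported.
    """
    if max_profiles < 1:
        raise ValueError("max_profiles must be >= 1")
    names = list(candidates) if candidates is not None else list(data.source_names)
    if not names:
        raise ValueError("no candidate sources")
    baseline = kfold_cv(data.subset_sources([]), objective, None, jcfg, k, seed,
                        fit_opts)
    chosen: list[str] = []
    steps: list[SelectionStep] = []
    remaining = list(names)
    while remaining and len(chosen) < max_profiles:
        trial_scores: dict[str, float] = {}
        for cand in remaining:
            sub = data.subset_sources(chosen + [cand])
            trial_scores[cand] = kfold_cv(sub, objective, None, jcfg, k, seed,
                                          fit_opts)
        best = remaining[0]
        for cand in remaining:
            if is_better(trial_scores[cand], trial_scores[best], objective):
                best = cand
        chosen.append(best)
        remaining.remove(best)
        steps.append(SelectionStep(best, trial_scores[best], trial_scores))
    return SelectionPath(baseline, steps, objective)


@dataclass
class PipelineReport:
    objective: Objective
    split_seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    selection: SelectionPath
    cv_results: list[dict]
    best_grouping: tuple[str, ...]
    best_penalty: PenaltyConfig
    best_cv_score: float
    weights: WeightMatrix
    test_scores: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "split_seed": self.split_seed,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "selection": {
                "baseline_score": self.selection.baseline_score,
                "steps": [{"source": s.source, "cv_score": s.cv_score,
                           "candidate_scores": s.candidate_scores}
                          for s in self.selection.steps],
            },
            "cv_results": self.cv_results,
            "best_grouping": list(self.best_grouping),
            "best_penalty": {"lambda1": self.best_penalty.lambda1,
                             "lambda2": self.best_penalty.lambda2,
                             "d": self.best_penalty.d},
            "best_cv_score": self.best_cv_score,
            "alpha": self.weights.alpha.tolist(),
            "alpha_sources": list(self.best_grouping),
            "test_scores": self.test_scores,
        }


def train_test_split(n: int, split_seed: int, test_fraction: float = 0.2,
                     donors: Sequence[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded CF-level train/test partition (default 80%/20%)."""
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test = np.array(sorted(perm[:n_test]), dtype=int)
    train = np.array(sorted(perm[n_test:]), dtype=int)
    return train, test


def run_pipeline(data: ModelData, grid: TuningGrid | None = None,
                 objective: Objective = "l2", split_seed: int = 0,
                 k: int = 5, max_profiles: int = 5,
                 jcfg: JaccardConfig | None = None,
                 fit_opts: FitOptions | None = None) -> PipelineReport:
    """End-to-end inference: split, select, tune, fit, evaluate.

    1. 80/20 train/test split by CF;
    2. forward stepwise selection on the training CFs (unpenalized CV);
    3. penalized CV over the tuning grid crossed with the shortlisted
       groupings (by default the best grouping at each path length);
    4. final penalized fit on all training CFs with the winning settings;
    5. unpenalized metrics on the held-out CFs, alongside the baseline.
    """
    grid = grid or TuningGrid()
    if objective == "jaccard_smooth":
        jcfg = jcfg or JaccardConfig()
    train_idx, test_idx = train_test_split(data.n_cf, split_seed)
    train = data.subset_cfs(train_idx)
    test = data.subset_cfs(test_idx)

    path = forward_select(train, None, objective, max_profiles, k, split_seed,
                          jcfg, fit_opts)
    groupings = grid.groupings or tuple(
        path.grouping(length) for length in range(1, len(path.steps) + 1))

    cv_results: list[dict] = []
    best: tuple[tuple[str, ...], PenaltyConfig, float] | None = None
    for grouping in groupings:
        sub = train.subset_sources(grouping)
        for pcfg in grid.cells():
            sc = kfold_cv(sub, objective, pcfg, jcfg, k, split_seed, fit_opts)
            cv_results.append({"grouping": list(grouping),
                               "lambda1": pcfg.lambda1, "lambda2": pcfg.lambda2,
                               "d": pcfg.d, "cv_score": sc})
            if best is None or is_better(sc, best[2], objective):
                best = (grouping, pcfg, sc)
    assert best is not None
    best_grouping, best_pcfg, best_cv = best

    final_train = train.subset_sources(best_grouping)
    w = fit(objective, final_train.x, final_train.xstar, final_train.y,
            best_pcfg, jcfg, opts=fit_opts).weights

    final_test = test.subset_sources(best_grouping)
    baseline_w = WeightMatrix.zeros(0)
    yhat = predict(final_test.x, final_test.xstar, w)
    base = predict(final_test.x, final_test.xstar.subset_sources([]), baseline_w)
    jt = (jcfg or JaccardConfig()).t
    test_scores = {
        "l2": l2_error(final_test.y, yhat),
        "jaccard": jaccard_exact(final_test.y, yhat, jt),
        "baseline_l2": l2_error(final_test.y, base),
        "baseline_jaccard": jaccard_exact(final_test.y, base, jt),
    }
    return PipelineReport(objective, split_seed,
                          tuple(data.x.cf_ids[i] for i in train_idx),
                          tuple(data.x.cf_ids[i] for i in test_idx),
                          path, cv_results, best_grouping, best_pcfg,
                          best_cv, w, test_scores)
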