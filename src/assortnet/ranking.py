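"""Stage 1: per-node Welch tests, significance filtering, top-k selection.

For a chosen local measure and modality, every atlas node gets an
unequal-variance two-sample t-test (Welch) between the two groups of a task;
nodes with p <= 0.05 are ranked by ascending p and the top k (default 5)
become the candidate discriminative set, later verified by classification.
No multiple-testing correction is applied by default — the pipeline relies
on the label-shuffle null and classifier verification instead — but a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .exceptions import DegenerateInputError, InvalidParameterError, TaskError
from .measures import compute_measure

__all__ = [
    "TASKS",
    "NodalFeatureMatrix",
    "RankingResult",
    "feature_matrix",
    "welch_test",
    "rank_nodes",
    "direction_summary",
    "age_covariate_check",
]

#: The three pairwise discrimination tasks across the decline spectrum.
TASKS = {
    "SCI-vs-MCI": ("SCI", "MCI"),
    "MCI-vs-ADD": ("MCI", "ADD"),
    "SCI-vs-ADD": ("SCI", "ADD"),
}


def task_groups(task: str) -> tuple[str, str]:
    if task not in TASKS:
        raise TaskError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    return TASKS[task]


@dataclass
class NodalFeatureMatrix:
    """Subjects x nodes matrix of one local measure for one modality."""

    values: np.ndarray
    measure: str
    modality: str
    subject_ids: list[str]
    groups: np.ndarray
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.groups):
            raise InvalidParameterError("feature matrix rows must match subject count")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("feature matrix contains missing values")

    def task_rows(self, task: str):
        """(X, y, row indices) restricted to a task's two groups; y in {0, 1}."""
        ga, gb = task_groups(task)
        for g in (ga, gb):
            if (self.groups == g).sum() < 2:
                raise TaskError(f"group {g!r} has fewer than 2 subjects")
        rows = np.nonzero((self.groups == ga) | (self.groups == gb))[0]
        y = (self.groups[rows] == gb).astype(int)
        return self.values[rows], y, rows


def feature_matrix(cohort: Cohort, measure: str, modality: str = "structural",
                   degree_mode: str = "binary") -> NodalFeatureMatrix:
    """Compute one local measure for every subject's network of one modality."""
    vals = np.stack([
        compute_measure(s.network(modality), measure, degree_mode).values
        for s in cohort.subjects
    ])
    return NodalFeatureMatrix(vals, measure, modality, cohort.subject_ids,
                              cohort.groups, cohort.ages)


@dataclass
class RankingResult:
    task: str
    measure: str
    modality: str
    t_statistics: np.ndarray
    p_values: np.ndarray
    #: sign of mean(group B) - mean(group A) per node
    signs: np.ndarray
    significant_nodes: np.ndarray  # p <= alpha, ascending p
    selected: np.ndarray           # top-k of significant_nodes
    k: int = 5
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        order = {int(n): r for r, n in enumerate(self.significant_nodes, start=1)}
        n = len(self.p_values)
        return pd.DataFrame({
            "node_id": np.arange(n),
            "t": self.t_statistics,
            "p": self.p_values,
            "sign": self.signs,
            "rank": [order.get(i, 0) for i in range(n)],
        })

    def summary(self) -> dict:
        """JSON-ready digest: task, selection and their statistics."""
        sel = [int(v) for v in self.selected]
        return {
            "task": self.task,
            "measure": self.measure,
            "modality": self.modality,
            "k": self.k,
            "alpha": self.alpha,
            "n_significant": int(len(self.significant_nodes)),
            "selected": sel,
            "selected_p": [float(self.p_values[v]) for v in sel],
            "selected_sign": [int(self.signs[v]) for v in sel],
        }


def welch_test(a: np.ndarray, b: np.ndarray):
    """Column-wise Welch t-test (unequal, unknown variances).

    Returns (t, p) with t oriented as mean(a) - mean(b). Nodes where both
    groups are exactly constant get the degenerate convention p = 0 if the
    means differ, p = 1 otherwise (with a warning).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
    t, p = np.atleast_1d(np.asarray(t)), np.atleast_1d(np.asarray(p))
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn("zero within-group variance at some nodes; applying degenerate-t convention")
        diff = a.mean(axis=0) - b.mean(axis=0)
        p[bad] = np.where(diff[bad] != 0, 0.0, 1.0)
        t[bad] = np.where(diff[bad] != 0, np.sign(diff[bad]) * np.inf, 0.0)
    return t, p


def rank_nodes(features: NodalFeatureMatrix, task: str, k: int = 5,
               alpha: float = 0.05, bh_correct: bool = False,
               labels: np.ndarray | None = None) -> RankingResult:
    """Welch-test every node, keep p <= alpha, rank ascending p, take top k.

    Ties on p break by larger |t|, then lower node id, so the selection is
    deterministic. ``labels`` overrides the 0/1 task labels (used by the
    shuffle null, which re-runs the ranking on permuted labels).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    X, y, _ = features.task_rows(task)
    if labels is not None:
        y = np.asarray(labels)
        if len(y) != X.shape[0]:
            raise InvalidParameterError("labels length must match task subject count")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise TaskError("each label class needs >= 2 subjects")
    t, p = welch_test(X[y == 0], X[y == 1])
    signs = np.sign(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)).astype(int)
    p_crit = p.copy()
    if bh_correct:
        p_crit = multipletests(p, method="fdr_bh")[1]
    sig_mask = p_crit <= alpha
    ids = np.nonzero(sig_mask)[0]
    order = np.lexsort((ids, -np.abs(np.where(np.isfinite(t[ids]), t[ids], np.inf)), p[ids]))
    significant = ids[order]
    return RankingResult(task, features.measure, features.modality, t, p, signs,
                         significant, significant[:k], k=k, alpha=alpha,
                         extras={"bh_correct": bh_correct})


def direction_summary(features: NodalFeatureMatrix, ranking: RankingResult) -> dict[int, int]:
    """Sign of the group-B-minus-group-A mean difference at each selected node.

    -1 marks a decrease across the transition (hypo-assortativity when the
    measure is NA), +1 an increase, 0 an exact tie.
    """
    return {int(v): int(ranking.signs[v]) for v in ranking.selected}


def age_covariate_check(features: NodalFeatureMatrix, ranking: RankingResult | None = None,
                        nodes=None):
    """Per-node simple linear regression of the feature on age.

    Returns a dict node -> (pearson_r, r_squared, f_test_p); for a simple
    regression the F-test of the model equals the t-test of the slope, so the
    slope p-value is reported as the F-test p.
    """
    if features.ages is None:
        raise DegenerateInputError("feature matrix carries no ages")
    ages = np.asarray(features.ages, dtype=float)
    if len(ages) < 3:
        raise DegenerateInputError("need >= 3 subjects for the age regression")
    if ages.std() == 0:
        raise DegenerateInputError("constant ages: age regression undefined")
    if nodes is None:
        if ranking is None:
            raise InvalidParameterError("pass a ranking or an explicit node list")
        nodes = ranking.selected
    out = {}
    for v in nodes:
        res = scipy.stats.linregress(ages, features.values[:, int(v)])
        out[int(v)] = (float(res.rvalue), float(res.rvalue) ** 2, float(res.pvalue))
    return out
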