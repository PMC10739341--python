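"""Observed-vs-simulated evaluation: k-fold CV, t-tests, sensitivity rate.

Model fidelity is judged by comparing the trait distributions of observed
root images against those of simulated systems re-extracted through the
same trait pipeline. Samples (whole plants/images, never individual roots)
are split into k folds; for every train/test fold permutation the training
folds parameterize the model, the model simulates one output per test
sample, and each shared trait is compared by a two-sided t-test with a
Bonferroni adjustment over the trait family. A significantly different
trait counts as a misclassification; the sensitivity rate is the
percentage of traits predicted correctly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldPlan",
    "TraitTestResult",
    "EvaluationReport",
    "kfold_split",
    "trait_ttest",
    "bonferroni_adjust",
    "sensitivity_rate",
    "compare_trait_tables",
    "cross_validate",
]


@dataclass
class FoldPlan:
    """A random partition of sample ids into k near-equal folds, plus every
    train/test permutation with 3 training and 2 test folds (for k = 5,
    all C(5,3) = 10 of them)."""

    k: int
    assignment: dict
    permutations: list  # (train_fold_ids, test_fold_ids) tuples

    def fold_members(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]

    def split(self, perm_index: int) -> tuple[list, list]:
        train_folds, test_folds = self.permutations[perm_index]
        train = [s for s, f in self.assignment.items() if f in train_folds]
        test = [s for s, f in self.assignment.items() if f in test_folds]
        return train, test


@dataclass
class TraitTestResult:
    trait: str
    raw_p: float
    adjusted_p: float
    misclassified: bool


@dataclass
class EvaluationReport:
    results: list
    alpha: float
    label: str = ""

    @property
    def n_traits(self) -> int:
        return len(self.results)

    @property
    def n_misclassified(self) -> int:
        return sum(r.misclassified for r in self.results)

    @property
    def sensitivity(self) -> float:
        return sensitivity_rate(self.n_traits, self.n_misclassified)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": r.trait,
                    "raw_p": r.raw_p,
                    "adj_p": r.adjusted_p,
                    "misclassified": r.misclassified,
                }
                for r in self.results
            ]
        )


def kfold_split(sample_ids, k: int = 5, rng=None, n_train_folds: int = 3) -> FoldPlan:
    """Random partition into k folds of near-equal size (differ by ≤ 1).

    All C(k, n_train_folds) train/test fold permutations are enumerated.
    """
    ids = list(sample_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} samples for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(perm)}
    folds = list(range(k))
    permutations = [
        (train, tuple(f for f in folds if f not in train))
        for train in itertools.combinations(folds, n_train_folds)
    ]
    return FoldPlan(k=k, assignment=assignment, permutations=permutations)


def trait_ttest(observed, simulated, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Degenerate cases: both groups constant with equal means → p = 1;
    constant groups with different means → p = 0 (perfect separation).
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(simulated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def bonferroni_adjust(p_values) -> np.ndarray:
    """adjusted_i = min(1, p_i · m). Monotone in the raw p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def sensitivity_rate(n_traits: int, n_misclassified: int) -> float:
    """Percentage of correctly predicted traits: 100·(n − m)/n."""
    if n_traits <= 0:
        raise ValueError("n_traits must be > 0")
    if not 0 <= n_misclassified <= n_traits:
        raise ValueError(
            f"n_misclassified must be in [0, {n_traits}], got {n_misclassified}"
        )
    return 100.0 * (n_traits - n_misclassified) / n_traits


def compare_trait_tables(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
    label: str = "",
) -> EvaluationReport:
    """Per-trait Welch t-tests over the shared numeric columns, Bonferroni
    over that trait family; adjusted p < alpha flags a misclassification."""
    shared = [
        c
        for c in observed.columns
        if c in simulated.columns
        and pd.api.types.is_numeric_dtype(observed[c])
        and pd.api.types.is_numeric_dtype(simulated[c])
    ]
    if not shared:
        raise ValueError("no shared numeric trait columns to compare")
    raw = []
    for c in shared:
        a = observed[c].dropna().to_numpy()
        b = simulated[c].dropna().to_numpy()
        raw.append(trait_ttest(a, b, equal_var=equal_var))
    adj = bonferroni_adjust(raw)
    results = [
        TraitTestResult(
            trait=c, raw_p=rp, adjusted_p=float(ap), misclassified=bool(ap < alpha)
        )
        for c, rp, ap in zip(shared, raw, adj)
    ]
    return EvaluationReport(results=results, alpha=alpha, label=label)


@dataclass
class CrossValidationSummary:
    reports: list
    n_iterations: int
    n_permutations: int
    failures: list = field(default_factory=list)

    @property
    def mean_misclassified(self) -> float:
        return float(np.mean([r.n_misclassified for r in self.reports]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r.sensitivity for r in self.reports]))


def cross_validate(
    observed: pd.DataFrame,
    pipeline,
    k: int = 5,
    iterations: int = 10,
    alpha: float = 0.05,
    rng=None,
    equal_var: bool = False,
) -> CrossValidationSummary:
    """k-fold cross-validation of a parameterize→simulate→extract pipeline.

    ``pipeline(train_df, n_out, rng)`` must return a simulated trait
    DataFrame with ``n_out`` rows, parameterized from the training rows
    only. Each iteration draws a fresh random split and evaluates every
    train/test fold permutation; each permutation yields one
    EvaluationReport comparing the test-fold observations against the
    simulated outputs. A pipeline failure flags that permutation in
    ``failures`` instead of silently dropping it.
    """
    if observed.empty:
        raise ValueError("observed trait table is empty")
    rng = np.random.default_rng(rng)
    reports, failures = [], []
    n_perms = 0
    for it in range(iterations):
        plan = kfold_split(list(observed.index), k=k, rng=rng)
        for pi in range(len(plan.permutations)):
            n_perms += 1
            train_ids, test_ids = plan.split(pi)
            label = f"iter{it}_perm{pi}"
            try:
                sim = pipeline(observed.loc[train_ids], len(test_ids), rng)
                rep = compare_trait_tables(
                    observed.loc[test_ids], sim, alpha=alpha,
                    equal_var=equal_var, label=label,
                )
                reports.append(rep)
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                failures.append((label, repr(exc)))
    if not reports:
        raise RuntimeError(f"every fold permutation failed: {failures[:3]}")
    return CrossValidationSummary(
        reports=reports,
        n_iterations=iterations,
        n_permutations=n_perms,
        failures=failures,
    )
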