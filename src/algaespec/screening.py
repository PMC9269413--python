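"""Variable screening: ANOVA/Tukey star counts and backward elimination.

Each of the 14 spectral variables is scored by a one-way ANOVA across the
class groups followed by Tukey's HSD on all class pairs; the *star count*
is the number of pairs significant at ``alpha`` (p <= alpha).  Variables
are ranked by descending star count, ties broken by a fixed reference
ordering.  Backward elimination then walks the nested chain defined by the
ranking — repeatedly dropping the lowest-ranked remaining variable,
re-evaluating a classifier accuracy after each removal — and selects the
subset with the highest accuracy (ties resolved toward the larger subset).

With six classes there are 15 pairs, so star counts range 0-15.  (The
published tabulation tops out at 14; whether that reflects a different
comparison layout cannot be resolved from the available material, so both
conventions are reported in the JSON output and the computed count is the
operative one.)
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import SIGNIFICANCE_ORDER

__all__ = [
    "VariableRanking",
    "EliminationTrace",
    "anova_oneway",
    "tukey_star_count",
    "rank_variables",
    "backward_eliminate",
]

logger = logging.getLogger(__name__)


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    If every value is identical across all groups (zero variance), the
    test is undefined; (F, p) = (0, 1) is returned with a warning flag.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("zero variance in ANOVA input; returning F=0, p=1", stacklevel=2)
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_star_count(
    groups: Sequence[np.ndarray],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> tuple[int, dict[tuple[str, str], float]]:
    """Tukey HSD over all group pairs; count pairs with p <= alpha.

    Returns ``(star_count, pairwise_p)`` where the pairwise map is keyed by
    label pairs (indices stringified if no labels given).  With zero pooled
    within-group variance the studentized range is degenerate: pairs with
    distinct means are counted significant (p = 0) and identical-mean pairs
    get p = 1, with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    within_var = sum(float(np.var(a)) * a.size for a in arrays)
    if within_var == 0:
        warnings.warn(
            "zero pooled within-group variance; pairs with distinct means "
            "counted significant",
            stacklevel=2,
        )
        pairwise = {
            (labels[i], labels[j]): (1.0 if np.mean(arrays[i]) == np.mean(arrays[j]) else 0.0)
            for i, j in pairs
        }
    else:
        res = stats.tukey_hsd(*arrays)
        pairwise = {(labels[i], labels[j]): float(res.pvalue[i, j]) for i, j in pairs}
    stars = sum(1 for p in pairwise.values() if p <= alpha)
    return stars, pairwise


@dataclass
class VariableRanking:
    """Descending-significance ordering of the screened variables."""

    order: list[str]
    star_counts: dict[str, int]
    anova_p: dict[str, float]
    anova_F: dict[str, float]
    pairwise_p: dict[str, dict[tuple[str, str], float]]
    alpha: float = 0.05
    n_pairs: int = 15

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.order,
                "star_count": [self.star_counts[v] for v in self.order],
                "anova_F": [self.anova_F[v] for v in self.order],
                "anova_p": [self.anova_p[v] for v in self.order],
            }
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_pairs": self.n_pairs,
            "order": list(self.order),
            "star_counts": dict(self.star_counts),
            "anova_p": dict(self.anova_p),
            "anova_F": dict(self.anova_F),
            "pairwise_p": {
                v: {f"{a}~{b}": p for (a, b), p in d.items()}
                for v, d in self.pairwise_p.items()
            },
        }


def rank_variables(
    table: pd.DataFrame,
    label_col: str = "species",
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    reference_order: Sequence[str] = SIGNIFICANCE_ORDER,
) -> VariableRanking:
    """Rank variables by Tukey star count (descending).

    Ties are broken by position in ``reference_order`` (variables absent
    from it sort after, alphabetically).  Rows with a missing value in a
    variable are dropped for that variable only (pairwise-complete), with
    the dropped count logged.
    """
    if variables is None:
        variables = [c for c in reference_order if c in table.columns]
        if not variables:
            raise ValueError("no known feature columns in table")
    labels = table[label_col]
    class_names = sorted(labels.unique())
    if len(class_names) < 2:
        raise ValueError("ranking needs at least 2 classes")
    star_counts, anova_p, anova_F, pairwise = {}, {}, {}, {}
    for var in variables:
        col = pd.to_numeric(table[var], errors="coerce")
        ok = col.notna()
        dropped = int((~ok).sum())
        if dropped:
            logger.info("rank_variables: %s: dropped %d sample(s) with missing values", var, dropped)
        groups = [col[ok & (labels == c)].to_numpy() for c in class_names]
        if any(g.size < 2 for g in groups):
            raise ValueError(f"variable {var}: a class has fewer than 2 complete samples")
        F, p = anova_oneway(groups)
        stars, pw = tukey_star_count(groups, alpha=alpha, labels=class_names)
        star_counts[var], anova_F[var], anova_p[var], pairwise[var] = stars, F, p, pw
    ref_index = {v: i for i, v in enumerate(reference_order)}

    def sort_key(v: str):
        return (-star_counts[v], ref_index.get(v, len(ref_index)), v)

    order = sorted(variables, key=sort_key)
    n_pairs = len(class_names) * (len(class_names) - 1) // 2
    return VariableRanking(
        order=order,
        star_counts=star_counts,
        anova_p=anova_p,
        anova_F=anova_F,
        pairwise_p=pairwise,
        alpha=alpha,
        n_pairs=n_pairs,
    )


@dataclass
class EliminationStep:
    removed: tuple[str, ...]
    remaining: tuple[str, ...]
    accuracy: float | None
    error: str | None = None


@dataclass
class EliminationTrace:
    """Record of the nested backward-elimination chain."""

    steps: list[EliminationStep] = field(default_factory=list)

    @property
    def best(self) -> EliminationStep:
        evaluated = [s for s in self.steps if s.accuracy is not None]
        if not evaluated:
            raise ValueError("no subset was successfully evaluated")
        best = evaluated[0]
        for s in evaluated[1:]:
            if s.accuracy > best.accuracy:  # strict: ties keep the larger subset
                best = s
        return best

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.best.remaining

    @property
    def best_accuracy(self) -> float:
        return float(self.best.accuracy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_remaining": [len(s.remaining) for s in self.steps],
                "removed": [";".join(s.removed) for s in self.steps],
                "accuracy": [s.accuracy for s in self.steps],
                "error": [s.error for s in self.steps],
            }
        )

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "removed": list(s.removed),
                    "remaining": list(s.remaining),
                    "n_remaining": len(s.remaining),
                    "accuracy": s.accuracy,
                    "error": s.error,
                }
                for s in self.steps
            ],
            "best_subset": list(self.best_subset),
            "best_accuracy": self.best_accuracy,
        }


def backward_eliminate(
    evaluator: Callable[[tuple[str, ...]], float],
    ranking: VariableRanking | Sequence[str],
) -> EliminationTrace:
    """Accuracy-driven backward elimination along the significance ranking.

    Starting from the full variable set, the lowest-ranked remaining
    variable is removed one at a time; after each removal the supplied
    ``evaluator`` maps the remaining subset (a tuple of names, in ranking
    order) to an accuracy in percent.  An evaluator failure on a subset is
    recorded and elimination continues.  The selected subset maximizes
    accuracy; on ties the larger subset wins.
    """
    order = list(ranking.order) if isinstance(ranking, VariableRanking) else list(ranking)
    if not order:
        raise ValueError("empty ranking")
    trace = EliminationTrace()
    removed: list[str] = []
    remaining = list(order)
    while remaining:
        subset = tuple(remaining)
        try:
            acc = float(evaluator(subset))
            err = None
        except Exception as exc:  # noqa: BLE001 - evaluator failures are recorded
            acc, err = None, f"{type(exc).__name__}: {exc}"
            logger.warning("evaluator failed on %d-variable subset: %s", len(subset), err)
        trace.steps.append(EliminationStep(tuple(removed), subset, acc, err))
        removed.append(remaining.pop())  # lowest-ranked remaining variable
    return trace
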