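"""Composite phenotype scoring and phenotype-transcriptome correlation.

Per age cohort, animals are ranked on each behavioral subtest (rank 1 = most
normal for that subtest's abnormality direction, midranks on ties), subtest
ranks are averaged within each test, and the per-test averages are summed
into a composite behavior score — range [T, T*n] for T tests and n animals,
i.e. [4, 32] for the canonical four-test, eight-animal battery.

The gene-expression score min-max-normalizes each signature gene to [0, 1]
across the cohort's samples and sums over signature genes, giving a score in
[0, G]. The two scores are compared by Pearson correlation; group
comparisons use an exact Mann-Whitney test for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .signatures import GeneSet

__all__ = [
    "TestDefinition",
    "DEFAULT_TESTS",
    "ExpressionScore",
    "CorrelationResult",
    "rank_subtest",
    "behavior_score",
    "expression_score",
    "correlate_scores",
    "group_compare",
]

HIGHER_IS_ABNORMAL = "higher_is_abnormal"
LOWER_IS_ABNORMAL = "lower_is_abnormal"


@dataclass(frozen=True)
class TestDefinition:
    """A behavioral test with its subtest columns and abnormality directions."""

    name: str
    subtests: tuple  # of (subtest_column, direction)

    def __post_init__(self) -> None:
        if not self.subtests:
            raise ValueError(f"test {self.name!r} must have >= 1 subtest")
        for _, direction in self.subtests:
            if direction not in (HIGHER_IS_ABNORMAL, LOWER_IS_ABNORMAL):
                raise ValueError(f"unknown direction {direction!r}")


#: The canonical four-test battery: water-maze escape latency on training days
#: 2-5 (longer = abnormal), fear-conditioning freezing to context and cue
#: (less freezing = abnormal), prepulse inhibition at 4/12/20 kHz (higher %PPI
#: = failure to adapt = abnormal) and rotarod time before drop on days 4-5
#: (shorter = abnormal).
DEFAULT_TESTS = (
    TestDefinition(
        "morris_water_maze",
        tuple((f"mwm_latency_d{d}", HIGHER_IS_ABNORMAL) for d in range(2, 6)),
    ),
    TestDefinition(
        "fear_conditioning",
        (("fc_context", LOWER_IS_ABNORMAL), ("fc_cue", LOWER_IS_ABNORMAL)),
    ),
    TestDefinition(
        "prepulse_inhibition",
        tuple((f"ppi_{k}khz", HIGHER_IS_ABNORMAL) for k in (4, 12, 20)),
    ),
    TestDefinition(
        "rotarod",
        (("rotarod_d4", LOWER_IS_ABNORMAL), ("rotarod_d5", LOWER_IS_ABNORMAL)),
    ),
)


def rank_subtest(values: pd.Series, direction: str) -> pd.Series:
    """Rank animals on one subtest, 1 = most normal, midranks on ties.

    Missing values are excluded from ranking and returned as NaN.
    """
    if direction not in (HIGHER_IS_ABNORMAL, LOWER_IS_ABNORMAL):
        raise ValueError(f"unknown direction {direction!r}")
    observed = values.dropna()
    if len(observed) < 2:
        raise ValueError("need >= 2 non-missing values to rank")
    x = observed.to_numpy(dtype=float)
    if direction == LOWER_IS_ABNORMAL:
        x = -x
    ranks = stats.rankdata(x, method="average")
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out.loc[observed.index] = ranks
    return out


def behavior_score(
    battery: pd.DataFrame, tests: tuple[TestDefinition, ...] = DEFAULT_TESTS
) -> pd.Series:
    """Composite behavior score: sum over tests of the mean subtest rank.

    ``battery`` is an animals x subtests table for one age cohort. An animal
    missing every subtest of some test gets a missing (NaN) score.
    """
    per_test = []
    for test in tests:
        cols = []
        for subtest, direction in test.subtests:
            if subtest not in battery.columns:
                raise ValueError(
                    f"subtest {subtest!r} of test {test.name!r} missing from battery"
                )
            cols.append(rank_subtest(battery[subtest], direction))
        per_test.append(pd.concat(cols, axis=1).mean(axis=1, skipna=True))
    # an animal with no data for an entire test has NaN mean -> NaN sum
    scores = pd.concat(per_test, axis=1).sum(axis=1, skipna=False)
    scores.name = "behavior_score"
    return scores


@dataclass
class ExpressionScore:
    """Per-animal signature expression score in [0, G]."""

    scores: pd.Series
    signature: str
    genes_used: int
    genes_dropped: int


def expression_score(
    expr: ExpressionMatrix, signature: GeneSet | list[str]
) -> ExpressionScore:
    """Sum of per-gene min-max-normalized expression over signature genes.

    Each gene's expression is rescaled to [0, 1] across the cohort's samples
    ((x - min) / (max - min)); per animal the rescaled values are summed.
    Genes constant across the cohort contribute 0 and are counted in
    ``genes_dropped``.
    """
    if isinstance(signature, GeneSet):
        wanted = set(signature.members)
        name = signature.name
    else:
        wanted = {str(g).strip().lower() for g in signature}
        name = "signature"
    if len(expr.sample_ids) < 2:
        raise ValueError("need >= 2 samples for min-max normalization")
    index_norm = {str(g).strip().lower(): g for g in expr.values.index}
    present = [index_norm[g] for g in sorted(wanted) if g in index_norm]
    if not present:
        raise ValueError("no signature genes found in the expression matrix")
    sub = expr.values.loc[present]
    lo = sub.min(axis=1)
    hi = sub.max(axis=1)
    span = hi - lo
    constant = span == 0
    scaled = sub.sub(lo, axis=0).div(span.where(~constant, 1.0), axis=0)
    scaled[constant] = 0.0
    scores = scaled.sum(axis=0)
    scores.name = "expression_score"
    return ExpressionScore(
        scores=scores,
        signature=name,
        genes_used=len(present),
        genes_dropped=int(constant.sum()),
    )


@dataclass
class CorrelationResult:
    """Pearson correlation between paired per-animal scores."""

    r: float
    n: int
    p: float


def correlate_scores(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson R between two per-animal scores with a two-sided t-test p.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs are required and both scores must vary.
    """
    if isinstance(x, ExpressionScore):
        x = x.scores
    paired = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(f"need >= 3 paired animals, have {len(paired)}")
    a = paired.iloc[:, 0].to_numpy(dtype=float)
    b = paired.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the scores; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), n=len(paired), p=float(p))


_EXACT_LIMIT = 20


def group_compare(values_a, values_b) -> float:
    """Two-sided Mann-Whitney p-value for two independent groups.

    For combined sample sizes up to 20 the rank-sum null is enumerated
    exactly over all C(n, n_a) group labelings of the pooled midranks (so
    ties are handled exactly); larger samples use the normal approximation
    with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n = a.size, a.size + b.size
    if n <= _EXACT_LIMIT:
        ranks = stats.rankdata(np.concatenate([a, b]), method="average")
        observed = ranks[:n_a].sum()
        mu = n_a * (n + 1) / 2.0
        dev = abs(observed - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n), n_a):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                extreme += 1
        return extreme / total
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )
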