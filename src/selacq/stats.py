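"""Group comparisons, effect sizes and surrogate-data tests for the
word-acquisition / essay-production experiments.

Conventions used throughout:

* essay lengths are normalized within subject (each subject's lengths sum to
  1) before any group comparison, cancelling between-subject differences in
  baseline productivity;
* confidence bands follow the printed boundaries exactly — the "analyzed"
  range is 50 <= c <= 100, its lower half is 50 <= c <= 75 and its upper half
  75 < c <= 100, and "certain" means c = 100;
* the probability of superiority (PS) counts ties as half, making it exactly
  U / (n_a * n_b) for the midrank Mann-Whitney U;
* surrogate-test p-values use the (k + 1) / (n + 1) correction so p > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from selacq.dataset import BehaviorDataset

logger = logging.getLogger(__name__)

#: inclusive analyzed range: below 50 the rating expresses confidence of absence
ANALYZED_RANGE = (50.0, 100.0)

_BANDS = {
    "lower": lambda c: (c >= 50.0) & (c <= 75.0),
    "upper": lambda c: (c > 75.0) & (c <= 100.0),
    "certain": lambda c: c == 100.0,
    "analyzed": lambda c: (c >= 50.0) & (c <= 100.0),
}


class InsufficientDataError(ValueError):
    """A test's sample-size precondition is not met."""


@dataclass
class GroupComparison:
    """Outcome of one two-group test with effect size and bootstrap CIs."""

    test: str
    statistic: float
    p_value: float
    effect_size_name: str  # "PS", "d" or "d_z"
    effect_size: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    ci_a: tuple[float, float]  # percentile-bootstrap CI of the group's
    ci_b: tuple[float, float]  # median (U test) or mean (t tests)
    alternative: str = "greater"
    degenerate: bool = False  # e.g. zero-variance paired differences

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_a"] = list(self.ci_a)
        d["ci_b"] = list(self.ci_b)
        return d


@dataclass
class SurrogateResult:
    """Observed statistic vs a shuffle/reassignment null distribution."""

    observed_stat: float
    null_samples: np.ndarray
    n_surrogate: int
    p_value: float  # upper tail, (k+1)/(n+1)
    theoretical_min: float
    theoretical_max: float  # = number of included subjects
    n_subjects: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_stat": float(self.observed_stat),
            "n_surrogate": int(self.n_surrogate),
            "p_value": float(self.p_value),
            "theoretical_min": float(self.theoretical_min),
            "theoretical_max": float(self.theoretical_max),
            "n_subjects": int(self.n_subjects),
            "n_excluded": int(self.n_excluded),
            "null_mean": float(np.mean(self.null_samples)),
            "null_sd": float(np.std(self.null_samples)),
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalize_lengths(lengths: Sequence[float]) -> np.ndarray:
    """Divide each essay length by the subject's total; zeros stay zero.

    Raises :class:`InsufficientDataError` when the total is zero (the subject
    wrote nothing and must be excluded upstream).
    """
    arr = np.asarray(lengths, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise InsufficientDataError("total essay length is zero")
    return arr / total


def filter_by_confidence(confidence: Sequence[float], band: str) -> np.ndarray:
    """Boolean mask of words in a confidence band.

    Bands: ``"analyzed"`` 50 <= c <= 100, ``"lower"`` 50 <= c <= 75,
    ``"upper"`` 75 < c <= 100, ``"certain"`` c = 100.  Note c = 75 belongs to
    the lower band only.
    """
    try:
        fn = _BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(_BANDS)}")
    return fn(np.asarray(confidence, dtype=float))


def probability_of_superiority(a: Sequence[float], b: Sequence[float]) -> float:
    """PS = P(A > B) + 0.5 P(A = B) over all cross-group pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _bootstrap_ci(
    x: np.ndarray,
    stat_fn,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``stat_fn`` over resamples of ``x``."""
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    reps = stat_fn(x[idx], axis=1)
    lo, hi = np.percentile(reps, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else np.nan


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "mann-whitney",
    alternative: str = "greater",
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> GroupComparison:
    """Compare two samples with the configured test, one-sided by default.

    ``test`` is one of ``"mann-whitney"`` (U test, PS effect size, bootstrap
    CIs of medians), ``"t-independent"`` (Cohen's d, CIs of means) or
    ``"t-paired"`` (d_z, CIs of means).  ``alternative`` states the
    pre-registered direction for group ``a`` relative to ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    min_n = 1 if test == "mann-whitney" else 2
    if len(a) < min_n or len(b) < min_n:
        raise InsufficientDataError(
            f"{test} needs n >= {min_n} per group; got n_a={len(a)}, n_b={len(b)}"
        )
    rng = np.random.default_rng(seed)
    degenerate = False
    if test == "mann-whitney":
        res = sps.mannwhitneyu(a, b, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
        es_name, es = "PS", probability_of_superiority(a, b)
        ci_stat = np.median
    elif test == "t-independent":
        res = sps.ttest_ind(a, b, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
        es_name, es = "d", _cohens_d(a, b)
        ci_stat = np.mean
    elif test == "t-paired":
        if len(a) != len(b):
            raise InsufficientDataError("paired test needs equal-length samples")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            # constant shift: t undefined; flag rather than fabricate
            degenerate = True
            stat, p, es = np.nan, np.nan, np.nan
        else:
            res = sps.ttest_rel(a, b, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
            es = float(d.mean() / sd)
        es_name = "d_z"
        ci_stat = np.mean
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test=test,
        statistic=stat,
        p_value=p,
        effect_size_name=es_name,
        effect_size=es,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        ci_a=_bootstrap_ci(a, ci_stat, n_boot, rng),
        ci_b=_bootstrap_ci(b, ci_stat, n_boot, rng),
        alternative=alternative,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# surrogate-data tests
# ---------------------------------------------------------------------------

def _surrogate_p(observed: float, null: np.ndarray) -> float:
    return float((1 + np.count_nonzero(null >= observed)) / (len(null) + 1))


def dot_product_surrogate_test(
    dataset: BehaviorDataset,
    n_surrogate: int = 10_000,
    seed: Optional[int] = None,
    word_set: str = "analyzed",
) -> SurrogateResult:
    """Confidence-length association test by within-subject shuffling.

    Per subject, the confidence and essay-length vectors over the analyzed
    words (50 <= c <= 100 by default; ``word_set="all"`` uses every word) are
    L2-unitized and their dot product taken; the statistic is the sum over
    subjects, so its theoretical range is [0, n_subjects] (all entries are
    non-negative, and parallel vectors give 1 per subject).  The null
    distribution shuffles each subject's length vector components, keeping
    the confidence vector fixed.  Upper-tail p with the +1 correction.

    Subjects with fewer than two qualifying words or a zero-norm length or
    confidence vector are excluded (counted in ``n_excluded``).
    """
    if word_set not in ("analyzed", "all"):
        raise ValueError("word_set must be 'analyzed' or 'all'")
    rng = np.random.default_rng(seed)
    observed = 0.0
    null = np.zeros(n_surrogate)
    n_inc = n_exc = 0
    for s in dataset.subjects:
        if word_set == "analyzed":
            mask = filter_by_confidence(s.confidence, "analyzed")
        else:
            mask = np.ones(s.n_words, dtype=bool)
        conf = s.confidence[mask]
        length = s.essay_len[mask]
        if conf.size < 2 or np.linalg.norm(length) == 0 or np.linalg.norm(conf) == 0:
            n_exc += 1
            continue
        u_conf = conf / np.linalg.norm(conf)
        u_len = length / np.linalg.norm(length)
        observed += float(u_conf @ u_len)
        shuffled = rng.permuted(
            np.broadcast_to(u_len, (n_surrogate, u_len.size)).copy(), axis=1
        )
        null += shuffled @ u_conf
        n_inc += 1
    if n_inc == 0:
        raise InsufficientDataError("no subjects qualify for the dot-product test")
    return SurrogateResult(
        observed_stat=observed,
        null_samples=null,
        n_surrogate=n_surrogate,
        p_value=_surrogate_p(observed, null),
        theoretical_min=0.0,
        theoretical_max=float(n_inc),
        n_subjects=n_inc,
        n_excluded=n_exc,
    )


def letter_reassignment_surrogate_test(
    dataset: BehaviorDataset,
    n_surrogate: int = 10_000,
    seed: Optional[int] = None,
) -> SurrogateResult:
    """Spontaneous-vs-forced essay-length test among certain words (c = 100).

    Per subject, lengths of the certain words are renormalized to total 1 and
    the statistic is the summed normalized length of the *spontaneously*
    memorized certain words.  The null reassigns the subject's letters (total
    character count) uniformly at random over the subject's certain words
    (multinomial), renormalizes, and sums the spontaneous entries.  Upper-tail
    p with the +1 correction; theoretical range [0, n_subjects].

    Subjects without a certain word, or whose certain words carry no letters,
    are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    observed = 0.0
    null = np.zeros(n_surrogate)
    n_inc = n_exc = 0
    for s in dataset.subjects:
        certain = filter_by_confidence(s.confidence, "certain")
        lengths = np.round(s.essay_len[certain]).astype(int)
        spont = s.condition_mask("spontaneous")[certain]
        total = int(lengths.sum())
        if certain.sum() == 0 or total <= 0:
            n_exc += 1
            continue
        observed += float(lengths[spont].sum() / total)
        k = lengths.size
        counts = rng.multinomial(total, np.full(k, 1.0 / k), size=n_surrogate)
        null += counts[:, spont].sum(axis=1) / total
        n_inc += 1
    if n_inc == 0:
        raise InsufficientDataError(
            "no subjects with certain-confidence words carrying letters"
        )
    return SurrogateResult(
        observed_stat=observed,
        null_samples=null,
        n_surrogate=n_surrogate,
        p_value=_surrogate_p(observed, null),
        theoretical_min=0.0,
        theoretical_max=float(n_inc),
        n_subjects=n_inc,
        n_excluded=n_exc,
    )
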