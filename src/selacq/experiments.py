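"""End-to-end analysis pipelines for the two behavioral experiments.

Both follow the statsmodels idiom: an analysis object is built from data,
``fit()`` runs every test and returns a results object carrying
:class:`~selacq.stats.GroupComparison` and
:class:`~selacq.stats.SurrogateResult` entries with a ``summary()`` table.

Experiment 1 (all words presented once): does essay length track recognition
confidence?  Pipeline: normalize lengths within subject -> restrict to the
analyzed confidence range (50-100) -> compare per-subject mean normalized
lengths between the lower (50 <= c <= 75) and upper (75 < c <= 100) bands
(Mann-Whitney, one-sided) -> confidence-length dot-product surrogate test ->
optional semantic comparison (paired, upper band hypothesized more
dissimilar).

Experiment 2 (two words presented five times to force memorization): does
strong memory per se explain longer essays?  Adds per-condition
certain-rating proportions, spontaneous-vs-forced length comparisons on the
upper and certain bands, the letter-reassignment surrogate test, and an
independent-samples semantic comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from selacq.dataset import BehaviorDataset
from selacq.semantic import EmbeddingModel, essay_similarity
from selacq.stats import (
    GroupComparison,
    InsufficientDataError,
    SurrogateResult,
    compare_groups,
    dot_product_surrogate_test,
    filter_by_confidence,
    letter_reassignment_surrogate_test,
    normalize_lengths,
)

logger = logging.getLogger(__name__)


def _band_means(dataset: BehaviorDataset, band: str,
                condition: Optional[str] = None) -> list[float]:
    """Per-subject mean normalized essay length over words in a confidence
    band (optionally restricted to one presentation condition).

    A subject contributes only if it has >= 1 word in the band (and a nonzero
    essay total); all-zero-essay subjects are excluded with a log entry.
    """
    values = []
    for s in dataset.subjects:
        if s.essay_len.sum() <= 0:
            logger.info("subject %s wrote no essays; excluded", s.subject_id)
            continue
        norm = normalize_lengths(s.essay_len)
        mask = filter_by_confidence(s.confidence, band)
        if condition is not None:
            mask &= s.condition_mask(condition)
        if mask.any():
            values.append(float(norm[mask].mean()))
    return values


def _semantic_scores(dataset: BehaviorDataset, embedding: EmbeddingModel,
                     band: str, condition: Optional[str] = None) -> dict[str, float]:
    """subject_id -> mean essay similarity over selected words in a band."""
    scores: dict[str, float] = {}
    for s in dataset.subjects:
        if s.essay_tokens is None:
            continue
        mask = filter_by_confidence(s.confidence, band) & (s.essay_len > 0)
        if condition is not None:
            mask &= s.condition_mask(condition)
        sims = []
        for k in np.nonzero(mask)[0]:
            toks = s.essay_tokens[k]
            if not toks:
                continue
            word = dataset.words.get(s.words[k]) if dataset.words else None
            if word is None:
                continue
            es = essay_similarity(embedding, toks, word)
            if es.defined:
                sims.append(es.mean_similarity)
        if sims:
            scores[s.subject_id] = float(np.mean(sims))
    return scores


@dataclass
class Experiment1Results:
    """Fitted results of :class:`Experiment1Analysis`."""

    length_comparison: GroupComparison  # upper vs lower band
    dot_product_test: SurrogateResult
    semantic_comparison: Optional[GroupComparison] = None  # upper vs lower, paired
    n_semantic_pairs: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [_comparison_row("norm. length: upper vs lower band",
                                self.length_comparison),
                _surrogate_row("confidence-length dot product", self.dot_product_test)]
        if self.semantic_comparison is not None:
            rows.append(_comparison_row(
                "semantic similarity: upper vs lower (paired)",
                self.semantic_comparison))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "length_comparison": self.length_comparison.to_dict(),
            "dot_product_test": self.dot_product_test.to_dict(),
        }
        if self.semantic_comparison is not None:
            out["semantic_comparison"] = self.semantic_comparison.to_dict()
            out["n_semantic_pairs"] = self.n_semantic_pairs
        return out


@dataclass
class Experiment2Results:
    """Fitted results of :class:`Experiment2Analysis`."""

    certain_proportion_comparison: GroupComparison  # forced vs spontaneous
    once_lower_upper_comparison: GroupComparison  # replication of exp 1
    spont_forced_upper_comparison: GroupComparison
    spont_forced_certain_comparison: GroupComparison
    letter_test: SurrogateResult
    semantic_comparison: Optional[GroupComparison] = None  # spont vs forced, indep.

    def summary(self) -> pd.DataFrame:
        rows = [
            _comparison_row("certain-rating measure: forced vs spontaneous",
                            self.certain_proportion_comparison),
            _comparison_row("once-presented norm. length: upper vs lower",
                            self.once_lower_upper_comparison),
            _comparison_row("norm. length upper band: spontaneous vs forced",
                            self.spont_forced_upper_comparison),
            _comparison_row("norm. length certain band: spontaneous vs forced",
                            self.spont_forced_certain_comparison),
            _surrogate_row("letter-reassignment (certain words)", self.letter_test),
        ]
        if self.semantic_comparison is not None:
            rows.append(_comparison_row(
                "semantic similarity: spontaneous vs forced (independent)",
                self.semantic_comparison))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "certain_proportion_comparison": self.certain_proportion_comparison.to_dict(),
            "once_lower_upper_comparison": self.once_lower_upper_comparison.to_dict(),
            "spont_forced_upper_comparison": self.spont_forced_upper_comparison.to_dict(),
            "spont_forced_certain_comparison": self.spont_forced_certain_comparison.to_dict(),
            "letter_test": self.letter_test.to_dict(),
        }
        if self.semantic_comparison is not None:
            out["semantic_comparison"] = self.semantic_comparison.to_dict()
        return out


def _comparison_row(label: str, c: GroupComparison) -> dict:
    return {
        "analysis": label,
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "effect": f"{c.effect_size_name}={c.effect_size:.3f}",
        "n": f"{c.n_a}/{c.n_b}",
    }


def _surrogate_row(label: str, r: SurrogateResult) -> dict:
    return {
        "analysis": label,
        "test": "surrogate",
        "statistic": r.observed_stat,
        "p_value": r.p_value,
        "effect": f"null mean={np.mean(r.null_samples):.3f}",
        "n": str(r.n_subjects),
    }


class Experiment1Analysis:
    """Confidence-productivity analysis for once-presented words."""

    def __init__(self, dataset: BehaviorDataset,
                 embedding: Optional[EmbeddingModel] = None):
        self.dataset = dataset
        self.embedding = embedding

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       embedding: Optional[EmbeddingModel] = None) -> "Experiment1Analysis":
        return cls(BehaviorDataset.from_dataframe(df, experiment_tag="exp1"),
                   embedding=embedding)

    def fit(self, n_surrogate: int = 10_000, n_boot: int = 10_000,
            seed: Optional[int] = None) -> Experiment1Results:
        rng = np.random.default_rng(seed)
        upper = _band_means(self.dataset, "upper")
        lower = _band_means(self.dataset, "lower")
        if not upper or not lower:
            raise InsufficientDataError(
                "no subjects remain in the upper or lower confidence band"
            )
        length_cmp = compare_groups(
            upper, lower, test="mann-whitney", alternative="greater",
            n_boot=n_boot, seed=int(rng.integers(2**31)),
        )
        dot_test = dot_product_surrogate_test(
            self.dataset, n_surrogate=n_surrogate, seed=int(rng.integers(2**31))
        )
        semantic_cmp = None
        n_pairs = 0
        if self.embedding is not None and self.dataset.words:
            up = _semantic_scores(self.dataset, self.embedding, "upper")
            lo = _semantic_scores(self.dataset, self.embedding, "lower")
            both = sorted(set(up) & set(lo))
            n_pairs = len(both)
            if n_pairs >= 2:
                semantic_cmp = compare_groups(
                    [up[s] for s in both], [lo[s] for s in both],
                    test="t-paired", alternative="less",
                    n_boot=n_boot, seed=int(rng.integers(2**31)),
                )
            else:
                logger.warning("only %d subjects with scores in both bands; "
                               "semantic comparison skipped", n_pairs)
        return Experiment1Results(length_cmp, dot_test, semantic_cmp, n_pairs)


class Experiment2Analysis:
    """Spontaneous-vs-forced memorization analysis."""

    def __init__(self, dataset: BehaviorDataset,
                 embedding: Optional[EmbeddingModel] = None,
                 certain_measure: str = "proportion"):
        if not dataset.has_condition("forced"):
            raise ValueError(
                "experiment-2 analysis needs force-presented words in the dataset"
            )
        if certain_measure not in ("proportion", "count"):
            raise ValueError("certain_measure must be 'proportion' or 'count'")
        self.dataset = dataset
        self.embedding = embedding
        self.certain_measure = certain_measure

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       embedding: Optional[EmbeddingModel] = None,
                       certain_measure: str = "proportion") -> "Experiment2Analysis":
        return cls(BehaviorDataset.from_dataframe(df, experiment_tag="exp2"),
                   embedding=embedding, certain_measure=certain_measure)

    def _certain_measure_by_condition(self, condition: str) -> list[float]:
        values = []
        for s in self.dataset.subjects:
            cond = s.condition_mask(condition)
            if not cond.any():
                continue
            n_certain = float((filter_by_confidence(s.confidence, "certain") & cond).sum())
            if self.certain_measure == "proportion":
                values.append(n_certain / cond.sum())
            else:
                values.append(n_certain)
        return values

    def fit(self, n_surrogate: int = 10_000, n_boot: int = 10_000,
            seed: Optional[int] = None) -> Experiment2Results:
        rng = np.random.default_rng(seed)

        def sub_seed() -> int:
            return int(rng.integers(2**31))

        certain_cmp = compare_groups(
            self._certain_measure_by_condition("forced"),
            self._certain_measure_by_condition("spontaneous"),
            test="mann-whitney", alternative="two-sided",
            n_boot=n_boot, seed=sub_seed(),
        )
        once_cmp = compare_groups(
            _band_means(self.dataset, "upper", condition="spontaneous"),
            _band_means(self.dataset, "lower", condition="spontaneous"),
            test="mann-whitney", alternative="greater",
            n_boot=n_boot, seed=sub_seed(),
        )
        sf_upper = compare_groups(
            _band_means(self.dataset, "upper", condition="spontaneous"),
            _band_means(self.dataset, "upper", condition="forced"),
            test="mann-whitney", alternative="greater",
            n_boot=n_boot, seed=sub_seed(),
        )
        sf_certain = compare_groups(
            _band_means(self.dataset, "certain", condition="spontaneous"),
            _band_means(self.dataset, "certain", condition="forced"),
            test="mann-whitney", alternative="greater",
            n_boot=n_boot, seed=sub_seed(),
        )
        letter = letter_reassignment_surrogate_test(
            self.dataset, n_surrogate=n_surrogate, seed=sub_seed()
        )
        semantic_cmp = None
        if self.embedding is not None and self.dataset.words:
            sp = _semantic_scores(self.dataset, self.embedding, "upper", "spontaneous")
            fo = _semantic_scores(self.dataset, self.embedding, "upper", "forced")
            if len(sp) >= 2 and len(fo) >= 2:
                semantic_cmp = compare_groups(
                    list(sp.values()), list(fo.values()),
                    test="t-independent", alternative="less",
                    n_boot=n_boot, seed=sub_seed(),
                )
            else:
                logger.warning("too few subjects per condition for the semantic "
                               "comparison (%d/%d)", len(sp), len(fo))
        return Experiment2Results(
            certain_cmp, once_cmp, sf_upper, sf_certain, letter, semantic_cmp
        )
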