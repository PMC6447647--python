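"""Tabular behavioral data: per-subject words, conditions, confidences, essays.

The on-disk format is a flat TSV/CSV with one row per subject x word and
columns ``subject_id, word_id, condition, confidence, essay_len`` plus
optional ``essay_tokens`` (space-separated) — the schema both the analysis
pipeline and the synthetic generator speak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

CONDITIONS = ("spontaneous", "forced")  # presented once vs five times per block


class SchemaError(ValueError):
    """Input table violates the expected schema."""


@dataclass
class SubjectRecord:
    """One subject's words, presentation conditions, ratings and essays."""

    subject_id: str
    words: list[str]
    condition: list[str]  # per word, "spontaneous" or "forced"
    confidence: np.ndarray  # per word, 0-100
    essay_len: np.ndarray  # per word, character count; 0 if not selected
    essay_tokens: Optional[list[Optional[list[str]]]] = None  # per word

    def __post_init__(self) -> None:
        n = len(self.words)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.essay_len = np.asarray(self.essay_len, dtype=float)
        if not (len(self.condition) == n and len(self.confidence) == n
                and len(self.essay_len) == n):
            raise SchemaError(f"subject {self.subject_id}: ragged per-word arrays")
        if np.any((self.confidence < 0) | (self.confidence > 100)):
            raise SchemaError(f"subject {self.subject_id}: confidence outside [0, 100]")
        if np.any(self.essay_len < 0):
            raise SchemaError(f"subject {self.subject_id}: negative essay length")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"subject {self.subject_id}: unknown conditions {bad}")
        if self.essay_tokens is not None and len(self.essay_tokens) != n:
            raise SchemaError(f"subject {self.subject_id}: ragged essay_tokens")

    @property
    def n_words(self) -> int:
        return len(self.words)

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for c in self.condition])


@dataclass
class BehaviorDataset:
    """A collection of subjects plus optional word metadata."""

    subjects: list[SubjectRecord]
    experiment_tag: str = ""
    # word_id -> CompositionalWord (selacq.semantic); filled by the essay
    # generator or by the caller when semantic scoring is wanted
    words: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise SchemaError("a dataset needs at least one subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def has_condition(self, condition: str) -> bool:
        return any(any(c == condition for c in s.condition) for s in self.subjects)

    # -- interchange ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for k, w in enumerate(s.words):
                row = {
                    "subject_id": s.subject_id,
                    "word_id": w,
                    "condition": s.condition[k],
                    "confidence": s.confidence[k],
                    "essay_len": int(s.essay_len[k]),
                }
                if s.essay_tokens is not None:
                    toks = s.essay_tokens[k]
                    row["essay_tokens"] = " ".join(toks) if toks else ""
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, experiment_tag: str = "") -> "BehaviorDataset":
        required = {"subject_id", "word_id", "condition", "confidence", "essay_len"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        has_tokens = "essay_tokens" in df.columns
        subjects = []
        for sid, g in df.groupby("subject_id", sort=False):
            tokens = None
            if has_tokens:
                tokens = [
                    str(t).split() if isinstance(t, str) and t.strip() else None
                    for t in g["essay_tokens"]
                ]
            subjects.append(
                SubjectRecord(
                    subject_id=str(sid),
                    words=[str(w) for w in g["word_id"]],
                    condition=[str(c) for c in g["condition"]],
                    confidence=g["confidence"].to_numpy(),
                    essay_len=g["essay_len"].to_numpy(),
                    essay_tokens=tokens,
                )
            )
        return cls(subjects=subjects, experiment_tag=experiment_tag)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, experiment_tag: str = "") -> "BehaviorDataset":
        df = pd.read_csv(path, sep="\t")
        return cls.from_dataframe(df, experiment_tag=experiment_tag)
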