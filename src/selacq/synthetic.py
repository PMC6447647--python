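"""Synthetic behavioral datasets and toy embeddings.

The subject data behind the analyses are not public, so the generator
emulates their structure: each subject sees ``n_words`` novel compositional
words (optionally ``n_forced`` of them presented five times instead of once),
rates recognition confidence 0-100, selects a subset to write essays about,
and produces essays whose lengths may or may not track a latent per-word
salience.  Every effect is a dial:

* ``conf_effect`` couples salience to confidence;
* ``forced_conf_boost`` inflates confidence for force-presented words;
* ``length_effect`` couples salience to essay selection and length — 0 gives
  the exact null of the confidence-length tests;
* ``semantic_leap`` steers essay tokens away from the word's component
  cluster in the toy embedding.

With all effect dials at 0 the dataset satisfies the null hypothesis of
every test in :mod:`selacq.stats`; generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from selacq.dataset import BehaviorDataset, SubjectRecord
from selacq.semantic import CompositionalWord, EmbeddingModel


@dataclass
class GeneratorConfig:
    """Dials of the behavioral-data generator.

    Distribution families are generator choices: confidence is a rounded,
    clipped Gaussian around ``conf_mid``; essay lengths are log-normal
    (character counts are positive and right-skewed).
    """

    n_subjects: int = 30
    n_words: int = 20
    n_forced: int = 2  # words presented five times; 0 emulates experiment 1
    conf_effect: float = 15.0  # confidence points per unit salience
    conf_mid: float = 75.0
    conf_noise_sd: float = 10.0
    forced_conf_boost: float = 0.0  # confidence inflation for forced words
    length_effect: float = 0.0  # salience -> log-length slope (0 = null)
    selection_rate: float = 0.4  # expected fraction of words with an essay
    semantic_leap: float = 0.3  # P(essay token leaves the component cluster)
    total_letters_mean: float = 1000.0  # expected letters per subject
    length_log_sd: float = 0.5
    tokens_per_char: float = 0.05  # essay token count per character
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.n_forced < self.n_words:
            raise ValueError("need 0 <= n_forced < n_words")
        for name in ("selection_rate", "semantic_leap"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("conf_effect", "forced_conf_boost", "length_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ToyEmbeddingSpec:
    """Geometry of the toy clustered embedding.

    Cluster centroids are exactly orthonormal (QR of a Gaussian matrix);
    token vectors are unit-normalized centroid-plus-isotropic-noise with the
    noise scale solved so the expected intra-cluster cosine matches
    ``within_cluster_cos``; inter-cluster cosines are ~0 by orthogonality.
    """

    n_clusters: int = 8
    tokens_per_cluster: int = 12
    dim: int = 50
    within_cluster_cos: float = 0.7
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_clusters > self.dim:
            raise ValueError("need n_clusters <= dim for orthogonal centroids")
        if not 0.0 < self.within_cluster_cos < 1.0:
            raise ValueError("within_cluster_cos must lie in (0, 1)")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(cfg: GeneratorConfig) -> BehaviorDataset:
    """Draw a full behavioral dataset.

    Per subject and word: latent salience ~ N(0, 1); confidence =
    round(clip(conf_mid + conf_effect * salience + noise [+ boost if
    forced])); essay written with probability
    logistic(logit(selection_rate) + length_effect * salience); essay length
    log-normal with log-location shifted by length_effect * salience.
    """
    rng = np.random.default_rng(cfg.seed)
    n_selected_mean = max(cfg.n_words * cfg.selection_rate, 1.0)
    # log-normal location so that E[total letters] ~ total_letters_mean
    mu0 = np.log(cfg.total_letters_mean / n_selected_mean) - 0.5 * cfg.length_log_sd**2
    base_logit = np.log(cfg.selection_rate / (1.0 - cfg.selection_rate)) \
        if 0 < cfg.selection_rate < 1 else np.inf * (1 if cfg.selection_rate >= 1 else -1)
    subjects = []
    word_ids = [f"w{k:02d}" for k in range(cfg.n_words)]
    for s in range(cfg.n_subjects):
        salience = rng.standard_normal(cfg.n_words)
        forced_idx = rng.choice(cfg.n_words, size=cfg.n_forced, replace=False)
        forced = np.zeros(cfg.n_words, dtype=bool)
        forced[forced_idx] = True
        conf = (
            cfg.conf_mid
            + cfg.conf_effect * salience
            + cfg.conf_noise_sd * rng.standard_normal(cfg.n_words)
            + cfg.forced_conf_boost * forced
        )
        conf = np.clip(np.round(conf), 0, 100)
        p_sel = _logistic(base_logit + cfg.length_effect * salience)
        selected = rng.random(cfg.n_words) < p_sel
        lengths = np.zeros(cfg.n_words)
        k = int(selected.sum())
        if k:
            lengths[selected] = np.round(
                np.exp(
                    mu0
                    + cfg.length_effect * salience[selected]
                    + cfg.length_log_sd * rng.standard_normal(k)
                )
            ).clip(min=1)
        subjects.append(
            SubjectRecord(
                subject_id=f"s{s:03d}",
                words=list(word_ids),
                condition=["forced" if f else "spontaneous" for f in forced],
                confidence=conf,
                essay_len=lengths,
            )
        )
    tag = "exp2" if cfg.n_forced > 0 else "exp1"
    return BehaviorDataset(subjects=subjects, experiment_tag=tag)


def reassign_letters_null(dataset: BehaviorDataset,
                          seed: Optional[int] = None) -> BehaviorDataset:
    """Sample a dataset from the letter-reassignment test's null hypothesis.

    Per subject, the total letter count over the certain-confidence words
    (c = 100) is redistributed uniformly at random over those words
    (multinomial); everything else is copied.  Under datasets drawn this way
    the letter-reassignment surrogate test is exactly calibrated.  Note this
    is a *different* null than independent log-normal lengths: the
    multinomial null asserts exchangeability of individual letters across a
    subject's certain words, not of whole essay lengths, and is much tighter
    than typical length variability.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for s in dataset.subjects:
        lengths = s.essay_len.copy()
        certain = (s.confidence == 100)
        k = int(certain.sum())
        total = int(round(lengths[certain].sum()))
        if k >= 1 and total > 0:
            lengths[certain] = rng.multinomial(total, np.full(k, 1.0 / k))
        subjects.append(
            SubjectRecord(
                subject_id=s.subject_id,
                words=list(s.words),
                condition=list(s.condition),
                confidence=s.confidence.copy(),
                essay_len=lengths,
                essay_tokens=s.essay_tokens,
            )
        )
    return BehaviorDataset(subjects=subjects, experiment_tag=dataset.experiment_tag,
                           words=dataset.words)


def _cluster_component_tokens(k: int) -> tuple[str, str]:
    return (f"c{k}_compA", f"c{k}_compB")


def generate_toy_embedding(spec: ToyEmbeddingSpec) -> EmbeddingModel:
    """Build a clustered embedding with known geometry.

    Each cluster contributes two designated component tokens
    (``c{k}_compA``/``c{k}_compB``) plus ``tokens_per_cluster`` ordinary
    tokens ``c{k}_t{i}``; all vectors are unit norm.
    """
    rng = np.random.default_rng(spec.seed)
    q, _ = np.linalg.qr(rng.standard_normal((spec.dim, spec.n_clusters)))
    centroids = q.T  # (n_clusters, dim), orthonormal rows
    w = spec.within_cluster_cos
    # token = unit(c + s*g), g ~ N(0, I): E[cos(token_i, token_j)] ~ 1/(1+s^2) = w
    s = np.sqrt((1.0 - w) / w)
    noise_scale = s / np.sqrt(spec.dim)
    vectors: dict[str, np.ndarray] = {}
    for k in range(spec.n_clusters):
        names = list(_cluster_component_tokens(k)) + [
            f"c{k}_t{i}" for i in range(spec.tokens_per_cluster)
        ]
        for name in names:
            v = centroids[k] + noise_scale * rng.standard_normal(spec.dim)
            vectors[name] = v / np.linalg.norm(v)
    return EmbeddingModel(vectors)


def generate_essays(
    dataset: BehaviorDataset,
    embedding: EmbeddingModel,
    cfg: GeneratorConfig,
    spec: Optional[ToyEmbeddingSpec] = None,
) -> BehaviorDataset:
    """Fill in essay tokens drawn from a cluster mixture.

    Each word id is mapped round-robin to a component cluster of the toy
    embedding; each token of a selected word's essay comes from the word's
    own cluster with probability ``1 - semantic_leap`` and from a uniformly
    chosen other cluster otherwise, so the expected essay similarity
    decreases strictly in ``semantic_leap``.  Token count is proportional to
    the essay's character count.  Returns a new dataset with ``essay_tokens``
    and the word -> components map filled in.
    """
    rng = np.random.default_rng(cfg.seed)
    cluster_tokens: dict[int, list[str]] = {}
    n_clusters = 0
    while True:
        names = [f"c{n_clusters}_t{i}" for i in range(10_000) if f"c{n_clusters}_t{i}" in embedding]
        if not names:
            break
        cluster_tokens[n_clusters] = names
        n_clusters += 1
    if n_clusters < 2:
        raise ValueError("essay generation needs >= 2 clusters in the embedding")

    word_ids = sorted({w for s in dataset.subjects for w in s.words})
    word_cluster = {w: i % n_clusters for i, w in enumerate(word_ids)}
    words = {
        w: CompositionalWord(w, *_cluster_component_tokens(word_cluster[w]))
        for w in word_ids
    }
    new_subjects = []
    for s in dataset.subjects:
        tokens: list[Optional[list[str]]] = []
        for k, w in enumerate(s.words):
            if s.essay_len[k] <= 0:
                tokens.append(None)
                continue
            n_tok = max(1, int(round(s.essay_len[k] * cfg.tokens_per_char)))
            own = word_cluster[w]
            others = [c for c in range(n_clusters) if c != own]
            leap = rng.random(n_tok) < cfg.semantic_leap
            toks = []
            for is_leap in leap:
                c = int(rng.choice(others)) if is_leap else own
                toks.append(str(rng.choice(cluster_tokens[c])))
            tokens.append(toks)
        new_subjects.append(
            SubjectRecord(
                subject_id=s.subject_id,
                words=list(s.words),
                condition=list(s.condition),
                confidence=s.confidence.copy(),
                essay_len=s.essay_len.copy(),
                essay_tokens=tokens,
            )
        )
    return BehaviorDataset(
        subjects=new_subjects, experiment_tag=dataset.experiment_tag, words=words
    )
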