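"""Semantic grouping of departments by the similarity of their papers' abstracts.

Departments with the same extracted name and top-level institution are pooled;
each department's profile is the mean of its papers' abstract vectors. An
abstract vector is the L2-normalized mean of its tokens' word vectors. Word
vectors come from a count-based distributional model trained on a seeded
random sample of the abstract corpus: windowed co-occurrence counts are
reweighted by positive pointwise mutual information and factored with a
truncated SVD, which is deterministic for a fixed seed. Out-of-vocabulary
tokens fall back to character-n-gram vectors (the mean vector of training
words sharing the n-gram), so unseen morphological variants still embed near
their relatives; a token with no vocabulary and no n-gram support contributes
nothing, and an abstract with no embeddable token at all is flagged and
excluded downstream.

Department profiles are reduced to 2-D with t-SNE (default perplexity 7) and
clustered with k-means (default k = 10) *on the 2-D coordinates*; a flag
switches clustering to the full-dimensional vectors for users who prefer it.
Rankings by index value are only meaningful within a cluster — fields differ
in reporting standards, so cross-cluster comparisons are discouraged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.manifold import TSNE

__all__ = [
    "WordEmbeddingModel",
    "AbstractVector",
    "DepartmentProfile",
    "train_embeddings",
    "embed_abstract",
    "build_profiles",
    "cluster_departments",
    "rank_within_clusters",
    "tokenize",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-'][a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _char_ngrams(token: str, n_min: int = 3, n_max: int = 5) -> set[str]:
    padded = f"<{token}>"
    return {
        padded[i : i + n]
        for n in range(n_min, n_max + 1)
        for i in range(len(padded) - n + 1)
    }


@dataclass
class WordEmbeddingModel:
    """Distributional word vectors with a character-n-gram OOV fallback."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim), rows L2-normalized (zero rows allowed)
    dim: int
    seed: int
    ngram_index: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def vector(self, token: str) -> np.ndarray | None:
        """The token's vector, via vocabulary or n-gram fallback; None if neither."""
        idx = self.vocab.get(token)
        if idx is not None:
            v = self.vectors[idx]
            return v if np.any(v) else None
        rows: list[int] = []
        for ng in _char_ngrams(token):
            rows.extend(self.ngram_index.get(ng, ()))
        if not rows:
            return None
        v = self.vectors[sorted(set(rows))].mean(axis=0)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else None


def train_embeddings(
    abstract_corpus: Sequence[str],
    sample_fraction: float = 0.01,
    dim: int = 300,
    seed: int = 0,
    window: int = 5,
    min_count: int = 1,
) -> WordEmbeddingModel:
    """Train word vectors on a seeded random sample of the abstracts.

    Co-occurrence counts within a symmetric window are PPMI-reweighted and
    factored with truncated SVD. When the sampled vocabulary is smaller than
    ``dim`` the spectrum is exhausted early and the remaining components are
    zero-padded, so vectors always have length ``dim``.
    """
    corpus = list(abstract_corpus)
    if not corpus:
        raise ValueError("abstract corpus is empty")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sample = max(1, int(round(sample_fraction * len(corpus))))
    sample_idx = sorted(rng.choice(len(corpus), size=n_sample, replace=False))
    sample = [corpus[i] for i in sample_idx]

    counts: dict[str, int] = {}
    tokenized = [tokenize(text) for text in sample]
    for toks in tokenized:
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    vocab = {t: i for i, t in enumerate(sorted(t for t, c in counts.items() if c >= min_count))}
    if not vocab:
        raise ValueError("no tokens above min_count in the sampled corpus")
    V = len(vocab)

    rows, cols, data = [], [], []
    for toks in tokenized:
        ids = [vocab[t] for t in toks if t in vocab]
        for i, wi in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if i == j:
                    continue
                rows.append(wi)
                cols.append(ids[j])
                data.append(1.0)
    cooc = sparse.coo_matrix((data, (rows, cols)), shape=(V, V)).tocsr()

    # positive PMI reweighting
    total = cooc.sum()
    if total == 0:
        ppmi = cooc
    else:
        row_sums = np.asarray(cooc.sum(axis=1)).ravel()
        col_sums = np.asarray(cooc.sum(axis=0)).ravel()
        coo = cooc.tocoo()
        with np.errstate(divide="ignore"):
            pmi = np.log(
                (coo.data * total)
                / (row_sums[coo.row] * col_sums[coo.col])
            )
        pmi = np.maximum(pmi, 0.0)
        ppmi = sparse.coo_matrix((pmi, (coo.row, coo.col)), shape=(V, V)).tocsr()

    k = min(dim, max(1, V - 1))
    svd = TruncatedSVD(n_components=k, random_state=seed)
    reduced = svd.fit_transform(ppmi)
    vectors = np.zeros((V, dim))
    vectors[:, :k] = reduced
    norms = np.linalg.norm(vectors, axis=1)
    nonzero = norms > 0
    vectors[nonzero] /= norms[nonzero, None]

    ngram_index: dict[str, list[int]] = {}
    for token, idx in vocab.items():
        if not np.any(vectors[idx]):
            continue
        for ng in _char_ngrams(token):
            ngram_index.setdefault(ng, []).append(idx)

    return WordEmbeddingModel(vocab=vocab, vectors=vectors, dim=dim, seed=seed, ngram_index=ngram_index)


@dataclass
class AbstractVector:
    """L2-normalized mean word vector of one abstract."""

    paper_id: str
    vector: np.ndarray
    embeddable: bool  # False when no token had a vector; excluded downstream


def embed_abstract(model: WordEmbeddingModel, text: str, paper_id: str = "") -> AbstractVector:
    """Mean of token vectors, L2-normalized; order of tokens is irrelevant."""
    if not text or not text.strip():
        raise ValueError("abstract text is empty")
    token_vectors = [v for t in tokenize(text) if (v := model.vector(t)) is not None]
    if not token_vectors:
        return AbstractVector(paper_id, np.zeros(model.dim), embeddable=False)
    v = np.mean(token_vectors, axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        return AbstractVector(paper_id, np.zeros(model.dim), embeddable=False)
    return AbstractVector(paper_id, v / norm, embeddable=True)


@dataclass
class DepartmentProfile:
    """Mean abstract vector and index value for one department."""

    department: str
    institution_id: str
    n_papers: int
    mean_vector: np.ndarray
    rti: float


def build_profiles(
    abstract_vectors: Mapping[str, AbstractVector],
    paper_departments: Mapping[str, tuple[str, str]],
    paper_scores: Mapping[str, float],
    min_papers: int = 200,
) -> list[DepartmentProfile]:
    """Pool papers by (department name, institution) into profiles.

    Only departments with more than ``min_papers`` papers are kept. Papers
    whose abstract could not be embedded, and papers with score 0 (not
    applicable), are excluded from the mean vector / index respectively.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for paper_id, key in paper_departments.items():
        groups.setdefault(key, []).append(paper_id)
    profiles = []
    for (dept, inst), paper_ids in sorted(groups.items()):
        vecs = [
            abstract_vectors[p].vector
            for p in paper_ids
            if p in abstract_vectors and abstract_vectors[p].embeddable
        ]
        scores = [paper_scores[p] for p in paper_ids if paper_scores.get(p, 0) > 0]
        if len(paper_ids) <= min_papers or not vecs or not scores:
            continue
        profiles.append(
            DepartmentProfile(
                department=dept,
                institution_id=inst,
                n_papers=len(paper_ids),
                mean_vector=np.mean(vecs, axis=0),
                rti=float(np.mean(scores)),
            )
        )
    return profiles


def cluster_departments(
    profiles: Sequence[DepartmentProfile],
    k: int = 10,
    perplexity: float = 7.0,
    seed: int = 0,
    reduce_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """t-SNE to 2-D, then k-means on the 2-D coordinates.

    Returns ``(labels, coords)`` aligned with ``profiles``. With
    ``reduce_first=False`` k-means runs on the full-dimensional mean vectors
    instead and the coordinates are returned for visualization only.
    """
    n = len(profiles)
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    X = np.vstack([p.mean_vector for p in profiles])
    tsne_perplexity = min(perplexity, max(1.0, (n - 1) / 3))
    coords = TSNE(
        n_components=2, perplexity=tsne_perplexity, random_state=seed, init="pca"
    ).fit_transform(X)
    km_input = coords if reduce_first else X
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(km_input)
    return labels, coords


def rank_within_clusters(
    profiles: Sequence[DepartmentProfile],
    labels: Iterable[int],
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Order departments by index value within each cluster.

    Ties are broken by larger paper count, then department name. Output
    columns match the export format: department, institution, n_papers, x, y,
    cluster, rti, rank_in_cluster.
    """
    rows = []
    for i, (p, lab) in enumerate(zip(profiles, labels)):
        rows.append(
            {
                "department": p.department,
                "institution": p.institution_id,
                "n_papers": p.n_papers,
                "x": float(coords[i, 0]) if coords is not None else np.nan,
                "y": float(coords[i, 1]) if coords is not None else np.nan,
                "cluster": int(lab),
                "rti": p.rti,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["cluster", "rti", "n_papers", "department"],
        ascending=[True, False, False, True],
    ).reset_index(drop=True)
    df["rank_in_cluster"] = df.groupby("cluster").cumcount() + 1
    return df
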