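"""Semantic spaces and their transforms.

Words live in two kinds of spaces here: a distributional embedding space
(an items x dims real matrix, one row per word) and a taxonomy (a rooted
tree whose leaves are the words).  Both are converted into item x item
similarity structure — a cosine kernel or Gram matrix ``X X^T`` for the
embedding, reciprocal path length for the taxonomy — and the cosine kernel
is further compressed into per-word factor scores by kernel PCA.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

__all__ = [
    "EmbeddingSpace",
    "TaxonomyTree",
    "SimilarityMatrix",
    "ComponentScores",
    "cosine_kernel",
    "dual_transform",
    "path_similarity_matrix",
    "kernel_pca",
    "top_scoring_words",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def _check_words(words: list[str]) -> list[str]:
    words = list(words)
    if len(set(words)) != len(words):
        seen: set[str] = set()
        for w in words:
            if w in seen:
                raise ValueError(f"duplicate word: {w!r}")
            seen.add(w)
    return words


@dataclass
class EmbeddingSpace:
    """A word list plus its dense items x dims embedding matrix."""

    words: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.words = _check_words(self.words)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.matrix.shape[0] != len(self.words):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but "
                f"{len(self.words)} words"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def dims(self) -> int:
        return self.matrix.shape[1]


class TaxonomyTree:
    """A rooted tree over a word set; each word is exactly one leaf.

    Backed by a :class:`skbio.TreeNode`.  Distances between words count
    edges on the unique leaf-to-leaf path (branch lengths are ignored),
    matching taxonomic distance through the lowest common ancestor.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [tip.name for tip in root.tips()]
        if any(n is None for n in names):
            raise ValueError("taxonomy has unnamed leaves")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._words = names

    @property
    def words(self) -> list[str]:
        return list(self._words)

    @property
    def n_leaves(self) -> int:
        return len(self._words)

    @classmethod
    def from_newick(cls, text: str) -> "TaxonomyTree":
        try:
            root = TreeNode.read(_io.StringIO(text))
        except Exception as exc:  # skbio raises several parse error types
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls(root)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.root.write(buf)
        return buf.getvalue()

    @classmethod
    def from_linkage(cls, linkage_matrix: np.ndarray, words: list[str]) -> "TaxonomyTree":
        root = TreeNode.from_linkage_matrix(linkage_matrix, list(words))
        return cls(root)

    def edge_distances(self, words: list[str]) -> np.ndarray:
        """Pairwise leaf-to-leaf edge counts for ``words``, in that order."""
        missing = sorted(set(words) - set(self._words))
        if missing:
            raise KeyError(f"words not in taxonomy: {missing}")
        # Unit branch lengths turn the branch-length metric into edge count.
        tree = self.root.copy()
        for node in tree.traverse(include_self=False):
            node.length = 1.0
        dm = tree.tip_tip_distances()
        idx = [dm.index(w) for w in words]
        return dm.data[np.ix_(idx, idx)]


@dataclass
class SimilarityMatrix:
    """Symmetric items x items similarity values over an ordered word list.

    ``kind`` records provenance: ``cosine`` (unit diagonal), ``path``
    (reciprocal taxonomy path length, unit diagonal) or ``dual`` (the Gram
    matrix ``X X^T``, diagonal unconstrained).
    """

    words: list[str]
    values: np.ndarray
    kind: str

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.words = _check_words(self.words)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.words)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > self._SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.kind in ("cosine", "path"):
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
                raise ValueError(f"{self.kind} similarity must have unit diagonal")


@dataclass
class ComponentScores:
    """Kernel-PCA factor scores: items x k, columns ordered by eigenvalue."""

    words: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.words = _check_words(self.words)
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.shape[0] != len(self.words):
            raise ValueError("score rows must match word count")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def k(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def cosine_kernel(space: EmbeddingSpace) -> SimilarityMatrix:
    """Pairwise cosine similarity of all embedding rows.

    Raises if any word has a zero-norm vector (cosine undefined).
    """
    norms = np.linalg.norm(space.matrix, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"zero-norm embedding for word {space.words[zero[0]]!r}; "
            "cosine similarity is undefined"
        )
    unit = space.matrix / norms[:, None]
    values = unit @ unit.T
    values = (values + values.T) / 2.0  # kill accumulation asymmetry
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(space.words, values, kind="cosine")


def dual_transform(space: EmbeddingSpace) -> SimilarityMatrix:
    """Gram matrix ``X X^T`` — the item x item dual of the embedding.

    A linear model on the embedding rows has an equivalent formulation on
    this matrix (the representer theorem), which is why similarity-to-all-
    words rows can stand in for the raw vectors as encoding features.
    """
    values = space.matrix @ space.matrix.T
    values = (values + values.T) / 2.0
    return SimilarityMatrix(space.words, values, kind="dual")


def path_similarity_matrix(tree: TaxonomyTree, words: list[str]) -> SimilarityMatrix:
    """Taxonomy path similarity ``1 / (1 + d)`` for every word pair.

    ``d`` is the number of edges on the leaf-to-leaf path through the
    tree (via the lowest common ancestor); identical words have d = 0 and
    similarity exactly 1.
    """
    d = tree.edge_distances(list(words))
    values = 1.0 / (1.0 + d)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(words), values, kind="path")


def kernel_pca(kernel: SimilarityMatrix, k: int) -> ComponentScores:
    """Factor scores from the top-``k`` eigenpairs of the centered kernel.

    The kernel is double-centered (``K - row means - column means + grand
    mean``) and eigendecomposed; score column ``j`` is ``eigenvector_j *
    sqrt(max(eigenvalue_j, 0))``, so each column sums to zero and squared
    column norms equal the eigenvalues.  Column signs are fixed so the
    largest-magnitude entry of each column is positive (eigenvector sign is
    otherwise arbitrary).
    """
    n = len(kernel.words)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    K = kernel.values
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    Kc = K - row - col + K.mean()
    Kc = (Kc + Kc.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scores = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
    # true scores are centered (the ones-vector is in the centered kernel's
    # null space); remove the numerical drift that null-space eigenvectors
    # reintroduce at zero eigenvalues
    scores = scores - scores.mean(axis=0)
    # deterministic sign: largest-|entry| of each column made positive
    flip = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return ComponentScores(kernel.words, scores, eigvals)


def top_scoring_words(
    scores: ComponentScores, component: int, m: int = 7
) -> tuple[list[str], list[str]]:
    """The ``m`` most positive and ``m`` most negative words on a component.

    Both lists are ordered by extremity (most extreme first); ties are
    broken by word order for determinism.  Default m = 7 — enough words to
    read a tentative meaning off each factor.
    """
    if not (0 <= component < scores.k):
        raise IndexError(f"component {component} out of range [0, {scores.k})")
    n = len(scores.words)
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, {n}], got {m}")
    col = scores.scores[:, component]
    asc = np.argsort(col, kind="stable")  # stable: ties keep word order
    desc = np.argsort(-col, kind="stable")
    positive = [scores.words[i] for i in desc[:m]]
    negative = [scores.words[i] for i in asc[:m]]
    return positive, negative
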