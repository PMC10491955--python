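"""Similarity views, kNN graph sparsification and Laplacian assembly.

Five similarity views feed the regularizer: for drugs, (1) cosine similarity
of side-effect frequency profiles, (2) Tanimoto similarity of topological
fingerprints, (3) Jaccard similarity of GO molecular-function annotations of
the drug's targets; for side effects, (1) cosine similarity of frequency
profiles and (2) Jaccard similarity of multi-hot MedDRA terms.

Each dense view ``A`` is sparsified to an asymmetric k-nearest-neighbor graph
``A~`` (row i keeps only the k1 largest similarities to other nodes), from
which the directed-style graph Laplacian

    L = (D + D~) - (A~ + A~^T)

is built, with ``D`` the diagonal of row sums and ``D~`` the diagonal of
column sums of ``A~``.  The quadratic form ``tr(U^T L U)`` then equals
``sum_{i,mu} A~(i,mu) ||u_i - u_mu||^2`` and penalizes embedding differences
between graph neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

FREQUENCY_PROFILE = "frequency_profile"
FINGERPRINT = "fingerprint"
ANNOTATION = "annotation"

_SYM_TOL = 1e-12


@dataclass
class SimilarityView:
    """A square symmetric similarity matrix in [0, 1] for one attribute.

    ``kind`` records which similarity measure produced it; the
    ``frequency_profile`` kind is special downstream (it is recomputed per CV
    fold and excluded from cold-start neighbor weighting).
    """

    matrix: np.ndarray
    kind: str = ANNOTATION
    axis: str = "drug"
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if self.matrix.min() < -_SYM_TOL or self.matrix.max() > 1 + 1e-9:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.matrix = (self.matrix + self.matrix.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NeighborGraph:
    """kNN-sparsified similarity graph A~ (generally asymmetric, zero diag)."""

    matrix: np.ndarray
    k1: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if (self.matrix < 0).any():
            raise ValueError("neighbor graph entries must be non-negative")


@dataclass
class LaplacianSet:
    """Laplacian L = (D + D~) - (A~ + A~^T) with its degree diagonals."""

    L: np.ndarray
    D: np.ndarray       # out-degree diagonal (row sums of A~)
    Dtilde: np.ndarray  # in-degree diagonal (column sums of A~)


# ---------------------------------------------------------------------------
# similarity measures
# ---------------------------------------------------------------------------

def cosine_profile_similarity(
    profile_matrix: np.ndarray, axis: str = "drug"
) -> SimilarityView:
    """Cosine similarity of frequency profiles (rows of R for drugs, columns
    for effects).  All-zero profiles get similarity 0 to everything."""
    X = np.asarray(profile_matrix, dtype=float)
    if axis == "effect":
        X = X.T
    elif axis != "drug":
        raise ValueError("axis must be 'drug' or 'effect'")
    S = _sk_cosine(X)  # zero rows stay zero under sklearn's normalization
    np.clip(S, 0.0, 1.0, out=S)
    return SimilarityView(S, kind=FREQUENCY_PROFILE, axis=axis)


def jaccard_similarity(multihot: np.ndarray, axis: str = "drug") -> SimilarityView:
    """Jaccard coefficient between multi-hot rows:
    ``|x_i AND x_j| / |x_i OR x_j|``; two empty rows score 0."""
    X = np.asarray(multihot)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("multi-hot input must be binary")
    X = X.astype(float)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return SimilarityView(S, kind=ANNOTATION, axis=axis)


def tanimoto_fingerprint_similarity(fingerprints: np.ndarray) -> SimilarityView:
    """Tanimoto similarity T = c / (a + b - c) over binary fingerprint bits;
    coincides with Jaccard on bit-vectors."""
    view = jaccard_similarity(fingerprints, axis="drug")
    return SimilarityView(view.matrix, kind=FINGERPRINT, axis="drug")


def fingerprints_from_smiles(
    smiles: dict[str, str], drug_ids: list[str], fp_size: int = 2048
) -> np.ndarray:
    """Topological (path-based) fingerprints from SMILES via RDKit.

    Raises a clear error when RDKit is unavailable so callers can supply
    precomputed fingerprints instead.
    """
    try:
        from rdkit import Chem  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "RDKit is required to derive fingerprints from SMILES; install the "
            "'chem' extra or precompute a binary fingerprint table"
        ) from exc
    rows = []
    for d in drug_ids:
        if d not in smiles:
            raise ValueError(f"no SMILES for drug {d!r}")
        mol = Chem.MolFromSmiles(smiles[d])
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {d!r}: {smiles[d]!r}")
        fp = Chem.RDKFingerprint(mol, fpSize=fp_size)
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
    return np.vstack(rows).astype(np.int8)


# ---------------------------------------------------------------------------
# graphs and Laplacians
# ---------------------------------------------------------------------------

def knn_sparsify(view: SimilarityView | np.ndarray, k1: int) -> NeighborGraph:
    """Keep, in each row, only the ``k1`` largest similarities to *other*
    nodes (ties broken by the smaller column index); zero elsewhere."""
    A = view.matrix if isinstance(view, SimilarityView) else np.asarray(view, float)
    n = A.shape[0]
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    k1 = min(k1, n - 1)
    work = A.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort of -row: descending values, ties resolved by lower index
    order = np.argsort(-work, axis=1, kind="stable")
    keep = order[:, :k1]
    out = np.zeros_like(A)
    rows = np.repeat(np.arange(n), k1)
    out[rows, keep.ravel()] = A[rows, keep.ravel()]
    np.fill_diagonal(out, 0.0)
    return NeighborGraph(out, k1=k1)


def build_laplacian(graph: NeighborGraph | np.ndarray) -> LaplacianSet:
    """Assemble L = (D + D~) - (A~ + A~^T) from a kNN graph."""
    A = graph.matrix if isinstance(graph, NeighborGraph) else np.asarray(graph, float)
    if (A < 0).any():
        raise ValueError("graph entries must be non-negative")
    D = np.diag(A.sum(axis=1))
    Dt = np.diag(A.sum(axis=0))
    L = (D + Dt) - (A + A.T)
    return LaplacianSet(L=L, D=D, Dtilde=Dt)


def build_view_graphs(
    views: list[SimilarityView], k1: int
) -> tuple[list[NeighborGraph], list[LaplacianSet]]:
    graphs = [knn_sparsify(v, k1) for v in views]
    return graphs, [build_laplacian(g) for g in graphs]
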