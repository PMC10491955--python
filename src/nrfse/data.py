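"""Containers and text-format readers/writers for frequency data.

The central object is :class:`FrequencyMatrix`: an ``n x m`` integer matrix
``R`` over drugs (rows) and side effects (columns), where an entry of 0 means
the pair has never been observed and entries 1..5 encode the ordinal frequency
class (very rare .. very frequent).  The masks ``known_mask`` (1 where R > 0)
and ``unknown_mask`` (1 where R == 0) partition the matrix and drive the
class-weighted factorization loss.

All on-disk formats are plain text: dense TSV with ID labels, triplet CSV,
two-column multi-hot annotation TSV, and fingerprint bit-string TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_CLASSES = 5


@dataclass
class FrequencyMatrix:
    """Drug x side-effect frequency-class matrix with known/unknown masks.

    Parameters
    ----------
    values : ndarray of shape (n_drugs, n_effects)
        Integer entries in {0, 1, ..., 5}; 0 marks an unobserved pair.
    drug_ids : sequence of str
        Unique row identifiers.
    effect_ids : sequence of str
        Unique column identifiers.
    """

    values: np.ndarray
    drug_ids: list[str] = field(default_factory=list)
    effect_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 drugs and 2 effects, got {n}x{m}")
        if not np.issubdtype(self.values.dtype, np.integer):
            vals = np.asarray(self.values, dtype=float)
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("frequency entries must be integers")
            self.values = np.round(vals).astype(np.int64)
        if self.values.min() < 0 or self.values.max() > N_CLASSES:
            raise ValueError(f"frequency classes must lie in 0..{N_CLASSES}")
        if not self.drug_ids:
            self.drug_ids = [f"d{i}" for i in range(n)]
        if not self.effect_ids:
            self.effect_ids = [f"e{j}" for j in range(m)]
        self.drug_ids = [str(x) for x in self.drug_ids]
        self.effect_ids = [str(x) for x in self.effect_ids]
        if len(self.drug_ids) != n or len(self.effect_ids) != m:
            raise ValueError("identifier lists must match matrix dimensions")
        if len(set(self.drug_ids)) != n or len(set(self.effect_ids)) != m:
            raise ValueError("identifiers must be unique")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_effects(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def known_mask(self) -> np.ndarray:
        """Binary indicator of observed pairs (I_Omega)."""
        return (self.values > 0).astype(float)

    @property
    def unknown_mask(self) -> np.ndarray:
        """Binary indicator of unobserved pairs (complement of known_mask)."""
        return (self.values == 0).astype(float)

    def new_drug_indices(self) -> np.ndarray:
        """Row indices with no known frequency item (cold-start drugs)."""
        return np.flatnonzero(~(self.values > 0).any(axis=1))

    def new_effect_indices(self) -> np.ndarray:
        """Column indices with no known frequency item (cold-start effects)."""
        return np.flatnonzero(~(self.values > 0).any(axis=0))

    def with_values(self, values: np.ndarray) -> "FrequencyMatrix":
        """Copy with the same identifiers but different entries."""
        return FrequencyMatrix(values, list(self.drug_ids), list(self.effect_ids))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_frequency_tsv(path: str | Path) -> FrequencyMatrix:
    """Read a dense frequency matrix: header row of effect IDs, first column
    of drug IDs, integer cells 0..5."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FrequencyMatrix(
        df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_frequency_tsv(freq: FrequencyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(freq.values, index=freq.drug_ids, columns=freq.effect_ids)
    df.to_csv(path, sep="\t")


def read_frequency_triplets(path: str | Path) -> FrequencyMatrix:
    """Read triplet CSV ``drug_id,effect_id,frequency``; absent pairs are 0."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (drug_id,effect_id,frequency)")
    dcol, ecol, fcol = df.columns[:3]
    drug_ids = sorted(df[dcol].unique())
    effect_ids = sorted(df[ecol].unique())
    didx = {d: i for i, d in enumerate(drug_ids)}
    eidx = {e: j for j, e in enumerate(effect_ids)}
    values = np.zeros((len(drug_ids), len(effect_ids)), dtype=np.int64)
    for row in df.itertuples(index=False):
        values[didx[getattr(row, dcol)], eidx[getattr(row, ecol)]] = int(
            getattr(row, fcol)
        )
    return FrequencyMatrix(values, drug_ids, effect_ids)


def write_frequency_triplets(freq: FrequencyMatrix, path: str | Path) -> None:
    rows, cols = np.nonzero(freq.values)
    pd.DataFrame(
        {
            "drug_id": [freq.drug_ids[i] for i in rows],
            "effect_id": [freq.effect_ids[j] for j in cols],
            "frequency": freq.values[rows, cols],
        }
    ).to_csv(path, index=False)


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Generic labeled TSV matrix (similarity matrices, factors, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_labeled_matrix(
    matrix: np.ndarray, row_ids, col_ids, path: str | Path
) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )


def read_multihot_tsv(path: str | Path, entity_ids: list[str]) -> np.ndarray:
    """Read a two-column ``entity_id<TAB>term_id`` file into a binary
    entities x terms matrix, rows ordered by ``entity_ids``.

    Entities absent from the file get an all-zero row (no annotations).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["entity", "term"], dtype=str)
    terms = sorted(df["term"].unique())
    tidx = {t: j for j, t in enumerate(terms)}
    eidx = {e: i for i, e in enumerate(entity_ids)}
    out = np.zeros((len(entity_ids), len(terms)), dtype=np.int8)
    unknown = set(df["entity"]) - set(entity_ids)
    if unknown:
        raise ValueError(
            f"{path}: {len(unknown)} entity IDs not in the frequency matrix "
            f"(e.g. {sorted(unknown)[:3]})"
        )
    for row in df.itertuples(index=False):
        out[eidx[row.entity], tidx[row.term]] = 1
    return out


def read_fingerprint_tsv(path: str | Path, drug_ids: list[str]) -> np.ndarray:
    """Read ``drug_id<TAB>bitstring`` rows into a binary drugs x bits matrix."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "bits"], dtype=str)
    bits = {row.drug: row.bits for row in df.itertuples(index=False)}
    missing = [d for d in drug_ids if d not in bits]
    if missing:
        raise ValueError(f"{path}: missing fingerprints for {missing[:3]} ...")
    lengths = {len(b) for b in bits.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: inconsistent fingerprint lengths {sorted(lengths)}")
    out = np.array(
        [[int(c) for c in bits[d]] for d in drug_ids], dtype=np.int8
    )
    if not np.isin(out, (0, 1)).all():
        raise ValueError(f"{path}: fingerprints must be 0/1 strings")
    return out


def read_smiles_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``drug_id<TAB>SMILES`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "smiles"], dtype=str)
    return dict(zip(df["drug"], df["smiles"]))


# ---------------------------------------------------------------------------
# model-state persistence
# ---------------------------------------------------------------------------

def save_model_state(
    outdir: str | Path,
    U: np.ndarray,
    V: np.ndarray,
    drug_weights: np.ndarray,
    effect_weights: np.ndarray,
    drug_ids: list[str],
    effect_ids: list[str],
    hyperparameters: dict,
    objective_trace: list[float],
    seed: int | None,
) -> None:
    """Persist a fitted model as TSV factor matrices plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = U.shape[1]
    comp = [f"z{c}" for c in range(k)]
    write_labeled_matrix(U, drug_ids, comp, outdir / "U.tsv")
    write_labeled_matrix(V, comp, effect_ids, outdir / "V.tsv")
    sidecar = {
        "drug_view_weights": list(map(float, drug_weights)),
        "effect_view_weights": list(map(float, effect_weights)),
        "hyperparameters": hyperparameters,
        "objective_trace": list(map(float, objective_trace)),
        "seed": seed,
    }
    (outdir / "state.json").write_text(json.dumps(sidecar, indent=2))


def load_model_state(outdir: str | Path) -> dict:
    outdir = Path(outdir)
    U, drug_ids, _ = read_labeled_matrix(outdir / "U.tsv")
    V, _, effect_ids = read_labeled_matrix(outdir / "V.tsv")
    sidecar = json.loads((outdir / "state.json").read_text())
    return {
        "U": U,
        "V": V,
        "drug_ids": drug_ids,
        "effect_ids": effect_ids,
        "drug_weights": np.array(sidecar["drug_view_weights"]),
        "effect_weights": np.array(sidecar["effect_view_weights"]),
        "hyperparameters": sidecar["hyperparameters"],
        "objective_trace": sidecar["objective_trace"],
        "seed": sidecar["seed"],
    }
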