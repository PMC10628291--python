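"""Compound featurization, structural similarity, and train/test split
strategies probing the applicability domain.

Descriptor computation is delegated to a provider behind the
:class:`DescriptorEngine` protocol; the default provider is RDKit's 2-D
descriptor catalogue. The original configuration this package models used
the 1826-descriptor Mordred catalogue; any fixed-length engine plugs in the
same way, and the descriptor ordering of an engine is frozen by its
manifest (the ordered name list) so cached vectors stay comparable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str = ""
    descriptors: np.ndarray | None = None
    atc_level1: str | None = None
    approval_year: int | None = None
    drug_like: bool = True


class DescriptorEngine(Protocol):
    """Provider contract: a stable ordered descriptor list + a compute call."""

    @property
    def names(self) -> list[str]: ...

    def compute(self, smiles: str) -> np.ndarray: ...


class RDKitDescriptorEngine:
    """Fixed-length 2-D descriptor vectors from RDKit's descriptor registry.

    Non-computable entries come back non-finite for downstream imputation.
    """

    def __init__(self):
        from rdkit.Chem import Descriptors

        self._desc = list(Descriptors.descList)  # ordered (name, fn) pairs

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._desc]

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:16]

    def compute(self, smiles: str) -> np.ndarray:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        out = np.empty(len(self._desc))
        for i, (_, fn) in enumerate(self._desc):
            try:
                out[i] = float(fn(mol))
            except Exception:  # descriptor failures become NaN
                out[i] = np.nan
        return out


def compute_descriptors(smiles: str, engine: DescriptorEngine | None = None) -> np.ndarray:
    engine = engine or RDKitDescriptorEngine()
    return engine.compute(smiles)


def compute_descriptor_matrix(
    smiles_list: Sequence[str], engine: DescriptorEngine | None = None
) -> np.ndarray:
    engine = engine or RDKitDescriptorEngine()
    return np.stack([engine.compute(s) for s in smiles_list])


# ---------------------------------------------------------------------------
# structural similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    values: np.ndarray
    compound_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    def median_offdiagonal(self) -> np.ndarray:
        """Per-compound median similarity to all *other* compounds."""
        n = self.values.shape[0]
        out = np.empty(n)
        for i in range(n):
            out[i] = np.median(np.delete(self.values[i], i))
        return out


def pairwise_structural_similarity(
    descriptors: np.ndarray, compound_ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Cosine similarity between per-feature z-scored descriptor vectors.

    Constant descriptors drop out (zero after standardization). A compound
    whose standardized vector is all-zero gets similarity 0 to every other
    compound (warned) and 1 on the diagonal.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n>=2, D) descriptor matrix")
    X = np.where(np.isfinite(X), X, 0.0)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    norms = np.linalg.norm(Z, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("pairwise_structural_similarity: %d all-zero standardized vectors",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    S = (Z / safe[:, None]) @ (Z / safe[:, None]).T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    ids = list(compound_ids) if compound_ids is not None else [str(i) for i in range(X.shape[0])]
    return SimilarityMatrix(values=np.clip(S, -1.0, 1.0), compound_ids=ids)


# ---------------------------------------------------------------------------
# split strategies
# ---------------------------------------------------------------------------

def _check_partition(train: list[str], test: list[str], all_ids: Sequence[str]) -> None:
    assert set(train) | set(test) == set(all_ids)
    assert not (set(train) & set(test))


def split_by_similarity(
    similarity: SimilarityMatrix, n_train: int
) -> tuple[list[str], list[str]]:
    """Rank compounds by median similarity to the others (descending); the
    top ``n_train`` go to training, so the held-out compounds are the ones
    least similar to everything else. Ties break lexicographically by id."""
    ids = similarity.compound_ids
    if not 0 < n_train < len(ids):
        raise ValueError("n_train must be in (0, n_compounds)")
    med = similarity.median_offdiagonal()
    order = sorted(range(len(ids)), key=lambda i: (-med[i], ids[i]))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    _check_partition(train, test, ids)
    return train, test


def split_by_atc(
    compounds: Sequence[CompoundRecord], test_codes: frozenset[str] | set[str] = frozenset({"R", "P"})
) -> tuple[list[str], list[str]]:
    """Therapeutic-class hold-out on WHO ATC level-1 codes.

    Compounds whose code is in ``test_codes`` form the test set; everything
    else — including unclassified compounds — trains.
    """
    test_codes = {c.upper() for c in test_codes}
    if not test_codes:
        logger.warning("split_by_atc: empty test_codes, test set will be empty")
    train, test = [], []
    for c in compounds:
        code = (c.atc_level1 or "").upper()
        (test if code in test_codes else train).append(c.compound_id)
    _check_partition(train, test, [c.compound_id for c in compounds])
    return train, test


def split_by_time(
    compounds: Sequence[CompoundRecord], cutoff_year: int = 1982
) -> tuple[list[str], list[str]]:
    """Time-split: drugs approved before the cutoff plus non-drug-like
    compounds train; drugs approved at/after the cutoff are held out."""
    missing = [c.compound_id for c in compounds if c.drug_like and c.approval_year is None]
    if missing:
        raise ValueError(f"drug-like compounds without approval_year: {missing}")
    train, test = [], []
    for c in compounds:
        if not c.drug_like or c.approval_year < cutoff_year:
            train.append(c.compound_id)
        else:
            test.append(c.compound_id)
    if not train:
        raise ValueError("time split produced an empty training set")
    _check_partition(train, test, [c.compound_id for c in compounds])
    return train, test


def split_random(
    compound_ids: Sequence[str], n_train: int, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random compound split (the original 80/20 development split)."""
    ids = list(compound_ids)
    if not 0 < n_train < len(ids):
        raise ValueError("n_train must be in (0, n_compounds)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    _check_partition(train, test, ids)
    return train, test


def descriptor_cache_to_csv(path, compound_ids: Sequence[str], matrix: np.ndarray,
                            engine: DescriptorEngine) -> None:
    """Persist descriptors keyed by compound_id, with the engine manifest
    hash recorded so stale caches are detectable."""
    df = pd.DataFrame(np.asarray(matrix), columns=engine.names)
    df.insert(0, "compound_id", list(compound_ids))
    mh = getattr(engine, "manifest_hash", "")
    with open(path, "w") as fh:
        fh.write(f"# manifest={mh}\n")
        df.to_csv(fh, index=False)


def descriptor_cache_from_csv(path) -> tuple[list[str], np.ndarray, str]:
    with open(path) as fh:
        header = fh.readline().strip()
        manifest = header.split("=", 1)[1] if header.startswith("# manifest=") else ""
        df = pd.read_csv(fh)
    ids = [str(x) for x in df["compound_id"]]
    return ids, df.drop(columns=["compound_id"]).to_numpy(dtype=float), manifest
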