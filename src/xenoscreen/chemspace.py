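"""Chemical-space relationships between compound libraries.

Compounds are represented by binary substructure fingerprints (bit sets);
similarity is the Tanimoto/Jaccard index |a & b| / |a | b|. Library
coverage of a chemical space is summarized by each query compound's
similarity to its closest library match; coverage distributions of
competing libraries are compared with a two-sample Kolmogorov-Smirnov
test. Fingerprint computation from SMILES is delegated to RDKit behind one
adapter so all set arithmetic is testable without chemistry software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "tanimoto",
    "max_similarity",
    "count_above",
    "ks_coverage_test",
    "binary_profile_distances",
    "fingerprints_from_smiles",
    "SimilarityResult",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Closest-library-match similarity for one query compound."""

    query_id: str
    nearest_id: str
    max_similarity: float


def tanimoto(a, b) -> float:
    """Tanimoto/Jaccard index of two bit sets; 0 when both are empty."""
    a, b = frozenset(a), frozenset(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def max_similarity(
    queries: dict[str, frozenset], library: dict[str, frozenset]
) -> list[SimilarityResult]:
    """Per query, the maximum Tanimoto similarity over the library.

    Ties are broken by the first library id in sorted order. Enlarging the
    library never decreases any query's max similarity.
    """
    if not library:
        raise ValueError("library must be non-empty")
    lib_items = sorted(library.items())
    out = []
    for qid in sorted(queries):
        best_id, best = lib_items[0][0], -1.0
        for lid, lbits in lib_items:
            s = tanimoto(queries[qid], lbits)
            if s > best:
                best_id, best = lid, s
        out.append(SimilarityResult(qid, best_id, best))
    return out


def count_above(similarities, threshold: float = 0.75) -> int:
    """Number of similarity values strictly greater than ``threshold``."""
    return int(np.sum(np.asarray(list(similarities), dtype=float) > threshold))


def ks_coverage_test(dist_a, dist_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of coverage distributions.

    Returns (D, p) with D = sup |ECDF_a - ECDF_b| and the asymptotic
    two-sided p-value.
    """
    a = np.asarray(list(dist_a), dtype=float)
    b = np.asarray(list(dist_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def binary_profile_distances(profiles: dict[str, frozenset]) -> pd.DataFrame:
    """Symmetric Jaccard distance matrix d(i, j) = 1 - tanimoto(i, j)."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    ids = sorted(profiles)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(profiles[ids[i]], profiles[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def fingerprints_from_smiles(
    smiles: dict[str, str], radius: int = 2, n_bits: int = 2048
) -> dict[str, frozenset]:
    """Morgan/ECFP fingerprints (default radius 2, 2048 bits) from SMILES.

    Adapter over RDKit; compounds whose SMILES fail to parse raise with the
    compound id named.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = {}
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {cid!r}")
        fp = gen.GetFingerprint(mol)
        out[cid] = frozenset(fp.GetOnBits())
    return out
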