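"""Pooled barcoded transposon-insertion fitness analysis.

Per-gene fitness of a pooled mutant library competed under a chemical vs a
vehicle/media control: insertion-site counts are depth-normalized with the
trimmed total read count (TTR), sites outside the central 80% of each coding
region are masked, counts are aggregated per gene, and condition-vs-control
differences are tested with a permutation (resampling) test on the per-arm
mean normalized counts. Fold changes can be rescaled by the ratio of culture
doublings to remove global growth-extent bias, and hit sets are tested for
pathway-term enrichment with Fisher's exact test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "InsertionCountTable",
    "central_mask",
    "ttr_normalize",
    "gene_aggregate",
    "resampling_test",
    "doublings_correct",
    "call_gene_hits",
    "term_enrichment",
    "TnFitnessScreen",
    "TnFitnessResults",
]


@dataclass(frozen=True)
class InsertionCountTable:
    """Insertion-site x sample read counts with site -> gene mapping.

    Attributes
    ----------
    sites
        DataFrame with columns position (1-based), gene_id ('' or NaN for
        intergenic) and barcode_id; one row per insertion site, aligned
        with the rows of ``counts``.
    counts
        site x sample DataFrame of nonnegative integer read counts.
    samples
        DataFrame indexed by sample id with columns condition, replicate
        and doublings.
    """

    sites: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.counts):
            raise ValueError("sites and counts row counts differ")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.sites["position"] < 1).any():
            raise ValueError("site positions are 1-based (>= 1)")
        if self.samples.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("counts columns must match sample ids")


def central_mask(position: int, start: int, end: int) -> bool:
    """True iff the site lies in the central 80% of the coding region.

    The fractional offset f = (position - start) / (end - start + 1) must
    satisfy 0.1 <= f < 0.9; positions outside the gene return False.
    """
    if position < start or position > end:
        return False
    f = (position - start) / (end - start + 1)
    return 0.1 <= f < 0.9


def _trimmed_mean_nonzero(values: np.ndarray, trim: float = 0.05) -> float:
    """Mean of nonzero values after discarding the top and bottom ``trim``."""
    nz = np.sort(values[values > 0])
    if nz.size == 0:
        raise ValueError("sample has no nonzero counts")
    k = int(np.floor(trim * nz.size))
    kept = nz[k: nz.size - k] if nz.size - 2 * k > 0 else nz
    return float(kept.mean())


def ttr_normalize(
    counts: pd.DataFrame, trim: float = 0.05, min_nonzero: int = 20
) -> tuple[pd.DataFrame, pd.Series]:
    """Trimmed-total-read-count normalization across samples.

    Per sample, the mean of nonzero site counts is computed after dropping
    the top and bottom 5% of nonzero values; each sample is scaled so this
    trimmed mean equals the across-sample grand trimmed mean. Returns the
    normalized matrix and the per-sample scale factors.
    """
    mat = counts.to_numpy(dtype=float)
    trimmed = []
    for j, sample in enumerate(counts.columns):
        col = mat[:, j]
        if (col > 0).sum() < min_nonzero:
            raise ValueError(f"sample {sample!r} has < {min_nonzero} nonzero sites")
        trimmed.append(_trimmed_mean_nonzero(col, trim))
    trimmed_arr = np.array(trimmed)
    grand = float(trimmed_arr.mean())
    factors = grand / trimmed_arr
    normalized = pd.DataFrame(
        mat * factors[None, :], index=counts.index, columns=counts.columns
    )
    return normalized, pd.Series(factors, index=counts.columns, name="factor")


def gene_aggregate(
    normalized: pd.DataFrame, sites: pd.DataFrame, gene_table: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Sum normalized counts over central-region sites per gene and sample.

    Returns the gene x sample matrix and the list of genes with zero
    retained sites (untestable; reported rather than given p = 1).
    """
    coords = gene_table.set_index("gene_id")
    keep_gene = []
    for pos, gid in zip(sites["position"], sites["gene_id"]):
        if isinstance(gid, str) and gid and gid in coords.index:
            row = coords.loc[gid]
            keep_gene.append(
                gid if central_mask(int(pos), int(row["start"]), int(row["end"])) else None
            )
        else:
            keep_gene.append(None)
    mat = normalized.to_numpy(dtype=float)
    sums: dict[str, np.ndarray] = {}
    for i, gid in enumerate(keep_gene):
        if gid is None:
            continue
        if gid not in sums:
            sums[gid] = np.zeros(mat.shape[1])
        sums[gid] += mat[i]
    gene_ids = list(gene_table["gene_id"])
    out = pd.DataFrame(
        [sums.get(g, np.zeros(mat.shape[1])) for g in gene_ids],
        index=gene_ids,
        columns=normalized.columns,
    )
    untestable = [g for g in gene_ids if g not in sums]
    return out.drop(index=untestable), untestable


def _enumerate_assignments(n_total: int, n_cond: int) -> np.ndarray:
    """All 0/1 arm-assignment vectors choosing ``n_cond`` of ``n_total``."""
    out = np.zeros((comb(n_total, n_cond), n_total), dtype=float)
    for i, combo in enumerate(itertools.combinations(range(n_total), n_cond)):
        out[i, list(combo)] = 1.0
    return out


def _assignment_matrix(
    n_total: int, n_cond: int, n_perm: int, rng: np.random.Generator,
    exhaustive: bool | None,
) -> tuple[np.ndarray, bool]:
    n_distinct = comb(n_total, n_cond)
    if exhaustive is None:
        exhaustive = n_distinct <= n_perm
    if exhaustive:
        return _enumerate_assignments(n_total, n_cond), True
    out = np.zeros((n_perm, n_total), dtype=float)
    for i in range(n_perm):
        out[i, rng.choice(n_total, size=n_cond, replace=False)] = 1.0
    return out, False


def _permutation_pvalues(
    data: np.ndarray, n_cond: int, n_perm: int, seed, exhaustive: bool | None
) -> np.ndarray:
    """Vectorized two-sided permutation p for each row of gene x sample data.

    The statistic is the difference of per-arm means (condition minus
    control, condition = first ``n_cond`` columns). p = fraction of
    permuted |statistic| >= |observed|, the observed arrangement included
    in numerator and denominator; p is floored at 1/n_perm.
    """
    n_total = data.shape[1]
    rng = np.random.default_rng(seed)
    A, is_exhaustive = _assignment_matrix(n_total, n_cond, n_perm, rng, exhaustive)
    n_ctrl = n_total - n_cond
    # weights turning an assignment row into a mean-difference statistic
    W = A / n_cond - (1.0 - A) / n_ctrl          # (n_assign, n_total)
    obs_w = np.zeros(n_total)
    obs_w[:n_cond] = 1.0 / n_cond
    obs_w[n_cond:] = -1.0 / n_ctrl
    obs = data @ obs_w                            # (n_genes,)
    perm = data @ W.T                             # (n_genes, n_assign)
    tol = 1e-12 * (1.0 + np.abs(obs))[:, None]
    more_extreme = np.abs(perm) >= np.abs(obs)[:, None] - tol
    if is_exhaustive:
        p = more_extreme.mean(axis=1)
    else:
        # sampled permutations: add the observed arrangement itself
        p = (more_extreme.sum(axis=1) + 1.0) / (perm.shape[1] + 1.0)
    return np.maximum(p, 1.0 / n_perm)


def resampling_test(
    gene_counts_cond,
    gene_counts_ctrl,
    n_perm: int = 20000,
    seed=None,
    exhaustive: bool | None = None,
) -> tuple[float, float]:
    """Permutation test of condition vs control normalized gene counts.

    The statistic is the difference of per-arm mean counts; assignments of
    whole samples to arms are enumerated exhaustively when there are at
    most ``n_perm`` distinct assignments (deterministic p for small
    designs) and sampled otherwise. Returns
    (log2fc, p) with log2fc = log2((mean_cond + 1) / (mean_ctrl + 1));
    the pseudocount keeps fully depleted genes finite.
    """
    cond = np.asarray(gene_counts_cond, dtype=float)
    ctrl = np.asarray(gene_counts_ctrl, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("both arms must be non-empty")
    if cond.size + ctrl.size < 2:
        raise ValueError("need >= 2 samples total")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    data = np.concatenate([cond, ctrl])[None, :]
    p = float(_permutation_pvalues(data, cond.size, n_perm, seed, exhaustive)[0])
    log2fc = float(np.log2((cond.mean() + 1.0) / (ctrl.mean() + 1.0)))
    return log2fc, p


def doublings_correct(log2fc: float, g_cond: float, g_ctrl: float) -> float:
    """Rescale a log2 fold change to the control's doubling count.

    log2fc_corrected = log2fc * (G_ctrl / G_cond): a per-doubling rescaling
    that removes global differences in culture expansion between arms.
    Nonpositive doublings leave the value uncorrected (flagged upstream).
    """
    if g_cond <= 0 or g_ctrl <= 0:
        raise ValueError("doublings must be positive")
    return log2fc * (g_ctrl / g_cond)


def call_gene_hits(
    results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.25
) -> pd.DataFrame:
    """Flag gene hits at P_adj < alpha and |log2FC| > lfc_min."""
    out = results.copy()
    out["is_hit"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > lfc_min)
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


def term_enrichment(
    hit_genes: set[str], background: set[str], term_map: dict[str, list[str]]
) -> pd.DataFrame:
    """One-sided Fisher enrichment of hits in each annotation term.

    ``term_map`` maps gene -> list of term ids; only background genes are
    considered. Terms with zero background genes are skipped. p-values are
    BH-corrected across terms.
    """
    if not hit_genes <= background:
        raise ValueError("hit_genes must be a subset of background")
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in term_map.items():
        if gene not in background:
            continue
        for t in gene_terms:
            terms.setdefault(t, set()).add(gene)
    n_genes = len(background)
    n_hits = len(hit_genes)
    rows = []
    for term, members in sorted(terms.items()):
        if not members:
            continue
        a = len(hit_genes & members)              # hits in term
        b = n_hits - a                            # hits outside term
        c = len(members) - a                      # non-hits in term
        d = n_genes - n_hits - c                  # non-hits outside term
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "term_id": term,
                "n_hits_in_term": a,
                "n_hits_total": n_hits,
                "n_genes_in_term": len(members),
                "n_genes_total": n_genes,
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "n_hits_in_term", "n_hits_total",
            "n_genes_in_term", "n_genes_total", "p",
        ],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


class TnFitnessScreen:
    """Model of a pooled transposon-fitness competition.

    Built from an :class:`InsertionCountTable` and a gene coordinate table;
    ``fit(condition, control)`` runs TTR normalization, central-80% site
    masking, gene aggregation, the sample-permutation resampling test with
    BH correction, the optional doublings correction, and hit calling.
    """

    def __init__(self, table: InsertionCountTable, gene_table: pd.DataFrame):
        self.table = table
        self.gene_table = gene_table

    def fit(
        self,
        condition: str,
        control: str,
        n_perm: int = 20000,
        seed=None,
        alpha: float = 0.05,
        lfc_min: float = 0.25,
        doublings_correction: bool = True,
        exhaustive: bool | None = None,
    ) -> "TnFitnessResults":
        samples = self.table.samples
        cond_ids = list(samples.index[samples["condition"] == condition])
        ctrl_ids = list(samples.index[samples["condition"] == control])
        if not cond_ids or not ctrl_ids:
            raise ValueError("both arms must have >= 1 sample")
        use = cond_ids + ctrl_ids
        normalized, factors = ttr_normalize(self.table.counts[use])
        gene_counts, untestable = gene_aggregate(
            normalized, self.table.sites, self.gene_table
        )
        data = gene_counts.to_numpy(dtype=float)
        n_cond = len(cond_ids)
        pvals = _permutation_pvalues(data, n_cond, n_perm, seed, exhaustive)
        mean_cond = data[:, :n_cond].mean(axis=1)
        mean_ctrl = data[:, n_cond:].mean(axis=1)
        log2fc = np.log2((mean_cond + 1.0) / (mean_ctrl + 1.0))
        results = pd.DataFrame(
            {
                "gene_id": gene_counts.index,
                "mean_cond": mean_cond,
                "mean_ctrl": mean_ctrl,
                "log2fc": log2fc,
                "p": pvals,
            }
        )
        results["p_adj"] = bh_adjust(results["p"].to_numpy())
        g_cond = float(samples.loc[cond_ids, "doublings"].mean())
        g_ctrl = float(samples.loc[ctrl_ids, "doublings"].mean())
        if doublings_correction and g_cond > 0 and g_ctrl > 0:
            results["log2fc_corrected"] = [
                doublings_correct(v, g_cond, g_ctrl) for v in results["log2fc"]
            ]
            corrected = True
        else:
            results["log2fc_corrected"] = results["log2fc"]
            corrected = False
        results = call_gene_hits(results, alpha=alpha, lfc_min=lfc_min)
        return TnFitnessResults(
            self, condition, control, results, untestable, factors, corrected
        )


class TnFitnessResults:
    """Per-gene fitness results of one condition-vs-control comparison."""

    def __init__(self, model, condition, control, results: pd.DataFrame,
                 untestable: list[str], factors: pd.Series, doublings_corrected: bool):
        self.model = model
        self.condition = condition
        self.control = control
        self.results = results
        self.untestable_genes = untestable
        self.normalization_factors = factors
        self.doublings_corrected = doublings_corrected

    def hits(self) -> pd.DataFrame:
        return self.results[self.results["is_hit"]].reset_index(drop=True)

    def enrichment(self, term_map: dict[str, list[str]]) -> pd.DataFrame:
        hit_genes = set(self.hits()["gene_id"])
        background = set(self.results["gene_id"])
        return term_enrichment(hit_genes, background, term_map)

    def summary(self) -> str:
        n_hits = int(self.results["is_hit"].sum())
        n_dep = int((self.results["is_hit"] & (self.results["log2fc"] < 0)).sum())
        lines = [
            f"Tn fitness screen: {self.condition} vs {self.control}",
            "=" * 40,
            f"genes tested:     {len(self.results)}",
            f"genes untestable: {len(self.untestable_genes)}",
            f"gene hits:        {n_hits} ({n_dep} depleted, {n_hits - n_dep} enriched)",
            f"doublings-corrected fold changes: {self.doublings_corrected}",
        ]
        return "\n".join(lines)
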