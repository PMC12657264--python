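"""Single-cell quantitative rules: QC, normalisation, scoring, DEGs, composition.

Implements the numeric conventions applied to droplet scRNA-seq of
hippocampal tissue in epilepsy studies:

* QC keeps cells with > 250 detected genes, > 1000 UMIs, and < 25%
  mitochondrial UMIs (strict inequalities, mouse ``mt-`` prefix);
* log-normalisation ``ln(1 + 10^4 * x / total)``;
* bin-matched control gene-set module scores (AddModuleScore-style);
* rank-based AUC pathway activity scores (AUCell-style);
* two-group Wilcoxon rank-sum DEGs with BH adjustment and the
  ``|avg_log2FC| > 1, p_adj < 0.05`` selection rule;
* per-group cell-type composition percentages.

The bundled oligodendrocyte lineage signatures are
MOL = {Klk6, Apod, Slc5a11, Pde1a}, MFOL = {Mal, Mog, Plp1, Opalin,
Serinc5}, NFOL = {Tcf7l2, Casr, Cemip2, Itpr2}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QcThresholds",
    "GeneSet",
    "OL_LINEAGE_SETS",
    "qc_filter",
    "log_normalize",
    "module_score",
    "auc_score",
    "wilcoxon_deg",
    "filter_degs",
    "composition",
]


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer UMI matrix with cell metadata."""

    counts: sparse.spmatrix
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_names) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("gene/cell name lengths inconsistent with counts shape")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            raise ValueError("cell_meta index must equal cell_ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of log-normalised expression."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass(frozen=True)
class QcThresholds:
    """Strict QC cutoffs: nFeature > 250, nCount > 1000, percent.mt < 25."""

    min_features: int = 250
    min_counts: int = 1000
    max_mito_pct: float = 25.0
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_features <= 0 or self.min_counts <= 0 or self.max_mito_pct <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


#: Oligodendrocyte lineage stage signatures used for module scoring.
OL_LINEAGE_SETS: dict[str, GeneSet] = {
    "MOL": GeneSet("MOL", ("Klk6", "Apod", "Slc5a11", "Pde1a")),
    "MFOL": GeneSet("MFOL", ("Mal", "Mog", "Plp1", "Opalin", "Serinc5")),
    "NFOL": GeneSet("NFOL", ("Tcf7l2", "Casr", "Cemip2", "Itpr2")),
}


# ---------------------------------------------------------------------------
# QC and normalisation


def qc_metrics(m: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell n_features, n_counts and mitochondrial UMI percentage."""
    csc = m.counts.tocsc()
    n_features = np.diff(csc.indptr)  # nonzero entries per cell
    n_counts = np.asarray(csc.sum(axis=0)).ravel()
    is_mito = np.array([str(g).startswith(mito_prefix) for g in m.gene_names])
    mito_counts = np.asarray(csc[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(n_counts > 0, 100.0 * mito_counts / n_counts, 0.0)
    return pd.DataFrame(
        {"n_features": n_features, "n_counts": n_counts, "mito_pct": mito_pct},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def qc_filter(m: CountMatrix, t: QcThresholds = QcThresholds()) -> CountMatrix:
    """Remove low-quality cells; all three rules are strict inequalities."""
    qm = qc_metrics(m, t.mito_prefix)
    keep = (
        (qm["n_features"].to_numpy() > t.min_features)
        & (qm["n_counts"].to_numpy() > t.min_counts)
        & (qm["mito_pct"].to_numpy() < t.max_mito_pct)
    )
    if not keep.any():
        removed = {
            "low_features": int((qm["n_features"] <= t.min_features).sum()),
            "low_counts": int((qm["n_counts"] <= t.min_counts).sum()),
            "high_mito": int((qm["mito_pct"] >= t.max_mito_pct).sum()),
        }
        raise ValueError(f"no cells survive QC; removal counts per rule: {removed}")
    idx = np.flatnonzero(keep)
    return CountMatrix(
        counts=m.counts[:, idx],
        gene_names=m.gene_names,
        cell_ids=m.cell_ids[idx],
        cell_meta=m.cell_meta.iloc[idx],
    )


def log_normalize(m: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """y = ln(1 + scale * x / column_total); dense output."""
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = list(np.asarray(m.cell_ids)[totals == 0][:5])
        raise ValueError(f"cells with zero total counts cannot be normalised: {bad}")
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = np.log1p(scale * dense / totals[np.newaxis, :])
    return NormalizedMatrix(
        values=values,
        gene_names=m.gene_names,
        cell_ids=m.cell_ids,
        cell_meta=m.cell_meta,
    )


# ---------------------------------------------------------------------------
# gene-set scoring


def module_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control module score, one value per cell.

    Genes are binned into ``n_bins`` equal-size bins by mean expression;
    each set member draws ``n_ctrl`` control genes (with replacement) from
    its own bin. Score = mean expression of set members minus mean over all
    drawn controls.
    """
    if norm.n_genes <= n_bins:
        raise ValueError("matrix must contain more genes than n_bins")
    present = [g for g in gene_set.members if g in set(norm.gene_names)]
    missing = [g for g in gene_set.members if g not in set(norm.gene_names)]
    if not present:
        raise KeyError(f"no member of set {gene_set.name!r} present; missing: {missing}")
    rng = np.random.default_rng(seed)
    avg = norm.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(norm.n_genes, dtype=int)
    bin_of[order] = (np.arange(norm.n_genes) * n_bins) // norm.n_genes
    members = norm.gene_index(present)
    ctrl_idx: list[np.ndarray] = []
    for g in members:
        pool = np.flatnonzero(bin_of == bin_of[g])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)
    return norm.values[members].mean(axis=0) - norm.values[ctrl].mean(axis=0)


def auc_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Rank-based recovery-curve AUC of the set within each cell's top ranks.

    Per cell, genes are ranked by decreasing expression (ties broken by one
    seed-fixed random permutation shared across cells); the score is the
    area under the set-member recovery curve over the top
    ``ceil(top_fraction * n_genes)`` ranks, normalised by its maximum, so it
    lies in [0, 1] regardless of set size.
    """
    n_genes = norm.n_genes
    k = int(math.ceil(top_fraction * n_genes))
    members = norm.gene_index([g for g in gene_set.members if g in set(norm.gene_names)])
    if members.size == 0:
        raise KeyError(f"no member of set {gene_set.name!r} present in the matrix")
    if members.size > k:
        raise ValueError(
            f"set size {members.size} exceeds the top-rank window k={k}; "
            "increase top_fraction"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)  # fixed tie-break order for all cells
    is_member = np.zeros(n_genes, dtype=bool)
    is_member[members] = True

    m = members.size
    max_auc = float(np.sum(k - np.arange(m)))  # all members at the very top
    scores = np.empty(norm.n_cells)
    vals = norm.values[perm]
    memb_perm = is_member[perm]
    for c in range(norm.n_cells):
        order = np.argsort(-vals[:, c], kind="stable")
        top = order[:k]
        pos = np.flatnonzero(memb_perm[top])  # 0-based positions in window
        scores[c] = float(np.sum(k - pos)) / max_auc
    return scores


# ---------------------------------------------------------------------------
# differential expression


def _exact_ranksum_p(ranks: np.ndarray, n1: int, combos: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    w_obs = ranks[:n1].sum()
    mu = n1 * ranks.mean()
    w_all = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-9))


def _approx_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided normal-approximation p with tie correction and continuity
    correction (the R ``wilcox.test`` convention)."""
    n = ranks.size
    n2 = n - n1
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    diff = abs(w - mu) - 0.5  # continuity correction
    z = max(diff, 0.0) / math.sqrt(sigma2)
    return float(2 * stats.norm.sf(z))


def wilcoxon_deg(
    norm: NormalizedMatrix,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    min_detected_cells: int = 3,
    max_exact_combinations: int = 20_000,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum differential expression.

    For each gene, a two-sided rank-sum p-value comparing ``groups[0]`` vs
    ``groups[1]`` (exact enumeration when the number of group assignments is
    small, else tie-corrected normal approximation), BH-adjusted across the
    tested genes. ``avg_log2FC = log2(mean(expm1 y)+1 | g1) -
    log2(mean(expm1 y)+1 | g2)``. Genes detected in fewer than
    ``min_detected_cells`` cells are skipped and listed in
    ``result.attrs["skipped_genes"]``.
    """
    labels = norm.cell_meta[group_col].to_numpy()
    if groups is None:
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ValueError("groups must be given when the label column is not binary")
        groups = (uniq[0], uniq[1])
    i1 = np.flatnonzero(labels == groups[0])
    i2 = np.flatnonzero(labels == groups[1])
    if len(i1) < 3 or len(i2) < 3:
        raise ValueError("each group must contain at least 3 cells")

    x1 = norm.values[:, i1]
    x2 = norm.values[:, i2]
    n1, n2 = x1.shape[1], x2.shape[1]
    n = n1 + n2
    combos = None
    if math.comb(n, n1) <= max_exact_combinations:
        combos = np.array(list(itertools.combinations(range(n), n1)), dtype=int)

    detected = (np.count_nonzero(x1, axis=1) + np.count_nonzero(x2, axis=1))
    tested = detected >= min_detected_cells
    skipped = list(np.asarray(norm.gene_names)[~tested])

    records = []
    for g in np.flatnonzero(tested):
        both = np.concatenate([x1[g], x2[g]])
        ranks = stats.rankdata(both)
        if combos is not None:
            p = _exact_ranksum_p(ranks, n1, combos)
        else:
            p = _approx_ranksum_p(ranks, n1)
        lfc = float(
            np.log2(np.expm1(x1[g]).mean() + 1) - np.log2(np.expm1(x2[g]).mean() + 1)
        )
        records.append(
            {
                "gene": norm.gene_names[g],
                "p_value": p,
                "avg_log2FC": lfc,
                "pct_1": float(np.count_nonzero(x1[g]) / n1),
                "pct_2": float(np.count_nonzero(x2[g]) / n2),
            }
        )
    result = pd.DataFrame.from_records(records)
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    result.attrs["skipped_genes"] = skipped
    result.attrs["groups"] = groups
    return result


def filter_degs(
    records: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep records with |avg_log2FC| > threshold AND p_adjusted < alpha
    (both strict, as the selection rule is printed)."""
    keep = (records["avg_log2FC"].abs() > lfc_threshold) & (
        records["p_adjusted"] < alpha
    )
    return records.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# composition


def composition(
    cell_meta: pd.DataFrame, group_col: str = "group", type_col: str = "cell_type"
) -> pd.DataFrame:
    """Per-(group, type) counts and percentages of the group total.

    Percentages are reported to one decimal, the convention in which
    findings like "45.2% (5292/11,707) OL in the TLE group" are stated.
    """
    if cell_meta.empty:
        raise ValueError("cell metadata is empty")
    counts = (
        cell_meta.groupby([group_col, type_col], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(group_col)["count"].transform("sum")
    if (totals == 0).any():
        raise ValueError("empty group in composition table")
    counts["group_total"] = totals
    counts["percent"] = (100.0 * counts["count"] / totals).round(1)
    return counts
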