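"""Single-cell coexpression disequilibrium (CD).

Treats binarized per-cell expression like biallelic traits in a population
and borrows the linkage-disequilibrium formalism: for features A and X,

    CD_AX = P(A and X) - P(A) * P(X)

over the cells of one replicate, where P are fractions of cells ON. CD is
normalized D'-style by its attainable extreme given the marginals
(``min(P_A, P_X) - P_A P_X`` for positive CD, ``P_A P_X - max(P_A + P_X -
1, 0)`` for negative), giving CD' in [-1, 1] comparable across abundances.

Binarization uses a dynamic per-feature threshold separating the lower
third of UMI counts (OFF) from the rest (ON). Per replicate, normalized CD
values of a transposon against every feature are ranked (descending, ties
averaged); each pair's per-replicate ranks are tested against the mean rank
with a one-sample t-test and corrected with Benjamini-Hochberg across the
transposon's pairs. Enrichment of transposon-neighbor pairs over random
gene sets is assessed with a goodness-of-fit chi-square.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TINY_P = 5e-324  # smallest subnormal double; degenerate zero-variance case


@dataclass
class BinaryExpressionMatrix:
    values: pd.DataFrame  # bool, features x cells
    thresholds: pd.Series  # per-feature UMI threshold
    replicates: pd.Series  # per-cell replicate label

    @property
    def replicate_names(self) -> list[str]:
        return sorted(self.replicates.unique())

    def cells_of(self, replicate: str) -> pd.Index:
        return self.replicates.index[self.replicates == replicate]


def binarize(
    dge: pd.DataFrame,
    replicates: pd.Series,
    rule: str = "lower-third",
) -> BinaryExpressionMatrix:
    """Binarize a DGE matrix (features x cells) to ON/OFF.

    Per feature, the threshold is the 33.33rd percentile of its UMI counts
    across all cells (zeros included, linear interpolation); a cell is ON
    iff its count exceeds the threshold. All-zero (or constant) features end
    up all OFF.
    """
    if rule != "lower-third":
        raise ValueError(f"unknown binarization rule {rule!r}")
    counts = dge.to_numpy()
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    t = np.percentile(counts, 100.0 / 3.0, axis=1)
    values = pd.DataFrame(
        counts > t[:, None], index=dge.index, columns=dge.columns
    )
    reps = replicates.reindex(dge.columns)
    if reps.isna().any():
        raise ValueError("replicate labels missing for some cells")
    return BinaryExpressionMatrix(values, pd.Series(t, index=dge.index), reps)


def cd_max_abs(pa: float, px: float, positive: bool) -> float:
    """Attainable |CD| extreme given the marginals."""
    if positive:
        return min(pa, px) - pa * px
    return pa * px - max(pa + px - 1.0, 0.0)


def compute_cd(
    matrix: BinaryExpressionMatrix, a: str, x: str, replicate: str
) -> tuple[float, float, float, float, float]:
    """(CD, CD_norm, P_A, P_X, P_AX) on one replicate's cells."""
    cells = matrix.cells_of(replicate)
    if len(cells) == 0:
        raise ValueError(f"replicate {replicate!r} has no cells")
    va = matrix.values.loc[a, cells].to_numpy()
    vx = matrix.values.loc[x, cells].to_numpy()
    pa, px = float(va.mean()), float(vx.mean())
    pax = float((va & vx).mean())
    cd = pax - pa * px
    denom = cd_max_abs(pa, px, cd >= 0)
    cd_norm = cd / denom if denom > 0 else 0.0
    return cd, cd_norm, pa, px, pax


def cd_norm_matrix(
    matrix: BinaryExpressionMatrix, replicate: str
) -> pd.DataFrame:
    """All-pairs normalized CD on one replicate (vectorized)."""
    cells = matrix.cells_of(replicate)
    B = matrix.values.loc[:, cells].to_numpy().astype(np.float64)
    n = B.shape[1]
    p = B.mean(axis=1)
    pax = (B @ B.T) / n
    cd = pax - np.outer(p, p)
    pos_max = np.minimum.outer(p, p) - np.outer(p, p)
    neg_max = np.outer(p, p) - np.maximum(np.add.outer(p, p) - 1.0, 0.0)
    denom = np.where(cd >= 0, pos_max, neg_max)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(denom > 0, cd / denom, 0.0)
    return pd.DataFrame(norm, index=matrix.values.index, columns=matrix.values.index)


@dataclass
class CDResult:
    feature_a: str  # the transposon
    feature_x: str
    per_replicate: pd.DataFrame  # columns: cd, cd_norm, p_a, p_x, p_ax, rank
    mean_rank: float
    t_stat: Optional[float]
    p_value: float
    p_adjusted: Optional[float] = None
    degenerate: bool = False


def rank_and_test(
    matrix: BinaryExpressionMatrix,
    te: str,
    features: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Rank a transposon's normalized CDs against every feature per
    replicate and test each pair's ranks against the expected mean rank.

    Ranks are descending (rank 1 = strongest co-expression), ties averaged.
    The one-sample t-test uses mu = (n_features + 1) / 2, the mean rank of a
    complete ranking; Benjamini-Hochberg correction is applied across this
    transposon's pairs. Zero-variance rank vectors are flagged degenerate
    (p = 1 when the mean equals mu, else the smallest representable value).
    """
    reps = matrix.replicate_names
    if len(reps) < 2:
        raise ValueError("testing requires >= 2 replicates")
    if features is None:
        features = [f for f in matrix.values.index if f != te]
    n_feat = len(features)
    mu = (n_feat + 1) / 2.0
    ranks = np.empty((len(reps), n_feat))
    cdn = np.empty((len(reps), n_feat))
    for i, rep in enumerate(reps):
        cells = matrix.cells_of(rep)
        B = matrix.values.loc[:, cells]
        va = B.loc[te].to_numpy()
        pa = va.mean()
        vx = B.loc[features].to_numpy()
        px = vx.mean(axis=1)
        pax = (vx & va).mean(axis=1)
        cd = pax - pa * px
        pos = np.minimum(pa, px) - pa * px
        neg = pa * px - np.maximum(pa + px - 1.0, 0.0)
        denom = np.where(cd >= 0, pos, neg)
        with np.errstate(invalid="ignore", divide="ignore"):
            cdn[i] = np.where(denom > 0, cd / denom, 0.0)
        ranks[i] = stats.rankdata(-cdn[i], method="average")
    rows = []
    for j, x in enumerate(features):
        r = ranks[:, j]
        sd = r.std(ddof=1)
        if sd == 0:
            degenerate = True
            t_stat = None
            p = 1.0 if r.mean() == mu else TINY_P
        else:
            degenerate = False
            t_stat, p = stats.ttest_1samp(r, mu)
        rows.append(
            dict(
                te=te, feature=x, mean_rank=r.mean(), mean_cd_norm=cdn[:, j].mean(),
                t_stat=t_stat, p_value=float(p), degenerate=degenerate,
            )
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


@dataclass
class EnrichmentReport:
    observed: int
    expected: float
    random_counts: list[int]
    chi2: float
    p_value: float
    n_pairs: int
    continuity_substituted: bool = False


def random_set_enrichment(
    tested: dict[str, pd.DataFrame],
    neighbor_map: dict[str, list[str]],
    all_genes: list[str],
    n_random_sets: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnrichmentReport:
    """Observed significant TE-neighbor pairs versus equal-size random gene
    assignments, with a two-category goodness-of-fit chi-square.

    ``tested`` maps each transposon to its rank_and_test output. For every
    random set, each transposon is assigned as many random genes as it has
    neighbors; the expected count is the mean number of significant pairs
    over the random sets.
    """
    rng = np.random.default_rng(seed)
    observed = 0
    n_pairs = 0
    padj = {
        te: dict(zip(df["feature"], df["p_adjusted"])) for te, df in tested.items()
    }
    for te, genes in neighbor_map.items():
        for g in genes:
            n_pairs += 1
            if padj.get(te, {}).get(g, 1.0) < alpha:
                observed += 1
    random_counts = []
    pool = np.array(all_genes)
    for _ in range(n_random_sets):
        cnt = 0
        for te, genes in neighbor_map.items():
            pick = rng.choice(pool, size=len(genes), replace=False)
            for g in pick:
                if padj.get(te, {}).get(g, 1.0) < alpha:
                    cnt += 1
        random_counts.append(cnt)
    expected = float(np.mean(random_counts))
    substituted = False
    if expected == 0:
        expected = 0.5
        substituted = True
    exp_not = max(n_pairs - expected, 0.5)
    chi2 = (observed - expected) ** 2 / expected + (
        (n_pairs - observed) - exp_not
    ) ** 2 / exp_not
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentReport(
        observed, expected, random_counts, float(chi2), p, n_pairs, substituted
    )


# ---------------------------------------------------------------------------
# IO helpers


def load_dge(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Load a features x cells DGE matrix from TSV or MatrixMarket.

    MatrixMarket input expects sibling ``<stem>.rows`` / ``<stem>.cols``
    files listing feature and cell names.
    """
    import os

    path = str(path)
    if fmt is None:
        fmt = "mtx" if path.endswith(".mtx") else "tsv"
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    from scipy.io import mmread

    mat = mmread(path).toarray()
    stem = os.path.splitext(path)[0]
    with open(stem + ".rows") as fh:
        rows = [line.strip() for line in fh if line.strip()]
    with open(stem + ".cols") as fh:
        cols = [line.strip() for line in fh if line.strip()]
    return pd.DataFrame(mat, index=rows, columns=cols)
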