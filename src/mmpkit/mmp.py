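"""The Microbial Metabolic Phenotype (MMP): matrix, typing, stability.

An MMP is a donor's vector of net SCFA production rates over the
fermentable-fiber x SCFA grid (study configuration: {inulin, pectin} x
{acetate, propionate, butyrate} = 6 columns), standardized per column
across the cohort. Donors are typed by average-linkage (UPGMA)
hierarchical clustering of their z-score rows; "high"/"low" producer
status per column is the sign of the z-score (z >= 0 is high, boundary
inclusive); temporal stability over two visits is tested with a
two-tailed Fisher exact test on the 2x2 high/low concordance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats


@dataclass
class MmpMatrix:
    """Donors x (fiber:SCFA) production-rate matrix, raw mM/h or z-scored.

    ``column_stats`` stores per-column (mean, sd) after z-scoring so the
    transform is invertible; ``constant_columns`` flags columns whose
    sample sd was 0 (their z-scores are set to 0).
    """

    values: pd.DataFrame  # rows = donors, columns = "fiber:scfa"
    zscored: bool = False
    column_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)

    @property
    def donors(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_rate_table(cls, rates: pd.DataFrame) -> "MmpMatrix":
        """Pivot a tidy (donor, fiber, scfa, rate_mM_per_h) frame."""
        wide = rates.pivot(index="donor", columns=["fiber", "scfa"],
                           values="rate_mM_per_h")
        wide.columns = [f"{f}:{s}" for f, s in wide.columns]
        wide = wide.sort_index(axis=1)
        if wide.isna().any().any():
            raise ValueError("rate table has missing donor x fiber:scfa cells")
        return cls(values=wide, zscored=False)


@dataclass
class StabilityTable:
    """2x2 high/low concordance counts between two visits.

    Rows = visit-1 class, columns = visit-2 class, order (high, low):
    ``table[0, 0]`` counts cells high at both visits.
    """

    table: np.ndarray
    donors: list[str]
    n_cells: int

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("contingency table must be non-negative 2x2")
        if self.table.sum() != self.n_cells:
            raise ValueError("table total does not match cells compared")


def build_mmp_matrix(rates: pd.DataFrame) -> MmpMatrix:
    """Tidy rate table -> raw MMP matrix (convenience alias)."""
    return MmpMatrix.from_rate_table(rates)


def zscore_columns(matrix: MmpMatrix) -> MmpMatrix:
    """Standardize each column across donors: (x - mean) / sd, sample sd (n-1).

    Columns with zero sample sd are flagged constant and mapped to all
    zeros rather than dividing by zero.
    """
    if matrix.zscored:
        raise ValueError("matrix is already z-scored")
    if len(matrix.values) < 2:
        raise ValueError("z-scoring needs >= 2 donors")
    stats: dict[str, tuple[float, float]] = {}
    constant: list[str] = []
    z = matrix.values.copy().astype(float)
    for col in z.columns:
        mean = float(z[col].mean())
        sd = float(z[col].std(ddof=1))
        stats[col] = (mean, sd)
        if sd == 0:
            constant.append(col)
            z[col] = 0.0
        else:
            z[col] = (z[col] - mean) / sd
    return MmpMatrix(values=z, zscored=True, column_stats=stats,
                     constant_columns=constant)


def inverse_zscore(matrix: MmpMatrix) -> MmpMatrix:
    """Recover the raw-scale matrix from a z-scored one via stored stats."""
    if not matrix.zscored:
        raise ValueError("matrix is not z-scored")
    raw = matrix.values.copy()
    for col, (mean, sd) in matrix.column_stats.items():
        raw[col] = raw[col] * sd + mean
    return MmpMatrix(values=raw, zscored=False)


def binarize_high_low(matrix: MmpMatrix) -> pd.DataFrame:
    """High/low producer calls: high iff z >= 0 (boundary is high).

    Returns a boolean frame (True = high) aligned with the input.
    """
    if not matrix.zscored:
        raise ValueError("binarization requires a z-scored matrix")
    return matrix.values >= 0


def upgma_cluster(
    matrix: MmpMatrix,
    k: int | None = 2,
    height: float | None = None,
    metric: str = "euclidean",
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage (UPGMA) clustering of donor rows.

    Returns the scipy linkage matrix and integer cluster labels (1-based,
    as assigned by ``scipy.cluster.hierarchy.fcluster``) indexed by donor.
    Cut either at a cluster count ``k`` (default 2, the Type I / Type II
    reading) or at a merge ``height``. Deterministic given row order;
    scipy breaks distance ties by lowest cluster index.
    """
    if len(matrix.values) < 2:
        raise ValueError("clustering needs >= 2 donors")
    if matrix.values.isna().any().any():
        raise ValueError("matrix has missing values")
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    linkage = sch.linkage(matrix.values.to_numpy(), method="average",
                          metric=metric)
    if k is not None:
        labels = sch.fcluster(linkage, t=k, criterion="maxclust")
    else:
        labels = sch.fcluster(linkage, t=height, criterion="distance")
    return linkage, pd.Series(labels, index=matrix.values.index, name="cluster")


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (text export)."""
    tree = sch.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        d = node.dist
        dl = d - (node.get_left().dist if not node.get_left().is_leaf() else 0)
        dr = d - (node.get_right().dist if not node.get_right().is_leaf() else 0)
        return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"

    return walk(tree) + ";"


def stability_contingency(
    visit1: pd.DataFrame, visit2: pd.DataFrame
) -> StabilityTable:
    """Count (high, low) class agreement over all donor x column cells.

    Both inputs are boolean high/low frames from :func:`binarize_high_low`
    over the same donors and fiber:SCFA columns.
    """
    if set(visit1.index) != set(visit2.index):
        raise ValueError("visits cover different donor sets")
    if list(visit1.columns) != list(visit2.columns):
        raise ValueError("visits have different columns")
    v2 = visit2.loc[visit1.index]
    a = visit1.to_numpy(dtype=bool)
    b = v2.to_numpy(dtype=bool)
    table = np.array(
        [[(a & b).sum(), (a & ~b).sum()],
         [(~a & b).sum(), (~a & ~b).sum()]],
        dtype=np.int64,
    )
    return StabilityTable(table=table, donors=list(visit1.index),
                          n_cells=int(a.size))


def fisher_exact_2x2(table: np.ndarray, two_tailed: bool = True) -> float:
    """Fisher exact p-value for a non-negative integer 2x2 table.

    Two-tailed uses the point-probability rule: sum of probabilities of
    every margin-fixed table whose hypergeometric probability does not
    exceed that of the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    alternative = "two-sided" if two_tailed else "greater"
    return float(scipy.stats.fisher_exact(t.astype(np.int64),
                                          alternative=alternative).pvalue)


def stability_test(visit1: pd.DataFrame, visit2: pd.DataFrame) -> tuple[StabilityTable, float]:
    """Contingency table plus its two-tailed Fisher exact p-value."""
    ct = stability_contingency(visit1, visit2)
    return ct, fisher_exact_2x2(ct.table)
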