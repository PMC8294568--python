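"""Downstream 16S OTU-table processing and composition-based prediction.

Pipeline order follows the study convention: depth-filter (drop samples
with fewer than 5,000 reads), rarefy to the lowest remaining depth for
diversity work, total-count normalize for relative-abundance work,
optionally collapse taxonomy to a rank, then train stratified
cross-validated random forests to call high vs low SCFA producers from
composition, reporting a vertically averaged ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from mmpkit.data_io import OtuTable

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class RelAbundanceTable:
    """Row-stochastic samples x features table (OTUs or a collapsed rank)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("relative abundances must be non-negative")
        sums = arr.sum(axis=1)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
        if bad.any():
            raise ValueError(
                f"rows do not sum to 1: {list(self.values.index[bad])}"
            )


@dataclass
class ClassifierReport:
    """Cross-validated high/low classifier summary.

    The mean ROC is a vertical average of per-fold ROC curves interpolated
    onto a common 101-point false-positive-rate grid.
    """

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    fold_aucs: list[float]
    mean_auc: float
    importances: pd.Series  # mean decrease in impurity, averaged over folds
    fold_assignments: pd.Series
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")


def filter_low_depth(
    table: OtuTable, min_reads: int = 5000
) -> tuple[OtuTable, list[str]]:
    """Drop samples with depth strictly below ``min_reads``.

    Returns the filtered table and the dropped sample IDs. A sample with
    exactly ``min_reads`` reads is kept.
    """
    depths = table.depths
    keep = depths >= min_reads
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(f"all {len(table.sample_ids)} samples below {min_reads} reads")
    return (
        OtuTable(
            sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
            otu_ids=list(table.otu_ids),
            counts=table.counts[keep],
            taxonomy=table.taxonomy,
        ),
        dropped,
    )


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to a common depth.

    ``depth`` defaults to the lowest sample depth. Uses the multivariate
    hypergeometric distribution (exact without-replacement draw);
    deterministic per seed.
    """
    depths = table.depths
    if depth is None:
        depth = int(depths.min())
    if (depths < depth).any():
        shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
        raise ValueError(f"samples below target depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        counts=out,
        taxonomy=table.taxonomy,
    )


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Normalize each sample's counts by its total read count."""
    depths = table.depths
    if (depths == 0).any():
        zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"zero-depth samples (filter first): {zero}")
    values = table.counts / depths[:, None]
    return RelAbundanceTable(
        pd.DataFrame(values, index=table.sample_ids, columns=table.otu_ids)
    )


def _truncate_lineage(lineage: str, rank: str) -> str:
    parts = [p.strip() for p in lineage.split(";")]
    level = RANKS.index(rank)
    parts = parts + ["unassigned"] * (len(RANKS) - len(parts))
    prefix = parts[: level + 1]
    if prefix[-1].lower() in {"", "unassigned", "na"}:
        # pool unassigned-at-rank under their deepest assigned parent
        assigned = [p for p in prefix[:-1] if p.lower() not in {"", "unassigned", "na"}]
        parent = ";".join(assigned) if assigned else "unassigned"
        return f"{parent};unassigned"
    return ";".join(prefix)


def collapse_taxonomy(
    table: RelAbundanceTable, taxonomy: dict[str, str], rank: str
) -> RelAbundanceTable:
    """Sum features within lineages truncated at ``rank``.

    Features unassigned at the requested rank are pooled into one
    ``<parent lineage>;unassigned`` feature per parent, so e.g. an
    unassigned-genus Lachnospiraceae OTU stays distinct from assigned
    genera of that family. Row sums are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[str, list[str]] = {}
    for feat in table.values.columns:
        lineage = taxonomy.get(feat, "unassigned")
        groups.setdefault(_truncate_lineage(lineage, rank), []).append(feat)
    collapsed = pd.DataFrame(
        {name: table.values[cols].sum(axis=1) for name, cols in sorted(groups.items())}
    )
    return RelAbundanceTable(collapsed)


def shannon_diversity(abundances: np.ndarray | pd.Series) -> float:
    """Shannon entropy -sum p ln p (natural log; 0 ln 0 = 0)."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"abundances must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance, sqrt(JSD) with log base 2, in [0, 1]."""
    import scipy.spatial.distance

    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if list(p.index) != list(q.index):
            raise ValueError("p and q are on different feature sets")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q are on different feature sets")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} is not a probability vector")
    d = float(scipy.spatial.distance.jensenshannon(p, q, base=2))
    return 0.0 if np.isnan(d) else d


def train_high_low_classifier(
    features: RelAbundanceTable,
    labels: pd.Series,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
) -> ClassifierReport:
    """Stratified K-fold random forest calling high vs low producers.

    Per fold, a forest (``n_estimators`` trees, sqrt-features splits) is
    trained on the training split; its ROC on the held-out split is
    interpolated onto a fixed 101-point FPR grid. Reports the vertical
    mean ROC, mean AUC, and impurity importances averaged over folds.
    Fully reproducible given ``seed``.
    """
    X = features.values.loc[labels.index]
    y = labels.astype(int).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    folds = min(folds, int(counts.min()))

    fpr_grid = np.linspace(0.0, 1.0, 101)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tprs, aucs, imps = [], [], []
    assignment = pd.Series(index=labels.index, dtype=int, name="fold")
    Xa = X.to_numpy()
    for fold_idx, (tr, te) in enumerate(skf.split(Xa, y)):
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed + fold_idx,
            n_jobs=1,
        )
        clf.fit(Xa[tr], y[tr])
        scores = clf.predict_proba(Xa[te])[:, 1]
        fpr, tpr, _ = roc_curve(y[te], scores)
        interp = np.interp(fpr_grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
        aucs.append(float(auc(fpr, tpr)))
        imps.append(clf.feature_importances_)
        assignment.iloc[te] = fold_idx
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    importances = pd.Series(
        np.mean(imps, axis=0), index=X.columns, name="importance"
    ).sort_values(ascending=False)
    return ClassifierReport(
        fpr_grid=fpr_grid,
        mean_tpr=mean_tpr,
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        importances=importances,
        fold_assignments=assignment,
        seed=seed,
        metadata={
            "folds": folds,
            "n_estimators": n_estimators,
            "roc_averaging": "vertical, 101-point FPR grid",
        },
    )
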