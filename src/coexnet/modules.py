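"""Module detection: TOM-dissimilarity clustering, dynamic tree cut,
eigengenes, intramodular connectivity, and module merging.

Modules carry size-ranked color names (turquoise, blue, brown, ...) following
the co-expression-network convention; genes not assigned to any module carry
the reserved label "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "cluster_genes",
    "dynamic_tree_cut",
    "compute_eigengene",
    "eigengene_dissimilarity",
    "eigengene_matrix",
    "auto_merge",
    "manual_merge",
    "reassign_by_kme",
    "connectivity_stats",
    "ModulePartition",
    "Eigengene",
    "ConnectivityStats",
]

GREY = "grey"

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

# deep_split in {0..4} -> minimum branch gap (fraction of the merge-height
# range) a subtree must keep between its own root and the cut to count as a
# module. Higher values accept shallower branches, i.e. split more eagerly.
_DEEP_SPLIT_GAP = {0: 0.02, 1: 0.01, 2: 0.005, 3: 0.0025, 4: 0.001}

# candidate cut heights scanned by the adaptive branch decomposition,
# as fractions of the merge-height range
_CUT_GRID = np.linspace(0.10, 0.999, 181)


@dataclass
class ModulePartition:
    """Gene -> module-name assignment with the parameters that produced it."""

    labels: pd.Series  # index gene_id, values module names incl. GREY
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        sizes = self.module_sizes()
        small = sizes[(sizes.index != GREY) & (sizes < self.min_module_size)]
        if len(small):
            raise ValueError(
                f"non-grey module(s) below min_module_size={self.min_module_size}: "
                f"{small.to_dict()}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    def modules(self, include_grey: bool = False) -> list[str]:
        """Module names ordered by decreasing size (ties by name)."""
        sizes = self.module_sizes()
        names = [m for m in sizes.index if include_grey or m != GREY]
        return names

    def module_sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        order = sorted(counts.index, key=lambda m: (-counts[m], m))
        return counts.loc[order]

    def members(self, module: str) -> list[str]:
        if module not in set(self.labels):
            raise KeyError(f"unknown module {module!r}")
        return list(self.labels.index[self.labels == module])

    def relabel(self, mapping: dict[str, str]) -> "ModulePartition":
        labels = self.labels.map(lambda m: mapping.get(m, m))
        return ModulePartition(
            labels=labels,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            merge_cut_height=self.merge_cut_height,
        )


def cluster_genes(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram of the topological-overlap dissimilarity 1-TOM."""
    if tom.shape[0] < 2:
        raise ValueError("clustering requires at least 2 genes")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    return hierarchy.linkage(condensed, method="average")


def _color_names(n: int) -> list[str]:
    names = list(MODULE_COLORS[:n])
    names += [f"module{i}" for i in range(len(names) + 1, n + 1)]
    return names


def _assign_color_names(
    gene_ids: list[str], cluster_ids: np.ndarray, keep: set[int]
) -> pd.Series:
    """Name kept clusters by decreasing size (ties by first gene position)."""
    order = []
    for cid in keep:
        members = np.flatnonzero(cluster_ids == cid)
        order.append((-members.size, members.min(), cid))
    order.sort()
    names = _color_names(len(order))
    mapping = {cid: name for (_, _, cid), name in zip(order, names)}
    labels = [mapping.get(cid, GREY) for cid in cluster_ids]
    return pd.Series(labels, index=gene_ids, name="module")


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> ModulePartition:
    """Adaptive branch decomposition of the dendrogram into modules.

    Branches are the connected subtrees below a cut height. A branch
    qualifies as a module iff it has at least ``min_module_size`` genes and
    is cohesive: its own root merge sits at least a minimum gap (a
    deep_split-dependent fraction of the merge-height range) below the cut,
    which is what separates genuine co-expression branches from the shallow
    clumps an unstructured dissimilarity produces near the tree root. Unless
    ``cut_height`` is fixed by the caller, candidate cuts across the height
    range are scanned and the one maximizing (number of qualifying branches,
    number of genes assigned) is kept, ties resolved toward the lowest cut.
    Unassigned genes are grey. Deterministic given its inputs.
    """
    if deep_split not in _DEEP_SPLIT_GAP:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    gene_ids = list(tom.index)
    n = len(gene_ids)
    all_grey = pd.Series([GREY] * n, index=gene_ids, name="module")
    if min_module_size > n:
        warnings.warn(
            f"min_module_size={min_module_size} exceeds gene count {n}; all genes grey",
            RuntimeWarning,
            stacklevel=2,
        )
        return ModulePartition(all_grey, min_module_size, deep_split)
    heights = dendrogram[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    h_range = h_max - h_min
    if h_range == 0:
        return ModulePartition(all_grey, min_module_size, deep_split)
    min_gap = _DEEP_SPLIT_GAP[deep_split] * h_range

    def evaluate(cut: float):
        cluster_ids = hierarchy.fcluster(dendrogram, t=cut, criterion="distance")
        nodes, cids = hierarchy.leaders(dendrogram, cluster_ids.astype(np.int32))
        root_height = {
            int(cid): (0.0 if node < n else float(dendrogram[node - n, 2]))
            for node, cid in zip(nodes, cids)
        }
        modules = []
        total_gap = 0.0
        for cid, count in zip(*np.unique(cluster_ids, return_counts=True)):
            cid = int(cid)
            gap = cut - root_height[cid]
            if count < min_module_size or gap < min_gap:
                continue
            modules.append(np.flatnonzero(cluster_ids == cid))
            total_gap += gap
        return modules, total_gap

    if cut_height is not None:
        modules, _ = evaluate(float(cut_height))
    else:
        # maximize the number of cohesive branches, then their total gap
        # (favoring pure, well-separated branches over contaminated ones)
        best = None
        for frac in _CUT_GRID:
            cut = h_min + float(frac) * h_range
            modules, total_gap = evaluate(cut)
            score = (len(modules), total_gap)
            if best is None or score > best[0]:
                best = (score, modules)
        _, modules = best
    cluster_ids = np.zeros(n, dtype=int)  # 0 = grey
    for mid, members in enumerate(modules, start=1):
        cluster_ids[members] = mid
    labels = _assign_color_names(gene_ids, cluster_ids, set(range(1, len(modules) + 1)))
    return ModulePartition(labels, min_module_size, deep_split)


def reassign_by_kme(
    partition: ModulePartition, expr: ExpressionMatrix, min_kme: float = 0.5
) -> ModulePartition:
    """Optional second stage: pull grey genes into their best-matching module.

    A grey gene joins the module whose eigengene it correlates with most, if
    that correlation reaches ``min_kme``. Off by default in the fitting
    pipeline; the cost is purer modules traded for coverage.
    """
    mods = partition.modules()
    if not mods:
        return partition
    me, _ = eigengene_matrix(expr, partition)
    grey_genes = partition.members(GREY) if GREY in set(partition.labels) else []
    if not grey_genes:
        return partition
    sub = expr.frame.loc[grey_genes].to_numpy(dtype=float)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
    labels = partition.labels.copy()
    mez = me.to_numpy(dtype=float)
    mez = (mez - mez.mean(axis=0)) / mez.std(axis=0)
    kme = z @ mez / sub.shape[1]
    best = np.argmax(kme, axis=1)
    for gene, b, row in zip(grey_genes, best, kme):
        if row[b] >= min_kme:
            labels[gene] = me.columns[b]
    return ModulePartition(
        labels,
        min_module_size=partition.min_module_size,
        deep_split=partition.deep_split,
        merge_cut_height=partition.merge_cut_height,
    )


@dataclass
class Eigengene:
    """First principal component of a module's gene-standardized expression."""

    vector: pd.Series  # over samples, unit Euclidean norm
    variance_explained: float
    sign_flipped: bool = False
    excluded_genes: list[str] = field(default_factory=list)


def compute_eigengene(expr: ExpressionMatrix, member_genes) -> Eigengene:
    """Module eigengene: leading right-singular vector of the z-scored submatrix.

    Oriented so the mean correlation with member-gene expression is >= 0
    (ties broken toward the first member gene's correlation being >= 0).
    Zero-variance members are excluded with a warning.
    """
    member_genes = list(member_genes)
    if not member_genes:
        raise ValueError("module has no member genes")
    sub = expr.frame.loc[member_genes].to_numpy(dtype=float)
    if sub.shape[1] < 2:
        raise ValueError("eigengene requires at least 2 samples")
    sd = sub.std(axis=1)
    excluded = [g for g, s in zip(member_genes, sd) if s == 0]
    if excluded:
        warnings.warn(
            f"excluding zero-variance gene(s) from eigengene: {excluded}",
            RuntimeWarning,
            stacklevel=2,
        )
        keep = sd > 0
        sub, member_genes = sub[keep], [g for g in member_genes if g not in set(excluded)]
        if sub.shape[0] == 0:
            raise ValueError("no member gene with nonzero variance")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    cors = _row_correlations(z, me)
    mean_cor = float(cors.mean())
    flipped = False
    if mean_cor < 0 or (mean_cor == 0 and cors[0] < 0):
        me, flipped = -me, True
    vector = pd.Series(me, index=expr.sample_ids, name="ME")
    return Eigengene(vector, var_explained, flipped, excluded)


def _row_correlations(z_rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each (already z-scored) row with vector v."""
    vc = v - v.mean()
    denom = np.linalg.norm(vc) * np.sqrt(z_rows.shape[1])
    if denom == 0:
        return np.zeros(z_rows.shape[0])
    zn = z_rows / np.sqrt(z_rows.shape[1])
    return zn @ (vc / np.linalg.norm(vc))


def eigengene_matrix(
    expr: ExpressionMatrix, partition: ModulePartition, include_grey: bool = False
) -> tuple[pd.DataFrame, dict[str, Eigengene]]:
    """Sample x module eigengene matrix for all (non-grey) modules."""
    entries: dict[str, Eigengene] = {}
    for module in partition.modules(include_grey=include_grey):
        entries[module] = compute_eigengene(expr, partition.members(module))
    frame = pd.DataFrame({m: e.vector for m, e in entries.items()})
    return frame, entries


def eigengene_dissimilarity(me_a: pd.Series, me_b: pd.Series) -> float:
    """1 - Pearson correlation of two eigengenes; range [0, 2]."""
    a = np.asarray(me_a, dtype=float)
    b = np.asarray(me_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("eigengenes must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance eigengene")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def auto_merge(
    partition: ModulePartition,
    expr: ExpressionMatrix,
    merge_cut_height: float | None = None,
) -> ModulePartition:
    """Merge modules whose eigengene dissimilarity is below the cut height.

    Eigengenes are clustered (average linkage on 1 - cor), the tree cut at
    the merge height, clusters unioned, and eigengenes recomputed; this
    repeats until no pair qualifies. Grey is never merged. A merged cluster
    keeps the name of its largest constituent.
    """
    if merge_cut_height is None:
        merge_cut_height = partition.merge_cut_height
    if merge_cut_height <= 0:
        return partition.relabel({})
    current = partition
    while True:
        mods = current.modules()
        if len(mods) < 2:
            break
        me, _ = eigengene_matrix(expr, current)
        dissim = 1.0 - np.corrcoef(me.to_numpy().T)
        dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
        # strict "< height" contract: shave an epsilon off the threshold
        groups = hierarchy.fcluster(link, t=merge_cut_height * (1 - 1e-9), criterion="distance")
        if len(set(groups)) == len(mods):
            break
        sizes = current.module_sizes()
        mapping: dict[str, str] = {}
        for gid in set(groups):
            group_mods = [m for m, g in zip(me.columns, groups) if g == gid]
            if len(group_mods) > 1:
                target = max(group_mods, key=lambda m: (sizes[m], m))
                for m in group_mods:
                    mapping[m] = target
        current = current.relabel(mapping)
    current.merge_cut_height = merge_cut_height
    return current


def manual_merge(
    partition: ModulePartition, module_names, new_name: str
) -> ModulePartition:
    """Union the named modules under ``new_name`` (rationale-driven merge)."""
    module_names = list(module_names)
    if len(module_names) != len(set(module_names)):
        raise ValueError(f"duplicated module name(s) in merge request: {module_names}")
    if len(module_names) < 2:
        raise ValueError("manual merge requires at least 2 distinct modules")
    if GREY in module_names:
        raise ValueError("the grey (unassigned) label cannot be merged")
    existing = set(partition.labels)
    unknown = [m for m in module_names if m not in existing]
    if unknown:
        raise KeyError(f"unknown module(s): {unknown}")
    return partition.relabel({m: new_name for m in module_names})


@dataclass
class ConnectivityStats:
    """Module membership (kME) and intramodular connectivity (kWithin)."""

    kme: pd.DataFrame  # genes x modules, Pearson cor with each eigengene
    kwithin: pd.Series  # per gene, adjacency summed over same-module co-members

    def hub_genes(self, partition: ModulePartition, module: str, n: int = 30) -> list[str]:
        """Top-n members of ``module`` by kWithin; ties broken lexically."""
        members = partition.members(module)
        ranked = sorted(members, key=lambda g: (-self.kwithin[g], g))
        return ranked[:n]


def connectivity_stats(
    expr: ExpressionMatrix,
    adjacency: pd.DataFrame,
    partition: ModulePartition,
    eigengenes: pd.DataFrame | None = None,
) -> ConnectivityStats:
    """kME against every module eigengene and kWithin inside the own module."""
    if eigengenes is None:
        eigengenes, _ = eigengene_matrix(expr, partition)
    x = expr.values.astype(float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    kme_cols = {}
    for module in eigengenes.columns:
        me = eigengenes[module].to_numpy(dtype=float)
        mez = (me - me.mean()) / me.std()
        kme_cols[module] = xz @ mez / x.shape[1]
    kme = pd.DataFrame(kme_cols, index=expr.gene_ids).clip(-1.0, 1.0)
    adj = adjacency.to_numpy(dtype=float)
    labels = partition.labels.loc[expr.gene_ids].to_numpy()
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    kwithin = pd.Series((adj * same).sum(axis=1), index=expr.gene_ids, name="kWithin")
    return ConnectivityStats(kme=kme, kwithin=kwithin)
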