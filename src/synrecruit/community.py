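"""Clade-level community profiles, station clustering and environmental tests.

Read assignments are rolled up to the clade level (strain/subclade counts
aggregate into their clade; assignments resolved only to subcluster 5.1
become category ``"5.1"``; genus-level assignments become ``"Syn"``; strains
of subclusters without a clade rank, e.g. SC 5.2 / 5.3, roll up to the
subcluster itself).  Raw counts are divided by the mean genome length of the
category (in Mbp) to give reads per Mbp, stations below a recruitment-density
floor (default 600 reads/Mbp) are removed, and the remaining rows are
total-sum scaled to relative abundances.  Stations are compared with
Bray-Curtis dissimilarity, clustered by UPGMA, and the resulting station
clusters tested for environmental differences with a Kruskal-Wallis test and
Dunn's post hoc comparisons summarised as a compact letter display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .recruitment import ReadAssignment
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

SYN_CATEGORY = "Syn"


def category_of(tree: TaxonomyTree, taxon_id: str) -> str:
    """Map an assignment taxon to its reporting category.

    Nearest ancestor-or-self at clade rank wins; otherwise the nearest
    subcluster (so an assignment at SC 5.1 reports as "5.1" and an SC 5.2
    strain reports as "5.2"); otherwise the genus-level catch-all "Syn".
    """
    node = tree.node(taxon_id)
    path = node.path()
    for candidate in reversed(path):
        if candidate.rank == "clade":
            return candidate.id
    for candidate in reversed(path):
        if candidate.rank == "subcluster":
            return candidate.id
    return SYN_CATEGORY


def aggregate_by_clade(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    station_id: str,
) -> pd.Series:
    """Tally one station's read assignments into clade-level categories."""
    counts: dict[str, int] = {}
    for a in assignments:
        cat = category_of(tree, a.taxon.id)
        counts[cat] = counts.get(cat, 0) + 1
    s = pd.Series(counts, dtype=float).sort_index()
    s.name = station_id
    return s


def build_count_table(rows: Sequence[pd.Series]) -> pd.DataFrame:
    """Stack per-station category tallies into a station x category table."""
    table = pd.DataFrame(list(rows)).fillna(0.0)
    table = table.reindex(sorted(table.columns), axis=1)
    table.index.name = "station_id"
    return table


def mean_genome_length_mbp(tree: TaxonomyTree, category: str) -> float:
    """Mean genome length (Mbp) over the in-group strains of a category."""
    if category == SYN_CATEGORY:
        strains = tree.ingroup_strains()
    else:
        strains = tree.strains_under(category)
    if not strains:
        raise ConfigurationError(
            f"category {category!r} has no strains with genome lengths"
        )
    lengths = [tree.strain(s).genome_length for s in strains]
    return float(np.mean(lengths)) / 1e6


def length_normalize(table: pd.DataFrame, tree: TaxonomyTree) -> pd.DataFrame:
    """Convert raw read counts to reads per Mbp of mean category genome."""
    divisors = {c: mean_genome_length_mbp(tree, c) for c in table.columns}
    return table.div(pd.Series(divisors), axis=1)


def filter_stations(
    table: pd.DataFrame, min_density: float = 600.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop stations whose summed normalized count falls below ``min_density``.

    The boundary is inclusive: a station at exactly the floor is retained.
    Returns the retained table and the list of removed station ids.
    """
    totals = table.sum(axis=1)
    keep = totals >= min_density
    removed = [str(s) for s in table.index[~keep]]
    if removed:
        logger.info("removed %d low-density stations: %s", len(removed), removed)
    return table.loc[keep], removed


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: each station row divided by its total."""
    totals = table.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding zero-total stations: {list(table.index[zero])}",
            stacklevel=2,
        )
        table = table.loc[~zero]
        totals = totals[~zero]
    return table.div(totals, axis=0)


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    Accepts any non-negative abundance table on a common category set and
    returns a symmetric station x station DataFrame with zero diagonal.
    """
    values = profiles.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    if (values.sum(axis=1) == 0).any():
        raise ValidationError(
            "Bray-Curtis is undefined for all-zero profiles; filter them first"
        )
    condensed = pdist(values, metric="braycurtis")
    return pd.DataFrame(
        squareform(condensed), index=profiles.index, columns=profiles.index
    )


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """UPGMA merge tree over stations.

    ``merges`` lists ``(left, right, height, size)`` in merge order, where
    ``left``/``right`` index leaves (0..n-1) or prior merges (n+i), matching
    the SciPy linkage convention; ``linkage`` exposes the same data as an
    (n-1) x 4 float matrix for cutting and plotting.
    """

    ids: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def linkage(self) -> np.ndarray:
        return np.array(
            [[l, r, h, s] for l, r, h, s in self.merges], dtype=float
        ).reshape(len(self.merges), 4)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.ids[i] for i in order]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.ids, columns=self.ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths as height differences."""

        def quote(label: str) -> str:
            return f"'{label}'" if any(c in label for c in " \t(),:;'") else label

        def render(idx: int, parent_height: float) -> str:
            if idx < self.n_leaves:
                return f"{quote(self.ids[idx])}:{parent_height:.10g}"
            left, right, height, _ = self.merges[idx - self.n_leaves]
            inner = ",".join(
                render(int(child), height - 0.0) for child in (left, right)
            )
            # branch from this merge up to its parent
            return f"({inner}):{max(parent_height - height, 0.0):.10g}"

        if not self.merges:
            return f"{quote(self.ids[0])};"
        left, right, height, _ = self.merges[-1]
        inner = ",".join(render(int(child), height) for child in (left, right))
        return f"({inner});"


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Unweighted pair-group average clustering of a distance matrix.

    Iteratively merges the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted arithmetic mean of the
    members' distances (equivalently, the unweighted mean over all
    inter-cluster leaf pairs).  Ties on the minimal distance are broken by
    the lexicographically smallest pair of cluster labels, a cluster's label
    being its smallest member station id.
    """
    ids = [str(i) for i in dist.index]
    n = len(ids)
    if n < 2:
        raise ValidationError("UPGMA needs at least two stations")
    d = dist.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 1e-12:
        raise ValidationError("distance matrix must be symmetric with zero diagonal")

    # active cluster bookkeeping: scipy-style indices
    active: dict[int, dict] = {
        i: {"size": 1, "label": ids[i]} for i in range(n)
    }
    # pairwise distances between active clusters, keyed by frozenset of indices
    dd: dict[frozenset, float] = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    dend = Dendrogram(ids=ids)
    next_idx = n
    for _ in range(n - 1):
        best_key = min(
            dd,
            key=lambda k: (
                dd[k],
                tuple(sorted(active[i]["label"] for i in k)),
            ),
        )
        i, j = sorted(best_key)
        height = dd[best_key]
        size = active[i]["size"] + active[j]["size"]
        label = min(active[i]["label"], active[j]["label"])
        for other in list(active):
            if other in (i, j):
                continue
            dij = (
                active[i]["size"] * dd[frozenset((i, other))]
                + active[j]["size"] * dd[frozenset((j, other))]
            ) / size
            dd[frozenset((next_idx, other))] = dij
        for key in [k for k in dd if i in k or j in k]:
            del dd[key]
        del active[i], active[j]
        active[next_idx] = {"size": size, "label": label}
        dend.merges.append((i, j, float(height), size))
        next_idx += 1
    return dend


def cut_clusters(
    dend: Dendrogram,
    k: Optional[int] = None,
    height: Optional[float] = None,
) -> pd.Series:
    """Cut the dendrogram into clusters, by count or by height.

    Cutting at a height keeps every merge at or below it, yielding the
    connected components below the cut; cutting at ``k`` picks a height
    between the (n-k)th and (n-k+1)th merges.  Returns a station -> cluster
    id Series (cluster ids are 1-based integers).
    """
    if (k is None) == (height is None):
        raise ValidationError("specify exactly one of k or height")
    n = dend.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValidationError(f"k={k} outside [1, {n}]")
        labels = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    else:
        if height < 0:
            raise ValidationError("cut height must be non-negative")
        labels = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    return pd.Series(labels, index=dend.ids, name="cluster")


# ---------------------------------------------------------------------------
# Environmental comparison of station clusters
# ---------------------------------------------------------------------------


@dataclass
class EnvTestReport:
    """Kruskal-Wallis + Dunn post hoc report for one environmental variable."""

    variable: str
    testable: bool
    h_statistic: float = np.nan
    p_value: float = np.nan
    group_stats: Optional[pd.DataFrame] = None   # per-cluster n / mean / median
    pairwise: Optional[pd.DataFrame] = None      # Dunn z and adjusted p per pair
    letters: Optional[dict] = None               # compact letter display
    reason: str = ""

    def distinct(self, a, b) -> bool:
        """True when clusters ``a`` and ``b`` share no display letter."""
        if not self.testable or self.letters is None:
            return False
        return not (set(self.letters[a]) & set(self.letters[b]))


def dunn_test(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """All pairwise Dunn z-statistics with multiplicity-adjusted p-values.

    Uses joint ranks with the standard tie correction; ``adjust`` is one of
    ``holm``, ``bh``, ``bonferroni``.
    """
    method = {"holm": "holm", "bh": "fdr_bh", "bonferroni": "bonferroni"}.get(adjust)
    if method is None:
        raise ConfigurationError(f"unknown adjustment method {adjust!r}")
    keys = sorted(groups)
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in keys])
    sizes = {k: len(groups[k]) for k in keys}
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for k in keys:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    # tie correction
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a_idx, a in enumerate(keys):
        for b in keys[a_idx + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"cluster_a": a, "cluster_b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method=method)[1]
    return table


def compact_letter_display(
    keys: Sequence, pairwise: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Assign display letters so clusters sharing a letter are not
    significantly different at the adjusted alpha.

    Built from the maximal cliques of the "not significantly different"
    graph, so every non-significant pair shares at least one letter and no
    letter spans a significant pair.
    """
    g = nx.Graph()
    g.add_nodes_from(keys)
    for _, row in pairwise.iterrows():
        if row["p_adj"] >= alpha:
            g.add_edge(row["cluster_a"], row["cluster_b"])
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(map(str, c)))
    letters = {k: "" for k in keys}
    for i, clique in enumerate(cliques):
        symbol = chr(ord("a") + i) if i < 26 else f"z{i - 25}"
        for member in clique:
            letters[member] += symbol
    return letters


def compare_clusters_env(
    labels: pd.Series,
    meta: pd.DataFrame,
    variable: str,
    adjust: str = "holm",
    alpha: float = 0.05,
) -> EnvTestReport:
    """Test whether an environmental variable differs among station clusters.

    ``labels`` maps station id to cluster; ``meta`` is indexed by station id
    and must carry ``variable`` as a column (NA allowed; stations with a
    missing value are dropped per-variable).  Requires at least two clusters
    with two or more non-missing values each; otherwise the report is marked
    not testable.
    """
    if variable not in meta.columns:
        return EnvTestReport(variable, False, reason=f"variable {variable!r} absent")
    merged = pd.DataFrame({"cluster": labels}).join(meta[[variable]], how="left")
    merged = merged.dropna(subset=[variable])
    groups = {
        k: v[variable].to_numpy(dtype=float)
        for k, v in merged.groupby("cluster")
        if len(v) >= 2
    }
    if len(groups) < 2:
        return EnvTestReport(
            variable, False, reason="fewer than 2 clusters with >=2 values"
        )
    keys = sorted(groups)
    stats_rows = pd.DataFrame(
        {
            "cluster": keys,
            "n": [len(groups[k]) for k in keys],
            "mean": [float(np.mean(groups[k])) for k in keys],
            "median": [float(np.median(groups[k])) for k in keys],
        }
    ).set_index("cluster")

    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        # identical constant values: no variance anywhere, nothing differs
        pairwise = pd.DataFrame(
            [
                {"cluster_a": a, "cluster_b": b, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                for i, a in enumerate(keys)
                for b in keys[i + 1 :]
            ]
        )
        letters = {k: "a" for k in keys}
        return EnvTestReport(
            variable, True, 0.0, 1.0, stats_rows, pairwise, letters
        )

    h, p = stats.kruskal(*[groups[k] for k in keys])
    pairwise = dunn_test(groups, adjust=adjust)
    letters = compact_letter_display(keys, pairwise, alpha=alpha)
    return EnvTestReport(variable, True, float(h), float(p), stats_rows, pairwise, letters)
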