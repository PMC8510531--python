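"""Gene-selection and summarization rules over differential-expression tables.

The pipeline consumes per-gene log2 fold change + p-value tables produced by
an upstream differential-expression tool (one table per strain/condition
versus its control) and applies the selection rules used for interaction
transcriptomics:

* the 2-SD rule: a gene is differentially expressed if its log2FC is more
  than two standard deviations from the table-wide mean log2FC and its
  p-value is below alpha;
* fixed-threshold rules: |log2FC| at or above a cutoff (2 for the global
  heatmaps, 1.58 ≈ 3-fold for specialized-metabolite genes) and p < alpha;
* multi-condition Venn counts of how many conditions flag each gene;
* biosynthetic-gene-cluster summaries: mean/SD log2FC over a cluster's
  genes, with two-sample t-tests between isolated and interacting growth;
* PCA of strain log2FC vectors and Euclidean average-linkage hierarchical
  clustering, as thin plumbing over scikit-learn / scipy.

p-values are taken as given; no multiple-testing correction is layered on
top (``use_padj=True`` switches the gates to an adjusted-p column instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .errors import InputError

__all__ = [
    "DETable",
    "GeneClusterDef",
    "DEFlagSet",
    "VennCounts",
    "ClusterSummary",
    "ConditionComparison",
    "PcaClusterResult",
    "LAN_CLUSTER",
    "flag_de_2sd",
    "flag_de_threshold",
    "venn_shared_counts",
    "cluster_average_lfc",
    "compare_conditions",
    "significance_stars",
    "pca_and_cluster",
]


@dataclass
class DETable:
    """Per-gene log2 fold change and p-value for one comparison."""

    frame: pd.DataFrame  # columns: gene_id, log2fc, pvalue[, padj]
    comparison_label: str = ""

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"DE table missing columns: {sorted(missing)}")
        if self.frame["gene_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise InputError(f"duplicate gene ids in table: {sorted(set(dupes))[:5]}")
        p = self.frame["pvalue"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise InputError("p-values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    def p_column(self, use_padj: bool) -> pd.Series:
        if use_padj:
            if "padj" not in self.frame.columns:
                raise InputError("use_padj requested but table has no 'padj' column")
            return self.frame["padj"]
        return self.frame["pvalue"]


@dataclass(frozen=True)
class GeneClusterDef:
    """A named, ordered list of gene identifiers (a biosynthetic cluster)."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"cluster {self.name!r} has no genes")


#: The cryptic lanthipeptide biosynthetic cluster, SCO6927–SCO6938.
LAN_CLUSTER = GeneClusterDef("lan", tuple(f"SCO{n}" for n in range(6927, 6939)))


@dataclass
class DEFlagSet:
    """Per-gene boolean flags plus the rule and thresholds that produced them."""

    flags: pd.Series  # bool, indexed by gene_id
    rule: str
    params: dict = field(default_factory=dict)
    comparison_label: str = ""

    @property
    def flagged_genes(self) -> set:
        return set(self.flags.index[self.flags])

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def flag_de_2sd(t: DETable, alpha: float = 0.05, use_padj: bool = False) -> DEFlagSet:
    """Flag genes whose log2FC lies beyond 2 SD of the table mean with p < alpha.

    Mean and SD are those of the table's own log2FC distribution (one table =
    one comparison); a zero-variance table flags nothing.
    """
    if len(t) < 3:
        raise InputError("2-SD rule needs at least 3 genes to estimate the spread")
    lfc = t.frame["log2fc"].to_numpy(dtype=float)
    mu, sd = lfc.mean(), lfc.std(ddof=1)
    p = t.p_column(use_padj).to_numpy(dtype=float)
    hit = (np.abs(lfc - mu) > 2.0 * sd) & (p < alpha)
    return DEFlagSet(
        flags=pd.Series(hit, index=t.frame["gene_id"].to_numpy()),
        rule="2sd",
        params={"alpha": alpha, "mean": float(mu), "sd": float(sd), "use_padj": use_padj},
        comparison_label=t.comparison_label,
    )


def flag_de_threshold(
    t: DETable, min_abs_log2fc: float, alpha: float = 0.05, use_padj: bool = False
) -> DEFlagSet:
    """Flag genes with |log2FC| ≥ min_abs_log2fc (boundary inclusive) and p < alpha."""
    if min_abs_log2fc <= 0:
        raise InputError("min_abs_log2fc must be positive")
    lfc = t.frame["log2fc"].to_numpy(dtype=float)
    p = t.p_column(use_padj).to_numpy(dtype=float)
    hit = (np.abs(lfc) >= min_abs_log2fc) & (p < alpha)
    return DEFlagSet(
        flags=pd.Series(hit, index=t.frame["gene_id"].to_numpy()),
        rule="threshold",
        params={"min_abs_log2fc": min_abs_log2fc, "alpha": alpha, "use_padj": use_padj},
        comparison_label=t.comparison_label,
    )


@dataclass
class VennCounts:
    """How many genes are flagged in exactly / at least k conditions."""

    exactly: dict[int, int]
    at_least: dict[int, int]
    n_conditions: int
    union_size: int


def venn_shared_counts(flagsets: "list[DEFlagSet]") -> VennCounts:
    """Count genes flagged in exactly k and in ≥ k of the given conditions.

    The gene universe is the union of gene ids; a gene absent from a table
    counts as unflagged there.
    """
    if len(flagsets) < 2:
        raise ValueError("need at least two flag sets to intersect")
    universe: set = set()
    for fs in flagsets:
        universe |= set(fs.flags.index)
    tally = pd.Series(0, index=sorted(universe))
    for fs in flagsets:
        flagged = fs.flags[fs.flags].index
        tally[flagged] += 1
    k = len(flagsets)
    exactly = {i: int((tally == i).sum()) for i in range(1, k + 1)}
    at_least = {i: int((tally >= i).sum()) for i in range(1, k + 1)}
    return VennCounts(
        exactly=exactly,
        at_least=at_least,
        n_conditions=k,
        union_size=int((tally > 0).sum()),
    )


@dataclass
class ClusterSummary:
    cluster: str
    mean_log2fc: float
    sd_log2fc: float
    n_genes_found: int
    missing_genes: tuple[str, ...]
    values: pd.Series  # per-gene log2fc for the genes found


def cluster_average_lfc(t: DETable, cluster: GeneClusterDef) -> ClusterSummary:
    """Mean and sample SD of log2FC over a gene cluster's members.

    Genes absent from the table are reported, never imputed.
    """
    sub = t.frame.set_index("gene_id")["log2fc"]
    found = [g for g in cluster.gene_ids if g in sub.index]
    missing = tuple(g for g in cluster.gene_ids if g not in sub.index)
    if not found:
        raise InputError(f"no genes of cluster {cluster.name!r} present in the table")
    vals = sub.loc[found].astype(float)
    if len(vals) == 1:
        warnings.warn(
            f"cluster {cluster.name!r} has a single gene in the table; SD reported as 0",
            stacklevel=2,
        )
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1))
    return ClusterSummary(
        cluster=cluster.name,
        mean_log2fc=float(vals.mean()),
        sd_log2fc=sd,
        n_genes_found=len(vals),
        missing_genes=missing,
        values=vals,
    )


_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation ('ns' above 0.05)."""
    for level, stars in _STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


@dataclass
class ConditionComparison:
    t_statistic: float
    pvalue: float
    stars: str


def compare_conditions(
    iso_values: np.ndarray, int_values: np.ndarray, equal_var: bool = False
) -> ConditionComparison:
    """Two-sample t-test between per-gene cluster log2FC under two conditions.

    Welch's unequal-variance test by default; pass ``equal_var=True`` for the
    pooled-variance variant.
    """
    a = np.asarray(iso_values, dtype=float)
    b = np.asarray(int_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each condition needs at least 2 values for a t-test")
    if np.array_equal(a, b) and a.std() == 0:
        # degenerate: both samples identical constants
        return ConditionComparison(0.0, 1.0, "ns")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ConditionComparison(float(t), float(p), significance_stars(float(p)))


@dataclass
class PcaClusterResult:
    coords: pd.DataFrame  # strains × components
    variance_explained: np.ndarray  # percentages per component
    linkage: np.ndarray  # scipy linkage matrix (average, Euclidean)
    dendrogram_order: list[str]
    n_shared_genes: int


def pca_and_cluster(tables: "list[DETable]", n_components: int = 2) -> PcaClusterResult:
    """PCA of strain log2FC vectors + Euclidean average-linkage clustering.

    Strains (tables) are the observations and the shared gene universe the
    features.  Reports per-component variance-explained percentages and the
    dendrogram leaf order.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    shared: set | None = None
    for t in tables:
        ids = set(t.frame["gene_id"])
        shared = ids if shared is None else (shared & ids)
    shared_ids = sorted(shared or ())
    if len(shared_ids) < 2:
        raise InputError(f"only {len(shared_ids)} genes shared across tables; need at least 2")
    labels = [t.comparison_label or f"table{i}" for i, t in enumerate(tables)]
    X = np.stack(
        [t.frame.set_index("gene_id")["log2fc"].loc[shared_ids].to_numpy(dtype=float) for t in tables]
    )
    k = min(n_components, len(tables), X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return PcaClusterResult(
        coords=pd.DataFrame(coords, index=labels, columns=[f"PC{i+1}" for i in range(k)]),
        variance_explained=pca.explained_variance_ratio_ * 100.0,
        linkage=Z,
        dendrogram_order=order,
        n_shared_genes=len(shared_ids),
    )
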