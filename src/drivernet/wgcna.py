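"""Weighted co-expression network construction and module detection.

One dataset at a time: the gene-gene similarity is the absolute Pearson
correlation S_mn = |cor(m, n)|, soft-thresholded into an adjacency
a_mn = S_mn^beta.  beta is chosen as the smallest power for which the network
approximates a scale-free degree distribution (squared correlation of
log p(k) vs log k at or above a cutoff, with negative slope).  The adjacency
is then transformed into the topological overlap similarity

    w_mn = (l_mn + a_mn) / (min{k_m, k_n} + 1 - a_mn),
    l_mn = sum_u a_mu * a_un,   k_m = sum_u a_mu,

whose dissimilarity d = 1 - w feeds average-linkage hierarchical clustering.
Branches obtained by a static cut of the dendrogram that contain at least
``min_module_size`` genes become modules; the rest stay unassigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

from .expression import ExpressionError, ExpressionMatrix

logger = logging.getLogger(__name__)

#: classic module color sequence, assigned to modules by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)

UNASSIGNED = "unassigned"
DEFAULT_POWERS = tuple(range(1, 21))


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded adjacency |cor|^beta with zero diagonal."""

    values: pd.DataFrame
    beta: int

    def __post_init__(self) -> None:
        V = self.values.to_numpy()
        if V.shape[0] != V.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if V.min() < -1e-12 or V.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def connectivity(self) -> pd.Series:
        """k_m = sum over u != m of a_mu (diagonal excluded)."""
        A = self.values.to_numpy(dtype=float).copy()
        np.fill_diagonal(A, 0.0)
        return pd.Series(A.sum(axis=1), index=self.values.index, name="k")


@dataclass
class TOMResult:
    """Topological overlap similarity w, dissimilarity d = 1 - w, and k."""

    similarity: pd.DataFrame
    dissimilarity: pd.DataFrame
    connectivity: pd.Series


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit of one candidate power."""

    power: int
    r_squared: float
    slope: float
    mean_connectivity: float


@dataclass
class ModuleAssignment:
    """Per-gene module label for one dataset.

    ``labels`` maps every input gene to either ``"M1"``, ``"M2"``, ... (by
    decreasing module size) or ``"unassigned"``; ``colors`` carries the
    conventional color alias per module (grey for unassigned).
    """

    labels: pd.Series
    colors: pd.Series
    cut_height: float
    min_module_size: int
    params: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_names(self) -> list[str]:
        """Module labels ordered M1, M2, ... (unassigned excluded)."""
        names = [l for l in self.labels.unique() if l != UNASSIGNED]
        return sorted(names, key=lambda s: int(s.lstrip("M")))

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"module": self.labels, "color": self.colors}).rename_axis("gene")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ModuleAssignment":
        df = pd.read_csv(path, sep="\t", index_col=0)
        colors = df["color"] if "color" in df else pd.Series("grey", index=df.index)
        return cls(labels=df["module"], colors=colors, cut_height=float("nan"), min_module_size=0)


# ---------------------------------------------------------------------------
# correlation and adjacency


def correlation_matrix(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Unsigned correlation S_mn = |Pearson cor| across samples.

    Genes with zero variance are removed with a warning; fewer than three
    samples is an error (a correlation over two points is +/-1 identically).
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ExpressionError("correlation requires at least 3 samples")
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(values.index[~keep])
        warnings.warn(f"removed {len(dropped)} zero-variance genes: {dropped[:5]}")
        X = X[keep]
    genes = values.index[keep]
    if X.shape[0] < 2:
        raise ExpressionError("fewer than 2 genes with positive variance")
    S = np.abs(np.corrcoef(X))
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=genes, columns=genes)


def adjacency(S: pd.DataFrame, beta: int) -> AdjacencyMatrix:
    """Power adjacency a_mn = S_mn^beta (soft thresholding)."""
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be a positive integer, got {beta!r}")
    A = S.to_numpy(dtype=float) ** int(beta)
    A = pd.DataFrame(A, index=S.index, columns=S.columns)
    return AdjacencyMatrix(values=A, beta=int(beta))


# ---------------------------------------------------------------------------
# scale-free topology fit and power selection


def scale_free_fit(A: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10 p(k) ~ log10 k over equal-width connectivity bins.

    Returns the squared correlation of the regression and its slope (a
    scale-free network shows a straight line with negative slope).
    """
    k = A.connectivity().to_numpy()
    pos = k[k > 0]
    if len(pos) < n_bins:
        raise ValueError(
            f"need at least {n_bins} genes with positive connectivity, got {len(pos)}"
        )
    if np.ptp(pos) == 0:
        raise ValueError("all connectivities equal; binning degenerate")
    edges = np.linspace(pos.min(), pos.max(), n_bins + 1)
    idx = np.clip(np.digitize(pos, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([pos[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    p_k = counts[nonempty] / len(pos)
    mean_k = mean_k[nonempty]
    if nonempty.sum() < 3:
        raise ValueError("fewer than 3 nonempty connectivity bins")
    fit = linregress(np.log10(mean_k), np.log10(p_k))
    return ScaleFreeFit(
        power=A.beta,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        mean_connectivity=float(k.mean()),
    )


def power_fit_table(
    S: pd.DataFrame,
    candidates: Sequence[int] = DEFAULT_POWERS,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free fit statistics for every candidate power."""
    rows = []
    for beta in candidates:
        entry = scale_free_fit(adjacency(S, beta), n_bins=n_bins)
        rows.append(
            {
                "power": entry.power,
                "r_squared": entry.r_squared,
                "slope": entry.slope,
                "mean_connectivity": entry.mean_connectivity,
            }
        )
    return pd.DataFrame(rows)


def select_power(
    m: ExpressionMatrix | pd.DataFrame,
    candidates: Sequence[int] = DEFAULT_POWERS,
    r2_cutoff: float = 0.9,
    n_bins: int = 10,
) -> int:
    """Smallest power whose fit reaches ``r2_cutoff`` with negative slope.

    Falls back to the candidate with maximal r-squared (with a warning) when
    no candidate crosses the cutoff.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    S = correlation_matrix(m) if isinstance(m, (ExpressionMatrix, pd.DataFrame)) else m
    table = power_fit_table(S, candidates, n_bins=n_bins)
    ok = table[(table.r_squared >= r2_cutoff) & (table.slope < 0)]
    if len(ok):
        return int(ok.iloc[0].power)
    best = int(table.loc[table.r_squared.idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached r2 >= {r2_cutoff}; "
        f"falling back to power {best} with max r2 {table.r_squared.max():.3f}"
    )
    return best


# ---------------------------------------------------------------------------
# topological overlap


def tom_similarity(A: AdjacencyMatrix | pd.DataFrame) -> TOMResult:
    """Topological overlap w_mn = (l_mn + a_mn)/(min{k_m,k_n} + 1 - a_mn)."""
    if isinstance(A, AdjacencyMatrix):
        values = A.values
    else:
        values = A
    a = values.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("adjacency asymmetric beyond 1e-9")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # zero diagonal of a removes the u=m and u=n terms
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = (L + a) / denom
    np.fill_diagonal(w, 1.0)
    np.clip(w, 0.0, 1.0, out=w)
    w = pd.DataFrame(w, index=values.index, columns=values.columns)
    d = 1.0 - w
    return TOMResult(
        similarity=w,
        dissimilarity=d,
        connectivity=pd.Series(k, index=values.index, name="k"),
    )


# ---------------------------------------------------------------------------
# module detection


def cluster_modules(
    d: pd.DataFrame,
    cut_height: float = 0.9,
    min_module_size: int = 30,
    cut_mode: str = "relative",
) -> ModuleAssignment:
    """Average-linkage clustering of a dissimilarity, static cut, size filter.

    The dendrogram is cut into branches; branches with at least
    ``min_module_size`` genes become modules labeled ``M1``, ``M2``, ... by
    decreasing size (ties broken by the lowest member gene index), smaller
    branches become ``unassigned``.  Deterministic for a fixed input.

    ``cut_mode="relative"`` (default) follows the tree-cut convention of
    placing the cut at ``cut_height`` of the dendrogram's merge-height range
    (5th percentile to maximum), which keeps module detection stable across
    soft-threshold powers — TOM dissimilarities compress toward 1 as beta
    grows, so a fixed absolute height would dissolve modules at high powers.
    ``cut_mode="absolute"`` cuts at the raw height ``cut_height``.
    """
    D = d.to_numpy(dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("dissimilarity must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-9:
        raise ValueError("dissimilarity diagonal must be zero")
    genes = list(d.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not 0.0 <= cut_height <= 1.0:
        raise ValueError("cut_height must lie in [0, 1]")
    if cut_mode not in ("relative", "absolute"):
        raise ValueError("cut_mode must be 'relative' or 'absolute'")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    if cut_mode == "relative":
        heights = Z[:, 2]
        h_lo = float(np.percentile(heights, 5))
        h_hi = float(heights.max())
        threshold = h_lo + cut_height * (h_hi - h_lo)
    else:
        threshold = cut_height
    # branches merging at (or within float fuzz of) the cut height are
    # split: the cut is strict, with a 1e-6 guard band on the [0, 1] scale
    branch = fcluster(Z, t=threshold - 1e-6, criterion="distance")

    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, b in enumerate(branch):
        sizes[b] = sizes.get(b, 0) + 1
        first_idx.setdefault(b, i)
    big = [b for b, s in sizes.items() if s >= min_module_size]
    big.sort(key=lambda b: (-sizes[b], first_idx[b]))

    label_of_branch = {b: f"M{r + 1}" for r, b in enumerate(big)}
    color_of_branch = {
        b: MODULE_COLORS[r % len(MODULE_COLORS)] for r, b in enumerate(big)
    }
    labels = pd.Series(
        [label_of_branch.get(b, UNASSIGNED) for b in branch], index=genes, name="module"
    )
    colors = pd.Series(
        [color_of_branch.get(b, "grey") for b in branch], index=genes, name="color"
    )
    return ModuleAssignment(
        labels=labels,
        colors=colors,
        cut_height=cut_height,
        min_module_size=min_module_size,
    )


# ---------------------------------------------------------------------------
# estimator facade


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Detect co-expression modules in a genes x samples matrix.

    sklearn-style clusterer: ``fit(X)`` runs correlation -> power selection
    -> adjacency -> topological overlap -> average-linkage cut, and exposes
    ``labels_`` over the input genes ("observations" here are genes, features
    are samples).

    Parameters
    ----------
    power : int or None
        Fixed soft-threshold power; when None it is selected as the smallest
        candidate reaching ``r2_cutoff`` scale-free fit.
    powers : sequence of int
        Candidate powers for the selection.
    r2_cutoff : float
        Scale-free topology fit threshold.
    cut_height : float
        Static dendrogram cut height on the TOM dissimilarity.
    min_module_size : int
        Minimum branch size to form a module.
    n_bins : int
        Connectivity bins for the scale-free fit.
    """

    def __init__(
        self,
        power: int | None = None,
        powers: Sequence[int] = DEFAULT_POWERS,
        r2_cutoff: float = 0.9,
        cut_height: float = 0.9,
        min_module_size: int = 30,
        n_bins: int = 10,
        cut_mode: str = "relative",
    ):
        self.power = power
        self.powers = powers
        self.r2_cutoff = r2_cutoff
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.n_bins = n_bins
        self.cut_mode = cut_mode

    def fit(self, X, y=None):
        if isinstance(X, ExpressionMatrix):
            values = X.values
        elif isinstance(X, pd.DataFrame):
            values = X
        else:
            X = np.asarray(X, dtype=float)
            values = pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])])
        S = correlation_matrix(values)
        if self.power is None:
            self.fit_table_ = power_fit_table(S, sorted(int(p) for p in self.powers), self.n_bins)
            ok = self.fit_table_[
                (self.fit_table_.r_squared >= self.r2_cutoff) & (self.fit_table_.slope < 0)
            ]
            if len(ok):
                self.beta_ = int(ok.iloc[0].power)
            else:
                self.beta_ = int(self.fit_table_.loc[self.fit_table_.r_squared.idxmax(), "power"])
                warnings.warn(
                    f"no power reached r2 >= {self.r2_cutoff}; using power {self.beta_}"
                )
        else:
            self.beta_ = int(self.power)
            self.fit_table_ = power_fit_table(S, [self.beta_], self.n_bins)
        A = adjacency(S, self.beta_)
        tom = tom_similarity(A)
        self.tom_ = tom
        self.connectivity_ = tom.connectivity
        self.assignment_ = cluster_modules(
            tom.dissimilarity,
            cut_height=self.cut_height,
            min_module_size=self.min_module_size,
            cut_mode=self.cut_mode,
        )
        self.assignment_.params.update(
            {"beta": self.beta_, "r2_cutoff": self.r2_cutoff, "n_bins": self.n_bins}
        )
        # genes dropped for zero variance are reported unassigned
        all_genes = list(values.index)
        self.labels_ = self.assignment_.labels.reindex(all_genes, fill_value=UNASSIGNED)
        self.n_modules_ = self.assignment_.n_modules
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()


def detect_modules(
    m: ExpressionMatrix,
    power: int | None = None,
    powers: Sequence[int] = DEFAULT_POWERS,
    r2_cutoff: float = 0.9,
    cut_height: float = 0.9,
    min_module_size: int = 30,
    cut_mode: str = "relative",
) -> tuple[ModuleAssignment, int, pd.DataFrame]:
    """Functional wrapper: returns (assignment, selected beta, fit table)."""
    est = CoexpressionModules(
        power=power,
        powers=powers,
        r2_cutoff=r2_cutoff,
        cut_height=cut_height,
        min_module_size=min_module_size,
        cut_mode=cut_mode,
    ).fit(m)
    assignment = ModuleAssignment(
        labels=est.labels_,
        colors=est.assignment_.colors.reindex(est.labels_.index, fill_value="grey"),
        cut_height=cut_height,
        min_module_size=min_module_size,
        params=dict(est.assignment_.params),
    )
    return assignment, est.beta_, est.fit_table_
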