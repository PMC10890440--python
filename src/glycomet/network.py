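"""Weighted correlation-network analysis of residualized metabolites and
modular differential connectivity (MDC) between intervention groups.

Per group, an unsigned soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^p
is built on covariate-residualized samples, converted to topological
overlap similarity (TOM), and average-linkage clustered with a static tree
cut to obtain modules (size-ranked WGCNA-style color labels; "grey" =
unassigned). A module's differential connectivity between groups A and B is
the signed sum of pairwise adjacency differences

    MDC(A, B) = sum_{i<j in module} (a_ij^A - a_ij^B)

(positive = tighter co-regulation in A, i.e. gain of connectivity), with
significance from a label-permutation null. The intramodular connectivity
ratio sum(a^A)/sum(a^B) is reported alongside as a secondary descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import DataError

#: WGCNA color sequence used for size-ranked module labels (cosmetic).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue", "violet",
)
UNASSIGNED = "grey"
SOFT_POWER_FALLBACK = 6


@dataclass
class NetworkConfig:
    correlation: str = "pearson"
    soft_power: int | str = "auto"
    scale_free_r2_target: float = 0.8
    tom_type: str = "unsigned"
    tree_cut_height: float = 0.75
    min_module_size: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise DataError("soft_power must be >= 1 or 'auto'")
        if not (0.0 < self.tree_cut_height < 1.0):
            raise DataError("tree_cut_height must be in (0, 1)")
        if self.min_module_size < 3:
            raise DataError("min_module_size must be >= 3")
        if self.n_perm < 100:
            raise DataError("n_perm must be >= 100")


# -- adjacency / TOM ---------------------------------------------------------


def adjacency(X, power: int | float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |pearson(x_i, x_j)|^power.

    ``X`` is sample x feature (DataFrame or array). Unit diagonal, entries
    in [0, 1]. Raises naming the first constant column.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    arr = Xdf.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = Xdf.columns[int(np.argmax(sd == 0))]
        raise DataError(f"constant column {bad!r} has undefined correlation")
    r = np.corrcoef(arr, rowvar=False)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=Xdf.columns, columns=Xdf.columns)


def tom_similarity(A) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    Adf = A if isinstance(A, pd.DataFrame) else pd.DataFrame(np.asarray(A, dtype=float))
    a = Adf.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise DataError("adjacency must be a symmetric square matrix")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise DataError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise DataError("adjacency must have a unit diagonal")
    L = a @ a
    k = a.sum(axis=0) - 1.0
    numer = L - a  # removes the u=i and u=j terms, then adds back a_ij
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):  # 0/0 on the diagonal, overwritten below
        tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=Adf.index, columns=Adf.columns)


# -- soft power selection ----------------------------------------------------


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 frequency vs log10 mean connectivity per bin.

    The scale-free topology criterion: connectivity values are binned, and
    log10 of the bin frequency is regressed on log10 of the bin's mean
    connectivity. Returns (r_squared, slope); degenerate inputs give (0, 0).
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r), float(slope)


def choose_soft_power(
    X,
    target: float = 0.8,
    powers=range(1, 21),
    n_bins: int = 10,
) -> int:
    """Smallest power whose scale-free fit reaches R^2 >= target with a
    negative slope; falls back to 6 with a warning when none qualifies."""
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if Xdf.shape[1] < 10:
        raise DataError("need at least 10 features to assess scale-free fit")
    if Xdf.shape[0] < 10:
        raise DataError("need at least 10 samples to assess scale-free fit")
    base = adjacency(Xdf, 1).to_numpy()
    r_abs = np.abs(base)
    for power in powers:
        a = r_abs ** power
        k = a.sum(axis=0) - 1.0
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        if slope < 0 and r2 >= target:
            return int(power)
    warnings.warn(
        f"no power in {list(powers)[:1]}..{list(powers)[-1]} reached scale-free "
        f"R^2 {target}; falling back to {SOFT_POWER_FALLBACK}",
        RuntimeWarning, stacklevel=2,
    )
    return SOFT_POWER_FALLBACK


# -- module detection --------------------------------------------------------


def detect_modules(
    tom: pd.DataFrame,
    tree_cut_height: float = 0.75,
    min_module_size: int = 5,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` are labeled 'grey'; the rest
    get color labels by decreasing size (ties broken by smallest member
    id). Deterministic given the input. If everything is grey a warning is
    emitted (not an error).
    """
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=tree_cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, name="module", dtype=object)
    clusters = []
    for c in np.unique(raw):
        members = tom.index[raw == c]
        if len(members) >= min_module_size:
            clusters.append((len(members), str(min(members)), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.loc[members] = color
    if not clusters:
        warnings.warn("all features unassigned (grey) at this tree cut",
                      RuntimeWarning, stacklevel=2)
    return labels


def hub_metabolite(A: pd.DataFrame, members) -> str:
    """Module member with maximal intramodular connectivity
    sum_{j in module, j != i} a_ij; ties broken lexicographically."""
    members = list(members)
    if len(members) == 0:
        raise DataError("empty module")
    sub = A.loc[members, members].to_numpy(dtype=float)
    conn = sub.sum(axis=1) - np.diag(sub)
    conn = pd.Series(conn, index=members)
    best = conn.max()
    return min(conn.index[np.isclose(conn, best, rtol=0, atol=1e-12)])


def intramodular_connectivity(A: pd.DataFrame, members) -> pd.Series:
    sub = A.loc[list(members), list(members)].to_numpy(dtype=float)
    return pd.Series(sub.sum(axis=1) - np.diag(sub), index=list(members))


# -- modular differential connectivity ---------------------------------------


@dataclass
class MDCResult:
    module: str
    group_a: str
    group_b: str
    statistic: float
    ratio: float
    perm_p: float
    call: str            # 'GOC', 'LOC' or 'none'
    n_perm: int
    members: tuple[str, ...] = field(default=(), repr=False)


def _pair_adjacency_sums(X: np.ndarray, power: float) -> float:
    a = np.abs(np.corrcoef(X, rowvar=False)) ** power
    iu = np.triu_indices(a.shape[1], 1)
    return a[iu]


def mdc_statistic(X_A, X_B, members, power: int | float) -> float:
    """Signed sum over module pairs of adjacency differences between the two
    groups' networks (computed within each group's own samples at a shared
    soft power). Antisymmetric in (A, B); exactly 0 when X_A is X_B."""
    members = list(members)
    if len(members) < 3:
        raise DataError("module needs >= 3 members")
    for name, X in (("A", X_A), ("B", X_B)):
        missing = [m for m in members if m not in X.columns]
        if missing:
            raise DataError(f"members missing from group {name}: {missing[:5]}")
    pa = _pair_adjacency_sums(X_A[members].to_numpy(dtype=float), power)
    pb = _pair_adjacency_sums(X_B[members].to_numpy(dtype=float), power)
    return float((pa - pb).sum())


def connectivity_ratio(X_A, X_B, members, power: int | float) -> float:
    members = list(members)
    pa = _pair_adjacency_sums(X_A[members].to_numpy(dtype=float), power).sum()
    pb = _pair_adjacency_sums(X_B[members].to_numpy(dtype=float), power).sum()
    return float(pa / pb) if pb > 0 else float("nan")


def mdc_permutation_test(
    X_A: pd.DataFrame,
    X_B: pd.DataFrame,
    members,
    power: int | float,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    module: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> MDCResult:
    """Two-sided permutation test of the MDC statistic.

    Samples of both groups are pooled and group labels re-drawn ``n_perm``
    times preserving group sizes; perm_p uses the add-one estimator
    (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1), so the smallest attainable
    p is 1/(n_perm + 1). GOC is called when the statistic is positive and
    perm_p < alpha; LOC when negative and perm_p < alpha.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    if len(X_A) < 5 or len(X_B) < 5:
        raise DataError("each group needs >= 5 samples for the permutation null")
    members = list(members)
    t_obs = mdc_statistic(X_A, X_B, members, power)
    ratio = connectivity_ratio(X_A, X_B, members, power)

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pooled = np.vstack([
        X_A[members].to_numpy(dtype=float), X_B[members].to_numpy(dtype=float)])
    n_a = len(X_A)
    n_tot = pooled.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        pa = _pair_adjacency_sums(pooled[perm[:n_a]], power)
        pb = _pair_adjacency_sums(pooled[perm[n_a:]], power)
        if abs(float((pa - pb).sum())) >= abs(t_obs):
            exceed += 1
    perm_p = (1.0 + exceed) / (n_perm + 1.0)
    if perm_p < alpha and t_obs > 0:
        call = "GOC"
    elif perm_p < alpha and t_obs < 0:
        call = "LOC"
    else:
        call = "none"
    return MDCResult(module, group_a, group_b, t_obs, ratio, perm_p, call,
                     n_perm, tuple(members))


# -- estimator facade --------------------------------------------------------


class ModuleDetector(BaseEstimator):
    """Clustering-style estimator: adjacency -> TOM -> static-cut modules.

    After ``fit(X)`` (X = residualized sample x metabolite DataFrame):

    - ``power_``: soft power used (auto-selected unless given),
    - ``adjacency_``, ``tom_``: the derived matrices,
    - ``labels_``: module color per feature (ndarray, 'grey' = unassigned),
    - ``assignment_``: same as a Series indexed by feature,
    - ``modules_``: dict color -> member index,
    - ``hubs_``: dict color -> hub metabolite id.
    """

    def __init__(self, soft_power: int | str = "auto",
                 scale_free_r2_target: float = 0.8,
                 tree_cut_height: float = 0.75, min_module_size: int = 5):
        self.soft_power = soft_power
        self.scale_free_r2_target = scale_free_r2_target
        self.tree_cut_height = tree_cut_height
        self.min_module_size = min_module_size

    def fit(self, X: pd.DataFrame, y=None):
        if self.soft_power == "auto":
            self.power_ = choose_soft_power(X, target=self.scale_free_r2_target)
        else:
            self.power_ = int(self.soft_power)
        self.adjacency_ = adjacency(X, self.power_)
        self.tom_ = tom_similarity(self.adjacency_)
        self.assignment_ = detect_modules(
            self.tom_, self.tree_cut_height, self.min_module_size)
        self.labels_ = self.assignment_.to_numpy()
        self.modules_ = {
            color: self.assignment_.index[self.assignment_ == color]
            for color in pd.unique(self.assignment_) if color != UNASSIGNED
        }
        self.hubs_ = {
            color: hub_metabolite(self.adjacency_, members)
            for color, members in self.modules_.items()
        }
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
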