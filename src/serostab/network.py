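"""Weighted correlation network construction and module detection.

The network is built from biweight midcorrelations (a median/MAD-weighted
robust correlation) between protein profiles, raised to a soft-threshold
power chosen by a scale-free topology criterion, and converted to a
topological overlap matrix (TOM) that scores two proteins as proximal when
they share network neighbors. Modules are detected by average-linkage
hierarchical clustering of the TOM dissimilarity with a static cut; small
clusters fall into the reserved "grey" (unassigned) label, and modules with
near-identical eigenproteins are merged. Each module is summarized by its
eigenprotein (first principal component of the standardized member profiles)
and each protein by its module membership (kME) and intramodular
connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "bicor",
    "bicor_matrix",
    "bicor_cross",
    "pick_soft_power",
    "tom_similarity",
    "detect_modules",
    "rescue_unassigned",
    "merge_close_modules",
    "module_eigenproteins",
    "module_membership",
    "intramodular_connectivity",
    "build_network",
    "CorrelationNetwork",
    "ModulePartition",
]

GREY = "grey"


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_prepare(v: np.ndarray) -> np.ndarray:
    """Median-centered, Tukey-biweight-weighted copy of ``v``.

    With m = median(v), MAD = median(|v - m|), u = (v - m) / (9 MAD) and
    weights w = (1 - u^2)^2 on |u| < 1, returns (v - m) * w. A zero MAD
    (more than half the values tied) degrades the weights to ones relative
    to the mean — i.e. that vector contributes as in a Pearson correlation.
    """
    v = np.asarray(v, dtype=float)
    m = np.median(v)
    mad = np.median(np.abs(v - m))
    if mad == 0.0:
        return v - np.mean(v)
    u = (v - m) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
    return (v - m) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation between two equal-length vectors.

    Robust alternative to Pearson correlation: observations far from the
    median (beyond 9 MADs) get zero weight. Falls back to Pearson weighting
    for a vector whose MAD is zero. Returns NaN (with a warning) if either
    weighted vector has zero norm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bicor expects two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("bicor needs at least 3 observations")
    xt = _bicor_prepare(x)
    yt = _bicor_prepare(y)
    nx = np.sqrt(np.sum(xt * xt))
    ny = np.sqrt(np.sum(yt * yt))
    if nx == 0.0 or ny == 0.0:
        warnings.warn("bicor undefined: zero weighted norm")
        return float("nan")
    return float(np.clip(np.sum(xt * yt) / (nx * ny), -1.0, 1.0))


def _prepare_columns(X: np.ndarray) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        out[:, j] = _bicor_prepare(X[:, j])
    norms = np.sqrt((out * out).sum(axis=0))
    zero = norms == 0.0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} columns with zero weighted norm (NaN bicor)")
        norms[zero] = np.nan
    return out / norms


def bicor_matrix(X: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """All-pairs biweight midcorrelation of the columns of ``X``."""
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if vals.shape[0] < 3:
        raise ValueError("bicor needs at least 3 observations")
    t = _prepare_columns(vals)
    c = np.clip(t.T @ t, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(c, index=X.columns, columns=X.columns)
    return c


def bicor_cross(X, Y):
    """Biweight midcorrelations between columns of ``X`` and columns of ``Y``."""
    xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    c = np.clip(_prepare_columns(xv).T @ _prepare_columns(yv), -1.0, 1.0)
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        return pd.DataFrame(c, index=X.columns, columns=Y.columns)
    return c


# ---------------------------------------------------------------------------
# soft-threshold power


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit of a connectivity vector.

    Bins connectivity into ``n_bins`` equal-width bins, computes each bin's
    relative frequency p(k) and mean connectivity, and regresses
    log10 p(k) on log10 mean-k over non-empty bins. Returns
    ``(signed_r2, slope)`` with signed R² = −sign(slope)·R², so a
    scale-free (decreasing) degree distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    keep = counts > 0
    mean_k = np.array(
        [k[which == b].mean() if counts[b] > 0 else np.nan for b in range(n_bins)]
    )
    keep &= mean_k > 0
    if keep.sum() < 2:
        return float("nan"), float("nan")
    lx = np.log10(mean_k[keep])
    ly = np.log10(counts[keep] / counts.sum())
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_power(
    cor,
    candidates=tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power β the adjacency |cor|^β yields a connectivity
    vector whose scale-free fit is scored by :func:`scale_free_fit_index`;
    the smallest β reaching ``r2_target`` wins. If no candidate reaches the
    target, the best-fitting β is returned with a warning.

    Returns ``(beta, fit_table)`` where the table holds per-candidate signed
    R², slope and mean connectivity.
    """
    c = cor.to_numpy(dtype=float) if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.abs(c).max() > 1 + 1e-9:
        raise ValueError("correlation entries must lie in [-1, 1]")
    absc = np.abs(c)
    rows = []
    for beta in candidates:
        a = absc**beta
        k = a.sum(axis=0) - 1.0  # exclude self-adjacency
        if np.all(k <= 1e-12):
            raise ValueError(f"all-zero connectivity at power {beta}: no network")
        r2s, slope = scale_free_fit_index(k, n_bins=n_bins)
        rows.append((beta, r2s, slope, float(k.mean()), float(k.max())))
    table = pd.DataFrame(
        rows, columns=["power", "signed_r2", "slope", "mean_k", "max_k"]
    )
    ok = table[table["signed_r2"] >= r2_target]
    if len(ok):
        beta = int(ok.iloc[0]["power"])
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached signed R^2 >= {r2_target}; "
            f"using best fit beta={beta}"
        )
    return beta, table


# ---------------------------------------------------------------------------
# topological overlap


def tom_similarity(adjacency):
    """Topological overlap matrix of an adjacency matrix.

    For i ≠ j, ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 −
    a_ij)`` with the sum over u ∉ {i, j} and connectivity k excluding the
    diagonal; the diagonal is 1 by convention. Input must be symmetric with
    entries in [0, 1] and unit diagonal.
    """
    a = (
        adjacency.to_numpy(dtype=float)
        if isinstance(adjacency, pd.DataFrame)
        else np.asarray(adjacency, float)
    )
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = a.sum(axis=0) - 1.0
    shared = a @ a - a  # (i,j) entry: sum_{u != i,j} a_iu a_uj + a_ij
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = shared / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# ---------------------------------------------------------------------------
# module detection


@dataclass
class CorrelationNetwork:
    """Correlation network artifacts: bicor matrix, power, adjacency, TOM."""

    cor: pd.DataFrame
    power: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    connectivity: pd.Series
    fit_table: pd.DataFrame | None = None


@dataclass
class ModulePartition:
    """Protein → module assignment with optional module summaries.

    ``labels`` maps proteins to module ids, with the reserved id ``"grey"``
    for proteins that could not be clustered; ``eigenproteins`` holds one
    unit-norm subject-space vector per module; ``kme`` the protein × module
    biweight midcorrelations with the eigenproteins; ``k_in`` / ``k_hat``
    the raw and max-standardized intramodular connectivities.
    """

    labels: pd.Series
    eigenproteins: pd.DataFrame | None = field(default=None)
    kme: pd.DataFrame | None = field(default=None)
    k_in: pd.Series | None = field(default=None)
    k_hat: pd.Series | None = field(default=None)

    @property
    def modules(self) -> list[str]:
        return sorted(m for m in self.labels.unique() if m != GREY)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels != GREY].value_counts()
        return sizes.sort_index()


def _canonical_labels(labels: pd.Series) -> pd.Series:
    """Rename modules M01, M02, … by decreasing size (ties: lowest index)."""
    order: list[str] = []
    sizes: dict[str, int] = {}
    first_pos: dict[str, int] = {}
    for pos, mid in enumerate(labels):
        if mid == GREY:
            continue
        if mid not in sizes:
            sizes[mid] = 0
            first_pos[mid] = pos
        sizes[mid] += 1
    order = sorted(sizes, key=lambda m: (-sizes[m], first_pos[m]))
    rename = {mid: f"M{i + 1:02d}" for i, mid in enumerate(order)}
    rename[GREY] = GREY
    return labels.map(rename)


def detect_modules(
    diss, min_module_size: int = 15, cut_height: float = 0.995
) -> ModulePartition:
    """Detect modules by average-linkage clustering of a dissimilarity.

    The tree is cut statically at ``cut_height``; clusters smaller than
    ``min_module_size`` are assigned to "grey". Module ids are deterministic:
    numbered by decreasing size with ties broken by lowest protein index.
    """
    d = diss.to_numpy(dtype=float) if isinstance(diss, pd.DataFrame) else np.asarray(diss, float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have zero diagonal")
    names = list(diss.index) if isinstance(diss, pd.DataFrame) else list(range(len(d)))
    n = d.shape[0]
    if n < min_module_size:
        warnings.warn("fewer proteins than min_module_size: everything grey")
        return ModulePartition(labels=pd.Series(GREY, index=names))
    z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series([f"C{c}" for c in flat], index=names)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = GREY
    return ModulePartition(labels=_canonical_labels(labels))


def rescue_unassigned(
    partition: ModulePartition,
    expr: pd.DataFrame,
    kme_threshold: float = 0.30,
) -> ModulePartition:
    """Attach unassigned proteins to the module they clearly belong to.

    The static tree cut operates on topological-overlap dissimilarity,
    which the soft-threshold power compresses toward 1: at high powers,
    weakly loaded module members can fail to attach even though their
    profiles clearly track a module eigenprotein. Module membership (kME)
    lives on the correlation scale and is immune to that compression, so
    each grey protein is assigned to the module with its largest |kME|
    when that membership reaches ``kme_threshold`` — the customary floor
    below which a protein is not considered a module member. Proteins
    under the floor for every module stay grey.
    """
    grey = [p for p in partition.labels.index if partition.labels[p] == GREY]
    if not grey or not partition.modules:
        return partition
    mes = module_eigenproteins(expr, partition)
    kme = bicor_cross(expr[grey], mes)
    labels = partition.labels.copy()
    best = kme.abs().idxmax(axis=1)
    strength = kme.abs().max(axis=1)
    for p in grey:
        if strength[p] >= kme_threshold:
            labels[p] = best[p]
    return ModulePartition(labels=_canonical_labels(labels))


def module_eigenproteins(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Columns of ``expr`` (subjects × proteins, log scale) belonging to each
    non-grey module are z-scored and decomposed; the module eigenprotein is
    the first left singular vector (a unit-norm vector over subjects),
    sign-fixed so the mean biweight midcorrelation of members with it is
    positive. Constant protein columns are dropped with a warning.
    """
    mes = {}
    for mid in partition.modules:
        cols = [p for p in partition.members(mid) if p in expr.columns]
        sub = expr[cols].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=0)
        if (sd == 0).any():
            warnings.warn(
                f"module {mid}: dropping {int((sd == 0).sum())} constant columns"
            )
            sub = sub[:, sd > 0]
            sd = sd[sd > 0]
        if sub.shape[1] < 2:
            raise ValueError(f"module {mid} has fewer than 2 usable members")
        z = (sub - sub.mean(axis=0)) / sd
        u, _, _ = np.linalg.svd(z, full_matrices=False)
        me = u[:, 0]
        sign = np.mean([bicor(z[:, j], me) for j in range(z.shape[1])])
        if sign < 0:
            me = -me
        mes[mid] = me
    return pd.DataFrame(mes, index=expr.index)


def merge_close_modules(
    partition: ModulePartition,
    expr: pd.DataFrame,
    me_diss_threshold: float = 0.25,
) -> ModulePartition:
    """Iteratively merge modules with near-identical eigenproteins.

    Module pairs whose eigenprotein correlation-dissimilarity (1 − Pearson
    r) falls strictly below the threshold are merged, closest pair first,
    recomputing eigenproteins after each merge until a fixed point. Labels
    are re-canonicalized (size order) at the end.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(labels=labels)
        mods = part.modules
        if len(mods) < 2 or me_diss_threshold <= 0:
            break
        mes = module_eigenproteins(expr, part)
        corr = np.corrcoef(mes[mods].to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= me_diss_threshold:
            break
        a, b = sorted((mods[i], mods[j]))
        labels[labels == b] = a
    return ModulePartition(labels=_canonical_labels(labels))


def module_membership(expr: pd.DataFrame, mes: pd.DataFrame) -> pd.DataFrame:
    """kME: biweight midcorrelation of every protein with every eigenprotein."""
    return bicor_cross(expr, mes)


def intramodular_connectivity(
    adjacency: pd.DataFrame, partition: ModulePartition
) -> tuple[pd.Series, pd.Series]:
    """Within-module connectivity and its max-standardized form.

    For protein i in module m, ``k_in_i`` sums the adjacency to the other
    members of m; ``k_hat_i = k_in_i / max_j k_in_j`` over the module, so
    the most connected member of every module scores exactly 1. Grey
    proteins are absent from the output; singleton modules are flagged
    (k_hat undefined).
    """
    k_in = {}
    k_hat = {}
    a = adjacency
    for mid in partition.modules:
        cols = partition.members(mid)
        sub = a.loc[cols, cols].to_numpy(dtype=float)
        k = sub.sum(axis=0) - np.diag(sub)
        kmax = k.max()
        if len(cols) < 2 or kmax == 0:
            warnings.warn(f"module {mid}: standardized connectivity undefined")
            for p, ki in zip(cols, k):
                k_in[p] = float(ki)
                k_hat[p] = float("nan")
            continue
        for p, ki in zip(cols, k):
            k_in[p] = float(ki)
            k_hat[p] = float(ki / kmax)
    return pd.Series(k_in, name="k_in"), pd.Series(k_hat, name="k_hat")


def build_network(
    log_expr: pd.DataFrame,
    candidates=tuple(range(1, 21)),
    r2_target: float = 0.8,
    min_module_size: int = 15,
    cut_height: float = 0.995,
    merge_threshold: float = 0.25,
    rescue_kme: float = 0.30,
) -> tuple[CorrelationNetwork, ModulePartition]:
    """Full chain: bicor → soft power → adjacency → TOM → modules → summaries.

    The unsigned network (adjacency |bicor|^β) is used so that both
    positively and negatively trait-correlated proteins can share a module.
    After the static cut, near-duplicate modules are merged and unassigned
    proteins with clear module membership are rescued by kME (see
    :func:`rescue_unassigned`; set ``rescue_kme`` above 1 to disable).
    Returns the network artifacts and a partition populated with
    eigenproteins, kME and intramodular connectivity.
    """
    cor = bicor_matrix(log_expr)
    beta, fit_table = pick_soft_power(cor, candidates=candidates, r2_target=r2_target)
    adjacency = np.abs(cor) ** beta
    np.fill_diagonal(adjacency.values, 1.0)
    tom = tom_similarity(adjacency)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    partition = detect_modules(
        diss, min_module_size=min_module_size, cut_height=cut_height
    )
    if partition.modules:
        partition = merge_close_modules(
            partition, log_expr, me_diss_threshold=merge_threshold
        )
        partition = rescue_unassigned(partition, log_expr, kme_threshold=rescue_kme)
        mes = module_eigenproteins(log_expr, partition)
        kme = module_membership(log_expr, mes)
        k_in, k_hat = intramodular_connectivity(adjacency, partition)
        partition = ModulePartition(
            labels=partition.labels, eigenproteins=mes, kme=kme,
            k_in=k_in, k_hat=k_hat,
        )
    connectivity = pd.Series(
        adjacency.to_numpy().sum(axis=0) - 1.0, index=adjacency.index, name="k"
    )
    net = CorrelationNetwork(
        cor=cor, power=beta, adjacency=adjacency, tom=tom,
        connectivity=connectivity, fit_table=fit_table,
    )
    return net, partition
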