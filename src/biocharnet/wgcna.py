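"""Weighted co-expression network analysis of OTU abundance profiles.

Implements the full keystone-taxa chain on an OTU table: standardisation
and outlier screening, soft-threshold selection by the scale-free topology
criterion, topological overlap (TOM), module detection on the TOM dendrogram,
module eigen-taxa, eigen-taxon merging, module-trait correlation, microbe
significance / taxon membership (MS/TM) hub classification, and lifting of
hub OTUs to hub genera.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta.  The
topological overlap between OTUs i and j is

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with k_i the connectivity of node i.  Modules are branches of the
average-linkage dendrogram of 1 - TOM: a static cut is refined by recursive
branch splitting (a branch is split when the relative gap between
cross-branch and within-branch dissimilarity exceeds a margin), weakly
connected members are pruned by intramodular connectivity, and modules whose
eigen-taxa are closer than ``merge_cut_height`` in correlation distance are
merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .community import OTUTable

GREY = 0  # label of unassigned OTUs


class WGCNAError(ValueError):
    pass


@dataclass
class WGCNAConfig:
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_fit_threshold: float = 0.9
    mean_connectivity_threshold: float = 10.0
    merge_cut_height: float = 0.25
    min_module_size: int = 5
    static_cut_height: float = 0.99
    split_margin: float = 0.2          # relative gap required to split a branch
    prune_fraction: float = 0.4        # member kIM below this x module median -> grey
    reassign_fraction: float = 0.8     # grey adoption: mean TOM vs module within-mean
    ms_threshold: float = 0.6
    tm_threshold: float = 0.9
    correlation: str = "pearson"       # or "spearman"
    outlier_cut_height: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.merge_cut_height <= 1) or not (0 < self.static_cut_height <= 1):
            raise WGCNAError("cut heights must lie in (0, 1]")
        if any(p < 1 for p in self.powers):
            raise WGCNAError("candidate powers must be positive integers")
        if self.correlation not in ("pearson", "spearman"):
            raise WGCNAError("correlation must be 'pearson' or 'spearman'")


@dataclass
class ModuleAssignment:
    """OTU -> module labels with per-module eigen-taxa.

    ``labels`` maps each OTU to an integer module id (0 = grey/unassigned);
    ``eigentaxa`` holds one unit-variance, zero-mean sample-score vector per
    module; ``explained`` the fraction of module variance its eigen-taxon
    captures.
    """

    labels: pd.Series
    eigentaxa: pd.DataFrame = field(default_factory=pd.DataFrame)
    explained: dict[int, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != GREY)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    table: OTUTable, config: WGCNAConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Standardise abundances and screen outlier samples.

    Zero-count OTUs are removed; abundances become ln(relative x 1e6 + 1),
    then each OTU profile is z-scored.  Samples are clustered (average
    linkage, Euclidean); with ``outlier_cut_height`` set, samples outside the
    largest cluster at that height are dropped.
    """
    config = config or WGCNAConfig()
    counts = table.counts
    zero = counts.index[counts.sum(axis=1) == 0]
    counts = counts.drop(index=zero)
    rel = counts / counts.sum(axis=0)
    logged = np.log(rel * 1e6 + 1.0)

    dropped_samples: list[str] = []
    if config.outlier_cut_height is not None and logged.shape[1] > 2:
        z = average(pdist(logged.to_numpy().T, metric="euclidean"))
        cl = fcluster(z, t=config.outlier_cut_height, criterion="distance")
        sizes = pd.Series(cl).value_counts()
        keep_cluster = sizes.idxmax()
        dropped_samples = [
            s for s, c in zip(logged.columns, cl) if c != keep_cluster
        ]
        logged = logged.drop(columns=dropped_samples)
    if logged.shape[1] < 4:
        raise WGCNAError("fewer than 4 samples remain; correlations unstable")

    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise WGCNAError(
            f"constant OTU profile(s): {list(logged.index[sd == 0])[:5]}"
        )
    z = logged.sub(mu, axis=0).div(sd, axis=0)
    report = {"dropped_otus": list(zero), "dropped_samples": dropped_samples}
    return z, report


def _correlation(matrix: pd.DataFrame, kind: str) -> np.ndarray:
    x = matrix.to_numpy()
    if kind == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    c = np.corrcoef(x)
    if np.any(~np.isfinite(c)):
        raise WGCNAError("undefined correlation (constant OTU profile)")
    return c


# ---------------------------------------------------------------------------
# soft threshold

def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned (~``n_bins`` bins); log10 p(k) is regressed on
    log10 of the bin-mean connectivity.  Returns (signed fit index, slope):
    the fit is sign-flipped when the slope is positive, as a rising degree
    distribution is the opposite of scale-free topology.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    pk, mk = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        pk.append(mask.mean())
        mk.append(k[mask].mean())
    if len(pk) < 3:
        return 0.0, 0.0
    res = stats.linregress(np.log10(mk), np.log10(pk))
    fit = float(res.rvalue**2)
    if res.slope > 0:
        fit = -fit
    return fit, float(res.slope)


def pick_soft_threshold(
    matrix: pd.DataFrame, config: WGCNAConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    The chosen power is the smallest with fit index above the threshold AND
    mean connectivity above the connectivity floor; when no power satisfies
    both, the power maximising the fit among those meeting the connectivity
    floor is returned with a warning (falling back to all powers if none do).
    """
    config = config or WGCNAConfig()
    corr = np.abs(_correlation(matrix, config.correlation))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in config.powers:
        adj = corr**beta
        k = adj.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append(
            {"power": beta, "fit": fit, "slope": slope,
             "mean_connectivity": float(k.mean())}
        )
    tab = pd.DataFrame(rows).set_index("power")
    ok = tab[
        (tab["fit"] > config.scale_free_fit_threshold)
        & (tab["mean_connectivity"] > config.mean_connectivity_threshold)
    ]
    if len(ok):
        return int(ok.index.min()), tab
    eligible = tab[tab["mean_connectivity"] > config.mean_connectivity_threshold]
    if eligible.empty:
        eligible = tab
    beta = int(eligible["fit"].idxmax())
    warnings.warn(
        "no power reaches the scale-free fit and connectivity thresholds "
        f"simultaneously; using power {beta} (max fit subject to connectivity)",
        stacklevel=2,
    )
    return beta, tab


# ---------------------------------------------------------------------------
# adjacency and TOM

def adjacency(matrix: pd.DataFrame, beta: int, kind: str = "pearson") -> np.ndarray:
    corr = np.abs(_correlation(matrix, kind))
    adj = corr**beta
    np.fill_diagonal(adj, 0.0)
    return adj


def adjacency_tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an (unsigned, zero-diagonal) adjacency."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    shared = a @ a            # diagonal of a is zero, so u != i, j is automatic
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection

def _subtree_leaves(z: np.ndarray, node: int, n: int) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(int(z[v - n, 0]))
            stack.append(int(z[v - n, 1]))
    return out


def detect_modules(
    tom: np.ndarray, config: WGCNAConfig | None = None, otu_ids=None
) -> ModuleAssignment:
    """Branch-wise module detection on the TOM dendrogram.

    Average-linkage clustering of 1 - TOM is cut statically; each resulting
    branch is split recursively wherever the relative dissimilarity gap
    between sub-branches exceeds ``split_margin`` and both sub-branches hold
    at least ``min_module_size`` leaves.  Members whose mean within-module
    TOM falls below ``prune_fraction`` of the module median are released to
    grey; modules dropping below the size floor dissolve.  Labels are
    ordered by decreasing module size; grey is 0.
    """
    config = config or WGCNAConfig()
    n = tom.shape[0]
    if config.min_module_size > n:
        raise WGCNAError("min_module_size exceeds the number of OTUs")
    if otu_ids is None:
        otu_ids = [f"OTU{i}" for i in range(n)]
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    z = average(squareform(diss, checks=False))
    static = fcluster(z, t=config.static_cut_height, criterion="distance")

    parent = {}
    for i in range(z.shape[0]):
        parent[int(z[i, 0])] = n + i
        parent[int(z[i, 1])] = n + i

    def _branch_root(members: set[int]) -> int:
        v = next(iter(members))
        while set(_subtree_leaves(z, v, n)) != members:
            v = parent[v]
        return v

    def _split(node: int) -> list[list[int]]:
        if node < n:
            return [[node]]
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        ll, rl = _subtree_leaves(z, left, n), _subtree_leaves(z, right, n)
        if len(ll) >= config.min_module_size and len(rl) >= config.min_module_size:
            dw_l = diss[np.ix_(ll, ll)][np.triu_indices(len(ll), 1)].mean()
            dw_r = diss[np.ix_(rl, rl)][np.triu_indices(len(rl), 1)].mean()
            dw = (dw_l + dw_r) / 2.0
            dc = diss[np.ix_(ll, rl)].mean()
            if (dc - dw) / max(1e-12, 1.0 - dw) > config.split_margin:
                return _split(left) + _split(right)
        return [_subtree_leaves(z, node, n)]

    labels = np.zeros(n, dtype=int)
    next_id = 1
    for c in np.unique(static):
        members = set(np.flatnonzero(static == c).tolist())
        if len(members) < config.min_module_size:
            continue
        for branch in _split(_branch_root(members)):
            if len(branch) >= config.min_module_size:
                labels[np.array(branch)] = next_id
                next_id += 1

    # prune weakly connected members (intramodular connectivity)
    tom = np.asarray(tom, dtype=float)
    for m in range(1, next_id):
        idx = np.flatnonzero(labels == m)
        if idx.size < 3:
            continue
        kim = np.array([tom[i, idx[idx != i]].mean() for i in idx])
        labels[idx[kim < config.prune_fraction * np.median(kim)]] = GREY
    for m in range(1, next_id):
        if (labels == m).sum() < config.min_module_size:
            labels[labels == m] = GREY

    ordered = sorted(
        (m for m in np.unique(labels) if m != GREY),
        key=lambda m: -(labels == m).sum(),
    )
    relabel = {m: i for i, m in enumerate(ordered, start=1)}
    labels = np.array([relabel.get(v, GREY) for v in labels])
    return ModuleAssignment(labels=pd.Series(labels, index=otu_ids, name="module"))


# ---------------------------------------------------------------------------
# eigen-taxa

def module_eigentaxon(
    matrix: pd.DataFrame, assignment: ModuleAssignment
) -> ModuleAssignment:
    """First principal component of each module, as a unit-variance profile.

    The eigen-taxon sign is oriented so that its correlation with the
    module's mean abundance profile is positive.  A single-OTU module falls
    back to that OTU's standardised profile.
    """
    eigentaxa = {}
    explained = {}
    for m in assignment.modules:
        members = assignment.members(m)
        sub = matrix.loc[members].to_numpy()
        if sub.shape[0] == 1:
            e = sub[0].copy()
            explained[m] = 1.0
        else:
            _, s, vt = np.linalg.svd(sub, full_matrices=False)
            e = vt[0]
            explained[m] = float(s[0] ** 2 / (s**2).sum())
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        e = (e - e.mean()) / e.std()
        eigentaxa[m] = e
    assignment.eigentaxa = pd.DataFrame(eigentaxa, index=matrix.columns)
    assignment.explained = explained
    return assignment


def merge_modules(
    matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    merge_cut_height: float = 0.25,
) -> ModuleAssignment:
    """Merge modules whose eigen-taxa are closer than the cut height.

    Average-linkage clustering on eigen-taxon correlation distance (1 - cor)
    cut at ``merge_cut_height``; eigen-taxa are recomputed after each merge
    round until stable.
    """
    if assignment.eigentaxa.empty:
        assignment = module_eigentaxon(matrix, assignment)
    while True:
        mods = assignment.modules
        if len(mods) < 2:
            return assignment
        e = assignment.eigentaxa[mods].to_numpy().T
        diss = 1.0 - np.corrcoef(e)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        cl = fcluster(
            average(squareform(diss, checks=False)),
            t=merge_cut_height,
            criterion="distance",
        )
        if cl.max() == len(mods):
            return assignment
        labels = assignment.labels.copy()
        for new_id in range(1, cl.max() + 1):
            for mod, c in zip(mods, cl):
                if c == new_id:
                    labels[labels == mod] = new_id
        assignment = module_eigentaxon(
            matrix, ModuleAssignment(labels=labels)
        )


def reassign_grey(
    tom: np.ndarray, assignment: ModuleAssignment, fraction: float = 0.8
) -> ModuleAssignment:
    """Adopt grey OTUs into the module they are most connected to.

    A grey OTU joins its best module when its mean TOM to that module's
    members exceeds ``fraction`` of the module's mean within-module TOM.
    """
    labels = assignment.labels.copy()
    arr = labels.to_numpy()
    mods = assignment.modules
    if not mods:
        return assignment
    member_idx = {m: np.flatnonzero(arr == m) for m in mods}
    within = {
        m: tom[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].mean()
        for m, idx in member_idx.items()
    }
    for i in np.flatnonzero(arr == GREY):
        kim = {m: tom[i, idx].mean() for m, idx in member_idx.items()}
        best = max(kim, key=kim.get)
        if kim[best] > fraction * within[best]:
            arr[i] = best
    labels[:] = arr
    return ModuleAssignment(labels=labels)


# ---------------------------------------------------------------------------
# module-trait relationships

@dataclass
class ModuleTraitResult:
    table: pd.DataFrame            # per-module r and p
    keystone: int | None           # module with max |r|, significant
    significant: bool              # whether the keystone passed p < alpha


def module_trait_correlation(
    assignment: ModuleAssignment, trait: pd.Series, alpha: float = 0.05
) -> ModuleTraitResult:
    """Pearson correlation of each module eigen-taxon with a sample trait.

    p-values are two-sided from the Student-t transform with n - 2 degrees
    of freedom.  The keystone module is the one with the largest |r| whose p
    is below ``alpha``; when none is significant, the top-|r| module is
    reported as a candidate with a warning.
    """
    if assignment.eigentaxa.empty:
        raise WGCNAError("eigen-taxa not computed; call module_eigentaxon first")
    t = trait.reindex(assignment.eigentaxa.index)
    if t.isna().any():
        raise WGCNAError("trait vector does not cover all retained samples")
    if t.std() == 0:
        raise WGCNAError("trait is constant")
    rows = {}
    for m in assignment.modules:
        r, p = stats.pearsonr(assignment.eigentaxa[m], t)
        rows[m] = {"r": float(r), "p": float(p)}
    tab = pd.DataFrame.from_dict(rows, orient="index")
    if tab.empty:
        return ModuleTraitResult(tab, None, False)
    top = tab["r"].abs().idxmax()
    significant = bool(tab.loc[top, "p"] < alpha)
    if not significant:
        warnings.warn(
            f"no module-trait correlation significant at alpha={alpha}; "
            f"module {top} reported as candidate keystone",
            stacklevel=2,
        )
    return ModuleTraitResult(tab, int(top), significant)


def correlation_t_pvalue(r: float, n: int) -> float:
    """Two-sided p of a Pearson correlation via the Student-t transform."""
    df = n - 2
    t = abs(r) * np.sqrt(df / (1.0 - r**2))
    return float(2.0 * stats.t.sf(t, df))


# ---------------------------------------------------------------------------
# MS / TM and hub classification

ROLES = ("hub", "taxon_hub", "connector", "peripheral")


def classify_role(
    ms: float, tm: float, ms_threshold: float = 0.6, tm_threshold: float = 0.9
) -> str:
    """Four-way hub classification from microbe significance and |TM|."""
    high_ms = ms >= ms_threshold
    high_tm = abs(tm) >= tm_threshold
    if high_ms and high_tm:
        return "hub"
    if high_tm:
        return "taxon_hub"
    if high_ms:
        return "connector"
    return "peripheral"


def compute_ms_tm(
    matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    trait: pd.Series,
    module: int,
    config: WGCNAConfig | None = None,
) -> pd.DataFrame:
    """MS, TM and hub role for every OTU of one module.

    MS is the absolute Pearson correlation of the OTU profile with the
    trait; TM the signed correlation of the module eigen-taxon with the OTU
    profile.
    """
    config = config or WGCNAConfig()
    if module not in assignment.modules:
        raise WGCNAError(f"module {module} does not exist")
    if assignment.eigentaxa.empty:
        raise WGCNAError("eigen-taxa not computed; call module_eigentaxon first")
    e = assignment.eigentaxa[module]
    t = trait.reindex(matrix.columns)
    rows = {}
    for otu in assignment.members(module):
        x = matrix.loc[otu]
        ms = float(abs(stats.pearsonr(x, t)[0]))
        tm = float(stats.pearsonr(e, x)[0])
        rows[otu] = {
            "MS": ms,
            "TM": tm,
            "role": classify_role(ms, tm, config.ms_threshold, config.tm_threshold),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def hub_genera(records: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Lift OTU-level hub roles to the genus level.

    A genus is a hub genus when at least one member OTU is classified hub;
    genera are sorted by the maximum member MS x |TM| score.
    """
    from .community import OTUTable as _T  # reuse rank extraction

    def genus_of(lineage: str) -> str:
        for token in str(lineage).split(";"):
            token = token.strip()
            if token.startswith("g__"):
                return token[3:] or "unclassified"
        return "unclassified"

    hubs = records[records["role"] == "hub"]
    rows = {}
    for otu, rec in hubs.iterrows():
        g = genus_of(taxonomy.get(otu, ""))
        score = rec["MS"] * abs(rec["TM"])
        if g not in rows or score > rows[g]["score"]:
            rows[g] = {"score": score, "n_hub_otus": 0}
    for otu in hubs.index:
        rows[genus_of(taxonomy.get(otu, ""))]["n_hub_otus"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        return pd.DataFrame(columns=["score", "n_hub_otus"])
    return out.sort_values("score", ascending=False)


# ---------------------------------------------------------------------------
# orchestrated chain

@dataclass
class WGCNAResult:
    matrix: pd.DataFrame
    power: int
    power_table: pd.DataFrame | None
    tom: np.ndarray
    assignment: ModuleAssignment
    module_trait: ModuleTraitResult
    ms_tm: pd.DataFrame
    hub_genera: pd.DataFrame
    preprocess_report: dict


def run_wgcna(
    table: OTUTable,
    trait: pd.Series,
    config: WGCNAConfig | None = None,
    power: int | None = 6,
) -> WGCNAResult:
    """Run the full chain: preprocess -> TOM -> modules -> keystone -> hubs.

    ``power`` fixes the soft threshold (default 6); pass ``None`` to select
    it by the scale-free topology criterion.
    """
    config = config or WGCNAConfig()
    matrix, report = preprocess(table, config)
    power_table = None
    if power is None:
        power, power_table = pick_soft_threshold(matrix, config)
    adj = adjacency(matrix, power, config.correlation)
    tom = adjacency_tom(adj)
    assignment = detect_modules(tom, config, otu_ids=list(matrix.index))
    assignment = module_eigentaxon(matrix, assignment)
    assignment = merge_modules(matrix, assignment, config.merge_cut_height)
    assignment = reassign_grey(tom, assignment, config.reassign_fraction)
    assignment = module_eigentaxon(matrix, assignment)
    trait = trait.reindex(matrix.columns)
    mt = module_trait_correlation(assignment, trait)
    if mt.keystone is not None:
        records = compute_ms_tm(matrix, assignment, trait, mt.keystone, config)
        hubs = hub_genera(records, table.taxonomy)
    else:
        records = pd.DataFrame(columns=["MS", "TM", "role"])
        hubs = pd.DataFrame(columns=["score", "n_hub_otus"])
    return WGCNAResult(
        matrix=matrix,
        power=power,
        power_table=power_table,
        tom=tom,
        assignment=assignment,
        module_trait=mt,
        ms_tm=records,
        hub_genera=hubs,
        preprocess_report=report,
    )
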