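"""Community-level analysis of an OTU count table.

Covers alpha diversity (observed richness, Shannon, Simpson, Chao1, ACE,
Pielou evenness, Good's coverage), Bray-Curtis beta diversity, principal
coordinate analysis, a seeded PERMANOVA, and genus-level composition
summaries.  Alpha-diversity indices delegate to ``skbio.diversity.alpha``;
PCoA delegates to ``skbio.stats.ordination``.  PERMANOVA is implemented
here so the permutation stream is explicitly seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.ordination import pcoa as _skbio_pcoa

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))


class OTUTableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass
class OTUTable:
    """OTU x sample count matrix with taxonomy and treatment labels.

    ``counts`` rows are OTU ids, columns sample ids; ``taxonomy`` maps OTU id
    to a 7-rank greengenes-style lineage string; ``treatments`` maps sample
    id to its group label (e.g. ``NB``/``AB``).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    treatments: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise OTUTableError("duplicate OTU ids in count table")
        if self.counts.columns.has_duplicates:
            raise OTUTableError("duplicate sample ids in count table")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise OTUTableError("counts must be non-negative integers")
        missing_tax = self.counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise OTUTableError(f"taxonomy missing for OTU(s): {list(missing_tax)[:5]}")
        unlabeled = self.counts.columns.difference(self.treatments.index)
        if len(unlabeled):
            raise OTUTableError(f"unlabeled sample(s): {list(unlabeled)[:5]}")
        if (self.counts.sum(axis=0) == 0).any():
            raise OTUTableError("all-zero sample in count table")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        self.treatments = self.treatments.reindex(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def rank_labels(self, level: str = "genus") -> pd.Series:
        """Extract one taxonomic rank from the lineage strings."""
        if level not in RANKS:
            raise OTUTableError(f"unknown rank {level!r}; choose from {RANKS}")
        prefix = _RANK_PREFIX[level]

        def pick(lineage: str) -> str:
            for token in str(lineage).split(";"):
                token = token.strip()
                if token.startswith(prefix):
                    name = token[len(prefix):].strip()
                    return name if name else "unclassified"
            return "unclassified"

        return self.taxonomy.map(pick)

    def subset_samples(self, sample_ids) -> "OTUTable":
        sub = self.counts.loc[:, list(sample_ids)]
        return OTUTable(sub, self.taxonomy.copy(), self.treatments.loc[list(sample_ids)])


def load_otu_table(counts_path, taxonomy_path, labels_path) -> OTUTable:
    """Load an OTU table from TSV counts, TSV taxonomy and CSV labels.

    OTUs with zero total count are dropped (logged).  Formats: counts TSV with
    OTU ids in the first column and sample ids in the header; taxonomy TSV
    ``OTU_ID<TAB>lineage``; labels CSV with columns ``sample,treatment``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = pd.read_csv(
        taxonomy_path, sep="\t", index_col=0, header=None, names=["otu", "lineage"]
    )["lineage"]
    labels = pd.read_csv(labels_path, index_col=0).iloc[:, 0]
    zero = counts.index[counts.sum(axis=1) == 0]
    if len(zero):
        logger.info("dropping %d OTU(s) with zero total count", len(zero))
        counts = counts.drop(index=zero)
    return OTUTable(counts, tax, labels.astype(str))


# ---------------------------------------------------------------------------
# alpha diversity

def alpha_diversity(table: OTUTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample diversity indices.

    Shannon H = -sum p_i log p_i (log base configurable, natural log by
    default), Simpson = 1 - sum p_i^2, bias-corrected Chao1, ACE (rare-OTU
    cutoff 10), Pielou J = H/ln S, Good's coverage = 1 - F1/N.
    """
    rows = {}
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        if c.sum() <= 0:
            raise OTUTableError(f"sample {s} has zero total count")
        c = c[c > 0].astype(int)
        shannon_nat = float(skbio_alpha.shannon(c, base=np.e))
        try:
            ace = float(skbio_alpha.ace(c, rare_threshold=10))
        except ValueError:
            ace = np.nan  # ACE undefined when every rare taxon is a singleton
        rows[s] = {
            "Sobs": int(c.size),
            "Shannon": float(skbio_alpha.shannon(c, base=base)),
            "Simpson": float(skbio_alpha.simpson(c)),
            "Chao1": float(skbio_alpha.chao1(c, bias_corrected=True)),
            "ACE": ace,
            "Pielou": 1.0 if c.size == 1 else shannon_nat / np.log(c.size),
            "Goods_coverage": float(skbio_alpha.goods_coverage(c)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


# ---------------------------------------------------------------------------
# beta diversity / ordination / PERMANOVA

def bray_curtis(table: OTUTable) -> pd.DataFrame:
    """Bray-Curtis distance matrix on per-sample relative abundances."""
    rel = table.relative_abundance().to_numpy().T
    if rel.shape[0] < 2:
        raise OTUTableError("need at least 2 samples for a distance matrix")
    dm = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # samples x axes, positive-eigenvalue axes only
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # fractions of positive inertia


def pcoa(distance: pd.DataFrame) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues (possible for semi-metric distances such as
    Bray-Curtis) are reported but contribute no coordinate axes.
    """
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=d.shape[0])
    eig = np.asarray(res.eigvals, dtype=float)
    pos = eig > 1e-12
    coords = np.asarray(res.samples)[:, pos]
    prop = eig[pos] / eig[pos].sum()
    idx = list(distance.index) if isinstance(distance, pd.DataFrame) else None
    cdf = pd.DataFrame(
        coords, index=idx, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
    )
    return PCoAResult(cdf, eig, prop)


@dataclass
class PermanovaResult:
    statistic: float   # pseudo-F
    r_squared: float   # SS_between / SS_total
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    distance: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (Adonis) on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), label permutations
    drawn from a seeded generator.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    d = np.asarray(distance, dtype=float)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(distance.index).to_numpy()
    groups = np.asarray(labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    n, a = d.shape[0], uniq.size
    d2 = d**2
    ss_total, ss_within = _permanova_ss(d2, groups)
    ss_between = ss_total - ss_within

    def pseudo_f(ssw: float) -> float:
        return ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(ss_within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, ssw = _permanova_ss(d2, perm)
        if pseudo_f(ssw) >= f_obs:
            hits += 1
    return PermanovaResult(
        statistic=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# composition summaries

def top_genera_summary(
    table: OTUTable, level: str = "genus", k: int = 10
) -> dict[str, dict]:
    """Top-k taxa per treatment by mean relative abundance at one rank.

    Counts are aggregated by the rank label, converted to per-sample relative
    abundances, and averaged within each treatment.  The cumulative share is
    the sum of the k means.  Returns, per treatment, the mean-share Series
    (descending) and the cumulative share of the top k.
    """
    genus = table.rank_labels(level)
    agg = table.counts.groupby(genus).sum()
    rel = agg / agg.sum(axis=0)
    out: dict[str, dict] = {}
    for treat in pd.unique(table.treatments):
        cols = table.treatments.index[table.treatments == treat]
        means = rel[cols].mean(axis=1).sort_values(ascending=False)
        top = means.iloc[:k]
        out[str(treat)] = {
            "top": top,
            "cumulative_share": float(top.sum()),
        }
    return out
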