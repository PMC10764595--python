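"""Cecal ASV-table analysis: set overlap, composition, diversity, ordination.

Operates on an ASV (amplicon sequence variant) count table with semicolon-
delimited 7-rank taxonomy lineages and an HR/LR sample grouping. Provides the
group ASV-set comparison (shared / exclusive), relative abundance aggregated
at phylum or genus level, five alpha-diversity indices (observed richness,
base-2 Shannon, Gini–Simpson, bias-guarded Chao1, Pielou evenness), classical
PCoA on Bray–Curtis dissimilarities, and per-taxon HR-vs-LR differential
abundance.

Conventions: Shannon entropy is reported in bits (log base 2) so that Pielou
evenness is shannon/log2(observed); Simpson is the Gini–Simpson probability
1 - sum(p^2); Chao1 uses the bias-guarded form S + F1(F1-1)/(2(F2+1)), defined
even when doubletons are absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity

from . import stats as pstats

logger = logging.getLogger(__name__)

__all__ = [
    "AsvTable",
    "AlphaDiversity",
    "PcoaResult",
    "read_asv_table",
    "write_asv_table",
    "asv_sets",
    "relative_abundance",
    "alpha",
    "alpha_table",
    "alpha_group_compare",
    "rarefy",
    "pcoa_from_distances",
    "bray_curtis_pcoa",
    "differential_abundance",
]

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]


@dataclass
class AsvTable:
    """Samples x ASVs count matrix with taxonomy and HR/LR sample groups."""

    counts: pd.DataFrame            # rows = samples, columns = ASV ids
    taxonomy: pd.Series             # ASV id -> semicolon-delimited lineage
    groups: pd.Series | None = None  # sample id -> HR/LR

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[bad[0]]!r}, "
                f"ASV {self.counts.columns[bad[1]]!r}")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"ASVs without taxonomy: {list(missing[:5])}")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    def lineage_frame(self) -> pd.DataFrame:
        """Parse lineages into a 7-rank frame ('unclassified' fill)."""
        rows = {}
        for asv, lin in self.taxonomy.items():
            parts = [p.strip() for p in str(lin).split(";")]
            vals = []
            for i in range(len(RANKS)):
                v = parts[i] if i < len(parts) else ""
                if v.startswith(_PREFIXES[i]):
                    v = v[len(_PREFIXES[i]):]
                vals.append(v if v else "unclassified")
            rows[asv] = vals
        return pd.DataFrame.from_dict(rows, orient="index", columns=RANKS)

    def subset_samples(self, ids) -> "AsvTable":
        g = self.groups.loc[ids] if self.groups is not None else None
        return AsvTable(self.counts.loc[ids], self.taxonomy, g)


@dataclass(frozen=True)
class AlphaDiversity:
    """Within-sample diversity of one ASV count vector."""

    observed: int
    shannon: float   # bits
    simpson: float   # Gini–Simpson, in [0, 1]
    chao1: float
    pielou: float

    def as_dict(self) -> dict:
        return {"observed": self.observed, "shannon": self.shannon,
                "simpson": self.simpson, "chao1": self.chao1,
                "pielou": self.pielou}


def read_asv_table(path, groups: pd.Series | None = None,
                   transposed: bool = False) -> AsvTable:
    """Read an ASV TSV: ASV rows x sample columns plus a `taxonomy` column.

    ``transposed=True`` accepts a samples-as-rows orientation (taxonomy then
    arrives as the first data row is not supported; transposed input must
    still carry a taxonomy column after transposition is undone by the
    caller's writer — in practice this flag simply swaps rows/columns of the
    count block).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if "taxonomy" not in raw.columns:
        raise ValueError("missing required 'taxonomy' column")
    taxonomy = raw["taxonomy"].astype(str)
    block = raw.drop(columns=["taxonomy"])
    for col in block.columns:
        vals = pd.to_numeric(block[col], errors="coerce")
        if vals.isna().any():
            r = block.index[vals.isna().argmax()]
            raise ValueError(f"non-numeric count at ASV {r!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            r = block.index[(~np.isclose(vals, np.round(vals))).argmax()]
            raise ValueError(f"non-integer count at ASV {r!r}, sample {col!r}")
    block = block.astype(np.int64)
    counts = block if transposed else block.T
    counts.index.name = None
    counts.columns.name = None
    taxonomy.index.name = None
    return AsvTable(counts=counts, taxonomy=taxonomy, groups=groups)


def write_asv_table(table: AsvTable, path) -> None:
    """Write ASV rows x sample columns TSV with a final taxonomy column."""
    out = table.counts.T.copy()
    out["taxonomy"] = table.taxonomy
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def asv_sets(table: AsvTable) -> dict:
    """Shared / group-exclusive ASV counts (presence = any count > 0 in group)."""
    if table.groups is None:
        raise ValueError("sample groups required")
    groups = table.groups
    out = {}
    present = {}
    for g in sorted(groups.unique()):
        ids = groups.index[groups == g]
        if len(ids) == 0:
            raise ValueError(f"group {g!r} has no samples")
        present[g] = table.counts.loc[ids].sum(axis=0) > 0
    gs = list(present)
    if len(gs) != 2:
        raise ValueError(f"expected exactly 2 groups, got {gs}")
    a, b = gs
    out[f"exclusive_{a}"] = int((present[a] & ~present[b]).sum())
    out[f"exclusive_{b}"] = int((present[b] & ~present[a]).sum())
    out["shared"] = int((present[a] & present[b]).sum())
    out["total"] = int((present[a] | present[b]).sum())
    return out


def relative_abundance(table: AsvTable, level: str = "phylum") -> pd.DataFrame:
    """Per-sample proportions aggregated at a taxonomic level.

    Unclassified lineages are labelled '<parent rank> unclassified' (e.g.
    'Barnesiellaceae unclassified'). Columns are ordered by overall mean
    abundance, most abundant first. Zero-depth samples are excluded with a
    log entry rather than producing NaN rows.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}")
    lin = table.lineage_frame()
    rank_i = RANKS.index(level)
    labels = []
    for asv, row in lin.iterrows():
        name = row[level]
        if name == "unclassified":
            parent = next((row[RANKS[j]] for j in range(rank_i - 1, -1, -1)
                           if row[RANKS[j]] != "unclassified"), "root")
            name = f"{parent} unclassified"
        labels.append(name)
    agg = table.counts.T.groupby(pd.Index(labels, name=level)).sum().T
    depth = agg.sum(axis=1)
    if (depth == 0).any():
        dropped = list(agg.index[depth == 0])
        logger.warning("excluding zero-depth samples: %s", dropped)
        agg = agg.loc[depth > 0]
        depth = depth.loc[depth > 0]
    props = agg.div(depth, axis=0)
    return props[props.mean(axis=0).sort_values(ascending=False).index]


def alpha(counts) -> AlphaDiversity:
    """Alpha diversity of a single sample's ASV counts.

    observed = number of nonzero ASVs; shannon = -sum p log2 p (bits);
    simpson = 1 - sum p^2; chao1 = S + F1(F1-1)/(2(F2+1)) from singleton and
    doubleton counts; pielou = shannon / log2(observed).
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero sample has no defined diversity")
    p = c / c.sum()
    observed = int(c.size)
    shannon = float(-(p * np.log2(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    pielou = shannon / np.log2(observed) if observed > 1 else np.nan
    return AlphaDiversity(observed, shannon, simpson, float(chao1), float(pielou))


def alpha_table(table: AsvTable) -> pd.DataFrame:
    """Five alpha indices per sample."""
    rows = {s: alpha(table.counts.loc[s].to_numpy()).as_dict()
            for s in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


def alpha_group_compare(table: AsvTable) -> pd.DataFrame:
    """Per-index HR-vs-LR pooled t comparison in mean ± SD table shape."""
    if table.groups is None:
        raise ValueError("sample groups required")
    at = alpha_table(table)
    gs = sorted(table.groups.unique())
    if len(gs) != 2:
        raise ValueError(f"expected 2 groups, got {gs}")
    a, b = ("HR", "LR") if set(gs) == {"HR", "LR"} else gs
    rows = []
    for index_name in at.columns:
        xa = at.loc[table.groups.index[table.groups == a], index_name]
        xb = at.loc[table.groups.index[table.groups == b], index_name]
        cmp_ = pstats.t_from_summary(pstats.GroupSummary.from_sample(xa),
                                     pstats.GroupSummary.from_sample(xb))
        rows.append({
            "index": index_name,
            f"mean_{a}": xa.mean(), f"sd_{a}": xa.std(ddof=1), f"n_{a}": len(xa),
            f"mean_{b}": xb.mean(), f"sd_{b}": xb.std(ddof=1), f"n_{b}": len(xb),
            "sem": cmp_.sem_pooled, "t": cmp_.t, "df": cmp_.df, "p": cmp_.p,
        })
    return pd.DataFrame(rows).set_index("index")


def rarefy(table: AsvTable, depth: int | None = None,
           rng: np.random.Generator | None = None) -> AsvTable:
    """Subsample every sample to equal depth without replacement."""
    rng = rng or np.random.default_rng(0)
    depths = table.counts.sum(axis=1)
    depth = int(depths.min()) if depth is None else int(depth)
    if (depths < depth).any():
        shallow = list(depths.index[depths < depth])
        raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
    new = {}
    for s in table.sample_ids:
        row = table.counts.loc[s].to_numpy()
        pool = np.repeat(np.arange(row.size), row)
        pick = rng.choice(pool, size=depth, replace=False)
        new[s] = np.bincount(pick, minlength=row.size)
    counts = pd.DataFrame(new, index=table.counts.columns).T
    return AsvTable(counts, table.taxonomy, table.groups)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # samples x axes (PC1, PC2, ...)
    eigvals: np.ndarray              # all eigenvalues, negatives included
    proportion_explained: np.ndarray
    distances: pd.DataFrame


def pcoa_from_distances(dist: pd.DataFrame) -> PcoaResult:
    """Classical (Gower) PCoA of a square symmetric dissimilarity matrix.

    Eigendecomposition of the double-centered squared-distance matrix
    ``-0.5 * J D^2 J``. All eigenvalues are reported, negatives included
    (non-Euclidean dissimilarities such as Bray–Curtis can produce them);
    coordinate axes are built from the positive eigenvalues only.
    Proportion explained uses the positive-eigenvalue total. Axis signs are
    fixed by making each axis's largest-magnitude coordinate positive, so
    output is deterministic.
    """
    ids = list(dist.index)
    n = len(ids)
    d = dist.to_numpy(float)
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, vecs = eigvals[order], vecs[:, order]
    pos = eigvals > 1e-12
    coords = vecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):
        if coords[np.abs(coords[:, k]).argmax(), k] < 0:
            coords[:, k] = -coords[:, k]
    pos_total = eigvals[pos].sum()
    prop = (np.where(pos, eigvals, 0.0) / pos_total if pos_total > 0
            else np.zeros_like(eigvals))
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"PC{k + 1}" for k in range(coords.shape[1])])
    return PcoaResult(coordinates=frame, eigvals=eigvals,
                      proportion_explained=prop, distances=dist)


def bray_curtis_pcoa(table: AsvTable) -> PcoaResult:
    """Classical PCoA of Bray–Curtis dissimilarities on relative abundances."""
    if len(table.sample_ids) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    props = table.counts.div(table.counts.sum(axis=1), axis=0)
    dm: DistanceMatrix = beta_diversity("braycurtis", props.to_numpy(),
                                        ids=table.sample_ids)
    dist = pd.DataFrame(dm.data, index=table.sample_ids,
                        columns=table.sample_ids)
    return pcoa_from_distances(dist)


def differential_abundance(props: pd.DataFrame, groups: pd.Series,
                           method: str = "wilcoxon",
                           bh_correct: bool = False) -> pd.DataFrame:
    """Per-taxon two-group test on proportions with direction and stars.

    ``method='wilcoxon'`` (default, robust for n=8 compositions) or ``'t'``.
    ``direction`` is the group whose mean proportion is larger. Taxa absent
    from all samples are skipped with a log entry. Benjamini–Hochberg
    correction available but off by default.
    """
    common = props.index.intersection(groups.index)
    props = props.loc[common]
    groups = groups.loc[common]
    gs = sorted(groups.unique())
    if len(gs) != 2:
        raise ValueError(f"expected 2 groups, got {gs}")
    a, b = ("HR", "LR") if set(gs) == {"HR", "LR"} else gs
    rows = []
    for taxon in props.columns:
        xa = props.loc[groups == a, taxon].to_numpy(float)
        xb = props.loc[groups == b, taxon].to_numpy(float)
        if xa.sum() == 0 and xb.sum() == 0:
            logger.info("taxon %r absent from all samples; skipped", taxon)
            continue
        if method == "wilcoxon":
            stat, p = pstats.wilcoxon_rank_sum(xa, xb)
        elif method == "t":
            cmp_ = pstats.t_raw(xa, xb)
            stat, p = cmp_.t, cmp_.p
        else:
            raise ValueError("method must be 'wilcoxon' or 't'")
        diff = xa.mean() - xb.mean()
        rows.append({"taxon": taxon, "statistic": stat, "p": p,
                     "mean_" + a: xa.mean(), "mean_" + b: xb.mean(),
                     "direction": a if diff > 0 else (b if diff < 0 else "none")})
    out = pd.DataFrame(rows).set_index("taxon")
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = out["p_adj"].map(pstats.stars)
    else:
        out["stars"] = out["p"].map(pstats.stars)
    return out
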