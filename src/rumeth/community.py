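"""Rumen microbial community comparison from an OTU count table.

Filtering, relative abundances, archaeal clade profiles, alpha diversity
(Shannon in bits, Pielou evenness), Bray-Curtis / Jaccard dissimilarity,
principal coordinate analysis, permutational MANOVA and run-blocked
per-feature tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import (
    IncompleteBlockError,
    InvalidGroupingError,
    InvalidParameterError,
    UndefinedDistanceError,
    UndefinedDiversityError,
    UndefinedProportionError,
)

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {"domain": ("d__", "k__"), "phylum": ("p__",), "class": ("c__",),
                  "order": ("o__",), "family": ("f__",), "genus": ("g__",),
                  "species": ("s__",)}

#: Default mapping of archaeal species patterns (matched case-insensitively
#: against the taxonomy string) to clades.
DEFAULT_CLADE_MAP = {
    "ruminantium": "RO",
    "olleyae": "RO",
    "smithii": "SGMT",
    "gottschalkii": "SGMT",
    "millerae": "SGMT",
    "thaueri": "SGMT",
    "methanosphaera": "Methanosphaera",
    "methanomassiliicoccales": "Methanomassiliicoccales",
    "methanomethylophilaceae": "Methanomassiliicoccales",
}

CLADES = ("RO", "SGMT", "Methanosphaera", "Methanomassiliicoccales", "other")


@dataclass
class OtuTable:
    """Sample x OTU counts with per-sample metadata and OTU taxonomy.

    ``counts`` is indexed by sample id with OTU ids as columns; ``metadata``
    is indexed by sample id and carries at least ``emitter`` and ``run``;
    ``taxonomy`` maps OTU id to a rank-delimited lineage string.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InvalidParameterError("counts must be nonnegative")
        missing_meta = set(self.counts.index) - set(self.metadata.index)
        if missing_meta:
            raise InvalidParameterError(f"samples without metadata: {sorted(missing_meta)}")
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise InvalidParameterError(
                f"OTUs without taxonomy: {sorted(missing_tax)[:5]} ..."
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarities with a zero diagonal."""

    data: np.ndarray
    ids: list

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n) or n != len(self.ids):
            raise InvalidParameterError("distance matrix must be square and match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise InvalidParameterError("distance matrix diagonal must be zero")


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # sample x axis, positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over the sum of positive eigenvalues


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: object = None


def parse_rank(lineage: str, rank: str) -> str:
    """Extract one rank label from a semicolon-delimited lineage string."""
    if rank not in RANKS:
        raise InvalidParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
    prefixes = _RANK_PREFIXES[rank]
    for part in str(lineage).split(";"):
        part = part.strip()
        for pref in prefixes:
            if part.lower().startswith(pref):
                label = part[len(pref):].strip()
                return label if label else "unclassified"
    return "unclassified"


def filter_otus(table: OtuTable, min_reads: int = 30, min_samples: int = 3) -> OtuTable:
    """Retain OTUs with >= min_reads in at least min_samples samples."""
    keep = (table.counts >= min_reads).sum(axis=0) >= min_samples
    kept = table.counts.loc[:, keep]
    return OtuTable(counts=kept, metadata=table.metadata,
                    taxonomy=table.taxonomy.loc[kept.columns])


def relative_abundance(table: OtuTable, rank: str = "phylum") -> pd.DataFrame:
    """Per-sample proportions aggregated at a taxonomic rank; rows sum to 1."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise UndefinedProportionError(
            f"samples with zero total counts: {list(zero.index)}"
        )
    labels = table.taxonomy.loc[table.counts.columns].map(lambda s: parse_rank(s, rank))
    agg = table.counts.T.groupby(labels.values).sum().T
    return agg.div(totals, axis=0)


def is_archaeal(lineage: str) -> bool:
    return "archaea" in str(lineage).lower()


def archaeal_profile(table: OtuTable, clade_map: dict = None) -> pd.DataFrame:
    """Per-sample clade proportions of the archaeal counts only.

    Samples with zero archaeal counts are excluded with a warning. Clades are
    assigned by case-insensitive substring match of the map's patterns
    against each archaeal OTU's taxonomy string; unmatched OTUs go to
    ``"other"``.
    """
    clade_map = DEFAULT_CLADE_MAP if clade_map is None else clade_map
    arch_otus = [o for o in table.counts.columns if is_archaeal(table.taxonomy[o])]
    if not arch_otus:
        raise InvalidParameterError("no archaeal OTUs in the table")

    def assign(lineage: str) -> str:
        low = str(lineage).lower()
        for pattern, clade in clade_map.items():
            if pattern.lower() in low:
                return clade
        return "other"

    clades = pd.Series({o: assign(table.taxonomy[o]) for o in arch_otus})
    arch = table.counts[arch_otus]
    totals = arch.sum(axis=1)
    empty = totals[totals <= 0].index
    if len(empty):
        logger.warning("excluding %d sample(s) with zero archaeal counts: %s",
                       len(empty), list(empty))
        arch = arch.drop(index=empty)
        totals = totals.drop(index=empty)
    agg = arch.T.groupby(clades.values).sum().T
    for clade in CLADES:
        if clade not in agg.columns:
            agg[clade] = 0.0
    return agg[list(CLADES)].div(totals, axis=0)


def alpha_diversity(counts) -> dict:
    """Observed OTUs, Shannon index (bits) and Pielou evenness of one sample."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise UndefinedDiversityError("alpha diversity undefined for an all-zero sample")
    p = counts[counts > 0] / total
    observed = int(p.size)
    shannon = float(-(p * np.log2(p)).sum())
    evenness = 0.0 if observed == 1 else shannon / np.log2(observed)
    return {"observed_otus": observed, "shannon": shannon, "evenness": evenness}


def beta_distance(table: OtuTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis or (presence/absence) Jaccard dissimilarities."""
    X = table.counts.values.astype(float)
    if X.shape[0] < 2:
        raise InvalidParameterError("need at least two samples")
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        ids = [table.counts.index[i] for i in zero_rows]
        raise UndefinedDistanceError(f"distance undefined between all-zero samples: {ids}")
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    else:
        raise InvalidParameterError(f"unsupported metric {metric!r}")
    return DistanceMatrix(squareform(d), list(table.counts.index))


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling: Gower double-centering of -d^2/2, eigendecomposition.

    Coordinates are returned for positive eigenvalues only; negative
    eigenvalues are reported uncorrected. Variance proportions are taken over
    the sum of positive eigenvalues.
    """
    n = d.data.shape[0]
    a = -0.5 * d.data ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    coord_df = pd.DataFrame(coords, index=d.ids,
                            columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return PcoaResult(coordinates=coord_df, eigenvalues=eigvals,
                      proportion_explained=proportion)


def _permanova_ss(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray):
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(d: DistanceMatrix, groups, n_permutations: int = 9999,
              seed=None) -> PermanovaResult:
    """Permutational MANOVA pseudo-F with seeded label permutations.

    p = (#{permuted F >= observed F} + 1) / (n_permutations + 1).
    """
    groups = np.asarray(list(groups))
    n = d.data.shape[0]
    if groups.size != n:
        raise InvalidParameterError("group labels must match the matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise InvalidGroupingError("need at least two groups")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise InvalidGroupingError(f"groups with fewer than two samples: {list(small)}")
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")

    d2 = d.data ** 2
    a = labels.size

    def pseudo_f(perm_groups):
        ss_total, ss_within = _permanova_ss(d2, perm_groups, labels)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if pseudo_f(groups[rng.permutation(n)]) >= f_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations, seed=seed)


def blocked_feature_test(features: pd.DataFrame, emitter, run) -> pd.DataFrame:
    """Per-feature two-way fixed-effects test: value ~ emitter + run.

    Requires a complete low/high pair in every run (one observation per
    cell). The emitter F statistic is on (1, n_runs - 1) degrees of freedom
    and equals the square of the paired t statistic across runs. Returns raw
    and Benjamini-Hochberg adjusted p-values plus the high-minus-low effect.
    """
    emitter = np.asarray(list(emitter))
    run = np.asarray(list(run))
    if len(emitter) != len(features) or len(run) != len(features):
        raise InvalidParameterError("emitter and run must match the feature table")
    groups = np.unique(emitter)
    if groups.size != 2:
        raise InvalidParameterError(f"expected exactly two emitter groups, got {list(groups)}")
    runs = np.unique(run)
    for r in runs:
        present = set(emitter[run == r])
        if present != set(groups):
            raise IncompleteBlockError(f"run {r!r} is missing a cell (has {sorted(present)})")
        if np.sum(run == r) != 2:
            raise IncompleteBlockError(f"run {r!r} must have exactly one observation per cell")

    g_low, g_high = sorted(groups)
    n_runs = runs.size
    rows = []
    for col in features.columns:
        y = features[col].to_numpy(dtype=float)
        grand = y.mean()
        ss_e = n_runs * sum((y[emitter == g].mean() - grand) ** 2 for g in groups)
        ss_r = 2 * sum((y[run == r].mean() - grand) ** 2 for r in runs)
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = max(ss_tot - ss_e - ss_r, 0.0)
        df_err = n_runs - 1
        ms_err = ss_err / df_err
        f = np.inf if ms_err == 0 and ss_e > 0 else (0.0 if ms_err == 0 else ss_e / ms_err)
        p = float(stats.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
        effect = y[emitter == g_high].mean() - y[emitter == g_low].mean()
        rows.append({"feature": col, "F": f, "p": p, "effect_high_minus_low": effect})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
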