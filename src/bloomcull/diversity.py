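"""Evaluation battery: rarefaction, alpha diversity, Bray-Curtis/PCoA, and
the nested-filter sweeps that show what bloom removal buys.

Two sweeps mirror the downstream validation of bloom filtering:

* :func:`age_diversity_sweep` — at each nested filter depth k, rarefy, compute
  observed richness per sample, and Kruskal-Wallis-test richness across age
  categories.  A biological age-diversity signal that is masked by blooms at
  k = 0 should become significant once the dominant blooms are removed.

* :func:`cross_study_distance_sweep` — at each depth k, the mean Bray-Curtis
  distance between random cross-study sample pairs.  Shipped-vs-frozen
  distances should fall as blooms are removed; frozen-vs-frozen pairs should
  stay flat, showing the filter does not distort bloom-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .tables import FeatureTable, SampleMetadata, TaxonomyMap, ValidationError
from .detect import relative_frequencies
from .filtering import nested_filter

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "KWSweepRecord",
    "DistanceSweepRecord",
    "rarefy",
    "observed_richness",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "kruskal_wallis",
    "age_diversity_sweep",
    "cross_study_distance_sweep",
    "class_taxonomy_summary",
]


# ---------------------------------------------------------------------------
# rarefaction & alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped.  Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_rows: list[int] = []
    new_counts: list[np.ndarray] = []
    for i in range(table.n_samples):
        if totals[i] < depth:
            continue
        kept_rows.append(i)
        if totals[i] == depth:
            new_counts.append(table.counts[i].copy())
        else:
            new_counts.append(
                rng.multivariate_hypergeometric(table.counts[i], depth).astype(np.int64)
            )
    return FeatureTable(
        [table.sample_ids[i] for i in kept_rows],
        list(table.feature_ids),
        np.array(new_counts, dtype=np.int64).reshape(len(kept_rows), table.n_features),
    )


def observed_richness(sample_counts: np.ndarray) -> int:
    """Number of features with a nonzero count."""
    counts = np.asarray(sample_counts)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return int(np.count_nonzero(counts))


# ---------------------------------------------------------------------------
# Bray-Curtis & PCoA
# ---------------------------------------------------------------------------

def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|u - v| / sum(u + v), in [0, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if u.min(initial=0) < 0 or v.min(initial=0) < 0:
        raise ValueError("abundance vectors must be non-negative")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if d.min(initial=0) < 0:
            raise ValidationError("distances must be non-negative")
        self.data = d

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.data[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )


def distance_matrix(table: FeatureTable, normalize: bool = True) -> DistanceMatrix:
    """All-pairs Bray-Curtis on per-sample relative frequencies.

    ``normalize=False`` computes on raw counts instead (then distances depend
    on sequencing depth; frequencies are the meaningful default for
    compositional data).
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    if normalize:
        freq = relative_frequencies(table)
        ids, mat = freq.sample_ids, freq.frequencies
    else:
        ids, mat = list(table.sample_ids), table.counts.astype(np.float64)
    from scipy.spatial.distance import pdist, squareform

    condensed = pdist(mat, metric="braycurtis")
    dm = squareform(condensed)
    np.fill_diagonal(dm, 0.0)
    dm = (dm + dm.T) / 2.0
    return DistanceMatrix(ids, dm)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may include < 0)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal-coordinate analysis by classical metric scaling.

    Double-center ``-0.5 * D**2``, eigendecompose, and scale eigenvectors by
    the square roots of their (positive) eigenvalues.  Negative eigenvalues —
    which arise because Bray-Curtis is non-Euclidean — are reported but
    excluded from both the coordinates and the proportion-explained
    denominator.
    """
    d = dm.data
    n = d.shape[0]
    b = d ** 2
    b = -0.5 * (
        b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    )
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > max(1e-12 * abs(eigvals[0]), 0.0) if n else eigvals > 0
    n_pos = int(positive.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(np.maximum(eigvals[:n_axes], 0.0))
    pos_sum = eigvals[positive].sum()
    proportion = np.where(positive, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate case: when every value across all groups is identical there is
    no rank information and H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("Kruskal-Wallis requires total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class KWSweepRecord:
    depth: int
    h_statistic: float
    p_value: float
    neg_log10_p: float
    n_samples: int
    rarefaction_depth: int


@dataclass
class DistanceSweepRecord:
    depth: int
    study_a: str
    study_b: str
    mean_distance: float
    sd_distance: float
    n_pairs: int

    @property
    def se_distance(self) -> float:
        return self.sd_distance / np.sqrt(self.n_pairs)


def default_rarefaction_depth(
    table: FeatureTable, ranked_bloom_sequences: Sequence[str], fraction: float = 0.9
) -> int:
    """90% of the smallest sample total after filtering the full bloom list.

    Using the fully-filtered table fixes one depth that is attainable at every
    nested filter level, so richness values are comparable across the sweep.
    """
    fully = nested_filter(table, list(ranked_bloom_sequences), len(ranked_bloom_sequences))
    totals = fully.sample_totals()
    totals = totals[totals > 0]
    if totals.size == 0:
        raise ValidationError("all samples empty after full bloom filtering")
    return max(1, int(fraction * totals.min()))


def age_diversity_sweep(
    table: FeatureTable,
    metadata: SampleMetadata,
    ranked_bloom_sequences: Sequence[str],
    rarefaction_depth: int | None = None,
    seed: int = 0,
) -> list[KWSweepRecord]:
    """Kruskal-Wallis of rarefied observed richness across age categories, at
    every nested filter depth 0..K.

    The same rarefaction seed is used at every depth so that depth-to-depth
    differences reflect the filtering, not resampling noise.
    """
    metadata.require_samples(table.sample_ids)
    if "age_category" not in metadata.frame.columns:
        raise ValidationError("metadata lacks age_category")
    ages_all = metadata.column("age_category", table.sample_ids)
    if ages_all.dropna().nunique() < 2:
        raise ValidationError("need >= 2 age categories for the diversity sweep")
    if rarefaction_depth is None:
        rarefaction_depth = default_rarefaction_depth(table, ranked_bloom_sequences)

    records: list[KWSweepRecord] = []
    for k in range(len(ranked_bloom_sequences) + 1):
        filtered = nested_filter(table, list(ranked_bloom_sequences), k)
        rarefied = rarefy(filtered, rarefaction_depth, seed)
        ages = metadata.column("age_category", rarefied.sample_ids)
        richness = pd.Series(
            [observed_richness(rarefied.counts[i]) for i in range(rarefied.n_samples)],
            index=rarefied.sample_ids,
            dtype=float,
        )
        groups = [richness[ages == cat].to_numpy() for cat in sorted(ages.dropna().unique())]
        groups = [g for g in groups if g.size]
        if len(groups) < 2:
            raise ValidationError(
                f"fewer than 2 age categories survive rarefaction at depth {k}"
            )
        h, p = kruskal_wallis(groups)
        records.append(
            KWSweepRecord(
                depth=k,
                h_statistic=h,
                p_value=p,
                neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
                n_samples=rarefied.n_samples,
                rarefaction_depth=rarefaction_depth,
            )
        )
    return records


def cross_study_distance_sweep(
    merged_table: FeatureTable,
    metadata: SampleMetadata,
    ranked_bloom_sequences: Sequence[str],
    n_pairs: int = 1000,
    seed: int = 0,
    study_pairs: Sequence[tuple[str, str]] | None = None,
) -> list[DistanceSweepRecord]:
    """Mean Bray-Curtis over random cross-study sample pairs at each depth.

    For every study pair and depth k, ``n_pairs`` pairs are drawn with
    replacement using a per-depth seed (``seed + k``), and Bray-Curtis is
    computed on the filtered relative frequencies.  Sample pairs are re-drawn
    independently at each depth.
    """
    metadata.require_samples(merged_table.sample_ids)
    studies = metadata.column("study_id", merged_table.sample_ids)
    study_names = sorted(studies.dropna().unique())
    if len(study_names) < 2:
        raise ValueError("need >= 2 studies for a cross-study distance sweep")
    if study_pairs is None:
        study_pairs = [
            (a, b) for i, a in enumerate(study_names) for b in study_names[i + 1 :]
        ]

    records: list[DistanceSweepRecord] = []
    for k in range(len(ranked_bloom_sequences) + 1):
        filtered = nested_filter(merged_table, list(ranked_bloom_sequences), k)
        freq = relative_frequencies(filtered)
        row = {s: i for i, s in enumerate(freq.sample_ids)}
        rng = np.random.default_rng(seed + k)
        for a, b in study_pairs:
            rows_a = [row[s] for s in studies.index[studies == a] if s in row]
            rows_b = [row[s] for s in studies.index[studies == b] if s in row]
            if not rows_a or not rows_b:
                import warnings

                warnings.warn(
                    f"study pair ({a}, {b}) skipped at depth {k}: no surviving samples",
                    stacklevel=2,
                )
                continue
            ia = rng.choice(rows_a, size=n_pairs, replace=True)
            ib = rng.choice(rows_b, size=n_pairs, replace=True)
            ua = freq.frequencies[ia]
            ub = freq.frequencies[ib]
            num = np.abs(ua - ub).sum(axis=1)
            den = (ua + ub).sum(axis=1)
            dists = num / den
            records.append(
                DistanceSweepRecord(
                    depth=k,
                    study_a=a,
                    study_b=b,
                    mean_distance=float(dists.mean()),
                    sd_distance=float(dists.std(ddof=1)) if n_pairs > 1 else 0.0,
                    n_pairs=int(n_pairs),
                )
            )
    return records


# ---------------------------------------------------------------------------
# taxonomy summaries
# ---------------------------------------------------------------------------

def class_taxonomy_summary(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Per-study mean class-level frequency profile (studies x classes).

    Each sample's frequencies are summed by taxonomic class (features missing
    from the taxonomy contribute to "unclassified"); studies average their
    samples unweighted.  Rows sum to 1.
    """
    metadata.require_samples(table.sample_ids)
    freq = relative_frequencies(table)
    classes = [taxonomy.class_of(f) for f in freq.feature_ids]
    class_names = sorted(set(classes))
    col_of = {c: i for i, c in enumerate(class_names)}
    agg = np.zeros((len(freq.sample_ids), len(class_names)))
    idx = np.array([col_of[c] for c in classes], dtype=np.intp)
    np.add.at(agg.T, idx, freq.frequencies.T)

    studies = metadata.column("study_id", freq.sample_ids)
    per_sample = pd.DataFrame(agg, index=freq.sample_ids, columns=class_names)
    return per_sample.groupby(studies).mean()
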