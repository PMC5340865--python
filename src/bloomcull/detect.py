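"""Score sOTUs for room-temperature blooming and select bloom candidates.

Two complementary lines of evidence identify taxa that grow during
room-temperature storage or shipping:

* **Storage fold change** — within controlled storage studies, each subject
  contributes a frozen day-0 baseline and one or more room-temperature
  time-point samples.  For every feature and comparison we compute
  ``log2(c_t / c_0)`` on depth-normalized counts, with a 10-read detection
  floor: a comparison where both counts fall below the floor is excluded, and
  a single sub-floor count is clamped up to the floor so large blooms from
  near-zero baselines still receive a finite score.  A feature's storage score
  is the maximum fold change over all comparisons.

* **Cross-study fold change** — a shipped cohort is compared against several
  fresh-frozen cohorts sharing its feature space.  A feature's score is the
  minimum, over frozen cohorts, of (mean shipped frequency) / (mean frozen
  frequency), with a pseudo-frequency guarding empty denominators.  True
  blooms should be elevated against *every* frozen cohort, hence the minimum.

A feature is called a bloom candidate when (a) both scores clear a 2-fold
threshold, (b) its storage fold change alone is extreme (>= 50-fold), or
(c) it was never observed in the storage studies but clears the cross-study
threshold.  Candidates are ranked by a severity score: shipped-cohort mean
relative frequency weighted by the (log-compressed) cross-study fold change,
so abundant, strongly enriched blooms rank first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tables import (
    FROZEN,
    ROOM_TEMPERATURE,
    FeatureTable,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "FrequencyResult",
    "StorageFoldChange",
    "CrossStudyFoldChange",
    "BloomCandidate",
    "relative_frequencies",
    "storage_fold_changes",
    "cross_study_fold_changes",
    "select_candidates",
    "rank_candidates",
    "detect_blooms",
]

DEFAULT_READ_THRESHOLD = 10.0
DEFAULT_PSEUDO_FREQ = 1e-6
DEFAULT_T_CROSS = 2.0
DEFAULT_T_STORAGE = 2.0
DEFAULT_T_EXTREME = 50.0

BOTH_AXES = "both_axes"
STORAGE_EXTREME = "storage_extreme"
CROSS_ONLY = "cross_only"


@dataclass
class FrequencyResult:
    """Per-sample relative frequencies; zero-total samples are dropped."""

    sample_ids: list[str]
    feature_ids: list[str]
    frequencies: np.ndarray  # (n_kept_samples, n_features), rows sum to 1
    dropped_samples: list[str]


def relative_frequencies(table: FeatureTable) -> FrequencyResult:
    """Convert counts to per-sample relative frequencies.

    Samples with zero total reads cannot be normalized; they are dropped and
    recorded in ``dropped_samples`` rather than raising.
    """
    totals = table.sample_totals()
    keep = totals > 0
    freqs = table.counts[keep].astype(np.float64)
    freqs /= totals[keep, None]
    return FrequencyResult(
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
        feature_ids=list(table.feature_ids),
        frequencies=freqs,
        dropped_samples=[s for s, k in zip(table.sample_ids, keep) if not k],
    )


@dataclass
class StorageFoldChange:
    """Per-feature storage-study fold changes relative to the frozen baseline.

    ``log2fc`` maps (study_id, subject_id, day) -> log2 fold change for every
    non-excluded comparison.  ``max_fold`` is the linear-scale maximum over
    those, or None (ABSENT) when the feature was below the detection floor in
    every comparison.
    """

    feature_id: str
    log2fc: dict[tuple[str, str, float], float] = field(default_factory=dict)
    max_fold: float | None = None

    @property
    def absent(self) -> bool:
        return self.max_fold is None


def storage_fold_changes(
    table: FeatureTable,
    metadata: SampleMetadata,
    read_threshold: float = DEFAULT_READ_THRESHOLD,
    depth_normalize: bool = True,
) -> list[StorageFoldChange]:
    """Compute per-feature fold changes of room-temperature vs day-0 samples.

    For each subject, the frozen day-0 sample is the baseline; every
    room-temperature sample at day > 0 yields one comparison.  When
    ``depth_normalize`` is on, both samples' counts are rescaled to the
    smaller of the two totals before the threshold is applied, so the
    detection floor means the same thing at unequal depths.
    """
    metadata.require_samples(table.sample_ids)
    md = metadata.frame.loc[table.sample_ids]
    for col in ("subject_id", "day", "condition"):
        if col not in md.columns:
            raise ValidationError(f"storage metadata lacks required column {col!r}")

    results = [StorageFoldChange(feature_id=f) for f in table.feature_ids]
    max_log2 = np.full(table.n_features, -np.inf)
    any_included = np.zeros(table.n_features, dtype=bool)

    sample_row = {s: i for i, s in enumerate(table.sample_ids)}
    for (study, subject), group in md.groupby(["study_id", "subject_id"], sort=True):
        baseline_rows = group.index[(group["day"] == 0) & (group["condition"] == FROZEN)]
        if len(baseline_rows) == 0:
            raise ValidationError(
                f"subject {subject!r} in study {study!r} has no frozen day-0 baseline"
            )
        c0_raw = table.counts[sample_row[baseline_rows[0]]].astype(np.float64)
        rt = group[(group["day"] > 0) & (group["condition"] == ROOM_TEMPERATURE)]
        for sid, rec in rt.iterrows():
            ct_raw = table.counts[sample_row[sid]].astype(np.float64)
            c0, ct = c0_raw, ct_raw
            if depth_normalize:
                d0, dt = c0_raw.sum(), ct_raw.sum()
                target = min(d0, dt)
                if target == 0:
                    continue
                c0 = c0_raw * (target / d0)
                ct = ct_raw * (target / dt)
            excluded = (c0 < read_threshold) & (ct < read_threshold)
            c0c = np.maximum(c0, read_threshold)
            ctc = np.maximum(ct, read_threshold)
            lfc = np.log2(ctc / c0c)
            include = ~excluded
            day = float(rec["day"])
            for j in np.nonzero(include)[0]:
                results[j].log2fc[(str(study), str(subject), day)] = float(lfc[j])
            max_log2 = np.where(include, np.maximum(max_log2, lfc), max_log2)
            any_included |= include

    for j, r in enumerate(results):
        if any_included[j]:
            r.max_fold = float(2.0 ** max_log2[j])
    return results


@dataclass
class CrossStudyFoldChange:
    """Shipped-vs-frozen frequency fold change for one feature.

    ``min_fold`` is the minimum over frozen studies of
    ``target_freq / max(frozen_freq, pseudo_freq)``; features absent from the
    shipped cohort score 0.
    """

    feature_id: str
    target_freq: float
    frozen_freqs: dict[str, float]
    min_fold: float


def cross_study_fold_changes(
    target_table: FeatureTable,
    frozen_tables: Mapping[str, FeatureTable],
    pseudo_freq: float = DEFAULT_PSEUDO_FREQ,
) -> list[CrossStudyFoldChange]:
    """Score features by shipped-cohort enrichment against every frozen cohort.

    Tables must share a feature space (merge them first when read lengths
    differ); features missing from a frozen table are treated as frequency 0
    there, hence guarded by ``pseudo_freq``.
    """
    if not frozen_tables:
        raise ValueError("cross_study_fold_changes requires at least one frozen table")
    if pseudo_freq <= 0:
        raise ValueError("pseudo_freq must be positive")

    target_freq = _mean_frequencies(target_table)
    frozen_means: dict[str, np.ndarray] = {}
    for name, ftab in frozen_tables.items():
        means = _mean_frequencies(ftab)
        # map onto the target's feature order; absent features -> 0
        idx = {f: i for i, f in enumerate(ftab.feature_ids)}
        aligned = np.zeros(target_table.n_features)
        for j, f in enumerate(target_table.feature_ids):
            if f in idx:
                aligned[j] = means[idx[f]]
        frozen_means[name] = aligned

    out: list[CrossStudyFoldChange] = []
    for j, fid in enumerate(target_table.feature_ids):
        tf = float(target_freq[j])
        ffs = {name: float(v[j]) for name, v in frozen_means.items()}
        if tf == 0.0:
            min_fold = 0.0
        else:
            min_fold = min(tf / max(v, pseudo_freq) for v in ffs.values())
        out.append(CrossStudyFoldChange(fid, tf, ffs, float(min_fold)))
    return out


def _mean_frequencies(table: FeatureTable) -> np.ndarray:
    freq = relative_frequencies(table)
    if freq.frequencies.shape[0] == 0:
        raise ValidationError("table has no samples with nonzero total")
    return freq.frequencies.mean(axis=0)


@dataclass
class BloomCandidate:
    """One selected bloom sequence with its scores, criterion and rank."""

    feature_id: str
    sequence: str
    max_storage_fold: float | None  # None = not observed in storage studies
    min_cross_fold: float
    criterion: str  # both_axes | storage_extreme | cross_only
    severity: float = float("nan")
    rank: int | None = None


def select_candidates(
    storage_fcs: Sequence[StorageFoldChange],
    cross_fcs: Sequence[CrossStudyFoldChange],
    t_cross: float = DEFAULT_T_CROSS,
    t_storage: float = DEFAULT_T_STORAGE,
    t_extreme: float = DEFAULT_T_EXTREME,
    sequences: Mapping[str, str] | None = None,
) -> list[BloomCandidate]:
    """Apply the three-way selection rule over the shared feature space.

    A feature is selected iff:

    * ``max_storage_fold >= t_storage`` and ``min_cross_fold >= t_cross``
      (criterion ``both_axes``), or
    * ``max_storage_fold >= t_extreme`` (criterion ``storage_extreme``), or
    * the feature is absent from the storage studies and
      ``min_cross_fold >= t_cross`` (criterion ``cross_only``).

    When both of the first two fire, ``both_axes`` is recorded.  Comparisons
    are inclusive (>=).  Features present in only one score list are treated
    as absent (storage) or zero (cross) in the other.
    """
    storage_by_id = {s.feature_id: s for s in storage_fcs}
    cross_by_id = {c.feature_id: c for c in cross_fcs}
    feature_ids = list(dict.fromkeys([*storage_by_id, *cross_by_id]))

    out: list[BloomCandidate] = []
    for fid in feature_ids:
        s = storage_by_id.get(fid)
        c = cross_by_id.get(fid)
        max_storage = None if (s is None or s.absent) else s.max_fold
        min_cross = 0.0 if c is None else c.min_fold
        criterion: str | None = None
        if max_storage is not None and max_storage >= t_storage and min_cross >= t_cross:
            criterion = BOTH_AXES
        elif max_storage is not None and max_storage >= t_extreme:
            criterion = STORAGE_EXTREME
        elif max_storage is None and min_cross >= t_cross:
            criterion = CROSS_ONLY
        if criterion is None:
            continue
        seq = sequences[fid] if sequences else fid
        out.append(
            BloomCandidate(
                feature_id=fid,
                sequence=seq,
                max_storage_fold=max_storage,
                min_cross_fold=min_cross,
                criterion=criterion,
            )
        )
    return out


def rank_candidates(
    candidates: Sequence[BloomCandidate],
    target_table: FeatureTable,
) -> list[BloomCandidate]:
    """Assign severity scores and 1-based ranks (most severe first).

    severity = (mean relative frequency in the shipped cohort)
             * log2(max(min_cross_fold, 1) + 1)

    so a bloom matters more the more of the shipped data it occupies and the
    more strongly it is enriched over frozen cohorts.  Ties break toward the
    lexicographically smaller sequence.
    """
    mean_freq = _mean_frequencies(target_table)
    freq_by_id = dict(zip(target_table.feature_ids, mean_freq))
    ranked = []
    for c in candidates:
        f = float(freq_by_id.get(c.feature_id, 0.0))
        sev = f * math.log2(max(c.min_cross_fold, 1.0) + 1.0)
        ranked.append(
            BloomCandidate(
                feature_id=c.feature_id,
                sequence=c.sequence,
                max_storage_fold=c.max_storage_fold,
                min_cross_fold=c.min_cross_fold,
                criterion=c.criterion,
                severity=sev,
            )
        )
    ranked.sort(key=lambda c: (-c.severity, c.sequence))
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def detect_blooms(
    target_table: FeatureTable,
    frozen_tables: Mapping[str, FeatureTable],
    storage_table: FeatureTable | None = None,
    storage_metadata: SampleMetadata | None = None,
    read_threshold: float = DEFAULT_READ_THRESHOLD,
    pseudo_freq: float = DEFAULT_PSEUDO_FREQ,
    t_cross: float = DEFAULT_T_CROSS,
    t_storage: float = DEFAULT_T_STORAGE,
    t_extreme: float = DEFAULT_T_EXTREME,
) -> list[BloomCandidate]:
    """Run the full detection pipeline and return ranked bloom candidates.

    The shipped (target) cohort and the frozen cohorts drive the cross-study
    axis; a controlled storage study, when supplied, drives the storage axis.
    All tables must already share a feature space.
    """
    cross = cross_study_fold_changes(target_table, frozen_tables, pseudo_freq)
    if storage_table is not None:
        if storage_metadata is None:
            raise ValueError("storage_table supplied without storage_metadata")
        storage = storage_fold_changes(storage_table, storage_metadata, read_threshold)
    else:
        storage = []
    selected = select_candidates(
        storage, cross, t_cross=t_cross, t_storage=t_storage, t_extreme=t_extreme
    )
    return rank_candidates(selected, target_table)


# ---------------------------------------------------------------------------
# artifact writers
# ---------------------------------------------------------------------------

def candidates_to_tsv(candidates: Sequence[BloomCandidate], path, header_lines=()) -> None:
    """Write ranked candidates as TSV (rank, ids, scores, criterion)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "rank\tfeature_id\tsequence\tcriterion\t"
            "max_storage_fold\tmin_cross_fold\tseverity\n"
        )
        for c in candidates:
            storage = "" if c.max_storage_fold is None else f"{c.max_storage_fold:.6g}"
            fh.write(
                f"{c.rank}\t{c.feature_id}\t{c.sequence}\t{c.criterion}\t"
                f"{storage}\t{c.min_cross_fold:.6g}\t{c.severity:.6g}\n"
            )


def candidates_to_fasta(candidates: Sequence[BloomCandidate], path) -> None:
    """Write candidate sequences as FASTA with rank-based headers."""
    from .tables import write_fasta

    write_fasta({f"bloom{c.rank}": c.sequence for c in candidates}, path)
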