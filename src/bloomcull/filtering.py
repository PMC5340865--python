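"""Remove exact-sequence matches to a bloom list from feature tables.

Matching is exact on the 5' prefix: a table feature matches a bloom when,
after trimming both sequences to the shorter of the two lengths, the strings
are identical.  No mismatches or indels are tolerated — the whole point of
sOTU-level filtering is that sequence identity is feature identity.

Filtering is destructive only for matched features; every surviving count is
bit-identical to the original.  The :class:`FilterReport` carries the removal
accounting (total reads removed, per-sample dropped fractions and their
quartiles) that characterizes how much of each sample was bloom-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .tables import FeatureTable

__all__ = ["FilterReport", "match_blooms", "filter_table", "nested_filter"]


@dataclass
class FilterReport:
    """Accounting of one filtering pass."""

    n_blooms_supplied: int
    n_matched_features: int
    reads_removed_total: int
    per_sample_dropped_fraction: dict[str, float]
    quartiles: tuple[float, float, float]  # p25, p50, p75 of dropped fractions
    matched_pairs: list[tuple[str, str]]  # (bloom_id, feature_id)
    empty_samples: list[str]  # samples reduced to zero total (kept, flagged)

    def quartiles_percent(self) -> tuple[float, float, float]:
        """Quartiles of per-sample dropped fractions, as percentages (1 dp)."""
        return tuple(round(100.0 * q, 1) for q in self.quartiles)  # type: ignore[return-value]


def match_blooms(
    feature_sequences: Mapping[str, str],
    bloom_sequences: Mapping[str, str],
) -> list[tuple[str, str]]:
    """Match table features against a bloom list by exact 5'-prefix identity.

    Parameters
    ----------
    feature_sequences :
        feature_id -> sequence for the table (for sequence-keyed tables,
        ``{f: f for f in table.feature_ids}``).
    bloom_sequences :
        bloom_id -> sequence.

    Returns
    -------
    list of (bloom_id, feature_id) pairs.  One bloom may match several
    features that share its trimmed prefix (e.g. length variants); all are
    returned, in bloom order then feature order.
    """
    if not bloom_sequences:
        raise ValueError("empty bloom list: filtering with nothing to filter")
    if not feature_sequences:
        raise ValueError("empty feature catalog")
    pairs: list[tuple[str, str]] = []
    for bloom_id, bloom_seq in bloom_sequences.items():
        bseq = bloom_seq.upper()
        for fid, fseq in feature_sequences.items():
            fseq_u = fseq.upper()
            n = min(len(bseq), len(fseq_u))
            if n and bseq[:n] == fseq_u[:n]:
                pairs.append((bloom_id, fid))
    return pairs


def filter_table(
    table: FeatureTable, matched_ids: Sequence[str], n_blooms_supplied: int | None = None,
    matched_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Drop the matched features; report what was removed.

    Samples reduced to zero total are retained (and flagged in the report);
    dropping them is left to explicit downstream steps such as rarefaction,
    so meta-analysis bookkeeping never loses samples silently.
    """
    matched = set(matched_ids)
    unknown = matched - set(table.feature_ids)
    if unknown:
        raise ValueError(f"matched_ids not in table: {sorted(unknown)[:5]}")
    keep = [f for f in table.feature_ids if f not in matched]
    filtered = table.subset_features(keep)

    orig_totals = table.sample_totals()
    new_totals = filtered.sample_totals()
    removed_per_sample = orig_totals - new_totals
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(orig_totals > 0, removed_per_sample / orig_totals, 0.0)
    if len(frac):
        q25, q50, q75 = np.percentile(frac, [25, 50, 75])  # linear interpolation
    else:
        q25 = q50 = q75 = float("nan")
    report = FilterReport(
        n_blooms_supplied=(
            n_blooms_supplied if n_blooms_supplied is not None else len(matched)
        ),
        n_matched_features=len(matched),
        reads_removed_total=int(removed_per_sample.sum()),
        per_sample_dropped_fraction=dict(
            zip(table.sample_ids, (float(x) for x in frac))
        ),
        quartiles=(float(q25), float(q50), float(q75)),
        matched_pairs=list(matched_pairs) if matched_pairs is not None else [],
        empty_samples=[
            s for s, t0, t1 in zip(table.sample_ids, orig_totals, new_totals)
            if t0 > 0 and t1 == 0
        ],
    )
    return filtered, report


def filter_blooms(
    table: FeatureTable, bloom_sequences: Mapping[str, str]
) -> tuple[FeatureTable, FilterReport]:
    """Convenience: match a bloom list against a sequence-keyed table and filter."""
    pairs = match_blooms({f: f for f in table.feature_ids}, bloom_sequences)
    matched = [fid for _, fid in pairs]
    filtered, report = filter_table(
        table, matched, n_blooms_supplied=len(bloom_sequences), matched_pairs=pairs
    )
    return filtered, report


def nested_filter(
    table: FeatureTable,
    ranked_bloom_sequences: Sequence[str],
    k: int,
) -> FeatureTable:
    """Filter with only the top-``k`` blooms of a severity-ranked list.

    ``ranked_bloom_sequences`` is ordered most-severe first; ``k = 0`` returns
    the table unchanged, and ``k = len(list)`` equals filtering with the full
    list.  Depth ``k`` always removes a superset of the reads removed at
    ``k - 1``.
    """
    if not 0 <= k <= len(ranked_bloom_sequences):
        raise ValueError(
            f"filter depth {k} out of range 0..{len(ranked_bloom_sequences)}"
        )
    if k == 0:
        return table
    blooms = {f"bloom{i + 1}": s for i, s in enumerate(ranked_bloom_sequences[:k])}
    filtered, _ = filter_blooms(table, blooms)
    return filtered
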