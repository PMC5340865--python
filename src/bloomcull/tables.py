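"""Feature tables, sample metadata, sequences and taxonomy: containers and I/O.

The central container is :class:`FeatureTable`, a dense samples x features
matrix of non-negative integer read counts whose feature identifiers are, in
the usual sOTU workflow, the exact denoised 16S amplicon sequences themselves.
Tables round-trip through two serializations: the BIOM 2.1 HDF5 layout and the
classic tab-separated "#OTU ID" text table (features as rows).

Multi-study meta-analysis requires a shared feature space.  Because sOTUs from
a common primer share their 5' start, tables sequenced to different read
lengths are merged by trimming every sequence to the global minimum length,
keeping the 5' prefix, and summing counts of sequences that collide after
trimming.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyMap",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_taxonomy",
    "merge_tables",
]

_DNA_RE = re.compile(r"^[ACGTN]+$")

FROZEN = "frozen"
ROOM_TEMPERATURE = "room_temperature"
_CONDITIONS = {FROZEN, ROOM_TEMPERATURE}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids :
        Ordered, unique sample identifiers (rows).
    feature_ids :
        Ordered, unique feature identifiers (columns).  In sequence-keyed
        mode these are uppercase DNA strings and ARE the features.
    counts :
        ``(n_samples, n_features)`` array of non-negative integers.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples x features matrix")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac, _ = np.modf(counts.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer count {counts[r, c]!r} at sample "
                    f"{self.sample_ids[r]!r} (row {r}), feature column {c}"
                )
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count {counts[r, c]} at sample {self.sample_ids[r]!r} "
                f"(row {r}), feature column {c}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise ValidationError(f"duplicate feature IDs: {dupes[:5]}")
        self.counts = counts

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.sum())

    def sequence_keyed(self) -> bool:
        """True when every feature ID is a nonempty uppercase DNA string."""
        return all(bool(_DNA_RE.match(f)) for f in self.feature_ids)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return FeatureTable(list(sample_ids), list(self.feature_ids), self.counts[rows])

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = self.feature_index()
        cols = [idx[f] for f in feature_ids]
        return FeatureTable(list(self.sample_ids), list(feature_ids), self.counts[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        """Features-as-rows DataFrame (the BIOM TSV orientation)."""
        return pd.DataFrame(self.counts.T, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


@dataclass
class SampleMetadata:
    """Per-sample study / storage-condition / subject / day / age annotations."""

    frame: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("study_id",)
    KNOWN = ("study_id", "condition", "subject_id", "day", "age_category")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in metadata")
        if "condition" in self.frame.columns:
            cond = self.frame["condition"].dropna()
            bad = sorted(set(cond) - _CONDITIONS)
            if bad:
                raise ValidationError(f"unrecognized storage conditions: {bad}")

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, object]]) -> "SampleMetadata":
        df = pd.DataFrame(list(records))
        df = df.set_index("sample_id")
        if "condition" in df.columns:
            df["condition"] = df["condition"].map(_normalize_condition)
        if "day" in df.columns:
            df["day"] = pd.to_numeric(df["day"])
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def require_samples(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples missing metadata rows: {missing[:5]}")

    def column(self, name: str, sample_ids: Sequence[str]) -> pd.Series:
        self.require_samples(sample_ids)
        return self.frame.loc[list(sample_ids), name]

    def studies(self) -> list[str]:
        return sorted(self.frame["study_id"].dropna().unique())

    def samples_of_study(self, study_id: str) -> list[str]:
        return list(self.frame.index[self.frame["study_id"] == study_id])


def _normalize_condition(value: object) -> object:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return value
    text = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    if text in {"rt", "roomtemp", "room_temp"}:
        text = ROOM_TEMPERATURE
    if text and text not in _CONDITIONS:
        raise ValidationError(
            f"storage condition {value!r} not recognized (expected one of {sorted(_CONDITIONS)})"
        )
    return text or None


@dataclass
class TaxonomyMap:
    """feature_id -> Greengenes-style lineage ("k__...;p__...;c__...;...")."""

    lineages: dict[str, str]

    UNCLASSIFIED = "unclassified"

    def class_of(self, feature_id: str) -> str:
        """Extract the class rank; absent/blank ranks map to "unclassified"."""
        lineage = self.lineages.get(feature_id)
        if lineage is None:
            return self.UNCLASSIFIED
        for rank in lineage.split(";"):
            rank = rank.strip()
            if rank.startswith("c__"):
                name = rank[3:].strip()
                return name if name else self.UNCLASSIFIED
        return self.UNCLASSIFIED


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, format_hint: str | None = None) -> FeatureTable:
    """Read a feature table from BIOM 2.1 HDF5 or tab-separated text.

    ``format_hint`` may be ``"hdf5"``/``"biom"`` or ``"tsv"``; when omitted the
    format is sniffed (HDF5 files carry a magic signature).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        format_hint = "hdf5" if h5py.is_hdf5(str(path)) else "tsv"
    fmt = format_hint.lower()
    if fmt in {"hdf5", "biom", "h5"}:
        return _read_biom_hdf5(path)
    if fmt in {"tsv", "txt", "text"}:
        return _read_tsv(path)
    raise FormatError(f"unknown feature-table format hint {format_hint!r}")


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    format_hint: str | None = None,
    generated_by: str = "bloomcull",
) -> None:
    """Write a table in BIOM 2.1 HDF5 or TSV; the format defaults to the suffix."""
    path = Path(path)
    if format_hint is None:
        format_hint = "hdf5" if path.suffix.lower() in {".biom", ".h5", ".hdf5"} else "tsv"
    fmt = format_hint.lower()
    if fmt in {"hdf5", "biom", "h5"}:
        _write_biom_hdf5(table, path, generated_by)
    elif fmt in {"tsv", "txt", "text"}:
        _write_tsv(table, path, generated_by)
    else:
        raise FormatError(f"unknown feature-table format hint {format_hint!r}")


def _read_tsv(path: Path) -> FeatureTable:
    header: list[str] | None = None
    feature_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#") and not line.startswith("#OTU ID"):
                    continue  # comment / provenance line
                header = line.split("\t")
                if not header[0]:
                    raise FormatError(f"{path}:{lineno}: malformed header line: {line!r}")
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: row has {len(cells)} fields, header has {len(header)}"
                )
            feature_ids.append(cells[0])
            row: list[int] = []
            for col, cell in enumerate(cells[1:], start=1):
                value = float(cell)
                if value < 0 or value != int(value):
                    raise ValidationError(
                        f"{path}: invalid count {cell!r} at row {lineno} (feature "
                        f"{cells[0]!r}), column {col} ({header[col]!r}): counts must "
                        "be non-negative integers"
                    )
                row.append(int(value))
            rows.append(row)
    if header is None:
        raise FormatError(f"{path}: no header line found")
    sample_ids = header[1:]
    counts = np.array(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    return FeatureTable(sample_ids, feature_ids, counts.T)


def _write_tsv(table: FeatureTable, path: Path, generated_by: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# Constructed by {generated_by}\n")
        fh.write("\t".join(["#OTU ID", *table.sample_ids]) + "\n")
        for j, fid in enumerate(table.feature_ids):
            fh.write("\t".join([fid, *(str(c) for c in table.counts[:, j])]) + "\n")


_BIOM_URL = "http://biom-format.org"


def _write_biom_hdf5(table: FeatureTable, path: Path, generated_by: str) -> None:
    """Write the BIOM 2.1 HDF5 layout: CSR matrices grouped by both axes."""
    obs = sp.csr_matrix(table.counts.T.astype(np.float64))   # observations x samples
    samp = sp.csr_matrix(table.counts.astype(np.float64))    # samples x observations
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = _BIOM_URL
        h5.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        h5.attrs["generated-by"] = generated_by
        h5.attrs["creation-date"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        h5.attrs["shape"] = np.array([table.n_features, table.n_samples], dtype=np.int64)
        h5.attrs["nnz"] = int(obs.nnz)
        for group_name, ids, mat in (
            ("observation", table.feature_ids, obs),
            ("sample", table.sample_ids, samp),
        ):
            grp = h5.create_group(group_name)
            grp.create_dataset("ids", data=np.array(ids, dtype=str_dt))
            m = grp.create_group("matrix")
            m.create_dataset("data", data=mat.data.astype(np.float64))
            m.create_dataset("indices", data=mat.indices.astype(np.int32))
            m.create_dataset("indptr", data=mat.indptr.astype(np.int32))
            grp.create_group("metadata")
            grp.create_group("group-metadata")


def _read_biom_hdf5(path: Path) -> FeatureTable:
    with h5py.File(path, "r") as h5:
        try:
            feature_ids = [_as_str(x) for x in h5["observation/ids"][:]]
            sample_ids = [_as_str(x) for x in h5["sample/ids"][:]]
            m = h5["observation/matrix"]
            data = m["data"][:]
            indices = m["indices"][:]
            indptr = m["indptr"][:]
        except KeyError as exc:
            raise FormatError(f"{path}: not a BIOM 2.1 HDF5 file ({exc})") from exc
    mat = sp.csr_matrix((data, indices, indptr), shape=(len(feature_ids), len(sample_ids)))
    dense = np.asarray(mat.todense())
    frac, _ = np.modf(dense)
    if np.any(frac != 0) or dense.min(initial=0) < 0:
        r, c = np.argwhere((frac != 0) | (dense < 0))[0]
        raise ValidationError(
            f"{path}: invalid count {dense[r, c]} at feature {feature_ids[r]!r}, "
            f"sample {sample_ids[c]!r}"
        )
    return FeatureTable(sample_ids, feature_ids, dense.T.astype(np.int64))


def _as_str(x: object) -> str:
    return x.decode("utf-8") if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an insertion-ordered id -> uppercase sequence mapping.

    The record ID is the first whitespace-delimited token of the header.
    Duplicate IDs are an error.
    """
    catalog: dict[str, str] = {}
    dupes: list[str] = []
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        nonlocal current, chunks
        if current is not None:
            seq = "".join(chunks).upper()
            if not seq:
                raise FormatError(f"{path}: record {current!r} has an empty sequence")
            if not _DNA_RE.match(seq):
                raise ValidationError(
                    f"{path}: record {current!r} contains non-ACGTN characters"
                )
            if current in catalog:
                dupes.append(current)
            else:
                catalog[current] = seq
        current, chunks = None, []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0] if len(line) > 1 else ""
                if not current:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
    _flush()
    if dupes:
        raise FormatError(f"{path}: duplicate FASTA IDs: {sorted(set(dupes))}")
    return catalog


def write_fasta(catalog: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in catalog.items():
            fh.write(f">{name}\n")
            seq = seq.upper()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# metadata / taxonomy TSV
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "study_id": "study_id",
    "condition": "condition",
    "subject_id": "subject_id",
    "day": "day",
    "age_category": "age_category",
}


def _leading_comment_rows(path: str | Path) -> int:
    """Count leading full-line comments ("# ..."); a '#Header' line with no
    space (e.g. '#SampleID') is treated as the header, not a comment."""
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and (len(line) < 2 or not line[1].isalnum()):
                n += 1
            else:
                break
    return n


def read_metadata(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> SampleMetadata:
    """Read a per-sample metadata TSV.

    ``column_map`` maps canonical names (sample_id, study_id, condition,
    subject_id, day, age_category) to the file's column headers.  sample_id
    and study_id are required; everything else is optional.  Leading "# "
    comment lines are skipped.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, skiprows=_leading_comment_rows(path))
    df.columns = [c.lstrip("#") for c in df.columns]
    for canonical in ("sample_id", "study_id"):
        if cols[canonical] not in df.columns:
            raise FormatError(
                f"{path}: required metadata column {cols[canonical]!r} "
                f"(for {canonical}) is missing"
            )
    out = pd.DataFrame(index=df[cols["sample_id"]].astype(str))
    out.index.name = "sample_id"
    for canonical in ("study_id", "condition", "subject_id", "day", "age_category"):
        src = cols[canonical]
        if src in df.columns:
            out[canonical] = df[src].values
    if "condition" in out.columns:
        out["condition"] = out["condition"].map(_normalize_condition)
    if "day" in out.columns:
        out["day"] = pd.to_numeric(out["day"])
    return SampleMetadata(out)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=True)


def read_taxonomy(path: str | Path, column_map: Mapping[str, str] | None = None) -> TaxonomyMap:
    """Read a feature -> lineage TSV (columns feature_id, taxonomy by default)."""
    cols = {"feature_id": "feature_id", "taxonomy": "taxonomy"}
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, skiprows=_leading_comment_rows(path))
    df.columns = [c.lstrip("#") for c in df.columns]
    for canonical, src in cols.items():
        if src not in df.columns:
            raise FormatError(f"{path}: required taxonomy column {src!r} is missing")
    return TaxonomyMap(dict(zip(df[cols["feature_id"]], df[cols["taxonomy"]])))


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\ttaxonomy\n")
        for fid, lineage in taxonomy.lineages.items():
            fh.write(f"{fid}\t{lineage}\n")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_tables(
    tables: Sequence[FeatureTable],
    table_ids: Sequence[str] | None = None,
    trim_length: int | None = None,
) -> FeatureTable:
    """Merge tables into one feature space keyed by trimmed exact sequence.

    Every feature ID (an exact sequence) is trimmed to ``trim_length`` —
    defaulting to the global minimum sequence length across all tables —
    keeping the 5' prefix.  Counts of sequences that collide after trimming
    are summed within a sample.  Sample IDs colliding across tables are
    disambiguated by prefixing with the corresponding ``table_ids`` entry;
    a collision without ``table_ids`` is an error.
    """
    if not tables:
        raise ValueError("merge_tables requires at least one table")
    for t in tables:
        if not t.sequence_keyed():
            raise ValidationError("merge_tables requires sequence-keyed feature IDs")
    if trim_length is None:
        lengths = [len(f) for t in tables for f in t.feature_ids]
        trim_length = min(lengths) if lengths else 0

    # global trimmed-feature order: first appearance across tables
    merged_features: list[str] = []
    feat_pos: dict[str, int] = {}
    for t in tables:
        for f in t.feature_ids:
            key = f[:trim_length]
            if key not in feat_pos:
                feat_pos[key] = len(merged_features)
                merged_features.append(key)

    # resolve sample-ID collisions
    all_samples: list[str] = []
    seen: set[str] = set()
    collision = any(
        s in seen or seen.add(s)  # type: ignore[func-returns-value]
        for t in tables
        for s in t.sample_ids
    )
    if collision and table_ids is None:
        raise ValidationError(
            "sample-ID collision across tables and no table_ids supplied to prefix them"
        )
    sample_names: list[list[str]] = []
    for i, t in enumerate(tables):
        if collision:
            names = [f"{table_ids[i]}.{s}" for s in t.sample_ids]
        else:
            names = list(t.sample_ids)
        sample_names.append(names)
        all_samples.extend(names)
    if len(set(all_samples)) != len(all_samples):
        raise ValidationError(
            f"sample IDs still collide after prefixing: {_duplicates(all_samples)[:5]}"
        )

    counts = np.zeros((len(all_samples), len(merged_features)), dtype=np.int64)
    row = 0
    for t in tables:
        cols = np.array([feat_pos[f[:trim_length]] for f in t.feature_ids], dtype=np.intp)
        block = counts[row : row + t.n_samples]
        # scatter-add along the feature axis; repeated cols (trim collisions) sum
        np.add.at(block.T, cols, t.counts.T)
        row += t.n_samples
    return FeatureTable(all_samples, merged_features, counts)
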