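"""Synthetic storage-study and multi-cohort generators with planted blooms.

The generative model is deliberately the minimal compositional one:

* Each sample has baseline relative abundances drawn from a symmetric
  Dirichlet around a uniform profile.
* A small set of planted "bloom" features grows exponentially with time spent
  at room temperature: after ``t`` days a bloom's relative mass is multiplied
  by ``2**(rate * t)`` and the composition renormalized, so one bloom at
  baseline frequency ``f`` reaches ``f * A / (1 + f * (A - 1))`` with
  ``A = 2**(rate * t)``.  Growth on the simplex is exactly what makes blooms
  pernicious: every other taxon's apparent frequency shrinks.
* Sequencing is multinomial at a fixed read depth — no overdispersion beyond
  the Dirichlet baseline, keeping closed-form expectations exact for tests.
* An age effect on alpha diversity is planted structurally: each age category
  has a fixed random subset of non-bloom features zeroed out before
  normalization, so categories genuinely differ in feature richness (the
  exact quantity the downstream Kruskal-Wallis sweep tests) rather than in
  abundance.

Two generators share one feature space per configuration seed: a controlled
storage time series (frozen day-0 baselines plus room-temperature time
points, a few subjects) and a multi-study cohort set (several fresh-frozen
studies plus one shipped study whose samples spend a random number of days in
transit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import FeatureTable, SampleMetadata, TaxonomyMap, FROZEN, ROOM_TEMPERATURE

__all__ = [
    "StorageDesign",
    "CohortDesign",
    "AgeEffect",
    "SimulationConfig",
    "GroundTruth",
    "simulate_sequences",
    "simulate_storage_study",
    "simulate_cohort_studies",
    "simulate_taxonomy",
]

GAMMAPROTEOBACTERIA_LINEAGE = (
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; "
    "o__Enterobacteriales; f__Enterobacteriaceae; g__; s__"
)

_BACKGROUND_CLASSES = (
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__; g__; s__",
    "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__; g__; s__",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__; g__; s__",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__; f__; g__; s__",
    "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__; f__; g__; s__",
)


@dataclass
class StorageDesign:
    """Controlled storage experiment: paired frozen day-0 vs room temperature."""

    n_subjects: int = 3
    days: tuple[float, ...] = (1.0, 4.0)
    depth: int = 5000
    study_id: str = "storage"


@dataclass
class CohortDesign:
    """Multi-study cohorts: fresh-frozen studies plus one shipped study."""

    n_frozen_studies: int = 3
    samples_per_study: int = 50
    depth: int = 5000
    shipping_days_range: tuple[float, float] = (4.0, 5.0)
    shipped_study_id: str = "shipped"
    frozen_study_prefix: str = "frozen"


@dataclass
class AgeEffect:
    """Category-dependent richness offsets via feature-presence masking.

    ``masked_features[i]`` non-bloom features are zeroed for every sample of
    ``categories[i]``, so the category's available richness is reduced by
    exactly that many features.
    """

    categories: tuple[str, ...] = ("young", "elderly")
    masked_features: tuple[int, ...] = (0, 100)


@dataclass
class SimulationConfig:
    """Full study-conditions bundle; ``seed`` is mandatory.

    ``baseline_concentration`` is the symmetric Dirichlet parameter of the
    per-sample baseline composition (a vector is accepted for non-uniform
    profiles).  ``bloom_growth_rates`` is in doublings per day at room
    temperature; a scalar applies to every planted bloom.
    """

    seed: int
    n_features: int = 500
    n_bloom_features: int = 5
    sequence_length: int = 150
    baseline_concentration: float | Sequence[float] = 10.0
    bloom_growth_rates: float | tuple[float, ...] = 2.0
    storage: StorageDesign = field(default_factory=StorageDesign)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    age_effect: AgeEffect = field(default_factory=AgeEffect)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.n_bloom_features < self.n_features:
            raise ValueError("need 0 <= n_bloom_features < n_features")
        rates = self.rates()
        if any(r < 0 for r in rates):
            raise ValueError("bloom growth rates must be >= 0")
        if len(self.age_effect.categories) != len(self.age_effect.masked_features):
            raise ValueError("age categories and masked_features lengths differ")
        if any(
            m >= self.n_features - self.n_bloom_features
            for m in self.age_effect.masked_features
        ):
            raise ValueError("age masking would remove all non-bloom features")

    def rates(self) -> tuple[float, ...]:
        if isinstance(self.bloom_growth_rates, (int, float)):
            return (float(self.bloom_growth_rates),) * self.n_bloom_features
        rates = tuple(float(r) for r in self.bloom_growth_rates)
        if len(rates) != self.n_bloom_features:
            raise ValueError("bloom_growth_rates length must equal n_bloom_features")
        return rates

    def concentration(self) -> np.ndarray:
        if np.isscalar(self.baseline_concentration):
            return np.full(self.n_features, float(self.baseline_concentration))
        alpha = np.asarray(self.baseline_concentration, dtype=np.float64)
        if alpha.shape != (self.n_features,):
            raise ValueError("baseline_concentration vector length != n_features")
        return alpha


@dataclass
class GroundTruth:
    """What was planted: blooms, growth rates, shipping times, age labels."""

    bloom_feature_ids: list[str]
    bloom_growth_rates: dict[str, float]
    shipping_time: dict[str, float]  # sample -> days at room temperature
    age_category: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("record_type\tkey\tvalue\n")
            for fid in self.bloom_feature_ids:
                fh.write(f"bloom\t{fid}\t{self.bloom_growth_rates[fid]}\n")
            for sid, t in self.shipping_time.items():
                fh.write(f"shipping_time\t{sid}\t{t}\n")
            for sid, cat in self.age_category.items():
                fh.write(f"age_category\t{sid}\t{cat}\n")


def simulate_sequences(n: int, length: int, seed: int) -> dict[str, str]:
    """``n`` distinct uniform-random DNA sequences of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    if n > 4 ** min(length, 32):  # cap the check to avoid overflow; 4^32 >> any n
        raise ValueError(f"cannot draw {n} distinct sequences of length {length}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    while len(seqs) < n:
        draw = "".join(alphabet[rng.integers(0, 4, size=length)])
        seqs[draw] = draw
    return seqs


def _streams(config: SimulationConfig) -> tuple[np.random.Generator, ...]:
    """Independent child streams so storage and cohort share the feature space."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _shared_features(
    config: SimulationConfig,
) -> tuple[list[str], np.ndarray]:
    """Feature sequences and planted-bloom indices, fixed per config seed."""
    seq_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    catalog = simulate_sequences(config.n_features, config.sequence_length, seq_seed)
    feature_ids = list(catalog)
    rng = np.random.default_rng(seq_seed + 1)
    bloom_idx = rng.choice(config.n_features, size=config.n_bloom_features, replace=False)
    return feature_ids, np.sort(bloom_idx)


def bloom_amplified(
    base: np.ndarray, bloom_idx: np.ndarray, rates: Sequence[float], t: float
) -> np.ndarray:
    """Apply exponential bloom growth for ``t`` days and renormalize."""
    p = base.astype(np.float64).copy()
    amps = np.array([2.0 ** (r * t) for r in rates])
    p[bloom_idx] *= amps
    return p / p.sum()


def simulate_storage_study(
    config: SimulationConfig,
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Paired frozen-baseline vs room-temperature time series per subject."""
    feature_ids, bloom_idx = _shared_features(config)
    _, rng, _ = _streams(config)
    rates = config.rates()
    alpha = config.concentration()
    design = config.storage

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    records: list[dict[str, object]] = []
    for subj in range(design.n_subjects):
        subject_id = f"subj{subj + 1}"
        base = rng.dirichlet(alpha)
        for day, condition in [(0.0, FROZEN)] + [
            (float(d), ROOM_TEMPERATURE) for d in design.days
        ]:
            p = bloom_amplified(base, bloom_idx, rates, day)
            counts = rng.multinomial(design.depth, p)
            sid = f"{design.study_id}.{subject_id}.d{day:g}"
            sample_ids.append(sid)
            rows.append(counts)
            records.append(
                {
                    "sample_id": sid,
                    "study_id": design.study_id,
                    "condition": condition,
                    "subject_id": subject_id,
                    "day": day,
                    "age_category": None,
                }
            )
    table = FeatureTable(sample_ids, feature_ids, np.array(rows, dtype=np.int64))
    metadata = SampleMetadata.from_records(records)
    bloom_ids = [feature_ids[i] for i in bloom_idx]
    truth = GroundTruth(
        bloom_feature_ids=bloom_ids,
        bloom_growth_rates=dict(zip(bloom_ids, rates)),
        shipping_time={r["sample_id"]: float(r["day"]) for r in records},  # type: ignore[arg-type]
        age_category={},
    )
    return table, metadata, truth


def simulate_cohort_studies(
    config: SimulationConfig,
) -> tuple[list[FeatureTable], SampleMetadata, GroundTruth]:
    """Fresh-frozen cohorts plus one shipped cohort with random transit times.

    Returns one table per study (shipped study first), a combined metadata
    frame, and the ground truth.  All tables share the configuration's
    feature space.
    """
    feature_ids, bloom_idx = _shared_features(config)
    _, _, rng = _streams(config)
    rates = config.rates()
    alpha = config.concentration()
    design = config.cohort
    age = config.age_effect

    # fixed per-category masked feature sets (non-bloom features only)
    non_bloom = np.setdiff1d(np.arange(config.n_features), bloom_idx)
    masks: dict[str, np.ndarray] = {}
    for cat, n_masked in zip(age.categories, age.masked_features):
        masks[cat] = rng.choice(non_bloom, size=n_masked, replace=False)

    studies = [design.shipped_study_id] + [
        f"{design.frozen_study_prefix}{i + 1}" for i in range(design.n_frozen_studies)
    ]
    tables: list[FeatureTable] = []
    records: list[dict[str, object]] = []
    shipping_time: dict[str, float] = {}
    age_category: dict[str, str] = {}
    lo, hi = design.shipping_days_range
    for study in studies:
        shipped = study == design.shipped_study_id
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        # balanced, shuffled age assignment
        cats = np.array(
            [age.categories[i % len(age.categories)] for i in range(design.samples_per_study)]
        )
        rng.shuffle(cats)
        for s in range(design.samples_per_study):
            cat = str(cats[s])
            base = rng.dirichlet(alpha)
            if len(masks[cat]):
                # reassign the masked features' mass to the surviving
                # non-bloom features, so the planted age effect changes
                # richness without touching baseline bloom load
                masked_mass = base[masks[cat]].sum()
                base[masks[cat]] = 0.0
                survivors = np.setdiff1d(non_bloom, masks[cat])
                surv_mass = base[survivors].sum()
                if surv_mass > 0:
                    base[survivors] *= (surv_mass + masked_mass) / surv_mass
            t = float(rng.uniform(lo, hi)) if shipped else 0.0
            p = bloom_amplified(base, bloom_idx, rates, t)
            counts = rng.multinomial(design.depth, p)
            sid = f"{study}.s{s + 1}"
            sample_ids.append(sid)
            rows.append(counts)
            shipping_time[sid] = t
            age_category[sid] = cat
            records.append(
                {
                    "sample_id": sid,
                    "study_id": study,
                    "condition": ROOM_TEMPERATURE if shipped else FROZEN,
                    "subject_id": sid,
                    "day": t,
                    "age_category": cat,
                }
            )
        tables.append(
            FeatureTable(sample_ids, feature_ids, np.array(rows, dtype=np.int64))
        )
    metadata = SampleMetadata.from_records(records)
    bloom_ids = [feature_ids[i] for i in bloom_idx]
    truth = GroundTruth(
        bloom_feature_ids=bloom_ids,
        bloom_growth_rates=dict(zip(bloom_ids, rates)),
        shipping_time=shipping_time,
        age_category=age_category,
    )
    return tables, metadata, truth


def simulate_taxonomy(
    feature_ids: Sequence[str],
    bloom_feature_ids: Sequence[str],
    seed: int,
    gamma_background_fraction: float = 0.02,
) -> TaxonomyMap:
    """Assign Greengenes-style lineages: blooms get a Gammaproteobacteria
    lineage (the class the real shipping blooms overwhelmingly belong to),
    everything else a random background class.

    A small fraction of non-bloom features also receives the
    Gammaproteobacteria lineage — real guts harbor legitimate members of the
    class, which is why class-level profiles do not drop to zero after bloom
    filtering."""
    rng = np.random.default_rng(seed)
    blooms = set(bloom_feature_ids)
    lineages: dict[str, str] = {}
    for fid in feature_ids:
        if fid in blooms or rng.random() < gamma_background_fraction:
            lineages[fid] = GAMMAPROTEOBACTERIA_LINEAGE
        else:
            lineages[fid] = _BACKGROUND_CLASSES[rng.integers(0, len(_BACKGROUND_CLASSES))]
    return TaxonomyMap(lineages)
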