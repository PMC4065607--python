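"""The combinatorial screening process: module libraries, pool assembly,
coverage arithmetic, and positive-only-sequencing labeling.

Engineering a meganuclease for a new site proceeds in two stages.  First,
module libraries are built once: sets of I-CreI half-variants mutated at the
p5N3 positions and screened on all 64 possible 5N3 region targets, and at
the p11N4 positions screened on all 256 possible 11N4 targets.  Then, for a
given full target, modules active on its 5N3 and 11N4 regions are combined
by random PCR assembly into a combinatorial pool of full variants, the pool
is screened in bulk, and only positive clones are sequenced.  Combinations
never seen among the positives are assumed negative — an assumption this
module makes explicit with a per-record ``measured`` flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scaffold import (
    P5N3_POSITIONS,
    P11N4_POSITIONS,
    ProteinVariant,
    Target,
    enumerate_region_space,
)

__all__ = [
    "ModuleLibrary",
    "CombinatorialPool",
    "ScreeningRecord",
    "ScreeningDataset",
    "expected_coverage",
    "assemble_pool",
    "label_pool",
    "records_to_frame",
    "save_dataset",
    "load_dataset",
]

_REGION_POSITIONS = {"p5N3": P5N3_POSITIONS, "p11N4": P11N4_POSITIONS}
_REGION_SPACE = {"p5N3": "5N3", "p11N4": "11N4"}


@dataclass
class ModuleLibrary:
    """A library of half-variants with activities on every region target.

    ``halves[i]`` maps each of the region's key positions to a residue;
    ``activities[i, j]`` is the (measured) normalized cleavage activity of
    half ``i`` on ``region_targets[j]``.
    """

    region: str
    halves: list[dict[int, str]]
    activities: np.ndarray
    region_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region not in _REGION_POSITIONS:
            raise ValueError(f"region must be 'p5N3' or 'p11N4', got {self.region!r}")
        if not self.region_targets:
            self.region_targets = enumerate_region_space(_REGION_SPACE[self.region])
        self.activities = np.asarray(self.activities, dtype=float)
        positions = set(_REGION_POSITIONS[self.region])
        for half in self.halves:
            if set(half) != positions:
                raise ValueError(
                    f"half-variant positions {sorted(half)} do not match "
                    f"{self.region} positions {sorted(positions)}"
                )
        if self.activities.shape != (len(self.halves), len(self.region_targets)):
            raise ValueError("activity table shape does not match halves x targets")
        if self.activities.size and (
            self.activities.min() < 0 or self.activities.max() > 1
        ):
            raise ValueError("activities must lie in [0,1]")
        self._target_index = {t: j for j, t in enumerate(self.region_targets)}
        self._half_index = {self._half_key(h): i for i, h in enumerate(self.halves)}

    def _half_key(self, half: Mapping[int, str]) -> str:
        return "".join(half[p] for p in _REGION_POSITIONS[self.region])

    def __len__(self) -> int:
        return len(self.halves)

    def activity_of(self, half: Mapping[int, str], region_target: str) -> float | None:
        """Measured activity of a half on a region target; None if the half
        is not in the library (the caller decides how to encode missingness)."""
        i = self._half_index.get(self._half_key(half))
        j = self._target_index.get(region_target)
        if i is None or j is None:
            return None
        return float(self.activities[i, j])

    def top_modules(self, region_target: str, n: int) -> list[int]:
        """Indices of the n halves most active on a region target
        (deterministic tie-break by half key)."""
        j = self._target_index[region_target]
        keys = [self._half_key(h) for h in self.halves]
        order = sorted(range(len(self)), key=lambda i: (-self.activities[i, j], keys[i]))
        return order[:n]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: module_id, region, residues, region_target, activity."""
        positions = _REGION_POSITIONS[self.region]
        rows = []
        for i, half in enumerate(self.halves):
            residues = "".join(half[p] for p in positions)
            for j, rt in enumerate(self.region_targets):
                rows.append(
                    {
                        "module_id": i,
                        "region": self.region,
                        "residues": residues,
                        "region_target": rt,
                        "activity": self.activities[i, j],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModuleLibrary":
        region = df["region"].iloc[0]
        positions = _REGION_POSITIONS[region]
        region_targets = enumerate_region_space(_REGION_SPACE[region])
        halves: list[dict[int, str]] = []
        ids = sorted(df["module_id"].unique())
        acts = np.zeros((len(ids), len(region_targets)))
        tindex = {t: j for j, t in enumerate(region_targets)}
        for k, mid in enumerate(ids):
            sub = df[df["module_id"] == mid]
            residues = sub["residues"].iloc[0]
            halves.append(dict(zip(positions, residues)))
            acts[k, [tindex[t] for t in sub["region_target"]]] = sub["activity"].to_numpy()
        return cls(region, halves, acts, region_targets)


@dataclass(frozen=True)
class ScreeningRecord:
    """One row of a screened combinatorial pool."""

    variant: ProteinVariant
    target: Target
    activity: float
    label: bool
    measured: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("activity must be in [0,1]")


@dataclass
class CombinatorialPool:
    """Assembled candidates for one target, with sequenced positives.

    ``module_pairs[i]`` records which (p5N3, p11N4) library indices candidate
    ``i`` was assembled from.  ``sequenced_positives`` maps a variant key to
    its measured activity; everything else in the pool is assumed negative.
    """

    target: Target
    candidates: list[ProteinVariant]
    module_pairs: list[tuple[int, int]]
    sequenced_positives: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.module_pairs):
            raise ValueError("candidates and module_pairs must align")
        keys = {v.key for v in self.candidates}
        stray = set(self.sequenced_positives) - keys
        if stray:
            raise ValueError(
                f"{len(stray)} sequenced positives are not in the candidate pool"
            )

    def __len__(self) -> int:
        return len(self.candidates)


def expected_coverage(n_combinations: int, oversampling: float) -> float:
    """Expected fraction of combinations hit by uniform sampling.

    Drawing ``oversampling * N`` module pairs uniformly with replacement from
    ``N`` possible combinations covers an expected fraction
    ``1 - (1 - 1/N)**(oversampling*N)``; as N grows this tends to
    ``1 - exp(-oversampling)`` (about 95% at 3x oversampling).
    """
    if n_combinations < 1:
        raise ValueError("n_combinations must be >= 1")
    if oversampling < 0:
        raise ValueError("oversampling must be nonnegative")
    n = n_combinations
    return 1.0 - (1.0 - 1.0 / n) ** (oversampling * n)


def assemble_pool(
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
    target: Target,
    p5_indices: Sequence[int] | None = None,
    p11_indices: Sequence[int] | None = None,
    oversampling: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> CombinatorialPool:
    """Randomly assemble full variants from two module sets.

    Draws ``ceil(oversampling * |p5| * |p11|)`` module pairs uniformly with
    replacement, then deduplicates (keeping first-draw order), mirroring the
    random PCR assembly step.  Candidate identity is the module pair.
    """
    p5 = list(p5_indices) if p5_indices is not None else list(range(len(lib5)))
    p11 = list(p11_indices) if p11_indices is not None else list(range(len(lib11)))
    if not p5 or not p11:
        raise ValueError("module sets must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_draws = math.ceil(oversampling * len(p5) * len(p11))
    i5 = rng.integers(0, len(p5), size=n_draws)
    i11 = rng.integers(0, len(p11), size=n_draws)
    seen: dict[tuple[int, int], None] = {}
    for a, b in zip(i5, i11):
        seen.setdefault((p5[a], p11[b]), None)
    pairs = list(seen)
    candidates = [
        ProteinVariant.from_halves(lib5.halves[a], lib11.halves[b]) for a, b in pairs
    ]
    provenance = {
        "p5_modules": p5,
        "p11_modules": p11,
        "oversampling": oversampling,
        "n_draws": n_draws,
    }
    return CombinatorialPool(target, candidates, pairs, {}, provenance)


def label_pool(pool: CombinatorialPool) -> list[ScreeningRecord]:
    """Turn a screened pool into records under positive-only sequencing.

    Every candidate yields exactly one record.  Sequenced positives carry
    their measured activity; all other candidates are labeled negative with
    activity 0 and flagged as assumed (``measured=False``), since a clone not
    found among the sequenced positives was never individually observed.
    """
    records = []
    for variant in pool.candidates:
        act = pool.sequenced_positives.get(variant.key)
        if act is not None:
            records.append(ScreeningRecord(variant, pool.target, float(act), True, True))
        else:
            records.append(ScreeningRecord(variant, pool.target, 0.0, False, False))
    return records


@dataclass
class ScreeningDataset:
    """A set of screened combinatorial pools sharing two module libraries."""

    lib5: ModuleLibrary
    lib11: ModuleLibrary
    pools: list[CombinatorialPool]
    records: list[list[ScreeningRecord]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pools) != len(self.records):
            raise ValueError("one record list per pool required")

    @property
    def targets(self) -> list[Target]:
        return [p.target for p in self.pools]

    def all_records(self) -> list[ScreeningRecord]:
        return [r for recs in self.records for r in recs]

    def records_for(self, target_indices: Iterable[int]) -> list[ScreeningRecord]:
        return [r for i in target_indices for r in self.records[i]]


def records_to_frame(records: Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Flatten screening records into a table with per-position columns."""
    rows = []
    for r in records:
        row = {"target": r.target.full_seq}
        for p in P11N4_POSITIONS + P5N3_POSITIONS:
            row[f"P{p}"] = r.variant.residues[p]
        row.update(activity=r.activity, label=int(r.label), measured=int(r.measured))
        rows.append(row)
    return pd.DataFrame(rows)


def save_dataset(dataset: ScreeningDataset, outdir) -> None:
    """Write a dataset as TSV tables plus a JSON sidecar of seeds/metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.lib5.to_frame().to_csv(outdir / "library_p5N3.tsv", sep="\t", index=False)
    dataset.lib11.to_frame().to_csv(outdir / "library_p11N4.tsv", sep="\t", index=False)
    rows = []
    for pool_id, (pool, recs) in enumerate(zip(dataset.pools, dataset.records)):
        frame = records_to_frame(recs)
        frame.insert(0, "pool_id", pool_id)
        pairs = {v.key: pr for v, pr in zip(pool.candidates, pool.module_pairs)}
        keys = [r.variant.key for r in recs]
        frame["module_p5"] = [pairs[k][0] for k in keys]
        frame["module_p11"] = [pairs[k][1] for k in keys]
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "screening_records.tsv", sep="\t", index=False
    )
    with open(outdir / "dataset_meta.json", "w") as fh:
        json.dump(dataset.meta, fh, indent=2, sort_keys=True)


def load_dataset(indir) -> ScreeningDataset:
    """Inverse of :func:`save_dataset`."""
    indir = Path(indir)
    lib5 = ModuleLibrary.from_frame(
        pd.read_csv(indir / "library_p5N3.tsv", sep="\t")
    )
    lib11 = ModuleLibrary.from_frame(
        pd.read_csv(indir / "library_p11N4.tsv", sep="\t")
    )
    df = pd.read_csv(indir / "screening_records.tsv", sep="\t")
    meta_path = indir / "dataset_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    pools, records = [], []
    for _, sub in df.groupby("pool_id", sort=True):
        target = Target(sub["target"].iloc[0])
        candidates, pairs, positives, recs = [], [], {}, []
        for _, row in sub.iterrows():
            residues = {p: row[f"P{p}"] for p in P11N4_POSITIONS + P5N3_POSITIONS}
            v = ProteinVariant(residues)
            candidates.append(v)
            pairs.append((int(row["module_p5"]), int(row["module_p11"])))
            rec = ScreeningRecord(
                v, target, float(row["activity"]), bool(row["label"]), bool(row["measured"])
            )
            recs.append(rec)
            if rec.label:
                positives[v.key] = rec.activity
        pools.append(CombinatorialPool(target, candidates, pairs, positives))
        records.append(recs)
    return ScreeningDataset(lib5, lib11, pools, records, meta)
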