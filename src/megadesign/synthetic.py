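"""Ground-truth generative simulator for combinatorial screening data.

The real training data (hundreds of screened combinatorial libraries) are
proprietary, so this module provides a generative stand-in with the same
observable structure and with *planted*, recoverable effects:

* two module libraries whose halves carry latent compatibility with every
  region target (each half has a cognate region target it cuts well, with
  activity decaying in Hamming distance), measured with small assay noise;
* a combined-variant activity model on the logit-free additive scale:
  module compatibilities of the two halves, plus per-mutation non-specific
  effects (e.g. a planted penalty for 44F and for 32K), pairwise
  protein-protein effects (a planted penalty for carrying 44R and 77R
  simultaneously, mimicking their electrostatic repulsion), and
  residue-nucleotide preferences at structurally contacting position pairs;
  the sum is noised and clipped to [0,1], and a variant is "active" when
  its score reaches the activity threshold.

The sequence-level effects model what changes when two mutated halves are
*combined* (folding, expression, interface cross-talk) and are therefore
invisible to the module-activity measurements — which is precisely what
makes sequence-aware models outperform a module-activity-only baseline on
this data, and what the ablation suites test.

Screening emulates the lab protocol: per target, the most active modules on
each region are pooled, assembled at 3x oversampling, screened in bulk, and
only positives are sequenced (everything else becomes an assumed negative).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .combinatorial import (
    CombinatorialPool,
    ModuleLibrary,
    ScreeningDataset,
    assemble_pool,
    label_pool,
)
from .scaffold import (
    P5N3_POSITIONS,
    P11N4_POSITIONS,
    ProteinVariant,
    Target,
    WT_RESIDUES,
    build_palindrome,
    enumerate_region_space,
    extract_regions,
)

__all__ = [
    "RESIDUE_POOLS",
    "CONTACTS",
    "PLANTED_NONSPECIFIC",
    "PLANTED_M2M",
    "GroundTruthModel",
    "SpecificityDataset",
    "simulate_module_libraries",
    "default_ground_truth",
    "ground_truth_activity",
    "generate_screening_dataset",
    "generate_specificity_dataset",
]

#: Plausible residue repertoires at each key position (wild type first).
RESIDUE_POOLS: Mapping[int, str] = {
    30: "NKRQHDT",
    32: "SKTRQNA",
    33: "YRHCGTS",
    38: "QRKNEHT",
    40: "SKRQANT",
    44: "QRKNATF",
    68: "RKQHNTS",
    70: "RKQNSAD",
    75: "DNEQVY",
    77: "IRKVNQT",
}

#: Relative sampling weights for the repertoires above.  Wild-type residues
#: and the workhorse base-contacting substitutions (arginine/lysine at the
#: reading positions) recur across many modules, as they do in engineered
#: libraries; rarer substitutions get unit weight.
RESIDUE_WEIGHTS: Mapping[int, tuple[float, ...]] = {
    30: (2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    32: (2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    33: (2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    38: (2.0, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0),
    40: (2.0, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0),
    44: (2.0, 3.5, 1.0, 1.0, 1.0, 1.0, 0.8),
    68: (2.5, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0),
    70: (2.5, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0),
    75: (2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    77: (2.0, 3.5, 1.0, 1.0, 1.0, 1.0, 1.0),
}


def _sample_residue(rng: np.random.Generator, pos: int) -> str:
    pool = RESIDUE_POOLS[pos]
    w = np.asarray(RESIDUE_WEIGHTS[pos], dtype=float)
    return pool[rng.choice(len(pool), p=w / w.sum())]

#: Base-specific protein-DNA contacts: position -> (region, 0-based offset).
#: Residue 70 reads bases +3/+4, 44 reads +4, 68 reads +5; on the distal
#: region, 30 and 38 read +9 and 33 reads +10.
CONTACTS: Mapping[int, tuple[tuple[str, int], ...]] = {
    70: (("r5N3", 0), ("r5N3", 1)),
    44: (("r5N3", 1),),
    68: (("r5N3", 2),),
    30: (("r11N4", 1),),
    38: (("r11N4", 1),),
    33: (("r11N4", 2),),
}

#: Named planted single-mutation penalties (combination-context effects).
PLANTED_NONSPECIFIC: Mapping[tuple[int, str], float] = {
    (44, "F"): -0.45,
    (32, "K"): -0.35,
}

#: Named planted protein-protein pair penalty: simultaneous 44R and 77R.
PLANTED_M2M: Mapping[tuple[tuple[int, str], tuple[int, str]], float] = {
    ((44, "R"), (77, "R")): -0.50,
}

_WT_R7N2 = "GT"  # the invariant 7N2 region used for all simulated targets


def _make_library(
    region: str,
    n_modules: int,
    rng: np.random.Generator,
    decay: float,
    quality_range: tuple[float, float],
    meas_sd: float,
) -> tuple[ModuleLibrary, np.ndarray]:
    positions = P5N3_POSITIONS if region == "p5N3" else P11N4_POSITIONS
    space = enumerate_region_space("5N3" if region == "p5N3" else "11N4")
    if n_modules < len(space):
        raise ValueError(
            f"need at least {len(space)} {region} modules to cover the region space"
        )
    halves = [
        {p: _sample_residue(rng, p) for p in positions} for _ in range(n_modules)
    ]
    # cognates cycle through a shuffled enumeration so every region target
    # is covered by at least one module
    order = rng.permutation(len(space))
    cognates = [space[order[i % len(space)]] for i in range(n_modules)]
    quality = rng.uniform(*quality_range, size=n_modules)
    k = len(space[0])
    dist = np.zeros((n_modules, len(space)), dtype=int)
    for j, s in enumerate(space):
        for i, c in enumerate(cognates):
            dist[i, j] = sum(a != b for a, b in zip(c, s))
    latent = quality[:, None] * decay ** dist
    measured = np.clip(latent + rng.normal(0.0, meas_sd, size=latent.shape), 0.0, 1.0)
    return ModuleLibrary(region, halves, measured, space), latent


@dataclass
class GroundTruthModel:
    """Latent activity model behind the simulated screens.

    ``latent5``/``latent11`` are the true module compatibilities; the
    libraries carry their noisy measured versions.  Effect dictionaries map
    mutations (and mutation pairs / mutation-nucleotide pairs) to additive
    contributions on the pre-clipping activity scale.
    """

    lib5: ModuleLibrary
    lib11: ModuleLibrary
    latent5: np.ndarray
    latent11: np.ndarray
    nonspecific: dict[tuple[int, str], float]
    m2m: dict[tuple[tuple[int, str], tuple[int, str]], float]
    m2t: dict[tuple[int, str, str, int, str], float]
    w5: float = 0.55
    w11: float = 0.55
    bias: float = -0.35
    noise_sd: float = 0.08
    tau_active: float = 0.25
    strong_threshold: float = 0.8

    def __post_init__(self) -> None:
        self._j5 = {t: j for j, t in enumerate(self.lib5.region_targets)}
        self._j11 = {t: j for j, t in enumerate(self.lib11.region_targets)}
        self._cache: dict = {}

    # ---- effect evaluation -------------------------------------------------

    def sequence_effect(self, residues: Mapping[int, str], target: Target) -> float:
        """Total planted sequence effect (non-specific + M2M + M2T) of a
        full residue assignment on one target."""
        eff = sum(self.nonspecific.get((p, a), 0.0) for p, a in residues.items())
        for ((p1, a1), (p2, a2)), e in self.m2m.items():
            if residues.get(p1) == a1 and residues.get(p2) == a2:
                eff += e
        regions = extract_regions(target)
        for (p, a, region, off, nt), e in self.m2t.items():
            if residues.get(p) == a and getattr(regions, region)[off] == nt:
                eff += e
        return eff

    def _module_effect_tables(self):
        """Per-module target-independent effects and the cross-pair matrix."""
        if "tables" in self._cache:
            return self._cache["tables"]
        e5 = np.array(
            [self._half_effect(h, P5N3_POSITIONS) for h in self.lib5.halves]
        )
        e11 = np.array(
            [self._half_effect(h, P11N4_POSITIONS) for h in self.lib11.halves]
        )
        cross = np.zeros((len(self.lib5), len(self.lib11)))
        for ((p1, a1), (p2, a2)), e in self.m2m.items():
            s1 = p1 in P5N3_POSITIONS
            s2 = p2 in P5N3_POSITIONS
            if s1 == s2:
                continue
            if not s1:  # orient as (p5 position, p11 position)
                (p1, a1), (p2, a2) = (p2, a2), (p1, a1)
            m5 = np.array([h[p1] == a1 for h in self.lib5.halves])
            m11 = np.array([h[p2] == a2 for h in self.lib11.halves])
            cross += e * np.outer(m5, m11)
        self._cache["tables"] = (e5, e11, cross)
        return self._cache["tables"]

    def _half_effect(self, half: Mapping[int, str], positions) -> float:
        eff = sum(self.nonspecific.get((p, half[p]), 0.0) for p in positions)
        pos_set = set(positions)
        for ((p1, a1), (p2, a2)), e in self.m2m.items():
            if p1 in pos_set and p2 in pos_set:
                if half.get(p1) == a1 and half.get(p2) == a2:
                    eff += e
        return eff

    def _m2t_vector(self, halves, positions, target: Target) -> np.ndarray:
        regions = extract_regions(target)
        out = np.zeros(len(halves))
        pos_set = set(positions)
        for (p, a, region, off, nt), e in self.m2t.items():
            if p not in pos_set or getattr(regions, region)[off] != nt:
                continue
            out += e * np.array([h[p] == a for h in halves])
        return out

    def _pool_z(
        self,
        pairs: Sequence[tuple[int, int]],
        target: Target,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        regions = extract_regions(target)
        i5 = np.array([p[0] for p in pairs], dtype=int)
        i11 = np.array([p[1] for p in pairs], dtype=int)
        e5, e11, cross = self._module_effect_tables()
        m2t5 = self._m2t_vector(self.lib5.halves, P5N3_POSITIONS, target)
        m2t11 = self._m2t_vector(self.lib11.halves, P11N4_POSITIONS, target)
        z = (
            self.bias
            + self.w5 * self.latent5[i5, self._j5[regions.r5N3]]
            + self.w11 * self.latent11[i11, self._j11[regions.r11N4]]
            + e5[i5]
            + e11[i11]
            + m2t5[i5]
            + m2t11[i11]
            + cross[i5, i11]
        )
        if rng is not None and self.noise_sd > 0:
            z = z + rng.normal(0.0, self.noise_sd, size=len(z))
        return z

    def pool_scores(
        self,
        pairs: Sequence[tuple[int, int]],
        target: Target,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """True activity scores for assembled (p5 index, p11 index) pairs."""
        return np.clip(self._pool_z(pairs, target, rng), 0.0, 1.0)

    def without_sequence_effects(self) -> "GroundTruthModel":
        """A copy in which activity depends only on module compatibilities
        (a world where the module-activity baseline is the optimal model)."""
        return dataclasses.replace(self, nonspecific={}, m2m={}, m2t={})

    def effects_dict(self) -> dict:
        """JSON-serializable dump of the planted effects, for oracle use."""
        return {
            "nonspecific": {f"{p}{a}": e for (p, a), e in self.nonspecific.items()},
            "m2m": {
                f"{p1}{a1}+{p2}{a2}": e
                for ((p1, a1), (p2, a2)), e in self.m2m.items()
            },
            "m2t": {
                f"{p}{a}:{region}[{off}]={nt}": e
                for (p, a, region, off, nt), e in self.m2t.items()
            },
            "w5": self.w5,
            "w11": self.w11,
            "bias": self.bias,
            "noise_sd": self.noise_sd,
            "tau_active": self.tau_active,
        }


def simulate_module_libraries(
    seed: int = 0,
    n5: int = 80,
    n11: int = 320,
    decay5: float = 0.35,
    decay11: float = 0.30,
    quality_range: tuple[float, float] = (0.55, 1.0),
    meas_sd: float = 0.04,
) -> tuple[ModuleLibrary, ModuleLibrary]:
    """Simulate the two module libraries (p5N3 over 64 targets, p11N4 over
    256).  Every region target is guaranteed at least one active module."""
    rng = np.random.default_rng(seed)
    lib5, _ = _make_library("p5N3", n5, rng, decay5, quality_range, meas_sd)
    lib11, _ = _make_library("p11N4", n11, rng, decay11, quality_range, meas_sd)
    return lib5, lib11


def default_ground_truth(
    seed: int = 0,
    n5: int = 80,
    n11: int = 320,
    decay5: float = 0.35,
    decay11: float = 0.30,
    quality_range: tuple[float, float] = (0.55, 1.0),
    meas_sd: float = 0.04,
    nonspec_prob: float = 0.4,
    nonspec_sd: float = 0.12,
    n_random_m2m_intra: int = 8,
    n_random_m2m_cross: int = 2,
    m2m_sd: float = 0.20,
    m2t_prob: float = 0.35,
    m2t_sd: float = 0.18,
    zero_sequence_effects: bool = False,
    **model_kwargs,
) -> GroundTruthModel:
    """Build the default ground-truth world: libraries plus planted effects.

    The planted named effects (44F down, 32K down, 44R x 77R down) are always
    present (unless ``zero_sequence_effects``); around them, random
    mutation-level, pairwise and residue-nucleotide effects are drawn once
    from the given scales.
    """
    rng = np.random.default_rng(seed)
    lib5, latent5 = _make_library("p5N3", n5, rng, decay5, quality_range, meas_sd)
    lib11, latent11 = _make_library("p11N4", n11, rng, decay11, quality_range, meas_sd)

    nonspecific: dict[tuple[int, str], float] = {}
    m2m: dict = {}
    m2t: dict = {}
    if not zero_sequence_effects:
        for p, pool in RESIDUE_POOLS.items():
            for a in pool:
                if a == WT_RESIDUES[p]:
                    continue  # wild type is the reference level
                if rng.random() < nonspec_prob:
                    nonspecific[(p, a)] = float(rng.normal(0.0, nonspec_sd))
        nonspecific.update(PLANTED_NONSPECIFIC)

        def _draw_pairs(pos_a, pos_b, count, sd):
            for _ in range(count):
                p1 = int(pos_a[rng.integers(len(pos_a))])
                p2 = int(pos_b[rng.integers(len(pos_b))])
                if p1 == p2:
                    continue
                a1 = RESIDUE_POOLS[p1][rng.integers(len(RESIDUE_POOLS[p1]))]
                a2 = RESIDUE_POOLS[p2][rng.integers(len(RESIDUE_POOLS[p2]))]
                key = tuple(sorted(((p1, a1), (p2, a2))))
                if key not in m2m:
                    m2m[key] = float(rng.normal(0.0, sd))

        _draw_pairs(np.array(P5N3_POSITIONS), np.array(P5N3_POSITIONS),
                    n_random_m2m_intra // 2, m2m_sd)
        _draw_pairs(np.array(P11N4_POSITIONS), np.array(P11N4_POSITIONS),
                    n_random_m2m_intra - n_random_m2m_intra // 2, m2m_sd)
        _draw_pairs(np.array(P5N3_POSITIONS), np.array(P11N4_POSITIONS),
                    n_random_m2m_cross, m2m_sd / 2)
        for (p1, a1), (p2, a2) in PLANTED_M2M:
            m2m[tuple(sorted(((p1, a1), (p2, a2))))] = PLANTED_M2M[((p1, a1), (p2, a2))]

        for p, contacts in CONTACTS.items():
            for region, off in contacts:
                for a in RESIDUE_POOLS[p]:
                    for nt in "ACGT":
                        if rng.random() < m2t_prob:
                            m2t[(p, a, region, off, nt)] = float(
                                rng.normal(0.0, m2t_sd)
                            )

    return GroundTruthModel(
        lib5, lib11, latent5, latent11, nonspecific, m2m, m2t, **model_kwargs
    )


def ground_truth_activity(
    model: GroundTruthModel,
    variant: ProteinVariant,
    target: Target,
    rng: np.random.Generator | None = None,
):
    """True activity of one variant on one target.

    Module compatibility is looked up by half identity; a half absent from
    the libraries contributes zero compatibility (an unscreened module).
    With ``rng=None`` the score is the deterministic noise-free value.
    """
    from .scaffold import ActivityScore

    regions = extract_regions(target)
    half5 = {p: variant.residues[p] for p in P5N3_POSITIONS}
    half11 = {p: variant.residues[p] for p in P11N4_POSITIONS}
    i5 = model.lib5._half_index.get(model.lib5._half_key(half5))
    i11 = model.lib11._half_index.get(model.lib11._half_key(half11))
    a5 = model.latent5[i5, model._j5[regions.r5N3]] if i5 is not None else 0.0
    a11 = model.latent11[i11, model._j11[regions.r11N4]] if i11 is not None else 0.0
    z = (
        model.bias
        + model.w5 * a5
        + model.w11 * a11
        + model.sequence_effect(variant.residues, target)
    )
    if rng is not None and model.noise_sd > 0:
        z += rng.normal(0.0, model.noise_sd)
    score = float(np.clip(z, 0.0, 1.0))
    return ActivityScore(score, score >= model.tau_active)


def _sample_target(rng: np.random.Generator, combo: int) -> Target:
    space5 = enumerate_region_space("5N3")
    space11 = enumerate_region_space("11N4")
    r11 = space11[combo // len(space5)]
    r5 = space5[combo % len(space5)]
    return build_palindrome("GTAC"[2:] + r5 + _WT_R7N2 + r11, None)


def _calibrated_bias(
    model: GroundTruthModel,
    seed: int,
    target_rate: float,
    n_modules: int,
    n_probe_targets: int = 20,
    n_probe_pairs: int = 2000,
) -> float:
    """Bias giving the requested marginal active rate in screened pools.

    The randomly drawn world-level effects shift the mean of the activity
    scale from world to world; a small probe simulation pins the quantile of
    the pre-clipping score so that the fraction of candidates reaching the
    activity threshold matches the target rate (about 15 positives in an
    1,160-candidate pool under the defaults).
    """
    rng = np.random.default_rng([seed, 90_001])
    n_combo = len(model.lib5.region_targets) * len(model.lib11.region_targets)
    zs = []
    for _ in range(n_probe_targets):
        target = _sample_target(rng, int(rng.integers(n_combo)))
        regions = extract_regions(target)
        p5 = model.lib5.top_modules(regions.r5N3, n_modules)
        p11 = model.lib11.top_modules(regions.r11N4, n_modules)
        pairs = list(
            zip(
                rng.choice(p5, size=n_probe_pairs),
                rng.choice(p11, size=n_probe_pairs),
            )
        )
        zs.append(model._pool_z(pairs, target, rng))
    z = np.concatenate(zs)
    return model.bias + model.tau_active - float(np.quantile(z, 1.0 - target_rate))


def generate_screening_dataset(
    model: GroundTruthModel,
    n_targets: int = 251,
    oversampling: float = 3.0,
    seed: int = 0,
    n_modules_mean: float = 35.0,
    n_modules_sd: float = 4.0,
    target_positive_rate: float | None = 15.0 / 1160.0,
    max_retries: int = 50,
) -> ScreeningDataset:
    """Simulate screening of combinatorial pools on ``n_targets`` distinct
    GTAC-centered pseudopalindromic targets.

    Per target: the modules most active (by measured library activity) on
    its 5N3 and 11N4 regions are pooled (about 35 a side), assembled at the
    given oversampling, and scored against the ground truth; positives are
    "sequenced" and everything else becomes an assumed negative.  Targets
    whose pool yields no positive are rejection-resampled, mirroring the
    real dataset in which every target had at least one positive mutant.

    Unless ``target_positive_rate`` is None, the model bias is first
    calibrated (on a probe simulation) so that the marginal fraction of
    active candidates matches the rate — about 15 positives per
    1,160-candidate pool by default.
    """
    if target_positive_rate is not None:
        bias = _calibrated_bias(
            model, seed, target_positive_rate, int(round(n_modules_mean))
        )
        model = dataclasses.replace(model, bias=bias)
    rng = np.random.default_rng(seed)
    n_combo = len(model.lib5.region_targets) * len(model.lib11.region_targets)
    if n_targets > n_combo:
        raise ValueError("more targets requested than distinct region combinations")
    pools: list[CombinatorialPool] = []
    records = []
    used: set[int] = set()
    for _ in range(n_targets):
        for attempt in range(max_retries):
            combo = int(rng.integers(n_combo))
            if combo in used:
                continue
            target = _sample_target(rng, combo)
            regions = extract_regions(target)
            n5_sel = int(np.clip(round(rng.normal(n_modules_mean, n_modules_sd)),
                                 15, len(model.lib5)))
            n11_sel = int(np.clip(round(rng.normal(n_modules_mean, n_modules_sd)),
                                  15, len(model.lib11)))
            p5_idx = model.lib5.top_modules(regions.r5N3, n5_sel)
            p11_idx = model.lib11.top_modules(regions.r11N4, n11_sel)
            pool = assemble_pool(
                model.lib5, model.lib11, target, p5_idx, p11_idx,
                oversampling=oversampling, seed=rng,
            )
            scores = model.pool_scores(pool.module_pairs, target, rng)
            positive = scores >= model.tau_active
            if not positive.any():
                continue
            pool.sequenced_positives = {
                pool.candidates[i].key: float(scores[i])
                for i in np.flatnonzero(positive)
            }
            pool.provenance["seed"] = seed
            used.add(combo)
            pools.append(pool)
            records.append(label_pool(pool))
            break
        else:
            raise RuntimeError(
                f"could not generate a pool with >=1 positive in {max_retries} tries; "
                "the activity threshold and effect scales are miscalibrated"
            )
    sizes = [len(p) for p in pools]
    npos = [len(p.sequenced_positives) for p in pools]
    meta = {
        "seed": seed,
        "oversampling": oversampling,
        "n_targets": n_targets,
        "mean_pool_size": float(np.mean(sizes)),
        "mean_positives_per_target": float(np.mean(npos)),
        "ground_truth": model.effects_dict(),
    }
    return ScreeningDataset(model.lib5, model.lib11, pools, records, meta)


@dataclass
class SpecificityDataset:
    """p5N3 mutants screened on all 64 5N3 region targets."""

    mutants: list[ProteinVariant]
    activities: pd.DataFrame  # mutants x 64 region targets, scores in [0,1]
    tau_active: float

    @property
    def labels(self) -> pd.DataFrame:
        return self.activities >= self.tau_active

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.to_numpy().mean())


def generate_specificity_dataset(
    model: GroundTruthModel,
    n_mutants: int = 2576,
    seed: int = 0,
    decay: float = 0.15,
    promiscuity_link: float = 0.40,
    quality_range: tuple[float, float] = (0.55, 1.0),
    target_positive_fraction: float | None = 0.066,
    max_retries: int = 200,
) -> SpecificityDataset:
    """Simulate a full mutant x 5N3-target activity matrix.

    Mutants carry a random p5N3 half (p11N4 half fixed to wild type), each
    with a cognate 5N3 target and quality; activity decays with Hamming
    distance from the cognate and is modulated by the planted sequence
    effects against each target.  Mutants with no active target are
    rejection-resampled, so every row has at least one positive.

    ``promiscuity_link`` encodes the classic activity/specificity trade-off:
    a mutant's off-cognate decay rises from ``decay`` (most specific) to
    ``decay + promiscuity_link`` linearly in its quality, so the most active
    mutants spread their activity over neighboring targets.  Set it to 0 for
    a world without the trade-off.
    """
    rng = np.random.default_rng(seed)
    space = enumerate_region_space("5N3")
    dist = np.array(
        [[sum(a != b for a, b in zip(c, s)) for s in space] for c in space]
    )
    wt11 = {p: WT_RESIDUES[p] for p in P11N4_POSITIONS}
    fixed_r11 = "AAAA"  # distal region held constant across the 5N3 space
    # nucleotide masks over the 64-target space, per 5N3 offset
    nt_mask = {
        (off, nt): np.array([s[off] == nt for s in space], dtype=float)
        for off in range(3)
        for nt in "ACGT"
    }
    # target-independent contribution of the wild-type p11 half
    wt_const = sum(model.nonspecific.get((p, a), 0.0) for p, a in wt11.items())
    for ((p1, a1), (p2, a2)), e in model.m2m.items():
        if wt11.get(p1) == a1 and wt11.get(p2) == a2:
            wt_const += e
    for (p, a, region, off, nt), e in model.m2t.items():
        if region == "r11N4" and wt11.get(p) == a and fixed_r11[off] == nt:
            wt_const += e

    def _effect_vector(half5: Mapping[int, str]) -> np.ndarray:
        merged = {**wt11, **half5}
        eff = wt_const + sum(
            model.nonspecific.get((p, a), 0.0) for p, a in half5.items()
        )
        for ((p1, a1), (p2, a2)), e in model.m2m.items():
            # pairs fully inside the wild-type half are already in wt_const
            if p1 not in half5 and p2 not in half5:
                continue
            if merged.get(p1) == a1 and merged.get(p2) == a2:
                eff += e
        out = np.full(len(space), eff)
        for (p, a, region, off, nt), e in model.m2t.items():
            if region == "r5N3" and half5.get(p) == a:
                out += e * nt_mask[(off, nt)]
        return out

    q_lo, q_hi = quality_range

    def _draw_row(r: np.random.Generator):
        half5 = {p: _sample_residue(r, p) for p in P5N3_POSITIONS}
        cognate = int(r.integers(len(space)))
        quality = r.uniform(q_lo, q_hi)
        d = decay + promiscuity_link * (quality - q_lo) / (q_hi - q_lo)
        base = quality * d ** dist[cognate]
        return half5, base + _effect_vector(half5) + r.normal(
            0.0, model.noise_sd, size=len(space)
        )

    # probe calibration: shift the scale so the marginal positive fraction
    # matches the requested rate despite world-level effect draws
    shift = 0.0
    if target_positive_fraction is not None:
        probe_rng = np.random.default_rng([seed, 90_002])
        probe = np.stack([_draw_row(probe_rng)[1] for _ in range(400)])

        def _frac_after_rejection(s: float) -> float:
            pos = probe + s >= model.tau_active
            kept = pos[pos.any(axis=1)]
            return float(kept.mean()) if len(kept) else 0.0

        lo, hi = -2.0, 2.0  # bisect: fraction is nondecreasing in the shift
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _frac_after_rejection(mid) < target_positive_fraction:
                lo = mid
            else:
                hi = mid
        shift = 0.5 * (lo + hi)

    mutants: list[ProteinVariant] = []
    rows = []
    for _ in range(n_mutants):
        for attempt in range(max_retries):
            half5, z = _draw_row(rng)
            variant = ProteinVariant.from_halves(half5, wt11)
            scores = np.clip(z + shift, 0.0, 1.0)
            if (scores >= model.tau_active).any():
                mutants.append(variant)
                rows.append(scores)
                break
        else:
            raise RuntimeError(
                "could not draw a mutant active on at least one target; "
                "the specificity calibration is off"
            )
    activities = pd.DataFrame(
        np.array(rows), index=[m.key for m in mutants], columns=space
    )
    return SpecificityDataset(mutants, activities, model.tau_active)
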