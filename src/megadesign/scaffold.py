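"""Domain types and the I-CreI target coordinate system.

I-CreI is a homodimeric LAGLIDADG meganuclease that cuts a 22 bp
pseudopalindromic DNA site.  Positions on the site are indexed from the
center, -11..-1 and +1..+11 (there is no position 0).  The right half-site
decomposes into four named regions:

* ``2N4``  -- the four central bases (-2,-1,+1,+2), cut but not contacted;
* ``5N3``  -- bases +3..+5, contacted by residues 44, 68, 70 (and the
  backbone-contacting 75, 77);
* ``7N2``  -- bases +6,+7, contacted by scaffold residues not varied here;
* ``11N4`` -- bases +8..+11, contacted by residues 30, 32, 33, 38, 40.

On a pseudopalindromic site the minus-strand regions are the reverse
complements of the plus-strand ones, so the whole site is determined by the
right half plus the central four bases.  All slicing lives in this module;
the rest of the package works with named regions only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "DNA_ALPHABET",
    "AMINO_ACIDS",
    "P5N3_POSITIONS",
    "P11N4_POSITIONS",
    "KEY_POSITIONS",
    "WT_RESIDUES",
    "WT_TARGET_SEQ",
    "STRONG_THRESHOLD",
    "REGION_LENGTHS",
    "InvalidSequenceError",
    "Target",
    "RegionDecomposition",
    "ProteinVariant",
    "ActivityScore",
    "revcomp",
    "extract_regions",
    "build_palindrome",
    "reduce_to_palindromes",
    "substitute_center",
    "target_distance",
    "enumerate_region_space",
    "read_targets_fasta",
    "targets_to_frame",
]

DNA_ALPHABET = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Interface residues contacting the 5N3 region (the "p5N3" module half).
P5N3_POSITIONS: tuple[int, ...] = (44, 68, 70, 75, 77)
#: Interface residues contacting the 11N4 region (the "p11N4" module half).
P11N4_POSITIONS: tuple[int, ...] = (30, 32, 33, 38, 40)
KEY_POSITIONS: tuple[int, ...] = tuple(sorted(P5N3_POSITIONS + P11N4_POSITIONS))

#: Wild-type I-CreI residues at the key interface positions.
WT_RESIDUES: Mapping[int, str] = {
    30: "N", 32: "S", 33: "Y", 38: "Q", 40: "S",
    44: "Q", 68: "R", 70: "R", 75: "D", 77: "I",
}

#: Default wild-type site: the palindromic 22-mer derived from the left half
#: of the natural I-CreI target (GTAC center).  Configurable, not assumed.
WT_TARGET_SEQ = "CAAAACGTCGTACGACGTTTTG"

#: Normalized cleavage activity above which a variant counts as strongly active.
STRONG_THRESHOLD = 0.8

REGION_LENGTHS = {"2N4": 4, "5N3": 3, "7N2": 2, "11N4": 4}

# right-half slice bounds on the 22-mer (0-based python indices)
_SLICES = {"2N4": (9, 13), "5N3": (13, 16), "7N2": (16, 18), "11N4": (18, 22)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """Raised for sequences with the wrong alphabet or length."""


def _check_dna(seq: str, length: int | None = None, what: str = "sequence") -> str:
    if not isinstance(seq, str):
        raise InvalidSequenceError(f"{what} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if length is not None and len(seq) != length:
        raise InvalidSequenceError(f"{what} must be {length} bases, got {len(seq)}")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-ACGT characters {sorted(bad)}; "
            "degenerate/IUPAC bases are not supported"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a plain ACGT string."""
    return _check_dna(seq, what="sequence").translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Target:
    """A 22 bp DNA site, positions -11..-1,+1..+11 from the center."""

    full_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_seq", _check_dna(self.full_seq, 22, "target"))

    @property
    def left_half(self) -> str:
        return self.full_seq[:11]

    @property
    def right_half(self) -> str:
        return self.full_seq[11:]

    @property
    def is_pseudopalindromic(self) -> bool:
        return self.full_seq == revcomp(self.full_seq)

    def base_at(self, position: int) -> str:
        """Base at a signed position in -11..-1, +1..+11."""
        if position == 0 or not -11 <= position <= 11:
            raise ValueError(f"position must be in -11..-1,+1..+11, got {position}")
        idx = 10 + position if position > 0 else 11 + position
        return self.full_seq[idx]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full_seq


@dataclass(frozen=True)
class RegionDecomposition:
    """Named regions of the right half-site (plus the central 2N4)."""

    r2N4: str
    r5N3: str
    r7N2: str
    r11N4: str

    def __post_init__(self) -> None:
        for name, length in REGION_LENGTHS.items():
            attr = f"r{name}"
            object.__setattr__(self, attr, _check_dna(getattr(self, attr), length, attr))

    def to_target(self) -> Target:
        """Reassemble the pseudopalindromic 22-mer these regions came from."""
        right = self.r2N4[2:] + self.r5N3 + self.r7N2 + self.r11N4
        left = revcomp(self.r11N4) + revcomp(self.r7N2) + revcomp(self.r5N3) + self.r2N4[:2]
        return Target(left + right)


def extract_regions(t: Target) -> RegionDecomposition:
    """Slice a target into its named right-half regions."""
    s = t.full_seq
    return RegionDecomposition(
        *(s[a:b] for a, b in (_SLICES["2N4"], _SLICES["5N3"], _SLICES["7N2"], _SLICES["11N4"]))
    )


def build_palindrome(half: str, center2: str | None = None) -> Target:
    """Build a pseudopalindromic target from its right half-site.

    Parameters
    ----------
    half:
        Either the full 11-base right half (positions +1..+11), or the 9
        bases at positions +3..+11 when `center2` is given.
    center2:
        Bases at positions +1,+2 (the right half of the central 2N4 region),
        prepended to `half` when provided.
    """
    if center2 is not None:
        half = _check_dna(center2, 2, "center2") + _check_dna(half, 9, "half (+3..+11)")
    half = _check_dna(half, 11, "right half-site")
    return Target(revcomp(half) + half)


def reduce_to_palindromes(t: Target) -> tuple[Target, Target]:
    """Split a (generally non-palindromic) site into two pseudopalindromes.

    A non-palindromic target is handled by designing one meganuclease per
    half: the left half is mirrored into a left-derived palindrome and the
    right half into a right-derived one.  A pseudopalindromic input is a
    fixed point (both outputs equal the input).
    """
    left, right = t.left_half, t.right_half
    return Target(left + revcomp(left)), Target(revcomp(right) + right)


def substitute_center(t: Target, center4: str = "GTAC") -> Target:
    """Replace the central 2N4 region (positions -2..+2) of a target.

    The 2N4 region is cleaved but not contacted by the interface residues;
    its effect on activity is independent of the other regions, so models
    here ignore it and GTAC substitution is offered as a target transform.
    """
    center4 = _check_dna(center4, 4, "center4")
    a, b = _SLICES["2N4"]
    return Target(t.full_seq[:a] + center4 + t.full_seq[b:])


_DEFAULT_SCOPE = ("r11N4", "r5N3")


def target_distance(
    t1: Target, t2: Target, scope: Sequence[str] = _DEFAULT_SCOPE
) -> int:
    """Hamming distance between two targets over a set of named regions.

    The default scope is the modeled half-site regions ``r11N4`` and
    ``r5N3`` — the regions the combinatorial process varies.
    """
    r1, r2 = extract_regions(t1), extract_regions(t2)
    valid = {"r2N4", "r5N3", "r7N2", "r11N4", "full"}
    dist = 0
    for name in scope:
        if name not in valid:
            raise ValueError(f"unknown region {name!r} in scope")
        if name == "full":
            a, b = t1.full_seq, t2.full_seq
        else:
            a, b = getattr(r1, name), getattr(r2, name)
        dist += sum(x != y for x, y in zip(a, b))
    return dist


def enumerate_region_space(region: str) -> list[str]:
    """All ACGT strings of a region's length, lexicographically sorted.

    ``"5N3"`` yields the 64 three-base targets, ``"11N4"`` the 256
    four-base targets (the spaces the module libraries are screened on).
    """
    name = region.lstrip("rp")
    if name not in ("5N3", "11N4"):
        raise ValueError(f"unknown region {region!r}; expected '5N3' or '11N4'")
    n = REGION_LENGTHS[name]
    return ["".join(p) for p in itertools.product("ACGT", repeat=n)]


@dataclass(frozen=True)
class ProteinVariant:
    """Residues of an I-CreI variant at the ten key interface positions.

    The positions split into two disjoint halves: the p5N3 half
    (44, 68, 70, 75, 77) and the p11N4 half (30, 32, 33, 38, 40).
    Auxiliary mutations outside the interface (e.g. the activity-boosting
    I132V) are carried as opaque metadata tags only.
    """

    residues: Mapping[int, str]
    extra_mutations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        res = dict(self.residues)
        missing = set(KEY_POSITIONS) - set(res)
        extra = set(res) - set(KEY_POSITIONS)
        if missing:
            raise ValueError(f"variant missing key positions {sorted(missing)}")
        if extra:
            raise ValueError(f"unexpected positions {sorted(extra)}")
        for pos, aa in res.items():
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid {aa!r} at position {pos}")
        object.__setattr__(self, "residues", res)
        object.__setattr__(self, "extra_mutations", frozenset(self.extra_mutations))

    @property
    def p5_half(self) -> tuple[str, ...]:
        return tuple(self.residues[p] for p in P5N3_POSITIONS)

    @property
    def p11_half(self) -> tuple[str, ...]:
        return tuple(self.residues[p] for p in P11N4_POSITIONS)

    @property
    def key(self) -> str:
        """Canonical string form, used as identifier and ranking tie-break."""
        return "".join(self.residues[p] for p in KEY_POSITIONS)

    @classmethod
    def from_halves(
        cls,
        p5: Mapping[int, str] | Sequence[str],
        p11: Mapping[int, str] | Sequence[str],
        extra_mutations: Iterable[str] = (),
    ) -> "ProteinVariant":
        res: dict[int, str] = {}
        for positions, half in ((P5N3_POSITIONS, p5), (P11N4_POSITIONS, p11)):
            if isinstance(half, Mapping):
                res.update(half)
            else:
                res.update(zip(positions, half))
        return cls(res, frozenset(extra_mutations))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return " ".join(f"{self.residues[p]}{p}" for p in KEY_POSITIONS)


@dataclass(frozen=True)
class ActivityScore:
    """Normalized cleavage activity in [0,1] with its binary screen label."""

    value: float
    label: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"activity must be in [0,1], got {self.value}")
        if self.strong and not self.label:
            raise ValueError("a strongly active score cannot be labeled inactive")

    @property
    def strong(self) -> bool:
        return self.value >= STRONG_THRESHOLD


def read_targets_fasta(path) -> list[Target]:
    """Read 22-mer targets from a FASTA file (one record per target)."""
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        targets.append(Target(str(rec.seq).upper()))
    return targets


def targets_to_frame(targets: Iterable[Target]) -> pd.DataFrame:
    """Tabulate targets as the full 22-mer plus derived region columns."""
    rows = []
    for t in targets:
        r = extract_regions(t)
        rows.append(
            {
                "full_seq": t.full_seq,
                "r2N4": r.r2N4,
                "r5N3": r.r5N3,
                "r7N2": r.r7N2,
                "r11N4": r.r11N4,
                "pseudopalindromic": t.is_pseudopalindromic,
            }
        )
    return pd.DataFrame(rows)
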