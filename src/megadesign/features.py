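"""Design-matrix construction: categorical, one-hot (Bin1) and
one-hot-plus-pairwise-interaction (Bin2) encodings, and the named
feature-group subsets used in the ablation analysis.

Every (variant, target) record is described by

* ten protein columns, one per key interface position (``P44`` ...);
* seven target columns, one per base of the modeled half-site regions
  (``T5N3.1..3``, ``T11N4.1..4``; the uncontacted 2N4 center and the
  invariant 7N2 region contribute no features);
* two real-valued module-activity columns ``Mact5``/``Mact11``: the measured
  cleavage activity of the record's p5N3 (p11N4) half on the target's 5N3
  (11N4) region, looked up in the module libraries.

Bin1 one-hot-expands the categorical columns; Bin2 appends elementwise
products of pairs of Bin1 columns to encode second-order interactions,
classed as M2M (protein x protein) or M2T (protein x target) and as
intra-module or cross-module.  Column metadata records enough provenance to
reconstruct any named group subset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .combinatorial import ModuleLibrary, ScreeningRecord
from .scaffold import (
    KEY_POSITIONS,
    P5N3_POSITIONS,
    P11N4_POSITIONS,
    ProteinVariant,
    Target,
    extract_regions,
)

__all__ = [
    "FeatureColumn",
    "FeatureMatrix",
    "FEATURE_GROUPS",
    "INTERACTION_GROUPS",
    "encode_categorical",
    "encode_bin1",
    "add_interactions",
    "select_group",
    "encode_binary_like",
    "encode_categorical_like",
]

#: Code used for a module-activity lookup that cannot be resolved.  Kept as
#: NaN (never a silent zero) so downstream learners treat it as missing.
MISSING_ACTIVITY = np.nan

_TARGET_COLS = [("T5N3", i, "r5N3") for i in range(3)] + [
    ("T11N4", i, "r11N4") for i in range(4)
]


@dataclass(frozen=True)
class FeatureColumn:
    """Metadata for one design-matrix column.

    ``block`` is the parent categorical column for order-1 binary columns
    (e.g. ``P44`` for ``P44=R``); ``iclass`` classifies order-2 products as
    M2M/M2T/T2T by their parents' sources.
    """

    name: str
    source: str  # protein_seq | target_seq | module_activity | interaction | external
    module_side: str  # p5N3 | p11N4 | cross | none
    order: int = 1
    kind: str = "categorical"  # categorical | binary | real
    block: str | None = None
    level: str | None = None
    parents: tuple[str, str] | None = None
    iclass: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.order == 2 and (self.parents is None or len(self.parents) != 2):
            raise ValueError("order-2 columns need exactly two parents")
        if self.order == 1 and self.parents is not None:
            raise ValueError("order-1 columns cannot have parents")


class FeatureMatrix:
    """Columns plus values; values are a DataFrame (categorical encoding)
    or a scipy sparse matrix (binary encodings)."""

    def __init__(self, columns: Sequence[FeatureColumn], values) -> None:
        self.columns = list(columns)
        self.values = values
        n_cols = values.shape[1]
        if n_cols != len(self.columns):
            raise ValueError(f"{len(self.columns)} columns but {n_cols} value columns")
        self._index = {c.name: i for i, c in enumerate(self.columns)}
        if len(self._index) != len(self.columns):
            raise ValueError("duplicate column names")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column_support(self) -> np.ndarray:
        """Number of nonzero entries per column (NaN counts as zero)."""
        if isinstance(self.values, pd.DataFrame):
            raise TypeError("support is defined for numeric matrices only")
        X = sp.csc_matrix(self.values)
        return np.diff(X.indptr)

    def subset(self, names: Iterable[str]) -> "FeatureMatrix":
        idx = [self._index[n] for n in names]
        cols = [self.columns[i] for i in idx]
        if isinstance(self.values, pd.DataFrame):
            return FeatureMatrix(cols, self.values.iloc[:, idx])
        return FeatureMatrix(cols, sp.csc_matrix(self.values)[:, idx].tocsr())


def _protein_side(pos: int) -> str:
    return "p5N3" if pos in P5N3_POSITIONS else "p11N4"


def _order1_columns() -> list[FeatureColumn]:
    cols = [
        FeatureColumn(f"P{p}", "protein_seq", _protein_side(p))
        for p in KEY_POSITIONS
    ]
    for region, i, _ in _TARGET_COLS:
        side = "p5N3" if region == "T5N3" else "p11N4"
        cols.append(FeatureColumn(f"{region}.{i + 1}", "target_seq", side))
    cols.append(FeatureColumn("Mact5", "module_activity", "p5N3", kind="real"))
    cols.append(FeatureColumn("Mact11", "module_activity", "p11N4", kind="real"))
    return cols


def _raw_frame(
    records: Sequence[ScreeningRecord],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> pd.DataFrame:
    data: dict[str, list] = {f"P{p}": [] for p in KEY_POSITIONS}
    for region, i, _ in _TARGET_COLS:
        data[f"{region}.{i + 1}"] = []
    data["Mact5"], data["Mact11"] = [], []
    for rec in records:
        regions = extract_regions(rec.target)
        for p in KEY_POSITIONS:
            data[f"P{p}"].append(rec.variant.residues[p])
        for region, i, attr in _TARGET_COLS:
            data[f"{region}.{i + 1}"].append(getattr(regions, attr)[i])
        a5 = lib5.activity_of(
            {p: rec.variant.residues[p] for p in P5N3_POSITIONS}, regions.r5N3
        )
        a11 = lib11.activity_of(
            {p: rec.variant.residues[p] for p in P11N4_POSITIONS}, regions.r11N4
        )
        data["Mact5"].append(MISSING_ACTIVITY if a5 is None else a5)
        data["Mact11"].append(MISSING_ACTIVITY if a11 is None else a11)
    return pd.DataFrame(data)


def encode_categorical(
    records: Sequence[ScreeningRecord],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> FeatureMatrix:
    """Categorical design matrix: 10 protein + 7 target string columns plus
    the two real module-activity columns (the tree-learner representation)."""
    df = _raw_frame(records, lib5, lib11)
    cols = []
    for c in _order1_columns():
        if c.kind == "real":
            cols.append(c)
        else:
            levels = tuple(sorted(df[c.name].unique()))
            cols.append(replace(c, levels=levels))
    return FeatureMatrix(cols, df)


def _binary_columns(
    cat: FeatureMatrix,
) -> tuple[list[FeatureColumn], list[FeatureColumn]]:
    """Expand categorical column metadata into one binary column per level."""
    binary, real = [], []
    for c in cat.columns:
        if c.kind == "real":
            real.append(c)
            continue
        for level in c.levels or ():
            binary.append(
                FeatureColumn(
                    f"{c.name}={level}",
                    c.source,
                    c.module_side,
                    kind="binary",
                    block=c.name,
                    level=level,
                )
            )
    return binary, real


def _indicator_array(
    frame: pd.DataFrame, binary_cols: Sequence[FeatureColumn]
) -> np.ndarray:
    out = np.zeros((len(frame), len(binary_cols)), dtype=np.uint8)
    for j, c in enumerate(binary_cols):
        out[:, j] = (frame[c.block].to_numpy() == c.level).astype(np.uint8)
    return out


def encode_bin1(
    records: Sequence[ScreeningRecord],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> FeatureMatrix:
    """One-hot expansion of the categorical matrix (Bin1).

    Each binary column encodes one residue at one protein position or one
    nucleotide at one target position; module-activity columns pass through
    as reals.  Levels are those observed in ``records``; at predict time an
    unseen level yields an all-zero block (see :func:`encode_binary_like`).
    """
    cat = encode_categorical(records, lib5, lib11)
    binary_cols, real_cols = _binary_columns(cat)
    D = _indicator_array(cat.values, binary_cols)
    reals = cat.values[[c.name for c in real_cols]].to_numpy(dtype=float)
    X = sp.hstack([sp.csr_matrix(D.astype(float)), sp.csr_matrix(reals)], format="csr")
    return FeatureMatrix(binary_cols + real_cols, X)


def _product_meta(c1: FeatureColumn, c2: FeatureColumn) -> FeatureColumn:
    sources = {c1.source, c2.source}
    if sources == {"protein_seq"}:
        iclass = "M2M"
    elif sources == {"protein_seq", "target_seq"}:
        iclass = "M2T"
    else:
        iclass = "T2T"
    side = c1.module_side if c1.module_side == c2.module_side else "cross"
    return FeatureColumn(
        f"{c1.name}*{c2.name}",
        "interaction",
        side,
        order=2,
        kind="binary",
        parents=(c1.name, c2.name),
        iclass=iclass,
    )


def add_interactions(
    bin1: FeatureMatrix,
    min_support: int = 200,
    rule: str = "parent",
    include_t2t: bool = False,
) -> FeatureMatrix:
    """Append pairwise products of Bin1 columns (the Bin2 encoding).

    Products are taken over unordered pairs of distinct order-1 *sequence*
    binary columns (module-activity reals are not binarized and do not
    interact).  The support filter keeps the enumeration bounded:

    * ``rule="parent"`` (default): both parents must have more than
      ``min_support`` nonzero entries;
    * ``rule="product"``: the product itself must have more than
      ``min_support`` nonzero entries (parents are pre-pruned by the same
      bound, which is sound since a product's support cannot exceed either
      parent's).

    Products of two levels of the same categorical block are identically
    zero and are dropped, as are any other identically-zero products.
    """
    if min_support < 0:
        raise ValueError("min_support must be nonnegative")
    if rule not in ("parent", "product"):
        raise ValueError(f"unknown support rule {rule!r}")
    seq_idx = [
        i
        for i, c in enumerate(bin1.columns)
        if c.order == 1 and c.kind == "binary" and c.source in ("protein_seq", "target_seq")
    ]
    X = sp.csc_matrix(bin1.values)
    D = np.asarray(X[:, seq_idx].todense(), dtype=np.uint8)
    support = D.sum(axis=0)
    eligible = [k for k in range(len(seq_idx)) if support[k] > min_support]

    prod_cols: list[FeatureColumn] = []
    rows_list: list[np.ndarray] = []
    indptr = [0]
    nnz = 0
    for a_i, a in enumerate(eligible):
        ca = bin1.columns[seq_idx[a]]
        for b in eligible[a_i + 1 :]:
            cb = bin1.columns[seq_idx[b]]
            if ca.block == cb.block:
                continue  # same one-hot block: product identically zero
            meta = _product_meta(ca, cb)
            if meta.iclass == "T2T" and not include_t2t:
                continue
            nz = np.flatnonzero(D[:, a] & D[:, b])
            if nz.size == 0:
                continue
            if rule == "product" and nz.size <= min_support:
                continue
            prod_cols.append(meta)
            rows_list.append(nz)
            nnz += nz.size
            indptr.append(nnz)
    if prod_cols:
        indices = np.concatenate(rows_list)
        data = np.ones(nnz, dtype=float)
        P = sp.csc_matrix(
            (data, indices, np.asarray(indptr)), shape=(bin1.n_rows, len(prod_cols))
        )
        values = sp.hstack([sp.csr_matrix(bin1.values), P.tocsr()], format="csr")
    else:
        values = sp.csr_matrix(bin1.values)
    return FeatureMatrix(list(bin1.columns) + prod_cols, values)


def _is_mact(c: FeatureColumn) -> bool:
    return c.source == "module_activity"


def _seq1(c: FeatureColumn, side: str | None = None) -> bool:
    return (
        c.order == 1
        and c.source in ("protein_seq", "target_seq")
        and (side is None or c.module_side == side)
    )


#: Named feature groups.  Every group contains the two module-activity
#: columns (each group is an extension of the module-activity baseline).
FEATURE_GROUPS = {
    "Mact": lambda c: _is_mact(c),
    "SM-5": lambda c: _is_mact(c) or _seq1(c, "p5N3"),
    "SM-11": lambda c: _is_mact(c) or _seq1(c, "p11N4"),
    "SM-5_11": lambda c: _is_mact(c) or _seq1(c),
    "SM-M2M": lambda c: _is_mact(c) or _seq1(c) or (c.order == 2 and c.iclass == "M2M"),
    "SM-M2T": lambda c: _is_mact(c) or _seq1(c) or (c.order == 2 and c.iclass == "M2T"),
    "SM-Intra": lambda c: _is_mact(c)
    or _seq1(c)
    or (c.order == 2 and c.module_side in ("p5N3", "p11N4")),
    "SM-Cross": lambda c: _is_mact(c)
    or _seq1(c)
    or (c.order == 2 and c.module_side == "cross"),
    "SeqMact": lambda c: _is_mact(c)
    or _seq1(c)
    or (c.order == 2 and c.iclass in ("M2M", "M2T")),
    "SeqMactFxStr-ext": lambda c: _is_mact(c)
    or _seq1(c)
    or (c.order == 2 and c.iclass in ("M2M", "M2T"))
    or c.source == "external",
}

#: Groups whose hypothesis class includes second-order interactions.
INTERACTION_GROUPS = frozenset(
    {"SM-M2M", "SM-M2T", "SM-Intra", "SM-Cross", "SeqMact", "SeqMactFxStr-ext"}
)


def select_group(matrix: FeatureMatrix, group: str) -> FeatureMatrix:
    """Deterministic column subset for a named feature group."""
    try:
        pred = FEATURE_GROUPS[group]
    except KeyError:
        raise ValueError(
            f"unknown feature group {group!r}; known: {sorted(FEATURE_GROUPS)}"
        ) from None
    return matrix.subset([c.name for c in matrix.columns if pred(c)])


def _records_like(
    records: Sequence[ScreeningRecord] | Sequence[tuple[ProteinVariant, Target]],
) -> list[ScreeningRecord]:
    out = []
    for r in records:
        if isinstance(r, ScreeningRecord):
            out.append(r)
        else:
            variant, target = r
            out.append(ScreeningRecord(variant, target, 0.0, False, False))
    return out


def encode_binary_like(
    columns: Sequence[FeatureColumn],
    records: Sequence[ScreeningRecord] | Sequence[tuple[ProteinVariant, Target]],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> FeatureMatrix:
    """Encode new records into exactly the given binary-encoding columns.

    Used at predict time so test pools align with the training design
    matrix: levels unseen in training contribute all-zero indicator blocks,
    and order-2 columns are recomputed as products of their parents.
    """
    recs = _records_like(records)
    frame = _raw_frame(recs, lib5, lib11)
    n = len(frame)
    dense: dict[str, np.ndarray] = {}
    for c in columns:
        if c.order == 1 and c.kind == "binary":
            dense[c.name] = (frame[c.block].to_numpy() == c.level).astype(float)
        elif c.kind == "real":
            dense[c.name] = frame[c.name].to_numpy(dtype=float)
    out = np.zeros((n, len(columns)))
    for j, c in enumerate(columns):
        if c.order == 2:
            p1, p2 = c.parents
            v1 = dense.get(p1)
            v2 = dense.get(p2)
            if v1 is None:
                v1 = _indicator_from_name(p1, frame)
            if v2 is None:
                v2 = _indicator_from_name(p2, frame)
            out[:, j] = v1 * v2
        else:
            out[:, j] = dense[c.name]
    return FeatureMatrix(list(columns), sp.csr_matrix(out))


def _indicator_from_name(name: str, frame: pd.DataFrame) -> np.ndarray:
    block, level = name.split("=", 1)
    return (frame[block].to_numpy() == level).astype(float)


def encode_categorical_like(
    columns: Sequence[FeatureColumn],
    records: Sequence[ScreeningRecord] | Sequence[tuple[ProteinVariant, Target]],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> pd.DataFrame:
    """Ordinal-code new records against training categorical levels.

    Unseen levels (and unresolvable module activities) become NaN, which the
    tree learner treats as missing.
    """
    recs = _records_like(records)
    frame = _raw_frame(recs, lib5, lib11)
    out = {}
    for c in columns:
        if c.kind == "real":
            out[c.name] = frame[c.name].to_numpy(dtype=float)
        else:
            cat = pd.Categorical(frame[c.name], categories=list(c.levels))
            codes = cat.codes.astype(float)
            codes[codes < 0] = np.nan
            out[c.name] = codes
    return pd.DataFrame(out)
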