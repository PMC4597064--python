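"""Typed in-memory relations and generic relational operators.

Each source modality is modelled as a relation (a :class:`pandas.DataFrame`
with a declared schema): somatic WES variants ``W``, methylation probes
``M``, copy-number segments ``C``, gene read counts ``H``, RNA variants
``RV``, transcript quantifications ``R``, the key-gene list ``K`` and
experiment metadata ``P``.  The integration pipeline is written as literal
relational algebra over these, so the operators here carry explicit null
semantics: a null key never satisfies an equality predicate, and nulls
propagate untouched through projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CHROMOSOMES",
    "normalize_chromosome",
    "WesVariant",
    "MethylationProbe",
    "CopyNumberSegment",
    "GeneCount",
    "RnaVariant",
    "TranscriptQuant",
    "GeneListEntry",
    "ExperimentMeta",
    "relation",
    "empty_relation",
    "left_outer_join",
    "equi_join",
    "intersect_on",
    "difference_on",
    "project_distinct",
    "interval_left_join",
]


class SchemaError(ValueError):
    """An operator referenced an attribute absent from a relation."""


#: Canonical chromosome labels, autosomes then sex chromosomes.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_SET = set(CHROMOSOMES)


def normalize_chromosome(label: str) -> str:
    """Map a chromosome label to the canonical ``1..22, X, Y`` dialect.

    Any ``chr`` prefix is stripped and case of X/Y is normalized, so mixed
    UCSC/Ensembl inputs integrate cleanly.
    """
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper() if lab.lower() in ("x", "y") else lab
    if lab not in _CHROM_SET:
        raise SchemaError(f"unknown chromosome label: {label!r}")
    return lab


# ---------------------------------------------------------------------------
# Domain row types.  ``kinds`` drives canonical TSV serialization and the
# dtype restoration on read (see io_formats).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WesVariant:
    """One DNA-level somatic mutation from a whole-exome experiment (W)."""

    chromosome: str
    position: int
    dna_depth: int
    dna_allelic_freq: float  # percent, 0-100
    ensembl_gene_id: str
    gene_symbol: str
    dna_change: str
    amino_acid_change: str | None
    effect_impact: str  # MODIFIER | LOW | MODERATE | HIGH
    experiment_id: str

    kinds = {
        "chromosome": "str",
        "position": "int",
        "dna_depth": "int",
        "dna_allelic_freq": "float",
        "ensembl_gene_id": "str",
        "gene_symbol": "str",
        "dna_change": "str",
        "amino_acid_change": "str",
        "effect_impact": "str",
        "experiment_id": "str",
    }

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.dna_depth <= 0:
            raise ValueError(f"dna_depth must be positive, got {self.dna_depth}")
        if not 0.0 <= self.dna_allelic_freq <= 100.0:
            raise ValueError(f"dna_allelic_freq outside [0,100]: {self.dna_allelic_freq}")
        if self.effect_impact not in ("MODIFIER", "LOW", "MODERATE", "HIGH"):
            raise ValueError(f"invalid effect_impact: {self.effect_impact!r}")


@dataclass(frozen=True)
class MethylationProbe:
    """One Infinium 450K probe with its beta value and annotation (M).

    The array vendor's single annotation string is carried as two fields,
    the regulatory-feature group and the relation to the nearest CpG
    island, matching how methylation exports print them.
    """

    target_id: str
    avg_beta: float  # fraction, 0-1
    regulatory_feature: str | None
    relation_to_cpg_island: str | None
    ensembl_gene_id: str | None
    experiment_id: str

    kinds = {
        "target_id": "str",
        "avg_beta": "float",
        "regulatory_feature": "str",
        "relation_to_cpg_island": "str",
        "ensembl_gene_id": "str",
        "experiment_id": "str",
    }

    def __post_init__(self):
        if not 0.0 <= self.avg_beta <= 1.0:
            raise ValueError(f"avg_beta outside [0,1]: {self.avg_beta}")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval with an integer tumor copy number (C).

    Intervals are 1-based and closed: a variant at ``position`` lies in the
    segment iff ``start <= position <= stop``.
    """

    chromosome: str
    start: int
    stop: int
    copy_number: int
    experiment_id: str

    kinds = {
        "chromosome": "str",
        "start": "int",
        "stop": "int",
        "copy_number": "int",
        "experiment_id": "str",
    }

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start > self.stop:
            raise ValueError(f"segment start {self.start} > stop {self.stop}")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")


@dataclass(frozen=True)
class GeneCount:
    """Raw (unnormalized) read count for one gene (H)."""

    ensembl_gene_id: str
    count: int
    experiment_id: str

    kinds = {"ensembl_gene_id": "str", "count": "int", "experiment_id": "str"}

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class RnaVariant:
    """One variant called from RNA-seq reads (RV)."""

    chromosome: str
    position: int
    ensembl_gene_id: str
    rna_depth: int
    rna_allelic_freq: float  # percent
    experiment_id: str

    kinds = {
        "chromosome": "str",
        "position": "int",
        "ensembl_gene_id": "str",
        "rna_depth": "int",
        "rna_allelic_freq": "float",
        "experiment_id": "str",
    }

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.rna_depth <= 0:
            raise ValueError(f"rna_depth must be positive, got {self.rna_depth}")
        if not 0.0 <= self.rna_allelic_freq <= 100.0:
            raise ValueError(f"rna_allelic_freq outside [0,100]: {self.rna_allelic_freq}")


@dataclass(frozen=True)
class TranscriptQuant:
    """FPKM quantification of one isoform (R); assembler-novel ids allowed."""

    ensembl_transcript_id: str
    ensembl_gene_id: str
    fpkm: float
    experiment_id: str

    kinds = {
        "ensembl_transcript_id": "str",
        "ensembl_gene_id": "str",
        "fpkm": "float",
        "experiment_id": "str",
    }

    def __post_init__(self):
        if self.fpkm < 0:
            raise ValueError(f"fpkm must be >= 0, got {self.fpkm}")


@dataclass(frozen=True)
class GeneListEntry:
    """A key-gene or tumor-suppressor list entry (K)."""

    ensembl_gene_id: str
    gene_symbol: str | None = None
    classification: str | None = None

    kinds = {"ensembl_gene_id": "str", "gene_symbol": "str", "classification": "str"}


@dataclass(frozen=True)
class ExperimentMeta:
    """Patient / experiment metadata row (P)."""

    patient_id: str
    experiment_id: str
    experiment_description: str | None = None
    sample_type: str | None = None
    sample_description: str | None = None
    experiment_date: str | None = None
    sample_collection_date: str | None = None

    kinds = {
        "patient_id": "str",
        "experiment_id": "str",
        "experiment_description": "str",
        "sample_type": "str",
        "sample_description": "str",
        "experiment_date": "str",
        "sample_collection_date": "str",
    }


_ROW_TYPES = (
    WesVariant,
    MethylationProbe,
    CopyNumberSegment,
    GeneCount,
    RnaVariant,
    TranscriptQuant,
    GeneListEntry,
    ExperimentMeta,
)


def columns_of(row_type) -> list[str]:
    return [f.name for f in dc_fields(row_type)]


def relation(rows: Iterable, row_type=None) -> pd.DataFrame:
    """Build a relation (DataFrame) from dataclass rows.

    ``row_type`` is required when ``rows`` is empty so the schema is known.
    """
    rows = list(rows)
    if not rows:
        if row_type is None:
            raise ValueError("row_type required for an empty relation")
        return empty_relation(row_type)
    rt = row_type or type(rows[0])
    cols = columns_of(rt)
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in rows], columns=cols)
    return _apply_kinds(df, rt.kinds)


def empty_relation(row_type) -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in columns_of(row_type)})
    return _apply_kinds(df, row_type.kinds)


def _apply_kinds(df: pd.DataFrame, kinds: Mapping[str, str]) -> pd.DataFrame:
    out = df.copy()
    for col, kind in kinds.items():
        if col not in out.columns:
            continue
        if kind == "int":
            out[col] = out[col].astype("Int64")
        elif kind == "float":
            out[col] = out[col].astype("float64")
        else:
            out[col] = out[col].astype("object")
            out[col] = out[col].where(pd.notna(out[col]), None)
    return out


# ---------------------------------------------------------------------------
# Generic operators
# ---------------------------------------------------------------------------


def _check_attrs(rel: pd.DataFrame, attrs: Sequence[str], side: str) -> None:
    missing = [a for a in attrs if a not in rel.columns]
    if missing:
        raise SchemaError(f"unknown attribute(s) in {side} relation: {', '.join(missing)}")


def _as_pairs(keys) -> list[tuple[str, str]]:
    pairs = []
    for k in keys:
        if isinstance(k, str):
            pairs.append((k, k))
        else:
            a, b = k
            pairs.append((a, b))
    return pairs


def _check_disjoint(left: pd.DataFrame, right: pd.DataFrame, right_keys: Sequence[str]) -> None:
    clash = (set(left.columns) & set(right.columns)) - set(right_keys)
    if clash:
        raise SchemaError(
            "non-key attributes present on both sides (rename before joining): "
            + ", ".join(sorted(clash))
        )


def _align_key_dtypes(left, right, pairs):
    """Cast mismatched join-key dtypes to object so merge can compare them."""
    left, right = left.copy(), right.copy()
    for a, b in pairs:
        if left[a].dtype != right[b].dtype:
            left[a] = left[a].astype(object)
            right[b] = right[b].astype(object)
    return left, right


def left_outer_join(
    left: pd.DataFrame,
    right: pd.DataFrame,
    predicate: Sequence | Callable[[pd.Series, pd.Series], bool],
) -> pd.DataFrame:
    """Left-outer join: every left tuple survives; unmatched rows carry nulls.

    ``predicate`` is either a sequence of key pairs ``[(left_attr,
    right_attr), ...]`` (strings when the names coincide), joined as an
    equality condition under null-never-matches semantics, or an arbitrary
    boolean callable over ``(left_row, right_row)`` evaluated by nested
    loop (adequate for the per-sample relation sizes this package handles).
    """
    if callable(predicate):
        return _predicate_left_join(left, right, predicate)
    pairs = _as_pairs(predicate)
    lk = [p[0] for p in pairs]
    rk = [p[1] for p in pairs]
    _check_attrs(left, lk, "left")
    _check_attrs(right, rk, "right")
    _check_disjoint(left, right, rk)
    left, right = _align_key_dtypes(left, right, pairs)
    # null keys never match: strip null-keyed right rows entirely, and join
    # null-keyed left rows to nothing.
    right_clean = right.dropna(subset=rk)
    merged = left.merge(
        right_clean, how="left", left_on=lk, right_on=rk, suffixes=("", "__r")
    )
    lk_null = left[lk].isna().any(axis=1)
    if lk_null.any():
        # pandas would have matched NaN==NaN; redo those rows as unmatched
        keep = merged[~merged[lk].isna().any(axis=1)]
        null_rows = left[lk_null].reindex(columns=merged.columns)
        merged = pd.concat([keep, null_rows], ignore_index=True)
    # drop duplicated right key columns when names differ from left's
    drop = [b for a, b in pairs if b != a and b in merged.columns]
    return merged.drop(columns=drop).reset_index(drop=True)


def _predicate_left_join(left, right, pred) -> pd.DataFrame:
    right_cols = [c for c in right.columns]
    clash = set(left.columns) & set(right_cols)
    if clash:
        raise SchemaError(
            "non-key attributes present on both sides (rename before joining): "
            + ", ".join(sorted(clash))
        )
    out_rows = []
    for _, lrow in left.iterrows():
        matched = False
        for _, rrow in right.iterrows():
            if pred(lrow, rrow):
                matched = True
                out_rows.append(pd.concat([lrow, rrow]))
        if not matched:
            out_rows.append(
                pd.concat([lrow, pd.Series({c: None for c in right_cols})])
            )
    if not out_rows:
        return pd.DataFrame(columns=list(left.columns) + right_cols)
    return pd.DataFrame(out_rows).reset_index(drop=True)


def equi_join(left: pd.DataFrame, right: pd.DataFrame, keys: Sequence) -> pd.DataFrame:
    """Inner equi-join on key pairs; null keys never match."""
    pairs = _as_pairs(keys)
    lk = [p[0] for p in pairs]
    rk = [p[1] for p in pairs]
    _check_attrs(left, lk, "left")
    _check_attrs(right, rk, "right")
    _check_disjoint(left, right, rk)
    left, right = _align_key_dtypes(left, right, pairs)
    left_clean = left.dropna(subset=lk)
    right_clean = right.dropna(subset=rk)
    merged = left_clean.merge(
        right_clean, how="inner", left_on=lk, right_on=rk, suffixes=("", "__r")
    )
    drop = [b for a, b in pairs if b != a and b in merged.columns]
    return merged.drop(columns=drop).reset_index(drop=True)


def intersect_on(a: pd.DataFrame, b: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Tuples of ``a`` whose key combination also occurs in ``b``.

    The output is deduplicated on the keys (first occurrence kept); null
    keys never match.
    """
    keys = list(keys)
    _check_attrs(a, keys, "left")
    _check_attrs(b, keys, "right")
    a, b = _align_key_dtypes(a, b, [(k, k) for k in keys])
    b_keys = b.dropna(subset=keys)[keys].drop_duplicates()
    a_clean = a.dropna(subset=keys)
    out = a_clean.merge(b_keys, how="inner", on=keys)
    return out.drop_duplicates(subset=keys).reset_index(drop=True)


def difference_on(a: pd.DataFrame, b: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Tuples of ``a`` whose key combination does not occur in ``b``.

    Deduplicated on the keys; a null-keyed ``a`` tuple matches nothing in
    ``b`` and is therefore retained.
    """
    keys = list(keys)
    _check_attrs(a, keys, "left")
    _check_attrs(b, keys, "right")
    b_key_set = set(map(tuple, b.dropna(subset=keys)[keys].itertuples(index=False)))
    a_dedup = a.drop_duplicates(subset=keys)
    mask = [
        tuple(row) not in b_key_set or any(pd.isna(v) for v in row)
        for row in a_dedup[keys].itertuples(index=False)
    ]
    return a_dedup[mask].reset_index(drop=True)


def _round_sig(x: float, sig: int = 10) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def project_distinct(
    rel: pd.DataFrame,
    attributes: Sequence[str],
    computed: Mapping[str, Callable[[pd.Series], object]] | None = None,
) -> pd.DataFrame:
    """Projection with duplicate elimination over the full projected tuple.

    ``computed`` maps new attribute names to per-row callables evaluated
    before projection.  Real-valued attributes are compared after rounding
    to 10 significant digits so floating-point noise does not defeat
    deduplication; the stored values are untouched.
    """
    attributes = list(attributes)
    out = rel.copy()
    if computed:
        for name, fn in computed.items():
            out[name] = [fn(row) for _, row in out.iterrows()] if len(out) else []
    _check_attrs(out, attributes, "input")
    out = out[attributes]
    if len(out) == 0:
        return out.reset_index(drop=True)

    def dedup_key(row):
        return tuple(
            _round_sig(v) if isinstance(v, float) and not pd.isna(v) else (None if pd.isna(v) else v)
            for v in row
        )

    keys = out.apply(dedup_key, axis=1)
    keep = ~keys.duplicated()
    return out[keep].reset_index(drop=True)


def interval_left_join(
    left: pd.DataFrame,
    segments: pd.DataFrame,
    *,
    chrom: str = "chromosome",
    pos: str = "position",
    seg_chrom: str = "chromosome",
    start: str = "start",
    stop: str = "stop",
    carry: Sequence[str] = ("copy_number",),
) -> pd.DataFrame:
    """Left-outer join of point loci onto closed genomic intervals.

    A left row matches a segment iff chromosomes are equal and
    ``start <= pos <= stop``.  Segments must not overlap within a
    chromosome: a locus matching two segments raises ``ValueError``.
    Unmatched rows carry null for every carried segment attribute.
    """
    _check_attrs(left, [chrom, pos], "left")
    _check_attrs(segments, [seg_chrom, start, stop, *carry], "right")
    out = left.copy()
    for c in carry:
        out[c] = pd.array([pd.NA] * len(out), dtype="object")
    if len(out) == 0 or len(segments) == 0:
        return out.reset_index(drop=True)
    seg_by_chrom = {c: g for c, g in segments.groupby(seg_chrom)}
    for idx, row in left.iterrows():
        segs = seg_by_chrom.get(row[chrom])
        if segs is None or pd.isna(row[pos]):
            continue
        hit = segs[(segs[start] <= row[pos]) & (row[pos] <= segs[stop])]
        if len(hit) > 1:
            raise ValueError(
                f"locus {row[chrom]}:{row[pos]} overlaps {len(hit)} copy-number "
                "segments; segments must be non-overlapping"
            )
        if len(hit) == 1:
            for c in carry:
                out.at[idx, c] = hit.iloc[0][c]
    return out.reset_index(drop=True)
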