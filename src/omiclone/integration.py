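"""The multi-omic integration pipeline.

Builds, by literal relational algebra, the integrated per-mutation
relation that joins filtered somatic WES variants to methylation probes
(by gene), RNA variants with transcript/count expression support (by
locus), and copy-number segments (by interval containment), then derives
the presentation tables: distinct mutations with glyphs, per-locus
transcripts, key-gene summaries, expressed-mutation transcripts, and
silenced tumor-suppressor methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import pandas as pd

from omiclone.relations import (
    difference_on,
    equi_join,
    intersect_on,
    interval_left_join,
    left_outer_join,
    project_distinct,
)

__all__ = [
    "Glyph",
    "FilterSettings",
    "filter_wes",
    "build_I",
    "build_J",
    "build_D",
    "build_integrated",
    "integrate",
    "distinct_mutations",
    "transcripts_for",
    "key_gene_table",
    "rna_table",
    "tsg_methylation_table",
    "mutated_key_gene_methylation",
    "paired_compare",
]

log = logging.getLogger(__name__)


class Glyph(IntEnum):
    """Per-mutation evidence marker: DNA-only vs DNA+RNA support."""

    WES_ONLY = 1
    WES_PLUS_RNA = 2


@dataclass
class FilterSettings:
    """Variant / methylation filter thresholds (toolbar defaults).

    VAF bounds are percent, depth bounds are reads, ``min_meth`` is a
    percent applied to beta fractions, ``opacity`` is the scatter-point
    alpha.
    """

    min_vaf: float = 4.0
    max_vaf: float = 100.0
    min_depth: int = 20
    max_depth: int = 1000
    min_meth: float = 25.0
    opacity: float = 0.5
    show_kg_only: bool = False

    def __post_init__(self):
        if self.min_vaf > self.max_vaf:
            raise ValueError("min_vaf > max_vaf")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")
        if not 0 < self.opacity <= 1:
            raise ValueError("opacity must be in (0, 1]")


def filter_wes(w: pd.DataFrame, s: FilterSettings | None = None) -> pd.DataFrame:
    """Retain variants with VAF and depth inside the (inclusive) bounds."""
    s = s or FilterSettings()
    keep = (
        (w["dna_allelic_freq"] >= s.min_vaf)
        & (w["dna_allelic_freq"] <= s.max_vaf)
        & (w["dna_depth"] >= s.min_depth)
        & (w["dna_depth"] <= s.max_depth)
    )
    out = w[keep].reset_index(drop=True)
    log.info("filter_wes: %d of %d variants retained", len(out), len(w))
    return out


_M_CARRY = ["target_id", "avg_beta", "regulatory_feature", "relation_to_cpg_island", "ensembl_gene_id"]


def build_I(w: pd.DataFrame, m: pd.DataFrame) -> pd.DataFrame:
    """Impact-restricted variants left-joined to methylation by gene.

    Keeps MODERATE/HIGH variants only, then left-outer-joins the probe
    relation on the Ensembl gene id; unmethylated genes carry null probe
    fields.
    """
    sel = w[w["effect_impact"].isin(["MODERATE", "HIGH"])].reset_index(drop=True)
    m_proj = m[_M_CARRY]
    out = left_outer_join(sel, m_proj, [("ensembl_gene_id", "ensembl_gene_id")])
    log.info("build_I: %d variant rows -> %d joined rows", len(sel), len(out))
    return out


def build_J(rv: pd.DataFrame, r: pd.DataFrame) -> pd.DataFrame:
    """RNA variants equi-joined to expressed transcripts (FPKM > 0)."""
    r_pos = r[r["fpkm"] > 0][["ensembl_transcript_id", "ensembl_gene_id", "fpkm"]]
    joined = equi_join(
        rv[["chromosome", "position", "ensembl_gene_id", "rna_depth", "rna_allelic_freq"]],
        r_pos.rename(columns={"ensembl_gene_id": "r_gene_id"}),
        [("ensembl_gene_id", "r_gene_id")],
    )
    out = joined[["chromosome", "position", "rna_depth", "rna_allelic_freq",
                  "ensembl_transcript_id", "fpkm"]]
    log.info("build_J: %d expressed-transcript rows", len(out))
    return out


def build_D(rv: pd.DataFrame, h: pd.DataFrame) -> pd.DataFrame:
    """RNA variants equi-joined to genes with raw read count > 0."""
    h_pos = h[h["count"] > 0][["ensembl_gene_id", "count"]]
    joined = equi_join(
        rv[["chromosome", "position", "ensembl_gene_id", "rna_depth", "rna_allelic_freq"]],
        h_pos.rename(columns={"ensembl_gene_id": "h_gene_id"}),
        [("ensembl_gene_id", "h_gene_id")],
    )
    out = joined[["chromosome", "position", "rna_depth", "rna_allelic_freq", "count"]]
    log.info("build_D: %d counted-gene rows", len(out))
    return out


def build_integrated(
    I: pd.DataFrame, J: pd.DataFrame, D: pd.DataFrame, c: pd.DataFrame
) -> pd.DataFrame:
    """Compose the final integrated relation and compute the glyph.

    Left-outer joins by locus: methylation-joined variants to expressed
    transcripts, then to counted genes, then to copy-number segments by
    closed-interval containment (a variant inside two segments is an
    integrity error).  The glyph is WES_PLUS_RNA iff the variant's locus
    matched an RNA variant carrying expression support (transcript FPKM >
    0 or raw count > 0), else WES_ONLY.
    """
    L = left_outer_join(I, J, [("chromosome", "chromosome"), ("position", "position")])
    d_ren = D.rename(columns={"rna_depth": "rna_depth_cnt", "rna_allelic_freq": "rna_allelic_freq_cnt"})
    N = left_outer_join(L, d_ren, [("chromosome", "chromosome"), ("position", "position")])
    # coalesce RNA evidence from the transcript and the count joins
    N["rna_depth"] = N["rna_depth"].where(N["rna_depth"].notna(), N["rna_depth_cnt"])
    N["rna_allelic_freq"] = N["rna_allelic_freq"].where(
        N["rna_allelic_freq"].notna(), N["rna_allelic_freq_cnt"]
    )
    N = N.drop(columns=["rna_depth_cnt", "rna_allelic_freq_cnt"])
    out = interval_left_join(
        N.rename(columns={}),
        c,
        carry=("copy_number",),
    )
    out["copy_number"] = pd.array(
        [None if pd.isna(v) else int(v) for v in out["copy_number"]], dtype="Int64"
    )
    rna_evidence = out["rna_depth"].notna() | out["count"].notna()
    out["glyph"] = [int(Glyph.WES_PLUS_RNA) if e else int(Glyph.WES_ONLY) for e in rna_evidence]
    log.info(
        "build_integrated: %d rows (%d loci, %d RNA-supported)",
        len(out),
        out[["chromosome", "position"]].drop_duplicates().shape[0],
        int(rna_evidence.sum()),
    )
    return out


def integrate(bundle, settings: FilterSettings | None = None) -> pd.DataFrame:
    """One-shot pipeline: filter, build the three join legs, integrate."""
    s = settings or FilterSettings()
    w = filter_wes(bundle.w, s)
    return build_integrated(
        build_I(w, bundle.m), build_J(bundle.rv, bundle.r), build_D(bundle.rv, bundle.h), bundle.c
    )


_W_HAT_COLS = [
    "chromosome",
    "position",
    "dna_depth",
    "copy_number",
    "dna_change",
    "amino_acid_change",
    "dna_allelic_freq",
    "gene_symbol",
    "glyph",
]


def distinct_mutations(integrated: pd.DataFrame) -> pd.DataFrame:
    """The distinct-mutation (scatter-plot) relation.

    Projects the integrated relation onto the per-mutation attributes and
    eliminates the duplication introduced by probe/transcript matches;
    ``experiment_id`` is carried along for report labelling.
    """
    cols = _W_HAT_COLS + (["experiment_id"] if "experiment_id" in integrated.columns else [])
    return project_distinct(integrated, cols)


def transcripts_for(w_hat_row, integrated: pd.DataFrame) -> pd.DataFrame:
    """Distinct expressed transcripts at one mutation's locus.

    ``w_hat_row`` is a row of :func:`distinct_mutations` (or any mapping
    with ``chromosome`` and ``position``).  Empty for DNA-only mutations.
    """
    sel = integrated[
        (integrated["chromosome"] == w_hat_row["chromosome"])
        & (integrated["position"] == w_hat_row["position"])
    ]
    sel = sel[sel["ensembl_transcript_id"].notna()]
    return project_distinct(sel, ["gene_symbol", "ensembl_transcript_id", "fpkm"])


def _key_gene_mask(rel: pd.DataFrame, k: pd.DataFrame) -> pd.Series:
    ids = set(k["ensembl_gene_id"].dropna()) if "ensembl_gene_id" in k.columns else set()
    symbols = set(k["gene_symbol"].dropna()) if "gene_symbol" in k.columns else set()
    mask = pd.Series(False, index=rel.index)
    if ids:
        mask |= rel["ensembl_gene_id"].isin(ids)
    if symbols:
        mask |= rel["gene_symbol"].isin(symbols)
    return mask


def key_gene_table(integrated: pd.DataFrame, k: pd.DataFrame) -> pd.DataFrame:
    """Key-gene summary: one row per key-gene variant.

    Columns mirror the per-sample driver summaries: gene symbol, DNA and
    amino-acid change, copy number, depth, allelic frequency, and whether
    the mutation is also expressed in RNA (glyph-derived flag).
    """
    if len(k) == 0:
        sel = integrated.iloc[0:0]
    else:
        sel = integrated[_key_gene_mask(integrated, k)]
    out = project_distinct(
        sel,
        [
            "gene_symbol",
            "dna_change",
            "amino_acid_change",
            "copy_number",
            "dna_depth",
            "dna_allelic_freq",
            "glyph",
        ],
    )
    out = out.assign(rna_expressed=[g == int(Glyph.WES_PLUS_RNA) for g in out["glyph"]])
    return out.sort_values("gene_symbol").reset_index(drop=True)


def rna_table(integrated: pd.DataFrame) -> pd.DataFrame:
    """Expressed-mutation transcript table: one row per transcript.

    Distinct (gene symbol, RNA depth, RNA allelic frequency, FPKM,
    transcript id) over rows with transcript evidence.
    """
    sel = integrated[integrated["ensembl_transcript_id"].notna()]
    return project_distinct(
        sel,
        ["gene_symbol", "rna_depth", "rna_allelic_freq", "fpkm", "ensembl_transcript_id"],
    )


def _norm_text(v) -> str | None:
    return None if v is None or pd.isna(v) else str(v).strip().lower()


def tsg_methylation_table(
    m: pd.DataFrame,
    h: pd.DataFrame,
    genes: pd.DataFrame,
    s: FilterSettings | None = None,
) -> pd.DataFrame:
    """Silencing screen over tumor-suppressor genes.

    Retains probes of TSG-classified genes passing all three criteria —
    beta at least ``min_meth`` percent, a promoter-associated regulatory
    feature, and location in a CpG island — and attaches each gene's raw
    RNA read count (0 when the gene is absent from the count table).
    ``silenced`` flags methylated promoters with zero RNA reads.

    Operates directly on the probe relation (not only on mutated genes),
    so epigenetically silenced genes are found whether or not they also
    carry a somatic mutation; see :func:`mutated_key_gene_methylation`
    for the mutation-restricted variant.
    """
    s = s or FilterSettings()
    tsg = genes
    if "classification" in genes.columns:
        cls = genes["classification"].map(_norm_text)
        if cls.notna().any():
            tsg = genes[cls == "tsg"]
    tsg = tsg.rename(columns={"ensembl_gene_id": "tsg_gene_id"})[
        [c for c in ("tsg_gene_id", "gene_symbol", "classification") if c in tsg.columns or c == "tsg_gene_id"]
    ]
    probes = equi_join(m, tsg, [("ensembl_gene_id", "tsg_gene_id")])
    beta_min = s.min_meth / 100.0
    keep = (
        (probes["avg_beta"] >= beta_min)
        & (probes["regulatory_feature"].map(_norm_text) == "promoter associated")
        & (probes["relation_to_cpg_island"].map(_norm_text) == "island")
    )
    probes = probes[keep].reset_index(drop=True)
    counts = dict(zip(h["ensembl_gene_id"], h["count"]))
    probes["rna_read_count"] = [int(counts.get(g, 0)) for g in probes["ensembl_gene_id"]]
    probes["silenced"] = probes["rna_read_count"] == 0
    cols = [
        "target_id",
        "avg_beta",
        "gene_symbol",
        "ensembl_gene_id",
        "rna_read_count",
        "classification",
        "regulatory_feature",
        "relation_to_cpg_island",
        "silenced",
    ]
    cols = [c for c in cols if c in probes.columns]
    sort_by = [c for c in ("gene_symbol", "target_id") if c in cols]
    return probes[cols].sort_values(sort_by).reset_index(drop=True)


def mutated_key_gene_methylation(integrated: pd.DataFrame, k: pd.DataFrame) -> pd.DataFrame:
    """Methylation of mutated key genes (the integration-restricted form).

    Joins the integrated relation to the key-gene list by gene id and
    projects the distinct probe evidence; this only surfaces methylation
    for genes that carry a retained somatic mutation.
    """
    ids = k.rename(columns={"ensembl_gene_id": "kg_gene_id"})[["kg_gene_id"]].dropna()
    sel = equi_join(integrated, ids, [("ensembl_gene_id", "kg_gene_id")])
    sel = sel[sel["target_id"].notna()]
    return project_distinct(
        sel,
        ["target_id", "avg_beta", "gene_symbol", "regulatory_feature",
         "relation_to_cpg_island", "ensembl_gene_id", "count"],
    )


def paired_compare(
    w1: pd.DataFrame, w2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition two samples' variants by locus.

    Returns ``(common, unique1, unique2)`` keyed on (chromosome,
    position): variants of the first sample also present in the second,
    and each sample's private variants.
    """
    keys = ["chromosome", "position"]
    return (
        intersect_on(w1, w2, keys),
        difference_on(w1, w2, keys),
        difference_on(w2, w1, keys),
    )
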