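"""Readers and writers for the source bioinformatics formats.

Converts standard per-sample files into the typed relations of
:mod:`omiclone.relations`:

* SnpEff-annotated somatic VCF (Strelka or GATK dialect) -> ``W``
* SnpEff-annotated RNA variant VCF (GATK allelic depths) -> ``RV``
* htseq-count two-column table -> ``H``
* Cufflinks isoform FPKM tracking table -> ``R``
* CNV segment table (ExomeCNV-style) -> ``C``
* Infinium 450K probe export -> ``M``
* gene lists (plain or tabular) -> ``K``

plus a canonical tab-separated dump/restore for every relation, and a
:class:`DatasetBundle` directory layout so a full sample can be written
and read back as plain-text files.  All readers accept gzip-compressed
input.
"""

from __future__ import annotations

import gzip
import io
import json
import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from omiclone._genome import GRCH37_CHROM_LENGTHS
from omiclone.relations import (
    CHROMOSOMES,
    CopyNumberSegment,
    ExperimentMeta,
    GeneCount,
    GeneListEntry,
    MethylationProbe,
    RnaVariant,
    TranscriptQuant,
    WesVariant,
    columns_of,
    empty_relation,
    normalize_chromosome,
    relation,
)

__all__ = [
    "DatasetBundle",
    "ParseError",
    "read_wes_vcf",
    "read_rna_vcf",
    "read_counts",
    "read_fpkm",
    "read_cnv",
    "read_methylation",
    "read_gene_list",
    "read_meta",
    "write_relation",
    "read_relation",
    "write_wes_vcf",
    "write_rna_vcf",
    "write_bundle",
    "read_bundle",
]


class ParseError(ValueError):
    """A source file violated its expected format."""


_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}


@dataclass
class DatasetBundle:
    """All relations for one sample, sharing one experiment id."""

    w: pd.DataFrame
    m: pd.DataFrame
    c: pd.DataFrame
    h: pd.DataFrame
    rv: pd.DataFrame
    r: pd.DataFrame
    meta: pd.DataFrame
    key_genes: pd.DataFrame | None = None

    @property
    def experiment_id(self) -> str | None:
        for rel in (self.w, self.rv, self.m, self.c, self.h, self.r):
            if len(rel) and "experiment_id" in rel.columns:
                ids = rel["experiment_id"].dropna()
                if len(ids):
                    return str(ids.iloc[0])
        return None


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _detect_dialect(vcf: pysam.VariantFile) -> str:
    fmts = set(vcf.header.formats.keys())
    if {"AU", "CU", "GU", "TU"} & fmts or {"TIR", "TAR"} & fmts:
        return "strelka"
    return "gatk"


def _pick_sample(vcf: pysam.VariantFile) -> str:
    samples = list(vcf.header.samples)
    if not samples:
        raise ParseError("VCF has no sample columns")
    for s in samples:
        if s.upper() == "TUMOR":
            return s
    return samples[-1]


def _parse_ann(rec, alt: str) -> list[tuple[str, str, str, str, str, str]]:
    """SnpEff ANN entries matching ``alt``.

    Returns tuples (gene_id, gene_symbol, impact, hgvs_c, hgvs_p,
    transcript_id).
    """
    ann = rec.info.get("ANN")
    if ann is None:
        raise ParseError(
            f"record {rec.chrom}:{rec.pos} {rec.ref}>{alt} lacks the SnpEff ANN field"
        )
    if isinstance(ann, str):
        ann = (ann,)
    out = []
    for entry in ann:
        parts = entry.split("|")
        if len(parts) < 11:
            raise ParseError(
                f"record {rec.chrom}:{rec.pos}: malformed ANN entry {entry!r}"
            )
        allele, _effect, impact, symbol, gene_id = parts[0], parts[1], parts[2], parts[3], parts[4]
        hgvs_c, hgvs_p = parts[9], parts[10]
        transcript = parts[6]
        if allele != alt:
            continue
        out.append((gene_id, symbol, impact, hgvs_c, hgvs_p, transcript))
    if not out:
        raise ParseError(
            f"record {rec.chrom}:{rec.pos} {rec.ref}>{alt}: no ANN entry for this allele"
        )
    return out


_STRELKA_SNV_FIELD = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}


def _allele_counts(rec, sample: str, alt_index: int, dialect: str) -> tuple[int, int] | None:
    """(TRV, TRR) for one alternate allele, or None when not derivable."""
    fmt = rec.samples[sample]
    alt = rec.alts[alt_index]
    if dialect == "strelka":
        if len(rec.ref) == 1 and len(alt) == 1 and alt in _STRELKA_SNV_FIELD:
            try:
                # tier-1 counts (first element of each tiered pair)
                trv = int(fmt[_STRELKA_SNV_FIELD[alt]][0])
                trr = int(fmt[_STRELKA_SNV_FIELD[rec.ref]][0])
                return trv, trr
            except (KeyError, TypeError):
                pass
        try:
            return int(fmt["TIR"][0]), int(fmt["TAR"][0])
        except (KeyError, TypeError):
            return None
    # GATK dialect: AD = (ref, alt1, alt2, ...)
    try:
        ad = fmt["AD"]
        return int(ad[alt_index + 1]), int(ad[0])
    except (KeyError, TypeError, IndexError):
        return None


def _vcf_records(path, dialect: str):
    """Yield (rec, alt_index, trv, trr, depth, annotations) per alternate."""
    with pysam.VariantFile(str(path)) as vcf:
        if dialect == "auto":
            dialect = _detect_dialect(vcf)
        sample = _pick_sample(vcf)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                counts = _allele_counts(rec, sample, ai, dialect)
                if counts is None:
                    raise ParseError(
                        f"record {rec.chrom}:{rec.pos}: no allele-support counts "
                        f"for dialect {dialect!r}"
                    )
                trv, trr = counts
                if trv + trr == 0:
                    warnings.warn(
                        f"skipping {rec.chrom}:{rec.pos} {rec.ref}>{alt}: "
                        "zero supporting reads (TRV + TRR = 0)"
                    )
                    continue
                fmt = rec.samples[sample]
                try:
                    depth = int(fmt["DP"])
                except (KeyError, TypeError):
                    depth = trv + trr
                yield rec, alt, trv, trr, depth, _parse_ann(rec, alt)


def read_wes_vcf(path, experiment_id: str, dialect: str = "auto") -> pd.DataFrame:
    """Read a SnpEff-annotated somatic VCF into the ``W`` relation.

    One row per (position, alternate allele, annotated gene); the
    highest-impact annotation is retained per variant-gene pair.  The
    allelic frequency is ``100 * TRV / (TRV + TRR)`` from tier-1 Strelka
    counts or GATK allelic depths.
    """
    rows: dict[tuple, WesVariant] = {}
    for rec, alt, trv, trr, depth, anns in _vcf_records(path, dialect):
        vaf = 100.0 * trv / (trv + trr)
        by_gene: dict[str, tuple] = {}
        for gene_id, symbol, impact, hgvs_c, hgvs_p, _tx in anns:
            prev = by_gene.get(gene_id)
            if prev is None or _IMPACT_RANK.get(impact, -1) > _IMPACT_RANK.get(prev[2], -1):
                by_gene[gene_id] = (gene_id, symbol, impact, hgvs_c, hgvs_p)
        for gene_id, symbol, impact, hgvs_c, hgvs_p in by_gene.values():
            key = (rec.chrom, rec.pos, alt, gene_id)
            rows[key] = WesVariant(
                chromosome=rec.chrom,
                position=rec.pos,
                dna_depth=depth,
                dna_allelic_freq=vaf,
                ensembl_gene_id=gene_id,
                gene_symbol=symbol,
                dna_change=hgvs_c,
                amino_acid_change=hgvs_p or None,
                effect_impact=impact,
                experiment_id=experiment_id,
            )
    return relation(rows.values(), WesVariant)


def read_rna_vcf(path, experiment_id: str, dialect: str = "auto") -> pd.DataFrame:
    """Read a SnpEff-annotated RNA variant VCF into the ``RV`` relation.

    One row per (position, annotated gene); allelic frequency from the
    allelic depths of the (single) RNA sample.
    """
    rows: dict[tuple, RnaVariant] = {}
    for rec, alt, trv, trr, depth, anns in _vcf_records(path, dialect):
        vaf = 100.0 * trv / (trv + trr)
        for gene_id in {a[0] for a in anns}:
            key = (rec.chrom, rec.pos, gene_id)
            rows[key] = RnaVariant(
                chromosome=rec.chrom,
                position=rec.pos,
                ensembl_gene_id=gene_id,
                rna_depth=depth,
                rna_allelic_freq=vaf,
                experiment_id=experiment_id,
            )
    return relation(rows.values(), RnaVariant)


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_counts(path, experiment_id: str) -> pd.DataFrame:
    """Read an htseq-count style two-column table into ``H``.

    Summary rows whose gene id begins with ``__`` (``__no_feature`` etc.)
    are excluded.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns, got {len(parts)}")
            gene, count = parts
            if gene.startswith("__"):
                continue
            try:
                count = int(count)
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-integer count {count!r}") from None
            rows.append(GeneCount(ensembl_gene_id=gene, count=count, experiment_id=experiment_id))
    return relation(rows, GeneCount)


def _find_column(df: pd.DataFrame, aliases: tuple[str, ...], what: str, path) -> str:
    norm = {c.lower().replace(" ", "_").replace("-", "_").replace(".", "_"): c for c in df.columns}
    for a in aliases:
        if a in norm:
            return norm[a]
    raise ParseError(f"{path}: no column for {what} (looked for {', '.join(aliases)})")


def read_fpkm(path, experiment_id: str) -> pd.DataFrame:
    """Read a Cufflinks-style isoform FPKM tracking table into ``R``.

    Assembler-novel transcript ids (``CUFF.n.m``) are accepted verbatim.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    tx = _find_column(df, ("tracking_id", "transcript_id", "ensembl_transcript_id"), "transcript id", path)
    gene = _find_column(df, ("gene_id", "ensembl_gene_id"), "gene id", path)
    fpkm = _find_column(df, ("fpkm",), "FPKM", path)
    rows = []
    for i, rec in df.iterrows():
        try:
            value = float(rec[fpkm])
        except ValueError:
            raise ParseError(f"{path}, row {i + 1}: non-numeric FPKM {rec[fpkm]!r}") from None
        if value < 0:
            raise ParseError(f"{path}, row {i + 1}: negative FPKM {value}")
        rows.append(
            TranscriptQuant(
                ensembl_transcript_id=str(rec[tx]),
                ensembl_gene_id=str(rec[gene]),
                fpkm=value,
                experiment_id=experiment_id,
            )
        )
    return relation(rows, TranscriptQuant)


def read_cnv(path, experiment_id: str) -> pd.DataFrame:
    """Read a CNV segment table (ExomeCNV-style columns) into ``C``.

    Segments are sorted by (chromosome, start); overlapping segments
    within a chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    chrom = _find_column(df, ("chromosome", "chr", "chrom"), "chromosome", path)
    start = _find_column(df, ("start", "probe_start", "chr_start"), "start", path)
    stop = _find_column(df, ("stop", "end", "probe_end", "chr_stop", "chr_end"), "stop", path)
    cn = _find_column(df, ("copy_number", "copy_number_", "cn", "copy"), "copy number", path)
    rows = []
    for i, rec in df.iterrows():
        try:
            rows.append(
                CopyNumberSegment(
                    chromosome=rec[chrom],
                    start=int(rec[start]),
                    stop=int(rec[stop]),
                    copy_number=int(rec[cn]),
                    experiment_id=experiment_id,
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}, row {i + 1}: {e}") from None
    rows.sort(key=lambda s: (CHROMOSOMES.index(s.chromosome), s.start))
    for a, b in zip(rows, rows[1:]):
        if a.chromosome == b.chromosome and b.start <= a.stop:
            raise ParseError(
                f"{path}: overlapping segments on chromosome {a.chromosome}: "
                f"[{a.start}, {a.stop}] and [{b.start}, {b.stop}]"
            )
    return relation(rows, CopyNumberSegment)


def read_methylation(path, experiment_id: str) -> pd.DataFrame:
    """Read a 450K probe export into ``M``.

    Betas are fractions in [0, 1]; rows lacking a gene id are retained
    with a null gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    tid = _find_column(df, ("targetid", "target_id"), "target id", path)
    beta = _find_column(df, ("avg_beta", "avgbeta", "beta"), "average beta", path)
    gene = _find_column(df, ("ensembl_geneid", "ensembl_gene_id", "gene_id"), "gene id", path)
    reg = _find_column(
        df, ("regulatory_feature", "regulatory_feature_group"), "regulatory feature", path
    )
    cpg = _find_column(
        df,
        ("relation_to_cpg_island", "relation_to_ucsc_cpg_island"),
        "CpG island relation",
        path,
    )
    rows = []
    for i, rec in df.iterrows():
        b = float(rec[beta])
        if not 0.0 <= b <= 1.0:
            raise ParseError(f"{path}, row {i + 1}: beta {b} outside [0, 1]")

        def _opt(v):
            return None if pd.isna(v) or str(v) == "" else str(v)

        rows.append(
            MethylationProbe(
                target_id=str(rec[tid]),
                avg_beta=b,
                regulatory_feature=_opt(rec[reg]),
                relation_to_cpg_island=_opt(rec[cpg]),
                ensembl_gene_id=_opt(rec[gene]),
                experiment_id=experiment_id,
            )
        )
    return relation(rows, MethylationProbe)


def read_gene_list(path) -> pd.DataFrame:
    """Read a key-gene / TSG list into ``K``, deduplicated.

    Accepts either one gene per line (Ensembl id or symbol) or a tabular
    file with ``ensembl_gene_id`` / ``gene_symbol`` / ``classification``
    columns.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        rest = fh.read()
    header_like = "ensembl_gene_id" in first.lower() or "gene_symbol" in first.lower()
    rows: list[GeneListEntry] = []
    if header_like:
        df = pd.read_csv(io.StringIO(first + rest), sep="\t", dtype=str)

        def _opt(rec, col):
            if col not in df.columns:
                return None
            v = rec[col]
            return None if pd.isna(v) or str(v) == "" else str(v)

        for _, rec in df.iterrows():
            rows.append(
                GeneListEntry(
                    ensembl_gene_id=_opt(rec, "ensembl_gene_id"),
                    gene_symbol=_opt(rec, "gene_symbol"),
                    classification=_opt(rec, "classification"),
                )
            )
    else:
        for line in (first + rest).splitlines():
            name = line.strip()
            if not name:
                continue
            if name.upper().startswith("ENSG"):
                rows.append(GeneListEntry(ensembl_gene_id=name))
            else:
                rows.append(GeneListEntry(ensembl_gene_id=None, gene_symbol=name))
    seen, unique = set(), []
    for r in rows:
        key = (r.ensembl_gene_id, r.gene_symbol)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return relation(unique, GeneListEntry)


def read_meta(path) -> pd.DataFrame:
    """Read the experiment metadata table ``P`` (canonical TSV)."""
    return read_relation(path, ExperimentMeta)


# ---------------------------------------------------------------------------
# Canonical TSV dump / restore
# ---------------------------------------------------------------------------

def _format_value(v, kind: str) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return ""
    if kind == "float":
        return f"{float(v):.10g}"
    if kind == "int":
        return str(int(v))
    return str(v)


def write_relation(rel: pd.DataFrame, path, row_type=None) -> None:
    """Dump a relation as a canonical tab-separated file.

    Header row, empty fields for nulls, reals at 10 significant digits,
    stable column order.  Re-reading with :func:`read_relation` (given the
    same row type) reproduces an equal relation.
    """
    if row_type is not None:
        cols = [c for c in columns_of(row_type) if c in rel.columns]
        kinds = row_type.kinds
    else:
        cols = list(rel.columns)
        kinds = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in rel.iterrows():
            fh.write(
                "\t".join(_format_value(row[c], kinds.get(c, _infer_kind(row[c]))) for c in cols)
                + "\n"
            )


def _infer_kind(v) -> str:
    if isinstance(v, float):
        return "float"
    if isinstance(v, (int,)) and not isinstance(v, bool):
        return "int"
    return "str"


def read_relation(path, row_type) -> pd.DataFrame:
    """Restore a relation written by :func:`write_relation`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for col in df.columns:
        kind = row_type.kinds.get(col, "str")
        series = df[col].replace("", None)
        if kind == "int":
            out[col] = pd.array([None if v is None else int(v) for v in series], dtype="Int64")
        elif kind == "float":
            out[col] = pd.array([math.nan if v is None else float(v) for v in series], dtype="float64")
        else:
            out[col] = pd.array(series, dtype="object")
    res = pd.DataFrame(out)
    if len(res) == 0:
        return empty_relation(row_type)[list(df.columns)]
    return res


# ---------------------------------------------------------------------------
# VCF writing (GATK dialect with SnpEff ANN) and bundle directories
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    + "".join(
        f"##contig=<ID={c},length={GRCH37_CHROM_LENGTHS[c]}>\n" for c in CHROMOSOMES
    )
    + '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
    "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type "
    "| Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p'\">\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)

_IMPACT_EFFECT = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intron_variant",
}


def _hgvs_alleles(dna_change: str | None) -> tuple[str, str]:
    """REF/ALT from an HGVS c. substitution, defaulting to A>C."""
    if dna_change and ">" in dna_change:
        body = dna_change.split(">")
        ref = body[0][-1]
        alt = body[1][0] if body[1] else "C"
        if ref in "ACGT" and alt in "ACGT" and ref != alt:
            return ref, alt
    return "A", "C"


def write_wes_vcf(w: pd.DataFrame, path, sample: str = "TUMOR") -> None:
    """Write a ``W`` relation as a SnpEff-annotated, GATK-dialect VCF.

    Allelic depths are back-computed from the stored frequency so that
    :func:`read_wes_vcf` reproduces ``dna_allelic_freq`` exactly.
    """
    _write_vcf(w, path, sample, mode="wes")


def write_rna_vcf(rv: pd.DataFrame, path, sample: str = "RNA") -> None:
    """Write an ``RV`` relation as an annotated GATK-dialect VCF."""
    _write_vcf(rv, path, sample, mode="rna")


def _write_vcf(rel: pd.DataFrame, path, sample: str, mode: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    df = rel.copy()
    order = [CHROMOSOMES.index(c) for c in df["chromosome"]] if len(df) else []
    df = df.assign(_ord=order).sort_values(["_ord", "position"]) if len(df) else df
    with opener(str(path), "wt", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        if not len(df):
            return
        for (chrom, pos), grp in df.groupby(["chromosome", "position"], sort=False):
            first = grp.iloc[0]
            if mode == "wes":
                ref, alt = _hgvs_alleles(first["dna_change"])
                depth = int(first["dna_depth"])
                vaf = float(first["dna_allelic_freq"])
            else:
                ref, alt = "A", "C"
                depth = int(first["rna_depth"])
                vaf = float(first["rna_allelic_freq"])
            trv = round(vaf * depth / 100.0)
            trr = depth - trv
            anns = []
            for _, row in grp.iterrows():
                if mode == "wes":
                    impact = row["effect_impact"]
                    anns.append(
                        f"{alt}|{_IMPACT_EFFECT[impact]}|{impact}|{row['gene_symbol']}"
                        f"|{row['ensembl_gene_id']}|transcript|{row['ensembl_gene_id']}.t1"
                        f"|protein_coding|1/1|{row['dna_change'] or ''}"
                        f"|{row['amino_acid_change'] or ''}"
                    )
                else:
                    anns.append(
                        f"{alt}|missense_variant|MODERATE|{row['ensembl_gene_id']}"
                        f"|{row['ensembl_gene_id']}|transcript|{row['ensembl_gene_id']}.t1"
                        f"|protein_coding|1/1||"
                    )
            fh.write(
                f"{chrom}\t{int(pos)}\t.\t{ref}\t{alt}\t.\tPASS\tANN={','.join(anns)}"
                f"\tGT:AD:DP\t0/1:{trr},{trv}:{depth}\n"
            )


_BUNDLE_FILES = {
    "w": "wes_variants.vcf",
    "rv": "rna_variants.vcf",
    "c": "cnv_segments.tsv",
    "h": "gene_counts.tsv",
    "r": "isoform_fpkm.tsv",
    "m": "methylation_probes.tsv",
    "key_genes": "gene_list.tsv",
    "meta": "experiments.tsv",
}


def write_bundle(bundle: DatasetBundle, directory, seed: int | None = None, config: dict | None = None) -> None:
    """Write a bundle as a directory of source-format files plus a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_wes_vcf(bundle.w, d / _BUNDLE_FILES["w"])
    write_rna_vcf(bundle.rv, d / _BUNDLE_FILES["rv"])
    write_relation(bundle.c, d / _BUNDLE_FILES["c"], CopyNumberSegment)
    with open(d / _BUNDLE_FILES["h"], "w", encoding="utf-8") as fh:
        for _, row in bundle.h.iterrows():
            fh.write(f"{row['ensembl_gene_id']}\t{int(row['count'])}\n")
    fpkm = bundle.r.rename(
        columns={"ensembl_transcript_id": "tracking_id", "ensembl_gene_id": "gene_id", "fpkm": "FPKM"}
    )[["tracking_id", "gene_id", "FPKM"]]
    fpkm.to_csv(d / _BUNDLE_FILES["r"], sep="\t", index=False)
    write_relation(bundle.m, d / _BUNDLE_FILES["m"], MethylationProbe)
    if bundle.key_genes is not None:
        write_relation(bundle.key_genes, d / _BUNDLE_FILES["key_genes"], GeneListEntry)
    write_relation(bundle.meta, d / _BUNDLE_FILES["meta"], ExperimentMeta)
    manifest = {
        "experiment_id": bundle.experiment_id,
        "files": dict(_BUNDLE_FILES),
        "seed": seed,
        "config": config,
    }
    with open(d / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_bundle(directory, experiment_id: str | None = None) -> DatasetBundle:
    """Read back a bundle directory written by :func:`write_bundle`."""
    d = Path(directory)
    if experiment_id is None:
        with open(d / "manifest.json", encoding="utf-8") as fh:
            experiment_id = json.load(fh)["experiment_id"]
    kg_path = d / _BUNDLE_FILES["key_genes"]
    return DatasetBundle(
        w=read_wes_vcf(d / _BUNDLE_FILES["w"], experiment_id),
        rv=read_rna_vcf(d / _BUNDLE_FILES["rv"], experiment_id),
        c=read_cnv(d / _BUNDLE_FILES["c"], experiment_id),
        h=read_counts(d / _BUNDLE_FILES["h"], experiment_id),
        r=read_fpkm(d / _BUNDLE_FILES["r"], experiment_id),
        m=read_methylation(d / _BUNDLE_FILES["m"], experiment_id),
        key_genes=read_gene_list(kg_path) if kg_path.exists() else None,
        meta=read_meta(d / _BUNDLE_FILES["meta"]),
    )
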