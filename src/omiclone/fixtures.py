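"""Synthetic multi-omic data with planted clonal structure.

Two sources of test data live here:

* :func:`generate_bundle` — a seeded generator that emulates the
  statistical shape of a real tumor sample: variant allele frequencies
  drawn from a mixture of clones (truncated normals around planted
  centers), depths consistent with integer read counts, a subset of
  mutations mirrored into the RNA layers so both evidence glyphs occur,
  and a methylation layer with a configurable number of silenced tumor
  suppressors.

* :func:`example_case_bundle` — a worked two-timepoint multiple myeloma
  case (a presentation sample and a relapse after therapy) encoded from
  published per-gene summary values; chromosome coordinates for its
  variants are synthetic (GRCh37-plausible) since the summaries print
  none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from omiclone.io_formats import DatasetBundle
from omiclone.relations import (
    CopyNumberSegment,
    ExperimentMeta,
    GeneCount,
    GeneListEntry,
    MethylationProbe,
    RnaVariant,
    TranscriptQuant,
    WesVariant,
    empty_relation,
    relation,
)

__all__ = [
    "FixtureConfig",
    "generate_bundle",
    "example_case_bundle",
    "example_key_gene_list",
    "key_genes_of",
    "tsg_genes_of",
]

#: Default copy-number landscape for generated samples: three whole-arm
#: scale segments with neutral, gained and lost states.  Chromosome 4 is
#: deliberately left uncovered so some variants carry a null copy number.
DEFAULT_CNV_PROFILE: tuple[tuple[str, int, int, int], ...] = (
    ("1", 1, 249_250_621, 2),
    ("2", 1, 243_199_373, 3),
    ("3", 1, 198_022_430, 1),
)

_VARIANT_CHROMS = ("1", "2", "3", "4")


@dataclass
class FixtureConfig:
    """Parameters of the synthetic sample generator.

    Defaults emulate a moderately heterogeneous exome: ~100 retained
    mutations in two clones (a dominant near-clonal population at VAF 45
    and a subclone at VAF 20, sd 4 VAF points), depths uniform over
    30-300x, roughly a third of mutations expressed in RNA, and four
    silenced tumor suppressors.
    """

    seed: int = 0
    n_variants: int = 100
    clone_centers: tuple[float, ...] = (45.0, 20.0)
    clone_weights: tuple[float, ...] = (0.6, 0.4)
    vaf_sd: float = 4.0
    depth_range: tuple[int, int] = (30, 300)
    fraction_rna_expressed: float = 0.35
    n_tsg_silenced: int = 4
    n_tsg_genes: int = 8
    cnv_profile: tuple[tuple[str, int, int, int], ...] = DEFAULT_CNV_PROFILE
    key_gene_fraction: float = 0.08
    experiment_id: str = "SIM"

    def __post_init__(self):
        if len(self.clone_centers) != len(self.clone_weights):
            raise ValueError("clone_centers and clone_weights differ in length")
        if abs(sum(self.clone_weights) - 1.0) > 1e-9:
            raise ValueError("clone_weights must sum to 1")
        if not all(0 < c < 100 for c in self.clone_centers):
            raise ValueError("clone centers must lie in (0, 100)")
        if self.n_tsg_silenced > self.n_tsg_genes:
            raise ValueError(
                f"n_tsg_silenced={self.n_tsg_silenced} exceeds the TSG list "
                f"size {self.n_tsg_genes}"
            )


def _truncnorm(rng, center: float, sd: float, size: int) -> np.ndarray:
    a, b = (0.5 - center) / sd, (99.5 - center) / sd
    return stats.truncnorm.rvs(a, b, loc=center, scale=sd, size=size, random_state=rng)


def generate_bundle(cfg: FixtureConfig) -> DatasetBundle:
    """Generate one synthetic sample bundle, deterministic for the seed."""
    rng = np.random.default_rng(cfg.seed)
    exp = cfg.experiment_id

    # clone assignment and VAFs
    clone = rng.choice(len(cfg.clone_centers), size=cfg.n_variants, p=cfg.clone_weights)
    vaf_drawn = np.empty(cfg.n_variants)
    for ci, center in enumerate(cfg.clone_centers):
        idx = np.flatnonzero(clone == ci)
        vaf_drawn[idx] = _truncnorm(rng, center, cfg.vaf_sd, idx.size)

    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=cfg.n_variants)
    trv = np.rint(vaf_drawn * depths / 100.0).astype(int)
    trv = np.clip(trv, 1, depths)  # keep every planted variant observable
    vaf = 100.0 * trv / depths

    chroms = rng.choice(_VARIANT_CHROMS, size=cfg.n_variants)
    positions: list[int] = []
    used: set[tuple[str, int]] = set()
    for ch in chroms:
        while True:
            p = int(rng.integers(10_000, 100_000_000))
            if (ch, p) not in used:
                used.add((ch, p))
                positions.append(p)
                break

    impacts = rng.choice(
        ["MODERATE", "HIGH", "LOW", "MODIFIER"], size=cfg.n_variants, p=[0.8, 0.1, 0.05, 0.05]
    )
    bases = ["A", "C", "G", "T"]
    w_rows = []
    for i in range(cfg.n_variants):
        ref, alt = rng.choice(bases, size=2, replace=False)
        aa = f"p.Ala{i + 10}Thr" if impacts[i] in ("MODERATE", "HIGH") else None
        w_rows.append(
            WesVariant(
                chromosome=chroms[i],
                position=positions[i],
                dna_depth=int(depths[i]),
                dna_allelic_freq=float(vaf[i]),
                ensembl_gene_id=f"ENSGSIM{i:08d}",
                gene_symbol=f"SIMG{i}",
                dna_change=f"c.{100 + i}{ref}>{alt}",
                amino_acid_change=aa,
                effect_impact=str(impacts[i]),
                experiment_id=exp,
            )
        )

    # RNA mirror: a random subset of variants is expressed
    n_expr = int(round(cfg.fraction_rna_expressed * cfg.n_variants))
    expr_idx = sorted(rng.choice(cfg.n_variants, size=n_expr, replace=False))
    rv_rows, r_rows, h_rows = [], [], []
    for i in expr_idx:
        rdp = int(rng.integers(5, 200))
        rtrv = int(np.clip(np.rint(vaf[i] * rdp / 100.0), 1, rdp))
        rv_rows.append(
            RnaVariant(
                chromosome=chroms[i],
                position=positions[i],
                ensembl_gene_id=f"ENSGSIM{i:08d}",
                rna_depth=rdp,
                rna_allelic_freq=100.0 * rtrv / rdp,
                experiment_id=exp,
            )
        )
        for t in range(int(rng.integers(1, 3))):
            r_rows.append(
                TranscriptQuant(
                    ensembl_transcript_id=f"ENSTSIM{i:06d}{t}",
                    ensembl_gene_id=f"ENSGSIM{i:08d}",
                    fpkm=float(np.round(rng.lognormal(1.5, 1.0), 4)),
                    experiment_id=exp,
                )
            )
        h_rows.append(
            GeneCount(
                ensembl_gene_id=f"ENSGSIM{i:08d}",
                count=int(rng.poisson(200) + 1),
                experiment_id=exp,
            )
        )

    # methylation layer: silenced and expressed tumor suppressors
    m_rows = []
    for t in range(cfg.n_tsg_genes):
        gid = f"ENSGTSG{t:08d}"
        silenced = t < cfg.n_tsg_silenced
        m_rows.append(
            MethylationProbe(
                target_id=f"cg{int(rng.integers(10_000_000, 99_999_999))}",
                avg_beta=float(np.round(rng.uniform(0.30, 0.95), 7)),
                regulatory_feature="Promoter Associated",
                relation_to_cpg_island="Island",
                ensembl_gene_id=gid,
                experiment_id=exp,
            )
        )
        h_rows.append(
            GeneCount(
                ensembl_gene_id=gid,
                count=0 if silenced else int(rng.poisson(40) + 1),
                experiment_id=exp,
            )
        )
    # plus a few probes failing the criteria (low beta / gene body)
    for t in range(3):
        m_rows.append(
            MethylationProbe(
                target_id=f"cg{int(rng.integers(10_000_000, 99_999_999))}",
                avg_beta=float(np.round(rng.uniform(0.01, 0.20), 7)),
                regulatory_feature="Gene Body" if t % 2 else "Promoter Associated",
                relation_to_cpg_island="N_Shore",
                ensembl_gene_id=f"ENSGTSG{t:08d}",
                experiment_id=exp,
            )
        )

    c_rows = [
        CopyNumberSegment(chromosome=ch, start=s, stop=e, copy_number=cn, experiment_id=exp)
        for ch, s, e, cn in cfg.cnv_profile
    ]

    n_kg = max(1, int(round(cfg.key_gene_fraction * cfg.n_variants)))
    kg_idx = sorted(rng.choice(cfg.n_variants, size=n_kg, replace=False))
    kg_rows = [
        GeneListEntry(
            ensembl_gene_id=f"ENSGSIM{i:08d}", gene_symbol=f"SIMG{i}", classification="KG"
        )
        for i in kg_idx
    ] + [
        GeneListEntry(
            ensembl_gene_id=f"ENSGTSG{t:08d}", gene_symbol=f"TSG{t}", classification="TSG"
        )
        for t in range(cfg.n_tsg_genes)
    ]

    meta = [
        ExperimentMeta(
            patient_id="SIMPATIENT",
            experiment_id=exp,
            experiment_description="synthetic multi-omic sample",
            sample_type="simulated tumor",
            sample_description=f"seed={cfg.seed}",
        )
    ]

    return DatasetBundle(
        w=relation(w_rows, WesVariant),
        m=relation(m_rows, MethylationProbe),
        c=relation(c_rows, CopyNumberSegment),
        h=relation(h_rows, GeneCount),
        rv=relation(rv_rows, RnaVariant),
        r=relation(r_rows, TranscriptQuant),
        key_genes=relation(kg_rows, GeneListEntry),
        meta=relation(meta, ExperimentMeta),
    )


# ---------------------------------------------------------------------------
# Worked example: a published two-timepoint myeloma case
# ---------------------------------------------------------------------------

# Synthetic (GRCh37-plausible) loci for the case's key-gene mutations;
# the published summaries print per-gene values without coordinates.
_KG_LOCI = {
    "DNA2": ("10", 70_225_000, "ENSG00000138346"),
    "MYC": ("8", 128_750_500, "ENSG00000136997"),
    "SETD2": ("3", 47_125_000, "ENSG00000181555"),
    "TET2": ("4", 106_157_000, "ENSG00000168769"),
    "TNFRSF11A": ("18", 60_027_000, "ENSG00000141655"),
    "KRAS": ("12", 25_398_284, "ENSG00000133703"),
    "MTOR": ("1", 11_188_000, "ENSG00000198793"),
    "MLL3": ("7", 151_860_000, "ENSG00000055609"),
}

# gene, dna_change, aa_change, CN, DP, AF(%), rna_expressed, class, impact
_PRESENTATION_KG = [
    ("DNA2", "c.146delG", None, 1, 82, 17, False, "DNA repair", "HIGH"),
    ("MYC", "c.226G>A", "p.Ala76Thr", 3, 207, 31, True, "Amp oncogene + VUS", "MODERATE"),
    ("SETD2", "c.7085A>G", "p.Gln2362Arg", 1, 94, 24, True, "HMT", "MODERATE"),
    ("TET2", "c.2725C>T", "p.Gln909*", 3, 117, 24, True, "Oncogene", "HIGH"),
    ("TNFRSF11A", "c.1097C>T", "p.Pro366Leu", 3, 244, 14, False, "Bone remodelling", "MODERATE"),
]

# "Same" entries at relapse resolve to the presentation mutation text.
_RELAPSE_KG = [
    ("DNA2", "c.146delG", None, 3, 70, 38, False, "DNA repair", "HIGH"),
    ("MYC", "c.226G>A", "p.Ala76Thr", 3, 257, 33, True, "Amp oncogene + VUS", "MODERATE"),
    ("SETD2", "c.7085A>G", "p.Gln2362Arg", 2, 105, 35, True, "HMT", "MODERATE"),
    ("TET2", "c.2725C>T", "p.Gln909*", 3, 129, 36, False, "Oncogene", "HIGH"),
    ("TNFRSF11A", "c.1097C>T", "p.Pro366Leu", 3, 283, 15, False, "Bone remodelling", "MODERATE"),
    ("KRAS", "c.183A>C", "p.Gln61His", 3, 175, 4, False, "Oncogene", "MODERATE"),
    ("MTOR", "c.6016G>C", "p.Val2006Leu", 1, 69, 23, True, "Oncogene", "MODERATE"),
    ("MLL3", "c.944G>A", "p.Gly315Asp", 1, 392, 4, False, "HMT", "MODERATE"),
]

# gene -> (rna depth, rna AF %, [(transcript, fpkm), ...])
_PRESENTATION_RNA = {
    "MYC": (192, 100, [("ENST00000377970", 42.0), ("ENST00000524013", 58.0)]),
    "SETD2": (25, 50, [("ENST00000409792", 9.5), ("ENST00000431180", 2.2)]),
    "TET2": (6, 50, [("ENST00000380013", 2.0), ("ENST00000265149", 1.2)]),
}

_RELAPSE_RNA = {
    "MYC": (100, 100, [("ENST00000377970", 24.0), ("ENST00000524013", 55.0)]),
    "SETD2": (
        29,
        50,
        [
            ("ENST00000409792", 3.2),
            ("ENST00000431180", 1.5),
            ("ENST00000445387", 1.2),
            ("CUFF.29743.3", 9.4),
        ],
    ),
    "MTOR": (20, 50, [("ENST00000361445", 4.7), ("ENST00000376838", 2.2)]),
}

_TSG_IDS = {
    "AXIN1": "ENSG00000103126",
    "BRCA1": "ENSG00000012048",
    "CDKN2A": "ENSG00000147889",
    "CEBPA": "ENSG00000245848",
    "MEN1": "ENSG00000133895",
    "MSH2": "ENSG00000095002",
    "PTCH1": "ENSG00000185920",
    "RUNX1": "ENSG00000159216",
    "SOCS1": "ENSG00000185338",
}

# target id, beta, gene, RNA read count
_PRESENTATION_METH = [
    ("cg27549619", 0.3934072, "AXIN1", 4),
    ("cg26370022", 0.6804651, "BRCA1", 0),
    ("cg11529738", 0.7789396, "BRCA1", 0),
    ("cg24900425", 0.9020266, "BRCA1", 0),
    ("cg13601799", 0.2905587, "CDKN2A", 13),
    ("cg01437571", 0.3243266, "CEBPA", 0),
    ("cg00976692", 0.291538, "MEN1", 8),
    ("cg14803009", 0.3387372, "MSH2", 0),
    ("cg22866426", 0.4628801, "RUNX1", 1),
    ("cg27003951", 0.2562254, "SOCS1", 0),
]

_RELAPSE_METH = [
    ("cg27549619", 0.443731, "AXIN1", 0),
    ("cg02086790", 0.4921295, "AXIN1", 0),
    ("cg26370022", 0.6747859, "BRCA1", 0),
    ("cg24900425", 0.8910863, "BRCA1", 0),
    ("cg11529738", 0.7637555, "BRCA1", 0),
    ("cg13601799", 0.467826, "CDKN2A", 38),
    ("cg00976692", 0.293402, "MEN1", 0),
    ("cg14803009", 0.4267139, "MSH2", 0),
    ("cg22073802", 0.2875548, "PTCH1", 23),
    ("cg22866426", 0.5251715, "RUNX1", 0),
    ("cg17339910", 0.399428, "RUNX1", 0),
    ("cg04004558", 0.2809271, "SOCS1", 0),
    ("cg27003951", 0.2598022, "SOCS1", 0),
]


def example_key_gene_list() -> pd.DataFrame:
    """The worked case's gene list: 8 key genes plus 9 tumor suppressors."""
    rows = [
        GeneListEntry(ensembl_gene_id=_KG_LOCI[g][2], gene_symbol=g, classification=cls)
        for g, _dna, _aa, _cn, _dp, _af, _expr, cls, _imp in _RELAPSE_KG
    ]
    rows += [
        GeneListEntry(ensembl_gene_id=gid, gene_symbol=sym, classification="TSG")
        for sym, gid in sorted(_TSG_IDS.items())
    ]
    return relation(rows, GeneListEntry)


def example_case_bundle(sample: str) -> DatasetBundle:
    """The worked myeloma case, ``sample`` in {"presentation", "relapse"}.

    Encodes the published key-gene, expressed-transcript and
    TSG-methylation summaries for the chosen timepoint into a full
    relation bundle (synthetic coordinates, see module docstring).
    """
    sample = sample.lower()
    if sample == "presentation":
        kg, rna, meth, exp, year = _PRESENTATION_KG, _PRESENTATION_RNA, _PRESENTATION_METH, "PRES", "2010"
    elif sample == "relapse":
        kg, rna, meth, exp, year = _RELAPSE_KG, _RELAPSE_RNA, _RELAPSE_METH, "REL", "2013"
    else:
        raise ValueError(f"unknown sample {sample!r}; expected 'presentation' or 'relapse'")

    w_rows, c_rows, rv_rows, r_rows, h_rows = [], [], [], [], []
    for gene, dna_change, aa, cn, dp, af, _expressed, _cls, impact in kg:
        chrom, pos, gid = _KG_LOCI[gene]
        w_rows.append(
            WesVariant(
                chromosome=chrom,
                position=pos,
                dna_depth=dp,
                dna_allelic_freq=float(af),
                ensembl_gene_id=gid,
                gene_symbol=gene,
                dna_change=dna_change,
                amino_acid_change=aa,
                effect_impact=impact,
                experiment_id=exp,
            )
        )
        c_rows.append(
            CopyNumberSegment(
                chromosome=chrom,
                start=pos - 500_000,
                stop=pos + 500_000,
                copy_number=cn,
                experiment_id=exp,
            )
        )
    for gene, (rdp, raf, transcripts) in rna.items():
        chrom, pos, gid = _KG_LOCI[gene]
        rv_rows.append(
            RnaVariant(
                chromosome=chrom,
                position=pos,
                ensembl_gene_id=gid,
                rna_depth=rdp,
                rna_allelic_freq=float(raf),
                experiment_id=exp,
            )
        )
        for tx, fpkm in transcripts:
            r_rows.append(
                TranscriptQuant(
                    ensembl_transcript_id=tx, ensembl_gene_id=gid, fpkm=fpkm, experiment_id=exp
                )
            )
        h_rows.append(GeneCount(ensembl_gene_id=gid, count=max(1, rdp), experiment_id=exp))

    m_rows = []
    counted = {r.ensembl_gene_id for r in h_rows}
    for tid, beta, gene, count in meth:
        gid = _TSG_IDS[gene]
        m_rows.append(
            MethylationProbe(
                target_id=tid,
                avg_beta=beta,
                regulatory_feature="Promoter Associated",
                relation_to_cpg_island="Island",
                ensembl_gene_id=gid,
                experiment_id=exp,
            )
        )
        if gid not in counted:
            h_rows.append(GeneCount(ensembl_gene_id=gid, count=count, experiment_id=exp))
            counted.add(gid)

    meta = [
        ExperimentMeta(
            patient_id="CASE01",
            experiment_id=exp,
            experiment_description=f"{sample} multi-omic profiling",
            sample_type="bone marrow aspirate, CD138-selected plasma cells",
            sample_description=f"{sample} sample",
            experiment_date=year,
            sample_collection_date=year,
        )
    ]

    return DatasetBundle(
        w=relation(w_rows, WesVariant),
        m=relation(m_rows, MethylationProbe),
        c=relation(c_rows, CopyNumberSegment),
        h=relation(h_rows, GeneCount),
        rv=relation(rv_rows, RnaVariant),
        r=relation(r_rows, TranscriptQuant),
        key_genes=example_key_gene_list(),
        meta=relation(meta, ExperimentMeta),
    )


def key_genes_of(gene_list: pd.DataFrame) -> pd.DataFrame:
    """Entries of a gene list that are not TSG-classified (the KG group)."""
    cls = gene_list["classification"].map(lambda v: None if pd.isna(v) else str(v).lower())
    return gene_list[cls != "tsg"].reset_index(drop=True)


def tsg_genes_of(gene_list: pd.DataFrame) -> pd.DataFrame:
    """TSG-classified entries of a gene list."""
    cls = gene_list["classification"].map(lambda v: None if pd.isna(v) else str(v).lower())
    return gene_list[cls == "tsg"].reset_index(drop=True)
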