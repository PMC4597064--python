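"""Static visualizations of clonal structure.

Three standard views: a genome-wide mutational overview (position vs VAF,
depth-colored), a paired presentation-vs-relapse VAF scatter, and a
two-panel figure combining the copy-number-weighted VAF kernel density
with a depth-vs-VAF scatter whose glyphs encode the evidence level.

Every plot also writes a sidecar tab-separated export of the plotted
coordinates, colors and glyphs next to the image; the export, not the
pixels, is the testable contract, so rendering stays backend independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from omiclone._genome import GRCH37_CHROM_LENGTHS
from omiclone.clonality import KdeCurve
from omiclone.integration import Glyph
from omiclone.relations import CHROMOSOMES, SchemaError

__all__ = ["PlotSpec", "plot_genomic_overview", "plot_paired_scatter", "plot_kde_scatter"]


@dataclass
class PlotSpec:
    """Rendering options shared by all plots."""

    title: str = ""
    path: str | Path = "plot.png"
    width_px: int = 1200
    height_px: int = 800
    opacity: float = 0.5
    label_genes: tuple[str, ...] = ()
    show_kg_only: bool = False

    def __post_init__(self):
        if not 0 < self.opacity <= 1:
            raise ValueError("opacity must be in (0, 1]")

    @property
    def export_path(self) -> Path:
        p = Path(self.path)
        return p.with_suffix(p.suffix + ".export.tsv") if p.suffix else p.with_suffix(".export.tsv")

    def _figure(self, nrows: int = 1):
        dpi = 100
        return plt.subplots(
            nrows,
            1,
            figsize=(self.width_px / dpi, self.height_px / dpi),
            dpi=dpi,
            sharex=(nrows > 1),
        )


def _kg_symbols(k: pd.DataFrame | None) -> set:
    if k is None or "gene_symbol" not in k.columns:
        return set()
    return set(k["gene_symbol"].dropna())


def _write_export(df: pd.DataFrame, spec: PlotSpec) -> None:
    df.to_csv(spec.export_path, sep="\t", index=False)


def _band_offsets() -> tuple[dict[str, float], float]:
    """Cumulative start offset of each chromosome band, genome scale."""
    offsets, acc = {}, 0.0
    for c in CHROMOSOMES:
        offsets[c] = acc
        acc += GRCH37_CHROM_LENGTHS[c]
    return offsets, acc


def plot_genomic_overview(w: pd.DataFrame, spec: PlotSpec) -> Path:
    """Genome-wide mutation overview ("genomic real estate").

    The x-axis is partitioned into 24 chromosome bands scaled by GRCh37
    chromosome length; each variant is placed at its genomic offset, with
    VAF on the y-axis and read depth mapped to a log-spaced color scale.
    """
    offsets, total = _band_offsets()
    unknown = set(w["chromosome"]) - set(CHROMOSOMES) if len(w) else set()
    if unknown:
        raise SchemaError(f"unknown chromosome label(s): {sorted(unknown)}")
    xs = (
        np.array([offsets[c] + p for c, p in zip(w["chromosome"], w["position"])], dtype=float)
        if len(w)
        else np.array([])
    )
    export = pd.DataFrame(
        {
            "chromosome": w["chromosome"] if len(w) else [],
            "position": w["position"] if len(w) else [],
            "x_genome": xs,
            "x_fraction": xs / total if len(w) else [],
            "vaf": w["dna_allelic_freq"] if len(w) else [],
            "depth": w["dna_depth"] if len(w) else [],
        }
    )
    fig, ax = spec._figure()
    if len(w):
        norm = matplotlib.colors.LogNorm(
            vmin=max(1, int(w["dna_depth"].min())), vmax=max(2, int(w["dna_depth"].max()))
        )
        sc = ax.scatter(
            xs, w["dna_allelic_freq"], c=w["dna_depth"].astype(float), cmap="viridis",
            norm=norm, s=14, alpha=spec.opacity, linewidths=0,
        )
        fig.colorbar(sc, ax=ax, label="depth (reads, log scale)")
    bounds = [offsets[c] for c in CHROMOSOMES] + [total]
    for b in bounds[1:-1]:
        ax.axvline(b, color="0.85", lw=0.6, zorder=0)
    ax.set_xticks([offsets[c] + GRCH37_CHROM_LENGTHS[c] / 2 for c in CHROMOSOMES])
    ax.set_xticklabels(CHROMOSOMES, fontsize=7)
    ax.set_xlim(0, total)
    ax.set_ylim(0, 100)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("VAF (%)")
    ax.set_title(spec.title or "Genomic mutational overview")
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    _write_export(export, spec)
    return Path(spec.path)


def plot_paired_scatter(
    common: pd.DataFrame,
    unique1: pd.DataFrame,
    unique2: pd.DataFrame,
    k: pd.DataFrame | None,
    spec: PlotSpec,
    vaf2_by_locus: dict[tuple[str, int], float] | None = None,
) -> Path:
    """Paired-sample VAF scatter: first sample on x, second on y.

    Shared variants are plotted at (VAF1, VAF2); sample-unique variants
    sit on their own axis with the other coordinate at 0.  Key genes are
    labelled; ``show_kg_only`` hides unlabelled points.  ``vaf2_by_locus``
    supplies the second sample's VAF for shared loci (default 0 when
    absent).
    """
    vaf2_by_locus = vaf2_by_locus or {}
    kg_symbols = _kg_symbols(k)

    def rows_for(rel, group, x_from_rel, y_lookup):
        out = []
        for _, r in rel.iterrows():
            locus = (r["chromosome"], int(r["position"]))
            vaf = float(r["dna_allelic_freq"])
            x, y = (vaf, y_lookup(locus, vaf))
            if group == "second_only":
                x, y = 0.0, vaf
            sym = r.get("gene_symbol")
            labelled = sym in kg_symbols
            out.append((r["chromosome"], r["position"], x, y, group, sym, labelled))
        return out

    rows = []
    rows += rows_for(common, "shared", True, lambda locus, v: float(vaf2_by_locus.get(locus, 0.0)))
    rows += rows_for(unique1, "first_only", True, lambda locus, v: 0.0)
    rows += rows_for(unique2, "second_only", False, lambda locus, v: 0.0)
    export = pd.DataFrame(
        rows, columns=["chromosome", "position", "x_vaf", "y_vaf", "group", "gene_symbol", "labelled"]
    )
    if spec.show_kg_only:
        export = export[export["labelled"]].reset_index(drop=True)

    colors = {"shared": "tab:blue", "first_only": "tab:green", "second_only": "tab:red"}
    fig, ax = spec._figure()
    for group, sub in export.groupby("group"):
        ax.scatter(sub["x_vaf"], sub["y_vaf"], c=colors[group], label=group.replace("_", " "),
                   alpha=spec.opacity, s=18, linewidths=0)
    for _, r in export[export["labelled"]].iterrows():
        ax.annotate(r["gene_symbol"], (r["x_vaf"], r["y_vaf"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.set_xlabel("VAF (%), first sample")
    ax.set_ylabel("VAF (%), second sample")
    ax.legend(fontsize=8)
    ax.set_title(spec.title or "Paired-sample variant comparison")
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    _write_export(export, spec)
    return Path(spec.path)


def plot_kde_scatter(
    w_hat: pd.DataFrame, curve: KdeCurve, k: pd.DataFrame | None, spec: PlotSpec
) -> Path:
    """Two-panel density-plus-scatter view of one sample.

    Upper panel: the copy-number-weighted VAF kernel density.  Lower
    panel: depth vs VAF, one marker per distinct mutation — a circle for
    DNA-only evidence, a star for mutations also expressed in RNA — with
    key genes labelled.  The panels share the VAF axis.
    """
    kg_symbols = _kg_symbols(k)
    export = pd.DataFrame(
        {
            "chromosome": w_hat["chromosome"],
            "position": w_hat["position"],
            "vaf": w_hat["dna_allelic_freq"],
            "depth": w_hat["dna_depth"],
            "glyph": w_hat["glyph"],
            "glyph_name": [Glyph(g).name for g in w_hat["glyph"]],
            "gene_symbol": w_hat["gene_symbol"],
            "labelled": [s in kg_symbols for s in w_hat["gene_symbol"]],
        }
    )
    if spec.show_kg_only:
        export = export[export["labelled"]].reset_index(drop=True)

    fig, (ax_kde, ax_sc) = spec._figure(nrows=2)
    ax_kde.plot(curve.grid, curve.density, color="tab:purple")
    ax_kde.fill_between(curve.grid, curve.density, alpha=0.25, color="tab:purple")
    ax_kde.set_ylabel("density")
    ax_kde.set_title(
        spec.title or f"VAF kernel density (h={curve.bandwidth:.2f}) and mutation scatter"
    )
    wes_only = export[export["glyph"] == int(Glyph.WES_ONLY)]
    wes_rna = export[export["glyph"] == int(Glyph.WES_PLUS_RNA)]
    ax_sc.scatter(wes_only["vaf"], wes_only["depth"], marker="o", c="tab:blue",
                  alpha=spec.opacity, s=22, linewidths=0, label="DNA only")
    ax_sc.scatter(wes_rna["vaf"], wes_rna["depth"], marker="*", c="tab:red",
                  alpha=min(1.0, spec.opacity + 0.3), s=90, linewidths=0, label="DNA + RNA")
    for _, r in export[export["labelled"]].iterrows():
        ax_sc.annotate(r["gene_symbol"], (r["vaf"], r["depth"]), fontsize=7,
                       xytext=(3, 3), textcoords="offset points")
    ax_sc.set_xlim(0, 100)
    ax_sc.set_xlabel("VAF (%)")
    ax_sc.set_ylabel("depth (reads)")
    ax_sc.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    _write_export(export, spec)
    return Path(spec.path)
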