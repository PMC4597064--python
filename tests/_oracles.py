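"""Independent naive oracles the implementation is checked against.

Everything here works on lists of plain dicts with nested loops and exact
set algebra — deliberately sharing no code with the package's pandas
implementations.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd


def rows_of(df: pd.DataFrame) -> list[dict]:
    out = []
    for _, row in df.iterrows():
        out.append({c: (None if pd.isna(row[c]) else row[c]) for c in df.columns})
    return out


def _round_sig(x, sig=10):
    if not isinstance(x, float) or x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def canon(df: pd.DataFrame, cols=None) -> Counter:
    """Order-insensitive multiset of rows for comparison."""
    cols = list(cols or df.columns)
    items = []
    for _, row in df.iterrows():
        items.append(
            tuple(None if pd.isna(row[c]) else _round_sig(float(row[c])) if isinstance(row[c], (float, np.floating)) else row[c] for c in cols)
        )
    return Counter(items)


def canon_rows(rows: list[dict], cols) -> Counter:
    items = []
    for r in rows:
        items.append(
            tuple(
                None
                if r.get(c) is None
                else _round_sig(float(r[c]))
                if isinstance(r[c], (float, np.floating))
                else r[c]
                for c in cols
            )
        )
    return Counter(items)


# --- nested-loop relational operators ---------------------------------------


def nl_left_outer_join(left, right, pairs, right_cols):
    out = []
    for lr in left:
        matched = False
        for rr in right:
            if all(
                lr.get(a) is not None and rr.get(b) is not None and lr[a] == rr[b]
                for a, b in pairs
            ):
                matched = True
                merged = dict(lr)
                merged.update({c: rr[c] for c in right_cols})
                out.append(merged)
        if not matched:
            merged = dict(lr)
            merged.update({c: None for c in right_cols})
            out.append(merged)
    return out


def nl_equi_join(left, right, pairs, right_cols):
    out = []
    for lr in left:
        for rr in right:
            if all(
                lr.get(a) is not None and rr.get(b) is not None and lr[a] == rr[b]
                for a, b in pairs
            ):
                merged = dict(lr)
                merged.update({c: rr[c] for c in right_cols})
                out.append(merged)
    return out


def nl_intersect(a, b, keys):
    bkeys = {tuple(r[k] for k in keys) for r in b if all(r.get(k) is not None for k in keys)}
    seen, out = set(), []
    for r in a:
        key = tuple(r.get(k) for k in keys)
        if any(v is None for v in key) or key in seen:
            continue
        if key in bkeys:
            seen.add(key)
            out.append(r)
    return out


def nl_difference(a, b, keys):
    bkeys = {tuple(r[k] for k in keys) for r in b if all(r.get(k) is not None for k in keys)}
    seen, out = set(), []
    for r in a:
        key = tuple(r.get(k) for k in keys)
        if key in seen:
            continue
        seen.add(key)
        if any(v is None for v in key) or key not in bkeys:
            out.append(r)
    return out


def nl_project_distinct(rows, attrs):
    seen, out = set(), []
    for r in rows:
        key = tuple(_round_sig(r.get(a)) if isinstance(r.get(a), float) else r.get(a) for a in attrs)
        if key not in seen:
            seen.add(key)
            out.append({a: r.get(a) for a in attrs})
    return out


# --- monolithic pipeline oracle ---------------------------------------------


def nl_pipeline(bundle, min_vaf=4.0, max_vaf=100.0, min_depth=20, max_depth=1000):
    """Distinct-mutation rows computed by one nested-loop pass.

    Returns dicts with (chromosome, position, gene_symbol, copy_number,
    glyph) — the discriminating columns of the distinct-mutation relation.
    """
    w = rows_of(bundle.w)
    rv = rows_of(bundle.rv)
    r = rows_of(bundle.r)
    h = rows_of(bundle.h)
    c = rows_of(bundle.c)
    out = {}
    for v in w:
        if not (min_vaf <= v["dna_allelic_freq"] <= max_vaf):
            continue
        if not (min_depth <= v["dna_depth"] <= max_depth):
            continue
        if v["effect_impact"] not in ("MODERATE", "HIGH"):
            continue
        locus_rv = [x for x in rv if x["chromosome"] == v["chromosome"] and x["position"] == v["position"]]
        expressed = False
        for x in locus_rv:
            has_fpkm = any(t["ensembl_gene_id"] == x["ensembl_gene_id"] and t["fpkm"] > 0 for t in r)
            has_count = any(g["ensembl_gene_id"] == x["ensembl_gene_id"] and g["count"] > 0 for g in h)
            if has_fpkm or has_count:
                expressed = True
        cn = None
        hits = [
            s for s in c
            if s["chromosome"] == v["chromosome"] and s["start"] <= v["position"] <= s["stop"]
        ]
        assert len(hits) <= 1, "oracle: overlapping segments"
        if hits:
            cn = hits[0]["copy_number"]
        key = (v["chromosome"], v["position"], v["gene_symbol"], v["dna_change"])
        out[key] = {
            "chromosome": v["chromosome"],
            "position": v["position"],
            "gene_symbol": v["gene_symbol"],
            "copy_number": cn,
            "glyph": 2 if expressed else 1,
        }
    return list(out.values())


# --- KDE double-loop oracle ---------------------------------------------------


def nl_weighted_kde(values, weights, h, grid):
    dens = []
    wsum = float(sum(weights))
    for g in grid:
        s = 0.0
        for x, w in zip(values, weights):
            u = (x - g) / h
            s += w * math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
        dens.append(s / (h * wsum))
    return np.array(dens)
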