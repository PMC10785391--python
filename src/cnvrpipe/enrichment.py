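"""Interval annotation of CNVRs and hypergeometric QTL enrichment.

Significant regions are intersected with gene and QTL interval
annotations (BED or GFF3; user-supplied, e.g. an Ensembl gene build and
a QTL database export — no network fetch).  QTL-type enrichment asks,
for each QTL trait type, how surprising the number of overlapping QTLs
of that type is: with N QTLs in the database, K of the type, and n QTLs
overlapping the candidate regions of which k are of the type,

    p = P[X >= k],  X ~ Hypergeometric(N, K, n).

No multiple-testing correction is applied to enrichment p-values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .genome import normalize_chromosome
from .regions import CnvRegion

__all__ = [
    "read_bed_features",
    "read_gff3_features",
    "overlap_features",
    "qtl_enrichment",
]

_FEATURE_COLUMNS = ["chromosome", "start", "end", "feature_id", "feature_class", "type_label"]


def read_bed_features(
    path: str | Path, feature_class: str, type_label_column: int | None = None
) -> pd.DataFrame:
    """Load features from BED (0-based half-open on disk -> 1-based inclusive).

    Column 4 is the feature id; ``type_label_column`` (0-based index)
    optionally names the column carrying a type label (e.g. QTL trait
    type), defaulting to column 4 as well.
    """
    import pyranges as pr

    gr = pr.read_bed(str(path), as_df=True)
    df = pd.DataFrame(
        {
            "chromosome": gr["Chromosome"].map(normalize_chromosome),
            "start": gr["Start"].astype(int) + 1,
            "end": gr["End"].astype(int),
            "feature_id": gr["Name"].astype(str)
            if "Name" in gr
            else [f"{feature_class}{i+1}" for i in range(len(gr))],
            "feature_class": feature_class,
        }
    )
    if type_label_column is not None:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        df["type_label"] = raw.iloc[:, type_label_column].astype(str).to_numpy()
    else:
        df["type_label"] = df["feature_id"]
    return df[_FEATURE_COLUMNS]


def read_gff3_features(
    path: str | Path, feature_class: str = "gene", feature_types: Sequence[str] = ("gene",)
) -> pd.DataFrame:
    """Load features of the given GFF3 types (coordinates already 1-based)."""
    import pyranges as pr

    gr = pr.read_gff3(str(path), as_df=True)
    sub = gr[gr["Feature"].isin(list(feature_types))].reset_index(drop=True)
    ids = None
    for col in ("ID", "gene_id", "Name"):
        if col in sub.columns:
            ids = sub[col].astype(str)
            break
    if ids is None:
        ids = pd.Series([f"{feature_class}{i+1}" for i in range(len(sub))])
    biotype = None
    for col in ("biotype", "gene_biotype"):
        if col in sub.columns:
            biotype = sub[col].astype(str)
            break
    return pd.DataFrame(
        {
            "chromosome": sub["Chromosome"].map(normalize_chromosome),
            "start": sub["Start"].astype(int) + 1,  # pyranges stores 0-based starts
            "end": sub["End"].astype(int),
            "feature_id": ids,
            "feature_class": feature_class,
            "type_label": biotype if biotype is not None else sub["Feature"].astype(str),
        }
    )[_FEATURE_COLUMNS]


def overlap_features(regions: Sequence[CnvRegion], features: pd.DataFrame) -> pd.DataFrame:
    """One row per (region, feature) pair sharing >= 1 base.

    Both inputs are 1-based inclusive; a malformed feature with
    ``start > end`` (a mixed-convention symptom) raises.
    """
    missing = [c for c in _FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"features table missing columns {missing}")
    if (features["start"] > features["end"]).any():
        raise ValueError("feature with start > end: mixed coordinate conventions?")

    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(features.itertuples(index=False)):
        chrom = normalize_chromosome(f.chromosome)
        # IntervalTree is half-open; shift end by +1 to keep inclusive ends
        trees.setdefault(chrom, IntervalTree()).addi(int(f.start), int(f.end) + 1, i)

    rows = []
    for r in regions:
        tree = trees.get(normalize_chromosome(r.chromosome))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            f = features.iloc[iv.data]
            ov = min(r.end, int(f["end"])) - max(r.start, int(f["start"])) + 1
            rows.append(
                {
                    "region_id": r.region_id,
                    "chromosome": r.chromosome,
                    "feature_id": f["feature_id"],
                    "feature_class": f["feature_class"],
                    "type_label": f["type_label"],
                    "feature_start": int(f["start"]),
                    "feature_end": int(f["end"]),
                    "overlap_bp": int(ov),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chromosome", "feature_id", "feature_class",
            "type_label", "feature_start", "feature_end", "overlap_bp",
        ],
    )


def qtl_enrichment(overlaps: pd.DataFrame, database: pd.DataFrame) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per QTL type label.

    ``overlaps`` is the output of :func:`overlap_features` restricted to
    QTL features; ``database`` is the full QTL feature table.  Distinct
    feature ids are counted, so a QTL overlapping two regions counts
    once.
    """
    qtl_overlaps = overlaps[overlaps["feature_class"] == "QTL"]
    db = database[database["feature_class"] == "QTL"]
    N = int(db["feature_id"].nunique())
    drawn = qtl_overlaps.drop_duplicates("feature_id")
    n = int(len(drawn))
    if n > N:
        raise ValueError("more overlapping QTLs than database entries")
    rows = []
    for type_label, grp in drawn.groupby("type_label", sort=True):
        k = int(len(grp))
        K = int(db.loc[db["type_label"] == type_label, "feature_id"].nunique())
        if k > K:
            raise ValueError(f"k > K for type {type_label!r}: inconsistent database")
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"type_label": type_label, "k": k, "n": n, "K": K, "N": N, "p": p})
    return pd.DataFrame(rows, columns=["type_label", "k", "n", "K", "N", "p"])
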