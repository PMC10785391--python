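"""CNV region (CNVR) inference: merging, classification, genotype coding.

A CNVR is the transitive closure of CNV calls that share at least one base
(1-based inclusive coordinates, so calls ``100-200`` and ``200-300`` merge
while ``100-200`` and ``201-300`` do not).  Regions are classified as
deletion (all member calls have copy state < 2), duplication (all > 2) or
mixed.  For association each QC-passing sample is coded -1 (deletion
carrier), 0 (non-carrier) or +1 (duplication carrier) per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import chromosome_sort_key
from .io_qc import CnvCall

__all__ = [
    "CnvRegion",
    "merge_cnvrs",
    "classify_cnvr",
    "genotype_matrix",
    "cnvr_frequency",
    "annotate_frequencies",
    "summarize_by_chromosome",
    "regions_to_frame",
    "write_bed",
]

logger = logging.getLogger(__name__)


@dataclass
class CnvRegion:
    """Merged population-level CNV region (1-based inclusive)."""

    region_id: str
    chromosome: str
    start: int
    end: int
    member_calls: list[CnvCall] = field(default_factory=list)
    type: str = "unknown"  # deletion | duplication | mixed
    n_carriers: int = 0
    carrier_freq: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_cnvr(region: CnvRegion) -> str:
    """Classify a region from its member copy states."""
    if not region.member_calls:
        raise ValueError(f"region {region.region_id} has no member calls")
    states = {c.copy_state for c in region.member_calls}
    if 2 in states:
        raise ValueError("member call with neutral copy state")
    has_del = any(s < 2 for s in states)
    has_dup = any(s > 2 for s in states)
    if has_del and has_dup:
        return "mixed"
    return "deletion" if has_del else "duplication"


def merge_cnvrs(calls: Iterable[CnvCall]) -> list[CnvRegion]:
    """Merge CNV calls overlapping by >= 1 bp into CNVRs.

    Calls are sorted by (chromosome, start) internally, so the result is
    invariant to input order.  Region ids ``CNVR1..CNVRn`` are assigned in
    (chromosome, start) order.
    """
    ordered = sorted(calls, key=lambda c: (chromosome_sort_key(c.chromosome), c.start, c.end))
    regions: list[CnvRegion] = []
    cur: CnvRegion | None = None
    for c in ordered:
        # share >= 1 base under inclusive coords iff c.start <= cur.end
        if cur is not None and c.chromosome == cur.chromosome and c.start <= cur.end:
            cur.end = max(cur.end, c.end)
            cur.member_calls.append(c)
        else:
            cur = CnvRegion(
                region_id="", chromosome=c.chromosome, start=c.start, end=c.end,
                member_calls=[c],
            )
            regions.append(cur)
    for i, r in enumerate(regions, start=1):
        r.region_id = f"CNVR{i}"
        r.type = classify_cnvr(r)
    return regions


def genotype_matrix(
    regions: Sequence[CnvRegion],
    calls: Iterable[CnvCall],
    samples: Sequence[str],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Code samples x regions as {-1, 0, +1}.

    -1 if the sample has a deletion call overlapping the region, +1 for a
    duplication call, 0 otherwise.  A sample carrying both a deletion and a
    duplication within one region cannot be expressed on this scale; it is
    coded 0 (conservative toward the null) and reported in the returned
    conflict list.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    has_del = np.zeros((len(samples), len(regions)), dtype=bool)
    has_dup = np.zeros_like(has_del)

    by_chrom: dict[str, list[tuple[int, CnvRegion]]] = {}
    for j, r in enumerate(regions):
        by_chrom.setdefault(r.chromosome, []).append((j, r))

    for c in calls:
        i = sample_index.get(c.sample_id)
        if i is None:
            continue
        for j, r in by_chrom.get(c.chromosome, ()):
            if c.start <= r.end and c.end >= r.start:
                if c.copy_state < 2:
                    has_del[i, j] = True
                else:
                    has_dup[i, j] = True

    codes = np.where(has_del & ~has_dup, -1, np.where(has_dup & ~has_del, 1, 0))
    conflicts = [
        (samples[i], regions[j].region_id)
        for i, j in zip(*np.nonzero(has_del & has_dup))
    ]
    for sample, region in conflicts:
        logger.warning(
            "sample %s carries both deletion and duplication in %s; coded 0",
            sample, region,
        )
    mat = pd.DataFrame(
        codes.astype(np.int8),
        index=pd.Index(samples, name="sample_id"),
        columns=[r.region_id for r in regions],
    )
    return mat, conflicts


def cnvr_frequency(n_carriers: int, n_samples: int, min_freq: float = 0.01) -> tuple[float, bool]:
    """Carrier frequency and whether it clears the reporting floor."""
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    freq = n_carriers / n_samples
    return freq, freq >= min_freq


def annotate_frequencies(
    regions: Sequence[CnvRegion], genotypes: pd.DataFrame, min_freq: float = 0.01
) -> None:
    """Fill ``n_carriers``/``carrier_freq`` in-place from the genotype matrix."""
    n = len(genotypes)
    carriers = (genotypes != 0).sum(axis=0)
    for r in regions:
        r.n_carriers = int(carriers.get(r.region_id, 0))
        r.carrier_freq, _ = cnvr_frequency(r.n_carriers, n, min_freq)


def summarize_by_chromosome(
    regions: Sequence[CnvRegion], chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome CNVR counts, covered bp and percent coverage.

    Emits one row per chromosome in ``chrom_lengths`` (zeros where no
    region lies) plus a ``total`` row over the whole genome.  Percentages
    are recomputed from lengths, never cached.
    """
    for r in regions:
        if r.chromosome not in chrom_lengths:
            raise ValueError(f"region {r.region_id} on unknown chromosome {r.chromosome!r}")
    rows = []
    for chrom in sorted(chrom_lengths, key=chromosome_sort_key):
        rs = [r for r in regions if r.chromosome == chrom]
        bp = sum(r.length for r in rs)
        clen = int(chrom_lengths[chrom])
        rows.append(
            {
                "chromosome": chrom,
                "chrom_length": clen,
                "n_cnvrs": len(rs),
                "total_cnvr_bp": bp,
                "pct_covered": 100.0 * bp / clen,
            }
        )
    total_len = sum(int(v) for v in chrom_lengths.values())
    total_bp = sum(r["total_cnvr_bp"] for r in rows)
    rows.append(
        {
            "chromosome": "total",
            "chrom_length": total_len,
            "n_cnvrs": sum(r["n_cnvrs"] for r in rows),
            "total_cnvr_bp": total_bp,
            "pct_covered": 100.0 * total_bp / total_len,
        }
    )
    return pd.DataFrame(rows)


def regions_to_frame(regions: Sequence[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "type": r.type,
                "n_calls": len(r.member_calls),
                "n_carriers": r.n_carriers,
                "carrier_freq": r.carrier_freq,
            }
            for r in regions
        ],
        columns=[
            "region_id", "chromosome", "start", "end", "length", "type",
            "n_calls", "n_carriers", "carrier_freq",
        ],
    )


def write_bed(regions: Sequence[CnvRegion], path) -> None:
    """Write regions as BED (0-based half-open, converted on write)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.region_id}\t0\t.\n")
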