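"""Parsing of CNV call tables and sample/call-level quality control.

CNV calls arrive either in the whitespace-delimited ``.rawcnv`` dialect
written by SNP-array CNV callers (one call per line, e.g.
``chr6:116755758-117164372 numsnp=12 length=408,615 state5,cn=3 S001``)
or as an equivalent headered TSV.  Coordinates are 1-based inclusive and
``length = end - start + 1`` throughout.

Quality control is two-stage, mirroring standard SNP-array CNV practice:

* sample level — samples whose intensity noise metrics exceed thresholds
  (LRR SD > 0.30, BAF drift > 0.01, \\|GC wave factor\\| > 0.05) are removed
  with all their calls;
* call level — calls supported by fewer than 3 SNPs, shorter than 1 kb or
  longer than 5 Mb, or outside the autosomes are discarded.

Boundary values are kept: removal requires strict exceedance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import AUTOSOMES, normalize_chromosome

__all__ = [
    "CnvCall",
    "SampleQc",
    "QcThresholds",
    "ParseResult",
    "CallFilterResult",
    "FormatError",
    "parse_rawcnv",
    "read_sample_qc",
    "filter_samples",
    "filter_calls",
    "calls_to_frame",
]


class FormatError(ValueError):
    """Raised when an input file yields no parsable records."""


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication call in one sample (1-based inclusive)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_state: int
    n_snps: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in call {self}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.copy_state == 2:
            raise ValueError("copy-neutral state (cn=2) is not a CNV call")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_deletion(self) -> bool:
        return self.copy_state < 2

    @property
    def is_duplication(self) -> bool:
        return self.copy_state > 2


@dataclass(frozen=True)
class SampleQc:
    """Per-sample array quality metrics."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    gc_wave_factor: float
    n_calls: int = 0

    def __post_init__(self) -> None:
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise ValueError("lrr_sd and baf_drift must be non-negative")


@dataclass(frozen=True)
class QcThresholds:
    """Sample- and call-level QC thresholds (kept iff within bounds)."""

    max_lrr_sd: float = 0.30
    max_baf_drift: float = 0.01
    max_abs_gcwf: float = 0.05
    min_len_bp: int = 1_000
    max_len_bp: int = 5_000_000
    min_snps: int = 3
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if self.min_len_bp >= self.max_len_bp:
            raise ValueError("min_len_bp must be < max_len_bp")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass
class ParseResult:
    calls: list[CnvCall]
    rejects: list[tuple[int, str, str]] = field(default_factory=list)
    """(line number, line text, reason) for every unparsable/rejected line."""


# chr6:116755758-117164372 numsnp=12 length=408,615 state5,cn=3 SAMPLE ...
_RAWCNV_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[\w]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state\d+,cn=(?P<cn>\d+)"
    r"\s+(?P<sample>\S+)"
    r"(?P<rest>.*)$"
)
_CONF_RE = re.compile(r"conf=(?P<conf>[-+0-9.eE]+)")

_TSV_REQUIRED = ["sample_id", "chromosome", "start", "end", "copy_state", "n_snps"]


def _parse_rawcnv_line(line: str) -> CnvCall:
    m = _RAWCNV_RE.match(line.strip())
    if m is None:
        raise ValueError("unrecognized rawcnv line")
    cn = int(m.group("cn"))
    if cn == 2:
        raise ValueError("neutral state")
    conf = None
    cm = _CONF_RE.search(m.group("rest"))
    if cm:
        conf = float(cm.group("conf"))
    return CnvCall(
        sample_id=m.group("sample"),
        chromosome=normalize_chromosome(m.group("chrom")),
        start=int(m.group("start")),
        end=int(m.group("end")),
        copy_state=cn,
        n_snps=int(m.group("numsnp").replace(",", "")),
        confidence=conf,
    )


def parse_rawcnv(path: str | Path, dialect: str = "rawcnv") -> ParseResult:
    """Parse a CNV call file into :class:`CnvCall` records.

    Parameters
    ----------
    path : file in ``rawcnv`` or headered ``tsv`` dialect.
    dialect : ``"rawcnv"`` (whitespace key=value lines) or ``"tsv"``.

    Malformed lines are not dropped silently: they are returned in
    ``result.rejects`` with a reason.  A file with zero parsable calls
    raises :class:`FormatError`.
    """
    path = Path(path)
    if dialect not in {"rawcnv", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    result = ParseResult(calls=[])
    if dialect == "rawcnv":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                try:
                    result.calls.append(_parse_rawcnv_line(line))
                except ValueError as exc:
                    result.rejects.append((i, line.rstrip("\n"), str(exc)))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in _TSV_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"TSV missing required columns: {missing}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                conf = getattr(row, "confidence", None)
                conf = None if conf is None or pd.isna(conf) else float(conf)
                result.calls.append(
                    CnvCall(
                        sample_id=str(row.sample_id),
                        chromosome=normalize_chromosome(row.chromosome),
                        start=int(row.start),
                        end=int(row.end),
                        copy_state=int(row.copy_state),
                        n_snps=int(row.n_snps),
                        confidence=conf,
                    )
                )
            except (ValueError, TypeError) as exc:
                result.rejects.append((i, str(tuple(row)), str(exc)))
    if not result.calls:
        raise FormatError(f"no parsable CNV calls in {path}")
    return result


def read_sample_qc(path: str | Path) -> list[SampleQc]:
    """Read per-sample QC metrics from a headered CSV."""
    df = pd.read_csv(path, comment="#")
    required = ["sample_id", "lrr_sd", "baf_drift", "gc_wave_factor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample QC CSV missing columns: {missing}")
    n_calls = df["n_calls"] if "n_calls" in df.columns else pd.Series(0, index=df.index)
    return [
        SampleQc(
            sample_id=str(r.sample_id),
            lrr_sd=float(r.lrr_sd),
            baf_drift=float(r.baf_drift),
            gc_wave_factor=float(r.gc_wave_factor),
            n_calls=int(n),
        )
        for r, n in zip(df.itertuples(index=False), n_calls)
    ]


def filter_samples(
    qc: Sequence[SampleQc], thr: QcThresholds = QcThresholds()
) -> tuple[set[str], pd.DataFrame]:
    """Apply sample-level QC; return passing sample ids and a failure report.

    A sample passes iff ``lrr_sd <= max_lrr_sd`` and
    ``baf_drift <= max_baf_drift`` and ``|gc_wave_factor| <= max_abs_gcwf``
    (boundary values pass).
    """
    seen: set[str] = set()
    for s in qc:
        if s.sample_id in seen:
            raise ValueError(f"duplicate sample_id {s.sample_id!r} in QC table")
        seen.add(s.sample_id)

    passing: set[str] = set()
    rows = []
    for s in qc:
        reasons = []
        if s.lrr_sd > thr.max_lrr_sd:
            reasons.append(f"lrr_sd {s.lrr_sd:g} > {thr.max_lrr_sd:g}")
        if s.baf_drift > thr.max_baf_drift:
            reasons.append(f"baf_drift {s.baf_drift:g} > {thr.max_baf_drift:g}")
        if abs(s.gc_wave_factor) > thr.max_abs_gcwf:
            reasons.append(f"|gcwf| {abs(s.gc_wave_factor):g} > {thr.max_abs_gcwf:g}")
        if reasons:
            rows.append({"sample_id": s.sample_id, "reasons": "; ".join(reasons)})
        else:
            passing.add(s.sample_id)
    report = pd.DataFrame(rows, columns=["sample_id", "reasons"])
    return passing, report


@dataclass
class CallFilterResult:
    kept: list[CnvCall]
    removed_counts: dict[str, int]
    """Removals attributed to the FIRST failing rule, in order:
    sample_qc, chromosome, min_snps, length.  kept + removed sums to input."""

    @property
    def n_input(self) -> int:
        return len(self.kept) + sum(self.removed_counts.values())


def filter_calls(
    calls: Iterable[CnvCall],
    thr: QcThresholds = QcThresholds(),
    passing_samples: set[str] | None = None,
) -> CallFilterResult:
    """Apply call-level QC (and drop calls from QC-failing samples)."""
    counts = {"sample_qc": 0, "chromosome": 0, "min_snps": 0, "length": 0}
    kept: list[CnvCall] = []
    for c in calls:
        if passing_samples is not None and c.sample_id not in passing_samples:
            counts["sample_qc"] += 1
        elif thr.autosomes_only and c.chromosome not in AUTOSOMES:
            counts["chromosome"] += 1
        elif c.n_snps < thr.min_snps:
            counts["min_snps"] += 1
        elif not (thr.min_len_bp <= c.length <= thr.max_len_bp):
            counts["length"] += 1
        else:
            kept.append(c)
    return CallFilterResult(kept=kept, removed_counts=counts)


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (the TSV dialect's column set)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chromosome": c.chromosome,
                "start": c.start,
                "end": c.end,
                "copy_state": c.copy_state,
                "n_snps": c.n_snps,
                "confidence": c.confidence,
            }
            for c in calls
        ],
        columns=["sample_id", "chromosome", "start", "end", "copy_state", "n_snps", "confidence"],
    )
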