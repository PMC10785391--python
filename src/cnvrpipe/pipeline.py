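"""End-to-end orchestration: QC -> CNVR -> adjust -> associate -> annotate.

The pipeline is configured from a YAML mapping (see
:class:`PipelineConfig`).  Inputs are either simulated in-process (the
default — the real herd data are available only on request) or loaded
from files in the formats the stage modules define.  Every output table
carries a provenance header line (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adjustment import DEFAULT_TRAIT_SPECS, AdjustmentSpec, adjust_phenotypes
from .association import run_association
from .enrichment import overlap_features, qtl_enrichment, read_bed_features, read_gff3_features
from .genome import ARS_UCD12_AUTOSOME_LENGTHS
from .io_qc import QcThresholds, calls_to_frame, filter_calls, filter_samples, parse_rawcnv, read_sample_qc
from .pedigree import a_matrix, read_pedigree
from .regions import (
    annotate_frequencies,
    genotype_matrix,
    merge_cnvrs,
    regions_to_frame,
    summarize_by_chromosome,
)
from .simulate import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report_tables"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "cnvrpipe_out"
    seed: int = 20_240_101
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    # file-mode inputs (used when simulate=False)
    calls_path: str | None = None
    calls_dialect: str = "rawcnv"
    sample_qc_path: str | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    qc: dict = field(default_factory=dict)
    traits: list[str] | None = None
    adjustment: dict = field(default_factory=dict)
    alpha: float = 0.05
    min_carrier_freq: float = 0.0
    genes_path: str | None = None
    genes_format: str = "gff3"
    qtl_path: str | None = None
    qtl_type_column: int | None = 4
    chromosome_lengths: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("calls_path", "sample_qc_path", "pedigree_path", "phenotypes_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate=false")
                if not Path(p).exists():
                    raise ValueError(f"{name}: no such file {p!r}")
        for name in ("genes_path", "qtl_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: no such file {p!r}")

    def digest(self) -> str:
        # outdir is where results land, not part of the analysis identity
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__) if k != "outdir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **meta) -> None:
    header = f"# cnvrpipe {__version__} seed={cfg.seed} config={cfg.digest()}"
    for k, v in meta.items():
        header += f" {k}={v}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns a dict of result objects.

    Stage failures are wrapped in :class:`PipelineError` carrying the
    stage name.  Outputs land under ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- inputs -----------------------------------------------------
    try:
        if cfg.simulate:
            sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
            study = simulate_study(sim_cfg)
            calls, sample_qc = study.calls, study.sample_qc
            pedigree, phenos = study.pedigree, study.phenotypes
            chrom_lengths = dict(sim_cfg.chromosome_lengths)
            results["study"] = study
        else:
            calls = parse_rawcnv(cfg.calls_path, dialect=cfg.calls_dialect).calls
            sample_qc = read_sample_qc(cfg.sample_qc_path)
            pedigree = read_pedigree(cfg.pedigree_path)
            phenos = pd.read_csv(cfg.phenotypes_path, comment="#")
            chrom_lengths = dict(cfg.chromosome_lengths or ARS_UCD12_AUTOSOME_LENGTHS)
    except (OSError, ValueError) as exc:
        raise PipelineError("input", str(exc)) from exc

    # ---- qc ---------------------------------------------------------
    try:
        thresholds = QcThresholds(**cfg.qc)
        passing, qc_report = filter_samples(sample_qc, thresholds)
        call_filter = filter_calls(calls, thresholds, passing)
        logger.info(
            "qc: %d/%d samples pass; %d/%d calls kept (%s)",
            len(passing), len(sample_qc), len(call_filter.kept), call_filter.n_input,
            call_filter.removed_counts,
        )
        _write(qc_report, outdir / "qc_failures.tsv", cfg)
        with open(outdir / "qc_summary.json", "w") as fh:
            json.dump(
                {
                    "n_samples": len(sample_qc),
                    "n_samples_pass": len(passing),
                    "n_calls_input": call_filter.n_input,
                    "n_calls_kept": len(call_filter.kept),
                    "removed_counts": call_filter.removed_counts,
                },
                fh, indent=2,
            )
        results["passing_samples"] = passing
        results["call_filter"] = call_filter
    except ValueError as exc:
        raise PipelineError("qc", str(exc)) from exc

    # ---- cnvr -------------------------------------------------------
    try:
        regions = merge_cnvrs(call_filter.kept)
        samples = sorted(passing)
        genotypes, conflicts = genotype_matrix(regions, call_filter.kept, samples)
        annotate_frequencies(regions, genotypes)
        if cfg.min_carrier_freq > 0:
            keep_ids = {r.region_id for r in regions if r.carrier_freq >= cfg.min_carrier_freq}
            regions = [r for r in regions if r.region_id in keep_ids]
            genotypes = genotypes[[r.region_id for r in regions]]
        summary = summarize_by_chromosome(regions, chrom_lengths)
        _write(regions_to_frame(regions), outdir / "cnvr.tsv", cfg)
        _write(summary, outdir / "cnvr_by_chromosome.tsv", cfg)
        logger.info("cnvr: %d regions from %d calls", len(regions), len(call_filter.kept))
        results.update(regions=regions, genotypes=genotypes, summary=summary,
                       genotype_conflicts=conflicts)
    except ValueError as exc:
        raise PipelineError("cnvr", str(exc)) from exc

    # ---- adjust -----------------------------------------------------
    try:
        trait_cols = cfg.traits or [
            c for c in phenos.columns
            if c not in {"animal_id", "animal"} and pd.api.types.is_numeric_dtype(phenos[c])
            and c not in {"CGw", "CGr", "BM", "CA", "AW", "ASW", "AST", "CG"}
        ]
        phenos = phenos.rename(columns={"animal": "animal_id"})
        adjusted_cols = {}
        for trait in trait_cols:
            if trait in cfg.adjustment:
                spec = AdjustmentSpec.from_dict({"trait": trait, **cfg.adjustment[trait]})
            elif trait in DEFAULT_TRAIT_SPECS:
                spec = DEFAULT_TRAIT_SPECS[trait]
            elif "CG" in phenos.columns:
                spec = AdjustmentSpec(trait, ("CG",), ())
            else:
                spec = None
            if spec is None:
                adjusted_cols[trait] = phenos.set_index("animal_id")[trait]
            else:
                adj, _ = adjust_phenotypes(phenos, spec, value_column=trait)
                adjusted_cols[trait] = adj.set_index("animal_id")["adjusted"]
        adjusted = pd.DataFrame(adjusted_cols)
        adjusted.index.name = "animal_id"
        _write(adjusted.reset_index(), outdir / "adjusted_phenotypes.tsv", cfg)
        results["adjusted"] = adjusted
    except ValueError as exc:
        raise PipelineError("adjust", str(exc)) from exc

    # ---- associate --------------------------------------------------
    try:
        A, ids = a_matrix(pedigree)
        assoc, meta = run_association(
            genotypes, adjusted, A, ids, alpha=cfg.alpha
        )
        meta["seed"] = cfg.seed
        _write(assoc, outdir / "association.tsv", cfg,
               threshold=f"{meta['threshold']:.4g}", m=meta["m"])
        with open(outdir / "association_meta.json", "w") as fh:
            json.dump({k: v for k, v in meta.items() if k != "skipped"} |
                      {"n_skipped": len(meta["skipped"])}, fh, indent=2, default=float)
        results.update(association=assoc, association_meta=meta, A=A, ids=ids)
    except ValueError as exc:
        raise PipelineError("associate", str(exc)) from exc

    # ---- annotate ---------------------------------------------------
    if cfg.genes_path or cfg.qtl_path:
        try:
            sig_ids = set(assoc.loc[assoc["significant"] == True, "region_id"])  # noqa: E712
            sig_regions = [r for r in regions if r.region_id in sig_ids]
            frames = []
            if cfg.genes_path:
                reader = read_gff3_features if cfg.genes_format == "gff3" else read_bed_features
                genes = reader(cfg.genes_path) if cfg.genes_format == "gff3" \
                    else read_bed_features(cfg.genes_path, "gene")
                frames.append(genes)
            qtls = None
            if cfg.qtl_path:
                qtls = read_bed_features(cfg.qtl_path, "QTL", cfg.qtl_type_column)
                frames.append(qtls)
            features = pd.concat(frames, ignore_index=True)
            overlaps = overlap_features(sig_regions, features)
            _write(overlaps, outdir / "annotation_overlaps.tsv", cfg)
            results["overlaps"] = overlaps
            if qtls is not None:
                enr = qtl_enrichment(overlaps, qtls)
                _write(enr, outdir / "qtl_enrichment.tsv", cfg)
                results["enrichment"] = enr
        except ValueError as exc:
            raise PipelineError("annotate", str(exc)) from exc

    # ---- report -----------------------------------------------------
    report = report_tables(results["summary"], assoc, regions)
    (outdir / "report.txt").write_text(report)
    results["report"] = report
    return results


def report_tables(summary: pd.DataFrame, association: pd.DataFrame, regions) -> str:
    """Human-readable per-chromosome summary and significant-region table.

    Percentages are recomputed from lengths here rather than copied from
    the summary table.
    """
    lines = ["CNVR distribution by chromosome", "=" * 32]
    tab = summary.copy()
    tab["pct_covered"] = 100.0 * tab["total_cnvr_bp"] / tab["chrom_length"]
    lines.append(
        tab.to_string(
            index=False,
            formatters={"pct_covered": lambda v: f"{v:.2f}",
                        "chrom_length": "{:,}".format,
                        "total_cnvr_bp": "{:,}".format},
        )
    )
    lines += ["", "Significant CNVR associations", "=" * 30]
    sig = association.loc[association["significant"] == True]  # noqa: E712
    info = {r.region_id: r for r in regions}
    rows = []
    for r in sig.itertuples(index=False):
        reg = info.get(r.region_id)
        rows.append(
            {
                "region_id": r.region_id,
                "chromosome": reg.chromosome if reg else "?",
                "start": reg.start if reg else "?",
                "end": reg.end if reg else "?",
                "type": reg.type if reg else "?",
                "trait": r.trait,
                "beta": f"{r.beta:.4f}",
                "p": f"{r.p:.3e}",
            }
        )
    sig_tab = pd.DataFrame(
        rows, columns=["region_id", "chromosome", "start", "end", "type", "trait", "beta", "p"]
    )
    lines.append(sig_tab.to_string(index=False) if len(sig_tab) else sig_tab.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
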