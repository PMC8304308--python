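"""End-to-end orchestration: simulate → scan → call → overlap → candidates.

A :class:`RunConfig` holds every path and parameter with defaults equal to
the standard QTL-seq settings (1 Mb window, 1 kb step, 1000 null
replicates, 95% level, Δ threshold 0.7); the seed is mandatory.  When no
variant table is supplied the pipeline simulates the full F2 bulk
experiment first, so the default configuration is a self-contained
demonstration.  Every output is written atomically and a machine-readable
manifest (parameters, seed, per-stage counts, version) is always emitted;
re-running the same configuration reproduces the manifest counts exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import core, io, simdata
from .candidates import PatternRule, candidate_cascade
from .intervals import GeneFeature, GenomicInterval, intersect
from .simdata import CrossConfig, VarietyPanel

logger = logging.getLogger("qtlbsa")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "parse_region",
           "build_candidate_inputs", "map_sites_to_genes"]

STAGES = ("simulate", "scan", "call", "overlap", "candidates")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the failing stage's name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.  Seed is mandatory."""

    outdir: str
    seed: int
    # optional external inputs; simulated when absent
    variants: Optional[str] = None
    intervals: Optional[str] = None
    genes: Optional[str] = None
    panel: Optional[str] = None
    groups: Optional[str] = None
    cds: Optional[str] = None
    region: Optional[str] = None
    # scan parameters
    bulk_size: int = 17
    window_bp: int = 1_000_000
    step_bp: int = 1_000
    reps: int = 1000
    level: float = 95.0
    min_depth: int = 7
    min_sites: int = 3
    min_run: int = 10
    delta_threshold: float = 0.7
    orientation: str = "l_minus_e"
    annotation_keyword: Optional[str] = "NF-YA"
    # overrides for the synthetic cross (CrossConfig fields)
    sim: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("run config must set an explicit seed")
        if "outdir" not in d:
            raise ValueError("run config must set outdir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        return cls.from_dict(io.load_config_file(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` with Mb coordinates into an interval."""
    m = re.fullmatch(r"([^:]+):([\d.]+)-([\d.]+)", text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:startMb-endMb")
    return GenomicInterval(m.group(1), float(m.group(2)), float(m.group(3)))


def map_sites_to_genes(
    sites: pd.DataFrame, features: list[GeneFeature]
) -> pd.DataFrame:
    """Attach ``gene_id`` and ``cds_pos`` to sites falling inside gene spans.

    Genes are treated as single-exon coding spans: on the plus strand
    ``cds_pos = pos - start + 1``, on the minus strand
    ``pos`` counts back from the gene end.  Sites outside every gene are
    dropped.
    """
    rows = []
    by_chrom: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for row in sites.itertuples(index=False):
        for f in by_chrom.get(row.chrom, ()):
            if f.start_bp <= row.pos <= f.end_bp:
                cds_pos = (
                    row.pos - f.start_bp + 1 if f.strand == "+" else f.end_bp - row.pos + 1
                )
                d = row._asdict()
                d["gene_id"] = f.gene_id
                d["cds_pos"] = int(cds_pos)
                rows.append(d)
                break
    return pd.DataFrame(rows, columns=list(sites.columns) + ["gene_id", "cds_pos"])


_RC = str.maketrans("ACGT", "TGCA")


def build_candidate_inputs(
    sites: pd.DataFrame,
    region: GenomicInterval,
    seed: int,
    pattern_fraction: float = 0.25,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, VarietyPanel, dict, list[GeneFeature], dict]:
    """Construct synthetic gene models, CDS, panel and annotations around
    observed scan sites, for self-contained demonstration runs.

    Sites inside ``region`` are grouped into single-exon genes; each gene's
    CDS is built to carry the observed reference bases at the mapped CDS
    positions, the strongest-Δ quarter of sites gets the planted XIS
    variety pattern, and one gene whose variant survives the Δ threshold,
    coding-effect and pattern stages is annotated as an NF-YA transcription
    factor (so the demonstration cascade ends at a single candidate).
    """
    rng = np.random.default_rng(seed)
    sel = sites[
        (sites["chrom"] == region.chrom)
        & (sites["pos"] >= region.start_bp)
        & (sites["pos"] <= region.end_bp)
        & np.isfinite(sites["delta"])
    ].sort_values("pos", kind="stable")
    if sel.empty:
        raise ValueError(f"no usable sites inside {region}")

    # group nearby sites into genes (<= 240 bp apart, gene <= 300 codons)
    groups: list[list] = []
    for row in sel.itertuples(index=False):
        if groups and row.pos - groups[-1][-1].pos <= 240 and (
            row.pos - groups[-1][0].pos
        ) < 850:
            groups[-1].append(row)
        else:
            groups.append([row])

    features, cds, annotations = [], {}, {}
    out_rows = []
    for gi, grp in enumerate(groups, start=1):
        gene_id = f"SimGene{gi:04d}"
        strand = "-" if gi % 3 == 0 else "+"
        start = int(grp[0].pos) - 3
        end = int(grp[-1].pos) + 3
        n_codons = (end - start + 1 + 2) // 3
        end = start + 3 * n_codons - 1
        planted = []
        for row in grp:
            cds_pos = row.pos - start + 1 if strand == "+" else end - row.pos + 1
            ref = row.ref if strand == "+" else row.ref.translate(_RC)
            alt = row.alt if strand == "+" else row.alt.translate(_RC)
            planted.append((int(cds_pos), ref, alt))
            d = row._asdict()
            d["gene_id"] = gene_id
            d["cds_pos"] = int(cds_pos)
            out_rows.append(d)
        seq, _ = simdata.simulate_cds_with_variants(
            n_codons, planted, seed=int(rng.integers(2**31))
        )
        features.append(GeneFeature(gene_id, region.chrom, start, end, strand))
        cds[gene_id] = (seq, strand)
        annotations[gene_id] = "hypothetical protein"

    mapped = pd.DataFrame(out_rows)
    # plant the XIS pattern on the strongest-Δ sites (demonstration fixture)
    n_pattern = max(1, int(round(pattern_fraction * len(mapped))))
    order = mapped["delta"].to_numpy().argsort()[::-1]
    pattern = np.zeros(len(mapped), dtype=bool)
    pattern[order[:n_pattern]] = True

    # flag one NF-YA gene among sites surviving Δ, coding-effect and pattern
    from .candidates import annotate_effect

    best_gene, best_delta = None, -np.inf
    for flag, row in zip(pattern, mapped.itertuples(index=False)):
        if not flag or not row.delta > max(threshold, best_delta):
            continue
        seq, strand = cds[row.gene_id]
        call = annotate_effect(row.gene_id, seq, strand, row.cds_pos, row.ref, row.alt)
        if call.consequence != "synonymous":
            best_gene, best_delta = row.gene_id, row.delta
    if best_gene is not None:
        annotations[best_gene] = "NF-YA transcription factor"

    varieties = list(simdata.DEFAULT_VARIETY_GROUPS)
    rows = [
        simdata._panel_row(rng, varieties, simdata.DEFAULT_VARIETY_GROUPS, bool(p))
        for p in pattern
    ]
    geno = pd.DataFrame(rows)
    geno.insert(0, "pos", mapped["pos"].to_numpy())
    geno.insert(0, "chrom", region.chrom)
    panel = VarietyPanel(genotypes=geno)
    return mapped, panel, cds, features, annotations


def _called_to_intervals(qtls: pd.DataFrame) -> list[GenomicInterval]:
    out = []
    for i, r in enumerate(qtls.itertuples(index=False), start=1):
        out.append(
            GenomicInterval(
                r.chrom, r.start / 1e6, r.end / 1e6, label=f"scan_qtl{i}"
            )
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline end-to-end and write all artifacts + manifest.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage (after writing the partial
    manifest).
    """
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, config.log_level.upper(), logging.INFO)
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    def finish_stage(name: str, **counts) -> None:
        manifest["stages"][name] = {"status": "completed", **counts}
        logger.info("stage %s completed: %s", name, counts)

    def fail(name: str, exc: BaseException) -> None:
        manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        io.atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(name, exc) from exc

    chrom_lengths = None

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        if config.variants is None:
            sim_cfg = CrossConfig(seed=config.seed, **config.sim)
            pop = simdata.simulate_f2(sim_cfg)
            e_idx, l_idx = simdata.make_bulks(pop, sim_cfg.bulk_size)
            variants = simdata.sample_depths(pop, e_idx, l_idx)
            config.bulk_size = sim_cfg.bulk_size
            chrom_lengths = {sim_cfg.chrom: sim_cfg.chrom_length_bp}
            io.write_vcf(variants, outdir / "variants.vcf")
            io.write_variant_tsv(variants, outdir / "variants.tsv")
            io.write_tsv(
                pd.DataFrame(
                    {"individual": np.arange(pop.n_individuals), "dff_days": pop.phenotypes}
                ),
                outdir / "phenotypes.tsv",
            )
            finish_stage(stage, n_individuals=pop.n_individuals, n_sites=int(pop.n_sites))
        else:
            variants = io.read_variant_table(config.variants)
            finish_stage(stage, n_sites=int(len(variants)), source="external")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # --- scan ---------------------------------------------------------
    stage = "scan"
    try:
        indexed, profile, rejected = core.scan(
            variants,
            bulk_size=config.bulk_size,
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            min_depth=config.min_depth,
            min_sites=config.min_sites,
            reps=config.reps,
            level=config.level,
            seed=config.seed,
            orientation=config.orientation,
            chrom_lengths=chrom_lengths,
        )
        io.write_tsv(indexed, outdir / "sites.tsv", header_note="coordinates are 1-based")
        io.write_tsv(
            profile, outdir / "profile.tsv",
            header_note="windows half-open [start, end); coordinates 1-based",
        )
        finish_stage(
            stage,
            n_polarized=int(len(indexed)),
            n_rejected=int(len(rejected)),
            n_windows=int(len(profile)),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- call ---------------------------------------------------------
    stage = "call"
    try:
        qtls = core.call_qtls(profile, min_run=config.min_run)
        io.write_tsv(qtls, outdir / "qtls.tsv", header_note="coordinates 1-based inclusive")
        io.write_qtl_bed(qtls, outdir / "qtls.bed")
        finish_stage(stage, n_qtls=int(len(qtls)))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- overlap ------------------------------------------------------
    stage = "overlap"
    try:
        experiment_ivs = (
            io.read_intervals_tsv(config.intervals) if config.intervals else []
        )
        called_ivs = _called_to_intervals(qtls)
        pool = experiment_ivs + called_ivs
        consensus = None
        if config.region:
            consensus = parse_region(config.region)
        elif pool:
            # intersect every interval on the best-supported chromosome
            target_chrom = (experiment_ivs or called_ivs)[0].chrom
            same = [iv for iv in pool if iv.chrom == target_chrom]
            consensus = intersect(same)
        if consensus is None:
            raise ValueError("no QTL intervals to overlap and no region supplied")
        io.write_intervals_tsv(pool + [dataclasses.replace(consensus, label="consensus")],
                               outdir / "overlap.tsv")
        finish_stage(
            stage,
            n_intervals=len(pool),
            consensus=str(consensus),
            consensus_width_mb=round(consensus.width, 6),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- candidates ---------------------------------------------------
    stage = "candidates"
    try:
        external = config.panel and config.cds and config.genes
        if external:
            panel = io.read_panel_tsv(config.panel, config.groups)
            cds = io.read_cds_fasta(config.cds)
            features = io.read_genes(config.genes)
            mapped = map_sites_to_genes(indexed, features)
            annotations = None
        else:
            mapped, panel, cds, features, annotations = build_candidate_inputs(
                indexed, consensus, seed=config.seed, threshold=config.delta_threshold
            )
            io.write_panel_tsv(panel, outdir / "panel.tsv", outdir / "panel_groups.tsv")
            io.write_cds_fasta(cds, outdir / "cds.fasta")
        result = candidate_cascade(
            mapped,
            panel,
            cds,
            features,
            consensus,
            threshold=config.delta_threshold,
            rule=PatternRule(),
            annotations=annotations,
            annotation_keyword=config.annotation_keyword if annotations else None,
        )
        io.write_tsv(result.candidates, outdir / "candidates.tsv")
        io.write_tsv(result.audit, outdir / "candidate_audit.tsv")
        finish_stage(
            stage,
            n_candidates=int(len(result.candidates)),
            funnel=result.stage_gene_counts(),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    io.atomic_write_text(
        outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
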