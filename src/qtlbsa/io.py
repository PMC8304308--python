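"""Readers and writers for the standard formats the pipeline touches.

Conventions: all TSV and VCF coordinates are 1-based; BED output is 0-based
half-open (stated in each file's header line).  Floats are printed with six
significant digits; tests compare values with tolerances, never printed
strings.  Output files are written atomically (temp file + rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneFeature, GenomicInterval
from .simdata import DEFAULT_VARIETY_GROUPS, VarietyPanel

logger = logging.getLogger("qtlbsa")

__all__ = [
    "read_variant_table",
    "write_variant_tsv",
    "write_vcf",
    "read_intervals_tsv",
    "write_intervals_tsv",
    "read_genes",
    "write_qtl_bed",
    "write_tsv",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_cds_fasta",
    "write_cds_fasta",
    "load_config_file",
    "atomic_write_text",
]

PathLike = Union[str, Path]

_SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "p1_gt", "p2_gt",
    "e_ref", "e_alt", "l_ref", "l_alt",
]
_VCF_SAMPLES = ("parent1", "parent2", "e_pool", "l_pool")
_GT_TO_TUPLE = {"ref_hom": (0, 0), "alt_hom": (1, 1), "het": (0, 1)}


def atomic_write_text(path: PathLike, text: str) -> None:
    """Write ``text`` to ``path`` atomically via a temp file and rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: PathLike, header_note: str = "") -> None:
    """Atomic TSV write with 6-significant-digit floats and an optional
    ``#`` header note."""
    text = df.to_csv(sep="\t", index=False, float_format="%.6g")
    if header_note:
        text = f"# {header_note}\n{text}"
    atomic_write_text(path, text)


# ---------------------------------------------------------------------------
# Variant tables


def write_variant_tsv(sites: pd.DataFrame, path: PathLike) -> None:
    write_tsv(sites, path, header_note="coordinates are 1-based")


def write_vcf(sites: pd.DataFrame, path: PathLike) -> None:
    """Write a site table as minimal VCF 4.2 with GT and AD per sample.

    Samples are ``parent1, parent2, e_pool, l_pool``; pools get no GT call,
    only allele depths.  Parent depths default to a fixed stand-in of 20
    when the table carries none.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = pysam.VariantHeader()
    header.add_line("##source=qtlbsa")
    for chrom in pd.unique(sites["chrom"]):
        length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">'
    )
    for s in _VCF_SAMPLES:
        header.add_sample(s)

    tmp = path.with_name(f".{path.name}.tmp")
    with pysam.VariantFile(str(tmp), "w", header=header) as vcf:
        has_parent_depth = {"p1_ref", "p1_alt", "p2_ref", "p2_alt"}.issubset(sites.columns)
        for row in sites.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.samples["parent1"]["GT"] = _GT_TO_TUPLE.get(row.p1_gt)
            rec.samples["parent2"]["GT"] = _GT_TO_TUPLE.get(row.p2_gt)
            if has_parent_depth:
                p1_ad = (int(row.p1_ref), int(row.p1_alt))
                p2_ad = (int(row.p2_ref), int(row.p2_alt))
            else:
                p1_ad = (20, 0) if row.p1_gt == "ref_hom" else (0, 20)
                p2_ad = (20, 0) if row.p2_gt == "ref_hom" else (0, 20)
            rec.samples["parent1"]["AD"] = p1_ad
            rec.samples["parent2"]["AD"] = p2_ad
            rec.samples["e_pool"]["AD"] = (int(row.e_ref), int(row.e_alt))
            rec.samples["l_pool"]["AD"] = (int(row.l_ref), int(row.l_alt))
            vcf.write(rec)
    os.replace(tmp, path)


def _gt_code(sample) -> str:
    alleles = sample.get("GT")
    if alleles is None or any(a is None for a in alleles):
        return "missing"
    s = set(alleles)
    if s == {0}:
        return "ref_hom"
    if s == {1}:
        return "alt_hom"
    return "het"


def read_variant_table(path: PathLike, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a variant table from minimal VCF (with per-sample AD) or TSV.

    ``fmt`` is inferred from the file suffix when omitted.  Multi-allelic
    and indel records are skipped with a logged count.  TSV and VCF
    encodings of the same sites parse to identical tables.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in _SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: TSV lacks required columns {missing}")
        return df
    if fmt != "vcf":
        raise ValueError(f"unknown variant table format {fmt!r}")

    rows = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for want in _VCF_SAMPLES:
            if want not in sample_names:
                raise ValueError(f"{path}: VCF lacks sample {want!r}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            ads = {}
            for s in _VCF_SAMPLES:
                ad = rec.samples[s].get("AD")
                if ad is None or any(a is None for a in ad):
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks AD for sample {s!r}"
                    )
                ads[s] = ad
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam exposes 1-based pos
                    "ref": ref,
                    "alt": alt,
                    "p1_gt": _gt_code(rec.samples["parent1"]),
                    "p2_gt": _gt_code(rec.samples["parent2"]),
                    "p1_ref": ads["parent1"][0],
                    "p1_alt": ads["parent1"][1],
                    "p2_ref": ads["parent2"][0],
                    "p2_alt": ads["parent2"][1],
                    "e_ref": ads["e_pool"][0],
                    "e_alt": ads["e_pool"][1],
                    "l_ref": ads["l_pool"][0],
                    "l_alt": ads["l_pool"][1],
                }
            )
    if n_skipped:
        logger.info("%s: skipped %d multi-allelic/indel records", path, n_skipped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intervals, genes, QTL calls


def read_intervals_tsv(path: PathLike) -> list[GenomicInterval]:
    """Read QTL intervals as TSV with columns chrom, start_mb, end_mb, label."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"chrom", "start_mb", "end_mb"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: interval TSV needs columns {sorted(needed)}")
    if "label" not in df.columns:
        df["label"] = ""
    return [
        GenomicInterval(r.chrom, float(r.start_mb), float(r.end_mb), str(r.label))
        for r in df.itertuples(index=False)
    ]


def write_intervals_tsv(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {"chrom": iv.chrom, "start_mb": iv.start_mb, "end_mb": iv.end_mb,
             "width_mb": iv.width, "label": iv.label}
            for iv in intervals
        ],
        columns=["chrom", "start_mb", "end_mb", "width_mb", "label"],
    )
    write_tsv(df, path, header_note="coordinates in Mb, 1-based inclusive")


def read_genes(path: PathLike, fmt: Optional[str] = None) -> list[GeneFeature]:
    """Read gene models from GFF3 (``gene`` features) or BED."""
    import gffutils

    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        feats = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}: BED gene lines need >= 4 columns")
                strand = parts[5] if len(parts) > 5 else "+"
                feats.append(
                    GeneFeature(parts[3], parts[0], int(parts[1]) + 1, int(parts[2]), strand)
                )
        return feats
    if fmt != "gff3":
        raise ValueError(f"unknown gene model format {fmt!r}")
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.features_of_type("gene"):
        gene_id = f.attributes.get("ID", [f.id])[0]
        feats.append(GeneFeature(gene_id, f.seqid, f.start, f.end, f.strand or "+"))
    return feats


def write_qtl_bed(qtls: pd.DataFrame, path: PathLike) -> None:
    """Write called QTLs as BED (0-based half-open) with the sign as name."""
    lines = ["# BED: 0-based half-open"]
    for r in qtls.itertuples(index=False):
        name = f"qtl_{'pos' if r.sign > 0 else 'neg'}"
        lines.append(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\t{name}\t0\t+")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variety panel


def write_panel_tsv(panel: VarietyPanel, path: PathLike, groups_path: Optional[PathLike] = None) -> None:
    write_tsv(panel.genotypes, path, header_note="genotype codes: ref/alt/het/missing")
    if groups_path is not None:
        gdf = pd.DataFrame(
            sorted(panel.groups.items()), columns=["variety", "group"]
        )
        write_tsv(gdf, groups_path)


def read_panel_tsv(path: PathLike, groups_path: Optional[PathLike] = None) -> VarietyPanel:
    geno = pd.read_csv(path, sep="\t", comment="#")
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", comment="#")
        groups = dict(zip(gdf["variety"], gdf["group"]))
    else:
        groups = dict(DEFAULT_VARIETY_GROUPS)
    return VarietyPanel(genotypes=geno, groups=groups)


# ---------------------------------------------------------------------------
# Coding sequences


def write_cds_fasta(cds: dict[str, tuple[str, str]], path: PathLike) -> None:
    """Write gene CDS as FASTA; the strand is recorded in the description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=gene, description=f"strand={strand}")
        for gene, (seq, strand) in cds.items()
    ]
    tmp = path.with_name(f".{path.name}.tmp")
    SeqIO.write(records, str(tmp), "fasta")
    os.replace(tmp, path)


def read_cds_fasta(path: PathLike) -> dict[str, tuple[str, str]]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        strand = "+"
        for token in rec.description.split():
            if token.startswith("strand="):
                strand = token.split("=", 1)[1]
        out[rec.id] = (str(rec.seq).upper(), strand)
    return out


# ---------------------------------------------------------------------------
# Configuration


def load_config_file(path: PathLike) -> dict:
    """Load a YAML or JSON run configuration; the seed field is mandatory."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "seed" not in cfg:
        raise ValueError(f"{path}: config must set an explicit seed")
    return cfg
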