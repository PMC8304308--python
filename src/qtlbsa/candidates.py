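"""Candidate-gene filtering: Δ threshold, coding effect, variety pattern.

After a genome scan nominates a QTL region, candidate genes are narrowed by
a cascade of filters:

1. keep variant sites with Δ(SNP-index) strictly above a threshold
   (default 0.7);
2. keep only sites whose coding consequence changes the protein
   (non-synonymous, including stop gains/losses);
3. keep genes overlapping the consensus QTL region;
4. keep genes whose variant shows the XIS-specific cross-variety pattern —
   every North and South China accession matches the reference genome while
   all three Xishuangbanna accessions share the same non-reference allele;
5. optionally, keep genes whose functional annotation matches a keyword
   (e.g. the NF-YA subunit of the CCAAT-binding complex).  The final
   functional choice is a human judgement in practice; the keyword stage
   only surfaces the supplied annotation metadata.

Each stage shrinks its input and the cascade records site and gene counts
after every stage as an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .intervals import GeneFeature, GenomicInterval, genes_in_region

__all__ = [
    "EffectCall",
    "PatternRule",
    "filter_delta_sites",
    "annotate_effect",
    "pattern_filter",
    "candidate_cascade",
    "CascadeResult",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

GT_CODES = ("ref", "alt", "het", "missing")


@dataclass(frozen=True)
class EffectCall:
    """Codon-level consequence of one single-nucleotide variant on one CDS."""

    gene_id: str
    cds_pos: int
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str  # synonymous | nonsynonymous | stop_gained | stop_lost

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def annotate_effect(
    gene_id: str,
    cds_seq: str,
    strand: str,
    cds_pos: int,
    ref: str,
    alt: str,
) -> EffectCall:
    """Classify a genomic SNV mapped to a position within a spliced CDS.

    ``ref``/``alt`` are the *genomic* alleles; for minus-strand genes they
    are reverse-complemented before codon lookup.  The CDS must have length
    divisible by 3 and carry ``ref`` (strand-adjusted) at ``cds_pos``
    (1-based).  Translation uses the standard genetic code.
    """
    cds_seq = cds_seq.upper()
    if len(cds_seq) % 3:
        raise ValueError(f"gene {gene_id}: CDS length {len(cds_seq)} not divisible by 3")
    if not 1 <= cds_pos <= len(cds_seq):
        raise ValueError(
            f"gene {gene_id}: CDS position {cds_pos} beyond CDS of length {len(cds_seq)}"
        )
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene_id}: strand must be '+' or '-'")
    ref, alt = ref.upper(), alt.upper()
    if strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    if cds_seq[cds_pos - 1] != ref:
        raise ValueError(
            f"gene {gene_id}: reference base mismatch at CDS position {cds_pos}: "
            f"CDS has {cds_seq[cds_pos - 1]}, variant claims {ref}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_pos = (cds_pos - 1) % 3 + 1
    start = 3 * (codon_index - 1)
    ref_codon = cds_seq[start:start + 3]
    alt_codon = ref_codon[: codon_pos - 1] + alt + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "nonsynonymous"
    return EffectCall(
        gene_id=gene_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def filter_delta_sites(sites: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Sites with Δ(SNP-index) strictly greater than ``threshold``.

    The inequality is strict — a site at exactly the threshold does not
    survive — and missing Δ never passes.
    """
    if "delta" not in sites.columns:
        raise ValueError("site table lacks a 'delta' column; run the scan first")
    return sites[sites["delta"] > threshold].copy()


@dataclass(frozen=True)
class PatternRule:
    """Cross-variety allele pattern for a photoperiod-sensitivity candidate.

    Sites pass when every variety in ``ref_groups`` carries the reference
    allele and every variety in ``alt_group`` the same non-reference allele.
    Heterozygous calls never match (the panel comprises resequenced inbred
    lines, expected homozygous).  ``missing_policy='fail'`` (default) drops
    any site with a missing relevant call; ``'ignore'`` skips missing calls
    but still requires at least one observed call in ``alt_group``.
    """

    ref_groups: frozenset[str] = frozenset({"north", "south"})
    alt_group: str = "xis"
    missing_policy: str = "fail"

    def __post_init__(self) -> None:
        if self.alt_group in self.ref_groups:
            raise ValueError("alt_group must be disjoint from ref_groups")
        if self.missing_policy not in ("fail", "ignore"):
            raise ValueError("missing_policy must be 'fail' or 'ignore'")


def pattern_filter(panel, rule: PatternRule = PatternRule()) -> pd.DataFrame:
    """Subset of panel sites matching the cross-variety allele pattern.

    ``panel`` is a :class:`~qtlbsa.simdata.VarietyPanel` (or any object with
    ``genotypes`` and ``groups`` attributes).  Returns the matching rows of
    ``panel.genotypes``.
    """
    geno: pd.DataFrame = panel.genotypes
    groups: dict[str, str] = panel.groups
    known = set(groups.values())
    for g in list(rule.ref_groups) + [rule.alt_group]:
        if g not in known:
            raise ValueError(f"unknown group label {g!r}; panel has {sorted(known)}")
    ref_cols = [v for v, g in groups.items() if g in rule.ref_groups and v in geno.columns]
    alt_cols = [v for v, g in groups.items() if g == rule.alt_group and v in geno.columns]
    if not alt_cols:
        raise ValueError(f"panel has no varieties in group {rule.alt_group!r}")

    if rule.missing_policy == "fail":
        ok_ref = (geno[ref_cols] == "ref").all(axis=1)
        ok_alt = (geno[alt_cols] == "alt").all(axis=1)
    else:
        ok_ref = ((geno[ref_cols] == "ref") | (geno[ref_cols] == "missing")).all(axis=1)
        ok_alt = ((geno[alt_cols] == "alt") | (geno[alt_cols] == "missing")).all(
            axis=1
        ) & (geno[alt_cols] == "alt").any(axis=1)
    return geno[ok_ref & ok_alt].copy()


@dataclass
class CascadeResult:
    """Outcome of the candidate cascade with per-stage provenance."""

    candidates: pd.DataFrame  # gene_id, chrom, pos, consequence, ref_aa, alt_aa, ...
    audit: pd.DataFrame  # stage, n_sites, n_genes
    effects: list[EffectCall] = field(default_factory=list)

    def stage_gene_counts(self) -> dict[str, int]:
        return dict(zip(self.audit["stage"], self.audit["n_genes"]))


def candidate_cascade(
    sites: pd.DataFrame,
    panel,
    cds: dict[str, tuple[str, str]],
    features: Sequence[GeneFeature],
    region: GenomicInterval,
    threshold: float = 0.7,
    rule: PatternRule = PatternRule(),
    annotations: Optional[dict[str, str]] = None,
    annotation_keyword: Optional[str] = None,
) -> CascadeResult:
    """Run the full candidate-gene filter cascade with an audit trail.

    ``sites`` must carry ``chrom, pos, ref, alt, delta, gene_id, cds_pos``;
    ``cds`` maps gene ids to ``(sequence, strand)``.  Stages: Δ threshold →
    protein-changing effect → genes overlapping ``region`` → cross-variety
    pattern → (optional) annotation keyword.  Counts after each stage are
    non-increasing by construction.
    """
    needed = {"chrom", "pos", "delta", "gene_id", "cds_pos", "ref", "alt"}
    if not needed.issubset(sites.columns):
        raise ValueError(f"site table lacks columns {sorted(needed - set(sites.columns))}")
    audit_rows = []

    def record(stage: str, df: pd.DataFrame) -> None:
        audit_rows.append(
            {"stage": stage, "n_sites": len(df), "n_genes": df["gene_id"].nunique()}
        )

    # 1. Δ(SNP-index) threshold
    stage = filter_delta_sites(sites, threshold)
    record("delta", stage)

    # 2. protein-changing consequence
    effects: list[EffectCall] = []
    keep_rows = []
    for row in stage.itertuples(index=False):
        if row.gene_id not in cds:
            raise KeyError(f"no coding sequence for gene {row.gene_id}")
        seq, strand = cds[row.gene_id]
        call = annotate_effect(row.gene_id, seq, strand, int(row.cds_pos), row.ref, row.alt)
        effects.append(call)
        keep_rows.append(call.consequence != "synonymous")
    stage = stage[pd.Series(keep_rows, index=stage.index, dtype=bool)] if len(stage) else stage
    effect_by_site = {
        (e.gene_id, e.cds_pos): e for e in effects if e.consequence != "synonymous"
    }
    record("nonsynonymous", stage)

    # 3. consensus region
    surviving_features = [f for f in features if f.gene_id in set(stage["gene_id"])]
    in_region = {f.gene_id for f in genes_in_region(surviving_features, region)}
    stage = stage[stage["gene_id"].isin(in_region)]
    record("region", stage)

    # 4. cross-variety pattern
    passing = pattern_filter(panel, rule)
    pass_keys = set(zip(passing["chrom"], passing["pos"]))
    stage = stage[[
        (c, p) in pass_keys for c, p in zip(stage["chrom"], stage["pos"])
    ]] if len(stage) else stage
    record("pattern", stage)

    # 5. annotation keyword (metadata surfaced, not a computed inference)
    if annotation_keyword is not None:
        annotations = annotations or {}
        kw = annotation_keyword.lower()
        stage = stage[
            [kw in annotations.get(g, "").lower() for g in stage["gene_id"]]
        ] if len(stage) else stage
        record("annotation", stage)

    out = stage.copy()
    if len(out):
        calls = [effect_by_site[(g, c)] for g, c in zip(out["gene_id"], out["cds_pos"])]
        out["consequence"] = [e.consequence for e in calls]
        out["ref_aa"] = [e.ref_aa for e in calls]
        out["alt_aa"] = [e.alt_aa for e in calls]
        out["protein_change"] = [e.protein_change for e in calls]
    else:
        for col in ("consequence", "ref_aa", "alt_aa", "protein_change"):
            out[col] = pd.Series(dtype=object)
    if annotations:
        out["annotation"] = [annotations.get(g, "") for g in out["gene_id"]]
    out = out.sort_values("delta", ascending=False, kind="stable").reset_index(drop=True)
    return CascadeResult(
        candidates=out,
        audit=pd.DataFrame(audit_rows, columns=["stage", "n_sites", "n_genes"]),
        effects=effects,
    )
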