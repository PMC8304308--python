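"""Synthetic data with the statistical structure a QTL-seq experiment assumes.

The generator emulates the mapping design the rest of the package analyses:
an F2 population from a cross between a photoperiod-insensitive early parent
(P1) and a photoperiod-sensitive late parent (P2), phenotyped for days to
first flowering (DFF); tail-selected early/late bulks; pooled short-read
allele-depth sampling at biallelic marker sites; a nine-variety resequencing
panel with a North / South / XIS (Xishuangbanna) group structure; and toy
coding sequences with planted variants for effect annotation.

Model summary
-------------
* Recombination: a uniform genetic map (default 250 kb/cM) with Haldane
  mapping — crossovers per gamete are Poisson in map length, placed
  uniformly, with no interference.
* Genotypes are coded as the dose of the P2 allele: 0 (hom P1), 1 (het),
  2 (hom P2).
* Phenotype: ``DFF = baseline + effect_days * g(dose) + N(0, noise_sd)``
  where ``g(0)=0``, ``g(2)=1`` and ``g(1)=(1-dominance)/2``; the default
  ``dominance=1`` makes the early P1 allele fully dominant.
* Depths: per pool per site, total depth is Poisson(mean_depth) and the
  alternate-read count Binomial(depth, pool alternate frequency), where the
  pool frequency is the mean genotype dose over bulk members divided by 2.
  A fixed-depth mode exists for exact enumeration tests.

Everything is reproducible bit-for-bit from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneFeature, GenomicInterval

__all__ = [
    "CrossConfig",
    "F2Population",
    "VarietyPanel",
    "CandidateTruth",
    "DEFAULT_VARIETY_GROUPS",
    "SD_BASELINE_DFF_DAYS",
    "ED_BASELINE_DFF_DAYS",
    "simulate_f2",
    "genetic_value",
    "make_bulks",
    "pool_alt_freq",
    "sample_depths",
    "simulate_variety_panel",
    "simulate_cds_with_variants",
    "simulate_candidate_truth",
]

# Reference DFF means of the sensitive parent under short-day (8 h light)
# and equal-day (12 h light) regimes; synthetic phenotypes live on this
# scale so that day-range bulk thresholds are meaningful.
SD_BASELINE_DFF_DAYS = 80.0
ED_BASELINE_DFF_DAYS = 98.0

#: The nine-variety resequencing panel: North and South China types match
#: the reference genome (9930 is itself the reference), the three XIS
#: accessions are the photoperiod-sensitive group.
DEFAULT_VARIETY_GROUPS: dict[str, str] = {
    "CC3": "north",
    "CCMC": "north",
    "9930": "north",
    "Cuiyu8": "south",
    "L8": "south",
    "Erzaozi": "south",
    "SWCC8": "xis",
    "SWCC20": "xis",
    "SWCC23": "xis",
}

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CrossConfig:
    """Full parameterization of the synthetic F2 / bulk experiment.

    Defaults reproduce the study design the analysis targets: an F2 of 234
    individuals with tail bulks of 17, ~30x pooled depth, a 20-day
    flowering delay per homozygous late allele with 2-day residual noise,
    and a fully dominant early allele.
    """

    n_individuals: int = 234
    bulk_size: int = 17
    n_sites: int = 1000
    chrom_length_bp: int = 10_000_000
    causal_pos_bp: Optional[int] = 5_000_000
    effect_days: float = 20.0
    dominance: float = 1.0
    noise_sd: float = 2.0
    mean_depth: float = 30.0
    baseline_days: float = SD_BASELINE_DFF_DAYS
    bp_per_cm: float = 250_000.0
    chrom: str = "chr1"
    seed: int = 0
    fixed_depth: bool = False

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 1 <= self.bulk_size <= self.n_individuals // 2:
            raise ValueError("bulk_size must satisfy 1 <= bulk_size <= n_individuals/2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.chrom_length_bp < 1:
            raise ValueError("chrom_length_bp must be >= 1")
        if self.causal_pos_bp is not None and not (
            1 <= self.causal_pos_bp <= self.chrom_length_bp
        ):
            raise ValueError(
                f"causal_pos_bp {self.causal_pos_bp} lies outside the "
                f"chromosome [1, {self.chrom_length_bp}]"
            )
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.bp_per_cm <= 0:
            raise ValueError("bp_per_cm must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class F2Population:
    """An F2 population on one chromosome.

    ``genotypes`` is a (n_sites, n_individuals) int8 matrix of P2-allele
    doses (0 hom P1, 1 het, 2 hom P2); ``phenotypes`` is DFF in days;
    ``site_positions`` are 1-based base-pair coordinates sorted ascending.
    ``causal_dose`` is the dose at the causal locus (zeros when the cross
    has no causal locus), kept so planted truth is recoverable in tests.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    site_positions: np.ndarray
    config: CrossConfig
    causal_dose: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]


def genetic_value(dose: np.ndarray, effect_days: float, dominance: float) -> np.ndarray:
    """Phenotypic shift (days) contributed by the causal P2-allele dose.

    Homozygous P1 contributes 0, homozygous P2 ``effect_days``; the
    heterozygote contributes ``effect_days * (1 - dominance) / 2`` so that
    ``dominance=0`` is additive and ``dominance=1`` makes the early P1
    allele fully dominant.
    """
    dose = np.asarray(dose)
    het = (1.0 - dominance) / 2.0
    return effect_days * np.where(dose == 2, 1.0, np.where(dose == 1, het, 0.0))


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n > length:
        raise ValueError("more sites requested than base pairs available")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _gamete_alleles(
    rng: np.random.Generator,
    n_gametes: int,
    length_bp: int,
    bp_per_cm: float,
    query_pos: np.ndarray,
) -> np.ndarray:
    """(n_gametes, n_query) matrix of parental-origin alleles (0 = P1, 1 = P2).

    Each gamete is a recombinant mosaic of the two parental haplotypes:
    crossover count Poisson in map length (Haldane, no interference),
    crossover positions uniform, starting haplotype fair-coin.
    """
    morgans = length_bp / bp_per_cm / 100.0
    out = np.empty((n_gametes, query_pos.size), dtype=np.int8)
    n_xo = rng.poisson(morgans, size=n_gametes)
    starts = rng.integers(0, 2, size=n_gametes)
    for i in range(n_gametes):
        if n_xo[i]:
            xo = np.sort(rng.uniform(0.0, length_bp, size=n_xo[i]))
            seg = np.searchsorted(xo, query_pos)
        else:
            seg = 0
        out[i] = (starts[i] + seg) % 2
    return out


def simulate_f2(config: CrossConfig) -> F2Population:
    """Simulate an F2 population with an optional causal flowering-time locus.

    Each individual's chromosome is built from two independent gametes, each
    a recombinant mosaic of the parental haplotypes under a uniform Haldane
    map.  The phenotype is the baseline DFF plus the causal genetic value
    plus Gaussian noise.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = _draw_positions(rng, config.n_sites, config.chrom_length_bp)

    query = positions.astype(float)
    causal_col = None
    if config.causal_pos_bp is not None:
        query = np.append(query, float(config.causal_pos_bp))
        causal_col = query.size - 1

    g1 = _gamete_alleles(rng, config.n_individuals, config.chrom_length_bp,
                         config.bp_per_cm, query)
    g2 = _gamete_alleles(rng, config.n_individuals, config.chrom_length_bp,
                         config.bp_per_cm, query)
    dose_all = (g1 + g2).T  # (n_query, n_individuals)

    if causal_col is not None:
        causal_dose = dose_all[causal_col].copy()
        genotypes = np.ascontiguousarray(dose_all[:causal_col])
    else:
        causal_dose = np.zeros(config.n_individuals, dtype=np.int8)
        genotypes = np.ascontiguousarray(dose_all)

    phenotypes = (
        config.baseline_days
        + genetic_value(causal_dose, config.effect_days, config.dominance)
        + rng.normal(0.0, config.noise_sd, size=config.n_individuals)
    )
    return F2Population(
        genotypes=genotypes,
        phenotypes=phenotypes,
        site_positions=positions,
        config=config,
        causal_dose=causal_dose,
    )


def make_bulks(
    pop: F2Population,
    bulk_size: int,
    mode: str = "tails",
    thresholds: Optional[tuple[tuple[float, float], float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select the early (E) and late (L) bulks from phenotyped individuals.

    Parameters
    ----------
    mode
        ``"tails"`` takes the ``bulk_size`` earliest- and latest-flowering
        individuals.  ``"thresholds"`` restricts eligibility first: the
        E-pool is drawn from individuals whose DFF lies inside the closed
        day range ``thresholds[0]`` and the L-pool from those flowering
        strictly later than ``thresholds[1]`` days.
    thresholds
        ``((e_lo, e_hi), l_min)`` day cutoffs, required for mode
        ``"thresholds"``.

    Ties are broken deterministically by ascending individual index (stable
    sort), so the two pools are always disjoint for ``bulk_size <= n/2``.

    Returns (e_indices, l_indices), each sorted ascending.
    """
    ph = np.asarray(pop.phenotypes)
    n = ph.size
    if mode == "tails":
        if bulk_size > n // 2:
            raise ValueError("bulk_size larger than half the population")
        order = np.argsort(ph, kind="stable")
        e_idx = order[:bulk_size]
        l_idx = order[n - bulk_size:]
    elif mode == "thresholds":
        if thresholds is None:
            raise ValueError("mode='thresholds' requires day cutoffs")
        (e_lo, e_hi), l_min = thresholds
        e_elig = np.flatnonzero((ph >= e_lo) & (ph <= e_hi))
        l_elig = np.flatnonzero(ph > l_min)
        if e_elig.size < bulk_size:
            raise ValueError(
                f"E-pool: only {e_elig.size} individuals flower within "
                f"[{e_lo}, {e_hi}] d, need {bulk_size}"
            )
        if l_elig.size < bulk_size:
            raise ValueError(
                f"L-pool: only {l_elig.size} individuals flower after "
                f"{l_min} d, need {bulk_size}"
            )
        e_idx = e_elig[np.argsort(ph[e_elig], kind="stable")[:bulk_size]]
        l_order = np.argsort(ph[l_elig], kind="stable")
        l_idx = l_elig[l_order[l_elig.size - bulk_size:]]
        if np.intersect1d(e_idx, l_idx).size:
            raise ValueError("threshold ranges overlap: pools are not disjoint")
    else:
        raise ValueError(f"unknown bulk selection mode {mode!r}")
    return np.sort(e_idx), np.sort(l_idx)


def pool_alt_freq(pop: F2Population, indices: np.ndarray) -> np.ndarray:
    """Per-site P2 (alternate) allele frequency of a bulk: mean dose / 2."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty pool")
    return pop.genotypes[:, indices].mean(axis=1) / 2.0


def sample_depths(
    pop: F2Population,
    e_pool: np.ndarray,
    l_pool: np.ndarray,
    mean_depth: Optional[float] = None,
    seed: Optional[int] = None,
    fixed_depth: Optional[bool] = None,
) -> pd.DataFrame:
    """Emulate pooled short-read sequencing of the two bulks and parents.

    Per site and pool the total depth is Poisson(mean_depth) (or exactly
    ``round(mean_depth)`` in fixed-depth mode) and the alternate-read count
    Binomial(depth, pool alternate frequency).  Parents are emitted as fixed
    homozygotes: P1 carries the reference allele, P2 the alternate.

    Returns the variant-site table consumed by the scan stage, with columns
    ``chrom, pos, ref, alt, p1_gt, p2_gt, p1_ref, p1_alt, p2_ref, p2_alt,
    e_ref, e_alt, l_ref, l_alt``.
    """
    cfg = pop.config
    if mean_depth is None:
        mean_depth = cfg.mean_depth
    if fixed_depth is None:
        fixed_depth = cfg.fixed_depth
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    n = pop.n_sites
    freqs = {"e": pool_alt_freq(pop, e_pool), "l": pool_alt_freq(pop, l_pool)}

    def draw_depth(size: int) -> np.ndarray:
        if fixed_depth:
            return np.full(size, int(round(mean_depth)), dtype=np.int64)
        return rng.poisson(mean_depth, size=size)

    cols: dict[str, np.ndarray] = {}
    for pool, freq in freqs.items():
        depth = draw_depth(n)
        alt = rng.binomial(depth, freq)
        cols[f"{pool}_ref"] = depth - alt
        cols[f"{pool}_alt"] = alt

    p1_depth = draw_depth(n)
    p2_depth = draw_depth(n)

    ref_codes = rng.integers(0, 4, size=n)
    alt_codes = (ref_codes + rng.integers(1, 4, size=n)) % 4

    return pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pop.site_positions,
            "ref": _BASES[ref_codes],
            "alt": _BASES[alt_codes],
            "p1_gt": "ref_hom",
            "p2_gt": "alt_hom",
            "p1_ref": p1_depth,
            "p1_alt": 0,
            "p2_ref": 0,
            "p2_alt": p2_depth,
            "e_ref": cols["e_ref"],
            "e_alt": cols["e_alt"],
            "l_ref": cols["l_ref"],
            "l_alt": cols["l_alt"],
        }
    )


# ---------------------------------------------------------------------------
# Variety panel


@dataclass
class VarietyPanel:
    """Genotype codes per site x variety plus a group label per variety.

    ``genotypes`` has columns ``chrom, pos`` followed by one column per
    variety with codes in {ref, alt, het, missing}; ``groups`` maps each
    variety to its photoperiod-sensitivity class (north / south / xis).
    """

    genotypes: pd.DataFrame
    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_VARIETY_GROUPS))

    def __post_init__(self) -> None:
        varieties = [c for c in self.genotypes.columns if c not in ("chrom", "pos")]
        missing = [v for v in varieties if v not in self.groups]
        if missing:
            raise ValueError(f"varieties without a group label: {missing}")


def _panel_row(
    rng: np.random.Generator,
    varieties: Sequence[str],
    groups: dict[str, str],
    pattern: bool,
) -> dict[str, str]:
    """One panel row; ``pattern=True`` plants the XIS-specific allele pattern."""
    row = {v: "ref" for v in varieties}
    xis = [v for v in varieties if groups[v] == "xis"]
    others = [v for v in varieties if groups[v] != "xis"]
    if pattern:
        for v in xis:
            row[v] = "alt"
        return row
    # Violate the pattern in a randomized way.
    kind = rng.integers(0, 5)
    if kind == 0:  # discordant XIS: one member back to reference
        for v in xis:
            row[v] = "alt"
        row[xis[rng.integers(len(xis))]] = "ref"
    elif kind == 1:  # variant shared with a non-XIS variety
        for v in xis:
            row[v] = "alt"
        row[others[rng.integers(len(others))]] = "alt"
    elif kind == 2:  # missing call inside the XIS group
        for v in xis:
            row[v] = "alt"
        row[xis[rng.integers(len(xis))]] = "missing"
    elif kind == 3:  # heterozygous XIS call
        for v in xis:
            row[v] = "alt"
        row[xis[rng.integers(len(xis))]] = "het"
    # kind == 4: monomorphic reference row
    return row


def simulate_variety_panel(
    n_sites: int,
    n_pattern_sites: int,
    seed: int = 0,
    chrom: str = "chr1",
    positions: Optional[np.ndarray] = None,
    groups: Optional[dict[str, str]] = None,
) -> VarietyPanel:
    """Nine-variety genotype panel with exactly ``n_pattern_sites`` planted
    XIS-specific sites (all XIS accessions share one non-reference allele,
    every North/South accession matches the reference); the remaining sites
    violate the pattern in randomized ways.
    """
    if n_pattern_sites > n_sites:
        raise ValueError("n_pattern_sites cannot exceed n_sites")
    groups = dict(DEFAULT_VARIETY_GROUPS) if groups is None else dict(groups)
    varieties = list(groups)
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = _draw_positions(rng, n_sites, max(10 * n_sites, 1000))
    positions = np.asarray(positions)
    if positions.size != n_sites:
        raise ValueError("positions length must equal n_sites")

    is_pattern = np.zeros(n_sites, dtype=bool)
    if n_pattern_sites:
        is_pattern[rng.choice(n_sites, size=n_pattern_sites, replace=False)] = True

    rows = [_panel_row(rng, varieties, groups, bool(p)) for p in is_pattern]
    geno = pd.DataFrame(rows)
    geno.insert(0, "pos", positions)
    geno.insert(0, "chrom", chrom)
    return VarietyPanel(genotypes=geno, groups=groups)


# ---------------------------------------------------------------------------
# Coding sequences with planted variants


def simulate_cds_with_variants(
    length_codons: int,
    planted: Sequence[tuple[int, str, str]],
    seed: int = 0,
    fixed_bases: Optional[dict[int, str]] = None,
) -> tuple[str, list[tuple[int, str, str]]]:
    """A valid coding sequence carrying the stated reference bases.

    The CDS starts with ATG, contains no stop codon, and has length
    ``3 * length_codons``.  ``planted`` lists ``(cds_pos, ref_base,
    alt_base)`` variants (1-based positions within the spliced CDS); the
    returned sequence carries ``ref_base`` at each ``cds_pos``.
    ``fixed_bases`` optionally pins additional positions (e.g. to force a
    specific codon context) without declaring a variant there.

    Raises ``ValueError`` when two constraints disagree on one position, a
    constraint conflicts with the ATG start, or a fully constrained codon is
    a stop.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    length = 3 * length_codons
    rng = np.random.default_rng(seed)

    constrained: dict[int, str] = {}

    def constrain(pos: int, base: str) -> None:
        if not 1 <= pos <= length:
            raise ValueError(f"CDS position {pos} outside [1, {length}]")
        base = base.upper()
        if base not in "ACGT":
            raise ValueError(f"invalid base {base!r} at CDS position {pos}")
        if constrained.get(pos, base) != base:
            raise ValueError(
                f"conflicting reference base at CDS position {pos}: "
                f"{constrained[pos]} vs {base}"
            )
        constrained[pos] = base

    variants: list[tuple[int, str, str]] = []
    for cds_pos, ref, alt in planted:
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError(f"variant at {cds_pos} has identical ref and alt")
        if alt not in "ACGT":
            raise ValueError(f"invalid alt base {alt!r} at CDS position {cds_pos}")
        constrain(cds_pos, ref)
        variants.append((cds_pos, ref, alt))
    for pos, base in (fixed_bases or {}).items():
        constrain(pos, base)
    for i, b in enumerate("ATG", start=1):  # start codon
        constrain(i, b)

    codons: list[str] = []
    for ci in range(length_codons):
        fixed = [constrained.get(3 * ci + k + 1) for k in range(3)]
        free = [k for k in range(3) if fixed[k] is None]
        for _ in range(64):
            trial = list(fixed)
            for k in free:
                trial[k] = _BASES[rng.integers(4)]
            codon = "".join(trial)  # type: ignore[arg-type]
            if codon not in _STOP_CODONS:
                break
        else:
            raise ValueError(f"codon {ci + 1} is constrained to a stop codon")
        codons.append(codon)
    return "".join(codons), variants


# ---------------------------------------------------------------------------
# Planted truth for the full candidate-gene cascade

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class CandidateTruth:
    """A fully synthetic fixture for the candidate-gene filter cascade.

    Planted so the funnel of surviving gene counts after the
    (non-synonymous, region, variety-pattern, annotation) stages is exactly
    ``(n_nonsyn_genes, n_region_genes, n_pattern_genes, n_annotated)``.
    """

    sites: pd.DataFrame
    panel: VarietyPanel
    cds: dict[str, tuple[str, str]]  # gene_id -> (sequence, strand)
    features: list[GeneFeature]
    region: GenomicInterval
    annotations: dict[str, str]
    expected_counts: dict[str, int]
    pattern_genes: list[str]
    annotated_genes: list[str]


def simulate_candidate_truth(
    n_nonsyn_genes: int = 150,
    n_region_genes: int = 15,
    n_pattern_genes: int = 4,
    n_annotated: int = 1,
    n_syn_decoys: int = 10,
    n_lowdelta_decoys: int = 20,
    region: Optional[GenomicInterval] = None,
    wide_interval: tuple[float, float] = (19.13, 27.72),
    seed: int = 0,
) -> CandidateTruth:
    """Plant a candidate-gene funnel on one chromosome.

    ``n_nonsyn_genes`` genes carry one non-synonymous variant site with
    Δ(SNP-index) above the 0.7 threshold; ``n_region_genes`` of them lie
    inside ``region`` (default chr1:21.65-23.03 Mb), ``n_pattern_genes`` of
    those additionally show the XIS-specific variety pattern, and
    ``n_annotated`` of those carry an NF-YA annotation.  Decoy genes carry
    either a synonymous high-Δ site or a non-synonymous low-Δ site
    (including one at exactly Δ = 0.7, which the strict ``>`` threshold must
    drop).
    """
    if not n_nonsyn_genes >= n_region_genes >= n_pattern_genes >= n_annotated >= 0:
        raise ValueError("funnel counts must be non-increasing")
    rng = np.random.default_rng(seed)
    if region is None:
        region = GenomicInterval("chr1", 21.65, 23.03, label="DFF1.1")
    chrom = region.chrom

    gene_len_codons = 30
    gene_len_bp = 3 * gene_len_codons

    # --- gene placement: inside the region, then flanks of the wide interval
    starts_inside = np.linspace(
        region.start_bp + 1000, region.end_bp - gene_len_bp - 1000, max(n_region_genes, 1)
    ).astype(int)[:n_region_genes]
    n_outside = n_nonsyn_genes - n_region_genes
    wide_lo = int(wide_interval[0] * 1e6)
    wide_hi = int(wide_interval[1] * 1e6)
    left = np.arange(wide_lo, region.start_bp - 50_000, 25_000)
    right = np.arange(region.end_bp + 50_000, wide_hi - gene_len_bp, 25_000)
    flank = np.concatenate([left, right])
    if flank.size < n_outside + n_syn_decoys + n_lowdelta_decoys:
        raise ValueError("wide interval too small for the requested gene count")
    picked = np.sort(rng.choice(flank, size=n_outside + n_syn_decoys + n_lowdelta_decoys,
                                replace=False))
    starts_outside = picked[:n_outside]
    starts_syn = picked[n_outside:n_outside + n_syn_decoys]
    starts_low = picked[n_outside + n_syn_decoys:]

    records: list[dict] = []
    features: list[GeneFeature] = []
    cds: dict[str, tuple[str, str]] = {}
    annotations: dict[str, str] = {}

    def add_gene(start: int, kind: str, idx: int) -> str:
        gene_id = f"Gene{idx:04d}"
        strand = "-" if idx % 7 == 0 else "+"
        end = start + gene_len_bp - 1
        features.append(GeneFeature(gene_id, chrom, int(start), int(end), strand))
        codon_index = int(rng.integers(2, gene_len_codons))  # 1-based, skip ATG
        base0 = 3 * (codon_index - 1)
        if kind == "syn":
            # GAT -> GAC, third position, aspartate both ways
            cds_pos, ref, alt = base0 + 3, "T", "C"
        else:
            # GAT -> GGT, second position, aspartate to glycine
            cds_pos, ref, alt = base0 + 2, "A", "G"
        seq, _ = simulate_cds_with_variants(
            gene_len_codons,
            [(cds_pos, ref, alt)],
            seed=int(rng.integers(2**31)),
            fixed_bases={base0 + 1: "G", base0 + 2: "A", base0 + 3: "T"},
        )
        cds[gene_id] = (seq, strand)
        if strand == "+":
            pos = start + cds_pos - 1
            gref, galt = ref, alt
        else:
            pos = end - cds_pos + 1
            gref, galt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        if kind == "low":
            delta = float(rng.uniform(0.2, 0.69))
        else:
            delta = float(rng.uniform(0.75, 0.95))
        records.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": gref,
                "alt": galt,
                "gene_id": gene_id,
                "cds_pos": int(cds_pos),
                "delta": delta,
            }
        )
        annotations[gene_id] = "hypothetical protein"
        return gene_id

    idx = 0
    region_genes = []
    for s in starts_inside:
        idx += 1
        region_genes.append(add_gene(s, "nonsyn", idx))
    for s in starts_outside:
        idx += 1
        add_gene(s, "nonsyn", idx)
    for s in starts_syn:
        idx += 1
        add_gene(s, "syn", idx)
    low_gene_ids = []
    for s in starts_low:
        idx += 1
        low_gene_ids.append(add_gene(s, "low", idx))
    if low_gene_ids:  # exercise the strict > threshold boundary
        boundary = low_gene_ids[0]
        for r in records:
            if r["gene_id"] == boundary:
                r["delta"] = 0.7

    sites = pd.DataFrame.from_records(records).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    pattern_genes = region_genes[:n_pattern_genes]
    annotated = pattern_genes[:n_annotated]
    for g in annotated:
        annotations[g] = "NF-YA transcription factor; CCAAT-binding complex subunit A"

    pattern_pos = set(
        sites.loc[sites["gene_id"].isin(pattern_genes), "pos"].tolist()
    )
    groups = dict(DEFAULT_VARIETY_GROUPS)
    varieties = list(groups)
    rows = [
        _panel_row(rng, varieties, groups, pattern=(p in pattern_pos))
        for p in sites["pos"]
    ]
    geno = pd.DataFrame(rows)
    geno.insert(0, "pos", sites["pos"].to_numpy())
    geno.insert(0, "chrom", chrom)
    panel = VarietyPanel(genotypes=geno, groups=groups)

    return CandidateTruth(
        sites=sites,
        panel=panel,
        cds=cds,
        features=features,
        region=region,
        annotations=annotations,
        expected_counts={
            "nonsynonymous": n_nonsyn_genes,
            "region": n_region_genes,
            "pattern": n_pattern_genes,
            "annotation": n_annotated,
        },
        pattern_genes=pattern_genes,
        annotated_genes=annotated,
    )
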