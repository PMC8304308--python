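"""The QTL-seq statistic: SNP-index, Δ(SNP-index), windows, null band, calls.

Bulked-segregant analysis by sequencing compares two pools of
extreme-phenotype F2 individuals.  At each biallelic site polarized against
the maternal (P1) parent, the SNP-index of a pool is the fraction of its
reads carrying the paternal (P2) allele: 0 means the pool reads look like
P1, 1 means fully divergent.  Δ(SNP-index) is the late-pool index minus the
early-pool index; at unlinked sites it fluctuates around 0, while linkage
to the selected trait pushes it toward ±1.

The scan averages Δ in sliding windows (defaults: 1 Mb window, 1 kb step)
and compares each window mean against a simulation null band: under the
no-QTL null each pool's allele frequency is the mean of ``bulk_size``
independent F2 genotype doses (0, 1/2, 1 with probability 1/4, 1/2, 1/4)
and read counts are Binomial(depth, frequency).  Windows are declared part
of a QTL when a sufficiently long run of them falls outside the band.

Site tables are pandas DataFrames with columns ``chrom, pos, ref, alt,
p1_gt, p2_gt, e_ref, e_alt, l_ref, l_alt`` (plus optional parent depths);
positions are 1-based, windows half-open internally, reported intervals
1-based inclusive.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "polarize_sites",
    "snp_index",
    "delta_snp_index",
    "compute_indices",
    "window_scan",
    "null_band",
    "window_profile",
    "call_qtls",
    "scan",
]

_SWAP_PAIRS = (
    ("ref", "alt"),
    ("e_ref", "e_alt"),
    ("l_ref", "l_alt"),
    ("p1_ref", "p1_alt"),
    ("p2_ref", "p2_alt"),
)


def polarize_sites(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orient sites so the alternate allele is the P2 (sensitive-parent) allele.

    Only sites where the two parents are opposite homozygotes are
    informative for an F2 bulk comparison.  Sites where P1 is the alternate
    homozygote and P2 the reference homozygote are kept with alleles and all
    ref/alt depth pairs swapped; everything else is rejected with a reason
    code (``het_parent``, ``missing_parent``, ``concordant_parents``).

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason`` column.
    Rejection is a value, not an exception.
    """
    p1 = sites["p1_gt"].to_numpy()
    p2 = sites["p2_gt"].to_numpy()

    het = (p1 == "het") | (p2 == "het")
    miss = (p1 == "missing") | (p2 == "missing")
    keep_fwd = (p1 == "ref_hom") & (p2 == "alt_hom")
    keep_rev = (p1 == "alt_hom") & (p2 == "ref_hom")

    reason = np.full(len(sites), "", dtype=object)
    reason[~(keep_fwd | keep_rev)] = "concordant_parents"
    reason[miss] = "missing_parent"
    reason[het] = "het_parent"

    kept = sites[keep_fwd | keep_rev].copy()
    rejected = sites[~(keep_fwd | keep_rev)].copy()
    rejected["reason"] = reason[~(keep_fwd | keep_rev)]

    rev = kept["p1_gt"].to_numpy() == "alt_hom"
    if rev.any():
        for a, b in _SWAP_PAIRS:
            if a in kept.columns and b in kept.columns:
                va, vb = kept[a].to_numpy().copy(), kept[b].to_numpy().copy()
                va[rev], vb[rev] = vb[rev], va[rev].copy()
                kept[a], kept[b] = va, vb
        kept.loc[rev, "p1_gt"] = "ref_hom"
        kept.loc[rev, "p2_gt"] = "alt_hom"
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


def snp_index(ref_depth, alt_depth, min_depth: int = 7):
    """SNP-index of a pool: alternate reads over total reads, in [0, 1].

    A pool whose reads all match the P1 reference scores 0; a pool fully
    divergent from P1 scores 1.  Sites with total depth below ``min_depth``
    are missing (NaN).  Accepts scalars or arrays.
    """
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read depths must be non-negative")
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total >= max(min_depth, 1), alt / np.where(total > 0, total, 1), np.nan)
    if np.isscalar(ref_depth) and np.isscalar(alt_depth):
        return float(idx) if not np.isnan(idx) else float("nan")
    return idx


def delta_snp_index(e_index, l_index):
    """Δ(SNP-index) = SNP-index(L-pool) − SNP-index(E-pool); NaN propagates."""
    return np.asarray(l_index, dtype=float) * 1.0 - np.asarray(e_index, dtype=float)


def compute_indices(
    sites: pd.DataFrame, min_depth: int = 7, orientation: str = "l_minus_e"
) -> pd.DataFrame:
    """Attach per-pool SNP-index and Δ(SNP-index) columns to a site table.

    ``orientation`` selects the sign convention of Δ: the default
    ``"l_minus_e"`` subtracts the E-pool index from the L-pool index, so a
    positive Δ means the late pool is enriched for the P2 allele;
    ``"e_minus_l"`` flips the sign.
    """
    if orientation not in ("l_minus_e", "e_minus_l"):
        raise ValueError(f"unknown orientation {orientation!r}")
    out = sites.copy()
    out["e_index"] = snp_index(out["e_ref"], out["e_alt"], min_depth)
    out["l_index"] = snp_index(out["l_ref"], out["l_alt"], min_depth)
    delta = delta_snp_index(out["e_index"], out["l_index"])
    if orientation == "e_minus_l":
        delta = -delta
    out["delta"] = delta
    return out


def _check_sorted(sites: pd.DataFrame) -> None:
    grouped = sites.groupby("chrom", sort=False)["pos"]
    if not all(g.is_monotonic_increasing for _, g in grouped):
        raise ValueError("site table must be sorted by (chrom, pos)")


def _window_starts(chrom_length: int, window_bp: int, step_bp: int) -> np.ndarray:
    """1-based start grid of windows fully inside [1, chrom_length]."""
    if chrom_length <= window_bp:
        return np.array([1], dtype=np.int64)
    n = (chrom_length - window_bp) // step_bp + 1
    return 1 + step_bp * np.arange(n, dtype=np.int64)


def _window_means(
    delta: np.ndarray, lo: np.ndarray, hi: np.ndarray, n: np.ndarray, min_sites: int
) -> np.ndarray:
    """Exact per-window means by direct summation over member sites."""
    mean = np.full(lo.size, np.nan)
    for i in range(lo.size):
        if n[i] >= max(min_sites, 1):
            mean[i] = delta[lo[i]:hi[i]].sum() / n[i]
    return mean


def window_scan(
    sites: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000,
    min_sites: int = 3,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Sliding-window mean of Δ(SNP-index) along each chromosome.

    Windows are ``[start, start + window_bp)`` half-open, stepping by
    ``step_bp``, restricted to windows fully inside the chromosome
    (``chrom_lengths`` defaults to the last site position per chromosome).
    Windows holding fewer than ``min_sites`` sites with a non-missing Δ are
    reported with ``mean_delta = NaN`` — missing, not zero.

    Returns columns ``chrom, start, end, n_sites, mean_delta`` with ``end``
    exclusive.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    _check_sorted(sites)
    frames = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        usable = grp[np.isfinite(grp["delta"])]
        pos = usable["pos"].to_numpy(dtype=np.int64)
        delta = usable["delta"].to_numpy(dtype=float)
        length = int(chrom_lengths[chrom]) if chrom_lengths else int(grp["pos"].max())
        starts = _window_starts(length, window_bp, step_bp)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        n = hi - lo
        mean = _window_means(delta, lo, hi, n, min_sites)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp,
                    "n_sites": n,
                    "mean_delta": mean,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def null_band(
    e_depth,
    l_depth,
    bulk_size: int,
    reps: int = 1000,
    level: float = 95.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site two-sided null quantiles of Δ(SNP-index).

    For each observed depth pair, ``reps`` replicates of Δ are simulated
    under the no-QTL null — each pool's allele frequency is the mean of
    ``bulk_size`` independent F2 doses, alternate reads are
    Binomial(depth, frequency) — and the two-sided ``level``% quantiles are
    taken.  Sites where either pool has zero depth get the vacuous band
    (−1, 1).  Reproducible from ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not 0 < level < 100:
        raise ValueError("level must lie strictly between 0 and 100")
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    e = np.atleast_1d(np.asarray(e_depth, dtype=np.int64))
    l = np.atleast_1d(np.asarray(l_depth, dtype=np.int64))
    rng = np.random.default_rng(seed)
    m2 = 2 * bulk_size
    n = e.size
    fe = rng.binomial(m2, 0.5, size=(n, reps)) / m2
    fl = rng.binomial(m2, 0.5, size=(n, reps)) / m2
    ae = rng.binomial(e[:, None], fe)
    al = rng.binomial(l[:, None], fl)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = al / np.where(l[:, None] > 0, l[:, None], 1) - ae / np.where(
            e[:, None] > 0, e[:, None], 1
        )
    a = (100.0 - level) / 200.0
    lo = np.quantile(d, a, axis=1)
    hi = np.quantile(d, 1.0 - a, axis=1)
    bad = (e == 0) | (l == 0)
    lo[bad], hi[bad] = -1.0, 1.0
    # the null is symmetric about 0; never let sampling noise exclude it
    return np.minimum(lo, 0.0), np.maximum(hi, 0.0)


def window_profile(
    sites: pd.DataFrame,
    bulk_size: int,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000,
    min_sites: int = 3,
    reps: int = 1000,
    level: float = 95.0,
    seed: Optional[int] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Window means of Δ together with a window-level simulation null band.

    The band is the two-sided ``level``% quantile of the *window-averaged*
    Δ under the no-QTL null.  Within a window the member sites of a bulk are
    tightly linked, so each null replicate draws one bulk allele frequency
    per pool (shared by all sites of the chromosome in that replicate,
    i.e. complete linkage at the window scale) and independent
    Binomial(depth, frequency) read counts per site; replicate window means
    are then aggregated exactly like the observed ones.  This keeps the
    stated coverage for the windowed statistic, which per-site bands
    averaged over a window would overstate.

    Windows with fewer than ``min_sites`` usable sites are missing (NaN
    mean and band).  Bands always contain 0.

    Returns columns ``chrom, start, end, n_sites, mean_delta, band_lo,
    band_hi``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not 0 < level < 100:
        raise ValueError("level must lie strictly between 0 and 100")
    _check_sorted(sites)
    rng = np.random.default_rng(seed)
    m2 = 2 * bulk_size
    a = (100.0 - level) / 200.0
    frames = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        e_tot = (grp["e_ref"] + grp["e_alt"]).to_numpy(dtype=np.int64)
        l_tot = (grp["l_ref"] + grp["l_alt"]).to_numpy(dtype=np.int64)
        usable = np.isfinite(grp["delta"].to_numpy(dtype=float)) & (e_tot > 0) & (l_tot > 0)
        pos = grp["pos"].to_numpy(dtype=np.int64)[usable]
        delta = grp["delta"].to_numpy(dtype=float)[usable]
        e_tot, l_tot = e_tot[usable], l_tot[usable]

        length = int(chrom_lengths[chrom]) if chrom_lengths else (
            int(grp["pos"].max()) if len(grp) else window_bp
        )
        starts = _window_starts(length, window_bp, step_bp)
        lo_i = np.searchsorted(pos, starts, side="left")
        hi_i = np.searchsorted(pos, starts + window_bp, side="left")
        n = hi_i - lo_i
        mean = _window_means(delta, lo_i, hi_i, n, min_sites)

        band_lo = np.full(starts.size, np.nan)
        band_hi = np.full(starts.size, np.nan)
        if pos.size:
            fe = rng.binomial(m2, 0.5, size=reps) / m2
            fl = rng.binomial(m2, 0.5, size=reps) / m2
            ae = rng.binomial(e_tot[:, None], fe[None, :])
            al = rng.binomial(l_tot[:, None], fl[None, :])
            d = (al / l_tot[:, None] - ae / e_tot[:, None]).astype(np.float32)
            csum2 = np.vstack([np.zeros((1, reps), dtype=np.float64),
                               np.cumsum(d, axis=0, dtype=np.float64)])
            ok = n >= min_sites
            if ok.any():
                w = (csum2[hi_i[ok]] - csum2[lo_i[ok]]) / n[ok][:, None]
                band_lo[ok] = np.minimum(np.quantile(w, a, axis=1), 0.0)
                band_hi[ok] = np.maximum(np.quantile(w, 1.0 - a, axis=1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp,
                    "n_sites": n,
                    "mean_delta": mean,
                    "band_lo": band_lo,
                    "band_hi": band_hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_qtls(profile: pd.DataFrame, min_run: int = 10) -> pd.DataFrame:
    """Call QTL intervals as runs of windows outside the null band.

    A QTL is a maximal run of at least ``min_run`` non-missing windows whose
    mean Δ lies outside [band_lo, band_hi] with a consistent sign
    (positive: late pool enriched for the P2 allele).  Runs separated only
    by fewer than ``min_run`` missing windows are merged; a window back
    inside the band always terminates a run.

    Returns one row per interval: ``chrom, start, end`` (1-based inclusive,
    first window start to last window end), ``sign, n_windows, peak_delta``.
    """
    if not {"band_lo", "band_hi"}.issubset(profile.columns):
        raise ValueError("profile must carry null-band columns")
    records = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        mean = grp["mean_delta"].to_numpy(dtype=float)
        blo = grp["band_lo"].to_numpy(dtype=float)
        bhi = grp["band_hi"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)

        cur = None  # [sign, first_idx, last_idx, n_windows, peak]
        gap = 0

        def close() -> None:
            nonlocal cur
            if cur and cur[3] >= min_run:
                records.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[cur[1]]),
                        "end": int(ends[cur[2]] - 1),
                        "sign": cur[0],
                        "n_windows": cur[3],
                        "peak_delta": cur[4],
                    }
                )
            cur = None

        for i in range(mean.size):
            if not np.isfinite(mean[i]):
                if cur is not None:
                    gap += 1
                    if gap >= min_run:
                        close()
                continue
            s = 1 if mean[i] > bhi[i] else (-1 if mean[i] < blo[i] else 0)
            if s == 0:
                close()
                gap = 0
                continue
            if cur is not None and s == cur[0]:
                cur[2] = i
                cur[3] += 1
                if abs(mean[i]) > abs(cur[4]):
                    cur[4] = float(mean[i])
            else:
                close()
                cur = [s, i, i, 1, float(mean[i])]
            gap = 0
        close()
    return pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "sign", "n_windows", "peak_delta"]
    )


def scan(
    sites: pd.DataFrame,
    bulk_size: int,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000,
    min_depth: int = 7,
    min_sites: int = 3,
    reps: int = 1000,
    level: float = 95.0,
    seed: Optional[int] = None,
    orientation: str = "l_minus_e",
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Polarize, index and window a variant table in one call.

    Returns ``(indexed_sites, profile, rejected)`` where ``profile``
    includes the simulation null band; feed it to :func:`call_qtls`.
    """
    kept, rejected = polarize_sites(sites)
    indexed = compute_indices(kept, min_depth=min_depth, orientation=orientation)
    profile = window_profile(
        indexed,
        bulk_size=bulk_size,
        window_bp=window_bp,
        step_bp=step_bp,
        min_sites=min_sites,
        reps=reps,
        level=level,
        seed=seed,
        chrom_lengths=chrom_lengths,
    )
    return indexed, profile, rejected
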