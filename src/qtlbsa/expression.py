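"""Expression utilities: RPKM, DEG thresholds, BH adjustment, 2^-ΔΔCt.

These are the small, fully specified computations the transcriptomic side
of a flowering-time study needs downstream of an external differential
expression fit: length/depth-normalized expression (RPKM),
Benjamini-Hochberg adjustment of supplied p-values, the significance filter
(FDR <= 0.001 and |log2FC| >= 1, boundaries inclusive), and relative qPCR
expression by the 2^-ΔΔCt method against a reference gene and calibrator
sample.  The differential-expression model itself is out of scope: its
p-values are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rpkm",
    "bh_adjust",
    "deg_filter",
    "QpcrSample",
    "ddct",
    "relative_expression",
]


def rpkm(count, cds_length_bp, mapped_reads):
    """Reads per kilobase of coding sequence per million mapped reads.

    ``count / (cds_length_bp / 1000) / (mapped_reads / 1e6)``; accepts
    scalars or arrays.  Zero CDS length or an empty library is an error,
    not a zero.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(cds_length_bp, dtype=float)
    mapped = np.asarray(mapped_reads, dtype=float)
    if (length <= 0).any():
        raise ValueError("cds_length_bp must be > 0")
    if (mapped <= 0).any():
        raise ValueError("mapped_reads must be > 0")
    if (count < 0).any():
        raise ValueError("read counts must be non-negative")
    out = count / (length / 1e3) / (mapped / 1e6)
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_filter(
    records: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.001
) -> pd.DataFrame:
    """Flag differentially expressed genes by fold change and FDR.

    Requires columns ``log2fc`` and either ``fdr`` or ``pvalue`` (BH
    adjustment is applied only when ``fdr`` is absent).  A gene is ``up``
    when ``log2fc >= lfc_min`` and ``fdr <= fdr_max``, ``down`` when
    ``log2fc <= -lfc_min`` and ``fdr <= fdr_max``, else
    ``not_significant``; both boundaries are inclusive.
    """
    if "log2fc" not in records.columns:
        raise ValueError("records need a 'log2fc' column")
    out = records.copy()
    if "fdr" not in out.columns:
        if "pvalue" not in out.columns:
            raise ValueError("records need an 'fdr' or 'pvalue' column")
        out["fdr"] = bh_adjust(out["pvalue"])
    sig = out["fdr"] <= fdr_max
    out["flag"] = np.select(
        [sig & (out["log2fc"] >= lfc_min), sig & (out["log2fc"] <= -lfc_min)],
        ["up", "down"],
        default="not_significant",
    )
    return out


@dataclass(frozen=True)
class QpcrSample:
    """Ct values of a target and reference gene in one qPCR sample."""

    target_ct: float
    reference_ct: float
    label: str = ""
    calibrator: bool = False

    def __post_init__(self) -> None:
        for ct in (self.target_ct, self.reference_ct):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"Ct values must be finite and positive, got {ct}")

    @property
    def dct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct(sample: QpcrSample, calibrator: QpcrSample) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    ``2 ** -((ΔCt_sample) - (ΔCt_calibrator))`` where ΔCt is target minus
    reference-gene Ct.  ``ddct(s, s) == 1`` for any sample.
    """
    if calibrator is None:
        raise ValueError("a calibrator sample is required")
    return float(2.0 ** -(sample.dct - calibrator.dct))


def relative_expression(samples: pd.DataFrame) -> pd.DataFrame:
    """2^-ΔΔCt for a table of qPCR samples.

    Requires columns ``sample, target_ct, ref_ct, calibrator`` (boolean).
    The calibrator ΔCt is the mean over all rows flagged as calibrator;
    at least one is required.
    """
    needed = {"sample", "target_ct", "ref_ct", "calibrator"}
    if not needed.issubset(samples.columns):
        raise ValueError(f"missing columns {sorted(needed - set(samples.columns))}")
    out = samples.copy()
    dct = out["target_ct"].astype(float) - out["ref_ct"].astype(float)
    cal = out["calibrator"].astype(bool)
    if not cal.any():
        raise ValueError("no calibrator sample flagged")
    out["rel_expr"] = 2.0 ** -(dct - dct[cal].mean())
    return out
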