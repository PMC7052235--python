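"""MDA-aware false-positive suppression for de novo candidates.

Whole-genome amplification of a few biopsied cells produces false
heterozygote calls whose variant allele fraction (VAF) clusters well
below the 0.5 expected of a true germline heterozygote.  Two gates
suppress them:

* the VAF gate rejects de novo SNV candidates with VAF < 0.35;
* the QD gate rejects candidates in the not-yet-catalogued (non-dbSNP)
  subfilter with quality-by-depth ≤ 12 (or missing).

Rejected candidates are preserved with a reason so the failsafe /
curation path can still surface them; nothing is silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

VAF_THRESHOLD = 0.35
QD_THRESHOLD = 12.0


@dataclass(frozen=True)
class VafPoint:
    key: tuple
    sample_id: str
    alt_reads: int
    total_reads: int
    variant_class: str = "snv"

    @property
    def vaf(self) -> float | None:
        if self.total_reads <= 0:
            return None
        return self.alt_reads / self.total_reads


def compute_vaf(call, key=(), sample_id="", variant_class="snv") -> VafPoint:
    """VAF of one genotype call: alt reads over total reads.

    The total is the sum of the allele depths (which the synthetic data
    constrains to equal DP); a zero total leaves the VAF undefined.
    Outputs report VAF to three decimals.
    """
    alt = call.allele_depths[1]
    total = call.allele_depths[0] + call.allele_depths[1]
    return VafPoint(tuple(key), sample_id, alt, total, variant_class)


@dataclass
class GateResult:
    retained: list
    rejected: list  # (candidate, reason) pairs

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.rejected)


def vaf_gate(candidates, threshold: float = VAF_THRESHOLD) -> GateResult:
    """Reject de novo candidates whose embryo VAF falls below threshold.

    Candidates must expose ``.vaf`` (None when depth is zero).  The
    boundary is inclusive: VAF exactly at the threshold is retained,
    since only fractions *below* it are removed.
    """
    retained, rejected = [], []
    for c in candidates:
        if c.vaf is None:
            rejected.append((c, "vaf_missing"))
        elif c.vaf < threshold:
            rejected.append((c, f"vaf_below_{threshold}"))
        else:
            retained.append(c)
    return GateResult(retained, rejected)


def qd_gate(candidates, threshold: float = QD_THRESHOLD) -> GateResult:
    """Reject novel-subfilter candidates with QD at or below threshold.

    The inequality is strict (QD must exceed the threshold) and a
    missing QD fails the gate — the conservative reading for de novo
    calls.
    """
    retained, rejected = [], []
    for c in candidates:
        qd = c.record.qd
        if qd is None:
            rejected.append((c, "qd_missing"))
        elif qd <= threshold:
            rejected.append((c, f"qd_le_{threshold:g}"))
        else:
            retained.append(c)
    return GateResult(retained, rejected)


def vaf_histogram(vafs, bin_width: float = 0.02):
    """Histogram VAFs on [0, 1] with fixed-width bins.

    Returns (bin_centers, counts).  Used for the per-sample VAF export
    and for locating the artifact mode.
    """
    import numpy as np

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram([v for v in vafs if v is not None], bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts


def vaf_mode(vafs, bin_width: float = 0.02) -> float:
    """Bin-centre mode of a VAF distribution."""
    centers, counts = vaf_histogram(vafs, bin_width)
    return float(centers[counts.argmax()])
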