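"""Loss-of-heterozygosity detection and dropout rescue.

MDA allele dropout erases one haplotype's evidence over multi-megabase
stretches, so the embryo appears homozygous at sites where the parental
genotypes guarantee heterozygosity.  This module detects such runs,
compares them against parental LoH (inherited homozygosity looks the
same locally but is present in a parent too), keeps an "expected but
missing" ledger of parental pathogenic variants the embryo data cannot
confirm, and attempts rescue by phasing the missing site against the
nearest informative flanking SNP on each side.  When the two flanks
disagree — e.g. a recombination fell between them — the status stays
unresolved: no imputation, no guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from embryoscreen.trio_io import TrioVariantRecord

MIN_VARIANTS = 100  # a run must contain MORE than this many informative sites
MIN_FRACTION = 0.95


@dataclass
class LoHSegment:
    chrom: str
    start: int  # position of first informative site in run (1-based)
    end: int    # position of last informative site in run
    variant_count: int       # informative sites in the run
    loh_count: int           # of which LoH-consistent
    sample_id: str = ""
    label: str = ""  # embryo_only | shared_parental (set by trio_call_loh)

    @property
    def loh_fraction(self) -> float:
        return self.loh_count / self.variant_count

    def overlap(self, other: "LoHSegment") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class MissingExpectedVariant:
    key: tuple
    expected_from: str  # paternal | maternal | either
    reason: str         # low_coverage | loh | uncalled
    rescue_status: str = "unresolved"  # carrier_inferred | noncarrier_inferred | unresolved
    flanking_snps: tuple = ()
    gene: str = ""
    grade: str = ""


# ---------------------------------------------------------------------------
# informative sites and run detection


def informative_sites(records: Iterable[TrioVariantRecord], sample_id: str,
                      father_id: str, mother_id: str):
    """Sites where the target sample is expected heterozygous.

    For an embryo the obligate-heterozygous universe is sites where the
    parents are opposite homozygotes (every transmission yields a het).
    For a parent sample, heterozygosity is "expected" wherever that
    parent's own call exists at a family-polymorphic site; runs of
    near-total homozygosity then mark genomic LoH.  Yields
    (chrom, pos, loh_consistent) with missing calls counted as
    LoH-consistent (no evidence of the second allele).
    """
    for r in records:
        call = r.calls.get(sample_id)
        if sample_id in (father_id, mother_id):
            if call is None or call.is_missing:
                continue
            yield r.chrom, r.pos, not call.is_het
        else:
            father, mother = r.calls.get(father_id), r.calls.get(mother_id)
            if father is None or mother is None:
                continue
            opposite = (father.is_hom_ref and mother.is_hom_alt) or (
                father.is_hom_alt and mother.is_hom_ref
            )
            if not opposite:
                continue
            loh = call is None or call.is_missing or not call.is_het
            yield r.chrom, r.pos, bool(loh)


def _runs_for_chrom(sites, min_variants: int, min_fraction: float):
    """Greedy maximal runs with LoH fraction >= min_fraction.

    Extends the current run while the running fraction stays above the
    threshold, then trims trailing non-LoH sites so every emitted run
    starts and ends on an LoH-consistent site.
    """
    segments = []
    run: list = []
    n_loh = 0

    def flush():
        nonlocal run, n_loh
        while run and not run[-1][1]:
            run.pop()
            # recompute: popped entries are non-LoH so n_loh unchanged
        if run:
            count = len(run)
            loh = sum(1 for _, c in run if c)
            if count > min_variants and loh / count >= min_fraction:
                segments.append((run[0][0], run[-1][0], count, loh))
        run, n_loh = [], 0

    for pos, consistent in sites:
        if consistent:
            run.append((pos, True))
            n_loh += 1
        else:
            if run and (n_loh + 0) / (len(run) + 1) >= min_fraction:
                run.append((pos, False))
            else:
                flush()
    flush()
    return segments


def detect_loh_segments(records, sample_id: str, father_id: str, mother_id: str,
                        min_variants: int = MIN_VARIANTS,
                        min_fraction: float = MIN_FRACTION) -> list:
    """Maximal LoH runs for one sample.

    Runs are emitted when they contain more than ``min_variants``
    informative sites with an LoH-consistent fraction of at least
    ``min_fraction``.
    """
    by_chrom: dict = {}
    for chrom, pos, consistent in informative_sites(records, sample_id, father_id, mother_id):
        by_chrom.setdefault(chrom, []).append((pos, consistent))
    segments = []
    for chrom in sorted(by_chrom):
        sites = sorted(by_chrom[chrom])
        for start, end, count, loh in _runs_for_chrom(sites, min_variants, min_fraction):
            segments.append(LoHSegment(chrom, start, end, count, loh, sample_id))
    return segments


def trio_call_loh(embryo_segments: Sequence[LoHSegment],
                  father_segments: Sequence[LoHSegment],
                  mother_segments: Sequence[LoHSegment],
                  min_reciprocal: float = 0.5) -> list:
    """Label embryo LoH segments against the parental LoH landscape.

    A segment reciprocally overlapping a parental segment by at least
    ``min_reciprocal`` is ``shared_parental`` (likely inherited
    homozygosity); anything else is ``embryo_only`` (likely MDA
    dropout).
    """
    parental = list(father_segments) + list(mother_segments)
    for seg in embryo_segments:
        seg.label = "embryo_only"
        for p in parental:
            ov = seg.overlap(p)
            if ov <= 0:
                continue
            if (ov / (seg.end - seg.start + 1) >= min_reciprocal
                    and ov / (p.end - p.start + 1) >= min_reciprocal):
                seg.label = "shared_parental"
                break
    return list(embryo_segments)


# ---------------------------------------------------------------------------
# expected-but-missing ledger


def ledger_expected_missing(parental_pathogenic, records_by_key: dict, embryo_id: str,
                            embryo_loh_segments: Sequence[LoHSegment],
                            depth_min: int = 10) -> list:
    """Account for parental pathogenic variants the embryo data misses.

    ``parental_pathogenic`` is an iterable of objects exposing ``key``,
    ``expected_from`` (paternal/maternal/either), ``gene`` and
    ``grade``.  A variant becomes a ledger entry when its embryo call
    is absent, missing, or below ``depth_min`` reads — or when the
    call lacks the expected allele while sitting inside an embryo-only
    LoH segment, where apparent homozygosity cannot be distinguished
    from allele dropout.  The reason is ``loh`` inside such a segment,
    ``low_coverage`` for an under-covered call, else ``uncalled``.
    """
    dropout_segs = [s for s in embryo_loh_segments if s.label != "shared_parental"]

    def in_dropout(chrom, pos):
        return any(s.chrom == chrom and s.start <= pos <= s.end for s in dropout_segs)

    entries = []
    for pv in parental_pathogenic:
        key = pv.key
        rec = records_by_key.get(key)
        call = rec.calls.get(embryo_id) if rec is not None else None
        chrom, pos = key[0], key[1]
        in_loh = in_dropout(chrom, pos)
        if call is not None and not call.is_missing and call.total_depth >= depth_min:
            if call.has_alt or not in_loh:
                continue  # adequate call; the inheritance engine handles it
        if in_loh:
            reason = "loh"
        elif call is not None and not call.is_missing and call.total_depth < depth_min:
            reason = "low_coverage"
        else:
            reason = "uncalled"
        entries.append(MissingExpectedVariant(
            key=key,
            expected_from=getattr(pv, "expected_from", "either"),
            reason=reason,
            gene=getattr(pv, "gene", ""),
            grade=getattr(pv, "grade", ""),
        ))
    return entries


# ---------------------------------------------------------------------------
# flanking-SNP phase rescue


def _informative_flank(record: TrioVariantRecord, carrier_id: str, other_id: str,
                       embryo_id: str, depth_min: int):
    """Which carrier-parent haplotype did the embryo inherit here?

    Usable flanks: carrier parent phased heterozygous, other parent
    homozygous, embryo adequately covered; the embryo's allele from the
    carrier parent is then its genotype minus the other parent's
    obligate contribution.  Returns the transmitted haplotype index (0
    or 1) or None.
    """
    carrier = record.calls.get(carrier_id)
    other = record.calls.get(other_id)
    embryo = record.calls.get(embryo_id)
    if carrier is None or other is None or embryo is None:
        return None
    if not (carrier.phased and carrier.is_het):
        return None
    if not (other.is_hom_ref or other.is_hom_alt):
        return None
    if embryo.is_missing or embryo.total_depth < depth_min or None in embryo.alleles:
        return None
    other_allele = 1 if other.is_hom_alt else 0
    transmitted = sum(embryo.alleles) - other_allele
    if transmitted not in (0, 1):
        return None  # inconsistent trio genotype at this flank
    for hap, allele in enumerate(carrier.alleles):
        if allele == transmitted and carrier.alleles[1 - hap] != transmitted:
            return hap
    return None


def phase_rescue(entry: MissingExpectedVariant, records, carrier_id: str, other_id: str,
                 embryo_id: str, variant_haplotype: int | None = None,
                 window: int = 1_000_000, depth_min: int = 10,
                 exclude_segments: Sequence[LoHSegment] = (),
                 segment_buffer: int = 50_000) -> MissingExpectedVariant:
    """Infer carrier status of a missing variant from flanking phase.

    ``variant_haplotype`` is the carrier parent's haplotype index
    bearing the variant; when None it is read from the carrier's phased
    genotype at the variant site (if that record exists).  The nearest
    informative flank on each side within ``window`` bp is located; if
    both flanks show the embryo inherited the variant-bearing haplotype
    the status becomes ``carrier_inferred``, if both show the other
    haplotype ``noncarrier_inferred``; a single usable flank or a
    disagreement leaves it ``unresolved``.

    Flanks inside ``exclude_segments`` (typically the embryo-only LoH
    segments containing the missing region itself) are skipped — their
    embryo genotypes carry the same dropout that made the variant
    unobservable.  Segments are padded by ``segment_buffer`` bp on each
    side because the true dropout boundary can extend past the last
    informative site that defined the segment.
    """
    chrom, pos = entry.key[0], entry.key[1]
    if variant_haplotype is None:
        for r in records:
            if r.key == entry.key:
                carrier = r.calls.get(carrier_id)
                if carrier is not None and carrier.phased and carrier.is_het:
                    variant_haplotype = carrier.alleles.index(1)
                break
    if variant_haplotype is None:
        entry.rescue_status = "unresolved"
        return entry

    # the flank window opens from the edges of the missing region: when
    # the variant sits inside an LoH segment, usable flanks start just
    # beyond the segment, not within `window` of the variant itself
    lo_edge, hi_edge = pos, pos
    for s in exclude_segments:
        if s.chrom == chrom and s.start - segment_buffer <= pos <= s.end + segment_buffer:
            lo_edge, hi_edge = s.start - segment_buffer, s.end + segment_buffer
            break

    left = right = None
    left_key = right_key = None
    for r in records:
        if r.chrom != chrom or r.key == entry.key:
            continue
        if not (lo_edge - window <= r.pos <= hi_edge + window):
            continue
        if any(s.chrom == r.chrom
               and s.start - segment_buffer <= r.pos <= s.end + segment_buffer
               for s in exclude_segments):
            continue
        hap = _informative_flank(r, carrier_id, other_id, embryo_id, depth_min)
        if hap is None:
            continue
        if r.pos < pos and (left is None or r.pos > left_key[1]):
            left, left_key = hap, r.key
        elif r.pos > pos and (right is None or r.pos < right_key[1]):
            right, right_key = hap, r.key

    if left is None or right is None:
        entry.rescue_status = "unresolved"
    elif left == right == variant_haplotype:
        entry.rescue_status = "carrier_inferred"
    elif left == right:
        entry.rescue_status = "noncarrier_inferred"
    else:
        entry.rescue_status = "unresolved"  # flanks disagree; never guess
    entry.flanking_snps = tuple(k for k in (left_key, right_key) if k is not None)
    return entry


# ---------------------------------------------------------------------------
# output


def write_loh_bed(path, segments: Sequence[LoHSegment]) -> None:
    """LoH segments as BED (0-based half-open) with sample and fraction."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample_id}\t"
                f"{s.loh_fraction:.4f}\t{s.variant_count}\t{s.label or '.'}\n"
            )
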