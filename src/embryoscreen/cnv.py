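"""Binned read-depth CNV calling for the trio.

Per-sample depth tracks are averaged into 10 kb bins and normalized by
each sample's autosomal median depth, making ratios scale-free.  The
embryo is scored against the parents as controls: per bin, the ratio of
embryo to mean parental normalized depth and a Z-score of the embryo
bin against the parental genome-wide normalized-depth distribution.
Duplications require ratio > 2.0 with Z > 0, deletions ratio < 0.5 with
Z < 0; calls must have mean control depth > 5 and contain no
quality-control-flagged bin (high control variation, low control depth,
low Z-score, or depth within the regional interquartile range of the
controls).  With a diploid control, these ratio cuts confine discovery
to homozygous losses and >= 2-copy gains — the events binned depth can
assert confidently against MDA noise.

Parents are scored against each other as mutual controls, CNV
inheritance is assigned by reciprocal overlap, recessive-evidence CNVs
are cross-checked against recessive SNV/indel hits of the same gene,
and externally discovered SV intervals are ingested through the same
dosage and trio logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BIN_SIZE = 10_000


@dataclass
class CnvConfig:
    bin_size: int = BIN_SIZE
    dup_ratio: float = 2.0   # strict >
    del_ratio: float = 0.5   # strict <
    min_mean_depth: float = 5.0  # mean control depth over the call, strict >
    control_cv_max: float = 0.5
    control_depth_min: float = 10.0
    z_min: float = 1.5       # |z| below this => low_z_score flag
    iqr_window_bins: int = 50
    min_reciprocal: float = 0.5
    sex_chroms: tuple = ("chrX", "chrY")


@dataclass
class DepthBin:
    chrom: str
    start: int  # 0-based half-open
    end: int
    depth: dict            # sample_id -> mean raw depth
    norm: dict = field(default_factory=dict)   # sample_id -> median-normalized depth
    ratio: float | None = None
    z: float | None = None
    qc_flags: set = field(default_factory=set)


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    state: str  # duplication | deletion
    mean_ratio: float
    mean_z: float
    mean_depth: float  # mean control depth over member bins
    n_bins: int
    sample_id: str = ""
    dosage_category: str = "none"       # haploinsufficiency | triplosensitivity | none
    dosage_evidence: str = "none"       # sufficient_evidence | autosomal_recessive_gene | none
    inheritance: str = "unlabelled"     # paternal | maternal | de_novo | ambiguous
    genes: tuple = ()
    source: str = "depth_binning"
    sv_type: str = ""

    def reciprocal_overlap(self, other: "CnvCall") -> float:
        if self.chrom != other.chrom:
            return 0.0
        ov = max(0, min(self.end, other.end) - max(self.start, other.start))
        if ov == 0:
            return 0.0
        return min(ov / (self.end - self.start), ov / (other.end - other.start))


# ---------------------------------------------------------------------------
# binning


def read_bedgraph(path):
    """Read a bedGraph depth track as a list of (chrom, start, end, value)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            out.append((chrom, int(start), int(end), float(value)))
    return out


def bin_depths(tracks: Mapping[str, Iterable], bin_size: int = BIN_SIZE,
               sex_chroms: Sequence[str] = ("chrX", "chrY")) -> list:
    """Average per-interval coverage into fixed-width bins per sample.

    ``tracks`` maps sample_id to (chrom, start, end, depth) intervals
    (0-based half-open).  Interval depth is apportioned to bins by
    overlap length.  Each sample's bin depths are then normalized by
    its autosomal median so that downstream ratios are scale-free.
    Contigs absent from a sample leave that sample's depth at 0, which
    surfaces later as a low-control-depth flag.
    """
    acc: dict = {}
    for sid, intervals in tracks.items():
        for chrom, start, end, value in intervals:
            b = start // bin_size
            while b * bin_size < end:
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                key = (chrom, b)
                slot = acc.setdefault(key, {})
                cov, length = slot.get(sid, (0.0, 0))
                slot[sid] = (cov + value * (hi - lo), length + (hi - lo))
                b += 1
    samples = list(tracks)
    bins = []
    for (chrom, b) in sorted(acc, key=lambda k: (k[0], k[1])):
        slot = acc[(chrom, b)]
        depth = {}
        for sid in samples:
            cov, length = slot.get(sid, (0.0, 0))
            depth[sid] = cov / length if length else 0.0
        bins.append(DepthBin(chrom, b * bin_size, (b + 1) * bin_size, depth))
    # per-sample autosomal median normalization
    for sid in samples:
        autosomal = [bn.depth[sid] for bn in bins if bn.chrom not in sex_chroms]
        med = float(np.median(autosomal)) if autosomal else 0.0
        for bn in bins:
            bn.norm[sid] = bn.depth[sid] / med if med > 0 else 0.0
    return bins


# ---------------------------------------------------------------------------
# scoring


def score_bins(bins: Sequence[DepthBin], target: str, controls: Sequence[str],
               cfg: CnvConfig | None = None, sample_sex: Mapping[str, str] | None = None,
               known_control_cnvs: Sequence[tuple] = ()) -> list:
    """Fill per-bin ratio, Z-score and QC flags for one target sample.

    The Z reference is the pooled genome-wide distribution of the
    controls' normalized bin depths (autosomes), not the degenerate
    per-bin spread of two samples.  ``sample_sex`` maps sample ids to
    ``male``/``female``; a male sample carries one sex-chromosome copy,
    so its sex-chromosome values are doubled to the diploid-equivalent
    expectation before ratios and Z-scores are computed.

    ``known_control_cnvs`` lists (chrom, start, end) intervals where a
    control sample carries a called CNV of its own: the control-
    variation flag is suppressed there, because the parents' depth
    disagreement is genuine biology — without this, an inherited CNV
    could never survive QC in the embryo.
    """
    cfg = cfg or CnvConfig()
    sample_sex = sample_sex or {}

    def in_known_cnv(bn):
        return any(bn.chrom == c and bn.start < e and s < bn.end
                   for c, s, e in known_control_cnvs)

    def dosage(bn, sid):
        if bn.chrom in cfg.sex_chroms and sample_sex.get(sid) == "male":
            return bn.norm[sid] * 2.0
        return bn.norm[sid]

    pooled = np.array([
        bn.norm[c] for bn in bins if bn.chrom not in cfg.sex_chroms for c in controls
    ])
    mu = float(pooled.mean()) if pooled.size else 0.0
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0

    norm_by_chrom: dict = {}
    for i, bn in enumerate(bins):
        norm_by_chrom.setdefault(bn.chrom, []).append(i)

    for bn in bins:
        flags = set()
        cvals = [dosage(bn, c) for c in controls]
        cdepths = [bn.depth[c] for c in controls]
        cmean = float(np.mean(cvals))
        if float(np.mean(cdepths)) < cfg.control_depth_min:
            flags.add("low_control_depth")
        if cmean > 0 and len(cvals) > 1 and not in_known_cnv(bn):
            if float(np.std(cvals, ddof=0)) / cmean > cfg.control_cv_max:
                flags.add("high_control_variation")
        tnorm = dosage(bn, target)
        bn.ratio = (tnorm / cmean) if cmean > 0 else (0.0 if tnorm == 0 else float("inf"))
        if sd > 0:
            bn.z = (tnorm - mu) / sd
            if abs(bn.z) < cfg.z_min:
                flags.add("low_z_score")
        elif pooled.size and tnorm == mu:
            bn.z = 0.0  # zero-variance control with a matching target
            flags.add("low_z_score")
        else:
            bn.z = None
            flags.add("low_control_depth")
        bn.qc_flags = flags

    # regional IQR flag: embryo depth indistinguishable from the local
    # control noise band (window of +-iqr_window_bins on the same contig)
    w = cfg.iqr_window_bins
    for chrom, idxs in norm_by_chrom.items():
        cvals = np.array([float(np.mean([dosage(bins[i], c) for c in controls])) for i in idxs])
        for j, i in enumerate(idxs):
            lo, hi = max(0, j - w), min(len(idxs), j + w + 1)
            window = cvals[lo:hi]
            q1, q3 = np.percentile(window, [25, 75])
            bn = bins[i]
            if q1 <= dosage(bn, target) <= q3:
                bn.qc_flags.add("within_regional_iqr")
    return list(bins)


# ---------------------------------------------------------------------------
# calling


def _bin_state(bn: DepthBin, cfg: CnvConfig) -> str | None:
    if bn.ratio is None or bn.z is None:
        return None
    if bn.ratio > cfg.dup_ratio and bn.z > 0:
        return "duplication"
    if bn.ratio < cfg.del_ratio and bn.z < 0:
        return "deletion"
    return None


def call_cnvs(bins: Sequence[DepthBin], target: str, controls: Sequence[str],
              cfg: CnvConfig | None = None) -> list:
    """Merge maximal runs of consecutive qualifying, unflagged bins.

    A run breaks at any flagged or non-qualifying bin (no gap-tolerant
    merging).  Calls failing the mean control depth requirement are
    discarded.
    """
    cfg = cfg or CnvConfig()
    calls = []
    run: list = []
    run_state = None
    run_chrom = None

    def flush():
        nonlocal run, run_state, run_chrom
        if run:
            mean_ctrl_depth = float(np.mean([
                np.mean([bn.depth[c] for c in controls]) for bn in run
            ]))
            if mean_ctrl_depth > cfg.min_mean_depth:
                calls.append(CnvCall(
                    chrom=run_chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    state=run_state,
                    mean_ratio=float(np.mean([bn.ratio for bn in run])),
                    mean_z=float(np.mean([bn.z for bn in run])),
                    mean_depth=mean_ctrl_depth,
                    n_bins=len(run),
                    sample_id=target,
                ))
        run, run_state, run_chrom = [], None, None

    for bn in bins:
        state = _bin_state(bn, cfg)
        ok = state is not None and not bn.qc_flags
        if ok and state == run_state and bn.chrom == run_chrom and run and bn.start == run[-1].end:
            run.append(bn)
        else:
            flush()
            if ok:
                run, run_state, run_chrom = [bn], state, bn.chrom
    flush()
    return calls


# ---------------------------------------------------------------------------
# dosage annotation


@dataclass
class DosageGene:
    gene: str
    chrom: str
    start: int
    end: int
    haploinsufficiency: str  # sufficient_evidence | autosomal_recessive_gene | none
    triplosensitivity: str


def read_dosage_table(path) -> list:
    """ClinGen-style dosage table TSV: gene, chrom, start, end, HI, TS."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {n: i for i, n in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            try:
                genes.append(DosageGene(
                    gene=parts[col["gene"]],
                    chrom=parts[col["chrom"]],
                    start=int(parts[col["start"]]),
                    end=int(parts[col["end"]]),
                    haploinsufficiency=parts[col["haploinsufficiency"]] or "none",
                    triplosensitivity=parts[col["triplosensitivity"]] or "none",
                ))
            except (KeyError, IndexError, ValueError) as exc:
                raise ValueError(f"malformed dosage table row: {line!r}") from exc
    return genes


def assign_dosage(calls: Sequence[CnvCall], dosage_table: Sequence[DosageGene]) -> list:
    """Categorise calls against gene dosage sensitivity.

    Deletions over a sufficient-evidence haploinsufficiency gene and
    duplications over a sufficient-evidence triplosensitivity gene are
    directly reportable; autosomal-recessive evidence routes the call
    to the recessive SNV/indel cross-check instead of auto-reporting.
    """
    for call in calls:
        hit_genes = [
            g for g in dosage_table
            if g.chrom == call.chrom and g.start < call.end and call.start < g.end
        ]
        call.genes = tuple(sorted({g.gene for g in hit_genes}))
        category = evidence = "none"
        for g in hit_genes:
            if call.state == "deletion" and g.haploinsufficiency != "none":
                if g.haploinsufficiency == "sufficient_evidence":
                    category, evidence = "haploinsufficiency", "sufficient_evidence"
                    break
                category, evidence = "haploinsufficiency", g.haploinsufficiency
            elif call.state == "duplication" and g.triplosensitivity != "none":
                if g.triplosensitivity == "sufficient_evidence":
                    category, evidence = "triplosensitivity", "sufficient_evidence"
                    break
                category, evidence = "triplosensitivity", g.triplosensitivity
        call.dosage_category = category
        call.dosage_evidence = evidence
    return list(calls)


# ---------------------------------------------------------------------------
# trio comparison and recessive cross-check


def trio_cnv_inheritance(embryo_calls: Sequence[CnvCall], father_calls: Sequence[CnvCall],
                         mother_calls: Sequence[CnvCall], min_reciprocal: float = 0.5) -> list:
    """Label embryo calls by reciprocal overlap with same-state parental calls."""
    for call in embryo_calls:
        pat = any(call.reciprocal_overlap(p) >= min_reciprocal and p.state == call.state
                  for p in father_calls)
        mat = any(call.reciprocal_overlap(p) >= min_reciprocal and p.state == call.state
                  for p in mother_calls)
        if pat and mat:
            call.inheritance = "ambiguous"
        elif pat:
            call.inheritance = "paternal"
        elif mat:
            call.inheritance = "maternal"
        else:
            call.inheritance = "de_novo"
    return list(embryo_calls)


@dataclass
class CompoundCnvFinding:
    gene: str
    cnv: CnvCall
    snv: object  # CandidateVariant


def crosscheck_recessive(recessive_cnvs: Sequence[CnvCall], het_candidates,
                         ) -> list:
    """Pair recessive-evidence CNV losses with trans pathogenic hets.

    A deletion inherited from one parent combined with a qualifying
    heterozygous SNV/indel of the *other* parental origin in the same
    gene is a compound finding for curation; same-parent combinations
    are cis and not disease-causing.
    """
    opposite = {"paternal": "maternal", "maternal": "paternal"}
    findings = []
    for cnv in recessive_cnvs:
        if cnv.state != "deletion":
            continue
        want = opposite.get(cnv.inheritance)
        for cand in het_candidates:
            if cand.gene and cand.gene in cnv.genes:
                if want is None or cand.origin == want or cand.origin == "de_novo":
                    if cand.origin != cnv.inheritance:
                        findings.append(CompoundCnvFinding(cand.gene, cnv, cand))
    return findings


# ---------------------------------------------------------------------------
# external SV ingestion


SV_DOSAGE_TYPES = {"DEL": "deletion", "DUP": "duplication"}


def ingest_sv_calls(path, source: str) -> list:
    """Read externally discovered SV intervals (BED-like TSV).

    Columns: chrom, start, end, type (DEL/DUP/INV/ITX/CTX/...).  DEL
    and DUP map onto the CNV dosage logic; other types are carried as
    annotation-only records (``state`` = "other"), with
    inter-chromosomal events reportable only in the SV section.
    """
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            svtype = parts[3].upper() if len(parts) > 3 else "OTHER"
            state = SV_DOSAGE_TYPES.get(svtype, "other")
            calls.append(CnvCall(
                chrom=chrom, start=start, end=end, state=state,
                mean_ratio=float("nan"), mean_z=float("nan"),
                mean_depth=float("nan"), n_bins=0,
                source=source, sv_type=svtype,
            ))
    return calls


def write_cnv_vcf(path, calls: Sequence[CnvCall], sample_id: str = "SAMPLE") -> None:
    """CNV calls as minimal VCF SV records (SVTYPE / END in INFO)."""
    svtype = {"duplication": "DUP", "deletion": "DEL"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##ALT=<ID=DEL,Description=\"Deletion\">\n")
        fh.write("##ALT=<ID=DUP,Description=\"Duplication\">\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for c in calls:
            t = svtype.get(c.state, c.sv_type or "SV")
            fh.write(f"{c.chrom}\t{c.start + 1}\t.\tN\t<{t}>\t.\tPASS\t"
                     f"SVTYPE={t};END={c.end}\tGT\t./.\n")


def write_cnv_bed(path, calls: Sequence[CnvCall]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            z = "nan" if c.mean_z is None else f"{c.mean_z:.3f}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.state}\t{c.mean_ratio:.3f}\t"
                f"{z}\t{c.inheritance}\t"
                f"{c.dosage_category}\t{','.join(c.genes) or '.'}\n"
            )
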