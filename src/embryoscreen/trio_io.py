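"""Data model and I/O for trio variant screening.

Variants use 1-based inclusive coordinates (VCF convention); all
interval outputs elsewhere in the package (BED, bedGraph) are 0-based
half-open.  Multiallelic VCF rows are decomposed into one biallelic
record per alternate allele on read — the screen must never silently
drop an alternate allele.  Indel keys are minimalised (shared suffix
then prefix trimmed) so joins against the annotation table are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

#: The six functional-prediction algorithms consumed as annotations.
PREDICTORS = (
    "sift",
    "polyphen2_hvar",
    "mutation_taster2",
    "mutation_assessor",
    "fathmm",
    "fathmm_mkl",
)

CLINVAR_CLASSES = {
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "conflicting",
    "likely_benign",
    "benign",
    "unclassified",
}


class PedigreeError(ValueError):
    """Invalid pedigree structure or a sample missing from the VCF header."""


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation table."""


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    role: str  # father | mother | embryo
    sex: str  # male | female | unknown
    father_id: str = ""
    mother_id: str = ""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one biallelic site.

    ``alleles`` holds 0 (ref), 1 (alt) or ``None`` (missing / other
    decomposed alternate) per haplotype; length equals ploidy.
    """

    alleles: tuple
    allele_depths: tuple  # (ref reads, alt reads)
    total_depth: int
    genotype_quality: float | None
    ploidy: int = 2
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def has_alt(self) -> bool:
        return any(a == 1 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and sorted(
            (a if a is not None else -1) for a in self.alleles
        ) == [0, 1]

    @property
    def is_hom_alt(self) -> bool:
        return not self.is_missing and all(a == 1 for a in self.alleles)

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def alt_depth(self) -> int:
        return self.allele_depths[1]

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


@dataclass
class TrioVariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qd: float | None
    calls: dict  # sample_id -> GenotypeCall

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def variant_class(self) -> str:
        if self.is_snv:
            return "snv"
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.ref) - len(self.alt) > 1:
            return "deletion_gt1bp"
        return "other"


@dataclass
class AnnotationRecord:
    key: VariantKey
    in_dbsnp: bool
    rsid: str = ""
    clinvar_class: str = "unclassified"
    review_stars: int = 0
    gene: str = ""
    predictor_verdicts: dict = field(default_factory=dict)
    mpc: float | None = None
    cadd_phred: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.review_stars <= 4:
            raise AnnotationError(
                f"review stars {self.review_stars} outside 0-4 for {self.key}"
            )
        for p in PREDICTORS:
            self.predictor_verdicts.setdefault(p, "missing")

    @property
    def n_damaging(self) -> int:
        return sum(1 for v in self.predictor_verdicts.values() if v == "damaging")


@dataclass
class ConcordanceSummary:
    sites_compared: int
    genotype_matches: int
    mismatch_list: list

    @property
    def concordance(self) -> float:
        return self.genotype_matches / self.sites_compared


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path) -> list[PedigreeSample]:
    """Read a 4-column pedigree TSV: sample, role, sex, parents.

    ``parents`` is ``father_id,mother_id`` for embryos and empty for
    parents.
    """
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PedigreeError(f"bad pedigree line: {line!r}")
            sid, role, sex = parts[0], parts[1], parts[2]
            father = mother = ""
            if len(parts) > 3 and parts[3]:
                bits = parts[3].split(",")
                if len(bits) != 2:
                    raise PedigreeError(f"embryo parents must be 'father,mother': {line!r}")
                father, mother = bits
            samples.append(PedigreeSample(sid, role, sex, father, mother))
    validate_pedigree(samples)
    return samples


def validate_pedigree(samples: Sequence[PedigreeSample]) -> None:
    ids = {s.sample_id for s in samples}
    for role in ("father", "mother"):
        if sum(1 for s in samples if s.role == role) > 1:
            raise PedigreeError(f"more than one {role} in pedigree")
    for s in samples:
        if s.role == "embryo":
            if not s.father_id or not s.mother_id:
                raise PedigreeError(f"embryo {s.sample_id} lacks parent references")
            if s.father_id not in ids or s.mother_id not in ids:
                raise PedigreeError(f"embryo {s.sample_id} references samples absent from pedigree")


def pedigree_roles(samples: Sequence[PedigreeSample]):
    """Return (father_id, mother_id, [embryo PedigreeSamples])."""
    father = next((s.sample_id for s in samples if s.role == "father"), None)
    mother = next((s.sample_id for s in samples if s.role == "mother"), None)
    embryos = [s for s in samples if s.role == "embryo"]
    return father, mother, embryos


# ---------------------------------------------------------------------------
# variant normalisation


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix, then shared prefix.

    Keyed this way, the annotation join does not depend on how the
    caller padded its indels.  Full left-alignment against a reference
    sequence is out of scope; trimming alone is deterministic and
    sufficient for the VCFs this package emits and consumes.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# VCF reading


def _decompose_gt(gt_indices, alt_index: int):
    """Re-index a (possibly multiallelic) genotype against one alt.

    Allele ``alt_index`` becomes 1, reference stays 0, and any *other*
    alternate becomes ``None`` so the evidence for it is not silently
    recoded as reference.
    """
    out = []
    for a in gt_indices:
        if a is None or a < 0:
            out.append(None)
        elif a == 0:
            out.append(0)
        elif a == alt_index:
            out.append(1)
        else:
            out.append(None)
    return tuple(out)


def read_trio_vcf(vcf_path, pedigree: Sequence[PedigreeSample]) -> Iterator[TrioVariantRecord]:
    """Stream normalized biallelic records from a multi-sample VCF.

    Multiallelic rows are decomposed into one record per alternate
    allele with allele depths re-indexed; missing genotypes are kept as
    missing.  Malformed rows are skipped with a counted warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    header_samples = set(vcf.samples)
    wanted = [s.sample_id for s in pedigree]
    missing = [s for s in wanted if s not in header_samples]
    if missing:
        raise PedigreeError(f"pedigree samples missing from VCF header: {missing}")
    sample_index = {s: vcf.samples.index(s) for s in wanted}

    n_skipped = 0
    for v in vcf:
        try:
            ad = v.format("AD")
            dp = v.format("DP")
            gq = v.format("GQ")
            qd = v.INFO.get("QD")
            qd = float(qd) if qd is not None else None
            for ai, alt in enumerate(v.ALT, start=1):
                pos, ref, nalt = normalize_variant(v.POS, v.REF, alt)
                calls = {}
                for sid, si in sample_index.items():
                    raw = v.genotypes[si]
                    gt_indices = raw[:-1]
                    phased = bool(raw[-1])
                    alleles = _decompose_gt(gt_indices, ai)
                    ref_d = int(ad[si][0]) if ad is not None else 0
                    alt_d = int(ad[si][ai]) if ad is not None and ad.shape[1] > ai else 0
                    ref_d = max(ref_d, 0)
                    alt_d = max(alt_d, 0)
                    depth = int(dp[si][0]) if dp is not None else ref_d + alt_d
                    q = float(gq[si][0]) if gq is not None else None
                    if q is not None and q < 0:
                        q = None
                    calls[sid] = GenotypeCall(
                        alleles=alleles,
                        allele_depths=(ref_d, alt_d),
                        total_depth=max(depth, 0),
                        genotype_quality=q,
                        ploidy=len(alleles),
                        phased=phased,
                    )
                yield TrioVariantRecord(v.CHROM, pos, ref, nalt, qd, calls)
        except (ValueError, IndexError, TypeError) as exc:  # malformed row
            n_skipped += 1
            log.warning("skipping malformed VCF row at %s:%s (%s)", v.CHROM, v.POS, exc)
    if n_skipped:
        log.warning("skipped %d malformed VCF rows", n_skipped)


# ---------------------------------------------------------------------------
# VCF writing


def write_trio_vcf(path, records: Iterable[TrioVariantRecord], sample_order: Sequence[str],
                   contigs: Mapping[str, int] | None = None) -> None:
    """Write biallelic records as VCF 4.2 with GT:AD:DP:GQ and INFO QD.

    Output is deterministic for a given record stream, so identical
    simulations round-trip byte-identically.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_order))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for r in records:
            info = f"QD={r.qd:.2f}" if r.qd is not None else "."
            fields = [r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", info, "GT:AD:DP:GQ"]
            for sid in sample_order:
                c = r.calls[sid]
                gq = "." if c.genotype_quality is None else str(int(round(c.genotype_quality)))
                fields.append(
                    f"{c.gt_string()}:{c.allele_depths[0]},{c.allele_depths[1]}:{c.total_depth}:{gq}"
                )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# annotation table


_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False, "": False}


def read_annotations(tsv_path) -> dict:
    """Read the per-variant annotation TSV into a dict keyed by variant.

    Required columns: chrom, pos, ref, alt, in_dbsnp, clinvar_class,
    review_stars.  Predictor / score columns are optional and treated
    as missing when absent or empty.  Duplicate variant keys are fatal.
    """
    table: dict = {}
    duplicates = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for req in ("chrom", "pos", "ref", "alt", "in_dbsnp", "clinvar_class", "review_stars"):
            if req not in col:
                raise AnnotationError(f"annotation table missing column {req!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(col):
                parts += [""] * (len(col) - len(parts))

            def get(name, default=""):
                return parts[col[name]] if name in col else default

            pos, ref, alt = normalize_variant(int(get("pos")), get("ref"), get("alt"))
            key = (get("chrom"), pos, ref, alt)
            if key in table:
                duplicates.append(key)
                continue
            cls = get("clinvar_class").strip().lower() or "unclassified"
            if cls not in CLINVAR_CLASSES:
                log.warning("unknown ClinVar class %r at %s; treating as unclassified", cls, key)
                cls = "unclassified"
            verdicts = {}
            for p in PREDICTORS:
                raw = get(p).strip().lower()
                verdicts[p] = raw if raw in ("damaging", "tolerated") else "missing"
            mpc = get("mpc").strip()
            cadd = get("cadd_phred").strip()
            table[key] = AnnotationRecord(
                key=key,
                in_dbsnp=_BOOL.get(get("in_dbsnp").strip().lower(), False),
                rsid=get("rsid").strip(),
                clinvar_class=cls,
                review_stars=int(get("review_stars") or 0),
                gene=get("gene").strip(),
                predictor_verdicts=verdicts,
                mpc=float(mpc) if mpc else None,
                cadd_phred=float(cadd) if cadd else None,
            )
    if duplicates:
        raise AnnotationError(f"duplicate variant keys in annotation table: {duplicates}")
    return table


# ---------------------------------------------------------------------------
# call-set concordance


def compare_callsets(set_a: Mapping, set_b: Mapping, site_subset: Iterable | None = None) -> ConcordanceSummary:
    """Genotype concordance between two call sets over shared keys.

    ``set_a`` / ``set_b`` map variant keys to hashable genotypes (e.g.
    sorted allele tuples).  When ``site_subset`` is None the comparison
    runs over keys heterozygous in ``set_a`` — the orthogonal-platform
    validation design, where array heterozygote calls are checked
    against sequencing.
    """
    shared = set(set_a) & set(set_b)
    if site_subset is None:
        keys = [k for k in shared if _is_het_genotype(set_a[k])]
    else:
        keys = [k for k in site_subset if k in shared]
    if not keys:
        raise ValueError("no shared sites to compare")
    mismatches = [k for k in keys if set_a[k] != set_b[k]]
    return ConcordanceSummary(
        sites_compared=len(keys),
        genotype_matches=len(keys) - len(mismatches),
        mismatch_list=sorted(mismatches),
    )


def _is_het_genotype(gt) -> bool:
    try:
        return len(set(gt)) > 1
    except TypeError:
        return False
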