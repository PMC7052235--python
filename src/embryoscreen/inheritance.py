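"""Inheritance-mode filter workflows.

Six parallel filter sets screen each embryo against its parents'
genomes: dominant heterozygous, recessive homozygous, compound
heterozygous, X-linked, de novo, and a low-specificity high-sensitivity
failsafe.  Every strict filter requires embryo depth >10x (implemented
as >= 10 reads) and a genotype-quality floor; the failsafe drops the
genotype-quality requirement and only asks for read depth > 1 so that
clinically actionable hits survive for manual curation even when the
strict filters reject them.  Each retained or rejected record carries
an ordered filter trail, so nothing vanishes silently.

Within each mode, candidates are split into a dbSNP-catalogued and a
not-yet-catalogued ("novel") subfilter; the novel de novo subfilter is
additionally gated on quality-by-depth downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from embryoscreen.denovo import compute_vaf
from embryoscreen.pathogenicity import PathogenicityGrade, grade_variant
from embryoscreen.trio_io import AnnotationRecord, TrioVariantRecord

MODES = ("dominant_het", "recessive_hom", "compound_het", "x_linked", "de_novo", "failsafe")


@dataclass
class FilterConfig:
    depth_min: int = 10          # strict filters: ">10x" read as >= 10 reads
    gq_min: float = 20.0         # genotype-quality floor for strict filters
    failsafe_depth_min: int = 2  # "read depth > 1" read as >= 2 reads
    parent_confident_depth: int = 20  # parent hom-ref at this depth => Mendelian violation
    x_chrom: str = "chrX"
    par_regions: tuple = ()      # ((chrom, start0, end0), ...) treated as autosomal
    x_infer_min_sites: int = 200
    x_infer_het_max: float = 0.1


@dataclass
class CandidateVariant:
    record: TrioVariantRecord
    embryo_id: str
    mode: str
    subfilter: str  # dbsnp | novel
    grade: PathogenicityGrade
    origin: str  # paternal | maternal | de_novo | ambiguous
    gene: str
    trail: list = field(default_factory=list)  # ordered (filter name, passed) pairs
    vaf: float | None = None

    @property
    def key(self):
        return self.record.key

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.trail)


@dataclass
class CompoundHetPair:
    gene: str
    hit_a: CandidateVariant
    hit_b: CandidateVariant


# ---------------------------------------------------------------------------
# transmission classification


def classify_transmission(record: TrioVariantRecord, embryo_id: str,
                          father_id: str, mother_id: str) -> str:
    """Label the embryo's alt allele by parental origin.

    Returns ``paternal``, ``maternal``, ``ambiguous`` (both parents
    carry the allele, or a parent genotype is missing), ``de_novo``
    (neither called parent carries it), ``none`` (embryo carries no alt)
    or ``unclassifiable`` (embryo genotype missing).
    """
    embryo = record.calls.get(embryo_id)
    if embryo is None or embryo.is_missing:
        return "unclassifiable"
    if not embryo.has_alt:
        return "none"
    father = record.calls.get(father_id)
    mother = record.calls.get(mother_id)
    f_missing = father is None or father.is_missing
    m_missing = mother is None or mother.is_missing
    if f_missing or m_missing:
        return "ambiguous"
    f_has, m_has = father.has_alt, mother.has_alt
    if f_has and m_has:
        return "ambiguous"
    if f_has:
        return "paternal"
    if m_has:
        return "maternal"
    return "de_novo"


# ---------------------------------------------------------------------------
# shared helpers


def _on_x(record: TrioVariantRecord, cfg: FilterConfig) -> bool:
    if record.chrom != cfg.x_chrom:
        return False
    for chrom, start, end in cfg.par_regions:
        if chrom == record.chrom and start < record.pos <= end:
            return False  # pseudoautosomal: hemizygosity logic invalid
    return True


def _subfilter(ann: AnnotationRecord | None) -> str:
    return "dbsnp" if ann is not None and ann.in_dbsnp else "novel"


def _gene(ann: AnnotationRecord | None) -> str:
    return ann.gene if ann is not None else ""


def _make_candidate(record, embryo_id, mode, ann, origin, trail) -> CandidateVariant:
    call = record.calls[embryo_id]
    vp = compute_vaf(call, record.key, embryo_id, record.variant_class)
    return CandidateVariant(
        record=record,
        embryo_id=embryo_id,
        mode=mode,
        subfilter=_subfilter(ann),
        grade=grade_variant(ann),
        origin=origin,
        gene=_gene(ann),
        trail=trail,
        vaf=vp.vaf,
    )


def _strict_checks(record, embryo_id, cfg: FilterConfig) -> list:
    call = record.calls[embryo_id]
    return [
        ("depth", call.total_depth >= cfg.depth_min),
        ("genotype_quality",
         call.genotype_quality is not None and call.genotype_quality >= cfg.gq_min),
    ]


# ---------------------------------------------------------------------------
# mode filters


def filter_dominant(records: Iterable[TrioVariantRecord], annotations: dict,
                    embryo_id: str, father_id: str, mother_id: str,
                    cfg: FilterConfig | None = None):
    """Dominant heterozygous workflow (autosomes and PAR).

    Retains transmitted alt-bearing embryo calls with a qualifying
    pathogenicity grade.  Returns (candidates, rejected).
    """
    cfg = cfg or FilterConfig()
    candidates, rejected = [], []
    for r in records:
        if _on_x(r, cfg):
            continue
        embryo = r.calls.get(embryo_id)
        if embryo is None or embryo.is_missing or not embryo.has_alt:
            continue
        ann = annotations.get(r.key)
        origin = classify_transmission(r, embryo_id, father_id, mother_id)
        trail = _strict_checks(r, embryo_id, cfg)
        trail.append(("transmitted_origin", origin in ("paternal", "maternal", "ambiguous")))
        trail.append(("pathogenic_grade", grade_variant(ann).qualifies))
        cand = _make_candidate(r, embryo_id, "dominant_het", ann, origin, trail)
        (candidates if cand.passed else rejected).append(cand)
    return candidates, rejected


@dataclass
class RecessiveResult:
    affected: list
    carriers: list
    dropout_suspects: list
    rejected: list


def filter_recessive(records, annotations, embryo_id, father_id, mother_id,
                     cfg: FilterConfig | None = None) -> RecessiveResult:
    """Recessive homozygous workflow.

    Embryo homozygous-alt calls with one alt from each parent become
    affected candidates; qualifying heterozygous calls are reported
    separately as carrier findings.  A homozygous-alt embryo where a
    parent is confidently homozygous-reference is a Mendelian
    impossibility and is flagged as an allele-dropout suspect rather
    than called.
    """
    cfg = cfg or FilterConfig()
    res = RecessiveResult([], [], [], [])
    for r in records:
        if _on_x(r, cfg):
            continue
        embryo = r.calls.get(embryo_id)
        if embryo is None or embryo.is_missing or not embryo.has_alt:
            continue
        ann = annotations.get(r.key)
        grade = grade_variant(ann)
        origin = classify_transmission(r, embryo_id, father_id, mother_id)
        trail = _strict_checks(r, embryo_id, cfg)
        if embryo.is_hom_alt:
            father, mother = r.calls.get(father_id), r.calls.get(mother_id)
            violation = any(
                p is not None and p.is_hom_ref and p.total_depth >= cfg.parent_confident_depth
                for p in (father, mother)
            )
            if violation:
                cand = _make_candidate(r, embryo_id, "recessive_hom", ann, origin, trail)
                res.dropout_suspects.append(cand)
                continue
            biparental = all(
                p is None or p.is_missing or p.has_alt for p in (father, mother)
            )
            trail.append(("alt_from_each_parent", biparental))
            trail.append(("pathogenic_grade", grade.qualifies))
            cand = _make_candidate(r, embryo_id, "recessive_hom", ann, origin, trail)
            (res.affected if cand.passed else res.rejected).append(cand)
        elif embryo.is_het:
            trail.append(("transmitted_origin", origin in ("paternal", "maternal", "ambiguous")))
            trail.append(("pathogenic_grade", grade.qualifies))
            cand = _make_candidate(r, embryo_id, "recessive_hom", ann, origin, trail)
            (res.carriers if cand.passed else res.rejected).append(cand)
    return res


def filter_compound_het(het_hits: Sequence[CandidateVariant]):
    """Pair heterozygous hits of the same gene on opposite haplotypes.

    ``het_hits`` are retained heterozygous qualifying candidates
    (transmitted carriers plus gate-surviving de novo hets).  Pairs
    whose origins are a paternal/maternal combination — or one
    inherited hit with one retained de novo — are called; pairs
    involving an ambiguous-origin hit go to a curation list because
    parental-origin phasing cannot place them on opposite haplotypes.

    Returns (pairs, curation_pairs).
    """
    by_gene: dict = {}
    for h in het_hits:
        if h.gene and h.record.calls[h.embryo_id].is_het:
            by_gene.setdefault(h.gene, []).append(h)
    pairs, curation = [], []
    for gene, hits in sorted(by_gene.items()):
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                if a.key == b.key:
                    continue
                origins = {a.origin, b.origin}
                if origins == {"paternal", "maternal"} or (
                    "de_novo" in origins and origins & {"paternal", "maternal"}
                ):
                    pairs.append(CompoundHetPair(gene, a, b))
                elif "ambiguous" in origins and len({a.origin, b.origin, "ambiguous"}) > 1:
                    curation.append(CompoundHetPair(gene, a, b))
    return pairs, curation


@dataclass
class XLinkedResult:
    affected: list
    carriers: list
    curation: list
    rejected: list


def infer_embryo_sex(records, embryo_id: str, cfg: FilterConfig | None = None) -> str:
    """Infer embryo sex from X heterozygosity.

    A male embryo is hemizygous on X, so its fraction of heterozygous
    calls among called X sites collapses toward zero.  Requires at
    least ``x_infer_min_sites`` informative sites; otherwise returns
    ``unknown``.
    """
    cfg = cfg or FilterConfig()
    n_called = n_het = 0
    for r in records:
        if not _on_x(r, cfg):
            continue
        call = r.calls.get(embryo_id)
        if call is None or call.is_missing:
            continue
        n_called += 1
        if call.is_het:
            n_het += 1
    if n_called < cfg.x_infer_min_sites:
        return "unknown"
    return "male" if n_het / n_called < cfg.x_infer_het_max else "female"


def filter_xlinked(records, annotations, embryo_id, father_id, mother_id,
                   embryo_sex: str, cfg: FilterConfig | None = None) -> XLinkedResult:
    """X-linked workflow over chrX records outside the PAR.

    Male embryos: any hemizygous qualifying alt is an affected call.
    Female embryos: homozygous alt is affected, heterozygous a carrier
    finding.  When the sex is unknown, hits are routed to curation.
    """
    cfg = cfg or FilterConfig()
    res = XLinkedResult([], [], [], [])
    for r in records:
        if not _on_x(r, cfg):
            continue
        embryo = r.calls.get(embryo_id)
        if embryo is None or embryo.is_missing or not embryo.has_alt:
            continue
        ann = annotations.get(r.key)
        origin = classify_transmission(r, embryo_id, father_id, mother_id)
        trail = _strict_checks(r, embryo_id, cfg)
        trail.append(("pathogenic_grade", grade_variant(ann).qualifies))
        cand = _make_candidate(r, embryo_id, "x_linked", ann, origin, trail)
        if not cand.passed:
            res.rejected.append(cand)
        elif embryo_sex == "male":
            res.affected.append(cand)
        elif embryo_sex == "female":
            (res.affected if embryo.is_hom_alt else res.carriers).append(cand)
        else:
            res.curation.append(cand)
    return res


def filter_denovo(records, annotations, embryo_id, father_id, mother_id,
                  cfg: FilterConfig | None = None):
    """De novo workflow: alt present in embryo, absent from both parents.

    Unlike the transmitted-mode filters, retention here does not demand
    a qualifying pathogenicity grade — de novo candidates are curated
    as a class and the grade is carried on the candidate for the
    report.  Candidates still face the MDA artifact gates
    (:func:`embryoscreen.denovo.vaf_gate` and, for the novel subfilter,
    :func:`embryoscreen.denovo.qd_gate`).  Returns (candidates,
    rejected).
    """
    cfg = cfg or FilterConfig()
    candidates, rejected = [], []
    for r in records:
        embryo = r.calls.get(embryo_id)
        if embryo is None or embryo.is_missing or not embryo.has_alt:
            continue
        origin = classify_transmission(r, embryo_id, father_id, mother_id)
        if origin != "de_novo":
            continue
        ann = annotations.get(r.key)
        trail = _strict_checks(r, embryo_id, cfg)
        cand = _make_candidate(r, embryo_id, "de_novo", ann, "de_novo", trail)
        (candidates if cand.passed else rejected).append(cand)
    return candidates, rejected


def filter_failsafe(records, annotations, embryo_id, actionable_genes,
                    cfg: FilterConfig | None = None):
    """Low-specificity, high-sensitivity failsafe capture.

    Any embryo alt-bearing call in a clinically actionable gene with
    read depth > 1 is retained — no genotype-quality requirement, no
    VAF gate, no grade requirement.  The output is intentionally rich
    in false positives and exists for manual curation.
    """
    cfg = cfg or FilterConfig()
    genes = {g.strip() for g in actionable_genes if g.strip()}
    out = []
    for r in records:
        embryo = r.calls.get(embryo_id)
        if embryo is None or embryo.is_missing or not embryo.has_alt:
            continue
        ann = annotations.get(r.key)
        if _gene(ann) not in genes:
            continue
        if embryo.total_depth < cfg.failsafe_depth_min:
            continue
        origin = classify_transmission(r, embryo_id, *_parent_ids_for(r, embryo_id))
        trail = [("actionable_gene", True), ("depth_gt1", True)]
        out.append(_make_candidate(r, embryo_id, "failsafe", ann, origin, trail))
    return out


def _parent_ids_for(record, embryo_id):
    # failsafe does not depend on origin; classify against whatever
    # other samples are present so the report can still show it
    others = [s for s in record.calls if s != embryo_id]
    father = others[0] if others else ""
    mother = others[1] if len(others) > 1 else ""
    return father, mother
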