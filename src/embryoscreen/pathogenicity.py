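"""Pathogenicity grading.

A variant is graded from ClinVar first; only variants ClinVar leaves
uncertain, conflicting or unclassified fall through to the stacked
prediction filter: at least two of the six functional predictors must
call the variant damaging, the MPC score must exceed 2 and the
Phred-scaled CADD score must exceed 35 (all three conjunctively).
Missing predictor verdicts count as not-damaging and a missing MPC or
CADD score fails its stage, so an indel with no predictor coverage can
only qualify through ClinVar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from embryoscreen.trio_io import AnnotationRecord

log = logging.getLogger(__name__)

#: Grades that qualify a candidate for the strict inheritance filters.
QUALIFYING_GRADES = frozenset({"pathogenic", "likely_pathogenic", "predicted_pathogenic"})

MIN_DAMAGING = 2  # "more than one" predictor
MPC_MIN = 2.0  # strict >
CADD_MIN = 35.0  # strict >


@dataclass(frozen=True)
class PathogenicityGrade:
    grade: str  # pathogenic | likely_pathogenic | predicted_pathogenic | vus | benign_like | unknown
    basis: str  # clinvar | prediction | none
    stars: int | None = None

    @property
    def qualifies(self) -> bool:
        return self.grade in QUALIFYING_GRADES


_CLINVAR_MAP = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "benign": "benign_like",
    "likely_benign": "benign_like",
}


def grade_clinvar(annotation: AnnotationRecord) -> PathogenicityGrade:
    """Grade from the ClinVar class, carrying the review stars.

    Uncertain / conflicting / unclassified variants return ``unknown``
    and remain eligible for the prediction stack.
    """
    cls = annotation.clinvar_class
    if cls in _CLINVAR_MAP:
        return PathogenicityGrade(_CLINVAR_MAP[cls], "clinvar", annotation.review_stars)
    return PathogenicityGrade("unknown", "none")


def grade_prediction(annotation: AnnotationRecord) -> PathogenicityGrade:
    """Stacked prediction filter for ClinVar-unknown variants."""
    consensus = annotation.n_damaging >= MIN_DAMAGING
    mpc_ok = annotation.mpc is not None and annotation.mpc > MPC_MIN
    cadd_ok = annotation.cadd_phred is not None and annotation.cadd_phred > CADD_MIN
    if annotation.mpc is None or annotation.cadd_phred is None:
        log.debug("missing MPC/CADD for %s; prediction stage cannot pass", annotation.key)
    if consensus and mpc_ok and cadd_ok:
        return PathogenicityGrade("predicted_pathogenic", "prediction")
    return PathogenicityGrade("vus", "prediction")


def grade_variant(annotation: AnnotationRecord | None) -> PathogenicityGrade:
    """Full grading ladder: ClinVar preempts prediction."""
    if annotation is None:
        return PathogenicityGrade("unknown", "none")
    clin = grade_clinvar(annotation)
    if clin.grade != "unknown":
        return clin
    return grade_prediction(annotation)


def screen_incidental(candidates, parental_carriers, incidental_genes) -> dict:
    """Intersect findings with an incidental-findings gene list.

    ``candidates`` are embryo candidate variants, ``parental_carriers``
    parental pathogenic carrier variants; both must expose ``.gene``
    and ``.grade``.  Returns a report section with embryos and parents
    separated; an empty gene list yields a notice instead of a section.
    """
    genes = {g.strip() for g in incidental_genes if g.strip()}
    if not genes:
        return {"notice": "no incidental-findings gene list supplied; section omitted"}

    def qualifies(c):
        grade = getattr(c.grade, "grade", c.grade)
        return c.gene in genes and grade in QUALIFYING_GRADES

    return {
        "embryo": [c for c in candidates if qualifies(c)],
        "parental": [c for c in parental_carriers if qualifies(c)],
    }
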