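"""Small builders for hand-written trio records in tests."""

from __future__ import annotations

from embryoscreen.trio_io import AnnotationRecord, GenotypeCall, TrioVariantRecord

FATHER, MOTHER, EMBRYO = "FATHER", "MOTHER", "EMBRYO1"


def mk_call(gt: str, ad=None, dp=None, gq=99.0) -> GenotypeCall:
    """Build a GenotypeCall from a VCF-style genotype string.

    ``ad`` defaults to a clean 40x split matching the genotype.
    """
    phased = "|" in gt
    alleles = tuple(None if a == "." else int(a) for a in gt.replace("|", "/").split("/"))
    if ad is None:
        n_alt = sum(1 for a in alleles if a == 1)
        if all(a is None for a in alleles):
            ad = (0, 0)
        elif len(alleles) == 1:
            ad = (0, 40) if n_alt else (40, 0)
        else:
            ad = {0: (40, 0), 1: (20, 20), 2: (0, 40)}[n_alt]
    dp = sum(ad) if dp is None else dp
    return GenotypeCall(alleles, tuple(ad), dp, gq, ploidy=len(alleles), phased=phased)


def mk_record(father: str | GenotypeCall, mother: str | GenotypeCall,
              embryo: str | GenotypeCall, chrom="chr1", pos=1000, ref="A", alt="G",
              qd=25.0) -> TrioVariantRecord:
    def as_call(x):
        return x if isinstance(x, GenotypeCall) else mk_call(x)

    return TrioVariantRecord(chrom, pos, ref, alt, qd, {
        FATHER: as_call(father), MOTHER: as_call(mother), EMBRYO: as_call(embryo),
    })


def mk_annotation(record: TrioVariantRecord, clinvar="pathogenic", stars=2, gene="GENE1",
                  in_dbsnp=True, damaging=0, mpc=None, cadd=None) -> AnnotationRecord:
    verdicts = {}
    from embryoscreen.trio_io import PREDICTORS

    for i, p in enumerate(PREDICTORS):
        verdicts[p] = "damaging" if i < damaging else "tolerated"
    return AnnotationRecord(
        key=record.key, in_dbsnp=in_dbsnp, clinvar_class=clinvar, review_stars=stars,
        gene=gene, predictor_verdicts=verdicts, mpc=mpc, cadd_phred=cadd,
    )
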