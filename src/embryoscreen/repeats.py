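"""Tandem-repeat disease-locus assessment.

Repeat genotypes (repeat-unit counts per allele, as produced by a
read-based repeat genotyper) are classified against per-locus normal /
premutation / pathogenic ranges, and parent-embryo transmission is
scored for exact concordance: each embryo allele must match a distinct
parental allele under a consistent one-allele-per-parent assignment,
with the assignment chosen to maximise the number of concordant
alleles.

The default panel is the 17 disease loci a standard repeat genotyper
ships with.  The shipped pathogenic ranges are curated defaults from
the clinical literature and are user-overridable; they are inclusive at
``pathogenic_min``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LocusThreshold:
    locus: str
    normal_max: int
    pathogenic_min: int
    premutation: tuple | None = None  # inclusive (low, high) or None

    def __post_init__(self):
        if not self.normal_max < self.pathogenic_min:
            raise ValueError(f"{self.locus}: normal_max must be < pathogenic_min")


@dataclass(frozen=True)
class RepeatGenotype:
    locus: str
    sample_id: str
    allele_1: int
    allele_2: int | None = None  # None = hemizygous single allele

    @property
    def alleles(self) -> tuple:
        return (self.allele_1,) if self.allele_2 is None else (self.allele_1, self.allele_2)


#: Curated default thresholds for the 17-locus panel (repeat units).
#: X-linked loci: AR, FMR1.
DEFAULT_PANEL = {
    "CBL": LocusThreshold("CBL", 79, 100, (80, 99)),
    "ATN1": LocusThreshold("ATN1", 35, 48, (36, 47)),
    "ATXN2": LocusThreshold("ATXN2", 31, 33, (32, 32)),
    "ATXN3": LocusThreshold("ATXN3", 44, 52, (45, 51)),
    "JPH3": LocusThreshold("JPH3", 28, 40, (29, 39)),
    "CACNA1A": LocusThreshold("CACNA1A", 18, 20, (19, 19)),
    "DMPK": LocusThreshold("DMPK", 34, 50, (35, 49)),
    "CSTB": LocusThreshold("CSTB", 3, 30, (4, 29)),
    "ATXN10": LocusThreshold("ATXN10", 32, 800, (280, 799)),
    "ATXN7": LocusThreshold("ATXN7", 27, 37, (28, 36)),
    "HTT": LocusThreshold("HTT", 26, 40, (27, 39)),
    "PPP2R2B": LocusThreshold("PPP2R2B", 32, 51, (33, 50)),
    "ATXN1": LocusThreshold("ATXN1", 35, 39, (36, 38)),
    "C9ORF72": LocusThreshold("C9ORF72", 23, 60, (24, 59)),
    "FXN": LocusThreshold("FXN", 33, 66, (34, 65)),
    "AR": LocusThreshold("AR", 34, 38, (35, 37)),
    "FMR1": LocusThreshold("FMR1", 44, 200, (45, 199)),
}

X_LINKED_LOCI = frozenset({"AR", "FMR1"})


def flag_pathogenic_repeats(genotype: RepeatGenotype,
                            thresholds: dict | None = None) -> list:
    """Classify each allele as normal, premutation or pathogenic.

    The pathogenic bound is inclusive: an allele exactly at
    ``pathogenic_min`` is pathogenic.
    """
    thresholds = thresholds if thresholds is not None else DEFAULT_PANEL
    t = thresholds.get(genotype.locus)
    if t is None:
        raise KeyError(f"no threshold configured for locus {genotype.locus}")
    labels = []
    for a in genotype.alleles:
        if a >= t.pathogenic_min:
            labels.append("pathogenic")
        elif t.premutation is not None and t.premutation[0] <= a <= t.premutation[1]:
            labels.append("premutation")
        else:
            labels.append("normal")
    return labels


def transmission_concordance(embryo: RepeatGenotype, father: RepeatGenotype | None,
                             mother: RepeatGenotype | None, tolerance: int = 0) -> list:
    """Per-allele transmission concordance at one locus.

    A diploid embryo genotype is concordant when, under one of the two
    parent-to-allele assignments, each embryo allele equals (within
    ``tolerance``, default exact) an allele of its assigned parent; the
    assignment maximising the concordant count is reported.  A
    hemizygous embryo allele at an X-linked locus is matched against
    the maternal alleles only.  Missing parental genotypes make the
    affected alleles unassessable.
    """
    def matches(count, parent):
        return parent is not None and any(abs(count - a) <= tolerance for a in parent.alleles)

    alleles = embryo.alleles
    if len(alleles) == 1:
        if mother is None:
            return ["unassessable"]
        return ["concordant" if matches(alleles[0], mother) else "discordant"]

    if father is None or mother is None:
        # one-allele-per-parent assignment is undetermined without both parents
        return ["unassessable"] * len(alleles)

    best = None
    for assignment in ((father, mother), (mother, father)):
        labels = [
            "concordant" if matches(a, p) else "discordant"
            for a, p in zip(alleles, assignment)
        ]
        score = labels.count("concordant")
        if best is None or score > best[0]:
            best = (score, labels)
    return best[1]


def read_repeat_genotypes(path) -> list:
    """Repeat genotype TSV: locus, sample_id, allele_1, allele_2."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {n: i for i, n in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            a2 = parts[col["allele_2"]].strip()
            out.append(RepeatGenotype(
                locus=parts[col["locus"]],
                sample_id=parts[col["sample_id"]],
                allele_1=int(parts[col["allele_1"]]),
                allele_2=int(a2) if a2 not in ("", ".") else None,
            ))
    return out
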