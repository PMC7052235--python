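"""Synthetic trio generator.

Produces father / mother / embryo data with the statistical structure
the screening pipeline assumes, together with a complete ground-truth
ledger:

* parental germline variation at a configurable site density, with
  heterozygote allele depths sampled binomially around VAF 0.5 and a
  substitution spectrum targeting a transition:transversion ratio of
  2.081;
* Mendelian transmission with Poisson-distributed crossovers per
  chromosome;
* de novo SNVs planted at an expected 74 per embryo genome (the
  genome-wide human estimate; the miniature genome carries the full
  count so the de novo workflow runs at realistic numbers);
* MDA amplification artifacts: multi-megabase allele-dropout regions
  that erase one inherited haplotype's evidence, false-heterozygote
  sites whose VAF follows a scaled Beta distribution on [0.08, 0.34]
  with mode 0.26, and depth degradation calibrated so that ~87.5% of
  the embryo genome reaches 20x versus ~96.4% for parental genomic
  DNA;
* planted pathogenic variants and CNVs with declared intent, plus
  tandem-repeat genotypes for the 17-locus panel.

The genome model is a scaled miniature (four 10 Mb autosomes plus a
10 Mb X by default) so a full family simulates in seconds.  All
randomness flows through one ``numpy`` generator seeded from
``SimParams.seed``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from embryoscreen.repeats import DEFAULT_PANEL, X_LINKED_LOCI
from embryoscreen.trio_io import GenotypeCall, TrioVariantRecord, write_trio_vcf

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

WAVE_REGION_BP = 100_000
TRACK_RES_BP = 2_000


class SimConfigError(ValueError):
    """A planted spec conflicts with the simulated genotypes."""


@dataclass
class CnvSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copies: dict  # role/sample -> copy number; absent => 2

    def copy_for(self, role: str) -> int:
        return int(self.copies.get(role, 2))


@dataclass
class PathogenicVariantSpec:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    mode: str  # dominant_het | recessive_hom | compound_het | x_linked | de_novo
    clinvar_class: str = "pathogenic"
    review_stars: int = 2
    in_dbsnp: bool = True
    father_gt: tuple = (0, 0)   # haplotype alleles (hap0, hap1)
    mother_gt: tuple = (0, 0)
    embryo_target: tuple = (0, 0)  # intended true embryo genotype (sorted)
    in_dropout: bool = False    # force an MDA dropout region over the site
    predicted: bool = False     # annotate for the prediction stack instead of ClinVar


def default_planted_variants() -> list:
    """Planted conditions spanning the inheritance modes under test."""
    return [
        PathogenicVariantSpec("chr1", 1_250_000, "C", "T", "KRT10", "dominant_het",
                              father_gt=(0, 1), embryo_target=(0, 1)),
        PathogenicVariantSpec("chr2", 5_100_000, "CTT", "C", "CFTR", "recessive_hom",
                              father_gt=(0, 1), mother_gt=(0, 1), embryo_target=(1, 1)),
        PathogenicVariantSpec("chr3", 5_200_000, "G", "A", "ABCA4", "compound_het",
                              clinvar_class="likely_pathogenic", review_stars=1,
                              father_gt=(0, 1), embryo_target=(0, 1)),
        PathogenicVariantSpec("chr3", 5_240_000, "T", "C", "ABCA4", "compound_het",
                              clinvar_class="likely_pathogenic", review_stars=1,
                              mother_gt=(0, 1), embryo_target=(0, 1)),
        PathogenicVariantSpec("chrX", 4_000_000, "A", "G", "GLA", "x_linked",
                              mother_gt=(0, 1), embryo_target=(1,)),
        PathogenicVariantSpec("chr4", 6_000_000, "C", "T", "ABL1", "de_novo",
                              embryo_target=(0, 1)),
        PathogenicVariantSpec("chr4", 2_000_000, "G", "A", "PAH", "dominant_het",
                              father_gt=(0, 1), embryo_target=(0, 1), in_dropout=True),
    ]


def default_planted_cnvs() -> list:
    """Six embryo CNVs >= 200 kb (plus two inherited from a parent)."""
    return [
        CnvSpec("chr1", 2_000_000, 2_300_000, {"embryo": 0}),
        CnvSpec("chr1", 6_000_000, 6_400_000, {"embryo": 6}),
        CnvSpec("chr2", 3_000_000, 3_250_000, {"embryo": 0, "father": 0}),
        CnvSpec("chr2", 7_000_000, 7_500_000, {"embryo": 6}),
        CnvSpec("chr3", 4_000_000, 4_400_000, {"embryo": 0, "mother": 0}),
        CnvSpec("chr3", 8_000_000, 8_300_000, {"embryo": 0}),
    ]


@dataclass
class SimParams:
    chromosomes: dict = field(default_factory=lambda: {
        "chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000,
        "chr4": 10_000_000, "chrX": 10_000_000,
    })
    het_density: float = 1 / 800          # candidate polymorphic sites per bp
    mean_depth_parent: float = 46.0
    mean_depth_embryo: float = 48.0
    parent_nb_size: float = 8.2           # NB dispersion; ~96.4% of windows >= 20x
    embryo_nb_size: float = 3.4           # with waves: ~87.5% of windows >= 20x
    wave_sigma: float = 0.15              # lognormal sd of MDA regional multipliers
    wave_clip: tuple = (0.6, 1.8)
    denovo_rate: float = 74.0             # expected de novo SNVs per embryo genome
    dropout_regions: int = 2              # expected MDA dropout regions per embryo
    dropout_length: tuple = (2_000_000, 3_000_000)
    artifact_het_rate: float = 20.0       # false-het sites per Mb
    artifact_vaf_params: tuple = (10.0, 5.0, 0.08, 0.34)  # Beta a, b on [lo, hi]; mode 0.26
    tstv_target: float = 2.081
    crossover_rate: float = 1.5           # expected crossovers per chromosome
    true_qd: tuple = (20.0, 3.0)          # mean, sd of QD at true variant sites
    artifact_qd: tuple = (6.0, 2.5)
    planted_variants: list = field(default_factory=default_planted_variants)
    planted_cnvs: list = field(default_factory=default_planted_cnvs)
    embryo_sexes: tuple = ("male", "female", "female")
    str_discordance_rate: float = 0.0
    father_id: str = "FATHER"
    mother_id: str = "MOTHER"
    x_chrom: str = "chrX"
    seed: int = 1

    @property
    def genome_bp(self) -> int:
        return sum(self.chromosomes.values())

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# parents


@dataclass
class ParentSim:
    params: SimParams
    sites: pd.DataFrame  # germline family sites with parental haplotypes + calls
    depth_tracks: dict   # sample_id -> {chrom: np.ndarray of per-window depth}


def _draw_depth(rng, mean, size_param, n):
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-3)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _alt_for(rng, ref, p_ts):
    is_ts = rng.random(len(ref)) < p_ts
    tv_pick = rng.integers(0, 2, size=len(ref))
    alt = np.empty(len(ref), dtype="<U1")
    for i, r in enumerate(ref):
        alt[i] = TRANSITION[r] if is_ts[i] else TRANSVERSIONS[r][tv_pick[i]]
    return alt


def _parent_track(params: SimParams, rng, cnv_mult_fn, halved_chroms=()):
    """Per-2kb-window depth track for a genomic-DNA (parental) sample.

    ``halved_chroms`` carries one copy instead of two (a male sample's
    X), so its expected depth halves.
    """
    track = {}
    for chrom, length in params.chromosomes.items():
        n = int(np.ceil(length / TRACK_RES_BP))
        mult = cnv_mult_fn(chrom, n)
        if chrom in halved_chroms:
            mult = mult * 0.5
        track[chrom] = _draw_depth(rng, params.mean_depth_parent * mult,
                                   params.parent_nb_size, n).astype(float)
    return track


def _cnv_multiplier(params: SimParams, role: str, res_bp: int):
    """Window-multiplier function from planted CNV copy numbers."""
    def fn(chrom, n):
        mult = np.ones(n)
        for spec in params.planted_cnvs:
            if spec.chrom != chrom:
                continue
            c = spec.copy_for(role)
            if c == 2:
                continue
            lo, hi = spec.start // res_bp, int(np.ceil(spec.end / res_bp))
            # residual coverage floor in homozygous losses (misaligned reads)
            mult[lo:hi] = max(c / 2.0, 0.03)
        return mult
    return fn


def simulate_parents(params: SimParams, rng=None) -> ParentSim:
    """Simulate the two parental germline genomes and depth tracks.

    Sites are drawn at ``het_density``; each of the four parental
    haplotypes carries the alternate allele with a site-specific
    population frequency, and sites with no alternate allele in the
    family are discarded.  Heterozygote allele depths are binomial at
    0.5.  Planted pathogenic variant specs overwrite the parental
    haplotypes at their positions.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    p_ts = params.tstv_target / (1.0 + params.tstv_target)
    frames = []
    for chrom, length in params.chromosomes.items():
        n_cand = int(round(length * params.het_density))
        pos = np.unique(rng.integers(1, length + 1, size=n_cand))
        n = len(pos)
        f = rng.uniform(0.05, 0.95, size=n)
        fh0 = (rng.random(n) < f).astype(np.int8)
        fh1 = (rng.random(n) < f).astype(np.int8)
        mh0 = (rng.random(n) < f).astype(np.int8)
        mh1 = (rng.random(n) < f).astype(np.int8)
        if chrom == params.x_chrom:
            fh1 = np.full(n, -1, dtype=np.int8)  # father hemizygous on X
        ref = rng.choice(np.array(list("ACGT")), size=n)
        alt = _alt_for(rng, ref, p_ts)
        keep = (fh0 == 1) | (fh1 == 1) | (mh0 == 1) | (mh1 == 1)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep], "ref": ref[keep], "alt": alt[keep],
            "fh0": fh0[keep], "fh1": fh1[keep], "mh0": mh0[keep], "mh1": mh1[keep],
        }))
    sites = pd.concat(frames, ignore_index=True)
    sites["origin_class"] = "germline"
    sites["spec_idx"] = -1

    # plant pathogenic variant specs into the parental haplotypes
    # (de novo specs are planted in the embryo, not here)
    extra = []
    for si, spec in enumerate(params.planted_variants):
        if spec.chrom not in params.chromosomes:
            raise SimConfigError(f"spec chromosome {spec.chrom} not simulated")
        if spec.mode == "de_novo":
            continue
        fh = spec.father_gt
        mh = spec.mother_gt
        if spec.mode == "recessive_hom" and not (1 in fh and 1 in mh):
            raise SimConfigError(
                f"recessive spec at {spec.chrom}:{spec.pos} requires both parents to carry the allele")
        row = {
            "chrom": spec.chrom, "pos": spec.pos, "ref": spec.ref, "alt": spec.alt,
            "fh0": fh[0], "fh1": (-1 if spec.chrom == params.x_chrom else fh[1]),
            "mh0": mh[0], "mh1": mh[1],
            "origin_class": "germline", "spec_idx": si,
        }
        extra.append(row)
    if extra:
        sites = sites[~sites.set_index(["chrom", "pos"]).index.isin(
            [(e["chrom"], e["pos"]) for e in extra])]
        sites = pd.concat([sites, pd.DataFrame(extra)], ignore_index=True)

    order = {c: i for i, c in enumerate(params.chromosomes)}
    sites = sites.sort_values(["chrom", "pos"],
                              key=lambda s: s.map(order) if s.name == "chrom" else s
                              ).reset_index(drop=True)

    n = len(sites)
    on_x = (sites["chrom"] == params.x_chrom).to_numpy()
    sites["qd"] = np.round(np.clip(rng.normal(*params.true_qd, size=n), 0.5, None), 2)
    for prefix, h0, h1 in (("f", "fh0", "fh1"), ("m", "mh0", "mh1")):
        site_mean = np.full(n, params.mean_depth_parent)
        if prefix == "f":
            site_mean[on_x] *= 0.5  # hemizygous X
        dp = _draw_depth(rng, site_mean, params.parent_nb_size, n)
        a0 = sites[h0].to_numpy()
        a1 = sites[h1].to_numpy()
        hemi = a1 == -1
        n_alt = np.where(hemi, a0, a0 + np.maximum(a1, 0))
        alt_reads = np.zeros(n, dtype=int)
        het = (~hemi) & (n_alt == 1)
        hom = (n_alt == 2) | (hemi & (a0 == 1))
        alt_reads[het] = np.clip(rng.binomial(dp[het], 0.5), 1, np.maximum(dp[het] - 1, 1))
        alt_reads[hom] = dp[hom]
        sites[f"{prefix}_dp"] = dp
        sites[f"{prefix}_alt"] = alt_reads
        sites[f"{prefix}_gq"] = np.minimum(99, 3 * dp)

    tracks = {
        params.father_id: _parent_track(params, rng, _cnv_multiplier(params, "father", TRACK_RES_BP),
                                        halved_chroms=(params.x_chrom,)),
        params.mother_id: _parent_track(params, rng, _cnv_multiplier(params, "mother", TRACK_RES_BP)),
    }
    return ParentSim(params, sites, tracks)


# ---------------------------------------------------------------------------
# embryo: transmission + de novo


@dataclass
class EmbryoSim:
    sample_id: str
    sex: str
    trans_f: np.ndarray  # transmitted father haplotype index per germline site (-1 on male X)
    trans_m: np.ndarray
    true_a1: np.ndarray  # paternal-derived allele (-1 on male X)
    true_a2: np.ndarray  # maternal-derived allele
    crossovers: dict     # (parent, chrom) -> breakpoint positions
    private: pd.DataFrame | None = None   # de novo + artifact rows (set by MDA stage)
    call_a1: np.ndarray | None = None     # observed alleles after MDA (-9 missing)
    call_a2: np.ndarray | None = None
    call_dp: np.ndarray | None = None
    call_alt: np.ndarray | None = None
    call_gq: np.ndarray | None = None
    dropout_regions: list = field(default_factory=list)  # (chrom, start, end, dropped)
    depth_track: dict = field(default_factory=dict)
    wave_mult: dict = field(default_factory=dict)  # chrom -> per-100kb multipliers
    sibling_calls: dict = field(default_factory=dict)  # (chrom,pos) -> (dp, gq) at sibling-private sites


def _transmitted_hap(rng, positions, length, crossover_rate):
    """Haplotype index per site for one transmitted parental chromosome."""
    k = rng.poisson(crossover_rate)
    breaks = np.sort(rng.integers(1, length + 1, size=k))
    start = rng.integers(0, 2)
    seg = np.searchsorted(breaks, positions, side="left")
    return ((start + seg) % 2).astype(np.int8), breaks


def simulate_embryo(parents: ParentSim, params: SimParams, rng=None,
                    sex: str = "female", sample_id: str = "EMBRYO",
                    plant_specs: bool = True) -> EmbryoSim:
    """Transmit one haplotype per parent with recombination; plant de novos.

    Planted pathogenic specs with an ``embryo_target`` are honoured by
    flipping the transmitted-haplotype parity of the relevant
    chromosome, so flanking phase stays consistent with the carried
    haplotype.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    sites = parents.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    n = len(sites)
    trans_f = np.zeros(n, dtype=np.int8)
    trans_m = np.zeros(n, dtype=np.int8)
    crossovers = {}
    for chrom, length in params.chromosomes.items():
        mask = chrom_arr == chrom
        positions = pos_arr[mask]
        for parent, arr in (("father", trans_f), ("mother", trans_m)):
            if chrom == params.x_chrom and parent == "father":
                hap = np.full(mask.sum(), -1 if sex == "male" else 0, dtype=np.int8)
                breaks = np.array([], dtype=int)  # father X transmits intact
            else:
                hap, breaks = _transmitted_hap(rng, positions, length, params.crossover_rate)
            arr[mask] = hap
            crossovers[(parent, chrom)] = breaks

    # honour planted embryo targets by flipping chromosome parity
    spec_idx = sites["spec_idx"].to_numpy()
    for si, spec in enumerate(params.planted_variants):
        where = np.nonzero(spec_idx == si)[0]
        if len(where) == 0:
            continue
        i = int(where[0])
        target = tuple(sorted(spec.embryo_target))
        if spec.mode == "de_novo":
            continue
        for parent, arr, h0col, h1col in (
            ("father", trans_f, "fh0", "fh1"), ("mother", trans_m, "mh0", "mh1"),
        ):
            if parent == "father" and spec.chrom == params.x_chrom:
                continue  # father X transmits his single haplotype (or none)
            parent_gt = spec.father_gt if parent == "father" else spec.mother_gt
            if 1 not in parent_gt:
                continue
            want = 1 if (target.count(1) >= (2 if spec.mode == "recessive_hom" else 1)
                         or (len(target) == 1 and target[0] == 1)) else 0
            haps = (sites.at[i, h0col], sites.at[i, h1col])
            cur_hap = arr[i]
            if cur_hap < 0:
                continue
            if haps[cur_hap] != want and haps[1 - cur_hap] == want:
                # flip the whole-chromosome haplotype parity: the natural
                # crossover structure is untouched, so no artificial phase
                # switch is introduced and flanking-SNP phase stays honest.
                # Limitation: at most one forced-transmission spec per
                # (parent, chromosome); a second spec there may not be
                # honoured.
                seg = chrom_arr == spec.chrom
                arr[seg] = np.where(arr[seg] >= 0, 1 - arr[seg], arr[seg])

    fh = sites[["fh0", "fh1"]].to_numpy()
    mh = sites[["mh0", "mh1"]].to_numpy()
    idx = np.arange(n)
    true_a1 = np.where(trans_f >= 0, fh[idx, np.maximum(trans_f, 0)], -1).astype(np.int8)
    true_a2 = mh[idx, trans_m].astype(np.int8)

    # de novo SNVs: expected count per genome, positions uniform
    k = rng.poisson(params.denovo_rate)
    chrom_names = list(params.chromosomes)
    lengths = np.array([params.chromosomes[c] for c in chrom_names], dtype=float)
    chosen = rng.choice(len(chrom_names), size=k, p=lengths / lengths.sum())
    p_ts = params.tstv_target / (1.0 + params.tstv_target)
    dn_rows = []
    taken = set(zip(chrom_arr.tolist(), pos_arr.tolist()))
    for c in chosen:
        chrom = chrom_names[c]
        while True:
            pos = int(rng.integers(1, params.chromosomes[chrom] + 1))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                break
        ref = str(rng.choice(list("ACGT")))
        alt = TRANSITION[ref] if rng.random() < p_ts else TRANSVERSIONS[ref][rng.integers(0, 2)]
        hap = "maternal" if (chrom == params.x_chrom and sex == "male") \
            else ("paternal" if rng.random() < 0.5 else "maternal")
        dn_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "origin_class": "de_novo", "hap": hap, "spec_idx": -1})
    if plant_specs:
        for si, spec in enumerate(params.planted_variants):
            if spec.mode != "de_novo":
                continue
            hap = "maternal" if (spec.chrom == params.x_chrom and sex == "male") else "paternal"
            dn_rows.append({"chrom": spec.chrom, "pos": spec.pos, "ref": spec.ref,
                            "alt": spec.alt, "origin_class": "de_novo", "hap": hap,
                            "spec_idx": si})
    emb = EmbryoSim(sample_id, sex, trans_f, trans_m, true_a1, true_a2, crossovers)
    emb.private = pd.DataFrame(dn_rows, columns=["chrom", "pos", "ref", "alt",
                                                 "origin_class", "hap", "spec_idx"])
    return emb


# ---------------------------------------------------------------------------
# MDA observation model


def _wave_multipliers(params: SimParams, rng):
    out = {}
    for chrom, length in params.chromosomes.items():
        n = int(np.ceil(length / WAVE_REGION_BP))
        m = rng.lognormal(-params.wave_sigma ** 2 / 2, params.wave_sigma, size=n)
        out[chrom] = np.clip(m, *params.wave_clip)
    return out


def simulate_mda(parents: ParentSim, embryo: EmbryoSim, params: SimParams, rng=None) -> EmbryoSim:
    """Apply the MDA observation model to a transmitted embryo genome.

    Dropout regions erase one inherited haplotype's evidence (driving
    apparent LoH); false-heterozygote artifact sites appear at
    ``artifact_het_rate`` with VAF drawn from the configured scaled
    Beta distribution; true sites get negative-binomial depth modulated
    by regional amplification waves, with heterozygote reads binomial
    at 0.5.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    sites = parents.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    n = len(sites)
    embryo.wave_mult = _wave_multipliers(params, rng)

    # ---- dropout regions (autosomes only; a forced region covers any
    # planted spec with in_dropout)
    autosomes = [c for c in params.chromosomes if c != params.x_chrom]
    regions = []
    for _ in range(params.dropout_regions):
        chrom = autosomes[rng.integers(0, len(autosomes))]
        length = int(rng.uniform(*params.dropout_length))
        start = int(rng.integers(1, max(params.chromosomes[chrom] - length, 2)))
        regions.append([chrom, start, start + length, None])
    for spec in params.planted_variants:
        if spec.in_dropout and spec.chrom != params.x_chrom:
            # drop the carrier parent's haplotype so the planted variant
            # goes missing from the embryo calls
            side = "paternal" if 1 in spec.father_gt else "maternal"
            length = int(np.mean(params.dropout_length))
            start = max(1, spec.pos - length // 2)
            regions.append([spec.chrom, start, start + length, side])
    for reg in regions:
        if reg[3] is None:
            reg[3] = "paternal" if rng.random() < 0.5 else "maternal"
    embryo.dropout_regions = [tuple(r) for r in regions]

    # ---- observed alleles at germline sites
    a1 = embryo.true_a1.copy()
    a2 = embryo.true_a2.copy()
    in_dropout = np.zeros(n, dtype=bool)
    for chrom, start, end, dropped in embryo.dropout_regions:
        mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
        in_dropout |= mask
        if dropped == "paternal":
            a1[mask] = a2[mask]  # paternal evidence gone: appears hom maternal
        else:
            a2[mask] = np.where(a1[mask] >= 0, a1[mask], a2[mask])

    # ---- depth at germline sites
    region_idx = pos_arr // WAVE_REGION_BP
    mult = np.array([embryo.wave_mult[c][r] for c, r in zip(chrom_arr, region_idx)])
    cnv_mult = np.ones(n)
    for spec in params.planted_cnvs:
        c = spec.copy_for("embryo")
        if c == 2:
            continue
        mask = (chrom_arr == spec.chrom) & (pos_arr > spec.start) & (pos_arr <= spec.end)
        cnv_mult[mask] = max(c / 2.0, 0.03)
    mult = mult * cnv_mult
    mult[in_dropout] *= 0.55  # one template lost
    if embryo.sex == "male":
        mult = np.where(chrom_arr == params.x_chrom, mult * 0.5, mult)
    dp = _draw_depth(rng, params.mean_depth_embryo * mult, params.embryo_nb_size, n)

    hemi = a1 == -1
    missing = dp == 0
    n_alt = np.where(hemi, a2, np.maximum(a1, 0) + a2)
    het = (~hemi) & (a1 != a2)
    hom_alt = (~hemi & (a1 == 1) & (a2 == 1)) | (hemi & (a2 == 1))
    alt_reads = np.zeros(n, dtype=int)
    het_dp = dp[het]
    alt_reads[het] = np.clip(rng.binomial(het_dp, 0.5), np.minimum(1, het_dp),
                             np.maximum(het_dp - 1, 1))
    alt_reads[hom_alt] = dp[hom_alt]

    embryo.call_a1 = np.where(missing, -9, a1).astype(np.int8)
    embryo.call_a2 = np.where(missing, -9, a2).astype(np.int8)
    embryo.call_dp = dp
    embryo.call_alt = np.where(missing, 0, alt_reads)
    embryo.call_gq = np.minimum(99, 3 * dp)

    # ---- private rows: de novo depths + artifact sites
    priv = embryo.private.copy() if embryo.private is not None else pd.DataFrame()
    a, b, lo, hi = params.artifact_vaf_params
    genome_mb = params.genome_bp / 1e6
    k_art = rng.poisson(params.artifact_het_rate * genome_mb)
    chrom_names = list(params.chromosomes)
    lengths = np.array([params.chromosomes[c] for c in chrom_names], dtype=float)
    taken = set(zip(chrom_arr.tolist(), pos_arr.tolist()))
    if len(priv):
        taken |= set(zip(priv["chrom"].tolist(), priv["pos"].tolist()))
    art_rows = []
    p_ts = params.tstv_target / (1.0 + params.tstv_target)
    chosen = rng.choice(len(chrom_names), size=k_art, p=lengths / lengths.sum())
    for c in chosen:
        chrom = chrom_names[c]
        while True:
            pos = int(rng.integers(1, params.chromosomes[chrom] + 1))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                break
        ref = str(rng.choice(list("ACGT")))
        alt = TRANSITION[ref] if rng.random() < p_ts else TRANSVERSIONS[ref][rng.integers(0, 2)]
        art_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "origin_class": "artifact", "hap": "", "spec_idx": -1})
    priv = pd.concat([priv, pd.DataFrame(art_rows, columns=["chrom", "pos", "ref", "alt",
                                                            "origin_class", "hap", "spec_idx"])],
                     ignore_index=True)

    if len(priv):
        p_region = priv["pos"].to_numpy() // WAVE_REGION_BP
        p_mult = np.array([embryo.wave_mult[c][r] for c, r in zip(priv["chrom"], p_region)])
        if embryo.sex == "male":
            p_mult = np.where(priv["chrom"].to_numpy() == params.x_chrom, p_mult * 0.5, p_mult)
        p_dp = np.maximum(_draw_depth(rng, params.mean_depth_embryo * p_mult,
                                      params.embryo_nb_size, len(priv)), 3)
        is_art = (priv["origin_class"] == "artifact").to_numpy()
        vaf = np.zeros(len(priv))
        vaf[is_art] = lo + (hi - lo) * rng.beta(a, b, size=int(is_art.sum()))
        p_alt = np.zeros(len(priv), dtype=int)
        p_alt[is_art] = np.clip(np.round(vaf[is_art] * p_dp[is_art]).astype(int),
                                1, p_dp[is_art] - 1)
        dn = ~is_art
        p_alt[dn] = np.clip(rng.binomial(p_dp[dn], 0.5), 1, np.maximum(p_dp[dn] - 1, 1))
        priv["e_dp"] = p_dp
        priv["e_alt"] = p_alt
        priv["vaf_drawn"] = vaf
        priv["e_gq"] = np.where(is_art,
                                rng.integers(10, 61, size=len(priv)),
                                np.minimum(99, 3 * p_dp))
        priv["qd"] = np.round(np.where(
            is_art,
            np.clip(rng.normal(*params.artifact_qd, size=len(priv)), 0.5, None),
            np.clip(rng.normal(*params.true_qd, size=len(priv)), 0.5, None)), 2)
        # a de novo inside a dropout region can lose its haplotype too
        for i in priv.index[dn]:
            for chrom, start, end, dropped in embryo.dropout_regions:
                if (priv.at[i, "chrom"] == chrom and start <= priv.at[i, "pos"] < end
                        and dropped == priv.at[i, "hap"]):
                    priv.at[i, "e_alt"] = 0
    embryo.private = priv

    # ---- embryo depth track
    track = {}
    cnv_fn = _cnv_multiplier(params, "embryo", TRACK_RES_BP)
    for chrom, length in params.chromosomes.items():
        nwin = int(np.ceil(length / TRACK_RES_BP))
        wave = np.repeat(embryo.wave_mult[chrom], WAVE_REGION_BP // TRACK_RES_BP)[:nwin]
        mult = wave * cnv_fn(chrom, nwin)
        if embryo.sex == "male" and chrom == params.x_chrom:
            mult = mult * 0.5
        track[chrom] = _draw_depth(rng, params.mean_depth_embryo * mult,
                                   params.embryo_nb_size, nwin).astype(float)
    embryo.depth_track = track
    return embryo


# ---------------------------------------------------------------------------
# family assembly and emission


@dataclass
class FamilySim:
    params: SimParams
    parents: ParentSim
    embryos: list


def simulate_family(params: SimParams) -> FamilySim:
    """Simulate parents and all embryos with one seeded generator."""
    rng = np.random.default_rng(params.seed)
    parents = simulate_parents(params, rng)
    embryos = []
    for i, sex in enumerate(params.embryo_sexes, start=1):
        # de novo specs are planted in the first embryo only
        emb = simulate_embryo(parents, params, rng, sex=sex, sample_id=f"EMBRYO{i}",
                              plant_specs=(i == 1))
        simulate_mda(parents, emb, params, rng)
        embryos.append(emb)
    # depth/AD for each embryo at sibling-private sites (hom-ref there)
    for emb in embryos:
        others = [e for e in embryos if e is not emb]
        rows = []
        for other in others:
            if other.private is not None and len(other.private):
                rows.append(other.private[["chrom", "pos"]])
        if not rows:
            emb.sibling_calls = {}
            continue
        sib = pd.concat(rows, ignore_index=True)
        region = sib["pos"].to_numpy() // WAVE_REGION_BP
        mult = np.array([emb.wave_mult[c][r] for c, r in zip(sib["chrom"], region)])
        dp = _draw_depth(rng, params.mean_depth_embryo * mult, params.embryo_nb_size, len(sib))
        emb.sibling_calls = {
            (c, int(p)): (int(d), int(min(99, 3 * d)))
            for c, p, d in zip(sib["chrom"], sib["pos"], dp)
        }
    return FamilySim(params, parents, embryos)


def _gt(a1, a2, phased=False):
    def sym(a):
        return None if a in (-9, None) else int(a)
    if a1 == -1:  # hemizygous, allele held in a2 (male embryo X)
        return (sym(a2),), phased
    if a2 == -1:  # hemizygous, allele held in a1 (father X)
        return (sym(a1),), phased
    return (sym(a1), sym(a2)), phased


def family_records(fam: FamilySim):
    """Yield TrioVariantRecords for the whole family, sorted."""
    params = fam.params
    father, mother = params.father_id, params.mother_id
    order = {c: i for i, c in enumerate(params.chromosomes)}
    rows = []
    sites = fam.parents.sites
    for i in range(len(sites)):
        s = sites.iloc[i]
        rows.append(("germline", i, s["chrom"], int(s["pos"])))
    for ei, emb in enumerate(fam.embryos):
        for j in range(len(emb.private)):
            p = emb.private.iloc[j]
            rows.append((("private", ei), j, p["chrom"], int(p["pos"])))
    rows.sort(key=lambda r: (order[r[2]], r[3]))

    sites_np = {c: sites[c].to_numpy() for c in sites.columns}
    for kind, i, chrom, pos in rows:
        if kind == "germline":
            ref, alt = sites_np["ref"][i], sites_np["alt"][i]
            qd = float(sites_np["qd"][i])
            calls = {}
            for sid, pre, h0, h1 in ((father, "f", "fh0", "fh1"), (mother, "m", "mh0", "mh1")):
                a0, a1v = int(sites_np[h0][i]), int(sites_np[h1][i])
                alleles, phased = _gt(a0, a1v if a1v != -1 else -1, phased=True)
                dp = int(sites_np[f"{pre}_dp"][i])
                altr = int(sites_np[f"{pre}_alt"][i])
                calls[sid] = GenotypeCall(alleles, (dp - altr, altr), dp,
                                          float(sites_np[f"{pre}_gq"][i]),
                                          ploidy=len(alleles), phased=True)
            for emb in fam.embryos:
                ea1, ea2 = int(emb.call_a1[i]), int(emb.call_a2[i])
                alleles, _ = _gt(ea1, ea2)
                dp = int(emb.call_dp[i])
                altr = int(emb.call_alt[i])
                calls[emb.sample_id] = GenotypeCall(alleles, (dp - altr, altr), dp,
                                                    float(emb.call_gq[i]),
                                                    ploidy=len(alleles))
            yield TrioVariantRecord(chrom, pos, str(ref), str(alt), qd, calls)
        else:
            _, ei = kind[0], kind[1]
            emb_owner = fam.embryos[ei]
            p = emb_owner.private.iloc[i]
            ref, alt = str(p["ref"]), str(p["alt"])
            qd = float(p["qd"])
            calls = {}
            # parents hom-ref with typical genomic depth (deterministic
            # midpoint; parents are clean gDNA at these positions)
            for sid in (father, mother):
                dp = int(round(params.mean_depth_parent))
                calls[sid] = GenotypeCall((0, 0), (dp, 0), dp, 99.0, ploidy=2, phased=True)
            for emb in fam.embryos:
                if emb is emb_owner:
                    dp, altr = int(p["e_dp"]), int(p["e_alt"])
                    gq = float(p["e_gq"])
                    if altr == 0:
                        alleles = (0, 0)
                    elif p["origin_class"] == "artifact":
                        alleles = (0, 1)
                    else:
                        alleles = (0, 1)
                    if emb.sex == "male" and p["chrom"] == params.x_chrom:
                        alleles = (alleles[-1],)
                    calls[emb.sample_id] = GenotypeCall(alleles, (dp - altr, altr), dp, gq,
                                                        ploidy=len(alleles))
                else:
                    dp, gq = emb.sibling_calls.get((p["chrom"], int(p["pos"])),
                                                   (int(round(params.mean_depth_embryo)), 99))
                    alleles = (0,) if (emb.sex == "male" and p["chrom"] == params.x_chrom) else (0, 0)
                    calls[emb.sample_id] = GenotypeCall(alleles, (dp, 0), dp, float(gq),
                                                        ploidy=len(alleles))
            yield TrioVariantRecord(str(p["chrom"]), pos, ref, alt, qd, calls)


# ---------------------------------------------------------------------------
# annotations, repeats and auxiliary tables


def gene_for_position(chrom: str, pos: int) -> str:
    """Synthetic gene model: a 50 kb gene at the start of every 500 kb tile."""
    tile = pos // 500_000
    if pos % 500_000 < 50_000:
        return f"G{chrom[3:]}_{tile}"
    return ""


def build_annotations(fam: FamilySim, rng=None) -> pd.DataFrame:
    """Annotation table for every simulated site.

    Planted specs carry their declared ClinVar class / stars (or a
    damaging prediction profile when ``predicted``); background sites
    are unclassified with benign-looking scores.  dbSNP membership is
    frequent for germline sites and rare for de novos and artifacts.
    """
    params = fam.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 9999)

    frames = [fam.parents.sites[["chrom", "pos", "ref", "alt"]].assign(
        origin_class="germline")]
    seen = set(zip(fam.parents.sites["chrom"], fam.parents.sites["pos"]))
    for emb in fam.embryos:
        if emb.private is None or not len(emb.private):
            continue
        priv = emb.private[["chrom", "pos", "ref", "alt", "origin_class"]]
        fresh = [not (c, p) in seen for c, p in zip(priv["chrom"], priv["pos"])]
        priv = priv[fresh]
        seen |= set(zip(priv["chrom"], priv["pos"]))
        frames.append(priv)
    df = pd.concat(frames, ignore_index=True)

    n = len(df)
    p_dbsnp = df["origin_class"].map(
        {"germline": 0.97, "de_novo": 0.05, "artifact": 0.02}).to_numpy()
    in_db = rng.random(n) < p_dbsnp
    rs_numbers = rng.integers(10 ** 6, 10 ** 8, size=n)
    df["in_dbsnp"] = in_db.astype(int)
    df["rsid"] = np.where(in_db, [f"rs{r}" for r in rs_numbers], "")
    df["clinvar_class"] = "unclassified"
    df["review_stars"] = 0
    df["gene"] = [gene_for_position(c, p) for c, p in zip(df["chrom"], df["pos"])]
    df["sift"] = "tolerated"
    df["polyphen2_hvar"] = "tolerated"
    for col in ("mutation_taster2", "mutation_assessor", "fathmm", "fathmm_mkl"):
        df[col] = ""
    df["mpc"] = np.round(rng.uniform(0, 1.5, size=n), 2)
    df["cadd_phred"] = np.round(rng.uniform(0, 20, size=n), 1)

    key_index = {(c, p, r, a): i for i, (c, p, r, a) in enumerate(
        zip(df["chrom"], df["pos"], df["ref"], df["alt"]))}
    for spec in params.planted_variants:
        i = key_index.get((spec.chrom, spec.pos, spec.ref, spec.alt))
        if i is None:
            continue
        df.loc[i, ["gene", "in_dbsnp"]] = [spec.gene, int(spec.in_dbsnp)]
        if spec.predicted:
            df.loc[i, ["sift", "polyphen2_hvar", "mutation_taster2"]] = "damaging"
            df.loc[i, ["mpc", "cadd_phred"]] = [2.6, 38.0]
        else:
            df.loc[i, ["clinvar_class", "review_stars"]] = [
                spec.clinvar_class, spec.review_stars]

    df = df.drop(columns="origin_class")
    order = {c: i for i, c in enumerate(params.chromosomes)}
    df["_c"] = df["chrom"].map(order)
    df = df.sort_values(["_c", "pos"]).drop(columns="_c").reset_index(drop=True)
    return df


def build_repeat_genotypes(fam: FamilySim, rng=None) -> pd.DataFrame:
    """Repeat-panel genotypes: parental alleles in the normal range,
    embryo alleles transmitted exactly (optionally jittered at
    ``str_discordance_rate`` to emulate read-based genotyping error)."""
    params = fam.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 777)
    rows = []
    for locus, t in DEFAULT_PANEL.items():
        low = max(2, t.normal_max - 15)
        f_alleles = (int(rng.integers(low, t.normal_max + 1)),
                     int(rng.integers(low, t.normal_max + 1)))
        m_alleles = (int(rng.integers(low, t.normal_max + 1)),
                     int(rng.integers(low, t.normal_max + 1)))
        if locus in X_LINKED_LOCI:
            rows.append({"locus": locus, "sample_id": params.father_id,
                         "allele_1": f_alleles[0], "allele_2": ""})
        else:
            rows.append({"locus": locus, "sample_id": params.father_id,
                         "allele_1": f_alleles[0], "allele_2": f_alleles[1]})
        rows.append({"locus": locus, "sample_id": params.mother_id,
                     "allele_1": m_alleles[0], "allele_2": m_alleles[1]})
        for emb in fam.embryos:
            ma = int(m_alleles[rng.integers(0, 2)])
            if locus in X_LINKED_LOCI and emb.sex == "male":
                alleles = [ma, ""]
            else:
                fa = f_alleles[0] if locus in X_LINKED_LOCI else f_alleles[rng.integers(0, 2)]
                alleles = [int(fa), ma]
            for k in (0, 1):
                if alleles[k] != "" and rng.random() < params.str_discordance_rate:
                    alleles[k] = int(alleles[k]) + int(rng.integers(1, 4))
            rows.append({"locus": locus, "sample_id": emb.sample_id,
                         "allele_1": alleles[0], "allele_2": alleles[1]})
    return pd.DataFrame(rows)


def default_dosage_table(params: SimParams) -> pd.DataFrame:
    """Dosage-sensitivity genes laid over the default planted CNVs."""
    rows = [
        {"gene": "HIGENE1", "chrom": "chr1", "start": 2_050_000, "end": 2_150_000,
         "haploinsufficiency": "sufficient_evidence", "triplosensitivity": "none"},
        {"gene": "TSGENE1", "chrom": "chr1", "start": 6_100_000, "end": 6_250_000,
         "haploinsufficiency": "none", "triplosensitivity": "sufficient_evidence"},
        {"gene": "ARGENE1", "chrom": "chr2", "start": 3_050_000, "end": 3_150_000,
         "haploinsufficiency": "autosomal_recessive_gene", "triplosensitivity": "none"},
        {"gene": "TSGENE2", "chrom": "chr2", "start": 7_100_000, "end": 7_300_000,
         "haploinsufficiency": "none", "triplosensitivity": "sufficient_evidence"},
        {"gene": "ARGENE2", "chrom": "chr3", "start": 4_100_000, "end": 4_250_000,
         "haploinsufficiency": "autosomal_recessive_gene", "triplosensitivity": "none"},
        {"gene": "HIGENE2", "chrom": "chr3", "start": 8_050_000, "end": 8_200_000,
         "haploinsufficiency": "sufficient_evidence", "triplosensitivity": "none"},
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth tables and emission


def truth_variants(fam: FamilySim) -> pd.DataFrame:
    """Per-embryo per-variant truth: origin class and true genotype."""
    frames = []
    sites = fam.parents.sites
    for emb in fam.embryos:
        a1 = emb.true_a1.astype(int)
        a2 = emb.true_a2.astype(int)
        carried = (np.maximum(a1, 0) + np.maximum(a2, 0)) > 0
        origin = np.select(
            [(a1 == 1) & (a2 == 1), a1 == 1, a2 == 1],
            ["paternal+maternal", "paternal", "maternal"], default="")
        gt = np.where(a1 == -1, a2.astype(str),
                      np.char.add(np.char.add(a1.astype(str), "|"), a2.astype(str)))
        g = pd.DataFrame({
            "sample_id": emb.sample_id,
            "chrom": sites["chrom"].to_numpy()[carried],
            "pos": sites["pos"].to_numpy()[carried],
            "ref": sites["ref"].to_numpy()[carried],
            "alt": sites["alt"].to_numpy()[carried],
            "class": "germline",
            "origin": origin[carried],
            "true_gt": gt[carried],
            "spec_idx": sites["spec_idx"].to_numpy()[carried],
        })
        frames.append(g)
        if emb.private is not None and len(emb.private):
            p = emb.private
            frames.append(pd.DataFrame({
                "sample_id": emb.sample_id,
                "chrom": p["chrom"], "pos": p["pos"], "ref": p["ref"], "alt": p["alt"],
                "class": p["origin_class"], "origin": p["origin_class"],
                "true_gt": np.where(p["origin_class"] == "de_novo", "0/1", "0/0"),
                "spec_idx": p["spec_idx"],
            }))
    return pd.concat(frames, ignore_index=True)


def truth_regions(fam: FamilySim) -> pd.DataFrame:
    rows = []
    for emb in fam.embryos:
        for chrom, start, end, dropped in emb.dropout_regions:
            rows.append({"sample_id": emb.sample_id, "type": "dropout", "chrom": chrom,
                         "start": start, "end": end, "detail": dropped})
    for spec in fam.params.planted_cnvs:
        rows.append({"sample_id": "*", "type": "cnv", "chrom": spec.chrom,
                     "start": spec.start, "end": spec.end,
                     "detail": ";".join(f"{k}={v}" for k, v in sorted(spec.copies.items()))})
    return pd.DataFrame(rows)


def coverage_fraction(track: dict, threshold: float = 20.0) -> float:
    values = np.concatenate([v for v in track.values()])
    return float((values >= threshold).mean())


def write_bedgraph(path, track: dict, res: int = TRACK_RES_BP) -> None:
    with open(path, "w") as fh:
        for chrom, values in track.items():
            for i, v in enumerate(values):
                fh.write(f"{chrom}\t{i * res}\t{(i + 1) * res}\t{v:.0f}\n")


def emit(fam: FamilySim, outdir) -> dict:
    """Write the family as pipeline-ready files; returns the path map."""
    import os

    params = fam.params
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    sample_order = [params.father_id, params.mother_id] + [e.sample_id for e in fam.embryos]
    paths["vcf"] = os.path.join(outdir, "family.vcf")
    write_trio_vcf(paths["vcf"], family_records(fam), sample_order, params.chromosomes)

    paths["pedigree"] = os.path.join(outdir, "pedigree.tsv")
    with open(paths["pedigree"], "w") as fh:
        fh.write(f"{params.father_id}\tfather\tmale\t\n")
        fh.write(f"{params.mother_id}\tmother\tfemale\t\n")
        for emb in fam.embryos:
            fh.write(f"{emb.sample_id}\tembryo\t{emb.sex}\t{params.father_id},{params.mother_id}\n")

    ann = build_annotations(fam)
    paths["annotations"] = os.path.join(outdir, "annotations.tsv")
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    for sid, track in {**fam.parents.depth_tracks,
                       **{e.sample_id: e.depth_track for e in fam.embryos}}.items():
        p = os.path.join(outdir, f"depth_{sid}.bedgraph")
        paths[f"depth_{sid}"] = p
        write_bedgraph(p, track)

    rep = build_repeat_genotypes(fam)
    paths["repeats"] = os.path.join(outdir, "repeats.tsv")
    rep.to_csv(paths["repeats"], sep="\t", index=False)

    paths["dosage"] = os.path.join(outdir, "dosage.tsv")
    default_dosage_table(params).to_csv(paths["dosage"], sep="\t", index=False)

    actionable = sorted({s.gene for s in params.planted_variants} | {"G1_1", "G2_4", "G4_11"})
    paths["actionable_genes"] = os.path.join(outdir, "actionable_genes.txt")
    with open(paths["actionable_genes"], "w") as fh:
        fh.write("\n".join(actionable) + "\n")
    paths["incidental_genes"] = os.path.join(outdir, "incidental_genes.txt")
    with open(paths["incidental_genes"], "w") as fh:
        fh.write("BRCA2\nKRT10\n")

    paths["truth_variants"] = os.path.join(outdir, "truth_variants.tsv")
    truth_variants(fam).to_csv(paths["truth_variants"], sep="\t", index=False)
    paths["truth_regions"] = os.path.join(outdir, "truth_regions.tsv")
    truth_regions(fam).to_csv(paths["truth_regions"], sep="\t", index=False)

    # ready-to-run pipeline config
    import yaml

    config = {
        "vcf": paths["vcf"],
        "pedigree": paths["pedigree"],
        "annotations": paths["annotations"],
        "actionable_genes": paths["actionable_genes"],
        "incidental_genes": paths["incidental_genes"],
        "depth_tracks": {sid: paths[f"depth_{sid}"] for sid in sample_order},
        "dosage_table": paths["dosage"],
        "repeats": paths["repeats"],
        "conditions": [{"gene": s.gene, "mode": s.mode} for s in params.planted_variants],
        "stages": {"cnv": True, "str": True, "loh": True},
        "thresholds": {"depth_min": 10, "gq_min": 20, "vaf": 0.35, "qd": 12},
        "out_dir": os.path.join(outdir, "report"),
    }
    paths["config"] = os.path.join(outdir, "config.yaml")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
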