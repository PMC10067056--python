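"""Seeded generator of gnomAD-like annotated KMT2A-D cohorts.

Two entry points:

* :func:`generate_cohort` draws a cohort from a
  :class:`GeneratorConfig` together with its ground truth (per-variant
  true allele frequency, planted manual classification and hotspot
  membership). Stratum allele counts are binomial draws from the true
  AF, so strata always sum to the overall AC, and every annotation is
  placed strictly inside a decision band (never on a threshold) so the
  planted class is recovered exactly by the manual classifier.

* :func:`generate_from_marginals` deterministically rebuilds a cohort
  whose manual classification reproduces requested per-gene /
  per-consequence marginal counts — useful for reconstructing printed
  summary tables as classifier input.

The generator emulates site-level gnomAD rows: per-gene variant totals
and consequence mix at roughly one tenth of the real survey's scale, a
heavy-tailed true-AF distribution dominated by singletons, sparse
ClinVar labels, and very unequal ancestry strata (large non-Finnish
European and African strata, tiny Amish and Middle Eastern ones). It
does not simulate genotypes, linkage or relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from kmt2pop.manual_classifier import Classification, HotspotRegion
from kmt2pop.variant_model import (
    ANCESTRIES,
    AnnotationBundle,
    ClinVarSignificance,
    Cohort,
    CohortRecord,
    ConsequenceClass,
    PopulationCounts,
    VariantRecord,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "MarginalTarget",
    "InfeasibleTargetError",
    "generate_cohort",
    "generate_from_marginals",
    "plp_marginal_targets",
]

GENES = ("KMT2A", "KMT2B", "KMT2C", "KMT2D")

#: Approximate gene geometry (GRCh38): chromosome, transcription start,
#: genomic span (bp) and protein length (aa).
GENE_INFO: dict[str, tuple[str, int, int, int]] = {
    "KMT2A": ("chr11", 118_436_492, 90_000, 3969),
    "KMT2B": ("chr19", 35_717_861, 25_000, 2715),
    "KMT2C": ("chr7", 152_134_922, 300_000, 4911),
    "KMT2D": ("chr12", 49_018_975, 45_000, 5537),
}

_CLASS_TERM: dict[ConsequenceClass, str] = {
    ConsequenceClass.LOF_FRAMESHIFT: "frameshift_variant",
    ConsequenceClass.LOF_NONSENSE: "stop_gained",
    ConsequenceClass.CANONICAL_SPLICE: "splice_donor_variant",
    ConsequenceClass.NON_CANONICAL_SPLICE: "splice_region_variant",
    ConsequenceClass.MISSENSE: "missense_variant",
    ConsequenceClass.STOP_LOST: "stop_lost",
    ConsequenceClass.INFRAME_INDEL: "inframe_deletion",
    ConsequenceClass.SYNONYMOUS: "synonymous_variant",
    ConsequenceClass.UTR: "5_prime_UTR_variant",
    ConsequenceClass.INTRONIC: "intron_variant",
}

#: Consequence mix of a gnomAD KMT2A-D export (proportions of the ten
#: classes in a ~14k-variant survey).
DEFAULT_CONSEQUENCE_MIX: dict[ConsequenceClass, float] = {
    ConsequenceClass.LOF_FRAMESHIFT: 38 / 14313,
    ConsequenceClass.LOF_NONSENSE: 17 / 14313,
    ConsequenceClass.STOP_LOST: 1 / 14313,
    ConsequenceClass.CANONICAL_SPLICE: 18 / 14313,
    ConsequenceClass.NON_CANONICAL_SPLICE: 509 / 14313,
    ConsequenceClass.MISSENSE: 5558 / 14313,
    ConsequenceClass.INFRAME_INDEL: 248 / 14313,
    ConsequenceClass.UTR: 172 / 14313,
    ConsequenceClass.SYNONYMOUS: 2961 / 14313,
    ConsequenceClass.INTRONIC: 4791 / 14313,
}

#: gnomAD v3 non-cancer genetic-ancestry proportions (individuals).
DEFAULT_ANCESTRY_PROPORTIONS: dict[str, float] = {
    "afr": 0.2724,
    "amr": 0.1004,
    "eas": 0.0342,
    "sas": 0.0318,
    "nfe": 0.4468,
    "asj": 0.0228,
    "fin": 0.0698,
    "ami": 0.0060,
    "mid": 0.0021,
    "oth": 0.0137,
}

#: Branch mix for missense variants (probabilities of the escalation
#: routes; chosen so the generated P/LP/VUS/LB shares resemble a real
#: gnomAD KMT2 export).
DEFAULT_MISSENSE_BRANCHES: dict[str, float] = {
    "hotspot": 0.03,
    "literature": 0.03,
    "clinvar_plp": 0.02,
    "high_score": 0.023,
    "intermediate": 0.60,
    "benign": 0.297,
}

#: Default planted hotspot regions (protein coordinates); the KMT2C
#: interval covers its first PHD finger, the only previously described
#: missense hotspot in the family.
DEFAULT_HOTSPOTS: dict[str, tuple[tuple[int, int], ...]] = {
    "KMT2A": ((3829, 3945),),
    "KMT2B": ((2510, 2560),),
    "KMT2C": ((344, 391),),
    "KMT2D": ((5397, 5443),),
}

# Margins kept between generated scores and the decision thresholds so
# planted-class recovery is never rounding-fragile.
CADD_MARGIN = 0.5
REVEL_MARGIN = 0.01


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``seed`` is mandatory; every draw flows from it. ``gene_counts``
    defaults to roughly a tenth of a real KMT2A-D gnomAD export;
    ``n_individuals`` (5,000 by default, configurable up to survey
    scale) fixes the ancestry allele-number vector via
    ``ancestry_proportions``. The true-AF mixture is singleton-heavy:
    ``singleton_fraction`` of variants get AF = 1/AN, the rest are
    log-uniform rare, with small common and very-common tails.
    """

    seed: int
    gene_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "KMT2A": 239, "KMT2B": 299, "KMT2C": 432, "KMT2D": 460,
        }
    )
    consequence_mix: Mapping[ConsequenceClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    missense_branches: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSENSE_BRANCHES)
    )
    n_individuals: int = 5000
    ancestry_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_PROPORTIONS)
    )
    hotspot_regions: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=lambda: {g: list(v) for g, v in DEFAULT_HOTSPOTS.items()}
    )
    singleton_fraction: float = 0.60
    rare_fraction: float = 0.30
    common_fraction: float = 0.08
    ncrna_rate: float = 0.10
    clinvar_label_rate: float = 0.08
    male_fraction: float = 0.50

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.gene_counts.values()):
            raise ValueError("gene_counts must be non-negative")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for name, mix in (
            ("consequence_mix", self.consequence_mix),
            ("missense_branches", self.missense_branches),
            ("ancestry_proportions", self.ancestry_proportions),
        ):
            total = sum(mix.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} proportions sum to {total}, not 1")
        tail = self.singleton_fraction + self.rare_fraction + self.common_fraction
        if tail > 1.0 + 1e-9:
            raise ValueError("AF mixture fractions exceed 1")

    def ancestry_an(self) -> dict[str, int]:
        """Per-stratum allele numbers summing exactly to 2 x individuals."""
        total_an = 2 * self.n_individuals
        raw = {
            a: int(round(self.ancestry_proportions[a] * total_an))
            for a in ANCESTRIES
        }
        # pin the rounding residue on the largest stratum
        largest = max(raw, key=raw.get)
        raw[largest] += total_an - sum(raw.values())
        if any(v <= 0 for v in raw.values()):
            raise ValueError("every ancestry stratum needs a positive AN")
        return raw


@dataclass
class GroundTruth:
    """Per-variant truth emitted alongside a generated cohort."""

    true_af: list[float]
    planted_class: list[Classification]
    hotspot_member: list[bool]
    hotspot_regions: dict[str, list[HotspotRegion]]


_BASES = ("A", "C", "G", "T")


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _draw_true_af(rng: np.random.Generator, cfg: GeneratorConfig, an_total: int) -> float:
    u = rng.random()
    if u < cfg.singleton_fraction:
        return 1.0 / an_total
    if u < cfg.singleton_fraction + cfg.rare_fraction:
        lo, hi = np.log10(1.0 / an_total), -2.0
        return float(10 ** rng.uniform(lo, hi))
    if u < cfg.singleton_fraction + cfg.rare_fraction + cfg.common_fraction:
        return float(10 ** rng.uniform(-2.0, np.log10(0.05)))
    return float(10 ** rng.uniform(np.log10(0.05), np.log10(0.20)))


def _draw_popcounts(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    ancestry_an: Mapping[str, int],
    true_af: float,
) -> PopulationCounts:
    an_total = sum(ancestry_an.values())
    per_ancestry: dict[str, tuple[int, int]] = {}
    for a in ANCESTRIES:
        an = ancestry_an[a]
        ac = int(rng.binomial(an, min(true_af, 1.0)))
        per_ancestry[a] = (ac, an)
    ac_total = sum(ac for ac, _ in per_ancestry.values())
    if ac_total == 0:
        # a gnomAD row exists because the allele was observed at least
        # once; seed a singleton in an AN-weighted stratum
        weights = np.array([ancestry_an[a] for a in ANCESTRIES], dtype=float)
        stratum = ANCESTRIES[rng.choice(len(ANCESTRIES), p=weights / weights.sum())]
        ac, an = per_ancestry[stratum]
        per_ancestry[stratum] = (ac + 1, an)
        ac_total = 1
    an_male = int(round(an_total * cfg.male_fraction))
    an_female = an_total - an_male
    ac_male = int(rng.hypergeometric(an_male, an_female, ac_total))
    per_sex = {
        "male": (ac_male, an_male),
        "female": (ac_total - ac_male, an_female),
    }
    return PopulationCounts(
        ac_total=ac_total,
        an_total=an_total,
        per_ancestry=per_ancestry,
        per_sex=per_sex,
    )


def _conserved_scores(rng: np.random.Generator) -> tuple[float, float]:
    return float(rng.uniform(2.5, 6.0)), float(rng.uniform(1.5, 8.0))


def _nonconserved_scores(rng: np.random.Generator) -> tuple[float, float]:
    # one model dissents, so agreement fails whichever the other says
    return float(rng.uniform(-3.0, 1.4)), float(rng.uniform(-2.0, 0.5))


def _sparse_clinvar(rng: np.random.Generator, cfg: GeneratorConfig) -> ClinVarSignificance:
    """Non-escalating ClinVar label (never P/LP)."""
    if rng.random() >= cfg.clinvar_label_rate:
        return ClinVarSignificance.NONE
    return rng.choice(  # type: ignore[return-value]
        np.array(
            [
                ClinVarSignificance.VUS,
                ClinVarSignificance.LB,
                ClinVarSignificance.B,
                ClinVarSignificance.CONFLICTING,
            ],
            dtype=object,
        ),
        p=[0.45, 0.25, 0.20, 0.10],
    )


def _sample_residue_outside(
    rng: np.random.Generator,
    protein_len: int,
    regions: Sequence[tuple[int, int]],
    margin: int = 2,
) -> int:
    """A residue at least ``margin`` residues away from every region."""
    for _ in range(1000):
        pos = int(rng.integers(1, protein_len + 1))
        if all(not (lo - margin <= pos <= hi + margin) for lo, hi in regions):
            return pos
    raise RuntimeError("could not place residue outside hotspot regions")


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a seeded gnomAD-like cohort with known ground truth.

    Reproducible: the same config (including seed) yields an identical
    cohort. The planted manual classification is consistent by
    construction — annotations are generated strictly inside the
    decision band of the intended class, missense records outside the
    planted hotspot regions never invoke PM1, and hotspot-branch
    records are themselves the seeds that the hotspot caller recovers.
    """
    rng = np.random.default_rng(config.seed)
    ancestry_an = config.ancestry_an()
    an_total = sum(ancestry_an.values())

    classes = list(config.consequence_mix)
    class_p = np.array([config.consequence_mix[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()
    branches = list(config.missense_branches)
    branch_p = np.array([config.missense_branches[b] for b in branches], dtype=float)
    branch_p = branch_p / branch_p.sum()

    records: list[CohortRecord] = []
    truth = GroundTruth(
        true_af=[],
        planted_class=[],
        hotspot_member=[],
        hotspot_regions={
            g: [HotspotRegion(g, lo, hi) for lo, hi in regions]
            for g, regions in config.hotspot_regions.items()
        },
    )

    for gene in GENES:
        count = int(config.gene_counts.get(gene, 0))
        if count == 0:
            continue
        chrom, start, span, protein_len = GENE_INFO[gene]
        regions = [tuple(r) for r in config.hotspot_regions.get(gene, ())]
        positions = rng.choice(span, size=count, replace=False) + start
        drawn = rng.choice(len(classes), size=count, p=class_p)
        for pos, class_idx in zip(positions, drawn):
            cls = classes[class_idx]
            term = _CLASS_TERM[cls]
            ref, alt = _snv(rng)
            protein_pos: int | None = None
            hgvs_p = ""
            gerp, phylop = (
                _conserved_scores(rng)
                if rng.random() < 0.5
                else _nonconserved_scores(rng)
            )
            cadd: float | None = float(rng.uniform(0.5, 19.5))
            revel: float | None = None
            clinvar = _sparse_clinvar(rng, config)
            pm1 = False
            literature = False
            ncrna = False
            hotspot_member = False

            if cls is ConsequenceClass.MISSENSE:
                branch = branches[rng.choice(len(branches), p=branch_p)]
                if branch == "hotspot" and regions:
                    lo, hi = regions[rng.integers(len(regions))]
                    protein_pos = int(rng.integers(lo, hi + 1))
                    pm1 = True
                    gerp, phylop = _conserved_scores(rng)
                    hotspot_member = True
                    planted = Classification.P
                else:
                    protein_pos = _sample_residue_outside(rng, protein_len, regions)
                    if branch == "literature" or (branch == "hotspot" and not regions):
                        literature = True
                        planted = Classification.P
                    elif branch == "clinvar_plp":
                        clinvar = (
                            ClinVarSignificance.P
                            if rng.random() < 0.5
                            else ClinVarSignificance.LP
                        )
                        planted = Classification.P
                    elif branch == "high_score":
                        if rng.random() < 0.5:
                            cadd = float(rng.uniform(30 + CADD_MARGIN, 45.0))
                            revel = float(rng.uniform(0.05, 0.5 - REVEL_MARGIN))
                        else:
                            cadd = float(rng.uniform(0.5, 20 - CADD_MARGIN))
                            revel = float(rng.uniform(0.75 + REVEL_MARGIN, 0.99))
                        planted = Classification.LP
                    elif branch == "intermediate":
                        cadd = float(
                            rng.uniform(20 + CADD_MARGIN, 30 - CADD_MARGIN)
                        )
                        revel = float(
                            rng.uniform(0.5 + REVEL_MARGIN, 0.75 - REVEL_MARGIN)
                        )
                        planted = Classification.VUS
                    else:  # benign
                        cadd = float(rng.uniform(0.5, 20 - CADD_MARGIN))
                        revel = float(rng.uniform(0.02, 0.5 - REVEL_MARGIN))
                        planted = Classification.LB
                hgvs_p = f"p.Ala{protein_pos}Thr"
            elif cls in (
                ConsequenceClass.LOF_FRAMESHIFT,
                ConsequenceClass.LOF_NONSENSE,
            ):
                protein_pos = int(rng.integers(1, protein_len + 1))
                if cls is ConsequenceClass.LOF_FRAMESHIFT:
                    ref, alt = ref + "AT", ref
                    hgvs_p = f"p.Leu{protein_pos}fs"
                else:
                    hgvs_p = f"p.Arg{protein_pos}Ter"
                cadd = float(rng.uniform(30.5, 45.0))
                planted = Classification.P
            elif cls is ConsequenceClass.CANONICAL_SPLICE:
                planted = Classification.P
            elif cls in (ConsequenceClass.STOP_LOST, ConsequenceClass.INFRAME_INDEL):
                protein_pos = int(rng.integers(1, protein_len + 1))
                if cls is ConsequenceClass.INFRAME_INDEL:
                    ref, alt = ref + "AGC", ref
                    hgvs_p = f"p.Ser{protein_pos}del"
                else:
                    hgvs_p = f"p.Ter{protein_pos}Leuext"
                # sub-high scores (or none) keep the call uncertain
                cadd = (
                    float(rng.uniform(5.0, 30 - CADD_MARGIN))
                    if rng.random() < 0.5
                    else None
                )
                planted = Classification.VUS
            elif cls is ConsequenceClass.UTR:
                ncrna = rng.random() < config.ncrna_rate
                planted = Classification.VUS if ncrna else Classification.LB
            else:  # SYNONYMOUS, INTRONIC, NON_CANONICAL_SPLICE
                planted = Classification.LB

            true_af = _draw_true_af(rng, config, an_total)
            popcounts = _draw_popcounts(rng, config, ancestry_an, true_af)
            variant = VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                gene=gene,
                transcript=f"{gene}_tx",
                hgvs_c=f"c.{int(pos) - start + 1}{ref}>{alt}",
                hgvs_p=hgvs_p,
                protein_pos=protein_pos,
                consequence=term,
            )
            annotations = AnnotationBundle(
                cadd_phred=cadd,
                revel=revel,
                gerp=gerp,
                phylop=phylop,
                clinvar=clinvar,
                pm1_invoked=pm1,
                literature_reported=literature,
                ncrna_designated=ncrna,
            )
            records.append(CohortRecord(variant, annotations, popcounts))
            truth.true_af.append(true_af)
            truth.planted_class.append(planted)
            truth.hotspot_member.append(hotspot_member)

    cohort = Cohort(
        records=records,
        n_individuals={g: config.n_individuals for g in GENES},
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Marginal-table reconstruction
# ---------------------------------------------------------------------------


class InfeasibleTargetError(ValueError):
    """A requested (consequence, classification) pair cannot occur."""


class MarginalTarget(NamedTuple):
    gene: str
    consequence: ConsequenceClass
    classification: Classification
    count: int


def _recipe(
    cls: ConsequenceClass, target: Classification
) -> dict[str, object]:
    """Annotation settings that force ``classify_manual`` to ``target``."""
    M, C = ConsequenceClass, Classification
    if cls in (M.LOF_FRAMESHIFT, M.LOF_NONSENSE, M.CANONICAL_SPLICE):
        if target is C.P:
            return {}
    elif cls is M.MISSENSE:
        if target is C.P:
            return {"literature_reported": True}
        if target is C.LP:
            return {"cadd_phred": 35.0}
        if target is C.VUS:
            return {"cadd_phred": 25.0}
        if target is C.LB:
            return {"cadd_phred": 10.0, "revel": 0.1}
    elif cls in (M.STOP_LOST, M.INFRAME_INDEL):
        if target is C.VUS:
            return {}
        if target is C.LP:
            return {"cadd_phred": 35.0}
    elif cls is M.UTR:
        if target is C.LB:
            return {}
        if target is C.VUS:
            return {"ncrna_designated": True}
    elif cls in (M.SYNONYMOUS, M.INTRONIC, M.NON_CANONICAL_SPLICE):
        if target is C.LB:
            return {}
    raise InfeasibleTargetError(
        f"{cls.name} cannot be classified {target.name} by the manual scheme"
    )


def plp_marginal_targets(
    p_per_gene: Mapping[str, int],
    lp_per_gene: Mapping[str, int] | None = None,
) -> list[MarginalTarget]:
    """Convenience targets: per-gene P (missense, literature-driven)
    and optional per-gene LP (missense, score-driven) counts."""
    targets = [
        MarginalTarget(g, ConsequenceClass.MISSENSE, Classification.P, n)
        for g, n in p_per_gene.items()
    ]
    for g, n in (lp_per_gene or {}).items():
        targets.append(
            MarginalTarget(g, ConsequenceClass.MISSENSE, Classification.LP, n)
        )
    return targets


def generate_from_marginals(
    targets: Sequence[MarginalTarget],
    n_individuals: int = 74_025,
) -> Cohort:
    """Deterministically build a cohort hitting requested marginals.

    Each target row contributes ``count`` singleton variants (AC = 1)
    whose annotations force the manual classifier to the requested
    class; running ``classify_cohort_manual`` on the output reproduces
    the marginals exactly. Raises :class:`InfeasibleTargetError` for
    impossible combinations (e.g. a pathogenic synonymous variant).
    """
    records: list[CohortRecord] = []
    offsets: dict[str, int] = {}
    for tgt in targets:
        if tgt.count < 0:
            raise InfeasibleTargetError("negative target count")
        if tgt.gene not in GENE_INFO:
            raise InfeasibleTargetError(f"unknown gene {tgt.gene!r}")
        ann_kwargs = _recipe(tgt.consequence, tgt.classification)
        chrom, start, _, protein_len = GENE_INFO[tgt.gene]
        term = _CLASS_TERM[tgt.consequence]
        for _ in range(tgt.count):
            i = offsets[tgt.gene] = offsets.get(tgt.gene, 0) + 1
            protein_altering = tgt.consequence in (
                ConsequenceClass.MISSENSE,
                ConsequenceClass.LOF_FRAMESHIFT,
                ConsequenceClass.LOF_NONSENSE,
                ConsequenceClass.STOP_LOST,
                ConsequenceClass.INFRAME_INDEL,
            )
            protein_pos = 1 + (i - 1) % protein_len if protein_altering else None
            ref, alt = ("AT", "A") if tgt.consequence in (
                ConsequenceClass.LOF_FRAMESHIFT,
            ) else (("AGCT", "A") if tgt.consequence is ConsequenceClass.INFRAME_INDEL
                    else ("A", "G"))
            variant = VariantRecord(
                chrom=chrom,
                pos=start + i,
                ref=ref,
                alt=alt,
                gene=tgt.gene,
                transcript=f"{tgt.gene}_tx",
                hgvs_c=f"c.{i}A>G",
                hgvs_p=f"p.Ala{protein_pos}Thr" if protein_pos else "",
                protein_pos=protein_pos,
                consequence=term,
            )
            annotations = AnnotationBundle(**ann_kwargs)  # type: ignore[arg-type]
            popcounts = PopulationCounts(ac_total=1, an_total=2 * n_individuals)
            records.append(CohortRecord(variant, annotations, popcounts))
    return Cohort(
        records=records,
        n_individuals={g: n_individuals for g in GENES},
    )
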