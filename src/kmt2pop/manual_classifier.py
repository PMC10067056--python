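"""Manual rule-based variant interpretation and missense hotspot calling.

The manual scheme assigns one of four ordered categories — likely benign
(LB) < uncertain significance (VUS) < likely pathogenic (LP) <
pathogenic (P) — from the variant's consequence class, curation flags
and in-silico scores:

* loss-of-function (frameshift, nonsense, canonical splice) -> P;
* missense in a mutational hotspot, reported in the literature, or with
  a ClinVar P/LP assertion -> P;
* other missense with CADD phred >= 30 or REVEL >= 0.75 -> LP; with
  CADD in [20, 30) or REVEL in [0.5, 0.75) -> VUS; otherwise LB;
* UTR variants designated ncRNA -> VUS, otherwise LB;
* stop-lost and in-frame indels -> VUS unless scores move them;
* synonymous, intronic and non-canonical splice -> LB.

Hotspots are protein-coordinate intervals seeded by missense variants
that both invoke the ACMG PM1 criterion and fall in a mammalian
conserved region (GERP and PhyloP in agreement).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from kmt2pop.variant_model import (
    AnnotationBundle,
    ClinVarSignificance,
    Cohort,
    ConsequenceClass,
    LOF_CLASSES,
    VariantRecord,
)

__all__ = [
    "Classification",
    "HotspotRegion",
    "ManualCall",
    "ManualThresholds",
    "ManualCohortResult",
    "is_conserved",
    "call_hotspots",
    "classify_manual",
    "classify_cohort_manual",
    "write_hotspot_bed",
    "read_hotspot_bed",
]

_CLINVAR_PLP = {ClinVarSignificance.P, ClinVarSignificance.LP}


class Classification(enum.IntEnum):
    """Four-level interpretation category, ordered LB < VUS < LP < P."""

    LB = 0
    VUS = 1
    LP = 2
    P = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True, order=True)
class HotspotRegion:
    """A closed interval of protein residues treated as a hotspot."""

    gene: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa or self.start_aa < 1:
            raise ValueError(
                f"invalid hotspot interval [{self.start_aa}, {self.end_aa}]"
            )

    def contains(self, protein_pos: int) -> bool:
        return self.start_aa <= protein_pos <= self.end_aa


@dataclass(frozen=True)
class ManualCall:
    """A classification plus the label of the decision branch taken."""

    classification: Classification
    rule_fired: str


@dataclass(frozen=True)
class ManualThresholds:
    """Tunable cutoffs of the manual scheme.

    ``cadd_high``/``revel_high`` bound the likely-pathogenic branch,
    ``cadd_intermediate``/``revel_intermediate`` the uncertain band;
    thresholds are closed on the pathogenic side (CADD 30.0 is high,
    29.99 intermediate). ``gerp_min``/``phylop_min`` define mammalian
    conservation (both models must agree). ``merge_window`` is the
    maximum residue gap between hotspot seeds merged into one region
    (0 = residue-exact).
    """

    cadd_high: float = 30.0
    cadd_intermediate: float = 20.0
    revel_high: float = 0.75
    revel_intermediate: float = 0.5
    gerp_min: float = 2.0
    phylop_min: float = 1.0
    merge_window: int = 0


DEFAULT_THRESHOLDS = ManualThresholds()


def is_conserved(
    gerp: float | None,
    phylop: float | None,
    thresholds: ManualThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff BOTH conservation scores are present and meet their cutoffs.

    Agreement of the two models is required; a missing score can never
    count as conserved.
    """
    return (
        gerp is not None
        and phylop is not None
        and gerp >= thresholds.gerp_min
        and phylop >= thresholds.phylop_min
    )


def _merge_seeds(seeds: Iterable[int], window: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for pos in sorted(set(seeds)):
        if out and pos - out[-1][1] <= window:
            out[-1] = (out[-1][0], pos)
        else:
            out.append((pos, pos))
    return out


def call_hotspots(
    cohort: Cohort,
    thresholds: ManualThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, list[HotspotRegion]]:
    """Identify missense mutational hotspot regions per gene.

    A residue seeds a hotspot iff at least one missense record at that
    residue has PM1 invoked AND sits in a mammalian conserved region
    (GERP and PhyloP agreement). Seeds within ``merge_window`` residues
    of each other are merged into one region. Missense records lacking
    a protein position are skipped with a warning.

    Deterministic given the cohort and thresholds.
    """
    seeds: dict[str, set[int]] = {}
    for variant, ann, _ in cohort:
        if variant.consequence_class is not ConsequenceClass.MISSENSE:
            continue
        if not (ann.pm1_invoked and is_conserved(ann.gerp, ann.phylop, thresholds)):
            continue
        if variant.protein_pos is None:
            warnings.warn(
                f"{variant.variant_id}: missense hotspot candidate without "
                "protein position; skipped",
                stacklevel=2,
            )
            continue
        seeds.setdefault(variant.gene, set()).add(variant.protein_pos)
    return {
        gene: [
            HotspotRegion(gene, start, end)
            for start, end in _merge_seeds(positions, thresholds.merge_window)
        ]
        for gene, positions in sorted(seeds.items())
    }


def in_hotspot(
    variant: VariantRecord, hotspots: Mapping[str, Sequence[HotspotRegion]]
) -> bool:
    """True iff the variant's protein position falls in a hotspot of its gene."""
    if variant.protein_pos is None:
        return False
    return any(
        region.contains(variant.protein_pos)
        for region in hotspots.get(variant.gene, ())
    )


def _score_branch(
    ann: AnnotationBundle, t: ManualThresholds, prefix: str = ""
) -> ManualCall:
    """Shared CADD/REVEL branch: high -> LP, intermediate -> VUS, else LB."""
    cadd, revel = ann.cadd_phred, ann.revel
    if cadd is not None and cadd >= t.cadd_high:
        return ManualCall(Classification.LP, prefix + "CADD_HIGH")
    if revel is not None and revel >= t.revel_high:
        return ManualCall(Classification.LP, prefix + "REVEL_HIGH")
    if (cadd is not None and t.cadd_intermediate <= cadd < t.cadd_high) or (
        revel is not None and t.revel_intermediate <= revel < t.revel_high
    ):
        return ManualCall(Classification.VUS, prefix + "INTERMEDIATE")
    return ManualCall(Classification.LB, prefix + "DEFAULT_LB")


def classify_manual(
    variant: VariantRecord,
    annotations: AnnotationBundle,
    hotspots: Mapping[str, Sequence[HotspotRegion]] | None = None,
    thresholds: ManualThresholds = DEFAULT_THRESHOLDS,
) -> ManualCall:
    """Classify one variant under the manual scheme.

    ``hotspots`` are the per-gene regions from :func:`call_hotspots`
    (or curated regions read from BED). Every consequence class reaches
    a terminal branch; the first matching branch wins and is recorded
    in ``rule_fired``.
    """
    hotspots = hotspots or {}
    cls = variant.consequence_class

    if cls in LOF_CLASSES:
        return ManualCall(Classification.P, "LOF")

    if cls is ConsequenceClass.MISSENSE:
        if in_hotspot(variant, hotspots):
            return ManualCall(Classification.P, "HOTSPOT")
        if annotations.literature_reported:
            return ManualCall(Classification.P, "LITERATURE")
        if annotations.clinvar in _CLINVAR_PLP:
            return ManualCall(Classification.P, "CLINVAR_PLP")
        return _score_branch(annotations, thresholds)

    if cls is ConsequenceClass.UTR:
        if annotations.ncrna_designated:
            return ManualCall(Classification.VUS, "NCRNA_VUS")
        return ManualCall(Classification.LB, "UTR_LB")

    if cls in (ConsequenceClass.STOP_LOST, ConsequenceClass.INFRAME_INDEL):
        if annotations.clinvar in _CLINVAR_PLP:
            return ManualCall(Classification.VUS, "INDEL_CLINVAR_VUS")
        if annotations.cadd_phred is not None or annotations.revel is not None:
            call = _score_branch(annotations, thresholds, prefix="INDEL_")
            if call.rule_fired == "INDEL_DEFAULT_LB":
                # scores present but unremarkable still leaves the
                # functional impact of a protein-length change uncertain
                return ManualCall(Classification.VUS, "INDEL_DEFAULT_VUS")
            return call
        return ManualCall(Classification.VUS, "INDEL_DEFAULT_VUS")

    # SYNONYMOUS, INTRONIC, NON_CANONICAL_SPLICE
    return ManualCall(Classification.LB, "BENIGN_CLASS_LB")


@dataclass
class ManualCohortResult:
    """Per-record calls plus count tables for a whole cohort."""

    calls: list[ManualCall]
    hotspots: dict[str, list[HotspotRegion]]
    #: gene x classification counts (rows: genes, cols: LB/VUS/LP/P).
    by_gene: pd.DataFrame
    #: consequence class x classification counts.
    by_consequence: pd.DataFrame

    @property
    def classifications(self) -> list[Classification]:
        return [c.classification for c in self.calls]


def classify_cohort_manual(
    cohort: Cohort,
    thresholds: ManualThresholds = DEFAULT_THRESHOLDS,
    hotspots: Mapping[str, Sequence[HotspotRegion]] | None = None,
) -> ManualCohortResult:
    """Run hotspot calling then the manual classifier over a cohort.

    Hotspots are computed from the cohort itself unless curated regions
    are supplied. Count tables sum to the cohort size.
    """
    if hotspots is None:
        hotspots = call_hotspots(cohort, thresholds)
    else:
        hotspots = {g: list(v) for g, v in hotspots.items()}
    calls = [
        classify_manual(variant, ann, hotspots, thresholds)
        for variant, ann, _ in cohort
    ]
    genes = [rec.variant.gene for rec in cohort]
    classes = [rec.variant.consequence_class.name for rec in cohort]
    labels = [c.classification.name for c in calls]
    order = [c.name for c in Classification]
    by_gene = (
        pd.crosstab(pd.Series(genes, name="gene"), pd.Series(labels, name="call"))
        .reindex(columns=order, fill_value=0)
        .astype(int)
    )
    by_consequence = (
        pd.crosstab(
            pd.Series(classes, name="consequence_class"),
            pd.Series(labels, name="call"),
        )
        .reindex(columns=order, fill_value=0)
        .astype(int)
    )
    return ManualCohortResult(
        calls=calls,
        hotspots=dict(hotspots),
        by_gene=by_gene,
        by_consequence=by_consequence,
    )


# ---------------------------------------------------------------------------
# Hotspot BED import/export (protein-space, 0-based half-open)
# ---------------------------------------------------------------------------

_BED_HEADER = "# coordinates=protein-space 0-based half-open"


def write_hotspot_bed(
    hotspots: Mapping[str, Sequence[HotspotRegion]], path
) -> None:
    """Write hotspot regions as BED (protein-space flag in the header)."""
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for gene in sorted(hotspots):
            for region in sorted(hotspots[gene]):
                fh.write(f"{gene}\t{region.start_aa - 1}\t{region.end_aa}\n")


def read_hotspot_bed(path) -> dict[str, list[HotspotRegion]]:
    """Read curated hotspot regions from the BED dialect written above."""
    out: dict[str, list[HotspotRegion]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, start, end = line.split("\t")[:3]
            out.setdefault(gene, []).append(
                HotspotRegion(gene, int(start) + 1, int(end))
            )
    for gene in out:
        out[gene].sort()
    return out
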