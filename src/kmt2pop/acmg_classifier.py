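"""Simplified ACMG/AMP evidence assignment and combining engine.

Evidence codes are assigned from the variant's annotations by explicit,
configurable rules (PVS1 for loss of function, PM1 for hotspot
location, PM2 for rarity, PP3/BP4 from in-silico scores, PP5/BP6 from
ClinVar, BA1/BS1 from allele frequency, PM4 for protein-length changes,
BP7 for unremarkable synonymous variants). PS2 and PM6 (de novo
evidence) are excluded throughout: population databases carry no
parental samples. Strong-level and several supporting codes (PS1, PS3,
PS4, PM5, PP2) require external curation and are accepted only as
user-supplied input.

Codes are combined by the published ACMG/AMP rules into a fine call
(P, LP, VUS with weak-pathogenic / weak-benign shades, LB, B,
CONFLICTING), then collapsed to the four-category scale shared with the
manual classifier: B and LB fold into LB; every uncertain or
conflicting call folds into VUS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from kmt2pop.manual_classifier import (
    Classification,
    HotspotRegion,
    in_hotspot,
)
from kmt2pop.variant_model import (
    AnnotationBundle,
    ClinVarSignificance,
    Cohort,
    ConsequenceClass,
    LOF_CLASSES,
    PopulationCounts,
    VariantRecord,
)

__all__ = [
    "ALLOWED_CODES",
    "EXCLUDED_CODES",
    "ACMGConfig",
    "ACMGEvidence",
    "FineCall",
    "ACMGCohortResult",
    "assign_criteria",
    "combine_criteria",
    "collapse_categories",
    "classify_cohort_acmg",
]

#: Criterion codes the engine accepts (PS2/PM6 deliberately absent).
ALLOWED_CODES: frozenset[str] = frozenset(
    {
        "PVS1",
        "PS1", "PS3", "PS4",
        "PM1", "PM2", "PM4", "PM5",
        "PP2", "PP3", "PP5",
        "BA1", "BS1", "BS2",
        "BP4", "BP6", "BP7",
    }
)

#: De novo codes, never assignable from population data.
EXCLUDED_CODES: frozenset[str] = frozenset({"PS2", "PM6"})

_PVS = frozenset({"PVS1"})
_PS = frozenset({"PS1", "PS3", "PS4"})
_PM = frozenset({"PM1", "PM2", "PM4", "PM5"})
_PP = frozenset({"PP2", "PP3", "PP5"})
_BS = frozenset({"BS1", "BS2"})
_BP = frozenset({"BP4", "BP6", "BP7"})
_PATHOGENIC_SIDE = _PVS | _PS | _PM | _PP
_BENIGN_SIDE = frozenset({"BA1"}) | _BS | _BP

#: Codes a user may supply through curation input.
CURATED_CODES: frozenset[str] = frozenset(
    {"PS1", "PS3", "PS4", "PM5", "PP2", "BS2"}
)


class FineCall(enum.Enum):
    """Five-tier call with the uncertain band shaded by leaning."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    VUS_WEAK_P = "VUS_WEAK_P"
    VUS_WEAK_B = "VUS_WEAK_B"
    LB = "LB"
    B = "B"
    CONFLICTING = "CONFLICTING"


@dataclass(frozen=True)
class ACMGEvidence:
    """The set of invoked codes plus per-code provenance notes."""

    invoked: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.invoked) & EXCLUDED_CODES
        if bad:
            raise ValueError(
                f"de novo criteria cannot be invoked here: {sorted(bad)}"
            )
        unknown = set(self.invoked) - ALLOWED_CODES
        if unknown:
            raise ValueError(f"unknown criterion code(s): {sorted(unknown)}")


@dataclass(frozen=True)
class ACMGConfig:
    """Cutoffs and toggles for automatic criterion assignment.

    ``pm2_cutoff`` is the overall allele frequency below which a variant
    counts as absent/rare (PM2); ``bs1_cutoff`` the frequency above
    which it is too common for the disorder (BS1); ``ba1_cutoff`` the
    stand-alone benign frequency (BA1). Score cutoffs mirror the manual
    scheme's bands. ``disabled`` removes codes from automatic
    assignment entirely.
    """

    pm2_cutoff: float = 1e-4
    bs1_cutoff: float = 1e-2
    ba1_cutoff: float = 0.05
    cadd_high: float = 30.0
    revel_high: float = 0.75
    cadd_benign: float = 20.0
    revel_benign: float = 0.5
    disabled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.pm2_cutoff < self.bs1_cutoff < self.ba1_cutoff:
            raise ValueError("expected pm2_cutoff < bs1_cutoff < ba1_cutoff")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ACMGConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "disabled" in raw:
            raw["disabled"] = frozenset(raw["disabled"])
        return cls(**raw)


DEFAULT_ACMG_CONFIG = ACMGConfig()

_CLINVAR_PLP = {ClinVarSignificance.P, ClinVarSignificance.LP}
_CLINVAR_BLB = {ClinVarSignificance.B, ClinVarSignificance.LB}


def assign_criteria(
    variant: VariantRecord,
    annotations: AnnotationBundle,
    popcounts: PopulationCounts,
    hotspots: Mapping[str, Sequence[HotspotRegion]] | None = None,
    config: ACMGConfig = DEFAULT_ACMG_CONFIG,
    curated: Iterable[str] = (),
) -> ACMGEvidence:
    """Assign evidence codes to one variant.

    ``curated`` may carry externally asserted codes (restricted to
    :data:`CURATED_CODES`); PS2/PM6 are rejected.
    """
    if popcounts.an_total <= 0:
        raise ValueError(f"{variant.variant_id}: allele number is zero")
    af = popcounts.af
    cls = variant.consequence_class
    cadd, revel = annotations.cadd_phred, annotations.revel

    invoked: dict[str, str] = {}

    def hit(code: str, why: str) -> None:
        if code not in config.disabled:
            invoked[code] = why

    if cls in LOF_CLASSES:
        hit("PVS1", f"loss-of-function consequence ({cls.name})")
    if hotspots and in_hotspot(variant, hotspots):
        hit("PM1", f"residue {variant.protein_pos} in mutational hotspot")
    if af < config.pm2_cutoff:
        hit("PM2", f"AF={af:.3g} < {config.pm2_cutoff:g}")
    if cls in (ConsequenceClass.INFRAME_INDEL, ConsequenceClass.STOP_LOST):
        hit("PM4", f"protein-length change ({cls.name})")
    if (cadd is not None and cadd >= config.cadd_high) or (
        revel is not None and revel >= config.revel_high
    ):
        hit("PP3", f"CADD={cadd}, REVEL={revel} at/above damaging cutoff")
    if annotations.clinvar in _CLINVAR_PLP:
        hit("PP5", f"ClinVar {annotations.clinvar.value}")

    benign_scores = (
        cadd is not None
        and revel is not None
        and cadd < config.cadd_benign
        and revel < config.revel_benign
    )
    if af > config.ba1_cutoff:
        hit("BA1", f"AF={af:.3g} > {config.ba1_cutoff:g}")
    elif af > config.bs1_cutoff:
        hit("BS1", f"AF={af:.3g} > {config.bs1_cutoff:g}")
    if benign_scores:
        hit("BP4", f"CADD={cadd}, REVEL={revel} below benign cutoffs")
    if annotations.clinvar in _CLINVAR_BLB:
        hit("BP6", f"ClinVar {annotations.clinvar.value}")
    if cls is ConsequenceClass.SYNONYMOUS and benign_scores:
        hit("BP7", "synonymous with benign in-silico profile")

    for code in curated:
        if code in EXCLUDED_CODES:
            raise ValueError(f"curated code {code} is excluded (de novo)")
        if code not in CURATED_CODES:
            raise ValueError(f"code {code} cannot be supplied via curation")
        invoked[code] = "user-supplied curation"

    return ACMGEvidence(invoked=frozenset(invoked), provenance=dict(invoked))


def combine_criteria(evidence: ACMGEvidence) -> FineCall:
    """Combine invoked codes into a fine call by the ACMG/AMP rules.

    Pathogenic and benign rule sets are evaluated independently; if
    both sides fire the result is CONFLICTING. When neither fires, the
    uncertain band is shaded by whichever side has any evidence at all
    (weak-pathogenic / weak-benign), matching commercial auto-
    classifier output categories.
    """
    codes = evidence.invoked
    pvs = len(codes & _PVS)
    ps = len(codes & _PS)
    pm = len(codes & _PM)
    pp = len(codes & _PP)
    ba1 = "BA1" in codes
    bs = len(codes & _BS)
    bp = len(codes & _BP)

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1)))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return FineCall.CONFLICTING
    if pathogenic:
        return FineCall.P
    if likely_pathogenic:
        return FineCall.LP
    if benign:
        return FineCall.B
    if likely_benign:
        return FineCall.LB

    has_path = bool(codes & _PATHOGENIC_SIDE)
    has_benign = bool(codes & _BENIGN_SIDE)
    if has_path and not has_benign:
        return FineCall.VUS_WEAK_P
    if has_benign and not has_path:
        return FineCall.VUS_WEAK_B
    return FineCall.VUS


_COLLAPSE: dict[FineCall, Classification] = {
    FineCall.B: Classification.LB,
    FineCall.LB: Classification.LB,
    FineCall.VUS: Classification.VUS,
    FineCall.VUS_WEAK_P: Classification.VUS,
    FineCall.VUS_WEAK_B: Classification.VUS,
    FineCall.CONFLICTING: Classification.VUS,
    FineCall.LP: Classification.LP,
    FineCall.P: Classification.P,
}


def collapse_categories(fine: FineCall | Classification) -> Classification:
    """Collapse a fine call onto the shared four-category scale.

    Benign and likely benign fold into LB; every uncertain shade and
    conflicting call folds into VUS. Idempotent: a Classification maps
    to itself.
    """
    if isinstance(fine, Classification):
        return fine
    return _COLLAPSE[fine]


@dataclass
class ACMGCohortResult:
    """Per-record evidence, fine and collapsed calls, plus count tables."""

    evidence: list[ACMGEvidence]
    fine_calls: list[FineCall]
    classifications: list[Classification]
    by_gene: pd.DataFrame

    def audit_frame(self, cohort: Cohort) -> pd.DataFrame:
        """Per-variant evidence provenance, one row per invoked code."""
        rows = []
        for rec, ev, fine, coll in zip(
            cohort, self.evidence, self.fine_calls, self.classifications
        ):
            for code in sorted(ev.invoked):
                rows.append(
                    {
                        "variant_id": rec.variant.variant_id,
                        "gene": rec.variant.gene,
                        "code": code,
                        "provenance": ev.provenance.get(code, ""),
                        "fine_call": fine.value,
                        "classification": coll.name,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "variant_id", "gene", "code", "provenance",
                "fine_call", "classification",
            ],
        )


def classify_cohort_acmg(
    cohort: Cohort,
    config: ACMGConfig = DEFAULT_ACMG_CONFIG,
    hotspots: Mapping[str, Sequence[HotspotRegion]] | None = None,
    curated: Mapping[str, Iterable[str]] | None = None,
) -> ACMGCohortResult:
    """Assign, combine and collapse over a whole cohort.

    ``curated`` maps variant_id -> externally asserted codes. Hotspots
    should be the same regions the manual classifier used, so the two
    methods are compared on identical inputs.
    """
    curated = curated or {}
    evidence: list[ACMGEvidence] = []
    fine: list[FineCall] = []
    collapsed: list[Classification] = []
    for variant, ann, pop in cohort:
        ev = assign_criteria(
            variant,
            ann,
            pop,
            hotspots=hotspots,
            config=config,
            curated=curated.get(variant.variant_id, ()),
        )
        fc = combine_criteria(ev)
        evidence.append(ev)
        fine.append(fc)
        collapsed.append(collapse_categories(fc))
    genes = [rec.variant.gene for rec in cohort]
    order = [c.name for c in Classification]
    by_gene = (
        pd.crosstab(
            pd.Series(genes, name="gene"),
            pd.Series([c.name for c in collapsed], name="call"),
        )
        .reindex(columns=order, fill_value=0)
        .astype(int)
    )
    return ACMGCohortResult(
        evidence=evidence,
        fine_calls=fine,
        classifications=collapsed,
        by_gene=by_gene,
    )
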