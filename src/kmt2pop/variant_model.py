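"""Domain types, consequence triage, readers/writers and inclusion filters.

The in-memory unit is a :class:`Cohort`: a list of
``(VariantRecord, AnnotationBundle, PopulationCounts)`` triples plus the
per-gene number of sequenced individuals. Cohorts are read from an
annotated tab-separated variant table (one row per unique variant, the
gnomAD-browser-export shape) or from a biallelic VCF with a configurable
INFO-key mapping.

Coordinates are 1-based, fully closed, GRCh38 throughout.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "ANCESTRIES",
    "ANCESTRY_LABELS",
    "SEXES",
    "ClinVarSignificance",
    "ConsequenceClass",
    "ConsequenceMappingError",
    "CohortValidationError",
    "TableFormatError",
    "VariantRecord",
    "AnnotationBundle",
    "PopulationCounts",
    "CohortRecord",
    "Cohort",
    "Exclusion",
    "consequence_class",
    "filter_included",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
]

#: gnomAD v3 genetic-ancestry strata, in browser display order.
ANCESTRIES: tuple[str, ...] = (
    "afr", "amr", "eas", "sas", "nfe", "asj", "fin", "ami", "mid", "oth",
)

ANCESTRY_LABELS: dict[str, str] = {
    "afr": "African American",
    "amr": "Latino/Admixed American",
    "eas": "East Asian",
    "sas": "South Asian",
    "nfe": "European (non-Finnish)",
    "asj": "Ashkenazi Jewish",
    "fin": "Finnish",
    "ami": "Amish",
    "mid": "Middle Eastern",
    "oth": "Other",
}

SEXES: tuple[str, ...] = ("male", "female")

#: Size (bp) above which an indel is treated as structural and excluded.
STRUCTURAL_INDEL_BP = 50

#: Default number of sequenced individuals per gene when the input does
#: not say (gnomAD v3.1.2 non-cancer subset carries ~74k per gene).
DEFAULT_N_INDIVIDUALS = 74_025


class ConsequenceMappingError(ValueError):
    """Raised when a sequence-ontology term has no consequence class."""


class CohortValidationError(ValueError):
    """Raised when a record violates a cohort invariant (e.g. AC > AN)."""


class TableFormatError(ValueError):
    """Raised for unreadable / mis-shaped input tables and VCFs."""


class ConsequenceClass(enum.Enum):
    """Ten-way triage of sequence-ontology consequence terms."""

    LOF_FRAMESHIFT = "lof_frameshift"
    LOF_NONSENSE = "lof_nonsense"
    CANONICAL_SPLICE = "canonical_splice"
    NON_CANONICAL_SPLICE = "non_canonical_splice"
    MISSENSE = "missense"
    STOP_LOST = "stop_lost"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    INTRONIC = "intronic"


#: Classes whose variants alter the protein sequence (and may carry a
#: protein position). Canonical splice variants act through the
#: transcript, not a residue, so they carry no protein position.
PROTEIN_ALTERING: frozenset[ConsequenceClass] = frozenset(
    {
        ConsequenceClass.LOF_FRAMESHIFT,
        ConsequenceClass.LOF_NONSENSE,
        ConsequenceClass.MISSENSE,
        ConsequenceClass.STOP_LOST,
        ConsequenceClass.INFRAME_INDEL,
    }
)

#: Loss-of-function classes called pathogenic outright.
LOF_CLASSES: frozenset[ConsequenceClass] = frozenset(
    {
        ConsequenceClass.LOF_FRAMESHIFT,
        ConsequenceClass.LOF_NONSENSE,
        ConsequenceClass.CANONICAL_SPLICE,
    }
)

# Total, deterministic SO-term -> class mapping. Canonical splice means
# the 2 intronic bases flanking an exon; splice-region terms beyond that
# boundary are non-canonical.
_SO_TERM_MAP: dict[str, ConsequenceClass] = {
    "frameshift_variant": ConsequenceClass.LOF_FRAMESHIFT,
    "stop_gained": ConsequenceClass.LOF_NONSENSE,
    "splice_acceptor_variant": ConsequenceClass.CANONICAL_SPLICE,
    "splice_donor_variant": ConsequenceClass.CANONICAL_SPLICE,
    "splice_region_variant": ConsequenceClass.NON_CANONICAL_SPLICE,
    "splice_donor_region_variant": ConsequenceClass.NON_CANONICAL_SPLICE,
    "splice_donor_5th_base_variant": ConsequenceClass.NON_CANONICAL_SPLICE,
    "splice_polypyrimidine_tract_variant": ConsequenceClass.NON_CANONICAL_SPLICE,
    "missense_variant": ConsequenceClass.MISSENSE,
    "stop_lost": ConsequenceClass.STOP_LOST,
    "inframe_deletion": ConsequenceClass.INFRAME_INDEL,
    "inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "stop_retained_variant": ConsequenceClass.SYNONYMOUS,
    "start_retained_variant": ConsequenceClass.SYNONYMOUS,
    "5_prime_UTR_variant": ConsequenceClass.UTR,
    "3_prime_UTR_variant": ConsequenceClass.UTR,
    "intron_variant": ConsequenceClass.INTRONIC,
}


def consequence_class(term: str) -> ConsequenceClass:
    """Map a sequence-ontology consequence term to its triage class.

    Parameters
    ----------
    term
        A non-empty SO term such as ``"stop_gained"``.

    Raises
    ------
    ConsequenceMappingError
        If the term is empty or not in the recognised vocabulary.
    """
    if not term:
        raise ConsequenceMappingError("empty consequence term")
    try:
        return _SO_TERM_MAP[term]
    except KeyError:
        raise ConsequenceMappingError(
            f"unrecognised sequence-ontology term: {term!r}"
        ) from None


class ClinVarSignificance(enum.Enum):
    """Collapsed ClinVar clinical-significance states."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CONFLICTING = "CONFLICTING"
    NONE = "NONE"

    @classmethod
    def parse(cls, text: str | None) -> "ClinVarSignificance":
        """Parse a ClinVar significance string (long or short form)."""
        if text is None or text != text or str(text).strip() in {"", "."}:
            return cls.NONE
        key = str(text).strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "pathogenic": cls.P,
            "p": cls.P,
            "likely_pathogenic": cls.LP,
            "lp": cls.LP,
            "pathogenic/likely_pathogenic": cls.P,
            "uncertain_significance": cls.VUS,
            "vus": cls.VUS,
            "likely_benign": cls.LB,
            "lb": cls.LB,
            "benign": cls.B,
            "b": cls.B,
            "benign/likely_benign": cls.B,
            "conflicting": cls.CONFLICTING,
            "conflicting_interpretations_of_pathogenicity": cls.CONFLICTING,
            "conflicting_classifications_of_pathogenicity": cls.CONFLICTING,
            "none": cls.NONE,
            "not_provided": cls.NONE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise TableFormatError(
                f"unrecognised ClinVar significance: {text!r}"
            ) from None


@dataclass(frozen=True)
class VariantRecord:
    """One unique germline variant on a single transcript.

    ``pos`` is the 1-based GRCh38 genomic position. ``protein_pos`` is
    the 1-based amino-acid coordinate; it must be absent for classes
    that do not alter the protein (it may be absent for protein-altering
    records whose HGVS p. annotation is unavailable, as in gnomAD).
    ``multiallelic`` marks rows flagged multi-allelic / homozygous /
    hemizygous in the source export; the inclusion filter drops them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    protein_pos: int | None = None
    consequence: str = "missense_variant"
    exon_or_intron: str | None = None
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise CohortValidationError(
                f"{self.variant_id}: ref equals alt ({self.ref!r})"
            )
        if self.pos < 1:
            raise CohortValidationError(f"{self.variant_id}: pos must be >= 1")
        cls = consequence_class(self.consequence)  # raises if unmapped
        if self.protein_pos is not None and cls not in PROTEIN_ALTERING:
            raise CohortValidationError(
                f"{self.variant_id}: protein_pos given for non-protein-altering "
                f"consequence {self.consequence!r}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def consequence_class(self) -> ConsequenceClass:
        return consequence_class(self.consequence)

    @property
    def is_structural(self) -> bool:
        """True if the ref/alt length change exceeds the SV bound."""
        return abs(len(self.ref) - len(self.alt)) > STRUCTURAL_INDEL_BP


@dataclass(frozen=True)
class AnnotationBundle:
    """Pathogenicity / conservation scores and curation flags.

    Missing scores are ``None`` (never zero); classifiers treat an
    absent score as "threshold not met".
    """

    cadd_phred: float | None = None
    revel: float | None = None
    gerp: float | None = None
    phylop: float | None = None
    clinvar: ClinVarSignificance = ClinVarSignificance.NONE
    pm1_invoked: bool = False
    literature_reported: bool = False
    ncrna_designated: bool = False

    def __post_init__(self) -> None:
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise CohortValidationError(f"REVEL out of [0,1]: {self.revel}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise CohortValidationError(f"negative CADD phred: {self.cadd_phred}")


@dataclass(frozen=True)
class PopulationCounts:
    """Overall, per-ancestry and per-sex allele counts and numbers.

    ``per_ancestry`` and ``per_sex`` map stratum label to ``(ac, an)``;
    strata absent from the source are simply absent from the map. When
    all ten ancestry strata (or both sexes) are present, their allele
    counts must sum to the overall AC.
    """

    ac_total: int
    an_total: int
    per_ancestry: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    per_sex: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.an_total <= 0:
            raise CohortValidationError("an_total must be positive")
        if not 0 <= self.ac_total <= self.an_total:
            raise CohortValidationError(
                f"ac_total={self.ac_total} outside [0, an_total={self.an_total}]"
            )
        for label, (ac, an) in {**self.per_ancestry, **self.per_sex}.items():
            if an < 0 or ac < 0 or ac > an:
                raise CohortValidationError(
                    f"stratum {label!r}: ac={ac} outside [0, an={an}]"
                )
        for strata, labels, what in (
            (self.per_ancestry, ANCESTRIES, "ancestry"),
            (self.per_sex, SEXES, "sex"),
        ):
            if set(strata) >= set(labels):
                total = sum(strata[k][0] for k in labels)
                if total != self.ac_total:
                    raise CohortValidationError(
                        f"per-{what} AC sums to {total}, expected {self.ac_total}"
                    )

    @property
    def af(self) -> float:
        return self.ac_total / self.an_total

    def ancestry_af(self, label: str) -> float | None:
        if label not in self.per_ancestry:
            return None
        ac, an = self.per_ancestry[label]
        return ac / an if an else 0.0


class CohortRecord(NamedTuple):
    variant: VariantRecord
    annotations: AnnotationBundle
    popcounts: PopulationCounts


@dataclass
class Cohort:
    """A set of unique annotated variants plus per-gene cohort sizes."""

    records: list[CohortRecord]
    n_individuals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, n in self.n_individuals.items():
            if n <= 0:
                raise CohortValidationError(f"n_individuals[{gene}] must be > 0")
        for rec in self.records:
            n = self.n_individuals.get(rec.variant.gene)
            if n is not None and rec.popcounts.an_total > 2 * n:
                raise CohortValidationError(
                    f"{rec.variant.variant_id}: an_total="
                    f"{rec.popcounts.an_total} exceeds 2 x n_individuals={n}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self.records)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.variant.gene, None)
        return list(seen)

    def subset(self, keep: Iterable[bool]) -> "Cohort":
        recs = [r for r, k in zip(self.records, keep) if k]
        return Cohort(records=recs, n_individuals=dict(self.n_individuals))


@dataclass(frozen=True)
class Exclusion:
    """One filtered-out record and the reason it was dropped."""

    variant_id: str
    reason: str


def filter_included(
    cohort: Cohort, *, structural_bp: int = STRUCTURAL_INDEL_BP
) -> tuple[Cohort, list[Exclusion]]:
    """Apply the study inclusion filter.

    Drops records flagged multi-allelic (which in the source export also
    covers homozygote/hemizygote collapsed rows) and structural records
    (ref/alt length change beyond ``structural_bp``). All ten
    consequence classes are retained. Idempotent.

    Returns the filtered cohort and an exclusion log.
    """
    kept: list[CohortRecord] = []
    log: list[Exclusion] = []
    for rec in cohort.records:
        v = rec.variant
        if v.multiallelic:
            log.append(Exclusion(v.variant_id, "multiallelic"))
        elif abs(len(v.ref) - len(v.alt)) > structural_bp:
            log.append(Exclusion(v.variant_id, "structural"))
        else:
            kept.append(rec)
    return Cohort(records=kept, n_individuals=dict(cohort.n_individuals)), log


# ---------------------------------------------------------------------------
# Annotated variant table (TSV) dialect
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
    "protein_pos", "consequence", "cadd_phred", "revel", "gerp", "phylop",
    "clinvar", "pm1", "literature", "ncrna", "ac", "an",
]
_STRATUM_COLUMNS = [
    f"{k}_{a}" for a in ANCESTRIES for k in ("ac", "an")
] + [f"{k}_{s}" for s in SEXES for k in ("ac", "an")]
#: Canonical column order of the annotated variant TSV.
TABLE_COLUMNS = _BASE_COLUMNS + _STRATUM_COLUMNS
_OPTIONAL_COLUMNS = {"multiallelic"}
_MANDATORY = {"chrom", "pos", "ref", "alt", "gene", "consequence", "ac", "an"}

MISSING = "."


def _opt_float(value, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in {"", MISSING}:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


def _opt_int(value, column: str, row: int) -> int | None:
    f = _opt_float(value, column, row)
    return None if f is None else int(round(f))


def _opt_bool(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def read_variant_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    n_individuals: int | Mapping[str, int] = DEFAULT_N_INDIVIDUALS,
) -> Cohort:
    """Read an annotated variant TSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        Tab-separated table, one row per unique variant, ``"."`` for
        missing cells. Lines starting with ``#`` are comments.
    dialect
        Optional mapping from logical column names (see
        :data:`TABLE_COLUMNS`) to the file's actual header names.
    n_individuals
        Per-gene number of sequenced individuals, either one integer
        applied to every gene or a ``gene -> n`` mapping.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", na_values=[], keep_default_na=False
    )
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    missing = _MANDATORY - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )

    def cell(row, col):
        val = row.get(col)
        if val is None:
            return None
        val = str(val).strip()
        return None if val in {"", MISSING} else val

    records: list[CohortRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        variant = VariantRecord(
            chrom=cell(row, "chrom") or "",
            pos=_opt_int(cell(row, "pos"), "pos", i) or 0,
            ref=cell(row, "ref") or "",
            alt=cell(row, "alt") or "",
            gene=cell(row, "gene") or "",
            transcript=cell(row, "transcript") or "",
            hgvs_c=cell(row, "hgvs_c") or "",
            hgvs_p=cell(row, "hgvs_p") or "",
            protein_pos=_opt_int(cell(row, "protein_pos"), "protein_pos", i),
            consequence=cell(row, "consequence") or "",
            exon_or_intron=cell(row, "exon_or_intron"),
            multiallelic=_opt_bool(cell(row, "multiallelic")),
        )
        annotations = AnnotationBundle(
            cadd_phred=_opt_float(cell(row, "cadd_phred"), "cadd_phred", i),
            revel=_opt_float(cell(row, "revel"), "revel", i),
            gerp=_opt_float(cell(row, "gerp"), "gerp", i),
            phylop=_opt_float(cell(row, "phylop"), "phylop", i),
            clinvar=ClinVarSignificance.parse(cell(row, "clinvar")),
            pm1_invoked=_opt_bool(cell(row, "pm1")),
            literature_reported=_opt_bool(cell(row, "literature")),
            ncrna_designated=_opt_bool(cell(row, "ncrna")),
        )
        per_ancestry: dict[str, tuple[int, int]] = {}
        for a in ANCESTRIES:
            an = _opt_int(cell(row, f"an_{a}"), f"an_{a}", i)
            if an is None:
                continue
            ac = _opt_int(cell(row, f"ac_{a}"), f"ac_{a}", i) or 0
            per_ancestry[a] = (ac, an)
        per_sex: dict[str, tuple[int, int]] = {}
        for s in SEXES:
            an = _opt_int(cell(row, f"an_{s}"), f"an_{s}", i)
            if an is None:
                continue
            ac = _opt_int(cell(row, f"ac_{s}"), f"ac_{s}", i) or 0
            per_sex[s] = (ac, an)
        popcounts = PopulationCounts(
            ac_total=_opt_int(cell(row, "ac"), "ac", i) or 0,
            an_total=_opt_int(cell(row, "an"), "an", i) or 0,
            per_ancestry=per_ancestry,
            per_sex=per_sex,
        )
        records.append(CohortRecord(variant, annotations, popcounts))

    genes = {rec.variant.gene for rec in records}
    if isinstance(n_individuals, Mapping):
        n_map = {g: int(n_individuals.get(g, DEFAULT_N_INDIVIDUALS)) for g in genes}
    else:
        n_map = {g: int(n_individuals) for g in genes}
    return Cohort(records=records, n_individuals=n_map)


def write_variant_table(
    cohort: Cohort, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a cohort in the annotated-variant TSV dialect.

    The output round-trips through :func:`read_variant_table`.
    """
    rows = []
    for variant, ann, pop in cohort.records:
        row: dict[str, object] = {
            "chrom": variant.chrom,
            "pos": variant.pos,
            "ref": variant.ref,
            "alt": variant.alt,
            "gene": variant.gene,
            "transcript": variant.transcript or MISSING,
            "hgvs_c": variant.hgvs_c or MISSING,
            "hgvs_p": variant.hgvs_p or MISSING,
            "protein_pos": variant.protein_pos if variant.protein_pos is not None else MISSING,
            "consequence": variant.consequence,
            "cadd_phred": ann.cadd_phred if ann.cadd_phred is not None else MISSING,
            "revel": ann.revel if ann.revel is not None else MISSING,
            "gerp": ann.gerp if ann.gerp is not None else MISSING,
            "phylop": ann.phylop if ann.phylop is not None else MISSING,
            "clinvar": ann.clinvar.value,
            "pm1": int(ann.pm1_invoked),
            "literature": int(ann.literature_reported),
            "ncrna": int(ann.ncrna_designated),
            "ac": pop.ac_total,
            "an": pop.an_total,
            "multiallelic": int(variant.multiallelic),
        }
        for a in ANCESTRIES:
            if a in pop.per_ancestry:
                row[f"ac_{a}"], row[f"an_{a}"] = pop.per_ancestry[a]
            else:
                row[f"ac_{a}"] = row[f"an_{a}"] = MISSING
        for s in SEXES:
            if s in pop.per_sex:
                row[f"ac_{s}"], row[f"an_{s}"] = pop.per_sex[s]
            else:
                row[f"ac_{s}"] = row[f"an_{s}"] = MISSING
        rows.append(row)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS + ["multiallelic"])
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF reader
# ---------------------------------------------------------------------------

#: Default logical-field -> INFO-key mapping for :func:`read_vcf`.
DEFAULT_INFO_MAP: dict[str, str] = {
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "protein_pos": "PROTEIN_POS",
    "consequence": "CONSEQUENCE",
    "cadd_phred": "CADD_PHRED",
    "revel": "REVEL",
    "gerp": "GERP",
    "phylop": "PHYLOP",
    "clinvar": "CLINVAR",
    "pm1": "PM1",
    "literature": "LITERATURE",
    "ncrna": "NCRNA",
    "multiallelic": "MULTIALLELIC",
    "ac": "AC",
    "an": "AN",
}


def read_vcf(
    path: str | Path,
    info_map: Mapping[str, str] | None = None,
    n_individuals: int | Mapping[str, int] = DEFAULT_N_INDIVIDUALS,
) -> Cohort:
    """Read a biallelic VCF into a :class:`Cohort`.

    INFO keys are resolved through ``info_map`` (logical field name ->
    INFO key; see :data:`DEFAULT_INFO_MAP`). Per-ancestry and per-sex
    strata are read from ``<AC key>_<stratum>`` / ``<AN key>_<stratum>``
    (e.g. ``AC_nfe``). Sites with more than one ALT allele must be
    pre-split and are rejected with an error.
    """
    from cyvcf2 import VCF  # heavyweight import kept local

    mapping = dict(DEFAULT_INFO_MAP)
    mapping.update(info_map or {})
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")

    records: list[CohortRecord] = []
    for i, v in enumerate(VCF(str(path))):
        if len(v.ALT) != 1:
            raise TableFormatError(
                f"{path.name}: record {v.CHROM}:{v.POS} has {len(v.ALT)} ALT "
                "alleles; pre-split multi-allelic sites before reading"
            )

        def info(field: str, default=None):
            return v.INFO.get(mapping[field], default)

        for required in ("ac", "an", "gene", "consequence"):
            if v.INFO.get(mapping[required]) is None:
                raise TableFormatError(
                    f"{path.name}: record {v.CHROM}:{v.POS} lacks INFO key "
                    f"{mapping[required]!r}"
                )
        pp = info("protein_pos")
        variant = VariantRecord(
            chrom=str(v.CHROM),
            pos=int(v.POS),
            ref=v.REF,
            alt=v.ALT[0],
            gene=str(info("gene")),
            transcript=str(info("transcript") or ""),
            hgvs_c=str(info("hgvs_c") or ""),
            hgvs_p=str(info("hgvs_p") or ""),
            protein_pos=int(pp) if pp is not None else None,
            consequence=str(info("consequence")),
            multiallelic=bool(info("multiallelic", False)),
        )
        annotations = AnnotationBundle(
            cadd_phred=_opt_float(info("cadd_phred"), "cadd_phred", i),
            revel=_opt_float(info("revel"), "revel", i),
            gerp=_opt_float(info("gerp"), "gerp", i),
            phylop=_opt_float(info("phylop"), "phylop", i),
            clinvar=ClinVarSignificance.parse(info("clinvar")),
            pm1_invoked=_opt_bool(info("pm1")),
            literature_reported=_opt_bool(info("literature")),
            ncrna_designated=_opt_bool(info("ncrna")),
        )
        per_ancestry: dict[str, tuple[int, int]] = {}
        for a in ANCESTRIES:
            an = v.INFO.get(f"{mapping['an']}_{a}")
            if an is None:
                continue
            ac = v.INFO.get(f"{mapping['ac']}_{a}", 0)
            per_ancestry[a] = (int(ac), int(an))
        per_sex: dict[str, tuple[int, int]] = {}
        for s in SEXES:
            an = v.INFO.get(f"{mapping['an']}_{s}")
            if an is None:
                continue
            ac = v.INFO.get(f"{mapping['ac']}_{s}", 0)
            per_sex[s] = (int(ac), int(an))
        popcounts = PopulationCounts(
            ac_total=int(info("ac")),
            an_total=int(info("an")),
            per_ancestry=per_ancestry,
            per_sex=per_sex,
        )
        records.append(CohortRecord(variant, annotations, popcounts))

    genes = {rec.variant.gene for rec in records}
    if isinstance(n_individuals, Mapping):
        n_map = {g: int(n_individuals.get(g, DEFAULT_N_INDIVIDUALS)) for g in genes}
    else:
        n_map = {g: int(n_individuals) for g in genes}
    return Cohort(records=records, n_individuals=n_map)
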