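"""Manual decision tree, hotspot calling and their invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmt2pop.manual_classifier import (
    Classification,
    HotspotRegion,
    ManualThresholds,
    call_hotspots,
    classify_cohort_manual,
    classify_manual,
    is_conserved,
    read_hotspot_bed,
    write_hotspot_bed,
)
from kmt2pop.synthetic_gnomad import (
    MarginalTarget,
    generate_from_marginals,
    plp_marginal_targets,
)
from kmt2pop.variant_model import ClinVarSignificance, ConsequenceClass

from conftest import make_cohort, make_record

T = ManualThresholds()


@pytest.mark.parametrize(
    "gerp,phylop,expected",
    [
        (4.0, 3.0, True),        # both models agree
        (None, 5.0, False),      # agreement impossible with a missing score
        (4.0, 0.0, False),       # one model dissents
        (1.0, 5.0, False),
        (2.0, 1.0, True),        # closed thresholds
    ],
)
def test_is_conserved_requires_agreement(gerp, phylop, expected):
    assert is_conserved(gerp, phylop, T) is expected


def _hotspot_candidate(pos, protein_pos, pm1=True, conserved=True, gene="KMT2A"):
    gerp, phylop = (4.0, 3.0) if conserved else (4.0, 0.0)
    return make_record(
        gene=gene, pos=pos, protein_pos=protein_pos,
        pm1_invoked=pm1, gerp=gerp, phylop=phylop,
    )


def test_single_seed_hotspot():
    cohort = make_cohort([_hotspot_candidate(1000, 391)])
    assert call_hotspots(cohort) == {"KMT2A": [HotspotRegion("KMT2A", 391, 391)]}


def _brute_force_merge(residues, window):
    """Independent oracle: transitive closure of the within-window relation."""
    residues = sorted(set(residues))
    groups = [[r] for r in residues]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups) - 1):
            if groups[i + 1][0] - groups[i][-1] <= window:
                groups[i] = groups[i] + groups.pop(i + 1)
                changed = True
                break
    return [(g[0], g[-1]) for g in groups]


@pytest.mark.parametrize(
    "residues,window",
    [
        ({100, 103}, 5),
        ({100, 103}, 2),
        ({10, 11, 12, 30, 36, 41}, 5),
        ({7}, 0),
        ({5, 6, 7, 100}, 1),
    ],
)
def test_hotspot_merge_matches_bruteforce(residues, window):
    cohort = make_cohort(
        [_hotspot_candidate(1000 + i, r) for i, r in enumerate(sorted(residues))]
    )
    got = call_hotspots(cohort, ManualThresholds(merge_window=window))
    expected = [
        HotspotRegion("KMT2A", lo, hi)
        for lo, hi in _brute_force_merge(residues, window)
    ]
    assert got == {"KMT2A": expected}


def test_both_pm1_and_conservation_required():
    cohort = make_cohort(
        [
            _hotspot_candidate(1000, 50, pm1=False, conserved=True),
            _hotspot_candidate(2000, 60, pm1=True, conserved=False),
        ]
    )
    assert call_hotspots(cohort) == {}


def test_missense_candidate_without_protein_pos_warns_and_skips():
    from kmt2pop.variant_model import AnnotationBundle, VariantRecord

    rec = make_record().__class__(
        variant=VariantRecord(
            chrom="chr11", pos=1000, ref="A", alt="G", gene="KMT2A",
            consequence="missense_variant", protein_pos=None,
        ),
        annotations=AnnotationBundle(pm1_invoked=True, gerp=4.0, phylop=3.0),
        popcounts=make_record().popcounts,
    )
    with pytest.warns(UserWarning, match="skipped"):
        assert call_hotspots(make_cohort([rec])) == {}


def test_hotspot_bed_roundtrip(tmp_path):
    hotspots = {
        "KMT2C": [HotspotRegion("KMT2C", 344, 391)],
        "KMT2A": [HotspotRegion("KMT2A", 100, 100)],
    }
    path = tmp_path / "h.bed"
    write_hotspot_bed(hotspots, path)
    assert read_hotspot_bed(path) == hotspots


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

HOTSPOTS = {"KMT2A": [HotspotRegion("KMT2A", 100, 100)]}


@pytest.mark.parametrize(
    "kwargs,expected_class,expected_rule",
    [
        (dict(consequence="frameshift_variant", ref="AT", alt="A"),
         Classification.P, "LOF"),
        (dict(consequence="stop_gained"), Classification.P, "LOF"),
        (dict(consequence="splice_donor_variant"), Classification.P, "LOF"),
        (dict(protein_pos=100), Classification.P, "HOTSPOT"),
        (dict(protein_pos=200, literature_reported=True), Classification.P, "LITERATURE"),
        (dict(protein_pos=200, clinvar="LP"), Classification.P, "CLINVAR_PLP"),
        (dict(protein_pos=200, cadd_phred=35.0), Classification.LP, "CADD_HIGH"),
        (dict(protein_pos=200, revel=0.9), Classification.LP, "REVEL_HIGH"),
        (dict(protein_pos=200, cadd_phred=25.0, revel=0.6), Classification.VUS, "INTERMEDIATE"),
        (dict(protein_pos=200, cadd_phred=10.0, revel=0.1), Classification.LB, "DEFAULT_LB"),
        (dict(protein_pos=200), Classification.LB, "DEFAULT_LB"),
        (dict(consequence="5_prime_UTR_variant", ncrna_designated=True),
         Classification.VUS, "NCRNA_VUS"),
        (dict(consequence="5_prime_UTR_variant"), Classification.LB, "UTR_LB"),
        (dict(consequence="stop_lost"), Classification.VUS, "INDEL_DEFAULT_VUS"),
        (dict(consequence="inframe_deletion", ref="AGCT", alt="A", clinvar="P"),
         Classification.VUS, "INDEL_CLINVAR_VUS"),
        (dict(consequence="inframe_deletion", ref="AGCT", alt="A", cadd_phred=35.0),
         Classification.LP, "INDEL_CADD_HIGH"),
        (dict(consequence="synonymous_variant"), Classification.LB, "BENIGN_CLASS_LB"),
        (dict(consequence="intron_variant"), Classification.LB, "BENIGN_CLASS_LB"),
        (dict(consequence="splice_region_variant"), Classification.LB, "BENIGN_CLASS_LB"),
    ],
)
def test_classify_manual_branches(kwargs, expected_class, expected_rule):
    rec = make_record(**kwargs)
    call = classify_manual(rec.variant, rec.annotations, HOTSPOTS)
    assert call.classification is expected_class
    assert call.rule_fired == expected_rule


def test_boundary_semantics_closed_on_pathogenic_side():
    for cadd, expected in [(30.0, Classification.LP), (29.5, Classification.VUS),
                           (20.0, Classification.VUS), (19.9, Classification.LB)]:
        rec = make_record(protein_pos=200, cadd_phred=cadd)
        assert classify_manual(rec.variant, rec.annotations).classification is expected
    for revel, expected in [(0.75, Classification.LP), (0.74, Classification.VUS),
                            (0.5, Classification.VUS), (0.49, Classification.LB)]:
        rec = make_record(protein_pos=200, revel=revel)
        assert classify_manual(rec.variant, rec.annotations).classification is expected


# Independent rule-table oracle for the exhaustive grid. Written as a
# flat transcription of the interpretation schematic, evaluated in a
# different style from the implementation's branch chain.
def _oracle(cls, cadd, revel, clinvar, hotspot, literature, ncrna):
    C = Classification
    high = (cadd is not None and cadd >= 30) or (revel is not None and revel >= 0.75)
    inter = (cadd is not None and 20 <= cadd < 30) or (
        revel is not None and 0.5 <= revel < 0.75
    )
    scored = cadd is not None or revel is not None
    clinvar_plp = clinvar in (ClinVarSignificance.P, ClinVarSignificance.LP)
    table = {
        ConsequenceClass.LOF_FRAMESHIFT: C.P,
        ConsequenceClass.LOF_NONSENSE: C.P,
        ConsequenceClass.CANONICAL_SPLICE: C.P,
        ConsequenceClass.SYNONYMOUS: C.LB,
        ConsequenceClass.INTRONIC: C.LB,
        ConsequenceClass.NON_CANONICAL_SPLICE: C.LB,
        ConsequenceClass.UTR: C.VUS if ncrna else C.LB,
    }
    if cls in table:
        return table[cls]
    if cls is ConsequenceClass.MISSENSE:
        if hotspot or literature or clinvar_plp:
            return C.P
        return C.LP if high else (C.VUS if inter else C.LB)
    # stop-lost / in-frame indel
    if clinvar_plp or not scored:
        return C.VUS
    return C.LP if high else C.VUS


def _grid():
    cadds = [None, 10.0, 20.0, 29.9, 30.0, 35.0]
    revels = [None, 0.1, 0.5, 0.74, 0.75, 0.9]
    return itertools.product(
        ConsequenceClass,
        cadds,
        revels,
        ClinVarSignificance,
        [False, True],  # hotspot
        [False, True],  # literature
        [False, True],  # ncrna
    )


def test_decision_tree_matches_grid_oracle():
    """Exhaustive grid agreement with an independently written rule table."""
    hotspot_regions = {"KMT2A": [HotspotRegion("KMT2A", 100, 100)]}
    protein_altering = {
        ConsequenceClass.MISSENSE: "missense_variant",
        ConsequenceClass.LOF_FRAMESHIFT: "frameshift_variant",
        ConsequenceClass.LOF_NONSENSE: "stop_gained",
        ConsequenceClass.STOP_LOST: "stop_lost",
        ConsequenceClass.INFRAME_INDEL: "inframe_deletion",
    }
    other = {
        ConsequenceClass.CANONICAL_SPLICE: "splice_donor_variant",
        ConsequenceClass.NON_CANONICAL_SPLICE: "splice_region_variant",
        ConsequenceClass.SYNONYMOUS: "synonymous_variant",
        ConsequenceClass.UTR: "5_prime_UTR_variant",
        ConsequenceClass.INTRONIC: "intron_variant",
    }
    n = 0
    for cls, cadd, revel, clinvar, hotspot, literature, ncrna in _grid():
        if cls in protein_altering:
            term = protein_altering[cls]
            protein_pos = 100 if hotspot else 200
        else:
            term = other[cls]
            protein_pos = 0  # suppressed by make_record for these terms
            if hotspot:
                continue  # hotspot membership needs a protein position
        rec = make_record(
            consequence=term,
            protein_pos=protein_pos or None,
            cadd_phred=cadd,
            revel=revel,
            clinvar=clinvar,
            literature_reported=literature,
            ncrna_designated=ncrna,
            ref="AT" if cls is ConsequenceClass.LOF_FRAMESHIFT else "A",
            alt="A" if cls is ConsequenceClass.LOF_FRAMESHIFT else "G",
        )
        got = classify_manual(rec.variant, rec.annotations, hotspot_regions)
        want = _oracle(cls, cadd, revel, clinvar, hotspot, literature, ncrna)
        assert got.classification is want, (
            cls, cadd, revel, clinvar, hotspot, literature, ncrna,
            got.classification, want,
        )
        n += 1
    assert n > 10_000  # the grid really was exhaustive


SCORE_IDX = st.integers(min_value=0, max_value=5)
_CADDS = [None, 10.0, 20.0, 29.9, 30.0, 35.0]
_REVELS = [None, 0.1, 0.5, 0.74, 0.75, 0.9]


@settings(max_examples=300, derandomize=True)
@given(
    cadd_lo=SCORE_IDX, cadd_hi=SCORE_IDX,
    revel_lo=SCORE_IDX, revel_hi=SCORE_IDX,
    literature=st.booleans(), hotspot=st.booleans(),
    clinvar_plp=st.booleans(),
)
def test_missense_monotonicity(cadd_lo, cadd_hi, revel_lo, revel_hi,
                               literature, hotspot, clinvar_plp):
    """Strengthening any evidence never lowers a missense classification."""
    if cadd_lo > cadd_hi or revel_lo > revel_hi:
        return
    def call(ci, ri, lit, hot, cv):
        rec = make_record(
            protein_pos=100 if hot else 200,
            cadd_phred=_CADDS[ci], revel=_REVELS[ri],
            literature_reported=lit,
            clinvar="P" if cv else "NONE",
        )
        return classify_manual(rec.variant, rec.annotations, HOTSPOTS).classification

    weak = call(cadd_lo, revel_lo, False, False, False)
    strong = call(cadd_hi, revel_hi, literature, hotspot, clinvar_plp)
    assert strong >= weak


def test_rule_fired_consistency(tiny_cohort):
    res = classify_cohort_manual(tiny_cohort)
    for call in res.calls:
        if call.rule_fired == "LOF":
            assert call.classification is Classification.P


# ---------------------------------------------------------------------------
# Cohort-level behaviour
# ---------------------------------------------------------------------------


def test_cohort_counts_sum_and_lof_lower_bound():
    records = [
        make_record(pos=1000 + i, consequence="frameshift_variant", ref="AT", alt="A")
        for i in range(10)
    ] + [make_record(pos=5000 + i, consequence="synonymous_variant") for i in range(90)]
    res = classify_cohort_manual(make_cohort(records))
    assert int(res.by_gene.to_numpy().sum()) == 100
    assert int(res.by_gene["P"].sum()) >= 10


def test_all_synonymous_cohort_has_no_plp():
    records = [
        make_record(pos=1000 + i, consequence="synonymous_variant") for i in range(30)
    ]
    res = classify_cohort_manual(make_cohort(records))
    assert int(res.by_gene["P"].sum()) == 0
    assert int(res.by_gene["LP"].sum()) == 0


def test_printed_per_gene_pathogenic_marginals():
    cohort = generate_from_marginals(
        plp_marginal_targets({"KMT2A": 109, "KMT2B": 119, "KMT2C": 167, "KMT2D": 139})
    )
    res = classify_cohort_manual(cohort)
    assert int(res.by_gene["P"].sum()) == 534
    assert res.by_gene["P"].to_dict() == {
        "KMT2A": 109, "KMT2B": 119, "KMT2C": 167, "KMT2D": 139,
    }


def test_determinism_identical_runs():
    targets = [
        MarginalTarget("KMT2A", ConsequenceClass.MISSENSE, Classification.P, 5),
        MarginalTarget("KMT2A", ConsequenceClass.SYNONYMOUS, Classification.LB, 5),
    ]
    cohort = generate_from_marginals(targets)
    first = classify_cohort_manual(cohort)
    second = classify_cohort_manual(cohort)
    assert first.calls == second.calls
    assert first.hotspots == second.hotspots
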