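"""Allele reconstruction from clones: variant sites, clustering, chimera
screening, parental origin and the single-allele sampling test."""

import numpy as np
import pytest
from scipy.stats import chi2

from clonephase import phasing as ph
from clonephase import synthdata as sd
from clonephase.errors import ClonephaseError, PhasingError
from clonephase.seqcore import SequenceRecord

from conftest import run_pipeline


def make_set(seqs, locus="loc", species="Pf"):
    clones = [
        SequenceRecord(f"{species}.i1.{locus}.c{k + 1:02d}", s, "nt")
        for k, s in enumerate(seqs)
    ]
    return ph.CloneSet(locus=locus, species=species, individual="i1", clones=clones)


# ---------------------------------------------------------------------------
# Variant sites


def test_variant_sites_require_min_support():
    cs = make_set(["AAAA", "AAAA", "ACAA", "ACAA", "AGAA"])
    # col 1: A x3, C x2 (supported), G x1 (error) -> variant
    assert ph.call_variant_sites(cs) == [1]
    assert ph.call_variant_sites(cs, min_support=3) == []


def test_no_variant_sites_in_identical_clones():
    cs = make_set(["ATGAAA"] * 6)
    assert ph.call_variant_sites(cs) == []


# ---------------------------------------------------------------------------
# Allele inference


def test_two_haplotypes_recovered_exactly(ar_alpha_truth):
    sets = sd.clone_sets_for_truth(ar_alpha_truth)
    call = ph.infer_alleles(sets["Pf"])
    got = {h.residues for h in call.ungapped_haplotypes()}
    expected = {a.residues for a in ar_alpha_truth.hybrid_alleles.values()}
    assert got == expected
    assert sum(call.support) == 12
    assert not call.excluded_clones


def test_single_allele_locus_yields_one_haplotype():
    truth = sd.simulate_locus(
        sd.preset_config("er_beta1", seed=2).model_copy(
            update={"base_error_rate": 0.0, "chimera_rate": 0.0}
        )
    )
    sets = sd.clone_sets_for_truth(truth)
    call = ph.infer_alleles(sets["Pf"])
    assert len(call.haplotypes) == 1
    assert call.support == [26]
    assert call.haplotypes[0].residues == truth.hybrid_alleles["Pf2"].residues


def test_clone_with_isolated_error_attaches_to_nearest_cluster():
    a, b = "AAAAAAAA", "TTTTAAAA"
    cs = make_set([a] * 5 + [b] * 5 + ["AAAAAAAC"])  # one clone, one error
    call = ph.infer_alleles(cs)
    assert sorted(call.support) == [5, 6]
    assert not call.excluded_clones


def test_shared_error_does_not_fabricate_second_allele():
    # two clones share the same miscalled base: still a single allele
    cs = make_set(["AAAAAAAA"] * 8 + ["AAAACAAA"] * 2)
    call = ph.infer_alleles(cs)
    assert len(call.haplotypes) == 1
    assert call.haplotypes[0].residues == "AAAAAAAA"


def test_far_minor_cluster_is_excluded_when_mosaic():
    a, b = "AAAACCCC", "TTTTGGGG"
    chimera = "AAAAGGGG"  # mosaic of a and b, far from both
    cs = make_set([a] * 5 + [b] * 5 + [chimera])
    call = ph.infer_alleles(cs)
    assert len(call.excluded_clones) == 1
    assert sorted(call.support) == [5, 5]


def test_third_nonmosaic_cluster_raises():
    cs = make_set(["AAAA"] * 4 + ["CCCC"] * 4 + ["GGGG"] * 3)
    with pytest.raises(PhasingError):
        ph.infer_alleles(cs)


def test_clone_assignment_covers_all_clones(ar_alpha_truth):
    sets = sd.clone_sets_for_truth(ar_alpha_truth)
    call = ph.infer_alleles(sets["Pf"])
    assert set(call.clone_assignment) == {c.id for c in sets["Pf"].clones}


# ---------------------------------------------------------------------------
# Chimera screening


def chimera_fixture():
    a = "A" * 12
    b = "T" * 12
    cs = make_set(
        [
            a,  # clean A
            b,  # clean B
            "A" * 11 + "G",  # clean A with one isolated miscall
            a[:6] + b[6:],  # chimera, two long segments
            "AT" * 6,  # alternating single sites: ambiguous
        ]
    )
    call = ph.AlleleCall(
        haplotypes=[SequenceRecord("h1", a), SequenceRecord("h2", b)],
        support=[3, 2],
        informative_sites=list(range(12)),
        excluded_clones=[],
        clone_assignment={},
    )
    return cs, call


def test_chimera_verdicts():
    cs, call = chimera_fixture()
    report = ph.detect_chimeras(cs, call)
    statuses = [v.verdict for v in report.verdicts]
    assert statuses == ["clean_A", "clean_B", "clean_A", "chimeric", "ambiguous"]
    assert report.chimeric_ids() == [cs.clones[3].id]


def test_chimera_labels_invariant_under_haplotype_swap():
    cs, call = chimera_fixture()
    swapped = ph.AlleleCall(
        haplotypes=[call.haplotypes[1], call.haplotypes[0]],
        support=call.support[::-1],
        informative_sites=call.informative_sites,
        excluded_clones=[],
        clone_assignment={},
    )
    s1 = [v.verdict for v in ph.detect_chimeras(cs, call).verdicts]
    s2 = [v.verdict for v in ph.detect_chimeras(cs, swapped).verdicts]
    relabel = {"clean_A": "clean_B", "clean_B": "clean_A"}
    assert s2 == [relabel.get(s, s) for s in s1]


def test_short_switch_segment_is_not_chimeric():
    a, b = "A" * 12, "T" * 12
    cs = make_set([a[:11] + b[11:]])  # terminal 1-site switch
    call = ph.AlleleCall(
        haplotypes=[SequenceRecord("h1", a), SequenceRecord("h2", b)],
        support=[1, 0],
        informative_sites=list(range(12)),
        excluded_clones=[],
        clone_assignment={},
    )
    report = ph.detect_chimeras(cs, call)
    assert report.verdicts[0].verdict == "clean_A"


def test_simulated_chimeras_are_flagged():
    cfg = sd.preset_config("dense", seed=5).model_copy(
        update={"base_error_rate": 0.0, "chimera_rate": 0.4}
    )
    truth = sd.simulate_locus(cfg)
    rng = np.random.default_rng(42)
    cs, labels = sd.generate_clone_reads(
        list(truth.hybrid_alleles.values()), 30, 0.0, 0.4, rng, locus="dense"
    )
    call = ph.infer_alleles(cs)
    report = ph.detect_chimeras(cs, call)
    truth_ids = set(labels[labels.source == "chimera"].clone_id)
    flagged = set(report.chimeric_ids())
    # no clean clone is ever miscalled chimeric at error rate 0
    assert flagged <= truth_ids
    # the vast majority of true chimeras are caught (breakpoints very close to
    # an end leave a sub-threshold segment and are legitimately missed)
    assert len(flagged) >= 0.8 * len(truth_ids)


def test_chimera_screen_requires_two_haplotypes():
    cs = make_set(["AAAA"] * 3)
    call = ph.infer_alleles(cs)
    with pytest.raises(ClonephaseError):
        ph.detect_chimeras(cs, call)


# ---------------------------------------------------------------------------
# Parental origin


def test_origin_assignment_matches_truth(ar_alpha_truth):
    call, origins, _ = run_pipeline(ar_alpha_truth)
    assert sorted(origins.values()) == ["Pl", "Pm"]
    by_origin = {v: k for k, v in origins.items()}
    haps = {h.id: h.ungapped().residues for h in call.haplotypes}
    assert (
        haps[by_origin["Pm"]] == ar_alpha_truth.hybrid_alleles["Pf1"].residues
    )
    assert (
        haps[by_origin["Pl"]] == ar_alpha_truth.hybrid_alleles["Pf2"].residues
    )


def test_origin_unresolved_for_identical_parents():
    hap = SequenceRecord("h", "ATGAAATAA")
    call = ph.AlleleCall([hap], [5], [], [], {})
    refs = {
        "Pm": SequenceRecord("pm", "ATGAAATAA"),
        "Pl": SequenceRecord("pl", "ATGAAATAA"),
    }
    assert ph.assign_parental_origin(call, refs) == {"h": "unresolved"}


def test_origin_requires_exactly_two_references():
    hap = SequenceRecord("h", "ATGAAATAA")
    call = ph.AlleleCall([hap], [5], [], [], {})
    with pytest.raises(ClonephaseError):
        ph.assign_parental_origin(call, {"Pm": hap})


# ---------------------------------------------------------------------------
# Single-allele sampling test


def test_single_allele_test_worked_example():
    res = ph.single_allele_test(26, (26, 0))
    assert res.chi2 == pytest.approx(26.0)
    assert res.df == 1
    assert res.p_value == pytest.approx(3.414e-07, rel=5e-4)


def test_single_allele_test_balanced_split_is_null():
    res = ph.single_allele_test(2, (1, 1))
    assert res.chi2 == 0.0 and res.p_value == 1.0


@pytest.mark.parametrize("n", [6, 12, 26])
def test_single_allele_test_matches_chi2_distribution(n):
    res = ph.single_allele_test(n, (n, 0))
    assert res.chi2 == pytest.approx(n)
    assert res.p_value == pytest.approx(float(chi2.sf(n, 1)))


def test_single_allele_test_validates_counts():
    with pytest.raises(ClonephaseError):
        ph.single_allele_test(10, (4, 5))
    with pytest.raises(ClonephaseError):
        ph.single_allele_test(0, (0, 0))
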