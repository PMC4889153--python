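"""Relative quantification, exact rank tests, reference-gene stability and
amplification efficiency."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from clonephase import expression as ex
from clonephase import synthdata as sd
from clonephase.errors import ClonephaseError


def ct_rows(species, tissue, individual, gene, cts):
    return [
        {
            "species": species,
            "tissue": tissue,
            "individual": individual,
            "gene": gene,
            "tech_replicate": k + 1,
            "ct": ct,
        }
        for k, ct in enumerate(cts)
    ]


# ---------------------------------------------------------------------------
# Replicate collapsing


def test_replicate_mean():
    t = pd.DataFrame(ct_rows("Pm", "ovary", "i1", "g", [20.0, 20.2, 20.4]))
    out = ex.collapse_technical_replicates(t)
    assert out.ct_mean.iloc[0] == pytest.approx(20.2)
    assert out.detected.iloc[0] and out.n_replicates.iloc[0] == 3


def test_all_replicates_above_ceiling_is_nondetect():
    t = pd.DataFrame(ct_rows("Pm", "ovary", "i1", "g", [36.0, 37.0, 38.0]))
    out = ex.collapse_technical_replicates(t)
    assert not out.detected.iloc[0]
    assert np.isnan(out.ct_mean.iloc[0]) and out.n_replicates.iloc[0] == 0


def test_partial_nondetect_drops_only_failing_replicate():
    t = pd.DataFrame(ct_rows("Pm", "ovary", "i1", "g", [34.0, 36.0]))
    out = ex.collapse_technical_replicates(t)
    assert out.ct_mean.iloc[0] == pytest.approx(34.0)
    assert out.n_replicates.iloc[0] == 1


def test_duplicate_replicate_rows_rejected():
    t = pd.DataFrame(ct_rows("Pm", "ovary", "i1", "g", [20.0]) * 2)
    with pytest.raises(ClonephaseError):
        ex.collapse_technical_replicates(t)


# ---------------------------------------------------------------------------
# Relative quantification


def zero_noise_table(mean_dct):
    design = sd.CtDesign.balanced(
        ["Pm", "Pf"], ["ovary"], ["geneA"],
        mean_dct=5.0, bio_sd=0.0, tech_sd=0.0,
        ref_bio_sd=0.0, ref_tech_sd=0.0,
    )
    design.group("Pf", "ovary", "geneA").mean_dct = mean_dct
    return sd.generate_ct_table(design, seed=0)


def test_calibrator_geometric_mean_rq_is_one():
    table = zero_noise_table(3.0)
    res = ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))
    cal = res[(res.species == "Pm") & (res.tissue == "ovary")]
    assert np.exp(np.log(cal.rq).mean()) == pytest.approx(1.0)


def test_planted_fold_change_is_recovered_exactly():
    # Pf's gene sits 2 cycles earlier than the calibrator's: 4-fold expression
    table = zero_noise_table(3.0)
    res = ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))
    pf = res[res.species == "Pf"]
    assert pf.rq.to_numpy() == pytest.approx(np.full(4, 4.0))


def test_nondetected_gene_keeps_rows_with_nan_rq():
    design = sd.CtDesign(
        groups=[
            sd.CtGroupSpec("Pm", "ovary", "geneA", 5.0, 0.0, 0.0),
            sd.CtGroupSpec("Pf", "ovary", "geneA", 5.0, 0.0, 0.0, detected=False),
        ],
        ref_bio_sd=0.0,
        ref_tech_sd=0.0,
    )
    table = sd.generate_ct_table(design, seed=3)
    res = ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))
    pf = res[res.species == "Pf"]
    assert (~pf.detected).all() and pf.rq.isna().all()
    assert len(pf) == 4  # reported as not expressed, never silently dropped


def test_missing_reference_sample_warns_and_excludes():
    rows = []
    for ind in ("i1", "i2", "i3"):
        ref_ct = [20.0] if ind != "i3" else [40.0]  # i3's reference fails
        rows += ct_rows("Pm", "ovary", ind, "rpl7", ref_ct)
        rows += ct_rows("Pm", "ovary", ind, "geneA", [25.0])
    table = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="reference"):
        res = ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))
    assert set(res.individual) == {"i1", "i2"}


def test_empty_calibrator_group_raises():
    table = pd.DataFrame(
        ct_rows("Pf", "ovary", "i1", "rpl7", [20.0])
        + ct_rows("Pf", "ovary", "i1", "geneA", [25.0])
    )
    with pytest.raises(ClonephaseError):
        ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum


def test_wilcoxon_fully_separated_groups():
    assert ex.wilcoxon_exact([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)


def test_wilcoxon_symmetry():
    a, b = [1.2, 3.4, 2.2], [0.5, 4.4, 9.1, 2.0]
    assert ex.wilcoxon_exact(a, b) == pytest.approx(ex.wilcoxon_exact(b, a))


@pytest.mark.parametrize(
    "a,b",
    [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 9, 3, 7], [2, 8, 4]),
        ([0.1, 0.5], [0.3, 0.2, 0.9, 1.4]),
        ([5, 1, 4, 2], [3, 6, 8, 7]),
    ],
)
def test_wilcoxon_matches_reference_exact_test(a, b):
    # tie-free data: the enumeration must agree with the reference
    # Mann-Whitney exact two-sided p-value
    expected = mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
    assert ex.wilcoxon_exact(a, b) == pytest.approx(float(expected))


def test_wilcoxon_handles_ties_with_midranks():
    p = ex.wilcoxon_exact([1.0, 1.0, 2.0], [2.0, 3.0])
    assert 0.0 < p <= 1.0


def test_wilcoxon_rejects_empty_group():
    with pytest.raises(ClonephaseError):
        ex.wilcoxon_exact([], [1.0])


@pytest.mark.parametrize(
    "p,expected", [(0.06, ""), (0.05, "*"), (0.02, "*"), (0.01, "*"), (0.009, "**")]
)
def test_star_annotation(p, expected):
    assert ex.stars(p) == expected


def test_compare_species_pairwise_structure():
    table = zero_noise_table(3.0)
    res = ex.delta_delta_ct(table, "rpl7", ("Pm", "ovary"))
    comp = ex.compare_species(res)
    assert len(comp) == 1  # one gene, one tissue, one species pair
    row = comp.iloc[0]
    assert {row.species_1, row.species_2} == {"Pm", "Pf"}
    assert row.p_value == pytest.approx(2 / 70)  # fully separated, 4 vs 4
    assert row.stars == "*"
    assert "p_bh" in comp.columns


# ---------------------------------------------------------------------------
# Reference-gene stability


def stability_table(noisy_gene=None, biased_gene=None, seed=0):
    genes = ["g1", "g2", "g3"]
    design = sd.CtDesign.balanced(
        ["Pm", "Pf"], ["ovary"], genes,
        mean_dct=5.0, bio_sd=0.05, tech_sd=0.0,
        ref_bio_sd=0.0, ref_tech_sd=0.0, n_individuals=6,
    )
    if noisy_gene:
        for spec in design.groups:
            if spec.gene == noisy_gene:
                spec.bio_sd = 1.5
    if biased_gene:
        design.group("Pf", "ovary", biased_gene).mean_dct = 8.0
    return sd.generate_ct_table(design, seed=seed)


def test_genorm_ranks_noisy_gene_least_stable():
    table = stability_table(noisy_gene="g2")
    res = ex.genorm_stability(table, ["g1", "g2", "g3"])
    assert res.ranking[-1] == "g2"
    assert set(res.pairwise_variation) == {"V2/3"}
    assert res.method == "geNorm"


def test_genorm_requires_three_genes():
    with pytest.raises(ClonephaseError):
        ex.genorm_stability(stability_table(), ["g1", "g2"])


def test_bestkeeper_ranks_by_raw_sd():
    table = stability_table(noisy_gene="g3")
    res = ex.bestkeeper_stability(table, ["g1", "g2", "g3"])
    assert res.ranking[-1] == "g3"
    tab = res.table.set_index("gene")
    assert tab.loc["g3", "bestkeeper_sd"] > tab.loc["g1", "bestkeeper_sd"]


def test_bestkeeper_constant_gene_has_undefined_r():
    table = stability_table()
    # make g1 perfectly constant
    table.loc[table.gene == "g1", "ct"] = 25.0
    res = ex.bestkeeper_stability(table, ["g1", "g2", "g3"])
    row = res.table.set_index("gene").loc["g1"]
    assert row.bestkeeper_sd == 0.0 and not row.r_defined
    assert res.ranking[0] == "g1"


def test_normfinder_flags_group_biased_gene():
    table = stability_table(biased_gene="g1")
    res = ex.normfinder_stability(table, ["g1", "g2", "g3"])
    assert res.ranking[-1] == "g1"


def test_normfinder_invariant_to_per_sample_shifts():
    table = stability_table(biased_gene="g1", seed=4)
    res1 = ex.normfinder_stability(table, ["g1", "g2", "g3"])
    shifted = table.copy()
    # a per-sample shift models loading differences; stability must not change
    rng = np.random.default_rng(7)
    for ind, delta in zip(
        shifted.individual.unique(), rng.normal(0, 2, shifted.individual.nunique())
    ):
        shifted.loc[shifted.individual == ind, "ct"] += delta
    res2 = ex.normfinder_stability(shifted, ["g1", "g2", "g3"])
    v1 = res1.table.set_index("gene").normfinder_stability
    v2 = res2.table.set_index("gene").normfinder_stability
    assert np.allclose(v1, v2)


def test_normfinder_single_group_warns():
    genes = ["g1", "g2"]
    design = sd.CtDesign.balanced(["Pm"], ["ovary"], genes, bio_sd=0.1)
    table = sd.generate_ct_table(design, seed=1)
    with pytest.warns(UserWarning, match="single group"):
        ex.normfinder_stability(table, genes)


# ---------------------------------------------------------------------------
# Amplification efficiency


def test_perfect_doubling_efficiency():
    slope = -1.0 / np.log10(2.0)  # -3.3219: one cycle per doubling
    pts = [(x, 30.0 + slope * x) for x in (0.0, -1.0, -2.0, -3.0)]
    res = ex.efficiency_from_dilution(pts)
    assert res.efficiency == pytest.approx(1.0)
    assert res.within_band and res.r_squared == pytest.approx(1.0)


def test_low_efficiency_flagged():
    pts = [(x, 30.0 - 3.6 * x) for x in (0.0, 1.0, 2.0)]
    res = ex.efficiency_from_dilution(pts)
    assert res.efficiency == pytest.approx(0.8957, abs=1e-3)
    assert not res.within_band


def test_efficiency_validates_input():
    with pytest.raises(ClonephaseError):
        ex.efficiency_from_dilution([(0, 30), (1, 28)])
    with pytest.raises(ClonephaseError):
        ex.efficiency_from_dilution([(0, 30), (1, 31), (2, 32)])
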