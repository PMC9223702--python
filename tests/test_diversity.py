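"""Rank profiles, Shannon-Wiener diversity, set analysis, proportion tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcsoil.diversity import (
    OTHER,
    abundance_difference,
    core_and_unique,
    genus_sets,
    relative_abundance,
    rankwise_diversity,
    shannon_wiener,
    threshold_filter,
    two_sample_proportion_test,
)
from tcsoil.lineage import parse_lineage
from tcsoil.tables import TaxonTable


def _table(rows, samples):
    """rows: list of (taxon_id, lineage string, counts per sample)."""
    counts = pd.DataFrame(
        {s: [r[2][i] for r in rows] for i, s in enumerate(samples)},
        index=[r[0] for r in rows],
    )
    return TaxonTable(counts, [parse_lineage(r[1]) for r in rows])


TWO_PHYLA = _table(
    [
        ("t1", "k__B; p__Proteobacteria; c__; o__; f__; g__Kaistobacter", [10, 25]),
        ("t2", "k__B; p__Proteobacteria; c__; o__; f__; g__Rhodoplanes", [30, 25]),
        ("t3", "k__B; p__Actinobacteria; c__; o__; f__; g__Streptomyces", [60, 50]),
    ],
    ["s1", "s2"],
)


def test_relative_abundance_percentages():
    profs = {p.sample_id: p for p in relative_abundance(TWO_PHYLA, "genus")}
    assert profs["s1"].proportions.tolist() == pytest.approx([10, 30, 60])
    assert profs["s1"].total == pytest.approx(100.0)


def test_relative_abundance_merges_shared_phylum():
    profs = {p.sample_id: p for p in relative_abundance(TWO_PHYLA, "phylum")}
    assert profs["s1"].proportions["Proteobacteria"] == pytest.approx(40.0)
    assert profs["s1"].proportions["Actinobacteria"] == pytest.approx(60.0)


def test_relative_abundance_single_taxon_is_100():
    t = _table([("t1", "k__B; p__P; c__; o__; f__; g__X", [7])], ["s1"])
    (prof,) = relative_abundance(t, "genus")
    assert prof.proportions.tolist() == [100.0]


def test_relative_abundance_scale_invariance():
    scaled = TaxonTable(TWO_PHYLA.counts * 13, TWO_PHYLA.lineages)
    for p1, p2 in zip(relative_abundance(TWO_PHYLA, "phylum"),
                      relative_abundance(scaled, "phylum")):
        pd.testing.assert_series_equal(p1.proportions, p2.proportions)


def test_empty_rank_buckets_to_unclassified():
    t = _table([("t1", "k__B; p__; c__; o__; f__; g__", [5]),
                ("t2", "k__B; p__P; c__; o__; f__; g__", [5])], ["s1"])
    (prof,) = relative_abundance(t, "phylum")
    assert prof.proportions["unclassified"] == pytest.approx(50.0)


def test_threshold_filter_boundary_inclusive_vs_strict():
    t = _table(
        [("t1", "k__B; p__A; c__; o__; f__; g__a", [10]),
         ("t2", "k__B; p__B; c__; o__; f__; g__b", [980]),
         ("t3", "k__B; p__C; c__; o__; f__; g__c", [10])],
        ["s1"],
    )
    (prof,) = relative_abundance(t, "genus")  # a and c at exactly 1.000 %
    inclusive = threshold_filter(prof, threshold=1.0)
    assert set(inclusive.proportions.index) == {"a", "b", "c"}
    strict = threshold_filter(prof, threshold=1.0, strict=True)
    assert set(strict.proportions.index) == {"b", OTHER}
    assert strict.proportions[OTHER] == pytest.approx(2.0)
    assert strict.total == pytest.approx(prof.total)


def test_threshold_filter_rejects_out_of_range():
    prof = relative_abundance(TWO_PHYLA, "phylum")[0]
    for bad in (0.0, 100.0, -1.0):
        with pytest.raises(ValueError):
            threshold_filter(prof, threshold=bad)


@pytest.mark.parametrize("weights,expected", [
    ([1.0], 0.0),
    ([0.25] * 4, math.log(4)),
    ([0.5, 0.25, 0.25], 1.040),
])
def test_shannon_frozen_examples(weights, expected):
    assert shannon_wiener(weights) == pytest.approx(expected, abs=5e-4)


def test_shannon_matches_skbio_on_random_counts(rng):
    skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
    for _ in range(20):
        counts = rng.integers(0, 200, size=12)
        if counts.sum() == 0:
            continue
        assert shannon_wiener(counts) == pytest.approx(
            float(skbio_alpha.shannon(counts, base=math.e)))


def test_shannon_empty_profile_is_nan():
    assert math.isnan(shannon_wiener([0.0, 0.0]))


def test_rankwise_nested_uniform():
    """2 phyla x 2 genera each, equal counts: ln 2 at phylum, ln 4 at genus."""
    t = _table(
        [("t1", "k__B; p__P1; c__; o__; f__; g__g1", [25]),
         ("t2", "k__B; p__P1; c__; o__; f__; g__g2", [25]),
         ("t3", "k__B; p__P2; c__; o__; f__; g__g3", [25]),
         ("t4", "k__B; p__P2; c__; o__; f__; g__g4", [25])],
        ["s1"],
    )
    h = rankwise_diversity(t)
    assert h.loc["s1", "phylum"] == pytest.approx(math.log(2))
    assert h.loc["s1", "genus"] == pytest.approx(math.log(4))


def test_rankwise_single_genus_is_zero_everywhere():
    t = _table([("t1", "k__B; p__P; c__C; o__O; f__F; g__G", [99])], ["s1"])
    assert (rankwise_diversity(t).loc["s1"] == 0.0).all()


def test_rankwise_diversity_nondecreasing_down_ranks(rng):
    """On fully specified nested lineages, refining the partition
    (phylum -> class -> ... -> genus) cannot lower the entropy.

    Note this refinement inequality needs every rank filled in: an empty
    field buckets the taxon into a shared "unclassified" group, which merges
    rather than refines the partition.
    """
    rows = []
    g = 0
    for i in range(3):          # phyla
        for j in range(2):      # classes per phylum
            for k in range(2):  # orders per class, 1 family, 2 genera
                for m in range(2):
                    lin = (f"k__B; p__P{i}; c__C{i}{j}; o__O{i}{j}{k}; "
                           f"f__F{i}{j}{k}; g__G{g}")
                    rows.append((f"t{g}", lin,
                                 [int(rng.integers(1, 500)) for _ in range(3)]))
                    g += 1
    table = _table(rows, ["s1", "s2", "s3"])
    h = rankwise_diversity(table)
    for coarse, fine in (("phylum", "class"), ("class", "order"),
                         ("order", "family"), ("family", "genus")):
        assert (h[fine] >= h[coarse] - 1e-12).all()


def test_core_and_unique_identical_sets():
    rep = core_and_unique({"A": {"x", "y"}, "B": {"x", "y"}})
    assert rep.core == {"x", "y"}
    assert all(not u for u in rep.unique.values())


def test_core_and_unique_disjoint_sets():
    rep = core_and_unique({"A": {"x"}, "B": {"y"}})
    assert rep.core == frozenset()
    assert rep.unique == {"A": {"x"}, "B": {"y"}}


def test_core_and_unique_empty_input_rejected():
    with pytest.raises(ValueError):
        core_and_unique({})


def test_core_fixture_mirrors_sown_soil_structure():
    """Deterministic fixture: exactly 3 genera pass 1 % in all four sown
    variants; Ralstonia passes only in ZmTc and is unique to it."""
    genera = {
        "Kaistobacter": ("Proteobacteria", [1500, 1500, 1500, 1500]),
        "Cellulosimicrobium": ("Actinobacteria", [1200, 1200, 1200, 1200]),
        "Rhodoplanes": ("Proteobacteria", [800, 800, 800, 800]),
        "Ralstonia": ("Proteobacteria", [10, 300, 10, 10]),
        "Nocardioides": ("Actinobacteria", [600, 10, 10, 10]),
    }
    samples = ["Zm", "ZmTc", "ZmG", "ZmTcG"]
    rows = [(g, f"k__Bacteria; p__{ph}; c__; o__; f__; g__{g}", counts)
            for g, (ph, counts) in genera.items()]
    # bulk reads with no genus assignment; must never enter the genus sets
    rows.append(("filler", "k__Bacteria; p__Firmicutes; c__; o__; f__; g__",
                 [5890, 6190, 7280, 7280]))
    t = _table(rows, samples)
    sets = genus_sets(t, {s: s for s in samples}, threshold=1.0)
    rep = core_and_unique(sets)
    assert rep.core == {"Kaistobacter", "Cellulosimicrobium", "Rhodoplanes"}
    assert "Ralstonia" in rep.unique["ZmTc"]
    assert "Nocardioides" in rep.unique["Zm"]
    # report invariants
    for s in rep.variant_sets.values():
        assert rep.core <= s
    uniq = list(rep.unique.values())
    for i in range(len(uniq)):
        assert not (uniq[i] & rep.core)
        for j in range(i + 1, len(uniq)):
            assert not (uniq[i] & uniq[j])


def test_set_report_invariants_on_random_inputs(rng):
    universe = [f"g{i}" for i in range(12)]
    for _ in range(25):
        sets = {f"v{k}": {g for g in universe if rng.random() < 0.4}
                for k in range(4)}
        rep = core_and_unique(sets)
        assert all(rep.core <= s for s in rep.variant_sets.values())
        keys = list(rep.unique)
        for i, ki in enumerate(keys):
            assert not (rep.unique[ki] & rep.core) or not rep.core
            assert rep.unique[ki] <= rep.variant_sets[ki]
            for kj in keys[i + 1:]:
                assert not (rep.unique[ki] & rep.unique[kj])


def test_abundance_difference_examples():
    p = relative_abundance(TWO_PHYLA, "phylum")
    profs = {x.sample_id: x for x in p}
    delta = abundance_difference(profs["s1"], profs["s1"])
    assert (delta == 0).all()
    delta = abundance_difference(profs["s1"], profs["s2"])
    assert delta.sum() == pytest.approx(0.0, abs=1e-9)  # complete profiles


def test_abundance_difference_missing_taxa_and_rank_guard():
    a = relative_abundance(TWO_PHYLA, "phylum")[0]
    g = relative_abundance(TWO_PHYLA, "genus")[0]
    with pytest.raises(ValueError, match="rank mismatch"):
        abundance_difference(a, g)
    other = type(a)("sX", "phylum", pd.Series({"Proteobacteria": 100.0}))
    delta = abundance_difference(a, other)
    assert delta["Actinobacteria"] == pytest.approx(60.0)  # absent -> 0


def test_proportion_test_identical_proportions():
    r = two_sample_proportion_test(5, 10, 5, 10)
    assert r.g_yates == pytest.approx(0.0, abs=1e-12)
    assert r.p_fisher == pytest.approx(1.0)


def test_proportion_test_fisher_frozen_example():
    # all-vs-none split of 5/5: two-sided p = 2/C(10,5) = 2/252
    r = two_sample_proportion_test(5, 5, 0, 5)
    assert r.p_fisher == pytest.approx(2 / 252, rel=1e-6)


def test_proportion_test_swap_symmetry():
    a = two_sample_proportion_test(7, 20, 3, 15)
    b = two_sample_proportion_test(3, 15, 7, 20)
    assert a.p_fisher == pytest.approx(b.p_fisher)
    assert a.p_g == pytest.approx(b.p_g)
    assert a.diff == pytest.approx(-b.diff)
    assert a.diff_ci_95[0] == pytest.approx(-b.diff_ci_95[1], abs=1e-9)
    assert a.diff_ci_95[1] == pytest.approx(-b.diff_ci_95[0], abs=1e-9)


def test_proportion_test_degenerate_margin():
    r = two_sample_proportion_test(0, 10, 0, 8)  # success column all zero
    assert math.isnan(r.g_yates)
    assert r.p_fisher == pytest.approx(1.0)


def test_yates_g_matches_scipy_log_likelihood(rng):
    from scipy.stats import chi2_contingency

    for _ in range(50):
        n1, n2 = rng.integers(5, 40, size=2)
        a, b = rng.integers(1, n1), rng.integers(1, n2)
        table = np.array([[a, n1 - a], [b, n2 - b]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        r = two_sample_proportion_test(a, n1, b, n2)
        ref = chi2_contingency(table, correction=True, lambda_="log-likelihood")
        assert r.g_yates == pytest.approx(float(ref.statistic), abs=1e-9)
        assert r.p_g == pytest.approx(float(ref.pvalue), abs=1e-9)


@given(st.integers(1, 25), st.integers(1, 25), st.data())
@settings(max_examples=100, deadline=None)
def test_proportion_test_inputs_validated(n1, n2, data):
    a = data.draw(st.integers(0, n1))
    b = data.draw(st.integers(0, n2))
    r = two_sample_proportion_test(a, n1, b, n2)
    assert 0 <= r.p_fisher <= 1
    assert r.diff_ci_95[0] <= r.diff <= r.diff_ci_95[1] + 1e-12
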