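import itertools
import math

import numpy as np
import pytest

from haplerode.diversity import (
    diversity_table,
    haplotype_diversity,
    heterozygosity,
    nucleotide_diversity,
    rarefied_allelic_richness,
)
from haplerode.haplotypes import collapse_haplotypes, segregating_sites
from haplerode.seqio import Alignment, GenotypeTable, ValidatedDataset

from .conftest import make_alignment, make_records


@pytest.mark.parametrize(
    "counts,expected",
    [((3, 2), 0.60), ((2, 1), 0.67), ((5,), 0.0), ((1,) * 8, 1.0)],
)
def test_haplotype_diversity_printed_values(counts, expected):
    """The unbiased estimator reproduces the published per-country values
    (two haplotypes at 3:2 -> 0.60, 2:1 -> 0.67, monomorphic -> 0, all
    distinct among eight -> 1)."""
    assert round(haplotype_diversity(counts), 2) == expected


def test_haplotype_diversity_needs_two_samples():
    with pytest.raises(ValueError):
        haplotype_diversity([1])


def test_unbiased_h_dominates_biased_form():
    rng = np.random.default_rng(3)
    for _ in range(50):
        counts = rng.integers(1, 10, size=rng.integers(1, 6))
        if counts.sum() < 2:
            continue
        p = counts / counts.sum()
        biased = 1 - np.sum(p**2)
        assert haplotype_diversity(list(counts)) >= biased - 1e-12


@pytest.mark.parametrize(
    "sizes,diffs,expected",
    [((3, 2), 4, 2.40), ((2, 1), 3, 2.00)],
)
def test_nucleotide_diversity_printed_values(sizes, diffs, expected):
    aln = make_alignment(list(sizes), n_diffs=diffs)
    assert round(nucleotide_diversity(aln), 2) == expected


def test_nucleotide_diversity_monomorphic_and_relabelling():
    aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
    assert nucleotide_diversity(aln) == 0.0
    aln2 = make_alignment([2, 2], n_diffs=5, seed=8)
    renamed = Alignment([f"z{i}" for i in range(len(aln2))], list(reversed(aln2.sequences)))
    assert nucleotide_diversity(aln2) == pytest.approx(nucleotide_diversity(renamed))


def test_pi_matches_allpairs_loop_and_is_bounded_by_P():
    """pi from the formula equals an explicit all-pairs double loop with
    pairwise deletion, and never exceeds the number of polymorphic sites."""
    rng = np.random.default_rng(11)
    for n in (5, 12, 30):
        seqs = ["".join(rng.choice(list("AACGTN-"), size=40)) for _ in range(n)]
        aln = Alignment([f"s{i}" for i in range(n)], seqs)
        total = 0
        for i, j in itertools.combinations(range(n), 2):
            a, b = aln.sequences[i], aln.sequences[j]
            total += sum(
                1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT" and x != y
            )
        expected = total / math.comb(n, 2)
        assert nucleotide_diversity(aln) == pytest.approx(expected)
        assert nucleotide_diversity(aln) <= segregating_sites(aln)


def geno(rows, loci=("L1",)):
    ids = [f"i{k}" for k in range(len(rows))]
    calls = np.array(rows, dtype=np.int64).reshape(len(rows), len(loci), 2)
    return GenotypeTable(ids, list(loci), calls)


def test_heterozygosity_closed_forms():
    # all homozygous for one allele
    table, multi = heterozygosity(geno([[7, 7], [7, 7]]))
    assert multi["H_E"] == 0.0 and multi["H_O"] == 0.0
    # a single A/B individual: H_O = 1, unbiased H_E = (2/1)(1 - 0.5) = 1
    _t, multi = heterozygosity(geno([[10, 12]]))
    assert multi["H_O"] == 1.0 and multi["H_E"] == pytest.approx(1.0)
    # two individuals AA and BB: H_O = 0, H_E = (4/3)(1 - 0.5) = 2/3
    _t, multi = heterozygosity(geno([[10, 10], [12, 12]]))
    assert multi["H_O"] == 0.0 and multi["H_E"] == pytest.approx(2 / 3)


def test_heterozygosity_excludes_empty_locus():
    gt = geno([[10, 12, 0, 0], [11, 12, 0, 0]], loci=("L1", "L2"))
    table, multi = heterozygosity(gt)
    assert multi["loci"] == 1
    assert np.isnan(table.set_index("locus").loc["L2", "H_E"])


def test_rarefaction_trivial_and_closed_form():
    # g=1 always gives exactly one allele in expectation
    _t, mean, _g = rarefied_allelic_richness(geno([[10, 12], [11, 11]]), g=1)
    assert mean == pytest.approx(1.0)
    # monomorphic locus: 1.0 at any valid g
    _t, mean, _g = rarefied_allelic_richness(geno([[9, 9], [9, 9]]), g=3)
    assert mean == pytest.approx(1.0)
    # allele counts (2,2), g=2: exhaustive expectation is 5/3
    _t, mean, _g = rarefied_allelic_richness(geno([[10, 10], [12, 12]]), g=2)
    assert mean == pytest.approx(5 / 3)


def test_rarefaction_matches_exhaustive_enumeration():
    """A_g equals the average allele count over all C(N, g) subsamples."""
    rng = np.random.default_rng(23)
    for _ in range(6):
        n_ind = int(rng.integers(2, 5))  # N = 2 * n_ind <= 8 gene copies
        rows = rng.choice([10, 11, 12, 13], size=(n_ind, 2))
        gt = geno([list(r) for r in rows])
        copies = list(rows.ravel())
        for g in range(1, len(copies) + 1):
            expected = np.mean([
                len(set(sub)) for sub in itertools.combinations(copies, g)
            ])
            _t, mean, _g = rarefied_allelic_richness(gt, g=g)
            assert mean == pytest.approx(expected)


def test_rarefaction_monotone_and_exact_at_full_depth():
    gt = geno([[10, 11], [12, 10], [13, 13]])
    values = [rarefied_allelic_richness(gt, g=g)[1] for g in range(1, 7)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(4)  # observed allele count at g = N


def test_rarefaction_g_too_large_names_locus():
    with pytest.raises(ValueError, match="L1"):
        rarefied_allelic_richness(geno([[10, 11]]), g=5)


def test_diversity_table_scopes_and_flags():
    """A purely historic group has identical total/historic rows and an
    empty extant row; singleton groups are flagged with undefined h."""
    aln = make_alignment([3, 2], n_diffs=4)
    recs = make_records(aln, pop="Chad", country="Chad")
    ds = ValidatedDataset(records=recs, alignment=aln)
    tab = diversity_table(ds, grouping="country").set_index(["group", "era_scope"])
    total = tab.loc[("Chad", "total")]
    hist = tab.loc[("Chad", "historic")]
    assert total["n"] == hist["n"] == 5
    assert round(total["h"], 2) == round(hist["h"], 2) == 0.60
    assert tab.loc[("Chad", "extant"), "n"] == 0

    recs[aln.ids[0]].country = "Lone"
    ds2 = ValidatedDataset(records=recs, alignment=aln)
    tab2 = diversity_table(ds2, grouping="country").set_index(["group", "era_scope"])
    lone = tab2.loc[("Lone", "total")]
    assert bool(lone["flagged_small"]) and np.isnan(lone["h"])


def test_diversity_table_reconciles_with_inventory(scenario_dataset):
    tab = diversity_table(scenario_dataset, grouping="local_population")
    inv = collapse_haplotypes(scenario_dataset.alignment,
                              records=scenario_dataset.records)
    species = tab[(tab.group == "Species-wide") & (tab.era_scope == "total")].iloc[0]
    assert species["n"] == inv.total_samples()
    assert species["nhaps"] == len(inv.haplotype_ids)
    per_pop = tab[(tab.group != "Species-wide") & (tab.era_scope == "total")]
    assert per_pop["n"].sum() == sum(
        inv.sample_count(p) for p in inv.populations
    )
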