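import itertools

import pytest

from haplerode.erosion import (
    build_extinction_report,
    classify_population,
    partition_loss,
    trace_persistence,
)
from haplerode.haplotypes import HaplotypeInventory, collapse_haplotypes
from haplerode.seqio import SampleRecord


def inventory(cells):
    """Build an inventory from {hap: {(pop, era): count}}."""
    return HaplotypeInventory(
        representative={h: "A" * 10 for h in cells},
        counts={h: dict(c) for h, c in cells.items()},
        assignments={},
    )


def test_classifier_spec_cases():
    """The four canonical outcomes: shared survival -> locally extinct,
    private loss -> genetically extinct, total loss -> globally extinct,
    modern samples -> extant regardless of losses."""
    # extirpated pop whose two haplotypes both persist in an extant stock
    inv = inventory({
        "h1": {("Gone", "historic"): 2, ("Alive", "extant"): 3},
        "h2": {("Gone", "historic"): 1, ("Alive", "extant"): 1},
    })
    assert classify_population("Gone", inv) == "locally_extinct"

    # private h3 lost, shared h1 survives
    inv = inventory({
        "h1": {("Gone", "historic"): 1, ("Other", "historic"): 1, ("Alive", "extant"): 2},
        "h3": {("Gone", "historic"): 2},
    })
    assert classify_population("Gone", inv) == "genetically_extinct"

    # nothing survives anywhere
    inv = inventory({
        "h1": {("Gone", "historic"): 2},
        "h2": {("Alive", "extant"): 2},
    })
    assert classify_population("Gone", inv) == "globally_extinct"

    # modern samples present: extant even though it lost haplotypes
    inv = inventory({
        "h1": {("Here", "historic"): 2},
        "h2": {("Here", "extant"): 1},
    })
    assert classify_population("Here", inv) == "extant"


def test_classifier_undetermined_and_unknown():
    inv = inventory({"h1": {("Alive", "extant"): 1, ("Odd", "extant"): 0}})
    with pytest.raises(KeyError):
        classify_population("Nowhere", inv)
    # a population with no historic haplotypes and no extant samples is
    # undetermined, not silently classified
    with pytest.raises(ValueError, match="undetermined"):
        classify_population("Odd", inv)


def test_classifier_truth_table_exhaustive():
    """Over every combination of (has extant samples, shared haplotype
    survives, private haplotype survives), the classifier returns exactly
    one status and follows the severity order."""
    for has_extant, shared_survives, private_survives in itertools.product(
        [False, True], repeat=3
    ):
        cells = {
            # a shared haplotype (also historic in Other)
            "hs": {("P", "historic"): 1, ("Other", "historic"): 1},
            # a private haplotype of P
            "hp": {("P", "historic"): 1},
        }
        if shared_survives:
            cells["hs"][("Elsewhere", "extant")] = 1
        if private_survives:
            cells["hp"][("Elsewhere", "extant")] = 1
        if has_extant:
            cells["hx"] = {("P", "extant"): 1}
        inv = inventory(cells)
        status = classify_population("P", inv)
        if has_extant:
            expected = "extant"
        elif not shared_survives and not private_survives:
            expected = "globally_extinct"
        elif not private_survives:
            expected = "genetically_extinct"
        else:
            expected = "locally_extinct"
        assert status == expected, (has_extant, shared_survives, private_survives)


def test_classification_invariant_to_haplotype_relabelling():
    cells = {
        "h1": {("Gone", "historic"): 1, ("Alive", "extant"): 1},
        "h2": {("Gone", "historic"): 2},
    }
    relabelled = {"zz" + h: c for h, c in cells.items()}
    assert classify_population("Gone", inventory(cells)) == classify_population(
        "Gone", inventory(relabelled)
    )


def records_for(inv_counts, stocks):
    """Expand {hap: {(pop, era): n}} into per-sample records + assignments."""
    records, assignments = {}, {}
    k = 0
    for hap, cells in inv_counts.items():
        for (pop, era), n in cells.items():
            for _ in range(n):
                sid = f"s{k}"
                k += 1
                country, stock = stocks.get(pop, (pop + "_country", ""))
                records[sid] = SampleRecord(
                    sample_id=sid, era=era, collection_year=1900 if era == "historic" else 2000,
                    country=country, local_population=pop,
                    modern_stock=stock if era == "extant" else "",
                )
                assignments[sid] = hap
    return records, assignments


def test_persistence_flags_extralimital_carriage():
    """A haplotype historically confined to country X, carried by a modern
    stock in country Y, is flagged; carriage within X is not."""
    cells = {
        "h_moved": {("Src", "historic"): 2, ("Far", "extant"): 2},
        "h_home": {("Home", "historic"): 2, ("Home", "extant"): 2},
    }
    inv = inventory(cells)
    records, assignments = records_for(cells, {
        "Src": ("Xland", ""),
        "Far": ("Yland", "Y_stock"),
        "Home": ("Xland", "X_stock"),
    })
    inv.assignments = assignments
    res = trace_persistence(inv, records)
    assert ("h_moved", "Y_stock") in res.extralimital
    assert all(stock != "X_stock" for _h, stock in res.extralimital)
    assert res.stocks_by_haplotype["h_moved"] == {"Y_stock"}


def test_persistence_pseudo_stock_for_unlabelled_extant():
    cells = {"h1": {("P", "historic"): 1, ("P", "extant"): 1}}
    inv = inventory(cells)
    records, assignments = records_for(cells, {"P": ("Xland", "")})
    inv.assignments = assignments
    res = trace_persistence(inv, records)
    assert res.stocks_by_haplotype["h1"] == {"Xland(country)"}
    assert res.warnings


def test_partition_loss_components_sum_and_zero_case():
    cells = {
        "h1": {("G", "historic"): 2},                       # lost via global extinction
        "h2": {("G", "historic"): 1, ("E", "historic"): 1,
               ("E", "extant"): 1},                         # survives
        "h3": {("Ge", "historic"): 2},                      # private of genetically-extinct pop
        "h4": {("Ge", "historic"): 1, ("E", "historic"): 1,
               ("E", "extant"): 1},                         # survives
        "h5": {("E", "historic"): 1},                       # drift loss in surviving pop
    }
    inv = inventory(cells)
    statuses = {"G": "globally_extinct", "Ge": "genetically_extinct", "E": "extant"}
    part = partition_loss(inv, statuses)
    assert part.total == 5 and part.surviving == 2 and part.lost == 3
    assert (part.via_global_extinction, part.via_genetic_extinction, part.via_drift) == (1, 1, 1)
    assert part.via_global_extinction + part.via_genetic_extinction + part.via_drift == part.lost

    all_survive = inventory({"h1": {("E", "historic"): 1, ("E", "extant"): 1}})
    part0 = partition_loss(all_survive, {"E": "extant"})
    assert part0.lost == 0 and part0.via_drift == 0 and part0.loss_fraction == 0


def test_scenario_report_matches_truth(scenario):
    """On the simulated fixture the classifier recovers every deme's true
    status, the scripted translocation is flagged extralimitally, and the
    Fig-3-style tallies satisfy their invariants."""
    inv = collapse_haplotypes(scenario.alignment, records=scenario.records)
    report = build_extinction_report(inv, scenario.records)
    got = {p: s.status for p, s in report.statuses.items()}
    assert got == scenario.truth.statuses

    # the translocated haplotypes are flagged in the destination stock
    moved = scenario.truth.translocations[0]
    flagged_stocks = {s for _h, s in report.persistence.extralimital}
    assert moved["dest_stock"] in flagged_stocks
    assert report.statuses[moved["dest_population"]].extralimital_introduction

    for s in report.statuses.values():
        assert s.SH <= s.H and s.SPH <= s.PH
        if s.status == "globally_extinct":
            assert s.SH == 0
    assert (
        report.loss.via_global_extinction
        + report.loss.via_genetic_extinction
        + report.loss.via_drift
        == report.loss.lost
    )
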