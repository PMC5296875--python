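"""Genetic-erosion accounting: extinction categories, haplotype persistence
and partitioning of species-wide haplotype loss.

A local population with modern samples is *extant*.  An extirpated
population is classified, in severity order:

``globally_extinct``
    none of its historic haplotypes is observed in any extant sample;
``genetically_extinct``
    at least one of its *private* historic haplotypes (private among
    historic local populations) is absent from all extant samples, even
    though some shared haplotype survives;
``locally_extinct``
    every one of its historic haplotypes survives in extant populations
    elsewhere.

Persistence tracing maps each historic haplotype to the modern stocks
that carry it, flagging a stock as an *extralimital* carrier when it
holds the haplotype outside the set of countries where the haplotype was
historically sampled (translocation signature).

Loss partitioning decomposes the species-wide haplotype loss into the
share attributable to globally-extinct populations, to private
haplotypes of genetically-extinct populations, and to residual drift
within surviving populations; categories are assigned first-match-wins
in severity order so the components always sum to the total loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .haplotypes import HaplotypeInventory, private_haplotypes
from .seqio import SampleRecord

__all__ = [
    "STATUSES",
    "PopulationStatus",
    "PersistenceResult",
    "LossPartition",
    "ExtinctionReport",
    "classify_population",
    "trace_persistence",
    "partition_loss",
    "build_extinction_report",
]

STATUSES = ("extant", "locally_extinct", "genetically_extinct", "globally_extinct")


@dataclass
class PopulationStatus:
    """Per-population status plus the tally columns of the erosion report
    (n = historic samples, H = historic haplotypes, PH = private historic
    haplotypes, SH = surviving haplotypes, SPH = surviving private ones)."""

    population: str
    status: str
    n: int
    H: int
    PH: int
    SH: int
    SPH: int
    eroded: bool
    extralimital_introduction: bool = False
    undetermined: bool = False


@dataclass
class PersistenceResult:
    stocks_by_haplotype: dict[str, set[str]]
    historic_countries: dict[str, set[str]]
    historic_populations: dict[str, set[str]]
    extralimital: set[tuple[str, str]]  # (haplotype, stock)
    warnings: list[str] = field(default_factory=list)

    def extralimital_haplotypes(self) -> set[str]:
        return {h for h, _s in self.extralimital}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for h in sorted(self.stocks_by_haplotype):
            stocks = self.stocks_by_haplotype[h]
            rows.append(
                {
                    "haplotype": h,
                    "historic_populations": ";".join(sorted(self.historic_populations.get(h, ()))),
                    "extant_stocks": ";".join(sorted(stocks)),
                    "extralimital": any((h, s) in self.extralimital for s in stocks),
                }
            )
        return pd.DataFrame(
            rows, columns=["haplotype", "historic_populations", "extant_stocks", "extralimital"]
        )


@dataclass
class LossPartition:
    total: int
    surviving: int
    lost: int
    via_global_extinction: int
    via_genetic_extinction: int
    via_drift: int

    @property
    def loss_fraction(self) -> float:
        return self.lost / self.total if self.total else 0.0

    @property
    def surviving_fraction(self) -> float:
        return self.surviving / self.total if self.total else 0.0

    def fraction_of_loss(self, component: int) -> float:
        return component / self.lost if self.lost else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "total_haplotypes": self.total,
                    "surviving": self.surviving,
                    "lost": self.lost,
                    "lost_via_global_extinction": self.via_global_extinction,
                    "lost_via_genetic_extinction": self.via_genetic_extinction,
                    "lost_via_drift": self.via_drift,
                    "loss_fraction": self.loss_fraction,
                    "surviving_fraction": self.surviving_fraction,
                }
            ]
        )


@dataclass
class ExtinctionReport:
    statuses: dict[str, PopulationStatus]
    persistence: PersistenceResult
    loss: LossPartition

    def status_of(self, pop: str) -> str:
        return self.statuses[pop].status

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pop in sorted(self.statuses):
            s = self.statuses[pop]
            rows.append(
                {
                    "population": pop,
                    "status": s.status,
                    "n": s.n,
                    "H": s.H,
                    "PH": s.PH,
                    "SH": s.SH,
                    "SPH": s.SPH,
                    "eroded": s.eroded,
                    "extralimital_introduction": s.extralimital_introduction,
                    "undetermined": s.undetermined,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "population", "status", "n", "H", "PH", "SH", "SPH",
                "eroded", "extralimital_introduction", "undetermined",
            ],
        )


def classify_population(pop: str, inventory: HaplotypeInventory) -> str:
    """Classify one local population; see module docstring for the rules.

    Raises ``KeyError`` for unknown populations and ``ValueError`` when an
    extirpated population has no historic haplotypes (undetermined).
    """
    if pop not in inventory.populations:
        raise KeyError(f"unknown population {pop!r}")
    if inventory.sample_count(pop, "extant") > 0:
        return "extant"
    historic = inventory.historic_haps(pop)
    if not historic:
        raise ValueError(f"population {pop!r} has no historic haplotypes; status undetermined")
    surviving_anywhere = inventory.extant_haps()
    if not historic & surviving_anywhere:
        return "globally_extinct"
    private = private_haplotypes(inventory, pop, "historic")
    if private - surviving_anywhere:
        return "genetically_extinct"
    return "locally_extinct"


def trace_persistence(
    inventory: HaplotypeInventory, records: Mapping[str, SampleRecord]
) -> PersistenceResult:
    """Map each historic haplotype to the extant stocks carrying it and flag
    extralimital carriage (stock country outside the haplotype's historic
    country range)."""
    historic_countries: dict[str, set[str]] = {}
    historic_pops: dict[str, set[str]] = {}
    stocks: dict[str, set[str]] = {}
    stock_country: dict[str, set[str]] = {}
    warns: list[str] = []

    for sid, hap in inventory.assignments.items():
        rec = records.get(sid)
        if rec is None:
            continue
        if rec.era == "historic":
            if rec.country:
                historic_countries.setdefault(hap, set()).add(rec.country)
            if rec.local_population:
                historic_pops.setdefault(hap, set()).add(rec.local_population)
        else:
            stock = rec.modern_stock
            if not stock:
                stock = f"{rec.country or 'UNKNOWN'}(country)"
                warns.append(
                    f"extant sample {sid!r} has no modern_stock; using pseudo-stock {stock!r}"
                )
            stocks.setdefault(hap, set()).add(stock)
            if rec.country:
                stock_country.setdefault(stock, set()).add(rec.country)

    extralimital: set[tuple[str, str]] = set()
    for hap, hap_stocks in stocks.items():
        home = historic_countries.get(hap)
        if not home:
            continue  # never seen historically: no range to be outside of
        for stock in hap_stocks:
            countries = stock_country.get(stock, set())
            if countries and not countries & home:
                extralimital.add((hap, stock))

    # ensure every historic haplotype appears in the map, surviving or not
    for hap in inventory.haps_anywhere("historic"):
        stocks.setdefault(hap, set())
    return PersistenceResult(
        stocks_by_haplotype=stocks,
        historic_countries=historic_countries,
        historic_populations=historic_pops,
        extralimital=extralimital,
        warnings=warns,
    )


def partition_loss(
    inventory: HaplotypeInventory, statuses: Mapping[str, str]
) -> LossPartition:
    """Decompose the species-wide haplotype loss by extinction category."""
    total_haps = inventory.haps_anywhere("total")
    surviving = inventory.extant_haps()
    lost = total_haps - surviving

    global_pops = [p for p, s in statuses.items() if s == "globally_extinct"]
    genetic_pops = [p for p, s in statuses.items() if s == "genetically_extinct"]
    haps_of_global: set[str] = set()
    for pop in global_pops:
        haps_of_global |= inventory.historic_haps(pop)
    private_of_genetic: set[str] = set()
    for pop in genetic_pops:
        private_of_genetic |= private_haplotypes(inventory, pop, "historic")

    via_global = lost & haps_of_global
    via_genetic = (lost & private_of_genetic) - via_global
    via_drift = lost - via_global - via_genetic
    return LossPartition(
        total=len(total_haps),
        surviving=len(surviving),
        lost=len(lost),
        via_global_extinction=len(via_global),
        via_genetic_extinction=len(via_genetic),
        via_drift=len(via_drift),
    )


def build_extinction_report(
    inventory: HaplotypeInventory, records: Mapping[str, SampleRecord]
) -> ExtinctionReport:
    """Classify every labelled population and assemble the full report."""
    persistence = trace_persistence(inventory, records)
    surviving_anywhere = inventory.extant_haps()

    # populations that RECEIVED an extralimital haplotype: some extant sample
    # of theirs carries, in its own stock, a haplotype flagged for that stock
    received: set[str] = set()
    for sid, hap in inventory.assignments.items():
        rec = records.get(sid)
        if rec is None or rec.era != "extant" or not rec.local_population:
            continue
        stock = rec.modern_stock or f"{rec.country or 'UNKNOWN'}(country)"
        if (hap, stock) in persistence.extralimital:
            received.add(rec.local_population)

    statuses: dict[str, PopulationStatus] = {}
    for pop in inventory.populations:
        undetermined = False
        try:
            status = classify_population(pop, inventory)
        except ValueError:
            status, undetermined = "extant", True
        historic = inventory.historic_haps(pop)
        private = private_haplotypes(inventory, pop, "historic") if historic else set()
        surviving = historic & surviving_anywhere
        statuses[pop] = PopulationStatus(
            population=pop,
            status=status,
            n=inventory.sample_count(pop, "historic"),
            H=len(historic),
            PH=len(private),
            SH=len(surviving),
            SPH=len(private & surviving_anywhere),
            eroded=len(surviving) < len(historic),
            extralimital_introduction=pop in received,
            undetermined=undetermined,
        )

    loss = partition_loss(inventory, {p: s.status for p, s in statuses.items()})
    return ExtinctionReport(statuses=statuses, persistence=persistence, loss=loss)
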