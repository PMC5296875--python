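"""Haplotype collapsing and the haplotype × population × era inventory.

Museum sequences are often fragmentary, so two ambiguity policies are
offered when deciding whether sequences carry the same haplotype:

``mask_pairwise`` (default)
    For each pair, alignment columns holding a gap, ``N`` or an IUPAC
    ambiguity code in either sequence are ignored; the pair matches if it
    is identical everywhere else.  Because this relation is not
    transitive, haplotype classes are its transitive closure (union-find).

``strict``
    Sequences must be byte-identical (columns that are gaps in every
    sequence are dropped first, with a warning).

Haplotype ids are assigned ``H001, H002, ...`` in order of first
appearance in the input, so numbering is stable across runs.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import Alignment, SampleRecord

__all__ = [
    "HaplotypeInventory",
    "collapse_haplotypes",
    "segregating_sites",
    "private_haplotypes",
]

_UNAMBIGUOUS = frozenset(b"ACGT")

ERA_SCOPES = ("total", "historic", "extant")


def _unambiguous_mask(matrix: np.ndarray) -> np.ndarray:
    """Boolean (n, L): True where the state is a plain A/C/G/T."""
    mask = np.zeros(matrix.shape, dtype=bool)
    for ch in _UNAMBIGUOUS:
        mask |= matrix == ch
    return mask


@dataclass
class HaplotypeInventory:
    """Counts of each haplotype per (local population, era).

    ``None`` as a population key collects samples without a population
    label; they contribute to species-wide totals only, never to per-
    population haplotype sets.
    """

    representative: dict[str, str]
    counts: dict[str, dict[tuple[str | None, str], int]]
    assignments: dict[str, str]  # sample_id -> haplotype_id
    policy: str = "mask_pairwise"
    warnings: list[str] = field(default_factory=list)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.representative)

    @property
    def populations(self) -> list[str]:
        pops: list[str] = []
        for cells in self.counts.values():
            for pop, _era in cells:
                if pop is not None and pop not in pops:
                    pops.append(pop)
        return sorted(pops)

    def total_samples(self) -> int:
        return sum(n for cells in self.counts.values() for n in cells.values())

    def haplotype_counts(self, era_scope: str = "total") -> dict[str, int]:
        """Total copies of each haplotype within an era scope."""
        _check_scope(era_scope)
        out: dict[str, int] = {}
        for h, cells in self.counts.items():
            n = sum(
                c for (pop, era), c in cells.items()
                if era_scope == "total" or era == era_scope
            )
            if n:
                out[h] = n
        return out

    def haps_in(self, pop: str | None, era_scope: str = "total") -> set[str]:
        """Haplotypes observed in one population (or anywhere, pop=None is
        NOT a wildcard — use :meth:`haps_anywhere`)."""
        _check_scope(era_scope)
        return {
            h
            for h, cells in self.counts.items()
            for (p, era), c in cells.items()
            if c and p == pop and (era_scope == "total" or era == era_scope)
        }

    def haps_anywhere(self, era_scope: str = "total") -> set[str]:
        _check_scope(era_scope)
        return {
            h
            for h, cells in self.counts.items()
            for (_p, era), c in cells.items()
            if c and (era_scope == "total" or era == era_scope)
        }

    def historic_haps(self, pop: str) -> set[str]:
        return self.haps_in(pop, "historic")

    def extant_haps(self, pop: str | None = None) -> set[str]:
        """Haplotypes surviving in ``pop`` (or anywhere when pop is None)."""
        if pop is None:
            return self.haps_anywhere("extant")
        return self.haps_in(pop, "extant")

    def private_haps(self, pop: str, era_scope: str = "historic") -> set[str]:
        return private_haplotypes(self, pop, era_scope)

    def sample_count(self, pop: str | None, era_scope: str = "total") -> int:
        _check_scope(era_scope)
        return sum(
            c
            for cells in self.counts.values()
            for (p, era), c in cells.items()
            if p == pop and (era_scope == "total" or era == era_scope)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Inventory TSV layout: haplotype, representative, one column per
        (population, era) cell."""
        cells = sorted(
            {pe for c in self.counts.values() for pe in c},
            key=lambda pe: (pe[0] is None, str(pe[0]), pe[1]),
        )
        rows = []
        for h in self.haplotype_ids:
            row: dict[str, object] = {
                "haplotype_id": h,
                "representative_sequence": self.representative[h],
            }
            for pop, era in cells:
                row[f"{pop if pop is not None else 'UNASSIGNED'}|{era}"] = (
                    self.counts[h].get((pop, era), 0)
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _check_scope(era_scope: str) -> None:
    if era_scope not in ERA_SCOPES:
        raise ValueError(f"era_scope must be one of {ERA_SCOPES}, got {era_scope!r}")


def _haplotype_classes(alignment: Alignment, policy: str) -> list[int]:
    """Class index per sequence, numbered by first occurrence."""
    n = len(alignment)
    if n == 0:
        return []
    m = alignment.to_matrix()
    good = _unambiguous_mask(m)

    if policy == "strict":
        all_gap = (m == ord("-")).all(axis=0)
        if all_gap.any():
            warnings.warn(
                f"dropping {int(all_gap.sum())} all-gap columns under strict policy",
                stacklevel=3,
            )
            m = m[:, ~all_gap]
        key_to_class: dict[bytes, int] = {}
        classes = []
        for i in range(n):
            classes.append(key_to_class.setdefault(m[i].tobytes(), len(key_to_class)))
        return classes

    if policy != "mask_pairwise":
        raise ValueError(f"unknown ambiguity policy {policy!r}")

    # union-find over the transitive closure of pairwise masked identity
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n - 1):
        rest = slice(i + 1, n)
        conflict = (m[rest] != m[i]) & good[rest] & good[i]
        compatible = ~conflict.any(axis=1)
        ri = find(i)
        for off in np.nonzero(compatible)[0]:
            rj = find(i + 1 + int(off))
            if ri != rj:
                parent[rj] = ri
                ri = find(ri)

    root_to_class: dict[int, int] = {}
    classes = []
    for i in range(n):
        classes.append(root_to_class.setdefault(find(i), len(root_to_class)))
    return classes


def collapse_haplotypes(
    alignment: Alignment,
    ambiguity_policy: str = "mask_pairwise",
    records: Mapping[str, SampleRecord] | None = None,
) -> HaplotypeInventory:
    """Collapse an alignment into haplotypes and tally them by (population, era).

    ``records`` supplies each sample's local population and era; samples
    missing from it (or with an empty population label) are tallied under
    the ``None`` population.  Without any records every sample is treated
    as historic and unassigned, which is enough for pure collapsing.
    """
    if len(alignment) == 0:
        raise ValueError("cannot collapse an empty alignment")
    classes = _haplotype_classes(alignment, ambiguity_policy)
    n_classes = max(classes) + 1
    width = max(3, len(str(n_classes)))
    hap_ids = [f"H{k + 1:0{width}d}" for k in range(n_classes)]

    representative: dict[str, str] = {}
    counts: dict[str, dict[tuple[str | None, str], int]] = {h: defaultdict(int) for h in hap_ids}
    assignments: dict[str, str] = {}
    for sid, seq, cls in zip(alignment.ids, alignment.sequences, classes):
        h = hap_ids[cls]
        representative.setdefault(h, seq)
        rec = records.get(sid) if records else None
        pop = rec.local_population if rec and rec.local_population else None
        era = rec.era if rec else "historic"
        counts[h][(pop, era)] += 1
        assignments[sid] = h
    return HaplotypeInventory(
        representative=representative,
        counts={h: dict(c) for h, c in counts.items()},
        assignments=assignments,
        policy=ambiguity_policy,
    )


def segregating_sites(alignment: Alignment) -> int:
    """Number of polymorphic sites: columns with >= 2 distinct unambiguous states."""
    if len(alignment) < 2:
        raise ValueError("segregating sites require at least two sequences")
    m = alignment.to_matrix()
    good = _unambiguous_mask(m)
    count = 0
    for j in range(alignment.length):
        states = set(m[good[:, j], j].tolist())
        if len(states) >= 2:
            count += 1
    return count


def private_haplotypes(
    inventory: HaplotypeInventory, pop: str, era_scope: str = "historic"
) -> set[str]:
    """Haplotypes observed in ``pop`` and in no other local population
    within the era scope.  Samples without a population label never make a
    haplotype non-private (they belong to no population)."""
    if pop not in inventory.populations:
        raise KeyError(f"unknown population {pop!r}")
    mine = inventory.haps_in(pop, era_scope)
    others: set[str] = set()
    for other in inventory.populations:
        if other != pop:
            others |= inventory.haps_in(other, era_scope)
    return mine - others
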