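"""Diversity statistics for mtDNA haplotypes and microsatellite genotypes.

Estimators
----------
Haplotype (gene) diversity uses the unbiased sample estimator

    h = n (1 - sum_i p_i^2) / (n - 1)

with p_i the sample frequency of haplotype i.  Nucleotide diversity is
reported as the mean number of pairwise differences,

    pi = sum_{i<j} d_ij / C(n, 2),

in count units (not per site), with pairwise deletion of ambiguous or
gapped positions; a per-site variant divides by the alignment length.
Expected heterozygosity is the small-sample-corrected
``(2N / (2N - 1)) (1 - sum_a p_a^2)`` per locus.  Allelic richness is
rarefied to a standard number of gene copies ``g`` by hypergeometric
expectation:

    A_g = sum_a [ 1 - C(N - N_a, g) / C(N, g) ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import _unambiguous_mask, collapse_haplotypes, segregating_sites
from .seqio import Alignment, GenotypeTable, ValidatedDataset

__all__ = [
    "DiversityStats",
    "haplotype_diversity",
    "nucleotide_diversity",
    "heterozygosity",
    "rarefied_allelic_richness",
    "diversity_table",
    "microsatellite_table",
]

MIN_GROUP_SIZE = 5  # groups below this are flagged, not dropped


@dataclass
class DiversityStats:
    """One row of a diversity table (mtDNA flavour)."""

    group: str
    era_scope: str
    n: int
    nhaps: int | None = None
    P: int | None = None
    h: float | None = None
    pi: float | None = None
    flagged_small: bool = False


def haplotype_diversity(counts: Sequence[int] | Mapping[str, int]) -> float:
    """Unbiased haplotype diversity from per-haplotype copy numbers."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    values = [c for c in values if c > 0]
    n = sum(values)
    if n < 2:
        raise ValueError(f"haplotype diversity undefined for n={n} (< 2)")
    p = np.asarray(values, dtype=float) / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def pairwise_difference_matrix(alignment: Alignment) -> np.ndarray:
    """(n, n) pairwise difference counts with pairwise deletion of
    ambiguous/gapped positions."""
    m = alignment.to_matrix()
    good = _unambiguous_mask(m)
    n = len(alignment)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        diffs = ((m[rest] != m[i]) & good[rest] & good[i]).sum(axis=1)
        d[i, i + 1 :] = diffs
        d[i + 1 :, i] = diffs
    return d


def nucleotide_diversity(alignment: Alignment, per_site: bool = False) -> float:
    """Mean number of pairwise differences (count units by default)."""
    n = len(alignment)
    if n < 2:
        raise ValueError(f"nucleotide diversity undefined for n={n} (< 2)")
    d = pairwise_difference_matrix(alignment)
    total = d[np.triu_indices(n, k=1)].sum()
    pi = float(total) / math.comb(n, 2)
    if per_site:
        pi /= alignment.length
    return pi


def heterozygosity(
    genotypes: GenotypeTable, group: Iterable[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-locus observed/expected heterozygosity plus multilocus means.

    ``group`` restricts to a subset of sample ids.  Loci with no
    non-missing calls in the group are excluded from the multilocus mean.
    H_E uses the 2N/(2N-1) small-sample correction.
    """
    gt = genotypes if group is None else genotypes.subset(group)
    rows = []
    for locus in gt.loci:
        calls = gt.locus_calls(locus)
        called = (calls > 0).all(axis=1)
        n_ind = int(called.sum())
        if n_ind == 0:
            rows.append({"locus": locus, "n": 0, "H_E": np.nan, "H_O": np.nan})
            continue
        obs = calls[called]
        h_o = float((obs[:, 0] != obs[:, 1]).mean())
        alleles = obs.ravel()
        _vals, cnt = np.unique(alleles, return_counts=True)
        p = cnt / cnt.sum()
        two_n = 2 * n_ind
        h_e = 0.0 if two_n < 2 else float(two_n / (two_n - 1) * (1.0 - np.sum(p**2)))
        rows.append({"locus": locus, "n": n_ind, "H_E": h_e, "H_O": h_o})
    table = pd.DataFrame(rows)
    with_data = table.dropna(subset=["H_E"])
    multilocus = {
        "H_E": float(with_data["H_E"].mean()) if len(with_data) else float("nan"),
        "H_O": float(with_data["H_O"].mean()) if len(with_data) else float("nan"),
        "loci": int(len(with_data)),
    }
    return table, multilocus


def _rarefied_alleles(allele_counts: np.ndarray, g: int) -> float:
    N = int(allele_counts.sum())
    if g < 1 or g > N:
        raise ValueError(f"rarefaction size g={g} outside [1, {N}]")
    total = 0.0
    for n_a in allele_counts:
        total += 1.0 - math.comb(N - int(n_a), g) / math.comb(N, g)
    return total


def rarefied_allelic_richness(
    genotypes: GenotypeTable, group: Iterable[str] | None = None, g: int | None = None
) -> tuple[pd.DataFrame, float, int]:
    """Rarefied allele count per locus and its mean over loci.

    ``g`` is the standardized number of gene copies; by default the
    smallest non-missing gene-copy count over loci in the group (so every
    locus can be rarefied).  Returns (per-locus table, mean, g used).
    """
    gt = genotypes if group is None else genotypes.subset(group)
    locus_counts = {}
    for locus in gt.loci:
        calls = gt.locus_calls(locus)
        alleles = calls[(calls > 0).all(axis=1)].ravel()
        if alleles.size:
            _vals, cnt = np.unique(alleles, return_counts=True)
            locus_counts[locus] = cnt
    if not locus_counts:
        raise ValueError("no locus has any non-missing calls in this group")
    if g is None:
        g = min(int(c.sum()) for c in locus_counts.values())
    rows = []
    for locus, cnt in locus_counts.items():
        if g > cnt.sum():
            raise ValueError(
                f"g={g} exceeds the {int(cnt.sum())} gene copies at locus {locus!r}"
            )
        rows.append({"locus": locus, "gene_copies": int(cnt.sum()),
                     "A_g": _rarefied_alleles(cnt, g)})
    table = pd.DataFrame(rows)
    return table, float(table["A_g"].mean()), g


# ---------------------------------------------------------------------------
# table builders


def _group_key(record, grouping: str, region_map: Mapping[str, str] | None):
    if grouping == "country":
        return record.country or None
    if grouping == "local_population":
        return record.local_population or None
    if grouping == "region":
        if region_map is None:
            raise ValueError("grouping='region' needs a country -> region map")
        return region_map.get(record.country) if record.country else None
    raise ValueError(f"unknown grouping {grouping!r}")


def diversity_table(
    dataset: ValidatedDataset,
    grouping: str = "country",
    era_scopes: Sequence[str] = ("total", "historic", "extant"),
    region_map: Mapping[str, str] | None = None,
    ambiguity_policy: str = "mask_pairwise",
    min_n: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """mtDNA diversity rows (n, nhaps, P, h, pi) per group per era scope.

    Samples without a group label are pooled into a ``Species-wide`` row
    only.  Groups smaller than ``min_n`` are emitted but flagged.
    """
    if dataset.alignment is None:
        raise ValueError("dataset has no alignment")
    groups: dict[str | None, list[str]] = {}
    for sid in dataset.alignment.ids:
        rec = dataset.records[sid]
        groups.setdefault(_group_key(rec, grouping, region_map), []).append(sid)

    rows = []
    all_ids = list(dataset.alignment.ids)
    for label, ids in [("Species-wide", all_ids)] + [
        (g, ids) for g, ids in sorted(groups.items(), key=lambda kv: str(kv[0]))
        if g is not None
    ]:
        for scope in era_scopes:
            scoped = [
                sid for sid in ids
                if scope == "total" or dataset.records[sid].era == scope
            ]
            row: dict[str, object] = {
                "group": label, "era_scope": scope, "n": len(scoped),
                "nhaps": 0, "P": 0, "h": np.nan, "pi": np.nan,
                "flagged_small": len(scoped) < min_n,
            }
            if scoped:
                sub = dataset.alignment.subset(scoped)
                inv = collapse_haplotypes(sub, ambiguity_policy)
                row["nhaps"] = len(inv.haplotype_ids)
                if len(scoped) >= 2:
                    row["P"] = segregating_sites(sub)
                    row["h"] = haplotype_diversity(list(inv.haplotype_counts().values()))
                    row["pi"] = nucleotide_diversity(sub)
            rows.append(row)
    return pd.DataFrame(rows)


def microsatellite_table(
    dataset: ValidatedDataset,
    grouping: str = "country",
    era_scopes: Sequence[str] = ("total", "historic", "extant"),
    region_map: Mapping[str, str] | None = None,
    g: int | None = None,
    min_n: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Microsatellite diversity rows (n, loci, H_E, H_O, A_g) per group/scope."""
    if dataset.genotypes is None:
        raise ValueError("dataset has no genotype table")
    groups: dict[str | None, list[str]] = {}
    for sid in dataset.genotypes.sample_ids:
        rec = dataset.records[sid]
        groups.setdefault(_group_key(rec, grouping, region_map), []).append(sid)

    rows = []
    all_ids = list(dataset.genotypes.sample_ids)
    for label, ids in [("Species-wide", all_ids)] + [
        (grp, ids) for grp, ids in sorted(groups.items(), key=lambda kv: str(kv[0]))
        if grp is not None
    ]:
        for scope in era_scopes:
            scoped = [
                sid for sid in ids
                if scope == "total" or dataset.records[sid].era == scope
            ]
            row: dict[str, object] = {
                "group": label, "era_scope": scope, "n": len(scoped),
                "loci": 0, "H_E": np.nan, "H_O": np.nan, "A": np.nan, "g": np.nan,
                "flagged_small": len(scoped) < min_n,
            }
            if scoped:
                _tab, multi = heterozygosity(dataset.genotypes, scoped)
                row["loci"] = multi["loci"]
                row["H_E"] = multi["H_E"]
                row["H_O"] = multi["H_O"]
                try:
                    _atab, a_mean, g_used = rarefied_allelic_richness(
                        dataset.genotypes, scoped, g=g
                    )
                    row["A"], row["g"] = a_mean, g_used
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)
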