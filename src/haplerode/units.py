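"""Conservation-unit designation: reciprocal monophyly, allele-frequency
differentiation and spatial exclusivity combined into ESU / MU calls.

The decision rule (after Moritz's gene-flow logic):

* a group that is monophyletic on the haplotype tree and whose
  geographic range is mutually exclusive with all other groups is an
  **ESU**;
* monophyletic groups whose ranges overlap are collapsed into the
  minimal monophyletic union — a **higher-order ESU** — and reported as
  members of it;
* a non-monophyletic group that differs significantly in nuclear allele
  frequencies is a **MU** (management unit), whether or not its range
  overlaps others;
* anything else receives no unit status.

Monophyly is assessed after collapsing branches whose support is below
``support_min`` into polytomies; a group is monophyletic when its leaves
form an exclusive clade.  On a rooted tree an exclusive clade is exactly
a bipartition of the leaf set, so group and complement are mutually
exclusive in the unrooted sense ("reciprocal").

Allele-frequency differentiation uses a per-locus Monte-Carlo exact
contingency test on allele counts (probability-ordering criterion, the
r x c generalization of Fisher's exact test), with per-locus p-values
combined by Fisher's method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .seqio import GenotypeTable, LabeledTree

__all__ = [
    "UnitDecision",
    "is_reciprocally_monophyletic",
    "frequency_differentiation",
    "designate_units",
    "DEFAULT_SUPPORT_MIN",
    "DEFAULT_OVERLAP_MAX",
]

DEFAULT_SUPPORT_MIN = 0.95
DEFAULT_OVERLAP_MAX = 0.05  # max range Jaccard still counted as "mutually exclusive"


@dataclass
class UnitDecision:
    group: str
    monophyletic: bool | None
    freq_differentiated: bool | None
    p_value: float | None
    spatially_distinct: bool | None
    max_overlap: float | None
    call: str  # ESU | MU | higher_order_esu_member | none
    higher_order_parent: str | None = None


# ---------------------------------------------------------------------------
# monophyly


def _collapse_unsupported(tree: dendropy.Tree, support_min: float) -> dendropy.Tree:
    """Clone and collapse internal branches with support < support_min.

    Unlabelled branches are treated as fully supported (input trees without
    support annotation are taken at face value).
    """
    work = tree.clone(depth=1)
    to_collapse = []
    for node in work.preorder_internal_node_iter(exclude_seed_node=True):
        if node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue
        if support < support_min:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return work


def _clade_leaf_sets(tree: dendropy.Tree) -> list[frozenset[str]]:
    out = []
    for node in tree.preorder_node_iter():
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def is_reciprocally_monophyletic(
    tree: LabeledTree | dendropy.Tree,
    labels: Mapping[str, str] | None = None,
    group: str | None = None,
    support_min: float = DEFAULT_SUPPORT_MIN,
) -> bool:
    """True iff the group's leaves form an exclusive supported clade.

    ``tree`` may be a :class:`LabeledTree` (its label map is used unless
    ``labels`` overrides it) or a bare dendropy tree with ``labels``
    supplied.  ``group`` selects which label to test.
    """
    if isinstance(tree, LabeledTree):
        dtree = tree.tree
        labels = labels if labels is not None else tree.labels
    else:
        dtree = tree
    if labels is None or group is None:
        raise ValueError("labels and group are required")
    members = {leaf for leaf, lab in labels.items() if lab == group}
    if not members:
        raise KeyError(f"group {group!r} has no leaves on the tree")
    leaf_names = {lf.taxon.label for lf in dtree.leaf_node_iter()}
    missing = members - leaf_names
    if missing:
        raise KeyError(f"group {group!r} leaves absent from tree: {sorted(missing)[:5]}")
    if members == leaf_names:
        return True
    work = _collapse_unsupported(dtree, support_min)
    taxa = [t for t in work.taxon_namespace if t.label in members]
    mrca = work.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == members


# ---------------------------------------------------------------------------
# allele-frequency differentiation


def _allele_counts(gt: GenotypeTable, ids: Iterable[str], locus: str) -> dict[int, int]:
    sub = gt.subset(ids)
    calls = sub.locus_calls(locus)
    alleles = calls[(calls > 0).all(axis=1)].ravel()
    vals, cnt = np.unique(alleles, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def _log_table_prob(x: np.ndarray, col_tot: np.ndarray, row_tot: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a 2 x k allele table
    with fixed margins; ``x`` is row A's counts."""
    n = int(col_tot.sum())
    nA = int(row_tot[0])
    lp = -(
        gammaln(n + 1) - gammaln(nA + 1) - gammaln(n - nA + 1)
    )
    for m, xa in zip(col_tot, x):
        lp += gammaln(m + 1) - gammaln(xa + 1) - gammaln(m - xa + 1)
    return float(lp)


def _mc_exact_p(
    a_counts: Mapping[int, int],
    b_counts: Mapping[int, int],
    n_mc: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo exact p for a 2 x k contingency table of allele counts.

    Criterion: probability ordering — p = P(table at least as improbable
    as observed), estimated over random reassignments of gene copies to
    groups with margins fixed; the observed table is included in the
    numerator and denominator (add-one rule), so p is never 0.
    """
    alleles = sorted(set(a_counts) | set(b_counts))
    col_tot = np.array([a_counts.get(al, 0) + b_counts.get(al, 0) for al in alleles])
    x_obs = np.array([a_counts.get(al, 0) for al in alleles])
    nA = int(x_obs.sum())
    n = int(col_tot.sum())
    row_tot = np.array([nA, n - nA])
    lp_obs = _log_table_prob(x_obs, col_tot, row_tot)

    pool = np.repeat(np.arange(len(alleles)), col_tot)
    hits = 0
    tol = 1e-9
    for _ in range(n_mc):
        rng.shuffle(pool)
        x = np.bincount(pool[:nA], minlength=len(alleles))
        if _log_table_prob(x, col_tot, row_tot) <= lp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: chi-square with 2k df on -2 sum(log p)."""
    ps = [p for p in p_values if not math.isnan(p)]
    if not ps:
        raise ValueError("no p-values to combine")
    x2 = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x2, df=2 * len(ps)))


def frequency_differentiation(
    genotypes: GenotypeTable,
    group_a: Iterable[str],
    group_b: Iterable[str],
    alpha: float = 0.05,
    n_mc: int = 2000,
    seed: int | None = None,
) -> tuple[float, bool]:
    """Test allele-frequency differentiation between two sample groups.

    Per shared locus, a Monte-Carlo exact contingency test on allele
    counts; loci combined by Fisher's method.  Returns (combined p,
    differentiated at ``alpha``).
    """
    rng = np.random.default_rng(seed)
    group_a, group_b = list(group_a), list(group_b)
    per_locus: list[float] = []
    for locus in genotypes.loci:
        ca = _allele_counts(genotypes, group_a, locus)
        cb = _allele_counts(genotypes, group_b, locus)
        if sum(ca.values()) < 2 or sum(cb.values()) < 2:
            continue
        per_locus.append(_mc_exact_p(ca, cb, n_mc, rng))
    if not per_locus:
        raise ValueError("no locus has data in both groups")
    p = fisher_combine(per_locus)
    return p, p < alpha


# ---------------------------------------------------------------------------
# unit designation


def _minimal_monophyletic_union(
    tree: LabeledTree, groups: Iterable[str], support_min: float
) -> tuple[str, set[str]]:
    """Smallest supported clade containing all leaves of ``groups``.

    Returns (parent label, set of groups fully contained in that clade).
    Falls back to the root (with a warning) when no smaller clade exists.
    """
    labels = tree.labels
    target = {leaf for leaf, lab in labels.items() if lab in set(groups)}
    work = _collapse_unsupported(tree.tree, support_min)
    best: frozenset[str] | None = None
    for clade in _clade_leaf_sets(work):
        if target <= clade and (best is None or len(clade) < len(best)):
            best = clade
    assert best is not None  # the root always contains everything
    all_leaves = frozenset(lf.taxon.label for lf in work.leaf_node_iter())
    if best == all_leaves and target != all_leaves:
        warnings.warn(
            "no monophyletic union short of the root contains the overlapping "
            "groups; reporting a root-level higher-order ESU",
            stacklevel=3,
        )
    contained = {
        g for g in set(labels.values())
        if {lf for lf, lab in labels.items() if lab == g} <= best
    }
    parent = "HO(" + "+".join(sorted(contained)) + ")"
    return parent, contained


def designate_units(
    monophyly: Mapping[str, bool],
    differentiation: Mapping[str, tuple[float | None, bool | None]] | Mapping[str, bool | None],
    overlap: pd.DataFrame,
    tree: LabeledTree | None = None,
    overlap_max: float = DEFAULT_OVERLAP_MAX,
    support_min: float = DEFAULT_SUPPORT_MIN,
) -> list[UnitDecision]:
    """Combine monophyly, differentiation and pairwise range overlap into
    unit decisions.

    ``overlap`` is a symmetric group x group Jaccard matrix (every pair
    must be present).  ``differentiation`` maps group -> (p, bool) or
    group -> bool/None (None = nuclear data unavailable).  ``tree`` is
    needed only to name the minimal monophyletic union behind higher-order
    ESUs; without it the overlapping cluster itself is used.
    Output is deterministically ordered by group name.
    """
    groups = sorted(monophyly)
    for a in groups:
        for b in groups:
            if a != b and (a not in overlap.index or b not in overlap.columns):
                raise KeyError(f"overlap matrix is missing the pair ({a}, {b})")

    def diff_of(g: str) -> tuple[float | None, bool | None]:
        v = differentiation.get(g)
        if v is None:
            return None, None
        if isinstance(v, tuple):
            return v
        return None, bool(v)

    max_ov = {
        g: max((float(overlap.loc[g, o]) for o in groups if o != g), default=0.0)
        for g in groups
    }
    distinct = {g: max_ov[g] <= overlap_max for g in groups}

    # connected components of the overlap graph
    adj = {
        g: {o for o in groups if o != g and float(overlap.loc[g, o]) > overlap_max}
        for g in groups
    }
    component: dict[str, frozenset[str]] = {}
    seen: set[str] = set()
    for g in groups:
        if g in seen:
            continue
        comp, frontier = set(), [g]
        while frontier:
            x = frontier.pop()
            if x in comp:
                continue
            comp.add(x)
            frontier.extend(adj[x] - comp)
        for x in comp:
            component[x] = frozenset(comp)
        seen |= comp

    # name a higher-order parent per overlapping component with >=1 monophyletic member
    parent_of: dict[frozenset[str], str] = {}
    for comp in set(component.values()):
        if len(comp) < 2 or not any(monophyly[g] for g in comp):
            continue
        if tree is not None:
            on_tree = {g for g in comp if g in set(tree.labels.values())}
            if on_tree:
                parent_of[comp] = _minimal_monophyletic_union(tree, on_tree, support_min)[0]
                continue
        parent_of[comp] = "HO(" + "+".join(sorted(comp)) + ")"

    decisions = []
    for g in groups:
        mono = monophyly[g]
        p, diff = diff_of(g)
        parent = parent_of.get(component[g])
        if mono and distinct[g]:
            call, keep_parent = "ESU", None
        elif mono:
            call, keep_parent = "higher_order_esu_member", parent
        elif diff:
            call, keep_parent = "MU", parent
        else:
            call, keep_parent = "none", None
        decisions.append(
            UnitDecision(
                group=g,
                monophyletic=mono,
                freq_differentiated=diff,
                p_value=p,
                spatially_distinct=distinct[g],
                max_overlap=max_ov[g],
                call=call,
                higher_order_parent=keep_parent,
            )
        )
    return decisions


def decisions_to_dataframe(decisions: Sequence[UnitDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "group": d.group,
                "monophyletic": d.monophyletic,
                "freq_different": "NA" if d.freq_differentiated is None else d.freq_differentiated,
                "p_value": "NA" if d.p_value is None else d.p_value,
                "spatially_distinct": d.spatially_distinct,
                "max_overlap": d.max_overlap,
                "call": d.call,
                "parent": d.higher_order_parent or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "monophyletic", "freq_different", "p_value",
            "spatially_distinct", "max_overlap", "call", "parent",
        ],
    )
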