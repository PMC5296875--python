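"""Readers, writers and validation for the external file formats.

The analysis joins four inputs: an aligned mtDNA FASTA, a per-sample
metadata table (TSV), an optional diploid microsatellite genotype table
(CSV) and an optional rooted haplotype tree (Newick).  Everything is
validated here once, so downstream modules can assume a consistent
:class:`ValidatedDataset`.

Conventions
-----------
* metadata is tab-separated UTF-8 with a mandatory header; missing values
  are empty strings;
* sequences are stored uppercase, ``U`` mapped to ``T``;
* genotype CSV holds two integer allele-size columns per locus
  (``locus_A1, locus_A2``), ``0`` meaning a missing call;
* a sample whose era is not given explicitly is assigned one from its
  collection year and the era cutoff (default 1990: at or after the
  cutoff → extant, before → historic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SampleRecord",
    "Alignment",
    "GenotypeTable",
    "LabeledTree",
    "ValidatedDataset",
    "AlignmentError",
    "ValidationError",
    "DEFAULT_ERA_CUTOFF",
    "read_fasta_alignment",
    "read_metadata",
    "read_genotypes",
    "read_tree",
    "read_dataset",
    "write_report_tables",
]

DEFAULT_ERA_CUTOFF = 1990

ERAS = ("historic", "extant")

METADATA_COLUMNS = (
    "sample_id",
    "era",
    "collection_year",
    "country",
    "local_population",
    "modern_stock",
    "lat",
    "lon",
)

VALID_CHARS = set("ACGTUMRWSYKVHDBN-")


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class ValidationError(ValueError):
    """Raised when metadata or genotype tables violate an invariant."""


@dataclass
class SampleRecord:
    """One sequenced and/or genotyped individual."""

    sample_id: str
    era: str
    collection_year: int | None = None
    country: str = ""
    local_population: str = ""
    modern_stock: str = ""
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise ValidationError(
                f"sample {self.sample_id!r}: era must be one of {ERAS}, got {self.era!r}"
            )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"sample {self.sample_id!r}: lat {self.lat} out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"sample {self.sample_id!r}: lon {self.lon} out of range")


class Alignment:
    """An aligned set of equal-length sequences keyed by sample id."""

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        if len(ids) != len(sequences):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dupes}")
        seqs = [normalize_sequence(s) for s in sequences]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.ids: list[str] = list(ids)
        self.sequences: list[str] = seqs
        self.length: int = lengths.pop() if lengths else 0
        self._index = {sid: k for k, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def sequence(self, sample_id: str) -> str:
        return self.sequences[self._index[sample_id]]

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        keep = [sid for sid in sample_ids if sid in self._index]
        return Alignment(keep, [self.sequence(sid) for sid in keep])

    def to_matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of ASCII codes, for vectorized comparisons."""
        if not self.ids:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.ids), self.length)


def normalize_sequence(seq: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - VALID_CHARS
    if bad:
        raise AlignmentError(f"invalid characters in sequence: {sorted(bad)}")
    return s


class GenotypeTable:
    """Diploid microsatellite genotypes: two allele sizes per locus, 0 = missing."""

    def __init__(self, sample_ids: Sequence[str], loci: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(sample_ids), len(loci), 2):
            raise ValidationError(
                f"genotype array shape {calls.shape} != ({len(sample_ids)}, {len(loci)}, 2)"
            )
        if (calls < 0).any():
            raise ValidationError("allele sizes must be positive integers (0 = missing)")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids in genotype table")
        self.sample_ids = list(sample_ids)
        self.loci = list(loci)
        self.calls = calls
        self._index = {sid: k for k, sid in enumerate(self.sample_ids)}

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Iterable[str]) -> "GenotypeTable":
        keep = [sid for sid in sample_ids if sid in self._index]
        rows = [self._index[sid] for sid in keep]
        return GenotypeTable(keep, self.loci, self.calls[rows])

    def locus_calls(self, locus: str) -> np.ndarray:
        """(n, 2) allele-size array for one locus."""
        return self.calls[:, self.loci.index(locus), :]

    def missingness(self) -> pd.Series:
        """Per-locus fraction of individuals with no call (either allele 0)."""
        miss = (self.calls == 0).any(axis=2).mean(axis=0)
        return pd.Series(miss, index=self.loci, name="missing_fraction")

    def to_dataframe(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids}
        for j, locus in enumerate(self.loci):
            data[f"{locus}_A1"] = self.calls[:, j, 0]
            data[f"{locus}_A2"] = self.calls[:, j, 1]
        return pd.DataFrame(data)


@dataclass
class LabeledTree:
    """Rooted haplotype tree plus a leaf → haplogroup label map."""

    tree: dendropy.Tree
    labels: Mapping[str, str] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def validate_against(self, haplotype_ids: Iterable[str]) -> None:
        known = set(haplotype_ids)
        extra = set(self.leaf_names) - known
        if extra:
            raise ValidationError(
                f"tree leaves not present among haplotype ids: {sorted(extra)[:5]}"
            )


@dataclass
class ValidatedDataset:
    """All inputs joined and validated; what the pipeline operates on."""

    records: dict[str, SampleRecord]
    alignment: Alignment | None = None
    genotypes: GenotypeTable | None = None
    tree: LabeledTree | None = None
    rejected: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def records_by(self, era: str | None = None) -> list[SampleRecord]:
        recs = self.records.values()
        if era is not None:
            recs = (r for r in recs if r.era == era)
        return list(recs)


# ---------------------------------------------------------------------------
# readers


def read_fasta_alignment(path: str | Path) -> Alignment:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return Alignment(ids, seqs)


def _parse_opt_int(value: str, *, what: str, sample: str) -> int | None:
    if value == "":
        return None
    try:
        return int(float(value))
    except ValueError as exc:
        raise ValidationError(f"sample {sample!r}: bad {what} {value!r}") from exc


def _parse_opt_float(value: str) -> float | None:
    return None if value == "" else float(value)


def read_metadata(
    path: str | Path, era_cutoff: int = DEFAULT_ERA_CUTOFF
) -> tuple[dict[str, SampleRecord], list[str]]:
    """Read the sample metadata TSV.

    Returns the records keyed by sample id plus a list of warnings.  An
    explicit ``era`` column wins; otherwise era is derived from
    ``collection_year`` against ``era_cutoff``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must contain a 'sample_id' column")
    warns: list[str] = []
    unknown = [c for c in df.columns if c not in METADATA_COLUMNS]
    if unknown:
        warns.append(f"ignoring unknown metadata columns: {unknown}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample_id in metadata: {dupes}")

    records: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["sample_id"]
        year = _parse_opt_int(d.get("collection_year", ""), what="collection_year", sample=sid)
        era = d.get("era", "")
        if era == "":
            if year is None:
                raise ValidationError(
                    f"sample {sid!r}: era missing and no collection_year to derive it from"
                )
            era = "extant" if year >= era_cutoff else "historic"
        records[sid] = SampleRecord(
            sample_id=sid,
            era=era,
            collection_year=year,
            country=d.get("country", ""),
            local_population=d.get("local_population", ""),
            modern_stock=d.get("modern_stock", ""),
            lat=_parse_opt_float(d.get("lat", "")),
            lon=_parse_opt_float(d.get("lon", "")),
        )
    return records, warns


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the genotype CSV (sample_id, then ``locus_A1,locus_A2`` pairs)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("genotype table must contain a 'sample_id' column")
    allele_cols = [c for c in df.columns if c != "sample_id"]
    loci: list[str] = []
    for col in allele_cols:
        if not (col.endswith("_A1") or col.endswith("_A2")):
            raise ValidationError(f"genotype column {col!r} is not of the form locus_A1/_A2")
        locus = col[:-3]
        if locus not in loci:
            loci.append(locus)
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for k, suffix in enumerate(("_A1", "_A2")):
            col = locus + suffix
            if col not in df.columns:
                raise ValidationError(f"locus {locus!r} is missing column {col!r}")
            calls[:, j, k] = df[col].fillna(0).astype(np.int64).to_numpy()
    return GenotypeTable(df["sample_id"].tolist(), loci, calls)


def read_tree(
    path: str | Path, labels: Mapping[str, str] | None = None
) -> LabeledTree:
    """Read a rooted Newick tree; branch supports, if any, must lie in [0, 1]."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = True
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                continue
            if not 0.0 <= support <= 1.0:
                raise ValidationError(f"branch support {support} outside [0, 1]")
    return LabeledTree(tree=tree, labels=dict(labels or {}))


def read_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    genotypes_path: str | Path | None = None,
    tree_path: str | Path | None = None,
    era_cutoff: int = DEFAULT_ERA_CUTOFF,
) -> ValidatedDataset:
    """Join sequences, metadata, genotypes and tree into one validated dataset.

    Samples lacking both a sequence and a genotype are rejected (reported in
    ``rejected``), never silently dropped.
    """
    records, warns = read_metadata(metadata_path, era_cutoff=era_cutoff)
    alignment = read_fasta_alignment(fasta_path)
    genotypes = read_genotypes(genotypes_path) if genotypes_path else None

    orphan_seqs = [sid for sid in alignment.ids if sid not in records]
    if orphan_seqs:
        raise ValidationError(
            f"sequences without metadata rows: {sorted(orphan_seqs)[:5]}"
        )

    rejected = [
        sid
        for sid in records
        if sid not in alignment and (genotypes is None or sid not in genotypes)
    ]
    for sid in rejected:
        del records[sid]
    if rejected:
        warns.append(f"rejected {len(rejected)} samples with neither sequence nor genotype")

    alignment = alignment.subset([sid for sid in records if sid in alignment])
    if genotypes is not None:
        genotypes = genotypes.subset([sid for sid in records if sid in genotypes])

    tree = read_tree(tree_path) if tree_path else None
    ds = ValidatedDataset(
        records=records,
        alignment=alignment,
        genotypes=genotypes,
        tree=tree,
        rejected=rejected,
        warnings=warns,
    )
    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return ds


# ---------------------------------------------------------------------------
# writers


def write_metadata(records: Mapping[str, SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records.values():
        rows.append(
            {
                "sample_id": r.sample_id,
                "era": r.era,
                "collection_year": "" if r.collection_year is None else r.collection_year,
                "country": r.country,
                "local_population": r.local_population,
                "modern_stock": r.modern_stock,
                "lat": "" if r.lat is None else r.lat,
                "lon": "" if r.lon is None else r.lon,
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")


def write_report_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table to ``out_dir`` as ``<name>.tsv``.

    Empty tables still produce a header-only file, so a report bundle always
    has the same file set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
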