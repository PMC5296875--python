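"""Config-driven orchestration of the full erosion analysis.

``run`` wires the stages together — read/validate, haplotype collapsing,
diversity tables, erosion report, conservation-unit decisions, kriged
range surfaces — and writes a report bundle (TSVs + a manifest with the
config hash, seed and library versions).  Every number in the bundle is
reproducible by calling the corresponding module function directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import diversity_table, microsatellite_table
from .erosion import ExtinctionReport, build_extinction_report
from .haplotypes import HaplotypeInventory, collapse_haplotypes
from .seqio import ValidatedDataset, read_dataset, write_report_tables
from .spatial import (
    GridSpec,
    MembershipPoints,
    RangeSurface,
    VariogramConfig,
    krige_membership,
    one_hot_membership,
    overlap_matrix,
)
from .units import (
    DEFAULT_OVERLAP_MAX,
    DEFAULT_SUPPORT_MIN,
    UnitDecision,
    decisions_to_dataframe,
    designate_units,
    frequency_differentiation,
    is_reciprocally_monophyletic,
)

logger = logging.getLogger("haplerode")

__all__ = ["RunConfig", "PipelineResult", "run", "load_config"]

_CONFIG_KEYS = {
    "fasta", "metadata", "genotypes", "tree", "out_dir", "era_cutoff",
    "ambiguity_policy", "rarefaction_g", "alpha", "n_mc", "support_min",
    "overlap_max", "range_threshold", "grid_spacing_deg", "grid_margin_deg",
    "seed", "grouping",
}


@dataclass
class RunConfig:
    fasta: str | Path | None = None
    metadata: str | Path | None = None
    genotypes: str | Path | None = None
    tree: str | Path | None = None
    out_dir: str | Path = "haplerode_run"
    era_cutoff: int = 1990
    ambiguity_policy: str = "mask_pairwise"
    rarefaction_g: int | None = None
    alpha: float = 0.05
    n_mc: int = 2000
    support_min: float = DEFAULT_SUPPORT_MIN
    overlap_max: float = DEFAULT_OVERLAP_MAX
    range_threshold: float = 0.4  # range edge: fraction of the group's surface peak
    grid_spacing_deg: float = 0.5
    grid_margin_deg: float = 2.0
    seed: int = 0
    grouping: str = "country"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.overlap_max <= 1:
            raise ValueError("overlap_max must be in [0, 1]")
        if not 0 < self.range_threshold < 1:
            raise ValueError("range_threshold must be in (0, 1)")
        if not 0 <= self.support_min <= 1:
            raise ValueError("support_min must be in [0, 1]")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class PipelineResult:
    dataset: ValidatedDataset
    inventory: HaplotypeInventory
    diversity: pd.DataFrame
    msat_diversity: pd.DataFrame | None
    erosion: ExtinctionReport
    units: list[UnitDecision] | None
    surface: RangeSurface | None
    overlap: pd.DataFrame | None
    paths: dict[str, Path] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "diversity": self.diversity,
            "inventory": self.inventory.to_dataframe(),
            "erosion": self.erosion.to_dataframe(),
            "persistence": self.erosion.persistence.to_dataframe(),
            "loss": self.erosion.loss.to_dataframe(),
        }
        if self.msat_diversity is not None:
            out["msat_diversity"] = self.msat_diversity
        if self.units is not None:
            out["units"] = decisions_to_dataframe(self.units)
        if self.surface is not None:
            out["range_grid"] = self.surface.to_dataframe()
        if self.overlap is not None:
            out["overlap"] = self.overlap.reset_index(names="group")
        return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _unit_stage(dataset: ValidatedDataset, inventory: HaplotypeInventory,
                cfg: RunConfig):
    """Monophyly, differentiation and spatial exclusivity per haplogroup."""
    if dataset.tree is None or not dataset.tree.labels:
        return None, None, None
    labels = dataset.tree.labels
    groups = sorted(set(labels.values()))
    hap_group = {h: g for h, g in labels.items()}
    sample_group = {
        sid: hap_group[h]
        for sid, h in inventory.assignments.items()
        if h in hap_group
    }

    monophyly = {
        g: is_reciprocally_monophyletic(dataset.tree, group=g, support_min=cfg.support_min)
        for g in groups
    }

    differentiation: dict[str, tuple[float | None, bool | None]] = {}
    if dataset.genotypes is not None:
        for g in groups:
            mine = [s for s, gg in sample_group.items() if gg == g and s in dataset.genotypes]
            rest = [s for s, gg in sample_group.items() if gg != g and s in dataset.genotypes]
            if len(mine) < 2 or len(rest) < 2:
                differentiation[g] = (None, None)
                continue
            p, diff = frequency_differentiation(
                dataset.genotypes, mine, rest,
                alpha=cfg.alpha, n_mc=cfg.n_mc, seed=cfg.seed,
            )
            differentiation[g] = (p, diff)
    else:
        differentiation = {g: (None, None) for g in groups}

    lats, lons, labs = [], [], []
    for sid, g in sample_group.items():
        rec = dataset.records.get(sid)
        if rec is not None and rec.lat is not None and rec.lon is not None:
            lats.append(rec.lat)
            lons.append(rec.lon)
            labs.append(g)
    surface = overlap = None
    if len(lats) >= 3 and len(set(labs)) >= 2:
        points = one_hot_membership(lats, lons, labs)
        surface = krige_membership(
            points,
            grid_spec=GridSpec(cfg.grid_spacing_deg, cfg.grid_margin_deg),
            seed=cfg.seed,
        )
        overlap = overlap_matrix(
            surface, threshold=cfg.range_threshold, groups=groups, relative=True
        )
    else:
        # no usable coordinates: treat every group as spatially distinct
        overlap = pd.DataFrame(0.0, index=groups, columns=groups)
        for g in groups:
            overlap.loc[g, g] = 1.0

    decisions = designate_units(
        monophyly, differentiation, overlap,
        tree=dataset.tree, overlap_max=cfg.overlap_max, support_min=cfg.support_min,
    )
    return decisions, surface, overlap


def run(config: RunConfig, dataset: ValidatedDataset | None = None) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    ``dataset`` may be supplied directly (e.g. from the simulator) instead
    of the file paths in ``config``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(handler)
    try:
        if dataset is None:
            if config.fasta is None or config.metadata is None:
                raise RuntimeError("pipeline stage 'read' failed: no dataset or input paths")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dataset = _stage("read")(read_dataset)(
                    config.fasta, config.metadata, config.genotypes, config.tree,
                    era_cutoff=config.era_cutoff,
                )
        if dataset.alignment is None or len(dataset.alignment) == 0:
            raise RuntimeError("pipeline stage 'read' failed: dataset has no alignment")

        inventory = _stage("haplotypes")(collapse_haplotypes)(
            dataset.alignment, config.ambiguity_policy, dataset.records
        )
        diversity = _stage("diversity")(diversity_table)(
            dataset, grouping=config.grouping, ambiguity_policy=config.ambiguity_policy
        )
        msat = None
        if dataset.genotypes is not None:
            msat = _stage("diversity")(microsatellite_table)(
                dataset, grouping=config.grouping, g=config.rarefaction_g
            )
        report = _stage("erosion")(build_extinction_report)(inventory, dataset.records)
        units, surface, overlap = _stage("units")(_unit_stage)(dataset, inventory, config)

        result = PipelineResult(
            dataset=dataset, inventory=inventory, diversity=diversity,
            msat_diversity=msat, erosion=report, units=units,
            surface=surface, overlap=overlap,
        )
        written = _stage("write")(write_report_tables)(result.tables(), out_dir)
        result.paths = {p.stem: p for p in written}

        cfg_dict = {
            k: str(v) for k, v in dataclasses.asdict(config).items()
        }
        manifest = {
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "versions": _versions(),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        result.paths["manifest"] = manifest_path
        logger.info("run complete: %d samples, %d haplotypes",
                    len(dataset.records), len(inventory.haplotype_ids))
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()


def _versions() -> dict[str, str]:
    import dendropy
    import msprime
    import numpy
    import pandas
    import scipy

    return {
        "haplerode": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "msprime": msprime.__version__,
        "dendropy": dendropy.__version__,
    }
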