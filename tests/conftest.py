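import warnings

import numpy as np
import pytest

from haplerode.pipeline import RunConfig, run
from haplerode.seqio import Alignment, SampleRecord, ValidatedDataset
from haplerode.simulate import scenario_rhino

SCENARIO_SEED = 7


def make_alignment(class_sizes, n_diffs, length=60, seed=0):
    """Alignment with one haplotype class per entry of ``class_sizes``;
    consecutive class representatives differ at ``n_diffs`` sites."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    reps = [base.copy()]
    cols = rng.choice(length, size=n_diffs * (len(class_sizes) - 1), replace=False)
    for k in range(1, len(class_sizes)):
        rep = reps[-1].copy()
        for col in cols[(k - 1) * n_diffs : k * n_diffs]:
            rep[col] = {"A": "C", "C": "G", "G": "T", "T": "A"}[rep[col]]
        reps.append(rep)
    ids, seqs = [], []
    for k, size in enumerate(class_sizes):
        for j in range(size):
            ids.append(f"c{k}_{j}")
            seqs.append("".join(reps[k]))
    return Alignment(ids, seqs)


def make_records(alignment, pop="PopA", era="historic", country="Xland", **kw):
    return {
        sid: SampleRecord(sample_id=sid, era=era, collection_year=1900 if era == "historic" else 2000,
                          country=country, local_population=pop, **kw)
        for sid in alignment.ids
    }


@pytest.fixture(scope="session")
def scenario():
    """The packaged 9-deme serially sampled fixture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenario_rhino(SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario_dataset(scenario):
    return ValidatedDataset(
        records=scenario.records,
        alignment=scenario.alignment,
        genotypes=scenario.genotypes,
        tree=scenario.tree,
    )


@pytest.fixture(scope="session")
def scenario_pipeline(scenario_dataset, tmp_path_factory):
    """Full pipeline run on the scenario (coarse grid keeps it fast)."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = RunConfig(out_dir=out, seed=1, grouping="local_population",
                    grid_spacing_deg=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run(cfg, dataset=scenario_dataset)
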