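import numpy as np
import pytest

from intronevo.config import PipelineConfig
from intronevo.simulate import SimConfig, emit_dataset, evolve_family


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A compact clean-mode dataset with all event mechanisms active."""
    cfg = SimConfig(seed=42, n_species=6, n_genes=12, substitution_rate=0.0,
                    gain_rate=0.2, loss_rate=0.25,
                    gain_mix={"transposon_tsd": 0.3, "mito_filler": 0.3,
                              "plain": 0.4},
                    loss_mix={"precise": 0.6, "nhej_imprecise": 0.4},
                    allow_homoplasy=False)
    models, truth = evolve_family(cfg)
    return cfg, models, truth


@pytest.fixture(scope="session")
def small_dataset(small_sim, tmp_path_factory):
    """The small simulation emitted to disk and reloaded via genomic_io."""
    from intronevo.pipeline import load_dataset

    _, models, truth = small_sim
    outdir = tmp_path_factory.mktemp("dataset")
    placed = emit_dataset(models, truth, str(outdir))
    return load_dataset(str(outdir)), placed, truth


@pytest.fixture(scope="session")
def small_inference(small_dataset):
    from intronevo.pipeline import infer_events

    dataset, _, _ = small_dataset
    return infer_events(dataset, PipelineConfig())


def truth_column_of(inference, dataset, truth, call):
    """Map an event call's column class to the simulator's truth column id."""
    gd = inference.data[call.group_id]
    fam = sorted(gd.group.members.values())[0].split("_", 1)[1]
    col = next(k for k in gd.colmap.columns if k.class_id == call.class_id)
    cols = set()
    for sp, idx in col.members:
        if sp == dataset.outgroup:
            continue
        by_idx = {i: c for i, c, _ in truth.leaf_introns[(sp, fam)]}
        cols.add(by_idx[idx])
    return fam, (cols.pop() if len(cols) == 1 else None)
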