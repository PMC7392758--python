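"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from pseudopan import io
from pseudopan.simulate import SimConfig, simulate_dataset
from pseudopan.trees import random_strain_tree

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATASET_DIR = RESULTS / "dataset"

# The study conditions for the whole analysis: 8 strains (one outgroup),
# ~1,000 automatic calls per strain, two retrotransposition bursts.  The
# strain panel is a ladder of progressively more distant relatives of the
# reference-like strain, as in a real inbred-strain collection.
STUDY = dict(seed=1, n_genes=400, expected_pseudogenes_per_strain=1000)


def study_config() -> SimConfig:
    cfg = SimConfig(**STUDY)
    cfg.tree = random_strain_tree(cfg.strains, seed=STUDY["seed"],
                                  outgroup=cfg.outgroup, shape="ladder")
    return cfg


def load_dataset():
    """Load the simulated study dataset, generating it on first use."""
    RESULTS.mkdir(exist_ok=True)
    if not (DATASET_DIR / "truth.json").exists():
        ds = simulate_dataset(study_config())
        io.write_dataset(ds, DATASET_DIR)
        return ds
    return io.read_dataset(DATASET_DIR)
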