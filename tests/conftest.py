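import numpy as np
import pandas as pd
import pytest

import anchorsig as a


@pytest.fixture
def tiny_dataset() -> a.ExpressionDataset:
    """3 genes x 4 samples, two per group, fixed values."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [1.2, 5.1, 2.2],
            "s3": [3.0, 5.0, 2.1],
            "s4": [3.2, 5.2, 1.9],
        },
        index=["GENEA", "GENEB", "GENEC"],
    )
    groups = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    return a.ExpressionDataset("T1", df, groups)


@pytest.fixture
def small_spec() -> a.SimulationSpec:
    """Small planted study: 300 genes, 20-gene module, 5 datasets."""
    module = tuple(f"GM{i + 1:03d}" for i in range(20))
    return a.SimulationSpec(
        n_genes=300, module_genes=module, effect_size=2.0, noise_sd=1.0,
        n_per_group=10, n_datasets=5, background_de_fraction=0.05, seed=7,
    )


def make_clique_graph(clique_sizes=(4, 4, 4, 4), p_background=0.0, seed=1):
    n = sum(clique_sizes)
    return a.generate_ppi(n, list(clique_sizes), p_background, seed=seed)


def write_panel(out_dir, panels):
    """Write generated datasets to disk; panels = [(spec, index, dataset_id)].

    Returns the ``datasets`` entries for a pipeline config, with paths
    relative to ``out_dir``.
    """
    entries = []
    for spec, index, ds_id in panels:
        ds = a.generate_dataset(spec, index)
        a.write_expression(ds, out_dir / f"{ds_id}.tsv",
                           out_dir / f"{ds_id}.groups.tsv")
        entries.append({"id": ds_id, "matrix": f"{ds_id}.tsv",
                        "groups": f"{ds_id}.groups.tsv"})
    return entries


def write_config(out_dir, name="run.yaml", **fields):
    import yaml

    path = out_dir / name
    path.write_text(yaml.safe_dump(fields))
    return path
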