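import pathlib

import pytest

from phosphoprio.core_io import read_newick
from phosphoprio.synthetic import FixtureSim, simulate_fixture, write_fixture


@pytest.fixture(scope="session")
def toy_tree(tmp_path_factory):
    """Four-leaf tree ((A:1,B:1):1,(C:1,D:3):1) used across modules."""
    p = tmp_path_factory.mktemp("tree") / "toy.nwk"
    p.write_text("((A:1,B:1):1,(C:1,D:3):1);\n")
    return read_newick(p)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> dict:
    """A written 200-site synthetic fixture shared by pipeline-level tests."""
    root = tmp_path_factory.mktemp("fixture")
    fx = simulate_fixture(FixtureSim(), seed=20210727)
    paths = write_fixture(fx, root)
    return {"fixture": fx, "paths": paths, "root": pathlib.Path(root)}


def pipeline_config(paths, outdir, seed=20210727, **params):
    base = {"n_bootstrap": 500}
    base.update(params)
    return {
        "seed": seed,
        "outdir": str(outdir),
        "inputs": {
            k: str(paths[k])
            for k in [
                "sites", "quant", "annotations", "msa_dir",
                "tree", "positives", "pathways",
            ]
        },
        "params": base,
    }
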