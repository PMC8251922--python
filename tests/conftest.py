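"""Shared fixtures: hand-built tiny bundles and a reusable synthetic dataset."""

import numpy as np
import pandas as pd
import pytest

from scntx.io import DonorBundle
from scntx.synthetic import SyntheticConfig, generate_atlas, generate_dataset


def make_bundle(
    donor_id="D1",
    expr=None,
    pa=None,
    entrez=None,
    coords=None,
    structures=None,
    hemisphere=None,
):
    """Build a small valid DonorBundle from plain arrays."""
    expr = np.asarray(expr if expr is not None else [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    n_probes, n_samples = expr.shape
    probe_ids = [f"p{i + 1}" for i in range(n_probes)]
    sample_ids = [f"{donor_id}_s{j + 1}" for j in range(n_samples)]
    if pa is None:
        pa = np.ones_like(expr, dtype=bool)
    if entrez is None:
        entrez = list(range(101, 101 + n_probes))
    if coords is None:
        coords = np.zeros((n_samples, 3))
    samples = pd.DataFrame(
        {
            "structure_acronym": structures or ["ctx"] * n_samples,
            "hemisphere": hemisphere or ["L"] * n_samples,
            "mni_x": np.asarray(coords)[:, 0],
            "mni_y": np.asarray(coords)[:, 1],
            "mni_z": np.asarray(coords)[:, 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return DonorBundle(
        donor_id=donor_id,
        expr=pd.DataFrame(expr, index=probe_ids, columns=sample_ids),
        pa=pd.DataFrame(np.asarray(pa, dtype=bool), index=probe_ids, columns=sample_ids),
        probes=pd.DataFrame(
            {"entrez_id": pd.array(entrez, dtype="Int64")},
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        samples=samples,
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions reused across integration tests."""
    return SyntheticConfig(
        seed=7,
        n_genes=300,
        samples_per_network=15,
        background_samples=10,
        n_stable_genes=30,
        planted={"C": (10, 10, (1.2, 2.0)), "D": (10, 10, (1.2, 2.0))},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    atlas = generate_atlas(small_config)
    bundles, truth = generate_dataset(small_config, atlas)
    return atlas, bundles, truth
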