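import numpy as np
import pytest

from mlascan.library import generate_nns_library
from mlascan.synthetic import random_wt_cds, sample_true_fitness


@pytest.fixture(scope="session")
def small_library():
    """30-codon library with a single sub-library (fast everywhere)."""
    return generate_nns_library(random_wt_cds(30, seed=11))


@pytest.fixture(scope="session")
def small_truth(small_library):
    return sample_true_fitness(small_library, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def brute_force_contacts(model, group_a, group_b, cutoff):
    """O(n^2) contact oracle: all heavy-atom pairs, min distance per residue pair."""
    from scipy.spatial.distance import cdist

    mask_a = model.atom_mask(set(group_a))
    mask_b = model.atom_mask(set(group_b))
    xa, xb = model.coords[mask_a], model.coords[mask_b]
    keys_a = list(zip(model.chain_ids[mask_a], model.res_ids[mask_a]))
    keys_b = list(zip(model.chain_ids[mask_b], model.res_ids[mask_b]))
    dist = cdist(xa, xb)
    pairs = {}
    for ia, ib in zip(*np.nonzero(dist < cutoff)):
        key = ((str(keys_a[ia][0]), int(keys_a[ia][1])), (str(keys_b[ib][0]), int(keys_b[ib][1])))
        d = float(dist[ia, ib])
        if d < pairs.get(key, np.inf):
            pairs[key] = d
    return pairs


def random_two_chain_model(rng, n_atoms_per_chain=40, box=20.0):
    """Random atom soup in a box, grouped into residues of ~3 atoms."""
    from mlascan.structure import StructureModel

    records = []
    for cid in ("A", "B"):
        coords = rng.uniform(0, box, size=(n_atoms_per_chain, 3))
        for i in range(n_atoms_per_chain):
            records.append((cid, 1 + i // 3, coords[i]))
    return StructureModel(
        chain_ids=np.array([r[0] for r in records]),
        res_ids=np.array([r[1] for r in records], dtype=np.int64),
        res_names=np.array(["GLY"] * len(records)),
        atom_names=np.array([f"C{i}" for i in range(len(records))]),
        elements=np.array(["C"] * len(records)),
        coords=np.array([r[2] for r in records]),
    )
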