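import numpy as np
import pytest

from fibrilsolv import FibrilRecipe, make_fibril, make_layer
from fibrilsolv.structure_io import AtomRecord, FibrilModel


@pytest.fixture(scope="session")
def small_stack():
    """5-layer, 10-residue, single-protofilament lysine-containing stack."""
    return make_fibril(FibrilRecipe(sequence="LKLLKLLKLL", path_shape="c_shape",
                                    rise=4.8, twist=-1.0, n_layers=5))


@pytest.fixture(scope="session")
def paired_stack():
    return make_fibril(FibrilRecipe(sequence="KLLKLL", protofilaments=2, n_layers=5))


@pytest.fixture(scope="session")
def tiny_layer():
    return make_layer(FibrilRecipe(sequence="AKA"))


def ca_chain(res_seqs, offset=0.0, chain_id="A", res_name="GLY"):
    """A Cα-only chain at arbitrary author numbering (test helper)."""
    atoms = []
    for i, seq in enumerate(res_seqs):
        atoms.append(AtomRecord(
            serial=i + 1, name="CA", element="C", alt_loc="",
            res_name=res_name, chain_id=chain_id, res_seq=int(seq),
            coords=(3.8 * i + offset, 0.1 * (i % 3), 0.0),
        ))
    return FibrilModel(atoms)


@pytest.fixture
def numbered_chain():
    """Cα-only chain spanning author residues 341..449 (109 residues)."""
    return ca_chain(range(341, 450))


def random_rotation(rng):
    """Uniform-ish random proper rotation from a random rotation vector."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
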