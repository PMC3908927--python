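import numpy as np
import pytest

from lnbench.structures import Atom, ComplexStructure


def make_structure(entries, structure_id="test", centers=None):
    """Build a ComplexStructure from (element, xyz) tuples."""
    atoms = [Atom(el, f"{el}{i + 1}", np.asarray(xyz, float))
             for i, (el, xyz) in enumerate(entries)]
    if centers is None:
        centers = tuple(i for i, (el, _) in enumerate(entries)
                        if el in ("Dy", "Ho", "Er"))
    return ComplexStructure(structure_id, atoms, tuple(centers))


@pytest.fixture
def square_planar():
    """Dy center with four O donors in a 2.4 Å square-planar arrangement."""
    r = 2.4
    return make_structure([
        ("Dy", (0, 0, 0)),
        ("O", (r, 0, 0)), ("O", (-r, 0, 0)), ("O", (0, r, 0)), ("O", (0, -r, 0)),
    ], "square")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
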