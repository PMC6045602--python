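import numpy as np
import pytest

from resistograph import synth


def pdb_line(
    serial,
    name,
    resname,
    chain,
    resnum,
    x,
    y,
    z,
    occ=1.00,
    alt="",
    element=None,
    record="ATOM",
    icode="",
):
    """Format one fixed-column PDB coordinate record."""
    element = element if element is not None else name.strip()[0]
    return (
        f"{record:<6}{serial:>5} {name:<4}{alt:1}{resname:>3} {chain:1}"
        f"{resnum:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def pdb_builder():
    return pdb_line


@pytest.fixture
def toy_helix():
    return synth.gen_toy_structure(10, "ideal_helix")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
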