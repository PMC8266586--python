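import numpy as np
import pytest

from if3cycle.structure import Structure
from if3cycle.synthetic import ToyStructureSpec, gen_toy_structure


@pytest.fixture()
def isolated_pair():
    """Two attachment atoms 80 A apart, nothing else (unobstructed AVs)."""
    return gen_toy_structure(ToyStructureSpec(geometry="isolated-attachment",
                                              separation=80.0))


@pytest.fixture()
def slab_structure():
    """Attachment atom over a dense slab occluding the lower half-space."""
    return gen_toy_structure(ToyStructureSpec(geometry="slab"))


@pytest.fixture()
def cluttered_structure():
    """Attachment atom amid a small reproducible cluster of obstacle atoms.

    Small enough (<= 50 atoms) for brute-force accessible-volume oracles.
    """
    rng = np.random.default_rng(20240917)
    n_obstacles = 24
    # obstacles in a shell 5.5-11 A out: they occlude directions without
    # burying the site for the default 4.5 A linker width
    dirs = rng.normal(size=(n_obstacles, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(5.5, 11.0, size=n_obstacles)
    coords = np.vstack([[0.0, 0.0, 0.0], dirs * radii[:, None]])
    elements = np.array(["S"] + ["C"] * n_obstacles)
    from if3cycle.structure import vdw_radius
    return Structure(
        serial=np.arange(1, n_obstacles + 2),
        name=np.array(["SG"] + ["C"] * n_obstacles),
        element=elements,
        res_seq=np.arange(1, n_obstacles + 2),
        res_name=np.array(["CYS"] + ["OBS"] * n_obstacles),
        chain=np.array(["A"] * (n_obstacles + 1)),
        coords=coords,
        radii=np.array([vdw_radius(e) for e in elements]),
        source="fixture:cluttered",
    )
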