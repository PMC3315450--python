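import numpy as np
import pytest

from dynevo.structure_io import Structure, Trajectory


def make_pdb(coords, res_names=None, res_numbers=None, models=None,
             atom_names=None):
    """Build a minimal PDB string by hand (independent of the package writer)."""
    n = len(coords) if models is None else len(models[0])
    res_names = res_names or ["ALA"] * n
    res_numbers = res_numbers or list(range(1, n + 1))
    atom_names = atom_names or ["CA"] * n
    frames = [coords] if models is None else models
    lines = []
    for m, frame in enumerate(frames, start=1):
        if len(frames) > 1:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for (x, y, z), nm, no, at in zip(frame, res_names, res_numbers, atom_names):
            pad = "" if len(at) >= 4 else " "
            lines.append(
                f"ATOM  {serial:5d} {pad}{at:<3s} {nm:<3s} A{no:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        if len(frames) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_residue_pdb():
    return make_pdb([(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (7.6, 0.0, 0.0)],
                    res_names=["ALA", "GLY", "LEU"])


@pytest.fixture
def random_structure(rng):
    def _make(n=10, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        coords = r.normal(scale=5.0, size=(n, 3))
        names = ["LEU" if i % 2 == 0 else "SER" for i in range(n)]
        return Structure(np.arange(1, n + 1), names, coords)
    return _make


@pytest.fixture
def small_trajectory(rng):
    """15-frame, 6-site trajectory with non-trivial internal motion."""
    base = rng.normal(scale=4.0, size=(6, 3))
    frames = base[None] + rng.normal(scale=0.4, size=(15, 6, 3))
    return Trajectory(frames, np.arange(1, 7), ["ALA"] * 6)
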