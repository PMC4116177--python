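import numpy as np
import pytest

from erdesign.structure_io import AtomRecord, ResidueKey, StructureModel


def make_atom(name, element, xyz, het=False, serial=1, occ=1.0, alt=""):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt,
        occupancy=occ,
        coords=np.asarray(xyz, dtype=float),
        is_hetero=het,
    )


@pytest.fixture
def toy_met_complex():
    """A single MET residue (full backbone + side chain) plus a hexagonal
    aromatic 6-ring ligand ~5 Å away — the smallest complex on which the
    whole mutate/score/proximity chain runs."""
    res = ResidueKey("A", 421, "", "MET")
    atoms = [
        make_atom("N", "N", [0, 0, 0]),
        make_atom("CA", "C", [1.458, 0, 0]),
        make_atom("C", "C", [2.0, 1.42, 0]),
        make_atom("O", "O", [1.3, 2.4, 0]),
        make_atom("CB", "C", [2.0, -0.77, 1.2]),
        make_atom("CG", "C", [3.5, -0.9, 1.2]),
        make_atom("SD", "S", [4.2, -2.0, 2.4]),
        make_atom("CE", "C", [5.9, -1.8, 2.2]),
    ]
    ring = []
    for i in range(6):
        a = np.deg2rad(60 * i)
        ring.append(
            make_atom(
                f"C{i + 1}",
                "C",
                [5 + 1.39 * np.cos(a), 5 + 1.39 * np.sin(a), 5],
                het=True,
                serial=10 + i,
            )
        )
    lig_key = ResidueKey("L", 1, "", "BPA")
    model = StructureModel("toy", {res: atoms, lig_key: ring})
    return model, res, lig_key
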