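"""Shared fixtures: small hand-built molecules and text records."""

from __future__ import annotations

import numpy as np
import pytest

from posekit.graph import AtomNode, Bond, BondOrder, MoleculeGraph


def mk(spec: list[tuple[str, tuple[float, float, float]]],
       bonds: list[tuple[int, int] | tuple[int, int, BondOrder]],
       name: str = "") -> MoleculeGraph:
    """Terse molecule builder: [(element, xyz), ...], [(i, j[, order]), ...]."""
    atoms = [AtomNode(e, xyz, i) for i, (e, xyz) in enumerate(spec)]
    bl = [Bond(*b) if len(b) == 3 else Bond(b[0], b[1]) for b in bonds]
    return MoleculeGraph(atoms, bl, name=name)


@pytest.fixture
def ethanol() -> MoleculeGraph:
    """C2H6O with explicit hydrogens (9 atoms, 8 bonds)."""
    heavy = [("C", (0.0, 0.0, 0.0)), ("C", (1.5, 0.0, 0.0)), ("O", (2.2, 1.2, 0.0))]
    hs = [("H", (-0.5, 0.9, 0.0)), ("H", (-0.5, -0.9, 0.0)), ("H", (0.0, 0.0, 1.0)),
          ("H", (1.9, -1.0, 0.0)), ("H", (1.9, 0.5, 0.9)), ("H", (3.1, 1.0, 0.0))]
    bonds = [(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)]
    return mk(heavy + hs, bonds, name="ethanol")


def benzene_ring(kekule: bool, z: float = 0.0, radius: float = 1.39) -> MoleculeGraph:
    spec = []
    for k in range(6):
        th = 2 * np.pi * k / 6
        spec.append(("C", (radius * np.cos(th), radius * np.sin(th), z)))
    orders = (
        [BondOrder.SINGLE, BondOrder.DOUBLE] * 3 if kekule else [BondOrder.AROMATIC] * 6
    )
    bonds = [(k, (k + 1) % 6, orders[k]) for k in range(6)]
    return mk(spec, bonds, name="benzene")


@pytest.fixture
def benzene_kekule() -> MoleculeGraph:
    return benzene_ring(kekule=True)


@pytest.fixture
def benzene_aromatic() -> MoleculeGraph:
    return benzene_ring(kekule=False)


@pytest.fixture
def propane() -> MoleculeGraph:
    return mk([("C", (0, 0, 0)), ("C", (1.5, 0, 0)), ("C", (3.0, 0, 0))],
              [(0, 1), (1, 2)], name="propane")


@pytest.fixture
def acetone() -> MoleculeGraph:
    return mk(
        [("C", (0, 0, 0)), ("C", (1.5, 0, 0)), ("C", (3.0, 0, 0)), ("O", (1.5, 1.25, 0))],
        [(0, 1), (1, 2), (1, 3, BondOrder.DOUBLE)],
        name="acetone",
    )


ETHANOL_SDF = """ethanol
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2000    1.2000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""


VINA_PDBQT = """MODEL 1
REMARK VINA RESULT:    -7.5      0.000      0.000
ATOM      1  C   LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C
ATOM      2  OA  LIG A   1       1.400   0.000   0.000  1.00  0.00    -0.200 OA
ENDMDL
MODEL 2
REMARK VINA RESULT:    -7.1      1.200      2.100
ATOM      1  C   LIG A   1       0.500   0.000   0.000  1.00  0.00    +0.000 C
ATOM      2  OA  LIG A   1       1.900   0.000   0.000  1.00  0.00    -0.200 OA
ENDMDL
MODEL 3
REMARK VINA RESULT:    -6.0      2.000      3.500
ATOM      1  C   LIG A   1       1.000   0.000   0.000  1.00  0.00    +0.000 C
ATOM      2  OA  LIG A   1       2.400   0.000   0.000  1.00  0.00    -0.200 OA
ENDMDL
"""
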