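"""Shared fixtures: toy molecule builders, an inline MOL2 fixture, and an
exhaustive maximum-common-substructure oracle for small graphs."""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import pytest

from ties_kit.ligand import Ligand, from_arrays


def make_ligand(name, elements, bonds, charges=None):
    """Toy ligand with dummy coordinates."""
    n = len(elements)
    charges = charges if charges is not None else [0.0] * n
    coords = [(float(i), 0.0, 0.0) for i in range(n)]
    return from_arrays(name, elements, charges, coords, bonds)


def chain(name, elements, charges=None):
    bonds = [(i, i + 1) for i in range(len(elements) - 1)]
    return make_ligand(name, elements, bonds, charges)


def ring(name, elements, charges=None, extra_bonds=()):
    n = len(elements)
    bonds = [(i, (i + 1) % n) for i in range(n)] + list(extra_bonds)
    return make_ligand(name, elements, bonds, charges)


def exhaustive_mcs_size(l1: Ligand, l2: Ligand) -> int:
    """Brute-force maximum connected common induced subgraph size.

    Enumerates every connected node subset of the first graph and every
    element-consistent bijection onto the second, checking induced edge
    agreement.  Only feasible for a handful of atoms — that is the point:
    it shares no code with the production search.
    """
    g1, g2 = l1.graph(), l2.graph()
    n1 = list(g1.nodes)
    best = 0
    for k in range(min(len(g1), len(g2)), 0, -1):
        if k <= best:
            break
        for sub1 in combinations(n1, k):
            sg1 = g1.subgraph(sub1)
            if not nx.is_connected(sg1):
                continue
            for sub2 in combinations(g2.nodes, k):
                for perm in permutations(sub2):
                    if any(
                        g1.nodes[a]["element"] != g2.nodes[b]["element"]
                        for a, b in zip(sub1, perm)
                    ):
                        continue
                    mapping = dict(zip(sub1, perm))
                    if all(
                        g1.has_edge(a, b) == g2.has_edge(mapping[a], mapping[b])
                        for a, b in combinations(sub1, 2)
                    ):
                        best = max(best, k)
                        break
                if best == k:
                    break
            if best == k:
                break
    return best


ETHANOL_MOL2 = """@<TRIPOS>MOLECULE
ethanol
 9 8 1 0 0
SMALL
USER_CHARGES

@<TRIPOS>ATOM
      1 C1      -0.8930    0.1240   -0.0360 C.3     1  LIG1       -0.0970
      2 C2       0.5590   -0.3170    0.0250 C.3     1  LIG1        0.1310
      3 O1       1.3820    0.8210    0.0900 O.3     1  LIG1       -0.6000
      4 H1      -1.5420   -0.7480   -0.0800 H       1  LIG1        0.0450
      5 H2      -1.1210    0.7320    0.8420 H       1  LIG1        0.0450
      6 H3      -1.0870    0.7170   -0.9330 H       1  LIG1        0.0450
      7 H4       0.7600   -0.9340   -0.8550 H       1  LIG1        0.0350
      8 H5       0.7360   -0.9020    0.9310 H       1  LIG1        0.0350
      9 H6       2.2890    0.5130    0.1390 H       1  LIG1        0.3610
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    1    4 1
     4    1    5 1
     5    1    6 1
     6    2    7 1
     7    2    8 1
     8    2    9 1
"""

NO_CHARGES_MOL2 = """@<TRIPOS>MOLECULE
methane
 1 0 1 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1       0.0000    0.0000    0.0000 C.3     1  LIG1
@<TRIPOS>BOND
"""


@pytest.fixture
def ethanol_mol2(tmp_path):
    p = tmp_path / "ethanol.mol2"
    p.write_text(ETHANOL_MOL2)
    return p


@pytest.fixture
def no_charges_mol2(tmp_path):
    p = tmp_path / "nocharges.mol2"
    p.write_text(NO_CHARGES_MOL2)
    return p
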