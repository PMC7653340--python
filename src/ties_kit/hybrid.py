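"""Dual-topology hybrid ligand construction.

The hybrid ligand used in a relative alchemical transformation combines a
shared *core* with a *disappearing* region (atoms unique to the initial
ligand, present at λ=0) and an *appearing* region (atoms unique to the final
ligand, present at λ=1).  The core is found as a maximum connected common
substructure (MCS) of the two molecular graphs, matched on element symbol
and bond topology, then pruned in two passes:

1. ring completeness — a mapped atom belonging to a ring (in either ligand)
   that is not entirely mapped is dropped, iterated to a fixed point;
2. charge tolerance — mapped pairs whose partial charges differ by more than
   a tolerance (default 0.1 e) are dropped, together with every ring they
   belong to, and ring completeness is re-applied.

Surviving core atoms take the arithmetic mean of the two endpoint charges;
the resulting drift of each physical end state's net charge is repaired by
spreading the residual over that end state's alchemical-region atoms (or the
core when the region is empty), so both endpoint net charges are preserved
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import MappingStageError, SchemaError
from .ligand import Ligand

__all__ = [
    "AtomMapping",
    "PrunedAtom",
    "CoreAtom",
    "HybridTopology",
    "find_common_substructure",
    "filter_incomplete_rings",
    "filter_charge_mismatch",
    "build_hybrid",
    "make_hybrid",
    "write_hybrid",
    "read_hybrid",
]

HYBRID_SCHEMA = "ties-kit/hybrid-topology"
HYBRID_SCHEMA_VERSION = 1

STAGE_MCS = "mcs"
STAGE_RING = "after_ring_filter"
STAGE_CHARGE = "after_charge_filter"
_STAGES = (STAGE_MCS, STAGE_RING, STAGE_CHARGE)


@dataclass(frozen=True)
class PrunedAtom:
    """Provenance record: one mapped pair removed by a filtering stage."""

    stage: str  # "ring_filter" | "charge_filter"
    l1_index: int
    l2_index: int
    reason: str


@dataclass
class AtomMapping:
    """Injective pairing of atoms between two ligands.

    ``pairs`` holds (index in L1, index in L2); ``source_stage`` records how
    far through the pruning pipeline the mapping has progressed and is
    checked by each downstream stage.  ``provenance`` accumulates every pair
    removed by a filter, with the reason.
    """

    pairs: list[tuple[int, int]]
    source_stage: str = STAGE_MCS
    provenance: list[PrunedAtom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source_stage not in _STAGES:
            raise ValueError(f"unknown stage {self.source_stage!r}")
        self.pairs = sorted((int(a), int(b)) for a, b in self.pairs)
        l1 = [a for a, _ in self.pairs]
        l2 = [b for _, b in self.pairs]
        if len(set(l1)) != len(l1) or len(set(l2)) != len(l2):
            raise ValueError("mapping is not injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    def l1_indices(self) -> set[int]:
        return {a for a, _ in self.pairs}

    def l2_indices(self) -> set[int]:
        return {b for _, b in self.pairs}

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)


# ---------------------------------------------------------------------------
# maximum connected common substructure


def find_common_substructure(
    l1: Ligand, l2: Ligand, match_bond_order: bool = False
) -> AtomMapping:
    """Maximum connected common substructure of two ligands.

    Atoms match on element symbol; the mapped subgraphs must be *induced*
    (a bond exists between two mapped atoms of L1 exactly when it exists
    between their images in L2) and connected.  Among equally large
    mappings, the lexicographically smallest pair sequence is returned,
    evaluated with the two ligands in a canonical order (so the choice is
    both reproducible and independent of argument order: swapping the
    ligands mirrors the mapping).

    The search is an exact branch-and-bound over pair extensions, seeded at
    every compatible atom pair.  Exponential in the worst case, as maximum
    common subgraph is NP-hard, but fast on element-labelled ligand-sized
    graphs.  ``match_bond_order`` is accepted for interface compatibility;
    bonds in :class:`~ties_kit.ligand.Ligand` carry no order, so it has no
    effect there.
    """
    del match_bond_order

    def ligand_key(l: Ligand):
        return (
            l.n_atoms,
            tuple(a.element for a in l.atoms),
            tuple(l.bonds),
            tuple(a.charge for a in l.atoms),
            l.name,
        )

    # canonical argument order: the lex tie-break below depends on which
    # ligand owns the first index, so evaluate in a fixed order and mirror
    if ligand_key(l2) < ligand_key(l1):
        swapped = find_common_substructure(l2, l1)
        return AtomMapping(
            pairs=[(b, a) for a, b in swapped.pairs], source_stage=STAGE_MCS
        )

    g1, g2 = l1.graph(), l2.graph()
    adj1 = {i: set(g1.neighbors(i)) for i in g1}
    adj2 = {j: set(g2.neighbors(j)) for j in g2}
    elem1 = {i: g1.nodes[i]["element"] for i in g1}
    elem2 = {j: g2.nodes[j]["element"] for j in g2}

    from collections import Counter

    def bound(mapped1: set[int], used2: set[int]) -> int:
        # per-element availability of unmapped atoms caps any extension
        c1 = Counter(elem1[i] for i in g1 if i not in mapped1)
        c2 = Counter(elem2[j] for j in g2 if j not in used2)
        return sum(min(c1[e], c2[e]) for e in c1)

    best: list[tuple[int, int]] = []

    def better(cand: list[tuple[int, int]]) -> bool:
        if len(cand) != len(best):
            return len(cand) > len(best)
        return sorted(cand) < sorted(best)

    def extensions(
        mapping: dict[int, int], used2: set[int], forbidden: set[tuple[int, int]]
    ) -> list[tuple[int, int]]:
        """Pairs (i, j) that extend ``mapping`` keeping it induced and connected."""
        out = []
        images = set(mapping.values())
        frontier1 = {n for i in mapping for n in adj1[i] if n not in mapping}
        for i in sorted(frontier1):
            req = {mapping[n] for n in adj1[i] if n in mapping}
            for j in sorted(set(adj2) - used2):
                if (i, j) in forbidden or elem2[j] != elem1[i]:
                    continue
                if (adj2[j] & images) != req:
                    continue  # induced-subgraph consistency
                out.append((i, j))
        return out

    def grow(
        mapping: dict[int, int], used2: set[int], forbidden: set[tuple[int, int]]
    ) -> None:
        nonlocal best
        cand = list(mapping.items())
        if better(cand):
            best = cand
        if len(mapping) + bound(set(mapping), used2) < len(best):
            return
        # exclude-after-explore: once a branch taking pair e is exhausted, e
        # is forbidden in the sibling branches, so each candidate mapping is
        # visited exactly once regardless of insertion order
        banned: set[tuple[int, int]] = set()
        for i, j in extensions(mapping, used2, forbidden):
            mapping[i] = j
            used2.add(j)
            grow(mapping, used2, forbidden | banned)
            del mapping[i]
            used2.discard(j)
            banned.add((i, j))

    seed_banned: set[tuple[int, int]] = set()
    for i in sorted(g1):
        for j in sorted(g2):
            if elem1[i] == elem2[j]:
                grow({i: j}, {j}, set(seed_banned))
                seed_banned.add((i, j))
    return AtomMapping(pairs=best, source_stage=STAGE_MCS)


# ---------------------------------------------------------------------------
# pruning filters


def _ring_fixed_point(
    pairs: list[tuple[int, int]],
    l1: Ligand,
    l2: Ligand,
    provenance: list[PrunedAtom],
    stage_tag: str,
) -> list[tuple[int, int]]:
    """Drop mapped atoms in incompletely mapped rings until nothing changes."""
    rings1 = l1.rings()
    rings2 = l2.rings()
    pairs = list(pairs)
    while True:
        fwd = dict(pairs)
        rev = {b: a for a, b in pairs}
        doomed1: set[int] = set()
        for ring in rings1:
            hit = ring & fwd.keys()
            if hit and hit != ring:
                doomed1 |= hit
        for ring in rings2:
            hit = ring & rev.keys()
            if hit and hit != ring:
                doomed1 |= {rev[b] for b in hit}
        if not doomed1:
            return pairs
        for a in sorted(doomed1):
            provenance.append(
                PrunedAtom(stage_tag, a, fwd[a], "member of incompletely mapped ring")
            )
        pairs = [(a, b) for a, b in pairs if a not in doomed1]


def filter_incomplete_rings(mapping: AtomMapping, l1: Ligand, l2: Ligand) -> AtomMapping:
    """Remove mapped atoms whose rings are only partially mapped.

    A ring (minimum-cycle-basis ring of either ligand) must be mapped in its
    entirety or not at all; partial rings would leave dangling alchemical
    ring fragments.  Applied iteratively to a fixed point.
    """
    if mapping.source_stage != STAGE_MCS:
        raise MappingStageError(
            f"ring filter expects stage {STAGE_MCS!r}, got {mapping.source_stage!r}"
        )
    provenance = list(mapping.provenance)
    pairs = _ring_fixed_point(mapping.pairs, l1, l2, provenance, "ring_filter")
    return AtomMapping(pairs=pairs, source_stage=STAGE_RING, provenance=provenance)


def filter_charge_mismatch(
    mapping: AtomMapping, l1: Ligand, l2: Ligand, tolerance: float = 0.1
) -> AtomMapping:
    """Remove mapped pairs whose partial charges differ by more than
    ``tolerance`` (e), together with any ring such an atom belongs to, then
    restore ring completeness.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    if mapping.source_stage != STAGE_RING:
        raise MappingStageError(
            f"charge filter expects stage {STAGE_RING!r}, got {mapping.source_stage!r}"
        )
    provenance = list(mapping.provenance)
    fwd = mapping.as_dict()
    rev = {b: a for a, b in mapping.pairs}
    doomed1: set[int] = set()
    reasons: dict[int, str] = {}
    for a, b in mapping.pairs:
        dq = abs(l1.atoms[a].charge - l2.atoms[b].charge)
        if dq > tolerance:
            doomed1.add(a)
            reasons[a] = f"charge difference {dq:.4f} e exceeds tolerance {tolerance} e"
    # an over-tolerance atom takes its whole ring with it
    ring_doom: set[int] = set()
    for ring in l1.rings():
        if ring & doomed1:
            ring_doom |= ring & fwd.keys()
    for ring in l2.rings():
        if {fwd[a] for a in doomed1 if a in fwd} & ring:
            ring_doom |= {rev[b] for b in ring if b in rev}
    for a in sorted(ring_doom - doomed1):
        reasons[a] = "member of a ring containing an over-tolerance atom"
    doomed1 |= ring_doom
    for a in sorted(doomed1):
        provenance.append(PrunedAtom("charge_filter", a, fwd[a], reasons[a]))
    pairs = [(a, b) for a, b in mapping.pairs if a not in doomed1]
    pairs = _ring_fixed_point(pairs, l1, l2, provenance, "charge_filter")
    return AtomMapping(pairs=pairs, source_stage=STAGE_CHARGE, provenance=provenance)


# ---------------------------------------------------------------------------
# hybrid assembly


@dataclass(frozen=True)
class CoreAtom:
    """One core pair: indices in both ligands and the averaged charge."""

    l1_index: int
    l2_index: int
    charge: float  # (q1 + q2) / 2, before endpoint correction offsets


@dataclass
class HybridTopology:
    """Core / disappearing / appearing partition of a dual-topology hybrid.

    ``disappearing`` and ``appearing`` atoms carry their endpoint charges
    including any net-charge correction; core atoms carry the averaged
    charge with per-state offsets (``core_state*_offset``) that are non-zero
    only when an alchemical region was empty and the correction had to be
    spread over the core.
    """

    ligand1: str
    ligand2: str
    core: list[CoreAtom]
    disappearing: list[tuple[int, float]]  # (L1 index, state-0 charge)
    appearing: list[tuple[int, float]]  # (L2 index, state-1 charge)
    core_state0_offset: float = 0.0
    core_state1_offset: float = 0.0
    provenance: list[PrunedAtom] = field(default_factory=list)

    def state0_charges(self) -> dict[int, float]:
        """Per-atom charges of the λ=0 end state, keyed by L1 atom index."""
        q = {c.l1_index: c.charge + self.core_state0_offset for c in self.core}
        q.update(dict(self.disappearing))
        return q

    def state1_charges(self) -> dict[int, float]:
        """Per-atom charges of the λ=1 end state, keyed by L2 atom index."""
        q = {c.l2_index: c.charge + self.core_state1_offset for c in self.core}
        q.update(dict(self.appearing))
        return q

    @property
    def n_core(self) -> int:
        return len(self.core)

    def summary(self) -> str:
        lines = [
            f"Hybrid topology {self.ligand1} -> {self.ligand2}",
            f"  core atoms        : {len(self.core)}",
            f"  disappearing (L1) : {len(self.disappearing)}",
            f"  appearing    (L2) : {len(self.appearing)}",
            f"  pruned pairs      : {len(self.provenance)}",
            f"  state-0 net charge: {sum(self.state0_charges().values()):+.6f} e",
            f"  state-1 net charge: {sum(self.state1_charges().values()):+.6f} e",
        ]
        return "\n".join(lines)


def build_hybrid(
    l1: Ligand,
    l2: Ligand,
    mapping: AtomMapping,
    charge_correction: bool = True,
) -> HybridTopology:
    """Assemble the hybrid from a fully filtered mapping.

    Core charges are the per-pair arithmetic means.  Averaging shifts each
    end state's net charge by half the core charge difference; when
    ``charge_correction`` is on (default) the residual is redistributed
    equally over that end state's alchemical-region atoms so the physical
    endpoints keep their original net charges exactly.
    """
    if mapping.source_stage != STAGE_CHARGE:
        raise MappingStageError(
            f"build_hybrid expects stage {STAGE_CHARGE!r}, got {mapping.source_stage!r}"
        )
    core = [
        CoreAtom(a, b, (l1.atoms[a].charge + l2.atoms[b].charge) / 2.0)
        for a, b in mapping.pairs
    ]
    dis_idx = sorted(set(range(l1.n_atoms)) - mapping.l1_indices())
    app_idx = sorted(set(range(l2.n_atoms)) - mapping.l2_indices())
    disappearing = [(i, l1.atoms[i].charge) for i in dis_idx]
    appearing = [(j, l2.atoms[j].charge) for j in app_idx]
    off0 = off1 = 0.0
    if charge_correction:
        res0 = l1.net_charge - (sum(c.charge for c in core) + sum(q for _, q in disappearing))
        res1 = l2.net_charge - (sum(c.charge for c in core) + sum(q for _, q in appearing))
        if disappearing:
            disappearing = [(i, q + res0 / len(disappearing)) for i, q in disappearing]
        elif core:
            off0 = res0 / len(core)
        if appearing:
            appearing = [(j, q + res1 / len(appearing)) for j, q in appearing]
        elif core:
            off1 = res1 / len(core)
    return HybridTopology(
        ligand1=l1.name,
        ligand2=l2.name,
        core=core,
        disappearing=disappearing,
        appearing=appearing,
        core_state0_offset=off0,
        core_state1_offset=off1,
        provenance=list(mapping.provenance),
    )


def make_hybrid(
    l1: Ligand,
    l2: Ligand,
    tolerance: float = 0.1,
    charge_correction: bool = True,
) -> HybridTopology:
    """Full pipeline: MCS -> ring filter -> charge filter -> hybrid."""
    m = find_common_substructure(l1, l2)
    m = filter_incomplete_rings(m, l1, l2)
    m = filter_charge_mismatch(m, l1, l2, tolerance=tolerance)
    return build_hybrid(l1, l2, m, charge_correction=charge_correction)


# ---------------------------------------------------------------------------
# hybrid document I/O (versioned JSON schema)


def write_hybrid(h: HybridTopology, path: str | Path) -> None:
    """Serialize a hybrid topology to the versioned JSON document."""
    doc = {
        "schema": HYBRID_SCHEMA,
        "version": HYBRID_SCHEMA_VERSION,
        "ligand1": h.ligand1,
        "ligand2": h.ligand2,
        "core": [[c.l1_index, c.l2_index, c.charge] for c in h.core],
        "disappearing": [[i, q] for i, q in h.disappearing],
        "appearing": [[j, q] for j, q in h.appearing],
        "core_state0_offset": h.core_state0_offset,
        "core_state1_offset": h.core_state1_offset,
        "provenance": [
            {"stage": p.stage, "l1_index": p.l1_index, "l2_index": p.l2_index, "reason": p.reason}
            for p in h.provenance
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_hybrid(path: str | Path) -> HybridTopology:
    """Read a hybrid-topology JSON document back into memory."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != HYBRID_SCHEMA:
        raise SchemaError(f"{path}: schema is not {HYBRID_SCHEMA!r}")
    if doc.get("version") != HYBRID_SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema version {doc.get('version')!r}")
    return HybridTopology(
        ligand1=doc["ligand1"],
        ligand2=doc["ligand2"],
        core=[CoreAtom(int(a), int(b), float(q)) for a, b, q in doc["core"]],
        disappearing=[(int(i), float(q)) for i, q in doc["disappearing"]],
        appearing=[(int(j), float(q)) for j, q in doc["appearing"]],
        core_state0_offset=float(doc["core_state0_offset"]),
        core_state1_offset=float(doc["core_state1_offset"]),
        provenance=[
            PrunedAtom(p["stage"], int(p["l1_index"]), int(p["l2_index"]), p["reason"])
            for p in doc["provenance"]
        ],
    )
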