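"""Neuron morphologies as trees of cylindrical sections.

A morphology is a rooted tree of :class:`Section` objects (cylinders with a
length and diameter). The root is conventionally the soma, represented as a
sphere-equivalent cylinder (length = diameter, so the lateral area equals the
sphere surface). Stimulus and recording locations are specified as *path
distances* in micrometres measured along the dendrite from its origin at the
soma; the soma's own extent does not contribute to path distance.

Spatial discretization follows the rule that every electrical compartment
("segment") must be no longer than one tenth of the section's AC length
constant at 100 Hz, or 10 um, whichever is smaller, using an odd number of
segments per section so that a segment center always sits at the section
midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
import numpy as np
import pandas as pd

__all__ = [
    "SectionKind",
    "Section",
    "Morphology",
    "MorphologyError",
    "SWCFormatError",
    "build_ball_and_stick",
    "attach_axon",
    "load_swc",
    "write_swc",
    "discretize",
    "lambda_f",
]


class MorphologyError(ValueError):
    """Invalid morphology parameters or structure."""


class SWCFormatError(ValueError):
    """Malformed SWC content; the message names the offending line."""


class SectionKind(str, Enum):
    SOMA = "soma"
    BASAL = "basal"
    APICAL = "apical"
    AXON_HILLOCK = "axon_hillock"
    AXON_MYELIN = "axon_myelin"
    AXON_NODE = "axon_node"


_DENDRITIC = (SectionKind.BASAL, SectionKind.APICAL)


@dataclass(frozen=True)
class Section:
    """A cylindrical cable section.

    ``length`` and ``diameter`` are in micrometres. ``spine_corrected``
    marks terminal dendrites whose passive membrane (capacitance and leak
    conductance) is scaled by 2.0 to account for unmodeled spine area.
    """

    id: int
    parent_id: int | None
    kind: SectionKind
    length: float
    diameter: float
    spine_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if not (self.diameter > 0):
            raise MorphologyError(f"section {self.id}: diameter must be > 0")


@dataclass
class Morphology:
    """A tree of sections plus the per-section electrical segment counts."""

    sections: list[Section]
    nseg: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.sections}
        if len(self._by_id) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        # cycle / dangling-parent check via iterative root-walk
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent_id is not None:
                if cur.parent_id not in self._by_id:
                    raise MorphologyError(
                        f"section {cur.id} references missing parent {cur.parent_id}"
                    )
                if cur.id in seen:
                    raise MorphologyError(f"cycle detected at section {cur.id}")
                seen.add(cur.id)
                cur = self._by_id[cur.parent_id]
        for sid, n in self.nseg.items():
            if n < 1:
                raise MorphologyError(f"section {sid}: nseg must be >= 1")

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> Section:
        return self._root

    def section(self, sid: int) -> Section:
        return self._by_id[sid]

    def children(self, sid: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sid]

    def sections_of_kind(self, *kinds: SectionKind) -> list[Section]:
        return [s for s in self.sections if s.kind in kinds]

    @property
    def basal_ids(self) -> list[int]:
        return [s.id for s in self.sections if s.kind is SectionKind.BASAL]

    def path_start(self, sid: int) -> float:
        """Path distance (um) from the soma to the proximal end of a section.

        The soma (and any ancestor soma sections) contribute zero length, so
        a dendrite attached directly to the soma starts at distance 0.
        """
        d = 0.0
        cur = self._by_id[sid]
        while cur.parent_id is not None:
            cur = self._by_id[cur.parent_id]
            if cur.kind is not SectionKind.SOMA:
                d += cur.length
        return d

    def path_distance(self, sid: int, offset: float = None) -> float:
        """Path distance from the soma to a point ``offset`` um along a section.

        With ``offset`` omitted, returns the distance to the distal end.
        """
        sec = self._by_id[sid]
        if offset is None:
            offset = sec.length
        if not (0 <= offset <= sec.length + 1e-9):
            raise MorphologyError(
                f"offset {offset} outside section {sid} of length {sec.length}"
            )
        return self.path_start(sid) + offset

    def total_length(self) -> float:
        return float(sum(s.length for s in self.sections))

    def fingerprint(self) -> tuple:
        """Hashable identity of the tree and its discretization."""
        return (
            tuple(
                (s.id, s.parent_id, s.kind.value, s.length, s.diameter, s.spine_corrected)
                for s in self.sections
            ),
            tuple(sorted(self.nseg.items())),
        )

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "parent_id": -1 if s.parent_id is None else s.parent_id,
                "kind": s.kind.value,
                "length_um": s.length,
                "diameter_um": s.diameter,
                "spine_corrected": s.spine_corrected,
                "nseg": self.nseg.get(s.id, 1),
                "path_start_um": self.path_start(s.id),
            }
            for s in self.sections
        ]
        return pd.DataFrame(rows)


# -- builders --------------------------------------------------------------

def build_ball_and_stick(
    n_basal: int,
    dend_length: float,
    dend_diam: float,
    soma_diam: float,
) -> Morphology:
    """Isopotential soma with ``n_basal`` identical terminal basal dendrites.

    The soma is a sphere-equivalent cylinder (length = diameter). Terminal
    dendrites carry the spine area correction flag.
    """
    if n_basal < 1:
        raise MorphologyError("n_basal must be >= 1")
    if min(dend_length, dend_diam, soma_diam) <= 0:
        raise MorphologyError("all dimensions must be > 0")
    sections = [Section(0, None, SectionKind.SOMA, soma_diam, soma_diam)]
    for i in range(n_basal):
        sections.append(
            Section(i + 1, 0, SectionKind.BASAL, dend_length, dend_diam,
                    spine_corrected=True)
        )
    return Morphology(sections)


def attach_axon(
    m: Morphology,
    hillock_length: float = 10.0,
    hillock_diam: float = 2.0,
    n_internodes: int = 3,
    internode_length: float = 100.0,
    internode_diam: float = 1.5,
    node_length: float = 1.0,
    node_diam: float = 1.0,
) -> Morphology:
    """Append a myelinated axon (hillock + internode/node chain) to the soma.

    The hillock and nodes are non-myelinated (high sodium density regions);
    internodes carry myelin passive properties.
    """
    next_id = max(s.id for s in m.sections) + 1
    sections = list(m.sections)
    parent = m.root.id
    sections.append(
        Section(next_id, parent, SectionKind.AXON_HILLOCK, hillock_length, hillock_diam)
    )
    parent = next_id
    next_id += 1
    for _ in range(n_internodes):
        sections.append(
            Section(next_id, parent, SectionKind.AXON_MYELIN,
                    internode_length, internode_diam)
        )
        parent = next_id
        next_id += 1
        sections.append(
            Section(next_id, parent, SectionKind.AXON_NODE, node_length, node_diam)
        )
        parent = next_id
        next_id += 1
    return Morphology(sections, dict(m.nseg))


# -- SWC I/O ---------------------------------------------------------------

_SWC_TO_KIND = {
    1: SectionKind.SOMA,
    2: SectionKind.AXON_HILLOCK,
    3: SectionKind.BASAL,
    4: SectionKind.APICAL,
}
_KIND_TO_SWC = {
    SectionKind.SOMA: 1,
    SectionKind.AXON_HILLOCK: 2,
    SectionKind.AXON_MYELIN: 2,
    SectionKind.AXON_NODE: 2,
    SectionKind.BASAL: 3,
    SectionKind.APICAL: 4,
}


def load_swc(path) -> Morphology:
    """Load a standard 7-column SWC file as a morphology.

    Contiguous chains of same-type points between branch points become
    sections; section length is the summed 3D point-to-point distance and
    diameter is twice the mean radius over the chain's points.
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(fields)}")
            try:
                pid = int(fields[0])
                ptype = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as e:
                raise SWCFormatError(f"line {lineno}: {e}") from None
            if pid in points:
                raise SWCFormatError(f"line {lineno}: duplicate point id {pid}")
            if ptype not in _SWC_TO_KIND:
                raise SWCFormatError(f"line {lineno}: unsupported SWC type {ptype}")
            points[pid] = (ptype, x, y, z, r, parent)
            order.append(pid)
    if not points:
        raise SWCFormatError("empty SWC file")
    roots = [pid for pid in order if points[pid][5] == -1]
    if len(roots) != 1:
        raise SWCFormatError(f"expected exactly one root point, found {len(roots)}")
    for pid in order:
        parent = points[pid][5]
        if parent != -1 and parent not in points:
            raise SWCFormatError(f"point {pid}: dangling parent reference {parent}")

    children: dict[int, list[int]] = {pid: [] for pid in order}
    for pid in order:
        parent = points[pid][5]
        if parent != -1:
            children[parent].append(pid)

    def is_break(pid: int) -> bool:
        """True when a chain must stop after this point."""
        ptype = points[pid][0]
        if len(children[pid]) != 1:
            return True
        return points[children[pid][0]][0] != ptype

    sections: list[Section] = []
    sec_of_point: dict[int, int] = {}
    next_sid = 0

    def emit(chain: list[int], parent_point: int | None) -> None:
        nonlocal next_sid
        ptype = points[chain[-1]][0]
        coords = [np.array(points[p][1:4]) for p in chain]
        if parent_point is not None:
            coords.insert(0, np.array(points[parent_point][1:4]))
        length = float(sum(np.linalg.norm(b - a) for a, b in zip(coords, coords[1:])))
        if length <= 0:
            raise SWCFormatError(
                f"chain ending at point {chain[-1]} has zero length"
            )
        diam = 2.0 * float(np.mean([points[p][4] for p in chain]))
        parent_sid = None if parent_point is None else sec_of_point[parent_point]
        kind = _SWC_TO_KIND[ptype]
        sections.append(Section(next_sid, parent_sid, kind, length, diam,
                                spine_corrected=(kind in _DENDRITIC)))
        for p in chain:
            sec_of_point[p] = next_sid
        next_sid += 1

    # walk chains: start a chain at the root and after every break point
    stack = [(roots[0], None)]
    while stack:
        start, parent_point = stack.pop()
        chain = [start]
        while not is_break(chain[-1]):
            chain.append(children[chain[-1]][0])
        end = chain[-1]
        if parent_point is None and len(chain) == 1 and not children[end]:
            raise SWCFormatError("single-point SWC defines no cable")
        if parent_point is None and len(chain) == 1:
            # a lone root point anchors its children but forms no section
            for c in children[end]:
                stack.append((c, end))
            sec_of_point[end] = None  # type: ignore[assignment]
            continue
        emit(chain, parent_point)
        for c in children[end]:
            stack.append((c, end))

    # a lone root point (e.g. a single-point soma with several children)
    # leaves multiple parentless sections: keep the first as root and attach
    # the siblings to it
    roots_in_secs = [s for s in sections if s.parent_id is None]
    if len(roots_in_secs) > 1:
        first = roots_in_secs[0]
        sections = [
            replace(s, parent_id=first.id)
            if s.parent_id is None and s.id != first.id
            else s
            for s in sections
        ]
    return Morphology(sections)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as SWC with synthetic straight-line coordinates.

    Geometry is generated (one point per section end, each sibling in a
    distinct direction) so that reloading preserves per-section lengths and
    diameters exactly; 3D shape is not meaningful.
    """
    # assign each section a direction; siblings fan out in the xy plane
    lines = ["# synthetic SWC written by dendsum"]
    point_of_section: dict[int, int] = {}
    pos_of_section: dict[int, np.ndarray] = {}
    next_pid = 1

    root = m.root
    root_pos = np.zeros(3)
    # root section: two points along +x
    lines.append(
        f"{next_pid} {_KIND_TO_SWC[root.kind]} 0 0 0 {root.diameter / 2:.17g} -1"
    )
    root_anchor = next_pid
    next_pid += 1
    end = root_pos + np.array([root.length, 0.0, 0.0])
    lines.append(
        f"{next_pid} {_KIND_TO_SWC[root.kind]} {end[0]:.17g} {end[1]:.17g} {end[2]:.17g} "
        f"{root.diameter / 2:.17g} {root_anchor}"
    )
    point_of_section[root.id] = next_pid
    pos_of_section[root.id] = end
    next_pid += 1

    # BFS over children, fanning out directions
    queue = [root.id]
    golden = math.pi * (3 - math.sqrt(5))
    k = 0
    while queue:
        sid = queue.pop(0)
        for child in m.children(sid):
            theta = golden * k + 0.31
            k += 1
            direction = np.array([math.cos(theta), math.sin(theta), 0.1 * (k % 5)])
            direction /= np.linalg.norm(direction)
            start = pos_of_section[sid]
            end = start + direction * child.length
            lines.append(
                f"{next_pid} {_KIND_TO_SWC[child.kind]} "
                f"{end[0]:.17g} {end[1]:.17g} {end[2]:.17g} "
                f"{child.diameter / 2:.17g} {point_of_section[sid]}"
            )
            point_of_section[child.id] = next_pid
            pos_of_section[child.id] = end
            next_pid += 1
            queue.append(child.id)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- discretization --------------------------------------------------------

def lambda_f(diam_um: float, f_hz: float, r_a: float, c_m: float) -> float:
    """AC length constant (um) of a cable at frequency ``f_hz``.

    ``lambda_f = (1/2) * sqrt(d / (pi * f * R_a * C_m))`` with the diameter in
    cm, ``r_a`` in ohm*cm and ``c_m`` in F/cm^2; returned in micrometres.
    """
    d_cm = diam_um * 1e-4
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * f_hz * r_a * c_m * 1e-6))
    return lam_cm * 1e4


def discretize(m: Morphology, biophys, f: float = 100.0,
               max_seg_um: float = 10.0) -> Morphology:
    """Set per-section segment counts from the 100 Hz length-constant rule.

    Each section gets the smallest *odd* number of segments making the
    segment length no greater than ``min(lambda_f / 10, max_seg_um)``.
    ``biophys`` must expose ``c_m_for(kind)`` (uF/cm^2) and ``r_a`` (ohm*cm);
    the spine correction factor of 2 on flagged sections enters the length
    constant through the corrected capacitance.
    """
    nseg: dict[int, int] = {}
    for s in m.sections:
        c_m = biophys.c_m_for(s.kind) * (2.0 if s.spine_corrected else 1.0)
        lam = lambda_f(s.diameter, f, biophys.r_a, c_m)
        cap = min(lam / 10.0, max_seg_um)
        n = max(1, math.ceil(s.length / cap - 1e-12))
        if n % 2 == 0:
            n += 1
        nseg[s.id] = n
    return Morphology(list(m.sections), nseg)
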