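"""Branched neuronal morphologies and their compartmental discretization.

A :class:`Morphology` is a tree of tapered-cylinder (frustum) segments; a
:class:`CompartmentGrid` is its discretization into equal-length
compartments per segment (``ceil(L / dl)`` compartments of length ``L/n``),
carrying the frustum geometry (volumes, lateral and cross-sectional areas)
needed by the cable and diffusion solvers.

Morphologies can be read from and written to standard 7-column SWC files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Segment",
    "Morphology",
    "CompartmentGrid",
    "discretize",
    "load_swc",
    "write_swc",
    "unbranched_cable",
    "spiny_dendrite",
    "consolidation_cell",
    "discretize_consolidation_cell",
    "random_tree",
]

REGIONS = ("soma", "apical", "basal", "dendrite", "spine")


@dataclass(frozen=True)
class Segment:
    """A tapered cylinder: proximal/distal radii and length in micrometers."""

    id: int
    parent: int | None
    r_prox: float
    r_dist: float
    length: float
    region: str = "dendrite"

    def __post_init__(self) -> None:
        if self.r_prox <= 0 or self.r_dist <= 0:
            raise ValueError(f"segment {self.id}: radii must be positive")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")
        if self.region not in REGIONS:
            raise ValueError(
                f"segment {self.id}: unknown region {self.region!r}"
            )


class Morphology:
    """A rooted tree of segments (exactly one root, acyclic parent links)."""

    def __init__(self, segments: Iterable[Segment]):
        segs = list(segments)
        if not segs:
            raise ValueError("empty morphology")
        ids = [s.id for s in segs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        by_id = {s.id: s for s in segs}
        roots = [s for s in segs if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for s in segs:
            if s.parent is not None and s.parent not in by_id:
                raise ValueError(
                    f"segment {s.id} references missing parent {s.parent}"
                )
        # cycle check by walking to the root from every node
        for s in segs:
            seen = set()
            cur: Segment | None = s
            while cur is not None:
                if cur.id in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(cur.id)
                cur = by_id[cur.parent] if cur.parent is not None else None
        # store in topological (parent-before-child) order
        order: list[Segment] = []
        children: dict[int | None, list[Segment]] = {}
        for s in segs:
            children.setdefault(s.parent, []).append(s)
        stack = [roots[0]]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(reversed(children.get(s.id, [])))
        self.segments: list[Segment] = order
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.segments)

    def segment(self, seg_id: int) -> Segment:
        return self._by_id[seg_id]

    @property
    def root(self) -> Segment:
        return self.segments[0]

    def total_volume(self) -> float:
        """Sum of segment frustum volumes, in cubic micrometers."""
        return sum(_frustum_volume(s.r_prox, s.r_dist, s.length)
                   for s in self.segments)


def _frustum_volume(r1: float, r2: float, length: float) -> float:
    return math.pi * length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


def _frustum_lateral(r1: float, r2: float, length: float) -> float:
    slant = math.hypot(length, r2 - r1)
    return math.pi * (r1 + r2) * slant


@dataclass
class CompartmentGrid:
    """Per-compartment geometry of a discretized morphology.

    ``parent[i]`` is the index of the compartment proximal to ``i`` (-1 for
    the root compartment).  ``a_face[i]`` is the cross-sectional area of the
    face shared with the parent, ``dist[i]`` the center-to-center distance
    across that face.  ``segment_slices`` maps segment id to the half-open
    compartment index range of that segment.
    """

    morphology: Morphology
    dl: float
    parent: np.ndarray
    length: np.ndarray
    volume: np.ndarray
    area_lateral: np.ndarray
    a_face: np.ndarray
    dist: np.ndarray
    region: list[str]
    segment_slices: dict[int, tuple[int, int]]
    prp_compartment: int | None = None

    @property
    def n(self) -> int:
        return self.length.size

    def compartment_at(self, seg_id: int, frac: float) -> int:
        """Index of the compartment at relative position ``frac`` (0..1)."""
        lo, hi = self.segment_slices[seg_id]
        k = min(int(frac * (hi - lo)), hi - lo - 1)
        return lo + k

    def total_volume(self) -> float:
        return float(self.volume.sum())


def discretize(
    morph: Morphology,
    dl: float,
    prp_segment: int | None = None,
) -> CompartmentGrid:
    """Split every segment into ``ceil(L/dl)`` equal-length compartments.

    Radii are interpolated linearly along each segment, so the summed
    compartment volumes equal the segment frustum volumes exactly.  If
    ``prp_segment`` is given, the (single-compartment) segment with that id
    is recorded as the designated PRP-synthesis compartment.
    """
    if dl <= 0:
        raise ValueError("dl must be positive")
    parent: list[int] = []
    length: list[float] = []
    volume: list[float] = []
    lateral: list[float] = []
    a_face: list[float] = []
    dist: list[float] = []
    region: list[str] = []
    slices: dict[int, tuple[int, int]] = {}
    last_comp: dict[int, int] = {}  # segment id -> index of its distal comp

    for seg in morph.segments:
        ncomp = max(1, math.ceil(seg.length / dl))
        sub = seg.length / ncomp
        start = len(length)
        for k in range(ncomp):
            f0 = k / ncomp
            f1 = (k + 1) / ncomp
            r0 = seg.r_prox + (seg.r_dist - seg.r_prox) * f0
            r1 = seg.r_prox + (seg.r_dist - seg.r_prox) * f1
            idx = len(length)
            if k == 0:
                if seg.parent is None:
                    parent.append(-1)
                    a_face.append(0.0)
                    dist.append(np.inf)
                else:
                    p = last_comp[seg.parent]
                    parent.append(p)
                    a_face.append(math.pi * r0 * r0)
                    dist.append(0.5 * (length[p] + sub))
            else:
                parent.append(idx - 1)
                a_face.append(math.pi * r0 * r0)
                dist.append(sub)
            length.append(sub)
            volume.append(_frustum_volume(r0, r1, sub))
            lateral.append(_frustum_lateral(r0, r1, sub))
            region.append(seg.region)
        slices[seg.id] = (start, len(length))
        last_comp[seg.id] = len(length) - 1

    prp_comp = None
    if prp_segment is not None:
        lo, hi = slices[prp_segment]
        prp_comp = lo

    return CompartmentGrid(
        morphology=morph,
        dl=dl,
        parent=np.asarray(parent, dtype=np.int64),
        length=np.asarray(length),
        volume=np.asarray(volume),
        area_lateral=np.asarray(lateral),
        a_face=np.asarray(a_face),
        dist=np.asarray(dist),
        region=region,
        segment_slices=slices,
        prp_compartment=prp_comp,
    )


# ---------------------------------------------------------------------------
# SWC input/output

_SWC_REGION = {1: "soma", 2: "dendrite", 3: "basal", 4: "apical"}
_REGION_SWC = {"soma": 1, "dendrite": 2, "basal": 3, "apical": 4, "spine": 5}


class SwcParseError(ValueError):
    pass


def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC sample file into a Morphology.

    Each non-root sample becomes one segment running from its parent sample
    to itself; the proximal radius is the parent's, the distal radius the
    sample's own.  Dangling parent references and non-positive radii raise
    :class:`SwcParseError` naming the offending line.
    """
    samples: dict[int, tuple[float, float, float, float, int, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(cols)}"
                )
            try:
                sid = int(cols[0])
                typ = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                par = int(cols[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            if r <= 0:
                raise SwcParseError(
                    f"{path}:{lineno}: non-positive radius {r}"
                )
            if par != -1 and par not in samples:
                raise SwcParseError(
                    f"{path}:{lineno}: sample {sid} references undefined "
                    f"parent {par}"
                )
            if sid in samples:
                raise SwcParseError(f"{path}:{lineno}: duplicate sample {sid}")
            samples[sid] = (x, y, z, r, typ, par)
            order.append(sid)

    roots = [sid for sid in order if samples[sid][5] == -1]
    if len(roots) != 1:
        raise SwcParseError(f"{path}: expected one root sample, "
                            f"found {len(roots)}")
    root = roots[0]
    root_children = [sid for sid in order if samples[sid][5] == root]
    # The root sample is a point.  With exactly one child it is folded into
    # that child's segment; otherwise (none, or a multifurcation) it becomes
    # a sphere-equivalent cylinder of length 2r so the tree has one root.
    seg_of_sample: dict[int, int | None]
    segments: list[Segment] = []
    if len(root_children) == 1:
        seg_of_sample = {root: None}
    else:
        x, y, z, r, typ, _ = samples[root]
        segments.append(Segment(id=root, parent=None, r_prox=r, r_dist=r,
                                length=2 * r,
                                region=_SWC_REGION.get(typ, "soma")))
        seg_of_sample = {root: root}
    for sid in order:
        x, y, z, r, typ, par = samples[sid]
        if par == -1:
            continue
        px, py, pz, pr, _ptyp, _ = samples[par]
        L = math.dist((x, y, z), (px, py, pz))
        if L <= 0:
            L = r  # coincident sample: stub of the sample radius
        segments.append(Segment(
            id=sid,
            parent=seg_of_sample[par],
            r_prox=pr,
            r_dist=r,
            length=L,
            region=_SWC_REGION.get(typ, "dendrite"),
        ))
        seg_of_sample[sid] = sid
    return Morphology(segments)


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as SWC samples laid out along the x axis.

    Geometry is synthesized (the internal representation keeps only radii
    and lengths), but the tree topology and radii round-trip exactly.
    """
    lines = ["# generated by synplast"]
    # sample 1 is the proximal end of the root segment
    root = morph.root
    lines.append(f"1 {_REGION_SWC[root.region]} 0 0 0 {root.r_prox:.9g} -1")
    sample_of: dict[int, int] = {}
    pos: dict[int, tuple[float, float, float]] = {}
    next_id = 2
    for seg in morph.segments:
        if seg.parent is None:
            px, py, pz = 0.0, 0.0, 0.0
            psample = 1
        else:
            px, py, pz = pos[seg.parent]
            psample = sample_of[seg.parent]
        lines.append(
            f"{next_id} {_REGION_SWC[seg.region]} "
            f"{px + seg.length:.9g} {py:.9g} {pz:.9g} {seg.r_dist:.9g} "
            f"{psample}"
        )
        sample_of[seg.id] = next_id
        pos[seg.id] = (px + seg.length, py, pz)
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Builders for the bundled cell geometries

def unbranched_cable(length: float, radius: float,
                     region: str = "dendrite") -> Morphology:
    """A single straight cylinder."""
    return Morphology([Segment(0, None, radius, radius, length, region)])


def spiny_dendrite(
    l_dendrite: float = 80.0,
    r_dendrite: float = 1.0,
    spine_positions: Sequence[float] = (-1.0, 0.0, 1.0, 3.0),
    r_head: float = 1.0,
    l_head: float = 1.0,
) -> tuple[Morphology, list[int]]:
    """Straight dendrite with single-compartment spines.

    Spine positions are micrometers relative to the dendrite midpoint.
    Returns the morphology and the spine segment ids (in input order).
    The dendrite is built from consecutive 1-um-scale sub-segments so that
    each spine attaches at its own x position.
    """
    half = l_dendrite / 2.0
    xs = sorted(set(spine_positions))
    cut_points = [-half] + [x for x in xs] + [half]
    segments: list[Segment] = []
    attach_at: dict[float, int] = {}
    prev: int | None = None
    sid = 0
    for a, b in zip(cut_points[:-1], cut_points[1:]):
        if b <= a:
            continue
        segments.append(Segment(sid, prev, r_dendrite, r_dendrite, b - a,
                                "dendrite"))
        prev = sid
        attach_at[b] = sid
        sid += 1
    spine_ids: list[int] = []
    for x in spine_positions:
        segments.append(Segment(sid, attach_at[x], r_head, r_head, l_head,
                                "spine"))
        spine_ids.append(sid)
        sid += 1
    return Morphology(segments), spine_ids


# segment ids used by consolidation_cell
SOMA_A, PRP_SEG, SOMA_B, APICAL_SEG, BASAL_SEG = 0, 1, 2, 3, 4


def consolidation_cell(
    r_comp: float = 6.0,
    l_soma: float = 12.0,
    l_apical: float = 12.5,
    l_basal: float = 5.0,
    l_prp: float = 1.0,
) -> Morphology:
    """Simplified pyramidal-like cell used in the consolidation networks.

    The soma of length ``l_soma`` is split into two cylinders with a short
    PRP-synthesis compartment between them; an apical branch extends from
    the distal soma end and a basal branch from the proximal end.  All
    compartments share the radius ``r_comp``.
    """
    r = r_comp
    return Morphology([
        Segment(SOMA_A, None, r, r, l_soma / 2.0, "soma"),
        Segment(PRP_SEG, SOMA_A, r, r, l_prp, "soma"),
        Segment(SOMA_B, PRP_SEG, r, r, l_soma / 2.0, "soma"),
        Segment(APICAL_SEG, SOMA_B, r, r, l_apical, "apical"),
        Segment(BASAL_SEG, SOMA_A, r, r, l_basal, "basal"),
    ])


def discretize_consolidation_cell(morph: Morphology,
                                  dl: float = 1.0) -> CompartmentGrid:
    """Discretize a consolidation cell, marking the PRP compartment."""
    return discretize(morph, dl, prp_segment=PRP_SEG)


def random_tree(
    depth: int,
    seed_stream,
    r_soma: float = 6.0,
    l_soma: float = 12.0,
    branch_length: tuple[float, float] = (20.0, 60.0),
    branch_radius: tuple[float, float] = (0.4, 1.0),
) -> Morphology:
    """Random dendritic tree of the given depth on a cylindrical soma.

    Each node spawns two children down to ``depth`` levels; lengths and
    radii are drawn from the given ranges via ``seed_stream`` (a
    :class:`synplast.rng.NoiseStream`), so the tree is reproducible per
    cell.
    """
    segments = [Segment(0, None, r_soma, r_soma, l_soma, "soma")]
    sid = 1
    frontier = [(0, 0)]  # (segment id, level)
    while frontier:
        parent_id, level = frontier.pop()
        if level >= depth:
            continue
        for _ in range(2):
            u1, u2 = seed_stream.uniform(), seed_stream.uniform()
            L = branch_length[0] + u1 * (branch_length[1] - branch_length[0])
            r = branch_radius[0] + u2 * (branch_radius[1] - branch_radius[0])
            segments.append(Segment(sid, parent_id, r, r, L, "dendrite"))
            frontier.append((sid, level + 1))
            sid += 1
    return Morphology(segments)
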