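"""Neuronal morphologies: SWC I/O, synthetic CA1-like cells, compartmentalization.

A morphology is a rooted tree of sample points (:class:`MorphNode`).  Each
parent->child edge defines a tapered cylindrical segment.  For simulation the
tree is discretized into a :class:`CompartmentalModel`: a parent-ordered list
of cylindrical compartments (parent index < child index, i.e. Hines ordering),
each carrying its own membrane-mechanism parameters.

SWC node ids are 1-based in files (the common dialect) and 0-based in memory;
the translation happens only at read/write time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# SWC type codes
REGIONS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
REGION_CODES = {v: k for k, v in REGIONS.items()}


class MorphologyError(ValueError):
    """Raised for structurally invalid morphologies or SWC files."""


@dataclass(frozen=True)
class MorphNode:
    """One sample point of a reconstructed or synthetic neuron.

    Coordinates and radius are in micrometres. ``parent`` is the 0-based index
    of the parent node, or -1 for the root.
    """

    id: int
    region: str
    x: float
    y: float
    z: float
    radius: float
    parent: int

    def __post_init__(self):
        if self.radius <= 0:
            raise MorphologyError(f"node {self.id}: radius must be > 0, got {self.radius}")
        if self.region not in REGION_CODES:
            raise MorphologyError(f"node {self.id}: unknown region {self.region!r}")


@dataclass
class NeuronMorphology:
    """Rooted tree of :class:`MorphNode` in topological order."""

    nodes: list[MorphNode]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise MorphologyError("morphology has no nodes")
        roots = [n for n in self.nodes if n.parent == -1]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        for i, n in enumerate(self.nodes):
            if n.id != i:
                raise MorphologyError(f"node ids must be consecutive from 0, got {n.id} at {i}")
            if n.parent >= i:
                raise MorphologyError(
                    f"node {i}: parent {n.parent} does not precede it (topological order)"
                )
            if n.parent < -1:
                raise MorphologyError(f"node {i}: bad parent {n.parent}")
        if not any(n.region == "soma" for n in self.nodes):
            raise MorphologyError("morphology has no soma")

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in self.nodes]
        for n in self.nodes[1:]:
            ch[n.parent].append(n.id)
        return ch

    def edge_length(self, i: int) -> float:
        """Length (µm) of the segment joining node i to its parent."""
        n, p = self.nodes[i], self.nodes[self.nodes[i].parent]
        return math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))

    def total_length(self) -> float:
        """Summed dendrite/axon segment length (µm), soma excluded."""
        return sum(
            self.edge_length(i)
            for i, n in enumerate(self.nodes)
            if n.parent != -1 and n.region != "soma"
        )


def read_swc(path) -> NeuronMorphology:
    """Read a whitespace-delimited 7-column SWC file.

    Comment lines starting with ``#`` are ignored.  Contiguous leading soma
    samples are merged into a single cylindrical root of equivalent membrane
    area (a spherical soma of diameter d becomes a cylinder with L = d).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                typ = int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                pid = int(parts[6])
            except ValueError as e:
                raise MorphologyError(f"{path}:{lineno}: {e}") from None
            rows.append((lineno, nid, typ, x, y, z, r, pid))

    if not rows:
        raise MorphologyError(f"{path}: no data lines")

    id_index = {nid: k for k, (_, nid, *_rest) in enumerate(rows)}
    for lineno, nid, typ, x, y, z, r, pid in rows:
        if pid != -1:
            if pid not in id_index:
                raise MorphologyError(f"{path}:{lineno}: parent id {pid} does not exist")
            if id_index[pid] >= id_index[nid]:
                raise MorphologyError(
                    f"{path}:{lineno}: parent id {pid} appears at or after node {nid} "
                    "(violates topological order)"
                )
        if r <= 0:
            raise MorphologyError(f"{path}:{lineno}: non-positive radius {r}")
        if typ not in REGIONS:
            raise MorphologyError(f"{path}:{lineno}: unknown SWC type {typ}")

    # Merge the contiguous block of soma samples at the top of the file into
    # one equivalent-area cylindrical root.
    soma_rows = []
    for row in rows:
        if row[2] == 1 and (not soma_rows or row[7] in {-1} | {r[1] for r in soma_rows}):
            soma_rows.append(row)
        else:
            break
    if not soma_rows:
        raise MorphologyError(f"{path}: first sample must be a soma (type 1) node")
    soma_ids = {r[1] for r in soma_rows}

    cx = float(np.mean([r[3] for r in soma_rows]))
    cy = float(np.mean([r[4] for r in soma_rows]))
    cz = float(np.mean([r[5] for r in soma_rows]))
    # Equivalent radius: preserve the area of the sphere through the max sample
    radius = max(r[6] for r in soma_rows)

    nodes = [MorphNode(0, "soma", cx, cy, cz, radius, -1)]
    remap = {r[1]: 0 for r in soma_rows}
    for row in rows:
        lineno, nid, typ, x, y, z, r, pid = row
        if nid in soma_ids:
            continue
        if typ == 1:
            raise MorphologyError(f"{path}:{lineno}: non-contiguous soma sample {nid}")
        parent = remap[pid] if pid != -1 else -1
        new_id = len(nodes)
        remap[nid] = new_id
        nodes.append(MorphNode(new_id, REGIONS[typ], x, y, z, r, parent))

    return NeuronMorphology(nodes, metadata={"source": str(path)})


def write_swc(morph: NeuronMorphology, path) -> None:
    """Write standard 7-column SWC (1-based ids), re-readable by read_swc."""
    morph.validate()
    with open(path, "w") as fh:
        fh.write("# SWC written by gabawindow\n")
        for n in morph.nodes:
            pid = n.parent + 1 if n.parent != -1 else -1
            fh.write(
                f"{n.id + 1} {REGION_CODES[n.region]} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {pid}\n"
            )


def make_synthetic_ca1(
    trunk_length: float = 400.0,
    n_obliques: int = 8,
    oblique_length: float = 150.0,
    seed: int = 0,
    soma_diam: float = 20.0,
    node_spacing: float = 10.0,
) -> NeuronMorphology:
    """Generate a stylized CA1 pyramidal cell.

    Soma (cylinder of ``soma_diam``), an apical trunk tapering from 4 to 1 µm
    diameter, and ``n_obliques`` unbranched oblique dendrites (1 µm diameter)
    attached at quasi-random path distances along the trunk.  The oblique field
    covers the region where coincident excitatory inputs arrive in CA1
    (tens to a few hundred µm from the soma).  Deterministic for a fixed seed.
    """
    if trunk_length <= 0:
        raise ValueError("trunk_length must be > 0")
    if n_obliques < 0:
        raise ValueError("n_obliques must be >= 0")
    rng = np.random.default_rng(seed)

    nodes = [MorphNode(0, "soma", 0.0, 0.0, 0.0, soma_diam / 2, -1)]

    # Apical trunk along +y, sampled every node_spacing µm.
    n_trunk = max(2, int(math.ceil(trunk_length / node_spacing)) + 1)
    ys = np.linspace(0.0, trunk_length, n_trunk)
    radii = np.interp(ys, [0.0, trunk_length], [2.0, 0.5])  # diam 4 -> 1 µm
    trunk_ids = []
    parent = 0
    for y, r in zip(ys[1:], radii[1:]):
        nid = len(nodes)
        nodes.append(MorphNode(nid, "apical", 0.0, float(y), 0.0, float(r), parent))
        trunk_ids.append(nid)
        parent = nid

    # Obliques branch at uniform positions along the trunk (sorted for
    # readability; the draw itself is the randomness).
    branch_y = np.sort(rng.uniform(0.1 * trunk_length, 0.95 * trunk_length, size=n_obliques))
    for k, by in enumerate(branch_y):
        # nearest trunk node at or below the branch point
        idx = int(np.searchsorted(ys[1:], by))
        idx = min(idx, len(trunk_ids) - 1)
        parent = trunk_ids[idx]
        py = nodes[parent].y
        angle = rng.uniform(0, 2 * math.pi)
        ux, uz = math.cos(angle), math.sin(angle)
        n_ob = max(1, int(math.ceil(oblique_length / node_spacing)))
        step = oblique_length / n_ob
        for j in range(1, n_ob + 1):
            nid = len(nodes)
            nodes.append(
                MorphNode(nid, "apical", ux * step * j, py, uz * step * j, 0.5, parent)
            )
            parent = nid

    return NeuronMorphology(
        nodes,
        metadata={
            "source": "synthetic_ca1",
            "trunk_length": trunk_length,
            "n_obliques": n_obliques,
            "oblique_length": oblique_length,
            "seed": seed,
        },
    )


@dataclass
class CompartmentalModel:
    """Discretized morphology plus per-compartment mechanism parameters.

    Arrays are parent-ordered (Hines ordering: parent[i] < i).  Geometry in µm;
    ``axial_resistivity`` in Ω·cm; ``specific_capacitance`` in µF/cm².
    Mechanism parameter arrays (conductance densities in mS/cm², reversal
    potentials in mV) are attached by :mod:`gabawindow.mechanisms`.
    """

    length: np.ndarray          # µm
    diam: np.ndarray            # µm
    region: np.ndarray          # int codes per REGIONS
    parent: np.ndarray          # int, -1 for root
    axial_resistivity: float = 90.0
    specific_capacitance: float = 1.0
    mech: dict = field(default_factory=dict)     # name -> per-compartment arrays / scalars
    synapses: list = field(default_factory=list)  # filled by protocol

    @property
    def n(self) -> int:
        return len(self.length)

    def area_cm2(self) -> np.ndarray:
        """Lateral membrane area of each cylindrical compartment (cm²)."""
        return math.pi * (self.diam * 1e-4) * (self.length * 1e-4)

    def path_distance(self) -> np.ndarray:
        """Path distance (µm) from the compartment centre to the soma root."""
        d = np.zeros(self.n)
        half = self.length / 2
        for i in range(1, self.n):
            p = self.parent[i]
            d[i] = d[p] + half[p] + half[i]
        return d

    def region_mask(self, name: str) -> np.ndarray:
        return self.region == REGION_CODES[name]

    def axial_conductance_mS(self) -> np.ndarray:
        """Coupling conductance (mS) between compartment i and its parent.

        Series sum of the two half-compartment axial resistances,
        R = Ra * (L/2) / (π r²); entry 0 is unused.
        """
        L_cm = self.length * 1e-4
        r_cm = (self.diam / 2) * 1e-4
        half_res = self.axial_resistivity * (L_cm / 2) / (math.pi * r_cm**2)  # Ω
        g = np.zeros(self.n)
        for i in range(1, self.n):
            g[i] = 1000.0 / (half_res[i] + half_res[self.parent[i]])  # Ω -> mS
        return g


def _sections(morph: NeuronMorphology):
    """Split the node tree into unbranched sections.

    Yields (node_index_path, parent_node_index) where the path excludes the
    parent node itself.  The soma root is its own section.
    """
    ch = morph.children()
    sections = []
    # Section starts: children of branch points / root.
    stack = list(ch[0])
    while stack:
        start = stack.pop()
        path = [start]
        while len(ch[path[-1]]) == 1 and morph.nodes[ch[path[-1]][0]].region == morph.nodes[path[-1]].region:
            path.append(ch[path[-1]][0])
        for c in ch[path[-1]]:
            stack.append(c)
        sections.append((path, morph.nodes[start].parent))
    sections.sort(key=lambda s: s[0][0])
    return sections


def discretize(morph: NeuronMorphology, max_seg_length: float = 10.0) -> CompartmentalModel:
    """Compartmentalize a morphology.

    Each unbranched section of length L becomes ceil(L / max_seg_length) equal
    compartments; diameters are taken from the section's nodes by arc-length
    interpolation (so total membrane area is conserved under refinement).  The
    soma is always a single compartment.
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be > 0")
    morph.validate()

    lengths, diams, regions, parents = [], [], [], []
    root = morph.root
    lengths.append(2 * root.radius)  # cylinder L = diam: sphere-equivalent area
    diams.append(2 * root.radius)
    regions.append(REGION_CODES[root.region])
    parents.append(-1)
    # last compartment index of each node
    node_comp = {0: 0}

    for path, parent_node in _sections(morph):
        pts = [morph.nodes[parent_node]] + [morph.nodes[i] for i in path]
        arcs = np.concatenate(
            [[0.0], np.cumsum([math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                               for a, b in zip(pts, pts[1:])])]
        )
        L = float(arcs[-1])
        if L <= 0:
            continue
        diam_pts = np.array([2 * p.radius for p in pts])
        # For a section emerging from the soma, the first point's "radius" is
        # the soma's; use the first true section node instead.
        if morph.nodes[parent_node].region != morph.nodes[path[0]].region:
            diam_pts[0] = diam_pts[1]
        ncomp = max(1, int(math.ceil(L / max_seg_length)))
        dx = L / ncomp
        parent_comp = node_comp[parent_node]
        for k in range(ncomp):
            mid = (k + 0.5) * dx
            d = float(np.interp(mid, arcs, diam_pts))
            idx = len(lengths)
            lengths.append(dx)
            diams.append(d)
            regions.append(REGION_CODES[morph.nodes[path[0]].region])
            parents.append(parent_comp)
            parent_comp = idx
        node_comp[path[-1]] = parent_comp

    return CompartmentalModel(
        length=np.asarray(lengths, dtype=float),
        diam=np.asarray(diams, dtype=float),
        region=np.asarray(regions, dtype=np.int64),
        parent=np.asarray(parents, dtype=np.int64),
    )
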