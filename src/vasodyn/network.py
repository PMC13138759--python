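"""Construction, validation and serialization of the segmented cerebrovascular network.

The network is a graph of cylindrical vessel segments joining nodes, with a
single arterial inlet (artery boundary node, ABN) and a single venous outlet
(vein boundary node, VBN).  The default geometry is a pial arteriolar tree
feeding 30 penetrating arterioles (PAs); each PA is a chain of 28 segments,
30 um long, diving 840 um into the cortex, with the diameter tapering
linearly from 18 um at the surface to 12.6 um at depth.  Each PA drains
through a fixed (non-reactive) chain of sphincter, transitional-zone and
capillary segments that lumps the parallel downstream microvascular bed into
an equivalent single tube.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

import networkx as nx
import pandas as pd

__all__ = [
    "NetworkNode",
    "VesselSegment",
    "VascularNetwork",
    "NetworkGenConfig",
    "pa_taper_diameter",
    "generate_default_network",
    "arteriolar_coupling_graph",
    "read_network",
    "write_network",
]

NODE_KINDS = ("interior", "artery_boundary", "vein_boundary")
SEGMENT_CLASSES = ("pial", "PA", "sphincter", "TZ", "capillary")

#: wall thickness as a fraction of the maximal active diameter
WALL_THICKNESS_FRACTION = 0.1


class NetworkError(ValueError):
    """Raised for malformed or inconsistent vascular networks."""


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str = "interior"
    boundary_pressure: Optional[float] = None  # mmHg, boundary nodes only

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkError(f"unknown node kind {self.kind!r}")
        is_boundary = self.kind != "interior"
        if is_boundary and self.boundary_pressure is None:
            raise NetworkError(f"boundary node {self.id} requires boundary_pressure")
        if not is_boundary and self.boundary_pressure is not None:
            raise NetworkError(f"interior node {self.id} must not carry a pressure")


@dataclass
class VesselSegment:
    """A cylindrical vessel segment between two nodes.

    ``diameter`` is the instantaneous (state) luminal diameter, while
    ``d_active_max`` is the maximal active diameter (full dilation at the
    lower autoregulation limit).  Wall thickness ``h`` is fixed at
    0.1 x d_active_max.  ``cortical_depth`` is the depth of the segment
    midpoint (0 at the pial surface, positive downward).
    """

    id: str
    cls: str
    node_a: str
    node_b: str
    length: float  # um
    diameter: float  # um
    d_active_max: float  # um
    wall_thickness: float  # um
    cortical_depth: float = 0.0  # um
    contractility_index: float = 1.0
    is_arteriolar: bool = False

    def __post_init__(self) -> None:
        if self.cls not in SEGMENT_CLASSES:
            raise NetworkError(f"unknown segment class {self.cls!r}")
        if self.length <= 0 or self.diameter <= 0:
            raise NetworkError(f"segment {self.id}: length and diameter must be > 0")
        if not (0.0 < self.contractility_index <= 1.0):
            raise NetworkError(f"segment {self.id}: contractility_index must be in (0,1]")


@dataclass
class VascularNetwork:
    nodes: Dict[str, NetworkNode] = field(default_factory=dict)
    segments: Dict[str, VesselSegment] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_node(self, node: NetworkNode) -> None:
        if node.id in self.nodes:
            raise NetworkError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_segment(self, seg: VesselSegment) -> None:
        if seg.id in self.segments:
            raise NetworkError(f"duplicate segment id {seg.id!r}")
        for n in (seg.node_a, seg.node_b):
            if n not in self.nodes:
                raise NetworkError(f"segment {seg.id} references unknown node {n!r}")
        self.segments[seg.id] = seg

    # -- derived views ---------------------------------------------------------
    @property
    def adjacency(self) -> Dict[str, List[str]]:
        """Map node id -> list of incident segment ids."""
        adj: Dict[str, List[str]] = {n: [] for n in self.nodes}
        for seg in self.segments.values():
            adj[seg.node_a].append(seg.id)
            adj[seg.node_b].append(seg.id)
        return adj

    @property
    def abn(self) -> NetworkNode:
        return self._single_boundary("artery_boundary")

    @property
    def vbn(self) -> NetworkNode:
        return self._single_boundary("vein_boundary")

    def _single_boundary(self, kind: str) -> NetworkNode:
        found = [n for n in self.nodes.values() if n.kind == kind]
        if len(found) != 1:
            raise NetworkError(f"network must have exactly one {kind} node, found {len(found)}")
        return found[0]

    def arteriolar_segments(self) -> List[VesselSegment]:
        return [s for s in self.segments.values() if s.is_arteriolar]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            attrs = {"kind": n.kind}
            if n.boundary_pressure is not None:
                attrs["boundary_pressure"] = float(n.boundary_pressure)
            g.add_node(n.id, **attrs)
        for s in self.segments.values():
            g.add_edge(
                s.node_a,
                s.node_b,
                key=s.id,
                id=s.id,
                cls=s.cls,
                length_um=float(s.length),
                diameter_um=float(s.diameter),
                d_active_max_um=float(s.d_active_max),
                h_um=float(s.wall_thickness),
                depth_um=float(s.cortical_depth),
                contractility=float(s.contractility_index),
                is_arteriolar=bool(s.is_arteriolar),
            )
        return g

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`NetworkError` on failure."""
        self.abn, self.vbn  # noqa: B018 -- exactly one of each
        g = self.to_networkx()
        if len(g) and not nx.is_connected(g):
            raise NetworkError("vascular network must be connected")
        for s in self.segments.values():
            expected_h = WALL_THICKNESS_FRACTION * s.d_active_max
            if not math.isclose(s.wall_thickness, expected_h, rel_tol=1e-6):
                raise NetworkError(
                    f"segment {s.id}: wall thickness {s.wall_thickness} != 0.1 x d_active_max"
                )


@dataclass(frozen=True)
class NetworkGenConfig:
    """Parameters of the default generated geometry."""

    n_PA: int = 30
    segments_per_PA: int = 28
    pa_segment_length: float = 30.0  # um
    d_surface: float = 18.0  # um, PA diameter at the pial surface
    d_deep: float = 12.6  # um, PA diameter at full depth
    n_pial_segments: int = 169
    seed: int = 0
    # pial-tree geometry (the source texts do not print it; see docs/methods.md)
    pial_d_root: float = 40.0  # um at the ABN
    pial_d_leaf: float = 20.0  # um at the PA roots
    pial_segment_length: float = 50.0  # um
    # downstream microvessel chain per PA (lumped parallel bed, fixed diameters)
    n_tz_orders: int = 3
    n_cap_orders: int = 3
    microvessel_length: float = 50.0  # um
    #: "distributed": one microvessel offtake chain per PA segment node
    #: (the PA bifurcates at every depth); "leaf": a single chain at the
    #: deepest node lumping the whole downstream bed
    microvessel_attachment: str = "distributed"

    def __post_init__(self) -> None:
        for name in ("n_PA", "segments_per_PA", "n_pial_segments"):
            if getattr(self, name) <= 0:
                raise NetworkError(f"{name} must be positive")
        if self.d_surface <= self.d_deep:
            raise NetworkError("d_surface must exceed d_deep")

    @property
    def pa_length(self) -> float:
        return self.segments_per_PA * self.pa_segment_length


def pa_taper_diameter(depth: float, cfg: NetworkGenConfig = NetworkGenConfig()) -> float:
    """Maximal active PA diameter (um) at cortical ``depth`` (um).

    Linear taper from ``d_surface`` at depth 0 to ``d_deep`` at the full PA
    length (segments_per_PA x pa_segment_length).
    """
    total = cfg.pa_length
    if not (0.0 <= depth <= total):
        raise NetworkError(f"depth {depth} outside [0, {total}] um")
    return cfg.d_surface - (cfg.d_surface - cfg.d_deep) * depth / total


def _binary_tree_leaves(n_leaves: int) -> nx.DiGraph:
    """A rooted binary tree (as a DiGraph, root 0) with exactly ``n_leaves`` leaves."""
    g = nx.DiGraph()
    g.add_node(0)
    leaves = [0]
    nxt = 1
    while len(leaves) < n_leaves:
        # split the shallowest leaf to keep the tree balanced; each split
        # turns one leaf into two, so the leaf count grows by exactly one
        leaves.sort(key=lambda n: g.nodes[n].get("level", 0))
        parent = leaves.pop(0)
        lvl = g.nodes[parent].get("level", 0)
        for _ in range(2):
            g.add_node(nxt, level=lvl + 1)
            g.add_edge(parent, nxt)
            leaves.append(nxt)
            nxt += 1
    return g


def _pial_tree_edges(cfg: NetworkGenConfig) -> List[List[str]]:
    """Pial topology as a list of node-id chains, one chain per tree edge.

    Returns chains of pial node ids; the first chain starts at the ABN.  The
    final nodes named ``pa_root_k`` (k = 0..n_PA-1) are the PA attachment
    points.  The total number of chain links equals ``n_pial_segments``.
    """
    n_pa, n_pial = cfg.n_PA, cfg.n_pial_segments
    if n_pial < n_pa:
        raise NetworkError("n_pial_segments must be >= n_PA")

    if n_pa == 1:
        return [["ABN"] + [f"p{i}" for i in range(n_pial - 1)] + ["pa_root_0"]]

    min_binary = 2 * n_pa - 2
    if n_pial >= min_binary:
        tree = _binary_tree_leaves(n_pa)
        edges = list(nx.edge_dfs(tree, 0))
        leaves = sorted(n for n in tree if tree.out_degree(n) == 0)
        # distribute extra subdivisions round-robin over the tree edges
        extra = n_pial - len(edges)
        subdiv = [1 + extra // len(edges)] * len(edges)
        for i in range(extra % len(edges)):
            subdiv[i] += 1
        leaf_names = {leaf: f"pa_root_{k}" for k, leaf in enumerate(leaves)}
        node_names = {0: "ABN"}
        counter = 0
        chains: List[List[str]] = []
        for (u, v), parts in zip(edges, subdiv):
            if v not in node_names:
                node_names[v] = leaf_names.get(v, f"pb{v}")
            chain = [node_names[u]]
            for _ in range(parts - 1):
                chain.append(f"p{counter}")
                counter += 1
            chain.append(node_names[v])
            chains.append(chain)
        return chains

    # not enough segments for a full binary tree: fan chains out of the ABN
    chains = []
    base, rem = divmod(n_pial, n_pa)
    counter = 0
    for k in range(n_pa):
        parts = base + (1 if k < rem else 0)
        chain = ["ABN"]
        for _ in range(parts - 1):
            chain.append(f"p{counter}")
            counter += 1
        chain.append(f"pa_root_{k}")
        chains.append(chain)
    return chains


def generate_default_network(cfg: NetworkGenConfig = NetworkGenConfig()) -> VascularNetwork:
    """Build the default cerebrovascular network.

    One ABN and one VBN; a pial arteriolar tree of ``n_pial_segments``
    segments connecting the ABN to ``n_PA`` PA roots; each PA is a chain of
    ``segments_per_PA`` active segments whose maximal active diameter follows
    :func:`pa_taper_diameter` at the segment midpoint; each PA drains through
    a fixed sphincter/TZ/capillary chain to the VBN.  Deterministic for a
    given configuration.
    """
    net = VascularNetwork()
    net.add_node(NetworkNode("ABN", "artery_boundary", 60.0))
    net.add_node(NetworkNode("VBN", "vein_boundary", 10.0))

    chains = _pial_tree_edges(cfg)

    # node levels (graph distance from ABN, in segments) for the diameter taper
    level: Dict[str, int] = {"ABN": 0}
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            level.setdefault(b, level[a] + 1)
    max_level = max(level.values())

    def pial_diam(la: int, lb: int) -> float:
        f = 0.5 * (la + lb) / max_level
        return cfg.pial_d_root - (cfg.pial_d_root - cfg.pial_d_leaf) * f

    si = 0
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            for n in (a, b):
                if n not in net.nodes:
                    net.add_node(NetworkNode(n))
            d = pial_diam(level[a], level[b])
            net.add_segment(
                VesselSegment(
                    id=f"pial_{si}",
                    cls="pial",
                    node_a=a,
                    node_b=b,
                    length=cfg.pial_segment_length,
                    diameter=d,
                    d_active_max=d,
                    wall_thickness=WALL_THICKNESS_FRACTION * d,
                    cortical_depth=0.0,
                    contractility_index=1.0,
                    is_arteriolar=True,
                )
            )
            si += 1

    n_micro = 1 + cfg.n_tz_orders + cfg.n_cap_orders
    micro_classes = (
        ["sphincter"] + ["TZ"] * cfg.n_tz_orders + ["capillary"] * cfg.n_cap_orders
    )
    for k in range(cfg.n_PA):
        prev = f"pa_root_{k}"
        for j in range(cfg.segments_per_PA):
            depth_mid = (j + 0.5) * cfg.pa_segment_length
            d = pa_taper_diameter(depth_mid, cfg)
            nxt = f"pa{k}_n{j}"
            net.add_node(NetworkNode(nxt))
            net.add_segment(
                VesselSegment(
                    id=f"pa{k}_s{j}",
                    cls="PA",
                    node_a=prev,
                    node_b=nxt,
                    length=cfg.pa_segment_length,
                    diameter=d,
                    d_active_max=d,
                    wall_thickness=WALL_THICKNESS_FRACTION * d,
                    cortical_depth=depth_mid,
                    contractility_index=d / cfg.d_surface,
                    is_arteriolar=True,
                )
            )
            prev = nxt
        # Downstream microvessel chains: each chain is an equivalent single
        # tube for a bed of 2**m parallel Murray-law daughters at order m, so
        # the effective diameter shrinks as 2**(-m/12) (Murray 2**(-m/3) per
        # daughter, compensated by a 2**(m/4) parallel-count factor on the
        # D^4 conductance).  In "distributed" mode every PA node feeds one
        # such chain (the PA bifurcates at each depth) and each chain lumps
        # 1/segments_per_PA of the bed; in "leaf" mode a single chain at the
        # deepest node lumps the whole bed.
        if cfg.microvessel_attachment == "distributed":
            offtakes = [(j, f"pa{k}_n{j}") for j in range(cfg.segments_per_PA)]
            share = 1.0 / cfg.segments_per_PA
        elif cfg.microvessel_attachment == "leaf":
            offtakes = [(cfg.segments_per_PA - 1, prev)]
            share = 1.0
        else:
            raise NetworkError(
                f"unknown microvessel_attachment {cfg.microvessel_attachment!r}"
            )
        f_branch = share**0.25  # equal-resistance split of the lumped bed
        for j, start in offtakes:
            depth0 = (j + 1) * cfg.pa_segment_length
            d_loc = pa_taper_diameter(min(depth0, cfg.pa_length), cfg)
            node = start
            for mo in range(1, n_micro + 1):
                d_eff = d_loc * 2.0 ** (-mo / 12.0) * f_branch
                nxt = "VBN" if mo == n_micro else f"pa{k}_b{j}_m{mo}"
                if nxt != "VBN":
                    net.add_node(NetworkNode(nxt))
                net.add_segment(
                    VesselSegment(
                        id=f"pa{k}_b{j}_micro{mo}",
                        cls=micro_classes[mo - 1],
                        node_a=node,
                        node_b=nxt,
                        length=cfg.microvessel_length,
                        diameter=d_eff,
                        d_active_max=d_eff,
                        wall_thickness=WALL_THICKNESS_FRACTION * d_eff,
                        cortical_depth=depth0 + (mo - 0.5) * cfg.microvessel_length,
                        contractility_index=1.0,
                        is_arteriolar=False,
                    )
                )
                node = nxt

    net.validate()
    n_art = len(net.arteriolar_segments())
    expected = cfg.n_pial_segments + cfg.n_PA * cfg.segments_per_PA
    if n_art != expected:
        raise NetworkError(f"arteriolar segment count {n_art} != expected {expected}")
    return net


def arteriolar_coupling_graph(net: VascularNetwork) -> Dict[str, Set[str]]:
    """Adjacency among arteriolar segments: two segments couple iff they share a node.

    Non-arteriolar (sphincter/TZ/capillary) segments are excluded.  The map is
    symmetric and covers every arteriolar segment (possibly with an empty set).
    """
    adj: Dict[str, Set[str]] = {s.id: set() for s in net.arteriolar_segments()}
    by_node: Dict[str, List[str]] = {}
    for s in net.arteriolar_segments():
        by_node.setdefault(s.node_a, []).append(s.id)
        by_node.setdefault(s.node_b, []).append(s.id)
    for segs in by_node.values():
        for a in segs:
            for b in segs:
                if a != b:
                    adj[a].add(b)
    return adj


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = [
    "id",
    "class",
    "node_a",
    "node_b",
    "length_um",
    "diameter_um",
    "d_active_max_um",
    "h_um",
    "depth_um",
    "contractility",
    "is_arteriolar",
]


def _nodes_path(path: Path) -> Path:
    return path.with_suffix(".nodes.csv")


def write_network(net: VascularNetwork, path: str | Path) -> None:
    """Write a network to GraphML (single file) or CSV (edge list + node table).

    The CSV form writes the edge list to ``path`` and the node table to
    ``path`` with the suffix replaced by ``.nodes.csv``.
    """
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if path.suffix == ".csv":
        rows = [
            {
                "id": s.id,
                "class": s.cls,
                "node_a": s.node_a,
                "node_b": s.node_b,
                "length_um": s.length,
                "diameter_um": s.diameter,
                "d_active_max_um": s.d_active_max,
                "h_um": s.wall_thickness,
                "depth_um": s.cortical_depth,
                "contractility": s.contractility_index,
                "is_arteriolar": s.is_arteriolar,
            }
            for s in net.segments.values()
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, index=False)
        nrows = [
            {"id": n.id, "kind": n.kind, "boundary_pressure_mmhg": n.boundary_pressure}
            for n in net.nodes.values()
        ]
        pd.DataFrame(nrows).to_csv(_nodes_path(path), index=False)
        return
    raise NetworkError(f"unsupported network format {path.suffix!r} (use .graphml or .csv)")


def read_network(path: str | Path) -> VascularNetwork:
    """Read a network written by :func:`write_network`; validates on load."""
    path = Path(path)
    net = VascularNetwork()
    if path.suffix == ".graphml":
        try:
            g = nx.read_graphml(path, force_multigraph=True)
        except Exception as exc:  # malformed XML etc.
            raise NetworkError(f"cannot parse GraphML {path}: {exc}") from exc
        for nid, attrs in g.nodes(data=True):
            bp = attrs.get("boundary_pressure")
            net.add_node(NetworkNode(str(nid), attrs.get("kind", "interior"),
                                     None if bp is None else float(bp)))
        for u, v, attrs in g.edges(data=True):
            net.add_segment(_segment_from_attrs(str(u), str(v), attrs))
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise NetworkError(f"CSV edge list missing columns: {missing}")
        ndf = pd.read_csv(_nodes_path(path))
        for _, r in ndf.iterrows():
            bp = r.get("boundary_pressure_mmhg")
            bp = None if pd.isna(bp) else float(bp)
            net.add_node(NetworkNode(str(r["id"]), str(r["kind"]), bp))
        for _, r in df.iterrows():
            attrs = {
                "id": r["id"],
                "cls": r["class"],
                "length_um": r["length_um"],
                "diameter_um": r["diameter_um"],
                "d_active_max_um": r["d_active_max_um"],
                "h_um": r["h_um"],
                "depth_um": r["depth_um"],
                "contractility": r["contractility"],
                "is_arteriolar": r["is_arteriolar"],
            }
            net.add_segment(_segment_from_attrs(str(r["node_a"]), str(r["node_b"]), attrs))
    else:
        raise NetworkError(f"unsupported network format {path.suffix!r}")
    net.validate()
    return net


def _segment_from_attrs(u: str, v: str, attrs: dict) -> VesselSegment:
    required = ["id", "length_um", "diameter_um", "d_active_max_um", "h_um"]
    for key in required:
        if key not in attrs or pd.isna(attrs[key]):
            raise NetworkError(f"segment attribute {key!r} missing on edge {u}-{v}")
    is_art = attrs.get("is_arteriolar", False)
    if isinstance(is_art, str):
        is_art = is_art.strip().lower() in ("true", "1", "yes")
    return VesselSegment(
        id=str(attrs["id"]),
        cls=str(attrs.get("cls", attrs.get("class", "pial"))),
        node_a=u,
        node_b=v,
        length=float(attrs["length_um"]),
        diameter=float(attrs["diameter_um"]),
        d_active_max=float(attrs["d_active_max_um"]),
        wall_thickness=float(attrs["h_um"]),
        cortical_depth=float(attrs.get("depth_um", 0.0)),
        contractility_index=float(attrs.get("contractility", 1.0)),
        is_arteriolar=bool(is_art),
    )
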