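"""Channel-graph hemodynamics for the printed vascular plexus.

The chip's vascular network is a planar graph of cylindrical channels.  At the
perfusion rates used (a few mL/min through 0.5 mm channels) flow is laminar and
channels are long relative to their diameter, so each segment is modelled as a
Hagen-Poiseuille resistor with hydraulic conductance

    g = pi * d^4 / (128 * mu * L)

and the network is solved as a linear conductance system: fixed volumetric
inflow at the inlet node, pressure pinned to zero at the outlet, mass conserved
at every interior node.  Wall shear stress per segment follows the Poiseuille
closed form tau = 32 * mu * |Q| / (pi * d^3), reported in dyn/cm^2.

The bundled default layout approximates the printed plexus: a 6 mm footprint of
0.5 mm-diameter channels with two innermost horizontal rails (high-shear), two
outermost rails (mid-shear) and vertical interconnects between them (low-shear).
Junction losses and 3D entrance effects are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import units

DEFAULT_VISCOSITY_MPAS = 1.0   # culture medium ~ water at 37 C
DEFAULT_INLET_FLOW_ML_MIN = 2.4

ZONE_LABELS = ("low", "mid", "high")


class GeometryError(ValueError):
    """Invalid channel-graph description (naming the offending element)."""


class SolverError(RuntimeError):
    """The conductance system could not be solved."""


@dataclass(frozen=True)
class ChannelSegment:
    """One cylindrical channel between two nodes.  Lengths/diameters in um."""

    id: str
    node_a: str
    node_b: str
    diameter_um: float
    length_um: float
    zone_hint: str | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise GeometryError(f"segment {self.id!r}: diameter must be > 0")
        if self.length_um <= 0:
            raise GeometryError(f"segment {self.id!r}: length must be > 0")
        if self.node_a == self.node_b:
            raise GeometryError(f"segment {self.id!r}: node_a == node_b")
        if self.zone_hint is not None and self.zone_hint not in ZONE_LABELS:
            raise GeometryError(
                f"segment {self.id!r}: zone_hint {self.zone_hint!r} not in {ZONE_LABELS}"
            )

    def conductance(self, viscosity_mpas: float) -> float:
        """Hydraulic conductance g = pi d^4 / (128 mu L) in SI (m^3/(Pa s))."""
        d = units.um_to_m(self.diameter_um)
        length = units.um_to_m(self.length_um)
        mu = viscosity_mpas * units.MPAS_TO_PAS
        return math.pi * d**4 / (128.0 * mu * length)


@dataclass(frozen=True)
class VascularNetwork:
    """Validated channel graph with declared inlet and outlet nodes."""

    nodes: Mapping[str, tuple[float, float]]   # id -> (x_um, y_um)
    segments: Sequence[ChannelSegment]
    inlet: str
    outlet: str

    def __post_init__(self) -> None:
        if self.inlet not in self.nodes:
            raise GeometryError(f"inlet node {self.inlet!r} not declared")
        if self.outlet not in self.nodes:
            raise GeometryError(f"outlet node {self.outlet!r} not declared")
        if self.inlet == self.outlet:
            raise GeometryError("inlet and outlet must be distinct")
        if not self.segments:
            raise GeometryError("network has no segments")
        seen = set()
        for seg in self.segments:
            if seg.id in seen:
                raise GeometryError(f"duplicate segment id {seg.id!r}")
            seen.add(seg.id)
            for n in (seg.node_a, seg.node_b):
                if n not in self.nodes:
                    raise GeometryError(f"segment {seg.id!r}: node {n!r} not declared")
        g = self.graph()
        if not nx.is_connected(g):
            comp = min(nx.connected_components(g), key=len)
            raise GeometryError(f"graph is disconnected; isolated component: {sorted(comp)}")

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments:
            g.add_edge(seg.node_a, seg.node_b, key=seg.id, segment=seg)
        return g


@dataclass
class FlowSolution:
    """Steady-state pressures, flows, shear stresses and zone labels.

    ``segment_flow`` is signed (positive node_a -> node_b) in uL/min;
    ``node_pressure`` in Pa relative to the outlet; ``segment_shear`` in
    dyn/cm^2.
    """

    network: VascularNetwork
    node_pressure: dict[str, float]
    segment_flow: dict[str, float]
    segment_shear: dict[str, float]
    zone_map: dict[str, str] = field(default_factory=dict)
    inlet_flow_ml_min: float = float("nan")
    viscosity_mpas: float = float("nan")

    def max_interior_imbalance(self) -> float:
        """Largest absolute net flow at any interior node, in uL/min."""
        net: dict[str, float] = {n: 0.0 for n in self.network.nodes}
        for seg in self.network.segments:
            q = self.segment_flow[seg.id]
            net[seg.node_a] -= q
            net[seg.node_b] += q
        interior = [n for n in net if n not in (self.network.inlet, self.network.outlet)]
        if not interior:
            return 0.0
        return max(abs(net[n]) for n in interior)


@dataclass
class ZoneClassification:
    """Per-segment zone labels with the ordering check low < mid < high."""

    zone_map: dict[str, str]
    zone_mean_shear: dict[str, float]
    ordering_ok: bool
    violations: list[str]


def build_network(layout_config: Mapping) -> VascularNetwork:
    """Build a validated :class:`VascularNetwork` from a config mapping.

    Expected keys: ``nodes`` (mapping id -> [x_um, y_um] or list of
    ``{id, x_um, y_um}``), ``segments`` (list of ``{id, node_a, node_b,
    diameter_um, length_um, zone_hint?}``; ``length_um`` may be omitted, in
    which case the Euclidean node distance is used), ``inlet``, ``outlet``.
    """
    for key in ("nodes", "segments", "inlet", "outlet"):
        if key not in layout_config:
            raise GeometryError(f"geometry config missing required key {key!r}")

    raw_nodes = layout_config["nodes"]
    nodes: dict[str, tuple[float, float]] = {}
    if isinstance(raw_nodes, Mapping):
        items = [(str(k), v) for k, v in raw_nodes.items()]
    else:
        items = [(str(n["id"]), (n["x_um"], n["y_um"])) for n in raw_nodes]
    for nid, xy in items:
        x, y = float(xy[0]), float(xy[1])
        nodes[nid] = (x, y)

    segments = []
    for s in layout_config["segments"]:
        na, nb = str(s["node_a"]), str(s["node_b"])
        length = s.get("length_um")
        if length is None:
            if na not in nodes or nb not in nodes:
                raise GeometryError(f"segment {s.get('id')!r}: node {na!r} or {nb!r} not declared")
            (xa, ya), (xb, yb) = nodes[na], nodes[nb]
            length = math.hypot(xb - xa, yb - ya)
        segments.append(
            ChannelSegment(
                id=str(s["id"]),
                node_a=na,
                node_b=nb,
                diameter_um=float(s["diameter_um"]),
                length_um=float(length),
                zone_hint=s.get("zone_hint"),
            )
        )

    return VascularNetwork(
        nodes=nodes,
        segments=segments,
        inlet=str(layout_config["inlet"]),
        outlet=str(layout_config["outlet"]),
    )


def default_layout() -> dict:
    """Bundled plexus layout approximating the printed chip geometry.

    A 6 mm footprint of 0.5 mm-diameter channels: the inlet feeds two innermost
    horizontal rails that carry the bulk of the flow (high-shear); five
    vertical interconnects per side (low-shear) bleed flow to an outermost
    rail at the top and bottom of the device (mid-shear) before it returns to
    the outlet manifold.  All positions in um; channel lengths derive from node
    distances.  Every dimension is overridable through a user config.
    """
    nodes: dict[str, list[float]] = {
        "inlet": [0.0, 3000.0],
        "jin": [600.0, 3000.0],
        "jout": [5400.0, 3000.0],
        "outlet": [6000.0, 3000.0],
    }
    segments: list[dict] = [
        {"id": "feed_in", "node_a": "inlet", "node_b": "jin", "diameter_um": 500.0},
        {"id": "feed_out", "node_a": "jout", "node_b": "outlet", "diameter_um": 500.0},
    ]
    taps = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
    for side, y_inner, y_outer in (("t", 3400.0, 5600.0), ("b", 2600.0, 400.0)):
        rail = [600.0] + taps + [5400.0]
        for i, x in enumerate(rail):
            nodes[f"{side}i{i}"] = [x, y_inner]
        for k, x in enumerate(taps):
            nodes[f"{side}o{k}"] = [x, y_outer]
        # inlet/outlet manifold stubs onto the inner rail
        segments.append({"id": f"{side}_stub_in", "node_a": "jin",
                         "node_b": f"{side}i0", "diameter_um": 500.0,
                         "zone_hint": "high"})
        segments.append({"id": f"{side}_stub_out", "node_a": f"{side}i{len(rail) - 1}",
                         "node_b": "jout", "diameter_um": 500.0, "zone_hint": "high"})
        # innermost horizontal rail: high shear
        for i in range(len(rail) - 1):
            segments.append({"id": f"{side}_inner_{i}", "node_a": f"{side}i{i}",
                             "node_b": f"{side}i{i + 1}", "diameter_um": 500.0,
                             "zone_hint": "high"})
        # outermost rail: mid shear
        for k in range(len(taps) - 1):
            segments.append({"id": f"{side}_outer_{k}", "node_a": f"{side}o{k}",
                             "node_b": f"{side}o{k + 1}", "diameter_um": 500.0,
                             "zone_hint": "mid"})
        # vertical interconnects: low shear
        for k in range(len(taps)):
            segments.append({"id": f"{side}_vert_{k}", "node_a": f"{side}i{k + 1}",
                             "node_b": f"{side}o{k}", "diameter_um": 500.0,
                             "zone_hint": "low"})
    return {"nodes": nodes, "segments": segments, "inlet": "inlet", "outlet": "outlet"}


def default_network() -> VascularNetwork:
    return build_network(default_layout())


def solve_flow(
    network: VascularNetwork,
    inlet_flow_ml_min: float = DEFAULT_INLET_FLOW_ML_MIN,
    viscosity_mpas: float = DEFAULT_VISCOSITY_MPAS,
) -> FlowSolution:
    """Solve the linear conductance system for pressures, flows and shear.

    Fixed volumetric inflow at the inlet, outlet pressure pinned to 0 Pa
    (gauge).  Raises :class:`SolverError` on a singular system.
    """
    if inlet_flow_ml_min <= 0:
        raise ValueError("inlet_flow_ml_min must be > 0")
    if viscosity_mpas <= 0:
        raise ValueError("viscosity_mpas must be > 0")

    node_ids = list(network.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    q_in = units.ml_min_to_m3_s(inlet_flow_ml_min)

    lap = np.zeros((n, n))
    for seg in network.segments:
        g = seg.conductance(viscosity_mpas)
        a, b = idx[seg.node_a], idx[seg.node_b]
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g

    rhs = np.zeros(n)
    rhs[idx[network.inlet]] = q_in
    rhs[idx[network.outlet]] = -q_in
    # pin outlet gauge pressure to zero
    out = idx[network.outlet]
    lap[out, :] = 0.0
    lap[out, out] = 1.0
    rhs[out] = 0.0

    try:
        pressure = np.linalg.solve(lap, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validation
        raise SolverError(f"singular conductance system: {exc}") from exc
    if not np.all(np.isfinite(pressure)):
        raise SolverError("non-finite pressures; check for isolated subgraphs")

    node_pressure = {nid: float(pressure[idx[nid]]) for nid in node_ids}
    segment_flow: dict[str, float] = {}
    segment_shear: dict[str, float] = {}
    for seg in network.segments:
        g = seg.conductance(viscosity_mpas)
        q_si = g * (pressure[idx[seg.node_a]] - pressure[idx[seg.node_b]])
        q_ul_min = units.m3_s_to_ul_min(q_si)
        segment_flow[seg.id] = float(q_ul_min)
        segment_shear[seg.id] = wall_shear(seg, q_ul_min, viscosity_mpas)

    sol = FlowSolution(
        network=network,
        node_pressure=node_pressure,
        segment_flow=segment_flow,
        segment_shear=segment_shear,
        inlet_flow_ml_min=inlet_flow_ml_min,
        viscosity_mpas=viscosity_mpas,
    )
    if any(s.zone_hint is not None for s in network.segments):
        sol.zone_map = classify_zones(sol).zone_map
    return sol


def wall_shear(segment: ChannelSegment, flow_ul_min: float, viscosity_mpas: float) -> float:
    """Poiseuille wall shear stress tau = 32 mu |Q| / (pi d^3), in dyn/cm^2."""
    d = units.um_to_m(segment.diameter_um)
    mu = viscosity_mpas * units.MPAS_TO_PAS
    q = abs(flow_ul_min) * units.UL_PER_MIN_TO_M3_PER_S
    tau_pa = 32.0 * mu * q / (math.pi * d**3)
    return units.pa_to_dyn_cm2(tau_pa)


def classify_zones(
    solution: FlowSolution,
    thresholds: tuple[float, float] | None = None,
) -> ZoneClassification:
    """Label segments low/mid/high shear.

    When the geometry carries ``zone_hint`` labels they are authoritative and
    the mean-shear ordering low < mid < high is *verified*; a violation is
    flagged in the result, never raised.  Without hints, segments are split by
    the two shear cutoffs ``thresholds`` (dyn/cm^2).  Segments with no hint in
    a hinted geometry are left unlabelled ("unzoned") and excluded from means.
    """
    segs = solution.network.segments
    hinted = any(s.zone_hint is not None for s in segs)
    zone_map: dict[str, str] = {}
    if hinted:
        for s in segs:
            zone_map[s.id] = s.zone_hint if s.zone_hint is not None else "unzoned"
    else:
        if thresholds is None:
            raise ValueError("no zone hints in geometry and no shear thresholds supplied")
        lo, hi = thresholds
        if not lo < hi:
            raise ValueError("thresholds must satisfy low < high")
        for s in segs:
            tau = solution.segment_shear[s.id]
            zone_map[s.id] = "low" if tau < lo else ("mid" if tau < hi else "high")

    zone_mean: dict[str, float] = {}
    for z in ZONE_LABELS:
        taus = [solution.segment_shear[s.id] for s in segs if zone_map[s.id] == z]
        if taus:
            zone_mean[z] = float(np.mean(taus))

    violations: list[str] = []
    present = [z for z in ZONE_LABELS if z in zone_mean]
    for za, zb in zip(present[:-1], present[1:]):
        if not zone_mean[za] < zone_mean[zb]:
            violations.append(
                f"mean shear ordering violated: {za} ({zone_mean[za]:.3g}) >= "
                f"{zb} ({zone_mean[zb]:.3g}) dyn/cm^2"
            )
    return ZoneClassification(
        zone_map=zone_map,
        zone_mean_shear=zone_mean,
        ordering_ok=not violations,
        violations=violations,
    )
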