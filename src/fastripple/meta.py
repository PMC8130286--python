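"""Meta-analytic pooling of per-event causal p-values and network metrics.

Each directed interaction per fast ripple is a sub-hypothesis of the same
null (zero causality).  Within one event × epoch the six directed
p-values are Bonferroni-adjusted (×6, capped at 1); each directed
connection is then pooled across events with the normal-curve method:

    Z = (x̄ − 0.5) / (0.2887 / √n)

where x̄ is the mean of the event-level probabilities, n their count and
0.2887 the standard deviation of U[0, 1].  The lower-tail standard-normal
area at Z is the overall probability of the pooled connection; only
connections with overall p < 0.05 enter the network.

Graph metrics on the retained edges: *unit causal density* — significant
interactions involving a node, normalized by the number of nodes (high
values mark causal hubs); *causal flow* — out-degree minus in-degree
(positive: causal source; negative: causal sink).  Causal flow sums to
zero over the network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

from .causality import CausalEpochResult

UNIFORM_SD = 0.2887
ALPHA = 0.05
N_COMPARISONS = 6  # directed pairs within one event x epoch


@dataclass
class PooledConnection:
    cause: str
    effect: str
    epoch: str  # 'pre' | 'post'
    n: int
    count_significant: int  # events with adjusted p < 0.05
    count_significant_raw: int  # same, on raw p-values
    mean_p: float
    z: float
    overall_p: float

    @property
    def retained(self) -> bool:
        return self.overall_p < ALPHA


@dataclass
class CausalNetwork:
    epoch: str
    regions: tuple[str, ...]
    edges: list  # retained PooledConnection objects
    unit_causal_density: dict = field(default_factory=dict)
    causal_flow: dict = field(default_factory=dict)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.cause, e.effect) for e in self.edges}

    def to_graph(self):
        """networkx DiGraph with density/flow/role node attributes."""
        import networkx as nx

        g = nx.DiGraph()
        roles = classify_nodes(self)
        for r in self.regions:
            g.add_node(
                r,
                unit_causal_density=self.unit_causal_density[r],
                causal_flow=self.causal_flow[r],
                **roles[r],
            )
        for e in self.edges:
            g.add_edge(e.cause, e.effect, overall_p=e.overall_p, n=e.n)
        return g


def adjust_pvalues(
    results: list[CausalEpochResult], m: int = N_COMPARISONS
) -> list[CausalEpochResult]:
    """Bonferroni adjustment within each event × epoch: p ← min(m·p, 1).

    Excluded (NaN) entries propagate unchanged.  Returns new result
    objects; inputs are not mutated.
    """
    out = []
    for r in results:
        out.append(
            CausalEpochResult(
                event_id=r.event_id,
                regions=r.regions,
                pre_matrix=np.minimum(r.pre_matrix * m, 1.0),
                post_matrix=np.minimum(r.post_matrix * m, 1.0),
                pre_lags=dict(r.pre_lags),
                post_lags=dict(r.post_lags),
                pre_stationary=r.pre_stationary,
                post_stationary=r.post_stationary,
            )
        )
    return out


def pool_connection(p_values: np.ndarray, cause: str, effect: str, epoch: str,
                    raw_p_values: np.ndarray | None = None) -> PooledConnection:
    """Normal-curve pooling of one directed connection's p-values.

    x̄ = mean of the event-level probabilities; Z = (x̄ − 0.5)/(0.2887/√n);
    overall p = Φ(Z) (one-sided toward small p-values, so consistently
    small event-level probabilities give a small overall probability).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    n = len(p)
    if n < 2:
        raise ValueError(f"insufficient n ({n}) to pool {cause}->{effect} {epoch}")
    mean_p = float(np.mean(p))
    z = (mean_p - 0.5) / (UNIFORM_SD / np.sqrt(n))
    raw = np.asarray(raw_p_values, dtype=float) if raw_p_values is not None else p
    raw = raw[~np.isnan(raw)]
    return PooledConnection(
        cause=cause,
        effect=effect,
        epoch=epoch,
        n=n,
        count_significant=int(np.sum(p < ALPHA)),
        count_significant_raw=int(np.sum(raw < ALPHA)),
        mean_p=mean_p,
        z=float(z),
        overall_p=float(stats.norm.cdf(z)),
    )


def pool_all_connections(
    results: list[CausalEpochResult],
    adjust: bool = True,
) -> dict[str, list[PooledConnection]]:
    """Pool every directed connection for both epochs across usable events.

    ``adjust`` pools Bonferroni-adjusted p-values (default); raw pooling
    is available since the literature reading is uncertain.  Events whose
    segments failed the stationarity screen contribute to no connection.
    """
    if not results:
        raise ValueError("no epoch results to pool")
    usable = [r for r in results if r.usable]
    if not usable:
        raise ValueError("no events passed the stationarity screen")
    adjusted = adjust_pvalues(usable) if adjust else usable
    regions = usable[0].regions
    pooled: dict[str, list[PooledConnection]] = {"pre": [], "post": []}
    for epoch in ("pre", "post"):
        attr = f"{epoch}_matrix"
        for i, j in permutations(range(len(regions)), 2):
            ps = np.array([getattr(r, attr)[i, j] for r in adjusted])
            raw = np.array([getattr(r, attr)[i, j] for r in usable])
            pooled[epoch].append(
                pool_connection(ps, regions[i], regions[j], epoch, raw_p_values=raw)
            )
    return pooled


def build_network(
    pooled: list[PooledConnection], epoch: str, regions: tuple[str, ...]
) -> CausalNetwork:
    """Retain overall-significant edges and compute density and flow."""
    edges = [c for c in pooled if c.epoch == epoch and c.retained]
    n_nodes = len(regions)
    density = {r: 0.0 for r in regions}
    flow = {r: 0 for r in regions}
    for e in edges:
        density[e.cause] += 1.0 / n_nodes
        density[e.effect] += 1.0 / n_nodes
        flow[e.cause] += 1
        flow[e.effect] -= 1
    return CausalNetwork(
        epoch=epoch,
        regions=regions,
        edges=edges,
        unit_causal_density=density,
        causal_flow=flow,
    )


def classify_nodes(network: CausalNetwork) -> dict[str, dict]:
    """Node roles: hub (maximal density, ties shared), source/sink by flow.

    An empty network leaves every node neutral (no hub, zero flow).
    """
    out = {}
    densities = network.unit_causal_density
    max_d = max(densities.values()) if densities else 0.0
    for r in network.regions:
        f = network.causal_flow[r]
        out[r] = {
            "hub": bool(max_d > 0 and densities[r] == max_d),
            "flow_role": "source" if f > 0 else ("sink" if f < 0 else "neutral"),
        }
    return out
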