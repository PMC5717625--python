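"""A priori causal network for the desert food-web SEM.

The model is a piecewise structural equation model: a directed graph in
which every endogenous node (a species group or a vegetation attribute)
carries its own local regression model, estimated independently of the
others.  The canonical graph encodes nine local models — insectivorous
dasyurids, spinifex cover, spinifex seed, rodents, mulgara, feral cat,
red fox, dingo and reptiles — totalling 26 directed effects.

Two kinds of edges are distinguished.  *Direct-dependency* edges feed one
node's response column straight into another node's linear predictor
(spinifex cover -> spinifex seed -> rodents); these must form a DAG because
scenario projection propagates predictions along them.  *Observed-rate*
edges enter as effort-standardised rates measured in the field (e.g.
rodents per 100 trap-nights as a predictor of dingo activity); they are
treated as observed covariates at fit time, so apparent feedback loops
through them (rodents <-> predators) do not obstruct local estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import yaml

#: predictor column -> source node or exogenous driver
TERM_SOURCES = {
    "site": "site",
    "mean_event_size_lag2": "rain_event_size_lag2",
    "mulgara_per_100tn": "mulgara",
    "years_since_fire": "wildfire",
    "rain_8mo": "rainfall_8mo",
    "spinifex_cover": "spinifex_cover",
    "seed_index": "spinifex_seed",
    "cat_per_cn": "cat",
    "fox_per_cn": "fox",
    "dingo_per_cn": "dingo",
    "rodents_per_100tn": "rodents",
    "phase": "phase",
    "phase:dingo_per_cn": "phase:dingo",
    "rain_days": "rain_days",
}

#: response column -> node name (used to detect direct dependencies)
RESPONSE_NODES = {
    "dasyurids": "dasyurids",
    "spinifex_cover": "spinifex_cover",
    "seed_index": "spinifex_seed",
    "rodents": "rodents",
    "mulgara": "mulgara",
    "cat": "cat",
    "fox": "fox",
    "dingo": "dingo",
    "reptiles": "reptiles",
}


@dataclass(frozen=True)
class NodeSpec:
    """Specification of one local model in the piecewise SEM."""

    name: str
    family: str  # 'poisson' | 'binomial'
    response: str
    predictors: tuple[str, ...]
    offset: str | None = None
    random_factor: str = "trip"
    binomial_denominator: int | None = None
    z_transform_predictors: bool = False
    categorical: tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in ("poisson", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.predictors if ":" in t)


@dataclass
class ModelGraph:
    """A validated collection of :class:`NodeSpec` with derived edges."""

    nodes: list[NodeSpec] = field(default_factory=list)

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Directed (source, target) pairs, one per predictor term."""
        out = []
        for spec in self.nodes:
            for term in spec.predictors:
                src = TERM_SOURCES.get(term, term)
                out.append((src, spec.name))
        return out

    def direct_dependency_edges(self) -> list[tuple[str, str]]:
        """Edges where a node's response column feeds another node directly."""
        node_names = {n.name for n in self.nodes}
        out = []
        for spec in self.nodes:
            for term in spec.predictors:
                src = RESPONSE_NODES.get(term)
                if src is not None and src in node_names and src != spec.name:
                    out.append((src, spec.name))
        return out

    def propagation_order(self) -> list[str]:
        """Topological order of nodes along direct dependencies."""
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from(self.direct_dependency_edges())
        return list(nx.topological_sort(g))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"nodes": [asdict(n) for n in self.nodes]}, sort_keys=False
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelGraph":
        raw = yaml.safe_load(text)
        nodes = []
        for d in raw["nodes"]:
            d["predictors"] = tuple(d["predictors"])
            d["categorical"] = tuple(d.get("categorical", ()))
            nodes.append(NodeSpec(**d))
        return cls(nodes=nodes)

    def render(self) -> str:
        lines = []
        for n in self.nodes:
            link = "log" if n.family == "poisson" else "logit"
            rhs = " + ".join(n.predictors)
            extra = f" + (1|{n.random_factor})"
            if n.offset:
                extra += f" + offset(log {n.offset})"
            lines.append(f"{link}({n.response}) <- {rhs}{extra}")
        return "\n".join(lines)


def canonical_graph() -> ModelGraph:
    """The nine-model desert food-web network (26 directed effects).

    Poisson nodes carry a log sampling-effort offset (trap-nights for
    pitfall captures, camera-nights for predator photographs); the two
    vegetation nodes are binomial-logit with denominators 100 (percentage
    cover) and 5 (seed index).  All nodes share a trip-level random
    intercept.  The red-fox model z-transforms its predictors, which was
    needed for convergence on the original data.
    """
    n = [
        NodeSpec(
            name="dasyurids",
            family="poisson",
            response="dasyurids",
            predictors=("site", "mean_event_size_lag2", "mulgara_per_100tn"),
            offset="trap_nights",
            categorical=("site",),
        ),
        NodeSpec(
            name="spinifex_cover",
            family="binomial",
            response="spinifex_cover",
            predictors=("years_since_fire", "rain_8mo"),
            binomial_denominator=100,
        ),
        NodeSpec(
            name="spinifex_seed",
            family="binomial",
            response="seed_index",
            predictors=("spinifex_cover", "rain_8mo"),
            binomial_denominator=5,
        ),
        NodeSpec(
            name="rodents",
            family="poisson",
            response="rodents",
            predictors=("seed_index", "cat_per_cn", "fox_per_cn", "dingo_per_cn"),
            offset="trap_nights",
        ),
        NodeSpec(
            name="mulgara",
            family="poisson",
            response="mulgara",
            predictors=("rodents_per_100tn", "spinifex_cover", "years_since_fire"),
            offset="trap_nights",
        ),
        NodeSpec(
            name="cat",
            family="poisson",
            response="cat",
            predictors=(
                "rodents_per_100tn",
                "dingo_per_cn",
                "phase",
                "phase:dingo_per_cn",
            ),
            offset="camera_nights",
        ),
        NodeSpec(
            name="fox",
            family="poisson",
            response="fox",
            predictors=(
                "rodents_per_100tn",
                "dingo_per_cn",
                "phase",
                "phase:dingo_per_cn",
            ),
            offset="camera_nights",
            z_transform_predictors=True,
        ),
        NodeSpec(
            name="dingo",
            family="poisson",
            response="dingo",
            predictors=("rodents_per_100tn",),
            offset="camera_nights",
        ),
        NodeSpec(
            name="reptiles",
            family="poisson",
            response="reptiles",
            predictors=("years_since_fire", "spinifex_cover", "rain_days"),
            offset="trap_nights",
        ),
    ]
    return ModelGraph(nodes=n)


def count_edges(graph: ModelGraph) -> int:
    """Number of directed effects; an interaction term counts once."""
    return len(graph.edges)


def validate_graph(graph: ModelGraph, schema: dict[str, set[str]] | set[str]) -> list[str]:
    """Check a graph against an available-column schema.

    ``schema`` is the set of columns present in the assembled node frames
    (or a mapping whose keys are those columns).  Returns a list of
    human-readable violations; an empty list means the graph is usable.
    """
    columns = set(schema)
    violations: list[str] = []
    seen = set()
    for spec in graph.nodes:
        if spec.name in seen:
            violations.append(f"duplicate node name {spec.name!r}")
        seen.add(spec.name)
        if spec.family == "poisson" and spec.offset is None:
            violations.append(f"poisson node {spec.name!r} has no offset")
        if spec.family == "binomial" and spec.binomial_denominator is None:
            violations.append(f"binomial node {spec.name!r} has no denominator")
        for col in (spec.response, spec.offset, spec.random_factor):
            if col is not None and col not in columns:
                violations.append(f"node {spec.name!r}: missing column {col!r}")
        for term in spec.predictors:
            parts = term.split(":")
            if len(parts) > 1:
                for p in parts:
                    if p not in spec.predictors:
                        violations.append(
                            f"node {spec.name!r}: interaction {term!r} references "
                            f"undeclared main effect {p!r}"
                        )
            for p in parts:
                if p not in columns:
                    violations.append(f"node {spec.name!r}: missing column {p!r}")
    g = nx.DiGraph()
    g.add_nodes_from(n.name for n in graph.nodes)
    g.add_edges_from(graph.direct_dependency_edges())
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        violations.append("cycle in direct dependencies: " + " -> ".join(e[0] for e in cyc))
    return violations
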