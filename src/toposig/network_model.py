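"""Domain types and readers/writers for interaction networks, differential
expression sets and gene-set collections.

All identifiers are normalized (uppercased, surrounding whitespace stripped)
at ingest so that every downstream stage compares entities consistently.  No
probe-to-gene or cross-accession mapping is attempted: inputs are assumed to
carry pre-mapped symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "Effect",
    "Edge",
    "InteractionNetwork",
    "DifferentialSet",
    "GeneSetCollection",
    "ReferenceUniverse",
    "NetworkParseError",
    "DifferentialSetError",
    "GeneSetError",
    "normalize_id",
    "read_network",
    "write_network",
    "filter_by_interaction_type",
    "read_differential_set",
    "differential_set_from_ratios",
    "read_gmt",
    "RATIO_UP_THRESHOLD",
    "RATIO_DOWN_THRESHOLD",
]

#: iTRAQ-style treated/control ratio cut-offs: ratio >= 1.2 flags a protein
#: up-regulated, ratio <= 0.83 flags it down-regulated (boundaries inclusive).
RATIO_UP_THRESHOLD = 1.2
RATIO_DOWN_THRESHOLD = 0.83


class NetworkParseError(ValueError):
    """Malformed network file."""


class DifferentialSetError(ValueError):
    """Malformed or self-contradictory differential-expression table."""


class GeneSetError(ValueError):
    """Malformed gene-set (GMT) collection."""


class InteractionType(str, Enum):
    transcriptional_regulation = "transcriptional_regulation"
    binding = "binding"
    phosphorylation = "phosphorylation"
    other = "other"


class Effect(str, Enum):
    activation = "activation"
    inhibition = "inhibition"
    unspecified = "unspecified"


def normalize_id(identifier: str) -> str:
    """Normalize an entity identifier: strip surrounding whitespace, uppercase.

    Raises ``ValueError`` for identifiers that are empty after stripping.
    """
    norm = identifier.strip().upper()
    if not norm:
        raise ValueError("empty identifier")
    return norm


@dataclass(frozen=True)
class Edge:
    """A typed, signed, weighted directed interaction."""

    source: str
    target: str
    interaction_type: InteractionType
    effect: Effect = Effect.unspecified
    trust: int = 1


@dataclass
class InteractionNetwork:
    """Directed network of molecular entities with typed, signed edges.

    ``nodes`` may include isolated entities (measured but unconnected);
    every edge endpoint is always a member of ``nodes``.  At most one edge
    exists per (source, target, interaction_type) triple.
    """

    nodes: set[str]
    edges: list[Edge]
    _digraph: Optional[nx.DiGraph] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, InteractionType]] = set()
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(
                    f"edge {e.source}->{e.target} has endpoint outside node set"
                )
            key = (e.source, e.target, e.interaction_type)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    # -- graph views -------------------------------------------------------

    def digraph(self) -> nx.DiGraph:
        """Simple directed view (edge types merged), cached.

        Reachability and distances ignore interaction type and effect; the
        dependency graph of a regulator is traced over every edge kind.
        """
        if self._digraph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from((e.source, e.target) for e in self.edges)
            self._digraph = g
        return self._digraph

    def multigraph(self) -> nx.MultiDiGraph:
        """Typed multigraph view, one keyed edge per interaction type."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                key=e.interaction_type.value,
                effect=e.effect,
                trust=e.trust,
            )
        return g

    def out_degree_nodes(self) -> list[str]:
        """Nodes with at least one outgoing edge, sorted."""
        return sorted({e.source for e in self.edges})

    def successors(
        self, node: str, interaction_type: Optional[InteractionType] = None
    ) -> set[str]:
        if interaction_type is None:
            return {e.target for e in self.edges if e.source == node}
        return {
            e.target
            for e in self.edges
            if e.source == node and e.interaction_type is interaction_type
        }


@dataclass
class DifferentialSet:
    """A measured universe plus the subsets flagged differentially expressed.

    ``ratios`` optionally carries treated/control ratios (dimensionless);
    when a set is built from ratios the iTRAQ thresholds define the flags.
    """

    universe: set[str]
    de_up: set[str]
    de_down: set[str]
    ratios: Optional[dict[str, float]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.de_up <= self.universe:
            raise DifferentialSetError("de_up not a subset of the universe")
        if not self.de_down <= self.universe:
            raise DifferentialSetError("de_down not a subset of the universe")
        common = self.de_up & self.de_down
        if common:
            raise DifferentialSetError(
                f"identifiers flagged both up and down: {sorted(common)[:5]}"
            )

    @property
    def de_all(self) -> set[str]:
        return self.de_up | self.de_down

    def side(self, which: str) -> set[str]:
        """DE subset for a side: ``up``, ``down`` or ``both``."""
        if which == "up":
            return set(self.de_up)
        if which == "down":
            return set(self.de_down)
        if which == "both":
            return self.de_all
        raise ValueError(f"unknown DE side {which!r}; use up, down or both")


@dataclass
class GeneSetCollection:
    """Named functional gene sets (GMT-style): name -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise GeneSetError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return sorted(self.sets)


@dataclass(frozen=True)
class ReferenceUniverse:
    """Background identifier set for an enrichment computation."""

    ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("reference universe is empty")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def of(cls, ids: Iterable[str]) -> "ReferenceUniverse":
        return cls(frozenset(ids))


# ---------------------------------------------------------------------------
# Network IO
# ---------------------------------------------------------------------------

_TYPE_TOKENS = {t.value: t for t in InteractionType}
_EFFECT_TOKENS = {e.value: e for e in Effect}


def _parse_interaction_type(token: str, lineno: int) -> InteractionType:
    tok = token.strip().lower()
    if tok not in _TYPE_TOKENS:
        raise NetworkParseError(
            f"line {lineno}: unknown interaction_type {token!r}; "
            f"accepted tokens: {sorted(_TYPE_TOKENS)}"
        )
    return _TYPE_TOKENS[tok]


def _parse_effect(token: str, lineno: int) -> Effect:
    tok = token.strip().lower()
    if tok not in _EFFECT_TOKENS:
        raise NetworkParseError(
            f"line {lineno}: unknown effect {token!r}; "
            f"accepted tokens: {sorted(_EFFECT_TOKENS)}"
        )
    return _EFFECT_TOKENS[tok]


def _build_network(raw_edges: list[Edge], origin: str) -> InteractionNetwork:
    """Collapse duplicates (max trust wins), drop self-loops, log a report."""
    n_self = 0
    collapsed: dict[tuple[str, str, InteractionType], Edge] = {}
    for e in raw_edges:
        if e.source == e.target:
            n_self += 1
            continue
        key = (e.source, e.target, e.interaction_type)
        prev = collapsed.get(key)
        if prev is None or e.trust > prev.trust:
            collapsed[key] = e
    edges = list(collapsed.values())
    nodes = {e.source for e in edges} | {e.target for e in edges}
    n_dup = len(raw_edges) - n_self - len(edges)
    if n_self:
        logger.warning("%s: dropped %d self-loop edge(s)", origin, n_self)
    logger.info(
        "%s: %d edge line(s), %d collapsed duplicate(s), %d edges, %d nodes",
        origin, len(raw_edges), n_dup, len(edges), len(nodes),
    )
    return InteractionNetwork(nodes=nodes, edges=edges)


def _read_edge_tsv(path: Path) -> list[Edge]:
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                src, typ, dst = fields
                effect, trust = Effect.unspecified, 1
            elif len(fields) == 5:
                src, typ, dst, eff, tr = fields
                effect = _parse_effect(eff, lineno)
                try:
                    trust = int(tr)
                except ValueError:
                    raise NetworkParseError(
                        f"line {lineno}: trust must be an integer, got {tr!r}"
                    ) from None
                if trust < 0:
                    raise NetworkParseError(
                        f"line {lineno}: trust must be non-negative, got {trust}"
                    )
            else:
                raise NetworkParseError(
                    f"line {lineno}: expected 5 fields "
                    f"(source, interaction_type, target, effect, trust) "
                    f"or 3, got {len(fields)}"
                )
            edges.append(
                Edge(
                    source=normalize_id(src),
                    target=normalize_id(dst),
                    interaction_type=_parse_interaction_type(typ, lineno),
                    effect=effect,
                    trust=trust,
                )
            )
    return edges


def _read_sif(path: Path) -> list[Edge]:
    # Cytoscape SIF: "source type target [target...]"; tab-delimited when a
    # tab is present, otherwise whitespace-delimited.
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise NetworkParseError(
                    f"line {lineno}: expected at least 3 fields "
                    f"(source, interaction_type, target...), got {len(fields)}"
                )
            src = normalize_id(fields[0])
            typ = _parse_interaction_type(fields[1], lineno)
            for dst in fields[2:]:
                edges.append(
                    Edge(source=src, target=normalize_id(dst),
                         interaction_type=typ)
                )
    return edges


def read_network(path: str | Path, format: str = "edge_tsv") -> InteractionNetwork:
    """Read a directed interaction network from ``edge_tsv`` or ``sif``.

    Duplicate (source, target, interaction_type) edges are collapsed keeping
    the maximum trust; self-loops are dropped with a logged warning.
    """
    path = Path(path)
    if format == "edge_tsv":
        raw = _read_edge_tsv(path)
    elif format == "sif":
        raw = _read_sif(path)
    else:
        raise ValueError(f"unknown network format {format!r}; use edge_tsv or sif")
    return _build_network(raw, str(path))


def write_network(
    net: InteractionNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Write a network in ``edge_tsv`` (full attributes) or ``sif`` dialect."""
    path = Path(path)
    edges = sorted(
        net.edges, key=lambda e: (e.source, e.target, e.interaction_type.value)
    )
    with open(path, "w", encoding="utf-8") as fh:
        if format == "edge_tsv":
            for e in edges:
                fh.write(
                    f"{e.source}\t{e.interaction_type.value}\t{e.target}\t"
                    f"{e.effect.value}\t{e.trust}\n"
                )
        elif format == "sif":
            for e in edges:
                fh.write(f"{e.source}\t{e.interaction_type.value}\t{e.target}\n")
        else:
            raise ValueError(
                f"unknown network format {format!r}; use edge_tsv or sif"
            )


def filter_by_interaction_type(
    net: InteractionNetwork, types: set[InteractionType] | Iterable[InteractionType]
) -> InteractionNetwork:
    """Keep exactly the edges whose type is in ``types``.

    The node set is restricted to the remaining edge endpoints (an empty
    result is permitted).
    """
    types = set(types)
    if not types:
        raise ValueError("types must be non-empty")
    edges = [e for e in net.edges if e.interaction_type in types]
    nodes = {e.source for e in edges} | {e.target for e in edges}
    return InteractionNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Differential sets
# ---------------------------------------------------------------------------

def differential_set_from_ratios(
    ratios: Mapping[str, float],
    label: str = "",
    up_threshold: float = RATIO_UP_THRESHOLD,
    down_threshold: float = RATIO_DOWN_THRESHOLD,
) -> DifferentialSet:
    """Build a DifferentialSet from treated/control ratios.

    iTRAQ rule, boundaries inclusive: ratio >= ``up_threshold`` is
    up-regulated, ratio <= ``down_threshold`` is down-regulated, anything
    in between is measured but unchanged.
    """
    norm = {normalize_id(k): float(v) for k, v in ratios.items()}
    up = {i for i, r in norm.items() if r >= up_threshold}
    down = {i for i, r in norm.items() if r <= down_threshold}
    return DifferentialSet(
        universe=set(norm), de_up=up, de_down=down, ratios=norm, label=label
    )


def read_differential_set(
    path: str | Path,
    label: str = "",
    up_threshold: float = RATIO_UP_THRESHOLD,
    down_threshold: float = RATIO_DOWN_THRESHOLD,
) -> DifferentialSet:
    """Read a DE table: header row with ``id`` then ``direction`` or ``ratio``.

    ``direction`` values are ``up``, ``down`` or ``none``; when only a
    ``ratio`` column is present, directions follow the iTRAQ thresholds.
    Identifiers repeated with contradictory directions are an error.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "id" not in cols:
        raise DifferentialSetError(f"{path}: missing required column 'id'")
    has_dir = "direction" in cols
    has_ratio = "ratio" in cols
    if not has_dir and not has_ratio:
        raise DifferentialSetError(
            f"{path}: need a 'direction' or a 'ratio' column"
        )

    label = label or path.stem
    if has_ratio and not has_dir:
        try:
            ratio_vals = df["ratio"].astype(float)
        except ValueError as exc:
            raise DifferentialSetError(f"{path}: non-numeric ratio: {exc}") from None
        ratios: dict[str, float] = {}
        for ident, r in zip(df["id"], ratio_vals):
            key = normalize_id(str(ident))
            if key in ratios and ratios[key] != r:
                raise DifferentialSetError(
                    f"{path}: identifier {key!r} repeated with differing ratios"
                )
            ratios[key] = float(r)
        return differential_set_from_ratios(
            ratios, label=label,
            up_threshold=up_threshold, down_threshold=down_threshold,
        )

    directions: dict[str, str] = {}
    for ident, d in zip(df["id"], df["direction"]):
        key = normalize_id(str(ident))
        val = str(d).strip().lower()
        if val not in ("up", "down", "none"):
            raise DifferentialSetError(
                f"{path}: direction must be up, down or none, got {d!r}"
            )
        if key in directions and directions[key] != val:
            raise DifferentialSetError(
                f"{path}: identifier {key!r} has contradictory directions"
            )
        directions[key] = val
    ratios = None
    if has_ratio:
        try:
            ratios = {
                normalize_id(str(i)): float(r)
                for i, r in zip(df["id"], df["ratio"])
            }
        except ValueError as exc:
            raise DifferentialSetError(f"{path}: non-numeric ratio: {exc}") from None
    return DifferentialSet(
        universe=set(directions),
        de_up={i for i, d in directions.items() if d == "up"},
        de_down={i for i, d in directions.items() if d == "down"},
        ratios=ratios,
        label=label,
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (MSigDB convention): name TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path} line {lineno}: gene set needs a name, a "
                    f"description and at least one member"
                )
            name = fields[0].strip()
            if name in sets:
                raise GeneSetError(f"{path} line {lineno}: duplicate set name {name!r}")
            members = frozenset(
                normalize_id(m) for m in fields[2:] if m.strip()
            )
            if not members:
                raise GeneSetError(f"{path} line {lineno}: set {name!r} has no members")
            sets[name] = (fields[1].strip(), members)
    return GeneSetCollection(sets=sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in gsc.names():
            desc, members = gsc.sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
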