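"""Regulatory network topologies and the ``.topo`` edge-list format.

A topology is a list of named nodes plus signed, mechanism-tagged directed
edges.  The same object feeds three consumers: the mechanistic ODE model
(where the mechanism tag selects shifted-Hill vs microRNA kinetics), the
random-parameter ensemble engine (which ignores mechanisms and treats every
edge as a shifted-Hill interaction), and the sign-randomization null model.

The on-disk format is the whitespace-delimited ``.topo`` dialect used by
random-circuit-perturbation tools: a header line ``Source Target Type`` and
one row per edge with ``Type`` 1 (activation) or 2 (inhibition).  An optional
fourth column ``Mechanism`` in {T, I, R} (transcriptional, indirect,
microRNA) is accepted and defaults to T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

ACTIVATION = "activation"
INHIBITION = "inhibition"
SIGNS = (ACTIVATION, INHIBITION)

TRANSCRIPTIONAL = "transcriptional"
INDIRECT = "indirect"
MIRNA = "mirna"
MECHANISMS = (TRANSCRIPTIONAL, INDIRECT, MIRNA)

_TYPE_TO_SIGN = {1: ACTIVATION, 2: INHIBITION}
_SIGN_TO_TYPE = {ACTIVATION: 1, INHIBITION: 2}
_CODE_TO_MECH = {"T": TRANSCRIPTIONAL, "I": INDIRECT, "R": MIRNA}
_MECH_TO_CODE = {v: k for k, v in _CODE_TO_MECH.items()}


class TopologyError(ValueError):
    """Raised for malformed topology files or invalid topology objects."""


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed, directed regulatory interaction."""

    source: str
    target: str
    sign: str
    mechanism: str = TRANSCRIPTIONAL

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise TopologyError(f"invalid sign {self.sign!r}")
        if self.mechanism not in MECHANISMS:
            raise TopologyError(f"invalid mechanism {self.mechanism!r}")

    @property
    def is_activation(self) -> bool:
        return self.sign == ACTIVATION


@dataclass
class NetworkTopology:
    """Named nodes plus signed directed edges, with validation."""

    nodes: list[str]
    edges: list[RegulatoryEdge]
    name: str = "topology"

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise TopologyError("duplicate node names")
        node_set = set(self.nodes)
        pairs = [(e.source, e.target) for e in self.edges]
        dup = [p for p, c in Counter(pairs).items() if c > 1]
        if dup:
            raise TopologyError(f"duplicate (source, target) pairs: {dup}")
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise TopologyError(
                    f"edge {e.source}->{e.target} references unknown node"
                )

    # ---- degree / sign bookkeeping -------------------------------------
    @property
    def n_activation(self) -> int:
        return sum(1 for e in self.edges if e.is_activation)

    @property
    def n_inhibition(self) -> int:
        return len(self.edges) - self.n_activation

    def in_degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.target] += 1
        return d

    def out_degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.source] += 1
        return d

    def sign_vector(self) -> tuple[bool, ...]:
        """Activation flags in edge order (the coordinate randomization permutes)."""
        return tuple(e.is_activation for e in self.edges)

    def with_signs(self, activation_flags: Iterable[bool], name: str | None = None
                   ) -> "NetworkTopology":
        """Same endpoints and mechanisms, new activation/inhibition assignment."""
        flags = list(activation_flags)
        if len(flags) != len(self.edges):
            raise TopologyError("sign vector length mismatch")
        edges = [
            RegulatoryEdge(e.source, e.target,
                           ACTIVATION if f else INHIBITION, e.mechanism)
            for e, f in zip(self.edges, flags)
        ]
        return NetworkTopology(list(self.nodes), edges,
                               name=name or f"{self.name}-resigned")

    def incoming(self, node: str) -> list[RegulatoryEdge]:
        return [e for e in self.edges if e.target == node]


# ---------------------------------------------------------------------------
# Shipped circuits
# ---------------------------------------------------------------------------

def core_emt() -> NetworkTopology:
    """Three-node core EMT circuit: SNAIL / miR-200 / ZEB.

    SNAIL is the external EMT-inducing signal; ZEB and miR-200 form the
    mutually inhibitory toggle with ZEB self-activation, and miR-200
    silences ZEB through its mRNA binding sites (mechanism ``mirna``).
    """
    nodes = ["SNAIL", "miR200", "ZEB"]
    edges = [
        RegulatoryEdge("SNAIL", "ZEB", ACTIVATION),
        RegulatoryEdge("SNAIL", "miR200", INHIBITION),
        RegulatoryEdge("ZEB", "miR200", INHIBITION),
        RegulatoryEdge("miR200", "ZEB", INHIBITION, MIRNA),
        RegulatoryEdge("ZEB", "ZEB", ACTIVATION),
    ]
    return NetworkTopology(nodes, edges, name="core")


def wildtype_coupled() -> NetworkTopology:
    """Five-node coupled EMT-NFATc circuit (6 activations, 5 inhibitions).

    On top of the core toggle, E-cadherin reports the epithelial program
    (repressed by ZEB, feeding back on ZEB indirectly through beta-catenin
    sequestration), NFATc activates ZEB, miR-200 and E-cadherin, and the
    SNAIL input amplifies its own expression.  The published schematic is
    not machine-readable and the eleventh (activating) edge cannot be
    pinned down from text; of the readings consistent with the 6/5 sign
    count, SNAIL self-amplification is the one that also reproduces the
    reported ensemble statistics (tristable-phase enrichment, hybrid-
    dominant basin sizes).  In the mechanistic ODE model SNAIL is the
    clamped input, so the self-edge is inert there.
    """
    nodes = ["SNAIL", "miR200", "ZEB", "Ecad", "NFATc"]
    edges = [
        RegulatoryEdge("SNAIL", "ZEB", ACTIVATION),
        RegulatoryEdge("SNAIL", "miR200", INHIBITION),
        RegulatoryEdge("ZEB", "miR200", INHIBITION),
        RegulatoryEdge("miR200", "ZEB", INHIBITION, MIRNA),
        RegulatoryEdge("ZEB", "ZEB", ACTIVATION),
        RegulatoryEdge("ZEB", "Ecad", INHIBITION),
        RegulatoryEdge("Ecad", "ZEB", INHIBITION, INDIRECT),
        RegulatoryEdge("NFATc", "ZEB", ACTIVATION),
        RegulatoryEdge("NFATc", "miR200", ACTIVATION),
        RegulatoryEdge("NFATc", "Ecad", ACTIVATION),
        RegulatoryEdge("SNAIL", "SNAIL", ACTIVATION),
    ]
    return NetworkTopology(nodes, edges, name="coupled")


def single_node() -> NetworkTopology:
    """One unregulated node; its unique steady state is g/k."""
    return NetworkTopology(["A"], [], name="single")


def toggle_switch() -> NetworkTopology:
    """Mutually inhibitory two-node switch, the canonical bistable toy."""
    return NetworkTopology(
        ["A", "B"],
        [RegulatoryEdge("A", "B", INHIBITION), RegulatoryEdge("B", "A", INHIBITION)],
        name="toggle",
    )


# ---------------------------------------------------------------------------
# .topo file I/O
# ---------------------------------------------------------------------------

def read_topo(path: str | Path) -> NetworkTopology:
    """Parse a ``.topo`` edge list; node order follows first appearance."""
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln.split()) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise TopologyError(f"{path}: empty file")
    header = [c.lower() for c in rows[0][1]]
    if header[:3] != ["source", "target", "type"]:
        raise TopologyError(f"{path}: line 1: expected header 'Source Target Type'")
    nodes: list[str] = []
    edges: list[RegulatoryEdge] = []
    for lineno, cols in rows[1:]:
        if len(cols) not in (3, 4):
            raise TopologyError(f"{path}: line {lineno}: expected 3 or 4 columns")
        src, tgt, type_str = cols[:3]
        try:
            sign = _TYPE_TO_SIGN[int(type_str)]
        except (KeyError, ValueError):
            raise TopologyError(
                f"{path}: line {lineno}: unknown Type code {type_str!r}"
            ) from None
        mech = TRANSCRIPTIONAL
        if len(cols) == 4:
            try:
                mech = _CODE_TO_MECH[cols[3].upper()]
            except KeyError:
                raise TopologyError(
                    f"{path}: line {lineno}: unknown Mechanism code {cols[3]!r}"
                ) from None
        for n in (src, tgt):
            if n not in nodes:
                nodes.append(n)
        edges.append(RegulatoryEdge(src, tgt, sign, mech))
    if not edges:
        import warnings

        warnings.warn(f"{path}: topology has no edges", stacklevel=2)
    return NetworkTopology(nodes, edges, name=path.stem)


def write_topo(topology: NetworkTopology, path: str | Path) -> None:
    """Write a topology with the optional Mechanism column (lossless)."""
    path = Path(path)
    out = ["Source Target Type Mechanism"]
    for e in topology.edges:
        out.append(
            f"{e.source} {e.target} {_SIGN_TO_TYPE[e.sign]} {_MECH_TO_CODE[e.mechanism]}"
        )
    path.write_text("\n".join(out) + "\n")
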