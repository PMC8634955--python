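"""Joint product-status state space and admissible transition flows.

A person's tobacco behaviour is summarised by one status per modelled
product: ``NEVER`` (never used), ``CURRENT`` (currently using) or
``FORMER`` (used in the past).  With ``N`` products on the market the
joint state space therefore has ``3**N`` population stocks, and from
each stock every non-empty subset of products may simultaneously perform
its single admissible move (never→current *initiation*, current→former
*quitting*, former→current *relapse*), giving ``3**N * (2**N - 1)``
potential transition flows: 3 flows for one product, 27 for two and 189
for three.

By convention product index 0 is the combustible cigarette; the
quit-time clock tracked elsewhere in the package is attached to that
product's FORMER status.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ProductStatus",
    "JointState",
    "FlowSpec",
    "StateSpace",
    "admissible_move",
    "enumerate_states",
    "enumerate_flows",
]

#: canonical status order used for lexicographic state enumeration
_STATUS_ORDER = ("NEVER", "CURRENT", "FORMER")


class ProductStatus(IntEnum):
    """Use status of a single product: exactly three values."""

    NEVER = 0
    CURRENT = 1
    FORMER = 2

    @property
    def code(self) -> str:
        """One-letter code used in serialized state ids (N/C/F)."""
        return "NCF"[int(self)]

    @classmethod
    def from_code(cls, code: str) -> "ProductStatus":
        try:
            return {"N": cls.NEVER, "C": cls.CURRENT, "F": cls.FORMER}[code.upper()]
        except KeyError:
            raise ValueError(f"unknown product-status code {code!r}") from None


_ADMISSIBLE = {
    ProductStatus.NEVER: (ProductStatus.CURRENT, "initiate"),
    ProductStatus.CURRENT: (ProductStatus.FORMER, "quit"),
    ProductStatus.FORMER: (ProductStatus.CURRENT, "relapse"),
}


def admissible_move(status: ProductStatus) -> tuple[ProductStatus, str]:
    """Return the single admissible move from ``status``.

    Each status has exactly one outgoing move: NEVER→CURRENT
    (``initiate``), CURRENT→FORMER (``quit``), FORMER→CURRENT
    (``relapse``).
    """
    return _ADMISSIBLE[ProductStatus(status)]


@dataclass(frozen=True)
class JointState:
    """One population stock: a status per product.

    ``statuses`` and ``product_labels`` are aligned; ``id`` is the
    concatenated one-letter code (e.g. ``"CN"`` = current smoker, never
    used the second product).
    """

    statuses: tuple[ProductStatus, ...]
    product_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.statuses) != len(self.product_labels):
            raise ValueError("statuses and product_labels must have equal length")

    @property
    def id(self) -> str:
        return "".join(s.code for s in self.statuses)

    def status_of(self, label: str) -> ProductStatus:
        return self.statuses[self.product_labels.index(label)]

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.id


@dataclass(frozen=True)
class FlowSpec:
    """A directed flow between two stocks.

    ``changed_products`` is the non-empty subset of product indices that
    move; every changed product performs its single admissible move and
    every unchanged product keeps its status.  ``move_kinds`` is aligned
    with ``changed_products``.
    """

    from_state: JointState
    to_state: JointState
    changed_products: tuple[int, ...]
    move_kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.changed_products:
            raise ValueError("changed_products must be non-empty")
        for i, status in enumerate(self.from_state.statuses):
            if i in self.changed_products:
                expected, kind = admissible_move(status)
                if self.to_state.statuses[i] is not expected:
                    raise ValueError(f"product {i}: inadmissible move in flow")
            elif self.to_state.statuses[i] is not status:
                raise ValueError(f"product {i}: unchanged product altered status")

    @property
    def key(self) -> str:
        """Canonical flow id, e.g. ``"CN>CC"``."""
        return f"{self.from_state.id}>{self.to_state.id}"

    @property
    def moves_label(self) -> str:
        """Human-readable move list, e.g. ``"ecig:initiate"``."""
        labels = self.from_state.product_labels
        return ",".join(
            f"{labels[i]}:{kind}" for i, kind in zip(self.changed_products, self.move_kinds)
        )

    def involves(self, product: int) -> bool:
        return product in self.changed_products

    def move_of(self, product: int) -> str | None:
        try:
            return self.move_kinds[self.changed_products.index(product)]
        except ValueError:
            return None


def _default_labels(n_products: int) -> tuple[str, ...]:
    base = ("cigarette", "ecig", "thp")
    if n_products <= 3:
        return base[:n_products]
    return base + tuple(f"product{i}" for i in range(4, n_products + 1))


def enumerate_states(
    n_products: int | None = None, labels: Sequence[str] | None = None
) -> list[JointState]:
    """Enumerate all ``3**N`` joint states in canonical order.

    The order is lexicographic over statuses (NEVER < CURRENT < FORMER)
    with product 0 most significant, so the all-NEVER state is first and
    serialized outputs are stable across runs.
    """
    if labels is not None:
        labels = tuple(labels)
        if n_products is not None and n_products != len(labels):
            raise ValueError("n_products inconsistent with labels")
        n_products = len(labels)
    if n_products is None or n_products < 1:
        raise ValueError("n_products must be a positive integer")
    if labels is None:
        labels = _default_labels(n_products)
    return [
        JointState(statuses=combo, product_labels=labels)
        for combo in itertools.product(tuple(ProductStatus), repeat=n_products)
    ]


def enumerate_flows(states: Sequence[JointState]) -> list[FlowSpec]:
    """Enumerate every admissible flow from a complete state enumeration.

    From each stock there is one flow per non-empty subset of products,
    each changed product applying its single admissible move:
    ``3**N * (2**N - 1)`` flows in total (3, 27 and 189 for N = 1, 2, 3).
    Subsets are visited in a deterministic order (by size, then by
    product indices).
    """
    if not states:
        raise ValueError("states must be a non-empty complete enumeration")
    n = len(states[0].statuses)
    seen = {s.statuses for s in states}
    if len(states) != 3**n or len(seen) != 3**n:
        raise ValueError(f"states is not a complete 3^{n} enumeration")

    labels = states[0].product_labels
    subsets: list[tuple[int, ...]] = []
    for size in range(1, n + 1):
        subsets.extend(itertools.combinations(range(n), size))

    flows: list[FlowSpec] = []
    for state in states:
        for subset in subsets:
            new_statuses = list(state.statuses)
            kinds = []
            for i in subset:
                new_status, kind = admissible_move(state.statuses[i])
                new_statuses[i] = new_status
                kinds.append(kind)
            flows.append(
                FlowSpec(
                    from_state=state,
                    to_state=JointState(tuple(new_statuses), labels),
                    changed_products=subset,
                    move_kinds=tuple(kinds),
                )
            )
    return flows


class StateSpace:
    """The enumerated state space for a product line-up, with index maps.

    Product 0 is treated as the combustible cigarette: its FORMER status
    carries the quit-time clock used for risk decay and relapse.
    """

    def __init__(self, labels: Sequence[str] = ("cigarette",)):
        self.labels: tuple[str, ...] = tuple(labels)
        if len(self.labels) < 1:
            raise ValueError("at least one product required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("product labels must be unique")
        self.n_products = len(self.labels)
        self.states = enumerate_states(labels=self.labels)
        self.flows = enumerate_flows(self.states)
        self.state_index: dict[str, int] = {s.id: i for i, s in enumerate(self.states)}
        self.flow_index: dict[str, int] = {f.key: i for i, f in enumerate(self.flows)}
        #: flow indices grouped by source state index
        self.flows_from: list[list[int]] = [[] for _ in self.states]
        for fi, f in enumerate(self.flows):
            self.flows_from[self.state_index[f.from_state.id]].append(fi)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_flows(self) -> int:
        return len(self.flows)

    def state(self, state_id: str) -> JointState:
        return self.states[self.state_index[state_id]]

    def flow(self, key: str) -> FlowSpec:
        return self.flows[self.flow_index[key]]

    def cigarette_status(self, state_index: int) -> ProductStatus:
        return self.states[state_index].statuses[0]

    def states_frame(self) -> pd.DataFrame:
        """States as a table (one row per stock) for audit export."""
        rows = [
            {"state_id": s.id, "index": i}
            | {label: s.statuses[j].name for j, label in enumerate(self.labels)}
            for i, s in enumerate(self.states)
        ]
        return pd.DataFrame(rows)

    def flows_frame(self) -> pd.DataFrame:
        """Flows as an edge list (one row per flow) for audit export."""
        rows = [
            {
                "flow_key": f.key,
                "from_state": f.from_state.id,
                "to_state": f.to_state.id,
                "moves": f.moves_label,
                "n_products_moving": len(f.changed_products),
            }
            for f in self.flows
        ]
        return pd.DataFrame(rows)
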