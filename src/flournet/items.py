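"""The Secure Flourish Measure item schema.

Twelve self-report items on a 0-10 response scale, two per flourishing
domain. The fixed item order defined here is the canonical node order for
every matrix and edge vector in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

CODES: tuple[str, ...] = ("H", "LS", "MH", "PH", "SP", "W", "PG", "GU", "C", "SR", "E", "WS")

LABELS: dict[str, str] = {
    "H": "Happiness",
    "LS": "Life satisfaction",
    "MH": "Mental health",
    "PH": "Physical health",
    "SP": "Sense of purpose",
    "W": "Life worthwhile",
    "PG": "Promote good",
    "GU": "Give up happiness",
    "C": "Content with relationships",
    "SR": "Satisfying relationships",
    "E": "Worry about expenses",
    "WS": "Worry about safety",
}

DOMAINS: dict[str, tuple[str, str]] = {
    "happiness & life satisfaction": ("H", "LS"),
    "mental & physical health": ("MH", "PH"),
    "meaning & purpose": ("SP", "W"),
    "character & virtue": ("PG", "GU"),
    "close social relationships": ("C", "SR"),
    "financial & material stability": ("E", "WS"),
}


@dataclass(frozen=True)
class ItemSchema:
    """Ordered item codes, display labels, domain assignment and response range."""

    codes: tuple[str, ...] = CODES
    labels: dict[str, str] = field(default_factory=lambda: dict(LABELS))
    domains: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DOMAINS))
    response_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if len(self.codes) != 12 or len(set(self.codes)) != 12:
            raise ValueError("schema requires exactly 12 distinct item codes")
        assigned = [c for pair in self.domains.values() for c in pair]
        if sorted(assigned) != sorted(self.codes):
            raise ValueError("each item must belong to exactly one domain")
        for name, pair in self.domains.items():
            if len(pair) != 2:
                raise ValueError(f"domain {name!r} must have exactly 2 items")

    @property
    def n_items(self) -> int:
        return len(self.codes)

    @property
    def n_pairs(self) -> int:
        p = len(self.codes)
        return p * (p - 1) // 2

    def domain_of(self, code: str) -> str:
        for name, pair in self.domains.items():
            if code in pair:
                return name
        raise KeyError(code)

    def index(self, code: str) -> int:
        return self.codes.index(code)


#: Module-level default schema; every matrix in the package uses its item order.
DEFAULT_SCHEMA = ItemSchema()
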