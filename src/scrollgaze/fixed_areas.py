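"""Fixed screen areas (sticky menus, sidebars, ads) and their redirection.

A *fixed area* is a rectangle on the screen whose content does not move
when the page scrolls; gaze samples inside it must not receive the scroll
offset but instead be redirected to the region of the full-page image
where that content is depicted. Areas are grouped into *bundles*, one per
page configuration (e.g. expanded vs. shrunk top menu), and each bundle is
paired with a *rule* — a deterministic predicate on the current scroll
state that decides whether the bundle applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .errors import ConfigurationError, ContractError, ValidationError


@dataclass(frozen=True)
class Rect:
    """Inclusive pixel rectangle: both corners are part of the rectangle."""

    left: int
    top: int
    right: int
    bottom: int

    def __post_init__(self):
        if self.right < self.left or self.bottom < self.top:
            raise ValidationError(
                f"degenerate rectangle: ({self.left},{self.top})-({self.right},{self.bottom})"
            )

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    @property
    def height(self) -> int:
        return self.bottom - self.top + 1

    def contains(self, x: float, y: float) -> bool:
        return self.left <= x <= self.right and self.top <= y <= self.bottom


@dataclass(frozen=True)
class FixedArea:
    """A screen rectangle redirected to a full-page-image rectangle."""

    screen_rect: Rect
    image_rect: Rect


@dataclass(frozen=True)
class Bundle:
    """An ordered, non-empty set of fixed areas for one page configuration."""

    areas: tuple[FixedArea, ...]

    def __post_init__(self):
        if not self.areas:
            raise ValidationError("a bundle must contain at least one fixed area")


class Rule:
    """Deterministic predicate on the scroll state gating a bundle.

    Evaluated against the same effective (lag-adjusted, clamped) scrolled
    value that the correction engine uses for y-offsetting, so bundle
    switching and coordinate correction stay mutually consistent.
    """

    def __init__(self, kind: str, predicate: Callable, value: float | None = None):
        self.kind = kind
        self.value = value
        self._predicate = predicate

    def __call__(self, state) -> bool:
        return bool(self._predicate(state))

    def __repr__(self):
        if self.value is None:
            return f"Rule({self.kind})"
        return f"Rule({self.kind}, {self.value})"


def always_active() -> Rule:
    """Rule that is true in every state."""
    return Rule("always_active", lambda state: True)


def scrolled_less_than(value: float) -> Rule:
    """True while fewer than ``value`` pixels have been scrolled down."""
    return Rule("scrolled_less_than", lambda state: state.scrolled < value, value)


def scrolled_at_least(value: float) -> Rule:
    """True once ``value`` or more pixels have been scrolled down."""
    return Rule("scrolled_at_least", lambda state: state.scrolled >= value, value)


_RULE_BUILDERS = {
    "always_active": lambda value: always_active(),
    "scrolled_less_than": scrolled_less_than,
    "scrolled_at_least": scrolled_at_least,
}


def active_areas(
    bundles: Sequence[Bundle], rules: Sequence[Rule], state
) -> list[FixedArea]:
    """Fixed areas of every bundle whose rule holds in ``state``.

    Bundles and rules are positionally paired; the result preserves
    bundle order, then area order within each bundle.
    """
    if len(bundles) != len(rules):
        raise ConfigurationError(
            f"bundles and rules must pair positionally: {len(bundles)} bundles "
            f"vs {len(rules)} rules"
        )
    out: list[FixedArea] = []
    for bundle, rule in zip(bundles, rules):
        if rule(state):
            out.extend(bundle.areas)
    return out


def capture(areas: Sequence[FixedArea], x: float, y: float) -> FixedArea | None:
    """First area (in order) whose screen rectangle contains the point.

    Containment is inclusive on all four edges; overlaps are resolved by
    declaration order (first match wins).
    """
    for area in areas:
        if area.screen_rect.contains(x, y):
            return area
    return None


def redirect(area: FixedArea, x: float, y: float) -> tuple[float, float]:
    """Map a captured screen point into the area's full-page rectangle.

    Affine per axis: the offset from the screen rect's top-left corner is
    scaled by ``(image_extent - 1) / (screen_extent - 1)`` and added to the
    image rect's top-left corner. Equal-size rectangles reduce to a pure
    translation; a screen extent of one pixel maps onto the image rect's
    top-left edge.
    """
    s, m = area.screen_rect, area.image_rect
    if not s.contains(x, y):
        raise ContractError(
            f"redirect called with point ({x}, {y}) outside screen rect "
            f"({s.left},{s.top})-({s.right},{s.bottom})"
        )
    sx = (m.width - 1) / (s.width - 1) if s.width > 1 else 0.0
    sy = (m.height - 1) / (s.height - 1) if s.height > 1 else 0.0
    return (m.left + (x - s.left) * sx, m.top + (y - s.top) * sy)


def _rect_from_list(values, label: str) -> Rect:
    if len(values) != 4:
        raise ConfigurationError(f"{label}: expected [left, top, right, bottom], got {values}")
    return Rect(*(int(v) for v in values))


def parse_area_config(doc: dict) -> tuple[list[Bundle], list[Rule]]:
    """Build ``(bundles, rules)`` from a declarative mapping.

    Expected shape::

        {"bundles": [
            {"rule": {"kind": "scrolled_less_than", "value": 1000},
             "areas": [{"screen": [l, t, r, b], "image": [l, t, r, b]}, ...]},
            ...
        ]}

    Rule kinds are limited to ``always_active``, ``scrolled_less_than`` and
    ``scrolled_at_least``; arbitrary predicates remain available
    programmatically via :class:`Rule`.
    """
    bundles: list[Bundle] = []
    rules: list[Rule] = []
    for i, entry in enumerate(doc.get("bundles", [])):
        rule_doc = entry.get("rule", {"kind": "always_active"})
        kind = rule_doc.get("kind")
        if kind not in _RULE_BUILDERS:
            raise ConfigurationError(
                f"bundle {i}: unknown rule kind {kind!r}; "
                f"supported: {sorted(_RULE_BUILDERS)}"
            )
        if kind != "always_active" and "value" not in rule_doc:
            raise ConfigurationError(f"bundle {i}: rule {kind!r} requires a 'value'")
        areas = tuple(
            FixedArea(
                screen_rect=_rect_from_list(a["screen"], f"bundle {i} screen rect"),
                image_rect=_rect_from_list(a["image"], f"bundle {i} image rect"),
            )
            for a in entry.get("areas", [])
        )
        bundles.append(Bundle(areas))
        rules.append(_RULE_BUILDERS[kind](rule_doc.get("value")))
    return bundles, rules


def load_area_config(path) -> tuple[list[Bundle], list[Rule]]:
    """Load a JSON fixed-area configuration file; see :func:`parse_area_config`."""
    doc = json.loads(Path(path).read_text())
    return parse_area_config(doc)


def dump_area_config(bundles: Sequence[Bundle], rules: Sequence[Rule]) -> dict:
    """Inverse of :func:`parse_area_config` for the built-in rule kinds."""
    out = []
    for bundle, rule in zip(bundles, rules):
        entry = {
            "rule": {"kind": rule.kind}
            | ({} if rule.value is None else {"value": rule.value}),
            "areas": [
                {
                    "screen": [a.screen_rect.left, a.screen_rect.top,
                               a.screen_rect.right, a.screen_rect.bottom],
                    "image": [a.image_rect.left, a.image_rect.top,
                              a.image_rect.right, a.image_rect.bottom],
                }
                for a in bundle.areas
            ],
        }
        out.append(entry)
    return {"bundles": out}
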