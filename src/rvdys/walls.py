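"""RV imaging views, wall regions, and the one/two/three-view wall groupings.

The right ventricle is assessed in three CMR views: the RV three-chamber
(RV3ch) and four-chamber (4ch) long-axis views, and a midventricular
short-axis (SAX) slice.  For dyssynchrony the RV is partitioned into six
wall regions, two per view: anterior and inferior walls in RV3ch, lateral
and septal walls in 4ch, and the antero-lateral-inferior (free) wall and
septal wall in SAX.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class View(str, Enum):
    """A CMR imaging view used for RV strain."""

    RV3CH = "RV3ch"
    CH4 = "4ch"
    SAX = "SAX"

    @classmethod
    def parse(cls, text: str) -> "View":
        for v in cls:
            if text.strip().lower() == v.value.lower():
                return v
        raise ValueError(f"unknown view {text!r}; expected one of "
                         f"{[v.value for v in cls]}")


class WallRegion(str, Enum):
    """One of the six RV wall regions, each belonging to exactly one view."""

    RV3CH_ANTERIOR = "RV3CH_ANTERIOR"
    RV3CH_INFERIOR = "RV3CH_INFERIOR"
    CH4_LATERAL = "CH4_LATERAL"
    CH4_SEPTAL = "CH4_SEPTAL"
    SAX_FREE = "SAX_FREE"          # antero-lateral-inferior free wall
    SAX_SEPTAL = "SAX_SEPTAL"

    @property
    def view(self) -> View:
        return _WALL_VIEW[self]

    @property
    def csv_name(self) -> str:
        """Short wall name used in the long-format strain/contour CSVs."""
        return _WALL_CSV[self]

    @classmethod
    def from_csv(cls, view: View | str, wall_name: str) -> "WallRegion":
        if not isinstance(view, View):
            view = View.parse(view)
        key = (view, wall_name.strip().lower())
        try:
            return _CSV_WALL[key]
        except KeyError:
            raise ValueError(
                f"unknown wall {wall_name!r} for view {view.value}") from None


_WALL_VIEW = {
    WallRegion.RV3CH_ANTERIOR: View.RV3CH,
    WallRegion.RV3CH_INFERIOR: View.RV3CH,
    WallRegion.CH4_LATERAL: View.CH4,
    WallRegion.CH4_SEPTAL: View.CH4,
    WallRegion.SAX_FREE: View.SAX,
    WallRegion.SAX_SEPTAL: View.SAX,
}

_WALL_CSV = {
    WallRegion.RV3CH_ANTERIOR: "anterior",
    WallRegion.RV3CH_INFERIOR: "inferior",
    WallRegion.CH4_LATERAL: "lateral",
    WallRegion.CH4_SEPTAL: "septal",
    WallRegion.SAX_FREE: "free",
    WallRegion.SAX_SEPTAL: "septal",
}

_CSV_WALL = {(w.view, n): w for w, n in _WALL_CSV.items()}

#: Free-wall series representing each view in PSC assessment.  For RV3ch both
#: walls are free walls; their point-wise mean curve is used.
PSC_REPRESENTATIVE: dict[View, tuple[WallRegion, ...]] = {
    View.RV3CH: (WallRegion.RV3CH_ANTERIOR, WallRegion.RV3CH_INFERIOR),
    View.CH4: (WallRegion.CH4_LATERAL,),
    View.SAX: (WallRegion.SAX_FREE,),
}


class ViewSetLabel(str, Enum):
    THREE_VIEW = "three_view"
    TWO_VIEW = "two_view"
    ONE_VIEW_4CH = "one_view_4ch"
    ONE_VIEW_RV3CH = "one_view_rv3ch"


VIEW_SET_WALLS: dict[ViewSetLabel, frozenset[WallRegion]] = {
    ViewSetLabel.THREE_VIEW: frozenset(WallRegion),
    ViewSetLabel.TWO_VIEW: frozenset({
        WallRegion.CH4_LATERAL, WallRegion.CH4_SEPTAL,
        WallRegion.SAX_FREE, WallRegion.SAX_SEPTAL}),
    ViewSetLabel.ONE_VIEW_4CH: frozenset({
        WallRegion.CH4_LATERAL, WallRegion.CH4_SEPTAL}),
    ViewSetLabel.ONE_VIEW_RV3CH: frozenset({
        WallRegion.RV3CH_ANTERIOR, WallRegion.RV3CH_INFERIOR}),
}


@dataclass(frozen=True)
class ViewSet:
    """A named wall grouping over which the dyssynchrony index is computed.

    ``fallback`` records that a reduced set was selected because the full
    three-view set was unavailable (typically a missing RV3ch view).
    """

    label: ViewSetLabel
    walls: frozenset[WallRegion] = field(default=None)  # type: ignore[assignment]
    fallback: bool = False

    def __post_init__(self):
        expected = VIEW_SET_WALLS[self.label]
        if self.walls is None:
            object.__setattr__(self, "walls", expected)
        elif frozenset(self.walls) != expected:
            raise ValueError(f"walls {self.walls} do not match {self.label}")

    @property
    def n_walls(self) -> int:
        return len(self.walls)


def select_view_set(available_views) -> ViewSet:
    """Pick the widest defined wall grouping supported by the available views.

    All three views give the six-wall set; with RV3ch missing the four walls
    of 4ch + SAX are used; with only 4ch (or 4ch + RV3ch) the two 4ch walls;
    an isolated RV3ch view gives its two free walls.  SAX alone supports no
    defined grouping.
    """
    views = {v if isinstance(v, View) else View.parse(v) for v in available_views}
    if views >= {View.RV3CH, View.CH4, View.SAX}:
        return ViewSet(ViewSetLabel.THREE_VIEW)
    if views >= {View.CH4, View.SAX}:
        return ViewSet(ViewSetLabel.TWO_VIEW, fallback=True)
    if View.CH4 in views:
        return ViewSet(ViewSetLabel.ONE_VIEW_4CH, fallback=True)
    if View.RV3CH in views:
        return ViewSet(ViewSetLabel.ONE_VIEW_RV3CH, fallback=True)
    raise ValueError(f"no usable view in {sorted(v.value for v in views)}")
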