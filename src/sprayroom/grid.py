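"""Compartment topology for the 2x2x2 room subdivision.

The room is split into eight equal-volume, individually well-mixed
compartments labelled by their (x, y, z) coordinates with each coordinate in
{1, 2}, rendered as "111" ... "222".  Bulk ventilation flows along the y axis:
each of the four (x, z) columns carries one quarter of the total flow Q from
outdoors through its y=1 compartment into its y=2 compartment and out.
Neighbouring compartments (face adjacency, i.e. labels differing in exactly
one coordinate) additionally exchange air symmetrically at the rate Q_ex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

#: Token for the chemical-free infiltrating air feeding the y=1 compartments.
OUTDOOR = "OUTDOOR"

#: Pseudo-compartment used by the well-mixed (single-zone) model.
WHOLE_ROOM = "WHOLE_ROOM"


@dataclass(frozen=True)
class CompartmentGrid:
    """The 2x2x2 compartment labelling with its flow topology.

    Attributes
    ----------
    labels : tuple of str
        The eight compartment labels in fixed lexicographic order
        ("111", "112", "121", "122", "211", "212", "221", "222"); all
        serialized column orders derive from this.
    neighbors : dict
        Map from label to the frozenset of the three face-adjacent labels
        (labels differing in exactly one coordinate).
    upstream : dict
        Map from label to the label feeding it through the directional flow:
        the y=1 compartment for a y=2 label, or :data:`OUTDOOR` for a y=1
        label.
    outlet : frozenset of str
        The y=2 labels, whose outflow leaves the room.
    """

    labels: tuple[str, ...]
    neighbors: dict[str, frozenset[str]] = field(repr=False)
    upstream: dict[str, str] = field(repr=False)
    outlet: frozenset[str]

    def index(self, label: str) -> int:
        """Position of *label* in the canonical ordering."""
        return self.labels.index(label)


def _coords(label: str) -> tuple[int, int, int]:
    x, y, z = (int(c) for c in label)
    return x, y, z


def build_grid() -> CompartmentGrid:
    """Build the canonical eight-compartment grid.

    Returns
    -------
    CompartmentGrid
        Labels ordered lexicographically; neighbours are the three labels at
        unit Hamming distance in coordinates; the upstream of a y=2 label is
        the same (x, z) column at y=1, and y=1 labels draw outdoor air.
    """
    labels = tuple(f"{x}{y}{z}" for x, y, z in product((1, 2), repeat=3))
    neighbors: dict[str, frozenset[str]] = {}
    upstream: dict[str, str] = {}
    for lab in labels:
        neighbors[lab] = frozenset(
            other
            for other in labels
            if sum(a != b for a, b in zip(lab, other)) == 1
        )
        x, y, z = _coords(lab)
        upstream[lab] = f"{x}{y - 1}{z}" if y == 2 else OUTDOOR
    outlet = frozenset(lab for lab in labels if _coords(lab)[1] == 2)
    return CompartmentGrid(labels=labels, neighbors=neighbors,
                           upstream=upstream, outlet=outlet)
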