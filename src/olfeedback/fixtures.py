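"""Deterministic miniature networks for tests and examples.

The fixture layout is small enough that every pair's connection probability
can be re-derived by brute-force numerical integration in a test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seeds import substream
from .geometry import (
    CellPlacement,
    ConnectivityGraph,
    LayoutSpec,
    build_network,
    place_cells,
)

__all__ = ["FixtureNetwork", "make_fixture", "FIXTURE_LAYOUT", "EMPTY_OVERLAP_LAYOUT"]

#: compact bulb: 3 glomerular columns, 12 mitral discs, 40 granule cones
FIXTURE_LAYOUT = LayoutSpec(
    n_mc=12,
    n_gc=40,
    n_glomeruli=3,
    box_xy=900.0,
    box_z=400.0,
    mc_disc_radius=300.0,
    mc_total_dendrite_length=12_000.0,
    gc_total_spines=150.0,
)

#: granule vertices above every mitral disc plane: no cone cross-sections,
#: hence no overlaps and an empty edge list
EMPTY_OVERLAP_LAYOUT = LayoutSpec(
    n_mc=6,
    n_gc=10,
    n_glomeruli=2,
    box_xy=900.0,
    box_z=400.0,
    mc_disc_radius=300.0,
    mc_type1_z=100.0,
    mc_type2_z=120.0,
    gc_z_range=(300.0, 380.0),
)


@dataclass
class FixtureNetwork:
    layout: LayoutSpec
    placement: CellPlacement
    graph: ConnectivityGraph
    seed: int


def make_fixture(seed: int, layout: LayoutSpec | None = None) -> FixtureNetwork:
    """Deterministic miniature placement + graph for the given seed."""
    layout = layout or FIXTURE_LAYOUT
    placement = place_cells(layout, substream(seed, "fixture.place"))
    graph = build_network(placement, layout, substream(seed, "fixture.build"))
    return FixtureNetwork(layout=layout, placement=placement, graph=graph, seed=seed)
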