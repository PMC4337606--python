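"""Descriptive comparison metrics: widths, shifts, overlaps, convergence.

All quantities are in percent egg length (%EL); positions and widths share
that unit scale. Shifts are signed with positive = anterior movement
(decreasing % A-P position), the prevailing direction of gap-domain
dynamics in the blastoderm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import SpatioTemporalAtlas
from .timeclasses import sort_classes

__all__ = [
    "DomainExtent",
    "ShiftRecord",
    "ConvergenceRecord",
    "domain_width",
    "boundary_shift",
    "domain_overlap",
    "convergence_time",
]


@dataclass(frozen=True)
class DomainExtent:
    """A domain's two edge positions at one time class (a pole edge is 0
    or 100)."""

    gene: str
    domain_id: str
    time_class: str
    a_pos: float
    p_pos: float

    def __post_init__(self):
        if self.a_pos is None or self.p_pos is None:
            raise ValueError("both edges must be resolved (pole = 0/100)")
        if np.isnan(self.a_pos) or np.isnan(self.p_pos):
            raise ValueError("unresolved (NaN) edge position")
        if self.p_pos < self.a_pos:
            raise ValueError("posterior edge must not precede anterior edge")

    @property
    def width(self) -> float:
        return self.p_pos - self.a_pos


@dataclass(frozen=True)
class ShiftRecord:
    gene: str
    domain_id: str
    edge: str
    from_class: str
    to_class: str
    shift: float  # %EL, positive = anterior movement


@dataclass(frozen=True)
class ConvergenceRecord:
    gene: str
    domain_id: str
    edge: str
    convergence_class: str | None
    first_contact_class: str | None
    tolerance: str | float


def domain_width(extent: DomainExtent) -> float:
    """Width of a domain in %EL (posterior minus anterior edge)."""
    return extent.width


def boundary_shift(atlas: SpatioTemporalAtlas, gene: str, domain_id: str,
                   edge: str, from_class: str, to_class: str) -> ShiftRecord:
    """Signed boundary displacement between two atlas cells; positive
    means the boundary moved anteriorly. Antisymmetric under swapping the
    classes and additive along a class chain."""
    try:
        p_from = atlas.median(gene, domain_id, edge, from_class)
        p_to = atlas.median(gene, domain_id, edge, to_class)
    except KeyError as err:
        raise KeyError(f"missing atlas cell: {err}") from None
    if np.isnan(p_from) or np.isnan(p_to):
        raise ValueError(
            f"atlas cell for ({gene}, {domain_id}, {edge}) is marked absent")
    return ShiftRecord(gene=gene, domain_id=domain_id, edge=edge,
                       from_class=from_class, to_class=to_class,
                       shift=p_from - p_to)


def domain_overlap(extent_a: DomainExtent, extent_b: DomainExtent) -> float:
    """Length (%EL) of the intersection of two domain intervals at the
    same time class; 0 when disjoint."""
    if extent_a.time_class != extent_b.time_class:
        raise ValueError("overlap requires extents at the same time class")
    lo = max(extent_a.a_pos, extent_b.a_pos)
    hi = min(extent_a.p_pos, extent_b.p_pos)
    return max(0.0, hi - lo)


def convergence_time(atlas_a: SpatioTemporalAtlas,
                     atlas_b: SpatioTemporalAtlas,
                     gene: str, domain_id: str, edge: str,
                     tolerance: float | str = "auto") -> ConvergenceRecord:
    """Earliest shared time class from which the two atlases' medians stay
    within tolerance at every later shared class (persistent convergence).
    ``tolerance='auto'`` uses, per class, the larger of the two cells'
    variabilities. The first transient contact is reported alongside, since
    boundaries can meet and diverge again before settling.
    """
    def cells(a):
        t = a.cells
        sub = t[(t["gene"] == gene) & (t["domain_id"] == domain_id)
                & (t["edge"] == edge) & t["median"].notna()]
        return {r["time_class"]: r for _, r in sub.iterrows()}

    ca, cb = cells(atlas_a), cells(atlas_b)
    shared = sort_classes(set(ca) & set(cb))
    if not shared:
        raise ValueError(
            f"no shared time classes for ({gene}, {domain_id}, {edge})")

    def within(tc) -> bool:
        delta = abs(ca[tc]["median"] - cb[tc]["median"])
        if tolerance == "auto":
            tol = max(ca[tc]["variability"], cb[tc]["variability"])
        else:
            tol = float(tolerance)
        return bool(delta <= tol)

    ok = [within(tc) for tc in shared]
    first_contact = next((tc for tc, o in zip(shared, ok) if o), None)
    convergence = None
    for i in range(len(shared)):
        if all(ok[i:]):
            convergence = shared[i]
            break
    return ConvergenceRecord(gene=gene, domain_id=domain_id, edge=edge,
                             convergence_class=convergence,
                             first_contact_class=first_contact,
                             tolerance=tolerance)
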