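"""Mass-preserving, capacity-constrained redistribution on a grid.

Two deterministic strategies share one core:

* :func:`redistribute_equal_spare` — excess above each cell's capacity is
  pooled and split equally among all cells with spare capacity (clipped at
  their spare, re-split until exhausted).  Used to keep harmonized
  agricultural areas within physical cell areas.
* :func:`redistribute_rings` — each hot cell's excess flows outwards through
  expanding 8-neighbour (Chebyshev) rings restricted to eligible cells,
  equal-split within a ring.  Used for the manure application cap.

Both conserve total mass exactly and optionally carry *companion*
components (e.g. cropland vs pasture shares of the moved mass): mass is
removed from donors pro-rata across components and added to receivers at
the pooled composition, so every component's total is conserved too.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, ring_neighbours

_TOL = 1e-12


class CapacityError(ValueError):
    """Total demanded mass exceeds total capacity of the eligible cells."""


def _drain_excess(values: np.ndarray, capacity: np.ndarray,
                  companions: list[np.ndarray]) -> tuple[float, np.ndarray]:
    """Clip cells to capacity; return (pooled excess, pooled composition)."""
    excess = np.maximum(values - capacity, 0.0)
    pool = float(excess.sum())
    comp = np.zeros(len(companions))
    if pool > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(values > 0, excess / np.where(values > 0, values, 1.0), 0.0)
        for k, c in enumerate(companions):
            removed = c * frac
            comp[k] = removed.sum()
            c -= removed
        values -= excess
    return pool, comp


def _fill_equal(pool: float, comp: np.ndarray, idx: np.ndarray, values: np.ndarray,
                capacity: np.ndarray, companions: list[np.ndarray]
                ) -> tuple[float, np.ndarray]:
    """Equal-split ``pool`` into cells ``idx`` (clipped at spare).

    Returns the leftover pool and its (proportionally shrunk) composition.
    """
    if pool <= _TOL:
        return 0.0, comp * 0.0
    comp_frac = comp / pool
    while pool > _TOL:
        spare = capacity[idx] - values[idx]
        recv = idx[spare > _TOL]
        if len(recv) == 0:
            break
        share = pool / len(recv)
        add = np.minimum(capacity[recv] - values[recv], share)
        values[recv] += add
        placed = float(add.sum())
        for k, c in enumerate(companions):
            c[recv] += add * comp_frac[k]
        pool -= placed
    pool = max(pool, 0.0)
    return pool, comp_frac * pool


def redistribute_equal_spare(
    values: np.ndarray,
    capacity: np.ndarray,
    companions: tuple[np.ndarray, ...] = (),
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Cap ``values`` at ``capacity``; spread pooled excess equally over spare cells.

    Raises :class:`CapacityError` if the total does not fit.
    """
    values = np.asarray(values, float).copy()
    capacity = np.asarray(capacity, float)
    comps = [np.asarray(c, float).copy() for c in companions]
    total = values.sum()
    if total > capacity.sum() * (1 + 1e-9) + _TOL:
        raise CapacityError(f"total {total:.6g} exceeds capacity {capacity.sum():.6g}")
    pool, comp = _drain_excess(values, capacity, comps)
    if pool > _TOL:
        leftover, _ = _fill_equal(pool, comp, np.arange(len(values)), values, capacity, comps)
        if leftover > 1e-6 * max(total, 1.0):
            raise CapacityError(f"could not place {leftover:.6g} of excess mass")
    return values, tuple(comps)


def redistribute_rings(
    values: np.ndarray,
    capacity: np.ndarray,
    grid: GridSpec,
    member: np.ndarray,
    receiver: np.ndarray | None = None,
    companions: tuple[np.ndarray, ...] = (),
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Push each hot cell's excess into expanding neighbour rings.

    ``member`` marks the cells of the domain under consideration (one
    country); any member cell above its capacity donates.  ``receiver``
    marks cells allowed to take mass (default: members with positive
    capacity, i.e. agricultural cells).  Hot cells are processed in fixed
    row-major order; within a ring, receivers share equally (clipped at
    spare).  Excess no ring can absorb raises :class:`CapacityError`.
    """
    values = np.asarray(values, float).copy()
    capacity = np.asarray(capacity, float)
    member = np.asarray(member, bool)
    if receiver is None:
        receiver = member & (capacity > 0)
    receiver = np.asarray(receiver, bool)
    comps = [np.asarray(c, float).copy() for c in companions]
    hot = np.flatnonzero((values > capacity + _TOL) & member)
    if len(hot) == 0:
        return values, tuple(comps)
    total_m = float(values[member].sum())
    cap_m = float(capacity[member].sum())
    if total_m > cap_m * (1 + 1e-9) + _TOL:
        raise CapacityError(f"total {total_m:.6g} exceeds capped capacity {cap_m:.6g}")
    max_radius = max(grid.n_lat, grid.n_lon)
    for cell in hot:
        pool = float(values[cell] - capacity[cell])
        if pool <= _TOL:
            continue  # a previous donor may have topped this cell differently
        comp = np.zeros(len(comps))
        frac = pool / values[cell]
        for k, c in enumerate(comps):
            comp[k] = c[cell] * frac
            c[cell] -= comp[k]
        values[cell] = capacity[cell]
        for radius in range(1, max_radius + 1):
            ring = ring_neighbours(grid, int(cell), radius)
            ring = ring[receiver[ring]]
            if len(ring) == 0:
                continue
            pool, comp = _fill_equal(pool, comp, ring, values, capacity, comps)
            if pool <= _TOL:
                break
        if pool > _TOL:
            raise CapacityError(f"cell {int(cell)}: {pool:.6g} excess could not be placed")
    return values, tuple(comps)
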