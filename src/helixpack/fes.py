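"""Free-energy-landscape analysis over the rotation angles (α, β).

Provides basin/state detection by steepest-descent watershed, the
block-minimum minimum-free-energy-path extraction (candidate points are
the lowest cells of 20° × 20° tiles by default), a cell-resolution
minimax-path search used as an independent oracle, and barrier/ΔG
bookkeeping between detected states.

Path optimality is the minimax (bottleneck) criterion: among block-adjacent
chains the path minimizes the highest energy en route, with total energy
and then lexicographic block order as deterministic tie-breaks.  All path
energies are grid values read at cells — no interpolation.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ContractError, FESGrid

__all__ = [
    "StateAssignment",
    "PathResult",
    "DEFAULT_BLOCK_DEGREES",
    "detect_states",
    "extract_block_minimum_path",
    "dijkstra_path_oracle",
    "barrier_analysis",
]

DEFAULT_BLOCK_DEGREES = 20.0

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
         "XI", "XII", "XIII", "XIV", "XV"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StateAssignment:
    label: str
    center: tuple              # (α°, β°)
    center_cell: tuple         # (i, j)
    free_energy: float         # kcal/mol at the center cell
    basin_cells: set
    depth: float               # lowest escape saddle minus center energy


@dataclass
class PathResult:
    points: list               # [(α, β, energy), ...] at path cells
    cells: list                # [(i, j), ...]
    segment_max: list          # max grid energy along each inter-point segment
    bottleneck: float          # highest energy anywhere along the path
    method: str
    block_size: float | None = None
    barriers: list = field(default_factory=list)
    endpoint_dg: float | None = None


# ---------------------------------------------------------------------------
# state detection
# ---------------------------------------------------------------------------

def _neighbors(i, j, shape, periodic=False):
    ni, nj = shape
    for di, dj in _NEIGHBORS:
        a, b = i + di, j + dj
        if periodic:
            yield a % ni, b % nj
        elif 0 <= a < ni and 0 <= b < nj:
            yield a, b


def detect_states(grid: FESGrid, min_depth: float = 0.5,
                  energy_ceiling: float | None = None,
                  periodic: bool = False) -> list:
    """Local minima and their steepest-descent basins.

    Minima on the 8-connected grid are found below ``energy_ceiling`` above
    the global minimum (default: no ceiling); every cell is assigned to the
    basin its steepest-descent path terminates in; basins whose escape
    depth (lowest boundary crossing minus center energy) is below
    ``min_depth`` kcal/mol are merged into the neighbor across that lowest
    boundary.  A constant grid yields a single degenerate state with a
    warning.  States are labelled I, II, … in ascending (α + β) of their
    centers, following the transition-coordinate ordering.
    """
    e = grid.energy
    shape = e.shape
    if np.ptp(e) < 1e-12:
        warnings.warn("constant free-energy grid: single degenerate state")
        cells = {(i, j) for i in range(shape[0]) for j in range(shape[1])}
        ci, cj = shape[0] // 2, shape[1] // 2
        return [StateAssignment("I", grid.cell_center((ci, cj)), (ci, cj),
                                float(e[ci, cj]), cells, 0.0)]

    # steepest-descent target per cell
    flat_target = np.full(shape, -1, dtype=object)
    order = np.dstack(np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                  indexing="ij")).reshape(-1, 2)

    def descend(i, j):
        path = []
        while flat_target[i, j] == -1:
            path.append((i, j))
            best = (i, j)
            best_e = e[i, j]
            for a, b in _neighbors(i, j, shape, periodic):
                if e[a, b] < best_e - 1e-15 or (
                        e[a, b] == best_e and (a, b) < best):
                    if e[a, b] <= best_e:
                        best, best_e = (a, b), e[a, b]
            if best == (i, j):
                root = (i, j)
                break
            i, j = best
        else:
            root = flat_target[i, j]
        for c in path:
            flat_target[c] = root
        return root

    basins: dict = {}
    for i, j in order:
        basins.setdefault(descend(i, j), set()).add((i, j))

    if energy_ceiling is not None:
        cut = float(e.min()) + energy_ceiling
        keep = {r for r in basins if e[r] <= cut}
        # cells of dropped minima go to the nearest kept basin by energy path
        for r in list(basins):
            if r not in keep:
                target = min(keep, key=lambda k: e[k])
                basins[target] |= basins.pop(r)
                flat_target[tuple(zip(*basins[target]))] = target

    # merge shallow basins into their neighbor across the lowest boundary
    def lowest_crossing(root):
        best = None
        for (i, j) in basins[root]:
            for a, b in _neighbors(i, j, shape, periodic):
                other = flat_target[a, b]
                if other != root:
                    barrier = max(e[i, j], e[a, b])
                    if best is None or barrier < best[0]:
                        best = (barrier, other)
        return best

    merged = True
    while merged and len(basins) > 1:
        merged = False
        for root in sorted(basins, key=lambda r: (e[r], r), reverse=True):
            crossing = lowest_crossing(root)
            if crossing is None:
                continue
            depth = crossing[0] - e[root]
            if depth < min_depth:
                target = crossing[1]
                basins[target] |= basins.pop(root)
                for c in basins[target]:
                    flat_target[c] = target
                merged = True
                break

    states = []
    roots = sorted(basins, key=lambda r: sum(grid.cell_center(r)))
    for n, root in enumerate(roots):
        crossing = lowest_crossing(root) if len(basins) > 1 else None
        depth = (crossing[0] - e[root]) if crossing else float(np.ptp(e))
        states.append(StateAssignment(
            label=ROMAN[n] if n < len(ROMAN) else str(n + 1),
            center=grid.cell_center(root),
            center_cell=root,
            free_energy=float(e[root]),
            basin_cells=basins[root],
            depth=float(depth),
        ))
    return states


# ---------------------------------------------------------------------------
# minimax path searches
# ---------------------------------------------------------------------------

def _minimax_dijkstra(nodes, edges, energies, start, end):
    """Shortest-bottleneck path with (bottleneck, total, lex) ordering."""
    if start not in nodes or end not in nodes:
        raise ContractError("start/end outside the graph")
    best = {start: (energies[start], energies[start], ())}
    heap = [(energies[start], energies[start], (start,), start)]
    visited = set()
    while heap:
        bott, total, path, node = heapq.heappop(heap)
        if node in visited:
            continue
        visited.add(node)
        if node == end:
            return list(path), bott
        for nxt, seg_max in edges(node):
            if nxt in visited:
                continue
            nb = max(bott, seg_max, energies[nxt])
            nt = total + energies[nxt]
            cand = (nb, nt, path + (nxt,))
            if nxt not in best or cand[:2] < best[nxt][:2]:
                best[nxt] = cand
                heapq.heappush(heap, (nb, nt, path + (nxt,), nxt))
    raise ContractError("no path between the requested endpoints")


def _segment_cells(c0, c1):
    """Cells along the straight line between two grid cells (inclusive)."""
    n = int(max(abs(c1[0] - c0[0]), abs(c1[1] - c0[1]))) + 1
    ii = np.rint(np.linspace(c0[0], c1[0], n)).astype(int)
    jj = np.rint(np.linspace(c0[1], c1[1], n)).astype(int)
    return list(zip(ii, jj))


def extract_block_minimum_path(grid: FESGrid, start, end,
                               block_size: float = DEFAULT_BLOCK_DEGREES) -> PathResult:
    """Minimum free-energy path through per-block minimum-energy cells.

    The grid is tiled into ``block_size`` × ``block_size`` (degree) blocks
    (the last block is padded by the remainder); the lowest-energy cell of
    each block is its candidate point.  The path is the chain of candidate
    points between the blocks containing ``start`` and ``end`` (8-connected
    block moves) minimizing the maximum energy en route, where a move's
    cost includes the grid cells on the straight segment between the two
    candidate cells; ties break on total energy, then block index.
    """
    e = grid.energy
    if block_size <= 0:
        raise ContractError("block size must be positive")
    sa = max(1, int(round(block_size / _spacing(grid.alpha_axis))))
    sb = max(1, int(round(block_size / _spacing(grid.beta_axis))))
    nba = int(np.ceil(e.shape[0] / sa))
    nbb = int(np.ceil(e.shape[1] / sb))

    candidate = {}
    for bi in range(nba):
        for bj in range(nbb):
            tile = e[bi * sa:(bi + 1) * sa, bj * sb:(bj + 1) * sb]
            k = np.unravel_index(np.argmin(tile), tile.shape)
            candidate[(bi, bj)] = (bi * sa + int(k[0]), bj * sb + int(k[1]))

    start_block = _cell_block(grid, start, sa, sb)
    end_block = _cell_block(grid, end, sa, sb)
    if start_block == end_block:
        cell = candidate[start_block]
        a, b = grid.cell_center(cell)
        return PathResult(points=[(a, b, float(e[cell]))], cells=[cell],
                          segment_max=[], bottleneck=float(e[cell]),
                          method="block_minimum", block_size=block_size)

    energies = {blk: float(e[c]) for blk, c in candidate.items()}
    seg_cache = {}

    def edges(blk):
        for nb in _neighbors(*blk, (nba, nbb)):
            key = (blk, nb)
            if key not in seg_cache:
                cells = _segment_cells(candidate[blk], candidate[nb])
                seg_cache[key] = max(float(e[c]) for c in cells)
            yield nb, seg_cache[key]

    blocks, bottleneck = _minimax_dijkstra(set(candidate), edges, energies,
                                           start_block, end_block)
    cells = [candidate[b] for b in blocks]
    points = [(*grid.cell_center(c), float(e[c])) for c in cells]
    seg_max = [max(float(e[c]) for c in _segment_cells(c0, c1))
               for c0, c1 in zip(cells[:-1], cells[1:])]
    return PathResult(points=points, cells=cells, segment_max=seg_max,
                      bottleneck=float(bottleneck), method="block_minimum",
                      block_size=block_size)


def dijkstra_path_oracle(grid: FESGrid, start, end) -> PathResult:
    """Cell-resolution minimax path on the 8-connected grid.

    Independent of the block construction; its bottleneck is a lower bound
    for any coarser path between the same endpoints.
    """
    e = grid.energy
    c0 = grid.nearest_cell(*start)
    c1 = grid.nearest_cell(*end)
    shape = e.shape

    def edges(c):
        for nb in _neighbors(*c, shape):
            yield nb, float(e[nb])

    nodes = {(i, j) for i in range(shape[0]) for j in range(shape[1])}
    energies = {c: float(e[c]) for c in nodes}
    cells, bottleneck = _minimax_dijkstra(nodes, edges, energies, c0, c1)
    points = [(*grid.cell_center(c), float(e[c])) for c in cells]
    return PathResult(points=points, cells=cells,
                      segment_max=[float(e[c]) for c in cells[1:]],
                      bottleneck=float(bottleneck), method="dijkstra")


def _spacing(axis: np.ndarray) -> float:
    return float(axis[1] - axis[0]) if axis.size > 1 else 1.0


def _cell_block(grid: FESGrid, point, sa, sb):
    i, j = grid.nearest_cell(*point)
    return i // sa, j // sb


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------

def barrier_analysis(path: PathResult, states: list) -> PathResult:
    """Barriers between consecutive states along a path, endpoint ΔG, and
    the overall barrier, written back onto the path result.

    For each consecutive pair of visited states the barrier is the maximum
    path energy between the basin centers minus the origin basin's center
    energy; the endpoint ΔG is E(end center) − E(start center).
    """
    by_cell = {}
    for s in states:
        for c in s.basin_cells:
            by_cell[c] = s
    visits = []   # (path index, state) in path order, deduplicated
    for k, c in enumerate(path.cells):
        s = by_cell.get(c)
        if s is None:
            continue
        if not visits or visits[-1][1].label != s.label:
            visits.append((k, s))
    if not visits:
        raise ContractError("path does not visit any detected state")
    if by_cell.get(path.cells[0]) is None or by_cell.get(path.cells[-1]) is None:
        raise ContractError("path endpoints do not lie in detected states")

    def seg_peak(k0, k1):
        peak = max(p[2] for p in path.points[k0:k1 + 1])
        if path.segment_max:
            peak = max([peak] + path.segment_max[k0:k1])
        return peak

    # anchor each visited state at its best (lowest-energy) path point
    anchors = {}
    for k, c in enumerate(path.cells):
        s = by_cell.get(c)
        if s is not None:
            if s.label not in anchors or path.points[k][2] < path.points[anchors[s.label]][2]:
                anchors[s.label] = k
    ordered = [s for _, s in visits]
    barriers = []
    for s0, s1 in zip(ordered[:-1], ordered[1:]):
        k0, k1 = sorted((anchors[s0.label], anchors[s1.label]))
        peak = seg_peak(k0, k1)
        barriers.append({
            "from": s0.label, "to": s1.label,
            "barrier": float(peak - s0.free_energy),
            "peak_energy": float(peak),
        })
    path.barriers = barriers
    start_state, end_state = ordered[0], ordered[-1]
    path.endpoint_dg = float(end_state.free_energy - start_state.free_energy)
    return path
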