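"""Laplace-equation thickness profiling of the corpus callosum.

The thickness model follows the streamline construction used in callosal
morphometry: the outer boundary of the midsagittal mask is split at its two
bottommost extremities into a superior and an inferior contour; a harmonic
potential is solved between them (inferior held at 0, superior at 1); the
0.5 equipotential is the callosal midline; and at 100 stations spaced
equally along the midline, streamlines are integrated along the potential
gradient to both contours.  The streamline length, in mm, is the local
thickness.  Node 0 is the posterior end of the midline, node 99 the
anterior end.

Near the two ends of the structure the superior and inferior contours
approach each other, and clamping Dirichlet values right up to the junction
produces a boundary layer in which the potential — and with it the midline
and the end streamlines — degenerates.  The solver therefore insulates
adaptive *end caps*: boundary pixels lying beyond the ends of the medial
axis (within a 45-degree cone past each end of the axis) carry no Dirichlet
value and act as natural zero-flux boundary.  On a rectangular band this
leaves the vertical sides insulated and the potential exactly linear; on a
half-annulus it insulates the flat end faces and recovers the exact polar
solution, so streamlines are radial everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .masks import MaskGrid

__all__ = [
    "BoundarySplit",
    "PotentialField",
    "Midline",
    "ThicknessProfile",
    "ConvergenceError",
    "split_boundary",
    "solve_laplace",
    "extract_midline",
    "trace_streamlines",
    "thickness_profile",
]

# clockwise 8-neighbourhood starting north (rows grow downward)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


class ConvergenceError(RuntimeError):
    """Raised when the relaxation solver fails to reach tolerance."""

    def __init__(self, message: str, residual: float, n_iter: int):
        super().__init__(message)
        self.residual = residual
        self.n_iter = n_iter


@dataclass
class BoundarySplit:
    """Closed outer boundary split at the bottommost extremities.

    ``superior`` and ``inferior`` are ordered posterior -> anterior and both
    include the two endpoint pixels.
    """

    endpoints: tuple[tuple[int, int], tuple[int, int]]  # (posterior, anterior)
    superior: np.ndarray  # (n, 2) int pixel coords
    inferior: np.ndarray
    cycle: np.ndarray  # full traced boundary, one closed pass


@dataclass
class PotentialField:
    """Discrete harmonic potential on the mask foreground."""

    psi: np.ndarray  # float, NaN on background
    mask: MaskGrid
    fixed_inferior: np.ndarray  # bool grids
    fixed_superior: np.ndarray
    cap: np.ndarray  # insulated boundary pixels (free, zero-flux)
    free: np.ndarray
    converged: bool
    residual: float
    n_iter: int
    tol: float


@dataclass
class Midline:
    """Ordered 0.5-equipotential polyline, posterior -> anterior."""

    points: np.ndarray  # (n, 2) float (row, col) pixel coords
    arclength_mm: float
    pixel_mm: float


@dataclass
class ThicknessProfile:
    """Per-node streamline thickness along the callosal midline."""

    thickness_mm: np.ndarray
    midline_arclength_mm: float
    stations_px: np.ndarray  # (n, 2) midline station coordinates (row, col)
    pixel_mm: float

    @property
    def n_nodes(self) -> int:
        return len(self.thickness_mm)

    def node_index(self) -> np.ndarray:
        return np.arange(self.n_nodes)


# ---------------------------------------------------------------------------
# boundary tracing and splitting


def _trace_cycle(fg: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of the outer boundary, clockwise, closed."""
    rows, cols = np.nonzero(fg)
    start = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))
    # start is the leftmost pixel of the topmost row; its west neighbour is bg
    backtrack = (start[0], start[1] - 1)
    cycle = [start]
    current = start
    first_move: tuple | None = None
    guard = 4 * fg.size
    for _ in range(guard):
        # scan clockwise starting just after the backtrack direction
        off = (backtrack[0] - current[0], backtrack[1] - current[1])
        k0 = _MOORE.index(off)
        nxt = None
        for j in range(1, 9):
            o = _MOORE[(k0 + j) % 8]
            cand = (current[0] + o[0], current[1] + o[1])
            if fg[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        if current == start and first_move is None:
            first_move = nxt
        elif current == start and nxt == first_move:
            break
        cycle.append(nxt)
        backtrack = (backtrack[0], backtrack[1])
        current = nxt
        if current == start:
            # candidate stop; confirmed on next pass via first_move check
            continue
    # drop the duplicated closing pixel if present
    arr = np.array(cycle, dtype=int)
    if len(arr) > 1 and tuple(arr[-1]) == start:
        arr = arr[:-1]
    return arr


def _pick_endpoint(
    cycle: np.ndarray, col_lo: float, col_hi: float, tie_col_extreme: str
) -> tuple[int, int]:
    sel = (cycle[:, 1] >= col_lo) & (cycle[:, 1] <= col_hi)
    cand = cycle[sel]
    if len(cand) == 0:
        raise ValueError("no boundary pixels in endpoint search window")
    bottom = cand[cand[:, 0] == cand[:, 0].max()]
    if tie_col_extreme == "min":
        pick = bottom[np.argmin(bottom[:, 1])]
    else:
        pick = bottom[np.argmax(bottom[:, 1])]
    return int(pick[0]), int(pick[1])


def split_boundary(mask: MaskGrid) -> BoundarySplit:
    """Trace the outer boundary and split it at the bottommost extremities.

    The endpoints are the lowest boundary pixels within the posterior and
    anterior thirds of the bounding box; ties are broken toward the extreme
    column.  The arc containing the topmost boundary pixel is the superior
    contour, the other the inferior; both are returned ordered posterior ->
    anterior and both contain the endpoints.
    """
    fg = mask.grid
    if not fg.any():
        raise ValueError("empty mask")
    cycle = _trace_cycle(fg)
    if len(cycle) < 16:
        raise ValueError(f"boundary of {len(cycle)} pixels is too short (< 16)")

    cols = np.nonzero(fg.any(axis=0))[0]
    c0, c1 = cols[0], cols[-1]
    third = (c1 - c0 + 1) / 3.0
    if mask.anterior == "right":
        post_win, ant_win = (c0, c0 + third), (c1 - third, c1)
        post_tie, ant_tie = "min", "max"
    else:
        post_win, ant_win = (c1 - third, c1), (c0, c0 + third)
        post_tie, ant_tie = "max", "min"
    e_post = _pick_endpoint(cycle, *post_win, post_tie)
    e_ant = _pick_endpoint(cycle, *ant_win, ant_tie)
    if e_post == e_ant:
        raise ValueError("degenerate shape: posterior and anterior endpoints coincide")

    idx_post = int(np.nonzero((cycle[:, 0] == e_post[0]) & (cycle[:, 1] == e_post[1]))[0][0])
    idx_ant = int(np.nonzero((cycle[:, 0] == e_ant[0]) & (cycle[:, 1] == e_ant[1]))[0][0])

    if idx_post <= idx_ant:
        arc_a = cycle[idx_post : idx_ant + 1]
        arc_b = np.concatenate([cycle[idx_ant:], cycle[: idx_post + 1]])
    else:
        arc_a = np.concatenate([cycle[idx_post:], cycle[: idx_ant + 1]])
        arc_b = cycle[idx_ant : idx_post + 1]
    # arc_a runs posterior -> anterior; arc_b anterior -> posterior
    arc_b = arc_b[::-1]

    top_row = cycle[:, 0].min()
    a_top = arc_a[1:-1, 0].min() if len(arc_a) > 2 else np.inf
    b_top = arc_b[1:-1, 0].min() if len(arc_b) > 2 else np.inf
    if a_top <= b_top:
        superior, inferior = arc_a, arc_b
    else:
        superior, inferior = arc_b, arc_a
    if min(a_top, b_top) > top_row:
        # topmost pixel is an endpoint; keep the choice above
        pass
    return BoundarySplit(
        endpoints=(e_post, e_ant), superior=superior, inferior=inferior, cycle=cycle
    )


# ---------------------------------------------------------------------------
# end caps from the medial axis


def _medial_path(fg: np.ndarray) -> np.ndarray | None:
    """Longest geodesic path through the skeleton, as (n, 2) pixel coords."""
    from skimage.morphology import skeletonize
    import networkx as nx

    skel = skeletonize(fg)
    pts = np.argwhere(skel)
    if len(pts) < 5:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    for i, (r, c) in enumerate(pts):
        for dr, dc in _MOORE[:4] + [_MOORE[5], _MOORE[7]]:  # half the moves suffice
            j = index.get((r + dr, c + dc))
            if j is not None:
                g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    # double-sweep: farthest node from an arbitrary node, then farthest again
    comp = max(nx.connected_components(g), key=len)
    src = next(iter(comp))
    far1 = max(nx.single_source_dijkstra_path_length(g, src).items(), key=lambda kv: kv[1])[0]
    lengths, paths = nx.single_source_dijkstra(g, far1)
    far2 = max(lengths.items(), key=lambda kv: kv[1])[0]
    return pts[paths[far2]]


def _end_caps(
    mask: MaskGrid, split: BoundarySplit, cone_slope: float = 0.7
) -> np.ndarray:
    """Boundary pixels to insulate: those beyond the ends of the medial axis.

    The medial path is trimmed where the local half-width (distance map)
    falls below 80% of its interior median, removing spurs into the corners;
    boundary pixels inside a cone past each trimmed end (opening set by
    ``cone_slope``: a pixel is capped when its along-axis excess exceeds
    ``cone_slope`` times its transverse offset) are declared end caps and
    excluded from the Dirichlet set.
    """
    fg = mask.grid
    caps = np.zeros_like(fg, dtype=bool)
    path = _medial_path(fg)
    if path is None or len(path) < 8:
        return caps
    edt = ndimage.distance_transform_edt(fg)
    w = edt[path[:, 0], path[:, 1]]
    mid = w[len(w) // 4 : 3 * len(w) // 4]
    thr = 0.8 * np.median(mid)
    lo = 0
    while lo < len(w) - 1 and w[lo] < thr:
        lo += 1
    hi = len(w) - 1
    while hi > lo and w[hi] < thr:
        hi -= 1
    path = path[lo : hi + 1]
    if len(path) < 8:
        return caps

    cycle = split.cycle
    n = len(cycle)

    def boundary_tangent(i: int) -> np.ndarray:
        a = cycle[(i - 3) % n].astype(float)
        b = cycle[(i + 3) % n].astype(float)
        v = b - a
        nv = np.hypot(*v)
        return v / nv if nv else v

    for endpoint in split.endpoints:
        # medial direction at the path end nearest this endpoint
        d0 = np.hypot(*(path[0] - np.array(endpoint)))
        d1 = np.hypot(*(path[-1] - np.array(endpoint)))
        end = 0 if d0 <= d1 else -1
        c = path[end].astype(float)
        w_end = float(edt[int(c[0]), int(c[1])])
        m = min(len(path) - 1, max(8, int(round(1.5 * w_end))))
        window = path[: m + 1] if end == 0 else path[-(m + 1) :]
        centred = window.astype(float) - window.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        t = vt[0]
        outward = c - path[m if end == 0 else -(m + 1)]
        if t @ outward < 0:
            t = -t
        # walk both ways from the endpoint; cap while the boundary runs
        # transverse to the medial direction (the end face), stop once it
        # turns longitudinal
        i0 = int(
            np.nonzero((cycle[:, 0] == endpoint[0]) & (cycle[:, 1] == endpoint[1]))[0][0]
        )
        caps[endpoint] = True
        limit = max(4, int(round(3 * w_end)))
        for step in (+1, -1):
            for k in range(1, limit + 1):
                i = (i0 + step * k) % n
                if abs(boundary_tangent(i) @ t) >= np.cos(np.pi / 4):
                    break
                caps[cycle[i, 0], cycle[i, 1]] = True
    return caps


# ---------------------------------------------------------------------------
# Laplace solver


def solve_laplace(
    mask: MaskGrid,
    split: BoundarySplit,
    tol: float = 1e-6,
    max_iter: int | None = None,
    caps: np.ndarray | None = None,
    omega: float | None = None,
) -> PotentialField:
    """Solve the Dirichlet problem psi=0 on the inferior contour, psi=1 on
    the superior contour, discrete-harmonic inside, by red-black SOR.

    Pixels flagged in ``caps`` are left free and act as insulated boundary
    (their update averages over foreground neighbours only, a natural
    zero-flux condition).  Raises :class:`ConvergenceError` if the maximum
    residual — the deviation of each free pixel from the mean of its
    foreground neighbours — does not fall below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    fg = mask.grid
    h, wd = fg.shape
    if max_iter is None:
        max_iter = max(20000, 60 * max(h, wd))
    if omega is None:
        omega = 2.0 / (1.0 + np.sin(np.pi / max(h, wd)))

    fixed_sup = np.zeros_like(fg)
    fixed_inf = np.zeros_like(fg)
    fixed_sup[split.superior[:, 0], split.superior[:, 1]] = True
    fixed_inf[split.inferior[:, 0], split.inferior[:, 1]] = True
    # endpoints belong to both contours; anchor them at the inferior value
    fixed_sup &= ~fixed_inf
    cap = np.zeros_like(fg) if caps is None else caps & fg
    fixed_sup &= ~cap
    fixed_inf &= ~cap
    free = fg & ~fixed_sup & ~fixed_inf

    psi = np.zeros((h, wd), dtype=float)
    psi[fg] = 0.5
    psi[fixed_inf] = 0.0
    psi[fixed_sup] = 1.0

    fgf = fg.astype(float)
    nb_cnt = np.zeros_like(psi)
    nb_cnt[1:, :] += fgf[:-1, :]
    nb_cnt[:-1, :] += fgf[1:, :]
    nb_cnt[:, 1:] += fgf[:, :-1]
    nb_cnt[:, :-1] += fgf[:, 1:]
    nb_cnt[nb_cnt == 0] = 1.0  # irrelevant outside fg

    rr, cc = np.meshgrid(np.arange(h), np.arange(wd), indexing="ij")
    parity = (rr + cc) % 2
    red = free & (parity == 0)
    black = free & (parity == 1)

    def nb_mean(p: np.ndarray) -> np.ndarray:
        s = np.zeros_like(p)
        s[1:, :] += p[:-1, :] * fgf[:-1, :]
        s[:-1, :] += p[1:, :] * fgf[1:, :]
        s[:, 1:] += p[:, :-1] * fgf[:, :-1]
        s[:, :-1] += p[:, 1:] * fgf[:, 1:]
        return s / nb_cnt

    residual = np.inf
    it = 0
    while it < max_iter:
        for grp in (red, black):
            m = nb_mean(psi)
            psi[grp] += omega * (m[grp] - psi[grp])
        it += 1
        if it % 25 == 0 or it == max_iter:
            m = nb_mean(psi)
            residual = float(np.abs(m[free] - psi[free]).max()) if free.any() else 0.0
            if residual <= tol:
                break
    converged = residual <= tol
    if not converged:
        raise ConvergenceError(
            f"SOR did not converge in {it} iterations (residual {residual:.3e})",
            residual,
            it,
        )
    out = psi.copy()
    out[~fg] = np.nan
    return PotentialField(
        psi=out,
        mask=mask,
        fixed_inferior=fixed_inf,
        fixed_superior=fixed_sup,
        cap=cap,
        free=free,
        converged=converged,
        residual=residual,
        n_iter=it,
        tol=tol,
    )


# ---------------------------------------------------------------------------
# midline extraction


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def extract_midline(field: PotentialField) -> Midline:
    """Extract the 0.5 level set of the potential as an ordered polyline.

    Marching squares runs on the potential with background masked out, so
    the midline terminates at the mask boundary near the two junctions.
    """
    from skimage import measure

    psi = field.psi
    interior = field.free & (psi > 0.05) & (psi < 0.95)
    if not interior.any():
        raise ValueError("potential field carries no intermediate values")
    contours = measure.find_contours(psi, 0.5)
    contours = [c for c in contours if len(c) >= 2]
    if not contours:
        raise ValueError("no 0.5 level set found in the potential field")
    lengths = sorted((_polyline_length(c) for c in contours), reverse=True)
    best = max(contours, key=_polyline_length)
    if len(lengths) > 1 and lengths[1] > 0.5 * lengths[0]:
        raise ValueError(
            "0.5 level set is disconnected "
            f"(two branches of length {lengths[0]:.1f} and {lengths[1]:.1f} px)"
        )
    # orient posterior -> anterior using the anterior flag
    k = max(1, len(best) // 10)
    start_col = best[:k, 1].mean()
    end_col = best[-k:, 1].mean()
    if (field.mask.anterior == "right" and start_col > end_col) or (
        field.mask.anterior == "left" and start_col < end_col
    ):
        best = best[::-1]
    return Midline(
        points=best,
        arclength_mm=_polyline_length(best) * field.mask.pixel_mm,
        pixel_mm=field.mask.pixel_mm,
    )


# ---------------------------------------------------------------------------
# streamline tracing


def _bilinear(arr: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    r = np.clip(r, 0, h - 1.001)
    c = np.clip(c, 0, w - 1.001)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    return (
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0 + 1, c0] * fr * (1 - fc)
        + arr[r0, c0 + 1] * (1 - fr) * fc
        + arr[r0 + 1, c0 + 1] * fr * fc
    )



def _smooth_boundary_cycles(
    fg: np.ndarray, sigma_ind: float = 0.7, sigma_arc: float = 2.8, trust_kappa: float = 0.25
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sub-pixel boundary polylines with staircase noise suppressed.

    The 0.5 contour of the lightly smoothed mask indicator tracks the
    geometric boundary but oscillates by a few tenths of a pixel with the
    pixel staircase.  Each closed contour is resampled to uniform arclength,
    low-pass filtered along arclength (periodic Gaussian, ``sigma_arc`` in
    px), and pushed back out along its normal by kappa * sigma_arc^2 / 2 to
    undo the curvature shrinkage of the filter.
    """
    from skimage import measure

    ind = ndimage.gaussian_filter(fg.astype(float), sigma_ind)
    cycles = []
    for c in measure.find_contours(ind, 0.5):
        if len(c) < 8 or not np.allclose(c[0], c[-1]):
            continue
        c = c[:-1]
        seg = np.hypot(*np.diff(np.vstack([c, c[:1]]), axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(32, int(round(total / 0.5)))
        u = np.arange(n) * total / n
        rr = np.interp(u, s[:-1], c[:, 0], period=total)
        cc = np.interp(u, s[:-1], c[:, 1], period=total)
        h = total / n
        freqs = np.fft.rfftfreq(n, d=1.0)
        damp = np.exp(-0.5 * (2 * np.pi * freqs * sigma_arc / h) ** 2)
        rs = np.fft.irfft(np.fft.rfft(rr) * damp, n)
        cs = np.fft.irfft(np.fft.rfft(cc) * damp, n)
        d1 = lambda x: (np.roll(x, -1) - np.roll(x, 1)) / (2 * h)
        d2 = lambda x: (np.roll(x, -1) - 2 * x + np.roll(x, 1)) / h**2
        rp, cp = d1(rs), d1(cs)
        rpp, cpp = d2(rs), d2(cs)
        sp = np.hypot(rp, cp)
        sp[sp == 0] = 1.0
        kappa = (rp * cpp - cp * rpp) / sp**3
        off = kappa * sigma_arc**2 / 2.0
        pts = np.column_stack([rs - off * (-cp / sp), cs - off * (rp / sp)])
        # points where the filter scale approaches the curvature radius
        # (corners) are not trustworthy stop surfaces
        trust = np.abs(kappa) * sigma_arc < trust_kappa
        cycles.append((pts, trust))
    return cycles


class _BoundaryRefiner:
    """Snaps streamline stop points onto the smoothed boundary polylines."""

    def __init__(self, fg: np.ndarray, sigma_ind: float, sigma_arc: float = 2.8, trust_kappa: float = 0.25):
        from scipy.spatial import cKDTree

        self.cycles = _smooth_boundary_cycles(fg, sigma_ind, sigma_arc, trust_kappa)
        pts = []
        segs = []
        for cyc, trust in self.cycles:
            keep = trust & np.roll(trust, -1)
            nxt = np.roll(cyc, -1, axis=0)
            pts.append(0.5 * (cyc + nxt)[keep])
            segs.append(np.stack([cyc, nxt], axis=1)[keep])
        if pts and sum(len(p) for p in pts):
            self.mid = np.concatenate(pts)
            self.seg = np.concatenate(segs)
            self.tree = cKDTree(self.mid)
        else:
            self.tree = None

    def shift(self, cross: np.ndarray, direction: np.ndarray, max_shift: float = 0.8) -> np.ndarray:
        """Signed along-ray correction from the rough crossing to the
        smoothed boundary; 0 where no trustworthy intersection exists
        (e.g. near corners, where the smoothed curve is cut)."""
        out = np.zeros(len(cross))
        if self.tree is None:
            return out
        neighbours = self.tree.query_ball_point(cross, r=3.0)
        for i, idxs in enumerate(neighbours):
            best = None
            for j in idxs:
                a, b = self.seg[j]
                e = b - a
                d = direction[i]
                denom = d[0] * (-e[1]) - d[1] * (-e[0])
                if abs(denom) < 1e-12:
                    continue
                rhs = a - cross[i]
                s = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / denom
                t = (d[0] * rhs[1] - d[1] * rhs[0]) / denom
                if -0.05 <= t <= 1.05 and abs(s) <= max_shift:
                    if best is None or abs(s) < abs(best):
                        best = s
            if best is not None:
                out[i] = best
        return out


def _resample_stations(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = (np.arange(n) + 0.5) / n * total
    rows = np.interp(targets, s, points[:, 0])
    cols = np.interp(targets, s, points[:, 1])
    return np.column_stack([rows, cols])


def trace_streamlines(
    field: PotentialField,
    midline: Midline,
    n_nodes: int = 100,
    step_px: float = 0.25,
    indicator_sigma: float = 1.0,
) -> ThicknessProfile:
    """Integrate gradient streamlines from equally spaced midline stations.

    The midline is resampled at the midpoints of ``n_nodes`` equal-arclength
    bins.  From each station the normalised potential gradient is followed
    by fixed-step RK2 toward the superior contour and (reversed) toward the
    inferior contour; each leg ends where the smoothed mask indicator
    crosses 0.5, i.e. at the geometric boundary of the structure.  Thickness
    is the summed length of the two legs.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    fg = field.mask.grid
    px = field.mask.pixel_mm

    # extend psi into the background (nearest foreground value) for gradients
    psi_ext = field.psi.copy()
    _, (ir, ic) = ndimage.distance_transform_edt(
        ~fg, return_distances=True, return_indices=True
    )
    psi_ext[~fg] = field.psi[ir[~fg], ic[~fg]]
    gy, gx = np.gradient(psi_ext)
    indicator = ndimage.gaussian_filter(fg.astype(float), sigma=indicator_sigma)
    ind_gy, ind_gx = np.gradient(indicator)
    refiner = _BoundaryRefiner(fg, indicator_sigma)

    stations = _resample_stations(midline.points, n_nodes)
    max_steps = int(16 * max(fg.shape) / step_px)

    def march(sign: float) -> np.ndarray:
        pos = stations.copy()
        length = np.zeros(n_nodes)
        prev_dir = np.zeros((n_nodes, 2))
        prev_dir[:, 0] = -sign  # default: superior is up (smaller rows)
        active = np.ones(n_nodes, dtype=bool)
        for _ in range(max_steps):
            if not active.any():
                break
            p = pos[active]
            d1 = _grad_dir(p, sign, prev_dir[active])
            midp = p + 0.5 * step_px * d1
            d2 = _grad_dir(midp, sign, d1)
            newp = p + step_px * d2
            ind = _bilinear(indicator, newp[:, 0], newp[:, 1])
            psv = _bilinear(psi_ext, newp[:, 0], newp[:, 1])
            # a leg terminates at the geometric boundary, but only once the
            # potential has essentially reached its target value -- this
            # keeps streamlines that legitimately graze an insulated end
            # face (where the gradient runs parallel to the boundary) from
            # stopping early on staircase jitter of the indicator
            armed = psv >= 0.98 if sign > 0 else psv <= 0.02
            graze = (ind < 0.58) & ~armed
            if graze.any():
                # slide along the wall: strip the outward-normal component
                # of the step so the leg stays inside the mask
                gi = np.column_stack(
                    [
                        _bilinear(ind_gy, newp[graze, 0], newp[graze, 1]),
                        _bilinear(ind_gx, newp[graze, 0], newp[graze, 1]),
                    ]
                )
                gn = np.hypot(gi[:, 0], gi[:, 1])
                gn[gn < 1e-12] = 1.0
                gi /= gn[:, None]  # inward normal (indicator increases inward)
                dg = d2[graze]
                out_comp = (dg * -gi).sum(axis=1)
                blend = np.clip((0.58 - ind[graze]) / 0.08, 0.0, 1.0)
                dg = dg + (blend * np.where(out_comp > 0, out_comp, 0.0))[:, None] * gi
                nn = np.hypot(dg[:, 0], dg[:, 1])
                keep = nn > 1e-6
                dg[keep] /= nn[keep, None]
                d2[graze] = np.where(keep[:, None], dg, d2[graze])
                # gentle inward nudge when already past the wall
                inw = np.clip(0.5 - ind[graze], 0.0, None)[:, None]
                newp[graze] = p[graze] + step_px * d2[graze] + inw * gi * step_px
                ind[graze] = _bilinear(indicator, newp[graze, 0], newp[graze, 1])
            crossed = (ind < 0.5) & (armed | (ind < 0.15))
            idx = np.flatnonzero(active)
            # bisect the final segment for the 0.5 crossing
            if crossed.any():
                a = p[crossed]
                b = newp[crossed]
                for _ in range(25):
                    m = 0.5 * (a + b)
                    inside = _bilinear(indicator, m[:, 0], m[:, 1]) >= 0.5
                    a[inside] = m[inside]
                    b[~inside] = m[~inside]
                cross = 0.5 * (a + b)
                frac = np.hypot(*(cross - p[crossed]).T)
                frac += refiner.shift(cross, d2[crossed])
                length[idx[crossed]] += frac
            length[idx[~crossed]] += step_px
            pos[idx] = newp
            prev_dir[idx] = d2
            active[idx[crossed]] = False
        if active.any():
            node = int(np.flatnonzero(active)[0])
            raise RuntimeError(
                f"streamline from node {node} did not reach the boundary "
                f"within {max_steps} steps"
            )
        return length

    def _grad_dir(p: np.ndarray, sign: float, fallback: np.ndarray) -> np.ndarray:
        g = np.column_stack(
            [_bilinear(gy, p[:, 0], p[:, 1]), _bilinear(gx, p[:, 0], p[:, 1])]
        )
        g *= sign
        norm = np.hypot(g[:, 0], g[:, 1])
        weak = norm < 1e-12
        g[weak] = fallback[weak]
        norm = np.hypot(g[:, 0], g[:, 1])
        norm[norm < 1e-12] = 1.0
        g /= norm[:, None]
        # avoid reversals at saddle-ish interpolation artefacts
        flip = (g * fallback).sum(axis=1) < -0.2
        g[flip] = fallback[flip]
        return g

    up = march(+1.0)  # toward psi = 1 (superior)
    down = march(-1.0)
    thickness = (up + down) * px
    if not np.all(np.isfinite(thickness)) or np.any(thickness <= 0):
        bad = int(np.flatnonzero(~np.isfinite(thickness) | (thickness <= 0))[0])
        raise RuntimeError(f"non-positive or non-finite thickness at node {bad}")
    return ThicknessProfile(
        thickness_mm=thickness,
        midline_arclength_mm=midline.arclength_mm,
        stations_px=stations,
        pixel_mm=px,
    )


# ---------------------------------------------------------------------------
# composition


def thickness_profile(
    mask: MaskGrid,
    n_nodes: int = 100,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> ThicknessProfile:
    """Full pipeline stage: boundary split, Laplace solve with adaptive end
    caps, midline extraction, and streamline tracing."""
    split = split_boundary(mask)
    caps = _end_caps(mask, split)
    field = solve_laplace(mask, split, tol=tol, max_iter=max_iter, caps=caps)
    midline = extract_midline(field)
    return trace_streamlines(field, midline, n_nodes=n_nodes)
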