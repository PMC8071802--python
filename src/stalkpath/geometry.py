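"""Morphological observables of membrane density fields.

All measurements use a hydrophobic iso-density threshold (default 2.2 nm⁻³)
to define the membrane interface: marching-squares contours of planar
slices, the minimal intermembrane (water-gap) distance d_w, the stalk
diameter d_st at the mid-plane between the membranes, azimuthally averaged
(R, z) density maps about the stalk axis, and membrane thickness as a
function of lateral distance from the axis.  Sub-cell positions are obtained
by linear interpolation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from skimage import measure

from .grids import DensityField

DEFAULT_THRESHOLD = 2.2  # hydrophobic number density at the interface, nm^-3

_AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


class UndefinedDistanceError(ValueError):
    """Fewer than two membrane bodies present along the measurement axis."""


@dataclass
class GeometryResult:
    """d_w and d_st of one density field at a given threshold."""

    d_w: float
    d_st: float | None
    threshold: float
    axis: int

    @property
    def connected(self) -> bool:
        return self.d_st is not None


@dataclass
class AxialProfile:
    """Azimuthally averaged density on (R, z) bins about the stalk axis."""

    R: np.ndarray
    z: np.ndarray
    mean_density: np.ndarray  # (nR, nZ), NaN where empty
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rr, zz = np.meshgrid(self.R, self.z, indexing="ij")
        return pd.DataFrame(
            {
                "R_nm": rr.ravel(),
                "z_nm": zz.ravel(),
                "density_nm3": self.mean_density.ravel(),
                "count": self.counts.ravel(),
            }
        )


def _axis_index(axis) -> int:
    if isinstance(axis, str):
        return _AXIS_NAMES[axis.lower()]
    return int(axis)


def interface_contour(
    field: DensityField, threshold: float = DEFAULT_THRESHOLD, plane=("y", None)
) -> list[np.ndarray]:
    """Iso-density polylines on a 2D slice, in nm.

    ``plane`` is (axis, coordinate): the slice normal and its position in nm
    (box center when None).  Returns marching-squares contours with linear
    sub-cell interpolation; each polyline is an (k, 2) array of in-plane
    coordinates ordered as the two remaining axes.
    """
    ax = _axis_index(plane[0])
    coord = plane[1]
    grid = field.grid
    if coord is None:
        coord = grid.box_lengths[ax] / 2.0
    if not (0 < threshold < float(field.values.max() or np.inf)):
        import warnings

        warnings.warn("threshold outside field range; no contours")
        return []
    idx = int(round(coord / grid.cell_lengths[ax] - 0.5)) % grid.n_cells[ax]
    slc = [slice(None)] * 3
    slc[ax] = idx
    plane_vals = field.values[tuple(slc)]
    keep = [a for a in range(3) if a != ax]
    dls = [grid.cell_lengths[a] for a in keep]
    out = []
    for c in measure.find_contours(plane_vals, threshold):
        poly = np.empty_like(c)
        poly[:, 0] = (c[:, 0] + 0.5) * dls[0]
        poly[:, 1] = (c[:, 1] + 0.5) * dls[1]
        out.append(poly)
    return out


def _column_runs(f: np.ndarray, thr: float):
    """Periodic above-threshold runs of one axial column.

    Returns a list of (z_enter, z_exit) crossing positions in units of cells
    (centers at j + 0.5), with z_exit possibly beyond the array length for a
    run wrapping the periodic boundary; empty when nothing is above
    threshold, None when everything is (fully connected column).
    """
    above = f >= thr
    n = len(f)
    if above.all():
        return None
    if not above.any():
        return []
    # rotate so index 0 is below threshold, then runs don't wrap
    start = int(np.argmin(above))
    fa = np.roll(f, -start)
    ab = np.roll(above, -start)
    runs = []
    j = 0
    while j < n:
        if ab[j]:
            k = j
            while k + 1 < n and ab[k + 1]:
                k += 1
            # entry crossing between j-1 (<thr) and j (>=thr)
            frac_in = (fa[j] - thr) / (fa[j] - fa[j - 1])
            z_in = j + 0.5 - frac_in
            if k < n - 1:
                frac_out = (fa[k] - thr) / (fa[k] - fa[k + 1])
                z_out = k + 0.5 + frac_out
            else:  # run touches the rotated end; exit is the wrap crossing
                frac_out = (fa[k] - thr) / (fa[k] - fa[0])
                z_out = k + 0.5 + frac_out
            runs.append((z_in + start, z_out + start))
            j = k + 1
        else:
            j += 1
    return runs


def _body_labels(field: DensityField, axis: int, thr: float) -> np.ndarray:
    """Connected-component labels of the above-threshold region.

    6-connectivity, periodic across the two lateral boundaries but *open*
    along the measurement axis, so a membrane and its periodic image along
    that axis count as distinct bodies (the vesicle-vs-image setup) while
    the two z-sides of one vesicle shell share a label.  Returned with the
    measurement axis moved last.
    """
    from scipy import ndimage

    binary = np.moveaxis(field.values, axis, -1) >= thr
    labels, n = ndimage.label(binary)
    if n == 0:
        return labels
    # union-find merge across the two (periodic) lateral faces
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for lat in (0, 1):
        lo = np.take(labels, 0, axis=lat)
        hi = np.take(labels, -1, axis=lat)
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(a), int(b))
    flat = np.array([find(i) for i in range(n + 1)])
    return flat[labels]


def _gap_candidates(field: DensityField, axis: int, thr: float,
                    exclude_same_body: bool = True):
    """Water gaps between distinct membrane bodies, per lateral column.

    Returns (candidates, any_connected): candidates is a list of
    (gap_length_nm, gap_center_nm, column_index) for every inter-run gap
    that separates two different bodies — or one body from its periodic
    image when the gap wraps the axis boundary; with ``exclude_same_body``
    gaps between the two sides of a single body (e.g. through a vesicle's
    interior) are excluded.  any_connected is True when some column is
    above threshold everywhere.
    """
    vals = np.moveaxis(field.values, axis, -1)
    labels = _body_labels(field, axis, thr) if exclude_same_body else None
    na, nb, nz = vals.shape
    dl = field.grid.cell_lengths[axis]
    lz = nz * dl
    cands = []
    any_connected = False
    for ia in range(na):
        for ib in range(nb):
            runs = _column_runs(vals[ia, ib], thr)
            if runs is None:
                any_connected = True
                continue
            if len(runs) < 2:
                continue
            k = len(runs)
            if labels is not None:
                col_labels = labels[ia, ib]
                run_label = [
                    col_labels[int((z_in + z_out) / 2.0) % nz]
                    for z_in, z_out in runs
                ]
            for r in range(k):
                z_out = runs[r][1] * dl
                z_in_next = runs[(r + 1) % k][0] * dl
                gap = (z_in_next - z_out) % lz
                wraps = (z_out % lz) + gap > lz
                if (
                    labels is not None
                    and not wraps
                    and run_label[r] == run_label[(r + 1) % k]
                ):
                    continue  # interior pocket of one body, not an intermembrane gap
                center = (z_out + gap / 2.0) % lz
                cands.append((gap, center, (ia, ib)))
    return cands, any_connected


def _column_value_at(f: np.ndarray, z: float, dl: float) -> float:
    """Periodic linear interpolation of a column profile at position z (nm)."""
    n = len(f)
    u = z / dl - 0.5
    j0 = int(np.floor(u)) % n
    t = (u - np.floor(u))
    return float((1.0 - t) * f[j0] + t * f[(j0 + 1) % n])


def intermembrane_distance(
    field: DensityField, threshold: float = DEFAULT_THRESHOLD, axis=2
) -> float:
    """Minimal water-gap distance d_w between two membrane bodies (nm).

    For every lateral column parallel to ``axis`` the below-threshold gaps
    between consecutive above-threshold runs are measured with linear
    sub-cell interpolation (periodically, so a gap across the box boundary —
    a vesicle facing its periodic image — is handled transparently).  d_w is
    the smallest such gap; it is 0 when the bodies are connected, i.e. when
    some column is above threshold at the level of the minimal gap.
    """
    ax = _axis_index(axis)
    cands, any_connected = _gap_candidates(field, ax, threshold)
    if any_connected:
        return 0.0
    if _find_bridge(field, threshold, ax) is not None:
        return 0.0  # a stalk spans the gap: membranes are connected
    if not cands:
        raise UndefinedDistanceError(
            "no column sees two membrane bodies along the axis"
        )
    gap, z_c, _ = min(cands, key=lambda c: c[0])
    return float(gap)


def _plane_at(field: DensityField, axis: int, z_star: float):
    """Density linearly interpolated onto the plane at ``z_star`` (nm).

    Returns (plane_values (A, B), lateral cell lengths)."""
    vals = np.moveaxis(field.values, axis, -1)
    nz = vals.shape[-1]
    dl = field.grid.cell_lengths[axis]
    u = z_star / dl - 0.5
    j0 = int(np.floor(u)) % nz
    t = u - np.floor(u)
    plane = (1.0 - t) * vals[:, :, j0] + t * vals[:, :, (j0 + 1) % nz]
    lat_axes = [a for a in range(3) if a != axis]
    return plane, [field.grid.cell_lengths[a] for a in lat_axes]


def midplane_density(field: DensityField, threshold: float, axis: int):
    """Density on the plane through the center of the minimal water gap."""
    ax = _axis_index(axis)
    cands, _ = _gap_candidates(field, ax, threshold)
    if not cands:
        raise UndefinedDistanceError("cannot locate an intermembrane gap")
    _, z_star, _ = min(cands, key=lambda c: c[0])
    return _plane_at(field, ax, z_star)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _bridge_in_plane(plane: np.ndarray, thr: float, dls):
    """Closed, simply connected above-threshold component of a mid-plane.

    The plane is recentred on its density maximum so the candidate bridge
    does not straddle the periodic edge; the innermost closed contour
    containing that maximum is accepted only if no other contour is nested
    inside it — a stalk cross-section is a filled disc, whereas a slice
    through a shell (e.g. a vesicle equator) is an annulus and is rejected.
    Returns (area, polygon) or None.
    """
    if plane.max() < thr:
        return None
    na, nb = plane.shape
    imax, jmax = np.unravel_index(np.argmax(plane), plane.shape)
    plane = np.roll(plane, (na // 2 - imax, nb // 2 - jmax), axis=(0, 1))
    center = np.array([(na // 2 + 0.5) * dls[0], (nb // 2 + 0.5) * dls[1]])
    polys = []
    for c in measure.find_contours(plane, thr):
        if not np.allclose(c[0], c[-1]):
            continue  # open contour touching the plane edge
        polys.append(
            np.column_stack([(c[:, 0] + 0.5) * dls[0], (c[:, 1] + 0.5) * dls[1]])
        )
    containing = [p for p in polys if MplPath(p).contains_point(center)]
    if not containing:
        return None
    best = min(containing, key=_polygon_area)
    path = MplPath(best)
    for q in polys:
        if q is best:
            continue
        if path.contains_point(q.mean(axis=0)) and _polygon_area(q) < _polygon_area(
            best
        ):
            return None  # annulus, not a bridge
    return _polygon_area(best), best


def _find_bridge(field: DensityField, thr: float, axis: int):
    """Locate the stalk cross-section at a candidate gap mid-plane.

    Tries the minimal inter-body gap first, then the minimal gap including
    same-body gaps (the flanks of a bridge fusing two bodies into one).
    """
    seen = set()
    for exclude in (True, False):
        cands, _ = _gap_candidates(field, axis, thr, exclude_same_body=exclude)
        if not cands:
            continue
        _, z_star, _ = min(cands, key=lambda c: c[0])
        key = round(z_star, 9)
        if key in seen:
            continue
        seen.add(key)
        plane, dls = _plane_at(field, axis, z_star)
        found = _bridge_in_plane(plane, thr, dls)
        if found is not None:
            return found
    return None


def stalk_diameter(
    field: DensityField,
    threshold: float = DEFAULT_THRESHOLD,
    axis=2,
    method: str = "area",
) -> float | None:
    """Diameter of the hydrophobic bridge at the inter-membrane mid-plane.

    The above-threshold region of the mid-plane containing the bridge is
    delineated by a marching-squares contour; ``method="area"`` (default)
    reports the diameter of the circle with the same enclosed area (robust to
    shape fluctuations, exact for circular stalks), ``method="chord"`` the
    maximal chord of the contour.  Returns None when no above-threshold
    connection spans the gap.
    """
    ax = _axis_index(axis)
    found = _find_bridge(field, threshold, ax)
    if found is None:
        return None
    area, poly = found
    if method == "area":
        return float(2.0 * np.sqrt(area / np.pi))
    if method == "chord":
        d2 = np.sum((poly[:, None, :] - poly[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))
    raise ValueError("method must be 'area' or 'chord'")


def measure_geometry(
    field: DensityField, threshold: float = DEFAULT_THRESHOLD, axis=2
) -> GeometryResult:
    """d_w and d_st of one field in a single call."""
    ax = _axis_index(axis)
    d_st = stalk_diameter(field, threshold, ax)
    if d_st is not None:
        d_w = 0.0
    else:
        d_w = intermembrane_distance(field, threshold, ax)
    return GeometryResult(d_w=d_w, d_st=d_st, threshold=threshold, axis=ax)


def geometry_table(
    replicas, s_values=None, threshold: float = DEFAULT_THRESHOLD, axis=2
) -> pd.DataFrame:
    """Per-replica (s, d_w, d_st) table along a path."""
    rows = []
    for i, rep in enumerate(replicas):
        res = measure_geometry(rep, threshold, axis)
        rows.append(
            {
                "s": s_values[i] if s_values is not None else i,
                "d_w_nm": res.d_w,
                "d_st_nm": res.d_st if res.d_st is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _min_image(d: np.ndarray, length: float) -> np.ndarray:
    return d - length * np.round(d / length)


def azimuthal_average(
    field: DensityField,
    center_xy: tuple[float, float] | None = None,
    axis=2,
    n_radial_bins: int = 30,
) -> AxialProfile:
    """Mean density on (R, z) bins about a vertical axis through ``center_xy``.

    R is the lateral minimum-image distance from the axis; z runs along the
    grid planes of ``axis``.  Bins with no cells are NaN (counts 0).
    """
    if n_radial_bins < 1:
        raise ValueError("need at least one radial bin")
    ax = _axis_index(axis)
    grid = field.grid
    lat = [a for a in range(3) if a != ax]
    box = np.asarray(grid.box_lengths)
    if center_xy is None:
        center_xy = (box[lat[0]] / 2.0, box[lat[1]] / 2.0)
    c0 = _min_image(grid.cell_centers(lat[0]) - center_xy[0], box[lat[0]])
    c1 = _min_image(grid.cell_centers(lat[1]) - center_xy[1], box[lat[1]])
    r = np.sqrt(c0[:, None] ** 2 + c1[None, :] ** 2)
    r_max = min(box[lat[0]], box[lat[1]]) / 2.0
    edges = np.linspace(0.0, r_max, n_radial_bins + 1)
    r_idx = np.clip(np.digitize(r, edges) - 1, 0, n_radial_bins - 1)
    vals = np.moveaxis(field.values, ax, -1)
    nz = vals.shape[-1]
    flat_bins = (r_idx[..., None] * nz + np.arange(nz)[None, None, :]).ravel()
    within = (r <= r_max)[..., None] & np.ones(nz, dtype=bool)
    sums = np.bincount(
        flat_bins[within.ravel()],
        weights=vals.ravel()[within.ravel()],
        minlength=n_radial_bins * nz,
    )
    counts = np.bincount(flat_bins[within.ravel()], minlength=n_radial_bins * nz)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    zc = grid.cell_centers(ax)
    return AxialProfile(
        R=0.5 * (edges[:-1] + edges[1:]),
        z=zc,
        mean_density=mean.reshape(n_radial_bins, nz),
        counts=counts.reshape(n_radial_bins, nz),
    )


def _column_body_extents(f: np.ndarray, mid: int, thr: float, dl: float):
    """Above-threshold extent (nm) of the lower and upper membrane body in a
    column, with linearly interpolated segment edges."""
    above = f >= thr
    segs = []
    j = 0
    n = len(f)
    while j < n:
        if above[j]:
            k = j
            while k + 1 < n and above[k + 1]:
                k += 1
            # interpolated entry and exit positions
            if j > 0:
                frac = (f[j] - thr) / (f[j] - f[j - 1])
                z_in = (j + 0.5 - frac) * dl
            else:
                z_in = 0.0
            if k < n - 1:
                frac = (f[k] - thr) / (f[k] - f[k + 1])
                z_out = (k + 0.5 + frac) * dl
            else:
                z_out = n * dl
            segs.append((z_in, z_out, 0.5 * (j + k) + 0.5))
            j = k + 1
        else:
            j += 1
    lower = sum(z1 - z0 for z0, z1, c in segs if c <= mid)
    upper = sum(z1 - z0 for z0, z1, c in segs if c > mid)
    return lower, upper


def thickness_profile(
    field: DensityField,
    threshold: float = DEFAULT_THRESHOLD,
    axis=2,
    center_xy: tuple[float, float] | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Membrane thickness vs lateral distance from the stalk axis.

    Per column, the above-threshold axial extent of each membrane body is
    measured with sub-cell interpolation; columns are binned by their lateral
    distance R from the axis.  Returns a table with columns R_nm,
    thickness_nm (mean over both bodies and the bin), and count; empty when
    the field holds no membrane.
    """
    ax = _axis_index(axis)
    grid = field.grid
    dl = grid.cell_lengths[ax]
    vals = np.moveaxis(field.values, ax, -1)
    nz = vals.shape[-1]
    # roll so the center of the minimal intermembrane gap sits mid-array,
    # splitting the two bodies into lower/upper halves
    try:
        cands, _ = _gap_candidates(field, ax, threshold)
    except Exception:
        cands = []
    if cands:
        _, z_c, _ = min(cands, key=lambda c: c[0])
        shift = nz // 2 - int(round(z_c / dl - 0.5))
    else:
        shift = 0
    arr = np.roll(vals, shift, axis=-1)
    na, nb, nz = arr.shape
    mid = nz // 2
    lat = [a for a in range(3) if a != ax]
    box = np.asarray(grid.box_lengths)
    if center_xy is None:
        center_xy = (box[lat[0]] / 2.0, box[lat[1]] / 2.0)
    c0 = _min_image(grid.cell_centers(lat[0]) - center_xy[0], box[lat[0]])
    c1 = _min_image(grid.cell_centers(lat[1]) - center_xy[1], box[lat[1]])
    r = np.sqrt(c0[:, None] ** 2 + c1[None, :] ** 2)
    r_max = min(box[lat[0]], box[lat[1]]) / 2.0
    edges = np.linspace(0.0, r_max, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ia in range(na):
        for ib in range(nb):
            if r[ia, ib] > r_max:
                continue
            lo, hi = _column_body_extents(arr[ia, ib], mid, threshold, dl)
            b = min(int(r[ia, ib] / r_max * n_bins), n_bins - 1)
            for th in (lo, hi):
                if th > 0:
                    sums[b] += th
                    counts[b] += 1
    out = pd.DataFrame(
        {
            "R_nm": 0.5 * (edges[:-1] + edges[1:]),
            "thickness_nm": np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
            "count": counts,
        }
    )
    return out[out["count"] > 0].reset_index(drop=True)
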