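"""Tag localization from multi-receiver detections.

Two steps reconstruct positions from a raw detection log. First, receiver
clocks are synchronized against stationary sync beacons at known positions:
within each fitting window the per-station offset relative to a reference
receiver is solved in least squares from beacon arrival-time differences,
and offsets are interpolated linearly between window midpoints (linearly
extrapolated at the edges, which is what captures clock drift). Second,
clock-corrected detections are grouped into transmissions, and each group
heard by three or more receivers is localized by minimizing the summed
pairwise difference-of-time-of-arrival (DToA) error over a horizontal grid
at the tag-reported depth:

    e(x) = sum over receiver pairs (i, j) of
           | (t_i - t_j) - (|x - r_i| - |x - r_j|) / c |

The argmin is found with a coarse-to-fine grid search (exhaustive search
available for validation) and refined by a local quadratic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SPEED_OF_SOUND, ReceiverArraySpec


@dataclass
class ClockModel:
    """Piecewise-linear per-station clock offsets relative to a reference."""

    station_ids: list[str]
    window_mids: np.ndarray  # s, ascending
    offsets: np.ndarray  # (n_windows, n_stations), s
    reference_id: str
    flagged: set[str] = field(default_factory=set)  # stations with no beacon coverage

    def offset(self, station_id: str, t: np.ndarray | float) -> np.ndarray | float:
        """Offset of a station clock at time t (receiver clock - true time)."""
        k = self.station_ids.index(station_id)
        col = self.offsets[:, k]
        if len(self.window_mids) == 1:
            return np.full_like(np.asarray(t, dtype=float), col[0]) if np.ndim(t) else col[0]
        # linear interpolation with linear (not constant) edge extrapolation
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.interp(t_arr, self.window_mids, col)
        m = self.window_mids
        lo = t_arr < m[0]
        hi = t_arr > m[-1]
        if lo.any():
            slope = (col[1] - col[0]) / (m[1] - m[0])
            out[lo] = col[0] + slope * (t_arr[lo] - m[0])
        if hi.any():
            slope = (col[-1] - col[-2]) / (m[-1] - m[-2])
            out[hi] = col[-1] + slope * (t_arr[hi] - m[-1])
        return out if np.ndim(t) else float(out[0])

    def correct(self, detections: pd.DataFrame) -> pd.DataFrame:
        """Return detections with arrival times moved onto the reference clock."""
        out = detections.reset_index(drop=True).copy()
        t = out["arrival_time_s"].to_numpy(dtype=float)
        corr = np.zeros_like(t)
        for sid in out["receiver_id"].unique():
            m = (out["receiver_id"] == sid).to_numpy()
            corr[m] = self.offset(sid, t[m])
        out["arrival_time_s"] = t - corr
        return out


def identity_clock(station_ids: list[str], reference_id: str | None = None) -> ClockModel:
    """A no-op clock model (all offsets zero)."""
    ref = reference_id or station_ids[0]
    return ClockModel(list(station_ids), np.array([0.0]), np.zeros((1, len(station_ids))), ref)


def fit_clock_model(
    beacon_detections: pd.DataFrame,
    beacons: pd.DataFrame,
    stations: pd.DataFrame,
    window_s: float = 3600.0,
    reference_id: str | None = None,
    speed_of_sound: float = SPEED_OF_SOUND,
    beacon_group_gap_s: float = 10.0,
) -> ClockModel:
    """Estimate per-station clock offsets from sync-beacon detections.

    For a beacon transmission heard by stations s and r, the travel-time
    corrected arrivals differ by exactly offset_s - offset_r, so each
    co-detection yields one linear equation in the station offsets. The
    per-window least-squares system is solved with the reference station
    pinned to zero; stations that never hear any beacon are flagged.
    """
    station_ids = list(stations["id"])
    st_xyz = stations.set_index("id")[["x_m", "y_m", "z_m"]]
    b_xyz = beacons.set_index("id")[["x_m", "y_m", "z_m"]]
    if reference_id is None:
        # station closest to the array centroid hears the most beacons
        c = st_xyz.to_numpy().mean(axis=0)
        reference_id = station_ids[int(np.argmin(np.linalg.norm(st_xyz.to_numpy() - c, axis=1)))]

    det = beacon_detections.copy()
    # travel-time corrected arrival = emission + station offset + noise
    st_arr = st_xyz.to_numpy(dtype=float)
    b_arr = b_xyz.to_numpy(dtype=float)
    st_pos = {s: i for i, s in enumerate(st_xyz.index)}
    b_pos = {b: i for i, b in enumerate(b_xyz.index)}
    ri = det["receiver_id"].map(st_pos).to_numpy()
    bi = det["tag_id"].map(b_pos).to_numpy()
    dist = np.linalg.norm(st_arr[ri] - b_arr[bi], axis=1)
    det["tau"] = det["arrival_time_s"].to_numpy(dtype=float) - dist / speed_of_sound

    heard = set(det["receiver_id"].unique())
    flagged = {s for s in station_ids if s not in heard}
    if reference_id in flagged:
        raise ValueError("reference station hears no beacon; choose another reference")

    t0, t1 = det["tau"].min(), det["tau"].max()
    n_win = max(1, int(np.ceil((t1 - t0) / window_s)))
    k_of = {s: i for i, s in enumerate(station_ids)}
    mids = np.empty(n_win)
    offsets = np.zeros((n_win, len(station_ids)))

    for w in range(n_win):
        lo, hi = t0 + w * window_s, t0 + (w + 1) * window_s
        mids[w] = 0.5 * (lo + hi)
        sub = det[(det["tau"] >= lo) & (det["tau"] < hi if w < n_win - 1 else det["tau"] <= hi)]
        # aggregate pairwise tau differences per (station, station) over all
        # transmissions of each beacon (grouped by a gap threshold)
        pair_sum: dict[tuple[str, str], tuple[float, int]] = {}
        for _, bsub in sub.groupby("tag_id"):
            bsub = bsub.sort_values("tau")
            taus = bsub["tau"].to_numpy()
            rids = bsub["receiver_id"].to_numpy()
            # same transmission iff taus agree to well under the beacon
            # interval; the gap must tolerate multi-second relative clock
            # offsets accumulated through drift
            brk = np.nonzero(np.diff(taus) > beacon_group_gap_s)[0] + 1
            for seg_t, seg_r in zip(np.split(taus, brk), np.split(rids, brk)):
                for a in range(len(seg_r)):
                    for b in range(a + 1, len(seg_r)):
                        if seg_r[a] == seg_r[b]:
                            continue
                        key = (seg_r[a], seg_r[b])
                        s, n = pair_sum.get(key, (0.0, 0))
                        pair_sum[key] = (s + (seg_t[a] - seg_t[b]), n + 1)
        if not pair_sum:
            offsets[w] = np.nan
            continue
        # only stations chained to the reference through co-detections are
        # solvable this window; the rest stay NaN and interpolate later
        connected = _component_of(reference_id, pair_sum.keys(), station_ids)
        rows, rhs, wts = [], [], []
        for (sa, sb), (s, n) in pair_sum.items():
            if sa not in connected or sb not in connected:
                continue
            row = np.zeros(len(station_ids))
            row[k_of[sa]] += 1.0
            row[k_of[sb]] -= 1.0
            rows.append(row)
            rhs.append(s / n)
            wts.append(np.sqrt(n))
        if not rows:
            offsets[w] = np.nan
            offsets[w, k_of[reference_id]] = 0.0
            continue
        # pin the reference offset to zero
        pin = np.zeros(len(station_ids))
        pin[k_of[reference_id]] = 1.0
        a_mat = np.vstack([np.asarray(rows) * np.asarray(wts)[:, None], pin[None, :] * 1e3])
        b_vec = np.concatenate([np.asarray(rhs) * np.asarray(wts), [0.0]])
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
        offsets[w] = sol - sol[k_of[reference_id]]
        for s in station_ids:
            if s not in connected:
                offsets[w, k_of[s]] = np.nan

    order = np.argsort(mids)
    mids, offsets = mids[order], offsets[order]
    # per-station interpolation over solvable windows; never-solvable -> flagged
    for k, s in enumerate(station_ids):
        col = offsets[:, k]
        ok = np.isfinite(col)
        if not ok.any():
            flagged.add(s)
            offsets[:, k] = 0.0
        elif not ok.all():
            offsets[:, k] = np.interp(mids, mids[ok], col[ok])
    return ClockModel(station_ids, mids, offsets, reference_id, flagged)


def _component_of(root: str, pairs, station_ids: list[str]) -> set[str]:
    """Stations reachable from ``root`` through co-detection pairs."""
    adj: dict[str, set[str]] = {s: set() for s in station_ids}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen = {root}
    stack = [root]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


@dataclass
class TransmissionGroup:
    """Detections of one tag transmission across receivers."""

    tag_id: str
    receiver_ids: np.ndarray
    times: np.ndarray  # clock-corrected arrival times, s
    depth: float  # median tag-reported depth, m

    @property
    def n_receivers(self) -> int:
        return len(np.unique(self.receiver_ids))

    @property
    def localizable(self) -> bool:
        return self.n_receivers >= 3


def group_transmissions(
    detections: pd.DataFrame,
    array_span_m: float,
    timing_noise_sd: float = 0.001,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> list[TransmissionGroup]:
    """Cluster clock-corrected detections into per-transmission groups.

    Single-linkage clustering in time per tag: a gap larger than the maximum
    in-array travel-time spread plus a noise guard starts a new group. Groups
    with fewer than three receivers are retained but flagged non-localizable.
    """
    gap = array_span_m / speed_of_sound + 6.0 * timing_noise_sd + 0.01
    groups: list[TransmissionGroup] = []
    for tag, sub in detections.groupby("tag_id", sort=True):
        sub = sub.sort_values("arrival_time_s")
        t = sub["arrival_time_s"].to_numpy(dtype=float)
        r = sub["receiver_id"].to_numpy()
        z = sub["depth_m"].to_numpy(dtype=float)
        brk = np.nonzero(np.diff(t) > gap)[0] + 1
        for ti, ri, zi in zip(np.split(t, brk), np.split(r, brk), np.split(z, brk)):
            groups.append(TransmissionGroup(str(tag), ri, ti, float(np.median(zi))))
    groups.sort(key=lambda g: g.times[0])
    return groups


@dataclass
class PositionFix:
    """A localized transmission."""

    tag_id: str
    time: float  # estimated emission time on the reference clock, s
    x: float
    y: float
    z: float
    residual: float  # summed pairwise DToA error at the fix, s
    n_receivers: int
    grid_xy: tuple[float, float] = (np.nan, np.nan)  # unrefined grid argmin


class DtoaGrid:
    """Shared search-grid geometry for localizing many transmissions.

    Precomputes squared horizontal distances from every cell of a coarse
    grid to every station; per-group 3D distances only add the depth term.
    """

    def __init__(
        self,
        stations: pd.DataFrame,
        spacing: float = 1.0,
        inflate: float = 50.0,
        coarse_factor: int = 5,
        detection_range: float | None = None,
        range_slack: float = 10.0,
    ):
        self.detection_range = detection_range
        self.range_slack = range_slack
        self.station_ids = list(stations["id"])
        self.xyz = stations[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
        self.spacing = float(spacing)
        self.coarse = float(spacing * coarse_factor)
        x0, x1 = self.xyz[:, 0].min() - inflate, self.xyz[:, 0].max() + inflate
        y0, y1 = self.xyz[:, 1].min() - inflate, self.xyz[:, 1].max() + inflate
        self.extent = (x0, x1, y0, y1)
        self.cx = np.arange(x0, x1 + self.coarse / 2, self.coarse)
        self.cy = np.arange(y0, y1 + self.coarse / 2, self.coarse)
        gx, gy = np.meshgrid(self.cx, self.cy, indexing="ij")
        self.coarse_pts = np.column_stack([gx.ravel(), gy.ravel()])
        dx = self.coarse_pts[:, 0][:, None] - self.xyz[None, :, 0]
        dy = self.coarse_pts[:, 1][:, None] - self.xyz[None, :, 1]
        self.coarse_h2 = dx * dx + dy * dy  # (n_cells, n_stations)
        self.k_of = {s: i for i, s in enumerate(self.station_ids)}

    def fine_axes(self, center: tuple[float, float], half_cells: int) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.extent
        h = half_cells * self.spacing
        fx = np.arange(max(x0, center[0] - h), min(x1, center[0] + h) + self.spacing / 2, self.spacing)
        fy = np.arange(max(y0, center[1] - h), min(y1, center[1] + h) + self.spacing / 2, self.spacing)
        return fx, fy


def _pair_error(dtoa: np.ndarray, d: np.ndarray, pairs: np.ndarray, c: float) -> np.ndarray:
    """Summed |DToA - predicted| over pairs; d is (n_cells, k) distances."""
    pred = (d[:, pairs[:, 0]] - d[:, pairs[:, 1]]) / c
    return np.abs(dtoa[None, :] - pred).sum(axis=1)


def localize_dtoa(
    group: TransmissionGroup,
    grid: DtoaGrid,
    speed_of_sound: float = SPEED_OF_SOUND,
    exhaustive: bool = False,
    refine: bool = True,
    collinear_tol: float = 1e-6,
) -> PositionFix | None:
    """Localize one transmission group by DToA error-map minimization.

    Arrival times of duplicate receivers are averaged first. Returns None
    for groups with fewer than three distinct receivers or a collinear
    station geometry (mirror-ambiguous). The search runs on a horizontal
    grid at the tag-reported depth; ``exhaustive`` forces a full fine-grid
    sweep (the validation path), otherwise a coarse sweep is followed by a
    fine local search, then sub-grid quadratic refinement.

    With three receivers only two independent DToAs exist and the two
    hyperbola-branch intersections both fit the arrival times; the physical
    constraint that a detecting receiver heard the tag at all (so the tag
    lies within its detection range, plus slack) is added as a penalty term
    to discard the spurious mirror solution.
    """
    ids, inv = np.unique(group.receiver_ids, return_inverse=True)
    if len(ids) < 3:
        return None
    t = np.array([group.times[inv == i].mean() for i in range(len(ids))])
    k_idx = np.array([grid.k_of[s] for s in ids])
    st = grid.xyz[k_idx]
    # collinearity: rank of centered horizontal coordinates
    cen = st[:, :2] - st[:, :2].mean(axis=0)
    if np.linalg.svd(cen, compute_uv=False)[-1] < collinear_tol * max(1.0, np.abs(cen).max()):
        return None
    ii, jj = np.triu_indices(len(ids), k=1)
    pairs = np.column_stack([ii, jj])
    dtoa = t[ii] - t[jj]
    z = group.depth
    dz2 = (z - st[:, 2]) ** 2

    rng_max = (
        grid.detection_range + grid.range_slack if grid.detection_range is not None else np.inf
    )

    def eval_on(pts: np.ndarray) -> np.ndarray:
        dx = pts[:, 0][:, None] - st[None, :, 0]
        dy = pts[:, 1][:, None] - st[None, :, 1]
        d = np.sqrt(dx * dx + dy * dy + dz2[None, :])
        err = _pair_error(dtoa, d, pairs, speed_of_sound)
        if np.isfinite(rng_max):
            # quadratic penalty per meter beyond a detecting receiver's range
            excess = np.clip(d - rng_max, 0.0, None)
            err = err + (excess**2).sum(axis=1) / speed_of_sound
        return err

    if exhaustive:
        x0, x1, y0, y1 = grid.extent
        fx = np.arange(x0, x1 + grid.spacing / 2, grid.spacing)
        fy = np.arange(y0, y1 + grid.spacing / 2, grid.spacing)
    else:
        h2 = grid.coarse_h2[:, k_idx]
        if np.isfinite(rng_max):
            # the tag was heard by every receiver of the group, so only
            # cells within range of all of them can host the true position
            cand = np.nonzero((h2 <= rng_max * rng_max).all(axis=1))[0]
            if len(cand) == 0:
                cand = np.arange(h2.shape[0])
        else:
            cand = np.arange(h2.shape[0])
        d_c = np.sqrt(h2[cand] + dz2[None, :])
        err_c = _pair_error(dtoa, d_c, pairs, speed_of_sound)
        if np.isfinite(rng_max):
            excess = np.clip(d_c - rng_max, 0.0, None)
            err_c = err_c + (excess**2).sum(axis=1) / speed_of_sound
        cbest = grid.coarse_pts[cand[int(np.argmin(err_c))]]
        fx, fy = grid.fine_axes((cbest[0], cbest[1]), half_cells=3 * int(round(grid.coarse / grid.spacing)))
    gx, gy = np.meshgrid(fx, fy, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    err = eval_on(pts)
    best = int(np.argmin(err))
    bi, bj = divmod(best, len(fy))
    x_hat, y_hat = fx[bi], fy[bj]
    residual = float(err[best])
    gx_hat, gy_hat = float(x_hat), float(y_hat)

    if refine:
        err2 = err.reshape(len(fx), len(fy))
        x_hat = _quad_refine(fx, err2[:, bj], bi)
        y_hat = _quad_refine(fy, err2[bi, :], bj)
        residual = float(eval_on(np.array([[x_hat, y_hat]]))[0])

    d_fix = np.sqrt((x_hat - st[:, 0]) ** 2 + (y_hat - st[:, 1]) ** 2 + dz2)
    residual = float(_pair_error(dtoa, d_fix[None, :], pairs, speed_of_sound)[0])
    t_emit = float(np.median(t - d_fix / speed_of_sound))
    return PositionFix(
        tag_id=group.tag_id,
        time=t_emit,
        x=float(x_hat),
        y=float(y_hat),
        z=float(z),
        residual=residual,
        n_receivers=len(ids),
        grid_xy=(gx_hat, gy_hat),
    )


def _quad_refine(axis: np.ndarray, err: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the argmin and its two neighbors."""
    if i == 0 or i == len(axis) - 1:
        return float(axis[i])
    y0, y1, y2 = err[i - 1], err[i], err[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(axis[i])
    shift = 0.5 * (y0 - y2) / denom
    h = axis[1] - axis[0]
    return float(axis[i] + np.clip(shift, -1.0, 1.0) * h)


def localize_all(
    detections: pd.DataFrame,
    array: ReceiverArraySpec,
    clock: ClockModel | None = None,
    grid_spacing: float = 1.0,
    inflate: float = 50.0,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> pd.DataFrame:
    """Clock-correct, group, and localize a full detection log.

    Returns a fixes table `tag_id, time_s, x_m, y_m, z_m, residual_s,
    n_receivers` with one row per transmission heard by >= 3 receivers.
    """
    if clock is None:
        clock = identity_clock(list(array.stations["id"]))
    usable = detections[~detections["receiver_id"].isin(clock.flagged)]
    if clock.flagged:
        warnings.warn(f"excluding unsynchronized stations: {sorted(clock.flagged)}")
    corrected = clock.correct(usable)
    xyz = array.station_xyz()
    span = float(np.linalg.norm(xyz[:, :2].max(axis=0) - xyz[:, :2].min(axis=0)))
    groups = group_transmissions(
        corrected, span, timing_noise_sd=array.timing_noise_sd, speed_of_sound=speed_of_sound
    )
    grid = DtoaGrid(
        array.stations, spacing=grid_spacing, inflate=inflate, detection_range=array.detection_range
    )
    rows = []
    for g in groups:
        fix = localize_dtoa(g, grid, speed_of_sound=speed_of_sound)
        if fix is None:
            continue
        rows.append((fix.tag_id, fix.time, fix.x, fix.y, fix.z, fix.residual, fix.n_receivers))
    return pd.DataFrame(
        rows, columns=["tag_id", "time_s", "x_m", "y_m", "z_m", "residual_s", "n_receivers"]
    ).sort_values(["tag_id", "time_s"]).reset_index(drop=True)
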