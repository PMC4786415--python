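"""Local coiled-coil periodicity, Crick angles and heptad register.

The local helix axis of each residue is built from four consecutive Cα
positions by the classic bisector construction: the bisectors of the
virtual Cα angles at residues i and i+1 both point at the helix axis, so
their cross product gives the local axis direction, and the radius follows
from requiring the offset Cα points to fall on a common line.  From the
axis frames we obtain, per residue, the helical twist (rotation of the Cα
about the local axis per residue) and the rise.

The local periodicity *relative to the bundle axis* corrects the twist by
the rotation of the local helix axis around the bundle axis:

    periodicity(i) = 360 / (twist(i) - axis_azimuth_advance(i))

A straight helix (no supercoil) measures ~3.63 residues per turn; a heptad
coiled coil, whose axis winds left-handed around the bundle, measures 3.5.

The Crick angle of a residue is the signed azimuth of its Cα about the
local helix axis, measured from the direction toward the bundle axis.
Heptad register positions a-g correspond to seven ideal Crick angles
spaced by 360/7 in sequence steps of 360/3.5; positions a and d straddle
the core direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chain import BackboneChain

#: Ideal Crick angles (degrees) of the seven heptad positions.  The phase
#: is chosen so that the hydrophobic core positions a and d straddle the
#: direction toward the bundle axis (Crick angle 0).
_STEP = 720.0 / 7.0  # Crick-angle advance per residue in an ideal heptad
IDEAL_CRICK = {
    label: ((25.714285 + k * _STEP) % 360.0)
    for k, label in enumerate("abcdefg")
}

#: Axis points closer than this to the bundle axis (Å) are treated as
#: lying on it: no azimuth correction, no defined Crick reference.
_ON_AXIS = 0.5


def _wrap(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap to (-180, 180]."""
    a = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return a if isinstance(angle, np.ndarray) else float(a)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else v * np.nan


def _signed_angle(u: np.ndarray, v: np.ndarray, about: np.ndarray) -> float:
    """Signed angle from u to v about the unit vector ``about`` (degrees)."""
    u = u - np.dot(u, about) * about
    v = v - np.dot(v, about) * about
    x = float(np.dot(u, v))
    y = float(np.dot(np.cross(u, v), about))
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class HelixFrames:
    """Per-residue local helix frames of one Cα trace.

    Frame i is built from Cα(i-1)..Cα(i+2); ``valid`` is False where the
    window leaves the trace or the geometry is degenerate (collinear Cα).
    """

    axis_point: np.ndarray   # (n, 3)
    axis_dir: np.ndarray     # (n, 3), unit, oriented along the chain
    twist: np.ndarray        # degrees per residue about the local axis
    rise: np.ndarray         # Å per residue along the local axis
    radius: np.ndarray       # Å, Cα distance from the local axis
    valid: np.ndarray        # bool


def local_helix_axis(ca_trace: np.ndarray) -> HelixFrames:
    """Local helix axis frames from an ordered Cα trace (n >= 4)."""
    P = np.asarray(ca_trace, dtype=float)
    n = len(P)
    frames = HelixFrames(
        axis_point=np.full((n, 3), np.nan),
        axis_dir=np.full((n, 3), np.nan),
        twist=np.full(n, np.nan),
        rise=np.full(n, np.nan),
        radius=np.full(n, np.nan),
        valid=np.zeros(n, dtype=bool),
    )
    if n < 4:
        return frames
    # Bisectors of the virtual Cα angle; point toward the local axis.
    bis = np.full((n, 3), np.nan)
    for i in range(1, n - 1):
        b = _unit(P[i - 1] - P[i]) + _unit(P[i + 1] - P[i])
        bis[i] = _unit(b)
    for i in range(1, n - 2):
        b1, b2 = bis[i], bis[i + 1]
        if not (np.isfinite(b1).all() and np.isfinite(b2).all()):
            continue
        d = np.cross(b1, b2)
        if np.linalg.norm(d) < 1e-8:  # straight / degenerate
            continue
        d = _unit(d)
        step = P[i + 1] - P[i]
        if np.dot(d, step) < 0:
            d = -d
        # radius r such that P[i] + r*b1 and P[i+1] + r*b2 differ only
        # along the axis direction (least squares).
        dperp = step - np.dot(step, d) * d
        db = b2 - b1
        dbperp = db - np.dot(db, d) * d
        denom = float(np.dot(dbperp, dbperp))
        if denom < 1e-12:
            continue
        r = -float(np.dot(dperp, dbperp)) / denom
        a1 = P[i] + r * b1
        rise = float(np.dot(step, d))
        a2 = a1 + rise * d
        twist = _signed_angle(P[i] - a1, P[i + 1] - a2, d)
        frames.axis_point[i] = a1
        frames.axis_dir[i] = d
        frames.twist[i] = twist
        frames.rise[i] = rise
        frames.radius[i] = float(np.linalg.norm(P[i] - a1 - np.dot(P[i] - a1, d) * d))
        frames.valid[i] = True
    return frames


@dataclass
class BundleAxis:
    """Central axis of a helix bundle: a fitted line plus the raw points."""

    line_point: np.ndarray
    line_dir: np.ndarray          # unit, oriented along the chains
    points: np.ndarray | None = None   # per-residue centroid axis points

    def closest_point(self, x: np.ndarray) -> np.ndarray:
        t = float(np.dot(np.asarray(x) - self.line_point, self.line_dir))
        return self.line_point + t * self.line_dir

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the line, for azimuth bookkeeping."""
        d = self.line_dir
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, d)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = _unit(ref - np.dot(ref, d) * d)
        e2 = np.cross(d, e1)
        return e1, e2

    def azimuth(self, x: np.ndarray) -> tuple[float, float]:
        """(azimuth degrees, radial distance) of a point about the line."""
        e1, e2 = self.frame()
        rho = np.asarray(x) - self.closest_point(x)
        return (
            float(np.degrees(np.arctan2(np.dot(rho, e2), np.dot(rho, e1)))),
            float(np.linalg.norm(rho)),
        )


def straight_axis(point, direction) -> BundleAxis:
    """A straight reference axis, e.g. for analysing a single helix."""
    return BundleAxis(np.asarray(point, float), _unit(np.asarray(direction, float)))


def bundle_axis(chains: list[BackboneChain]) -> BundleAxis:
    """Central axis of a bundle: centroid of per-chain local axis points.

    Needs at least two chains; the centroid is taken over residue indices
    where every chain has a valid local frame, smoothed with a width-3
    moving average, and a straight line is fitted through the result.  For
    an exactly C3-symmetric bundle the fitted line is the symmetry axis.
    """
    if len(chains) < 2:
        raise ValueError("bundle_axis needs at least 2 chains")
    frame_list = [local_helix_axis(c.ca) for c in chains]
    m = min(len(c) for c in chains)
    valid = np.all([f.valid[:m] for f in frame_list], axis=0)
    if valid.sum() < 2:
        raise ValueError("chains have no overlapping residues with valid frames")
    pts = np.full((m, 3), np.nan)
    centroid = np.mean([f.axis_point[:m] for f in frame_list], axis=0)
    pts[valid] = centroid[valid]
    for k in range(3):
        pts[:, k] = smooth(pts[:, k], window=3, valid=valid)
    good = pts[valid]
    center = good.mean(axis=0)
    _, _, vt = np.linalg.svd(good - center)
    direction = _unit(vt[0])
    if np.dot(direction, good[-1] - good[0]) < 0:
        direction = -direction
    return BundleAxis(center, direction, points=pts)


@dataclass
class LocalPeriodicityTrace:
    """Per-residue periodicity and Crick angle of one chain."""

    chain_id: str
    periodicity: np.ndarray
    crick_angle: np.ndarray
    axis_point: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.periodicity)

    def smoothed(self, window: int = 3) -> "LocalPeriodicityTrace":
        """Copy with the periodicity smoothed by a centered moving average."""
        return replace(
            self,
            periodicity=smooth(self.periodicity, window=window, valid=self.valid),
        )


def periodicity_trace(chain: BackboneChain, axis: BundleAxis) -> LocalPeriodicityTrace:
    """Per-residue local periodicity and Crick angle relative to an axis.

    The per-residue rotation of the Cα about the local helix axis is
    corrected by the advance of the local axis point around the bundle
    axis, so a left-handed supercoil lowers the periodicity below the
    ~3.63 of the straight helix and a right-handed one raises it.
    """
    frames = local_helix_axis(chain.ca)
    n = len(chain)
    periodicity = np.full(n, np.nan)
    crick = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if not frames.valid[i]:
            continue
        # Crick angle: azimuth of the Cα about the local axis, from the
        # direction toward the bundle axis.
        a = frames.axis_point[i]
        d = frames.axis_dir[i]
        toward = axis.closest_point(a) - a
        if np.linalg.norm(toward - np.dot(toward, d) * d) > 1e-6:
            crick[i] = _signed_angle(toward, chain.ca[i] - a, d) % 360.0
        if i + 1 < n and frames.valid[i + 1]:
            az1, rho1 = axis.azimuth(frames.axis_point[i])
            az2, rho2 = axis.azimuth(frames.axis_point[i + 1])
            advance = 0.0
            if rho1 > _ON_AXIS and rho2 > _ON_AXIS:
                advance = float(_wrap(az2 - az1))
            denom = frames.twist[i] - advance
            if denom > 1e-6:
                periodicity[i] = 360.0 / denom
                valid[i] = True
    return LocalPeriodicityTrace(
        chain.chain_id, periodicity, crick, frames.axis_point, valid
    )


def smooth(values: np.ndarray, window: int = 3, valid: np.ndarray | None = None) -> np.ndarray:
    """Centered moving average over valid neighbours; length preserved.

    The window must be odd; at the ends (and next to invalid entries) it
    shrinks to the available valid neighbours.  Entries that are invalid
    (or NaN) stay NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    out = np.full_like(x, np.nan)
    half = window // 2
    for i in range(len(x)):
        if not ok[i]:
            continue
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        sel = ok[lo:hi]
        out[i] = x[lo:hi][sel].mean()
    return out


# ---------------------------------------------------------------------------
# Register assignment


#: Minimum displacement (degrees) of a pre-layer residue's Crick angle
#: from ideal g toward c for it to be labelled as the hybrid g/c position.
GC_THRESHOLD = 10.0


def _segment_crick(
    chain: BackboneChain,
    frames: HelixFrames,
    axis: BundleAxis,
    run: tuple[int, int],
) -> np.ndarray:
    """Crick angles over a helical run, robust at the run edges.

    Frames whose 4-residue window stays inside the run are used directly;
    edge residues (whose windows would reach into a flanking β-strand or
    off the chain) are measured about the axis line of the nearest
    interior frame instead.
    """
    start, stop = run
    crick = np.full(len(chain), np.nan)
    interior = [
        i for i in range(start, stop)
        if frames.valid[i] and i - 1 >= start and i + 2 <= stop - 1
    ]
    for i in range(start, stop):
        if interior:
            k = min(interior, key=lambda j: abs(j - i))
        elif frames.valid[start:stop].any():
            k = start + int(np.flatnonzero(frames.valid[start:stop])[0])
        else:
            continue
        a_k = frames.axis_point[k]
        d = frames.axis_dir[k]
        a_i = a_k + np.dot(chain.ca[i] - a_k, d) * d
        toward = axis.closest_point(a_i) - a_i
        if np.linalg.norm(toward - np.dot(toward, d) * d) < 1e-6:
            continue
        crick[i] = _signed_angle(toward, chain.ca[i] - a_i, d) % 360.0
    return crick


def _nearest_label(angle: float) -> str:
    return min(
        IDEAL_CRICK,
        key=lambda lab: abs(_wrap(angle - IDEAL_CRICK[lab])),
    )


def assign_register(
    chain: BackboneChain,
    axis: BundleAxis,
    strand_windows: list[tuple[int, int, int]] = (),
    gc_threshold: float = GC_THRESHOLD,
) -> list[str]:
    """Heptad register labels for every residue of one chain.

    ``strand_windows`` lists β-layer strands on this chain as index
    triplets (β₁, β₂, β₃).  Helical residues are labelled by the nearest
    ideal Crick angle; strand residues are labelled β1/β2/β3; the residue
    directly after a β₃ is forced to e (β-layers dictate the downstream
    register); and a residue directly before a β₁ whose Crick angle is
    displaced from ideal g toward c by more than ``gc_threshold`` degrees
    is labelled g/c.
    """
    n = len(chain)
    labels = ["undefined"] * n
    frames = local_helix_axis(chain.ca)
    strand_idx: set[int] = set()
    for b1, b2, b3 in strand_windows:
        if not (b1 + 1 == b2 == b3 - 1):
            raise ValueError("strand windows must be consecutive index triplets")
        labels[b1], labels[b2], labels[b3] = "β1", "β2", "β3"
        strand_idx |= {b1, b2, b3}
    # Helical runs between strands / chain ends.
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if i in strand_idx:
            i += 1
            continue
        j = i
        while j < n and j not in strand_idx:
            j += 1
        runs.append((i, j))
        i = j
    starts_after_b3 = {b3 + 1 for _, _, b3 in strand_windows}
    before_b1 = {b1 - 1 for b1, _, _ in strand_windows}
    for run in runs:
        crick = _segment_crick(chain, frames, axis, run)
        for i in range(run[0], run[1]):
            if not np.isfinite(crick[i]):
                continue
            labels[i] = _nearest_label(crick[i])
            if i in before_b1:
                # Displaced from ideal g toward c by more than the
                # threshold, but still nearest to g (beyond half the g-c
                # separation the plain nearest-angle label c applies).
                disp = (IDEAL_CRICK["g"] - crick[i]) % 360.0
                if gc_threshold < disp <= (IDEAL_CRICK["g"] - IDEAL_CRICK["c"]) / 2.0:
                    labels[i] = "g/c"
        if run[0] in starts_after_b3:
            labels[run[0]] = "e"
    return labels


def chain_path_rotation(
    chain: BackboneChain,
    axis: BundleAxis,
    strand: tuple[int, int, int],
    flank: int = 10,
) -> float:
    """Azimuthal rotation (degrees) of a chain's path across a β-layer.

    Measures the angle about the bundle axis between the helix-axis
    position of the segment preceding the strand and that of the segment
    following it.  A canonical β-layer moves each chain 120° around the
    trimer axis (counterclockwise viewed from the N terminus); the
    returned value is signed about ``axis.line_dir``.
    """
    b1, _, b3 = strand
    up = chain.ca[max(0, b1 - 1 - flank) : b1 - 1]
    down = chain.ca[b3 + 2 : b3 + 2 + flank]
    if len(up) < 6 or len(down) < 6:
        raise ValueError("need at least 6 residues of helix on both sides")
    angles = []
    for seg in (up, down):
        frames = local_helix_axis(seg)
        pts = frames.axis_point[frames.valid]
        az, rho = axis.azimuth(pts.mean(axis=0))
        if rho < _ON_AXIS:
            raise ValueError("helical segment lies on the bundle axis")
        angles.append(az)
    return float(_wrap(angles[1] - angles[0]))


def periodicity_table(
    chain: BackboneChain,
    axis: BundleAxis,
    strand_windows: list[tuple[int, int, int]] = (),
    window: int = 3,
) -> pd.DataFrame:
    """Per-residue periodicity/Crick/register table (TSV-ready)."""
    trace = periodicity_trace(chain, axis)
    register = assign_register(chain, axis, strand_windows)
    return pd.DataFrame(
        {
            "chain": chain.chain_id,
            "resnum": chain.seq_ids,
            "aa": chain.aas,
            "periodicity_raw": np.round(trace.periodicity, 4),
            "periodicity_smoothed": np.round(
                smooth(trace.periodicity, window=window, valid=trace.valid), 4
            ),
            "crick_angle": np.round(trace.crick_angle, 2),
            "register": register,
        }
    )
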