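"""Small vector/VSEPR toolbox.

Direction construction for completing idealized coordination polyhedra around
sp/sp2/sp3 centres.  All functions are pure and operate on unit vectors; bond
lengths are applied by the callers.
"""

from __future__ import annotations

import numpy as np

TET_ANGLE = 109.4712206344907  # arccos(-1/3), degrees


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    c = np.dot(unit(a), unit(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = unit(v)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def rotate_about(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation of v about axis by deg degrees."""
    axis = unit(axis)
    t = np.radians(deg)
    return (v * np.cos(t)
            + np.cross(axis, v) * np.sin(t)
            + axis * np.dot(axis, v) * (1 - np.cos(t)))


def cone_direction(axis: np.ndarray, ref_perp: np.ndarray,
                   half_angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Unit vector at half_angle from axis, rotated by torsion about axis.

    torsion 0 lies in the (axis, ref_perp) plane on the ref_perp side.
    """
    axis = unit(axis)
    perp = unit(ref_perp - np.dot(ref_perp, axis) * axis)
    t = np.radians(half_angle_deg)
    d = axis * np.cos(t) + perp * np.sin(t)
    return rotate_about(d, axis, torsion_deg)


def complete_directions(neighbor_dirs: list[np.ndarray], n_new: int,
                        ideal_angle: float,
                        ref_dir: np.ndarray | None = None) -> list[np.ndarray]:
    """Unit vectors completing an idealized polyhedron around a centre.

    neighbor_dirs: unit vectors toward already-placed substituents.
    n_new: number of directions to generate.
    ideal_angle: the class angle (180 sp, 120 sp2, ~109.47 sp3, 104.5 water).
    ref_dir: optional torsion reference for rotationally ambiguous cases;
        the first new direction is placed anti (staggered) to it.

    The construction is exact: every generated pair of new directions and, for
    single-neighbour centres, every new-to-neighbour angle equals ideal_angle.
    For 2- and 3-neighbour centres the new directions follow the exterior
    bisector, which matches the class angle only when the existing frame is
    itself ideal.
    """
    k = len(neighbor_dirs)
    if n_new <= 0:
        return []

    if k == 0:
        # Isolated centre (water): first direction +z-ish deterministic.
        d0 = np.array([0.0, 0.0, 1.0])
        if n_new == 1:
            return [d0]
        d1 = cone_direction(d0, np.array([1.0, 0.0, 0.0]), ideal_angle, 0.0)
        out = [d0, d1]
        if n_new > 2:  # tetrahedral completion of the remaining positions
            out.extend(_complete_tet_pair(d0, d1)[: n_new - 2])
        return out[:n_new]

    if k == 1:
        axis = -neighbor_dirs[0]
        if abs(ideal_angle - 180.0) < 1e-9:
            return [axis] * 1  # sp: single linear position
        half = 180.0 - ideal_angle
        if ref_dir is not None:
            perp = ref_dir - np.dot(ref_dir, axis) * axis
            if np.linalg.norm(perp) < 1e-8:
                perp = any_perpendicular(axis)
            perp = unit(perp)
            base_torsion = 180.0  # anti / staggered w.r.t. the reference
        else:
            perp = any_perpendicular(axis)
            base_torsion = 0.0
        step = 360.0 / max(n_new, int(round(360.0 / 120.0)) if ideal_angle < 115 else 2)
        # sp2 with one neighbour: two in-plane positions at +-(180-120)=60 deg
        # from the inverted neighbour direction; sp3: three staggered.
        if ideal_angle > 115.0:  # sp2
            torsions = [base_torsion, base_torsion + 180.0][:n_new]
            half = 180.0 - ideal_angle
            return [cone_direction(axis, rotate_about(perp, axis, 0.0),
                                   half, t) for t in torsions]
        torsions = [base_torsion + i * (360.0 / 3) for i in range(3)][:n_new] \
            if n_new <= 3 else [base_torsion + i * step for i in range(n_new)]
        return [cone_direction(axis, perp, half, t) for t in torsions]

    if k == 2:
        d1, d2 = unit(neighbor_dirs[0]), unit(neighbor_dirs[1])
        bis = -(d1 + d2)
        if np.linalg.norm(bis) < 1e-8:  # linear frame: sp centre, no room
            return [any_perpendicular(d1)][:n_new]
        bis = unit(bis)
        if n_new == 1 and ideal_angle > 115.0:
            return [bis]  # sp2 in-plane completion
        if n_new == 1:
            return [bis]  # sp3 with one lone pair kept implicit: bisector
        # two new directions, symmetric about the neighbour plane with the
        # exact ideal mutual angle
        normal = unit(np.cross(d1, d2))
        t = np.radians(ideal_angle / 2.0)
        return [unit(bis * np.cos(t) + normal * np.sin(t)),
                unit(bis * np.cos(t) - normal * np.sin(t))][:n_new]

    # k >= 3: single remaining vertex along the negated vector sum
    s = -np.sum([unit(d) for d in neighbor_dirs], axis=0)
    if np.linalg.norm(s) < 1e-8:
        s = np.cross(neighbor_dirs[0], neighbor_dirs[1])
        if np.linalg.norm(s) < 1e-8:
            s = any_perpendicular(neighbor_dirs[0])
    return [unit(s)][:n_new]


def _complete_tet_pair(d0: np.ndarray, d1: np.ndarray) -> list[np.ndarray]:
    """The two remaining exact-tetrahedral directions given two occupied."""
    bis = -(d0 + d1)
    bis = unit(bis)
    normal = unit(np.cross(d0, d1))
    t = np.radians(TET_ANGLE / 2.0)
    return [unit(bis * np.cos(t) + normal * np.sin(t)),
            unit(bis * np.cos(t) - normal * np.sin(t))]


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                 p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees (trans = +-180)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))
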