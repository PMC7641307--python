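"""Parametric four-way-junction conformers and geometric model discrimination.

A junction is modeled as four straight helical arms (X, B, H, R in cyclic
order, so X-H and B-R are opposite) radiating from a center.  A gold label
sits at the end of each arm at

    reach = center_gap/2 + bp_per_arm * rise + axial_offset + salt_shift

along the arm direction; stacked forms have no central gap.  The default
axial offset (10.2 A) is an effective value folding in the rotational
offset, calibrated so a continuous B-form helix of 22 bp with terminal
labels measures 93.0 A.  Model families — planar cross, square pyramid,
tetrahedron, free directions — predict the label-pair distances and can be
ranked by their RMSD against measured distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

ARM_ORDER = ("X", "B", "H", "R")
OPPOSITE_PAIRS = ({"X", "H"}, {"B", "R"})

#: default geometric constants (Angstrom)
DEFAULT_BP_PER_ARM = 11
DEFAULT_RISE = 3.3
DEFAULT_CENTER_GAP = 16.3
DEFAULT_AXIAL_OFFSET = 10.2
#: axial-offset increase at intermediate salt
SALT_OFFSET_SHIFT = 2.0


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=float).reshape(4, 3)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("arm directions must be non-zero")
    return v / norms


@dataclass
class JunctionGeometry:
    """Coarse junction conformer predicting gold positions per arm."""

    arm_directions: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0, 0], [0, 1.0, 0],
                                          [-1.0, 0, 0], [0, -1.0, 0]]))
    bp_per_arm: int = DEFAULT_BP_PER_ARM
    rise: float = DEFAULT_RISE
    center_gap: float = DEFAULT_CENTER_GAP
    axial_offset: float = DEFAULT_AXIAL_OFFSET
    salt_offset_shift: float = 0.0

    def __post_init__(self) -> None:
        self.arm_directions = _unit_rows(self.arm_directions)
        if self.bp_per_arm < 1:
            raise ValueError("bp_per_arm must be >= 1")
        if self.rise <= 0:
            raise ValueError("helical rise must be positive")

    @property
    def reach(self) -> float:
        """Distance from junction center to each gold label, Angstrom."""
        return (self.center_gap / 2.0 + self.bp_per_arm * self.rise
                + self.axial_offset + self.salt_offset_shift)

    def direction(self, arm: str) -> np.ndarray:
        try:
            return self.arm_directions[ARM_ORDER.index(arm)]
        except ValueError:
            raise KeyError(f"unknown arm {arm!r}; arms are {ARM_ORDER}") from None


def planar_cross(**kwargs) -> JunctionGeometry:
    """Square-planar open form: arms at 90 deg in a plane, 16.3 A gap."""
    return JunctionGeometry(**kwargs)


def square_pyramid(half_angle_deg: float = 70.0, **kwargs) -> JunctionGeometry:
    """Arms at a common polar angle from an apex axis, square azimuths.

    ``half_angle_deg`` = 90 recovers the planar cross.
    """
    t = np.radians(half_angle_deg)
    az = np.radians([0.0, 90.0, 180.0, 270.0])
    dirs = np.column_stack([np.sin(t) * np.cos(az), np.sin(t) * np.sin(az),
                            np.full(4, np.cos(t))])
    return JunctionGeometry(arm_directions=dirs, **kwargs)


def tetrahedral(**kwargs) -> JunctionGeometry:
    """Tetrahedral arm arrangement (all inter-arm angles arccos(-1/3))."""
    dirs = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
    return JunctionGeometry(arm_directions=dirs, **kwargs)


def stacked(**kwargs) -> JunctionGeometry:
    """Continuous-helix limit for one stacked pair: collinear arms, no gap."""
    kwargs.setdefault("center_gap", 0.0)
    dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    return JunctionGeometry(arm_directions=dirs, **kwargs)


def label_positions(geom: JunctionGeometry) -> dict[str, np.ndarray]:
    """Gold label coordinates per arm, each at ``reach`` along its direction."""
    return {arm: geom.reach * geom.direction(arm) for arm in ARM_ORDER}


def pair_distance(geom: JunctionGeometry, pair: str) -> float:
    """Euclidean gold-gold distance for a two-letter arm pair (e.g. 'BR')."""
    if len(pair) != 2 or pair[0] == pair[1]:
        raise KeyError(f"pair must name two distinct arms, got {pair!r}")
    pos = label_positions(geom)
    return float(np.linalg.norm(pos[pair[0]] - pos[pair[1]]))


def all_pair_distances(geom: JunctionGeometry) -> dict[str, float]:
    """Predicted distances for all six label pairs."""
    return {a + b: pair_distance(geom, a + b)
            for a, b in combinations(ARM_ORDER, 2)}


def stacked_helix_distance(geom: JunctionGeometry | None = None) -> float:
    """End-to-end label distance of a continuous stacked helix.

    Two collinear arms with no central gap: 2*bp*rise + 2*axial_offset
    (= 93.0 A with the defaults, the continuous B-form prediction).
    """
    g = stacked() if geom is None else geom
    return 2.0 * g.bp_per_arm * g.rise + 2.0 * (g.axial_offset + g.salt_offset_shift)


def ida_from_short_distance(d_short: float,
                            geom: JunctionGeometry | None = None) -> float:
    """Inter-duplex angle (deg) from the short label-pair distance.

    For a stacked X-form the two short-pair labels sit at L' = bp*rise +
    axial_offset from the junction point, so d = 2 L' sin(IDA/2); this
    inverts that relation.  Raises for distances outside (0, 2 L'].
    """
    g = stacked() if geom is None else geom
    arm = g.bp_per_arm * g.rise + g.axial_offset + g.salt_offset_shift
    ratio = d_short / (2.0 * arm)
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"distance {d_short} outside the invertible range "
                         f"(0, {2 * arm:.1f}]")
    return float(np.degrees(2.0 * np.arcsin(ratio)))


@dataclass
class GeometryFit:
    """Best-fit geometry for one model family with its distance RMSD."""

    family: str
    geometry: JunctionGeometry
    rmsd: float                       # Angstrom
    predicted: dict[str, float]
    params: dict = field(default_factory=dict)
    overparameterized: bool = False


def _rmsd(geom: JunctionGeometry, measured: Mapping[str, float]) -> float:
    pred = label_positions(geom)
    sq = [(np.linalg.norm(pred[p[0]] - pred[p[1]]) - dist) ** 2
          for p, dist in measured.items()]
    return float(np.sqrt(np.mean(sq)))


def _normalize_measured(measured: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for pair, dist in measured.items():
        if len(pair) != 2 or any(a not in ARM_ORDER for a in pair):
            raise KeyError(f"unknown label pair {pair!r}")
        key = pair if ARM_ORDER.index(pair[0]) < ARM_ORDER.index(pair[1]) \
            else pair[::-1]
        out[key] = float(dist)
    return out


def fit_arm_directions(measured: Mapping[str, float],
                       geom: JunctionGeometry | None = None,
                       model_family: str = "free",
                       seed: int = 0) -> GeometryFit:
    """Least-squares fit of a model family to measured pair distances.

    Families: ``planar`` (no free parameters), ``pyramid`` (apex
    half-angle), ``tetrahedral`` (no free parameters), ``free`` (four unit
    vectors up to a global rotation; multi-start Nelder-Mead with fixed
    seeds).  Arm lengths are fixed by the geometry constants.  A free-family
    fit against fewer than three distances is flagged over-parameterized.
    """
    measured = _normalize_measured(measured)
    if len(measured) < 2:
        raise ValueError("need at least two measured pair distances")
    base = geom or JunctionGeometry()
    kwargs = dict(bp_per_arm=base.bp_per_arm, rise=base.rise,
                  center_gap=base.center_gap, axial_offset=base.axial_offset,
                  salt_offset_shift=base.salt_offset_shift)

    if model_family == "planar":
        g = planar_cross(**kwargs)
        return GeometryFit("planar", g, _rmsd(g, measured),
                           {p: pair_distance(g, p) for p in measured})

    if model_family == "tetrahedral":
        g = tetrahedral(**kwargs)
        return GeometryFit("tetrahedral", g, _rmsd(g, measured),
                           {p: pair_distance(g, p) for p in measured})

    if model_family == "pyramid":
        def loss(theta: float) -> float:
            return _rmsd(square_pyramid(theta, **kwargs), measured)
        grid = np.linspace(1.0, 179.0, 179)
        best = grid[int(np.argmin([loss(t) for t in grid]))]
        res = optimize.minimize_scalar(
            loss, bounds=(max(best - 2.0, 0.5), min(best + 2.0, 179.5)),
            method="bounded", options={"xatol": 1e-8})
        theta = float(res.x) if res.fun <= loss(best) else float(best)
        g = square_pyramid(theta, **kwargs)
        return GeometryFit("pyramid", g, _rmsd(g, measured),
                           {p: pair_distance(g, p) for p in measured},
                           params={"half_angle_deg": theta})

    if model_family == "free":
        def angles_to_dirs(x: np.ndarray) -> np.ndarray:
            th, ph = x[:4], x[4:]
            return np.column_stack([np.sin(th) * np.cos(ph),
                                    np.sin(th) * np.sin(ph), np.cos(th)])

        def loss_vec(x: np.ndarray) -> float:
            return _rmsd(replace(base, arm_directions=angles_to_dirs(x)), measured)

        def dirs_to_angles(dirs: np.ndarray) -> np.ndarray:
            th = np.arccos(np.clip(dirs[:, 2], -1, 1))
            ph = np.arctan2(dirs[:, 1], dirs[:, 0])
            return np.concatenate([th, ph])

        rng = np.random.default_rng(seed)
        starts = [dirs_to_angles(planar_cross(**kwargs).arm_directions),
                  dirs_to_angles(tetrahedral(**kwargs).arm_directions),
                  dirs_to_angles(square_pyramid(70.0, **kwargs).arm_directions)]
        pyr = fit_arm_directions(measured, base, "pyramid")
        starts.append(dirs_to_angles(pyr.geometry.arm_directions))
        starts += [rng.uniform([0] * 4 + [-np.pi] * 4,
                               [np.pi] * 4 + [np.pi] * 4) for _ in range(3)]
        best_x, best_f = None, np.inf
        for x0 in starts:
            res = optimize.minimize(loss_vec, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-10,
                                             "maxiter": 4000})
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
        g = replace(base, arm_directions=angles_to_dirs(best_x))
        return GeometryFit("free", g, _rmsd(g, measured),
                           {p: pair_distance(g, p) for p in measured},
                           overparameterized=len(measured) < 3)

    raise ValueError(f"unknown model family {model_family!r}")


def compare_families(measured: Mapping[str, float],
                     geom: JunctionGeometry | None = None,
                     families: tuple[str, ...] = ("planar", "pyramid",
                                                  "tetrahedral", "free"),
                     seed: int = 0) -> pd.DataFrame:
    """Per-family RMSD table for a set of measured distances."""
    rows = []
    for fam in families:
        fit = fit_arm_directions(measured, geom, fam, seed=seed)
        rows.append({"family": fam, "rmsd_A": fit.rmsd,
                     "overparameterized": fit.overparameterized,
                     **{f"pred_{p}": v for p, v in fit.predicted.items()}})
    return pd.DataFrame(rows)
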