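"""Forward scattering model: sphere form factors, interference basis, Debye sums.

Scattering interferometry reads the distance between two heavy labels off
the oscillation period of their interference cross-term.  For two gold
nanocrystals of radius R separated by d, the orientationally averaged
cross-term is ``F(q,R)^2 * sinc(q d)``, where F is the hard-sphere form
amplitude.  The full intensity of a labeled construct follows the Debye
formula over all pairs of scatterers (DNA beads and gold labels), which is
what the synthetic-data generator simulates so the extraction arithmetic
can be tested term by term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScatteringProfile

#: gold nanocrystal radius in Angstrom
GOLD_RADIUS = 7.0
#: scattering weight of a gold label relative to one DNA base-pair bead
GOLD_DNA_CONTRAST = 25.0


def default_q_grid(n: int = 256, q_min: float = 0.01, q_max: float = 0.35) -> np.ndarray:
    """Linear momentum-transfer grid in 1/Angstrom (default 0.01-0.35, 256 pts)."""
    return np.linspace(q_min, q_max, n)


def default_d_grid(d_min: float = 5.0, d_max: float = 150.0, step: float = 1.0) -> np.ndarray:
    """Uniform distance grid in Angstrom spanning all plausible label separations."""
    return np.arange(d_min, d_max + 0.5 * step, step)


def sinc(x: np.ndarray | float) -> np.ndarray:
    """sin(x)/x with the continuous limit 1 at x = 0 (unnormalized sinc)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def sphere_form_amplitude(q: np.ndarray | float, radius: float = GOLD_RADIUS) -> np.ndarray:
    """Hard-sphere form amplitude F(q) = 3[sin(qR) - qR cos(qR)]/(qR)^3.

    F(0) = 1 by continuous extension (a 5th-order series is used below
    x = 1e-3 to avoid cancellation).
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    x = q * radius
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the masked branch
    exact = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    series = 1.0 - x**2 / 10.0 + x**4 / 280.0
    return np.where(small, series, exact)


def interference_basis(q_grid: np.ndarray, d: float,
                       radius: float = GOLD_RADIUS) -> np.ndarray:
    """Gold-gold interference basis curve B(q, d) = F(q,R)^2 * sinc(q d).

    At d = 0 this reduces to F^2; zeros fall at q d = k*pi.  The overall
    amplitude (gold intensity units) is left to the inversion's free scale.
    """
    if d < 0:
        raise ValueError("label separation d must be non-negative")
    q = np.asarray(q_grid, dtype=float)
    return sphere_form_amplitude(q, radius) ** 2 * sinc(q * d)


@dataclass
class BasisMatrix:
    """Matrix of interference basis curves, one row per candidate distance."""

    d_grid: np.ndarray
    q_grid: np.ndarray
    values: np.ndarray  # shape (len(d_grid), len(q_grid))

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.d_grid.size, self.q_grid.size):
            raise ValueError("basis matrix shape must be (|d_grid|, |q_grid|)")


def build_basis_matrix(q_grid: np.ndarray, d_grid: np.ndarray,
                       radius: float = GOLD_RADIUS) -> BasisMatrix:
    """Stack :func:`interference_basis` rows for every distance in ``d_grid``."""
    q = np.asarray(q_grid, dtype=float)
    d = np.asarray(d_grid, dtype=float)
    if q.size == 0 or d.size == 0:
        raise ValueError("q and d grids must be non-empty")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    f2 = sphere_form_amplitude(q, radius) ** 2
    values = f2[None, :] * sinc(d[:, None] * q[None, :])
    return BasisMatrix(d_grid=d, q_grid=q, values=values)


@dataclass
class BeadModel:
    """Coarse-grained scatterer set: one bead per base pair plus 0-2 gold labels.

    DNA beads are point scatterers; gold beads additionally carry the sphere
    form amplitude of radius ``gold_radius``.
    """

    coords: np.ndarray          # (N, 3) Angstrom
    weights: np.ndarray         # (N,) scattering weights
    gold: np.ndarray            # (N,) bool, True for gold labels
    gold_radius: float = GOLD_RADIUS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        self.gold = np.asarray(self.gold, dtype=bool)
        n = self.coords.shape[0]
        if n == 0:
            raise ValueError("bead model needs at least one bead")
        if self.weights.shape != (n,) or self.gold.shape != (n,):
            raise ValueError("weights and gold flags must match the bead count")
        if not np.all(np.isfinite(self.coords)) or not np.all(np.isfinite(self.weights)):
            raise ValueError("bead model contains non-finite values")
        if int(self.gold.sum()) not in (0, 1, 2):
            raise ValueError("a construct carries 0, 1 or 2 gold labels")


def debye_intensity(model: BeadModel, q_grid: np.ndarray) -> ScatteringProfile:
    """Orientationally averaged intensity by the Debye double sum.

    I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij), where f is the bead weight
    times the sphere form amplitude for gold beads.  The i = j term is
    f_i^2 (sinc -> 1); the result is rotation- and translation-invariant.
    The returned profile carries a tiny positive placeholder sigma (the
    simulation itself is noise-free).
    """
    q = np.asarray(q_grid, dtype=float)
    diff = model.coords[:, None, :] - model.coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))          # (N, N)
    f = np.where(model.gold[None, :],
                 sphere_form_amplitude(q, model.gold_radius)[:, None], 1.0)
    f = f * model.weights[None, :]                     # (Nq, N)
    s = sinc(q[:, None, None] * r[None, :, :])         # (Nq, N, N)
    intensity = np.einsum("qi,qij,qj->q", f, s, f)
    sigma = np.full_like(intensity, max(1e-12, 1e-12 * abs(float(intensity[0]))))
    return ScatteringProfile(q, intensity, sigma, label="derived")
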