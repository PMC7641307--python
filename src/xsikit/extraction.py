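"""Reduction of a six-profile bundle to the gold-gold interference pattern.

The intensity of the doubly labeled construct contains the molecule term,
both gold self terms, both molecule-gold cross terms, and the gold-gold
interference term.  The weighted combination AB + U - A - B cancels every
term except the gold-gold interference whenever the four constructs share
one conformer ensemble; this module performs that arithmetic with full
uncertainty propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ProfileBundle, ScatteringProfile, ValidationError


@dataclass
class InterferencePattern:
    """Gold-gold interference curve I_AuAu(q); oscillates about zero."""

    q: np.ndarray
    values: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.values.shape == self.sigma.shape):
            raise ValidationError("q, values and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValidationError("all sigma values must be positive")

    def to_profile(self) -> ScatteringProfile:
        return ScatteringProfile(self.q, self.values, self.sigma, label="derived")


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=1e-9, atol=0.0):
        raise ValidationError(f"q-grid mismatch in {what}")


def subtract_buffer(sample: ScatteringProfile, buffer: ScatteringProfile,
                    scale: float = 1.0) -> ScatteringProfile:
    """Subtract ``scale`` times the buffer profile, propagating sigma in quadrature."""
    _check_grid(sample.q, buffer.q, "buffer subtraction")
    intensity = sample.intensity - scale * buffer.intensity
    sigma = np.sqrt(sample.sigma**2 + scale**2 * buffer.sigma**2)
    return ScatteringProfile(sample.q, intensity, sigma, label="derived")


def extract_interference(ab: ScatteringProfile, a: ScatteringProfile,
                         b: ScatteringProfile, u: ScatteringProfile,
                         weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
                         ) -> InterferencePattern:
    """I_AuAu = w1*AB + w2*U - w3*A - w4*B on buffer-subtracted profiles.

    Unit weights assume equal molar concentrations; sigma is the quadrature
    sum.  The free-gold (Au) profile is not part of the arithmetic (it is
    reserved for form-factor calibration).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be four finite scale factors")
    for other, what in ((a, "A"), (b, "B"), (u, "U")):
        _check_grid(ab.q, other.q, f"interference extraction ({what})")
    values = (w[0] * ab.intensity + w[1] * u.intensity
              - w[2] * a.intensity - w[3] * b.intensity)
    sigma = np.sqrt((w[0] * ab.sigma) ** 2 + (w[1] * u.sigma) ** 2
                    + (w[2] * a.sigma) ** 2 + (w[3] * b.sigma) ** 2)
    return InterferencePattern(ab.q, values, sigma)


def fit_single_label_weights(ab: ScatteringProfile, a: ScatteringProfile,
                             b: ScatteringProfile, u: ScatteringProfile,
                             q_min: float = 0.25) -> tuple[float, float]:
    """Least-squares rescaling of the singly labeled profiles on high q.

    Beyond ``q_min`` the interference term has decayed, so AB + U should
    equal A + B there; fitting (w3, w4) absorbs concentration errors in
    real data.  Returns the fitted weights for :func:`extract_interference`.
    """
    mask = ab.q >= q_min
    if mask.sum() < 2:
        raise ValidationError(f"no q points beyond {q_min} for weight fitting")
    target = (ab.intensity + u.intensity)[mask]
    design = np.column_stack([a.intensity[mask], b.intensity[mask]])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(coef[0]), float(coef[1])


def extract_bundle(bundle: ProfileBundle, buffer_scale: float = 1.0,
                   weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
                   rescale_high_q: bool = False, q_min: float = 0.25,
                   ) -> InterferencePattern:
    """Buffer-subtract AB, A, B, U and extract the interference pattern."""
    buf = bundle["Buf"]
    sub = {role: subtract_buffer(bundle[role], buf, scale=buffer_scale)
           for role in ("AB", "A", "B", "U")}
    if rescale_high_q:
        w3, w4 = fit_single_label_weights(sub["AB"], sub["A"], sub["B"], sub["U"],
                                          q_min=q_min)
        weights = (weights[0], weights[1], weights[2] * w3, weights[3] * w4)
    return extract_interference(sub["AB"], sub["A"], sub["B"], sub["U"], weights=weights)
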