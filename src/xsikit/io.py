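"""Reading and writing of scattering profiles, condition bundles and distance distributions.

The on-disk profile format is the common beamline ASCII ``.dat`` dialect:
whitespace-separated columns ``q  I(q)  sigma``, with ``#`` comment lines.
Columns beyond the third are ignored.  Distance distributions are two-column
CSV files whose ``#`` header records the grid step and fit diagnostics.
Loaders never modify numeric content; writers use ``%.17g`` so that a
write/read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger("xsikit")

#: the six roles of a complete XSI measurement set: doubly labeled, the two
#: singly labeled constructs, unlabeled macromolecule, free gold, and buffer.
ROLES = ("AB", "A", "B", "U", "Au", "Buf")

_VALID_LABELS = set(ROLES) | {"derived"}


class ProfileError(ValueError):
    """Base class for profile I/O and validation failures."""


class ParseError(ProfileError):
    """A data file could not be parsed; the message names the line."""


class ValidationError(ProfileError):
    """Numeric content violates a profile invariant."""


@dataclass
class ScatteringProfile:
    """A measured or simulated scattering curve I(q) with uncertainties.

    Attributes
    ----------
    q : ndarray
        Momentum transfer grid in 1/Angstrom, strictly increasing, > 0.
    intensity : ndarray
        Scattering intensity in arbitrary units (may be negative for
        derived interference curves).
    sigma : ndarray
        Per-point 1-sigma uncertainty, same units as intensity, all > 0.
    label : str
        Role tag: one of AB|A|B|U|Au|Buf for measured curves, "derived"
        for computed ones.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = "derived"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1:
            raise ValidationError("q grid must be one-dimensional")
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValidationError("q, intensity and sigma must have equal length")
        if self.q.size == 0:
            raise ValidationError("empty profile")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)) \
                or not np.all(np.isfinite(self.sigma)):
            raise ValidationError("profile contains non-finite values")
        if np.any(self.q <= 0):
            raise ValidationError("all q values must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q grid must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValidationError("all sigma values must be positive")
        if self.label not in _VALID_LABELS:
            raise ValidationError(f"unknown profile label {self.label!r}")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class ProfileBundle:
    """The six-profile set (AB, A, B, U, Au, Buf) for one label pair and salt.

    All six profiles share a single q grid; ``condition`` carries free-form
    metadata such as the salt description and the label-pair name.
    """

    profiles: dict[str, ScatteringProfile]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.profiles]
        if missing:
            raise ValidationError(f"bundle is missing role(s): {', '.join(missing)}")
        extra = [r for r in self.profiles if r not in ROLES]
        if extra:
            raise ValidationError(f"bundle has unknown role(s): {', '.join(extra)}")
        q0 = self.profiles[ROLES[0]].q
        for role in ROLES[1:]:
            q = self.profiles[role].q
            if q.shape != q0.shape or not np.allclose(q, q0, rtol=1e-9, atol=0.0):
                raise ValidationError(f"q grid of role {role!r} does not match role 'AB'")

    @property
    def q(self) -> np.ndarray:
        return self.profiles["AB"].q

    def __getitem__(self, role: str) -> ScatteringProfile:
        return self.profiles[role]


def read_profile(path: str | Path, label: str = "derived") -> ScatteringProfile:
    """Read a whitespace-separated ``q I sigma`` file into a profile.

    Lines starting with ``#`` (and blank lines) are skipped; rows containing
    non-finite numbers are rejected with their count logged.  A malformed
    line raises :class:`ParseError` naming the line number.
    """
    path = Path(path)
    q, intensity, sigma = [], [], []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                row = [float(parts[0]), float(parts[1]), float(parts[2])]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if not all(np.isfinite(row)):
                n_dropped += 1
                continue
            q.append(row[0])
            intensity.append(row[1])
            sigma.append(row[2])
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
    if not q:
        raise ParseError(f"{path}: no data rows")
    return ScatteringProfile(np.array(q), np.array(intensity), np.array(sigma), label=label)


def write_profile(profile: ScatteringProfile, path: str | Path,
                  header: Iterable[str] = ()) -> None:
    """Write a profile as ``q I sigma`` with optional ``#`` header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# role: {profile.label}\n")
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# columns: q(1/A) intensity(a.u.) sigma(a.u.)\n")
        for qi, ii, si in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{qi:.17g} {ii:.17g} {si:.17g}\n")


def load_bundle(manifest: Mapping[str, str | Path],
                condition: Mapping | None = None) -> ProfileBundle:
    """Assemble a :class:`ProfileBundle` from a role -> file-path mapping.

    All six roles must be present and all files must share one q grid
    (equal within 1e-9 relative); mismatches raise, nothing is silently
    interpolated.
    """
    missing = [r for r in ROLES if r not in manifest]
    if missing:
        raise ValidationError(f"manifest is missing role(s): {', '.join(missing)}")
    profiles = {role: read_profile(manifest[role], label=role) for role in ROLES}
    return ProfileBundle(profiles, condition=dict(condition or {}))


def write_bundle(bundle: ProfileBundle, outdir: str | Path,
                 header: Iterable[str] = ()) -> Path:
    """Write the six profiles plus a ``manifest.yaml`` into ``outdir``.

    Returns the manifest path.  The directory is created if needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"condition": dict(bundle.condition), "roles": {}}
    for role in ROLES:
        fname = f"{role}.dat"
        write_profile(bundle.profiles[role], outdir / fname, header=header)
        manifest["roles"][role] = fname
    mpath = outdir / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_bundle_dir(path: str | Path) -> ProfileBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    path = Path(path)
    mpath = path / "manifest.yaml" if path.is_dir() else path
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    base = mpath.parent
    roles = {role: base / fname for role, fname in manifest["roles"].items()}
    return load_bundle(roles, condition=manifest.get("condition") or {})


def write_distribution(dist, path: str | Path, header: Iterable[str] = ()) -> None:
    """Write a distance distribution as two-column CSV (distance_A, probability).

    The ``#`` header records the grid step and the fit diagnostics so a run
    is auditable from its artifacts alone.  Round-trips exactly via
    :func:`read_distribution`.
    """
    path = Path(path)
    step = float(dist.d[1] - dist.d[0]) if dist.d.size > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(f"# grid_step_A: {step:.17g}\n")
        fh.write(f"# amplitude: {dist.amplitude:.17g}\n")
        fh.write(f"# chi2_per_point: {dist.chi2_per_point:.17g}\n")
        fh.write(f"# entropy: {dist.entropy:.17g}\n")
        fh.write(f"# iterations: {dist.iterations}\n")
        fh.write(f"# infeasible: {dist.infeasible}\n")
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("distance_A,probability\n")
        for di, wi in zip(dist.d, dist.weights):
            fh.write(f"{di:.17g},{wi:.17g}\n")


def read_distribution(path: str | Path):
    """Read a distribution CSV written by :func:`write_distribution`."""
    from .maxent import DistanceDistribution

    meta: dict[str, str] = {}
    d, w = [], []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if ":" in stripped:
                    key, _, val = stripped.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if stripped.startswith("distance"):
                continue
            a, _, b = stripped.partition(",")
            d.append(float(a))
            w.append(float(b))
    return DistanceDistribution(
        d=np.array(d),
        weights=np.array(w),
        amplitude=float(meta.get("amplitude", "nan")),
        chi2_per_point=float(meta.get("chi2_per_point", "nan")),
        entropy=float(meta.get("entropy", "nan")),
        iterations=int(meta.get("iterations", "0")),
        infeasible=meta.get("infeasible", "False") == "True",
    )
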