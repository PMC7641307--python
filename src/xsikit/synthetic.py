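"""Synthetic XSI bundles and smFRET traces from named scenario presets.

A scenario describes one salt condition for one label pair as a mixture of
conformational states, each with a mean gold-gold distance and a weight.
The generator samples conformers per state (Gaussian axial breathing of
the label separation), builds bead models for all four constructs from the
*same* conformer set (so the molecule and cross terms cancel exactly in the
downstream extraction), averages their Debye intensities, adds a flat
buffer baseline and exposure-averaged counting-like noise.

The shipped presets encode the reported salt-dependent ensembles of a
four-way (Holliday) junction: two stacked conformers (isoII favored 84:16)
at high divalent salt, an isoII-like stacked state plus a displaced minor
state at intermediate salt, and single open states above 80 A at low salt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .forward import GOLD_DNA_CONTRAST, BeadModel, debye_intensity, default_q_grid
from .fret import FretTrace, StateModel
from .io import ProfileBundle, ScatteringProfile

#: base pairs per junction arm (four 22-mers -> four 11-bp arms)
BP_PER_ARM = 11
#: helical rise per base pair, Angstrom
RISE = 3.3


@dataclass(frozen=True)
class ScenarioState:
    """One mixture component: mean label-pair distance (A) and weight."""

    distance: float
    weight: float


@dataclass
class Scenario:
    """Recipe for one synthetic XSI condition bundle.

    Defaults follow the measurement protocol being emulated: 10 exposures
    per sample, 1% relative noise anchored at the lowest q, 5 A distance
    jitter, 200 sampled conformers per state.
    """

    label_pair: str                      # BH | HR | BR | RX
    states: tuple[ScenarioState, ...]
    jitter: float = 5.0                  # per-state distance sd, Angstrom
    noise: float = 0.01                  # relative noise at the low-q anchor
    exposures: int = 10
    n_conformers: int = 200
    buffer_level: float = 50.0           # flat solvent baseline, a.u.
    salt: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.label_pair not in ("BH", "HR", "BR", "RX"):
            raise ValueError(f"unknown label pair {self.label_pair!r}")
        if len(self.states) == 0:
            raise ValueError("scenario needs at least one state")
        w = np.array([s.weight for s in self.states], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("state weights must be >= 0 and sum to 1")
        if any(s.distance <= 0 for s in self.states):
            raise ValueError("state distances must be positive")
        if self.jitter < 0:
            raise ValueError("distance jitter must be non-negative")
        if self.noise < 0:
            raise ValueError("noise level must be non-negative")
        if self.exposures < 1 or self.n_conformers < 1:
            raise ValueError("exposures and n_conformers must be >= 1")


#: reported peak positions (A) and major/minor split per condition and pair.
#: high_Mg_BR peak positions are not printed in the source study (the two
#: peaks overlap); 70/75 A is a stand-in preserving that overlap.
SCENARIO_PRESETS: dict[str, Scenario] = {
    "high_Mg_BH": Scenario("BH", (ScenarioState(54.0, 0.84), ScenarioState(89.0, 0.16)),
                           salt="10 mM MgCl2, 30 mM Tris-HCl pH 7.4"),
    "high_Mg_HR": Scenario("HR", (ScenarioState(89.0, 0.84), ScenarioState(57.0, 0.16)),
                           salt="10 mM MgCl2, 30 mM Tris-HCl pH 7.4"),
    "high_Mg_BR": Scenario("BR", (ScenarioState(70.0, 0.84), ScenarioState(75.0, 0.16)),
                           salt="10 mM MgCl2, 30 mM Tris-HCl pH 7.4"),
    "intermediate_Mg_BH": Scenario("BH", (ScenarioState(61.0, 0.84), ScenarioState(84.0, 0.16)),
                                   salt="150 uM MgCl2, 30 mM Tris-HCl pH 7.4"),
    "low_salt_BR": Scenario("BR", (ScenarioState(93.0, 1.0),),
                            salt="30 mM Tris-HCl pH 7.4"),
    "low_salt_HR": Scenario("HR", (ScenarioState(90.0, 1.0),),
                            salt="30 mM Tris-HCl pH 7.4"),
    "low_salt_RX": Scenario("RX", (ScenarioState(87.0, 1.0),),
                            salt="30 mM Tris-HCl pH 7.4"),
}


def get_scenario(name: str) -> Scenario:
    """Return a copy of a named scenario preset."""
    try:
        preset = SCENARIO_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown scenario preset {name!r}; "
                       f"available: {', '.join(sorted(SCENARIO_PRESETS))}") from None
    return replace(preset, states=tuple(preset.states))


def _conformer_beads(d: float, n_bp: int = 2 * BP_PER_ARM,
                     rise: float = RISE) -> tuple[np.ndarray, np.ndarray]:
    """DNA bead coordinates (one per bp on the helix axis) and gold positions.

    The two arms carrying the labels are laid out along one axis with the
    golds placed symmetrically so their separation is exactly ``d``; radial
    helical detail is below interferometry resolution.
    """
    z = (np.arange(n_bp) - (n_bp - 1) / 2.0) * rise
    dna = np.column_stack([np.zeros(n_bp), np.zeros(n_bp), z])
    golds = np.array([[0.0, 0.0, d / 2.0], [0.0, 0.0, -d / 2.0]])
    return dna, golds


def _construct_intensity(dna: np.ndarray, golds: np.ndarray, which: str,
                         q: np.ndarray) -> np.ndarray:
    """Debye intensity of one construct: 'AB', 'A', 'B' or 'U'."""
    picks = {"AB": [0, 1], "A": [0], "B": [1], "U": []}[which]
    coords = np.vstack([dna] + [golds[i][None, :] for i in picks]) if picks else dna
    n_dna = dna.shape[0]
    weights = np.concatenate([np.ones(n_dna), np.full(len(picks), GOLD_DNA_CONTRAST)])
    gold = np.concatenate([np.zeros(n_dna, dtype=bool), np.ones(len(picks), dtype=bool)])
    return debye_intensity(BeadModel(coords, weights, gold), q).intensity


def generate_xsi_bundle(scenario: Scenario, q_grid: np.ndarray | None = None,
                        seed: int | None = None) -> ProfileBundle:
    """Simulate the six-profile bundle (AB, A, B, U, Au, Buf) for a scenario.

    Per state, ``n_conformers`` label separations are drawn around the state
    distance (sd = ``jitter``); the same conformer set parameterizes the
    doubly-, singly- and un-labeled constructs so that AB + U - A - B leaves
    only the gold-gold interference term.  Gaussian noise with
    sigma(q) = noise * sqrt(I(q) * I(q0)) is added per exposure and the
    exposures averaged; the recorded sigma is the standard error of that
    mean.  Deterministic for a given seed.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)

    ideal = {role: np.zeros_like(q) for role in ("AB", "A", "B", "U")}
    for state in scenario.states:
        d_samples = rng.normal(state.distance, scenario.jitter, scenario.n_conformers)
        d_samples = np.clip(d_samples, 1.0, None)
        per_state = {role: np.zeros_like(q) for role in ideal}
        for d in d_samples:
            dna, golds = _conformer_beads(float(d))
            for role in per_state:
                per_state[role] += _construct_intensity(dna, golds, role, q)
        for role in ideal:
            ideal[role] += state.weight * per_state[role] / scenario.n_conformers

    # free gold: two uncorrelated spheres (separation far beyond coherence)
    au_coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0e4]])
    au_model = BeadModel(au_coords, np.full(2, GOLD_DNA_CONTRAST),
                         np.ones(2, dtype=bool))
    ideal["Au"] = debye_intensity(au_model, q).intensity
    ideal["Buf"] = np.zeros_like(q)

    baseline = scenario.buffer_level
    profiles: dict[str, ScatteringProfile] = {}
    for role in ("AB", "A", "B", "U", "Au", "Buf"):
        clean = ideal[role] + baseline
        anchor = abs(float(clean[0]))
        sig_exp = scenario.noise * np.sqrt(np.abs(clean) * max(anchor, 1e-30))
        if scenario.noise > 0:
            draws = rng.normal(0.0, 1.0, (scenario.exposures, q.size)) * sig_exp[None, :]
            observed = clean + draws.mean(axis=0)
        else:
            observed = clean.copy()
        sigma = sig_exp / math.sqrt(scenario.exposures)
        sigma = np.maximum(sigma, 1e-12 * max(anchor, 1.0))
        profiles[role] = ScatteringProfile(q, observed, sigma, label=role)

    condition = {"label_pair": scenario.label_pair, "salt": scenario.salt,
                 "seed": scenario.seed if seed is None else seed}
    return ProfileBundle(profiles, condition=condition)


def generate_fret_trace(model: StateModel, duration: float, fps: float = 306.0,
                        total_intensity: float = 1000.0, noise_sd: float = 80.0,
                        seed: int | None = None) -> FretTrace:
    """Simulate a two-state telegraph FRET trace at a fixed frame rate.

    A continuous-time path with exponential dwells at the model's rates is
    integrated over each frame, so transition frames carry fractional
    occupancy.  Donor/acceptor intensities share a fixed total and receive
    independent Gaussian noise per channel (clipped at zero to keep
    intensities physical).  The latent majority-state path is returned with
    the trace.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    k_out = {0: model.k_i_to_ii, 1: model.k_ii_to_i}   # 0 = isoI (low E), 1 = isoII
    p_ii = model.k_i_to_ii / (model.k_i_to_ii + model.k_ii_to_i)
    state = 1 if rng.random() < p_ii else 0

    bounds = [0.0]
    seg_states = []
    t = 0.0
    while t < duration:
        dwell = rng.exponential(1.0 / k_out[state])
        t = min(t + dwell, duration)
        seg_states.append(state)
        bounds.append(t)
        state = 1 - state
    bounds_arr = np.array(bounds)
    # cumulative isoII occupancy time at segment boundaries
    seg_dur = np.diff(bounds_arr)
    cum_ii = np.concatenate([[0.0], np.cumsum(seg_dur * np.array(seg_states))])

    n_frames = int(round(duration * fps))
    edges = np.arange(n_frames + 1) / fps
    occ_ii = np.diff(np.interp(edges, bounds_arr, cum_ii)) * fps
    efficiency = model.e_low + occ_ii * (model.e_high - model.e_low)

    acceptor = total_intensity * efficiency
    donor = total_intensity * (1.0 - efficiency)
    if noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, noise_sd, n_frames)
        donor = donor + rng.normal(0.0, noise_sd, n_frames)
    acceptor = np.clip(acceptor, 0.0, None)
    donor = np.clip(donor, 0.0, None)

    times = (np.arange(n_frames) + 0.5) / fps
    true_states = (occ_ii > 0.5).astype(int)
    return FretTrace(times=times, donor=donor, acceptor=acceptor, fps=fps,
                     true_states=true_states, true_occupancy=occ_ii)
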