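"""Synthetic data generators.

Everything downstream of this module is testable without an instrument:
1:1 and biphasic sensorgram plates from known ground-truth kinetics,
sequential two-ligand competition traces with a tunable epitope-overlap
fraction, and sequences with planted complementary-hydropathy motifs.

Deterministic signals are computed from the closed-form 1:1 Langmuir
solutions; Gaussian noise and linear baseline drift are added afterwards,
so noiseless traces satisfy the closed form exactly.  Identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .bli import (
    ROLE_REFERENCE_BUFFER,
    ROLE_REFERENCE_PIN,
    ROLE_SAMPLE,
    Plate,
    Sensorgram,
    Step,
)
from .errors import DesignError
from .hydropathy import KYTE_DOOLITTLE, hydropathy_map


@dataclass(frozen=True)
class KineticParams:
    """1:1 Langmuir kinetic parameters.

    k_on in M⁻¹s⁻¹ (> 0), k_off in s⁻¹ (≥ 0), r_max in nm (> 0).
    """

    k_on: float
    k_off: float
    r_max: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "r_max"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.k_on > 0):
            raise DesignError(f"k_on must be > 0, got {self.k_on}")
        if not (self.k_off >= 0):
            raise DesignError(f"k_off must be >= 0, got {self.k_off}")
        if not (self.r_max > 0):
            raise DesignError(f"r_max must be > 0, got {self.r_max}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant k_off / k_on (M)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class AssayDesign:
    """Concentration series and acquisition settings for one plate."""

    concentrations: tuple[float, ...]  # M, strictly positive, ascending
    t_assoc: float  # s
    t_dissoc: float  # s
    sample_rate: float = 5.0  # points per second
    noise_sd: float = 0.0  # nm
    drift_rate: float = 0.0  # nm/s, common to all channels
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        if not self.concentrations:
            raise DesignError("concentration series is empty")
        if any(c <= 0 for c in self.concentrations):
            raise DesignError("concentrations must be strictly positive")
        if list(self.concentrations) != sorted(set(self.concentrations)):
            raise DesignError("concentrations must be ascending and unique")
        if not (self.t_assoc > 0 and self.t_dissoc > 0):
            raise DesignError("step durations must be > 0")
        if not (self.sample_rate > 0):
            raise DesignError("sample_rate must be > 0")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")


def _grid(duration: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    return np.linspace(0.0, duration, n + 1)


def response_1to1(
    params: KineticParams, concentration: float, t_assoc: np.ndarray, t_dissoc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless 1:1 association/dissociation responses on the given grids.

    Association: R(t) = R_eq · (1 − exp(−(k_on·C + k_off)·t)) with
    R_eq = R_max·C/(C + K_D); dissociation: exponential decay at k_off from
    the end-of-association response.
    """
    if concentration < 0:
        raise DesignError("concentration must be >= 0")
    k_obs = params.k_on * concentration + params.k_off
    if concentration == 0:
        r_eq = 0.0
    else:
        r_eq = params.r_max * concentration / (concentration + params.kd)
    assoc = r_eq * -np.expm1(-k_obs * t_assoc)
    r_end = r_eq * -np.expm1(-k_obs * t_assoc[-1]) if t_assoc.size else 0.0
    dissoc = r_end * np.exp(-params.k_off * t_dissoc)
    return assoc, dissoc


def _assemble_sensorgram(
    sensor_id: str,
    assoc: np.ndarray,
    dissoc: np.ndarray,
    design: AssayDesign,
    rng: np.random.Generator,
    analyte: str,
    concentration: float,
    role: str,
) -> Sensorgram:
    t_a = _grid(design.t_assoc, design.sample_rate)
    t_d = _grid(design.t_dissoc, design.sample_rate)
    # drift accumulates over the global clock; noise is i.i.d. per sample
    drift_a = design.drift_rate * t_a
    drift_d = design.drift_rate * (design.t_assoc + t_d)
    noise_a = rng.normal(0.0, design.noise_sd, t_a.size) if design.noise_sd else 0.0
    noise_d = rng.normal(0.0, design.noise_sd, t_d.size) if design.noise_sd else 0.0
    return Sensorgram(
        sensor_id=sensor_id,
        steps=[
            Step("assoc1", t_a, assoc + drift_a + noise_a),
            Step("dissoc", t_d, dissoc + drift_d + noise_d),
        ],
        analyte=analyte,
        concentration=concentration,
        role=role,
    )


def _simulate_plate(signal_fn, design: AssayDesign, analyte: str, metadata: dict) -> Plate:
    rng = np.random.default_rng(design.seed)
    t_a = _grid(design.t_assoc, design.sample_rate)
    t_d = _grid(design.t_dissoc, design.sample_rate)
    zero = np.zeros_like

    sensorgrams = []
    for i, conc in enumerate(design.concentrations):
        assoc, dissoc = signal_fn(conc, t_a, t_d)
        sensorgrams.append(
            _assemble_sensorgram(
                f"S{i:02d}", assoc, dissoc, design, rng, analyte, conc, ROLE_SAMPLE
            )
        )
    # loaded sensor into buffer: zero analyte, drift + noise only
    sensorgrams.append(
        _assemble_sensorgram(
            "REFBUF", zero(t_a), zero(t_d), design, rng, analyte, 0.0, ROLE_REFERENCE_BUFFER
        )
    )
    # unloaded (biotin-only) pin into each analyte concentration: no signal
    for i, conc in enumerate(design.concentrations):
        sensorgrams.append(
            _assemble_sensorgram(
                f"REFPIN{i:02d}", zero(t_a), zero(t_d), design, rng, analyte, conc,
                ROLE_REFERENCE_PIN,
            )
        )
    return Plate(sensorgrams, metadata)


def simulate_1to1_sensorgram(
    params: KineticParams, design: AssayDesign, analyte: str = "analyte"
) -> Plate:
    """Simulate a 1:1 Langmuir plate: one sample trace per concentration plus
    a zero-concentration buffer reference and per-concentration pin references."""

    def signal(conc, t_a, t_d):
        return response_1to1(params, conc, t_a, t_d)

    meta = {
        "model": "1to1",
        "analyte": analyte,
        "k_on": params.k_on,
        "k_off": params.k_off,
        "r_max": params.r_max,
        "seed": design.seed,
    }
    return _simulate_plate(signal, design, analyte, meta)


def simulate_biphasic_sensorgram(
    params_a: KineticParams,
    params_b: KineticParams,
    fractions: tuple[float, float],
    design: AssayDesign,
    analyte: str = "analyte",
) -> Plate:
    """Simulate a two-component plate: the weighted sum of two independent
    1:1 signals (weights must sum to 1)."""
    fa, fb = (float(f) for f in fractions)
    if fa < 0 or fb < 0 or abs(fa + fb - 1.0) > 1e-9:
        raise DesignError(f"fractions must be non-negative and sum to 1, got {fractions}")

    def signal(conc, t_a, t_d):
        aa, ad = response_1to1(params_a, conc, t_a, t_d)
        ba, bd = response_1to1(params_b, conc, t_a, t_d)
        return fa * aa + fb * ba, fa * ad + fb * bd

    meta = {"model": "biphasic", "analyte": analyte, "fractions": (fa, fb), "seed": design.seed}
    return _simulate_plate(signal, design, analyte, meta)


@dataclass(frozen=True)
class SequentialDesign:
    """Two-ligand sequential (competition) experiment with epitope overlap φ.

    The sensor sees ligand 1 during Association 1, buffer during the
    dissociation step, and ligand 2 during Association 2.  ``overlap`` is the
    fraction of ligand 2's epitope blocked by bound ligand 1 (and vice
    versa); 0 decouples the ligands exactly, 1 is a fully shared site.
    ``conc1`` may be 0 for the no-competitor arm.
    """

    ligand1: KineticParams
    conc1: float  # M
    ligand2: KineticParams
    conc2: float  # M
    overlap: float  # φ in [0, 1]
    t_assoc1: float
    t_dissoc: float
    t_assoc2: float
    ligand1_name: str = "ligand1"
    ligand2_name: str = "ligand2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise DesignError(f"overlap must be in [0, 1], got {self.overlap}")
        if self.conc1 < 0 or self.conc2 < 0:
            raise DesignError("concentrations must be >= 0")
        if min(self.t_assoc1, self.t_dissoc, self.t_assoc2) <= 0:
            raise DesignError("step durations must be > 0")


def simulate_sequential(
    design: SequentialDesign,
    sample_rate: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    drift_rate: float = 0.0,
) -> Sensorgram:
    """Integrate the shared-site occupancy model over the three steps.

    dθ1/dt = k_on1·C1(t)·(1 − θ1 − φ·θ2) − k_off1·θ1 (and symmetrically for
    θ2); response = R_max1·θ1 + R_max2·θ2.  Integrated with a stiff-capable
    adaptive solver at absolute tolerance 1e-10 on the occupancies.
    """
    if sample_rate <= 0:
        raise DesignError("sample_rate must be > 0")
    if noise_sd < 0:
        raise DesignError("noise_sd must be >= 0")
    l1, l2, phi = design.ligand1, design.ligand2, design.overlap

    def rhs(_t, y, c1, c2):
        th1, th2 = y
        d1 = l1.k_on * c1 * (1.0 - th1 - phi * th2) - l1.k_off * th1
        d2 = l2.k_on * c2 * (1.0 - th2 - phi * th1) - l2.k_off * th2
        return (d1, d2)

    rng = np.random.default_rng(seed)
    y0 = np.array([0.0, 0.0])
    t_offset = 0.0
    steps = []
    schedule = [
        ("assoc1", design.t_assoc1, design.conc1, 0.0),
        ("dissoc", design.t_dissoc, 0.0, 0.0),
        ("assoc2", design.t_assoc2, 0.0, design.conc2),
    ]
    for label, duration, c1, c2 in schedule:
        t = _grid(duration, sample_rate)
        sol = solve_ivp(
            rhs,
            (0.0, duration),
            y0,
            t_eval=t,
            args=(c1, c2),
            method="LSODA",
            atol=1e-10,
            rtol=1e-8,
        )
        if not sol.success:
            raise DesignError(f"occupancy integration failed in step {label!r}: {sol.message}")
        theta = np.clip(sol.y, 0.0, 1.0)
        if np.any(sol.y < -1e-7) or np.any(sol.y > 1.0 + 1e-7):
            raise DesignError(f"occupancy left [0, 1] in step {label!r}")
        if phi == 1.0 and np.any(theta.sum(axis=0) > 1.0 + 1e-7):
            raise DesignError(f"shared-site occupancy exceeded 1 in step {label!r}")
        resp = l1.r_max * theta[0] + l2.r_max * theta[1]
        resp = resp + drift_rate * (t_offset + t)
        if noise_sd:
            resp = resp + rng.normal(0.0, noise_sd, t.size)
        steps.append(Step(label, t, resp))
        y0 = sol.y[:, -1]
        t_offset += duration

    return Sensorgram(
        sensor_id="SEQ",
        steps=steps,
        analyte=design.ligand2_name,
        concentration=design.conc2,
        role=ROLE_SAMPLE,
    )


@dataclass(frozen=True)
class PlantedMotifSpec:
    """Fixture generator settings for the hydropathy screen."""

    motif_length: int
    target_length: int
    plant_position: int  # 1-based start of the planted window in the target
    alphabet: tuple[str, ...] = field(default=tuple(KYTE_DOOLITTLE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 3:
            raise DesignError("motif_length must be >= 3")
        if self.plant_position < 1:
            raise DesignError("plant_position is 1-based and must be >= 1")
        if self.plant_position + self.motif_length - 1 > self.target_length:
            raise DesignError("planted window does not fit inside the target")
        bad = set(self.alphabet) - set(KYTE_DOOLITTLE)
        if bad:
            raise DesignError(f"alphabet contains non-standard letters: {sorted(bad)}")


# Residues whose pairing with the key residue has opposite hydropathy sign
# AND |H − H'| > 4.5, so a planted window scores 100% match and degree > 0.5.
_STRONG_COMPLEMENT = {
    aa: tuple(
        other
        for other, h2 in KYTE_DOOLITTLE.items()
        if (h1 > 0) != (h2 > 0) and abs(h1 - h2) > 4.5
    )
    for aa, h1 in KYTE_DOOLITTLE.items()
}


def plant_complementary_motif(spec: PlantedMotifSpec) -> tuple[str, str]:
    """Return (motif, target) where the target carries, at ``plant_position``,
    a window sign-opposite to the motif at every residue (degree > 0.5)."""
    rng = np.random.default_rng(spec.seed)
    alphabet = [aa for aa in spec.alphabet]
    motif = "".join(rng.choice(alphabet) for _ in range(spec.motif_length))
    target = [str(rng.choice(alphabet)) for _ in range(spec.target_length)]
    for i, aa in enumerate(motif):
        target[spec.plant_position - 1 + i] = str(rng.choice(_STRONG_COMPLEMENT[aa]))
    target_seq = "".join(target)
    # construction guarantee: planted window signs all oppose the motif's
    m_signs, _ = hydropathy_map(motif)
    w_signs, _ = hydropathy_map(
        target_seq[spec.plant_position - 1 : spec.plant_position - 1 + spec.motif_length]
    )
    assert np.all(m_signs != w_signs)
    return motif, target_seq
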