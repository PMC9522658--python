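"""Generative scenario descriptions for the endo-lysosomal forward simulator.

A :class:`Scenario` describes everything the simulator needs to produce
line-scan waveforms and whole-tubule time series for one virtual experiment:
the set of intracellular compartments (each a Gaussian spatial profile on the
normalized apical→basolateral axis with one or more kinetic phases), the
fluorophore labeling density, the noise level, and the perturbation switches
(cathepsin inhibition, reduced uptake, delayed apical transit).

Named default scenarios mirror the experimental conditions of the study
system: a healthy early proximal tubule (S1), cathepsin inhibition (e64),
low/high labeling density, and two disease-like perturbations (OCRL-like
reduced uptake, ClC-5-like delayed apical transit).

Position convention: 0 = apical, 1 = basolateral.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class KineticPhase:
    """One kinetic phase of a compartment's time course.

    The phase contributes ``amplitude * (1 - exp(-(t-onset)/rise_tau)) *
    exp(-(t-onset)/decay_tau)`` for ``t >= onset`` (zero before onset).
    ``decay_tau=inf`` gives a rising plateau.

    ``gated_by_unquenching`` marks phases whose fluorescence originates from
    degraded (unquenched) protein: their amplitude is scaled by the degraded-
    protein brightness and they vanish entirely when lysosomal proteolysis is
    inhibited.
    """

    onset: float
    rise_tau: float
    decay_tau: float
    amplitude: float
    gated_by_unquenching: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.rise_tau <= 0:
            raise ValueError(f"rise_tau must be > 0, got {self.rise_tau}")
        if not (self.decay_tau > 0):  # inf allowed
            raise ValueError(f"decay_tau must be > 0 or inf, got {self.decay_tau}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class CompartmentSpec:
    """A spatially localized endo-lysosomal compartment.

    The spatial profile is a Gaussian ``exp(-((x-center)/width)^2 / 2)`` on the
    normalized position axis [0, 1] (0 = apical).
    """

    name: str
    center: float
    width: float
    phases: tuple[KineticPhase, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 1.0:
            raise ValueError(f"center must lie in [0, 1], got {self.center}")
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if len(self.phases) < 1:
            raise ValueError("a compartment needs at least one kinetic phase")
        object.__setattr__(self, "phases", tuple(self.phases))


@dataclass(frozen=True)
class LabelingSpec:
    """Fluorophore labeling density of the injected protein.

    ``n_labels`` fluorophores per protein self-quench while the protein is
    intact; proteolysis relieves quenching. Per-additional-fluorophore
    quenching factor ``quench_q`` in (0, 1].
    """

    n_labels: int = 4
    quench_q: float = 0.6

    def __post_init__(self) -> None:
        if self.n_labels < 1:
            raise ValueError(f"n_labels must be >= 1, got {self.n_labels}")
        if not 0.0 < self.quench_q <= 1.0:
            raise ValueError(f"quench_q must be in (0, 1], got {self.quench_q}")


@dataclass(frozen=True)
class Scenario:
    """Complete generative description of one virtual line-scan experiment."""

    compartments: tuple[CompartmentSpec, ...]
    labeling: LabelingSpec = LabelingSpec()
    noise_sigma: float = 0.05
    n_profiles: int = 50
    n_timepoints: int = 60
    duration: float = 60.0
    n_bins: int = 100
    cathepsin_inhibited: bool = False
    uptake_scale: float = 1.0
    ee_transit_delay: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if len(self.compartments) < 1:
            raise ValueError("scenario needs at least one compartment")
        if self.n_profiles < 1:
            raise ValueError(f"n_profiles must be >= 1, got {self.n_profiles}")
        if self.n_timepoints < 2:
            raise ValueError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0.0 <= self.uptake_scale <= 1.0:
            raise ValueError(f"uptake_scale must be in [0, 1], got {self.uptake_scale}")
        if self.ee_transit_delay < 0:
            raise ValueError("ee_transit_delay must be >= 0")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        object.__setattr__(self, "compartments", tuple(self.compartments))

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# Named default scenarios.
#
# Compartment geometry: early endosomes (EE) sub-apical; large apical
# vacuoles (LAV) broad mid-cell; lysosomes (LYS) narrow mid-cell, overlapping
# the LAV zone.  Kinetics: EE shows an early rise and fall (rapid transit);
# LAV fills biphasically (an early intact-protein phase and a late
# degradation-dependent phase); LYS carries a delayed degradation signal
# starting at the ~10 min unquenching onset.  Phase amplitudes are expressed
# per protein count; fluorophore brightness scaling is applied by the
# simulator (see lysoscan.simulate).
# --------------------------------------------------------------------------

DEGRADATION_DELAY_MIN = 10.0

_EE = CompartmentSpec(
    name="EE", center=0.15, width=0.08,
    phases=(KineticPhase(onset=0.5, rise_tau=2.0, decay_tau=5.0, amplitude=2.5),),
)
_LAV = CompartmentSpec(
    name="LAV", center=0.45, width=0.18,
    phases=(
        KineticPhase(onset=1.0, rise_tau=5.0, decay_tau=25.0, amplitude=1.2),
        KineticPhase(onset=DEGRADATION_DELAY_MIN, rise_tau=8.0, decay_tau=math.inf,
                     amplitude=0.30, gated_by_unquenching=True),
    ),
)
_LYS = CompartmentSpec(
    name="LYS", center=0.45, width=0.07,
    phases=(
        KineticPhase(onset=DEGRADATION_DELAY_MIN, rise_tau=6.0, decay_tau=25.0,
                     amplitude=0.45, gated_by_unquenching=True),
    ),
)


def healthy_s1(seed: int = 0) -> Scenario:
    """Healthy S1 proximal-tubule segment: three overlapping compartments."""
    return Scenario(compartments=(_EE, _LAV, _LYS), seed=seed, name="healthy-S1")


def e64_inhibited(seed: int = 0) -> Scenario:
    """Cathepsin-inhibited (e64): degradation-gated phases abolished."""
    return healthy_s1(seed).replace(cathepsin_inhibited=True, name="e64-inhibited")


def low_label(seed: int = 0) -> Scenario:
    """Single fluorophore per protein: no self-quenching, no unquenching gain."""
    return healthy_s1(seed).replace(labeling=LabelingSpec(n_labels=1), name="low-label")


def high_label(seed: int = 0) -> Scenario:
    """Six fluorophores per protein: strongly quenched until degraded."""
    return healthy_s1(seed).replace(labeling=LabelingSpec(n_labels=6), name="high-label")


def ocrl_like(seed: int = 0) -> Scenario:
    """OCRL-knockout-like: endocytotic uptake reduced by more than half."""
    return healthy_s1(seed).replace(uptake_scale=0.45, name="OCRL-like")


def clc5_like(seed: int = 0) -> Scenario:
    """ClC-5-knockout-like: transit through the apical compartments delayed."""
    return healthy_s1(seed).replace(ee_transit_delay=5.0, name="ClC-5-like")


DEFAULT_SCENARIOS = {
    "healthy-S1": healthy_s1,
    "e64-inhibited": e64_inhibited,
    "low-label": low_label,
    "high-label": high_label,
    "OCRL-like": ocrl_like,
    "ClC-5-like": clc5_like,
}

# Separable test-bench scenarios: spatially separated compartments with
# temporally disjoint pulses and distinct amplitudes, so the generating rank
# is unambiguous and the factors are identifiable (near-equal singular values
# would make the decomposition rotationally degenerate).
_SEPARATED = (
    CompartmentSpec("C1", 0.12, 0.05,
                    (KineticPhase(1.0, 1.5, 3.0, 1.0),)),
    CompartmentSpec("C2", 0.38, 0.06,
                    (KineticPhase(13.0, 1.5, 3.0, 0.7),)),
    CompartmentSpec("C3", 0.62, 0.06,
                    (KineticPhase(27.0, 1.5, 3.0, 0.5),)),
    CompartmentSpec("C4", 0.86, 0.05,
                    (KineticPhase(42.0, 1.5, 3.0, 0.35),)),
)


def separable_scenario(rank: int, seed: int = 0, noise_sigma: float = 0.0) -> Scenario:
    """A scenario of known generating rank (1-4) for recovery experiments."""
    if not 1 <= rank <= 4:
        raise ValueError(f"rank must be in 1..4, got {rank}")
    return Scenario(compartments=_SEPARATED[:rank], noise_sigma=noise_sigma,
                    seed=seed, name=f"separable-{rank}")


# --------------------------------------------------------------------------
# JSON round-trip. Unknown keys are rejected so config typos fail loudly.
# --------------------------------------------------------------------------

def scenario_to_dict(s: Scenario) -> dict:
    d = dataclasses.asdict(s)
    for comp in d["compartments"]:
        for ph in comp["phases"]:
            if math.isinf(ph["decay_tau"]):
                ph["decay_tau"] = "inf"
    return d


def scenario_from_dict(d: dict) -> Scenario:
    allowed = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    comps = []
    for comp in d.get("compartments", ()):
        c_allowed = {f.name for f in dataclasses.fields(CompartmentSpec)}
        c_unknown = set(comp) - c_allowed
        if c_unknown:
            raise ValueError(f"unknown compartment keys: {sorted(c_unknown)}")
        phases = []
        for ph in comp["phases"]:
            p_allowed = {f.name for f in dataclasses.fields(KineticPhase)}
            p_unknown = set(ph) - p_allowed
            if p_unknown:
                raise ValueError(f"unknown phase keys: {sorted(p_unknown)}")
            ph = dict(ph)
            if ph.get("decay_tau") == "inf":
                ph["decay_tau"] = math.inf
            phases.append(KineticPhase(**ph))
        comps.append(CompartmentSpec(comp["name"], comp["center"], comp["width"],
                                     tuple(phases)))
    kwargs = {k: v for k, v in d.items() if k not in ("compartments", "labeling")}
    if "labeling" in d:
        l_allowed = {f.name for f in dataclasses.fields(LabelingSpec)}
        l_unknown = set(d["labeling"]) - l_allowed
        if l_unknown:
            raise ValueError(f"unknown labeling keys: {sorted(l_unknown)}")
        kwargs["labeling"] = LabelingSpec(**d["labeling"])
    return Scenario(compartments=tuple(comps), **kwargs)


def load_scenario(path) -> Scenario:
    """Load a Scenario from a JSON file (or a named default via {"name": ...})."""
    with open(path) as fh:
        d = json.load(fh)
    if set(d) <= {"name", "seed"} and d.get("name") in DEFAULT_SCENARIOS:
        return DEFAULT_SCENARIOS[d["name"]](seed=d.get("seed", 0))
    return scenario_from_dict(d)


def save_scenario(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(s), fh, indent=2, sort_keys=True)
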