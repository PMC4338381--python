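"""Configuration objects for the ANF model and the electrode-position experiment.

Unit conventions used throughout the package:

* cross-section geometry: millimetres (mm)
* fiber morphology: micrometres (um)
* time: milliseconds at the API level; the integration step is given in
  microseconds (``dt_us``)
* electrode current: milliamperes (mA); membrane currents: nanoamperes (nA)
* conductance: microsiemens (uS); capacitance: nanofarads (nF)
* potentials: millivolts (mV)

All defaults are plain dataclass fields so a configuration can be round-tripped
through YAML (``ExperimentConfig.to_yaml`` / ``from_yaml``) and hashed for
reproducibility (``config_hash``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any

import yaml

# Physical constants
GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.332        # C / mol

# Canonical published parameter values used by validate_config (mV, pS, um^-2,
# degrees C, us, (Ohm m)^-1).
CANONICAL = {
    "gamma_na_pS": 22.65,
    "gamma_k_pS": 50.0,
    "rho_na_per_um2": 80.0,
    "rho_k_per_um2": 45.0,
    "e_na_mV": 66.0,
    "e_k0_mV": -88.0,
    "temperature_C": 37.0,
    "dt_us": 1.0,
    "phase_us": 40.0,
    "conductivities": {
        "scala_tympani": 1.43,
        "scala_vestibuli": 1.43,
        "scala_media": 1.67,
        "organ_of_corti": 0.012,
        "modiolus": 0.156,
        "nerve": 0.3,
    },
}


@dataclass
class TissueModel:
    """Tissue conductivities of the cochlear cross-section, in (Ohm m)^-1."""

    conductivities: dict[str, float] = field(
        default_factory=lambda: dict(CANONICAL["conductivities"])
    )

    def __post_init__(self) -> None:
        for name, sigma in self.conductivities.items():
            if sigma <= 0:
                raise ValueError(f"conductivity of {name!r} must be > 0, got {sigma}")

    def sigma(self, region: str) -> float:
        return self.conductivities[region]


@dataclass
class ElectrodeConfig:
    """A ball stimulus electrode in the scala-tympani cross-section plane."""

    label: str
    position: tuple[float, float]  # (x, y) mm
    ball_diameter: float = 0.45    # mm
    region: str = "scala_tympani"


@dataclass
class GeometryConfig:
    """Surrogate 2D cross-section geometry.

    The fiber is laid out along the x axis with the peripheral terminal at the
    origin and the central axon running toward the modiolus (+x).  Electrode
    positions are free parameters of the surrogate volume conductor; the
    defaults place A at the lateral wall, B underneath the peripheral
    dendrite, C next to the soma / first central nodes and D in the middle of
    the scala tympani, so that the perimodiolar contact couples most strongly
    to central nodes and the others to peripheral nodes.
    """

    electrodes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (-0.95, -0.50),
            "B": (0.06, -0.35),
            "C": (0.52, -0.28),
            "D": (0.35, -0.50),
        }
    )
    ball_diameter: float = 0.45          # mm
    electrode_region: str = "scala_tympani"
    # x (mm) beyond which central compartments are assigned to nerve tissue
    # rather than modiolus.
    nerve_transition_mm: float = 1.8
    # x (mm) where the peripheral process leaves the organ of Corti and
    # enters the bony channel toward the soma (habenular crossing)
    oc_boundary_mm: float = 0.18
    # effective-conductivity blend: "transmission" (planar-interface
    # transmission factor) or "harmonic" (harmonic mean of the two regions)
    sigma_blend: str = "transmission"
    # exponential screening length (mm) emulating the bounded cochlear duct;
    # None disables screening (pure monopole decay)
    screening_length_mm: float | None = 0.8

    def electrode(self, label: str) -> ElectrodeConfig:
        return ElectrodeConfig(
            label=label,
            position=tuple(self.electrodes[label]),
            ball_diameter=self.ball_diameter,
            region=self.electrode_region,
        )


@dataclass
class FiberMorphology:
    """Compartmentalised cat ANF geometry (um)."""

    peripheral_diameter: float = 1.2
    central_diameter: float = 2.3
    nodal_gap: float = 1.0
    myelin_thickness: float = 1.0
    n_peripheral_nodes: int = 6
    n_central_nodes: int = 20
    passive_per_internode: int = 9
    has_soma: bool = True
    soma_diameter: float = 20.0
    # loose myelin around the cell body (membranes in series with its own)
    soma_myelin_membranes: int = 12
    # internode length = internode_length_ratio * fiber diameter
    internode_length_ratio: float = 100.0

    def __post_init__(self) -> None:
        if self.n_central_nodes < 16:
            raise ValueError("need at least 16 central nodes (recording at C16)")
        if self.passive_per_internode != 9:
            raise ValueError("each internode carries nine passive compartments")
        if min(self.peripheral_diameter, self.central_diameter, self.nodal_gap) <= 0:
            raise ValueError("fiber dimensions must be positive")


@dataclass
class GatingCoefficients:
    """Rate-constant coefficients of the mammalian-node HH-type kinetics.

    Rates are functions of the depolarisation V = Vm - Vrest (mV) and are in
    1/ms, referenced to 37 C.  ``alpha_m``, ``beta_m``, ``alpha_h``, ``alpha_n``
    and ``beta_n`` use the linoid form A*(V-B)/(1-exp((B-V)/C)) (with the sign
    of A setting the direction); ``beta_h`` uses the sigmoid A/(1+exp((B-V)/C)).
    """

    alpha_m: tuple[float, float, float] = (2.246, 25.41, 6.06)
    beta_m: tuple[float, float, float] = (-4.768, 21.001, -9.41)
    alpha_h: tuple[float, float, float] = (-0.549, -27.74, -9.06)
    beta_h: tuple[float, float, float] = (15.8, 56.0, 12.5)
    alpha_n: tuple[float, float, float] = (0.0258, 35.0, 10.0)
    beta_n: tuple[float, float, float] = (-0.0647, 35.0, -10.0)
    q10_na: float = 2.2
    q10_k: float = 3.0
    reference_temperature_C: float = 37.0


@dataclass
class KAccumulationConfig:
    """Extracellular potassium accumulation driving spike-rate adaptation.

    Outward K current at each active node is convolved with a single
    exponential decay kernel g(t) = exp(-t/tau) and converted to a
    concentration increment through an effective perinodal volume (node area
    times ``shell_thickness_um``).  The shifted K Nernst potential also moves
    the nodal leak reversal with weight ``leak_k_fraction`` (the nodal leak is
    predominantly potassium-selective).
    """

    enabled: bool = True
    tau_ms: float = 20.0
    shell_thickness_um: float = 0.003
    leak_k_fraction: float = 0.8
    k_in_mM: float = 140.0


@dataclass
class MembraneParams:
    """Active-membrane and passive-cable parameters."""

    gamma_na_pS: float = 22.65
    gamma_k_pS: float = 50.0
    rho_na_per_um2: float = 80.0
    rho_k_per_um2: float = 45.0
    e_na_mV: float = 66.0
    e_k0_mV: float = -88.0
    temperature_C: float = 37.0
    v_rest_mV: float = -78.0
    # passive cable
    cm_uF_cm2: float = 0.4              # specific membrane capacitance (nodes, soma)
    rm_node_ohm_cm2: float = 300.0      # nodal leak: 1/(3.3 mS/cm^2)
    rm_passive_ohm_cm2: float = 1000.0  # bare internodal membrane
    rm_soma_ohm_cm2: float = 1000.0
    rho_axial_ohm_cm: float = 200.0     # effective axoplasmic resistivity
    axon_diameter_ratio: float = 0.6    # axon core / fiber outer diameter
    myelin_lamella_nm: float = 12.0     # lamella period; two membranes per wrap
    # spike detection
    spike_threshold_mV: float = -20.0
    refractory_ms: float = 0.5
    gating: GatingCoefficients = field(default_factory=GatingCoefficients)
    k_accumulation: KAccumulationConfig = field(default_factory=KAccumulationConfig)

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in mV (~26.7 mV at 37 C)."""
        return 1e3 * GAS_CONSTANT * self.temperature_K / FARADAY

    @property
    def k_ext0_mM(self) -> float:
        """Baseline extracellular K+ chosen so that E_K(0) equals ``e_k0_mV``."""
        import math

        return self.k_accumulation.k_in_mM * math.exp(self.e_k0_mV / self.rt_over_f_mV)

    @property
    def myelin_attenuation(self) -> float:
        """Series-capacitance division factor of the myelin sheath."""
        n_lamellae = 1000.0 / self.myelin_lamella_nm  # per um of myelin
        return 1.0 + 2.0 * n_lamellae * 1.0  # myelin thickness folded in build_fiber


@dataclass
class ProtocolConfig:
    """Stimulation and analysis protocol constants."""

    dt_us: float = 1.0
    phase_us: float = 40.0
    n_single_sweeps: int = 100
    n_train_sweeps: int = 30
    single_sweep_ms: float = 2.0
    train_duration_ms: float = 200.0
    rates_pps: tuple[float, float] = (250.0, 5000.0)
    fe_targets: tuple[float, ...] = (0.2, 0.5, 0.9)
    onset_rate_targets_low: tuple[float, ...] = (100.0, 200.0, 250.0)
    onset_rate_targets_high: tuple[float, ...] = (100.0, 250.0, 350.0)
    onset_window_ms: tuple[float, float] = (0.0, 12.0)
    steady_window_ms: tuple[float, float] = (100.0, 200.0)
    fe_tolerance: float = 0.05
    rate_tolerance_sp_s: float = 10.0
    # levels for FE curves: n_levels spanning theta*(1 +/- grid_halfwidth_rs*RS)
    n_levels: int = 9
    grid_halfwidth_rs: float = 4.0


@dataclass
class ExperimentConfig:
    """Everything needed to run the full electrode-position experiment grid."""

    tissue: TissueModel = field(default_factory=TissueModel)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    morphology: FiberMorphology = field(default_factory=FiberMorphology)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    master_seed: int = 20150210
    electrodes: tuple[str, ...] = ("A", "B", "C", "D")

    # ---- serialisation ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        kwargs: dict[str, Any] = {}
        data = dict(data)
        if "tissue" in data:
            kwargs["tissue"] = TissueModel(**data.pop("tissue"))
        if "geometry" in data:
            geo = data.pop("geometry")
            geo["electrodes"] = {k: tuple(v) for k, v in geo["electrodes"].items()}
            kwargs["geometry"] = GeometryConfig(**geo)
        if "morphology" in data:
            kwargs["morphology"] = FiberMorphology(**data.pop("morphology"))
        if "membrane" in data:
            mem = data.pop("membrane")
            if "gating" in mem:
                gat = {
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in mem.pop("gating").items()
                }
                mem["gating"] = GatingCoefficients(**gat)
            if "k_accumulation" in mem:
                mem["k_accumulation"] = KAccumulationConfig(**mem.pop("k_accumulation"))
            kwargs["membrane"] = MembraneParams(**mem)
        if "protocol" in data:
            proto = data.pop("protocol")
            for key, val in list(proto.items()):
                if isinstance(val, list):
                    proto[key] = tuple(val)
            kwargs["protocol"] = ProtocolConfig(**proto)
        for key in ("master_seed",):
            if key in data:
                kwargs[key] = data.pop(key)
        if "electrodes" in data:
            kwargs["electrodes"] = tuple(data.pop("electrodes"))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "ExperimentConfig":
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = path_or_text
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _plainify(obj: Any) -> Any:
    """Convert tuples to lists recursively so YAML output is plain."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj


class ConfigWarning(UserWarning):
    """A configuration value deviates from the published model constants."""


def validate_config(config: ExperimentConfig) -> list[str]:
    """Check paper-anchored constants and return (and warn) any deviations.

    Deviations are reported as warnings, never errors: the configuration is
    deliberately editable, but silent drift from the published channel
    parameters would make results incomparable.
    """
    messages: list[str] = []
    mem = config.membrane

    def check(actual: float, key: str, what: str) -> None:
        expected = CANONICAL[key]
        if abs(actual - expected) > 1e-9 * max(1.0, abs(expected)):
            messages.append(f"{what} = {actual} deviates from published value {expected}")

    check(mem.gamma_na_pS, "gamma_na_pS", "Na single-channel conductance (pS)")
    check(mem.gamma_k_pS, "gamma_k_pS", "K single-channel conductance (pS)")
    check(mem.rho_na_per_um2, "rho_na_per_um2", "Na channel density (1/um^2)")
    check(mem.rho_k_per_um2, "rho_k_per_um2", "K channel density (1/um^2)")
    check(mem.e_na_mV, "e_na_mV", "Na Nernst potential (mV)")
    check(mem.e_k0_mV, "e_k0_mV", "initial K Nernst potential (mV)")
    check(mem.temperature_C, "temperature_C", "temperature (C)")
    check(config.protocol.dt_us, "dt_us", "integration step (us)")
    check(config.protocol.phase_us, "phase_us", "pulse phase duration (us)")
    for region, sigma in CANONICAL["conductivities"].items():
        actual = config.tissue.conductivities.get(region)
        if actual is None:
            messages.append(f"tissue region {region!r} missing from conductivity table")
        elif abs(actual - sigma) > 1e-9:
            messages.append(
                f"conductivity of {region!r} = {actual} deviates from published value {sigma}"
            )
    # channel-number-tracking validity: per-step transition probability bound.
    # Fastest rates are ~100/ms near the spike peak; require rate*dt << 1.
    if config.protocol.dt_us > 2.0:
        messages.append(
            f"dt = {config.protocol.dt_us} us: per-step channel transition "
            "probabilities may exceed the validity bound of the "
            "channel-number-tracking update (rate*dt must stay below 1)"
        )
    for msg in messages:
        warnings.warn(msg, ConfigWarning, stacklevel=2)
    return messages
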