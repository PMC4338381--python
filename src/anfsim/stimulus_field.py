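"""Stimulus waveforms and the parametric extracellular-field surrogate.

The original experiment computed the intracochlear potential distribution with
a 3D finite-element solve of a segmented cochlear cross-section.  Here the
field is generated by an analytic point-source volume-conductor surrogate:
each electrode is an ideal monopole in its tissue region, and the potential at
compartment ``k`` of the fiber is

    Ve[k][t] = R_t[k] * I(t),      R_t[k] = T_k / (4 pi sigma_src r_k)

where ``r_k`` is the electrode-to-compartment distance, ``sigma_src`` the
conductivity of the electrode's region, and ``T_k`` a region blend factor
accounting for the compartment sitting in a different tissue than the
electrode (see :func:`compute_transfer_vector`).  The quasi-static assumption
(static transfer vector scaled by the stimulus current) matches the use of a
static field solve driven by the stimulus waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ElectrodeConfig, FiberMorphology, GeometryConfig, TissueModel

__all__ = [
    "StimulusWaveform",
    "FiberTrajectory",
    "FieldProfile",
    "InvalidStimulusError",
    "GeometryError",
    "make_waveform",
    "build_trajectory",
    "compute_transfer_vector",
    "field_at",
]


class InvalidStimulusError(ValueError):
    """Requested stimulus parameters cannot form a valid pulse sequence."""


class GeometryError(ValueError):
    """Electrode/fiber geometry is inconsistent (e.g. compartment inside ball)."""


@dataclass
class StimulusWaveform:
    """A sampled electrode-current sequence (mA) on a uniform time base."""

    kind: str                  # "single_pulse" | "pulse_train"
    amplitude: float           # mA
    phase_duration: float      # us
    polarity: str              # "cathodic_first"
    rate: float | None         # pulses/s, trains only
    duration: float            # ms
    sample_step: float         # us
    current: np.ndarray        # mA, shape (n_samples,)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.current.size) * self.sample_step * 1e-3

    @property
    def n_pulses(self) -> int:
        if self.kind == "single_pulse":
            return 1
        return int(math.floor(self.rate * self.duration * 1e-3))

    def scaled(self, amplitude: float) -> "StimulusWaveform":
        """Return a copy of this waveform at a different amplitude."""
        factor = amplitude / self.amplitude if self.amplitude != 0 else 0.0
        current = self.current * factor if self.amplitude != 0 else self.current.copy()
        return StimulusWaveform(
            self.kind, amplitude, self.phase_duration, self.polarity,
            self.rate, self.duration, self.sample_step, current,
        )


def make_waveform(
    kind: str,
    amplitude: float,
    phase_duration: float,
    rate: float | None = None,
    duration: float = 1.0,
    sample_step: float = 1.0,
) -> StimulusWaveform:
    """Build a cathodic-first rectangular biphasic pulse or pulse train.

    Parameters
    ----------
    kind : "single_pulse" or "pulse_train"
    amplitude : pulse amplitude in mA (>= 0; the cathodic phase is -amplitude)
    phase_duration : duration of each phase in us (a multiple of sample_step)
    rate : pulse rate in pulses/s (trains only)
    duration : total sampled duration in ms
    sample_step : sample step in us
    """
    if amplitude < 0:
        raise InvalidStimulusError("amplitude must be >= 0")
    n_phase = phase_duration / sample_step
    if abs(n_phase - round(n_phase)) > 1e-9:
        raise InvalidStimulusError("phase_duration must be a multiple of sample_step")
    n_phase = int(round(n_phase))
    n_samples = int(round(duration * 1e3 / sample_step)) + 1
    current = np.zeros(n_samples)

    if kind == "single_pulse":
        onsets_us = [0.0]
        rate = None
    elif kind == "pulse_train":
        if rate is None or rate <= 0:
            raise InvalidStimulusError("pulse_train requires a positive rate")
        period_us = 1e6 / rate
        if 2 * phase_duration > period_us:
            raise InvalidStimulusError(
                f"pulse width {2 * phase_duration} us exceeds the period {period_us:.1f} us"
            )
        n_pulses = int(math.floor(rate * duration * 1e-3))
        onsets_us = [i * period_us for i in range(n_pulses)]
    else:
        raise InvalidStimulusError(f"unknown stimulus kind {kind!r}")

    for onset in onsets_us:
        i0 = int(round(onset / sample_step))
        if i0 + 2 * n_phase > n_samples:
            break
        current[i0:i0 + n_phase] = -amplitude          # cathodic phase first
        current[i0 + n_phase:i0 + 2 * n_phase] = amplitude

    return StimulusWaveform(
        kind=kind, amplitude=float(amplitude), phase_duration=float(phase_duration),
        polarity="cathodic_first", rate=rate, duration=float(duration),
        sample_step=float(sample_step), current=current,
    )


@dataclass
class FiberTrajectory:
    """Per-compartment 2D positions (mm) and tissue-region assignment."""

    positions: np.ndarray            # (n_comp, 2) mm
    regions: list[str]               # tissue region per compartment
    arc_mm: np.ndarray = field(default=None)  # cumulative arc length

    def __post_init__(self) -> None:
        if len(self.regions) != self.positions.shape[0]:
            raise ValueError("one region per compartment required")
        if self.arc_mm is None:
            deltas = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
            self.arc_mm = np.concatenate([[0.0], np.cumsum(deltas)])


def compartment_layout(morphology: FiberMorphology) -> tuple[list[str], np.ndarray]:
    """Compartment kinds and lengths (um) from the peripheral terminal inward.

    Layout: P1, 9 passive, P2, ..., P6, 9 passive, soma, C1, 9 passive, C2,
    ..., C20.  Returns (kinds, lengths_um) where kind is one of
    ``"P<i>"``, ``"soma"``, ``"pas_p"``, ``"pas_c"``, ``"C<i>"``.
    """
    m = morphology
    kinds: list[str] = []
    lengths: list[float] = []
    seg_p = m.internode_length_ratio * m.peripheral_diameter / m.passive_per_internode
    seg_c = m.internode_length_ratio * m.central_diameter / m.passive_per_internode
    for i in range(m.n_peripheral_nodes):
        kinds.append(f"P{i + 1}")
        lengths.append(m.nodal_gap)
        for _ in range(m.passive_per_internode):
            kinds.append("pas_p")
            lengths.append(seg_p)
    if m.has_soma:
        kinds.append("soma")
        lengths.append(m.soma_diameter)
    for i in range(m.n_central_nodes):
        kinds.append(f"C{i + 1}")
        lengths.append(m.nodal_gap)
        if i < m.n_central_nodes - 1:
            for _ in range(m.passive_per_internode):
                kinds.append("pas_c")
                lengths.append(seg_c)
    return kinds, np.asarray(lengths)


def build_trajectory(
    morphology: FiberMorphology,
    geometry: GeometryConfig | None = None,
) -> FiberTrajectory:
    """Lay the fiber out along the x axis of the cross-section plane.

    The peripheral process runs from the origin through the organ of Corti,
    the soma sits at the bony boundary and the central axon continues into the
    modiolus, transitioning to nerve tissue beyond
    ``geometry.nerve_transition_mm``.
    """
    geometry = geometry or GeometryConfig()
    kinds, lengths_um = compartment_layout(morphology)
    centers_um = np.cumsum(lengths_um) - lengths_um / 2.0
    x_mm = centers_um * 1e-3
    positions = np.column_stack([x_mm, np.zeros_like(x_mm)])

    soma_index = kinds.index("soma") if morphology.has_soma else None
    regions: list[str] = []
    for i, kind in enumerate(kinds):
        if soma_index is not None and i < soma_index:
            if x_mm[i] < geometry.oc_boundary_mm:
                regions.append("organ_of_corti")
            else:
                regions.append("modiolus")
        elif soma_index is not None and i == soma_index:
            regions.append("modiolus")
        else:
            if x_mm[i] < geometry.nerve_transition_mm:
                regions.append("modiolus")
            else:
                regions.append("nerve")
    return FiberTrajectory(positions=positions, regions=regions)


@dataclass
class FieldProfile:
    """Per-compartment transfer resistance (Ohm = mV per mA) of one electrode."""

    electrode: ElectrodeConfig
    transfer_resistance: np.ndarray   # (n_comp,) Ohm
    distances_mm: np.ndarray
    regions: list[str]

    def __post_init__(self) -> None:
        tr = np.asarray(self.transfer_resistance, float)
        if not np.all(np.isfinite(tr)) or np.any(tr <= 0):
            raise GeometryError("transfer resistances must be finite and positive")
        self.transfer_resistance = tr

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compartment": np.arange(self.transfer_resistance.size),
                "region": self.regions,
                "distance_mm": self.distances_mm,
                "transfer_resistance_ohm": self.transfer_resistance,
            }
        )


def _blend_sigma(sigma_src: float, sigma_comp: float, mode: str) -> tuple[float, float]:
    """Return (sigma_eff, transmission) for the chosen blending mode.

    ``harmonic``: sigma_eff is the harmonic mean of the electrode-region and
    compartment-region conductivities (transmission factor 1).

    ``transmission`` (default): the monopole potential is evaluated in the
    electrode's own medium and multiplied by the planar-interface transmission
    factor T = 2*sigma_src/(sigma_src + sigma_comp); equivalently
    sigma_eff = (sigma_src + sigma_comp)/2.  This keeps the point-source decay
    governed by the scala-tympani perilymph that actually carries the
    stimulating current, with a bounded first-order correction for the target
    compartment's tissue.
    """
    if mode == "harmonic":
        return 2.0 / (1.0 / sigma_src + 1.0 / sigma_comp), 1.0
    if mode == "transmission":
        return sigma_src, 2.0 * sigma_src / (sigma_src + sigma_comp)
    raise ValueError(f"unknown sigma blend mode {mode!r}")


def compute_transfer_vector(
    electrode: ElectrodeConfig,
    trajectory: FiberTrajectory,
    tissue: TissueModel,
    sigma_blend: str = "transmission",
    screening_length_mm: float | None = 0.8,
) -> FieldProfile:
    """Point-source transfer resistance of one electrode to every compartment.

    The ball electrode is treated as an ideal monopole at its centre; the ball
    diameter only guards against compartments lying inside the conductor.
    ``screening_length_mm`` multiplies the monopole potential by
    exp(-r/length): an unbounded medium overstates the far field of an
    electrode inside the narrow fluid-filled duct, whose walls divert return
    current; pass None for the pure 1/(4 pi sigma r) monopole.
    """
    pos = np.asarray(electrode.position, float)
    r_mm = np.linalg.norm(trajectory.positions - pos[None, :], axis=1)
    if np.any(r_mm <= electrode.ball_diameter / 2.0):
        raise GeometryError(
            f"compartment(s) inside the {electrode.ball_diameter} mm electrode ball"
        )
    sigma_src = tissue.sigma(electrode.region)
    tr = np.empty_like(r_mm)
    for k, region in enumerate(trajectory.regions):
        sigma_eff, trans = _blend_sigma(sigma_src, tissue.sigma(region), sigma_blend)
        tr[k] = trans / (4.0 * math.pi * sigma_eff * r_mm[k] * 1e-3)
        if screening_length_mm is not None:
            tr[k] *= math.exp(-r_mm[k] / screening_length_mm)
    return FieldProfile(
        electrode=electrode,
        transfer_resistance=tr,
        distances_mm=r_mm,
        regions=list(trajectory.regions),
    )


def field_at(profile: FieldProfile, waveform: StimulusWaveform) -> np.ndarray:
    """Extracellular potential Ve[k][t] (mV), quasi-static outer product."""
    return profile.transfer_resistance[:, None] * waveform.current[None, :]
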