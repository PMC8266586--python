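"""Kinetic scenario catalogue for the IF3 initiation cycle.

Each reaction of the translation-initiation cycle is described by a
kernel: one or two kinetic phases, each with an amplitude share of the
total fluorescence change and a rate law giving its apparent rate as a
function of titrant concentration (hyperbolic saturation for
binding-then-isomerization steps, linear for a plain bimolecular step).

The registry holds the six reactions in cycle order — 30S binding, IF2,
IF1, initiator-tRNA, mRNA and 50S joining — with the saturating rates and
amplitude splits of the measured conformational changes of doubly
labelled IF3, plus the tRNA-binding variant on mRNA-programmed
complexes.  Signed amplitudes around the cycle sum to zero (the FRET
signal is conserved over a full round of initiation and factor
recycling).

The rapid-equilibration constant of the hyperbolic law is set to
``DEFAULT_KS = 0.1`` uM for every reaction so that the standard titrant
grid (0.05-1 uM) spans half- to ten-fold saturation, matching the
curvature of measured rate-concentration plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import (DEFAULT_N_POINTS, DEFAULT_N_REPLICATES,
                        DEFAULT_NOISE_FRACTION, TraceParams, gen_replicates,
                        recommended_t_max)
from .traces import Trace

DEFAULT_KS = 0.1  # uM, rapid-equilibration constant of the hyperbolic law

#: standard titrant grid, uM (pseudo-first-order excess over 0.05 uM complex)
DEFAULT_CONCENTRATIONS = (0.05, 0.1, 0.2, 0.4, 0.7, 1.0)
#: grid for bimolecular (linear) titrations
LINEAR_CONCENTRATIONS = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class RateLaw:
    """Apparent-rate vs concentration law of one kinetic phase."""

    kind: str                     # "hyperbolic" | "linear"
    vmax: float = 0.0             # s^-1 (hyperbolic)
    ks: float = DEFAULT_KS        # uM (hyperbolic)
    slope: float = 0.0            # uM^-1 s^-1 (linear)
    intercept: float = 0.0        # s^-1 (linear)

    def rate(self, conc: float) -> float:
        if self.kind == "hyperbolic":
            return self.vmax * conc / (self.ks + conc)
        if self.kind == "linear":
            return self.slope * conc + self.intercept
        raise ValueError(f"unknown rate law {self.kind!r}")

    @property
    def saturating_value(self) -> float:
        """The quantity a saturation fit recovers (V_max, or the slope)."""
        return self.vmax if self.kind == "hyperbolic" else self.slope


def hyperbolic(vmax: float, ks: float = DEFAULT_KS) -> RateLaw:
    return RateLaw(kind="hyperbolic", vmax=vmax, ks=ks)


def linear(slope: float, intercept: float = 0.0) -> RateLaw:
    return RateLaw(kind="linear", slope=slope, intercept=intercept)


@dataclass(frozen=True)
class PhaseKernel:
    amplitude_fraction: float
    law: RateLaw


@dataclass(frozen=True)
class ReactionScenario:
    """One reaction of the cycle: titrant, direction, amplitude, phases."""

    name: str
    titrant: str
    sign: int                      # +1 fluorescence increase (domains open)
    total_amplitude: float         # volts
    phases: tuple[PhaseKernel, ...]
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    baseline: float = 2.5          # volts, arbitrary instrument offset

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def models(self) -> list[str]:
        return [p.law.kind for p in self.phases]

    def kernel_at(self, conc: float) -> list[tuple[float, float]]:
        """(signal-model amplitude, rate) per phase at one concentration.

        The signal-model amplitude is the negative of the observed
        change, since F relaxes from F0 + sum F_i down to F0.
        """
        return [(-self.sign * p.amplitude_fraction * self.total_amplitude,
                 p.law.rate(conc)) for p in self.phases]


#: The six cycle reactions (in order) plus the mRNA-programmed
#: initiator-tRNA variant whose second phase reports P-site accommodation.
REACTIONS: dict[str, ReactionScenario] = {
    "30S": ReactionScenario(
        name="30S", titrant="30S", sign=+1, total_amplitude=2.3,
        phases=(PhaseKernel(1.4 / 2.3, hyperbolic(113.0)),
                PhaseKernel(0.9 / 2.3, hyperbolic(5.2))),
    ),
    "IF2": ReactionScenario(
        name="IF2", titrant="IF2", sign=-1, total_amplitude=0.8,
        phases=(PhaseKernel(1.0, hyperbolic(11.0)),),
    ),
    "IF1": ReactionScenario(
        name="IF1", titrant="IF1", sign=-1, total_amplitude=0.7,
        phases=(PhaseKernel(0.4, hyperbolic(3.0)),
                PhaseKernel(0.6, hyperbolic(0.47))),
    ),
    "tRNA": ReactionScenario(
        name="tRNA", titrant="fMet-tRNA", sign=+1, total_amplitude=0.4,
        phases=(PhaseKernel(1.0, linear(17.0, 1.0)),),
        concentrations=LINEAR_CONCENTRATIONS,
    ),
    "tRNA+mRNA": ReactionScenario(
        name="tRNA+mRNA", titrant="fMet-tRNA", sign=+1, total_amplitude=0.4,
        phases=(PhaseKernel(0.5, linear(17.0, 1.0)),
                PhaseKernel(0.5, hyperbolic(4.0))),
        concentrations=LINEAR_CONCENTRATIONS,
    ),
    "mRNA": ReactionScenario(
        name="mRNA", titrant="mRNA", sign=+1, total_amplitude=0.3,
        phases=(PhaseKernel(1.0, hyperbolic(0.22)),),
    ),
    "50S": ReactionScenario(
        name="50S", titrant="50S", sign=-1, total_amplitude=1.5,
        phases=(PhaseKernel(0.36, hyperbolic(12.9)),
                PhaseKernel(0.64, hyperbolic(0.54))),
    ),
}

#: reactions that constitute the closed cycle, in order of progression
CYCLE_ORDER = ("30S", "IF2", "IF1", "tRNA", "mRNA", "50S")


def generate_scenario(scenario: ReactionScenario, seed: int | None = None,
                      n_replicates: int = DEFAULT_N_REPLICATES,
                      n_points: int = DEFAULT_N_POINTS,
                      noise_fraction: float = DEFAULT_NOISE_FRACTION) -> list[Trace]:
    """Generate the full replicate titration of one reaction scenario.

    Per concentration: the kernel rates follow the scenario's rate laws,
    the trace duration is five time constants of the slowest phase, and
    ``n_replicates`` noisy replicates share the noiseless kernel (noise
    sd = ``noise_fraction`` of the total amplitude).  The master seed
    deterministically spawns per-concentration seeds.
    """
    children = np.random.SeedSequence(seed).spawn(len(scenario.concentrations))
    traces: list[Trace] = []
    for conc, child in zip(scenario.concentrations, children):
        kernel = scenario.kernel_at(conc)
        params = TraceParams(
            baseline=scenario.baseline, phases=tuple(kernel),
            t_max=recommended_t_max([k for _, k in kernel]),
            n_points=n_points,
            noise_sd=noise_fraction * scenario.total_amplitude,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        traces.extend(gen_replicates(params, n_rep=n_replicates,
                                     titrant=scenario.titrant,
                                     conc_uM=float(conc)))
    return traces
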