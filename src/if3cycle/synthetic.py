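"""Synthetic stopped-flow traces, titration series and toy structures.

Everything downstream of the instrument is testable against data whose
ground truth is known: multi-exponential FRET traces (the closed-form
signal model plus additive Gaussian photomultiplier noise), titration
series generated by numerically integrating a two-step binding mechanism
(rapid binding equilibrium followed by a conformational change), and
small PDB structures with exactly known geometry for the
accessible-volume engine.

Default study conditions mirror the stopped-flow design the package
targets: 1000 samples per trace, 7 replicates per reaction averaged or
fitted independently, additive noise of 2% of the total signal amplitude,
and pseudo-first-order titrant excess over the labelled complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .structure import Structure, vdw_radius
from .traces import Trace

DEFAULT_N_POINTS = 1000       # samples acquired per stopped-flow shot
DEFAULT_N_REPLICATES = 7
DEFAULT_NOISE_FRACTION = 0.02  # noise sd as a fraction of total amplitude


class PseudoFirstOrderWarning(UserWarning):
    """Titrant excess below 5x the labelled species."""


@dataclass(frozen=True)
class TraceParams:
    """Closed-form signal parameters: F(t) = F0 + sum_i F_i exp(-k_i t).

    ``phases`` is an ordered tuple of (amplitude in volts, apparent rate
    in 1/s); it is stored sorted by decreasing rate.  ``noise_sd`` is the
    additive Gaussian noise standard deviation in volts.
    """

    baseline: float
    phases: tuple[tuple[float, float], ...]
    t_max: float
    n_points: int = DEFAULT_N_POINTS
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        phases = tuple((float(a), float(k)) for a, k in self.phases)
        if any(k <= 0 for _, k in phases):
            raise ValueError("all apparent rates must be positive")
        object.__setattr__(self, "phases",
                           tuple(sorted(phases, key=lambda p: -p[1])))

    @property
    def total_amplitude(self) -> float:
        return float(sum(abs(a) for a, _ in self.phases))

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Noiseless closed-form signal on an arbitrary time grid."""
        t = np.asarray(t, dtype=float)
        f = np.full_like(t, self.baseline, dtype=float)
        for amp, rate in self.phases:
            f += amp * np.exp(-rate * t)
        return f


def recommended_t_max(rates, n_time_constants: float = 5.0) -> float:
    """Trace duration resolving the slowest phase: n time constants of min(k)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    return float(n_time_constants / rates.min())


def gen_multiexp_trace(params: TraceParams, **trace_meta) -> Trace:
    """Generate one trace: closed-form kernel plus i.i.d. Gaussian noise.

    The time grid is linear on [0, t_max].  With ``noise_sd = 0`` the
    output equals the closed form to machine precision; an identical seed
    reproduces the trace bitwise.
    """
    t = np.linspace(0.0, params.t_max, params.n_points)
    f = params.evaluate(t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    return Trace(time=t, fluorescence=f, **trace_meta)


def gen_replicates(params: TraceParams, n_rep: int = DEFAULT_N_REPLICATES,
                   **trace_meta) -> list[Trace]:
    """Replicate traces sharing the noiseless kernel with independent noise.

    A single master seed deterministically spawns one child seed per
    replicate, so the full set is reproducible while replicates stay
    statistically independent.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    children = np.random.SeedSequence(params.seed).spawn(n_rep)
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        p = replace(params, seed=child_seed)
        out.append(gen_multiexp_trace(p, replicate=i, **trace_meta))
    return out


@dataclass(frozen=True)
class MechanismParams:
    """Two-step binding scheme R + L <=(Ks)=> RL -(k_fwd/k_rev)-> RL*.

    Binding is a rapid pre-equilibrium with equilibration constant ``Ks``
    (uM); the observed conformational change is the isomerization with
    maximal forward rate ``k_fwd`` (1/s) and reverse rate ``k_rev``.
    In the rapid-equilibrium limit the slow relaxation obeys
    ``k_app = k_fwd [C] / (Ks + [C]) + k_rev``.

    ``fret_levels`` maps species ("R", "RL", "RLs") to donor-fluorescence
    levels in volts per unit population.  ``equilibration_scale`` sets how
    much faster than ``k_fwd`` the binding step equilibrates
    (k_on = scale * k_fwd / Ks, k_off = scale * k_fwd).
    """

    Ks: float
    k_fwd: float
    k_rev: float = 0.0
    ligand_conc: float = 0.5
    labelled_conc: float = 0.05
    fret_levels: tuple[tuple[str, float], ...] = (("R", 1.0), ("RL", 1.0), ("RLs", 2.0))
    equilibration_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.Ks <= 0 or self.k_fwd <= 0 or self.k_rev < 0:
            raise ValueError("require Ks > 0, k_fwd > 0, k_rev >= 0")
        if self.ligand_conc < 5 * self.labelled_conc:
            warnings.warn(
                f"titrant {self.ligand_conc} uM below 5x labelled species "
                f"{self.labelled_conc} uM: pseudo-first-order approximation degraded",
                PseudoFirstOrderWarning)

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.fret_levels)

    def k_app_closed_form(self, conc: float) -> float:
        """Rapid-equilibrium apparent rate of the conformational phase."""
        return self.k_fwd * conc / (self.Ks + conc) + self.k_rev


@dataclass(frozen=True)
class BimolecularParams:
    """Single-step scheme R + L <=> RL; relaxation k_app = k_on [C] + k_off.

    ``k_on`` in 1/(uM s), ``k_off`` in 1/s.
    """

    k_on: float
    k_off: float = 0.0
    labelled_conc: float = 0.05
    fret_levels: tuple[tuple[str, float], ...] = (("R", 1.0), ("RL", 2.0))

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError("require k_on > 0, k_off >= 0")

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.fret_levels)

    def k_app_closed_form(self, conc: float) -> float:
        return self.k_on * conc + self.k_off


class SimulationError(RuntimeError):
    """ODE integration of a binding mechanism failed."""


def _integrate(rate_matrix: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    sol = solve_ivp(lambda _, x: rate_matrix @ x, (t[0], t[-1]), x0,
                    t_eval=t, method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    return sol.y


def gen_titration(mech: MechanismParams | BimolecularParams,
                  concentrations, n_points: int = DEFAULT_N_POINTS,
                  t_max: float | None = None, noise_sd: float = 0.0,
                  seed: int | None = None, titrant: str | None = None) -> list[Trace]:
    """Numerically integrate the binding scheme at each titrant concentration.

    Returns one trace per concentration under pseudo-first-order titrant
    excess; species populations are converted to fluorescence through the
    per-species FRET levels.  ``t_max`` defaults to five time constants
    of the slowest relaxation at each concentration.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    seeds = np.random.SeedSequence(seed).spawn(concentrations.size)
    traces = []
    for conc, child in zip(concentrations, seeds):
        if isinstance(mech, MechanismParams):
            if conc < 5 * mech.labelled_conc:
                warnings.warn(
                    f"titrant {conc} uM below 5x labelled species: "
                    "pseudo-first-order approximation degraded",
                    PseudoFirstOrderWarning)
            k_on = mech.equilibration_scale * mech.k_fwd / mech.Ks
            k_off = k_on * mech.Ks
            A = np.array([
                [-k_on * conc, k_off, 0.0],
                [k_on * conc, -(k_off + mech.k_fwd), mech.k_rev],
                [0.0, mech.k_fwd, -mech.k_rev],
            ])
            levels = [mech.levels[s] for s in ("R", "RL", "RLs")]
            slowest = mech.k_app_closed_form(conc)
        else:
            A = np.array([
                [-mech.k_on * conc, mech.k_off],
                [mech.k_on * conc, -mech.k_off],
            ])
            levels = [mech.levels[s] for s in ("R", "RL")]
            slowest = mech.k_app_closed_form(conc)
        dur = t_max if t_max is not None else recommended_t_max([slowest])
        t = np.linspace(0.0, dur, n_points)
        x0 = np.zeros(A.shape[0])
        x0[0] = 1.0
        pops = _integrate(A, x0, t)
        f = np.asarray(levels) @ pops
        if noise_sd > 0:
            rng = np.random.default_rng(int(child.generate_state(1)[0] % (2**31)))
            f = f + rng.normal(0.0, noise_sd, size=t.size)
        traces.append(Trace(time=t, fluorescence=f, titrant=titrant,
                            conc_uM=float(conc), replicate=0))
    return traces


# ---------------------------------------------------------------------------
# Toy structures for the accessible-volume engine


@dataclass(frozen=True)
class ToyStructureSpec:
    """Programmatic fixture structures with exactly known geometry.

    geometry:
      * ``isolated-attachment`` — only the attachment atoms themselves,
        ``separation`` A apart along x (unobstructed AV limit);
      * ``slab`` — an attachment atom at the origin plus a dense square
        slab of atoms occluding the half-space below ``z = -slab_gap``;
      * ``two-domain`` — two small atom clusters whose marker residues
        (65 and 166) carry Calpha atoms exactly ``separation`` A apart.
    """

    geometry: str
    separation: float = 80.0
    element: str = "S"
    slab_gap: float = 2.0
    slab_extent: float = 30.0
    slab_spacing: float = 1.5
    min_atom_distance: float = 0.5

    def __post_init__(self) -> None:
        if self.geometry not in ("isolated-attachment", "slab", "two-domain"):
            raise ValueError(f"unknown toy geometry {self.geometry!r}")
        if not np.isfinite(self.separation) or self.separation < 0:
            raise ValueError("separation must be finite and non-negative")


def _structure_from_records(records, source: str) -> Structure:
    serial, name, element, res_seq, res_name, chain, xyz = zip(*records)
    coords = np.array(xyz, dtype=float)
    if len(coords) > 1:
        from scipy.spatial.distance import pdist
        if pdist(coords).min() < 0.25:
            raise ValueError("overlapping atoms in toy structure spec")
    return Structure(
        serial=np.array(serial, dtype=int), name=np.array(name),
        element=np.array(element), res_seq=np.array(res_seq, dtype=int),
        res_name=np.array(res_name), chain=np.array(chain),
        coords=coords,
        radii=np.array([vdw_radius(e) for e in element], dtype=float),
        source=source,
    )


def gen_toy_structure(spec: ToyStructureSpec, path=None) -> Structure:
    """Build a toy structure; optionally also write it as a PDB file."""
    records = []
    if spec.geometry == "isolated-attachment":
        records.append((1, "SG", spec.element, 1, "CYS", "A", (0.0, 0.0, 0.0)))
        records.append((2, "SG", spec.element, 2, "CYS", "A",
                        (spec.separation, 0.0, 0.0)))
    elif spec.geometry == "slab":
        records.append((1, "SG", spec.element, 1, "CYS", "A", (0.0, 0.0, 0.0)))
        serial = 2
        ax = np.arange(-spec.slab_extent, spec.slab_extent + 1e-9, spec.slab_spacing)
        z = -spec.slab_gap - vdw_radius("C")
        for x in ax:
            for y in ax:
                records.append((serial, "C", "C", 2, "SLB", "B", (x, y, z)))
                serial += 1
    elif spec.geometry == "two-domain":
        half = spec.separation / 2.0
        serial = 1
        for sign, res in ((-1, 65), (+1, 166)):
            cx = sign * half
            records.append((serial, "CA", "C", res, "CYS", "A", (cx, 0.0, 0.0)))
            serial += 1
            records.append((serial, "SG", "S", res, "CYS", "A", (cx, 2.0, 0.0)))
            serial += 1
            for j, (dx, dy, dz) in enumerate(
                    [(2.0, 2.0, 0.0), (-2.0, 2.0, 0.0), (0.0, -2.5, 1.5)]):
                records.append((serial, "C", "C", res + j + 1, "GLY", "A",
                                (cx + dx, dy, dz)))
                serial += 1
    struct = _structure_from_records(records, source=f"toy:{spec.geometry}")
    if path is not None:
        from .structure import write_structure
        write_structure(struct, path)
    return struct
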