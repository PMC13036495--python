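"""Seeded synthetic magnetic-tweezers traces with known ground truth.

The generator emulates the statistical structure of single-bead experiments
on protein-filament assembly along a dsRNA tether:

* constant-force assembly: a bare-tether baseline, an exponential nucleation
  waiting time per lattice segment, then linear coverage growth (monomers/s)
  that stiffens the tether and raises its equilibrium WLC extension;
* ATP-driven compaction: linear extension loss with Poisson-distributed
  abrupt upward rupture jumps, ending clamped at a low-extension floor with
  strongly reduced noise;
* force ramps (force-extension protocol) and rotation-extension sweeps;
* binomially sampled occupancy counts for binding-isotherm inference.

Partial coverage alpha maps to stiffness through the inverse of the
occupancy transform used by the analysis: sqrt(1/Lp) interpolates linearly
between the bare and the fully covered value, so simulator and estimator are
self-consistent by construction.  Extension noise is independent Gaussian
per sample with sd(F) = noise_sd * sqrt(0.1 pN / F): fluctuations grow as
the trap force drops, qualitatively matching raw trace envelopes, without
claiming a physical bead model.  All randomness flows from the integer seed
in the configuration; identical (config, truth, seed) gives bit-identical
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .trace import TimeTrace
from .wlc import WLCParams, invert_wlc

_ALPHA_GRID = 257  # resolution of the coverage -> extension lookup table


@dataclass(frozen=True)
class ForceProtocol:
    """Piecewise description of the applied force over a trace.

    kind 'constant': force `value` throughout.
    kind 'ramp': log-linear force from `start` to `stop` pN over the trace
    (a magnet ramp produces a roughly exponential force profile in time).
    kind 'step': `value` before `t_step`, `stop` after.
    """

    kind: str = "constant"
    value: float = 0.1
    start: float = 0.1
    stop: float = 8.0
    t_step: float = 0.0

    def at(self, time: np.ndarray, duration: float) -> np.ndarray:
        if self.kind == "constant":
            return np.full_like(time, self.value)
        if self.kind == "ramp":
            frac = np.clip(time / duration, 0.0, 1.0)
            return self.start * (self.stop / self.start) ** frac
        if self.kind == "step":
            return np.where(time < self.t_step, self.value, self.stop)
        raise ValueError(f"unknown force protocol kind {self.kind!r}")


@dataclass(frozen=True)
class TurnsProtocol:
    """Linear magnet-turn sweep from `start` to `stop` turns over the trace."""

    start: float = -50.0
    stop: float = 50.0

    def at(self, time: np.ndarray, duration: float) -> np.ndarray:
        frac = np.clip(time / duration, 0.0, 1.0)
        return self.start + (self.stop - self.start) * frac


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and protocol settings for one synthetic trace."""

    duration: float  # s
    sample_rate: float = 58.0  # Hz, camera acquisition frequency
    force_protocol: ForceProtocol = field(default_factory=ForceProtocol)
    turns_protocol: TurnsProtocol | None = None
    noise_sd: float = 30.0  # nm, extension noise sd at the 0.1 pN reference force
    flush_start: float = 20.0  # s, protein flush; nucleation clock starts here
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def time_axis(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate


@dataclass(frozen=True)
class GapSpec:
    """A single-strand gap at tether fraction `position` blocking growth.

    The gap splits the lattice into two independently nucleating segments;
    filament growth never crosses it.
    """

    position: float  # fraction of tether length in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.position < 1.0:
            raise ValueError("gap position must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a synthetic trace.

    Defaults are the wild-type, 300 nM, saturating-condition values: slow
    nucleation (0.062 1/s), cooperative growth (8 monomers/s with a 14 bp
    monomer footprint on a 3149 bp tether), compaction at 5 nm/s, bare-tether
    persistence length 45 nm rising to 200 nm for the complete filament on a
    896 nm contour, rupture forces 20 +/- 4 pN, and rotation-extension
    slopes of 15 (positive turns, low force) and 1 nm/turn (negative turns).
    """

    k_nucl: float = 0.062  # nucleation rate, 1/s
    k_form: float = 8.0  # growth rate, monomers/s
    k_comp: float = 5.0  # compaction rate, nm/s
    footprint_bp: int = 14  # bp occluded per bound monomer
    tether_bp: int = 3149  # tether length, bp
    lp_bare: float = 45.0  # nm
    lp_full: float = 200.0  # nm
    lc: float = 896.0  # nm
    kbt: float = 4.11  # pN nm
    rupture_rate: float = 0.0  # rupture events per second during compaction
    rupture_size_nm: float = 40.0  # mean abrupt upward jump, nm
    rupture_force_mean: float = 20.0  # pN (force-ramp rupture sampling)
    rupture_force_sd: float = 4.0  # pN
    pos_turn_slope: float = 15.0  # nm extension loss per added positive turn
    neg_turn_slope: float = 1.0  # nm extension loss per added negative turn
    floor_frac: float = 0.10  # compacted floor as a fraction of lc
    floor_noise_scale: float = 0.2  # noise reduction once compacted
    gap_spec: GapSpec | None = None

    def __post_init__(self) -> None:
        for name in ("k_nucl", "k_form", "k_comp", "rupture_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.lp_bare <= self.lp_full:
            raise ValueError("require 0 < lp_bare <= lp_full")

    @property
    def capacity_monomers(self) -> float:
        """Monomers needed to saturate the whole tether."""
        return self.tether_bp / self.footprint_bp

    def lp_at_coverage(self, alpha) -> np.ndarray:
        """Persistence length at fractional coverage alpha (inverse-sqrt mixing)."""
        a = np.clip(np.asarray(alpha, dtype=float), 0.0, 1.0)
        s = np.sqrt(1.0 / self.lp_bare) + a * (
            np.sqrt(1.0 / self.lp_full) - np.sqrt(1.0 / self.lp_bare))
        return 1.0 / s**2

    def extension_at_coverage(self, alpha, force: float) -> np.ndarray:
        """Equilibrium WLC extension at coverage alpha under constant force.

        Uses a precomputed lookup over the coverage grid (the per-sample
        root solve would dominate runtime otherwise); interpolation error is
        far below the noise floor.
        """
        grid = np.linspace(0.0, 1.0, _ALPHA_GRID)
        ext_grid = np.array([
            invert_wlc(force, WLCParams(self.lp_at_coverage(a), self.lc, self.kbt))
            for a in grid])
        return np.interp(np.clip(alpha, 0.0, 1.0), grid, ext_grid)

    def delta_ext_full(self, force: float) -> float:
        """Extension change from bare tether to complete filament at `force`."""
        bare = invert_wlc(force, WLCParams(self.lp_bare, self.lc, self.kbt))
        full = invert_wlc(force, WLCParams(self.lp_full, self.lc, self.kbt))
        return float(full - bare)

    def public_dict(self) -> dict:
        d = asdict(self)
        if self.gap_spec is not None:
            d["gap_spec"] = {"position": self.gap_spec.position}
        return d


def _noise_sd_at(force, noise_sd: float) -> np.ndarray:
    """Force-dependent extension noise sd: noise_sd referenced to 0.1 pN."""
    return noise_sd * np.sqrt(0.1 / np.asarray(force, dtype=float))


def _segments(truth: GroundTruth) -> list[float]:
    """Fractional sizes of independently nucleating lattice segments."""
    if truth.gap_spec is None:
        return [1.0]
    g = truth.gap_spec.position
    return [g, 1.0 - g]


def simulate_assembly_trace(config: SimulationConfig,
                            truth: GroundTruth) -> TimeTrace:
    """Constant-force filament assembly: baseline, nucleation, growth.

    Phases: (i) bare-tether equilibrium extension until the protein flush;
    (ii) per-segment exponential nucleation waiting time at rate ``k_nucl``
    after the flush; (iii) linear coverage growth at ``k_form`` monomers/s
    until each segment saturates (a gap blocks growth past it); Gaussian
    extension noise throughout.  Ground-truth phase boundaries are recorded
    in the metadata.
    """
    if config.force_protocol.kind != "constant":
        raise ValueError("assembly simulation requires a constant-force protocol")
    force = config.force_protocol.value
    rng = np.random.default_rng(config.seed)
    time = config.time_axis()

    seg_fracs = _segments(truth)
    # nucleation waiting time per segment, measured from the flush start
    if truth.k_nucl > 0:
        waits = rng.exponential(1.0 / truth.k_nucl, size=len(seg_fracs))
    else:
        waits = np.full(len(seg_fracs), np.inf)

    # coverage (fraction of the whole tether) summed over segments
    alpha = np.zeros_like(time)
    growth_frac_per_s = (truth.k_form / truth.capacity_monomers
                         if truth.k_form > 0 else 0.0)
    for frac, wait in zip(seg_fracs, waits):
        if growth_frac_per_s == 0.0 or not np.isfinite(wait):
            continue
        t_start = config.flush_start + wait
        alpha += np.clip((time - t_start) * growth_frac_per_s, 0.0, frac)
    alpha = np.minimum(alpha, 1.0)  # coverage can never exceed the tether

    extension = truth.extension_at_coverage(alpha, force)
    if config.noise_sd > 0:
        extension = extension + rng.normal(
            0.0, _noise_sd_at(force, config.noise_sd), size=time.size)

    t_nucl = [float(config.flush_start + w) for w in waits]
    sat_times = []
    for frac, w in zip(seg_fracs, waits):
        if growth_frac_per_s > 0 and np.isfinite(w):
            sat_times.append(config.flush_start + w + frac / growth_frac_per_s)
    meta = {
        "protocol": "assembly",
        "force_pN": force,
        "seed": config.seed,
        "flush_start_s": config.flush_start,
        "t_nucleation_s": t_nucl if len(t_nucl) > 1 else t_nucl[0],
        "t_saturated_s": (max(sat_times) if sat_times else None),
        "truth": truth.public_dict(),
    }
    return TimeTrace(time, extension, np.full_like(time, force),
                     np.zeros_like(time), meta)


def simulate_compaction_phase(config: SimulationConfig, truth: GroundTruth,
                              start_extension: float) -> TimeTrace:
    """ATP-driven compaction from ``start_extension`` down to the floor.

    Extension decreases at ``k_comp`` nm/s; ruptures arrive as a Poisson
    process at ``rupture_rate`` and each adds an abrupt upward jump of about
    ``rupture_size_nm`` within one sample; once the floor (``floor_frac *
    lc``) is reached the trace stays clamped there with noise scaled down by
    ``floor_noise_scale``, emulating the reduction in bead fluctuation of
    the tightly compacted complex.  Ruptures stop once compacted.
    """
    if config.force_protocol.kind != "constant":
        raise ValueError("compaction simulation requires a constant-force protocol")
    if truth.k_comp < 0:
        raise ValueError("k_comp must be non-negative")
    floor = truth.floor_frac * truth.lc
    if start_extension <= floor:
        raise ValueError("start_extension must exceed the compacted floor")
    force = config.force_protocol.value
    rng = np.random.default_rng(config.seed)
    time = config.time_axis()
    dt = 1.0 / config.sample_rate

    # Poisson rupture arrivals over the whole window; events after the trace
    # has clamped at the floor are discarded below.
    n_events = rng.poisson(truth.rupture_rate * config.duration)
    event_times = np.sort(rng.uniform(0.0, config.duration, size=n_events))
    event_sizes = np.abs(rng.normal(truth.rupture_size_nm,
                                    0.2 * truth.rupture_size_nm, size=n_events))

    extension = np.empty_like(time)
    at_floor = np.zeros(time.size, dtype=bool)
    ext = float(start_extension)
    ev = 0
    kept_times, kept_sizes = [], []
    compacted = False
    for i, t in enumerate(time):
        if not compacted:
            while ev < n_events and event_times[ev] <= t:
                ext += event_sizes[ev]
                kept_times.append(float(event_times[ev]))
                kept_sizes.append(float(event_sizes[ev]))
                ev += 1
            ext = max(floor, ext - truth.k_comp * dt)
            if ext <= floor:
                compacted = True
        extension[i] = ext
        at_floor[i] = compacted

    if config.noise_sd > 0:
        sd = _noise_sd_at(force, config.noise_sd) * np.where(
            at_floor, truth.floor_noise_scale, 1.0)
        extension = extension + rng.normal(0.0, sd, size=time.size)

    t_floor = float(time[at_floor][0]) if at_floor.any() else None
    meta = {
        "protocol": "compaction",
        "force_pN": force,
        "seed": config.seed,
        "start_extension_nm": float(start_extension),
        "floor_nm": float(floor),
        "t_floor_s": t_floor,
        "rupture_times_s": kept_times,
        "rupture_sizes_nm": kept_sizes,
        "truth": truth.public_dict(),
    }
    return TimeTrace(time, extension, np.full_like(time, force),
                     np.zeros_like(time), meta)


def simulate_force_ramp(config: SimulationConfig, params: WLCParams,
                        noise_sd: float,
                        rupture_force: tuple[float, float] | None = None,
                        post_rupture_params: WLCParams | None = None) -> TimeTrace:
    """Force-ramp (force-extension) protocol on a WLC tether.

    The force follows the configured ramp; the extension is the WLC
    equilibrium response plus force-dependent Gaussian noise.  In high-force
    mode, a rupture force drawn Normal(mean, sd) switches the response to
    the ``post_rupture_params`` branch (e.g. a compacted complex breaking
    back to the bare tether) at the sample where the ramp crosses it.
    """
    if config.force_protocol.kind != "ramp":
        raise ValueError("force-ramp simulation requires a ramp protocol")
    if config.force_protocol.start <= 0 or config.force_protocol.stop <= 0:
        raise ValueError("ramp forces must be positive")
    rng = np.random.default_rng(config.seed)
    time = config.time_axis()
    force = config.force_protocol.at(time, config.duration)

    drawn_rupture = None
    if rupture_force is not None:
        if post_rupture_params is None:
            raise ValueError("post_rupture_params required with rupture sampling")
        mean, sd = rupture_force
        drawn_rupture = float(rng.normal(mean, sd))
        pre = force < drawn_rupture
        extension = np.empty_like(force)
        extension[pre] = invert_wlc(force[pre], params)
        extension[~pre] = invert_wlc(force[~pre], post_rupture_params)
    else:
        extension = invert_wlc(force, params)

    if noise_sd > 0:
        extension = extension + rng.normal(
            0.0, _noise_sd_at(force, noise_sd), size=time.size)

    meta = {
        "protocol": "ramp",
        "seed": config.seed,
        "f_min_pN": config.force_protocol.start,
        "f_max_pN": config.force_protocol.stop,
        "lp_nm": params.lp,
        "lc_nm": params.lc,
        "rupture_force_pN": drawn_rupture,
    }
    return TimeTrace(time, extension, force, np.zeros_like(time), meta)


def simulate_rotation_extension(config: SimulationConfig, truth: GroundTruth,
                                coilable: bool) -> TimeTrace:
    """Rotation-extension sweep at constant force.

    A coilable tether loses ``pos_turn_slope`` nm per added positive turn and
    ``neg_turn_slope`` nm per added negative turn from the zero-turn apex; a
    non-coilable tether ignores the magnet rotation entirely.
    """
    if config.turns_protocol is None:
        raise ValueError("rotation simulation requires a turns protocol")
    force = config.force_protocol.value
    rng = np.random.default_rng(config.seed)
    time = config.time_axis()
    turns = config.turns_protocol.at(time, config.duration)

    apex = invert_wlc(force, WLCParams(truth.lp_bare, truth.lc, truth.kbt))
    if coilable:
        drop = np.where(turns >= 0, truth.pos_turn_slope * turns,
                        truth.neg_turn_slope * (-turns))
        extension = np.maximum(apex - drop, 0.0)
    else:
        extension = np.full_like(time, apex)
    if config.noise_sd > 0:
        extension = extension + rng.normal(
            0.0, _noise_sd_at(force, config.noise_sd), size=time.size)

    meta = {
        "protocol": "rotation",
        "force_pN": force,
        "seed": config.seed,
        "coilable": bool(coilable),
        "apex_nm": float(apex),
        "truth": truth.public_dict(),
    }
    return TimeTrace(time, extension, np.full_like(time, force), turns, meta)


def simulate_occupancy_counts(concentrations, kd: float, n: float,
                              n_all: int, seed: int = 0):
    """Binomially sampled occupancy per concentration from the Hill isotherm.

    For each concentration c the true occupancy is c^n / (kd^n + c^n); the
    observed fraction is Binomial(n_all, alpha)/n_all with its binomial
    standard error attached.  Returns a list of OccupancyPoint.
    """
    from .binding import OccupancyPoint, binomial_error

    if kd <= 0 or n <= 0:
        raise ValueError("kd and n must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    if n_all < 1:
        raise ValueError("n_all must be at least 1")
    rng = np.random.default_rng(seed)
    points = []
    for c in concentrations:
        alpha_true = c**n / (kd**n + c**n)
        n_i = int(rng.binomial(n_all, alpha_true))
        fe = binomial_error(n_i, n_all)
        points.append(OccupancyPoint(concentration=float(c), alpha=fe.f_rel,
                                     sigma_alpha=fe.delta_f, n_tethers=n_all))
    return points


def concat_traces(first: TimeTrace, second: TimeTrace) -> TimeTrace:
    """Join two traces in time (second shifted to start after first)."""
    dt = 1.0 / first.sample_rate if len(first) > 1 else 0.0
    offset = first.time[-1] + dt
    meta = dict(first.metadata)
    meta["appended"] = second.metadata.get("protocol")
    for key in ("t_floor_s", "rupture_times_s", "rupture_sizes_nm", "floor_nm"):
        if key in second.metadata and second.metadata[key] is not None:
            val = second.metadata[key]
            if key.endswith("_s"):
                if isinstance(val, list):
                    val = [v + offset for v in val]
                else:
                    val = val + offset
            meta[key] = val
    return TimeTrace(
        np.concatenate([first.time, second.time + offset]),
        np.concatenate([first.extension, second.extension]),
        np.concatenate([first.force, second.force]),
        np.concatenate([first.turns, second.turns]),
        meta,
    )


def simulate_archetype(label: str, truth: GroundTruth, seed: int,
                       force: float = 1.0, noise_sd: float = 15.0,
                       sample_rate: float = 58.0) -> TimeTrace:
    """One trace of a named behavioural class, for labeled cohorts.

    Classes mirror the four-way outcome of compaction experiments:
    ``fully_compacted`` (growth then compaction clamped at the floor),
    ``partially_compacted`` (extension drops below the bare tether but never
    reaches a stable floor), ``dissociated`` (extension decays back to the
    bare level), and ``extended`` (growth then a stable plateau).
    """
    from dataclasses import replace

    bare = invert_wlc(force, WLCParams(truth.lp_bare, truth.lc, truth.kbt))
    full = invert_wlc(force, WLCParams(truth.lp_full, truth.lc, truth.kbt))
    grow_cfg = SimulationConfig(duration=120.0, sample_rate=sample_rate,
                                force_protocol=ForceProtocol("constant", force),
                                noise_sd=noise_sd, flush_start=20.0, seed=seed)
    fast = replace(truth, k_nucl=0.2)  # keep nucleation inside the window
    head = simulate_assembly_trace(grow_cfg, fast)

    def comp(duration: float, floor_frac: float, seed_off: int) -> TimeTrace:
        cfg = SimulationConfig(duration=duration, sample_rate=sample_rate,
                               force_protocol=ForceProtocol("constant", force),
                               noise_sd=noise_sd, seed=seed + seed_off)
        return simulate_compaction_phase(cfg, replace(fast, floor_frac=floor_frac,
                                                      rupture_rate=0.0),
                                         start_extension=full)

    if label == "extended":
        trace = head
    elif label == "fully_compacted":
        tail = comp(duration=(full - truth.floor_frac * truth.lc) / truth.k_comp + 60.0,
                    floor_frac=truth.floor_frac, seed_off=1)
        trace = concat_traces(head, tail)
    elif label == "partially_compacted":
        # stop between the floor and the bare level: ends below bare, unstable
        target = 0.6 * bare / truth.lc
        tail = comp(duration=(full - 0.6 * bare) / truth.k_comp + 5.0,
                    floor_frac=target, seed_off=2)
        m = tail.extension > 0.55 * bare  # truncate before a long stable tail forms
        tail = TimeTrace(tail.time[m], tail.extension[m], tail.force[m],
                         tail.turns[m], tail.metadata)
        trace = concat_traces(head, tail)
    elif label == "dissociated":
        target = bare / truth.lc
        tail = comp(duration=(full - bare) / truth.k_comp + 40.0,
                    floor_frac=target, seed_off=3)
        trace = concat_traces(head, tail)
    else:
        raise ValueError(f"unknown archetype {label!r}")
    trace.metadata["class_truth"] = label
    trace.metadata["bare_extension_nm"] = float(bare)
    return trace


def simulate_labeled_cohort(n_per_class: int, truth: GroundTruth,
                            seed: int = 0, **kwargs) -> list[TimeTrace]:
    """Labeled cohort with n traces of each behavioural class."""
    labels = ("fully_compacted", "partially_compacted", "dissociated", "extended")
    out = []
    for j, label in enumerate(labels):
        for i in range(n_per_class):
            out.append(simulate_archetype(label, truth,
                                          seed=seed + 1000 * j + i, **kwargs))
    return out
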