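"""Synthetic epidermal-monolayer movies with controllable elimination modes.

Generates track tables, fate tables and reporter traces carrying the
statistical structure the analysis pipeline assumes, so every stage is
testable without microscopy data:

* a jittered hexagonal monolayer of nuclei imaged at a 10-min cadence over
  ~20 h starting at 20 hAPF;
* a two-phase elimination hazard (infrequent early, rapid late, boundary at
  25 hAPF);
* three elimination modes — ``random`` (each cell dies independently),
  ``protected`` (surviving neighbors of a dying cell become refractory for
  ~60 min, enforcing isolated deaths), and ``contagion`` (a death
  transiently multiplies its neighbors' hazard, producing clustered
  deaths);
* a nuclear ERK reporter that drifts upward globally (ERK falling) with
  transient dips (ERK pulses) injected into protected neighbors of dying
  cells, beginning 60 min before the death event, plus a constant
  cytoplasmic channel so ratio operations are exercised;
* tracks that terminate at nuclear breakdown (the death frame).

Every run is deterministic under its seed, and :func:`write_fixture` emits
the standard spot-table dialect next to a machine-readable truth file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import neighbor_graph, track_io

logger = logging.getLogger(__name__)

MODES = ("random", "protected", "contagion", "graded")


@dataclass
class LatticeConfig:
    n_cols: int = 30
    n_rows: int = 20
    pitch_um: float = 30.0   # centre spacing of the large polyploid nuclei
    jitter_um: float = 3.0   # Gaussian positional jitter (SD)

    def __post_init__(self):
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")


@dataclass
class MovieConfig:
    n_frames: int = 120
    frame_interval_min: float = 10.0
    start_hAPF: float = 20.0


@dataclass
class HazardConfig:
    """Per-cell elimination hazard, per hour, by phase."""

    early_per_hour: float = 0.005
    late_per_hour: float = 0.05
    phase_boundary_hAPF: float = 25.0

    def __post_init__(self):
        if self.early_per_hour < 0 or self.late_per_hour < 0:
            raise ValueError("hazard rates must be >= 0")


@dataclass
class ProtectionConfig:
    refractory_min: float = 60.0   # neighbor refractory period after a death
    protection_prob: float = 1.0   # chance each neighbor is protected (gets the pulse)

    def __post_init__(self):
        if self.refractory_min < 0:
            raise ValueError("refractory period must be >= 0")


@dataclass
class ContagionConfig:
    multiplier: float = 20.0   # neighbor hazard multiplier after a death
    window_min: float = 60.0   # duration of the elevated hazard


@dataclass
class ReporterConfig:
    baseline: float = 100.0         # nuclear reporter at movie start, AU
    cytoplasmic: float = 100.0      # constant cytoplasmic channel, AU
    drift_per_hour: float = 4.0     # global nuclear rise (ERK decreasing), AU/h
    pulse_amplitude: float = 30.0   # depth of the neighbor dip (ERK pulse), AU
    pulse_lead_min: float = 60.0    # dip starts this long before the death event
    pulse_duration_min: float = 30.0  # falling ramp duration
    pulse_hold_min: float = 20.0    # time at full depth past the event
    pulse_recovery_min: float = 30.0  # ramp back to baseline
    predeath_rise: float = 20.0     # nuclear rise of the dying cell itself, AU
    predeath_rise_min: float = 40.0
    noise_sd: float = 3.0           # additive Gaussian noise, AU


@dataclass
class MigrationConfig:
    enabled: bool = False          # the null ignores migration; off by default
    speed_um_per_hour: float = 10.0
    midline_y_um: float | None = None  # default: lattice centre


@dataclass
class SynthConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    movie: MovieConfig = field(default_factory=MovieConfig)
    hazard: HazardConfig = field(default_factory=HazardConfig)
    mode: str = "random"
    protection: ProtectionConfig = field(default_factory=ProtectionConfig)
    contagion: ContagionConfig = field(default_factory=ContagionConfig)
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    migration: MigrationConfig = field(default_factory=MigrationConfig)
    max_dist_factor: float = neighbor_graph.DEFAULT_MAX_DIST_FACTOR
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        kwargs = dict(d)
        for name, sub in [
            ("lattice", LatticeConfig), ("movie", MovieConfig),
            ("hazard", HazardConfig), ("protection", ProtectionConfig),
            ("contagion", ContagionConfig), ("reporter", ReporterConfig),
            ("migration", MigrationConfig),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


def generate_lattice(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jittered hexagonal-offset grid of nuclei.

    Returns ``(ids, xy, segment_labels)``: integer ids 0..n-1, an (n, 2)
    position array in micrometres, and a segment label per cell (columns
    split into two abdominal segments, 'A2' left / 'A3' right).
    """
    lat = cfg.lattice
    cols = np.arange(lat.n_cols)
    rows = np.arange(lat.n_rows)
    cc, rr = np.meshgrid(cols, rows)
    x = cc * lat.pitch_um + (rr % 2) * lat.pitch_um / 2.0
    y = rr * lat.pitch_um * np.sqrt(3) / 2.0
    xy = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    if lat.jitter_um > 0:
        xy = xy + rng.normal(0.0, lat.jitter_um, size=xy.shape)
    ids = np.arange(xy.shape[0])
    segments = np.where(cc.ravel() < lat.n_cols // 2, "A2", "A3")
    return ids, xy, segments


def _neighbor_lists(xy: np.ndarray, max_dist_factor: float) -> list[np.ndarray]:
    ids = np.arange(xy.shape[0])
    positions = {int(i): tuple(xy[i]) for i in ids}
    cutoff = neighbor_graph.resolve_max_dist(positions, None, max_dist_factor)
    edges = neighbor_graph.prune_edges(
        neighbor_graph.delaunay_edges(positions), positions, cutoff
    )
    nbrs: list[list[int]] = [[] for _ in ids]
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    return [np.asarray(sorted(n), dtype=np.int64) for n in nbrs]


def simulate_elimination(
    xy: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator,
    segments: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-cell death frames under the configured elimination mode.

    Hazards are per-frame Bernoulli with p = rate x frame interval, using
    the early rate before the phase boundary and the late rate after.
    ``protected``: when a cell dies, each surviving neighbor becomes
    refractory (hazard zero) for the refractory period with probability
    ``protection_prob``; deaths within a frame are resolved sequentially in
    random order with refractoriness applied immediately, so a protected
    neighbor can never die concurrently with its protector.  ``contagion``:
    a death multiplies its surviving neighbors' hazard for the contagion
    window (boosts act from the following frame; contagious deaths within
    one frame are simultaneous).  ``graded`` combines the two, emulating
    the survival-signalling model directly: each neighbor of a dying cell
    either receives the protective pulse (probability ``protection_prob``)
    or, lacking it, is sensitized by the contagion multiplier.  ``random``
    has no neighbor interaction at all.

    Returns ``(fates, truth)`` where ``truth`` records the mode, death
    frames, protected-neighbor pulse events, and (for contagion/graded)
    the potential contagion components (adjacent cells dying within one
    contagion window of each other).
    """
    n = xy.shape[0]
    mov, haz = cfg.movie, cfg.hazard
    dt_h = mov.frame_interval_min / 60.0
    nbrs = _neighbor_lists(xy, cfg.max_dist_factor)

    protection_prob = cfg.protection.protection_prob if cfg.mode in ("protected", "graded") else 0.0
    multiplier = cfg.contagion.multiplier if cfg.mode in ("contagion", "graded") else 1.0

    death_frame = np.full(n, -1, dtype=np.int64)  # -1 = alive at movie end
    refractory_until = np.full(n, -np.inf)        # minutes
    boosted_until = np.full(n, -np.inf)           # minutes
    pulse_events: list[dict] = []                 # protected-neighbor dips

    # refractory duration quantized up to whole frames (inf allowed)
    tau = cfg.protection.refractory_min
    refr_dur = (
        np.inf
        if np.isinf(tau)
        else np.ceil(tau / mov.frame_interval_min) * mov.frame_interval_min
    )
    for f in range(mov.n_frames):
        t_min = f * mov.frame_interval_min
        t_h = mov.start_hAPF + f * dt_h
        base_rate = haz.early_per_hour if t_h < haz.phase_boundary_hAPF else haz.late_per_hour
        p = base_rate * dt_h
        # Per-cell hazard fixed at frame start; same-frame deaths cannot
        # boost each other, only protect (refractoriness is immediate).
        rate = np.where(boosted_until >= t_min, min(p * multiplier, 1.0), p)
        alive = death_frame < 0
        eligible = alive & (refractory_until < t_min)
        draws = np.flatnonzero(eligible & (rng.random(n) < rate))
        if protection_prob > 0:
            rng.shuffle(draws)
        for c in draws:
            if refractory_until[c] >= t_min or death_frame[c] >= 0:
                continue  # protected earlier in this same frame
            death_frame[c] = f
            event_t = (f + 0.5) * mov.frame_interval_min
            if protection_prob > 0 or multiplier != 1.0:
                for nb in nbrs[c]:
                    if death_frame[nb] >= 0:
                        continue
                    if protection_prob > 0 and rng.random() < protection_prob:
                        refractory_until[nb] = max(
                            refractory_until[nb], t_min + refr_dur
                        )
                        pulse_events.append(
                            dict(cell=int(nb), trigger=int(c), event_t_min=float(event_t))
                        )
                    elif multiplier != 1.0:
                        boosted_until[nb] = max(
                            boosted_until[nb], t_min + cfg.contagion.window_min
                        )

    censored = death_frame < 0
    last = np.where(censored, mov.n_frames - 1, death_frame)
    fates = pd.DataFrame(
        dict(
            cell_id=np.arange(n),
            first_frame=0,
            last_frame=last,
            censored=censored,
            x0_um=xy[:, 0],
            y0_um=xy[:, 1],
        )
    ).set_index("cell_id")
    fates.attrs["movie_end_frame"] = mov.n_frames - 1
    fates.attrs["frame_interval_min"] = mov.frame_interval_min

    truth = dict(
        mode=cfg.mode,
        seed=cfg.seed,
        death_frame={int(i): int(d) for i, d in enumerate(death_frame) if d >= 0},
        pulses=[
            dict(
                cell=ev["cell"],
                trigger=ev["trigger"],
                event_t_min=ev["event_t_min"],
                t_start_min=ev["event_t_min"] - cfg.reporter.pulse_lead_min,
                t_end_min=ev["event_t_min"]
                - cfg.reporter.pulse_lead_min
                + cfg.reporter.pulse_duration_min,
            )
            for ev in pulse_events
        ],
    )
    if cfg.mode in ("contagion", "graded"):
        truth["contagion_components"] = _contagion_components(
            death_frame, nbrs, cfg.contagion.window_min, mov.frame_interval_min
        )
    if segments is not None:
        truth["segments"] = {int(i): str(s) for i, s in enumerate(segments)}
    return fates, truth


def _contagion_components(
    death_frame: np.ndarray,
    nbrs: list[np.ndarray],
    window_min: float,
    frame_interval_min: float,
) -> list[list[int]]:
    """Components of 'potential contagion lineage': adjacent cells dying
    within one contagion window of each other.  Any concurrent-death pair
    (margin <= window) is such a link, so detector clusters are always
    subsets of these components."""
    import networkx as nx

    window_frames = window_min / frame_interval_min
    g = nx.Graph()
    for a, nb in enumerate(nbrs):
        if death_frame[a] < 0:
            continue
        for b in nb:
            if b > a and death_frame[b] >= 0 and abs(
                death_frame[a] - death_frame[b]
            ) <= window_frames:
                g.add_edge(int(a), int(b))
    return [sorted(c) for c in nx.connected_components(g)]


def _dip_profile(t: np.ndarray, event_t: float, rep: ReporterConfig) -> np.ndarray:
    """Piecewise-linear ERK-pulse dip: ramp down over the lead-in, hold at
    full depth through the event, recover afterwards."""
    t0 = event_t - rep.pulse_lead_min
    knots_t = np.array(
        [t0, t0 + rep.pulse_duration_min, event_t + rep.pulse_hold_min,
         event_t + rep.pulse_hold_min + rep.pulse_recovery_min]
    )
    knots_v = np.array([0.0, -rep.pulse_amplitude, -rep.pulse_amplitude, 0.0])
    return np.interp(t, knots_t, knots_v, left=0.0, right=0.0)


def synthesize_traces(
    fates: pd.DataFrame,
    cfg: SynthConfig,
    rng: np.random.Generator,
    truth: dict | None = None,
    segments: np.ndarray | None = None,
) -> pd.DataFrame:
    """Reporter traces for every cell: a track table with ``nuclear`` and
    ``cytoplasmic`` channels.

    nuclear = baseline + drift * t + noise, plus injected neighbor dips
    (from the truth's pulse events, protected mode) and a pre-death nuclear
    rise in dying cells.  The cytoplasmic channel is constant.  Traces end
    at each cell's last frame.
    """
    mov, rep = cfg.movie, cfg.reporter
    dt = mov.frame_interval_min
    rows = []
    pulse_by_cell: dict[int, list[float]] = {}
    for ev in (truth or {}).get("pulses", []):
        pulse_by_cell.setdefault(int(ev["cell"]), []).append(float(ev["event_t_min"]))

    midline = cfg.migration.midline_y_um
    if midline is None:
        midline = float(fates["y0_um"].mean())

    for cid in fates.index:
        last = int(fates.at[cid, "last_frame"])
        frames = np.arange(int(fates.at[cid, "first_frame"]), last + 1)
        t = frames * dt
        nuclear = rep.baseline + rep.drift_per_hour * t / 60.0
        for event_t in pulse_by_cell.get(int(cid), []):
            nuclear = nuclear + _dip_profile(t, event_t, rep)
        if not fates.at[cid, "censored"] and rep.predeath_rise > 0:
            t_death = (last + 0.5) * dt
            nuclear = nuclear + np.interp(
                t, [t_death - rep.predeath_rise_min, t_death],
                [0.0, rep.predeath_rise], left=0.0,
            )
        if rep.noise_sd > 0:
            nuclear = nuclear + rng.normal(0.0, rep.noise_sd, size=t.size)
        nuclear = np.maximum(nuclear, 0.0)

        x0, y0 = fates.at[cid, "x0_um"], fates.at[cid, "y0_um"]
        x = np.full(t.size, x0)
        y = np.full(t.size, y0)
        if cfg.migration.enabled:
            step = cfg.migration.speed_um_per_hour * dt / 60.0
            drift = np.minimum(np.arange(t.size) * step, abs(y0 - midline))
            y = y0 + np.sign(midline - y0) * drift
        for k in range(t.size):
            rows.append(
                (cid, int(frames[k]), float(t[k]), float(x[k]), float(y[k]),
                 float(nuclear[k]), float(rep.cytoplasmic))
            )
    tracks = pd.DataFrame(
        rows, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "nuclear", "cytoplasmic"]
    )
    if segments is not None:
        tracks["segment_label"] = tracks["cell_id"].map(
            {int(i): str(s) for i, s in enumerate(segments)}
        )
    tracks.attrs["frame_interval_min"] = dt
    return tracks


def generate_movie(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end synthetic movie: ``(tracks, fates, truth)``, deterministic
    under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    ids, xy, segments = generate_lattice(cfg, rng)
    fates, truth = simulate_elimination(xy, cfg, rng, segments)
    tracks = synthesize_traces(fates, cfg, rng, truth, segments)
    return tracks, fates, truth


def write_fixture(cfg: SynthConfig, out_dir) -> dict[str, Path]:
    """Emit a spot table, a truth file and a config echo into ``out_dir``.

    The spot table uses the standard dialect read by
    :func:`apoclust.track_io.read_spot_table`; the truth file records the
    generating mode, the true death frames, injected pulse windows and (for
    contagion) the true cluster memberships for test assertions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, fates, truth = generate_movie(cfg)
    paths = {
        "spot_table": out / "spot_table.csv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    track_io.write_spot_table(tracks, paths["spot_table"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return paths
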