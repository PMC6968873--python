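"""Synthetic multi-session fluorescence studies with planted structure.

Emulates the design of a longitudinal two-photon calcium-imaging experiment:
the same field of view is revisited over days to weeks, cells are tracked
across sessions, and ~10 minutes of spontaneous activity are recorded per
session at ~30 Hz.  The generator plants the statistical structure the
analysis pipeline is meant to recover:

* hierarchically modular correlation structure (cells share smooth latent
  signals at every level of a branching hierarchy),
* spatially compact modules (positions scatter around module centers),
* gradual day-to-day reorganization (non-core cells drift to other modules
  with a per-day probability),
* partial cell overlap between sessions (independent dropout), and
* a small persistent core whose module membership never drifts.

Traces are in arbitrary fluorescence units (per-cell affine gain/offset is
applied); the downstream pipeline is invariant to that scaling because it
correlates differenced traces.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("spontnet")

__all__ = [
    "SyntheticConfig",
    "FluorescenceSession",
    "GroundTruth",
    "generate_study",
    "summarize_study",
    "save_study",
    "load_study",
    "write_metadata_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated experiment: 5 sessions spread over two
    weeks, 10 min of activity at 30 Hz per session (18000 frames), a
    two-level module hierarchy (2 coarse modules each split in 2), a ~20%
    stable core, and mild day-to-day drift and dropout.
    """

    n_cells: int = 150
    n_sessions: int = 5
    day_offsets: tuple[int, ...] = (0, 3, 7, 10, 14)
    n_frames: int = 18000
    sampling_rate_hz: float = 30.0
    hierarchy_branching: tuple[int, ...] = (2, 2)
    signal_strength_per_level: tuple[float, ...] = (0.8, 0.6)
    noise_sd: float = 1.0
    core_fraction: float = 0.2
    drift_prob_per_day: float = 0.05
    dropout_prob: float = 0.1
    spatial_module_sd: float = 40.0
    fov_size_um: float = 500.0
    # probability that a drifting cell stays under its coarse parent module
    keep_parent_prob: float = 0.8
    # spread of per-cell drift rates: cell i drifts at drift_prob_per_day
    # times u_i ~ Uniform(1 - h, 1 + h).  Real populations lie on a
    # stability continuum rather than splitting into perfectly stable and
    # uniformly volatile cells; h = 0 recovers homogeneous drift.
    drift_heterogeneity: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if len(self.day_offsets) != self.n_sessions:
            raise ValueError("day_offsets must have length n_sessions")
        if any(b - a < 0 for a, b in zip(self.day_offsets, self.day_offsets[1:])):
            raise ValueError("day_offsets must be nondecreasing")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(self.hierarchy_branching) == 0 or any(
            b < 1 for b in self.hierarchy_branching
        ):
            raise ValueError("hierarchy_branching entries must be >= 1")
        if int(np.prod(self.hierarchy_branching)) > self.n_cells:
            raise ValueError("hierarchy_branching product must be <= n_cells")
        if len(self.signal_strength_per_level) != len(self.hierarchy_branching):
            raise ValueError(
                "signal_strength_per_level must match hierarchy_branching length"
            )
        if not 0.0 <= self.drift_heterogeneity < 1.0:
            raise ValueError("drift_heterogeneity must be in [0, 1)")
        for name in (
            "core_fraction",
            "drift_prob_per_day",
            "dropout_prob",
            "keep_parent_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= w <= 1.0 for w in self.signal_strength_per_level):
            raise ValueError("signal_strength_per_level must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spatial_module_sd < 0:
            raise ValueError("spatial_module_sd must be >= 0")
        if self.fov_size_um <= 0:
            raise ValueError("fov_size_um must be positive")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FluorescenceSession:
    """One recording session: traces, tracked cell ids, positions, day."""

    session_id: str
    day_offset: int
    cell_ids: np.ndarray        # (n,) integer stable cell labels
    positions: np.ndarray       # (n, 2) in micrometers
    traces: np.ndarray          # (n, n_frames) arbitrary fluorescence units
    sampling_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        n = len(self.cell_ids)
        if self.traces.shape[0] != n or self.positions.shape[0] != n:
            raise ValueError("traces/positions row count must equal len(cell_ids)")
        if self.traces.shape[1] < 3:
            raise ValueError("sessions need at least 3 frames")
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids within a session")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class GroundTruth:
    """Planted structure: per-session hierarchical labels, core mask, latents.

    ``labels[s]`` has shape (n_levels, n_cells) with level 0 the coarsest;
    labels are defined for every cell, including cells dropped from session
    ``s``.  ``latents[s][l]`` holds the level-``l`` module signals of session
    ``s`` (one row per module at that level).
    """

    labels: list[np.ndarray]
    core_mask: np.ndarray
    latents: list[list[np.ndarray]]
    config: SyntheticConfig

    def finest_labels(self, session: int) -> np.ndarray:
        return self.labels[session][-1]

    def level_labels(self, session: int, level: int) -> np.ndarray:
        """1-based level (1 = coarsest)."""
        return self.labels[session][level - 1]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _smooth_latent(rng: np.random.Generator, n_frames: int, window: int) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise, standardized to unit variance.

    Smoothing (~0.5 s window) keeps the *differenced* series non-degenerate
    and temporally structured, which is what the jitter null destroys.
    """
    x = rng.standard_normal(n_frames + window)
    kernel = np.ones(window) / window
    y = np.convolve(x, kernel, mode="valid")[:n_frames]
    sd = y.std()
    return y / sd if sd > 0 else y


def _ancestor_labels(finest: np.ndarray, branching: tuple[int, ...]) -> np.ndarray:
    """Stack of labels at every level (coarse -> fine) from finest labels."""
    n_levels = len(branching)
    out = np.empty((n_levels, finest.shape[0]), dtype=int)
    for lvl in range(n_levels):
        div = int(np.prod(branching[lvl + 1:])) if lvl + 1 < n_levels else 1
        out[lvl] = finest // div
    return out


def _draw_dropout(
    rng: np.random.Generator, config: SyntheticConfig
) -> list[np.ndarray]:
    """Independent per-session presence masks; every session pair must share
    at least 10 cells (or the whole pattern is redrawn, up to 100 attempts)."""
    min_shared = min(10, config.n_cells)
    for _ in range(100):
        present = [
            rng.random(config.n_cells) >= config.dropout_prob
            for _ in range(config.n_sessions)
        ]
        ok = all(
            int(np.sum(present[u] & present[v])) >= min_shared
            for u in range(config.n_sessions)
            for v in range(u + 1, config.n_sessions)
        )
        if ok:
            return present
    raise RuntimeError(
        "dropout left a session pair with fewer than 10 shared cells "
        "after 100 redraw attempts"
    )


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[FluorescenceSession], GroundTruth]:
    """Generate a multi-session study with planted hierarchical modules.

    Deterministic given ``config`` (all randomness flows from
    ``config.seed`` through fixed substreams).  Each cell's trace is a
    weighted sum of its modules' latent signals across hierarchy levels,
    plus white observation noise, passed through a per-cell affine map to
    arbitrary fluorescence units.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed substreams: structure, dropout, then one per session
    keys = root.spawn(2 + config.n_sessions)
    rng_struct = np.random.default_rng(keys[0])
    rng_drop = np.random.default_rng(keys[1])

    branching = tuple(int(b) for b in config.hierarchy_branching)
    n_fine = int(np.prod(branching))
    n_levels = len(branching)
    n = config.n_cells

    # base assignment: cells spread as evenly as possible over finest modules
    base_finest = rng_struct.permutation(np.arange(n) % n_fine)

    # The core is a coherent, persistently co-active assembly: its cells are
    # drawn from as few finest modules as possible so that they stay strongly
    # correlated with *one another* across sessions (a scattering of
    # individually stable cells would share no edges and would not form a
    # temporal core in the network sense).
    n_core = int(round(config.core_fraction * n))
    module_order = rng_struct.permutation(n_fine)
    pool = np.concatenate(
        [
            rng_struct.permutation(np.flatnonzero(base_finest == m))
            for m in module_order
        ]
    )
    core_mask = np.zeros(n, dtype=bool)
    core_mask[pool[:n_core]] = True

    # spatial layout: finest-module centers inside the field of view
    centers = rng_struct.uniform(
        0.15 * config.fov_size_um, 0.85 * config.fov_size_um, size=(n_fine, 2)
    )
    positions = centers[base_finest] + rng_struct.normal(
        0.0, config.spatial_module_sd, size=(n, 2)
    )
    positions = np.clip(positions, 0.0, config.fov_size_um)

    # arbitrary-unit affine map per cell
    gains = rng_struct.uniform(0.5, 1.5, size=n)
    offsets = rng_struct.uniform(0.0, 100.0, size=n)

    # Module labels evolve session to session (drift for non-core cells
    # only).  Drifting cells reorganize among *peripheral* modules: the core
    # assembly is closed, so modules hosting core cells are not drift
    # targets (otherwise transient visitors would acquire spurious
    # persistent coupling to the core).
    core_modules = set(np.unique(base_finest[core_mask]).tolist())
    open_modules = np.array(
        [m for m in range(n_fine) if m not in core_modules], dtype=int
    )
    if open_modules.size == 0:
        open_modules = np.arange(n_fine)

    h = config.drift_heterogeneity
    cell_rate = config.drift_prob_per_day * rng_struct.uniform(1 - h, 1 + h, size=n)

    finest_per_session: list[np.ndarray] = []
    finest = base_finest.copy()
    b_last = branching[-1]
    for s in range(config.n_sessions):
        if s > 0:
            gap = config.day_offsets[s] - config.day_offsets[s - 1]
            p_drift = 1.0 - (1.0 - np.clip(cell_rate, 0, 1)) ** gap
            drifts = (rng_struct.random(n) < p_drift) & ~core_mask
            for i in np.flatnonzero(drifts):
                if rng_struct.random() < config.keep_parent_prob and b_last > 1:
                    parent = finest[i] // b_last
                    siblings = parent * b_last + np.arange(b_last)
                    cand = siblings[np.isin(siblings, open_modules)]
                else:
                    cand = open_modules
                if cand.size == 0:
                    cand = open_modules
                finest[i] = int(cand[rng_struct.integers(cand.size)])
        finest_per_session.append(finest.copy())

    present = _draw_dropout(rng_drop, config)

    window = max(1, int(round(0.5 * config.sampling_rate_hz)))
    weights = np.asarray(config.signal_strength_per_level, dtype=float)

    sessions: list[FluorescenceSession] = []
    all_labels: list[np.ndarray] = []
    all_latents: list[list[np.ndarray]] = []
    for s in range(config.n_sessions):
        rng_s = np.random.default_rng(keys[2 + s])
        labels = _ancestor_labels(finest_per_session[s], branching)
        all_labels.append(labels)

        # independent smooth latent signals, redrawn per session
        latents_s: list[np.ndarray] = []
        for lvl in range(n_levels):
            n_mod = int(np.prod(branching[: lvl + 1]))
            latents_s.append(
                np.vstack(
                    [
                        _smooth_latent(rng_s, config.n_frames, window)
                        for _ in range(n_mod)
                    ]
                )
            )
        all_latents.append(latents_s)

        signal = np.zeros((n, config.n_frames))
        for lvl in range(n_levels):
            signal += weights[lvl] * latents_s[lvl][labels[lvl]]
        traces = signal + config.noise_sd * rng_s.standard_normal(
            (n, config.n_frames)
        )
        traces = gains[:, None] * traces + offsets[:, None]

        idx = np.flatnonzero(present[s])
        sessions.append(
            FluorescenceSession(
                session_id=f"ses-{s:02d}",
                day_offset=int(config.day_offsets[s]),
                cell_ids=idx.copy(),
                positions=positions[idx],
                traces=traces[idx],
                sampling_rate_hz=config.sampling_rate_hz,
            )
        )

    truth = GroundTruth(
        labels=all_labels, core_mask=core_mask, latents=all_latents, config=config
    )
    return sessions, truth


# ---------------------------------------------------------------------------
# summaries and I/O
# ---------------------------------------------------------------------------

def summarize_study(sessions: list[FluorescenceSession]) -> dict[str, pd.DataFrame]:
    """Per-session cell counts plus pairwise shared-cell counts and day gaps."""
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    per_session = pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "day_offset": [s.day_offset for s in sessions],
            "n_cells": [s.n_cells for s in sessions],
        }
    )
    rows = []
    for u, su in enumerate(sessions):
        for v in range(u, len(sessions)):
            sv = sessions[v]
            shared = np.intersect1d(su.cell_ids, sv.cell_ids)
            rows.append(
                {
                    "u": su.session_id,
                    "v": sv.session_id,
                    "n_shared": len(shared),
                    "day_gap": abs(sv.day_offset - su.day_offset),
                }
            )
    return {"sessions": per_session, "pairs": pd.DataFrame(rows)}


def save_study(
    path,
    sessions: list[FluorescenceSession],
    truth: GroundTruth | None = None,
) -> None:
    """Write a study to one HDF5 container (sessions + optional ground truth)."""
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("sessions")
        for s in sessions:
            g = grp.create_group(s.session_id)
            g.attrs["day_offset"] = s.day_offset
            g.attrs["sampling_rate_hz"] = s.sampling_rate_hz
            g.create_dataset("cell_ids", data=np.asarray(s.cell_ids, dtype=np.int64))
            g.create_dataset("positions", data=s.positions)
            g.create_dataset("traces", data=s.traces)
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("core_mask", data=truth.core_mask)
            for i, lab in enumerate(truth.labels):
                g.create_dataset(f"labels/{i:02d}", data=lab)
            g.attrs["config"] = json.dumps(dataclasses.asdict(truth.config))


def load_study(path) -> tuple[list[FluorescenceSession], GroundTruth | None]:
    import h5py

    sessions: list[FluorescenceSession] = []
    truth = None
    with h5py.File(path, "r") as f:
        for sid in sorted(f["sessions"]):
            g = f["sessions"][sid]
            sessions.append(
                FluorescenceSession(
                    session_id=sid,
                    day_offset=int(g.attrs["day_offset"]),
                    cell_ids=g["cell_ids"][()],
                    positions=g["positions"][()],
                    traces=g["traces"][()],
                    sampling_rate_hz=float(g.attrs.get("sampling_rate_hz", 30.0)),
                )
            )
        if "ground_truth" in f:
            g = f["ground_truth"]
            cfg_raw = json.loads(g.attrs["config"])
            for key in (
                "day_offsets",
                "hierarchy_branching",
                "signal_strength_per_level",
            ):
                cfg_raw[key] = tuple(cfg_raw[key])
            labels = [
                g[f"labels/{name}"][()] for name in sorted(g["labels"])
            ]
            truth = GroundTruth(
                labels=labels,
                core_mask=g["core_mask"][()].astype(bool),
                latents=[],
                config=SyntheticConfig(**cfg_raw),
            )
    sessions.sort(key=lambda s: s.day_offset)
    return sessions, truth


def write_metadata_csv(sessions: list[FluorescenceSession], path) -> pd.DataFrame:
    """Cell-metadata table: cell_id, session_id, day_offset, x_um, y_um."""
    rows = []
    for s in sessions:
        for cid, (x, y) in zip(s.cell_ids, s.positions):
            rows.append(
                {
                    "cell_id": int(cid),
                    "session_id": s.session_id,
                    "day_offset": s.day_offset,
                    "x_um": float(x),
                    "y_um": float(y),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
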