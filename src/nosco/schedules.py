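"""Complementary non-uniform sampling schedules for titration series.

The full indirect-dimension grid of N1 t1 increments is divided among the
n_x points of a titration series so that each ligand-to-protein ratio owns
a unique, disjoint set of t1 indices ("partition" mode: the union is the
whole grid, e.g. 256 increments -> 8 schedules of 32 points).  In
"undersampled" mode each schedule draws only a fraction of its share and
the union is a strict subset of the grid (a hook for compressed-sensing
reconstruction, which this package does not implement).

Indices are 0-based everywhere, including nuslist files (one index per
line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingScheduleSet",
    "make_complementary_schedules",
    "x_of_t1",
    "write_nuslist",
    "read_nuslist",
    "write_schedule_manifest",
    "read_schedule_manifest",
]


@dataclass
class SamplingScheduleSet:
    """n_x pairwise-disjoint t1 index sets, one per titration point.

    ``schedules[k]`` is a sorted array of 0-based t1 grid indices owned by
    titration point k; ``x_per_schedule[k]`` is the ligand-to-protein ratio
    bound to it (schedules are bound in increasing-x order, mirroring the
    physical titration).  ``x_per_schedule`` may be ``None`` until bound
    via :meth:`with_x`.
    """

    grid_size: int
    schedules: list[np.ndarray]
    mode: str = "partition"
    seed: int = 0
    x_per_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("partition", "undersampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.schedules = [
            np.sort(np.asarray(s, dtype=int)) for s in self.schedules
        ]
        allidx = np.concatenate(self.schedules) if self.schedules else np.array([], int)
        if allidx.size and (allidx.min() < 0 or allidx.max() >= self.grid_size):
            raise ValueError("schedule index outside the t1 grid")
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("schedules are not pairwise disjoint")
        if self.mode == "partition" and allidx.size != self.grid_size:
            raise ValueError("partition-mode schedules must cover the full grid")
        if self.x_per_schedule is not None:
            xv = np.asarray(self.x_per_schedule, dtype=float)
            if len(xv) != self.n_x:
                raise ValueError("x_per_schedule length must equal n_x")
            self.x_per_schedule = xv
        # owner[t1] = schedule index, or -1 if unsampled
        owner = np.full(self.grid_size, -1, dtype=int)
        for k, s in enumerate(self.schedules):
            owner[s] = k
        self._owner = owner

    @property
    def n_x(self) -> int:
        return len(self.schedules)

    def owner_of(self, t1_index: int) -> int:
        """Schedule index owning a t1 grid index, or -1 if unsampled."""
        if not 0 <= t1_index < self.grid_size:
            raise IndexError(
                f"t1 index {t1_index} outside grid [0, {self.grid_size})"
            )
        return int(self._owner[t1_index])

    def with_x(self, x_values) -> "SamplingScheduleSet":
        """Return a copy with schedule k bound to x_values[k]."""
        return SamplingScheduleSet(
            grid_size=self.grid_size,
            schedules=[s.copy() for s in self.schedules],
            mode=self.mode,
            seed=self.seed,
            x_per_schedule=np.asarray(x_values, dtype=float),
        )

    def sampling_levels(self) -> np.ndarray:
        """Per-schedule fraction of the full t1 grid that is sampled."""
        return np.array([len(s) / self.grid_size for s in self.schedules])


def make_complementary_schedules(
    n1: int,
    n_x: int,
    seed: int = 0,
    mode: str = "partition",
    level: float | None = None,
    weighting: str = "uniform",
    decay: float = 2.0,
    x_values=None,
) -> SamplingScheduleSet:
    """Randomly assign the t1 grid to n_x complementary schedules.

    In partition mode the grid is shuffled and dealt round-robin, so n_x
    must divide N1 and every schedule receives exactly N1/n_x indices.  In
    undersampled mode each schedule draws ``level * N1`` indices (without
    replacement, disjoint across schedules), optionally weighted towards
    early t1 times with ``weighting="exponential"`` (weight proportional to
    exp(-decay * t1/N1), the usual NUS bias matching signal decay; ignored
    in partition mode where every index is used anyway).  Deterministic for
    a given seed.
    """
    if n_x < 1 or n1 < n_x:
        raise ValueError("need N1 >= n_x >= 1")
    if weighting not in ("uniform", "exponential"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)

    if mode == "partition":
        if n1 % n_x != 0:
            raise ValueError(
                f"partition mode needs n_x to divide N1; got N1={n1}, "
                f"n_x={n_x} (remainder {n1 % n_x}); pad the grid or use "
                "undersampled mode"
            )
        perm = rng.permutation(n1)
        schedules = [perm[k::n_x] for k in range(n_x)]
    elif mode == "undersampled":
        if level is None:
            raise ValueError("undersampled mode requires a sampling level")
        per = int(round(level * n1))
        if per < 4:
            raise ValueError(
                f"level {level} gives {per} points per schedule; need >= 4"
            )
        if per * n_x > n1:
            raise ValueError("total sampled points exceed the grid")
        if weighting == "exponential":
            w = np.exp(-decay * np.arange(n1) / n1)
        else:
            w = np.ones(n1)
        pool = np.arange(n1)
        schedules = []
        for _ in range(n_x):
            p = w[pool] / w[pool].sum()
            pick = rng.choice(pool, size=per, replace=False, p=p)
            schedules.append(pick)
            pool = np.setdiff1d(pool, pick)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ss = SamplingScheduleSet(
        grid_size=n1, schedules=schedules, mode=mode, seed=seed
    )
    if x_values is not None:
        ss = ss.with_x(x_values)
    return ss


def x_of_t1(schedule_set: SamplingScheduleSet, t1_index: int):
    """Ligand-to-protein ratio sampled at a t1 grid index.

    Returns the x bound to the unique schedule owning the index, or
    ``None`` for indices left unsampled in undersampled mode.
    """
    k = schedule_set.owner_of(t1_index)
    if k < 0:
        return None
    if schedule_set.x_per_schedule is None:
        raise ValueError("schedule set has no bound x values; use with_x()")
    return float(schedule_set.x_per_schedule[k])


def write_nuslist(schedule, path) -> None:
    """Write one schedule as a nuslist file: one 0-based t1 index per line."""
    idx = np.asarray(schedule, dtype=int)
    Path(path).write_text("".join(f"{i}\n" for i in idx))


def read_nuslist(path) -> np.ndarray:
    """Read a nuslist file, preserving order; rejects junk and duplicates."""
    seen: set[int] = set()
    out: list[int] = []
    lines = Path(path).read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s:
            continue
        try:
            i = int(s)
        except ValueError:
            raise ValueError(f"{path}: line {ln}: not an index: {raw!r}") from None
        if i < 0:
            raise ValueError(f"{path}: line {ln}: negative index {i}")
        if i in seen:
            raise ValueError(f"{path}: line {ln}: duplicate index {i}")
        seen.add(i)
        out.append(i)
    if not out:
        raise ValueError(f"{path}: empty nuslist")
    return np.array(out, dtype=int)


def write_schedule_manifest(schedule_set: SamplingScheduleSet, directory) -> Path:
    """Write per-schedule nuslist files plus a JSON manifest.

    The manifest records grid size, mode, seed, per-schedule file names and
    bound x values; nuslist files are named ``nuslist_00.txt`` etc.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = []
    for k, s in enumerate(schedule_set.schedules):
        name = f"nuslist_{k:02d}.txt"
        write_nuslist(s, d / name)
        names.append(name)
    manifest = {
        "grid_size_N1": schedule_set.grid_size,
        "mode": schedule_set.mode,
        "seed": schedule_set.seed,
        "nuslists": names,
        "x_values": (
            None
            if schedule_set.x_per_schedule is None
            else [float(v) for v in schedule_set.x_per_schedule]
        ),
    }
    path = d / "schedule_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_schedule_manifest(path) -> SamplingScheduleSet:
    p = Path(path)
    m = json.loads(p.read_text())
    schedules = [read_nuslist(p.parent / name) for name in m["nuslists"]]
    return SamplingScheduleSet(
        grid_size=m["grid_size_N1"],
        schedules=schedules,
        mode=m["mode"],
        seed=m["seed"],
        x_per_schedule=None if m["x_values"] is None else np.array(m["x_values"]),
    )
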