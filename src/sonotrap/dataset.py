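"""Time-reversal training-data collection, splitting and CSV persistence.

A dataset row pairs a target position ``P`` with the per-element time of
flight ``T`` (microseconds) and arrival amplitude ``A`` (Pa) recorded when a
point source at ``P`` emits and the array elements receive.  The element
positions ``p`` are constant per dataset and stored in the file header.

CSV schema (exact column order)::

    target_x_mm, target_y_mm, tof_e1..e{n}_us, amp_e1..e{n}_pa, split

with '#'-prefixed metadata lines carrying frequency, element count and
centres, sample density and the split seed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sonotrap.phantom import ArrayGeometry, SamplingPlan, TissueMap
from sonotrap.wavesim import (SimulationConfig, amplitude_at,
                              element_response, tof_map)

__all__ = [
    "Sample",
    "TrainingDataset",
    "build_dataset",
    "subsample_density",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

log = logging.getLogger(__name__)

SPLIT_LABELS = ("train", "validation", "holdout")
#: hold-out / validation / train fractions used throughout the study
DEFAULT_FRACTIONS = (0.745, 0.13, 0.125)


@dataclass
class Sample:
    """One (target, ToF vector, amplitude vector) record."""

    target: np.ndarray            # (2,) mm
    tof: np.ndarray               # (n,) us
    amplitude: np.ndarray         # (n,) Pa
    split_label: str | None = None
    grid_index: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.tof = np.asarray(self.tof, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.tof.shape != self.amplitude.shape:
            raise ValueError("tof and amplitude must have the same length")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be strictly positive")
        if self.split_label is not None and self.split_label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {self.split_label!r}")


@dataclass
class TrainingDataset:
    """A collection of samples sharing one array geometry."""

    samples: list[Sample]
    density: float                       # D, samples per mm
    element_positions: np.ndarray        # (n, 2) mm
    frequency_mhz: float = 1.0
    seed: int | None = None              # split seed, if split

    @property
    def m(self) -> int:
        return len(self.samples)

    @property
    def n(self) -> int:
        return len(self.element_positions)

    def targets(self) -> np.ndarray:
        return np.array([s.target for s in self.samples]).reshape(-1, 2)

    def tof_matrix(self) -> np.ndarray:
        return np.array([s.tof for s in self.samples]).reshape(-1, self.n)

    def amplitude_matrix(self) -> np.ndarray:
        return np.array([s.amplitude for s in self.samples]).reshape(-1, self.n)

    def subset(self, label: str) -> "TrainingDataset":
        if label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {label!r}")
        return TrainingDataset(
            samples=[s for s in self.samples if s.split_label == label],
            density=self.density, element_positions=self.element_positions,
            frequency_mhz=self.frequency_mhz, seed=self.seed)

    def split_counts(self) -> dict[str, int]:
        out = {k: 0 for k in SPLIT_LABELS + (None,)}
        for s in self.samples:
            out[s.split_label] += 1
        return out


def build_dataset(tissue_map: TissueMap, array: ArrayGeometry,
                  plan: SamplingPlan, cfg: SimulationConfig | None = None,
                  element_tof_maps=None) -> TrainingDataset:
    """Collect one sample per planned target via time reversal.

    Uses transmission reciprocity: one travel-time solve per *element*
    (n total), each read at every target, instead of one solve per target.
    Targets outside the map are skipped with a logged warning.
    """
    cfg = cfg or SimulationConfig()
    if len(plan) == 0:
        raise ValueError("empty sampling plan")
    if element_tof_maps is None:
        element_tof_maps = [tof_map(tissue_map, c) for c in array.centers]
    if len(element_tof_maps) != array.n:
        raise ValueError("need one travel-time map per element")
    tof_cols = []
    inside = []
    for t in plan.targets:
        inside.append(tissue_map.contains_point(t))
        if not inside[-1]:
            log.warning("target %s outside map: skipped", tuple(t))
    inside = np.asarray(inside)
    kept = plan.targets[inside]
    kept_idx = plan.grid_index[inside]
    tof_cols = np.column_stack([tm.at(kept) for tm in element_tof_maps])
    amp_cols = np.column_stack([
        np.array([amplitude_at(tissue_map, t, c, cfg.source_amplitude, cfg)
                  for t in kept])
        for c in array.centers])
    if cfg.directivity:
        amp_cols = amp_cols * np.column_stack([
            element_response(array, j, kept, cfg) for j in range(array.n)])
    samples = []
    for i, tgt in enumerate(kept):
        amps = amp_cols[i]
        samples.append(Sample(target=tgt, tof=tof_cols[i], amplitude=amps,
                              grid_index=(int(kept_idx[i, 0]), int(kept_idx[i, 1]))))
    return TrainingDataset(samples=samples, density=plan.density,
                           element_positions=array.centers.copy(),
                           frequency_mhz=cfg.frequency)


def subsample_density(ds: TrainingDataset, factor: int) -> TrainingDataset:
    """Keep every ``factor``-th grid position along both plan axes.

    Requires samples built from a grid plan (grid indices recorded); the
    resulting sample density is ``D / factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("subsampling factor must be a positive integer")
    if factor == 1:
        return ds
    kept = []
    for s in ds.samples:
        if s.grid_index is None:
            raise ValueError("dataset was not built from a grid plan")
        col, row = s.grid_index
        if col % factor == 0 and row % factor == 0:
            kept.append(s)
    if not kept:
        warnings.warn(f"subsampling by {factor} leaves an empty dataset")
    return TrainingDataset(samples=kept, density=ds.density / factor,
                           element_positions=ds.element_positions,
                           frequency_mhz=ds.frequency_mhz, seed=ds.seed)


def split_counts(m: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """(train, validation, holdout) counts for ``m`` samples.

    Hold-out and validation are rounded to nearest; train takes the
    remainder.  With m = 920 and the default 74.5/13/12.5 fractions this
    yields 685/120/115.
    """
    f_train, f_val, f_hold = fractions
    if min(fractions) < 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    n_hold = int(round(m * f_hold))
    n_val = int(round(m * f_val))
    n_train = m - n_val - n_hold
    if n_train < 0:
        raise ValueError("fractions leave no training samples")
    return n_train, n_val, n_hold


def split_dataset(ds: TrainingDataset,
                  fractions: Sequence[float] = DEFAULT_FRACTIONS,
                  seed: int = 0, mode: str = "random") -> TrainingDataset:
    """Assign train/validation/holdout labels by a seeded uniform shuffle.

    ``mode="spatial"`` replaces the shuffle with a deterministic
    every-k-th-sample assignment (ablation aid); counts are identical.
    """
    if ds.m < 3:
        raise ValueError("need at least 3 samples to split")
    n_train, n_val, n_hold = split_counts(ds.m, fractions)
    labels = np.empty(ds.m, dtype=object)
    if mode == "random":
        order = np.random.default_rng(seed).permutation(ds.m)
        labels[order[:n_train]] = "train"
        labels[order[n_train:n_train + n_val]] = "validation"
        labels[order[n_train + n_val:]] = "holdout"
    elif mode == "spatial":
        # deterministic interleave: hold-out samples evenly spread in plan
        # order, then validation evenly spread over the remainder
        labels[:] = "train"
        hold_idx = np.unique(np.round(np.linspace(0, ds.m - 1, n_hold)).astype(int)) \
            if n_hold else np.array([], dtype=int)
        labels[hold_idx] = "holdout"
        rest = np.flatnonzero(labels == "train")
        val_pos = np.unique(np.round(np.linspace(0, len(rest) - 1, n_val)).astype(int)) \
            if n_val else np.array([], dtype=int)
        labels[rest[val_pos]] = "validation"
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    new_samples = [replace(s, split_label=lab)
                   for s, lab in zip(ds.samples, labels)]
    return TrainingDataset(samples=new_samples, density=ds.density,
                           element_positions=ds.element_positions,
                           frequency_mhz=ds.frequency_mhz, seed=seed)


def _dataframe(ds: TrainingDataset) -> pd.DataFrame:
    n = ds.n
    cols: dict[str, np.ndarray] = {
        "target_x_mm": ds.targets()[:, 0],
        "target_y_mm": ds.targets()[:, 1],
    }
    tofm = ds.tof_matrix()
    ampm = ds.amplitude_matrix()
    for j in range(n):
        cols[f"tof_e{j + 1}_us"] = tofm[:, j]
    for j in range(n):
        cols[f"amp_e{j + 1}_pa"] = ampm[:, j]
    cols["split"] = np.array(
        [s.split_label or "" for s in ds.samples], dtype=object)
    return pd.DataFrame(cols)


def write_dataset(ds: TrainingDataset, path) -> None:
    """Write the dataset CSV with a '#'-prefixed metadata header block."""
    path = Path(path)
    centers = ";".join(f"{c[0]:.9g},{c[1]:.9g}" for c in ds.element_positions)
    grid = ";".join(
        "" if s.grid_index is None else f"{s.grid_index[0]},{s.grid_index[1]}"
        for s in ds.samples)
    header = [
        f"# frequency_mhz: {ds.frequency_mhz:.9g}",
        f"# n_elements: {ds.n}",
        f"# element_centers_mm: {centers}",
        f"# density_per_mm: {ds.density:.12g}",
        f"# seed: {'' if ds.seed is None else ds.seed}",
        f"# grid_index: {grid}",
    ]
    buf = io.StringIO()
    _dataframe(ds).to_csv(buf, index=False, float_format="%.17g")
    path.write_text("\n".join(header) + "\n" + buf.getvalue())


def read_dataset(path) -> TrainingDataset:
    """Read a dataset CSV written by :func:`write_dataset` (lossless)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise ValueError(f"malformed metadata at line {lineno}: {line!r}")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    n = int(meta["n_elements"])
    centers = np.array([[float(v) for v in pair.split(",")]
                        for pair in meta["element_centers_mm"].split(";")])
    if centers.shape != (n, 2):
        raise ValueError("element_centers_mm inconsistent with n_elements")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)),
                     keep_default_na=False, dtype={"split": str},
                     float_precision="round_trip")
    expected = (["target_x_mm", "target_y_mm"]
                + [f"tof_e{j + 1}_us" for j in range(n)]
                + [f"amp_e{j + 1}_pa" for j in range(n)]
                + ["split"])
    for col in expected:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} for n={n}")
    if list(df.columns) != expected:
        raise ValueError("unexpected column order or extra columns")
    grid_raw = meta.get("grid_index", "")
    grid = [None if g == "" else tuple(int(v) for v in g.split(","))
            for g in grid_raw.split(";")] if grid_raw else [None] * len(df)
    samples = []
    for i, row in df.iterrows():
        samples.append(Sample(
            target=np.array([row["target_x_mm"], row["target_y_mm"]]),
            tof=np.array([row[f"tof_e{j + 1}_us"] for j in range(n)]),
            amplitude=np.array([row[f"amp_e{j + 1}_pa"] for j in range(n)]),
            split_label=row["split"] or None,
            grid_index=grid[i] if i < len(grid) else None))
    seed_raw = meta.get("seed", "")
    return TrainingDataset(samples=samples,
                           density=float(meta["density_per_mm"]),
                           element_positions=centers,
                           frequency_mhz=float(meta["frequency_mhz"]),
                           seed=int(seed_raw) if seed_raw else None)
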