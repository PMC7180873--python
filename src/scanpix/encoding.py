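"""Coordinates-based view transformation: scanpath -> PI / MI / LI images.

A scanpath is rendered into three 3-channel rasters by depositing, at the
grid cell each fixation falls in, quantities describing how the gaze arrived
there:

* **PI** (punctual information): the arrival angle theta of the last saccade,
  the distance from the previous fixation (r-1), and the fixation duration.
* **MI** (mean information): the distances from the fixations 2 and 3 steps
  back (r-2, r-3) and the lead time — the summed duration of the 3
  preceding fixations.
* **LI** (long information): r-5, r-10 and the lead time over the 10
  preceding fixations.

Each channel is then scaled so that its maximum deposited value maps to
``normalization_constant`` (255 by default), producing unsigned 8-bit
planes suitable as CNN input.  Cells no fixation maps to stay 0.

Conventions where the gaze history is too short: theta, r-k and lead time
are 0 when the required predecessors do not exist (0 is the no-information
raster value).  The arrival angle uses the two-argument arctangent of
(delta-y, delta-x) — range (-pi, pi] — since a single-argument arctan of the
slope cannot distinguish direction; it is shifted by +pi before
normalization so every deposited angle is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image

from .fixation_io import FixationRecord, Scanpath

logger = logging.getLogger(__name__)

CollisionPolicy = Literal["max", "last", "sum"]

#: Channel semantics per image, in file channel order.
CHANNEL_LAYOUT: dict[str, tuple[str, str, str]] = {
    "PI": ("theta", "r-1", "duration"),
    "MI": ("r-2", "r-3", "leadtime-3"),
    "LI": ("r-5", "r-10", "leadtime-10"),
}

IMAGE_KINDS = ("PI", "MI", "LI")


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the view transformation."""

    grid_dims: tuple[int, int] = (224, 224)  # (width, height)
    screen_dims: tuple[int, int] = (1920, 1080)
    normalization_constant: int = 255
    lead_time_windows: tuple[int, int] = (3, 10)  # (n for MI, n for LI)
    lag_set_mi: tuple[int, int] = (2, 3)
    lag_set_li: tuple[int, int] = (5, 10)
    collision_policy: CollisionPolicy = "max"
    #: normalize theta by the observed per-image maximum (like every other
    #: channel) or by the fixed full range 2*pi
    theta_fixed_range: bool = False

    def __post_init__(self) -> None:
        if min(self.grid_dims) <= 0 or min(self.screen_dims) <= 0:
            raise ValueError("grid and screen dimensions must be positive")
        if not 1 <= self.normalization_constant <= 255:
            raise ValueError("normalization_constant must be in [1, 255]")
        lags = self.lag_set_mi + self.lag_set_li + self.lead_time_windows
        if any(k < 1 for k in lags):
            raise ValueError("lags and window sizes must be positive integers")
        if self.collision_policy not in ("max", "last", "sum"):
            raise ValueError(f"unknown collision policy {self.collision_policy!r}")


@dataclass
class EncodedImageSet:
    """The three rasters encoding one scanpath, plus provenance."""

    pi: np.ndarray  # (H, W, 3) uint8
    mi: np.ndarray
    li: np.ndarray
    subject: str = ""
    stimulus: str = ""
    label: str | None = None

    def images(self) -> dict[str, np.ndarray]:
        return {"PI": self.pi, "MI": self.mi, "LI": self.li}


def compute_angle(p_prev: tuple[float, float], p_curr: tuple[float, float]) -> float:
    """Arrival angle at ``p_curr`` coming from ``p_prev``, in radians.

    Two-argument arctangent of (dy, dx) with screen coordinates (x right,
    y down); range (-pi, pi].  Coincident points return 0 by convention.
    """
    dx = p_curr[0] - p_prev[0]
    dy = p_curr[1] - p_prev[1]
    if dx == 0 and dy == 0:
        logger.debug("coincident fixations %s; angle set to 0", p_curr)
        return 0.0
    return math.atan2(dy, dx)


def compute_lag_distance(scanpath: Scanpath, i: int, k: int) -> float:
    """Euclidean distance between fixation ``i`` and fixation ``i - k``.

    Returns 0 when fixation ``i`` has no ``k``-th predecessor.
    """
    if not 0 <= i < len(scanpath):
        raise IndexError(f"fixation index {i} out of range [0, {len(scanpath)})")
    if k < 1:
        raise ValueError("lag k must be >= 1")
    if i < k:
        return 0.0
    a, b = scanpath.records[i], scanpath.records[i - k]
    return math.hypot(a.x - b.x, a.y - b.y)


def compute_lead_time(scanpath: Scanpath, i: int, n: int) -> float:
    """Sum of the durations of the ``min(n, i)`` fixations preceding ``i``."""
    if not 0 <= i < len(scanpath):
        raise IndexError(f"fixation index {i} out of range [0, {len(scanpath)})")
    if n < 1:
        raise ValueError("window size n must be >= 1")
    start = max(0, i - n)
    return float(sum(r.duration_ms for r in scanpath.records[start:i]))


def map_to_grid(
    record: FixationRecord,
    screen_dims: tuple[int, int],
    grid_dims: tuple[int, int],
) -> tuple[int, int]:
    """Map a validated screen coordinate to its (column, row) grid cell.

    ``column = floor(x * grid_w / screen_w)`` and likewise for the row; an
    in-bounds screen coordinate always lands in an in-bounds cell, and with
    ``grid_dims == screen_dims`` the mapping is the identity.
    """
    sw, sh = screen_dims
    gw, gh = grid_dims
    col = int(record.x * gw // sw)
    row = int(record.y * gh // sh)
    return col, row


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (values >= 0)."""
    return np.floor(values + 0.5)


def normalize_channel(
    values: np.ndarray,
    config: EncodingConfig,
    *,
    max_data: float | None = None,
) -> np.ndarray:
    """Scale a non-negative channel so its maximum maps to the scale ceiling.

    ``NData = Data * NormalizationConstant / MaxData`` where ``MaxData`` is
    the channel maximum (or a fixed ceiling, e.g. 2*pi for the angle channel
    in fixed-range mode), then rounded to integers.  An all-zero channel is
    returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("normalize_channel requires non-negative input")
    peak = float(values.max()) if max_data is None else float(max_data)
    if peak == 0:
        return np.zeros_like(values, dtype=np.uint8)
    scaled = values * (config.normalization_constant / peak)
    return _round_half_away(scaled).astype(np.uint8)


def _raw_channels(scanpath: Scanpath, config: EncodingConfig) -> dict[str, list[float]]:
    """Per-fixation raw values for all nine channels."""
    n_mi, n_li = config.lead_time_windows
    lags = {
        "r-1": 1,
        "r-2": config.lag_set_mi[0],
        "r-3": config.lag_set_mi[1],
        "r-5": config.lag_set_li[0],
        "r-10": config.lag_set_li[1],
    }
    out: dict[str, list[float]] = {name: [] for names in CHANNEL_LAYOUT.values() for name in names}
    pts = scanpath.xy()
    for i, rec in enumerate(scanpath.records):
        if i == 0:
            theta = 0.0
        else:
            # shift (-pi, pi] -> (0, 2*pi] so the raster stays non-negative
            theta = compute_angle(pts[i - 1], pts[i]) + math.pi
        out["theta"].append(theta)
        for name, k in lags.items():
            out[name].append(compute_lag_distance(scanpath, i, k))
        out["duration"].append(rec.duration_ms)
        out["leadtime-3"].append(compute_lead_time(scanpath, i, n_mi))
        out["leadtime-10"].append(compute_lead_time(scanpath, i, n_li))
    return out


def raw_channel_values(
    scanpath: Scanpath, config: EncodingConfig | None = None
) -> dict[str, list[float]]:
    """Per-fixation raw (pre-normalization) values for every channel.

    Keys are the channel names of :data:`CHANNEL_LAYOUT`; each list holds one
    value per fixation, in scanpath order.  These are the exact quantities
    deposited on the grid before the collision policy and scaling.
    """
    return _raw_channels(scanpath, config or EncodingConfig())


def _deposit(
    raw: list[float],
    cells: list[tuple[int, int]],
    grid_dims: tuple[int, int],
    policy: CollisionPolicy,
) -> np.ndarray:
    gw, gh = grid_dims
    plane = np.zeros((gh, gw), dtype=float)
    seen = np.zeros((gh, gw), dtype=bool)
    for value, (col, row) in zip(raw, cells):
        if policy == "max":
            plane[row, col] = value if not seen[row, col] else max(plane[row, col], value)
        elif policy == "last":
            plane[row, col] = value
        else:  # sum
            plane[row, col] += value
        seen[row, col] = True
    return plane


def encode_scanpath(scanpath: Scanpath, config: EncodingConfig | None = None) -> EncodedImageSet:
    """Encode one scanpath into the PI, MI and LI images.

    Deterministic: a pure function of (scanpath, config).  Fixations that
    collide in one grid cell are merged channel-wise under the configured
    collision policy (default: keep the maximum, which is order-independent
    and preserves the strongest signal).
    """
    config = config or EncodingConfig()
    if not scanpath.records:
        raise ValueError("cannot encode an empty scanpath")
    raw = _raw_channels(scanpath, config)
    cells = [
        map_to_grid(rec, scanpath.screen_dims, config.grid_dims)
        for rec in scanpath.records
    ]
    n_collisions = len(cells) - len(set(cells))
    if n_collisions:
        logger.debug(
            "%s/%s: %d fixation(s) collided on the %dx%d grid",
            scanpath.subject, scanpath.stimulus, n_collisions, *config.grid_dims,
        )
    planes: dict[str, np.ndarray] = {}
    for name, values in raw.items():
        plane = _deposit(values, cells, config.grid_dims, config.collision_policy)
        max_data = None
        if name == "theta" and config.theta_fixed_range:
            max_data = 2 * math.pi
        planes[name] = normalize_channel(plane, config, max_data=max_data)
    images = {
        kind: np.stack([planes[c] for c in CHANNEL_LAYOUT[kind]], axis=-1)
        for kind in IMAGE_KINDS
    }
    return EncodedImageSet(
        pi=images["PI"], mi=images["MI"], li=images["LI"],
        subject=scanpath.subject, stimulus=scanpath.stimulus, label=scanpath.label,
    )


def write_image_set(image_set: EncodedImageSet, out_dir: str | Path) -> list[Path]:
    """Write the three rasters as lossless 8-bit RGB PNGs.

    Files are named ``<subject>_<stimulus>_<KIND>.png``; channel order in
    the file is the channel order documented in :data:`CHANNEL_LAYOUT`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind, arr in image_set.images().items():
        p = out_dir / f"{image_set.subject}_{image_set.stimulus}_{kind}.png"
        Image.fromarray(arr, mode="RGB").save(p, format="PNG")
        paths.append(p)
    return paths


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG written by :func:`write_image_set` back to (H, W, 3) uint8."""
    return np.asarray(Image.open(path).convert("RGB"))
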