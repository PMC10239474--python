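"""Cutting volumes into overlapping boxes and putting them back together.

Training uses 60^3 boxes with stride 30 that are jointly rotated (the 24
proper cube rotations) and randomly cropped to the network input size;
inference uses network-sized boxes with stride 12 whose processed
overlaps are averaged back into a full map.
"""

from __future__ import annotations

import dataclasses
import itertools
import json

import numpy as np

from .grid import DensityGrid

__all__ = [
    "ChunkLayout", "BoxPair", "plan_chunks", "extract_boxes",
    "extract_training_pairs", "augment_pair", "reassemble",
    "ROTATIONS_24", "apply_rotation",
]


@dataclasses.dataclass
class ChunkLayout:
    """Box positions covering a (possibly padded) volume."""

    box: int
    stride: int
    starts: list[tuple[int, int, int]]
    padded_shape: tuple[int, int, int]
    out_shape: tuple[int, int, int]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["starts"] = [list(s) for s in self.starts]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ChunkLayout":
        d = json.loads(text)
        return cls(d["box"], d["stride"], [tuple(s) for s in d["starts"]],
                   tuple(d["padded_shape"]), tuple(d["out_shape"]))


@dataclasses.dataclass
class BoxPair:
    """A matched (experimental, simulated-target) training cube pair."""

    experimental: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        if self.experimental.shape != self.target.shape:
            raise ValueError("box pair members must have identical shape")

    @property
    def side(self) -> int:
        return self.experimental.shape[0]


def _axis_starts(dim: int, box: int, stride: int) -> list[int]:
    starts = list(range(0, max(dim - box, 0) + 1, stride))
    if starts[-1] + box < dim:
        starts.append(dim - box)   # flush-end box touching the boundary
    return starts


def plan_chunks(shape, box: int, stride: int) -> ChunkLayout:
    """Plan box start positions so every voxel is covered at least once.

    Per axis the starts are 0, stride, 2*stride, ...; when the last
    regular box stops short of the boundary an extra flush-end start at
    ``dim - box`` is appended.  Axes shorter than ``box`` are zero-padded.
    """
    if box < 1:
        raise ValueError("box must be >= 1")
    if not 1 <= stride <= box:
        raise ValueError("stride must satisfy 1 <= stride <= box")
    shape = tuple(int(n) for n in shape)
    padded = tuple(max(n, box) for n in shape)
    per_axis = [_axis_starts(n, box, stride) for n in padded]
    starts = [tuple(s) for s in itertools.product(*per_axis)]
    return ChunkLayout(box, stride, starts, padded, shape)


def extract_boxes(values: np.ndarray, layout: ChunkLayout) -> np.ndarray:
    """Stack of boxes, shape (n_boxes, box, box, box)."""
    b = layout.box
    if values.shape != layout.padded_shape:
        pad = [(0, p - n) for n, p in zip(values.shape, layout.padded_shape)]
        values = np.pad(values, pad)
    return np.stack([values[z:z + b, y:y + b, x:x + b]
                     for z, y, x in layout.starts])


def reassemble(boxes: np.ndarray, layout: ChunkLayout,
               out_shape=None) -> np.ndarray:
    """Average overlapping processed boxes back into a full volume."""
    if len(boxes) != len(layout.starts):
        raise ValueError(f"expected {len(layout.starts)} boxes, got {len(boxes)}")
    out_shape = tuple(out_shape) if out_shape is not None else layout.out_shape
    b = layout.box
    acc = np.zeros(layout.padded_shape, dtype=np.float64)
    cnt = np.zeros(layout.padded_shape, dtype=np.int32)
    for box, (z, y, x) in zip(boxes, layout.starts):
        acc[z:z + b, y:y + b, x:x + b] += box
        cnt[z:z + b, y:y + b, x:x + b] += 1
    acc /= cnt   # coverage guarantees cnt >= 1
    return acc[:out_shape[0], :out_shape[1], :out_shape[2]].astype(np.float32)


def extract_training_pairs(exp: DensityGrid, sim: DensityGrid,
                           box: int = 60, stride: int = 30
                           ) -> list[BoxPair]:
    """Paired raw boxes at identical positions; non-positive pairs dropped.

    A pair is kept only when both members contain some positive density
    (an all-zero experimental or target box carries no training signal).
    """
    if not exp.same_geometry(sim):
        raise ValueError("experimental and simulated grids must share geometry")
    layout = plan_chunks(exp.shape, box, stride)
    eb = extract_boxes(exp.values, layout)
    sb = extract_boxes(sim.values, layout)
    return [BoxPair(e, s) for e, s in zip(eb, sb)
            if e.max() > 0 and s.max() > 0]


def _proper_rotations() -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """The 24 proper rotations of a cube as (axis permutation, sign flips)."""
    rots = []
    for perm in itertools.permutations((0, 1, 2)):
        parity = 1 if perm in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else -1
        for signs in itertools.product((1, -1), repeat=3):
            if parity * signs[0] * signs[1] * signs[2] == 1:
                rots.append((perm, signs))
    return rots


ROTATIONS_24 = _proper_rotations()


def apply_rotation(vol: np.ndarray, perm, signs) -> np.ndarray:
    out = np.transpose(vol, perm)
    sl = tuple(slice(None, None, s) for s in signs)
    return np.ascontiguousarray(out[sl])


def augment_pair(pair: BoxPair, rng: np.random.Generator,
                 crop: int = 48) -> BoxPair:
    """Apply one random rigid transform jointly to both members.

    The same rotation (uniform over the 24 proper cube rotations) and the
    same random ``crop``-sized offset are applied to the experimental and
    the target cube.
    """
    if pair.side < crop:
        raise ValueError(f"raw pair side {pair.side} < crop {crop}")
    perm, signs = ROTATIONS_24[rng.integers(len(ROTATIONS_24))]
    margin = pair.side - crop
    off = rng.integers(0, margin + 1, size=3)
    sl = tuple(slice(o, o + crop) for o in off)
    e = apply_rotation(pair.experimental, perm, signs)[sl]
    t = apply_rotation(pair.target, perm, signs)[sl]
    return BoxPair(np.ascontiguousarray(e), np.ascontiguousarray(t))
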