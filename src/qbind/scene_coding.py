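"""Blockworld scenes and their encoding into cognitive entities.

A visual scene is a set of recognized objects (segregation is assumed solved):
each object has a shape, a position and an extent on a binary pictogram.  An
object is encoded as a *cognitive entity* — the concatenation of three
associative fields:

* identity field: the object's bitmap, normalized for size and (trivially,
  for axis-aligned blocks) orientation to a fixed 10x10 grid, flattened
  row-major (100 bits);
* abscissa field: a binary bar over the canvas width marking ``[x0, x0+w)``;
* ordinate field: a binary bar over the canvas height marking ``[y0, y0+h)``.

With the default 100x100 canvas each entity has ``p = 100 + 100 + 100 = 300``
bits, and a category of M = 3 entities concatenates to 900 bits.

The synthetic generator emulates a blockworld of cubes and pyramids with a
planted "tower" category (pyramid on two stacked cubes).  Pixel noise is
applied to the rendered pictogram; identity fields are then extracted from the
noisy pictogram while the position bars come from the scene description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lernmatrix import as_binary_vector, learn_pairs

__all__ = [
    "IDENTITY_SIDE",
    "ObjectSpec",
    "CognitiveEntity",
    "Scene",
    "Blockworld",
    "TOWER_TEMPLATE",
    "shape_mask",
    "render_scene",
    "encode_object",
    "encode_category",
    "decode_bar",
    "add_noise",
    "instantiate_template",
    "template_extent",
    "category_vector",
    "learn_category_positions",
    "generate_blockworld",
    "read_pbm",
    "write_pbm",
    "save_scene",
    "load_scene",
]

IDENTITY_SIDE = 10  # identity field is a 10x10 bitmap -> 100 bits


# ---------------------------------------------------------------------------
# shapes


def _cube_mask(h: int, w: int) -> np.ndarray:
    return np.ones((h, w), dtype=np.uint8)


def _pyramid_mask(h: int, w: int) -> np.ndarray:
    """Centered isosceles triangle, apex up, base at the bottom row."""
    m = np.zeros((h, w), dtype=np.uint8)
    cols = np.arange(w)
    for r in range(h):
        half = (r + 1) * w / (2 * h)
        m[r, np.abs(cols - (w - 1) / 2) <= half] = 1
    return m


SHAPES = {"cube": _cube_mask, "pyramid": _pyramid_mask}


def shape_mask(shape_id: str, h: int, w: int) -> np.ndarray:
    try:
        return SHAPES[shape_id](h, w)
    except KeyError:
        raise ValueError(f"unknown shape_id {shape_id!r}") from None


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ObjectSpec:
    """A recognized object: shape plus bounding box (0-based, origin top-left)."""

    shape_id: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("object extent must be at least 1x1")

    def inside(self, canvas_shape: tuple[int, int]) -> bool:
        H, W = canvas_shape
        return (0 <= self.x0 and self.x0 + self.width <= W
                and 0 <= self.y0 and self.y0 + self.height <= H)

    def overlaps(self, other: "ObjectSpec") -> bool:
        return not (self.x0 + self.width <= other.x0
                    or other.x0 + other.width <= self.x0
                    or self.y0 + self.height <= other.y0
                    or other.y0 + other.height <= self.y0)


@dataclass(frozen=True)
class CognitiveEntity:
    """identity || abscissa-bar || ordinate-bar, ``p`` bits in total."""

    identity_field: np.ndarray
    x_field: np.ndarray
    y_field: np.ndarray

    @property
    def p(self) -> int:
        return self.identity_field.size + self.x_field.size + self.y_field.size

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.identity_field, self.x_field, self.y_field])


@dataclass
class Scene:
    """Ordered entities with implicit 1-based addresses 1..N (flags rest at 0)."""

    entities: list[CognitiveEntity]
    specs: list[ObjectSpec] | None = None
    canvas_shape: tuple[int, int] = (100, 100)

    @property
    def N(self) -> int:
        return len(self.entities)

    @property
    def p(self) -> int:
        return self.entities[0].p

    @property
    def addresses(self) -> list[int]:
        return list(range(1, self.N + 1))

    def entity_matrix(self) -> np.ndarray:
        """(N, p) matrix of entity vectors, row i = address i+1."""
        return np.vstack([e.vector for e in self.entities])

    def __getitem__(self, address: int) -> CognitiveEntity:
        """Entity at a 1-based scene address."""
        if not 1 <= address <= self.N:
            raise IndexError(f"address {address} outside 1..{self.N}")
        return self.entities[address - 1]


# ---------------------------------------------------------------------------
# encoding


def _normalize_bitmap(crop: np.ndarray, side: int = IDENTITY_SIDE) -> np.ndarray:
    """Nearest-neighbor rescale of a binary crop to ``side x side``."""
    h, w = crop.shape
    rows = np.minimum((((np.arange(side) + 0.5) * h) / side).astype(int), h - 1)
    cols = np.minimum((((np.arange(side) + 0.5) * w) / side).astype(int), w - 1)
    return crop[np.ix_(rows, cols)].astype(np.uint8)


def _bar(length: int, start: int, extent: int) -> np.ndarray:
    b = np.zeros(length, dtype=np.uint8)
    b[start:start + extent] = 1
    return b


def encode_object(obj: ObjectSpec, canvas_shape: tuple[int, int] = (100, 100),
                  pictogram: np.ndarray | None = None) -> CognitiveEntity:
    """Encode an object into its cognitive entity.

    The identity field is taken from the object's bounding-box crop of
    ``pictogram`` when given (so pixel noise propagates into the identity),
    otherwise from the ideal shape mask.  Orientation normalization is a
    no-op for the axis-aligned blockworld shapes.
    """
    H, W = canvas_shape
    if not obj.inside(canvas_shape):
        raise ValueError(f"object {obj} outside the {H}x{W} canvas")
    if pictogram is not None:
        crop = np.asarray(pictogram)[obj.y0:obj.y0 + obj.height,
                                     obj.x0:obj.x0 + obj.width]
    else:
        crop = shape_mask(obj.shape_id, obj.height, obj.width)
    return CognitiveEntity(
        identity_field=_normalize_bitmap(crop).ravel(),
        x_field=_bar(W, obj.x0, obj.width),
        y_field=_bar(H, obj.y0, obj.height),
    )


def encode_category(entities: Sequence[CognitiveEntity]) -> np.ndarray:
    """Concatenate M entities, in order, into one M*p-bit category vector."""
    if len(entities) == 0:
        raise ValueError("a category needs at least one entity")
    p = entities[0].p
    if any(e.p != p for e in entities):
        raise ValueError("all entities in a category must share p")
    return np.concatenate([e.vector for e in entities])


def decode_bar(bar) -> tuple[int, int]:
    """Recover (start, extent) from a contiguous position bar."""
    bar = as_binary_vector(bar)
    idx = np.flatnonzero(bar)
    if idx.size == 0:
        raise ValueError("empty position bar")
    start, extent = int(idx[0]), int(idx.size)
    if idx[-1] - idx[0] + 1 != extent:
        raise ValueError("position bar is not contiguous")
    return start, extent


# ---------------------------------------------------------------------------
# noise


def add_noise(a, rate: float, seed=None, rng: np.random.Generator | None = None):
    """Flip each bit independently with probability ``rate`` (seeded)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("noise rate must be in [0, 1]")
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("noise applies to binary arrays only")
    if rng is None:
        rng = np.random.default_rng(seed)
    flips = rng.random(a.shape) < rate
    return np.bitwise_xor(a.astype(np.uint8), flips.astype(np.uint8))


# ---------------------------------------------------------------------------
# tower template and generator

# (shape_id, dx, dy, width, height) relative to the template origin; order is
# the category's slot order (top-down: pyramid roof, then the two cubes).
TOWER_TEMPLATE: tuple[tuple[str, int, int, int, int], ...] = (
    ("pyramid", 0, 0, 20, 20),
    ("cube", 0, 20, 20, 20),
    ("cube", 0, 40, 20, 20),
)


def template_extent(template=TOWER_TEMPLATE) -> tuple[int, int]:
    w = max(dx + bw for _, dx, _, bw, _ in template)
    h = max(dy + bh for _, _, dy, _, bh in template)
    return h, w


def instantiate_template(template, x0: int, y0: int) -> list[ObjectSpec]:
    return [ObjectSpec(s, x0 + dx, y0 + dy, bw, bh)
            for s, dx, dy, bw, bh in template]


def category_vector(template, x0: int, y0: int,
                    canvas_shape: tuple[int, int] = (100, 100)) -> np.ndarray:
    """Noise-free encoded category at one position (the learned ground truth)."""
    ents = [encode_object(o, canvas_shape) for o in instantiate_template(template, x0, y0)]
    return encode_category(ents)


def learn_category_positions(template, positions: Sequence[tuple[int, int]],
                             canvas_shape: tuple[int, int] = (100, 100)):
    """Auto-associate the encoded category at each position.

    Returns ``(W, vectors)`` with W of dimension ``M*p`` (900 for the default
    configuration) and the list of learned category vectors.
    """
    vecs = [category_vector(template, x0, y0, canvas_shape) for x0, y0 in positions]
    W = learn_pairs([(v, v) for v in vecs], auto_associative=True)
    return W, vecs


@dataclass
class Blockworld:
    """A generated fixture with its ground truth."""

    pictogram: np.ndarray            # noisy rendering (what the demo "sees")
    clean_pictogram: np.ndarray
    scene: Scene
    category_specs: list[ObjectSpec]
    learned_positions: list[tuple[int, int]]
    planted_position: tuple[int, int] | None
    planted_addresses: tuple[int, ...] | None  # scene addresses, template order
    noise_rate: float
    seed: int | None = None
    template: tuple = TOWER_TEMPLATE


def render_scene(specs: Sequence[ObjectSpec],
                 canvas_shape: tuple[int, int] = (100, 100)) -> np.ndarray:
    H, W = canvas_shape
    pic = np.zeros((H, W), dtype=np.uint8)
    for o in specs:
        if not o.inside(canvas_shape):
            raise ValueError(f"object {o} outside the {H}x{W} canvas")
        mask = shape_mask(o.shape_id, o.height, o.width)
        region = pic[o.y0:o.y0 + o.height, o.x0:o.x0 + o.width]
        np.bitwise_or(region, mask, out=region)
    return pic


def generate_blockworld(canvas_shape: tuple[int, int] = (100, 100),
                        n_objects: int = 10,
                        template=TOWER_TEMPLATE,
                        n_positions: int = 10,
                        noise_rate: float = 0.02,
                        block_size: int = 20,
                        plant_category: bool = True,
                        seed: int | None = 0,
                        max_tries: int = 500) -> Blockworld:
    """Generate a blockworld scene with a planted category and ground truth.

    ``n_positions`` distinct tower positions are drawn; all of them are meant
    to be learned (see :func:`learn_category_positions`) and the scene's tower
    stands at one of them.  The remaining ``n_objects - M`` objects are
    distractor blocks placed without overlap.  Deterministic under ``seed``.
    """
    H, W = canvas_shape
    rng = np.random.default_rng(seed)
    th, tw = template_extent(template)
    M = len(template)
    if plant_category and n_objects < M:
        raise ValueError(f"need at least {M} objects to plant the category")

    # distinct candidate positions for the category
    nx, ny = W - tw + 1, H - th + 1
    if nx < 1 or ny < 1:
        raise ValueError("template does not fit the canvas")
    if n_positions > nx * ny:
        raise ValueError("more positions requested than fit the canvas")
    flat = rng.choice(nx * ny, size=n_positions, replace=False)
    positions = [(int(f % nx), int(f // nx)) for f in flat]

    specs: list[ObjectSpec] = []
    category_specs: list[ObjectSpec] = []
    planted_pos = None
    if plant_category:
        planted_pos = positions[int(rng.integers(n_positions))]
        category_specs = instantiate_template(template, *planted_pos)
        specs.extend(category_specs)

    shapes = sorted(SHAPES)
    n_distractors = n_objects - len(category_specs)
    for _ in range(n_distractors):
        for attempt in range(max_tries):
            o = ObjectSpec(
                shapes[int(rng.integers(len(shapes)))],
                int(rng.integers(W - block_size + 1)),
                int(rng.integers(H - block_size + 1)),
                block_size, block_size,
            )
            if not any(o.overlaps(q) for q in specs):
                specs.append(o)
                break
        else:
            raise RuntimeError(
                f"could not place a distractor without overlap in {max_tries} tries")

    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    planted_addresses = None
    if plant_category:
        inv = {int(order[i]): i + 1 for i in range(len(specs))}
        planted_addresses = tuple(inv[i] for i in range(M))

    clean = render_scene(specs, canvas_shape)
    noisy = add_noise(clean, noise_rate, rng=rng)
    entities = [encode_object(o, canvas_shape, pictogram=noisy) for o in specs]
    scene = Scene(entities=entities, specs=specs, canvas_shape=canvas_shape)
    return Blockworld(
        pictogram=noisy, clean_pictogram=clean, scene=scene,
        category_specs=category_specs, learned_positions=positions,
        planted_position=planted_pos, planted_addresses=planted_addresses,
        noise_rate=noise_rate, seed=seed, template=tuple(template),
    )


# ---------------------------------------------------------------------------
# plain-text formats: P1 portable bitmap and JSON scenes


def write_pbm(pic: np.ndarray, path) -> None:
    """Write a binary image as plain-text P1 PBM (bit-exact round trip)."""
    pic = np.asarray(pic, dtype=np.uint8)
    H, W = pic.shape
    with open(path, "w") as fh:
        fh.write(f"P1\n{W} {H}\n")
        for row in pic:
            fh.write(" ".join(map(str, row.tolist())) + "\n")


def read_pbm(path) -> np.ndarray:
    with open(path) as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError("not a plain-text P1 PBM file")
    W, H = int(tokens[1]), int(tokens[2])
    bits = np.array([int(t) for t in tokens[3:3 + W * H]], dtype=np.uint8)
    if bits.size != W * H:
        raise ValueError("PBM pixel count does not match header")
    return bits.reshape(H, W)


def save_scene(scene: Scene, path) -> None:
    if scene.specs is None:
        raise ValueError("scene has no object specs to serialize")
    doc = {
        "schema": "qbind-scene/1",
        "canvas": {"height": scene.canvas_shape[0], "width": scene.canvas_shape[1]},
        "objects": [
            {"shape_id": o.shape_id, "x0": o.x0, "y0": o.y0,
             "width": o.width, "height": o.height}
            for o in scene.specs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_scene(path, pictogram: np.ndarray | None = None) -> Scene:
    """Load a scene description; entities are re-encoded (from ``pictogram``
    when given, else from ideal shape masks)."""
    with open(path) as fh:
        doc = json.load(fh)
    canvas = (doc["canvas"]["height"], doc["canvas"]["width"])
    specs = [ObjectSpec(d["shape_id"], d["x0"], d["y0"], d["width"], d["height"])
             for d in doc["objects"]]
    entities = [encode_object(o, canvas, pictogram=pictogram) for o in specs]
    return Scene(entities=entities, specs=specs, canvas_shape=canvas)
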