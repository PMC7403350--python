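"""Orthographic stimulus construction.

Builds the word/pseudoword string stimuli and the single-letter stimuli used
throughout the analyses: four-letter strings rendered in a monospaced font
under three letter sizes (0.8, 1.2, 1.6 degrees of visual angle per letter)
and two cases, and individual letters at each of the four string slots.
Also provides per-string mean bigram frequency metadata and the pixel-level
reflectivity statistic (intersection-over-union after mirror reflection)
between letter glyphs.

Coordinate conventions: images are square binary masks (foreground = glyph),
row 0 at the top.  A "horizontal" reflection mirrors left-right (the b/d
axis); a "vertical" reflection mirrors top-bottom (the b/p axis).
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw, ImageFont

VOWELS = frozenset("aeiou")
CONSONANTS = frozenset("bcdfghjklmnpqrstvwxyz")

#: letter height in degrees of visual angle for each named size
LETTER_DEG = {"small": 0.8, "medium": 1.2, "large": 1.6}
SIZES = ("small", "medium", "large")
CASES = ("upper", "lower")
#: the six case x size variations, in canonical order
VARIATIONS = tuple((c, s) for c in CASES for s in SIZES)

# Approximate English letter frequencies (per cent); used only to sample
# pseudoword letters so that generated strings span common and rare bigrams.
_LETTER_FREQ = {
    "a": 8.2, "b": 1.5, "c": 2.8, "d": 4.3, "e": 12.7, "f": 2.2, "g": 2.0,
    "h": 6.1, "i": 7.0, "j": 0.15, "k": 0.77, "l": 4.0, "m": 2.4, "n": 6.7,
    "o": 7.5, "p": 1.9, "q": 0.095, "r": 6.0, "s": 6.3, "t": 9.1, "u": 2.8,
    "v": 0.98, "w": 2.4, "x": 0.15, "y": 2.0, "z": 0.074,
}


# ---------------------------------------------------------------------------
# fonts


class MonospaceFont:
    """Scalable monospaced font (DejaVu Sans Mono, bundled with matplotlib).

    The font size is chosen so that the fixed glyph advance equals the slot
    width; a four-letter string then spans exactly four slot widths.
    """

    def __init__(self, path: str | None = None):
        if path is None:
            import matplotlib.font_manager as fm

            path = fm.findfont("DejaVu Sans Mono", fallback_to_default=False)
        self.path = path
        self._cache: dict[int, ImageFont.FreeTypeFont] = {}
        ref = ImageFont.truetype(path, 100)
        adv = ref.getlength("M")
        if adv != ref.getlength("i"):
            raise ValueError(f"font at {path} is not monospaced")
        self._adv_per_size = adv / 100.0

    def _font_for_slot(self, slot_px: int) -> ImageFont.FreeTypeFont:
        size = max(4, round(slot_px / self._adv_per_size))
        if size not in self._cache:
            self._cache[size] = ImageFont.truetype(self.path, size)
        return self._cache[size]

    def render(self, text: str, slot_px: int, canvas_px: int, left_px: int) -> np.ndarray:
        img = Image.new("L", (canvas_px, canvas_px), 0)
        draw = ImageDraw.Draw(img)
        font = self._font_for_slot(slot_px)
        draw.text((left_px, canvas_px // 2), text, font=font, fill=255, anchor="lm")
        return np.asarray(img)


# A tiny synthetic bitmap font in which b/d are bit-exact horizontal mirror
# pairs and b/p bit-exact vertical mirror pairs; used in tests of the
# reflectivity statistic and of mirror-symmetric simulated tuning.
_B = [
    "#....",
    "#....",
    "####.",
    "#...#",
    "#...#",
    "#...#",
    "####.",
]
_EXTRA = {
    "c": ["....", ".###", "#...", "#...", "#...", ".###", "...."],
    "o": ["....", ".##.", "#..#", "#..#", "#..#", ".##.", "...."],
    "n": ["....", "###.", "#..#", "#..#", "#..#", "#..#", "...."],
    "l": ["#...", "#...", "#...", "#...", "#...", "#...", ".##."],
    "x": ["....", "#..#", ".##.", ".##.", ".##.", "#..#", "...."],
    "t": [".#..", ".#..", "####", ".#..", ".#..", ".#..", "..##"],
    "a": ["....", ".##.", "...#", ".###", "#..#", ".###", "...."],
    "e": ["....", ".##.", "#..#", "####", "#...", ".##.", "...."],
}


def _bits(rows: list[str]) -> np.ndarray:
    return np.array([[ch == "#" for ch in row] for row in rows], dtype=bool)


class MirrorFont:
    """Synthetic bitmap test font with exact mirror-pair glyphs.

    ``d`` is defined as the left-right flip of ``b`` and ``p``/``q`` as the
    top-bottom flips of ``b``/``d``, so reflectivity has known exact values.
    """

    def __init__(self):
        b = _bits(_B)
        self.glyphs: dict[str, np.ndarray] = {
            "b": b,
            "d": np.fliplr(b),
            "p": np.flipud(b),
            "q": np.flipud(np.fliplr(b)),
        }
        self.glyphs.update({k: _bits(v) for k, v in _EXTRA.items()})

    def render(self, text: str, slot_px: int, canvas_px: int, left_px: int) -> np.ndarray:
        out = np.zeros((canvas_px, canvas_px), dtype=np.uint8)
        for k, ch in enumerate(text):
            ch = ch.lower()
            if ch not in self.glyphs:
                raise KeyError(f"mirror test font has no glyph for {ch!r}")
            g = self.glyphs[ch]
            scale = max(1, slot_px // (g.shape[0] + 1))
            big = np.kron(g, np.ones((scale, scale), dtype=bool))
            h, w = big.shape
            x0 = left_px + k * slot_px + (slot_px - w) // 2
            y0 = canvas_px // 2 - h // 2
            out[y0 : y0 + h, x0 : x0 + w] |= big.astype(np.uint8) * 255
        return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GlyphConfig:
    """Rendering configuration: pixel grid and font resource."""

    px_per_degree: int = 32
    canvas_deg: float = 8.0
    font: object = None  # MonospaceFont-like; defaults lazily to DejaVu Mono

    @property
    def canvas_px(self) -> int:
        return round(self.px_per_degree * self.canvas_deg)

    def get_font(self):
        return self.font if self.font is not None else _default_font()


_DEFAULT_FONT: list = []


def _default_font() -> MonospaceFont:
    if not _DEFAULT_FONT:
        _DEFAULT_FONT.append(MonospaceFont())
    return _DEFAULT_FONT[0]


@dataclass(frozen=True)
class GlyphImage:
    """Binary glyph mask on a square canvas."""

    pixels: np.ndarray  # 2-D bool, True = foreground
    canvas_size: int
    letter_height_px: int

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 2 or px.shape[0] != px.shape[1] or px.shape[0] != self.canvas_size:
            raise ValueError("glyph canvas must be square and match canvas_size")
        if not px.any():
            raise ValueError("glyph mask has no foreground pixels")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive, of foreground."""
        rows = np.flatnonzero(self.pixels.any(axis=1))
        cols = np.flatnonzero(self.pixels.any(axis=0))
        return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


@dataclass(frozen=True)
class StimulusMeta:
    stimulus_id: str
    text: str
    lexical_class: str  # word | pseudoword | letter
    font_case: str
    font_size: str
    position_slot: int | None = None  # 1..4, letters only
    mean_bigram_freq: float | None = None  # counts per million, strings only

    def __post_init__(self):
        if self.lexical_class in ("word", "pseudoword") and len(self.text) != 4:
            raise ValueError("words and pseudowords must have exactly 4 letters")
        if self.lexical_class == "pseudoword":
            nv = sum(c in VOWELS for c in self.text.lower())
            if nv != 1:
                raise ValueError("pseudowords must contain exactly one vowel")
        if self.lexical_class == "letter" and self.position_slot is None:
            raise ValueError("letter stimuli require a position slot")


@dataclass
class StimulusSet:
    """Parallel lists of rendered glyph images and their metadata."""

    images: list[GlyphImage]
    meta: list[StimulusMeta]
    config: GlyphConfig = field(default_factory=GlyphConfig)

    def __post_init__(self):
        if len(self.images) != len(self.meta):
            raise ValueError("images and meta must have equal length")
        ids = [m.stimulus_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus_ids must be unique")

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def stimulus_ids(self) -> list[str]:
        return [m.stimulus_id for m in self.meta]

    def subset(self, ids) -> "StimulusSet":
        wanted = set(ids)
        keep = [i for i, m in enumerate(self.meta) if m.stimulus_id in wanted]
        missing = wanted - {self.meta[i].stimulus_id for i in keep}
        if missing:
            raise KeyError(f"unknown stimulus ids: {sorted(missing)[:5]}")
        return StimulusSet([self.images[i] for i in keep], [self.meta[i] for i in keep], self.config)

    def concat(self, other: "StimulusSet") -> "StimulusSet":
        return StimulusSet(self.images + other.images, self.meta + other.meta, self.config)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(m) for m in self.meta])

    def write(self, directory):
        """Write PNG images, a manifest JSON and a metadata CSV."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for img, m in zip(self.images, self.meta):
            fname = f"{m.stimulus_id}.png"
            Image.fromarray(img.pixels.astype(np.uint8) * 255).save(directory / fname)
            manifest[m.stimulus_id] = fname
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        self.to_dataframe().to_csv(directory / "stimulus_meta.csv", index=False)


@dataclass(frozen=True)
class ReflectivityRecord:
    letter_a: str
    letter_b: str
    R_H: float
    R_V: float

    def __post_init__(self):
        if self.letter_a == self.letter_b:
            raise ValueError("identity pairs are excluded from reflectivity records")

    @property
    def delta_R(self) -> float:
        return self.R_H - self.R_V


# ---------------------------------------------------------------------------
# rendering


def render_string(
    text: str,
    font_case: str = "upper",
    font_size: str = "medium",
    config: GlyphConfig | None = None,
    position_slot: int | None = None,
) -> GlyphImage:
    """Render a 1-4 letter string as a binary glyph mask.

    Strings occupy four letter slots centred on the canvas, each slot as wide
    as the letter height in degrees (so a four-letter string spans 4x the
    letter size: 3.2/4.8/6.4 degrees for small/medium/large).  A single
    letter with ``position_slot`` k (1-based) is placed in slot k of that
    layout; without a slot it is centred.
    """
    if config is None:
        config = GlyphConfig()
    if not (1 <= len(text) <= 4) or not text.isalpha():
        raise ValueError(f"text must be 1-4 alphabetic characters, got {text!r}")
    if font_case not in CASES:
        raise ValueError(f"unknown font case {font_case!r}")
    if font_size not in LETTER_DEG:
        raise ValueError(f"unknown font size {font_size!r}")
    shown = text.upper() if font_case == "upper" else text.lower()
    slot_px = round(LETTER_DEG[font_size] * config.px_per_degree)
    canvas_px = config.canvas_px
    layout_left = (canvas_px - 4 * slot_px) // 2
    if len(text) == 1 and position_slot is not None:
        if not 1 <= position_slot <= 4:
            raise ValueError("position_slot must be in 1..4")
        left = layout_left + (position_slot - 1) * slot_px
    elif len(text) == 4:
        left = layout_left
    else:
        left = (canvas_px - len(text) * slot_px) // 2
    gray = config.get_font().render(shown, slot_px, canvas_px, left)
    peak = int(gray.max())
    if peak == 0:
        raise ValueError(f"rendering produced an empty mask for {text!r}")
    mask = gray > 0.5 * peak
    return GlyphImage(pixels=mask, canvas_size=canvas_px, letter_height_px=slot_px)


# ---------------------------------------------------------------------------
# word / pseudoword / letter sets


def load_word_list() -> list[str]:
    """The packaged list of four-letter English words (lowercase)."""
    text = importlib.resources.files("orthopop.data").joinpath("words4.txt").read_text()
    return text.split()


def generate_pseudowords(n: int, seed: int, word_list=None, rng=None) -> list[str]:
    """Nonsense four-letter strings with exactly one vowel and three consonants.

    Letters are sampled according to coarse English letter frequencies so the
    pseudoword population spans common and rare bigrams; real words from
    ``word_list`` and duplicates are rejected.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    forbidden = set(word_list or load_word_list())
    vowels = sorted(VOWELS)
    cons = sorted(CONSONANTS)
    pv = np.array([_LETTER_FREQ[c] for c in vowels])
    pv = pv / pv.sum()
    pc = np.array([_LETTER_FREQ[c] for c in cons])
    pc = pc / pc.sum()
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        slot = rng.integers(4)
        letters = [cons[i] for i in rng.choice(len(cons), size=4, p=pc)]
        letters[slot] = vowels[rng.choice(len(vowels), p=pv)]
        s = "".join(letters)
        if s in forbidden or s in seen:
            continue
        seen.add(s)
        out.append(s)
    return out


def _string_meta(text: str, lexical_class: str, case: str, size: str, table) -> StimulusMeta:
    return StimulusMeta(
        stimulus_id=f"{text}_{case}_{size}",
        text=text,
        lexical_class=lexical_class,
        font_case=case,
        font_size=size,
        mean_bigram_freq=mean_bigram_frequency(text, table),
    )


def build_base_set(
    word_list=None,
    n_words: int = 308,
    n_pseudo: int = 308,
    seed: int = 0,
    config: GlyphConfig | None = None,
    bigram_table=None,
) -> StimulusSet:
    """Word/pseudoword string set rendered under all 3 sizes x 2 cases.

    Defaults give 616 strings and 3696 images.
    """
    rng = np.random.default_rng(seed)
    if config is None:
        config = GlyphConfig()
    if word_list is None:
        word_list = load_word_list()
    if len(word_list) < n_words:
        raise ValueError(f"word list has {len(word_list)} entries, need {n_words}")
    if bigram_table is None:
        bigram_table = load_bigram_table()
    words = [word_list[i] for i in rng.choice(len(word_list), size=n_words, replace=False)]
    pseudos = generate_pseudowords(n_pseudo, seed=seed, word_list=word_list, rng=rng)
    images, meta = [], []
    for text, cls in [(w, "word") for w in words] + [(p, "pseudoword") for p in pseudos]:
        for case, size in VARIATIONS:
            images.append(render_string(text, case, size, config))
            meta.append(_string_meta(text, cls, case, size, bigram_table))
    return StimulusSet(images, meta, config)


def build_letter_set(
    alphabet: str = "abcdefghijklmnopqrstuvwxyz",
    positions: int = 4,
    variations: int = 6,
    config: GlyphConfig | None = None,
) -> StimulusSet:
    """Single letters at each string slot under case/size variations.

    Full defaults give 26 letters x 4 positions x 6 variations = 624 stimuli.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if not 1 <= variations <= len(VARIATIONS):
        raise ValueError("variations must be in 1..6")
    if config is None:
        config = GlyphConfig()
    images, meta = [], []
    for letter in alphabet:
        for slot in range(1, positions + 1):
            for case, size in VARIATIONS[:variations]:
                images.append(render_string(letter, case, size, config, position_slot=slot))
                meta.append(
                    StimulusMeta(
                        stimulus_id=f"{letter.lower()}_{case}_{size}_pos{slot}",
                        text=letter.lower(),
                        lexical_class="letter",
                        font_case=case,
                        font_size=size,
                        position_slot=slot,
                    )
                )
    return StimulusSet(images, meta, config)


# ---------------------------------------------------------------------------
# bigram frequency


def build_bigram_table(words) -> dict[str, float]:
    """Adjacent-bigram counts per million bigram tokens over a word corpus.

    All 676 ordered bigrams are present; unseen bigrams get 0.
    """
    counts = {a + b: 0 for a in "abcdefghijklmnopqrstuvwxyz" for b in "abcdefghijklmnopqrstuvwxyz"}
    total = 0
    for w in words:
        w = w.lower()
        for i in range(len(w) - 1):
            counts[w[i : i + 2]] += 1
            total += 1
    return {bg: 1e6 * c / total for bg, c in counts.items()}


def load_bigram_table() -> dict[str, float]:
    """The frozen packaged bigram-frequency table (counts per million)."""
    text = importlib.resources.files("orthopop.data").joinpath("bigram_freq.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.strip().splitlines()[1:]:
        bg, v = line.split("\t")
        table[bg] = float(v)
    return table


def mean_bigram_frequency(text: str, bigram_table) -> float:
    """Arithmetic mean frequency of a string's adjacent bigrams."""
    text = text.lower()
    if len(text) < 2:
        raise ValueError("text must have at least 2 characters")
    freqs = [bigram_table.get(text[i : i + 2], 0.0) for i in range(len(text) - 1)]
    return float(np.mean(freqs))


# ---------------------------------------------------------------------------
# reflectivity


def _crop(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def reflect_about_bbox(mask: np.ndarray, axis: str) -> np.ndarray:
    """Mirror the foreground about its bounding-box centre, in place on the canvas.

    ``horizontal`` flips left-right (b -> d), ``vertical`` flips top-bottom
    (b -> p).  Applying the same reflection twice returns the original mask.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    out = mask.copy()
    sl = np.s_[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if axis == "horizontal":
        out[sl] = np.fliplr(mask[sl])
    elif axis == "vertical":
        out[sl] = np.flipud(mask[sl])
    else:
        raise ValueError(f"axis must be horizontal or vertical, got {axis!r}")
    return out


def aligned_overlap(img_a, img_b, flip: str | None = None) -> float:
    """Pixel IoU of two glyphs after bounding-box centre alignment.

    ``flip`` mirrors the second glyph about its own bounding-box centre
    first (``horizontal`` = left-right, ``vertical`` = top-bottom).
    """
    a = img_a.pixels if isinstance(img_a, GlyphImage) else np.asarray(img_a, bool)
    b = img_b.pixels if isinstance(img_b, GlyphImage) else np.asarray(img_b, bool)
    ca = _crop(a)
    cb = _crop(b)
    if flip == "horizontal":
        cb = np.fliplr(cb)
    elif flip == "vertical":
        cb = np.flipud(cb)
    elif flip is not None:
        raise ValueError(f"flip must be horizontal, vertical or None, got {flip!r}")
    # 2x upsampling makes every (canvas - crop) gap even, so centring is exact
    ca = np.kron(ca, np.ones((2, 2), dtype=bool))
    cb = np.kron(cb, np.ones((2, 2), dtype=bool))
    H = max(ca.shape[0], cb.shape[0])
    W = max(ca.shape[1], cb.shape[1])

    def place(c):
        out = np.zeros((H, W), dtype=bool)
        r0 = (H - c.shape[0]) // 2
        c0 = (W - c.shape[1]) // 2
        out[r0 : r0 + c.shape[0], c0 : c0 + c.shape[1]] = c
        return out

    A, B = place(ca), place(cb)
    union = np.logical_or(A, B).sum()
    inter = np.logical_and(A, B).sum()
    return float(inter) / float(union)


def reflectivity(img_a, img_b, axis: str) -> float:
    """Intersection-over-union of one glyph with the reflected other.

    The second glyph is mirrored about its own bounding-box centre along
    ``axis`` (``horizontal`` = left-right, the b/d contrast; ``vertical`` =
    top-bottom, the b/p contrast); the two bounding boxes are then aligned
    at their centres and the pixel IoU returned.  Symmetric in its arguments
    to numerical exactness.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be horizontal or vertical, got {axis!r}")
    return aligned_overlap(img_a, img_b, flip=axis)


def all_letter_pair_reflectivity(letter_images: dict[str, GlyphImage]) -> list[ReflectivityRecord]:
    """R_H, R_V and delta_R for every unordered distinct letter pair.

    26 letters give C(26,2) = 325 records; identity pairs are excluded
    because most letters are more horizontally than vertically symmetric to
    themselves, which would bias the mirror-symmetry analysis.
    """
    letters = sorted(letter_images)
    if len(letters) != len(letter_images):
        raise ValueError("duplicate letters in input")
    records = []
    for a, b in itertools.combinations(letters, 2):
        records.append(
            ReflectivityRecord(
                letter_a=a,
                letter_b=b,
                R_H=reflectivity(letter_images[a], letter_images[b], "horizontal"),
                R_V=reflectivity(letter_images[a], letter_images[b], "vertical"),
            )
        )
    return records


def canonical_letter_glyphs(stimulus_set: StimulusSet) -> dict[str, GlyphImage]:
    """One glyph per letter, preferring lower case and medium size.

    Lower case is the canonical basis for reflectivity and tuning similarity
    because the classic mirror pairs (b/d, p/q) are lower-case forms.
    """
    glyphs: dict[str, GlyphImage] = {}
    ranks: dict[str, int] = {}
    for img, m in zip(stimulus_set.images, stimulus_set.meta):
        if m.lexical_class != "letter":
            continue
        rank = (0 if m.font_case == "lower" else 2) + (0 if m.font_size == "medium" else 1)
        if rank < ranks.get(m.text, 99):
            ranks[m.text] = rank
            glyphs[m.text] = img
    return glyphs


def pixel_feature_matrix(stimulus_set: StimulusSet, downsample: int = 8) -> np.ndarray:
    """Stimuli x pixels matrix of block-averaged mask intensities.

    A deliberately low-level control feature space for the decoding battery
    (an externally supplied feature matrix standing in for early vision).
    """
    feats = []
    for img in stimulus_set.images:
        m = img.pixels.astype(float)
        n = m.shape[0] // downsample
        m = m[: n * downsample, : n * downsample]
        feats.append(m.reshape(n, downsample, n, downsample).mean(axis=(1, 3)).ravel())
    return np.array(feats)
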