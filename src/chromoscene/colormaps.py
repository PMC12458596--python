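"""Built-in colormaps and palettes, embedded as RGB constants.

Continuous maps are lists of >= 2 RGB stops, interpolated piecewise-
linearly with stops equally spaced on [0, 1].  Categorical palettes are
cycled by category index.  All values are 8-bit per channel.
"""

from __future__ import annotations

#: 8-stop perceptually ordered dark-purple -> yellow map.
VIRIDIS_8 = [
    (68, 1, 84),
    (70, 50, 126),
    (54, 92, 141),
    (39, 127, 142),
    (31, 161, 135),
    (74, 193, 109),
    (160, 218, 57),
    (253, 231, 37),
]

#: Two-stop black -> white ramp.
GREYS_2 = [
    (0, 0, 0),
    (255, 255, 255),
]

#: 12-color categorical palette (paired hues, print-safe).
CATEGORY_12 = [
    (166, 206, 227),
    (31, 120, 180),
    (178, 223, 138),
    (51, 160, 44),
    (251, 154, 153),
    (227, 26, 28),
    (253, 191, 111),
    (255, 127, 0),
    (202, 178, 214),
    (106, 61, 154),
    (255, 255, 153),
    (177, 89, 40),
]

#: Registry of named maps usable in a view config.
CONTINUOUS = {
    "viridis-8": VIRIDIS_8,
    "greys-2": GREYS_2,
}

CATEGORICAL = {
    "category-12": CATEGORY_12,
}


def get_continuous(name: str) -> list[tuple[int, int, int]]:
    try:
        return CONTINUOUS[name]
    except KeyError:
        raise KeyError(
            f"unknown continuous colormap {name!r}; available: {sorted(CONTINUOUS)}"
        ) from None


def get_categorical(name: str) -> list[tuple[int, int, int]]:
    try:
        return CATEGORICAL[name]
    except KeyError:
        raise KeyError(
            f"unknown categorical palette {name!r}; available: {sorted(CATEGORICAL)}"
        ) from None
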