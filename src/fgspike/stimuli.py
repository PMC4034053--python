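"""Binary polygon and circle stimuli and their transforms.

The displays are ``N x N`` binary grids (1 = white) built from an inner
``n x n`` square surrounded by a black margin of width ``m`` (``N = n + 2m``).
A polygon figure is bounded by straight frame edges on the top, bottom and
one side of the inner square, and by a "profile" line on the other side.
The profile runs between the mid-points of the top and bottom inner edges;
under that constraint the total border length is conserved across
mirror reversal, contrast reversal and figure-ground (FG) reversal, which
is what makes the four-member image sets geometrically comparable.

Default geometry: inner side ``n = 64``, margin ``m = 6`` (``N = 76``),
figure area 1720 white pixels (area ratio 0.42 of the inner square,
0.30 of the full array).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_INNER",
    "DEFAULT_MARGIN",
    "DEFAULT_WHITE",
    "BinaryImage",
    "BorderMetrics",
    "ImageSet",
    "ProfileSpec",
    "border_length",
    "contrast_reverse",
    "default_fixtures",
    "default_circle_sets",
    "fg_reverse",
    "generate_circle_stimulus",
    "generate_polygon_stimulus",
    "make_image_set",
    "mirror_reverse",
    "rotate90",
    "solve_circle_radius",
    "white_area_ratio",
]

DEFAULT_INNER = 64
DEFAULT_MARGIN = 6
DEFAULT_WHITE = 1720


@dataclasses.dataclass(frozen=True)
class BorderMetrics:
    """Exact border lengths of a binary image under 4-adjacency.

    ``bh`` counts vertically-adjacent differing pixel pairs (horizontal
    border length in pixels); ``bv`` counts horizontally-adjacent differing
    pairs (vertical border length).
    """

    bh: int
    bv: int

    @property
    def total(self) -> int:
        return self.bh + self.bv


@dataclasses.dataclass(frozen=True)
class ProfileSpec:
    """Single-valued profile line: one column index per inner row.

    ``columns[r]`` is the number of white columns in inner row ``r`` when the
    frame side is the left one (white pixels are those with inner column
    ``c < columns[r]``).  Endpoints are pinned to ``n/2`` so the profile runs
    between the mid-points of the top and bottom inner edges.
    """

    columns: tuple[int, ...]
    frame_side: str = "left"

    def __post_init__(self) -> None:
        n = len(self.columns)
        if n < 2 or n % 2:
            raise ValueError(f"profile needs an even number of rows >= 2, got {n}")
        if self.frame_side not in ("left", "right"):
            raise ValueError(f"frame_side must be 'left' or 'right', got {self.frame_side!r}")
        if self.columns[0] != n // 2 or self.columns[-1] != n // 2:
            raise ValueError(
                f"profile endpoints must sit at the mid-point column {n // 2}, "
                f"got {self.columns[0]} and {self.columns[-1]}"
            )
        for r, c in enumerate(self.columns):
            if not 1 <= c <= n - 1:
                raise ValueError(f"profile column {c} at row {r} outside [1, {n - 1}]")

    @property
    def n(self) -> int:
        return len(self.columns)

    def flipped(self) -> "ProfileSpec":
        side = "right" if self.frame_side == "left" else "left"
        return ProfileSpec(self.columns, side)


@dataclasses.dataclass
class BinaryImage:
    """An ``N x N`` binary stimulus grid with inner size ``n`` and margin ``m``."""

    pixels: np.ndarray
    n: int
    m: int
    polarity_tag: str = "framed-on-black"
    label: str = ""
    profile: Optional[ProfileSpec] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        N = self.n + 2 * self.m
        if self.pixels.shape != (N, N):
            raise ValueError(f"expected {N}x{N} pixel array, got {self.pixels.shape}")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("pixels must be exactly 0 or 1")
        if self.polarity_tag not in ("framed-on-black", "inverted"):
            raise ValueError(f"unknown polarity_tag {self.polarity_tag!r}")
        if self.polarity_tag == "framed-on-black" and self.m and self.margin_mask().any():
            if self.pixels[self.margin_mask()].any():
                raise ValueError("framed-on-black image has white margin pixels")

    @property
    def N(self) -> int:
        return self.n + 2 * self.m

    @property
    def white_count(self) -> int:
        return int(self.pixels.sum())

    def inner(self) -> np.ndarray:
        """View of the inner ``n x n`` block."""
        return self.pixels[self.m : self.m + self.n, self.m : self.m + self.n]

    def inner_mask(self) -> np.ndarray:
        mask = np.zeros((self.N, self.N), dtype=bool)
        mask[self.m : self.m + self.n, self.m : self.m + self.n] = True
        return mask

    def margin_mask(self) -> np.ndarray:
        return ~self.inner_mask()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryImage):
            return NotImplemented
        return (
            self.n == other.n
            and self.m == other.m
            and self.polarity_tag == other.polarity_tag
            and np.array_equal(self.pixels, other.pixels)
        )


def _profile_white_count(columns: tuple[int, ...], frame_side: str, n: int) -> int:
    s = sum(columns)
    return s if frame_side == "left" else n * n - s


def generate_polygon_stimulus(
    spec: ProfileSpec,
    n: int = DEFAULT_INNER,
    m: int = DEFAULT_MARGIN,
    target_white: int = DEFAULT_WHITE,
) -> BinaryImage:
    """Rasterize a framed polygon with exactly ``target_white`` white pixels.

    The white region is the inner-square region on the frame side of the
    profile.  When the supplied profile does not hit ``target_white``
    exactly, interior profile columns (never the pinned endpoints) are
    shifted by single pixels in a deterministic round-robin sweep until the
    count matches.  The figure stays 4-connected because every row keeps at
    least one white pixel against the frame side.
    """
    if n % 2:
        raise ValueError(f"inner side n must be even, got {n}")
    if spec.n != n:
        raise ValueError(f"profile has {spec.n} rows but n={n}")
    if not 0 < target_white < n * n:
        raise ValueError(f"target_white must lie strictly inside (0, {n * n})")

    half = n // 2
    lo_sum = 2 * half + (n - 2) * 1
    hi_sum = 2 * half + (n - 2) * (n - 1)
    want_sum = target_white if spec.frame_side == "left" else n * n - target_white
    if not lo_sum <= want_sum <= hi_sum:
        lo_w = lo_sum if spec.frame_side == "left" else n * n - hi_sum
        hi_w = hi_sum if spec.frame_side == "left" else n * n - lo_sum
        raise ValueError(
            f"target_white={target_white} unreachable with pinned mid-point "
            f"endpoints; achievable range is [{lo_w}, {hi_w}]"
        )

    cols = list(spec.columns)
    deficit = want_sum - sum(cols)
    while deficit:
        moved = False
        for r in range(1, n - 1):
            if deficit > 0 and cols[r] < n - 1:
                cols[r] += 1
                deficit -= 1
                moved = True
            elif deficit < 0 and cols[r] > 1:
                cols[r] -= 1
                deficit += 1
                moved = True
            if not deficit:
                break
        if not moved:  # pragma: no cover - excluded by the range check above
            raise ValueError("profile adjustment stalled")
    adjusted = ProfileSpec(tuple(cols), spec.frame_side)

    N = n + 2 * m
    pixels = np.zeros((N, N), dtype=np.uint8)
    inner_cols = np.arange(n)
    p = np.array(adjusted.columns)
    if adjusted.frame_side == "left":
        inner = (inner_cols[None, :] < p[:, None]).astype(np.uint8)
    else:
        # frame_side="right": same dividing line, complementary side filled.
        inner = (inner_cols[None, :] >= p[:, None]).astype(np.uint8)
    pixels[m : m + n, m : m + n] = inner
    img = BinaryImage(pixels, n, m, profile=adjusted)
    assert img.white_count == target_white
    return img


def mirror_reverse(img: BinaryImage) -> BinaryImage:
    """Horizontal flip of the full array (left-right mirror image)."""
    profile = img.profile.flipped() if img.profile is not None else None
    return BinaryImage(
        np.flip(img.pixels, axis=1).copy(),
        img.n,
        img.m,
        polarity_tag=img.polarity_tag,
        label=img.label,
        profile=profile,
    )


def contrast_reverse(img: BinaryImage) -> BinaryImage:
    """Bitwise NOT of every pixel, margins included; borders are unchanged."""
    tag = "inverted" if img.polarity_tag == "framed-on-black" else "framed-on-black"
    return BinaryImage(
        1 - img.pixels,
        img.n,
        img.m,
        polarity_tag=tag,
        label=img.label,
        profile=img.profile,
    )


def fg_reverse(img: BinaryImage) -> BinaryImage:
    """Figure-ground reversal: the complementary inner region becomes the figure.

    The dividing contour is kept, the margins stay black and the white figure
    is the inner-square complement of the original figure (for a profile
    polygon this is exactly the same profile read from the opposite frame
    side).  Requires a framed-on-black image.
    """
    if img.polarity_tag != "framed-on-black":
        raise ValueError("fg_reverse expects a framed-on-black image")
    pixels = np.zeros_like(img.pixels)
    sl = slice(img.m, img.m + img.n)
    pixels[sl, sl] = 1 - img.pixels[sl, sl]
    profile = img.profile.flipped() if img.profile is not None else None
    return BinaryImage(pixels, img.n, img.m, label=img.label, profile=profile)


def rotate90(img: BinaryImage) -> BinaryImage:
    """Quarter-turn (counter-clockwise); exchanges horizontal and vertical borders."""
    return BinaryImage(
        np.rot90(img.pixels).copy(),
        img.n,
        img.m,
        polarity_tag=img.polarity_tag,
        label=img.label,
    )


def border_length(img: BinaryImage) -> BorderMetrics:
    """Exact 4-adjacency border counts (see :class:`BorderMetrics`)."""
    px = img.pixels
    bh = int((px[1:, :] != px[:-1, :]).sum())
    bv = int((px[:, 1:] != px[:, :-1]).sum())
    return BorderMetrics(bh=bh, bv=bv)


def white_area_ratio(img: BinaryImage, include_margin: bool = False) -> float:
    """White pixel count over ``N^2`` (margins included) or ``n^2`` (excluded)."""
    denom = img.N**2 if include_margin else img.n**2
    return img.white_count / denom


def generate_circle_stimulus(
    radius: float,
    connected: bool = False,
    n: int = DEFAULT_INNER,
    m: int = DEFAULT_MARGIN,
) -> BinaryImage:
    """Filled white disc centred in the inner square.

    With ``connected=True`` the disc is joined to the mid-points of the top
    and bottom inner edges by a 1-px-wide white bridge along the vertical
    midline, so that the shape runs between mid-points of opposed frame
    sides like the polygon profiles do.
    """
    if not 0 < radius < n / 2:
        raise ValueError(f"radius must lie in (0, {n / 2}), got {radius}")
    N = n + 2 * m
    centre = m + (n - 1) / 2
    rr, cc = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    pixels = (((rr - centre) ** 2 + (cc - centre) ** 2) <= radius**2).astype(np.uint8)
    if connected:
        pixels[m : m + n, m + n // 2] = 1
    return BinaryImage(pixels, n, m)


def solve_circle_radius(
    target_ratio: float = 0.42, n: int = DEFAULT_INNER, m: int = DEFAULT_MARGIN
) -> float:
    """Radius whose rasterized disc best matches the inner white-area ratio.

    Deterministic grid search in 1/16-px steps; ties resolve to the smaller
    radius.
    """
    best_r, best_err = None, None
    for r in np.arange(1.0, n / 2, 1 / 16):
        img = generate_circle_stimulus(float(r), connected=False, n=n, m=m)
        err = abs(img.white_count / n**2 - target_ratio)
        if best_err is None or err < best_err:
            best_r, best_err = float(r), err
    assert best_r is not None
    return best_r


@dataclasses.dataclass
class ImageSet:
    """An original stimulus with its mirror, contrast and FG reversals."""

    original: BinaryImage
    mirror: BinaryImage
    contrast: BinaryImage
    fg: BinaryImage
    label: str = ""

    MEMBERS = ("original", "mirror", "contrast", "fg")

    def member(self, name: str) -> BinaryImage:
        if name not in self.MEMBERS:
            raise KeyError(name)
        return getattr(self, name)

    def border_totals(self) -> dict[str, int]:
        return {name: border_length(self.member(name)).total for name in self.MEMBERS}

    @property
    def borders_conserved(self) -> bool:
        totals = set(self.border_totals().values())
        return len(totals) == 1


def make_image_set(original: BinaryImage, label: str = "") -> ImageSet:
    """Bundle an original with its three reversals.

    Polygon sets (original carries a profile) must conserve the total border
    length across all four members and fail loudly otherwise; circle sets
    merely record the inequality through :attr:`ImageSet.borders_conserved`.
    """
    s = ImageSet(
        original=original,
        mirror=mirror_reverse(original),
        contrast=contrast_reverse(original),
        fg=fg_reverse(original),
        label=label or original.label,
    )
    if original.profile is not None and not s.borders_conserved:
        raise AssertionError(
            f"border length not conserved for polygon set {label!r}: {s.border_totals()}"
        )
    return s


# ---------------------------------------------------------------------------
# Default fixtures
# ---------------------------------------------------------------------------

def _set1_profile(n: int = DEFAULT_INNER) -> ProfileSpec:
    """Smooth staircase profile: vertical borders dominate (Bv > Bh)."""
    if n != DEFAULT_INNER:
        raise ValueError("default profiles are defined for n=64")
    cols = [32] + [29] * 9 + [26] * 12 + [24] * 20 + [26] * 12 + [29] * 9 + [32]
    return ProfileSpec(tuple(cols), "left")


def _set2_profile(n: int = DEFAULT_INNER) -> ProfileSpec:
    """Comb-like profile with large total variation: horizontal borders dominate."""
    if n != DEFAULT_INNER:
        raise ValueError("default profiles are defined for n=64")
    cols = [32]
    level_hi, level_lo = 39, 18
    for block in range(10):
        level = level_hi if block % 2 == 0 else level_lo
        cols.extend([level] * 6)
    cols.extend([level_hi] * 2)
    cols.append(32)
    return ProfileSpec(tuple(cols), "left")


def default_fixtures(
    n: int = DEFAULT_INNER, m: int = DEFAULT_MARGIN, target_white: int = DEFAULT_WHITE
) -> tuple[ImageSet, ImageSet]:
    """The two built-in polygon image sets.

    Both originals carry the same white count (1720 by default, area ratio
    0.42 of the inner square).  Set 1 is vertical-border dominant
    (``Bv > Bh``), set 2 horizontal-border dominant (``Bh > Bv``); that
    orientation contrast is what the network's two output cells separate.
    """
    set1 = make_image_set(
        generate_polygon_stimulus(_set1_profile(n), n, m, target_white), label="set1"
    )
    set2 = make_image_set(
        generate_polygon_stimulus(_set2_profile(n), n, m, target_white), label="set2"
    )
    b1 = border_length(set1.original)
    b2 = border_length(set2.original)
    assert b1.bv > b1.bh, "set1 must be vertical-border dominant"
    assert b2.bh > b2.bv, "set2 must be horizontal-border dominant"
    assert set1.original.white_count == set2.original.white_count == target_white
    return set1, set2


def circle_profile_spec(radius: float, n: int = DEFAULT_INNER) -> ProfileSpec:
    """Profile line that bulges around a centred circle of the given radius.

    The profile runs from the top inner-edge mid-point down the display,
    around the circle, and back to the bottom mid-point, so the circular
    shape is connected to the frame at the mid-points of opposed sides and
    the total border length is conserved across all four reversals (it is an
    ordinary profile-class display).
    """
    if not 0 < radius < n / 2:
        raise ValueError(f"radius must lie in (0, {n / 2}), got {radius}")
    half = n // 2
    centre = (n - 1) / 2
    cols = []
    for r in range(n):
        dy = r - centre
        if abs(dy) < radius:
            bulge = int(round((radius**2 - dy**2) ** 0.5))
            cols.append(min(half + bulge, n - 1))
        else:
            cols.append(half)
    cols[0] = cols[-1] = half
    return ProfileSpec(tuple(cols), "left")


def default_circle_sets(
    n: int = DEFAULT_INNER, m: int = DEFAULT_MARGIN, target_white: int = DEFAULT_WHITE
) -> tuple[ImageSet, ImageSet]:
    """Circle control sets: (disconnected disc, frame-connected circle).

    The radius is solved so the disconnected disc's inner area ratio is as
    close as possible to the polygon fixtures' 0.42.  The disconnected disc
    touches no frame side, so its FG reversal does not conserve border
    length (the set records the inequality).  The connected control is a
    profile-class display — the profile line bulges around the circle
    between the two edge mid-points — with the white count adjusted to the
    polygon fixtures' value, so border length is conserved exactly and the
    standard FG-reversal reading applies.
    """
    r = solve_circle_radius(0.42, n, m)
    disc = generate_circle_stimulus(r, connected=False, n=n, m=m)
    disc.label = "circle-disconnected"
    conn = generate_polygon_stimulus(circle_profile_spec(r, n), n, m, target_white)
    conn.label = "circle-connected"
    return (
        make_image_set(disc, label="circle-disconnected"),
        make_image_set(conn, label="circle-connected"),
    )
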