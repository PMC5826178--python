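"""Membrane cleanup and watershed-based recovery of missing-dye boundaries.

Adipocytes are closely packed, so in a well-stained section all membrane
segments form one large connected network while debris ("minced membrane")
shows up as small isolated components.  Cleanup therefore drops small
components, applies opening / closing / dilation, inverts the mask and
fills holes to obtain solid cell interiors.

Staining failures leave gaps in the membrane, merging neighboring cells
into a single region.  Those gaps are recovered by a watershed transform of
the (negated) Euclidean distance map of the interior mask: a merged pair of
cells is a dumbbell-shaped region with two distance maxima, and the
watershed line between the two basins crosses the gap.  Because the
watershed over-segments, each candidate line is accepted as membrane only
if it is short (missing-dye gaps produce short boundary segments),

    L < L_T,

and separates sub-domains of similar area,

    A1 / A2 < R_a        (A1 >= A2),

both strict.  Accepted lines split their parent region; rejected lines are
erased, leaving the sub-domains merged.

Connectivity convention: membrane components are 8-connected, cell
interiors 4-connected.  The complementary duality prevents interiors from
leaking through diagonal membrane junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as morph
from skimage.segmentation import watershed

__all__ = [
    "MorphoParams",
    "WatershedCandidate",
    "WatershedFilterParams",
    "remove_small_components",
    "morph_cleanup",
    "cell_interior_mask",
    "distance_map",
    "watershed_split",
    "filter_watersheds",
    "resegment",
]

_STRUCT_4 = ndi.generate_binary_structure(2, 1)
_STRUCT_8 = ndi.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class MorphoParams:
    """Cleanup parameters: minimum component area and disk radii (pixels)."""

    area_threshold: int = 64
    open_radius: int = 1
    close_radius: int = 1
    dilate_radius: int = 1

    def __post_init__(self) -> None:
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")
        for name in ("open_radius", "close_radius", "dilate_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WatershedCandidate:
    """One internal watershed line between two flanking basins.

    ``area_large`` / ``area_small`` are the pixel areas of the two basins
    (``area_large >= area_small``); ``length`` is the number of line pixels.
    """

    line_pixels: tuple[tuple[int, int], ...]
    area_large: int
    area_small: int
    domain_id: int
    basin_pair: tuple[int, int] = field(default=(0, 0))

    @property
    def length(self) -> int:
        return len(self.line_pixels)

    @property
    def area_ratio(self) -> float:
        return self.area_large / self.area_small


@dataclass(frozen=True)
class WatershedFilterParams:
    """Acceptance thresholds: maximum line length L_T and area ratio R_a."""

    max_length: float = 50.0
    max_area_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ValueError("max_length must be > 0")
        if self.max_area_ratio <= 1:
            raise ValueError("max_area_ratio must be > 1")


def remove_small_components(mask: np.ndarray, area_threshold: int) -> np.ndarray:
    """Drop 8-connected membrane components with area strictly below T.

    Components with area exactly T survive.
    """
    mask = np.asarray(mask, dtype=bool)
    if area_threshold <= 0:
        return mask.copy()
    labels, n = ndi.label(mask, structure=_STRUCT_8)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= area_threshold
    keep[0] = False
    return keep[labels]


def morph_cleanup(mask: np.ndarray, params: MorphoParams) -> np.ndarray:
    """Apply opening, closing and dilation sequentially with disk elements."""
    out = np.asarray(mask, dtype=bool)
    if params.open_radius > 0:
        out = morph.opening(out, morph.disk(params.open_radius))
    if params.close_radius > 0:
        out = morph.closing(out, morph.disk(params.close_radius))
    if params.dilate_radius > 0:
        out = morph.dilation(out, morph.disk(params.dilate_radius))
    return out


def cell_interior_mask(membrane: np.ndarray) -> np.ndarray:
    """Invert the membrane mask and fill enclosed holes.

    After inversion the cell interiors are foreground.  Any hole — a
    non-interior region not connected to the image border, i.e. a detached
    membrane fragment floating inside a cell — is filled, absorbing it into
    the surrounding interior.
    """
    membrane = np.asarray(membrane, dtype=bool)
    return ndi.binary_fill_holes(~membrane, structure=_STRUCT_4)


def distance_map(interior: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each interior pixel to nearest background."""
    return ndi.distance_transform_edt(np.asarray(interior, dtype=bool))


def _seed_markers(dist: np.ndarray, interior: np.ndarray, h: float) -> np.ndarray:
    """Label regional maxima of the distance map, merged within depth h.

    h-maxima reconstruction merges maxima whose separating saddle is less
    than ``h`` below the lower peak, which keeps one seed per convex cell
    (pixelation produces many spurious shallow maxima) while preserving
    separate seeds for genuinely merged cells.

    Maxima are taken on the reconstruction of ``dist - h`` under ``dist``
    rather than on ``dist`` itself: in the reconstructed surface the saddle
    between two peaks closer than ``h`` in height joins their plateaus, so
    such peaks yield a single connected marker instead of two.
    """
    if h > 0:
        rec = morph.reconstruction(dist - h, dist, method="dilation")
        peaks = morph.local_maxima(rec)
    else:
        peaks = morph.local_maxima(dist)
    peaks &= interior
    # A shallow component (peak height <= h) is flattened into the
    # background plateau by the reconstruction and yields no maximum at
    # all; seed such components at their deepest pixel so no region is
    # dropped by the watershed.
    parents, _ = ndi.label(interior, structure=_STRUCT_4)
    missing = np.setdiff1d(np.unique(parents[interior]), np.unique(parents[peaks]))
    for cid in missing:
        rc = np.argwhere(parents == cid)
        r, c = rc[np.argmax(dist[rc[:, 0], rc[:, 1]])]
        peaks[r, c] = True
    markers, _ = ndi.label(peaks, structure=_STRUCT_8)
    return markers


def _neighbor_basins(
    labels: np.ndarray, parents: np.ndarray, r: int, c: int
) -> np.ndarray:
    """Basin labels in the 3x3 neighborhood of (r, c), own parent only.

    Interiors of two *different* parent components may touch diagonally;
    restricting the scan to pixels of the line pixel's own parent keeps
    basin pairings (and hence merges/splits) within one parent component.
    """
    h_img, w_img = labels.shape
    r0, r1 = max(r - 1, 0), min(r + 2, h_img)
    c0, c1 = max(c - 1, 0), min(c + 2, w_img)
    win = labels[r0:r1, c0:c1]
    same_parent = parents[r0:r1, c0:c1] == parents[r, c]
    return np.unique(win[(win > 0) & same_parent])


def watershed_split(
    dist: np.ndarray,
    interior: np.ndarray,
    h_maxima: float = 1.0,
) -> tuple[np.ndarray, list[WatershedCandidate]]:
    """Watershed the negated distance map; extract internal line candidates.

    Returns the (potentially over-segmented) basin label map, with line
    pixels labeled 0, and one :class:`WatershedCandidate` per watershed line
    separating a pair of adjacent basins inside the same parent component.
    Line pixels adjacent to three or more basins (junction points) belong to
    no single pair and are not counted in any candidate's length.
    """
    interior = np.asarray(interior, dtype=bool)
    if not interior.any():
        return np.zeros(interior.shape, dtype=np.int32), []
    markers = _seed_markers(dist, interior, h_maxima)
    labels = watershed(
        -dist, markers, mask=interior, connectivity=1, watershed_line=True
    ).astype(np.int32)
    parents, _ = ndi.label(interior, structure=_STRUCT_4)
    areas = np.bincount(labels.ravel())

    line_rc = np.argwhere(interior & (labels == 0))
    pair_pixels: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in line_rc:
        neigh = _neighbor_basins(labels, parents, r, c)
        if len(neigh) == 2:
            pair = (int(neigh[0]), int(neigh[1]))
            pair_pixels.setdefault(pair, []).append((int(r), int(c)))

    candidates = []
    for (a, b), pixels in sorted(pair_pixels.items()):
        r, c = pixels[0]
        a1, a2 = int(areas[a]), int(areas[b])
        if a2 > a1:
            a1, a2 = a2, a1
        candidates.append(
            WatershedCandidate(
                line_pixels=tuple(pixels),
                area_large=a1,
                area_small=a2,
                domain_id=int(parents[r, c]),
                basin_pair=(a, b),
            )
        )
    return labels, candidates


def filter_watersheds(
    candidates: list[WatershedCandidate], params: WatershedFilterParams
) -> list[WatershedCandidate]:
    """Accept candidates with L < L_T and A1/A2 < R_a (both strict).

    Accepted candidates are returned sorted by increasing length (the
    shortest, most membrane-like lines first), giving a deterministic
    processing order downstream.
    """
    accepted = [
        c
        for c in candidates
        if c.length < params.max_length and c.area_ratio < params.max_area_ratio
    ]
    return sorted(accepted, key=lambda c: (c.length, c.basin_pair))


def resegment(
    interior: np.ndarray,
    params: WatershedFilterParams = WatershedFilterParams(),
    h_maxima: float = 1.0,
) -> np.ndarray:
    """Split merged cells along accepted watershed lines.

    Basins whose shared line is rejected are merged back together; basins
    whose line is accepted stay separate, the line pixels becoming
    background (inferred membrane).  The resulting label map has labels
    1..n in raster order; when no candidate is accepted it coincides with
    the 4-connected components of ``interior``.

    In a parent component holding many basins, an accepted pair can still
    end up merged when its two basins are also joined through a chain of
    rejected lines (merging is transitive), so the final region count lies
    between the initial component count and components + accepted lines.
    """
    interior = np.asarray(interior, dtype=bool)
    dist = distance_map(interior)
    labels, candidates = watershed_split(dist, interior, h_maxima=h_maxima)
    parents, _ = ndi.label(interior, structure=_STRUCT_4)
    accepted = filter_watersheds(candidates, params)
    accepted_pairs = {c.basin_pair for c in accepted}

    n_basins = int(labels.max())
    if n_basins == 0:
        return np.zeros(interior.shape, dtype=np.int32)

    # Union-find over basins: merge every adjacent pair that was not accepted.
    parent = np.arange(n_basins + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for c in candidates:
        if c.basin_pair not in accepted_pairs:
            union(*c.basin_pair)

    # Junction line pixels can make basins adjacent without a two-basin
    # line between them; merge such pairs too unless explicitly accepted.
    line_rc = np.argwhere(interior & (labels == 0))
    for r, c in line_rc:
        neigh = _neighbor_basins(labels, parents, r, c)
        if len(neigh) > 2:
            for i in range(len(neigh)):
                for j in range(i + 1, len(neigh)):
                    pair = (int(neigh[i]), int(neigh[j]))
                    if pair not in accepted_pairs:
                        union(*pair)

    roots = np.array([find(i) for i in range(n_basins + 1)])
    merged = roots[labels]

    # Re-attach line pixels whose surrounding basins all merged into one root.
    out = merged.copy()
    for r, c in line_rc:
        neigh = _neighbor_basins(merged, parents, r, c)
        if len(neigh) == 1:
            out[r, c] = neigh[0]
        else:
            out[r, c] = 0

    return _renumber_raster(out)


def _renumber_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..n by first appearance in raster order."""
    flat = labels.ravel()
    order: dict[int, int] = {}
    for v in flat:
        if v > 0 and v not in order:
            order[int(v)] = len(order) + 1
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for old, new in order.items():
        lut[old] = new
    return lut[labels]
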