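"""Synthetic membrane-stained adipose tissue with exact ground truth.

Real adipocytes in a section are closely packed convex-ish regions
separated by thin stained membrane.  The generator emulates this with a
Voronoi tessellation of dart-thrown seed points: cells are the Voronoi
regions (which also gives the exact ground-truth label map), membrane is
drawn along region boundaries, and three degradation modes mimic common
staining / imaging defects:

* membrane gaps — contiguous boundary runs are erased, modeling membrane
  the dye failed to mark (merges neighboring cells unless re-segmented);
* debris — small dark fragments of minced membrane scattered in the tissue;
* vignette — radial illumination falloff darkening the image corners.

Rendering is brightfield-like: near-white background, brownish stain, mild
Gaussian texture noise, rendered to 8-bit RGB.  Identical specs (including
``rng_seed``) yield byte-identical images and label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import morphology
from skimage.segmentation import find_boundaries

__all__ = ["TissueSpec", "SeedPlacementError", "generate_tissue"]

#: Stain color at full darkness (v=0), pure white at v=255; linear ramp.
_STAIN_DARK = np.array([110.0, 60.0, 45.0])


class SeedPlacementError(RuntimeError):
    """Raised when seeds cannot satisfy min_spacing after bounded retries."""


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of one synthetic tissue image.

    Defaults model a moderately sized, moderately degraded section:
    ~35 cells of mean equivalent diameter ~45 px in a 256 x 256 frame,
    5% of the membrane skeleton erased in gap runs, a handful of debris
    fragments and a mild corner vignette.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 35
    min_spacing: float = 24.0
    membrane_width: int = 3
    membrane_intensity: float = 70.0
    background_intensity: float = 215.0
    noise_sigma: float = 5.0
    gap_fraction: float = 0.05
    gap_run_length: float = 12.0
    n_debris: int = 6
    debris_size: int = 12
    vignette_strength: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.membrane_intensity >= self.background_intensity:
            raise ValueError("membrane must be darker than background")


def _place_seeds(spec: TissueSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing seed placement honoring min_spacing."""
    seeds: list[np.ndarray] = []
    max_tries = 500 * spec.n_cells
    tries = 0
    while len(seeds) < spec.n_cells:
        if tries >= max_tries:
            raise SeedPlacementError(
                f"could not place {spec.n_cells} seeds with "
                f"min_spacing={spec.min_spacing} in "
                f"{spec.height}x{spec.width} after {max_tries} tries"
            )
        tries += 1
        p = rng.uniform([0, 0], [spec.height, spec.width])
        if all(np.hypot(*(p - q)) >= spec.min_spacing for q in seeds):
            seeds.append(p)
    return np.array(seeds)


def _erase_gaps(
    skeleton: np.ndarray, spec: TissueSpec, rng: np.random.Generator
) -> np.ndarray:
    """Erase contiguous runs of boundary-skeleton pixels totaling gap_fraction."""
    if spec.gap_fraction <= 0:
        return skeleton
    out = skeleton.copy()
    total = int(skeleton.sum())
    target = int(round(spec.gap_fraction * total))
    erased = 0
    struct = ndi.generate_binary_structure(2, 2)
    guard = 0
    while erased < target and guard < 10 * spec.n_cells:
        guard += 1
        remaining = np.argwhere(out)
        if len(remaining) == 0:
            break
        start = tuple(remaining[rng.integers(len(remaining))])
        run_len = max(2, int(round(rng.exponential(spec.gap_run_length))))
        # breadth-first walk along the 8-connected skeleton
        frontier = [start]
        run: list[tuple[int, int]] = []
        seen = {start}
        while frontier and len(run) < run_len:
            r, c = frontier.pop(0)
            run.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if (
                        q not in seen
                        and 0 <= q[0] < out.shape[0]
                        and 0 <= q[1] < out.shape[1]
                        and out[q]
                        and struct[dr + 1, dc + 1]
                    ):
                        seen.add(q)
                        frontier.append(q)
        for q in run:
            out[q] = False
        erased += len(run)
    return out


def _paint_debris(
    dark: np.ndarray, spec: TissueSpec, rng: np.random.Generator
) -> None:
    """Stamp small dark fragments (minced membrane) at random positions."""
    radius = max(1, int(round(np.sqrt(spec.debris_size / np.pi))))
    footprint = morphology.disk(radius)
    fh, fw = footprint.shape
    for _ in range(spec.n_debris):
        r = int(rng.integers(0, spec.height - fh + 1))
        c = int(rng.integers(0, spec.width - fw + 1))
        dark[r : r + fh, c : c + fw] |= footprint.astype(bool)


def generate_tissue(spec: TissueSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one synthetic tissue image.

    Returns ``(rgb, truth, truth_count)``: an H x W x 3 uint8 image, the
    ground-truth label map (Voronoi regions, labels 1..n_cells, every pixel
    labeled) and the true cell count.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _place_seeds(spec, rng)

    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    grid = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(seeds).query(grid)
    truth = (nearest + 1).reshape(spec.height, spec.width).astype(np.int32)

    skeleton = find_boundaries(truth, connectivity=1, mode="thick")
    skeleton = _erase_gaps(skeleton, spec, rng)
    extra = (spec.membrane_width - 1) // 2
    if extra > 0:
        membrane = morphology.dilation(skeleton, morphology.disk(extra))
    else:
        membrane = skeleton

    dark = membrane.copy()
    if spec.n_debris > 0:
        _paint_debris(dark, spec, rng)

    gray = np.full(
        (spec.height, spec.width), spec.background_intensity, dtype=np.float64
    )
    gray[dark] = spec.membrane_intensity
    gray = ndi.gaussian_filter(gray, 0.7)  # soft stain edges

    if spec.vignette_strength > 0:
        cy, cx = (spec.height - 1) / 2, (spec.width - 1) / 2
        d = np.hypot(rows - cy, cols - cx)
        gray *= 1.0 - spec.vignette_strength * (d / d.max()) ** 2

    gray += rng.normal(0.0, spec.noise_sigma, gray.shape)
    gray = gray.clip(0, 255)

    t = (gray / 255.0)[..., None]
    rgb = _STAIN_DARK * (1 - t) + 255.0 * t
    rgb = np.floor(rgb + 0.5).clip(0, 255).astype(np.uint8)
    return rgb, truth, spec.n_cells


def spec_to_dict(spec: TissueSpec) -> dict:
    """Spec echo for the truth JSON sidecar."""
    return asdict(spec)
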