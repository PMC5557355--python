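"""Seeded synthetic-data generators with ground truth.

Every input the analysis pipeline consumes can be fabricated here: two-channel
puncta fields (pre/postsynaptic marker images with a controlled fraction of
truly paired red/green couples), 1-px-wide dendritic-tree skeletons with known
junction/tip counts and total length, per-spine morphometric tables with
labels assigned by literal evaluation of the classification predicates, and
qPCR Ct tables with planted fold changes.  All generators are deterministic
given their spec (which embeds the seed), so downstream modules can be tested
against exact generative bookkeeping without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = [
    "GenerationError",
    "PunctaFieldSpec",
    "PunctaGroundTruth",
    "TreeSpec",
    "TreeSample",
    "SpineSetSpec",
    "CtSpec",
    "generate_psf",
    "generate_puncta_field",
    "generate_tree",
    "generate_spine_table",
    "generate_ct_table",
]


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its geometric constraints."""


# --------------------------------------------------------------------------
# Point spread function
# --------------------------------------------------------------------------

def generate_psf(
    sigma_um: float,
    pixel_size_um: float = 0.07,
    truncate_radius_px: int | None = None,
) -> np.ndarray:
    """Normalized 2-D Gaussian blur kernel.

    The microscope blur is modeled as an isotropic Gaussian of standard
    deviation ``sigma_um``; with sigma ≈ 0.055 μm the kernel FWHM
    (2.355 sigma ≈ 0.13 μm) matches the lateral resolution of a deconvolved
    confocal image sampled at 70 nm/pixel.

    Returns an odd-sized square kernel that is nonnegative, symmetric under
    reflection and transposition, and sums to 1.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be > 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    sigma_px = sigma_um / pixel_size_um
    if truncate_radius_px is None:
        truncate_radius_px = max(1, int(math.ceil(4.0 * sigma_px)))
    if truncate_radius_px < 1:
        raise ValueError("truncate_radius_px must be >= 1")
    ax = np.arange(-truncate_radius_px, truncate_radius_px + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    return kernel / kernel.sum()


# --------------------------------------------------------------------------
# Two-channel puncta fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctaFieldSpec:
    """Parameters of a synthetic two-channel synaptic-puncta field.

    Defaults emulate confocal acquisition of PSD95 (red) / vGlut1 (green)
    immunofluorescence at 70 nm/pixel.  Paired couples are placed with a small
    fixed center offset so that their segmented areas genuinely overlap after
    blurring; all other puncta are kept at least ``min_separation_factor``
    times the maximum radius apart so that no accidental pairs arise.
    """

    image_shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.07
    n_red: int = 200
    n_green: int = 200
    pairing_fraction: float = 0.5
    paired_offset_um: float = 0.05
    punctum_radius_um_range: tuple[float, float] = (0.30, 0.50)
    amplitude_range: tuple[float, float] = (80.0, 150.0)
    background: float = 10.0
    gaussian_noise_sd: float = 2.0
    psf_sigma_um: float = 0.055
    poisson_noise: bool = True
    render_mode: str = "gaussian"  # "gaussian" spots or hard "disk"s
    min_separation_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pairing_fraction <= 1.0):
            raise ValueError("pairing_fraction must lie in [0, 1]")
        if self.n_red < 0 or self.n_green < 0:
            raise ValueError("puncta counts must be >= 0")
        lo, hi = self.punctum_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("punctum_radius_um_range must be positive and ordered")
        for name in ("pixel_size_um", "paired_offset_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.render_mode not in ("gaussian", "disk"):
            raise ValueError("render_mode must be 'gaussian' or 'disk'")


@dataclass
class PunctaGroundTruth:
    """Generative bookkeeping for a puncta field.

    Centers and radii are in μm (x = column direction, y = row direction,
    origin at the top-left pixel center).  ``paired_index_pairs`` holds
    (red_index, green_index) couples; a punctum appears in at most one pair.
    """

    red_centers: list[tuple[float, float, float]]
    green_centers: list[tuple[float, float, float]]
    paired_index_pairs: list[tuple[int, int]]
    roi_polygon: list[tuple[float, float]]


def _place_points(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_sep: float,
    existing: list[tuple[float, float]],
    max_attempts_per_point: int = 2000,
) -> list[tuple[float, float]]:
    """Uniform rejection sampling with a minimum-separation constraint."""
    x0, y0, x1, y1 = bounds
    pts: list[tuple[float, float]] = []
    anchors = list(existing)
    for _ in range(n):
        for _attempt in range(max_attempts_per_point):
            x = rng.uniform(x0, x1)
            y = rng.uniform(y0, y1)
            ok = all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in anchors)
            if ok:
                pts.append((x, y))
                anchors.append((x, y))
                break
        else:
            raise GenerationError(
                "could not place puncta with the requested separation; "
                "enlarge the image or reduce the counts"
            )
    return pts


def _render_spot(img: np.ndarray, x_um: float, y_um: float, radius_um: float,
                 amplitude: float, pixel_size_um: float, mode: str) -> None:
    r_px = radius_um / pixel_size_um
    cx = x_um / pixel_size_um
    cy = y_um / pixel_size_um
    ext = int(math.ceil(4 * r_px)) + 1
    r0 = max(0, int(cy) - ext)
    r1 = min(img.shape[0], int(cy) + ext + 1)
    c0 = max(0, int(cx) - ext)
    c1 = min(img.shape[1], int(cx) + ext + 1)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d2 = (rows - cy) ** 2 + (cols - cx) ** 2
    if mode == "disk":
        img[r0:r1, c0:c1] += amplitude * (d2 <= r_px**2)
    else:
        img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * r_px**2))


def generate_puncta_field(
    spec: PunctaFieldSpec,
) -> tuple[np.ndarray, np.ndarray, PunctaGroundTruth]:
    """Render a registered red/green puncta field with known pairing.

    Exactly ``round(pairing_fraction * min(n_red, n_green))`` red/green
    couples are placed at a center-to-center offset of ``paired_offset_um``;
    the remaining puncta of both channels are placed uniformly inside the ROI
    with a minimum separation of ``min_separation_factor`` times the maximum
    radius from every unrelated punctum.  Spots are convolved with the
    Gaussian PSF, then Poisson noise is applied to the signal (if enabled)
    and additive Gaussian read noise on top.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape_px
    px = spec.pixel_size_um
    r_lo, r_hi = spec.punctum_radius_um_range
    min_sep = spec.min_separation_factor * r_hi

    margin = 3.0 * r_hi + spec.paired_offset_um
    x_max = (w - 1) * px
    y_max = (h - 1) * px
    if x_max - 2 * margin <= 0 or y_max - 2 * margin <= 0:
        raise GenerationError("image too small for the requested punctum size")
    roi = [
        (margin, margin),
        (x_max - margin, margin),
        (x_max - margin, y_max - margin),
        (margin, y_max - margin),
    ]
    bounds = (margin, margin, x_max - margin, y_max - margin)

    n_pairs = int(round(spec.pairing_fraction * min(spec.n_red, spec.n_green)))
    anchors = _place_points(rng, n_pairs + (spec.n_red - n_pairs) + (spec.n_green - n_pairs),
                            bounds, min_sep, existing=[])

    pair_anchors = anchors[:n_pairs]
    single_red = anchors[n_pairs : n_pairs + (spec.n_red - n_pairs)]
    single_green = anchors[n_pairs + (spec.n_red - n_pairs):]

    red_centers: list[tuple[float, float, float]] = []
    green_centers: list[tuple[float, float, float]] = []
    paired: list[tuple[int, int]] = []
    for i, (x, y) in enumerate(pair_anchors):
        theta = rng.uniform(0, 2 * math.pi)
        dx = 0.5 * spec.paired_offset_um * math.cos(theta)
        dy = 0.5 * spec.paired_offset_um * math.sin(theta)
        red_centers.append((x - dx, y - dy, rng.uniform(r_lo, r_hi)))
        green_centers.append((x + dx, y + dy, rng.uniform(r_lo, r_hi)))
        paired.append((i, i))
    for x, y in single_red:
        red_centers.append((x, y, rng.uniform(r_lo, r_hi)))
    for x, y in single_green:
        green_centers.append((x, y, rng.uniform(r_lo, r_hi)))

    psf = generate_psf(spec.psf_sigma_um, px)
    images = []
    for centers in (red_centers, green_centers):
        img = np.zeros((h, w), dtype=float)
        for x, y, r in centers:
            amp = rng.uniform(*spec.amplitude_range)
            _render_spot(img, x, y, r, amp, px, spec.render_mode)
        img = fftconvolve(img, psf, mode="same")
        np.clip(img, 0, None, out=img)
        if spec.poisson_noise:
            img = rng.poisson(img + spec.background).astype(float)
        else:
            img = img + spec.background
        if spec.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=img.shape)
        images.append(np.clip(img, 0, None))

    truth = PunctaGroundTruth(red_centers, green_centers, paired, roi)
    return images[0], images[1], truth


# --------------------------------------------------------------------------
# Dendritic-tree skeletons
# --------------------------------------------------------------------------

# 8-compass unit steps as (drow, dcol); index i rotated by +-45 deg is i +- 1 mod 8
_DIRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a synthetic dendritic arbor skeleton.

    Segments run along the 8 compass directions (step length 1 or sqrt(2)
    pixels) so the rasterized skeleton is exactly one pixel wide and its
    graph-theoretic content is known by construction.  At a branch point the
    two daughters turn +-45 deg from a straight parent and +-90 deg from a
    diagonal parent (the unique turns whose first pixels are not 8-adjacent
    to each other or to the parent's penultimate pixel, keeping every
    junction exactly degree 3).  A daughter colliding with already-drawn
    structure is silently dropped, and the bookkeeping reflects what was
    actually drawn.
    """

    n_primary: int = 4
    branch_prob_per_junction: float = 0.7
    segment_length_um_range: tuple[float, float] = (3.0, 8.0)
    max_depth: int = 4
    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.16
    soma_radius_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (1 <= self.n_primary <= 8):
            raise ValueError("n_primary must be in 1..8")
        lo, hi = self.segment_length_um_range
        if not (0 < lo <= hi):
            raise ValueError("segment lengths must be positive and ordered")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class TreeSample:
    """A generated skeleton plus its exact generative ground truth."""

    skeleton: np.ndarray  # bool, 1-px-wide skeleton (excludes soma interior)
    soma_mask: np.ndarray  # bool disk
    pixel_size_um: float
    nodes: int  # junctions where two daughters were drawn
    tips: int  # terminal segment ends
    total_length_um: float
    n_primary_drawn: int


def _step_len_um(d: tuple[int, int], pixel_size_um: float) -> float:
    return pixel_size_um * (math.sqrt(2.0) if d[0] != 0 and d[1] != 0 else 1.0)


def generate_tree(spec: TreeSpec) -> TreeSample:
    """Grow a collision-free compass-direction tree from a central soma disk."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape_px
    occupied = np.zeros((h, w), dtype=bool)
    skeleton = np.zeros((h, w), dtype=bool)
    cy, cx = h // 2, w // 2
    rr, cc = np.ogrid[:h, :w]
    soma = (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.soma_radius_px**2
    occupied |= soma

    def neighbors_in(mask: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (r + dr, c + dc)
                if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
                    out.append(q)
        return out

    def candidate_ok(pixels: list[tuple[int, int]], anchor: tuple[int, int] | None,
                     allow_soma_first: bool) -> bool:
        for i, q in enumerate(pixels):
            if not (1 <= q[0] < h - 1 and 1 <= q[1] < w - 1):
                return False
            if occupied[q]:
                return False
            occ_nb = neighbors_in(occupied, q)
            if i == 0:
                for nb in occ_nb:
                    if nb == anchor:
                        continue
                    if allow_soma_first and soma[nb]:
                        continue
                    return False
            elif occ_nb:
                return False
        return True

    def sample_steps(d: tuple[int, int]) -> int:
        lo, hi = spec.segment_length_um_range
        target = rng.uniform(lo, hi)
        return max(2, int(round(target / _step_len_um(d, spec.pixel_size_um))))

    nodes = 0
    tips = 0
    total_len = 0.0
    n_primary_drawn = 0

    def grow(anchor: tuple[int, int] | None, di: int, depth: int) -> bool:
        """Draw one segment (and recursively its subtree); True if drawn."""
        nonlocal nodes, tips, total_len, n_primary_drawn
        d = _DIRS[di]
        k = sample_steps(d)
        if anchor is None:
            # primary dendrite: first pixel just outside the soma along d
            p = (cy, cx)
            while soma[p]:
                p = (p[0] + d[0], p[1] + d[1])
            pixels = [p] + [(p[0] + j * d[0], p[1] + j * d[1]) for j in range(1, k + 1)]
            if not candidate_ok(pixels, anchor=None, allow_soma_first=True):
                return False
            n_primary_drawn += 1
        else:
            pixels = [(anchor[0] + j * d[0], anchor[1] + j * d[1])
                      for j in range(1, k + 1)]
            if not candidate_ok(pixels, anchor=anchor, allow_soma_first=False):
                return False
        for q in pixels:
            skeleton[q] = True
            occupied[q] = True
        total_len += k * _step_len_um(d, spec.pixel_size_um)
        end = pixels[-1]

        branch = (depth < spec.max_depth
                  and rng.uniform() < spec.branch_prob_per_junction)
        if not branch:
            tips += 1
            return True
        turn = 1 if di % 2 == 0 else 2  # straight parent: +-45; diagonal: +-90
        drawn = 0
        for ndi in ((di + turn) % 8, (di - turn) % 8):
            if grow(end, ndi, depth + 1):
                drawn += 1
        if drawn == 2:
            nodes += 1
        elif drawn == 0:
            tips += 1
        # exactly one drawn daughter is a bend: neither junction nor tip
        return True

    for di in rng.permutation(8)[: spec.n_primary]:
        grow(None, int(di), 1)

    return TreeSample(
        skeleton=skeleton & ~soma,
        soma_mask=soma,
        pixel_size_um=spec.pixel_size_um,
        nodes=nodes,
        tips=tips,
        total_length_um=total_len,
        n_primary_drawn=n_primary_drawn,
    )


# --------------------------------------------------------------------------
# Spine morphometry tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineSetSpec:
    """Ranges for random per-spine morphometric records.

    Defaults span all regions of the stubby/mushroom/thin decision rules so a
    generated table contains every reachable label.
    """

    n_spines: int = 200
    length_um_range: tuple[float, float] = (0.3, 3.5)
    head_width_um_range: tuple[float, float] = (0.1, 1.0)
    neck_width_um_range: tuple[float, float] = (0.05, 0.8)
    min_width_um_range: tuple[float, float] = (0.05, 0.6)
    branched_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_um_range", "head_width_um_range",
                     "neck_width_um_range", "min_width_um_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.n_spines < 0:
            raise ValueError("n_spines must be >= 0")


def _literal_spine_label(length: float, head: float, neck: float,
                         min_w: float) -> str:
    """Direct transcription of the three classification predicates.

    Evaluated here independently of the spines module (which has its own
    implementation) so generated labels can serve as an oracle.  Precedence:
    stubby, then mushroom, then thin; no rule -> unclassified.
    """
    if length < 1.0 and 0.9 < min_w / head < 1.1:
        return "stubby"
    if length < 3.0 and head / neck > 0.75:
        return "mushroom"
    if head / length < 0.5:
        return "thin"
    return "unclassified"


def generate_spine_table(spec: SpineSetSpec) -> pd.DataFrame:
    """Random spine records labeled by literal rule evaluation.

    Columns: length_um, mean_width_head_um, max_width_neck_um, min_width_um,
    volume_um3, is_branched, parent_dendrite_id, true_class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_spines
    length = rng.uniform(*spec.length_um_range, size=n)
    head = rng.uniform(*spec.head_width_um_range, size=n)
    neck = rng.uniform(*spec.neck_width_um_range, size=n)
    min_w = rng.uniform(*spec.min_width_um_range, size=n)
    volume = (math.pi / 6.0) * head**3 + 0.25 * math.pi * neck**2 * length
    branched = rng.uniform(size=n) < spec.branched_fraction
    labels = [
        _literal_spine_label(length[i], head[i], neck[i], min_w[i]) for i in range(n)
    ]
    return pd.DataFrame(
        {
            "length_um": length,
            "mean_width_head_um": head,
            "max_width_neck_um": neck,
            "min_width_um": min_w,
            "volume_um3": volume,
            "is_branched": branched,
            "parent_dendrite_id": rng.integers(0, max(1, n // 20), size=n),
            "true_class": labels,
        }
    )


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CtSpec:
    """Planted-fold-change qPCR design.

    Ct values follow Ct(target, condition) = Ct(target, reference) -
    log2(fold_change(condition)) + noise, with the housekeeping gene constant
    across conditions up to noise (amplification efficiency 2 assumed, as in
    the 2^-ddCt model).  ``true_fold_changes`` maps each condition to a
    positive fold relative to the reference condition (which must map to 1).
    """

    genes: tuple[str, ...] = ("En1", "En2")
    housekeeping_gene: str = "HPRT"
    conditions: tuple[str, ...] = ("E16", "P5")
    reference_condition: str = "E16"
    true_fold_changes: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("En1", (("E16", 1.0), ("P5", 1.0))),
        ("En2", (("E16", 1.0), ("P5", 0.25))),
    )
    base_ct: float = 28.0
    housekeeping_ct: float = 20.0
    ct_noise_sd: float = 0.2
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        folds = dict((g, dict(v)) for g, v in self.true_fold_changes)
        for g in self.genes:
            if folds.get(g, {}).get(self.reference_condition, 1.0) != 1.0:
                raise ValueError("reference condition must have fold change 1")
            for cond, f in folds.get(g, {}).items():
                if f <= 0:
                    raise ValueError("fold changes must be positive")

    def fold(self, gene: str, condition: str) -> float:
        return dict((g, dict(v)) for g, v in self.true_fold_changes)[gene][condition]


def generate_ct_table(spec: CtSpec) -> pd.DataFrame:
    """Tidy Ct table: columns gene, condition, replicate, ct."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        for rep in range(spec.replicates):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
            rows.append((spec.housekeeping_gene, cond, rep, spec.housekeeping_ct + noise))
            for gene in spec.genes:
                ct = spec.base_ct - math.log2(spec.fold(gene, cond))
                noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                rows.append((gene, cond, rep, ct + noise))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
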