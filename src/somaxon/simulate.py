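"""Seeded synthetic fluorescence image generator for both compartments.

The generator emulates single-marker (beta-tubulin III-like) grayscale
micrographs of a compartmentalized sensory-neuron culture:

* **soma area** - a field of round bright cell bodies. Damage shrinks the
  bodies, perturbs their contours with low-order angular harmonics, and
  sprinkles small bright puncta (Poisson-distributed per cell) emulating
  autofluorescent debris.
* **axon area** - a field of elongated, predominantly horizontal fibers.
  Damage pulls fibers toward shared bundle paths (aggregation, leaving
  low-intensity cavities) and blanks stretches of fiber (fragmentation /
  transection).

Images are 16-bit with a background around 5% of full scale; the noise
model is Poisson shot noise plus Gaussian read noise. All geometry is
expressed relative to a full-scale 2304-pixel local image and multiplied
by ``scale``, so a quarter-scale 576-pixel image is a geometrically
faithful reduction that preserves the tile-count arithmetic downstream.

Every function is deterministic given (parameters, seed): the same call
twice returns bit-identical pixel arrays.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError
from .images import BIT_DEPTH_MAX, AreaImage
from .phenotypes import (CompoundProfile, PhenotypeParams, StudyDesign,
                         profiles_by_name)
from .tiling import BASE_IMAGE_SIDE

# Full-scale geometry constants (pixels at a 2304-pixel local image).
SOMA_RADIUS = 56.0          # mean cell-body radius
SOMA_RADIUS_CV = 0.15       # radius coefficient of variation
SOMA_PEAK_MEAN = 0.55       # blob peak intensity (fraction of full scale)
SOMA_PEAK_SD = 0.05
PUNCTA_SIGMA = 8.0          # punctum Gaussian sigma
PUNCTA_AMPLITUDE = 0.55     # punctum added intensity
PUNCTA_MIN_SEP = 24.0       # min separation between puncta in one cell
DEFAULT_N_SOMATA = 60

FIBER_SIGMA = 4.8           # fiber cross-section Gaussian sigma
FIBER_AMP_MEAN = 0.45
FIBER_AMP_SD = 0.07
FIBER_MEANDER = 36.0        # meander amplitude of a free fiber
FRAG_CELL = 64.0            # fragmentation cell length (one "unit" of length)
DEFAULT_N_FIBERS = 28
N_BUNDLES = 3

BACKGROUND = 0.05           # background level, fraction of full scale
PHOTON_SCALE = 800.0        # photons per unit intensity (shot noise strength)

# Baseline culture heterogeneity, independent of treatment: a small fraction
# of cells look stressed even in vehicle wells, and fiber fields contain
# occasional clumps/varicosities. Real negative controls are not pristine -
# the assay's decision line exists precisely to absorb this background rate.
SPONTANEOUS_STRESS_RATE = 0.02   # per soma: drawn with moderate damage
SPONTANEOUS_STRESS_LEVEL = 0.6   # severity-equivalent of a stressed cell
SPONTANEOUS_CLUMP_MEAN = 1.5     # Poisson mean of mini-bundles per axon image
CLUMP_HALF_WIDTH = 100.0         # base Gaussian half-width of a mini-bundle (full-scale px)


def _finalize(img: np.ndarray, params: PhenotypeParams,
              rng: np.random.Generator) -> np.ndarray:
    """Add background, shot + read noise, quantize to uint16."""
    base = np.clip(img + BACKGROUND, 0.0, 1.0)
    shot = rng.poisson(base * PHOTON_SCALE).astype(np.float64) / PHOTON_SCALE
    noisy = shot + rng.normal(0.0, params.background_noise_sd, size=img.shape)
    return (np.clip(noisy, 0.0, 1.0) * BIT_DEPTH_MAX).round().astype(np.uint16)


def _check_dims(width: int, height: int) -> None:
    if width < 1 or height < 1:
        raise DimensionError(f"image dimensions must be positive, got {width}x{height}")


def generate_soma_image(params: PhenotypeParams, width: int = 576,
                        height: int = 576, seed: int = 0, *,
                        n_somata: int | None = None,
                        scale: float | None = None,
                        spontaneous: bool = True) -> AreaImage:
    """Render one soma-area image.

    ``scale`` defaults to ``width / 2304`` so geometry follows image size.
    ``n_somata`` is the number of cell bodies (default 60); damage does not
    remove cells, it shrinks and deforms them. ``spontaneous`` controls the
    baseline rate of stressed-looking cells present even without treatment.
    """
    _check_dims(width, height)
    if scale is None:
        scale = width / BASE_IMAGE_SIDE
    n = DEFAULT_N_SOMATA if n_somata is None else int(n_somata)
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width), dtype=np.float64)

    r0 = SOMA_RADIUS * scale
    p_sigma = PUNCTA_SIGMA * scale
    p_sep = PUNCTA_MIN_SEP * scale
    harmonics = np.arange(2, 6)

    lvl = SPONTANEOUS_STRESS_LEVEL
    for _ in range(n):
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        stressed = spontaneous and rng.random() < SPONTANEOUS_STRESS_RATE
        shrinkage = params.soma_shrinkage
        irregularity = params.contour_irregularity
        dimming = params.luminance_loss
        puncta_rate = params.puncta_rate
        if stressed:  # spontaneous stress overrides milder treatment effects
            shrinkage = max(shrinkage, 0.45 * lvl)
            irregularity = max(irregularity, 0.35 * lvl)
            dimming = max(dimming, 0.35 * lvl)
            puncta_rate = max(puncta_rate, 6.0 * lvl)
        rb_orig = r0 * float(np.clip(rng.normal(1.0, SOMA_RADIUS_CV), 0.6, 1.5))
        rb = rb_orig * (1.0 - shrinkage)
        peak = float(np.clip(rng.normal(SOMA_PEAK_MEAN, SOMA_PEAK_SD), 0.40, 0.68))
        peak *= (1.0 - dimming)
        a = rng.normal(0.0, 1.0, size=harmonics.size)
        b = rng.normal(0.0, 1.0, size=harmonics.size)
        norm = np.sqrt((a ** 2 + b ** 2).sum() / 2.0)
        if norm > 0:
            a, b = a / norm, b / norm

        reach = rb * (1.0 + 2.5 * irregularity) + 2.0
        x0, x1 = int(max(0, np.floor(cx - reach))), int(min(width, np.ceil(cx + reach) + 1))
        y0, y1 = int(max(0, np.floor(cy - reach))), int(min(height, np.ceil(cy + reach) + 1))
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx, dy = xs - cx, ys - cy
        d = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        g = np.zeros_like(theta)
        for k, ak, bk in zip(harmonics, a, b):
            g += ak * np.cos(k * theta) + bk * np.sin(k * theta)
        rho = rb * np.clip(1.0 + irregularity * g, 0.2, None)
        rel = np.clip(d / rho, 0.0, 1.0)
        profile = peak * (1.0 - rel ** 2) ** 0.7
        profile[d > rho] = 0.0
        np.maximum(img[y0:y1, x0:x1], profile, out=img[y0:y1, x0:x1])

        # bright puncta (autofluorescent debris) scattered over the cell's
        # original footprint - a shrunken cell leaves debris where it was
        n_p = int(rng.poisson(puncta_rate))
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_p and attempts < 50 * max(n_p, 1):
            attempts += 1
            rr = 0.7 * rb_orig * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2 * np.pi)
            px, py = cx + rr * np.cos(ang), cy + rr * np.sin(ang)
            if any(np.hypot(px - qx, py - qy) < p_sep for qx, qy in placed):
                continue
            placed.append((px, py))
        for px, py in placed:
            half = int(np.ceil(3 * p_sigma))
            gx0, gx1 = int(max(0, np.floor(px - half))), int(min(width, np.ceil(px + half) + 1))
            gy0, gy1 = int(max(0, np.floor(py - half))), int(min(height, np.ceil(py + half) + 1))
            if gx0 >= gx1 or gy0 >= gy1:
                continue
            yg, xg = np.mgrid[gy0:gy1, gx0:gx1]
            bump = PUNCTA_AMPLITUDE * np.exp(
                -((xg - px) ** 2 + (yg - py) ** 2) / (2 * p_sigma ** 2))
            img[gy0:gy1, gx0:gx1] += bump

    pixels = _finalize(img, params, rng)
    return AreaImage(pixels=pixels, area_kind="soma", seed=seed,
                     meta={"params": params, "n_somata": n})


def _smooth_path(rng: np.random.Generator, width: int, amplitude: float) -> np.ndarray:
    """A smooth zero-mean meander over x in [0, width)."""
    x = np.arange(width) / max(width, 1)
    path = np.zeros(width)
    for k in (1, 2, 3):
        path += (rng.normal(0.0, 1.0) * np.sin(2 * np.pi * k * x) +
                 rng.normal(0.0, 1.0) * np.cos(2 * np.pi * k * x)) / k
    path -= path.mean()
    return amplitude * path / 2.0


def generate_axon_image(params: PhenotypeParams, width: int = 576,
                        height: int = 576, seed: int = 0, *,
                        n_fibers: int | None = None,
                        scale: float | None = None,
                        spontaneous: bool = True) -> AreaImage:
    """Render one axon-area image of oriented fiber-like curves.

    ``spontaneous`` controls the baseline rate of clump/varicosity
    anomalies present even in damage-free fields.
    """
    _check_dims(width, height)
    if scale is None:
        scale = width / BASE_IMAGE_SIDE
    m = DEFAULT_N_FIBERS if n_fibers is None else int(n_fibers)
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width), dtype=np.float64)

    sigma = FIBER_SIGMA * scale
    meander = FIBER_MEANDER * scale
    cell = max(1, int(round(FRAG_CELL * scale)))
    x = np.arange(width)

    bundle_y = rng.uniform(0.15 * height, 0.85 * height, size=N_BUNDLES)
    bundle_path = [by + _smooth_path(rng, width, meander) for by in bundle_y]

    # baseline outgrowth variability: even untreated fields show a little
    # bundling and the odd broken fiber, on a continuum with mild damage
    agg = params.aggregation
    frag = params.fragmentation
    if spontaneous:
        agg = max(agg, float(rng.beta(1.0, 4.0)) * 0.25)
        frag = max(frag, float(rng.beta(1.0, 4.0)) * 0.15)
    span = int(np.ceil(3 * sigma)) + 1
    offsets = np.arange(-span, span + 1)

    # healthy outgrowth covers the channel fairly evenly: stratified-uniform
    # baselines (one fiber per vertical stratum, jittered) rather than iid
    strata = rng.permutation(m)
    fiber_paths: list[np.ndarray] = []
    baselines: list[float] = []
    amps: list[float] = []

    for fi in range(m):
        lo, hi = 0.06 * height, 0.94 * height
        pitch = (hi - lo) / max(m, 1)
        y0 = lo + (strata[fi] + 0.5 + rng.uniform(-0.45, 0.45)) * pitch
        solo = y0 + _smooth_path(rng, width, meander)
        j = int(np.argmin(np.abs(bundle_y - y0)))
        within = rng.normal(0.0, 3.0 * scale * 4)  # fiber offset inside its bundle
        bund = bundle_path[j] + within * (1.0 - 0.8 * agg)
        fiber_paths.append((1.0 - agg) * solo + agg * bund)
        baselines.append(y0)
        amps.append(float(np.clip(rng.normal(FIBER_AMP_MEAN, FIBER_AMP_SD),
                                  0.30, 0.65)))

    # spontaneous local aggregation: neighboring fibers converge onto an
    # anchor over a short window. Strength varies per event; the strong end
    # overlaps what mild treatment-induced aggregation looks like locally,
    # which is why negative controls never score exactly zero.
    n_clumps = int(rng.poisson(SPONTANEOUS_CLUMP_MEAN)) if (spontaneous and m > 4) else 0
    for _ in range(n_clumps):
        u = float(rng.uniform(0.3, 0.9))          # local severity of the event
        anchor = int(rng.integers(0, m))
        xc = float(rng.uniform(0, width))
        w_half = (CLUMP_HALF_WIDTH + 300.0 * u) * scale
        taper = np.exp(-((x - xc) ** 2) / (2 * w_half ** 2))
        order = np.argsort(np.abs(np.asarray(baselines) - baselines[anchor]))
        n_join = 2 + int(round(2 * u))
        for j in order[1:1 + n_join]:
            offset = rng.normal(0.0, (3.0 - 2.0 * u) * scale * 4)
            fiber_paths[j] = fiber_paths[j] + taper * (
                fiber_paths[anchor] + offset - fiber_paths[j])

    for fi in range(m):
        y = fiber_paths[fi]
        n_cells = width // cell + 1
        keep = rng.random(n_cells) >= frag
        mask = np.repeat(keep, cell)[:width].astype(np.float64)

        base = np.floor(y).astype(int)
        frac = y - base
        for k in offsets:
            rows = base + k
            weight = np.exp(-((k - frac) ** 2) / (2 * sigma ** 2))
            valid = (rows >= 0) & (rows < height)
            np.add.at(img, (rows[valid], x[valid]),
                      amps[fi] * mask[valid] * weight[valid])

    pixels = _finalize(img, params, rng)
    return AreaImage(pixels=pixels, area_kind="axon", seed=seed,
                     meta={"params": params, "n_fibers": m})


def generate_study(design: StudyDesign,
                   profiles: Sequence[CompoundProfile],
                   seed: int = 0, *, scale: float = 0.25,
                   n_somata: int | None = None,
                   n_fibers: int | None = None) -> list[AreaImage]:
    """Generate every image of a study design.

    One image per (row, replicate); per-image seeds derive deterministically
    from ``(seed, row index, replicate)``, so regenerating the same study
    with the same seed reproduces every pixel.
    """
    side = int(round(BASE_IMAGE_SIDE * scale))
    if side % 24 != 0:
        raise ConfigurationError(
            f"scale {scale} gives image side {side}, which must be divisible by 24")
    by_name = profiles_by_name(profiles)
    images: list[AreaImage] = []
    for row_i, row in enumerate(design):
        profile = by_name.get(row.compound)
        if profile is None:
            raise ConfigurationError(f"no profile for compound {row.compound!r}")
        params = profile.params_for(row.concentration)
        for rep in range(row.n_images):
            child = int(np.random.SeedSequence([seed, row_i, rep]).generate_state(1)[0])
            if row.area_kind == "soma":
                img = generate_soma_image(params, side, side, child,
                                          n_somata=n_somata, scale=scale)
            else:
                img = generate_axon_image(params, side, side, child,
                                          n_fibers=n_fibers, scale=scale)
            img.compound = row.compound
            img.concentration = row.concentration
            img.split = row.split
            img.replicate = rep
            conc = row.concentration.label.replace(" ", "").replace("%", "pct")
            img.image_id = (f"{row.compound}_{conc}_{row.area_kind}"
                            f"_{row.split}_r{rep:03d}")
            images.append(img)
    return images
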