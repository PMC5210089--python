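"""Synthetic-data generators with recorded ground truth.

Every input the quantification pipeline consumes can be generated here with
known, discretely-computed ground truth: 3D nuclei carrying bright DNA-damage
foci over Gaussian background, two-channel stacks with a controlled overlap
fraction, CD31-like ring vessels with lumens and wall gaps of controlled
width, ABR intensity–amplitude growth series on the 0–100 dB SPL / 5 dB grid,
sigmoidal dose–survival tables, and grouped endpoint measurements.

Ground truth is always *discrete* — voxel/pixel counts of the rendered
objects, not analytic sphere or annulus formulas — so that downstream
measurements can be required to match it exactly on noiseless input.

Determinism: all randomness flows from ``SimulationConfig.seed`` through
per-call ``numpy.random.default_rng`` substreams, so identical (config,
arguments) give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, PlacementError
from .types import ImageStack3D, NucleusMask, VesselField

ABR_GRID_DB = np.arange(0, 105, 5)
ABR_FREQUENCIES_KHZ = (4.0, 6.3, 8.0, 10.0, 12.5, 16.0, 20.0, 25.0, 32.0)

# Study-design constants for the in-vitro hair-cell dose response:
# 5 doses bracketing the half-maximal concentration, 5 replicates each.
DOSE_DESIGN_UM = (0.0, 5.0, 7.5, 10.0, 20.0)
DOSE_DESIGN_N_REP = 5
DOSE_DESIGN_EC50_UM = 9.4


@dataclass
class SimulationConfig:
    """Global knobs shared by all generators.

    Parameters
    ----------
    seed
        Master seed; fixed seed implies byte-identical outputs.
    voxel_size_um
        3D voxel pitch ``(dz, dy, dx)`` in μm.  Default 0.3/0.1/0.1 μm,
        a typical confocal sampling with coarser axial resolution.
    pixel_size_um
        2D pixel pitch in μm (20x objective scale).
    noise_sd
        Additive Gaussian noise scale.  Units are intensity counts for
        images, μV for ABR amplitudes, survival percentage points for
        dose–response tables.
    background_mean
        Mean background intensity for images.
    """

    seed: int = 0
    voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1)
    pixel_size_um: float = 0.32
    noise_sd: float = 0.0
    background_mean: float = 10.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be strictly positive")
        if self.noise_sd < 0 or self.background_mean < 0:
            raise ValueError("noise_sd and background_mean must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Per-stage substream of the master seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Generating values recorded alongside each synthetic dataset."""

    foci_centers: list[tuple[int, int, int]] = field(default_factory=list)
    foci_radii_um: list[float] = field(default_factory=list)
    foci_voxel_counts: list[int] = field(default_factory=list)
    true_count: int = 0
    true_total_volume_um3: float = 0.0
    overlap_pairs: list[tuple[int, int]] = field(default_factory=list)
    true_cd31_area_um2: float = 0.0
    true_lumen_area_um2: float = 0.0
    ring_is_lumen: list[bool] = field(default_factory=list)
    ring_interior_area_um2: list[float] = field(default_factory=list)
    true_threshold_db: float | None = None
    true_ec50_um: float | None = None
    true_hill: float | None = None
    true_survival_pct: dict[float, float] = field(default_factory=dict)
    differing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.true_count != len(self.foci_centers):
            raise ValueError("true_count must equal len(foci_centers)")
        if self.true_total_volume_um3 < 0:
            raise ValueError("volumes must be non-negative")

    def to_json(self, path: str | Path) -> None:
        """Write the ground truth as a JSON sidecar."""
        d = asdict(self)
        d["true_survival_pct"] = {str(k): v for k, v in d["true_survival_pct"].items()}
        Path(path).write_text(json.dumps(d, indent=1, default=float))


# ---------------------------------------------------------------------------
# 3D foci stacks


def _sphere_voxels(
    center: tuple[int, int, int],
    radius_um: float,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of voxels whose centers lie within ``radius_um`` of ``center``."""
    dz, dy, dx = voxel_size_um
    cz, cy, cx = center
    rz = int(np.ceil(radius_um / dz)) + 1
    ry = int(np.ceil(radius_um / dy)) + 1
    rx = int(np.ceil(radius_um / dx)) + 1
    zz, yy, xx = np.meshgrid(
        np.arange(max(0, cz - rz), min(shape[0], cz + rz + 1)),
        np.arange(max(0, cy - ry), min(shape[1], cy + ry + 1)),
        np.arange(max(0, cx - rx), min(shape[2], cx + rx + 1)),
        indexing="ij",
    )
    d2 = ((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
    inside = d2 <= radius_um**2
    return zz[inside], yy[inside], xx[inside]


def _ellipsoid_mask(
    shape: tuple[int, int, int], semiaxes_frac: tuple[float, float, float] = (0.4, 0.4, 0.4)
) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    az, ay, ax = semiaxes_frac[0] * nz, semiaxes_frac[1] * ny, semiaxes_frac[2] * nx
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _place_centers(
    rng: np.random.Generator,
    n: int,
    mask: np.ndarray,
    radius_um: float,
    voxel_size_um: tuple[float, float, float],
    min_sep_um: float,
    existing: list[tuple[int, int, int]] | None = None,
    max_tries: int = 10_000,
) -> list[tuple[int, int, int]]:
    """Rejection-sample focus centers inside the mask, pairwise separated."""
    dz, dy, dx = voxel_size_um
    candidates = np.argwhere(mask)
    if candidates.size == 0 and n > 0:
        raise PlacementError("mask is empty")
    centers: list[tuple[int, int, int]] = list(existing or [])
    n_pre = len(centers)
    scale = np.array([dz, dy, dx])
    tries = 0
    while len(centers) - n_pre < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} foci of radius {radius_um} μm without overlap"
            )
        tries += 1
        c = tuple(int(v) for v in candidates[rng.integers(len(candidates))])
        # all sphere voxels must stay inside the mask
        zz, yy, xx = _sphere_voxels(c, radius_um, mask.shape, voxel_size_um)
        if not mask[zz, yy, xx].all():
            continue
        ok = True
        for o in centers:
            d = np.linalg.norm((np.array(c) - np.array(o)) * scale)
            if d < min_sep_um:
                ok = False
                break
        if ok:
            centers.append(c)
    return centers[n_pre:]


def make_nucleus_stack(
    n_foci: int,
    radius_um: float = 0.3,
    focus_intensity: float = 120.0,
    config: SimulationConfig = SimulationConfig(),
    shape: tuple[int, int, int] = (24, 48, 48),
) -> tuple[ImageStack3D, NucleusMask, GroundTruth]:
    """Render one nucleus containing ``n_foci`` spherical bright foci.

    Foci are hard spheres of uniform intensity ``focus_intensity`` over a
    Gaussian background (mean ``config.background_mean``, sd
    ``config.noise_sd``), placed non-overlapping inside an ellipsoidal
    nucleus mask.  Ground truth records the *voxelized* focus volumes.

    Raises
    ------
    PlacementError
        If the requested foci cannot be placed without overlap.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    if n_foci > 0 and focus_intensity <= config.background_mean:
        raise ValueError("focus_intensity must exceed background_mean")
    rng = config.rng(stream=1)
    mask = _ellipsoid_mask(shape)
    img = np.full(shape, config.background_mean, dtype=np.float64)

    centers = _place_centers(
        rng, n_foci, mask, radius_um, config.voxel_size_um,
        min_sep_um=2 * radius_um + 2 * max(config.voxel_size_um),
    )
    voxel_counts = []
    total_voxels = 0
    for c in centers:
        zz, yy, xx = _sphere_voxels(c, radius_um, shape, config.voxel_size_um)
        img[zz, yy, xx] = focus_intensity
        voxel_counts.append(len(zz))
        total_voxels += len(zz)
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)

    vvol = float(np.prod(config.voxel_size_um))
    stack = ImageStack3D(img[np.newaxis], config.voxel_size_um, ["foci"])
    truth = GroundTruth(
        foci_centers=centers,
        foci_radii_um=[radius_um] * n_foci,
        foci_voxel_counts=voxel_counts,
        true_count=n_foci,
        true_total_volume_um3=total_voxels * vvol,
    )
    return stack, NucleusMask(mask), truth


def make_coloc_stack(
    n_a: int,
    n_b: int,
    n_overlapping: int,
    config: SimulationConfig = SimulationConfig(),
    radius_um: float = 0.3,
    focus_intensity: float = 120.0,
    shape: tuple[int, int, int] = (32, 64, 64),
) -> tuple[ImageStack3D, NucleusMask, GroundTruth]:
    """Two-channel stack where exactly ``n_overlapping`` A-foci touch a B-focus.

    The default volume is larger than the single-channel default so that
    up to ~2×10 mutually separated foci fit inside the nuclear mask.

    Overlapping pairs are rendered at identical centers (guaranteeing voxel
    intersection); all other foci are kept physically separated so no
    accidental overlap occurs.
    """
    if not (0 <= n_overlapping <= min(n_a, n_b)):
        raise ValueError("need 0 <= n_overlapping <= min(n_a, n_b)")
    rng = config.rng(stream=2)
    mask = _ellipsoid_mask(shape)
    sep = 2 * radius_um + 2 * max(config.voxel_size_um)

    # one pool of mutually separated sites: overlapping pairs share a site
    n_sites = n_a + n_b - n_overlapping
    sites = _place_centers(rng, n_sites, mask, radius_um, config.voxel_size_um, sep)
    centers_a = sites[:n_a]
    centers_b = sites[:n_overlapping] + sites[n_a:]

    imgs = []
    for centers in (centers_a, centers_b):
        img = np.full(shape, config.background_mean, dtype=np.float64)
        for c in centers:
            zz, yy, xx = _sphere_voxels(c, radius_um, shape, config.voxel_size_um)
            img[zz, yy, xx] = focus_intensity
        imgs.append(img)
    if config.noise_sd > 0:
        for img in imgs:
            img += rng.normal(0.0, config.noise_sd, size=shape)
            np.clip(img, 0.0, None, out=img)

    stack = ImageStack3D(np.stack(imgs), config.voxel_size_um, ["A", "B"])
    truth = GroundTruth(
        foci_centers=centers_a,
        foci_radii_um=[radius_um] * n_a,
        true_count=n_a,
        overlap_pairs=[(i, i) for i in range(n_overlapping)],
    )
    return stack, NucleusMask(mask), truth


# ---------------------------------------------------------------------------
# 2D vessel fields


def make_vessel_field(
    rings: list[tuple[tuple[float, float], float, float, float]],
    config: SimulationConfig = SimulationConfig(),
    shape: tuple[int, int] = (256, 256),
    wall_intensity: float = 200.0,
) -> tuple[VesselField, GroundTruth]:
    """Render annular CD31-like vessel walls with optional radial gaps.

    Parameters
    ----------
    rings
        Each ring is ``((cy_um, cx_um), outer_radius_um, wall_um,
        gap_width_um)``.  ``gap_width_um = 0`` renders a closed ring; a
        positive value cuts one slot of that physical width through the
        wall (toward +x).
    config
        Supplies pixel size, background and noise.

    Ground truth stores discrete wall-pixel areas and, per ring, the
    interior (candidate-lumen) pixel area plus whether the gap rule
    (gap ≤ 1 μm) leaves the interior countable as a lumen.

    Raises
    ------
    GeometryError
        If a ring extends beyond the field.
    """
    px = config.pixel_size_um
    ny, nx = shape
    img = np.full(shape, config.background_mean, dtype=np.float64)
    yy, xx = np.meshgrid(np.arange(ny) * px, np.arange(nx) * px, indexing="ij")

    wall_total = np.zeros(shape, dtype=bool)
    ring_is_lumen: list[bool] = []
    ring_interior: list[float] = []
    lumen_area = 0.0
    for (cy, cx), outer_r, wall, gap in rings:
        if not (outer_r > wall > 0):
            raise GeometryError("need outer_radius > wall > 0")
        if gap < 0:
            raise GeometryError("gap_width must be >= 0")
        if (cy - outer_r < 0 or cx - outer_r < 0
                or cy + outer_r > (ny - 1) * px or cx + outer_r > (nx - 1) * px):
            raise GeometryError("ring extends beyond field")
        d = np.hypot(yy - cy, xx - cx)
        inner_r = outer_r - wall
        wall_px = (d >= inner_r) & (d <= outer_r)
        if gap > 0:
            slot = (np.abs(yy - cy) < gap / 2) & (xx > cx)
            wall_px &= ~slot
        wall_total |= wall_px
        interior = (d < inner_r)
        interior_area = float(interior.sum()) * px**2
        is_lumen = gap <= 1.0  # gaps wider than 1 μm break lumen enclosure
        ring_is_lumen.append(is_lumen)
        ring_interior.append(interior_area)
        if is_lumen:
            lumen_area += interior_area

    img[wall_total] = wall_intensity
    if config.noise_sd > 0:
        rng = config.rng(stream=3)
        img += rng.normal(0.0, config.noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)

    fld = VesselField(img[np.newaxis], px, ["CD31"])
    truth = GroundTruth(
        true_cd31_area_um2=float(wall_total.sum()) * px**2,
        true_lumen_area_um2=lumen_area,
        ring_is_lumen=ring_is_lumen,
        ring_interior_area_um2=ring_interior,
    )
    return fld, truth


# ---------------------------------------------------------------------------
# ABR series


def make_abr_series(
    true_threshold_db: float,
    frequencies_khz: list[float] | tuple[float, ...] = ABR_FREQUENCIES_KHZ,
    config: SimulationConfig = SimulationConfig(),
    noise_floor_uv: float = 1.0,
    snr: float = 8.0,
    n_replicates: int = 2,
    growth_per_step: float = 0.5,
) -> pd.DataFrame:
    """Simulate intensity–amplitude growth functions on the 5 dB grid.

    Below the programmed threshold, wave amplitudes are folded-Gaussian
    noise; from the threshold up, the mean amplitude is
    ``snr * noise_floor_uv`` growing by ``growth_per_step`` of itself per
    5 dB step, with additive Gaussian measurement noise of sd
    ``config.noise_sd`` (μV).  ``true_threshold_db = inf`` simulates a
    non-responsive ear (ceiling case).

    Returns a tidy table ``frequency_khz, intensity_db, replicate,
    amplitude_uv`` with ``n_replicates`` replicate series per frequency.
    """
    ceiling = np.isinf(true_threshold_db)
    if not ceiling:
        if not (0 <= true_threshold_db <= 100) or true_threshold_db % 5 != 0:
            raise ValueError("true_threshold_db must lie on the 5 dB grid in [0, 100]")
    rng = config.rng(stream=4)
    rows = []
    for f in frequencies_khz:
        for rep in range(n_replicates):
            for inten in ABR_GRID_DB:
                if ceiling or inten < true_threshold_db:
                    amp = abs(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
                else:
                    steps = (inten - true_threshold_db) / 5.0
                    amp = snr * noise_floor_uv * (1.0 + growth_per_step * steps)
                    if config.noise_sd > 0:
                        amp = max(0.0, amp + rng.normal(0.0, config.noise_sd))
                rows.append((f, int(inten), rep, amp))
    return pd.DataFrame(rows, columns=["frequency_khz", "intensity_db", "replicate", "amplitude_uv"])


# ---------------------------------------------------------------------------
# Dose–response tables


def four_pl(dose: np.ndarray, top: float, bottom: float, ec50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic, with dose 0 handled as the hill-sign limit."""
    dose = np.asarray(dose, dtype=np.float64)
    out = np.empty_like(dose)
    zero = dose == 0
    out[zero] = top if hill > 0 else bottom
    nz = ~zero
    out[nz] = bottom + (top - bottom) / (1.0 + (dose[nz] / ec50) ** hill)
    return out


def make_dose_response(
    ec50_um: float = DOSE_DESIGN_EC50_UM,
    hill: float = 2.0,
    doses_um: list[float] | tuple[float, ...] = DOSE_DESIGN_UM,
    n_rep: int = DOSE_DESIGN_N_REP,
    config: SimulationConfig = SimulationConfig(),
    top: float = 100.0,
    bottom: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate percent hair-cell survival per dose and replicate.

    ``survival = 4PL(dose) + N(0, noise_sd)`` clipped to [0, 100], with
    ``hill > 0`` meaning loss at high dose (survival falls from ``top``
    toward ``bottom``).  Defaults reproduce the study design: doses
    0/5/7.5/10/20 μM, 5 replicates, generating EC50 9.4 μM.
    """
    if ec50_um <= 0:
        raise ValueError("ec50 must be positive")
    doses = np.asarray(doses_um, dtype=np.float64)
    if (doses < 0).any():
        raise ValueError("doses must be non-negative")
    rng = config.rng(stream=5)
    rows = []
    for d in doses:
        mu = float(four_pl(np.array([d]), top, bottom, ec50_um, hill)[0])
        for rep in range(n_rep):
            y = mu + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            rows.append((d, rep, float(np.clip(y, 0.0, 100.0))))
    table = pd.DataFrame(rows, columns=["dose_um", "replicate", "survival_pct"])
    truth = GroundTruth(true_ec50_um=ec50_um, true_hill=hill)
    return table, truth


# ---------------------------------------------------------------------------
# Grouped endpoints


def make_grouped_endpoint(
    group_means: list[float],
    sd: float,
    n_per_group: int,
    config: SimulationConfig = SimulationConfig(),
    group_names: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gaussian endpoint samples per group, with truly-differing pairs recorded."""
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if group_names is None:
        group_names = [f"g{i + 1}" for i in range(len(group_means))]
    rng = config.rng(stream=6)
    rows = []
    for name, mu in zip(group_names, group_means):
        vals = rng.normal(mu, sd, size=n_per_group)
        for j, v in enumerate(vals):
            rows.append((f"{name}_s{j}", name, float(v)))
    table = pd.DataFrame(rows, columns=["subject", "group", "value"])
    differing = [
        (group_names[i], group_names[j])
        for i in range(len(group_means))
        for j in range(i + 1, len(group_means))
        if group_means[i] != group_means[j]
    ]
    truth = GroundTruth(differing_pairs=differing)
    return table, truth


# ---------------------------------------------------------------------------
# File output


def write_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Write a channel-major multi-page TIFF plus a JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    sidecar = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channel_names": stack.channel_names,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def write_field(fld: VesselField, path: str | Path) -> None:
    """Write a 2D field TIFF plus a JSON pixel-size sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, fld.intensities.astype(np.float32))
    sidecar = {"pixel_size_um": fld.pixel_size_um, "channel_names": fld.channel_names}
    path.with_suffix(".json").write_text(json.dumps(sidecar))
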