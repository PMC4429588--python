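"""Synthetic fixtures for every pipeline stage.

Every generator is a pure function of its spec (seed included) and returns
the ground truth alongside the data — the planted cell mask and realised
area fraction, the template shapes and their volumes, the planted
co-activation link table — so downstream recovery tests never re-derive it.

Default parameters emulate the magnitudes of the real material: cell-area
fractions of a few percent, nucleus volumes of order 10–800 mm^3 on a 1-mm
reference grid with ten moderately jittered subjects, and a coordinate
database on the scale of one-to-several-thousand experiments with planted
co-activation targets and domain enrichments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .atlas import SubjectLabelVolume
from .grids import Grid
from .histomorph import Micrograph
from .macm import Experiment

__all__ = [
    "SyntheticMicrographSpec",
    "SyntheticMicrograph",
    "gen_micrograph",
    "gen_denticulated_contour",
    "NucleusTemplate",
    "SyntheticAtlasSpec",
    "SyntheticAtlasResult",
    "gen_subject_labels",
    "PlantedLink",
    "SyntheticDatabaseSpec",
    "SyntheticDatabase",
    "gen_experiment_db",
    "gen_paired_density_samples",
    "sphere_mask",
    "ellipsoid_mask",
    "default_atlas_spec",
    "default_database_spec",
]


# ---------------------------------------------------------------------------
# micrographs


@dataclass(frozen=True)
class SyntheticMicrographSpec:
    """Recipe for a micrograph with a planted cell-area fraction.

    Cells are non-overlapping disks: the area fraction — the only quantity
    the density estimator measures — is shape-agnostic, so disk geometry is
    sufficient.  Intensities mimic silver-stained material (dark cells on a
    light background).
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 1.0
    target_fraction: float = 0.041
    cell_radius_um: tuple[float, float] = (3.0, 8.0)
    foreground_mean: float = 80.0
    background_mean: float = 200.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.cell_radius_um[0] <= 0 or self.cell_radius_um[1] < self.cell_radius_um[0]:
            raise ValueError("cell radii must be positive and ordered")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class SyntheticMicrograph:
    """Generated micrograph plus ground truth."""

    micrograph: Micrograph
    cell_mask: np.ndarray
    realized_fraction: float
    spec: SyntheticMicrographSpec


def gen_micrograph(spec: SyntheticMicrographSpec) -> SyntheticMicrograph:
    """Plant non-overlapping disk 'cells' until the target area fraction is
    met, then add Gaussian intensity noise.

    The last disk's radius is trimmed toward the remaining deficit so the
    realised fraction lands within a small fraction of one minimal disk of
    the target (far inside the 0.005 contract).  Unreachable targets (radii
    too large for the frame, or no room left) fail loudly.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    total = h * w
    mask = np.zeros((h, w), dtype=bool)
    r_lo, r_hi = (r / spec.pixel_size_um for r in spec.cell_radius_um)
    if 2 * r_hi >= min(h, w):
        raise ValueError("cell radius too large for the image")
    target_px = spec.target_fraction * total
    placed_px = 0
    max_consecutive_failures = 5000
    failures = 0
    min_disk_px = np.pi * r_lo**2
    while True:
        deficit = target_px - placed_px
        if deficit < min_disk_px / 2:
            break  # within half of one minimal disk of the target
        r = rng.uniform(r_lo, r_hi)
        # trim the final disk toward the remaining deficit
        r = min(r, max(r_lo, float(np.sqrt(deficit / np.pi))))
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        y0, y1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)) + 1)
        x0, x1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)) + 1)
        yy = np.arange(y0, y1)[:, None]
        xx = np.arange(x0, x1)[None, :]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        sl = (slice(y0, y1), slice(x0, x1))
        if (mask[sl] & disk).any():
            failures += 1
            if failures > max_consecutive_failures:
                raise ValueError(
                    "cannot reach the target fraction with the given radii/size"
                )
            continue
        failures = 0
        mask[sl] |= disk
        placed_px = int(mask.sum())
    realized = mask.sum() / total
    if abs(realized - spec.target_fraction) > 0.005:
        raise ValueError(
            f"realised fraction {realized:.4f} misses target "
            f"{spec.target_fraction:.4f} by more than 0.005"
        )
    img = np.full((h, w), spec.background_mean, dtype=float)
    img[mask] = spec.foreground_mean
    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    return SyntheticMicrograph(
        micrograph=Micrograph(pixels=img, pixel_size_um=spec.pixel_size_um),
        cell_mask=mask,
        realized_fraction=float(realized),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# denticulated contours


def gen_denticulated_contour(
    n_teeth: int,
    base_radius: float = 10.0,
    tooth_amplitude: float = 3.0,
    seed: int = 0,
    vertices_per_tooth: int = 24,
) -> np.ndarray:
    """Closed star-shaped polygon with ``n_teeth`` outward lobes.

    ``n_teeth=0`` (or zero amplitude) yields a regular polygon approximating
    a circle — convex, so its folding index is exactly 1.  Star-shapedness
    about the origin guarantees simplicity; it is verified anyway.

    Returns an ``(n, 2)`` vertex array in mm (not closed; the first vertex is
    implied to follow the last).
    """
    if n_teeth < 0:
        raise ValueError("n_teeth must be >= 0")
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    if n_teeth == 0 or tooth_amplitude == 0:
        n_teeth = 0  # zero amplitude degenerates to the toothless case
    n_vert = max(96, vertices_per_tooth * max(n_teeth, 1))
    theta = np.linspace(0.0, 2.0 * np.pi, n_vert, endpoint=False)
    if n_teeth == 0:
        r = np.full(n_vert, base_radius)
    else:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.normal(0.0, 0.03 * tooth_amplitude, n_vert)
        r = (
            base_radius
            + tooth_amplitude * 0.5 * (1.0 + np.cos(n_teeth * theta + phase))
            + jitter
        )
        if np.any(r <= 0):
            raise ValueError("tooth amplitude too large; radius went non-positive")
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    poly = Polygon(verts)
    if not (poly.is_valid and poly.is_simple):
        raise ValueError("generated contour self-intersects")
    return verts


# ---------------------------------------------------------------------------
# multi-subject label volumes


@dataclass(frozen=True)
class NucleusTemplate:
    """A named ellipsoidal template shape on the reference grid.

    ``denticulation_amplitude`` is a dimensionless in-plane radial modulation
    (``r -> r * (1 + a cos(k phi))`` in the template's x-y plane) giving the
    dentate-like shell its folded outline; 0 keeps a plain ellipsoid.
    """

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    denticulation_amplitude: float = 0.0
    denticulation_folds: int = 8

    def analytic_volume_mm3(self) -> float:
        """Exact ellipsoid volume; for denticulated shells this is the volume
        of the unmodulated ellipsoid (the modulation is volume-preserving only
        to first order)."""
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Recipe for a jittered multi-subject label set.

    One rigid-ish perturbation per subject (translation plus a global scale)
    models residual misregistration after spatial normalisation; applying the
    same perturbation to all of a subject's nuclei preserves within-subject
    disjointness, as in real delineations.
    """

    n_subjects: int = 10
    nucleus_templates: tuple[NucleusTemplate, ...] = ()
    jitter_translation_sd_mm: float = 1.0
    jitter_scale_sd: float = 0.03
    grid: Grid = field(default_factory=lambda: Grid.isotropic((44, 40, 32), (-30.0, -20.0, -16.0)))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.jitter_translation_sd_mm < 0 or self.jitter_scale_sd < 0:
            raise ValueError("jitter magnitudes must be non-negative")
        if not self.nucleus_templates:
            raise ValueError("at least one nucleus template is required")


@dataclass
class SyntheticAtlasResult:
    """Jittered label volumes plus template ground truth."""

    label_volumes: list[SubjectLabelVolume]
    template_masks: dict[str, np.ndarray]
    template_volumes_mm3: dict[str, float]
    template_voxel_volumes_mm3: dict[str, float]
    grid: Grid

    def by_nucleus(self, nucleus: str) -> list[SubjectLabelVolume]:
        return [v for v in self.label_volumes if v.nucleus == nucleus]

    def nuclei(self) -> list[str]:
        seen = []
        for v in self.label_volumes:
            if v.nucleus not in seen:
                seen.append(v.nucleus)
        return seen


def _voxelize_template(
    t: NucleusTemplate, grid: Grid, translation=(0.0, 0.0, 0.0), scale: float = 1.0
) -> np.ndarray:
    x, y, z = grid.coordinate_arrays()
    cx, cy, cz = t.center_mm
    rx, ry, rz = (r * scale for r in t.radii_mm)
    dx = (x - cx - translation[0]) / rx
    dy = (y - cy - translation[1]) / ry
    dz = (z - cz - translation[2]) / rz
    rho = np.sqrt(dx**2 + dy**2 + dz**2)
    if t.denticulation_amplitude > 0:
        phi = np.arctan2(dy, dx)
        limit = 1.0 + t.denticulation_amplitude * np.cos(t.denticulation_folds * phi)
        return rho <= limit
    return rho <= 1.0


def _template_bounds_ok(
    t: NucleusTemplate, grid: Grid, translation, scale
) -> bool:
    x, y, z = grid.coordinate_arrays()
    mins = np.array([x.min(), y.min(), z.min()])
    maxs = np.array([x.max(), y.max(), z.max()])
    reach = np.array(t.radii_mm) * scale * (1.0 + t.denticulation_amplitude)
    c = np.array(t.center_mm) + np.asarray(translation)
    return bool(np.all(c - reach > mins) and np.all(c + reach < maxs))


def gen_subject_labels(spec: SyntheticAtlasSpec) -> SyntheticAtlasResult:
    """Voxelise each template per subject under a per-subject jitter.

    Raises if the unjittered templates overlap, or if any jitter pushes a
    label outside the grid.
    """
    grid = spec.grid
    template_masks = {}
    occupancy = np.zeros(grid.shape, dtype=bool)
    for t in spec.nucleus_templates:
        if not _template_bounds_ok(t, grid, (0, 0, 0), 1.0):
            raise ValueError(f"template {t.name!r} does not fit inside the grid")
        m = _voxelize_template(t, grid)
        if (occupancy & m).any():
            raise ValueError(f"template {t.name!r} overlaps another template")
        occupancy |= m
        template_masks[t.name] = m
    vv = grid.voxel_volume_mm3
    rng = np.random.default_rng(spec.seed)
    volumes: list[SubjectLabelVolume] = []
    for s in range(spec.n_subjects):
        translation = rng.normal(0.0, spec.jitter_translation_sd_mm, size=3)
        scale = float(rng.normal(1.0, spec.jitter_scale_sd))
        if scale <= 0:
            raise ValueError("jitter produced a non-positive scale")
        for t in spec.nucleus_templates:
            if not _template_bounds_ok(t, grid, translation, scale):
                raise ValueError(
                    f"jitter pushed template {t.name!r} off the grid for subject {s}"
                )
            mask = _voxelize_template(t, grid, translation, scale)
            volumes.append(
                SubjectLabelVolume(
                    subject_id=f"S{s:02d}", nucleus=t.name, mask=mask, grid=grid
                )
            )
    return SyntheticAtlasResult(
        label_volumes=volumes,
        template_masks=template_masks,
        template_volumes_mm3={
            t.name: t.analytic_volume_mm3() for t in spec.nucleus_templates
        },
        template_voxel_volumes_mm3={
            name: float(m.sum()) * vv for name, m in template_masks.items()
        },
        grid=grid,
    )


def default_atlas_spec(seed: int = 0, **overrides) -> SyntheticAtlasSpec:
    """Ten-subject fixture with four nucleus templates at realistic volumes
    (dentate ≈ 400 mm^3 per hemisphere down to globose ≈ 10 mm^3)."""
    templates = (
        NucleusTemplate("dentate", (-16.0, 0.0, 0.0), (6.2, 5.0, 3.1), 0.12, 8),
        NucleusTemplate("emboliform", (-7.0, 3.0, 0.0), (2.9, 2.3, 1.8)),
        NucleusTemplate("globose", (-2.5, 5.0, 1.0), (1.4, 1.35, 1.2)),
        NucleusTemplate("fastigial", (-2.0, -4.0, 2.0), (2.75, 2.2, 1.7)),
    )
    kw = dict(n_subjects=10, nucleus_templates=templates, seed=seed)
    kw.update(overrides)
    return SyntheticAtlasSpec(**kw)


# ---------------------------------------------------------------------------
# coordinate database


def ellipsoid_mask(grid: Grid, center_mm, radii_mm) -> np.ndarray:
    x, y, z = grid.coordinate_arrays()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def sphere_mask(grid: Grid, center_mm, radius_mm: float) -> np.ndarray:
    return ellipsoid_mask(grid, center_mm, (radius_mm,) * 3)


@dataclass(frozen=True)
class PlantedLink:
    """A planted seed-to-target co-activation.

    A fraction ``seed_hit_rate`` of experiments receives one focus uniformly
    inside the seed sphere; each such experiment additionally receives, with
    probability ``coactivation_probability``, a focus at the target centre
    (jittered uniformly within one voxel).
    """

    seed_name: str
    seed_center_mm: tuple[float, float, float]
    seed_radius_mm: float
    target_center_mm: tuple[float, float, float]
    coactivation_probability: float
    seed_hit_rate: float

    def __post_init__(self):
        for p in (self.coactivation_probability, self.seed_hit_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticDatabaseSpec:
    """Recipe for a coordinate database with planted structure.

    Background foci fall uniformly over the volume of a brain-shaped
    ellipsoid mask; focus counts are 1 + Poisson, sample sizes uniform over
    ``sample_size_range``.  ``domain_base_rates`` / ``paradigm_base_rates``
    assign labels independently per experiment; per-link enrichments replace
    the base rate for seed-hitting experiments.
    """

    n_experiments: int = 1000
    foci_per_experiment_mean: float = 4.0
    sample_size_range: tuple[int, int] = (8, 30)
    grid: Grid = field(default_factory=lambda: Grid.isotropic((41, 49, 37), (-40.0, -48.0, -36.0), 2.0))
    background_radii_mm: tuple[float, float, float] = (40.0, 48.0, 36.0)
    planted_links: tuple[PlantedLink, ...] = ()
    domain_base_rates: dict = field(default_factory=dict)
    domain_enrichment: dict = field(default_factory=dict)  # seed_name -> {label: rate}
    paradigm_base_rates: dict = field(default_factory=dict)
    paradigm_enrichment: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_experiments < 0:
            raise ValueError("n_experiments must be >= 0")
        if self.foci_per_experiment_mean < 1:
            raise ValueError("mean foci per experiment must be >= 1")
        for rates in (self.domain_base_rates, self.paradigm_base_rates):
            for v in rates.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("label probabilities must lie in [0, 1]")
        for enr, base in (
            (self.domain_enrichment, self.domain_base_rates),
            (self.paradigm_enrichment, self.paradigm_base_rates),
        ):
            for seed_name, rates in enr.items():
                if not base:
                    raise ValueError(
                        f"enrichment for {seed_name!r} requested with an empty label set"
                    )
                for lab, v in rates.items():
                    if lab not in base:
                        raise ValueError(f"enriched label {lab!r} has no base rate")
                    if not 0.0 <= v <= 1.0:
                        raise ValueError("label probabilities must lie in [0, 1]")

    def background_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid, (0.0, 0.0, 0.0), self.background_radii_mm)

    def seed_mask(self, seed_name: str) -> np.ndarray:
        for link in self.planted_links:
            if link.seed_name == seed_name:
                return sphere_mask(self.grid, link.seed_center_mm, link.seed_radius_mm)
        raise KeyError(seed_name)


@dataclass
class SyntheticDatabase:
    """Generated experiments plus the planted-structure ground truth."""

    experiments: list[Experiment]
    ground_truth: dict  # experiment_id -> {seed_name: {"seed_hit", "target_focus"}}
    spec: SyntheticDatabaseSpec

    def seed_hitters(self, seed_name: str) -> list[str]:
        return [
            eid
            for eid, links in self.ground_truth.items()
            if links.get(seed_name, {}).get("seed_hit", False)
        ]


def gen_experiment_db(spec: SyntheticDatabaseSpec) -> SyntheticDatabase:
    """Generate a coordinate database with planted links and enrichments."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    mask = spec.background_mask()
    mask_idx = np.argwhere(mask)
    if mask_idx.shape[0] == 0:
        raise ValueError("background mask is empty")
    for link in spec.planted_links:
        tgt_idx, inside = grid.mm_to_nearest_voxel(link.target_center_mm)
        if not inside[0] or not mask[tuple(tgt_idx[0])]:
            raise ValueError(
                f"planted target for {link.seed_name!r} lies outside the background mask"
            )
    seed_vox = {
        link.seed_name: np.argwhere(
            sphere_mask(grid, link.seed_center_mm, link.seed_radius_mm) & mask
        )
        for link in spec.planted_links
    }
    voxsize = grid.voxel_sizes_mm
    experiments: list[Experiment] = []
    truth: dict[str, dict] = {}
    for i in range(spec.n_experiments):
        eid = f"E{i:05d}"
        n_subj = int(rng.integers(spec.sample_size_range[0], spec.sample_size_range[1] + 1))
        n_foci = 1 + int(rng.poisson(max(0.0, spec.foci_per_experiment_mean - 1.0)))
        foci: list[np.ndarray] = []
        links_truth: dict[str, dict] = {}
        enriched_domains: dict[str, float] = {}
        enriched_paradigms: dict[str, float] = {}
        for link in spec.planted_links:
            hit = bool(rng.random() < link.seed_hit_rate)
            got_target = False
            if hit:
                vox = seed_vox[link.seed_name]
                pick = vox[rng.integers(0, vox.shape[0])]
                jit = rng.uniform(-0.5, 0.5, 3) * voxsize
                foci.append(grid.voxel_to_mm(pick)[0] + jit)
                if rng.random() < link.coactivation_probability:
                    jit = rng.uniform(-0.5, 0.5, 3) * voxsize
                    foci.append(np.asarray(link.target_center_mm) + jit)
                    got_target = True
                enriched_domains.update(spec.domain_enrichment.get(link.seed_name, {}))
                enriched_paradigms.update(
                    spec.paradigm_enrichment.get(link.seed_name, {})
                )
            links_truth[link.seed_name] = {"seed_hit": hit, "target_focus": got_target}
        n_background = max(n_foci - len(foci), 0)
        if n_background:
            draws = mask_idx[rng.integers(0, mask_idx.shape[0], size=n_background)]
            jit = rng.uniform(-0.5, 0.5, (n_background, 3)) * voxsize
            foci.extend(grid.voxel_to_mm(draws) + jit)
        domains = [
            lab
            for lab, p in spec.domain_base_rates.items()
            if rng.random() < enriched_domains.get(lab, p)
        ]
        paradigms = [
            lab
            for lab, p in spec.paradigm_base_rates.items()
            if rng.random() < enriched_paradigms.get(lab, p)
        ]
        experiments.append(
            Experiment(
                experiment_id=eid,
                foci=np.vstack(foci),
                n_subjects=n_subj,
                domains=domains,
                paradigms=paradigms,
            )
        )
        truth[eid] = links_truth
    return SyntheticDatabase(experiments=experiments, ground_truth=truth, spec=spec)


def default_database_spec(seed: int = 0, **overrides) -> SyntheticDatabaseSpec:
    """Database fixture with one dentate-seed link (150/1000 expected seed
    experiments, co-activation probability 0.8) and a smaller interposed-seed
    link, plus domain/paradigm enrichments for the dentate seed."""
    links = (
        PlantedLink(
            seed_name="dentate",
            seed_center_mm=(-16.0, 0.0, 0.0),
            seed_radius_mm=7.0,
            target_center_mm=(20.0, 26.0, 16.0),
            coactivation_probability=0.8,
            seed_hit_rate=0.15,
        ),
        PlantedLink(
            seed_name="interposed",
            seed_center_mm=(-5.0, 4.0, 0.5),
            seed_radius_mm=5.0,
            target_center_mm=(-30.0, 0.0, 2.0),
            coactivation_probability=0.5,
            seed_hit_rate=0.08,
        ),
    )
    kw = dict(
        n_experiments=1000,
        planted_links=links,
        domain_base_rates={
            "action": 0.10,
            "cognition": 0.25,
            "pain": 0.08,
            "speech": 0.12,
            "music": 0.05,
            "vision": 0.15,
        },
        domain_enrichment={"dentate": {"action": 0.30, "speech": 0.24}},
        paradigm_base_rates={
            "motor_task": 0.12,
            "nback": 0.10,
            "passive_listening": 0.08,
            "visual_search": 0.12,
        },
        paradigm_enrichment={"dentate": {"motor_task": 0.30}},
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticDatabaseSpec(**kw)


# ---------------------------------------------------------------------------
# paired density samples


def gen_paired_density_samples(
    n_brains: int = 10,
    mean_a: float = 4.09,
    mean_b: float = 3.39,
    between_brain_sd: float = 0.55,
    within_part_sd: float = 0.35,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-brain mean densities for two parts of one structure.

    A shared per-brain baseline (staining intensity, overall packing) plus
    part-specific noise: marginal SDs are ``sqrt(between^2 + within^2)``
    (≈ 0.65 at the defaults, matching the observed spread on the percent
    display scale) while the paired differences only carry the within-part
    noise — the design that gives a small cohort its power.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, between_brain_sd, n_brains)
    a = mean_a + base + rng.normal(0.0, within_part_sd, n_brains)
    b = mean_b + base + rng.normal(0.0, within_part_sd, n_brains)
    return a, b


def write_ground_truth_json(path, payload: dict) -> None:
    """JSON sidecar writer for generator ground truth."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
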