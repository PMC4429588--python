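"""Meta-analytic connectivity modeling (MACM) via Activation Likelihood
Estimation.

Given a coordinate database of neuroimaging experiments, MACM selects the
experiments reporting at least one activation focus inside a seed region and
asks where else those experiments consistently activate.  Each experiment's
foci are modelled as 3-D Gaussians whose width reflects the spatial
uncertainty of reported coordinates (a fixed between-template term plus a
between-subject term shrinking with the square root of the sample size);
per experiment the modelled activation (MA) at a voxel is the maximum over
its focus kernels, and the ALE score combines experiments by a probabilistic
union, ``ALE(v) = 1 - prod_e(1 - MA_e(v))``.

Significance is assessed against a Monte-Carlo null that redistributes each
experiment's foci uniformly within a background mask (preserving focus
counts and sample sizes), with cluster-level family-wise-error correction on
cluster extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid

__all__ = [
    "Experiment",
    "MaMap",
    "AleResult",
    "ContrastResult",
    "default_fwhm",
    "filter_by_seed",
    "ma_map",
    "ale_map",
    "compute_ale",
    "significance",
    "contrast",
    "write_experiments",
    "read_experiments",
]

#: 26-connected structuring element used for cluster formation.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# Euclidean coordinate uncertainties (mm) of the standard two-component ALE
# kernel model (per the Eickhoff et al. 2009 convention): between-subject
# variability, shrinking as 1/sqrt(n), and residual between-template spread.
EUCLIDEAN_SUBJECT_MM = 11.6
EUCLIDEAN_TEMPLATE_MM = 5.7
# Euclidean distance -> per-axis standard deviation for an isotropic 3-D
# Gaussian: E|d| = 2*sqrt(2/pi) * sigma_axis.
_EUCLID_TO_AXIS = 2.0 * math.sqrt(2.0 / math.pi)
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class NoExperimentsError(ValueError):
    """A stage received an empty experiment set and refuses to proceed."""


@dataclass
class Experiment:
    """One archived neuroimaging experiment: foci, sample size, taxonomy."""

    experiment_id: str
    foci: np.ndarray  # (n_foci, 3) mm
    n_subjects: int
    domains: list[str] = field(default_factory=list)
    paradigms: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if self.foci.shape[0] < 1 or self.foci.shape[1] != 3:
            raise ValueError("an experiment needs >= 1 focus with 3 coordinates")
        if not np.all(np.isfinite(self.foci)):
            raise ValueError("focus coordinates must be finite")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class MaMap:
    """Modelled-activation map of one experiment."""

    experiment_id: str
    values: np.ndarray
    fwhm_used_mm: float
    grid: Grid


@dataclass
class AleResult:
    """Thresholded ALE analysis: score map, voxel p, cluster table."""

    ale: np.ndarray
    voxel_p: np.ndarray
    clusters: pd.DataFrame
    threshold_spec: dict
    grid: Grid
    mask: np.ndarray
    ale_threshold: float
    null_max_sizes: np.ndarray
    n_experiments: int
    #: calibration diagnostics at requested probe voxels (None unless asked)
    probe_obs: np.ndarray | None = None
    probe_null: np.ndarray | None = None

    def significant_mask(self) -> np.ndarray:
        """Voxels belonging to FWE-significant clusters."""
        out = np.zeros(self.grid.shape, dtype=bool)
        lab, _ = ndimage.label(self.ale >= self.ale_threshold, structure=_STRUCT26)
        for _, row in self.clusters.iterrows():
            if row["fwe_p"] < self.threshold_spec["fwe_p"]:
                out |= lab == row["label_id"]
        return out & self.mask


@dataclass
class ContrastResult:
    """Seed-vs-seed ALE difference analysis."""

    diff: np.ndarray
    p_a_gt_b: np.ndarray
    p_b_gt_a: np.ndarray
    clusters_a_gt_b: pd.DataFrame
    clusters_b_gt_a: pd.DataFrame
    grid: Grid


def default_fwhm(
    n_subjects: int,
    subject_mm: float = EUCLIDEAN_SUBJECT_MM,
    template_mm: float = EUCLIDEAN_TEMPLATE_MM,
) -> float:
    """Sample-size-dependent kernel width (mm FWHM).

    Combines a between-subject Euclidean uncertainty shrinking as 1/sqrt(n)
    with a fixed between-template term; both are converted to a per-axis
    Gaussian sigma before combining in quadrature.  Monotone non-increasing
    in ``n_subjects``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sd_subj = subject_mm / _EUCLID_TO_AXIS / math.sqrt(n_subjects)
    sd_temp = template_mm / _EUCLID_TO_AXIS
    return _FWHM_PER_SIGMA * math.hypot(sd_subj, sd_temp)


# ---------------------------------------------------------------------------
# seed filtering


def filter_by_seed(
    experiments: list[Experiment], seed_mask: np.ndarray, seed_grid: Grid
) -> list[Experiment]:
    """Experiments with at least one focus inside the seed region.

    Foci (mm) are mapped to their nearest voxel on the seed's grid; foci
    falling outside the grid simply cannot hit the seed.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != seed_grid.shape:
        raise ValueError("seed mask shape must match its grid")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    kept = []
    for e in experiments:
        idx, inside = seed_grid.mm_to_nearest_voxel(e.foci)
        hit = False
        for (i, j, k), ok in zip(idx, inside):
            if ok and seed_mask[i, j, k]:
                hit = True
                break
        if hit:
            kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# kernels and MA/ALE maps


def _diag_voxsizes(grid: Grid) -> np.ndarray:
    A = grid.affine[:3, :3]
    if not np.allclose(A, np.diag(np.diag(A))):
        raise ValueError("MACM computations require an axis-aligned grid")
    return np.abs(np.diag(A))


def _focus_patch(
    focus_mm: np.ndarray, sigma_mm: float, grid: Grid, truncate: float = 3.5
):
    """Gaussian kernel evaluated on the voxel patch around one focus.

    Returns ``(slices, values)`` with the kernel normalised to peak 1 at the
    focus position; ``None`` if the patch misses the grid entirely.
    """
    vox = _diag_voxsizes(grid)
    origin = grid.affine[:3, 3]
    center_vox = (np.asarray(focus_mm, dtype=float) - origin) / np.diag(
        grid.affine[:3, :3]
    )
    half = np.ceil(truncate * sigma_mm / vox).astype(int)
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + half + 1, grid.shape)
    if np.any(lo >= hi):
        return None
    axes = []
    for d in range(3):
        coords = (np.arange(lo[d], hi[d]) - center_vox[d]) * np.diag(
            grid.affine[:3, :3]
        )[d]
        axes.append(coords**2)
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    vals = np.exp(-d2 / (2.0 * sigma_mm**2))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, vals


def ma_map(e: Experiment, grid: Grid, fwhm_fn=default_fwhm) -> MaMap:
    """Modelled-activation map: per-voxel max over the experiment's focus
    kernels (no within-experiment self-reinforcement)."""
    fwhm = float(fwhm_fn(e.n_subjects))
    if fwhm <= 0:
        raise ValueError("kernel FWHM must be positive")
    sigma = fwhm / _FWHM_PER_SIGMA
    values = np.zeros(grid.shape, dtype=np.float64)
    for focus in e.foci:
        patch = _focus_patch(focus, sigma, grid)
        if patch is None:
            continue
        sl, vals = patch
        np.maximum(values[sl], vals, out=values[sl])
    return MaMap(e.experiment_id, values, fwhm, grid)


def ale_map(mas: list[MaMap]) -> np.ndarray:
    """ALE score: probabilistic union ``1 - prod(1 - MA_e)`` across maps."""
    if not mas:
        raise NoExperimentsError("no MA maps; nothing to combine")
    grid = mas[0].grid
    acc = np.ones(grid.shape, dtype=np.float64)
    for m in mas:
        grid.require_match(m.grid)
        acc *= 1.0 - m.values
    return 1.0 - acc


def _bbox_overlaps(sl_a, sl_b) -> bool:
    return all(a.start < b.stop and b.start < a.stop for a, b in zip(sl_a, sl_b))


def _accumulate_experiment(acc_one_minus: np.ndarray, patches: list) -> None:
    """Fold one experiment's focus patches into the running ALE product.

    Within an experiment foci combine by maximum (no self-reinforcement);
    patches with disjoint bounding boxes can be multiplied in directly, while
    overlapping patches need an explicit MA on the union bounding box.
    """
    if not patches:
        return
    disjoint = all(
        not _bbox_overlaps(patches[i][0], patches[j][0])
        for i in range(len(patches))
        for j in range(i + 1, len(patches))
    )
    if disjoint:
        for sl, vals in patches:
            acc_one_minus[sl] *= 1.0 - vals
        return
    lo = [min(p[0][d].start for p in patches) for d in range(3)]
    hi = [max(p[0][d].stop for p in patches) for d in range(3)]
    ma = np.zeros(tuple(h - l for l, h in zip(lo, hi)))
    for sl, vals in patches:
        sub = tuple(slice(s.start - l, s.stop - l) for s, l in zip(sl, lo))
        np.maximum(ma[sub], vals, out=ma[sub])
    usl = tuple(slice(l, h) for l, h in zip(lo, hi))
    acc_one_minus[usl] *= 1.0 - ma


def compute_ale(
    experiments: list[Experiment], grid: Grid, fwhm_fn=default_fwhm
) -> np.ndarray:
    """ALE map over experiments without materialising per-experiment MA maps."""
    if not experiments:
        raise NoExperimentsError("no experiments; refusing to produce an ALE map")
    acc = np.ones(grid.shape, dtype=np.float64)
    for e in experiments:
        fwhm = float(fwhm_fn(e.n_subjects))
        sigma = fwhm / _FWHM_PER_SIGMA
        patches = [
            p for f in e.foci if (p := _focus_patch(f, sigma, grid)) is not None
        ]
        _accumulate_experiment(acc, patches)
    return 1.0 - acc


def _null_ale(
    foci_counts: np.ndarray,
    sigmas: np.ndarray,
    mask_idx: np.ndarray,
    grid: Grid,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Monte-Carlo null ALE map.

    Each experiment's foci are redistributed uniformly over the background
    mask volume (a uniformly chosen mask voxel plus a uniform sub-voxel
    offset — the same continuous law the synthetic generator uses), keeping
    per-experiment focus counts and kernel widths.
    """
    acc = np.ones(grid.shape, dtype=np.float64)
    total = int(foci_counts.sum())
    draws = mask_idx[rng.integers(0, mask_idx.shape[0], size=total)]
    offsets = rng.uniform(-0.5, 0.5, size=(total, 3))
    A, t = grid.affine[:3, :3], grid.affine[:3, 3]
    pts = (draws + offsets) @ A.T + t
    pos = 0
    for count, sigma in zip(foci_counts, sigmas):
        patches = [
            p
            for f in pts[pos : pos + count]
            if (p := _focus_patch(f, sigma, grid)) is not None
        ]
        pos += count
        _accumulate_experiment(acc, patches)
    return 1.0 - acc


def _peak_voxel(stat: np.ndarray, cluster_sel: np.ndarray) -> tuple[int, ...]:
    """Peak voxel of a cluster; plateaus (score ties, e.g. saturated ALE)
    resolve to the tied voxel nearest the cluster centroid."""
    vox = np.argwhere(cluster_sel)
    vals = stat[cluster_sel]
    top = vox[vals == vals.max()]
    if top.shape[0] == 1:
        return tuple(int(i) for i in top[0])
    centroid = vox.mean(axis=0)
    d2 = ((top - centroid) ** 2).sum(axis=1)
    return tuple(int(i) for i in top[int(np.argmin(d2))])


def _cluster_table(
    ale: np.ndarray, threshold: float, mask: np.ndarray, grid: Grid
) -> pd.DataFrame:
    lab, n = ndimage.label((ale >= threshold) & mask, structure=_STRUCT26)
    rows = []
    vv = grid.voxel_volume_mm3
    for lid in range(1, n + 1):
        sel = lab == lid
        size = int(sel.sum())
        ijk = _peak_voxel(ale, sel)
        xyz = grid.voxel_to_mm(np.array(ijk))[0]
        rows.append(
            {
                "label_id": lid,
                "size_vox": size,
                "size_mm3": size * vv,
                "peak_x": xyz[0],
                "peak_y": xyz[1],
                "peak_z": xyz[2],
                "peak_stat": float(ale[ijk]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label_id",
            "size_vox",
            "size_mm3",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_stat",
        ],
    )
    return df.sort_values("size_vox", ascending=False).reset_index(drop=True)


def significance(
    experiments: list[Experiment],
    grid: Grid,
    background_mask: np.ndarray,
    n_null: int = 1000,
    cluster_forming_p: float = 0.001,
    fwe_p: float = 0.05,
    seed: int | None = None,
    fwhm_fn=default_fwhm,
    probe_voxels: np.ndarray | None = None,
) -> AleResult:
    """ALE analysis with Monte-Carlo voxel null and cluster-level FWE.

    The null redistributes each experiment's foci uniformly over the
    background mask (same focus counts, same kernel widths).  Voxel p-values
    come from each voxel's own null histogram; the cluster-forming ALE
    threshold is the pooled-null ``1 - cluster_forming_p`` quantile; a
    cluster's FWE p is the fraction of null iterations whose largest
    supra-threshold cluster is at least as big.

    ``probe_voxels`` (k x 3 voxel indices) requests the raw observed and null
    ALE values at those voxels for calibration diagnostics.
    """
    if not experiments:
        raise NoExperimentsError("no experiments; refusing to run ALE significance")
    if n_null < 100:
        raise ValueError("n_null must be >= 100 (>= 1000 recommended)")
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != grid.shape:
        raise ValueError("background mask must match the grid")
    mask_idx = np.argwhere(background_mask)
    if mask_idx.shape[0] == 0:
        raise ValueError("background mask is empty")
    fwhms = np.array([float(fwhm_fn(e.n_subjects)) for e in experiments])
    sigma_max = fwhms.max() / _FWHM_PER_SIGMA
    extent_mm = (mask_idx.max(axis=0) - mask_idx.min(axis=0) + 1) * _diag_voxsizes(
        grid
    )
    if np.any(extent_mm < 2 * sigma_max):
        raise ValueError("background mask is smaller than the kernel support")
    foci_counts = np.array([e.foci.shape[0] for e in experiments])

    ale = compute_ale(experiments, grid, fwhm_fn)
    rng = np.random.default_rng(seed)
    sigmas = fwhms / _FWHM_PER_SIGMA
    null_maps = np.empty((n_null,) + grid.shape, dtype=np.float32)
    for i in range(n_null):
        null_maps[i] = _null_ale(foci_counts, sigmas, mask_idx, grid, rng)

    mvox = background_mask
    null_in_mask = null_maps[:, mvox]  # (n_null, n_mask_vox)
    # per-voxel empirical p with add-one smoothing
    obs_in_mask = ale[mvox].astype(np.float32)
    counts = (null_in_mask >= obs_in_mask[None, :]).sum(axis=0)
    voxel_p = np.ones(grid.shape, dtype=np.float64)
    voxel_p[mvox] = (1.0 + counts) / (1.0 + n_null)
    # pooled cluster-forming threshold (fine-grained across voxels x iterations)
    ale_threshold = float(
        np.quantile(null_in_mask.ravel(), 1.0 - cluster_forming_p)
    )
    null_max = np.zeros(n_null, dtype=np.int64)
    for i in range(n_null):
        lab, n = ndimage.label(
            (null_maps[i] >= ale_threshold) & mvox, structure=_STRUCT26
        )
        if n:
            null_max[i] = np.bincount(lab.ravel())[1:].max()
    clusters = _cluster_table(ale, ale_threshold, mvox, grid)
    clusters["fwe_p"] = [
        (1.0 + (null_max >= s).sum()) / (1.0 + n_null) for s in clusters["size_vox"]
    ]
    clusters["significant"] = clusters["fwe_p"] < fwe_p
    probe_obs = probe_null = None
    if probe_voxels is not None:
        pv = np.atleast_2d(np.asarray(probe_voxels, dtype=int))
        probe_obs = ale[pv[:, 0], pv[:, 1], pv[:, 2]]
        probe_null = null_maps[:, pv[:, 0], pv[:, 1], pv[:, 2]]
    return AleResult(
        ale=ale,
        voxel_p=voxel_p,
        clusters=clusters,
        threshold_spec={
            "cluster_forming_p": cluster_forming_p,
            "fwe_p": fwe_p,
            "n_null": n_null,
        },
        grid=grid,
        mask=mvox,
        ale_threshold=ale_threshold,
        null_max_sizes=null_max,
        n_experiments=len(experiments),
        probe_obs=probe_obs,
        probe_null=probe_null,
    )


def contrast(
    experiments_a: list[Experiment],
    experiments_b: list[Experiment],
    grid: Grid,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    restrict_to: np.ndarray | None = None,
    fwhm_fn=default_fwhm,
) -> ContrastResult:
    """Seed-vs-seed ALE contrast by permuting experiment membership.

    The voxelwise ALE difference (A - B) is compared against a null obtained
    by reassigning experiments between the two sets (set sizes preserved);
    the null is symmetrised so the two one-sided maps swap exactly when the
    inputs are swapped.  ``restrict_to`` (typically the union of the two
    main-effect significant masks) limits where voxels may be declared
    significant.
    """
    if not experiments_a or not experiments_b:
        raise NoExperimentsError("both experiment sets must be non-empty")
    ale_a = compute_ale(experiments_a, grid, fwhm_fn)
    ale_b = compute_ale(experiments_b, grid, fwhm_fn)
    diff = ale_a - ale_b

    combined = sorted(
        list(experiments_a) + list(experiments_b), key=lambda e: e.experiment_id
    )
    n_a, n_b = len(experiments_a), len(experiments_b)
    k = min(n_a, n_b)
    small_is_a = n_a <= n_b
    rng = np.random.default_rng(seed)
    ge_obs = np.zeros(grid.shape, dtype=np.int64)  # for A > B tail
    ge_neg = np.zeros(grid.shape, dtype=np.int64)  # for B > A tail
    idx_all = np.arange(len(combined))
    for _ in range(n_perm):
        sel = rng.choice(idx_all, size=k, replace=False)
        in_small = np.zeros(len(combined), dtype=bool)
        in_small[sel] = True
        ale_small = compute_ale(
            [combined[i] for i in idx_all[in_small]], grid, fwhm_fn
        )
        ale_large = compute_ale(
            [combined[i] for i in idx_all[~in_small]], grid, fwhm_fn
        )
        d = (ale_small - ale_large) if small_is_a else (ale_large - ale_small)
        # symmetrised null: count both d and -d
        ge_obs += (d >= diff) + (-d >= diff)
        ge_neg += (d >= -diff) + (-d >= -diff)
    denom = 1.0 + 2 * n_perm
    p_a_gt_b = (1.0 + ge_obs) / denom
    p_b_gt_a = (1.0 + ge_neg) / denom

    allowed = (
        np.ones(grid.shape, dtype=bool)
        if restrict_to is None
        else np.asarray(restrict_to, dtype=bool)
    )
    sig_ab = (p_a_gt_b < alpha) & (diff > 0) & allowed
    sig_ba = (p_b_gt_a < alpha) & (diff < 0) & allowed
    cl_ab = _signed_cluster_table(diff, sig_ab, grid)
    cl_ba = _signed_cluster_table(-diff, sig_ba, grid)
    return ContrastResult(diff, p_a_gt_b, p_b_gt_a, cl_ab, cl_ba, grid)


def _signed_cluster_table(stat: np.ndarray, sig: np.ndarray, grid: Grid) -> pd.DataFrame:
    lab, n = ndimage.label(sig, structure=_STRUCT26)
    rows = []
    vv = grid.voxel_volume_mm3
    for lid in range(1, n + 1):
        sel = lab == lid
        ijk = _peak_voxel(stat, sel)
        xyz = grid.voxel_to_mm(np.array(ijk))[0]
        rows.append(
            {
                "label_id": lid,
                "size_vox": int(sel.sum()),
                "size_mm3": int(sel.sum()) * vv,
                "peak_x": xyz[0],
                "peak_y": xyz[1],
                "peak_z": xyz[2],
                "peak_stat": float(stat[ijk]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["label_id", "size_vox", "size_mm3", "peak_x", "peak_y", "peak_z", "peak_stat"],
    )
    return df.sort_values("size_vox", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# database I/O (one row per focus, repeated experiment metadata)


def write_experiments(path, experiments: list[Experiment]) -> None:
    """Write a coordinate database as TSV (one row per focus)."""
    rows = []
    for e in experiments:
        for x, y, z in e.foci:
            rows.append(
                {
                    "experiment_id": e.experiment_id,
                    "x": x,
                    "y": y,
                    "z": z,
                    "n_subjects": e.n_subjects,
                    "domains": ";".join(e.domains),
                    "paradigms": ";".join(e.paradigms),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_experiments(path) -> list[Experiment]:
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str}, keep_default_na=False)
    out = []
    for eid, sub in df.groupby("experiment_id", sort=False):
        first = sub.iloc[0]
        out.append(
            Experiment(
                experiment_id=str(eid),
                foci=sub[["x", "y", "z"]].to_numpy(float),
                n_subjects=int(first["n_subjects"]),
                domains=[d for d in str(first["domains"]).split(";") if d],
                paradigms=[p for p in str(first["paradigms"]).split(";") if p],
            )
        )
    return out
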