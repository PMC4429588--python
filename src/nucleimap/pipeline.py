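"""End-to-end orchestration of the synthetic study.

``run`` executes simulate → morphometry → volumetry → atlas → MACM →
decoding from a single JSON-serialisable configuration, writes every stage's
tables and volumes into an output directory, and records a reproducibility
manifest (config hash, per-output checksums, stage durations, library
versions).  Re-running with an identical config reproduces identical
checksums for all stages.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import atlas_overlap_report, build_mpm, build_probability_map
from .decoding import contrast_profiles, decode
from .grids import save_volume
from .histomorph import compare_paired_densities, folding_index, gli, segment_cells
from .macm import contrast, filter_by_seed, significance, write_experiments
from .synthdata import (
    SyntheticMicrographSpec,
    default_atlas_spec,
    default_database_spec,
    gen_denticulated_contour,
    gen_experiment_db,
    gen_micrograph,
    gen_paired_density_samples,
    gen_subject_labels,
    write_ground_truth_json,
)
from .volumetry import SectionSeries, aggregate_table, cavalieri_volume, volume_group_tests

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run", "default_demo_config"]


class PipelineError(RuntimeError):
    """A stage failed; downstream stages were not run."""


@dataclass
class PipelineConfig:
    """Full study configuration; every stochastic stage carries its own seed."""

    simulate_seed: int | None = 0
    volumetry_seed: int | None = 1
    macm_seed: int | None = 2
    stages: dict = field(
        default_factory=lambda: {
            "morphometry": True,
            "volumetry": True,
            "atlas": True,
            "macm": True,
            "decoding": True,
        }
    )
    # morphometry
    n_micrographs_per_part: int = 3
    micrograph_size: tuple[int, int] = (512, 512)
    planted_fractions: dict = field(
        default_factory=lambda: {"dorsal": 0.041, "ventral": 0.034}
    )
    fi_teeth: dict = field(default_factory=lambda: {"dorsal": 14, "ventral": 7})
    fi_amplitudes: dict = field(default_factory=lambda: {"dorsal": 4.2, "ventral": 16.0})
    fi_sections_per_part: int = 10
    # atlas / volumetry
    n_subjects: int = 10
    jitter_translation_sd_mm: float = 1.0
    jitter_scale_sd: float = 0.03
    mpm_min_prob: float = 0.0
    shrinkage_factors: tuple[float, ...] = (2.15, 2.5, 2.25, 1.9, 1.51, 1.72, 2.2, 2.14, 1.6, 1.84)
    brain_volume_mm3: float = 1.2e6
    n_perm_volumetry: int = 2000
    # database / macm
    n_experiments: int = 400
    n_null: int = 150
    cluster_forming_p: float = 0.001
    fwe_p: float = 0.05
    n_perm_contrast: int = 150
    decoding_q: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def validate(self) -> None:
        for name in ("simulate_seed", "volumetry_seed", "macm_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"stochastic stage seed {name!r} must be set")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    versions: dict
    stages: list = field(default_factory=list)

    def record(self, name: str, status: str, duration_s: float, outputs: dict):
        self.stages.append(
            {
                "stage": name,
                "status": status,
                "duration_s": round(duration_s, 3),
                "outputs": outputs,
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import nibabel
    import scipy
    import skimage

    return {
        "nucleimap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "nibabel": nibabel.__version__,
    }


def default_demo_config() -> PipelineConfig:
    """Small configuration that exercises every stage in a few minutes."""
    return PipelineConfig()


def run(config: PipelineConfig, outdir) -> RunManifest:
    """Run the configured stages in dependency order.

    Each stage writes its artifacts under ``outdir`` and its checksums into
    the manifest; a failure halts downstream stages and leaves the manifest
    (with the partial state) on disk before the error propagates.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), versions=_versions())
    manifest_path = outdir / "manifest.json"
    report: list[str] = ["# Synthetic cerebellar-nuclei study", ""]
    state: dict = {}

    stage_fns = [
        ("simulate", _stage_simulate),
        ("morphometry", _stage_morphometry),
        ("volumetry", _stage_volumetry),
        ("atlas", _stage_atlas),
        ("macm", _stage_macm),
        ("decoding", _stage_decoding),
    ]
    for name, fn in stage_fns:
        if name != "simulate" and not config.stages.get(name, True):
            manifest.record(name, "skipped", 0.0, {})
            continue
        t0 = time.perf_counter()
        try:
            outputs = fn(config, outdir, state, report)
        except Exception as err:
            manifest.record(name, f"failed: {err}", time.perf_counter() - t0, {})
            manifest.to_json(manifest_path)
            raise PipelineError(f"stage {name!r} failed") from err
        checksums = {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
        manifest.record(name, "ok", time.perf_counter() - t0, checksums)

    (outdir / "report.md").write_text("\n".join(report) + "\n")
    manifest.record("report", "ok", 0.0, {"report.md": _sha256(outdir / "report.md")})
    manifest.to_json(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    rng = np.random.default_rng(cfg.simulate_seed)
    micrographs = {}
    for part, frac in cfg.planted_fractions.items():
        micrographs[part] = [
            gen_micrograph(
                SyntheticMicrographSpec(
                    image_size=tuple(cfg.micrograph_size),
                    target_fraction=frac,
                    seed=int(rng.integers(2**31)),
                )
            )
            for _ in range(cfg.n_micrographs_per_part)
        ]
    state["micrographs"] = micrographs
    state["atlas_left"] = gen_subject_labels(
        default_atlas_spec(
            seed=int(rng.integers(2**31)),
            n_subjects=cfg.n_subjects,
            jitter_translation_sd_mm=cfg.jitter_translation_sd_mm,
            jitter_scale_sd=cfg.jitter_scale_sd,
        )
    )
    state["atlas_right"] = gen_subject_labels(
        default_atlas_spec(
            seed=int(rng.integers(2**31)),
            n_subjects=cfg.n_subjects,
            jitter_translation_sd_mm=cfg.jitter_translation_sd_mm,
            jitter_scale_sd=cfg.jitter_scale_sd,
        )
    )
    db = gen_experiment_db(
        default_database_spec(
            seed=int(rng.integers(2**31)), n_experiments=cfg.n_experiments
        )
    )
    state["db"] = db
    db_path = outdir / "experiments.tsv"
    write_experiments(db_path, db.experiments)
    gt_path = outdir / "ground_truth.json"
    write_ground_truth_json(
        gt_path,
        {
            "planted_fractions": cfg.planted_fractions,
            "realized_fractions": {
                part: [m.realized_fraction for m in ms]
                for part, ms in micrographs.items()
            },
            "template_volumes_mm3": state["atlas_left"].template_volumes_mm3,
            "db_links": db.ground_truth,
        },
    )
    report.append(
        f"Simulated {cfg.n_experiments} experiments, {cfg.n_subjects} subjects, "
        f"{sum(len(v) for v in micrographs.values())} micrographs."
    )
    return [db_path, gt_path]


def _stage_morphometry(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    rows = []
    for part, ms in state["micrographs"].items():
        for i, sm in enumerate(ms):
            mask = segment_cells(sm.micrograph)
            g = gli(mask, sm.micrograph, part_label=part, section_id=f"{part}_{i}")
            rows.append(
                {
                    "part": part,
                    "section": i,
                    "gli": g.gli,
                    "gli_percent": g.gli_percent,
                    "planted": sm.spec.target_fraction,
                }
            )
    gli_df = pd.DataFrame(rows)
    gli_path = outdir / "gli_table.tsv"
    gli_df.to_csv(gli_path, sep="\t", index=False)

    dorsal, ventral = gen_paired_density_samples(
        n_brains=cfg.n_subjects, seed=cfg.simulate_seed
    )
    cmp_report = compare_paired_densities(dorsal, ventral, n_comparisons=2)

    fi_rows = []
    rng = np.random.default_rng(cfg.simulate_seed)
    for part in cfg.fi_teeth:
        for i in range(cfg.fi_sections_per_part):
            contour = gen_denticulated_contour(
                n_teeth=cfg.fi_teeth[part],
                tooth_amplitude=cfg.fi_amplitudes[part],
                seed=int(rng.integers(2**31)),
            )
            fr = folding_index(contour)
            fi_rows.append({"part": part, "section": i, "fi": fr.fi})
    fi_df = pd.DataFrame(fi_rows)
    fi_path = outdir / "fi_table.tsv"
    fi_df.to_csv(fi_path, sep="\t", index=False)

    density_path = outdir / "density_comparison.json"
    write_ground_truth_json(
        density_path,
        {
            "dorsal_mean": float(np.mean(dorsal)),
            "ventral_mean": float(np.mean(ventral)),
            "p_value": cmp_report.p_value,
            "p_adjusted": cmp_report.p_adjusted,
            "significant": cmp_report.significant,
        },
    )
    state["gli_table"] = gli_df
    state["fi_table"] = fi_df
    report.append(
        "Density: mean GLI "
        + ", ".join(
            f"{part} {100 * gli_df.loc[gli_df.part == part, 'gli'].mean():.2f}%"
            for part in cfg.planted_fractions
        )
        + f"; dorsal-vs-ventral adjusted p = {cmp_report.p_adjusted:.4g}."
    )
    report.append(
        "Folding Index: "
        + ", ".join(
            f"{part} {fi_df.loc[fi_df.part == part, 'fi'].mean():.2f}"
            for part in cfg.fi_teeth
        )
        + "."
    )
    return [gli_path, fi_path, density_path]


def _stage_volumetry(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    rng = np.random.default_rng(cfg.volumetry_seed)
    records = []
    sexes = ["male"] * (cfg.n_subjects // 2) + ["female"] * (
        cfg.n_subjects - cfg.n_subjects // 2
    )
    shrink = list(cfg.shrinkage_factors)
    while len(shrink) < cfg.n_subjects:
        shrink.append(float(rng.uniform(1.5, 2.5)))
    for hemi, atlas_key in (("left", "atlas_left"), ("right", "atlas_right")):
        result = state[atlas_key]
        grid = result.grid
        for vol in result.label_volumes:
            s_idx = int(vol.subject_id[1:])
            series = SectionSeries(
                section_masks=[vol.mask[:, :, k] for k in range(grid.shape[2])],
                section_thickness_um=grid.voxel_sizes_mm[2] * 1000,
                sampling_interval=1,
                pixel_size_um=grid.voxel_sizes_mm[0] * 1000,
            )
            rec = cavalieri_volume(
                series,
                shrinkage_factor=shrink[s_idx],
                nucleus=vol.nucleus,
                hemisphere=hemi,
                brain_id=vol.subject_id,
                sex=sexes[s_idx],
                brain_volume_mm3=cfg.brain_volume_mm3
                * float(rng.normal(1.0, 0.05)),
            )
            records.append(rec)
    table = aggregate_table(records)
    table_path = outdir / "volume_table.tsv"
    table.to_csv(table_path, sep="\t")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tests = volume_group_tests(
            records, n_perm=cfg.n_perm_volumetry, seed=cfg.volumetry_seed
        )
    tests_path = outdir / "volume_tests.tsv"
    tests.to_csv(tests_path, sep="\t", index=False)
    state["volume_table"] = table
    report.append(
        f"Volumetry: {len(table)} nuclei; "
        f"{int(tests['significant'].sum())} significant group contrasts at FDR."
    )
    return [table_path, tests_path]


def _stage_atlas(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    result = state["atlas_left"]
    maps = [
        build_probability_map(result.by_nucleus(nuc)) for nuc in result.nuclei()
    ]
    mpm = build_mpm(maps, min_prob=cfg.mpm_min_prob)
    overlap = atlas_overlap_report(maps)
    outputs = []
    for pm in maps:
        p = outdir / f"probmap_{pm.nucleus}.nii.gz"
        save_volume(p, pm.values.astype(np.float32), pm.grid)
        outputs.append(p)
    mpm_path = outdir / "mpm.nii.gz"
    save_volume(mpm_path, mpm.labels, mpm.grid)
    outputs.append(mpm_path)
    lookup_path = outdir / "mpm_labels.json"
    write_ground_truth_json(lookup_path, mpm.label_lookup())
    outputs.append(lookup_path)
    overlap_path = outdir / "overlap.tsv"
    overlap.to_csv(overlap_path, sep="\t", index=False)
    outputs.append(overlap_path)
    state["probmaps"] = maps
    state["mpm"] = mpm
    report.append(
        "Atlas: max probability "
        + ", ".join(f"{pm.nucleus} {pm.values.max():.1f}" for pm in maps)
        + f"; MPM assigns {int((mpm.labels > 0).sum())} voxels."
    )
    return outputs


def _stage_macm(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    db = state["db"]
    mpm = state["mpm"]
    grid = db.spec.grid
    seeds = {
        "dentate": mpm.mask_for("dentate"),
        "interposed": mpm.mask_for("emboliform") | mpm.mask_for("globose"),
    }
    bg = db.spec.background_mask()
    outputs = []
    results = {}
    subsets = {}
    for name, seed_mask in seeds.items():
        subset = filter_by_seed(db.experiments, seed_mask, mpm.grid)
        subsets[name] = subset
        res = significance(
            subset,
            grid,
            bg,
            n_null=cfg.n_null,
            cluster_forming_p=cfg.cluster_forming_p,
            fwe_p=cfg.fwe_p,
            seed=cfg.macm_seed,
        )
        results[name] = res
        cl_path = outdir / f"macm_clusters_{name}.tsv"
        res.clusters.to_csv(cl_path, sep="\t", index=False)
        ale_path = outdir / f"ale_{name}.nii.gz"
        save_volume(ale_path, res.ale.astype(np.float32), grid)
        outputs.extend([cl_path, ale_path])
        n_sig = int(res.clusters["significant"].sum())
        report.append(
            f"MACM {name}: {len(subset)} seed experiments, "
            f"{n_sig} FWE-significant clusters."
        )
    restrict = results["dentate"].significant_mask() | results[
        "interposed"
    ].significant_mask()
    con = contrast(
        subsets["dentate"],
        subsets["interposed"],
        grid,
        n_perm=cfg.n_perm_contrast,
        seed=cfg.macm_seed,
        restrict_to=restrict,
    )
    for tag, table in (
        ("dentate_gt_interposed", con.clusters_a_gt_b),
        ("interposed_gt_dentate", con.clusters_b_gt_a),
    ):
        p = outdir / f"contrast_{tag}.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    state["macm_results"] = results
    state["macm_subsets"] = subsets
    return outputs


def _stage_decoding(cfg: PipelineConfig, outdir: Path, state: dict, report: list):
    db = state["db"]
    subsets = state["macm_subsets"]
    outputs = []
    profiles = {}
    for name, subset in subsets.items():
        for axis in ("domains", "paradigms"):
            prof = decode(db.experiments, subset, label_axis=axis, q=cfg.decoding_q)
            profiles[(name, axis)] = prof
            df = pd.DataFrame(
                [
                    {
                        "label": p.label,
                        "k": p.k,
                        "n": p.n,
                        "base_rate": p.base_rate,
                        "p": p.p_binomial,
                        "q": p.q_fdr,
                        "enriched": p.enriched,
                    }
                    for p in prof
                ]
            )
            path = outdir / f"decoding_{name}_{axis}.tsv"
            df.to_csv(path, sep="\t", index=False)
            outputs.append(path)
        enriched = [p.label for p in profiles[(name, "domains")] if p.enriched]
        report.append(f"Decoding {name}: enriched domains {enriched or 'none'}.")
    diff = contrast_profiles(
        profiles[("dentate", "domains")], profiles[("interposed", "domains")]
    )
    diff_path = outdir / "decoding_contrast_domains.tsv"
    diff.to_csv(diff_path, sep="\t", index=False)
    outputs.append(diff_path)
    state["decoding_profiles"] = profiles
    return outputs
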