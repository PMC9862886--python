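"""End-to-end pipeline: simulate -> quantify -> Kerboul -> report.

A run is driven by a single TOML config (one ``[seeds]`` section feeds
every stochastic stage). Stages are isolated through their on-disk
artifacts: deleting a downstream output and re-running regenerates it
identically without re-simulating upstream ones.

Layout of a run directory::

    workdir/
      volumes/            NIfTI label volumes + JSON sidecars + truth
      manifest.csv        case_id, arco_grade, source, path
      metrics.csv         tidy per-case/per-source metrics + Kerboul
      reports/            summary/paired/group/correlation CSVs + JSON
      manifest.json       artifact checksums (deterministic)
      run_log.json        versions, seeds, timings, per-case failures
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kerboul import fit_head_sphere, modified_kerboul
from .mask_io import (
    CaseRecord,
    Source,
    read_label_volume,
    read_manifest,
    write_case_record,
    write_label_volume,
    write_manifest,
)
from .phantom_sim import (
    CohortSpec,
    NoiseSpec,
    draw_cohort_specs,
    generate_phantom,
    perturb_segmentation,
)
from .quant3d import quantify_case
from .stats_report import build_report

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fhnquant.pipeline")

#: fixed shape of the cropped anisotropic 2D grid dialect
ANISO2D_SHAPE = (160, 30, 160)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    workdir: Path
    n_early: int = 6
    n_advanced: int = 24
    theta_range_early: tuple[float, float] = (20.0, 40.0)
    theta_range_advanced: tuple[float, float] = (40.0, 62.0)
    r_range: tuple[float, float] = (20.0, 30.0)
    grid_3d: str = "iso3d"
    grid_2d: str = "aniso2d"
    target_dice_necrotic: float = 0.75
    target_dice_unaffected: float = 0.91
    trim_margin_mm: float = 3.0
    seed_cohort: int = 0
    seed_noise: int = 0
    seed_plane: int = 20230112

    def __post_init__(self) -> None:
        object.__setattr__(self, "workdir", Path(self.workdir))
        # fail fast before any stage runs
        self.cohort_spec()
        self.noise_spec(case_seed=0)
        if self.trim_margin_mm < 0:
            raise ValueError("trim_margin_mm must be >= 0")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_early=self.n_early,
            n_advanced=self.n_advanced,
            theta_range_early=self.theta_range_early,
            theta_range_advanced=self.theta_range_advanced,
            r_range=self.r_range,
            grid=self.grid_3d,
            seed=self.seed_cohort,
        )

    def noise_spec(self, case_seed: int) -> NoiseSpec:
        return NoiseSpec(
            target_dice_necrotic=self.target_dice_necrotic,
            target_dice_unaffected=self.target_dice_unaffected,
            seed=case_seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["workdir"] = str(self.workdir)
        return d

    @classmethod
    def from_toml(cls, path: str | Path, workdir: str | Path | None = None) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        cohort = raw.get("cohort", {})
        noise = raw.get("noise", {})
        seeds = raw.get("seeds", {})

        def pair(v):
            return tuple(float(x) for x in v) if v is not None else None

        kwargs: dict = {}
        if workdir is not None:
            kwargs["workdir"] = Path(workdir)
        elif "workdir" in raw:
            kwargs["workdir"] = Path(path).parent / raw["workdir"]
        else:
            raise ValueError("config must set 'workdir' (or pass one explicitly)")
        for key in ("n_early", "n_advanced"):
            if key in cohort:
                kwargs[key] = int(cohort[key])
        for key in ("theta_range_early", "theta_range_advanced", "r_range"):
            if key in cohort:
                kwargs[key] = pair(cohort[key])
        for key in ("grid_3d", "grid_2d"):
            if key in cohort:
                kwargs[key] = cohort[key]
        if "target_dice_necrotic" in noise:
            kwargs["target_dice_necrotic"] = float(noise["target_dice_necrotic"])
        if "target_dice_unaffected" in noise:
            kwargs["target_dice_unaffected"] = float(noise["target_dice_unaffected"])
        if "trim_margin_mm" in raw:
            kwargs["trim_margin_mm"] = float(raw["trim_margin_mm"])
        for key, attr in (("cohort", "seed_cohort"), ("noise", "seed_noise"), ("plane", "seed_plane")):
            if key in seeds:
                kwargs[attr] = int(seeds[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_stage(config: RunConfig) -> Path:
    manifest_path = config.workdir / "manifest.csv"
    if manifest_path.exists():
        log.info("simulate: manifest exists, skipping")
        return manifest_path
    voldir = config.workdir / "volumes"
    voldir.mkdir(parents=True, exist_ok=True)
    noise_rng = np.random.default_rng(config.seed_noise)

    rows: list[tuple[CaseRecord, str]] = []
    for case_id, grade, spec in draw_cohort_specs(config.cohort_spec()):
        vol3d, truth = generate_phantom(spec, case_id=case_id, trim_margin=config.trim_margin_mm)
        spec2d = dataclasses.replace(spec, grid=config.grid_2d)
        shape2d = ANISO2D_SHAPE if config.grid_2d == "aniso2d" else None
        vol2d, _ = generate_phantom(
            spec2d, case_id=case_id, trim_margin=config.trim_margin_mm, shape=shape2d
        )
        auto2d = perturb_segmentation(
            vol2d, config.noise_spec(case_seed=int(noise_rng.integers(0, 2**31 - 1)))
        )

        (voldir / f"{case_id}_truth.json").write_text(
            json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True) + "\n"
        )
        for source, vol in (
            (Source.MANUAL3D, vol3d),
            (Source.MANUAL2D, vol2d),
            (Source.AUTO2D, auto2d),
        ):
            name = f"{case_id}_{source.value}.nii"
            write_label_volume(vol, voldir / name)
            record = CaseRecord(case_id=case_id, arco_grade=grade, source=source)
            write_case_record(record, voldir / f"{case_id}_{source.value}.json")
            rows.append((record, f"volumes/{name}"))
    write_manifest(rows, manifest_path)
    log.info("simulate: wrote %d volumes", len(rows))
    return manifest_path


def _quantify_stage(config: RunConfig, manifest_path: Path) -> tuple[Path, list[dict]]:
    metrics_path = config.workdir / "metrics.csv"
    failures: list[dict] = []
    if metrics_path.exists():
        log.info("quantify: metrics exist, skipping")
        return metrics_path, failures
    rows = []
    for record, vol_path in read_manifest(manifest_path):
        try:
            vol = read_label_volume(vol_path, case_id=record.case_id)
            metrics = quantify_case(vol, margin=config.trim_margin_mm, plane_seed=config.seed_plane)
            head = fit_head_sphere(vol, margin=config.trim_margin_mm)
            kerb = modified_kerboul(vol, head=head)
        except Exception as exc:  # keep completed cases; report the rest
            log.warning("quantify failed for %s/%s: %s", record.case_id, record.source.value, exc)
            failures.append(
                {"case_id": record.case_id, "source": record.source.value, "error": str(exc)}
            )
            continue
        rows.append(
            {
                "case_id": record.case_id,
                "arco_grade": record.arco_grade.value,
                "group": record.group,
                "source": record.source.value,
                **metrics.as_dict(),
                "kerboul_coronal": kerb.coronal_angle,
                "kerboul_sagittal": kerb.sagittal_angle,
                "kerboul_modified": kerb.modified_angle,
                "head_radius_mm": head.radius,
                "plane_warnings": "; ".join(
                    w for w in metrics.provenance.get("warnings", [])
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values(["case_id", "source"]).reset_index(drop=True)
    df.to_csv(metrics_path, index=False, float_format="%.10g")
    log.info("quantify: %d cases quantified, %d failures", len(rows), len(failures))
    return metrics_path, failures


def _report_stage(config: RunConfig, metrics_path: Path) -> dict[str, Path]:
    reports_dir = config.workdir / "reports"
    df = pd.read_csv(metrics_path)
    cfg = config.to_dict()
    cfg.pop("workdir")  # keep report bytes independent of run location
    return build_report(
        df,
        reports_dir,
        metadata={"config": cfg, "fhnquant_version": __version__},
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run summary (also written to disk)."""
    t0 = time.perf_counter()
    config.workdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t = time.perf_counter()
    manifest_path = _simulate_stage(config)
    timings["simulate_s"] = time.perf_counter() - t

    t = time.perf_counter()
    metrics_path, failures = _quantify_stage(config, manifest_path)
    timings["quantify_s"] = time.perf_counter() - t

    t = time.perf_counter()
    reports = _report_stage(config, metrics_path)
    timings["report_s"] = time.perf_counter() - t
    timings["total_s"] = time.perf_counter() - t0

    artifacts = sorted(
        p for p in config.workdir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run_log.json")
    )
    manifest = {
        "config": config.to_dict(),
        "artifacts": {
            str(p.relative_to(config.workdir)): _sha256(p) for p in artifacts
        },
    }
    (config.workdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    run_log = {
        "fhnquant_version": __version__,
        "seeds": {
            "cohort": config.seed_cohort,
            "noise": config.seed_noise,
            "plane": config.seed_plane,
        },
        "timings": timings,
        "failures": failures,
    }
    (config.workdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    summary = {
        "workdir": str(config.workdir),
        "n_volumes": len(manifest["artifacts"]),
        "reports": {k: str(v) for k, v in reports.items()},
        "failures": failures,
        "timings": timings,
    }
    log.info("pipeline complete in %.1fs", timings["total_s"])
    return summary
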