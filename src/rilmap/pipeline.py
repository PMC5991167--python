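"""Pipeline orchestration: simulate -> observe -> qc -> pav-call -> linkage ->
place-pav -> constitution -> ld, with a validated configuration, per-stage
seeding and a manifest recording parameters and output hashes.

Every threshold default is the published analysis value: 35% missingness cut,
depth-20 stringency, PAV presence band 0.3–0.7 with mean pair depth 8,
placement RF/LOD 0.2/11, grouping LOD 6, distortion alpha 0.05, three-call
confirmation, and a base of 14 observable crossovers at F1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import constitution as cst
from . import io as gio
from . import linkage as lk
from . import observe as obs
from . import pav as pavmod
from . import placement as plc
from . import qc as qcmod
from .simulate import GenomeModel, advance_ssd

STAGES = [
    "simulate", "observe", "qc", "pav-call", "linkage",
    "place-pav", "constitution", "ld",
]


@dataclass
class RunConfig:
    seed: int
    n_lines: int = 41
    target_generation: int = 6
    n_snp: int = 1200
    n_pav: int = 120
    suppression: float = 0.4
    attrition_rate: float = 0.0
    snp_mean_depth: float = 60.0
    snp_dispersion: float = 10.0
    missing_rate: float = 0.02
    pav_mean_depth: float = 8.0
    pav_dispersion: float = 1.0
    pav_noise_fraction: float = 0.02
    max_missing: float = 0.35
    min_depth: int = 20
    strict_monomorphic: bool = False
    pav_band: tuple[float, float] = (0.3, 0.7)
    pav_min_mean_depth: float = 8.0
    rf_max: float = 0.2
    lod_min: float = 11.0
    group_min_lod: float = 6.0
    group_max_rf: float = 0.35
    alpha: float = 0.05
    min_confirm: int = 3
    base_observable: float = 14.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a fixed integer seed is required")
        checks = [
            (0.0 < self.max_missing < 1.0, "max_missing must lie in (0, 1)"),
            (self.min_depth >= 0, "min_depth must be >= 0"),
            (0.0 <= self.pav_band[0] < self.pav_band[1] <= 1.0,
             "pav_band must be an increasing sub-interval of [0, 1]"),
            (0.0 < self.rf_max <= 0.5, "rf_max must lie in (0, 0.5]"),
            (self.lod_min >= 0, "lod_min must be >= 0"),
            (0.0 < self.alpha < 1.0, "alpha must lie in (0, 1)"),
            (self.min_confirm >= 1, "min_confirm must be >= 1"),
            (self.base_observable > 0, "base_observable must be > 0"),
            (0.0 <= self.suppression <= 1.0, "suppression must lie in [0, 1]"),
            (self.n_lines >= 1, "n_lines must be >= 1"),
            (self.target_generation >= 2, "target_generation must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat key = value TOML file."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "pav_band" in data:
            data["pav_band"] = tuple(data["pav_band"])
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = list(value)
            if isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            else:
                lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages in canonical order; write a manifest.

    Stage outputs land in ``outdir``; the manifest records the configuration,
    per-stage seeds and a sha256 of every file written, so a rerun with an
    identical configuration is byte-reproducible.
    """
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    state: dict = {}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    def require(stage: str, key: str):
        if key not in state:
            raise RuntimeError(f"stage '{stage}' requires '{key}' from an earlier stage")
        return state[key]

    for stage in stages:
        if stage == "simulate":
            genome = GenomeModel.ryegrass_default(suppression=config.suppression)
            cohort = advance_ssd(
                config.n_lines, config.target_generation, genome,
                config.stage_seed("simulate"), attrition_rate=config.attrition_rate,
            )
            state["cohort"] = cohort
            files = []
            ped = outdir / "pedigree.tsv"
            cohort.pedigree().to_csv(ped, sep="\t", index=False)
            files.append(ped)
            from .simulate import truth_genotype_matrix

            panel = obs.sample_marker_panel(
                genome, config.n_snp, config.n_pav, config.stage_seed("simulate") + 1
            )
            state["panel"] = panel
            for g in sorted(cohort.generations):
                truth = truth_genotype_matrix(
                    cohort.lines(g), panel.subset("SNP_codominant")
                )
                p = outdir / f"truth_F{g}.csv"
                gio.write_genotype_csv(truth, p)
                files.append(p)
            junc = outdir / "truth_junctions.tsv"
            cohort.truth_junctions(cohort.final_generation).to_csv(junc, sep="\t", index=False)
            files.append(junc)
            record(stage, files)
        elif stage == "observe":
            cohort = require(stage, "cohort")
            panel = require(stage, "panel")
            dm_snp = obs.DepthModel(
                config.snp_mean_depth, config.snp_dispersion, config.missing_rate
            )
            dm_pav = obs.DepthModel(config.pav_mean_depth, config.pav_dispersion, 0.0)
            sam = outdir / "pav_alignments.sam"
            matrix, _truth_presence = obs.observe_cohort(
                cohort, panel, dm_snp, config.stage_seed("observe"),
                sam_path=sam, noise_fraction=config.pav_noise_fraction,
                pav_depth_model=dm_pav,
            )
            state["observed"] = matrix
            state["sam"] = sam
            p = outdir / "observed_snps.csv"
            gio.write_genotype_csv(matrix, p)
            record(stage, [p, sam])
        elif stage == "qc":
            matrix = require(stage, "observed")
            fw, reports, bins = qcmod.qc_pipeline(
                matrix,
                max_missing=config.max_missing,
                min_depth=config.min_depth,
                strict_monomorphic=config.strict_monomorphic,
            )
            state["framework"] = fw
            p = outdir / "framework_snps.csv"
            gio.write_genotype_csv(fw, p)
            rp = outdir / "qc_report.tsv"
            pd.concat([r.to_frame() for r in reports]).to_csv(rp, sep="\t", index=False)
            record(stage, [p, rp])
        elif stage == "pav-call":
            sam = require(stage, "sam")
            cohort = state.get("cohort")
            samples = (
                [ln.line_id for ln in cohort.lines(cohort.final_generation)]
                if cohort else None
            )
            table, rep = pavmod.call_pavs_from_sam(
                [sam], samples=samples,
                band=config.pav_band, min_mean_depth=config.pav_min_mean_depth,
            )
            pav_matrix = pavmod.presence_to_matrix(table, panel=state.get("panel"))
            state["pav_matrix"] = pav_matrix
            p = outdir / "pav_matrix.csv"
            gio.write_genotype_csv(pav_matrix, p)
            rp = outdir / "pav_filter_report.tsv"
            rep.to_csv(rp, sep="\t")
            record(stage, [p, rp])
        elif stage == "linkage":
            fw = require(stage, "framework")
            rf, lod, n = lk.pairwise_ril(fw)
            state["rf"], state["lod"] = rf, lod
            groups, sweep = lk.group_markers(
                rf, lod, min_lod=config.group_min_lod, max_rf=config.group_max_rf
            )
            sd, per_chrom = lk.segregation_test(fw, alpha=config.alpha)
            files = []
            for name, df in (("pairwise_rf.tsv", rf), ("pairwise_lod.tsv", lod)):
                p = outdir / name
                df.to_csv(p, sep="\t")
                files.append(p)
            p = outdir / "linkage_groups.json"
            p.write_text(json.dumps({"groups": groups, "lod_sweep": {str(k): v for k, v in sweep.items()}}, indent=1))
            files.append(p)
            p = outdir / "segregation_distortion.tsv"
            lk.sd_results_frame(sd).to_csv(p, sep="\t", index=False)
            files.append(p)
            p = outdir / "distortion_per_chromosome.tsv"
            per_chrom.to_csv(p, sep="\t")
            files.append(p)
            record(stage, files)
        elif stage == "place-pav":
            fw = require(stage, "framework")
            pav_matrix = require(stage, "pav_matrix")
            placements = plc.place_pavs(
                fw, pav_matrix, rf_max=config.rf_max, lod_min=config.lod_min
            )
            p = outdir / "pav_placements.tsv"
            plc.placements_frame(placements).to_csv(p, sep="\t", index=False)
            record(stage, [p])
        elif stage == "constitution":
            fw = require(stage, "framework")
            report = cst.analyze_constitution(fw, min_confirm=config.min_confirm)
            summary = cst.cohort_summary(report)
            theory = cst.CrossoverTheory(config.base_observable)
            summary["expected_observable_cumulative"] = cst.floor_one_decimal(
                theory.cumulative(config.target_generation)
            )
            p = outdir / "constitution_summary.json"
            p.write_text(json.dumps(summary, indent=1))
            gg = outdir / "graphical_genotypes.tsv"
            gio.write_graphical_genotypes(fw, report.class_codes, path=gg)
            record(stage, [p, gg])
        elif stage == "ld":
            fw = require(stage, "framework")
            r2 = lk.ld_r2(fw)
            p = outdir / "ld_r2.tsv"
            r2.to_csv(p, sep="\t")
            record(stage, [p])

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
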