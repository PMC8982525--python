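"""End-to-end orchestration on a synthetic input bundle.

Stages run in order: simulate -> descriptors -> fits -> lrcf -> assemble
-> split -> gfa -> validate -> screen.  Every stage is a pure function of
the manifest inputs, so rerunning an identical config reproduces identical
output digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .contacts import ContactSettings, ScoredPose, build_lrcf_matrix, write_receptor_pdb
from .descriptors import descriptor_table, write_sdf
from .pharmacophore import best_fit, bundled_models, screen_molecule
from .qsar import (
    GASettings,
    RegressorSpec,
    assemble_matrix,
    gfa_select,
    split_train_test,
    validate_model,
)
from .screening import ScreeningThresholds, rank_and_filter_hits
from .synthetic import SimConfig, gen_activities, gen_ligands, gen_pocket, gen_poses

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("phoreqsar.pipeline")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    seed: int = 0
    n_compounds: int = 40
    match_fraction: float = 0.5
    noise_sd: float = 0.1
    pocket_atoms: int = 120
    regressor: str = "MLR"
    ga_population: int = 60
    ga_generations: int = 15
    ga_min_features: int = 3
    ga_max_features: int = 8
    true_support: Optional[Dict[str, float]] = None  # None -> auto-pick per block

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        return PipelineConfig(**payload)


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stages: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: RunManifest, name: str, outputs: List[Path], note: str) -> None:
    manifest.stages.append(
        {
            "name": name,
            "outputs": {p.name: _digest(p) for p in outputs},
            "note": note,
        }
    )
    logger.info("stage %-12s %s", name, note)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute all nine stages under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed, config=asdict(config))

    try:
        # --- stage 1: simulate inputs
        sim = SimConfig(
            seed=config.seed,
            n_compounds=config.n_compounds,
            noise_sd=config.noise_sd,
            pocket_atoms=config.pocket_atoms,
        )
        models = bundled_models()
        pocket = gen_pocket(sim)
        ligands = gen_ligands(sim, models[0], config.match_fraction)
        poses = gen_poses(sim, pocket, ligands)
        pdb_path = out / "pocket.pdb"
        write_receptor_pdb(pocket, pdb_path)
        sdf_path = out / "ligands.sdf"
        write_sdf(ligands, sdf_path)
        score_rows = []
        pose_rows = []
        for lid, plist in poses.items():
            for p in plist:
                score_rows.append(
                    {"ligand_id": lid, "pose_id": p.pose_id, **p.scores}
                )
                for k, (x, y, z) in enumerate(p.coordinates):
                    pose_rows.append(
                        {
                            "ligand_id": lid,
                            "pose_id": p.pose_id,
                            "atom": k,
                            "x": x,
                            "y": y,
                            "z": z,
                        }
                    )
        scores_path = out / "pose_scores.tsv"
        _write_tsv(pd.DataFrame(score_rows), scores_path, index=False)
        poses_path = out / "pose_coords.tsv"
        _write_tsv(pd.DataFrame(pose_rows), poses_path, index=False)
        _stage(
            manifest,
            "simulate",
            [pdb_path, sdf_path, scores_path, poses_path],
            f"{len(ligands)} ligands, pocket of {len(pocket.atoms)} atoms",
        )

        # --- stage 2: physicochemical descriptors
        physchem = descriptor_table(ligands, grid_step=0.2).set_index("compound_id")
        physchem_path = out / "physchem.tsv"
        _write_tsv(physchem, physchem_path)
        _stage(manifest, "descriptors", [physchem_path], f"{physchem.shape[1]} columns")

        # --- stage 3: pharmacophore fit values
        fit_rows = {}
        for lig in ligands:
            row = {}
            for model in models:
                result = best_fit(lig, model, require_all=False)
                row[model.name] = 0.0 if result is None else result[1].fit
            fit_rows[lig.id] = row
        fits = pd.DataFrame.from_dict(fit_rows, orient="index")
        fits.index.name = "compound_id"
        fits_path = out / "fits.tsv"
        _write_tsv(fits, fits_path)
        _stage(manifest, "fits", [fits_path], f"{fits.shape[1]} pharmacophores")

        # --- stage 4: contact fingerprints
        lrcf = build_lrcf_matrix(pocket, poses, ContactSettings())
        lrcf_path = out / "lrcf.tsv"
        _write_tsv(lrcf, lrcf_path)
        _stage(manifest, "lrcf", [lrcf_path], f"{lrcf.shape[1]} contact bits")

        # --- stage 5: assemble with planted activities
        combined = pd.concat([fits, lrcf, physchem], axis=1)
        support = config.true_support
        if support is None:
            support = {fits.columns[0]: 1.0, "CHI_2": 0.5}
            if lrcf.shape[1]:
                support[lrcf.columns[0]] = -0.7
        sim_support = SimConfig(
            seed=config.seed,
            n_compounds=config.n_compounds,
            noise_sd=config.noise_sd,
            true_support=support,
        )
        activity = gen_activities(combined, sim_support)
        matrix = assemble_matrix(fits, lrcf, physchem, activity)
        matrix_path = out / "matrix.tsv"
        _write_tsv(matrix.values.assign(log_inv_ic50=matrix.activity), matrix_path)
        _stage(
            manifest,
            "assemble",
            [matrix_path],
            f"{matrix.values.shape[0]} x {matrix.values.shape[1]}",
        )

        # --- stage 6: split
        train_ids, test_ids = split_train_test(matrix)
        split_path = out / "split.tsv"
        split_frame = pd.DataFrame(
            {
                "compound_id": train_ids + test_ids,
                "role": ["train"] * len(train_ids) + ["test"] * len(test_ids),
            }
        )
        _write_tsv(split_frame, split_path, index=False)
        _stage(manifest, "split", [split_path], f"{len(train_ids)}/{len(test_ids)}")

        # --- stage 7: GA feature selection on the training rows
        spec = RegressorSpec(method=config.regressor, seed=config.seed)
        ga = GASettings(
            population_size=config.ga_population,
            max_generations=config.ga_generations,
            min_features=config.ga_min_features,
            max_features=config.ga_max_features,
            seed=config.seed,
        )
        from .qsar import DescriptorMatrix

        train_matrix = DescriptorMatrix(
            matrix.values.loc[train_ids],
            matrix.blocks,
            matrix.activity.loc[train_ids],
        )
        subset, _, trace = gfa_select(train_matrix, spec, ga)
        selected_path = out / "selected.json"
        selected_path.write_text(json.dumps({"subset": subset}, indent=2) + "\n")
        trace_path = out / "fitness_trace.tsv"
        _write_tsv(
            pd.DataFrame(trace, columns=["generation", "best", "mean"]),
            trace_path,
            index=False,
        )
        _stage(manifest, "gfa", [selected_path, trace_path], f"{len(subset)} descriptors")

        # --- stage 8: validation
        report = validate_model(matrix, (train_ids, test_ids), subset, spec)
        validation_path = out / "validation.json"
        validation_path.write_text(json.dumps(asdict(report), indent=2) + "\n")
        _stage(
            manifest,
            "validate",
            [validation_path],
            f"r2={report.r2_resub:.3f} q2loo={report.r2_loo:.3f} "
            f"r2press={report.r2_press:.3f}",
        )

        # --- stage 9: screen, predict for hits only, rank and filter
        from .qsar import fit_regressor

        X_train = matrix.values.loc[train_ids, subset].to_numpy(dtype=float)
        y_train = matrix.activity.loc[train_ids].to_numpy(dtype=float)
        model_fitted = fit_regressor(X_train, y_train, spec)
        hit_ids = []
        for lig in ligands:
            if any(screen_molecule(lig, m)[0] for m in models):
                hit_ids.append(lig.id)
        predictions = {}
        for cid in hit_ids:
            x = matrix.values.loc[[cid], subset].to_numpy(dtype=float)
            predictions[cid] = float(model_fitted.predict(x)[0])
        retained = rank_and_filter_hits(predictions, ScreeningThresholds())
        hits_path = out / "hits.tsv"
        _write_tsv(
            pd.DataFrame(retained, columns=["compound_id", "predicted_log_inv_ic50"]),
            hits_path,
            index=False,
        )
        _stage(
            manifest,
            "screen",
            [hits_path],
            f"{len(hit_ids)} screen hits -> {len(retained)} retained",
        )
    except Exception as exc:
        stage_name = (
            manifest.stages[-1]["name"] if manifest.stages else "(startup)"
        )
        raise RuntimeError(
            f"pipeline aborted after stage {stage_name!r}: {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest
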