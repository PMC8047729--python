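"""End-to-end pipeline driver: structure → exemplar → screen → fits → SAR.

On synthetic inputs every stage consumes the previous stage's output plus
generated ground truth, so a single seeded run exercises the whole workflow
deterministically; on user inputs the same stages run on the supplied PDB,
library, assay table and score table.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .assays import fit_competition, fit_saturation, read_measurements_csv
from .config import PipelineConfig
from .exemplar import build_exemplar, exemplar_to_pdb, exemplar_to_text, params_to_json
from .molio import read_library, write_sdf
from .pharmacophore import featurize_molecule
from .pose import minimize_pose, pose_from_rdkit, read_scores_csv
from .sar import (
    AffinityRecord,
    build_ddg_pairs,
    correlate,
    ddg_from_ic50,
    rank_structures,
    reports_to_json,
    scatter_table,
)
from .screening import screen_library
from .structure import PocketSpec, load_pdb, select_pocket
from .synthetic import (
    AssayTruth,
    groove_structure,
    make_groove,
    make_library,
    simulate_competition,
    simulate_saturation,
    simulate_score_records,
)

#: Site-2 competition ground truths (nM) used for the synthetic assay panel.
SYNTHETIC_PANEL_NM = {
    "6": 9.49,
    "24": 95.1,
    "28": 3.32,
    "31": 68.7,
    "39": 95.7,
    "40": 19.6,
    "52": 30.7,
}
SYNTHETIC_KD_NM = 1.06


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "input_hashes": self.input_hashes,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(out_dir: str, name: str, text: str) -> str:
    path = os.path.join(out_dir, name)
    with open(path, "w") as fh:
        fh.write(text)
    return path


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; short-circuits with a partial report on failure."""
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    report = RunReport(config=config.model_dump())
    written: list[str] = []

    def record(stage: str, params: dict, outputs: list[str]):
        report.stages.append(
            {
                "name": stage,
                "status": "ok",
                "params": params,
                "outputs": [os.path.basename(p) for p in outputs],
            }
        )
        written.extend(outputs)

    def fail(stage: str, exc: Exception):
        report.stages.append({"name": stage, "status": f"error: {exc}", "params": {}})
        for path in written:
            report.outputs[os.path.basename(path)] = _sha256(path)
        return report

    syn = config.synthetic_params
    seed_seq = np.random.SeedSequence(syn.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(8)]

    # -- stage 1: structure -------------------------------------------------
    try:
        if config.synthetic:
            pdb_text, manifest = make_groove(
                syn.seed, syn.n_strands, syn.n_residues, tuple(syn.planted)
            )
            pdb_path = _write(out_dir, "structure.pdb", pdb_text)
            manifest_path = _write(out_dir, "groove_manifest.json", manifest.to_json())
            structure = groove_structure(pdb_text, structure_id="groove")
            spec = manifest.pocket_spec(config.site.site_label)
            record("structure", {"seed": syn.seed, "n_strands": syn.n_strands},
                   [pdb_path, manifest_path])
        else:
            structure = load_pdb(config.structure_path)
            report.input_hashes["structure"] = _sha256(config.structure_path)
            spec = PocketSpec(
                site_label=config.site.site_label,
                member_residues=tuple(config.site.residues),
                anchor_residue=config.site.anchor,
                chain_selection=tuple(config.site.chains),
                numbering=config.site.numbering,
            )
            record("structure", {"path": config.structure_path}, [])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        return fail("structure", exc)

    # -- stage 2: exemplar --------------------------------------------------
    try:
        params = config.exemplar.to_params()
        exemplar = build_exemplar(structure, spec, params)
        p1 = _write(out_dir, "exemplar.txt", exemplar_to_text(exemplar))
        p2 = _write(out_dir, "exemplar_params.json", params_to_json(params))
        p3 = _write(out_dir, "exemplar.pdb", exemplar_to_pdb(exemplar))
        record("exemplar", {"n_points": len(exemplar.points)}, [p1, p2, p3])
    except Exception as exc:
        return fail("exemplar", exc)

    # -- stage 3: screen ----------------------------------------------------
    try:
        if config.synthetic:
            library = make_library(
                sub_seeds[0], syn.n_decoys, manifest.complement_sites()
            )
            lib_path = os.path.join(out_dir, "library.sdf")
            write_sdf(library, lib_path)
        else:
            library = read_library(config.library_path)
            report.input_hashes["library"] = _sha256(config.library_path)
        result = screen_library(
            exemplar,
            library,
            top_n=config.screen.top_n,
            seed=config.screen.seed,
            n_starts=config.screen.n_starts,
            lead_like_filter=config.screen.lead_like_filter,
        )
        screen_path = os.path.join(out_dir, "screen.csv")
        result.to_frame().to_csv(screen_path, index=False)
        outputs = [screen_path] + ([lib_path] if config.synthetic else [])
        record(
            "screen",
            {"top_n": config.screen.top_n, "seed": config.screen.seed,
             "n_starts": config.screen.n_starts, "n_ranked": len(result.ranked)},
            outputs,
        )
    except Exception as exc:
        return fail("screen", exc)

    # -- stage 4: binding-assay fits -----------------------------------------
    try:
        affinities: list[AffinityRecord] = []
        fits = {}
        site = config.sar.site
        if config.synthetic:
            for i, (compound, ic50_nm) in enumerate(sorted(SYNTHETIC_PANEL_NM.items())):
                truth = AssayTruth(
                    compound_id=compound,
                    site_label=site,
                    seed=sub_seeds[1] + i,
                    true_log_ic50=float(np.log10(ic50_nm * 1e-9)),
                    noise_cv=syn.noise_cv,
                    n_replicates=syn.n_replicates,
                )
                fit = fit_competition(simulate_competition(truth))
                fits[compound] = {
                    "ic50_nM": fit.ic50 * 1e9,
                    "ci95_nM": [fit.ci95_ic50[0] * 1e9, fit.ci95_ic50[1] * 1e9],
                    "n_points": fit.n_points,
                }
                affinities.append(
                    AffinityRecord(compound, site, fit.ic50, tuple(fit.ci95_ic50))
                )
            sat_truth = AssayTruth(
                compound_id="61",
                site_label=site,
                seed=sub_seeds[2],
                true_kd=SYNTHETIC_KD_NM * 1e-9,
                noise_cv=syn.noise_cv,
                n_replicates=syn.n_replicates,
            )
            sat = fit_saturation(simulate_saturation(sat_truth))
            fits["saturation_61"] = {
                "kd_nM": sat.kd * 1e9,
                "bmax": sat.bmax,
                "ci95_nM": [sat.ci95_kd[0] * 1e9, sat.ci95_kd[1] * 1e9],
            }
        else:
            measurements = read_measurements_csv(config.assay_path)
            report.input_hashes["assays"] = _sha256(config.assay_path)
            by_compound: dict[str, list] = {}
            for m in measurements:
                by_compound.setdefault(m.compound_id, []).append(m)
            for compound, data in sorted(by_compound.items()):
                fit = fit_competition(data)
                fits[compound] = {
                    "ic50_nM": fit.ic50 * 1e9,
                    "ci95_nM": [fit.ci95_ic50[0] * 1e9, fit.ci95_ic50[1] * 1e9],
                    "n_points": fit.n_points,
                }
                affinities.append(
                    AffinityRecord(compound, data[0].site_label, fit.ic50, tuple(fit.ci95_ic50))
                )
        fits_path = _write(out_dir, "fits.json", json.dumps(fits, indent=2, sort_keys=True))
        record("assays", {"n_compounds": len(affinities)}, [fits_path])
    except Exception as exc:
        return fail("assays", exc)

    # -- stage 5: pose scoring of the top screened hit ------------------------
    try:
        top_id = result.ranked[0][0]
        top_entry = next(e for e in library if e.id == top_id)
        pocket_atoms = select_pocket(structure, spec)
        model = featurize_molecule(top_entry.mol, mol_id=top_id)
        pose = pose_from_rdkit(
            top_entry.mol, structure.id, spec.site_label, pharmacophore=model
        )
        _, score_record = minimize_pose(
            pose, pocket_atoms, exemplar, seed=sub_seeds[3], compound_id=top_id
        )
        pose_path = _write(
            out_dir,
            "pose_score.json",
            json.dumps(
                {
                    "compound_id": score_record.compound_id,
                    "score": score_record.score,
                    "components": score_record.components,
                },
                indent=2,
                sort_keys=True,
            ),
        )
        record("pose", {"compound_id": top_id}, [pose_path])
    except Exception as exc:
        return fail("pose", exc)

    # -- stage 6: SAR correlation ---------------------------------------------
    try:
        ref = config.sar.reference_compound
        if config.synthetic:
            ref_aff = next(a for a in affinities if a.compound_id == ref)
            ddg_exp = {
                a.compound_id: ddg_from_ic50(a.ic50, ref_aff.ic50, config.sar.temperature)
                for a in affinities
            }
            scores = simulate_score_records(
                sub_seeds[4], ddg_exp, "structA", slope=1.0, noise_sd=0.15,
                scale=config.sar.scale, reference_compound=ref,
            ) + simulate_score_records(
                sub_seeds[5], ddg_exp, "structB", slope=0.5, noise_sd=0.6,
                scale=config.sar.scale, reference_compound=ref,
            )
        else:
            scores = read_scores_csv(config.scores_path)
            report.input_hashes["scores"] = _sha256(config.scores_path)
        pairs = build_ddg_pairs(
            affinities,
            scores,
            reference_compound=ref,
            site_label=config.sar.site,
            temperature=config.sar.temperature,
            scale=config.sar.scale,
            include_reference=config.sar.include_reference,
            censored_policy=config.sar.censored_policy,
        )
        by_structure: dict[str, list] = {}
        for p in pairs:
            by_structure.setdefault(p.structure_id, []).append(p)
        reports = [correlate(v) for _, v in sorted(by_structure.items())]
        ranking = rank_structures(reports)
        sar_path = _write(out_dir, "sar_report.json", reports_to_json(ranking))
        scatter_path = os.path.join(out_dir, "sar_scatter.csv")
        scatter_table(pairs).to_csv(scatter_path, index=False)
        record(
            "sar",
            {"reference": ref, "temperature": config.sar.temperature,
             "scale": config.sar.scale, "best_structure": ranking[0].structure_id},
            [sar_path, scatter_path],
        )
    except Exception as exc:
        return fail("sar", exc)

    for path in written:
        report.outputs[os.path.basename(path)] = _sha256(path)
    report_path = os.path.join(out_dir, "run_report.json")
    with open(report_path, "w") as fh:
        fh.write(report.to_json())
    return report
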