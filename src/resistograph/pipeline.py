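"""End-to-end orchestration: run the analysis stages and emit a JSON report.

A configuration maps stage names to either input file paths or synthetic
generator settings; stages run in dependency order (structure → stability →
evolutionary scoring → binding → trajectory) and absent sections are marked
skipped. The report keeps full precision and records provenance (inputs,
seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import binding as _binding
from . import evo as _evo
from . import stability as _stab
from . import structio as _struct
from . import synth as _synth
from . import trajectory as _traj

logger = logging.getLogger("resistograph")

__all__ = ["AnalysisReport", "run_pipeline", "load_config"]


@dataclass
class AnalysisReport:
    provenance: dict
    structure: dict | str = "skipped"
    stability: dict | str = "skipped"
    evo: dict | str = "skipped"
    binding: dict | str = "skipped"
    trajectory: dict | str = "skipped"

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _require_file(path: str, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"[{stage}] input file not found: {path}")
    return p


def _structure_stage(cfg: dict, seed: int) -> dict:
    if "pdb" in cfg:
        text = _require_file(cfg["pdb"], "structure").read_text()
        structure = _struct.parse_pdb(text, identifier=str(cfg["pdb"]))
    else:
        structure = _synth.gen_toy_structure(
            int(cfg.get("n_res", 30)), cfg.get("geometry", "ideal_helix")
        )
    areas = _struct.shrake_rupley_sasa(
        structure,
        probe_radius=float(cfg.get("probe", 1.4)),
        n_sphere_points=int(cfg.get("points", 960)),
    )
    residues = _struct.residue_sasa(structure, areas)
    top = max(residues, key=lambda r: r.sasa)
    classes = {c: sum(1 for r in residues if r.exposure_class == c) for c in ("buried", "intermediate", "exposed")}
    return {
        "identifier": structure.identifier,
        "n_atoms": len(structure),
        "n_residues": len(residues),
        "total_sasa_A2": float(sum(r.sasa for r in residues)),
        "max_sasa_residue": f"{top.residue_name}{top.residue_number}",
        "max_sasa_A2": top.sasa,
        "exposure_counts": classes,
        "residue_sasa": [
            {"chain": r.chain_id, "resnum": r.residue_number, "sasa_A2": r.sasa, "exposure": r.exposure_class}
            for r in residues
        ],
    }


def _stability_stage(cfg: dict, seed: int) -> dict:
    if "table" in cfg:
        records = _stab.read_stability_table(_require_file(cfg["table"], "stability"))
        sasa_df = pd.read_csv(_require_file(cfg["sasa"], "stability"), sep="\t") if "sasa" in cfg else None
        by_prov: dict[str, list] = {}
        for r in records:
            by_prov.setdefault(r.provenance, []).append(r)
    else:
        lc_kwargs = {k: v for k, v in cfg.items() if k in _synth.LandscapeConfig.__dataclass_fields__}
        lc = _synth.LandscapeConfig(**lc_kwargs)
        all_df, obs_df, sasa_df = _synth.gen_stability_landscape(lc, seed=seed)
        records = _stab.read_stability_table(_df_buffer(all_df), provenance="all_possible")
        records += _stab.read_stability_table(_df_buffer(obs_df), provenance="observed")
        by_prov = {
            "all_possible": [r for r in records if r.provenance == "all_possible"],
            "observed": [r for r in records if r.provenance == "observed"],
        }

    out: dict[str, Any] = {"landscape": {}}
    for prov, recs in by_prov.items():
        summary = _stab.landscape_summary(recs)
        values = [r.ddg_fold for r in recs]
        section = dict(summary)
        if len(set(values)) > 2:
            curve = _stab.kde_density(values)
            peaks = _stab.find_peaks(curve)
            section["kde_bandwidth"] = curve.bandwidth
            section["kde_peaks"] = peaks[:5]
        out["landscape"][prov] = section

    if sasa_df is not None:
        sasa_records = [
            _struct.ResidueSASA(
                chain_id=str(row["chain"]),
                residue_number=int(row["resnum"]),
                residue_name=str(row["resname"]),
                sasa=float(row["sasa_A2"]),
                exposure_class=str(row["exposure"]),
            )
            for _, row in sasa_df.iterrows()
        ]
        corr_recs = [
            r
            for r in records
            if not r.mutation.is_multi_site and not r.mutation.is_synonymous
        ]
        rho, _pairs = _stab.correlate_sasa_stability(corr_recs, sasa_records)
        out["sasa_spearman_rho"] = rho
        out["n_sasa_pairs"] = len(_pairs)
    return out


def _df_buffer(df: pd.DataFrame):
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf


def _evo_stage(cfg: dict, seed: int) -> dict:
    if "model" in cfg:
        model = _evo.read_potts_model(_require_file(cfg["model"], "evo"))
        wt = Path(_require_file(cfg["wt"], "evo")).read_text().strip().splitlines()
        wt_seq = "".join(l.strip() for l in wt if not l.startswith(">"))
        mutations_df = pd.read_csv(_require_file(cfg["mutations"], "evo"), sep="\t")
        mutations = [str(m) for m in mutations_df["mutation"]]
        labels = (
            [str(x) for x in mutations_df["label"]]
            if "label" in mutations_df.columns
            else ["not_specified"] * len(mutations)
        )
    else:
        L = int(cfg.get("L", 6))
        q = int(cfg.get("q", 4))
        model, wt_seq = _synth.gen_potts_model(L, q, float(cfg.get("density", 0.5)), seed=seed)
        rng = np.random.default_rng(seed + 1)
        mutations, labels = [], []
        for _ in range(int(cfg.get("n_mutations", 25))):
            pos = int(rng.integers(L))
            wt_letter = wt_seq[pos]
            mut = rng.choice([a for a in model.alphabet if a != wt_letter])
            mutations.append(f"{wt_letter}{model.position_map[pos]}{mut}")
            labels.append("pathogenic" if rng.uniform() < 0.7 else "not_specified")
    scores = [
        _evo.delta_e(model, wt_seq, _stab.parse_mutation_notation(m), label=lab)
        for m, lab in zip(mutations, labels)
    ]
    result = {"summary_all": _evo.summarize_scores(scores)}
    if any(s.pathogenicity_label == "pathogenic" for s in scores):
        result["summary_pathogenic"] = _evo.summarize_scores(scores, label="pathogenic")
    result["scores"] = [
        {"mutation": s.mutation.notation, "delta_e": s.delta_e, "label": s.pathogenicity_label}
        for s in scores
    ]
    return result


def _binding_stage(cfg: dict, seed: int) -> dict:
    truth = None
    if "energies" in cfg:
        records = _binding.binding_records_from_table(
            _binding.read_energy_table(_require_file(cfg["energies"], "binding"))
        )
        kis = _binding.read_ki_table(_require_file(cfg["ki"], "binding")) if "ki" in cfg else []
        atp_ligand = cfg.get("atp_ligand", "ATP")
    else:
        ec_kwargs = {k: v for k, v in cfg.items() if k in _synth.EnergyTableConfig.__dataclass_fields__}
        ec = _synth.EnergyTableConfig(**ec_kwargs)
        records, kis, truth = _synth.gen_energy_tables(ec, seed=seed)
        atp_ligand = ec.atp_ligand

    matrix, summary = _binding.build_profile(records)
    out: dict[str, Any] = {
        "profile_matrix": {lig: {v: _nan_none(x) for v, x in row.items()} for lig, row in matrix.iterrows()},
        "per_ligand_summary": {lig: {k: _nan_none(v) for k, v in row.items()} for lig, row in summary.iterrows()},
    }
    if kis:
        scheme = records[0].scheme
        pred = {(r.ligand, r.variant): matrix.loc[r.ligand, r.variant] for r in records if r.variant != _binding.WILD_TYPE and r.ligand in matrix.index}
        pairs = [
            (pred[(k.ligand, k.variant)], _binding.ddg_fr_experimental(k))
            for k in kis
            if (k.ligand, k.variant) in pred
        ]
        if len(pairs) >= 3:
            ev = _binding.evaluate_scheme(pairs, scheme=scheme)
            out["scheme_evaluation"] = {"scheme": ev.scheme, "n_pairs": len(ev.pairs), "r_squared": ev.r_squared}

    threshold = float(cfg.get("high_threshold", 8.0))
    calls = []
    for ligand in matrix.index:
        if ligand == atp_ligand:
            continue
        for variant in matrix.columns:
            ddg = matrix.loc[ligand, variant]
            if pd.isna(ddg):
                continue
            atp = (
                matrix.loc[atp_ligand, variant]
                if atp_ligand in matrix.index and not pd.isna(matrix.loc[atp_ligand, variant])
                else None
            )
            calls.append(_binding.classify_resistance(float(ddg), atp, threshold, ligand=ligand, variant=variant))
    out["resistance_calls"] = [asdict(c) for c in calls]
    if truth is not None:
        lookup = {(c.ligand, c.variant): c.call for c in calls}
        hits = sum(
            1
            for _, row in truth.iterrows()
            if lookup.get((row["ligand"], row["variant"]))
            == ("resistant" if row["resistant"] else "likely_sensitive")
        )
        out["truth_accuracy"] = hits / len(truth)
    return out


def _trajectory_stage(cfg: dict, seed: int) -> dict:
    if "trajectory" in cfg:
        traj = _traj.read_trajectory_tsv(_require_file(cfg["trajectory"], "trajectory"))
    else:
        tc_kwargs = {k: v for k, v in cfg.items() if k in _synth.TrajectoryConfig.__dataclass_fields__}
        tc = _synth.TrajectoryConfig(**tc_kwargs)
        ref = _synth.gen_toy_structure(int(cfg.get("n_res", 20)))
        traj, _ = _synth.gen_trajectory(ref, tc, seed=seed)
    burn_in = float(cfg.get("burn_in_ps", 0.0))
    series, mean_rmsd = _traj.rmsd_series(traj, burn_in=burn_in)
    pca = _traj.covariance_pca(traj)
    return {
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "mean_rmsd_A": mean_rmsd,
        "max_rmsd_A": float(series.max()),
        "burn_in_ps": burn_in,
        "pca_top5_variance_fraction": pca.variance_fraction[:5].tolist(),
        "pc1_pc2_variance": float(pca.variance_fraction[:2].sum()),
    }


def _nan_none(x):
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


_STAGES = [
    ("structure", _structure_stage),
    ("stability", _stability_stage),
    ("evo", _evo_stage),
    ("binding", _binding_stage),
    ("trajectory", _trajectory_stage),
]


def run_pipeline(config: dict, seed: int | None = None) -> AnalysisReport:
    """Run configured stages in dependency order; absent stages are skipped.

    ``config`` maps stage names to their settings (file inputs or synthetic
    parameters). A stage error propagates with a stage-labelled message.
    """
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    canonical = json.dumps(config, sort_keys=True, default=str)
    provenance = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest()[:16],
        "inputs": {
            stage: sorted(str(v) for v in cfg.values() if isinstance(v, str))
            for stage, cfg in config.items()
            if isinstance(cfg, dict)
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    report = AnalysisReport(provenance=provenance)
    for name, fn in _STAGES:
        if name not in config or config[name] in (None, False):
            continue
        stage_cfg = config[name] if isinstance(config[name], dict) else {}
        logger.info("[%s] running", name)
        try:
            setattr(report, name, fn(stage_cfg, seed))
        except Exception as exc:
            raise RuntimeError(f"[{name}] stage failed: {exc}") from exc
    return report
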