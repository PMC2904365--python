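"""End-to-end model selection: dock, electrostatic screen, distance-constraint
filter, register filter, interface rescoring, ranking, selection.

Survivors of the filters are rescored rigidly (interaction energy + buried
interface area); no minimization is applied between filtering and ranking.
"Largest binding energy" means most negative interaction energy. The joint
ranking rule selects the pose that is maximal in BOTH energy magnitude and
interface area when such a pose exists, and otherwise falls back to the best
rank-sum (recorded in the selection rationale).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filters import (ConstraintSet, RegisterFilterSpec, apply_constraints,
                      apply_register_filter, parse_constraints)
from .grid import DockParams, Pose, apply_pose, dock, electrostatic_screen
from .interface import EnergyParams, interaction_energy, interface_asa
from .structure import Structure, save_structure, superpose

__all__ = ["PipelineConfig", "SelectionReport", "run_pipeline",
           "rank_survivors", "validate_against_reference", "poses_to_tsv",
           "poses_from_tsv", "poses_to_multimodel_pdb"]


@dataclass
class PipelineConfig:
    static: Structure
    mobile: Structure
    dock_params: DockParams = field(default_factory=DockParams)
    constraints: Optional[ConstraintSet] = None
    register_spec: Optional[RegisterFilterSpec] = None
    energy_params: EnergyParams = field(default_factory=EnergyParams)
    ranking_rule: str = "joint"          # joint | energy | asa
    electrostatic_filter: bool = True
    seed: int = 0
    poses: Optional[List[Pose]] = None   # skip docking, filter these instead
    output_dir: Optional[str] = None
    asa_n_points: int = 960

    def __post_init__(self):
        if self.ranking_rule not in ("joint", "energy", "asa"):
            raise ValueError(f"unknown ranking rule {self.ranking_rule!r}")


@dataclass
class SelectionReport:
    stage_counts: Dict[str, int]
    survivors: pd.DataFrame            # pose_id, shape_score, energy, asa
    selected_pose_id: Optional[int]
    rationale: str
    emptying_stage: Optional[str] = None

    def to_json(self) -> str:
        payload = {
            "stage_counts": self.stage_counts,
            "survivors": [
                {"pose_id": int(r.pose_id),
                 "shape_score": int(r.shape_score),
                 "interaction_energy": round(float(r.interaction_energy), 6),
                 "interface_asa": round(float(r.interface_asa), 6)}
                for r in self.survivors.itertuples()],
            "selected_pose_id": (None if self.selected_pose_id is None
                                 else int(self.selected_pose_id)),
            "rationale": self.rationale,
            "emptying_stage": self.emptying_stage,
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def run_pipeline(config: PipelineConfig) -> Tuple[SelectionReport, List[Pose]]:
    """Execute the full selection procedure; returns the report and the final
    survivor poses (ordered as in the report).

    A stage that empties the candidate list is recorded in the report
    (``emptying_stage``) rather than raising.
    """
    static, mobile = config.static, config.mobile
    counts: Dict[str, int] = {}

    if config.poses is not None:
        poses = list(config.poses)
        counts["input"] = len(poses)
    else:
        poses = dock(static, mobile, config.dock_params, seed=config.seed)
        counts["dock"] = len(poses)

    def empty_report(stage: str) -> Tuple[SelectionReport, List[Pose]]:
        return (SelectionReport(counts, _empty_survivors(), None,
                                f"no candidates left after stage {stage!r}",
                                emptying_stage=stage), [])

    if not poses:
        return empty_report("dock")

    if config.electrostatic_filter:
        poses = electrostatic_screen(poses, static, mobile,
                                     config.energy_params.dielectric_factor)
        counts["electrostatic"] = len(poses)
        if not poses:
            return empty_report("electrostatic")

    if config.constraints is not None and len(config.constraints):
        poses, creport = apply_constraints(poses, static, mobile,
                                           config.constraints, mode="staged")
        counts["constraints"] = len(poses)
        if not poses:
            return empty_report("constraints")

    if config.register_spec is not None:
        poses, _ = apply_register_filter(poses, static, mobile,
                                         config.register_spec)
        counts["register"] = len(poses)
        if not poses:
            return empty_report("register")

    rows = []
    for pose in poses:
        placed = apply_pose(mobile, pose)
        e = interaction_energy(static, placed, config.energy_params)
        a = interface_asa(static, placed, n_points=config.asa_n_points)
        rows.append({"pose_id": pose.pose_id, "shape_score": pose.shape_score,
                     "interaction_energy": e, "interface_asa": a})
    table = pd.DataFrame(rows, columns=_SURVIVOR_COLUMNS)
    counts["scored"] = len(table)

    ranked, selected_id, rationale = rank_survivors(table, config.ranking_rule)
    report = SelectionReport(counts, ranked, selected_id, rationale)

    if config.output_dir:
        _write_outputs(config, report, poses)

    id_order = {pid: i for i, pid in enumerate(ranked.pose_id)}
    poses_sorted = sorted(poses, key=lambda p: id_order[p.pose_id])
    return report, poses_sorted


_SURVIVOR_COLUMNS = ["pose_id", "shape_score", "interaction_energy",
                     "interface_asa"]


def _empty_survivors() -> pd.DataFrame:
    return pd.DataFrame(columns=_SURVIVOR_COLUMNS)


def rank_survivors(table: pd.DataFrame, rule: str = "joint"
                   ) -> Tuple[pd.DataFrame, Optional[int], str]:
    """Order the survivor table and pick the selected pose.

    joint: if one pose is maximal both in energy magnitude (most negative
    interaction energy) and in interface area, select it; otherwise select the
    pose with the best (lowest) sum of the two ranks. energy/asa: single-key
    sorts. Ties break toward the lower pose id.
    """
    if table.empty:
        return table.copy(), None, "empty survivor table"
    t = table.copy()
    e_rank = t.interaction_energy.rank(method="min", ascending=True)
    a_rank = t.interface_asa.rank(method="min", ascending=False)
    if rule == "energy":
        t = t.sort_values(["interaction_energy", "pose_id"],
                          ignore_index=True)
        return t, int(t.pose_id.iloc[0]), "energy-only ranking"
    if rule == "asa":
        t = t.sort_values(["interface_asa", "pose_id"],
                          ascending=[False, True], ignore_index=True)
        return t, int(t.pose_id.iloc[0]), "interface-ASA-only ranking"

    t["rank_sum"] = e_rank + a_rank
    t = t.sort_values(["rank_sum", "pose_id"], ignore_index=True)
    best_e = t.interaction_energy.min()
    best_a = t.interface_asa.max()
    dominant = t[(t.interaction_energy == best_e) & (t.interface_asa == best_a)]
    if len(dominant):
        sel = int(dominant.pose_id.min())
        rationale = ("joint ranking: pose maximal in both interaction energy "
                     "magnitude and interface ASA")
    else:
        sel = int(t.pose_id.iloc[0])
        rationale = ("joint ranking fallback: no pose dominates both keys; "
                     "selected best rank-sum")
    t = t.drop(columns=["rank_sum"])
    return t, sel, rationale


def validate_against_reference(poses: Sequence[Pose], static: Structure,
                               mobile: Structure, reference: Structure,
                               atom_name: str = "CA") -> pd.DataFrame:
    """Per-pose RMSD of the posed mobile structure to a reference assembly.

    The reference must contain the static and mobile chains with matching
    (chain, residue, atom) identities. The reference is first superposed onto
    the static part; the table reports the unfitted RMSD of the mobile
    selection plus the paper-style histogram bin (<4.5, 4.5-8, >8 A).
    """
    ref_map = {(reference.chain_id[i], int(reference.residue_number[i]),
                reference.name[i]): i for i in range(reference.n_atoms)}

    def matched(part: Structure, sel_name: str) -> Tuple[np.ndarray, np.ndarray]:
        idx_part, idx_ref = [], []
        for i in range(part.n_atoms):
            if sel_name and part.name[i] != sel_name:
                continue
            key = (part.chain_id[i], int(part.residue_number[i]), part.name[i])
            if key not in ref_map:
                raise ValueError(f"reference lacks atom {key}")
            idx_part.append(i)
            idx_ref.append(ref_map[key])
        if not idx_part:
            raise ValueError("empty selection after matching")
        return np.asarray(idx_part), np.asarray(idx_ref)

    s_part, s_ref = matched(static, atom_name)
    m_part, m_ref = matched(mobile, atom_name)
    # bring the reference into the static frame
    R, t, _ = superpose(reference.positions[s_ref], static.positions[s_part])
    ref_mobile = reference.positions[m_ref] @ R.T + t

    rows = []
    for pose in poses:
        placed = pose.apply(mobile.positions[m_part])
        rmsd = float(np.sqrt(((placed - ref_mobile) ** 2).sum(axis=1).mean()))
        bin_label = ("<4.5" if rmsd < 4.5 else
                     "4.5-8" if rmsd < 8.0 else ">8")
        rows.append({"pose_id": pose.pose_id, "rmsd": rmsd, "bin": bin_label})
    return pd.DataFrame(rows, columns=["pose_id", "rmsd", "bin"])


# ----------------------------------------------------------------- pose I/O
def poses_to_multimodel_pdb(poses: Sequence[Pose], mobile: Structure,
                            path, static: Optional[Structure] = None) -> None:
    """Write placed poses as a multi-model PDB (one MODEL per pose); if
    ``static`` is given each model contains the full assembly."""
    if not poses:
        raise ValueError("no poses to write")
    frames = []
    for pose in poses:
        placed = apply_pose(mobile, pose)
        model = Structure.concat([static, placed]) if static is not None \
            else placed
        frames.append(model.positions)
    template = Structure.concat([static, mobile]) if static is not None \
        else mobile
    save_structure(template.with_coords(np.stack(frames)), path)


def poses_to_tsv(poses: Sequence[Pose], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tpose_id\tshape_score\telec_energy\t" +
                 "\t".join(f"r{i}{j}" for i in range(3) for j in range(3)) +
                 "\ttx\tty\ttz\n")
        for p in poses:
            rot = "\t".join(f"{v:.8f}" for v in p.rotation.reshape(-1))
            trans = "\t".join(f"{v:.6f}" for v in p.translation)
            ee = "" if p.elec_energy is None else f"{p.elec_energy:.6f}"
            fh.write(f"{p.rank}\t{p.pose_id}\t{p.shape_score}\t{ee}\t"
                     f"{rot}\t{trans}\n")


def poses_from_tsv(path) -> List[Pose]:
    df = pd.read_csv(path, sep="\t")
    poses = []
    rot_cols = [f"r{i}{j}" for i in range(3) for j in range(3)]
    for row in df.itertuples():
        R = np.array([getattr(row, c) for c in rot_cols]).reshape(3, 3)
        t = np.array([row.tx, row.ty, row.tz])
        ee = getattr(row, "elec_energy", None)
        ee = None if ee is None or (isinstance(ee, float) and np.isnan(ee)) \
            else float(ee)
        poses.append(Pose(rotation=R, translation=t,
                          shape_score=int(row.shape_score), elec_energy=ee,
                          rank=int(row.rank), pose_id=int(row.pose_id)))
    return poses


def _write_outputs(config: PipelineConfig, report: SelectionReport,
                   poses: Sequence[Pose]) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    poses_to_tsv(poses, os.path.join(out, "surviving.tsv"))
    report.survivors.to_csv(os.path.join(out, "survivors_scored.tsv"),
                            sep="\t", index=False)
    with open(os.path.join(out, "selection.json"), "w") as fh:
        fh.write(report.to_json())
    if report.selected_pose_id is not None:
        sel = next(p for p in poses if p.pose_id == report.selected_pose_id)
        final = Structure.concat([config.static,
                                  apply_pose(config.mobile, sel)])
        save_structure(final, os.path.join(out, "final_model.pdb"))
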