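"""One-shot comparative report and its configuration.

``run_full_report`` orchestrates the whole analysis for a subject structure
against one or more comparison structures: the RMSD decomposition table,
secondary-structure tracks, difference distance matrices with block
summaries, per-chain pocket descriptor panels, the contact report and the
R/T marker panel. All numbers land in a machine-readable ``report.json``
(the source of truth); CSV/TSV/PNG files are views of the same data.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .contacts import (ContactCutoffs, RTMarkerNumbering, ch_pi_contacts,
                       ring_stacking, rt_marker_panel, salt_bridges)
from .ddm import block_summary, difference_matrix, render_ddm
from .errors import ConfigError, HbstateError, StageError, UnitUnavailableError
from .pocket import descriptor_panel, find_hemes
from .secstruct import assign_secondary_structure, comparison_track, helix_segments
from .structure import (build_biological_assembly, guess_subunit_types,
                        parse_structure, resolve_altlocs)
from .superpose import rmsd_units, tetramer_chain_map, tetramer_correspondence
from .survey import survey_structure

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Validated configuration for :func:`run_full_report`."""
    structures: list[str]
    output_dir: str = "hbstate_report"
    assembly: str = "auto"             # auto | none
    correspondence_mode: str = "by_number"
    e7_map: dict[str, int] = field(
        default_factory=lambda: {"alpha": 59, "beta": 63})
    subunit_map: dict[str, dict[str, str]] = field(default_factory=dict)
    contact_cutoffs: dict[str, float] = field(default_factory=dict)
    marker_numbering: dict[str, object] = field(default_factory=dict)
    ddm_clamp: float = 2.0

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if not data.get("structures") or len(data["structures"]) < 2:
            raise ConfigError("config needs at least two structure paths")
        cfg = cls(**data)
        if cfg.assembly not in ("auto", "none"):
            raise ConfigError("assembly must be 'auto' or 'none'")
        if cfg.correspondence_mode not in ("by_number", "by_alignment"):
            raise ConfigError(
                "correspondence_mode must be by_number or by_alignment")
        if cfg.ddm_clamp <= 0:
            raise ConfigError("ddm_clamp must be positive")
        return cfg

    def cutoffs(self) -> ContactCutoffs:
        return ContactCutoffs(**self.contact_cutoffs)

    def numbering(self) -> RTMarkerNumbering:
        data = dict(self.marker_numbering)
        if "helix_c_range" in data:
            data["helix_c_range"] = tuple(data["helix_c_range"])
        return RTMarkerNumbering(**data)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _load(path: str, cfg: AnalysisConfig):
    structure = resolve_altlocs(parse_structure(path))
    sub = cfg.subunit_map.get(path) or cfg.subunit_map.get(
        structure.structure_id)
    if sub:
        for cid, stype in sub.items():
            chain = structure.chain(cid)
            if chain is not None:
                chain.subunit_type = stype
    guess_subunit_types(structure)
    if cfg.assembly == "auto":
        n_protein = sum(1 for c in structure.chains if c.standard_residues())
        if n_protein < 4 and structure.assembly_transforms:
            structure = build_biological_assembly(structure)
            guess_subunit_types(structure)
    return structure


def run_full_report(config: AnalysisConfig | dict) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the report dictionary; raises :class:`StageError` naming the
    first failing stage (after writing whatever was already computed).
    """
    cfg = (config if isinstance(config, AnalysisConfig)
           else AnalysisConfig.from_dict(config))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "hbstate_version": __version__,
        "config": _jsonable(dataclasses.asdict(cfg)),
    }
    stage = "parse"
    try:
        structures = [_load(p, cfg) for p in cfg.structures]
        subject, others = structures[0], structures[1:]
        report["structures"] = [
            {"structure_id": s.structure_id,
             "chains": [{"chain_id": c.chain_id,
                         "subunit_type": c.subunit_type,
                         "n_standard_residues": len(c.standard_residues())}
                        for c in s.chains],
             "n_standard_residues": s.n_standard_residues(),
             "n_waters": s.n_waters()}
            for s in structures]

        stage = "rmsd"
        rmsd_tables = {}
        for other in others:
            try:
                table = rmsd_units(subject, other,
                                   correspondence_mode=cfg.correspondence_mode)
            except UnitUnavailableError:
                table = rmsd_units(subject, other,
                                   units=("alpha_chain", "beta_chain", "dimer"),
                                   correspondence_mode=cfg.correspondence_mode)
            key = f"{subject.structure_id}_vs_{other.structure_id}"
            rmsd_tables[key] = table
            table.to_csv(out / f"rmsd_{key}.csv", index=False)
        report["rmsd"] = {k: v.to_dict(orient="records")
                          for k, v in rmsd_tables.items()}

        stage = "secstruct"
        ss = {}
        for s in structures:
            for chain in s.chains:
                if len(chain.standard_residues()) < 5:
                    continue
                assign = assign_secondary_structure(chain, s.structure_id)
                ss[(s.structure_id, chain.chain_id)] = assign
        report["secondary_structure"] = {
            f"{sid}/{cid}": {"codes": a.codes,
                             "segments": helix_segments(a)}
            for (sid, cid), a in ss.items()}
        tracks = []
        for other in others:
            for ca in subject.chains:
                key_a = (subject.structure_id, ca.chain_id)
                for cb in other.chains:
                    key_b = (other.structure_id, cb.chain_id)
                    if (key_a in ss and key_b in ss
                            and ca.subunit_type == cb.subunit_type):
                        tracks.append(
                            f"{key_a[0]}/{ca.chain_id} vs "
                            f"{key_b[0]}/{cb.chain_id}\n"
                            + comparison_track(ss[key_a], ss[key_b]))
                        break
        (out / "secstruct_tracks.txt").write_text("\n\n".join(tracks))

        stage = "ddm"
        report["ddm_blocks"] = {}
        for other in others:
            key = f"{subject.structure_id}_vs_{other.structure_id}"
            try:
                corr, map_a, _ = tetramer_correspondence(
                    subject, other, cfg.correspondence_mode)
            except UnitUnavailableError as exc:
                logger.info("ddm %s skipped: %s", key, exc)
                continue
            labels = {v: k for k, v in map_a.items()}
            ddm = difference_matrix(subject, other, corr, chain_labels=labels)
            render_ddm(ddm, clamp=(-cfg.ddm_clamp, cfg.ddm_clamp),
                       out_path=out / f"ddm_{key}.png",
                       csv_path=out / f"ddm_{key}.csv")
            blocks = block_summary(ddm)
            blocks.to_csv(out / f"ddm_blocks_{key}.tsv", sep="\t",
                          index=False)
            report["ddm_blocks"][key] = blocks.to_dict(orient="records")

        stage = "pocket"
        pockets = {}
        for s in structures:
            for heme in find_hemes(s):
                chain = s.chain(heme.owner_chain_id)
                e7 = cfg.e7_map.get(chain.subunit_type)
                try:
                    panel = descriptor_panel(chain, heme, e7=e7)
                except HbstateError as exc:
                    logger.warning("pocket %s/%s: %s", s.structure_id,
                                   chain.chain_id, exc)
                    continue
                pockets[f"{s.structure_id}/{chain.chain_id}"] = panel
        report["pocket"] = {k: _jsonable(v) for k, v in pockets.items()}
        report["survey"] = [
            _jsonable(r) for s in structures
            for r in survey_structure(s, cfg.e7_map)]

        stage = "contacts"
        cutoffs = cfg.cutoffs()
        report["contacts"] = {}
        for s in structures:
            recs = (salt_bridges(s, cutoffs=cutoffs)
                    + ch_pi_contacts(s, cutoffs=cutoffs)
                    + ring_stacking(s, cutoffs=cutoffs))
            report["contacts"][s.structure_id] = [_jsonable(r) for r in recs]
        report["rt_markers"] = {}
        for s in structures:
            try:
                chain_map = tetramer_chain_map(s)
            except UnitUnavailableError:
                continue
            panel = rt_marker_panel(s, chain_map,
                                    numbering=cfg.numbering())
            report["rt_markers"][s.structure_id] = _jsonable(panel)

        stage = "write"
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True))
    except HbstateError as exc:
        # persist the partial bundle before surfacing the failing stage
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True))
        raise StageError(stage, str(exc)) from exc
    return report
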