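"""Batch Fe - NE2(distal His) survey over hemoglobin chains.

For every chain with a heme in a user-provided list of coordinate files the
survey records the distance between the heme iron and the NE2 atom of the
distal (E7) histidine and classifies the coordination state:

* ``bis_histidyl``   — distal His coordinates the iron (<= 3.0 A);
* ``canonical_distal`` — His in the normal distal pocket (3.0, 6.0] A;
* ``displaced``      — side chain swung out of the pocket (> 6.0 A);
* ``unclassified``   — distance not measurable.

The class boundaries operationalise the green/blue populations seen in
Fe-NE2 distance distributions; both are config-exposed. Structure
selection is the caller's responsibility: the survey consumes a frozen
file list so results are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HbstateError
from .pocket import descriptor_panel, find_hemes, identify_proximal_his
from .structure import Structure, guess_subunit_types, parse_structure, resolve_altlocs

logger = logging.getLogger(__name__)

BIS_HISTIDYL_MAX = 3.0    # A
CANONICAL_MAX = 6.0       # A


@dataclass
class SurveyRecord:
    structure_id: str
    chain_id: str
    subunit_type: str
    fe_ne2_distance: float | None
    coordination_class: str


def classify_coordination(distance: float | None,
                          bis_max: float = BIS_HISTIDYL_MAX,
                          canonical_max: float = CANONICAL_MAX) -> str:
    """Total, monotone step classification of the Fe-NE2 distance."""
    if distance is None:
        return "unclassified"
    if distance < 0:
        raise ValueError(f"negative Fe-NE2 distance: {distance}")
    if distance <= bis_max:
        return "bis_histidyl"
    if distance <= canonical_max:
        return "canonical_distal"
    return "displaced"


def survey_structure(structure: Structure,
                     e7_config: dict[str, int] | None = None
                     ) -> list[SurveyRecord]:
    """One record per chain with a heme; failures record as unclassified."""
    guess_subunit_types(structure)
    records = []
    try:
        hemes = find_hemes(structure)
    except HbstateError as exc:
        logger.warning("%s: %s", structure.structure_id, exc)
        return []
    for heme in hemes:
        chain = structure.chain(heme.owner_chain_id)
        e7 = (e7_config or {}).get(chain.subunit_type)
        try:
            panel = descriptor_panel(chain, heme, e7=e7)
            d = panel.fe_ne2_distal
        except HbstateError as exc:
            logger.warning("%s/%s: %s", structure.structure_id,
                           chain.chain_id, exc)
            d = None
        records.append(SurveyRecord(
            structure_id=structure.structure_id,
            chain_id=chain.chain_id,
            subunit_type=chain.subunit_type,
            fe_ne2_distance=d,
            coordination_class=classify_coordination(d)))
    return records


def run_survey(file_list, e7_config: dict[str, int] | None = None
               ) -> list[SurveyRecord]:
    """Survey every file in ``file_list``.

    Unparseable or heme-free files are logged and skipped; the batch never
    aborts on a single bad entry. Output is sorted by (structure_id,
    chain_id) regardless of input order.
    """
    files = list(file_list)
    if not files:
        raise ValueError("empty survey file list")
    records: list[SurveyRecord] = []
    for path in files:
        try:
            structure = resolve_altlocs(parse_structure(path))
        except HbstateError as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        recs = survey_structure(structure, e7_config)
        if not recs:
            logger.info("no heme in %s; skipped", path)
        records.extend(recs)
    records.sort(key=lambda r: (r.structure_id, r.chain_id))
    return records


def records_frame(records: list[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def histogram(records: list[SurveyRecord], bin_width: float = 0.5,
              plot_path=None):
    """Distance histogram with fixed bin origin at 0.

    Returns (bin_edges, counts); counts sum to the number of records with a
    measured distance.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    distances = [r.fe_ne2_distance for r in records
                 if r.fe_ne2_distance is not None]
    if not distances:
        raise ValueError("no records with a measured distance")
    top = max(distances)
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=bin_width, align="edge",
               edgecolor="k")
        ax.set_xlabel(r"Fe - NE2(distal His) distance ($\AA$)")
        ax.set_ylabel("chains")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return edges, counts
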