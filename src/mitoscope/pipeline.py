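"""End-to-end per-object analysis of one segmented field of view."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mitoscope.biomarker import bound_fraction
from mitoscope.imaging import ImageFrame, LabeledMask
from mitoscope.morphometry import compute_region_features
from mitoscope.morphotype import Morphotype, classify_morphotype
from mitoscope.topology import build_skeleton_graph, skeletonize, topology_summary


def analyze_objects(
    mask: LabeledMask,
    frame: ImageFrame | None = None,
    biomarker_kind: str = "viscosity",
) -> pd.DataFrame:
    """Morphometry, topology, and morphotype for every labeled object.

    When an intensity frame is supplied, the biomarker bound fraction is
    appended.  Returns one row per object keyed by ``object_id``.
    """
    rows = []
    for label in range(1, mask.n_objects + 1):
        obj = mask.object_mask(label)
        graph = build_skeleton_graph(skeletonize(obj), label)
        topo = topology_summary(graph)
        feats = compute_region_features(obj, topo.total_length_px, label)
        mtype = classify_morphotype(feats, topo)
        row = {"object_id": label}
        row.update(feats.as_dict())
        row.update(
            {
                "endpoints": topo.endpoints,
                "junctions": topo.junctions,
                "loops": topo.loops,
                "branch_count": topo.branch_count,
                "mean_branch_length_px": topo.mean_branch_length_px,
                "mean_branch_angle_deg": topo.mean_branch_angle_deg,
                "total_length_px": topo.total_length_px,
                "morphotype": mtype.kind,
                "rule_gap": mtype.rule_gap,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if frame is not None and len(table):
        measurements = bound_fraction(mask, frame, kind=biomarker_kind)
        table[f"{biomarker_kind.lower()}_fraction"] = [m.fraction for m in measurements]
    return table


def morphotypes_from_table(table: pd.DataFrame) -> list[Morphotype]:
    return [
        Morphotype(int(r.object_id), r.morphotype, bool(r.rule_gap))
        for r in table.itertuples()
    ]
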