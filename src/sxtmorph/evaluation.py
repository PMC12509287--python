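"""Segmentation scoring, refinement selection and quality-control filters.

Scores are voxel-wise: per-label F1 (Dice overlap) and RelVol (predicted
over target volume).  ``flag_for_refinement`` drives the human-in-the-loop
iterative refinement: it returns the worst-scoring cells first so they can
be corrected and added to the next training round.  ``qc_filter`` applies
the post-segmentation cleanup used before morphometrics: internal hole
filling, removal of spurious components below per-organelle volume
thresholds (0.3 µm³ vacuole, 0.4 µm³ nucleus, 0.02 µm³ lipid droplet), and
removal of cells clipped by the volume boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LABEL_IDS, LabeledVolume

#: 26-connectivity for component analysis.
CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Minimum retained component volume (µm³) per organelle label.
QC_MIN_VOLUME_UM3 = {
    LABEL_IDS["vacuole"]: 0.3,
    LABEL_IDS["nucleus"]: 0.4,
    LABEL_IDS["lipid_droplet"]: 0.02,
}


@dataclass
class EvalRecord:
    """Per-cell, per-iteration segmentation scores."""

    cell_id: int
    iteration: int
    f1: dict[int, float | None]
    rel_vol: dict[int, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def f1_per_label(pred: LabeledVolume, target: LabeledVolume,
                 labels: list[int] | None = None) -> dict[int, float | None]:
    """Voxel F1 (= Dice) per label: 2|P∩T| / (|P|+|T|).

    A label absent from both volumes is reported as ``None`` (undefined),
    not 0.  Background (label 0) is skipped unless explicitly requested.
    """
    if pred.shape != target.shape:
        raise ValueError("prediction and target grids differ in shape")
    if labels is None:
        labels = sorted(set(target.label_dictionary) - {0})
    scores: dict[int, float | None] = {}
    for label in labels:
        p = pred.data == label
        t = target.data == label
        denom = int(p.sum()) + int(t.sum())
        if denom == 0:
            scores[label] = None
        else:
            scores[label] = 2.0 * int((p & t).sum()) / denom
    return scores


def rel_vol(pred: LabeledVolume, target: LabeledVolume, label: int) -> float:
    """|P| / |T| for one label; errors when the target label is empty."""
    if pred.shape != target.shape:
        raise ValueError("prediction and target grids differ in shape")
    n_target = int((target.data == label).sum())
    if n_target == 0:
        raise ValueError(f"target label {label} is empty; RelVol undefined")
    return int((pred.data == label).sum()) / n_target


def flag_for_refinement(records: list[EvalRecord],
                        f1_threshold: float = 0.8,
                        rel_vol_band: float | None = None) -> list[int]:
    """Cell ids needing manual refinement, worst first.

    A cell is flagged when any defined per-label F1 falls below
    ``f1_threshold`` or, if ``rel_vol_band`` is set, when any |RelVol − 1|
    exceeds it.  Ordering is by ascending minimum per-label F1 with ties
    broken by cell id.
    """
    flagged: list[tuple[float, int]] = []
    for rec in records:
        defined = [v for v in rec.f1.values() if v is not None]
        min_f1 = min(defined) if defined else 1.0
        bad = min_f1 < f1_threshold
        if rel_vol_band is not None:
            bad = bad or any(abs(rv - 1.0) > rel_vol_band
                             for rv in rec.rel_vol.values())
        if bad:
            flagged.append((min_f1, rec.cell_id))
    flagged.sort()
    return [cell_id for _f1, cell_id in flagged]


def _fill_label_holes(data: np.ndarray, label: int) -> int:
    """Fill internal cavities of one label, claiming only background voxels."""
    mask = data == label
    if not mask.any():
        return 0
    filled = ndimage.binary_fill_holes(mask)
    gained = filled & ~mask & (data == 0)
    data[gained] = label
    return int(gained.sum())


def qc_filter(labeled: LabeledVolume,
              min_volumes_um3: dict[int, float] | None = None,
              drop_boundary_cells: bool = True,
              ) -> tuple[LabeledVolume, dict]:
    """Clean a semantic segmentation; returns (cleaned volume, report).

    Steps, in order: fill internal holes per label; remove 26-connected
    components below the per-label volume thresholds; drop whole cells
    (connected components of the foreground) that touch the volume
    boundary.  Idempotent: applying twice equals applying once.
    """
    thresholds = dict(QC_MIN_VOLUME_UM3 if min_volumes_um3 is None
                      else min_volumes_um3)
    data = labeled.data.copy()
    voxel3 = labeled.voxel_um ** 3
    report = {"holes_filled_voxels": {}, "removed_small_components": {},
              "removed_boundary_cells": 0}

    for label in sorted(set(np.unique(data)) - {0}):
        report["holes_filled_voxels"][int(label)] = \
            _fill_label_holes(data, label)

    for label, min_vol in sorted(thresholds.items()):
        mask = data == label
        if not mask.any():
            report["removed_small_components"][int(label)] = 0
            continue
        comp, n = ndimage.label(mask, structure=CONN26)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1))
        removed = 0
        for idx, size in enumerate(sizes, start=1):
            if size * voxel3 < min_vol:
                comp_mask = comp == idx
                # reassign to the dominant surrounding label (cytosol for a
                # speck inside a cell, background outside) so no new internal
                # cavity is created and the filter stays idempotent
                ring = ndimage.binary_dilation(comp_mask, structure=CONN26) \
                    & ~comp_mask
                surrounding = data[ring]
                surrounding = surrounding[surrounding != label]
                fill_value = 0
                if surrounding.size:
                    values, counts = np.unique(surrounding,
                                               return_counts=True)
                    fill_value = int(values[np.argmax(counts)])
                data[comp_mask] = fill_value
                removed += 1
        report["removed_small_components"][int(label)] = removed

    if drop_boundary_cells:
        fg = data > 0
        comp, n = ndimage.label(fg, structure=CONN26)
        boundary_ids = set()
        for axis in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                boundary_ids |= set(np.unique(comp[tuple(sl)]).tolist())
        boundary_ids.discard(0)
        for idx in boundary_ids:
            data[comp == idx] = 0
        report["removed_boundary_cells"] = len(boundary_ids)

    return (LabeledVolume(data, labeled.voxel_um,
                          label_dictionary=labeled.label_dictionary,
                          origin=labeled.origin), report)
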