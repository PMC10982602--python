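"""Atlas-ROI mean z-scores and the piecewise MSA/PSP diagnostic index.

The index compares the most atrophic PSP-typical region (midbrain, higher
side) against the most atrophic MSA-typical region (putamen or middle
cerebellar peduncle, highest of the four):

    Z_psp = max(midbrain left, midbrain right)
    Z_msa = max(putamen left/right, MCP left/right)

    Index = Z_psp   if Z_psp > 0 and Z_psp >= Z_msa
          = -Z_msa  if Z_msa > 0 and Z_psp < Z_msa
          = 0       if Z_psp <= 0 and Z_msa <= 0

Positive values point toward PSP (midbrain-dominant atrophy), negative
toward MSA (putamen/MCP-dominant atrophy). ROI means are taken from the
unthresholded z-maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ROI_TABLE_COLUMNS, INDEX_TABLE_COLUMNS, RoiAtlas
from .normative import ZMap

logger = logging.getLogger(__name__)

PSP_SIDE = "PSP_SIDE"
MSA_SIDE = "MSA_SIDE"
ZERO = "ZERO"

#: Operating cutoffs on the index scale: MSA is called at or below the MSA
#: cutoff, PSP at or above the PSP cutoff.
DEFAULT_MSA_CUTOFF = -1.43
DEFAULT_PSP_CUTOFF = 1.14

#: Substrings used to recognize the index's structure groups in ROI names
#: (case-insensitive), accommodating both the synthetic atlas and common
#: anatomical atlas naming.
_MIDBRAIN_PATTERNS = ("midbrain",)
_PUTAMEN_PATTERNS = ("putamen",)
_MCP_PATTERNS = ("mcp", "middle cerebellar", "middle_cerebellar")


@dataclass
class IndexResult:
    """Per-subject index: Z_psp, Z_msa, the signed index, and its branch."""

    subject_id: str
    z_psp: float
    z_msa: float
    index: float
    branch: str


@dataclass
class CutoffRule:
    """A one-disease decision rule on the index scale.

    The direction is fixed by the disease: MSA is predicted when
    ``index <= cutoff`` (atrophy dominance in putamen/MCP drives the index
    negative), PSP when ``index >= cutoff``.
    """

    disease: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.disease not in ("MSA", "PSP"):
            raise ValueError("disease must be 'MSA' or 'PSP'")

    def predict(self, index: float) -> bool:
        if self.disease == "MSA":
            return index <= self.cutoff
        return index >= self.cutoff


def extract_roi_z(
    zmap: ZMap,
    atlas: RoiAtlas,
    roi_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean z per ROI over voxels inside both the ROI and the z-map mask.

    Returns one row per ROI with columns
    ``(subject_id, roi_name, compartment, mean_z, n_voxels)``. An ROI that
    falls entirely outside the mask is reported with ``n_voxels = 0`` and
    ``mean_z = NaN`` (flagged missing, not zero). Requesting an ROI whose
    compartment differs from the z-map's raises.
    """
    if atlas.labels.shape != zmap.z.shape:
        raise ValueError("atlas grid does not match z-map grid")
    if roi_names is None:
        roi_names = [
            name for name, comp in atlas.lookup.values()
            if zmap.compartment is None or comp == zmap.compartment
        ]
    rows = []
    for name in roi_names:
        comp = atlas.compartment_of(name)  # raises KeyError for unknown names
        if zmap.compartment is not None and comp != zmap.compartment:
            raise ValueError(
                f"compartment mismatch: ROI {name!r} is {comp}, z-map is {zmap.compartment}"
            )
        sel = atlas.roi_mask(name) & zmap.mask
        n = int(sel.sum())
        mean_z = float(zmap.z[sel].mean()) if n else math.nan
        rows.append(
            {"subject_id": zmap.subject_id, "roi_name": name, "compartment": comp,
             "mean_z": mean_z, "n_voxels": n}
        )
    return pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS))


def _match(name: str, patterns: Iterable[str]) -> bool:
    low = name.lower()
    return any(p in low for p in patterns)


def _group_max(table: pd.DataFrame, patterns: Iterable[str], what: str) -> float:
    rows = table[[_match(n, patterns) for n in table["roi_name"]]]
    if rows.empty:
        raise ValueError(f"no {what} ROI rows in table")
    vals = rows["mean_z"].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError(f"all {what} ROI rows are missing (outside the mask)")
    if finite.size < vals.size:
        logger.warning(
            "%d of %d %s ROI(s) missing; taking the max over available sides",
            vals.size - finite.size, vals.size, what,
        )
    return float(finite.max())


def compute_index(roi_table: pd.DataFrame, subject_id: str | None = None) -> IndexResult:
    """Evaluate the piecewise index from one subject's ROI z-table.

    ``Z_psp`` is the larger midbrain-side mean z; ``Z_msa`` the largest of
    the putamen and MCP sides. Rows with missing (NaN) means are skipped
    with a warning as long as at least one side per structure group remains.
    A tie ``Z_psp = Z_msa > 0`` resolves to the PSP branch.
    """
    table = roi_table
    if subject_id is not None:
        table = table[table["subject_id"] == subject_id]
    sids = set(table["subject_id"])
    if len(sids) != 1:
        raise ValueError(f"roi_table must contain exactly one subject, got {sorted(sids)}")
    sid = sids.pop()

    z_psp = _group_max(table, _MIDBRAIN_PATTERNS, "midbrain")
    msa_rows = table[
        [_match(n, _PUTAMEN_PATTERNS) or _match(n, _MCP_PATTERNS) for n in table["roi_name"]]
    ]
    z_msa = _group_max(msa_rows, _PUTAMEN_PATTERNS + _MCP_PATTERNS, "putamen/MCP")

    if z_psp > 0 and z_psp >= z_msa:
        index, branch = z_psp, PSP_SIDE
    elif z_msa > 0 and z_psp < z_msa:
        index, branch = -z_msa, MSA_SIDE
    else:
        index, branch = 0.0, ZERO
    return IndexResult(str(sid), z_psp, z_msa, index, branch)


def compute_indices(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject index table with columns (subject_id, z_psp, z_msa, index, branch)."""
    rows = []
    for sid, sub in roi_table.groupby("subject_id", sort=True):
        res = compute_index(sub)
        rows.append(
            {"subject_id": res.subject_id, "z_psp": res.z_psp, "z_msa": res.z_msa,
             "index": res.index, "branch": res.branch}
        )
    return pd.DataFrame(rows, columns=list(INDEX_TABLE_COLUMNS))


def classify(result: IndexResult | float, rule: CutoffRule) -> str:
    """Apply a cutoff rule to an index; returns the disease name or ``"others"``."""
    index = result.index if isinstance(result, IndexResult) else float(result)
    return rule.disease if rule.predict(index) else "others"
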