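"""End-to-end glue: simulate a study, fit references, score and evaluate.

These helpers chain the lower-level modules in the standard order —
(optional smoothing) -> compartment masks -> normative GLM per compartment
-> z-maps -> ROI means -> index -> ROC/LOOCV evaluation — and are what the
command-line interface and the worked examples call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GM, WM, CovariateRecord, RoiAtlas, VolumeImage, compartment_mask, smooth_gaussian
from .normative import NormativeDB, ZMap, fit_reference, z_transform
from .scoring import DEFAULT_MSA_CUTOFF, DEFAULT_PSP_CUTOFF, compute_indices, extract_roi_z
from .simulate import SimulationConfig, make_atlas, simulate_cohort
from .stats import evaluate_index

INDEX_ROIS = {
    GM: ("putamen_l", "putamen_r"),
    WM: ("midbrain_l", "midbrain_r", "mcp_l", "mcp_r"),
}


@dataclass
class SyntheticStudy:
    """A simulated cohort: atlas, covariates and per-subject GM/WM images."""

    config: SimulationConfig
    atlas: RoiAtlas
    records: list[CovariateRecord]
    images: dict[str, dict[str, VolumeImage]]

    def subjects(self, groups: tuple[str, ...] | None = None) -> list[CovariateRecord]:
        if groups is None:
            return list(self.records)
        return [r for r in self.records if r.group in groups]


def simulate_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    cfg = cfg or SimulationConfig()
    from .simulate import default_atlas_spec

    atlas = make_atlas(default_atlas_spec(cfg.grid_shape))
    records, images = simulate_cohort(cfg, atlas)
    return SyntheticStudy(cfg, atlas, records, images)


def fit_references(
    study: SyntheticStudy,
    mask_threshold: float = 0.1,
    smooth_fwhm: float = 0.0,
) -> dict[str, NormativeDB]:
    """Fit one normative database per compartment on the study's HC subjects.

    ``smooth_fwhm`` applies Gaussian smoothing (mm FWHM) before masking and
    fitting; the synthetic default is 0 because generated noise is already
    voxel-independent.
    """
    hcs = study.subjects(("HC",))
    if not hcs:
        raise ValueError("study contains no healthy controls")
    dbs: dict[str, NormativeDB] = {}
    for comp in (GM, WM):
        imgs = {r.subject_id: study.images[r.subject_id][comp] for r in hcs}
        if smooth_fwhm > 0:
            imgs = {sid: smooth_gaussian(im, smooth_fwhm) for sid, im in imgs.items()}
        mask = compartment_mask(list(imgs.values()), mask_threshold)
        dbs[comp] = fit_reference(imgs, hcs, mask)
    return dbs


def score_subjects(
    study: SyntheticStudy,
    dbs: dict[str, NormativeDB],
    records: list[CovariateRecord] | None = None,
    smooth_fwhm: float = 0.0,
    roi_names: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-transform subjects, extract index ROIs and compute indices.

    Returns ``(roi_table, index_table)`` over the given records (default:
    all non-HC subjects).
    """
    if records is None:
        records = study.subjects(("PD", "MSA", "PSP"))
    roi_names = roi_names or INDEX_ROIS
    tables = []
    for rec in records:
        for comp in (GM, WM):
            img = study.images[rec.subject_id][comp]
            if smooth_fwhm > 0:
                img = smooth_gaussian(img, smooth_fwhm)
            zmap = z_transform(img, rec, dbs[comp])
            tables.append(extract_roi_z(zmap, study.atlas, roi_names[comp]))
    roi_table = pd.concat(tables, ignore_index=True)
    index_table = compute_indices(roi_table)
    return roi_table, index_table


def evaluate_study(
    index_table: pd.DataFrame,
    records: list[CovariateRecord],
    ci_level: float = 0.95,
    loocv: bool = True,
) -> dict:
    """MSA-vs-others and PSP-vs-others evaluation of an index table."""
    truth = {r.subject_id: r.group for r in records}
    merged = index_table.assign(group=[truth[s] for s in index_table["subject_id"]])
    scores = merged["index"].to_numpy(dtype=float)
    out = {}
    for disease, direction in (("MSA", "less"), ("PSP", "greater")):
        is_disease = (merged["group"] == disease).to_numpy()
        out[disease] = evaluate_index(scores, is_disease, direction, ci_level, loocv)
    return out


def hc_calibration(
    n_reference: int = 200,
    n_test: int = 50,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    z_threshold: float = 2.0,
) -> dict:
    """Held-out healthy-control calibration of the normative z-maps.

    Simulates ``n_reference + n_test`` healthy controls, fits GM and WM
    references on the first ``n_reference`` and z-transforms the held-out
    rest. Reports the per-subject fraction of masked voxels with
    ``z > z_threshold`` (pooled over both compartments) and the pooled z
    sample itself for distributional checks.
    """
    cfg = SimulationConfig(
        grid_shape=grid_shape,
        n_per_group={"HC": n_reference + n_test},
        seed=seed,
    )
    study = simulate_study(cfg)
    hcs = study.subjects(("HC",))
    ref, held = hcs[:n_reference], hcs[n_reference:]

    dbs: dict[str, NormativeDB] = {}
    for comp in (GM, WM):
        imgs = {r.subject_id: study.images[r.subject_id][comp] for r in ref}
        mask = compartment_mask(list(imgs.values()))
        dbs[comp] = fit_reference(imgs, ref, mask)

    fractions = []
    pooled = []
    for rec in held:
        n_above = 0
        n_masked = 0
        for comp in (GM, WM):
            zmap = z_transform(study.images[rec.subject_id][comp], rec, dbs[comp])
            zs = zmap.z[zmap.mask]
            n_above += int((zs > z_threshold).sum())
            n_masked += zs.size
            pooled.append(zs)
        fractions.append(n_above / n_masked)
    pooled_z = np.concatenate(pooled)
    return {
        "tail_fractions": np.asarray(fractions),
        "mean_tail_fraction": float(np.mean(fractions)),
        "pooled_z": pooled_z,
        "dbs": dbs,
        "n_reference": n_reference,
        "n_test": n_test,
    }
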