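"""Volumetric image, atlas and covariate-table I/O plus masking and smoothing.

All images taking part in one analysis are assumed to live on a single common
grid (spatial normalization is upstream of this package). Volumes are
NIfTI-1 (``.nii``/``.nii.gz``), tables are tab-separated UTF-8 with a header
row, and evaluation summaries are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

GM = "GM"
WM = "WM"
COMPARTMENTS = (GM, WM)
GROUPS = ("HC", "PD", "MSA", "PSP")
SUBTYPES = ("MSA-P", "MSA-C", "PSP-RS", "PSP-P")

#: Numeric sex codes used in design matrices; the mapping is recorded in
#: model metadata so it travels with any serialized reference database.
SEX_ENCODING = {"F": 0, "M": 1}

#: FWHM -> Gaussian sigma conversion factor, 1 / (2 * sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

ROI_TABLE_COLUMNS = ("subject_id", "roi_name", "compartment", "mean_z", "n_voxels")
INDEX_TABLE_COLUMNS = ("subject_id", "z_psp", "z_msa", "index", "branch")
COVARIATE_COLUMNS = ("subject_id", "age", "sex", "tiv", "group")


@dataclass
class VolumeImage:
    """A 3-D tissue-volume map (modulated density, unitless) on a regular grid.

    Parameters
    ----------
    data
        3-D array of finite voxel values.
    voxel_size
        Edge length of a voxel per axis, in mm.
    compartment
        ``"GM"`` or ``"WM"`` when known, else ``None``.
    space_tag
        Free-text label of the reference space (e.g. ``"MNI"``, ``"synthetic"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    compartment: str | None = None
    space_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValueError("all image dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite voxel values")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """Scaling-only NIfTI affine (voxel indices are 0-based)."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """New image on the same grid with replaced voxel data."""
        return VolumeImage(data, self.voxel_size, self.compartment, self.space_tag)


@dataclass
class CovariateRecord:
    """One subject's covariates for the normative design: age, sex, TIV."""

    subject_id: str
    age: float
    sex: int
    tiv: float
    group: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        self.age = float(self.age)
        self.tiv = float(self.tiv)
        self.sex = int(self.sex)
        if self.age <= 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0, got {self.age}")
        if self.tiv <= 0:
            raise ValueError(f"subject {self.subject_id}: tiv must be > 0, got {self.tiv}")
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: sex must be coded 0/1")
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.subject_id}: unknown group {self.group!r}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"subject {self.subject_id}: unknown subtype {self.subtype!r}")


@dataclass
class RoiAtlas:
    """Integer label image (0 = background) with a label lookup.

    ``lookup`` maps each nonzero label to ``(roi_name, compartment)``.
    """

    labels: np.ndarray
    lookup: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label image must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels present in grid but absent from lookup: {sorted(missing)}")
        for lab, (name, comp) in self.lookup.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"ROI {name!r}: compartment must be one of {COMPARTMENTS}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.lookup.values()]

    def label_of(self, roi_name: str) -> int:
        for lab, (name, _) in self.lookup.items():
            if name == roi_name:
                return lab
        raise KeyError(f"unknown ROI name {roi_name!r}")

    def compartment_of(self, roi_name: str) -> str:
        return self.lookup[self.label_of(roi_name)][1]

    def roi_mask(self, roi_name: str) -> np.ndarray:
        return self.labels == self.label_of(roi_name)


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(
    path: str | Path,
    compartment: str | None = None,
    space_tag: str = "unknown",
) -> VolumeImage:
    """Read a 3-D NIfTI volume; voxel sizes come from the header.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for a
    non-3-D image or non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D: {path}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data, voxel_size, compartment, space_tag)


def write_volume(img: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a scaling-only affine."""
    path = Path(path)
    nii = nib.Nifti1Image(np.asarray(img.data, dtype=np.float64), img.affine)
    nii.header.set_zooms(img.voxel_size)
    nib.save(nii, str(path))
    return path


def read_atlas(label_path: str | Path, lookup_path: str | Path) -> RoiAtlas:
    """Read an atlas label NIfTI plus a TSV lookup (label, roi_name, compartment)."""
    label_path = Path(label_path)
    if not label_path.exists():
        raise FileNotFoundError(f"atlas not found: {label_path}")
    img = nib.load(str(label_path))
    labels = np.asarray(img.get_fdata())
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("atlas label image contains non-integer values")
    labels = np.round(labels).astype(np.int32)
    table = pd.read_csv(lookup_path, sep="\t")
    required = {"label", "roi_name", "compartment"}
    if not required.issubset(table.columns):
        raise ValueError(f"atlas lookup must have columns {sorted(required)}")
    lookup = {
        int(row.label): (str(row.roi_name), str(row.compartment))
        for row in table.itertuples()
    }
    return RoiAtlas(labels, lookup)


def write_atlas(atlas: RoiAtlas, label_path: str | Path, lookup_path: str | Path,
                voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)) -> None:
    aff = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), aff), str(label_path))
    rows = [
        {"label": lab, "roi_name": name, "compartment": comp}
        for lab, (name, comp) in sorted(atlas.lookup.items())
    ]
    pd.DataFrame(rows).to_csv(lookup_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Covariate tables


def read_covariates(path: str | Path) -> list[CovariateRecord]:
    """Read a covariate TSV with columns subject_id, age, sex, tiv, group.

    ``sex`` may be 0/1 codes or F/M letters; an optional ``subtype`` column
    is carried through. Duplicate subject ids and non-numeric age/tiv raise.
    """
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table missing column(s): {missing}")
    dup = table["subject_id"][table["subject_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))}")
    records = []
    for row in table.itertuples():
        for col in ("age", "tiv"):
            val = getattr(row, col)
            try:
                float(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"subject {row.subject_id}: non-numeric {col} value {val!r}"
                ) from None
        sex = row.sex
        if isinstance(sex, str) and sex.upper() in SEX_ENCODING:
            sex = SEX_ENCODING[sex.upper()]
        subtype = getattr(row, "subtype", None)
        if subtype is not None and (pd.isna(subtype) or subtype == ""):
            subtype = None
        records.append(
            CovariateRecord(row.subject_id, float(row.age), int(sex),
                            float(row.tiv), str(row.group), subtype)
        )
    return records


def write_covariates(records: Sequence[CovariateRecord], path: str | Path) -> Path:
    rows = [
        {"subject_id": r.subject_id, "age": r.age, "sex": r.sex, "tiv": r.tiv,
         "group": r.group, "subtype": r.subtype if r.subtype is not None else ""}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS) + ["subtype"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


# ---------------------------------------------------------------------------
# Smoothing and masking


def smooth_gaussian(img: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """3-D Gaussian smoothing with the given full-width-at-half-maximum in mm.

    The kernel sigma per axis is ``fwhm * FWHM_TO_SIGMA / voxel_size``;
    boundaries are zero-padded, matching modulated-density semantics outside
    the head. ``fwhm_mm = 0`` is the identity.
    """
    fwhm = float(fwhm_mm)
    if fwhm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return img.with_data(img.data.copy())
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in img.voxel_size]
    smoothed = ndimage.gaussian_filter(img.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return img.with_data(smoothed)


def compartment_mask(
    hc_images: Sequence[VolumeImage],
    threshold: float = 0.1,
) -> np.ndarray:
    """Analysis mask from healthy-control images of one compartment.

    A voxel is kept iff the HC mean value is at least ``threshold`` (an
    absolute density floor excluding non-tissue regions) and the HC variance
    is strictly positive (a z-score is undefined where controls do not vary).
    """
    if len(hc_images) == 0:
        raise ValueError("compartment_mask requires at least one image")
    if len(hc_images) < 2:
        raise ValueError("compartment_mask requires >= 2 reference images")
    shapes = {im.shape for im in hc_images}
    if len(shapes) > 1:
        raise ValueError(f"images have inconsistent shapes: {shapes}")
    stack = np.stack([im.data for im in hc_images], axis=0)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0)
    return (mean >= float(threshold)) & (var > 0)


# ---------------------------------------------------------------------------
# Evaluation reports


def empty_roi_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(ROI_TABLE_COLUMNS))


def empty_index_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(INDEX_TABLE_COLUMNS))


def write_report(
    path: str | Path,
    *,
    roi_table: pd.DataFrame | None = None,
    index_table: pd.DataFrame | None = None,
    contingency: Mapping | None = None,
    roc_summary: Mapping | None = None,
    volumes: Mapping[str, VolumeImage] | None = None,
) -> dict[str, Path]:
    """Write evaluation outputs under a directory.

    ROI z-tables and index tables go to TSV, contingency/ROC summaries to
    JSON, and any named volumes (e.g. thresholded z-maps) to NIfTI. Returns
    a mapping of output kind to written path.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if roi_table is not None:
        p = outdir / "roi_z_table.tsv"
        roi_table.reindex(columns=list(ROI_TABLE_COLUMNS)).to_csv(p, sep="\t", index=False)
        written["roi_table"] = p
    if index_table is not None:
        p = outdir / "index_table.tsv"
        index_table.reindex(columns=list(INDEX_TABLE_COLUMNS)).to_csv(p, sep="\t", index=False)
        written["index_table"] = p
    if contingency is not None:
        p = outdir / "contingency.json"
        p.write_text(json.dumps(contingency, indent=2, default=_jsonify))
        written["contingency"] = p
    if roc_summary is not None:
        p = outdir / "roc_summary.json"
        p.write_text(json.dumps(roc_summary, indent=2, default=_jsonify))
        written["roc_summary"] = p
    if volumes:
        for name, vol in volumes.items():
            p = outdir / f"{name}.nii.gz"
            write_volume(vol, p)
            written[f"volume:{name}"] = p
    return written


def read_roi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def read_index_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
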