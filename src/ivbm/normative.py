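"""Healthy-control normative database and single-subject atrophy z-maps.

The referential database is a voxel-wise ordinary-least-squares fit of
tissue volume on (1, age, sex, TIV) across healthy controls, one fit per
compartment (GM and WM are fully independent: separate masks, coefficients
and residual scales). A new subject is scored voxel-by-voxel as

    z = (predicted - observed) / residual_scale

so that volume *below* the covariate-adjusted healthy prediction — atrophy —
yields a positive z. Maps are conventionally visualized at z >= 2, the level
at which fewer than roughly 2.5% of healthy-control voxels appear.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    COMPARTMENTS,
    SEX_ENCODING,
    CovariateRecord,
    VolumeImage,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

#: Design-matrix column order of the normative GLM.
DESIGN_COLUMNS = ("intercept", "age", "sex", "tiv")

#: Default visualization threshold on the inverted z-scale.
Z_THRESHOLD = 2.0

#: Residual scales below this fraction of the data's RMS are treated as
#: numerically degenerate and dropped from the mask.
DEGENERATE_SCALE_REL = 1e-10


@dataclass
class NormativeDB:
    """Per-voxel GLM coefficients and residual scale from healthy controls.

    ``coefficients`` has shape ``(4,) + grid`` in :data:`DESIGN_COLUMNS`
    order; off-mask voxels are NaN. ``dof`` is the residual degrees of
    freedom ``n_reference - 4``.
    """

    coefficients: np.ndarray
    residual_scale: np.ndarray
    mask: np.ndarray
    n_reference: int
    dof: int
    compartment: str | None
    covariate_spec: dict
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != len(DESIGN_COLUMNS):
            raise ValueError("coefficients must have one map per design column")
        if self.dof < 1:
            raise ValueError("residual degrees of freedom must be >= 1")
        if np.any(self.residual_scale[self.mask] <= 0):
            raise ValueError("residual_scale must be > 0 on the mask")
        if not np.all(np.isfinite(self.coefficients[:, self.mask])):
            raise ValueError("coefficients must be finite on the mask")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def predict(self, cov: CovariateRecord) -> np.ndarray:
        """Expected healthy volume map for a subject's covariates."""
        x = design_row(cov)
        return np.tensordot(x, self.coefficients, axes=1)

    def save(self, path: str | Path) -> Path:
        """Serialize as a directory of NIfTI maps plus JSON metadata."""
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, col in enumerate(DESIGN_COLUMNS):
            write_volume(
                VolumeImage(np.nan_to_num(self.coefficients[i]), self.voxel_size),
                outdir / f"coef_{col}.nii.gz",
            )
        write_volume(VolumeImage(np.nan_to_num(self.residual_scale), self.voxel_size),
                     outdir / "residual_scale.nii.gz")
        write_volume(VolumeImage(self.mask.astype(float), self.voxel_size),
                     outdir / "mask.nii.gz")
        meta = {
            "n_reference": self.n_reference,
            "dof": self.dof,
            "compartment": self.compartment,
            "covariate_spec": self.covariate_spec,
            "voxel_size": list(self.voxel_size),
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
        return outdir

    @classmethod
    def load(cls, path: str | Path) -> "NormativeDB":
        indir = Path(path)
        meta = json.loads((indir / "meta.json").read_text())
        mask = read_volume(indir / "mask.nii.gz").data > 0.5
        coefs = np.stack(
            [read_volume(indir / f"coef_{c}.nii.gz").data for c in DESIGN_COLUMNS]
        )
        scale = read_volume(indir / "residual_scale.nii.gz").data
        coefs[:, ~mask] = np.nan
        scale[~mask] = np.nan
        return cls(
            coefficients=coefs,
            residual_scale=scale,
            mask=mask,
            n_reference=int(meta["n_reference"]),
            dof=int(meta["dof"]),
            compartment=meta.get("compartment"),
            covariate_spec=meta["covariate_spec"],
            voxel_size=tuple(meta["voxel_size"]),
        )


@dataclass
class ZMap:
    """Inverted atrophy z-scores for one subject and compartment.

    Positive z means the subject's volume lies below the covariate-adjusted
    healthy prediction. Voxels outside the mask are NaN (flagged missing).
    """

    z: np.ndarray
    mask: np.ndarray
    subject_id: str
    compartment: str | None
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if self.z.shape != self.mask.shape:
            raise ValueError("z and mask shapes differ")
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValueError("z must be finite on the mask")


def design_row(cov: CovariateRecord) -> np.ndarray:
    return np.array([1.0, cov.age, float(cov.sex), cov.tiv])


def design_matrix(covariates: Sequence[CovariateRecord]) -> np.ndarray:
    return np.stack([design_row(c) for c in covariates])


def _check_design(X: np.ndarray) -> None:
    for j, col in enumerate(DESIGN_COLUMNS[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(
                f"rank-deficient design: column '{col}' is constant across the reference cohort"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: covariate columns are collinear")


def fit_reference(
    hc_images: Sequence[VolumeImage] | Mapping[str, VolumeImage],
    hc_covariates: Sequence[CovariateRecord],
    mask: np.ndarray,
) -> NormativeDB:
    """Fit the voxel-wise normative GLM on healthy-control images.

    ``hc_images`` may be a mapping subject_id -> image (aligned to the
    covariates by id) or a sequence parallel to ``hc_covariates``. Per
    masked voxel an OLS fit of volume on (1, age, sex, TIV) is computed;
    the residual scale is ``sqrt(RSS / (n - 4))``. Voxels with numerically
    degenerate residual variance are dropped from the mask.
    """
    if isinstance(hc_images, Mapping):
        missing = [c.subject_id for c in hc_covariates if c.subject_id not in hc_images]
        if missing:
            raise ValueError(f"no image for subject(s): {missing}")
        imgs = [hc_images[c.subject_id] for c in hc_covariates]
    else:
        imgs = list(hc_images)
        if len(imgs) != len(hc_covariates):
            raise ValueError("hc_images and hc_covariates lengths differ")
    n = len(imgs)
    p = len(DESIGN_COLUMNS)
    if n <= p + 1:
        raise ValueError(
            f"insufficient reference subjects: n = {n}, need at least {p + 2}"
        )
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"reference images have inconsistent shapes: {shapes}")
    grid = imgs[0].shape
    if mask.shape != grid:
        raise ValueError("mask shape does not match image grid")
    comps = {im.compartment for im in imgs}
    if len(comps) != 1:
        raise ValueError(f"reference images mix compartments: {comps}")
    compartment = comps.pop()

    X = design_matrix(hc_covariates)
    _check_design(X)
    mask = mask.copy()
    Y = np.stack([im.data[mask] for im in imgs])  # (n, n_vox)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - p
    scale = np.sqrt((resid ** 2).sum(axis=0) / dof)

    # Drop voxels whose residual variance is numerically zero.
    rms = float(np.sqrt(np.mean(Y ** 2))) or 1.0
    good = scale > DEGENERATE_SCALE_REL * rms
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.info("dropping %d degenerate voxel(s) from the mask", n_dropped)
        idx = np.flatnonzero(mask.ravel())
        keep = np.zeros(mask.size, dtype=bool)
        keep[idx[good]] = True
        mask = keep.reshape(grid)
        beta = beta[:, good]
        scale = scale[good]

    coef_maps = np.full((p,) + grid, np.nan)
    coef_maps[:, mask] = beta
    scale_map = np.full(grid, np.nan)
    scale_map[mask] = scale

    return NormativeDB(
        coefficients=coef_maps,
        residual_scale=scale_map,
        mask=mask,
        n_reference=n,
        dof=dof,
        compartment=compartment,
        covariate_spec={
            "columns": list(DESIGN_COLUMNS),
            "sex_encoding": dict(SEX_ENCODING),
        },
        voxel_size=imgs[0].voxel_size,
    )


def z_transform(
    subject_img: VolumeImage,
    subject_cov: CovariateRecord,
    db: NormativeDB,
) -> ZMap:
    """Score one subject against the reference: z = (predicted - observed) / scale.

    The sign is inverted relative to a raw residual so that atrophy (volume
    below the healthy prediction) gives positive z.
    """
    if subject_img.shape != db.grid_shape:
        raise ValueError(
            f"image grid {subject_img.shape} does not match reference grid {db.grid_shape}"
        )
    if (
        db.compartment is not None
        and subject_img.compartment is not None
        and subject_img.compartment != db.compartment
    ):
        raise ValueError(
            f"compartment mismatch: image is {subject_img.compartment}, "
            f"reference is {db.compartment}"
        )
    predicted = db.predict(subject_cov)
    z = np.full(db.grid_shape, np.nan)
    m = db.mask
    z[m] = (predicted[m] - subject_img.data[m]) / db.residual_scale[m]
    return ZMap(z, m, subject_cov.subject_id, db.compartment, db.voxel_size)


def threshold_zmap(zmap: ZMap, threshold: float = Z_THRESHOLD) -> VolumeImage:
    """Keep z where z >= threshold (inclusive) on the mask, 0 elsewhere."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = np.zeros(zmap.z.shape)
    sel = zmap.mask & (np.nan_to_num(zmap.z, nan=-np.inf) >= threshold)
    out[sel] = zmap.z[sel]
    return VolumeImage(out, zmap.voxel_size, zmap.compartment, "zmap-thresholded")


def overlay_color(z: float, threshold: float, z_max: float) -> tuple[float, float, float, float]:
    """RGBA assigned to a suprathreshold z in the overlay's red-yellow ramp.

    ``z = threshold`` maps to red, ``z = z_max`` to yellow.
    """
    import matplotlib

    cmap = matplotlib.colormaps["autumn"]
    if z_max <= threshold:
        return cmap(0.0)
    frac = np.clip((z - threshold) / (z_max - threshold), 0.0, 1.0)
    return cmap(float(frac))


def render_overlay(
    thresholded: VolumeImage,
    template: VolumeImage,
    path: str | Path | None = None,
    threshold: float = Z_THRESHOLD,
    n_cols: int = 6,
    slice_step: int = 2,
) -> np.ndarray:
    """Axial mosaic of the thresholded z-map over a template, red-yellow ramp.

    Returns the rendered RGBA pixel buffer; if ``path`` is given the mosaic
    is also written as PNG. Rendering is deterministic for fixed inputs.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    if thresholded.shape != template.shape:
        raise ValueError("thresholded map and template grids differ")
    nz = thresholded.shape[2]
    slices = list(range(0, nz, max(1, int(slice_step))))
    n_rows = int(np.ceil(len(slices) / n_cols))
    z_vals = thresholded.data[thresholded.data > 0]
    z_max = float(z_vals.max()) if z_vals.size else threshold + 1.0
    if z_max <= threshold:
        z_max = threshold + 1.0

    fig = Figure(figsize=(2 * n_cols, 2 * n_rows), dpi=72)
    canvas = FigureCanvasAgg(fig)
    for ax_i, k in enumerate(slices):
        ax = fig.add_subplot(n_rows, n_cols, ax_i + 1)
        ax.imshow(template.data[:, :, k].T, cmap="gray", origin="lower",
                  interpolation="nearest")
        overlay = np.ma.masked_less_equal(thresholded.data[:, :, k].T, 0.0)
        ax.imshow(overlay, cmap="autumn", vmin=threshold, vmax=z_max,
                  origin="lower", interpolation="nearest")
        z_mm = k * thresholded.voxel_size[2]
        ax.text(0.02, 0.02, f"z={z_mm:.1f}", transform=ax.transAxes,
                color="white", fontsize=6)
        ax.set_axis_off()
    canvas.draw()
    buffer = np.asarray(canvas.buffer_rgba()).copy()
    if path is not None:
        fig.savefig(str(path), format="png")
    return buffer
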