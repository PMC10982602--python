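"""Synthetic cohorts of GM/WM volume maps for testing the normative pipeline.

The generator emulates exactly the statistical structure the normative model
assumes: each tissue voxel is linear in age, sex and total intracranial
volume with homoscedastic Gaussian noise, and disease groups carry
multiplicative volume loss inside their characteristic regions — putamen in
the parkinsonian variant of multiple system atrophy (MSA-P), pons and middle
cerebellar peduncles in the cerebellar variant (MSA-C), midbrain in
progressive supranuclear palsy (PSP), and none in Parkinson's disease (PD)
or healthy controls (HC).

It makes no attempt at realistic anatomy: regions are disjoint boxes on a
small grid, which is sufficient for every property the analysis depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import (
    GM,
    WM,
    CovariateRecord,
    RoiAtlas,
    VolumeImage,
)

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

#: Disease-group keys accepted by ``n_per_group`` / ``atrophy_map``. Keys are
#: subtype-level where the atrophy pattern is subtype-specific.
GROUP_KEYS = ("HC", "PD", "MSA-P", "MSA-C", "PSP")

_GROUP_OF = {"HC": "HC", "PD": "PD", "MSA-P": "MSA", "MSA-C": "MSA", "PSP": "PSP"}
_SUBTYPE_OF = {"MSA-P": "MSA-P", "MSA-C": "MSA-C"}


@dataclass
class SyntheticAtlasSpec:
    """Box-shaped ROIs (half-open voxel index ranges) with compartment tags.

    ``rois`` maps roi_name -> (box, compartment). Boxes must be pairwise
    disjoint and contain at least ``min_voxels`` voxels each.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    rois: dict[str, tuple[Box, str]] = field(default_factory=dict)
    min_voxels: int = 20


def default_atlas_spec(grid_shape: tuple[int, int, int] = (32, 32, 32)) -> SyntheticAtlasSpec:
    """The default synthetic parcellation.

    Structures relevant to the MSA/PSP index (putamen, midbrain, MCP, pons)
    plus cerebellar and background tissue, laid out on disjoint axial slabs
    of a 32-cube so that each structure is comfortably larger than 20 voxels.
    """
    rois: dict[str, tuple[Box, str]] = {
        "cerebellum":   (((8, 24), (8, 24), (2, 8)), GM),
        "pons":         (((12, 20), (12, 20), (8, 12)), WM),
        "mcp_l":        (((4, 10), (12, 20), (8, 12)), WM),
        "mcp_r":        (((22, 28), (12, 20), (8, 12)), WM),
        "midbrain_l":   (((10, 15), (12, 20), (12, 16)), WM),
        "midbrain_r":   (((17, 22), (12, 20), (12, 16)), WM),
        "putamen_l":    (((6, 12), (12, 20), (16, 21)), GM),
        "putamen_r":    (((20, 26), (12, 20), (16, 21)), GM),
        "cortex":       (((4, 28), (4, 28), (22, 30)), GM),
        "white_matter": (((4, 28), (4, 10), (8, 20)), WM),
    }
    return SyntheticAtlasSpec(grid_shape=grid_shape, rois=rois)


def make_atlas(spec: SyntheticAtlasSpec | None = None) -> RoiAtlas:
    """Deterministic label image + lookup from an atlas spec.

    Labels are assigned 1..K in the spec's ROI order. Overlapping boxes
    raise an error naming both ROIs involved.
    """
    if spec is None:
        spec = default_atlas_spec()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    lookup: dict[int, tuple[str, str]] = {}
    owner: dict[str, str] = {}
    for lab, (name, (box, comp)) in enumerate(spec.rois.items(), start=1):
        (i0, i1), (j0, j1), (k0, k1) = box
        region = labels[i0:i1, j0:j1, k0:k1]
        if np.any(region != 0):
            clash = int(region[region != 0].flat[0])
            raise ValueError(
                f"ROI {name!r} overlaps ROI {lookup[clash][0]!r}"
            )
        n_vox = (i1 - i0) * (j1 - j0) * (k1 - k0)
        if n_vox < spec.min_voxels:
            raise ValueError(f"ROI {name!r} has {n_vox} voxels, need >= {spec.min_voxels}")
        labels[i0:i1, j0:j1, k0:k1] = lab
        lookup[lab] = (name, comp)
        owner[name] = name
    return RoiAtlas(labels, lookup)


def _default_n_per_group() -> dict[str, int]:
    # Study-scale cohort: 48 HC, 96 PD, 18 MSA (12 P / 6 C), 20 PSP.
    return {"HC": 48, "PD": 96, "MSA-P": 12, "MSA-C": 6, "PSP": 20}


def _default_atrophy_map() -> dict[str, list[tuple[str, float]]]:
    return {
        "MSA-P": [("putamen_l", 0.25), ("putamen_r", 0.25)],
        "MSA-C": [("pons", 0.30), ("mcp_l", 0.25), ("mcp_r", 0.25)],
        "PSP": [("midbrain_l", 0.30), ("midbrain_r", 0.30)],
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Covariate effects act per voxel: a tissue voxel in compartment c is
    ``baseline_c + beta_age*age + beta_sex*sex + beta_tiv*tiv + noise``,
    then scaled by ``(1 - atrophy_fraction)`` inside the disease-target
    regions of the subject's group. Defaults produce ROI z-scores roughly
    in the 0–6 range for patients.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_per_group: dict[str, int] = field(default_factory=_default_n_per_group)
    age_range: tuple[float, float] = (50.0, 80.0)
    tiv_mean: float = 1450.0
    tiv_sd: float = 130.0
    beta_age: float = -0.003
    beta_sex: float = 0.02
    beta_tiv: float = 2.0e-4
    noise_sd: float = 0.05
    baseline_gm: float = 0.6
    baseline_wm: float = 0.7
    atrophy_map: dict[str, list[tuple[str, float]]] = field(default_factory=_default_atrophy_map)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tiv_sd < 0 or self.tiv_mean <= 0:
            raise ValueError("tiv_mean must be > 0 and tiv_sd >= 0")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ValueError("age_range must satisfy 0 < low < high")
        for key, targets in self.atrophy_map.items():
            if key not in GROUP_KEYS:
                raise ValueError(f"unknown group key in atrophy_map: {key!r}")
            for roi, frac in targets:
                if not (0 <= frac < 1):
                    raise ValueError(
                        f"atrophy_fraction for {roi!r} must be in [0, 1), got {frac}"
                    )
        for key in self.n_per_group:
            if key not in GROUP_KEYS:
                raise ValueError(f"unknown group key in n_per_group: {key!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "atrophy_map" in raw:
            raw["atrophy_map"] = {
                k: [(str(r), float(f)) for r, f in v] for k, v in raw["atrophy_map"].items()
            }
        for key in ("grid_shape", "voxel_size", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        raw = asdict(self)
        raw["grid_shape"] = list(self.grid_shape)
        raw["voxel_size"] = list(self.voxel_size)
        raw["age_range"] = list(self.age_range)
        raw["atrophy_map"] = {k: [list(t) for t in v] for k, v in self.atrophy_map.items()}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
        return Path(path)


def simulate_cohort(
    cfg: SimulationConfig,
    atlas: RoiAtlas,
) -> tuple[list[CovariateRecord], dict[str, dict[str, VolumeImage]]]:
    """Draw a full cohort of covariates and GM/WM images.

    Returns ``(records, images)`` where ``images[subject_id]["GM"|"WM"]``
    is that subject's volume map. Fully reproducible from ``cfg.seed``: one
    top-level seed sequence spawns an independent substream per subject.
    """
    if atlas.labels.shape != tuple(cfg.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match config grid {tuple(cfg.grid_shape)}"
        )
    roi_names = set(atlas.names)
    for key, targets in cfg.atrophy_map.items():
        for roi, _ in targets:
            if roi not in roi_names:
                raise ValueError(f"atrophy target ROI {roi!r} not in atlas")

    comp_vox = {
        GM: np.zeros(cfg.grid_shape, dtype=bool),
        WM: np.zeros(cfg.grid_shape, dtype=bool),
    }
    baseline = {
        GM: np.zeros(cfg.grid_shape),
        WM: np.zeros(cfg.grid_shape),
    }
    base_value = {GM: cfg.baseline_gm, WM: cfg.baseline_wm}
    for lab, (name, comp) in atlas.lookup.items():
        sel = atlas.labels == lab
        comp_vox[comp] |= sel
        baseline[comp][sel] = base_value[comp]

    top = np.random.SeedSequence(cfg.seed)
    n_total = sum(cfg.n_per_group.values())
    streams = top.spawn(n_total + 1)
    cov_rng = np.random.default_rng(streams[0])

    records: list[CovariateRecord] = []
    images: dict[str, dict[str, VolumeImage]] = {}
    idx = 0
    for key in GROUP_KEYS:
        n = cfg.n_per_group.get(key, 0)
        targets = cfg.atrophy_map.get(key, [])
        for _ in range(n):
            idx += 1
            sid = f"{key.lower().replace('-', '')}_{idx:04d}"
            age = float(cov_rng.uniform(*cfg.age_range))
            sex = int(cov_rng.integers(0, 2))
            tiv = float(abs(cov_rng.normal(cfg.tiv_mean, cfg.tiv_sd)))
            rec = CovariateRecord(sid, age, sex, tiv, _GROUP_OF[key], _SUBTYPE_OF.get(key))
            records.append(rec)
            sub_rng = np.random.default_rng(streams[idx])
            subj_imgs: dict[str, VolumeImage] = {}
            for comp in (GM, WM):
                tissue = comp_vox[comp]
                data = np.zeros(cfg.grid_shape)
                covar_term = cfg.beta_age * age + cfg.beta_sex * sex + cfg.beta_tiv * tiv
                data[tissue] = (
                    baseline[comp][tissue]
                    + covar_term
                    + sub_rng.normal(0.0, cfg.noise_sd, size=int(tissue.sum()))
                )
                for roi, frac in targets:
                    sel = atlas.roi_mask(roi)
                    data[sel] *= 1.0 - frac
                subj_imgs[comp] = VolumeImage(data, cfg.voxel_size, comp, "synthetic")
            images[sid] = subj_imgs
    return records, images


def expected_voxel_value(cfg: SimulationConfig, compartment: str,
                         age: float | None = None, sex: float = 0.5,
                         tiv: float | None = None) -> float:
    """Analytic expectation of a healthy tissue voxel under the config.

    Used by tests to compare simulated group means against closed form.
    """
    if age is None:
        age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    if tiv is None:
        tiv = cfg.tiv_mean
    base = cfg.baseline_gm if compartment == GM else cfg.baseline_wm
    return base + cfg.beta_age * age + cfg.beta_sex * sex + cfg.beta_tiv * tiv


def simulate_rater_decisions(
    truth: Sequence[str],
    rater_profiles: Sequence[Mapping[str, tuple[float, float]]],
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw per-rater diagnostic labels with given sensitivity/specificity.

    ``rater_profiles`` gives, per rater, ``{disease: (sens, spec)}``. For a
    subject whose true label is a profiled disease, the rater assigns that
    disease with probability ``sens`` and otherwise a uniformly random other
    label; for non-profiled truths each profiled disease is a false alarm
    with probability ``1 - spec`` (first alarm in sorted order wins), else
    the true label is kept. With sens = spec = 1 the decisions equal truth.
    """
    truth = np.asarray(truth, dtype=object)
    universe = sorted(set(truth))
    for prof in rater_profiles:
        for d, (sens, spec) in prof.items():
            if not (0 <= sens <= 1 and 0 <= spec <= 1):
                raise ValueError(f"sens/spec for {d!r} must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    decisions = []
    for prof in rater_profiles:
        labels = np.empty(len(truth), dtype=object)
        for i, t in enumerate(truth):
            if t in prof:
                sens, _ = prof[t]
                if rng.random() < sens:
                    labels[i] = t
                else:
                    others = [u for u in universe if u != t]
                    labels[i] = others[int(rng.integers(len(others)))] if others else t
            else:
                labels[i] = t
                for d in sorted(prof):
                    _, spec = prof[d]
                    if rng.random() < 1.0 - spec:
                        labels[i] = d
                        break
        decisions.append(labels)
    return decisions
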