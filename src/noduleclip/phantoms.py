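"""Seeded synthetic-cohort generator: CT-like volumes whose rendered nodule
morphology encodes sampled semantic records, with outcome labels drawn from a
declared logistic model on those records.

The generator is the desk-scale stand-in for screening cohorts: semantic
records are sampled from configurable marginals (shaped like the prevalences
of a screening population), each record is rendered into a noisy HU volume —
consistency sets interior attenuation, margin sets spiculation/lobulation/edge
blur, shape sets the radial profile, and internal/external findings add
calcifications, cyst-like spaces or a pleural wall — and the one-year cancer
label depends on the semantics only, never on the pixels directly, so an
image-based predictor must recover the signal through the rendered morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import CTVolume
from .semantics import (MISSING, SemanticRecord, SemanticSchema, default_schema,
                        write_semantics_csv)

__all__ = [
    "PhantomConfig", "PhantomCase", "DEFAULT_MARGINALS", "DEFAULT_MISSINGNESS",
    "DEFAULT_BETA", "sample_semantics", "render_volume", "assign_label",
    "generate_cases", "generate_dataset",
]

# marginal prevalences, loosely shaped like a screening cohort
DEFAULT_MARGINALS: dict = {
    "margin": {"smooth": 0.67, "lobulated": 0.22, "spiculated": 0.24,
               "ill-defined": 0.19},
    "consistency": {"solid": 0.73, "pure ground glass": 0.09, "part-solid": 0.08,
                    "semiconsolidation": 0.08, "peri-cystic": 0.02},
    "shape": {"irregular": 0.31, "ovoid": 0.35, "polygonal": 0.14, "round": 0.20},
    "margin_conspicuity": {"well marginated": 0.84, "poorly marginated": 0.16},
    "reticulation": 0.88,
    "cyst-like_spaces": 0.14,
    "necrosis": 0.004,
    "eccentric_calcification": 0.03,
    "cavitation": 0.004,
    "intra-nodular_bronchiectasis": 0.03,
    "airway_cutoff": 0.07,
    "vascular_convergence": 0.10,
    "pleural_retraction": 0.80,
    "pleural_attachment": 0.53,
    "paracicatricial_emphysema": 0.12,
    "septal_stretching": 0.69,
}

DEFAULT_MISSINGNESS: dict = {"airway_cutoff": 0.71, "consistency": 0.02,
                             "shape": 0.02, "eccentric_calcification": 0.02}

# logistic label model on the semantic covariates (radius in mm)
DEFAULT_BETA: dict = {
    "intercept": -2.0,
    "spiculated": 2.0,
    "ill-defined": 1.0,
    "smooth": -1.0,
    "pure ground glass": 0.5,
    "eccentric_calcification": -1.5,
    "vascular_convergence": 1.0,
    "radius": 0.8,  # applied as beta * (r - 6) / 3
}

# interior HU targets per consistency class
_HU_TARGET = {"solid": 30.0, "pure ground glass": -620.0, "semiconsolidation": -300.0,
              "peri-cystic": 30.0, "part-solid": 30.0}
_HU_GG = -620.0
_HU_CYST = -800.0
_HU_CALC = 400.0
_HU_PLEURA = 0.0


@dataclass
class PhantomConfig:
    n_cases: int = 400
    volume_size: int = 64          # voxels per axis at 1 mm spacing
    background_hu_mean: float = -850.0
    background_hu_sd: float = 40.0
    nodule_hu_sd: float = 20.0
    radius_range_mm: tuple[float, float] = (3.0, 15.0)
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    seed: int = 7

    def __post_init__(self):
        lo, hi = self.radius_range_mm
        cap = self.volume_size / 2 - 6
        if lo <= 0:
            raise ValueError("nodule radius must be positive")
        if lo > cap:
            raise ValueError("radius range exceeds the volume half-extent")
        self.radius_range_mm = (lo, min(hi, cap))


@dataclass
class PhantomCase:
    volume: CTVolume
    centroid_mm: np.ndarray
    record: SemanticRecord
    label: int
    render_params: dict


# ------------------------------------------------------------- semantics
def sample_semantics(cfg: PhantomConfig, rng: np.random.Generator,
                     patient_id: str = "P0", nodule_id: str = "N0",
                     schema: SemanticSchema | None = None) -> SemanticRecord:
    """Draw a record from the configured marginals.

    Declared dependencies: a spiculated margin excludes "smooth", and a pure
    ground-glass nodule never carries an eccentric calcification.  The
    missingness mask is applied after sampling.
    """
    schema = schema or default_schema()
    m = cfg.marginals
    values: dict = {}

    # irregular margin descriptors can co-occur; "smooth" excludes them all
    # (a margin with lobulation, spiculation or blur is not smooth)
    margin_p = m["margin"]
    labels = [c for c in ("lobulated", "spiculated", "ill-defined")
              if rng.random() < margin_p[c]]
    if not labels:
        labels = ["smooth"]
    order = ("smooth", "lobulated", "spiculated", "ill-defined")
    values["margin"] = tuple(c for c in order if c in labels)

    for name in ("consistency", "shape", "margin_conspicuity"):
        classes, probs = zip(*m[name].items())
        p = np.asarray(probs, dtype=float)
        values[name] = str(rng.choice(classes, p=p / p.sum()))

    for f in schema:
        if f.kind == "binary":
            values[f.name] = bool(rng.random() < float(m[f.name]))
    if values["consistency"] == "pure ground glass":
        values["eccentric_calcification"] = False

    for name, p_miss in cfg.missingness.items():
        if rng.random() < float(p_miss):
            values.pop(name, None)

    rec = SemanticRecord(patient_id, nodule_id, values)
    rec.validate(schema)
    return rec


# -------------------------------------------------------------- rendering
def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def render_volume(rec: SemanticRecord, cfg: PhantomConfig,
                  rng: np.random.Generator) -> tuple[CTVolume, np.ndarray, dict]:
    """Render one record into an HU volume; returns (volume, centroid_mm,
    ground-truth render parameters)."""
    from scipy import ndimage

    margin = tuple(rec.get("margin") or ("smooth",))
    if "spiculated" in margin and "smooth" in margin:
        raise ValueError("inconsistent record: margin both spiculated and smooth")
    consistency = rec.get("consistency") or "solid"
    shape = rec.get("shape") or "round"

    n = cfg.volume_size
    vox = rng.normal(cfg.background_hu_mean, cfg.background_hu_sd,
                     (n, n, n)).astype(np.float32)
    center = np.full(3, (n - 1) / 2.0) + rng.uniform(-3, 3, size=3)
    radius = float(rng.uniform(*cfg.radius_range_mm))

    grid = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
    rel = grid - center
    dist = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore"):
        u = rel / np.maximum(dist, 1e-9)[..., None]

    # ---- shape class sets the base radial profile
    r_dir = np.full(dist.shape, radius)
    if shape == "ovoid":
        scales = rng.permutation([1.0, 0.85, 0.7])
        dist_eff = np.linalg.norm(rel / scales, axis=-1)
    elif shape == "polygonal":
        dist_eff = (np.abs(rel) ** 4).sum(axis=-1) ** 0.25
    elif shape == "irregular":
        a = rng.standard_normal((3, 3))
        q = (a + a.T) / 2
        q -= np.eye(3) * np.trace(q) / 3
        f = np.einsum("...i,ij,...j->...", u, q, u)
        # global asymmetry, kept gentler than margin-class surface detail
        r_dir = radius * (1.0 + 0.15 * np.tanh(f))
        dist_eff = dist
    else:  # round
        dist_eff = dist

    # ---- margin classes modulate the surface
    if "lobulated" in margin:
        for _ in range(int(rng.integers(2, 5))):
            v = _random_unit(rng)
            r_dir = r_dir + radius * 0.3 * np.maximum(u @ v, 0.0) ** 6

    mask = (dist_eff <= r_dir).astype(np.float32)

    n_spikes = 0
    if "spiculated" in margin:
        # radiating strands, thick at the nodule surface and tapering outward,
        # so that section planes through the centroid reliably cut them
        n_spikes = max(3, int(rng.poisson(8)))
        for _ in range(n_spikes):
            v = _random_unit(rng)
            length = float(rng.uniform(2.0, 6.0))
            proj = rel @ v
            perp = np.sqrt(np.maximum(dist**2 - proj**2, 0.0))
            frac = np.clip((proj - 0.6 * radius) / (0.4 * radius + length), 0.0, 1.0)
            width = 2.4 - 1.6 * frac  # mm, base -> tip
            spike = (proj >= 0.6 * radius) & (proj <= radius + length) & (perp <= width)
            mask[spike] = 1.0

    if "ill-defined" in margin:
        mask = ndimage.gaussian_filter(mask, sigma=1.5)

    # ---- interior attenuation per consistency class
    interior = np.full(dist.shape, _HU_TARGET[consistency], dtype=np.float32)
    if consistency == "part-solid":
        interior[:] = _HU_GG
        interior[dist_eff <= radius / 2.0] = _HU_TARGET["solid"]
    interior += rng.normal(0.0, cfg.nodule_hu_sd, dist.shape).astype(np.float32)

    vox = vox * (1.0 - mask) + interior * mask

    # ---- internal findings
    if rec.get("cyst-like_spaces") is True or consistency == "peri-cystic":
        n_cysts = 2 if consistency == "peri-cystic" else 1
        for _ in range(n_cysts):
            off = _random_unit(rng) * rng.uniform(0.0, radius / 3.0)
            cyst_r = max(1.0, radius / 3.0)
            cyst = np.linalg.norm(rel - off, axis=-1) <= cyst_r
            vox[cyst & (mask > 0.5)] = _HU_CYST
    if rec.get("eccentric_calcification") is True:
        off = _random_unit(rng) * rng.uniform(radius / 2.0, 0.9 * radius)
        calc_r = float(rng.uniform(1.0, 2.0))
        vox[np.linalg.norm(rel - off, axis=-1) <= calc_r] = _HU_CALC

    # ---- external findings: a 3 mm pleural wall tangent to the nodule
    if rec.get("pleural_attachment") is True:
        axis = int(rng.integers(0, 3))
        sign = 1 if rng.random() < 0.5 else -1
        coord = sign * rel[..., axis]
        vox[(coord >= radius - 0.5) & (coord <= radius + 2.5)] = _HU_PLEURA

    vol = CTVolume(vox, np.ones(3), np.zeros(3))
    centroid_mm = center.copy()  # spacing 1 mm, origin 0
    params = {"radius_mm": radius, "n_spikes": n_spikes,
              "hu_target": float(_HU_TARGET[consistency]),
              "consistency": consistency, "margin": margin, "shape": shape}
    return vol, centroid_mm, params


# ------------------------------------------------------------------ labels
def _covariates(rec: SemanticRecord, radius_mm: float) -> dict[str, float]:
    margin = tuple(rec.get("margin") or ())
    return {
        "spiculated": float("spiculated" in margin),
        "ill-defined": float("ill-defined" in margin),
        "smooth": float("smooth" in margin),
        "pure ground glass": float(rec.get("consistency") == "pure ground glass"),
        "eccentric_calcification": float(rec.get("eccentric_calcification") is True),
        "vascular_convergence": float(rec.get("vascular_convergence") is True),
        "radius": (radius_mm - 6.0) / 3.0,
    }


def linear_predictor(rec: SemanticRecord, beta: dict, radius_mm: float) -> float:
    """eta = intercept + beta^T x; missing features contribute 0."""
    x = _covariates(rec, radius_mm)
    return float(beta.get("intercept", 0.0)
                 + sum(beta.get(k, 0.0) * v for k, v in x.items()))


def assign_label(rec: SemanticRecord, beta: dict, rng: np.random.Generator,
                 radius_mm: float = 6.0) -> int:
    eta = linear_predictor(rec, beta, radius_mm)
    p = 1.0 / (1.0 + np.exp(-eta))
    return int(rng.random() < p)


# ----------------------------------------------------------------- dataset
def generate_cases(cfg: PhantomConfig) -> list[PhantomCase]:
    """Generate the cohort in memory, fully reproducible from ``cfg.seed``."""
    schema = default_schema()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cases)
    cases = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        pid, nid = f"P{i:04d}", "N0"
        rec = sample_semantics(cfg, rng, pid, nid, schema)
        vol, centroid, params = render_volume(rec, cfg, rng)
        label = assign_label(rec, cfg.beta, rng, radius_mm=params["radius_mm"])
        cases.append(PhantomCase(vol, centroid, rec, label, params))
    return cases


def generate_dataset(cfg: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write NIfTI volumes plus manifest and semantics CSVs in the formats the
    preprocessing modules read; returns the manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} already exists")
    cases = generate_cases(cfg)
    rows = []
    for case in cases:
        name = f"{case.record.patient_id}_{case.record.nodule_id}.nii.gz"
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(case.volume.voxels, affine), out / name)
        rows.append({"patient_id": case.record.patient_id,
                     "nodule_id": case.record.nodule_id,
                     "image_path": name,
                     "x_mm": case.centroid_mm[0], "y_mm": case.centroid_mm[1],
                     "z_mm": case.centroid_mm[2], "label": case.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    write_semantics_csv([c.record for c in cases], out / "semantics.csv")
    return manifest
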