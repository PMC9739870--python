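"""Synthetic *Salamandrina* data with the statistical structure the analysis assumes.

The field data behind the study design (five populations, two species, two
oviposition-site typologies) are not publicly deposited, so this module
generates stand-ins for every input the pipeline consumes:

* a biometric table — body size (AG, the axilla–groin distance) driven by
  species, site typology and a population-level random intercept, the other
  measurements allometrically tied to AG, and SVL/TL built to be nearly
  collinear with AG;
* head landmark configurations — a built-in, hand-authored 33-point template
  (9 landmarks + 24 outline semi-landmarks) perturbed by Gaussian landmark
  noise and a random similarity transform per individual;
* binary head-pattern images — a stylized yellow "V" patch rendered in each
  individual's shape frame, with two latent patch geometries (clusters)
  associated with habitat.

Everything is driven by a single integer seed; generation is fully
deterministic given the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import FEATURE_COLUMNS, TpsRecord, validate_biometric_table
from .morphometrics import N_LANDMARKS, LandmarkConfiguration

__all__ = [
    "HEAD_TEMPLATE",
    "PatchGeometry",
    "SyntheticDesign",
    "generate_biometric_dataset",
    "generate_head_dataset",
    "render_v_patch",
    "template_configuration",
]

# landmark indices in the template (and in every generated configuration)
SNOUT, NOSTRIL_L, NOSTRIL_R, EYE_L, EYE_R, TEMPORAL_L, TEMPORAL_R, OCCIPUT, MIDHEAD = range(9)


def _template_points() -> np.ndarray:
    """Hand-authored bilaterally quasi-symmetric head, anterior pointing +y.

    Outline: 24 points on a smooth egg-like closed curve (an ellipse narrowed
    toward the snout), clockwise from the snout tip.  Landmarks: snout tip,
    paired nostrils, eyes and temporal corners, the occiput and a mid-head
    point.  Units are arbitrary shape units (head length about 2).
    """
    landmarks = np.array(
        [
            [0.00, 0.95],    # snout tip
            [-0.12, 0.88],   # left nostril
            [0.12, 0.88],    # right nostril
            [-0.30, 0.55],   # left eye
            [0.30, 0.55],    # right eye
            [-0.42, 0.00],   # left temporal corner
            [0.42, 0.00],    # right temporal corner
            [0.00, -0.85],   # occiput
            [0.00, 0.20],    # mid-head
        ]
    )
    theta = np.deg2rad(90.0 - 15.0 * np.arange(24))
    x = 0.7 * np.cos(theta) * (1.0 - 0.25 * np.maximum(np.sin(theta), 0.0))
    y = np.sin(theta)
    return np.vstack([landmarks, np.column_stack([x, y])])


HEAD_TEMPLATE: np.ndarray = _template_points()


def template_configuration() -> LandmarkConfiguration:
    """The built-in 33-point head template as a landmark configuration."""
    return LandmarkConfiguration(points=HEAD_TEMPLATE.copy(), id="template")


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of the stylized V patch, in units of the snout–occiput length.

    The apex sits at ``apex_frac`` of the way from snout to occiput; the two
    arms run back toward the posterior at ``+- half_angle`` from the head
    axis, with length ``arm_len_frac`` and stroke width ``width_frac``.
    """

    half_angle: float = 0.5      # radians
    width_frac: float = 0.07
    apex_frac: float = 0.30
    arm_len_frac: float = 0.55

    def validate(self) -> None:
        if self.width_frac <= 0:
            raise ValueError("degenerate patch: width_frac must be > 0")
        if self.arm_len_frac <= 0:
            raise ValueError("degenerate patch: arm_len_frac must be > 0")
        if not 0.0 <= self.half_angle <= np.pi / 2:
            raise ValueError("half_angle must be in [0, pi/2]")
        if not 0.0 <= self.apex_frac <= 0.8:
            raise ValueError("apex_frac must be in [0, 0.8]")


#: five-site study design: (code, species, site typology, n)
DEFAULT_POPULATIONS: tuple[tuple[str, str, str, int], ...] = (
    ("AC", "perspicillata", "lentic", 28),
    ("CN", "perspicillata", "lentic", 19),
    ("SA", "perspicillata", "brook", 27),
    ("TC", "terdigitata", "brook", 41),
    ("TR", "terdigitata", "brook", 41),
)

# allometry of each non-AG feature on AG: (intercept mm, slope, residual SD mm)
DEFAULT_ALLOMETRY: dict[str, tuple[float, float, float]] = {
    "CL": (3.0, 0.10, 0.35),
    "HL": (4.0, 0.18, 0.45),
    "HW": (3.0, 0.14, 0.40),
    "No": (1.0, 0.04, 0.18),
    "RU": (2.0, 0.16, 0.50),
    "TF": (2.5, 0.18, 0.50),
    "tL": (20.0, 1.00, 2.00),
    "tW": (1.5, 0.08, 0.30),
}

SHAPE_FEATURES = tuple(DEFAULT_ALLOMETRY)  # the 8 features modelled in the multivariate set


@dataclass
class SyntheticDesign:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the five-site design (n = 28, 19, 27, 41, 41) with
    lentic animals larger than brook ones and a mild species effect, a
    population random intercept on size, allometric dependence of the other
    features on AG, and two habitat-associated latent patch clusters.
    """

    populations: tuple[tuple[str, str, str, int], ...] = DEFAULT_POPULATIONS
    # size model for AG (mm)
    size_intercept: float = 22.0          # baseline: S. terdigitata, brook
    species_effect: float = 2.5           # added for S. perspicillata
    habitat_effect: float = 4.0           # added for lentic sites
    population_sd: float = 0.3            # SD of the population random intercept
    residual_sd: float = 1.8              # individual residual SD
    # allometry of the 8 shape features on AG
    allometry: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ALLOMETRY)
    )
    allometry_population_sd_frac: float = 0.5   # population SD as fraction of each residual SD
    # colour-pattern model: two latent clusters, habitat-associated
    patch_geometries: tuple[PatchGeometry, ...] = (
        PatchGeometry(half_angle=0.50, width_frac=0.07, apex_frac=0.35),
        PatchGeometry(half_angle=0.90, width_frac=0.12, apex_frac=0.22),
    )
    cluster_habitat_prob: float = 0.9     # P(cluster 0 | lentic) = P(cluster 1 | brook)
    # landmark perturbation (template shape units) and similarity transform ranges
    landmark_sd: float = 0.02
    rotation_range_deg: tuple[float, float] = (-20.0, 20.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    translation_frac: float = 0.04        # of the grid's smaller dimension
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for code, species, site, n in self.populations:
            if n <= 0:
                raise ValueError(f"population {code}: n must be > 0")
        for sd in (self.population_sd, self.residual_sd, self.landmark_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.cluster_habitat_prob <= 1.0:
            raise ValueError("cluster_habitat_prob must be in [0, 1]")
        for g in self.patch_geometries:
            g.validate()


def generate_biometric_dataset(design: SyntheticDesign | None = None) -> pd.DataFrame:
    """Generate the per-individual biometric table under the design.

    AG = intercept + species_effect*1[perspicillata] + habitat_effect*1[lentic]
    + b_pop + eps, with b_pop ~ N(0, population_sd^2); each shape feature is
    a_f + c_f*AG + d_pop,f + eps_f; SVL and TL are built on AG so that their
    sample correlation with AG is high (they are size proxies).
    """
    design = design or SyntheticDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)

    rows = []
    for code, species, site, n in design.populations:
        b_pop = rng.normal(0.0, design.population_sd)
        d_pop = {
            f: rng.normal(0.0, design.allometry_population_sd_frac * sd)
            for f, (_, _, sd) in design.allometry.items()
        }
        for i in range(n):
            ag = (
                design.size_intercept
                + design.species_effect * (species == "perspicillata")
                + design.habitat_effect * (site == "lentic")
                + b_pop
                + rng.normal(0.0, design.residual_sd)
            )
            rec: dict[str, object] = {
                "id": f"{code}_{i + 1:03d}",
                "species": species,
                "site_typology": site,
                "population": code,
            }
            for f, (a, c, sd) in design.allometry.items():
                rec[f] = a + c * ag + d_pop[f] + rng.normal(0.0, sd)
            svl = 10.0 + 1.15 * ag + rng.normal(0.0, 0.8)
            tl = svl + rec["tL"] + rng.normal(0.0, 1.0)
            rec["AG"] = ag
            rec["SVL"] = svl
            rec["TL"] = tl
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["id", "species", "site_typology", "population"] + FEATURE_COLUMNS)
    return validate_biometric_table(df)


def render_v_patch(
    shape: LandmarkConfiguration,
    geometry: PatchGeometry,
    grid: tuple[int, int],
) -> np.ndarray:
    """Render the V patch of ``geometry`` in an individual's shape frame.

    The patch is the union of two constant-width strokes meeting at the apex
    (hence a single 4-connected component), anchored on the snout–occiput
    axis of the landmark configuration.  Coordinates are raster (x=col,
    y=row); the returned {0,1} raster has shape ``grid``.
    """
    geometry.validate()
    rows, cols = grid
    if rows < 32 or cols < 32:
        raise ValueError("grid too small to render the patch (need >= 32x32)")
    snout = shape.points[SNOUT]
    occiput = shape.points[OCCIPUT]
    axis = occiput - snout
    head_len = float(np.linalg.norm(axis))
    if head_len == 0:
        raise ValueError("degenerate configuration: snout and occiput coincide")
    u = axis / head_len
    apex = snout + geometry.apex_frac * axis
    arm_len = geometry.arm_len_frac * head_len
    half_w = 0.5 * geometry.width_frac * head_len
    if half_w <= 0:
        raise ValueError("degenerate patch: zero stroke width")

    c, s = np.cos(geometry.half_angle), np.sin(geometry.half_angle)
    dirs = [
        np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]]),
        np.array([c * u[0] + s * u[1], -s * u[0] + c * u[1]]),
    ]
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([cc.ravel().astype(float), rr.ravel().astype(float)])
    out = np.zeros(rows * cols, dtype=bool)
    for d in dirs:
        end = apex + arm_len * d
        out |= _dist_to_segment(pts, apex, end) <= half_w
    return out.reshape(rows, cols).astype(np.uint8)


def _dist_to_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def generate_head_dataset(
    design: SyntheticDesign | None = None,
    grid: tuple[int, int] = (128, 128),
) -> tuple[list[TpsRecord], list[np.ndarray], pd.DataFrame]:
    """Generate landmark records, binary patch rasters and true labels.

    Each individual gets: a latent patch cluster (habitat-associated with
    probability ``cluster_habitat_prob``), the template perturbed by Gaussian
    landmark noise, a random similarity transform (rotation, scale,
    translation) placing it in a ``grid``-sized image, and its cluster's V
    patch rendered in that frame.  Landmark records use the TPS y-convention
    (origin bottom-left); rasters use raster convention.
    """
    design = design or SyntheticDesign()
    design.validate()
    rows, cols = grid
    if rows < 32 or cols < 32:
        raise ValueError("grid must be at least 32x32")
    rng = np.random.default_rng(design.seed + 1)

    base_scale = 0.35 * min(rows, cols)
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    lo_rot, hi_rot = np.deg2rad(design.rotation_range_deg)
    n_clusters = len(design.patch_geometries)

    records: list[TpsRecord] = []
    rasters: list[np.ndarray] = []
    labels = []
    for code, species, site, n in design.populations:
        for i in range(n):
            p0 = design.cluster_habitat_prob if site == "lentic" else 1.0 - design.cluster_habitat_prob
            if n_clusters == 2:
                cluster = 0 if rng.random() < p0 else 1
            else:
                cluster = int(rng.integers(n_clusters))
            pts = HEAD_TEMPLATE + rng.normal(0.0, design.landmark_sd, HEAD_TEMPLATE.shape)
            phi = rng.uniform(lo_rot, hi_rot)
            scl = rng.uniform(*design.scale_range)
            trans = rng.uniform(-1.0, 1.0, 2) * design.translation_frac * min(rows, cols)
            rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            img_pts = (pts @ rot.T) * np.array([1.0, -1.0]) * base_scale * scl + center + trans

            config = LandmarkConfiguration(points=img_pts, id=f"{code}_{i + 1:03d}")
            raster = render_v_patch(config, design.patch_geometries[cluster], grid)
            tps_pts = img_pts.copy()
            tps_pts[:, 1] = (rows - 1) - tps_pts[:, 1]
            records.append(
                TpsRecord(id=config.id, points=tps_pts, image=f"{config.id}.png", scale=None)
            )
            rasters.append(raster)
            labels.append(
                {
                    "id": config.id,
                    "population": code,
                    "species": species,
                    "site_typology": site,
                    "cluster": cluster,
                }
            )
    return records, rasters, pd.DataFrame(labels)
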