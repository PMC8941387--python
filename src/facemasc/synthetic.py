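"""Synthetic face cohorts with the structure the analysis assumes.

Two generators are provided.

``generate_cohort`` works at the *geometry* level: each subject's 21
landmarks are the female template plus a sex-scaled sexual-dimorphism
displacement (plus a fraction of the same displacement for the
masculinized family group), an age trend, a global size factor and
isotropic landmark jitter.  Meshes follow the landmarks by thin-plate
spline deformation of the template surface.

``generate_feature_table`` works at the *distance* level: per
group-by-sex cell multivariate-normal draws of the analysis variables
(the ten sex-discriminating distances and a latent masculinity axis),
calibrated to published cell means and standard deviations, with age and
facial-area covariates correlated with every feature through a latent
size factor and a shared within-sex masculinity factor.  This is the
generator used for statistical calibration studies.

Both are bitwise deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import LANDMARK_CODES, LandmarkSet
from .mesh import FaceMesh
from .template import (
    DIMORPHISM_FIELD,
    FEMALE_TEMPLATE,
    subject_mesh,
    surface_height,
    template_mesh,
)

SEXES = ("male", "female")
FAMILY_GROUPS = ("autism_parent", "comparison_parent")

#: Cohort cells in canonical order: (sex, family_group).
CELLS = (
    ("male", "autism_parent"),
    ("female", "autism_parent"),
    ("male", "comparison_parent"),
    ("female", "comparison_parent"),
)

#: Published cohort structure: cell sizes and age mean/s.d. (years).
CELL_SIZES = {
    ("male", "autism_parent"): 58,
    ("female", "autism_parent"): 134,
    ("male", "comparison_parent"): 50,
    ("female", "comparison_parent"): 113,
}
CELL_AGES = {
    ("male", "autism_parent"): (43.4, 7.40),
    ("female", "autism_parent"): (41.9, 5.93),
    ("male", "comparison_parent"): (41.9, 8.32),
    ("female", "comparison_parent"): (39.1, 7.44),
}

#: Published per-cell mean and s.d. for the masculinity score and the ten
#: sex-discriminating facial distances (mm), keyed by analysis column.
#: Cell order matches CELLS.
TABLE_STATS: dict[str, tuple[tuple[float, float], ...]] = {
    "masculinity_score": ((0.85, 0.08), (0.32, 0.12), (0.80, 0.11), (0.28, 0.09)),
    "e_nose_width": ((19.8, 1.86), (18.2, 1.84), (19.3, 2.11), (17.6, 1.88)),
    "e_nasal_tip_protrusion": ((21.1, 2.05), (17.2, 2.22), (19.5, 2.62), (16.2, 2.50)),
    "e_nasal_bridge_length": ((51.0, 3.86), (46.3, 3.66), (49.3, 2.83), (45.4, 3.29)),
    "e_upper_lip_height": ((25.5, 3.11), (23.1, 2.73), (24.8, 3.04), (22.7, 2.71)),
    "g_upper_facial_height": ((73.0, 4.57), (67.7, 4.57), (70.7, 4.51), (65.5, 4.58)),
    "g_outer_canthal_width": ((120.6, 9.03), (109.8, 7.82), (117.3, 8.96), (106.9, 7.92)),
    "g_forehead_width": ((167.3, 11.5), (153.1, 8.04), (160.7, 11.7), (150.1, 7.20)),
    "g_mandible_height": ((77.7, 5.50), (71.8, 4.79), (76.0, 7.67), (71.7, 4.77)),
    "g_upper_cheek_height_left": ((80.0, 5.06), (73.9, 3.80), (77.9, 4.00), (73.2, 3.95)),
    "g_upper_cheek_height_right": ((79.6, 4.40), (73.9, 3.59), (77.4, 4.56), (72.7, 3.81)),
}

#: Published facial area (mm^2) by family group: mean, s.d.
GROUP_AREA = {
    "autism_parent": (35435.0, 4320.0),
    "comparison_parent": (35142.0, 4248.0),
}


class CohortError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str
    family_group: str
    age: float

    def __post_init__(self):
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex {self.sex!r}")
        if self.family_group not in FAMILY_GROUPS:
            raise CohortError(f"unknown family group {self.family_group!r}")
        if not self.age > 0:
            raise CohortError(f"age must be positive, got {self.age}")


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "sex": r.sex,
          "family_group": r.family_group, "age": r.age} for r in records]
    )


# ---------------------------------------------------------------------------
# geometry-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the landmark-level cohort generator.

    Defaults emulate the published cohort: its cell sizes and age
    distributions, full-strength sexual dimorphism, a masculinization
    shift of the autism-parent group of 15% of the dimorphism field
    (producing small-to-medium per-distance group effects), 1 mm
    isotropic landmark jitter, a 3.5% s.d. global size factor and a
    +0.2%-per-year size trend with age.
    """

    group_sizes: dict = field(default_factory=lambda: dict(CELL_SIZES))
    age_means_sd: dict = field(default_factory=lambda: dict(CELL_AGES))
    dimorphism_scale: float = 1.0
    group_shift: float = 0.15
    noise_sd: float = 1.0     # mm, per landmark coordinate
    size_sd: float = 0.035    # s.d. of the global scale factor
    age_slope: float = 0.002  # relative size change per year of age
    seed: int = 0

    def __post_init__(self):
        for cell, n in self.group_sizes.items():
            if cell not in CELLS:
                raise CohortError(f"unknown cohort cell {cell!r}")
            if n < 0:
                raise CohortError(f"negative count for cell {cell!r}")
        if self.noise_sd < 0 or self.size_sd < 0:
            raise CohortError("noise_sd and size_sd must be >= 0")


#: Mean age about which the age trend is centred (years).
AGE_CENTER = 41.0


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[SubjectRecord], list[LandmarkSet]]:
    """Generate subject records and landmark sets for one cohort.

    Landmarks: ``template + s_sex * dimorphism + shift * dimorphism``,
    then scaled about the template centroid by the size factor
    ``(1 + size_sd * z) * (1 + age_slope * (age - 41))`` and jittered with
    isotropic Gaussian noise.  Sex scales the dimorphism field (1 for
    males, 0 for females, times ``dimorphism_scale``); the autism-parent
    group receives an extra ``group_shift`` fraction of the same field.
    """
    total = sum(config.group_sizes.values())
    if total == 0:
        raise CohortError("cohort has zero subjects")
    rng = np.random.default_rng(config.seed)
    centroid = FEMALE_TEMPLATE.mean(axis=0)

    records: list[SubjectRecord] = []
    landmark_sets: list[LandmarkSet] = []
    idx = 1
    for cell in CELLS:
        sex, grp = cell
        n = config.group_sizes.get(cell, 0)
        age_mu, age_sd = config.age_means_sd[cell]
        for _ in range(n):
            age = float(np.clip(rng.normal(age_mu, age_sd), 18.0, 90.0))
            sid = f"S{idx:04d}"
            idx += 1
            records.append(SubjectRecord(sid, sex, grp, age))

            s_sex = config.dimorphism_scale if sex == "male" else 0.0
            shift = config.group_shift if grp == "autism_parent" else 0.0
            coords = FEMALE_TEMPLATE + (s_sex + shift) * DIMORPHISM_FIELD
            scale = (1.0 + config.size_sd * rng.standard_normal()) * \
                    (1.0 + config.age_slope * (age - AGE_CENTER))
            coords = centroid + scale * (coords - centroid)
            coords = coords + config.noise_sd * rng.standard_normal((21, 3))
            landmark_sets.append(LandmarkSet.from_array(sid, coords))
    return records, landmark_sets


# ---------------------------------------------------------------------------
# distance-level generator
# ---------------------------------------------------------------------------

#: Default size-factor loadings: large facial spans follow overall face
#: size strongly, nose-region features only weakly (their feature-area
#: correlations are then 0.8 x loading, inside the published 0.12-0.56
#: band on both ends).
DEFAULT_SIZE_LOADINGS = {
    "e_nose_width": 0.30,
    "e_nasal_tip_protrusion": 0.30,
    "e_nasal_bridge_length": 0.30,
    "e_upper_lip_height": 0.30,
    "g_upper_facial_height": 0.30,
    "g_outer_canthal_width": 0.30,
    "g_forehead_width": 0.30,
    "g_mandible_height": 0.30,
    "g_upper_cheek_height_left": 0.30,
    "g_upper_cheek_height_right": 0.30,
}


@dataclass(frozen=True)
class FeatureTableConfig:
    """Parameters of the distance-level (statistical) generator.

    ``cell_stats[var]`` holds one (mean, sd) pair per cell, in CELLS
    order.  Within each cell, each distance variable (standardised) is

        x = r_age * z_age + b * z_size + u * w + residual

    with ``z_age`` the standardised age, ``z_size`` a latent size factor
    shared with facial area (so the feature-area correlation is
    ``b * area_factor_loading``), and ``w`` a within-sex masculinity
    factor whose loading pattern follows the *common* part of the
    male-female gap (its overall scale is ``masc_scale``).  The residual
    is idiosyncratic noise whose component along the *contrast* part of
    the sex gap — the part orthogonal to the all-features and size
    patterns — is shrunk by ``contrast_shrink``.  This near-deterministic
    shape contrast is what gives a discriminant the very large male-female
    separation observed empirically for adult faces (about 4.7 pooled
    within-sex s.d.) while every single feature keeps its published cell
    mean, s.d. and positive covariate correlations.

    The latent ``masculinity_score`` variable (if present in
    ``cell_stats``) loads on the same components via ``score_loadings``
    = (age, size, masculinity) loadings.
    """

    cell_stats: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in TABLE_STATS.items()}
    )
    age_means_sd: dict = field(default_factory=lambda: dict(CELL_AGES))
    group_area: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in GROUP_AREA.items()}
    )
    father_area_mean: float = 38600.0
    area_sd: float = 3800.0
    r_age: float = 0.28
    area_factor_loading: float = 0.8
    size_loadings: dict | None = None
    masc_scale: float = 0.05
    contrast_shrink: float = 0.12
    score_loadings: tuple[float, float, float] = (0.15, 0.25, 0.75)

    SCORE_VAR = "masculinity_score"

    def __post_init__(self):
        for var, stats in self.cell_stats.items():
            if len(stats) != len(CELLS):
                raise CohortError(f"{var}: need one (mean, sd) per cell")
            for (_, sd) in stats:
                if not sd > 0:
                    raise CohortError(f"{var}: sd must be > 0")
        if not -1 < self.r_age < 1:
            raise CohortError("r_age must be in (-1, 1)")
        if not 0 < self.contrast_shrink <= 1:
            raise CohortError("contrast_shrink must be in (0, 1]")
        if not 0 < self.area_factor_loading <= 1:
            raise CohortError("area_factor_loading must be in (0, 1]")
        self.design()  # validates positive residual variance

    @property
    def distance_variables(self) -> list[str]:
        return [v for v in self.cell_stats if v != self.SCORE_VAR]

    def _size_loading(self, var: str) -> float:
        table = self.size_loadings or DEFAULT_SIZE_LOADINGS
        return float(table.get(var, 0.45))

    def standardized_sex_gap(self) -> np.ndarray:
        """Per-distance (male - female) mean gap over pooled cell s.d.,
        averaged over family groups with the published cell weights."""
        return self._standardized_gap(axis="sex")

    def standardized_group_gap(self, sex: str) -> np.ndarray:
        """Per-distance (autism-parent - comparison) gap over pooled cell
        s.d. within one sex."""
        gaps = []
        for var in self.distance_variables:
            stats = self.cell_stats[var]
            i1 = CELLS.index((sex, "autism_parent"))
            i2 = CELLS.index((sex, "comparison_parent"))
            sd = np.sqrt((stats[i1][1] ** 2 + stats[i2][1] ** 2) / 2)
            gaps.append((stats[i1][0] - stats[i2][0]) / sd)
        return np.asarray(gaps)

    def _standardized_gap(self, axis: str) -> np.ndarray:
        gaps = []
        for var in self.distance_variables:
            stats = self.cell_stats[var]
            num = 0.0
            den = 0.0
            for grp in FAMILY_GROUPS:
                i1 = CELLS.index(("male", grp))
                i2 = CELLS.index(("female", grp))
                n = CELL_SIZES[CELLS[i1]] + CELL_SIZES[CELLS[i2]]
                sd = np.sqrt((stats[i1][1] ** 2 + stats[i2][1] ** 2) / 2)
                num += n * (stats[i1][0] - stats[i2][0]) / sd
                den += n
            gaps.append(num / den)
        return np.asarray(gaps)

    def design(self) -> dict:
        """Per-distance loading vectors (a, b, u, c) plus the unit shape
        contrast, all in standardised units.

        Raises a configuration error when the requested loadings leave
        no positive residual variance (non-positive-definite request).
        """
        varnames = self.distance_variables
        p = len(varnames)
        a = self.r_age
        b = np.array([self._size_loading(v) for v in varnames])
        gap = self.standardized_sex_gap()
        if p >= 5 and np.linalg.norm(gap) > 0:
            # orthonormal basis of the "ordinary" span: the all-features
            # direction, the size-loading pattern and the per-sex
            # family-group gap patterns.  The shape contrast carrying the
            # shrunk residual is the part of the sex gap orthogonal to
            # all of these, so group effects never leak into the
            # near-deterministic direction.
            basis = []
            for v in (np.ones(p), b,
                      self.standardized_group_gap("male"),
                      self.standardized_group_gap("female")):
                w = v.astype(float).copy()
                for s in basis:
                    w -= (s @ w) * s
                n_ = np.linalg.norm(w)
                if n_ > 1e-10:
                    basis.append(w / n_)
            common = sum((s @ gap) * s for s in basis[:2])
            delta = gap.copy()
            for s in basis:
                delta -= (s @ delta) * s
            nd = np.linalg.norm(delta)
            dhat = delta / nd if nd > 1e-12 else np.zeros(p)
            scale = np.abs(common).mean()
            u = self.masc_scale * common / scale if scale > 1e-12 \
                else np.zeros(p)
        else:
            u = np.zeros(p)
            dhat = np.zeros(p)
        c2 = 1.0 - a ** 2 - b ** 2 - u ** 2
        if (c2 <= 0).any():
            bad = varnames[int(np.argmin(c2))]
            raise CohortError(
                f"requested covariance is not positive definite "
                f"(no residual variance left for {bad!r})"
            )
        sa, sb, su = self.score_loadings
        sc2 = 1.0 - sa ** 2 - sb ** 2 - su ** 2
        if sc2 <= 0:
            raise CohortError(
                "score_loadings leave no residual variance for the score"
            )
        return {
            "variables": varnames, "a": a, "b": b, "u": u,
            "c": np.sqrt(c2), "dhat": dhat,
            "gamma": self.contrast_shrink,
            "score_c": float(np.sqrt(sc2)),
        }

    def pooled_sd(self, variable: str) -> float:
        """Cell-size-weighted pooled s.d. of one variable (all cells)."""
        stats = self.cell_stats[variable]
        num = den = 0.0
        for i, cell in enumerate(CELLS):
            n = CELL_SIZES[cell]
            num += n * stats[i][1] ** 2
            den += n
        return float(np.sqrt(num / den))

    def contrast_frame(self) -> dict:
        """mm-space machinery of the shape-contrast channel: the fixed
        covector ``wstar`` annihilated in every cell's residual, the
        vector ``q`` added back with the gamma-shrunk shared contrast,
        and the pooled per-variable s.d. vector."""
        des = self.design()
        s_pool = np.array([self.pooled_sd(v) for v in des["variables"]])
        dhat = des["dhat"]
        with np.errstate(divide="ignore", invalid="ignore"):
            wstar = np.where(s_pool > 0, dhat / s_pool, 0.0)
        n2 = float(wstar @ wstar)
        q = wstar / n2 if n2 > 0 else wstar
        return {"wstar": wstar, "q": q, "s_pool": s_pool,
                "add": s_pool * dhat}

    def expected_residual_sd(self, variable: str) -> float:
        """Analytic ANCOVA residual s.d. of ``variable`` (mm): the s.d.
        left after the cell means and the age and facial-area covariates
        are regressed out, pooled over cells with the published sizes.
        The generator's own construction — the oracle for effect-size
        recovery."""
        des = self.design()
        frame = self.contrast_frame()
        varnames = des["variables"]
        j = varnames.index(variable)
        a, b_j, u_j = des["a"], des["b"][j], des["u"][j]
        c, dhat, gamma = des["c"], des["dhat"], des["gamma"]
        C2 = np.diag(c ** 2)
        var_contrast = float(dhat @ C2 @ dhat)
        wstar, q, add = frame["wstar"], frame["q"], frame["add"]
        p = len(c)
        num = den = 0.0
        for ci, cell in enumerate(CELLS):
            S = np.diag([self.cell_stats[v][ci][1] for v in varnames])
            sd = S[j, j]
            M = (np.eye(p) - np.outer(q, wstar)) @ S
            resid_var = float((M @ C2 @ M.T)[j, j])
            var_j = sd ** 2 * (a ** 2 + b_j ** 2 + u_j ** 2) + resid_var \
                + (gamma * add[j]) ** 2 * var_contrast
            explained = sd ** 2 * (
                a ** 2 + (b_j * self.area_factor_loading) ** 2
            )
            n = CELL_SIZES[cell]
            num += n * (var_j - explained)
            den += n
        return float(np.sqrt(num / den))

    # -- derived configurations -------------------------------------------

    def null_group_effect(self) -> "FeatureTableConfig":
        """The no-group-effect null: per sex, both family groups share
        (size-weighted) pooled feature means, age distributions and
        facial-area levels, so the family-group factor carries no signal
        either directly or through the covariates.  Dimorphism and the
        within-cell covariate structure are unchanged."""
        pooled = {}
        for var, stats in self.cell_stats.items():
            new = list(stats)
            for sex in SEXES:
                ids = [i for i, c in enumerate(CELLS) if c[0] == sex]
                ns = [CELL_SIZES[CELLS[i]] for i in ids]
                mu = float(np.average([stats[i][0] for i in ids], weights=ns))
                for i in ids:
                    new[i] = (mu, stats[i][1])
            pooled[var] = tuple(new)
        ages = dict(self.age_means_sd)
        for sex in SEXES:
            cells = [c for c in CELLS if c[0] == sex]
            ns = np.array([CELL_SIZES[c] for c in cells], dtype=float)
            mus = np.array([ages[c][0] for c in cells])
            sds = np.array([ages[c][1] for c in cells])
            mu = float(np.average(mus, weights=ns))
            sd = float(np.sqrt(np.average(sds ** 2, weights=ns)))
            for c in cells:
                ages[c] = (mu, sd)
        ns = np.array([sum(CELL_SIZES[c] for c in CELLS if c[1] == g)
                       for g in FAMILY_GROUPS], dtype=float)
        areas = np.array([self.group_area[g][0] for g in FAMILY_GROUPS])
        area_sds = np.array([self.group_area[g][1] for g in FAMILY_GROUPS])
        area_mu = float(np.average(areas, weights=ns))
        area_sd = float(np.sqrt(np.average(area_sds ** 2, weights=ns)))
        group_area = {g: (area_mu, area_sd) for g in FAMILY_GROUPS}
        return replace(self, cell_stats=pooled, age_means_sd=ages,
                       group_area=group_area)

    def with_group_effect(self, variable: str, d: float) -> "FeatureTableConfig":
        """Inject a known covariate-adjusted standardized group effect on
        one variable: starting from the null, both autism-parent cells
        are shifted by ``d`` times the analytic residual s.d."""
        base = self.null_group_effect()
        stats = list(base.cell_stats[variable])
        shift = d * base.expected_residual_sd(variable)
        for i, c in enumerate(CELLS):
            if c[1] == "autism_parent":
                stats[i] = (stats[i][0] + shift, stats[i][1])
        new_stats = dict(base.cell_stats)
        new_stats[variable] = tuple(stats)
        return replace(base, cell_stats=new_stats)


def generate_feature_table(config: FeatureTableConfig | None = None,
                           group_sizes: dict | None = None,
                           seed: int = 0
                           ) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    """Draw a cohort feature table from the distance-level model.

    Returns a table with subject metadata (sex, family_group, age),
    facial_area and one column per configured variable, plus the
    corresponding subject records.  Empirical cell means converge to the
    configured means as cell sizes grow.
    """
    config = config or FeatureTableConfig()
    sizes = dict(CELL_SIZES) if group_sizes is None else dict(group_sizes)
    if sum(sizes.values()) == 0:
        raise CohortError("cohort has zero subjects")
    rng = np.random.default_rng(seed)

    des = config.design()
    frame = config.contrast_frame()
    varnames = des["variables"]
    p = len(varnames)
    a, b, u, c = des["a"], des["b"], des["u"], des["c"]
    dhat, gamma = des["dhat"], des["gamma"]
    b_area = config.area_factor_loading
    c_area = float(np.sqrt(1.0 - b_area ** 2))
    sa, sb, su = config.score_loadings
    sc = des["score_c"]
    has_score = config.SCORE_VAR in config.cell_stats

    frames = []
    records: list[SubjectRecord] = []
    idx = 1
    for ci, cell in enumerate(CELLS):
        sex, grp = cell
        n = sizes.get(cell, 0)
        if n == 0:
            continue
        age_mu, age_sd = config.age_means_sd[cell]
        area_mu = _cell_area_mean(config, cell)

        z_age = rng.standard_normal(n)
        z_size = rng.standard_normal(n)
        w = rng.standard_normal(n)
        eps = rng.standard_normal((n, p))
        eps_area = rng.standard_normal(n)
        eps_score = rng.standard_normal(n)

        age = np.clip(age_mu + age_sd * z_age, 18.0, 90.0)
        area = area_mu + config.area_sd * (b_area * z_size + c_area * eps_area)
        # per-cell mm residual with the fixed contrast covector
        # annihilated, plus the gamma-shrunk shared contrast channel —
        # the same near-deterministic mm direction in every cell
        sd_cell = np.array([config.cell_stats[v][ci][1] for v in varnames])
        scaled = eps * c[None, :]
        eps_contrast = scaled @ dhat
        resid_mm = scaled * sd_cell[None, :]
        resid_mm -= np.outer(resid_mm @ frame["wstar"], frame["q"])
        resid_mm += gamma * np.outer(eps_contrast, frame["add"])
        z = (a * z_age[:, None] + np.outer(z_size, b) + np.outer(w, u))

        ids = [f"S{i:04d}" for i in range(idx, idx + n)]
        idx += n
        records.extend(
            SubjectRecord(s, sex, grp, float(ag)) for s, ag in zip(ids, age)
        )
        data = {"subject_id": ids, "sex": sex, "family_group": grp,
                "age": age, "facial_area": area}
        for j, var in enumerate(varnames):
            mu, sd = config.cell_stats[var][ci]
            data[var] = mu + sd * z[:, j] + resid_mm[:, j]
        if has_score:
            mu, sd = config.cell_stats[config.SCORE_VAR][ci]
            data[config.SCORE_VAR] = mu + sd * (
                sa * z_age + sb * z_size + su * w + sc * eps_score
            )
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)
    return table, records


def _cell_area_mean(config: FeatureTableConfig, cell) -> float:
    """Sex-specific facial-area cell means that reproduce the published
    per-family-group means under the group's father/mother mix."""
    sex, grp = cell
    n_m = CELL_SIZES[("male", grp)]
    n_f = CELL_SIZES[("female", grp)]
    grp_mean = config.group_area[grp][0]
    father = config.father_area_mean
    if sex == "male":
        return father
    return (grp_mean * (n_m + n_f) - n_m * father) / n_f


# ---------------------------------------------------------------------------
# fixture meshes
# ---------------------------------------------------------------------------

def fixture_mesh(kind: str, resolution: int | None = None,
                 landmarks: LandmarkSet | None = None) -> FaceMesh:
    """Geometric fixture surfaces for oracle tests.

    kind:
        ``plane`` — flat triangulated 100 x 100 mm rectangle
        (``resolution`` = grid points per side, default 25);
        ``unit_sphere`` — icosphere of radius 1 (``resolution`` =
        subdivision level, default 4);
        ``face_template`` — the analytic face surface (``resolution``
        controls grid density, default 18), deformed to interpolate
        ``landmarks`` when given.
    """
    if kind == "plane":
        n = resolution or 25
        if n < 2:
            raise CohortError("plane resolution must be >= 2")
        xs = np.linspace(0.0, 100.0, n)
        X, Y = np.meshgrid(xs, xs)
        V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                tris.append([a, a + 1, a + n + 1])
                tris.append([a, a + n + 1, a + n])
        return FaceMesh(V, np.asarray(tris, dtype=np.int64))
    if kind == "unit_sphere":
        import trimesh

        sub = 4 if resolution is None else resolution
        tm = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        return FaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if kind == "face_template":
        res = resolution or 18
        if landmarks is None:
            return template_mesh(resolution=res)
        return subject_mesh(landmarks, resolution=res)
    raise CohortError(f"unknown fixture kind {kind!r}")


__all__ = [
    "SubjectRecord", "CohortConfig", "FeatureTableConfig",
    "generate_cohort", "generate_feature_table", "fixture_mesh",
    "records_to_frame", "CELLS", "CELL_SIZES", "CELL_AGES",
    "TABLE_STATS", "GROUP_AREA", "CohortError", "SEXES", "FAMILY_GROUPS",
]
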