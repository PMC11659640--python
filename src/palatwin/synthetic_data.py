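"""Synthetic twin cohorts and parametric palate casts with known ground truth.

Two generators make every downstream stage testable without any external
data:

* :func:`simulate_twin_traits` draws twin-pair trait values from the
  bivariate-normal classical twin model.  Standardized variance components
  A (additive genetic), C (shared environment), D (dominance genetic) and
  E (non-shared environment) imply within-pair correlations

      r_MZ = A + C + D          r_DZ = A/2 + C + D/4

  because additive and dominance genetic effects correlate 1 in monozygotic
  pairs and 0.5 / 0.25 in dizygotic pairs, while the shared environment
  correlates 1 in both.  Traits are simulated directly at the trait level;
  the classical twin model only constrains second moments, so this matches
  the structural model's assumptions exactly.

* :func:`generate_palate_mesh` builds a laterally tapered superellipse dome
  emulating a palatal vault, with landmarks placed so that the ground-truth
  widths, depths and antero-posterior length are exactly the requested
  parameters; reference area and volume come from high-resolution quadrature
  of the same parametric surface.

Default simulation parameters reproduce the study conditions this package
models: 104 MZ + 124 DZ pairs followed over primary, mixed and permanent
dentition stages with attrition to 170 pairs, and per-stage trait means,
standard deviations and variance components typical of palatal dimensions
in children of those ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import trimesh
from scipy.integrate import quad
from scipy.special import beta as beta_fn, roots_jacobi

from .io_formats import (
    LandmarkSet,
    RAPHE_NAMES,
    STAGE_TEETH,
    STAGES,
    TERMINAL_TEETH,
    TRAIT_NAMES,
    WIDTH_TEETH,
    antimere_map,
    cohort_to_frame,
    CohortRecord,
)
from .palate_geometry import PalatalTraits


class SpecError(ValueError):
    """Invalid simulation specification."""


# ---------------------------------------------------------------------------
# twin trait simulation


@dataclass(frozen=True)
class SimulationSpec:
    """One trait's twin simulation at one dentition stage."""

    n_mz: int
    n_dz: int
    components: Mapping[str, float]
    trait_mean: float = 0.0
    trait_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        comp = {k: float(self.components.get(k, 0.0)) for k in "ACDE"}
        if any(v < 0 for v in comp.values()):
            raise SpecError("variance components must be non-negative")
        if abs(sum(comp.values()) - 1.0) > 1e-12:
            raise SpecError("components A + C + D + E must sum to 1")
        if comp["C"] > 0 and comp["D"] > 0:
            raise SpecError(
                "C and D cannot both be positive: they are not separately "
                "identifiable from twins raised together"
            )
        if self.n_mz < 0 or self.n_dz < 0:
            raise SpecError("pair counts must be non-negative")
        if self.trait_sd <= 0:
            raise SpecError("trait_sd must be positive")
        object.__setattr__(self, "components", comp)

    @property
    def r_mz(self) -> float:
        c = self.components
        return c["A"] + c["C"] + c["D"]

    @property
    def r_dz(self) -> float:
        c = self.components
        return 0.5 * c["A"] + c["C"] + 0.25 * c["D"]


def _draw_pairs(
    n: int, mean: float, sd: float, r: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) bivariate-normal pairs with exchangeable correlation r."""
    cov = sd * sd * np.array([[1.0, r], [r, 1.0]])
    return rng.multivariate_normal([mean, mean], cov, size=n)


def simulate_twin_traits(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (mz_pairs, dz_pairs) value arrays of shape (n, 2).

    Deterministic given ``spec.seed`` (or an explicit generator).
    """
    if rng is None:
        if spec.seed is None:
            raise SpecError("simulation requires a seed or an explicit generator")
        rng = np.random.default_rng(spec.seed)
    mz = _draw_pairs(spec.n_mz, spec.trait_mean, spec.trait_sd, spec.r_mz, rng)
    dz = _draw_pairs(spec.n_dz, spec.trait_mean, spec.trait_sd, spec.r_dz, rng)
    return mz, dz


#: per-stage trait means and SDs used as simulator defaults (trait units)
DEFAULT_STAGE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "primary": {
        "area": (753.7, 78.4), "volume": (2630.1, 471.7),
        "anterior_width": (22.1, 1.9), "posterior_width": (27.4, 2.1),
        "anterior_depth": (4.6, 1.2), "posterior_depth": (10.6, 1.3),
        "ap_length": (25.3, 1.6),
    },
    "mixed": {
        "area": (1240.7, 116.2), "volume": (5338.2, 905.0),
        "anterior_width": (24.7, 1.9), "posterior_width": (31.9, 2.3),
        "anterior_depth": (4.5, 1.3), "posterior_depth": (10.6, 1.7),
        "ap_length": (35.8, 2.1),
    },
    "permanent": {
        "area": (1266.8, 146.1), "volume": (6169.4, 1121.5),
        "anterior_width": (23.9, 2.1), "posterior_width": (33.5, 2.8),
        "anterior_depth": (4.7, 1.6), "posterior_depth": (13.2, 2.1),
        "ap_length": (34.9, 2.3),
    },
}

#: per-stage standardized variance components used as simulator defaults
DEFAULT_STAGE_COMPONENTS: dict[str, dict[str, dict[str, float]]] = {
    "primary": {
        "area": {"A": 0.37, "C": 0.32, "E": 0.31},
        "volume": {"A": 0.37, "C": 0.38, "E": 0.25},
        "anterior_width": {"A": 0.84, "E": 0.16},
        "posterior_width": {"A": 0.85, "E": 0.15},
        "anterior_depth": {"A": 0.70, "E": 0.30},
        "posterior_depth": {"A": 0.89, "E": 0.11},
        "ap_length": {"A": 0.73, "E": 0.27},
    },
    "mixed": {
        "area": {"A": 0.53, "E": 0.47},
        "volume": {"A": 0.68, "E": 0.32},
        "anterior_width": {"A": 0.76, "E": 0.24},
        "posterior_width": {"A": 0.82, "E": 0.18},
        "anterior_depth": {"A": 0.78, "E": 0.22},
        "posterior_depth": {"A": 0.89, "E": 0.11},
        "ap_length": {"A": 0.75, "E": 0.25},
    },
    "permanent": {
        "area": {"A": 0.56, "E": 0.44},
        "volume": {"A": 0.82, "E": 0.18},
        "anterior_width": {"A": 0.69, "E": 0.31},
        "posterior_width": {"A": 0.86, "E": 0.14},
        "anterior_depth": {"A": 0.70, "E": 0.30},
        "posterior_depth": {"A": 0.86, "E": 0.14},
        "ap_length": {"A": 0.83, "E": 0.17},
    },
}

#: default per-stage pair counts (MZ, DZ): cohort of 228 pairs with attrition
DEFAULT_STAGE_PAIRS = {"primary": (104, 124), "mixed": (103, 122), "permanent": (78, 92)}

#: default mean twin age (years) at each stage
DEFAULT_STAGE_AGES = {"primary": 5.8, "mixed": 9.4, "permanent": 14.3}


def default_stage_specs(
    n_pairs: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, dict[str, SimulationSpec]]:
    """Per-stage, per-trait simulation specs at the default study conditions."""
    if n_pairs is None:
        n_pairs = DEFAULT_STAGE_PAIRS
    out: dict[str, dict[str, SimulationSpec]] = {}
    for stage in STAGES:
        n_mz, n_dz = n_pairs[stage]
        out[stage] = {}
        for trait in TRAIT_NAMES:
            mean, sd = DEFAULT_STAGE_MOMENTS[stage][trait]
            out[stage][trait] = SimulationSpec(
                n_mz=n_mz, n_dz=n_dz,
                components=DEFAULT_STAGE_COMPONENTS[stage][trait],
                trait_mean=mean, trait_sd=sd,
            )
    return out


def simulate_longitudinal_cohort(
    specs: Mapping[str, Mapping[str, SimulationSpec]],
    seed: int,
):
    """Simulate a three-stage twin cohort as a long-format table.

    ``specs`` maps stage -> trait -> :class:`SimulationSpec`.  Pair counts per
    stage come from the specs (identical across traits within a stage) and
    must be non-increasing over stages; attrition removes whole pairs
    uniformly at random within zygosity (missing completely at random).
    Each trait is drawn independently at each stage; within-pair correlation
    follows each trait's components, stage-to-stage correlation is not
    modelled.  Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    stages = [s for s in STAGES if s in specs]
    counts: dict[str, tuple[int, int]] = {}
    for stage in stages:
        per_trait = {(sp.n_mz, sp.n_dz) for sp in specs[stage].values()}
        if len(per_trait) != 1:
            raise SpecError(f"pair counts differ across traits at stage {stage!r}")
        counts[stage] = per_trait.pop()
    base_mz, base_dz = counts[stages[0]]
    for stage in stages[1:]:
        if counts[stage][0] > base_mz or counts[stage][1] > base_dz:
            raise SpecError("pair counts may not grow at later stages")

    families = [
        {"family_id": f"MZ{i:04d}", "zygosity": "MZ"} for i in range(base_mz)
    ] + [
        {"family_id": f"DZ{i:04d}", "zygosity": "DZ"} for i in range(base_dz)
    ]
    # twins of a pair share sex (same-sex pairs keep MZ/DZ comparable)
    for fam in families:
        fam["sex"] = "M" if rng.random() < 0.5 else "F"

    records: list[CohortRecord] = []
    retained_mz = np.arange(base_mz)
    retained_dz = np.arange(base_dz)
    for stage in stages:
        n_mz, n_dz = counts[stage]
        retained_mz = np.sort(rng.choice(retained_mz, size=n_mz, replace=False))
        retained_dz = np.sort(rng.choice(retained_dz, size=n_dz, replace=False))
        draws = {}
        for trait in specs[stage]:
            sp = specs[stage][trait]
            draws[trait] = simulate_twin_traits(sp, rng)
        age0 = DEFAULT_STAGE_AGES.get(stage, 0.0)
        for zi, (zyg, retained) in enumerate(
            (("MZ", retained_mz), ("DZ", retained_dz))
        ):
            for row, fam_i in enumerate(retained):
                fam = families[int(fam_i) + (base_mz if zyg == "DZ" else 0)]
                age = age0 + rng.normal(0.0, 0.5)
                for member in (0, 1):
                    traits = {
                        t: float(draws[t][zi][row, member]) for t in draws
                    }
                    records.append(CohortRecord(
                        twin_id=f"{fam['family_id']}.{member + 1}",
                        family_id=fam["family_id"],
                        zygosity=zyg,
                        sex=fam["sex"],
                        stage=stage,
                        age=round(float(age), 2),
                        traits=traits,
                    ))
    return cohort_to_frame(records)


# ---------------------------------------------------------------------------
# parametric palate casts


@dataclass(frozen=True)
class PalateShapeParams:
    """Ground-truth dimensions and tessellation of one synthetic cast."""

    anterior_width: float = 22.1
    posterior_width: float = 27.4
    anterior_depth: float = 4.6
    posterior_depth: float = 10.6
    ap_length: float = 25.3
    edge_length: float = 0.5
    asymmetry: float = 0.0
    superellipse_degree: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (
            self.anterior_width, self.posterior_width, self.anterior_depth,
            self.posterior_depth, self.ap_length,
        )
        if any(d <= 0 for d in dims):
            raise SpecError("all palate dimensions must be positive")
        if self.edge_length <= 0:
            raise SpecError("target edge length must be positive")
        if self.asymmetry < 0:
            raise SpecError("asymmetry perturbation must be non-negative")


def _cosine_blend(y, y0, y1, v0, v1):
    """Smooth monotone interpolation with zero slope at both ends."""
    t = np.clip((y - y0) / (y1 - y0), 0.0, 1.0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * t))


class _VaultProfile:
    """Half-width W(y) and depth d(y) of the vault along the raphe axis.

    The cast coordinate frame: x lateral (midline at x=0), y antero-posterior
    (posterior plane at y=0, anterior positive), z vertical with the gingival
    plane at z=0 and the vault below (z < 0 interior).
    """

    def __init__(self, p: PalateShapeParams):
        self.p = p
        self.y_molar = 2.0
        self.y_canine = p.ap_length - 2.0
        self.y_tip = p.ap_length
        if self.y_canine <= self.y_molar:
            raise SpecError("ap_length too short for the molar/canine layout")

    def half_width(self, y):
        y = np.asarray(y, float)
        p = self.p
        w_post, w_ant = 0.5 * p.posterior_width, 0.5 * p.anterior_width
        mid = _cosine_blend(y, self.y_molar, self.y_canine, w_post, w_ant)
        ant = _cosine_blend(y, self.y_canine, self.y_tip, w_ant, 1.5)
        return np.where(y <= self.y_molar, w_post, np.where(y <= self.y_canine, mid, ant))

    def depth(self, y):
        y = np.asarray(y, float)
        p = self.p
        mid = _cosine_blend(y, self.y_molar, self.y_canine,
                            p.posterior_depth, p.anterior_depth)
        ant = _cosine_blend(y, self.y_canine, self.y_tip, p.anterior_depth, 0.0)
        return np.where(y <= self.y_molar, p.posterior_depth,
                        np.where(y <= self.y_canine, mid, ant))

    def surface_z(self, x, y):
        """Vault height z(x, y) <= 0 (superellipse cross-sections)."""
        w = self.half_width(y)
        d = self.depth(y)
        q = self.p.superellipse_degree
        u = np.clip(np.abs(x) / w, 0.0, 1.0)
        return -d * (1.0 - u**q) ** (1.0 / q)


def _reference_area_volume(
    prof: _VaultProfile, ny: int = 2001, nu: int = 200
) -> tuple[float, float]:
    """High-resolution quadrature of the parametric vault surface.

    Volume has the semi-closed form  c_q * int d(y) W(y) dy  with
    c_q = 2 B(1/q, 1 + 1/q) / q  (the superellipse fill factor).  The area
    integrand |r_u x r_y| has an integrable (1 - u^2)^(1/q - 1) singularity
    at the rim (the vault wall is vertical there), so the lateral integral
    uses Gauss-Jacobi quadrature with exactly that weight.
    """
    q = prof.p.superellipse_degree
    c_q = 2.0 * beta_fn(1.0 / q, 1.0 + 1.0 / q) / q
    vol = c_q * quad(
        lambda y: float(prof.depth(y) * prof.half_width(y)),
        0.0, prof.y_tip, limit=400,
    )[0]

    alpha = 1.0 / q - 1.0
    u, w = roots_jacobi(nu, alpha, alpha)
    y = np.linspace(0.0, prof.y_tip, ny)
    W = prof.half_width(y)[:, None]
    d = prof.depth(y)[:, None]
    dy = 1e-6
    Wp = ((prof.half_width(y + dy) - prof.half_width(y - dy)) / (2 * dy))[:, None]
    dp = ((prof.depth(y + dy) - prof.depth(y - dy)) / (2 * dy))[:, None]
    au = np.abs(u)[None, :]
    one_minus_u2 = (1.0 - u**2)[None, :]
    g = (1.0 - au**q) ** (1.0 / q)
    gp = -np.sign(u)[None, :] * au ** (q - 1.0) * (1.0 - au**q) ** (1.0 / q - 1.0)
    c1 = d * gp
    c2 = -d * gp * Wp * u[None, :] + W * dp * g
    c3 = W * np.ones_like(g)
    smooth = np.sqrt(c1**2 + c2**2 + c3**2) / one_minus_u2**alpha
    area = float(np.trapezoid(smooth @ w, y))
    return area, float(vol)


def _arch_positions(prof: _VaultProfile, stage: str) -> dict[str, np.ndarray]:
    """Dento-gingival landmark coordinates on the z = 0 rim."""
    p = prof.p
    teeth = sorted(STAGE_TEETH[stage])
    canine_r, _ = WIDTH_TEETH[stage]["canine"]
    molar_r, _ = WIDTH_TEETH[stage]["molar"]
    # anterior->posterior ordering by tooth number within quadrant; first
    # permanent molars (x6) sit most posteriorly in mixed dentition
    def _rank(code: str) -> float:
        if stage == "mixed":
            order = {"1": 0, "2": 1, "3": 2, "4": 3, "5": 4, "6": 5}
            return order[code[1]]
        return float(code[1])

    right = sorted({t for t in teeth if t[0] in "15"}, key=_rank)
    y_c, y_m, y_tip = prof.y_canine, prof.y_molar, prof.y_tip
    rank_c, rank_m = _rank(canine_r), _rank(molar_r)
    out: dict[str, np.ndarray] = {}
    for code in right:
        r = _rank(code)
        if r <= rank_c:
            y = y_c + (rank_c - r) / max(rank_c, 1.0) * (y_tip + 1.5 - y_c)
        elif r >= rank_m:
            y = y_m
        else:
            y = y_c + (r - rank_c) / (rank_m - rank_c) * (y_m - y_c)
        if code == canine_r:
            x = 0.5 * p.anterior_width
        elif code == molar_r:
            x = 0.5 * p.posterior_width
        else:
            x = float(prof.half_width(min(y, y_tip)))
        mirror = {"1": "2", "5": "6"}[code[0]] + code[1]
        out[f"dg_{code}"] = np.array([x, y, 0.0])
        out[f"dg_{mirror}"] = np.array([-x, y, 0.0])
    return out


def generate_palate_mesh(
    params: PalateShapeParams, stage: str = "primary"
) -> tuple[trimesh.Trimesh, LandmarkSet, PalatalTraits]:
    """Build a synthetic palatal cast with known ground-truth traits.

    Returns ``(mesh, landmarks, truth)`` where ``truth`` holds the exact
    widths/depths/length and high-resolution reference area and volume of the
    parametric surface.  With ``asymmetry == 0`` the landmark set is exactly
    bilaterally symmetric about x = 0; a positive value rotates the
    right-side dento-gingival landmarks rigidly about the raphe axis by a
    random angle scaled so the largest landmark displacement is about
    ``asymmetry`` mm (a structured left/right difference, as real casts
    show, rather than per-landmark noise).
    """
    prof = _VaultProfile(params)
    p = params

    ny = max(int(np.ceil(prof.y_tip / p.edge_length)), 8) + 1
    nu = max(int(np.ceil(p.posterior_width / p.edge_length)), 8) + 1
    y = np.linspace(0.0, prof.y_tip, ny)
    u = np.linspace(-1.0, 1.0, nu)
    Y, U = np.meshgrid(y, u, indexing="ij")
    X = prof.half_width(Y) * U
    Z = prof.surface_z(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(ny * nu).reshape(ny, nu)
    quads = np.stack(
        [idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1
    ).reshape(-1, 4)
    faces = np.vstack([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.area_faces > 1e-12)
    mesh.merge_vertices()

    rng = np.random.default_rng(p.seed)
    dg = _arch_positions(prof, stage)
    if p.asymmetry > 0:
        r_max = max(np.hypot(v[0], v[2]) for v in dg.values())
        angle = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0]) * p.asymmetry / r_max
        ca, sa = np.cos(angle), np.sin(angle)
        rot_y = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
        for name in sorted(dg):
            if dg[name][0] > 0:  # right side only
                dg[name] = rot_y @ dg[name]

    points = dict(dg)
    points["raphe_anterior"] = np.array([0.0, prof.y_tip, 0.0])
    points["raphe_middle"] = np.array(
        [0.0, prof.y_canine, -p.anterior_depth]
    )
    points["raphe_posterior"] = np.array(
        [0.0, prof.y_molar, -p.posterior_depth]
    )
    for code in TERMINAL_TEETH[stage]:
        sign = 1.0 if code[0] in "15" else -1.0
        points[f"distal_{code}"] = np.array(
            [sign * 0.5 * p.posterior_width, 0.0, 0.0]
        )
    lm = LandmarkSet(cast_id=f"synthetic-{p.seed}", stage=stage, points=points)

    area, volume = _reference_area_volume(prof)
    truth = PalatalTraits(
        anterior_width=p.anterior_width,
        posterior_width=p.posterior_width,
        anterior_depth=p.anterior_depth,
        posterior_depth=p.posterior_depth,
        ap_length=p.ap_length,
        area=area,
        volume=volume,
    )
    return mesh, lm, truth


def drop_landmarks(lm: LandmarkSet, names: Sequence[str]) -> LandmarkSet:
    """Copy of ``lm`` with the named landmarks removed (testing missingness).

    Refuses to remove both members of an antimere pair, which downstream
    completion could not restore.
    """
    names = list(names)
    for n in names:
        if n not in lm.points:
            raise SpecError(f"cannot drop absent landmark {n!r}")
    amap = antimere_map(lm.stage)
    gone = set(names) | set(lm.missing)
    pairs = {tuple(sorted((n, amap[n]))) for n in names if amap.get(n) in gone and amap[n] != n}
    if pairs:
        raise SpecError(f"refusing to drop both antimeres: {sorted(pairs)}")
    return replace(
        lm, points={k: v for k, v in lm.points.items() if k not in names}
    )
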