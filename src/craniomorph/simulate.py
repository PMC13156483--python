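"""Synthetic cohorts of P10 mouse skull and mandible landmark configurations.

The generator emulates the statistical structure of a three-genotype
(control / loss-of-function / gain-of-function) craniofacial micro-CT study:

* bilaterally symmetric 3D templates for the cranium and the two
  hemimandibles, plus a 59-point 2D outline of the mandibular coronoid,
  condylar, and angular processes;
* genotype effects planted as percent changes on named panel measurements,
  realized by displacing the measurement-defining landmarks so the (by
  default size-normalized) measurement hits template x (1 + pct/100) exactly
  at zero noise — all effects of a genotype are solved jointly so shared
  landmarks cannot silently distort each other's targets;
* lognormal size scatter and per-coordinate isotropic Gaussian landmark noise;
* partially penetrant snout-deviation asymmetry (rightward), applied as a
  rotation of the anterior nasal landmark about the nasion;
* a genotype-specific mandibular-process dysmorphology field and an
  allometric size-shape covariation field on the outlines.

All randomness flows from one counter-based (Philox) stream per cohort, so a
spec plus a seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .io import CohortTable, LandmarkConfiguration
from .measure import (MeasurementDefinition, default_panel, polygon_area,
                      root_centroid_size)
from .schemes import CRANIUM_SCHEME, MANDIBLE_SCHEME, OUTLINE_SCHEME, LandmarkScheme


class EffectConflictError(ValueError):
    """Planted effects could not be realized jointly; message lists the clash."""


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

# Canonical head frame, mm: x mediolateral (right +), y anteroposterior
# (anterior +), z superoinferior (superior +). Magnitudes approximate a P10
# mouse; the geometry is a functional stand-in, not a measured atlas.
_CRANIUM_MIDLINE_XYZ = {
    "nasal_anterior": (0.0, 12.0, 2.0),
    "internasal_anterior": (0.0, 11.5, 2.1),
    "nasion": (0.0, 8.0, 3.0),
    "bregma": (0.0, 2.0, 5.0),
    "parietal_mid": (0.0, -1.0, 4.9),
    "lambda": (0.0, -4.0, 4.2),
    "basion": (0.0, -5.8, -1.2),
    "prosthion": (0.0, 11.0, -1.8),
    "palatine_posterior": (0.0, 2.5, -2.2),
    "frontal_crest_tip": (0.0, 4.5, 5.6),
}

_CRANIUM_RIGHT_XYZ = {
    "premaxilla_anterior": (1.2, 11.2, 0.2),
    "maxilla_anterior": (2.0, 9.0, -0.5),
    "maxilla_posterior": (2.6, 3.0, -0.8),
    "maxillary_M1": (2.5, 6.0, -1.0),
    "maxillary_M3": (2.3, 3.8, -1.1),
    "basisphenoid_rostral": (1.5, -1.0, -2.0),
    "zygoma_anterior": (3.0, 6.5, 0.5),
    "zygoma_posterior": (3.2, 0.5, 0.8),
    "frontal_orbital": (1.8, 5.5, 2.5),
}

# Right hemimandible; the left is its mirror image in x.
_MANDIBLE_RIGHT_XYZ = {
    "incisor_alveolus_superior": (1.0, 9.0, 1.0),
    "incisor_alveolus_inferior": (1.0, 8.8, -0.6),
    "molar_field_anterior": (1.5, 5.0, 1.0),
    "molar_field_posterior": (1.8, 2.0, 1.1),
    "coronoid_tip": (2.6, 0.0, 3.0),
    "coronoid_condylar_notch": (2.8, -1.2, 2.0),
    "condyle_posterior": (3.0, -2.6, 2.3),
    "condylar_angular_notch": (3.0, -1.8, 0.4),
    "angular_process_posterior": (3.2, -3.0, -0.6),
    "angular_process_inferior": (3.1, -1.8, -1.3),
    "ramus_ventral_notch": (2.6, 1.2, -0.9),
}

# Anchor polygon for the mandibular-process outline (lateral view; u runs
# anterior -> posterior, v ventral -> dorsal, mm). Smoothed to 59 points by a
# periodic spline.
_OUTLINE_ANCHORS = np.array([
    (0.0, 0.5),    # anterior ramus, base of coronoid
    (0.3, 2.2),    # coronoid anterior edge
    (0.8, 3.2),    # coronoid tip
    (1.3, 2.2),    # coronoid posterior edge
    (1.8, 1.6),    # sigmoid (coronoid-condylar) notch
    (2.6, 2.2),    # condylar neck, anterior
    (3.2, 2.6),    # condyle articular surface
    (3.6, 2.2),    # condyle posterior
    (3.4, 1.2),    # posterior ramus border
    (3.8, 0.2),    # angular process tip
    (3.2, -0.6),   # angular process inferior
    (1.8, -0.8),   # ventral border
    (0.6, -0.4),   # antegonial region
])


def make_template(structure: str) -> LandmarkConfiguration:
    """Bilaterally symmetric template for 'cranium', 'mandible' (left/right via
    :func:`make_mandible_template`), or the 59-point 'outline'."""
    if structure == "cranium":
        pts = []
        for name in CRANIUM_SCHEME.landmark_names:
            if name in _CRANIUM_MIDLINE_XYZ:
                pts.append(_CRANIUM_MIDLINE_XYZ[name])
            elif name.endswith("_R"):
                pts.append(_CRANIUM_RIGHT_XYZ[name[:-2]])
            else:
                x, y, z = _CRANIUM_RIGHT_XYZ[name[:-2]]
                pts.append((-x, y, z))
        return LandmarkConfiguration("template", np.array(pts), structure="cranium",
                                     side="whole", scheme_ref=CRANIUM_SCHEME.name)
    if structure == "mandible":
        return make_mandible_template("right")
    if structure == "outline":
        return LandmarkConfiguration("template", _outline_points(), structure="outline",
                                     side="left", scheme_ref=OUTLINE_SCHEME.name)
    raise ValueError(f"unknown structure {structure!r}")


def make_mandible_template(side: str) -> LandmarkConfiguration:
    pts = np.array([_MANDIBLE_RIGHT_XYZ[n] for n in MANDIBLE_SCHEME.landmark_names])
    if side == "left":
        pts = pts * np.array([-1.0, 1.0, 1.0])
    elif side != "right":
        raise ValueError(f"side must be left or right, got {side!r}")
    return LandmarkConfiguration("template", pts, structure="mandible", side=side,
                                 scheme_ref=MANDIBLE_SCHEME.name)


def _outline_points(n: int = 59) -> np.ndarray:
    anchors = _OUTLINE_ANCHORS
    closed = np.vstack([anchors, anchors[:1]])
    tck, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=0, per=True, k=3)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    x, y = interpolate.splev(t, tck)
    return np.column_stack([x, y])


def _gaussian_bump(points: np.ndarray, center: Sequence[float], width: float) -> np.ndarray:
    d2 = np.sum((points - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def outline_dysmorphology_field(points: np.ndarray) -> np.ndarray:
    """Unit-scale displacement field for the GOF mandibular-process phenotype.

    Shortens and flattens the coronoid process, pinches the condylar neck,
    rounds the articular surface, and tilts the angular process downward.
    Magnitudes are in mm at scale 1.
    """
    field = np.zeros_like(points)
    field += _gaussian_bump(points, (0.8, 3.2), 0.7)[:, None] * np.array([0.05, -0.55])
    field += _gaussian_bump(points, (2.6, 2.2), 0.5)[:, None] * np.array([0.22, -0.10])
    field += _gaussian_bump(points, (3.2, 2.6), 0.45)[:, None] * np.array([0.00, 0.12])
    field += _gaussian_bump(points, (3.8, 0.2), 0.7)[:, None] * np.array([0.05, -0.40])
    return field


def outline_allometry_field(points: np.ndarray) -> np.ndarray:
    """Unit displacement field for size-dependent process-shape change.

    Oriented along the negative dysmorphology direction, so smaller
    individuals (log size < 0) are displaced further toward the dysmorphic
    shape — the allometric pattern the gain-of-function phenotype shows.
    """
    field = outline_dysmorphology_field(points)
    norm = np.sqrt(np.sum(field**2))
    return -field / norm if norm > 0 else field


def outline_variation_modes(points: np.ndarray) -> np.ndarray:
    """Three smooth, unit-norm displacement fields of individual shape variation.

    Low-frequency sinusoids along the outline index, emulating the broad
    between-individual shape differences real cohorts show on top of
    genotype effects. Returns an (3, n, 2) array.
    """
    n = points.shape[0]
    t = np.arange(n) / n
    modes = np.stack([
        np.column_stack([np.sin(2 * np.pi * t), 0.6 * np.cos(2 * np.pi * t + 0.7)]),
        np.column_stack([0.5 * np.sin(4 * np.pi * t + 1.1), np.cos(4 * np.pi * t)]),
        np.column_stack([np.cos(6 * np.pi * t + 0.3), 0.8 * np.sin(6 * np.pi * t + 2.0)]),
    ])
    return modes / np.sqrt(np.sum(modes**2, axis=(1, 2)))[:, None, None]


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

def default_effect_map() -> dict[tuple[str, str], float]:
    """Genotype effect magnitudes (percent change vs control) on panel measurements.

    LOF: midface hypoplasia (shorter projected upper-jaw and maxilla lengths,
    shorter skull), wider maxillary intermolar and rostral basisphenoid
    widths, wider interorbital width, shorter molar fields. GOF: macrocephaly
    (taller frontal crest and cranial vault), shorter palate, longer
    zygomatic, micrognathia (shorter superior/inferior mandible and angular
    process), larger ventral and smaller coronoid-condylar inlet areas, wider
    bigonial width.
    """
    return {
        ("LOF", "skull_length"): -1.7,
        ("LOF", "projected_upper_jaw_length"): -4.9,
        ("LOF", "projected_maxilla_length"): -10.4,
        ("LOF", "maxillary_intermolar_width"): 8.3,
        ("LOF", "rostral_basisphenoid_width"): 14.5,
        ("LOF", "interorbital_width"): 5.6,
        ("LOF", "maxillary_molar_field_length"): -7.7,
        ("LOF", "mandibular_molar_field_length"): -6.5,
        ("GOF", "frontal_crest_height"): 6.4,
        ("GOF", "anterior_cranial_vault_height"): 4.2,
        ("GOF", "middle_cranial_vault_height"): 3.8,
        ("GOF", "posterior_cranial_vault_height"): 3.8,
        ("GOF", "palate_length"): -5.8,
        ("GOF", "projected_zygomatic_length"): 5.4,
        ("GOF", "superior_mandible_length"): -3.5,
        ("GOF", "inferior_mandible_length"): -4.4,
        ("GOF", "angular_process_inferior_length"): -12.1,
        ("GOF", "ventral_inlet_area"): 13.1,
        ("GOF", "coronoid_condylar_inlet_area"): -25.3,
        ("GOF", "bigonial_width"): 4.4,
    }


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic generator.

    Defaults reproduce the study conditions: n = 6 control, 6 LOF, 8 GOF;
    the printed percent-change effect magnitudes; landmark noise giving
    within-group CVs of roughly 1-2 percent; ~3 percent lognormal size
    scatter; rightward snout deviation in about half of the mutants; and a
    mandibular-process dysmorphology plus negative allometric slope in the
    GOF group only.
    """

    n_per_genotype: dict[str, int] = field(
        default_factory=lambda: {"control": 6, "LOF": 6, "GOF": 8})
    effect_map: dict[tuple[str, str], float] = field(default_factory=default_effect_map)
    landmark_noise_sd: float = 0.04          # mm, isotropic per coordinate
    size_sd: float = 0.03                    # lognormal sigma of the size multiplier
    asymmetry: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: {"control": (0.0, (0.0, 0.0)),
                                 "GOF": (0.375, (2.0, 10.0)),
                                 "LOF": (0.5, (2.0, 10.0))})
    outline_mode_sd: float = 0.3             # mm, per individual-variation mode
    allometry_slope: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "LOF": 0.0, "GOF": 3.0})
    outline_effect: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "LOF": 0.0, "GOF": 1.0})
    eruption_effect: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("LOF", "mandibular"): -46.5,
                                 ("LOF", "maxillary"): -36.5})
    eruption_baseline: float = 8.0           # mean unobstructed cusps in controls
    n_cusps: int = 13                        # scoreable cusp tips per jaw quadrant row
    plant_on: str = "normalized"             # "normalized" | "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_genotype.values()):
            raise ValueError("group sizes must be nonnegative")
        if self.landmark_noise_sd < 0 or self.size_sd < 0:
            raise ValueError("noise and size scatter must be nonnegative")
        for g, (pen, rng_) in self.asymmetry.items():
            if not 0.0 <= pen <= 1.0:
                raise ValueError(f"asymmetry penetrance for {g!r} must be in [0, 1]")
            if rng_[0] > rng_[1]:
                raise ValueError(f"asymmetry angle range for {g!r} is inverted")
        if self.plant_on not in ("normalized", "raw"):
            raise ValueError("plant_on must be 'normalized' or 'raw'")


@dataclass
class SpecimenTruth:
    specimen_id: str
    genotype: str
    sex: str
    effects: dict[str, float]
    size_multiplier: float
    deviation_angle_deg: float   # 0 for unaffected specimens
    asymmetric: bool


@dataclass
class GroundTruth:
    seed: int
    specimens: list[SpecimenTruth]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.specimens])


# ---------------------------------------------------------------------------
# Effect planting (joint solve)
# ---------------------------------------------------------------------------

def _panel_by_name() -> dict[str, MeasurementDefinition]:
    return {d.name: d for d in default_panel()}


def _effect_direction(defn: MeasurementDefinition, cranium: np.ndarray,
                      mandible_r: np.ndarray) -> tuple[list[tuple[str, int, np.ndarray]], str]:
    """Moving landmarks for one planted effect.

    Returns a list of (structure, landmark index, unit direction) triples that
    are displaced by ``+t x direction`` (with the left-side mirror applied
    implicitly for mandibles and handled explicitly for bilateral cranial
    stems), plus the structure name.
    """
    axis_vec = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
                "z": np.array([0, 0, 1.0])}
    moves: list[tuple[str, int, np.ndarray]] = []
    if defn.structure == "cranium":
        pts, scheme = cranium, CRANIUM_SCHEME
    else:
        pts, scheme = mandible_r, MANDIBLE_SCHEME

    def pos(name: str) -> np.ndarray:
        return pts[scheme.index(name)]

    if defn.kind == "span":
        # widen both sides symmetrically; the left mirror follows automatically
        name = defn.landmark_refs[0]
        moves.append((defn.structure, scheme.index(name), np.array([0.5, 0, 0])))
        return moves, defn.structure
    if defn.kind in ("linear", "projected"):
        refs = defn.landmark_refs
        if defn.structure == "cranium" and defn.bilateral:
            sided = [(r + "_R", r + "_L") for r in refs]
            mobile_r, mobile_l = sided[0]
            anchor_r = sided[1][0]
            if defn.kind == "projected":
                k = {"x": 0, "y": 1, "z": 2}[defn.axis]
                sign = np.sign(pos(mobile_r)[k] - pos(anchor_r)[k]) or 1.0
                direction = sign * axis_vec[defn.axis]
            else:
                direction = pos(mobile_r) - pos(anchor_r)
                direction = direction / np.linalg.norm(direction)
            moves.append(("cranium", scheme.index(mobile_r), direction))
            mirror_dir = direction * np.array([-1.0, 1.0, 1.0])
            moves.append(("cranium", scheme.index(mobile_l), mirror_dir))
            return moves, "cranium"
        mobile, anchor = refs[0], refs[1]
        if defn.structure == "cranium" and scheme.mirror_of(mobile) == anchor:
            # within-configuration bilateral width: expand both symmetrically
            direction = pos(mobile) - pos(anchor)
            direction = direction / np.linalg.norm(direction)
            moves.append(("cranium", scheme.index(mobile), 0.5 * direction))
            moves.append(("cranium", scheme.index(anchor), -0.5 * direction))
            return moves, "cranium"
        if defn.kind == "projected":
            k = {"x": 0, "y": 1, "z": 2}[defn.axis]
            sign = np.sign(pos(mobile)[k] - pos(anchor)[k]) or 1.0
            direction = sign * axis_vec[defn.axis]
        else:
            direction = pos(mobile) - pos(anchor)
            direction = direction / np.linalg.norm(direction)
        moves.append((defn.structure, scheme.index(mobile), direction))
        return moves, defn.structure
    if defn.kind == "area":
        refs = defn.landmark_refs
        verts = np.array([pos(r) for r in refs])
        mobile = refs[0]
        others = verts[1:]
        d = verts[0] - others.mean(axis=0)
        centered = verts - verts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        normal = vt[-1]
        d_inplane = d - np.dot(d, normal) * normal
        norm = np.linalg.norm(d_inplane)
        if norm == 0:
            raise EffectConflictError(f"{defn.name}: cannot derive an area direction")
        moves.append((defn.structure, scheme.index(mobile), d_inplane / norm))
        return moves, defn.structure
    raise EffectConflictError(
        f"effects on kind {defn.kind!r} measurements ({defn.name}) are not plantable")


def _measure_template(defn: MeasurementDefinition, cranium: np.ndarray,
                      mandible_r: np.ndarray, mandible_l: np.ndarray,
                      normalized: bool) -> float:
    """Evaluate one panel measurement on raw template arrays."""
    cr = LandmarkConfiguration("t", cranium, structure="cranium", side="whole",
                               scheme_ref=CRANIUM_SCHEME.name)
    mr = LandmarkConfiguration("t", mandible_r, structure="mandible", side="right",
                               scheme_ref=MANDIBLE_SCHEME.name)
    ml = LandmarkConfiguration("t", mandible_l, structure="mandible", side="left",
                               scheme_ref=MANDIBLE_SCHEME.name)
    # Measure the cranium in the same canonical frame the pipeline uses, so
    # planted projected measurements are exact after frame fitting too.
    from .measure import _measure_on_config, align_canonical

    if defn.structure == "cranium":
        cr = align_canonical(cr)

    if defn.structure == "cranium":
        if defn.bilateral:
            raw = 0.5 * (_measure_on_config(defn, cr, "left")
                         + _measure_on_config(defn, cr, "right"))
        else:
            raw = _measure_on_config(defn, cr)
        rcs = root_centroid_size(cranium)
    else:
        if defn.kind == "span":
            name = defn.landmark_refs[0]
            raw = float(np.linalg.norm(mr.point(name) - ml.point(name)))
        else:
            raw = 0.5 * (_measure_on_config(defn, mr) + _measure_on_config(defn, ml))
        rcs = 0.5 * (root_centroid_size(mandible_r) + root_centroid_size(mandible_l))
    if not normalized:
        return raw
    return raw / rcs**2 if defn.kind == "area" else raw / rcs


def apply_effects(effects: Mapping[str, float], *, plant_on: str = "normalized",
                  rel_tol: float = 1e-10) -> dict[str, np.ndarray]:
    """Solve landmark displacements so every planted measurement hits its target.

    ``effects`` maps measurement names to percent changes. Displacement
    magnitudes (one scalar per effect, along a fixed direction applied to the
    measurement's mobile landmarks) are solved jointly, so effects sharing
    landmarks remain exactly composable; an unsolvable system raises
    :class:`EffectConflictError` naming the offending measurements.

    Each affected structure additionally carries one compensation unknown
    constrained so its root centroid size equals the template's: the study
    conditions include unchanged cranial and mandibular centroid sizes, and
    without the constraint normalized-target planting would shrink or inflate
    the whole structure. The compensation rigidly translates the block of
    landmarks no planted measurement touches along the anteroposterior axis,
    which restores centroid size while leaving every unplanted measurement's
    raw value intact; when no such block exists a uniform scale is used
    instead.

    Returns {"cranium": (28,3), "mandible_right": (11,3), "mandible_left": ...}.
    """
    panel = _panel_by_name()
    cranium0 = make_template("cranium").points
    mandible_r0 = make_mandible_template("right").points
    unknown = [m for m in effects if m not in panel]
    if unknown:
        raise KeyError(f"effect map names unknown measurements: {sorted(unknown)}")
    names = list(effects)
    if not names:
        left = mandible_r0 * np.array([-1.0, 1.0, 1.0])
        return {"cranium": cranium0, "mandible_right": mandible_r0, "mandible_left": left}

    move_sets = []
    for name in names:
        moves, _ = _effect_direction(panel[name], cranium0, mandible_r0)
        move_sets.append(moves)
    normalized = plant_on == "normalized"
    targets = {}
    for name in names:
        base = _measure_template(panel[name], cranium0, mandible_r0,
                                 mandible_r0 * np.array([-1.0, 1.0, 1.0]), normalized)
        targets[name] = base * (1.0 + effects[name] / 100.0)

    mirror = np.array([-1.0, 1.0, 1.0])
    affected = {structure for moves in move_sets for structure, _, _ in moves}
    compensated = [s for s in ("cranium", "mandible") if s in affected]
    rcs0 = {"cranium": root_centroid_size(cranium0),
            "mandible": root_centroid_size(mandible_r0)}
    centers = {"cranium": cranium0.mean(axis=0), "mandible": mandible_r0.mean(axis=0)}

    # Landmarks each planted measurement touches, per structure; everything
    # else forms the compensation block (the anterior nasal tip stays fixed:
    # it carries the asymmetry phenotype and the skull-length measurement).
    touched: dict[str, set[int]] = {"cranium": set(), "mandible": set()}
    for name in names:
        defn = panel[name]
        scheme = CRANIUM_SCHEME if defn.structure == "cranium" else MANDIBLE_SCHEME
        refs = list(defn.landmark_refs)
        if defn.structure == "cranium" and defn.bilateral:
            refs = [r + side for r in defn.landmark_refs for side in ("_L", "_R")]
        touched[defn.structure].update(scheme.index(r) for r in refs)
    blocks: dict[str, np.ndarray] = {}
    shift_dirs: dict[str, np.ndarray] = {}
    for s in compensated:
        scheme = CRANIUM_SCHEME if s == "cranium" else MANDIBLE_SCHEME
        pts0 = cranium0 if s == "cranium" else mandible_r0
        free = [i for i in range(scheme.n_landmarks) if i not in touched[s]]
        pinned = {"nasal_anterior"} | set(scheme.axis_chord or ())
        free = [i for i in free
                if scheme.landmark_names[i] not in pinned]
        if scheme.axis_chord is not None:
            post, ant = scheme.axis_chord
            direction = pts0[scheme.index(ant)] - pts0[scheme.index(post)]
            direction = direction / np.linalg.norm(direction)
        else:
            direction = np.array([0.0, 1.0, 0.0])
        shift_dirs[s] = direction
        lever = sum(float((pts0[i] - centers[s]) @ direction) for i in free)
        blocks[s] = np.array(free) if free and abs(lever) > 1e-6 else None

    def build(t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cr = cranium0.copy()
        mr = mandible_r0.copy()
        for ti, moves in zip(t[:len(names)], move_sets):
            for structure, idx, direction in moves:
                if structure == "cranium":
                    cr[idx] = cr[idx] + ti * direction
                else:
                    mr[idx] = mr[idx] + ti * direction
        for s, w in zip(compensated, t[len(names):]):
            pts = cr if s == "cranium" else mr
            if blocks[s] is not None:
                pts[blocks[s]] = pts[blocks[s]] + w * shift_dirs[s]
            else:  # no free block: fall back to uniform scaling
                pts[:] = centers[s] + (pts - centers[s]) * np.exp(w)
        return cr, mr, mr * mirror

    def residuals(t: np.ndarray) -> np.ndarray:
        cr, mr, ml = build(t)
        res = [_measure_template(panel[name], cr, mr, ml, normalized)
               / targets[name] - 1.0 for name in names]
        for s in compensated:
            new = root_centroid_size(cr if s == "cranium" else mr)
            res.append(new / rcs0[s] - 1.0)
        return np.array(res)

    x0 = np.zeros(len(names) + len(compensated))
    for i, name in enumerate(names):
        base_raw = _measure_template(panel[name], cranium0, mandible_r0,
                                     mandible_r0 * mirror, False)
        if panel[name].kind != "area":
            x0[i] = base_raw * effects[name] / 100.0
    sol = optimize.least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    res = residuals(sol.x)
    if np.max(np.abs(res)) > rel_tol:
        bad = [(names + [f"{s} centroid size" for s in compensated])[i]
               for i in np.flatnonzero(np.abs(res) > rel_tol)]
        raise EffectConflictError(
            f"planted effects are not jointly realizable; residual targets missed "
            f"for: {bad} (conflicting landmark subsets?)")
    cr, mr, ml = build(sol.x)
    return {"cranium": cr, "mandible_right": mr, "mandible_left": ml}


# ---------------------------------------------------------------------------
# Specimen and cohort generation
# ---------------------------------------------------------------------------

def _rng_for(spec: CohortSpec) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(spec.seed))


def _rotate_snout(points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate the anterior nasal landmark about the canonical vertical axis
    through the nasion by ``angle_deg`` to the right (+x side).

    The rotation happens in the configuration's own canonical axial plane, so
    the snout-deviation measurement recovers exactly the planted angle.
    """
    from .measure import canonical_axes

    cfg = LandmarkConfiguration("t", points, structure="cranium", side="whole",
                                scheme_ref=CRANIUM_SCHEME.name)
    _, rot = canonical_axes(cfg)
    out = points.copy()
    i_nas = CRANIUM_SCHEME.index("nasion")
    i_ant = CRANIUM_SCHEME.index("nasal_anterior")
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    v = rot @ (out[i_ant] - out[i_nas])     # canonical coordinates
    v_rot = np.array([v[0] * c + v[1] * s, -v[0] * s + v[1] * c, v[2]])
    out[i_ant] = out[i_nas] + rot.T @ v_rot
    return out


def generate_specimen(spec: CohortSpec, genotype: str, rng: np.random.Generator,
                      specimen_id: str, *, sex: str = "unknown",
                      deviation_angle: float = 0.0,
                      templates: Mapping[str, np.ndarray] | None = None
                      ) -> tuple[list[LandmarkConfiguration], SpecimenTruth]:
    """One specimen: cranium, left/right hemimandibles, left/right outlines.

    Order of construction: genotype effects (template-level, deterministic),
    uniform size scaling, snout-deviation rotation, then landmark noise.
    """
    effects = {m: p for (g, m), p in spec.effect_map.items() if g == genotype}
    if templates is None:
        templates = apply_effects(effects, plant_on=spec.plant_on)
    size_mult = float(np.exp(rng.normal(0.0, spec.size_sd))) if spec.size_sd > 0 else 1.0

    outline0 = make_template("outline").points
    outline = outline0 + spec.outline_effect.get(genotype, 0.0) * \
        outline_dysmorphology_field(outline0)
    outline = outline + spec.allometry_slope.get(genotype, 0.0) * \
        np.log(size_mult) * outline_allometry_field(outline0)
    if spec.outline_mode_sd > 0:
        modes = outline_variation_modes(outline0)
        coeffs = rng.normal(0.0, spec.outline_mode_sd, size=modes.shape[0])
        outline = outline + np.tensordot(coeffs, modes, axes=1)

    cranium = templates["cranium"] * size_mult
    if deviation_angle != 0.0:
        cranium = _rotate_snout(cranium, deviation_angle)
    arrays = {
        ("cranium", "whole"): cranium,
        ("mandible", "left"): templates["mandible_left"] * size_mult,
        ("mandible", "right"): templates["mandible_right"] * size_mult,
        ("outline", "left"): outline * size_mult,
        ("outline", "right"): outline * size_mult * np.array([-1.0, 1.0]),
    }
    configs = []
    for (structure, side), pts in arrays.items():
        noisy = pts + rng.normal(0.0, spec.landmark_noise_sd, pts.shape) \
            if spec.landmark_noise_sd > 0 else pts
        scheme = {"cranium": CRANIUM_SCHEME, "mandible": MANDIBLE_SCHEME,
                  "outline": OUTLINE_SCHEME}[structure]
        configs.append(LandmarkConfiguration(
            specimen_id, noisy, structure=structure, side=side, genotype=genotype,
            sex=sex, scheme_ref=scheme.name))
    truth = SpecimenTruth(specimen_id=specimen_id, genotype=genotype, sex=sex,
                          effects=effects, size_multiplier=size_mult,
                          deviation_angle_deg=deviation_angle,
                          asymmetric=deviation_angle != 0.0)
    return configs, truth


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """A full cohort: per genotype, ``n`` specimens each with cranium, both
    hemimandibles, and both process outlines; asymmetry assigned to exactly
    ``round(penetrance x n)`` specimens drawn without replacement."""
    rng = _rng_for(spec)
    configs: list[LandmarkConfiguration] = []
    truths: list[SpecimenTruth] = []
    meta: dict[str, dict[str, str]] = {}
    for genotype in ("control", "LOF", "GOF"):
        n = spec.n_per_genotype.get(genotype, 0)
        if n == 0:
            continue
        effects = {m: p for (g, m), p in spec.effect_map.items() if g == genotype}
        templates = apply_effects(effects, plant_on=spec.plant_on)
        pen, (lo, hi) = spec.asymmetry.get(genotype, (0.0, (0.0, 0.0)))
        n_affected = int(np.floor(pen * n + 0.5))
        affected = set(rng.choice(n, size=n_affected, replace=False).tolist())
        # mixed-sex groups, balanced as in a managed breeding design
        sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
        rng.shuffle(sexes)
        for i in range(n):
            spec_id = f"{genotype}_{i + 1:02d}"
            sex = str(sexes[i])
            angle = float(rng.uniform(lo, hi)) if i in affected else 0.0
            cfgs, truth = generate_specimen(spec, genotype, rng, spec_id, sex=sex,
                                            deviation_angle=angle, templates=templates)
            configs.extend(cfgs)
            truths.append(truth)
            meta[spec_id] = {"genotype": genotype, "sex": sex}
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    metadata.index.name = "specimen_id"
    return (CohortTable(configurations=configs, metadata=metadata),
            GroundTruth(seed=spec.seed, specimens=truths))


def generate_cusp_table(spec: CohortSpec, truth: GroundTruth) -> pd.DataFrame:
    """Cusp eruption states per specimen and jaw, targeting the group mean
    unobstructed counts implied by ``eruption_effect`` (percent vs control)."""
    rng = np.random.Generator(np.random.Philox([spec.seed, 1]))
    rows = []
    for s in truth.specimens:
        for jaw in ("mandibular", "maxillary"):
            pct = spec.eruption_effect.get((s.genotype, jaw), 0.0)
            target = spec.eruption_baseline * (1.0 + pct / 100.0)
            count = int(np.clip(np.floor(target + rng.normal(0.0, 0.7) + 0.5),
                                0, spec.n_cusps))
            for cusp in range(spec.n_cusps):
                if cusp < count:
                    state = "fully_unobstructed"
                elif cusp < count + (spec.n_cusps - count + 1) // 2:
                    state = "partially_covered"
                else:
                    state = "covered"
                rows.append({"specimen_id": s.specimen_id, "jaw": jaw,
                             "cusp_id": f"c{cusp + 1:02d}", "state": state})
    return pd.DataFrame(rows)
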