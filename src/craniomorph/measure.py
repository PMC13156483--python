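"""Traditional landmark morphometrics: the measurement panel and its primitives.

Implements root centroid size, linear / projected / angular measurements,
snout-deviation grading against a control reference set, bilateral averaging,
centroid-size normalization, and molar-eruption scoring.

Measurement kinds
-----------------
``linear``     Euclidean distance between two landmarks.
``projected``  Distance between parallel planes through two landmarks,
               i.e. |coordinate difference| along a canonical-frame axis.
``angular``    Angle at a vertex landmark, degrees in [0, 180].
``area``       Magnitude of the vector area of a landmark polygon.
``span``       Distance between the same landmark on the left and right
               configurations of a paired structure (e.g. bigonial width).
``deviation``  Signed axial-plane angle of a point off the midsagittal
               plane about a vertex (snout deviation; right positive).
``count``      Placeholder for tally phenotypes; scored from cusp state
               tables via :func:`eruption_score`, not from landmarks.

Lengths are normalized by the structure's root centroid size (RCS), areas by
RCS squared; angles are never normalized. Projected and deviation measurements
assume the configuration is in the canonical head frame (midsagittal plane at
x = 0, anteroposterior y, superoinferior z); :func:`align_canonical` fits that
frame from the midline landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CohortTable, LandmarkConfiguration
from .schemes import LandmarkScheme, get_scheme

MEASUREMENT_KINDS = ("linear", "projected", "angular", "area", "span", "deviation", "count")


@dataclass(frozen=True)
class MeasurementDefinition:
    """A declarative rule mapping landmark names to a scalar phenotype.

    For bilateral cranial measurements ``landmark_refs`` hold side-less stems
    that resolve to ``<stem>_L`` / ``<stem>_R``; for hemimandible measurements
    they are plain names evaluated once per side. The first ref is the
    conventionally "mobile" landmark used when the synthetic generator plants
    an effect on this measurement.
    """

    name: str
    kind: str
    landmark_refs: tuple[str, ...]
    structure: str = "cranium"
    axis: str | None = None  # projected only: "x" | "y" | "z"
    bilateral: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        n = len(self.landmark_refs)
        if self.kind in ("linear", "projected") and n != 2:
            raise ValueError(f"{self.name}: {self.kind} needs 2 landmarks, got {n}")
        if self.kind in ("angular", "deviation") and n != 3:
            raise ValueError(f"{self.name}: {self.kind} needs 3 landmarks (middle = vertex)")
        if self.kind == "area" and n < 3:
            raise ValueError(f"{self.name}: area needs >= 3 landmarks")
        if self.kind == "span" and n != 1:
            raise ValueError(f"{self.name}: span needs exactly 1 landmark")
        if (self.axis is not None) != (self.kind == "projected"):
            raise ValueError(f"{self.name}: axis must be given iff kind is 'projected'")
        if self.axis is not None and self.axis not in ("x", "y", "z"):
            raise ValueError(f"{self.name}: axis must be x, y, or z")

    def resolve(self, scheme: LandmarkScheme, side: str | None = None) -> tuple[str, ...]:
        """Resolve refs (appending _L/_R for bilateral cranial stems) and check them."""
        refs = self.landmark_refs
        if self.bilateral and side in ("left", "right") and self.structure == "cranium":
            suffix = "_L" if side == "left" else "_R"
            refs = tuple(r + suffix for r in refs)
        missing = [r for r in refs if r not in scheme.landmark_names]
        if missing:
            raise KeyError(f"measurement {self.name!r}: landmarks {missing} "
                           f"not in scheme {scheme.name!r}")
        return refs


@dataclass
class MeasurementValue:
    specimen_id: str
    measurement: str
    raw: float            # mm, mm^2, or degrees
    normalized: float | None  # raw / RCS (lengths) or raw / RCS^2 (areas); None for angles
    side: str             # left | right | bilateral-mean | midline | single-left | single-right
    genotype: str = "control"
    degenerate: bool = False


@dataclass
class AsymmetryGrade:
    specimen_id: str
    deviation_deg: float  # signed, right positive
    grade: str            # none | mild | pronounced
    genotype: str = "control"


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def root_centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Root centroid size: sqrt of summed squared distances of landmarks from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if pts.size == 0:
        raise ValueError("cannot compute centroid size of an empty configuration")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered * centered)))


def linear_distance(config: LandmarkConfiguration, a: str, b: str) -> float:
    if a == b:
        raise ValueError(f"linear distance needs two distinct landmarks, got {a!r} twice")
    return float(np.linalg.norm(config.point(a) - config.point(b)))


def projected_distance(config: LandmarkConfiguration, a: str, b: str, axis: str) -> float:
    """Distance between parallel planes normal to *axis* through landmarks a and b."""
    try:
        k = _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}") from None
    if k >= config.dimension:
        raise ValueError(f"axis {axis!r} not available in a {config.dimension}D configuration")
    return float(abs(config.point(a)[k] - config.point(b)[k]))


def angle_at_vertex(config: LandmarkConfiguration, a: str, vertex: str, b: str,
                    *, on_degenerate: str = "zero") -> tuple[float, bool]:
    """Angle a-vertex-b in degrees, in [0, 180].

    Returns ``(angle, degenerate)``. A zero-length arm is degenerate: policy
    ``"zero"`` (default) returns 0 with the flag set, ``"raise"`` raises.
    """
    u = config.point(a) - config.point(vertex)
    v = config.point(b) - config.point(vertex)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        if on_degenerate == "raise":
            raise ValueError(f"degenerate angle {a}-{vertex}-{b}: zero-length arm")
        return 0.0, True
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))), False


def polygon_area(points: np.ndarray) -> float:
    """Area of a (possibly 3D) landmark polygon as the magnitude of its vector area."""
    pts = np.asarray(points, float)
    if pts.shape[0] < 3:
        raise ValueError("polygon area needs >= 3 points")
    if pts.shape[1] == 2:
        x, y = pts[:, 0], pts[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)
    total = np.zeros(3)
    for i in range(pts.shape[0]):
        total += np.cross(pts[i], pts[(i + 1) % pts.shape[0]])
    return float(np.linalg.norm(total) / 2.0)


def snout_deviation(config: LandmarkConfiguration,
                    midline_ref: str = "internasal_anterior",
                    vertex: str = "nasion",
                    anterior: str = "nasal_anterior",
                    *, tol: float = 1e-9) -> float:
    """Signed axial-plane angle of the anterior nasal point off the midsagittal line.

    The magnitude is the angle at the nasion between the midline reference
    point and the anterior nasal point, measured in the axial (x-y) plane of
    the canonical frame; the sign is positive when the anterior point lies to
    the right (x > 0) of the midsagittal plane. Returns 0 when the two
    anterior landmarks coincide within ``tol``.
    """
    m = config.point(midline_ref)[:2] - config.point(vertex)[:2]
    a = config.point(anterior)[:2] - config.point(vertex)[:2]
    if np.linalg.norm(config.point(anterior) - config.point(midline_ref)) <= tol:
        return 0.0
    nm, na = np.linalg.norm(m), np.linalg.norm(a)
    if nm <= tol or na <= tol:
        raise ValueError("snout deviation: anterior landmark coincides with the nasion")
    cosang = np.clip(np.dot(m, a) / (nm * na), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    sign = 1.0 if config.point(anterior)[0] > config.point(midline_ref)[0] else -1.0
    return sign * angle


# ---------------------------------------------------------------------------
# Canonical frame
# ---------------------------------------------------------------------------

def canonical_axes(config: LandmarkConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """Canonical head frame of a 3D configuration: ``(center, rotation)``.

    Rows of ``rotation`` are the canonical x (midsagittal normal, right +),
    y (anteroposterior, anterior +), and z (superoinferior, superior +) axes
    expressed in the configuration's stored frame; ``center`` is the midline
    centroid. ``(points - center) @ rotation.T`` maps into the canonical frame.
    """
    scheme = config.scheme
    if scheme is None or not scheme.midline_names:
        raise ValueError("canonical alignment needs a scheme with midline landmarks")
    if config.dimension != 3:
        raise ValueError("canonical alignment is defined for 3D configurations")
    mid = np.array([config.point(n) for n in scheme.midline_names])
    center = mid.mean(axis=0)
    centered = mid - center
    # Least-squares plane: normal = singular vector of smallest singular value.
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    x_axis = vt[2]
    if scheme.axis_chord is not None:
        # anteroposterior axis pinned by an anatomical chord, projected
        # into the midsagittal plane
        post, ant = scheme.axis_chord
        chord = config.point(ant) - config.point(post)
        chord = chord - np.dot(chord, x_axis) * x_axis
        norm = np.linalg.norm(chord)
        if norm == 0:
            raise ValueError("axis-chord landmarks coincide; cannot orient the frame")
        y_axis = chord / norm
    else:
        y_axis = vt[0]
        # Orient y toward the anterior landmark.
        if scheme.anterior_name is not None:
            if np.dot(config.point(scheme.anterior_name) - center, y_axis) < 0:
                y_axis = -y_axis
    # Orient x so the right-side members of bilateral pairs average x > 0;
    # otherwise orient z upward via the superior hint. z completes the
    # right-handed frame either way.
    if scheme.bilateral_pairs:
        rights = np.array([config.point(r) for _, r in scheme.bilateral_pairs]) - center
        if np.mean(rights @ x_axis) < 0:
            x_axis = -x_axis
        z_axis = np.cross(x_axis, y_axis)
    else:
        z_axis = np.cross(x_axis, y_axis)
        if scheme.superior_name is not None:
            if np.dot(config.point(scheme.superior_name) - center, z_axis) < 0:
                x_axis, z_axis = -x_axis, -z_axis
    return center, np.stack([x_axis, y_axis, z_axis])


def align_canonical(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Rigidly move a 3D configuration into the canonical head frame.

    The midsagittal plane (least-squares plane through the midline landmarks)
    becomes x = 0 with the right side at x > 0; the in-plane principal axis of
    the midline landmarks becomes y (anterior positive, oriented by the
    scheme's anterior landmark); z completes a right-handed frame (superior
    positive, oriented by the superior landmark). Rigid only: distances,
    angles, and centroid size are unchanged.
    """
    center, rot = canonical_axes(config)
    out = config.copy()
    out.points = (config.points - center) @ rot.T
    return out


# ---------------------------------------------------------------------------
# Normalization / averaging / grading
# ---------------------------------------------------------------------------

def normalize_by_size(raw: float, rcs: float, kind: str) -> float | None:
    """Size-normalize a raw value: lengths / RCS, areas / RCS^2, angles untouched (None)."""
    if kind in ("angular", "deviation", "count"):
        return None
    if rcs <= 0:
        raise ValueError(f"centroid size must be positive, got {rcs}")
    if kind == "area":
        return raw / rcs**2
    return raw / rcs


def bilateral_mean(left: MeasurementValue | None, right: MeasurementValue | None,
                   rcs: float, kind: str) -> MeasurementValue:
    """Average left and right raw values; normalization is applied after averaging.

    With one side missing, the present side is emitted with a ``single-<side>``
    provenance flag instead of failing the specimen.
    """
    if left is None and right is None:
        raise ValueError("bilateral mean: both sides missing")
    if left is not None and right is not None:
        if left.measurement != right.measurement or left.specimen_id != right.specimen_id:
            raise ValueError("bilateral mean: sides disagree on measurement or specimen")
        raw = 0.5 * (left.raw + right.raw)
        side = "bilateral-mean"
        ref = left
    else:
        ref = left if left is not None else right
        raw = ref.raw
        side = f"single-{ref.side}"
    return MeasurementValue(specimen_id=ref.specimen_id, measurement=ref.measurement,
                            raw=raw, normalized=normalize_by_size(raw, rcs, kind),
                            side=side, genotype=ref.genotype)


def classify_asymmetry(deviations: Mapping[str, float], control_ids: Sequence[str],
                       genotypes: Mapping[str, str] | None = None,
                       *, boundary_pronounced_inclusive: bool = True
                       ) -> list[AsymmetryGrade]:
    """Grade snout deviations against the control range.

    With ``m`` the largest control deviation magnitude: ``|d| <= m`` is none,
    ``m < |d| < 2m`` is mild, and ``|d| >= 2m`` is pronounced (the ``2m``
    boundary goes to pronounced by default; set
    ``boundary_pronounced_inclusive=False`` for mild).
    """
    controls = [deviations[c] for c in control_ids if c in deviations]
    if not controls or not all(np.isfinite(controls)):
        raise ValueError("asymmetry grading needs at least one control with a finite deviation")
    m = max(abs(c) for c in controls)
    grades = []
    for spec_id, d in deviations.items():
        mag = abs(d)
        if mag <= m:
            grade = "none"
        elif mag > 2 * m or (boundary_pronounced_inclusive and mag == 2 * m):
            grade = "pronounced"
        else:
            grade = "mild"
        grades.append(AsymmetryGrade(
            specimen_id=spec_id, deviation_deg=float(d), grade=grade,
            genotype=(genotypes or {}).get(spec_id, "control")))
    return grades


def penetrance_summary(grades: Iterable[AsymmetryGrade]) -> pd.DataFrame:
    """Per-genotype counts of none/mild/pronounced grades and affected fraction."""
    df = pd.DataFrame([{"genotype": g.genotype, "grade": g.grade} for g in grades])
    counts = df.groupby("genotype")["grade"].value_counts().unstack(fill_value=0)
    for col in ("none", "mild", "pronounced"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["none", "mild", "pronounced"]]
    counts["n"] = counts.sum(axis=1)
    counts["penetrance"] = (counts["mild"] + counts["pronounced"]) / counts["n"]
    return counts.reset_index()


# ---------------------------------------------------------------------------
# Eruption scoring
# ---------------------------------------------------------------------------

CUSP_STATES = ("fully_unobstructed", "partially_covered", "covered")


def eruption_score(cusp_table: pd.DataFrame, genotypes: Mapping[str, str],
                   control: str = "control") -> pd.DataFrame:
    """Count fully unobstructed molar cusp tips per specimen and summarize per group.

    ``cusp_table`` rows: specimen_id, jaw (mandibular|maxillary), cusp_id,
    state. Returns one row per (jaw, genotype) with the mean unobstructed
    count and the percent difference vs the control group.
    """
    bad = set(cusp_table["state"]) - set(CUSP_STATES)
    if bad:
        raise ValueError(f"unknown cusp states: {sorted(bad)}")
    dup = cusp_table.duplicated(subset=["specimen_id", "jaw", "cusp_id"])
    if dup.any():
        raise ValueError("duplicate (specimen, jaw, cusp) rows in cusp table")
    per_spec = (cusp_table.assign(unobstructed=lambda d: d["state"] == "fully_unobstructed")
                .groupby(["specimen_id", "jaw"])["unobstructed"].sum().reset_index())
    per_spec["genotype"] = per_spec["specimen_id"].map(dict(genotypes))
    if per_spec["genotype"].isna().any():
        missing = sorted(per_spec.loc[per_spec["genotype"].isna(), "specimen_id"])
        raise ValueError(f"specimens without genotype: {missing}")
    summary = (per_spec.groupby(["jaw", "genotype"])["unobstructed"]
               .agg(["mean", "std", "count"]).reset_index()
               .rename(columns={"mean": "mean_count", "std": "sd_count", "count": "n"}))
    ctrl_means = summary[summary["genotype"] == control].set_index("jaw")["mean_count"]
    summary["percent_diff_vs_control"] = [
        (row["mean_count"] - ctrl_means[row["jaw"]]) / ctrl_means[row["jaw"]] * 100.0
        if ctrl_means.get(row["jaw"], 0) != 0 else np.nan
        for _, row in summary.iterrows()]
    return summary


# ---------------------------------------------------------------------------
# The default measurement panel
# ---------------------------------------------------------------------------

def default_panel() -> list[MeasurementDefinition]:
    """The package's cranial and mandibular measurement panel.

    Names mirror the phenotypes of the mouse craniofacial study the package
    models: projected jaw lengths, transverse widths, vault heights, palate
    length, zygomatic length, molar field lengths, mandibular lengths and
    inlet areas, bigonial width, and the snout-deviation angle. The first
    landmark in each ref tuple is the one the synthetic generator displaces
    when planting an effect on that measurement.
    """
    M = MeasurementDefinition
    return [
        # Cranium
        # mobile landmark first: the nasal tip is in no other length measurement
        M("skull_length", "linear", ("nasal_anterior", "basion")),
        M("projected_upper_jaw_length", "projected",
          ("premaxilla_anterior", "maxilla_posterior"), axis="y", bilateral=True),
        M("projected_maxilla_length", "projected",
          ("maxilla_anterior", "maxilla_posterior"), axis="y", bilateral=True),
        M("maxillary_intermolar_width", "linear", ("maxillary_M1_L", "maxillary_M1_R")),
        M("rostral_basisphenoid_width", "linear",
          ("basisphenoid_rostral_L", "basisphenoid_rostral_R")),
        M("interorbital_width", "linear", ("frontal_orbital_L", "frontal_orbital_R")),
        M("frontal_crest_height", "projected", ("frontal_crest_tip", "basion"), axis="z"),
        M("anterior_cranial_vault_height", "projected", ("bregma", "basion"), axis="z"),
        M("middle_cranial_vault_height", "projected", ("parietal_mid", "basion"), axis="z"),
        M("posterior_cranial_vault_height", "projected", ("lambda", "basion"), axis="z"),
        M("palate_length", "linear", ("prosthion", "palatine_posterior")),
        M("projected_zygomatic_length", "projected",
          ("zygoma_posterior", "zygoma_anterior"), axis="y", bilateral=True),
        M("maxillary_molar_field_length", "linear",
          ("maxillary_M3", "maxillary_M1"), bilateral=True),
        M("snout_deviation", "deviation", ("internasal_anterior", "nasion", "nasal_anterior")),
        # Mandible (per hemimandible, averaged across sides)
        M("superior_mandible_length", "linear",
          ("incisor_alveolus_superior", "condyle_posterior"),
          structure="mandible", bilateral=True),
        M("inferior_mandible_length", "linear",
          ("incisor_alveolus_inferior", "angular_process_posterior"),
          structure="mandible", bilateral=True),
        M("angular_process_inferior_length", "linear",
          ("ramus_ventral_notch", "angular_process_inferior"),
          structure="mandible", bilateral=True),
        M("mandibular_molar_field_length", "linear",
          ("molar_field_anterior", "molar_field_posterior"),
          structure="mandible", bilateral=True),
        M("ventral_inlet_area", "area",
          ("angular_process_inferior", "angular_process_posterior",
           "condylar_angular_notch", "ramus_ventral_notch"),
          structure="mandible", bilateral=True),
        M("coronoid_condylar_inlet_area", "area",
          ("coronoid_condylar_notch", "condyle_posterior", "coronoid_tip"),
          structure="mandible", bilateral=True),
        M("bigonial_width", "span", ("angular_process_posterior",), structure="mandible"),
    ]


def _measure_on_config(defn: MeasurementDefinition, config: LandmarkConfiguration,
                       side: str | None = None) -> float:
    refs = defn.resolve(config.scheme, side)
    if defn.kind == "linear":
        return linear_distance(config, *refs)
    if defn.kind == "projected":
        return projected_distance(config, *refs, axis=defn.axis)
    if defn.kind == "angular":
        angle, _ = angle_at_vertex(config, refs[0], refs[1], refs[2])
        return angle
    if defn.kind == "deviation":
        return snout_deviation(config, refs[0], refs[1], refs[2])
    if defn.kind == "area":
        return polygon_area(np.array([config.point(r) for r in refs]))
    raise ValueError(f"kind {defn.kind!r} not computable on a single configuration")


def compute_panel(cohort: CohortTable, definitions: Sequence[MeasurementDefinition],
                  *, align: bool = True) -> list[MeasurementValue]:
    """Evaluate the measurement panel for every specimen of a cohort.

    One value per (specimen, measurement); bilateral measurements are computed
    per side and averaged before normalization. Per-specimen failures are
    aggregated and reported together rather than silently dropped.
    """
    values: list[MeasurementValue] = []
    failures: list[str] = []
    for spec_id in cohort.specimen_ids():
        genotype = cohort.genotype_of(spec_id)
        crania = [c for c in cohort.select(structure="cranium") if c.specimen_id == spec_id]
        mands = {c.side: c for c in cohort.select(structure="mandible")
                 if c.specimen_id == spec_id}
        cranium = crania[0] if crania else None
        if cranium is not None and align:
            cranium = align_canonical(cranium)
        cr_rcs = root_centroid_size(cranium) if cranium is not None else None
        md_rcs = {s: root_centroid_size(c) for s, c in mands.items()}
        md_rcs_mean = float(np.mean(list(md_rcs.values()))) if md_rcs else None

        for defn in definitions:
            if defn.kind == "count":
                raise ValueError(
                    f"{defn.name}: count measurements are scored from cusp state "
                    "tables via eruption_score, not from landmarks")
            try:
                if defn.structure == "cranium":
                    if cranium is None:
                        continue
                    rcs = cr_rcs
                    if defn.bilateral:
                        sides = {}
                        for side in ("left", "right"):
                            raw = _measure_on_config(defn, cranium, side)
                            sides[side] = MeasurementValue(spec_id, defn.name, raw, None,
                                                           side, genotype)
                        values.append(bilateral_mean(sides["left"], sides["right"],
                                                     rcs, defn.kind))
                    else:
                        raw = _measure_on_config(defn, cranium)
                        side = "midline" if defn.kind in ("deviation",) else "whole"
                        values.append(MeasurementValue(
                            spec_id, defn.name, raw,
                            normalize_by_size(raw, rcs, defn.kind), side, genotype))
                else:  # mandible
                    if not mands:
                        continue
                    if defn.kind == "span":
                        if "left" not in mands or "right" not in mands:
                            raise ValueError(f"{defn.name}: needs both hemimandibles")
                        name = defn.landmark_refs[0]
                        raw = float(np.linalg.norm(
                            mands["left"].point(name) - mands["right"].point(name)))
                        values.append(MeasurementValue(
                            spec_id, defn.name, raw,
                            normalize_by_size(raw, md_rcs_mean, "linear"),
                            "bilateral-mean", genotype))
                    else:
                        side_vals = {s: MeasurementValue(
                            spec_id, defn.name, _measure_on_config(defn, c), None, s, genotype)
                            for s, c in mands.items()}
                        values.append(bilateral_mean(side_vals.get("left"),
                                                     side_vals.get("right"),
                                                     md_rcs_mean, defn.kind))
            except (ValueError, KeyError) as exc:
                failures.append(f"{spec_id}/{defn.name}: {exc}")
        # centroid sizes reported as raw phenotypes of their own
        if not definitions:
            continue
        if cranium is not None:
            values.append(MeasurementValue(spec_id, "cranial_centroid_size",
                                           cr_rcs, None, "whole", genotype))
        if md_rcs_mean is not None:
            values.append(MeasurementValue(spec_id, "mandibular_centroid_size",
                                           md_rcs_mean, None, "bilateral-mean", genotype))
    if failures:
        raise ValueError("panel computation failed for:\n  " + "\n  ".join(failures))
    return values


def panel_frame(values: Iterable[MeasurementValue]) -> pd.DataFrame:
    """Panel values as a tidy DataFrame (one row per specimen x measurement)."""
    return pd.DataFrame([{
        "specimen_id": v.specimen_id, "measurement": v.measurement, "raw": v.raw,
        "normalized": v.normalized, "side": v.side, "genotype": v.genotype,
    } for v in values])
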