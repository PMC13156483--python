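"""Landmark data containers and TPS / CSV readers and writers.

Supports the tpsDig2 dialect of TPS files (``LM=``/``LM3=`` records with
``ID=`` required and ``IMAGE=``/``SCALE=`` optional) and a long-format
landmark CSV with one row per (specimen, landmark). All files are UTF-8 text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemes import LandmarkScheme, get_scheme

STRUCTURES = ("cranium", "mandible", "outline")
SIDES = ("left", "right", "whole")
GENOTYPES = ("control", "LOF", "GOF")
SEXES = ("F", "M", "unknown")


class TpsParseError(ValueError):
    """Malformed TPS record; message names the offending line."""


@dataclass
class LandmarkConfiguration:
    """One specimen side/structure's ordered landmark coordinates plus metadata.

    ``points`` is an (n_landmarks, dim) float array in mm, ordered per the
    referenced scheme (when ``scheme_ref`` is set).
    """

    specimen_id: str
    points: np.ndarray
    structure: str = "cranium"
    side: str = "whole"
    genotype: str = "control"
    sex: str = "unknown"
    scheme_ref: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError(
                f"points must be (n, 2|3); got shape {self.points.shape} "
                f"for specimen {self.specimen_id!r}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates for specimen {self.specimen_id!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.scheme_ref is not None:
            scheme = get_scheme(self.scheme_ref)
            if self.points.shape[0] != scheme.n_landmarks:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: {self.points.shape[0]} points "
                    f"but scheme {scheme.name!r} defines {scheme.n_landmarks}"
                )
            if self.points.shape[1] != scheme.dimension:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: dimension {self.points.shape[1]} "
                    f"does not match scheme {scheme.name!r} ({scheme.dimension}D)"
                )

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def scheme(self) -> LandmarkScheme | None:
        return get_scheme(self.scheme_ref) if self.scheme_ref else None

    def point(self, landmark_name: str) -> np.ndarray:
        scheme = self.scheme
        if scheme is None:
            raise ValueError(f"configuration {self.specimen_id!r} has no scheme")
        return self.points[scheme.index(landmark_name)]

    def copy(self) -> "LandmarkConfiguration":
        return dataclasses.replace(self, points=self.points.copy())


@dataclass
class CohortTable:
    """A set of configurations plus one metadata row per specimen."""

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame  # index: specimen_id; columns: genotype, sex[, body_mass]

    def __post_init__(self) -> None:
        ids = {c.specimen_id for c in self.configurations}
        missing = ids - set(self.metadata.index)
        if missing:
            raise ValueError(f"specimens without metadata rows: {sorted(missing)}")
        bad = set(self.metadata["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes in metadata: {sorted(bad)}")

    def select(self, structure: str | None = None, side: str | None = None,
               genotype: str | None = None) -> list[LandmarkConfiguration]:
        out = self.configurations
        if structure is not None:
            out = [c for c in out if c.structure == structure]
        if side is not None:
            out = [c for c in out if c.side == side]
        if genotype is not None:
            out = [c for c in out if c.genotype == genotype]
        return list(out)

    def specimen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.configurations:
            seen.setdefault(c.specimen_id, None)
        return list(seen)

    def genotype_of(self, specimen_id: str) -> str:
        return str(self.metadata.loc[specimen_id, "genotype"])


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a tpsDig2-style TPS file into configurations, preserving record order.

    Each record starts with ``LM=<n>`` (2D) or ``LM3=<n>`` (3D), followed by
    ``n`` whitespace-separated coordinate lines, then ``ID=`` (required) and
    optionally ``IMAGE=`` / ``SCALE=``. When SCALE is present the raw
    coordinates are multiplied by it.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    records: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            dim, count_str = 3, line[4:]
        elif upper.startswith("LM="):
            dim, count_str = 2, line[3:]
        else:
            raise TpsParseError(f"{path.name}:{i + 1}: expected LM=/LM3= header, got {line!r}")
        try:
            n_pts = int(count_str)
        except ValueError:
            raise TpsParseError(f"{path.name}:{i + 1}: bad landmark count {count_str!r}") from None
        i += 1
        pts = np.empty((n_pts, dim))
        for j in range(n_pts):
            if i >= n_lines:
                raise TpsParseError(
                    f"{path.name}:{i}: record ended after {j} of {n_pts} points")
            fields = lines[i].split()
            if len(fields) != dim or any(_not_number(f) for f in fields):
                raise TpsParseError(
                    f"{path.name}:{i + 1}: expected {dim} coordinates, got {lines[i]!r} "
                    f"(point count mismatch vs LM={n_pts}?)")
            pts[j] = [float(f) for f in fields]
            i += 1
        spec_id: str | None = None
        scale: float | None = None
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            upper = line.upper()
            if upper.startswith(("LM=", "LM3=")):
                break
            if upper.startswith("ID="):
                spec_id = line[3:].strip()
            elif upper.startswith("IMAGE="):
                pass
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line[6:])
                except ValueError:
                    raise TpsParseError(f"{path.name}:{i + 1}: bad SCALE value {line!r}") from None
            else:
                raise TpsParseError(f"{path.name}:{i + 1}: unrecognized line {line!r}")
            i += 1
        if spec_id is None:
            raise TpsParseError(f"{path.name}:{i}: record missing required ID= line")
        if scale is not None:
            pts = pts * scale
        records.append(LandmarkConfiguration(specimen_id=spec_id, points=pts,
                                             structure="outline" if dim == 2 else "cranium"))
    return records


def _not_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return True
    return False


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as TPS records (coordinates at full precision, no SCALE)."""
    path = Path(path)
    chunks: list[str] = []
    for cfg in configs:
        header = f"LM3={cfg.points.shape[0]}" if cfg.dimension == 3 else f"LM={cfg.points.shape[0]}"
        body = "\n".join(" ".join(format(float(v), ".17g") for v in row)
                         for row in cfg.points)
        chunks.append(f"{header}\n{body}\nID={cfg.specimen_id}\n")
    path.write_text("".join(chunks), encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-format landmark CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["specimen_id", "structure", "side", "genotype", "sex",
                "landmark_name", "x", "y", "z"]


_STRUCTURE_SCHEMES = {"cranium": "cranium_p10", "mandible": "hemimandible_p10",
                      "outline": "mandible_process_outline"}


def read_landmark_csv(path: str | Path, scheme: LandmarkScheme | None = None) -> CohortTable:
    """Assemble a cohort from a long-format CSV, in scheme order regardless of row order.

    Expected columns: specimen_id, structure, side, landmark_name, x, y[, z],
    optionally genotype and sex. When ``scheme`` is None, each block's scheme
    is resolved from its ``structure`` column via the standard registry. A
    specimen/structure/side block missing any scheme landmark is rejected with
    an error naming the gap; unknown landmark names and duplicate
    (specimen, landmark) rows are errors.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str}, float_precision="round_trip")
    required = {"specimen_id", "structure", "side", "landmark_name", "x", "y"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing_cols)}")

    configs: list[LandmarkConfiguration] = []
    meta_rows: dict[str, dict[str, str]] = {}
    for (spec_id, structure, side), block in df.groupby(
            ["specimen_id", "structure", "side"], sort=False):
        if scheme is None:
            try:
                block_scheme = get_scheme(_STRUCTURE_SCHEMES[str(structure)])
            except KeyError:
                raise ValueError(f"unknown structure {structure!r} in CSV") from None
        else:
            block_scheme = scheme
        unknown = sorted(set(block["landmark_name"]) - set(block_scheme.landmark_names))
        if unknown:
            raise ValueError(f"unknown landmark names for scheme "
                             f"{block_scheme.name!r}: {unknown}")
        coord_cols = ["x", "y", "z"][: block_scheme.dimension]
        if block_scheme.dimension == 3 and "z" not in df.columns:
            raise ValueError("scheme is 3D but CSV has no z column")
        dup = block["landmark_name"].duplicated()
        if dup.any():
            dups = sorted(set(block.loc[dup, "landmark_name"]))
            raise ValueError(f"duplicate landmarks for specimen {spec_id!r}: {dups}")
        present = set(block["landmark_name"])
        gaps = [n for n in block_scheme.landmark_names if n not in present]
        if gaps:
            raise ValueError(f"specimen {spec_id!r} ({structure}/{side}) missing landmarks: {gaps}")
        indexed = block.set_index("landmark_name")
        pts = indexed.loc[list(block_scheme.landmark_names), coord_cols].to_numpy(dtype=float)
        genotype = str(block["genotype"].iloc[0]) if "genotype" in block else "control"
        sex = str(block["sex"].iloc[0]) if "sex" in block else "unknown"
        configs.append(LandmarkConfiguration(
            specimen_id=str(spec_id), points=pts, structure=str(structure),
            side=str(side), genotype=genotype, sex=sex, scheme_ref=block_scheme.name))
        meta_rows.setdefault(str(spec_id), {"genotype": genotype, "sex": sex})
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    metadata.index.name = "specimen_id"
    return CohortTable(configurations=configs, metadata=metadata)


def write_landmark_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort in the long format read_landmark_csv expects (lossless round-trip)."""
    rows = []
    for cfg in cohort.configurations:
        scheme = cfg.scheme
        names = scheme.landmark_names if scheme else [f"p{i}" for i in range(len(cfg.points))]
        for name, pt in zip(names, cfg.points):
            row = {"specimen_id": cfg.specimen_id, "structure": cfg.structure,
                   "side": cfg.side, "genotype": cfg.genotype, "sex": cfg.sex,
                   "landmark_name": name, "x": pt[0], "y": pt[1]}
            if cfg.dimension == 3:
                row["z"] = pt[2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_results_table(results, path: str | Path) -> None:
    """Write any tabular result (DataFrame or list of dataclass rows) as CSV.

    Stable column order, header always present, floats at full precision.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in results]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")
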