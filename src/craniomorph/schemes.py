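"""Named landmark schemes for the mouse cranium, hemimandible, and mandibular-process outline.

A scheme fixes the identity, order, and laterality of every landmark so that
configurations read from files, produced by the synthetic generator, and fed to
the measurement panel all agree on what each coordinate row means.

The cranial and mandibular inventories are package-internal functional schemes:
they name enough midline and bilaterally paired points to express the full
measurement panel (projected jaw lengths, transverse widths, vault heights,
palate length, molar fields, mandibular process lengths and inlet areas,
bigonial width, and the snout-deviation triple), not a reproduction of any
published atlas.

Axis convention (canonical head frame): x mediolateral with the midsagittal
plane at x = 0 and the right side at x > 0; y anteroposterior, anterior
positive; z superoinferior, superior positive. Units are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered, named landmark inventory with laterality annotations.

    Parameters
    ----------
    name : str
        Scheme identifier referenced by configurations.
    landmark_names : tuple of str
        Unique names in canonical order.
    dimension : int
        2 or 3.
    bilateral_pairs : tuple of (left, right) name pairs
        Landmarks mirrored across the midsagittal plane.
    midline_names : tuple of str
        Landmarks lying on the midsagittal plane; disjoint from the
        bilateral pairs.
    anterior_name, superior_name : str or None
        Orientation hints used when fitting the canonical frame.
    """

    name: str
    landmark_names: tuple[str, ...]
    dimension: int
    bilateral_pairs: tuple[tuple[str, str], ...] = ()
    midline_names: tuple[str, ...] = ()
    anterior_name: str | None = None
    superior_name: str | None = None
    # (posterior, anterior) midline landmarks pinning the anteroposterior
    # axis of the canonical frame, cephalometric-chord style; when None the
    # in-plane principal axis of the midline landmarks is used instead.
    axis_chord: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        names = self.landmark_names
        if len(set(names)) != len(names):
            raise ValueError(f"scheme {self.name!r}: duplicate landmark names")
        known = set(names)
        paired: set[str] = set()
        for left, right in self.bilateral_pairs:
            for nm in (left, right):
                if nm not in known:
                    raise ValueError(f"scheme {self.name!r}: bilateral name {nm!r} not in inventory")
                paired.add(nm)
        for nm in self.midline_names:
            if nm not in known:
                raise ValueError(f"scheme {self.name!r}: midline name {nm!r} not in inventory")
            if nm in paired:
                raise ValueError(f"scheme {self.name!r}: {nm!r} is both midline and bilateral")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def index(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not in scheme {self.name!r}") from None

    def mirror_of(self, name: str) -> str | None:
        """Contralateral partner of a bilateral landmark, else None."""
        for left, right in self.bilateral_pairs:
            if name == left:
                return right
            if name == right:
                return left
        return None


def _pairs(*stems: str) -> tuple[tuple[str, str], ...]:
    return tuple((f"{s}_L", f"{s}_R") for s in stems)


# The anterior nasal tip deviates laterally in asymmetric snouts, so it is
# deliberately not part of the midline set used to fit the midsagittal plane.
_CRANIUM_MIDLINE = (
    "internasal_anterior",  # anterior internasal-suture point on the midsagittal plane
    "nasion",
    "bregma",
    "parietal_mid",
    "lambda",
    "basion",
    "prosthion",
    "palatine_posterior",
    "frontal_crest_tip",
)

_CRANIUM_PAIR_STEMS = (
    "premaxilla_anterior",
    "maxilla_anterior",
    "maxilla_posterior",
    "maxillary_M1",
    "maxillary_M3",
    "basisphenoid_rostral",
    "zygoma_anterior",
    "zygoma_posterior",
    "frontal_orbital",
)

CRANIUM_SCHEME = LandmarkScheme(
    name="cranium_p10",
    landmark_names=("nasal_anterior",) + _CRANIUM_MIDLINE
    + tuple(n for pair in _pairs(*_CRANIUM_PAIR_STEMS) for n in pair),
    dimension=3,
    bilateral_pairs=_pairs(*_CRANIUM_PAIR_STEMS),
    midline_names=_CRANIUM_MIDLINE,
    anterior_name="internasal_anterior",
    superior_name="bregma",
    axis_chord=("basion", "nasion"),
)

# One hemimandible; left and right sides are separate configurations sharing
# this scheme, stored in the common head frame.
_MANDIBLE_NAMES = (
    "incisor_alveolus_superior",
    "incisor_alveolus_inferior",
    "molar_field_anterior",
    "molar_field_posterior",
    "coronoid_tip",
    "coronoid_condylar_notch",
    "condyle_posterior",
    "condylar_angular_notch",
    "angular_process_posterior",
    "angular_process_inferior",
    "ramus_ventral_notch",
)

MANDIBLE_SCHEME = LandmarkScheme(
    name="hemimandible_p10",
    landmark_names=_MANDIBLE_NAMES,
    dimension=3,
    anterior_name="incisor_alveolus_superior",
    superior_name="coronoid_tip",
)

# 59 semilandmarks along a closed outline of the coronoid, condylar, and
# angular processes in lateral view (2D).
OUTLINE_SCHEME = LandmarkScheme(
    name="mandible_process_outline",
    landmark_names=tuple(f"sl{i:02d}" for i in range(59)),
    dimension=2,
)

SCHEMES: dict[str, LandmarkScheme] = {
    s.name: s for s in (CRANIUM_SCHEME, MANDIBLE_SCHEME, OUTLINE_SCHEME)
}


def get_scheme(name: str) -> LandmarkScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown landmark scheme {name!r}; known: {sorted(SCHEMES)}") from None
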