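"""Domain records for islet-level T cell infiltration data.

The unit of observation is a single pancreatic islet on a stained tissue
section: its parenchymal area, total cell (nucleus) count, insulin status
(insulin-containing, ICI, vs insulin-deficient/pseudoatrophic, IDI) and the
number of infiltrating T cells by marker (CD3+, split into CD3+CD8+ and
CD3+CD8-).  Islets are grouped under the donor whose section they came from,
together with the donor's exocrine (non-islet) measurements.

Areas are mm^2 throughout; spatial-mode coordinates are micrometres.  The
single conversion constant lives in :data:`UM2_PER_MM2`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

#: 1 mm^2 expressed in um^2 -- the only place the unit conversion is defined.
UM2_PER_MM2 = 1.0e6


class Group(str, enum.Enum):
    """Donor group: non-diabetic, single/double autoantibody-positive, T1D."""

    ND = "ND"
    AAB1 = "AAB1"
    AAB2 = "AAB2"
    T1D = "T1D"


class InsulinStatus(str, enum.Enum):
    """Insulin status of an islet.

    ICI: insulin-containing islet; IDI: insulin-deficient (pseudoatrophic)
    islet.  UNKNOWN is permitted (e.g. unstained sections) and is excluded
    from ICI/IDI-stratified analyses but included in "all islets" metrics.
    """

    ICI = "ICI"
    IDI = "IDI"
    UNKNOWN = "UNKNOWN"


class ValidationError(ValueError):
    """A record violates a typed invariant.

    ``errors`` collects every violation found, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class IsletRecord:
    """One islet: area, cellularity, insulin status and marker counts."""

    donor_id: str
    islet_id: str
    area_mm2: float
    n_cells: int
    insulin_status: InsulinStatus = InsulinStatus.UNKNOWN
    cd3_count: int = 0
    cd3cd8pos_count: int = 0
    cd3cd8neg_count: int = 0

    def violations(self) -> list[str]:
        errs = []
        if not self.area_mm2 > 0:
            errs.append(f"islet {self.islet_id}: area_mm2 must be > 0, got {self.area_mm2}")
        for name in ("n_cells", "cd3_count", "cd3cd8pos_count", "cd3cd8neg_count"):
            v = getattr(self, name)
            if v < 0:
                errs.append(f"islet {self.islet_id}: {name} must be >= 0, got {v}")
        if self.cd3_count != self.cd3cd8pos_count + self.cd3cd8neg_count:
            errs.append(
                f"islet {self.islet_id}: cd3_count ({self.cd3_count}) != "
                f"cd3cd8pos_count + cd3cd8neg_count "
                f"({self.cd3cd8pos_count} + {self.cd3cd8neg_count})"
            )
        return errs

    def validate(self) -> "IsletRecord":
        errs = self.violations()
        if errs:
            raise ValidationError(errs)
        return self

    def marker_count(self, marker: str) -> int:
        """Infiltrating cell count for ``marker`` in {cd3, cd3cd8pos, cd3cd8neg}."""
        return getattr(self, f"{_canonical_marker(marker)}_count")


#: Markers quantified per islet / per donor.
MARKERS = ("cd3", "cd3cd8pos", "cd3cd8neg")


def _canonical_marker(marker: str) -> str:
    m = marker.lower().replace("+", "pos").replace("-", "neg").replace("cd8", "cd8")
    m = {"cd3": "cd3", "cd3cd8pos": "cd3cd8pos", "cd3cd8neg": "cd3cd8neg",
         "cd8pos": "cd3cd8pos", "cd8neg": "cd3cd8neg"}.get(m)
    if m is None:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    return m


@dataclass
class DonorRecord:
    """A donor: group label, islets, section-level and exocrine measurements."""

    donor_id: str
    group: Group
    islets: list[IsletRecord] = field(default_factory=list)
    total_area_mm2: float = math.nan
    endocrine_area_mm2: float = math.nan
    exocrine_cd3: int = 0
    exocrine_cd3cd8pos: int = 0
    exocrine_cd3cd8neg: int = 0
    metadata: dict = field(default_factory=dict)

    #: relative slack allowed when checking sum(islet areas) <= endocrine area
    _AREA_TOL = 1e-9

    @property
    def exocrine_area_mm2(self) -> float:
        """Exocrine tissue area: total section area minus endocrine area."""
        return self.total_area_mm2 - self.endocrine_area_mm2

    def exocrine_marker_count(self, marker: str) -> int:
        return getattr(self, f"exocrine_{_canonical_marker(marker)}")

    def violations(self) -> list[str]:
        errs = []
        for islet in self.islets:
            errs.extend(f"donor {self.donor_id}: {e}" for e in islet.violations())
        has_section = not (math.isnan(self.total_area_mm2) and math.isnan(self.endocrine_area_mm2))
        if has_section:
            if not self.total_area_mm2 > 0:
                errs.append(f"donor {self.donor_id}: total_area_mm2 must be > 0")
            if self.endocrine_area_mm2 < 0:
                errs.append(f"donor {self.donor_id}: endocrine_area_mm2 must be >= 0")
            if self.endocrine_area_mm2 > self.total_area_mm2:
                errs.append(
                    f"donor {self.donor_id}: endocrine_area_mm2 "
                    f"({self.endocrine_area_mm2}) exceeds total_area_mm2 "
                    f"({self.total_area_mm2})"
                )
            islet_area = sum(i.area_mm2 for i in self.islets)
            if islet_area > self.endocrine_area_mm2 * (1 + self._AREA_TOL) + 1e-12:
                errs.append(
                    f"donor {self.donor_id}: sum of islet areas ({islet_area:.6g}) "
                    f"exceeds endocrine_area_mm2 ({self.endocrine_area_mm2:.6g})"
                )
        for name in ("exocrine_cd3", "exocrine_cd3cd8pos", "exocrine_cd3cd8neg"):
            if getattr(self, name) < 0:
                errs.append(f"donor {self.donor_id}: {name} must be >= 0")
        return errs

    def validate(self) -> "DonorRecord":
        errs = self.violations()
        if errs:
            raise ValidationError(errs)
        return self


@dataclass
class CellDetection:
    """A detected cell in spatial mode: planar position (um) + marker flags.

    CD8 positivity here means CD3+CD8+ (a CD8+ detection implies CD3+).
    """

    x_um: float
    y_um: float
    is_cd3: bool = False
    is_cd8: bool = False

    def violations(self) -> list[str]:
        if self.is_cd8 and not self.is_cd3:
            return [f"detection at ({self.x_um}, {self.y_um}): is_cd8 implies is_cd3"]
        return []

    def validate(self) -> "CellDetection":
        errs = self.violations()
        if errs:
            raise ValidationError(errs)
        return self


@dataclass
class IsletBoundary:
    """Islet outline in spatial mode: a simple closed ring, vertices in um."""

    islet_id: str
    ring_um: list[tuple[float, float]]
    insulin_status: InsulinStatus = InsulinStatus.UNKNOWN

    def polygon(self):
        """The boundary as a :class:`shapely.Polygon` (coordinates in um)."""
        import shapely

        return shapely.Polygon(self.ring_um)

    @property
    def area_mm2(self) -> float:
        return self.polygon().area / UM2_PER_MM2

    def violations(self) -> list[str]:
        poly = self.polygon()
        errs = []
        if not poly.is_simple or not poly.is_valid:
            errs.append(f"islet {self.islet_id}: boundary ring is self-intersecting")
        elif not poly.area > 0:
            errs.append(f"islet {self.islet_id}: boundary has zero area")
        return errs

    def validate(self) -> "IsletBoundary":
        errs = self.violations()
        if errs:
            raise ValidationError(errs)
        return self
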