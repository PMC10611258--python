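"""Phenotype parameterization, compound profiles and study designs.

The synthetic study emulates a compartmentalized neurotoxicity screen:
primary sensory neurons cultured in a microphysiological device that
separates cell bodies ("soma area") from their neurites ("axon area").
Each compound x concentration condition is summarized by a
:class:`PhenotypeParams` object whose fields control the morphological
damage the image generator draws:

* soma damage - shrinkage of cell bodies, irregular contours, bright
  autofluorescent puncta;
* axon damage - fibers pulling together into bundles (leaving cavities)
  and fragmentation/transection of fibers.

Severities are abstract in [0, 1]; the severity -> effect-amplitude
mapping is linear (the simplest monotone choice) and its slopes are the
module constants below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .errors import ConfigurationError

AreaKind = Literal["soma", "axon"]
Split = Literal["train", "test"]
Role = Literal["vehicle", "negative", "training-toxicant", "validation-toxicant"]

#: Linear severity -> effect slopes (value of each damage parameter at severity 1).
SHRINKAGE_AT_MAX = 0.45
IRREGULARITY_AT_MAX = 0.35
PUNCTA_AT_MAX = 6.0
LUMINANCE_LOSS_AT_MAX = 0.35
AGGREGATION_AT_MAX = 0.8
FRAGMENTATION_AT_MAX = 0.5

#: Default read-noise standard deviation (fraction of full intensity scale).
DEFAULT_BACKGROUND_NOISE_SD = 0.008


@dataclass(frozen=True)
class PhenotypeParams:
    """Damage parameters for one compound x concentration condition.

    ``soma_severity``/``axon_severity`` are the abstract per-compartment
    severities; the remaining fields are the concrete effect amplitudes
    the generator uses. A severity of exactly 0 forces the corresponding
    effect parameters to their no-effect values.
    """

    soma_severity: float = 0.0
    axon_severity: float = 0.0
    soma_shrinkage: float = 0.0        # fractional radius reduction
    contour_irregularity: float = 0.0  # boundary perturbation, fraction of radius
    puncta_rate: float = 0.0           # expected bright puncta per soma
    luminance_loss: float = 0.0        # fractional dimming of the cell body
    aggregation: float = 0.0           # fiber bundling strength
    fragmentation: float = 0.0         # per-cell break probability along fibers
    background_noise_sd: float = DEFAULT_BACKGROUND_NOISE_SD

    def __post_init__(self) -> None:
        for name in ("soma_severity", "axon_severity", "soma_shrinkage",
                     "contour_irregularity", "luminance_loss", "aggregation",
                     "fragmentation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} outside [0, 1]")
        if self.puncta_rate < 0:
            raise ConfigurationError(f"puncta_rate={self.puncta_rate!r} must be >= 0")
        if self.background_noise_sd < 0:
            raise ConfigurationError("background_noise_sd must be >= 0")
        if self.soma_severity == 0.0 and any(
            getattr(self, n) != 0.0
            for n in ("soma_shrinkage", "contour_irregularity", "puncta_rate",
                      "luminance_loss")
        ):
            raise ConfigurationError(
                "soma_severity=0 requires all soma damage parameters to be 0"
            )
        if self.axon_severity == 0.0 and (self.aggregation != 0.0 or self.fragmentation != 0.0):
            raise ConfigurationError(
                "axon_severity=0 requires all axon damage parameters to be 0"
            )

    @classmethod
    def from_severity(
        cls,
        soma_severity: float = 0.0,
        axon_severity: float = 0.0,
        background_noise_sd: float = DEFAULT_BACKGROUND_NOISE_SD,
    ) -> "PhenotypeParams":
        """Map abstract severities to effect amplitudes linearly."""
        return cls(
            soma_severity=soma_severity,
            axon_severity=axon_severity,
            soma_shrinkage=SHRINKAGE_AT_MAX * soma_severity,
            contour_irregularity=IRREGULARITY_AT_MAX * soma_severity,
            puncta_rate=PUNCTA_AT_MAX * soma_severity,
            luminance_loss=LUMINANCE_LOSS_AT_MAX * soma_severity,
            aggregation=AGGREGATION_AT_MAX * axon_severity,
            fragmentation=FRAGMENTATION_AT_MAX * axon_severity,
            background_noise_sd=background_noise_sd,
        )


@dataclass(frozen=True, order=True)
class Concentration:
    """A dose with its unit (uM for compounds, % for the vehicle)."""

    value: float
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ConfigurationError("concentration must be >= 0")

    @property
    def label(self) -> str:
        v = self.value
        text = f"{v:g}"
        return f"{text}{self.unit}" if self.unit == "%" else f"{text} {self.unit}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class CompoundProfile:
    """Per-compound severity profile across its tested concentrations."""

    name: str
    role: Role
    levels: tuple[tuple[Concentration, PhenotypeParams], ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ConfigurationError(f"profile {self.name!r} has no concentration levels")
        if self.role in ("vehicle", "negative"):
            for conc, p in self.levels:
                if p.soma_severity != 0.0 or p.axon_severity != 0.0:
                    raise ConfigurationError(
                        f"{self.role} profile {self.name!r} must have zero severities "
                        f"(violated at {conc.label})"
                    )
        ordered = sorted(self.levels, key=lambda cp: cp[0].value)
        for (c0, p0), (c1, p1) in zip(ordered, ordered[1:]):
            if p1.soma_severity < p0.soma_severity or p1.axon_severity < p0.axon_severity:
                raise ConfigurationError(
                    f"severities of {self.name!r} must be non-decreasing with "
                    f"concentration ({c0.label} -> {c1.label})"
                )

    def params_for(self, concentration: Concentration) -> PhenotypeParams:
        for conc, params in self.levels:
            if conc == concentration:
                return params
        raise ConfigurationError(
            f"profile {self.name!r} has no level at {concentration.label}"
        )

    @property
    def concentrations(self) -> tuple[Concentration, ...]:
        return tuple(c for c, _ in self.levels)


@dataclass(frozen=True)
class DesignRow:
    compound: str
    concentration: Concentration
    area_kind: AreaKind
    split: Split
    n_images: int

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ConfigurationError("n_images must be >= 1")
        if self.area_kind not in ("soma", "axon"):
            raise ConfigurationError(f"unknown area_kind {self.area_kind!r}")
        if self.split not in ("train", "test"):
            raise ConfigurationError(f"unknown split {self.split!r}")


@dataclass(frozen=True)
class StudyDesign:
    """A table of (compound, concentration, area, split, n) rows."""

    rows: tuple[DesignRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for row in self.rows:
            key = (row.compound, row.concentration, row.area_kind, row.split)
            if key in seen:
                raise ConfigurationError(
                    f"duplicate design row for {key}"
                )
            seen.add(key)

    def subset(self, *, area_kind: AreaKind | None = None, split: Split | None = None) -> "StudyDesign":
        rows = tuple(
            r for r in self.rows
            if (area_kind is None or r.area_kind == area_kind)
            and (split is None or r.split == split)
        )
        return StudyDesign(rows)

    def scaled_counts(self, factor: float) -> "StudyDesign":
        """Return a copy with every n multiplied by ``factor`` (min 1)."""
        rows = tuple(
            replace(r, n_images=max(1, round(r.n_images * factor))) for r in self.rows
        )
        return StudyDesign(rows)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Default compound panel and study design
# ---------------------------------------------------------------------------

DMSO = Concentration(0.1, "%")
_UM = lambda v: Concentration(v, "uM")


def default_profiles() -> tuple[CompoundProfile, ...]:
    """The default seven-compound panel.

    Severity topology: oxaliplatin is soma-dominant, vincristine
    axon-dominant, paclitaxel damages both compartments, while suramin and
    bortezomib are moderate dual toxicants. DMSO (vehicle) and sucrose
    (negative) are damage-free. Absolute severity values are arbitrary
    choices on the [0, 1] scale (the morphologies they emulate were
    described only qualitatively); only their ordering and compartment
    assignment matter downstream.
    """
    sev = PhenotypeParams.from_severity
    return (
        CompoundProfile("DMSO", "vehicle", ((DMSO, sev(0.0, 0.0)),)),
        CompoundProfile("sucrose", "negative", ((_UM(10), sev(0.0, 0.0)),)),
        CompoundProfile("oxaliplatin", "training-toxicant", (
            (_UM(10), sev(0.6, 0.0)),
            (_UM(100), sev(1.0, 0.0)),
        )),
        CompoundProfile("vincristine", "training-toxicant", (
            (_UM(0.003), sev(0.0, 0.6)),
            (_UM(0.03), sev(0.0, 1.0)),
        )),
        CompoundProfile("paclitaxel", "validation-toxicant", (
            (_UM(0.1), sev(0.5, 0.5)),
            (_UM(1), sev(0.8, 0.8)),
        )),
        CompoundProfile("suramin", "validation-toxicant", (
            (_UM(10), sev(0.3, 0.35)),
            (_UM(100), sev(0.45, 0.5)),
        )),
        CompoundProfile("bortezomib", "validation-toxicant", (
            (_UM(0.01), sev(0.35, 0.4)),
        )),
    )


def default_design() -> StudyDesign:
    """Default study design for both compartments.

    The soma classifier trains on vehicle/negative plus oxaliplatin; the
    axon classifier trains on vehicle/negative plus vincristine. All
    compounds appear in the test split. Image counts follow the published
    per-condition sample sizes of the screen this design emulates.
    """
    S, A = "soma", "axon"
    rows = [
        # --- soma area ---
        DesignRow("DMSO", DMSO, S, "train", 24),
        DesignRow("sucrose", _UM(10), S, "train", 24),
        DesignRow("oxaliplatin", _UM(10), S, "train", 12),
        DesignRow("oxaliplatin", _UM(100), S, "train", 8),
        DesignRow("DMSO", DMSO, S, "test", 8),
        DesignRow("sucrose", _UM(10), S, "test", 12),
        DesignRow("oxaliplatin", _UM(10), S, "test", 8),
        DesignRow("oxaliplatin", _UM(100), S, "test", 8),
        DesignRow("paclitaxel", _UM(0.1), S, "test", 38),
        DesignRow("paclitaxel", _UM(1), S, "test", 10),
        DesignRow("vincristine", _UM(0.003), S, "test", 13),
        DesignRow("vincristine", _UM(0.03), S, "test", 24),
        DesignRow("suramin", _UM(10), S, "test", 20),
        DesignRow("suramin", _UM(100), S, "test", 16),
        DesignRow("bortezomib", _UM(0.01), S, "test", 8),
        # --- axon area ---
        DesignRow("DMSO", DMSO, A, "train", 10),
        DesignRow("sucrose", _UM(10), A, "train", 7),
        DesignRow("vincristine", _UM(0.003), A, "train", 8),
        DesignRow("vincristine", _UM(0.03), A, "train", 9),
        DesignRow("DMSO", DMSO, A, "test", 6),
        DesignRow("sucrose", _UM(10), A, "test", 3),
        DesignRow("vincristine", _UM(0.003), A, "test", 5),
        DesignRow("vincristine", _UM(0.03), A, "test", 6),
        DesignRow("paclitaxel", _UM(0.1), A, "test", 10),
        DesignRow("paclitaxel", _UM(1), A, "test", 10),
        DesignRow("oxaliplatin", _UM(10), A, "test", 16),
        DesignRow("oxaliplatin", _UM(100), A, "test", 15),
        DesignRow("suramin", _UM(10), A, "test", 10),
        DesignRow("suramin", _UM(100), A, "test", 13),
        DesignRow("bortezomib", _UM(0.01), A, "test", 6),
    ]
    return StudyDesign(tuple(rows))


def profiles_by_name(profiles: Iterable[CompoundProfile]) -> dict[str, CompoundProfile]:
    return {p.name: p for p in profiles}


def default_label_map(profiles: Sequence[CompoundProfile]) -> dict[str, str]:
    """Weak-label map: vehicle/negative compounds -> negative, rest -> positive."""
    return {
        p.name: ("negative" if p.role in ("vehicle", "negative") else "positive")
        for p in profiles
    }
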