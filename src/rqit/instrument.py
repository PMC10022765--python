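"""Instrument data model and the multi-attribute scoring engine.

A research-question importance instrument is a set of dimensions (e.g. patient
burden), each with a small number of ordered levels.  A *profile* picks one
level per dimension; its score is the sum of the chosen elements' utilities on
a 0-1000 interval scale, and its standard error follows from the element
standard errors and their estimation-error correlation matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "Instrument",
    "Profile",
    "UtilityTable",
    "Score",
    "load_instrument",
    "load_default_table",
    "score_profile",
    "propagate_profile_se",
]


class InstrumentError(ValueError):
    """Invalid instrument definition or profile."""


@dataclass(frozen=True)
class Dimension:
    """One attribute of research-question importance with ordered levels.

    ``levels`` is ordered from lowest (index 1) to highest; codes are the
    dimension letter plus a 1-based level index, e.g. ``"A1"``.
    """

    code: str
    label: str
    levels: tuple[tuple[str, str], ...]  # (code, descriptor), ordinal order

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise InstrumentError(
                f"dimension {self.code!r} needs >=2 ordered levels, got {len(self.levels)}"
            )

    @property
    def level_codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.levels)


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of dimensions defining the scoring space."""

    dimensions: tuple[Dimension, ...]
    name: str = "instrument"
    version: str = "0"

    def __post_init__(self) -> None:
        if len(self.dimensions) < 1:
            raise InstrumentError("instrument needs at least one dimension")
        seen: set[str] = set()
        for dim in self.dimensions:
            for code in dim.level_codes:
                if code in seen:
                    raise InstrumentError(f"duplicate level code {code!r}")
                seen.add(code)

    @property
    def element_codes(self) -> tuple[str, ...]:
        """All level codes in instrument order (e.g. A1..A4, B1..B3, ...)."""
        return tuple(c for d in self.dimensions for c in d.level_codes)

    @property
    def n_elements(self) -> int:
        return len(self.element_codes)

    def dimension_of(self, element: str) -> Dimension:
        for dim in self.dimensions:
            if element in dim.level_codes:
                return dim
        raise KeyError(f"unknown element code {element!r}")

    def iter_profiles(self) -> Iterable["Profile"]:
        """All full factorial profiles (cartesian product of levels)."""
        import itertools

        for combo in itertools.product(*(d.level_codes for d in self.dimensions)):
            yield Profile(combo)


@dataclass(frozen=True)
class Profile:
    """One level code per dimension, e.g. ("A4","B1","C3","D3","E1")."""

    elements: tuple[str, ...]

    def __init__(self, elements: Iterable[str] | str):
        if isinstance(elements, str):
            elements = [e.strip() for e in elements.split(",")]
        object.__setattr__(self, "elements", tuple(elements))

    def validate(self, instrument: Instrument) -> None:
        if len(self.elements) != len(instrument.dimensions):
            raise InstrumentError(
                f"profile has {len(self.elements)} elements for a "
                f"{len(instrument.dimensions)}-dimension instrument"
            )
        for dim, code in zip(instrument.dimensions, self.elements):
            if code not in dim.level_codes:
                raise InstrumentError(
                    f"element {code!r} is not a level of dimension {dim.code!r}"
                )

    def __str__(self) -> str:
        return ",".join(self.elements)


@dataclass(frozen=True)
class UtilityTable:
    """Element utilities on the 0-1000 scale with their estimation uncertainty.

    ``utilities`` and ``standard_errors`` map element codes to score units;
    ``correlations`` holds the correlation matrix of the utility *estimates*
    (not of respondent preferences), used for profile-SE propagation.
    """

    instrument: Instrument
    utilities: Mapping[str, float]
    standard_errors: Mapping[str, float]
    correlations: np.ndarray  # aligned with instrument.element_codes
    scale: tuple[float, float] = (0.0, 1000.0)
    _index: Mapping[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        codes = self.instrument.element_codes
        missing = [c for c in codes if c not in self.utilities]
        if missing:
            raise InstrumentError(f"utility table missing elements: {missing}")
        rho = np.asarray(self.correlations, dtype=float)
        n = len(codes)
        if rho.shape != (n, n):
            raise InstrumentError(
                f"correlation matrix shape {rho.shape} != ({n}, {n})"
            )
        if not np.allclose(rho, rho.T, atol=1e-8):
            i, j = np.unravel_index(np.argmax(np.abs(rho - rho.T)), rho.shape)
            raise InstrumentError(
                f"correlation matrix not symmetric at ({codes[i]}, {codes[j]})"
            )
        if np.any(np.abs(rho) > 1 + 1e-9):
            raise InstrumentError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-9):
            raise InstrumentError("correlation matrix diagonal must be 1")
        object.__setattr__(self, "correlations", rho)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(codes)})

    def utility(self, element: str) -> float:
        try:
            return float(self.utilities[element])
        except KeyError:
            raise KeyError(f"element {element!r} not in utility table") from None

    def se(self, element: str) -> float:
        return float(self.standard_errors[element])

    def rho(self, a: str, b: str) -> float:
        return float(self.correlations[self._index[a], self._index[b]])

    def max_profile(self) -> Profile:
        return Profile(tuple(d.level_codes[-1] for d in self.instrument.dimensions))

    def min_profile(self) -> Profile:
        return Profile(tuple(d.level_codes[0] for d in self.instrument.dimensions))


@dataclass(frozen=True)
class Score:
    """A profile's importance score (0-1000 scale) and its standard error."""

    value: float
    standard_error: float

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard error must be >= 0")


def _instrument_from_dict(doc: Mapping) -> Instrument:
    dims = []
    for d in doc.get("dimensions", []):
        levels = tuple((lv["code"], lv.get("descriptor", "")) for lv in d.get("levels", []))
        if not levels:
            raise InstrumentError(f"dimension {d.get('code')!r} has no levels")
        dims.append(Dimension(code=d["code"], label=d.get("label", ""), levels=levels))
    return Instrument(
        dimensions=tuple(dims),
        name=doc.get("name", "instrument"),
        version=str(doc.get("version", "0")),
    )


def load_instrument(definition: str | Mapping | None = None) -> Instrument:
    """Build a validated :class:`Instrument` from a JSON definition.

    ``definition`` may be a JSON string, a parsed mapping, or ``None`` for the
    packaged ANZMUSC-RQIT (5 dimensions, 18 elements).
    """
    if definition is None:
        return load_default_table().instrument
    if isinstance(definition, str):
        definition = json.loads(definition)
    return _instrument_from_dict(definition)


def table_from_dict(doc: Mapping) -> UtilityTable:
    """Build a :class:`UtilityTable` (with its instrument) from a mapping."""
    instrument = _instrument_from_dict(doc)
    utilities: dict[str, float] = {}
    ses: dict[str, float] = {}
    for d in doc["dimensions"]:
        for lv in d["levels"]:
            utilities[lv["code"]] = float(lv["utility"])
            ses[lv["code"]] = float(lv.get("se", 0.0))
    corr = doc.get("correlations")
    codes = list(instrument.element_codes)
    if corr is None:
        rho = np.eye(len(codes))
    else:
        if corr.get("codes") != codes:
            raise InstrumentError(
                "correlation block element codes do not match instrument order"
            )
        rho = np.asarray(corr["matrix"], dtype=float)
    scale = tuple(doc.get("scale", (0.0, 1000.0)))
    return UtilityTable(
        instrument=instrument,
        utilities=utilities,
        standard_errors=ses,
        correlations=rho,
        scale=scale,
    )


def load_default_table() -> UtilityTable:
    """The packaged ANZMUSC-RQIT utility table (published values)."""
    text = resources.files("rqit.data").joinpath("anzmusc_rqit.json").read_text()
    return table_from_dict(json.loads(text))


def score_profile(profile: Profile | Sequence[str] | str, table: UtilityTable) -> Score:
    """Score a profile: sum of element utilities, SE by error propagation.

    The worked example on the published table: profile (A4,B1,C3,D3,E1)
    scores 582 — important to all stakeholders, mild symptoms, a common
    condition, potentially curative treatment, equity not addressed.
    """
    if not isinstance(profile, Profile):
        profile = Profile(profile)
    profile.validate(table.instrument)
    value = sum(table.utility(e) for e in profile.elements)
    se = propagate_profile_se(profile, table)
    return Score(value=value, standard_error=se)


def propagate_profile_se(profile: Profile | Sequence[str] | str, table: UtilityTable) -> float:
    """Standard error of a profile score.

    The profile score is a sum of correlated utility estimates, so its
    variance is the quadratic form  sum_e sum_e' rho_{e,e'} sigma_e sigma_e'
    over all ordered pairs of the profile's elements.
    """
    if not isinstance(profile, Profile):
        profile = Profile(profile)
    profile.validate(table.instrument)
    sigma = np.array([table.se(e) for e in profile.elements])
    idx = [table._index[e] for e in profile.elements]
    rho = table.correlations[np.ix_(idx, idx)]
    var = float(sigma @ rho @ sigma)
    if var < -1e-9:
        raise InstrumentError(
            f"negative propagated variance ({var:.3g}): inconsistent rho/sigma inputs"
        )
    return float(np.sqrt(max(var, 0.0)))
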