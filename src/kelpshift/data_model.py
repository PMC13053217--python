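"""Domain types and survey-table plumbing.

Covers are stored as fractions in [0, 1].  Field sheets that record
ordinal cover classes are converted to bin midpoints via
:func:`cover_code_to_fraction`; the lowest ("trace") class has no printed
midpoint and defaults to 0.005 (midpoint of the open (0%, 1%) bin),
overridable through ``plus_value``.

Depth is metres below chart datum, positive downward.  Rows above chart
datum (negative depth) are rejected: the analyses cover the subtidal zone
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "COVER_CODES",
    "SUBSTRATES",
    "FUNCTIONAL_GROUPS",
    "QuadratSurvey",
    "PairedQuadrat",
    "SpeciesRecord",
    "cover_code_to_fraction",
    "filter_quadrats",
    "rare_species_filter",
    "pair_surveys",
    "normalize_species_name",
    "read_surveys",
    "write_surveys",
    "read_species",
    "write_species",
    "write_exclusion_log",
]

#: Ordinal cover classes, lowest to highest, with their bin midpoints.
#: "+" (<1%) has no printed midpoint; see module docstring.
COVER_CODES: dict[str, float] = {
    "+": 0.005,  # (0%, 1%)
    "1": 0.03,   # 1%-5%
    "2": 0.155,  # 6%-25%
    "3": 0.38,   # 26%-50%
    "4": 0.63,   # 51%-75%
    "5": 0.88,   # 76%-100%
}

SUBSTRATES: frozenset[str] = frozenset(
    {"sand", "pebble", "cobble", "boulder", "bedrock"}
)

FUNCTIONAL_GROUPS: frozenset[str] = frozenset(
    {
        "kelp",
        "red_blade",
        "green_blade",
        "thick_turf",
        "thin_turf",
        "articulated_coralline",
        "introduced",
    }
)

_SUBSTRATE_SEP = "|"


def normalize_species_name(name: str) -> str:
    """Canonical species key: trimmed, case-folded, single-spaced.

    Taxonomic synonym resolution is the caller's responsibility.
    """
    return " ".join(str(name).strip().casefold().split())


def cover_code_to_fraction(code: str, plus_value: float = 0.005) -> float:
    """Convert an ordinal cover class to its bin-midpoint fraction.

    Parameters
    ----------
    code
        One of ``"+", "1", ..., "5"``.
    plus_value
        Fraction assigned to the trace class ``"+"``.

    Raises
    ------
    ValueError
        If *code* is not a recognised class symbol.
    """
    key = str(code).strip()
    if key not in COVER_CODES:
        raise ValueError(
            f"unknown cover code {code!r}; expected one of "
            f"{sorted(COVER_CODES)}"
        )
    if key == "+":
        if not 0.0 < plus_value <= 0.01:
            raise ValueError(f"plus_value must lie in (0, 0.01], got {plus_value}")
        return plus_value
    return COVER_CODES[key]


@dataclass(frozen=True)
class QuadratSurvey:
    """One quadrat observed at one timepoint."""

    quadrat_id: str
    transect_id: str
    year: int
    depth_m: float
    substrate: frozenset[str]
    cover: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.depth_m == self.depth_m) or self.depth_m in (
            float("inf"),
            float("-inf"),
        ):
            raise ValueError(f"depth_m must be finite, got {self.depth_m}")
        if self.depth_m < 0:
            raise ValueError(
                f"quadrat {self.quadrat_id}: depth_m {self.depth_m} is above "
                "chart datum; intertidal rows are out of scope"
            )
        unknown = set(self.substrate) - SUBSTRATES
        if unknown:
            raise ValueError(f"unknown substrate(s): {sorted(unknown)}")
        for sp, c in self.cover.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(
                    f"quadrat {self.quadrat_id}: cover for {sp!r} is {c}, "
                    "outside [0, 1]"
                )

    @property
    def total_cover(self) -> float:
        # may exceed 1: canopy and understory overlap
        return float(sum(self.cover.values()))

    def is_sand_only(self) -> bool:
        return self.substrate == frozenset({"sand"})


@dataclass(frozen=True)
class PairedQuadrat:
    """The same quadrat surveyed at two timepoints."""

    quadrat_id: str
    historical: QuadratSurvey
    modern: QuadratSurvey

    def __post_init__(self) -> None:
        if self.historical.quadrat_id != self.quadrat_id or (
            self.modern.quadrat_id != self.quadrat_id
        ):
            raise ValueError(
                f"pair {self.quadrat_id}: member surveys carry different ids"
            )
        if self.historical.year == self.modern.year:
            raise ValueError(
                f"pair {self.quadrat_id}: both surveys share year "
                f"{self.historical.year}"
            )


@dataclass(frozen=True)
class SpeciesRecord:
    """Species identity, functional group, and latitudinal range limits."""

    name: str
    functional_group: str
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown functional group {self.functional_group!r}; "
                f"expected one of {sorted(FUNCTIONAL_GROUPS)}"
            )
        if not self.lat_min < self.lat_max:
            raise ValueError(
                f"{self.name}: lat_min ({self.lat_min}) must be < lat_max "
                f"({self.lat_max})"
            )


def filter_quadrats(
    pairs: Sequence[PairedQuadrat],
) -> tuple[list[PairedQuadrat], list[dict]]:
    """Drop pairs whose substrate was sand-only at either timepoint.

    Returns the retained pairs and an exclusion log (one dict per dropped
    pair with the reason).  ``len(kept) + len(log) == len(pairs)``.
    """
    kept: list[PairedQuadrat] = []
    log: list[dict] = []
    for pair in pairs:
        sandy_when = [
            label
            for label, s in (
                ("historical", pair.historical),
                ("modern", pair.modern),
            )
            if s.is_sand_only()
        ]
        if sandy_when:
            log.append(
                {
                    "quadrat_id": pair.quadrat_id,
                    "reason": "sand-only substrate",
                    "timepoints": sandy_when,
                }
            )
        else:
            kept.append(pair)
    return kept, log


def rare_species_filter(
    pairs: Sequence[PairedQuadrat], threshold: float = 0.05
) -> set[str]:
    """Species reaching *threshold* cover in at least one quadrat at either
    timepoint.  ``threshold=0`` keeps every observed species."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    keep: set[str] = set()
    for pair in pairs:
        for survey in (pair.historical, pair.modern):
            for sp, c in survey.cover.items():
                if (threshold == 0 and c > 0) or (threshold > 0 and c >= threshold):
                    keep.add(sp)
    return keep


def pair_surveys(surveys: Iterable[QuadratSurvey]) -> list[PairedQuadrat]:
    """Assemble paired quadrats from a flat survey list.

    Each quadrat id must occur at exactly two distinct years; the earlier
    year is taken as historical.
    """
    by_id: dict[str, list[QuadratSurvey]] = {}
    for s in surveys:
        by_id.setdefault(s.quadrat_id, []).append(s)
    pairs = []
    for qid in sorted(by_id):
        group = sorted(by_id[qid], key=lambda s: s.year)
        if len(group) != 2:
            raise ValueError(
                f"quadrat {qid!r} has {len(group)} timepoints; expected 2"
            )
        pairs.append(PairedQuadrat(qid, historical=group[0], modern=group[1]))
    return pairs


# ---------------------------------------------------------------------------
# Tabular I/O (long-format CSV)
# ---------------------------------------------------------------------------

_SURVEY_KEY_COLS = ["quadrat_id", "transect_id", "year", "depth_m", "substrate"]


def read_surveys(path: str | Path, plus_value: float = 0.005) -> list[QuadratSurvey]:
    """Read a long-format survey CSV.

    Required columns: quadrat_id, transect_id, year, depth_m, substrate
    (``|``-separated), species, and exactly one of ``cover_code`` or
    ``cover_fraction``.
    """
    df = pd.read_csv(path, dtype={"quadrat_id": str, "transect_id": str})
    missing = [c for c in _SURVEY_KEY_COLS + ["species"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_code = "cover_code" in df.columns
    has_frac = "cover_fraction" in df.columns
    if has_code == has_frac:
        raise ValueError(
            f"{path}: exactly one of 'cover_code' or 'cover_fraction' required"
        )
    dup = df.duplicated(subset=["quadrat_id", "year", "species"])
    if dup.any():
        rows = df.loc[dup, ["quadrat_id", "year", "species"]].head()
        raise ValueError(f"{path}: duplicate (quadrat, year, species) rows:\n{rows}")

    if has_code:
        df = df.assign(
            cover_fraction=[
                cover_code_to_fraction(c, plus_value=plus_value)
                for c in df["cover_code"]
            ]
        )
    bad = df[(df["cover_fraction"] < 0) | (df["cover_fraction"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"{path}: cover_fraction outside [0, 1] in rows "
            f"{bad.index.tolist()[:5]}"
        )

    surveys = []
    for (qid, tid, year, depth, sub), g in df.groupby(
        _SURVEY_KEY_COLS, sort=True
    ):
        cover = {
            normalize_species_name(sp): float(c)
            for sp, c in zip(g["species"], g["cover_fraction"])
        }
        surveys.append(
            QuadratSurvey(
                quadrat_id=str(qid),
                transect_id=str(tid),
                year=int(year),
                depth_m=float(depth),
                substrate=frozenset(str(sub).split(_SUBSTRATE_SEP)),
                cover=cover,
            )
        )
    return surveys


def write_surveys(surveys: Sequence[QuadratSurvey], path: str | Path) -> None:
    """Write surveys to canonical long-format CSV (cover_fraction column,
    rows sorted; write∘read is the identity on canonical form)."""
    rows = []
    for s in surveys:
        sub = _SUBSTRATE_SEP.join(sorted(s.substrate))
        for sp in sorted(s.cover):
            rows.append(
                {
                    "quadrat_id": s.quadrat_id,
                    "transect_id": s.transect_id,
                    "year": s.year,
                    "depth_m": s.depth_m,
                    "substrate": sub,
                    "species": sp,
                    "cover_fraction": s.cover[sp],
                }
            )
    df = pd.DataFrame(
        rows, columns=_SURVEY_KEY_COLS + ["species", "cover_fraction"]
    ).sort_values(["quadrat_id", "year", "species"], kind="stable")
    df.to_csv(path, index=False)


def read_species(path: str | Path) -> list[SpeciesRecord]:
    df = pd.read_csv(path)
    required = ["name", "functional_group", "lat_min", "lat_max"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        SpeciesRecord(
            name=normalize_species_name(r.name),
            functional_group=str(r.functional_group),
            lat_min=float(r.lat_min),
            lat_max=float(r.lat_max),
        )
        for r in df.itertuples(index=False)
    ]


def write_species(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "functional_group": r.functional_group,
                "lat_min": r.lat_min,
                "lat_max": r.lat_max,
            }
            for r in sorted(records, key=lambda r: r.name)
        ]
    ).to_csv(path, index=False)


def write_exclusion_log(log: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(log), indent=2) + "\n")
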