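"""Species and community temperature indices.

A species temperature index (STI) is the unweighted mean of a
latitude-binned coastal SST climatology over the species' latitudinal
range.  The community temperature index (CTI) of a quadrat is the
cover-weighted mean STI of the species present.  Species are classified
warm- or cold-affinity against the unweighted mean STI of the species
present in the historical survey.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import QuadratSurvey, SpeciesRecord

__all__ = [
    "Climatology",
    "SpeciesThermalRecord",
    "bin_climatology",
    "compute_sti",
    "classify_affinity",
    "compute_cti",
    "read_climatology",
    "write_climatology",
    "read_thermal_records",
    "write_thermal_records",
]

WARM = "warm"
COLD = "cold"


@dataclass(frozen=True)
class Climatology:
    """Latitude-binned coastal mean-SST field.

    Bin centers sit on the grid ``k * bin_width`` (k integer) and are
    strictly increasing; empty bins are simply absent.  Each bin covers
    the half-open interval ``[center - w/2, center + w/2)``.
    """

    lat_centers: np.ndarray
    mean_sst: np.ndarray
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        lats = np.asarray(self.lat_centers, dtype=float)
        sst = np.asarray(self.mean_sst, dtype=float)
        object.__setattr__(self, "lat_centers", lats)
        object.__setattr__(self, "mean_sst", sst)
        if lats.ndim != 1 or lats.shape != sst.shape:
            raise ValueError("lat_centers and mean_sst must be equal-length 1-D")
        if lats.size == 0:
            raise ValueError("climatology has no bins")
        if not (np.diff(lats) > 0).all():
            raise ValueError("bin centers must be strictly increasing")
        if not np.isfinite(sst).all() or not np.isfinite(lats).all():
            raise ValueError("climatology contains non-finite values")
        # centers must align with the k*bin_width grid
        k = lats / self.bin_width
        if not np.allclose(k, np.round(k), atol=1e-6):
            raise ValueError(
                f"bin centers are not on a {self.bin_width}-degree grid"
            )


@dataclass(frozen=True)
class SpeciesThermalRecord:
    """A species with its STI and (once classified) thermal affinity."""

    species: SpeciesRecord
    sti: float
    affinity: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.sti):
            raise ValueError(f"{self.species.name}: STI must be finite")
        if self.affinity not in (None, WARM, COLD):
            raise ValueError(f"invalid affinity {self.affinity!r}")

    @property
    def name(self) -> str:
        return self.species.name


def bin_climatology(
    lats: Sequence[float],
    ssts: Sequence[float],
    bin_width: float = 0.1,
) -> Climatology:
    """Bin coastal (latitude, SST) samples into a latitudinal climatology.

    Each bin's value is the arithmetic mean of the samples whose latitude
    falls in the half-open interval ``[center - w/2, center + w/2)``.
    Samples are assumed already coastal-masked.
    """
    lats = np.asarray(lats, dtype=float)
    ssts = np.asarray(ssts, dtype=float)
    if lats.size == 0:
        raise ValueError("no samples")
    if lats.shape != ssts.shape:
        raise ValueError("lats and ssts must have the same shape")
    if not (np.isfinite(lats).all() and np.isfinite(ssts).all()):
        raise ValueError("non-finite latitude or SST sample")
    idx = np.floor(lats / bin_width + 0.5).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    uniq, start = np.unique(idx[order], return_index=True)
    sums = np.add.reduceat(ssts[order], start)
    counts = np.diff(np.append(start, idx.size))
    return Climatology(
        lat_centers=uniq * bin_width,
        mean_sst=sums / counts,
        bin_width=bin_width,
    )


def compute_sti(species: SpeciesRecord, clim: Climatology) -> float:
    """Unweighted mean of climatology bin values whose centers fall inside
    the species' latitudinal range (inclusive on both ends)."""
    mask = (clim.lat_centers >= species.lat_min) & (
        clim.lat_centers <= species.lat_max
    )
    if not mask.any():
        raise ValueError(
            f"{species.name}: range [{species.lat_min}, {species.lat_max}] "
            "overlaps no climatology bin"
        )
    return float(clim.mean_sst[mask].mean())


def classify_affinity(
    records: Sequence[SpeciesThermalRecord],
    historical_species: Iterable[str],
) -> list[SpeciesThermalRecord]:
    """Classify every record warm/cold against the historical baseline.

    The baseline is the unweighted mean STI over species present
    historically; ``sti > baseline`` is warm, anything else (including an
    exact tie) is cold.  All species, whichever timepoint they were seen
    in, are classified against this single baseline.
    """
    hist = set(historical_species)
    if not hist:
        raise ValueError("historical species set is empty")
    by_name = {r.name: r for r in records}
    missing = hist - set(by_name)
    if missing:
        raise ValueError(
            f"historical species without thermal records: {sorted(missing)}"
        )
    baseline = float(np.mean([by_name[n].sti for n in sorted(hist)]))
    return [
        replace(r, affinity=WARM if r.sti > baseline else COLD) for r in records
    ]


def compute_cti(
    survey: QuadratSurvey,
    sti: Mapping[str, float],
) -> float:
    """Cover-weighted mean STI over the species of a quadrat.

    Only species present in *sti* participate (the caller applies the
    rare-species filter by restricting that mapping).  Raises if no
    retained species has positive cover.
    """
    num = 0.0
    den = 0.0
    for sp, c in survey.cover.items():
        if c > 0 and sp in sti:
            num += c * sti[sp]
            den += c
    if den == 0:
        raise ValueError(
            f"quadrat {survey.quadrat_id} (year {survey.year}): no retained "
            "species with positive cover"
        )
    return num / den


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_climatology(path: str | Path, bin_width: float = 0.1) -> Climatology:
    df = pd.read_csv(path)
    for col in ("lat_center", "mean_sst"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("lat_center")
    return Climatology(
        lat_centers=df["lat_center"].to_numpy(float),
        mean_sst=df["mean_sst"].to_numpy(float),
        bin_width=bin_width,
    )


def write_climatology(clim: Climatology, path: str | Path) -> None:
    pd.DataFrame(
        {"lat_center": clim.lat_centers, "mean_sst": clim.mean_sst}
    ).to_csv(path, index=False)


def read_thermal_records(
    path: str | Path, species: Sequence[SpeciesRecord]
) -> list[SpeciesThermalRecord]:
    """Read an STI table (species, sti[, affinity]) back into records."""
    df = pd.read_csv(path)
    by_name = {r.name: r for r in species}
    out = []
    for row in df.itertuples(index=False):
        name = str(row.species)
        if name not in by_name:
            raise ValueError(f"{path}: unknown species {name!r}")
        affinity = getattr(row, "affinity", None)
        if isinstance(affinity, float) and np.isnan(affinity):
            affinity = None
        out.append(
            SpeciesThermalRecord(
                species=by_name[name], sti=float(row.sti), affinity=affinity
            )
        )
    return out


def write_thermal_records(
    records: Sequence[SpeciesThermalRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"species": r.name, "sti": r.sti, "affinity": r.affinity}
            for r in sorted(records, key=lambda r: r.name)
        ]
    ).to_csv(path, index=False)
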