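"""Ground-truth-bearing generators for every pipeline input.

Three generators: a latitudinal SST climatology with species whose STIs
are known in closed form; paired quadrat communities with a known CTI
shift or a known four-process mix; and a daily SST series with known
trend, seasonality, AR(1) noise, and injected threshold-exceedance
blocks.  All are bit-reproducible given (scenario, seed) and return a
ledger recording the ground truth they embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import PairedQuadrat, QuadratSurvey, SpeciesRecord
from .thermal_affinity import (
    COLD,
    WARM,
    Climatology,
    SpeciesThermalRecord,
)
from .cti_analysis import PROCESSES, assign_process
from .sst_events import (
    MORTALITY_MIN_DAYS,
    MORTALITY_THRESHOLD,
    STRESS_MIN_DAYS,
    STRESS_THRESHOLD,
    DailySSTSeries,
)

__all__ = [
    "ClimatologyScenario",
    "CommunityScenario",
    "SSTScenario",
    "gen_climatology",
    "gen_paired_surveys",
    "gen_sst_series",
]


# ---------------------------------------------------------------------------
# Climatology + species ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimatologyScenario:
    """Linear coastal gradient sst = intercept + slope * latitude."""

    lat_min: float = 5.0
    lat_max: float = 61.0
    bin_width: float = 0.1
    intercept: float = 30.0
    slope: float = -0.35  # degC per degree latitude; must be monotone
    noise_sd: float = 0.0
    samples_per_bin: int = 1
    n_species: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("gradient must be monotone (slope != 0)")
        if self.lat_min >= self.lat_max:
            raise ValueError("lat_min must be < lat_max")


def gen_climatology(
    scenario: ClimatologyScenario,
) -> tuple[Climatology, list[SpeciesRecord], dict[str, float]]:
    """Generate a binned climatology plus species ranges with closed-form
    expected STIs (exact when noise_sd is 0)."""
    rng = np.random.default_rng(scenario.seed)
    w = scenario.bin_width
    k0 = int(np.floor(scenario.lat_min / w + 0.5))
    k1 = int(np.floor(scenario.lat_max / w + 0.5))
    centers = np.arange(k0, k1 + 1) * w
    lats = np.repeat(centers, scenario.samples_per_bin)
    ssts = scenario.intercept + scenario.slope * lats
    if scenario.noise_sd > 0:
        ssts = ssts + rng.normal(0.0, scenario.noise_sd, size=ssts.size)
    # bin by construction: mean per center
    sst_binned = ssts.reshape(centers.size, scenario.samples_per_bin).mean(axis=1)
    clim = Climatology(lat_centers=centers, mean_sst=sst_binned, bin_width=w)

    species: list[SpeciesRecord] = []
    expected: dict[str, float] = {}
    groups = ["kelp", "red_blade", "thick_turf", "green_blade", "thin_turf"]
    for i in range(scenario.n_species):
        lo, hi = np.sort(
            rng.uniform(scenario.lat_min, scenario.lat_max, size=2)
        )
        if hi - lo < 2 * w:  # guarantee >= 1 bin inside the range
            hi = min(lo + 2 * w, scenario.lat_max)
            lo = hi - 2 * w
        rec = SpeciesRecord(
            name=f"species {i:02d}",
            functional_group=groups[i % len(groups)],
            lat_min=float(lo),
            lat_max=float(hi),
        )
        inside = centers[(centers >= lo) & (centers <= hi)]
        # closed form: mean of the line over the included bin centers
        expected[rec.name] = float(
            scenario.intercept + scenario.slope * inside.mean()
        )
        species.append(rec)
    return clim, species, expected


# ---------------------------------------------------------------------------
# Paired quadrat communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityScenario:
    """Paired-quadrat community design with known ground truth.

    If *target_delta_cti* is set, per-quadrat covers of a cold and a warm
    anchor species are solved so that each pair's CTI difference is
    ``target_delta_cti + noise`` (noise mean zero): the true mean shift is
    known exactly.  Otherwise the *process_mix* construction applies:
    every species gets a constant signed cover change whose depth-binned
    L1 shares reproduce the requested mix.
    """

    n_quadrats: int = 48
    depth_range: tuple[float, float] = (0.0, 6.0)
    n_cold: int = 4
    n_warm: int = 4
    sti_cold: float = 10.0
    sti_warm: float = 16.0
    mean_cover: float = 0.4
    concentration: float = 200.0  # beta concentration for cover noise
    delta_total: float = 0.4  # summed |cover change| per quadrat
    process_mix: dict[str, float] = field(
        default_factory=lambda: {
            "deborealization": 1.0,
            "tropicalization": 0.0,
            "borealization": 0.0,
            "detropicalization": 0.0,
        }
    )
    target_delta_cti: float | None = None
    delta_cti_sd: float = 0.0
    historical_year: int = 1972
    modern_year: int = 2023
    depth_taper_midpoint: float | None = None  # logistic taper on cover
    depth_taper_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.process_mix) - set(PROCESSES)
        if unknown:
            raise ValueError(f"unknown process(es) {sorted(unknown)}")
        mix = {p: self.process_mix.get(p, 0.0) for p in PROCESSES}
        if any(v < 0 for v in mix.values()):
            raise ValueError("process mix fractions must be >= 0")
        if self.target_delta_cti is None:
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("process mix must sum to 1")
            if (mix["borealization"] or mix["deborealization"]) and not self.n_cold:
                raise ValueError("cold-process mix requested with zero cold species")
            if (mix["tropicalization"] or mix["detropicalization"]) and not self.n_warm:
                raise ValueError("warm-process mix requested with zero warm species")
        object.__setattr__(self, "process_mix", mix)

    @property
    def full_mix(self) -> dict[str, float]:
        return dict(self.process_mix)


def _depth_taper(scn: CommunityScenario, depth: float) -> float:
    if scn.depth_taper_midpoint is None:
        return 1.0
    z = (depth - scn.depth_taper_midpoint) / scn.depth_taper_scale
    return 1.0 / (1.0 + np.exp(z))


def _beta_around(rng, mean: float, conc: float, size=None):
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def _make_records(scn: CommunityScenario) -> list[SpeciesThermalRecord]:
    recs = []
    for i in range(scn.n_cold):
        sp = SpeciesRecord(f"cold {i:02d}", "kelp", 40.0, 60.0)
        recs.append(SpeciesThermalRecord(sp, sti=scn.sti_cold, affinity=COLD))
    for i in range(scn.n_warm):
        sp = SpeciesRecord(f"warm {i:02d}", "red_blade", 20.0, 40.0)
        recs.append(SpeciesThermalRecord(sp, sti=scn.sti_warm, affinity=WARM))
    return recs


def gen_paired_surveys(
    scenario: CommunityScenario,
) -> tuple[list[PairedQuadrat], list[SpeciesThermalRecord], dict]:
    """Generate paired quadrats plus thermal records and a ground-truth
    ledger (true mean CTI shift and/or true process mix)."""
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    records = _make_records(scn)
    depths = np.linspace(scn.depth_range[0], scn.depth_range[1], scn.n_quadrats)

    if scn.target_delta_cti is not None:
        return _gen_cti_shift_design(scn, rng, records, depths)
    return _gen_process_mix_design(scn, rng, records, depths)


def _gen_cti_shift_design(scn, rng, records, depths):
    if scn.n_cold < 1 or scn.n_warm < 1:
        raise ValueError("CTI-shift design needs >= 1 cold and 1 warm species")
    s_lo, s_hi = scn.sti_cold, scn.sti_warm
    cold_name = records[0].name
    warm_name = records[scn.n_cold].name
    mid = (s_lo + s_hi) / 2.0
    span = s_hi - s_lo
    pairs = []
    deltas = []
    for q, depth in enumerate(depths):
        # target CTIs: historical near the middle of the STI span, modern
        # shifted by the scenario delta plus mean-zero noise
        t_hist = mid + rng.uniform(-0.15, 0.15) * span
        noise = rng.normal(0.0, scn.delta_cti_sd) if scn.delta_cti_sd else 0.0
        t_mod = float(
            np.clip(t_hist + scn.target_delta_cti + noise, s_lo, s_hi)
        )
        t_hist = float(np.clip(t_hist, s_lo, s_hi))
        deltas.append(t_mod - t_hist)
        taper = _depth_taper(scn, depth)
        total = float(_beta_around(rng, scn.mean_cover, scn.concentration)) * taper

        def covers(target):
            w_warm = (target - s_lo) / span
            return {
                cold_name: total * (1.0 - w_warm),
                warm_name: total * w_warm,
            }

        qid = f"Q{q:03d}"
        tid = f"T{q % 8:02d}"
        sub = frozenset({"bedrock"})
        pairs.append(
            PairedQuadrat(
                qid,
                historical=QuadratSurvey(
                    qid, tid, scn.historical_year, float(depth), sub, covers(t_hist)
                ),
                modern=QuadratSurvey(
                    qid, tid, scn.modern_year, float(depth), sub, covers(t_mod)
                ),
            )
        )
    ledger = {
        "design": "cti_shift",
        "true_delta_cti": float(scn.target_delta_cti),
        "realized_mean_delta_cti": float(np.mean(deltas)),
        "n_pairs": len(pairs),
        "seed": scn.seed,
    }
    return pairs, records, ledger


def _species_deltas(scn: CommunityScenario, records) -> dict[str, float]:
    """Constant signed cover change per species realizing the target mix."""
    cold = [r.name for r in records if r.affinity == COLD]
    warm = [r.name for r in records if r.affinity == WARM]
    roles = {
        "borealization": (cold, +1.0),
        "deborealization": (cold, -1.0),
        "tropicalization": (warm, +1.0),
        "detropicalization": (warm, -1.0),
    }
    deltas = dict.fromkeys([r.name for r in records], 0.0)
    # each process budget is spread over half its class, rounding up, so
    # gain- and loss-processes of one class use disjoint species
    assigned: set[str] = set()
    for proc in PROCESSES:
        frac = scn.process_mix[proc]
        if frac == 0:
            continue
        pool, sign = roles[proc]
        avail = [s for s in pool if s not in assigned]
        if not avail:
            raise ValueError(f"not enough species to realize {proc}")
        take = avail[: max(1, len(avail) // 2) if len(avail) > 1 else 1]
        budget = frac * scn.delta_total
        for s in take:
            deltas[s] = sign * budget / len(take)
            assigned.add(s)
    return deltas


def _gen_process_mix_design(scn, rng, records, depths):
    deltas = _species_deltas(scn, records)
    names = [r.name for r in records]
    base_mean = {}
    for r in records:
        # keep base + delta comfortably inside [0, 1]
        lo_margin = max(0.05, -deltas[r.name] + 0.05)
        hi_margin = min(0.95, 1.0 - deltas[r.name] - 0.05)
        base_mean[r.name] = float(np.clip(scn.mean_cover, lo_margin, hi_margin))
    pairs = []
    for q, depth in enumerate(depths):
        taper = _depth_taper(scn, depth)
        hist_cover = {}
        mod_cover = {}
        for name in names:
            base = float(_beta_around(rng, base_mean[name], scn.concentration))
            hist = base * taper
            mod = (base + deltas[name]) * taper
            hist_cover[name] = float(np.clip(hist, 0.0, 1.0))
            mod_cover[name] = float(np.clip(mod, 0.0, 1.0))
        qid = f"Q{q:03d}"
        tid = f"T{q % 8:02d}"
        sub = frozenset({"bedrock", "boulder"})
        pairs.append(
            PairedQuadrat(
                qid,
                historical=QuadratSurvey(
                    qid, tid, scn.historical_year, float(depth), sub, hist_cover
                ),
                modern=QuadratSurvey(
                    qid, tid, scn.modern_year, float(depth), sub, mod_cover
                ),
            )
        )
    sti = {r.name: r.sti for r in records}
    total_abs = sum(abs(v) for v in deltas.values())
    true_mix = dict.fromkeys(PROCESSES, 0.0)
    for r in records:
        dv = deltas[r.name]
        if dv != 0:
            true_mix[assign_process(dv, r.affinity)] += abs(dv) / total_abs
    # expected CTI change implied by the constant per-species deltas
    mean_total_hist = sum(base_mean[n] for n in names)
    num_hist = sum(base_mean[n] * sti[n] for n in names)
    num_mod = sum((base_mean[n] + deltas[n]) * sti[n] for n in names)
    mean_total_mod = mean_total_hist + sum(deltas.values())
    expected_delta_cti = num_mod / mean_total_mod - num_hist / mean_total_hist
    ledger = {
        "design": "process_mix",
        "true_process_mix": true_mix,
        "species_deltas": deltas,
        "expected_delta_cti": float(expected_delta_cti),
        "n_pairs": len(pairs),
        "seed": scn.seed,
    }
    return pairs, records, ledger


# ---------------------------------------------------------------------------
# Daily SST series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedEvent:
    year: int
    start_doy: int  # 1-based day of year
    length: int
    level: float


@dataclass(frozen=True)
class SSTScenario:
    """Daily series = mean + trend + seasonal sinusoid + AR(1) noise, with
    optional injected constant-level exceedance blocks and gap years."""

    start_year: int = 1961
    end_year: int = 2023
    mean_sst: float = 11.0
    seasonal_amp: float = 4.0  # peak-minus-mean, peak around Aug 1
    peak_doy: int = 213
    trend_per_decade: float = 0.0
    ar1: float = 0.0
    noise_sd: float = 0.0
    events: tuple = ()
    gap_years: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        evs = tuple(
            e if isinstance(e, InjectedEvent) else InjectedEvent(*e)
            for e in self.events
        )
        spans = []
        for e in evs:
            if e.length < 1:
                raise ValueError("event length must be >= 1")
            t0 = pd.Timestamp(year=e.year, month=1, day=1) + pd.Timedelta(
                days=e.start_doy - 1
            )
            spans.append((t0, t0 + pd.Timedelta(days=e.length - 1)))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("injected events overlap")
        object.__setattr__(self, "events", evs)


def gen_sst_series(
    scenario: SSTScenario,
) -> tuple[DailySSTSeries, list[dict]]:
    """Generate the daily series and a ledger of injected events that meet
    the stress/mortality definitions."""
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    dates = pd.date_range(
        f"{scn.start_year}-01-01", f"{scn.end_year}-12-31", freq="D"
    )
    t_years = (dates - dates[0]).days.to_numpy() / 365.25
    doy = dates.dayofyear.to_numpy()
    sst = (
        scn.mean_sst
        + scn.trend_per_decade / 10.0 * t_years
        + scn.seasonal_amp * np.cos(2 * np.pi * (doy - scn.peak_doy) / 365.25)
    )
    if scn.noise_sd > 0:
        eps = rng.normal(0.0, scn.noise_sd, size=len(dates))
        noise = np.empty(len(dates))
        noise[0] = eps[0] / np.sqrt(1 - scn.ar1**2) if scn.ar1 else eps[0]
        for i in range(1, len(dates)):
            noise[i] = scn.ar1 * noise[i - 1] + eps[i]
        sst = sst + noise

    ledger: list[dict] = []
    for e in scn.events:
        t0 = pd.Timestamp(year=e.year, month=1, day=1) + pd.Timedelta(
            days=e.start_doy - 1
        )
        idx0 = dates.searchsorted(t0)
        sst[idx0 : idx0 + e.length] = e.level
        entry = {
            "year": e.year,
            "start_date": str(t0.date()),
            "length": e.length,
            "level": e.level,
            "is_stress": bool(
                e.level >= STRESS_THRESHOLD and e.length >= STRESS_MIN_DAYS
            ),
            "is_mortality": bool(
                e.level >= MORTALITY_THRESHOLD and e.length >= MORTALITY_MIN_DAYS
            ),
        }
        ledger.append(entry)

    if scn.gap_years:
        keep = ~np.isin(dates.year, np.asarray(scn.gap_years))
        dates = dates[keep]
        sst = sst[keep]
    return DailySSTSeries(dates=dates, sst=sst), ledger
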