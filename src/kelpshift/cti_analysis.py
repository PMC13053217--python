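"""CTI shift estimation and four-process decomposition.

The shift between timepoints is, by default, the mean per-pair CTI
difference with a percentile bootstrap CI over quadrats; an optional
spline model integrates year-stratified depth smooths instead.  The
decomposition attributes cover change to four processes by the sign of
each species' change crossed with its thermal affinity:

    warm & gain -> tropicalization      warm & loss -> detropicalization
    cold & gain -> borealization        cold & loss -> deborealization

To correct for the shallow bias of historical sampling, quadrats are
grouped into depth bins (historical depth, 1 m by default); within each
bin species are weighted by |mean cover change| (L1-normalized), and the
overall proportions average the bins equally.  A config switch weights
bins by their share of total |change| instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import PairedQuadrat
from .thermal_affinity import COLD, WARM, SpeciesThermalRecord, compute_cti

__all__ = [
    "PROCESSES",
    "CTIShift",
    "ProcessDecomposition",
    "build_cti_table",
    "estimate_cti_shift",
    "assign_process",
    "decompose_cti_change",
    "dominant_process",
]

TROPICALIZATION = "tropicalization"
DEBOREALIZATION = "deborealization"
BOREALIZATION = "borealization"
DETROPICALIZATION = "detropicalization"
PROCESSES = (TROPICALIZATION, DEBOREALIZATION, BOREALIZATION, DETROPICALIZATION)


@dataclass(frozen=True)
class CTIShift:
    """Integrated modern-minus-historical CTI change with CI."""

    delta_cti: float
    ci_low: float
    ci_high: float
    method: str
    n_pairs: int
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.delta_cti <= self.ci_high:
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"estimate {self.delta_cti}"
            )


@dataclass(frozen=True)
class ProcessDecomposition:
    """Proportional contribution of each thermal process to CTI change."""

    proportions: Mapping[str, float]
    per_species: pd.DataFrame
    no_change: bool = False
    bin_weighting: str = "equal"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PROCESSES) - set(self.proportions)
        if missing:
            raise ValueError(f"missing processes {sorted(missing)}")
        vals = np.array([self.proportions[p] for p in PROCESSES])
        if (vals < -1e-12).any():
            raise ValueError("negative proportion")
        total = float(vals.sum())
        if self.no_change:
            if abs(total) > 1e-12:
                raise ValueError("no_change flag with nonzero proportions")
        elif abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")


def build_cti_table(
    pairs: Sequence[PairedQuadrat], sti: Mapping[str, float]
) -> pd.DataFrame:
    """Per-quadrat CTI at both timepoints (columns: quadrat_id, depth_m,
    cti_historical, cti_modern)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "quadrat_id": p.quadrat_id,
                "depth_m": p.historical.depth_m,
                "cti_historical": compute_cti(p.historical, sti),
                "cti_modern": compute_cti(p.modern, sti),
            }
        )
    return pd.DataFrame(rows)


def estimate_cti_shift(
    cti_table: pd.DataFrame,
    method: str = "paired_bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
    ci: float = 0.95,
) -> CTIShift:
    """Estimate the community-wide CTI shift from a per-quadrat table.

    ``paired_bootstrap`` (default): point estimate is the mean per-pair
    difference; the CI is a percentile bootstrap resampling quadrats.
    ``spline_model``: year-stratified smoothing splines of CTI on depth
    with per-quadrat intercepts; the shift is the difference of
    depth-integrated smooths (CI still by quadrat bootstrap).
    """
    required = {"quadrat_id", "cti_historical", "cti_modern"}
    missing = required - set(cti_table.columns)
    if missing:
        raise ValueError(f"cti_table missing columns {sorted(missing)}")
    n = len(cti_table)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0

    if method == "paired_bootstrap":
        diffs = (
            cti_table["cti_modern"] - cti_table["cti_historical"]
        ).to_numpy(float)
        point = float(diffs.mean())
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = diffs[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        lo, hi = min(lo, point), max(hi, point)
    elif method == "spline_model":
        if "depth_m" not in cti_table.columns:
            raise ValueError("spline_model needs a depth_m column")
        point = _spline_shift(cti_table)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            sub = cti_table.iloc[rng.integers(0, n, size=n)]
            boots[b] = _spline_shift(sub)
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        lo, hi = min(lo, point), max(hi, point)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CTIShift(
        delta_cti=point,
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        n_pairs=n,
        n_boot=n_boot,
        seed=seed,
    )


def _spline_shift(table: pd.DataFrame, grid_size: int = 101) -> float:
    """Difference of depth-integrated year smooths after removing
    per-quadrat intercepts (within-pair centering)."""
    from scipy.interpolate import make_smoothing_spline

    depth = table["depth_m"].to_numpy(float)
    hist = table["cti_historical"].to_numpy(float)
    mod = table["cti_modern"].to_numpy(float)
    # quadrat random intercept: remove each pair's mean, keep grand mean
    pair_mean = (hist + mod) / 2.0
    grand = pair_mean.mean()
    hist_c = hist - pair_mean + grand
    mod_c = mod - pair_mean + grand
    order = np.argsort(depth, kind="stable")
    d = depth[order]
    # collapse duplicate depths (spline needs strictly increasing x)
    grid = np.linspace(d[0], d[-1], grid_size)

    def fit(y: np.ndarray) -> np.ndarray:
        dd, inv = np.unique(d, return_inverse=True)
        ym = np.zeros(dd.size)
        np.add.at(ym, inv, y[order])
        counts = np.bincount(inv)
        ym /= counts
        if dd.size < 4:  # too few distinct depths for a smooth: use mean
            return np.full_like(grid, ym.mean())
        spl = make_smoothing_spline(dd, ym)
        return spl(grid)

    return float(np.mean(fit(mod_c) - fit(hist_c)))


def assign_process(delta_cover: float, affinity: str) -> str:
    """Map a signed cover change and an affinity label to a process."""
    if delta_cover == 0:
        raise ValueError("zero cover change contributes to no process")
    if affinity == WARM:
        return TROPICALIZATION if delta_cover > 0 else DETROPICALIZATION
    if affinity == COLD:
        return BOREALIZATION if delta_cover > 0 else DEBOREALIZATION
    raise ValueError(f"unknown affinity {affinity!r}")


def decompose_cti_change(
    pairs: Sequence[PairedQuadrat],
    records: Sequence[SpeciesThermalRecord],
    bin_width: float = 1.0,
    bin_weighting: str = "equal",
) -> ProcessDecomposition:
    """Depth-bin-corrected four-process decomposition of cover change.

    Per depth bin (half-open [k*w, (k+1)*w) on historical depth): average
    cover per species per timepoint over the quadrats in the bin, take the
    change, L1-normalize |change| into species weights, and sum weights by
    assigned process.  Overall proportions average the non-empty bins
    (``bin_weighting="equal"``) or weight bins by their share of total
    |change| (``"delta_share"``).
    """
    if bin_weighting not in ("equal", "delta_share"):
        raise ValueError(f"unknown bin_weighting {bin_weighting!r}")
    if not pairs:
        raise ValueError("no pairs")
    affinities = {
        r.name: r.affinity for r in records if r.affinity in (WARM, COLD)
    }
    if not affinities:
        raise ValueError("no species with assigned affinity")
    species = sorted(affinities)

    bins: dict[int, list[PairedQuadrat]] = {}
    for p in pairs:
        bins.setdefault(math.floor(p.historical.depth_m / bin_width), []).append(p)

    bin_props: list[dict[str, float]] = []
    bin_abs_totals: list[float] = []
    sp_weights = {s: [] for s in species}  # signed weight per bin
    for k in sorted(bins):
        group = bins[k]
        delta = {}
        for s in species:
            hist = np.mean([p.historical.cover.get(s, 0.0) for p in group])
            mod = np.mean([p.modern.cover.get(s, 0.0) for p in group])
            delta[s] = mod - hist
        total_abs = sum(abs(v) for v in delta.values())
        if total_abs == 0:
            continue  # inactive bin: contributes to no process
        proc_abs = dict.fromkeys(PROCESSES, 0.0)
        for s, dv in delta.items():
            w = abs(dv) / total_abs
            if dv != 0:
                proc_abs[assign_process(dv, affinities[s])] += abs(dv)
            sp_weights[s].append(math.copysign(w, dv) if dv != 0 else 0.0)
        # divide summed |change| (not per-species quotients) so a bin whose
        # change is all one process yields exactly 1.0
        props = {p: v / total_abs for p, v in proc_abs.items()}
        bin_props.append(props)
        bin_abs_totals.append(total_abs)

    n_bins_total = len(bins)
    if not bin_props:  # nothing changed anywhere
        per_species = pd.DataFrame(
            {
                "species": species,
                "affinity": [affinities[s] for s in species],
                "mean_signed_weight": 0.0,
                "process": None,
            }
        )
        return ProcessDecomposition(
            proportions=dict.fromkeys(PROCESSES, 0.0),
            per_species=per_species,
            no_change=True,
            bin_weighting=bin_weighting,
            extra={"n_bins": n_bins_total, "n_active_bins": 0},
        )

    if bin_weighting == "equal":
        raw_w = [1.0] * len(bin_props)
    else:
        raw_w = bin_abs_totals
    w_sum = float(sum(raw_w))
    proportions = {
        proc: float(sum(w * bp[proc] for w, bp in zip(raw_w, bin_props)) / w_sum)
        for proc in PROCESSES
    }

    rows = []
    for s in species:
        ws = [w for w in sp_weights[s]]
        mean_w = float(np.mean(ws)) if ws else 0.0
        proc = (
            assign_process(mean_w, affinities[s]) if mean_w != 0 else None
        )
        rows.append(
            {
                "species": s,
                "affinity": affinities[s],
                "mean_signed_weight": mean_w,
                "process": proc,
            }
        )
    per_species = pd.DataFrame(rows)
    return ProcessDecomposition(
        proportions=proportions,
        per_species=per_species,
        no_change=False,
        bin_weighting=bin_weighting,
        extra={"n_bins": n_bins_total, "n_active_bins": len(bin_props)},
    )


def dominant_process(decomp: ProcessDecomposition) -> list[str]:
    """Process(es) with the largest proportion; ties are all reported."""
    if decomp.no_change:
        raise ValueError("no cover change: no dominant process")
    best = max(decomp.proportions[p] for p in PROCESSES)
    return [p for p in PROCESSES if decomp.proportions[p] >= best - 1e-12]
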