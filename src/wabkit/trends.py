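"""Cross-composition analyses of decomposed WAB data.

Three questions are asked of a series of samples spanning S/P ratios:

1. Do the normalized band profiles split into two *families* (a
   protein-dominated, low-frequency-heavy family at low S/P and a
   sugar-dominated, high-frequency-heavy family at high S/P), and where is
   the transition? Operationalized as the largest L2 gap between
   consecutive S/P-ordered profiles; the transition ratio is labeled on the
   low side of that gap.
2. Does a sub-band population grow or shrink with sugar content?
   Operationalized as a Spearman rank correlation of population against
   log2(S/P) (the design doubles S/P between levels).
3. Does a sub-band's peak frequency drift red (down) or blue (up) with
   S/P? A shift is declared only when the endpoint difference exceeds the
   combined replicate SD of the two endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import spearmanr

from wabkit.errors import UsageError
from wabkit.preprocess import WAB_REGION, Region, extract_region, normalize_area
from wabkit.spectra_io import Spectrum

#: Below this separation score a family split is reported but flagged unreliable.
SEPARATION_RELIABILITY_THRESHOLD = 2.0

#: |Spearman rho| at or above which a population trend is called directional.
RHO_THRESHOLD = 0.7


@dataclass(frozen=True)
class FamilySplit:
    """Two-family partition of the finite S/P values with a transition ratio."""

    low_family: tuple[float, ...]
    high_family: tuple[float, ...]
    transition_sp: float
    separation_score: float
    reliable: bool


@dataclass(frozen=True)
class TrendResult:
    """Population direction and peak-shift classification for one sub-band."""

    direction: str  # increasing | decreasing | flat
    rank_correlation: float
    shift: str = "none"  # red | blue | none
    shift_magnitude: float = 0.0
    sd_missing: bool = False


def cluster_families(
    profiles: Mapping[float, Spectrum],
    region: Region = WAB_REGION,
    reliability_threshold: float = SEPARATION_RELIABILITY_THRESHOLD,
) -> FamilySplit:
    """Split S/P-ordered normalized profiles at the largest consecutive L2 gap.

    Profiles are area-normalized internally over ``region`` (the split is
    therefore invariant to a common rescaling) and must share a common
    wavenumber grid. Requires at least 3 finite S/P values. The transition
    S/P is the value immediately below the largest gap; the separation score
    is that gap divided by the mean of the remaining gaps (1.0 when all
    other gaps vanish together with the largest).
    """
    sps = sorted(sp for sp in profiles if math.isfinite(sp))
    if len(sps) < 3:
        raise UsageError(f"cluster_families needs >= 3 finite S/P profiles, got {len(sps)}")
    norm = []
    grid = None
    for sp in sps:
        s = normalize_area(extract_region(profiles[sp], region), region)
        if grid is None:
            grid = s.wavenumbers
        elif not np.array_equal(grid, s.wavenumbers):
            raise UsageError("profiles are not on a common wavenumber grid")
        norm.append(s.absorbance)
    gaps = np.array(
        [float(np.linalg.norm(norm[i + 1] - norm[i])) for i in range(len(norm) - 1)]
    )
    i_max = int(np.argmax(gaps))
    largest = float(gaps[i_max])
    others = np.delete(gaps, i_max)
    mean_others = float(np.mean(others)) if len(others) else 0.0
    if largest == 0.0:
        score = 1.0
    elif mean_others == 0.0:
        score = math.inf
    else:
        score = largest / mean_others
    return FamilySplit(
        low_family=tuple(sps[: i_max + 1]),
        high_family=tuple(sps[i_max + 1 :]),
        transition_sp=sps[i_max],
        separation_score=score,
        reliable=score >= reliability_threshold,
    )


def population_trend(populations: Mapping[float, float]) -> TrendResult:
    """Direction of one sub-band's population with increasing S/P.

    Spearman rank correlation of population against log2(S/P) over at least
    4 finite S/P points; rho >= 0.7 is increasing, rho <= -0.7 decreasing,
    otherwise flat. Constant populations give rho = 0 / flat.
    """
    pts = sorted((sp, p) for sp, p in populations.items() if math.isfinite(sp))
    if len(pts) < 4:
        raise UsageError(f"population_trend needs >= 4 finite S/P points, got {len(pts)}")
    x = np.log2([sp for sp, _ in pts])
    y = np.array([p for _, p in pts])
    if np.all(y == y[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(x, y).statistic)
        if math.isnan(rho):
            rho = 0.0
    if rho >= RHO_THRESHOLD:
        direction = "increasing"
    elif rho <= -RHO_THRESHOLD:
        direction = "decreasing"
    else:
        direction = "flat"
    return TrendResult(direction=direction, rank_correlation=rho)


def peak_shift(centers: Mapping[float, tuple[float, float | None]]) -> TrendResult:
    """Red/blue classification of a sub-band's peak frequency across S/P.

    Compares the lowest- and highest-S/P endpoint means; a shift is declared
    iff |delta| exceeds the combined SD sqrt(sd_lo^2 + sd_hi^2). Missing SDs
    are treated as 0 and flagged. Red = frequency decreases with S/P,
    blue = increases.
    """
    pts = sorted((sp, ms) for sp, ms in centers.items() if math.isfinite(sp))
    if len(pts) < 2:
        raise UsageError(f"peak_shift needs >= 2 finite S/P points, got {len(pts)}")
    (_, (m_lo, sd_lo)), (_, (m_hi, sd_hi)) = pts[0], pts[-1]
    sd_missing = sd_lo is None or sd_hi is None
    sd_lo = 0.0 if sd_lo is None else sd_lo
    sd_hi = 0.0 if sd_hi is None else sd_hi
    delta = m_hi - m_lo
    combined = math.hypot(sd_lo, sd_hi)
    if abs(delta) > combined:
        shift = "blue" if delta > 0 else "red"
        magnitude = abs(delta)
    else:
        shift, magnitude = "none", 0.0
    return TrendResult(
        direction="flat",
        rank_correlation=0.0,
        shift=shift,
        shift_magnitude=magnitude,
        sd_missing=sd_missing,
    )


def trend_report(
    populations_by_class: Mapping[str, Mapping[float, float]],
    centers_by_class: Mapping[str, Mapping[float, tuple[float, float | None]]] | None = None,
) -> dict[str, dict]:
    """Per-class population trend + peak shift, as a JSON-ready dict."""
    report: dict[str, dict] = {}
    for name, pops in populations_by_class.items():
        t = population_trend(pops)
        entry = {
            "direction": t.direction,
            "rank_correlation": t.rank_correlation,
            "shift": "none",
            "shift_magnitude": 0.0,
        }
        if centers_by_class and name in centers_by_class:
            usable = {
                sp: ms for sp, ms in centers_by_class[name].items() if ms[0] is not None
            }
            if len([sp for sp in usable if math.isfinite(sp)]) >= 2:
                s = peak_shift(usable)
                entry["shift"] = s.shift
                entry["shift_magnitude"] = s.shift_magnitude
        report[name] = entry
    return report
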