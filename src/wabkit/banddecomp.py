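"""Window-constrained Gaussian decomposition of the water association band.

The normalized WAB is modeled as a sum of at most seven Gaussian sub-bands,
each confined to a fixed frequency window that identifies a class of water
hydrogen-bond environment, from strongly destructured (chaotropic, around
2000 cm-1) to ice-like (kosmotropic, around 2250 cm-1 — the cubic-ice
maximum at 2255 cm-1 falls in the W4 window):

====  ==============  ==========================
name  window (cm-1)   attribution
====  ==============  ==========================
W0a   2000-2010       strongly destructured
W0b   2015-2035       strongly destructured
W1    2045-2065       destructured
W2a   2080-2120       weakly destructured (bulk-like)
W2b   2120-2160       weakly structured (bulk-like)
W3    2170-2200       structured
W4    2230-2270       strongly structured (ice-like)
====  ==============  ==========================

Five classes (W0b, W1, W2a, W3, W4) are mandatory — they occur in every
sample — while W0a and W2b are optional duplications admitted only when the
data demand them. Model selection follows the parsimony principle: the
smallest set of Gaussians that describes the band, operationalized here as
an exhaustive BIC comparison of the four candidate class sets (mandatory,
+W0a, +W2b, +both) with a strong-evidence acceptance threshold.

A sub-band's *fractional population* is its analytic area divided by the
total fitted area; populations are the primary observable of the analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from wabkit.errors import FitError, RangeError, UsageError
from wabkit.gaussians import FWHM_OVER_SIGMA, gaussian_area
from wabkit.preprocess import Region
from wabkit.spectra_io import Spectrum

# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class SubBandClass:
    """One entry of the seven-class sub-band taxonomy."""

    name: str
    window: Region
    attribution: str
    mandatory: bool


#: The seven sub-band classes, in ascending frequency order.
TAXONOMY: dict[str, SubBandClass] = {
    c.name: c
    for c in (
        SubBandClass("W0a", Region(2000.0, 2010.0), "strongly destructured", False),
        SubBandClass("W0b", Region(2015.0, 2035.0), "strongly destructured", True),
        SubBandClass("W1", Region(2045.0, 2065.0), "destructured", True),
        SubBandClass("W2a", Region(2080.0, 2120.0), "weakly destructured (bulk-like)", True),
        SubBandClass("W2b", Region(2120.0, 2160.0), "weakly structured (bulk-like)", True),
        SubBandClass("W3", Region(2170.0, 2200.0), "structured", True),
        SubBandClass("W4", Region(2230.0, 2270.0), "strongly structured (ice-like)", True),
    )
}
# W2b is a duplication band: optional despite sitting mid-taxonomy.
TAXONOMY["W2b"] = replace(TAXONOMY["W2b"], mandatory=False)

CLASS_ORDER = tuple(TAXONOMY)  # ascending frequency
MANDATORY_CLASSES = tuple(n for n in CLASS_ORDER if TAXONOMY[n].mandatory)
OPTIONAL_CLASSES = tuple(n for n in CLASS_ORDER if not TAXONOMY[n].mandatory)


def assign_band(center: float) -> tuple[str, bool]:
    """Map a peak frequency to a sub-band class.

    Returns ``(name, in_window)``. The 2120 cm-1 boundary shared by W2a and
    W2b belongs to W2a by convention. A center in an inter-window gap maps
    to the nearest class (``in_window`` False), ties broken toward the
    lower-frequency class. Centers outside [2000, 2500] cm-1 are rejected.
    """
    if not 2000.0 <= center <= 2500.0:
        raise RangeError(f"center {center} outside the WAB range [2000, 2500] cm-1")
    # closed windows, scanned in ascending order: the shared 2120 cm-1
    # boundary therefore belongs to W2a, the lower-frequency class
    for name in CLASS_ORDER:
        win = TAXONOMY[name].window
        if win.lo <= center <= win.hi:
            return name, True
    best, best_d = None, math.inf
    for name in CLASS_ORDER:
        win = TAXONOMY[name].window
        d = max(win.lo - center, center - win.hi, 0.0)
        if d < best_d:  # strict: ties keep the lower-frequency class
            best, best_d = name, d
    return best, best_d == 0.0


# ---------------------------------------------------------------------------
# fit containers


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted sub-band: class label, center, FWHM, amplitude."""

    class_name: str
    center: float
    fwhm: float
    amplitude: float

    @property
    def area(self) -> float:
        return gaussian_area(self.amplitude, self.fwhm)


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the constrained fit and the minimal-model selection."""

    fwhm_bounds: tuple[float, float] = (20.0, 200.0)
    selection_threshold: float = 10.0
    max_iterations: int = 2000
    tolerance: float = 1e-12
    param_tolerance: float = 1e-10
    init_fwhm: float = 60.0
    seed: int = 0
    multistart: int = 0

    def __post_init__(self):
        lo, hi = self.fwhm_bounds
        if not (0 < lo < hi):
            raise UsageError(f"fwhm_bounds must be positive and ordered, got {self.fwhm_bounds}")
        if self.selection_threshold < 0:
            raise UsageError("selection_threshold must be >= 0")


@dataclass(frozen=True)
class Decomposition:
    """Fitted components, fractional populations and fit diagnostics."""

    components: tuple[GaussianComponent, ...]
    populations: dict[str, float]
    rss: float
    n_points: int
    bic: float
    sample_id: str = ""

    def component(self, name: str) -> GaussianComponent:
        for c in self.components:
            if c.class_name == name:
                return c
        raise KeyError(name)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.class_name for c in self.components)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "components": [
                    {
                        "class": c.class_name,
                        "center": c.center,
                        "fwhm": c.fwhm,
                        "amplitude": c.amplitude,
                    }
                    for c in self.components
                ],
                "populations": self.populations,
                "rss": self.rss,
                "n_points": self.n_points,
                "bic": self.bic,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# fitting


def _resolve_classes(classes: Iterable[SubBandClass | str]) -> list[SubBandClass]:
    out = []
    for c in classes:
        out.append(TAXONOMY[c] if isinstance(c, str) else c)
    if not out:
        raise UsageError("empty class set")
    names = [c.name for c in out]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate class names in {names}")
    return sorted(out, key=lambda c: CLASS_ORDER.index(c.name))


def _model_and_jac(w: np.ndarray, k: int):
    """Return residual-model evaluator and analytic Jacobian for k Gaussians.

    Parameter vector layout: (center, fwhm, amplitude) per component.
    """

    def model(p):
        y = np.zeros_like(w)
        for i in range(k):
            c, fw, a = p[3 * i : 3 * i + 3]
            s = fw / FWHM_OVER_SIGMA
            y += a * np.exp(-0.5 * ((w - c) / s) ** 2)
        return y

    def jac(p):
        J = np.empty((w.size, 3 * k))
        for i in range(k):
            c, fw, a = p[3 * i : 3 * i + 3]
            s = fw / FWHM_OVER_SIGMA
            z = (w - c) / s
            g = np.exp(-0.5 * z**2)
            J[:, 3 * i] = a * g * z / s
            J[:, 3 * i + 1] = a * g * z**2 / fw
            J[:, 3 * i + 2] = g
        return J

    return model, jac


def _bic(rss: float, n: int, n_params: int) -> float:
    # Gaussian-likelihood BIC up to a model-independent constant.
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + n_params * math.log(n)


def fit_fixed_set(
    spectrum: Spectrum,
    classes: Iterable[SubBandClass | str],
    config: FitConfig = FitConfig(),
    warm_from: Decomposition | None = None,
) -> Decomposition:
    """Bounded least-squares fit of one Gaussian per class.

    Centers are box-constrained to the class windows (half-open at the
    upper edge except W4, so the shared 2120 cm-1 boundary belongs to W2a),
    FWHMs to ``config.fwhm_bounds``, amplitudes to [0, inf). The spectrum is
    expected to be background-subtracted and area-normalized over the WAB
    region. Deterministic for fixed inputs and config.

    ``warm_from`` seeds the initial point from a previously fitted
    decomposition: shared classes start at their fitted parameters, extra
    classes at the default initials with amplitude 0. This guarantees that a
    superset fit never ends with a larger residual than the subset fit it
    was warmed from.
    """
    cls = _resolve_classes(classes)
    for c in cls:
        if not spectrum.covers(c.window.lo, c.window.hi):
            raise RangeError(
                f"spectrum span {spectrum.span} does not cover the {c.name} window "
                f"({c.window.lo}, {c.window.hi})"
            )
    w = spectrum.wavenumbers
    y = spectrum.absorbance
    k = len(cls)

    fw_lo, fw_hi = config.fwhm_bounds
    eps = 1e-9
    lb = np.empty(3 * k)
    ub = np.empty(3 * k)
    x0 = np.empty(3 * k)
    warm = {c.class_name: c for c in warm_from.components} if warm_from is not None else {}
    for i, c in enumerate(cls):
        hi = c.window.hi - (eps if c.name != "W4" else 0.0)
        lb[3 * i : 3 * i + 3] = (c.window.lo, fw_lo, 0.0)
        ub[3 * i : 3 * i + 3] = (hi, fw_hi, np.inf)
        if c.name in warm:
            prev = warm[c.name]
            x0[3 * i : 3 * i + 3] = (
                min(max(prev.center, c.window.lo), hi),
                min(max(prev.fwhm, fw_lo), fw_hi),
                max(prev.amplitude, 0.0),
            )
        else:
            mid = min(max(0.5 * (c.window.lo + c.window.hi), c.window.lo), hi)
            amp0 = 0.0 if warm_from is not None else max(float(spectrum.interp(mid)), 0.0)
            x0[3 * i : 3 * i + 3] = (mid, min(max(config.init_fwhm, fw_lo), fw_hi), amp0)

    model, jac = _model_and_jac(w, k)

    def resid(p):
        return model(p) - y

    def solve(x_init):
        # Converged when the relative RSS change < tolerance or the
        # parameter step < param_tolerance. The solver is re-run from its
        # own solution until no further RSS improvement: overlapping
        # Gaussians form long sloppy valleys in which a single trust-region
        # descent stalls with a shrunken radius; resetting the radius lets
        # the final Gauss-Newton steps land on the minimum.
        # an RSS at the double-precision floor of the data norm is
        # numerically zero: further restarts only polish meaningless digits
        cost_floor = 0.5 * (100 * np.finfo(float).eps) ** 2 * float(y @ y)
        best = None
        stalled = False
        x_cur = x_init
        for _ in range(8):
            run = least_squares(
                resid, x_cur, jac=jac, bounds=(lb, ub),
                ftol=config.tolerance, xtol=config.param_tolerance, gtol=None,
                max_nfev=config.max_iterations,
            )
            if best is None or run.cost <= best.cost:
                stalled = best is not None and best.cost - run.cost <= config.tolerance * max(
                    best.cost, 1e-300
                )
                best = run
            else:
                stalled = True
            if stalled or best.cost <= cost_floor:
                break
            x_cur = run.x
        converged = best.status > 0 or stalled or best.cost <= cost_floor
        return best, converged

    sol, converged = solve(x0)
    if config.multistart > 0:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.multistart):
            jitter = rng.uniform(-1.0, 1.0, size=3 * k)
            x_try = np.clip(x0 + jitter * 0.1 * (np.where(np.isfinite(ub), ub, x0 + 1) - lb), lb,
                            np.where(np.isfinite(ub), ub, np.inf))
            alt, alt_conv = solve(x_try)
            if alt.cost < sol.cost:
                sol, converged = alt, alt_conv
    if not converged:
        raise FitError(
            "sub-band fit did not converge",
            diagnostics={"status": sol.status, "message": sol.message,
                         "nfev": sol.nfev, "cost": sol.cost,
                         "classes": [c.name for c in cls]},
        )

    comps = tuple(
        GaussianComponent(
            cls[i].name,
            float(sol.x[3 * i]),
            float(sol.x[3 * i + 1]),
            float(sol.x[3 * i + 2]),
        )
        for i in range(k)
    )
    areas = np.array([c.area for c in comps])
    total = float(areas.sum())
    if total <= 0:
        raise FitError("all fitted component areas are zero; nothing to normalize",
                       diagnostics={"classes": [c.name for c in cls]})
    populations = {c.class_name: float(a / total) for c, a in zip(comps, areas)}
    rss = float(2.0 * sol.cost)
    n = int(w.size)
    return Decomposition(
        components=comps,
        populations=populations,
        rss=rss,
        n_points=n,
        bic=_bic(rss, n, 3 * k),
        sample_id=spectrum.meta.sample_id,
    )


def select_minimal_model(
    spectrum: Spectrum, config: FitConfig = FitConfig()
) -> Decomposition:
    """Fit the WAB with the smallest adequate set of sub-bands.

    The five mandatory classes are always fitted; the optional duplication
    bands W0a and W2b (each alone, and both) are admitted only when they
    improve the BIC by at least ``config.selection_threshold`` over the best
    accepted smaller model. Among BIC-equivalent candidates the model with
    the fewest components wins. Superset fits are warm-started from the
    mandatory fit (and the better of warm/cold starts kept).
    """
    base = fit_fixed_set(spectrum, MANDATORY_CLASSES, config)

    def fit_superset(extra: Sequence[str]) -> Decomposition:
        names = MANDATORY_CLASSES + tuple(extra)
        warm = fit_fixed_set(spectrum, names, config, warm_from=base)
        cold = fit_fixed_set(spectrum, names, config)
        return warm if warm.rss <= cold.rss else cold

    candidates = {
        5: [base],
        6: [fit_superset(("W0a",)), fit_superset(("W2b",))],
        7: [fit_superset(("W0a", "W2b"))],
    }
    accepted = base
    for size in (6, 7):
        best = min(candidates[size], key=lambda d: d.bic)
        if best.bic <= accepted.bic - config.selection_threshold:
            accepted = best
    return accepted


# ---------------------------------------------------------------------------
# replicate aggregation


@dataclass(frozen=True)
class ClassStats:
    """Replicate statistics for one sub-band class."""

    mean_population: float
    sd_population: float
    mean_center: float | None
    sd_center: float | None
    n_present: int


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-sample aggregate over replicate decompositions."""

    sample_id: str
    classes: dict[str, ClassStats]
    n_replicates: int


def _sample_sd(values: Sequence[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def aggregate_replicates(decomps: Sequence[Decomposition]) -> ReplicateSummary:
    """Mean and sample SD of populations and centers across replicates.

    A class absent from a replicate contributes population 0 to the
    population statistics; its center statistics are taken only over the
    replicates where the class is present. All decompositions must share one
    sample_id. SDs are sample (n-1) standard deviations and are 0 for a
    single observation; the instrumental-resolution uncertainty is not
    folded in.
    """
    decomps = list(decomps)
    if not decomps:
        raise UsageError("aggregate_replicates: no decompositions")
    ids = {d.sample_id for d in decomps}
    if len(ids) > 1:
        raise UsageError(f"aggregate_replicates: mixed sample_ids {sorted(ids)}")
    present_classes = [n for n in CLASS_ORDER if any(n in d.populations for d in decomps)]
    stats: dict[str, ClassStats] = {}
    for name in present_classes:
        pops = [d.populations.get(name, 0.0) for d in decomps]
        centers = [d.component(name).center for d in decomps if name in d.populations]
        stats[name] = ClassStats(
            mean_population=float(np.mean(pops)),
            sd_population=_sample_sd(pops),
            mean_center=float(np.mean(centers)) if centers else None,
            sd_center=_sample_sd(centers) if centers else None,
            n_present=len(centers),
        )
    return ReplicateSummary(sample_id=decomps[0].sample_id, classes=stats,
                            n_replicates=len(decomps))
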