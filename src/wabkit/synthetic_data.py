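"""Synthetic WAB spectra and study designs with planted ground truth.

The generator is the forward model of the decomposition: a spectrum is a
sum of sub-band Gaussians whose analytic areas are proportional to planted
fractional populations, sitting on a constant + CH-stretch-tail background,
with additive white Gaussian noise at 1 cm-1 resolution.

Composition dependence is encoded per sugar as a logistic interpolation (in
log2 S/P) between a protein-dominated population vector ``p_low`` (heavy in
the low-frequency, chaotropic classes) and a sugar-dominated vector
``p_high`` (heavy in the high-frequency, kosmotropic classes); the switch
midpoint and steepness distinguish sugars with smooth (trehalose-like) from
abrupt (sucrose-like) regime changes. Whole study designs add
replicate-level Dirichlet jitter of the populations and truncated-normal
jitter of the centers, with all randomness derived from a single seed via
stable per-(sugar, S/P, replicate) substreams.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from wabkit.banddecomp import CLASS_ORDER, TAXONOMY
from wabkit.errors import UsageError
from wabkit.gaussians import gaussian, sigma_from_fwhm
from wabkit.preprocess import BackgroundModel
from wabkit.spectra_io import (
    PROTEIN_FREE,
    SampleMeta,
    Spectrum,
    write_manifest,
    write_spectrum,
)

# ---------------------------------------------------------------------------
# defaults

#: Planted sub-band centers: window midpoints.
DEFAULT_CENTERS: dict[str, float] = {
    name: 0.5 * (TAXONOMY[name].window.lo + TAXONOMY[name].window.hi) for name in CLASS_ORDER
}

#: Planted sub-band FWHMs (cm-1). Narrow enough (22-36) that neighboring
#: classes produce resolvable structure — the decomposition's premise is
#: that the sub-bands are distinguishable features, and much wider
#: components render the seven-band mixture statistically unidentifiable at
#: realistic noise. The composite envelope still spans the ~250-300 cm-1
#: full-band scale because the centers spread over 2000-2270 cm-1.
DEFAULT_FWHMS: dict[str, float] = {
    "W0a": 22.0,
    "W0b": 25.0,
    "W1": 28.0,
    "W2a": 36.0,
    "W2b": 34.0,
    "W3": 32.0,
    "W4": 30.0,
}

#: Default background: small constant offset plus a CH-stretch tail whose
#: low-frequency wing reaches into the 2400-2600 cm-1 anchor window.
DEFAULT_BACKGROUND = BackgroundModel(
    offset=0.05, tail_center=2900.0, tail_fwhm=300.0, tail_amplitude=1.0
)

#: Default measurement-noise SD as a fraction of the maximum absorbance.
DEFAULT_NOISE_SD = 0.003

#: Total planted band area (absorbance * cm-1); arbitrary since the
#: analysis normalizes, chosen to give peak absorbance of order 0.5.
DEFAULT_TOTAL_AREA = 60.0

#: Dirichlet concentration for replicate population jitter (population SDs
#: of a few percent, on the scale of real replicate error bars).
DEFAULT_DIRICHLET_CONC = 400.0

#: SD (cm-1) of the truncated-normal replicate jitter on sub-band centers.
DEFAULT_CENTER_JITTER_SD = 2.0


def default_grid(lo: float = 2000.0, hi: float = 2600.0, step: float = 1.0) -> np.ndarray:
    """Canonical 1 cm-1 wavenumber grid covering band + background anchor."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted populations/centers/widths, background, noise level and seed."""

    populations: dict[str, float]
    centers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CENTERS))
    fwhms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FWHMS))
    background: BackgroundModel = DEFAULT_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    total_area: float = DEFAULT_TOTAL_AREA

    def __post_init__(self):
        pops = self.populations
        unknown = set(pops) - set(CLASS_ORDER)
        if unknown:
            raise UsageError(f"unknown sub-band classes {sorted(unknown)}")
        if any(p < 0 for p in pops.values()):
            raise UsageError("populations must be >= 0")
        total = sum(pops.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise UsageError(f"populations must sum to 1, got {total}")
        for name, c in self.centers.items():
            if name in pops and pops[name] > 0:
                win = TAXONOMY[name].window
                if not win.lo <= c <= win.hi:
                    raise UsageError(f"{name} center {c} outside window ({win.lo}, {win.hi})")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SugarPreset:
    """Composition response of one sugar: two regime vectors and a switch."""

    name: str
    p_low: dict[str, float]
    p_high: dict[str, float]
    switch_sp: float = 110.0
    steepness: float = 3.0

    def __post_init__(self):
        for vec in (self.p_low, self.p_high):
            if any(v < 0 for v in vec.values()):
                raise UsageError("population vectors must be >= 0")
            if not math.isclose(sum(vec.values()), 1.0, abs_tol=1e-9):
                raise UsageError("population vectors must sum to 1")
        if self.switch_sp <= 0:
            raise UsageError("switch_sp must be > 0")


def _vec(**kw: float) -> dict[str, float]:
    v = {name: kw.get(name, 0.0) for name in CLASS_ORDER}
    s = sum(v.values())
    return {k: x / s for k, x in v.items()}


#: Qualitative per-sugar presets (this package's encodings of the study
#: design, not measured data). Trehalose converts smoothly, sucrose
#: abruptly with W2a dominant until high S/P, maltose/lactose are
#: intermediate with lactose switching W2a->W2b early, raffinose never
#: develops W2b. The labeled transition of the designs is S/P = 80; the
#: logistic midpoint sits between the 80 and 160 levels.
PRESETS: dict[str, SugarPreset] = {
    "trehalose": SugarPreset(
        "trehalose",
        p_low=_vec(W0a=0.10, W0b=0.15, W1=0.04, W2a=0.45, W2b=0.06, W3=0.10, W4=0.10),
        p_high=_vec(W0b=0.05, W1=0.14, W2a=0.15, W2b=0.28, W3=0.22, W4=0.16),
        steepness=1.5,
    ),
    "sucrose": SugarPreset(
        "sucrose",
        p_low=_vec(W0a=0.08, W0b=0.14, W1=0.04, W2a=0.55, W2b=0.0, W3=0.07, W4=0.12),
        p_high=_vec(W0b=0.05, W1=0.16, W2a=0.25, W2b=0.33, W3=0.06, W4=0.15),
        steepness=6.0,
    ),
    "maltose": SugarPreset(
        "maltose",
        p_low=_vec(W0a=0.09, W0b=0.14, W1=0.03, W2a=0.40, W2b=0.13, W3=0.11, W4=0.10),
        p_high=_vec(W0b=0.05, W1=0.12, W2a=0.17, W2b=0.27, W3=0.22, W4=0.17),
        steepness=2.5,
    ),
    "lactose": SugarPreset(
        "lactose",
        p_low=_vec(W0a=0.09, W0b=0.14, W1=0.03, W2a=0.30, W2b=0.23, W3=0.11, W4=0.10),
        p_high=_vec(W0b=0.05, W1=0.13, W2a=0.12, W2b=0.32, W3=0.21, W4=0.17),
        steepness=3.0,
    ),
    "raffinose": SugarPreset(
        "raffinose",
        p_low=_vec(W0a=0.08, W0b=0.14, W1=0.05, W2a=0.50, W2b=0.0, W3=0.11, W4=0.12),
        p_high=_vec(W0b=0.06, W1=0.16, W2a=0.40, W2b=0.0, W3=0.20, W4=0.18),
        steepness=4.0,
    ),
}


# ---------------------------------------------------------------------------
# operations


def population_model(sp_ratio: float, preset: SugarPreset) -> dict[str, float]:
    """Logistic blend of the two regime population vectors at a given S/P.

    ``p(sp) = p_low + sigma(steepness * (log2 sp - log2 switch_sp)) *
    (p_high - p_low)``, renormalized to the simplex. The protein-free
    sentinel (inf) returns ``p_high`` with the protein-surface class W0a
    forced to 0.
    """
    if sp_ratio == PROTEIN_FREE:
        v = dict(preset.p_high)
        v["W0a"] = 0.0
        s = sum(v.values())
        return {k: x / s for k, x in v.items()}
    if not sp_ratio > 0:
        raise UsageError(f"sp_ratio must be > 0 or inf, got {sp_ratio}")
    t = preset.steepness * (math.log2(sp_ratio) - math.log2(preset.switch_sp))
    sig = 1.0 / (1.0 + math.exp(-t))
    v = {
        name: preset.p_low.get(name, 0.0)
        + sig * (preset.p_high.get(name, 0.0) - preset.p_low.get(name, 0.0))
        for name in CLASS_ORDER
    }
    s = sum(v.values())
    return {k: x / s for k, x in v.items()}


def clean_spectrum(truth: SyntheticTruth, grid: Sequence[float]) -> np.ndarray:
    """Noiseless forward model: sub-band Gaussians + background on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    y = truth.background.evaluate(grid)
    for name, pop in truth.populations.items():
        if pop <= 0:
            continue
        area = pop * truth.total_area
        fwhm = truth.fwhms[name]
        amp = area / (sigma_from_fwhm(fwhm) * math.sqrt(2 * math.pi))
        y = y + gaussian(grid, truth.centers[name], fwhm, amp)
    return y


def generate_spectrum(
    truth: SyntheticTruth,
    grid: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """One synthetic measurement: forward model + white noise.

    Noise SD is ``truth.noise_sd`` times the maximum of the noiseless
    spectrum. ``seed`` defaults to ``truth.seed``; passing the same seed
    reproduces the spectrum bit for bit.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 2000.0 or grid[-1] < 2600.0:
        raise UsageError(
            f"grid [{grid[0]}, {grid[-1]}] must cover (2000, 2600) cm-1 so that "
            "background fitting is exercisable"
        )
    y = clean_spectrum(truth, grid)
    if truth.noise_sd > 0:
        if isinstance(seed, np.random.Generator):
            rng = seed
        else:
            rng = np.random.default_rng(truth.seed if seed is None else seed)
        y = y + rng.normal(0.0, truth.noise_sd * float(np.max(y)), size=grid.size)
    return Spectrum(grid, y, meta or SampleMeta())


def _substream(seed: int, sugar: str, sp: float, replicate: int) -> np.random.Generator:
    """Stable per-(sugar, S/P, replicate) random substream.

    Keys are hashed with crc32 (stable across processes and platforms), so
    adding a sugar or S/P level to a design leaves other draws unchanged.
    """
    key = (
        zlib.crc32(sugar.encode()),
        zlib.crc32(repr(float(sp)).encode()),
        replicate,
    )
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass(frozen=True)
class StudyRecord:
    """One generated replicate: metadata, spectrum and its planted truth."""

    meta: SampleMeta
    spectrum: Spectrum
    truth: SyntheticTruth


@dataclass(frozen=True)
class Study:
    """A full synthetic study: all replicate records, design-ordered."""

    records: tuple[StudyRecord, ...]

    def by_sample(self) -> dict[str, list[StudyRecord]]:
        out: dict[str, list[StudyRecord]] = {}
        for r in self.records:
            out.setdefault(r.meta.sample_id, []).append(r)
        return out


def _jitter_populations(
    p: Mapping[str, float], conc: float | None, rng: np.random.Generator
) -> dict[str, float]:
    if conc is None:
        return dict(p)
    names = [n for n, v in p.items() if v > 0]
    alpha = np.array([conc * p[n] for n in names])
    draw = rng.dirichlet(alpha)
    out = {n: 0.0 for n in p}
    out.update({n: float(d) for n, d in zip(names, draw)})
    return out


def _jitter_centers(
    centers: Mapping[str, float], sd: float, rng: np.random.Generator
) -> dict[str, float]:
    if sd <= 0:
        return dict(centers)
    out = {}
    for name, c in centers.items():
        win = TAXONOMY[name].window
        out[name] = float(np.clip(c + rng.normal(0.0, sd), win.lo, win.hi))
    return out


def generate_study(
    presets: Mapping[str, SugarPreset] | None = None,
    design: Sequence[float] = (20, 40, 80, 160, 320, 640),
    replicates: int = 4,
    seed: int = 0,
    out_dir: str | Path | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    dirichlet_conc: float | None = DEFAULT_DIRICHLET_CONC,
    center_jitter_sd: float = DEFAULT_CENTER_JITTER_SD,
    grid: Sequence[float] | None = None,
) -> Study:
    """Generate a whole study: (sugar x S/P x replicate) spectra with truth.

    Replicate-level populations are Dirichlet perturbations (concentration
    ``dirichlet_conc``; None disables jitter) of the preset's
    :func:`population_model` output; centers get truncated-normal jitter
    within their windows. 3-8 replicates per sample is the realistic range.
    If ``out_dir`` is given, spectra (CSV), a manifest and a truth table are
    written there.
    """
    if presets is None:
        presets = PRESETS
    design = list(design)
    if not design:
        raise UsageError("empty design")
    if not 1 <= replicates <= 64:
        raise UsageError(f"implausible replicate count {replicates}")
    if grid is None:
        grid = default_grid()

    records: list[StudyRecord] = []
    for sugar, preset in presets.items():
        for sp in design:
            base = population_model(sp, preset)
            sp_tag = "inf" if math.isinf(sp) else f"{sp:g}"
            sample_id = f"{sugar}_sp{sp_tag}"
            for rep in range(1, replicates + 1):
                rng = _substream(seed, sugar, sp, rep)
                pops = _jitter_populations(base, dirichlet_conc, rng)
                centers = _jitter_centers(DEFAULT_CENTERS, center_jitter_sd, rng)
                truth = SyntheticTruth(
                    populations=pops,
                    centers=centers,
                    noise_sd=noise_sd,
                    seed=seed,
                )
                meta = SampleMeta(
                    sample_id=sample_id, sugar=sugar, sp_ratio=float(sp), replicate_index=rep
                )
                spectrum = generate_spectrum(truth, grid, seed=rng, meta=meta)
                records.append(StudyRecord(meta=meta, spectrum=spectrum, truth=truth))
    study = Study(records=tuple(records))
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: Study, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    truth_rows = []
    for r in study.records:
        fname = f"{r.meta.sample_id}_r{r.meta.replicate_index}.csv"
        write_spectrum(r.spectrum, out_dir / fname)
        entries.append((r.meta, fname))
        for name in CLASS_ORDER:
            if r.truth.populations.get(name, 0.0) > 0:
                truth_rows.append(
                    f"{r.meta.sample_id},{r.meta.replicate_index},{name},"
                    f"{r.truth.populations[name]!r},{r.truth.centers[name]!r},"
                    f"{r.truth.fwhms[name]!r}\n"
                )
    write_manifest(entries, out_dir / "manifest.csv")
    with (out_dir / "truth.csv").open("w") as fh:
        fh.write("sample_id,replicate,class,population,center,fwhm\n")
        fh.writelines(truth_rows)
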