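"""End-to-end pipeline: manifest -> decompositions -> summaries -> trends.

A :class:`RunConfig` gathers every tunable of the chain (regions, fit and
selection settings, trend thresholds, constants) and validates strictly on
load — unknown keys are rejected so that typos cannot silently fall back to
defaults. :func:`run_pipeline` is deterministic for fixed inputs and config
and writes a versioned report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy
import yaml

from wabkit import __version__
from wabkit.banddecomp import (
    Decomposition,
    FitConfig,
    ReplicateSummary,
    aggregate_replicates,
    select_minimal_model,
)
from wabkit.errors import UsageError, WabError
from wabkit.preprocess import (
    ANCHOR_REGION,
    STABILIZATION_TOL,
    TAIL_CENTER_BOUNDS,
    WAB_REGION,
    Region,
    extract_region,
    fit_background,
    normalize_area,
    subtract_background,
)
from wabkit.spectra_io import read_manifest, read_spectrum, write_decomposition_table
from wabkit.trends import (
    RHO_THRESHOLD,
    SEPARATION_RELIABILITY_THRESHOLD,
    trend_report,
)

log = logging.getLogger("wabkit")


@dataclass(frozen=True)
class RunConfig:
    """Validated, flat configuration for the whole pipeline."""

    wab_region: tuple[float, float] = (WAB_REGION.lo, WAB_REGION.hi)
    anchor_region: tuple[float, float] = (ANCHOR_REGION.lo, ANCHOR_REGION.hi)
    tail_center_bounds: tuple[float, float] = TAIL_CENTER_BOUNDS
    stabilization_tol: float = STABILIZATION_TOL
    fwhm_bounds: tuple[float, float] = (20.0, 200.0)
    selection_threshold: float = 10.0
    max_iterations: int = 2000
    tolerance: float = 1e-12
    init_fwhm: float = 60.0
    seed: int = 0
    multistart: int = 0
    rho_threshold: float = RHO_THRESHOLD
    separation_reliability_threshold: float = SEPARATION_RELIABILITY_THRESHOLD
    log_level: str = "INFO"

    def fit_config(self) -> FitConfig:
        return FitConfig(
            fwhm_bounds=tuple(self.fwhm_bounds),
            selection_threshold=self.selection_threshold,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            init_fwhm=self.init_fwhm,
            seed=self.seed,
            multistart=self.multistart,
        )

    @property
    def wab(self) -> Region:
        return Region(*self.wab_region)

    @property
    def anchor(self) -> Region:
        return Region(*self.anchor_region)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config_yaml() -> str:
    """The full default configuration as a YAML document."""
    return yaml.safe_dump(RunConfig().to_dict(), sort_keys=True)


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise UsageError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise UsageError(f"{path}: unknown config keys {sorted(unknown)}")
    for f in dataclasses.fields(RunConfig):
        if f.name in raw and isinstance(getattr(RunConfig(), f.name), tuple):
            raw[f.name] = tuple(raw[f.name])
    return RunConfig(**raw)


def decompose_spectrum(spectrum, config: RunConfig = RunConfig()) -> Decomposition:
    """Background-subtract, normalize and decompose one raw spectrum."""
    bg = fit_background(
        spectrum,
        wab_region=config.wab,
        anchor_region=config.anchor,
        tail_center_bounds=tuple(config.tail_center_bounds),
    )
    corrected = subtract_background(spectrum, bg)
    band = normalize_area(extract_region(corrected, config.wab), config.wab)
    return select_minimal_model(band, config.fit_config())


def run_pipeline(manifest_path, config: RunConfig, out_dir) -> dict:
    """Run the full analysis over a manifest and write a report bundle.

    Bundle contents: per-spectrum decomposition JSONs, a per-(sample, class)
    summary table, a per-sugar trend report, and a run log recording the
    config hash and library versions. Any stage failure aborts with the
    offending sample identified.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "decompositions").mkdir(exist_ok=True)

    entries = read_manifest(manifest_path)
    decomps_by_sample: dict[str, list[Decomposition]] = {}
    sample_info: dict[str, tuple[str, float]] = {}
    events = []
    for meta, path in entries:
        try:
            spectrum = read_spectrum(path, meta=meta)
            decomp = decompose_spectrum(spectrum, config)
        except WabError as exc:
            raise type(exc)(
                f"sample {meta.sample_id!r} replicate {meta.replicate_index}: {exc}"
            ) from exc
        fname = f"{meta.sample_id}_r{meta.replicate_index}.json"
        (out_dir / "decompositions" / fname).write_text(decomp.to_json())
        decomps_by_sample.setdefault(meta.sample_id, []).append(decomp)
        sample_info[meta.sample_id] = (meta.sugar, meta.sp_ratio)
        events.append(
            {
                "sample_id": meta.sample_id,
                "replicate": meta.replicate_index,
                "classes": list(decomp.class_names),
                "rss": decomp.rss,
                "bic": decomp.bic,
            }
        )
        log.debug("fit %s r%d: %s rss=%.3e bic=%.2f", meta.sample_id,
                  meta.replicate_index, ",".join(decomp.class_names), decomp.rss, decomp.bic)

    summaries: list[ReplicateSummary] = [
        aggregate_replicates(ds) for ds in decomps_by_sample.values()
    ]
    write_decomposition_table(summaries, out_dir / "summary.csv")

    # per-sugar trend reports over finite S/P samples
    trends: dict[str, dict] = {}
    by_sugar: dict[str, list[str]] = {}
    for sid, (sugar, _) in sample_info.items():
        by_sugar.setdefault(sugar, []).append(sid)
    for sugar, sids in by_sugar.items():
        pops: dict[str, dict[float, float]] = {}
        cents: dict[str, dict[float, tuple[float, float | None]]] = {}
        for sid in sids:
            sp = sample_info[sid][1]
            if not math.isfinite(sp):
                continue
            summary = next(s for s in summaries if s.sample_id == sid)
            for name, st in summary.classes.items():
                pops.setdefault(name, {})[sp] = st.mean_population
                if st.mean_center is not None:
                    cents.setdefault(name, {})[sp] = (st.mean_center, st.sd_center)
        usable = {n: p for n, p in pops.items() if len(p) >= 4}
        if usable:
            trends[sugar] = trend_report(usable, cents)
    (out_dir / "trends.json").write_text(json.dumps(trends, indent=2, sort_keys=True))

    run_log = {
        "wabkit_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_spectra": len(entries),
        "events": events,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return {"summaries": summaries, "trends": trends, "out_dir": str(out_dir)}
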