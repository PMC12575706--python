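"""End-to-end experiment runners: structure → spectra → band stats → color.

Each runner sweeps one structural parameter of the nacre model and returns
a tidy DataFrame (one row per condition) summarizing the resulting band and
color. The sweeps mirror the questions the physics raises:

* ``d1-scan`` — plate thickness sets the hue; thickness disorder broadens
  the band;
* ``d2-scan`` — gap width and gap index set band strength, white-noise
  baseline and hence saturation (the nanogap story);
* ``homogeneity-scan`` — depth drift of the lamination period broadens the
  band at matched mean period;
* ``order-scan`` — which Bragg order puts each shell's period in the
  visible;
* ``angle-scan`` — iridescence: the band blue-shifts with viewing angle.

Runners are deterministic for a given config seed; per-condition seeds are
spawned from it so conditions are statistically independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .colorimetry import peak_stats, spectrum_to_chromaticity
from .models import bragg_prediction, effective_index
from .structure import LayerStack, RefractiveModel, StackSpec, sample_stack
from .tmm import (
    DEFAULT_WAVELENGTHS,
    IncidenceGeometry,
    Spectrum,
    ensemble_reflectance,
    tmm_reflectance,
)

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "run_experiment",
    "run_d1_scan",
    "run_d2_scan",
    "run_homogeneity_scan",
    "run_order_scan",
    "run_angle_scan",
    "make_fixtures",
    "FIXTURE_SPECS",
]


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run.

    ``grids`` holds the experiment-specific sweep values (each runner
    documents its keys and supplies defaults); ``template`` is the base
    stack recipe the sweep perturbs.
    """

    experiment: str = "d1-scan"
    template: StackSpec = field(default_factory=StackSpec)
    grids: dict = field(default_factory=dict)
    reps: int = 100
    seed: int = 0
    wavelengths: Optional[np.ndarray] = None
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {sorted(EXPERIMENTS)}"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for k, v in self.grids.items():
            if hasattr(v, "__len__") and len(v) == 0:
                raise ValueError(f"empty grid {k!r}")

    @property
    def wl(self) -> np.ndarray:
        return DEFAULT_WAVELENGTHS if self.wavelengths is None else np.asarray(self.wavelengths)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        template = raw.pop("template", None)
        template = StackSpec.from_dict(template) if template else StackSpec()
        wl = raw.pop("wavelengths", None)
        return cls(template=template, wavelengths=None if wl is None else np.asarray(wl), **raw)


def _condition_seeds(seed: int, n: int) -> list:
    """Independent, reproducible per-condition seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _summarize(spectrum: Spectrum) -> dict:
    ps = peak_stats(spectrum)
    chrom = spectrum_to_chromaticity(spectrum)
    return {
        "lambda_max": np.nan if ps.lambda_max is None else ps.lambda_max,
        "fwhm": np.nan if ps.fwhm is None else ps.fwhm,
        "peak": ps.peak_reflectance,
        "baseline": ps.baseline,
        "x": chrom.x,
        "y": chrom.y,
        "saturation": chrom.saturation,
    }


def _write_outputs(df: pd.DataFrame, config: ExperimentConfig) -> None:
    if config.outdir is None:
        return
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{config.experiment}.csv", index=False)
    summary = {
        "experiment": config.experiment,
        "seed": config.seed,
        "reps": config.reps,
        "n_conditions": len(df),
    }
    with open(out / f"{config.experiment}.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run_d1_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Hue and broadening versus plate thickness.

    Grid keys: ``d1`` (default [137, 157, 194] nm) and the paired
    measured SDs ``d1_sd`` (default [18, 8, 15] nm). Each thickness is run
    both ordered (SD = 0, deterministic) and disordered (paired SD,
    ensemble of ``reps``). The gap is fixed at the template's d2 (4 nm air
    by default).
    """
    d1s = list(config.grids.get("d1", [137.0, 157.0, 194.0]))
    sds = list(config.grids.get("d1_sd", [18.0, 8.0, 15.0]))
    if len(sds) != len(d1s):
        raise ValueError("d1 and d1_sd grids must have equal length")
    seeds = _condition_seeds(config.seed, len(d1s))
    rows = []
    for d1, sd, cseed in zip(d1s, sds, seeds):
        for use_sd in (0.0, sd):
            spec = config.template.with_(d1_mean=d1, d1_sd=use_sd, seed=cseed)
            sp = ensemble_reflectance(spec, config.reps, config.wl)
            rows.append({"d1": d1, "d1_sd": use_sd, **_summarize(sp)})
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


def run_d2_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Band strength, white noise and saturation versus gap width/index.

    Grid keys: ``d2`` (default [1, 4, 11, 20] nm) × ``n2`` (default
    [1.0, 1.43]), plus scalar ``d1``/``d1_sd`` overrides fixing the
    disordered plate population (default 150 ± 15 nm).
    """
    d2s = list(config.grids.get("d2", [1.0, 4.0, 11.0, 20.0]))
    n2s = list(config.grids.get("n2", [1.0, 1.43]))
    tmpl = config.template.with_(
        d1_mean=float(config.grids.get("d1", 150.0)),
        d1_sd=float(config.grids.get("d1_sd", 15.0)),
    )
    conditions = [(n2, d2) for n2 in n2s for d2 in d2s]
    seeds = _condition_seeds(config.seed, len(conditions))
    rows = []
    for (n2, d2), cseed in zip(conditions, seeds):
        refr = RefractiveModel(
            n1=tmpl.refr.n1, n2=n2,
            n_ambient=tmpl.refr.n_ambient, n_substrate=tmpl.refr.n_substrate,
        )
        spec = tmpl.with_(d2_mean=d2, refr=refr, seed=cseed)
        sp = ensemble_reflectance(spec, config.reps, config.wl)
        rows.append({"n2": n2, "d2": d2, **_summarize(sp)})
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


def run_homogeneity_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Band width versus depth drift of the lamination period.

    Grid key: ``drift_rate`` (nm of period drift per period, default
    [0.0, 0.05, 0.1]). Stacks are ordered (zero SD) and centered so every
    drift rate has the same *mean* period — isolating inhomogeneity from a
    hue change. Rate 0 is the constant profile.
    """
    rates = list(config.grids.get("drift_rate", [0.0, 0.05, 0.1]))
    rows = []
    for rate in rates:
        # center the drift on the template mean: start lower by half the total drift
        start = config.template.d1_mean - 0.5 * rate * (config.template.n_periods - 1)
        profile = "constant" if rate == 0 else "linear_drift"
        spec = config.template.with_(
            d1_mean=start, d1_sd=0.0, d2_sd=0.0, profile=profile, drift_rate=rate
        )
        sp = tmm_reflectance(sample_stack(spec), config.wl)
        rows.append({"profile": profile, "drift_rate": rate, **_summarize(sp)})
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


def run_order_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Bragg order and peak wavelength across shell-like period scales.

    Grid key: ``cases`` — list of dicts with ``name, d1, d2, n2``; defaults
    cover the blue/green/red Ammolite plates with 4 nm air gaps (m = 1 in
    the visible) and blue/green abalone plates with 11 nm organic gaps
    (visible only at m = 2). Cross-checks each Bragg prediction against the
    solved peak of the ordered stack.
    """
    cases = config.grids.get("cases", [
        {"name": "ammolite_blue", "d1": 140.0, "d2": 4.0, "n2": 1.00},
        {"name": "ammolite_green", "d1": 160.0, "d2": 4.0, "n2": 1.00},
        {"name": "ammolite_red", "d1": 190.0, "d2": 4.0, "n2": 1.00},
        {"name": "abalone_blue", "d1": 250.0, "d2": 11.0, "n2": 1.43},
        {"name": "abalone_green", "d1": 300.0, "d2": 11.0, "n2": 1.43},
    ])
    rows = []
    for case in cases:
        n1 = case.get("n1", 1.63)
        pred = bragg_prediction(case["d1"], case["d2"], n1=n1, n2=case["n2"])
        spec = config.template.with_(
            d1_mean=case["d1"], d2_mean=case["d2"], d1_sd=0.0, d2_sd=0.0,
            profile="constant", drift_rate=0.0,
            refr=RefractiveModel(n1=n1, n2=case["n2"], n_substrate=n1),
        )
        sp = tmm_reflectance(sample_stack(spec), config.wl)
        ps = peak_stats(sp)
        rows.append({
            "name": case["name"], "d": pred.d, "n_eff": pred.n_eff, "m": pred.m,
            "lambda_bragg": pred.lambda_peak,
            "lambda_tmm": np.nan if ps.lambda_max is None else ps.lambda_max,
        })
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


def run_angle_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Iridescence: band position versus incidence angle.

    Grid key: ``theta`` (degrees, default [0, 15, 30, 45]). Uses the
    ordered template stack; reports the solved λ_max next to the
    Bragg-Snell prediction at each angle.
    """
    thetas = list(config.grids.get("theta", [0.0, 15.0, 30.0, 45.0]))
    spec = config.template.with_(d1_sd=0.0, d2_sd=0.0)
    stack = sample_stack(spec)
    n_eff = effective_index(spec.d1_mean, spec.d2_mean, spec.refr.n1, spec.refr.n2)
    rows = []
    for th in thetas:
        sp = tmm_reflectance(stack, config.wl, IncidenceGeometry(theta=th))
        ps = peak_stats(sp)
        pred = bragg_prediction(
            spec.d1_mean, spec.d2_mean, n1=spec.refr.n1, n2=spec.refr.n2, theta=th
        )
        rows.append({
            "theta": th,
            "lambda_max": np.nan if ps.lambda_max is None else ps.lambda_max,
            "lambda_bragg": pred.lambda_peak,
            "fwhm": np.nan if ps.fwhm is None else ps.fwhm,
        })
    df = pd.DataFrame(rows)
    _write_outputs(df, config)
    return df


EXPERIMENTS = {
    "d1-scan": run_d1_scan,
    "d2-scan": run_d2_scan,
    "homogeneity-scan": run_homogeneity_scan,
    "order-scan": run_order_scan,
    "angle-scan": run_angle_scan,
}


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch a config to its runner."""
    return EXPERIMENTS[config.experiment](config)


# Canonical stack recipes with the measured structural parameters.
# Nautilus plate thickness is not reported; 300 nm is a synthetic stand-in
# consistent with the thick-plate/large-organic-gap character of its nacre.
FIXTURE_SPECS = {
    "ammolite_blue": dict(d1_mean=140.0, d1_sd=18.0, d2_mean=4.0, d2_sd=2.0,
                          refr=RefractiveModel(n2=1.00)),
    "ammolite_green": dict(d1_mean=160.0, d1_sd=8.0, d2_mean=4.0, d2_sd=2.0,
                           refr=RefractiveModel(n2=1.00)),
    "ammolite_red": dict(d1_mean=190.0, d1_sd=15.0, d2_mean=4.0, d2_sd=2.0,
                         refr=RefractiveModel(n2=1.00)),
    "abalone_blue": dict(d1_mean=250.0, d1_sd=15.0, d2_mean=11.0, d2_sd=3.0,
                         refr=RefractiveModel(n2=1.43)),
    "abalone_green": dict(d1_mean=300.0, d1_sd=15.0, d2_mean=11.0, d2_sd=3.0,
                          refr=RefractiveModel(n2=1.43)),
    "nautilus_like_synthetic": dict(d1_mean=300.0, d1_sd=15.0, d2_mean=20.0, d2_sd=3.0,
                                    refr=RefractiveModel(n2=1.43)),
    "madagascar_like": dict(d1_mean=160.0, d1_sd=15.0, d2_mean=1.0, d2_sd=1.0,
                            profile="linear_drift", drift_rate=0.1,
                            refr=RefractiveModel(n2=1.00)),
}


def make_fixtures(outdir, seed: int = 0) -> list:
    """Write the canonical StackSpec YAMLs plus small ordered spectra.

    One YAML per recipe in :data:`FIXTURE_SPECS` (with a per-fixture seed
    derived from ``seed``) and, for each, the deterministic (zero-SD)
    reflectance spectrum as CSV. Byte-reproducible for a fixed seed.
    Returns the list of written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    names = sorted(FIXTURE_SPECS)
    seeds = _condition_seeds(seed, len(names))
    written = []
    for name, cseed in zip(names, seeds):
        spec = StackSpec(seed=cseed, **FIXTURE_SPECS[name])
        ypath = out / f"{name}.yaml"
        spec.to_yaml(ypath)
        written.append(ypath)
        ordered = spec.with_(d1_sd=0.0, d2_sd=0.0, profile="constant", drift_rate=0.0)
        sp = tmm_reflectance(sample_stack(ordered), DEFAULT_WAVELENGTHS)
        cpath = out / f"{name}_ordered_spectrum.csv"
        sp.to_csv(cpath)
        written.append(cpath)
    return written
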