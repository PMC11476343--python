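"""End-to-end orchestration and the photochemical-assay analysis.

``run_pipeline`` drives simulate -> analyze -> report for any subset of the
experiments (steady-state FLIM, distribution deconvolution, assembly
kinetics, FRAP, AFM, density, photochemical assay) from one serializable
configuration, writing a versioned machine-readable results JSON.  A run is
fully reproducible from its config plus seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import afm, density, flim, frap, kinetics, synthetic

__all__ = ["AssaySeries", "RunConfig", "assay_analyze", "run_pipeline"]

RESULTS_SCHEMA_VERSION = 1
log = logging.getLogger("memquant")


@dataclass
class AssaySeries:
    """Ordered photochemical-assay conditions, each with >= 1 field of view.

    ``conditions`` is a list of ``(label, fields)`` where each field is
    ``(mean_intensity, DecayHistogram)``.  The first condition is the
    pre-treatment baseline that intensities are normalized to.
    """

    conditions: list
    channel: str = "Chl"

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("at least one condition required")
        for label, fields in self.conditions:
            if len(fields) < 1:
                raise ValueError(f"condition {label!r} has no fields of view")

    @property
    def labels(self):
        return [label for label, _ in self.conditions]


def assay_analyze(series: AssaySeries, baseline: str | None = None
                  ) -> dict:
    """Per-condition normalized intensity (%) and mean lifetime table.

    Intensities are normalized per field of view to the baseline condition's
    mean, then averaged across fields of view with their standard deviation;
    lifetimes come from multi-exponential decay fits per field of view.  A
    single field of view reports NaN (undefined) standard deviations.
    """
    labels = series.labels
    if baseline is None:
        baseline = labels[0]
    if baseline not in labels:
        raise ValueError(f"baseline condition {baseline!r} missing")
    base_fields = dict(series.conditions)[baseline]
    base_mean = float(np.mean([i for i, _ in base_fields]))
    table = {}
    for label, fields in series.conditions:
        intensities = np.array([i for i, _ in fields], dtype=float)
        norm = 100.0 * intensities / base_mean
        taus = []
        for _, hist in fields:
            fit = flim.fit_decay(hist, n_components="auto")
            taus.append(fit.mean_lifetime_ns)
        taus = np.array(taus)
        n = len(fields)
        table[label] = {
            "intensity_percent": float(norm.mean()),
            "intensity_percent_sd": float(norm.std(ddof=1)) if n > 1
            else float("nan"),
            "mean_lifetime_ns": float(taus.mean()),
            "mean_lifetime_ns_sd": float(taus.std(ddof=1)) if n > 1
            else float("nan"),
            "n_fields_of_view": n,
        }
    return table


@dataclass
class RunConfig:
    """Serializable run configuration: seed, output paths, stage toggles."""

    seed: int = 0
    out_dir: str = "memquant_results"
    stages: tuple = ("flim", "distribution", "assembly", "frap", "afm",
                     "density", "assay")
    n_photons_flim: int = 10 ** 6
    n_pixels_distribution: int = 10 ** 4
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        missing = [k for k in ("seed",) if k not in data]
        if missing:
            raise ValueError(f"config missing required block(s): {missing}")
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _stage_flim(rng, cfg):
    out = {}
    for name, model in (("thylakoid", synthetic.thylakoid_model()),
                        ("hybrid", synthetic.hybrid_model())):
        hist = synthetic.simulate_decay(
            model, cfg.n_photons_flim,
            rng_seed=int(rng.integers(2 ** 31)))
        fit = flim.fit_decay(hist, n_components="auto")
        out[name] = {
            "mean_lifetime_ns": {"value": round(fit.mean_lifetime_ns, 2),
                                 "units": "ns"},
            "generative_mean_lifetime_ns": {
                "value": model.mean_lifetime_ns, "units": "ns"},
            "chi_squared_reduced": fit.chi_squared_reduced,
            "n_components": fit.n_components,
        }
    return out


def _stage_distribution(rng, cfg):
    n = cfg.n_pixels_distribution
    c1, f1 = synthetic.THYLAKOID_POPULATION
    c2, f2 = synthetic.HYBRID_POPULATION
    s = flim.FWHM_TO_SIGMA
    taus = np.concatenate([rng.normal(c1, f1 * s, n // 2),
                           rng.normal(c2, f2 * s, n - n // 2)])
    taus = taus[taus > 0]
    w = 0.025
    edges = np.arange(0.0, taus.max() + w, w)
    freq, edges = np.histogram(taus, bins=edges)
    dist = flim.LifetimeDistribution(0.5 * (edges[:-1] + edges[1:]),
                                     freq.astype(float))
    comps, r2 = flim.fit_gaussians(dist, n=2)
    return {
        "short": {"center_ns": {"value": comps[0].center_ns, "units": "ns"},
                  "fwhm_ns": {"value": comps[0].fwhm_ns, "units": "ns"}},
        "long": {"center_ns": {"value": comps[1].center_ns, "units": "ns"},
                 "fwhm_ns": {"value": comps[1].fwhm_ns, "units": "ns"}},
        "r_squared": r2,
    }


def _stage_assembly(rng, cfg):
    out = {}
    for name, rate in (("lipid", 0.039), ("protein", 0.007)):
        t = np.arange(0.0, 1000.0 + 1e-9, 20.0)
        track = kinetics.AmplitudeTrack(
            label="lipid_dye" if name == "lipid" else "hybrid_long_tau",
            t_s=t, amplitude=1.0 - np.exp(-rate * t))
        fit = kinetics.fit_langmuir(track)
        out[name] = {
            "rate_per_s": {"value": fit.rate_per_s, "units": "s^-1"},
            "generative_rate_per_s": {"value": rate, "units": "s^-1"},
            "t_sat_s": {"value": round(fit.t_sat_s, -1), "units": "s"},
        }
    ratio, _ = (out["lipid"]["rate_per_s"]["value"]
                / out["protein"]["rate_per_s"]["value"], None)
    out["rate_ratio_lipid_over_protein"] = {"value": ratio, "units": "1"}
    return out


def _stage_frap(rng, cfg):
    out = {}
    for name, mf in (("protein", 0.77), ("lipid", 0.97)):
        series, _ = synthetic.simulate_frap_series(
            mobile_fraction=mf, recovery_halftime_s=20.0,
            reference_bleach_rate=-np.log(0.99) / 4.0, n_frames=50,
            frame_interval_s=4.0, noise_sd=0.02,
            rng_seed=int(rng.integers(2 ** 31)))
        result = frap.fit_recovery(series)
        out[name] = {
            "mobile_fraction_percent": {
                "value": 100.0 * result.mobile_fraction, "units": "%"},
            "generative_percent": {"value": 100.0 * mf, "units": "%"},
            "recovery_halftime_s": {"value": result.recovery_halftime_s,
                                    "units": "s"},
        }
    return out


def _stage_afm(rng, cfg):
    # empty-template step
    topo, _ = synthetic.simulate_topograph(
        shape=(400, 800), pixel_size_nm=5.0, template="left-half",
        mesa_height_nm=4.81, roughness_rms_nm=0.1,
        tilt_nm_per_um=(0.05, 0.05), rng_seed=int(rng.integers(2 ** 31)))
    template = np.zeros((400, 800), dtype=bool)
    template[:, :400] = True
    leveled = afm.level(topo, order=1, exclusion_mask=template)
    step = afm.step_height(leveled, lower_mask=~template & _inner(template),
                           upper_mask=template & _inner(template))
    # pores
    ptopo, ptruth = synthetic.simulate_topograph(
        shape=(1000, 1000), pixel_size_nm=2.0, membrane_height_nm=4.62,
        n_pores=12, pore_depth_nm=4.45, pore_diameter_nm=100.0,
        roughness_rms_nm=0.15, rng_seed=int(rng.integers(2 ** 31)))
    pleveled = afm.level(ptopo, order=1)
    pores = afm.detect_pores(pleveled)
    # particles
    ttopo, ttruth = synthetic.simulate_topograph(
        shape=(500, 500), pixel_size_nm=2.0, membrane_height_nm=0.0,
        n_particles=77, roughness_rms_nm=0.15,
        rng_seed=int(rng.integers(2 ** 31)))
    tleveled = afm.level(ttopo, order=1,
                         exclusion_mask=ttopo.heights_nm > 1.0)
    particles = afm.detect_particles(tleveled)
    return {
        "template_step_nm": {"value": round(step.step_height_nm, 2),
                             "units": "nm"},
        "pore_mean_depth_nm": {"value": round(pores.mean_depth_nm, 2),
                               "units": "nm"},
        "pore_count": {"value": len(pores), "units": "1",
                       "planted": len(ptruth.pores)},
        "particle_density_per_um2": {
            "value": round(particles.density_per_um2, 1), "units": "um^-2",
            "planted": len(ttruth.particles)},
    }


def _inner(mask, border=5):
    m = np.ones_like(mask, dtype=bool)
    m[:border] = m[-border:] = False
    m[:, :border] = m[:, -border:] = False
    return m


def _stage_density(rng, cfg):
    est = density.estimate_from_config(density.default_config())
    recon = density.reconcile_with_afm((84.0, 451.0), 60.0, 0.8)
    return {
        "lhcii_equivalents_per_corral": {
            "value": round(est.lhcii_equivalents.value),
            "sigma": round(est.lhcii_equivalents.sigma), "units": "1"},
        "density_per_um2": {"value": round(est.density_per_um2.value),
                            "units": "um^-2"},
        "area_fraction_percent": {
            "value": round(est.area_fraction_percent.value, 2),
            "units": "%"},
        "afm_reconciliation": recon,
    }


def _stage_assay(rng, cfg):
    raw = synthetic.simulate_assay_series(
        rng_seed=int(rng.integers(2 ** 31)))
    table = assay_analyze(AssaySeries(conditions=raw))
    return {label: {
        "intensity_percent": {"value": round(row["intensity_percent"], 1),
                              "units": "%"},
        "mean_lifetime_ns": {"value": round(row["mean_lifetime_ns"], 2),
                             "units": "ns"},
    } for label, row in table.items()}


_STAGES = {
    "flim": _stage_flim,
    "distribution": _stage_distribution,
    "assembly": _stage_assembly,
    "frap": _stage_frap,
    "afm": _stage_afm,
    "density": _stage_density,
    "assay": _stage_assay,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the results bundle.

    Deterministic under a fixed seed; any stage failure aborts with the
    stage name in the exception.  Returns the results dict (also written to
    ``<out_dir>/results.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
    results = {"schema_version": RESULTS_SCHEMA_VERSION,
               "seed": config.seed, "stages": {}}
    # one child seed stream per stage keeps stages independent of ordering
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child)
               for name, child in zip(_STAGES, root.spawn(len(_STAGES)))}
    for name in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            results["stages"][name] = _STAGES[name](streams[name], config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc
        log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 sort_keys=True))
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2,
                                                default=list))
    summary = [f"memquant pipeline (seed {config.seed})"]
    for name, res in results["stages"].items():
        summary.append(f"  [{name}] {json.dumps(res, sort_keys=True)[:200]}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return results
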