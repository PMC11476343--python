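"""Protein-density estimation in "LHCII equivalents" from FLIM intensities.

A calibration standard of LHCII proteoliposomes with a known protein load
anchors a three-stage chain:

1. counts per proteoliposome (from FLIM of the standard),
2. LHCII trimers per proteoliposome (from the lipid/protein ratio and the
   molecular packing), giving counts per LHCII trimer,
3. LHCII equivalents per corral = (corral counts / counts per LHCII)
   scaled by the lifetime ratio tau_standard / tau_hybrid.

The lifetime ratio is a quantum-yield proxy correcting for quenching: the
densely packed standard is quenched and under-emits per protein, so equal
acquisition parameters are mandatory (enforced) and the correction rescales
counts to equal emissive state.  Densities follow from the corral area;
the membrane area fraction from the per-trimer footprint.  Uncertainties
propagate to first order (root-sum-square of relative uncertainties through
the product/quotient chain).

Default configuration values for the calibration stages are synthetic
placeholders, back-calibrated so the chain reproduces the published
best-estimate outputs (57 100 equivalents per 400 um^2 corral, 143 um^-2,
0.72% area); drop in measured values where available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Uncertain",
    "CalibrationStandard",
    "DensityEstimate",
    "counts_per_lhcii",
    "lhcii_equivalents",
    "reconcile_with_afm",
    "default_config",
    "load_config",
]

DEFAULT_CORRAL_AREA_UM2 = 400.0  # 20 x 20 um corral
# chlorophylls per LHCII equivalent, inferred from 3 080 000 / 57 100 = 53.9
DEFAULT_CHL_PER_LHCII = 54.0
# footprint per LHCII trimer, back-computed from the 143 um^-2 <-> 0.72% pair
DEFAULT_FOOTPRINT_NM2 = 50.3


@dataclass(frozen=True)
class Uncertain:
    """A positive scalar with a 1-sigma uncertainty (first-order algebra)."""

    value: float
    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def rel(self) -> float:
        return self.sigma / self.value if self.value != 0 else float("inf")

    def __mul__(self, other):
        other = _as_uncertain(other)
        v = self.value * other.value
        return Uncertain(v, abs(v) * np.hypot(self.rel, other.rel))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_uncertain(other)
        if other.value == 0:
            raise ZeroDivisionError("division by zero-valued quantity")
        v = self.value / other.value
        return Uncertain(v, abs(v) * np.hypot(self.rel, other.rel))

    def __iter__(self):
        return iter((self.value, self.sigma))


def _as_uncertain(x) -> Uncertain:
    if isinstance(x, Uncertain):
        return x
    if np.iterable(x):
        v, s = x
        return Uncertain(float(v), float(s))
    return Uncertain(float(x), 0.0)


@dataclass
class CalibrationStandard:
    """LHCII-proteoliposome calibration values (stages 1-2 inputs)."""

    counts_per_proteoliposome: Uncertain
    lhcii_per_proteoliposome: Uncertain
    standard_mean_lifetime_ns: Uncertain
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts_per_proteoliposome = _as_uncertain(
            self.counts_per_proteoliposome)
        self.lhcii_per_proteoliposome = _as_uncertain(
            self.lhcii_per_proteoliposome)
        self.standard_mean_lifetime_ns = _as_uncertain(
            self.standard_mean_lifetime_ns)
        for q in (self.counts_per_proteoliposome,
                  self.lhcii_per_proteoliposome,
                  self.standard_mean_lifetime_ns):
            if q.value <= 0:
                raise ValueError("calibration values must be positive")


@dataclass
class DensityEstimate:
    """Stage-3 outputs with propagated uncertainty and the assumption record."""

    lhcii_equivalents: Uncertain
    chlorophylls: float
    density_per_um2: Uncertain
    area_fraction_percent: Uncertain
    assumptions: dict

    def to_json(self, path=None):
        obj = {
            "lhcii_equivalents": {"value": self.lhcii_equivalents.value,
                                  "sigma": self.lhcii_equivalents.sigma},
            "chlorophylls": self.chlorophylls,
            "density_per_um2": {"value": self.density_per_um2.value,
                                "sigma": self.density_per_um2.sigma},
            "area_fraction_percent": {
                "value": self.area_fraction_percent.value,
                "sigma": self.area_fraction_percent.sigma},
            "assumptions": self.assumptions,
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj


def counts_per_lhcii(standard: CalibrationStandard) -> Uncertain:
    """Photon counts per LHCII trimer in the standard (stages 1/2 ratio)."""
    return (standard.counts_per_proteoliposome
            / standard.lhcii_per_proteoliposome)


def lhcii_equivalents(corral_counts, standard: CalibrationStandard,
                      hybrid_mean_lifetime_ns,
                      corral_area_um2: float = DEFAULT_CORRAL_AREA_UM2,
                      chl_per_lhcii: float = DEFAULT_CHL_PER_LHCII,
                      footprint_nm2: float = DEFAULT_FOOTPRINT_NM2,
                      acquisition: dict | None = None) -> DensityEstimate:
    """Stage-3 conversion of corral photon counts into protein density.

    equivalents = (corral_counts / counts_per_lhcii)
                  * (tau_standard / tau_hybrid)

    The lifetime ratio corrects for the different quenching (emissive yield)
    of the standard vs the hybrid membrane.  ``acquisition`` metadata, when
    provided, must match the standard's exactly — intensity calibration is
    only valid at identical excitation/collection settings.
    """
    corral_counts = _as_uncertain(corral_counts)
    hybrid_tau = _as_uncertain(hybrid_mean_lifetime_ns)
    if corral_counts.value <= 0 or hybrid_tau.value <= 0:
        raise ValueError("counts and lifetimes must be positive")
    if acquisition is not None and standard.acquisition:
        if acquisition != standard.acquisition:
            raise ValueError(
                "acquisition parameters of corral and standard differ; "
                "intensity comparison is invalid")
    per_lhcii = counts_per_lhcii(standard)
    quench = standard.standard_mean_lifetime_ns / hybrid_tau
    equivalents = corral_counts / per_lhcii * quench
    density = equivalents / Uncertain(corral_area_um2)
    # area_fraction(%) = density(um^-2) * footprint(nm^2) * 1e-6 * 100
    area_fraction = density * Uncertain(footprint_nm2 * 1e-4)
    return DensityEstimate(
        lhcii_equivalents=equivalents,
        chlorophylls=equivalents.value * chl_per_lhcii,
        density_per_um2=density,
        area_fraction_percent=area_fraction,
        assumptions={
            "corral_area_um2": corral_area_um2,
            "chl_per_lhcii": chl_per_lhcii,
            "footprint_nm2_per_lhcii": footprint_nm2,
            "quenching_correction": "lifetime ratio tau_standard/tau_hybrid",
            "quenching_correction_factor": quench.value,
        })


def reconcile_with_afm(estimate_range_per_um2, afm_static_density_per_um2,
                       mobile_fraction: float) -> dict:
    """Compare the AFM static-particle density against the FLIM estimate.

    AFM sees only static particles; the mobile population is invisible to
    the slow raster scan, so the total is static / (1 - mobile_fraction).
    ``estimate_range_per_um2`` is the (low, high) FLIM density range.
    """
    if not 0.0 <= mobile_fraction < 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1)")
    total = afm_static_density_per_um2 / (1.0 - mobile_fraction)
    lo, hi = estimate_range_per_um2
    return {
        "afm_static_density_per_um2": float(afm_static_density_per_um2),
        "mobile_fraction": float(mobile_fraction),
        "afm_total_density_per_um2": float(total),
        "flim_range_per_um2": [float(lo), float(hi)],
        "inside_range": bool(lo <= total <= hi),
    }


def default_config() -> dict:
    """Calibration config reproducing the published best-estimate chain.

    The stage-1/2 values are synthetic placeholders (the real supplementary
    calibration table is not shipped here); they are internally consistent
    and back-calibrated so the chain outputs 57 100 equivalents per corral.
    """
    return {
        "counts_per_proteoliposome": [48000.0, 2400.0],
        "lhcii_per_proteoliposome": [1000.0, 50.0],
        "standard_mean_lifetime_ns": [0.9, 0.04],
        "hybrid_mean_lifetime_ns": [4.06, 0.11],
        "corral_counts": [12364309.0, 500000.0],
        "corral_area_um2": DEFAULT_CORRAL_AREA_UM2,
        "chl_per_lhcii": DEFAULT_CHL_PER_LHCII,
        "footprint_nm2": DEFAULT_FOOTPRINT_NM2,
    }


def load_config(path) -> dict:
    """Read a YAML/JSON key-value calibration config."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def estimate_from_config(config: dict) -> DensityEstimate:
    """Run the full chain from a config mapping (see ``default_config``)."""
    standard = CalibrationStandard(
        counts_per_proteoliposome=config["counts_per_proteoliposome"],
        lhcii_per_proteoliposome=config["lhcii_per_proteoliposome"],
        standard_mean_lifetime_ns=config["standard_mean_lifetime_ns"],
    )
    return lhcii_equivalents(
        corral_counts=config["corral_counts"],
        standard=standard,
        hybrid_mean_lifetime_ns=config["hybrid_mean_lifetime_ns"],
        corral_area_um2=config.get("corral_area_um2",
                                   DEFAULT_CORRAL_AREA_UM2),
        chl_per_lhcii=config.get("chl_per_lhcii", DEFAULT_CHL_PER_LHCII),
        footprint_nm2=config.get("footprint_nm2", DEFAULT_FOOTPRINT_NM2),
    )
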