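"""Synthetic thorax phantoms and case-level cohorts with known ground truth.

Two generators make the whole pipeline testable without scan data:

* :func:`generate_thorax_phantom` rasterises a soft-tissue body ellipsoid
  containing two lung ellipsoids whose voxels are drawn from a configurable
  Gaussian mixture (a low-attenuation mode plus a parenchymal mode), an
  optional walled airway (tracheal stem plus two bronchial branches carved at
  -1000 HU), an optional ventro-dorsal density gradient emulating hypostasis,
  and global Gaussian noise.  The true lung-parenchyma and airway-lumen masks
  are returned alongside the volume, and the lung HU distribution has a
  closed form, so densitometry and segmentation can be checked analytically.

* :func:`generate_cohort_measurements` draws per-case densitometry endpoints
  and demographics from group-specific distributions calibrated to a
  published two-group comparison (20 asphyxia vs 21 control cases): LAA
  endpoints are log-normal with the group median matched exactly and the
  spread set from the upper quartile, Perc15 is normal from median and IQR
  width, and demographics are truncated normals from the printed group
  means/SDs.  Within a case the endpoints are drawn comonotonically (high
  LAA with low Perc15), which both reflects their physical coupling and
  enforces LAA(-910) >= LAA(-950).

Both generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .cohort import CaseRecord
from .densitometry import DensitometryResult
from .io_ct import CTVolume, MaskVolume, LungDensError, ParameterError

log = logging.getLogger(__name__)


class PhantomSpecError(LungDensError):
    pass


# ---------------------------------------------------------------------------
# Gaussian-mixture oracles
# ---------------------------------------------------------------------------

def _check_mixture(mixture):
    w = np.array([c[0] for c in mixture], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError("mixture weights must be non-negative and sum to 1")


def mixture_mean(mixture) -> float:
    _check_mixture(mixture)
    return float(sum(w * mu for w, mu, _ in mixture))


def mixture_cdf(mixture, x: float) -> float:
    _check_mixture(mixture)
    total = 0.0
    for w, mu, sd in mixture:
        if sd == 0:
            total += w * (1.0 if mu <= x else 0.0)
        else:
            total += w * norm.cdf((x - mu) / sd)
    return total


def analytic_mixture_laa(mixture, cutoff: float) -> float:
    """Expected LAA (percent) of a Gaussian mixture at *cutoff*.

    A degenerate component (sd = 0) contributes all of its weight when its
    mean lies strictly below the cutoff and nothing otherwise.
    """
    _check_mixture(mixture)
    total = 0.0
    for w, mu, sd in mixture:
        if sd == 0:
            total += w * (100.0 if mu < cutoff else 0.0)
        else:
            total += w * 100.0 * norm.cdf((cutoff - mu) / sd)
    return total


def analytic_mixture_percentile(mixture, fraction: float) -> float:
    """The unique HU value q with mixture CDF(q) = fraction (bracketed root)."""
    _check_mixture(mixture)
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    if all(sd == 0 for _, _, sd in mixture):
        raise ParameterError("percentile oracle needs at least one non-degenerate component")
    lo = min(mu - 10 * max(sd, 1.0) for _, mu, sd in mixture)
    hi = max(mu + 10 * max(sd, 1.0) for _, mu, sd in mixture)
    return brentq(lambda q: mixture_cdf(mixture, q) - fraction, lo, hi, xtol=1e-6)


def convolve_noise(mixture, noise_sd: float):
    """The lung HU mixture after independent Gaussian noise is added."""
    return [(w, mu, float(np.hypot(sd, noise_sd))) for w, mu, sd in mixture]


# ---------------------------------------------------------------------------
# voxel phantom
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    center: tuple[float, float, float]   # mm, grid coordinates
    semi_axes: tuple[float, float, float]  # mm


@dataclass
class AirwaySpec:
    """Tracheal stem plus two bronchial branches, lumen carved at -1000 HU."""
    radius: float = 5.0        # lumen radius, mm
    wall_thickness: float = 2.5  # soft-tissue wall around the lumen, mm
    lumen_hu: float = -1000.0
    stem_above_lungs: float = 15.0  # how far the stem rises above the lung apex, mm


@dataclass
class PhantomSpec:
    """Parametric synthetic thorax with analytic ground truth.

    Defaults give a 128 mm³-cube thorax at 1 mm isotropic spacing (slice
    thickness matching thin-slice densitometry protocols) whose lung voxels
    follow ``0.2 N(-980, 15) + 0.8 N(-850, 60)`` — a low-attenuation mode on
    top of a parenchymal mode.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body: Ellipsoid | None = None          # default: centred, near-filling
    body_hu: float = 40.0
    lungs: tuple[Ellipsoid, Ellipsoid] | None = None
    lung_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.2, -980.0, 15.0), (0.8, -850.0, 60.0)])
    gradient_slope: float = 0.0            # HU per mm along ventro-dorsal (y) axis
    airway: AirwaySpec | None = field(default_factory=AirwaySpec)
    noise_sd: float = 5.0                  # HU, added everywhere
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self):
        _check_mixture(self.lung_mixture)
        ext = tuple(n * s for n, s in zip(self.dims, self.spacing))
        if self.body is None:
            self.body = Ellipsoid(tuple(e / 2 for e in ext),
                                  tuple(e / 2 - 2 * s for e, s in zip(ext, self.spacing)))
        if self.lungs is None:
            cx, cy, cz = self.body.center
            a, b, c = self.body.semi_axes
            semi = (0.40 * a, 0.58 * b, 0.72 * c)
            off = 0.46 * a
            self.lungs = (Ellipsoid((cx - off, cy, cz), semi),
                          Ellipsoid((cx + off, cy, cz), semi))

    def effective_lung_mixture(self):
        """Lung HU mixture including acquisition noise (gradient must be off)."""
        return convolve_noise(self.lung_mixture, self.noise_sd)


def _ellipsoid_mask(coords, e: Ellipsoid) -> np.ndarray:
    X, Y, Z = coords
    cx, cy, cz = e.center
    a, b, c = e.semi_axes
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def generate_thorax_phantom(spec: PhantomSpec):
    """Rasterise a phantom; returns ``(CTVolume, lung MaskVolume, airway MaskVolume)``.

    The lung mask marks parenchyma only (airway wall and lumen excluded); the
    airway mask marks the full lumen including the extrapulmonary stem.
    Identical specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    dx, dy, dz = spec.spacing
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = (X, Y, Z)

    body = _ellipsoid_mask(coords, spec.body)
    lung_rasters = [_ellipsoid_mask(coords, lg) for lg in spec.lungs]
    lungs = lung_rasters[0] | lung_rasters[1]
    # require a watertight soft-tissue shell: lungs must stay inside the body
    # with at least a two-voxel margin, or the cavity opens to outside air
    margin = 2.0 * max(spec.spacing)
    if min(spec.body.semi_axes) <= margin:
        raise PhantomSpecError("body ellipsoid too small for a tissue shell")
    shrunk = Ellipsoid(spec.body.center,
                       tuple(s - margin for s in spec.body.semi_axes))
    if np.any(lungs & ~_ellipsoid_mask(coords, shrunk)):
        raise PhantomSpecError(
            "lung ellipsoids reach the body surface (no soft-tissue shell)")

    vol = np.full(spec.dims, spec.background_hu, dtype=np.float64)
    vol[body] = spec.body_hu

    # lung voxels: categorical component choice, then the component normal
    n_lung = int(lungs.sum())
    weights = np.array([c[0] for c in spec.lung_mixture])
    mus = np.array([c[1] for c in spec.lung_mixture])
    sds = np.array([c[2] for c in spec.lung_mixture])
    comp = rng.choice(len(weights), size=n_lung, p=weights)
    draws = mus[comp] + sds[comp] * rng.standard_normal(n_lung)
    if spec.gradient_slope != 0.0:
        draws = draws + spec.gradient_slope * (Y[lungs] - spec.body.center[1])
    vol[lungs] = draws

    # airway: wall painted first, then lumen carved
    lumen = np.zeros(spec.dims, dtype=bool)
    if spec.airway is not None:
        aw = spec.airway
        cx, cy, cz = spec.body.center
        lung_top = max(lg.center[2] + lg.semi_axes[2] for lg in spec.lungs)
        z_top = min(lung_top + aw.stem_above_lungs,
                    spec.body.center[2] + spec.body.semi_axes[2] - 2 * dz)
        carina_z = spec.lungs[0].center[2] + 0.25 * spec.lungs[0].semi_axes[2]
        r_out = aw.radius + aw.wall_thickness
        r_br = 0.8 * aw.radius
        r_br_out = r_br + aw.wall_thickness

        def v_cyl(r):  # vertical stem
            return (((X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2)
                    & (Z >= carina_z) & (Z <= z_top))

        def h_cyl(r, x0, x1):  # horizontal branch along x at carina height
            lo, hi = min(x0, x1), max(x0, x1)
            return (((Y - cy) ** 2 + (Z - carina_z) ** 2 <= r ** 2)
                    & (X >= lo) & (X <= hi))

        wall = v_cyl(r_out)
        lumen = v_cyl(aw.radius)
        for lg in spec.lungs:
            wall |= h_cyl(r_br_out, cx, lg.center[0])
            lumen |= h_cyl(r_br, cx, lg.center[0])
        wall &= ~lumen
        vol[wall] = spec.body_hu
        vol[lumen] = aw.lumen_hu

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.dims)

    if spec.airway is not None:
        lung_truth = lungs & ~wall & ~lumen
    else:
        lung_truth = lungs
    ct = CTVolume(vol.astype(np.float32), spec.spacing)
    return (ct,
            MaskVolume(lung_truth, spec.spacing),
            MaskVolume(lumen, spec.spacing))


# ---------------------------------------------------------------------------
# case-level cohort generator
# ---------------------------------------------------------------------------

_Z75 = norm.ppf(0.75)


def lognormal_from_quantiles(median: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) with the given median and upper quartile.

    The median is matched exactly; sigma comes from the upper quartile
    because a lower quartile near the zero bound is unstable on the log
    scale.
    """
    if median <= 0 or q3 <= median:
        raise ParameterError("need 0 < median < q3")
    return float(np.log(median)), float((np.log(q3) - np.log(median)) / _Z75)


def normal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Normal (mean, sd) from a printed median and interquartile range."""
    if q3 <= q1:
        raise ParameterError("need q1 < q3")
    return float(median), float((q3 - q1) / (2 * _Z75))


@dataclass
class EndpointModel:
    """Group-level sampling model for one densitometry endpoint."""
    kind: str               # "lognormal" | "normal"
    loc: float              # mu (log scale) or mean
    scale: float            # sigma

    def quantile(self, u):
        z = norm.ppf(u)
        if self.kind == "lognormal":
            return np.exp(self.loc + self.scale * z)
        return self.loc + self.scale * z


# printed group statistics used as calibration targets
_DEFAULT_ENDPOINTS = {
    "asphyxia": {
        "laa950": EndpointModel("lognormal", *lognormal_from_quantiles(3.1, 4.98)),
        "laa910": EndpointModel("lognormal", *lognormal_from_quantiles(4.8, 8.46)),
        "perc15": EndpointModel("normal", *normal_from_median_iqr(-816, -886, -745)),
    },
    "control": {
        "laa950": EndpointModel("lognormal", *lognormal_from_quantiles(1.7, 3.25)),
        "laa910": EndpointModel("lognormal", *lognormal_from_quantiles(2.8, 5.0)),
        "perc15": EndpointModel("normal", *normal_from_median_iqr(-775, -886, -690)),
    },
}

# choking cases present distinctly denser lungs; modelled as a subtype
# override of the Perc15 endpoint
_CH_PERC15 = EndpointModel("normal", *normal_from_median_iqr(-605, -665, -555))

_DEMOGRAPHICS = {
    # variable: (asphyxia (mean, sd), control (mean, sd), (lower, upper) truncation)
    "age": ((48.1, 15.2), (46.9, 12.4), (16.0, 80.0)),
    "height_cm": ((176.1, 10.4), (176.0, 9.6), (120.0, 220.0)),
    "weight_kg": ((75.9, 14.2), (88.1, 30.3), (30.0, 250.0)),
    "pmi_days": ((2.1, 1.0), (2.6, 1.1), (0.1, 5.0)),
    "volume_ml": ((2769.05, 952.57), (2484.81, 865.39), (300.0, 8000.0)),
}

_SEX_P_FEMALE = {"asphyxia": 3 / 20, "control": 5 / 21}
_SUBTYPE_COUNTS = {"HA": 9, "CH": 3, "LS": 1, "MS": 4, "SM": 3}  # per 20 cases
_CONTROL_CAUSES = ["cardiac"] * 8 + ["unknown_other"] * 6 + ["ketoacidosis"] * 4 + ["ich"] * 3


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic two-group cohort."""
    n_asphyxia: int = 20
    n_control: int = 21
    endpoints: dict = field(default_factory=lambda: {
        g: dict(models) for g, models in _DEFAULT_ENDPOINTS.items()})
    ch_perc15_override: EndpointModel | None = field(
        default_factory=lambda: _CH_PERC15)
    zero_effect: bool = False   # draw both groups from the control models
    seed: int = 0

    def __post_init__(self):
        if self.n_asphyxia <= 0 or self.n_control <= 0:
            raise ParameterError("group sizes must be positive")


def _allocate_subtypes(n: int) -> list[str]:
    """Spread asphyxia subtypes in the reference 9:3:1:4:3 proportions."""
    labels = list(_SUBTYPE_COUNTS)
    quotas = np.array([_SUBTYPE_COUNTS[s] for s in labels], dtype=float)
    ideal = quotas / quotas.sum() * n
    counts = np.floor(ideal).astype(int)
    rema = ideal - counts
    for i in np.argsort(-rema)[: n - counts.sum()]:
        counts[i] += 1
    out = []
    for lab, c in zip(labels, counts):
        out.extend([lab] * c)
    return out


def _trunc_draw(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def generate_cohort_measurements(spec: CohortSpec) -> list[CaseRecord]:
    """Draw a reproducible synthetic cohort of :class:`CaseRecord` objects."""
    rng = np.random.default_rng(spec.seed)
    endpoints = spec.endpoints
    if spec.zero_effect:
        endpoints = {"asphyxia": endpoints["control"], "control": endpoints["control"]}

    records = []
    groups = [("asphyxia", g) for g in _allocate_subtypes(spec.n_asphyxia)]
    groups += [("control", "control")] * spec.n_control
    for i, (arm, label) in enumerate(groups):
        models = endpoints[arm]
        u = rng.uniform()
        laa950 = float(models["laa950"].quantile(u))
        laa910 = float(max(models["laa910"].quantile(u), laa950))
        perc_model = models["perc15"]
        if (label == "CH" and not spec.zero_effect
                and spec.ch_perc15_override is not None):
            perc_model = spec.ch_perc15_override
        perc15 = float(perc_model.quantile(1.0 - u))  # comonotone decreasing
        laa950 = min(laa950, 100.0)
        laa910 = min(laa910, 100.0)

        demo = {}
        for var, (asp, ctl, (lo, hi)) in _DEMOGRAPHICS.items():
            mean, sd = asp if arm == "asphyxia" else ctl
            demo[var] = _trunc_draw(rng, mean, sd, lo, hi)
        sex = "F" if rng.uniform() < _SEX_P_FEMALE[arm] else "M"
        putrefaction = ["none", "mild", "moderate"][rng.choice(3, p=[0.5, 0.35, 0.15])]
        control_cause = (_CONTROL_CAUSES[i % len(_CONTROL_CAUSES)]
                         if arm == "control" else None)

        volume_ml = demo["volume_ml"]
        n_vox = int(round(volume_ml * 1000.0))
        dens = DensitometryResult(
            laa950=laa950, laa910=laa910, perc15=perc15,
            pd15=perc15 + 1000.0, volume_ml=volume_ml, n_voxels=n_vox,
            mean_hu=float(perc15 + 140.0 + 20.0 * rng.standard_normal()),
        )
        records.append(CaseRecord(
            case_id=f"{'A' if arm == 'asphyxia' else 'C'}{i:03d}",
            group=label, age=demo["age"], sex=sex,
            height_cm=demo["height_cm"], weight_kg=demo["weight_kg"],
            pmi_days=demo["pmi_days"], putrefaction=putrefaction,
            control_cause=control_cause, densitometry=dens,
        ))
    return records
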