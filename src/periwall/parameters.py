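"""Physical parameter space of the peri-arterial wall model.

The model describes a cylindrical artery wall made of three concentric porous
layers — inner layers (intima + media), adventitia, and perivascular adipose
tissue (PVAT) — irrigated by vasa vasorum (Starling-type distributed fluid
source) and drained by lymphatic vessels (uniform distributed sink).

This module defines the typed parameter containers, a distribution registry
from which Monte-Carlo parameter sets are drawn, and the multiplicative
factors that turn a healthy draw into an atherosclerotic one.  The shipped
``data/defaults.yaml`` is a documented default configuration assembled from
values reported in the literature for coronary arteries; it acts as the
package's synthetic-data generator.  Users with better site-specific
distributions substitute them via the same config schema.

Units: internal storage is SI.  Config files accept mmHg for pressures and
micrometres for lengths; conversion happens on load (see :mod:`periwall.units`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .units import MMHG, UM

logger = logging.getLogger(__name__)

HEALTHY = "healthy"
ATHEROSCLEROTIC = "atherosclerotic"


class ConfigurationError(ValueError):
    """Raised for malformed or unknown entries in a parameter config."""


class SamplingError(RuntimeError):
    """Raised when a distribution cannot produce an admissible draw."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Geometry:
    """Radial build of the wall, in metres.

    ``r_lu`` is the lumen radius; ``t_i``, ``t_a``, ``t_p`` the thicknesses of
    the inner layers, adventitia and PVAT.  Derived radii: ``r_ia`` (media–
    adventitia boundary, the EEL), ``r_ap`` (adventitia–PVAT boundary),
    ``r_ext`` (outer PVAT).
    """

    r_lu: float
    t_i: float
    t_a: float
    t_p: float

    def __post_init__(self) -> None:
        for name in ("r_lu", "t_i", "t_a", "t_p"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"Geometry.{name} must be strictly positive")

    @property
    def r_ia(self) -> float:
        return self.r_lu + self.t_i

    @property
    def r_ap(self) -> float:
        return self.r_ia + self.t_a

    @property
    def r_ext(self) -> float:
        return self.r_ap + self.t_p


@dataclass(frozen=True)
class TissueProperties:
    """Darcy permeabilities (m²) per layer and interstitial fluid viscosity (Pa·s)."""

    k_i: float
    k_a: float
    k_p: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("k_i", "k_a", "k_p", "mu"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"TissueProperties.{name} must be strictly positive")


@dataclass(frozen=True)
class VasaParams:
    """Vasa vasorum microvessel properties.

    ``l_pv``: endothelial hydraulic conductivity (m·Pa⁻¹·s⁻¹); ``N_v``: vessel
    count per tissue cross-sectional area (m⁻²); ``d_v``: capillary diameter
    (m); ``p_v``: luminal hydrostatic pressure (Pa); ``pi_v`` / ``pi_t``:
    plasma / tissue osmotic pressures (Pa); ``sigma``: osmotic reflection
    coefficient; ``kappa_v``: solute diffusive permeability of the vasa
    endothelium (m·s⁻¹).
    """

    l_pv: float
    N_v: float
    d_v: float
    p_v: float
    pi_v: float
    pi_t: float
    sigma: float
    kappa_v: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("VasaParams.sigma must lie in [0, 1]")
        for name in ("l_pv", "N_v", "d_v", "kappa_v"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"VasaParams.{name} must be non-negative")

    @property
    def a_bar_v(self) -> float:
        """Vasa surface-area density Ā_v = N_v·π·d_v (m⁻¹)."""
        return self.N_v * math.pi * self.d_v

    def delta_p(self, p: float | np.ndarray) -> float | np.ndarray:
        """Starling driving pressure δP(p) = p_v − p − σ(π_t − π_v), in Pa.

        Positive δP drives filtration from the vasa lumen into the tissue.
        """
        return self.p_v - p - self.sigma * (self.pi_t - self.pi_v)


@dataclass(frozen=True)
class LymphParams:
    """Lymphatic drainage properties.

    ``N_l``: vessel count per cross-sectional area (m⁻²); ``q_tilde_l``:
    drainage flux per unit vessel length (m²·s⁻¹); ``l_bar_l``: vessel length
    per unit radial thickness (dimensionless, conventionally 1).
    """

    N_l: float
    q_tilde_l: float
    l_bar_l: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N_l", "q_tilde_l", "l_bar_l"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"LymphParams.{name} must be non-negative")

    @property
    def sink_rate(self) -> float:
        """Volumetric drainage rate s_ℓ = N_ℓ·q̃_ℓ·l̄_ℓ (s⁻¹)."""
        return self.N_l * self.q_tilde_l * self.l_bar_l


@dataclass(frozen=True)
class ParameterSet:
    """One complete physical configuration of the wall (SI units)."""

    geometry: Geometry
    tissue: TissueProperties
    vasa: VasaParams
    lymph: LymphParams
    p_lu: float
    condition: str = HEALTHY
    sample_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in (HEALTHY, ATHEROSCLEROTIC):
            raise ValueError(f"unknown condition {self.condition!r}")

    def replace(self, **flat: float) -> "ParameterSet":
        """Return a copy with dotted-path fields replaced, e.g. ``tissue.k_i``."""
        values = self.to_flat_dict()
        for path, value in flat.items():
            if path not in values:
                raise KeyError(f"unknown parameter path {path!r}")
            values[path] = value
        return build_parameter_set(
            values,
            condition=self.condition,
            sample_id=self.sample_id,
            seed=self.seed,
        )

    def to_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for section in ("geometry", "tissue", "vasa", "lymph"):
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                out[f"{section}.{f.name}"] = getattr(obj, f.name)
        out["boundary.p_lu"] = self.p_lu
        return out


def build_parameter_set(
    values: Mapping[str, float],
    condition: str = HEALTHY,
    sample_id: int = 0,
    seed: int = 0,
) -> ParameterSet:
    """Assemble a :class:`ParameterSet` from a flat ``{path: SI value}`` mapping.

    ``tissue.k_p`` falls back to ``tissue.k_a`` when absent: the PVAT lies
    beyond the dominant resistances, so its permeability is secondary and is
    tied to the adventitial one unless specified.
    """
    v = dict(values)
    if "tissue.k_p" not in v or v["tissue.k_p"] is None:
        v["tissue.k_p"] = v["tissue.k_a"]

    def sect(name: str, cls):
        kwargs = {}
        for f in dataclasses.fields(cls):
            path = f"{name}.{f.name}"
            if path in v:
                kwargs[f.name] = v[path]
        return cls(**kwargs)

    return ParameterSet(
        geometry=sect("geometry", Geometry),
        tissue=sect("tissue", TissueProperties),
        vasa=sect("vasa", VasaParams),
        lymph=sect("lymph", LymphParams),
        p_lu=v["boundary.p_lu"],
        condition=condition,
        sample_id=sample_id,
        seed=seed,
    )


def vasa_area_density(vasa: VasaParams) -> float:
    """Surface-area density of vasa vasorum Ā_v = N_v·π·d_v (m⁻¹).

    Vasa density is usually reported as a vessel count per cross-sectional
    area; the exchange surface per tissue volume is approximated by the total
    vessel circumference per unit cross-sectional area.
    """
    return vasa.a_bar_v


# --------------------------------------------------------------------------
# schema: parameter paths, units, admissibility
# --------------------------------------------------------------------------

# config-file unit per path: "um" (µm → m), "mmhg" (mmHg → Pa), or None (SI)
_PATH_UNITS: dict[str, str | None] = {
    "geometry.r_lu": "um",
    "geometry.t_i": "um",
    "geometry.t_a": "um",
    "geometry.t_p": "um",
    "tissue.k_i": None,
    "tissue.k_a": None,
    "tissue.k_p": None,
    "tissue.mu": None,
    "vasa.l_pv": None,
    "vasa.N_v": None,
    "vasa.d_v": "um",
    "vasa.p_v": "mmhg",
    "vasa.pi_v": "mmhg",
    "vasa.pi_t": "mmhg",
    "vasa.sigma": None,
    "vasa.kappa_v": None,
    "lymph.N_l": None,
    "lymph.q_tilde_l": None,
    "lymph.l_bar_l": None,
    "boundary.p_lu": "mmhg",
}

SCHEMA_PATHS: tuple[str, ...] = tuple(_PATH_UNITS)

# (lower bound, bound strict?, upper bound) in SI; None = unbounded.
# Pressures may take either sign and are unconstrained.
_PATH_BOUNDS: dict[str, tuple[float | None, bool, float | None]] = {
    **{p: (0.0, True, None) for p in (
        "geometry.r_lu", "geometry.t_i", "geometry.t_a", "geometry.t_p",
        "tissue.k_i", "tissue.k_a", "tissue.k_p", "tissue.mu",
    )},
    **{p: (0.0, False, None) for p in (
        "vasa.l_pv", "vasa.N_v", "vasa.d_v", "vasa.kappa_v",
        "lymph.N_l", "lymph.q_tilde_l", "lymph.l_bar_l",
    )},
    "vasa.sigma": (0.0, False, 1.0),
    "vasa.p_v": (None, False, None),
    "vasa.pi_v": (None, False, None),
    "vasa.pi_t": (None, False, None),
    "boundary.p_lu": (None, False, None),
}

_UNIT_FACTORS = {"um": UM, "mmhg": MMHG, None: 1.0}


def _admissible(path: str, x: float) -> bool:
    lo, strict, hi = _PATH_BOUNDS[path]
    if lo is not None and (x <= lo if strict else x < lo):
        return False
    if hi is not None and x > hi:
        return False
    return True


# --------------------------------------------------------------------------
# distributions
# --------------------------------------------------------------------------

_KINDS = ("fixed", "gaussian", "uniform", "loguniform")
_REQUIRED = {
    "fixed": ("value",),
    "gaussian": ("mean", "sd"),
    "uniform": ("low", "high"),
    "loguniform": ("low", "high"),
}

#: bound on the rejection loop for Gaussian draws violating positivity
MAX_REJECTION_DRAWS = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling rule for one parameter path.

    ``params`` holds SI-converted scalars keyed per ``kind``: ``value``
    (fixed), ``mean``/``sd`` (gaussian), ``low``/``high`` (uniform and
    loguniform).  Gaussian draws violating the target parameter's
    admissibility bounds are rejected and redrawn (never truncated at the
    bound, which would place probability mass exactly at zero).
    """

    name: str
    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _PATH_UNITS:
            raise ConfigurationError(f"unknown parameter name {self.name!r}")
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"{self.name}: unknown distribution kind {self.kind!r}"
            )
        missing = [k for k in _REQUIRED[self.kind] if k not in self.params]
        if missing:
            raise ConfigurationError(
                f"{self.name}: {self.kind} distribution missing {missing}"
            )
        if self.kind in ("uniform", "loguniform"):
            if not self.params["low"] < self.params["high"]:
                raise ConfigurationError(f"{self.name}: requires low < high")
        if self.kind == "loguniform" and self.params["low"] <= 0.0:
            raise ConfigurationError(f"{self.name}: loguniform requires low > 0")
        if self.kind == "gaussian" and self.params["sd"] < 0.0:
            raise ConfigurationError(f"{self.name}: gaussian requires sd >= 0")

    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed" or (
            self.kind == "gaussian" and self.params["sd"] == 0.0
        )

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.kind == "fixed":
            x = p["value"]
            if not _admissible(self.name, x):
                raise SamplingError(f"fixed value for {self.name} is inadmissible")
            return x
        if self.kind == "uniform":
            return float(rng.uniform(p["low"], p["high"]))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"]))))
        # gaussian with rejection
        for _ in range(MAX_REJECTION_DRAWS):
            x = float(rng.normal(p["mean"], p["sd"]))
            if _admissible(self.name, x):
                return x
        raise SamplingError(
            f"no admissible gaussian draw for {self.name} "
            f"(mean={p['mean']:g}, sd={p['sd']:g}) in {MAX_REJECTION_DRAWS} attempts"
        )

    def rejection_fraction(self) -> float:
        """Probability mass a gaussian spec loses to rejection (0 otherwise)."""
        if self.kind != "gaussian" or self.params["sd"] == 0.0:
            return 0.0
        from scipy.stats import norm

        lo, _, hi = _PATH_BOUNDS[self.name]
        frac = 0.0
        if lo is not None:
            frac += norm.cdf(lo, self.params["mean"], self.params["sd"])
        if hi is not None:
            frac += norm.sf(hi, self.params["mean"], self.params["sd"])
        return float(frac)


@dataclass(frozen=True)
class AtheroFactors:
    """Multiplicative atherosclerotic modification factors.

    Each entry maps a parameter path to a :class:`DistributionSpec` drawn in
    *factor* space (dimensionless); a factor of 1 leaves the parameter
    unchanged.  Absent paths are implicitly 1.
    """

    factors: dict[str, DistributionSpec] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {name: _sample_factor(spec, rng) for name, spec in self.factors.items()}


def _sample_factor(spec: DistributionSpec, rng: np.random.Generator) -> float:
    # factors are dimensionless multipliers; reuse the distribution machinery but
    # without parameter-path admissibility (positivity is enforced directly)
    p = spec.params
    if spec.kind == "fixed":
        return float(p["value"])
    if spec.kind == "uniform":
        return float(rng.uniform(p["low"], p["high"]))
    if spec.kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"]))))
    for _ in range(MAX_REJECTION_DRAWS):
        x = float(rng.normal(p["mean"], p["sd"]))
        if x > 0.0:
            return x
    raise SamplingError(f"no positive factor draw for {spec.name}")


# directions reported for atherosclerotic remodelling: thicker inner layers and
# adventitia, more permeable inner layers, denser/more conductive vasa vasorum,
# denser but slower-draining lymphatics.
_EXPECTED_FACTOR_DIRECTIONS = {
    "geometry.t_i": "up",
    "geometry.t_a": "up",
    "tissue.k_i": "up",
    "vasa.N_v": "up",
    "vasa.l_pv": "up",
    "lymph.N_l": "up",
    "lymph.q_tilde_l": "down",
}


# --------------------------------------------------------------------------
# registry and config loading
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterRegistry:
    """Complete set of distributions plus atherosclerotic factors."""

    distributions: dict[str, DistributionSpec]
    athero: AtheroFactors

    def spec(self, path: str) -> DistributionSpec:
        return self.distributions[path]

    def with_overrides(self, **specs: DistributionSpec) -> "ParameterRegistry":
        d = dict(self.distributions)
        for path, spec in specs.items():
            d[path] = spec
        return ParameterRegistry(d, self.athero)

    def fixed(self, **values: float) -> "ParameterRegistry":
        """Registry copy with the named paths pinned to SI values."""
        return self.with_overrides(
            **{
                p: DistributionSpec(p, "fixed", {"value": v})
                for p, v in values.items()
            }
        )


def _default_config_text() -> str:
    return resources.files("periwall").joinpath("data/defaults.yaml").read_text()


def _convert_leaf(path: str, leaf: Any, unit_factor: float) -> DistributionSpec:
    if isinstance(leaf, (int, float)):
        return DistributionSpec(path, "fixed", {"value": float(leaf) * unit_factor})
    if not isinstance(leaf, Mapping):
        raise ConfigurationError(f"{path}: expected scalar or mapping, got {leaf!r}")
    d = dict(leaf)
    kind = d.pop("kind", None)
    if kind is None:
        raise ConfigurationError(f"{path}: distribution mapping needs a 'kind'")
    params = {k: float(v) * unit_factor for k, v in d.items()}
    return DistributionSpec(path, str(kind), params)


def load_distributions(
    config_source: str | Mapping[str, Any] | None = None,
) -> ParameterRegistry:
    """Load the distribution registry, optionally overriding the defaults.

    ``config_source`` may be ``None`` (shipped defaults), a path to a YAML
    file, a YAML string, or an already-parsed mapping.  The config has one
    section per parameter group (``geometry``, ``tissue``, ``vasa``,
    ``lymph``, ``boundary``) plus ``athero_factors``; every leaf is either a
    scalar (fixed) or a ``{kind: ..., ...}`` mapping.  Pressures are given in
    mmHg and lengths in µm; entries missing from a user config fall back to
    the shipped defaults with a logged warning.
    """
    defaults = yaml.safe_load(_default_config_text())

    if config_source is None:
        user: dict[str, Any] = {}
    elif isinstance(config_source, Mapping):
        user = dict(config_source)
    else:
        text = str(config_source)
        if "\n" not in text and (text.endswith((".yaml", ".yml", ".json")) or "/" in text):
            with open(text) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            parsed = yaml.safe_load(text)
            if not isinstance(parsed, Mapping):
                raise ConfigurationError("config did not parse to a mapping")
            user = dict(parsed)

    dists: dict[str, DistributionSpec] = {}
    sections = ("geometry", "tissue", "vasa", "lymph", "boundary")
    for section in sections:
        merged = dict(defaults.get(section, {}))
        user_section = user.get(section, {})
        if not isinstance(user_section, Mapping):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        for key in user_section:
            if f"{section}.{key}" not in _PATH_UNITS:
                raise ConfigurationError(f"unknown parameter name {section}.{key}")
        merged.update(user_section)
        for key, leaf in merged.items():
            path = f"{section}.{key}"
            if path not in _PATH_UNITS:
                raise ConfigurationError(f"unknown parameter name {path}")
            dists[path] = _convert_leaf(path, leaf, _UNIT_FACTORS[_PATH_UNITS[path]])

    # every schema path except the optional k_p must be covered
    for path in SCHEMA_PATHS:
        if path not in dists and path != "tissue.k_p":
            logger.warning("no distribution for %s; using in-package default", path)
            raise ConfigurationError(f"defaults incomplete: missing {path}")

    unknown_sections = set(user) - set(sections) - {"athero_factors"}
    if unknown_sections:
        raise ConfigurationError(f"unknown config sections {sorted(unknown_sections)}")

    af_raw = dict(defaults.get("athero_factors", {}))
    af_raw.update(user.get("athero_factors", {}) or {})
    factors: dict[str, DistributionSpec] = {}
    for path, leaf in af_raw.items():
        if path not in _PATH_UNITS:
            raise ConfigurationError(f"unknown parameter name in athero_factors: {path}")
        factors[path] = _convert_leaf(path, leaf, 1.0)  # factors are dimensionless

    return ParameterRegistry(distributions=dists, athero=AtheroFactors(factors))


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def sample_parameter_sets(
    registry: ParameterRegistry,
    n: int,
    seed: int,
    condition: str = HEALTHY,
) -> list[ParameterSet]:
    """Draw ``n`` parameter sets, reproducibly for a given ``seed``.

    Each sample uses its own child random stream, so sample ``i`` is the same
    whatever ``n`` is.  Gaussian draws that violate admissibility are redrawn;
    specs losing more than 1 % of their mass to rejection are logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for spec in registry.distributions.values():
        frac = spec.rejection_fraction()
        if frac > 0.01:
            logger.warning(
                "distribution for %s loses %.1f%% of its mass to rejection",
                spec.name,
                100 * frac,
            )
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        values = {p: spec.sample(rng) for p, spec in registry.distributions.items()}
        out.append(
            build_parameter_set(values, condition=condition, sample_id=i, seed=seed)
        )
    return out


def baseline_values(registry: ParameterRegistry) -> dict[str, float]:
    """Central value of every distribution (mean / midpoint / geometric mean)."""
    out: dict[str, float] = {}
    for path, spec in registry.distributions.items():
        p = spec.params
        if spec.kind == "fixed":
            out[path] = p["value"]
        elif spec.kind == "gaussian":
            out[path] = p["mean"]
        elif spec.kind == "uniform":
            out[path] = 0.5 * (p["low"] + p["high"])
        else:  # loguniform
            out[path] = float(np.sqrt(p["low"] * p["high"]))
    return out


def baseline_parameter_set(registry: ParameterRegistry, **overrides: float) -> ParameterSet:
    """Parameter set at the centre of every distribution (SI overrides allowed)."""
    vals = baseline_values(registry)
    vals.update(overrides)
    return build_parameter_set(vals)


def apply_athero_factors(
    ps: ParameterSet,
    factors: AtheroFactors,
    seed: int | np.random.Generator,
) -> ParameterSet:
    """Turn a healthy draw into its atherosclerotic counterpart.

    Factors multiply the healthy values; the condition flag flips to
    ``atherosclerotic``.  A drawn factor moving a parameter against the
    direction reported for atherosclerotic remodelling raises a validation
    warning (the draw is kept: the distributions own the physics).
    """
    if ps.condition != HEALTHY:
        raise ValueError("apply_athero_factors expects a healthy parameter set")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    drawn = factors.sample(rng)
    flat = ps.to_flat_dict()
    for path, factor in drawn.items():
        direction = _EXPECTED_FACTOR_DIRECTIONS.get(path)
        if direction == "up" and factor < 1.0 or direction == "down" and factor > 1.0:
            warnings.warn(
                f"athero factor for {path} ({factor:.3g}) moves against the "
                f"direction reported for atherosclerosis ({direction})",
                stacklevel=2,
            )
        flat[path] = flat[path] * factor
    return build_parameter_set(
        flat,
        condition=ATHEROSCLEROTIC,
        sample_id=ps.sample_id,
        seed=ps.seed,
    )


# --------------------------------------------------------------------------
# tabular export
# --------------------------------------------------------------------------


def parameter_sets_to_frame(sets: Iterable[ParameterSet]) -> pd.DataFrame:
    """One row per parameter set; columns are parameter paths, SI units."""
    rows = []
    for ps in sets:
        row: dict[str, Any] = {"sample_id": ps.sample_id, "condition": ps.condition}
        row.update(ps.to_flat_dict())
        rows.append(row)
    return pd.DataFrame(rows)
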